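"""Genotype quality control: call rate, Hardy-Weinberg, minor allele frequency.

The pipeline order is animal call rate -> SNP call rate -> HWE exact
test -> MAF, each with strictly-below removal semantics, and every
removed item records the first filter it failed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeMatrix


class QcError(ValueError):
    pass


@dataclass
class QcReport:
    removed_animals: list = field(default_factory=list)
    removed_snps: list = field(default_factory=list)  # (snp_id, reason)
    thresholds: dict = field(default_factory=dict)

    def merge(self, other: "QcReport") -> "QcReport":
        return QcReport(
            self.removed_animals + other.removed_animals,
            self.removed_snps + other.removed_snps,
            {**self.thresholds, **other.thresholds},
        )

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed_snps, columns=["snp", "reason"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "removed_animals": [str(a) for a in self.removed_animals],
                    "removed_snps": [[str(s), r] for s, r in self.removed_snps],
                    "thresholds": self.thresholds,
                },
                fh,
                indent=1,
            )


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts (of the same parity) whose conditional
    probability does not exceed that of the observed configuration.
    Monomorphic SNPs return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        return 1.0
    hets = np.arange(nA % 2, min(nA, na) + 1, 2)
    aa_counts = (nA - hets) // 2
    # log P(het | n, nA) up to a constant shared by all configurations
    logp = hets * np.log(2.0) - (
        gammaln(aa_counts + 1) + gammaln(hets + 1) + gammaln((na - hets) // 2 + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == n_Aa][0]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-12)].sum()))


def genotype_counts(calls: np.ndarray) -> np.ndarray:
    """Per-SNP (n_AA, n_Aa, n_aa) counts over non-missing calls,
    with AA the reference homozygote (call 0)."""
    return np.stack(
        [np.nansum(calls == k, axis=0) for k in (0.0, 1.0, 2.0)], axis=1
    ).astype(int)


def filter_call_rate(
    g: GenotypeMatrix, min_rate: float = 0.90
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove animals, then SNPs, with a non-missing fraction < min_rate."""
    if not 0.0 < min_rate <= 1.0:
        raise ValueError("min_rate must be in (0, 1]")
    ok = ~g.missing_mask()
    animal_rate = ok.mean(axis=1) if g.n_snps else np.ones(g.n_animals)
    keep_a = animal_rate >= min_rate
    report = QcReport(
        removed_animals=list(g.animal_ids[~keep_a]), thresholds={"min_call_rate": min_rate}
    )
    snp_rate = ok[keep_a].mean(axis=0) if keep_a.any() else np.zeros(g.n_snps)
    keep_s = snp_rate >= min_rate
    report.removed_snps += [(s, "call_rate") for s in g.snp_ids[~keep_s]]
    out = GenotypeMatrix(
        g.animal_ids[keep_a], g.snp_ids[keep_s], g.calls[np.ix_(keep_a, keep_s)]
    )
    if out.n_animals == 0 or out.n_snps == 0:
        raise QcError("call-rate filtering removed all animals or all SNPs")
    return out, report


def filter_hwe(
    g: GenotypeMatrix, p_threshold: float = 1e-15
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs whose HWE exact-test p-value is < p_threshold."""
    counts = genotype_counts(g.calls)
    pvals = np.array([hwe_exact_test(*c) if c.sum() else 1.0 for c in counts])
    keep = pvals >= p_threshold
    report = QcReport(
        removed_snps=[(s, "hwe") for s in g.snp_ids[~keep]],
        thresholds={"hwe_p": p_threshold},
    )
    return GenotypeMatrix(g.animal_ids, g.snp_ids[keep], g.calls[:, keep]), report


def filter_maf(
    g: GenotypeMatrix, min_maf: float = 0.005
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs with minor allele frequency < min_maf (non-missing calls)."""
    p = g.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    keep = ~np.isnan(maf) & (maf >= min_maf)
    report = QcReport(
        removed_snps=[(s, "maf") for s in g.snp_ids[~keep]],
        thresholds={"min_maf": min_maf},
    )
    return GenotypeMatrix(g.animal_ids, g.snp_ids[keep], g.calls[:, keep]), report


def run_qc(
    g: GenotypeMatrix,
    min_call_rate: float = 0.90,
    hwe_p: float = 1e-15,
    min_maf: float = 0.005,
) -> tuple[GenotypeMatrix, QcReport]:
    """Full QC pipeline: call rates, then HWE, then MAF."""
    g1, r1 = filter_call_rate(g, min_call_rate)
    g2, r2 = filter_hwe(g1, hwe_p)
    g3, r3 = filter_maf(g2, min_maf)
    return g3, r1.merge(r2).merge(r3)
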