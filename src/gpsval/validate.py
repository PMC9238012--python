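"""Forward validation against progeny yield deviations (PYD).

A validation animal is a post-cutoff animal with no parent in the
validation population and at least one phenotyped progeny.  Its PYD per
trait is the average over phenotyped progeny of the progeny's
precorrected phenotype minus half the mate's EBV, a proxy for half the
animal's breeding value.  (G)EBV and PYD are rescaled to the common
genetic base of the first training generations, and accuracy (weighted
Pearson correlation), level bias (weighted mean of PYD - GEBV/2 in
additive genetic SD units; negative = GEBV overestimated) and
dispersion bias (weighted regression slope of PYD on GEBV; 0.5 expected
without selection) are computed with PYD-reliability weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .datatypes import StudyDataset
from .mme import EvaluationResult


def select_validation_animals(data: StudyDataset) -> np.ndarray:
    """Animal ids meeting both validation requirements."""
    ped = data.pedigree
    post = ped.cohort > data.training_cutoff
    post_ids = set(ped.ids[post].tolist())
    frame = ped.frame
    parent_in_val = frame["sire"].isin(post_ids) | frame["dam"].isin(post_ids)
    candidates = ped.ids[post & ~parent_in_val.to_numpy()]

    phenotyped = set(data.phenotypes["animal"])
    counts = {}
    for _, row in frame[frame["sire"].isin(candidates) | frame["dam"].isin(candidates)].iterrows():
        if row["animal"] in phenotyped:
            for p in (row["sire"], row["dam"]):
                counts[p] = counts.get(p, 0) + 1
    out = np.array([a for a in candidates if counts.get(a, 0) > 0])
    if len(out) == 0:
        raise ValueError("no validation animals: empty validation set")
    return out


def compute_pyd(
    full_data: StudyDataset,
    mate_ebv_source: EvaluationResult,
    validation_animals=None,
) -> pd.DataFrame:
    """PYD per validation animal and trait from the full (pre-removal) data.

    Progeny whose other parent is unknown are skipped and counted in
    ``n_skipped``.  Mate EBV come from the mean-only pedigree model on
    the full data (the same model that defines the PYD scale).
    """
    if validation_animals is None:
        validation_animals = select_validation_animals(full_data)
    vset = set(np.asarray(validation_animals).tolist())
    ped = full_data.pedigree.frame
    ebv = mate_ebv_source.ebv
    phen = full_data.phenotypes
    traits = full_data.traits

    yc = phen.set_index(["animal", "trait"])["value"]
    rows = []
    prog = ped[ped["sire"].isin(vset) | ped["dam"].isin(vset)]
    terms: dict = {}
    skipped: dict = {}
    for _, r in prog.iterrows():
        for parent, mate in ((r["sire"], r["dam"]), (r["dam"], r["sire"])):
            if parent not in vset:
                continue
            for trait in traits:
                key = (r["animal"], trait)
                if key not in yc.index:
                    continue
                if mate == 0 or mate not in ebv.index:
                    skipped[(parent, trait)] = skipped.get((parent, trait), 0) + 1
                    continue
                terms.setdefault((parent, trait), []).append(
                    yc.loc[key] - 0.5 * ebv.loc[mate, trait]
                )
    for (animal, trait), vals in terms.items():
        rows.append(
            {
                "animal": animal,
                "trait": trait,
                "pyd": float(np.mean(vals)),
                "n_progeny": len(vals),
                "n_skipped": skipped.get((animal, trait), 0),
            }
        )
    return pd.DataFrame(rows)


def pyd_reliability(n, h2):
    """Approximate reliability of a PYD from n half-sib progeny:
    (n h2 / 4) / (1 + (n - 1) h2 / 4)."""
    n = np.asarray(n, dtype=float)
    if (n < 1).any():
        raise ValueError("n_progeny must be >= 1")
    if not np.all((0.0 <= np.asarray(h2)) & (np.asarray(h2) <= 1.0)):
        raise ValueError("h2 must be in [0, 1]")
    return 0.25 * n * h2 / (1.0 + 0.25 * (n - 1.0) * h2)


def pyd_reliability_full_sib(n, h2):
    """Reliability variant treating all progeny as full sibs:
    (n h2 / 2) / (1 + (n - 1) h2 / 2)."""
    n = np.asarray(n, dtype=float)
    return 0.5 * n * h2 / (1.0 + 0.5 * (n - 1.0) * h2)


def base_animals(data: StudyDataset, n_base_cohorts: int = 3) -> np.ndarray:
    """All animals of the first ``n_base_cohorts`` training generations."""
    ped = data.pedigree
    return ped.ids[ped.cohort < n_base_cohorts]


def rescale_to_base(
    pyd: pd.DataFrame,
    trait: str,
    evaluation: EvaluationResult,
    pyd_model: EvaluationResult,
    base_ids: np.ndarray,
) -> pd.DataFrame:
    """Express PYD and (G)EBV against the common early-generation base.

    PYD_i -> PYD_i - mean(base EBV of the PYD model) / 2;
    GEBV_i -> GEBV_i - mean(base (G)EBV of the evaluation).
    """
    if len(base_ids) == 0:
        raise ValueError("empty genetic-base set")
    sub = pyd[pyd["trait"] == trait].copy()
    pyd_base = pyd_model.ebv.loc[pyd_model.ebv.index.intersection(base_ids), trait].mean()
    eval_base = evaluation.ebv.loc[evaluation.ebv.index.intersection(base_ids), trait].mean()
    keep = sub["animal"].isin(evaluation.ebv.index)
    sub = sub[keep]
    sub["pyd_rescaled"] = sub["pyd"] - 0.5 * pyd_base
    sub["gebv_rescaled"] = (
        evaluation.ebv.loc[sub["animal"], trait].to_numpy() - eval_base
    )
    return sub


@dataclass
class ValidationMetrics:
    accuracy: float
    accuracy_se: float
    level_bias: float
    level_bias_se: float
    dispersion: float
    dispersion_se: float
    n_validation: int
    weighting: str = "half_sib_reliability"


def weighted_metrics(
    pyd: np.ndarray,
    gebv: np.ndarray,
    weights: np.ndarray,
    genetic_sd: float,
    weighting: str = "half_sib_reliability",
) -> ValidationMetrics:
    """Accuracy, level bias and dispersion bias with standard errors.

    Accuracy SE comes from the Fisher-z interval at the effective sample
    size (sum w)^2 / sum w^2; the level-bias SE is the weighted-mean SE
    sqrt(sum w^2 (x - xbar_w)^2) / sum w; the dispersion SE is the WLS
    slope SE.
    """
    pyd, gebv, w = (np.asarray(a, dtype=float) for a in (pyd, gebv, weights))
    if len(pyd) < 3:
        raise ValueError("need at least 3 validation pairs")
    if np.ptp(gebv) == 0:
        raise ValueError("zero-variance GEBV")
    wsum = w.sum()
    xm, ym = (w * gebv).sum() / wsum, (w * pyd).sum() / wsum
    cov = (w * (gebv - xm) * (pyd - ym)).sum()
    r = cov / np.sqrt((w * (gebv - xm) ** 2).sum() * (w * (pyd - ym) ** 2).sum())
    n_eff = wsum**2 / (w**2).sum()
    if n_eff > 3:
        z, half = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)), 1.959964 / np.sqrt(n_eff - 3)
        r_se = (np.tanh(z + half) - np.tanh(z - half)) / (2 * 1.959964)
    else:
        r_se = np.nan

    diff = pyd - 0.5 * gebv
    dbar = (w * diff).sum() / wsum
    d_se = np.sqrt((w**2 * (diff - dbar) ** 2).sum()) / wsum

    wls = sm.WLS(pyd, sm.add_constant(gebv), weights=w).fit()
    return ValidationMetrics(
        accuracy=float(r),
        accuracy_se=float(r_se),
        level_bias=float(dbar / genetic_sd),
        level_bias_se=float(d_se / genetic_sd),
        dispersion=float(wls.params[1]),
        dispersion_se=float(wls.bse[1]),
        n_validation=len(pyd),
        weighting=weighting,
    )


@dataclass
class Comparison:
    z: float
    p_value: float
    different: bool


def compare_estimates(a: float, se_a: float, b: float, se_b: float, alpha: float = 0.05) -> Comparison:
    """One-tailed two-sample z/t comparison of two independent estimates."""
    denom = float(np.hypot(se_a, se_b))
    if denom == 0:
        raise ValueError("both standard errors are zero")
    z = (a - b) / denom
    p = float(1.0 - norm.cdf(abs(z)))
    return Comparison(float(z), p, p < alpha)
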