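"""Synthetic multi-generation breeding program with genomic preselection.

Emulates the data structure of a closed pig line under truncation
selection: discrete cohorts, multi-trait phenotypes with a fixed batch
effect and a non-genetic litter effect, an additive SNP architecture
gene-dropped from HWE founders, selective genotyping, and parents
truncation-selected each generation on an index of current-information
(G)EBV.  Founder cohorts form unknown-parent groups.  The last cohort
consists of progeny of the validation generation and exists to provide
progeny yield deviations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .datatypes import ScenarioSpec, StudyDataset, TraitCovariances
from .genotypes import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree


@dataclass
class SimConfig:
    """Breeding-program parameters.

    Trait variances are on a phenotypic-variance-1 scale: additive
    variance h2, litter variance ``litter_var``, residual the rest.
    The fixed batch effect sits on top of that scale.

    The program has two phases.  The first ``historic_generations``
    offspring cohorts emulate the era before genomic preselection:
    replacement-sized litters (``historic_litter_size``), parents chosen
    by ``historic_selection`` (default random), no genotyping.  Later
    cohorts are the modern phase: full litters, selective genotyping
    from cohort ``genotyping_start`` on, and truncation preselection on
    the index of ``selection_on`` information — random parent choice,
    true breeding values, pedigree EBV, or ssGBLUP GEBV (the first
    modern generation falls back to pedigree EBV when no informative
    genotypes exist yet).
    """

    n_founders: int = 200
    founder_male_fraction: float = 0.3
    n_generations: int = 5  # offspring cohorts 1..n; last is validation progeny
    historic_generations: int = 2
    n_snps: int = 2000
    maf_range: tuple = (0.05, 0.5)
    traits: tuple = ("adg_test", "adg_life", "backfat", "loin_depth")
    h2: tuple = (0.25, 0.30, 0.50, 0.60)
    genetic_corr: float = 0.3
    residual_corr: float = 0.2
    litter_var: float = 0.10
    batch_sd: float = 0.5
    batches_per_cohort: int = 4
    n_sires: int = 35
    n_dams: int = 140
    litter_size: int = 5
    historic_litter_size: int = 2
    selection_on: str = "ssgblup"  # random | tbv | pblup | ssgblup
    historic_selection: str = "random"
    index_weights: tuple | None = None
    genotyping_start: int = 2  # first cohort with genotyped animals
    genotyping_rate: float = 0.6
    phenotyping_rate: float = 0.95
    missing_call_rate: float = 0.01

    def __post_init__(self):
        if len(self.h2) != len(self.traits):
            raise ValueError("one h2 per trait required")
        if self.n_generations < 3:
            raise ValueError("need >= 3 generations: training, validation, progeny")
        if self.historic_generations >= self.n_generations - 1:
            raise ValueError("historic phase must end before the validation generation")
        for sel in (self.selection_on, self.historic_selection):
            if sel not in ("random", "tbv", "pblup", "ssgblup"):
                raise ValueError(f"unknown selection rule {sel!r}")
        if not all(0.0 < h < 1.0 - self.litter_var + 1e-12 for h in self.h2):
            raise ValueError("h2 + litter_var must stay below 1")

    def covariances(self) -> TraitCovariances:
        t = len(self.traits)
        h2 = np.asarray(self.h2)
        su = np.sqrt(h2)
        se = np.sqrt(1.0 - h2 - self.litter_var)
        Cg = np.full((t, t), self.genetic_corr) + (1 - self.genetic_corr) * np.eye(t)
        Cr = np.full((t, t), self.residual_corr) + (1 - self.residual_corr) * np.eye(t)
        G = Cg * np.outer(su, su)
        R = Cr * np.outer(se, se)
        return TraitCovariances(
            list(self.traits), G, R, {"litter": np.full(t, self.litter_var)}
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for k in ("maf_range", "traits", "h2", "index_weights"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def _selection_index(ebv: pd.DataFrame, weights) -> pd.Series:
    """Sum of standardised per-trait EBV with the given weights."""
    z = (ebv - ebv.mean()) / ebv.std(ddof=0).replace(0.0, 1.0)
    w = np.ones(ebv.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    return (z * w).sum(axis=1)


def _current_ebv(
    cfg: SimConfig,
    selection_on: str,
    rows: list,
    phen_rows: list,
    calls: np.ndarray,
    geno_mask: np.ndarray,
    tbv: np.ndarray,
    rng: np.random.Generator,
    candidate_cohort: int | None = None,
) -> pd.DataFrame:
    """(G)EBV of all animals born so far, from current information.

    Genomic preselection acts on *young* animals, so the records of the
    candidate cohort itself are excluded from the selection evaluation:
    candidates are ranked on parent information plus their own
    genotypes, never on their own phenotypes.
    """
    ids = np.array([r[0] for r in rows])
    if selection_on == "random":
        return pd.DataFrame(
            rng.normal(size=(len(ids), len(cfg.traits))), index=ids, columns=cfg.traits
        )
    if selection_on == "tbv":
        return pd.DataFrame(tbv[: len(ids)], index=ids, columns=list(cfg.traits))

    from . import mme  # deferred: mme does not depend on simulate

    ped = Pedigree(
        pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "cohort", "group"])
    )
    phen = pd.DataFrame(
        phen_rows, columns=["animal", "trait", "value", "batch", "litter"]
    )
    if candidate_cohort is not None:
        young = set(ped.ids[ped.cohort == candidate_cohort].tolist())
        phen = phen[~phen["animal"].isin(young)].reset_index(drop=True)
    n_geno = int(geno_mask[: len(ids)].sum())
    model = "PBLUP" if (selection_on == "pblup" or n_geno < 2) else "ssGBLUP"
    if model == "ssGBLUP":
        gsel = geno_mask[: len(ids)]
        geno = GenotypeMatrix(ids[gsel], np.arange(calls.shape[1]), calls[: len(ids)][gsel])
    else:
        geno = GenotypeMatrix(ids[:0], np.arange(calls.shape[1]), calls[:0])
    covs = cfg.covariances()
    rel, n_groups = mme.build_relationship(
        StudyDataset(ped, geno, phen, pd.DataFrame(tbv[: len(ids)], index=ids, columns=list(cfg.traits)), 0),
        model,
        use_groups=True,
    )
    ebv = {}
    for j, trait in enumerate(cfg.traits):  # single-trait solves keep this cheap
        spec = mme.ModelSpec(
            covariances=covs.subset([trait]),
            relationship=rel,
            fixed_effects=["batch"],
            random_effects=["litter"],
            n_groups=n_groups,
        )
        res = mme.solve_mme(mme.assemble_mme(phen[phen["trait"] == trait], spec))
        ebv[trait] = res.ebv[trait]
    return pd.DataFrame(ebv)


def simulate_program(config: SimConfig, seed: int) -> StudyDataset:
    """Run the generator and return the full study dataset.

    Phenotype = batch effect + litter effect + TBV + residual; TBV
    follows the additive SNP model with genotypes gene-dropped from
    HWE founders; parents are within-sex truncation-selected on the
    preselection index.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    t = len(cfg.traits)
    covs = cfg.covariances()

    p0 = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    scale = 2.0 * np.sum(p0 * (1.0 - p0))
    beta = rng.normal(size=(cfg.n_snps, t)) @ np.linalg.cholesky(covs.G / scale).T

    n_total_guess = cfg.n_founders + cfg.n_dams * (
        cfg.historic_generations * cfg.historic_litter_size
        + (cfg.n_generations - cfg.historic_generations) * cfg.litter_size
    )
    calls = np.zeros((n_total_guess, cfg.n_snps), dtype=np.float32)
    tbv = np.zeros((n_total_guess, t))

    rows: list = []  # pedigree rows
    phen_rows: list = []
    geno_mask = np.zeros(n_total_guess, dtype=bool)
    litter_effects: dict = {}
    batch_effects: dict = {}
    chol_R = np.linalg.cholesky(covs.R)

    def make_phenotypes(idx_list: list[int], cohort: int, litters: list):
        phenotyped = rng.random(len(idx_list)) < cfg.phenotyping_rate
        batches = rng.integers(cfg.batches_per_cohort, size=len(idx_list))
        for k, i in enumerate(idx_list):
            if not phenotyped[k]:
                continue
            batch = f"b{cohort}_{batches[k]}"
            if batch not in batch_effects:
                batch_effects[batch] = rng.normal(0.0, cfg.batch_sd, size=t)
            lit = litters[k]
            if lit not in litter_effects:
                litter_effects[lit] = rng.normal(size=t) * np.sqrt(covs.P["litter"])
            e = chol_R @ rng.normal(size=t)
            y = batch_effects[batch] + litter_effects[lit] + tbv[i] + e
            for j, trait in enumerate(cfg.traits):
                phen_rows.append((rows[i][0], trait, float(y[j]), batch, lit))

    # founders
    n_m = int(round(cfg.n_founders * cfg.founder_male_fraction))
    aid = 0
    founder_idx = []
    for i in range(cfg.n_founders):
        sex = "M" if i < n_m else "F"
        rows.append((aid + 1, UNKNOWN, UNKNOWN, sex, 0, "g0"))
        founder_idx.append(aid)
        aid += 1
    calls[:cfg.n_founders] = rng.binomial(2, p0, size=(cfg.n_founders, cfg.n_snps))
    tbv[:cfg.n_founders] = (calls[:cfg.n_founders] - 2.0 * p0) @ beta
    if cfg.genotyping_start == 0:
        geno_mask[:cfg.n_founders] = rng.random(cfg.n_founders) < cfg.genotyping_rate
    make_phenotypes(founder_idx, 0, [f"lit0_{i // 10}" for i in range(cfg.n_founders)])

    prev_idx = founder_idx
    for g in range(1, cfg.n_generations + 1):
        historic = g <= cfg.historic_generations
        sel_on = cfg.historic_selection if historic else cfg.selection_on
        litter_size = cfg.historic_litter_size if historic else cfg.litter_size
        cand_ids = [rows[i][0] for i in prev_idx]
        ebv = _current_ebv(
            cfg, sel_on, rows, phen_rows, calls, geno_mask, tbv, rng,
            candidate_cohort=g - 1,
        ).loc[cand_ids]
        index = _selection_index(ebv, cfg.index_weights)
        sexes = np.array([rows[i][3] for i in prev_idx])
        order = np.argsort(-index.to_numpy(), kind="stable")
        males = [prev_idx[i] for i in order if sexes[i] == "M"][: cfg.n_sires]
        fems = [prev_idx[i] for i in order if sexes[i] == "F"][: cfg.n_dams]
        if not males or not fems:
            raise ValueError("selection produced zero sires or zero dams")
        if g - 1 >= cfg.genotyping_start:  # modern parents are always genotyped
            geno_mask[males] = True
            geno_mask[fems] = True

        sire_of_dam = rng.permuted(np.resize(np.asarray(males), len(fems)))
        new_idx, new_litters = [], []
        for dam_i, sire_i in zip(fems, sire_of_dam):
            lit = f"lit{g}_{rows[dam_i][0]}"
            for _ in range(litter_size):
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append((aid + 1, rows[sire_i][0], rows[dam_i][0], sex, g, None))
                calls[aid] = rng.binomial(1, calls[sire_i] / 2.0) + rng.binomial(
                    1, calls[dam_i] / 2.0
                )
                tbv[aid] = (calls[aid] - 2.0 * p0) @ beta
                new_idx.append(aid)
                new_litters.append(lit)
                aid += 1
        if g >= cfg.genotyping_start:
            geno_mask[new_idx] = rng.random(len(new_idx)) < cfg.genotyping_rate
        make_phenotypes(new_idx, g, new_litters)
        prev_idx = new_idx

    n = aid
    ped = Pedigree(
        pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "cohort", "group"])
    )
    ids = np.array([r[0] for r in rows])
    observed = calls[:n].astype(float)
    observed[rng.random(observed.shape) < cfg.missing_call_rate] = np.nan
    gsel = geno_mask[:n]
    geno = GenotypeMatrix(
        ids[gsel], np.array([f"snp{j}" for j in range(cfg.n_snps)]), observed[gsel]
    )
    phen = pd.DataFrame(phen_rows, columns=["animal", "trait", "value", "batch", "litter"])
    tbv_df = pd.DataFrame(tbv[:n], index=ids, columns=list(cfg.traits))
    return StudyDataset(
        pedigree=ped,
        genotypes=geno,
        phenotypes=phen,
        true_breeding_values=tbv_df,
        training_cutoff=cfg.n_generations - 2,
        seed=seed,
    )


# -- preselection scenarios -------------------------------------------


def _discard(data: StudyDataset, discard_ids: set) -> StudyDataset:
    """Remove genotypes and phenotypes of the given animals.

    A discarded animal survives as a bare pedigree node only when it is
    an ancestor of a kept animal; all non-discarded animals stay."""
    if not discard_ids:
        return data
    phen = data.phenotypes[~data.phenotypes["animal"].isin(discard_ids)].reset_index(
        drop=True
    )
    keep_g = [a for a in data.genotypes.animal_ids if a not in discard_ids]
    geno = data.genotypes.subset(animals=keep_g)
    ped = data.pedigree
    not_discarded = ~pd.Series(ped.ids).isin(discard_ids).to_numpy()
    keep = ped.ancestors_closure(np.where(not_discarded)[0])
    # progeny certificates: "has progeny in the data" refers to the data
    # the filter was applied to, so a kept parent must not lose its last
    # progeny link to pruning; retain its first progeny node as evidence
    prog = ped.progeny_lists()
    for i in np.where(keep)[0]:
        if prog[i] and not any(keep[c] for c in prog[i]):
            keep[min(prog[i])] = True
    keep = ped.ancestors_closure(np.where(keep)[0])
    sub = ped.subset(keep)
    tbv = data.true_breeding_values.loc[sub.ids]
    return data.replace(
        pedigree=sub, genotypes=geno, phenotypes=phen, true_breeding_values=tbv
    )


def apply_scenario(data: StudyDataset, scenario: ScenarioSpec) -> StudyDataset:
    """Apply the preselection filter of the named scenario.

    VGP discards genotypes and phenotypes of progeny-less animals in the
    validation generation; MGP additionally discards progeny-less
    animals in all training generations.  The reference scenario keeps
    everything.
    """
    if scenario.name == "reference":
        return data
    counts = data.progeny_counts()
    coh = pd.Series(data.pedigree.cohort, index=data.pedigree.ids)
    no_progeny = counts.index[counts == 0]
    discard = set(no_progeny[coh.loc[no_progeny] == data.validation_cohort])
    if scenario.name == "MGP":
        discard |= set(no_progeny[coh.loc[no_progeny] <= data.training_cutoff])
    return _discard(data, discard)


def drop_validation_descendants(data: StudyDataset) -> StudyDataset:
    """Remove all records of progeny of validation-population animals.

    Run this on the evaluation input only; progeny yield deviations are
    computed from the full data beforehand.
    """
    ped = data.pedigree
    val_ids = set(ped.ids[ped.cohort > data.training_cutoff].tolist())
    parent_frame = ped.frame
    is_prog = (
        parent_frame["sire"].isin(val_ids) | parent_frame["dam"].isin(val_ids)
    ).to_numpy()
    if not is_prog.any():
        return data
    prog_ids = set(ped.ids[is_prog].tolist())
    phen = data.phenotypes[~data.phenotypes["animal"].isin(prog_ids)].reset_index(drop=True)
    keep_g = [a for a in data.genotypes.animal_ids if a not in prog_ids]
    geno = data.genotypes.subset(animals=keep_g)
    sub = ped.subset(~is_prog)
    return data.replace(
        pedigree=sub,
        genotypes=geno,
        phenotypes=phen,
        true_breeding_values=data.true_breeding_values.loc[sub.ids],
    )


def strip_validation_records(data: StudyDataset) -> StudyDataset:
    """Drop own phenotypes of validation-generation animals; pedigree
    and genotypes stay."""
    ped = data.pedigree
    val = set(ped.ids[ped.cohort > data.training_cutoff].tolist())
    phen = data.phenotypes[~data.phenotypes["animal"].isin(val)].reset_index(drop=True)
    return data.replace(phenotypes=phen)
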