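"""End-to-end preselection experiment.

Simulate a breeding program, precorrect phenotypes on the full data,
compute progeny yield deviations, then for every cell of the grid

    scenario in {reference, VGP, MGP}
    x records on validation animals in {with, without}
    x model in {ssGBLUP, PBLUP}

run genotype QC, scenario-specific variance-component estimation, the
mean-only subsequent evaluation, and the PYD-based validation metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .datatypes import ScenarioSpec, StudyDataset, TraitCovariances
from .mme import EvaluationResult, ModelSpec, assemble_mme, build_relationship, solve_mme
from .precorrect import precorrect_phenotypes
from .simulate import (
    SimConfig,
    apply_scenario,
    drop_validation_descendants,
    simulate_program,
    strip_validation_records,
)
from .validate import (
    base_animals,
    compare_estimates,
    compute_pyd,
    pyd_reliability,
    rescale_to_base,
    select_validation_animals,
    weighted_metrics,
)
from .varcomp import make_reml_context, reml_estimate

log = logging.getLogger("gpsval.pipeline")


@dataclass
class ExperimentConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    min_call_rate: float = 0.90
    hwe_p: float = 1e-15
    min_maf: float = 0.005
    blend_weight: float = 0.95
    n_base_cohorts: int = 3
    estimate_varcomp: bool = True
    multi_trait_precorrect: bool = True
    scenarios: tuple = ("reference", "VGP", "MGP")
    models: tuple = ("ssGBLUP", "PBLUP")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame
    manifest: dict

    def to_tsv(self, path) -> None:
        """Metrics grid as a headered TSV (one row per scenario x
        records x model x trait)."""
        self.metrics.to_csv(path, sep="\t", index=False)


def load_config(path) -> ExperimentConfig:
    """Read an experiment configuration from a JSON or YAML document.

    The document mirrors ExperimentConfig; the ``sim`` block holds the
    SimConfig fields.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sim = SimConfig.from_dict(doc.pop("sim", {}))
    return ExperimentConfig(sim=sim, **{k: v for k, v in doc.items()})


def mean_only_evaluation(
    data: StudyDataset,
    covs: TraitCovariances,
    relationship,
    n_groups: int,
) -> EvaluationResult:
    """Per-trait mean-only (G)EBV solves, merged into one result.

    Single-trait solves keep the equations small; genetic correlations
    only enter through the precorrection model.
    """
    ebv_cols, groups_cols, fixed = {}, {}, {}
    diagnostics = {}
    for trait in covs.traits:
        spec = ModelSpec(
            covariances=covs.subset([trait]),
            relationship=relationship,
            fixed_effects=["mean"],
            random_effects=[],
            n_groups=n_groups,
        )
        res = solve_mme(assemble_mme(data.phenotypes, spec))
        ebv_cols[trait] = res.ebv[trait]
        groups_cols[trait] = res.group_solutions[trait]
        fixed[trait] = res.fixed_solutions["mean"]
        diagnostics[trait] = res.diagnostics
    return EvaluationResult(
        ebv=pd.DataFrame(ebv_cols),
        fixed_solutions={"mean": pd.concat(fixed)},
        random_solutions={},
        group_solutions=pd.DataFrame(groups_cols),
        diagnostics=diagnostics,
    )


def run_experiment(config: ExperimentConfig, seed: int) -> ExperimentResult:
    """Run the full grid and return the metrics table plus a manifest."""
    t0 = time.perf_counter()
    cfg = config
    truth = cfg.sim.covariances()
    traits = list(cfg.sim.traits)

    data = simulate_program(cfg.sim, seed)
    log.info("simulated %d animals, %d genotyped", data.pedigree.n, data.genotypes.n_animals)

    yc, _ = precorrect_phenotypes(
        data, truth, multi_trait=cfg.multi_trait_precorrect
    )
    data_c = data.replace(phenotypes=yc.drop(columns=["subtracted"]))

    rel_full, ng_full = build_relationship(data_c, "PBLUP", use_groups=True)
    pyd_model = mean_only_evaluation(data_c, truth, rel_full, ng_full)
    val_ids = select_validation_animals(data_c)
    pyd = compute_pyd(data_c, pyd_model, val_ids)
    base_ids = base_animals(data_c, cfg.n_base_cohorts)

    rows = []
    manifest: dict = {
        "seed": seed,
        "config_hash": cfg.config_hash(),
        "n_validation": int(len(val_ids)),
        "scenario_counts": {},
    }
    for scen_name in cfg.scenarios:
        s_data = apply_scenario(data_c, ScenarioSpec(name=scen_name))
        e_data = drop_validation_descendants(s_data)
        if e_data.genotypes.n_animals:
            geno_qc, _ = qc_mod.run_qc(
                e_data.genotypes, cfg.min_call_rate, cfg.hwe_p, cfg.min_maf
            )
            e_data = e_data.replace(genotypes=geno_qc)
        manifest["scenario_counts"][scen_name] = {
            "pedigree": int(e_data.pedigree.n),
            "phenotyped": int(e_data.phenotypes["animal"].nunique()),
            "genotyped": int(e_data.genotypes.n_animals),
        }
        relationships = {
            m: build_relationship(e_data, m, use_groups=True, blend_weight=cfg.blend_weight)
            for m in cfg.models
        }
        for with_records in (True, False):
            d = e_data if with_records else strip_validation_records(e_data)
            if cfg.estimate_varcomp:
                ctx = make_reml_context(
                    d.pedigree, d.phenotypes["animal"].unique(), use_groups=True
                )
                vc = {t: reml_estimate(d.phenotypes, trait=t, context=ctx) for t in traits}
                su = {t: vc[t].sigma_u2 for t in traits}
                se = {t: vc[t].sigma_e2 for t in traits}
            else:
                su = {t: truth.G[i, i] for i, t in enumerate(traits)}
                se = {t: truth.R[i, i] for i, t in enumerate(traits)}
            h2 = {t: su[t] / (su[t] + se[t]) for t in traits}
            for model in cfg.models:
                rel, ng = relationships[model]
                ev = {}
                for t in traits:
                    covs_t = TraitCovariances([t], [[su[t]]], [[se[t]]])
                    spec = ModelSpec(
                        covariances=covs_t,
                        relationship=rel,
                        fixed_effects=["mean"],
                        random_effects=[],
                        n_groups=ng,
                    )
                    res = solve_mme(assemble_mme(d.phenotypes, spec))
                    ev[t] = res
                for t in traits:
                    pairs = rescale_to_base(pyd, t, ev[t], pyd_model, base_ids)
                    w = pyd_reliability(pairs["n_progeny"], h2[t])
                    m = weighted_metrics(
                        pairs["pyd_rescaled"],
                        pairs["gebv_rescaled"],
                        w,
                        genetic_sd=float(np.sqrt(su[t])),
                    )
                    rows.append(
                        {
                            "scenario": scen_name,
                            "records": "with" if with_records else "without",
                            "model": model,
                            "trait": t,
                            "h2": h2[t],
                            "sigma_u2": su[t],
                            "sigma_e2": se[t],
                            "accuracy": m.accuracy,
                            "accuracy_se": m.accuracy_se,
                            "level_bias": m.level_bias,
                            "level_bias_se": m.level_bias_se,
                            "dispersion": m.dispersion,
                            "dispersion_se": m.dispersion_se,
                            "n_validation": m.n_validation,
                        }
                    )
        log.info("scenario %s done at %.1fs", scen_name, time.perf_counter() - t0)
    manifest["runtime_s"] = time.perf_counter() - t0
    return ExperimentResult(pd.DataFrame(rows), manifest)


def dispersion_expectation_study(
    seed: int,
    n_replicates: int = 20,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Replicated check of the no-selection dispersion expectation.

    Simulates programs with random parent choice, runs the subsequent
    ssGBLUP evaluation (validation progeny excluded), computes PYD with
    half-sib reliabilities, rescales to the early-generation base, and
    fits the reliability-weighted regression of PYD on GEBV.  Without
    selection the slope expectation is 0.5 (PYD carries half the
    parent's breeding value).  Returns one row per replicate x trait.
    """
    cfg = config or SimConfig(selection_on="random")
    if cfg.selection_on != "random":
        raise ValueError("the dispersion expectation holds without selection only")
    truth = cfg.covariances()
    h2 = truth.heritabilities()
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_replicates)
    rows = []
    for rep, s in enumerate(rep_seeds):
        data = simulate_program(cfg, int(s))
        yc, _ = precorrect_phenotypes(data, truth, multi_trait=True)
        d = data.replace(phenotypes=yc.drop(columns=["subtracted"]))
        rel, ng = build_relationship(d, "PBLUP", use_groups=True)
        pyd_model = mean_only_evaluation(d, truth, rel, ng)
        val = select_validation_animals(d)
        pyd = compute_pyd(d, pyd_model, val)
        e_data = drop_validation_descendants(d)
        rel_h, ng_h = build_relationship(e_data, "ssGBLUP", use_groups=True)
        ev = mean_only_evaluation(e_data, truth, rel_h, ng_h)
        base_ids = base_animals(d)
        for i, t in enumerate(cfg.traits):
            pairs = rescale_to_base(pyd, t, ev, pyd_model, base_ids)
            w = pyd_reliability(pairs["n_progeny"], h2[i])
            m = weighted_metrics(
                pairs["pyd_rescaled"],
                pairs["gebv_rescaled"],
                w,
                genetic_sd=float(np.sqrt(truth.G[i, i])),
            )
            rows.append(
                {
                    "replicate": rep,
                    "trait": t,
                    "accuracy": m.accuracy,
                    "level_bias": m.level_bias,
                    "dispersion": m.dispersion,
                    "dispersion_se": m.dispersion_se,
                    "n_validation": m.n_validation,
                }
            )
        log.info("dispersion study replicate %d/%d done", rep + 1, n_replicates)
    return pd.DataFrame(rows)


def report(result: ExperimentResult) -> str:
    """Markdown grid with significance flags against the reference
    scenario (one-tailed comparison at the 5% level)."""
    df = result.metrics
    lines = [
        "| scenario | records | model | trait | h2 | accuracy | level bias | dispersion |",
        "|---|---|---|---|---|---|---|---|",
    ]
    ref = df[df["scenario"] == "reference"].set_index(["records", "model", "trait"])
    for _, r in df.iterrows():
        flags = {}
        key = (r["records"], r["model"], r["trait"])
        for meas in ("accuracy", "level_bias", "dispersion"):
            flag = ""
            if r["scenario"] != "reference" and key in ref.index:
                cmp = compare_estimates(
                    r[meas], r[f"{meas}_se"], ref.loc[key, meas], ref.loc[key, f"{meas}_se"]
                )
                flag = "*" if cmp.different else ""
            flags[meas] = flag
        lines.append(
            "| {scenario} | {records} | {model} | {trait} | {h2:.2f} "
            "| {acc:.2f} ({acc_se:.2f}){fa} | {lb:.2f} ({lb_se:.2f}){fl} "
            "| {disp:.2f} ({disp_se:.2f}){fd} |".format(
                scenario=r["scenario"],
                records=r["records"],
                model=r["model"],
                trait=r["trait"],
                h2=r["h2"],
                acc=r["accuracy"],
                acc_se=r["accuracy_se"],
                fa=flags["accuracy"],
                lb=r["level_bias"],
                lb_se=r["level_bias_se"],
                fl=flags["level_bias"],
                disp=r["dispersion"],
                disp_se=r["dispersion_se"],
                fd=flags["dispersion"],
            )
        )
    return "\n".join(lines)
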