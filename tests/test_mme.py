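import numpy as np
import pandas as pd
import pytest

from gpsval.datatypes import ScenarioSpec, StudyDataset, TraitCovariances
from gpsval.genotypes import GenotypeMatrix
from gpsval.mme import (
    ModelSpec,
    assemble_mme,
    build_relationship,
    evaluate,
    solve_mme,
)
from gpsval.pedigree import Pedigree
from gpsval.relmat import (
    build_A22,
    build_A_inverse,
    build_H_inverse,
    group_fractions,
    tabular_A,
)
from gpsval.simulate import SimConfig, simulate_program

from conftest import build_random_pedigree


def _single_founder():
    return Pedigree(
        pd.DataFrame(
            [(1, 0, 0, "M", 0, "g0")],
            columns=["animal", "sire", "dam", "sex", "cohort", "group"],
        )
    )


def _covs1(su=0.3, se=0.7):
    return TraitCovariances(["t"], [[su]], [[se]])


def test_single_record_heritability_shrinkage():
    """One founder, one record, known zero mean: u = h2 * y."""
    spec = ModelSpec(_covs1(), build_A_inverse(_single_founder()), fixed_effects=[])
    phen = pd.DataFrame({"animal": [1], "trait": ["t"], "value": [2.0]})
    res = solve_mme(assemble_mme(phen, spec))
    assert res.ebv.loc[1, "t"] == pytest.approx(0.3 * 2.0)


def test_recordless_unrelated_animal_has_zero_ebv(trio_pedigree):
    spec = ModelSpec(_covs1(), build_A_inverse(trio_pedigree), fixed_effects=[])
    phen = pd.DataFrame({"animal": [1], "trait": ["t"], "value": [1.0]})
    res = solve_mme(assemble_mme(phen, spec))
    assert res.ebv.loc[2, "t"] == pytest.approx(0.0, abs=1e-12)


def _gls_oracle(ped, phen, covs, traits):
    """Dense GLS-BLUP with V = Z(A x G)Z' + R over the observed records."""
    A = tabular_A(ped)
    K = np.kron(A, covs.G)
    t_of = {t: i for i, t in enumerate(traits)}
    a_of = {a: i for i, a in enumerate(ped.ids)}
    idx = [a_of[a] * len(traits) + t_of[t] for a, t in zip(phen["animal"], phen["trait"])]
    Z = np.zeros((len(phen), K.shape[0]))
    Z[np.arange(len(phen)), idx] = 1.0
    R = np.zeros((len(phen), len(phen)))
    for p in range(len(phen)):
        for q in range(len(phen)):
            if phen["animal"].iat[p] == phen["animal"].iat[q]:
                R[p, q] = covs.R[t_of[phen["trait"].iat[p]], t_of[phen["trait"].iat[q]]]
    V = Z @ K @ Z.T + R
    X = np.zeros((len(phen), len(traits)))
    X[np.arange(len(phen)), [t_of[t] for t in phen["trait"]]] = 1.0
    Vi = np.linalg.inv(V)
    y = phen["value"].to_numpy()
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = K @ Z.T @ Vi @ (y - X @ b)
    return b, u.reshape(len(ped.ids), len(traits))


def _random_records(ped, traits, seed, keep=0.8):
    rng = np.random.default_rng(seed)
    recs = [
        (a, t, rng.normal())
        for a in ped.ids
        for t in traits
        if rng.random() < keep
    ]
    return pd.DataFrame(recs, columns=["animal", "trait", "value"])


def test_multi_trait_solution_equals_dense_gls():
    ped = build_random_pedigree(1, n_founders=12, n_gens=2, per_gen=14)
    traits = ["a", "b"]
    covs = TraitCovariances(
        traits, [[0.3, 0.1], [0.1, 0.4]], [[0.7, 0.2], [0.2, 0.6]]
    )
    phen = _random_records(ped, traits, seed=2)
    spec = ModelSpec(covs, build_A_inverse(ped), fixed_effects=["mean"])
    res = solve_mme(assemble_mme(phen, spec))
    b, u = _gls_oracle(ped, phen, covs, traits)
    assert np.abs(res.ebv.to_numpy() - u).max() <= 1e-8
    means = [res.fixed_solutions["mean"].loc[(t, 1), "solution"] for t in traits]
    assert np.abs(np.array(means) - b).max() <= 1e-8


def test_record_order_permutation_invariance():
    ped = build_random_pedigree(3, n_founders=8, n_gens=2, per_gen=10)
    covs = _covs1()
    phen = _random_records(ped, ["t"], seed=3)
    spec = ModelSpec(covs, build_A_inverse(ped), fixed_effects=["mean"])
    res1 = solve_mme(assemble_mme(phen, spec))
    shuffled = phen.sample(frac=1.0, random_state=0).reset_index(drop=True)
    res2 = solve_mme(assemble_mme(shuffled, spec))
    assert np.abs(res1.ebv.to_numpy() - res2.ebv.to_numpy()).max() <= 1e-8


def test_location_invariance_of_ebv():
    ped = build_random_pedigree(5, n_founders=8, n_gens=2, per_gen=10)
    phen = _random_records(ped, ["t"], seed=5)
    spec = ModelSpec(_covs1(), build_A_inverse(ped), fixed_effects=["mean"])
    res1 = solve_mme(assemble_mme(phen, spec))
    shifted = phen.assign(value=phen["value"] + 3.5)
    res2 = solve_mme(assemble_mme(shifted, spec))
    mu1 = res1.fixed_solutions["mean"].loc[("t", 1), "solution"]
    mu2 = res2.fixed_solutions["mean"].loc[("t", 1), "solution"]
    assert mu2 - mu1 == pytest.approx(3.5, abs=1e-8)
    assert np.abs(res1.ebv.to_numpy() - res2.ebv.to_numpy()).max() <= 1e-8


def test_diagonal_covariances_decouple_traits():
    ped = build_random_pedigree(6, n_founders=8, n_gens=2, per_gen=10)
    traits = ["a", "b"]
    covs = TraitCovariances(traits, np.diag([0.3, 0.5]), np.diag([0.7, 0.5]))
    phen = _random_records(ped, traits, seed=6)
    rel = build_A_inverse(ped)
    joint = solve_mme(assemble_mme(phen, ModelSpec(covs, rel, fixed_effects=["mean"])))
    for t in traits:
        single = solve_mme(
            assemble_mme(
                phen[phen["trait"] == t],
                ModelSpec(covs.subset([t]), rel, fixed_effects=["mean"]),
            )
        )
        assert np.abs(joint.ebv[t].to_numpy() - single.ebv[t].to_numpy()).max() <= 1e-8


def test_group_equations_match_explicit_covariate_model():
    """Quaas-Pollak augmented equations reproduce the model fitting
    genome-fraction group covariates explicitly."""
    ped = build_random_pedigree(7, n_founders=8, n_gens=2, per_gen=12)
    # two founder groups
    frame = ped.frame.copy()
    frame.loc[frame["group"].notna() & (frame["animal"] % 2 == 0), "group"] = "g1"
    ped = Pedigree(frame)
    covs = _covs1()
    phen = _random_records(ped, ["t"], seed=7, keep=0.9)

    qp = solve_mme(
        assemble_mme(
            phen,
            ModelSpec(
                covs,
                build_A_inverse(ped, groups=True),
                fixed_effects=["mean"],
                n_groups=ped.n_groups,
            ),
        )
    )
    # explicit model: u ~ A, group fractions as fixed covariates
    # (first group absorbed by the mean), total EBV = Qg + u
    Q = group_fractions(ped)
    pos = ped.index_of(phen["animal"].to_numpy())
    Xfull = np.column_stack([np.ones(len(phen)), Q[pos, 1]])
    Ainv = np.linalg.inv(tabular_A(ped))
    Zi = np.zeros((len(phen), ped.n))
    Zi[np.arange(len(phen)), pos] = 1.0
    lam = covs.R[0, 0] / covs.G[0, 0]
    C = np.block(
        [
            [Xfull.T @ Xfull, Xfull.T @ Zi],
            [Zi.T @ Xfull, Zi.T @ Zi + Ainv * lam],
        ]
    )
    r = np.concatenate([Xfull.T @ phen["value"], Zi.T @ phen["value"]])
    sol = np.linalg.solve(C, r)
    g1 = sol[1]
    u = sol[2:]
    total = Q @ np.array([0.0, g1]) + u
    assert np.abs(qp.ebv["t"].to_numpy() - total).max() <= 1e-6


def _simulated_dataset(seed=0, **kw):
    cfg = SimConfig(
        n_founders=60,
        n_generations=3,
        historic_generations=1,
        n_snps=400,
        n_sires=8,
        n_dams=20,
        litter_size=4,
        historic_litter_size=2,
        traits=("t",),
        h2=(0.4,),
        selection_on=kw.pop("selection_on", "random"),
        genotyping_rate=kw.pop("genotyping_rate", 1.0),
        genotyping_start=kw.pop("genotyping_start", 1),
        **kw,
    )
    return cfg, simulate_program(cfg, seed)


def test_ssgblup_with_A22_blend_equals_pblup():
    cfg, data = _simulated_dataset(seed=4)
    covs = cfg.covariances()
    rel_a = build_A_inverse(data.pedigree, groups=True)
    ng = data.pedigree.n_groups
    pos = data.pedigree.index_of(data.genotypes.animal_ids)
    A22, A22inv = build_A22(data.pedigree, data.genotypes.animal_ids)
    rel_h = build_H_inverse(rel_a, pos, A22.values, A22inv.values)
    covs1 = TraitCovariances(["t"], [[covs.G[0, 0]]], [[covs.R[0, 0]]])
    spec_a = ModelSpec(covs1, rel_a, fixed_effects=["mean"], n_groups=ng)
    spec_h = ModelSpec(covs1, rel_h, fixed_effects=["mean"], n_groups=ng)
    res_a = solve_mme(assemble_mme(data.phenotypes, spec_a))
    res_h = solve_mme(assemble_mme(data.phenotypes, spec_h))
    assert np.abs(res_a.ebv.to_numpy() - res_h.ebv.to_numpy()).max() <= 1e-6


def test_group_solutions_track_genetic_trend():
    """With directional selection, later founder-free cohorts improve;
    fitting one group per founder cohort, the group terms carry the
    trend even though only total EBV are reported."""
    cfg = SimConfig(
        n_founders=60,
        n_generations=3,
        historic_generations=1,
        historic_selection="tbv",
        n_snps=100,
        n_sires=5,
        n_dams=20,
        litter_size=4,
        historic_litter_size=3,
        traits=("t",),
        h2=(0.4,),
        selection_on="tbv",
    )
    data = simulate_program(cfg, 9)
    covs = cfg.covariances()
    rel, ng = build_relationship(data, "PBLUP", use_groups=True)
    res = evaluate(
        data,
        ScenarioSpec(model="PBLUP"),
        TraitCovariances(["t"], [[covs.G[0, 0]]], [[covs.R[0, 0]]]),
        relationship=(rel, ng),
    )
    coh = pd.Series(data.pedigree.cohort, index=data.pedigree.ids)
    mean_by_cohort = res.ebv["t"].groupby(coh).mean()
    assert mean_by_cohort.iloc[-1] > mean_by_cohort.iloc[0]


def test_genomic_information_improves_validation_accuracy():
    """Paired over replicates, ssGBLUP GEBV correlate with true
    breeding values at least as well as pedigree EBV when validation
    records are excluded."""
    from gpsval.simulate import strip_validation_records

    diffs = []
    for seed in range(20):
        cfg, data = _simulated_dataset(seed=seed, selection_on="random")
        covs1 = TraitCovariances(
            ["t"], [[cfg.covariances().G[0, 0]]], [[cfg.covariances().R[0, 0]]]
        )
        d = strip_validation_records(data)
        cors = {}
        for model in ("ssGBLUP", "PBLUP"):
            res = evaluate(d, ScenarioSpec(model=model), covs1)
            val = d.pedigree.ids[d.pedigree.cohort == d.validation_cohort]
            geno_val = [a for a in val if a in set(d.genotypes.animal_ids.tolist())]
            cors[model] = np.corrcoef(
                res.ebv.loc[geno_val, "t"], d.true_breeding_values.loc[geno_val, "t"]
            )[0, 1]
        diffs.append(cors["ssGBLUP"] - cors["PBLUP"])
    from scipy.stats import ttest_1samp

    t = ttest_1samp(diffs, 0.0, alternative="greater")
    assert np.mean(diffs) > 0
    assert t.pvalue < 0.05


def test_solver_diagnostics_and_residual_contract():
    ped = build_random_pedigree(8, n_founders=8, n_gens=2, per_gen=10)
    phen = _random_records(ped, ["t"], seed=8)
    spec = ModelSpec(_covs1(), build_A_inverse(ped), fixed_effects=["mean"])
    sys = assemble_mme(phen, spec)
    res = solve_mme(sys, tol=1e-10)
    assert res.diagnostics["residual"] <= 1e-10
    assert res.diagnostics["n_equations"] == sys.C.shape[0]
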