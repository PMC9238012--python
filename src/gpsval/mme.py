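"""Henderson's mixed-model equations for multi-trait PBLUP and ssGBLUP.

The model per trait j is

    y_j = X_j b_j + W_j p_j + Z_j u_j + e_j

with u ~ N(0, K^-1-penalised) where the relationship inverse K is either
the pedigree A^-1 or the single-step H^-1, both optionally augmented
with unknown-parent-group columns (Quaas-Pollak structure: animal
solutions are then total breeding values including group means).  The
evaluation model of the preselection study is the mean-only special
case (no W, X = 1).  Residual covariances are applied per animal over
its observed traits, so arbitrary missing-trait patterns are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .datatypes import ScenarioSpec, StudyDataset, TraitCovariances
from .relmat import (
    RelMatrix,
    build_A22,
    build_A_inverse,
    build_Gr,
    build_H_inverse,
    adjust_Gt,
    blend,
    compute_inbreeding,
)


class SolverError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """What to fit: effects, covariances and the relationship inverse."""

    covariances: TraitCovariances
    relationship: RelMatrix  # kind A_inv or H_inv, ids = animals (+ groups)
    fixed_effects: list = field(default_factory=lambda: ["mean"])
    random_effects: list = field(default_factory=list)
    n_groups: int = 0  # trailing group columns in the relationship


@dataclass
class EvaluationResult:
    ebv: pd.DataFrame  # animals x traits
    fixed_solutions: dict
    random_solutions: dict
    group_solutions: pd.DataFrame
    diagnostics: dict

    def to_tsv(self, path) -> None:
        """Write the breeding values as a long (animal, trait, ebv) TSV."""
        long = self.ebv.rename_axis("animal").reset_index().melt(
            id_vars="animal", var_name="trait", value_name="ebv"
        )
        long.to_csv(path, sep="\t", index=False)

    def diagnostics_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.diagnostics, fh, indent=1, default=float)

    def fitted_nongenetic(self, phenotypes: pd.DataFrame) -> np.ndarray:
        """Fixed + non-genetic random solution totals per phenotype row."""
        out = np.zeros(len(phenotypes))
        for table in (self.fixed_solutions, self.random_solutions):
            for eff, sol in table.items():
                levels = (
                    np.ones(len(phenotypes), dtype=int)
                    if eff == "mean"
                    else phenotypes[eff].to_numpy()
                )
                key = pd.MultiIndex.from_arrays([phenotypes["trait"].to_numpy(), levels])
                out += sol.reindex(key)["solution"].to_numpy()
        return out


@dataclass
class MMESystem:
    C: sp.csr_array
    rhs: np.ndarray
    columns: pd.DataFrame  # term, effect, level, trait, unit per column
    constrained: np.ndarray
    spec: ModelSpec


def _column_layout(spec: ModelSpec, phen: pd.DataFrame):
    """Assign a column index to every (effect, trait, level) combination
    and to every relationship unit x trait pair (unit-major order)."""
    traits = spec.covariances.traits
    frames = []
    phen = phen.copy()
    phen["mean"] = 1
    for term, effects in (("fixed", spec.fixed_effects), ("random", spec.random_effects)):
        for eff in effects:
            combos = (
                phen[["trait", eff]]
                .drop_duplicates()
                .sort_values(["trait", eff], kind="stable")
            )
            frames.append(
                pd.DataFrame(
                    {
                        "term": term,
                        "effect": eff,
                        "level": combos[eff].to_numpy(),
                        "trait": combos["trait"].to_numpy(),
                        "unit": -1,
                    }
                )
            )
    units = np.asarray(spec.relationship.ids)
    frames.append(
        pd.DataFrame(
            {
                "term": "u",
                "effect": "animal",
                "level": np.repeat(units, len(traits)),
                "trait": np.tile(np.asarray(traits, dtype=object), len(units)),
                "unit": np.repeat(np.arange(len(units)), len(traits)),
            }
        )
    )
    columns = pd.concat(frames, ignore_index=True)
    return columns


def assemble_mme(phenotypes: pd.DataFrame, spec: ModelSpec) -> MMESystem:
    """Build the symmetric coefficient matrix and right-hand side.

    ``phenotypes`` is long format with columns ``animal, trait, value``
    plus one column per class effect named in the spec.
    """
    covs = spec.covariances
    traits = list(covs.traits)
    phen = phenotypes[phenotypes["trait"].isin(traits)].reset_index(drop=True).copy()
    phen["mean"] = 1
    columns = _column_layout(spec, phen)
    ncol = len(columns)
    u_offset = int((columns["term"] != "u").sum())

    # map each record to its term columns
    col_of = {}
    for eff in spec.fixed_effects + spec.random_effects:
        sub = columns[columns["effect"] == eff]
        lookup = pd.Series(
            sub.index.to_numpy(), index=pd.MultiIndex.from_arrays([sub["trait"], sub["level"]])
        )
        key = pd.MultiIndex.from_arrays([phen["trait"], phen[eff]])
        got = lookup.reindex(key).to_numpy()
        if np.isnan(got.astype(float)).any():
            raise KeyError(f"record class label absent from layout for effect {eff!r}")
        col_of[eff] = got.astype(np.int64)
    unit_pos = pd.Index(np.asarray(spec.relationship.ids)[: len(spec.relationship.ids)])
    animal_unit = unit_pos.get_indexer(phen["animal"])
    if (animal_unit < 0).any():
        raise KeyError("phenotyped animal missing from relationship ids")
    trait_code = pd.Index(traits).get_indexer(phen["trait"])
    col_of["animal"] = u_offset + animal_unit * len(traits) + trait_code

    terms = spec.fixed_effects + spec.random_effects + ["animal"]
    nrec = len(phen)
    Zr = np.concatenate([col_of[t] for t in terms])
    Z = sp.csr_array(
        (np.ones(len(Zr)), (np.tile(np.arange(nrec), len(terms)), Zr)),
        shape=(nrec, ncol),
    )

    # residual weight matrix: block R_S^-1 per animal over observed traits
    omega_r, omega_c, omega_v = [], [], []
    rec_of = {
        (a, t): i for i, (a, t) in enumerate(zip(phen["animal"], phen["trait"]))
    }
    obs = phen.groupby("animal", sort=False)["trait"].apply(tuple)
    patterns = {}
    for a, pat in obs.items():
        patterns.setdefault(tuple(sorted(pat, key=traits.index)), []).append(a)
    for pat, animals in patterns.items():
        idx = [traits.index(t) for t in pat]
        Rinv = np.linalg.inv(covs.R[np.ix_(idx, idx)])
        rows = np.array([[rec_of[(a, t)] for t in pat] for a in animals])
        for j in range(len(pat)):
            for k in range(len(pat)):
                omega_r.append(rows[:, j])
                omega_c.append(rows[:, k])
                omega_v.append(np.full(len(animals), Rinv[j, k]))
    Omega = sp.csr_array(
        (np.concatenate(omega_v), (np.concatenate(omega_r), np.concatenate(omega_c))),
        shape=(nrec, nrec),
    )

    y = phen["value"].to_numpy(dtype=float)
    C = (Z.T @ Omega @ Z).tocsr()
    rhs = Z.T @ (Omega @ y)

    Ginv = np.linalg.inv(covs.G)
    K = spec.relationship.values
    if not sp.issparse(K):
        K = sp.csr_array(np.asarray(K))
    pen = sp.kron(K, sp.csr_array(Ginv), format="csr") if len(traits) > 1 else K * Ginv[0, 0]
    n_u = K.shape[0] * len(traits)
    C = C + sp.block_diag(
        [sp.csr_array((u_offset, u_offset)), pen], format="csr"
    )
    assert C.shape == (ncol, ncol) and n_u + u_offset == ncol
    for eff in spec.random_effects:
        var = covs.P[eff]
        mask = (columns["effect"] == eff).to_numpy()
        tcode = pd.Index(traits).get_indexer(columns.loc[mask, "trait"])
        d = np.zeros(ncol)
        d[np.where(mask)[0]] = 1.0 / var[tcode]
        C = C + sp.diags_array(d, format="csr")

    constrained = _constraints(spec, columns)
    return MMESystem(C.tocsr(), rhs, columns, constrained, spec)


def _constraints(spec: ModelSpec, columns: pd.DataFrame) -> np.ndarray:
    """Columns fixed to zero to make the system full rank: the first
    level (per trait) of every fixed effect beyond the first, and the
    first unknown-parent group (per trait) whenever groups are fitted
    alongside any fixed effect."""
    out = []
    for eff in spec.fixed_effects[1:]:
        sub = columns[(columns["effect"] == eff)]
        out += list(sub.groupby("trait", sort=False).head(1).index)
    if spec.n_groups > 0 and spec.fixed_effects:
        n_units = len(spec.relationship.ids)
        first_group_unit = n_units - spec.n_groups
        sub = columns[(columns["term"] == "u") & (columns["unit"] == first_group_unit)]
        out += list(sub.index)
    return np.asarray(sorted(out), dtype=np.int64)


def solve_mme(system: MMESystem, tol: float = 1e-10, dense_cutoff: int = 6500) -> EvaluationResult:
    """Solve the assembled equations by a direct factorisation.

    Constrained columns are zeroed with a unit diagonal.  One step of
    iterative refinement is applied; the relative residual must come
    out below ``max(tol, 1e-8)`` or a SolverError is raised.
    """
    C, rhs = system.C.copy(), system.rhs.copy()
    n = C.shape[0]
    if len(system.constrained):
        mask = np.zeros(n, dtype=bool)
        mask[system.constrained] = True
        keep = sp.diags_array((~mask).astype(float), format="csr")
        C = keep @ C @ keep + sp.diags_array(mask.astype(float), format="csr")
        rhs = rhs * ~mask

    if n <= dense_cutoff:
        import scipy.linalg as sla

        Cd = C.toarray()
        try:
            cho = sla.cho_factor(Cd, check_finite=False)
            sol = sla.cho_solve(cho, rhs, check_finite=False)
            sol += sla.cho_solve(cho, rhs - Cd @ sol, check_finite=False)
        except np.linalg.LinAlgError:
            sol = np.linalg.solve(Cd, rhs)
    else:
        lu = spla.splu(C.tocsc())
        sol = lu.solve(rhs)
        sol += lu.solve(rhs - C @ sol)

    denom = np.linalg.norm(rhs)
    resid = np.linalg.norm(C @ sol - rhs) / (denom if denom > 0 else 1.0)
    if resid > max(tol, 1e-8):
        raise SolverError(f"MME solve did not converge: relative residual {resid:.2e}")

    return _decode(system, sol, {"residual": float(resid), "n_equations": int(n)})


def _decode(system: MMESystem, sol: np.ndarray, diagnostics: dict) -> EvaluationResult:
    columns = system.columns
    traits = system.spec.covariances.traits
    fixed, random = {}, {}
    for eff in system.spec.fixed_effects:
        sub = columns[columns["effect"] == eff]
        fixed[eff] = pd.DataFrame(
            {"solution": sol[sub.index]},
            index=pd.MultiIndex.from_arrays([sub["trait"], sub["level"]]),
        )
    for eff in system.spec.random_effects:
        sub = columns[columns["effect"] == eff]
        random[eff] = pd.DataFrame(
            {"solution": sol[sub.index]},
            index=pd.MultiIndex.from_arrays([sub["trait"], sub["level"]]),
        )
    usub = columns[columns["term"] == "u"]
    n_units = len(system.spec.relationship.ids)
    n_groups = system.spec.n_groups
    uvals = sol[usub.index].reshape(n_units, len(traits))
    units = np.asarray(system.spec.relationship.ids)
    ebv = pd.DataFrame(uvals[: n_units - n_groups], index=units[: n_units - n_groups], columns=traits)
    groups = pd.DataFrame(uvals[n_units - n_groups :], index=units[n_units - n_groups :], columns=traits)
    return EvaluationResult(ebv, fixed, random, groups, diagnostics)


def build_relationship(
    data: StudyDataset,
    model: str,
    use_groups: bool = True,
    blend_weight: float = 0.95,
    F: np.ndarray | None = None,
) -> tuple[RelMatrix, int]:
    """A^-1 for PBLUP or H^-1 for ssGBLUP over the dataset's pedigree."""
    ped = data.pedigree
    if F is None:
        F = compute_inbreeding(ped)
    A_inv = build_A_inverse(ped, F=F, groups=use_groups)
    n_groups = ped.n_groups if use_groups else 0
    if model == "PBLUP":
        return A_inv, n_groups
    geno = data.genotypes
    if geno.n_animals == 0:
        return RelMatrix(A_inv.ids, A_inv.values, "H_inv"), n_groups
    pos = ped.index_of(geno.animal_ids)
    A22, A22_inv = build_A22(ped, geno.animal_ids, F=F)
    Gr = build_Gr(geno.calls, geno.allele_frequencies())
    Gt = adjust_Gt(Gr, float(np.mean(F[pos])))
    Gb = blend(Gt, A22.values, w=blend_weight)
    return build_H_inverse(A_inv, pos, Gb, A22_inv.values), n_groups


def evaluate(
    data: StudyDataset,
    scenario: ScenarioSpec,
    covariances: TraitCovariances,
    use_groups: bool = True,
    relationship: tuple[RelMatrix, int] | None = None,
) -> EvaluationResult:
    """Mean-only (G)EBV evaluation of a scenario-filtered dataset.

    PBLUP and ssGBLUP share the identical data path; only the
    relationship inverse differs.
    """
    rel, n_groups = relationship or build_relationship(data, scenario.model, use_groups)
    spec = ModelSpec(
        covariances=covariances,
        relationship=rel,
        fixed_effects=["mean"],
        random_effects=[],
        n_groups=n_groups,
    )
    return solve_mme(assemble_mme(data.phenotypes, spec))
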