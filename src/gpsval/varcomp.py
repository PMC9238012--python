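"""EM-REML variance components for the single-trait pedigree animal model.

The evaluation model is y = X beta + a + e over the recorded animals,
with a ~ N(0, sigma_u^2 A_rec) and A_rec the recorded-animal block of
the numerator relationship matrix (the REML likelihood depends on the
pedigree only through that block).  A one-time eigendecomposition
A_rec = U D U' turns every EM iteration into O(n) work, so the
expectation-maximisation updates

    sigma_u^2 <- sigma_u^2 + sigma_u^4 (y'PAPy - tr(PA)) / n
    sigma_e^2 <- sigma_e^2 + sigma_e^4 (y'PPy  - tr(P))  / n

(with P the REML projection) can be iterated to tight tolerance; they
increase the restricted log-likelihood monotonically.  Unknown-parent
groups enter as fixed genome-fraction covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .relmat import a_matvec, compute_inbreeding, group_fractions


class RemlError(RuntimeError):
    pass


@dataclass
class RemlResult:
    sigma_u2: float
    sigma_e2: float
    converged: bool
    n_iter: int
    n_records: int
    loglik_path: list = field(default_factory=list)

    @property
    def h2(self) -> float:
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "sigma_u2": self.sigma_u2,
                    "sigma_e2": self.sigma_e2,
                    "h2": self.h2,
                    "converged": self.converged,
                    "n_iter": self.n_iter,
                    "n_records": self.n_records,
                    "loglik_path": self.loglik_path,
                },
                fh,
                indent=1,
            )


def recorded_relationship(ped: Pedigree, animal_ids, F=None) -> np.ndarray:
    """Dense pedigree-relationship block of the recorded animals."""
    pos = ped.index_of(animal_ids)
    E = np.zeros((ped.n, len(pos)))
    E[pos, np.arange(len(pos))] = 1.0
    A = a_matvec(ped, E, F=F)[pos]
    return 0.5 * (A + A.T)


@dataclass
class RemlContext:
    """Reusable spectral factorisation of one recorded-animal set, so
    several traits sharing the record pattern pay for one eigh call."""

    animals: np.ndarray
    dvals: np.ndarray
    U: np.ndarray
    X: np.ndarray


def make_reml_context(ped: Pedigree, animal_ids, use_groups: bool = True) -> RemlContext:
    animal_ids = np.asarray(animal_ids)
    F = compute_inbreeding(ped)
    A = recorded_relationship(ped, animal_ids, F=F)
    dvals, U = np.linalg.eigh(A)
    dvals = np.clip(dvals, 0.0, None)
    X = np.ones((len(animal_ids), 1))
    if use_groups and ped.n_groups > 1:
        Q = group_fractions(ped)[ped.index_of(animal_ids)]
        X = np.hstack([X, Q[:, 1:]])  # first group absorbed by the mean
    return RemlContext(animal_ids, dvals, U, X)


def reml_estimate(
    phenotypes: pd.DataFrame,
    ped: Pedigree | None = None,
    trait: str | None = None,
    use_groups: bool = True,
    max_iter: int = 1000,
    tol: float = 1e-6,
    init_h2: float = 0.5,
    context: RemlContext | None = None,
) -> RemlResult:
    """Estimate (sigma_u^2, sigma_e^2) for one trait by EM-REML.

    ``phenotypes`` is the long table; one record per animal and trait.
    """
    phen = phenotypes if trait is None else phenotypes[phenotypes["trait"] == trait]
    if phen["animal"].duplicated().any():
        raise RemlError("repeated records per animal are not supported")
    n = len(phen)
    if n < 10:
        raise RemlError("too few records for variance estimation")
    if context is None:
        if ped is None:
            raise RemlError("either a pedigree or a context is required")
        context = make_reml_context(ped, phen["animal"].to_numpy(), use_groups)
    y = (
        phen.set_index("animal")["value"].reindex(context.animals).to_numpy(dtype=float)
    )
    if np.isnan(y).any():
        raise RemlError("records do not cover the context's animal set")
    dvals, U, Xt_raw = context.dvals, context.U, context.X
    Xt = U.T @ Xt_raw
    yt = U.T @ y

    vary = float(np.var(y))
    su = max(init_h2 * vary, 1e-8)
    se = max((1.0 - init_h2) * vary, 1e-8)
    floor = 1e-10 * vary
    path: list[float] = []
    converged = False
    for it in range(max_iter):
        v = su * dvals + se
        Xv = Xt / v[:, None]
        B = Xt.T @ Xv
        w = yt / v - Xv @ np.linalg.solve(B, Xt.T @ (yt / v))  # rotated P y
        ypy = float(yt @ w)
        sign, logdetB = np.linalg.slogdet(B)
        ll = -0.5 * (np.sum(np.log(v)) + logdetB + ypy)
        path.append(ll)

        Xv2 = Xt / (v**2)[:, None]
        trP = np.sum(1.0 / v) - np.trace(np.linalg.solve(B, Xt.T @ Xv2))
        trPA = np.sum(dvals / v) - np.trace(np.linalg.solve(B, Xt.T @ (Xv2 * dvals[:, None])))
        yPAPy = float(np.sum(dvals * w * w))
        yPPy = float(np.sum(w * w))

        su_new = max(su + su * su * (yPAPy - trPA) / n, floor)
        se_new = max(se + se * se * (yPPy - trP) / n, floor)
        delta = max(abs(su_new - su) / max(su, floor), abs(se_new - se) / max(se, floor))
        su, se = su_new, se_new
        if delta < tol:
            converged = True
            break
    if not converged and max_iter > 50:
        # EM stalls near a zero-variance boundary; that is a valid solution
        converged = su <= 10 * floor or se <= 10 * floor
    return RemlResult(float(su), float(se), converged, len(path), n, path)
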