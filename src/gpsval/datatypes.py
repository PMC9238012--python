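"""Shared domain types: trait covariances, scenarios, study datasets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

SCENARIOS = ("reference", "VGP", "MGP")
MODELS = ("ssGBLUP", "PBLUP")


def _check_spd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(M).min() <= 0:
        raise ValueError(f"{name} must be positive definite")
    return M


@dataclass
class TraitCovariances:
    """Trait-by-trait additive (G) and residual (R) covariances, plus the
    variances of independent non-genetic random class effects (one value
    per trait per effect)."""

    traits: list
    G: np.ndarray
    R: np.ndarray
    P: dict = field(default_factory=dict)  # effect name -> length-t variance vector

    def __post_init__(self):
        t = len(self.traits)
        self.G = _check_spd(self.G, "G")
        self.R = _check_spd(self.R, "R")
        if self.G.shape != (t, t) or self.R.shape != (t, t):
            raise ValueError("covariance dimensions must match the trait list")
        self.P = {k: np.asarray(v, dtype=float).reshape(t) for k, v in self.P.items()}
        for k, v in self.P.items():
            if (v <= 0).any():
                raise ValueError(f"non-genetic variances for {k!r} must be positive")

    def subset(self, traits) -> "TraitCovariances":
        idx = [self.traits.index(t) for t in traits]
        return TraitCovariances(
            list(traits),
            self.G[np.ix_(idx, idx)],
            self.R[np.ix_(idx, idx)],
            {k: v[idx] for k, v in self.P.items()},
        )

    def heritabilities(self) -> np.ndarray:
        """sigma_u^2 / (sigma_u^2 + sigma_p^2 + sigma_e^2) per trait."""
        g, r = np.diag(self.G), np.diag(self.R)
        p = sum(self.P.values()) if self.P else 0.0
        return g / (g + p + r)


@dataclass
class ScenarioSpec:
    """One cell of the preselection study grid."""

    name: str = "reference"
    include_validation_records: bool = True
    model: str = "ssGBLUP"

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ValueError(f"scenario name must be one of {SCENARIOS}")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")


@dataclass
class StudyDataset:
    """A simulated breeding-program dataset.

    ``phenotypes`` is a long table (animal, trait, value, class labels);
    ``true_breeding_values`` is animals x traits and is simulation truth
    only, never an input to the evaluations.
    """

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    true_breeding_values: pd.DataFrame
    training_cutoff: int
    seed: int | None = None

    def __post_init__(self):
        ids = set(self.pedigree.ids.tolist())
        if not set(self.phenotypes["animal"]).issubset(ids):
            raise ValueError("phenotyped animals missing from pedigree")
        if not set(self.genotypes.animal_ids.tolist()).issubset(ids):
            raise ValueError("genotyped animals missing from pedigree")

    @property
    def traits(self) -> list:
        return list(self.true_breeding_values.columns)

    @property
    def validation_cohort(self) -> int:
        """The single generation directly after the training cut-off."""
        return self.training_cutoff + 1

    def replace(self, **kw) -> "StudyDataset":
        return replace(self, **kw)

    def progeny_counts(self) -> pd.Series:
        """Number of offspring recorded in the pedigree, per animal id."""
        ped = self.pedigree.frame
        parents = pd.concat([ped["sire"], ped["dam"]])
        counts = parents[parents != 0].value_counts()
        return counts.reindex(self.pedigree.ids, fill_value=0)
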