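import numpy as np
import pandas as pd
import pytest

from gpsval.datatypes import StudyDataset
from gpsval.genotypes import GenotypeMatrix
from gpsval.pedigree import Pedigree


def build_random_pedigree(seed, n_founders=12, n_gens=3, per_gen=15, male_frac=0.5):
    """Random discrete-generation pedigree for oracle tests."""
    rng = np.random.default_rng(seed)
    rows, aid = [], 1
    n_m = max(1, int(n_founders * male_frac))
    for i in range(n_founders):
        rows.append((aid, 0, 0, "M" if i < n_m else "F", 0, "g0"))
        aid += 1
    for c in range(1, n_gens + 1):
        males = [r[0] for r in rows if r[3] == "M" and r[4] == c - 1]
        fems = [r[0] for r in rows if r[3] == "F" and r[4] == c - 1]
        for _ in range(per_gen):
            rows.append(
                (
                    aid,
                    int(rng.choice(males)),
                    int(rng.choice(fems)),
                    "M" if rng.random() < 0.5 else "F",
                    c,
                    None,
                )
            )
            aid += 1
    return Pedigree(
        pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "cohort", "group"])
    )


@pytest.fixture
def trio_pedigree():
    """Sire, dam and one offspring, all base-generation parents."""
    return Pedigree(
        pd.DataFrame(
            [
                (1, 0, 0, "M", 0, "g0"),
                (2, 0, 0, "F", 0, "g0"),
                (3, 1, 2, "M", 1, None),
            ],
            columns=["animal", "sire", "dam", "sex", "cohort", "group"],
        )
    )


@pytest.fixture
def fullsib_mating_pedigree():
    """Founder grandparents, full-sib parents, inbred offspring (F = 0.25)."""
    return Pedigree(
        pd.DataFrame(
            [
                (1, 0, 0, "M", 0, "g0"),
                (2, 0, 0, "F", 0, "g0"),
                (3, 1, 2, "M", 1, None),
                (4, 1, 2, "F", 1, None),
                (5, 3, 4, "M", 2, None),
            ],
            columns=["animal", "sire", "dam", "sex", "cohort", "group"],
        )
    )


def tiny_dataset():
    """Handmade three-generation dataset for the validation-rule tests.

    Cohort 2 is the validation generation (cutoff 1), cohort 3 holds
    progeny of validation animals.
    """
    ped = pd.DataFrame(
        [
            # founders
            (1, 0, 0, "M", 0, "g0"),
            (2, 0, 0, "F", 0, "g0"),
            (3, 0, 0, "M", 0, "g0"),
            (4, 0, 0, "F", 0, "g0"),
            # training generation
            (5, 1, 2, "M", 1, None),
            (6, 3, 4, "F", 1, None),
            (7, 1, 4, "F", 1, None),  # training animal without progeny
            # validation generation
            (8, 5, 6, "M", 2, None),   # validation sire with progeny
            (9, 5, 6, "F", 2, None),   # validation dam with progeny
            (10, 5, 6, "M", 2, None),  # no progeny -> preculled under VGP
            # progeny of validation animals
            (11, 8, 9, "M", 3, None),
            (12, 8, 9, "F", 3, None),
        ],
        columns=["animal", "sire", "dam", "sex", "cohort", "group"],
    )
    animals = ped["animal"].to_numpy()
    phen = pd.DataFrame(
        {
            "animal": animals,
            "trait": "t",
            "value": np.linspace(-1.0, 1.0, len(animals)),
            "batch": "b0",
            "litter": "l0",
        }
    )
    rng = np.random.default_rng(0)
    geno = GenotypeMatrix(
        animals,
        np.array(["s1", "s2", "s3", "s4"]),
        rng.integers(0, 3, size=(len(animals), 4)).astype(float),
    )
    tbv = pd.DataFrame({"t": np.zeros(len(animals))}, index=animals)
    return StudyDataset(
        Pedigree(ped), geno, phen, tbv, training_cutoff=1, seed=0
    )


@pytest.fixture
def small_dataset():
    return tiny_dataset()
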