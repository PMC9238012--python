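"""Pedigree container, validation and I/O.

A pedigree is an ordered set of animal records with parent links, sex,
a discrete birth cohort, and (for animals with at least one unknown
parent) an unknown-parent-group label.  Unknown parents are coded as 0
on disk and as index -1 internally.  Records must be topologically
orderable: every known parent is itself an animal with a strictly
smaller cohort, so sorting by cohort yields parents-before-offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = 0

_COLUMNS = ["animal", "sire", "dam", "sex", "cohort", "group"]


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Validated pedigree in parents-before-offspring order.

    Parameters
    ----------
    frame
        Columns ``animal, sire, dam, sex, cohort`` and optionally
        ``group``.  ``animal`` ids are positive integers, unknown
        parents are ``0``, ``sex`` is ``"M"``/``"F"``, ``cohort`` a
        non-negative integer generation index.  ``group`` labels the
        unknown-parent group and must be present exactly for animals
        with at least one unknown parent.
    """

    frame: pd.DataFrame
    ids: np.ndarray = field(init=False, repr=False)
    sire_idx: np.ndarray = field(init=False, repr=False)
    dam_idx: np.ndarray = field(init=False, repr=False)
    cohort: np.ndarray = field(init=False, repr=False)
    sex: np.ndarray = field(init=False, repr=False)
    groups: list = field(init=False, repr=False)
    group_idx: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        df = self.frame.copy()
        missing = [c for c in ("animal", "sire", "dam", "sex", "cohort") if c not in df.columns]
        if missing:
            raise PedigreeError(f"pedigree is missing columns {missing}")
        if "group" not in df.columns:
            df["group"] = None
        df = df[_COLUMNS].sort_values(["cohort", "animal"], kind="stable").reset_index(drop=True)

        ids = df["animal"].to_numpy(dtype=np.int64)
        if len(np.unique(ids)) != len(ids):
            raise PedigreeError("duplicate animal ids")
        if (ids <= 0).any():
            raise PedigreeError("animal ids must be >= 1")
        pos = {a: i for i, a in enumerate(ids)}

        def parent_index(col: str) -> np.ndarray:
            out = np.full(len(ids), -1, dtype=np.int64)
            for i, p in enumerate(df[col].to_numpy(dtype=np.int64)):
                if p == UNKNOWN:
                    continue
                if p not in pos:
                    raise PedigreeError(f"{col} {p} of animal {ids[i]} not in pedigree")
                out[i] = pos[p]
            return out

        self.ids = ids
        self.sire_idx = parent_index("sire")
        self.dam_idx = parent_index("dam")
        self.cohort = df["cohort"].to_numpy(dtype=np.int64)
        self.sex = df["sex"].to_numpy(dtype=object)
        if not np.isin(self.sex, ["M", "F"]).all():
            raise PedigreeError("sex must be 'M' or 'F'")

        for name, pidx, want in (("sire", self.sire_idx, "M"), ("dam", self.dam_idx, "F")):
            known = pidx >= 0
            if known.any():
                if (self.cohort[pidx[known]] >= self.cohort[known]).any():
                    raise PedigreeError(f"{name} cohorts must precede offspring cohorts")
                if (self.sex[pidx[known]] != want).any():
                    raise PedigreeError(f"every {name} must have sex {want}")

        has_unknown = (self.sire_idx < 0) | (self.dam_idx < 0)
        glab = df["group"].to_numpy(dtype=object)
        if any(g is None or (isinstance(g, float) and np.isnan(g)) for g in glab[has_unknown]):
            raise PedigreeError("animals with an unknown parent need a group label")
        self.groups = sorted({g for g in glab[has_unknown]})
        gpos = {g: k for k, g in enumerate(self.groups)}
        self.group_idx = np.array(
            [gpos[g] if u else -1 for g, u in zip(glab, has_unknown)], dtype=np.int64
        )
        self.frame = df

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def index_of(self, animals) -> np.ndarray:
        """Positions of the given animal ids, in the given order."""
        pos = pd.Index(self.ids)
        loc = pos.get_indexer(np.asarray(animals, dtype=np.int64))
        if (loc < 0).any():
            missing = np.asarray(animals)[loc < 0]
            raise PedigreeError(f"animals not in pedigree: {missing[:5].tolist()}")
        return loc

    def progeny_lists(self) -> list[list[int]]:
        """Per-animal list of offspring positions."""
        out: list[list[int]] = [[] for _ in range(self.n)]
        for i in range(self.n):
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0:
                    out[p].append(i)
        return out

    def ancestors_closure(self, positions) -> np.ndarray:
        """Boolean mask of the given positions plus all their ancestors."""
        keep = np.zeros(self.n, dtype=bool)
        stack = list(np.asarray(positions, dtype=np.int64))
        while stack:
            i = stack.pop()
            if keep[i]:
                continue
            keep[i] = True
            for p in (self.sire_idx[i], self.dam_idx[i]):
                if p >= 0 and not keep[p]:
                    stack.append(p)
        return keep

    def subset(self, mask: np.ndarray) -> "Pedigree":
        """Restrict to the masked animals; parents outside the mask become unknown.

        Animals that lose a known parent this way must already carry a
        group label or inherit the label of their cohort's base group;
        here we require the mask to be ancestor-closed so that never
        happens.
        """
        mask = np.asarray(mask, dtype=bool)
        kept = set(self.ids[mask].tolist())
        sub = self.frame.loc[mask].copy()
        if not set(sub.loc[sub["sire"] != UNKNOWN, "sire"]).issubset(kept) or not set(
            sub.loc[sub["dam"] != UNKNOWN, "dam"]
        ).issubset(kept):
            raise PedigreeError("subset mask must be closed under ancestry")
        return Pedigree(sub)

    # -- I/O ------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out["group"] = out["group"].fillna("-")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t")
        df["group"] = df["group"].replace("-", None)
        return cls(df)
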