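"""Biallelic SNP genotype matrix (0/1/2 allele counts, NaN missing)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class GenotypeMatrix:
    """Animals x SNPs matrix of minor/alt allele counts.

    ``calls`` holds 0.0, 1.0, 2.0 or NaN (missing call).
    """

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    calls: np.ndarray

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("calls shape does not match id lists")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("calls must be 0, 1, 2 or NaN")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.calls)

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP alt allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    def subset(self, animals=None, snps=None) -> "GenotypeMatrix":
        """Restrict to the given animal ids and/or SNP ids (order kept)."""
        a = np.arange(self.n_animals)
        s = np.arange(self.n_snps)
        if animals is not None:
            a = pd.Index(self.animal_ids).get_indexer(animals)
            if (a < 0).any():
                raise KeyError("unknown animal id in subset")
        if snps is not None:
            s = pd.Index(self.snp_ids).get_indexer(snps)
            if (s < 0).any():
                raise KeyError("unknown SNP id in subset")
        return GenotypeMatrix(self.animal_ids[a], self.snp_ids[s], self.calls[np.ix_(a, s)])

    # -- I/O ------------------------------------------------------------
    def to_raw(self, path) -> None:
        """Write PLINK .raw-style whitespace text (FID = IID = animal id)."""
        df = pd.DataFrame(self.calls, columns=self.snp_ids)
        meta = pd.DataFrame(
            {
                "FID": self.animal_ids,
                "IID": self.animal_ids,
                "PAT": 0,
                "MAT": 0,
                "SEX": 0,
                "PHENOTYPE": -9,
            }
        )
        out = pd.concat([meta.reset_index(drop=True), df.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep=" ", index=False, na_rep="NA")

    @classmethod
    def from_raw(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep=r"\s+")
        snps = [c for c in df.columns if c not in _RAW_META]
        return cls(df["IID"].to_numpy(), np.asarray(snps), df[snps].to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        """Compact matrix TSV: one row per animal, one column per SNP."""
        pd.DataFrame(self.calls, index=self.animal_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", index_label="animal", na_rep="NA"
        )

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="animal", na_values="NA")
        return cls(df.index.to_numpy(), df.columns.to_numpy(), df.to_numpy(dtype=float))
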