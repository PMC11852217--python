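"""Core in-memory containers shared across the pipeline.

The pipeline moves marker data around as a :class:`GenotypeMatrix`
(individual-major dosage matrix plus SNP metadata), phenotypes as a
:class:`PhenotypeTable` (tidy pandas frame), and realised kinship as a
:class:`GRMatrix`.  Missing genotypes are encoded as ``-1`` in an ``int8``
dosage matrix so that a 500 x 50k panel stays around 25 MB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: columns every snp_meta frame must carry
SNP_META_COLS = ("chrom", "pos", "snp_id", "a1", "a2")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with per-SNP metadata.

    dosages
        ``int8`` array, entries in {0, 1, 2} counting copies of allele
        ``a1``; ``-1`` marks a missing call.
    snp_meta
        DataFrame with columns ``chrom, pos, snp_id, a1, a2``; positions
        strictly increasing within each chromosome.
    sample_ids
        one id per row of ``dosages``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if self.dosages.shape[1] != len(self.snp_meta):
            raise ValueError("snp_meta length does not match dosage columns")
        bad = ~np.isin(self.dosages, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")
        missing = [c for c in SNP_META_COLS if c not in self.snp_meta.columns]
        if missing:
            raise ValueError(f"snp_meta lacks columns {missing}")
        for _, grp in self.snp_meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def dosages_float(self, impute_mean: bool = False) -> np.ndarray:
        """Dosages as float64 with missing as NaN (or mean-imputed per SNP)."""
        x = self.dosages.astype(np.float64)
        x[self.dosages == MISSING] = np.nan
        if impute_mean:
            col_mean = np.nanmean(x, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(x))
            x[idx] = col_mean[idx[1]]
        return x

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            snp_meta=self.snp_meta.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            snp_meta=self.snp_meta,
            sample_ids=[self.sample_ids[i] for i in index],
        )


@dataclass
class PhenotypeTable:
    """Tidy phenotype + covariate table, one row per individual record."""

    data: pd.DataFrame
    trait_cols: list[str]
    categorical_covariates: list[str] = field(default_factory=list)
    numeric_covariates: list[str] = field(default_factory=list)
    id_col: str = "sample_id"

    def __post_init__(self) -> None:
        cols = [self.id_col, *self.trait_cols, *self.categorical_covariates,
                *self.numeric_covariates]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data[self.id_col].astype(str).tolist()


@dataclass
class GRMatrix:
    """Symmetric genomic relationship matrix with provenance of weights."""

    values: np.ndarray
    sample_ids: list[str]
    weights_used: np.ndarray | None = None  # None == uniform

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match GRM order")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM must be symmetric to 1e-10")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def index_of(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as err:  # pragma: no cover - message formatting
            raise KeyError(f"sample id {err} not present in GRM") from err
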