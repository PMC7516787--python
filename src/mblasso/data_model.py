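"""Core domain types shared by every stage of the pipeline.

The genetic model is the linear mixed model

    y = 1*mu + Q*alpha + X*beta + eps,    eps ~ MVN(0, sigma2_e * I)

where ``X`` is an n x p matrix of SNP genotypes coded additively: the two
homozygotes are +1 and -1, the heterozygote is 0. ``Q`` holds optional fixed
effects such as population-structure proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

GENOTYPE_CODES = (-1, 0, 1)

PHENOTYPE_STAGES = ("raw", "corrected", "screen-corrected")


class GenotypeCodingError(ValueError):
    """A genotype entry falls outside the additive coding {1, 0, -1}."""


class StructuralError(ValueError):
    """Genotype matrix and SNP map are structurally inconsistent."""


def _as_map_frame(snp_map) -> pd.DataFrame:
    m = pd.DataFrame(snp_map)
    required = ["snp_id", "chromosome", "position"]
    if not all(c in m.columns for c in required):
        if m.shape[1] == 3:
            m.columns = required
        else:
            raise StructuralError(
                "SNP map needs columns (snp_id, chromosome, position); "
                f"got {list(m.columns)}"
            )
    return m[required].reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Validated n x p additive-coded SNP panel plus its physical map.

    Attributes
    ----------
    X : ndarray of shape (n, p)
        Genotype codes in {1, 0, -1} (int8).
    snp_map : DataFrame with columns snp_id, chromosome, position
        One row per SNP column, positions in base pairs. Internally columns
        are 0-based; all file I/O and reports are 1-based.
    """

    X: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self):
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise StructuralError("genotype matrix must be 2-dimensional")
        bad = ~np.isin(self.X, GENOTYPE_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeCodingError(
                f"genotype code {self.X[i, j]!r} at row {i}, column {j} "
                "is not in {1, 0, -1}"
            )
        self.X = self.X.astype(np.int8)
        self.snp_map = _as_map_frame(self.snp_map)
        if len(self.snp_map) != self.p:
            raise StructuralError(
                f"SNP map has {len(self.snp_map)} rows but matrix has "
                f"{self.p} columns"
            )
        pos = self.snp_map["position"].to_numpy()
        if not np.issubdtype(pos.dtype, np.integer) or (pos < 0).any():
            raise StructuralError("positions must be non-negative integers")
        if self.snp_map.duplicated(["chromosome", "position"]).any():
            raise StructuralError("(chromosome, position) pairs must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset_individuals(self, rows) -> "GenotypeMatrix":
        return GenotypeMatrix(self.X[np.asarray(rows)], self.snp_map.copy())

    def subset_snps(self, cols) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        return GenotypeMatrix(
            self.X[:, cols], self.snp_map.iloc[cols].reset_index(drop=True)
        )


def validate_genotypes(raw_matrix, snp_map) -> GenotypeMatrix:
    """Validate a raw integer matrix + map into a :class:`GenotypeMatrix`.

    Raises :class:`GenotypeCodingError` for entries outside {1, 0, -1}
    (missing values must be imputed first, see :func:`impute_mode`) and
    :class:`StructuralError` for map/matrix mismatches.
    """
    arr = np.asarray(raw_matrix)
    if arr.dtype == object:
        raise StructuralError("genotype matrix must be rectangular and numeric")
    return GenotypeMatrix(arr, snp_map)


def impute_mode(raw_matrix, missing=np.nan) -> np.ndarray:
    """Optional pre-step: fill missing genotype calls with the column mode.

    ``missing`` may be NaN or a sentinel code. Ties between modes resolve to
    the smaller code, deterministically.
    """
    arr = np.asarray(raw_matrix, dtype=float)
    if np.isnan(missing) if isinstance(missing, float) else False:
        mask = np.isnan(arr)
    else:
        mask = arr == missing
    out = arr.copy()
    for j in range(arr.shape[1]):
        col_mask = mask[:, j]
        if not col_mask.any():
            continue
        observed = arr[~col_mask, j]
        if observed.size == 0:
            raise GenotypeCodingError(f"column {j} is entirely missing")
        codes, counts = np.unique(observed, return_counts=True)
        out[col_mask, j] = codes[np.argmax(counts)]
    return out.astype(np.int8)


@dataclass
class PhenotypeVector:
    """Quantitative trait values with their correction stage.

    ``stage`` tracks whether the vector is the raw trait y, the
    fixed-effect-corrected y', or the screening-corrected y''.
    """

    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype values must all be finite")
        if self.stage not in PHENOTYPE_STAGES:
            raise ValueError(f"stage must be one of {PHENOTYPE_STAGES}")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class FixedEffects:
    """Fixed-effect covariates Q (n x q) and, after correction, alpha-hat."""

    Q: np.ndarray
    alpha_hat: np.ndarray | None = None

    def __post_init__(self):
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        if self.Q.size == 0:
            self.Q = self.Q.reshape(self.Q.shape[0] if self.Q.ndim == 2 else 0, 0)

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def q(self) -> int:
        return self.Q.shape[1]


@dataclass
class ScreenResult:
    """Outcome of one screening branch (Pearson or mutual information).

    ``type_i`` holds SNPs picked directly by SIS-SCAD; ``type_ii`` holds SNPs
    revived by the single ISIS iteration on the complement panel, so the two
    sets are disjoint by construction.
    """

    scores: np.ndarray
    type_i: np.ndarray
    type_ii: np.ndarray
    measure: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.type_i = np.asarray(sorted(set(np.asarray(self.type_i, dtype=int).tolist())))
        self.type_ii = np.asarray(sorted(set(np.asarray(self.type_ii, dtype=int).tolist())))
        if self.measure not in ("pearson", "mutual_information"):
            raise ValueError("measure must be 'pearson' or 'mutual_information'")
        if np.intersect1d(self.type_i, self.type_ii).size:
            raise ValueError("type I and type II screened sets must be disjoint")

    @property
    def union_set(self) -> np.ndarray:
        return np.union1d(self.type_i, self.type_ii).astype(int)

    @property
    def size(self) -> int:
        return self.type_i.size + self.type_ii.size


ASSOCIATION_COLUMNS = [
    "snp_id",
    "chromosome",
    "position",
    "effect",
    "lod",
    "p_value",
    "significant",
]


def association_table(
    snp_ids: Sequence,
    chromosomes: Sequence,
    positions: Sequence,
    effects: Sequence,
    lods: Sequence,
    p_values: Sequence,
    significant: Sequence,
) -> pd.DataFrame:
    """Assemble the final association table (one row per tested SNP)."""
    return pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chromosome": np.asarray(chromosomes),
            "position": np.asarray(positions),
            "effect": np.asarray(effects, dtype=float),
            "lod": np.asarray(lods, dtype=float),
            "p_value": np.asarray(p_values, dtype=float),
            "significant": np.asarray(significant, dtype=bool),
        }
    )


def empty_association_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": pd.Series(dtype=object),
            "chromosome": pd.Series(dtype=int),
            "position": pd.Series(dtype=int),
            "effect": pd.Series(dtype=float),
            "lod": pd.Series(dtype=float),
            "p_value": pd.Series(dtype=float),
            "significant": pd.Series(dtype=bool),
        }
    )


@dataclass
class SimTruth:
    """Ground truth of a simulated trait: QTN placement, effects, variances."""

    qtn_indices: np.ndarray
    qtn_effects: np.ndarray
    heritabilities: np.ndarray
    mu: float
    sigma2_e: float
    sigma2_pg: float = 0.0
    epistatic_pairs: list = field(default_factory=list)
    kinship: np.ndarray | None = None

    def __post_init__(self):
        self.qtn_indices = np.asarray(self.qtn_indices, dtype=int)
        self.qtn_effects = np.asarray(self.qtn_effects, dtype=float)
        self.heritabilities = np.asarray(self.heritabilities, dtype=float)
        h = self.heritabilities
        if ((h <= 0) | (h >= 1)).any() or h.sum() >= 1:
            raise ValueError("heritabilities must lie in (0,1) and sum below 1")
        if self.kinship is not None:
            K = np.asarray(self.kinship, dtype=float)
            if not np.allclose(K, K.T, atol=1e-8):
                raise ValueError("kinship matrix must be symmetric")
            w = np.linalg.eigvalsh(K)
            if w.min() < -1e-6 * max(1.0, abs(w.max())):
                raise ValueError("kinship matrix must be positive semi-definite")
            self.kinship = K
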