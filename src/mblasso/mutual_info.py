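"""Entropy and mutual information between SNP genotypes and a trait.

Mutual information I(X;Y) = H(X) + H(Y) - H(X,Y) is used as the second
screening measure alongside Pearson correlation: it is sensitive to any
dependence between a genotype column and the phenotype, not only linear
trends. The phenotype is discretized by equal-width binning (default
round(sqrt(n)) bins); genotypes are already discrete on {1, 0, -1}. All
entropies are in nats; rankings are base-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import PhenotypeVector


def entropy(p) -> float:
    """Shannon entropy -sum p*log(p) in nats, with 0*log(0) := 0."""
    p = np.asarray(p, dtype=float).ravel()
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1 (got {p.sum():.12g})")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class JointDistribution:
    """Joint distribution of a discrete genotype X and binned phenotype Y."""

    joint: np.ndarray  # |X| x |Y| probabilities
    n_obs: int

    def __post_init__(self):
        self.joint = np.asarray(self.joint, dtype=float)
        if (self.joint < 0).any():
            raise ValueError("joint probabilities must be non-negative")
        if abs(self.joint.sum() - 1.0) > 1e-9:
            raise ValueError("joint probabilities must sum to 1")

    @classmethod
    def from_counts(cls, counts, laplace: float = 0.0) -> "JointDistribution":
        counts = np.asarray(counts, dtype=float)
        n_obs = int(round(counts.sum()))
        if laplace > 0:
            counts = counts + laplace
        total = counts.sum()
        if total <= 0:
            raise ValueError("joint counts are empty")
        return cls(counts / total, n_obs=n_obs)

    @property
    def px(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def py(self) -> np.ndarray:
        return self.joint.sum(axis=0)


def mutual_information(joint: JointDistribution) -> float:
    """I(X;Y) via the entropy identity H(X) + H(Y) - H(X,Y)."""
    return entropy(joint.px) + entropy(joint.py) - entropy(joint.joint.ravel())


def mutual_information_direct(joint: JointDistribution) -> float:
    """I(X;Y) via the double sum of p(x,y)*log(p(x,y)/(p(x)p(y))).

    Kept alongside :func:`mutual_information` as an algebraically independent
    route to the same quantity; the two must agree to tight tolerance.
    """
    p = joint.joint
    px = joint.px[:, None]
    py = joint.py[None, :]
    mask = p > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, p * np.log(p / (px * py)), 0.0)
    return float(terms[mask].sum())


def discretize_phenotype(values, bins: int) -> np.ndarray:
    """Equal-width binning of a continuous trait over [min, max].

    Returns integer bin labels in [0, bins). The maximum value lands in the
    top bin. A constant trait maps to bin 0 everywhere.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros(v.size, dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    labels = np.digitize(v, edges[1:-1], right=False)
    return labels


def default_bins(n: int) -> int:
    """Histogram rule of thumb: round(sqrt(n)) equal-width bins."""
    return max(2, int(round(np.sqrt(n))))


def snp_phenotype_mi(x_col, y_prime, bins: int | None = None,
                     laplace: float = 0.0) -> float:
    """Mutual information between one SNP column and the (binned) trait."""
    x = np.asarray(x_col).ravel()
    y = y_prime.values if isinstance(y_prime, PhenotypeVector) else np.asarray(
        y_prime, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("genotype column and phenotype lengths differ")
    if bins is None:
        bins = default_bins(y.size)
    if bins < 2:
        raise ValueError("need at least 2 phenotype bins")
    if y.max() == y.min():
        warnings.warn("constant phenotype: mutual information is 0")
        return 0.0
    yb = discretize_phenotype(y, bins)
    xi = (x + 1).astype(int)  # codes {-1,0,1} -> states {0,1,2}
    counts = np.zeros((3, bins))
    np.add.at(counts, (xi, yb), 1.0)
    return mutual_information(JointDistribution.from_counts(counts, laplace))


def mi_scores(X, y_prime, bins: int | None = None,
              laplace: float = 0.0) -> np.ndarray:
    """MI of every SNP column against the trait (the psi score vector)."""
    X = np.asarray(X)
    y = y_prime.values if isinstance(y_prime, PhenotypeVector) else np.asarray(
        y_prime, dtype=float).ravel()
    n, p = X.shape
    if bins is None:
        bins = default_bins(n)
    if y.max() == y.min():
        warnings.warn("constant phenotype: all MI scores are 0")
        return np.zeros(p)
    yb = discretize_phenotype(y, bins)
    # flat joint index per SNP: 3 genotype states x `bins` phenotype bins
    out = np.empty(p)
    for j in range(p):
        flat = (X[:, j].astype(int) + 1) * bins + yb
        counts = np.bincount(flat, minlength=3 * bins).reshape(3, bins)
        out[j] = mutual_information(
            JointDistribution.from_counts(counts, laplace)
        )
    return out
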