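"""Stage-1 screening: marginal sure-independence screening refined by SCAD.

Two branches run on the corrected phenotype y':

* Pearson branch: rank SNPs by |correlation| (omega scores), keep the top
  n-1, fit SCAD on the survivors, keep the nonzero coefficients (Type I set
  A2). One ISIS iteration then subtracts the fitted Type-I contribution from
  y' and re-screens the complement panel, reviving SNPs that are marginally
  weak but jointly informative (Type II set A3).
* Mutual-information branch: identical flow with MI (psi) scores, used raw
  since MI is non-negative (sets B2, B3).

The candidate set for stage 2 is C = (A2 u A3) u (B2 u B3) with duplicates
removed.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import MblassoConfig
from .data_model import PhenotypeVector, ScreenResult
from .mutual_info import mi_scores
from .scad import ScadFit, scad_fit


def _values(y) -> np.ndarray:
    return y.values if isinstance(y, PhenotypeVector) else np.asarray(
        y, dtype=float).ravel()


def pearson_scores(X, y_prime) -> np.ndarray:
    """Pearson correlation of every SNP column with y' (the omega vector)."""
    X = np.asarray(X, dtype=float)
    y = _values(y_prime)
    if X.shape[0] != y.size:
        raise ValueError("genotype rows and phenotype length differ")
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    if y_ss == 0:
        raise ValueError("phenotype is constant; correlations undefined")
    Xc = X - X.mean(axis=0)
    x_ss = (Xc**2).sum(axis=0)
    const = x_ss == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant SNP column(s) scored 0")
    denom = np.sqrt(np.where(const, 1.0, x_ss) * y_ss)
    omega = (Xc.T @ yc) / denom
    omega[const] = 0.0
    return omega


def top_select(scores, n: int, use_absolute: bool = True) -> np.ndarray:
    """Indices whose score reaches the (n-1)-th largest value, ties included.

    ``n`` is the sample size; the screen targets the n-1 top-ranked SNPs but
    every SNP tied with the cutoff value is kept, so the result may be
    larger. When the panel is smaller than the target, everything is kept.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    vals = np.abs(scores) if use_absolute else np.asarray(scores, dtype=float)
    k = n - 1
    p = vals.size
    if p <= k:
        warnings.warn(f"panel size {p} <= screen target {k}; keeping all SNPs")
        return np.arange(p)
    cutoff = np.partition(vals, p - k)[p - k]
    return np.flatnonzero(vals >= cutoff)


def _scores(X, y_prime, measure: str, config: MblassoConfig) -> np.ndarray:
    if measure == "pearson":
        return pearson_scores(X, y_prime)
    if measure in ("mi", "mutual_information"):
        return mi_scores(X, y_prime, bins=config.bins, laplace=config.laplace)
    raise ValueError(f"unknown measure {measure!r}")


def sis_scad(X, y_prime, measure: str,
             config: MblassoConfig | None = None
             ) -> tuple[np.ndarray, ScadFit, np.ndarray]:
    """Marginal screen + SCAD refinement (SIS-SCAD / MI-SIS-SCAD).

    Returns (type_i indices into X's columns, the SCAD fit on the screened
    design, the full score vector).
    """
    config = config or MblassoConfig()
    X = np.asarray(X, dtype=float)
    y = _values(y_prime)
    scores = _scores(X, y_prime, measure, config)
    target = config.screen_target(y.size) + 1  # top_select takes sample size
    selected = top_select(scores, target,
                          use_absolute=(measure == "pearson"))
    fit = scad_fit(y, X[:, selected], gamma=config.gamma,
                   lambda_strategy=config.lambda_strategy,
                   cv=config.cv_folds, random_state=config.seed)
    type_i = selected[fit.nonzero]
    return type_i, fit, scores


def isis_iteration(X, y_prime, type_i, fit: ScadFit, measure: str,
                   config: MblassoConfig | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One ISIS step: correct y' by the Type-I SCAD fit, re-screen the rest.

    y'' = y' - X[:, type_i] @ beta_scad (coefficients from the Step-3 fit,
    not refitted). Returns (type_ii indices, y'' values). Exactly one
    iteration is performed.
    """
    config = config or MblassoConfig()
    X = np.asarray(X, dtype=float)
    y = _values(y_prime)
    type_i = np.asarray(type_i, dtype=int)
    p = X.shape[1]
    if type_i.size >= p:
        return np.array([], dtype=int), y.copy()
    if type_i.size == 0:
        y_dprime = y.copy()
    else:
        # type_i == selected[fit.nonzero], both ascending, so the Type-I
        # columns align with the nonzero entries of the screened-design fit
        y_dprime = y - X[:, type_i] @ fit.beta_hat[fit.nonzero]
    complement = np.setdiff1d(np.arange(p), type_i)
    y2 = PhenotypeVector(y_dprime, stage="screen-corrected")
    try:
        type_ii_local, _, _ = sis_scad(X[:, complement], y2, measure, config)
    except ValueError:
        warnings.warn("ISIS iteration skipped: corrected phenotype degenerate")
        return np.array([], dtype=int), y_dprime
    return complement[type_ii_local], y_dprime


def screen(X, y_prime, measure: str,
           config: MblassoConfig | None = None) -> ScreenResult:
    """Full SIS-SCAD + one-iteration ISIS for one measure; A or B set."""
    config = config or MblassoConfig()
    type_i, fit, scores = sis_scad(X, y_prime, measure, config)
    type_ii, _ = isis_iteration(X, y_prime, type_i, fit, measure, config)
    label = "pearson" if measure == "pearson" else "mutual_information"
    return ScreenResult(scores=scores, type_i=type_i, type_ii=type_ii,
                        measure=label)


def union_candidates(A: ScreenResult, B: ScreenResult
                     ) -> tuple[np.ndarray, float]:
    """Union C = A u B of the two branches, plus the overlap ratio.

    Overlap is |A n B| / |C|, the Jaccard-style diagnostic of how different
    the two measures' selections are. |C| <= |A| + |B| after de-duplication.
    """
    a, b = A.union_set, B.union_set
    C = np.union1d(a, b).astype(int)
    if C.size == 0:
        return C, 0.0
    overlap = np.intersect1d(a, b).size / C.size
    return C, float(overlap)
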