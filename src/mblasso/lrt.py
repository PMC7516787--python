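"""Likelihood-ratio testing of retained markers with LOD scoring.

For the retained design of o markers, each marker k is tested by comparing
the maximized Gaussian log-likelihood of the full model (L1) against the
model with marker k removed (L0), all other effects, the mean and the
residual variance re-maximized under the null. The LOD score is

    LOD = -2 (L0 - L1) / 4.6052          (4.6052 = 2 ln 10)

i.e. the log10 likelihood ratio. Under H0, LOD * 4.6052 follows chi^2 with
1 df, so LOD >= 3 corresponds to p ~ 0.0002 — a deliberately stringent
multi-locus significance rule that needs no further multiple-test
correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

LOD_SCALE = 4.6052  # 2 * ln(10), to the precision conventionally used


def lod_score(L0: float, L1: float) -> float:
    """LOD = -2 (L0 - L1) / 4.6052 from two natural-log likelihoods."""
    if not (np.isfinite(L0) and np.isfinite(L1)):
        raise ValueError("log-likelihoods must be finite")
    if L1 < L0:
        warnings.warn("L1 < L0 for nested models; clamping LOD at 0")
        return 0.0
    return float(-2.0 * (L0 - L1) / LOD_SCALE)


def lod_p_value(lod) -> np.ndarray | float:
    """Upper-tail chi^2(1 df) probability at the deviance LOD * 4.6052."""
    return stats.chi2.sf(np.asarray(lod, dtype=float) * LOD_SCALE, df=1)


def _profile_loglik(y: np.ndarray, design: np.ndarray) -> float:
    """Max Gaussian log-likelihood with effects and sigma2 profiled out.

    ``design`` includes the intercept column. Singular designs are
    ridge-stabilized with a warning.
    """
    n = y.size
    coef, rss_arr, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("singular design in likelihood-ratio test; "
                      "applying ridge-stabilized refit")
        G = design.T @ design + 1e-8 * np.eye(design.shape[1])
        coef = np.linalg.solve(G, design.T @ y)
    resid = y - design @ coef
    sigma2 = max(float(resid @ resid) / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def test_marker(y, X_retained, k: int) -> tuple[float, float]:
    """LOD and p-value for marker ``k`` within the retained design.

    L1: full o-marker model (plus intercept); L0: marker k removed,
    remaining o-1 effects, the mean and the residual variance re-maximized.
    """
    yv = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X_retained, dtype=float))
    if X.shape[0] != yv.size:
        raise ValueError("design rows and phenotype length differ")
    o = X.shape[1]
    if not 0 <= k < o:
        raise IndexError(f"marker index {k} outside 0..{o - 1}")
    ones = np.ones((yv.size, 1))
    L1 = _profile_loglik(yv, np.hstack([ones, X]))
    L0 = _profile_loglik(yv, np.hstack([ones, np.delete(X, k, axis=1)]))
    lod = lod_score(L0, L1)
    return lod, float(lod_p_value(lod))


def test_all_markers(y, X_retained) -> tuple[np.ndarray, np.ndarray]:
    """LOD and p-value for every marker of the retained design."""
    X = np.atleast_2d(np.asarray(X_retained, dtype=float))
    lods = np.empty(X.shape[1])
    pvals = np.empty(X.shape[1])
    for k in range(X.shape[1]):
        lods[k], pvals[k] = test_marker(y, X, k)
    return lods, pvals


def call_significant(results: pd.DataFrame, threshold: float = 3.0
                     ) -> pd.DataFrame:
    """Flag rows whose LOD reaches the threshold (inclusive)."""
    if "lod" not in results.columns:
        raise ValueError("results table lacks a 'lod' column")
    out = results.copy()
    out["significant"] = out["lod"] >= threshold
    return out
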