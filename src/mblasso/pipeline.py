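"""End-to-end orchestration of the two-stage multi-locus GWAS.

Flow (the MBLASSO pathway):

1.  correct the phenotype for fixed effects (population structure), y -> y'
2.  Pearson SIS-SCAD + one ISIS iteration         -> sets A2, A3
3.  mutual-information SIS-SCAD + one ISIS iter   -> sets B2, B3
4.  union the branches, de-duplicated             -> candidate set C
5.  EM Bayesian Lasso on the ORIGINAL y over C, retain |beta| >= 1e-5
6.  likelihood-ratio test per retained marker, significance at LOD >= 3

Setting measure="pearson" reproduces the Pearson-only (ISIS EM-BLASSO
style) pathway; a single-stage mode skips screening entirely and shrinks
the whole panel (guarded by a size cap).
"""

from __future__ import annotations

import json
import logging
import time
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import MblassoConfig
from .data_model import (
    FixedEffects,
    GenotypeMatrix,
    PhenotypeVector,
    ScreenResult,
    association_table,
    empty_association_table,
)
from .emblasso import EMBayesianLasso
from .io_preprocess import correct_phenotype
from .lrt import test_all_markers
from .screening import screen, union_candidates

logger = logging.getLogger("mblasso")


class MBLASSO(BaseEstimator):
    """Two-stage multi-locus GWAS estimator.

    Parameters mirror :class:`~mblasso.config.MblassoConfig`; see there for
    semantics. ``fit`` accepts a genotype matrix (or raw array), the trait
    vector, and optionally fixed-effect covariates.

    Attributes (after fit)
    ----------------------
    results_ : DataFrame
        One row per tested marker: snp_id, chromosome, position, effect,
        lod, p_value, significant.
    candidates_ : ndarray        -- candidate set C (column indices)
    screen_pearson_, screen_mi_ : ScreenResult or None
    overlap_ratio_ : float       -- |A n B| / |C| diagnostic
    stage_sizes_ : dict          -- k2, k3, k, tau2, tau3, tau, nu, o
    emblasso_ : EMBayesianLasso  -- fitted stage-2 model
    """

    def __init__(self, measure="both", screening_size="n-1", bins=None,
                 laplace=0.0, gamma=3.7, lambda_strategy="bic", cv_folds=5,
                 lod_threshold=3.0, effect_threshold=1e-5, em_max_iter=1000,
                 em_tol=1e-8, single_stage_cap=5000, seed=0):
        self.measure = measure
        self.screening_size = screening_size
        self.bins = bins
        self.laplace = laplace
        self.gamma = gamma
        self.lambda_strategy = lambda_strategy
        self.cv_folds = cv_folds
        self.lod_threshold = lod_threshold
        self.effect_threshold = effect_threshold
        self.em_max_iter = em_max_iter
        self.em_tol = em_tol
        self.single_stage_cap = single_stage_cap
        self.seed = seed

    # ------------------------------------------------------------------
    def _config(self) -> MblassoConfig:
        return MblassoConfig(**{k: getattr(self, k) for k in (
            "measure", "screening_size", "bins", "laplace", "gamma",
            "lambda_strategy", "cv_folds", "lod_threshold",
            "effect_threshold", "em_max_iter", "em_tol",
            "single_stage_cap", "seed")})

    @staticmethod
    def _coerce(G, y, Q):
        if not isinstance(G, GenotypeMatrix):
            from .data_model import validate_genotypes
            import pandas as pd

            p = np.asarray(G).shape[1]
            snp_map = pd.DataFrame({
                "snp_id": [f"snp{j + 1}" for j in range(p)],
                "chromosome": 1,
                "position": np.arange(1, p + 1),
            })
            G = validate_genotypes(np.asarray(G), snp_map)
        if not isinstance(y, PhenotypeVector):
            y = PhenotypeVector(np.asarray(y, dtype=float), stage="raw")
        if Q is None:
            Q = FixedEffects(np.zeros((G.n, 0)))
        elif not isinstance(Q, FixedEffects):
            Q = FixedEffects(np.asarray(Q, dtype=float))
        if G.n != y.n:
            raise ValueError(f"genotypes have {G.n} rows, phenotype {y.n}")
        return G, y, Q

    def _finalize(self, G, y, em: EMBayesianLasso, candidates: np.ndarray):
        """Stage 2 epilogue: threshold, LRT, assemble the results table."""
        cfg = self._config()
        retained = candidates[em.retained_]
        self.stage_sizes_["o"] = int(retained.size)
        if retained.size == 0:
            warnings.warn("no marker survived the shrinkage threshold; "
                          "empty association result")
            self.results_ = empty_association_table()
            self.significant_ = self.results_
            return self
        X_ret = G.X[:, retained].astype(float)
        lods, pvals = test_all_markers(y.values, X_ret)
        effects = em.coef_[em.retained_]
        m = G.snp_map.iloc[retained]
        self.results_ = association_table(
            m["snp_id"], m["chromosome"], m["position"], effects, lods,
            pvals, lods >= cfg.lod_threshold,
        )
        self.retained_ = retained
        self.significant_ = self.results_[self.results_["significant"]]
        return self

    # ------------------------------------------------------------------
    def fit(self, G, y, Q=None):
        """Run screening + shrinkage + testing; populates ``results_``."""
        t0 = time.time()
        cfg = self._config()
        G, y, Q = self._coerce(G, y, Q)
        self.stage_sizes_ = {}

        y_prime = correct_phenotype(y, Q)
        X = G.X.astype(float)

        A: ScreenResult | None = None
        B: ScreenResult | None = None
        if cfg.measure in ("both", "pearson"):
            A = screen(X, y_prime, "pearson", cfg)
            self.stage_sizes_.update(
                k2=int(A.type_i.size), k3=int(A.type_ii.size), k=int(A.size))
            logger.info("Pearson screen: |A2|=%d |A3|=%d",
                        A.type_i.size, A.type_ii.size)
        if cfg.measure in ("both", "mi"):
            B = screen(X, y_prime, "mi", cfg)
            self.stage_sizes_.update(
                tau2=int(B.type_i.size), tau3=int(B.type_ii.size),
                tau=int(B.size))
            logger.info("MI screen: |B2|=%d |B3|=%d",
                        B.type_i.size, B.type_ii.size)

        if A is not None and B is not None:
            C, overlap = union_candidates(A, B)
        else:
            C = (A or B).union_set
            overlap = 1.0 if C.size else 0.0
        self.screen_pearson_ = A
        self.screen_mi_ = B
        self.overlap_ratio_ = overlap
        self.candidates_ = C
        self.stage_sizes_["nu"] = int(C.size)
        logger.info("candidate set: nu=%d (overlap %.3f)", C.size, overlap)

        if C.size == 0:
            warnings.warn("empty candidate set after screening; "
                          "empty association result")
            self.stage_sizes_["o"] = 0
            self.results_ = empty_association_table()
            self.significant_ = self.results_
            return self

        # Stage 2 runs on the ORIGINAL phenotype y
        em = EMBayesianLasso(max_iter=cfg.em_max_iter, tol=cfg.em_tol,
                             effect_threshold=cfg.effect_threshold)
        em.fit(X[:, C], y.values)
        self.emblasso_ = em
        self._finalize(G, y, em, C)
        logger.info("pipeline done in %.2fs: %s", time.time() - t0,
                    self.stage_sizes_)
        return self

    def fit_single_stage(self, G, y, Q=None):
        """No-screening mode: EM Bayesian Lasso over the whole panel + LRT.

        Refuses panels larger than ``single_stage_cap`` columns; use the
        screened pathway for those.
        """
        cfg = self._config()
        G, y, Q = self._coerce(G, y, Q)
        if G.p > cfg.single_stage_cap:
            raise ValueError(
                f"panel has {G.p} SNPs, above the single-stage cap of "
                f"{cfg.single_stage_cap}; run the screened pipeline instead")
        self.stage_sizes_ = {"nu": int(G.p)}
        self.screen_pearson_ = self.screen_mi_ = None
        self.overlap_ratio_ = float("nan")
        self.candidates_ = np.arange(G.p)
        em = EMBayesianLasso(max_iter=cfg.em_max_iter, tol=cfg.em_tol,
                             effect_threshold=cfg.effect_threshold)
        em.fit(G.X.astype(float), y.values)
        self.emblasso_ = em
        return self._finalize(G, y, em, self.candidates_)

    def log_json(self, path) -> None:
        """Write the per-stage bookkeeping to a JSON file."""
        payload = {"stage_sizes": self.stage_sizes_,
                   "overlap_ratio": self.overlap_ratio_,
                   "n_significant": int(self.results_["significant"].sum())}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def run_mblasso(G, y, Q=None, config: MblassoConfig | None = None
                ) -> pd.DataFrame:
    """Functional wrapper over :class:`MBLASSO`; returns the results table."""
    config = config or MblassoConfig()
    est = MBLASSO(**config.to_dict())
    est.fit(G, y, Q)
    return est.results_


def run_emblasso_single_stage(G, y, Q=None,
                              config: MblassoConfig | None = None
                              ) -> pd.DataFrame:
    """Single-stage (no pre-screening) pathway; returns the results table."""
    config = config or MblassoConfig()
    est = MBLASSO(**config.to_dict())
    est.fit_single_stage(G, y, Q)
    return est.results_
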