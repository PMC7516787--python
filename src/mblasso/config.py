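"""Run configuration shared by the screening stage and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class MblassoConfig:
    """All tunables of the two-stage pipeline.

    Attributes
    ----------
    measure : {"both", "pearson", "mi"}
        Which screening branches to run. "pearson" reproduces the
        Pearson-only (ISIS EM-BLASSO style) pathway.
    screening_size : {"n-1", "n/logn"}
        Target size of each marginal screen.
    bins : int or None
        Phenotype bins for the MI screen; None -> round(sqrt(n)).
    laplace : float
        Optional pseudo-count smoothing of MI joint tables (0 = off).
    gamma : float
        SCAD shrinkage parameter (> 2).
    lambda_strategy : {"bic", "cv"}
        SCAD penalty selection along the path.
    lod_threshold : float
        Significance cutoff on the LOD score (default 3).
    effect_threshold : float
        Post-shrinkage retention rule: keep |beta| >= this (default 1e-5).
    single_stage_cap : int
        Guard for the no-screening mode: refuse p above this.
    seed : int
        Seeds any stochastic component (CV folds); the default pipeline
        (BIC selection) is fully deterministic.
    """

    measure: str = "both"
    screening_size: str = "n-1"
    bins: int | None = None
    laplace: float = 0.0
    gamma: float = 3.7
    lambda_strategy: str = "bic"
    cv_folds: int = 5
    lod_threshold: float = 3.0
    effect_threshold: float = 1e-5
    em_max_iter: int = 1000
    em_tol: float = 1e-8
    single_stage_cap: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.measure not in ("both", "pearson", "mi"):
            raise ValueError("measure must be 'both', 'pearson' or 'mi'")
        if self.screening_size not in ("n-1", "n/logn"):
            raise ValueError("screening_size must be 'n-1' or 'n/logn'")

    def screen_target(self, n: int) -> int:
        """Number of SNPs each marginal screen aims to keep."""
        import numpy as np

        if self.screening_size == "n-1":
            return max(2, n - 1)
        return max(2, int(np.floor(n / np.log(n))))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "MblassoConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
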