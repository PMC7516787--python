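"""Synthetic genotype panels and the three benchmark trait scenarios.

The generator emulates the benchmark design used throughout the package's
evaluation suite: n = 199 individuals, p SNPs spread evenly over five
chromosomes, six genuine QTNs with per-QTN heritabilities
(0.10, 0.05, 0.05, 0.15, 0.05, 0.05), QTN allele frequency ~= 0.30,
overall mean 10.0 and residual variance 10.0. Three trait scenarios:

1. additive:      y = mu + sum_i x_i b_i + eps
2. + polygenes:   ... + u,  u ~ MVN(0, sigma2_pg K)   (sigma2_pg = 2)
3. + epistasis:   ... + sum_j (A_j . B_j) b_jj        (Hadamard product,
                  three pairs, sigma2_epi = 1.25 each)

Effect sizes are back-calculated from heritabilities through the variance
accounting identity

    V_P = (sum_i h_i) V_P + sigma2_pg + sigma2_epi_total + sigma2_e
    =>  V_P = (sigma2_e + sigma2_pg + sigma2_epi_total) / (1 - sum_i h_i)

and b_i = sqrt(h_i V_P / Var(x_i)) with Var(x_i) = 2 f_i (1 - f_i) under
Hardy-Weinberg equilibrium for the {1, 0, -1} coding. Genotypes are drawn
under HWE, optionally with autoregressive within-block correlation to
emulate linkage disequilibrium.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GenotypeMatrix, PhenotypeVector, SimTruth

BENCHMARK_HERITABILITIES = (0.10, 0.05, 0.05, 0.15, 0.05, 0.05)
BENCHMARK_MU = 10.0
BENCHMARK_SIGMA2_E = 10.0
BENCHMARK_SIGMA2_PG = 2.0
BENCHMARK_SIGMA2_EPI = 1.25
QTN_MAF = 0.30


def _hwe_probs(f: np.ndarray) -> np.ndarray:
    """P(code = +1, 0, -1) columns under HWE for +1-allele frequency f."""
    return np.stack([f**2, 2 * f * (1 - f), (1 - f) ** 2], axis=-1)


def genotype_variance(f) -> np.ndarray:
    """Var of the {1,0,-1} code under HWE: 2 f (1-f)."""
    f = np.asarray(f, dtype=float)
    return 2.0 * f * (1.0 - f)


def default_qtn_indices(p: int, n_qtn: int = 6) -> np.ndarray:
    """Spread the QTNs evenly through the panel (deterministic)."""
    return np.unique((np.arange(1, n_qtn + 1) * p // (n_qtn + 1)).astype(int))


def simulate_genotypes(n: int, p: int, maf_range=(0.05, 0.5),
                       qtn_indices=None, qtn_maf: float = QTN_MAF,
                       ld_rho: float = 0.0, ld_block: int = 50,
                       n_chromosomes: int = 5, mean_spacing: int = 400,
                       seed=None) -> GenotypeMatrix:
    """Sample an n x p HWE genotype panel in {1, 0, -1} coding.

    Per-SNP +1-allele frequencies are uniform on ``maf_range``; columns
    listed in ``qtn_indices`` are forced to ``qtn_maf``. With ``ld_rho`` > 0
    a Gaussian copula with AR(1) correlation inside blocks of ``ld_block``
    SNPs induces linkage-disequilibrium-like local correlation. SNPs are
    assigned to ``n_chromosomes`` chromosomes with strictly increasing
    positions (mean spacing ~``mean_spacing`` bp).
    """
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    freqs = rng.uniform(lo, hi, size=p)
    if qtn_indices is not None:
        freqs[np.asarray(qtn_indices, dtype=int)] = qtn_maf

    probs = _hwe_probs(freqs)  # p x 3 for codes (+1, 0, -1)
    if ld_rho == 0.0:
        u = rng.random((n, p))
    else:
        if not -1 < ld_rho < 1:
            raise ValueError("ld_rho must lie in (-1, 1)")
        z = np.empty((n, p))
        innov = rng.standard_normal((n, p))
        scale = np.sqrt(1 - ld_rho**2)
        for j in range(p):
            if j % ld_block == 0:
                z[:, j] = innov[:, j]
            else:
                z[:, j] = ld_rho * z[:, j - 1] + scale * innov[:, j]
        u = stats.norm.cdf(z)
    # thresholds of the copula: u < f^2 -> +1 ; < f^2 + 2f(1-f) -> 0 ; else -1
    t1 = probs[:, 0]
    t2 = probs[:, 0] + probs[:, 1]
    X = np.where(u < t1, 1, np.where(u < t2, 0, -1)).astype(np.int8)

    per_chrom = int(np.ceil(p / n_chromosomes))
    chrom = 1 + np.arange(p) // per_chrom
    spacing = rng.integers(mean_spacing // 2, mean_spacing * 3 // 2, size=p)
    position = np.empty(p, dtype=int)
    for c in np.unique(chrom):
        mask = chrom == c
        position[mask] = np.cumsum(spacing[mask])
    snp_map = pd.DataFrame({
        "snp_id": [f"snp{j + 1}" for j in range(p)],
        "chromosome": chrom.astype(int),
        "position": position,
    })
    return GenotypeMatrix(X, snp_map)


def total_phenotypic_variance(heritabilities, sigma2_e: float,
                              sigma2_pg: float = 0.0,
                              sigma2_epi_total: float = 0.0) -> float:
    """Solve V_P = (sum h) V_P + sigma2_pg + sigma2_epi_total + sigma2_e."""
    h_sum = float(np.sum(heritabilities))
    if h_sum >= 1:
        raise ValueError("heritabilities must sum below 1")
    return (sigma2_e + sigma2_pg + sigma2_epi_total) / (1.0 - h_sum)


def effects_from_heritability(heritabilities, mafs, sigma2_e: float,
                              sigma2_pg: float = 0.0,
                              sigma2_epi_total: float = 0.0) -> np.ndarray:
    """QTN effects b_i = sqrt(h_i V_P / Var(x_i)), positive sign convention."""
    h = np.asarray(heritabilities, dtype=float)
    V_P = total_phenotypic_variance(h, sigma2_e, sigma2_pg, sigma2_epi_total)
    var_x = genotype_variance(mafs)
    if np.any(var_x <= 0):
        raise ValueError("QTN allele frequencies must lie strictly in (0, 1)")
    return np.sqrt(h * V_P / var_x)


def kinship(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """VanRaden-style kinship K = Z Z' / p from column-standardized genotypes.

    Zero-variance columns are skipped with a warning. The result is
    symmetrized and is PSD by construction (up to rounding).
    """
    import warnings

    X = G.X if isinstance(G, GenotypeMatrix) else np.asarray(G)
    X = X.astype(float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-variance column(s) skipped "
                      "in kinship computation")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    K = Z @ Z.T / keep.sum()
    return (K + K.T) / 2.0


def _epistatic_effect(b_pair_var: float, f_a: float, f_b: float) -> float:
    """Effect b_jj contributing variance sigma2_epi via the product column.

    For independent HWE loci, Var(x_a * x_b) = E[x_a^2]E[x_b^2]
    - (E[x_a]E[x_b])^2 with E[x] = 2f - 1 and E[x^2] = f^2 + (1-f)^2.
    """
    def m2(f):
        return f**2 + (1 - f) ** 2

    def m1(f):
        return 2 * f - 1

    var_prod = m2(f_a) * m2(f_b) - (m1(f_a) * m1(f_b)) ** 2
    return float(np.sqrt(b_pair_var / var_prod))


def make_sim_truth(G: GenotypeMatrix, qtn_indices=None,
                   heritabilities=BENCHMARK_HERITABILITIES, mu: float = BENCHMARK_MU,
                   sigma2_e: float = BENCHMARK_SIGMA2_E, scenario: int = 1,
                   sigma2_pg: float = BENCHMARK_SIGMA2_PG,
                   sigma2_epi: float = BENCHMARK_SIGMA2_EPI,
                   epistatic_pairs=None, qtn_maf: float = QTN_MAF,
                   seed=None) -> SimTruth:
    """Assemble the ground truth for one of the three scenarios."""
    rng = np.random.default_rng(seed)
    if qtn_indices is None:
        qtn_indices = default_qtn_indices(G.p, len(heritabilities))
    qtn_indices = np.asarray(qtn_indices, dtype=int)
    h = np.asarray(heritabilities, dtype=float)

    pg = sigma2_pg if scenario == 2 else 0.0
    n_pairs = 3 if scenario == 3 else 0
    epi_total = sigma2_epi * n_pairs

    b = effects_from_heritability(h, np.full(qtn_indices.size, qtn_maf),
                                  sigma2_e, pg, epi_total)

    pairs = []
    if scenario == 3:
        if epistatic_pairs is None:
            pool = np.setdiff1d(np.arange(G.p), qtn_indices)
            chosen = rng.choice(pool, size=2 * n_pairs, replace=False)
            epistatic_pairs = list(zip(chosen[:n_pairs], chosen[n_pairs:]))
        from .io_preprocess import allele_frequencies

        f = allele_frequencies(G)
        for a, bx in epistatic_pairs:
            a, bx = int(a), int(bx)
            if a in qtn_indices or bx in qtn_indices:
                raise ValueError("epistatic locus collides with a QTN index")
            pairs.append((a, bx, _epistatic_effect(sigma2_epi, f[a], f[bx])))

    K = kinship(G) if scenario == 2 else None
    return SimTruth(qtn_indices=qtn_indices, qtn_effects=b, heritabilities=h,
                    mu=mu, sigma2_e=sigma2_e, sigma2_pg=pg,
                    epistatic_pairs=pairs, kinship=K)


def simulate_phenotype(G: GenotypeMatrix, truth: SimTruth, scenario: int = 1,
                       seed=None) -> PhenotypeVector:
    """Draw one trait vector for the given scenario and truth."""
    if scenario not in (1, 2, 3):
        raise ValueError("scenario must be 1, 2 or 3")
    rng = np.random.default_rng(seed)
    n = G.n
    X = G.X.astype(float)
    y = np.full(n, truth.mu)
    y += X[:, truth.qtn_indices] @ truth.qtn_effects
    if scenario == 2:
        if truth.kinship is None:
            raise ValueError("scenario 2 requires a kinship matrix in truth")
        L = np.linalg.cholesky(
            truth.sigma2_pg * truth.kinship
            + 1e-8 * np.eye(n)
        )
        y += L @ rng.standard_normal(n)
    if scenario == 3:
        for a, b, b_jj in truth.epistatic_pairs:
            if a in truth.qtn_indices or b in truth.qtn_indices:
                raise ValueError("epistatic locus collides with a QTN index")
            y += b_jj * X[:, a] * X[:, b]
    y += rng.normal(0.0, np.sqrt(truth.sigma2_e), size=n)
    return PhenotypeVector(y, stage="raw")


def simulate_scenario(scenario: int = 1, n: int = 199, p: int = 10_000,
                      seed=None, **truth_kwargs
                      ) -> tuple[GenotypeMatrix, PhenotypeVector, SimTruth]:
    """Convenience: genotypes + truth + one trait draw in one call."""
    rng = np.random.default_rng(seed)
    qtn = default_qtn_indices(p, len(truth_kwargs.get(
        "heritabilities", BENCHMARK_HERITABILITIES)))
    G = simulate_genotypes(n, p, qtn_indices=qtn,
                           seed=rng.integers(2**31 - 1))
    truth = make_sim_truth(G, qtn_indices=qtn, scenario=scenario,
                           seed=rng.integers(2**31 - 1), **truth_kwargs)
    y = simulate_phenotype(G, truth, scenario=scenario,
                           seed=rng.integers(2**31 - 1))
    return G, y, truth
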