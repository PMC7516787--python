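"""Readers/writers and the pre-screening phenotype pipeline.

Covers MAF filtering, the log transform applied to positive traits, and the
fixed-effect correction y' = y - Q*alpha_hat with alpha estimated by ordinary
least squares of y on [1, Q]. Only the Q part is subtracted: the grand mean
stays in y' because the second-stage shrinkage model fits mu itself.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_model import (
    FixedEffects,
    GenotypeMatrix,
    PhenotypeVector,
    StructuralError,
    validate_genotypes,
)


# ---------------------------------------------------------------------------
# filtering / transforms

def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Frequency of the +1-coded allele per SNP: (2*#(+1) + #(0)) / (2n)."""
    X = G.X
    n = G.n
    n_plus = (X == 1).sum(axis=0)
    n_het = (X == 0).sum(axis=0)
    return (2.0 * n_plus + n_het) / (2.0 * n)


def maf_filter(G: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Drop SNPs whose minor allele frequency is below ``threshold``."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    f = allele_frequencies(G)
    maf = np.minimum(f, 1.0 - f)
    keep = np.flatnonzero(maf >= threshold)
    if keep.size == 0:
        raise ValueError("MAF filter removed every SNP (empty panel)")
    if keep.size == G.p:
        return G
    return G.subset_snps(keep)


def log_transform(y: PhenotypeVector) -> PhenotypeVector:
    """Natural-log transform of a strictly positive trait."""
    if (y.values <= 0).any():
        raise ValueError("log transform requires strictly positive phenotype values")
    return PhenotypeVector(np.log(y.values), stage=y.stage)


def correct_phenotype(y: PhenotypeVector, Q: FixedEffects) -> PhenotypeVector:
    """Remove fixed effects: y' = y - Q @ alpha_hat.

    alpha_hat comes from OLS of y on [1, Q]; the intercept is estimated but
    not subtracted. With q = 0 the phenotype passes through unchanged (still
    relabelled as corrected). Stores alpha_hat on ``Q``.
    """
    if Q.q == 0:
        Q.alpha_hat = np.zeros(0)
        return PhenotypeVector(y.values.copy(), stage="corrected")
    if Q.n != y.n:
        raise ValueError(f"Q has {Q.n} rows but phenotype has {y.n} values")
    design = np.column_stack([np.ones(y.n), Q.Q])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        cols = [design[:, 0]]
        for j in range(Q.q):
            trial = np.column_stack(cols + [Q.Q[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(j)
            else:
                cols.append(Q.Q[:, j])
        raise ValueError(
            f"fixed-effect matrix Q is rank deficient; collinear columns: {bad}"
        )
    coef, *_ = np.linalg.lstsq(design, y.values, rcond=None)
    alpha = coef[1:]
    Q.alpha_hat = alpha
    return PhenotypeVector(y.values - Q.Q @ alpha, stage="corrected")


def drop_missing_phenotype(
    G: GenotypeMatrix, y_raw: np.ndarray
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Drop individuals with missing (NaN) trait values; subset G to match."""
    y_raw = np.asarray(y_raw, dtype=float).ravel()
    keep = np.flatnonzero(np.isfinite(y_raw))
    if keep.size == 0:
        raise ValueError("all phenotype values are missing")
    if keep.size < y_raw.size:
        G = G.subset_individuals(keep)
    return G, PhenotypeVector(y_raw[keep], stage="raw")


# ---------------------------------------------------------------------------
# text I/O (all readers tolerate '#' comment lines)

def read_phenotype(path, sep=None) -> pd.DataFrame:
    """Read a 2-column (individual_id, value) table; NaN marks missing."""
    df = pd.read_csv(path, sep=sep or r"\s+", comment="#", header=None,
                     names=["individual_id", "value"], engine="python")
    return df


def read_covariates(path, sep=None) -> FixedEffects:
    """Read an n x q fixed-effect matrix from delimited text."""
    arr = pd.read_csv(path, sep=sep or r"\s+", comment="#", header=None,
                      engine="python").to_numpy(dtype=float)
    return FixedEffects(arr)


def read_genotypes(genotype_path, map_path, sep=None) -> GenotypeMatrix:
    """Read genotypes (individuals x SNPs, header = SNP ids) + 3-column map."""
    sep = sep or r"\s+"
    geno = pd.read_csv(genotype_path, sep=sep, comment="#", engine="python")
    snp_map = pd.read_csv(map_path, sep=sep, comment="#", header=None,
                          names=["snp_id", "chromosome", "position"],
                          engine="python")
    if list(geno.columns) != list(snp_map["snp_id"]):
        if len(geno.columns) != len(snp_map):
            raise StructuralError(
                f"genotype file has {len(geno.columns)} SNP columns but map "
                f"file lists {len(snp_map)} SNPs"
            )
        warnings.warn("SNP id order differs between genotype header and map; "
                      "reordering map to match genotypes")
        snp_map = snp_map.set_index("snp_id").loc[list(geno.columns)].reset_index()
    return validate_genotypes(geno.to_numpy(), snp_map)


def write_genotypes(G: GenotypeMatrix, genotype_path, map_path, sep="\t") -> None:
    pd.DataFrame(G.X, columns=G.snp_map["snp_id"]).to_csv(
        genotype_path, sep=sep, index=False
    )
    G.snp_map.to_csv(map_path, sep=sep, index=False, header=False)


def read_plink_raw(path) -> GenotypeMatrix:
    """Ingest a PLINK ``.raw`` additive-recode file (plink --recode A).

    Dosages 0/1/2 of the counted allele map to codes -1/0/+1. Chromosome and
    position are not carried by ``.raw``; the map records chromosome 0 and the
    column order as position. Missing calls (NA) are mode-imputed.
    """
    from .data_model import impute_mode

    df = pd.read_csv(path, sep=r"\s+", engine="python")
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
                 if c in df.columns]
    snp_cols = [c for c in df.columns if c not in meta_cols]
    dosage = df[snp_cols].to_numpy(dtype=float)
    if np.isnan(dosage).any():
        dosage = impute_mode(dosage)
    codes = dosage - 1.0
    snp_map = pd.DataFrame({
        "snp_id": snp_cols,
        "chromosome": 0,
        "position": np.arange(1, len(snp_cols) + 1),
    })
    return validate_genotypes(codes.astype(int), snp_map)
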