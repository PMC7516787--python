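"""Scoring of GWAS output against simulated ground truth.

Conventions:

* a significant SNP within 1 kb (same chromosome) of a QTN counts as a
  detection of that QTN; each significant SNP matches at most one QTN
  (the nearest);
* power_i = detections_i / replicates; robustness is the SD of power over
  a designated subset of QTNs (the equal-heritability ones);
* MSE_i averages (beta_hat_ij - b_i)^2 over replicates; by default only
  replicates where QTN i was detected contribute (configurable to count
  undetected replicates as beta_hat = 0);
* the type-1 error ratio is the number of false-positive significant SNPs
  divided by (null SNPs tested x replicates), in percent, where null SNPs
  are those outside every 1 kb QTN window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import MblassoConfig
from .data_model import GenotypeMatrix, SimTruth
from .pipeline import MBLASSO
from . import simulator


def n_null_snps(G: GenotypeMatrix, truth: SimTruth, window: int = 1000) -> int:
    """SNPs outside every (chromosome, +-window bp) QTN neighbourhood."""
    chrom = G.snp_map["chromosome"].to_numpy()
    pos = G.snp_map["position"].to_numpy()
    near = np.zeros(G.p, dtype=bool)
    for q in truth.qtn_indices:
        near |= (chrom == chrom[q]) & (np.abs(pos - pos[q]) <= window)
    return int((~near).sum())


def match_qtns(result: pd.DataFrame, truth: SimTruth, snp_map: pd.DataFrame,
               window: int = 1000) -> dict:
    """Match significant SNPs to QTNs by the 1 kb proximity rule.

    Returns dict with ``detected`` (bool per QTN), ``effects`` (matched
    effect estimate per QTN, NaN when undetected; nearest significant SNP
    wins) and ``n_false_positives`` (significant SNPs matching no QTN).
    """
    n_qtn = truth.qtn_indices.size
    detected = np.zeros(n_qtn, dtype=bool)
    effects = np.full(n_qtn, np.nan)
    sig = result[result["significant"]]
    if sig.empty:
        return {"detected": detected, "effects": effects,
                "n_false_positives": 0}

    q_chrom = snp_map["chromosome"].to_numpy()[truth.qtn_indices]
    q_pos = snp_map["position"].to_numpy()[truth.qtn_indices]

    s_chrom = sig["chromosome"].to_numpy()
    s_pos = sig["position"].to_numpy()
    s_eff = sig["effect"].to_numpy()

    # each significant SNP matches its nearest QTN within the window
    fp = 0
    best_dist = np.full(n_qtn, np.inf)
    for c, pos_j, eff in zip(s_chrom, s_pos, s_eff):
        dist = np.where(q_chrom == c, np.abs(q_pos - pos_j), np.inf)
        i = int(np.argmin(dist))
        if dist[i] <= window:
            detected[i] = True
            if dist[i] < best_dist[i]:
                best_dist[i] = dist[i]
                effects[i] = eff
        else:
            fp += 1
    return {"detected": detected, "effects": effects,
            "n_false_positives": fp}


def power_per_qtn(detection_flags, robust_subset=None) -> dict:
    """Power per QTN across replicates, plus mean and robustness SD.

    ``detection_flags`` is (replicates x n_qtn) boolean. ``robust_subset``
    names the QTN indices over which the robustness SD is taken (default:
    all QTNs sharing the minimum heritability cannot be inferred here, so
    all QTNs are used unless a subset is given).
    """
    flags = np.asarray(detection_flags, dtype=float)
    if flags.ndim != 2 or flags.shape[0] < 1:
        raise ValueError("need at least one replicate of detection flags")
    power = flags.mean(axis=0)
    subset = np.asarray(robust_subset, dtype=int) if robust_subset is not None \
        else np.arange(power.size)
    return {
        "power": power,
        "mean_power": float(power.mean()),
        "power_sd": float(np.std(power[subset], ddof=1)) if subset.size > 1
        else 0.0,
    }


def mse_per_qtn(estimates, truth_effects, undetected: str = "skip") -> dict:
    """Per-QTN mean squared error of matched effect estimates.

    ``estimates`` is (replicates x n_qtn) with NaN where the QTN went
    undetected. ``undetected="skip"`` averages over detected replicates
    only; ``undetected="zero"`` scores missing estimates as beta_hat = 0.
    """
    est = np.asarray(estimates, dtype=float)
    b = np.asarray(truth_effects, dtype=float)
    if undetected == "zero":
        est = np.where(np.isnan(est), 0.0, est)
    elif undetected != "skip":
        raise ValueError("undetected must be 'skip' or 'zero'")
    sq = (est - b[None, :]) ** 2
    with np.errstate(invalid="ignore"):
        mse = np.nanmean(sq, axis=0)
    detected_counts = (~np.isnan(est)).sum(axis=0)
    mse = np.where(detected_counts > 0, mse, np.nan)
    return {
        "mse": mse,
        "mean_mse": float(np.nanmean(mse)) if np.isfinite(mse).any() else float("nan"),
        "n_detected": detected_counts,
    }


def type1_error_ratio(total_false_positives: int, n_null: int,
                      n_runs: int) -> float:
    """False positives / (null SNPs x replicates), in percent."""
    denom = n_null * n_runs
    if denom <= 0:
        raise ValueError("need a positive null-SNP count and replicate count")
    return 100.0 * total_false_positives / denom


def simulation_study(n_reps: int = 100, scenario: int = 1, n: int = 199,
                     p: int = 2000, seed: int = 0,
                     config: MblassoConfig | None = None,
                     window: int = 1000, mse_undetected: str = "skip",
                     verbose: bool = False) -> dict:
    """Replicate driver: simulate, run the pipeline, score, aggregate.

    Genotypes and ground truth are drawn fresh per replicate (seeded from
    ``seed``); the same scoring window and significance rule apply to every
    replicate. Returns a dict with power/MSE/type-1 summaries plus the raw
    per-replicate arrays.
    """
    config = config or MblassoConfig()
    root = np.random.default_rng(seed)
    flags, effects, fps, nulls = [], [], [], []
    overlaps, nus = [], []
    truth_effects = None
    for rep in range(n_reps):
        rep_seed = int(root.integers(2**31 - 1))
        G, y, truth = simulator.simulate_scenario(
            scenario=scenario, n=n, p=p, seed=rep_seed)
        truth_effects = truth.qtn_effects
        est = MBLASSO(**config.to_dict())
        est.fit(G, y)
        scored = match_qtns(est.results_, truth, G.snp_map, window=window)
        flags.append(scored["detected"])
        effects.append(scored["effects"])
        fps.append(scored["n_false_positives"])
        nulls.append(n_null_snps(G, truth, window=window))
        overlaps.append(est.overlap_ratio_)
        nus.append(est.stage_sizes_.get("nu", 0))
        if verbose:
            print(f"rep {rep + 1}/{n_reps}: detected="
                  f"{scored['detected'].astype(int)} fp="
                  f"{scored['n_false_positives']}")

    flags = np.asarray(flags)
    effects = np.asarray(effects)
    h = np.asarray(simulator.BENCHMARK_HERITABILITIES)
    equal_h = np.flatnonzero(h == h.min())  # the four 5%-heritability QTNs
    pw = power_per_qtn(flags, robust_subset=equal_h)
    ms = mse_per_qtn(effects, truth_effects, undetected=mse_undetected)
    t1 = type1_error_ratio(int(np.sum(fps)), int(np.mean(nulls)), n_reps)
    return {
        "n_reps": n_reps,
        "scenario": scenario,
        "n": n,
        "p": p,
        **pw,
        **ms,
        "type1_error_pct": t1,
        "false_positives": np.asarray(fps),
        "n_null_snps": int(np.mean(nulls)),
        "detection_flags": flags,
        "effect_estimates": effects,
        "truth_effects": truth_effects,
        "mean_overlap_ratio": float(np.nanmean(overlaps)),
        "mean_candidates": float(np.mean(nus)),
    }
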