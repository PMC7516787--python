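import numpy as np
import pandas as pd
import pytest

from mblasso.data_model import SimTruth, association_table
from mblasso.evaluate import (
    match_qtns,
    mse_per_qtn,
    n_null_snps,
    power_per_qtn,
    type1_error_ratio,
)


def _snp_map(positions, chrom=1):
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(positions))],
        "chromosome": chrom,
        "position": positions,
    })


def _truth(qtn_indices, n_qtn=None):
    q = np.asarray(qtn_indices)
    return SimTruth(q, np.ones(q.size), np.full(q.size, 0.1),
                    mu=10.0, sigma2_e=10.0)


def _result(snp_map, rows, sig):
    idx = list(rows)
    return association_table(
        snp_map["snp_id"].iloc[idx], snp_map["chromosome"].iloc[idx],
        snp_map["position"].iloc[idx], np.ones(len(idx)),
        np.full(len(idx), 5.0), np.full(len(idx), 1e-6), sig)


class TestMatchQtns:
    def test_exact_position_detected(self):
        m = _snp_map([1000, 5000, 9000])
        truth = _truth([1])
        res = _result(m, [1], [True])
        out = match_qtns(res, truth, m)
        assert out["detected"][0] and out["n_false_positives"] == 0

    def test_1kb_boundary(self):
        m = _snp_map([5000, 5999, 6001 + 1000])
        truth = _truth([0])
        inside = match_qtns(_result(m, [1], [True]), truth, m)
        assert inside["detected"][0]  # 999 bp away
        outside = match_qtns(_result(m, [2], [True]), truth, m)
        assert not outside["detected"][0]  # 2001 bp away -> false positive
        assert outside["n_false_positives"] == 1

    def test_chromosome_must_match(self):
        m = pd.concat([_snp_map([5000], chrom=1), _snp_map([5000], chrom=2)],
                      ignore_index=True)
        truth = _truth([0])
        out = match_qtns(_result(m, [1], [True]), truth, m)
        assert not out["detected"][0] and out["n_false_positives"] == 1

    def test_no_significant_snps(self):
        m = _snp_map([100, 200])
        out = match_qtns(_result(m, [], []), _truth([0]), m)
        assert not out["detected"].any()
        assert out["n_false_positives"] == 0

    def test_each_snp_matches_nearest_qtn_only(self):
        m = _snp_map([1000, 1400, 2000])
        truth = _truth([0, 2])
        out = match_qtns(_result(m, [1], [True]), truth, m)
        # 400 bp from QTN0, 600 bp from QTN1 -> only the nearest is credited
        assert out["detected"].tolist() == [True, False]


class TestPowerPerQtn:
    def test_rate_and_formula(self):
        flags = np.zeros((1000, 1), dtype=bool)
        flags[:724, 0] = True
        out = power_per_qtn(flags)
        assert out["power"][0] == pytest.approx(0.724)

    def test_zero_detections(self):
        out = power_per_qtn(np.zeros((10, 3), dtype=bool))
        np.testing.assert_allclose(out["power"], 0.0)

    def test_identical_powers_sd_zero(self):
        flags = np.tile([True, True, False], (9, 2)).reshape(9, 6)[:, :4]
        out = power_per_qtn(np.ones((5, 4), dtype=bool))
        assert out["power_sd"] == 0.0

    def test_robust_subset(self):
        flags = np.array([[1, 1, 0, 0], [1, 0, 0, 0]], dtype=bool)
        out = power_per_qtn(flags, robust_subset=[2, 3])
        assert out["power_sd"] == 0.0  # both subset powers are 0


class TestMsePerQtn:
    def test_perfect_estimates(self):
        est = np.tile([2.0, 1.5], (5, 1))
        out = mse_per_qtn(est, [2.0, 1.5])
        np.testing.assert_allclose(out["mse"], 0.0)

    def test_constant_bias_of_one(self):
        est = np.tile([3.0], (4, 1))
        out = mse_per_qtn(est, [2.0])
        assert out["mse"][0] == pytest.approx(1.0)

    def test_two_run_hand_computation(self):
        est = np.array([[2.1], [1.7]])
        out = mse_per_qtn(est, [2.0])
        assert out["mse"][0] == pytest.approx((0.01 + 0.09) / 2)

    def test_undetected_skip_vs_zero(self):
        est = np.array([[2.0], [np.nan]])
        skip = mse_per_qtn(est, [2.0], undetected="skip")
        zero = mse_per_qtn(est, [2.0], undetected="zero")
        assert skip["mse"][0] == pytest.approx(0.0)
        assert zero["mse"][0] == pytest.approx(2.0)


class TestType1Error:
    def test_zero_false_positives(self):
        assert type1_error_ratio(0, 1000, 10) == 0.0

    def test_hand_ratio(self):
        assert type1_error_ratio(3, 10_000, 1) == pytest.approx(0.03)

    def test_everything_called(self):
        assert type1_error_ratio(5000, 500, 10) == pytest.approx(100.0)

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            type1_error_ratio(0, 0, 5)


def test_n_null_snps_excludes_windows():
    from mblasso import simulator as sim

    G = sim.simulate_genotypes(10, 50, seed=30)
    truth = _truth([10])
    n_null = n_null_snps(G, truth, window=1000)
    pos = G.snp_map["position"].to_numpy()
    chrom = G.snp_map["chromosome"].to_numpy()
    manual = np.sum(~((chrom == chrom[10]) & (np.abs(pos - pos[10]) <= 1000)))
    assert n_null == manual < 50


def test_lod_threshold_tradeoff(rng):
    """Lowering the LOD threshold never lowers power or the type-1 ratio
    on the same result set."""
    from mblasso import simulator as sim
    from mblasso.lrt import call_significant

    m = _snp_map(np.arange(100) * 5000)
    truth = _truth([10, 50])
    lods = rng.uniform(0, 6, size=20)
    idx = rng.choice(100, 20, replace=False)
    base = association_table(
        m["snp_id"].iloc[idx], m["chromosome"].iloc[idx],
        m["position"].iloc[idx], np.ones(20), lods,
        np.full(20, 0.1), lods >= 3)
    strict = match_qtns(call_significant(base, 3), truth, m)
    loose = match_qtns(call_significant(base, 2), truth, m)
    assert loose["detected"].sum() >= strict["detected"].sum()
    assert loose["n_false_positives"] >= strict["n_false_positives"]
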