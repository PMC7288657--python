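"""Ct transform, QC filters, batch adjustment and control comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonescreen import (
    ChipSpec,
    ExpressionMatrix,
    adjust_batch,
    compare_to_control,
    ct_to_expression,
    filter_probes,
    filter_samples,
    simulate_chip,
)
from clonescreen.fluidigm import average_technical_replicates

from conftest import SEED


def _matrix(values: np.ndarray) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"S{i}" for i in range(arr.shape[0])],
            columns=[f"P{j}" for j in range(arr.shape[1])],
        )
    )


class TestCtTransform:
    @pytest.mark.parametrize("ct,expected", [(20.0, 10.0), (30.0, 0.0), (35.0, 0.0), (0.0, 30.0)])
    def test_thirty_minus_ct_clamped_at_zero(self, ct, expected):
        m = ct_to_expression(pd.DataFrame([[ct]]))
        assert m.values.iloc[0, 0] == expected

    def test_missing_reactions_become_unexpressed(self):
        m = ct_to_expression(pd.DataFrame([[np.nan, 12.0]]))
        assert m.values.iloc[0, 0] == 0.0
        assert m.values.iloc[0, 1] == 18.0

    def test_negative_ct_rejected(self):
        with pytest.raises(ValueError):
            ct_to_expression(pd.DataFrame([[-1.0]]))

    def test_full_chip_transforms_all_2304_assays(self, chip):
        ct, meta = chip
        m = ct_to_expression(ct, sample_meta=meta)
        assert m.values.size == 2304
        assert (m.values.to_numpy() >= 0).all()
        assert (m.values.to_numpy() <= 30).all()


class TestSampleFilter:
    def test_strict_boundary_at_forty_zeros(self):
        values = np.full((3, 48), 5.0)
        values[0, :41] = 0.0  # 41 unexpressed -> removed
        values[1, :40] = 0.0  # exactly 40 -> kept
        m = filter_samples(_matrix(values))
        assert list(m.values.index) == ["S1", "S2"]

    def test_all_expressed_matrix_unchanged(self, random_expression):
        m = ExpressionMatrix(random_expression)
        out = filter_samples(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_warns_when_everything_dropped(self):
        values = np.zeros((2, 48))
        with pytest.warns(UserWarning, match="every sample"):
            out = filter_samples(_matrix(values))
        assert out.n_samples == 0


class TestProbeFilter:
    def test_strict_boundary_at_five_samples(self):
        values = np.zeros((8, 2))
        values[:4, 0] = 3.0  # expressed in 4 samples -> removed
        values[:5, 1] = 3.0  # expressed in exactly 5 -> kept
        m = filter_probes(_matrix(values))
        assert list(m.values.columns) == ["P1"]

    def test_housekeeping_drop_warns(self):
        values = np.zeros((8, 1))
        base = _matrix(values)
        base.probe_meta = pd.DataFrame({"housekeeping": [True]}, index=base.values.columns)
        with pytest.warns(UserWarning, match="housekeeping"):
            filter_probes(base)

    def test_filters_are_idempotent(self, rng):
        values = rng.uniform(0, 10, size=(20, 48))
        values[values < 2] = 0.0
        m = _matrix(values)
        once = filter_probes(filter_samples(m))
        twice = filter_probes(filter_samples(once))
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_filter_order_regression(self):
        # a sample at the zero-count boundary flips depending on order: with
        # a dead probe removed first its zero count drops below the cutoff.
        # The documented order is samples first, then probes.
        values = np.full((8, 6), 4.0)
        values[:, 5] = 0.0      # dead probe, expressed nowhere -> dropped
        values[0, :4] = 0.0     # S0: 5 zeros incl. the dead probe
        m = _matrix(values)
        sample_first = filter_probes(filter_samples(m, max_unexpressed=4), min_samples=5)
        probe_first = filter_samples(filter_probes(m, min_samples=5), max_unexpressed=4)
        assert "S0" not in sample_first.values.index
        assert "S0" in probe_first.values.index
        assert "P5" not in sample_first.values.columns
        assert "P5" not in probe_first.values.columns


class TestBatchAdjustment:
    def test_identical_batches_reduce_to_plain_standardisation(self, rng):
        block = rng.normal(10, 2, size=(6, 5))
        values = np.vstack([block, block])
        m = _matrix(values)
        batches = ["a"] * 6 + ["b"] * 6
        out = adjust_batch(m, batches).values.to_numpy()
        plain = (values - values.mean(0)) / values.std(0, ddof=1)
        plain = (plain - plain.mean(0)) / plain.std(0, ddof=1)
        np.testing.assert_allclose(out, plain, atol=1e-10)

    def test_known_shift_recovered(self):
        ct, meta = simulate_chip(ChipSpec(batch_shift=2.0, dropout_fraction=0.0), SEED)
        m = ct_to_expression(ct, sample_meta=meta)
        adj = adjust_batch(m)
        batch = meta["batch"].to_numpy()
        diff = (
            adj.values[batch == "fresh"].mean(0) - adj.values[batch == "frozen"].mean(0)
        )
        assert np.abs(diff).max() < 0.05

    def test_standardisation_contract(self, chip):
        ct, meta = chip
        adj = adjust_batch(ct_to_expression(ct, sample_meta=meta))
        np.testing.assert_allclose(adj.values.mean(0), 0.0, atol=1e-8)
        np.testing.assert_allclose(adj.values.std(0, ddof=1), 1.0, atol=1e-8)
        assert adj.standardized

    def test_single_sample_batch_rejected(self, random_expression):
        m = ExpressionMatrix(random_expression)
        with pytest.raises(ValueError, match="single sample"):
            adjust_batch(m, ["a"] + ["b"] * (m.n_samples - 1))


class TestCompareToControl:
    def test_identical_constant_groups_tie(self, rng):
        values = np.full((8, 1), 3.0)
        m = _matrix(values)
        with pytest.warns(UserWarning, match="degenerate"):
            est, p = compare_to_control(m, "P0", ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert est == 0.0 and p == 1.0

    def test_rejection_rate_matches_two_sample_power_oracle(self, rng):
        from statsmodels.stats.power import TTestIndPower

        n, sims = 8, 800
        expected = TTestIndPower().power(effect_size=1.0, nobs1=n, ratio=1.0, alpha=0.05)
        hits = 0
        for _ in range(sims):
            x = rng.normal(1.0, 1.0, n)
            y = rng.normal(0.0, 1.0, n)
            m = _matrix(np.concatenate([x, y])[:, None])
            group = [f"S{i}" for i in range(n)]
            ctrl = [f"S{i}" for i in range(n, 2 * n)]
            _, p = compare_to_control(m, "P0", ctrl, group)
            hits += p < 0.05
        rate = hits / sims
        assert rate == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / sims))

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        for _ in range(500):
            m = _matrix(rng.normal(0, 1, size=(16, 1)))
            _, p = compare_to_control(
                m, "P0", [f"S{i}" for i in range(8)], [f"S{i}" for i in range(8, 16)]
            )
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_average_technical_replicates():
    tidy = pd.DataFrame(
        {
            "sample": ["A", "A", "A", "A", "B", "B"],
            "probe": ["P0", "P0", "P1", "P1", "P0", "P1"],
            "ct": [10.0, 12.0, 20.0, 22.0, 15.0, 25.0],
        }
    )
    wide = average_technical_replicates(tidy)
    assert wide.loc["A", "P0"] == 11.0
    assert wide.loc["A", "P1"] == 21.0
    assert wide.loc["B", "P0"] == 15.0
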