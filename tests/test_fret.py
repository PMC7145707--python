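"""FRET-efficiency computation, pooling, classification and f_unwound tests."""

import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from smfret_unwind import (
    ClassificationThresholds,
    FretSample,
    build_histogram,
    classify,
    compute_fret,
    estimate_f_unwound,
    fret_from_traces,
    pool_first_k,
    simulate_trace_set,
)
from smfret_unwind.containers import FretSeries

from conftest import make_condition
from smfret_unwind import PhotophysicsParams


def sample_from(values):
    values = np.asarray(values, dtype=float)
    return FretSample(label="t", values=values,
                      molecule_index=np.arange(len(values)),
                      n_molecules=len(values), k=1)


class TestComputeFret:
    def test_elementwise_ratio(self):
        series = compute_fret([[100.0]], [[300.0]], total_floor=10.0)
        assert series.e[0, 0] == pytest.approx(0.75)

    def test_zero_acceptor(self):
        series = compute_fret([[400.0]], [[0.0]], total_floor=10.0)
        assert series.e[0, 0] == 0.0

    def test_low_total_marked_invalid_not_nan_propagated(self):
        series = compute_fret([[0.0, 100.0]], [[0.0, 300.0]], total_floor=10.0)
        assert not series.valid[0, 0]
        assert np.isnan(series.e[0, 0])
        assert series.valid[0, 1]

    def test_floor_from_configured_total(self):
        series = compute_fret([[30.0]], [[10.0]], configured_total=500.0)
        assert series.total_floor == pytest.approx(50.0)
        assert not series.valid[0, 0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_fret([[1.0, 2.0]], [[1.0]])


class TestPoolFirstK:
    def test_pools_k_per_molecule(self):
        e = np.tile(np.linspace(0.1, 1.0, 10), (3, 1))
        series = FretSeries(e=e, valid=np.ones_like(e, bool), total_floor=1.0)
        sample = pool_first_k(series, k=5)
        assert len(sample.values) == 15
        assert sample.n_molecules == 3 and sample.k == 5

    def test_molecule_with_fewer_valid_frames_contributes_what_exists(self):
        e = np.full((1, 10), 0.5)
        valid = np.zeros((1, 10), bool)
        valid[0, [1, 4, 7]] = True
        series = FretSeries(e=e, valid=valid, total_floor=1.0)
        assert len(pool_first_k(series, k=5).values) == 3

    def test_pools_first_valid_not_first_frames(self):
        e = np.array([[np.nan, 0.2, 0.3, 0.4]])
        valid = np.array([[False, True, True, True]])
        series = FretSeries(e=e, valid=valid, total_floor=1.0)
        np.testing.assert_array_equal(pool_first_k(series, k=2).values, [0.2, 0.3])

    def test_small_histogram_warns(self, caplog):
        e = np.full((1500, 6), 0.5)
        series = FretSeries(e=e, valid=np.ones_like(e, bool), total_floor=1.0)
        with caplog.at_level(logging.WARNING):
            pool_first_k(series, k=5)
        assert any("1500" in r.message for r in caplog.records)
        caplog.clear()
        e = np.full((2500, 6), 0.5)
        series = FretSeries(e=e, valid=np.ones_like(e, bool), total_floor=1.0)
        with caplog.at_level(logging.WARNING):
            pool_first_k(series, k=5)
        assert not caplog.records

    def test_empty_input_rejected(self):
        series = FretSeries(e=np.empty((0, 5)), valid=np.empty((0, 5), bool), total_floor=1.0)
        with pytest.raises(ValueError, match="empty"):
            pool_first_k(series)


class TestHistogram:
    def test_single_occupied_bin(self):
        hist = build_histogram(sample_from([0.75] * 10), bin_width=0.02)
        occupied = hist[hist["count"] > 0]
        assert len(occupied) == 1
        assert occupied["bin_lo"].iloc[0] == pytest.approx(0.74)
        assert occupied["bin_hi"].iloc[0] == pytest.approx(0.76)

    def test_density_normalized(self):
        rng = np.random.default_rng(3)
        hist = build_histogram(sample_from(rng.normal(0.5, 0.2, 5000)))
        assert hist["density"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_sample_density_matches_binomial_oracle(self):
        rng = np.random.default_rng(4)
        n = 100_000
        hist = build_histogram(sample_from(rng.uniform(0.0, 1.0, n)), bin_width=0.02)
        inside = hist[(hist["bin_lo"] >= 0.0) & (hist["bin_hi"] <= 1.0)]
        p = 0.02
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(inside["density"] - p) <= 3 * se)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError, match="bin_width"):
            build_histogram(sample_from([0.5]), bin_width=0.0)


class TestClassify:
    def test_three_populations(self):
        counts = classify(sample_from([0.0, 0.4, 0.8]))
        assert (counts.n_donor_only, counts.n_low, counts.n_high) == (1, 1, 1)

    def test_tie_breaks(self):
        # donor_only_max goes to donor-only; the boundary goes to high
        counts = classify(sample_from([0.2, 0.65]))
        assert (counts.n_donor_only, counts.n_low, counts.n_high) == (1, 0, 1)

    @given(hnp.arrays(float, st.integers(0, 200),
                      elements=st.floats(-0.5, 1.5, allow_nan=False)))
    def test_counts_conserve_sample_size(self, values):
        counts = classify(values)
        assert counts.total == len(values)

    def test_raising_boundary_never_decreases_n_low(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(0.3, 0.08, 5000), rng.normal(0.75, 0.08, 5000)])
        n_lows = [
            classify(values, ClassificationThresholds(low_high_boundary=b)).n_low
            for b in (0.6, 0.65, 0.7)
        ]
        oracle = [np.sum((values > 0.2) & (values < b)) for b in (0.6, 0.65, 0.7)]
        assert n_lows == oracle
        assert n_lows[0] <= n_lows[1] <= n_lows[2]


class TestEstimateFUnwound:
    def test_all_high_fret_gives_zero(self):
        e = np.full((10, 5), 0.75)
        series = FretSeries(e=e, valid=np.ones_like(e, bool), total_floor=1.0)
        est = estimate_f_unwound(series, n_boot=10, seed=0)
        assert est.f_unwound == 0.0

    def test_no_fret_active_molecules_is_an_error(self):
        e = np.full((5, 5), 0.05)  # everything donor-only
        series = FretSeries(e=e, valid=np.ones_like(e, bool), total_floor=1.0)
        with pytest.raises(ValueError, match="FRET-active"):
            estimate_f_unwound(series, n_boot=10, seed=0)

    def test_recovers_simulated_occupancy(self):
        """f_unwound matches the simulator occupancy (p=0.6, 3000 molecules,
        modes 0.30/0.75) within 0.03."""
        phot = PhotophysicsParams.with_fret_sd(0.05, e_state=0.75, donor_only_fraction=0.0)
        cond = make_condition(0.6, phot)
        traces, _ = simulate_trace_set(cond, 3000, 6, seed=61)
        est = estimate_f_unwound(
            fret_from_traces(traces, configured_total=phot.total_intensity),
            n_boot=300, seed=62,
        )
        assert est.f_unwound == pytest.approx(0.6, abs=0.03)
        assert 0.25 < est.mean_e_low < 0.35

    def test_bootstrap_sd_matches_binomial_closed_form(self):
        """Molecule-level bootstrap SD at 3000 molecules is within a factor
        of 1.5 of sqrt(p(1-p)/n) -- frames within a molecule are correlated
        under slow exchange, so molecules are the effective sample unit."""
        phot = PhotophysicsParams.with_fret_sd(0.04, e_state=0.75, donor_only_fraction=0.0)
        cond = make_condition(0.6, phot)
        traces, _ = simulate_trace_set(cond, 3000, 6, seed=63)
        est = estimate_f_unwound(
            fret_from_traces(traces, configured_total=phot.total_intensity),
            n_boot=500, seed=64,
        )
        closed_form = np.sqrt(0.6 * 0.4 / 3000)
        assert closed_form / 1.5 < est.sd < closed_form * 1.5

    def test_denominator_convention_flag(self):
        e = np.array([[0.0, 0.4], [0.4, 0.8]])
        series = FretSeries(e=e, valid=np.ones_like(e, bool), total_floor=1.0)
        excl = estimate_f_unwound(series, n_boot=2, seed=0, k=2)
        incl = estimate_f_unwound(series, n_boot=2, seed=0, include_donor_only=True)
        assert excl.f_unwound == pytest.approx(2 / 3)
        assert incl.f_unwound == pytest.approx(2 / 4)


class TestRecoveryProperties:
    def test_parameter_recovery_across_occupancies(self):
        """|f_hat - p_unwound| < 0.03 across the occupancy range at state
        separation 0.45 and per-frame E SD within the <=0.08 regime."""
        phot = PhotophysicsParams.with_fret_sd(0.04, e_state=0.75, donor_only_fraction=0.0)
        for i, p in enumerate([0.05, 0.25, 0.5, 0.75, 0.95]):
            cond = make_condition(p, phot)
            traces, _ = simulate_trace_set(cond, 3000, 6, seed=70 + i)
            est = estimate_f_unwound(
                fret_from_traces(traces, configured_total=phot.total_intensity),
                n_boot=50, seed=80 + i,
            )
            assert est.f_unwound == pytest.approx(p, abs=0.03), f"p_unwound={p}"

    def test_f_hat_monotone_in_occupancy(self, tight_photophysics):
        sweep = np.linspace(0.05, 0.95, 10)
        f_hats = []
        for i, p in enumerate(sweep):
            cond = make_condition(float(p), tight_photophysics)
            traces, _ = simulate_trace_set(cond, 1000, 6, seed=90 + i)
            est = estimate_f_unwound(
                fret_from_traces(traces, configured_total=tight_photophysics.total_intensity),
                n_boot=2, seed=1,
            )
            f_hats.append(est.f_unwound)
        assert np.all(np.diff(f_hats) >= 0)

    def test_boundary_choice_barely_moves_f_hat(self, tight_photophysics):
        """On well-separated peaks, moving the low/high boundary across
        0.6 / 0.65 / 0.7 shifts f_hat by less than 0.02."""
        cond = make_condition(0.5, tight_photophysics)
        traces, _ = simulate_trace_set(cond, 2000, 6, seed=95)
        series = fret_from_traces(traces, configured_total=tight_photophysics.total_intensity)
        f_hats = [
            estimate_f_unwound(
                series, ClassificationThresholds(low_high_boundary=b), n_boot=2, seed=1
            ).f_unwound
            for b in (0.6, 0.65, 0.7)
        ]
        assert max(f_hats) - min(f_hats) < 0.02
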