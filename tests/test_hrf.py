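"""HRF bases, stimulus convolution and design-matrix construction."""

import numpy as np
import pytest

from splash.hrf import (
    HRF_WINDOW,
    StimulusTrain,
    build_basis,
    build_design,
    canonical_hrf,
    convolve_regressor,
    read_stimulus_tsv,
)


class TestCanonicalHRF:
    def test_zero_at_origin_and_unit_peak(self):
        t = np.linspace(0.0, 32.0, 4097)
        h = canonical_hrf(t)
        assert h[0] == 0.0
        assert np.isclose(h.max(), 1.0)
        assert np.all(np.isfinite(h))

    def test_peak_latency_near_five_seconds(self):
        t = np.linspace(0.0, 32.0, 32001)
        h = canonical_hrf(t)
        assert 4.5 <= t[np.argmax(h)] <= 5.5

    def test_undershoot_present(self):
        t = np.linspace(0.0, 32.0, 3201)
        h = canonical_hrf(t)
        assert h[(t > 10) & (t < 25)].min() < 0

    @pytest.mark.parametrize("bad", [{"peak_delay": -1.0}, {"ratio": np.nan}])
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises(ValueError):
            canonical_hrf(np.linspace(0, 32, 10), **bad)

    def test_negative_times_raise(self):
        with pytest.raises(ValueError):
            canonical_hrf(np.array([-1.0, 0.0]))


class TestBuildBasis:
    def test_fir_bins_tile_window(self):
        basis = build_basis("fir", 4, TR=1.0, window=16.0)
        assert basis.values.shape[1] == 4
        # each bin covers 4 s, bins are disjoint and tile [0, window)
        grid = basis.sample_grid
        inside = grid < 16.0
        assert np.all(basis.values[inside].sum(axis=1) == 1.0)
        widths = basis.values.sum(axis=0) * (grid[1] - grid[0])
        assert np.allclose(widths, 4.0, atol=grid[1] - grid[0])

    def test_bspline_partition_of_unity(self):
        basis = build_basis("bspline", 5, TR=2.0, window=20.0)
        grid = basis.sample_grid
        interior = (grid > 1.0) & (grid < 19.0)
        assert np.allclose(basis.values[interior].sum(axis=1), 1.0)

    def test_canonical_matches_direct_evaluation(self):
        basis = build_basis("canonical", 1, TR=2.0)
        np.testing.assert_allclose(
            basis.values[:, 0], canonical_hrf(basis.sample_grid)
        )

    def test_canonical_with_multiple_functions_rejected(self):
        with pytest.raises(ValueError, match="canonical"):
            build_basis("canonical", 2, TR=1.0)

    def test_grid_spacing_at_most_tr_over_16(self):
        basis = build_basis("canonical", 1, TR=0.8)
        assert np.all(np.diff(basis.sample_grid) <= 0.8 / 16 + 1e-12)


class TestConvolveRegressor:
    def test_empty_train_gives_zero_column(self):
        stim = StimulusTrain("a", np.array([]), np.array([]))
        col = convolve_regressor(stim, np.ones(17), TR=1.0, T=50)
        assert col.shape == (50,)
        assert np.all(col == 0)

    def test_impulse_with_delta_fir_bin_reproduces_indicator(self):
        # single-bin FIR over [0, TR) acts as a discrete delta
        basis = build_basis("fir", 1, TR=1.0, window=1.0)
        stim = StimulusTrain("a", np.array([0.0]), np.array([0.0]))
        col = convolve_regressor(stim, basis.values[:, 0], TR=1.0, T=10)
        expect = np.zeros(10)
        expect[0] = 1.0
        np.testing.assert_allclose(col, expect, atol=1e-12)

    def test_brute_force_fine_grid_oracle(self):
        # oracle: explicit Riemann convolution on the fine grid
        TR, T = 1.0, 40
        dt = TR / 16
        basis = build_basis("canonical", 1, TR)
        stim = StimulusTrain("a", np.array([3.0, 17.0]), np.array([5.0, 2.0]))
        n_fine = T * 16
        u = np.zeros(n_fine)
        tt = np.arange(n_fine) * dt
        for onset, dur in zip(stim.onsets, stim.durations):
            u[(tt >= onset) & (tt < onset + dur)] += 1.0
        b = basis.values[:, 0]
        expect = np.array(
            [sum(u[m] * b[j * 16 - m] for m in range(max(0, j * 16 - b.size + 1), j * 16 + 1)) * dt
             for j in range(T)]
        )
        col = convolve_regressor(stim, b, TR, T)
        np.testing.assert_allclose(col, expect, atol=1e-10)

    def test_linearity_over_events(self):
        basis = build_basis("canonical", 1, 1.0)
        both = StimulusTrain("a", np.array([2.0, 60.0]), np.array([5.0, 5.0]))
        first = StimulusTrain("a", np.array([2.0]), np.array([5.0]))
        second = StimulusTrain("a", np.array([60.0]), np.array([5.0]))
        c = convolve_regressor(both, basis.values[:, 0], 1.0, 120)
        c1 = convolve_regressor(first, basis.values[:, 0], 1.0, 120)
        c2 = convolve_regressor(second, basis.values[:, 0], 1.0, 120)
        np.testing.assert_allclose(c, c1 + c2, atol=1e-12)

    def test_amplitude_scaling(self):
        basis = build_basis("canonical", 1, 1.0)
        base = StimulusTrain("a", np.array([4.0]), np.array([8.0]))
        c1 = convolve_regressor(base, basis.values[:, 0], 1.0, 80)
        c3 = convolve_regressor(base.scaled(3.0), basis.values[:, 0], 1.0, 80)
        np.testing.assert_allclose(c3, 3.0 * c1, atol=1e-12)

    def test_shift_by_whole_volumes(self):
        basis = build_basis("canonical", 1, 1.0)
        stim = StimulusTrain("a", np.array([5.0]), np.array([10.0]))
        delayed = StimulusTrain("a", np.array([9.0]), np.array([10.0]))
        c = convolve_regressor(stim, basis.values[:, 0], 1.0, 100)
        cd = convolve_regressor(delayed, basis.values[:, 0], 1.0, 100)
        np.testing.assert_allclose(cd[4:], c[:-4], atol=1e-12)


class TestBuildDesign:
    def test_two_conditions_give_two_task_columns(self, small_design):
        assert small_design.X.shape == (120, 2)
        assert small_design.KB == 2
        assert [lbl for lbl, _ in small_design.column_labels] == ["a", "b"]

    def test_nuisance_columns_not_counted_in_kb(self):
        stims = [StimulusTrain("a", np.array([0.0]), np.array([15.0]))]
        basis = build_basis("canonical", 1, 1.0)
        nuis = np.column_stack([np.ones(100), np.arange(100.0)])
        d = build_design(stims, basis, 100, 1.0, nuisance=nuis)
        assert d.KB == 1
        assert d.n_nuisance == 2
        assert d.full_matrix().shape == (100, 3)

    def test_columns_match_convolve_regressor(self, small_design):
        basis = build_basis("canonical", 1, 1.0)
        stims = [
            StimulusTrain("a", np.arange(0.0, 110.0, 60.0), np.full(2, 15.0)),
            StimulusTrain("b", np.arange(30.0, 110.0, 60.0), np.full(2, 15.0)),
        ]
        for j, s in enumerate(stims):
            np.testing.assert_allclose(
                small_design.X[:, j],
                convolve_regressor(s, basis.values[:, 0], 1.0, 120),
            )

    def test_kmajor_order_with_multibasis(self):
        stims = [
            StimulusTrain("a", np.array([0.0]), np.array([4.0])),
            StimulusTrain("b", np.array([40.0]), np.array([4.0])),
        ]
        basis = build_basis("fir", 3, 1.0, window=12.0)
        d = build_design(stims, basis, 100, 1.0)
        assert d.column_labels == [("a", 0), ("a", 1), ("a", 2), ("b", 0), ("b", 1), ("b", 2)]

    def test_identical_conditions_flagged(self):
        stims = [
            StimulusTrain("a", np.array([0.0]), np.array([15.0])),
            StimulusTrain("a2", np.array([0.0]), np.array([15.0])),
        ]
        basis = build_basis("canonical", 1, 1.0)
        with pytest.warns(UserWarning, match="rank deficient"):
            d = build_design(stims, basis, 100, 1.0)
        assert d.rank_deficient

    def test_too_few_volumes_rejected(self):
        stims = [StimulusTrain("a", np.array([0.0]), np.array([0.5]))]
        basis = build_basis("fir", 8, 1.0, window=8.0)
        with pytest.raises(ValueError, match="exceed"):
            build_design(stims, basis, 8, 1.0)

    def test_fir_integer_grid_reproduces_lag_matrix(self):
        # oracle: FIR regressors for impulses on the TR grid are exact lagged
        # stick functions
        T, TR, B = 60, 1.0, 5
        onsets = np.array([3.0, 20.0, 41.0])
        stim = StimulusTrain("a", onsets, np.zeros(3))
        basis = build_basis("fir", B, TR, window=B * TR)
        d = build_design([stim], basis, T, TR)
        sticks = np.zeros(T)
        sticks[onsets.astype(int)] = 1.0
        lag = np.column_stack([np.roll(sticks, l) for l in range(B)])
        for l in range(B):
            lag[:l, l] = 0.0
        np.testing.assert_allclose(d.X, lag, atol=1e-10)


def test_stimulus_tsv_round_trip(tmp_path):
    p = tmp_path / "cond-a.tsv"
    p.write_text("10.0\t2.0\t1.0\n0.0\t2.0\t0.5\n")
    stim = read_stimulus_tsv(p)
    np.testing.assert_allclose(stim.onsets, [0.0, 10.0])  # resorted
    np.testing.assert_allclose(stim.amplitudes, [0.5, 1.0])
    assert stim.condition_id == "cond-a"


def test_stimulus_invariants():
    with pytest.raises(ValueError):
        StimulusTrain("a", np.array([5.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        StimulusTrain("a", np.array([-1.0]), np.array([1.0]))
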