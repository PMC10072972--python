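"""Instantaneous phase, PLI, window grids and phase collapse."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitconn as gc
from gaitconn.connectivity import (
    PREPARATION_WINDOWS,
    WALKING_WINDOWS,
    WindowGrid,
    wrap_phase,
)


def pli_reference(phase_x, phase_y):
    """Independent brute-force oracle: literal sum over the signum of the
    wrapped phase difference, one sample at a time."""
    total = 0.0
    for px, py in zip(phase_x, phase_y):
        d = px - py
        while d <= -np.pi:
            d += 2 * np.pi
        while d > np.pi:
            d -= 2 * np.pi
        if d > 0:
            total += 1.0
        elif d < 0:
            total -= 1.0
    return abs(total / len(phase_x))


class TestInstantaneousPhase:
    def test_cosine_phase_slope_matches_frequency(self):
        rate, f = 500.0, 8.0
        t = np.arange(2500) / rate
        phases = gc.instantaneous_phase(np.cos(2 * np.pi * f * t)[None, :])
        slope = np.diff(np.unwrap(phases[0, 200:-200])).mean() * rate
        assert abs(slope - 2 * np.pi * f) < 0.05 * 2 * np.pi * f

    def test_quadrature_pair_locked_at_half_pi(self):
        rate, f = 500.0, 8.0
        t = np.arange(2500) / rate
        x = np.sin(2 * np.pi * f * t)
        y = np.cos(2 * np.pi * f * t)
        p = gc.instantaneous_phase(np.stack([x, y]))
        d = wrap_phase(p[1, 300:-300] - p[0, 300:-300])
        assert np.allclose(d, np.pi / 2, atol=0.05)

    def test_phase_is_amplitude_invariant(self, rng):
        x = rng.normal(size=(3, 600))
        assert np.allclose(
            gc.instantaneous_phase(x), gc.instantaneous_phase(10.0 * x)
        )

    def test_non_finite_input_rejected(self):
        x = np.zeros((1, 100))
        x[0, 3] = np.nan
        with pytest.raises(ValueError):
            gc.instantaneous_phase(x)


class TestPliPair:
    def test_identical_signals_give_zero(self):
        p = np.linspace(0, 10, 200)
        assert gc.pli_pair(p, p) == 0.0

    def test_constant_quarter_cycle_lag_gives_one(self):
        p = np.linspace(0, 10, 200)
        assert gc.pli_pair(p + np.pi / 2, p) == 1.0

    def test_matches_bruteforce_oracle_on_random_windows(self, rng):
        for _ in range(100):
            px = rng.uniform(-np.pi, np.pi, size=125)
            py = rng.uniform(-np.pi, np.pi, size=125)
            assert abs(gc.pli_pair(px, py) - pli_reference(px, py)) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gc.pli_pair(np.zeros(10), np.zeros(11))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_range(self, seed):
        r = np.random.default_rng(seed)
        px = r.uniform(-np.pi, np.pi, size=64)
        py = r.uniform(-np.pi, np.pi, size=64)
        v = gc.pli_pair(px, py)
        assert v == gc.pli_pair(py, px)
        assert 0.0 <= v <= 1.0


class TestWindowGrid:
    def test_standard_epoch_has_19_windows(self):
        assert WindowGrid(epoch_len_s=2.5).n_windows == 19

    def test_preparation_segment_has_5_windows(self):
        assert WindowGrid(epoch_len_s=0.75).n_windows == 5

    def test_window_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            WindowGrid(epoch_len_s=0.2)

    def test_subphase_windows_align_with_gait_events(self):
        # at 500 Hz the walking sub-phases start 375/500/625 samples in
        grid = WindowGrid(epoch_len_s=2.5)
        starts = grid.start_samples(500.0)
        assert starts[WALKING_WINDOWS["RO_RC"]] == 375
        assert starts[WALKING_WINDOWS["RC_LO"]] == 500
        assert starts[WALKING_WINDOWS["LO_LC"]] == 625
        assert [starts[i] for i in PREPARATION_WINDOWS] == [0, 125, 250]


class TestSlidingPli:
    def test_output_slices_are_valid_adjacency(self, rng):
        data = rng.normal(size=(3, 4, 1250))
        epochs = gc.EpochSet(data, 500.0, ["FF", "FU", "UF"],
                             [f"c{i}" for i in range(4)])
        tensor = gc.sliding_pli(epochs)
        assert tensor.values.shape == (3, 19, 4, 4)
        v = tensor.values
        assert np.allclose(v, v.transpose(0, 1, 3, 2))
        assert np.all(np.diagonal(v, axis1=2, axis2=3) == 0)
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_amplitude_scaling_leaves_pli_unchanged(self, rng):
        data = rng.normal(size=(2, 3, 1250))
        scales = rng.uniform(0.1, 10.0, size=(2, 3, 1))
        e1 = gc.EpochSet(data, 500.0, ["FF", "FU"], ["a", "b", "c"])
        e2 = gc.EpochSet(data * scales, 500.0, ["FF", "FU"], ["a", "b", "c"])
        assert np.allclose(
            gc.sliding_pli(e1).values, gc.sliding_pli(e2).values, atol=1e-12
        )

    def test_window_longer_than_epoch_rejected(self, rng):
        epochs = gc.EpochSet(rng.normal(size=(1, 2, 100)), 500.0, ["FF"],
                             ["a", "b"])
        with pytest.raises(ValueError):
            gc.sliding_pli(epochs, WindowGrid(epoch_len_s=2.5))


def _tensor_from_window_values(values_per_window, n_ch=4):
    """19-window tensor whose every matrix is constant off-diagonal."""
    v = np.zeros((1, 19, n_ch, n_ch))
    off = ~np.eye(n_ch, dtype=bool)
    for w, val in enumerate(values_per_window):
        v[0, w][off] = val
    return gc.ConnectivityTensor(
        v, WindowGrid(epoch_len_s=2.5), np.array(["FF"], dtype=object),
        rate=500.0, channel_names=[f"c{i}" for i in range(n_ch)],
    )


class TestCollapsePhases:
    def test_identical_preparation_windows_pass_through(self):
        tensor = _tensor_from_window_values([0.4] * 19)
        pc = gc.collapse_phases(tensor)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(pc.values[0, 0][off], 0.4)

    def test_preparation_mean_uses_windows_1_3_5(self):
        vals = np.zeros(19)
        vals[:5] = [0.1, 0.2, 0.3, 0.4, 0.5]
        pc = gc.collapse_phases(_tensor_from_window_values(vals))
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(pc.values[0, 0][off], 0.3)  # mean of 0.1, 0.3, 0.5

    def test_walking_phases_pick_coincident_windows(self):
        vals = np.zeros(19)
        vals[6], vals[8], vals[10] = 0.6, 0.7, 0.8
        pc = gc.collapse_phases(_tensor_from_window_values(vals))
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(pc.values[0, 1][off], 0.6)
        assert np.allclose(pc.values[0, 2][off], 0.7)
        assert np.allclose(pc.values[0, 3][off], 0.8)

    def test_output_is_four_phases(self, rng):
        data = rng.normal(size=(2, 4, 1250))
        epochs = gc.EpochSet(data, 500.0, ["FF", "FU"], list("abcd"))
        pc = gc.collapse_phases(gc.sliding_pli(epochs))
        assert pc.values.shape == (2, 4, 4, 4)

    def test_nonstandard_grid_rejected_with_expected_grid_named(self, rng):
        data = rng.normal(size=(1, 2, 600))
        epochs = gc.EpochSet(data, 500.0, ["FF"], ["a", "b"])
        tensor = gc.sliding_pli(epochs)  # 1.2-s epoch -> not 19 windows
        with pytest.raises(ValueError, match="250-ms windows"):
            gc.collapse_phases(tensor)


class TestConditionAverage:
    def test_three_conditions_present(self, rng):
        v = rng.uniform(0, 1, size=(6, 4, 3, 3))
        v = (v + v.transpose(0, 1, 3, 2)) / 2
        for m in v.reshape(-1, 3, 3):
            np.fill_diagonal(m, 0)
        pc = gc.PhaseConnectivity(v, np.array(["FF", "FU", "UF"] * 2))
        avg, conds = gc.condition_average(pc)
        assert avg.shape == (3, 4, 3, 3)
        assert conds == ("FF", "FU", "UF")

    def test_single_epoch_average_is_identity(self, rng):
        v = np.abs(rng.uniform(0, 1, size=(3, 4, 3, 3)))
        v = (v + v.transpose(0, 1, 3, 2)) / 2
        pc = gc.PhaseConnectivity(v, np.array(["FF", "FU", "UF"]))
        avg, conds = gc.condition_average(pc)
        for ci, cond in enumerate(conds):
            idx = list(pc.conditions).index(cond)
            assert np.allclose(avg[ci], v[idx])

    def test_symmetry_and_range_preserved(self, classification_session):
        avg, _ = gc.condition_average(classification_session["phase_conn"])
        assert np.allclose(avg, avg.transpose(0, 1, 3, 2))
        assert avg.min() >= 0.0 and avg.max() <= 1.0

    def test_empty_condition_omitted_with_warning(self, rng):
        v = np.zeros((2, 4, 3, 3))
        pc = gc.PhaseConnectivity(v, np.array(["FF", "FF"]))
        with pytest.warns(UserWarning, match="no epochs"):
            avg, conds = gc.condition_average(pc, conditions=("FF", "FU"))
        assert conds == ("FF",)
        assert avg.shape[0] == 1
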