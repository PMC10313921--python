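"""The eleven therapeutic-window parameters and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slicescore import (
    AssayError,
    CurveShape,
    auc_window,
    biphasic_window,
    compute_all_windows,
    detect_shape,
    ecx_window,
    growth_window,
    incomplete_kill_window,
    max_kill_window,
    slope_window,
)
from conftest import DOSES6, make_survival, make_tox


def shape(max_growth=100.0, remaining=0.0, biphasic=False, max_kill=1.0,
          slope=1.0):
    return CurveShape(
        max_kill=max_kill, max_growth_percent=max_growth,
        remaining_at_max=remaining, biphasic=biphasic, slope_at_ec50=slope,
    )


survival_values = st.lists(
    st.floats(min_value=0.0, max_value=2.0, allow_nan=False),
    min_size=6, max_size=6,
)
tox_values = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    min_size=6, max_size=6,
)


class TestEcxWindow:
    def test_reached_at_zero_tox_gives_target_level(self):
        tumor = make_survival([0.9, 0.7, 0.5, 0.3, 0.1, 0.0])
        tox = make_tox([0.0] * 6)
        w, reached = ecx_window(tumor, tox, 50)
        assert reached
        assert w == pytest.approx(0.5)

    def test_matched_curves_give_zero(self):
        s = np.array([0.95, 0.85, 0.6, 0.4, 0.15, 0.05])
        tumor = make_survival(s)
        tox = make_tox(1.0 - s)
        for x in (10, 25, 50, 75, 90):
            w, reached = ecx_window(tumor, tox, x)
            assert reached
            assert w == pytest.approx(0.0, abs=1e-12)

    def test_nr_shortfall_penalty_clamps_at_minus_one(self):
        # max kill 0.2, tox 0.9 at top dose, x = 90: 0.2 - 0.9 - 0.9 -> -1
        tumor = make_survival([1.0, 1.0, 0.95, 0.9, 0.85, 0.8])
        tox = make_tox([0.1, 0.3, 0.5, 0.7, 0.8, 0.9])
        w, reached = ecx_window(tumor, tox, 90)
        assert not reached
        assert w == -1.0

    def test_below_range_reads_both_curves_at_lowest_dose(self):
        tumor = make_survival([0.1, 0.05, 0.02, 0.0, 0.0, 0.0])
        tox = make_tox([0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
        w, reached = ecx_window(tumor, tox, 50)
        assert reached
        assert w == pytest.approx(0.9 - 0.2)

    def test_perfect_agent_scores_plus_one_at_every_level(self):
        tumor = make_survival([0.0] * 6)
        tox = make_tox([0.0] * 6)
        for x in (10, 25, 50, 75, 90):
            w, reached = ecx_window(tumor, tox, x)
            assert reached and w == 1.0

    def test_worst_nr_mode_assigns_floor(self):
        tumor = make_survival([1.0] * 6)
        tox = make_tox([0.0] * 6)
        w, reached = ecx_window(tumor, tox, 50, nr_mode="worst")
        assert not reached and w == -1.0

    def test_unit_mismatch_hard_error(self):
        tumor = make_survival([1.0, 0.0], doses=[1.0, 10.0], unit="uM")
        tox = make_tox([0.0, 0.1], doses=[1.0, 10.0], unit="Gy")
        with pytest.raises(AssayError, match="mismatch"):
            ecx_window(tumor, tox, 50)


class TestMaxKillWindow:
    @pytest.mark.parametrize(
        "s_top, tox_top, expected",
        [(0.0, 0.0, 1.0), (1.0, 1.0, -1.0), (0.2, 0.3, 0.5)],
    )
    def test_kill_minus_tox_at_top_dose(self, s_top, tox_top, expected):
        tumor = make_survival([1.0, 0.9, 0.8, 0.7, 0.6, s_top])
        tox = make_tox([0.0, 0.0, 0.0, 0.0, 0.0, tox_top])
        assert max_kill_window(tumor, tox) == pytest.approx(expected)


class TestSlopeWindow:
    def test_equal_slopes_cancel(self):
        s = np.array([0.9, 0.8, 0.6, 0.4, 0.2, 0.1])
        assert slope_window(make_survival(s), make_tox(1 - s)) == pytest.approx(0.0)

    def test_tumor_only_slope_is_plus_one(self):
        tumor = make_survival([1.0, 0.9, 0.7, 0.3, 0.1, 0.0])
        tox = make_tox([0.2] * 6)  # flat: slope 0
        assert slope_window(tumor, tox) == pytest.approx(1.0)

    def test_tox_only_slope_is_minus_one(self):
        tumor = make_survival([1.0] * 6)  # flat kill
        tox = make_tox([0.0, 0.1, 0.3, 0.6, 0.8, 0.9])
        assert slope_window(tumor, tox) == pytest.approx(-1.0)

    def test_both_flat_same_side_is_zero(self):
        # neither flat curve crosses 50%: no slope advantage either way
        assert slope_window(make_survival([1.0] * 6), make_tox([0.0] * 6)) == 0.0

    def test_degenerate_slopes_decided_by_crossing_status(self):
        # tumor sits at full kill (crossed 50% before the grid), tox never
        # crosses: maximally favorable despite two flat segments
        assert slope_window(make_survival([0.0] * 6), make_tox([0.0] * 6)) == 1.0
        # reverse: tissue fully dead everywhere, tumor untouched
        assert slope_window(make_survival([1.0] * 6), make_tox([1.0] * 6)) == -1.0


class TestAucWindow:
    def test_identical_curves_cancel(self):
        s = np.array([0.9, 0.7, 0.5, 0.3, 0.2, 0.1])
        assert auc_window(make_survival(s), make_tox(1 - s)) == pytest.approx(0.0)

    def test_full_kill_no_tox_is_plus_one(self):
        assert auc_window(
            make_survival([0.0] * 6), make_tox([0.0] * 6)
        ) == pytest.approx(1.0)

    def test_growth_plus_tox_clamps_to_minus_one(self):
        # kill -0.5 (uniform growth), tox 0.6 -> -1.1 clamped
        assert auc_window(
            make_survival([1.5] * 6), make_tox([0.6] * 6)
        ) == -1.0


class TestTernaryWindows:
    @pytest.mark.parametrize("growth, expected",
                             [(120.0, 1.0), (140.0, 0.0), (160.0, -1.0)])
    def test_growth_window_bands(self, growth, expected):
        assert growth_window(shape(max_growth=growth)) == expected

    @pytest.mark.parametrize("growth, expected", [(125.0, 1.0), (150.0, 0.0)])
    def test_growth_window_band_edges(self, growth, expected):
        assert growth_window(shape(max_growth=growth)) == expected

    def test_biphasic_window(self):
        assert biphasic_window(shape(biphasic=False)) == 1.0
        assert biphasic_window(shape(biphasic=True)) == -1.0

    @pytest.mark.parametrize("remaining, expected",
                             [(5.0, 1.0), (15.0, 0.0), (30.0, -1.0),
                              (10.0, 0.0), (25.0, 0.0)])
    def test_incomplete_kill_window_bands(self, remaining, expected):
        assert incomplete_kill_window(shape(remaining=remaining)) == expected


class TestComputeAllWindows:
    def test_matched_monotone_complete_kill(self):
        s = np.array([0.95, 0.8, 0.55, 0.3, 0.12, 0.02])
        win = compute_all_windows(make_survival(s), make_tox(1 - s))
        d = win.as_dict()
        for name in ("max_kill", "ec10", "ec25", "ec50", "ec75", "ec90",
                     "slope", "auc"):
            assert d[name] == pytest.approx(0.0, abs=1e-12), name
        assert d["growth"] == d["biphasic"] == d["incomplete"] == 1.0

    def test_best_case_all_plus_one(self):
        win = compute_all_windows(make_survival([0.0] * 6), make_tox([0.0] * 6))
        assert win.as_tuple() == (1.0,) * 11

    def test_worst_comparative_case(self):
        # zero kill, full tox, 100% remaining, no growth
        win = compute_all_windows(make_survival([1.0] * 6), make_tox([1.0] * 6))
        d = win.as_dict()
        for name in ("max_kill", "ec10", "ec25", "ec50", "ec75", "ec90",
                     "slope", "auc"):
            assert d[name] == -1.0, name
        assert d["growth"] == 1.0 and d["biphasic"] == 1.0
        assert d["incomplete"] == -1.0
        assert all(win.nr_flags.values())

    def test_tox_grid_interpolated_onto_tumor_grid(self):
        tumor = make_survival([0.9, 0.5, 0.1], doses=[1.0, 10.0, 100.0])
        tox_fine = make_tox(
            [0.0, 0.05, 0.1, 0.15, 0.2], doses=[0.5, 2.0, 10.0, 50.0, 200.0]
        )
        win = compute_all_windows(tumor, tox_fine)
        assert -1.0 <= win.w_auc <= 1.0

    def test_tumor_grid_beyond_tox_grid_rejected(self):
        tumor = make_survival([0.9, 0.1], doses=[1.0, 1000.0])
        tox = make_tox([0.0, 0.2], doses=[1.0, 100.0])
        with pytest.raises(AssayError, match="beyond"):
            compute_all_windows(tumor, tox)


@settings(max_examples=150, derandomize=True)
@given(s=survival_values, t=tox_values)
def test_all_windows_bounded_for_arbitrary_curves(s, t):
    """Every window stays in [-1, +1] whatever the (valid) inputs."""
    win = compute_all_windows(make_survival(s), make_tox(t))
    for v in win.as_tuple():
        assert -1.0 <= v <= 1.0
    for name in ("w_growth", "w_biphasic", "w_incomplete"):
        assert getattr(win, name) in (-1.0, 0.0, 1.0)


@settings(max_examples=100, derandomize=True)
@given(
    s=st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
               min_size=6, max_size=6).map(lambda v: sorted(v, reverse=True)),
    t=st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
               min_size=6, max_size=6).map(sorted),
    delta=st.floats(min_value=0.0, max_value=0.5, allow_nan=False),
)
def test_more_kill_never_hurts_comparative_windows(s, t, delta):
    """With toxicity fixed and nondecreasing, pointwise-higher kill never
    lowers the max-kill, ECx, or AUC windows."""
    s = np.array(s)
    tox = make_tox(t)
    lo = compute_all_windows(make_survival(s), tox)
    hi = compute_all_windows(make_survival(np.maximum(s - delta, 0.0)), tox)
    eps = 1e-9
    assert hi.w_max_kill >= lo.w_max_kill - eps
    assert hi.w_auc >= lo.w_auc - eps
    for name in ("w_ec10", "w_ec25", "w_ec50", "w_ec75", "w_ec90"):
        assert getattr(hi, name) >= getattr(lo, name) - eps


@settings(max_examples=100, derandomize=True)
@given(
    s=survival_values,
    t=st.lists(st.floats(min_value=0.0, max_value=0.5, allow_nan=False),
               min_size=6, max_size=6),
    delta=st.floats(min_value=0.0, max_value=0.5, allow_nan=False),
)
def test_more_toxicity_never_helps(s, t, delta):
    """With the tumor curve fixed, a pointwise toxicity increase never
    increases any of the comparative windows (parameters 1-8)."""
    t = np.array(t)
    tumor = make_survival(s)
    lo = compute_all_windows(tumor, make_tox(t))
    hi = compute_all_windows(tumor, make_tox(np.minimum(t + delta, 1.0)))
    eps = 1e-9
    for name in ("w_max_kill", "w_ec10", "w_ec25", "w_ec50", "w_ec75",
                 "w_ec90", "w_auc"):
        assert getattr(hi, name) <= getattr(lo, name) + eps
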