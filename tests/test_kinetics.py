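import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortkin import (
    PosteriorDraws,
    constraint_filter,
    critical_points,
    derive_all,
    grid_argmax,
    summarize_derived,
)

WORKED = np.array([0.0, 12.0, -9.0, 2.0])  # f(t) = 2t^3 - 9t^2 + 12t


def grid_local_maxima(coeffs, window, step):
    """Times of discrete local maxima of the cubic on a dense grid (oracle)."""
    from cortkin import predict_curve

    lo, hi = window
    grid = np.arange(lo, hi + step / 2, step)
    vals = predict_curve(np.asarray(coeffs, dtype=float), grid)
    d = np.diff(vals)
    interior = (d[:-1] > 0) & (d[1:] < 0)
    return grid[1:-1][interior], vals[1:-1][interior]


def draws_from_betas(betas) -> PosteriorDraws:
    """Wrap explicit coefficient vectors as a single-chain posterior."""
    beta = np.asarray(betas, dtype=float)[None, :, :]
    sigma = np.ones(beta.shape[:2])
    return PosteriorDraws(beta=beta, sigma=sigma)


class TestCriticalPoints:
    def test_worked_cubic(self):
        cp = critical_points(WORKED)
        assert cp.t_max == 1.0
        assert cp.t_min == 2.0

    def test_textbook_cubic(self):
        # f(t) = t^3 - 3t: max at -1, min at +1
        cp = critical_points([0.0, -3.0, 0.0, 1.0])
        assert cp.t_max == -1.0
        assert cp.t_min == 1.0

    def test_monotone_cubic_absent(self):
        # f(t) = t^3 + t has negative discriminant
        cp = critical_points([0.0, 1.0, 0.0, 1.0])
        assert cp.t_max is None and cp.t_min is None

    def test_quadratic_max(self):
        # b3 = 0: parabola -t^2 + 4t, vertex (max) at 2
        cp = critical_points([0.0, 4.0, -1.0, 0.0])
        assert cp.t_max == 2.0 and cp.t_min is None

    def test_quadratic_min(self):
        cp = critical_points([0.0, -4.0, 1.0, 0.0])
        assert cp.t_min == 2.0 and cp.t_max is None

    def test_linear_absent(self):
        cp = critical_points([1.0, 2.0, 0.0, 0.0])
        assert cp.t_max is None and cp.t_min is None

    @given(
        b1=st.floats(-50, 50),
        b2=st.floats(-5, 5),
        b3=st.floats(-0.5, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_grid_oracle(self, b1, b2, b3):
        coeffs = np.array([10.0, b1, b2, b3])
        cp = critical_points(coeffs)
        if cp.t_max is None or not (-40 < cp.t_max < 40):
            return
        step = 0.001
        if cp.t_min is not None and abs(cp.t_max - cp.t_min) < 10 * step:
            return  # extrema closer than grid resolution: oracle can't see them
        if abs(6 * b3 * cp.t_max + 2 * b2) < 1e-6:
            return  # curvature below float resolution on the grid
        t_grid, _ = grid_local_maxima(coeffs, (cp.t_max - 1.0, cp.t_max + 1.0), step)
        assert len(t_grid) == 1
        assert abs(t_grid[0] - cp.t_max) <= step


class TestConstraintFilter:
    def test_spec_examples(self):
        draws = draws_from_betas(
            [
                [0.0, -3.0, 0.0, 1.0],   # t^3 - 3t: max at t=-1 -> removed
                [1.0, 12.0, -9.0, 2.0],  # 2t^3-9t^2+12t+1 -> retained
                [0.0, 1.0, 0.0, 1.0],    # monotone: no critical points -> removed
            ]
        )
        constraint_filter(draws, (0.0, 12.0))
        assert draws.flat_retained.tolist() == [False, True, False]

    def test_positivity_constraint(self):
        # retained shape but dips negative inside the window
        draws = draws_from_betas([[-1.0, 12.0, -9.0, 2.0]])
        constraint_filter(draws, (0.0, 12.0))
        assert draws.flat_retained.tolist() == [False]

    def test_draws_never_deleted(self):
        draws = draws_from_betas([[0.0, 1.0, 0.0, 1.0]] * 5)
        n_before = draws.n_total
        constraint_filter(draws, (0.0, 12.0))
        assert draws.n_total == n_before

    def test_shrinking_window_grows_retained_set(self):
        rng = np.random.default_rng(3)
        betas = np.column_stack(
            [
                rng.normal(5, 20, 500),
                rng.normal(0, 5, 500),
                rng.normal(0, 0.5, 500),
                rng.normal(0, 0.01, 500),
            ]
        )
        wide = draws_from_betas(betas)
        constraint_filter(wide, (0.0, 84.0))
        narrow = draws_from_betas(betas)
        constraint_filter(narrow, (0.0, 12.0))
        # every draw retained on the wide window is retained on the narrow one
        assert np.all(narrow.flat_retained[wide.flat_retained])

    def test_all_filtered_refused_downstream(self):
        draws = draws_from_betas([[0.0, 1.0, 0.0, 1.0]])
        constraint_filter(draws, (0.0, 12.0))
        with pytest.raises(ValueError, match="no retained draws"):
            derive_all(draws)


class TestDeriveAll:
    def test_worked_cubic(self):
        draws = draws_from_betas([WORKED + np.array([1.0, 0, 0, 0])])
        constraint_filter(draws, (0.0, 12.0))
        out = derive_all(draws)
        row = out.iloc[0]
        assert row["t_max"] == 1.0
        assert row["t_min"] == 2.0
        assert row["cort_max"] == pytest.approx(6.0)  # f(1) + 1 offset
        assert row["distribution_time"] == 1.0
        assert row["elimination_time"] == 1.0
        assert not row["min_before_max"]

    def test_b3_negative_flagged(self):
        # f(t) = -(t-4)^3 + 3(t-4) + 10: local min at 3, local max at 5
        # expanded: b0 = 62, b1 = -45, b2 = 12, b3 = -1
        coeffs = np.array([62.0, -45.0, 12.0, -1.0])
        cp_draws = draws_from_betas([coeffs])
        constraint_filter(cp_draws, (0.0, 6.0))
        assert cp_draws.flat_retained.all()
        out = derive_all(cp_draws)
        row = out.iloc[0]
        assert row["t_max"] == pytest.approx(5.0)
        assert row["t_min"] == pytest.approx(3.0)
        assert row["min_before_max"]
        assert np.isnan(row["elimination_time"])

    def test_requires_filter_first(self):
        draws = draws_from_betas([WORKED])
        with pytest.raises(ValueError, match="retained_mask not set"):
            derive_all(draws)

    def test_closed_form_matches_grid_oracle_bulk(self):
        rng = np.random.default_rng(11)
        betas = np.column_stack(
            [
                rng.uniform(10, 300, 1000),
                rng.normal(5, 20, 1000),
                rng.normal(-1, 2, 1000),
                rng.normal(0, 0.05, 1000),
            ]
        )
        draws = draws_from_betas(betas)
        constraint_filter(draws, (0.0, 12.0))
        out = derive_all(draws)
        step = 0.01
        checked = 0
        for draw_id, row in out.iterrows():
            if not (0.0 < row["t_max"] < 12.0):
                continue
            t_grid, v_grid = grid_local_maxima(betas[draw_id], (0.0, 12.0), step)
            assert len(t_grid) == 1
            assert abs(t_grid[0] - row["t_max"]) <= step
            assert v_grid[0] <= row["cort_max"] + 1e-9
            checked += 1
        assert checked > 100

    def test_elimination_positive_for_positive_b3(self):
        rng = np.random.default_rng(12)
        betas = np.column_stack(
            [
                rng.uniform(10, 100, 300),
                rng.normal(5, 10, 300),
                rng.normal(-1, 1, 300),
                np.abs(rng.normal(0, 0.05, 300)) + 1e-6,
            ]
        )
        draws = draws_from_betas(betas)
        constraint_filter(draws, (0.0, 84.0))
        if draws.flat_retained.any():
            out = derive_all(draws)
            assert (out["elimination_time"].dropna() > 0).all()
            assert not out["min_before_max"].any()


class TestSummarizeDerived:
    def test_identical_draws_zero_width(self):
        draws = draws_from_betas([WORKED + np.array([1.0, 0, 0, 0])] * 10)
        constraint_filter(draws, (0.0, 12.0))
        out = summarize_derived(derive_all(draws))
        row = out.loc["t_max"]
        assert row["mean"] == row["ci_low"] == row["ci_high"] == 1.0

    def test_quantile_rule_hand_example(self):
        # linear interpolation between order statistics on draws 1..100
        derived = pd.DataFrame(
            {
                "t_max": np.arange(1.0, 101.0),
                "t_min": np.arange(1.0, 101.0),
                "cort_max": np.arange(1.0, 101.0),
                "distribution_time": np.arange(1.0, 101.0),
                "elimination_time": np.arange(1.0, 101.0),
                "min_before_max": [False] * 100,
            }
        )
        out = summarize_derived(derived)
        assert out.loc["t_max", "mean"] == pytest.approx(50.5)
        assert out.loc["t_max", "ci_low"] == pytest.approx(5.95)
        assert out.loc["t_max", "ci_high"] == pytest.approx(95.05)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_ci_bounds_ordered(self, values):
        derived = pd.DataFrame(
            {q: values for q in ("t_max", "t_min", "cort_max",
                                 "distribution_time", "elimination_time")}
        )
        derived["min_before_max"] = False
        out = summarize_derived(derived)
        ok = out.dropna()
        assert (ok["ci_low"] <= ok["ci_high"]).all()

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no derived draws"):
            summarize_derived(pd.DataFrame())
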