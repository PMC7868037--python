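"""Synthetic study generator: two-compartment cortisol kinetics with known truth.

Plasma concentration is baseline plus a handling spike (single exponential
decay from the injection event) plus, in treatment arms, a first-order
absorption/elimination pulse (Bateman form).  Mucus receives cortisol from
plasma through a first-order transfer compartment and clears it at its own
rate, which delays and attenuates the mucus response relative to plasma.
All noise is multiplicative lognormal so concentrations stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

Matrix = Literal["plasma", "mucus"]
Arm = Literal["treatment", "control"]

#: columns of the tidy measurement table, in canonical order
MEASUREMENT_COLUMNS = [
    "fish_id",
    "tank_id",
    "trial",
    "arm",
    "matrix",
    "time_h",
    "cortisol_ng_ml",
]

# rates closer together than this are treated as coincident and routed to
# the ODE / limit branch instead of the closed-form difference quotient
_RATE_TOL = 1e-9


@dataclass(frozen=True)
class KineticsParams:
    """Ground-truth kinetic and noise parameters for the simulator.

    Rates are per hour, concentrations ng/ml.  ``cv_plasma`` / ``cv_mucus``
    are assay coefficients of variation as fractions of the mean;
    ``fish_sd_log`` is the sd of the between-fish lognormal multiplier on
    the log scale.
    """

    baseline_plasma: float = 230.0
    baseline_mucus: float = 8.0
    handling_amp: float = 150.0
    handling_decay: float = 0.35
    pulse_amp: float = 550.0
    k_abs: float = 0.11
    k_elim: float = 0.065
    k_transfer: float = 0.002
    k_mucus: float = 0.003
    fish_sd_log: float = 0.25
    cv_plasma: float = 0.1095
    cv_mucus: float = 0.1266

    def __post_init__(self) -> None:
        for name in ("handling_decay", "k_abs", "k_elim", "k_transfer", "k_mucus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate {name!r} must be > 0, got {getattr(self, name)}")
        for name in ("baseline_plasma", "baseline_mucus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("handling_amp", "pulse_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"amplitude {name!r} must be >= 0")
        for name in ("cv_plasma", "cv_mucus"):
            cv = getattr(self, name)
            if not 0 <= cv < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {cv}")
        if self.fish_sd_log < 0:
            raise ValueError("fish_sd_log must be >= 0")
        if abs(self.k_abs - self.k_elim) <= _RATE_TOL:
            raise ValueError(
                "k_abs == k_elim gives a degenerate Bateman pulse; "
                "perturb one of the rates"
            )


@dataclass(frozen=True)
class TrialSpec:
    """One injection trial: a name and its tank allocation."""

    name: str
    treatment_tanks: int
    control_tanks: int

    def __post_init__(self) -> None:
        if self.treatment_tanks < 0 or self.control_tanks < 0:
            raise ValueError("tank counts must be non-negative")
        if self.treatment_tanks + self.control_tanks == 0:
            raise ValueError(f"trial {self.name!r} has no tanks")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling schedule and tank layout of the study.

    Each fish is sampled exactly twice: once at a time inside
    ``first_window`` and once inside ``second_window``, with at least
    ``min_resample_gap`` hours between its two handlings.  One fish per
    tank is sampled at each sampling time.
    """

    trials: tuple[TrialSpec, ...] = (
        TrialSpec("ACTH", treatment_tanks=3, control_tanks=1),
        TrialSpec("cortisol", treatment_tanks=2, control_tanks=2),
    )
    fish_per_tank: int = 5
    sampling_times: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0, 72.0, 84.0)
    first_window: tuple[float, float] = (0.0, 12.0)
    second_window: tuple[float, float] = (24.0, 84.0)
    min_resample_gap: float = 24.0

    def __post_init__(self) -> None:
        times = np.asarray(self.sampling_times, dtype=float)
        if times.size == 0 or np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("sampling_times must be strictly increasing and non-negative")
        if self.fish_per_tank < 1:
            raise ValueError("fish_per_tank must be >= 1")
        if len({t.name for t in self.trials}) != len(self.trials):
            raise ValueError("trial names must be unique")

    @property
    def first_window_times(self) -> tuple[float, ...]:
        lo, hi = self.first_window
        return tuple(t for t in self.sampling_times if lo <= t <= hi)

    @property
    def second_window_times(self) -> tuple[float, ...]:
        lo, hi = self.second_window
        return tuple(t for t in self.sampling_times if lo <= t <= hi)

    def n_tanks(self, trial: TrialSpec) -> int:
        return trial.treatment_tanks + trial.control_tanks


ACTH_TRIAL_DESIGN = StudyDesign(trials=(TrialSpec("ACTH", 3, 1),))


def _bateman(t: np.ndarray, amp: float, k_abs: float, k_elim: float) -> np.ndarray:
    """Difference-of-exponentials pulse; amp scales the pre-factor form."""
    return amp * (k_abs / (k_abs - k_elim)) * (np.exp(-k_elim * t) - np.exp(-k_abs * t))


def bateman_peak_time(k_abs: float, k_elim: float) -> float:
    """Closed-form argmax of the Bateman pulse."""
    return float(np.log(k_abs / k_elim) / (k_abs - k_elim))


def _exp_response(t: np.ndarray, rate: float, k_out: float) -> np.ndarray:
    """Response of d/dt y = e^(-rate*t) - k_out*y, y(0)=0.

    Closed form (e^(-rate t) - e^(-k_out t)) / (k_out - rate) when the rates
    are distinct; t*e^(-k_out t) in the coincident limit.
    """
    if abs(k_out - rate) <= _RATE_TOL:
        return t * np.exp(-k_out * t)
    return (np.exp(-rate * t) - np.exp(-k_out * t)) / (k_out - rate)


def _plasma_excess(params: KineticsParams, arm: Arm, t: np.ndarray) -> np.ndarray:
    out = params.handling_amp * np.exp(-params.handling_decay * t)
    if arm == "treatment":
        out = out + _bateman(t, params.pulse_amp, params.k_abs, params.k_elim)
    return out


def _mucus_excess(params: KineticsParams, arm: Arm, t: np.ndarray) -> np.ndarray:
    # superposition of the transfer ODE's response to each exponential term
    # of the plasma excess
    p = params
    out = p.k_transfer * p.handling_amp * _exp_response(t, p.handling_decay, p.k_mucus)
    if arm == "treatment":
        scale = p.pulse_amp * p.k_abs / (p.k_abs - p.k_elim)
        out = out + p.k_transfer * scale * (
            _exp_response(t, p.k_elim, p.k_mucus) - _exp_response(t, p.k_abs, p.k_mucus)
        )
    return out


def true_curve(
    params: KineticsParams,
    matrix: Matrix,
    arm: Arm,
    t: float | Sequence[float] | np.ndarray,
) -> np.ndarray | float:
    """Noise-free concentration at time(s) ``t`` hours post-injection.

    Plasma is baseline + handling spike + (treatment only) Bateman pulse.
    Mucus solves d/dt C_m = k_transfer*(C_p(t) - baseline_plasma)
    - k_mucus*(C_m - baseline_mucus) in closed form (exact superposition of
    exponential responses; coincident-rate limits handled analytically).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if matrix == "plasma":
        out = params.baseline_plasma + _plasma_excess(params, arm, t_arr)
    elif matrix == "mucus":
        out = params.baseline_mucus + _mucus_excess(params, arm, t_arr)
    else:
        raise ValueError(f"unknown matrix {matrix!r}")
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def mucus_curve_ode(
    params: KineticsParams,
    arm: Arm,
    t: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> np.ndarray:
    """Mucus curve by direct numerical integration of the transfer ODE.

    Independent cross-check for the closed-form branch of :func:`true_curve`.
    """
    t = np.asarray(t, dtype=float)

    def rhs(tt: float, y: np.ndarray) -> np.ndarray:
        cp_excess = _plasma_excess(params, arm, np.asarray(tt))
        return params.k_transfer * cp_excess - params.k_mucus * (y - params.baseline_mucus)

    sol = solve_ivp(
        rhs,
        (0.0, float(t.max()) if t.size else 0.0),
        [params.baseline_mucus],
        t_eval=t,
        rtol=rtol,
        atol=atol,
        method="DOP853",
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]


@dataclass(frozen=True)
class PeakResult:
    t_peak: float
    c_peak: float
    at_boundary: bool


def true_peak(
    params: KineticsParams,
    matrix: Matrix,
    arm: Arm = "treatment",
    window: tuple[float, float] | None = None,
    grid_step: float = 0.01,
) -> PeakResult:
    """Ground-truth peak of the noise-free curve over the matrix window.

    Dense grid search (step <= ``grid_step``) refined by bounded local
    maximization.  ``at_boundary`` flags curves that are monotone over the
    window (argmax at an endpoint).
    """
    if window is None:
        window = (0.0, 12.0) if matrix == "plasma" else (0.0, 84.0)
    lo, hi = window
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    vals = np.asarray(true_curve(params, matrix, arm, grid))
    i = int(np.argmax(vals))
    if i == 0 or i == len(grid) - 1:
        return PeakResult(float(grid[i]), float(vals[i]), at_boundary=True)
    res = minimize_scalar(
        lambda tt: -true_curve(params, matrix, arm, tt),
        bounds=(grid[i - 1], grid[i + 1]),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return PeakResult(float(res.x), float(-res.fun), at_boundary=False)


def _schedule_one_tank(
    design: StudyDesign, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Assign each fish slot in a tank its two sampling times.

    Returns (fish_slot, time) pairs.  Fish are assigned to first-window
    times by a seeded permutation; second-window times are then matched so
    every pairing respects the minimum resample gap.
    """
    first = list(design.first_window_times)
    second = list(design.second_window_times)
    if len(first) != design.fish_per_tank or len(second) != design.fish_per_tank:
        raise ValueError(
            f"design needs exactly fish_per_tank={design.fish_per_tank} sampling "
            f"times in each window; got {len(first)} in the first and "
            f"{len(second)} in the second — too few fish for the schedule"
        )
    slots = list(rng.permutation(design.fish_per_tank))
    # greedy match: hardest-to-place first-window times (latest) pick first
    # from the shrinking pool of feasible second-window times
    order = np.argsort([-t for t in first])
    second_pool = sorted(second)
    assignment: dict[int, tuple[float, float]] = {}
    for idx in order:
        t1 = first[idx]
        feasible = [t2 for t2 in second_pool if t2 - t1 >= design.min_resample_gap]
        if not feasible:
            raise ValueError(
                f"no second-window time >= {design.min_resample_gap} h after "
                f"first-window time {t1} h"
            )
        t2 = feasible[int(rng.integers(len(feasible)))]
        second_pool.remove(t2)
        assignment[slots[idx]] = (t1, t2)
    events = []
    for slot, (t1, t2) in assignment.items():
        events.append((slot, t1))
        events.append((slot, t2))
    return events


def simulate_study(
    design: StudyDesign,
    params: KineticsParams,
    seed: int,
) -> pd.DataFrame:
    """Simulate the full study; returns a tidy measurement table.

    One plasma row and one mucus row per (fish, sampling event).  Observed
    value = true_curve * per-fish lognormal multiplier (log-sd
    ``fish_sd_log``) * mean-one lognormal assay error at the matrix CV.
    Deterministic in (design, params, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows: list[dict] = []
    fish_counter = 0
    for trial in design.trials:
        n_tanks = design.n_tanks(trial)
        arms = ["treatment"] * trial.treatment_tanks + ["control"] * trial.control_tanks
        arm_order = rng.permutation(n_tanks)
        for tank_i in range(n_tanks):
            arm = arms[arm_order[tank_i]]
            tank_id = f"{trial.name}_tank{tank_i + 1}"
            fish_ids = [f"fish{fish_counter + j + 1:03d}" for j in range(design.fish_per_tank)]
            fish_counter += design.fish_per_tank
            fish_mult = np.exp(rng.normal(0.0, params.fish_sd_log, design.fish_per_tank))
            for slot, t in _schedule_one_tank(design, rng):
                for matrix in ("plasma", "mucus"):
                    cv = params.cv_plasma if matrix == "plasma" else params.cv_mucus
                    mu_true = true_curve(params, matrix, arm, t)
                    # mean-one lognormal: exp(N(-s^2/2, s)); exact 1 when cv=0
                    s = float(np.sqrt(np.log1p(cv**2)))
                    noise = float(np.exp(rng.normal(-(s**2) / 2, s)))
                    rows.append(
                        {
                            "fish_id": fish_ids[slot],
                            "tank_id": tank_id,
                            "trial": trial.name,
                            "arm": arm,
                            "matrix": matrix,
                            "time_h": float(t),
                            "cortisol_ng_ml": float(mu_true * fish_mult[slot] * noise),
                        }
                    )
    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return table.sort_values(
        ["trial", "tank_id", "time_h", "matrix", "fish_id"], kind="stable"
    ).reset_index(drop=True)


def noiseless(params: KineticsParams) -> KineticsParams:
    """Copy of ``params`` with all noise sources switched off."""
    return replace(params, fish_sd_log=0.0, cv_plasma=0.0, cv_mucus=0.0)
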