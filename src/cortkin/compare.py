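"""Treatment/control proportional curves, exceedance significance, and the
full analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import baseline_summary, subset_for_model, validate_measurements, window_for_matrix
from .kinetics import (
    DEFAULT_GRID_STEP,
    constraint_filter,
    cubic_eval,
    derive_all,
    summarize_derived,
)
from .model import PosteriorDraws, Priors, SamplerSettings, fit_cubic, predict_curve


@dataclass(frozen=True)
class ProportionalCurve:
    """Pointwise treatment/control ratio curve with a 90% band."""

    grid: np.ndarray
    mean_ratio: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n_pairs: int
    n_excluded_points: int  # (pair, point) entries dropped for control <= 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.grid,
                "mean_ratio": self.mean_ratio,
                "band_low": self.band_low,
                "band_high": self.band_high,
            }
        )


@dataclass(frozen=True)
class ExceedanceResult:
    p_above_t0: float
    p_above_control: float
    n_draws: int
    n_pairs: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_above_t0 <= 1.0 and 0.0 <= self.p_above_control <= 1.0):
            raise ValueError("exceedance proportions must lie in [0, 1]")


def pair_retained(
    treat: PosteriorDraws,
    control: PosteriorDraws,
    pairing_seed: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair retained draws one-to-one.

    Both retained coefficient sets are (optionally) shuffled with a seeded
    permutation, then truncated to the shorter length and paired by index.
    ``pairing_seed=None`` skips the shuffle (pure index pairing), which
    makes identical posteriors pair draw-for-draw.
    """
    tb = treat.retained_beta()
    cb = control.retained_beta()
    if len(tb) == 0 or len(cb) == 0:
        raise ValueError("no retained draws on one side of the pairing")
    if pairing_seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence(pairing_seed))
        tb = tb[rng.permutation(len(tb))]
        cb = cb[rng.permutation(len(cb))]
    n = min(len(tb), len(cb))
    return tb[:n], cb[:n]


def proportional_curve(
    treat: PosteriorDraws,
    control: PosteriorDraws,
    grid: np.ndarray,
    pairing_seed: int | None = None,
    ci_level: float = 0.90,
) -> ProportionalCurve:
    """Per-pair treatment/control cubic ratio on a time grid, summarized
    pointwise by mean and equal-tailed band."""
    grid = np.asarray(grid, dtype=float)
    tb, cb = pair_retained(treat, control, pairing_seed)
    treat_curves = predict_curve(tb, grid)
    control_curves = predict_curve(cb, grid)
    bad = control_curves <= 0.0
    n_excluded = int(bad.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bad, np.nan, treat_curves / control_curves)
    alpha = (1.0 - ci_level) / 2.0
    mean = np.nanmean(ratio, axis=0)
    low, high = np.nanpercentile(ratio, [100 * alpha, 100 * (1 - alpha)], axis=0)
    return ProportionalCurve(
        grid=grid,
        mean_ratio=mean,
        band_low=low,
        band_high=high,
        n_pairs=len(tb),
        n_excluded_points=n_excluded,
    )


def exceedance(
    derived: pd.DataFrame,
    t0_mean: float,
    control: PosteriorDraws,
    pairing_seed: int | None = None,
) -> ExceedanceResult:
    """Proportion of draws whose cort_max exceeds each baseline threshold.

    p_above_t0 uses every retained treatment draw against the scalar mean
    time-0 concentration.  p_above_control pairs treatment draws with
    retained control draws (seeded shuffle + truncation) and compares each
    cort_max with the paired control cubic evaluated at that draw's own
    t_max ("temporally aligned" control value).
    """
    if derived.empty:
        raise ValueError("empty derived draw set")
    cort_max = derived["cort_max"].to_numpy()
    t_max = derived["t_max"].to_numpy()
    p_t0 = float(np.mean(cort_max > t0_mean))

    cb = control.retained_beta()
    if len(cb) == 0:
        raise ValueError("no retained control draws")
    if pairing_seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence(pairing_seed))
        order_t = rng.permutation(len(derived))
        cb = cb[rng.permutation(len(cb))]
    else:
        order_t = np.arange(len(derived))
    n = min(len(order_t), len(cb))
    idx = order_t[:n]
    tm = t_max[idx]
    control_at_tmax = cubic_eval(cb[:n], tm)
    p_ctrl = float(np.mean(cort_max[idx] > control_at_tmax))
    return ExceedanceResult(
        p_above_t0=p_t0, p_above_control=p_ctrl, n_draws=len(derived), n_pairs=n
    )


@dataclass(frozen=True)
class AnalysisConfig:
    settings: SamplerSettings = SamplerSettings()
    priors: Priors = Priors()
    grid_step: float = DEFAULT_GRID_STEP
    curve_grid_step: float = 0.1
    pairing_seed: int = 0
    ci_level: float = 0.90


@dataclass
class AnalysisReport:
    """All artifacts of one end-to-end run, keyed by model-fit group."""

    fits: dict[str, PosteriorDraws] = field(default_factory=dict)
    derived: dict[str, pd.DataFrame] = field(default_factory=dict)
    summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    prop_curves: dict[str, ProportionalCurve] = field(default_factory=dict)
    exceedances: dict[str, ExceedanceResult] = field(default_factory=dict)
    baselines: dict[str, float] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def summary_table(self) -> pd.DataFrame:
        """One row per (group, quantity): mean, 90% CI, retained count."""
        rows = []
        for group, summ in self.summaries.items():
            n_retained = int(self.fits[group].flat_retained.sum())
            for q, r in summ.iterrows():
                rows.append(
                    {
                        "group": group,
                        "quantity": q,
                        "mean": r["mean"],
                        "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"],
                        "n_retained": n_retained,
                    }
                )
        return pd.DataFrame(rows)

    def exceedance_table(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "p_above_t0": e.p_above_t0,
                "p_above_control": e.p_above_control,
                "n_draws": e.n_draws,
                "n_pairs": e.n_pairs,
            }
            for g, e in self.exceedances.items()
        ]
        return pd.DataFrame(rows)


def _fit_group(
    table: pd.DataFrame,
    trial: str | None,
    matrix: str,
    arm: str,
    pool_controls: bool,
    config: AnalysisConfig,
    seed_offset: int,
    log: list[str],
) -> tuple[pd.DataFrame, PosteriorDraws]:
    subset = subset_for_model(table, trial, matrix, arm, pool_controls=pool_controls)
    settings = SamplerSettings(
        chains=config.settings.chains,
        iterations=config.settings.iterations,
        thin=config.settings.thin,
        burnin_draws=config.settings.burnin_draws,
        seed=config.settings.seed + seed_offset,
    )
    draws = fit_cubic(subset, settings, config.priors)
    window = window_for_matrix(matrix)
    constraint_filter(draws, window, grid_step=config.grid_step)
    n_ret = int(draws.flat_retained.sum())
    log.append(
        f"fit trial={trial} matrix={matrix} arm={arm} pooled={pool_controls}: "
        f"n_obs={len(subset)} draws={draws.n_total} retained={n_ret} "
        f"max_rhat={max(draws.rhat.values()):.4f}"
    )
    if n_ret == 0:
        raise RuntimeError(
            f"all draws filtered out for trial={trial}, matrix={matrix}, arm={arm}"
        )
    return subset, draws


def run_full_analysis(table: pd.DataFrame, config: AnalysisConfig | None = None
                      ) -> AnalysisReport:
    """Fit all six models, filter, derive, summarize, and compare.

    Six fits: one per (trial, matrix) treatment group plus one pooled
    control per matrix.  Four proportional curves and four exceedance
    results: each treatment group against its matrix's pooled control.
    """
    config = config or AnalysisConfig()
    table = validate_measurements(table)
    trials = sorted(table["trial"].unique())
    matrices = ("plasma", "mucus")
    for arm in ("treatment", "control"):
        if not (table["arm"] == arm).any():
            raise ValueError(f"table has no {arm} rows")

    report = AnalysisReport()
    stage = "setup"
    try:
        offset = 0
        for matrix in matrices:
            stage = f"fit pooled control / {matrix}"
            subset, draws = _fit_group(
                table, None, matrix, "control", True, config, offset, report.log
            )
            key = f"control_{matrix}_pooled"
            report.fits[key] = draws
            report.derived[key] = derive_all(draws)
            report.summaries[key] = summarize_derived(
                report.derived[key], config.ci_level
            )
            offset += 1

        for trial in trials:
            for matrix in matrices:
                stage = f"fit {trial} / {matrix} / treatment"
                subset, draws = _fit_group(
                    table, trial, matrix, "treatment", False, config, offset, report.log
                )
                key = f"{trial}_{matrix}_treatment"
                report.fits[key] = draws
                derived = derive_all(draws)
                report.derived[key] = derived
                report.summaries[key] = summarize_derived(derived, config.ci_level)
                offset += 1

                stage = f"compare {trial} / {matrix}"
                control = report.fits[f"control_{matrix}_pooled"]
                lo, hi = window_for_matrix(matrix)
                grid = np.arange(lo, hi + config.curve_grid_step / 2,
                                 config.curve_grid_step)
                pc = proportional_curve(
                    draws, control, grid, pairing_seed=config.pairing_seed
                )
                report.prop_curves[key] = pc
                if pc.n_excluded_points:
                    report.log.append(
                        f"{key}: excluded {pc.n_excluded_points} (pair, point) "
                        "ratio entries with non-positive control values"
                    )
                t0 = baseline_summary(subset, time=0.0)
                report.baselines[key] = t0.mean
                report.exceedances[key] = exceedance(
                    derived, t0.mean, control, pairing_seed=config.pairing_seed
                )
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage '{stage}': {exc}") from exc
    return report
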