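"""Measurement-table loading, validation, subsetting and assay QC."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .simulate import MEASUREMENT_COLUMNS, StudyDesign

#: time restriction applied to plasma model subsets, hours (repeat-sampling
#: confound: only the first sampling window is comparable across fish)
PLASMA_WINDOW: tuple[float, float] = (0.0, 12.0)
MUCUS_WINDOW: tuple[float, float] = (0.0, 84.0)


class ValidationError(ValueError):
    """Raised when a measurement table violates the schema invariants."""


def window_for_matrix(matrix: str) -> tuple[float, float]:
    if matrix == "plasma":
        return PLASMA_WINDOW
    if matrix == "mucus":
        return MUCUS_WINDOW
    raise ValueError(f"unknown matrix {matrix!r}")


def validate_measurements(
    table: pd.DataFrame, design: StudyDesign | None = None
) -> pd.DataFrame:
    """Validate a tidy measurement table; returns it with canonical dtypes.

    Every violation is collected and reported with its (0-based) row number
    in a single :class:`ValidationError`.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")

    table = table.copy()
    problems: list[str] = []

    for col in ("time_h", "cortisol_ng_ml"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna()]
        for i in bad:
            problems.append(f"row {i}: non-numeric {col} ({table.loc[i, col]!r})")
        table[col] = coerced

    ok_time = table["time_h"].notna()
    for i in table.index[ok_time & (table["time_h"] < 0)]:
        problems.append(f"row {i}: negative time_h ({table.loc[i, 'time_h']})")

    ok_conc = table["cortisol_ng_ml"].notna()
    for i in table.index[ok_conc & (table["cortisol_ng_ml"] <= 0)]:
        problems.append(
            f"row {i}: non-positive cortisol_ng_ml ({table.loc[i, 'cortisol_ng_ml']})"
        )

    for col in ("matrix", "arm"):
        allowed = {"plasma", "mucus"} if col == "matrix" else {"treatment", "control"}
        for i in table.index[~table[col].isin(allowed)]:
            problems.append(
                f"row {i}: {col} must be one of {sorted(allowed)}, got {table.loc[i, col]!r}"
            )

    dup = table.duplicated(subset=["fish_id", "time_h", "matrix"], keep=False)
    if dup.any():
        for i in table.index[dup]:
            key = tuple(table.loc[i, ["fish_id", "time_h", "matrix"]])
            problems.append(f"row {i}: duplicate (fish_id, time_h, matrix) key {key}")

    if design is not None:
        allowed_times = set(design.sampling_times)
        for i in table.index[ok_time & ~table["time_h"].isin(allowed_times)]:
            problems.append(
                f"row {i}: time_h {table.loc[i, 'time_h']} not in the design's "
                f"sampling times {sorted(allowed_times)}"
            )

    if problems:
        raise ValidationError(
            f"{len(problems)} invalid row(s):\n" + "\n".join(problems)
        )
    return table


def load_measurements(
    path: str | Path, design: StudyDesign | None = None
) -> pd.DataFrame:
    """Read and validate a measurement CSV (comma separated, UTF-8, header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, float_precision="round_trip")
    return validate_measurements(table, design=design)


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table as CSV, canonical column order."""
    table[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def subset_for_model(
    table: pd.DataFrame,
    trial: str | None,
    matrix: str,
    arm: str,
    pool_controls: bool = False,
) -> pd.DataFrame:
    """Select the rows entering one model fit.

    Treatment subsets filter on (trial, matrix, arm="treatment").  Control
    subsets with ``pool_controls=True`` pool control rows of the given
    matrix across all trials (``trial`` is ignored and may be None).
    Plasma subsets are additionally restricted to the first sampling
    window, 0-12 h, because each fish is resampled only after 24 h.
    """
    mask = (table["matrix"] == matrix) & (table["arm"] == arm)
    if arm == "control" and pool_controls:
        pass  # pooled across trials
    else:
        if trial is None:
            raise ValueError("trial is required unless pooling controls")
        mask &= table["trial"] == trial
    if matrix == "plasma":
        lo, hi = PLASMA_WINDOW
        mask &= (table["time_h"] >= lo) & (table["time_h"] <= hi)
    out = table[mask].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"empty subset for trial={trial!r}, matrix={matrix!r}, arm={arm!r}"
            f"{' (pooled controls)' if pool_controls else ''}"
        )
    return out


@dataclass(frozen=True)
class AssayCV:
    intra_pct: float
    inter_pct: float | None  # None when only one plate was run
    n_samples: int
    n_plates: int


def assay_cv(dups: pd.DataFrame, reference_ids: Iterable[str] | None = None) -> AssayCV:
    """Intra-/inter-assay coefficients of variation, in percent.

    ``dups`` needs columns sample_id, plate_id, value, with >= 2 replicate
    rows per (sample_id, plate_id).  Intra-assay CV is the mean over
    samples of replicate sd / replicate mean.  Inter-assay CV is the CV of
    plate-level means of reference samples run on every plate (by default,
    any sample_id appearing on >= 2 plates).
    """
    required = {"sample_id", "plate_id", "value"}
    if not required.issubset(dups.columns):
        raise ValueError(f"duplicate table needs columns {sorted(required)}")
    if (dups["value"] <= 0).any():
        raise ValueError("replicate values must be > 0")

    by_sample = dups.groupby(["sample_id", "plate_id"])["value"]
    counts = by_sample.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"samples with < 2 replicates: {bad}")
    ratios = by_sample.std(ddof=1) / by_sample.mean()
    intra = float(ratios.mean() * 100.0)

    plate_means = by_sample.mean().reset_index()
    n_plates = plate_means["plate_id"].nunique()
    if reference_ids is None:
        plates_per_sample = plate_means.groupby("sample_id")["plate_id"].nunique()
        reference_ids = plates_per_sample[plates_per_sample >= 2].index.tolist()
    else:
        reference_ids = list(reference_ids)

    inter: float | None = None
    if n_plates >= 2 and reference_ids:
        cvs = []
        for sid in reference_ids:
            means = plate_means.loc[plate_means["sample_id"] == sid, "value"]
            if len(means) >= 2:
                cvs.append(means.std(ddof=1) / means.mean())
        if cvs:
            inter = float(np.mean(cvs) * 100.0)
    return AssayCV(
        intra_pct=intra,
        inter_pct=inter,
        n_samples=int(counts.size),
        n_plates=int(n_plates),
    )


@dataclass(frozen=True)
class BaselineSummary:
    mean: float
    sd: float  # 0.0 (flagged) when n == 1
    n: int
    sd_defined: bool


def baseline_summary(table: pd.DataFrame, time: float = 0.0) -> BaselineSummary:
    """Mean +/- sample sd (n-1) of concentrations at one sampling time."""
    vals = table.loc[table["time_h"] == time, "cortisol_ng_ml"].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError(f"no rows at time_h == {time}")
    if vals.size == 1:
        return BaselineSummary(mean=float(vals[0]), sd=0.0, n=1, sd_defined=False)
    return BaselineSummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n=int(vals.size),
        sd_defined=True,
    )
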