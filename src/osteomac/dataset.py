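"""Longitudinal time-course datasets: replicates, summaries, CSV I/O.

Two plain-CSV dialects are supported:

* long form — columns ``time_days, variable, replicate, value`` (one row per
  animal per variable per time point);
* summary form — columns ``time_days, variable, mean, sd``.

The default study design observes 8 variables at days 0, 1, 2, 3, 7, 14.
Baseline (day 0) means provide initial conditions; the five post-baseline
time points contribute the 8 x 5 = 40 residual cells used by the fitting
objectives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .state import OBSERVED_VARIABLES

LONG_COLUMNS = ("time_days", "variable", "replicate", "value")
SUMMARY_COLUMNS = ("time_days", "variable", "mean", "sd")


@dataclass
class TimeCourseDataset:
    """Observed variables x time points, with optional replicate values.

    ``means`` and ``sds`` are DataFrames indexed by time (days) with one
    column per observed variable.  ``replicates`` is the long-form frame or
    None when only summaries are available.
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    replicates: pd.DataFrame | None = None

    def __post_init__(self):
        if list(self.means.columns) != list(self.sds.columns):
            raise DataError("means and sds must have identical variable columns")
        if not np.array_equal(self.means.index.to_numpy(), self.sds.index.to_numpy()):
            raise DataError("means and sds must have identical time indices")
        bad = set(self.means.columns) - set(OBSERVED_VARIABLES)
        if bad:
            raise DataError(f"unknown variable name(s): {sorted(bad)}; "
                            f"expected a subset of {OBSERVED_VARIABLES}")
        if self.means.index[0] != 0:
            raise DataError("dataset must include a baseline time point at day 0")
        post = self.sds.loc[self.sds.index > 0]
        zero = np.argwhere(~(post.to_numpy() > 0))
        if zero.size:
            i, j = zero[0]
            raise DataError(
                "post-baseline standard deviations must be > 0; offending cell: "
                f"variable {post.columns[j]!r} at day {post.index[i]}"
            )

    # -- structure ---------------------------------------------------------

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.means.columns)

    @property
    def times(self) -> np.ndarray:
        return self.means.index.to_numpy(dtype=float)

    @property
    def post_times(self) -> np.ndarray:
        """Post-baseline times contributing residual cells."""
        t = self.times
        return t[t > 0]

    @property
    def n_residual_cells(self) -> int:
        return len(self.post_times) * len(self.variables)

    def baseline_means(self) -> dict[str, float]:
        return {v: float(self.means.loc[0, v]) for v in self.variables}

    # -- I/O ----------------------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        if self.replicates is None:
            raise DataError("dataset carries no replicate-level values")
        return self.replicates.copy()

    def to_summary_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.times:
            for v in self.variables:
                rows.append({"time_days": t, "variable": v,
                             "mean": self.means.loc[t, v], "sd": self.sds.loc[t, v]})
        return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))

    def write_csv(self, path, form: str = "long") -> None:
        if form == "long":
            df = self.to_long_frame()
        elif form == "summary":
            df = self.to_summary_frame()
        else:
            raise DataError(f"form must be 'long' or 'summary', got {form!r}")
        df.to_csv(path, index=False, float_format="%.17g")

    def __eq__(self, other):
        if not isinstance(other, TimeCourseDataset):
            return NotImplemented
        same = (self.means.equals(other.means) and self.sds.equals(other.sds))
        if self.replicates is None or other.replicates is None:
            return same and (self.replicates is None) == (other.replicates is None)
        return same and self.replicates.reset_index(drop=True).equals(
            other.replicates.reset_index(drop=True))


def summarize_replicates(long_df: pd.DataFrame, sd_floor: float = 1e-6,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell sample means and SDs (n-1 denominator) from long-form data.

    Cells with zero spread get ``sd_floor`` and a warning: a zero SD would
    make the standardized residual undefined.
    """
    grouped = long_df.groupby(["time_days", "variable"])["value"]
    counts = grouped.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise DataError(
            f"at least 2 replicates required per cell to estimate an SD; "
            f"cell {bad} has {int(counts.min())}"
        )
    means = grouped.mean().unstack("variable")
    sds = grouped.std(ddof=1).unstack("variable")
    order = [v for v in OBSERVED_VARIABLES if v in means.columns]
    means, sds = means[order], sds[order]
    n_zero = int((sds.to_numpy() <= 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} cell(s) had zero sample SD; replaced by floor {sd_floor}",
            stacklevel=2,
        )
        sds = sds.mask(sds <= 0, sd_floor)
    return means, sds


def dataset_from_long(long_df: pd.DataFrame, sd_floor: float = 1e-6) -> TimeCourseDataset:
    """Build a dataset (with summaries) from a long-form replicate frame."""
    long_df = long_df.astype({"time_days": float, "replicate": int, "value": float})
    _validate_long(long_df)
    means, sds = summarize_replicates(long_df, sd_floor=sd_floor)
    return TimeCourseDataset(means=means, sds=sds,
                             replicates=long_df.reset_index(drop=True))


def dataset_from_summary(summary_df: pd.DataFrame) -> TimeCourseDataset:
    missing = set(SUMMARY_COLUMNS) - set(summary_df.columns)
    if missing:
        raise DataError(f"summary CSV missing column(s): {sorted(missing)}")
    summary_df = summary_df.astype({"time_days": float, "mean": float, "sd": float})
    dup = summary_df.duplicated(subset=["time_days", "variable"])
    if dup.any():
        row = summary_df[dup].iloc[0]
        raise DataError(f"duplicate (time, variable) key: "
                        f"({row['time_days']}, {row['variable']})")
    if (summary_df["sd"] < 0).any():
        row = summary_df[summary_df["sd"] < 0].iloc[0]
        raise DataError(f"negative SD for variable {row['variable']!r} "
                        f"at day {row['time_days']}")
    means = summary_df.pivot(index="time_days", columns="variable", values="mean")
    sds = summary_df.pivot(index="time_days", columns="variable", values="sd")
    order = [v for v in OBSERVED_VARIABLES if v in means.columns]
    return TimeCourseDataset(means=means[order], sds=sds[order])


def _validate_long(long_df: pd.DataFrame) -> None:
    missing = set(LONG_COLUMNS) - set(long_df.columns)
    if missing:
        raise DataError(f"long CSV missing column(s): {sorted(missing)}")
    dup = long_df.duplicated(subset=["time_days", "variable", "replicate"])
    if dup.any():
        row = long_df[dup].iloc[0]
        raise DataError(
            "duplicate (time, variable, replicate) key: "
            f"({row['time_days']}, {row['variable']}, {row['replicate']})"
        )
    bad = set(long_df["variable"].unique()) - set(OBSERVED_VARIABLES)
    if bad:
        raise DataError(f"unknown variable name(s): {sorted(bad)}")


def read_dataset(path) -> TimeCourseDataset:
    """Read a dataset CSV, dispatching on its columns (long or summary form)."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    if set(LONG_COLUMNS) <= cols:
        return dataset_from_long(df[list(LONG_COLUMNS)])
    if set(SUMMARY_COLUMNS) <= cols:
        return dataset_from_summary(df[list(SUMMARY_COLUMNS)])
    raise DataError(
        f"unrecognized dataset CSV: columns {sorted(cols)}; expected "
        f"{LONG_COLUMNS} (long form) or {SUMMARY_COLUMNS} (summary form)"
    )


def write_dataset(dataset: TimeCourseDataset, path, form: str | None = None) -> None:
    if form is None:
        form = "long" if dataset.replicates is not None else "summary"
    dataset.write_csv(path, form=form)
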