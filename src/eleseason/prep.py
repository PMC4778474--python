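"""Panel preparation: centering, monthly means, demographic profiles.

Turns the raw inputs — a longitudinal physiology panel, a demographic event
table, a climate table — into the 12-slot calendar-month series consumed by
the seasonality test and the lagged cross-correlation stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSeriesError,
    InsufficientDataError,
    MissingDataError,
    SchemaError,
)
from .series import MonthlySeries

log = logging.getLogger(__name__)

PANEL_COLUMNS = ("id", "month", "variable", "value")


def validate_panel(panel: pd.DataFrame) -> None:
    """Check the tidy-panel schema and basic value constraints."""
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise SchemaError(f"panel missing columns: {sorted(missing)}")
    months = panel["month"].to_numpy()
    if len(months) and (months.min() < 1 or months.max() > 12):
        raise SchemaError("panel month values must lie in 1..12")
    if not np.all(np.isfinite(panel["value"].to_numpy(dtype=float))):
        raise SchemaError("panel values must be finite")
    dup = panel.duplicated(subset=["id", "month", "variable"])
    if dup.any():
        raise SchemaError(
            f"{int(dup.sum())} duplicate (id, month, variable) observations"
        )


def _select_variable(panel: pd.DataFrame, variable: str) -> pd.DataFrame:
    validate_panel(panel)
    sub = panel[panel["variable"] == variable]
    if sub.empty:
        raise InsufficientDataError(f"no observations of variable {variable!r}")
    return sub


@dataclass
class CenteredPanel:
    """Within-individual centred observations.

    ``observations`` carries the original columns plus ``individual_mean``
    and ``value_centred`` (observed value minus the individual's own mean
    across its observed months).  ``individual_means`` maps id → mean;
    ``dropped`` lists ids excluded for having fewer than two observations.
    """

    observations: pd.DataFrame
    individual_means: pd.Series
    dropped: list[str]


def center_within_individual(
    panel: pd.DataFrame, variable: str, negate: bool = False
) -> CenteredPanel:
    """Decompose repeated measures into individual means and deviations.

    Centring isolates within-subject (seasonal) variation from stable
    between-subject differences.  The deviation convention is
    ``value − individual mean`` (so each individual's centred values sum to
    zero); pass ``negate=True`` for the opposite sign.  Individuals with a
    single observation carry no within-subject information and are dropped
    (and logged).
    """
    sub = _select_variable(panel, variable)
    counts = sub.groupby("id")["value"].size()
    dropped = sorted(counts.index[counts < 2])
    if dropped:
        log.warning(
            "centering %s: dropped %d individual(s) with < 2 observations: %s",
            variable, len(dropped), ", ".join(map(str, dropped)),
        )
    kept = sub[~sub["id"].isin(dropped)].copy()
    if kept.empty:
        raise InsufficientDataError(
            f"no individual has >= 2 observations of {variable!r}"
        )
    means = kept.groupby("id")["value"].mean()
    kept["individual_mean"] = kept["id"].map(means)
    centred = kept["value"] - kept["individual_mean"]
    kept["value_centred"] = -centred if negate else centred
    return CenteredPanel(
        observations=kept.reset_index(drop=True),
        individual_means=means,
        dropped=list(dropped),
    )


@dataclass
class GroupMeans:
    """Per-group monthly mean series and the pooled balanced mean.

    ``pooled`` is the unweighted mean of the per-group monthly means, so a
    month in which one group happens to be over-sampled is not pulled
    toward that group's level; its ``n_contributing`` counts contributing
    groups, not raw observations.
    """

    per_group: dict
    pooled: MonthlySeries
    grouping: tuple


def monthly_group_means(
    panel: pd.DataFrame,
    variable: str,
    grouping: tuple = ("sex", "age_group"),
    value_column: str = "value",
    units: str = "",
) -> GroupMeans:
    """Average a panel variable by calendar month within covariate groups."""
    sub = _select_variable(panel, variable)
    grouping = tuple(grouping)
    absent = set(grouping) - set(sub.columns)
    if absent:
        raise SchemaError(f"grouping field(s) absent from panel: {sorted(absent)}")
    if value_column not in sub.columns:
        raise SchemaError(f"value column {value_column!r} absent from panel")

    per_group: dict = {}
    keys = list(grouping) if grouping else []
    grouped = sub.groupby(keys) if keys else [((), sub)]
    for key, gdf in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        stats = gdf.groupby("month")[value_column].agg(["mean", "size"])
        values = np.full(12, np.nan)
        counts = np.zeros(12, dtype=int)
        values[stats.index.to_numpy() - 1] = stats["mean"].to_numpy()
        counts[stats.index.to_numpy() - 1] = stats["size"].to_numpy()
        label = f"{variable} " + "/".join(map(str, key)) if key else variable
        per_group[key] = MonthlySeries(label, units, values, counts)

    matrix = np.vstack([s.values for s in per_group.values()])
    n_groups = np.sum(~np.isnan(matrix), axis=0)
    pooled_values = np.full(12, np.nan)
    has_data = n_groups > 0
    pooled_values[has_data] = np.nanmean(matrix[:, has_data], axis=0)
    pooled = MonthlySeries(
        f"{variable} pooled balanced mean", units, pooled_values, n_groups
    )
    return GroupMeans(per_group=per_group, pooled=pooled, grouping=grouping)


@dataclass
class DemographicSeries:
    """Monthly profile of birth or death events across years."""

    event_type: str
    per_month_mean: MonthlySeries
    raw_counts: np.ndarray  # total events per calendar month
    total_events: int
    years_covered: int
    max_month: int | None
    min_month: int | None
    max_min_ratio: float | None  # None when undefined (no/zero-count months)


def monthly_event_profile(
    events: pd.DataFrame, event_type: str, years_covered: int | None = None
) -> DemographicSeries:
    """Mean number of events per calendar month across years.

    ``years_covered`` defaults to the span of the ``year`` column; the
    max/min month ratio quantifies demographic seasonality (it is reported
    as missing when the minimum month has zero events, never as an error).
    """
    for col in ("type", "year", "month"):
        if col not in events.columns:
            raise SchemaError(f"event table missing column {col!r}")
    sub = events[events["type"] == event_type]
    if years_covered is None:
        if events.empty:
            raise InsufficientDataError("empty event table and no years_covered given")
        years_covered = int(events["year"].max() - events["year"].min() + 1)
    if years_covered < 1:
        raise SchemaError("years_covered must be >= 1")

    counts = np.zeros(12)
    if not sub.empty:
        months = sub["month"].to_numpy(dtype=int)
        if months.min() < 1 or months.max() > 12:
            raise SchemaError("event month values must lie in 1..12")
        counts = np.bincount(months - 1, minlength=12).astype(float)
    per_month = counts / years_covered
    series = MonthlySeries(
        f"{event_type} rate", "events/year", per_month,
        np.full(12, years_covered, dtype=int),
    )
    total = int(counts.sum())
    if total == 0:
        return DemographicSeries(
            event_type, series, counts, 0, years_covered, None, None, None
        )
    max_month = int(np.argmax(counts)) + 1
    min_month = int(np.argmin(counts)) + 1
    ratio = (
        float(counts[max_month - 1] / counts[min_month - 1])
        if counts[min_month - 1] > 0
        else None
    )
    return DemographicSeries(
        event_type, series, counts, total, years_covered, max_month, min_month, ratio
    )


def zscore(series: MonthlySeries) -> MonthlySeries:
    """Standardize a monthly series to mean 0, SD 1 (sample SD, ddof = 1).

    Z-scoring puts series of different units on one scale so seasonal
    profiles can be overlaid; missing months stay missing.  Ranks — and
    hence Spearman correlations — are unchanged.
    """
    mask = series.present
    if mask.sum() < 2:
        raise InsufficientDataError("z-score needs >= 2 non-missing months")
    vals = series.values[mask]
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise DegenerateSeriesError(f"series {series.label!r} has zero variance")
    out = np.full(12, np.nan)
    out[mask] = (vals - vals.mean()) / sd
    return MonthlySeries(
        f"{series.label} (z)", "z", out, series.n_contributing.copy()
    )


def pct_diff(series: MonthlySeries, month_a: int, month_b: int) -> float:
    """Percent difference of month ``a`` relative to month ``b``.

    Returns ``100 · (value[a] − value[b]) / value[b]``; e.g. +83.6 means
    month *a* is 83.6 % higher than the reference month *b*.
    """
    va, vb = series.value(month_a), series.value(month_b)
    if np.isnan(va) or np.isnan(vb):
        raise MissingDataError(
            f"month {month_a if np.isnan(va) else month_b} is missing"
        )
    if vb == 0:
        raise ZeroDivisionError(f"reference month {month_b} has value 0")
    return 100.0 * (va - vb) / vb
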