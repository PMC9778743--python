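"""Weekly panel assembly: behavior index + emotion indices, standardization,
and the pairwise Pearson correlation screen.

The behavior series is a Google-Trends-style relative index on a 0-100
scale (period maximum standardized to 100).  It is aligned with the
weekly emotion series into a fixed-column panel
[behavior, <emotions...>], which is the data of the vector
autoregression downstream.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateColumnError, GapError, TrendsLoadError
from .scoring import WeeklyEmotionSeries

__all__ = [
    "BehaviorSeries",
    "WeeklyPanel",
    "CorrelationResult",
    "read_trends_csv",
    "assemble_weekly_panel",
    "standardize_panel",
    "pearson_correlation",
    "correlation_screen",
]


@dataclass(frozen=True)
class BehaviorSeries:
    """0-100 relative index keyed by period start date (daily or weekly)."""

    values: pd.Series  # index: date, strictly increasing; values in [0, 100]
    granularity: str  # "daily" | "weekly"

    def __post_init__(self):
        if self.granularity not in ("daily", "weekly"):
            raise TrendsLoadError(f"unknown granularity {self.granularity!r}")
        v = self.values
        if ((v < 0) | (v > 100)).any():
            raise TrendsLoadError("behavior values must lie in [0, 100]")
        if not v.index.is_monotonic_increasing or v.index.has_duplicates:
            raise TrendsLoadError("behavior periods must be strictly increasing")


def read_trends_csv(path: str | Path) -> BehaviorSeries:
    """Read a Google-Trends-style CSV of a 0-100 index.

    Leading metadata lines are skipped until a header whose first cell is
    ``Day`` or ``Week``; subsequent rows are ``date,value`` with value an
    integer in [0, 100] or the literal ``<1`` (stored as 0.5).
    """
    path = Path(path)
    if not path.exists():
        raise TrendsLoadError(f"trends file not found: {path}")
    lines = path.read_text(encoding="utf-8").splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        first = line.split(",")[0].strip().lower()
        if first in ("day", "week", "date"):
            header_idx = i
            break
    if header_idx is None:
        raise TrendsLoadError("no 'Day,...' or 'Week,...' header found")
    granularity = "daily" if lines[header_idx].split(",")[0].strip().lower() == "day" else "weekly"

    dates: list[dt.date] = []
    vals: list[float] = []
    for rownum, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 2:
            raise TrendsLoadError(f"row {rownum}: expected 'date,value'")
        try:
            d = dt.date.fromisoformat(parts[0])
        except ValueError:
            raise TrendsLoadError(f"row {rownum}: unparseable date {parts[0]!r}") from None
        raw = parts[1]
        if raw == "<1":
            v = 0.5
        else:
            try:
                v = float(raw)
            except ValueError:
                raise TrendsLoadError(f"row {rownum}: unparseable value {raw!r}") from None
        if not (0.0 <= v <= 100.0):
            raise TrendsLoadError(f"row {rownum}: value {v} outside [0, 100]")
        if dates and d <= dates[-1]:
            raise TrendsLoadError(f"row {rownum}: duplicate or out-of-order period {d}")
        dates.append(d)
        vals.append(v)
    if not dates:
        raise TrendsLoadError("trends file contains no data rows")
    series = pd.Series(vals, index=pd.Index(dates, name="period"), dtype=float)
    return BehaviorSeries(values=series, granularity=granularity)


@dataclass(frozen=True)
class WeeklyPanel:
    """Aligned weekly matrix [behavior, emotions...] for the VAR.

    ``data`` is indexed by week 0..T-1 with a fixed, recorded column
    order; ``provenance`` records start date, sources and whether the
    columns have been standardized.
    """

    data: pd.DataFrame
    start_date: dt.date
    standardized: bool = False
    provenance: dict = field(default_factory=dict)

    @property
    def T(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def __post_init__(self):
        if self.data.isna().any().any():
            raise GapError(int(self.data.isna().any(axis=1).idxmax()), "panel")
        if self.standardized:
            means = self.data.mean()
            sds = self.data.std(ddof=1)
            if (means.abs() > 1e-9).any() or ((sds - 1).abs() > 1e-9).any():
                raise DegenerateColumnError(
                    "standardized flag set but columns are not mean-0 / sd-1")


def assemble_weekly_panel(
    emotions: WeeklyEmotionSeries,
    behavior: BehaviorSeries,
    start_date: dt.date,
    n_weeks: int,
    behavior_name: str = "behavior",
) -> WeeklyPanel:
    """Align weekly emotion indices with the behavior index.

    A daily behavior series is averaged over the same 7-day blocks as
    the emotions (the index is a relative volume, not a count, so block
    means — not sums — are the natural weekly reduction).  Any requested
    week absent from either source raises :class:`GapError`.
    """
    cols: dict[str, list[float]] = {behavior_name: []}
    for m in emotions.emotions:
        cols[m] = []

    bvals = behavior.values
    offsets = np.array(
        [(d - start_date).days for d in bvals.index], dtype=int)
    for w in range(n_weeks):
        if behavior.granularity == "weekly":
            mask = offsets == 7 * w
        else:
            mask = (offsets >= 7 * w) & (offsets <= 7 * w + 6)
        if not mask.any():
            raise GapError(w, "behavior")
        cols[behavior_name].append(float(bvals.values[mask].mean()))
        if w >= len(emotions.data):
            raise GapError(w, "emotions")
        for m in emotions.emotions:
            cols[m].append(float(emotions.data[m].iloc[w]))

    df = pd.DataFrame(cols)
    df.index.name = "week"
    prov = {
        "start_date": start_date.isoformat(),
        "n_weeks": n_weeks,
        "behavior_granularity": behavior.granularity,
        "standardized": False,
    }
    return WeeklyPanel(data=df, start_date=start_date, standardized=False,
                       provenance=prov)


def standardize_panel(panel: WeeklyPanel) -> WeeklyPanel:
    """Center each column and scale to unit sample standard deviation.

    The sample standard deviation uses denominator T - 1.  Constant
    columns raise :class:`DegenerateColumnError`.
    """
    if panel.T < 2:
        raise DegenerateColumnError("need T >= 2 to standardize")
    sds = panel.data.std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise DegenerateColumnError(
            f"constant column(s): {', '.join(zero.index)}")
    data = (panel.data - panel.data.mean()) / sds
    prov = dict(panel.provenance)
    prov["standardized"] = True
    return WeeklyPanel(data=data, start_date=panel.start_date,
                       standardized=True, provenance=prov)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of two panel columns with its two-sided p-value."""

    col_a: str
    col_b: str
    r: float
    p_value: float
    n: int


def pearson_correlation(panel: WeeklyPanel, col_a: str, col_b: str) -> CorrelationResult:
    """Sample Pearson r with a two-sided t test on n - 2 degrees of freedom."""
    for c in (col_a, col_b):
        if c not in panel.data.columns:
            raise KeyError(f"column {c!r} not in panel")
    x = panel.data[col_a].to_numpy()
    y = panel.data[col_b].to_numpy()
    n = len(x)
    if n < 3:
        raise DegenerateColumnError("need T >= 3 for a correlation test")
    if np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0:
        raise DegenerateColumnError("zero-variance column in correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(col_a=col_a, col_b=col_b, r=r, p_value=p, n=n)


def correlation_screen(
    panel: WeeklyPanel, behavior_name: str = "behavior"
) -> list[CorrelationResult]:
    """Correlate every emotion column against the behavior column."""
    return [
        pearson_correlation(panel, m, behavior_name)
        for m in panel.columns if m != behavior_name
    ]
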