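"""Race-tube and conidium phenotype analysis.

Race tubes record linear growth along an agar tube: the growth front
is marked every 24 h, and conidiation bands are laid down periodically.
Positions along the tube map to times by piecewise-linear interpolation
between the 24 h marks, so the period is read out as the growth time
between adjacent band centers — robust to day-to-day changes in growth
speed.

Microconidia are classified by the morphometric criterion used at the
hemocytometer: a conidium with length/width ratio strictly below 1.5
counts as a microconidium (they are nearly round); everything else is
a macroconidium.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RaceTubeRecord",
    "ConidiumMeasure",
    "position_to_time",
    "band_periods",
    "daily_growth",
    "relative_growth",
    "growth_ratio",
    "is_microconidium",
    "microconidia_proportion",
    "condition_correlation",
    "two_sample_test",
    "significance_stars",
    "MICROCONIDIUM_RATIO_MAX",
    "MARK_INTERVAL_H",
]

#: aspect-ratio threshold: length/width < 1.5 (strict) is a microconidium
MICROCONIDIUM_RATIO_MAX = 1.5
#: growth front is marked every 24 h from inoculation
MARK_INTERVAL_H = 24.0


@dataclass(frozen=True)
class RaceTubeRecord:
    """One race tube: growth-front marks at 24 h intervals plus
    conidiation band centers, both in mm from the inoculation end."""

    mark_positions: tuple[float, ...]
    band_positions: tuple[float, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        marks = tuple(float(m) for m in self.mark_positions)
        bands = tuple(float(b) for b in self.band_positions)
        object.__setattr__(self, "mark_positions", marks)
        object.__setattr__(self, "band_positions", bands)
        if len(marks) < 2:
            raise ValueError("need at least 2 growth marks")
        if not all(a < b for a, b in zip(marks, marks[1:])):
            raise ValueError("mark positions must be strictly increasing")
        if not all(a < b for a, b in zip(bands, bands[1:])):
            raise ValueError("band positions must be strictly increasing")
        for b in bands:
            if not marks[0] <= b <= marks[-1]:
                raise ValueError(
                    f"band at {b} mm lies outside the marked range "
                    f"[{marks[0]}, {marks[-1]}] mm"
                )

    # -- CSV dialect: section-tagged rows ------------------------------
    def to_csv(self, path_or_buf=None):
        rows = [("condition", self.condition)]
        rows += [("mark", m) for m in self.mark_positions]
        rows += [("band", b) for b in self.band_positions]
        df = pd.DataFrame(rows, columns=["row_type", "position_mm"])
        return df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "RaceTubeRecord":
        df = pd.read_csv(path_or_buf)
        if list(df.columns) != ["row_type", "position_mm"]:
            raise ValueError("expected columns row_type, position_mm")
        cond = df.loc[df.row_type == "condition", "position_mm"]
        return cls(
            mark_positions=tuple(df.loc[df.row_type == "mark", "position_mm"].astype(float)),
            band_positions=tuple(df.loc[df.row_type == "band", "position_mm"].astype(float)),
            condition=str(cond.iloc[0]) if len(cond) else "",
        )


@dataclass(frozen=True)
class ConidiumMeasure:
    """Length and width of one conidium (µm)."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.width > 0):
            raise ValueError("conidium dimensions must be > 0")

    @property
    def aspect_ratio(self) -> float:
        return self.length / self.width


def position_to_time(record: RaceTubeRecord, position: float) -> float:
    """Time (h) at which the growth front reached ``position`` (mm).

    Piecewise-linear between the 24 h marks: between marks j and j+1,
    t = 24*j + 24*(position - p_j)/(p_{j+1} - p_j).
    """
    marks = np.asarray(record.mark_positions)
    if not marks[0] <= position <= marks[-1]:
        raise ValueError(
            f"position {position} mm outside marked range [{marks[0]}, {marks[-1]}]"
        )
    j = int(np.searchsorted(marks, position, side="right")) - 1
    j = min(j, len(marks) - 2)
    return MARK_INTERVAL_H * (j + (position - marks[j]) / (marks[j + 1] - marks[j]))


@dataclass(frozen=True)
class PeriodSummary:
    periods: tuple[float, ...]
    mean: float | None
    sd: float | None
    defined: bool


def band_periods(record: RaceTubeRecord) -> PeriodSummary:
    """Growth times between adjacent conidiation bands.

    Positions enter only through ratios of inter-mark distances, so the
    result is invariant to a uniform rescaling of all positions.
    """
    if len(record.band_positions) < 2:
        return PeriodSummary((), None, None, False)
    times = np.array([position_to_time(record, b) for b in record.band_positions])
    periods = np.diff(times)
    return PeriodSummary(tuple(float(p) for p in periods),
                         float(periods.mean()), float(periods.std()), True)


def daily_growth(record: RaceTubeRecord) -> np.ndarray:
    """Growth per 24 h interval (mm/day): successive mark differences."""
    return np.diff(np.asarray(record.mark_positions))


def relative_growth(record: RaceTubeRecord, reference: RaceTubeRecord) -> float:
    """Mean daily growth normalized to a reference condition
    (conventionally LD12:12)."""
    ref = daily_growth(reference).mean()
    if ref == 0:
        raise ValueError("reference record has zero growth")
    return float(daily_growth(record).mean() / ref)


def growth_ratio(record_a: RaceTubeRecord, record_b: RaceTubeRecord) -> float | None:
    """Ratio of mean daily growth a/b; None (undefined) if b has zero growth."""
    gb = daily_growth(record_b).mean()
    if gb == 0:
        return None
    return float(daily_growth(record_a).mean() / gb)


def is_microconidium(m: ConidiumMeasure) -> bool:
    """True iff length/width < 1.5 (strict: ratio exactly 1.5 is a
    macroconidium)."""
    return m.aspect_ratio < MICROCONIDIUM_RATIO_MAX


def microconidia_proportion(measures) -> float | None:
    """Microconidia count over total count; None for an empty set."""
    measures = list(measures)
    if not measures:
        return None
    return sum(is_microconidium(m) for m in measures) / len(measures)


def significance_stars(p: float) -> str:
    """Significance labels: * p<=0.05, ** p<=0.01, *** p<=0.001, else ns."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def condition_correlation(cycle_lengths, values, method: str = "pearson"):
    """Correlation between LD cycle length and a phenotype value.

    Pearson by default (``method='spearman'`` gives the rank-based
    alternative).  Returns ``(r, p)``; ``(None, None)`` if either input
    has zero variance, where the coefficient is undefined.
    """
    x = np.asarray(cycle_lengths, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        return None, None
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


def two_sample_test(a, b) -> tuple[float, str]:
    """Two-sided two-sample Student's t test with star label."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    _, p = stats.ttest_ind(a, b)
    return float(p), significance_stars(float(p))
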