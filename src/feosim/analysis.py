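"""Quantification of activity records: binning, actograms, waveforms,
FAA ratios, bout detection, free-running-period regression and periodograms.

All operations act on an :class:`ActivityRecord` — time-binned activity
counts — so simulated and empirically recorded activity are analyzed by
the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .model import ActivitySeries
from .schedules import FeedingProtocol

__all__ = [
    "ActivityRecord",
    "ActogramRaster",
    "BoutEstimate",
    "PeriodFit",
    "FaaRatio",
    "PeriodogramResult",
    "bin_activity",
    "running_average",
    "make_actogram",
    "fold_modulo",
    "faa_ratio",
    "detect_bouts",
    "estimate_period",
    "chi_square_periodogram",
    "lomb_scargle",
    "persisting_bout_periods",
]


@dataclass
class ActivityRecord:
    """Time-binned activity counts.

    ``counts[k]`` covers the half-open interval
    ``[start + k*bin_width, start + (k+1)*bin_width)`` (bin width in
    minutes, ``start`` in hours since the protocol origin).
    """

    bin_width: float  # minutes
    counts: np.ndarray
    start: float = 0.0  # hours

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size == 0:
            raise ValueError("record must contain at least one bin")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and non-negative")

    @property
    def bin_width_h(self) -> float:
        return self.bin_width / 60.0

    @property
    def times(self) -> np.ndarray:
        """Left edges of the bins, in hours."""
        return self.start + np.arange(self.counts.size) * self.bin_width_h

    @property
    def centers(self) -> np.ndarray:
        return self.times + 0.5 * self.bin_width_h

    @property
    def span(self) -> float:
        """Total record length in hours."""
        return self.counts.size * self.bin_width_h

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# bin_width_min={self.bin_width:g}\n")
            pd.DataFrame({"time_h": self.times, "count": self.counts}).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ActivityRecord":
        path = Path(path)
        bin_width = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "bin_width_min=" in first:
            bin_width = float(first.split("bin_width_min=")[1])
        df = pd.read_csv(path, comment="#")
        if "time_h" not in df or "count" not in df:
            raise ValueError(f"{path}: expected columns time_h, count")
        t = df["time_h"].to_numpy(dtype=float)
        if bin_width is None:
            if t.size < 2:
                raise ValueError(f"{path}: cannot infer bin width from a single row")
            bin_width = float(np.median(np.diff(t)) * 60.0)
        return cls(bin_width=bin_width, counts=df["count"].to_numpy(dtype=float), start=float(t[0]))


@dataclass
class ActogramRaster:
    """Raster representation of a record: one row per day, quantized bar
    heights 0–5 (0 = no activity, 1–5 = quintile rank)."""

    day_length: float  # hours
    rows: np.ndarray  # (n_days, bins_per_day) ints in 0..5
    bin_width: float  # minutes
    double_plotted: bool = False

    def to_csv(self, path) -> None:
        pd.DataFrame(self.rows).to_csv(path, index=False, header=False)


@dataclass
class BoutEstimate:
    """A detected activity bout; ``center`` is the phase marker regressed
    against cycle number to estimate the free-running period."""

    onset: float  # hours
    end: float  # hours
    center: float  # hours
    cycle_index: int

    def __post_init__(self) -> None:
        if self.end <= self.onset:
            raise ValueError("bout end must exceed onset")


@dataclass
class PeriodFit:
    """OLS fit of bout center (h) against cycle index: slope = period."""

    period: float
    intercept: float
    r_squared: float
    n_bouts: int


@dataclass
class FaaRatio:
    """Pre-meal activity as a proportion of daily or intermeal activity."""

    mealtime_tag: str
    meal_start: float
    window: float  # hours of pre-meal span
    ratio: float
    denominator_mode: str  # whole_day | intermeal
    degenerate: bool = False  # True when the denominator was zero


@dataclass
class PeriodogramResult:
    periods: np.ndarray  # hours (chi-square) — or 1/frequencies for LS
    power: np.ndarray
    significance: np.ndarray | None  # per-period 0.05 line (chi-square only)
    peak_period: float


def bin_activity(source, bin_width: float = 10.0, span: float | None = None) -> ActivityRecord:
    """Bin an :class:`~feosim.model.ActivitySeries` (bin mean) or raw event
    times in hours (bin count) into an :class:`ActivityRecord`.

    ``bin_width`` is in minutes.  For event input the total count is
    preserved; events beyond ``span`` (if given) are dropped.
    """
    bw_h = bin_width / 60.0
    if isinstance(source, ActivitySeries):
        t, v = source.times, source.activity
        if t.size == 0:
            raise ValueError("empty activity series")
        n = int(np.floor((t[-1] - t[0]) / bw_h + 1e-9)) + 1
        idx = np.minimum(((t - t[0]) / bw_h + 1e-9).astype(int), n - 1)
        sums = np.bincount(idx, weights=v, minlength=n)
        cnts = np.bincount(idx, minlength=n)
        counts = np.divide(sums, cnts, out=np.zeros(n), where=cnts > 0)
        return ActivityRecord(bin_width=bin_width, counts=counts, start=float(t[0]))
    events = np.asarray(source, dtype=float)
    if events.size == 0:
        raise ValueError("empty event list")
    end = span if span is not None else events.max() + bw_h
    n = int(np.ceil(end / bw_h))
    events = events[events < end]
    idx = (events / bw_h).astype(int)
    counts = np.bincount(idx, minlength=n)
    return ActivityRecord(bin_width=bin_width, counts=counts.astype(float), start=0.0)


def running_average(record: ActivityRecord, window: float = 40.0) -> ActivityRecord:
    """Centered running mean over ``window`` minutes.

    Edges use shrinking centered windows, preserving record length.  For an
    even number of bins the window covers ``[i - w//2, i + (w-1)//2]``.
    """
    if window < record.bin_width:
        raise ValueError("smoothing window must be at least one bin wide")
    w = max(int(round(window / record.bin_width)), 1)
    left = w // 2
    right = w - 1 - left
    x = record.counts
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    i = np.arange(n)
    lo = np.maximum(i - left, 0)
    hi = np.minimum(i + right, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return ActivityRecord(bin_width=record.bin_width, counts=smoothed, start=record.start)


def _quintile_ranks(counts: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map counts to 0 (zero activity) or quintile rank 1–5 of the nonzero
    reference distribution."""
    ranks = np.zeros(counts.shape, dtype=int)
    nz_ref = reference[reference > 0]
    nz = counts > 0
    if nz_ref.size == 0:
        return ranks
    qs = np.quantile(nz_ref, [0.2, 0.4, 0.6, 0.8])
    ranks[nz] = np.searchsorted(qs, counts[nz], side="left") + 1
    return ranks


def make_actogram(
    record: ActivityRecord,
    day_length: float = 24.0,
    double_plotted: bool = False,
    per_day_scaling: bool = False,
) -> ActogramRaster:
    """Quantize a record into the standard raster format.

    Each row is one ``day_length`` period; nonzero bins are ranked into
    quintiles of the whole record's nonzero-count distribution (or of each
    day's, with ``per_day_scaling``).  ``double_plotted`` concatenates day
    d and day d+1 on every row.
    """
    bins_per_day = day_length / record.bin_width_h
    if abs(bins_per_day - round(bins_per_day)) > 1e-9:
        raise ValueError("day_length must be an integer number of bins")
    bins_per_day = int(round(bins_per_day))
    n_days = record.counts.size // bins_per_day
    if n_days < 1:
        raise ValueError("record shorter than one day")
    data = record.counts[: n_days * bins_per_day].reshape(n_days, bins_per_day)
    if per_day_scaling:
        rows = np.vstack([_quintile_ranks(r, r) for r in data])
    else:
        rows = _quintile_ranks(data, data.ravel())
    if double_plotted:
        nxt = np.vstack([rows[1:], np.zeros((1, bins_per_day), dtype=int)])
        rows = np.hstack([rows, nxt])
    return ActogramRaster(
        day_length=day_length, rows=rows, bin_width=record.bin_width, double_plotted=double_plotted
    )


def fold_modulo(record: ActivityRecord, period: float, n_cycles: int | None = None):
    """Average the record modulo ``period``: bins at equal phase
    (t mod period) are averaged across cycles.

    Returns ``(phase_hours, mean, sem)``; requires at least two complete
    cycles.
    """
    bins_per_cycle = period / record.bin_width_h
    if abs(bins_per_cycle - round(bins_per_cycle)) > 1e-9:
        raise ValueError("period must be an integer number of bins")
    bins_per_cycle = int(round(bins_per_cycle))
    avail = record.counts.size // bins_per_cycle
    cycles = avail if n_cycles is None else min(n_cycles, avail)
    if cycles < 2:
        raise ValueError("need at least 2 complete cycles to fold")
    data = record.counts[: cycles * bins_per_cycle].reshape(cycles, bins_per_cycle)
    mean = data.mean(axis=0)
    sem = data.std(axis=0, ddof=1) / np.sqrt(cycles)
    phase = np.arange(bins_per_cycle) * record.bin_width_h
    return phase, mean, sem


def _activity_between(record: ActivityRecord, t0: float, t1: float) -> float:
    """Sum of counts over [t0, t1), apportioning partial bins linearly."""
    bw = record.bin_width_h
    lo = (t0 - record.start) / bw
    hi = (t1 - record.start) / bw
    lo = max(lo, 0.0)
    hi = min(hi, record.counts.size)
    if hi <= lo:
        return 0.0
    i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
    total = record.counts[i0:i1].sum()
    total -= record.counts[i0] * (lo - i0)
    if i1 - 1 < record.counts.size:
        total -= record.counts[i1 - 1] * (i1 - hi)
    return float(total)


def faa_ratio(
    record: ActivityRecord,
    protocol: FeedingProtocol,
    window: float = 2.0,
    denominator_mode: str = "whole_day",
) -> list[FaaRatio]:
    """Food-anticipation ratio for every meal covered by the record.

    The numerator is the activity in the ``window`` hours preceding the
    meal.  With ``denominator_mode="whole_day"`` the denominator is the
    day's total activity excluding activity during meal windows; with
    ``"intermeal"`` it is the activity since the end of the previous meal.
    A zero denominator yields ratio 0 with ``degenerate=True``.
    """
    if denominator_mode not in ("whole_day", "intermeal"):
        raise ValueError("denominator_mode must be 'whole_day' or 'intermeal'")
    if window <= 0:
        raise ValueError("window must be > 0")
    t_end = record.start + record.span
    meals = [e for e in protocol.events if record.start <= e.start and e.end <= t_end]
    out: list[FaaRatio] = []
    for i, meal in enumerate(meals):
        prev = meals[i - 1] if i > 0 else None
        if prev is not None and meal.start - window < prev.end:
            raise ValueError(
                f"FAA window before meal at {meal.start} h overlaps the previous "
                f"meal ending at {prev.end} h"
            )
        numer = _activity_between(record, meal.start - window, meal.start)
        if denominator_mode == "whole_day":
            day0 = np.floor(meal.start / 24.0) * 24.0
            denom = _activity_between(record, max(day0, record.start), min(day0 + 24.0, t_end))
            for m in meals:
                if m.end > day0 and m.start < day0 + 24.0:
                    denom -= _activity_between(record, max(m.start, day0), min(m.end, day0 + 24.0))
        else:
            lo = prev.end if prev is not None else max(meal.start - 24.0, record.start)
            denom = _activity_between(record, lo, meal.start)
        degenerate = denom <= 0
        out.append(
            FaaRatio(
                mealtime_tag=meal.tag,
                meal_start=meal.start,
                window=window,
                ratio=0.0 if degenerate else numer / denom,
                denominator_mode=denominator_mode,
                degenerate=degenerate,
            )
        )
    return out


def detect_bouts(
    record: ActivityRecord,
    search_windows: list[tuple[float, float]],
    smoothing: float = 40.0,
    onset_frac: float = 0.2,
    offset_frac: float = 0.2,
    min_peak: float = 0.0,
    persistence_bins: int = 3,
    center: str = "midpoint",
    cycle_indices: list[int] | None = None,
) -> list[BoutEstimate]:
    """Threshold-on-smoothed-signal bout detection.

    Within each search window, on the record smoothed over ``smoothing``
    minutes: the onset is the first bin whose value exceeds
    ``onset_frac`` × the window peak and stays above it for at least
    ``persistence_bins`` bins; the end is the last bin above
    ``offset_frac`` × peak.  Windows whose peak does not exceed
    ``min_peak`` yield no bout.  ``center`` is the onset–end midpoint or,
    with ``center="centroid"``, the activity-weighted mean time.
    """
    ws = sorted(search_windows)
    for (a0, a1), (b0, b1) in zip(ws, ws[1:]):
        if b0 < a1:
            raise ValueError(f"search windows ({a0},{a1}) and ({b0},{b1}) overlap")
    if center not in ("midpoint", "centroid"):
        raise ValueError("center must be 'midpoint' or 'centroid'")
    smoothed = running_average(record, smoothing) if smoothing >= record.bin_width else record
    t = smoothed.centers
    bouts: list[BoutEstimate] = []
    if cycle_indices is None:
        cycle_indices = list(range(len(search_windows)))
    for cyc, (w0, w1) in zip(cycle_indices, search_windows):
        mask = (t >= w0) & (t < w1)
        if not mask.any():
            continue
        x = smoothed.counts[mask]
        tt = t[mask]
        peak = x.max()
        if not peak > min_peak:
            continue
        above_on = x > onset_frac * peak
        onset_i = None
        run = 0
        for k, flag in enumerate(above_on):
            run = run + 1 if flag else 0
            if run >= min(persistence_bins, x.size):
                onset_i = k - run + 1
                break
        if onset_i is None:
            continue
        above_off = np.nonzero(x > offset_frac * peak)[0]
        end_i = int(above_off[-1])
        if end_i <= onset_i:
            end_i = onset_i + 1 if onset_i + 1 < x.size else onset_i
        onset_t = float(tt[onset_i])
        end_t = float(tt[end_i])
        if end_t <= onset_t:
            end_t = onset_t + smoothed.bin_width_h
        if center == "midpoint":
            c = 0.5 * (onset_t + end_t)
        else:
            seg = slice(onset_i, end_i + 1)
            c = float(np.average(tt[seg], weights=np.maximum(x[seg], 1e-12)))
        bouts.append(BoutEstimate(onset=onset_t, end=end_t, center=c, cycle_index=int(cyc)))
    return bouts


def estimate_period(bouts: list[BoutEstimate]) -> PeriodFit:
    """Free-running period via OLS regression of bout center on cycle index."""
    if len(bouts) < 2 or len({b.cycle_index for b in bouts}) < 2:
        raise ValueError("need at least 2 bouts with distinct cycle indices")
    x = np.array([b.cycle_index for b in bouts], dtype=float)
    y = np.array([b.center for b in bouts])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PeriodFit(period=float(slope), intercept=float(intercept), r_squared=r2, n_bouts=len(bouts))


def chi_square_periodogram(
    record: ActivityRecord,
    period_grid: np.ndarray | None = None,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Sokolove–Bushell chi-square periodogram.

    For each trial period (an integer number of bins) the record is folded
    and Qp = Σ_h n_h (M_h − M̄)² / σ̂² computed, where M_h are the column
    means, M̄ the grand mean and σ̂² the record variance; under the null
    Qp ~ χ² with (bins-per-period − 1) degrees of freedom, giving the
    per-period significance line at ``alpha``.
    """
    bw = record.bin_width_h
    if period_grid is None:
        period_grid = np.arange(round(20 / bw), round(28 / bw) + 1) * bw
    period_grid = np.asarray(period_grid, dtype=float)
    if np.any(period_grid * 2 > record.span):
        raise ValueError("record must span at least twice the longest trial period")
    x = record.counts
    grand = x.mean()
    var = float(np.mean((x - grand) ** 2))
    qp = np.zeros(period_grid.size)
    sig = np.zeros(period_grid.size)
    for i, p in enumerate(period_grid):
        k = p / bw
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"trial period {p} h is not an integer number of bins")
        k = int(round(k))
        idx = np.arange(x.size) % k
        n_h = np.bincount(idx, minlength=k).astype(float)
        m_h = np.bincount(idx, weights=x, minlength=k) / n_h
        if var > 0:
            qp[i] = float(np.sum(n_h * (m_h - grand) ** 2) / var)
        sig[i] = _stats.chi2.ppf(1 - alpha, k - 1)
    peak = float(period_grid[int(np.argmax(qp))])
    return PeriodogramResult(periods=period_grid, power=qp, significance=sig, peak_period=peak)


def lomb_scargle(
    record: ActivityRecord,
    frequency_grid: np.ndarray | None = None,
) -> PeriodogramResult:
    """Normalized Lomb–Scargle power spectrum of a (possibly unevenly
    sampled) record; frequencies in cycles/hour."""
    if record.counts.size < 2:
        raise ValueError("need at least 2 samples")
    if frequency_grid is None:
        frequency_grid = np.linspace(1 / 30.0, 1 / 18.0, 400)
    frequency_grid = np.asarray(frequency_grid, dtype=float)
    if frequency_grid.size < 2 or np.any(frequency_grid <= 0):
        raise ValueError("frequency grid must contain positive frequencies")
    t = record.centers
    y = record.counts - record.counts.mean()
    if np.allclose(y, 0):
        power = np.zeros(frequency_grid.size)
    else:
        power = _signal.lombscargle(t, y, 2 * np.pi * frequency_grid, normalize=True)
    peak_f = float(frequency_grid[int(np.argmax(power))])
    return PeriodogramResult(
        periods=1.0 / frequency_grid, power=power, significance=None, peak_period=1.0 / peak_f
    )


def persisting_bout_periods(
    record: ActivityRecord,
    protocol: FeedingProtocol,
    tags: tuple = ("T24", "T26"),
    cycle_lengths: dict | None = None,
    window_halfwidth: float = 3.0,
    smoothing: float = 40.0,
    onset_frac: float = 0.2,
    offset_frac: float = 0.2,
    min_peak: float = 0.0,
) -> dict:
    """Free-running period of each schedule's persisting activity bout.

    For every schedule tag, search windows are centered on mealtimes
    extrapolated from the last scheduled meal at that schedule's cycle
    length (cycle 0 = the last scheduled meal itself), spanning the
    terminal deprivation segment.  Windows that would overlap a window of
    another tag — the two schedules' expected times cross during extended
    deprivation — are discarded on both sides.  Bouts are detected in the
    remaining windows and their centers regressed on cycle index.

    Returns ``{tag: PeriodFit}`` (a tag is omitted when fewer than two
    bouts are found).
    """
    if cycle_lengths is None:
        cycle_lengths = {}
    t_end = record.start + record.span
    windows: dict[str, list[tuple[int, float, float]]] = {}
    for tag in tags:
        meals = protocol.meals_with_tag(tag)
        if not meals:
            raise ValueError(f"protocol has no meals tagged {tag!r}")
        if tag in cycle_lengths:
            T = float(cycle_lengths[tag])
        elif len(meals) >= 2:
            T = float(np.median(np.diff([m.start for m in meals])))
        else:
            raise ValueError(f"cannot infer cycle length for tag {tag!r}")
        anchor = meals[-1].start
        wins = []
        k = 0
        while anchor + k * T - window_halfwidth <= t_end:
            c = anchor + k * T
            wins.append((k, c - window_halfwidth, c + window_halfwidth))
            k += 1
        windows[tag] = wins
    # drop windows that overlap a window of a different tag (the schedules'
    # expected times cross during extended deprivation and a merged bout
    # cannot be attributed to either schedule); also require the window to
    # lie fully inside the record
    kept: dict[str, list[tuple[int, float, float]]] = {tag: [] for tag in tags}
    for tag in tags:
        for k, w0, w1 in windows[tag]:
            if w0 < record.start or w1 > t_end:
                continue
            clash = any(
                o0 < w1 and w0 < o1
                for other in tags
                if other != tag
                for _, o0, o1 in windows[other]
            )
            if not clash:
                kept[tag].append((k, w0, w1))
    fits: dict[str, PeriodFit] = {}
    for tag in tags:
        if len(kept[tag]) < 2:
            continue
        bouts = detect_bouts(
            record,
            [(w0, w1) for _, w0, w1 in kept[tag]],
            smoothing=smoothing,
            onset_frac=onset_frac,
            offset_frac=offset_frac,
            min_peak=min_peak,
            cycle_indices=[k for k, _, _ in kept[tag]],
        )
        if len(bouts) >= 2 and len({b.cycle_index for b in bouts}) >= 2:
            fits[tag] = estimate_period(bouts)
    return fits
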