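"""Feeding protocols as event timelines and the binary food stimulus F(t).

A :class:`FeedingProtocol` is an ordered list of meal events (start, duration,
schedule tag) plus coarse segments describing lighting and feeding mode
(ad-lib / scheduled / deprived).  The food stimulus ``F(t)`` is 1 while any
meal is in progress and 0 otherwise; meal intervals are half-open
``[start, start + duration)`` so that ``F`` is single-valued at boundaries.

Times are in hours since the protocol origin (day 0, ZT0).  Zeitgeber time
(ZT) maps to protocol hours as ``24 * day + ZT``; during constant-dark
segments ZT labels are retained only as a notational convenience.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MealEvent",
    "ProtocolSegment",
    "FeedingProtocol",
    "food_stimulus",
    "discontinuity_times",
    "build_preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class MealEvent:
    """A single feeding opportunity.

    Parameters
    ----------
    start : float
        Hours since the protocol origin.
    duration : float
        Meal duration in hours; must be positive.
    tag : str
        Free-text schedule label, e.g. ``"T24"`` or ``"T26"``.
    """

    start: float
    duration: float
    tag: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"meal duration must be > 0, got {self.duration}")
        if self.start < 0:
            raise ValueError(f"meal start must be >= 0, got {self.start}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class ProtocolSegment:
    """A contiguous stretch of the protocol with fixed lighting and feeding mode."""

    start: float
    end: float
    lighting: str = "LD"  # LD | DD | dim
    feeding_mode: str = "scheduled"  # ad_lib | scheduled | deprived

    _LIGHTING = ("LD", "DD", "dim")
    _MODES = ("ad_lib", "scheduled", "deprived")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end ({self.end}) must exceed start ({self.start})")
        if self.lighting not in self._LIGHTING:
            raise ValueError(f"lighting must be one of {self._LIGHTING}, got {self.lighting!r}")
        if self.feeding_mode not in self._MODES:
            raise ValueError(f"feeding_mode must be one of {self._MODES}, got {self.feeding_mode!r}")


@dataclass
class FeedingProtocol:
    """Timeline of meal events and lighting/feeding segments.

    Invariants enforced at construction: events sorted by start, no exact
    duplicates, every event inside a ``scheduled`` segment, and segments
    tiling ``[0, total_duration]`` without gaps or overlap.
    """

    events: list[MealEvent]
    segments: list[ProtocolSegment]
    lights_on_offset: float = 0.0  # clock hour at which ZT0 (lights-on) falls
    name: str = ""

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.start, e.end, e.tag))
        seen = set()
        for ev in self.events:
            key = (ev.start, ev.duration, ev.tag)
            if key in seen:
                raise ValueError(f"duplicate meal event at start={ev.start}, duration={ev.duration}")
            seen.add(key)
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        self.segments = sorted(self.segments, key=lambda s: s.start)
        if self.segments[0].start != 0:
            raise ValueError("first segment must start at 0")
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.end, b.start):
                raise ValueError(f"segments must tile the timeline: gap/overlap at {a.end} vs {b.start}")
        for ev in self.events:
            if not any(
                s.feeding_mode == "scheduled" and s.start <= ev.start and ev.end <= s.end
                for s in self.segments
            ):
                raise ValueError(f"meal at {ev.start} h does not lie inside a scheduled segment")
        # merged meal intervals (logical OR of possibly overlapping schedules)
        self._merged = _merge_intervals([(e.start, e.end) for e in self.events])

    @property
    def total_duration(self) -> float:
        return self.segments[-1].end

    # --- F(t) ----------------------------------------------------------
    def food_stimulus(self, t):
        """Binary food stimulus: 1 iff ``t`` falls inside a meal interval.

        Accepts scalars or arrays; raises for times outside the protocol.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0) or np.any(t_arr > self.total_duration):
            raise ValueError(
                f"time outside protocol [0, {self.total_duration}] h: {t}"
            )
        if self._merged.size == 0:
            out = np.zeros(t_arr.shape, dtype=int)
        else:
            starts = self._merged[:, 0]
            ends = self._merged[:, 1]
            idx = np.searchsorted(starts, t_arr, side="right") - 1
            inside = (idx >= 0) & (t_arr < ends[np.clip(idx, 0, len(ends) - 1)])
            out = inside.astype(int)
        return out.item() if np.isscalar(t) or t_arr.ndim == 0 else out

    def discontinuity_times(self) -> np.ndarray:
        """Sorted, deduplicated meal starts and ends.

        ``F(t)`` is constant on every open interval between consecutive
        entries, so these are the restart points for piecewise ODE
        integration.
        """
        pts = [e.start for e in self.events] + [e.end for e in self.events]
        return np.unique(np.asarray(pts, dtype=float))

    def meals_with_tag(self, tag: str) -> list[MealEvent]:
        return [e for e in self.events if e.tag == tag]

    def deprivation_start(self) -> float | None:
        """Start of the terminal food-deprivation segment, if any."""
        for seg in reversed(self.segments):
            if seg.feeding_mode == "deprived":
                return seg.start
        return None

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lights_on_offset": self.lights_on_offset,
            "events": [asdict(e) for e in self.events],
            "segments": [asdict(s) for s in self.segments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeedingProtocol":
        return cls(
            events=[MealEvent(**e) for e in d["events"]],
            segments=[ProtocolSegment(**s) for s in d["segments"]],
            lights_on_offset=d.get("lights_on_offset", 0.0),
            name=d.get("name", ""),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path) -> "FeedingProtocol":
        """Load from YAML (JSON is a YAML subset and is accepted too)."""
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def events_to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "start_h": [e.start for e in self.events],
                "duration_h": [e.duration for e in self.events],
                "tag": [e.tag for e in self.events],
            }
        )
        df.to_csv(path, index=False)


def _merge_intervals(intervals: list[tuple[float, float]]) -> np.ndarray:
    """Union of half-open intervals, returned as an (m, 2) array."""
    if not intervals:
        return np.empty((0, 2))
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


# --- module-level functional aliases ------------------------------------

def food_stimulus(protocol: FeedingProtocol, t):
    """See :meth:`FeedingProtocol.food_stimulus`."""
    return protocol.food_stimulus(t)


def discontinuity_times(protocol: FeedingProtocol) -> np.ndarray:
    """See :meth:`FeedingProtocol.discontinuity_times`."""
    return protocol.discontinuity_times()


# --- presets ------------------------------------------------------------

def _zt(day: int, zt: float) -> float:
    return 24.0 * day + zt


def three_meal(
    days: int = 21,
    meal_zts: tuple = (2.0, 10.0, 18.0),
    meal_duration: float = 0.5,
    deprivation_h: float = 60.0,
    lights_on_offset: float = 0.0,
) -> FeedingProtocol:
    """Three fixed daily meals at 8-h intervals, then total food deprivation.

    Defaults: 21 days of 30-min meals at ZT2, ZT10 and ZT18, followed by
    60 h of deprivation in constant dark.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    events = [
        MealEvent(_zt(d, z), meal_duration, tag=f"ZT{z:g}")
        for d in range(days)
        for z in meal_zts
    ]
    sched_end = 24.0 * days
    segments = [ProtocolSegment(0.0, sched_end, "LD", "scheduled")]
    if deprivation_h > 0:
        segments.append(ProtocolSegment(sched_end, sched_end + deprivation_h, "DD", "deprived"))
    return FeedingProtocol(events, segments, lights_on_offset, name="three_meal")


def four_meal(
    days: int = 40,
    meal_zts: tuple = (3.0, 9.0, 15.0, 21.0),
    meal_duration: float = 1 / 3,
    deprivation_h: float = 48.0,
    lights_on_offset: float = 0.0,
) -> FeedingProtocol:
    """Four ~20-min daily meals at 6-h intervals (ZT3/9/15/21), then deprivation."""
    if days < 1:
        raise ValueError("days must be >= 1")
    events = [
        MealEvent(_zt(d, z), meal_duration, tag=f"ZT{z:g}")
        for d in range(days)
        for z in meal_zts
    ]
    sched_end = 24.0 * days
    segments = [ProtocolSegment(0.0, sched_end, "LD", "scheduled")]
    if deprivation_h > 0:
        segments.append(ProtocolSegment(sched_end, sched_end + deprivation_h, "DD", "deprived"))
    return FeedingProtocol(events, segments, lights_on_offset, name="four_meal")


def tcycle_single(
    period: float = 24.0,
    days: int = 15,
    first_meal_zt: float = 6.0,
    meal_duration: float = 2.0,
    deprivation_h: float = 0.0,
    lights_on_offset: float = 0.0,
) -> FeedingProtocol:
    """A single daily meal recurring every ``period`` hours (a T-cycle)."""
    if days < 1:
        raise ValueError("days must be >= 1")
    starts = first_meal_zt + period * np.arange(days)
    events = [MealEvent(float(s), meal_duration, tag=f"T{period:g}") for s in starts]
    sched_end = float(np.ceil((starts[-1] + meal_duration) / 24.0) * 24.0)
    segments = [ProtocolSegment(0.0, sched_end, "LD", "scheduled")]
    if deprivation_h > 0:
        segments.append(ProtocolSegment(sched_end, sched_end + deprivation_h, "DD", "deprived"))
    return FeedingProtocol(events, segments, lights_on_offset, name=f"tcycle_T{period:g}")


def tcycle_concurrent(
    t24_days: int = 15,
    t25_days: int = 7,
    t26_days: int = 9,
    single_meal_duration: float = 2.0,
    concurrent_days: int = 27,
    concurrent_meal_duration: float = 1.0,
    first_meal_zt: float = 6.0,
    t24_meal_zt: float = 17.0,
    deprivation_h: float = 90.0,
    lights_on_offset: float = 0.0,
) -> FeedingProtocol:
    """Single-meal T24 → T25 → T26 ramp, then concurrent T24 + T26 meals,
    then terminal food deprivation.

    Defaults follow the two-schedule experiment: 15 days of a 2-h meal at
    ZT6 (T24), 7 days with the meal delayed 1 h/day (T25), 9 days delayed
    2 h/day (T26), then 27 days with a second 1-h meal at ZT17 (T24) while
    the first meal keeps recurring every 26 h (1 h), and finally 90 h of
    deprivation in constant dark.
    """
    for nm, v in [("t24_days", t24_days), ("t25_days", t25_days), ("t26_days", t26_days),
                  ("concurrent_days", concurrent_days)]:
        if v < 0 or (nm in ("t24_days", "concurrent_days") and v < 1):
            raise ValueError(f"{nm} must be positive, got {v}")
    events: list[MealEvent] = []
    s = first_meal_zt
    for _ in range(t24_days):
        events.append(MealEvent(s, single_meal_duration, tag="T24-single"))
        s += 24.0
    s -= 24.0  # last single-T24 start
    for _ in range(t25_days):
        s += 25.0
        events.append(MealEvent(s, single_meal_duration, tag="T25"))
    for _ in range(t26_days):
        s += 26.0
        events.append(MealEvent(s, single_meal_duration, tag="T26"))
    ramp_last = s
    # second daily meal begins at the first ZT `t24_meal_zt` after the ramp ends
    d0 = int(np.floor(ramp_last / 24.0))
    if 24.0 * d0 + t24_meal_zt <= ramp_last:
        d0 += 1
    conc_end = 24.0 * (d0 + concurrent_days)
    for k in range(concurrent_days):
        events.append(MealEvent(24.0 * (d0 + k) + t24_meal_zt, concurrent_meal_duration, tag="T24"))
    k = 1
    while ramp_last + 26.0 * k + concurrent_meal_duration <= conc_end:
        events.append(MealEvent(ramp_last + 26.0 * k, concurrent_meal_duration, tag="T26"))
        k += 1
    segments = [ProtocolSegment(0.0, conc_end, "LD", "scheduled")]
    if deprivation_h > 0:
        segments.append(ProtocolSegment(conc_end, conc_end + deprivation_h, "DD", "deprived"))
    return FeedingProtocol(events, segments, lights_on_offset, name="tcycle_concurrent")


def scn_two_meal(
    two_meal_days: int = 15,
    t25_days: int = 17,
    t26_days: int = 41,
    meal_duration: float = 1.0,
    fixed_meal_hour: float = 17.0,
    delayed_meal_hour: float = 5.0,
    omit_crossing_meal: bool = True,
    deprivation_h: float = 72.0,
    lights_on_offset: float = 0.0,
) -> FeedingProtocol:
    """Two daily 1-h meals 12 h apart; one meal then delayed 1 h/day (T25)
    and 2 h/day (T26) while the other stays fixed (T24); ends in deprivation.

    The animals in this arm were SCN-ablated and kept in constant dim light,
    so meal hours are local clock times; the anchor is configurable.  One
    T26 meal is omitted (meal-omission test) on the cycle where it falls
    closest to 10 h before the fixed meal.
    """
    events: list[MealEvent] = []
    for d in range(two_meal_days):
        events.append(MealEvent(24.0 * d + fixed_meal_hour, meal_duration, tag="T24"))
        events.append(MealEvent(24.0 * d + delayed_meal_hour, meal_duration, tag="T24b"))
    s = 24.0 * (two_meal_days - 1) + delayed_meal_hour
    t26_starts = []
    for _ in range(t25_days):
        s += 25.0
        events.append(MealEvent(s, meal_duration, tag="T25"))
    for _ in range(t26_days):
        s += 26.0
        t26_starts.append(s)
    last = max(s + meal_duration, 24.0 * (two_meal_days) + fixed_meal_hour)
    n_fixed_days = int(np.ceil(s / 24.0))
    for d in range(two_meal_days, n_fixed_days):
        events.append(MealEvent(24.0 * d + fixed_meal_hour, meal_duration, tag="T24"))
    omit_idx = None
    if omit_crossing_meal:
        # gap (hours) from the T26 meal forward to the same-day fixed meal
        gaps = [((fixed_meal_hour - st) % 24.0) for st in t26_starts]
        omit_idx = int(np.argmin([abs(g - 10.0) for g in gaps]))
    for i, st in enumerate(t26_starts):
        if i == omit_idx:
            continue
        events.append(MealEvent(st, meal_duration, tag="T26"))
    sched_end = float(np.ceil(last / 24.0) * 24.0)
    segments = [ProtocolSegment(0.0, sched_end, "dim", "scheduled")]
    if deprivation_h > 0:
        segments.append(ProtocolSegment(sched_end, sched_end + deprivation_h, "DD", "deprived"))
    return FeedingProtocol(events, segments, lights_on_offset, name="scn_two_meal")


_PRESETS = {
    "three_meal": three_meal,
    "four_meal": four_meal,
    "tcycle_single": tcycle_single,
    "tcycle_concurrent": tcycle_concurrent,
    "scn_two_meal": scn_two_meal,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def build_preset(name: str, **options) -> FeedingProtocol:
    """Build one of the named experimental feeding protocols.

    ``name`` must be one of :data:`PRESET_NAMES`; keyword options override
    the default day counts, meal durations and deprivation lengths.
    """
    try:
        fn = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}") from None
    return fn(**options)
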