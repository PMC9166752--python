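"""Synthetic operant-activity records for testing the analysis pipeline.

Real records are counts of lever presses or nose-pokes per time bin: a low
Poisson background punctuated by food-anticipatory bouts that build up
over the ~2 h before each (possibly non-24-h) mealtime.  The generator
emulates this as Poisson counts whose rate is a constant background plus a
Gaussian bump repeating at the bout period.  It reproduces the count
statistics and periodicity of operant records, not their fine structure
(no meal-driven suppression, no day-to-day amplitude drift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import ActivityRecord

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic activity record.

    ``bout_amplitude`` and ``background_rate`` are expected counts per bin
    (at the bump peak and away from it, respectively); ``bout_center_phase``
    is the bump center in hours within each cycle of ``bout_period``.
    """

    n_days: float = 6.0
    bin_width: float = 10.0  # minutes
    bout_period: float = 24.0  # hours
    bout_center_phase: float = 12.0  # hours within the cycle
    bout_sd: float = 0.75  # hours
    bout_amplitude: float = 20.0  # expected counts/bin at peak
    background_rate: float = 1.0  # expected counts/bin
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_days", "bin_width", "bout_period", "bout_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bout_amplitude < 0 or self.background_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.bout_sd >= self.bout_period / 4:
            raise ValueError("bout_sd must be < bout_period / 4")


def generate_fixture(spec: FixtureSpec) -> ActivityRecord:
    """Draw a seeded Poisson record with periodic Gaussian activity bouts.

    The per-bin rate is ``background + amplitude * exp(-d²/(2·sd²))`` where
    ``d`` is the circular distance (hours) from the bin center to the bout
    center within the cycle.
    """
    bw_h = spec.bin_width / 60.0
    n_bins = int(round(spec.n_days * 24.0 / bw_h))
    t = (np.arange(n_bins) + 0.5) * bw_h
    phase = np.mod(t - spec.bout_center_phase, spec.bout_period)
    d = np.minimum(phase, spec.bout_period - phase)
    rate = spec.background_rate + spec.bout_amplitude * np.exp(-0.5 * (d / spec.bout_sd) ** 2)
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(rate).astype(float)
    return ActivityRecord(bin_width=spec.bin_width, counts=counts, start=0.0)
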