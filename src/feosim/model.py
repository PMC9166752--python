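"""Coupled phase-oscillator model of food-entrainable circadian rhythms.

A population of ``n`` food-entrainable oscillators (FEOs) is modelled as
Kuramoto phase oscillators with normally distributed intrinsic periods.
Each phase obeys

    dθ_i/dt = 2π/T_i + (K/n) Σ_j sin(θ_j − θ_i) − K_F · F(t) · M(θ_i)

where ``F(t)`` is the binary food stimulus of a feeding protocol and
``M(θ)`` is a truncated Fourier sine series that is local (zero outside a
~6 h neighbourhood of the mealtime phase θ = 0) and restoring (it pulls
phases toward θ = 0 while food is present).  The behavioural output is the
fraction χ(t) of oscillators inside a narrow phase window just before
θ = 0 — oscillators "predicting" the meal — passed through a saturating
sigmoid α(χ) that represents the animal's all-or-none activity response.

``F(t)`` is piecewise constant, so the system is integrated segment by
segment between meal boundaries with an adaptive explicit Runge–Kutta
scheme at tight tolerance; the model is deterministic once periods and
initial phases have been sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .schedules import FeedingProtocol

__all__ = [
    "TABLE1_FOURIER_COEFFS",
    "ModelParams",
    "OscillatorPopulation",
    "PhaseTrajectory",
    "ActivitySeries",
    "sample_periods",
    "modulation",
    "phase_derivative",
    "integrate",
    "meal_indication",
    "activity_output",
    "simulate",
]

TWO_PI = 2.0 * np.pi

#: Default coefficients of the food phase-modulation series M(θ).
TABLE1_FOURIER_COEFFS = (0.2142, 0.3295, 0.3177, 0.2259, 0.1236, 0.0523, 0.0170, 0.0041)


@dataclass(frozen=True)
class ModelParams:
    """Model constants.

    Parameters
    ----------
    coupling : float
        Mutual FEO coupling strength K (rad/h at full asynchrony→synchrony
        scale; weak by default).
    food_gain : float
        Strength K_F of the phase modulation exerted by food intake.
    n : int
        Number of oscillators in the population.
    period_mean, period_sd : float
        Mean and SD (hours) of the normal distribution of intrinsic periods.
    indication_width : float
        Width θ* (radians) of the pre-mealtime phase window whose occupancy
        defines χ.  0.2 rad ≈ 45 min at a 24-h period.
    sigmoid_rate, sigmoid_location : float
        Rate (k1) and location (k2) of saturation of the activity sigmoid
        α(χ).  The shift c = 1/(1+k2) is derived, never user-set.
    fourier_coeffs : tuple of 8 floats
        Coefficients a_1..a_8 of M(θ) = Σ a_j sin(jθ).
    """

    coupling: float = 0.001
    food_gain: float = 0.6433
    n: int = 1000
    period_mean: float = 24.0
    period_sd: float = 1.0
    indication_width: float = 0.2
    sigmoid_rate: float = 40.0
    sigmoid_location: float = 5.0
    fourier_coeffs: tuple = TABLE1_FOURIER_COEFFS

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.period_sd <= 0:
            raise ValueError("period_sd must be > 0")
        if not (0 < self.indication_width < TWO_PI):
            raise ValueError("indication_width must lie in (0, 2*pi)")
        if self.sigmoid_rate <= 0 or self.sigmoid_location <= 0:
            raise ValueError("sigmoid_rate and sigmoid_location must be > 0")
        if len(self.fourier_coeffs) != 8:
            raise ValueError("fourier_coeffs must have exactly 8 entries")

    @property
    def sigmoid_shift(self) -> float:
        """Derived shift c = 1/(1 + k2) making α(0) = 0."""
        return 1.0 / (1.0 + self.sigmoid_location)

    def meal_window_minutes(self) -> float:
        """Duration of the meal-indication phase window at the mean period."""
        return self.indication_width / TWO_PI * self.period_mean * 60.0

    def to_dict(self) -> dict:
        return {
            "coupling": self.coupling,
            "food_gain": self.food_gain,
            "n": self.n,
            "period_mean": self.period_mean,
            "period_sd": self.period_sd,
            "indication_width": self.indication_width,
            "sigmoid_rate": self.sigmoid_rate,
            "sigmoid_location": self.sigmoid_location,
            "fourier_coeffs": list(self.fourier_coeffs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        if "fourier_coeffs" in d:
            d["fourier_coeffs"] = tuple(d["fourier_coeffs"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class OscillatorPopulation:
    """Intrinsic periods and current phases of the oscillator population."""

    periods: np.ndarray
    phases: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.periods = np.asarray(self.periods, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if self.periods.shape != self.phases.shape:
            raise ValueError("periods and phases must have the same length")
        if np.any(self.periods <= 0):
            raise ValueError("all intrinsic periods must be positive")
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("all phases must be finite")

    @classmethod
    def from_seed(cls, params: ModelParams, seed: int) -> "OscillatorPopulation":
        """Seeded draw: periods first, then uniform initial phases on [0, 2π)."""
        rng = np.random.default_rng(seed)
        periods = rng.normal(params.period_mean, params.period_sd, params.n)
        phases = rng.uniform(0.0, TWO_PI, params.n)
        return cls(periods=periods, phases=phases, seed=seed)


@dataclass
class PhaseTrajectory:
    """Sampled solution θ_i(t) of the phase ODEs, reduced to [0, 2π)."""

    times: np.ndarray
    phases: np.ndarray  # shape (n, len(times))
    params: ModelParams
    protocol: FeedingProtocol
    periods: np.ndarray | None = None

    def to_csv(self, path) -> None:
        cols = {"time_h": self.times}
        for i in range(self.phases.shape[0]):
            cols[f"osc_{i}"] = self.phases[i]
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class ActivitySeries:
    """Model output on a uniform grid: χ(t) and the activity α(χ(t))."""

    times: np.ndarray
    chi: np.ndarray
    activity: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "chi": self.chi, "activity": self.activity})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ActivitySeries":
        df = pd.read_csv(path)
        return cls(
            times=df["time_h"].to_numpy(),
            chi=df["chi"].to_numpy(),
            activity=df["activity"].to_numpy(),
        )


def sample_periods(params: ModelParams, seed: int) -> np.ndarray:
    """Draw the n intrinsic periods from Normal(period_mean, period_sd)."""
    rng = np.random.default_rng(seed)
    return rng.normal(params.period_mean, params.period_sd, params.n)


def modulation(theta, coeffs=TABLE1_FOURIER_COEFFS):
    """Food phase-modulation M(θ) = Σ_{j=1..8} a_j sin(jθ).

    2π-periodic and odd about θ = 0; effectively zero outside a ~6 h
    neighbourhood of the mealtime phase.
    """
    theta = np.asarray(theta, dtype=float)
    out = np.zeros_like(theta)
    for j, a in enumerate(coeffs, start=1):
        out += a * np.sin(j * theta)
    return out if out.ndim else float(out)


def phase_derivative(
    phases: np.ndarray,
    periods: np.ndarray,
    params: ModelParams,
    food: int,
    method: str = "mean_field",
) -> np.ndarray:
    """Right-hand side dθ_i/dt of the coupled phase equations.

    ``method="mean_field"`` evaluates the coupling sum via the Kuramoto
    order parameter, (K/n) Σ_j sin(θ_j − θ_i) = K·R·sin(ψ − θ_i), in O(n);
    ``method="double_sum"`` is the literal O(n²) sum (testing oracle).
    """
    phases = np.asarray(phases, dtype=float)
    periods = np.asarray(periods, dtype=float)
    if phases.shape != periods.shape:
        raise ValueError("phases and periods must have the same length")
    rate = TWO_PI / periods
    if params.coupling != 0.0:
        if method == "mean_field":
            z = np.exp(1j * phases).mean()
            rate = rate + params.coupling * (z.imag * np.cos(phases) - z.real * np.sin(phases))
        elif method == "double_sum":
            diff = phases[None, :] - phases[:, None]
            rate = rate + params.coupling / phases.size * np.sin(diff).sum(axis=1)
        else:
            raise ValueError(f"unknown method {method!r}")
    if food and params.food_gain != 0.0:
        rate = rate - params.food_gain * modulation(phases, params.fourier_coeffs)
    return rate


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails inside a continuity segment."""


def integrate(
    population: OscillatorPopulation,
    params: ModelParams,
    protocol: FeedingProtocol,
    sampling_interval: float = 1 / 6,
    rtol: float = 1e-10,
    atol: float = 1e-10,
    method: str = "DOP853",
) -> PhaseTrajectory:
    """Integrate the phase ODEs across the whole protocol.

    The food stimulus is piecewise constant, so the solver is restarted at
    every meal boundary and ``F`` is held fixed within each segment; state
    is carried continuously across boundaries.  Phases are integrated
    unwrapped (every term of the RHS is 2π-periodic) and reduced mod 2π
    only in the returned trajectory.
    """
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be > 0")
    total = protocol.total_duration
    grid = np.arange(0.0, total + 0.5 * sampling_interval, sampling_interval)
    grid = grid[grid <= total]
    boundaries = np.unique(
        np.concatenate(([0.0], protocol.discontinuity_times(), [total]))
    )
    boundaries = boundaries[(boundaries >= 0.0) & (boundaries <= total)]

    periods = population.periods
    y = population.phases.astype(float).copy()
    out = np.empty((periods.size, grid.size))
    filled = 0
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        if t1 <= t0:
            continue
        food = int(protocol.food_stimulus(0.5 * (t0 + t1)))
        last = t1 >= boundaries[-1]
        if last:
            seg_pts = grid[(grid >= t0) & (grid <= t1)]
        else:
            seg_pts = grid[(grid >= t0) & (grid < t1)]
        t_eval = np.unique(np.append(seg_pts, t1))
        sol = solve_ivp(
            lambda t, th: phase_derivative(th, periods, params, food),
            (t0, t1),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE solver failed on segment [{t0}, {t1}] h (F={food}): {sol.message}"
            )
        keep = np.isin(sol.t, seg_pts)
        n_keep = int(keep.sum())
        out[:, filled:filled + n_keep] = sol.y[:, keep]
        filled += n_keep
        y = sol.y[:, -1]
    assert filled == grid.size
    return PhaseTrajectory(
        times=grid,
        phases=np.mod(out, TWO_PI),
        params=params,
        protocol=protocol,
        periods=periods.copy(),
    )


def meal_indication(trajectory: PhaseTrajectory, indication_width: float | None = None) -> np.ndarray:
    """Fraction χ(t) of oscillators inside the pre-mealtime phase window.

    The window is θ ∈ [−θ*, 0], i.e. after reduction mod 2π the closed set
    [2π − θ*, 2π) ∪ {0}; an oscillator there is signalling an imminent meal.
    """
    width = trajectory.params.indication_width if indication_width is None else indication_width
    if not (0 < width < TWO_PI):
        raise ValueError("indication width must lie in (0, 2*pi)")
    wrapped = np.mod(trajectory.phases, TWO_PI)
    inside = (wrapped >= TWO_PI - width) | (wrapped == 0.0)
    return inside.mean(axis=0)


def activity_output(chi, params: ModelParams) -> np.ndarray:
    """Saturating sigmoid α(χ) mapping window occupancy to activity in [0, 1].

    α(χ) = (1/(1−c)) · (exp(k1·χ)/(exp(k1·χ)+k2) − c) with c = 1/(1+k2);
    evaluated in the overflow-safe form 1/(1 + k2·exp(−k1·χ)).
    """
    chi_arr = np.asarray(chi, dtype=float)
    if np.any(chi_arr < 0) or np.any(chi_arr > 1):
        raise ValueError("chi must lie in [0, 1]")
    c = params.sigmoid_shift
    inner = 1.0 / (1.0 + params.sigmoid_location * np.exp(-params.sigmoid_rate * chi_arr))
    out = (inner - c) / (1.0 - c)
    return out if out.ndim else float(out)


def simulate(
    params: ModelParams,
    protocol: FeedingProtocol,
    seed: int,
    sampling_interval: float = 1 / 6,
    return_trajectory: bool = False,
    rtol: float = 1e-10,
    atol: float = 1e-10,
):
    """End-to-end simulation: seeded population → ODE solve → χ → α.

    Returns an :class:`ActivitySeries`; with ``return_trajectory=True``
    returns ``(series, trajectory)``.  Fully reproducible given
    ``(params, protocol, seed, sampling_interval)``.
    """
    population = OscillatorPopulation.from_seed(params, seed)
    traj = integrate(population, params, protocol, sampling_interval, rtol=rtol, atol=atol)
    chi = meal_indication(traj)
    series = ActivitySeries(times=traj.times, chi=chi, activity=activity_output(chi, params))
    if return_trajectory:
        return series, traj
    return series
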