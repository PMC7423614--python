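"""Aequorin luminescence -> mitochondrial Ca2+ quantification.

Aequorin is a Ca2+-dependent photoprotein: its instantaneous luminescence,
normalized by the total remaining dischargeable luminescence (L/Lmax),
reports the ambient Ca2+ concentration while irreversibly consuming the
reporter pool.  This module converts photon-count kinetics recorded on a
plate reader into calibrated molar Ca2+ traces and bell-curve summary
kinetics (peak amplitude, peak time, rising-phase slope), with replicate
aggregation as mean +/- SEM.

The processing chain per well is

    counts --(penalized cubic smoothing spline)--> smoothed counts
           --(fractional consumption rate)-------> R_i  (per second)
           --(calibration)-----------------------> [Ca2+] (M)
           --(spline parametrization)------------> peak, peak_time, slope

The calibration for wild-type aequorin with native coelenterazine is

    [Ca2+](M) = (x + x*K_TR - 1) / (K_R - x*K_R),   x = (R * lambda)^(1/n)

with lambda = 1, K_R = 7.23e6, K_TR = 120, n = 2.99.  The fractional rate
at sample i uses the total remaining discharge as Lmax:

    remaining_i = sum_{j >= i} counts_j + lysis_counts
    R_i = (counts_i / dt) / remaining_i

where lysis_counts is the residual signal collected after detergent lysis
saturates the remaining reporter with Ca2+.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline


class CalibrationDomainError(ValueError):
    """Fractional rate outside the invertible domain of the calibration."""


@dataclass(frozen=True)
class CalibrationConstants:
    """Calibration constants for WT aequorin + native coelenterazine."""

    lam: float = 1.0
    k_r: float = 7.23e6
    k_tr: float = 120.0
    n: float = 2.99

    def __post_init__(self) -> None:
        for name in ("lam", "k_r", "k_tr", "n"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def zero_point(self) -> float:
        """The value of x = (R*lam)^(1/n) at which calibrated Ca2+ is 0."""
        return 1.0 / (1.0 + self.k_tr)


@dataclass(frozen=True)
class SmoothingConfig:
    """Fidelity/roughness tradeoff p for the cubic smoothing spline.

    The spline minimizes  p * sum_i (y_i - f(x_i))^2 + (1-p) * int (f'')^2.
    p = 1 interpolates; p -> 0 approaches the least-squares line.
    """

    p: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("smoothing parameter p must be in [0, 1]")


@dataclass(frozen=True)
class LuminescenceTrace:
    """Uniformly sampled photon counts plus the post-lysis residual."""

    times: np.ndarray
    counts: np.ndarray
    lysis_counts: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)
        if times.ndim != 1 or times.shape != counts.shape:
            raise ValueError("times and counts must be equal-length 1-D arrays")
        if len(times) < 4:
            raise ValueError("need at least 4 samples (spline minimum)")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("non-uniform sampling interval; resample upstream")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise ValueError("counts must be finite and non-negative")
        if self.lysis_counts < 0:
            raise ValueError("lysis_counts must be >= 0")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class CalciumTrace:
    """Calibrated molar Ca2+ series (clamped at 0)."""

    times: np.ndarray
    ca: np.ndarray
    ca_raw: np.ndarray | None = None  # unclamped diagnostic values

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ca = np.asarray(self.ca, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ca", ca)
        if times.shape != ca.shape:
            raise ValueError("times and ca must have equal length")
        if not np.all(np.isfinite(ca)):
            raise ValueError("ca must be finite")


@dataclass(frozen=True)
class KineticsSummary:
    peak: float
    peak_time: float
    left_slope: float
    secant_slope: float
    label: str = ""


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    peak_mean: float
    peak_sem: float
    slope_mean: float
    slope_sem: float


def smooth_trace(times, values, cfg: SmoothingConfig | float = SmoothingConfig()):
    """Penalized natural cubic smoothing spline.

    Minimizes p * sum (y_i - f(x_i))^2 + (1 - p) * int (f'')^2 dx; this is the
    same minimizer as sum (y - f)^2 + lam * int (f'')^2 with lam = (1-p)/p,
    which is what :func:`scipy.interpolate.make_smoothing_spline` solves.

    Returns ``(fitted_values_at_times, spline)``; the spline is a
    :class:`scipy.interpolate.BSpline` usable for analytic derivatives.
    """
    if isinstance(cfg, (int, float)):
        cfg = SmoothingConfig(p=float(cfg))
    x = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit the smoothing spline")
    if cfg.p == 0.0:
        # limit of infinite roughness penalty: ordinary least-squares line
        slope, intercept = np.polyfit(x, y, 1)
        coeffs = np.array([intercept + slope * x[0], intercept + slope * x[-1]])
        spline = BSpline(np.r_[[x[0], x[0]], [x[-1], x[-1]]], coeffs, 1)
        return spline(x), spline
    lam = (1.0 - cfg.p) / cfg.p
    spline = make_smoothing_spline(x, y, lam=lam)
    return spline(x), spline


def fractional_rate(trace: LuminescenceTrace, counts: np.ndarray | None = None
                    ) -> np.ndarray:
    """Per-second fractional consumption rate R_i = (counts_i/dt)/remaining_i.

    ``remaining_i`` is the total still-dischargeable signal at sample i:
    the future counts (this sample included) plus the post-lysis residual.
    Pass ``counts`` to substitute a smoothed series for the numerator and
    the remaining-pool accounting; the trace itself is never mutated.
    """
    c = trace.counts if counts is None else np.asarray(counts, dtype=float)
    if c.shape != trace.times.shape:
        raise ValueError("counts override must match the trace length")
    c = np.clip(c, 0.0, None)
    remaining = np.cumsum(c[::-1])[::-1] + trace.lysis_counts
    if remaining[0] <= 0:
        raise ValueError("no reporter signal: all counts and lysis residual are zero")
    rate = np.divide(c / trace.dt, remaining, out=np.zeros_like(c),
                     where=remaining > 0)
    return rate


def calibrate(rate, constants: CalibrationConstants = CalibrationConstants(),
              clamp: bool = True) -> np.ndarray:
    """Convert fractional luminescence rates to molar Ca2+.

    Ca = (x*(1 + K_TR) - 1) / (K_R * (1 - x)) with x = (R*lam)^(1/n);
    monotone non-decreasing in R.  Values whose numerator is negative sit
    below the calcium-independent luminescence floor and are clamped to 0
    (set ``clamp=False`` for the raw diagnostic values).
    """
    r = np.asarray(rate, dtype=float)
    if np.any(r < 0):
        raise ValueError("fractional rates must be >= 0")
    x = np.power(r * constants.lam, 1.0 / constants.n)
    if np.any(x >= 1.0):
        raise CalibrationDomainError(
            "R*lambda >= 1: rate implies total instantaneous consumption")
    ca = (x * (1.0 + constants.k_tr) - 1.0) / (constants.k_r * (1.0 - x))
    if clamp:
        ca = np.clip(ca, 0.0, None)
    return ca


def calibrate_trace(trace: LuminescenceTrace,
                    constants: CalibrationConstants = CalibrationConstants(),
                    smoothing: SmoothingConfig | None = SmoothingConfig(),
                    ) -> CalciumTrace:
    """Full chain for one well: smooth the luminescence, then rate, then Ca2+.

    Smoothing the luminescence signal first (rather than the calibrated
    trace) is the default order; pass ``smoothing=None`` to skip it.
    """
    if smoothing is None:
        counts = None
    else:
        counts, _ = smooth_trace(trace.times, trace.counts, smoothing)
    rate = fractional_rate(trace, counts=counts)
    ca_raw = calibrate(rate, constants, clamp=False)
    return CalciumTrace(trace.times, np.clip(ca_raw, 0.0, None), ca_raw=ca_raw)


def parametrize_kinetics(ca: CalciumTrace, stimulus_time: float,
                         smoothing_p: float = 1.0, label: str = "",
                         _oversample: int = 10) -> KineticsSummary:
    """Peak / peak-time / left-slope of a bell-shaped transient.

    The trace is represented by a cubic spline (interpolating by default,
    ``smoothing_p < 1`` to re-smooth); peak is its maximum after the
    stimulus, the left slope the maximum of the analytic spline derivative
    on [stimulus_time, peak_time].  A secant slope over the rising phase is
    reported alongside.
    """
    t = ca.times
    if not (t[0] <= stimulus_time <= t[-1]):
        raise ValueError("stimulus_time outside the trace span")
    _, spline = smooth_trace(t, ca.ca, SmoothingConfig(p=smoothing_p))
    grid = np.linspace(stimulus_time, t[-1],
                       max(2, _oversample * len(t)))
    vals = spline(grid)
    imax = int(np.argmax(vals))  # first index on ties
    peak = float(vals[imax])
    peak_time = float(grid[imax])
    if peak_time <= stimulus_time:
        warnings.warn("no rising phase after stimulus; left slope set to 0")
        return KineticsSummary(peak, peak_time, 0.0, 0.0, label)
    dgrid = grid[grid <= peak_time]
    deriv = spline.derivative()(dgrid)
    left_slope = float(max(np.max(deriv), 0.0))
    v0 = float(spline(stimulus_time))
    secant = (peak - v0) / (peak_time - stimulus_time)
    return KineticsSummary(peak, peak_time, left_slope, secant, label)


def quantify_experiment(plate: dict[str, LuminescenceTrace],
                        groups: dict[str, str],
                        stimulus_time: float = 0.0,
                        constants: CalibrationConstants = CalibrationConstants(),
                        smoothing: SmoothingConfig = SmoothingConfig(),
                        ) -> tuple[dict[str, KineticsSummary], list[GroupSummary]]:
    """Per-well kinetics summaries plus per-group mean +/- SEM.

    Every well must be assigned to a group; groups with a single well get
    SEM = NaN (not estimable).
    """
    missing = set(plate) - set(groups)
    if missing:
        raise ValueError(f"wells without group assignment: {sorted(missing)}")
    per_well: dict[str, KineticsSummary] = {}
    for well, trace in plate.items():
        ca = calibrate_trace(trace, constants, smoothing)
        per_well[well] = parametrize_kinetics(ca, stimulus_time, label=well)
    summaries = []
    for group in sorted(set(groups[w] for w in plate)):
        wells = [w for w in plate if groups[w] == group]
        peaks = np.array([per_well[w].peak for w in wells])
        slopes = np.array([per_well[w].left_slope for w in wells])
        n = len(wells)
        sem = lambda a: float(np.std(a, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        summaries.append(GroupSummary(group, n, float(peaks.mean()), sem(peaks),
                                      float(slopes.mean()), sem(slopes)))
    return per_well, summaries


def with_constants(constants: CalibrationConstants, **overrides) -> CalibrationConstants:
    return replace(constants, **overrides)
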