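"""Arterial-monitor processing: background, calibration, dispersion, delay.

Turns raw monitor counts into a calibrated, background-subtracted,
delay-aligned arterial input function, and provides the curve comparison
metrics (peak, tail, AUC, percent difference) used to validate image-derived
input functions against arterial ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timing_io import BloodCurve, Tac, TracerConstants, frame_average

__all__ = [
    "BackgroundFit",
    "CurveMetrics",
    "fit_background",
    "subtract_background",
    "calibrate",
    "dispersion_correct",
    "estimate_delay",
    "detect_bolus_arrival",
    "curve_metrics",
    "percent_difference",
    "process_monitor",
]

#: Default tail window: 1 min starting at 2 min 40 s post-injection.
DEFAULT_TAIL_WINDOW = (160.0, 220.0)


@dataclass(frozen=True)
class BackgroundFit:
    """Residual-activity background: A₀·e^{-λt} with the rate fixed at tracer λ."""

    amplitude: float
    decay_constant: float
    window: tuple[float, float]
    residual_rms: float


@dataclass(frozen=True)
class CurveMetrics:
    """Peak, tail-window mean, and AUC of a frame-resolution curve."""

    peak: float
    tail: float
    auc: float


def fit_background(
    raw: BloodCurve, window: tuple[float, float], tracer: TracerConstants
) -> BackgroundFit:
    """Least-squares amplitude of A₀·e^{-λt} on a pre-bolus window.

    With the rate fixed at the tracer decay constant the solution is closed
    form: A₀ = Σ y·e^{-λt} / Σ e^{-2λt}.  Negative fitted amplitudes are
    floored at 0 (activity is non-negative).  Requires >= 3 samples in the
    window.
    """
    t_a, t_b = window
    sel = (raw.time_s >= t_a) & (raw.time_s <= t_b)
    if np.count_nonzero(sel) < 3:
        raise ValueError("background window must contain at least 3 samples")
    t = raw.time_s[sel]
    y = raw.activity[sel]
    lam = tracer.decay_constant
    e = np.exp(-lam * t)
    denom = float(e @ e)
    if denom == 0.0:
        raise ValueError("degenerate background design")
    a0 = max(0.0, float(y @ e) / denom)
    resid = y - a0 * e
    return BackgroundFit(a0, lam, (t_a, t_b), float(np.sqrt(np.mean(resid**2))))


def subtract_background(raw: BloodCurve, bg: BackgroundFit) -> BloodCurve:
    """Subtract the fitted background, flooring negative results at 0."""
    corrected = raw.activity - bg.amplitude * np.exp(-bg.decay_constant * raw.time_s)
    return raw.with_activity(np.maximum(corrected, 0.0))


def calibrate(raw: BloodCurve, sensitivity: float, tracer: TracerConstants) -> BloodCurve:
    """Convert monitor counts to concentration, decay-corrected to injection time.

    activity = raw / sensitivity · e^{+λt}.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    lam = tracer.decay_constant
    out = raw.with_activity(raw.activity / sensitivity * np.exp(lam * raw.time_s))
    return BloodCurve(out.time_s, out.activity, tracer=tracer, calibrated=True)


def dispersion_correct(
    curve: BloodCurve, tau_s: float, presmooth: bool = True
) -> BloodCurve:
    """Invert exponential external dispersion: c_true = c + τ·dc/dt.

    The derivative is taken by central differences after an optional 3-point
    moving-average pre-smooth; requires uniform sampling.  A step input will
    overshoot at the edge — an inherent property of the derivative form of
    the correction.  Results are floored at 0.
    """
    if tau_s < 0:
        raise ValueError("dispersion time constant must be >= 0")
    if tau_s == 0:
        return curve
    dt = np.diff(curve.time_s)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("dispersion correction requires uniform sampling")
    y = curve.activity
    if presmooth and y.size >= 3:
        pad = np.concatenate([[y[0]], y, [y[-1]]])
        y = (pad[:-2] + pad[1:-1] + pad[2:]) / 3.0
    dydt = np.gradient(y, curve.time_s)
    return curve.with_activity(np.maximum(y + tau_s * dydt, 0.0))


def detect_bolus_arrival(raw: BloodCurve, factor: float = 5.0) -> float:
    """Time of the first sample exceeding ``factor`` × the median of earlier samples.

    A simple arrival detector used to pick the default background window
    ``[0, arrival − 5 s]``.
    """
    y = raw.activity
    i_peak = int(np.argmax(y))
    med = np.median(y[: max(3, i_peak // 4)]) if i_peak >= 3 else 0.0
    thresh = max(factor * med, 0.02 * np.max(y))
    above = np.nonzero(y > thresh)[0]
    if above.size == 0 or i_peak == 0:
        raise ValueError("no bolus detected")
    return float(raw.time_s[above[0]])


def estimate_delay(
    blood: BloodCurve,
    lv_tac: Tac,
    search_s: tuple[float, float] = (-30.0, 30.0),
    step_s: float = 0.5,
) -> float:
    """Time shift (to add to the blood curve's times) aligning it with the LV TAC.

    Maximizes Pearson correlation between the shifted, frame-averaged blood
    curve and the LV TAC over a candidate grid; ties resolve to the smallest
    |shift|.  A blood curve measured ``d`` seconds late is therefore assigned
    a shift of ``-d``.
    """
    lv = lv_tac.values
    if np.std(lv) == 0:
        raise ValueError("LV TAC is constant; correlation undefined")
    schedule = lv_tac.frames
    lo, hi = search_s
    candidates = np.arange(lo, hi + 0.5 * step_s, step_s)
    candidates = candidates[np.argsort(np.abs(candidates), kind="stable")]
    best_r, best_d = -np.inf, None
    for d in candidates:
        shifted = blood.shifted(d)
        if shifted.time_s[-1] <= schedule.start_s[0] or shifted.time_s[0] >= schedule.end_s[-1]:
            continue
        covered = np.count_nonzero(
            (schedule.end_s > shifted.time_s[0]) & (schedule.start_s < shifted.time_s[-1])
        )
        if covered < 5:
            continue
        fa = frame_average(shifted, schedule).values
        if np.std(fa) == 0:
            continue
        r = float(np.corrcoef(fa, lv)[0, 1])
        if r > best_r + 1e-12:  # candidates are |shift|-sorted: ties keep smaller
            best_r, best_d = r, float(d)
    if best_d is None:
        raise ValueError("no candidate shift gives at least 5 overlapping frames")
    return best_d


def curve_metrics(
    tac: Tac, tail_window: tuple[float, float] = DEFAULT_TAIL_WINDOW
) -> CurveMetrics:
    """Peak, duration-weighted tail mean, and AUC of a frame TAC.

    The tail is the duration-weighted mean of the frame portions overlapping
    ``tail_window``; the AUC is Σ value·Δt over the whole schedule.  Raises if
    the schedule does not cover the tail window.
    """
    sched = tac.frames
    t_a, t_b = tail_window
    if t_a < sched.start_s[0] - 1e-9 or t_b > sched.end_s[-1] + 1e-9:
        raise ValueError("schedule does not cover the tail window")
    overlap = np.minimum(sched.end_s, t_b) - np.maximum(sched.start_s, t_a)
    overlap = np.maximum(overlap, 0.0)
    if overlap.sum() <= 0:
        raise ValueError("no frames overlap the tail window")
    tail = float((tac.values * overlap).sum() / overlap.sum())
    auc = float((tac.values * sched.duration_s).sum())
    return CurveMetrics(peak=float(np.max(tac.values)), tail=tail, auc=auc)


def percent_difference(idif_metric: float, aif_metric: float) -> float:
    """100 × (IDIF − AIF) / AIF — the arterial-referenced comparison metric."""
    if aif_metric == 0:
        raise ValueError("reference metric is zero")
    return 100.0 * (idif_metric - aif_metric) / aif_metric


def process_monitor(
    raw: BloodCurve,
    tracer: TracerConstants,
    sensitivity: float,
    bg_window: tuple[float, float] | None = None,
    dispersion_tau_s: float = 2.5,
    lv_tac: Tac | None = None,
    subtract_bg: bool = True,
) -> tuple[BloodCurve, dict]:
    """Full monitor-to-AIF chain: background → calibration → dispersion → delay.

    If ``bg_window`` is None it defaults to [0, bolus arrival − 5 s].  The
    delay step runs only when an LV TAC is supplied; the returned info dict
    carries the background fit and estimated delay.  Background subtraction is
    skipped (e.g. for O-15 water, where the line is flushed) with
    ``subtract_bg=False``.
    """
    info: dict = {}
    curve = raw
    if subtract_bg:
        if bg_window is None:
            arrival = detect_bolus_arrival(raw)
            bg_window = (0.0, max(arrival - 5.0, raw.time_s[0] + 2.0))
        bg = fit_background(curve, bg_window, tracer)
        info["background"] = bg
        curve = subtract_background(curve, bg)
    curve = calibrate(curve, sensitivity, tracer)
    curve = dispersion_correct(curve, dispersion_tau_s)
    if lv_tac is not None:
        delay = estimate_delay(curve, lv_tac)
        info["delay_s"] = delay
        curve = curve.shifted(delay)
    return curve, info
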