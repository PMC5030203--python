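"""Synthetic ground truth: input functions, a cardiac phantom, and a blood monitor.

Everything a dynamic cardiac PET pipeline consumes can be generated here with
known truth: a bolus-shaped arterial input function with a recirculation tail,
a voxelized phantom (LV cavity, RV crescent, myocardial shell) whose tissue
follows one-tissue-compartment kinetics with blood spillover, resolution blur,
frame-dependent noise consistent with decay and frame duration, and a raw
arterial-monitor reading with delay, dispersion, and a decaying residual
activity background (the unflushed-infusion-line signal seen with Rb-82
elution systems).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._conv import expconv
from .kinetics import model_tac
from .timing_io import (
    TISSUE_DENSITY_G_PER_ML,
    BloodCurve,
    FrameSchedule,
    TracerConstants,
    frame_average,
)

__all__ = [
    "PhantomSpec",
    "MonitorSpec",
    "SimulationResult",
    "make_input_function",
    "make_phantom_labels",
    "simulate_dynamic_pet",
    "simulate_blood_monitor",
    "LABEL_BACKGROUND",
    "LABEL_LV",
    "LABEL_RV",
    "LABEL_MYO",
]

LABEL_BACKGROUND, LABEL_LV, LABEL_RV, LABEL_MYO = 0, 1, 2, 3


def make_input_function(
    peak_time_s: float = 25.0,
    peak_amp: float = 50_000.0,
    tail_frac: float = 0.15,
    tracer: TracerConstants | None = None,
    dt_s: float = 0.2,
    t0_s: float = 10.0,
    alpha: float = 2.0,
    tail_onset_s: float = 20.0,
    tail_decay_s: float = 600.0,
    total_s: float = 260.0,
) -> BloodCurve:
    """Deterministic arterial input: gamma-variate bolus plus recirculation tail.

    The bolus is ``((t-t0)/(tp-t0))^α · e^{α(1-(t-t0)/(tp-t0))}`` peaking at
    ``peak_time_s``; the tail rises with time constant ``tail_onset_s``,
    decays with ``tail_decay_s``, and equals ``tail_frac · peak_amp`` at 3 min.
    The bolus amplitude is chosen so the curve maximum is ``peak_amp``.  The
    curve is zero before ``t0_s`` and linear in ``peak_amp`` by construction.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    if peak_amp <= 0 or not (0 <= tail_frac < 1) or peak_time_s <= t0_s:
        raise ValueError("require peak_amp > 0, 0 <= tail_frac < 1, peak after arrival")
    t = np.arange(0.0, total_s + 0.5 * dt_s, dt_s)
    tau = np.maximum(t - t0_s, 0.0)
    tp = peak_time_s - t0_s
    bolus = (tau / tp) ** alpha * np.exp(alpha * (1.0 - tau / tp))
    tail_shape = -np.expm1(-tau / tail_onset_s) * np.exp(-tau / tail_decay_s)
    ref = 180.0 - t0_s  # tail anchored at 3 min post-injection
    tail_ref = -np.expm1(-ref / tail_onset_s) * np.exp(-ref / tail_decay_s)
    tail = tail_frac * peak_amp * tail_shape / tail_ref if tail_frac > 0 else 0.0
    tail_at_peak = (
        tail_frac * peak_amp
        * (-np.expm1(-tp / tail_onset_s) * np.exp(-tp / tail_decay_s)) / tail_ref
        if tail_frac > 0
        else 0.0
    )
    activity = (peak_amp - tail_at_peak) * bolus + tail
    return BloodCurve(t, activity, tracer=tracer, calibrated=True)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and ground-truth kinetics of the cardiac phantom.

    Concentric cylinders along z: an LV cavity of radius ``lv_radius_mm``, a
    myocardial shell of thickness ``shell_thickness_mm`` around it, and an
    optional RV crescent hugging the shell on the -x side.  Per-region true
    parameters are (K1 mL/min/g, k2 1/min, V_A, V_RV); blood regions are pure
    blood (V_A or V_RV = 1).  ``psf_sigma_mm`` is the Gaussian blur emulating
    scanner resolution, applied per frame before noise.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (2.036, 2.036, 2.0)
    lv_radius_mm: float = 10.0
    shell_thickness_mm: float = 10.0
    rv_thickness_mm: float = 8.0
    include_rv: bool = True
    axial_extent_mm: float = 60.0
    myo_k1: float = 0.8
    myo_k2: float = 0.2
    myo_va: float = 0.30
    myo_vrv: float = 0.05
    psf_sigma_mm: float = 2.5
    density: float = TISSUE_DENSITY_G_PER_ML

    def __post_init__(self) -> None:
        if min(self.myo_k1, self.myo_k2, self.myo_va, self.myo_vrv) < 0:
            raise ValueError("true kinetic parameters must be non-negative")
        if self.myo_va + self.myo_vrv >= 1:
            raise ValueError("V_A + V_RV must be < 1")
        if self.psf_sigma_mm < 0:
            raise ValueError("psf_sigma_mm must be >= 0")


def make_phantom_labels(spec: PhantomSpec) -> np.ndarray:
    """Voxel label volume: 0 background, 1 LV cavity, 2 RV cavity, 3 myocardium."""
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.voxel_size_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    z = (np.arange(nz) - (nz - 1) / 2.0) * dz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    r = np.hypot(X, Y)
    in_z = np.abs(Z) <= spec.axial_extent_mm / 2.0
    labels = np.zeros(spec.shape, dtype=np.int16)
    r_shell = spec.lv_radius_mm + spec.shell_thickness_mm
    labels[(r <= spec.lv_radius_mm) & in_z] = LABEL_LV
    labels[(r > spec.lv_radius_mm) & (r <= r_shell) & in_z] = LABEL_MYO
    if spec.include_rv:
        rv = (
            (r > r_shell)
            & (r <= r_shell + spec.rv_thickness_mm)
            & (X < 0)
            & in_z
        )
        labels[rv] = LABEL_RV
    return labels


@dataclass
class SimulationResult:
    """A simulated dynamic acquisition plus everything needed to grade fits."""

    image4d: np.ndarray  # (x, y, z, n_frames), Bq/mL
    labels: np.ndarray
    schedule: FrameSchedule
    truth: dict[str, np.ndarray]  # K1, k2, V_A, V_RV truth volumes
    region_tacs: dict[int, np.ndarray]  # noiseless pre-blur TAC per label


def simulate_dynamic_pet(
    phantom: PhantomSpec,
    aif: BloodCurve,
    rvif: BloodCurve,
    schedule: FrameSchedule,
    noise_scale: float = 0.0,
    seed: int = 0,
    tracer: TracerConstants | None = None,
) -> SimulationResult:
    """Forward-simulate a dynamic acquisition from the phantom's true kinetics.

    Each region's noiseless TAC is the spillover observation model evaluated
    at its true parameters; blood regions carry the frame-averaged input
    curves directly.  Gaussian spatial blur of ``psf_sigma_mm`` is applied per
    frame *before* noise; noise is Gaussian with variance
    ``noise_scale² · value · dcf² / Δt`` (dcf = e^{λ·mid}), the model implied
    by Poisson-like raw counts after decay correction, so the NEC weights used
    in fitting are inverse-variance.  Fully reproducible from ``seed``.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    tracer = tracer or aif.tracer
    if noise_scale > 0 and tracer is None:
        raise ValueError("a tracer (decay constant) is required for noisy simulation")
    labels = make_phantom_labels(phantom)
    n_frames = len(schedule)
    fa_aif = frame_average(aif, schedule).values
    fa_rvif = frame_average(rvif, schedule).values
    myo = model_tac(
        phantom.myo_k1, phantom.myo_k2, phantom.myo_va, phantom.myo_vrv,
        aif, rvif, schedule, density=phantom.density,
    ).values
    region_tacs = {
        LABEL_BACKGROUND: np.zeros(n_frames),
        LABEL_LV: fa_aif,
        LABEL_RV: fa_rvif,
        LABEL_MYO: myo,
    }
    image = np.zeros(phantom.shape + (n_frames,))
    for lab, tac in region_tacs.items():
        if lab == LABEL_BACKGROUND:
            continue
        image[labels == lab] = tac
    if phantom.psf_sigma_mm > 0:
        sig_vox = [phantom.psf_sigma_mm / v for v in phantom.voxel_size_mm]
        for f in range(n_frames):
            image[..., f] = ndimage.gaussian_filter(image[..., f], sig_vox)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        dcf = np.exp(tracer.decay_constant * schedule.mid_s)
        var = noise_scale**2 * np.maximum(image, 0.0) * dcf**2 / schedule.duration_s
        image = image + rng.standard_normal(image.shape) * np.sqrt(var)

    def truth_vol(myo_val: float, lv_val: float, rv_val: float) -> np.ndarray:
        out = np.zeros(phantom.shape)
        out[labels == LABEL_MYO] = myo_val
        out[labels == LABEL_LV] = lv_val
        out[labels == LABEL_RV] = rv_val
        return out

    truth = {
        "K1": truth_vol(phantom.myo_k1, 0.0, 0.0),
        "k2": truth_vol(phantom.myo_k2, 0.0, 0.0),
        "V_A": truth_vol(phantom.myo_va, 1.0, 0.0),
        "V_RV": truth_vol(phantom.myo_vrv, 0.0, 1.0),
    }
    return SimulationResult(image, labels, schedule, truth, region_tacs)


@dataclass(frozen=True)
class MonitorSpec:
    """Arterial-monitor characteristics for the raw-count simulation.

    ``delay_s`` is the transit delay between the LV and the sampling site;
    ``dispersion_tau_s`` the external dispersion time constant; the background
    is ``background_amp`` counts at t = 0 decaying at the tracer's λ (residual
    activity left in the infusion line); ``sensitivity`` converts Bq/mL to
    monitor counts/s.
    """

    delay_s: float = 8.0
    dispersion_tau_s: float = 2.5
    background_amp: float = 0.0
    sensitivity: float = 1.0
    sampling_interval_s: float = 1.0
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion_tau_s < 0:
            raise ValueError("dispersion_tau_s must be >= 0")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")
        if self.sampling_interval_s <= 0 or self.noise_scale < 0:
            raise ValueError("invalid sampling interval or noise scale")


def simulate_blood_monitor(
    aif: BloodCurve, spec: MonitorSpec, tracer: TracerConstants | None = None
) -> BloodCurve:
    """Raw (uncalibrated) monitor counts from a true, decay-corrected AIF.

    output = sensitivity · disperse(shift(aif, delay), τ) · e^{-λt}
             + A₀·e^{-λt} + noise,

    where dispersion is convolution with ``(1/τ)·e^{-t/τ}``.  Gaussian noise
    with σ = noise_scale·sqrt(max(value, 1)) emulates count statistics.
    """
    tracer = tracer or aif.tracer
    if tracer is None:
        raise ValueError("tracer decay constant required")
    lam = tracer.decay_constant
    t = np.arange(
        0.0,
        aif.time_s[-1] + spec.delay_s + 0.5 * spec.sampling_interval_s,
        spec.sampling_interval_s,
    )
    shifted = np.interp(t - spec.delay_s, aif.time_s, aif.activity, left=0.0)
    if spec.dispersion_tau_s > 0:
        rate = 1.0 / spec.dispersion_tau_s
        dispersed = rate * expconv(t, shifted, rate)
    else:
        dispersed = shifted
    counts = spec.sensitivity * dispersed * np.exp(-lam * t)
    counts = counts + spec.background_amp * np.exp(-lam * t)
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_scale * np.sqrt(np.maximum(counts, 1.0))
        counts = counts + rng.standard_normal(counts.shape) * sigma
    return BloodCurve(t, counts, tracer=tracer, calibrated=False)
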