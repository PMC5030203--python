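"""One-tissue compartment modeling with spillover terms, fit by basis functions.

The tissue response is ``C_T(t) = K1 · e^{-k2 t} ⊗ C_A(t)`` (K1 in mL/min/g,
k2 in 1/min, times internally in seconds) and the observed voxel/VOI activity
in Bq/mL is

    C_PET(t) = ρ (1 - V_A - V_RV) C_T(t) + V_A C_A(t) + V_RV C_RV(t)

with tissue density ρ = 1.05 g/mL folded into the observation so that the
blood-spillover fractions V_A, V_RV keep their Bq/mL meaning.  Fitting
linearizes the problem over a grid of k2 values: for each candidate k2 the
remaining parameters enter linearly and are solved by constrained weighted
least squares; the grid minimum is then refined by golden-section search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._conv import FrameConvolver
from .timing_io import (
    TISSUE_DENSITY_G_PER_ML,
    BloodCurve,
    FrameSchedule,
    Tac,
    TracerConstants,
    frame_average,
)

__all__ = [
    "KineticFit",
    "FitWeights",
    "ParametricMaps",
    "default_k2_grid",
    "model_tac",
    "nec_weights",
    "make_basis",
    "fit_tac",
    "fit_parametric",
    "voi_stats",
]

# Upper bound on V_A + V_RV.  Pure-blood voxels legitimately reach the cap,
# where the tissue amplitude is exactly 0 and K1 = amp/(1-V_A-V_RV) is taken
# as 0 (the denominator is floored); capping strictly below 1 would instead
# force a spurious tissue term whose amplitude is inflated by the tiny
# denominator.
_VMAX = 1.0
_DENOM_FLOOR = 1e-3


@dataclass(frozen=True)
class KineticFit:
    """Result of a one-tissue compartment fit.

    K1 in mL/min/g, k2 in 1/min; V_A and V_RV are unitless blood fractions
    (V_RV is None for the three-parameter model).  ``wss`` is the weighted
    residual sum of squares at the optimum; ``on_boundary`` marks solutions
    pinned at a constraint (e.g. pure-blood voxels with V_A at its cap).
    """

    K1: float
    k2: float
    V_A: float
    V_RV: float | None
    wss: float
    n_params: int
    converged: bool = True
    on_boundary: bool = False


@dataclass(frozen=True)
class FitWeights:
    """Per-frame WLS weights (non-negative, not all zero, mean-normalized)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 1 or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be 1-D, non-negative, not all zero")


@dataclass
class ParametricMaps:
    """Voxelwise kinetic parameter volumes plus a fit-failure mask."""

    K1: np.ndarray
    k2: np.ndarray
    V_A: np.ndarray
    V_RV: np.ndarray | None
    wss: np.ndarray
    failure: np.ndarray  # True where the fit failed or did not converge
    boundary: np.ndarray  # True where a constraint was active


def default_k2_grid(n: int = 100, lo: float = 0.01, hi: float = 12.0) -> np.ndarray:
    """Log-spaced k2 grid in 1/min covering rest Rb-82 washout up to stress water."""
    return np.geomspace(lo, hi, n)


def model_tac(
    K1: float,
    k2: float,
    V_A: float,
    V_RV: float,
    aif: BloodCurve,
    rvif: BloodCurve | None,
    schedule: FrameSchedule,
    density: float = TISSUE_DENSITY_G_PER_ML,
) -> Tac:
    """Noise-free frame-averaged observation for one parameter set (Bq/mL).

    The convolution of the piecewise-linear input with the exponential kernel
    and its frame averages are computed analytically (no frame-scale
    discretization).  ``rvif`` may be None when ``V_RV`` is 0.
    """
    if min(K1, k2, V_A) < 0 or V_RV < 0 or V_A + V_RV >= 1:
        raise ValueError("parameters must satisfy K1,k2,V_A,V_RV >= 0 and V_A+V_RV < 1")
    conv = FrameConvolver(aif, schedule)
    tissue_g = (K1 / 60.0) * conv.frame_avg(k2 / 60.0)  # Bq/g
    values = density * (1.0 - V_A - V_RV) * tissue_g
    values = values + V_A * frame_average(aif, schedule).values
    if V_RV != 0:
        if rvif is None:
            raise ValueError("V_RV != 0 requires an RV input curve")
        values = values + V_RV * frame_average(rvif, schedule).values
    return Tac(schedule, values, "Bq/mL")


def nec_weights(
    total_tac: Tac,
    tracer: TracerConstants,
    eps_frac: float = 1e-10,
) -> FitWeights:
    """Noise-equivalent-count frame weights for WLS fitting.

    w_i = Δt_i² · dcf_i⁻² / max(c_i·Δt_i, ε) with dcf_i = e^{λ·mid_i} the
    decay-correction factor, normalized to mean 1.  This is the inverse of the
    frame variance for decay-corrected data whose raw counts are Poisson-like:
    long frames with few (decay-corrected) counts are upweighted, frames whose
    values rest on a large decay correction are downweighted.
    """
    c = np.asarray(total_tac.values, dtype=float)
    if np.any(c < 0):
        raise ValueError("total TAC must be non-negative")
    if not np.any(c > 0):
        raise ValueError("total TAC is identically zero")
    sched = total_tac.frames
    dt = sched.duration_s
    dcf = np.exp(tracer.decay_constant * sched.mid_s)
    eps = eps_frac * float(np.max(c * dt))
    w = dt**2 / dcf**2 / np.maximum(c * dt, eps)
    return FitWeights(w / np.mean(w))


def make_basis(
    k2_grid: np.ndarray,
    aif: BloodCurve,
    schedule: FrameSchedule,
    conv: FrameConvolver | None = None,
) -> np.ndarray:
    """Basis matrix (n_frames × n_grid): frame-averaged ``e^{-k2 t} ⊗ C_A`` at unit K1.

    Column j is the tissue response C_T in Bq/g for K1 = 1 mL/min/g at
    k2 = k2_grid[j] (1/min).  The k2 → 0 column is the frame-averaged running
    integral of the input (scaled by the min/s conversion).
    """
    grid = np.asarray(k2_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("k2 grid is empty")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("k2 grid must be sorted, non-negative")
    if conv is None:
        conv = FrameConvolver(aif, schedule)
    return conv.frame_avg(grid / 60.0) / 60.0


# ---------------------------------------------------------------------------
# Constrained linear subproblem
# ---------------------------------------------------------------------------

def _feasible(theta: np.ndarray, has_rv: bool) -> np.ndarray:
    """Check amplitude/V_A/V_RV constraints columnwise; theta is (p, V)."""
    ok = np.all(theta >= -1e-12, axis=0)
    vsum = theta[1] + (theta[2] if has_rv else 0.0)
    return ok & (vsum <= _VMAX + 1e-12)


def _constrained_solve(D: np.ndarray, yw: np.ndarray, has_rv: bool) -> np.ndarray:
    """Minimize ||D θ - yw||² s.t. θ >= 0 and V_A (+ V_RV) <= _VMAX.

    NNLS handles the non-negativity; if the blood-fraction cap is then
    violated the optimum lies on that face (convexity), where the problem
    reduces to a bounded least squares in the remaining coordinates.
    """
    theta, _ = optimize.nnls(D, yw)
    vsum = theta[1] + (theta[2] if has_rv else 0.0)
    if vsum <= _VMAX:
        return theta
    if has_rv:
        # face V_A + V_RV = _VMAX: substitute V_RV = _VMAX - V_A
        resid = yw - _VMAX * D[:, 2]
        D2 = np.column_stack([D[:, 0], D[:, 1] - D[:, 2]])
        sol = optimize.lsq_linear(D2, resid, bounds=([0.0, 0.0], [np.inf, _VMAX]))
        amp, va = sol.x
        return np.array([amp, va, _VMAX - va])
    # face V_A = _VMAX
    resid = yw - _VMAX * D[:, 1]
    b = D[:, 0]
    amp = max(0.0, float(b @ resid) / float(b @ b))
    return np.array([amp, _VMAX])


def _solve_grid_point(
    Dw: np.ndarray, Yw: np.ndarray, yty: np.ndarray, has_rv: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the weighted linear problem for all voxels at one k2.

    ``Dw`` (frames × p) is shared across voxels.  Returns (theta (p, V),
    wss (V,), boundary (V,)).  Voxels whose unconstrained solution violates
    the constraints are re-solved individually under them.
    """
    G = Dw.T @ Dw
    C = Dw.T @ Yw
    try:
        theta = np.linalg.solve(G, C)
    except np.linalg.LinAlgError:
        theta = np.linalg.lstsq(Dw, Yw, rcond=None)[0]
    wss = yty - np.sum(theta * C, axis=0)
    ok = _feasible(theta, has_rv)
    boundary = np.zeros(Yw.shape[1], dtype=bool)
    for v in np.nonzero(~ok)[0]:
        th = _constrained_solve(Dw, Yw[:, v], has_rv)
        theta[:, v] = th
        r = Yw[:, v] - Dw @ th
        wss[v] = float(r @ r)
        boundary[v] = True
    np.maximum(wss, 0.0, out=wss)
    return theta, wss, boundary


def _solve_per_voxel_k2(
    bcols: np.ndarray,
    blood_w: np.ndarray,
    Yw: np.ndarray,
    yty: np.ndarray,
    has_rv: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched solve where every voxel has its own tissue column.

    ``bcols`` is (frames, V); ``blood_w`` is (frames, p-1) shared columns.
    """
    n_frames, n_vox = bcols.shape
    p = 1 + blood_w.shape[1]
    D = np.empty((n_vox, n_frames, p))
    D[:, :, 0] = bcols.T
    D[:, :, 1:] = blood_w[None, :, :]
    G = np.einsum("vfp,vfq->vpq", D, D)
    C = np.einsum("vfp,fv->vp", D, Yw)
    try:
        theta = np.linalg.solve(G, C[..., None])[..., 0]  # (V, p)
    except np.linalg.LinAlgError:
        theta = np.stack(
            [np.linalg.lstsq(D[v], Yw[:, v], rcond=None)[0] for v in range(n_vox)]
        )
    wss = yty - np.sum(theta * C, axis=1)
    ok = _feasible(theta.T, has_rv)
    boundary = np.zeros(n_vox, dtype=bool)
    for v in np.nonzero(~ok)[0]:
        th = _constrained_solve(D[v], Yw[:, v], has_rv)
        theta[v] = th
        r = Yw[:, v] - D[v] @ th
        wss[v] = float(r @ r)
        boundary[v] = True
    np.maximum(wss, 0.0, out=wss)
    return theta.T, wss, boundary


def _bfm_fit(
    Y: np.ndarray,
    conv: FrameConvolver,
    fa_aif_w: np.ndarray,
    fa_rvif_w: np.ndarray | None,
    sqrtw: np.ndarray,
    k2_grid: np.ndarray,
    density: float,
    refine: bool,
    refine_iters: int = 48,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core basis-function fit for a matrix of TACs.

    ``Y`` is (frames, V) unweighted; blood columns arrive pre-weighted.
    Returns (theta (p, V) with rows [amplitude·ρ-scaled, V_A(, V_RV)],
    k2 (V,) in 1/min, wss (V,), boundary (V,)) — packed as a tuple of
    (params, wss, boundary) where params stacks [amp, V_A(, V_RV), k2].
    """
    has_rv = fa_rvif_w is not None
    Yw = Y * sqrtw[:, None]
    yty = np.sum(Yw * Yw, axis=0)
    blood_w = (
        np.column_stack([fa_aif_w, fa_rvif_w]) if has_rv else fa_aif_w[:, None]
    )
    basis = make_basis(k2_grid, None, None, conv=conv) * density  # (frames, m)
    basis_w = basis * sqrtw[:, None]

    n_vox = Y.shape[1]
    best_wss = np.full(n_vox, np.inf)
    best_theta = np.zeros((1 + blood_w.shape[1], n_vox))
    best_j = np.zeros(n_vox, dtype=int)
    best_bnd = np.zeros(n_vox, dtype=bool)
    for j in range(k2_grid.size):
        Dw = np.column_stack([basis_w[:, j], blood_w])
        theta, wss, bnd = _solve_grid_point(Dw, Yw, yty, has_rv)
        better = wss < best_wss  # strict: ties keep the smaller k2
        best_wss[better] = wss[better]
        best_theta[:, better] = theta[:, better]
        best_j[better] = j
        best_bnd[better] = bnd[better]

    best_k2 = k2_grid[best_j]
    if refine and k2_grid.size >= 2:
        lo = np.log(k2_grid[np.maximum(best_j - 1, 0)])
        hi = np.log(k2_grid[np.minimum(best_j + 1, k2_grid.size - 1)])
        invphi = (math.sqrt(5.0) - 1.0) / 2.0

        def evaluate(logk: np.ndarray):
            k2 = np.exp(logk)
            bcols = conv.frame_avg(k2 / 60.0) * (density / 60.0) * sqrtw[:, None]
            return _solve_per_voxel_k2(bcols, blood_w, Yw, yty, has_rv)

        for _ in range(refine_iters):
            x1 = hi - invphi * (hi - lo)
            x2 = lo + invphi * (hi - lo)
            _, w1, _ = evaluate(x1)
            _, w2, _ = evaluate(x2)
            left = w1 <= w2
            hi = np.where(left, x2, hi)
            lo = np.where(left, lo, x1)
        xm = 0.5 * (lo + hi)
        theta_r, wss_r, bnd_r = evaluate(xm)
        improved = wss_r < best_wss
        best_wss[improved] = wss_r[improved]
        best_theta[:, improved] = theta_r[:, improved]
        best_k2 = np.where(improved, np.exp(xm), best_k2)
        best_bnd[improved] = bnd_r[improved]

    vsum = best_theta[1] + (best_theta[2] if has_rv else 0.0)
    best_bnd |= (best_theta[0] <= 0.0) | (vsum >= _VMAX - 1e-9)
    return best_theta, best_k2, best_wss, best_bnd


def _unpack(theta: np.ndarray, has_rv: bool):
    amp = theta[0]
    va = theta[1]
    vrv = theta[2] if has_rv else np.zeros_like(va)
    K1 = amp / np.maximum(1.0 - va - vrv, _DENOM_FLOOR)
    return K1, va, vrv


def fit_tac(
    tac: Tac,
    aif: BloodCurve,
    rvif: BloodCurve | None = None,
    weights: FitWeights | None = None,
    k2_grid: np.ndarray | None = None,
    density: float = TISSUE_DENSITY_G_PER_ML,
    refine: bool = True,
    refine_iters: int = 48,
) -> KineticFit:
    """Fit the spillover-corrected 1TCM to one TAC by the basis function method.

    For each grid k2 the non-negatively constrained weighted linear problem in
    (amplitude, V_A[, V_RV]) is solved, where amplitude = (1 - V_A - V_RV)·K1;
    the grid minimizer is then refined by golden-section search between its
    neighbors.  Passing ``rvif`` selects the four-parameter model.  Weights
    default to uniform.
    """
    schedule = tac.frames
    if k2_grid is None:
        k2_grid = default_k2_grid()
    w = weights.w if weights is not None else np.ones(len(schedule))
    if w.size != len(schedule):
        raise ValueError("weights length must match frame count")
    sqrtw = np.sqrt(w)
    conv = FrameConvolver(aif, schedule)
    fa_aif = frame_average(aif, schedule).values
    if not np.any(fa_aif != 0):
        raise ValueError("input function is identically zero over the schedule")
    fa_aif_w = fa_aif * sqrtw
    fa_rvif_w = (
        frame_average(rvif, schedule).values * sqrtw if rvif is not None else None
    )
    theta, k2, wss, bnd = _bfm_fit(
        tac.values[:, None], conv, fa_aif_w, fa_rvif_w, sqrtw,
        np.asarray(k2_grid, dtype=float), density, refine, refine_iters,
    )
    has_rv = rvif is not None
    K1, va, vrv = _unpack(theta, has_rv)
    return KineticFit(
        K1=float(K1[0]),
        k2=float(k2[0]),
        V_A=float(va[0]),
        V_RV=float(vrv[0]) if has_rv else None,
        wss=float(wss[0]),
        n_params=4 if has_rv else 3,
        converged=True,
        on_boundary=bool(bnd[0]),
    )


def fit_parametric(
    image4d: np.ndarray,
    aif: BloodCurve,
    rvif: BloodCurve | None,
    mask: np.ndarray,
    schedule: FrameSchedule,
    k2_grid: np.ndarray | None = None,
    weights: FitWeights | None = None,
    tracer: TracerConstants | None = None,
    density: float = TISSUE_DENSITY_G_PER_ML,
    refine: bool = True,
    refine_iters: int = 40,
) -> ParametricMaps:
    """Voxelwise 1TCM fit over a mask; returns parameter volumes.

    ``image4d`` has shape (x, y, z, n_frames) in Bq/mL.  If ``weights`` is
    None and ``tracer`` is given, NEC weights are derived from the mean masked
    TAC; otherwise uniform weights are used.  Failed voxels are flagged in
    ``failure`` and left as NaN, never silently zeroed.
    """
    mask = np.asarray(mask, dtype=bool)
    if image4d.shape[:3] != mask.shape:
        raise ValueError("mask shape must match the image grid")
    if image4d.shape[3] != len(schedule):
        raise ValueError("frame axis must match the schedule")
    if not np.any(mask):
        raise ValueError("mask is empty")
    Y = image4d[mask].T  # (frames, V)
    if weights is None and tracer is not None:
        weights = nec_weights(
            Tac(schedule, np.maximum(Y.mean(axis=1), 0.0)), tracer
        )
    if k2_grid is None:
        k2_grid = default_k2_grid()
    w = weights.w if weights is not None else np.ones(len(schedule))
    sqrtw = np.sqrt(w)
    conv = FrameConvolver(aif, schedule)
    fa_aif_w = frame_average(aif, schedule).values * sqrtw
    fa_rvif_w = (
        frame_average(rvif, schedule).values * sqrtw if rvif is not None else None
    )
    theta, k2, wss, bnd = _bfm_fit(
        Y, conv, fa_aif_w, fa_rvif_w, sqrtw,
        np.asarray(k2_grid, dtype=float), density, refine, refine_iters,
    )
    has_rv = rvif is not None
    K1, va, vrv = _unpack(theta, has_rv)
    bad = ~np.isfinite(K1) | ~np.isfinite(k2) | ~np.isfinite(wss)

    def volume(vals: np.ndarray) -> np.ndarray:
        out = np.full(mask.shape, np.nan)
        out[mask] = np.where(bad, np.nan, vals)
        return out

    failure = np.zeros(mask.shape, dtype=bool)
    failure[mask] = bad
    boundary = np.zeros(mask.shape, dtype=bool)
    boundary[mask] = bnd
    return ParametricMaps(
        K1=volume(K1),
        k2=volume(k2),
        V_A=volume(va),
        V_RV=volume(vrv) if has_rv else None,
        wss=volume(wss),
        failure=failure,
        boundary=boundary,
    )


def voi_stats(
    volume: np.ndarray,
    labels: np.ndarray,
    label: int = 1,
    exclude: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Mean, unbiased variance, and voxel count of a map over one VOI label.

    Voxels in ``exclude`` (e.g. a fit-failure mask) or with NaN values are
    dropped; an empty VOI after exclusions raises.
    """
    sel = np.asarray(labels) == label
    if exclude is not None:
        sel &= ~np.asarray(exclude, dtype=bool)
    vals = np.asarray(volume)[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("VOI is empty after exclusions")
    mean = float(np.mean(vals))
    var = float(np.var(vals, ddof=1)) if vals.size > 1 else 0.0
    return mean, var, int(vals.size)
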