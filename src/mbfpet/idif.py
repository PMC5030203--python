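"""Image-derived input functions and their correction models.

An IDIF is the mean TAC of a blood-pool VOI in the LV cavity.  Limited
resolution and motion mix myocardial signal into it and spill cavity signal
out, so four correction models are provided, all estimated against an
arterial gold standard by weighted least squares:

* one-parameter partial-volume model  C_LV = β·C_A + (1-β)·C_T
* two-parameter mixture               C_LV = β₁·C_A + β₂·C_T
* WLS scale                           C_LV = β_s·C_A
* AUC-ratio scale                     β_AUC = AUC(C_LV)/AUC(C_A)

with C_T the model-predicted myocardial tissue curve.  Nested models are
compared by F tests.  In a population workflow IDIFs are corrected by the
reciprocal of the mean per-tracer β_AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinetics import FitWeights, KineticFit, fit_tac
from .timing_io import (
    TISSUE_DENSITY_G_PER_ML,
    BloodCurve,
    FrameSchedule,
    Tac,
)
from ._conv import FrameConvolver

__all__ = [
    "IFCorrection",
    "extract_voi_tac",
    "estimate_reference_tissue",
    "fit_pvc1",
    "fit_pvc2",
    "fit_scale_wls",
    "fit_scale_auc",
    "apply_scale",
    "population_scale_factor",
    "f_test_nested",
]


@dataclass(frozen=True)
class IFCorrection:
    """A fitted input-function correction model.

    ``kind`` is one of pvc1 / pvc2 / scale_wls / scale_auc; ``params`` holds
    (β,), (β₁, β₂), (β_s,), or (β_AUC,).  ``in_range`` flags whether a pvc1
    recovery coefficient landed in (0, 1] (it is estimated unconstrained).
    """

    kind: str
    params: tuple[float, ...]
    wss: float
    n_params: int
    in_range: bool = True

    @property
    def beta(self) -> float:
        return self.params[0]


def extract_voi_tac(
    image4d: np.ndarray,
    labels: np.ndarray,
    schedule: FrameSchedule,
    label: int = 1,
    units: str = "Bq/mL",
) -> Tac:
    """Per-frame mean of a 4-D image over one VOI label."""
    sel = np.asarray(labels) == label
    if not np.any(sel):
        raise ValueError("VOI is empty")
    return Tac(schedule, image4d[sel].mean(axis=0), units)


def voi_voxel_count(volume_ml: float, voxel_size_mm: tuple[float, float, float]) -> int:
    """Number of voxels in a fixed-volume VOI (e.g. the 6.5 mL cylinder)."""
    voxel_ml = np.prod(voxel_size_mm) / 1000.0
    return int(round(volume_ml / voxel_ml))


def estimate_reference_tissue(
    myo_tac: Tac,
    aif: BloodCurve,
    weights: FitWeights | None = None,
    k2_grid: np.ndarray | None = None,
    density: float = TISSUE_DENSITY_G_PER_ML,
) -> tuple[Tac, KineticFit]:
    """Model-predicted myocardial tissue curve C_T from a global myocardium TAC.

    Fits the three-parameter model (no RV term) to ``myo_tac`` with the AIF,
    then returns the fitted tissue component ρ·K1·(e^{-k2 t} ⊗ C_A),
    frame-averaged, in Bq/mL — the reference used by the partial-volume
    correction models.  Never negative for non-negative inputs.
    """
    fit = fit_tac(myo_tac, aif, rvif=None, weights=weights, k2_grid=k2_grid, density=density)
    conv = FrameConvolver(aif, myo_tac.frames)
    tissue = density * (fit.K1 / 60.0) * conv.frame_avg(fit.k2 / 60.0)
    return Tac(myo_tac.frames, tissue, "Bq/mL"), fit


def _weights(w: FitWeights | None, n: int) -> np.ndarray:
    return w.w if w is not None else np.ones(n)


def fit_pvc1(
    lv_tac: Tac, aif_tac: Tac, c_t: Tac, weights: FitWeights | None = None
) -> IFCorrection:
    """One-parameter partial-volume model: C_LV = β·C_A + (1-β)·C_T (closed form)."""
    w = _weights(weights, len(lv_tac))
    d = aif_tac.values - c_t.values
    denom = float(np.sum(w * d * d))
    if denom == 0:
        raise ValueError("degenerate design: C_A equals C_T")
    beta = float(np.sum(w * (lv_tac.values - c_t.values) * d)) / denom
    resid = lv_tac.values - (beta * aif_tac.values + (1 - beta) * c_t.values)
    return IFCorrection(
        "pvc1", (beta,), float(np.sum(w * resid**2)), 1, in_range=0 < beta <= 1
    )


def fit_pvc2(
    lv_tac: Tac, aif_tac: Tac, c_t: Tac, weights: FitWeights | None = None
) -> IFCorrection:
    """Two-parameter mixture C_LV = β₁·C_A + β₂·C_T; the sum β₁+β₂ is unconstrained."""
    w = _weights(weights, len(lv_tac))
    sw = np.sqrt(w)
    X = np.column_stack([aif_tac.values, c_t.values]) * sw[:, None]
    y = lv_tac.values * sw
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("collinear design: C_A and C_T are not independent")
    beta, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return IFCorrection("pvc2", (float(beta[0]), float(beta[1])), float(resid @ resid), 2)


def fit_scale_wls(
    lv_tac: Tac, aif_tac: Tac, weights: FitWeights | None = None
) -> IFCorrection:
    """WLS scale: β_s = Σw·C_LV·C_A / Σw·C_A² — the WSS-optimal scalar multiple."""
    w = _weights(weights, len(lv_tac))
    denom = float(np.sum(w * aif_tac.values**2))
    if denom == 0:
        raise ValueError("input function is identically zero")
    beta = float(np.sum(w * lv_tac.values * aif_tac.values)) / denom
    resid = lv_tac.values - beta * aif_tac.values
    return IFCorrection("scale_wls", (beta,), float(np.sum(w * resid**2)), 1)


def fit_scale_auc(
    lv_tac: Tac, aif_tac: Tac, weights: FitWeights | None = None
) -> IFCorrection:
    """AUC-ratio scale: β_AUC = AUC(C_LV)/AUC(C_A) over the schedule.

    Cannot beat the WLS scale in WSS (which is optimal by construction); the
    WSS reported here uses the same weights for comparability.
    """
    dt = lv_tac.frames.duration_s
    denom = float(np.sum(aif_tac.values * dt))
    if denom == 0:
        raise ValueError("input function AUC is zero")
    beta = float(np.sum(lv_tac.values * dt)) / denom
    w = _weights(weights, len(lv_tac))
    resid = lv_tac.values - beta * aif_tac.values
    return IFCorrection("scale_auc", (beta,), float(np.sum(w * resid**2)), 1)


def apply_scale(idif: Tac, factor: float) -> Tac:
    """Multiply an IDIF by a correction factor (e.g. 1/mean β_AUC)."""
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    return idif.with_values(idif.values * factor)


def population_scale_factor(beta_aucs: np.ndarray) -> float:
    """Population correction factor: reciprocal of the mean per-scan β_AUC."""
    mean = float(np.mean(beta_aucs))
    if mean <= 0:
        raise ValueError("mean β_AUC must be > 0")
    return 1.0 / mean


def f_test_nested(
    fit_reduced: IFCorrection, fit_full: IFCorrection, n_frames: int
) -> tuple[float, float]:
    """F test between nested correction models.

    F = ((WSS_r − WSS_f)/(p_f − p_r)) / (WSS_f/(n − p_f)); the statistic is
    floored at 0 if the full model's WSS exceeds the reduced one's (possible
    only through numerical noise).  Returns (F, p).
    """
    p_r, p_f = fit_reduced.n_params, fit_full.n_params
    if p_f <= p_r:
        raise ValueError("full model must have more parameters than reduced")
    if n_frames <= p_f:
        raise ValueError("need more frames than full-model parameters")
    df1, df2 = p_f - p_r, n_frames - p_f
    num = max(fit_reduced.wss - fit_full.wss, 0.0) / df1
    den = fit_full.wss / df2
    if den == 0:
        return (np.inf, 0.0) if num > 0 else (0.0, 1.0)
    f = num / den
    return float(f), float(stats.f.sf(f, df1, df2))
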