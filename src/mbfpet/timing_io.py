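"""Frame schedules, activity-curve containers, tracer constants, and file I/O.

Time is measured in seconds from the start of tracer injection throughout the
package.  Frames are half-open intervals ``[start, end)``; schedules are stored
explicitly and never inferred from data.  Activity curves are decay-corrected
concentrations referenced to injection time unless stated otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "BloodCurve",
    "Tac",
    "TracerConstants",
    "RB82",
    "O15_WATER",
    "TISSUE_DENSITY_G_PER_ML",
    "default_schedule",
    "read_tac_table",
    "write_tac_table",
    "read_blood_curve",
    "write_blood_curve",
    "read_schedule",
    "write_schedule",
    "frame_average",
    "density_convert",
    "write_nifti",
    "read_nifti",
]

#: Assumed myocardial tissue density used to convert Bq/mL to Bq/g.
TISSUE_DENSITY_G_PER_ML = 1.05

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class TracerConstants:
    """Physical constants for a PET tracer.

    Parameters
    ----------
    name:
        Short tracer label, e.g. ``"rb82"``.
    decay_constant:
        Radioactive decay constant ``λ`` in 1/s.
    positron_range_class:
        Informal resolution class (metadata only; not used in computation).
    """

    name: str
    decay_constant: float
    positron_range_class: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.decay_constant > 0:
            raise ValueError("decay_constant must be > 0")

    @property
    def half_life_s(self) -> float:
        return _LN2 / self.decay_constant


#: Rubidium-82 (half-life 76.38 s; large positron range).
RB82 = TracerConstants("rb82", _LN2 / 76.38, "large")

#: Oxygen-15 labelled water (half-life 122.24 s).
O15_WATER = TracerConstants("o15_water", _LN2 / 122.24, "medium")


@dataclass(frozen=True)
class FrameSchedule:
    """Dynamic-frame timing: per-frame start and end times in seconds.

    Frames must be strictly ordered and non-overlapping (gaps are allowed).
    """

    start_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        end = np.asarray(self.end_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValueError("start_s and end_s must be equal-length 1-D arrays")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(end)):
            raise ValueError("frame times must be finite")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(end <= start):
            raise ValueError("each frame end must exceed its start")
        if np.any(end[:-1] > start[1:] + 1e-9):
            raise ValueError("frames must not overlap")

    def __len__(self) -> int:
        return self.start_s.size

    @property
    def duration_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    @property
    def mid_s(self) -> np.ndarray:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def total_end_s(self) -> float:
        return float(self.end_s[-1])

    def isclose(self, other: "FrameSchedule", atol: float = 1e-6) -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.start_s, other.start_s, atol=atol, rtol=0)
            and np.allclose(self.end_s, other.end_s, atol=atol, rtol=0)
        )


def default_schedule() -> FrameSchedule:
    """The default 4-min dynamic schedule: 20 x 3 s, 6 x 10 s, 6 x 20 s (32 frames)."""
    durations = np.concatenate([np.full(20, 3.0), np.full(6, 10.0), np.full(6, 20.0)])
    end = np.cumsum(durations)
    return FrameSchedule(end - durations, end)


@dataclass(frozen=True)
class BloodCurve:
    """A finely sampled blood activity curve (arterial input or synthetic truth).

    ``activity`` is a concentration in Bq/mL by convention; ``calibrated`` marks
    curves that have been sensitivity- and decay-corrected.
    """

    time_s: np.ndarray
    activity: np.ndarray
    tracer: TracerConstants | None = None
    calibrated: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "activity", a)
        if t.ndim != 1 or t.shape != a.shape or t.size < 2:
            raise ValueError("time_s and activity must be equal-length 1-D arrays, length >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if not np.all(np.isfinite(a)) or not np.all(np.isfinite(t)):
            raise ValueError("curve samples must be finite")

    def __len__(self) -> int:
        return self.time_s.size

    def with_activity(self, activity: np.ndarray) -> "BloodCurve":
        return replace(self, activity=np.asarray(activity, dtype=float))

    def shifted(self, dt_s: float) -> "BloodCurve":
        """Return a copy with ``dt_s`` added to every sample time."""
        return replace(self, time_s=self.time_s + dt_s)


@dataclass(frozen=True)
class Tac:
    """A frame-resolution time-activity curve bound to a schedule."""

    frames: FrameSchedule
    values: np.ndarray
    units: str = "Bq/mL"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size != len(self.frames):
            raise ValueError("values must be 1-D with one entry per frame")
        if not np.all(np.isfinite(v)):
            raise ValueError("TAC values must be finite")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Tac":
        return Tac(self.frames, np.asarray(values, dtype=float), units or self.units)


# ---------------------------------------------------------------------------
# File I/O.  All tables are comma-separated UTF-8 with '.' decimals and a
# header row; schedules are JSON lists of [start_s, end_s] pairs.
# ---------------------------------------------------------------------------

def read_tac_table(path: str | Path, schedule: FrameSchedule, units: str = "Bq/mL") -> Tac:
    """Read a frame TAC from CSV (columns frame_start_s, frame_end_s, value).

    The file's frame timing must match ``schedule`` to within 1e-6 s;
    mismatched length or timing raises rather than coercing.
    """
    df = pd.read_csv(path)
    required = {"frame_start_s", "frame_end_s", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"TAC table must have columns {sorted(required)}")
    if len(df) != len(schedule):
        raise ValueError(
            f"TAC table has {len(df)} rows but schedule has {len(schedule)} frames"
        )
    start = df["frame_start_s"].to_numpy(dtype=float)
    end = df["frame_end_s"].to_numpy(dtype=float)
    if not (
        np.allclose(start, schedule.start_s, atol=1e-6, rtol=0)
        and np.allclose(end, schedule.end_s, atol=1e-6, rtol=0)
    ):
        raise ValueError("TAC table frame timing does not match the schedule")
    values = df["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("TAC table contains non-finite values")
    return Tac(schedule, values, units)


def write_tac_table(path: str | Path, tac: Tac) -> None:
    pd.DataFrame(
        {
            "frame_start_s": tac.frames.start_s,
            "frame_end_s": tac.frames.end_s,
            "value": tac.values,
        }
    ).to_csv(path, index=False)


def read_blood_curve(
    path: str | Path,
    tracer: TracerConstants | None = None,
    calibrated: bool = True,
) -> BloodCurve:
    """Read a blood curve from CSV (columns time_s, activity_bq_ml)."""
    df = pd.read_csv(path)
    if not {"time_s", "activity_bq_ml"}.issubset(df.columns):
        raise ValueError("blood curve CSV must have columns time_s, activity_bq_ml")
    return BloodCurve(
        df["time_s"].to_numpy(dtype=float),
        df["activity_bq_ml"].to_numpy(dtype=float),
        tracer=tracer,
        calibrated=calibrated,
    )


def write_blood_curve(path: str | Path, curve: BloodCurve) -> None:
    pd.DataFrame({"time_s": curve.time_s, "activity_bq_ml": curve.activity}).to_csv(
        path, index=False
    )


def read_schedule(path: str | Path) -> FrameSchedule:
    pairs = np.asarray(json.loads(Path(path).read_text()), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("schedule JSON must be a list of [start_s, end_s] pairs")
    return FrameSchedule(pairs[:, 0], pairs[:, 1])


def write_schedule(path: str | Path, schedule: FrameSchedule) -> None:
    pairs = [[float(s), float(e)] for s, e in zip(schedule.start_s, schedule.end_s)]
    Path(path).write_text(json.dumps(pairs))


# ---------------------------------------------------------------------------
# Curve resampling and unit conversion
# ---------------------------------------------------------------------------

def _piecewise_linear_integrals(
    time_s: np.ndarray, activity: np.ndarray, edges_start: np.ndarray, edges_end: np.ndarray
) -> np.ndarray:
    """Exact integrals of the piecewise-linear curve over each [start, end).

    The curve is extended by 0 before its first sample and by its last value
    after its last sample (pre-arrival activity is physically zero; holding the
    tail constant minimises truncation bias for short overhangs).
    """
    t0, tN = time_s[0], time_s[-1]
    grid = np.unique(np.concatenate([time_s, edges_start, edges_end]))
    grid = grid[(grid >= t0) & (grid <= tN)]
    if grid.size >= 2:
        vals = np.interp(grid, time_s, activity)
        seg = 0.5 * (vals[1:] + vals[:-1]) * np.diff(grid)  # exact: integrand linear
        cum = np.concatenate([[0.0], np.cumsum(seg)])
    else:
        cum = np.zeros(1)
    # Every frame edge inside [t0, tN] is a grid node, so cumulative segment
    # sums evaluated at nodes are exact integrals of the interpolant.
    out = np.zeros(edges_start.shape, dtype=float)
    last_val = activity[-1]
    for i, (a, b) in enumerate(zip(edges_start, edges_end)):
        total = 0.0
        ia, ib = max(a, t0), min(b, tN)
        if ib > ia and grid.size >= 2:
            ka = int(np.searchsorted(grid, ia))
            kb = int(np.searchsorted(grid, ib))
            total += cum[kb] - cum[ka]
        if b > tN:
            total += (b - max(a, tN)) * last_val
        out[i] = total
    return out


def frame_average(curve: BloodCurve, schedule: FrameSchedule, units: str = "Bq/mL") -> Tac:
    """Average a finely sampled curve over each frame of a schedule.

    Uses exact integration of the piecewise-linear interpolant; the curve is
    taken as 0 before its first sample and constant after its last.  Raises if
    the curve lies entirely outside the schedule.
    """
    if curve.time_s[-1] <= schedule.start_s[0] or curve.time_s[0] >= schedule.end_s[-1]:
        raise ValueError("curve does not overlap the frame schedule")
    integrals = _piecewise_linear_integrals(
        curve.time_s, curve.activity, schedule.start_s, schedule.end_s
    )
    return Tac(schedule, integrals / schedule.duration_s, units)


def write_nifti(
    path: str | Path,
    volume: np.ndarray,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    """Write a 3-D map (or 4-D dynamic image) as NIfTI with the given voxel size."""
    import nibabel as nib

    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def density_convert(
    tac: Tac, direction: str = "per_ml_to_per_g", density: float = TISSUE_DENSITY_G_PER_ML
) -> Tac:
    """Convert a tissue TAC between Bq/mL and Bq/g using the tissue density.

    ``direction`` is ``"per_ml_to_per_g"`` (divide by density) or
    ``"per_g_to_per_ml"`` (multiply).  The units tag must match the direction.
    """
    if direction == "per_ml_to_per_g":
        if tac.units != "Bq/mL":
            raise ValueError(f"expected units Bq/mL, got {tac.units}")
        return tac.with_values(tac.values / density, units="Bq/g")
    if direction == "per_g_to_per_ml":
        if tac.units != "Bq/g":
            raise ValueError(f"expected units Bq/g, got {tac.units}")
        return tac.with_values(tac.values * density, units="Bq/mL")
    raise ValueError(f"unknown direction {direction!r}")
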