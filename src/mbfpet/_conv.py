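"""Exact convolution of a piecewise-linear curve with an exponential kernel.

The one-tissue compartment response ``y(t) = ∫_0^t e^{-k2 (t-s)} c(s) ds``
satisfies the ODE ``y' = c - k2·y``.  For a piecewise-linear input ``c`` the
update over one sampling interval has a closed form, so ``y`` can be propagated
node-to-node with no discretization error, and frame averages follow from the
same ODE:  ``∫_a^b y dt = (∫_a^b c dt - (y(b) - y(a))) / k2``  for k2 > 0.

This module deliberately avoids any frame-scale discretization: the node grid
is the union of the curve's sample times and the frame edges, and all integrals
over that grid are analytic.
"""

from __future__ import annotations

import numpy as np

from .timing_io import BloodCurve, FrameSchedule

__all__ = ["FrameConvolver", "expconv"]


def _interval_update(
    y: np.ndarray, h: float, cl: float, cr: float, k2: np.ndarray
) -> np.ndarray:
    """Propagate y' = c - k2*y across one interval of width h (c linear cl→cr).

    ``k2`` is an array of strictly positive rates; ``y`` has matching shape.
    """
    e = np.exp(-k2 * h)
    i0 = -np.expm1(-k2 * h) / k2          # ∫_0^h e^{-k2 (h-s)} ds
    i1 = (h - i0) / k2                    # ∫_0^h s e^{-k2 (h-s)} ds
    slope = (cr - cl) / h
    return y * e + cl * i0 + slope * i1


class FrameConvolver:
    """Frame-averaged exponential convolution of one input curve.

    Precomputes the union node grid of ``curve`` sample times and ``schedule``
    frame edges on ``[0, T]`` so that repeated evaluations for many ``k2``
    values (the basis-function grid, or one ``k2`` per voxel during
    refinement) share all curve-dependent work.

    The input curve is treated as 0 before its first sample and constant after
    its last, matching :func:`mbfpet.timing_io.frame_average`.
    """

    def __init__(self, curve: BloodCurve, schedule: FrameSchedule):
        self.schedule = schedule
        t_end = schedule.total_end_s
        nodes = np.unique(
            np.concatenate(
                [[0.0], curve.time_s, schedule.start_s, schedule.end_s, [t_end]]
            )
        )
        nodes = nodes[(nodes >= 0.0) & (nodes <= t_end)]
        self.nodes = nodes
        self.c = np.interp(nodes, curve.time_s, curve.activity, left=0.0)
        self.h = np.diff(nodes)
        seg = 0.5 * (self.c[1:] + self.c[:-1]) * self.h
        self._cum_c = np.concatenate([[0.0], np.cumsum(seg)])
        self._start_idx = np.searchsorted(nodes, schedule.start_s)
        self._end_idx = np.searchsorted(nodes, schedule.end_s)
        # frame edges are grid nodes by construction
        assert np.allclose(nodes[self._start_idx], schedule.start_s)
        assert np.allclose(nodes[self._end_idx], schedule.end_s)
        self.int_c_frames = self._cum_c[self._end_idx] - self._cum_c[self._start_idx]
        self._favg_k0: np.ndarray | None = None

    def _edge_values(self, k2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """y at frame starts and ends, shape (n_frames, len(k2)); all k2 > 0."""
        n_frames = len(self.schedule)
        y_start = np.zeros((n_frames, k2.size))
        y_end = np.zeros((n_frames, k2.size))
        record: dict[int, list[tuple[np.ndarray, int]]] = {}
        for f, idx in enumerate(self._start_idx):
            record.setdefault(int(idx), []).append((y_start, f))
        for f, idx in enumerate(self._end_idx):
            record.setdefault(int(idx), []).append((y_end, f))
        y = np.zeros(k2.size)
        for target, f in record.get(0, []):
            target[f] = y
        for i in range(self.h.size):
            y = _interval_update(y, self.h[i], self.c[i], self.c[i + 1], k2)
            for target, f in record.get(i + 1, []):
                target[f] = y
        return y_start, y_end

    def _favg_zero_rate(self) -> np.ndarray:
        """Frame averages of the running integral of c (the k2 = 0 response)."""
        if self._favg_k0 is None:
            # y0 is piecewise quadratic; integrate each interval analytically
            y0 = self._cum_c
            slope = np.diff(self.c) / self.h
            iy = (
                y0[:-1] * self.h
                + 0.5 * self.c[:-1] * self.h**2
                + slope * self.h**3 / 6.0
            )
            cum_y = np.concatenate([[0.0], np.cumsum(iy)])
            num = cum_y[self._end_idx] - cum_y[self._start_idx]
            self._favg_k0 = num / self.schedule.duration_s
        return self._favg_k0

    def frame_avg(self, k2_per_s: np.ndarray | float) -> np.ndarray:
        """Frame-averaged ``∫_0^t e^{-k2 (t-s)} c(s) ds`` for each rate.

        Returns an array of shape ``(n_frames, len(k2_per_s))`` (or ``(n_frames,)``
        for scalar input).  Rates must be >= 0; the 0 limit is the running
        integral of the curve.
        """
        scalar = np.isscalar(k2_per_s)
        k2 = np.atleast_1d(np.asarray(k2_per_s, dtype=float))
        if np.any(k2 < 0):
            raise ValueError("k2 rates must be >= 0")
        out = np.empty((len(self.schedule), k2.size))
        pos = k2 > 0
        if np.any(pos):
            kp = k2[pos]
            y_start, y_end = self._edge_values(kp)
            dt = self.schedule.duration_s[:, None]
            out[:, pos] = (self.int_c_frames[:, None] - (y_end - y_start)) / (kp[None, :] * dt)
        if np.any(~pos):
            out[:, ~pos] = self._favg_zero_rate()[:, None]
        return out[:, 0] if scalar else out


def expconv(time_s: np.ndarray, values: np.ndarray, rate_per_s: float) -> np.ndarray:
    """``y(t_i) = ∫_0^{t_i} e^{-rate (t_i - s)} c(s) ds`` on the sample grid.

    ``c`` is the piecewise-linear interpolant of (time_s, values); integration
    starts at the first sample.  Used e.g. for exponential dispersion of blood
    curves, where the dispersed curve is ``rate * expconv(...)``.
    """
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if rate_per_s < 0:
        raise ValueError("rate must be >= 0")
    y = np.zeros_like(v)
    if rate_per_s == 0:
        h = np.diff(t)
        y[1:] = np.cumsum(0.5 * (v[1:] + v[:-1]) * h)
        return y
    k = np.asarray([rate_per_s])
    acc = np.zeros(1)
    for i in range(t.size - 1):
        acc = _interval_update(acc, t[i + 1] - t[i], v[i], v[i + 1], k)
        y[i + 1] = acc[0]
    return y
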