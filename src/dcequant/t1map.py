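"""Pixel-wise baseline T1 and M0 estimation from multi-flip-angle SPGR data.

The primary estimator is the classical linearization (DESPOT1): plotting
y_i = S_i/sin(a_i) against x_i = S_i/tan(a_i) turns the SPGR steady-state
equation into a straight line with slope E1 = exp(-TR/T1) and intercept
M0 (1 - E1), so an unweighted least-squares line yields T1 = -TR/ln(E1)
and M0 = intercept/(1 - E1). Voxels whose fitted slope falls outside (0, 1)
have no physical T1 and are flagged rather than clamped. A nonlinear
refinement of the same two parameters is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .acquisition import AcquisitionParams
from .errors import InputError
from .phantom import spgr_signal

__all__ = ["ParametricMap", "fit_vfa", "fit_vfa_voxel", "fit_vfa_nonlinear", "map_t1_volume"]


@dataclass(frozen=True)
class ParametricMap:
    """3D map of a fitted quantity with a validity mask.

    ``values`` are finite wherever ``valid_mask`` is true; outside the mask
    they hold NaN sentinels.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    quantity_name: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != self.valid_mask.shape:
            raise InputError("values and valid_mask shapes differ")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise InputError(f"{self.quantity_name}: non-finite values inside valid mask")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


def fit_vfa(
    signals: np.ndarray,
    flip_angles_deg,
    tr_ms: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized linearized VFA fit.

    Parameters
    ----------
    signals:
        Array of shape ``(..., n_angles)``; any leading shape (a single
        voxel, a volume, a stack of replicates).

    Returns
    -------
    (t1_ms, m0, valid):
        Arrays of the leading shape. Invalid voxels (slope outside (0, 1),
        degenerate signals) carry NaN and ``valid = False``.
    """
    flips = np.asarray(flip_angles_deg, dtype=float)
    if flips.size < 2 or np.unique(flips).size < 2:
        raise InputError("VFA fitting needs at least 2 distinct flip angles")
    s = np.asarray(signals, dtype=float)
    if s.shape[-1] != flips.size:
        raise InputError(
            f"last axis of signals ({s.shape[-1]}) must match flip angle count ({flips.size})"
        )
    if np.any(s[np.isfinite(s)] < 0):
        raise InputError("signals must be >= 0")
    a = np.deg2rad(flips)
    y = s / np.sin(a)
    x = s / np.tan(a)
    n = flips.size
    sx, sy = x.sum(-1), y.sum(-1)
    sxx, sxy = (x * x).sum(-1), (x * y).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * sxx - sx**2
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n
        t1 = -tr_ms / np.log(slope)
        m0 = intercept / (1.0 - slope)
    valid = (
        np.isfinite(slope)
        & (slope > 0)
        & (slope < 1)
        & np.isfinite(t1)
        & (t1 > 0)
        & np.isfinite(m0)
    )
    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid, m0, np.nan)
    return t1, m0, valid


def fit_vfa_voxel(signals, flip_angles_deg, tr_ms: float) -> tuple[float, float, bool]:
    """Single-voxel convenience wrapper around :func:`fit_vfa`."""
    t1, m0, valid = fit_vfa(np.atleast_1d(np.asarray(signals, float)), flip_angles_deg, tr_ms)
    return float(t1), float(m0), bool(valid)


def fit_vfa_nonlinear(
    signals: np.ndarray,
    flip_angles_deg,
    tr_ms: float,
    t1_init: float = 1000.0,
    m0_init: float | None = None,
) -> tuple[float, float, bool]:
    """Two-parameter nonlinear least-squares SPGR fit for one voxel."""
    s = np.asarray(signals, dtype=float)
    flips = np.asarray(flip_angles_deg, dtype=float)
    if flips.size < 2:
        raise InputError("VFA fitting needs at least 2 distinct flip angles")
    m0_init = m0_init if m0_init is not None else max(s.max(), 1e-6) * 10

    def resid(p):
        m0, t1 = p
        return np.array([spgr_signal(m0, max(t1, 1e-3), f, tr_ms) for f in flips]) - s

    sol = least_squares(resid, x0=[m0_init, t1_init], bounds=([0, 1e-3], [np.inf, 1e5]))
    m0, t1 = sol.x
    ok = bool(sol.success and np.isfinite(t1) and t1 > 0)
    return float(t1), float(m0), ok


def default_signal_threshold(highest_flip_volume: np.ndarray) -> float:
    """5% of the 99th-percentile signal of the highest-flip-angle volume."""
    return 0.05 * float(np.percentile(highest_flip_volume, 99))


def map_t1_volume(
    vfa_volumes: np.ndarray,
    acquisition: AcquisitionParams,
    signal_threshold: float | None = None,
    nonlinear: bool = False,
) -> tuple[ParametricMap, ParametricMap]:
    """Fit T1 and M0 maps over a 4D multi-flip-angle stack.

    ``vfa_volumes`` has shape ``(x, y, z, n_angles)`` in the order of
    ``acquisition.flip_angles_deg``. Voxels whose highest-flip-angle signal
    falls below ``signal_threshold`` (default: 5% of that volume's 99th
    percentile) are masked out before fitting.
    """
    v = np.asarray(vfa_volumes, dtype=float)
    if v.ndim != 4:
        raise InputError(f"expected a 4D (x, y, z, angle) stack, got {v.ndim}D")
    if v.shape[-1] != len(acquisition.flip_angles_deg):
        raise InputError(
            f"stack has {v.shape[-1]} volumes but acquisition lists "
            f"{len(acquisition.flip_angles_deg)} flip angles"
        )
    hi = int(np.argmax(acquisition.flip_angles_deg))
    if signal_threshold is None:
        signal_threshold = default_signal_threshold(v[..., hi])
    in_mask = v[..., hi] >= signal_threshold
    t1, m0, fit_ok = fit_vfa(v, acquisition.flip_angles_deg, acquisition.tr_ms)
    if nonlinear:
        for idx in np.argwhere(in_mask & fit_ok):
            i, j, k = idx
            t1[i, j, k], m0[i, j, k], ok = fit_vfa_nonlinear(
                v[i, j, k], acquisition.flip_angles_deg, acquisition.tr_ms,
                t1_init=t1[i, j, k], m0_init=m0[i, j, k],
            )
            fit_ok[i, j, k] &= ok
    valid = in_mask & fit_ok
    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid, m0, np.nan)
    return (
        ParametricMap(t1, valid, "T1", "ms"),
        ParametricMap(m0, valid, "M0", "a.u."),
    )
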