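"""Dynamic-series quantification: concentration, arrival, AUC90, ROI curves.

The dynamic SPGR signal is converted to gadolinium concentration by exact
algebraic inversion of the steady-state signal equation (no linearized
low-concentration approximation): given baseline T1 and M0 at a voxel,

    E1(t) = (M0 sin a - S(t)) / (M0 sin a - S(t) cos a),
    1/T1(t) = -ln(E1(t))/TR,   C(t) = (1/T1(t) - 1/T1_0) / r1.

The semi-quantitative vascularity metric is the initial area under the
concentration curve over the first 90 seconds after contrast arrival in
tissue (AUC90, reported in mM*min); rim and core regions of interest are
derived morphologically from the tumor mask, and region-averaged signal is
expressed as relative enhancement SI_rel(t) = (SI(t) - SI_base)/SI_base*100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acquisition import AcquisitionParams
from .errors import InputError, ParameterError
from .phantom import DynamicSeries
from .t1map import ParametricMap

__all__ = [
    "ConcentrationSeries",
    "EnhancementCurve",
    "RoiPair",
    "ArrivalResult",
    "HistogramResult",
    "signal_to_concentration",
    "detect_arrival",
    "auc90_voxel",
    "auc90_map",
    "auc90_histogram",
    "define_rim_core_rois",
    "relative_enhancement",
]


@dataclass(frozen=True)
class ConcentrationSeries:
    """4D gadolinium concentration (mM) on the dynamic grid."""

    data: np.ndarray
    times_s: np.ndarray
    arrival_index: int
    valid_mask: np.ndarray
    arrival_fell_back: bool = False

    def __post_init__(self) -> None:
        if self.data.shape[:3] != self.valid_mask.shape:
            raise InputError("valid_mask shape must match the spatial grid")
        if not 0 <= self.arrival_index < self.data.shape[-1]:
            raise InputError("arrival_index outside the frame range")


@dataclass(frozen=True)
class ArrivalResult:
    index: int
    fell_back: bool


@dataclass(frozen=True)
class EnhancementCurve:
    """ROI-averaged relative signal enhancement, percent."""

    times_s: np.ndarray
    si_rel_percent: np.ndarray
    roi_name: str

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.si_rel_percent):
            raise InputError("curve and time axis lengths differ")


@dataclass(frozen=True)
class RoiPair:
    rim_mask: np.ndarray
    core_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.rim_mask & self.core_mask):
            raise InputError("rim and core masks must be disjoint")
        if not self.rim_mask.any() or not self.core_mask.any():
            raise InputError("rim and core masks must both be non-empty")


def detect_arrival(
    conc: np.ndarray,
    baseline_frames: np.ndarray,
    k_sigma: float = 3.0,
    m_consecutive: int = 2,
    mask: np.ndarray | None = None,
    fallback_index: int | None = None,
) -> ArrivalResult:
    """Detect the contrast-arrival frame from the tissue-median curve.

    Arrival is the first frame after the baseline window at which the
    spatial median concentration (over ``mask``) exceeds ``k_sigma`` times
    the baseline standard deviation of that median curve for
    ``m_consecutive`` consecutive frames. If never triggered, falls back to
    ``fallback_index`` (typically the injection frame) with a flag.
    """
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    if baseline_frames.size < 2:
        raise InputError("arrival detection needs at least 2 baseline frames")
    if mask is None:
        mask = np.ones(conc.shape[:3], dtype=bool)
    curve = np.median(conc[mask], axis=0)
    base_sd = float(np.std(curve[baseline_frames]))
    threshold = max(k_sigma * base_sd, 1e-12)  # noiseless series: any nonzero rise
    start = int(baseline_frames.max()) + 1
    above = curve > threshold
    for i in range(start, len(curve) - m_consecutive + 1):
        if above[i : i + m_consecutive].all():
            return ArrivalResult(index=i, fell_back=False)
    if fallback_index is None:
        fallback_index = start
    warnings.warn("no contrast arrival detected; falling back to the injection frame")
    return ArrivalResult(index=int(fallback_index), fell_back=True)


def signal_to_concentration(
    series: DynamicSeries,
    t1_map: ParametricMap,
    m0_map: ParametricMap,
    acquisition: AcquisitionParams | None = None,
    arrival_index: int | None = None,
    k_sigma: float = 3.0,
    m_consecutive: int = 2,
    arrival_mask: np.ndarray | None = None,
) -> ConcentrationSeries:
    """Convert the dynamic signal series to a concentration series.

    Voxels lacking a valid baseline T1/M0, or where the inversion is
    undefined at any frame (signal at or beyond the SPGR asymptote
    M0 sin a), are excluded from the validity mask.
    """
    acq = acquisition or series.acquisition
    if acq.relaxivity_r1 <= 0:
        raise ParameterError("relaxivity_r1 must be > 0")
    a = np.deg2rad(acq.dynamic_flip_deg)
    valid = t1_map.valid_mask & m0_map.valid_mask
    s = series.data
    m0 = m0_map.values[..., None]
    sin_a, cos_a = np.sin(a), np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (m0 * sin_a - s) / (m0 * sin_a - s * cos_a)
        invertible = (e1 > 0) & (e1 < 1)
        r1_t = -np.log(np.where(invertible, e1, 0.5)) / (acq.tr_ms / 1000.0)  # s^-1
        conc = (r1_t - 1000.0 / t1_map.values[..., None]) / acq.relaxivity_r1
    valid = valid & invertible.all(axis=-1)
    conc = np.where(valid[..., None], conc, np.nan)
    arr_mask = valid if arrival_mask is None else (arrival_mask & valid)
    if arrival_index is None:
        res = detect_arrival(
            np.nan_to_num(conc),
            acq.baseline_frames,
            k_sigma=k_sigma,
            m_consecutive=m_consecutive,
            mask=arr_mask,
            fallback_index=acq.injection_frame,
        )
        arrival_index, fell_back = res.index, res.fell_back
    else:
        fell_back = False
    return ConcentrationSeries(conc, series.times_s, int(arrival_index), valid, fell_back)


def _auc_weights(times_s: np.ndarray, arrival_index: int, window_s: float = 90.0) -> np.ndarray:
    """Trapezoid quadrature weights over [t_arr, t_arr + window] in seconds.

    The window end rarely lands on a frame; the final partial interval is
    integrated against the linear interpolant between the bracketing frames.
    """
    times = np.asarray(times_s, dtype=float)
    t0 = times[arrival_index]
    t_end = t0 + window_s
    if t_end > times[-1] + 1e-9:
        raise InputError(
            f"AUC window ends at {t_end:.1f} s but the run stops at {times[-1]:.1f} s "
            f"({t_end - times[-1]:.1f} s short)"
        )
    w = np.zeros_like(times)
    j = arrival_index
    while j + 1 < len(times) and times[j + 1] <= t_end + 1e-9:
        h = times[j + 1] - times[j]
        w[j] += h / 2
        w[j + 1] += h / 2
        j += 1
    if times[j] < t_end - 1e-9:  # partial last interval
        h = times[j + 1] - times[j]
        tau = t_end - times[j]
        f = tau / h
        w[j] += tau / 2 * (2 - f)
        w[j + 1] += tau / 2 * f
    return w


def auc90_voxel(
    conc_curve: np.ndarray,
    times_s: np.ndarray,
    arrival_index: int,
    window_s: float = 90.0,
) -> float:
    """Initial area under one concentration curve, mM*min."""
    w = _auc_weights(times_s, arrival_index, window_s)
    return float(w @ np.asarray(conc_curve, dtype=float)) / 60.0


def auc90_map(
    conc: ConcentrationSeries,
    valid_mask: np.ndarray | None = None,
    window_s: float = 90.0,
) -> ParametricMap:
    """Voxel-wise AUC90 map (mM*min) inside the validity mask."""
    mask = conc.valid_mask if valid_mask is None else (conc.valid_mask & valid_mask)
    w = _auc_weights(conc.times_s, conc.arrival_index, window_s)
    values = np.tensordot(np.nan_to_num(conc.data), w, axes=([-1], [0])) / 60.0
    values = np.where(mask, values, np.nan)
    return ParametricMap(values, mask, "AUC90", "mM*min")


@dataclass(frozen=True)
class HistogramResult:
    counts: np.ndarray
    bin_edges: np.ndarray
    n_below: int
    n_above: int

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.n_below + self.n_above


def auc90_histogram(
    auc_map: ParametricMap,
    mask: np.ndarray | None = None,
    bin_edges: np.ndarray | None = None,
) -> HistogramResult:
    """Histogram of AUC90 values over a region, with out-of-range tallies.

    Counts (plus the below/above-range tallies) sum to the number of valid
    in-mask voxels. Bins follow numpy convention: [e0, e1), ..., last bin
    closed.
    """
    edges = np.asarray(bin_edges if bin_edges is not None else np.linspace(0.0, 2.0, 11), float)
    if np.any(np.diff(edges) <= 0):
        raise InputError("bin edges must be strictly increasing")
    region = auc_map.valid_mask if mask is None else (auc_map.valid_mask & mask)
    vals = auc_map.values[region]
    if vals.size == 0:
        warnings.warn("empty mask: histogram has no samples")
        return HistogramResult(np.zeros(len(edges) - 1, int), edges, 0, 0)
    counts, _ = np.histogram(vals, bins=edges)
    n_below = int(np.sum(vals < edges[0]))
    n_above = int(np.sum(vals > edges[-1]))
    return HistogramResult(counts, edges, n_below, n_above)


def _ball(radius: int) -> np.ndarray:
    g = np.ogrid[-radius : radius + 1, -radius : radius + 1, -radius : radius + 1]
    return (g[0] ** 2 + g[1] ** 2 + g[2] ** 2) <= radius**2


def define_rim_core_rois(tumor_mask: np.ndarray, rim_width_vox: int = 2) -> RoiPair:
    """Split a tumor mask into an outer rim shell and an inner core.

    The core is the tumor mask eroded by a Euclidean ball of radius
    ``rim_width_vox`` (border treated as foreground, so a tumor truncated by
    the volume edge does not erode at that face); the rim is the remainder.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise InputError("tumor mask is empty")
    if rim_width_vox < 1:
        raise InputError("rim_width_vox must be >= 1")
    core = ndimage.binary_erosion(tumor_mask, structure=_ball(int(rim_width_vox)), border_value=1)
    if not core.any():
        raise InputError(
            f"eroding by {rim_width_vox} voxels empties the core; use a smaller rim width"
        )
    return RoiPair(rim_mask=tumor_mask & ~core, core_mask=core)


def relative_enhancement(
    series: DynamicSeries,
    roi_mask: np.ndarray,
    baseline_frames: np.ndarray | None = None,
    roi_name: str = "",
) -> EnhancementCurve:
    """ROI-averaged relative signal enhancement SI_rel(t), percent.

    The ROI-mean signal SI(t) is formed first; SI_base is its average over
    the pre-injection baseline frames, and
    SI_rel(t) = (SI(t) - SI_base)/SI_base * 100%.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise InputError("ROI mask is empty")
    if baseline_frames is None:
        baseline_frames = series.acquisition.baseline_frames
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    if baseline_frames.size == 0:
        raise InputError("no baseline frames given")
    si = series.data[roi_mask].mean(axis=0)
    si_base = float(si[baseline_frames].mean())
    if si_base == 0:
        raise InputError("SI_base is zero (air ROI?); relative enhancement undefined")
    si_rel = (si - si_base) / si_base * 100.0
    return EnhancementCurve(series.times_s, si_rel, roi_name)
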