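"""Acquisition protocol constants shared by the simulator and the fitters.

The defaults reproduce a 3 T dynamic contrast-enhanced protocol built on a
3D spoiled gradient echo (SPGR / T1-FFE): variable-flip-angle T1 mapping at
2°/10°/20° with TR = 6.2 ms, then a dynamic run of 8 min 52 s at one frame
every 9.1 s with the gadolinium bolus injected 2 minutes after the start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner and protocol constants.

    Parameters
    ----------
    tr_ms:
        Repetition time of the SPGR sequence, milliseconds.
    flip_angles_deg:
        Flip angles of the variable-flip-angle T1-mapping acquisition,
        degrees, each in (0, 90].
    dynamic_flip_deg:
        Flip angle of the dynamic series (same SPGR readout), degrees.
    frame_interval_s:
        Temporal resolution of the dynamic series, seconds per frame.
    run_duration_s:
        Total length of the dynamic run, seconds.
    injection_time_s:
        Bolus injection time after the start of the dynamic run, seconds.
    relaxivity_r1:
        Longitudinal relaxivity of the contrast agent, s^-1 mM^-1.
    """

    tr_ms: float = 6.2
    flip_angles_deg: tuple[float, ...] = (2.0, 10.0, 20.0)
    dynamic_flip_deg: float = 20.0
    frame_interval_s: float = 9.1
    run_duration_s: float = 532.0  # 8 min 52 s
    injection_time_s: float = 120.0
    relaxivity_r1: float = 3.7

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ParameterError(f"tr_ms must be > 0, got {self.tr_ms}")
        if len(self.flip_angles_deg) == 0:
            raise ParameterError("at least one flip angle is required")
        for a in (*self.flip_angles_deg, self.dynamic_flip_deg):
            if not 0 < a <= 90:
                raise ParameterError(f"flip angle {a}° outside (0°, 90°]")
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be > 0")
        if not 0 <= self.injection_time_s < self.run_duration_s:
            raise ConfigurationError(
                "injection_time_s must lie within [0, run_duration_s): "
                f"got {self.injection_time_s} vs {self.run_duration_s}"
            )
        if self.relaxivity_r1 <= 0:
            raise ParameterError("relaxivity_r1 must be > 0")
        object.__setattr__(self, "flip_angles_deg", tuple(float(a) for a in self.flip_angles_deg))

    @property
    def n_frames(self) -> int:
        """Number of dynamic frames: floor(run/interval) + 1 (frame at t = 0)."""
        return math.floor(self.run_duration_s / self.frame_interval_s) + 1

    @property
    def frame_times_s(self) -> np.ndarray:
        """Frame timestamps, seconds; t = 0 at the first dynamic frame."""
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def baseline_frames(self) -> np.ndarray:
        """Indices of pre-injection frames, with one frame of guard.

        All frames strictly earlier than ``injection_time_s`` minus one frame
        interval, so that no partially enhanced frame enters the baseline.
        """
        t = self.frame_times_s
        return np.flatnonzero(t < self.injection_time_s - self.frame_interval_s)

    @property
    def injection_frame(self) -> int:
        """Index of the first frame acquired at or after injection."""
        return int(np.searchsorted(self.frame_times_s, self.injection_time_s))
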