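"""Run configuration: every tunable of the pipeline with a default.

The configuration round-trips losslessly through YAML so that a pipeline
run is fully described by one file plus a seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .acquisition import AcquisitionParams
from .phantom import AIFParams


def _plain(obj):
    """Tuples -> lists recursively, so YAML can represent the config."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass(frozen=True)
class RunConfig:
    """All parameters of a simulate-fit-quantify run."""

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    aif: AIFParams = field(default_factory=AIFParams)
    # phantom geometry
    shape_vox: tuple[int, int, int] = (32, 32, 8)
    core_radius_vox: float = 5.0
    rim_width_vox: int = 2
    voxel_size_mm: tuple[float, float, float] = (0.6, 0.6, 1.0)
    # noise: explicit sigma wins; otherwise derived from the rim-baseline SNR
    noise_sigma: float | None = None
    snr: float = 50.0
    # analysis parameters
    signal_threshold: float | None = None
    arrival_k_sigma: float = 3.0
    arrival_m_consecutive: int = 2
    auc_window_s: float = 90.0
    histogram_edges: tuple[float, ...] = tuple(round(0.2 * i, 10) for i in range(11))
    seed: int = 0

    def to_dict(self) -> dict:
        return _plain(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "acquisition" in d and isinstance(d["acquisition"], dict):
            acq = dict(d["acquisition"])
            if "flip_angles_deg" in acq:
                acq["flip_angles_deg"] = tuple(acq["flip_angles_deg"])
            d["acquisition"] = AcquisitionParams(**acq)
        if "aif" in d and isinstance(d["aif"], dict):
            a = dict(d["aif"])
            for key in ("decay_amplitudes", "decay_rates_per_min"):
                if key in a:
                    a[key] = tuple(a[key])
            d["aif"] = AIFParams(**a)
        for key in ("shape_vox", "voxel_size_mm", "histogram_edges"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
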