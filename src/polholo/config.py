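"""Run configuration and manifest plumbing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from polholo.phantom import PRESETS, DEFAULT_PIXEL_PITCH

__all__ = ["RunConfig", "config_hash"]


@dataclass
class RunConfig:
    """Validated end-to-end pipeline configuration with materialized defaults."""

    preset_experimental: str = "myocardium_aci"
    preset_control: str = "myocardium_chd"
    seed: int = 0
    n_per_group: int = 12
    grid_size: int = 256
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    carrier: tuple = (0.25, 0.25)
    ref_amplitude: float = 6.0
    quantize_bits: int | None = None
    dstep: float = float(np.pi / 40)
    rel_tol: float = 0.05
    cap_delta_t: float | None = None
    scales: tuple = tuple(range(2, 61, 2))
    component: str = "beta"  # map fed to the wavelet stage
    marker_stat: str = "z2"  # z1 or z2 at the selected small scale
    depol_degree: float | None = None  # None -> preset value
    out_dir: str = "polholo_run"

    def validate(self) -> "RunConfig":
        if self.preset_experimental not in PRESETS or self.preset_control not in PRESETS:
            raise ValueError(f"presets must be one of {sorted(PRESETS)}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.grid_size < 32:
            raise ValueError("grid_size must be >= 32")
        if not (0 < self.dstep <= np.pi):
            raise ValueError("dstep must be in (0, pi]")
        if not (0 < self.rel_tol < 1):
            raise ValueError("rel_tol must be in (0, 1)")
        u0, v0 = self.carrier
        if not (abs(u0) < 0.5 and abs(v0) < 0.5):
            raise ValueError("carrier must be below Nyquist")
        if self.component not in ("alpha", "beta"):
            raise ValueError("component must be alpha or beta")
        if self.marker_stat not in ("z1", "z2"):
            raise ValueError("marker_stat must be z1 or z2")
        if list(self.scales) != sorted(set(self.scales)) or min(self.scales) < 1:
            raise ValueError("scales must be strictly increasing positive")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["carrier"] = list(self.carrier)
        d["scales"] = list(self.scales)
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        if "carrier" in d:
            d["carrier"] = tuple(d["carrier"])
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        return RunConfig(**d).validate()


def config_hash(cfg: RunConfig) -> str:
    """Stable digest of the scientific configuration (output location excluded)."""
    d = cfg.to_dict()
    d.pop("out_dir", None)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
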