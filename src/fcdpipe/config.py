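"""Pipeline configuration: every tunable of the analysis, with defaults
equal to the study parameters (r = 0.25, 3/25 mm radii, 0.01-0.08 Hz band,
10 discarded volumes, 8 mm smoothing, voxel p = 0.05, alpha = 0.05).

Serialized as a flat YAML mapping with dotted-path keys
(e.g. ``fcd.r_threshold: 0.25``); unknown keys are rejected and the
round trip is lossless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .images import FcdPipeError
from .synth import (
    GROUPS,
    CohortConfig,
    ConnectivitySpec,
    GroupEffects,
    default_hub_layout,
)


@dataclass
class SynthSection:
    grid_shape: list = field(default_factory=lambda: [12, 12, 12])
    voxel_size_mm: float = 3.0
    n_volumes: int = 100
    tr_s: float = 2.0
    n_control: int = 8
    n_nonhe: int = 8
    n_mhe: int = 8
    local_coupling: float = 0.5
    pair_local_coupling: float = 0.0
    distant_coupling: float = 0.35
    region_radius_mm: float = 3.0
    noise_sd: float = 1.0
    patient_local_multiplier: float = 1.0
    mhe_distant_cortical_multiplier: float = 1.0
    mhe_distant_subcortical_multiplier: float = 1.0
    motion_spike_rate: float = 0.01


@dataclass
class PreprocessSection:
    n_discard: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.08
    use_global: bool = True
    max_trans_mm: float = 1.0
    max_rot_deg: float = 1.0
    fd_threshold_mm: float = 0.5


@dataclass
class FcdSection:
    r_threshold: float = 0.25
    local_radius_mm: float = 3.0
    distant_radius_mm: float = 25.0
    block_size: int = 512
    normalize_per_map: bool = True


@dataclass
class StatsSection:
    smooth_fwhm_mm: float = 8.0
    voxel_p: float = 0.05
    alpha: float = 0.05
    connectivity: int = 18
    n_iterations: int = 1000
    null_pool_size: int = 200


@dataclass
class CorrelateSection:
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    """All pipeline knobs, grouped in sections."""

    seed: int = 0
    synth: SynthSection = field(default_factory=SynthSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    fcd: FcdSection = field(default_factory=FcdSection)
    stats: StatsSection = field(default_factory=StatsSection)
    correlate: CorrelateSection = field(default_factory=CorrelateSection)

    # --- flat dotted-path serialization ----------------------------------

    def to_flat_dict(self) -> dict:
        out = {"seed": self.seed}
        for section in ("synth", "preprocess", "fcd", "stats", "correlate"):
            obj = getattr(self, section)
            for f in dataclasses.fields(obj):
                val = getattr(obj, f.name)
                out[f"{section}.{f.name}"] = list(val) if isinstance(val, tuple) else val
        return out

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "PipelineConfig":
        cfg = cls()
        known = set(cfg.to_flat_dict())
        unknown = set(flat) - known
        if unknown:
            raise FcdPipeError(f"unknown config keys: {sorted(unknown)}")
        for key, val in flat.items():
            if key == "seed":
                cfg.seed = int(val)
                continue
            section, name = key.split(".", 1)
            obj = getattr(cfg, section)
            current = getattr(obj, name)
            if isinstance(current, bool):
                val = bool(val)
            elif isinstance(current, int) and not isinstance(val, bool):
                val = int(val)
            elif isinstance(current, float):
                val = float(val)
            setattr(obj, name, val)
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        if not isinstance(flat, dict):
            raise FcdPipeError("config file must be a flat key/value mapping")
        return cls.from_flat_dict(flat)

    # --- derived objects ---------------------------------------------------

    def connectivity_spec(self) -> ConnectivitySpec:
        s = self.synth
        hubs, pairs = default_hub_layout(tuple(s.grid_shape), s.voxel_size_mm)
        paired = {h for pair in pairs for h in pair}
        local_c = [
            s.pair_local_coupling if i in paired else s.local_coupling
            for i in range(len(hubs))
        ]
        return ConnectivitySpec(
            grid_shape=tuple(s.grid_shape), voxel_size_mm=s.voxel_size_mm,
            n_volumes=s.n_volumes, tr_s=s.tr_s, hub_seeds=hubs, hub_pairs=pairs,
            local_coupling=local_c, distant_coupling=s.distant_coupling,
            noise_sd=s.noise_sd, region_radius_mm=s.region_radius_mm,
            distant_radius_mm=self.fcd.distant_radius_mm,
            motion_spike_rate=s.motion_spike_rate,
        )

    def group_effects(self) -> dict:
        s = self.synth
        return {
            "control": GroupEffects(group="control"),
            "nonHE": GroupEffects(
                group="nonHE", local_coupling_multiplier=s.patient_local_multiplier,
            ),
            "MHE": GroupEffects(
                group="MHE", local_coupling_multiplier=s.patient_local_multiplier,
                distant_cortical_multiplier=s.mhe_distant_cortical_multiplier,
                distant_subcortical_multiplier=s.mhe_distant_subcortical_multiplier,
            ),
        }

    def cohort_config(self) -> CohortConfig:
        s = self.synth
        sizes = {"control": s.n_control, "nonHE": s.n_nonhe, "MHE": s.n_mhe}
        sizes = {g: n for g, n in sizes.items() if n > 0 and g in GROUPS}
        return CohortConfig(
            group_sizes=sizes, spec=self.connectivity_spec(),
            effects=self.group_effects(),
        )
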