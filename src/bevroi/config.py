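"""Run configuration: one serializable object covering every stage.

Every source of randomness must carry an explicit seed; validation fails
before any computation otherwise.  Configs round-trip through YAML/JSON
unchanged and hash deterministically, and every artifact a run writes
records the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .apertures import SearchConfig
from .phantom import PhantomSpec
from .projection import ArcSpec, three_arc_geometry

__all__ = ["DetectorSpec", "RegistrationConfig", "TraceSpec", "RunConfig"]


@dataclass
class DetectorSpec:
    pixels: tuple[int, int] = (1190, 1190)
    panel_pitch_mm: float = 0.336


@dataclass
class RegistrationConfig:
    bins: int = 50
    bound_mm: float = 3.0
    refine_tol_mm: float = 0.005
    # recorded for provenance: the clinical platform's optimizer setting;
    # the deterministic grid-refinement optimizer does not use it
    initial_radius: float = 6.25e-4


@dataclass
class TraceSpec:
    kind: str = "none"  # 'none' | 'linear-drift' | 'sudden-shift'
    magnitude_mm: float = 1.5
    onset: int | None = None


@dataclass
class RunConfig:
    seed: int | None = None
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    arcs: list[ArcSpec] = field(default_factory=three_arc_geometry)
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    search: SearchConfig = field(default_factory=SearchConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    trace: TraceSpec = field(default_factory=TraceSpec)
    threshold: str = "60"
    mu_water: float = 0.00505

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("RunConfig.seed must be set explicitly")
        for name, s in (("phantom", self.phantom.seed), ("search", self.search.seed)):
            if s is None:
                raise ValueError(f"{name} seed must be set explicitly")
        if self.threshold != "open":
            level = float(self.threshold)
            if not (0 < level <= 100):
                raise ValueError("threshold must be 'open' or a level in (0, 100]")

    @classmethod
    def desk_scale(cls, seed: int) -> "RunConfig":
        """Reduced problem size for single-CPU runs: 1 mm voxels, 15-degree
        control-point spacing, 0.75 mm panel pitch, 300-aperture search
        with a 3x3 scoring grid."""
        return cls(
            seed=seed,
            phantom=PhantomSpec(voxel_spacing=1.0, seed=seed),
            arcs=three_arc_geometry(spacing_deg=15.0),
            detector=DetectorSpec(pixels=(544, 544), panel_pitch_mm=0.75),
            search=SearchConfig(
                n_apertures=300, grid_half_width_mm=1.8, grid_n=3, seed=seed
            ),
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["phantom"] = PhantomSpec(**_tupled(d.get("phantom", {}),
                                             ("outer_semi_axes", "sinus_size_range")))
        d["arcs"] = [ArcSpec(**a) for a in d.get("arcs", [])]
        d["detector"] = DetectorSpec(**_tupled(d.get("detector", {}), ("pixels",)))
        d["search"] = SearchConfig(
            **_tupled(d.get("search", {}), ("area_range_cm2", "aspect_range"))
        )
        d["registration"] = RegistrationConfig(**d.get("registration", {}))
        d["trace"] = TraceSpec(**d.get("trace", {}))
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        try:
            is_file = Path(source).is_file()
        except (OSError, TypeError):
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _asdict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def _tupled(d: dict, keys) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d
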