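"""Pipeline configuration.

All tunable parameters live in one nested dataclass schema with physical
units spelled out in the field names (``_um`` = micrometres, ``_um3`` =
cubic micrometres).  Most geometric defaults are derived from a single
``nominal_radius_um`` -- the typical nucleus radius of the organism being
tracked -- so that a user normally only has to set that one number.
Configs round-trip through a single YAML document.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class DeconvolveConfig:
    enabled: bool = False
    psf_path: str | None = None
    iterations: int = 20


@dataclass
class RegisterConfig:
    enabled: bool = False


@dataclass
class FlowConfig:
    enabled: bool = False
    block_size: int = 16


@dataclass
class PreprocessConfig:
    deconvolve: DeconvolveConfig = field(default_factory=DeconvolveConfig)
    register: RegisterConfig = field(default_factory=RegisterConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)


@dataclass
class DetectConfig:
    """Nucleus detection parameters.

    ``scales_um`` defaults to ``{0.5, 0.75, 1.0, 1.5} x nominal_radius_um``
    when left empty.  ``z_threshold`` is the significance z-score below
    which a candidate region is rejected as background.
    """

    scales_um: list[float] = field(default_factory=list)
    z_threshold: float = 4.0
    # volume gates; non-positive values derive from the nominal radius as
    # 0.2x and 10x the nominal nucleus volume
    min_volume_um3: float = 0.0
    max_volume_um3: float = 0.0
    gradient_sigma: float = 10.0  # sigma_g of the min-cut boundary term (intensity units)
    max_local_max_floor: float = 1e-12


@dataclass
class LinkConfig:
    """Minimum-cost-circulation linking parameters.

    Gating radius and motion sigma default to multiples of the nominal
    nucleus radius.  ``strict_factor`` shrinks the gate for the
    high-confidence "tracklet" pass used inside the correction loop.
    """

    sigma_motion_um: float = 0.0  # 0 -> nominal radius
    gating_radius_um: float = 0.0  # 0 -> 3 x nominal radius (per unit gap)
    g_max: int = 2
    c_skip: float = 1.0
    c_border: float = 4.0
    div_discount: float = 0.25
    strict_factor: float = 1.5  # strict gate = strict_factor x nominal radius
    volume_weight: float = 1.0
    knn_transitions: int = 4
    knn_div: int = 3


@dataclass
class CorrectConfig:
    max_iterations: int = 5
    redetect_relax: float = 0.5  # rho: relaxed threshold = rho * z_threshold
    volume_tolerance: float = 0.3  # tau: +-30% volume agreement for merge proposals
    underseg_gamma: float = 1.6  # split proposal when volume > gamma * track median
    window_frames: int = 3


@dataclass
class LineageConfig:
    tracklet_gap_max: int = 3
    relax_factor: float = 2.0
    division_min_parent_len: int = 5
    division_child_volume_frac: tuple[float, float] = (0.3, 0.7)
    batch_size: int = 0  # 0 -> no batching
    batch_overlap: int = 5


@dataclass
class PipelineConfig:
    nominal_radius_um: float = 2.75
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    link: LinkConfig = field(default_factory=LinkConfig)
    correct: CorrectConfig = field(default_factory=CorrectConfig)
    lineage: LineageConfig = field(default_factory=LineageConfig)

    def __post_init__(self) -> None:
        if self.nominal_radius_um <= 0:
            raise ValueError("nominal_radius_um must be > 0")
        if self.correct.max_iterations < 1:
            raise ValueError("correct.max_iterations must be >= 1")
        if self.link.g_max < 1:
            raise ValueError("link.g_max must be >= 1")
        if not self.detect.scales_um:
            self.detect.scales_um = [
                f * self.nominal_radius_um for f in (0.5, 0.75, 1.0, 1.5)
            ]
        if any(s <= 0 for s in self.detect.scales_um):
            raise ValueError("detection scales must be > 0")
        if self.link.sigma_motion_um <= 0:
            self.link.sigma_motion_um = self.nominal_radius_um
        if self.link.gating_radius_um <= 0:
            self.link.gating_radius_um = 3.0 * self.nominal_radius_um
        nominal_volume = 4.0 / 3.0 * 3.141592653589793 * self.nominal_radius_um**3
        if self.detect.min_volume_um3 <= 0:
            self.detect.min_volume_um3 = 0.2 * nominal_volume
        if self.detect.max_volume_um3 <= 0:
            self.detect.max_volume_um3 = 10.0 * nominal_volume

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        def build(tp, d):
            if not dataclasses.is_dataclass(tp):
                return d
            kwargs = {}
            fields = {f.name: f for f in dataclasses.fields(tp)}
            for key, val in (d or {}).items():
                if key not in fields:
                    raise KeyError(f"unknown config key: {key!r}")
                ftype = fields[key].type
                sub = _SECTION_TYPES.get((tp.__name__, key))
                if sub is not None:
                    kwargs[key] = build(sub, val)
                elif key == "division_child_volume_frac":
                    kwargs[key] = tuple(val)
                else:
                    kwargs[key] = val
            return tp(**kwargs)

        return build(cls, data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


_SECTION_TYPES = {
    ("PipelineConfig", "preprocess"): PreprocessConfig,
    ("PipelineConfig", "detect"): DetectConfig,
    ("PipelineConfig", "link"): LinkConfig,
    ("PipelineConfig", "correct"): CorrectConfig,
    ("PipelineConfig", "lineage"): LineageConfig,
    ("PreprocessConfig", "deconvolve"): DeconvolveConfig,
    ("PreprocessConfig", "register"): RegisterConfig,
    ("PreprocessConfig", "flow"): FlowConfig,
}
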