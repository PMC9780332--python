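"""Declarative pipeline configuration with lossless YAML round-tripping.

One config object holds every tunable of the chain -- scene generation,
background subtraction, shape constraints, condensate calling, the experiment
design (variants x replicates x timepoints) and the global seed -- plus a
content hash stamped into every output so results are traceable to the exact
configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Union

import yaml

from .call import DEFAULT_CUTOFF, DEFAULT_THRESHOLD
from .segment import ShapeConstraints
from .synthdata import SceneParams


@dataclass
class SegmentationConfig:
    rolling_ball_radius_px: int = 100
    constraints: ShapeConstraints = field(default_factory=ShapeConstraints)


@dataclass
class CallingConfig:
    threshold: float = DEFAULT_THRESHOLD
    cutoff: float = DEFAULT_CUTOFF
    min_focus_px: int = 4
    disk_radius_px: int = 3
    sweep: tuple[float, float, float] = (1.05, 2.00, 0.05)  # lo, hi, step

    def validate(self) -> None:
        if self.threshold <= 1.0:
            raise ValueError(f"ratio threshold must exceed 1.0, got {self.threshold}")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff must be in (0, 1), got {self.cutoff}")
        if self.min_focus_px < 1:
            raise ValueError("min_focus_px must be >= 1")
        lo, hi, step = self.sweep
        if lo <= 1.0 or hi < lo or step <= 0:
            raise ValueError(f"invalid sweep specification {self.sweep}")


@dataclass
class VariantSpec:
    """One strain: its net charge and the true condensate fraction over time."""

    name: str
    net_charge: int
    fractions_by_time: dict[float, float]

    def validate(self) -> None:
        if not self.fractions_by_time:
            raise ValueError(f"variant {self.name!r} has no timepoints")
        for t, f in self.fractions_by_time.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"variant {self.name!r}: fraction {f} at t={t} outside [0, 1]")


@dataclass
class PipelineConfig:
    scene: SceneParams = field(default_factory=SceneParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    variants: list[VariantSpec] = field(default_factory=list)
    n_replicates: int = 3
    run_sweep: bool = True
    seed: int = 0

    def validate(self) -> None:
        self.scene.validate()
        self.calling.validate()
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.variants:
            raise ValueError("no variants configured")
        times = None
        for v in self.variants:
            v.validate()
            if times is None:
                times = set(v.fractions_by_time)
            elif set(v.fractions_by_time) != times:
                raise ValueError(f"variant {v.name!r} timepoints differ from the others")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        # YAML-friendly: stringify float timepoint keys
        for v in d["variants"]:
            v["fractions_by_time"] = {str(k): val for k, val in v["fractions_by_time"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        scene_d = dict(d.get("scene", {}))
        for key in (
            "image_shape", "cell_length_range", "cell_width_range",
            "condensate_radius_range",
        ):
            if key in scene_d and scene_d[key] is not None:
                scene_d[key] = tuple(scene_d[key])
        scene = SceneParams(**scene_d)

        seg_d = dict(d.get("segmentation", {}))
        cons_d = dict(seg_d.pop("constraints", {}))
        for key in ("area_px", "length_um", "width_um", "circularity"):
            if key in cons_d:
                cons_d[key] = tuple(cons_d[key])
        segmentation = SegmentationConfig(
            constraints=ShapeConstraints(**cons_d), **seg_d
        )

        call_d = dict(d.get("calling", {}))
        if "sweep" in call_d:
            call_d["sweep"] = tuple(call_d["sweep"])
        calling = CallingConfig(**call_d)

        variants = [
            VariantSpec(
                name=v["name"],
                net_charge=int(v["net_charge"]),
                fractions_by_time={float(k): float(val) for k, val in v["fractions_by_time"].items()},
            )
            for v in d.get("variants", [])
        ]
        return cls(
            scene=scene,
            segmentation=segmentation,
            calling=calling,
            variants=variants,
            n_replicates=int(d.get("n_replicates", 3)),
            run_sweep=bool(d.get("run_sweep", True)),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        """Short content hash of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    # -- canned experiment -------------------------------------------------

    @classmethod
    def demo(cls, seed: int = 0) -> "PipelineConfig":
        """A small nine-variant experiment emulating the tagged-GFP library.

        Three globular domains (charges -7, 0, +6; the -7 domain carries a +1
        lysine linker) each fused to one, two, or three tag repeats give
        fusion charges 0..+24 in steps of +6.  The true condensate-carrying
        fractions encode the observed phenomenology: fusions at or above +12
        keep condensates through the final timepoint, the +6 fusion on the
        anisotropic (-7) domain persists weakly, the +6 fusion on the neutral
        domain is transient, and the 0-charge fusion never assembles.
        """
        times = (2.0, 4.0, 6.0, 24.0)

        def schedule(values) -> dict[float, float]:
            return dict(zip(times, values))

        persistent = (0.55, 0.7, 0.8, 0.85)
        weak_persistent = (0.3, 0.45, 0.55, 0.55)
        transient = (0.03, 0.4, 0.65, 0.03)
        none = (0.02, 0.02, 0.02, 0.02)

        variants = [
            VariantSpec("sfGFP-tag1", 0, schedule(none)),
            VariantSpec("sfGFP-tag2", 6, schedule(weak_persistent)),
            VariantSpec("sfGFP-tag3", 12, schedule(persistent)),
            VariantSpec("GFP(0)-tag1", 6, schedule(transient)),
            VariantSpec("GFP(0)-tag2", 12, schedule(persistent)),
            VariantSpec("GFP(0)-tag3", 18, schedule(persistent)),
            VariantSpec("GFP(+6)-tag1", 12, schedule(persistent)),
            VariantSpec("GFP(+6)-tag2", 18, schedule(persistent)),
            VariantSpec("GFP(+6)-tag3", 24, schedule(persistent)),
        ]
        scene = SceneParams(image_shape=(320, 320), n_cells=18)
        return cls(scene=scene, variants=variants, n_replicates=3, seed=seed)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)
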