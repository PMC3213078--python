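"""Analysis configuration.

Holds the geometric parameters of the tracing/detection pipeline. The two
named parameter sets mirror the acquisition modes the method was designed
around:

* **fixed mode** — fixed, deconvolved widefield stacks of mature neurons:
  minimum spine end diameter 0.215 um (2x the in-plane pixel width) and
  maximum spine length 5 um.
* **live mode** — confocal time-lapse of younger neurons: minimum spine end
  diameter 0.3 um and maximum spine length 15 um, so that dendritic
  filopodia are included.

All lengths are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field, fields

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    #: smallest local diameter a skeleton voxel may have and still be part of
    #: the dendrite backbone (um)
    min_dendrite_end_diameter: float = 0.75
    #: smallest tip diameter a protrusion may have and still count as a spine
    min_spine_end_diameter: float = 0.215
    #: protrusions longer than this (shaft surface to tip) are not spines
    max_spine_length: float = 5.0
    #: stubby/thin length boundary (stubby iff length <= this)
    stubby_length_max: float = 1.0
    #: mushroom iff head_width / neck_width >= this
    class_ratio_threshold: float = 1.5
    #: maximum attachment displacement (um) for linking spines across frames
    tracking_gate: float = 1.0
    #: weight of the azimuthal term in the tracking cost (um per half-turn)
    azimuth_cost_weight: float = 0.5
    #: automatic threshold selector; only "otsu" is implemented
    threshold_method: str = "otsu"
    #: hysteresis low threshold as a fraction of the automatic threshold
    #: (above background); dim voxels connected to bright structure are kept
    hysteresis_low_fraction: float = 0.5
    #: Gaussian pre-smoothing applied before thresholding (um); mild default
    #: denoising, roughly half an in-plane voxel
    presmooth_sigma_um: float = 0.05
    #: skeleton side branches protruding less than this beyond the dendrite
    #: surface are treated as surface roughness, not spines
    min_protrusion_um: float = 0.2
    #: minimum median occupancy over the distal half of a candidate branch;
    #: separates genuine protrusions (bright core, possibly dimmed by the
    #: PSF) from noise fuzz riding the segmentation's hysteresis shell
    min_tip_occupancy: float = 0.35
    #: the tip diameter used by the detection filter is the maximum local
    #: diameter over this much trailing arclength of the spine path
    tip_window_um: float = 0.3
    #: fraction of the spine path (distal end) searched for the head maximum
    head_fraction: float = 0.5
    #: moving-average window used to smooth the centerline polyline (um)
    smoothing_window_um: float = 0.5

    # -- named modes ------------------------------------------------------
    @classmethod
    def fixed(cls) -> "AnalysisConfig":
        """Parameters for fixed-neuron stacks (default)."""
        return cls()

    @classmethod
    def live(cls) -> "AnalysisConfig":
        """Parameters for live time-lapse series (includes filopodia)."""
        return cls(min_spine_end_diameter=0.3, max_spine_length=15.0)

    @classmethod
    def from_mode(cls, mode: str) -> "AnalysisConfig":
        if mode == "fixed":
            return cls.fixed()
        if mode == "live":
            return cls.live()
        raise ValueError(f"unknown mode {mode!r}; expected 'fixed' or 'live'")

    # -- validation / IO --------------------------------------------------
    def validate(self) -> "AnalysisConfig":
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "threshold_method":
                if v != "otsu":
                    raise ValueError(f"unsupported threshold_method {v!r}")
                continue
            if f.name == "presmooth_sigma_um":
                if v < 0:
                    raise ValueError("presmooth_sigma_um must be >= 0")
                continue
            if not v > 0:
                raise ValueError(f"{f.name} must be positive, got {v}")
        if not self.min_spine_end_diameter < self.min_dendrite_end_diameter:
            raise ValueError(
                "min_spine_end_diameter must be < min_dendrite_end_diameter"
            )
        if not self.stubby_length_max < self.max_spine_length:
            raise ValueError("stubby_length_max must be < max_spine_length")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()
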