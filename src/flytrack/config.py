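"""Pipeline configuration: every tunable of the tracking pipeline, with
documented defaults, YAML round-trip and validation."""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclasses.dataclass
class PipelineConfig:
    """All tunables of the background/detection/tracking pipeline.

    Defaults follow the published operating point where one exists
    (``n_sigma = 10``, ``c_clean = 15``, ``c_mad = 1.4826``, probation of 50
    frames at 15 fps); the remaining values are engineering defaults,
    exposed here precisely because they are judgement calls.
    """

    # acquisition
    fps: float = 15.0
    seed: int = 0
    # pre-processing
    smooth_sigma: float = 1.0  # Gaussian pre-filter sd (px); 0 disables
    polarity: str = "dark"  # dark | bright | both
    # background model
    n_sigma: float = 10.0  # front-detection threshold multiplier N
    c_mad: float = 1.4826  # MAD -> sigma consistency constant
    sigma_floor: float = 1.0  # intensity units
    update_period: int = 100  # frames between selective updates; 0 disables
    learning_rate: float = 0.05
    warmup_frames: int = 100
    # area model / validation
    c_clean: float = 15.0  # cleaning multiplier in th_min = mu - c*sigma
    area_sigma_rel_floor: float = 0.15
    acceptance_floor: float = math.exp(-3.0)
    threshold_growth: float = 1.6  # geometric step of the re-threshold search
    max_steps: int = 8
    improvement: float = 1.05
    # plate / reflections
    plate_detect: bool = True
    plate: tuple[float, float, float] | None = None  # (cx, cy, r) override
    reflection_band_px: float = 12.0
    # Kalman process / measurement noise (px, px/frame, rad units, squared)
    q_pos: float = 0.25
    q_vel: float = 1.0
    q_ang: float = 0.01
    q_angvel: float = 0.01
    r_pos: float = 0.25
    r_vel: float = 1.0
    r_ang: float = 0.01
    r_angvel: float = 0.04
    merge_r_inflate: float = 100.0
    # assignment and lifecycle
    gate: float = 4.0  # Mahalanobis gate on the position marginal
    gate_sigma_floor: float = 2.0  # px; minimum prediction spread in the gate
    probation: int = 50  # frames of stability testing for new trackers
    max_coast: int = 15  # 1 s at 15 fps
    max_wait: int = 450  # 30 s at 15 fps
    wait_sigma: float = 20.0  # px; position spread of a waiting tracker
    velocity_window: int = 5
    velocity_decay: float = 0.7
    static_speed: float = 0.5  # px/frame below which a cluster counts as static
    kmeans_area_ratio: float = 1.4
    min_split_sep: float = 4.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_sigma < 0:
            raise ValueError("n_sigma must be >= 0")
        if self.polarity not in ("dark", "bright", "both"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.c_clean < 0 or self.c_mad <= 0:
            raise ValueError("c_clean must be >= 0 and c_mad > 0")
        if self.update_period < 0 or self.warmup_frames < 3:
            raise ValueError("update_period >= 0 and warmup_frames >= 3 required")
        if not (0.0 < self.acceptance_floor <= 1.0):
            raise ValueError("acceptance_floor must be in (0, 1]")
        if min(self.q_pos, self.q_vel, self.q_ang, self.q_angvel,
               self.r_pos, self.r_vel, self.r_ang, self.r_angvel) <= 0:
            raise ValueError("Q/R scales must be positive")
        if self.gate <= 0 or self.probation < 0 or self.max_coast < 0 or self.max_wait < 0:
            raise ValueError("gate > 0 and non-negative lifecycle limits required")
        if self.plate is not None:
            self.plate = tuple(float(v) for v in self.plate)  # type: ignore[assignment]
            if len(self.plate) != 3 or self.plate[2] <= 0:
                raise ValueError("plate override must be (cx, cy, r) with r > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if d["plate"] is not None:
            d["plate"] = list(d["plate"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
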