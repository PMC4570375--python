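"""Synthetic arena videos with ground truth.

Emulates the published imaging conditions — a bright backlit circular plate
(radius 180 px at 4 px/mm, i.e. a 4.5 cm dish), 8 flies (0.12 flies/cm^2),
15 fps — with dark elliptical fly blobs, additive Gaussian pixel noise,
optional slow sinusoidal illumination drift, and optional specular
"reflection" artifacts at the plate boundary.

Flies are rendered as anisotropic Gaussian darkening profiles because the
segmentation explicitly models fly brightness as 2-D Gaussians: a fly with
nominal half-axes ``(a, b)`` is drawn with profile standard deviations
``(a/2, b/2)``, making the weighted-covariance ellipse fit's targets
analytic. Motion is a smooth heading-persistent random walk with specular
reflection at the wall; scripted events force crossings, stop-and-merge
episodes and boundary reflections so the merge/split and lifecycle logic
can be exercised deterministically.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "crossing_event",
    "stop_and_merge_event",
    "reflection_event",
    "simulate_trajectories",
    "render_frame",
    "render_sequence",
    "generate_dataset",
]


@dataclasses.dataclass
class SceneConfig:
    """Arena geometry, imaging conditions and motion parameters."""

    width: int = 480
    height: int = 480
    plate_center: tuple[float, float] | None = None  # defaults to frame centre
    plate_radius: float = 180.0  # px; 4.5 cm at 4 px/mm
    n_flies: int = 8
    fps: float = 15.0
    background_level: float = 220.0
    outside_level: float = 60.0
    fly_contrast: float = 120.0  # peak darkening below the plate level
    fly_axes: tuple[float, float] = (6.0, 3.0)  # nominal half-axes (px)
    noise_sd: float = 3.0  # additive Gaussian pixel noise
    drift_amplitude: float = 0.0  # slow illumination drift (intensity units)
    drift_period: float = 500.0  # frames
    speed_range: tuple[float, float] = (1.0, 3.0)  # px/frame (~4-11 mm/s)
    heading_noise: float = 0.15  # rad/frame
    wall_margin: float = 12.0  # px the walk keeps away from the wall
    min_separation: float = 0.0  # px; >0 makes flies avoid each other
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 0 or self.noise_sd < 0:
            raise ValueError("n_flies and noise_sd must be non-negative")
        cx, cy = self.center
        r = self.plate_radius
        if cx - r < -1 or cy - r < -1 or cx + r > self.width or cy + r > self.height:
            raise ValueError("plate does not fit in the frame")

    @property
    def center(self) -> tuple[float, float]:
        if self.plate_center is not None:
            return tuple(self.plate_center)  # type: ignore[return-value]
        return ((self.width - 1) / 2.0, (self.height - 1) / 2.0)

    def density_flies_per_cm2(self, px_per_mm: float = 4.0) -> float:
        """Fly density implied by the geometry, at the given image resolution."""
        r_cm = self.plate_radius / px_per_mm / 10.0
        return self.n_flies / (math.pi * r_cm**2)


def crossing_event(frame: int, flies: tuple[int, int],
                   point: tuple[float, float] | None = None,
                   angle: float = math.pi / 2) -> dict:
    """Force two flies through a common point at ``frame`` on transversal
    straight paths.

    ``angle`` is the minimum angle between the two approach bearings: a
    trajectory crossing requires the paths to actually intersect
    transversally; two flies converging from the same side would form a
    co-moving pair instead (use :func:`stop_and_merge_event` for prolonged
    proximity).
    """
    return {"kind": "crossing", "frame": frame, "flies": tuple(flies),
            "point": point, "angle": angle}


def stop_and_merge_event(frame: int, flies: tuple[int, int], duration: int = 30,
                         point: tuple[float, float] | None = None) -> dict:
    """Two flies meet at ``frame``, stop overlapped for ``duration``, then part."""
    return {"kind": "stop_and_merge", "frame": frame, "flies": tuple(flies),
            "duration": duration, "point": point}


def reflection_event(frame: int, duration: int = 2,
                     position: tuple[float, float] | None = None) -> dict:
    """A spurious reflection blob at the plate boundary for ``duration`` frames."""
    return {"kind": "reflection", "frame": frame, "duration": duration,
            "position": position}


@dataclasses.dataclass
class GroundTruth:
    """Per-frame, per-fly true state with persistent identities."""

    x: np.ndarray  # (T, n)
    y: np.ndarray
    theta: np.ndarray  # heading, rad
    vx: np.ndarray  # px/frame
    vy: np.ndarray
    w: np.ndarray  # rad/frame
    overlaps: list[list[tuple[int, int]]]  # per frame: index pairs whose blobs merge
    reflections: list[tuple[int, float, float]]  # (frame, x, y) scripted artifacts

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_flies(self) -> int:
        return self.x.shape[1]

    def to_dataframe(self, fps: float = 15.0) -> pd.DataFrame:
        rows = []
        for t in range(self.n_frames):
            flagged = set()
            for i, j in self.overlaps[t]:
                flagged.update((i, j))
            for i in range(self.n_flies):
                rows.append(
                    [t, t / fps, i, self.x[t, i], self.y[t, i], self.theta[t, i],
                     self.vx[t, i], self.vy[t, i], self.w[t, i], i in flagged]
                )
        return pd.DataFrame(
            rows,
            columns=["frame", "time_s", "true_id", "x", "y", "theta",
                     "vx", "vy", "w", "overlap"],
        )


def _initial_positions(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    cx, cy = cfg.center
    rmax = cfg.plate_radius - cfg.wall_margin - 2 * cfg.fly_axes[0]
    min_sep = 6 * cfg.fly_axes[0]
    pos = []
    while len(pos) < cfg.n_flies:
        r = rmax * math.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * math.pi)
        p = (cx + r * math.cos(phi), cy + r * math.sin(phi))
        if all(math.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in pos):
            pos.append(p)
    return np.asarray(pos, dtype=float).reshape(cfg.n_flies, 2)


def simulate_trajectories(
    cfg: SceneConfig, n_frames: int, events: Sequence[dict] = ()
) -> GroundTruth:
    """Smooth heading-persistent random walk, wall reflection, scripted events.

    Fully reproducible from ``cfg.seed`` (single RNG stream, no global state).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_flies
    cx, cy = cfg.center
    rwall = cfg.plate_radius - cfg.wall_margin
    X = np.zeros((n_frames, n))
    Y = np.zeros((n_frames, n))
    TH = np.zeros((n_frames, n))
    reflections: list[tuple[int, float, float]] = []
    if n == 0:
        for ev in events:
            if ev["kind"] == "reflection":
                px, py = ev["position"] or (cx + cfg.plate_radius - 4, cy)
                for k in range(ev["duration"]):
                    reflections.append((ev["frame"] + k, px, py))
        empty = np.zeros((n_frames, 0))
        return GroundTruth(X, Y, TH, empty.copy(), empty.copy(), empty.copy(),
                           [[] for _ in range(n_frames)], reflections)
    pos = _initial_positions(cfg, rng)
    heading = rng.uniform(-math.pi, math.pi, n)
    base_speed = rng.uniform(*cfg.speed_range, n)
    speed = base_speed.copy()
    # steering control state per fly: (mode, data)
    hold_until = np.full(n, -1)  # no heading noise while held
    stopped_until = np.full(n, -1)

    approach = 25  # frames of steering before a scripted meeting
    bearings: dict[int, tuple[float, float]] = {}  # event index -> approach bearings

    def _steer_to(f: int, target: tuple[float, float], arrive: int, t: int) -> None:
        dx, dy = target[0] - pos[f, 0], target[1] - pos[f, 1]
        heading[f] = math.atan2(dy, dx)
        speed[f] = min(max(math.hypot(dx, dy) / max(arrive - t, 1), 0.5), 4.0)

    for t in range(n_frames):
        X[t], Y[t], TH[t] = pos[:, 0], pos[:, 1], heading
        for ei, ev in enumerate(events):
            if ev["kind"] == "reflection":
                if ev["frame"] <= t < ev["frame"] + ev["duration"]:
                    px, py = ev["position"] or (cx + cfg.plate_radius - 4.0, cy)
                    reflections.append((t, float(px), float(py)))
                continue
            tc = ev["frame"]
            i, j = ev["flies"]
            point = ev.get("point") or (cx, cy)
            if tc - approach <= t < tc:
                if ev["kind"] == "crossing":
                    if ei not in bearings:
                        # fix the two approach bearings so the paths are
                        # transversal (at least ev["angle"] apart)
                        phi_i = math.atan2(point[1] - pos[i, 1], point[0] - pos[i, 0])
                        phi_nat = math.atan2(point[1] - pos[j, 1], point[0] - pos[j, 0])
                        dphi = math.remainder(phi_nat - phi_i, 2 * math.pi)
                        if abs(dphi) < ev["angle"]:
                            dphi = math.copysign(ev["angle"], dphi if dphi else 1.0)
                        bearings[ei] = (phi_i, phi_i + dphi)
                    half = tc - approach // 2
                    for f, phi in zip((i, j), bearings[ei]):
                        if t < half:
                            # staging point on the approach ray, inside the wall
                            d_in = (tc - half) * base_speed[f]
                            sx = point[0] - d_in * math.cos(phi)
                            sy = point[1] - d_in * math.sin(phi)
                            rr = math.hypot(sx - cx, sy - cy)
                            if rr > rwall - 5:
                                sx = cx + (sx - cx) * (rwall - 5) / rr
                                sy = cy + (sy - cy) * (rwall - 5) / rr
                            _steer_to(f, (sx, sy), half, t)
                        else:
                            _steer_to(f, point, tc, t)
                        hold_until[f] = tc + 10
                else:
                    for f in (i, j):
                        _steer_to(f, point, tc, t)
                        hold_until[f] = tc + 10
            if ev["kind"] == "stop_and_merge" and tc <= t < tc + ev["duration"]:
                for f in (i, j):
                    speed[f] = 0.0
                    stopped_until[f] = tc + ev["duration"]
            if ev["kind"] == "stop_and_merge" and t == tc + ev["duration"]:
                phi = rng.uniform(-math.pi, math.pi)
                heading[i], heading[j] = phi, phi + math.pi
                speed[i], speed[j] = base_speed[i], base_speed[j]
                hold_until[i] = hold_until[j] = t + 15
        # step
        for f in range(n):
            if t < stopped_until[f]:
                continue
            if t >= hold_until[f]:
                heading[f] += cfg.heading_noise * rng.standard_normal()
                speed[f] = base_speed[f]
                if cfg.min_separation > 0:
                    # non-interacting condition: steer away from close flies
                    away = np.zeros(2)
                    for g2 in range(n):
                        if g2 == f:
                            continue
                        dx = pos[f, 0] - pos[g2, 0]
                        dy = pos[f, 1] - pos[g2, 1]
                        if math.hypot(dx, dy) < cfg.min_separation:
                            away += (dx, dy)
                    if away.any():
                        heading[f] = math.atan2(away[1], away[0])
            pos[f, 0] += speed[f] * math.cos(heading[f])
            pos[f, 1] += speed[f] * math.sin(heading[f])
            # specular reflection at the wall
            dx, dy = pos[f, 0] - cx, pos[f, 1] - cy
            d = math.hypot(dx, dy)
            if d > rwall:
                nx, ny = dx / d, dy / d
                vx, vy = math.cos(heading[f]), math.sin(heading[f])
                dot = vx * nx + vy * ny
                heading[f] = math.atan2(vy - 2 * dot * ny, vx - 2 * dot * nx)
                pos[f, 0] = cx + nx * (2 * rwall - d)
                pos[f, 1] = cy + ny * (2 * rwall - d)
    VX = np.gradient(X, axis=0) if n_frames > 1 else np.zeros_like(X)
    VY = np.gradient(Y, axis=0) if n_frames > 1 else np.zeros_like(Y)
    THu = np.unwrap(TH, axis=0)
    W = np.gradient(THu, axis=0) if n_frames > 1 else np.zeros_like(TH)
    merge_dist = 2.0 * 2.23 * (cfg.fly_axes[0] / 2.0)  # blobs touch at threshold
    overlaps: list[list[tuple[int, int]]] = []
    for t in range(n_frames):
        pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                if math.hypot(X[t, i] - X[t, j], Y[t, i] - Y[t, j]) < merge_dist:
                    pairs.append((i, j))
        overlaps.append(pairs)
    return GroundTruth(X, Y, TH, VX, VY, W, overlaps, reflections)


def _stamp_gaussian(img: np.ndarray, x: float, y: float, theta: float,
                    sa: float, sb: float, amplitude: float) -> None:
    """Subtract a rotated anisotropic Gaussian profile in place."""
    h, w = img.shape
    ext = int(math.ceil(4 * sa))
    c0, c1 = max(int(x) - ext, 0), min(int(x) + ext + 1, w)
    r0, r1 = max(int(y) - ext, 0), min(int(y) + ext + 1, h)
    if c0 >= c1 or r0 >= r1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx, dy = xx - x, yy - y
    ct, st = math.cos(theta), math.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    img[r0:r1, c0:c1] -= amplitude * np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2))


def render_frame(truth: GroundTruth, t: int, cfg: SceneConfig) -> np.ndarray:
    """Render frame ``t``: bright plate, dark Gaussian flies, noise, drift.

    Deterministic per (seed, frame): each frame uses its own derived RNG
    stream, so frames can be re-rendered independently.
    """
    cx, cy = cfg.center
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    plate = (xx - cx) ** 2 + (yy - cy) ** 2 <= cfg.plate_radius**2
    level = cfg.background_level
    if cfg.drift_amplitude > 0:
        level = level + cfg.drift_amplitude * math.sin(2 * math.pi * t / cfg.drift_period)
    img = np.where(plate, level, cfg.outside_level).astype(float)
    sa, sb = cfg.fly_axes[0] / 2.0, cfg.fly_axes[1] / 2.0
    for i in range(truth.n_flies):
        _stamp_gaussian(img, truth.x[t, i], truth.y[t, i], truth.theta[t, i],
                        sa, sb, cfg.fly_contrast)
    for tf, px, py in truth.reflections:
        if tf == t:
            _stamp_gaussian(img, px, py, 0.0, sa, sa, 0.5 * cfg.fly_contrast)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng([cfg.seed % (2**31), 1000003 + t])
        img += rng.normal(0.0, cfg.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_sequence(truth: GroundTruth, cfg: SceneConfig) -> list[np.ndarray]:
    """Render every frame of a simulated trajectory set."""
    return [render_frame(truth, t, cfg) for t in range(truth.n_frames)]


def generate_dataset(
    cfg: SceneConfig,
    n_frames: int,
    out_dir: str | Path,
    events: Sequence[dict] = (),
) -> dict[str, Path]:
    """Write a rendered dataset: numbered PNGs, truth CSV, config YAML."""
    import imageio.v3 as iio

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        truth = simulate_trajectories(cfg, n_frames, events)
        frame_paths = []
        for t in range(n_frames):
            p = out / f"frame_{t:05d}.png"
            iio.imwrite(p, render_frame(truth, t, cfg))
            frame_paths.append(p)
        truth_path = out / "truth.csv"
        truth.to_dataframe(cfg.fps).to_csv(truth_path, index=False)
        cfg_path = out / "scene.yaml"
        d = dataclasses.asdict(cfg)
        for key in ("plate_center", "fly_axes", "speed_range"):
            if d[key] is not None:
                d[key] = list(d[key])
        d["n_frames"] = n_frames
        cfg_path.write_text(yaml.safe_dump(d, sort_keys=False))
    except OSError as exc:
        raise OSError(f"failed writing dataset under {out}: {exc}") from exc
    return {"frames": out, "truth": truth_path, "config": cfg_path}
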