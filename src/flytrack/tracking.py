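"""Identity tracking: one Kalman filter per fly, Hungarian assignment.

Each fly is followed by a *tracker* holding a 6-dimensional state
``(x, y, Vx, Vy, theta, w)`` — position in px, velocity in px/frame,
orientation in rad, angular velocity in rad/frame — propagated by a
constant-velocity linear model and corrected by a full-state measurement
(position and orientation from the fitted ellipse, velocities from a
weighted moving average of finite differences).

Per frame, predicted tracker positions and validated detections are matched
by the Hungarian algorithm on a Gaussian score
``(1/(2 pi sx sy)) exp(-((x-mx)/sx)^2/2 - ((y-my)/sy)^2/2)`` whose spreads
come from the predicted covariance. When several trackers gate onto one
detection the flies have merged into a single blob: the blob is first
re-segmented at a raised threshold; failing that, trackers coast on their
predictions (or wait at the last known position when the cluster is
static, with a k-means/EM disambiguation at separation).

New trackers are provisional for a probation period (50 frames at 15 fps):
short-lived spurious blobs — e.g. specular reflections at the plate wall —
never enter the final trajectory table.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import deque
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import background as bg
from . import detection as det
from .config import PipelineConfig
from .detection import (
    EllipseDetection,
    PlateROI,
    ValidationContext,
    split_component,
    wrap_angle,
)

__all__ = [
    "AssignmentResult",
    "FrameResult",
    "TrackerState",
    "assign_identities",
    "assignment_cost",
    "kalman_predict",
    "kalman_update",
    "lifecycle_step",
    "resolve_merge",
    "smooth_velocity",
    "solve_assignment",
    "track_sequence",
    "transition_matrix",
]

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = [
    "frame",
    "time_s",
    "track_id",
    "x_px",
    "y_px",
    "theta_rad",
    "a_px",
    "b_px",
    "vx",
    "vy",
    "w",
    "status",
    "n_merged",
]


# ---------------------------------------------------------------------------
# tracker state and the Kalman filter


@dataclasses.dataclass
class TrackerState:
    """One fly's Kalman state, covariance and lifecycle bookkeeping."""

    id: int
    x_state: np.ndarray
    P: np.ndarray
    status: str = "active"  # active | merged | coasting | waiting | retired
    age_frames: int = 0
    frames_since_seen: int = 0
    last_known_position: tuple[float, float] = (0.0, 0.0)
    history: deque = dataclasses.field(default_factory=lambda: deque(maxlen=12))
    last_a: float = 0.0
    last_b: float = 0.0
    spawn_frame: int = 0
    pending_rows: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.x_state = np.asarray(self.x_state, dtype=float).copy()
        self.P = np.asarray(self.P, dtype=float).copy()

    @property
    def position(self) -> tuple[float, float]:
        return float(self.x_state[0]), float(self.x_state[1])

    @property
    def speed(self) -> float:
        return float(math.hypot(self.x_state[2], self.x_state[3]))

    def copy(self) -> "TrackerState":
        t = dataclasses.replace(self)
        t.history = deque(self.history, maxlen=self.history.maxlen)
        t.pending_rows = list(self.pending_rows)
        return t


def transition_matrix(dt: float = 1.0) -> np.ndarray:
    """Constant-velocity transition: x += Vx dt, y += Vy dt, theta += w dt."""
    A = np.eye(6)
    A[0, 2] = dt
    A[1, 3] = dt
    A[4, 5] = dt
    return A


def kalman_predict(t: TrackerState, dt: float = 1.0, Q: np.ndarray | None = None) -> TrackerState:
    """Time update: state through the transition model, covariance grown by Q*dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if Q is None:
        Q = np.diag([0.25, 0.25, 1.0, 1.0, 0.01, 0.01])
    A = transition_matrix(dt)
    out = t.copy()
    out.x_state = A @ t.x_state
    out.x_state[4] = wrap_angle(out.x_state[4])
    out.P = A @ t.P @ A.T + Q * dt
    out.P = 0.5 * (out.P + out.P.T)
    return out


def kalman_update(t: TrackerState, z: np.ndarray, R: np.ndarray) -> TrackerState:
    """Measurement update with the full-state observation (H = I).

    The measured angle ``z[4]`` must already be unwrapped to within pi of the
    predicted orientation. Joseph-form covariance update keeps P symmetric
    positive semidefinite.
    """
    z = np.asarray(z, dtype=float)
    R = np.asarray(R, dtype=float)
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("measurement covariance R must be positive definite") from exc
    out = t.copy()
    S = t.P + R
    K = t.P @ np.linalg.inv(S)
    innov = z - t.x_state
    out.x_state = t.x_state + K @ innov
    I_K = np.eye(6) - K
    out.P = I_K @ t.P @ I_K.T + K @ R @ K.T
    out.P = 0.5 * (out.P + out.P.T)
    out.x_state[4] = wrap_angle(out.x_state[4])
    return out


def smooth_velocity(
    history: np.ndarray,
    window: int = 5,
    *,
    decay: float = 0.7,
    innovation: float | None = None,
    innovation_scale: float = 1.0,
) -> np.ndarray:
    """Weighted moving average of finite differences.

    ``history`` is a (k, d) array of successive measured states (most recent
    last). Differences within the window are averaged with exponentially
    decaying weights (recent counts more); when the innovation magnitude is
    supplied, the newest difference's weight grows with it — the larger the
    error, the larger the correction. ``window=1`` degenerates to the raw
    finite difference. A single entry yields a zero-velocity measurement.
    """
    h = np.atleast_2d(np.asarray(history, dtype=float))
    if h.shape[0] < 2:
        return np.zeros(h.shape[1])
    diffs = np.diff(h[-(window + 1):], axis=0)
    m = diffs.shape[0]
    w = decay ** np.arange(m - 1, -1, -1.0)
    if innovation is not None:
        w[-1] *= 1.0 + min(abs(innovation) / innovation_scale, 2.0)
    return (w[:, None] * diffs).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# assignment


@dataclasses.dataclass
class AssignmentResult:
    """Tracker-to-detection correspondence for one frame."""

    pairs: dict[int, int] = dataclasses.field(default_factory=dict)
    unassigned_trackers: list[int] = dataclasses.field(default_factory=list)
    unassigned_detections: list[int] = dataclasses.field(default_factory=list)
    merged_groups: dict[int, set[int]] = dataclasses.field(default_factory=dict)


def assignment_cost(
    pred: tuple[float, float, float, float], detection: tuple[float, float]
) -> float:
    """Gaussian probability score of a detection under a tracker's prediction."""
    mux, muy, sx, sy = pred
    if sx <= 0 or sy <= 0:
        raise ValueError("prediction spreads must be positive")
    x, y = detection
    e = -0.5 * ((x - mux) / sx) ** 2 - 0.5 * ((y - muy) / sy) ** 2
    return math.exp(e) / (2.0 * math.pi * sx * sy)


def solve_assignment(scores: np.ndarray) -> list[tuple[int, int]]:
    """Maximize the total score of a (rectangular) score matrix.

    Hungarian minimization of negative log-scores on a square-padded matrix.
    """
    s = np.asarray(scores, dtype=float)
    cost = -np.log(np.clip(s, 1e-300, None))
    n = max(s.shape)
    padded = np.full((n, n), 1e6)
    padded[: s.shape[0], : s.shape[1]] = cost
    rows, cols = linear_sum_assignment(padded)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < s.shape[0] and j < s.shape[1]
    ]


def _prediction_marginal(t: TrackerState, sigma_floor: float = 2.0) -> tuple[float, float, float, float]:
    sx = max(math.sqrt(max(t.P[0, 0], 0.0)), sigma_floor)
    sy = max(math.sqrt(max(t.P[1, 1], 0.0)), sigma_floor)
    return t.x_state[0], t.x_state[1], sx, sy


def assign_identities(
    trackers: Sequence[TrackerState],
    detections: Sequence[EllipseDetection],
    *,
    gate: float = 4.0,
    sigma_floor: float = 2.0,
) -> AssignmentResult:
    """Hungarian identity assignment with Mahalanobis gating and merge grouping.

    A pairing is feasible when the detection lies within ``gate`` Mahalanobis
    units of the prediction's position marginal. Trackers left without a
    feasible detection of their own join the merged group of their best
    feasible detection — the several-flies-one-blob case.
    """
    res = AssignmentResult()
    nt, nd = len(trackers), len(detections)
    if nt == 0:
        res.unassigned_detections = list(range(nd))
        return res
    if nd == 0:
        res.unassigned_trackers = [t.id for t in trackers]
        return res
    scores = np.zeros((nt, nd))
    feasible = np.zeros((nt, nd), dtype=bool)
    for i, t in enumerate(trackers):
        mux, muy, sx, sy = _prediction_marginal(t, sigma_floor)
        for j, d in enumerate(detections):
            m = math.hypot((d.x - mux) / sx, (d.y - muy) / sy)
            scores[i, j] = assignment_cost((mux, muy, sx, sy), (d.x, d.y))
            feasible[i, j] = m <= gate
    cost = -np.log(np.clip(scores, 1e-300, None))
    cost[~feasible] = 1e12
    # stability bias: on exact ties the lowest tracker id keeps the detection
    # nearest to its current position
    order = np.argsort([t.id for t in trackers])
    for rank, i in enumerate(order):
        j_near = int(np.argmin([(d.x - trackers[i].x_state[0]) ** 2
                                + (d.y - trackers[i].x_state[1]) ** 2 for d in detections]))
        cost[i, j_near] -= 1e-9 * 0.5**rank
    n = max(nt, nd)
    padded = np.full((n, n), 1e6)
    padded[:nt, :nd] = cost
    rows, cols = linear_sum_assignment(padded)
    matched_det: dict[int, int] = {}
    for i, j in zip(rows, cols):
        if i < nt and j < nd and feasible[i, j]:
            res.pairs[trackers[i].id] = j
            matched_det[j] = trackers[i].id
    assigned_ids = set(res.pairs)
    groups: dict[int, set[int]] = {}
    for i, t in enumerate(trackers):
        if t.id in assigned_ids:
            continue
        if feasible[i].any():
            j_best = int(np.argmax(np.where(feasible[i], scores[i], -np.inf)))
            groups.setdefault(j_best, set()).add(t.id)
        else:
            res.unassigned_trackers.append(t.id)
    for j, grp in groups.items():
        if j in matched_det:
            grp.add(matched_det[j])
            del res.pairs[matched_det[j]]
            res.merged_groups[j] = grp
        elif len(grp) == 1:
            res.pairs[next(iter(grp))] = j  # lost the auction to nobody: pair it
        else:
            res.merged_groups[j] = grp
    taken = set(res.pairs.values()) | set(res.merged_groups)
    res.unassigned_detections = [j for j in range(nd) if j not in taken]
    return res


# ---------------------------------------------------------------------------
# merge resolution


def resolve_merge(
    group: set[int],
    detection: EllipseDetection,
    ctx: ValidationContext,
    trackers_by_id: dict[int, TrackerState],
    area_model: det.AreaModel | None,
    cfg: PipelineConfig,
) -> dict[int, tuple[str, EllipseDetection | None]]:
    """Resolve several trackers claiming one blob.

    First re-runs the threshold-raising segmentation to split the blob into
    as many sub-elements as trackers; split parts are re-assigned within the
    group by the Gaussian score. If splitting fails on an elongated blob,
    k-means on the component pixels (seeded at last known positions, refined
    by expectation-maximization) is attempted. Otherwise every tracker
    coasts on its prediction — or waits at its last known position when the
    whole cluster is static.
    """
    k = len(group)
    comp = detection.pixels
    outcomes: dict[int, tuple[str, EllipseDetection | None]] = {}
    sub: list[EllipseDetection] = []
    if comp is not None:
        parts = split_component(
            comp, ctx, growth=cfg.threshold_growth, max_steps=cfg.max_steps, max_parts=k
        )
        if parts is not None and len(parts) >= 2:
            sub = [ctx.fit(p) for p in parts if p.area > 0]
        elif (
            area_model is not None
            and k >= 2
            and detection.area >= cfg.kmeans_area_ratio * area_model.mu_areas
        ):
            sub = _kmeans_split(comp, ctx, k, [trackers_by_id[i].last_known_position
                                               for i in sorted(group)], cfg)
    if len(sub) >= 2:
        members = [trackers_by_id[i] for i in sorted(group)]
        scores = np.zeros((len(members), len(sub)))
        for i, t in enumerate(members):
            marg = _prediction_marginal(t)
            for j, e in enumerate(sub):
                scores[i, j] = assignment_cost(marg, (e.x, e.y))
        for i, j in solve_assignment(scores):
            outcomes[members[i].id] = ("measured", sub[j])
        for t in members:
            outcomes.setdefault(t.id, ("coast", None))
        return outcomes
    static = all(trackers_by_id[i].speed < cfg.static_speed for i in group)
    mode = "waiting" if static else "coast"
    return {i: (mode, None) for i in group}


def _kmeans_split(
    comp: det.Component,
    ctx: ValidationContext,
    k: int,
    seeds: Sequence[tuple[float, float]],
    cfg: PipelineConfig,
) -> list[EllipseDetection]:
    """k-means on component pixels seeded at last known positions, EM-refined."""
    from sklearn.cluster import KMeans
    from sklearn.mixture import GaussianMixture

    xy = comp.xy
    if xy.shape[0] < 2 * k:
        return []
    w = ctx.weights_at(comp.rows, comp.cols)
    km = KMeans(n_clusters=k, init=np.asarray(seeds, dtype=float), n_init=1, max_iter=50)
    try:
        km.fit(xy, sample_weight=w)
        gm = GaussianMixture(
            n_components=k, means_init=km.cluster_centers_, max_iter=30, random_state=0
        )
        labels = gm.fit_predict(xy)
        centers = gm.means_
    except Exception:  # degenerate geometry: fall back to coasting
        return []
    dmin = min(
        np.linalg.norm(centers[i] - centers[j])
        for i in range(k)
        for j in range(i + 1, k)
    )
    if dmin < cfg.min_split_sep:
        return []
    out = []
    for lab in range(k):
        sel = labels == lab
        if sel.sum() < 2:
            return []
        part = det.Component(rows=comp.rows[sel], cols=comp.cols[sel], values=comp.values[sel])
        out.append(ctx.fit(part))
    return out


# ---------------------------------------------------------------------------
# lifecycle


class _IdCounter:
    def __init__(self) -> None:
        self.next = 0

    def take(self) -> int:
        i = self.next
        self.next += 1
        return i


def lifecycle_step(
    trackers: list[TrackerState],
    assignment: AssignmentResult,
    detections: Sequence[EllipseDetection],
    frame_index: int,
    cfg: PipelineConfig,
    ids: _IdCounter,
    events: list[str] | None = None,
) -> list[TrackerState]:
    """Spawn, probation-test, coast, wait and retire trackers.

    Unassigned detections spawn provisional trackers. A provisional tracker
    (younger than the probation period) that loses its detection, or whose
    detection already belongs to another tracker, is retired on the spot —
    this removes reflections and other short-lived spurious blobs. A mature
    tracker missing its fly coasts on the prediction for ``max_coast``
    frames, then waits frozen at the last known position for ``max_wait``
    frames, then is retired with a logged identity loss.
    """
    if events is None:
        events = []
    merged_ids = set().union(*assignment.merged_groups.values()) if assignment.merged_groups else set()
    keep: list[TrackerState] = []
    for t in trackers:
        provisional = t.age_frames < cfg.probation
        if t.id in assignment.pairs:
            keep.append(t)
            continue
        if t.id in merged_ids:
            if provisional:
                events.append(f"frame {frame_index}: provisional tracker {t.id} "
                              "joined an occupied blob; retired")
                t.status = "retired"
                continue
            keep.append(t)
            continue
        # unassigned
        if provisional:
            events.append(f"frame {frame_index}: provisional tracker {t.id} lost "
                          "its element; retired")
            t.status = "retired"
            continue
        if t.frames_since_seen <= cfg.max_coast:
            t.status = "coasting"
        elif t.frames_since_seen <= cfg.max_coast + cfg.max_wait:
            if t.status != "waiting":
                events.append(f"frame {frame_index}: tracker {t.id} waiting at "
                              f"last known position {t.last_known_position}")
            t.status = "waiting"
            t.x_state[0], t.x_state[1] = t.last_known_position
            t.x_state[2] = t.x_state[3] = t.x_state[5] = 0.0
            t.P[0, 0] = t.P[1, 1] = cfg.wait_sigma**2
        else:
            t.status = "retired"
            events.append(f"frame {frame_index}: tracker {t.id} retired "
                          "(identity lost)")
            continue
        keep.append(t)
    for j in assignment.unassigned_detections:
        e = detections[j]
        t = TrackerState(
            id=ids.take(),
            x_state=np.array([e.x, e.y, 0.0, 0.0, e.theta, 0.0]),
            P=np.diag([cfg.r_pos, cfg.r_pos, 25.0, 25.0, cfg.r_ang, 1.0]),
            last_known_position=(e.x, e.y),
            spawn_frame=frame_index,
            last_a=e.a,
            last_b=e.b,
        )
        t.history.append([e.x, e.y, e.theta])
        assignment.pairs[t.id] = j
        events.append(f"frame {frame_index}: spawned tracker {t.id} at "
                      f"({e.x:.1f}, {e.y:.1f})")
        keep.append(t)
    return keep


# ---------------------------------------------------------------------------
# the full pipeline


@dataclasses.dataclass
class FrameResult:
    """Validated detections plus identity assignments for one frame."""

    frame_index: int
    detections: list[EllipseDetection]
    assignment: AssignmentResult
    events: list[str] = dataclasses.field(default_factory=list)


def _preprocess(frame: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    a = np.asarray(getattr(frame, "pixels", frame), dtype=np.float32)
    if a.ndim == 3:  # luminance average over channels
        a = a.mean(axis=2)
    if cfg.smooth_sigma > 0:
        a = gaussian_filter(a, cfg.smooth_sigma)
    return a


def _measurement_R(cfg: PipelineConfig, inflate: float = 1.0) -> np.ndarray:
    return inflate * np.diag(
        [cfg.r_pos, cfg.r_pos, cfg.r_vel, cfg.r_vel, cfg.r_ang, cfg.r_angvel]
    )


def _unwrap_axis_measurement(theta_det: float, theta_pred: float) -> float:
    """Nearest representative of an axis angle (mod pi) to the prediction."""
    delta = math.fmod(theta_det - theta_pred, math.pi)
    if delta > math.pi / 2:
        delta -= math.pi
    elif delta <= -math.pi / 2:
        delta += math.pi
    return theta_pred + delta


def _detect_frame(
    img: np.ndarray,
    model: bg.BackgroundModel,
    area_model: det.AreaModel | None,
    roi: PlateROI,
    cfg: PipelineConfig,
) -> tuple[list[EllipseDetection], "det.ValidationContext", bg.ForegroundImage]:
    fg = bg.subtract_background(model, img, cfg.n_sigma, polarity=cfg.polarity)
    if roi.enabled:
        inside = roi.contains_mask(img.shape)
        fg.mask &= inside
        fg.values[~inside] = 0.0
    ctx = ValidationContext(
        diff=model.mu - img, sigma=model.sigma_eff(), n_sigma=cfg.n_sigma
    )
    comps = det.connected_components(fg)
    if area_model is not None:
        comps = det.area_filter(comps, area_model)
    else:
        comps = [c for c in comps if c.area > 1]
    dets = det.validate(
        comps,
        area_model,
        ctx,
        acceptance_floor=cfg.acceptance_floor,
        growth=cfg.threshold_growth,
        max_steps=cfg.max_steps,
        improvement=cfg.improvement,
    )
    dets = det.mask_reflections(dets, roi)
    return dets, ctx, fg


def track_sequence(
    frames: Sequence[np.ndarray],
    cfg: PipelineConfig | None = None,
) -> tuple[list[FrameResult], pd.DataFrame]:
    """Run the full pipeline on an image sequence.

    Fits the background and area models on the warmup frames, then per frame:
    subtract, segment, validate, predict, assign, resolve merges, lifecycle.
    Returns per-frame results and a trajectory table with one row per
    (frame, tracker); identities are never reused. Trackers retired during
    probation never appear in the table.
    """
    if cfg is None:
        cfg = PipelineConfig()
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    if len(frames) < 3:
        raise bg.InsufficientDataError("need at least 3 frames")
    imgs = [_preprocess(f, cfg) for f in frames]
    n_warm = min(cfg.warmup_frames, len(imgs))
    model = bg.fit_background(
        imgs[:n_warm],
        cfg.c_mad,
        update_period_frames=cfg.update_period,
        learning_rate=cfg.learning_rate,
        sigma_floor=cfg.sigma_floor,
    )
    # plate region of interest
    if cfg.plate is not None:
        cx, cy, r = cfg.plate
        roi = PlateROI(center_x=cx, center_y=cy, radius=r,
                       reflection_band_px=cfg.reflection_band_px)
    elif cfg.plate_detect:
        roi = det.detect_plate(model.mu)
        roi.reflection_band_px = cfg.reflection_band_px
    else:
        roi = PlateROI.full_frame(model.shape)
    # area model from warmup detections (ellipse areas, consistent with the
    # likelihood), with a relative spread floor against degeneracy
    areas: list[float] = []
    for img in imgs[: n_warm : max(1, n_warm // 25)]:
        dets, _, _ = _detect_frame(img, model, None, roi, cfg)
        areas.extend(e.area for e in dets if e.area > 0)
    area_model = (
        det.fit_area_model(areas, cfg.c_clean, min_rel_sigma=cfg.area_sigma_rel_floor)
        if areas
        else None
    )

    Q = np.diag([cfg.q_pos, cfg.q_pos, cfg.q_vel, cfg.q_vel, cfg.q_ang, cfg.q_angvel])
    ids = _IdCounter()
    trackers: list[TrackerState] = []
    results: list[FrameResult] = []
    rows: list[list] = []

    for fi, img in enumerate(imgs):
        events: list[str] = []
        dets, ctx, fg = _detect_frame(img, model, area_model, roi, cfg)
        trackers = [kalman_predict(t, 1.0, Q) for t in trackers]
        assignment = assign_identities(
            trackers, dets, gate=cfg.gate, sigma_floor=cfg.gate_sigma_floor
        )
        by_id = {t.id: t for t in trackers}
        # merge resolution: split, k-means/EM, or coast/wait
        merge_outcomes: dict[int, tuple[str, EllipseDetection | None]] = {}
        for j, grp in list(assignment.merged_groups.items()):
            outcomes = resolve_merge(grp, dets[j], ctx, by_id, area_model, cfg)
            split_ok = any(o[0] == "measured" for o in outcomes.values())
            single_fly = (
                area_model is not None
                and dets[j].area < cfg.kmeans_area_ratio * area_model.mu_areas
            )
            if not split_ok and single_fly:
                # the blob has single-fly size: this is not a real merge but
                # several trackers courting one fly — the mature tracker with
                # the best score keeps it, the others stay unassigned
                mature = [i for i in grp if by_id[i].age_frames >= cfg.probation]
                cand = mature or sorted(grp)
                best = max(
                    cand,
                    key=lambda i: assignment_cost(
                        _prediction_marginal(by_id[i], cfg.gate_sigma_floor),
                        (dets[j].x, dets[j].y),
                    ),
                )
                del assignment.merged_groups[j]
                assignment.pairs[best] = j
                assignment.unassigned_trackers.extend(sorted(grp - {best}))
                continue
            events.append(f"frame {fi}: trackers {sorted(grp)} merged on one blob")
            merge_outcomes.update(outcomes)
        trackers = lifecycle_step(trackers, assignment, dets, fi, cfg, ids, events)
        by_id = {t.id: t for t in trackers}
        merged_size = {
            tid: len(grp)
            for grp in assignment.merged_groups.values()
            for tid in grp
        }
        # measurement updates
        for t in trackers:
            outcome = merge_outcomes.get(t.id)
            measured: EllipseDetection | None = None
            inflate = 1.0
            if t.id in assignment.pairs:
                measured = dets[assignment.pairs[t.id]]
            elif outcome is not None and outcome[0] == "measured":
                measured = outcome[1]
                inflate = cfg.merge_r_inflate
            if measured is not None:
                theta_m = _unwrap_axis_measurement(measured.theta, t.x_state[4])
                hist_prev = t.history[-1] if t.history else [measured.x, measured.y, theta_m]
                theta_cont = hist_prev[2] + wrap_angle(theta_m - hist_prev[2])
                t.history.append([measured.x, measured.y, theta_cont])
                innov = math.hypot(measured.x - t.x_state[0], measured.y - t.x_state[1])
                vel = smooth_velocity(
                    np.asarray(t.history),
                    cfg.velocity_window,
                    decay=cfg.velocity_decay,
                    innovation=innov,
                    innovation_scale=2.0,
                )
                z = np.array([measured.x, measured.y, vel[0], vel[1], theta_m, vel[2]])
                upd = kalman_update(t, z, _measurement_R(cfg, inflate))
                t.x_state, t.P = upd.x_state, upd.P
                t.frames_since_seen = 0
                t.last_known_position = (float(measured.x), float(measured.y))
                t.last_a, t.last_b = measured.a, measured.b
                t.status = "merged" if t.id in merged_size else "active"
            else:
                t.frames_since_seen += 1
                if t.id in merged_size:
                    t.status = "merged"
                if t.status in ("active", "merged", "coasting"):
                    # coasting on the prediction: keep the history stepping
                    t.history.append([t.x_state[0], t.x_state[1], t.x_state[4]])
            t.age_frames += 1
            row = [
                fi,
                fi / cfg.fps,
                t.id,
                float(t.x_state[0]),
                float(t.x_state[1]),
                float(t.x_state[4]),
                t.last_a,
                t.last_b,
                float(t.x_state[2]),
                float(t.x_state[3]),
                float(t.x_state[5]),
                t.status,
                merged_size.get(t.id, 0),
            ]
            if t.age_frames <= cfg.probation:
                t.pending_rows.append(row)
                if t.age_frames == cfg.probation:
                    rows.extend(t.pending_rows)
                    t.pending_rows = []
            else:
                rows.append(row)
        # periodic selective background update (foreground frozen)
        if cfg.update_period > 0:
            model = bg.update_background(model, img, fg.mask, frame_index=fi)
        results.append(FrameResult(fi, dets, assignment, events))
        for ev in events:
            logger.info(ev)
    # trackers still inside probation when the sequence ends never proved
    # their stability; their buffered rows are dropped, like any other
    # provisional tracker's
    table = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    table = table.sort_values(["frame", "track_id"]).reset_index(drop=True)
    return results, table
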