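"""Tracking-quality statistics.

Two error frequencies summarize an experiment:

* ``Error/Occlusions`` — identity errors (swaps + losses) per occlusion
  *event*, in percent: ``100 * errors / occlusions``. An occlusion is an
  episode in which two or more flies merge into a single blob.
* ``Error/rho/t`` — errors normalized by fly population density rho
  (flies/cm^2) and video duration t (seconds), in percent:
  ``100 * errors / (rho * t)``. Duration is always recomputed from the frame
  count and frame rate, never taken from a printed table.

Occlusion *frames* (frames containing at least one merged blob) and
occlusion *events* are distinct quantities and are never conflated: the two
frequencies above take whichever denominator they are defined on.

Against synthetic ground truth the module also scores identity swaps,
losses and spurious tracks by frame-wise optimal position matching.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ExperimentRecord",
    "TruthScore",
    "count_occlusion_events",
    "count_occlusion_frames",
    "error_per_density_time",
    "error_per_occlusion",
    "score_against_truth",
]


@dataclasses.dataclass
class ExperimentRecord:
    """Counts and metadata of one tracking experiment."""

    n_frames: int
    n_occlusion_frames: int
    n_occlusion_events: int
    swaps: int
    losses: int
    spurious: int
    fps: float
    density: float  # flies/cm^2

    def __post_init__(self) -> None:
        counts = (self.n_frames, self.n_occlusion_frames, self.n_occlusion_events,
                  self.swaps, self.losses, self.spurious)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.fps <= 0 or self.density <= 0:
            raise ValueError("fps and density must be positive")

    @property
    def errors(self) -> int:
        """Identity errors: swaps plus losses."""
        return self.swaps + self.losses

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def error_per_occlusion(errors: int, occlusions: int) -> float:
    """Percentage of occlusion events that produced an identity error."""
    if occlusions <= 0:
        raise ValueError("undefined metric: no occlusions")
    if errors < 0:
        raise ValueError("errors must be non-negative")
    return 100.0 * errors / occlusions


def error_per_density_time(
    errors: int, density: float, n_frames: int, fps: float
) -> float:
    """Errors per fly density and duration, in percent.

    ``100 * errors / (density * n_frames / fps)`` with density in flies/cm^2
    and duration in seconds.
    """
    if density <= 0 or fps <= 0:
        raise ValueError("density and fps must be positive")
    duration = n_frames / fps
    if duration <= 0:
        raise ValueError("undefined metric: zero duration")
    return 100.0 * errors / (density * duration)


def _merged_flags(frame_results: Iterable) -> list[bool]:
    flags = []
    for fr in frame_results:
        assignment = getattr(fr, "assignment", fr)
        flags.append(bool(getattr(assignment, "merged_groups", {})))
    return flags


def count_occlusion_frames(frame_results: Iterable) -> int:
    """Frames whose assignment contains at least one merged group."""
    return int(sum(_merged_flags(frame_results)))


def count_occlusion_events(frame_results: Iterable) -> int:
    """Maximal runs of consecutive occlusion frames."""
    flags = _merged_flags(frame_results)
    return int(sum(1 for i, f in enumerate(flags) if f and (i == 0 or not flags[i - 1])))


@dataclasses.dataclass
class TruthScore:
    """Identity errors of an output trajectory set against ground truth."""

    swaps: int
    losses: int
    spurious: int

    def __iter__(self):
        return iter((self.swaps, self.losses, self.spurious))


def _std_columns(df: pd.DataFrame, id_candidates: Sequence[str],
                 x_candidates: Sequence[str], y_candidates: Sequence[str]) -> pd.DataFrame:
    def pick(cands):
        for c in cands:
            if c in df.columns:
                return c
        raise KeyError(f"none of {cands} found in columns {list(df.columns)}")

    return df.rename(columns={pick(id_candidates): "id", pick(x_candidates): "x",
                              pick(y_candidates): "y"})[["frame", "id", "x", "y"]]


def score_against_truth(
    trajectories: pd.DataFrame,
    ground_truth: pd.DataFrame,
    *,
    match_radius: float = 10.0,
    max_gap: int = 50,
) -> TruthScore:
    """Score output identities against synthetic ground truth.

    Per frame, output and truth positions are matched optimally (Hungarian on
    distance, gated at ``match_radius`` px). A *swap* is a frame at which an
    output id's matched truth id changes while the two truth flies are
    distinguishable (further than ``match_radius`` apart — changes during the
    overlapped phase of an occlusion are matching flicker, not identity
    errors); a *loss* is an episode of more than ``max_gap`` consecutive
    frames in which a truth id has no matched output; a *spurious* track is
    an output id that never matches any truth id.
    """
    if len(ground_truth) == 0:
        raise ValueError("empty ground truth")
    out = _std_columns(trajectories, ["track_id", "id"], ["x_px", "x"], ["y_px", "y"])
    tru = _std_columns(ground_truth, ["true_id", "id"], ["x"], ["y"])
    frames = np.intersect1d(out["frame"].unique(), tru["frame"].unique())
    matched_of: dict[int, int | None] = {}
    swaps = 0
    truth_matched_frames: dict[int, list[int]] = {int(i): [] for i in tru["id"].unique()}
    ever_matched: set[int] = set()
    out_by_frame = dict(tuple(out.groupby("frame")))
    tru_by_frame = dict(tuple(tru.groupby("frame")))
    for f in frames:
        o = out_by_frame[f]
        g = tru_by_frame[f]
        if len(o) == 0 or len(g) == 0:
            continue
        op = o[["x", "y"]].to_numpy()
        gp = g[["x", "y"]].to_numpy()
        dist = np.linalg.norm(op[:, None, :] - gp[None, :, :], axis=2)
        cost = np.where(dist <= match_radius, dist, 1e9)
        n = max(len(o), len(g))
        padded = np.full((n, n), 1e6)
        padded[: len(o), : len(g)] = cost
        rows, cols = linear_sum_assignment(padded)
        tru_pos = {int(r.id): (r.x, r.y) for r in g.itertuples()}
        for i, j in zip(rows, cols):
            if i >= len(o) or j >= len(g) or dist[i, j] > match_radius:
                continue
            oid = int(o["id"].iloc[i])
            tid = int(g["id"].iloc[j])
            ever_matched.add(oid)
            truth_matched_frames[tid].append(int(f))
            prev = matched_of.get(oid)
            if prev is not None and prev != tid:
                if prev in tru_pos:
                    px, py = tru_pos[prev]
                    qx, qy = tru_pos[tid]
                    if (px - qx) ** 2 + (py - qy) ** 2 <= match_radius**2:
                        continue  # truths overlapped: ambiguous, not a swap
                swaps += 1
            matched_of[oid] = tid
    losses = 0
    f_end = int(frames[-1]) if len(frames) else 0
    for tid, fs in truth_matched_frames.items():
        if not fs:
            losses += 1
            continue
        gaps = np.diff(np.asarray(fs)) - 1
        losses += int(np.sum(gaps > max_gap))
        if f_end - fs[-1] > max_gap:
            losses += 1
    spurious = int(len(set(out["id"].unique().astype(int)) - ever_matched))
    return TruthScore(swaps=swaps, losses=losses, spurious=spurious)
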