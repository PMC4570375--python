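"""Segmentation of the foreground into validated fly ellipses.

Connected foreground components are fitted with ellipses through a
weighted covariance: every pixel carries the weight
``W_i = |I(p_i) - mu(p_i)| / sigma(p_i)`` (its normalized darkening against
the background model), the component centre is the weighted mean, and the
half-axes/orientation come from the eigendecomposition of the weighted
covariance (``a = 2*sqrt(lambda_1)``, ``b = 2*sqrt(lambda_2)``).

A probabilistic area model (mean and population variance of element areas)
then scores each ellipse with a Laplace-style likelihood
``p = exp(-|pi*a*b - mu_areas| / sigma_areas)``. Low-likelihood components
are re-segmented by locally raising the front-detection threshold (merged
flies split; cf. the fact that a blob's area shrinks as the threshold
rises) or lowering it (under-segmented flies grow); too-small blobs that
never reach an acceptable likelihood are discarded as spurious.

The circular plate is located with a Canny + circle-Hough transform, and a
boundary band of the plate can be masked to suppress specular reflections
of flies at the wall.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Sequence

import numpy as np
from skimage import feature, measure, transform

from .background import ForegroundImage, InsufficientDataError

__all__ = [
    "AreaModel",
    "Component",
    "EllipseDetection",
    "PlateROI",
    "ValidationContext",
    "area_filter",
    "connected_components",
    "detect_plate",
    "ellipse_likelihood",
    "fit_area_model",
    "fit_ellipse",
    "mask_reflections",
    "split_component",
    "validate",
    "wrap_angle",
    "wrap_axis_angle",
]

logger = logging.getLogger(__name__)


def wrap_angle(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    t = math.fmod(theta + math.pi, 2.0 * math.pi)
    if t <= 0.0:
        t += 2.0 * math.pi
    return t - math.pi


def wrap_axis_angle(theta: float) -> float:
    """Wrap an axis orientation (mod pi, ellipses are symmetric) to (-pi/2, pi/2]."""
    t = math.fmod(theta, math.pi)
    if t > math.pi / 2:
        t -= math.pi
    elif t <= -math.pi / 2:
        t += math.pi
    return t


@dataclasses.dataclass
class AreaModel:
    """First two moments of the element-area distribution (px^2).

    ``sigma_areas`` is the square root of the population variance
    ``E[A^2] - mu^2``. ``c_clean`` is the multiplier of the foreground
    cleaning threshold ``th_min = mu_areas - c_clean * sigma_areas``.
    """

    mu_areas: float
    sigma_areas: float
    c_clean: float = 15.0
    n_samples: int = 0

    @property
    def th_min(self) -> float:
        return self.mu_areas - self.c_clean * self.sigma_areas


@dataclasses.dataclass
class Component:
    """One 8-connected foreground component.

    ``rows``/``cols`` index the component pixels; ``values`` carries the
    foreground image values at those pixels.
    """

    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray

    @property
    def area(self) -> int:
        """Pixel-count area."""
        return int(self.rows.size)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of (x, y) = (col, row) pixel-centre coordinates."""
        return np.column_stack([self.cols, self.rows]).astype(float)


@dataclasses.dataclass
class EllipseDetection:
    """A segmented element: centre, orientation, half-axes, likelihood."""

    x: float
    y: float
    theta: float
    a: float
    b: float
    weight_sum: float = 0.0
    likelihood: float = 1.0
    pixels: Component | None = dataclasses.field(default=None, repr=False, compare=False)

    @property
    def area(self) -> float:
        """Ellipse area pi*a*b (px^2)."""
        return math.pi * self.a * self.b


@dataclasses.dataclass
class PlateROI:
    """Circular region of interest: the backlit plate."""

    center_x: float
    center_y: float
    radius: float
    enabled: bool = True
    reflection_band_px: float = 12.0

    def __post_init__(self) -> None:
        if self.enabled and self.radius <= 0:
            raise ValueError("enabled plate ROI requires radius > 0")

    @classmethod
    def full_frame(cls, shape: tuple[int, int]) -> "PlateROI":
        h, w = shape
        return cls(
            center_x=(w - 1) / 2.0,
            center_y=(h - 1) / 2.0,
            radius=math.hypot(h, w),
            enabled=False,
        )

    def contains_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels inside the plate circle."""
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return (xx - self.center_x) ** 2 + (yy - self.center_y) ** 2 <= self.radius**2


# ---------------------------------------------------------------------------
# plate detection


def detect_plate(
    frame: np.ndarray,
    *,
    r_min: int | None = None,
    r_max: int | None = None,
    canny_sigma: float = 2.0,
    min_accumulator: float = 0.4,
) -> PlateROI:
    """Locate the circular plate with a Canny edge map + circle Hough transform.

    Returns the strongest circle; ties on the (normalized) accumulator are
    broken toward the smaller radius. If no sufficiently supported circle is
    found the ROI degrades to a disabled full-frame region with a warning,
    matching the manual-disable mode of operation.
    """
    img = np.asarray(getattr(frame, "pixels", frame), dtype=float)
    shape = img.shape
    span = min(shape)
    if r_min is None:
        r_min = max(8, int(0.25 * span))
    if r_max is None:
        r_max = int(0.48 * span)
    if r_max <= r_min:
        r_max = r_min + 1
    ptp = img.max() - img.min()
    if ptp <= 0:
        logger.warning("plate detection failed: blank frame; ROI disabled")
        return PlateROI.full_frame(shape)
    edges = feature.canny((img - img.min()) / ptp, sigma=canny_sigma)
    if not edges.any():
        logger.warning("plate detection failed: no edges; ROI disabled")
        return PlateROI.full_frame(shape)
    radii = np.arange(r_min, r_max + 1)
    accum = transform.hough_circle(edges, radii, normalize=True)
    per_radius = accum.reshape(len(radii), -1).max(axis=1)
    # argmax takes the first maximum: radii ascend, so ties go to the
    # smaller radius.
    best = int(np.argmax(per_radius))
    if per_radius[best] < min_accumulator:
        logger.warning(
            "plate detection failed: best accumulator %.2f < %.2f; ROI disabled",
            per_radius[best],
            min_accumulator,
        )
        return PlateROI.full_frame(shape)
    cy, cx = np.unravel_index(int(np.argmax(accum[best])), shape)
    return PlateROI(center_x=float(cx), center_y=float(cy), radius=float(radii[best]))


# ---------------------------------------------------------------------------
# components and the area model


def connected_components(fg: ForegroundImage) -> list[Component]:
    """8-connected foreground components, ordered by (min-row, min-col)."""
    labels = measure.label(fg.mask, connectivity=2)
    n = labels.max()
    comps: list[Component] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        comps.append(Component(rows=rows, cols=cols, values=fg.values[rows, cols]))
    comps.sort(key=lambda c: (int(c.rows.min()), int(c.cols[c.rows == c.rows.min()].min())))
    return comps


def fit_area_model(
    areas: Sequence[float], c_clean: float = 15.0, *, min_rel_sigma: float = 0.0
) -> AreaModel:
    """Fit mean and population standard deviation of element areas.

    ``min_rel_sigma`` optionally floors ``sigma_areas`` at a fraction of the
    mean — useful when the elements are near-identical and the raw spread
    would make the area likelihood degenerate.
    """
    a = np.asarray(list(areas), dtype=float)
    if a.size == 0:
        raise InsufficientDataError("cannot fit an area model from zero areas")
    mu = float(a.mean())
    var = float(np.mean(a**2) - mu**2)
    sigma = math.sqrt(max(var, 0.0))
    sigma = max(sigma, min_rel_sigma * mu)
    return AreaModel(mu_areas=mu, sigma_areas=sigma, c_clean=c_clean, n_samples=int(a.size))


def area_filter(components: Sequence[Component], model: AreaModel) -> list[Component]:
    """Clean the foreground: drop components below th_min = mu - c*sigma.

    Components at or above the threshold are kept; single-pixel specks are
    always dropped.
    """
    return [c for c in components if c.area >= model.th_min and c.area > 1]


# ---------------------------------------------------------------------------
# ellipse fitting and likelihood


def fit_ellipse(pixels: np.ndarray, weights: np.ndarray) -> EllipseDetection:
    """Weighted-covariance ellipse fit of a pixel set.

    ``pixels`` is an (n, 2) array of (x, y) coordinates, ``weights`` the
    per-pixel W_i >= 0 (not all zero). The centre is the weighted mean; the
    eigendecomposition of the weighted covariance gives the half-axes
    (a = 2*sqrt(lambda_max) >= b) and the major-axis orientation.
    """
    p = np.atleast_2d(np.asarray(pixels, dtype=float))
    w = np.asarray(weights, dtype=float).ravel()
    if p.shape[0] != w.size or p.shape[1] != 2:
        raise ValueError("pixels must be (n, 2) with one weight per pixel")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    z = float(w.sum())
    if z <= 0:
        raise ValueError("degenerate input: all-zero weights")
    mu = (w[:, None] * p).sum(axis=0) / z
    d = p - mu
    cov = (w[:, None, None] * (d[:, :, None] * d[:, None, :])).sum(axis=0) / z
    cov = 0.5 * (cov + cov.T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.clip(evals, 0.0, None)
    a = 2.0 * math.sqrt(evals[1])
    b = 2.0 * math.sqrt(evals[0])
    if evals[1] - evals[0] < 1e-12:
        theta = 0.0
    else:
        vx, vy = evecs[0, 1], evecs[1, 1]
        theta = wrap_axis_angle(math.atan2(vy, vx))
    return EllipseDetection(
        x=float(mu[0]), y=float(mu[1]), theta=theta, a=a, b=b, weight_sum=z
    )


def ellipse_likelihood(e: EllipseDetection, model: AreaModel) -> float:
    """Laplace-style area likelihood p = exp(-|pi*a*b - mu| / sigma)."""
    if model.sigma_areas <= 0:
        warnings.warn(
            "area model has zero spread; likelihood degenerates to an "
            "indicator at mu_areas",
            stacklevel=2,
        )
        return 1.0 if math.isclose(e.area, model.mu_areas) else 0.0
    return math.exp(-abs(e.area - model.mu_areas) / model.sigma_areas)


# ---------------------------------------------------------------------------
# validation (adaptive-threshold split / merge / spurious rejection)


@dataclasses.dataclass
class ValidationContext:
    """Access to the raw difference image for local re-thresholding.

    ``diff`` is the signed background difference (mu - I for dark flies),
    ``sigma`` the floored deviation image, ``n_sigma`` the base threshold
    multiplier N.
    """

    diff: np.ndarray
    sigma: np.ndarray
    n_sigma: float

    def weights_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.abs(self.diff[rows, cols]) / self.sigma[rows, cols]

    def fit(self, comp: Component) -> EllipseDetection:
        e = fit_ellipse(comp.xy, self.weights_at(comp.rows, comp.cols))
        e.pixels = comp
        return e


def _regroup_by_cores(
    comp: Component, core_labels: np.ndarray, core_rows: np.ndarray, core_cols: np.ndarray
) -> list[Component]:
    """Assign every component pixel to the nearest threshold-raised core.

    Raising the threshold shrinks each fly to its dark core; re-expanding the
    cores over the full component keeps sub-element areas on the same scale
    as the area model.
    """
    n_cores = core_labels.max()
    centroids = np.array(
        [
            [core_rows[core_labels == k].mean(), core_cols[core_labels == k].mean()]
            for k in range(1, n_cores + 1)
        ]
    )
    pts = np.column_stack([comp.rows, comp.cols]).astype(float)
    d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    owner = d2.argmin(axis=1)
    out = []
    for k in range(n_cores):
        sel = owner == k
        out.append(
            Component(rows=comp.rows[sel], cols=comp.cols[sel], values=comp.values[sel])
        )
    return out


def split_component(
    comp: Component,
    ctx: ValidationContext,
    *,
    n_start: float | None = None,
    growth: float = 1.6,
    max_steps: int = 8,
    max_parts: int | None = None,
    min_core_px: int = 2,
) -> list[Component] | None:
    """Try to split a component by raising the local front-detection threshold.

    Steps N upward geometrically from ``n_start`` (default: the context's
    base N) within the component's own pixel set; at the first threshold
    where at least two cores of >= ``min_core_px`` pixels survive, all
    component pixels are regrouped to the nearest core. Returns None when no
    split is found. Geometric stepping is needed because the gap between the
    base threshold and the blobs' peak darkening can span more than an order
    of magnitude.
    """
    if n_start is None:
        n_start = ctx.n_sigma
    dvals = np.abs(ctx.diff[comp.rows, comp.cols])
    svals = ctx.sigma[comp.rows, comp.cols]
    r0, c0 = comp.rows.min(), comp.cols.min()
    h = comp.rows.max() - r0 + 1
    w = comp.cols.max() - c0 + 1
    local = np.zeros((h, w), dtype=bool)
    for step in range(1, max_steps + 1):
        n_k = n_start * growth**step
        keep = dvals > n_k * svals
        if keep.sum() < 2 * min_core_px:
            return None
        local[:] = False
        local[comp.rows[keep] - r0, comp.cols[keep] - c0] = True
        labels = measure.label(local, connectivity=2)
        counts = np.bincount(labels.ravel())[1:]
        good = np.nonzero(counts >= min_core_px)[0] + 1
        if len(good) >= 2:
            if max_parts is not None and len(good) > max_parts:
                good = good[np.argsort(counts[good - 1])[::-1][:max_parts]]
            relabel = np.zeros(labels.max() + 1, dtype=int)
            relabel[good] = np.arange(1, len(good) + 1)
            lab2 = relabel[labels]
            rows = comp.rows[keep] - r0
            cols = comp.cols[keep] - c0
            core_lab = lab2[rows, cols]
            sel = core_lab > 0
            return _regroup_by_cores(
                comp,
                core_lab[sel].astype(int),
                comp.rows[keep][sel],
                comp.cols[keep][sel],
            )
    return None


def _grow_component(
    comp: Component,
    ctx: ValidationContext,
    *,
    growth: float,
    max_steps: int,
    pad: int = 5,
) -> list[Component]:
    """Candidate regrowths of a too-small component at lowered thresholds."""
    h_img, w_img = ctx.diff.shape
    r0 = max(int(comp.rows.min()) - pad, 0)
    r1 = min(int(comp.rows.max()) + pad + 1, h_img)
    c0 = max(int(comp.cols.min()) - pad, 0)
    c1 = min(int(comp.cols.max()) + pad + 1, w_img)
    sub_d = ctx.diff[r0:r1, c0:c1]
    sub_s = ctx.sigma[r0:r1, c0:c1]
    out = []
    for step in range(1, max_steps + 1):
        n_k = ctx.n_sigma / growth**step
        if n_k <= 0:
            break
        mask = sub_d > n_k * sub_s
        labels = measure.label(mask, connectivity=2)
        # keep the sub-component containing the original seed
        seed = labels[comp.rows[0] - r0, comp.cols[0] - c0]
        if seed == 0:
            continue
        rows, cols = np.nonzero(labels == seed)
        out.append(
            Component(
                rows=rows + r0,
                cols=cols + c0,
                values=np.abs(sub_d[rows, cols]),
            )
        )
    return out


def validate(
    components: Sequence[Component],
    area_model: AreaModel | None,
    ctx: ValidationContext,
    *,
    acceptance_floor: float = math.exp(-3.0),
    growth: float = 1.6,
    max_steps: int = 8,
    improvement: float = 1.05,
) -> list[EllipseDetection]:
    """Turn components into validated ellipses via the area-likelihood model.

    Components whose likelihood already clears the acceptance floor pass
    unchanged. A low-likelihood component that is too large is re-segmented
    at raised local thresholds (merged flies split); one that is too small
    is regrown at lowered thresholds and discarded as spurious if its
    likelihood never recovers. Among the configurations tried, the one
    maximizing the likelihood product of its accepted sub-elements wins
    (first configuration improving the product by more than ``improvement``
    is taken, a bounded hysteresis).
    """
    if area_model is None:
        return [ctx.fit(c) for c in components]
    out: list[EllipseDetection] = []
    for comp in components:
        e0 = ctx.fit(comp)
        e0.likelihood = ellipse_likelihood(e0, area_model)
        if e0.likelihood >= acceptance_floor:
            out.append(e0)
            continue
        if e0.area > area_model.mu_areas:
            # probably several merged flies: split at raised thresholds
            cap = int(round(e0.area / max(area_model.mu_areas, 1e-9))) + 1
            parts = split_component(
                comp, ctx, growth=growth, max_steps=max_steps, max_parts=max(cap, 2)
            )
            best_score = e0.likelihood
            best: list[EllipseDetection] = [e0]
            if parts is not None:
                cand = []
                for part in parts:
                    if part.area == 0:
                        continue
                    e = ctx.fit(part)
                    e.likelihood = ellipse_likelihood(e, area_model)
                    if e.likelihood >= acceptance_floor:
                        cand.append(e)
                if cand:
                    score = float(np.prod([e.likelihood for e in cand]))
                    if score > improvement * best_score:
                        best, best_score = cand, score
            out.extend(best)
        else:
            # too small: regrow at lowered thresholds, else spurious
            best_e, best_p = e0, e0.likelihood
            for grown in _grow_component(comp, ctx, growth=growth, max_steps=max_steps):
                e = ctx.fit(grown)
                e.likelihood = ellipse_likelihood(e, area_model)
                if e.likelihood > improvement * best_p:
                    best_e, best_p = e, e.likelihood
                    if best_p >= acceptance_floor:
                        break
            if best_p >= acceptance_floor:
                out.append(best_e)
            # else: spurious artifact, dropped
    return out


# ---------------------------------------------------------------------------
# reflection masking


def mask_reflections(
    detections: Sequence[EllipseDetection], roi: PlateROI
) -> list[EllipseDetection]:
    """Drop detections lying entirely within the plate-boundary band.

    Specular reflections of flies at the plate wall appear inside a thin
    circumferential band; an ellipse entirely within the band (its innermost
    point no closer to the centre than the band's inner edge) is masked out.
    Elements straddling the band edge are kept. No-op when the ROI is
    disabled.
    """
    if not roi.enabled:
        return list(detections)
    inner = roi.radius - roi.reflection_band_px
    kept = []
    for e in detections:
        d = math.hypot(e.x - roi.center_x, e.y - roi.center_y)
        if d - e.a >= inner:
            continue
        kept.append(e)
    return kept
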