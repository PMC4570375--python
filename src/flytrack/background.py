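"""Per-pixel median/MAD background model and foreground extraction.

The arena is backlit, so the fly-free scene is bright and nearly static:
each pixel's brightness is well described by a unimodal Gaussian. The model
stores a robust location (temporal median, ``mu``) and a robust scale
(scaled median absolute deviation, ``sigma``) per pixel. A pixel of a new
frame is declared foreground when its darkening relative to ``mu`` exceeds
``N * sigma`` — the front-detection threshold.

The MAD is scaled by c = 1/Phi^-1(3/4) ~ 1.4826 so that ``sigma`` is a
consistent estimate of the Gaussian standard deviation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MAD_SCALE",
    "mad_scale_constant",
    "BackgroundModel",
    "ForegroundImage",
    "InsufficientDataError",
    "NotFittedError",
    "fit_background",
    "update_background",
    "subtract_background",
]

#: Consistency constant scaling the MAD to a Gaussian standard deviation.
MAD_SCALE = 1.4826


def mad_scale_constant() -> float:
    """Return 1/Phi^-1(3/4), the Gaussian-consistency scale of the MAD.

    The median absolute deviation of a Gaussian sample converges to
    ``sigma * Phi^-1(3/4)``; dividing by that quantile (i.e. multiplying the
    MAD by ~1.4826) makes it an unbiased estimate of ``sigma``, so that the
    expected fraction of data falls within one standard deviation of the
    median.
    """
    from scipy.stats import norm

    return float(1.0 / norm.ppf(0.75))


class InsufficientDataError(ValueError):
    """Raised when too few frames/samples are supplied to fit a model."""


class NotFittedError(RuntimeError):
    """Raised when an operation requires a fitted model."""


@dataclasses.dataclass
class ForegroundImage:
    """Foreground of one frame in the inverted-brightness convention.

    ``values`` is 0 at background pixels and ``255 - I(p)`` at foreground
    pixels (dark flies on a bright plate become bright blobs). ``mask`` is
    the boolean foreground map.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")


@dataclasses.dataclass
class BackgroundModel:
    """Median/scaled-MAD background model with selective updating."""

    mu: np.ndarray
    sigma: np.ndarray
    c: float = MAD_SCALE
    update_period_frames: int = 100
    learning_rate: float = 0.05
    sigma_floor: float = 1.0
    n_frames_fitted: int = 0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu/sigma shape mismatch")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if self.update_period_frames < 1:
            raise ValueError("update_period_frames must be positive")

    @property
    def fitted(self) -> bool:
        return self.n_frames_fitted > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.mu.shape  # type: ignore[return-value]

    def sigma_eff(self) -> np.ndarray:
        """Deviation image floored at ``sigma_floor``.

        On noiseless input the fitted MAD is exactly zero; flooring keeps the
        front-detection threshold ``N * sigma`` meaningful there.
        """
        return np.maximum(self.sigma, self.sigma_floor)

    def copy(self) -> "BackgroundModel":
        return dataclasses.replace(self, mu=self.mu.copy(), sigma=self.sigma.copy())

    # -- serialization (two-band float TIFF) --------------------------------

    def save(self, path: str | Path) -> None:
        """Write the model as a 2-band float32 TIFF (bands: mu, sigma)."""
        import tifffile

        meta = {
            "c": self.c,
            "update_period_frames": self.update_period_frames,
            "learning_rate": self.learning_rate,
            "sigma_floor": self.sigma_floor,
            "n_frames_fitted": self.n_frames_fitted,
        }
        stack = np.stack([self.mu, self.sigma]).astype(np.float32)
        tifffile.imwrite(str(path), stack, description=json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "BackgroundModel":
        import tifffile

        with tifffile.TiffFile(str(path)) as tif:
            stack = tif.asarray()
            desc = tif.pages[0].description or "{}"
        meta = json.loads(desc)
        return cls(mu=stack[0], sigma=stack[1], **meta)


def _as_stack(frames: Iterable[np.ndarray]) -> np.ndarray:
    arrs = []
    for f in frames:
        a = np.asarray(getattr(f, "pixels", f), dtype=np.float32)
        if a.ndim != 2:
            raise ValueError("frames must be 2-D grayscale arrays")
        arrs.append(a)
    if len(arrs) < 3:
        raise InsufficientDataError(
            f"need at least 3 frames to fit a background model, got {len(arrs)}"
        )
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError(f"frame shape mismatch: {a.shape} != {shape}")
    return np.stack(arrs)


def fit_background(
    frames: Sequence[np.ndarray],
    c: float = MAD_SCALE,
    *,
    update_period_frames: int = 100,
    learning_rate: float = 0.05,
    sigma_floor: float = 1.0,
) -> BackgroundModel:
    """Fit the per-pixel median / scaled-MAD model from a frame stack.

    ``mu`` is the temporal median per pixel; ``sigma`` is ``c`` times the
    temporal median of absolute deviations from ``mu``.
    """
    stack = _as_stack(frames)
    mu = np.median(stack, axis=0)
    sigma = c * np.median(np.abs(stack - mu[None]), axis=0)
    return BackgroundModel(
        mu=mu,
        sigma=sigma,
        c=c,
        update_period_frames=update_period_frames,
        learning_rate=learning_rate,
        sigma_floor=sigma_floor,
        n_frames_fitted=stack.shape[0],
    )


def update_background(
    model: BackgroundModel,
    frame: np.ndarray,
    fg_mask: np.ndarray,
    *,
    frame_index: int | None = None,
) -> BackgroundModel:
    """Selectively refresh the model from one frame.

    Pixels currently classified as foreground are frozen — this is what
    prevents a fly that stops moving from burning a phantom dark spot into
    ``mu``. Background pixels have ``mu`` blended toward the frame with the
    model's learning rate. The deviation image is a sequence statistic and
    is not re-estimated from a single frame.

    When ``frame_index`` is given, the update is only applied every
    ``update_period_frames`` frames; other frames return the model unchanged.
    """
    if not model.fitted:
        raise NotFittedError("background model has not been fitted")
    pixels = np.asarray(getattr(frame, "pixels", frame), dtype=float)
    fg_mask = np.asarray(fg_mask, dtype=bool)
    if pixels.shape != model.shape or fg_mask.shape != model.shape:
        raise ValueError("frame/mask dimensions do not match the model")
    if frame_index is not None and frame_index % model.update_period_frames != 0:
        return model
    out = model.copy()
    bg = ~fg_mask
    a = model.learning_rate
    out.mu[bg] = (1.0 - a) * out.mu[bg] + a * pixels[bg]
    return out


def subtract_background(
    model: BackgroundModel,
    frame: np.ndarray,
    n_sigma: float = 10.0,
    *,
    polarity: str = "dark",
) -> ForegroundImage:
    """Threshold a frame against the model (front-detection threshold N*sigma).

    With the default ``dark`` polarity a pixel is foreground iff
    ``mu(p) - I(p) > N * sigma(p)`` — dark flies on the bright backlit plate.
    ``bright`` inverts the test; ``both`` unions the two.
    """
    if not model.fitted:
        raise NotFittedError("background model has not been fitted")
    if n_sigma < 0:
        raise ValueError("threshold multiplier N must be >= 0")
    if polarity not in ("dark", "bright", "both"):
        raise ValueError(f"unknown polarity {polarity!r}")
    pixels = np.asarray(getattr(frame, "pixels", frame), dtype=float)
    if pixels.shape != model.shape:
        raise ValueError("frame dimensions do not match the model")
    thr = n_sigma * model.sigma_eff()
    dark = (model.mu - pixels) > thr
    bright = (pixels - model.mu) > thr
    if polarity == "dark":
        mask = dark
        values = np.where(mask, 255.0 - pixels, 0.0)
    elif polarity == "bright":
        mask = bright
        values = np.where(mask, pixels, 0.0)
    else:
        mask = dark | bright
        values = np.where(dark, 255.0 - pixels, np.where(bright, pixels, 0.0))
    return ForegroundImage(values=values, mask=mask)
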