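"""Frame input: numbered image directories or video containers."""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

__all__ = ["Frame", "read_frames", "to_grayscale"]

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


class Frame(NamedTuple):
    """One grayscale frame with its index and timestamp."""

    pixels: np.ndarray
    index: int
    timestamp_s: float


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luminance-average grayscale conversion."""
    a = np.asarray(img)
    if a.ndim == 3:
        a = a.mean(axis=2)
    return a.astype(np.float32)


def _numeric_key(p: Path) -> tuple:
    nums = re.findall(r"\d+", p.stem)
    return (int(nums[-1]) if nums else 0, p.name)


def read_frames(path: str | Path, fps: float = 15.0) -> Iterator[Frame]:
    """Yield grayscale frames from a directory of numbered images or a video.

    Directory entries are ordered by the trailing number in their file name.
    Video containers are read through imageio when a suitable plugin is
    available.
    """
    import imageio.v3 as iio

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such input: {p}")
    if p.is_dir():
        files = sorted(
            (f for f in p.iterdir() if f.suffix.lower() in IMAGE_SUFFIXES),
            key=_numeric_key,
        )
        if not files:
            raise FileNotFoundError(f"no image files under {p}")
        for i, f in enumerate(files):
            yield Frame(to_grayscale(iio.imread(f)), i, i / fps)
        return
    try:
        for i, img in enumerate(iio.imiter(p)):
            yield Frame(to_grayscale(img), i, i / fps)
    except Exception as exc:
        raise OSError(
            f"cannot read {p} as a video container ({exc}); "
            "a directory of numbered PNG/TIFF frames always works"
        ) from exc
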