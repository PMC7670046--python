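"""Grid-count feature extraction from RGB spectrogram images.

A walking micro-Doppler spectrogram (time on the horizontal axis, Doppler
velocity on the vertical, rendered through a jet-style colormap) is reduced
to a short count vector in three steps:

1. channel selection — one of the raw red/green/blue planes, or the YUV
   luminance ``Y = 0.299 r + 0.587 g + 0.114 b``;
2. binarization — pixels at or above an integer threshold become white
   (255), the rest black (0);
3. grid separation and counting — the mask is cut into ``n_cols`` contiguous
   column strips (time axis, one per step of the walk) and ``n_rows`` row
   strips (velocity bands: stance, body, swing, fast extremity motion), and
   the white pixels in each strip are counted.

The default 4x4 grid yields 8 features (column strips a–d left to right,
then row strips e–h top to bottom).  Each of the column-strip counts and the
row-strip counts partitions the same mask, so both groups sum to the total
white-pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CHANNELS",
    "Y_WEIGHTS",
    "DEFAULT_THRESHOLDS",
    "BinarizationConfig",
    "GridSpec",
    "extract_channel",
    "binarize",
    "grid_counts",
    "extract_features",
    "feature_names",
]

CHANNELS = ("red", "green", "blue", "Y")

#: ITU-R BT.601 luma weights for (red, green, blue).
Y_WEIGHTS = (0.299, 0.587, 0.114)

#: Threshold ladder swept during evaluation: 50..220 inclusive, step 10.
DEFAULT_THRESHOLDS = tuple(range(50, 221, 10))


@dataclass(frozen=True)
class GridSpec:
    """Separation grid: ``n_rows`` velocity bands x ``n_cols`` time strips."""

    n_rows: int = 4
    n_cols: int = 4

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.n_rows}x{self.n_cols}")

    @property
    def n_features(self) -> int:
        return self.n_rows + self.n_cols

    @classmethod
    def parse(cls, text: str) -> "GridSpec":
        """Parse ``"ROWSxCOLS"`` (e.g. ``"4x4"``, ``"4x5"``)."""
        try:
            rows, cols = text.lower().split("x")
            return cls(int(rows), int(cols))
        except (ValueError, AttributeError):
            raise ValueError(f"cannot parse grid spec {text!r}; expected ROWSxCOLS") from None

    def __str__(self) -> str:
        return f"{self.n_rows}x{self.n_cols}"


@dataclass(frozen=True)
class BinarizationConfig:
    """Channel + threshold pair defining one binarization."""

    channel: str = "red"
    threshold: int = 170

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold {self.threshold} outside 0..255")


def _as_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    return image


def extract_channel(image: np.ndarray, channel: str) -> np.ndarray:
    """Return one HxW intensity plane of an RGB image.

    ``"red"``/``"green"``/``"blue"`` return the raw 8-bit plane; ``"Y"``
    returns the real-valued luminance 0.299 r + 0.587 g + 0.114 b without
    rounding, so that the subsequent ``>= threshold`` comparison is applied
    to the exact weighted sum.
    """
    image = _as_image(image)
    if channel == "red":
        return image[:, :, 0]
    if channel == "green":
        return image[:, :, 1]
    if channel == "blue":
        return image[:, :, 2]
    if channel == "Y":
        wr, wg, wb = Y_WEIGHTS
        planes = image.astype(np.float64)
        return wr * planes[:, :, 0] + wg * planes[:, :, 1] + wb * planes[:, :, 2]
    raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")


def binarize(plane: np.ndarray, threshold: int) -> np.ndarray:
    """Binarize an intensity plane: 255 where ``plane >= threshold`` else 0."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold {threshold} outside 0..255")
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D intensity plane, got shape {plane.shape}")
    return np.where(plane >= threshold, 255, 0).astype(np.uint8)


def _strip_slices(n: int, parts: int) -> list[slice]:
    # Near-equal contiguous strips; earlier strips absorb the remainder.
    sizes = [n // parts + (1 if k < n % parts else 0) for k in range(parts)]
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [slice(int(edges[k]), int(edges[k + 1])) for k in range(parts)]


def grid_counts(mask: np.ndarray, grid: GridSpec = GridSpec(), normalize: bool = False) -> np.ndarray:
    """Count white pixels per column strip (left→right) then per row strip
    (top→bottom).

    Returns a vector of length ``grid.n_cols + grid.n_rows`` of non-negative
    counts, or of strip white fractions in [0, 1] when ``normalize`` is set.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {mask.shape}")
    h, w = mask.shape
    if h < grid.n_rows or w < grid.n_cols:
        raise ValueError(f"mask {h}x{w} smaller than grid {grid}")
    white = mask != 0
    col_sums = white.sum(axis=0)  # per column
    row_sums = white.sum(axis=1)  # per row
    counts = []
    areas = []
    for sl in _strip_slices(w, grid.n_cols):
        counts.append(col_sums[sl].sum())
        areas.append(h * (sl.stop - sl.start))
    for sl in _strip_slices(h, grid.n_rows):
        counts.append(row_sums[sl].sum())
        areas.append(w * (sl.stop - sl.start))
    counts = np.asarray(counts, dtype=np.int64)
    if normalize:
        return counts / np.asarray(areas, dtype=np.float64)
    return counts


def extract_features(
    image: np.ndarray,
    config: BinarizationConfig = BinarizationConfig(),
    grid: GridSpec = GridSpec(),
    normalize: bool = True,
) -> np.ndarray:
    """Channel selection → binarization → grid counting, composed.

    With ``normalize`` (default) each count is divided by its strip's pixel
    area, giving scale-free values in [0, 1]; with ``normalize=False`` the
    raw integer counts are returned.
    """
    plane = extract_channel(image, config.channel)
    mask = binarize(plane, config.threshold)
    return grid_counts(mask, grid, normalize=normalize)


def feature_names(grid: GridSpec = GridSpec()) -> list[str]:
    """Strip labels: letters a.. for columns then rows (a–h for the 4x4 grid)."""
    n = grid.n_features
    if n <= 26:
        return [chr(ord("a") + k) for k in range(n)]
    return [f"f{k + 1}" for k in range(n)]
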