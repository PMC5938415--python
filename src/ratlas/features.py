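"""Keypoint detection and descriptor matching for histology plate images.

Detection/description delegates to scikit-image's SIFT (difference-of-
Gaussians extrema with 128-dimensional gradient-orientation histograms,
Lowe's default pyramid parameters).  Matching is the classic two-nearest-
neighbor ratio test: a region-of-interest descriptor u matches its nearest
target descriptor v only when |u - v| / |u - w| < ratio, with w the second
nearest.  An optional absolute distance cutoff on |u - v| can be enabled;
it is off by default because the ratio test is the operative filter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import SIFT

__all__ = [
    "Keypoint", "FeatureSet", "Match", "MatchSet", "MatchConfig",
    "load_image", "to_grayscale_u8", "detect_features", "match_descriptors",
]

DESCRIPTOR_DIM = 128


class Keypoint(NamedTuple):
    """One detected point: (row, col) position, detection scale (sigma, px),
    and dominant gradient orientation in [0, 2*pi)."""

    row: float
    col: float
    scale: float
    orientation: float


@dataclass
class FeatureSet:
    """Parallel arrays of keypoints and their 128-d descriptors."""

    positions: np.ndarray    # (n, 2) float64, (row, col)
    scales: np.ndarray       # (n,) float64, detection sigma in px
    orientations: np.ndarray  # (n,) float64, radians in [0, 2*pi)
    descriptors: np.ndarray  # (n, 128) float32
    image_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 2)
        self.scales = np.asarray(self.scales, dtype=np.float64).reshape(-1)
        self.orientations = np.asarray(self.orientations, dtype=np.float64).reshape(-1)
        self.descriptors = np.asarray(self.descriptors, dtype=np.float32).reshape(
            -1, DESCRIPTOR_DIM
        ) if np.asarray(self.descriptors).size else np.empty(
            (0, DESCRIPTOR_DIM), dtype=np.float32
        )
        n = len(self.positions)
        if not (len(self.scales) == len(self.orientations) == len(self.descriptors) == n):
            raise ValueError("keypoint arrays and descriptors must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    def keypoint(self, i: int) -> Keypoint:
        return Keypoint(
            float(self.positions[i, 0]), float(self.positions[i, 1]),
            float(self.scales[i]), float(self.orientations[i]),
        )

    @property
    def xy(self) -> np.ndarray:
        """Positions as (x, y) = (col, row), the geometry convention used by
        the homography stage."""
        return self.positions[:, ::-1].copy()

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(
                ["row", "col", "scale", "orientation"]
                + [f"d{i}" for i in range(DESCRIPTOR_DIM)]
            )
            for i in range(len(self)):
                writer.writerow(
                    [f"{self.positions[i, 0]:.3f}", f"{self.positions[i, 1]:.3f}",
                     f"{self.scales[i]:.5f}", f"{self.orientations[i]:.6f}"]
                    + [f"{v:g}" for v in self.descriptors[i]]
                )

    @classmethod
    def from_csv(cls, path: str | Path, image_id: str = "") -> "FeatureSet":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if rows.size == 0:
            return cls.empty(image_id)
        return cls(rows[:, :2], rows[:, 2], rows[:, 3], rows[:, 4:], image_id)

    @classmethod
    def empty(cls, image_id: str = "") -> "FeatureSet":
        return cls(
            np.empty((0, 2)), np.empty(0), np.empty(0),
            np.empty((0, DESCRIPTOR_DIM), dtype=np.float32), image_id,
        )


class Match(NamedTuple):
    roi_index: int
    target_index: int
    distance: float


@dataclass
class MatchSet:
    pairs: list[Match]
    roi_id: str = ""
    target_id: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass(frozen=True)
class MatchConfig:
    """``ratio``: nearest/second-nearest distance cutoff (ratio = 1 disables
    the filter, reducing matching to plain nearest-neighbor assignment).
    ``abs_threshold``: optional absolute cutoff on the nearest distance;
    ``None`` disables it."""

    ratio: float = 0.8
    abs_threshold: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.ratio <= 1.0):
            raise ValueError("ratio must lie in (0, 1]")
        if self.abs_threshold is not None and self.abs_threshold <= 0:
            raise ValueError("abs_threshold must be positive when enabled")


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF raster and return 8-bit grayscale."""
    import imageio.v3 as iio

    return to_grayscale_u8(iio.imread(path))


def to_grayscale_u8(image: np.ndarray) -> np.ndarray:
    """Collapse to single-channel 8-bit luminance (16-bit inputs rescaled)."""
    image = np.asarray(image)
    original = image.dtype
    if image.ndim == 3:
        if image.shape[2] == 4:  # drop alpha
            image = image[..., :3]
        if image.shape[2] == 3:
            weights = np.array([0.2125, 0.7154, 0.0721])
            image = image.astype(np.float64) @ weights
        else:
            image = image[..., 0]
    if original == np.uint8:
        return np.clip(np.rint(image), 0, 255).astype(np.uint8) \
            if image.dtype != np.uint8 else image
    image = image.astype(np.float64)
    if np.issubdtype(original, np.integer):
        if image.max() > 255.0:  # 16-bit range
            image = image / 257.0
    elif image.size and 0.0 <= image.min() and image.max() <= 1.0:
        image = image * 255.0  # unit-range float convention
    return np.clip(np.rint(image), 0, 255).astype(np.uint8)


def detect_features(image: np.ndarray, image_id: str = "") -> FeatureSet:
    """Detect DoG keypoints and 128-d descriptors in a grayscale raster.

    Deterministic for a fixed image.  A degenerate image (constant
    intensity, or too small a pyramid) yields an empty FeatureSet rather
    than an error, mirroring how a blank candidate plate should score.
    """
    image = to_grayscale_u8(image)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError("detect_features expects a 2-D image with >=2 rows/cols")
    detector = SIFT()
    try:
        detector.detect_and_extract(image)
    except RuntimeError:  # skimage raises when no features survive
        return FeatureSet.empty(image_id)
    orientations = np.mod(detector.orientations, 2.0 * np.pi)
    return FeatureSet(
        positions=detector.keypoints.astype(np.float64),
        scales=detector.sigmas.astype(np.float64),
        orientations=orientations,
        descriptors=detector.descriptors.astype(np.float32),
        image_id=image_id,
    )


def match_descriptors(
    roi: FeatureSet, target: FeatureSet, config: MatchConfig = MatchConfig()
) -> MatchSet:
    """Ratio-test matching of every ROI descriptor against the target set.

    For each ROI descriptor the nearest and second-nearest target
    descriptors are found by Euclidean distance (ties broken toward the
    smaller target index); the pair is kept when the distance ratio falls
    below ``config.ratio`` and, if enabled, the nearest distance falls below
    ``config.abs_threshold``.  Output is sorted by ROI index, one best match
    per ROI feature.
    """
    if len(roi) == 0 or len(target) == 0:
        raise ValueError("both feature sets must be non-empty")
    if len(target) < 2:
        raise ValueError(
            "target needs >=2 descriptors: the ratio test requires a second "
            "nearest neighbor"
        )
    dist = cdist(
        roi.descriptors.astype(np.float64), target.descriptors.astype(np.float64)
    )
    nearest = dist.argmin(axis=1)  # argmin takes the smallest index on ties
    d1 = dist[np.arange(len(roi)), nearest]
    dist[np.arange(len(roi)), nearest] = np.inf
    second = dist.argmin(axis=1)
    d2 = dist[np.arange(len(roi)), second]

    if config.ratio >= 1.0:  # filter disabled: plain nearest-neighbor matching
        keep = np.ones(len(roi), dtype=bool)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d2 > 0, d1 / d2, np.where(d1 == 0, np.inf, 1.0))
        keep = ratio < config.ratio
    if config.abs_threshold is not None:
        keep &= d1 < config.abs_threshold
    pairs = [
        Match(int(i), int(nearest[i]), float(d1[i]))
        for i in np.flatnonzero(keep)
    ]
    return MatchSet(pairs, roi.image_id, target.image_id)
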