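"""Synthetic histology-like fixtures for exercising the matching pipeline.

Real atlas photomicrographs are copyrighted, so tests and demonstrations
run on generated stand-ins: fields of seeded Gaussian blobs plus
band-limited noise, which share the statistics the matcher relies on
(hundreds of stable multi-scale keypoints) without imitating actual Nissl
cytoarchitecture.  A *stack* emulates sequential atlas plates: each level
re-samples a fraction of the blobs and smoothly drifts the rest, so
structural similarity decays with level distance just as neighboring
tissue sections resemble each other more than distant ones.

``perturb_roi`` reproduces the published stress test for the matcher: crop
a region of interest, rotate it (155 degrees by default), and distort it
with a smooth scattered-control-point warp.  The exact forward transform is
returned so tests can verify recovered geometry against ground truth.

All generators are pure functions of their spec, seed included: repeated
calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.interpolate import RBFInterpolator, RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from skimage.transform import warp as _sk_warp

__all__ = [
    "FixtureImageSpec", "StackSpec", "WarpSpec", "RoiTransform",
    "make_image", "make_stack", "make_variant_stack", "perturb_roi",
    "make_point_dataset", "normalized_cross_correlation",
]


@dataclass(frozen=True)
class FixtureImageSpec:
    """Blob-texture image: ``n_blobs`` seeded Gaussian spots of varied size
    and polarity on a mid-gray background, plus band-limited noise of
    relative amplitude ``noise_scale``."""

    width: int = 512
    height: int = 512
    n_blobs: int = 160
    noise_scale: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_blobs < 0 or self.noise_scale < 0:
            raise ValueError("n_blobs and noise_scale must be nonnegative")


@dataclass(frozen=True)
class StackSpec:
    """Ordered stack of ``n_levels`` images; between consecutive levels a
    fraction ``morph_step`` of blobs is re-sampled and every blob center
    drifts along a smooth random field of RMS amplitude ``drift_px``."""

    n_levels: int = 40
    morph_step: float = 0.2
    drift_px: float = 6.0
    image: FixtureImageSpec = FixtureImageSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("a stack needs at least 2 levels")
        if not (0.0 <= self.morph_step <= 1.0):
            raise ValueError("morph_step must lie in [0, 1]")


@dataclass(frozen=True)
class WarpSpec:
    """ROI perturbation: rotation about the crop center plus a smooth
    scattered-control-point warp with displacements of magnitude at most
    ``max_displacement_px``."""

    rotation_deg: float = 155.0
    n_control_points: int = 25
    max_displacement_px: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control_points < 4:
            raise ValueError("need at least 4 control points")
        if self.max_displacement_px < 0:
            raise ValueError("max_displacement_px must be nonnegative")


# ---------------------------------------------------------------------------
# blob rendering
# ---------------------------------------------------------------------------

def _sample_blobs(rng: np.random.Generator, spec: FixtureImageSpec) -> np.ndarray:
    """(n, 4) array of blob parameters: row, col, sigma, signed amplitude."""
    n = spec.n_blobs
    blobs = np.empty((n, 4))
    blobs[:, 0] = rng.uniform(0, spec.height, n)
    blobs[:, 1] = rng.uniform(0, spec.width, n)
    blobs[:, 2] = rng.uniform(3.0, 16.0, n)
    amplitude = rng.uniform(0.35, 1.0, n)
    sign = np.where(rng.random(n) < 0.6, -1.0, 1.0)  # mostly dark spots
    blobs[:, 3] = amplitude * sign
    return blobs


def _make_noise(rng: np.random.Generator, spec: FixtureImageSpec) -> np.ndarray | None:
    if spec.noise_scale <= 0:
        return None
    raw = gaussian_filter(rng.standard_normal((spec.height, spec.width)), sigma=1.5)
    return spec.noise_scale * raw / 0.2  # sigma=1.5 smoothing leaves ~0.2 RMS


def _render(blobs: np.ndarray, spec: FixtureImageSpec,
            noise: np.ndarray | None) -> np.ndarray:
    img = np.zeros((spec.height, spec.width), dtype=np.float64)
    for row, col, sigma, amp in blobs:
        r0 = max(int(row - 3 * sigma), 0)
        r1 = min(int(row + 3 * sigma) + 1, spec.height)
        c0 = max(int(col - 3 * sigma), 0)
        c1 = min(int(col + 3 * sigma) + 1, spec.width)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1, dtype=np.float64)[:, None]
        cc = np.arange(c0, c1, dtype=np.float64)[None, :]
        img[r0:r1, c0:c1] += amp * np.exp(
            -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma * sigma)
        )
    if noise is not None:
        img += noise
    # fixed mapping to 8 bit: background mid-gray, +-2.0 spans the range
    out = np.clip((img / 2.0 + 0.5) * 255.0, 0, 255)
    return np.rint(out).astype(np.uint8)


def make_image(spec: FixtureImageSpec = FixtureImageSpec()) -> np.ndarray:
    """Render one blob-texture image (uint8 grayscale, height x width)."""
    rng = np.random.default_rng(spec.seed)
    blobs = _sample_blobs(rng, spec)
    return _render(blobs, spec, _make_noise(rng, spec))


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], amplitude: float,
    grid: int = 5,
) -> Callable[[np.ndarray], np.ndarray]:
    """Random smooth displacement field: coarse grid of Gaussian vectors,
    linearly interpolated.  Returns a callable on (n, 2) (row, col) points."""
    rows = np.linspace(0, shape[0], grid)
    cols = np.linspace(0, shape[1], grid)
    disp = rng.normal(0.0, amplitude, size=(grid, grid, 2))
    interp = RegularGridInterpolator(
        (rows, cols), disp, bounds_error=False, fill_value=None
    )
    return lambda pts: interp(pts)


def make_stack(spec: StackSpec = StackSpec()) -> list[np.ndarray]:
    """Sequential plate-like images with smoothly decaying similarity."""
    rng = np.random.default_rng(spec.seed)
    blobs = _sample_blobs(rng, spec.image)
    shape = (spec.image.height, spec.image.width)
    # one noise field per stack: it is part of the shared texture, so a
    # zero-morph stack is bit-identical across levels
    noise = _make_noise(rng, spec.image)
    levels = [_render(blobs, spec.image, noise)]
    n_resample = int(round(spec.morph_step * spec.image.n_blobs))
    for _ in range(spec.n_levels - 1):
        if n_resample > 0:
            idx = rng.choice(len(blobs), size=n_resample, replace=False)
            fresh = _sample_blobs(rng, spec.image)[: len(idx)]
            blobs = blobs.copy()
            blobs[idx] = fresh
        if spec.drift_px > 0:
            field = _smooth_field(rng, shape, spec.drift_px)
            blobs = blobs.copy()
            blobs[:, :2] += field(blobs[:, :2])
        levels.append(_render(blobs, spec.image, noise))
    return levels


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-shape images."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a -= a.mean()
    b -= b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# ROI perturbation with exact ground-truth transform
# ---------------------------------------------------------------------------

class RoiTransform:
    """Ground truth for a perturbed ROI.

    Maps (x, y) pixel coordinates of the *source image* to coordinates in
    the perturbed ROI raster and back.  The perturbation is
    q + D(q) = R(p - origin) where R is the rotation about the crop center
    and D the smooth control-point displacement field evaluated in the
    output frame; ``apply`` solves this fixed-point relation (the field is
    a contraction for the small displacements used here), so
    ``invert(apply(p)) == p`` to high precision.
    """

    def __init__(
        self,
        crop_origin_xy: tuple[float, float],
        rotation_matrix: np.ndarray,
        center_xy: np.ndarray,
        displacement: Callable[[np.ndarray], np.ndarray] | None,
    ) -> None:
        self.crop_origin_xy = np.asarray(crop_origin_xy, dtype=np.float64)
        self._rot = rotation_matrix
        self._center = center_xy
        self._disp = displacement

    def _rotate(self, pts: np.ndarray) -> np.ndarray:
        return (pts - self._center) @ self._rot.T + self._center

    def _unrotate(self, pts: np.ndarray) -> np.ndarray:
        return (pts - self._center) @ self._rot + self._center

    def invert(self, roi_xy: np.ndarray) -> np.ndarray:
        """Perturbed-ROI coordinates -> source-image coordinates."""
        q = np.atleast_2d(np.asarray(roi_xy, dtype=np.float64))
        moved = q + (self._disp(q) if self._disp is not None else 0.0)
        return self._unrotate(moved) + self.crop_origin_xy

    def apply(self, image_xy: np.ndarray) -> np.ndarray:
        """Source-image coordinates -> perturbed-ROI coordinates."""
        p = np.atleast_2d(np.asarray(image_xy, dtype=np.float64))
        target = self._rotate(p - self.crop_origin_xy)
        q = target.copy()
        if self._disp is not None:
            for _ in range(100):
                step = target - self._disp(q)
                if np.abs(step - q).max() < 1e-12:
                    q = step
                    break
                q = step
        return q


def perturb_roi(
    image: np.ndarray,
    crop_rect: tuple[int, int, int, int],
    warp: WarpSpec = WarpSpec(),
) -> tuple[np.ndarray, RoiTransform]:
    """Crop, rotate about the crop center, and smoothly point-warp an ROI.

    ``crop_rect`` is (row0, col0, height, width) and must lie inside the
    image.  Returns the perturbed ROI raster (same size as the crop, with
    uncovered corners filled with the crop's mean intensity) and the exact
    :class:`RoiTransform`.  Zero rotation with zero displacement returns
    the crop unchanged.
    """
    image = np.asarray(image)
    row0, col0, height, width = crop_rect
    if (row0 < 0 or col0 < 0 or height <= 0 or width <= 0
            or row0 + height > image.shape[0] or col0 + width > image.shape[1]):
        raise ValueError(f"crop_rect {crop_rect} outside image {image.shape}")
    crop = image[row0:row0 + height, col0:col0 + width].astype(np.float64)

    rng = np.random.default_rng(warp.seed)
    theta = np.deg2rad(warp.rotation_deg)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    center = np.array([(width - 1) / 2.0, (height - 1) / 2.0])

    displacement: Callable[[np.ndarray], np.ndarray] | None = None
    if warp.max_displacement_px > 0:
        n = warp.n_control_points
        control = np.column_stack(
            [rng.uniform(0, width - 1, n), rng.uniform(0, height - 1, n)]
        )
        angle = rng.uniform(0, 2 * np.pi, n)
        radius = rng.uniform(0, warp.max_displacement_px, n)
        values = np.column_stack([radius * np.cos(angle), radius * np.sin(angle)])
        rbf = RBFInterpolator(
            control, values, kernel="thin_plate_spline", smoothing=1.0
        )
        displacement = rbf

    transform = RoiTransform((float(col0), float(row0)), rot, center, displacement)

    identity = warp.rotation_deg % 360.0 == 0.0 and displacement is None
    if identity:
        return crop.astype(image.dtype, copy=True), transform

    def inverse_map(coords: np.ndarray) -> np.ndarray:
        # skimage passes output (col, row); source = inverse transform
        src = transform.invert(coords) - transform.crop_origin_xy
        return src

    warped = _sk_warp(
        crop, inverse_map, order=1, cval=float(crop.mean()), preserve_range=True
    )
    return np.rint(warped).astype(np.uint8), transform


def make_variant_stack(
    levels: list[np.ndarray],
    *,
    scale: tuple[float, float] = (1.15, 1.25),
    max_displacement_px: float = 4.0,
    gamma: float = 1.1,
    seed: int = 0,
) -> list[np.ndarray]:
    """A 'second reference space' for a stack: every level anisotropically
    scaled, smoothly warped, and gamma-adjusted -- the analogue of the same
    brain drawn in a different atlas geometry."""
    rng = np.random.default_rng(seed)
    sx, sy = scale
    if sx <= 0 or sy <= 0:
        raise ValueError("scale factors must be positive")
    out: list[np.ndarray] = []
    for level in levels:
        h, w = level.shape
        oh, ow = int(round(h * sy)), int(round(w * sx))
        disp = None
        if max_displacement_px > 0:
            n = 16
            control = np.column_stack(
                [rng.uniform(0, ow - 1, n), rng.uniform(0, oh - 1, n)]
            )
            angle = rng.uniform(0, 2 * np.pi, n)
            radius = rng.uniform(0, max_displacement_px, n)
            disp = RBFInterpolator(
                control,
                np.column_stack([radius * np.cos(angle), radius * np.sin(angle)]),
                kernel="thin_plate_spline",
                smoothing=1.0,
            )

        def inverse_map(coords: np.ndarray, disp=disp) -> np.ndarray:
            moved = coords + (disp(coords) if disp is not None else 0.0)
            return moved / np.array([sx, sy])

        warped = _sk_warp(
            level.astype(np.float64), inverse_map, output_shape=(oh, ow),
            order=1, cval=float(level.mean()), preserve_range=True,
        )
        adjusted = 255.0 * (np.clip(warped, 0, 255) / 255.0) ** gamma
        out.append(np.rint(adjusted).astype(np.uint8))
    return out


# ---------------------------------------------------------------------------
# point-source datasets with planted corrections
# ---------------------------------------------------------------------------

def make_point_dataset(
    n_points: int,
    planted_shift: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Uncorrected/corrected point pairs with a planted constant offset.

    A positions are uniform in the 2 x 2 mm workspace; B = A +
    ``planted_shift`` plus optional Gaussian noise (mm).  Returns two lists
    of :class:`~ratlas.migration.PointSource` in the migration CSV schema.
    """
    from .migration import PointSource

    if n_points < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    ax = rng.uniform(-1.0, 1.0, n_points)
    ay = rng.uniform(-1.0, 1.0, n_points)
    dx, dy = planted_shift
    bx = ax + dx + (rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else 0.0)
    by = ay + dy + (rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else 0.0)
    a_points = [
        PointSource(f"case{i:03d}", "a", float(ax[i]), float(ay[i]), "synthetic")
        for i in range(n_points)
    ]
    b_points = [
        PointSource(f"case{i:03d}", "a", float(bx[i]), float(by[i]), "synthetic")
        for i in range(n_points)
    ]
    return a_points, b_points


def write_point_csv(points, path) -> None:
    """Write PointSource records in the ``pair,case_label,tag,x_mm,y_mm`` schema."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["pair", "case_label", "tag", "x_mm", "y_mm"])
        for p in points:
            writer.writerow([p.pair, p.case_label, p.tag,
                             f"{p.x_mm:.5f}", f"{p.y_mm:.5f}"])
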