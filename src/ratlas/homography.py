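"""Homography estimation and randomized consensus search (RANSAC).

A set of putative point correspondences between a region of interest and a
candidate plate is geometrically consistent if a single plane-projective
transform H maps each ROI point onto its partner.  RANSAC searches for the
transform with the largest consensus: it repeatedly fits H to a random
minimal sample of four correspondences and counts how many correspondences
reproject within a pixel threshold (strictly below; an error exactly equal
to the threshold is an outlier).  The winning inlier count is the
similarity metric used to rank candidate plates.

The homography fit is a normalized direct linear transform (DLT): both
point sets are translated/scaled to zero centroid and mean distance
sqrt(2), the 2n x 9 design matrix is solved by SVD, and the result is
de-normalized.  Minimal four-point samples with repeated points or any
three points collinear are degenerate (the DLT loses rank) and are redrawn
without consuming an iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Homography", "DegenerateSampleError", "fit_homography",
    "reprojection_error", "count_inliers", "RansacConfig", "RansacResult",
    "ransac",
]

_COLLINEAR_TOL = 1e-9


class DegenerateSampleError(ValueError):
    """The point configuration cannot determine a homography (rank loss)."""


@dataclass(frozen=True)
class Homography:
    """An invertible 3x3 projective plane transform.

    The matrix is normalized so its bottom-right entry equals 1 whenever
    that entry is nonzero.  Points are (x, y); `apply` dehomogenizes.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-15:
            raise DegenerateSampleError("homography matrix is singular")
        if m[2, 2] != 0:
            m = m / m[2, 2]
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) points; rows mapping to the plane at infinity give inf."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        hom = np.hstack([pts, np.ones((len(pts), 1))]) @ self.matrix.T
        with np.errstate(divide="ignore", invalid="ignore"):
            out = hom[:, :2] / hom[:, 2:3]
        out[hom[:, 2] == 0] = np.inf
        return out

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))


def _normalization(points: np.ndarray) -> np.ndarray:
    """Hartley similarity transform: zero centroid, mean distance sqrt(2)."""
    centroid = points.mean(axis=0)
    dist = np.sqrt(((points - centroid) ** 2).sum(axis=1)).mean()
    scale = np.sqrt(2.0) / dist if dist > 0 else 1.0
    return np.array(
        [[scale, 0.0, -scale * centroid[0]],
         [0.0, scale, -scale * centroid[1]],
         [0.0, 0.0, 1.0]]
    )


def _is_degenerate_quad(points: np.ndarray) -> bool:
    """True if any points repeat or any three of the four are collinear."""
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if np.all(np.abs(points[i] - points[j]) < _COLLINEAR_TOL):
                return True
    idx = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    for a, b, c in idx:
        u, v = points[b] - points[a], points[c] - points[a]
        area2 = abs(u[0] * v[1] - u[1] * v[0])
        norm = max(np.hypot(*u), np.hypot(*v), 1.0)
        if area2 < _COLLINEAR_TOL * norm:
            return True
    return False


def fit_homography(p: np.ndarray, q: np.ndarray) -> Homography:
    """Least-squares homography mapping points ``p`` onto ``q`` (both (n, 2)).

    Exactly four non-degenerate correspondences are reproduced to machine
    precision; more than four give the algebraic least-squares solution of
    the normalized DLT.
    """
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    q = np.atleast_2d(np.asarray(q, dtype=np.float64))
    if p.shape != q.shape or p.shape[0] < 4 or p.shape[1] != 2:
        raise ValueError("need >=4 (p, q) correspondences of 2-D points")
    if p.shape[0] == 4 and (_is_degenerate_quad(p) or _is_degenerate_quad(q)):
        raise DegenerateSampleError(
            "minimal sample has repeated or collinear points"
        )
    matrices = _fit_batch(p[np.newaxis], q[np.newaxis])
    try:
        return Homography(matrices[0])
    except DegenerateSampleError:
        raise DegenerateSampleError(
            "correspondences do not determine an invertible homography"
        ) from None


def _fit_batch(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Vectorized normalized DLT over m samples: (m, n, 2) x2 -> (m, 3, 3)."""
    m, n, _ = p.shape
    # per-sample Hartley normalization
    def norm_params(pts):
        c = pts.mean(axis=1, keepdims=True)                      # (m,1,2)
        d = np.sqrt(((pts - c) ** 2).sum(axis=2)).mean(axis=1)   # (m,)
        s = np.where(d > 0, np.sqrt(2.0) / np.where(d > 0, d, 1.0), 1.0)
        return c[:, 0, :], s

    cp, sp = norm_params(p)
    cq, sq = norm_params(q)
    pn = (p - cp[:, None, :]) * sp[:, None, None]
    qn = (q - cq[:, None, :]) * sq[:, None, None]

    A = np.zeros((m, 2 * n, 9))
    x, y = pn[..., 0], pn[..., 1]
    u, v = qn[..., 0], qn[..., 1]
    A[:, 0::2, 0] = -x
    A[:, 0::2, 1] = -y
    A[:, 0::2, 2] = -1.0
    A[:, 0::2, 6] = u * x
    A[:, 0::2, 7] = u * y
    A[:, 0::2, 8] = u
    A[:, 1::2, 3] = -x
    A[:, 1::2, 4] = -y
    A[:, 1::2, 5] = -1.0
    A[:, 1::2, 6] = v * x
    A[:, 1::2, 7] = v * y
    A[:, 1::2, 8] = v
    _, _, vt = np.linalg.svd(A)
    H_norm = vt[:, -1, :].reshape(m, 3, 3)

    # de-normalize: H = Tq^-1 Hn Tp
    Tp = np.zeros((m, 3, 3))
    Tp[:, 0, 0] = sp
    Tp[:, 1, 1] = sp
    Tp[:, 0, 2] = -sp * cp[:, 0]
    Tp[:, 1, 2] = -sp * cp[:, 1]
    Tp[:, 2, 2] = 1.0
    Tq_inv = np.zeros((m, 3, 3))
    inv_sq = 1.0 / sq
    Tq_inv[:, 0, 0] = inv_sq
    Tq_inv[:, 1, 1] = inv_sq
    Tq_inv[:, 0, 2] = cq[:, 0]
    Tq_inv[:, 1, 2] = cq[:, 1]
    Tq_inv[:, 2, 2] = 1.0
    H = Tq_inv @ H_norm @ Tp
    w = H[:, 2, 2]
    nonzero = w != 0
    H[nonzero] = H[nonzero] / w[nonzero, None, None]
    return H


def reprojection_error(H: Homography, p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance |H(p) - q| in pixels (inf if p maps to infinity)."""
    projected = H.apply(np.asarray(p, dtype=np.float64).reshape(1, 2))[0]
    if not np.all(np.isfinite(projected)):
        return np.inf
    return float(np.hypot(*(projected - np.asarray(q, dtype=np.float64))))


def count_inliers(
    H: Homography, matches: np.ndarray, threshold: float
) -> np.ndarray:
    """Inlier flags under ``H``: reprojection error *strictly* below the
    threshold (an error exactly equal to the threshold is an outlier)."""
    pairs = np.asarray(matches, dtype=np.float64).reshape(-1, 2, 2)
    projected = H.apply(pairs[:, 0, :])
    err = np.linalg.norm(projected - pairs[:, 1, :], axis=1)
    return np.nan_to_num(err, nan=np.inf) < threshold


@dataclass(frozen=True)
class RansacConfig:
    """``iterations`` random minimal samples are scored; matches with
    reprojection error strictly below ``inlier_threshold_px`` count as
    inliers.  ``min_sample`` is fixed at 4, the minimal set determining a
    homography.  ``refit`` re-estimates the winning transform on its inliers
    (off by default: the winning raw four-point hypothesis is retained)."""

    iterations: int = 2000
    inlier_threshold_px: float = 10.0
    min_sample: int = 4
    seed: int = 0
    refit: bool = False

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if self.inlier_threshold_px <= 0:
            raise ValueError("inlier_threshold_px must be positive")
        if self.min_sample != 4:
            raise ValueError("min_sample is fixed at 4 for a homography")


@dataclass
class RansacResult:
    homography: Homography | None
    inlier_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    inlier_count: int = 0

    def __post_init__(self) -> None:
        self.inlier_flags = np.asarray(self.inlier_flags, dtype=bool)
        if self.inlier_count != int(self.inlier_flags.sum()):
            raise ValueError("inlier_count must equal the number of set flags")


_MAX_REDRAW_ROUNDS = 64


def ransac(
    matches: np.ndarray | list[tuple[np.ndarray, np.ndarray]],
    config: RansacConfig = RansacConfig(),
) -> RansacResult:
    """Consensus search over putative correspondences.

    ``matches`` is an (n, 2, 2) array (or list of (p, q) pairs) of matched
    (x, y) points.  Runs exactly ``config.iterations`` valid minimal
    samples (degenerate draws are replaced without consuming an iteration),
    scores each four-point hypothesis by its strict-inequality inlier
    count, and returns the earliest hypothesis attaining the maximum.
    Fewer than four matches yield an absent homography and zero inliers.
    Bit-for-bit reproducible for a fixed seed and input order.
    """
    pairs = np.asarray(
        [(np.asarray(p, float), np.asarray(q, float)) for p, q in matches],
        dtype=np.float64,
    ).reshape(-1, 2, 2)
    n = len(pairs)
    if n < 4:
        return RansacResult(None, np.zeros(n, dtype=bool), 0)

    p_all, q_all = pairs[:, 0, :], pairs[:, 1, :]
    rng = np.random.default_rng(config.seed)
    iters = config.iterations

    # draw minimal samples, replacing degenerate ones (never counting them)
    samples = np.empty((iters, 4), dtype=np.intp)
    need = np.ones(iters, dtype=bool)
    for _ in range(_MAX_REDRAW_ROUNDS):
        k = int(need.sum())
        if k == 0:
            break
        draw = rng.random((k, n)).argsort(axis=1)[:, :4]
        samples[need] = draw
        bad = _degenerate_mask(p_all[samples[need]]) | _degenerate_mask(
            q_all[samples[need]]
        )
        idx = np.flatnonzero(need)
        need[idx[~bad]] = False
    if need.any():
        # the match set offers (almost) no non-degenerate quadruple
        return RansacResult(None, np.zeros(n, dtype=bool), 0)

    H_batch = _fit_batch(p_all[samples], q_all[samples])

    # score every hypothesis: reprojection error of all matches
    hom = np.concatenate([p_all, np.ones((n, 1))], axis=1)  # (n, 3)
    proj = np.einsum("mij,nj->mni", H_batch, hom)            # (m, n, 3)
    w = proj[:, :, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        xy = proj[:, :, :2] / w[:, :, None]
    err = np.linalg.norm(xy - q_all[None, :, :], axis=2)
    err[(w == 0) | ~np.isfinite(err)] = np.inf
    inlier_mask = err < config.inlier_threshold_px
    counts = inlier_mask.sum(axis=1)

    best = int(np.argmax(counts))  # argmax returns the earliest maximum
    best_flags = inlier_mask[best]
    best_count = int(counts[best])
    if best_count == 0:
        return RansacResult(None, np.zeros(n, dtype=bool), 0)

    try:
        H_best = Homography(H_batch[best])
    except DegenerateSampleError:
        return RansacResult(None, np.zeros(n, dtype=bool), 0)

    if config.refit and best_count >= 4:
        try:
            H_ref = fit_homography(p_all[best_flags], q_all[best_flags])
        except (DegenerateSampleError, ValueError):
            H_ref = None
        if H_ref is not None:
            ref_flags = count_inliers(H_ref, pairs, config.inlier_threshold_px)
            if int(ref_flags.sum()) >= best_count:
                H_best, best_flags = H_ref, ref_flags
                best_count = int(ref_flags.sum())

    return RansacResult(H_best, best_flags, best_count)


def _degenerate_mask(quads: np.ndarray) -> np.ndarray:
    """Vectorized degeneracy test for (m, 4, 2) minimal samples."""
    m = quads.shape[0]
    bad = np.zeros(m, dtype=bool)
    for i in range(4):
        for j in range(i + 1, 4):
            bad |= np.all(
                np.abs(quads[:, i] - quads[:, j]) < _COLLINEAR_TOL, axis=1
            )
    for a, b, c in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
        u = quads[:, b] - quads[:, a]
        v = quads[:, c] - quads[:, a]
        area2 = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
        norm = np.maximum(
            np.maximum(np.hypot(u[:, 0], u[:, 1]), np.hypot(v[:, 0], v[:, 1])), 1.0
        )
        bad |= area2 < _COLLINEAR_TOL * norm
    return bad
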