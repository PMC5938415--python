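"""End-to-end plate matcher: features -> ratio-test matches -> RANSAC rank.

Given a region of interest (ROI) and a stack of candidate plate images, the
matcher detects keypoints in all images, matches ROI descriptors against
each candidate with the ratio test, and scores each candidate by the RANSAC
inlier count -- the number of matches consistent with a single homography.
Candidates are ranked by inlier count (descending), then raw match count,
then input order.  Each candidate's consensus search runs with an
independent seed derived from the base seed and the candidate's position so
that a ranking is reproducible end to end.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .features import FeatureSet, MatchConfig, detect_features, match_descriptors
from .homography import RansacConfig, RansacResult, ransac

__all__ = ["CandidateScore", "RankedResult", "score_candidate",
           "score_features", "rank_plates", "rank_plate_features",
           "write_ranking_csv"]


@dataclass(frozen=True)
class CandidateScore:
    candidate_id: str
    sift_matches: int
    ransac_inliers: int

    def __post_init__(self) -> None:
        if self.ransac_inliers > self.sift_matches:
            raise ValueError("inliers cannot exceed the number of matches")


@dataclass
class RankedResult:
    scores: list[CandidateScore]

    @property
    def best(self) -> str:
        return self.scores[0].candidate_id


def score_features(
    roi: FeatureSet,
    candidate: FeatureSet,
    match_config: MatchConfig = MatchConfig(),
    ransac_config: RansacConfig = RansacConfig(),
) -> tuple[CandidateScore, RansacResult]:
    """Score one candidate from precomputed feature sets."""
    cid = candidate.image_id
    if len(roi) == 0 or len(candidate) < 2:
        if len(candidate) < 2:
            warnings.warn(
                f"candidate {cid or '<unnamed>'} yields {len(candidate)} "
                "descriptors (<2); scoring it 0",
                stacklevel=2,
            )
        return CandidateScore(cid, 0, 0), RansacResult(None)
    matches = match_descriptors(roi, candidate, match_config)
    if len(matches) == 0:
        return CandidateScore(cid, 0, 0), RansacResult(None)
    roi_xy, cand_xy = roi.xy, candidate.xy
    pairs = np.stack(
        [
            np.array([roi_xy[m.roi_index] for m in matches]),
            np.array([cand_xy[m.target_index] for m in matches]),
        ],
        axis=1,
    )
    result = ransac(pairs, ransac_config)
    return CandidateScore(cid, len(matches), result.inlier_count), result


def score_candidate(
    roi_image: np.ndarray,
    candidate_image: np.ndarray,
    match_config: MatchConfig = MatchConfig(),
    ransac_config: RansacConfig = RansacConfig(),
    *,
    candidate_id: str = "",
) -> CandidateScore:
    """Feature-match one ROI against one candidate plate image."""
    roi = detect_features(roi_image, "roi")
    candidate = detect_features(candidate_image, candidate_id)
    score, _ = score_features(roi, candidate, match_config, ransac_config)
    return score


def rank_plate_features(
    roi: FeatureSet,
    candidates: Sequence[FeatureSet],
    match_config: MatchConfig = MatchConfig(),
    ransac_config: RansacConfig = RansacConfig(),
) -> RankedResult:
    """Rank precomputed candidate feature sets against an ROI feature set."""
    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    scored: list[tuple[int, CandidateScore]] = []
    for index, cand in enumerate(candidates):
        cfg = RansacConfig(
            iterations=ransac_config.iterations,
            inlier_threshold_px=ransac_config.inlier_threshold_px,
            seed=ransac_config.seed + index,
            refit=ransac_config.refit,
        )
        score, _ = score_features(roi, cand, match_config, cfg)
        if not score.candidate_id:
            score = CandidateScore(str(index), score.sift_matches, score.ransac_inliers)
        scored.append((index, score))
    scored.sort(key=lambda t: (-t[1].ransac_inliers, -t[1].sift_matches, t[0]))
    return RankedResult([s for _, s in scored])


def rank_plates(
    roi_image: np.ndarray,
    candidates: Sequence[np.ndarray] | Mapping[str, np.ndarray],
    match_config: MatchConfig = MatchConfig(),
    ransac_config: RansacConfig = RansacConfig(),
) -> RankedResult:
    """Rank candidate plate images by geometric similarity to the ROI."""
    if isinstance(candidates, Mapping):
        items = list(candidates.items())
    else:
        items = [(str(i), img) for i, img in enumerate(candidates)]
    if not items:
        raise ValueError("need at least one candidate")
    roi = detect_features(roi_image, "roi")
    feature_sets = [detect_features(img, cid) for cid, img in items]
    return rank_plate_features(roi, feature_sets, match_config, ransac_config)


def write_ranking_csv(result: RankedResult, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["rank", "candidate_id", "sift_matches", "ransac_inliers"])
        for rank, score in enumerate(result.scores, start=1):
            writer.writerow(
                [rank, score.candidate_id, score.sift_matches, score.ransac_inliers]
            )
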