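# Methods

`ratlas` implements a three-part framework for moving neuroanatomical data
between the two dominant rat-brain reference spaces: the Paxinos–Watson
(*PW*) and Swanson (*S*) stereotaxic atlases. The parts are independent and
composable: (1) a craniometric alignment of atlas *levels* (transverse
plates) along the anteroposterior axis, (2) a feature-based computer-vision
matcher that ranks candidate plate images by similarity to a queried region
of interest, and (3) a point-source data-migration step with quantitative
analysis of the expert corrections it requires.

## Craniometric alignment

Every atlas plate is published with its anteroposterior distance *z* from
the skull landmark Bregma (β), positive anterior. The eleven atlas editions
collapse into four reference spaces — `PW1` ('82/'86/'97, one tissue set),
`PW2` ('98, same tissue plus two extra plates, shifting the numbering),
`PW3` ('05/'07/'14, a different animal sampled at ~120 µm rather than
~500 µm), and `S` ('92/'98/'04/'18, one tissue set) — and the bundled
registry (`table1_registry.csv`) carries one `(group, level, z)` row per
plate, 387 rows in total (76 PW1, 78 PW2, 160 PW3, 73 S).

*z* is stored as an **integer number of micrometers**. The classification
rests on exact equality ("fully in register", z_PW = z_S) and an inclusive
50 µm window ("narrowly in register", 0 < |Δz| ≤ 50 µm; beyond that, "not
in register"), and neither comparison is safe in floating point. The 50 µm
default reflects the physical scale of injection cannulae and probe tracks:
two plates closer than a probe diameter are interchangeable targets for
most purposes. The threshold is configurable (`AlignmentConfig`), and an
exactly-at-threshold separation counts as narrow.

The alignment engine enumerates *all* cross-group pairs within the window
rather than nearest neighbors only — the published concordance lists a PW3
level paired with two S levels, which a nearest-only rule cannot produce —
and reports nearest-match pairs separately (ties reported both, ordered by
level index). The dot-plot export assigns each group a rank on a dummy
categorical axis and colors each dot by its proximity to the comparison
group (black = fully, open = narrowly, red = not in register), written as
CSV and a minimal SVG.

### Transcription notes on the bundled registry

The printed source table contains several typographical defects, carried or
resolved as follows (nothing else was edited):

- Near z = −11 mm the printed PW3 column repeats indices 117/118/119 (first
  seen near −10.1 mm) and the S column repeats 52/53, while PW3 125–128 and
  S 56/57 are skipped. The loadable registry renumbers the five second
  occurrences to the skipped consecutive indices, keeping every printed z.
  A verbatim file (`table1_as_printed.csv`) retains the duplicates; the
  `validate_monotonicity` auditor flags them (z must strictly decrease with
  plate number within a group).
- The printed z = −11.28 row carries no level at all, so one PW3 plate
  (index 128) is absent from any transcription; the source text's count of
  312 unique levels (76 PW1 + 2 PW2-only + 161 PW3 + 73 S) is therefore one
  more than the printed table can support.
- The published fully-in-register list for PW3↔S contains a row pairing
  PW3 level 11 with S level 11 at z = 0.00, contradicting the registry
  (those levels sit at +3.00 and +1.70 mm). It is treated as an erratum;
  the engine finds the seven self-consistent pairs.
- Two PW1↔S pairs satisfy the stated ≤50 µm rule but are absent from the
  published narrow list: (PW1 19, S 19, 40 µm) and (PW1 55, S 49, 50 µm).
  The engine reports them; tests pin them as the only extras.

## Feature-based plate matching

The matcher follows the classic retrieval pipeline:

1. **Detection/description.** Keypoints are difference-of-Gaussians extrema
   in scale space with 128-dimensional gradient-orientation descriptors
   (SIFT). This step delegates to scikit-image's implementation with Lowe's
   published defaults; the pipeline contract (determinism, 128-d
   descriptors, scale and dominant orientation per keypoint, positional
   consistency under cropping) is what the tests assert, not internal
   pyramid parameters. Images are reduced to 8-bit luminance first; a
   constant image yields an empty feature set, not an error.
2. **Matching.** For each ROI descriptor *u* the two nearest target
   descriptors *v*, *w* are found by Euclidean distance; (*u*, *v*) is a
   match iff |u−v|/|u−w| < 0.8. An absolute cutoff on |u−v| is available
   but disabled by default — no value is established for it, and the ratio
   test is the operative filter. Distance ties break toward the smaller
   target index, so matching is deterministic and invariant to target
   order.
3. **Consensus (RANSAC).** A homography H is fit to a random minimal sample
   of 4 matches by normalized DLT (Hartley normalization, SVD); matches
   with reprojection error |H(p)−q| strictly below 10 px are inliers. This
   repeats for exactly 2000 valid samples — degenerate draws (repeated
   points, or any 3 of 4 collinear within 1e−9 relative area) are redrawn
   without consuming an iteration — and the earliest hypothesis with the
   most inliers is retained, raw (no least-squares refit; a refit is
   available behind `RansacConfig(refit=True)` but changes the headline
   metric, so it is off by default). Fewer than 4 matches score 0.
   Sampling is driven by a seeded generator; results are reproducible
   bit-for-bit for a fixed seed and input order.

The **inlier count is the similarity metric**; candidates are ranked by it
(ties: raw match count, then input order). In ranking, each candidate's
search uses seed `base + index` so the full ranking is one reproducible
unit. A four-point sample determines a homography, and the published
pipeline uses that sample size, so the projective (not affine) model is
implemented.

## Synthetic image fixtures

Atlas photomicrographs are copyrighted, so all image tests run on generated
stand-ins: 512×512 fields of 160 seeded Gaussian blobs (3–16 px scale,
mixed polarity on mid-gray) plus band-limited noise at 0.08 relative
amplitude. This density yields several hundred SIFT keypoints per image —
enough for stable ranking statistics at tractable test runtimes. The
fixtures deliberately do *not* imitate Nissl cytoarchitecture (no laminae,
no cell-density gradients); they reproduce the *feature-matching* regime
only, so passing tests demonstrate the pipeline's geometric correctness,
not its performance on real histology.

A 40-level *stack* emulates a sequential tissue series: each level
re-samples 20% of the blobs and drifts all blob centers along a smooth
random field (6 px RMS), so structural correlation decays with level
distance — the property that makes "top-ranked plates cluster around the
true level" a meaningful expectation. A *variant stack* (anisotropic
1.15/1.25 scaling, mild smooth warp, gamma shift) stands in for the same
brain rendered in a second atlas geometry.

`perturb_roi` reproduces the published ROI stress test: crop, rotate 155°
about the crop center, and apply a scattered-control-point warp
(thin-plate-spline displacements ≤ 5 px — the source calls the distortion
"slight" without quantifying it; 5 px keeps it within SIFT's partial
invariance to geometric distortion). The warp is defined by its inverse
map; the forward map solves the fixed-point relation to <1e−9 px, and the
exact transform object is returned so tests can verify recovered keypoint
geometry against ground truth.

Experiment analogues (in `tests/test_acceptance.py`): a rotated+warped ROI
must rank its source level first for 10/10 seeds; an undistorted self-crop
must strictly outrank every other level, with ≥80% of its matches surviving
consensus; an ROI from the variant stack must rank within ±1 level of its
true source for ≥9/10 seeds. Problem sizes (40 levels, 200×200 ROIs, 10
seeds) keep the full suite to a few minutes while leaving the failure
probabilities of the stochastic assertions negligible.

## Point-source migration and correction analysis

A mapped datum is reduced to a point (x = mediolateral, y = dorsoventral,
mm from origin O of a 2×2 mm Cartesian workspace; positions outside the
workspace warn but do not fail, since other datasets may use larger
quadrants). Transfer between frames is anisotropic scaling about O —
defaults 139% horizontal / 161% vertical for S→PW grid alignment, or a
single 139.5% factor in `normalize_both` mode. The documented ~0.4%/~0.1%
discrepancy between the two routes depends on atlas grid geometry not
bundled here and is surfaced, not asserted.

Expert-guided relocation is strictly an input (a corrected-positions file
joined on pair + case label + tag). For each pair A (uncorrected) and B
(corrected) the correction vector is

    ABx = |Bx − Ax|,  ABy = Ay − By,
    AB  = √(ABx² + ABy²),  φ = atan2(ABy, ABx) · 180/π,

with φ = 0 by convention when A = B. These component conventions are the
ones the published reference table satisfies across all 24 rows (ten rows
have Bx < Ax with a positive printed ABx, and the one correction that
crosses the midline rules out a |‖Bx‖−‖Ax‖| reading); ABy is positive for
ventral corrections. Summaries report per-column mean and SEM with
SEM = sd(n−1)/√n.

Transcription notes on the bundled reference dataset: three Ay cells in the
printed source are typos, each restorable from the table's own error
columns and printed means — one sign flip, one value duplicated from the
row above, one 0.001 slip — and the bundled `table7_A.csv` stores the
restored values. The printed SEM row divides the sample SD by √26 rather
than √24 (verified to the printed precision for every column; evidently a
spreadsheet range slip); `summarize` uses the correct √n, and the test
suite reproduces the printed row via the reconstructed divisor.

## Numerical and design choices

- Integer µm for z; round-half-away-from-zero parsing through decimal
  digits (no float rounding).
- Homography matrices normalized to H[2,2] = 1 when nonzero; points mapping
  to the plane at infinity get infinite reprojection error.
- RANSAC inequality is strict (< threshold); equal-count ties keep the
  earlier iteration.
- Descriptor-distance ties break to the smaller target index; ratio = 1
  disables the ratio filter (plain nearest-neighbor assignment).
- All generators are pure functions of their spec including the seed;
  acceptance-relevant fixtures pin their seeds in the tests.
- CSV outputs print mm to 5 decimals and degrees to 3, matching the
  precision of the reference tables so diffs are textual.

## Known limitations

- Craniometric alignment is one-dimensional by design; it cannot detect
  plane-of-section (tilt) differences between atlases, and no interpolation
  between plates is attempted.
- The matcher assumes a single global homography per plate pair; strong
  non-rigid tissue distortion degrades the inlier count (no thin-plate
  consensus model).
- Synthetic fixtures bound what the tests can claim: results on real
  photomicrographs will differ in match counts and margins.
- The expert correction is quantified, never imitated; the migration step
  is a first-order transfer, not a registration.
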