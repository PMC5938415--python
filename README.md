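# ratlas

Cross-atlas alignment of rat-brain reference spaces.

Neuroscientists map rat-brain data into one of two standard stereotaxic
atlases — Paxinos–Watson (*PW*, seven editions across three tissue sets
`PW1`/`PW2`/`PW3`) or Swanson (*S*, four editions, one tissue set) — and
data mapped in one frame cannot be compared with data mapped in the other
without a level-by-level correspondence. `ratlas` provides that bridge,
for anatomists, physiologists, and anyone curating legacy microinjection
or tracing datasets:

1. **Craniometric alignment.** Every atlas plate carries its
   anteroposterior distance *z* from the skull landmark Bregma (β). A
   bundled registry of 387 plates lets you classify any PW↔S level pair as
   *fully in register* (z_PW = z_S), *narrowly in register*
   (0 < |Δz| ≤ 50 µm, the scale of an injection cannula), or *not in
   register*, and export Cleveland-style dot plots of all four level
   sequences.
2. **Feature-based plate matching.** A computer-vision matcher ranks
   candidate plate images against a queried region of interest (ROI):
   SIFT keypoints (128-d gradient-orientation descriptors), Lowe ratio-test
   matching (|u−v|/|u−w| < 0.8), and RANSAC homography consensus (2000
   four-point samples, 10 px inlier threshold). The inlier count — the
   number of matches consistent with a single projective transform H with
   H(p_i) ≈ q_i — is the similarity metric.
3. **Point-source migration.** Point data (x = mediolateral,
   y = dorsoventral, mm) transfer between frames by anisotropic scaling
   (139%/161%, after Swanson's published factors), and expert corrections
   of the migrated positions are quantified as vectors: ABx = |Bx−Ax|,
   ABy = Ay−By, magnitude √(ABx²+ABy²), direction φ = atan2(ABy, ABx).

A reference dataset of 24 migrated hypothalamic microinjection sites
(uncorrected and expert-corrected positions) is bundled alongside the
level registry. See `docs/methods.md` for the model details, transcription
notes, and design choices.

## Worked example

```python
import ratlas as rt

reg = rt.load_bundled_registry()
print(len(rt.fully_table(reg, "PW1", "S")), "PW1 levels fully in register with S")
print("PW1 L4 z =", reg.z_of("PW1", 4), "um;  S L4 z =", reg.z_of("S", 4), "um")
print("narrow pairs PW3-S:", len(rt.narrowly_table(reg, "PW3", "S")),
      "; closest:", min(d for *_ , d in rt.narrowly_table(reg, "PW3", "S")), "um")

a, b = rt.load_bundled_point_data()
summary = rt.migrate_dataset(a, b, spec=None).summary
print(f"mean correction: {summary.mean['magnitude_ab']:.6f} mm "
      f"at {summary.mean['phi_deg']:.3f} deg "
      f"(ML {summary.mean['abx']*1000:.0f} um, DV {summary.mean['aby']*1000:.0f} um)")
```

prints

```
8 PW1 levels fully in register with S
PW1 L4 z = 5200 um;  S L4 z = 5200 um
narrow pairs PW3-S: 54 ; closest: 10 um
mean correction: 0.460175 mm at 78.351 deg (ML 76 um, DV 442 um)
```

i.e. only eight PW1 plates sit at exactly the same Bregma coordinate as an
S plate; the higher-resolution PW3 series comes within 10 µm of S plates;
and across the bundled migrated dataset the expert moved points on average
0.46 mm, almost straight ventrally (φ ≈ 78°, dorsoventral component 442 µm
vs 76 µm mediolateral).

The same operations are available from the shell:

```sh
ratlas align --registry src/ratlas/data/table1_registry.csv --source PW1 --dest S --out out/
ratlas migrate --points-a src/ratlas/data/table7_A.csv \
               --points-b src/ratlas/data/table7_B.csv --no-scale --out out/
ratlas simulate stack --n-levels 40 --seed 11 --out stack/
ratlas match --roi roi.png --candidates stack/ --seed 0 --out out/
```

Every run writes a `manifest.json` (inputs, parameters, seed, version) so
stochastic results are reproducible.

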