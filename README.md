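# uncrowding

A grouping/segmentation model of visual crowding and uncrowding for
peripheral vernier discrimination, together with the statistical analysis of
subjective Likert ratings of the flanker percepts and a seeded synthetic
rating generator.

The model pipeline has four stages:

1. **`stimuli`** — declarative geometry and rasterization of eight
   vernier/flanker/Pacman conditions (vernier alone; equal-length, long,
   or gapped flanker triplets; gapped or long flankers with four inward- or
   outward-facing Pacman inducers). All geometry is in degrees of visual
   angle; default rendering is 10 px/deg on a 16° × 14° field with a 75%
   luminance background and 25% luminance elements.
2. **`cortical_dynamics`** — orientation-channel boundary responses
   (quadrature edge-energy operators at 4 orientations) with a first-order
   temporal profile: exponential rise from stimulus onset (20 ms), decay
   after offset (140 ms), reported as trailing 20-ms accumulated maps up to
   300 ms.
3. **`grouping_segmentation`** — a boundary graph whose edges join
   like-oriented collinear nodes across gaps (illusory-contour-style
   grouping links) plus terminator attachments; disk-shaped top-down
   selection signals over the flanker tops seed a constant-speed geodesic
   spread that shifts reached contours from Segmentation Layer 0 into
   Layer 1.
4. **`decision`** — vernier-offset evidence as a normalized difference of
   right/left template matches against the Layer-0 vertical-channel
   activity after stimulus offset. Flanker activity left in Layer 0 dilutes
   the evidence (crowding); segmentation that removes it restores the
   evidence (uncrowding).

The analysis side:

* **`rating_analysis`** — per-condition and per-participant Likert
  summaries, an exact Wilcoxon signed-rank test (midranks; smaller
  signed-rank sum as the statistic; exact p by the full 2^n sign-assignment
  distribution for n ≤ 25, normal approximation with tie correction
  beyond), and a within-person consistency metric (mean absolute pairwise
  rating difference per participant × condition cell).
* **`synthetic_data`** — a thresholded-Gaussian (cumulative-link) generator
  reproducing the study design: 15 participants × 6 configurations ×
  2 sides × 2 repetitions = 24 judgments per participant, ratings 1–5,
  fully deterministic per seed.

## Command line

```bash
# rasterize a condition to an 8-bit grayscale PNG
uncrowding render --condition GAPPED_INWARD --offset right --ppd 10 --out img.png

# run the 8-condition evidence battery (optionally vs. an empirical table)
uncrowding evidence --conditions all --out evidence.csv
uncrowding evidence --conditions all --out evidence.csv --empirical acc.csv

# generate a synthetic rating dataset and analyze it
uncrowding simulate-ratings --seed 7 --out ratings.csv
uncrowding ratings analyze --in ratings.csv --test A:D --out report/
```

Rating CSVs are long format with header
`participant,condition,side,repetition,rating`; condition codes are
A = long, B = gapped, C = long+inward, D = gapped+inward, E = long+outward,
F = gapped+outward.

## Notes

* Evidence is antisymmetric under mirroring the vernier offset; the
  `VERNIER_ONLY` condition is the battery maximum.
* The battery reports raw evidence; no psychometric link to proportion
  correct is fitted. `decision.correlate_with_empirical` computes a Pearson
  r against a user-supplied per-condition accuracy table.
* The published quantitative rating statistics depend on unpublished human
  data; the generator defaults are illustrative and documented as such.
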