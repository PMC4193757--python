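# Methods

## Problem and pipeline

Cervical intraepithelial neoplasia (CIN) is graded 1–3 by the fraction of
the squamous epithelium occupied by atypical cells. As the grade rises,
nuclei become denser, larger and more irregularly clustered, so the binary
mask of nuclear pixels in an H&E tile becomes more space-filling. This
package quantifies that change with two scaling statistics of the nuclear
mask — the box-counting dimension `d_BOX` and the generalized-dimension
spectrum `D_q` — and feeds them into a standard group-statistics and
classification layer.

Stages: (1) relative-RGB segmentation of blue-stained nuclei, (2) small-blob
removal, (3) `d_BOX` by grid counting and log–log regression, (4) `D_q`
from box-mass moments, (5) per-case aggregation by the median, (6) group
statistics (ANOVA + Tukey HSD, pooled t-test, KS normality) and
nearest-median grade prediction with confusion matrices.

## Segmentation

A pixel is nuclear when the blue channel's share of the RGB sum is at least
`ratio` percent: `100·B ≥ ratio·(R+G+B)`, evaluated in integer arithmetic so
the threshold and its inclusive tie rule are exact. The default `ratio=41`
sits between the blue share of eosin-pink background (≈33 %) and
haematoxylin-blue nuclei (≳50 %). Pure black pixels, where the share is
undefined, are background — black is not nuclear stain. The rule is
deliberately simple and parameterized; other normalizations (e.g.
max-channel ratios) can be swapped in by replacing one function.

Blob removal deletes connected components below `min_blob_area` pixels
(default 2, i.e. only isolated pixels — components with no adjacent
foreground pixel) using 8-connectivity by default. Both knobs are exposed
for noisier material. The operation is idempotent.

## Box-counting dimension

`N(r)` is the number of top-left-anchored grid boxes of side `r` containing
foreground; `d_BOX` is the negative OLS slope of `log N(r)` vs `log r` over
a geometric ladder of sides, by default dyadic `{L, L/2, …, 2}` including
the trivial `r = L` point (a config switch drops the largest scales; an
optional multi-offset minimum approximates multi-grid sampling — both off
by default, recorded in provenance when used). Images whose side is not a
power of the ladder base are padded with background, which leaves the
counts of the real content unchanged. Natural logs are used; the base
cancels in the slope. An empty mask raises rather than returning 0, so a
failed segmentation is loud.

On exact self-similar test sets the estimator is exact: filled square 2,
line 1, point 0, and the discrete Sierpinski constructions used here have
exactly `3^k` (triangle) / `8^k` (carpet) occupied boxes at depth `k`, so
the fitted slopes equal log 3/log 2 and log 8/log 3 to floating precision.

## Multifractal spectrum

With box masses `N_υ(ε)` (foreground pixels — or sampled points — per
non-empty box) and `p_υ = N_υ/ΣN_υ`, the moment sum `Σ p_υ^q` is regressed
on `ln ε` with `ε` the box side *relative to the image side*, giving

    D_q = 1/(q−1) · slope[ln Σ p^q vs ln ε]   (q ≠ 1)
    D_1 =           slope[Σ p ln p  vs ln ε]

The default q grid is −10 to +10.75 in steps of 0.25 (84 points), which
contains q = 1 exactly, so the entropy branch is mandatory, never a
numerical epsilon hack. Empty boxes are always excluded: for q < 0 the
moment of a vanishing box diverges. The default scale ladder runs from
L/2 down to 4 pixels: the r = L sum is identically 1 and carries no
information, and boxes of a few pixels make negative-q moments explode.
`D_0` equals the box-counting dimension computed from the identical grid
and scales by construction (`Σ p^0` counts the non-empty boxes).

Spectra are computed on the blob-cleaned mask — the same input as `d_BOX` —
and record their scale set and grid origin in provenance.

## Synthetic data

The generators define the test conditions; no external images are needed.

**Benchmarks.** Deterministic masks with known dimensions (above).

**Cascades.** A four-cell multiplicative cascade with weights `w1..w4`
(Σ = 1) subdivides the square `depth` times. The exact-measure mode returns
the cell-mass grid, for which the estimator reproduces the closed form
`D_q = −log2(Σ w_i^q)/(q−1)` to numerical precision at every depth and
scale subset. The point-sample mode draws i.i.d. cells from that measure
and returns the *point-count grid*, not a binarized occupancy: the moment
estimator's `N_υ` is the number of points per box, and binarizing saturates
dense cells, which measurably biases `D_q` for q > 0 at any depth. With
10⁵ points at depth 9 the counts route recovers the closed form within
0.04 over q ∈ [0, 5].

**Pseudo-histology.** A tile is a pink background (default RGB
(235, 185, 205)) with blue-purple elliptical nuclei (default (70, 50, 150));
both colours get ±5 per-channel jitter, which keeps every background pixel
below and every nuclear pixel above the 41 % blue-share threshold, so the
exact ground-truth mask is recoverable by the default segmentation. The
basal `atypia_fraction` of the tile height (thirds rule: 0, 1/3, 2/3, 1 for
normal/CIN1/CIN2/CIN3) carries atypical nuclei — 3.5× denser, 1.35× larger,
more pleomorphic (axis ratio down to 0.5), placed by a parent–offspring
cluster process (6 nuclei per cluster, Gaussian spread 18 px) — while the
remainder carries sparse regular nuclei at 4.5·10⁻⁴ nuclei/px² with mean
radius 7 px (SD 1.5). These defaults were chosen once to give nuclear
coverage from ≈7 % (normal) to ≈30 % (CIN3), the regime where `d_BOX` of
the mask rises monotonically with grade; no quantitative density data were
available to calibrate against, so absolute `d_BOX` values of the synthetic
tiles are not meaningful — only their ordering and the pipeline's ability
to separate the groups. Real H&E variability (stain variation, texture,
out-of-focus regions, touching-nucleus ambiguity) is deliberately not
modelled: passing tests demonstrate correctness of the estimators and the
pipeline's monotone response to nuclear crowding, not clinical performance.

All randomness flows through one integer seed per spec; cohort generation
spawns independent per-tile seeds from the cohort seed, so cohorts are
bit-reproducible.

## Statistics

Each patient contributes the median of their ROI-level `d_BOX` values
(mean of the central pair for even n). Group comparisons: one-way ANOVA
with Tukey HSD post-hoc tests in the Tukey–Kramer form for unequal group
sizes (pairwise SE from `1/n_i + 1/n_j`, studentized-range distribution);
a two-sided pooled-variance Student t-test for low-grade (CIN 1) vs
high-grade (CIN 2+3), with Welch available by flag. Normality screening
uses the Kolmogorov–Smirnov test with the Lilliefors correction on by
default, because plain KS with estimated mean/SD is anti-conservative; the
uncorrected p is available by flag. Significance labels follow α = 0.05 /
0.01. Per-q spectrum comparisons run the same ANOVA/Tukey machinery at
every q on the grid and report, per pair, the maximal contiguous q-interval
of significance; no multiple-testing correction is applied across the 84
q-points by default (a Holm option exists at the call sites that need it).

Grade prediction assigns a case to the group whose reference median is
nearest in absolute `d_BOX` distance, with exact ties broken toward the
less severe grade; reference medians default to resubstitution (the full
sample's own medians). The rule is pluggable — the choice of classifier is
genuinely open, and nearest-median is the simplest monotone rule consistent
with medians ordered by grade. Confusion matrices report counts,
row-normalized percents and overall percent agreement (100·trace/total)
with the pathologist's grading taken as ground truth.

## Numerical choices and problem sizes

- Threshold ties: inclusive (`≥`), fixed and documented.
- Regression: OLS on natural logs; `r²` reported per fit; constant-count
  fits report `r² = 1` (a perfect fit of a constant).
- Degenerate inputs: empty masks raise; degenerate variances raise;
  classifier requires distinct reference medians.
- Test problem sizes: benchmark dimensions are checked at 512 px
  (triangle) and 729 px (carpet); cascade oracles at depth 7 (exact) and
  depth 9 with 10⁵ points (sampled); the end-to-end grade-ordering check
  runs 20 cohort seeds × 46 tiles at 512 px, sizes at which the relevant
  invariants are already sharp. The tile generator's own default remains
  1024 px.

## Known limitations

- The exact semantics of the "relative RGB ratio" segmentation in the
  original GUI tooling are not published; the blue-share rule here is a
  documented, swappable interpretation.
- Single fixed grid origin by default; grid-origin averaging schemes can
  shift `D_q` slightly for masks without exact dyadic structure.
- The nearest-median classifier is a deliberately simple baseline; its
  confusion counts on synthetic cohorts are not comparable to any
  particular published table because the published prediction rule is
  unspecified.
- Tukey HSD p-values computed from 2-decimal published per-case values can
  differ in the second decimal from values computed on unrounded data.
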