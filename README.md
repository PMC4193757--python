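# fractalcin

Fractal and multifractal grading of cervical intraepithelial neoplasia
(CIN) from H&E histology tiles.

CIN lesions — the precursors of cervical cancer — are graded 1–3 by how
much of the squamous epithelium is occupied by atypical cells, a
semi-quantitative judgement made at the microscope. As the grade rises,
nuclei become denser, larger and more irregularly clustered, so the binary
mask of nuclear pixels becomes more space-filling. `fractalcin` turns that
observation into objective numbers:

- **Segmentation** — a pixel is nuclear when the blue channel's relative
  share of the RGB sum reaches a threshold (default 41 %:
  `100·B/(R+G+B) ≥ 41`), separating haematoxylin-blue nuclei from the
  eosin-pink background; isolated speckle is removed by a small-blob
  filter.
- **Box-counting dimension** — `d_BOX` is the negative slope of the OLS
  fit of `log N(r)` vs `log r`, where `N(r)` counts grid boxes of side `r`
  containing foreground over a dyadic ladder of scales.
- **Multifractal spectrum** — generalized dimensions
  `D_q = 1/(q−1)·slope[ln Σ_υ p_υ(ε)^q vs ln ε]` (entropy form at q = 1)
  with box probabilities `p_υ = N_υ/ΣN_υ` over non-empty boxes, on the
  standard q grid −10 … +10.75 in 0.25 steps.
- **Statistics & grading** — per-patient medians, group summaries, one-way
  ANOVA with Tukey HSD, pooled t-tests, KS/Lilliefors normality checks,
  per-q spectrum comparisons, and nearest-median grade prediction with
  confusion matrices.

A synthetic-data module supplies deterministic benchmark fractals and
multiplicative cascades with closed-form dimensions (estimator oracles)
plus grade-parameterized pseudo-H&E tiles with exact ground-truth masks,
so the whole pipeline is testable without any image downloads. A bundled
46-case reference cohort of per-case `d_BOX` values (15 normal / 8 CIN 1 /
6 CIN 2 / 17 CIN 3) drives the worked-example statistics.

## Worked example

```python
from fractalcin import (reference_dbox_values, anova_tukey, two_sample_t,
                        HistologySpec, generate_histology, segment_tile,
                        box_dimension, dq_spectrum)

ref = reference_dbox_values()                       # 46-case reference cohort
res = anova_tukey(ref)
print(f"ANOVA F = {res.anova_f:.2f}, p = {res.anova_p:.2e}")
print(f"Tukey CIN2 vs CIN3: p = {res.p_for('CIN2', 'CIN3'):.4f}")
t, p = two_sample_t(ref["CIN1"], ref["CIN2"] + ref["CIN3"])
print(f"low vs high grade t = {t:.2f}, p = {p:.2e}")

tile, truth = generate_histology(HistologySpec(size=512, grade="CIN3", seed=7))
mask = segment_tile(tile, ratio=41)
bc = box_dimension(mask)
spec = dq_spectrum(mask)
print(f"CIN3 tile: d_BOX = {bc.d_box:.3f} (r2 = {bc.r_squared:.4f}), "
      f"D0 = {spec.d_at(0.0):.3f}, D2 = {spec.d_at(2.0):.3f}")
```

prints

```
ANOVA F = 34.96, p = 1.71e-11
Tukey CIN2 vs CIN3: p = 0.0225
low vs high grade t = -5.32, p = 1.06e-05
CIN3 tile: d_BOX = 1.743 (r2 = 0.9974), D0 = 1.714, D2 = 1.661
```

The four grade groups differ strongly overall (ANOVA), CIN 2 and CIN 3
remain distinguishable after Tukey's multiple-comparison adjustment, and
low-grade differs from high-grade neoplasia at far below the 1 % level.
For the synthetic CIN 3 tile, the segmented nuclear mask has `d_BOX ≈ 1.74`
with an excellent log–log fit; the matching normal-epithelium tile (same
seed) gives `d_BOX ≈ 1.46`, illustrating the monotone rise of fractal
dimension with grade that the grading rule exploits. `D_0` agrees with the
box-counting dimension on the shared scale range by construction, and
`D_0 > D_1 > D_2` reflects the mild multifractality of the clustered
nuclear pattern.

## Command line

```sh
fractalcin simulate --grade CIN2 --seed 7 --out tile.png --mask-out truth.png
fractalcin segment  --in tile.png --out mask.png --ratio 41
fractalcin boxcount --mask mask.png --out result.json
fractalcin mfspec   --mask mask.png --out spectrum.csv
fractalcin simulate-study --outdir study/ --seed 1 --size 512
fractalcin run      --manifest study/manifest.csv --outdir results/
fractalcin analyze  --measurements dbox.csv --outdir results/
```

`run` executes the whole pipeline over a manifest CSV
(`case_id, grade, path`), writes per-ROI and per-case tables, group
summaries, Tukey pairwise p-values, the confusion matrix and a
`report.json`, and embeds the fully resolved configuration so any run can
be replayed exactly.

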