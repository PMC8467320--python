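# ppdxdeg

Quantitative assessment of the hydrolytic degradation of polydioxanone
(PPDX) stent fiber from three complementary measurements:

* **Raman spectroscopy** — the degradation metric at the core of the
  package: the area under the high-wavenumber shoulder of the
  1732 cm⁻¹ ester-carbonyl peak,

  *A*ₛ = ∫₁₇₃₆¹⁷⁴⁹ *I*(ν̃)/*h*₁₇₃₂ dν̃  [cm⁻¹],

  where *h*₁₇₃₂ is the baseline-corrected peak height. The shoulder is
  attributed to C=O vibrations in the *amorphous* phase; because
  hydrolysis attacks amorphous regions preferentially, *A*ₛ decreases
  monotonically with degradation time. Normalising by the peak height
  makes the metric invariant to laser power, focus and acquisition time.
* **SEM crack morphometry** — cracks on the fiber surface are measured
  on binary masks with six descriptors: area, perimeter, Feret's
  diameter and angle (maximum caliper and its orientation), aspect ratio
  (moment-fitted ellipse), circularity 4π·area/perimeter², and solidity
  area/convex area.
* **DSC crystallinity** — percent crystalline phase
  *X*꜀ = 100·Δ*H*ₘ/Δ*H*ᵣₑ𝒻 from the integrated melting endotherm of the
  first heating scan.

Per-period samples (64 spectra on an 8 × 8 grid per specimen) are
compared across consecutive degradation periods with a distribution-free
workflow: D'Agostino K² normality screening (mean ± SD vs
median (Q1, Q3) reporting), paired Wilcoxon signed-rank tests, and
Bonferroni familywise control (α = 0.05 over 4 comparisons →
0.0125 per test).

Because instrument data for such studies is rarely shared, the package
ships a synthetic-data generator (`ppdxdeg.synthgen`) that produces
Raman/FT-IR spectra (pseudo-Voigt peak sets on smooth backgrounds),
crack masks (rasterized ellipse populations with known ground truth) and
DSC thermograms, parameterised by published per-period values. Every
analysis stage is therefore testable end to end against known truth.

## Worked example

Simulate a full five-period degradation study (non-degraded and 4, 8,
16, 24 weeks in phosphate-buffered saline) and analyse it:

```python
from ppdxdeg import pipeline as pl

cfg = pl.RunConfig(output_dir="demo_run")
report = pl.run_synthetic(cfg)
print(report.shoulder[["week", "n", "mean", "sd", "normal", "display"]])
```

which prints (seeds fixed in the default config):

```
 week  n  mean    sd  normal     display
    0 64 9.748 0.441    True 9.75 ± 0.44
    4 64 9.158 0.381    True 9.16 ± 0.38
    8 64 7.886 0.387    True 7.89 ± 0.39
   16 64 6.584 0.305    True 6.58 ± 0.31
   24 64 6.202 0.293    True 6.20 ± 0.29
```

Each row is the grid mean ± SD of the normalized shoulder area (cm⁻¹)
after asymmetric-least-squares baseline removal; the strictly decreasing
mean column is the degradation signal. The accompanying comparison
table shows every consecutive-period drop is significant under the
Bonferroni-corrected signed-rank test:

```
 week_a  week_b     W      p_value  alpha_per_test  significant  direction
      0       4 144.0 2.115763e-09          0.0125         True         -1
      4       8   6.0 4.794335e-12          0.0125         True         -1
      8      16   0.0 3.610097e-12          0.0125         True         -1
     16      24 249.0 1.246976e-07          0.0125         True         -1
```

`report.crystallinity` recovers the configured DSC truths (e.g.
47.63 ± 0.07 % for the non-degraded period from three replicate
thermograms), and `report.cracks` summarises the six morphological
descriptors per period. All intermediate artifacts (spectra CSVs, PGM
masks with ground truth, thermogram CSVs, per-item metric tables) are
written under `output_dir`, and every summary cell is recomputable from
them.

The same pipeline runs on user data (2-column spectrum/thermogram CSVs,
PGM/PNG masks with a pixel-size sidecar) via `pl.run_user_data` or the
CLI:

```
ppdx-degrade simulate --config run.yaml
ppdx-degrade analyze  --config run.yaml
ppdx-degrade spectra  --manifest grid_manifest.json --baseline asls --out metrics.csv
ppdx-degrade cracks   --mask mask.pgm --pixel-size 0.066 --out cracks.csv
```

## Layout

| module | contents |
| --- | --- |
| `ppdxdeg.specquant` | spectra containers, AsLS / anchor baseline correction, shoulder metric, dye-peak tracking, FT-IR band emergence |
| `ppdxdeg.crackmorph` | labeling, boundary tracing, convex hull, rotating-calipers Feret, moment ellipse, the six descriptors, summaries |
| `ppdxdeg.dsc` | thermogram container, endotherm integration, crystallinity |
| `ppdxdeg.degstats` | D'Agostino K², conditional summaries, exact/approximate Wilcoxon signed-rank, Bonferroni, period comparisons |
| `ppdxdeg.synthgen` | calibrated synthetic spectra, crack masks, thermograms |
| `ppdxdeg.pipeline` / `ppdxdeg.cli` | end-to-end orchestration, report tables, `ppdx-degrade` |

See `docs/methods.md` for the models, conventions and numerical choices.
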