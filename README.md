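# stedring

Quantitative analysis of two-channel super-resolution images of ring-shaped
organelle membranes — built for STED imaging of yeast peroxisomes labeled
with a membrane marker (e.g. Pex3) alongside a confocal companion channel
(e.g. the pexophagy receptor Atg30), and for any comparable
membrane-ring / companion-protein imaging problem.

Given a high-resolution membrane channel in which each organelle appears as
a ring, a lower-resolution companion channel on the same pixel grid, and a
table of manually clicked approximate ring centers, the pipeline measures,
per organelle:

- a sub-pixel **circle fit** to the membrane signal (radius, center,
  circumference 2πr),
- the **membrane intensity profile** of both channels as a function of
  arc-length position along the fitted ring,
- the **moving-average Pearson correlation** *R* between the two channel
  profiles,
- a **"Between" / "Outside"** classification of every membrane position
  (at an organelle–organelle contact vs. exposed to the cytosol), with
  per-ring and per-cell class means and the percentage of cells whose
  companion signal is predominantly Outside,

and aggregates everything by condition and biological replicate with a
one-way ANOVA and a one-tailed paired t-test.

## The measurement model

**Ring fit.** From each seeded center, `n_rays` (default 360) radial
intensity profiles are scanned (bilinear interpolation, 0.25 px steps); each
ray's peak is refined to sub-step precision with a parabola. Peaks deviating
more than 10% from the mean distance to the center are excluded (single
pass), and an algebraic least-squares (Kåsa) circle is fitted to the
survivors, re-shooting the rays from the refined center. Because the crest
of a Gaussian-blurred thin ring sits inward of the true radius by ≈ σ²/2r,
the fitted radius is debiased by inverting the analytic crest relation
ρ/r = I₁(ρr/σ²)/I₀(ρr/σ²) with the blur scale σ measured from the radial
profile width. Very small organelles with no central intensity dip are
handled by a segmentation fallback (threshold → connected component →
centroid and major axis). Where fitted rings touch, a contact-aware
refinement pass re-fits each circle from rays outside the optically merged
zones.

**Profiles and R.** Both channels are sampled at the same angles over a
radial band r̂ ± 2 px; the companion channel uses a two-times-wider band to
account for its lower resolution. Per organelle,
R = Pearson(ma(ch1), ma(ch2)) with a circular moving average (default
window 5 samples).

**Between/Outside.** A membrane position is *Between* when it lies within
`gap_nm` (default 30 nm) boundary-to-boundary of another fitted ring. A
cell is classified *outside* when its pooled Outside companion mean exceeds
the pooled Between mean (ratio > 1; ties → between). An optional
membrane-normalized rule divides the companion ratio by the membrane-channel
ratio, removing the purely geometric intensity transfer at contacts (two
membranes superpose, and blur accumulates signal inside clusters).

**Synthetic scenes.** `stedring.synthetic_scenes` generates ground-truthed
two-channel test data: rings with patchy angular emission (von Mises
mixtures), a companion channel coupled to the membrane truth by a mixing
weight α ∈ [0, 1], optional Outside-enrichment β, clusters of tangent rings,
Gaussian PSF blur at two scales (60 nm STED / 250 nm confocal FWHM by
default, 20 nm pixels), background, and Poisson noise — everything seeded
and exactly reproducible, with exported true geometry, angular truths, and
expected contact labels.

## Worked example

```python
from stedring import build_demo_dataset, run_pipeline

cfg = build_demo_dataset("demo_data", seed=7, n_replicates=2)
results = run_pipeline(cfg)
results.write(cfg.output_dir)
print(results.summary[["condition", "n_rings", "circumference_nm_mean", "R_mean"]])
print(results.tests[["test", "metric", "statistic", "p_value"]])
```

prints

```
condition  n_rings  circumference_nm_mean  R_mean
   growth       30               1362.106   0.817
    shift       36               1315.262   0.499

         test           metric  statistic  p_value
one_way_anova circumference_nm     0.3319   0.5666
one_way_anova         mean_ch2   198.8815   0.0000
one_way_anova                R    21.8522   0.0000
```

The two simulated conditions share the same ring-size distribution (ANOVA on
circumference: p = 0.57) but differ in planted channel coupling (α = 0.8 vs
0.3), which the per-organelle moving-average R recovers (0.82 vs 0.50,
ANOVA p < 10⁻⁴) together with the companion-intensity difference.

The same stages are available from the shell:

```bash
stedring simulate --outdir demo_data --seed 7
stedring analyze --config demo_data/run_config.json
stedring summarize --per-ring demo_data/results/per_peroxisome.csv
```

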