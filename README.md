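# sharksize

Error and bias in visual body-length estimates of whale sharks
(*Rhincodon typus*), quantified against stereo-video measurement, with the
demographic consequences for an aggregation's maturity structure.

## The problem

Total length (TL) is the workhorse demographic metric for whale sharks at
coastal aggregations, but free-swimming animals cannot be restrained:
lengths are usually judged by eye against an object of known size, at about
0.5 m resolution. Stereo-video photogrammetry measures the same animals to
roughly 1% and therefore exposes the observer error. Because maturity is
inferred from length (L50 ≈ 9 m; "mature or close" above ≈ 8 m), a
size-dependent bias in visual estimates propagates directly into estimates
of how many mature animals attend an aggregation.

This package implements that analysis end to end, for anyone comparing a
cheap, biased measurement method against an accurate reference on repeated
sightings of identifiable individuals:

* **QC preprocessing** — stereo measurements kept when the software-reported
  precision is ≤ 5% of the length; repeat stereo measurements of the same
  shark within a year averaged into one reference length (TLN) while every
  visual estimate is kept; calibration acceptance check against 1/3/5 m
  targets.
* **Bias model** — linear mixed-effects models of the absolute error
  `diff_ij = x_ij'β + b_i + ε_ij`, with a random intercept `b_i ~ N(0, σ²_id)`
  per shark and candidate fixed effects {TLN, time, day, previsual}. Models
  are ranked by AICc/BIC weights `w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)` and
  described by marginal/conditional R²
  (`Rm² = σ²_f/(σ²_f+σ²_id+σ²_ε)`, `Rc² = (σ²_f+σ²_id)/(…)`).
  Fitting profiles the likelihood over the variance ratio `σ²_id/σ²_ε`
  with closed-form GLS at each ratio — deterministic, no random starts.
* **Bootstrap** — 10,000-iteration resampling of the difference in mean
  length between methods (with a central percentile interval) and the
  bootstrap standard error of the stereo mean.
* **Demography** — size-class histograms, threshold counts per individual,
  and extrapolation of whole-percent maturity proportions to the
  aggregation's population range (300–500 individuals).
* **Literature synthesis** — a packaged, schema-validated transcription of
  published length records from aggregations worldwide, summarised per
  location and report year (the last year of each study's period).
* **Synthetic surveys** — a generator reproducing the field study's
  statistical structure (95 individuals, 123 sightings, truncated-normal
  true lengths, size-dependent underestimation with per-individual
  repeatability, 65:11:19 M:F:U sex ratio) so the whole pipeline runs with
  no download.

## Worked example

```python
from sharksize import (SyntheticConfig, make_dataset, filter_by_precision,
                       collapse_repeats, rank_models, ols_bias_line)
from sharksize.bias_model import comparison_frame

records, _ = make_dataset(SyntheticConfig(seed=42))
kept, dropped = filter_by_precision(records)   # 5% precision QC
pairs, _ = collapse_repeats(kept)              # repeat-averaged stereo TLN
print(comparison_frame(rank_models(table=pairs)).to_string(index=False))
line = ols_bias_line(pairs)
print(f"diff = {line.slope:.3f} * TLN {line.intercept:+.3f} (R2 = {line.r2:.3f})")
```

prints

```
                                       model  wAICc  wBIC   Rm2   Rc2  ...
                         diff ~ TLN + (1|ID)  0.429 0.750 0.376 0.698  ...
                  diff ~ TLN + time + (1|ID)  0.401 0.224 0.389 0.719  ...
            diff ~ TLN + time + day + (1|ID)  0.128 0.023 0.389 0.719  ...
diff ~ TLN + time + day + previsual + (1|ID)  0.043 0.003 0.390 0.719  ...
                           diff ~ 1 + (1|ID)  0.000 0.000 0.000 0.703  ...
diff = 0.353 * TLN -1.013 (R2 = 0.387)
```

The stereo-length-only model carries the most evidence weight: the visual
error grows with the true size of the shark (positive slope), and roughly a
third of its variance is explained by size alone, more once per-shark
repeatability is added. The `examples/` directory has one short script per
capability (simulation, bias model, bootstrap, maturity, literature), and a
`sharksize` CLI (`simulate`, `analyze`, `literature`, `report`) wraps the
full pipeline for shell use.

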