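# mbcwarm

Does soil microbial biomass carbon (MBC) decline under warming? Large-scale
statistical models trained on *spatial* MBC–climate gradients have reported
a global MBC decline over 1992–2013 driven by temperature. `mbcwarm`
implements, as a tested pipeline with fully synthetic, ground-truth-known
inputs, the three independent checks a skeptic would run:

1. **Meta-analysis of field warming experiments** — log response ratios
   LN(RR) = ln(MBC_warmed) − ln(MBC_control) pooled with a
   DerSimonian–Laird random-effects model, overall and within
   warming-magnitude (<1, 1–2, 2–3, 3–4, 4–5 °C) and duration bins, plus a
   quadratic LN(RR)~ΔT dose–response fit.
2. **Publication-bias work-up** — funnel plots, the Egger regression
   asymmetry test, and iterative Duval–Tweedie trim-and-fill correction
   with re-pooling.
3. **Long-term in-situ series** — per-site OLS regressions of multi-year
   MBC on annual temperature with t-based 95% CIs.
4. **The space-for-time (SFT) diagnostic** — the centerpiece: 200
   m-out-of-n bootstrap replicates (m = 500 of n = 762) each train a
   Random Forest on spatial MBC observations, mask the prediction grid to
   the model's area of applicability (Mahalanobis or dissimilarity-index),
   predict global MBC annually for 1992–2013 under a +0.28 °C linear
   warming, and reduce the series to a change rate (% yr⁻¹). If predicted
   "temporal" decline tracks each replicate's *spatial* MBC–temperature
   slope — on a world where the true temporal sensitivity is exactly
   zero — the decline is an artifact of space-for-time substitution.

The synthetic-data module (`mbcwarm.simulate`) is first-class: it generates
all three input families with controllable truth (per-bin warming effects,
injectable publication bias, independent spatial-slope and
temporal-sensitivity knobs), so every stage has a parameter-recovery test.

## Worked example

```python
from mbcwarm import (WarmingSimConfig, WorldSimConfig, RandomEffectsMeta,
                     SFTBootstrap, generate_warming_pairs, generate_world,
                     log_response_ratio)

eff = log_response_ratio(generate_warming_pairs(WarmingSimConfig(seed=1)))
print(RandomEffectsMeta(eff["yi"], eff["vi"]).fit().summary())

obs, grid = generate_world(WorldSimConfig(spatial_slope_true=-8.0, seed=3))
print(SFTBootstrap(obs, grid, m=500, reps=200, n_trees=60).fit(seed=4).summary())
```

prints:

```
Random-effects meta-analysis (DerSimonian-Laird)
  k studies        : 130
  pooled LN(RR)    : -0.0505  (SE 0.0198)
  95% CI           : [-0.0892, -0.0118]
  tau^2            : 0.03397
  Q (heterogeneity): 672.055   I^2: 80.8%
  p (mu = 0)       : 0.01062
Space-for-time bootstrap diagnostic
  replicates             : 200 (failed: 0)
  mean change rate       : -0.0401 % yr^-1
  95% CI (across reps)   : [-0.0405, -0.0398]
  corr(rate, slope)      : r = 0.214, p = 0.00233
  mean spatial slope     : -7.876 mmol kg^-1 K^-1
  mean coverage fraction : 0.936
```

Read: the 130-pair pooled effect is small (−0.05 on the log scale, i.e.
about −5%; the generating truth is +0.08 at 1–2 °C, −0.15 at 4–5 °C and
zero elsewhere — per-bin pooling via `subgroup_meta` recovers that
pattern, with only the 4–5 °C bin showing a clear decrease). Meanwhile the
Random Forest trained on the spatial gradient (slope ≈ −8 mmol kg⁻¹ °C⁻¹)
predicts a significantly negative "temporal" trend on a world whose true
temporal sensitivity is exactly zero — and across replicates that rate
correlates positively with the replicate's spatial slope: the predicted
decline is inherited from space, not time.

## Command line

```bash
mbcwarm simulate -c config.yaml --seed 1 --out-dir out/   # all three input families
mbcwarm meta     --records out/warming_pairs.csv --out-dir out/
mbcwarm bias     --records out/warming_pairs.csv --out-dir out/
mbcwarm longterm --series out/longterm_series.csv --out-dir out/
mbcwarm sft      -c config.yaml --seed 1 --out-dir out/
```

Every run writes plain CSVs plus a YAML manifest recording the
configuration, the seed and every decision switch.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch at the published protocol's
scale — the 130-pair meta-analysis with per-bin pooling and bias work-up,
the six-site long-term regressions, and the 200-replicate m = 500/n = 762
bootstrap SFT diagnostic on a 2,000-cell world (with and without the
106-observation flatter-gradient augmentation) — printing each stage's
summary and writing the results JSON. Runtime is a few minutes on one CPU.
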