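# cytofuzz

Tools for analysing cytokine-driven expansion of activated CD4+ T cells:
growth-rate estimation from well-plate count trajectories, interaction
statistics across a three-cytokine dose design, a particle-swarm-tuned
Mamdani fuzzy model that predicts growth rate from IL-2/IL-7/IL-15 doses,
dose-response surface optimization, and a transcriptome screening stage.
A synthetic-data generator with known ground truth makes every stage testable
without any experimental download.

## The problem

Expanding T cells ex vivo for cell therapies depends on cytokine
supplementation, and IL-2, IL-7 and IL-15 — which all signal through the
common γ chain — interact nonlinearly: combinations help at moderate doses
and can inhibit at high ones. Given well-level live-cell concentrations
c(t) for a panel of dose combinations, the pipeline:

1. estimates a per-condition exponential growth rate from two bracketing
   timepoints, **G = ln(c₂/c₁)/(t₂−t₁)** (hr⁻¹), using day 3 (end of the
   post-thaw lag) to day 7, truncated to day 6 for datasets that reach
   confluent densities and decline;
2. normalizes rates to each dataset's mean rate (removing batch scale) and
   compares conditions by pairwise pooled-SD t-tests with a compact letter
   display, plus a Type I factorial ANOVA `rate ~ il2 * il7 * il15` for the
   interaction terms;
3. fits a Mamdani fuzzy inference system — Gaussian *Low*/*High* membership
   functions on each dose and on the output rate, a complete 8-rule base,
   min implication, max aggregation, centroid defuzzification — by particle
   swarm optimization of all 16 membership parameters against RMSE;
4. evaluates the fitted model over the full dose box
   (IL-2 ∈ [0, 40], IL-7, IL-15 ∈ [0, 100] ng/mL) to map the response
   surface and rank predicted-optimal cocktails;
5. screens gene fold-change matrices: a ±50% change filter, 2-D PCA with
   distance-based outlier-gene calling, and correlation of gene time
   profiles with the growth profile.

## Worked example

```python
import cytofuzz as cf

design = cf.make_design_table()                      # 16 dose conditions
counts = cf.simulate_trajectories(design, cf.SimulationConfig(seed=42))
table = cf.normalize_rates(cf.compute_growth_table(counts, design))
print(table.groupby("key")["normalized_rate"].mean().nlargest(4))
```

prints (seed 42):

```
key
200    1.344330
011    1.327871
100    1.277461
020    1.262841
```

— condition 200 (15/6/6 ng/mL IL-2/IL-7/IL-15) grew ~34% faster than its
dataset average, and the top group is a statistical tie of moderate-dose
cocktails rather than the all-maximum condition. The `examples/` directory
has one narrative script per capability (simulation, statistics, fuzzy
fitting, response surface, expression screen); each prints its numbers with
a line on what they mean.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch on seeded synthetic data — growth
simulation, rate normalization, diagnostics, pairwise letters, interaction
ANOVA, PSO-tuned fuzzy fit with a held-out dataset, surface optimum, and the
expression screen — printing a run summary and writing the results JSON.
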