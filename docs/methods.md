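# Methods

## Growth model and rate estimation

Cultures are assumed to grow exponentially between the end of the post-thaw
lag (day 3) and the experiment endpoint, so a single rate per condition and
dataset follows from two bracketing mean concentrations:

    G = ln(c2 / c1) / (t2 - t1)      [hr^-1], t in hours (day k -> 24k h)

Replicate wells are combined by the arithmetic mean of concentrations at each
timepoint before the ratio is taken (one rate per condition per dataset);
negative rates are retained, since an unsupplemented control may decline.

The endpoint is day 7 unless a dataset hit confluence earlier: a condition
"triggers" when its day-6 mean concentration reaches the density threshold
(default 1e6 cells/mL) *and* its day-7 value is lower. When at least 25% of
a dataset's conditions trigger, the whole dataset is scored day 3 → day 6.
The rule is per-dataset, not per-condition, so all rates within a dataset
share a time window and remain comparable.

Because replicate experiments differ by a roughly multiplicative batch factor
(donor state, thaw quality, counting technique), each rate is divided by the
mean rate of its own dataset. Normalization is exactly invariant to scaling
any dataset's rates by a positive constant, and within a dataset the
normalized values average to 1 by construction.

## Statistics layer

*Pairwise tests.* All condition pairs are compared with two-sided t tests
using a standard deviation pooled across **all** conditions (not just the
pair): t = (x̄ᵢ − x̄ⱼ)/(s_p √(1/nᵢ + 1/nⱼ)) with s_p² = Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1)
and df = N − k. This matches the semantics of R's `pairwise.t.test` with
pooled SD. No multiplicity adjustment is applied by default — the intended
use is descriptive grouping, and the letter display operates on the raw
matrix — but Holm and Benjamini-Hochberg adjustments are available.
Shapiro-Wilk (pooled within-group residuals) and Bartlett diagnostics are
advisory: failures warn, they do not abort.

*Letter display.* The compact letter display uses the insert-and-absorb
algorithm: start with one letter column holding every condition; for each
significant pair, split every column containing both; absorb columns that are
subsets of another. Two conditions share a letter iff their pairwise p ≥ α.
Letters are assigned in a caller-supplied order (typically descending mean
rate, so the fastest group reads "a").

*Factorial ANOVA.* The interaction analysis fits
`rate ~ il2 * il7 * il15` with each dose as a single-df numeric covariate and
reports Type I (sequential) sums of squares in fixed term order — main
effects, two-way interactions, the three-way term, residuals — via
statsmodels OLS + `anova_lm`. The no-cytokine control is excluded (it is not
on the dose lattice) but participates in the pairwise tests. A
categorical-factor variant is available behind a flag. With n observations
the residual df is structurally n − 8.

## Mamdani fuzzy model

Each input (dose, ng/mL) and the output (rate, hr⁻¹) carries two Gaussian
membership functions labelled Low and High — deliberately coarse, keeping
16 free parameters total. Inference is classic Mamdani: min t-norm for rule
firing (product available), min implication, max aggregation, centroid
defuzzification on a uniform output grid (default 201 points). The rule base
enumerates all 2³ antecedent combinations, so a rule always fires for any
input clamped to the universes; out-of-universe doses are clamped rather than
rejected so the surface module can evaluate the full lattice including
0 ng/mL.

Numerical notes:

* The centroid uses trapezoidal end-weights (half weight on the two edge grid
  points). A plain unweighted sum costs O(h) centroid accuracy whenever a
  consequent MF sits near a universe edge; with the end-weights the
  resolution-101 centroid agrees with a 10⁵-point reference to better than
  1e-3 of the universe width across random systems.
* Because implication clips the consequent, the centroid of an edge-centered
  clipped Gaussian depends slightly on clip height: a rule base collapsed to
  one consequent is exactly dose-independent only when that consequent is
  symmetric within the universe. Predictions are continuous in dose but can
  be locally flat where the max-aggregated rule's binding antecedent does not
  involve the perturbed input — an inherent property of min/max composition.

Initialization (`init_fis`): input MFs start at the universe edges
(Low mean = lo, High mean = hi, σ = width/4); the output universe is
[0, 1.25 × max observed rate]. Rule consequents come from a nearest-corner
vote: training points are assigned to the nearest of the 8 corners in
unit-scaled dose space, and a corner votes High when its points' mean
response exceeds the overall mean (empty corners fall back to an
inverse-distance-weighted mean). The vote is deliberately crude — consequents
stay fixed during tuning, and with only two MFs per variable the tuned MF
means can compensate for a mislabelled corner.

## PSO tuning

Canonical global-best particle swarm with inertia w = 0.729 and
c₁ = c₂ = 1.49445 (constriction-equivalent values), swarm 30, 200
iterations by default; positions are clamped to the search box, velocities
are not. The objective is the RMSE between model predictions and observed
rates (raw hr⁻¹ scale by default; normalized-rate mode is a switch).
Parameter boxes: MF means within their variable's universe; σ within
[1%, 100%] of the universe width, preventing degenerate spikes. Infeasible
candidates (including underflow-induced "no rule fires" states) score a large
penalty instead of raising so the swarm can traverse. The template's own
parameters warm-start particle 0; `tune_fis(n_restarts=k)` runs k swarms
from derived seeds and keeps the best, which matters in this 16-dimensional
multimodal landscape. Everything is deterministic under a fixed seed, and
the incumbent-best trace is non-increasing by construction.

Gaussian-MF surfaces are not identifiable in their parameters (different
parameter vectors give the same surface), so recovery claims are always about
predictions on a dose grid, never parameter values.

## Response surface

The fitted model is evaluated over the experimental dose box, default
IL-2 ∈ [0, 40], IL-7 ∈ [0, 100], IL-15 ∈ [0, 100] ng/mL at 41×51×51 (about
10⁵ evaluations, chunked). Optima are the top-k lattice points, ties broken
lexicographically by dose; there is no continuous optimization — the lattice
is the contract. The long-format TSV is the canonical artifact; the rendered
PNG is best-effort.

## Transcriptome screen

Fold-change matrices (genes × condition/day samples, relative to an
unsupplemented control) pass three stages. The ±50% filter keeps genes with
FC ≥ 1.5 or ≤ 0.5 in any sample — the plain symmetric reading of "50%
change"; a reciprocal (≤ 1/1.5) mode exists. PCA treats genes as
observations and samples as features, after log2 transform (stabilizes the
multiplicative scale; a raw-FC flag exists), column-centered, projecting on
the top two components. Outlier genes lie farther than mean + k·SD (default
k = 2) from the score centroid — a declared stand-in for an unspecified
"PCA and clustering" step. Growth correlation ranks genes by the Pearson r
of their day-4/5/7 profile against the culture's growth profile; with three
timepoints this is deliberately coarse, ties are broken by profile magnitude,
and constant profiles are reported but unranked.

## Synthetic-data generator

The generator is a stated world: its defaults are the conditions the
downstream analysis is designed to detect, not knobs.

*Design.* The 16-condition table (control "PC" plus a 3-level coded design,
IL-2: 1/10/15, IL-7 and IL-15: 6/36/80 ng/mL).

*Ground-truth surface.* Hill activation per cytokine plus three interaction
terms:

    h_i  = d_i^n / (K_i^n + d_i^n),   n = 2,  K = (5, 25, 30) ng/mL
    g15  = d15^m / (K_inh^m + d15^m), m = 4,  K_inh = 60 ng/mL
    G = G0 + a2 h2 + a7 h7 + a15 h15 (1 − h2)
          + s27 h2 h7 − o27 (h2 h7)² − q g15          (clipped at 0)

with G0 = 0.010, a2 = a7 = 0.012, a15 = 0.0075, s27 = 0.008, o27 = 0.035,
q = 0.010 hr⁻¹. The terms encode, respectively: IL-2×IL-7 synergy that
*over-stimulates* at high combined doses (cell-death pathways dominating —
without the quadratic penalty any surface of this family is monotone in IL-7
and the all-high condition would always win, contradicting the
moderate-dose-optimum phenotype); IL-15 benefit competed away by IL-2
(shared receptor chain, the 1 − h2 factor); and steep high-IL-15
self-inhibition (negligible at 36 ng/mL, strong at 80). Under these defaults
the top true normalized rates belong to conditions 110, 020, 011 and 200 in
a near-tie (within ~0.5%), the all-high 222 is poor, and high IL-15 alone
(002) is among the worst.

*Trajectories.* Latent concentrations: flat at the seeding level
(166,667 cells/mL; 0.300 mL per well, i.e. 50,000 cells) through the 3-day
lag, then exactly exponential at exp(ε_d)·G with a per-dataset batch factor
ε_d ~ N(0, 0.15), hard-capped at the confluence ceiling and declining 20%/day
once capped. The cap is hard rather than logistic so that the noise-free
exponential phase is *exactly* log-linear (the rate estimator inverts the
generator to machine precision). The ceiling default is 2.5e6 cells/mL,
high enough that confluence truncation is an occasional high-batch-factor
event rather than the norm — a ceiling close to the typical day-7 density
would compress every fast condition onto the cap and erase the contrasts the
statistics must detect. Observations add hemocytometer counting noise —
Poisson on the counted cells in 4×10⁻⁴ mL (4 squares), disabled by
`counting_volume_ml=None` — times a mean-one lognormal well effect with 10%
CV. Wells per condition defaults to 4 (quadruplicate), 4 datasets.

*Expression.* Background log fold changes are N(0, 0.15). Planted classes,
returned in a planting record for assertions: *responders* shifted past the
±50% boundary in one condition (one sample anchored exactly at the planted
magnitude so the guarantee is deterministic); *outliers* with ~10× background
spread confined to a shared random 2-D profile subspace — co-regulated
outlier groups; more than two mutually independent extreme directions could
not all be visible to a rank-2 projection — and *trackers* whose day-4/5/7
profile is exactly proportional to the condition's latent growth curve.

*What a green test does not establish.* The generator has no donor effects,
no differentiation or viability dynamics, no within-well temporal error
correlation, and its expression matrices are fold changes with planted
structure, not read-level data: passing tests demonstrate that the analysis
recovers the structure this world contains, not performance on real assays.

## Known limitations

* The two-label fuzzy model is intentionally low-capacity; its training RMSE
  on realistic noisy rates plateaus well above zero, and predicted optima
  are coarse (lattice-resolution) estimates.
* The corner-vote rule initialization can mislabel consequents when the
  design concentrates in one region of scaled dose space; tuning compensates
  in predictions but the printed linguistic rules should be read with care.
* Pairwise tests assume homoscedastic conditions (pooled SD); the Bartlett
  diagnostic warns when that is doubtful.
* With three timepoints, growth-profile correlation distinguishes profile
  shape only weakly; it is a ranking device, not an inference.
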