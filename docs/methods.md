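# Methods

This note documents the models and procedures implemented in `pcosmet`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic validation does and does not establish.

## Cohort model and derived indices

A cohort is a set of women assessed at baseline (m0) and after six (m6) and
twelve (m12) months of metformin, with a disposition: completed the year,
dropped out (side effects / no perceived benefit / lost to follow-up) in one
of the two intervals, or became pregnant. Visits must be contiguous from m0;
a completer is exactly a woman with an m12 visit.

Derived indices follow the conventional formulas of gynaecological
endocrinology: BMI (kg/m²), waist-to-hip ratio, LH/FSH, the free androgen
index FAI = T (ng/mL) × 347 / SHBG (nmol/L) expressed in percent, and
HOMA-IR = glucose (mg/dL) × 0.05551 × insulin (μU/mL) / 22.5 (0.05551
converts mg/dL to mmol/L). Any missing or degenerate input (SHBG ≤ 0,
FSH ≤ 0, hip ≤ 0) leaves the index *undefined* for that visit — undefined
values propagate to labels as "no label", never as zero or false.

**Outcomes.** BMI response = drop ≥ 1 kg/m² in women with baseline
BMI ≥ 25 (WHO overweight cutoff; the eligibility threshold is a parameter);
FAI response = drop ≥ 1 percentage point in women with baseline FAI ≥ 6 %.
Twelve-month labels measure *further* improvement of the same magnitude
relative to the six-month value, matching the reading of a "further
improvement" at one year.

**Flow accounting.** `flow_report` counts enrolment, per-interval retention,
drop-outs by reason and interval, pregnancies, and response rates. Six-month
response denominators are all baseline-eligible women (intention-to-treat):
a woman who never reached m6 cannot enter the numerator but stays in the
denominator. Twelve-month further-response denominators are eligible women
with an m12 visit. Percentages are reported to one decimal with banker's
(half-even) rounding, and every reported rate carries its own
numerator/denominator pair so it can be recomputed exactly.

## Synthetic cohort generator

The generator is the package's stand-in for the unavailable clinical data;
its defaults are the study conditions, not tuning knobs.

* **Marginals.** Each baseline variable targets the published mean ± SD.
  Right-skewed positive variables (insulin, triglycerides, T, SHBG, DHEAS,
  LH/FSH) are moment-matched log-normals, which also lands near the
  published medians (e.g. insulin: mean 21.03, log-normal median 18.4 vs
  published 18). Symmetric variables are truncated Gaussians whose
  underlying location is solved numerically (Brent) so the truncated — and
  for count variables (menses/6 months, Ferriman–Gallwey, antral follicle
  count) the discretized — mean hits the target; without this correction a
  strongly truncated variable such as menses/6 months (target mean 2.0 on
  [0, 6]) would be biased by ≈ 0.3. Height is N(1.63 m, 0.06), unreported in
  the source population but chosen so weight/height² reproduces the
  published BMI scale; hip circumference and FSH are likewise unpublished
  and set to plausible clinical scales.
* **Dependence.** A Gaussian copula imposes a small set of physiologically
  motivated latent correlations (weight–insulin 0.40, glucose–insulin 0.30,
  T–SHBG −0.35, menses–T −0.30, weight–WHR 0.25, FG–T 0.30). These are
  synthetic choices that make the planted structure discoverable; since FAI
  is computed from T and SHBG rather than drawn, the intended FAI
  associations are realized through its inputs. An infeasible (non
  positive-definite) specification raises an error naming the pairs.
* **Response.** Responder status is drawn from a logistic model on
  *dichotomized* baseline indicators. For BMI response the planted log-odds
  are oligo-amenorrhea 1.2, high FAI 0.9, high FG 0.6, high HOMA 0.3
  (intercept −1.5, overall rate ≈ 0.5, matching the observed ≈ 52 % six-month
  response); for FAI response: oligo-amenorrhea 1.2, high FAI 1.0, low DHEAS
  0.8, high BMI 0.6, high triglycerides 0.5, low glucose 0.4 (intercept
  −2.25). The deliberate ordering of coefficients is what the semantic-map
  recovery experiments test.
* **Treatment effects.** Responders lose ≈ 1.7 BMI units per first interval
  (non-responders 0.3), FAI responders gain SHBG (+4.5 nmol/L) and lose T
  (−0.15 ng/mL) with smaller shifts otherwise, plus common on-drug trends
  (glucose, insulin, lipids, menses, FG, AFC). Second-interval shifts are
  the same scaled by a persistence factor 0.6. Gaussian noise is added per
  shift, so planted responder status and the realized label agree strongly
  but not perfectly — as labels derived from noisy measurements would.
* **Drop-out.** A logistic model in the indicator 1[T < 0.90 ng/mL] with
  γ_lowT = ln 6.5 (the planted odds ratio) and γ0 = −1.81, chosen to give
  the study's ≈ 43 % twelve-month discontinuation at the generated
  low-T prevalence. Interval and reason follow the study's observed
  multinomial proportions (side effects 14/46, no benefit 21/46, lost
  11/46); pregnancies remove ≈ 4.5 % of on-drug women per interval.
* **Reproducibility.** One seed keys everything; each patient consumes a
  counter-derived substream (`default_rng([seed, stage, i])`), so the first
  m patients are identical whatever n is — a tested invariant.

The generator does **not** model assay error, visit-time jitter, seasonal
effects, or the mixing of future drop-outs into follow-up summary columns;
passing recovery tests therefore show that the *pipeline* recovers structure
of this planted kind at these sample sizes, not that the original clinical
findings are reproduced.

A separate deterministic builder, `reference_flow_cohort()`, plants exact
dispositions and response changes to replicate the study flow chart
(136 screened → 108 enrolled → 82 at m6 → 53 at m12, with 54/103 and 45/89
six-month responders). It exists so the flow accounting can be verified
against every printed count. The published twelve-month denominators (72 and
51) exceed the 53 women who reach m12 and therefore cannot arise from any
internally consistent cohort; the package reports further response over
eligible women with an m12 visit and verifies the printed percentages at the
rate-arithmetic level instead.

## Median dichotomization

Cutoff = sample median (mean of the central order statistics for even n),
computed by default on the analysis subset (outcome-eligible women at
baseline); values strictly above the cutoff activate the HIGH node, values
at or below it the LOW node. Ties going LOW is consistent with strict ">"
semantics of the HIGH nodes. Each variable contributes *both* polarities as
separate nodes because both carry map information. Constant variables are
flagged degenerate; all-missing variables are dropped with a warning; rows
missing any mapped variable are excluded and logged.

## Auto-contractive map and semantic connectivity map

For records x ∈ [0,1]^N the network contracts twice —
h_i = x_i(1 − v_i/C), net_j = Σ_i h_i(1 − W_ij/C), out_j = h_j(1 − net_j/C) —
and adapts by Δv_i = x_i(x_i − h_i)(1 − v_i/C) and
ΔW_ij = (h_i − out_i)(1 − W_ij/C)·h_j, the published auto-contractive
formulation in which the weight between i and j grows with the co-activity
of the two nodes. C defaults to N (a published convention). Numerical
choices that matter:

* **Initialization** is a deterministic small positive constant,
  v = W = 0.01·C. Zero is a fixed point of the Δv rule (h = x ⇒ Δv = 0), so
  a zero start would never train; any small positive start flows to the same
  attractor (v → C for active nodes) and keeps training fully deterministic.
* **Batch updates**: deltas are averaged over the epoch's records and
  applied once, making training invariant to row order (up to float
  summation order; the resulting map is identical).
* **Convergence**: the energy Σ|Δv| + Σ|ΔW| decreases geometrically once v
  approaches C (hidden activations quench learning); training stops at
  energy < 1e−6 or 3000 epochs (a non-convergent run is flagged, not
  silently accepted). Typical fits converge in a few hundred epochs.

Distances are d_ij = C − (W_ij + W_ji)/2 with zero diagonal; min–max
rescaling to [0,1] is available for layout only — the spanning tree is always
computed on unrescaled distances, since rescaling is monotone and cosmetic.
The MST uses Kruskal with edges sorted by (weight, i, j), so ties break
lexicographically and the map is reproducible. Pole priorities order nodes
by (tree edges from the pole, summed path weight, name).

On planted cohorts the oligo-amenorrhea node (`CYCL_LOW`) reliably attaches
directly to the responder pole, ahead of the weaker planted hirsutism node —
the recovery property that is tested. A *total* ordering of all four planted
predictors above all decoys is not expected and not asserted: decoy nodes
(T, baseline BMI) are genuinely correlated with planted drivers, so the tree
legitimately routes some of them early.

## Feature selection with ab/ba validation

The selector evolves (feature mask, A/B split) pairs with a generational GA:
tournament selection (size 2), uniform crossover (rate 0.8), per-bit
mutation (rate 0.02), elitism (2), population 50 × 100 generations by
default. Splits are repaired to a 40–60 % balance after variation; a half
missing an outcome class scores 0. Fitness is the mean of the two held-out
accuracies (AUC optional) of a single-hidden-layer backprop classifier —
full-batch gradient descent with momentum on cross-entropy, standardized
inputs, seeded initialization, with sigmoid (4 hidden units) and sine
(8 hidden units) presets. Fitness values are cached by candidate identity,
which makes elitist re-evaluation free. The elite fitness track is
non-decreasing by construction. The evolutionary engine the design
approximates is proprietary; the contract here is recovery of planted
informative features (≥ 3 of 4 at n = 600 with 8 decoys in ≥ 8 of 10 seeded
runs), not equivalence with any specific software.

## Classical inference

All tests are two-sided with significance at p < 0.05 and no multiplicity
correction. Mann–Whitney uses exact enumeration for n1 + n2 ≤ 10 without
ties and the tie-corrected normal approximation otherwise. The Friedman
statistic is computed from within-subject ranks with the standard tie
correction (implemented directly so that k = 2 conditions is supported;
cross-checked against scipy for k ≥ 3). Logistic regression is
maximum-likelihood (statsmodels Newton/IRLS) with Wald 95 % CIs on the odds
ratios — Wald rather than profile-likelihood intervals, the form that
produces the very wide small-sample ranges typical of such tables; constant
covariates, rank deficiency and perfect separation raise errors naming the
covariate. The 2×2 odds ratio uses the Woolf log-SE interval with the
Haldane–Anscombe 0.5 correction when a cell is zero; on a single binary
covariate the logistic fit reproduces the 2×2 OR to 1e−6 (tested). The
completers-vs-discontinued comparison takes group labels from record status,
with both the "any drop-out" and the "m12 completion" groupings available.

## Pipeline

`run_pipeline` chains ingest/simulate → flow report → cutoffs → SCMs (BMI
outcome at m6, FAI outcome at m12) → feature selection (BMI outcome, m6) →
drop-out statistics, writing JSON/CSV/GraphML artefacts plus a manifest
(semantic config hash, seed, version). Identical config + seed gives
byte-identical outputs (tested). Stages that need a model fit skip with a
warning below 20 analysable records, well under the smallest analysis set
the design contemplates.

## Validation scale and limitations

Acceptance-level experiments run at deliberately desk-scale sizes chosen as
the package's own validation budget: 100 random graphs (N ≤ 7) against a
brute-force spanning-tree oracle; 10 seeded runs for feature-selection and
map recovery (n = 600 and n = 2000 cohorts); 50 replicates at n = 2000 for
drop-out OR coverage; 1000 replicates at n = 150 for Wald calibration. The
package does not attempt to reproduce the source study's real-cohort
accuracies, follow-up tables, or ROC curves, which would require the
original data; nor does it adjudicate PCOS diagnoses or provide clinical
recommendations.
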