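# Methods

## The design problem

Drotrecogin alfa (activated) was given preferentially to younger,
sicker severe-sepsis patients, so any retrospective genotype-by-treatment
comparison must first remove that confounding. The pipeline implements a
matched-cohort design: treated patients are matched to untreated
controls on the variables that drive both treatment selection and
mortality, the matched sets are locked while still blind to outcomes
and genotypes, and only then is the biomarker hypothesis tested within
sets.

## Eligibility

Screening is a pure function of transfer-1 data (demographics, severity
scores, SIRS vitals, organ-dysfunction flags with onset dates). The
INDICATED population requires age ≥ 18; severe sepsis = suspected or
proven infection (a boolean input — it is not derivable from the other
fields) + SIRS (2 of 4: temperature < 36 or > 38 °C; heart rate
> 90/min; respiratory rate > 20/min or PaCO₂ < 32 mm Hg or mechanical
ventilation; WBC < 4,000 or > 12,000/mm³) + at least one organ
dysfunction (cardiovascular = hypotension with pH ≤ 7.3, or vasopressor
use alone; PaO₂/FiO₂ ≤ 300; GCS ≤ 12; platelets ≤ 80,000; creatinine
≥ 2.0; bilirubin ≥ 2.0 — all inclusive as written, SIRS temperature/WBC
bounds strict as written); high risk of death (APACHE II ≥ 25, SAPS II
≥ 54, or ≥ 2 organ dysfunctions with onset dates within 2 calendar days,
inclusive; a pair with a missing onset never qualifies); platelets
≥ 30,000/mm³; known treatment status; and enrollment no earlier than 24
whole months before the drug's in-hospital availability date (or the
country approval date when availability is unknown) — the exact
24-month boundary is eligible. Patients failing only the high-risk
criterion are NON_INDICATED; the two labels are disjoint and their
union is the severe-sepsis population. Every exclusion carries
machine-readable reasons.

Missing data are never imputed to satisfy eligibility. For matching
variables only, a center may impute a variable when its missingness
there is under 30% (center mode for categorical, lower-median for
continuous; determinism over convention); at most two variables per
patient, and never age or the severity score — patients beyond those
limits are excluded from matching and reported.

## Propensity model and calipers

The propensity score is an in-repo Newton/IRLS logistic MLE of
treatment on: age, severity score standardized within score type (so
APACHE II and SAPS II cohorts pool into one column), four
organ-dysfunction indicators (cardiovascular, pulmonary, renal,
coagulation), ventilation, medical/surgical status, infection-site
indicators (reference "other"), and fixed-effect center indicators
(largest center as reference). Five pre-specified age interactions
(age × severity and age × each dysfunction) are screened one at a time;
those with two-sided Wald p < 0.05 are refit jointly. Writing the MLE
in-repo (rather than delegating) lets separation and rank deficiency
surface as first-class errors naming the offending covariate; the fit
is cross-checked against statsmodels in the test suite.

The propensity caliper is 0.6 × the sample SD (ddof = 1) of the fitted
scores on the probability scale; a logit-scale variant is a config
switch. The score-balance identity (Σ scores = number treated) is
enforced to 1e-8 as a fit invariant.

## Matching

Candidate pairs must share a cohort (never merely a center) and pass
every caliper: |Δage| ≤ 5 y, |Δseverity| ≤ 2 APACHE II points or 4
SAPS II points, |Δpropensity| ≤ 0.6 SD, |Δenrollment| ≤ 24 whole
months. Distance is Mahalanobis over (age, severity, four dysfunction
indicators, ventilation, medical/surgical, infection-site one-hot)
with the pooled within-treatment-group covariance per cohort,
ridge-regularized (ε·tr(Σ)/p on the diagonal, ε = 1e-6) when the
condition number exceeds 1e10.

Among feasible matchings with 1–3 controls per treated and each control
used once, the solver optimizes lexicographically: (1) number of
treated matched at all, (2) total matched controls, (3) total distance.
Prioritizing control count before distance serves the design's 2:1
average target. The three tiers collapse into a single min-cost flow
with tiered integer costs: distances are integerized at 1e-6 resolution
with ties broken canonically by (distance, treated id, control id), the
per-extra-control bonus exceeds any total distance, and the coverage
bonus exceeds any total control bonus — so one exact network-simplex
solve returns the lexicographic optimum. An independent
exhaustive-search oracle (bitmask dynamic programming over control
subsets) verifies the flow solution on random small instances.
Unmatched treated patients are reported with nearest-miss diagnostics
(which calipers the closest control failed).

Balance diagnostics report standardized differences and tests before
matching (all treated vs all controls) and after (matched treated vs
controls weighted 1/mₛ within each set, with effective-sample-size
adjusted Welch/chi-square tests).

## Blinding

Blinding is structural: `PatientRecord` has no outcome or genotype
fields, transfer-1 readers drop any such column with a warning, and the
analysis join refuses to run without a lock token — a SHA-256 of the
sorted matched-set membership, so any post-lock membership edit
invalidates it. Matching output is bit-identical under permutation or
withholding of the transfer-2 file (tested).

## Biomarker and ancestry

Each IRP is two SNPs (IRP A: rs684923/RYR2, rs3751501/ACIN1; IRP B:
rs3179969/SPATA7, rs640098/FLI1) with configured responsive genotype
sets; only rs3751501's (AA|AG) is publicly documented, so the other
three are simulation-time declarations. Status is the OR rule: positive
if any present call is responsive; negative if both calls present and
non-responsive; indeterminate otherwise (missing-call handling is this
package's decision — indeterminate patients are excluded from
stratified analyses and counted). The rule is symmetric and monotone
(property-tested).

AIM-panel PCA: dosages 0/1/2, SNPs with ≥ 20% missingness or no
variation dropped with a log entry, mean imputation, columns centered
and scaled by 1/√(p̂(1−p̂)), eigen-decomposition of the sample
covariance, sign fixed by making each component's largest-magnitude
loading positive. k = 3 components by default — the relevant ancestral
groups are European, African and Asian. Plate layouts shuffle set order
and wells under a seed but never split a matched set across plates.

## Primary analysis

For matched set s with covariates xᵢ and dₛ deaths among nₛ members,
the conditional likelihood contribution is
exp(Σ_{deaths} xᵢᵀβ) / Σ_{|C|=dₛ} exp(Σ_{i∈C} xᵢᵀβ), enumerated exactly
(≤ C(4,2) = 6 subsets for 1:3 sets); concordant sets contribute nothing
and are counted as dropped. Gradient and Hessian are the mean and
covariance of the induced subset distribution; fitting is Newton–Raphson
from β = 0 with step-halving, converged at max|gradient| < 1e-8 and
step < 1e-8. Monotone likelihood (within-set separation) is flagged
non-estimable when a coefficient passes ±15 — never reported as a
finite estimate, and interaction tests on such fits are inconclusive,
never significant. On 1:1 pairs with a treatment-only covariate the fit
reproduces the McNemar closed form log(b/c) exactly; the implementation
is cross-checked against an independent conditional-logit routine in
the tests.

Primary covariates: treatment, IRP status, their interaction, and the
ancestry PCs; the secondary adjusted analysis adds matching variables
through the same machinery. The primary endpoint is death on or before
day 28 *and* before hospital discharge (discharged-alive-before-28
counts as alive); 28-day all-location mortality is a config switch.
Each IRP's interaction is Wald-tested two-sided at α = 0.025 (family
5% by Bonferroni across the two IRPs); a likelihood-ratio p can be
reported alongside. Subgroup ORs are exp(β_treat) in IRP− and
exp(β_treat + β_int) in IRP+ with delta-method CIs.

ARR per stratum: treated mortality is the unweighted mean over treated;
control mortality weights each control 1/mₛ so every set contributes one
control unit; the 95% CI is a seeded percentile bootstrap over whole
matched sets (B = 2,000) — the weighting and CI method are this
package's choices and are stated in the report.

## Synthetic cohorts

The generator's defaults are the study conditions: 10 cohorts over 8
centers (3 SAPS II cohorts), 400 patients each, 8% treated (the drug
was used in under 10% of indicated patients), age ~ N(62, 15²)
truncated to [18, 90], APACHE II ~ N(27, 6²), SAPS II ~ N(50, 11²).
Treatment follows a logistic model with slopes −0.4 per age SD and
+0.5 per severity SD (younger and sicker treated); the intercept is
Brent-root-found so the large-sample mean of the assignment probability
hits the target fraction (fixed-seed 200k-draw average, tolerance
1e-10, infeasible targets raise). Organ-dysfunction flags come from a
Gaussian copula with common correlation 0.2 and marginals
(cardio 0.70, pulmonary 0.75, CNS 0.20, coagulation 0.20, renal 0.45,
hepatic 0.15 — in the range of reported severe-sepsis cohorts);
supporting values (BP, pH, P/F ratio, GCS, platelets, creatinine,
bilirubin) are drawn on the matching side of each threshold so the
records replay exactly through the screening rules.

Biomarker SNPs: the composite prevalence π is inverted assuming the two
SNPs contribute symmetrically and independently (per-SNP responsive
probability q from 1−(1−q)² = π) and a carrier responsive set under
Hardy–Weinberg (allele frequency f from 1−(1−f)² = q). Defaults
π_A = 0.337, π_B = 0.261 — the observed replication rates. AIM SNPs are
Balding–Nichols draws (divergence 0.15) across 3 latent populations at
mixing 75/15/10. Outcomes are Bernoulli at saturated-logistic cell
probabilities: control mortality 0.35 per stratum (severe-sepsis
mortality runs 30–60%; the baseline is a free parameter because the
design states none), treated mortality reduced by 15 points in IRP+
and 1.5 points (midpoint of the stated 1–2%) in IRP−.

What the generator does *not* emulate: realistic sepsis physiology
beyond the consumed fields, LD among AIM SNPs, informative missingness,
center-level outcome heterogeneity, or any dependence of outcome on the
matching covariates beyond treatment and biomarker. Passing tests
therefore demonstrate the pipeline's statistical correctness under the
design's assumptions, not robustness to violations of them.

## Power engine

Matched sets are generated directly (1 treated + m controls, biomarker
i.i.d. by prevalence, outcomes by stratum/arm mortality, independent of
matching covariates). The closed-form cross-check uses the interaction
log-OR Δ = [logit(p₀⁺−ARR⁺) − logit(p₀⁺)] − [logit(p₀⁻−ARR⁻) −
logit(p₀⁻)] with variance Σ 1/(n·p·(1−p)) over the four stratum×arm
cells and power Φ(|Δ|/SE − z₁₋α/₂) (plus the opposite tail). At the
planned size this gives 0.899 at two-sided α = 0.05.

The replicate analysis mode defaults to **unconditional** logistic
(Wald on the interaction): the planned "about 90%" is a design-stage
calculation whose assumptions match the normal approximation, and
measured simulation agrees with the closed form to Monte-Carlo error in
that mode. The conditional matched-set analysis is exposed as
`mode="conditional"` and is materially less efficient here
(≈0.79 at the default scenario) because conditioning discards
between-set information that, under the generator's
covariate-independent outcomes, is informative; the CLI power report
prints α = 0.05 and α = 0.025 side by side. Family-wise error under the
two-biomarker null is the fraction of replicates where either test
rejects at 0.025 (Bonferroni bound 1−0.975² ≈ 0.0494).

## Problem sizes and numerical choices

Default simulations use 2,000 replicates (Monte-Carlo SE ≤ 1.2 points
at 90% power) and the synthetic study uses 4,000 patients — sizes at
which every reported quantity is stable to its stated tolerance while
the full suite stays interactive. Flow costs are exact integers
(1e-6 distance resolution); PCA signs, median/mode tie-breaks, flow
tie-breaks and all RNG streams are deterministic under the configured
seed. Degenerate inputs (empty strata, concordant-only sets, zero-variance
scores, monomorphic SNPs, oversized plate sets, infeasible calibration
targets) raise typed errors or are reported as undefined rather than
silently estimated.

## Known limitations

Real transfer files will have messier missingness and coding than the
generator produces; the VCF reader handles only diploid biallelic GT
fields; no full matching (many treated to one control) or cross-cohort
rescue matching is offered; secondary time-to-event and free-day
endpoint models are out of scope.
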