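# Methods

`vertclaims` implements a claims-based comparison of annual medical spending
and care quality between patients attributed to hospital-owned and
physician-owned physician organizations, exercised end to end on a synthetic
claims population because real commercial-insurer claims are proprietary.
This note documents the models, the generator, the numerical conventions and
the design choices that were genuinely open.

## The estimands

For each attributed member-year, annual spending is the sum of allowed
amounts (insurer payment plus member cost share) over all claims in the
calendar year. Three model families share one inference convention:

* **Percent differences** come from a quasi-likelihood GLM with a log link,
  E[y|x] = exp(xᵀβ), fitted by IRLS to a relative deviance change below 1e-8
  (at most 100 iterations). The variance function is Var ∝ μ (quasi-Poisson)
  by default — the standard choice for non-negative spending with a point
  mass at zero, since it keeps zero-spend member-years in the estimation
  sample; Var ∝ μ² (gamma) is available for strictly positive responses.
  The ownership coefficient β is reported as 100·(exp(β) − 1).
* **Dollar differences** come from OLS on the dollar scale with the same
  covariates.
* **Quality odds ratios** come from maximum-likelihood logistic models fitted
  on eligible member-years only, with the ownership odds ratio exp(β).

**Cluster-robust inference.** Standard errors allow arbitrary error
correlation within a physician organization (held constant across years)
via the sandwich V = A⁻¹(Σ_g s_g s_gᵀ)A⁻¹ with A the estimated information
and s_g the summed score contributions of cluster g. The bread and scores
are computed family-specifically (Poisson: A = XᵀWX with W = μ and s_i =
x_i(y_i − μ_i); Gaussian: W = 1; logit: W = p(1−p); gamma/log: s_i =
x_i(y_i − μ_i)/μ_i, W = 1), so the quasi-likelihood scale cancels. A
two-sided p ≤ 0.05 is the significance convention.

Two small-sample conventions are provided. The default is the
Bell–McCaffrey CR2 estimator — per-cluster scores are adjusted by
(I − H_gg)^{-1/2} in the working-weight inner product, applied through a
thin SVD of the n_g×k cluster block so large clusters cost O(n_g·k²) — with
per-contrast Satterthwaite degrees of freedom (Σ_g a_g)²/Σ_g a_g², a_g =
cᵀT_g c. The alternative (`cluster_correction="cr0"`) is the plain CR0
sandwich with a G/(G−1) factor and t(G−1) reference; with singleton
clusters and the factor off it reduces exactly to HC0. CR2 is the default
because the ownership indicator is a cluster-level regressor carried by few,
size-skewed hospital organizations at desk scale: in a 400-replicate null
study (G = 72), CR0/t(G−1) rejected a true null at 10.2% nominal 5% while
the same fits under CR2/Satterthwaite are close to nominal — the well-known
few-treated-clusters failure mode that CR2 was designed for. At the source
study's scale (~1,900 organizations) the two conventions agree closely.

**Covariates.** Pooled hospital-vs-physician indicator (a three-level coding
with a Wald equality test of the two hospital coefficients is available);
MSA×year cells as one combined factor (its 12 cells absorb MSA and year main
effects — with 2 MSAs and 3 years this yields 5 indicator columns after the
reference drop); age bands 19–29/30–39/40–54/55–64 (or age + age² as a
sensitivity option); sex; deciles of the concurrent risk score cut on the
estimation sample; CDHP enrollment; wage index and its square; practice-size
categories ≤500 / 501–10,000 / 10,001–15,000 / 15,001+ attributed patients
per organization-year (decile bins as a sensitivity option); attributed
PCP's specialty. Quality models use MSA and year main effects (plus wage
index) instead of the interaction cells.

**Exact collinearity** is resolved before fitting by a greedy QR pass that
drops, with a log entry, any column lying in the span of the intercept and
the columns kept before it; ownership columns are protected and raise an
error if degenerate. This matters in practice: a wage index that varies only
at the MSA-year level is exactly aliased by the MSA×year cells, so in
spending models the wage terms are pruned and the regional price level is
absorbed by the cells; in quality models (MSA + year mains) the wage terms
are identified through their within-MSA trend differences.

**Price/utilization decomposition.** A median-price table (per BETOS
category × calendar year, pooled across ownership types; even-count medians
are the mean of the central pair) replaces each claim's price. Re-estimating
the spending model on standardized totals isolates the utilization channel;
the price channel is the difference between the actual and standardized
percent effects. Medians are computed within year rather than pooled across
years to avoid conflating calendar price growth with ownership price
differences; this choice is recorded in the output metadata.

## Attribution

A member-year enters the cohort when the member is aged 19–64, continuously
enrolled, and has raw annual spending ≤ $100,000 (strictly greater excluded;
the boundary value $100,000.00 is retained). Exclusion reasons are assigned
with a fixed precedence (age, enrollment, cap, then no-PCP-visits) so they
partition the dropped member-years. Attribution counts professional
evaluation-and-management claims rendered by a primary-care physician
(family practice, general practice, geriatrics, internal medicine,
pediatrics) in a 24-month window — the calendar year plus six flanking
months on each side (1 July of the prior year through 30 June of the next;
the flank is configurable). The member is attributed to the PCP with the
plurality of visits; ties break to the most recent visit date, then the
lexicographically smallest PCP id; the organization is the one on that PCP's
most recent in-window claim, which resolves mid-window practice switches.
Plurality rather than strict majority avoids silently dropping members whose
visits are split across several PCPs.

## Spending aggregation

All spending arithmetic runs in integer cents, so the conservation
identities — total = Σ BETOS categories = Σ settings per member-year — are
bit-exact and testable. Professional claims map HCPCS → BETOS through the
packaged (~60 code) crosswalk, with unmapped codes assigned to
`unclassified` under a logged warning so conservation always holds; facility
claims without a HCPCS map through a revenue-center table, with
operating/recovery-room revenue codes (0360/0370/0710) in `unclassified`.
Standardized amounts are cents with at most a .5 fraction (exactly
representable), so standardized sums are also exact, and standardization is
idempotent.

## Quality measures

Five claims-detected indicators, measurement window = calendar year:

* **30-day readmission**: overlapping or same-day-transfer inpatient stays
  are merged; a member-year is eligible if it has a merged discharge in the
  year, and counts a readmission if any later stay admits within the
  half-open interval (discharge, discharge + 30 days] — "within 30 days"
  read inclusively, so a day-30 admission counts and day-31 does not.
  All-cause, any facility.
* **HbA1c, LDL, retinal exam**: eligible = any claim carrying a diabetes
  diagnosis flag in the year; numerator = any claim bearing a code from the
  measure's (configurable, packaged-default) code set in the year.
* **Screening mammography**: women aged 50–64 in the year; numerator = any
  screening-mammography claim.

Full HEDIS technical specifications (continuous-enrollment lookbacks,
exclusion hierarchies) are out of scope.

## The synthetic generator

The generator emulates the joint structure the analysis needs rather than
actuarial detail. Per member: an MSA (uneven metro populations, ramp
weights), one organization (rank-weighted within MSA and ownership type with
exponent `org_size_skew` = 2, producing the right-skewed organization sizes
real panels show — at n = 20,000 members, org-years range from single digits
to ~1,000 patients and practice-size categories span all ownership types),
one PCP inside that organization, sex, CDHP status, a diabetes flag, and an
age path. Per member-year: a lognormal concurrent risk score (mean 1.25,
σ = 0.6), enrollment with probability 0.97.

Claim counts per BETOS category are Poisson with rate
rate_c · risk · exp(MSA×year shift) · exp((1 − price_share)·e·hosp), and
per-claim prices are lognormal with mean
price_c · (1.025)^(year − y₀) · exp(price_share·e·hosp), where e is the
ownership log effect (default 0.058) and price_share (default 0.155) is the
fraction of the effect operating through prices — calibrated so that
median-price standardization removes about one percentage point of a ~5.8%
differential. Because E[spend] = E[N]·E[price], the expected spending ratio
between ownership groups is exp(e) exactly, and the decomposition is
identifiable by construction: with price_share = 1 the standardized effect
is 0; with price_share = 0 it equals the actual effect. Evaluation-and-
management visits are guaranteed ≥ 1 per member-year (1 + Poisson(λ − 1),
which preserves the expected count except for the rare clamp at λ < 1), so
every member-year is attributable and attribution can be validated against
the generator's truth table. A configured share of imaging and laboratory
claims is routed to the outpatient-facility setting (identified by revenue
code only), with a higher share for hospital-owned practices. Inpatient
stays, 30-day readmissions (admission gap 1–30 days) and well-separated
later stays (gap 40–90 days), and quality events (HbA1c, LDL, retinal,
mammography claims) are drawn at configured rates, with hospital rates
shifted by per-measure odds ratios; quality events are emitted as claims
with real codes so the measure logic exercises its production detection
path. Default category rates and prices put mean annual spending near
$5,000/member with zero-mass per category, matching the scale of commercial
PPO populations.

Randomness uses a single master seed with per-module substreams
(`numpy.random.SeedSequence.spawn`), so identical configurations are
byte-identical on disk.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic ICD/CPT vocabularies, within-member
serial correlation of utilization beyond the shared risk score, provider
switching, benefit-design detail, pharmacy claims, and any unmeasured
confounding between ownership and illness burden (a `risk_ownership_corr`
knob exists but defaults to independence). Parameter-recovery results
therefore validate the pipeline's correctness, not the causal
interpretation of ownership effects in observational claims.

## Problem sizes and numerical conventions

Replicate suites use scaled study conditions chosen once: parameter recovery
runs 200 replicates of n = 5,000 members over a single calendar year;
channel-decomposition checks run 100 replicates at n = 2,000; the type-I
error study runs 400 null replicates at n = 1,200; the headline
recomputation script uses n = 20,000 members over 2014–2016. Tolerances:
IRLS deviance 1e-8; oracle equivalences at 1e-8 (sandwich) and 1e-6
(logistic); Monte-Carlo comparisons at 2 Monte-Carlo (or binomial) standard
errors. Degenerate inputs fail loudly: empty claim sets, all-zero responses,
negative allowed amounts, missing median-price entries, orphan PCP ids and
rank-deficient dollar-scale designs all raise typed errors naming the
offending values. Quality models whose eligible pool is too small to
support the covariate set (fewer than 50 rows) or that separate are reported
as flagged rows rather than aborting the pipeline.

## Known limitations

The 24-month window composition is a documented stand-in (symmetric flank),
not a reproduction of any specific production attribution rule. The
logistic quality models can be unstable in small demo runs (readmission
eligibility is a few percent of members). Cluster-robust t(G−1) inference
is approximate with few clusters; the type-I error study quantifies the
realized size under the default scenario. Currency conservation assumes
non-negative allowed amounts; adjustment/reversal claims are rejected
rather than netted.
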