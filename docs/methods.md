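# Methods

## The experiment being modelled

Grow-finish barrows from three genetic lines (a fast-growing commercial
cross and two lines divergently selected for low/high residual feed intake)
are housed individually, fed a low- or high-fiber diet ad libitum in one of
two rooms, and exposed to three 4-day heat-stress (HS) bouts separated by
7-day thermoneutral (TN) recovery periods after a 20-day TN adaptation/
baseline: TN1 [d8,20), HS1 [20,24), TN2 [24,31), HS2 [31,35), TN3 [35,42),
HS3 [42,46), TN4 [46,53). Body weight is weighed one day before each period
boundary (days 1, 8, 19, 23, 30, 34, 41, 45, 52), feed disappearance daily,
ultrasound backfat/loin-eye on days 19 and 52; slaughter on day 55. Periods
are half-open day intervals so printed spans are exact (TN1 spans 12 d).

## Phenotype derivation

Boundary body weights (days 20, 24, 31, 35, 42, 46, 53) are completed by a
sequential forward fill processed chronologically: for period [s,e) with
day e−1 measured, `rate = (BW(e−1) − BW(s))/(e−1−s)` and
`BW(e) = BW(e−1) + rate`. Two properties motivated this reading of the
"add the period's average gain" convention over the alternative that shifts
the pre-boundary weight with the *next* period's rate (also implemented,
`method="next_period"`): the derived period gain then equals the measured-
interval rate identically (e.g. BWG over HS1 ≡ (BW23−BW20)/3), and the
per-period gains telescope exactly to the measured total. When a
mid-schedule weighing is missing, the chain restarts by bridging the
affected boundary with the following period's measured rate, so only the
periods that genuinely need the missing anchor are dropped.

Per period: `BWG = (BW_end − BW_start)/span`; `FI` = mean daily feed
disappearance over the half-open interval (at most one missing day imputed
by the period mean); `MBW = ((BW_start+BW_end)/2)^0.75`; backfat is the
day-19 scan for TN1/HS1, the day-52 scan for HS3/TN4, and their mean for
the middle periods; `FCE = BWG/FI`, deliberately kept (negative) under
weight loss — FCR (feed/gain) is provided but undefined at zero gain and
not used in reports. Losses: `Loss_c = value(HS_c) − value(TN_c)`,
negative = drop. TN1 gain is computed from day 8, discarding the d1–8
adaptation (its gain is exposed but enters no model).

## TN-anchored RFI

The intake equation `FI = b0 + b1·MBW + b2·BWG + b3·BFT + e` is plain OLS
over all TN pig-periods pooled with equal weight (a 4-d period counts like
a 7-d one), no random effects — mirroring how phenotypic RFI is defined —
and its coefficients are then applied unchanged to the HS rows. TN RFI
therefore averages exactly zero in the fitted cohort and HS RFI measures
intake relative to the TN expectation. Both plain and adjusted R² are
reported. Two statistical caveats are inherent to this pooled design and
are visible in the synthetic cohorts: (i) line-level intake offsets (the
between-line RFI differences) correlate with line growth means, so the
pooled `b2` absorbs part of them; (ii) repeated pig-periods share the
pig's persistent intake deviation, so naive OLS standard errors are
anti-conservative. Parameter-recovery tests run under conditions where the
estimator is consistent and the errors independent (single line, exact
weights, day-level intake noise only); on the full default cohort the fit
is reported as the method defines it, biases and all.

The feed-requirement model replaces the single gain slope with a
line-by-climate-specific slope (`FI ~ climate + diet + line + room + age +
MBW + BFT + BWG:climate:line`, random litter intercept nested in line, IID
residuals, REML). Reference levels are fixed at HS / low fiber / high-RFI
line / room 2 so the estimate table always has the same zero rows. On
noiseless data all six slopes are recovered to machine precision.

## REML engine

Marginal model `V = Σ_k σ²_k Z_k Z_kᵀ + blockdiag(R_i)`, where R_i is the
subject's submatrix of a structured T×T period covariance: IID, CS, AR(1),
ARH(1), Toeplitz, unstructured, or spatial power (`ρ^{|t_i−t_j|}`, for
unequally spaced times). The AR(1)/ARH(1) repeated models additionally get
a random animal intercept, the convention used for this design. Fixed
effects are profiled out by GLS; the REML criterion includes its constants
so likelihoods are comparable across software.

Unconstrained parameterisation: log variances; Fisher-z for AR1/Toeplitz
correlations; CS correlation mapped by a scaled sigmoid onto
(−1/(T−1), 1) so the matrix stays positive definite; logit for the spatial
power ρ ∈ (0,1); log-Cholesky for UN; non-PD Toeplitz proposals are
rejected with a large objective value. Optimisation is L-BFGS-B from a
data-driven start (pooled within-subject residual covariance of the OLS
fit), with seeded jittered restarts and a Nelder-Mead polish for
low-dimensional structures; a quasi-Newton restart finishes off stalled
high-dimensional (UN) runs, and a stationary point with a small relative
gradient is accepted as converged. Degenerate variances are floored at
1e-10 (GLS then reproduces OLS exactly). Likelihood evaluation is
block-wise over independent subject groups (pigs sharing a litter merge
into one block) with one Cholesky per distinct block pattern, so balanced
designs cost O(T³) per evaluation.

Model choice ranks converged structures by AICc (REML sample size
n − rank X); the two best are compared by a likelihood-ratio chi-square on
the difference in covariance-parameter counts when their families are
nested, choosing the simpler at p ≥ 0.05. The Bayesian criterion reported
alongside is Schwarz BIC on the number of subjects (no "Sawa" variant is
defined here). Fixed-effect tests are Wald F with residual denominator df
(n − rank X); no Kenward–Roger/Satterthwaite adjustment, so p-values are
approximate in small samples — direction and significance at simulated
effect sizes are the contract, not SAS-exact values. Interaction pruning
removes the single interaction with the largest p ≥ 0.10 and refits until
none remains above threshold (α ≥ 1 removes all); note the stepwise
survivor is the minimum-p term, so under a global null a dataset retains
one interaction with probability ≈ P(min of k uniforms < α). LS means
average the observed valid factor combinations with equal weight
(nested factors only combine with their own group) and put covariates at
training means; pairwise Wald t tests feed an insert-and-absorb compact
letter display at α = 0.05.

## Synthetic cohorts

Each pig carries persistent latents: TN gain deviation `u` (litter +
animal), an intake deviation (its true RFI), and an HS robustness deviation
`r`. True gains: TN periods `line mean + u`; HS cycle c
`line mean + u + m_c + s·u + r + ε_c`, with cycle drops
m = (−0.529, −0.294, −0.245) kg/d and a negative trade-off slope `s` making
fast TN growers lose more. Intake: the TN feed-requirement equation
(b0 2.42, b1 −0.01 per kg^0.75, b2 0.480, b3 0.0) evaluated at the pig's
true MBW/gain/backfat, plus a line-level offset chosen so each line's TN
intake mean matches its configured value (3.22/2.63/2.77 kg/d), the pig's
intake deviation, and a −0.26 kg/d shift for high-fiber commercial pigs;
HS intake is the same cycle's TN level plus the total drop
(−0.662, −0.506, −0.439 kg/d) plus transient noise, so E[LossFI_c] equals
the configured drop exactly. Daily intake multiplies mean-one lognormal
noise (CV 0.20); measured weights add N(0, 0.5 kg) weighing error; the
adaptation-period gain is drawn independently of `u` (its observed
correlation with TN1 gain is near zero, as in the data the design mimics).
Start weights 59(5.9)/81(11.0)/81(8.7) kg; ages 147 ± 7 d (commercial fixed
at the mean); 13/10 litters for the selection lines, singletons for the
commercial line; scans, loin depth, carcass weight (dressing 0.75) and the
lean percentage (the Fat-O-Meater equation plus N(0,1) noise) complete the
tables. One master seed; per-pig and per-litter substreams are derived by
stable hashing of their ids, so enlarging a cohort never perturbs existing
pigs. Remaining defaults chosen once as typical finishing-pig values:
between-animal gain SD 0.15 kg/d, litter SD 0.05 kg/d, intake deviation SD
0.25 kg/d, transient HS gain/intake noise 0.12/0.15 kg/d.

### Closed-form calibration of the trade-off

Every observed per-period BWG is a *linear* function of
(u, r, ε_c, weighing errors), including the boundary-fill propagation, so
the model-implied correlations are exact quadratic forms. The coefficient
matrix is obtained by pushing basis unit vectors through the very same
boundary-fill and phenotype code the analysis uses (it is affine in the
slope, so two evaluations are cached). `calibrate_tradeoff` solves for the
slope and the robustness SD; when the repeatability target lies below the
shared-mechanism floor it pins robustness at zero and lets the transient
noise SD absorb the difference, accepting the closest solution within a
0.05 correlation tolerance (the default target pair −0.70/0.36 sits just
outside the exactly-achievable frontier; the calibrated configuration
reproduces both to ~0.02, well inside the study's own uncertainty) and
raising a calibration error otherwise — e.g. a strong trade-off with zero
repeatability has no non-negative-variance solution. Zero targets return
the mechanism's independence configuration (slope 0, robustness 0).

A consequence worth knowing: with the mechanism switched off entirely, the
observation process alone — weighing error amplified by short 4-day
periods and shared across the boundary fill — still induces a pooled
TN-gain/loss correlation ≈ −0.44 and a cycle repeatability ≈ 0.29. Short-
period resilience phenotypes derived this way carry substantial
measurement-induced structure, and the calibration deliberately targets the
*observed* totals, mechanism plus observation process, because that is what
any real analysis of such a design measures. Joint feasibility of the two
default targets in fact requires this observation layer; the latent gains
alone cannot produce pooled −0.70 with repeatability 0.36.

### What the generator does not emulate

Within-day intake autocorrelation (days are conditionally independent
given the period mean); compensatory-growth dynamics beyond the linear
period model; thermoregulatory physiology, humidity effects, mortality;
genetic relatedness beyond a litter intercept. Passing tests therefore
demonstrate correctness of the estimators and the internal consistency of
the analysis chain under the study's statistical structure, not biological
validity on real herds.

## Problem sizes used in the tests

Study-scale checks use 20 cohorts of 96 pigs (the experiment's size);
law-of-large-numbers checks one cohort of ~10⁴ pigs; REML recovery
experiments 100–500 subjects with 3–4 repeated levels; the null
calibration of the AR1-vs-UN likelihood-ratio test 200 simulated datasets.

## Known limitations

No Kenward–Roger df; no heterogeneous-by-room residuals; the pruning trail
and LS means mirror the report layout but exact p-value parity with
SAS MIXED is out of scope; phenotypic (not genetic) parameters throughout.
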