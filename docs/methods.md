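# Methods

## The procedure

The pipeline estimates relative need for adult secondary mental healthcare
and psychological-therapy services from person-level utilisation, in five
stages.

**Costing.** Each person's annual cost is the sum of in-patient bed-days,
community care contacts and IAPT contacts, each times a unit cost. Unit
costs are derived from a reference-cost schedule giving total annual cost
and volume per care cluster and setting (admitted, non-admitted, IAPT):
admitted and non-admitted totals are first scaled by an annualisation
factor (default 0.75, a nine-month costing window under constant service
delivery); the cluster's admitted cost divided by the weighted sum of
bed-days (intensive days counting as 1.97 general days) gives the cluster
general bed-day unit cost, and 1.97 times it the intensive one; cluster
units are averaged across clusters weighted by the cluster's own bed-day
counts. Care contacts are weighted by the ratio of the professional's
pay-band mid-point salary to the band-2 mid-point (missing band → band 6,
the fallback for unrecorded roles); the non-admitted cost over the weighted
contact sum gives the cluster base cost, averaged across clusters weighted
by contact counts. The IAPT unit cost is total cost over total treatment
contacts (initial assessments are never represented as a costable event
type). Person costs are truncated at £100 000 to control outlier leverage.
The published 2015/16 unit-cost figures are packaged as defaults so the
costing engine works without a schedule; deriving from a schedule overrides
them. Clusters with scheduled cost but no matching activity raise a
degenerate-cluster error naming the cluster; clusters with activity but no
scheduled cost are logged and skipped.

**Regression.** Truncated cost is regressed by OLS on the tagged design
matrix, with HC1 heteroskedasticity-robust standard errors. Robust SEs are
not clustered by practice; that is a documented departure candidate, since
the flavour of "robust" is a genuine design choice — HC1 is the common
default and keeps the estimator assumptions minimal. The
estimation/validation split is a random 50/50 partition *of practices*
(all of a practice's persons share an arm; odd counts give the estimation
arm the extra practice), so validation measures out-of-sample performance
for whole practices, the unit at which allocations are judged. Collinear
columns are dropped (later-indexed first) via a pivoted-Cholesky screen on
the Gram matrix with a 1e-8 relative tolerance, with a logged warning.

**Sterilisation.** Need estimates are model predictions with every supply
column — and every ethnicity column, whose negative-or-depressed
coefficients are read as unmet need rather than lower need — replaced by
its population-average value. The averages are constants of the allocation
run (they can be passed in externally); by linearity the population mean
prediction is preserved exactly, and a person's estimate no longer depends
on their own supply values at all. Ethnicity sterilisation uses the same
fixing mechanism as supply: the ethnicity terms still shape the other
coefficients through the joint fit (the indirect effect), but contribute no
direct variation to the allocations. Negative individual predictions are
retained, not floored: flooring would break the aggregate-conservation
property of OLS means that the normalisation step relies on. They are
counted in the log.

**Weights and indices.** Stratum need weights are mean sterilised
estimates by (practice, gender, 5-year age band) — the same bands as the
model, avoiding within-stratum heterogeneity — multiplied by stratum
registration counts. Registration counts are injectable (allocation-year
registers need not be the estimation-year population) and default to the
population's own counts. Practice raw weighted populations are normalised
so their total equals the total registered population; a CCG's need index
is its weighted over unweighted population. The population-weighted mean
index is exactly 1 by construction. Empty strata produce no row (no
imputation). A run with no activity at all degenerates gracefully: all
indices are set to 1.0 with a warning and the redistribution metrics are
reported as missing.

**Evaluation.** Predictive metrics on practice-level totals: R² is the
squared Pearson correlation between actual and predicted unit totals
(computable on the validation arm without refitting; undefined — reported
missing — under zero variance), mean absolute prediction error, and the
proportion of practices whose prediction is not within 10% of actual
(strict inequality: exactly 10% off counts as within; configurable).
Redistribution metrics on share vectors: the redistribution index
½Σ|need share − cost share|, the mean absolute percentage change in share,
and the proportion of practices changed by at least 5% (inclusive). By its
formula the redistribution index can reach 1 on disjoint-support shares,
although it is often described as ranging 0–0.5; the formula is
implemented verbatim and the discrepancy is left to the reader. Units with
zero cost share are excluded with a warning.

## The synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which every end-to-end property is demonstrated.

Geography is a unit square. Providers and LSOAs are placed uniformly;
practices sit on a jittered grid (roughly even spacing, hence roughly even
list sizes, as real practices locate to serve population) and are assigned
to CCGs in contiguous location bands. LSOA deprivation follows a spatial
gradient plus noise and drives the out-of-work benefit rate, practice SMI
prevalence, and (mildly) diagnosis-flag prevalence, so CCGs differ
systematically in deprivation and the need-versus-deprivation gradient is
reproducible in form. Distance is Euclidean distance to the nearest
provider scaled to minutes; road-network drive times are not modelled.
Provider contact shares decay with practice–provider distance and sum to
less than 1 per practice (a practice's patients need not contact any
provider), which also avoids exact collinearity with the intercept.

Households are addresses with 1–8 residents drawn from a fixed categorical
distribution (mean ≈ 2.3); a small fraction of addresses (0.5%) are care
homes, flagged directly. The empirical distribution of household sizes and
care-home residence is not published for the study population; these
defaults are arbitrary and documented as such. Household type is derived
from co-residents: care-home flag wins; then sole resident → alone; two
opposite-gender residents → the reference two-adult household; at or above
a configurable threshold (default 7) → communal; otherwise the two-plus
bucket.

Expected annual cost is linear in the generated covariates with known
ground-truth coefficients. Published effect sizes are used where available
(e.g. drug-poisoning admission £1699, living alone £101, care home £437,
out-of-work benefit £2.70/point, SMI prevalence £22/point, student practice
−£28, distance −£0.33/minute); the age–gender profile is a smooth bump
peaking in the early 40s with men costlier under 30 and women costlier
between 30 and 65; CCG effects are deterministic scrambled values in
[0, 400] and provider-share effects ramp over [0, 60]. The supply effects
are deliberately material: at the desk scale the package runs at
(2×10⁵ persons, 200 practices — the full study population is more than two
hundred times larger), practice-level sampling noise under a 4% contact
rate is large, and smaller supply effects would be undetectable; the
magnitudes are chosen once so that the qualitative structure the method
expects (supply variables add validation R²; deprived areas carry more
need) is visible at that scale.

Service use is generated in two regimes. In the stochastic regime
(noise_sd > 0, the default), a contact_rate fraction of persons (default
4.01%) are users, drawn independently of covariates; a user's cost target
is the linear predictor divided by the contact rate, times a mean-one
lognormal multiplier (log-sd 0.5, the heavy tail), plus Gaussian noise
(default £50); the target is split across admitted care, contacts and IAPT
by a random service mix and converted to integer event counts by Poisson
draws at the generative unit costs. Expected cost given covariates
therefore equals the linear predictor exactly, which is what makes the
ground truth recoverable by OLS. Pay bands are multinomial over bands 2–9
with a 2.7% missing fraction (costed as band 6 downstream, consistent with
generation). In the noise-free limit (noise_sd = 0), gating, multiplier
and Poisson discretisation are disabled and every person's activity
encodes the linear predictor exactly as fractional band-2 contacts; this
is the regime for exact-recovery checks, and is the one place event counts
are not integers.

The reference schedule is constructed from the generated activity so that
the costing engine's derivation chain (annualise → divide by weighted
volumes → average across clusters) recovers the generative unit costs
exactly, and total person cost reproduces scheduled totals to rounding. By
default every cluster shares the same generative unit costs
(cluster_cost_spread = 0); with a nonzero spread, cross-cluster-averaged
units no longer conserve per-cluster totals — the same property the
flat-unit costing of the real schedules has.

What passing tests on this generator do **not** show: the synthetic
population has no real geography, no informative missingness, no
provider-level reporting heterogeneity, and users are selected
independently of need given covariates, so the tests demonstrate the
correctness and internal consistency of the pipeline, not the external
validity of any particular coefficient on real data.

## Numerical choices and problem sizes

- OLS via statsmodels; oracle equivalence with the closed-form
  normal-equations solution asserted to 1e-8 relative on small fixtures.
- Collinearity tolerance 1e-8 (relative, Gram-matrix pivoted Cholesky);
  ties broken by keeping the earlier-indexed column.
- Normalisation identities asserted to 1e-10; sterilisation mean
  preservation to 1e-8; share sums validated to 1e-6.
- Default problem sizes: module tests run at 2×10⁴ persons / 40 practices;
  recovery and qualitative-shape checks at the default 2×10⁵ persons /
  200 practices / 10 CCGs, 20 replicates for coefficient recovery. These
  sizes were chosen as the package's desk-scale study conditions.
- Ground-truth recovery is judged against 3 robust SEs per coefficient;
  with ~63 coefficients and heavy-tailed costs the t-statistics are only
  asymptotically normal, so rare-flag coefficients (admission diagnoses at
  0.5–1% prevalence) are the binding cases.
- Truncation at £100 000 is idempotent and monotone and is applied after
  raw-cost summation; the £94 single-IAPT cost is the smallest nonzero
  person cost under the default table.

## Known limitations

- Robust SEs are unclustered; practice-level clustering would widen them.
- The 50% practice split is unstratified simple randomisation.
- Model selection (sign/significance screening of candidate variables) is
  a human process and is out of scope; the pipeline takes the covariate
  specification as given, with the evaluation table as a reporting aid.
- Combining the mental-health need indices with other funding-stream
  formulae into overall target shares is out of scope.
- Negative stratum weights are possible under OLS and are retained;
  whether to floor them before publication is a policy choice left
  configurable.
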