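# Methods

## Model

The package implements a cost-minimisation analysis: the eConsultant
advice service and the traditional hospital outpatient referral are
assumed to deliver equivalent clinical outcomes for the same referral
population, so the comparison is purely in expected cost per patient,
from the hospital provider perspective, in 2020/21 Australian dollars.
With a one-year horizon no discounting is applied. GP-side time, patient
travel and digital-infrastructure costs are outside the perspective and
outside this package's scope, as are QALYs, utilities and any
cost-effectiveness ratio.

Each arm is a tree of chance nodes; rollback computes the expected cost
as the sum over root-to-leaf paths of the product of branch
probabilities times the terminal cost. Terminal costs are linear
expressions in the inputs: sums of (minutes × staff rate) products and
attendance costs, the latter optionally multiplied by the scale
variable λ. Because everything is linear in costs and in λ, the
incremental cost is exactly linear in λ, which the threshold analysis
exploits.

## Inputs

The packaged base case has 23 parameters: 8 transition probabilities, 6
eConsult handling times (minutes), 2 staff rates (AUD/min), 6
outpatient attendance costs (AUD, one per stratum × modality), and the
scale variable λ (dimensionless, base 1.0).

Conventions used throughout:

* **Probabilities** are estimated from binomial counts with
  beta(successes, failures) uncertainty, whose analytic mean equals the
  observed proportion exactly. A zero cell has no valid beta
  distribution; it is rejected (surfacing as an empty-stratum error in
  the estimation pipeline) rather than clamped or smoothed.
* **Gamma** uncertainty uses the shape/rate convention (mean = α/λ,
  sd = √α/λ), fitted by moment matching: α = (mean/sd)², rate =
  mean/sd². Every self-consistent row of the shipped table obeys this
  convention. Sample standard deviations use the n−1 denominator.
* **Staff rates** are salary × 1.30 (a 30% employer oncost markup) with
  normal uncertainty, σ = 10% of the mean. Per-minute award rates are
  taken as given; no payroll computation from award schedules.
* **Face-to-face duration scale.** Managerial costing assumes a 30-min
  new-patient slot; an audit of new consultations found a longer mean,
  and face-to-face costs are scaled by audited-mean/30. The reported
  factor is truncated (not rounded) to 2 decimals, matching the
  convention evident in the published 41/30 → 1.36 factor. The shipped
  attendance costs already include this scaling; the function exists for
  re-derivation from raw extracts.
* **Times** carry gamma uncertainty in the shipped table; a lognormal
  moment-matched alternative is provided as a configurable family, since
  either is a defensible choice for positive skewed durations.
* Several shipped gamma rows (notably the specialist times and some
  attendance costs) do **not** moment-match their printed base values.
  Both are preserved deliberately: base values drive the deterministic
  base case, the stated gammas drive the probabilistic analysis, and the
  validation report flags every row whose gamma mean differs from its
  base value by more than 2%.

## Structure variants

The exact tree behind the published base-case figures is not published,
so the open structural choices are explicit, enumerable variants rather
than silent assumptions:

* **DNA handling** — default `payoff_equal`: a missed face-to-face
  appointment costs the same as an attended one (opportunity-cost rule),
  making the DNA chance nodes payoff-equal, hence removable without
  changing any expectation (tested). `gross_up` instead rebooks missed
  appointments, multiplying face-to-face costs by 1/(1−p_DNA).
* **Traditional-arm case mix** — default `shared`: both arms use the
  eConsult service's 96.2% new-patient mix, because the comparison is
  per patient of a common referral population. `observed_traditional`
  uses the review-heavy mix seen in the outpatient extract (136 new /
  351 review) instead.
* **Modality split** — default `conditional`: the video probability is
  conditional on the attendance not being face-to-face (6.7% / 7.5%),
  with telephone as its complement. `unconditional` splits all three
  modalities at one node, since the published labelling admits either
  reading.

The traditional-arm beta distributions use the source count pairs
(106/30, 298/53, 2/28, 4/49); the shipped table's printed rows for
these appear row-shifted and the counts are treated as authoritative.
The subsequent-attendance cost after an eConsult uses the
stratum-matched face-to-face cost times λ, and the same cost parameter
appears in both arms, so a Monte Carlo draw of that cost is common to
both arms by construction.

The canonical variant gives $203.87 (eConsult) vs $554.44
(traditional); the published figures are $226.13 vs $587.20. The
residual gap (−9.8% and −5.6%) is reported, not hidden; the
`variant-sweep` command tabulates all 12 variants, of which the DNA
gross-up variant comes closest on the traditional arm ($585.64, −0.3%).
No variant was found that closes the eConsult-arm gap entirely;
candidate explanations are unpublished handling-time components or a
different subsequent-attendance costing in the original tree.

## Sensitivity analyses

* **One-way / tornado.** Each input moves to its distribution's 2.5th
  and 97.5th percentiles (the published analysis does not state its
  bounds policy; quantile bounds are the common default and the policy
  is an argument). Bounds outside an input's domain are clipped with a
  warning record. Entries sort by descending span with ties broken on
  id, so output is order-invariant.
* **Threshold.** Bisection on the incremental cost, iterated until the
  function value is below 1e-6 (AUD), cross-checked against the
  two-point closed form wherever a three-point collinearity probe shows
  the model is linear in the target input; disagreement beyond tolerance
  is an error, not a warning. Default bracket [0, 20] on λ.
* **PSA.** All parameters are drawn jointly and independently — no
  correlation structure is imposed, none being stated for the original
  analysis. One seed feeds a per-parameter substream keyed by a stable
  32-bit hash of the parameter id, so draws are reproducible,
  order-invariant, and unperturbed by adding parameters. Domain
  enforcement clips probabilities to [0,1] and floors
  times/costs/rates/λ at 0 (normal(1, 0.25) puts ~3×10⁻⁵ mass below
  zero); the number of clipped draws per parameter is reported rather
  than silently absorbed. The decision summary is the fraction of draws
  with positive incremental cost plus mean and 2.5/97.5 percentiles.

At 10,000 draws the canonical model yields eConsult cheaper in ~98.4%
of draws (10-seed mean), versus the published 96.5% — within two
percentage points, with the residual again attributable to the
unpublished tree details.

## Synthetic data

The generator emulates the four raw inputs the estimation pipeline
reads: an RFA log (stratum, specialist minutes, subsequent-F2F flag),
an outpatient attendance extract (stratum, modality, cost, attended
flag), a duration audit, and staff-rate rows. Categorical fields are
Bernoulli draws at the true probabilities (review eConsult patients
arise at their true ~4% rate, so tiny-stratum sparsity is exercised);
minutes and costs are per-record gamma draws. Its default truth table
is the base case with gamma rows re-derived from their base values, so
recovery is unbiased. It does not emulate wait times, triage
categories, arrival processes, duplicate referrals, or any
within-patient correlation between time and cost — so passing recovery
tests demonstrate statistical correctness of the pipeline under the
model's own assumptions, not robustness to real-world data quirks.
Administration handling times and λ are not carried in activity
records and are filled from configuration during re-estimation. The
ground truth travels in a JSON sidecar the pipeline never reads.

## Problem sizes and numerical choices in the test suite

Recovery calibration runs 50 seeded replicates at 15,000 records per
service arm (≈570 review-stratum records, comfortably above the
500-per-stratum design point), requiring the recovered incremental cost
within ±10% of truth in ≥90% of replicates and each true probability
inside its recovered 95% beta credible interval in ≥90% of replicates.
Monte Carlo checks use 10,000 draws across ten fixed seeds. Sampling
moment checks gate at 3 standard errors. Zero-probability branch
pruning and payoff-equal node removal are required to leave
expectations unchanged; tree rollback is checked against an independent
path-enumeration oracle on the canonical tree and on randomised trees
of depth ≤ 4.

## Known limitations

* The reproduction is structural-inference-limited: the published
  per-arm costs cannot be matched beyond ~5–10% without the original
  tree file, and the package reports rather than tunes away that gap.
* Costs enter linearly; there is no machinery for nonlinear cost
  functions, multi-year horizons, discounting, or correlation between
  inputs.
* The DNA probability applies to face-to-face attendances only; video
  and telephone non-attendance is not modelled, mirroring the source
  data.
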