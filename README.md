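# econsult-cma

Decision-analytic cost-minimisation modelling of an **eConsultant
service** (asynchronous, clinician-to-clinician specialist advice with a
3-business-day response target) versus a **traditional hospital-based
outpatient appointment**, from the hospital provider perspective, in
AUD 2020/21.

The package is aimed at health-services researchers and health
economists who want to re-run, stress-test, or re-parameterise this
comparison: it estimates model inputs from raw activity records, rolls
back a two-arm decision tree, and quantifies uncertainty with one-way,
threshold, and probabilistic sensitivity analyses.

## The model

Each arm's expected cost per patient is the probability-weighted sum
over root-to-leaf pathways,

```
E[C_arm] = Σ_paths ( Π_branches p_branch ) × C_leaf ,
```

with both arms branching first on the shared new/review case mix
(96.2% new). In the eConsult arm a request costs administration plus
specialist handling time (stratum-specific), and with probability
`p_subsequent` the patient still needs a face-to-face attendance,
costed at the traditional face-to-face attendance cost times a scale
variable λ (1.0 in the base case). In the traditional arm every
referral becomes an attendance — face-to-face, or (conditionally on not
face-to-face) video or telephone — at its stratum/modality cost.
Missed face-to-face appointments (DNA) are costed equal to attended
ones (opportunity-cost rule), so the DNA chance nodes are payoff-equal.

The primary outcome is the incremental cost
`ΔC = E[C_traditional] − E[C_econsult]` (positive values favour
eConsult) and the efficiency fraction `ΔC / E[C_traditional]`.

Input uncertainty follows standard second-order distributions:
beta(successes, failures) for transition probabilities, moment-matched
shape/rate gamma for times and attendance costs, normal for staff rates
(σ = 10% of the mean, rates include a 30% oncost markup) and for
λ (normal(1, 0.25)). Where the shipped gamma parameters do not
moment-match their base-case values the disagreement is flagged by the
validation report, never silently corrected: base values drive the base
case, the stated gammas drive the probabilistic analysis.

## Worked example

```sh
$ econsult-cma rollback
...per-leaf pathway table...
eConsult arm:      $203.87/patient
traditional arm:   $554.44/patient
incremental:       $350.57/patient
efficiency:        63.2%
```

The eConsult episode costs $203.87 against $554.44 for a traditional
referral: a saving of $350.57 per patient, i.e. the eConsult pathway
delivers the episode at about a third of the traditional cost.

```sh
$ econsult-cma threshold
incremental cost reaches zero at attendance_scale = 4.6862 (achieved incremental 1.94e-07)
```

A post-eConsult face-to-face attendance would have to cost 4.69× a
traditional attendance before the two pathways break even.

```sh
$ econsult-cma psa --seed 1 --out-summary psa.json
eConsult cheaper in 98.3% of 10000 draws (seed 1)
```

Sampling every input from its uncertainty distribution, the eConsult
arm is cheaper in ~98% of Monte Carlo draws.

The published structure behind this comparison is not fully specified,
so `econsult-cma variant-sweep` tabulates the base case across every
documented structural choice (DNA handling, traditional-arm case mix,
modality-split convention); for example the DNA gross-up variant gives
$209.94 vs $585.64. `econsult-cma simulate` generates synthetic
activity records with known ground truth and `econsult-cma estimate`
re-estimates the full parameter table from such records (or real ones).

In Python:

```python
from econsult_cma import load_base_case, build_base_case_tree, rollback, run_psa

tree = build_base_case_tree(load_base_case())
print(rollback(tree).incremental)          # 350.57 (AUD/patient)
print(run_psa(tree, 10_000, seed=1).fraction_econsult_cheaper)  # 0.983
```

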