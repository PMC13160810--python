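# Methods

This note documents the models, numerical choices and limitations behind
`reqrank`, in the order the pipeline runs them.

## Kano classification

Each (functional, dysfunctional) answer pair is looked up in a 5×5
evaluation table over the levels *like, must-be, neutral, live-with,
dislike*. The package ships the conventional table (cells: O:1, A:3, M:3,
Q:2, R:7, I:9) as an overridable CSV; studies using a different convention
can load their own. Per indicator, category fractions are computed over
the respondents who answered that indicator, and the final demand type is
the **maximum frequency over {A, O, M, I}**. R and Q fractions are
reported but never win the assignment: a reverse or questionable majority
signals a survey problem, not a demand type, and an indicator answered
*only* with R/Q raises an error rather than guessing.

Ties are broken by a configurable precedence, default **M > O > A > I**.
The default puts must-be first because the intended application area is
safety-critical facilities, where missing a must-be requirement is the
costliest error. The assignment is invariant to positive rescaling of a
distribution, so published percentage rows that do not sum to 100% are
renormalized before use without affecting the outcome.

Better–Worse coefficients use the standard denominators excluding R and Q:
Better = (A+O)/(A+O+M+I), Worse = −(O+M)/(A+O+M+I). They are undefined
(reported as missing) when the denominator is zero.

## Psychometrics

Cronbach's α, KMO and Bartlett's sphericity all operate on a complete
subjects × items matrix; missing-data handling is deliberately the
caller's job. Sample variances use the n−1 denominator throughout (α
shifts slightly under the alternative convention, so this is fixed, not
configurable). KMO obtains partial correlations from the scaled inverse
correlation matrix, q_ij = −R⁻¹_ij/√(R⁻¹_ii R⁻¹_jj); a condition number
above 1e12 raises with a diagnostic rather than returning an unstable
value. Bartlett's χ² uses the log-determinant via `slogdet` for numerical
range, and requires more subjects than items. The item count is always
taken from the data — never from a constant — because the bundled case
study itself reports contradictory item counts (28 items in the
reliability table versus 19 indicators) and a degrees-of-freedom value
(151) consistent with neither; those published statistics additionally
depend on raw response data that was never released, so they are treated
as non-reproducible context and the battery is certified instead by
closed forms (Spearman–Brown, equicorrelated partials) and null
simulation.

## AHP

Weights come from the dominant eigenvector, computed by power iteration
with a uniform start vector, convergence when successive normalized
vectors differ by less than 1e-12 in max-norm, and a 10,000-iteration cap;
λmax is the mean of (A·w)/w at convergence. Row geometric means are
available as a cross-check method; the two agree to O(σ²) near
consistency. CI = (λmax−n)/(n−1), CR = CI/RI(n) with Saaty's classic
random-index table shipped as a data file; n ≤ 2 gives CR = 0 by
definition, and n outside the table raises a configuration error instead
of extrapolating. The order n is always derived from the matrix, never
from a reported value — the bundled case study prints consistency numbers
whose implied orders disagree with the printed matrix sizes.

Published judgment matrices are frequently not exactly reciprocal (the
bundled must-be matrix even has a non-unit diagonal entry), so matrix
objects accept any positive square grid and reciprocity is a *validation*,
not a construction invariant. The default pipeline mode `repair_upper`
keeps the strict upper triangle and rebuilds diagonal and lower triangle;
`strict` mode refuses non-reciprocal input. Repair is idempotent.

Global synthesis multiplies criterion-layer by indicator-layer weights and
renormalizes; an indicator appearing under two criteria is an integrity
error. Rankings break ties by input order for determinism.

## TRIZ

The contradiction matrix, the engineering-parameter list and the
inventive-principle names are all loadable CSVs. This matters because
real studies (including the bundled one) use nonstandard parameter
numberings; the package therefore ships the case study's four conflicts
with their *as-published* principle sets rather than asserting
correspondence with the classical 39×39 matrix. Physical contradictions
have no matrix cell by definition and carry their principle sets on the
case, with provenance recorded (`matrix` vs `configured`). Principle id
order is preserved since it may encode priority. The stage is advisory:
its output annotates the report and never feeds back into weights or
rankings.

## TOPSIS

Expert and user raters are pooled with equal weight into cell means (no
group weighting is applied; a study wanting differential trust between
groups should weight before aggregation). Columns are vector-normalized,
weighted, and compared to the per-column ideals; all indicators default to
*benefit* direction, overridable per indicator. Closeness is
Cᵢ = Sᵢ⁻/(Sᵢ⁺+Sᵢ⁻); when an alternative is identical to all others
(Sᵢ⁺+Sᵢ⁻ = 0) it receives 0.5 by convention and is flagged. Useful exact
properties, all tested: Cᵢ ∈ [0,1]; invariance to positive rescaling of
the weight vector; dominance monotonicity; permutation equivariance; and
C₁+C₂ = 1 for any two-alternative all-benefit problem. The last identity
is also why the bundled case study's published closeness pair
(0.894, 0.167) cannot be reproduced by any weight vector — it is logged as
a divergence, and the regression target is instead the value computed by
an independent step-by-step oracle (0.8818/0.1182 with the renormalized
published weights).

The weight vector for the bundled evaluation is the published combined
indicator-weight column renormalized to sum to one (as printed it sums to
2.268). The hierarchy recomputed from the published judgment matrices
covers a different indicator set (7+5+4) than the 15-column evaluation
matrix, so the two published layers cannot be joined consistently; the
renormalized published vector is the only 15-length weight vector the
source material supplies.

## Synthetic data

The generators define the package's test conditions:

* **Kano responses** — mixture model: with probability 1−ε a uniform draw
  over the evaluation-table cells of the planted category, with
  probability ε a uniform draw over all 25 cells. Chosen as the simplest
  model whose zero-noise limit is exact. Default ε in end-to-end tests is
  0.05; recovery tests use ε = 0.1 with n = 200 respondents.
* **Judgment matrices** — a_ij = (w_i/w_j)·exp(e_ij) with antisymmetric
  N(0, σ²) log-noise, preserving positivity and reciprocity by
  construction; optional snapping to the Saaty value set
  {1/9…1/2, 1…9} (nearest in log space, applied to the upper triangle).
* **Likert scores** — true mean + N(0, sd²), rounded and clipped to 1–7;
  raters split evenly into expert/user groups of 20 each, matching the
  dual-panel design the evaluation stage expects.
* **Factor items** — x = λf + √(1−λ²)e, giving inter-item correlation λ²
  and Spearman–Brown closed forms for α.

All generators are pure functions of (specification, seed) via
`numpy.random.default_rng`. What they deliberately do **not** emulate:
demographic effects on answering, missing data, acquiescence or other
response styles, and the unknown real response process behind the bundled
case study's published category percentages (whose rows do not sum to
100%). Passing recovery tests therefore certify the *estimators* under a
clean generative model, not robustness to messy field data.

## Problem sizes and tolerances

Test and acceptance runs use: 100 seeds × 200 respondents × 19 indicators
for Kano recovery; 200 seeds per σ level on a 5-item weight-recovery
grid; 500 null simulations (n = 200, p = 10) for Bartlett calibration;
n = 2000 subjects for the Spearman–Brown check (±0.03); 50 random
matrices at 1e-8 for oracle equivalence; and 100 random instances for the
TOPSIS identities (1e-12). Method cross-agreement (eigenvector vs
geometric mean, 1e-3 L1) is asserted at σ = 0.03, within the
near-consistent regime where the two are analytically close; at larger σ
they legitimately differ at the 1e-3–1e-2 level.

## Known limitations

* Group aggregation of multiple judges' matrices is out of scope (single
  matrices per layer, as in the bundled study); no fuzzy-AHP extensions.
* No factor extraction or rotation — only adequacy statistics.
* Conflict identification from requirements text is manual; the TRIZ
  module resolves cases, it does not discover them.
* Reports are deterministic by construction (sorted keys, fixed rounding),
  but stage timings are logged to stderr only, precisely so that reports
  stay byte-identical across runs.
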