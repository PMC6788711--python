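# Methods

## Model and assumptions

The package tests the null of no causal effect of a binary treatment on a
binary outcome in a one-to-one matched observational design.  It assumes:

* **SUTVA** — one unit's treatment does not affect another's outcome.
* **Exchangeability within partitions** — after exact matching on the
  (coarsened) covariate signature, any treated unit in a partition is an
  admissible match for any control unit in the same partition.  Any matching
  algorithm whose admissible pairs can be organised into such cells is
  covered; the partition structure is the only thing the test sees.
* **Normal approximation** — the continuity-corrected statistic
  Λ = (B − C − 1)/√(B + C) is treated as standard normal under the null,
  which requires at least one discordant pair (B + C ≥ 1) and is accurate
  for the pair counts the method targets (hundreds and up).

The quantity tested is direction of effect only; no point estimate of the
average treatment effect is produced.

## Closed-form extrema and the robustness condition

Because Λ is strictly increasing in B and non-increasing in C, the extrema
of Λ over all admissible pairings with total discordant count m are attained
by packing one discordant type to its capacity:

* maximize: B* = min(m, B_max), C* = m − B*;
* minimize: C* = min(m, C_max), B* = m − C*;

where B_max and C_max are sums over partitions of min(per-arm outcome
counts).  The per-partition quadruple (B, C, A, D) obtained by assigning
both discordant capacities and then filling the concordant types satisfies
B + C + A + D = min(N_t, N_c): matching the discordant capacities first
never sacrifices total pairs.  At m = B_max + C_max both branches coincide
at (B_max, C_max) — the robustness condition — and for any m strictly
between 1 and that maximum (with both capacities ≥ 1) the envelope is
strictly open.  The extremum computation is O(P) per m after one O(P·q)
capacity pass (P partitions, q largest arm), which the test suite checks as
a rank correlation between instance size and runtime rather than a
wall-clock bound.

The published table this package reproduces contains two entries
(Λ_max at m = 1000 and at m = 20000) that contradict the closed form implied
by the statistic's own monotonicity (they print 61.60 and 21.83 where the
closed form gives 31.60 and 29.44, with the 21.83 duplicating the m = 21000
row).  These are treated as typographic and excluded from the reproduction
checks; all other rows agree to two decimals.

## p-values and the decision rule

The reference distribution behind the published p-value band is not stated;
this package uses the standard-normal law with a one-sided upper tail as the
default (the alternative of a positive effect), which reproduces the
published band endpoint of 0.23 at m = 19 000, and always reports the
two-sided value (doubled tail, capped at 1) alongside.  The classification
vocabulary is: *absolute-robust* when the extreme p-values coincide,
*alpha-robust (reject / fail to reject)* when both fall on the same side of
α, and *not robust* when they straddle α.  α defaults to 0.05 and is
configurable.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance level for the robustness classification |
| `sidedness` | `one_sided_upper` | p-value tail; `two_sided` also available |
| sweep `increment` | ceil(m_max/200) | step in m; chosen so the default profile stays ≤ 200 rows (the published profile uses an irregular coarse grid and states no default); m_max is always appended |
| oracle `guard` | 12 per arm | exhaustive-enumeration size cap, configurable |

## Numerical choices and degenerate inputs

* Coarsening bins are left-closed/right-open, the last bin closed by +∞ when
  declared open-ended; out-of-range and missing values are rejected, never
  clipped or imputed (imputation would silently change the good-match set).
* Partitions lacking either arm are dropped and counted (common support);
  partition order is fixed by sorting signatures so reports are byte-stable.
* B_max + C_max = 0 raises an explicit error: the statistic is undefined.
* One-sided capacity cases (B_max = 0 or C_max = 0) collapse the envelope to
  a single curve for every m, not only at m_max; the strict-openness
  property is asserted only when both capacities are ≥ 1.
* The continuity-correction constant −1 is applied identically in both the
  maximization and minimization branches.
* The per-partition allocation of an aggregate optimal split (fill B in
  signature order, then C) is an audit aid only; the statistic depends on
  the totals alone.

## Synthetic data: what it emulates and what it does not

`generate_units` plants an exact partition structure: a configured number of
two-armed covariate signatures with per-arm Bernoulli outcome rates constant
within a partition (precisely the exchangeability the closed form exploits),
plus optional single-armed signatures that exercise the common-support drop.
Its ground-truth record carries per-partition tallies and capacity
quadruples computed by an explicit pairing simulation (pool decrementing),
deliberately different arithmetic from the main code path's minima, so that
agreement between the two is an informative dual-path check.

`generate_hrrp_like` emulates the covariate scheme of a readmission-penalty
policy cohort: nine categorical covariates (age in six bands, gender, income
quartile, primary diagnosis, comorbidity index in four bands, teaching
status, ownership, hospital size, location) drawn independently with
realistic marginals, a post-policy treatment indicator with treated fraction
≈ 0.411, and per-arm non-index-readmission rates 0.24 (pre) / 0.28 (post) —
chosen to be consistent with an overall non-index share near 0.256 at those
arm weights, since per-arm rates are not published.  It does **not**
reproduce any real dataset's partition count or pair total, covariate
correlations, ICD coding, or readmission-window logic; passing tests on it
demonstrate correctness of the machinery on data with the assumed structure,
not calibration to the real cohort.

Default generator conditions: 2–6 units per arm per partition, outcome
rates 0.5/0.5, no single-armed signatures unless requested; covariate
alphabet sized 26 × 60, with an explicit error when more signatures are
requested than the alphabet admits.  All randomness flows through
`numpy.random.default_rng(seed)`; a fixed seed gives byte-identical output.

## The exhaustive oracle

For small instances the closed form is validated against brute force.  The
default enumerator iterates per-partition discordant split counts
(b_p ≤ B_p, c_p ≤ C_p, Σ = m), which is equivalent to enumerating raw
unit-level assignments because units of equal (arm, outcome) within a
partition are exchangeable; a raw assignment enumerator (injective
treated→control maps) exists for single partitions up to 4×4 as a direct
check of that equivalence.  No integer-programming solver is involved
anywhere; the enumerator is the sole ground truth.

## Known limitations

* Binary outcomes only; continuous-outcome robust testing is out of scope.
* No effect-size estimation, exact (binomial) McNemar p-values, or power
  computation.
* Balance constraints beyond exact partition membership (calipers,
  user-defined balance sets) must be applied upstream when constructing the
  good-match set.
* The normal approximation is poor for very small discordant counts; the
  package computes the statistic there anyway and leaves the judgement to
  the analyst.
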