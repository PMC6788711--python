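# robustmcnemar

Matching-algorithm-independent McNemar test for one-to-one matched
observational studies with binary outcomes.

## The problem

In a matched observational study (say, evaluating a hospital readmission
penalty policy), a matching algorithm pairs each treated unit with a
comparable control and the McNemar test is applied to the resulting
discordant pairs.  But the set of *admissible* pairings is usually huge, and
pair construction ignores outcomes — so two analysts using different (both
valid) matching algorithms can reach opposite conclusions from the same
data.  This package computes, in closed form, the exact maximum and minimum
of the test statistic over **all** admissible one-to-one pairings, and
identifies the condition under which that ambiguity vanishes.

## The statistic and its extrema

Within an exact-match partition (a cell of units identical on all coarsened
covariates) any treated unit may pair with any control.  For discordant
counts *B* (treated outcome 0, control 1) and *C* (treated 1, control 0),
the continuity-corrected statistic

```
Λ = (B − C − 1) / √(B + C)
```

is approximately standard normal under the null of no effect.  Λ is strictly
increasing in *B* and non-increasing in *C*, so with the total discordant
count fixed at *m* the extrema depend on the data only through the
*capacities*

```
B_max = Σ_p min(n_t⁰, n_c¹),    C_max = Σ_p min(n_t¹, n_c⁰)
```

(per-partition minima of the per-arm outcome counts):

* Λ_max at B = min(m, B_max), C = m − B;
* Λ_min at C = min(m, C_max), B = m − C.

At **m = B_max + C_max** both branches force (B_max, C_max): Λ_max = Λ_min
and the test result is *absolute-robust* — no admissible pairing can change
it.  For smaller *m* the pair (Λ_min, Λ_max) and its p-value band quantify
how much the conclusion could depend on the pairing choice.

## Worked example

```python
from robustmcnemar import RobustMcNemar

model = RobustMcNemar.from_capacities(12082, 9448)   # aggregate capacities
results = model.fit()
print(results.summary())
```

```
Robust McNemar Test (matching-algorithm-independent)
========================================================
Partitions                               n/a (aggregate)
Max one-to-one pairs                               21530
B_max (treated 0 / control 1)                      12082
C_max (treated 1 / control 0)                       9448
m at robustness condition                          21530
--------------------------------------------------------
Lambda_robust                                      17.94
p-value (one-sided upper)                      2.654e-72
p-value (two-sided)                            5.308e-72
alpha                                               0.05
classification                           absolute-robust
========================================================
```

Λ_robust = 17.94 is the unique value of the statistic once all
B_max + C_max = 21530 discordant pairs are matched; its one-sided p-value is
effectively zero, so the null of no effect is rejected and, because the
extrema coincide, no admissible pairing could have said otherwise.  At
smaller *m* the band can be wide: `results.uncertainty_profile(m_grid=[19000])`
shows Λ ranging from 0.75 to 37.46 — one-sided p anywhere between 0 and
0.23 — so an analyst matching only 19 000 discordant pairs could reach
either conclusion depending on the pairing.

Starting from unit-level data instead:

```python
import robustmcnemar as rm

df, truth = rm.generate_units(rm.SyntheticConfig(n_partitions=20, seed=9))
results = rm.RobustMcNemar.from_dataframe(df).fit()
print(results.classification)        # 'absolute-robust'
```

There is also a CLI (`robust-mcnemar run / profile / simulate`) that reads a
CSV plus a YAML coarsening config and writes the capacities summary, the
uncertainty profile (TSV) and the decision report.

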