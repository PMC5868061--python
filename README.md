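# ctenotrade

Statistical tools for detecting **coordinated spawning (gamete trading)**
in paired, simultaneously hermaphroditic broadcast spawners — built
around arena experiments of the kind used for the ctenophore
*Mnemiopsis leidyi*, where two animals spawn overnight on either side of
a perforated (cue-permeable) or watertight (sealed) barrier and the egg
count on each side is recorded.

The scientific question: when partners can sense each other, does one
of them withhold eggs? If so, the split of a pair's total egg output
becomes lopsided relative to chance.

## The statistic and the test

For each paired arena with side counts $(e_A, e_B)$, compute the shares
$p_A = e_A/(e_A+e_B)$, $p_B = 1 - p_A$, and sum the per-arena absolute
differences over the $n$ replicates:

$$ D = \sum_{i=1}^{n} |p_{A,i} - p_{B,i}|. $$

Under the null that each split is an independent Uniform(0, 1) draw,
$|2U-1| \sim U(0,1)$, so $D \sim$ **Irwin–Hall(n)** (mean $n/2$,
variance $n/12$). The package computes one-tailed p-values two ways —
a 10,000-draw Monte-Carlo null and the exact Irwin–Hall tail evaluated
in exact rational arithmetic — and cross-checks them. Upper tail:
coordinated, one-sided spawning; lower tail: suspiciously even output.

Around that core: double-zero and low-egg-count exclusion filters with
audit trails, a pooled/Welch t-test comparing two arms' per-replicate
differences, blocked least-squares + Tukey HSD models of egg counts and
offspring viability, a seeded generator of complete synthetic
experiments (size-sorted blocks of five, log-linear fecundity,
binomial-thinning suppression with strength γ, 2.3% cross-barrier egg
drift, selfing viability cost), and a type-I/power study over γ.

## Worked example

The headline inference with the published observed totals as inputs
(15.8 for the cue-permeable arm, 7.6 for the sealed arm, 26 replicates
each):

```python
from ctenotrade import (AbsoluteDifferenceTotal, Tail,
                        build_null_distribution, mc_p_value)

null = build_null_distribution(n_replicates=26, n_sims=10_000, seed=1)
for total, tail in [(15.8, Tail.UPPER), (7.6, Tail.LOWER)]:
    res = mc_p_value(AbsoluteDifferenceTotal(total, 26), null, tail)
    print(f"total={total:5.1f} tail={tail.value:5s} "
          f"exceed={res.exceed_count:4d} p_mc={res.p_mc:.4f}  "
          f"p_analytic={res.p_analytic:.3e}")
```

```
total= 15.8 tail=upper exceed= 305 p_mc=0.0305  p_analytic=2.842e-02
total=  7.6 tail=lower exceed=   0 p_mc=0.0000  p_analytic=8.819e-05
```

Reading: only ~3% of uniform-split experiments produce a total as
lopsided as 15.8 (the permeable pairs split their output unevenly —
consistent with one partner suppressing), while a total as *even* as
7.6 is about an 9-in-100,000 event (sealed pairs, who cannot sense each
other, split far more evenly than chance — as size-matched independent
spawners should). The exceedance counts are strict; the analytic column
is the exact Irwin–Hall tail the Monte-Carlo estimates.

The same from the command line, on simulated data:

```bash
$ ctenotrade simulate --gamma 0.9 --seed 42 --out strong.csv
$ ctenotrade analyze --input strong.csv --treatment permeable \
      --n-sims 10000 --seed 7 --tail upper --out strong.json
observed=21.025 (n=29) tail=upper p_mc=0 p_analytic=7.891e-06
$ ctenotrade power --gamma-grid 0,0.5,1.0 --n-experiments 500 --seed 3 \
      --out power.json
gamma=0.00  rejection rate=0.0480
gamma=0.50  rejection rate=0.1160
gamma=1.00  rejection rate=1.0000
```

At γ = 0.9 the simulated permeable arm is detected decisively; the
power study shows the test calibrated at γ = 0 (≈ 5% false positives)
and certain at γ = 1. `ctenotrade report` adds the treatment-level
egg-count and viability models (blocked ANOVA + Tukey HSD), and
`run_end_to_end` chains simulate → analyze → report with byte-identical
reruns from one seed.

See `docs/methods.md` for the full model description, parameter
defaults and their rationale, and known limitations.

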