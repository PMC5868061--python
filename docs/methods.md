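# Methods

`ctenotrade` tests whether paired, simultaneously hermaphroditic spawners
(the motivating system is the ctenophore *Mnemiopsis leidyi*) coordinate
their egg output when they can exchange chemical cues. This note records
the statistical model, the synthetic-data model, the numerical choices,
and what the package's own tests do and do not establish.

## The trading statistic and its null

Each divided arena yields two overnight egg counts, one per side. For a
pair with counts $(e_A, e_B)$, $e_A + e_B > 0$, the side shares are
$p_A = e_A / (e_A + e_B)$ and $p_B = 1 - p_A$, and the per-replicate
signal is $|p_A - p_B| \in [0, 1]$. The test statistic is the
**absolute difference total**

$$ D = \sum_{i=1}^{n} \lvert p_{A,i} - p_{B,i} \rvert , \qquad 0 \le D \le n. $$

The null hypothesis is an *uninformed split*: each pair's share is a
uniform draw, $p_A \sim U(0,1)$, independently across arenas. Because
$|2U - 1|$ is itself Uniform(0, 1), the null distribution of $D$ is
exactly **Irwin–Hall(n)** — the sum of $n$ iid standard uniforms — with
mean $n/2$ and variance $n/12$. Coordinated (one-sided) spawning pushes
$D$ into the upper tail; more-even-than-random output pushes it into the
lower tail. Both one-tailed tests are provided.

Two independent routes compute the tail probability:

* **Monte-Carlo**: 10,000 simulated totals by default (`n_sims`
  configurable); the p-value is the fraction of simulated totals
  *strictly* beyond the observed one. An optional conservative
  estimator $(c+1)/(m+1)$ is available (`tie_correction`), which can
  never return exactly zero.
* **Analytic**: the exact Irwin–Hall CDF
  $F(x) = \frac{1}{n!}\sum_{k=0}^{\lfloor x\rfloor} (-1)^k \binom{n}{k}(x-k)^n$.
  In double precision this alternating sum is destroyed by cancellation
  (at $n = 26$ individual terms reach $\sim 10^{22}$ while tail values
  are $\sim 10^{-4}$), so it is evaluated in exact rational arithmetic:
  every float argument is a dyadic rational, so the only rounding is
  the final conversion to float. Property tests assert the reflection
  identity $F(n - x) = 1 - F(x)$ and agreement with an independent
  implementation.

Every test result records both p-values, the strict exceedance count,
the simulation seed and the filters applied.

### Filters

* **Double-zero exclusion**: a 0/0 split is undefined; pairs in which
  neither animal spawned are removed before the statistic, and
  `proportion_split` raises rather than imputing 0.5.
* **Low-output exclusion** (sensitivity rerun): pairs with *threshold or
  fewer* total eggs (default threshold 25; a pair at exactly 25 is
  dropped) are removed and the Monte-Carlo null is rebuilt with the
  reduced replicate count, keeping experimental and simulated $n$
  matched.

Side labels A/B are arbitrary; all statistics are invariant under
swapping them, and tests assert this.

### Arm comparison

The per-replicate $|p_A - p_B|$ values of two treatments are compared
with a two-sample t-test; the pooled-variance variant is the default,
Welch's is a flag, and the result records which was used.

## Treatment-level models

Egg counts (per arena, sides summed) and offspring viability
(developed / spawned at 24 h; undefined and excluded when nothing was
spawned) are analysed twice:

* `blocked_least_squares`: fixed-effects `response ~ treatment + block`
  for the three block-randomised treatments, with the treatment effect
  tested by a marginal (type-III) F so unbalanced tables are handled.
* `one_way_anova`: a plain four-treatment F test including the
  sealed-barrier arm, which has no block structure.

Pairwise contrasts use Tukey's HSD on the studentized range
(Tukey–Kramer for unequal sizes). When a blocked fit is supplied, its
residual mean square and degrees of freedom replace the one-way pooled
error, so pairwise tests are block-adjusted consistently with the
omnibus test. Viability is analysed as a linear-model response on the
fraction; a logistic reformulation is deliberately out of scope.
Arenas failing the 25-egg rule are excluded from both responses.

## The synthetic experiment generator

The generator emulates the arena experiment closely enough that every
downstream stage is exercised on data with the right structure:

* **Sizes**: animals are measured to the nearest mm; sizes are drawn
  from a normal truncated to [30, 57] mm. The configured mean (38.8 mm)
  and SD (6.7 mm) describe the *observed* population, so the latent
  location is solved numerically to make the truncated mean equal the
  target (with these asymmetric bounds the naive parameterisation would
  inflate the mean by ~1.2 mm).
* **Blocks**: animals are sorted by size and grouped in fives; each
  block supplies one solitary arena, one free (no-barrier) pair and one
  permeable-barrier pair, assigned at random within the block. Sealed
  pairs are generated separately and matched by adjacent size rank,
  mirroring their independent collection.
* **Fecundity**: log-linear in size, $\mu = \exp(\beta_0 + \beta_1 s)$,
  defaults $\beta_0 = 3.5$, $\beta_1 = 0.06\,\mathrm{mm}^{-1}$, putting
  a 39 mm animal near 340 eggs and spanning roughly 200–1000 over the
  size range. These coefficients are placeholders — the true allometry
  is not published — and every calibration result in the test suite is
  designed to be insensitive to them (blocking keeps within-pair means
  close, which is what matters).
* **Count noise**: negative binomial with mean $\mu$ and variance
  $\mu + \mu^2/k$, default dispersion $k = 1$. Two reasons: per-animal
  egg output is enormously variable (zero to thousands; CV ≈ 1), and
  with $k = 1$ a pair's share of the joint output is approximately
  Beta(1, 1) = Uniform(0, 1) under independent spawning, so the
  generator's independence regime matches the analysis's constructed
  null exactly. This identity is what makes the type-I calibration a
  meaningful test of the machinery rather than of a distributional
  mismatch.
* **Suppression**: with probability given by a fair coin (or by
  relative size under `size_weighted`) one partner is dominant; the
  other's count is binomially thinned with retention $1 - \gamma$.
  $\gamma = 0$ reproduces independent spawning exactly; $\gamma = 1$
  silences the suppressed partner. The default $\gamma = 0.75$ was set
  by a closed-form calculation: under thinning the expected
  per-replicate difference is
  $E|2B - 1| \approx 0.60$ at $\gamma = 0.75$, i.e. an expected total
  ≈ 15.6 at $n = 26$, the magnitude of effect the test is meant to
  detect. Dominance is *not* size-determined by default because
  observed dominance in real pairs is roughly coin-like.
* **Egg drift**: in permeable arenas each egg independently crosses the
  barrier with probability 0.023 (the measured rate); totals are
  conserved. Drift shrinks every proportion difference by the factor
  $1 - 2 \cdot \mathrm{drift}$ exactly in expectation.
* **Viability**: binomial per side; self-fertilised eggs (solitary and
  sealed arms, where no partner sperm is in the water) develop with
  probability 0.3, outcrossed eggs 0.7. Only the direction of this gap
  is empirically grounded; the magnitudes are free parameters.
* The one-hour pre-exposure "interaction bowl" step is not modelled
  separately; its behavioural effect is absorbed into $\gamma$.

What the generator does **not** emulate: spatial egg transport,
repeated spawning nights, sperm competition, seasonal covariates, or
measurement error in egg counting. Passing calibration tests therefore
show that the inference machinery is correct *given* this generative
structure, not that real arenas satisfy it.

## Type-I error and power study

`run_power_study` simulates paired arms across a grid of $\gamma$
values (default 26 pairs, 2,000 experiments per point) and records the
upper-tail rejection rate at level $\alpha$, using the exact Irwin-Hall
critical value (double-zero pairs, which carry no split information,
are dropped with the critical value recomputed at the reduced $n$).

The study simulates the spawning model *without* barrier drift by
default. Drift is a nuisance of the permeable arena, not part of the
spawning behaviour: because it contracts each difference by
$1 - 2\cdot\mathrm{drift}$, including it makes the uniform-split test
strictly conservative (measured type-I error ≈ 1.7% instead of 5% at
the default 2.3% drift). The `include_drift` flag retains it for
quantifying exactly that conservatism. At the defaults the test is
calibrated (≈ 5% rejections at $\gamma = 0$), power rises monotonically
in $\gamma$, and detection is essentially certain at $\gamma = 1$.

## Numerical and design notes

* All randomness flows from one top-level seed through
  `numpy.random.SeedSequence` substreams; every report embeds the seed
  and a config hash, and end-to-end reruns are byte-identical.
* Strict inequalities in the Monte-Carlo count follow the quoted
  procedure ("larger than" / "smaller than"); the tie-corrected
  estimator is opt-in.
* A constant response in the linear models is flagged degenerate
  (F = 0, p = 1) instead of returning 0/0.
* `tail="auto"` picks the upper tail when the observed total exceeds
  $n/2$, the lower otherwise; explicit tails are available everywhere.
* Problem sizes in the test suite (2,000 experiments per grid point for
  calibration, 60 seeded experiments for the viability direction check,
  10,000-draw nulls) were chosen so the full suite completes in well
  under a minute of compute while keeping Monte-Carlo standard errors
  small relative to the asserted tolerances.

## Known limitations

* The published F statistics, t-ratio and drift percentage are
  properties of the unpublished raw data; the package treats the
  printed observed totals (15.8, 7.6) as inputs and reproduces the
  inference layer around them, not the raw-data quantities.
* The suppression mechanism (binomial thinning of one partner) is the
  simplest model producing the observed asymmetry; the data cannot
  distinguish it from, e.g., graded mutual suppression.
* Viability is modelled per-egg-independent; clutch-level correlation
  would widen the real sampling distribution of viability fractions.
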