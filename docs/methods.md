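# Methods

This note documents the statistical model behind `censuslife`, the
conventions and numerical choices it fixes, what the synthetic-data
generator does and does not emulate, and the limitations a user should
keep in mind.

## Data model

The unit of observation is one monitored animal: an entry age class
(0 = born under observation; >0 = present at study onset or immigrated),
an exit age class with one of three fates (death; permanent disappearance
whose cause — death or emigration — cannot be resolved; right censoring,
i.e. end of observation while alive), a list of birth events for females,
and per-age observation fractions. Ages are one-year classes, class `x`
covering `[x, x+1)` years; no within-year timing is represented anywhere
in the pipeline. Immigrants are treated as entering at the start of their
entry interval and are fully at risk in it; the alternative (half
exposure on entry) would change `N_x` by at most half the immigrant count
in the entry class and is not implemented.

## Actuarial life table

Counts per class and sex: entries `t_x` (with `t_0` births), deaths
`d_x`, permanent disappearances `p_x`, censors `c_x`. The at-risk series
is the recurrence `N_0 = t_0`, `N_x = N_{x−1} − dp_{x−1} − c_{x−1} + t_x`
with `dp_x = d_x + p_x`. Pooling disappearances with deaths is the
default because treating them as censored can grossly underestimate
mortality for a dispersing sex; the `disappearances="censored"` switch
implements the alternative with a logged caution. Mortality is

    q_x = dp_x / N_q.x,   N_q.x = N_x − c_x / 2,

the classical actuarial adjustment (censored individuals at risk for half
the interval on average), and survivorship is the cumulative product
`l_0 = 1`, `l_x = ∏_{i<x}(1 − q_i)`. The estimable table ends at `ω`,
the last class with an observed death (or earlier, if `l` reaches 0 or a
class has nobody at risk). A `q_x` ratio above 1 is clamped with a
warning; with internally consistent counts (`N_x ≥ dp_x + c_x`) the ratio
cannot exceed 1, so the clamp only matters for hand-edited tables.

## Fertility

`m_x` is daughters per female per year. For each female alive in class
`x` with observation fraction `w`: the numerator accumulates `w` times
her observed newborns at `x` and the denominator accumulates `w`
(`N_m.x`, the fertility sample size). All newborns count — including
those that died before they could be sexed — and the total birth rate is
halved under a 50:50 birth sex ratio; this trades a small assumption for
much less demographic stochasticity than counting sexed daughters only.
The sex-ratio assumption is checked with an exact (Clopper–Pearson)
binomial interval on the sexed newborns; the per-age probabilities of
producing a son or daughter (weighted sexed offspring over `N_m.x`)
necessarily ignore unsexed newborns. Age at first reproduction (AFR) is
the earliest birth-event age per reproducing female, summarised by median
and quartiles with the linear-interpolation convention; a flag restricts
the distribution to known-age females (entry age 0), since immigrant ages
are estimates in real data.

## Leslie matrix and derived statistics

With the female table complete up to `ω`:

* `R0 = Σ_{x=0}^{ω} l_x m_x`, `G = Σ x l_x m_x / R0`.
* The projection matrix has `m_x` in the first row and the survival
  ratios `l_{x+1}/l_x` on the subdiagonal, zeros elsewhere — the
  undiscounted layout, implemented exactly as stated rather than the
  birth-pulse variant that discounts fertility by survival. The
  Euler–Lotka identity used for validation,
  `Σ m_x l_x λ^{−(x+1)} = 1`, is the characteristic equation of this same
  matrix, so the two are mutually consistent by construction.
* `λ`, `w`, `v` come from a full eigen-decomposition with modulus
  ordering; among modulus ties the real positive (Perron) root is
  selected, so single-age (periodic) fertility schedules still yield the
  real growth rate. Imaginary residues above 1e−9 raise instead of being
  silently discarded. `w` is normalised to sum 1, `v` to `v_0 = 1`.
  Power iteration is provided as an independent cross-check only.
* Life expectancy: `U` is the Leslie matrix with the fertility row
  zeroed; `e` is the column-sum vector of the fundamental matrix
  `(I − U)^{-1}`. This discrete convention counts the current interval,
  so `e_x ≥ 1`; no half-interval correction is applied. Because `U` has
  the subdiagonal only, `I − U` is unit-triangular-like and always
  invertible.
* Survival to the median AFR is the lookup `l` at the rounded median age;
  an `interpolate=True` flag interpolates linearly between flanking
  integer ages instead.

## Parametric bootstrap

Each of `n_reps` replicates (default 4999) resamples the table from the
sampling distributions of its own estimates, holding `ω` fixed:

* mortality: `D_x ~ Binomial(n_x, q̂_x)` with `n_x = ⌈N_q.x⌉` (fractional
  at-risk counts are rounded up), `q*_x = D_x / n_x`, and `l*` by the
  cumulative product;
* fertility: `⌈N_m.x⌉` females each contribute `Poisson(m̂_x)` daughters;
  the total over females divided by their number is `m*_x`. The
  implementation draws the total as a single `Poisson(n_x · m̂_x)`
  variate, which is identical in distribution by Poisson additivity. The
  Poisson allows the occasional two births in one interval (early infant
  death, twinning).

All statistics are recomputed per replicate and the 2.5th/97.5th
percentiles (linear-interpolation order statistics, `numpy.percentile`)
give the 95% limits. Replicates with `R0* = 0` leave `G*` undefined and
are excluded from G's percentile set with a logged count; replicates with
all `m* = 0` have `λ* = 0` and undefined `w*`, `v*`. One seeded generator
drives the run, with draws ordered replicate-by-replicate, mortality
before fertility, ages ascending, so envelopes are bit-reproducible.
Per-replicate Leslie matrices are built from `1 − q*_x` directly
(identical to `l*_{x+1}/l*_x` wherever `l* > 0`, and well-defined even
when a sampled `q*` reaches 1).

## Synthetic-data generator

The generator emulates the monitoring design that produces such records:
a founding cohort of newborns plus immigrants at configurable entry ages;
per-class mortality `true_q` and daughter fertility `true_m` (newborns of
both sexes drawn `Poisson(2·true_m_x)` per female-year, sexes i.i.d.
Bernoulli); annual censoring; per-sex annual disappearance (mimicking a
dispersing sex); per-female per-age observation fractions from a
configurable law (default: fully observed); and optionally a fraction of
newborns whose sex is never recorded. Offspring become records themselves
and are simulated recursively, so schedules must be subcritical
(`R0 < 1`) or hit the population-size guard.

**Censoring model.** Censoring is decided first within each year (by the
annual hazard, or forced in the terminal class `max_age`, where every
survivor's observation ends). An individual whose observation ends in
class `x` is taken to leave mid-interval and dies beforehand with
probability `q_x/(2 − q_x)` — the self-consistent value under the
actuarial convention, chosen so that the downstream estimator
`dp_x/(N_x − c_x/2)` is exactly ratio-unbiased at every censoring
intensity. A naive end-of-interval censoring model (full death exposure,
then censor) would bias `q̂` upward by the factor `N_x/(N_x − c_x/2)`,
which is material precisely where censors pile up — the terminal class.
Individuals observed through the whole interval face death, then
disappearance, as independent sequential hazards. One consequence: in a
configuration with no annual censoring, the raw death fraction in the
terminal class reflects the half-interval exposure of the forced
study-end censoring, not `true_q[max_age]`; validation of the raw
mortality law therefore uses schedules with `true_q[max_age] = 1`, where
no forced censoring occurs.

Features of real data the generator does **not** emulate: calendar time
(year effects, density dependence, study-specific monitoring gaps),
age-estimation error for immigrants, within-year birth seasonality,
correlation between a female's observation fraction and her birth count
(the weighting estimator corrects for exactly that correlation in real
data; in the generator births are fully recorded and weights are
independent noise, so weighted and unweighted estimators have the same
expectation), and social structure. Passing recovery tests therefore
show estimator correctness under the stated sampling model, not
robustness to those field realities.

## Reference study conditions

The reference schedule is 10 classes shaped like a medium-sized
cercopithecine monkey compressed onto a 10-year span — elevated infant
mortality (q_0 = 0.25), a low adult plateau (0.06–0.08), actuarial
senescence to q_9 = 0.45; reproduction from age 3 peaking mid-life at
0.35 daughters/female/yr — giving `R0 ≈ 0.88` (subcritical, so simulated
lineages stay finite) and `λ ≈ 0.98`. Default study conditions add 5%/yr
end-of-study censoring, male-biased disappearance (8%/yr vs 1%/yr),
and 5% unsexed newborns. The analyses use 5000 founding births
(~12,000–15,000 records); the coverage experiment uses 100 studies of
1000 births with 499 bootstrap replicates each, sizes at which the full
suite and the reproduction script run in well under a minute apiece.

## Known limitations

* Permanent disappearances pooled with deaths overestimate mortality of
  a dispersing sex (visible in the worked example as `λ̂` slightly below
  the generating truth); the censored policy underestimates it. A
  competing-risks treatment of disappearances is out of scope.
* The bootstrap resamples `q̂` and `m̂` independently across ages and
  from their estimated (not true) values; its intervals are percentile
  intervals without acceleration/bias correction. Measured coverage for
  `λ` at the reference conditions is close to nominal (~95%).
* No smoothing or parametric hazard models; estimates at sparsely
  observed old ages are noisy by design and the table simply truncates
  at the last death.
* Binned count tables carry no individual-level information, so AFR,
  sex-ratio and observation-weighting diagnostics require raw records.
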