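# Methods

## The model

Gestational age (GA) at spontaneous delivery is treated as a time-to-event
phenotype. Pregnancies enter the risk set at gestational day 150 (`t = 0`;
earlier losses are considered unviable and are outside the model), and all
simulated deliveries are capped at day 300, mirroring the clinical practice
of post-term induction. The cap is recorded as an observed delivery, not a
censoring; whether capped outcomes should instead be censored in the Cox
analyses is exposed as a flag (`censor_at_cap`) since the choice is
substantively open.

The baseline hazard is Gompertz,

    λ₀(t) = λ e^{αt},   t ≥ 0 (days since day 150),

selected by AIC among exponential, Weibull and Gompertz on register-like
data (`hazard.select_baseline`). Maternal susceptibility loci enter the log
hazard additively through the 0/1/2 minor-allele dosage `Gᵢ`:

    λ(t) = λ e^{αt} · exp( Σᵢ Gᵢ Eᵢ(t) ),

with two kinds of per-allele effect trajectory:

* **constant**: `Eᵢ(t) = γᵢ` — a classical proportional-hazards covariate;
* **varying**: `Eᵢ(t) = γᵢ/(σ√2π) · exp(−((d−μ)/σ)²/2)`, a Gaussian
  "window of sensitivity" parameterised on the gestational-day scale `d =
  150 + t`, centred at day `μ` with spread `σ` days and total mass `γᵢ`
  (the window integrates to `γᵢ`).

Loci are organised into classes of `n` identical, independently segregating
loci (no linkage disequilibrium, no dominance), each class described by
(`γ`, MAF `p`, `n`, and for varying classes `μ`, `σ`). The minor allele is
always the effect allele. γ is a log-hazard-scale quantity: it cannot be
read as a mean shift of GA in days.

Familial correlation arises by simulating the loci jointly in full-sibling
pairs (mothers who are sisters, hence maternal-cousin children). The 3×3
sibling joint genotype distribution follows exactly from random mating of
Hardy–Weinberg parents and Mendelian segregation; under additive coding it
has sibling covariance `pq`, i.e. correlation 1/2. Sampling is a single
categorical draw over the nine cells.

## Survival-time generation

Two engines generate GAs, mirroring a dual-implementation cross-check:

* **analytic** (constant effects only): with a constant multiplier `c` the
  cumulative hazard inverts in closed form; with `E ~ Exp(1)`,
  `T = log1p(αE/(cλ))/α` (limit `E/(cλ)` as `α → 0`). Times are discretised
  by ceiling to whole days, and capped: `day = min(150 + ⌈T⌉, 300)`.
* **iterative** (general): days `t = 1…150` are scanned; the day-`t` event
  probability is `1 − exp(−Hₜ)` where `Hₜ` is the *integrated* baseline
  hazard over `(t−1, t]` times the genetic multiplier evaluated at mid-day
  `150 + t − ½`. A uniform draw below that probability assigns the birth;
  anyone still pregnant after day 299 delivers at day 300.

Using the integrated daily hazard (rather than the instantaneous hazard at
the day's end) makes the discrete process *exactly* the distribution of the
ceiled continuous time whenever all effects are constant; evaluating at the
end of each day would inflate the discrete cumulative hazard by
`α e^α/(e^α−1) ≈ 1.07` at the default shape, a visible distributional
shift. For Gaussian windows (`σ = 10` d in the canonical models) the
mid-day rule is a midpoint quadrature with error far below Monte-Carlo
noise. The event rule is `U < 1 − e^{−Hₜ}`, the standard discrete-hazard
process.

RNG discipline: every public sampler takes an explicit seeded
`numpy.random.Generator`; cohort simulation spawns one child stream per
locus class, so results are reproducible at module granularity.

## Baseline calibration and fitting

The fitted register values of (λ, α) are not available, so the package
default is calibrated, not copied: (λ, α) are solved so the continuous
baseline-only model has median GA 280 d and 10th percentile 266 d (a
typical term distribution), giving λ ≈ 2.36e−9 /day and α ≈ 0.1346 /day.
The calibration and its targets are recorded in every fixture manifest.

`fit_parametric_baseline` maximises the uncensored likelihood on the
shifted scale `t = ga − 150` (all observations are live births). The
Gompertz fit uses a 1-D profile likelihood in α (λ concentrates out in
closed form), bounded to |α| ≤ 0.5/day with `xatol = 1e−10`; Weibull uses
`scipy.stats.weibull_min.fit` with the location pinned at 0; the
exponential MLE is closed-form. AIC is `2k − 2ℓ` with `k = 1, 2, 2`; ties
break toward fewer parameters. A note on precision: at the calibrated
(steep) baseline, `log λ̂` and `α̂` are ≈ −99.7% correlated and the relative
SE of λ̂ is ≈ 4% even at n = 100,000, so recovery checks on λ are run at a
better-conditioned parameter point.

## Conditional quantile table and cost

Pair members are relabelled at random (pair order is arbitrary); the
conditioning member's GA is binned into 7-day windows anchored so 280 is a
bin edge, and the 5th/25th/50th/75th/95th percentiles of the other member's
GA are computed per bin (linear interpolation between order statistics).
Only bins with **strictly more than 100** pairs are retained in the
reference table — the retention rule selects which observed bins are
trustworthy fitting targets. A height-like analysis uses the same machinery
with a 5-unit bin width.

Simulated tables are scored against the reference by

    cost = Σ_bins √N_bin · Σ_{5 quantiles} (sim_q − ref_q)²,

with `N_bin` always the *reference* counts (quantile sampling error scales
as 1/√N). Simulated quantiles are computed in every populated bin — no
retention cut on the simulated side — because applying the >100 rule to
simulated replicates makes marginal bins flip in and out and the resulting
penalty dominates the replicate variance. A reference bin the simulation
leaves literally empty contributes a fixed 25 d deviation per quantile
(logged); with simulated cohorts matched to the reference size this
essentially never happens. The `quantile_slope_contrast` statistic —
least-squares slope of the 5th minus the 95th percentile series across bin
index — summarises nonuniformity: positive when lower quantiles climb
faster, ~0 for parallel (bivariate-normal-like) patterns.

## Model fitting

Models M0–M4 (see `gestwin.models`) are fitted by random search: free
constant-class parameters are drawn as `γ ~ Unif(−5, 5)`,
`p ~ Unif(0, 0.5)`, `n ~ 1 + Poisson(1)`; each candidate is scored with one
simulated cohort (replicates configurable). The statistic `Σ γpn` over the
free classes strongly predicts cost, so fits use two stages: the best 1% of
stage-1 candidates define a `Σγpn` interval (widened by 10% of its length
per side, minimum width 0.01), and stage 2 samples candidates inside the
interval by rejection, which preserves the marginal draw distributions.
Classes that are fully pinned (the fixed Gaussian windows of M3) shift
`Σγpn` by a constant and are excluded from the statistic. Models flagged
without meta-modeling (M4) run a single unconstrained stage. Finally the
top 20 candidates are re-scored with the iterative engine at 10 replicates
and re-ranked among themselves, so engine discretisation differences cannot
decide the ranking. Default budgets are 10,000 per stage; the bundled
self-calibration checks use 1,000 + 1,000, which recovers `Σγpn` of a known
generating M1 model within a few percent at the default cohort size of
35,541 pairs. The cost deliberately carries no penalty for parameter count;
model comparison is by equal search protocol, not information criteria.

## Power and type-I error

Cohorts of unrelated individuals are simulated under a model (canonically
the M3-like configuration), two null control loci (MAFs 0.015 and 0.3) are
appended, and every locus is tested marginally by (a) univariate linear
regression of GA in days on dosage and (b) the Wald test of a
one-covariate Cox model. Power is the fraction of replicates with
p < 5×10⁻⁸; control loci are tabulated at nominal levels, with binomial
CIs, flagging cells with expected minor-allele count `2np ≤ 3` where no
test holds its level. Defaults are 1,000 replicates per sample size on the
grid {100, 500, 1000, 5000, 20000, 50000}; Monte-Carlo SE of a power
estimate is ≤ 0.016 at 1,000 replicates.

Integer-day times are heavily tied, so the partial likelihood uses the
Efron approximation. The solver is a dedicated Newton–Raphson maximiser for
the single-covariate case, vectorised over risk sets (power runs need tens
of thousands of fits; per-fit overhead of general-purpose survival
packages dominates at these sizes). It is verified in the test suite
against lifelines' `CoxPHFitter` and against an independent explicit-loop
Efron maximiser (agreement to 1e−6 in β̂, SE and p on tied data). Monotone
partial likelihoods (|β̂| diverging) are flagged non-converged and the
replicate is counted as failed rather than contributing a spurious
p-value.

## Fixtures: what they emulate, and what they do not

`make_reference_population` stands in for the register cousin-pair sample
(35,541 pairs): the generating model couples the four fixed Gaussian-window
classes (peaks at days 230/237/244/258, σ = 10 d, masses 100/80/60/−100,
MAFs 0.005/0.01/0.015/0.3) with a free-form constant class fixed at
γ = 2.6, p = 0.01, n = 2 — a plausible value in the region where
constant-effect fits concentrate (effect sizes 2.4–2.8, rare alleles),
chosen for the fixture rather than estimated from data. The fixture
reproduces the *qualitative* register pattern — lower GA quantiles climbing
much faster across bins than upper ones (contrast ≈ +2.4 d/bin at default
settings) — not the register's numeric quantile values, which are not
available. It also omits everything the register adjustment handled:
parity, year, ultrasound dating, and all environmental covariates are
absent, so GAs are "pre-adjusted" by construction. Passing tests therefore
demonstrate internal consistency and pattern reproduction, not agreement
with clinical data.

`make_polygenic_control` emulates the height contrast: a plain additive
Gaussian trait (not a survival trait — a deliberate modelling distinction)
summing 1,000 small-effect shared sibling loci with heritability 0.5, so
the sibling correlation is 0.25 and conditional quantile series are
parallel. The preregistered uniformity threshold for
`|quantile_slope_contrast|` is 0.5 trait units per bin — 40% of the
parallel ascent `(h²/2)·bin_width = 1.25` — several times the sampling
noise at register scale.

## Numerical and degenerate-input conventions

* `p = 0` is accepted by the samplers as the degenerate monomorphic case;
  `p > 0.5` is rejected, never silently flipped.
* `(e^{αt}−1)/α` is computed via `expm1` with a series fallback for
  |α| < 1e−12, so the exponential limit is continuous.
* Quantile tables with no retained bin carry an explicit empty flag.
* Constant genotype columns make both association tests undefined; they
  return NaN / a non-converged fit and are counted per replicate.
* Search determinism: identical spec + seed reproduce rankings bit-for-bit;
  rejection sampling caps at 100,000 proposals per candidate before
  raising.

## Problem sizes used by the bundled checks

The self-calibration check uses a 1,000 + 1,000 candidate budget at 35,541
pairs; null calibration uses 10,000 replicates at n = 500 (uniformity) and
5,000 at n = 1,000 (level); power ordering uses 1,000 replicates at
n = 500 and 2,000; fixture patterns use 5–10 seeds at full register size.
These sizes give Monte-Carlo error comfortably below each check's
tolerance while keeping a full run in minutes on one core.

## Known limitations

Linkage disequilibrium, dominance, X-linkage, fetal-genome effects,
gene–gene and gene–environment interaction, incomplete penetrance, early
miscarriage (< day 150) and twin pregnancies are all out of scope. The cost
function compares models under an equal search protocol but does not
penalise dimensionality. The Gaussian window is one convenient shape for
smoothly appearing/disappearing effects; nothing in the machinery depends
on it specifically, and alternative trajectories can be added by extending
`effect_trajectory`.
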