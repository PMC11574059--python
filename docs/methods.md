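# Methods

## The model

`frfit` analyses no-replacement predation trials: a single predator is
offered `N0` prey in a closed arena for a fixed time `T` (hours), and the
number eaten `Ne` is recorded. Because eaten prey are not replaced, prey
density declines during the trial and the classical Holling disc equation
(`Ne = aNT / (1 + ahN)`, constant density `N`) overestimates consumption.
The package therefore fits the Rogers random-predator equation,

    Ne = N0 * (1 - exp(a * (Ne*h - T))),

which integrates the Type-II attack process over the depleting prey pool.
Here `a` is the attack rate (instantaneous search efficiency, per unit
search time and per arena — counts are per arena, so `a` is specific to
the arena volume used) and `h` is the handling time (time to capture,
consume and digest one prey item, in the units of `T`). The Type-II
asymptote is the maximum feeding rate `1/(hT)` prey per trial.

The implicit equation is solved in closed form with the principal branch
of the Lambert W function,

    Ne = N0 - W0(a*h*N0 * exp(-a*(T - h*N0))) / (a*h).

`W0` gives the unique ecologically meaningful root in `[0, N0)`. When the
log of the W argument exceeds 700 (where `exp` would overflow a double),
the solver switches to Brent bracketing of the implicit equation on
`[0, N0]`; the two routes agree to better than 1e-8 everywhere we have
gridded them (`a` up to 10, `h` up to 0.5, `N0` up to 256, and beyond).
Special cases short-circuit: `a = 0` or `N0 = 0` returns exactly 0, and
`h = 0` uses the exponential-depletion closed form `N0*(1 - exp(-aT))`.
`N0` may be non-integer so that optimizers see a smooth surface.

## Inference

**Type determination.** A binomial GLM (logit link) regresses
eaten-out-of-offered on a polynomial in `N0` (degree 1 by default; degree
2 is available for explicit sigmoid detection). A significantly negative
first-order coefficient at `alpha` (default 0.05, configurable) is read
as Type II, significantly positive as Type III, otherwise ambiguous.
Degree 1 and `alpha = 0.05` are conventions of the field, not forced by
the data; both are options.

**Fitting.** The likelihood is per-trial binomial: `Ne_i ~
Binomial(N0_i, p_i)` with `p_i` the Rogers-predicted proportion eaten.
Because the predicted proportion is strictly inside (0, 1) for positive
`a` and `h`, trials in which every prey was eaten remain informative and
are retained by default (`include_depleted=False` gives the sensitivity
variant). Optimization is Nelder-Mead on `(log a, log h)` — positivity
by construction — from a deterministic multi-start grid (`a` in
{0.1, 1, 10} crossed with `h` candidates `1/max(N0)`, `T/max(Ne)` and
0.1), tolerance 1e-8 on the log-likelihood, guarding against the known
ridge between `a` and `h`. The likelihood is evaluated on unique
(duration, density) design cells rather than per trial, which makes the
bootstrap refits cheap without changing the value.

Standard errors come from the inverse of a central-difference Hessian of
the negative log-likelihood at the optimum (step `1e-4` per log-unit),
delta-method transformed to the natural scale; Z statistics are
`estimate/SE` with two-sided normal p-values. Wald intervals are formed
on the log scale and back-transformed, which respects positivity and has
close-to-nominal coverage at the 3-replicate design size (verified by
simulation in the test suite). A fitted `h` at or below 1e-8 is flagged
as a boundary fit: handling time indistinguishable from zero, maximum
feeding rate reported as undefined rather than infinite.

**Group comparison.** Juliano's indicator-variable method refits the
pooled two-group data with `a = a1 + Δa·j`, `h = h1 + Δh·j` (`j` the
group indicator) and Wald-tests `Δa` and `Δh` against zero. The
four-parameter optimization runs on the natural scale (with a positivity
penalty), warm-started from the two separate fits, then restarted once
from its own solution — the restart plus swap-symmetric Hessian step
scales make the reported p-values invariant (to ~1e-6) under exchanging
the group order, as they must be. Across more than two groups the test
is applied pairwise; raw and Holm-adjusted p-values are both reported,
and compact letter displays are built from the adjusted ones (the
adjustment choice is ours; both sets are emitted for transparency).

**Bootstrap bands.** The resampling unit is the whole trial (one fish
per tank is the independent unit). Each of `n_boot` replicates (2000 by
default) resamples trials with replacement, refits the Rogers MLE
(single warm start from the full-data fit), and evaluates the curve on a
density grid; the band is the pointwise 2.5/97.5 percentile envelope,
with the bootstrap-mean curve and the point-estimate curve both
reported (percentile bands of refits need not bracket the point
estimate). Replicates whose refit fails are dropped and counted — never
redrawn, so a seed fully determines the output; more than 20% failures
raises an instability error. Percentile rather than BCa intervals are
used; BCa could be added but the percentile form matches common
practice for this procedure.

## Prey-size selection

Mixed-prey trials offer small and large prey 1:1. Consumption of the two
classes is compared only at densities where, within a group, no
replicate fully depleted either class — a strict rule, since a single
ceiling-censored replicate biases the cell mean. Per temperature, a t
statistic compares small vs large counts (Welch by default — the safer
choice when variances differ; pooled-variance and paired-within-tank
variants are options). One-way ANOVA with Tukey HSD compares consumption
across temperatures per class, with compact letters (Latin for small
prey, Greek for large, following the display convention). Counts convert
to biomass with the class mean masses, 0.13 mg (small, 4–6 mm) and
0.93 mg (large, 10–12 mm) per larva; masses enter as constants, the
class SDs are carried only for optional noise in the simulator.

## The synthetic-data generator

No raw trial data ship with the package, so the generator emulates the
factorial study design end to end: 3 replicates x 2 sexes x 3
temperatures (22, 25, 28 °C) x doubling densities 2–64 (extended to 128
and 256 for females on small prey, where the asymptote is otherwise not
reached) x three prey treatments (small, large, mixed 1:1), plus a
pregnancy experiment (2 stages x 25 °C x densities 2–256 x small prey),
all with T = 1 h.

Two noise processes are deliberately distinct:

* **binomial** draws `Ne ~ Binomial(N0, Ne_hat/N0)` — exactly the
  fitting likelihood, so recovery tests isolate "does the fitter work";
* **mechanistic** simulates the renewal sequence (exponential waiting
  time at rate `a * N_remaining`, then a deterministic handling period
  `h` that blocks search) — model-independent of the likelihood, so it
  probes adequacy. Its mean consumption sits slightly above the Rogers
  deterministic root (about 0.16 prey at `a=1, h=0.1, N0=10` over 5000
  replicates); the gap is a real property of the stochastic renewal
  process, recorded in the tests rather than assumed away. Handling is
  deterministic, matching the classical disc-equation derivation.

Mixed-prey cells use two competing capture streams with class-specific
`(a, h)` sharing one time budget (handling either class blocks both) —
the minimal mechanistic extension, chosen because no standard mixed-prey
depletion model exists.

The default per-cell parameters encode the qualitative structure of a
strongly size-dimorphic larvivore and are fixed once: female small-prey
handling times 0.0125/0.0100/0.0072 h at 22/25/28 °C (asymptotes ≈
80/100/139 prey/h), males 0.185/0.100/0.070 (≈ 5/10/14), female large
prey 0.070 at all temperatures with the attack rate peaking at 25 °C,
male large prey 0.45, and pregnancy stages 0.0103/0.0084 against the
non-pregnant 0.0100 at 25 °C; attack rates 1–3 per hour with the female
small-prey value highest at 22 °C. What the generator does *not*
emulate: satiety/gut-volume limits, within-trial behavioural change,
temperature-dependent metabolism, or between-fish heterogeneity beyond
binomial/renewal noise. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under the design's
structure — not that the Rogers model is adequate for any particular
real predator.

## Numerical choices and problem sizes

Simulation-based checks in the test suite use sizes chosen for a
single-CPU run: 200 datasets for CI-coverage and type-determination
rates, 200 null + 50 alternative simulations for the difference-test
calibration and power, and 100 datasets x 300 bootstrap replicates for
band coverage (the analysis default remains n_boot = 2000). Ties and
degenerate inputs: single-density designs, all-zero and all-depleted
datasets raise explicit degenerate-data errors; zero-variance ANOVA
inputs return a flagged degenerate result with all groups sharing one
letter.

## Known limitations

* Wald inference on `Δa`, `Δh` is first-order; at 3 replicates per
  density the null rejection rate sits near but not exactly at 5%
  (within [0.02, 0.10] in simulation).
* The attack rate is arena-specific; comparing `a` across studies
  requires a common arena/volume normalization the package does not
  attempt.
* Temperature is a grouping label, never a fitted covariate — the
  pipeline compares per-temperature fits rather than fitting, say, an
  Arrhenius model for `a(T)`.
* No random effects across replicates; fish are treated as exchangeable
  within a cell.
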