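# frfit

Comparative functional-response analysis for no-replacement predation
trials.

Feeding trials that offer a predator a fixed number of prey for a fixed
time — and do not replace prey as they are eaten — violate the
constant-density assumption of the Holling disc equation. `frfit`
implements the standard depletion-corrected workflow used in
comparative functional-response (CFR) studies of predator impact (for
example, comparing female and male guppies preying on chironomid larvae
across warming temperatures):

1. **Type determination** — binomial logistic regression of the
   proportion eaten on prey density; a significantly negative
   first-order term indicates a Type-II (decelerating) response, a
   positive one Type III (sigmoidal).
2. **Fitting** — maximum-likelihood estimation of the Rogers
   random-predator equation

       Ne = N0 (1 − exp(a (Ne·h − T))),

   solved via the Lambert W function, giving the attack rate `a`,
   handling time `h`, their standard errors and Z-test p-values, and the
   maximum feeding rate `1/(hT)`.
3. **Comparison** — Juliano's indicator-variable method (`a = a₁ + Δa·j`,
   `h = h₁ + Δh·j`) Wald-tests parameter differences between sexes,
   temperatures or pregnancy stages, with Holm adjustment and compact
   letter displays across >2 groups; non-parametric bootstrap
   (n = 2000 by default) gives 95% confidence bands around the FR
   curves.
4. **Prey-size selection** — small-vs-large consumption tests at
   non-depleted densities, cross-temperature ANOVA with Tukey letters,
   and count→biomass conversion (0.13 mg / 0.93 mg per small / large
   larva).

A seeded synthetic-trial generator reproduces the factorial study
design (2 sexes × 3 temperatures × doubling densities 2–256 × three
prey-size treatments, plus a pregnancy experiment), so the entire
pipeline is testable with no external data. See `docs/methods.md` for
the model, assumptions and numerical details.

## Worked example

```python
from frfit import (simulate_study_design, fit_rogers, classify_fr_type,
                   summarize_fit, juliano_compare)

trials = simulate_study_design(seed=1)
females = [t for t in trials if t.sex == "female" and t.prey_size == "small"
           and t.temperature_C == 25.0 and t.pregnancy == "none"]
males = [t for t in trials if t.sex == "male" and t.prey_size == "small"
         and t.temperature_C == 25.0]

tt = classify_fr_type(females)
print(f"type: {tt.inferred_type} (first-order term {tt.first_order_coef:.4f}, "
      f"p = {tt.p_value:.2e})")

s = summarize_fit(fit_rogers(females))
print(f"a = {s['a']:.3f} (p = {s['p_a']:.2e}), h = {s['h']:.4f} h/prey "
      f"(p = {s['p_h']:.2e}), max feeding rate = {s['max_feeding_rate']:.1f} prey/h")

cmp = juliano_compare(females, males, "female", "male")
print(f"male - female: delta_h = {cmp.delta_h:+.4f} (p = {cmp.p_delta_h:.2e}), "
      f"delta_a = {cmp.delta_a:+.3f} (p = {cmp.p_delta_a:.3f})")
```

prints

```
type: TypeII (first-order term -0.0088, p = 3.64e-44)
a = 2.077 (p = 4.78e-29), h = 0.0099 h/prey (p = 1.83e-52), max feeding rate = 101.2 prey/h
male - female: delta_h = +0.0734 (p = 1.89e-06), delta_a = -0.930 (p = 0.012)
```

The negative first-order term confirms a Type-II response; the female
fit estimates an attack rate of about 2.1 arena⁻¹ h⁻¹ and a handling
time of about 0.010 h per prey, i.e. a maximum feeding rate of roughly
101 small prey per hour. The positive `Δh` (male minus female) says
males handle prey significantly more slowly — here roughly an
order-of-magnitude lower asymptote.

The same stages are available from the shell:

```sh
frfit simulate --seed 1 --out trials.csv
frfit fit trials.csv --sex female --temperature 25 --prey-size small --pregnancy none
frfit run --seed 1 --n-boot 2000 --out report.json
```

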