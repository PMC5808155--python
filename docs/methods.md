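# Methods

## Model

Conditional (single-compound) responses are modelled with the four-parameter
log-logistic curve

    f(x) = y_inf + (y0 − y_inf) / (1 + (x/e)^s),

the parameterisation used by standard dose–response fitting software: `y0` is
the response at zero dose, `y_inf` the asymptote at infinite dose (maximal
effect), `e` the EC50 in the dose units of the record's axis, and `s` the
slope. The package works in the inhibitory orientation (`y0 > y_inf`,
`s > 0`, response decreasing in dose), matching viability and growth
readouts. `(x/e)^s` at `x = 0` is defined as 0 so that `f(0) = y0` exactly;
`x = +inf` is an accepted sentinel mapping to `y_inf`. The closed-form
inverse `f⁻¹(y) = e·((y0−y)/(y−y_inf))^(1/s)` returns 0 at `y0` and the
`+inf` sentinel at or below `y_inf` (effect unreachable at finite dose). The
theory requires only a monotone, twice-differentiable curve; the
proportionality shortcut below is Hill-specific and labelled as such.

A *record* is one compound pair × cell line: two conditional series plus the
full combination checkerboard. The unit on which all surfaces are defined is
the `CurvePair` — two Hill curves constrained to share `y0`, since both
conditionals measure the same untreated wells. Dose units may differ between
the two axes; the pair never converts units, and the EC50 ratio `c_hat`
carries an explicit unit caveat.

## Null reference surfaces

Loewe additivity is built on dose equivalence: `x1_equiv(x2) = f1⁻¹(f2(x2))`
is the compound-1 dose matching the effect of `x2`, and vice versa. Four
surfaces predict the no-interaction response:

* **General isobole equation (`gi`)** — the `y` solving
  `x1/f1⁻¹(y) + x2/f2⁻¹(y) = 1`, implicit and solved numerically.
* **One-sided explicit surfaces (`2to1`, `1to2`)** —
  `f1(x1 + x1_equiv(x2))` and `f2(x2_equiv(x1) + x2)`.
* **Explicit mean (`mean`, `geomean`)** — the arithmetic (default) or
  geometric mean of the two one-sided surfaces. The weight is fixed at 1/2:
  the symmetric arithmetic mean is the combination that stays closest to the
  implicit surface under mild consistency violations, and a tunable weight
  is deliberately not exposed.

**Consistency.** The Loewe Additivity Consistency Condition (LACC) —
`f_2→1 = f_1→2` everywhere — holds iff a dose and its equivalent are
proportional, which for Hill pairs means equal `y0`, `y_inf` and `s` with
only `e` differing. The package checks it two ways: the parameter criterion
(relative tolerance 1e-6 on slope and on asymptote difference scaled by the
response span — the condition is exact in theory, the slack is for floats)
and the measured asymmetry `max |f_2→1 − f_1→2|` on a dose grid, the
testable surrogate for "for all doses". Under the LACC all four surfaces
coincide; the test suite verifies equality to solver tolerance and the exact
linearity of the equivalence maps rather than re-deriving the proof.

**Unequal maximal effects.** Where `f2(x2) < min f1` the equivalent dose is
infinite; the affected surfaces degrade to the reachable conditional
(`gi` and `2to1` return `f2(x2)`, symmetric on the other side), and the
explicit mean remains the average of the two one-sided surfaces with those
fallbacks embedded. Ties within the bracket padding are routed to the
fallback so no unbounded inverse is ever evaluated.

## Numerical choices

* **GI solver:** bracketed bisection on
  `g(y) = x1/f1⁻¹(y) + x2/f2⁻¹(y) − 1`, which is strictly monotone in `y`
  for decreasing curves. Bracket `(max(y_inf)+ε, y0−ε)` with relative
  padding `ε = bracket_pad·(y0 − max y_inf)`, `bracket_pad = 1e-12`;
  defaults `y_tol = 1e-9` (absolute, response units), `max_iter = 200`.
  Bisection is preferred over derivative methods because `g` has unbounded
  slope at the bracket ends. If `g` is non-negative at the lower bracket end
  the true root lies within `ε` of the floor and the padded endpoint is
  returned. Each cell is solved independently in scalar arithmetic — simple,
  robust, and an honest basis for the implicit/explicit timing comparison.
  Axes are special-cased to the exact conditionals.
* **Responses are not clamped** to [0, 1]; the models are defined on the
  fitted curves as-is, including negative fitted asymptotes.
* **Contours:** marching squares (`skimage.measure.find_contours`) on the
  surface matrix, grid indices mapped back to doses by linear interpolation.
  Grid resolution is the caller's responsibility; there is no adaptive
  refinement. Straightness is quantified as the maximum perpendicular
  deviation of a contour polyline from its endpoint chord, relative to chord
  length.

## Fitting and filtering

Both conditional series are fitted jointly by unweighted least squares over
their concatenated residuals: seven free parameters (shared `y0`; `y_inf`,
`log10(e)`, `s` per curve — the log transform conditions the EC50 search).
Levenberg–Marquardt with an analytic Jacobian runs from a deterministic
multistart grid: one data-driven EC50 start per curve (the dose at which the
series crosses halfway between its zero-dose and lowest response, clipped to
the observed dose range) crossed with slope starts {0.5, 1, 2, 4, −1}. The
negative start lets the optimiser represent increasing series, so the
standard record filter — exclude fits with non-positive slope or EC50 — can
actually fire instead of returning a distorted decreasing fit. Per-start
settings `xtol = ftol = 1e-9`, `max_nfev = 60`: on identifiable data LM
converges well inside this budget, and on flat, weakly identified records a
larger budget was observed to change nothing but runtime. Best summed
squared residuals wins; ties go to grid order. Other pathologies (e.g. a
fitted `y_inf` above `y0`) are flagged but not excluded, since the filter
rule names only slope and EC50; flagged fits carry their raw parameters but
no usable `CurvePair`.

## Evaluation

Per record and model: residual = predicted − observed over all finite
measured cells (conditional row/column included by default, since measured
axis cells are data too; a flag restricts to combination cells). `bias` is
the mean residual — positive means the model over-predicts response, i.e.
under-predicts effect — and `mse` the mean squared residual; `mse ≥ bias²`
always. The optional outlier rule (off by default, appropriate when the
noise model is known) excludes cells with `|residual| > 5·MAD` of the
record's residuals under the evaluated model; this robust screen is this
package's own choice.

Model comparison refits every record, evaluates both surfaces, and applies
the paired Wilcoxon signed-rank test (scipy), one-sided by default with the
alternative "the implicit model's mse is greater". Zero differences are
dropped per the standard convention; if all paired mse differences are
within what the GI solver tolerance alone can induce
(`2·y_tol·(√mse_max + y_tol)`), the comparison is flagged degenerate with
`p = 1` — differences at that scale say nothing about the models. Records
whose fit is excluded, or on which a solver fails, are dropped with a logged
reason rather than aborting the batch. The population-level LACC test
applies the same signed-rank machinery two-sidedly to the per-record fitted
slope pairs and asymptote pairs.

## Synthetic data

The generator exists so that every stage is testable end-to-end without
external downloads. It emulates two screening layouts:

* `dilution6` — 6 doses per axis: a top dose (defaults 2.5 and 125, the
  micromolar top doses typical of one-to-all cancer screens), four 4-fold
  dilutions, and zero.
* `linear8` — 8 doses per axis, linear from 0 to a top dose.

Curve-pair scenarios mirror the canonical illustration settings
(`lacc`: e1=1, e2=2, shared y0=1, y_inf=0, s=2; `slopes`: s1=1 vs s2=2;
`max_effect`: y_inf 0.3 vs 0; `both`). Randomised draws use EC50
log-uniform on [0.25, 4], slope uniform on [0.5, 4], asymptote uniform on
[0, 0.4], with "unequal" enforced by margins (0.2 in slope, 0.1 in
asymptote) so a scenario cannot degenerate into near-consistency. Records
are a chosen truth surface plus i.i.d. homoscedastic Gaussian noise
(default σ = 0.02 response units, a typical replicate spread for normalised
viability data), unclipped. Population simulation derives per-record seeds
from the master seed via `SeedSequence.spawn`, so populations are
reproducible and records independent.

For *population* simulations the default design is a per-record `linear8`
grid dosing up to 4× each compound's EC50, emulating protocols that pick
per-compound top doses near the maximal-effect dose. This matters: under a
fixed dose range many simulated compounds respond barely or entirely within
the first dilution step, their conditional fits are weakly identified, and
fitted-parameter noise — not the models — dominates the evaluation, which is
precisely the regime real fixed-range screens handle by discarding a large
fraction of records. The fixed designs remain available for studying exactly
that regime.

What the generator does **not** emulate: plate effects, heteroscedastic or
dose-dependent noise, interaction (synergy/antagonism) terms, and real
screens' compound-specific dose-range misses. Passing tests therefore
demonstrate correctness of the models, solvers, fits and statistics under
the stated noise model, not performance on any particular laboratory
dataset.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at sizes chosen to make each
property decisive on a single CPU: 100 random pairs for the
equivalence/sham/proportionality properties (10×10 grids), 20 instances ×
10⁶ scan points for solver verification, 201-point grids for contour
geometry, 50 seeded replicates for noisy fit recovery, 20 batches of
50-record populations for truth-model identifiability, and 200 repeats of
50-record null populations for the type-I rate of the population test.

## Known limitations

* The proportionality shortcut in the LACC report assumes Hill conditionals;
  the asymmetry grid works for any monotone curve family.
* The GI solver's reported response is accurate to `y_tol`; quantities
  derived from differences below that scale are flagged degenerate rather
  than interpreted.
* Fit quality on 6-point dilution series with off-range EC50s is inherently
  poor; the exclusion rule catches only sign pathologies, by design.
* The timing benchmark measures this implementation on the host machine;
  only the ordering (explicit faster than implicit), not the factor, is
  asserted anywhere.
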