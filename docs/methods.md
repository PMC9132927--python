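# Methods

## Models

All dose–response curves map a strictly positive concentration c (in one of
nM, µM, mM, µg/L, mg/L) to a fractional effect in [0, 1] and are monotone
non-decreasing. The registry covers the Hill, Weibull and Logit families in
two-, three- and four-parameter forms plus the Box–Cox–Weibull,
Box–Cox–Logit and generalized-logit equations (13 equations; the registry
is an open dict, so further forms can be added). Parameters are serialized
(α, β, γ, δ): α is location/intercept, β > 0 the slope, γ the upper
asymptote for the three/four-parameter forms (shape for Box–Cox and
generalized logit), δ the lower asymptote of four-parameter forms. Every
registered equation carries a closed-form inverse; a bisection fallback on
log₁₀(c) (auto-expanded bracket, effect tolerance ~1e-9) exists for
registry extensions without one.

Mixture predictors, for components with fractions pᵢ on the basis of the
working unit:

- CA: ECₓ,mix = (Σ pᵢ / ECₓ,ᵢ)⁻¹ — defined only where every component can
  reach effect x.
- IA: E(c) = 1 − Π (1 − Fᵢ(pᵢ c)); its effective concentrations come from
  bracketed root finding on log₁₀(c). The supremum effect is
  1 − Π (1 − γᵢ); requests above it raise the same "unattainable" error
  that drives grid truncation. Scaled doses that underflow a curve's
  domain contribute zero effect, which is IA's known inability to
  accumulate sub-NOEC responses.
- GCA: the CA formula with the full inverse function. For slope-1
  Hill-type curves the reciprocal inverse 1/Fᵢ⁻¹(E) = (γᵢ − E)/(αᵢE) is
  linear and decreasing in E across the asymptote, so the mixture relation
  Σ pᵢ c / Fᵢ⁻¹(E) = 1 stays monotone and is solved by bisection on E
  (effect-at-concentration) or evaluated directly
  (concentration-at-effect). The extension is implemented exactly for the
  slope-1 Hill family (Hill_two; Hill_three/Hill_four with β = 1), which
  is the family GCA is formulated for; for any other partial-agonist curve
  the search is capped below that component's asymptote. A useful
  consequence, verified by a closed-form oracle in the tests: for slope-1
  Hill components E_mix(c) = Σ(γᵢcᵢ/αᵢ) / (1 + Σ cᵢ/αᵢ). Wherever every
  inverse is defined (below all asymptotes) GCA and CA solve the same
  equation and therefore coincide; published implementations that refit
  curves to a different family for GCA can show small CA–GCA gaps even
  below the asymptotes, which this package does not reproduce by design.
- Two-stage prediction: cluster components into MoA surrogates, apply the
  generalized CA form within each cluster g at its share P_g·c of the dose
  (internal fractions qᵢ = pᵢ/P_g), then IA across cluster effects. With
  one cluster this reduces exactly to CA; with all-singleton clusters, to
  IA (both covered by equivalence tests at 1e-6 relative).
- Simple CA: reciprocal weight/EC50 sum on summary endpoints. Weights are
  used exactly as entered: composition ranges from safety data sheets are
  often evaluated at their maxima and then sum to less than 1, and
  renormalizing would silently change the scenario.

## Structure pipeline

Descriptors are RDKit's standard 2-D set (~210 after dropping non-finite
and constant columns), standardized to zero mean and unit variance. This
is a deliberate open substitution for the much larger commercial descriptor
blocks used by server-side tools; cluster assignments are therefore not
expected to replicate any specific commercial pipeline, and the two-stage
acceptance checks are property-based (degenerate equivalences, interval
position logged) rather than numeric reproduction. PCA retains the fewest
components reaching 95% cumulative explained variance (configurable), with
a deterministic sign convention (largest-magnitude loading positive).
k-means uses a fixed default seed (20220525) and 25 restarts; labels are
renumbered by first occurrence so component order, not solver internals,
defines the numbering. k defaults to the silhouette maximizer over
2..min(n−1, 8), ties toward smaller k; a user-supplied k overrides.
Binary mixtures skip clustering: ECFP6 = Morgan circular fingerprints of
diameter 6 (radius 3), 2048 bits; Tanimoto similarity strictly greater
than 0.7 selects CA, otherwise IA (the threshold is a strict inequality).

## Units and composition basis

Conversions inside the molar (nM/µM/mM) or mass (µg/L, mg/L) family are
exact prefix arithmetic; crossing the boundary uses the component MW
(g/mol). Composition fractions are interpreted on the same basis as the
working unit — mole fractions for molar units, mass fractions for mass
units. `MixtureSpec.to_unit` converts the basis explicitly (and the
fraction-weighted mean MW links the two predictions: EC in mg/L equals EC
in µM × mean MW × 10⁻³), which the unit-invariance tests verify to 1e-9
relative.

## Fitting and confidence intervals

`fit_drc` is scipy `least_squares` (TRF, bounded) with five deterministic
starts derived from a linearized fit on the model's own link scale and
from data quantiles — no random restarts, so refits are bit-reproducible.
The parameter covariance (Gauss–Newton, residual-variance scaled) is
stored on the fitted curve. Confidence intervals on the effect grid are
parametric bootstrap: parameters resampled per component from that
covariance (or, for transcribed literature curves without one, from
independent normals with a 5% coefficient of variation), invalid draws
rejected, percentile 2.5/97.5 across draws under a caller-provided seed.
The interval method is this package's own choice; interval widths are
reported, never treated as reproduction targets.

## Predictable-range truncation

Mixtures containing low-efficacy components cannot be predicted at effect
levels above the smallest component asymptote. Rather than erroring, the
reporting grid's upper bound is lowered to the largest grid effect
strictly attainable by every component (default request 10–90% in decadal
steps); a mixture whose joint ceiling falls below the lowest requested
grid effect raises a "no predictable range" error. The packaged
partial-agonist fixture (asymptotes 0.62–0.75) truncates to 10–60%, and
per-model rows that remain unattainable (e.g. IA near its supremum) are
omitted rather than reported as failures.

## Packaged fixtures and the synthetic generator

- `cs2` (coating product) is fully specified by published SDS inputs
  (worst-case composition 0.75/0.05/0.05/0.05 summing to 0.90; EC50s
  11.5/1983/1000/9268 mg/L) and is the package's exact reproduction case:
  Simple CA gives 15.314 mg/L.
- `cs1` (23-pesticide mixture, µM) and `cs3` (three perfluorinated
  carboxylic acids, partial agonists) carry **synthetic stand-in**
  regression parameters, generated once under a fixed seed and frozen into
  the packaged CSVs, because the original supplementary parameter tables
  are not redistributable here. The stand-ins preserve the scientifically
  relevant structure — cs1: 23 curves spanning four model families,
  EC50s over ~3 decades, fractions summing to 1, real pesticide SMILES
  spanning recognizable chemical classes (triazines, phenylureas,
  organophosphates, carbamates, chloroacetanilides, dinitroanilines,
  phenoxy acids) so the descriptor pipeline has genuine MoA structure;
  cs3: slope-1 Hill_three curves with asymptotes 0.62/0.68/0.75 and
  half-asymptote concentrations 8/15/30 µM, equal molar fractions, chosen
  once so the predictable range truncates at 60% as low-efficacy PPARα
  agonist mixtures do. Absolute predictions on cs1/cs3 characterize the
  method, not the original laboratory mixtures, and the test suite marks
  the corresponding literature-value comparisons as such.
- `generate_synthetic_mixture` produces seeded mixtures with known
  generating curves (model family cycle, log-uniform EC50s in 0.1–100 µM,
  slopes 1–4, equal or Dirichlet fractions, optional partial-agonist share
  realized as slope-1 Hill_three with γ ∈ [0.3, 0.9)). It emulates the
  input side of real assessments — clean parametric curves — and not
  measurement noise, inter-laboratory variance, synergy or antagonism;
  green property tests therefore demonstrate correctness of the additivity
  arithmetic, not predictive accuracy on interacting real mixtures.

## Numerical choices and problem sizes

Root finding uses Brent's method at ~machine tolerance on effect;
inversion roundtrips hold to <1e-8 and unit roundtrips to machine
precision. Components with zero fraction are dropped with a warning;
duplicate CAS numbers are allowed but warned (sub-mixtures may repeat
chemicals). Degenerate concentration 0 is outside every model's domain.
The brute-force cross-checks use a 10⁵-point log-concentration grid and
2-component mixtures; fit-recovery checks use 12 noise-free points per
curve; bootstrap examples use 100–200 draws — sizes chosen so the whole
suite and the acceptance script each run in seconds on one core while
leaving the comparisons' tolerances (0.1% against the grid oracle, 1e-4
fit recovery) far above the solver noise floor.

## Known limitations

Monotone curves only (no hormesis), no time-resolved toxicity, no
Bayesian fitting, no synergy/antagonism modelling, no exposure assessment
or risk characterization. The QSAR stage assigns grouping only — toxicity
always comes from user-supplied curves, and no activity is predicted from
structure. The CLI is English-only and file-based.
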