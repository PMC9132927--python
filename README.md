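# mixtoxpred

Additive mixture-toxicity prediction from component dose–response data.

Regulatory mixture risk assessment (REACH-style screening of products that
are "compositions of at least two different substances") needs the toxicity
of a mixture long before anyone can test it: twenty chemicals already form
190 binary combinations and over a million mixtures of three or more.
`mixtoxpred` is a Python library (with a thin CLI) for risk assessors and
product developers that predicts a mixture's effective concentrations from
whatever is known about its components — full dose–response curves, bare
EC50/LC50 values from a safety data sheet, or molecular structures — using
five additivity models:

- **CA — concentration addition** (Loewe additivity), for similarly acting
  chemicals: the mixture concentration producing effect *x* solves
  Σᵢ pᵢ·c / ECₓ,ᵢ = 1, i.e. ECₓ,mix = (Σᵢ pᵢ / ECₓ,ᵢ)⁻¹, where pᵢ is the
  composition fraction and ECₓ,ᵢ the component's effective concentration.
- **IA — independent action** (Bliss independence, response addition), for
  dissimilarly acting chemicals: E(c) = 1 − Πᵢ (1 − Fᵢ(pᵢ·c)), with Fᵢ the
  component dose–response function. Inverted numerically for the effect
  grid; below a component's effective domain its factor is 1 (the NOEC
  behaviour of IA).
- **GCA — generalized concentration addition**, for mixtures containing
  partial agonists: CA's inverse is replaced by the full inverse regression
  function Fᵢ⁻¹(E), which for slope-1 Hill curves extends algebraically
  above the asymptote (c = αE/(γ−E), negative there), so effect levels CA
  cannot reach remain predictable.
- **QSAR-TSP — structure-based two-stage prediction**, for complex mixtures
  with mixed modes of action (MoA): 2-D molecular descriptors → PCA →
  k-means clusters as MoA surrogates, then CA within each cluster and IA
  across clusters. Binary mixtures use an ECFP6 (Morgan radius-3, 2048-bit)
  Tanimoto rule instead: similarity > 0.7 → CA, otherwise IA.
- **Simple CA**, when only summary EC50/LC50 endpoints exist: the CA
  reciprocal sum applied directly to the entered weights (not renormalized,
  so worst-case composition scenarios behave as entered).

Underneath sits a dose–response curve registry (Hill, Weibull, Logit
families in 2/3/4-parameter forms, Box–Cox–Weibull/Logit, generalized
logit) with closed-form inversion, least-squares fitting with deterministic
multi-start, conversion among nM/µM/mM/µg/L/mg/L, and automatic truncation
of the reporting grid to the effect range every component can actually
reach.

## Worked example

A coating product known only through its SDS — four solvents, worst-case
composition, Daphnia magna 48-h EC50s, no curves:

```bash
python examples/simple_ca_from_sds.py
```

```
coating product (SDS worst case): 4 components (mg/L basis)
  Toluene             75.0%   EC50 =     11.5 mg/L
  n-Butanol            5.0%   EC50 =   1983.0 mg/L
  2-Butoxyethanol      5.0%   EC50 =   1000.0 mg/L
  Ethyl alcohol        5.0%   EC50 =   9268.0 mg/L

Simple CA mixture EC50: 15.314 mg/L
```

The mixture EC50 (15.314 mg/L) is the reciprocal of the weight-over-EC50
sum; toluene, the most toxic and most abundant component, dominates it.
The other examples cover the full-curve models on a 23-component pesticide
mixture (`ca_ia_effect_grid.py`, `qsar_tsp_grouping.py`), partial agonists
and grid truncation (`gca_partial_agonists.py`), and the fit → predict →
report workflow with bootstrap confidence intervals
(`fit_report_workflow.py`).

From the shell, the same workflow is:

```bash
mixtoxpred --input mixture.csv --models ca --models ia --output report/
```

which writes `summary.txt`, `effect_grid.csv`/`.xlsx`, `report.json` and a
curve plot. Template columns are documented in `mixtoxpred/io.py`.

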