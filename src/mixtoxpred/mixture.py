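"""Additivity models for mixture toxicity: CA, IA, GCA and Simple CA.

All predictors operate on a :class:`MixtureSpec` whose component fractions
are interpreted on the same basis as the working concentration unit (molar
fractions for molar units, mass fractions for mass units).  Concentration
addition (CA, Loewe additivity) sums scaled reciprocal effective
concentrations; independent action (IA, Bliss independence) multiplies
non-responses at scaled doses; generalized concentration addition (GCA)
replaces CA's inverse with the full inverse regression function so that
partial agonists contribute (possibly negatively) above their asymptote;
Simple CA applies the CA formula directly to summary EC50/LC50 endpoints
when no curve information exists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .drc import (
    EffectRange,
    EffectUnattainableError,
    FittedDRC,
    effect_grid,
    inverse_drc,
    predictable_effect_range,
)
from .units import ConcentrationValue, convert, normalize_unit

__all__ = [
    "MixtureComponent",
    "MixtureSpec",
    "PredictionResult",
    "MODEL_NAMES",
    "ca_effective_concentration",
    "ia_effect",
    "ia_effective_concentration",
    "gca_effect",
    "gca_effective_concentration",
    "simple_ca_ec50",
    "predict_mixture",
    "lowest_predicted_ecx",
]

MODEL_NAMES = ("CA", "IA", "GCA", "TSP", "SimpleCA")


@dataclass(frozen=True)
class MixtureComponent:
    """One chemical in a product.

    ``fraction`` is the composition p_i on the basis of the spec's working
    unit.  A prediction needs at least one of ``endpoint_value`` (Simple CA)
    or ``drc`` (curve-based models); ``structure`` (SMILES text) is needed
    only by the QSAR two-stage path.
    """

    name: str
    fraction: float
    cas: str | None = None
    mw: float | None = None
    endpoint_value: ConcentrationValue | None = None
    drc: FittedDRC | None = None
    structure: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError(
                f"component {self.name!r}: fraction must be in (0, 1], got {self.fraction}"
            )


@dataclass(frozen=True)
class MixtureSpec:
    """An ordered mixture of >= 2 components with a common output unit."""

    components: tuple[MixtureComponent, ...]
    output_unit: str = "uM"
    endpoint_type: str = "EC50"
    product_name: str = "mixture"

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "output_unit", normalize_unit(self.output_unit))
        if len(self.components) < 2:
            raise ValueError("a mixture is at least two different substances")
        if self.endpoint_type not in ("EC50", "LC50"):
            raise ValueError(f"endpoint_type must be EC50 or LC50, got {self.endpoint_type}")
        seen: set[str] = set()
        for comp in self.components:
            if comp.cas and comp.cas in seen:
                warnings.warn(
                    f"duplicate CAS number {comp.cas} in mixture (sub-mixtures may repeat chemicals)",
                    stacklevel=2,
                )
            if comp.cas:
                seen.add(comp.cas)

    @property
    def drcs(self) -> tuple[FittedDRC, ...]:
        missing = [c.name for c in self.components if c.drc is None]
        if missing:
            raise ValueError(f"components without dose-response curves: {missing}")
        return tuple(c.drc for c in self.components)

    def mean_molecular_weight(self) -> float:
        """Fraction-weighted mean MW on the spec's own fraction basis."""
        if any(c.mw is None for c in self.components):
            raise ValueError("all components need a molecular weight")
        from .units import MOLAR_UNITS

        if self.output_unit in MOLAR_UNITS:
            return sum(c.fraction * c.mw for c in self.components) / sum(
                c.fraction for c in self.components
            )
        return sum(c.fraction for c in self.components) / sum(
            c.fraction / c.mw for c in self.components
        )

    def to_unit(self, unit: str) -> "MixtureSpec":
        """Re-express the spec in another unit, recomputing the fraction basis.

        Crossing molar<->mass converts fractions with component molecular
        weights (mole fractions <-> mass fractions) and renormalizes to the
        original total.
        """
        from .units import MOLAR_UNITS

        unit = normalize_unit(unit)
        src_molar = self.output_unit in MOLAR_UNITS
        dst_molar = unit in MOLAR_UNITS
        comps = list(self.components)
        if src_molar != dst_molar:
            if any(c.mw is None for c in comps):
                raise ValueError("molecular weights required to change fraction basis")
            total = sum(c.fraction for c in comps)
            raw = [c.fraction * c.mw if dst_molar is False else c.fraction / c.mw for c in comps]
            scale = total / sum(raw)
            comps = [replace(c, fraction=r * scale) for c, r in zip(comps, raw)]
        return replace(self, components=tuple(comps), output_unit=unit)


def _scaled_inverse(comp: MixtureComponent, effect: float, unit: str) -> float:
    """Component effective concentration at ``effect``, in ``unit``."""
    ec = inverse_drc(comp.drc, effect)
    return convert(ec, comp.drc.conc_unit, unit, comp.mw)


def _component_effect(comp: MixtureComponent, dose: float, unit: str) -> float:
    """Component fractional effect at a dose given in ``unit``.

    A scaled dose that underflows the curve's numerical domain contributes
    zero effect (IA's no-effect behaviour below the NOEC).
    """
    c = convert(dose, unit, comp.drc.conc_unit, comp.mw)
    if c <= 0 or not math.isfinite(c):
        return 0.0
    return comp.drc.effect(c)


def _active(components: Iterable[MixtureComponent]) -> tuple[MixtureComponent, ...]:
    out = []
    for comp in components:
        if comp.fraction == 0:
            warnings.warn(f"dropping component {comp.name!r} with zero fraction", stacklevel=3)
            continue
        out.append(comp)
    return tuple(out)


# ---------------------------------------------------------------------------
# Concentration addition

def ca_effective_concentration(
    components: Sequence[MixtureComponent], effect: float, unit: str = "uM"
) -> float:
    """CA mixture concentration producing ``effect``.

    Solves sum_i (p_i * c) / EC_{effect,i} = 1, i.e.
    c = 1 / sum_i (p_i / EC_{effect,i}), all in a common unit.
    """
    comps = _active(components)
    s = sum(comp.fraction / _scaled_inverse(comp, effect, unit) for comp in comps)
    return 1.0 / s


# ---------------------------------------------------------------------------
# Independent action

def ia_effect(
    components: Sequence[MixtureComponent], conc: float, unit: str = "uM"
) -> float:
    """IA mixture effect at total concentration ``conc``:
    1 - prod_i (1 - F_i(p_i * c))."""
    if not conc > 0:
        raise ValueError(f"concentration must be > 0, got {conc}")
    comps = _active(components)
    non_response = 1.0
    for comp in comps:
        non_response *= 1.0 - _component_effect(comp, comp.fraction * conc, unit)
    return 1.0 - non_response


def ia_effective_concentration(
    components: Sequence[MixtureComponent], effect: float, unit: str = "uM"
) -> float:
    """Numeric inversion of :func:`ia_effect` on log10(concentration)."""
    comps = _active(components)
    sup = 1.0 - math.prod(1.0 - c.drc.max_effect for c in comps)
    if effect >= sup:
        raise EffectUnattainableError(
            f"effect {effect:.4g} exceeds IA's supremum {sup:.4g} for this mixture"
        )
    if not 0 < effect < 1:
        raise ValueError(f"effect must be in (0, 1), got {effect}")
    f = lambda t: ia_effect(comps, 10.0**t, unit) - effect
    lo, hi = -9.0, 9.0
    for _ in range(40):
        if f(lo) <= 0:
            break
        lo -= 9.0
    for _ in range(40):
        if f(hi) >= 0:
            break
        hi += 9.0
    t = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=300)
    return float(10.0**t)


# ---------------------------------------------------------------------------
# Generalized concentration addition

def gca_effective_concentration(
    components: Sequence[MixtureComponent], effect: float, unit: str = "uM"
) -> float:
    """GCA mixture concentration at ``effect``: like CA but with the
    inverse-function extension, so partial agonists enter with negative
    reciprocal terms above their asymptote.

    Raises when the reciprocal sum is non-positive (effect beyond what the
    mixture can reach at any finite concentration).
    """
    comps = _active(components)
    s = 0.0
    for comp in comps:
        r = comp.drc.inverse_reciprocal_extended(effect)  # 1/EC, unit of the curve
        # convert reciprocal concentration: 1/c in curve unit -> 1/c in target
        if r != 0.0:
            r = 1.0 / convert(1.0 / r, comp.drc.conc_unit, unit, comp.mw)
        s += comp.fraction * r
    if s <= 0:
        raise EffectUnattainableError(
            f"effect {effect:.4g} is not reachable by GCA for this mixture "
            "(non-positive reciprocal concentration sum)"
        )
    return 1.0 / s


def gca_effect(
    components: Sequence[MixtureComponent], conc: float, unit: str = "uM"
) -> float:
    """GCA mixture effect at ``conc``: the E solving
    sum_i (p_i * c) / f_i^{-1}(E) = 1, found by monotone bisection on E."""
    if not conc > 0:
        raise ValueError(f"concentration must be > 0, got {conc}")
    comps = _active(components)
    # E is searchable up to 1 for extended (slope-1 Hill) components, but
    # must stay below the asymptote of any component without an extension
    e_hi = 1.0 - 1e-12
    for comp in comps:
        m = comp.drc.model
        extended = m.inverse_extended is not None and (
            m.inverse_extended(comp.drc.params, comp.drc.max_effect / 2.0) is not None
        )
        if not extended:
            e_hi = min(e_hi, comp.drc.max_effect - 1e-12)

    def g(e: float) -> float:
        try:
            return conc / gca_effective_concentration(comps, e, unit) - 1.0
        except EffectUnattainableError:
            return -1.0  # reciprocal sum <= 0: treat as effect too high

    lo = 1e-12
    if g(lo) < 0:
        return 0.0
    if g(e_hi) > 0:
        raise EffectUnattainableError(
            f"no GCA effect solution below {e_hi:.4g} at concentration {conc:.4g} {unit}"
        )
    e = brentq(g, lo, e_hi, xtol=1e-13, rtol=8.9e-16, maxiter=300)
    return float(e)


# ---------------------------------------------------------------------------
# Simple CA on summary endpoints

def simple_ca_ec50(
    weights: Sequence[float],
    ec50s: Sequence[ConcentrationValue],
    unit: str = "mg/L",
    mws: Sequence[float | None] | None = None,
) -> ConcentrationValue:
    """Mixture EC50 from summary endpoints: (sum_i w_i / EC50_i)^-1.

    Weights are used exactly as entered and are NOT renormalized — a
    worst-case composition scenario may sum to less than 1.
    """
    if len(weights) != len(ec50s):
        raise ValueError("weights and ec50s must have the same length")
    if mws is None:
        mws = [None] * len(weights)
    s = 0.0
    for w, ec, mw in zip(weights, ec50s, mws):
        if not 0 < w <= 1:
            raise ValueError(f"weights must be in (0, 1], got {w}")
        v = ec.to(unit, mw).value
        if not v > 0:
            raise ValueError(f"EC50 values must be > 0, got {ec}")
        s += w / v
    return ConcentrationValue(1.0 / s, unit)


# ---------------------------------------------------------------------------
# Orchestration

@dataclass(frozen=True)
class PredictionResult:
    """One model's effect grid of effective concentrations.

    ``effect_percent`` and ``concentrations`` align; Simple CA yields a
    single 50% row and no curve.  ``lowest_ecx`` (minimum effective
    concentration at the reference effect across all models selected in the
    same run) is attached by :func:`predict_mixture`.
    """

    model: str
    unit: str
    effect_percent: tuple[float, ...]
    concentrations: tuple[float, ...]
    ci_low: tuple[float, ...] | None = None
    ci_high: tuple[float, ...] | None = None
    lowest_ecx: float | None = None
    reference_effect_percent: float = 50.0
    note: str = ""

    @property
    def ecx_at_reference(self) -> float | None:
        for e, c in zip(self.effect_percent, self.concentrations):
            if abs(e - self.reference_effect_percent) < 1e-9:
                return c
        return None


def _grid_concentrations(
    model: str,
    spec: MixtureSpec,
    grid: np.ndarray,
    clustering=None,
) -> list[float]:
    comps = spec.components
    unit = spec.output_unit
    out = []
    for e in grid:
        if model == "CA":
            out.append(ca_effective_concentration(comps, e, unit))
        elif model == "IA":
            out.append(ia_effective_concentration(comps, e, unit))
        elif model == "GCA":
            out.append(gca_effective_concentration(comps, e, unit))
        elif model == "TSP":
            from .qsar import tsp_effective_concentration

            out.append(tsp_effective_concentration(spec, clustering, e))
        else:  # pragma: no cover
            raise ValueError(model)
    return out


def _bootstrap_ci(
    model: str,
    spec: MixtureSpec,
    grid: np.ndarray,
    n: int,
    seed: int | None,
    clustering=None,
    rel_sd: float = 0.05,
):
    """Percentile CI from parametric resampling of DRC parameters.

    Parameters are drawn from the fitted covariance when a curve carries
    one, otherwise from independent normals with a 5% coefficient of
    variation; draws producing invalid curves are rejected.
    """
    rng = np.random.default_rng(seed)
    draws = np.full((n, len(grid)), np.nan)
    for b in range(n):
        comps = []
        for comp in spec.components:
            d = comp.drc
            for _ in range(50):
                if d.param_cov is not None:
                    p = rng.multivariate_normal(d.params, np.asarray(d.param_cov))
                else:
                    p = np.asarray(d.params) * (1.0 + rel_sd * rng.standard_normal(len(d.params)))
                try:
                    newd = FittedDRC(d.model_id, tuple(p), d.conc_unit)
                    break
                except ValueError:
                    continue
            else:
                newd = d
            comps.append(replace(comp, drc=newd))
        bspec = replace(spec, components=tuple(comps))
        for j, e in enumerate(grid):
            try:
                draws[b, j] = _grid_concentrations(model, bspec, np.array([e]), clustering)[0]
            except (EffectUnattainableError, ValueError):
                pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(draws, 2.5, axis=0)
        hi = np.nanpercentile(draws, 97.5, axis=0)
    return tuple(float(v) for v in lo), tuple(float(v) for v in hi)


def predict_mixture(
    spec: MixtureSpec,
    models: Sequence[str] = ("CA", "IA"),
    requested: EffectRange = EffectRange(0.10, 0.90),
    grid_step: float = 0.10,
    bootstrap_n: int = 0,
    seed: int | None = None,
    clustering=None,
) -> list[PredictionResult]:
    """Run the selected additivity models over the effect grid.

    Each model's grid is truncated to the predictable range; a model whose
    required inputs are missing yields a result carrying an error note while
    the other models are still computed.  The minimum effective
    concentration at the reference effect (50% when attainable, else the
    highest attainable grid effect) across the selected models is attached
    to every result as ``lowest_ecx``.
    """
    models = list(dict.fromkeys(models))
    bad = [m for m in models if m not in MODEL_NAMES]
    if bad:
        raise ValueError(f"unknown models {bad}; choose from {MODEL_NAMES}")
    if not models:
        raise ValueError("select at least one prediction model")

    results: list[PredictionResult] = []
    curve_models = [m for m in models if m != "SimpleCA"]

    ref_pct = 50.0
    rng_all: EffectRange | None = None
    if curve_models:
        try:
            rng_all = predictable_effect_range(spec.drcs, requested, grid_step)
            ref = 0.5 if rng_all.lo <= 0.5 <= rng_all.hi else rng_all.hi
            ref_pct = round(ref * 100.0, 6)
        except ValueError:
            rng_all = None

    for m in models:
        if m == "SimpleCA":
            try:
                weights = [c.fraction for c in spec.components]
                ecs = []
                for c in spec.components:
                    if c.endpoint_value is None:
                        raise ValueError(
                            f"component {c.name!r} has no {spec.endpoint_type} endpoint value"
                        )
                    ecs.append(c.endpoint_value)
                ec = simple_ca_ec50(weights, ecs, spec.output_unit,
                                    [c.mw for c in spec.components])
                results.append(PredictionResult(
                    "SimpleCA", spec.output_unit, (50.0,), (ec.value,),
                    note="scalar EC50 only; no mixture curve"))
            except (ValueError, KeyError) as err:
                results.append(PredictionResult(
                    "SimpleCA", spec.output_unit, (), (), note=f"input error: {err}"))
            continue

        try:
            drcs = spec.drcs
            if m == "TSP" and clustering is None:
                raise ValueError("TSP requires a structure-based clustering")
            if rng_all is None:
                raise ValueError("no predictable effect range for this mixture")
            grid = effect_grid(rng_all, grid_step)
            # IA/GCA may not reach the top of the CA-attainable grid
            concs: list[float] = []
            kept: list[float] = []
            for e in grid:
                try:
                    concs.append(_grid_concentrations(m, spec, np.array([e]), clustering)[0])
                    kept.append(float(e))
                except EffectUnattainableError:
                    continue
            pct = tuple(round(e * 100.0, 6) for e in kept)
            ci_lo = ci_hi = None
            if bootstrap_n > 0:
                ci_lo, ci_hi = _bootstrap_ci(m, spec, np.array(kept), bootstrap_n,
                                             seed, clustering)
            results.append(PredictionResult(
                m, spec.output_unit, pct, tuple(concs), ci_lo, ci_hi,
                reference_effect_percent=ref_pct))
        except (ValueError, KeyError) as err:
            results.append(PredictionResult(
                m, spec.output_unit, (), (), note=f"input error: {err}"))

    lowest = lowest_predicted_ecx(results)
    return [replace(r, lowest_ecx=lowest) for r in results]


def lowest_predicted_ecx(results: Sequence[PredictionResult]) -> float | None:
    """Minimum effective concentration at each result's reference effect
    (Simple CA contributes its scalar EC50)."""
    vals = []
    for r in results:
        if r.model == "SimpleCA" and r.concentrations:
            vals.append(r.concentrations[0])
        else:
            v = r.ecx_at_reference
            if v is not None:
                vals.append(v)
    return min(vals) if vals else None
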