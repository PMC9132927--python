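"""Dose-response curve (DRC) model registry, evaluation and inversion.

Every registered model maps a strictly positive concentration ``c`` (in the
curve's own unit) onto a fractional effect in [0, 1] and is monotone
non-decreasing in ``c``.  Parameters follow the mixtox naming convention:
``alpha`` (location/intercept), ``beta`` (slope, > 0), ``gamma`` (upper
asymptote for the *_three models, shape for Box-Cox and generalized-logit
models) and, for the *_four models, ``delta`` (lower asymptote).

All models carry a closed-form inverse; a bracketed bisection on
log10(concentration) is kept as a fallback for registry extensions that do
not (tolerance 1e-9 on effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .units import normalize_unit

__all__ = [
    "DRCModel",
    "FittedDRC",
    "EffectRange",
    "MODEL_REGISTRY",
    "RegistryError",
    "EffectUnattainableError",
    "NoPredictableRangeError",
    "evaluate_drc",
    "inverse_drc",
    "predictable_effect_range",
]

_EFFECT_TOL = 1e-9


class RegistryError(KeyError):
    """Unknown DRC model id."""


class EffectUnattainableError(ValueError):
    """Requested effect at or above the curve's maximal attainable effect.

    This error drives predictable-range truncation: grid effects that raise
    it are omitted from reports rather than reported as failures.
    """


class NoPredictableRangeError(ValueError):
    """No requested grid effect is attainable by every component."""


def _logit(e: float) -> float:
    return math.log(e / (1.0 - e))


def _cloglog(e: float) -> float:
    # inverse of the Weibull link 1 - exp(-exp(x))
    return math.log(-math.log(1.0 - e))


def _boxcox(c: float, g: float) -> float:
    return math.log(c) if g == 0 else (c**g - 1.0) / g


def _inv_boxcox(u: float, g: float) -> float:
    if g == 0:
        return math.exp(u)
    base = g * u + 1.0
    if base <= 0:
        raise EffectUnattainableError("Box-Cox inverse outside the concentration domain")
    return base ** (1.0 / g)


@dataclass(frozen=True)
class DRCModel:
    """A registry entry: forward curve, closed-form inverse, asymptotes."""

    model_id: str
    n_params: int
    forward: Callable[[Sequence[float], float], float]
    inverse: Callable[[Sequence[float], float], float] | None
    max_effect: Callable[[Sequence[float]], float]
    min_effect: Callable[[Sequence[float]], float]
    validate: Callable[[Sequence[float]], None]
    # real-valued algebraic continuation of the inverse above the asymptote
    # (only slope-1 Hill-type models define one); used by GCA
    inverse_extended: Callable[[Sequence[float], float], float] | None = None


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _val_slope(p: Sequence[float]) -> None:
    _require(p[1] > 0, f"slope beta must be > 0, got {p[1]}")


def _val_hill(p: Sequence[float]) -> None:
    _require(p[0] > 0, f"Hill location alpha must be > 0, got {p[0]}")
    _require(p[1] > 0, f"slope beta must be > 0, got {p[1]}")


def _val_gamma(p: Sequence[float]) -> None:
    _require(0 < p[2] <= 1, f"upper asymptote gamma must be in (0, 1], got {p[2]}")


def _val_delta(p: Sequence[float]) -> None:
    _require(0 <= p[3] < p[2], f"lower asymptote delta must be in [0, gamma), got {p[3]}")


MODEL_REGISTRY: dict[str, DRCModel] = {}


def _register(model: DRCModel) -> None:
    MODEL_REGISTRY[model.model_id] = model


# ---- Hill family: E = gamma / (1 + (alpha/c)^beta) -------------------------

def _hill_fwd(p, c, lo=0.0, hi=1.0, beta=None):
    a = p[0]
    b = p[1] if beta is None else beta
    return lo + (hi - lo) / (1.0 + (a / c) ** b)


def _hill_inv(p, e, lo=0.0, hi=1.0, beta=None):
    a = p[0]
    b = p[1] if beta is None else beta
    f = (e - lo) / (hi - lo)
    return a * (1.0 / f - 1.0) ** (-1.0 / b)


_register(DRCModel(
    "Hill", 2,
    forward=lambda p, c: _hill_fwd(p, c),
    inverse=lambda p, e: _hill_inv(p, e),
    max_effect=lambda p: 1.0,
    min_effect=lambda p: 0.0,
    validate=_val_hill,
))

# slope-1 two-parameter Hill: E = beta * c / (alpha + c); max effect beta
_register(DRCModel(
    "Hill_two", 2,
    forward=lambda p, c: p[1] * c / (p[0] + c),
    inverse=lambda p, e: p[0] * e / (p[1] - e),
    max_effect=lambda p: p[1],
    min_effect=lambda p: 0.0,
    validate=lambda p: (_require(p[0] > 0, "alpha must be > 0"),
                        _require(0 < p[1] <= 1, "max effect beta must be in (0, 1]")),
    inverse_extended=lambda p, e: p[0] * e / (p[1] - e),
))

_register(DRCModel(
    "Hill_three", 3,
    forward=lambda p, c: _hill_fwd(p, c, hi=p[2]),
    inverse=lambda p, e: _hill_inv(p, e, hi=p[2]),
    max_effect=lambda p: p[2],
    min_effect=lambda p: 0.0,
    validate=lambda p: (_val_hill(p), _val_gamma(p)),
    inverse_extended=lambda p, e: (p[0] * e / (p[2] - e)) if p[1] == 1 else None,
))

_register(DRCModel(
    "Hill_four", 4,
    forward=lambda p, c: _hill_fwd(p, c, lo=p[3], hi=p[2]),
    inverse=lambda p, e: _hill_inv(p, e, lo=p[3], hi=p[2]),
    max_effect=lambda p: p[2],
    min_effect=lambda p: p[3],
    validate=lambda p: (_val_hill(p), _val_gamma(p), _val_delta(p)),
))


# ---- Weibull family: E = 1 - exp(-exp(alpha + beta*log10 c)) ---------------

def _weib_fwd(p, c, lo=0.0, hi=1.0):
    x = p[0] + p[1] * math.log10(c)
    # exp(x) overflows harmlessly toward effect hi
    return lo + (hi - lo) * (-math.expm1(-math.exp(min(x, 700.0))))


def _weib_inv(p, e, lo=0.0, hi=1.0):
    f = (e - lo) / (hi - lo)
    return 10.0 ** ((_cloglog(f) - p[0]) / p[1])


_register(DRCModel(
    "Weibull", 2,
    forward=lambda p, c: _weib_fwd(p, c),
    inverse=lambda p, e: _weib_inv(p, e),
    max_effect=lambda p: 1.0,
    min_effect=lambda p: 0.0,
    validate=_val_slope,
))

_register(DRCModel(
    "Weibull_three", 3,
    forward=lambda p, c: _weib_fwd(p, c, hi=p[2]),
    inverse=lambda p, e: _weib_inv(p, e, hi=p[2]),
    max_effect=lambda p: p[2],
    min_effect=lambda p: 0.0,
    validate=lambda p: (_val_slope(p), _val_gamma(p)),
))

_register(DRCModel(
    "Weibull_four", 4,
    forward=lambda p, c: _weib_fwd(p, c, lo=p[3], hi=p[2]),
    inverse=lambda p, e: _weib_inv(p, e, lo=p[3], hi=p[2]),
    max_effect=lambda p: p[2],
    min_effect=lambda p: p[3],
    validate=lambda p: (_val_slope(p), _val_gamma(p), _val_delta(p)),
))


# ---- Logit family: E = 1 / (1 + exp(-alpha - beta*log10 c)) ----------------

def _logit_fwd(p, c, lo=0.0, hi=1.0):
    x = p[0] + p[1] * math.log10(c)
    if x >= 0:
        f = 1.0 / (1.0 + math.exp(-x))
    else:
        z = math.exp(x)
        f = z / (1.0 + z)
    return lo + (hi - lo) * f


def _logit_inv(p, e, lo=0.0, hi=1.0):
    f = (e - lo) / (hi - lo)
    return 10.0 ** ((_logit(f) - p[0]) / p[1])


_register(DRCModel(
    "Logit", 2,
    forward=lambda p, c: _logit_fwd(p, c),
    inverse=lambda p, e: _logit_inv(p, e),
    max_effect=lambda p: 1.0,
    min_effect=lambda p: 0.0,
    validate=_val_slope,
))

_register(DRCModel(
    "Logit_three", 3,
    forward=lambda p, c: _logit_fwd(p, c, hi=p[2]),
    inverse=lambda p, e: _logit_inv(p, e, hi=p[2]),
    max_effect=lambda p: p[2],
    min_effect=lambda p: 0.0,
    validate=lambda p: (_val_slope(p), _val_gamma(p)),
))

_register(DRCModel(
    "Logit_four", 4,
    forward=lambda p, c: _logit_fwd(p, c, lo=p[3], hi=p[2]),
    inverse=lambda p, e: _logit_inv(p, e, lo=p[3], hi=p[2]),
    max_effect=lambda p: p[2],
    min_effect=lambda p: p[3],
    validate=lambda p: (_val_slope(p), _val_gamma(p), _val_delta(p)),
))


# ---- Box-Cox transformed links and generalized logit -----------------------

_register(DRCModel(
    "BCW", 3,
    forward=lambda p, c: -math.expm1(-math.exp(min(p[0] + p[1] * _boxcox(c, p[2]), 700.0))),
    inverse=lambda p, e: _inv_boxcox((_cloglog(e) - p[0]) / p[1], p[2]),
    max_effect=lambda p: 1.0,
    min_effect=lambda p: 0.0,
    validate=lambda p: (_val_slope(p), _require(p[2] > 0, "Box-Cox exponent gamma must be > 0")),
))

_register(DRCModel(
    "BCL", 3,
    forward=lambda p, c: 1.0 / (1.0 + math.exp(-min(max(p[0] + p[1] * _boxcox(c, p[2]), -700.0), 700.0))),
    inverse=lambda p, e: _inv_boxcox((_logit(e) - p[0]) / p[1], p[2]),
    max_effect=lambda p: 1.0,
    min_effect=lambda p: 0.0,
    validate=lambda p: (_val_slope(p), _require(p[2] > 0, "Box-Cox exponent gamma must be > 0")),
))

# generalized logit: E = (1 + exp(-alpha - beta*log10 c))^(-gamma)
_register(DRCModel(
    "GL", 3,
    forward=lambda p, c: (1.0 + math.exp(-min(max(p[0] + p[1] * math.log10(c), -700.0), 700.0))) ** (-p[2]),
    inverse=lambda p, e: 10.0 ** ((-p[0] - math.log(e ** (-1.0 / p[2]) - 1.0)) / p[1]),
    max_effect=lambda p: 1.0,
    min_effect=lambda p: 0.0,
    validate=lambda p: (_val_slope(p), _require(p[2] > 0, "shape gamma must be > 0")),
))


def get_model(model_id: str) -> DRCModel:
    try:
        return MODEL_REGISTRY[model_id]
    except KeyError:
        raise RegistryError(
            f"unknown DRC model {model_id!r}; registered: {sorted(MODEL_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class FittedDRC:
    """A fitted dose-response regression bound to a concentration unit.

    ``params`` are serialized in (alpha, beta, gamma, delta) order with
    trailing parameters omitted for lower-arity models.  ``param_cov`` and
    ``rss`` are populated by :func:`mixtoxpred.fitting.fit_drc` and feed the
    parametric bootstrap; transcribed literature curves leave them ``None``.
    """

    model_id: str
    params: tuple[float, ...]
    conc_unit: str = "uM"
    param_cov: tuple[tuple[float, ...], ...] | None = None
    rss: float | None = None

    def __post_init__(self) -> None:
        model = get_model(self.model_id)
        params = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", params)
        object.__setattr__(self, "conc_unit", normalize_unit(self.conc_unit))
        if len(params) != model.n_params:
            raise ValueError(
                f"{self.model_id} takes {model.n_params} parameters, got {len(params)}"
            )
        model.validate(params)

    @property
    def model(self) -> DRCModel:
        return get_model(self.model_id)

    @property
    def max_effect(self) -> float:
        return self.model.max_effect(self.params)

    @property
    def min_effect(self) -> float:
        return self.model.min_effect(self.params)

    def effect(self, conc: float) -> float:
        return evaluate_drc(self, conc)

    def inverse(self, effect: float) -> float:
        return inverse_drc(self, effect)

    def inverse_reciprocal_extended(self, effect: float) -> float:
        """1 / inverse(effect) with the algebraic continuation above the
        asymptote where the model family defines one (slope-1 Hill-type).

        The reciprocal is the natural GCA quantity: for slope-1 Hill curves
        it is linear and strictly decreasing in effect across the asymptote
        (zero at effect == gamma, negative above), which keeps the GCA
        mixture equation monotone.
        """
        model = self.model
        if model.inverse_extended is not None:
            if abs(effect - self.max_effect) < 1e-15:
                return 0.0
            c = model.inverse_extended(self.params, effect)
            if c is not None:
                return 1.0 / c
        if effect >= self.max_effect - _EFFECT_TOL:
            raise EffectUnattainableError(
                f"effect {effect:.4g} is at or above the maximal attainable "
                f"effect {self.max_effect:.4g} of {self.model_id} and the model "
                "defines no inverse extension"
            )
        return 1.0 / inverse_drc(self, effect)


def evaluate_drc(drc: FittedDRC, conc: float) -> float:
    """Fractional effect of ``drc`` at a strictly positive concentration."""
    if not conc > 0:
        raise ValueError(f"concentration must be > 0, got {conc}")
    e = drc.model.forward(drc.params, float(conc))
    # clip numerical noise at the asymptotes
    return min(max(e, 0.0), drc.max_effect)


def inverse_drc(drc: FittedDRC, effect: float) -> float:
    """Concentration (in ``drc.conc_unit``) producing a fractional effect.

    Uses the registered closed-form inverse; falls back to bisection on
    log10(concentration) for registry extensions without one.
    """
    if not effect > 0:
        raise ValueError(f"effect must be > 0, got {effect}")
    if effect <= drc.min_effect:
        raise ValueError(
            f"effect {effect:.4g} is at or below the lower asymptote "
            f"{drc.min_effect:.4g} of {drc.model_id}"
        )
    if effect >= drc.max_effect:
        raise EffectUnattainableError(
            f"effect {effect:.4g} unattainable: maximal attainable effect of "
            f"{drc.model_id}{drc.params} is {drc.max_effect:.4g}"
        )
    model = drc.model
    if model.inverse is not None:
        return float(model.inverse(drc.params, float(effect)))
    return _numeric_inverse(drc, float(effect))


def _numeric_inverse(drc: FittedDRC, effect: float) -> float:
    """Bisection on log10(c), bracket auto-expanded from the curve midpoint."""
    f = lambda t: evaluate_drc(drc, 10.0**t) - effect
    lo, hi = -6.0, 6.0
    for _ in range(60):
        if f(lo) <= 0:
            break
        lo -= 6.0
    for _ in range(60):
        if f(hi) >= 0:
            break
        hi += 6.0
    t = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    return float(10.0**t)


@dataclass(frozen=True)
class EffectRange:
    """A fractional effect window 0 < lo < hi <= 1."""

    lo: float = 0.10
    hi: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi <= 1):
            raise ValueError(f"need 0 < lo < hi <= 1, got ({self.lo}, {self.hi})")


def predictable_effect_range(
    drcs: Sequence[FittedDRC],
    requested: EffectRange = EffectRange(0.10, 0.90),
    grid_step: float = 0.10,
) -> EffectRange:
    """Truncate the requested effect window to what every curve can invert.

    Mixtures containing low-toxicity (partial-agonist) components cannot be
    predicted at effect levels above the smallest component asymptote; the
    upper bound is lowered to the largest grid effect strictly attainable by
    every component, so those grid rows are omitted rather than failing.
    """
    if not drcs:
        raise ValueError("need at least one dose-response curve")
    attainable_sup = min(d.max_effect for d in drcs)
    # largest grid multiple strictly below the joint asymptote
    n_steps = math.floor((attainable_sup - 1e-12) / grid_step)
    hi = min(requested.hi, round(n_steps * grid_step, 12))
    if hi < requested.lo:
        raise NoPredictableRangeError(
            f"no grid effect in [{requested.lo}, {requested.hi}] is attainable "
            f"by all components (joint maximal effect {attainable_sup:.4g})"
        )
    return EffectRange(requested.lo, hi)


def effect_grid(rng: EffectRange, step: float = 0.10) -> np.ndarray:
    """Decadal (by default) fractional-effect grid spanning ``rng``."""
    n = int(round((rng.hi - rng.lo) / step))
    return np.round(rng.lo + step * np.arange(n + 1), 12)
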