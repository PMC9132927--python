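"""Packaged case-study inputs and a seeded synthetic-mixture generator.

Three case-study fixtures mirror the situations the package addresses:

``cs1``
    A 23-pesticide mixture with per-component dose-response curves and
    real pesticide structures, worked in uM.  The regression parameters
    and composition are a synthetic stand-in generated once under a fixed
    seed (the originating study's supplementary parameter table is not
    redistributable), so absolute predictions are illustrative; the
    structures are the real molecules, exercising the full QSAR path.
``cs2``
    A four-component coating product known only through its safety data
    sheet: composition ranges and Daphnia magna 48-h EC50s in mg/L, no
    curves.  Values are the published worst-case (maximum composition)
    inputs, so only Simple CA applies.
``cs3``
    Three perfluorinated carboxylic acids acting as partial agonists
    (PPARalpha-style low-efficacy curves), slope-1 Hill-three with
    sub-maximal asymptotes — synthetic stand-in parameters chosen so the
    predictable effect range truncates at 60%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .drc import FittedDRC
from .mixture import MixtureComponent, MixtureSpec
from .units import ConcentrationValue

__all__ = [
    "case_study_fixture",
    "SyntheticMixtureConfig",
    "generate_synthetic_mixture",
    "enumerate_mixture_count",
]

_CS2_ROWS = (
    # substance, CAS, MW g/mol, worst-case mass fraction, EC50 mg/L (48 h, D. magna)
    ("Toluene", "108-88-3", 92.140, 0.75, 11.5),
    ("n-Butanol", "71-36-3", 74.120, 0.05, 1983.0),
    ("2-Butoxyethanol", "111-76-2", 118.170, 0.05, 1000.0),
    ("Ethyl alcohol", "64-17-5", 46.070, 0.05, 9268.0),
)


def _data_path(name: str) -> Path:
    return Path(resources.files("mixtoxpred.data") / name)


def case_study_fixture(fixture_id: str) -> MixtureSpec:
    """Load one of the packaged case-study mixtures (``cs1``/``cs2``/``cs3``).

    ``cs1`` comes back with component SMILES already attached; ``cs2`` is a
    worst-case SDS spec (endpoint values only, weights summing to 0.90 —
    deliberately not renormalized); ``cs3`` carries partial-agonist curves.
    """
    from .io import attach_structures, read_mixture_table

    if fixture_id == "cs2":
        comps = tuple(
            MixtureComponent(
                name=name, cas=cas, fraction=frac, mw=mw,
                endpoint_value=ConcentrationValue(ec50, "mg/L"),
            )
            for name, cas, mw, frac, ec50 in _CS2_ROWS
        )
        return MixtureSpec(comps, output_unit="mg/L", endpoint_type="EC50",
                           product_name="coating product (SDS worst case)")
    if fixture_id == "cs1":
        spec, _ = read_mixture_table(_data_path("cs1_synthetic_components.csv"))
        return attach_structures(spec, _data_path("cs1_synthetic_structures.smi"))
    if fixture_id == "cs3":
        spec, _ = read_mixture_table(_data_path("cs3_synthetic_components.csv"))
        return spec
    raise ValueError(f"unknown fixture id {fixture_id!r}; expected cs1, cs2 or cs3")


@dataclass(frozen=True)
class SyntheticMixtureConfig:
    """Ground-truth controlled generator settings.

    ``partial_agonist_fraction`` is the share of components given a
    sub-maximal asymptote (gamma drawn in [0.3, 0.9)), which exercises
    predictable-range truncation and the GCA extension.
    """

    n_components: int = 4
    models: tuple[str, ...] = ("Logit", "Weibull", "Hill", "Hill_three")
    ec50_range: tuple[float, float] = (0.1, 100.0)
    slope_range: tuple[float, float] = (1.0, 4.0)
    fraction_scheme: str = "equal"  # or "random-dirichlet"
    partial_agonist_fraction: float = 0.0
    unit: str = "uM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ValueError("a mixture needs at least 2 components")
        if self.fraction_scheme not in ("equal", "random-dirichlet"):
            raise ValueError(f"unknown fraction scheme {self.fraction_scheme!r}")
        if not 0 <= self.partial_agonist_fraction <= 1:
            raise ValueError("partial_agonist_fraction must be in [0, 1]")


def generate_synthetic_mixture(config: SyntheticMixtureConfig) -> MixtureSpec:
    """Reproducible random mixture with known generating curves.

    Partial agonists are realized as slope-1 Hill_three curves (the family
    whose inverse extension GCA uses); full agonists cycle through the
    configured model families.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_components
    if config.fraction_scheme == "equal":
        fracs = np.full(n, 1.0 / n)
    else:
        fracs = rng.dirichlet(np.full(n, 4.0))
    n_partial = int(round(config.partial_agonist_fraction * n))
    partial_idx = set(rng.choice(n, size=n_partial, replace=False).tolist())

    lo, hi = config.ec50_range
    comps = []
    for i in range(n):
        ec50 = float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))
        beta = float(rng.uniform(*config.slope_range))
        if i in partial_idx:
            gamma = float(rng.uniform(0.3, 0.9))
            drc = FittedDRC("Hill_three", (ec50, 1.0, gamma), config.unit)
        else:
            model = config.models[i % len(config.models)]
            if model == "Logit":
                drc = FittedDRC("Logit", (-beta * math.log10(ec50), beta), config.unit)
            elif model == "Weibull":
                alpha = math.log(math.log(2.0)) - beta * math.log10(ec50)
                drc = FittedDRC("Weibull", (alpha, beta), config.unit)
            elif model == "Hill":
                drc = FittedDRC("Hill", (ec50, beta), config.unit)
            elif model == "Hill_three":
                drc = FittedDRC("Hill_three", (ec50, beta, 1.0), config.unit)
            else:
                raise ValueError(f"unsupported generator model {model!r}")
        comps.append(MixtureComponent(
            name=f"synthetic-{i + 1}", cas=f"0-{i + 1:02d}-S",
            fraction=float(fracs[i]), mw=float(rng.uniform(80, 400)), drc=drc,
        ))
    return MixtureSpec(tuple(comps), output_unit=config.unit,
                       product_name=f"synthetic mixture (seed {config.seed})")


def enumerate_mixture_count(n_chemicals: int, size: int | tuple[int, int]) -> int:
    """Number of distinct mixtures of ``size`` components (or a size range,
    inclusive) drawable from ``n_chemicals``; exact binomial arithmetic."""
    if n_chemicals < 1:
        raise ValueError("need at least one chemical")
    if isinstance(size, tuple):
        lo, hi = size
    else:
        lo = hi = size
    if not 1 <= lo <= hi <= n_chemicals:
        raise ValueError(f"size range must satisfy 1 <= lo <= hi <= {n_chemicals}")
    return sum(math.comb(n_chemicals, k) for k in range(lo, hi + 1))
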