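"""Additivity models: CA, IA, GCA, Simple CA and the orchestrator.

The brute-force cross-checks deliberately re-derive curves from raw
formulas written out in this file (not via the package's registry) so the
two routes stay independent.
"""

import math
from dataclasses import replace

import numpy as np
import pytest

from mixtoxpred import (
    ConcentrationValue,
    EffectRange,
    EffectUnattainableError,
    FittedDRC,
    MixtureComponent,
    MixtureSpec,
    ca_effective_concentration,
    gca_effect,
    gca_effective_concentration,
    ia_effect,
    ia_effective_concentration,
    lowest_predicted_ecx,
    predict_mixture,
    simple_ca_ec50,
)


def _comp(name, fraction, drc, mw=None, cas=None):
    return MixtureComponent(name, fraction, cas=cas, mw=mw, drc=drc)


class TestConcentrationAddition:
    def test_single_component_identity(self):
        drc = FittedDRC("Logit", (0.3, 2.0))
        comps = [_comp("A", 1.0, drc)]
        assert ca_effective_concentration(comps, 0.5) == pytest.approx(
            drc.inverse(0.5), rel=1e-12)

    def test_sham_additivity_two_copies(self):
        """A chemical mixed with itself predicts its own curve (CA exactly)."""
        drc = FittedDRC("Weibull", (0.5, 1.5))
        comps = [_comp("A", 0.5, drc), _comp("A'", 0.5, drc)]
        for e in np.arange(0.1, 0.95, 0.1):
            assert ca_effective_concentration(comps, e) == pytest.approx(
                drc.inverse(e), rel=1e-10)

    def test_sham_additivity_many_unequal_fractions(self):
        drc = FittedDRC("Hill", (2.0, 1.7))
        fr = [0.1, 0.2, 0.3, 0.4]
        comps = [_comp(f"c{i}", f, drc) for i, f in enumerate(fr)]
        for e in (0.2, 0.5, 0.8):
            assert ca_effective_concentration(comps, e) == pytest.approx(
                drc.inverse(e), rel=1e-10)

    def test_unattainable_effect_propagates(self, partial_trio):
        with pytest.raises(EffectUnattainableError):
            ca_effective_concentration(partial_trio.components, 0.7)


class TestIndependentAction:
    def test_single_component_is_own_curve(self):
        drc = FittedDRC("Logit", (0.3, 2.0))
        comps = [_comp("A", 1.0, drc)]
        for c in (0.1, 1.0, 10.0):
            assert ia_effect(comps, c) == pytest.approx(drc.effect(c), rel=1e-12)

    def test_bliss_product_formula(self):
        """Two components each at effect 0.3 combine to 1 - 0.7^2 = 0.51."""
        drc1 = FittedDRC("Logit", (0.0, 2.0))
        drc2 = FittedDRC("Hill", (5.0, 1.3))
        c1 = drc1.inverse(0.3)
        c2 = drc2.inverse(0.3)
        # choose fractions and total conc so each scaled dose hits its EC30
        total = c1 + c2
        comps = [_comp("A", c1 / total, drc1), _comp("B", c2 / total, drc2)]
        assert ia_effect(comps, total) == pytest.approx(1 - 0.7**2, rel=1e-10)

    def test_inversion_roundtrip(self, logit_pair):
        for e in (0.15, 0.5, 0.85):
            c = ia_effective_concentration(logit_pair.components, e)
            assert ia_effect(logit_pair.components, c) == pytest.approx(e, abs=1e-9)

    def test_supremum_guard(self, partial_trio):
        sup = 1 - (1 - 0.55) * (1 - 0.7) * (1 - 0.8)
        with pytest.raises(EffectUnattainableError):
            ia_effective_concentration(partial_trio.components, sup + 0.01)


class TestGeneralizedConcentrationAddition:
    def test_coincides_with_ca_for_full_agonists(self, logit_pair):
        """CA == GCA at every grid effect when every inverse exists."""
        for e in np.arange(0.1, 0.95, 0.1):
            ca = ca_effective_concentration(logit_pair.components, e)
            gca = gca_effective_concentration(logit_pair.components, e)
            assert abs(gca / ca - 1) < 1e-6

    def test_sham_additivity(self):
        drc = FittedDRC("Hill_three", (4.0, 1.0, 0.7))
        comps = [_comp("A", 0.3, drc), _comp("A'", 0.7, drc)]
        for e in (0.1, 0.3, 0.6):
            assert gca_effective_concentration(comps, e) == pytest.approx(
                drc.inverse(e), rel=1e-10)

    def test_hill_slope_one_closed_form(self):
        """Independent oracle: for slope-1 Hill partial agonists
        E_mix(c) = sum(gamma_i c_i / K_i) / (1 + sum(c_i / K_i))."""
        K = [5.0, 12.0]
        G = [0.55, 0.8]
        fr = [0.35, 0.65]
        comps = [_comp(f"H{i}", fr[i], FittedDRC("Hill_three", (K[i], 1.0, G[i])))
                 for i in range(2)]
        for c in (0.5, 3.0, 20.0, 200.0):
            ci = [f * c for f in fr]
            expected = sum(g * x / k for g, x, k in zip(G, ci, K)) / (
                1 + sum(x / k for x, k in zip(ci, K)))
            assert gca_effect(comps, c) == pytest.approx(expected, abs=1e-9)

    def test_reaches_above_smallest_asymptote(self, partial_trio):
        """GCA extends beyond CA's ceiling (the smallest component
        asymptote) because extended inverses go negative above it."""
        c = gca_effective_concentration(partial_trio.components, 0.60)
        assert c > 0
        assert gca_effect(partial_trio.components, c) == pytest.approx(0.60, abs=1e-9)
        with pytest.raises(EffectUnattainableError):
            ca_effective_concentration(partial_trio.components, 0.60)

    def test_effect_concentration_roundtrip(self, partial_trio):
        for e in (0.1, 0.4, 0.6):
            c = gca_effective_concentration(partial_trio.components, e)
            assert gca_effect(partial_trio.components, c) == pytest.approx(e, abs=1e-9)

    def test_unreachable_effect_raises(self, partial_trio):
        # weighted asymptote ceiling for this trio is below 0.9
        with pytest.raises(EffectUnattainableError):
            gca_effective_concentration(partial_trio.components, 0.9)


class TestBruteForceOracle:
    """Two-component CA/IA versus direct evaluation of raw curve formulas
    on a 1e5-point log-concentration grid."""

    GRID = np.logspace(-5, 4, 100_000)

    def test_ca_against_grid_search(self):
        # raw formulas, written independently of the registry
        f1 = lambda c: 1 / (1 + np.exp(-(0.5 + 2.0 * np.log10(c))))    # Logit
        f2 = lambda c: 1 / (1 + (3.0 / c) ** 1.5)                       # Hill
        comps = [_comp("A", 0.4, FittedDRC("Logit", (0.5, 2.0))),
                 _comp("B", 0.6, FittedDRC("Hill", (3.0, 1.5)))]
        e1 = f1(self.GRID)
        e2 = f2(self.GRID)
        for target in (0.1, 0.5, 0.9):
            # oracle inversion by interpolation on the dense grid
            ec1 = np.interp(target, e1, self.GRID)
            ec2 = np.interp(target, e2, self.GRID)
            oracle = 1.0 / (0.4 / ec1 + 0.6 / ec2)
            pred = ca_effective_concentration(comps, target)
            assert abs(pred / oracle - 1) < 1e-3

    def test_ia_against_grid_search(self):
        f1 = lambda c: 1 / (1 + np.exp(-(0.5 + 2.0 * np.log10(c))))
        f2 = lambda c: 1 / (1 + (3.0 / c) ** 1.5)
        comps = [_comp("A", 0.4, FittedDRC("Logit", (0.5, 2.0))),
                 _comp("B", 0.6, FittedDRC("Hill", (3.0, 1.5)))]
        mix = 1 - (1 - f1(0.4 * self.GRID)) * (1 - f2(0.6 * self.GRID))
        for target in (0.1, 0.5, 0.9):
            oracle = np.interp(target, mix, self.GRID)
            pred = ia_effective_concentration(comps, target)
            assert abs(pred / oracle - 1) < 1e-3


class TestSimpleCA:
    def test_sds_worst_case(self):
        """Four-component coating product at maximum composition values;
        weights sum to 0.90 and are used exactly as entered."""
        ec = simple_ca_ec50(
            [0.75, 0.05, 0.05, 0.05],
            [ConcentrationValue(v, "mg/L") for v in (11.5, 1983.0, 1000.0, 9268.0)],
            "mg/L",
        )
        assert ec.value == pytest.approx(15.314, abs=1e-3)

    def test_sham_additivity(self):
        ec = simple_ca_ec50([0.5, 0.5],
                            [ConcentrationValue(10.0, "mg/L")] * 2, "mg/L")
        assert ec.value == pytest.approx(10.0, rel=1e-12)

    def test_single_weight_not_renormalized(self):
        ec = simple_ca_ec50([0.9], [ConcentrationValue(9.0, "mg/L")], "mg/L")
        assert ec.value == pytest.approx(10.0, rel=1e-12)

    def test_unit_mixing_with_mw(self):
        ec = simple_ca_ec50(
            [0.5, 0.5],
            [ConcentrationValue(10.0, "uM"), ConcentrationValue(1.0, "mg/L")],
            "uM", mws=[None, 100.0],
        )
        assert ec.value == pytest.approx(1 / (0.05 + 0.05), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simple_ca_ec50([1.5], [ConcentrationValue(1.0, "uM")], "uM")
        with pytest.raises(ValueError):
            simple_ca_ec50([0.5], [ConcentrationValue(1.0, "uM")] * 2, "uM")


class TestPredictMixture:
    def test_grid_tables_and_ordering(self, logit_pair):
        results = predict_mixture(logit_pair, ["CA", "IA"])
        assert [r.model for r in results] == ["CA", "IA"]
        for r in results:
            assert r.effect_percent[0] == 10.0 and r.effect_percent[-1] == 90.0
            assert len(r.effect_percent) == 9
            diffs = np.diff(r.concentrations)
            assert np.all(diffs > 0), "effective concentrations must increase with effect"

    def test_empty_selection_rejected(self, logit_pair):
        with pytest.raises(ValueError):
            predict_mixture(logit_pair, [])
        with pytest.raises(ValueError):
            predict_mixture(logit_pair, ["XX"])

    def test_per_model_input_error_does_not_block_others(self):
        comps = (
            MixtureComponent("A", 0.5, endpoint_value=ConcentrationValue(10, "mg/L")),
            MixtureComponent("B", 0.5, endpoint_value=ConcentrationValue(20, "mg/L")),
        )
        spec = MixtureSpec(comps, output_unit="mg/L")
        results = predict_mixture(spec, ["CA", "SimpleCA"])
        by_model = {r.model: r for r in results}
        assert by_model["CA"].note.startswith("input error")
        assert by_model["SimpleCA"].concentrations[0] == pytest.approx(
            1 / (0.5 / 10 + 0.5 / 20))

    def test_lowest_ecx_is_minimum_at_reference(self, logit_pair):
        results = predict_mixture(logit_pair, ["CA", "IA"])
        at50 = [r.ecx_at_reference for r in results]
        assert results[0].lowest_ecx == pytest.approx(min(at50))
        assert lowest_predicted_ecx(results) == results[0].lowest_ecx

    def test_partial_agonist_grid_truncation(self, partial_trio):
        results = predict_mixture(partial_trio, ["CA", "GCA", "IA"])
        by_model = {r.model: r for r in results}
        # CA stops below the smallest asymptote (0.55 -> grid hi 50%)
        assert by_model["CA"].effect_percent[-1] == 50.0
        assert by_model["GCA"].effect_percent[-1] == 50.0
        # reference effect stays at 50% since it is attainable
        assert by_model["CA"].reference_effect_percent == 50.0

    def test_bootstrap_ci_brackets_estimate(self, logit_pair):
        results = predict_mixture(logit_pair, ["CA"], bootstrap_n=60, seed=7)
        (r,) = results
        assert r.ci_low is not None and r.ci_high is not None
        for lo, v, hi in zip(r.ci_low, r.concentrations, r.ci_high):
            assert lo <= v <= hi

    def test_bootstrap_is_seed_reproducible(self, logit_pair):
        a = predict_mixture(logit_pair, ["CA"], bootstrap_n=30, seed=11)[0]
        b = predict_mixture(logit_pair, ["CA"], bootstrap_n=30, seed=11)[0]
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high


class TestUnitInvariance:
    def test_predicting_in_molar_equals_mass_route(self):
        """CA predicted in uM, converted to mg/L with the mixture's mean
        molecular weight, matches a direct mg/L prediction with converted
        mass fractions."""
        drc_a = FittedDRC("Logit", (0.5, 2.0), "uM")
        drc_b = FittedDRC("Hill", (3.0, 1.5), "uM")
        spec = MixtureSpec(
            (
                _comp("A", 0.4, drc_a, mw=100.0, cas="1-1"),
                _comp("B", 0.6, drc_b, mw=250.0, cas="2-2"),
            ),
            output_unit="uM",
        )
        mass_spec = spec.to_unit("mg/L")
        assert sum(c.fraction for c in mass_spec.components) == pytest.approx(1.0)
        for e in (0.2, 0.5, 0.8):
            c_molar = ca_effective_concentration(spec.components, e, "uM")
            c_mass = ca_effective_concentration(mass_spec.components, e, "mg/L")
            mw_mix = spec.mean_molecular_weight()
            assert c_mass == pytest.approx(c_molar * mw_mix * 1e-3, rel=1e-9)

    def test_fraction_basis_roundtrip(self):
        spec = MixtureSpec(
            (
                _comp("A", 0.4, FittedDRC("Logit", (0.5, 2.0), "uM"), mw=100.0, cas="1-1"),
                _comp("B", 0.6, FittedDRC("Hill", (3.0, 1.5), "uM"), mw=250.0, cas="2-2"),
            ),
            output_unit="uM",
        )
        back = spec.to_unit("mg/L").to_unit("uM")
        for c0, c1 in zip(spec.components, back.components):
            assert c1.fraction == pytest.approx(c0.fraction, rel=1e-12)


def test_zero_fraction_component_dropped_with_warning():
    drc = FittedDRC("Logit", (0.3, 2.0))
    good = _comp("A", 1.0, drc)
    bad = MixtureComponent.__new__(MixtureComponent)  # bypass validation
    object.__setattr__(bad, "name", "Z")
    object.__setattr__(bad, "fraction", 0.0)
    object.__setattr__(bad, "cas", None)
    object.__setattr__(bad, "mw", None)
    object.__setattr__(bad, "endpoint_value", None)
    object.__setattr__(bad, "drc", drc)
    object.__setattr__(bad, "structure", None)
    with pytest.warns(UserWarning, match="zero fraction"):
        c = ca_effective_concentration([good, bad], 0.5)
    assert c == pytest.approx(drc.inverse(0.5), rel=1e-12)


def test_duplicate_cas_warns():
    drc = FittedDRC("Logit", (0.3, 2.0))
    with pytest.warns(UserWarning, match="duplicate CAS"):
        MixtureSpec((_comp("A", 0.5, drc, cas="1-1"), _comp("B", 0.5, drc, cas="1-1")))
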