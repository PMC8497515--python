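"""Substrate characterization: stoichiometry, heating value and BMP models."""

import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from codigest import (
    CompositionError,
    UltimateAnalysis,
    ValidationError,
    bmp_buswell,
    bmp_forgacs,
    buswell_stoichiometry,
    characterize,
    empirical_formula,
    hhv_dulong,
    mixture_bmp,
    synergy_index,
    thod,
    validate_ultimate_analysis,
)
from codigest.bmp import BMPConstants, DEFAULT_CONSTANTS, EmpiricalFormula

CH2O = UltimateAnalysis(
    name="carbohydrate", ts=1.0, vs_of_ts=1.0,
    c=12 / 30, h=2 / 30, n=0.0, s=0.0, o=16 / 30,
)
METHANE = UltimateAnalysis(
    name="methane", ts=1.0, vs_of_ts=1.0, c=12 / 16, h=4 / 16, n=0.0, s=0.0, o=0.0
)


def compositions():
    """Random feasible organic compositions (mass fractions of TS)."""
    return st.builds(
        dict,
        c=st.floats(0.10, 0.55),
        h=st.floats(0.02, 0.10),
        n=st.floats(0.0, 0.06),
        s=st.floats(1e-4, 0.03),
        o=st.floats(0.05, 0.55),
        vs=st.floats(0.4, 1.0),
    ).filter(lambda d: d["c"] + d["h"] + d["n"] + d["s"] + d["o"] <= 1.0)


def _ua(d, name="random"):
    return UltimateAnalysis(
        name=name, ts=0.2, vs_of_ts=d["vs"],
        c=d["c"], h=d["h"], n=d["n"], s=d["s"], o=d["o"],
    )


class TestValidation:
    def test_cow_row_accepted_with_consistent_elemental_sum(self):
        ua = validate_ultimate_analysis(
            dict(name="cow", ts_pct=14.5, vs_pct_ts=88.7, c_pct=25.7,
                 h_pct=3.8, n_pct=4.9, s_pct=0.2, o_pct=54.0)
        )
        assert ua.ts == pytest.approx(0.145)
        assert ua.elemental_sum == pytest.approx(0.886)
        # elemental sum matches the volatile-solids fraction to ~0.1%
        assert abs(ua.elemental_sum - ua.vs_of_ts) < 0.005

    @pytest.mark.parametrize(
        "row, message",
        [
            (dict(ts_pct=14.5, vs_pct_ts=88.7, c_pct=-1.0, h_pct=3.8,
                  n_pct=4.9, s_pct=0.2, o_pct=54.0), "c"),
            (dict(ts_pct=14.5, vs_pct_ts=88.7, c_pct=60.0, h_pct=10.0,
                  n_pct=0.0, s_pct=0.0, o_pct=40.0), "sum"),
            (dict(ts_pct=14.5, vs_pct_ts=0.0, c_pct=25.7, h_pct=3.8,
                  n_pct=4.9, s_pct=0.2, o_pct=54.0), "vs_of_ts"),
            (dict(ts_pct=14.5, vs_pct_ts=88.7, c_pct=0.0, h_pct=0.0,
                  n_pct=0.0, s_pct=0.0, o_pct=0.0), "zero"),
        ],
        ids=["negative-element", "mass-balance", "zero-vs", "all-zero"],
    )
    def test_invalid_rows_rejected(self, row, message):
        with pytest.raises(ValidationError, match=message):
            validate_ultimate_analysis({"name": "bad", **row})


class TestEmpiricalFormula:
    def test_cow_means_give_integer_subscripts(self, manures):
        f = empirical_formula(manures["cow"], integer=True)
        assert (f.a_c, f.b_h, f.c_o, f.d_n, f.e_s) == (343, 608, 540, 56, 1)
        assert f.normalized_to == "S"
        assert str(f) == "C343H608O540N56S"

    def test_sulfur_free_normalizes_to_carbon_with_warning(self):
        with pytest.warns(UserWarning, match="sulfur-free"):
            f = empirical_formula(CH2O)
        assert f.normalized_to == "C"
        assert f.a_c == pytest.approx(1.0)
        assert f.b_h == pytest.approx(2.0, rel=1e-9)
        assert f.c_o == pytest.approx(1.0, rel=1e-9)

    def test_doubling_sulfur_halves_all_subscripts(self, manures):
        cow = manures["cow"]
        doubled = UltimateAnalysis(
            name="cow2s", ts=cow.ts, vs_of_ts=cow.vs_of_ts,
            c=cow.c, h=cow.h, n=cow.n, s=2 * cow.s, o=cow.o,
        )
        f1, f2 = empirical_formula(cow), empirical_formula(doubled)
        for attr in ("a_c", "b_h", "c_o", "d_n"):
            assert getattr(f2, attr) == pytest.approx(getattr(f1, attr) / 2)
        assert f2.e_s == 1.0


class TestBuswellStoichiometry:
    def test_carbohydrate_gives_equimolar_methane_and_co2(self):
        coeff = buswell_stoichiometry(EmpiricalFormula(1, 2, 1, 0, 0, "C"))
        assert coeff.ch4 == pytest.approx(0.5)
        assert coeff.co2 == pytest.approx(0.5)
        assert coeff.water == pytest.approx(0.0)

    def test_methane_formula_is_fixed_point(self):
        coeff = buswell_stoichiometry(EmpiricalFormula(1, 4, 0, 0, 0, "C"))
        assert coeff.ch4 == pytest.approx(1.0)
        assert coeff.co2 == pytest.approx(0.0)
        # H balance forces zero water: b + 2*water = 4*ch4
        assert coeff.water == pytest.approx(0.0)

    def test_atom_conservation_on_random_formulas(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a = rng.uniform(0.5, 500)
            b = rng.uniform(0.5, 1000)
            c = rng.uniform(0.0, 600)
            d = rng.uniform(0.0, 60)
            e = rng.uniform(0.0, 5)
            f = EmpiricalFormula(a, b, c, d, e, "S")
            try:
                x = buswell_stoichiometry(f)
            except CompositionError:
                continue
            # independent oracle: count each element on both reaction sides
            assert math.isclose(a, x.ch4 + x.co2, rel_tol=0, abs_tol=1e-9)
            assert math.isclose(
                b + 2 * x.water, 4 * x.ch4 + 3 * x.nh3 + 2 * x.h2s, abs_tol=1e-9
            )
            assert math.isclose(c + x.water, 2 * x.co2, abs_tol=1e-9)
            assert math.isclose(d, x.nh3, abs_tol=0)
            assert math.isclose(e, x.h2s, abs_tol=0)

    def test_over_oxidized_composition_rejected(self):
        with pytest.raises(CompositionError, match="too oxidized"):
            buswell_stoichiometry(EmpiricalFormula(1.0, 0.5, 3.0, 0.0, 0.0, "C"))


class TestThODAndHHV:
    def test_textbook_anchors(self):
        assert thod(METHANE) == pytest.approx(4.00, abs=0.01)
        assert thod(CH2O) == pytest.approx(1.07, abs=0.01)

    def test_fully_oxidized_rejected(self):
        co2_like = UltimateAnalysis(
            name="co2", ts=1.0, vs_of_ts=1.0, c=0.26, h=0.0, n=0.0, s=0.001, o=0.72
        )
        with pytest.raises(CompositionError, match="oxidized"):
            thod(co2_like)

    def test_non_combustible_rejected(self):
        wet_ash = UltimateAnalysis(
            name="ash", ts=1.0, vs_of_ts=1.0, c=0.01, h=0.0, n=0.0, s=0.0, o=0.6
        )
        with pytest.raises(CompositionError, match="non-combustible"):
            hhv_dulong(wet_ash)

    @given(compositions())
    def test_thod_strictly_increases_with_carbon(self, d):
        assume(d["c"] + 0.05 + d["h"] + d["n"] + d["s"] + d["o"] <= 1.0)
        low, high = _ua(d), _ua({**d, "c": d["c"] + 0.05})
        try:
            t_low = thod(low)
        except CompositionError:
            assume(False)
        assert thod(high) > t_low
        assert bmp_buswell(high) > bmp_buswell(low)
        assert bmp_forgacs(high) > bmp_forgacs(low)


class TestBMPModels:
    def test_carbohydrate_buswell_yield(self):
        # 0.5 mol CH4 per 30 g of CH2O = 22400 * 0.5/30 mL/g
        assert bmp_buswell(CH2O) == pytest.approx(22400 * 0.5 / 30, rel=1e-9)

    def test_unit_cod_gives_350(self):
        ua = CH2O
        assert bmp_forgacs(ua) == pytest.approx(350.0 * thod(ua), rel=1e-12)

    def test_unit_hhv_ratio(self):
        from codigest.bmp import bmp_dulong_from_hhv

        assert bmp_dulong_from_hhv(37.78) == pytest.approx(1.0)

    @given(compositions())
    def test_mass_fraction_shortcut_equals_molar_route(self, d):
        """Two independent code paths: the per-gram mass-fraction form and the
        empirical-formula + stoichiometry + molar-mass route must agree."""
        ua = _ua(d)
        try:
            direct = bmp_buswell(ua)
        except CompositionError:
            assume(False)
        f = empirical_formula(ua)
        coeff = buswell_stoichiometry(f)
        moles_formula_per_g_ts = (ua.c / 12.0) / f.a_c
        via_formula = (
            DEFAULT_CONSTANTS.molar_volume * coeff.ch4 * moles_formula_per_g_ts / ua.vs_of_ts
        )
        assert direct == pytest.approx(via_formula, rel=1e-9)

    def test_characterize_is_deterministic(self, manures):
        r1, r2 = characterize(manures["pig"]), characterize(manures["pig"])
        assert r1 == r2

    def test_constants_are_overridable(self, manures):
        doubled = BMPConstants(molar_volume=44_800.0)
        assert bmp_buswell(manures["cow"], doubled) == pytest.approx(
            2 * bmp_buswell(manures["cow"]), rel=1e-12
        )

    def test_constants_must_be_positive(self):
        with pytest.raises(ValidationError):
            BMPConstants(cod_to_ch4=0.0)


class TestMixtureAndSynergy:
    def test_equal_mix_is_mean(self):
        assert mixture_bmp([(100.0, 0.5), (200.0, 0.5)]) == pytest.approx(150.0)

    def test_single_component_identity(self):
        assert mixture_bmp([(123.4, 1.0)]) == pytest.approx(123.4)

    def test_cow_horse_equal_mix(self, manures):
        mix = mixture_bmp(
            [(bmp_buswell(manures["cow"]), 0.5), (bmp_buswell(manures["horse"]), 0.5)]
        )
        assert mix == pytest.approx(197.3, abs=0.5)

    @pytest.mark.parametrize(
        "components",
        [[], [(100.0, -0.5), (200.0, 1.5)], [(100.0, 0.3), (200.0, 0.3)]],
        ids=["empty", "negative-share", "shares-not-normalized"],
    )
    def test_invalid_mixtures_rejected(self, components):
        with pytest.raises(ValidationError):
            mixture_bmp(components)

    @given(
        st.lists(
            st.tuples(st.floats(1.0, 500.0), st.floats(0.01, 1.0)),
            min_size=1,
            max_size=6,
        )
    )
    def test_mixture_within_component_range_and_permutation_invariant(self, raw):
        import warnings

        total = sum(s for _, s in raw)
        comps = [(b, s / total) for b, s in raw]
        warnings.simplefilter("ignore", UserWarning)  # float-dust renormalization
        mix = mixture_bmp(comps)
        bmps = [b for b, _ in comps]
        assert min(bmps) - 1e-9 <= mix <= max(bmps) + 1e-9
        assert mixture_bmp(list(reversed(comps))) == pytest.approx(mix, rel=1e-12)

    @pytest.mark.parametrize(
        "observed, expected, value", [(150, 150, 1.0), (180, 150, 1.2), (120, 150, 0.8)]
    )
    def test_synergy_index_arithmetic(self, observed, expected, value):
        assert synergy_index(observed, expected) == pytest.approx(value)

    def test_synergy_requires_positive_expectation(self):
        with pytest.raises(ValidationError):
            synergy_index(150.0, 0.0)
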