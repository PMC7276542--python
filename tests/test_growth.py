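"""Energy-coupled growth law: dynamic stoichiometry, yield and rate."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermocomm as tc
from thermocomm.constants import R_KJ
from thermocomm.growth import CONCENTRATION_FLOOR, pathway_specific_rate

T = 310.15


class TestLambdaCat:
    def test_lactate_sulfate_standard_conditions(self):
        # printed energetics of the sulfate-respiring pathway
        assert tc.lambda_cat(-228.2, 18.11, -170.17) == pytest.approx(1.447, abs=1e-3)

    def test_hydrogenotrophic_standard_conditions(self):
        assert tc.lambda_cat(-876.4, -64.73, -48.12) == pytest.approx(16.87, abs=5e-3)

    def test_degenerate_when_all_energy_stored(self):
        assert tc.lambda_cat(-100.0, -100.0, -50.0) == 0.0

    def test_requires_exergonic_catabolism(self):
        with pytest.raises(ValueError, match="F_T"):
            tc.lambda_cat(-100.0, 18.0, 5.0)


class TestGrowthYield:
    def test_reciprocal_of_total_draw(self):
        assert tc.growth_yield(1.447, 0.35) == pytest.approx(1 / 1.797, abs=1e-4)

    def test_pure_catabolic_draw(self):
        assert tc.growth_yield(1.0, 0.0) == 1.0

    def test_strictly_decreasing_in_lambda(self):
        ys = [tc.growth_yield(lam, 0.35) for lam in (0.5, 1.0, 2.0, 10.0)]
        assert all(a > b for a, b in zip(ys, ys[1:]))

    def test_nonpositive_draw_rejected(self):
        with pytest.raises(ValueError):
            tc.growth_yield(-0.5, 0.2)


class TestKineticFactor:
    def test_half_saturation(self):
        assert tc.kinetic_factor({"S": 1e-3}, {"S": 1e-3}) == 0.5

    def test_saturating_limit(self):
        assert tc.kinetic_factor({"S": 10.0}, {"S": 1e-6}) == pytest.approx(1.0, abs=1e-6)

    def test_two_substrates_multiply(self):
        f = tc.kinetic_factor({"S": 1e-3, "R": 2e-4}, {"S": 1e-3, "R": 2e-4})
        assert f == pytest.approx(0.25)

    def test_missing_substrate_concentration(self):
        with pytest.raises(tc.ConfigurationError, match="'S'"):
            tc.kinetic_factor({}, {"S": 1e-3})


class TestThermodynamicFactor:
    def test_exactly_zero_at_threshold(self):
        assert tc.thermodynamic_factor(-30.0, -30.0, T) == 0.0

    def test_half_at_rt_ln2_below_threshold(self):
        dg = -30.0 - R_KJ * T * math.log(2.0)
        assert tc.thermodynamic_factor(dg, -30.0, T) == pytest.approx(0.5)

    def test_zero_above_threshold(self):
        assert tc.thermodynamic_factor(-20.0, -30.0, T) == 0.0

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(dg=st.floats(-500.0, 100.0), dgmin=st.floats(-80.0, -1.0))
    def test_bounded_on_half_open_interval(self, dg, dgmin):
        f = tc.thermodynamic_factor(dg, dgmin, T)
        assert 0.0 <= f <= 1.0
        # the bound is strict wherever 1 - F_T is representable in doubles
        if (dg - dgmin) / (R_KJ * T) > -34.0:
            assert f < 1.0


def _toy_system(dgf_b=-200.0, dgmet=-100.0, v_max=0.3, dgmin=-30.0, gamma=0.45):
    comp = tc.ElementComposition.parse("C1")
    species = {
        "A": tc.ChemSpecies("A", composition=comp, dgf=0.0),
        "B": tc.ChemSpecies("B", composition=comp, dgf=dgf_b),
        "X": tc.ChemSpecies(
            "X",
            composition=tc.ElementComposition.parse("C1H1.8O0.5N0.2"),
            dgf=-10.0,
            fixed_activity=1.0,
        ),
    }
    pathway = tc.CatabolicPathway(
        name="cat",
        reaction=tc.Reaction({"A": -1.0, "B": 1.0}, reference="A"),
        v_max=v_max,
        k_s={"A": 1e-3},
        dg_min=dgmin,
        dg_met=dgmet,
    )
    anabolic = tc.AnabolicReaction(
        reaction=tc.Reaction({"A": -gamma, "X": 1.0}, reference="X"),
        biomass="X",
        electron_donor="A",
    )
    pop = tc.Population(
        name="toy", biomass_species="X", pathways=(pathway,), anabolic=anabolic
    )
    return species, pop


class TestPathwaySpecificRate:
    def test_zero_substrate_means_zero_rate(self):
        species, pop = _toy_system()
        st_ = pathway_specific_rate(
            pop.pathways[0], pop.anabolic, species, {"A": 0.0, "B": 1.0}, 7.0, T
        )
        assert st_.rate == 0.0

    def test_shut_down_at_unfavorable_energy(self):
        # an endergonic conversion: no rate regardless of substrate level
        species, pop = _toy_system(dgf_b=50.0)
        st_ = pathway_specific_rate(
            pop.pathways[0], pop.anabolic, species, {"A": 1.0, "B": 1.0}, 7.0, T
        )
        assert st_.f_t == 0.0
        assert st_.rate == 0.0
        assert st_.lambda_cat is None

    def test_rate_never_exceeds_v_max(self):
        species, pop = _toy_system()
        st_ = pathway_specific_rate(
            pop.pathways[0], pop.anabolic, species, {"A": 100.0, "B": 1e-9}, 7.0, T
        )
        assert 0.0 < st_.rate <= pop.pathways[0].v_max

    def test_forward_kinetics_variant_ignores_f_t(self):
        species, pop = _toy_system(dgf_b=-20.0, dgmin=-50.0)
        on = pathway_specific_rate(
            pop.pathways[0], pop.anabolic, species, {"A": 1.0, "B": 1.0}, 7.0, T
        )
        off = pathway_specific_rate(
            pop.pathways[0], pop.anabolic, species, {"A": 1.0, "B": 1.0}, 7.0, T,
            thermodynamics=False,
        )
        assert on.rate == 0.0  # -20 is above the -50 threshold
        assert off.f_t == 1.0 and off.rate > 0.0
        assert off.lambda_cat is not None  # dG_cat < 0 still couples growth


class TestCommunityDerivatives:
    def test_zero_biomass_is_stationary(self):
        species, pop = _toy_system()
        d_chem, d_bio, _ = tc.community_derivatives(
            {"toy": (pop, 0.0)}, species, {"A": 1.0, "B": 1.0}, 7.0, T
        )
        assert all(v == 0.0 for v in d_chem.values())
        assert d_bio["toy"] == 0.0

    def test_reduces_to_monod_growth_at_saturation(self):
        # strongly exergonic, saturating substrate: dX/X -> v_max/lambda - k_d
        species, pop = _toy_system()
        conc = {"A": 1.0, "B": 1.0}
        x = 1e-3
        d_chem, d_bio, states = tc.community_derivatives(
            {"toy": (pop, x)}, species, conc, 7.0, T
        )
        st_ = states[("toy", "cat")]
        assert st_.f_t == pytest.approx(1.0, abs=1e-10)
        lam = tc.lambda_cat(-100.0, st_.dg_an, st_.dg_cat)
        f_d = 1.0 / (1.0 + 1e-3)
        expected = x * (pop.pathways[0].v_max * f_d / lam - pop.k_d)
        assert d_bio["toy"] == pytest.approx(expected, rel=1e-12)

    def test_matches_hand_expanded_two_population_oracle(self):
        # two populations on a shared substrate; oracle is the fully
        # hand-expanded algebra of the rate law and coupling
        species, pop1 = _toy_system()
        _, pop2 = _toy_system(dgmet=-150.0, v_max=0.1, gamma=0.2)
        conc = {"A": 0.01, "B": 0.3}
        x1, x2 = 2e-3, 5e-4
        d_chem, d_bio, _ = tc.community_derivatives(
            {"p1": (pop1, x1), "p2": (pop2, x2)}, species, conc, 7.0, T
        )

        def oracle(pop, x):
            a, b = conc["A"], conc["B"]
            dg_cat = -200.0 + R_KJ * T * math.log(b / a)
            dg_an = -10.0 - pop.anabolic.gamma_d * 0.0 + R_KJ * T * math.log(
                a ** (-pop.anabolic.gamma_d)
            )
            f_d = a / (1e-3 + a)
            f_t = 1.0 - math.exp(min(0.0, dg_cat + 30.0) / (R_KJ * T))
            r = pop.pathways[0].v_max * f_d * f_t
            lam = (pop.pathways[0].dg_met - dg_an) / dg_cat
            da = x * (r * -1.0 + (r / lam) * -pop.anabolic.gamma_d)
            db = x * r
            dx = x * (r / lam - pop.k_d)
            return da, db, dx

        da1, db1, dx1 = oracle(pop1, x1)
        da2, db2, dx2 = oracle(pop2, x2)
        assert d_chem["A"] == pytest.approx(da1 + da2, rel=1e-12)
        assert d_chem["B"] == pytest.approx(db1 + db2, rel=1e-12)
        assert d_bio["p1"] == pytest.approx(dx1, rel=1e-12)
        assert d_bio["p2"] == pytest.approx(dx2, rel=1e-12)

    def test_yield_rises_as_catabolism_gets_more_exergonic(self):
        # more energy per catabolic run -> fewer runs per biomass
        yields = []
        for dgf_b in (-150.0, -200.0, -300.0):
            species, pop = _toy_system(dgf_b=dgf_b)
            st_ = pathway_specific_rate(
                pop.pathways[0], pop.anabolic, species, {"A": 1.0, "B": 1.0}, 7.0, T
            )
            yields.append(st_.yield_x)
        assert yields[0] < yields[1] < yields[2]

    def test_depleted_pool_halts_consuming_pathway(self):
        species, pop = _toy_system()
        d_chem, d_bio, states = tc.community_derivatives(
            {"toy": (pop, 1e-3)},
            species,
            {"A": CONCENTRATION_FLOOR / 2, "B": 1.0},
            7.0,
            T,
            depleted={"A": True, "B": False},
        )
        assert states[("toy", "cat")].rate == 0.0
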