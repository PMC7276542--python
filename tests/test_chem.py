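"""Chemical bookkeeping and reaction free energies."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermocomm as tc
from thermocomm.chem import ConfigurationError, formation_energy
from thermocomm.constants import R_KJ, T_REF

BIOMASS = tc.ElementComposition.parse("C1H1.8O0.5N0.2")


class TestComposition:
    def test_biomass_molar_mass(self):
        assert tc.molar_mass(BIOMASS) == pytest.approx(24.6, abs=0.05)

    def test_water_molar_mass(self):
        assert tc.molar_mass(tc.ElementComposition.parse("H2O")) == pytest.approx(
            18.02, abs=0.01
        )

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ConfigurationError, match="Xx"):
            tc.ElementComposition({"Xx": 1.0})

    def test_empty_composition_rejected(self):
        with pytest.raises(ConfigurationError):
            tc.ElementComposition({"C": 0.0})

    def test_parse_fractional_counts(self):
        comp = tc.ElementComposition.parse("C1H1.8O0.5N0.2", charge=0.0)
        assert comp.count("H") == pytest.approx(1.8)
        with pytest.raises(ConfigurationError):
            tc.ElementComposition.parse("C1H1.8x")


def _toy_species(dgf_a=-100.0, dgf_b=-40.0, dgf_c=-10.0):
    comp = tc.ElementComposition.parse("C1")
    return {
        "A": tc.ChemSpecies("A", composition=comp, dgf=dgf_a),
        "B": tc.ChemSpecies("B", composition=comp, dgf=dgf_b),
        "C": tc.ChemSpecies("C", composition=comp, dgf=dgf_c),
    }


class TestStandardEnergy:
    def test_zero_net_formation_energy(self):
        sp = _toy_species(0.0, 0.0, 0.0)
        rxn = tc.Reaction({"A": -1, "B": 1}, reference="A")
        assert tc.standard_reaction_energy(rxn, sp) == 0.0

    def test_equals_formation_sum_at_reference_temperature(self):
        sp = _toy_species()
        rxn = tc.Reaction({"A": -1, "B": 0.5, "C": 0.5}, reference="A")
        expected = -(-100.0) + 0.5 * (-40.0) + 0.5 * (-10.0)
        assert tc.standard_reaction_energy(rxn, sp, T_REF) == pytest.approx(
            expected, abs=1e-12
        )

    def test_renormalization_scales_energy_linearly(self):
        sp = _toy_species()
        rxn = tc.Reaction({"A": -1, "B": -0.5, "C": 2.0}, reference="A")
        doubled = rxn.normalized_to("B")
        assert tc.standard_reaction_energy(doubled, sp) == pytest.approx(
            2.0 * tc.standard_reaction_energy(rxn, sp)
        )

    def test_missing_formation_energy_names_species(self):
        sp = _toy_species()
        sp["B"] = tc.ChemSpecies("B", composition=sp["B"].composition, dgf=None)
        rxn = tc.Reaction({"A": -1, "B": 1}, reference="A")
        with pytest.raises(ConfigurationError, match="'B'"):
            tc.standard_reaction_energy(rxn, sp)

    def test_gibbs_helmholtz_applied_only_with_enthalpy(self):
        comp = tc.ElementComposition.parse("C1")
        with_h = tc.ChemSpecies("A", composition=comp, dgf=-100.0, dhf=-200.0)
        without_h = tc.ChemSpecies("B", composition=comp, dgf=-100.0)
        T = 310.15
        expected = -200.0 - (T / T_REF) * (-200.0 + 100.0)
        assert formation_energy(with_h, T) == pytest.approx(expected)
        assert formation_energy(without_h, T) == -100.0


class TestReactionEnergy:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(1e-9, 10.0),
        b=st.floats(1e-9, 10.0),
        c=st.floats(1e-9, 10.0),
    )
    def test_activity_dependence_is_rt_log_q(self, a, b, c):
        sp = _toy_species()
        rxn = tc.Reaction({"A": -1, "B": -0.5, "C": 1.5}, reference="A")
        T = 310.15
        acts = {"A": a, "B": b, "C": c}
        ones = {"A": 1.0, "B": 1.0, "C": 1.0}
        dg = tc.reaction_energy(rxn, sp, acts, pH=7.0, T=T)
        dg0 = tc.reaction_energy(rxn, sp, ones, pH=7.0, T=T)
        log_q = -math.log(a) - 0.5 * math.log(b) + 1.5 * math.log(c)
        assert dg - dg0 == pytest.approx(R_KJ * T * log_q, rel=1e-10, abs=1e-10)

    def test_additive_over_summed_reactions(self):
        sp = _toy_species()
        r1 = tc.Reaction({"A": -1, "B": 1}, reference="A")
        r2 = tc.Reaction({"B": -1, "C": 1}, reference="B")
        total = tc.Reaction({"A": -1, "C": 1}, reference="A")
        acts = {"A": 0.3, "B": 2.0, "C": 0.01}
        args = (sp, acts, 7.0, 310.15)
        assert tc.reaction_energy(r1, *args) + tc.reaction_energy(
            r2, *args
        ) == pytest.approx(tc.reaction_energy(total, *args))

    def test_strictly_increasing_in_product_activity(self):
        sp = _toy_species()
        rxn = tc.Reaction({"A": -1, "C": 1}, reference="A")
        energies = [
            tc.reaction_energy(rxn, sp, {"A": 1.0, "C": c}, 7.0, 310.15)
            for c in (1e-6, 1e-3, 1.0, 1e3)
        ]
        assert all(x < y for x, y in zip(energies, energies[1:]))

    def test_zero_activity_rejected(self):
        sp = _toy_species()
        rxn = tc.Reaction({"A": -1, "C": 1}, reference="A")
        with pytest.raises(ValueError, match="floor"):
            tc.reaction_energy(rxn, sp, {"A": 0.0, "C": 1.0}, 7.0, 310.15)

    def test_proton_term_from_ph(self, species, unit_activities):
        # at unit activities the pH enters only through the proton coefficient
        rxn = tc.Reaction(
            {"lactate-": -1, "H2O": -2, "acetate-": 1, "H2(aq)": 2, "HCO3-": 1, "H+": 1},
            reference="lactate-",
        )
        T = 310.15
        dg7 = tc.reaction_energy(rxn, species, unit_activities, 7.0, T)
        dg0 = tc.reaction_energy(rxn, species, unit_activities, 0.0, T)
        assert dg7 - dg0 == pytest.approx(R_KJ * T * math.log(1e-7))


TABLE_ENERGIES = [
    # (pathway lookup, expected kJ/mol at pH 7, 310.15 K, unit activities)
    (("Dv", "lactate_fermentation", None), 27.58),
    (("Dv", "lactate_sulfate_respiration", "SO4-2"), -170.17),
    (("Dv", "hydrogen_sulfate_respiration", None), -56.33),
    (("Mm", "hydrogenotrophic_methanogenesis", None), -48.12),
    (("Mb", "acetoclastic_methanogenesis", None), -14.65),
]


class TestModelSystemEnergetics:
    @pytest.mark.parametrize("lookup,expected", TABLE_ENERGIES)
    def test_catabolic_energies(
        self, tri_config, species, unit_activities, lookup, expected
    ):
        pop_name, pw_name, renorm = lookup
        pop = next(p for p in tri_config.populations if p.name == pop_name)
        rxn = next(p for p in pop.pathways if p.name == pw_name).reaction
        if renorm:
            rxn = rxn.normalized_to(renorm)
        dg = tc.reaction_energy(rxn, species, unit_activities, 7.0, 310.15)
        assert dg == pytest.approx(expected, abs=0.5)

    def test_hydrogenotrophic_anabolism_energy(
        self, tri_config, species, unit_activities
    ):
        mm = next(p for p in tri_config.populations if p.name == "Mm")
        dg = tc.reaction_energy(
            mm.anabolic.reaction, species, unit_activities, 7.0, 310.15
        )
        assert dg == pytest.approx(-64.73, abs=0.5)


class TestBalanceCheck:
    def test_hydrogenotrophic_anabolism_balances(self, tri_config, species):
        mm = next(p for p in tri_config.populations if p.name == "Mm")
        report = tc.balance_check(mm.anabolic.reaction, species)
        assert report.balanced

    def test_lactate_anabolism_carries_printed_rounding(self, tri_config, species):
        dv = next(p for p in tri_config.populations if p.name == "Dv")
        report = tc.balance_check(dv.anabolic.reaction, species)
        assert report.flagged["C"] == pytest.approx(0.05, abs=1e-9)
        assert not report.balanced

    def test_identity_conversion_balances(self):
        comp = tc.ElementComposition.parse("C2H4O2")
        sp = {
            "A": tc.ChemSpecies("A", composition=comp),
            "A'": tc.ChemSpecies("A'", composition=comp),
        }
        rxn = tc.Reaction({"A": -1, "A'": 1}, reference="A")
        report = tc.balance_check(rxn, sp)
        assert all(abs(v) < 1e-12 for v in report.imbalance.values())


class TestReactionInvariants:
    def test_reference_must_be_present_and_unit(self):
        with pytest.raises(ConfigurationError):
            tc.Reaction({"A": -2, "B": 1}, reference="A")
        with pytest.raises(ConfigurationError):
            tc.Reaction({"A": -1}, reference="B")

    def test_normalize_requires_consumed_species(self):
        rxn = tc.Reaction({"A": -1, "B": 1}, reference="A")
        with pytest.raises(ConfigurationError):
            rxn.normalized_to("B")
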