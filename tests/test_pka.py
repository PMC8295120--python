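"""Microscopic and macroscopic pKa over protonation microstates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from logpka import (
    Microstate,
    MicrostateSet,
    macro_pka,
    micro_pka,
    microstate_free_energy,
    validate_microstate_table,
)
from logpka.exceptions import (
    ChargeMismatchError,
    EmptyEnsembleError,
    InvalidValueError,
    MissingChargeStateError,
)
from logpka.thermo import ProtonParameters, ThermoConditions

LOG2 = math.log10(2.0)


def micro(mid, charge, energies, compound="C"):
    return Microstate(mid, compound, charge, energies)


class TestMicrostateFreeEnergy:
    def test_single_conformer_identity(self):
        assert microstate_free_energy(micro("m1", 0, [-12.5])) == pytest.approx(-12.5)

    def test_degenerate_pair_gains_rt_ln2(self, cond):
        g = microstate_free_energy(micro("m1", 0, [-3.0, -3.0]), cond)
        assert g == pytest.approx(-3.0 - cond.rt * math.log(2.0), abs=1e-9)

    def test_matches_high_precision_summation(self, cond):
        energies = [0.0, 1.0, 2.0]
        direct = -cond.rt * math.log(
            math.fsum(math.exp(-g / cond.rt) for g in energies)
        )
        assert microstate_free_energy(micro("m1", 0, energies), cond) == pytest.approx(
            direct, abs=1e-10
        )

    def test_empty_conformer_list_rejected(self):
        with pytest.raises(EmptyEnsembleError):
            micro("m1", 0, [])


class TestMicroPka:
    def test_zero_when_cycle_closes(self, proton, cond):
        acid = micro("a", 0, [-20.0])
        base = micro("b", -1, [-20.0 - proton.total()])
        assert micro_pka(acid, base, proton, cond) == pytest.approx(0.0, abs=1e-9)

    def test_one_rtln10_driving_force(self, proton, cond):
        acid = micro("a", 0, [0.0])
        base = micro("b", -1, [271.65424])
        assert micro_pka(acid, base, proton, cond) == pytest.approx(1.000, abs=1e-3)

    def test_doubling_base_degeneracy_lowers_pka_by_log2(self, proton, cond):
        acid = micro("a", 0, [0.0])
        base1 = micro("b", -1, [-250.0])
        base2 = micro("b", -1, [-250.0, -250.0])
        shift = micro_pka(acid, base1, proton, cond) - micro_pka(acid, base2, proton, cond)
        assert shift == pytest.approx(LOG2, abs=1e-9)

    def test_charge_mismatch_rejected(self, proton):
        with pytest.raises(ChargeMismatchError):
            micro_pka(micro("a", 0, [0.0]), micro("b", 0, [0.0]), proton)
        with pytest.raises(ChargeMismatchError):
            micro_pka(micro("a", 0, [0.0]), micro("b", -2, [0.0]), proton)


class TestMacroPka:
    def test_single_tautomer_collapses_to_micro(self, proton, cond):
        ms = MicrostateSet("C", [micro("a", 0, [-10.0]), micro("b", -1, [250.0])])
        res = macro_pka(ms, 0, proton, cond)
        assert res.macro_pka == pytest.approx(res.micro_pkas[("a", "b")], abs=1e-12)

    def test_two_degenerate_base_tautomers_lower_macro_by_log2(self, proton, cond):
        acid = micro("a", 0, [-10.0])
        single = MicrostateSet("C", [acid, micro("b1", -1, [250.0])])
        double = MicrostateSet(
            "C", [acid, micro("b1", -1, [250.0]), micro("b2", -1, [250.0])]
        )
        m1 = macro_pka(single, 0, proton, cond)
        m2 = macro_pka(double, 0, proton, cond)
        assert m1.macro_pka - m2.macro_pka == pytest.approx(LOG2, abs=1e-9)
        assert m2.micro_pkas[("a", "b1")] == pytest.approx(m1.macro_pka, abs=1e-12)

    def test_two_degenerate_acid_tautomers_raise_macro_by_log2(self, proton, cond):
        base = micro("b", -1, [250.0])
        single = MicrostateSet("C", [micro("a1", 0, [-10.0]), base])
        double = MicrostateSet(
            "C", [micro("a1", 0, [-10.0]), micro("a2", 0, [-10.0]), base]
        )
        m1 = macro_pka(single, 0, proton, cond)
        m2 = macro_pka(double, 0, proton, cond)
        assert m2.macro_pka - m1.macro_pka == pytest.approx(LOG2, abs=1e-9)

    def test_missing_charge_state_names_compound_and_charge(self, proton):
        ms = MicrostateSet("CMPD9", [micro("a", 0, [0.0], "CMPD9")])
        with pytest.raises(MissingChargeStateError) as err:
            macro_pka(ms, 0, proton)
        assert "CMPD9" in str(err.value)
        assert "-1" in str(err.value)

    @given(
        acid_sets=st.lists(
            st.lists(st.floats(-30, -20, allow_nan=False), min_size=1, max_size=3),
            min_size=1, max_size=3,
        ),
        base_sets=st.lists(
            st.lists(st.floats(230, 240, allow_nan=False), min_size=1, max_size=3),
            min_size=1, max_size=3,
        ),
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_direct_exponential_oracle(self, acid_sets, base_sets, proton, cond):
        """Macro pKa equals the brute-force partition-function computation."""
        microstates = [
            micro(f"a{i}", 0, g) for i, g in enumerate(acid_sets)
        ] + [micro(f"b{i}", -1, g) for i, g in enumerate(base_sets)]
        ms = MicrostateSet("C", microstates)
        rt = cond.rt
        z_acid = math.fsum(
            math.exp(-g / rt) for gs in acid_sets for g in gs
        )
        z_base = math.fsum(
            math.exp(-g / rt) for gs in base_sets for g in gs
        )
        expected = (
            (-rt * math.log(z_base)) + proton.total() - (-rt * math.log(z_acid))
        ) / cond.rt_ln10
        assert macro_pka(ms, 0, proton, cond).macro_pka == pytest.approx(
            expected, abs=1e-9
        )

    @given(
        acid_sets=st.lists(
            st.lists(st.floats(-30, -20, allow_nan=False), min_size=1, max_size=3),
            min_size=1, max_size=3,
        ),
        base_sets=st.lists(
            st.lists(st.floats(230, 240, allow_nan=False), min_size=1, max_size=3),
            min_size=1, max_size=3,
        ),
    )
    @settings(max_examples=60, derandomize=True)
    def test_hierarchical_equals_flat_pooling(self, acid_sets, base_sets, proton, cond):
        """Collapsing microstates first then pooling equals flat pooling."""
        from logpka.ensemble import ensemble_free_energy

        microstates = [
            micro(f"a{i}", 0, g) for i, g in enumerate(acid_sets)
        ] + [micro(f"b{i}", -1, g) for i, g in enumerate(base_sets)]
        ms = MicrostateSet("C", microstates)
        res = macro_pka(ms, 0, proton, cond)
        g_acid_hier = ensemble_free_energy(
            [ensemble_free_energy(g, cond) for g in acid_sets], cond
        )
        g_base_hier = ensemble_free_energy(
            [ensemble_free_energy(g, cond) for g in base_sets], cond
        )
        assert res.charge_state_free_energies[0] == pytest.approx(g_acid_hier, abs=1e-10)
        assert res.charge_state_free_energies[-1] == pytest.approx(g_base_hier, abs=1e-10)

    def test_shift_invariance_of_macro_pka(self, proton, cond):
        microstates = [
            micro("a1", 0, [-25.0, -24.0]),
            micro("b1", -1, [235.0]),
            micro("b2", -1, [236.0, 237.0]),
        ]
        shifted = [
            micro(m.microstate_id, m.formal_charge, [g + 7.3 for g in m.conformer_free_energies])
            for m in microstates
        ]
        m0 = macro_pka(MicrostateSet("C", microstates), 0, proton, cond).macro_pka
        m1 = macro_pka(MicrostateSet("C", shifted), 0, proton, cond).macro_pka
        assert m1 == pytest.approx(m0, abs=1e-9)

    def test_lowering_base_energy_never_raises_macro_pka(self, proton, cond):
        def build(g_b1):
            return MicrostateSet(
                "C", [micro("a", 0, [-25.0]), micro("b1", -1, [g_b1]),
                      micro("b2", -1, [236.0])]
            )
        high = macro_pka(build(235.0), 0, proton, cond).macro_pka
        low = macro_pka(build(233.0), 0, proton, cond).macro_pka
        assert low <= high

    def test_lowering_acid_energy_never_lowers_macro_pka(self, proton, cond):
        def build(g_a):
            return MicrostateSet(
                "C", [micro("a", 0, [g_a]), micro("b", -1, [235.0])]
            )
        assert (
            macro_pka(build(-27.0), 0, proton, cond).macro_pka
            >= macro_pka(build(-25.0), 0, proton, cond).macro_pka
        )

    def test_macro_bracketed_by_micro_range_with_degeneracy_slack(self, proton, cond):
        microstates = [
            micro("a1", 0, [-25.0]),
            micro("a2", 0, [-24.0, -23.5]),
            micro("b1", -1, [235.0]),
            micro("b2", -1, [236.0]),
            micro("b3", -1, [234.0, 235.5]),
        ]
        ms = MicrostateSet("C", microstates)
        res = macro_pka(ms, 0, proton, cond)
        lo = min(res.micro_pkas.values()) - math.log10(3)
        hi = max(res.micro_pkas.values()) + math.log10(2)
        assert lo <= res.macro_pka <= hi

    def test_relative_dialect_rejects_proton_parameters(self, proton):
        ms = MicrostateSet(
            "C",
            [micro("a", 0, [0.0]), micro("b", -1, [5.0])],
            dialect="relative_transition",
            reference_microstate="a",
        )
        with pytest.raises(InvalidValueError):
            macro_pka(ms, 0, proton)
        # without the proton term the cycle is direct
        res = macro_pka(ms, 0, None)
        assert res.macro_pka == pytest.approx(5.0 / ThermoConditions().rt_ln10, abs=1e-9)


class TestValidateMicrostateTable:
    def _consistent_set(self):
        return MicrostateSet(
            "C", [micro("a", 0, [-25.0]), micro("b", -1, [235.0, 236.0])]
        )

    def test_consistent_table_not_flagged(self, proton, cond):
        ms = self._consistent_set()
        truth = macro_pka(ms, 0, proton, cond).macro_pka
        report = validate_microstate_table(ms, truth, 0.10, 0, proton, cond)
        assert not report.flagged
        assert report.discrepancy == pytest.approx(0.0, abs=1e-12)

    def test_report_carries_microstate_free_energies(self, proton, cond):
        ms = self._consistent_set()
        report = validate_microstate_table(ms, 0.0, 0.10, 0, proton, cond)
        assert set(report.microstate_free_energies) == {"a", "b"}

    def test_flip_across_charge_states_is_flagged(self, cond):
        """A submission file with acid/base free energies flipped recomputes
        to a visibly different macroscopic pKa."""
        from logpka.synthetic import flipped_microstate_scenario

        correct, corrupted, reported = flipped_microstate_scenario(3.90, cond)
        ok = validate_microstate_table(correct, reported, 0.10, 0, None, cond)
        bad = validate_microstate_table(corrupted, reported, 0.10, 0, None, cond)
        assert not ok.flagged
        assert bad.flagged
        assert abs(bad.discrepancy) == pytest.approx(3.90, abs=0.01)

    def test_non_positive_tolerance_rejected(self, proton):
        with pytest.raises(InvalidValueError):
            validate_microstate_table(self._consistent_set(), 0.0, 0.0, 0, proton)
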