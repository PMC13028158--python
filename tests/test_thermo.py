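import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fesnet import (
    BalanceError,
    Formula,
    FormulaError,
    MissingEnergyError,
    Species,
    ThermoComponents,
    ValidationError,
    assemble_solution_free_energy,
    balance_formation,
    compute_grel,
    default_reference_set,
    formation_reaction_string,
)
from fesnet.thermo import ReferenceSet


class TestFormula:
    @pytest.mark.parametrize(
        "text,counts",
        [
            ("C2H4O4S", (2, 4, 4, 1)),
            ("C2H4SO4", (2, 4, 4, 1)),  # permissive non-Hill order
            ("CH2O", (1, 2, 1, 0)),
            ("H2SO3", (0, 2, 3, 1)),
            ("H2", (0, 2, 0, 0)),
            ("C5H10O9S2", (5, 10, 9, 2)),
        ],
    )
    def test_parse(self, text, counts):
        assert Formula.parse(text).counts() == counts

    def test_rejects_foreign_element(self):
        with pytest.raises(FormulaError, match="P"):
            Formula.parse("C3H7O6P")

    def test_rejects_empty_and_garbage(self):
        with pytest.raises(FormulaError):
            Formula.parse("")
        with pytest.raises(FormulaError):
            Formula.parse("2CO")

    def test_rejects_all_zero(self):
        with pytest.raises(FormulaError):
            Formula(0, 0, 0, 0)

    def test_str_hill_order(self):
        assert str(Formula.parse("C2H4SO4")) == "C2H4O4S"
        assert str(Formula.parse("H2SO3")) == "H2O3S"


class TestAssemble:
    def test_worked_example(self):
        c = ThermoComponents(-10.0, 1.0, 0.020, -5.0)
        got = assemble_solution_free_energy(c, temperature=298.15, entropy_fraction=0.5)
        assert got == pytest.approx(-16.9815, abs=1e-12)

    def test_zero_entropy_leaves_sum(self):
        c = ThermoComponents(-10.0, 1.0, 0.0, -5.0)
        assert assemble_solution_free_energy(c) == pytest.approx(-14.0)

    @given(
        e=st.floats(-200, 200),
        h=st.floats(-50, 50),
        s=st.floats(0, 0.5),
        g=st.floats(-50, 50),
        t=st.floats(1.0, 1000.0),
    )
    def test_fraction_difference_identity(self, e, h, s, g, t):
        c = ThermoComponents(e, h, s, g)
        full = assemble_solution_free_energy(c, t, 1.0)
        half = assemble_solution_free_energy(c, t, 0.5)
        assert full - half == pytest.approx(-0.5 * t * s, abs=1e-9 * max(1.0, t * s))

    def test_rejects_nonfinite_component(self):
        with pytest.raises(ValidationError, match="solvation_g"):
            ThermoComponents(0.0, 0.0, 0.0, float("nan"))

    def test_rejects_negative_entropy(self):
        with pytest.raises(ValidationError, match="gas_entropy"):
            ThermoComponents(0.0, 0.0, -0.1, 0.0)

    def test_rejects_bad_temperature_and_fraction(self):
        c = ThermoComponents(0.0, 0.0, 0.01, 0.0)
        with pytest.raises(ValidationError):
            assemble_solution_free_energy(c, temperature=-1.0)
        with pytest.raises(ValidationError):
            assemble_solution_free_energy(c, entropy_fraction=1.5)


class TestBalanceFormation:
    def test_printed_worked_example(self):
        # 2 CO2 + 4 H2 + H2SO3 -> C2H4O4S + 3 H2O
        coeffs = balance_formation(Formula.parse("C2H4SO4"))
        assert coeffs == {
            "CO2": Fraction(2),
            "H2": Fraction(4),
            "H2O": Fraction(-3),
            "H2SO3": Fraction(1),
        }

    def test_reference_identity(self):
        coeffs = balance_formation(Formula.parse("CO2"))
        assert coeffs == {"CO2": 1, "H2": 0, "H2O": 0, "H2SO3": 0}

    def test_c2_aldehyde(self):
        # hand-solved 4x4 system: 2 CO2 + 4 H2 -> C2H4O2 + 2 H2O
        coeffs = balance_formation(Formula.parse("C2H4O2"))
        assert coeffs == {"CO2": 2, "H2": 4, "H2O": -2, "H2SO3": 0}

    def test_fractional_coefficients(self):
        coeffs = balance_formation(Formula.parse("CHO2"))  # odd hydrogen count
        assert coeffs["H2"] == Fraction(1, 2)

    @given(
        c=st.integers(0, 8), h=st.integers(0, 20), o=st.integers(0, 12), s=st.integers(0, 3)
    )
    def test_exact_element_conservation(self, c, h, o, s):
        if c + h + o + s == 0:
            return
        f = Formula(c, h, o, s)
        coeffs = balance_formation(f)
        refs = default_reference_set()
        # target + sum(coeff * ref) balances exactly in rational arithmetic
        for row in range(4):
            total = Fraction(f.counts()[row])
            for rid, x in coeffs.items():
                total -= x * refs.formula(rid).counts()[row]
            assert total == 0

    def test_singular_basis_rejected(self):
        refs = ReferenceSet(
            members=(
                ("H2O", Formula.parse("H2O")),
                ("H2O2", Formula.parse("H2O2")),
                ("H2", Formula.parse("H2")),
                ("O2", Formula.parse("O2")),  # dependent on the other three
            )
        )
        with pytest.raises(BalanceError, match="degenerate"):
            balance_formation(Formula.parse("H2O2"), refs)

    def test_out_of_span_rejected(self):
        refs = ReferenceSet(members=(("H2O", Formula.parse("H2O")), ("H2", Formula.parse("H2"))))
        with pytest.raises(BalanceError, match="span"):
            balance_formation(Formula.parse("CO2"), refs)

    def test_reaction_string(self):
        s = formation_reaction_string(Formula.parse("C2H4SO4"))
        assert s == "2 CO2 + 4 H2 + H2SO3 -> C2H4O4S + 3 H2O"


def _basis_energies(co2=-100.0, h2=-5.0, h2o=-60.0, h2so3=-150.0):
    return {"CO2": co2, "H2": h2, "H2O": h2o, "H2SO3": h2so3}


class TestComputeGrel:
    def test_formation_dg_is_grel(self):
        # construct an energy whose formation dG is exactly -12.8
        refs = default_reference_set()
        f = Formula.parse("C2H4SO4")
        energies = _basis_energies()
        coeffs = balance_formation(f, refs)
        target_energy = -12.8 + sum(float(x) * energies[rid] for rid, x in coeffs.items())
        energies["X"] = target_energy
        sp = Species(id="X", formula=f, components=ThermoComponents(0, 0, 0, 0))
        assert compute_grel(sp, refs, energies) == pytest.approx(-12.8, abs=1e-9)

    def test_reference_species_are_zero(self):
        refs = default_reference_set()
        for rid, formula in refs.members:
            sp = Species(id=rid, formula=formula, g_rel=0.0)
            assert compute_grel(sp, refs, _basis_energies()) == 0.0

    def test_same_formula_difference(self):
        refs = default_reference_set()
        f = Formula.parse("C2H6O5S")
        energies = _basis_energies()
        energies.update({"A": -400.0, "B": -397.3})
        a = Species(id="A", formula=f, g_rel=0.0)
        b = Species(id="B", formula=f, g_rel=0.0)
        diff = compute_grel(b, refs, energies) - compute_grel(a, refs, energies)
        assert diff == pytest.approx(2.7, abs=1e-9)

    def test_missing_energy_listed(self):
        refs = default_reference_set()
        sp = Species(id="X", formula=Formula.parse("CH2O"), g_rel=0.0)
        with pytest.raises(MissingEnergyError) as err:
            compute_grel(sp, refs, {"X": -1.0, "CO2": 0.0})
        assert "H2" in err.value.missing_ids
        assert "H2O" in err.value.missing_ids

    @settings(max_examples=30)
    @given(
        shift=st.floats(-50, 50),
        c=st.integers(1, 5),
        h=st.integers(0, 12),
        o=st.integers(0, 8),
        s=st.integers(0, 2),
    )
    def test_shift_invariance(self, shift, c, h, o, s):
        # adding `shift` to every basis energy and (total stoichiometry x
        # shift) to the target leaves G_rel unchanged
        refs = default_reference_set()
        f = Formula(c, h, o, s)
        coeffs = balance_formation(f, refs)
        total_stoich = float(sum(coeffs.values()))
        energies = _basis_energies()
        energies["X"] = -42.0
        sp = Species(id="X", formula=f, g_rel=0.0)
        base = compute_grel(sp, refs, energies)
        shifted = {rid: e + shift for rid, e in energies.items() if rid != "X"}
        shifted["X"] = energies["X"] + total_stoich * shift
        again = compute_grel(sp, refs, shifted)
        assert again == pytest.approx(base, abs=1e-9)

    def test_roundtrip_hidden_truth(self):
        # synthetic species whose energy embeds a hidden true formation value
        refs = default_reference_set()
        energies = _basis_energies()
        truth = 7.321
        f = Formula.parse("C3H6O5S")
        coeffs = balance_formation(f, refs)
        energies["X"] = truth + sum(float(x) * energies[rid] for rid, x in coeffs.items())
        sp = Species(id="X", formula=f, g_rel=0.0)
        assert compute_grel(sp, refs, energies) == pytest.approx(truth, abs=1e-9)
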