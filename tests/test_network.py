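import pytest

from fesnet import (
    BarrierSet,
    FreeEnergyMap,
    MissingEnergyError,
    NoBarrier,
    Reaction,
    Species,
    ValidationError,
    activation_barriers,
    audit,
    element_balance_check,
    hess_cycle_residuals,
    localize_inconsistency,
    reaction_delta_g,
    variant_ledger,
)
from fesnet.thermo import Formula


def toy_map(grels, reactions):
    species = {
        sid: Species(id=sid, formula=Formula.parse(formula), g_rel=g)
        for sid, (formula, g) in grels.items()
    }
    return FreeEnergyMap(species=species, reactions=reactions)


class TestElementBalance:
    def test_fixture_adduct_reaction_balances(self, fmap):
        assert element_balance_check(fmap.reactions["add_c2_hydroxyl"], fmap) == {}

    def test_identity_reaction(self, fmap):
        rxn = Reaction(id="noop", reactants={"4": 1}, products={"4": 1})
        assert element_balance_check(rxn, fmap) == {}

    def test_typo_detected(self, fmap):
        m = toy_map(
            {"a": ("CH2O", 2.6), "bad": ("C2H4O3", -11.4)},
            [Reaction(id="r", reactants={"a": 2}, products={"bad": 1})],
        )
        assert element_balance_check(m.reactions["r"], m) == {"O": 1}

    def test_unknown_id_rejected(self, fmap):
        rxn = Reaction(id="r", reactants={"nope": 1}, products={"4": 1})
        with pytest.raises(KeyError):
            element_balance_check(rxn, fmap)

    def test_all_fixture_reactions_balance(self, fmap):
        for rxn in fmap.reactions.values():
            assert element_balance_check(rxn, fmap) == {}, rxn.id


class TestDeltaG:
    def test_rearrangement(self, fmap):
        assert reaction_delta_g(fmap.reactions["shift_6_8"], fmap) == pytest.approx(-2.6)

    def test_catalyzed_aldol_with_references(self, fmap):
        # 17 + 1 + H2O -> 20 + H2SO3 with references contributing zero
        assert reaction_delta_g(fmap.reactions["aldol_c3_elim"], fmap) == pytest.approx(-12.6)

    def test_identity_is_zero(self, fmap):
        rxn = Reaction(id="noop", reactants={"4": 1}, products={"4": 1})
        assert reaction_delta_g(rxn, fmap) == 0.0

    def test_missing_energy_listed(self):
        from fesnet import ThermoComponents

        m = toy_map({"a": ("CH2O", 1.0)}, [])
        # species with components but no tabulated g_rel
        m.species["b"] = Species(
            id="b",
            formula=Formula.parse("CH2O"),
            g_rel=None,
            components=ThermoComponents(0, 0, 0, 0),
        )
        rxn = Reaction(id="r", reactants={"a": 1}, products={"b": 1})
        with pytest.raises(MissingEnergyError) as err:
            reaction_delta_g(rxn, m)
        assert err.value.missing_ids == ["b"]

    def test_path_additivity(self, fmap):
        step1 = reaction_delta_g(fmap.reactions["shift_6_8"], fmap)
        step2 = reaction_delta_g(fmap.reactions["dehydr_8_7"], fmap)
        composed = Reaction(id="c", reactants={"6": 1}, products={"7": 1, "H2O": 1})
        assert reaction_delta_g(composed, fmap) == pytest.approx(step1 + step2, abs=1e-12)


class TestBarriers:
    def test_c1_o_attack(self, fmap):
        b = activation_barriers(fmap.reactions["add_c1_o"], fmap)
        assert isinstance(b, BarrierSet)
        assert b.forward == pytest.approx(5.2)
        assert b.delta_g == pytest.approx(-3.0)
        assert b.reverse == pytest.approx(8.2)  # 5.2 - (-3.0)
        assert not b.submerged

    def test_no_ts_is_typed(self, fmap):
        b = activation_barriers(fmap.reactions["dehydr_8_7"], fmap)
        assert isinstance(b, NoBarrier)
        assert not b
        assert b != 0.0

    def test_zero_barrier(self, fmap):
        m = toy_map(
            {
                "a": ("CH2O", 3.0),
                "b": ("CH2O", 1.0),
                "ts": ("CH2O", 3.0),
            },
            [],
        )
        m.species["ts"] = Species(id="ts", formula=Formula.parse("CH2O"), role="transition_state", g_rel=3.0)
        rxn = Reaction(id="r", reactants={"a": 1}, products={"b": 1}, ts_id="ts")
        b = activation_barriers(rxn, m)
        assert b.forward == 0.0

    def test_ring_shift_submerged(self, fmap):
        # flanking TSs (+16.9, +17.7) sit below the intermediate (+18.3)
        entry = activation_barriers(fmap.reactions["shift_6_9"], fmap)
        exit_ = activation_barriers(fmap.reactions["shift_9_8"], fmap)
        assert entry.submerged_reverse and entry.submerged
        assert exit_.submerged_forward and exit_.submerged
        assert entry.reverse == pytest.approx(-1.4)

    def test_forward_minus_reverse_identity(self, fmap):
        for rxn in fmap.reactions.values():
            b = activation_barriers(rxn, fmap)
            if isinstance(b, BarrierSet):
                assert b.forward - b.reverse == pytest.approx(
                    reaction_delta_g(rxn, fmap), abs=1e-12
                ), rxn.id


class TestHessCycles:
    def test_fixture_residuals_all_zero(self, fmap):
        # every dG derives from one stored G_rel per species: telescoping
        for res in hess_cycle_residuals(fmap):
            assert res.residual == pytest.approx(0.0, abs=1e-12)

    def test_acyclic_map_empty(self):
        m = toy_map(
            {"a": ("CH2O", 0.0), "b": ("CH2O", 1.0)},
            [Reaction(id="r", reactants={"a": 1}, products={"b": 1})],
        )
        assert hess_cycle_residuals(m) == []

    def test_perturbed_copy_shows_residual(self, fmap):
        rxn = fmap.reactions["shift_6_8"]
        rxn.local_g_rel["8"] = fmap.species["8"].g_rel + 0.5
        try:
            bad = audit(fmap, 1e-9)
            assert bad, "expected a failing cycle"
            assert any(abs(abs(r.residual) - 0.5) < 1e-9 for r in bad)
        finally:
            rxn.local_g_rel.clear()

    def test_localization(self, fmap):
        rxn = fmap.reactions["shift_9_8"]
        rxn.local_g_rel["9"] = fmap.species["9"].g_rel - 0.7
        try:
            found = localize_inconsistency(fmap, 1e-9)
            assert found is not None
            sid, rid, shift = found
            assert (sid, rid) == ("9", "shift_9_8")
            assert shift == pytest.approx(-0.7)
        finally:
            rxn.local_g_rel.clear()

    def test_synthetic_map_consistent(self, synth_map):
        for res in hess_cycle_residuals(synth_map):
            assert res.residual == pytest.approx(0.0, abs=1e-9)


class TestVariantLedger:
    def test_aldol_ts_pair(self, fmap):
        rows = variant_ledger(fmap, [("aldol_c2_keep", "aldol_c2_elim")])
        assert rows[0].ddg_barrier == pytest.approx(-14.0)

    def test_retro_aldol_pair(self, fmap):
        # non-sulfur +2.9 as base vs bisulfite -5.7 as variant
        rows = variant_ledger(fmap, [("retro_ns_thr", "retro_thr")])
        assert rows[0].ddg == pytest.approx(-8.6)
        assert rows[0].ddg_barrier is None  # overall retro step carries no TS

    def test_identity_pairs_zero(self, fmap):
        rows = variant_ledger(fmap, [("add_c1_o", "add_c1_o"), ("retro_thr", "retro_thr")])
        for row in rows:
            assert row.ddg == 0.0
            assert row.ddg_barrier in (0.0, None)

    def test_unknown_id_rejected(self, fmap):
        with pytest.raises(ValidationError, match="nope"):
            variant_ledger(fmap, [("add_c1_o", "nope")])


class TestMapValidation:
    def test_fixture_validates(self, fmap):
        fmap.validate()

    def test_detached_ts_rejected(self):
        m = toy_map({"a": ("CH2O", 0.0)}, [])
        m.species["ts"] = Species(
            id="ts", formula=Formula.parse("CH2O"), role="transition_state", g_rel=5.0
        )
        with pytest.raises(ValidationError, match="not attached"):
            m.validate()

    def test_ts_must_have_ts_role(self, fmap):
        m = toy_map(
            {"a": ("CH2O", 0.0), "b": ("CH2O", 1.0)},
            [Reaction(id="r", reactants={"a": 1}, products={"b": 1}, ts_id="a")],
        )
        with pytest.raises(ValidationError, match="not a transition state"):
            m.validate()
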