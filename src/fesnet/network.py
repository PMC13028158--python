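"""Reaction network on top of the free-energy map.

Reactions are stored once, in their forward orientation; the reverse
direction is a query-time sign flip. Reference species (CO2, H2, H2O,
H2SO3) may appear freely on either side and contribute ``G_rel = 0``
(water at the map's implicit 1 M-equivalent standard state).

The Hess audit exploits the fact that ``G_rel`` is a state function: the
signed sum of ΔG around any closed cycle of the complex graph (nodes =
reactant/product multisets, edges = reactions) must vanish for a
consistent map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from numbers import Rational
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx

from .errors import MissingEnergyError, ValidationError
from .thermo import (
    ELEMENTS,
    ROLE_TRANSITION_STATE,
    Formula,
    ReferenceSet,
    Species,
    default_reference_set,
)

CATEGORIES = frozenset(
    {
        "adduct_formation",
        "rearrangement",
        "dehydration",
        "enolization",
        "tautomerization",
        "aldol",
        "retro_aldol",
        "cannizzaro",
        "ring_closure",
        "other",
    }
)

Multiplicity = Union[int, Rational]


def _normalize_side(side) -> dict[str, Multiplicity]:
    """Accept a dict id->mult or an iterable of ids (with repeats)."""
    if isinstance(side, Mapping):
        out = dict(side)
    else:
        out = {}
        for sid in side:
            out[sid] = out.get(sid, 0) + 1
    for sid, mult in out.items():
        if mult <= 0:
            raise ValidationError(f"non-positive multiplicity for {sid!r}")
    return out


@dataclass
class Reaction:
    """One reaction: reactant/product multisets, optional TS link, category."""

    id: str
    reactants: dict[str, Multiplicity]
    products: dict[str, Multiplicity]
    ts_id: Optional[str] = None
    category: str = "other"
    annotations: dict = field(default_factory=dict)
    #: Reaction-local G_rel overrides (used by the corruption machinery and
    #: detected by the Hess audit).
    local_g_rel: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.reactants = _normalize_side(self.reactants)
        self.products = _normalize_side(self.products)
        if self.category not in CATEGORIES:
            raise ValidationError(f"reaction {self.id!r}: unknown category {self.category!r}")
        if not self.reactants or not self.products:
            raise ValidationError(f"reaction {self.id!r}: both sides must be non-empty")

    def participant_ids(self) -> set[str]:
        return set(self.reactants) | set(self.products)


@dataclass
class FreeEnergyMap:
    """Species registry + reaction list + reference basis."""

    species: dict[str, Species]
    reactions: dict[str, Reaction]
    reference: ReferenceSet = field(default_factory=default_reference_set)
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.species, (list, tuple)):
            self.species = {s.id: s for s in self.species}
        if isinstance(self.reactions, (list, tuple)):
            self.reactions = {r.id: r for r in self.reactions}

    # -- lookups ---------------------------------------------------------
    def formula(self, sid: str) -> Formula:
        if sid in self.species:
            return self.species[sid].formula
        if sid in self.reference.ids:
            return self.reference.formula(sid)
        raise KeyError(f"unknown species id {sid!r}")

    def g_rel(self, sid: str, reaction: Optional[Reaction] = None) -> float:
        """G_rel of a species, honouring reaction-local overrides."""
        if reaction is not None and sid in reaction.local_g_rel:
            return reaction.local_g_rel[sid]
        if sid in self.reference.ids and sid not in self.species:
            return 0.0
        sp = self.species.get(sid)
        if sp is None or sp.g_rel is None:
            raise MissingEnergyError([sid])
        return sp.g_rel

    def validate(self) -> None:
        """Check referential integrity and TS attachment invariants."""
        attached: dict[str, list[str]] = {}
        for rxn in self.reactions.values():
            for sid in rxn.participant_ids():
                if sid not in self.species and sid not in self.reference.ids:
                    raise ValidationError(f"reaction {rxn.id!r} references unknown species {sid!r}")
            if rxn.ts_id is not None:
                ts = self.species.get(rxn.ts_id)
                if ts is None:
                    raise ValidationError(f"reaction {rxn.id!r}: unknown ts_id {rxn.ts_id!r}")
                if ts.role != ROLE_TRANSITION_STATE:
                    raise ValidationError(f"reaction {rxn.id!r}: ts_id {rxn.ts_id!r} is not a transition state")
                attached.setdefault(rxn.ts_id, []).append(rxn.id)
        for sid, sp in self.species.items():
            if sp.role == ROLE_TRANSITION_STATE and sid not in attached:
                raise ValidationError(f"transition state {sid!r} is not attached to any reaction")


# ---------------------------------------------------------------------------
# per-reaction computations
# ---------------------------------------------------------------------------

def element_balance_check(reaction: Reaction, registry: FreeEnergyMap) -> dict[str, Multiplicity]:
    """Signed per-element imbalance (products minus reactants).

    Empty dict iff the reaction is balanced.
    """
    totals = dict.fromkeys(ELEMENTS, 0)
    for sid, mult in reaction.products.items():
        for el, n in zip(ELEMENTS, registry.formula(sid).counts()):
            totals[el] += n * mult
    for sid, mult in reaction.reactants.items():
        for el, n in zip(ELEMENTS, registry.formula(sid).counts()):
            totals[el] -= n * mult
    return {el: v for el, v in totals.items() if v != 0}


def _side_g(side: dict[str, Multiplicity], fmap: FreeEnergyMap, reaction: Reaction) -> float:
    missing = []
    total = 0.0
    for sid, mult in side.items():
        try:
            total += float(mult) * fmap.g_rel(sid, reaction)
        except MissingEnergyError:
            missing.append(sid)
    if missing:
        raise MissingEnergyError(missing)
    return total


def reaction_delta_g(reaction: Reaction, fmap: FreeEnergyMap) -> float:
    """ΔG = G_rel(products) - G_rel(reactants), with multiplicity."""
    return _side_g(reaction.products, fmap, reaction) - _side_g(reaction.reactants, fmap, reaction)


@dataclass(frozen=True)
class NoBarrier:
    """Typed absence of kinetic information (no TS on the reaction)."""

    reaction_id: str

    def __bool__(self) -> bool:  # falsy so `if barriers:` reads naturally
        return False


@dataclass(frozen=True)
class BarrierSet:
    """Forward/reverse activation free energies for one reaction."""

    reaction_id: str
    ts_id: str
    forward: float
    reverse: float
    delta_g: float
    #: True when the TS lies below the reactant (resp. product) asymptote —
    #: reported explicitly instead of being silently negative.
    submerged_forward: bool = False
    submerged_reverse: bool = False

    @property
    def submerged(self) -> bool:
        return self.submerged_forward or self.submerged_reverse


def activation_barriers(reaction: Reaction, fmap: FreeEnergyMap) -> Union[BarrierSet, NoBarrier]:
    """Forward and reverse ΔG‡ from the TS G_rel; identity
    ``forward - reverse == ΔG`` holds by construction."""
    if reaction.ts_id is None:
        return NoBarrier(reaction.id)
    ts_g = fmap.g_rel(reaction.ts_id, reaction)
    g_react = _side_g(reaction.reactants, fmap, reaction)
    g_prod = _side_g(reaction.products, fmap, reaction)
    fwd = ts_g - g_react
    rev = ts_g - g_prod
    return BarrierSet(
        reaction_id=reaction.id,
        ts_id=reaction.ts_id,
        forward=fwd,
        reverse=rev,
        delta_g=g_prod - g_react,
        submerged_forward=fwd < 0,
        submerged_reverse=rev < 0,
    )


# ---------------------------------------------------------------------------
# Hess-cycle audit
# ---------------------------------------------------------------------------

def _complex_key(side: dict[str, Multiplicity]) -> str:
    parts = []
    for sid in sorted(side):
        mult = side[sid]
        parts.extend([sid] * int(mult) if float(mult).is_integer() else [f"{mult} {sid}"])
    return "+".join(parts)


@dataclass(frozen=True)
class CycleResidual:
    """Signed ΔG sum around one independent cycle of the complex graph."""

    reactions: tuple[tuple[str, int], ...]  # (reaction id, orientation ±1)
    residual: float


def hess_cycle_residuals(fmap: FreeEnergyMap) -> list[CycleResidual]:
    """Residuals over a deterministic cycle basis of the complex graph.

    Parallel reactions between the same complex pair contribute 2-cycles;
    longer cycles come from :func:`networkx.cycle_basis` on the simple
    collapsed graph. Empty list for an acyclic map.
    """
    edges: dict[tuple[str, str], list[tuple[str, float]]] = {}
    loops: list[tuple[str, float]] = []
    for rid in sorted(fmap.reactions):
        rxn = fmap.reactions[rid]
        u = _complex_key(rxn.reactants)
        v = _complex_key(rxn.products)
        dg = reaction_delta_g(rxn, fmap)
        if u == v:
            loops.append((rid, dg))
            continue
        if u <= v:
            edges.setdefault((u, v), []).append((rid, dg))
        else:
            edges.setdefault((v, u), []).append((rid, -dg))

    residuals: list[CycleResidual] = []
    for rid, dg in loops:
        residuals.append(CycleResidual(reactions=((rid, 1),), residual=dg))
    for (u, v), lst in sorted(edges.items()):
        first_rid, first_dg = lst[0]
        for rid, dg in lst[1:]:
            residuals.append(
                CycleResidual(reactions=((rid, 1), (first_rid, -1)), residual=dg - first_dg)
            )

    graph = nx.Graph()
    for (u, v), lst in sorted(edges.items()):
        graph.add_edge(u, v, rid=lst[0][0], dg=lst[0][1], u=u)
    for cycle in nx.cycle_basis(graph):
        chain = []
        total = 0.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            data = graph[a][b]
            sign = 1 if data["u"] == a else -1
            chain.append((data["rid"], sign))
            total += sign * data["dg"]
        residuals.append(CycleResidual(reactions=tuple(chain), residual=total))
    return residuals


def audit(fmap: FreeEnergyMap, tolerance: float = 1e-9) -> list[CycleResidual]:
    """Cycle residuals whose magnitude exceeds ``tolerance``."""
    return [r for r in hess_cycle_residuals(fmap) if abs(r.residual) > tolerance]


def localize_inconsistency(
    fmap: FreeEnergyMap, tolerance: float = 1e-9
) -> Optional[tuple[str, str, float]]:
    """Pinpoint a single corrupted species from failing Hess cycles.

    Returns ``(species_id, reaction_id, implied_shift)`` for the candidate
    whose reaction-local correction zeroes every failing residual, or
    ``None`` when the audit passes.
    """
    failing = audit(fmap, tolerance)
    if not failing:
        return None
    # Reactions implicated by every failing cycle.
    common = set.intersection(*[{rid for rid, _ in r.reactions} for r in failing])
    for rid in sorted(common):
        rxn = fmap.reactions[rid]
        for sid in sorted(rxn.participant_ids()):
            base = None
            if sid in fmap.species and fmap.species[sid].g_rel is not None:
                base = fmap.species[sid].g_rel
            elif sid in fmap.reference.ids:
                base = 0.0
            if base is None:
                continue
            local = fmap.g_rel(sid, rxn)
            shift = local - base
            if abs(shift) <= tolerance:
                continue
            # Check this single correction explains all failing cycles.
            saved = dict(rxn.local_g_rel)
            rxn.local_g_rel[sid] = base
            ok = not audit(fmap, tolerance)
            rxn.local_g_rel.clear()
            rxn.local_g_rel.update(saved)
            if ok:
                return (sid, rid, shift)
    return None


# ---------------------------------------------------------------------------
# variant ledger
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRow:
    base_id: str
    variant_id: str
    delta_g_base: float
    delta_g_variant: float
    ddg: float
    barrier_base: Optional[float] = None
    barrier_variant: Optional[float] = None
    ddg_barrier: Optional[float] = None


def variant_ledger(
    fmap: FreeEnergyMap, correspondence: Iterable[tuple[str, str]]
) -> list[VariantRow]:
    """ΔΔG (and ΔΔG‡ where both reactions carry a TS) across matched
    reaction pairs, e.g. bisulfite vs non-sulfur variants of a step."""
    rows = []
    for base_id, variant_id in correspondence:
        if base_id not in fmap.reactions or variant_id not in fmap.reactions:
            missing = [i for i in (base_id, variant_id) if i not in fmap.reactions]
            raise ValidationError(f"variant_ledger: unknown reaction ids {missing}")
        base = fmap.reactions[base_id]
        var = fmap.reactions[variant_id]
        dg_b = reaction_delta_g(base, fmap)
        dg_v = reaction_delta_g(var, fmap)
        bar_b = activation_barriers(base, fmap)
        bar_v = activation_barriers(var, fmap)
        have_both = isinstance(bar_b, BarrierSet) and isinstance(bar_v, BarrierSet)
        rows.append(
            VariantRow(
                base_id=base_id,
                variant_id=variant_id,
                delta_g_base=dg_b,
                delta_g_variant=dg_v,
                ddg=dg_v - dg_b,
                barrier_base=bar_b.forward if isinstance(bar_b, BarrierSet) else None,
                barrier_variant=bar_v.forward if isinstance(bar_v, BarrierSet) else None,
                ddg_barrier=(bar_v.forward - bar_b.forward) if have_both else None,
            )
        )
    return rows
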