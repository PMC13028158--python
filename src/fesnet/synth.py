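"""Synthetic thermochemistry test data.

Generates species sets with component energies drawn from configurable
distributions, wires them into element-balanced reaction networks whose
energies derive from a single state function (so every Hess cycle closes
exactly), and injects controlled inconsistencies for audit testing.

The numbers produced here are test scaffolding with plausible magnitudes
for small CHOS molecules — not science.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .network import FreeEnergyMap, Reaction, hess_cycle_residuals
from .thermo import (
    ROLE_TRANSITION_STATE,
    Formula,
    ReferenceSet,
    Species,
    ThermoComponents,
    _solve_exact,
    assemble_solution_free_energy,
    compute_grel,
    default_reference_set,
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_species: int = 20
    #: inclusive (lo, hi) ranges per element
    c_range: tuple[int, int] = (1, 5)
    h_range: tuple[int, int] = (2, 12)
    o_range: tuple[int, int] = (1, 8)
    s_range: tuple[int, int] = (0, 2)
    e_zpe_mean: float = -50.0
    e_zpe_sd: float = 20.0
    h_corr_mean: float = 3.0
    h_corr_sd: float = 1.0
    s_gas_mean: float = 0.08
    s_gas_sd: float = 0.02
    g_solv_mean: float = -8.0
    g_solv_sd: float = 4.0
    ts_offset_min: float = 2.0
    ts_offset_mean: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for name in ("e_zpe_sd", "h_corr_sd", "s_gas_sd", "g_solv_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.ts_offset_min <= 0 or self.ts_offset_mean <= 0:
            raise ValidationError("TS offsets must be positive")
        for name in ("c_range", "h_range", "o_range", "s_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValidationError(f"degenerate element range {name}={lo, hi}")
        if self.n_species < 0:
            raise ValidationError("n_species must be >= 0")


@dataclass(frozen=True)
class CorruptionRecord:
    species_id: str
    reaction_id: str
    shift: float
    seed: int
    below_threshold: bool = False

    def __post_init__(self):
        if self.shift == 0:
            raise ValidationError("corruption shift must be nonzero")


def _draw_components(rng: np.random.Generator, cfg: GeneratorConfig) -> ThermoComponents:
    s_gas = abs(rng.normal(cfg.s_gas_mean, cfg.s_gas_sd))
    if s_gas == 0.0:
        s_gas = cfg.s_gas_mean or 1e-6
    return ThermoComponents(
        electronic_plus_zpe=rng.normal(cfg.e_zpe_mean, cfg.e_zpe_sd),
        enthalpy_correction=rng.normal(cfg.h_corr_mean, cfg.h_corr_sd),
        gas_entropy=s_gas,
        solvation_g=rng.normal(cfg.g_solv_mean, cfg.g_solv_sd),
    )


def generate_species_set(config: GeneratorConfig) -> list[Species]:
    """Reproducible random species with component energies.

    The four reference species come first (tagged ``reference``) so the
    downstream G_rel computation has a complete basis.
    """
    rng = np.random.default_rng(config.seed)
    out: list[Species] = []
    for rid, formula in default_reference_set().members:
        out.append(
            Species(
                id=rid,
                formula=formula,
                components=_draw_components(rng, config),
                tags=frozenset({"reference"}),
            )
        )
    for i in range(config.n_species):
        while True:
            c = int(rng.integers(config.c_range[0], config.c_range[1] + 1))
            h = int(rng.integers(config.h_range[0], config.h_range[1] + 1))
            o = int(rng.integers(config.o_range[0], config.o_range[1] + 1))
            s = int(rng.integers(config.s_range[0], config.s_range[1] + 1))
            if c + h + o + s > 0:
                break
        out.append(
            Species(
                id=f"S{i:03d}",
                formula=Formula(c=c, h=h, o=o, s=s),
                components=_draw_components(rng, config),
                tags=frozenset({"synthetic"}),
            )
        )
    return out


def assemble_grel_map(
    species: Sequence[Species],
    temperature: float = 298.15,
    entropy_fraction: float = 0.5,
) -> dict[str, float]:
    """Assemble free energies from components and convert to G_rel."""
    refs = default_reference_set()
    energies = {
        sp.id: assemble_solution_free_energy(sp.components, temperature, entropy_fraction)
        for sp in species
        if sp.components is not None
    }
    out = {}
    for sp in species:
        out[sp.id] = compute_grel(sp, refs, energies)
    return out


@dataclass(frozen=True)
class NetworkRules:
    n_reactions: int = 15
    max_side: int = 2       # species drawn per side before reference balancing
    with_ts: bool = True
    #: how many reactions get a parallel alternate route (same complexes,
    #: its own TS) — guarantees the map has auditable Hess cycles
    duplicate_routes: int = 2


def generate_network(
    species: Sequence[Species],
    rules: Optional[NetworkRules] = None,
    seed: int = 0,
) -> FreeEnergyMap:
    """Build an element-balanced reaction network over generated species.

    Reactions combine randomly drawn species on each side and close the
    element balance exactly with reference species; integer stoichiometry
    is restored by clearing denominators. Each TS is placed at
    ``max(G_reactants, G_products) + offset`` with a strictly positive
    offset, so no generated barrier is submerged. Energies all derive from
    one G_rel store, hence every Hess cycle closes exactly.
    """
    rules = rules or NetworkRules()
    non_ref = [sp for sp in species if "reference" not in sp.tags]
    if len(non_ref) < 2:
        raise ValidationError("need at least 2 non-reference species")
    rng = np.random.default_rng(seed)
    refs = default_reference_set()
    grel = assemble_grel_map(species)
    registry: dict[str, Species] = {
        sp.id: replace(sp, g_rel=grel[sp.id]) for sp in species
    }
    reactions: dict[str, Reaction] = {}
    cfg_offsets = rng.exponential  # keep draw order stable

    attempts = 0
    while len(reactions) < rules.n_reactions and attempts < rules.n_reactions * 50:
        attempts += 1
        n_r = int(rng.integers(1, rules.max_side + 1))
        n_p = int(rng.integers(1, rules.max_side + 1))
        chosen = rng.choice(len(non_ref), size=n_r + n_p, replace=False)
        lhs = [non_ref[i] for i in chosen[:n_r]]
        rhs = [non_ref[i] for i in chosen[n_r:]]
        reactants: dict[str, Fraction] = {sp.id: Fraction(1) for sp in lhs}
        products: dict[str, Fraction] = {sp.id: Fraction(1) for sp in rhs}
        # close the balance with reference species: the reactant side
        # currently exceeds the product side by `diff` atoms
        diff = [0, 0, 0, 0]
        for sp in lhs:
            diff = [d + n for d, n in zip(diff, sp.formula.counts())]
        for sp in rhs:
            diff = [d - n for d, n in zip(diff, sp.formula.counts())]
        matrix = [
            [Fraction(refs.formula(rid).counts()[row]) for rid in refs.ids]
            for row in range(4)
        ]
        x = _solve_exact(matrix, [Fraction(d) for d in diff])
        coeffs = dict(zip(refs.ids, x))  # >0 -> product side
        for rid, c in coeffs.items():
            if c > 0:
                products[rid] = products.get(rid, Fraction(0)) + c
            elif c < 0:
                reactants[rid] = reactants.get(rid, Fraction(0)) + (-c)
        # clear denominators for integer stoichiometry
        denom = 1
        for c in list(reactants.values()) + list(products.values()):
            denom = np.lcm(denom, Fraction(c).denominator)
        reactants_i = {k: int(v * denom) for k, v in reactants.items() if v != 0}
        products_i = {k: int(v * denom) for k, v in products.items() if v != 0}
        shared = set(reactants_i) & set(products_i)
        for sid in shared:
            m = min(reactants_i[sid], products_i[sid])
            reactants_i[sid] -= m
            products_i[sid] -= m
        reactants_i = {k: v for k, v in reactants_i.items() if v > 0}
        products_i = {k: v for k, v in products_i.items() if v > 0}
        if not reactants_i or not products_i:
            continue
        rid = f"R{len(reactions):03d}"
        rxn = Reaction(id=rid, reactants=reactants_i, products=products_i, category="other")
        ts_id = None
        if rules.with_ts:
            g_r = sum(grel.get(s, 0.0) * m for s, m in reactants_i.items())
            g_p = sum(grel.get(s, 0.0) * m for s, m in products_i.items())
            offset = 2.0 + cfg_offsets(8.0)
            ts_formula_counts = [0, 0, 0, 0]
            for s, m in reactants_i.items():
                f = registry[s].formula if s in registry else refs.formula(s)
                ts_formula_counts = [a + b * m for a, b in zip(ts_formula_counts, f.counts())]
            ts_id = f"TS_{rid}"
            registry[ts_id] = Species(
                id=ts_id,
                formula=Formula(*ts_formula_counts),
                role=ROLE_TRANSITION_STATE,
                g_rel=max(g_r, g_p) + offset,
                tags=frozenset({"synthetic"}),
            )
            rxn.ts_id = ts_id
        reactions[rid] = rxn
    if not reactions:
        warnings.warn("no balanceable reaction combinations found; returning empty network")
    # parallel alternate routes: identical complexes, independent TS —
    # these close exact 2-cycles so the Hess audit has something to chew on
    for rid in list(reactions)[: rules.duplicate_routes]:
        src = reactions[rid]
        alt_id = f"{rid}_alt"
        alt = Reaction(
            id=alt_id,
            reactants=dict(src.reactants),
            products=dict(src.products),
            category=src.category,
        )
        if rules.with_ts:
            g_r = sum(grel.get(s, 0.0) * m for s, m in alt.reactants.items())
            g_p = sum(grel.get(s, 0.0) * m for s, m in alt.products.items())
            counts = [0, 0, 0, 0]
            for s, m in alt.reactants.items():
                counts = [a + b * m for a, b in zip(counts, registry[s].formula.counts())]
            ts_id = f"TS_{alt_id}"
            registry[ts_id] = Species(
                id=ts_id,
                formula=Formula(*counts),
                role=ROLE_TRANSITION_STATE,
                g_rel=max(g_r, g_p) + 2.0 + cfg_offsets(8.0),
                tags=frozenset({"synthetic"}),
            )
            alt.ts_id = ts_id
        reactions[alt_id] = alt
    fmap = FreeEnergyMap(species=registry, reactions=reactions)
    fmap.validate()
    return fmap


def corrupt(
    fmap: FreeEnergyMap, magnitude: float, seed: int = 0, audit_tolerance: float = 0.01
) -> tuple[FreeEnergyMap, CorruptionRecord]:
    """Shift one species' G_rel inside a single cycle-borne reaction.

    The perturbation lives in the reaction-local override table, so stored
    species energies stay intact while Hess residuals become nonzero —
    exactly the failure mode the audit is meant to catch.
    """
    if magnitude == 0:
        raise ValidationError("corruption magnitude must be nonzero")
    residuals = hess_cycle_residuals(fmap)
    cycle_rids = sorted({rid for res in residuals for rid, _ in res.reactions})
    candidates = []
    for rid in cycle_rids:
        rxn = fmap.reactions[rid]
        for sid, mult in sorted({**rxn.reactants, **rxn.products}.items()):
            if sid in fmap.reference.ids:
                continue
            if sid in fmap.species and fmap.species[sid].g_rel is not None:
                candidates.append((rid, sid, int(mult)))
    if not candidates:
        raise ValidationError("map has no cycle through a perturbable species; nothing detectable")
    rng = np.random.default_rng(seed)
    rid, sid, mult = candidates[int(rng.integers(len(candidates)))]
    # the cycle residual scales with stoichiometry; divide so the audit sees
    # exactly `magnitude`
    applied = magnitude / mult
    perturbed = FreeEnergyMap(
        species=dict(fmap.species),
        reactions={
            k: Reaction(
                id=r.id,
                reactants=dict(r.reactants),
                products=dict(r.products),
                ts_id=r.ts_id,
                category=r.category,
                annotations=dict(r.annotations),
                local_g_rel=dict(r.local_g_rel),
            )
            for k, r in fmap.reactions.items()
        },
        reference=fmap.reference,
        notes=dict(fmap.notes),
    )
    base = fmap.species[sid].g_rel
    perturbed.reactions[rid].local_g_rel[sid] = base + applied
    record = CorruptionRecord(
        species_id=sid,
        reaction_id=rid,
        shift=applied,
        seed=seed,
        below_threshold=abs(magnitude) <= audit_tolerance,
    )
    return perturbed, record
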