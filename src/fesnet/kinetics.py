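"""Eyring microkinetics on top of the free-energy map.

Selected reactions become reversible mass-action steps with
``k = (k_B T / h) exp(-ΔG‡ / RT)`` and ``k_rev = k_fwd exp(ΔG / RT)``
(detailed balance), at a 1 M standard state for bimolecular steps.
Buffered species (by default water) are held at unit activity and folded
into the rate constants, which also keeps molecularity <= 2 for the
hydrolytic steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .constants import (
    DEFAULT_IMPUTED_BARRIER,
    DEFAULT_TEMPERATURE,
    H_PLANCK,
    K_BOLTZMANN,
    R_KCAL,
)
from .errors import SimulationError, ValidationError
from .network import BarrierSet, FreeEnergyMap, activation_barriers, element_balance_check, reaction_delta_g
from .thermo import Formula


def eyring_rate(barrier: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Transition-state-theory rate constant for an activation free energy
    in kcal/mol (units s^-1, or M^-1 s^-1 at the 1 M standard state)."""
    if not temperature > 0:
        raise ValidationError("temperature must be positive")
    return (K_BOLTZMANN * temperature / H_PLANCK) * math.exp(-barrier / (R_KCAL * temperature))


@dataclass(frozen=True)
class BarrierPolicy:
    """How to assign forward barriers to steps without an optimized TS.

    ``default_barrier`` mirrors the very low (~2 kcal/mol) addition
    barriers; per-reaction overrides take precedence. ``global_offset`` is
    added to every barrier for sensitivity runs (the protocol's known
    systematic 2-3 kcal/mol barrier error).
    """

    default_barrier: Optional[float] = DEFAULT_IMPUTED_BARRIER
    overrides: Mapping[str, float] = field(default_factory=dict)
    global_offset: float = 0.0
    buffered: frozenset[str] = frozenset({"H2O"})


@dataclass
class Step:
    """One reversible elementary step of the ODE model."""

    reaction_id: str
    reactants: dict[str, int]       # dynamic species only
    products: dict[str, int]
    k_fwd: float
    k_rev: float
    delta_g: float
    barrier_fwd: float
    imputed: bool


@dataclass
class KineticModel:
    species_ids: list[str]
    formulas: dict[str, Formula]
    initial: np.ndarray             # mol/L, aligned with species_ids
    steps: list[Step]
    temperature: float
    buffered: frozenset[str]

    def index(self, sid: str) -> int:
        return self.species_ids.index(sid)


def _dynamic_side(side, buffered) -> dict[str, int]:
    out = {}
    for sid, mult in side.items():
        if sid in buffered:
            continue
        m = int(mult)
        if m != mult:
            raise ValidationError(f"non-integer stoichiometry {mult} for {sid!r} in a kinetic step")
        out[sid] = m
    return out


def build_rate_model(
    fmap: FreeEnergyMap,
    selection: Sequence[str],
    initial: Mapping[str, float],
    policy: Optional[BarrierPolicy] = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> KineticModel:
    """Turn selected map reactions into a thermodynamically consistent
    reversible mass-action model.

    Every selected reaction must be element-balanced and must either carry a
    TS or be covered by the barrier policy. Steps of molecularity > 2
    (after removing buffered species) are rejected.
    """
    policy = policy or BarrierPolicy()
    rt = R_KCAL * temperature
    steps: list[Step] = []
    uncovered: list[str] = []
    for rid in selection:
        if rid not in fmap.reactions:
            raise ValidationError(f"unknown reaction id {rid!r}")
        rxn = fmap.reactions[rid]
        imbalance = element_balance_check(rxn, fmap)
        if imbalance:
            raise ValidationError(f"reaction {rid!r} is unbalanced: {imbalance}")
        dg = reaction_delta_g(rxn, fmap)
        barriers = activation_barriers(rxn, fmap)
        imputed = False
        if isinstance(barriers, BarrierSet):
            barrier = barriers.forward
        elif rid in policy.overrides:
            barrier, imputed = policy.overrides[rid], True
        elif policy.default_barrier is not None:
            barrier, imputed = policy.default_barrier, True
        else:
            uncovered.append(rid)
            continue
        barrier += policy.global_offset
        # A barrier below the endergonicity (or below zero) is unphysical
        # for a rate law; clamp so k_rev never exceeds the TST prefactor.
        barrier_eff = max(barrier, dg, 0.0)
        reactants = _dynamic_side(rxn.reactants, policy.buffered)
        products = _dynamic_side(rxn.products, policy.buffered)
        if sum(reactants.values()) > 2 or sum(products.values()) > 2:
            raise ValidationError(
                f"reaction {rid!r}: molecularity > 2 after removing buffered species"
            )
        if not reactants or not products:
            raise ValidationError(f"reaction {rid!r}: a side is entirely buffered")
        k_fwd = eyring_rate(barrier_eff, temperature)
        k_rev = k_fwd * math.exp(dg / rt)
        steps.append(
            Step(
                reaction_id=rid,
                reactants=reactants,
                products=products,
                k_fwd=k_fwd,
                k_rev=k_rev,
                delta_g=dg,
                barrier_fwd=barrier_eff,
                imputed=imputed,
            )
        )
    if uncovered:
        raise ValidationError(
            "no transition state and no barrier policy for: " + ", ".join(uncovered)
        )
    ids = sorted({sid for st in steps for sid in (*st.reactants, *st.products)} | set(initial))
    init = np.array([float(initial.get(sid, 0.0)) for sid in ids])
    if np.any(init < 0):
        raise ValidationError("initial concentrations must be non-negative")
    formulas = {sid: fmap.formula(sid) for sid in ids}
    return KineticModel(
        species_ids=ids,
        formulas=formulas,
        initial=init,
        steps=steps,
        temperature=temperature,
        buffered=policy.buffered,
    )


@dataclass
class Trajectory:
    """Time series of concentrations plus bookkeeping helpers."""

    t: np.ndarray                   # s
    conc: np.ndarray                # species x time, mol/L
    species_ids: list[str]
    formulas: dict[str, Formula]

    def series(self, sid: str) -> np.ndarray:
        return self.conc[self.species_ids.index(sid)]

    def pool(self, pool_ids: Iterable[str]) -> np.ndarray:
        idx = [self.species_ids.index(sid) for sid in pool_ids]
        return self.conc[idx].sum(axis=0)

    def element_total(self, element: str) -> np.ndarray:
        row = {"C": 0, "H": 1, "O": 2, "S": 3}[element]
        weights = np.array([self.formulas[sid].counts()[row] for sid in self.species_ids])
        return weights @ self.conc


def _rhs(model: KineticModel):
    n = len(model.species_ids)
    index = {sid: i for i, sid in enumerate(model.species_ids)}
    compiled = []
    for st in model.steps:
        r_idx = [(index[s], m) for s, m in st.reactants.items()]
        p_idx = [(index[s], m) for s, m in st.products.items()]
        compiled.append((r_idx, p_idx, st.k_fwd, st.k_rev))

    def rhs(_t, y):
        yc = np.maximum(y, 0.0)
        dy = np.zeros(n)
        for r_idx, p_idx, kf, kr in compiled:
            vf = kf
            for i, m in r_idx:
                vf *= yc[i] ** m
            vr = kr
            for i, m in p_idx:
                vr *= yc[i] ** m
            v = vf - vr
            for i, m in r_idx:
                dy[i] -= m * v
            for i, m in p_idx:
                dy[i] += m * v
        return dy

    return rhs


def simulate(
    model: KineticModel,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-14,
    n_points: int = 400,
) -> Trajectory:
    """Integrate the stiff mass-action ODE system to ``t_end`` seconds.

    The reporting grid is log-spaced (plus t = 0) because rate constants
    span many decades. Small negative excursions are clipped to zero.
    """
    if t_end <= 0:
        raise ValidationError("t_end must be positive")
    t_eval = np.concatenate([[0.0], np.geomspace(t_end * 1e-12, t_end, n_points - 1)])
    sol = solve_ivp(
        _rhs(model),
        (0.0, t_end),
        model.initial,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed: {sol.message}",
            t_last=sol.t[-1] if sol.t.size else 0.0,
            y_last=sol.y[:, -1] if sol.y.size else model.initial,
        )
    conc = np.clip(sol.y, 0.0, None)
    return Trajectory(t=sol.t, conc=conc, species_ids=list(model.species_ids), formulas=dict(model.formulas))


@dataclass(frozen=True)
class AutocatalysisMetrics:
    max_per_capita_growth: float    # s^-1, max over time of (dP/dt)/P
    leakage_fraction: float         # consumed C1 carbon ending in the drain pool
    c1_half_depletion_time: Optional[float]


def autocatalysis_metrics(
    traj: Trajectory,
    c2_pool: Sequence[str],
    drain_pool: Sequence[str],
    c1_pool: Sequence[str] = ("1",),
    floor: float = 1e-12,
) -> AutocatalysisMetrics:
    """Quantify autocatalytic throughput vs parasitic leakage.

    The per-capita rate uses the numerically differentiated C2-pool series;
    leakage is carbon-weighted: carbon atoms accumulated in the drain pool
    divided by carbon atoms removed from the C1 food pool.
    """
    for name, pool in (("c2_pool", c2_pool), ("drain_pool", drain_pool), ("c1_pool", c1_pool)):
        if not pool:
            raise ValidationError(f"{name} is empty")
        missing = [sid for sid in pool if sid not in traj.species_ids]
        if missing:
            raise ValidationError(f"{name}: ids absent from trajectory: {missing}")
    p = traj.pool(c2_pool)
    dpdt = np.gradient(p, traj.t)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_capita = np.where(p > floor, dpdt / np.maximum(p, floor), -np.inf)
    max_growth = float(np.max(per_capita))

    def carbon(pool):
        w = np.array([traj.formulas[sid].carbon() for sid in pool])
        idx = [traj.species_ids.index(sid) for sid in pool]
        return w @ traj.conc[idx]

    c1_carbon = carbon(c1_pool)
    consumed = c1_carbon[0] - c1_carbon[-1]
    drained = carbon(drain_pool)[-1] - carbon(drain_pool)[0]
    leakage = float(drained / consumed) if consumed > floor else 0.0

    half = None
    below = np.nonzero(c1_carbon <= 0.5 * c1_carbon[0])[0]
    if below.size:
        half = float(traj.t[below[0]])
    return AutocatalysisMetrics(
        max_per_capita_growth=max_growth,
        leakage_fraction=leakage,
        c1_half_depletion_time=half,
    )
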