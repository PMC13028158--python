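"""Equilibrium analysis of isomer/adduct groups.

Groups are closed at fixed total amount; members must be mutually
interconvertible up to exchange species (reference molecules such as water,
which sit at the map's zero of free energy and therefore do not shift the
comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .constants import DEFAULT_TEMPERATURE, R_KCAL
from .errors import ValidationError
from .network import FreeEnergyMap
from .thermo import ELEMENTS, _solve_exact


@dataclass(frozen=True)
class IsomerGroup:
    """A labelled set of species ids competing for the same material."""

    label: str
    members: tuple[str, ...]
    exchange: tuple[str, ...] = ()

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"group {self.label!r}: duplicate members")


def check_group_balanceable(group: IsomerGroup, fmap: FreeEnergyMap) -> None:
    """Every member must differ from the first by an exact rational
    combination of the exchange species' formulas."""
    if not group.members:
        raise ValidationError(f"group {group.label!r} is empty")
    ref_counts = [fmap.formula(group.members[0]).counts()]
    exch = [fmap.formula(sid).counts() for sid in group.exchange]
    for sid in group.members[1:]:
        diff = [
            Fraction(a - b)
            for a, b in zip(fmap.formula(sid).counts(), ref_counts[0])
        ]
        if all(d == 0 for d in diff):
            continue
        if not exch:
            raise ValidationError(
                f"group {group.label!r}: member {sid!r} differs in formula and no "
                "exchange species are allowed"
            )
        matrix = [[Fraction(col[row]) for col in exch] for row in range(len(ELEMENTS))]
        try:
            _solve_exact(matrix, diff)
        except Exception as exc:
            raise ValidationError(
                f"group {group.label!r}: member {sid!r} is not balanceable against "
                f"{group.members[0]!r} using exchange species {group.exchange}: {exc}"
            ) from exc


def boltzmann_distribution(
    group: IsomerGroup,
    fmap: FreeEnergyMap,
    temperature: float = DEFAULT_TEMPERATURE,
) -> dict[str, float]:
    """Equilibrium fraction of each member.

    ``fraction_i ∝ g_i * exp(-(G_i - G_min)/RT)`` with degeneracy ``g_i``;
    shifting the minimum out first keeps the exponentials well-scaled.
    """
    if not group.members:
        raise ValidationError(f"group {group.label!r} is empty")
    if not temperature > 0:
        raise ValidationError("temperature must be positive")
    check_group_balanceable(group, fmap)
    rt = R_KCAL * temperature
    energies = {sid: fmap.g_rel(sid) for sid in group.members}
    g_min = min(energies.values())
    weights = {
        sid: fmap.species[sid].degeneracy * math.exp(-(g - g_min) / rt)
        if sid in fmap.species
        else math.exp(-(g - g_min) / rt)
        for sid, g in energies.items()
    }
    total = sum(weights.values())
    return {sid: w / total for sid, w in weights.items()}


@dataclass(frozen=True)
class RankEntry:
    species_id: str
    g_rel: float
    rank: int                      # 1-based; tied members share a rank
    gap_from_best: float
    tied: bool


def rank_isomers(
    group: IsomerGroup, fmap: FreeEnergyMap, tie_tolerance: float = 1e-9
) -> list[RankEntry]:
    """Members in ascending G_rel order with gaps from the most stable.

    Ties (within ``tie_tolerance``) share a rank and are ordered
    lexicographically by id.
    """
    if not group.members:
        raise ValidationError(f"group {group.label!r} is empty")
    check_group_balanceable(group, fmap)
    items = sorted(group.members, key=lambda sid: (fmap.g_rel(sid), sid))
    best = fmap.g_rel(items[0])
    entries: list[RankEntry] = []
    rank = 0
    prev_g: Optional[float] = None
    block: list[int] = []
    for i, sid in enumerate(items):
        g = fmap.g_rel(sid)
        if prev_g is None or g - prev_g > tie_tolerance:
            rank = i + 1
            block = [i]
        else:
            block.append(i)
        entries.append(RankEntry(sid, g, rank, g - best, tied=False))
        if len(block) > 1:
            for j in block:
                e = entries[j]
                entries[j] = RankEntry(e.species_id, e.g_rel, rank, e.gap_from_best, tied=True)
        prev_g = g
    return entries


def thermodynamic_sink(group: IsomerGroup, fmap: FreeEnergyMap) -> str:
    """Id of the lowest-G_rel member (lexicographic tie-break)."""
    return rank_isomers(group, fmap)[0].species_id
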