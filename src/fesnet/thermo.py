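"""Solution-phase free-energy assembly and reference-state relative energies.

A species' aqueous free energy is composed from four ingredients computed
upstream by quantum chemistry (which this package does *not* run): the
electronic energy including zero-point correction, the 298.15 K enthalpy
correction, the gas-phase entropy, and the implicit-solvation free energy.
The solvation entropy is approximated as a fixed fraction (default one half)
of the gas-phase entropy.

Relative free energies (``G_rel``) are defined as the free-energy change of
a balanced formation reaction from a reference basis — by default
CO2, H2, H2O and H2SO3, each assigned ``G_rel = 0`` — so that arbitrary
species on the map can be compared on a single scale.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

from .constants import DEFAULT_ENTROPY_FRACTION, DEFAULT_TEMPERATURE
from .errors import BalanceError, FormulaError, MissingEnergyError, ValidationError

ELEMENTS = ("C", "H", "O", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

ROLE_MINIMUM = "minimum"
ROLE_TRANSITION_STATE = "transition_state"
ROLES = frozenset({ROLE_MINIMUM, ROLE_TRANSITION_STATE})


@dataclass(frozen=True)
class Formula:
    """Element counts over the C/H/O/S alphabet.

    Counts are non-negative integers and at least one must be positive.
    """

    c: int = 0
    h: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self):
        for name in ("c", "h", "o", "s"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise FormulaError(f"element count {name.upper()}={v!r} must be a non-negative integer")
        if self.c == 0 and self.h == 0 and self.o == 0 and self.s == 0:
            raise FormulaError("formula must contain at least one atom")

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a formula string permissively (both Hill order ``C2H4O4S``
        and the non-Hill ``C2H4SO4`` are accepted)."""
        s = text.strip()
        if not s:
            raise FormulaError("empty formula")
        counts = {e: 0 for e in ELEMENTS}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(s):
            if m.start() != pos or m.group(0) == "":
                break
            el, num = m.group(1), m.group(2)
            if el not in counts:
                raise FormulaError(f"unsupported element {el!r} in formula {text!r} (allowed: C, H, O, S)")
            counts[el] += int(num) if num else 1
            pos = m.end()
        if pos != len(s):
            raise FormulaError(f"could not parse formula {text!r} at position {pos}")
        return cls(c=counts["C"], h=counts["H"], o=counts["O"], s=counts["S"])

    def counts(self) -> tuple[int, int, int, int]:
        return (self.c, self.h, self.o, self.s)

    def carbon(self) -> int:
        return self.c

    def __str__(self) -> str:
        # Hill order for a carbon-containing compound: C, H, then the rest
        # alphabetically; otherwise fully alphabetical.
        parts = []
        if self.c:
            order = [("C", self.c), ("H", self.h), ("O", self.o), ("S", self.s)]
        else:
            order = [("H", self.h), ("O", self.o), ("S", self.s)]
        for el, n in order:
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)


def _combine(formulas: Sequence[tuple[Formula, int]]) -> tuple[int, int, int, int]:
    tot = [0, 0, 0, 0]
    for f, mult in formulas:
        for i, n in enumerate(f.counts()):
            tot[i] += n * mult
    return tuple(tot)


@dataclass(frozen=True)
class ThermoComponents:
    """Energy decomposition of one species.

    All energies in kcal/mol; ``gas_entropy`` in kcal/(mol*K).
    """

    electronic_plus_zpe: float
    enthalpy_correction: float
    gas_entropy: float
    solvation_g: float

    def __post_init__(self):
        for name in ("electronic_plus_zpe", "enthalpy_correction", "gas_entropy", "solvation_g"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"component {name} is not finite: {v!r}")
        if self.gas_entropy < 0:
            raise ValidationError(f"gas_entropy must be >= 0, got {self.gas_entropy}")


@dataclass(frozen=True)
class Species:
    """A node on the free-energy map.

    Either a direct ``g_rel`` (kcal/mol) or a :class:`ThermoComponents`
    record must be present. ``degeneracy`` counts indistinguishable
    stereo-partners (2 for an enantiomer pair represented once).
    """

    id: str
    formula: Formula
    role: str = ROLE_MINIMUM
    g_rel: Optional[float] = None
    components: Optional[ThermoComponents] = None
    tags: frozenset = frozenset()
    degeneracy: int = 1
    provenance: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"species {self.id!r}: unknown role {self.role!r}")
        if self.g_rel is None and self.components is None:
            raise ValidationError(f"species {self.id!r}: needs g_rel or components")
        if self.g_rel is not None and not math.isfinite(self.g_rel):
            raise ValidationError(f"species {self.id!r}: g_rel is not finite")
        if self.degeneracy < 1:
            raise ValidationError(f"species {self.id!r}: degeneracy must be >= 1")
        if not isinstance(self.tags, frozenset):
            object.__setattr__(self, "tags", frozenset(self.tags))


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered thermodynamic basis; every member has G_rel identically 0."""

    members: tuple[tuple[str, Formula], ...]

    def __post_init__(self):
        ids = [i for i, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValidationError("reference set has duplicate ids")
        if not self.members:
            raise ValidationError("reference set is empty")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.members)

    def formula(self, species_id: str) -> Formula:
        for i, f in self.members:
            if i == species_id:
                return f
        raise KeyError(species_id)


def default_reference_set() -> ReferenceSet:
    """CO2 / H2 / H2O / H2SO3 basis used throughout the shipped map."""
    return ReferenceSet(
        members=(
            ("CO2", Formula.parse("CO2")),
            ("H2", Formula.parse("H2")),
            ("H2O", Formula.parse("H2O")),
            ("H2SO3", Formula.parse("H2SO3")),
        )
    )


def assemble_solution_free_energy(
    components: ThermoComponents,
    temperature: float = DEFAULT_TEMPERATURE,
    entropy_fraction: float = DEFAULT_ENTROPY_FRACTION,
) -> float:
    """Compose the solution-phase free energy of one species.

    ``G = E+ZPE + H_corr - T * f * S_gas + G_solv`` with ``f`` the retained
    entropy fraction (default 0.5).
    """
    if not temperature > 0:
        raise ValidationError(f"temperature must be positive, got {temperature}")
    if not 0.0 <= entropy_fraction <= 1.0:
        raise ValidationError(f"entropy_fraction must lie in [0, 1], got {entropy_fraction}")
    return (
        components.electronic_plus_zpe
        + components.enthalpy_correction
        - temperature * entropy_fraction * components.gas_entropy
        + components.solvation_g
    )


def _solve_exact(matrix: list[list[Fraction]], rhs: list[Fraction]) -> list[Fraction]:
    """Solve ``A x = b`` exactly over the rationals.

    ``A`` is m x n with m >= n required for uniqueness. Raises
    :class:`BalanceError` when the system is singular/ambiguous or
    inconsistent.
    """
    m = len(matrix)
    n = len(matrix[0]) if m else 0
    aug = [row[:] + [rhs[i]] for i, row in enumerate(matrix)]
    pivots = []
    r = 0
    for c in range(n):
        pivot = next((i for i in range(r, m) if aug[i][c] != 0), None)
        if pivot is None:
            continue
        aug[r], aug[pivot] = aug[pivot], aug[r]
        pv = aug[r][c]
        aug[r] = [x / pv for x in aug[r]]
        for i in range(m):
            if i != r and aug[i][c] != 0:
                f = aug[i][c]
                aug[i] = [a - f * b for a, b in zip(aug[i], aug[r])]
        pivots.append(c)
        r += 1
        if r == m:
            break
    if len(pivots) < n:
        free = [c for c in range(n) if c not in pivots]
        raise BalanceError(
            f"reference basis is degenerate: columns {free} are linearly dependent "
            "so formation coefficients are not unique"
        )
    for i in range(r, m):
        if aug[i][n] != 0:
            raise BalanceError("formula lies outside the span of the reference basis")
    x = [Fraction(0)] * n
    for i, c in enumerate(pivots):
        x[c] = aug[i][n]
    return x


def balance_formation(target: Formula, refs: Optional[ReferenceSet] = None) -> dict[str, Fraction]:
    """Balance the formation reaction of ``target`` from the reference basis.

    Returns signed rational coefficients keyed by reference id: positive
    coefficients sit on the reactant side, negative ones on the product side
    alongside the target (itself carrying an implicit coefficient of 1).
    Element conservation is exact.
    """
    refs = refs or default_reference_set()
    matrix = [
        [Fraction(refs.formula(rid).counts()[row]) for rid in refs.ids]
        for row in range(len(ELEMENTS))
    ]
    rhs = [Fraction(n) for n in target.counts()]
    coeffs = _solve_exact(matrix, rhs)
    return dict(zip(refs.ids, coeffs))


def formation_reaction_string(target: Formula, refs: Optional[ReferenceSet] = None) -> str:
    """Human-readable rendering, e.g. ``2 CO2 + 4 H2 + H2SO3 -> C2H4O4S + 3 H2O``."""
    refs = refs or default_reference_set()
    coeffs = balance_formation(target, refs)

    def fmt(rid: str, c: Fraction) -> str:
        c = abs(c)
        return rid if c == 1 else f"{c} {rid}"

    lhs = [fmt(rid, c) for rid, c in coeffs.items() if c > 0]
    rhs = [str(target)] + [fmt(rid, c) for rid, c in coeffs.items() if c < 0]
    return " + ".join(lhs or ["(nothing)"]) + " -> " + " + ".join(rhs)


def compute_grel(
    target: Species,
    refs: Optional[ReferenceSet] = None,
    free_energies: Optional[Mapping[str, float]] = None,
) -> float:
    """Relative free energy of ``target`` as the ΔG of its balanced
    formation reaction.

    ``free_energies`` maps species id -> assembled solution free energy and
    must cover the target and every reference species. Reference species
    themselves come out at exactly 0.
    """
    refs = refs or default_reference_set()
    free_energies = free_energies or {}
    if target.id in refs.ids:
        # The basis defines the zero of the scale.
        return 0.0
    needed = [target.id, *refs.ids]
    missing = [sid for sid in needed if sid not in free_energies]
    if missing:
        raise MissingEnergyError(missing)
    coeffs = balance_formation(target.formula, refs)
    # dG = G(products) - G(reactants); the signed coefficients fold both
    # sides into a single sum.
    dg = free_energies[target.id]
    for rid, c in coeffs.items():
        dg -= float(c) * free_energies[rid]
    return dg
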