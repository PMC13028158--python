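"""Readers/writers for species, reaction, group and scenario files.

Tables are tab-separated text with ``#`` comment lines. Formulas are
accepted both in Hill order (``C2H4O4S``) and in the permissive
non-Hill order (``C2H4SO4``); they are canonicalized to element counts.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import networkx as nx
import yaml

from .errors import TableError, ValidationError
from .network import FreeEnergyMap, Reaction, reaction_delta_g
from .speciation import IsomerGroup
from .thermo import Formula, Species, ThermoComponents

PathLike = Union[str, Path]

SPECIES_COLUMNS = ["id", "formula", "role", "g_rel", "degeneracy", "tags", "provenance"]
COMPONENT_COLUMNS = ["id", "e_zpe", "h_corr", "s_gas", "g_solv"]
REACTION_COLUMNS = ["id", "reactants", "products", "ts_id", "category", "annotation", "overrides"]


def _open(source: Union[PathLike, TextIO], mode="r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, encoding="utf-8", newline=""), True


def _rows(handle: TextIO):
    """Yield (line_number, fields) skipping comments and blank lines."""
    for lineno, line in enumerate(handle, start=1):
        stripped = line.rstrip("\n")
        if not stripped.strip() or stripped.lstrip().startswith("#"):
            continue
        yield lineno, stripped.split("\t")


def read_components_table(source: Union[PathLike, TextIO]) -> dict[str, ThermoComponents]:
    """Companion table of raw energy components keyed by species id."""
    handle, close = _open(source)
    try:
        rows = _rows(handle)
        try:
            _, header = next(rows)
        except StopIteration:
            raise TableError("empty components table")
        if header[: len(COMPONENT_COLUMNS)] != COMPONENT_COLUMNS:
            raise TableError(f"expected columns {COMPONENT_COLUMNS}, got {header}")
        out = {}
        for lineno, fields in rows:
            if len(fields) < 5:
                raise TableError("expected 5 fields", line=lineno)
            sid = fields[0].strip()
            if sid in out:
                raise TableError(f"duplicate id {sid!r}", line=lineno)
            try:
                out[sid] = ThermoComponents(
                    electronic_plus_zpe=float(fields[1]),
                    enthalpy_correction=float(fields[2]),
                    gas_entropy=float(fields[3]),
                    solvation_g=float(fields[4]),
                )
            except (ValueError, ValidationError) as exc:
                raise TableError(str(exc), line=lineno) from exc
        return out
    finally:
        if close:
            handle.close()


def read_species_table(
    source: Union[PathLike, TextIO],
    components: Optional[dict[str, ThermoComponents]] = None,
) -> list[Species]:
    """Parse a species table; raises :class:`TableError` with line numbers."""
    components = components or {}
    handle, close = _open(source)
    try:
        rows = _rows(handle)
        try:
            _, header = next(rows)
        except StopIteration:
            raise TableError("empty species table")
        idx = {name: i for i, name in enumerate(header)}
        for required in ("id", "formula", "role"):
            if required not in idx:
                raise TableError(f"missing required column {required!r} in header {header}")
        seen = set()
        out: list[Species] = []
        for lineno, fields in rows:
            def get(col, default=""):
                i = idx.get(col)
                return fields[i].strip() if i is not None and i < len(fields) else default

            sid = get("id")
            if not sid:
                raise TableError("empty species id", line=lineno)
            if sid in seen:
                raise TableError(f"duplicate species id {sid!r}", line=lineno)
            seen.add(sid)
            try:
                formula = Formula.parse(get("formula"))
            except Exception as exc:
                raise TableError(str(exc), line=lineno) from exc
            g_rel_text = get("g_rel")
            g_rel = None
            if g_rel_text not in ("", "-", "NA", "nan"):
                try:
                    g_rel = float(g_rel_text)
                except ValueError as exc:
                    raise TableError(f"bad g_rel {g_rel_text!r}", line=lineno) from exc
            tags_text = get("tags")
            tags = frozenset(t for t in tags_text.split(";") if t) if tags_text else frozenset()
            try:
                out.append(
                    Species(
                        id=sid,
                        formula=formula,
                        role=get("role") or "minimum",
                        g_rel=g_rel,
                        components=components.get(sid),
                        tags=tags,
                        degeneracy=int(get("degeneracy") or 1),
                        provenance=get("provenance"),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise TableError(str(exc), line=lineno) from exc
        return out
    finally:
        if close:
            handle.close()


def write_species_table(species: Iterable[Species], target: Union[PathLike, TextIO]) -> None:
    handle, close = _open(target, "w")
    try:
        handle.write("\t".join(SPECIES_COLUMNS) + "\n")
        for sp in species:
            handle.write(
                "\t".join(
                    [
                        sp.id,
                        str(sp.formula),
                        sp.role,
                        "" if sp.g_rel is None else repr(sp.g_rel),
                        str(sp.degeneracy),
                        ";".join(sorted(sp.tags)),
                        sp.provenance,
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


def parse_side(text: str) -> dict[str, int]:
    """Parse ``"7 + 1 + H2O"`` / ``"2 H2O + 17"`` into a multiset.

    A leading integer separated by whitespace is a stoichiometric
    coefficient; a bare token (even a numeric one like ``4``) is an id.
    """
    out: dict[str, int] = {}
    for token in text.split("+"):
        token = token.strip()
        if not token:
            raise ValidationError(f"empty term in side {text!r}")
        parts = token.split()
        if len(parts) == 2 and parts[0].isdigit():
            mult, sid = int(parts[0]), parts[1]
        else:
            mult, sid = 1, token
        out[sid] = out.get(sid, 0) + mult
    return out


def format_side(side: dict[str, int]) -> str:
    parts = []
    for sid in sorted(side):
        mult = side[sid]
        if mult == 1:
            parts.append(sid)
        elif sid.isdigit():
            parts.extend([sid] * mult)  # "4 + 4", never the ambiguous "2 4"
        else:
            parts.append(f"{mult} {sid}")
    return " + ".join(parts)


def read_reaction_table(source: Union[PathLike, TextIO]) -> list[Reaction]:
    handle, close = _open(source)
    try:
        rows = _rows(handle)
        try:
            _, header = next(rows)
        except StopIteration:
            raise TableError("empty reaction table")
        idx = {name: i for i, name in enumerate(header)}
        for required in ("id", "reactants", "products"):
            if required not in idx:
                raise TableError(f"missing required column {required!r} in header {header}")
        seen = set()
        out = []
        for lineno, fields in rows:
            def get(col, default=""):
                i = idx.get(col)
                return fields[i].strip() if i is not None and i < len(fields) else default

            rid = get("id")
            if rid in seen:
                raise TableError(f"duplicate reaction id {rid!r}", line=lineno)
            seen.add(rid)
            ts = get("ts_id")
            annotation = get("annotation")
            overrides_text = get("overrides")
            overrides = {}
            if overrides_text and overrides_text != "-":
                try:
                    for term in overrides_text.split(";"):
                        sid, value = term.split("=")
                        overrides[sid.strip()] = float(value)
                except ValueError as exc:
                    raise TableError(f"bad overrides {overrides_text!r}", line=lineno) from exc
            try:
                out.append(
                    Reaction(
                        id=rid,
                        reactants=parse_side(get("reactants")),
                        products=parse_side(get("products")),
                        ts_id=None if ts in ("", "-") else ts,
                        category=get("category") or "other",
                        annotations={"note": annotation} if annotation else {},
                        local_g_rel=overrides,
                    )
                )
            except ValidationError as exc:
                raise TableError(str(exc), line=lineno) from exc
        return out
    finally:
        if close:
            handle.close()


def write_reaction_table(reactions: Iterable[Reaction], target: Union[PathLike, TextIO]) -> None:
    handle, close = _open(target, "w")
    try:
        handle.write("\t".join(REACTION_COLUMNS) + "\n")
        for rxn in reactions:
            handle.write(
                "\t".join(
                    [
                        rxn.id,
                        format_side(rxn.reactants),
                        format_side(rxn.products),
                        rxn.ts_id or "-",
                        rxn.category,
                        str(rxn.annotations.get("note", "")),
                        ";".join(f"{sid}={value!r}" for sid, value in sorted(rxn.local_g_rel.items())) or "-",
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


def read_groups(source: Union[PathLike, TextIO]) -> dict[str, IsomerGroup]:
    handle, close = _open(source)
    try:
        raw = yaml.safe_load(handle.read()) or {}
    finally:
        if close:
            handle.close()
    groups = {}
    for key, spec in raw.items():
        groups[key] = IsomerGroup(
            label=str(spec.get("label", key)),
            members=tuple(str(m) for m in spec["members"]),
            exchange=tuple(str(e) for e in spec.get("exchange", [])),
        )
    return groups


# ---------------------------------------------------------------------------
# map exports
# ---------------------------------------------------------------------------

def map_to_json_dict(fmap: FreeEnergyMap) -> dict:
    """JSON-able document mirroring the internal map (full precision)."""
    return {
        "reference": list(fmap.reference.ids),
        "species": [
            {
                "id": sp.id,
                "formula": str(sp.formula),
                "role": sp.role,
                "g_rel": sp.g_rel,
                "degeneracy": sp.degeneracy,
                "tags": sorted(sp.tags),
                "provenance": sp.provenance,
            }
            for sp in fmap.species.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "reactants": {k: int(v) for k, v in r.reactants.items()},
                "products": {k: int(v) for k, v in r.products.items()},
                "ts_id": r.ts_id,
                "category": r.category,
                "annotations": r.annotations,
                "local_g_rel": r.local_g_rel,
                "delta_g": reaction_delta_g(r, fmap),
            }
            for r in fmap.reactions.values()
        ],
        "notes": fmap.notes,
    }


def export_graphml(fmap: FreeEnergyMap, target: PathLike) -> None:
    """Bipartite expansion: species nodes (with ``g_rel``) and reaction
    nodes (with category/ΔG), directed reactant->reaction->product edges."""
    graph = nx.DiGraph()
    for sid in fmap.reference.ids:
        if sid not in fmap.species:
            graph.add_node(sid, kind="species", g_rel=0.0, formula=str(fmap.reference.formula(sid)))
    for sp in fmap.species.values():
        graph.add_node(
            sp.id,
            kind="species",
            role=sp.role,
            formula=str(sp.formula),
            **({"g_rel": sp.g_rel} if sp.g_rel is not None else {}),
        )
    for rxn in fmap.reactions.values():
        node = f"rxn:{rxn.id}"
        graph.add_node(node, kind="reaction", category=rxn.category, delta_g=reaction_delta_g(rxn, fmap))
        for sid, mult in rxn.reactants.items():
            graph.add_edge(sid, node, stoichiometry=int(mult))
        for sid, mult in rxn.products.items():
            graph.add_edge(node, sid, stoichiometry=int(mult))
        if rxn.ts_id:
            graph.add_edge(f"rxn:{rxn.id}", rxn.ts_id, stoichiometry=0)
    nx.write_graphml(graph, str(target))


@dataclass
class RunConfig:
    """Execution settings shared by the CLI subcommands."""

    temperature: float = 298.15
    entropy_fraction: float = 0.5
    imputed_barrier: float = 2.0
    barrier_offset: float = 0.0
    audit_tolerance: float = 1e-6
    fixture_audit_tolerance: float = 0.15
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        for name in ("audit_tolerance", "fixture_audit_tolerance"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def load_run_config(source: Union[PathLike, TextIO]) -> RunConfig:
    handle, close = _open(source)
    try:
        raw = yaml.safe_load(handle.read()) or {}
    finally:
        if close:
            handle.close()
    return RunConfig(**raw)
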