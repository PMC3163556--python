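"""Loading and validation of the compound-target knowledge base.

Three kinds of resources are handled: a compound library with annotated
compound→protein interactions, an undirected physical protein-protein
interaction (PPI) graph, and named ontologies (collections of gene/protein
categories) in GMT format.  All loaders enforce referential integrity, sort
their contents canonically so in-memory results are independent of input row
order, and log what they loaded.

Identifiers live in one canonical symbol space; an optional two-column mapping
file translates foreign ids at load time (unmapped ids are dropped with a
logged count).
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .chemistry import (
    Fingerprint,
    FingerprintScheme,
    Molecule,
    compute_fingerprint,
    read_smiles_file,
)
from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

EFFECTS = {"activation", "inhibition", "unspecified"}
DIRECTNESS = {"direct", "indirect"}


@dataclass(frozen=True)
class CompoundRecord:
    """One knowledge-base compound with its precomputed fingerprint."""

    compound_id: str
    smiles: str
    molecule: Molecule
    fingerprint: Fingerprint


@dataclass(frozen=True)
class TargetInteraction:
    """An annotated compound→protein interaction."""

    compound_id: str
    protein_id: str
    effect: str = "unspecified"
    directness: str = "direct"

    def __post_init__(self):
        if self.effect not in EFFECTS:
            raise FormatError(f"unknown effect {self.effect!r}")
        if self.directness not in DIRECTNESS:
            raise FormatError(f"unknown directness {self.directness!r}")


@dataclass(frozen=True)
class Ontology:
    """A named collection of categories, each a set of gene/protein ids.

    ``universe`` defaults to the union of category members and is the
    reference population for over-representation tests.
    """

    name: str
    categories: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self):
        for cat, members in self.categories.items():
            if not members:
                raise FormatError(f"ontology category {cat!r} is empty")
            if not members <= self.universe:
                raise FormatError(
                    f"ontology category {cat!r} has members outside the universe"
                )


def load_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV translating foreign ids to the canonical symbol space."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


def _translate(ids: Iterable[str], id_map: Mapping[str, str] | None, what: str) -> list[str]:
    if id_map is None:
        return list(ids)
    out, dropped = [], 0
    for i in ids:
        if i in id_map:
            out.append(id_map[i])
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d unmapped %s ids", dropped, what)
    return out


def load_compound_db(
    structures_path: str | Path,
    interactions_path: str | Path,
    scheme: FingerprintScheme = FingerprintScheme(),
    id_map: Mapping[str, str] | None = None,
) -> tuple[list[CompoundRecord], list[TargetInteraction]]:
    """Load the compound library (.smi) and its interaction table (TSV).

    Fingerprints are precomputed at load.  Raises :class:`IntegrityError` on
    duplicate compound ids or on interaction rows referencing unknown
    compounds (all offenders listed).
    """
    molecules = read_smiles_file(structures_path)
    ids = [m.id for m in molecules]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise IntegrityError(f"duplicate compound ids: {dupes}")

    records = sorted(
        (
            CompoundRecord(
                compound_id=m.id,
                smiles=m.smiles,
                molecule=m,
                fingerprint=compute_fingerprint(m, scheme),
            )
            for m in molecules
        ),
        key=lambda r: r.compound_id,
    )
    known = {r.compound_id for r in records}

    interactions: list[TargetInteraction] = []
    with open(interactions_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"compound_id", "protein_id"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"interaction table missing columns: {sorted(missing)}")
        for row in reader:
            interactions.append(
                TargetInteraction(
                    compound_id=row["compound_id"],
                    protein_id=row["protein_id"],
                    effect=row.get("effect") or "unspecified",
                    directness=row.get("directness") or "direct",
                )
            )

    unknown = sorted({i.compound_id for i in interactions} - known)
    if unknown:
        raise IntegrityError(f"interactions reference unknown compounds: {unknown}")

    if id_map is not None:
        kept = []
        dropped = 0
        for i in interactions:
            if i.protein_id in id_map:
                kept.append(
                    TargetInteraction(i.compound_id, id_map[i.protein_id], i.effect, i.directness)
                )
            else:
                dropped += 1
        if dropped:
            logger.info("dropped %d interactions with unmapped protein ids", dropped)
        interactions = kept

    interactions = sorted(
        set(interactions), key=lambda i: (i.compound_id, i.protein_id, i.effect, i.directness)
    )
    logger.info(
        "loaded %d compounds and %d interactions", len(records), len(interactions)
    )
    return records, interactions


def load_interaction_graph(
    edges_path: str | Path, id_map: Mapping[str, str] | None = None
) -> nx.Graph:
    """Load an undirected PPI graph from a TSV or SIF edge list.

    Edges are deduplicated (undirected); self-loops are dropped with a warning
    count.  Raises :class:`FormatError` with the line number on malformed
    lines.
    """
    graph = nx.Graph()
    self_loops = 0
    with open(edges_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:  # SIF: node relation node
                a, _, b = parts
            else:
                raise FormatError(
                    f"{edges_path}:{lineno}: expected 2 (TSV) or 3 (SIF) columns"
                )
            if id_map is not None:
                if a not in id_map or b not in id_map:
                    continue
                a, b = id_map[a], id_map[b]
            if a == b:
                self_loops += 1
                continue
            graph.add_edge(a, b)
    if self_loops:
        logger.warning("dropped %d self-loop edge(s)", self_loops)
    logger.info(
        "loaded interaction graph: %d nodes, %d edges",
        graph.number_of_nodes(),
        graph.number_of_edges(),
    )
    return graph


def load_ontology(
    gmt_path: str | Path,
    name: str | None = None,
    universe: Iterable[str] | None = None,
    id_map: Mapping[str, str] | None = None,
) -> Ontology:
    """Load an ontology from a GMT file (name, description, members...).

    The universe defaults to the union of all category members; pass
    ``universe`` to override (e.g. with the knowledge-base protein space).
    Raises on empty categories and duplicate category names.
    """
    categories: dict[str, frozenset[str]] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: GMT line needs name, description, >=1 member"
                )
            cat, members = parts[0], [p for p in parts[2:] if p]
            members = _translate(members, id_map, "ontology member")
            if not members:
                raise FormatError(f"{gmt_path}:{lineno}: category {cat!r} is empty")
            if cat in categories:
                raise FormatError(f"{gmt_path}:{lineno}: duplicate category {cat!r}")
            categories[cat] = frozenset(members)
    if not categories:
        raise FormatError(f"{gmt_path}: no categories found")

    union = frozenset().union(*categories.values())
    uni = frozenset(universe) if universe is not None else union
    categories = {c: m & uni for c, m in sorted(categories.items())}
    categories = {c: m for c, m in categories.items() if m}
    return Ontology(
        name=name or Path(gmt_path).stem, categories=categories, universe=uni
    )


def write_gmt(path: str | Path, ont: Ontology) -> None:
    """Write an ontology back to GMT (round-trips membership)."""
    with open(path, "w") as fh:
        for cat in sorted(ont.categories):
            members = "\t".join(sorted(ont.categories[cat]))
            fh.write(f"{cat}\tna\t{members}\n")
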