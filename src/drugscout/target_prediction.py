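"""The structure arm: similarity search, target collection, neighbor
expansion, and the common/similar/unique partition.

A query drug (parent structure plus its predicted metabolites) is compared
against every knowledge-base compound by Tanimoto similarity; compounds at or
above the threshold (default 0.7) contribute their annotated protein targets
to the drug's "possible target" set.  That set is then expanded by one hop in
the physical PPI graph ("first-step interaction partners").  Target sets of
k >= 2 drugs are partitioned into members common to all drugs, shared by
exactly one pair, or unique to one drug.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .chemistry import Fingerprint, tanimoto
from .errors import DrugscoutError, IntegrityError
from .knowledgebase import CompoundRecord, TargetInteraction

DEFAULT_THRESHOLD = 0.7


@dataclass(frozen=True)
class SimilarityHit:
    """A knowledge-base compound retrieved by the similarity search."""

    query_id: str
    db_compound_id: str
    similarity: float


@dataclass
class TargetSet:
    """A drug's protein set at one stage ('possible' or 'expanded').

    ``provenance`` maps each protein to the evidence that brought it in:
    ``("hit", compound_id, similarity)`` for database annotations and
    ``("neighbor-of", seed_protein)`` for network expansion.
    """

    drug_id: str
    stage: str
    members: set[str]
    provenance: dict[str, list[tuple]] = field(default_factory=dict)


@dataclass
class TargetPartition:
    """Decomposition of k drug sets into disjoint membership classes.

    ``common``: members of every set.  ``similar``: members of exactly one
    pair of sets.  ``unique``: members of a single set.  ``multi`` (k >= 4
    only): members of three or more but not all sets.  The classes are
    mutually disjoint and cover the union of the inputs.
    """

    drugs: list[str]
    common: set[str]
    similar: dict[tuple[str, str], set[str]]
    unique: dict[str, set[str]]
    multi: dict[tuple[str, ...], set[str]] = field(default_factory=dict)

    def class_counts(self) -> dict:
        return {
            "common": len(self.common),
            "similar": {"|".join(k): len(v) for k, v in sorted(self.similar.items())},
            "unique": {k: len(v) for k, v in sorted(self.unique.items())},
            "multi": {"|".join(k): len(v) for k, v in sorted(self.multi.items())},
        }


def similarity_search(
    queries: Mapping[str, Fingerprint],
    db: Sequence[CompoundRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[SimilarityHit]:
    """Retrieve all database compounds with Tanimoto >= threshold to any query.

    ``queries`` maps query id (parent or metabolite) to its fingerprint.  A
    database compound similar to several queries is reported once, at its
    maximum similarity.  Hits are sorted by similarity descending, ties broken
    by compound id.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not db:
        raise DrugscoutError("similarity search against an empty database")
    if not queries:
        return []

    best: dict[str, SimilarityHit] = {}
    for rec in db:
        for qid in sorted(queries):
            sim = tanimoto(queries[qid], rec.fingerprint)
            if sim < threshold:
                continue
            cur = best.get(rec.compound_id)
            if cur is None or sim > cur.similarity:
                best[rec.compound_id] = SimilarityHit(qid, rec.compound_id, sim)
    return sorted(best.values(), key=lambda h: (-h.similarity, h.db_compound_id))


def collect_possible_targets(
    hits: Sequence[SimilarityHit],
    interactions: Sequence[TargetInteraction],
    drug_id: str,
) -> TargetSet:
    """Union of annotated targets over all hit compounds, with provenance."""
    by_compound: dict[str, list[TargetInteraction]] = {}
    for i in interactions:
        by_compound.setdefault(i.compound_id, []).append(i)

    members: set[str] = set()
    provenance: dict[str, list[tuple]] = {}
    for hit in hits:
        for inter in by_compound.get(hit.db_compound_id, []):
            members.add(inter.protein_id)
            provenance.setdefault(inter.protein_id, []).append(
                ("hit", hit.db_compound_id, hit.similarity)
            )
    return TargetSet(drug_id=drug_id, stage="possible", members=members, provenance=provenance)


def expand_by_neighbors(t: TargetSet, graph: nx.Graph, hops: int = 1) -> TargetSet:
    """Expand a possible-target set by its first-step PPI partners.

    Seeds are retained; proteins absent from the graph pass through unchanged.
    ``hops`` > 1 repeats the expansion on the grown set.
    """
    if t.stage != "possible":
        raise ValueError("expand_by_neighbors expects a possible-stage target set")
    members = set(t.members)
    provenance = {p: list(v) for p, v in t.provenance.items()}
    frontier = set(members)
    for _ in range(hops):
        added: set[str] = set()
        for seed in sorted(frontier):
            if seed not in graph:
                continue
            for nb in graph.neighbors(seed):
                if nb not in members:
                    added.add(nb)
                    provenance.setdefault(nb, []).append(("neighbor-of", seed))
        members |= added
        frontier = added
        if not added:
            break
    return TargetSet(drug_id=t.drug_id, stage="expanded", members=members, provenance=provenance)


def partition_sets(
    sets: Mapping[str, set[str]] | Sequence[tuple[str, set[str]]],
) -> TargetPartition:
    """Partition k >= 2 named sets by membership pattern.

    Every element of the union is classified by which input sets contain it:
    all k -> common; exactly 2 -> that pair's similar class; exactly 1 ->
    that drug's unique class; otherwise (only possible for k >= 4) -> multi.
    """
    if not isinstance(sets, Mapping):
        names = [n for n, _ in sets]
        if len(names) != len(set(names)):
            raise IntegrityError("duplicate drug_id in partition input")
        sets = dict(sets)
    drugs = sorted(sets)
    if len(drugs) < 2:
        raise ValueError("partition requires at least two sets")

    common: set[str] = set()
    similar: dict[tuple[str, str], set[str]] = {}
    unique: dict[str, set[str]] = {d: set() for d in drugs}
    multi: dict[tuple[str, ...], set[str]] = {}

    union = set().union(*sets.values())
    for element in union:
        holders = tuple(d for d in drugs if element in sets[d])
        if len(holders) == len(drugs):
            common.add(element)
        elif len(holders) == 1:
            unique[holders[0]].add(element)
        elif len(holders) == 2:
            similar.setdefault(holders, set()).add(element)
        else:
            multi.setdefault(holders, set()).add(element)

    # materialize empty pairwise classes so reports always show every pair
    for i, a in enumerate(drugs):
        for b in drugs[i + 1 :]:
            similar.setdefault((a, b), set())
    return TargetPartition(drugs=drugs, common=common, similar=similar, unique=unique, multi=multi)


# ---------------------------------------------------------------------------
# output writers


def write_target_set(path: str | Path, t: TargetSet) -> None:
    """TSV: protein_id, provenance (semicolon-joined evidence records)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tprovenance\n")
        for p in sorted(t.members):
            ev = ";".join(
                ",".join(f"{x:.4f}" if isinstance(x, float) else str(x) for x in rec)
                for rec in t.provenance.get(p, [])
            )
            fh.write(f"{p}\t{ev}\n")


def write_partition(path: str | Path, part: TargetPartition) -> None:
    """TSV: protein_id, class, drugs holding it."""
    rows: list[tuple[str, str, str]] = []
    rows += [(p, "common", "|".join(part.drugs)) for p in part.common]
    for pair, members in part.similar.items():
        rows += [(p, "similar", "|".join(pair)) for p in members]
    for drug, members in part.unique.items():
        rows += [(p, "unique", drug) for p in members]
    for group, members in part.multi.items():
        rows += [(p, "multi", "|".join(group)) for p in members]
    with open(path, "w") as fh:
        fh.write("protein_id\tclass\tdrugs\n")
        for p, cls, drugs in sorted(rows):
            fh.write(f"{p}\t{cls}\t{drugs}\n")


def write_partition_summary(path: str | Path, part: TargetPartition) -> None:
    with open(path, "w") as fh:
        json.dump(part.class_counts(), fh, indent=2, sort_keys=True)
        fh.write("\n")
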