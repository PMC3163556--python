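"""Seeded synthetic-data generators for every pipeline input.

The generators emit a complete, self-consistent study in miniature, with the
ground truth written alongside each file so downstream results can be scored
without any external data:

* a compound library with planted similarity clusters, built by scaffold
  decoration: each cluster shares a large multi-ring scaffold and varies only
  a small substituent, so within-cluster Tanimoto similarity (under the
  default fingerprint) stays above a configurable bound while between-cluster
  similarity stays low.  Constraints are verified at generation and the
  scaffolds are resampled if violated;
* a compound→target table assigning each cluster a characteristic block of
  proteins;
* a random undirected PPI graph with a target expected degree;
* an ontology whose planted category is drawn from a designated cluster's
  target block, so enrichment signal flows through the whole
  compound→target→ontology chain;
* an expression matrix with planted differentially expressed genes wired to
  the same target blocks, so the structure arm and the expression arm of the
  pipeline agree by construction.

Every generator is a pure function of its spec (including the seed).
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .chemistry import FingerprintScheme, compute_fingerprint, parse_structure, tanimoto
from .errors import FixtureError

RING_BLOCKS = [
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "c1ccsc1",
    "c1ccoc1", "C1CCNCC1", "C1CCOCC1", "c1cncnc1",
]
LINKERS = ["C", "CC", "O", "N", "CO"]
BASE_TAILS = ["", "C", "CC", "O", "N", "F", "Cl", "OC", "CCC", "CN", "CCO"]
MAX_BETWEEN_SIMILARITY = 0.5
GENERATION_RETRIES = 30


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the synthetic study, seed included."""

    seed: int = 17
    n_compounds: int = 30
    n_clusters: int = 3
    cluster_tightness: float = 0.7
    n_proteins: int = 300
    graph_degree: float = 4.0
    n_categories: int = 20
    planted_category: str | None = "PLANTED_RESPONSE"
    n_genes: int = 200
    n_samples_per_group: int = 5
    planted_deg_count: int = 20
    planted_log2_effect: float = 2.0
    noise_sigma: float = 0.25
    target_block_size: int = 12

    def __post_init__(self):
        counts = (
            self.n_compounds, self.n_clusters, self.n_proteins, self.n_categories,
            self.n_genes, self.n_samples_per_group, self.target_block_size,
        )
        if any(c <= 0 for c in counts):
            raise FixtureError("all fixture counts must be positive")
        if not 0 < self.cluster_tightness < 1:
            raise FixtureError("cluster_tightness must be in (0, 1)")
        if self.n_clusters * self.target_block_size > self.n_proteins:
            raise FixtureError("n_proteins too small for the requested target blocks")
        if self.n_genes > self.n_proteins:
            raise FixtureError("n_genes must not exceed n_proteins (shared id space)")

    def protein_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(1, self.n_proteins + 1)]

    def gene_ids(self) -> list[str]:
        return self.protein_ids()[: self.n_genes]

    def cluster_block(self, cluster: int) -> list[str]:
        ids = self.protein_ids()
        lo = cluster * self.target_block_size
        return ids[lo : lo + self.target_block_size]


def _tail_pool() -> list[str]:
    return BASE_TAILS + ["C" + t for t in BASE_TAILS if t]


def _sample_scaffolds(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    """One scaffold per cluster, built from a disjoint pair of ring blocks."""
    pairs = list(itertools.combinations(range(len(RING_BLOCKS)), 2))
    disjoint: list[tuple[int, int]] = []
    used: set[int] = set()
    order = rng.permutation(len(pairs))
    for idx in order:
        i, j = pairs[idx]
        if i not in used and j not in used:
            disjoint.append((i, j))
            used |= {i, j}
    if spec.n_clusters > len(disjoint):
        raise FixtureError(
            f"cannot build {spec.n_clusters} chemically separated clusters from "
            f"{len(RING_BLOCKS)} ring blocks; reduce n_clusters to <= {len(disjoint)}"
        )
    scaffolds = []
    for i, j in disjoint[: spec.n_clusters]:
        l1, l2 = rng.choice(LINKERS, size=2)
        b1, b2 = RING_BLOCKS[i], RING_BLOCKS[j]
        scaffolds.append(b1 + l1 + b2 + l2 + b1 + l1 + b2)
    return scaffolds


def generate_compound_db(
    spec: FixtureSpec,
    out_dir: str | Path,
    scheme: FingerprintScheme = FingerprintScheme(),
) -> dict:
    """Write compounds.smi, interactions.tsv and the cluster ground truth.

    Within-cluster pairwise Tanimoto must reach ``cluster_tightness`` and
    between-cluster similarity must stay below 0.5; both are verified over
    all pairs at generation time, and the scaffolds are resampled (bounded
    retries) on violation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_cluster = int(np.ceil(spec.n_compounds / spec.n_clusters))
    tails_all = _tail_pool()
    if per_cluster > len(tails_all):
        raise FixtureError(
            f"at most {len(tails_all)} compounds per cluster supported; "
            "reduce n_compounds or increase n_clusters"
        )

    for attempt in range(GENERATION_RETRIES):
        rng = np.random.default_rng([spec.seed, 1, attempt])
        scaffolds = _sample_scaffolds(spec, rng)
        clusters: list[list] = []
        n_made = 0
        for c, scaf in enumerate(scaffolds):
            take = min(per_cluster, spec.n_compounds - n_made)
            tails = rng.choice(tails_all, size=take, replace=False)
            mols = []
            for t in tails:
                cid = f"CPD{c}{len(mols):03d}"
                mols.append(parse_structure(cid, scaf + t))
            clusters.append(mols)
            n_made += take
        fps = [[compute_fingerprint(m, scheme) for m in cl] for cl in clusters]

        ok = True
        for cl in fps:
            for a, b in itertools.combinations(cl, 2):
                if tanimoto(a, b) < spec.cluster_tightness:
                    ok = False
        for ca, cb in itertools.combinations(fps, 2):
            for a in ca:
                for b in cb:
                    if tanimoto(a, b) >= MAX_BETWEEN_SIMILARITY:
                        ok = False
        if ok:
            break
    else:
        raise FixtureError(
            f"could not satisfy cluster_tightness={spec.cluster_tightness} after "
            f"{GENERATION_RETRIES} attempts; try a lower tightness or fewer clusters"
        )

    rng = np.random.default_rng([spec.seed, 2])
    proteins = spec.protein_ids()
    with open(out_dir / "compounds.smi", "w") as fh:
        for cl in clusters:
            for m in cl:
                fh.write(f"{m.smiles}\t{m.id}\n")

    rows = []
    for c, cl in enumerate(clusters):
        block = spec.cluster_block(c)
        for m in cl:
            n_core = max(2, int(round(len(block) * rng.uniform(0.75, 1.0))))
            core = sorted(rng.choice(block, size=n_core, replace=False))
            off_pool = [p for p in proteins if p not in block]
            extras = sorted(rng.choice(off_pool, size=rng.integers(0, 3), replace=False))
            for p in core + extras:
                effect = rng.choice(["activation", "inhibition", "unspecified"])
                directness = rng.choice(["direct", "indirect"])
                rows.append((m.id, p, effect, directness))
    with open(out_dir / "interactions.tsv", "w") as fh:
        fh.write("compound_id\tprotein_id\teffect\tdirectness\n")
        for r in sorted(rows):
            fh.write("\t".join(r) + "\n")

    truth = {
        "scaffolds": scaffolds,
        "clusters": {m.id: c for c, cl in enumerate(clusters) for m in cl},
        "target_blocks": {str(c): spec.cluster_block(c) for c in range(spec.n_clusters)},
    }
    with open(out_dir / "truth_compounds.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


def generate_interaction_graph(spec: FixtureSpec, out_dir: str | Path) -> nx.Graph:
    """Erdos-Renyi PPI stand-in with expected degree ``graph_degree``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = 0.0 if spec.n_proteins < 2 else spec.graph_degree / (spec.n_proteins - 1)
    seed = int(np.random.default_rng([spec.seed, 3]).integers(0, 2**31 - 1))
    g = nx.gnp_random_graph(spec.n_proteins, min(p, 1.0), seed=seed)
    g = nx.relabel_nodes(g, dict(enumerate(spec.protein_ids())))
    with open(out_dir / "ppi_edges.tsv", "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")
    return g


def generate_ontology(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """GMT ontology with random categories plus one planted category.

    The planted category's members come from cluster 0's target block, so the
    drug assigned to that cluster is enriched for it by construction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([spec.seed, 4])
    proteins = spec.protein_ids()

    categories: dict[str, list[str]] = {}
    if spec.planted_category:
        block = spec.cluster_block(0)
        size = min(10, len(block))
        members = sorted(rng.choice(block, size=size, replace=False))
        categories[spec.planted_category] = members
    n_random = spec.n_categories - len(categories)
    for i in range(1, n_random + 1):
        size = int(rng.integers(5, 26))
        categories[f"CAT_{i:03d}"] = sorted(rng.choice(proteins, size=size, replace=False))

    with open(out_dir / "ontology.gmt", "w") as fh:
        for cat in sorted(categories):
            fh.write(cat + "\tsynthetic\t" + "\t".join(categories[cat]) + "\n")
    truth = {"planted_category": spec.planted_category,
             "planted_members": categories.get(spec.planted_category, [])}
    with open(out_dir / "truth_ontology.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


def generate_expression(
    spec: FixtureSpec,
    out_dir: str | Path,
    drugs: list[str] | None = None,
    drug_clusters: dict[str, int] | None = None,
) -> dict:
    """Expression matrix + design + truth with planted DEGs per drug.

    One control group plus one treatment group per drug, n samples each.
    Each drug's planted gene set is its cluster's target block (up-regulated
    by ``planted_log2_effect``) topped up with random extra genes of random
    direction to reach ``planted_deg_count``.  Intensities are log-normal:
    2 ** (baseline + effect + N(0, noise_sigma)).  A few decoy genes carry an
    absent call on every array to exercise the preprocessing filter.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([spec.seed, 5])
    genes = spec.gene_ids()
    if drugs is None:
        drugs = [f"DRG{i+1}" for i in range(min(spec.n_clusters, 3))]
    if drug_clusters is None:
        drug_clusters = {d: i % spec.n_clusters for i, d in enumerate(drugs)}

    blocks = {d: [g for g in spec.cluster_block(drug_clusters[d]) if g in genes]
              for d in drugs}
    in_any_block = {g for bl in blocks.values() for g in bl}
    free_genes = [g for g in genes if g not in in_any_block]

    planted: dict[str, dict[str, str]] = {}
    for d in drugs:
        chosen = dict.fromkeys(blocks[d][: spec.planted_deg_count], "up")
        n_extra = max(0, spec.planted_deg_count - len(chosen))
        extras = rng.choice(free_genes, size=min(n_extra, len(free_genes)), replace=False)
        for g in extras:
            chosen[g] = str(rng.choice(["up", "down"]))
        planted[d] = chosen

    decoy_pool = [g for g in free_genes if all(g not in planted[d] for d in drugs)]
    decoys = sorted(rng.choice(decoy_pool, size=min(3, len(decoy_pool)), replace=False))

    groups = ["CTRL"] + list(drugs)
    samples = [f"{g}_{i+1}" for g in groups for i in range(spec.n_samples_per_group)]
    baseline = rng.normal(8.0, 1.5, size=len(genes))

    log2 = np.tile(baseline[:, None], (1, len(samples)))
    for d in drugs:
        cols = [j for j, s in enumerate(samples) if s.startswith(d + "_")]
        for g, direction in planted[d].items():
            i = genes.index(g)
            shift = spec.planted_log2_effect if direction == "up" else -spec.planted_log2_effect
            log2[i, cols] += shift
    log2 += rng.normal(0.0, spec.noise_sigma, size=log2.shape)
    values = np.power(2.0, log2)

    matrix = pd.DataFrame(values, index=genes, columns=samples)
    matrix.round(4).to_csv(out_dir / "expression.tsv", sep="\t", index_label="gene")
    presence = pd.DataFrame("P", index=genes, columns=samples)
    presence.loc[decoys, :] = "A"
    presence.to_csv(out_dir / "presence.tsv", sep="\t", index_label="gene")
    with open(out_dir / "design.tsv", "w") as fh:
        fh.write("sample\tgroup\n")
        for s in samples:
            fh.write(f"{s}\t{s.rsplit('_', 1)[0]}\n")

    truth = {"planted": planted, "absent_decoys": decoys,
             "contrasts": {d: [d, "CTRL"] for d in drugs}}
    with open(out_dir / "truth_expression.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


def generate_run_directory(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Emit a complete, ready-to-run fixture study.

    Three query drugs are planted so that DRG1 and DRG2 come from cluster 0
    (structurally similar, shared target block) while DRG3 comes from cluster
    1 — the shared-pair-versus-outlier pattern the partition step must
    recover.  Writes all input files, ground truth, and a config.json that
    the pipeline can run directly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if spec.n_clusters < 2:
        raise FixtureError("a run directory needs at least 2 clusters")

    truth_cpd = generate_compound_db(spec, out_dir)
    generate_interaction_graph(spec, out_dir)
    generate_ontology(spec, out_dir)

    by_cluster: dict[int, list[str]] = {}
    for cid, c in sorted(truth_cpd["clusters"].items()):
        by_cluster.setdefault(c, []).append(cid)
    drug_sources = {"DRG1": by_cluster[0][0], "DRG2": by_cluster[0][1], "DRG3": by_cluster[1][0]}
    smiles_of = {}
    with open(out_dir / "compounds.smi") as fh:
        for line in fh:
            smi, cid = line.strip().split("\t")
            smiles_of[cid] = smi
    with open(out_dir / "queries.smi", "w") as fh:
        for drug, source in drug_sources.items():
            fh.write(f"{smiles_of[source]}\t{drug}\n")

    drugs = list(drug_sources)
    drug_clusters = {d: truth_cpd["clusters"][src] for d, src in drug_sources.items()}
    truth_expr = generate_expression(spec, out_dir, drugs=drugs, drug_clusters=drug_clusters)

    config = {
        "queries": "queries.smi",
        "compound_db": "compounds.smi",
        "interactions": "interactions.tsv",
        "graph": "ppi_edges.tsv",
        "ontologies": ["ontology.gmt"],
        "rules": None,
        "expression": {
            "matrix": "expression.tsv",
            "presence": "presence.tsv",
            "design": "design.tsv",
            "contrasts": truth_expr["contrasts"],
        },
        "params": {},
        "seed": spec.seed,
    }
    with open(out_dir / "config.json", "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
    with open(out_dir / "truth_run.json", "w") as fh:
        json.dump(
            {"drug_sources": drug_sources, "spec": asdict(spec),
             "designated_drug": "DRG1"},
            fh, indent=2, sort_keys=True,
        )
    return out_dir
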