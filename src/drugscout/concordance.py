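"""Concordance between the structure arm and the expression arm, plus the
end-to-end pipeline.

The two arms rank ontology categories for the same drug from independent
evidence: the structure arm from chemical-similarity-derived (and
network-expanded) protein targets, the expression arm from differentially
expressed genes.  Agreement between the two rankings — overlap of the top-k
categories, rank correlation over shared categories, categories significant
in both — is the tool's headline output: because the arms share no inputs,
concordance is independent support for a predicted effect.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Sequence

from scipy import stats

from . import chemistry, knowledgebase, target_prediction, transcriptome
from .enrichment import EnrichmentResult, enrich_set, write_enrichment
from .errors import ConfigError, DrugscoutError, PipelineStageError

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 10
DEFAULT_PARAMS = {
    "threshold": target_prediction.DEFAULT_THRESHOLD,
    "max_path": chemistry.DEFAULT_PATH_LENGTH,
    "n_bits": chemistry.DEFAULT_N_BITS,
    "alpha": transcriptome.DEFAULT_ALPHA,
    "fdr": transcriptome.DEFAULT_FDR,
    "t_alpha": transcriptome.DEFAULT_T_ALPHA,
    "log2_cut": transcriptome.DEFAULT_LOG2_CUT,
    "floor": transcriptome.DEFAULT_FLOOR,
    "top_k": DEFAULT_TOP_K,
    "hops": 1,
    "metabolism_depth": 1,
    "enrich_stage": "expanded",
    "significance": 0.05,
}


@dataclass
class ConcordanceReport:
    """Agreement between two ranked category lists for one drug/ontology."""

    drug_id: str
    ontology: str
    top_structure: list[str]
    top_expression: list[str]
    overlap_count: int
    jaccard_topk: float
    rank_correlation: float | None
    n_shared: int
    shared_significant: list[str]

    def to_dict(self) -> dict:
        return {
            "drug_id": self.drug_id,
            "ontology": self.ontology,
            "top_structure": self.top_structure,
            "top_expression": self.top_expression,
            "overlap_count": self.overlap_count,
            "jaccard_topk": self.jaccard_topk,
            "rank_correlation": self.rank_correlation,
            "n_shared": self.n_shared,
            "shared_significant": self.shared_significant,
        }


def compare_arms(
    structure_arm: Sequence[EnrichmentResult],
    expression_arm: Sequence[EnrichmentResult],
    k: int = DEFAULT_TOP_K,
    drug_id: str = "",
    significance: float = 0.05,
) -> ConcordanceReport:
    """Compare the two arms' category rankings.

    Top-k overlap is summarized by the Jaccard index of the two top-k name
    sets (0 when both are empty).  Rank correlation is Spearman's rho over
    categories present in both lists, reported together with the shared-
    category count; it is None when fewer than two categories are shared.
    ``shared_significant`` lists categories with BH-adjusted p below the
    significance level in both arms.
    """
    onts = {r.ontology for r in structure_arm} | {r.ontology for r in expression_arm}
    if len(onts) > 1:
        raise DrugscoutError(f"arms computed on different ontologies: {sorted(onts)}")
    ontology = onts.pop() if onts else ""

    def topk(arm):
        return [r.category for r in sorted(arm, key=lambda r: r.rank)[:k]]

    top_s, top_e = topk(structure_arm), topk(expression_arm)
    union = set(top_s) | set(top_e)
    inter = set(top_s) & set(top_e)
    jaccard = len(inter) / len(union) if union else 0.0

    rank_s = {r.category: r.rank for r in structure_arm}
    rank_e = {r.category: r.rank for r in expression_arm}
    shared = sorted(set(rank_s) & set(rank_e))
    rho: float | None = None
    if len(shared) >= 2:
        r = stats.spearmanr([rank_s[c] for c in shared], [rank_e[c] for c in shared])
        rho = None if r.statistic != r.statistic else float(r.statistic)  # NaN guard

    sig_s = {r.category for r in structure_arm if r.p_adjusted < significance}
    sig_e = {r.category for r in expression_arm if r.p_adjusted < significance}
    both = sorted(sig_s & sig_e, key=lambda c: (rank_s[c] + rank_e[c], c))

    return ConcordanceReport(
        drug_id=drug_id,
        ontology=ontology,
        top_structure=top_s,
        top_expression=top_e,
        overlap_count=len(inter),
        jaccard_topk=jaccard,
        rank_correlation=rho,
        n_shared=len(shared),
        shared_significant=both,
    )


# ---------------------------------------------------------------------------
# pipeline


_CONFIG_KEYS = {
    "queries", "compound_db", "interactions", "graph", "ontologies",
    "rules", "expression", "params", "seed",
}


def validate_config(config: dict, base_dir: Path) -> dict:
    """Validate and resolve a run configuration before any computation.

    Required keys: queries, compound_db, interactions, graph, ontologies.
    Optional: rules (null = shipped defaults), expression
    (matrix/presence/design/contrasts), params (overrides of DEFAULT_PARAMS),
    seed.  Relative paths are resolved against ``base_dir``.  Raises
    :class:`ConfigError` on schema violations or missing files.
    """
    if not isinstance(config, dict):
        raise ConfigError("config must be a JSON object")
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("queries", "compound_db", "interactions", "graph", "ontologies"):
        if key not in config:
            raise ConfigError(f"config missing required key {key!r}")

    def resolve(p, what):
        path = Path(p)
        if not path.is_absolute():
            path = base_dir / path
        if not path.exists():
            raise ConfigError(f"{what} file not found: {path}")
        return path

    resolved = {
        "queries": resolve(config["queries"], "queries"),
        "compound_db": resolve(config["compound_db"], "compound_db"),
        "interactions": resolve(config["interactions"], "interactions"),
        "graph": resolve(config["graph"], "graph"),
        "seed": int(config.get("seed", 0)),
    }
    onts = config["ontologies"]
    if not isinstance(onts, list) or not onts:
        raise ConfigError("ontologies must be a non-empty list of GMT paths")
    resolved["ontologies"] = [resolve(p, "ontology") for p in onts]
    resolved["rules"] = (
        resolve(config["rules"], "rules") if config.get("rules") else None
    )

    expr = config.get("expression")
    if expr is not None:
        for key in ("matrix", "design", "contrasts"):
            if key not in expr:
                raise ConfigError(f"expression config missing key {key!r}")
        contrasts = expr["contrasts"]
        if not isinstance(contrasts, dict) or not all(
            isinstance(v, (list, tuple)) and len(v) == 2 for v in contrasts.values()
        ):
            raise ConfigError("contrasts must map drug_id -> [treatment, control]")
        resolved["expression"] = {
            "matrix": resolve(expr["matrix"], "expression matrix"),
            "presence": resolve(expr["presence"], "presence") if expr.get("presence") else None,
            "design": resolve(expr["design"], "design"),
            "contrasts": {d: tuple(v) for d, v in contrasts.items()},
        }
    else:
        resolved["expression"] = None

    params = dict(DEFAULT_PARAMS)
    overrides = config.get("params") or {}
    unknown = set(overrides) - set(params)
    if unknown:
        raise ConfigError(f"unknown params: {sorted(unknown)}")
    params.update(overrides)
    if not 0 < params["threshold"] <= 1:
        raise ConfigError("threshold must be in (0, 1]")
    if params["enrich_stage"] not in ("possible", "expanded"):
        raise ConfigError("enrich_stage must be 'possible' or 'expanded'")
    resolved["params"] = params
    return resolved


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, base_dir: str | Path, out_dir: str | Path) -> Path:
    """Execute both arms end to end and write the full report directory.

    Stages: load knowledge base -> per-drug metabolism + similarity search +
    target collection + network expansion -> target partition -> structure-arm
    enrichment -> DEG calling per contrast -> DEG partitions -> expression-arm
    enrichment -> concordance.  A manifest (inputs with content hashes,
    parameters, seed, tool version) makes runs reproducible: identical config
    and inputs give byte-identical outputs.  Any stage error aborts with the
    stage name; partial outputs are flagged in the manifest.
    """
    cfg = validate_config(config, Path(base_dir))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg["params"]
    scheme = chemistry.FingerprintScheme(
        max_path=int(params["max_path"]), n_bits=int(params["n_bits"])
    )

    manifest = {
        "tool": "drugscout",
        "version": _pkg_version("drugscout"),
        "seed": cfg["seed"],
        "parameters": params,
        "inputs": {},
        "complete": False,
    }
    for key in ("queries", "compound_db", "interactions", "graph"):
        manifest["inputs"][key] = {"path": str(cfg[key]), "sha256": _sha256(cfg[key])}
    manifest["inputs"]["ontologies"] = [
        {"path": str(p), "sha256": _sha256(p)} for p in cfg["ontologies"]
    ]
    if cfg["expression"]:
        for key in ("matrix", "presence", "design"):
            p = cfg["expression"][key]
            if p is not None:
                manifest["inputs"][f"expression_{key}"] = {
                    "path": str(p), "sha256": _sha256(p)
                }

    def _write_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    _write_manifest()

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage: %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    _write_manifest()  # leaves complete: false as the partial-run flag
                    raise PipelineStageError(name, exc) from exc

        return _Ctx()

    with stage("load_knowledge_base"):
        records, interactions = knowledgebase.load_compound_db(
            cfg["compound_db"], cfg["interactions"], scheme
        )
        graph = knowledgebase.load_interaction_graph(cfg["graph"])
        ontologies = [knowledgebase.load_ontology(p) for p in cfg["ontologies"]]
        queries = chemistry.read_smiles_file(cfg["queries"])
        rules = (
            chemistry.load_rules(cfg["rules"]) if cfg["rules"] else chemistry.default_rules()
        )

    structure_sets: dict[str, target_prediction.TargetSet] = {}
    structure_enrichment: dict[tuple[str, str], list[EnrichmentResult]] = {}
    with stage("structure_arm"):
        for drug in queries:
            metabolites = chemistry.generate_metabolites(
                drug, rules, depth=int(params["metabolism_depth"])
            )
            chemistry.write_smiles_file(out / f"metabolites_{drug.id}.smi", metabolites)
            fps = {m.id: chemistry.compute_fingerprint(m, scheme) for m in [drug, *metabolites]}
            hits = target_prediction.similarity_search(
                fps, records, threshold=float(params["threshold"])
            )
            with open(out / f"hits_{drug.id}.tsv", "w") as fh:
                fh.write("query_id\tdb_compound_id\tsimilarity\n")
                for h in hits:
                    fh.write(f"{h.query_id}\t{h.db_compound_id}\t{h.similarity:.4f}\n")
            possible = target_prediction.collect_possible_targets(hits, interactions, drug.id)
            expanded = target_prediction.expand_by_neighbors(
                possible, graph, hops=int(params["hops"])
            )
            target_prediction.write_target_set(out / f"targets_possible_{drug.id}.tsv", possible)
            target_prediction.write_target_set(out / f"targets_expanded_{drug.id}.tsv", expanded)
            structure_sets[drug.id] = (
                expanded if params["enrich_stage"] == "expanded" else possible
            )

    with stage("target_partition"):
        if len(structure_sets) >= 2:
            part = target_prediction.partition_sets(
                {d: t.members for d, t in structure_sets.items()}
            )
            target_prediction.write_partition(out / "partition_targets.tsv", part)
            target_prediction.write_partition_summary(out / "partition_targets.json", part)

    with stage("structure_enrichment"):
        for drug_id, tset in structure_sets.items():
            for ont in ontologies:
                res = enrich_set(tset.members, ont)
                structure_enrichment[(drug_id, ont.name)] = res
                write_enrichment(
                    out / f"enrichment_structure_{drug_id}_{ont.name}.tsv", res
                )

    deg_lists_up: dict[str, set[str]] = {}
    deg_lists_down: dict[str, set[str]] = {}
    expression_enrichment: dict[tuple[str, str], list[EnrichmentResult]] = {}
    if cfg["expression"]:
        with stage("expression_arm"):
            values = transcriptome.read_matrix(cfg["expression"]["matrix"])
            presence = (
                transcriptome.read_presence(cfg["expression"]["presence"])
                if cfg["expression"]["presence"] is not None
                else None
            )
            raw = transcriptome.ExpressionMatrix(values=values, presence=presence)
            pre = transcriptome.preprocess_matrix(raw, floor=float(params["floor"]))
            for drug_id, contrast in sorted(cfg["expression"]["contrasts"].items()):
                design = transcriptome.read_design(cfg["expression"]["design"], contrast)
                degs = transcriptome.call_degs(
                    pre, design,
                    alpha=float(params["alpha"]),
                    fdr=float(params["fdr"]),
                    t_alpha=float(params["t_alpha"]),
                )
                transcriptome.write_deg_table(out / f"degs_{drug_id}.tsv", degs)
                up, down = transcriptome.apply_fold_threshold(
                    degs, log2_cut=float(params["log2_cut"])
                )
                transcriptome.write_gene_list(out / f"deg_up_{drug_id}.txt", up)
                transcriptome.write_gene_list(out / f"deg_down_{drug_id}.txt", down)
                deg_lists_up[drug_id] = {r.gene for r in up}
                deg_lists_down[drug_id] = {r.gene for r in down}

        with stage("deg_partition"):
            for direction, lists in (("up", deg_lists_up), ("down", deg_lists_down)):
                if len(lists) >= 2:
                    part = transcriptome.partition_deg_lists(lists)
                    target_prediction.write_partition(
                        out / f"partition_deg_{direction}.tsv", part
                    )
                    target_prediction.write_partition_summary(
                        out / f"partition_deg_{direction}.json", part
                    )

        with stage("expression_enrichment"):
            for drug_id in sorted(cfg["expression"]["contrasts"]):
                deg_genes = deg_lists_up.get(drug_id, set()) | deg_lists_down.get(drug_id, set())
                for ont in ontologies:
                    if not deg_genes or not (deg_genes & ont.universe):
                        expression_enrichment[(drug_id, ont.name)] = []
                        continue
                    res = enrich_set(deg_genes, ont)
                    expression_enrichment[(drug_id, ont.name)] = res
                    write_enrichment(
                        out / f"enrichment_expression_{drug_id}_{ont.name}.tsv", res
                    )

        with stage("concordance"):
            reports = []
            for drug_id in sorted(cfg["expression"]["contrasts"]):
                if drug_id not in structure_sets:
                    continue
                for ont in ontologies:
                    rep = compare_arms(
                        structure_enrichment[(drug_id, ont.name)],
                        expression_enrichment.get((drug_id, ont.name), []),
                        k=int(params["top_k"]),
                        drug_id=drug_id,
                        significance=float(params["significance"]),
                    )
                    reports.append(rep.to_dict())
                    with open(out / f"concordance_{drug_id}_{ont.name}.json", "w") as fh:
                        json.dump(rep.to_dict(), fh, indent=2, sort_keys=True)
                        fh.write("\n")
            with open(out / "concordance.json", "w") as fh:
                json.dump(reports, fh, indent=2, sort_keys=True)
                fh.write("\n")

    manifest["complete"] = True
    _write_manifest()
    return out
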