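"""End-to-end orchestration: overlap -> targets -> enrichment -> mining
-> ranking -> drug shortlist, from a single config.

The two directions (up/down) run the same code with separate
parameterization after the overlap stage — notably the gene-level support
thresholds (0.15 up, 0.40 down).  Every stage's row counts and parameters
are logged and written with the report bundle, and each stage's on-disk
output is sufficient to re-run any later stage in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from fractions import Fraction
from pathlib import Path

import pandas as pd
import yaml

from . import formats
from .drug_filter import (DEFAULT_MIN_SCORE, DEFAULT_TOP_K, DrugInteraction,
                          filter_drugs, select_query_genes)
from .enrichment import (DEFAULT_ADJ_THRESHOLD, DEFAULT_EXCLUSION_KEYWORDS,
                         EnrichmentResult, GeneSetLibrary, TransactionDB,
                         enrich, filter_pathways)
from .errors import ValidationError
from .mining import (DEFAULT_MIN_ITEM_SUPPORT_DOWN, DEFAULT_MIN_ITEM_SUPPORT_UP,
                     DEFAULT_MIN_RULE_SUPPORT, AssociationRule, ItemsetSupport,
                     MiningParams, PathwayScore, apriori, association_rules,
                     rank_pathways, render_support)
from .overlap import Direction, SharedMirnaSet, find_shared_mirnas
from .synthetic_data import SyntheticBundle, SyntheticConfig, generate_bundle
from .target_mapping import (TargetSets, build_edge_list, collect_targets,
                             filter_strong_mti)

logger = logging.getLogger(__name__)


@dataclass
class InputPaths:
    mirna_a: str
    mirna_b: str
    mti: str
    gmt: list[str]
    drugs: str

    def all_paths(self) -> list[str]:
        return [self.mirna_a, self.mirna_b, self.mti, *self.gmt, self.drugs]


@dataclass
class PipelineConfig:
    """Exactly one of ``inputs`` (real files) or ``synthetic`` is set."""

    inputs: InputPaths | None = None
    synthetic: SyntheticConfig | None = None
    out_dir: str = "crossmir_out"
    seed: int | None = None
    collapse_families: bool = False
    adj_threshold: float = DEFAULT_ADJ_THRESHOLD
    exclusion_keywords: tuple[str, ...] = DEFAULT_EXCLUSION_KEYWORDS
    universe_size: int | None = None
    transaction_genes: str = "overlap"
    min_item_support_up: Fraction = DEFAULT_MIN_ITEM_SUPPORT_UP
    min_item_support_down: Fraction = DEFAULT_MIN_ITEM_SUPPORT_DOWN
    min_rule_support: Fraction = DEFAULT_MIN_RULE_SUPPORT
    min_score: float = DEFAULT_MIN_SCORE
    approved_only: bool = True
    top_k: int = DEFAULT_TOP_K

    def __post_init__(self):
        if (self.inputs is None) == (self.synthetic is None):
            raise ValidationError(
                "config must set exactly one of input paths or a synthetic block")
        if self.inputs is not None:
            missing = [p for p in self.inputs.all_paths()
                       if not Path(p).exists()]
            if missing:
                raise ValidationError(f"input file(s) not found: {missing}")
        if self.synthetic is not None and self.seed is not None:
            self.synthetic = _replace_seed(self.synthetic, self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "inputs" in raw and raw["inputs"] is not None:
            raw["inputs"] = InputPaths(**raw["inputs"])
        if "synthetic" in raw and raw["synthetic"] is not None:
            block = raw["synthetic"]
            raw["synthetic"] = (SyntheticConfig(**block)
                                if isinstance(block, dict) else block)
        if "exclusion_keywords" in raw:
            raw["exclusion_keywords"] = tuple(raw["exclusion_keywords"])
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def mining_params(self, direction: Direction) -> MiningParams:
        mis = (self.min_item_support_up if direction is Direction.UP
               else self.min_item_support_down)
        return MiningParams(min_item_support=mis,
                            min_rule_support=self.min_rule_support)


def _replace_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    kwargs = {f.name: getattr(cfg, f.name) for f in dc_fields(cfg)}
    kwargs["seed"] = seed
    return SyntheticConfig(**kwargs)


@dataclass
class DirectionResult:
    enrichment: list[EnrichmentResult]
    transactions: TransactionDB
    frequent: list[ItemsetSupport]
    rules: list[AssociationRule]
    scores: list[PathwayScore]
    query_genes: set[str]


@dataclass
class RunResult:
    config: PipelineConfig
    shared: SharedMirnaSet
    target_sets: TargetSets
    per_direction: dict[str, DirectionResult]
    shortlist: dict[str, list[DrugInteraction]]
    counts: dict[str, int | float | str]
    manifest: dict = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        bundle = generate_bundle(config.synthetic)
        return (bundle.table_a, bundle.table_b, bundle.mti, bundle.library,
                bundle.drugs, bundle)
    ip = config.inputs
    table_a = formats.read_mirna_table(ip.mirna_a)
    table_b = formats.read_mirna_table(ip.mirna_b)
    mti = formats.read_mti_table(ip.mti)
    libraries = [formats.read_gmt(p, universe_size=None) for p in ip.gmt]
    library = merge_libraries(libraries, universe_size=config.universe_size)
    drugs = formats.read_drug_table(ip.drugs)
    return table_a, table_b, mti, library, drugs, None


def merge_libraries(libraries: list[GeneSetLibrary],
                    universe_size: int | None = None) -> GeneSetLibrary:
    """Concatenate pathway libraries; duplicate pathway names are errors."""
    pathways: dict[str, frozenset[str]] = {}
    for lib in libraries:
        for pid, genes in lib.pathways.items():
            if pid in pathways:
                raise ValidationError(
                    f"pathway {pid!r} appears in more than one library")
            pathways[pid] = genes
    return GeneSetLibrary(name="+".join(l.name for l in libraries),
                          pathways=pathways, universe_size=universe_size)


def run_pipeline(config: PipelineConfig, write: bool = True) -> RunResult:
    """Execute every stage; optionally write the report bundle.

    Deterministic under a fixed config (and seed, in synthetic mode): two
    runs produce byte-identical bundles.
    """
    table_a, table_b, mti, library, drugs, bundle = _load_inputs(config)
    counts: dict[str, int | float | str] = {
        "n_mirnas_a": len(table_a.mirnas()),
        "n_mirnas_b": len(table_b.mirnas()),
        "n_observations_a": len(table_a),
        "n_observations_b": len(table_b),
        "n_mti_records": len(mti),
        "n_library_pathways": len(library),
        "n_drug_records": len(drugs),
    }

    shared = find_shared_mirnas(table_a, table_b,
                                collapse_families=config.collapse_families)
    counts.update(n_shared=len(shared.shared), n_shared_up=len(shared.up),
                  n_shared_down=len(shared.down),
                  n_excluded=len(shared.excluded))
    logger.info("overlap: %d shared (%d up / %d down), %d excluded",
                counts["n_shared"], counts["n_shared_up"],
                counts["n_shared_down"], counts["n_excluded"])

    strong = filter_strong_mti(mti)
    target_sets = collect_targets(shared, strong)
    counts.update(n_strong_mti=len(strong),
                  n_targets_up=len(target_sets.up_targets),
                  n_targets_down=len(target_sets.down_targets),
                  n_missing_mirnas=len(target_sets.missing))
    logger.info("targets: %d up / %d down, %d shared miRNAs missing",
                counts["n_targets_up"], counts["n_targets_down"],
                counts["n_missing_mirnas"])

    per_direction: dict[str, DirectionResult] = {}
    all_query_genes: set[str] = set()
    for direction in (Direction.UP, Direction.DOWN):
        d = direction.value
        query = target_sets.targets(direction)
        if not query:
            per_direction[d] = DirectionResult(
                enrichment=[], transactions=TransactionDB(), frequent=[],
                rules=[], scores=[], query_genes=set())
            counts[f"n_transactions_{d}"] = 0
            continue
        results = enrich(query, library, universe_size=config.universe_size)
        db = filter_pathways(results, adj_threshold=config.adj_threshold,
                             exclusion_keywords=config.exclusion_keywords,
                             transaction_genes=config.transaction_genes,
                             library=library)
        params = config.mining_params(direction)
        frequent = apriori(db, params) if len(db) else []
        rules = association_rules(frequent, db,
                                  config.min_rule_support) if frequent else []
        scores = rank_pathways(db) if len(db) else []
        query_genes = select_query_genes(frequent, config.top_k) if frequent else set()
        all_query_genes |= query_genes
        per_direction[d] = DirectionResult(
            enrichment=results, transactions=db, frequent=frequent,
            rules=rules, scores=scores, query_genes=query_genes)
        counts[f"n_transactions_{d}"] = len(db)
        counts[f"n_frequent_itemsets_{d}"] = len(frequent)
        counts[f"n_rules_{d}"] = len(rules)
        if scores:
            counts[f"top_pathway_{d}"] = scores[0].pathway_id
        logger.info("%s: %d transactions, %d frequent itemsets, %d rules",
                    d, len(db), len(frequent), len(rules))

    shortlist = filter_drugs(drugs, all_query_genes,
                             min_score=config.min_score,
                             approved_only=config.approved_only)
    counts["n_query_genes"] = len(all_query_genes)
    counts["n_shortlisted_drugs"] = sum(len(v) for v in shortlist.values())

    result = RunResult(config=config, shared=shared, target_sets=target_sets,
                       per_direction=per_direction, shortlist=shortlist,
                       counts=counts)
    if write:
        result.manifest = write_bundle(result, table_a, table_b)
    return result


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def _join(genes) -> str:
    return ";".join(sorted(genes))


def result_tables(result: RunResult, table_a, table_b) -> dict[str, pd.DataFrame]:
    shared = result.shared
    label_a, label_b = table_a.disease_label, table_b.disease_label

    shared_rows = []
    for direction, names in (("up", shared.up), ("down", shared.down)):
        for name in sorted(names):
            prov = shared.provenance.get(name, [])
            shared_rows.append({
                "mirna": name, "direction": direction,
                f"studies_{label_a}": ";".join(
                    sorted({s for d, s in prov if d == label_a})),
                f"studies_{label_b}": ";".join(
                    sorted({s for d, s in prov if d == label_b})),
            })
    excluded_rows = [{"mirna": m, "reason": r.value}
                     for m, r in sorted(shared.excluded.items())]

    tables = {
        "shared_mirnas": pd.DataFrame(
            shared_rows, columns=["mirna", "direction", f"studies_{label_a}",
                                  f"studies_{label_b}"]),
        "excluded_mirnas": pd.DataFrame(
            excluded_rows, columns=["mirna", "reason"]),
        "missing_mirnas": pd.DataFrame(
            sorted(result.target_sets.missing), columns=["mirna"]),
        "edge_list": pd.DataFrame(
            build_edge_list(result.target_sets),
            columns=["source", "target", "direction"]),
    }
    for d in ("up", "down"):
        dr = result.per_direction[d]
        tables[f"targets_{d}"] = pd.DataFrame(
            sorted(result.target_sets.targets(Direction(d))), columns=["gene"])
        tables[f"enrichment_{d}"] = pd.DataFrame(
            [{"pathway": r.pathway_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
              "p_value": r.p_value, "adj_p": r.adj_p,
              "overlap_genes": _join(r.overlap_genes)}
             for r in sorted(dr.enrichment,
                             key=lambda r: (r.adj_p, r.pathway_id))],
            columns=["pathway", "k", "K", "n", "N", "p_value", "adj_p",
                     "overlap_genes"])
        tables[f"transactions_{d}"] = pd.DataFrame(
            [{"pathway": pid, "genes": _join(genes)}
             for pid, genes in dr.transactions.transactions],
            columns=["pathway", "genes"])
        tables[f"itemsets_{d}"] = pd.DataFrame(
            [{"items": _join(f.itemset), "count": f.count,
              "support": render_support(f.support)} for f in dr.frequent],
            columns=["items", "count", "support"])
        tables[f"rules_{d}"] = pd.DataFrame(
            [{"antecedent": _join(r.antecedent),
              "consequent": _join(r.consequent),
              "support": render_support(r.support),
              "confidence": render_support(r.confidence)} for r in dr.rules],
            columns=["antecedent", "consequent", "support", "confidence"])
        tables[f"pathway_scores_{d}"] = pd.DataFrame(
            [{"pathway": s.pathway_id, "score": render_support(s.score, 6),
              "rank": s.rank} for s in dr.scores],
            columns=["pathway", "score", "rank"])

    tables["drug_shortlist"] = pd.DataFrame(
        [{"gene": gene, "drug": r.drug,
          "interaction_score": r.interaction_score,
          "approved": "true" if r.approved else "false",
          "sources": ";".join(r.sources)}
         for gene in sorted(result.shortlist)
         for r in result.shortlist[gene]],
        columns=["gene", "drug", "interaction_score", "approved", "sources"])
    tables["summary"] = pd.DataFrame(
        [{"key": k, "value": v} for k, v in result.counts.items()],
        columns=["key", "value"])
    return tables


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_bundle(result: RunResult, table_a, table_b) -> dict:
    config = result.config
    metadata = {
        "mode": "synthetic" if config.synthetic is not None else "files",
        "seed": (config.synthetic.seed if config.synthetic is not None
                 else config.seed),
        "parameters": {
            "adj_threshold": config.adj_threshold,
            "exclusion_keywords": list(config.exclusion_keywords),
            "transaction_genes": config.transaction_genes,
            "min_item_support_up": str(config.min_item_support_up),
            "min_item_support_down": str(config.min_item_support_down),
            "min_rule_support": str(config.min_rule_support),
            "min_score": config.min_score,
            "approved_only": config.approved_only,
            "top_k": config.top_k,
            "collapse_families": config.collapse_families,
        },
        "counts": {k: v for k, v in result.counts.items()},
    }
    if config.inputs is not None:
        metadata["inputs"] = {p: _sha256(p) for p in config.inputs.all_paths()}
    tables = result_tables(result, table_a, table_b)
    return formats.write_report_bundle(tables, config.out_dir, metadata)


def summarize(out_dir) -> str:
    """Human-readable digest of a completed run's bundle."""
    out_dir = Path(out_dir)
    lines = []
    manifest_path = out_dir / "manifest.json"
    if not manifest_path.exists():
        return f"no manifest found under {out_dir}; run the pipeline first"
    manifest = json.loads(manifest_path.read_text())
    lines.append(f"run bundle: {out_dir} ({len(manifest['files'])} files)")

    meta_path = out_dir / "run_metadata.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        lines.append(f"mode={meta.get('mode')} seed={meta.get('seed')}")
        for k, v in sorted(meta.get("counts", {}).items()):
            lines.append(f"  {k} = {v}")
    else:
        lines.append("warning: run_metadata.json missing; partial summary")

    for d in ("up", "down"):
        for name, head in ((f"pathway_scores_{d}", "top pathways"),
                           (f"rules_{d}", "top rules")):
            path = out_dir / f"{name}.tsv"
            if not path.exists():
                lines.append(f"warning: {name}.tsv missing")
                continue
            frame = pd.read_csv(path, sep="\t")
            if frame.empty:
                lines.append(f"{d}: direction empty ({name})")
                continue
            lines.append(f"{d} {head}:")
            for _, row in frame.head(5).iterrows():
                lines.append("  " + " | ".join(str(v) for v in row.values))
    return "\n".join(lines)
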