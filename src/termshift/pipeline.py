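"""End-to-end pipeline: selection → preprocessing → terms → networks →
clustering → cross-tabulation, with a run manifest and stage logging."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from ._util import ConfigurationError
from . import corpus as corpus_mod
from . import network as net
from . import preprocess as pp
from . import terms as tx
from . import crosstab  # noqa: F401  (ensure submodule is loaded)

# the `crosstab` *function* shadows the submodule as a package attribute
import sys

ct = sys.modules["termshift.crosstab"]
from .corpus import Corpus, filter_by_month, read_records, select_seed_records

log = logging.getLogger(__name__)

DEFAULT_SEED_VARIANTS = ("antimicrobial", "antibiotic", "antibacterial", "anti-infective")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """All pipeline parameters; every method parameter is a default here."""

    corpus_path: str = ""
    out_dir: str = "out"
    synonyms_path: str | None = None
    exclusions_path: str | None = None
    compounds_path: str | None = None
    seed_variants: tuple[str, ...] = DEFAULT_SEED_VARIANTS
    canonical_seed: str = "antimicrobial"
    cutoff: str = "2018-04"
    theta: float = 0.3
    top_percentile: float = 0.05
    extract_compounds: bool = True
    cluster_fraction: float = 0.10
    k_override: int | None = None
    dice_pool: str = "pooled"  # pooled | pre | post
    rng_seed: int = 0
    sensitivity_exclude_from: str = "2020-04"
    exclude_record_type: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.theta <= 1.0):
            raise ConfigurationError(f"theta={self.theta} must lie in (0, 1]")
        if not (0.0 < self.top_percentile < 1.0):
            raise ConfigurationError("top_percentile must lie in (0, 1)")
        if self.dice_pool not in ("pooled", "pre", "post"):
            raise ConfigurationError(f"unknown dice_pool {self.dice_pool!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "seed_variants" in data:
            data["seed_variants"] = tuple(data["seed_variants"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seed_variants"] = list(self.seed_variants)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(
    config: PipelineConfig,
    corpus: Corpus | None = None,
    comparison_label: str = "pre vs post",
) -> dict:
    """Execute the full analysis and write the artifact bundle.

    Returns the results dictionary (also written as ``results.json``).
    Artifacts: corpus summary TSV, per-period seed co-occurrence tables,
    per-period GraphML networks + MST + communities, cluster membership
    lists, the association report (TSV) and a run manifest with artifact
    hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    @_stage("load")
    def load() -> Corpus:
        if corpus is not None:
            return corpus
        if not config.corpus_path:
            raise ConfigurationError("corpus_path is required")
        records = read_records(config.corpus_path, cutoff=config.cutoff)
        return Corpus(records)

    full = load()

    @_stage("select")
    def select(c: Corpus) -> Corpus:
        if config.exclude_record_type:
            c = corpus_mod.exclude_record_type(c, config.exclude_record_type)
        sel = select_seed_records(c, list(config.seed_variants))
        for period in sorted(sel.total_per_period):
            kept = sum(1 for r in sel.records if r.period == period)
            total = sel.total_per_period[period]
            log.info(
                "period %s: %d of %d records contain the seed term (%.2f%%)",
                period,
                kept,
                total,
                100.0 * kept / total if total else 0.0,
            )
        return sel

    selected = select(full)

    @_stage("preprocess")
    def preprocess(c: Corpus):
        tables = pp.load_tables(
            config.synonyms_path, config.exclusions_path, config.compounds_path
        )
        # seed variants collapse onto the canonical seed term
        for v in config.seed_variants:
            tables.synonym_map.setdefault(pp.normalize_term(v), config.canonical_seed)
        if config.extract_compounds:
            filtered = []
            for rec in c.records:
                toks = (
                    rec.tokens
                    if isinstance(rec, corpus_mod.TokenizedRecord)
                    else pp.tokenize(rec.text)
                )
                filtered.append(pp.anonymize(pp.pos_filter(toks)))
            candidates = tx.extract_candidates(filtered)
            if candidates:
                scored = tx.score_lr(candidates)
                selected_terms = tx.select_top_percentile(scored, config.top_percentile)
                log.info("extracted %d compound terms", len(selected_terms))
                path = out / "compounds_extracted.tsv"
                tx.write_compounds_tsv(selected_terms, path)
                artifacts["compounds_extracted"] = path
                for s in selected_terms:
                    tables.compound_lexicon.setdefault(
                        s.candidate.parts, " ".join(s.candidate.parts)
                    )
        analyzed = pp.standardize_corpus(c, tables)
        return analyzed, tables

    analyzed, tables = preprocess(selected)

    @_stage("summarize")
    def summarize_stage():
        summary = corpus_mod.summarize(selected, analyzed)
        path = out / "corpus_summary.tsv"
        path.write_text(summary.to_tsv(), encoding="utf-8")
        artifacts["corpus_summary"] = path
        return summary

    summarize_stage()

    @_stage("network")
    def network_stage():
        pooled = net.build_incidence(analyzed)
        results_nets = {}
        union_terms: set[str] = set()
        for period in ("pre", "post"):
            m = pooled.for_period(period)
            if m.n_records == 0:
                log.warning("no records in period %s; skipping network", period)
                continue
            table = net.seed_cooccurring_terms(m, config.canonical_seed, config.theta)
            tpath = out / f"seed_cooccurrence_{period}.tsv"
            table.to_csv(tpath, sep="\t", index=False)
            artifacts[f"seed_cooccurrence_{period}"] = tpath
            G = net.build_network(m, config.canonical_seed, config.theta)
            partition = net.detect_communities(G, random_seed=config.rng_seed)
            gpath = out / f"network_{period}.graphml"
            net.export_graphml(G, gpath, partition)
            artifacts[f"network_{period}"] = gpath
            if G.number_of_nodes() > 1:
                T = net.max_spanning_tree(G)
                mpath = out / f"mst_{period}.graphml"
                net.export_graphml(T, mpath, partition)
                artifacts[f"mst_{period}"] = mpath
            comm_sets = partition.communities()
            log.info(
                "period %s: %d direct co-occurring terms, %d network nodes, "
                "%d communities",
                period,
                len(table),
                G.number_of_nodes(),
                len(comm_sets),
            )
            results_nets[period] = {
                "direct_cooccurring_terms": int(len(table)),
                "network_nodes": int(G.number_of_nodes()),
                "network_edges": int(G.number_of_edges()),
                "communities": len(comm_sets),
                "modularity": partition.modularity,
                "community_members": [sorted(s) for s in comm_sets],
            }
            union_terms |= set(G.nodes)
        return pooled, results_nets, sorted(union_terms)

    pooled, results_nets, union_terms = network_stage()

    @_stage("cluster")
    def cluster_stage():
        if len(union_terms) < 2:
            log.warning("fewer than 2 network terms; skipping clustering")
            return None, None
        pool = pooled if config.dice_pool == "pooled" else pooled.for_period(config.dice_pool)
        D = ct.dissimilarity_matrix(pool, union_terms)
        Z = ct.ward_cluster(D)
        assignment = ct.cut_clusters(
            Z, union_terms, config.cluster_fraction, config.k_override
        )
        members = {cid: assignment.members(cid) for cid in assignment.clusters()}
        path = out / "cluster_members.json"
        path.write_text(
            json.dumps({str(k): v for k, v in members.items()}, indent=2),
            encoding="utf-8",
        )
        artifacts["cluster_members"] = path
        log.info("clustered %d terms into %d groups", len(union_terms), assignment.k)
        return assignment, members

    assignment, members = cluster_stage()

    @_stage("crosstab")
    def crosstab_stage():
        if assignment is None:
            return []
        incidence = ct.record_cluster_incidence(pooled, assignment)
        tables2 = ct.crosstab(incidence, pooled.periods)
        results = ct.associate(assignment, tables2)
        report = ct.results_table(results)
        path = out / "association_report.tsv"
        report.to_csv(path, sep="\t", index=False)
        artifacts["association_report"] = path
        return results

    assoc = crosstab_stage()

    results = {
        "comparison": comparison_label,
        "config": config.to_dict(),
        "n_records": {p: int(sum(1 for r in selected.records if r.period == p)) for p in selected.periods()},
        "total_records": dict(selected.total_per_period),
        "networks": results_nets,
        "n_union_terms": len(union_terms),
        "clusters": {str(k): v for k, v in (members or {}).items()},
        "associations": ct.results_json(assoc),
    }
    rpath = out / "results.json"
    rpath.write_text(json.dumps(results, indent=2, sort_keys=True), encoding="utf-8")
    artifacts["results"] = rpath

    manifest = {
        "config": config.to_dict(),
        "rng_seed": config.rng_seed,
        "comparison": comparison_label,
        "artifacts": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in artifacts.items()},
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return results


def run_sensitivity(config: PipelineConfig, corpus: Corpus | None = None) -> dict:
    """Re-run the pipeline excluding months from ``sensitivity_exclude_from``
    onward (pre vs early-post comparison)."""
    if not config.sensitivity_exclude_from:
        raise ConfigurationError("sensitivity_exclude_from must be configured")
    if corpus is None:
        records = read_records(config.corpus_path, cutoff=config.cutoff)
        corpus = Corpus(records)
    filtered = filter_by_month(corpus, config.sensitivity_exclude_from)
    present = {r.period for r in filtered.records}
    if not {"pre", "post"} <= present:
        raise PipelineStageError(
            "stage 'sensitivity' failed: month filter left a period empty"
        )
    sub = dataclasses.replace(config, out_dir=str(Path(config.out_dir) / "sensitivity"))
    return run_pipeline(sub, corpus=filtered, comparison_label="pre vs early-post")
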