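"""End-to-end orchestration: screened corpus through every report table.

``run_all`` executes the full analysis in a fixed stage order and writes
one artifact per report surface (annual statistics, miRNA-by-year matrix,
top-document tables, country tables, clustered networks, keyword top-N),
each stamped with the config hash and seed so a rerun with the same
config is verifiably identical. Any stage failure aborts with the stage
name; artifacts already written are left in place.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import corpus as corpus_io
from . import geo, graphs, keywords, metrics, mirna, synth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths and thresholds of a pipeline run; serialises losslessly."""

    corpus_path: str = "synthetic"  # CSV/JSON path, or "synthetic" for the preset
    screen_path: str | None = None
    catalog_paths: list[str] = field(default_factory=list)  # empty -> bundled
    thesaurus_path: str | None = None
    exclusions_path: str | None = None
    country_aliases_path: str | None = None
    out_dir: str = "bibliomir_out"
    ref_year: int = 2025
    match_threshold: float = 0.90
    min_occurrence: int = 5
    resolution: float = 0.5
    min_cluster_size: int = 10
    max_nodes: int = 30
    walk_length: int = 4
    top_keywords: int = 100
    top_documents: int = 10
    n_records: int = 828  # synthetic preset size
    seed: int = 20240925
    window_end: int | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat: dict = {}
        for key, value in data.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in flat.items() if k in known})

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded)."""
        params = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def _load_corpus(config: RunConfig) -> corpus_io.Corpus:
    if config.corpus_path == "synthetic":
        corpus, _ = synth.generate_corpus(
            synth.study_like_config(seed=config.seed, n_records=config.n_records)
        )
        return corpus
    path = Path(config.corpus_path)
    if path.suffix == ".json":
        return corpus_io.corpus_from_json(path)
    return corpus_io.read_scopus_csv(path)


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns a manifest of outputs and headline numbers."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    manifest: dict = {"stamp": stamp, "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:  # abort with the failing stage named
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            manifest["stages"][name] = result
            return result
        return wrap

    corpus: corpus_io.Corpus | None = None

    @stage("corpus")
    def _corpus():
        nonlocal corpus
        corpus = _load_corpus(config)
        report = None
        if config.screen_path:
            keep = {
                line.strip()
                for line in Path(config.screen_path).read_text().splitlines()
                if line.strip()
            }
            corpus, report = corpus_io.apply_screening(
                corpus, corpus_io.ScreeningList(keep_ids=keep)
            )
        summary = corpus_io.corpus_summary(corpus)
        (out / "corpus_summary.json").write_text(
            json.dumps({**stamp, "summary": summary, "screening": report}, indent=1)
        )
        return {"n_records": len(corpus), "screening": report}

    @stage("annual_stats")
    def _annual():
        rows = metrics.annual_production(corpus)
        with open(out / "annual_stats.tsv", "w") as fh:
            fh.write(f"# {stamp}\nYear\tNP\tPct\tTC\tTC_per_NP\n")
            for r in rows:
                tcnp = "" if r.TC_per_NP is None else f"{r.TC_per_NP}"
                fh.write(f"{r.year}\t{r.NP}\t{r.pct}\t{r.TC}\t{tcnp}\n")
        np_by_year = {r.year: r.NP for r in rows}
        nonzero = [y for y in np_by_year if np_by_year[y] > 0]
        growth = metrics.cagr(np_by_year, min(nonzero), max(nonzero)) if len(nonzero) > 1 else None
        return {
            "n_years": len(rows),
            "total_np": sum(r.NP for r in rows),
            "growth_rate_pct": None if growth is None else growth.rate_pct,
        }

    @stage("mirna_matrix")
    def _mirna():
        catalog = (
            mirna.load_catalog(config.catalog_paths)
            if config.catalog_paths
            else mirna.bundled_catalog()
        )
        matrix = mirna.annual_mirna_matrix(corpus, catalog, window_end=config.window_end)
        matrix.to_dataframe().to_csv(out / "mirna_matrix.tsv", sep="\t", index=False)
        ranked = mirna.rank_mirnas(matrix, top_n=10, metric="total")
        ranked.to_csv(out / "mirna_top10.tsv", sep="\t", index=False)
        return {
            "n_mirnas": len(matrix.mirnas),
            "top": ranked["miRNA"].tolist()[:3] if len(ranked) else [],
        }

    @stage("citations")
    def _citations():
        scores = metrics.citation_scores(corpus, config.ref_year, config.match_threshold)
        with open(out / "citation_scores.tsv", "w") as fh:
            fh.write(f"# {stamp}\nrecord_id\tGCS\tLCS\tTC_per_year\n")
            for s in scores:
                fh.write(f"{s.record_id}\t{s.GCS}\t{s.LCS}\t{s.TC_per_year:.4f}\n")
        for key in ("GCS", "LCS"):
            table = metrics.top_documents(scores, corpus, key=key, n=config.top_documents)
            table.to_csv(out / f"top_documents_{key.lower()}.tsv", sep="\t", index=False)
        return {
            "total_gcs": sum(s.GCS for s in scores),
            "total_lcs": sum(s.LCS for s in scores),
        }

    @stage("countries")
    def _countries():
        table = geo.load_country_aliases(config.country_aliases_path)
        appearances = geo.author_appearance_counts(corpus, table)
        appearances.to_csv(out / "country_appearances.tsv", sep="\t", index=False)
        scp_mcp, excluded = geo.scp_mcp_counts(corpus, table)
        scp_mcp.to_csv(out / "country_scp_mcp.tsv", sep="\t", index=False)
        return {
            "n_countries": len(appearances),
            "corr_total": int(scp_mcp["corr_articles"].sum()) if len(scp_mcp) else 0,
            "scp_total": int(scp_mcp["SCP"].sum()) if len(scp_mcp) else 0,
            "mcp_total": int(scp_mcp["MCP"].sum()) if len(scp_mcp) else 0,
            "excluded": excluded,
        }

    thesaurus = keywords.load_thesaurus(config.thesaurus_path, config.exclusions_path)
    if not thesaurus.exclusion_set and config.exclusions_path is None:
        thesaurus.exclusion_set = {kw for kw in synth.QUERY_TERMS}

    @stage("networks")
    def _networks():
        table = geo.load_country_aliases(config.country_aliases_path)
        collab = graphs.collaboration_network(corpus, table)
        collab_pruned = graphs.prune_network(collab, max_nodes=config.max_nodes)
        collab_part = (
            graphs.walktrap_communities(collab_pruned, config.walk_length)
            if collab_pruned.nodes
            else graphs.Partition(assignment={})
        )
        graphs.write_graphml(collab_pruned, out / "collaboration.graphml", collab_part)
        cooc = graphs.cooccurrence_network(
            corpus, thesaurus, min_occurrence=config.min_occurrence, counting="fractional"
        )
        cooc_norm = graphs.normalize_association(cooc)
        cooc_part = graphs.resolution_clustering(
            cooc_norm,
            resolution=config.resolution,
            min_cluster_size=config.min_cluster_size,
            seed=config.seed,
        )
        graphs.write_graphml(cooc_norm, out / "keyword_network.graphml", cooc_part)
        (out / "keyword_network.json").write_text(graphs.node_link_json(cooc_norm, cooc_part))
        with open(out / "keyword_clusters.tsv", "w") as fh:
            fh.write(f"# {stamp}\nkeyword\tcluster\n")
            for node in sorted(cooc_part.assignment):
                fh.write(f"{node}\t{cooc_part.assignment[node]}\n")
        return {
            "collab_nodes": len(collab_pruned.nodes),
            "collab_clusters": collab_part.n_clusters,
            "keyword_nodes": len(cooc_norm.nodes),
            "keyword_clusters": cooc_part.n_clusters,
        }

    @stage("keywords")
    def _keywords():
        table = keywords.keyword_frequencies(corpus, thesaurus, top_n=config.top_keywords)
        table.to_csv(out / "keyword_top.tsv", sep="\t", index=False)
        return {
            "n_keywords": len(table),
            "head": table.head(3).to_dict(orient="records") if len(table) else [],
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
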