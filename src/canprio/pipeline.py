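"""End-to-end orchestration: ingest -> bicluster -> mSVM-RFE -> enrichment -> filter.

Each stage writes its plain-text intermediates before the next starts, so any
stage can be re-run in isolation, and an identical config + seed produces a
byte-identical summary JSON (wall-clock timing is kept on the in-memory
summary object and logged, but excluded from the serialized summary for that
reason).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .bicluster import bicluster as _bicluster, to_newick
from .enrichment import fisher_enrich, rank_terms, read_gmt, results_to_tsv
from .ingest import read_expression_matrix, read_region_set, subset_regions
from .phenotab import (
    PhenotypeTable,
    annotate_npd,
    filter_by_criteria,
    format_tokens,
    read_phenotype_table,
)
from .rfe import RFEConfig, run_msvm_rfe, top_hub_genes
from .errors import ConfigError, PipelineError

__all__ = ["PipelineConfig", "RunSummary", "run_pipeline"]

log = logging.getLogger("canprio")


@dataclass
class PipelineConfig:
    matrix_path: str
    regions_path: str
    outdir: str
    gene_list_path: str | None = None
    gmt_paths: list[str] = field(default_factory=list)
    phenotype_path: str | None = None
    k_min: int = 2
    k_max: int = 10
    rfe: RFEConfig = field(default_factory=RFEConfig)
    enrich_top: int = 10
    top_hubs: int | None = None  # None -> min(99, n_genes - 1)
    filter_criteria: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        rfe_cfg = RFEConfig(**raw.pop("rfe", {}))
        criteria = [tuple(c) for c in raw.pop("filter_criteria", [])]
        return cls(rfe=rfe_cfg, filter_criteria=criteria, **raw)

    def validate(self) -> None:
        for name in ("matrix_path", "regions_path"):
            if not Path(getattr(self, name)).exists():
                raise ConfigError(f"{name}: file not found: {getattr(self, name)}")
        for p in self.gmt_paths:
            if not Path(p).exists():
                raise ConfigError(f"gmt_paths: file not found: {p}")
        if self.gene_list_path and not Path(self.gene_list_path).exists():
            raise ConfigError(f"gene_list_path: file not found: {self.gene_list_path}")
        if self.filter_criteria and not self.phenotype_path:
            raise ConfigError(
                "phenotype_path is required when filter_criteria are requested"
            )
        if self.phenotype_path and not Path(self.phenotype_path).exists():
            raise ConfigError(f"phenotype_path: file not found: {self.phenotype_path}")


@dataclass
class RunSummary:
    seed: int
    genes_requested: int
    genes_retained: int
    regions_used: int
    gene_k: int
    region_k: int
    gene_cluster_sizes: dict[str, int]
    region_cluster_sizes: dict[str, int]
    dropped_zero_variance: list[str]
    rfe_runs: int
    top_hubs: int
    hub_partition: dict[str, int]
    enrichment_top_terms: dict[str, list[str]]
    filtered_candidates: list[str]
    candidate_npd: dict[str, int]
    elapsed_seconds: float = field(default=0.0, compare=False)

    def to_json(self) -> str:
        payload = asdict(self)
        payload.pop("elapsed_seconds")  # keeps equal configs byte-identical
        return json.dumps(payload, indent=2, sort_keys=True)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute all stages in order, writing intermediates under ``config.outdir``."""
    t0 = time.monotonic()
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- ingest ---------------------------------------------------------
    def ingest_stage():
        regions = read_region_set(config.regions_path)
        whitelist = None
        if config.gene_list_path:
            whitelist = [
                line.strip()
                for line in Path(config.gene_list_path).read_text().splitlines()
                if line.strip()
            ]
        matrix, report = read_expression_matrix(config.matrix_path, whitelist)
        matrix = subset_regions(matrix, regions, strict=False)
        report.to_json(out / "ingest_report.json")
        return matrix, regions, report

    matrix, regions, report = _stage("ingest")(ingest_stage)
    log.info("ingest: %d genes x %d regions", *matrix.shape)

    # --- bicluster ------------------------------------------------------
    def cluster_stage():
        res = _bicluster(matrix, regions, config.k_min, config.k_max)
        for assign, fname in ((res.genes, "gene"), (res.regions, "region")):
            frame = assign.to_frame()
            if fname == "gene":
                frame["cluster_name"] = [
                    res.gene_cluster_names.get(c, str(c)) for c in frame["cluster"]
                ]
            frame.to_csv(out / f"{fname}_clusters.tsv", sep="\t", index=False)
            sil = [(k, v) for k, v in sorted(assign.silhouette_by_k.items())]
            with open(out / f"{fname}_silhouette.tsv", "w") as fh:
                fh.write("k\tmean_silhouette\n")
                for k, v in sil:
                    fh.write(f"{k}\t{v:.10g}\n")
            (out / f"{fname}_tree.nwk").write_text(to_newick(assign.tree))
        return res

    clusters = _stage("bicluster")(cluster_stage)
    log.info(
        "bicluster: gene k=%d, region k=%d", clusters.genes.k, clusters.regions.k
    )

    # --- mSVM-RFE -------------------------------------------------------
    def rfe_stage():
        runs, ranking = run_msvm_rfe(
            clusters.z.values,
            clusters.regions.labels,
            clusters.genes.labels,
            config.rfe,
        )
        ranking.table.to_csv(out / "hub_ranking.tsv", sep="\t", index=False)
        with open(out / "rfe_final_sets.tsv", "w") as fh:
            fh.write("run_id\tfinal_features\n")
            for r in runs:
                fh.write(f"{r.run_id}\t{','.join(sorted(r.final_features))}\n")
        n_genes = len(ranking.table)
        top_n = config.top_hubs or min(99, n_genes - 1)
        top_n = min(top_n, n_genes)
        partition = top_hub_genes(ranking, top_n)
        return runs, ranking, partition, top_n

    runs, ranking, partition, top_n = _stage("msvm_rfe")(rfe_stage)
    log.info("rfe: %d runs, top %d hubs", len(runs), top_n)

    # --- enrichment -----------------------------------------------------
    def enrich_stage():
        top_terms: dict[str, list[str]] = {}
        analysis_genes = {g.upper() for g in clusters.z.gene_ids}
        for gmt_path in config.gmt_paths:
            library = read_gmt(gmt_path)
            universe = library.gene_universe() & analysis_genes
            for c in sorted(set(clusters.genes.labels.values())):
                cname = clusters.gene_cluster_names.get(c, str(c))
                query = {
                    g.upper() for g in clusters.genes.members(c)
                } & universe
                if not query or not universe:
                    continue
                results = fisher_enrich(query, library, universe)
                ranked = rank_terms(results, config.enrich_top)
                results_to_tsv(
                    results, out / f"enrichment_{library.name}_{cname}.tsv"
                )
                top_terms[f"{library.name}/{cname}"] = [r.term for r in ranked]
        return top_terms

    top_terms = _stage("enrichment")(enrich_stage)

    # --- phenotype filter -----------------------------------------------
    def filter_stage():
        if not config.phenotype_path:
            return [], {"annotated": 0, "limited_or_none": 0, "unknown": 0}
        table = read_phenotype_table(config.phenotype_path)
        hub_genes = [g for genes in partition.values() for g in genes]
        in_table = [g for g in hub_genes if table.get(g) is not None]
        sub = PhenotypeTable([r for r in table.rows if r.gene_id in set(in_table)])
        candidates = (
            filter_by_criteria(sub, config.filter_criteria) if len(sub) else []
        )
        npd = annotate_npd(table, candidates)
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("gene_id\tmatched_tokens\tnpd_status\n")
            for g in candidates:
                row = table.get(g)
                fh.write(
                    f"{g}\t{format_tokens(row.ecg_tokens)}\t{row.npd_status}\n"
                )
        return candidates, {k: len(v) for k, v in npd.items()}

    candidates, npd_counts = _stage("phenotype_filter")(filter_stage)

    summary = RunSummary(
        seed=config.seed,
        genes_requested=report.requested_genes,
        genes_retained=report.retained_genes,
        regions_used=matrix.shape[1],
        gene_k=clusters.genes.k,
        region_k=clusters.regions.k,
        gene_cluster_sizes={
            clusters.gene_cluster_names.get(c, str(c)): n
            for c, n in sorted(clusters.genes.sizes().items())
        },
        region_cluster_sizes={
            str(c): n for c, n in sorted(clusters.regions.sizes().items())
        },
        dropped_zero_variance=clusters.z.dropped_rows,
        rfe_runs=len(runs),
        top_hubs=top_n,
        hub_partition={
            clusters.gene_cluster_names.get(c, str(c)): len(genes)
            for c, genes in sorted(partition.items(), key=lambda kv: str(kv[0]))
        },
        enrichment_top_terms=top_terms,
        filtered_candidates=candidates,
        candidate_npd=npd_counts,
        elapsed_seconds=time.monotonic() - t0,
    )
    if sum(summary.hub_partition.values()) != summary.top_hubs:
        raise PipelineError("summary inconsistent: hub partition does not sum to top_n")
    (out / "summary.json").write_text(summary.to_json())
    log.info("pipeline finished in %.1fs", summary.elapsed_seconds)
    return summary
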