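"""Synthetic expression bundles with planted, recoverable structure.

The generator emulates the statistical shape of in-situ-hybridization
expression energies (non-negative, right-skewed) over a gene × brain-region
grid, with three planted layers of ground truth:

* region classes — contiguous, as-even-as-possible groups of regions,
  standing in for clustered brain structures;
* gene clusters — each cluster is "on" (log-mean raised by ``signal``) across
  a contiguous "home" subset of the region classes, emulating
  feedforward-type vs feedback-type expression programs;
* informative genes — a subset that carries, on top of its cluster's home
  pattern, an extra ``signal`` bump in exactly one region class inside the
  home set, making the classes linearly separable for the downstream SVM
  stage while staying close to the rest of their gene cluster.

Energies are ``exp(log-mean + Gaussian noise)``, hence strictly positive.
With one gene cluster the home set covers every class and non-informative
genes are exactly flat. A companion region list tags regions whose class
falls in the first cluster's home set as ``feedforward`` and the rest as
``feedback``, and companion phenotype tables / GMT libraries complete a
bundle on which every downstream stage is testable without any download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ingest import ExpressionMatrix, RegionSet, write_expression_matrix
from .enrichment import GeneSetLibrary, write_gmt
from .phenotab import (
    PhenotypeRow,
    PhenotypeTable,
    PhenotypeToken,
    format_tokens,
    write_phenotype_table,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_expression",
    "generate_phenotypes",
    "generate_gmt",
    "write_bundle",
]

# Named substreams fanned out from the single bundle seed, so each artifact
# can be regenerated independently.
STREAM_MATRIX = 0
STREAM_PHENOTYPES = 1
STREAM_GMT = 2


def substream(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one named substream of a bundle seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 100
    n_regions: int = 47
    k_region_clusters: int = 7
    k_gene_clusters: int = 2
    n_informative_genes: int = 15
    signal: float = 3.0  # mean log-energy offset between on and off blocks
    noise_sd: float = 0.3  # log-scale Gaussian noise
    informative_signal: float | None = None  # bump amplitude; defaults to signal
    base: float = 1.0  # baseline log-energy
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_regions", "k_region_clusters", "k_gene_clusters"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_informative_genes < 0 or self.n_informative_genes > self.n_genes:
            raise ConfigError(
                f"n_informative_genes must be in [0, n_genes], got {self.n_informative_genes}"
            )
        if self.k_region_clusters > self.n_regions:
            raise ConfigError("k_region_clusters exceeds n_regions")
        if self.k_gene_clusters > self.n_genes:
            raise ConfigError("k_gene_clusters exceeds n_genes")
        if self.k_gene_clusters > self.k_region_clusters:
            raise ConfigError("k_gene_clusters exceeds k_region_clusters")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.informative_signal is not None and self.informative_signal < 0:
            raise ConfigError(
                f"informative_signal must be >= 0, got {self.informative_signal}"
            )

    @property
    def bump(self) -> float:
        return self.signal if self.informative_signal is None else self.informative_signal


@dataclass
class GroundTruth:
    region_labels: dict[str, int]
    gene_labels: dict[str, int]
    informative_genes: set[str]
    on_class: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "region_labels": self.region_labels,
                    "gene_labels": self.gene_labels,
                    "informative_genes": sorted(self.informative_genes),
                    "on_class": self.on_class,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _even_split(n: int, k: int) -> np.ndarray:
    """Contiguous group label per item, group sizes differing by at most 1."""
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    return np.repeat(np.arange(k), sizes)


def generate_expression(config: SyntheticConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one expression-energy matrix plus its planted ground truth."""
    cfg = config
    rng = substream(cfg.seed, STREAM_MATRIX)

    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    region_ids = [f"REG{j:03d}" for j in range(cfg.n_regions)]

    region_class = _even_split(cfg.n_regions, cfg.k_region_clusters)
    gene_cluster = _even_split(cfg.n_genes, cfg.k_gene_clusters)
    # Home region-class subset per gene cluster (contiguous, even).
    class_home = _even_split(cfg.k_region_clusters, cfg.k_gene_clusters)

    # Informative genes are spread round-robin over gene clusters so every
    # region class keeps discriminative genes.
    by_cluster: list[list[int]] = [
        [g for g in range(cfg.n_genes) if gene_cluster[g] == c]
        for c in range(cfg.k_gene_clusters)
    ]
    interleaved: list[int] = []
    depth = 0
    while len(interleaved) < cfg.n_genes:
        for c in range(cfg.k_gene_clusters):
            if depth < len(by_cluster[c]):
                interleaved.append(by_cluster[c][depth])
        depth += 1
    informative = sorted(interleaved[: cfg.n_informative_genes])

    # On-class per informative gene: cycle through its cluster's home classes.
    on_class: dict[int, int] = {}
    counters = [0] * cfg.k_gene_clusters
    for g in informative:
        c = gene_cluster[g]
        home = np.flatnonzero(class_home == c)
        on_class[g] = int(home[counters[c] % len(home)])
        counters[c] += 1

    log_mean = np.full((cfg.n_genes, cfg.n_regions), cfg.base)
    for g in range(cfg.n_genes):
        home_mask = class_home[region_class] == gene_cluster[g]
        log_mean[g, home_mask] += cfg.signal
        if g in on_class:
            # class-discriminative bump on top of the cluster's home pattern
            log_mean[g, region_class == on_class[g]] += cfg.bump

    noise = rng.normal(0.0, cfg.noise_sd, size=log_mean.shape) if cfg.noise_sd > 0 else 0.0
    values = pd.DataFrame(np.exp(log_mean + noise), index=gene_ids, columns=region_ids)

    matrix = ExpressionMatrix(values, provenance=f"synthetic(seed={cfg.seed})")
    truth = GroundTruth(
        region_labels={region_ids[j]: int(region_class[j]) for j in range(cfg.n_regions)},
        gene_labels={gene_ids[g]: int(gene_cluster[g]) for g in range(cfg.n_genes)},
        informative_genes={gene_ids[g] for g in informative},
        on_class={gene_ids[g]: k for g, k in on_class.items()},
    )
    return matrix, truth


def region_set_for(config: SyntheticConfig, truth: GroundTruth) -> RegionSet:
    """Companion region list; the first gene cluster's home classes are tagged
    feedforward, everything else feedback."""
    class_home = _even_split(config.k_region_clusters, config.k_gene_clusters)
    rows = []
    for rid, cls in truth.region_labels.items():
        role = "feedforward" if class_home[cls] == 0 else "feedback"
        rows.append((rid, rid.lower(), role))
    return RegionSet(pd.DataFrame(rows, columns=["region_id", "acronym", "can_role"]))


def generate_phenotypes(
    genes: list[str],
    fraction_hr_up: float,
    fraction_hrv_down: float,
    seed: int = 0,
) -> PhenotypeTable:
    """Bernoulli-planted HR-up / HRV-down phenotype table for ``genes``."""
    if not genes:
        raise ConfigError("genes list is empty")
    for name, frac in (("fraction_hr_up", fraction_hr_up), ("fraction_hrv_down", fraction_hrv_down)):
        if not 0.0 <= frac <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1], got {frac}")
    rng = substream(seed, STREAM_PHENOTYPES)
    hr_up = rng.random(len(genes)) < fraction_hr_up
    hrv_down = rng.random(len(genes)) < fraction_hrv_down
    behaviors = rng.random(len(genes)) < 0.5
    limited = rng.random(len(genes)) < 0.7

    rows = []
    for i, g in enumerate(genes):
        tokens: set[PhenotypeToken] = set()
        if hr_up[i]:
            tokens.add(PhenotypeToken("HR", "up"))
        if hrv_down[i]:
            tokens.add(PhenotypeToken("HRV", "down"))
        rows.append(
            PhenotypeRow(
                gene_id=g,
                ecg_raw=format_tokens(tokens),
                ecg_tokens=frozenset(tokens),
                behavior_terms=["Hyperactivity"] if behaviors[i] else [],
                npd_status="limited_or_none" if limited[i] else "annotated",
                npd_terms=[] if limited[i] else ["Bipolar disorder"],
            )
        )
    return PhenotypeTable(rows)


def generate_gmt(
    n_terms: int,
    genes: list[str],
    set_size_range: tuple[int, int] = (5, 20),
    seed: int = 0,
    query: list[str] | None = None,
) -> GeneSetLibrary:
    """Random gene-set library with one planted term equal to ``query``.

    The planted term guarantees the downstream enrichment ranking has a term
    with minimal attainable p for that query.
    """
    if n_terms < 0:
        raise ConfigError(f"n_terms must be >= 0, got {n_terms}")
    lo, hi = set_size_range
    if not 1 <= lo <= hi:
        raise ConfigError(f"invalid set_size_range {set_size_range}")
    if hi > len(genes):
        raise ConfigError(
            f"set_size_range upper bound {hi} exceeds gene universe of {len(genes)}"
        )
    if query is not None and not set(query) <= set(genes):
        raise ConfigError("query genes must be drawn from the gene universe")
    rng = substream(seed, STREAM_GMT)
    terms: dict[str, tuple[str, ...]] = {}
    start = 0
    if n_terms > 0 and query:
        terms["PLANTED_QUERY"] = tuple(sorted({g.upper() for g in query}))
        start = 1
    for t in range(start, n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        terms[f"TERM{t:04d}"] = tuple(sorted(genes[m].upper() for m in members))
    return GeneSetLibrary(name=f"synthetic(seed={seed})", terms=terms)


def write_bundle(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a complete analysis bundle under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(config)
    regions = region_set_for(config, truth)
    phenos = generate_phenotypes(
        list(matrix.gene_ids), fraction_hr_up=0.3, fraction_hrv_down=0.1, seed=config.seed
    )
    library = generate_gmt(
        n_terms=25,
        genes=list(matrix.gene_ids),
        set_size_range=(5, min(20, config.n_genes)),
        seed=config.seed,
        query=sorted(truth.informative_genes),
    )
    paths = {
        "matrix": out / "expression.tsv",
        "regions": out / "regions.csv",
        "phenotypes": out / "phenotypes.tsv",
        "gmt": out / "library.gmt",
        "truth": out / "ground_truth.json",
    }
    write_expression_matrix(matrix, paths["matrix"])
    regions.frame.to_csv(paths["regions"], index=False)
    write_phenotype_table(phenos, paths["phenotypes"])
    write_gmt(library, paths["gmt"])
    truth.to_json(paths["truth"])
    return paths
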