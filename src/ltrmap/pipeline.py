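"""End-to-end pipeline: simulate → call → unify → summarize → annotate →
overlay, driven by a single serializable configuration with one seed.

Every stage's random stream is derived deterministically from the top-level
seed, so identical (config, seed) runs produce byte-identical tables. Each
run writes a machine-readable ``manifest.json`` with the package version,
seed, parameter values, and per-stage record counts, and asserts the
pipeline's conservation invariants (pileup area = summed read lengths; sum
of cluster prevalences = unified calls; symmetric sharing matrix).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import ProximityParams, annotate_all
from .calling import SiteCallingParams, call_sites, compute_coverage, sites_to_table
from .expression import (
    ExpressionMatrix,
    OverlayParams,
    ltr_presence_contrast,
    simulate_null_counts,
)
from .io import write_bedgraph, write_site_table
from .synthetic import (
    CohortConfig,
    GenomeModel,
    default_genome,
    simulate_cohort,
    simulate_enrichment_reads,
    simulate_genes,
    write_truth,
)
from .transposome import (
    classify_prevalence,
    clusters_to_table,
    pairwise_shared_matrix,
    population_summary,
    unify_sites,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameter blocks plus run-level settings."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    calling: SiteCallingParams = field(default_factory=SiteCallingParams)
    unify_tolerance: int = 200
    proximity: ProximityParams = field(default_factory=ProximityParams)
    overlay: OverlayParams = field(default_factory=OverlayParams)
    genome: GenomeModel | None = None
    genes_per_mbp: float = 10.0
    n_expression_samples: int = 6
    n_expression_genes: int = 200
    prevalence_k: int = 10
    outdir: str = "ltrmap_run"
    seed: int = 0
    log_level: str = "INFO"
    write_coverage: bool = False

    def __post_init__(self) -> None:
        # the run-level seed overrides per-block seeds so one value governs
        # every random stream
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        self.overlay = dataclasses.replace(
            self.overlay, seed=self.seed
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "cohort": dataclasses.asdict(self.cohort),
            "calling": dataclasses.asdict(self.calling),
            "unify_tolerance": self.unify_tolerance,
            "proximity": dataclasses.asdict(self.proximity),
            "overlay": dataclasses.asdict(self.overlay),
            "genome": None
            if self.genome is None
            else {
                "chromosomes": [list(c) for c in self.genome.chromosomes],
                "env_loci": [list(e) for e in self.genome.env_loci],
            },
            "genes_per_mbp": self.genes_per_mbp,
            "n_expression_samples": self.n_expression_samples,
            "n_expression_genes": self.n_expression_genes,
            "prevalence_k": self.prevalence_k,
            "outdir": self.outdir,
            "seed": self.seed,
            "log_level": self.log_level,
            "write_coverage": self.write_coverage,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            for key in ("individuals_per_population", "shared_site_pool_size"):
                if key in cohort:
                    cohort[key] = tuple(cohort[key])
            cohort = CohortConfig(**cohort)
        calling = d.pop("calling", {})
        if isinstance(calling, dict):
            calling = SiteCallingParams(**calling)
        proximity = d.pop("proximity", {})
        if isinstance(proximity, dict):
            proximity = ProximityParams(**proximity)
        overlay = d.pop("overlay", {})
        if isinstance(overlay, dict):
            overlay = OverlayParams(**overlay)
        genome = d.pop("genome", None)
        if isinstance(genome, dict):
            genome = GenomeModel(
                chromosomes=tuple(tuple(c) for c in genome["chromosomes"]),
                env_loci=tuple(tuple(e) for e in genome.get("env_loci", ())),
            )
        return cls(
            cohort=cohort,
            calling=calling,
            proximity=proximity,
            overlay=overlay,
            genome=genome,
            **d,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Writes per-individual truth and site tables, the cluster table,
    prevalence and population summaries, the sharing matrix, the proximity
    annotation, the expression overlay, and ``manifest.json`` under
    ``config.outdir``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = config.genome or default_genome()
    manifest: dict = {
        "tool": "ltrmap",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
    }

    # -- simulate ----------------------------------------------------------
    logger.info("simulating cohort (seed=%d)", config.seed)
    cohort = _stage("simulate")(simulate_cohort)(config.cohort, genome)
    write_truth(cohort, outdir / "truth")
    manifest["stages"]["simulate"] = {
        "n_individuals": len(cohort.individuals),
        "n_truth_sites": sum(len(v) for v in cohort.truth.values()),
    }

    # -- call sites per individual ----------------------------------------
    sites_by_ind = {}
    flagged_by_ind = {}
    n_reads_total = 0
    sites_dir = outdir / "sites"
    sites_dir.mkdir(exist_ok=True)
    for ind in cohort.individuals:
        reads = _stage("simulate-reads")(simulate_enrichment_reads)(
            cohort, ind, config.cohort
        )
        n_reads_total += len(reads)
        track = compute_coverage(reads)
        area = track.total_area
        read_len_sum = int((reads.reads["end"] - reads.reads["start"]).sum())
        if area != read_len_sum:
            raise RuntimeError(
                f"pipeline stage 'call-sites' failed for {ind}: pileup area "
                f"{area} != summed read length {read_len_sum}"
            )
        kept, flagged = _stage("call-sites")(call_sites)(
            reads, genome.env_loci, config.calling
        )
        sites_by_ind[ind] = kept
        flagged_by_ind[ind] = flagged
        write_site_table(sites_to_table(kept), sites_dir / f"{ind}.sites.tsv")
        write_site_table(
            sites_to_table(flagged), sites_dir / f"{ind}.env_flagged.tsv"
        )
        if config.write_coverage:
            write_bedgraph(
                {c: track.runs[c].tolist() for c in track.runs},
                sites_dir / f"{ind}.coverage.bedgraph",
            )
    manifest["stages"]["call_sites"] = {
        "n_reads": n_reads_total,
        "n_called": sum(len(v) for v in sites_by_ind.values()),
        "n_env_flagged": sum(len(v) for v in flagged_by_ind.values()),
    }

    # -- unify -------------------------------------------------------------
    clusters = _stage("unify")(unify_sites)(sites_by_ind, config.unify_tolerance)
    clusters_to_table(clusters).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False
    )
    n_calls = sum(len(v) for v in sites_by_ind.values())
    n_prev = sum(c.prevalence for c in clusters)
    if n_prev != n_calls:
        raise RuntimeError(
            "pipeline stage 'unify' failed: sum of cluster prevalences "
            f"{n_prev} != unified calls {n_calls}"
        )
    manifest["stages"]["unify"] = {
        "n_calls": n_calls,
        "n_clusters": len(clusters),
    }

    # -- summarize ---------------------------------------------------------
    summary = _stage("summarize")(classify_prevalence)(
        clusters, len(cohort.individuals), k_list=(config.prevalence_k,)
    )
    sharing = pairwise_shared_matrix(clusters, cohort.individuals)
    if not (sharing.to_numpy() == sharing.to_numpy().T).all():
        raise RuntimeError("pipeline stage 'summarize' failed: asymmetric sharing")
    sharing.to_csv(outdir / "sharing_matrix.tsv", sep="\t")
    pop = population_summary(clusters, cohort.populations)
    pop["table"].to_csv(outdir / "population_table.tsv", sep="\t", index=False)
    manifest["stages"]["summarize"] = {
        "n_clusters": summary.n_clusters,
        "n_singletons": summary.n_singletons,
        "n_fixed": summary.n_fixed,
        "n_at_least_k": summary.n_at_least,
        "singleton_percent": summary.singleton_percent,
        "kruskal_total": pop["kruskal_total"],
        "kruskal_unique": pop["kruskal_unique"],
    }

    # -- annotate ----------------------------------------------------------
    genes = simulate_genes(genome, config.genes_per_mbp, seed=config.seed)
    table, reverse, annotations = _stage("annotate")(annotate_all)(
        clusters, genes, config.proximity, known_chroms=list(genome.lengths)
    )
    table.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    manifest["stages"]["annotate"] = {
        "n_genes": len(genes),
        "n_rows": len(table),
        "n_orphans": sum(a.orphan for a in annotations),
    }

    # -- overlay (null expression matrix over the synthetic cohort) --------
    expr_inds = cohort.individuals[: config.n_expression_samples]
    samples = [f"{ind}_rna" for ind in expr_inds]
    gene_ids = [g.gene_id for g in genes[: config.n_expression_genes]]
    counts = simulate_null_counts(gene_ids, samples, seed=config.seed)
    meta = pd.DataFrame({"individual": expr_inds}, index=samples)
    em = ExpressionMatrix(counts, meta)
    overlay = _stage("overlay")(ltr_presence_contrast)(
        em, clusters, annotations, config.overlay
    )
    overlay.to_csv(outdir / "overlay.tsv", sep="\t", index=False)
    manifest["stages"]["overlay"] = {
        "n_tests": len(overlay),
        "n_significant": int(overlay["significant"].sum()) if len(overlay) else 0,
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
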