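"""Gene-proximity annotation of unified integration sites.

LTRs carry promoter and enhancer elements, so each unified site is related
to nearby genes at two scales: a promoter window (genes whose TSS lies
within 1 kb downstream of the junction by default) and an enhancer window
(gene bodies within 1 Mb of the junction — the generally accepted maximal
reach of LTR enhancer action). "Downstream" is taken relative to the
cluster's consensus LTR polarity when ``promoter_oriented`` is set; clusters
with ambiguous polarity fall back to an unoriented +/- window. Distances are
measured from the junction to the nearest gene-body boundary, 0 when the
junction lies inside the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io import GeneRecord
from .transposome import SiteCluster

logger = logging.getLogger(__name__)

__all__ = [
    "ProximityParams",
    "ProximityAnnotation",
    "GeneIndex",
    "genes_near_site",
    "annotate_all",
]


@dataclass(frozen=True)
class ProximityParams:
    promoter_window: int = 1_000
    enhancer_window: int = 1_000_000
    promoter_oriented: bool = True

    def __post_init__(self) -> None:
        if self.promoter_window > self.enhancer_window:
            raise ValueError("promoter_window must be <= enhancer_window")
        if self.promoter_window < 0:
            raise ValueError("windows must be >= 0")


@dataclass
class ProximityAnnotation:
    """Genes within promoter / enhancer distance of one unified site."""

    cluster_id: str
    promoter_genes: list[tuple[str, int]]  # (gene_id, distance)
    enhancer_genes: list[tuple[str, int]]
    orphan: bool


class GeneIndex:
    """Per-chromosome interval index over gene bodies."""

    def __init__(
        self,
        genes: Sequence[GeneRecord],
        known_chroms: Sequence[str] | None = None,
    ) -> None:
        self.genes: list[GeneRecord] = []
        self._trees: dict[str, IntervalTree] = {}
        known = set(known_chroms) if known_chroms is not None else None
        for g in genes:
            if known is not None and g.chrom not in known:
                logger.warning(
                    "gene %s on chromosome %r absent from the genome; ignored",
                    g.gene_id,
                    g.chrom,
                )
                continue
            self.genes.append(g)
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g
            )

    def within(self, chrom: str, junction: int, window: int) -> list[GeneRecord]:
        """Genes whose body lies within ``window`` bp of ``junction``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(junction - window, junction + window + 1)
        return [h.data for h in hits]


def body_distance(gene: GeneRecord, junction: int) -> int:
    """bp from the junction to the nearest gene-body base (0 if inside)."""
    return max(gene.start - junction, junction - gene.end + 1, 0)


def _promoter_hit(
    gene: GeneRecord, junction: int, polarity: str, params: ProximityParams
) -> bool:
    w = params.promoter_window
    if params.promoter_oriented and polarity in ("+", "-"):
        delta = gene.tss - junction if polarity == "+" else junction - gene.tss
        return 0 <= delta <= w
    return abs(gene.tss - junction) <= w


def genes_near_site(
    cluster: SiteCluster,
    genes: Sequence[GeneRecord] | GeneIndex,
    params: ProximityParams | None = None,
) -> ProximityAnnotation:
    """Annotate one cluster with its promoter- and enhancer-distance genes.

    The promoter set is always a subset of the enhancer set; ``orphan`` is
    set when no gene falls within the enhancer window.
    """
    if params is None:
        params = ProximityParams()
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    near = index.within(cluster.chrom, cluster.junction, params.enhancer_window)
    near.sort(key=lambda g: (body_distance(g, cluster.junction), g.gene_id))
    enhancer = [(g.gene_id, body_distance(g, cluster.junction)) for g in near]
    promoter = [
        (g.gene_id, body_distance(g, cluster.junction))
        for g in near
        if _promoter_hit(g, cluster.junction, cluster.polarity, params)
    ]
    return ProximityAnnotation(
        cluster_id=cluster.cluster_id,
        promoter_genes=promoter,
        enhancer_genes=enhancer,
        orphan=not enhancer,
    )


def annotate_all(
    clusters: Sequence[SiteCluster],
    genes: Sequence[GeneRecord],
    params: ProximityParams | None = None,
    known_chroms: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]], list[ProximityAnnotation]]:
    """Annotate every cluster; return the long table, a gene -> clusters
    reverse index, and the per-cluster annotations.

    The table has one row per (cluster, gene, relation, distance) with
    relation in {promoter, enhancer}; ordering is deterministic.
    """
    if params is None:
        params = ProximityParams()
    index = GeneIndex(genes, known_chroms=known_chroms)
    annotations = [genes_near_site(c, index, params) for c in clusters]

    rows = []
    reverse: dict[str, list[str]] = {}
    for ann in annotations:
        for relation, pairs in (
            ("promoter", ann.promoter_genes),
            ("enhancer", ann.enhancer_genes),
        ):
            for gene_id, dist in sorted(pairs):
                rows.append(
                    {
                        "cluster_id": ann.cluster_id,
                        "gene_id": gene_id,
                        "relation": relation,
                        "distance": dist,
                    }
                )
        for gene_id, _ in ann.enhancer_genes:
            reverse.setdefault(gene_id, [])
            if ann.cluster_id not in reverse[gene_id]:
                reverse[gene_id].append(ann.cluster_id)
    table = pd.DataFrame(
        rows, columns=["cluster_id", "gene_id", "relation", "distance"]
    )
    table = table.sort_values(
        ["cluster_id", "relation", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    return table, reverse, annotations
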