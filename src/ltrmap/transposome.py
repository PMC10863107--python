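"""Cross-individual transposome analysis.

Unifies called integration sites across individuals into clusters (two
calls mark the same locus when their junctions differ by less than a
tolerance, 200 bp by default), classifies cluster prevalence (singleton /
conserved / fixed), computes pairwise sharing matrices, and compares
per-individual site counts between populations with a Kruskal-Wallis test.

The "< tolerance" pairwise criterion is not transitive, so clustering uses
a deterministic greedy leader rule: calls are scanned per chromosome in
junction order; a call joins the open cluster iff its junction is within
the tolerance of the cluster's leftmost member (the leader), otherwise it
founds a new cluster. This bounds within-cluster spread at the tolerance
and avoids unbounded chaining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CalledSite

__all__ = [
    "SiteCluster",
    "PrevalenceSummary",
    "unify_sites",
    "classify_prevalence",
    "pairwise_shared_matrix",
    "kruskal_wallis",
    "population_summary",
    "clusters_to_table",
]


@dataclass
class SiteCluster:
    """One unified integration locus with its cross-individual membership."""

    cluster_id: str
    chrom: str
    junction: int  # median of member junctions
    members: dict[str, CalledSite]
    polarity: str = "ambiguous"
    leader_junction: int = -1  # leftmost member junction (clustering anchor)

    @property
    def prevalence(self) -> int:
        return len(self.members)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class PrevalenceSummary:
    """Cohort-level prevalence bookkeeping for unified clusters."""

    n_total_calls: int
    n_clusters: int
    n_singletons: int
    n_fixed: int
    n_at_least: dict[int, int]
    singleton_fraction: float

    @property
    def singleton_percent(self) -> float:
        """Singleton share of clusters, as a percentage to 1 decimal."""
        return round(100.0 * self.singleton_fraction, 1)


def _consensus_polarity(members: Mapping[str, CalledSite]) -> str:
    votes = [m.polarity for m in members.values() if m.polarity != "ambiguous"]
    if not votes:
        return "ambiguous"
    plus = votes.count("+")
    minus = votes.count("-")
    if plus > minus:
        return "+"
    if minus > plus:
        return "-"
    return "ambiguous"


def unify_sites(
    sites: Sequence[CalledSite] | Mapping[str, Sequence[CalledSite]],
    tolerance: int = 200,
) -> list[SiteCluster]:
    """Greedy leader clustering of per-individual calls into unified loci.

    ``sites`` may be a flat list of calls (each carrying its individual) or
    a mapping individual -> calls. Calls from the same individual landing in
    one cluster are collapsed to the deeper call. Deterministic: calls are
    processed in (chrom, junction, individual) order.
    """
    if isinstance(sites, Mapping):
        flat = [s for lst in sites.values() for s in lst]
    else:
        flat = list(sites)
    flat.sort(key=lambda s: (s.chrom, s.junction, s.individual))

    clusters: list[SiteCluster] = []
    open_members: dict[str, CalledSite] = {}
    leader: CalledSite | None = None

    def close() -> None:
        if not open_members:
            return
        junctions = sorted(m.junction for m in open_members.values())
        med = int(np.median(junctions))
        clusters.append(
            SiteCluster(
                cluster_id=f"cl{len(clusters) + 1:05d}",
                chrom=leader.chrom,
                junction=med,
                members=dict(open_members),
                polarity=_consensus_polarity(open_members),
                leader_junction=leader.junction,
            )
        )

    for s in flat:
        if (
            leader is not None
            and s.chrom == leader.chrom
            and s.junction - leader.junction < tolerance
        ):
            prev = open_members.get(s.individual)
            if prev is None or s.peak_depth > prev.peak_depth:
                open_members[s.individual] = s
        else:
            close()
            open_members = {s.individual: s}
            leader = s
    close()
    return clusters


def classify_prevalence(
    clusters: Sequence[SiteCluster],
    n_individuals: int,
    k_list: Sequence[int] = (10,),
) -> PrevalenceSummary:
    """Count singleton / at-least-k / fixed clusters across the cohort."""
    prevs = [c.prevalence for c in clusters]
    n_clusters = len(prevs)
    n_singletons = sum(1 for p in prevs if p == 1)
    return PrevalenceSummary(
        n_total_calls=int(sum(prevs)),
        n_clusters=n_clusters,
        n_singletons=n_singletons,
        n_fixed=sum(1 for p in prevs if p == n_individuals),
        n_at_least={k: sum(1 for p in prevs if p >= k) for k in k_list},
        singleton_fraction=(n_singletons / n_clusters) if n_clusters else 0.0,
    )


def pairwise_shared_matrix(
    clusters: Sequence[SiteCluster], individuals: Sequence[str]
) -> pd.DataFrame:
    """Symmetric individual x individual matrix of shared-cluster counts.

    Entry (i, j) counts clusters containing both i and j; the diagonal is
    each individual's total cluster count.
    """
    idx = {ind: k for k, ind in enumerate(individuals)}
    mat = np.zeros((len(individuals), len(individuals)), dtype=np.int64)
    for c in clusters:
        ks = [idx[i] for i in c.members if i in idx]
        for a in ks:
            for b in ks:
                mat[a, b] += 1
    return pd.DataFrame(mat, index=list(individuals), columns=list(individuals))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with mid-rank ties and tie correction.

    H = [12 / (N(N+1)) * sum R_i^2 / n_i - 3(N+1)] / C with the tie
    correction C = 1 - sum(t^3 - t) / (N^3 - N); the p-value comes from the
    chi-square approximation with (k - 1) degrees of freedom. When every
    observation is identical, (H, p) = (0, 1) is returned rather than an
    error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0] + sizes)
    rank_sums = [
        ranks[bounds[i] : bounds[i + 1]].sum() for i in range(len(arrays))
    ]
    h = 12.0 / (n * (n + 1)) * sum(
        rs * rs / sz for rs, sz in zip(rank_sums, sizes)
    ) - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if correction == 0.0:  # all observations identical
        return 0.0, 1.0
    h /= correction
    h = max(h, 0.0)
    p = float(stats.chi2.sf(h, df=len(arrays) - 1))
    return float(h), p


def population_summary(
    clusters: Sequence[SiteCluster],
    populations: Mapping[str, str],
    exclude: str | None = None,
) -> dict:
    """Per-individual total and unique (cohort-wide singleton) site counts
    plus Kruskal-Wallis comparisons between populations.

    ``exclude`` drops one individual's row (and its singleton clusters)
    before testing, mirroring a with/without-outlier dual analysis.
    """
    totals = {ind: 0 for ind in populations}
    uniques = {ind: 0 for ind in populations}
    for c in clusters:
        for ind in c.members:
            if ind in totals:
                totals[ind] += 1
        if c.prevalence == 1:
            (only,) = c.members
            if only in uniques:
                uniques[only] += 1

    table = pd.DataFrame(
        {
            "individual": list(populations),
            "population": [populations[i] for i in populations],
            "total_sites": [totals[i] for i in populations],
            "unique_sites": [uniques[i] for i in populations],
        }
    )
    if exclude is not None:
        if exclude not in populations:
            raise KeyError(f"unknown individual {exclude!r}")
        table = table[table["individual"] != exclude].reset_index(drop=True)

    pops = sorted(table["population"].unique())
    by_pop_tot = [
        table.loc[table["population"] == p, "total_sites"].to_list()
        for p in pops
    ]
    by_pop_uni = [
        table.loc[table["population"] == p, "unique_sites"].to_list()
        for p in pops
    ]
    h_tot, p_tot = kruskal_wallis(by_pop_tot)
    h_uni, p_uni = kruskal_wallis(by_pop_uni)
    return {
        "table": table,
        "kruskal_total": {"H": h_tot, "p": p_tot},
        "kruskal_unique": {"H": h_uni, "p": p_uni},
        "excluded": exclude,
    }


def clusters_to_table(clusters: Sequence[SiteCluster]) -> pd.DataFrame:
    """Flatten clusters to a TSV-ready table (one row per cluster)."""
    from .io import display_label

    rows = [
        {
            "cluster_id": c.cluster_id,
            "chrom": c.chrom,
            "junction": c.junction,
            "display": display_label(c.chrom, c.junction),
            "polarity": c.polarity,
            "prevalence": c.prevalence,
            "individuals": ",".join(c.individuals),
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "chrom",
            "junction",
            "display",
            "polarity",
            "prevalence",
            "individuals",
        ],
    )
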