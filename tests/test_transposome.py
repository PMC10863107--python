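"""Cross-individual clustering, prevalence, sharing, Kruskal-Wallis."""

import numpy as np
import pytest
from scipy import stats

from ltrmap import (
    classify_prevalence,
    kruskal_wallis,
    pairwise_shared_matrix,
    population_summary,
    unify_sites,
)
from ltrmap.calling import CalledSite
from ltrmap.transposome import SiteCluster


def _call(junction, individual, depth=200, chrom="chr1"):
    return CalledSite(
        chrom=chrom,
        start=junction,
        end=junction + 300,
        junction=junction,
        polarity="+",
        peak_depth=depth,
        n_reads=depth,
        individual=individual,
    )


class TestUnify:
    def test_within_tolerance_merges(self):
        clusters = unify_sites([_call(1000, "catA"), _call(1150, "catB")])
        assert len(clusters) == 1
        assert clusters[0].prevalence == 2
        assert clusters[0].junction == 1075  # median of member junctions

    def test_beyond_tolerance_splits(self):
        clusters = unify_sites([_call(1000, "catA"), _call(1250, "catB")])
        assert [c.prevalence for c in clusters] == [1, 1]

    def test_leader_rule_prevents_chaining(self):
        clusters = unify_sites(
            [_call(1000, "a"), _call(1150, "b"), _call(1320, "c")]
        )
        junction_sets = [sorted(m.junction for m in c.members.values()) for c in clusters]
        assert junction_sets == [[1000, 1150], [1320]]

    def test_same_individual_duplicate_keeps_deeper(self):
        clusters = unify_sites(
            [_call(1000, "a", depth=150), _call(1100, "a", depth=400)]
        )
        assert len(clusters) == 1
        assert clusters[0].members["a"].peak_depth == 400
        assert clusters[0].prevalence == 1

    def test_empty_input(self):
        assert unify_sites([]) == []

    def test_partition_conservation(self):
        rng = np.random.default_rng(3)
        calls = [
            _call(int(j), f"cat{rng.integers(6)}")
            for j in np.sort(rng.integers(0, 100_000, size=200))
        ]
        clusters = unify_sites(calls)
        # every call is represented once, modulo same-individual collapses
        n_collapsed = sum(c.prevalence for c in clusters)
        assert n_collapsed <= len(calls)
        # with unique individuals per junction there is exact conservation
        calls_uniq = [_call(int(j), f"cat{i}") for i, j in enumerate(
            np.sort(rng.integers(0, 100_000, size=100))
        )]
        clusters2 = unify_sites(calls_uniq)
        assert sum(c.prevalence for c in clusters2) == len(calls_uniq)

    def test_idempotence_on_leader_representatives(self):
        """Consecutive leaders are >= tolerance apart by construction, so
        re-unifying one call per cluster at the leader junction is a no-op."""
        rng = np.random.default_rng(4)
        calls = [_call(int(j), f"cat{i}") for i, j in enumerate(
            np.sort(rng.integers(0, 50_000, size=80))
        )]
        clusters = unify_sites(calls)
        reps = [
            _call(c.leader_junction, f"rep{i}") for i, c in enumerate(clusters)
        ]
        assert len(unify_sites(reps)) == len(clusters)

    def test_tolerance_monotonicity(self):
        rng = np.random.default_rng(5)
        calls = [_call(int(j), f"cat{i}") for i, j in enumerate(
            np.sort(rng.integers(0, 50_000, size=120))
        )]
        counts = [len(unify_sites(calls, tol)) for tol in (50, 200, 500, 2000)]
        assert counts == sorted(counts, reverse=True)


class TestPrevalence:
    def test_hand_enumerated_classes(self):
        clusters = []
        for k, prev in enumerate((1, 1, 3, 20)):
            members = {f"cat{i}": _call(1000 * k, f"cat{i}") for i in range(prev)}
            clusters.append(
                SiteCluster(f"cl{k}", "chr1", 1000 * k, members)
            )
        summary = classify_prevalence(clusters, n_individuals=20, k_list=(10,))
        assert summary.n_singletons == 2
        assert summary.n_at_least[10] == 1
        assert summary.n_fixed == 1
        assert summary.n_total_calls == 25

    def test_all_fixed(self):
        members = {f"cat{i}": _call(0, f"cat{i}") for i in range(5)}
        clusters = [SiteCluster(f"cl{k}", "chr1", k, dict(members)) for k in range(4)]
        s = classify_prevalence(clusters, n_individuals=5)
        assert s.n_fixed == s.n_clusters == 4
        assert s.singleton_fraction == 0.0

    def test_published_prevalence_table_fraction(self):
        """412 singletons among 765 unified sites prints as 53.9%."""
        clusters = [
            SiteCluster(f"cl{k}", "chr1", k, {"a": _call(k, "a")})
            for k in range(412)
        ] + [
            SiteCluster(
                f"cl{412 + k}",
                "chr1",
                k,
                {"a": _call(k, "a"), "b": _call(k, "b")},
            )
            for k in range(353)
        ]
        s = classify_prevalence(clusters, n_individuals=20)
        assert s.n_clusters == 765
        assert s.singleton_percent == 53.9


class TestSharing:
    def test_hand_enumerated_matrix(self):
        def cluster(cid, inds):
            return SiteCluster(
                cid, "chr1", 0, {i: _call(0, i) for i in inds}
            )

        clusters = [
            cluster("c1", ["A", "B"]),
            cluster("c2", ["A", "B"]),
            cluster("c3", ["A", "B", "C"]),
            cluster("c4", ["C"]),
        ]
        mat = pairwise_shared_matrix(clusters, ["A", "B", "C"])
        assert mat.loc["A"].tolist() == [3, 3, 1]
        assert mat.loc["B"].tolist() == [3, 3, 1]
        assert mat.loc["C"].tolist() == [1, 1, 2]
        assert (mat.to_numpy() == mat.to_numpy().T).all()

    def test_disjoint_sets_zero_off_diagonal(self):
        clusters = [
            SiteCluster("c1", "chr1", 0, {"A": _call(0, "A")}),
            SiteCluster("c2", "chr1", 500, {"B": _call(500, "B")}),
        ]
        mat = pairwise_shared_matrix(clusters, ["A", "B"])
        assert mat.loc["A", "B"] == 0
        assert mat.loc["A", "A"] == 1


class TestKruskalWallis:
    def test_two_group_hand_value(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert round(h, 3) == 3.857

    def test_identical_groups_zero(self):
        h, _ = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_observations(self):
        assert kruskal_wallis([[5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_shift_invariance(self):
        groups = [[1, 5, 9], [2, 3, 11], [4, 8, 10]]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([[x + 100 for x in g] for g in groups])
        assert h1 == pytest.approx(h2)

    def test_matches_independent_oracle_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [
                rng.integers(0, 12, size=int(rng.integers(3, 10))).tolist()
                for _ in range(k)
            ]
            if all(x == groups[0][0] for g in groups for x in g):
                continue
            h, p = kruskal_wallis(groups)
            h_ref, p_ref = stats.kruskal(*groups)
            assert h == pytest.approx(h_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_inputs_refused(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestPopulationSummary:
    @staticmethod
    def _clusters_from_counts(counts_by_ind, singles_by_ind):
        clusters = []
        cid = 0
        inds = list(counts_by_ind)
        # shared backbone clusters containing everyone, to fill totals
        max_shared = {
            i: counts_by_ind[i] - singles_by_ind[i] for i in inds
        }
        for n in range(max(max_shared.values(), default=0)):
            members = {
                i: _call(1000 * cid, i) for i in inds if max_shared[i] > n
            }
            if len(members) < 2:
                # pad with a second member so these stay non-singleton
                continue
            clusters.append(SiteCluster(f"s{cid}", "chr1", 1000 * cid, members))
            cid += 1
        for i in inds:
            for _ in range(singles_by_ind[i]):
                clusters.append(
                    SiteCluster(f"u{cid}", "chr1", 1000 * cid, {i: _call(1000 * cid, i)})
                )
                cid += 1
        return clusters

    def test_identical_distributions_nonsignificant(self):
        pops = {f"cat{i}": f"pop{i % 2 + 1}" for i in range(6)}
        counts = {i: 5 for i in pops}
        singles = {i: 2 for i in pops}
        clusters = self._clusters_from_counts(counts, singles)
        rep = population_summary(clusters, pops)
        assert rep["kruskal_unique"]["p"] == pytest.approx(1.0)

    def test_exclusion_drops_row_and_its_singletons(self):
        pops = {"a": "pop1", "b": "pop1", "c": "pop2", "d": "pop2"}
        clusters = self._clusters_from_counts(
            {"a": 4, "b": 3, "c": 3, "d": 2}, {"a": 2, "b": 1, "c": 1, "d": 1}
        )
        rep = population_summary(clusters, pops, exclude="a")
        assert "a" not in rep["table"]["individual"].tolist()
        full = population_summary(clusters, pops)
        # other individuals' counts are untouched by the exclusion
        merged = rep["table"].set_index("individual")
        for ind in ("b", "c", "d"):
            row_full = full["table"].set_index("individual").loc[ind]
            assert (merged.loc[ind] == row_full).all()

    def test_shifted_population_raises_h(self):
        pops = {f"cat{i}": ("pop1" if i < 7 else "pop2") for i in range(14)}
        rng = np.random.default_rng(9)
        base = {i: int(rng.integers(10, 20)) for i in pops}
        shifted = {
            i: base[i] + (50 if pops[i] == "pop2" else 0) for i in pops
        }
        h_flat, _ = kruskal_wallis(
            [
                [base[i] for i in pops if pops[i] == "pop1"],
                [base[i] for i in pops if pops[i] == "pop2"],
            ]
        )
        h_shift, _ = kruskal_wallis(
            [
                [shifted[i] for i in pops if pops[i] == "pop1"],
                [shifted[i] for i in pops if pops[i] == "pop2"],
            ]
        )
        assert h_shift > h_flat
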