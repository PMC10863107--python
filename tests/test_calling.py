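"""Site calling: coverage, interval extraction, filters, polarity, env."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltrmap import (
    CohortConfig,
    GenomeModel,
    SiteCallingParams,
    call_sites,
    compute_coverage,
    extract_intervals,
    filter_sites,
    infer_polarity,
    merge_within_individual,
    exclude_env,
    simulate_cohort,
    simulate_enrichment_reads,
)
from ltrmap.calling import CalledSite, CandidateInterval

from conftest import make_reads, random_reads
from oracles import naive_intervals, naive_pileup, runs_to_array

PARAMS = SiteCallingParams()


def test_coverage_overlapping_reads_collapsed_runs():
    track = compute_coverage(make_reads([(10, 20), (15, 25)]))
    assert track.runs["chr1"].tolist() == [[10, 15, 1], [15, 20, 2], [20, 25, 1]]


def test_coverage_single_and_empty():
    assert compute_coverage(make_reads([(0, 5)])).runs["chr1"].tolist() == [
        [0, 5, 1]
    ]
    assert compute_coverage(make_reads([])).runs == {}


def test_coverage_conservation_identity():
    rng = np.random.default_rng(5)
    reads = random_reads(rng, 500, 50_000)
    track = compute_coverage(reads)
    assert track.total_area == int(
        (reads.reads["end"] - reads.reads["start"]).sum()
    )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(1, 300))
def test_coverage_and_intervals_match_naive_oracle(seed, n_reads):
    """Collapsed-run pileup and interval extraction agree with a per-base
    array implementation."""
    rng = np.random.default_rng(seed)
    length = 20_000
    reads = random_reads(rng, n_reads, length)
    track = compute_coverage(reads)
    expected = naive_pileup(reads.reads, length, "chr1")
    got = runs_to_array(track.runs.get("chr1", np.empty((0, 3), int)), length)
    assert (expected == got).all()
    floor = int(rng.integers(1, 4))
    params = SiteCallingParams(coverage_floor=floor)
    ours = [
        (iv.start, iv.end, iv.peak_depth)
        for iv in extract_intervals(track, params)
    ]
    assert ours == naive_intervals(expected, floor)


def test_extract_intervals_floor_semantics():
    track = compute_coverage(make_reads([(10, 20), (15, 25)]))
    (iv,) = extract_intervals(track, SiteCallingParams(coverage_floor=1))
    assert (iv.start, iv.end, iv.peak_depth) == (10, 25, 2)
    (iv2,) = extract_intervals(track, SiteCallingParams(coverage_floor=2))
    assert (iv2.start, iv2.end, iv2.peak_depth) == (15, 20, 2)
    assert extract_intervals(compute_coverage(make_reads([])), PARAMS) == []


@pytest.mark.parametrize(
    "length,depth,kept",
    [
        (100, 500, False),  # length boundary is exclusive
        (1000, 500, False),  # upper length boundary exclusive
        (400, 100, False),  # depth boundary exclusive
        (400, 250, True),  # interior point
        (101, 101, True),  # just inside all three bounds
        (999, 101, True),
    ],
)
def test_filter_strict_inequalities(length, depth, kept):
    iv = CandidateInterval("chr1", 1000, 1000 + length, depth)
    assert (filter_sites([iv], PARAMS) == [iv]) is kept


def _profile_reads(reverse=False):
    # stepped profile 200,198,150,90,40,10 over six 100-bp runs, every read
    # anchored at the blunt edge
    intervals = []
    for end, n in [(100, 2), (200, 48), (300, 60), (400, 50), (500, 30), (600, 10)]:
        intervals += [(0, end)] * n
    if reverse:
        intervals = [(600 - e, 600 - s) for s, e in intervals]
    return make_reads(intervals)


def test_polarity_blunt_left_edge_is_plus():
    reads = _profile_reads()
    track = compute_coverage(reads)
    (iv,) = extract_intervals(track, PARAMS)
    depth = naive_pileup(reads.reads, 600, "chr1")
    assert depth.tolist() == [200] * 100 + [198] * 100 + [150] * 100 + [
        90
    ] * 100 + [40] * 100 + [10] * 100
    polarity, junction = infer_polarity(iv, track, PARAMS)
    assert polarity == "+" and junction == 0


def test_polarity_mirrored_profile_is_minus():
    reads = _profile_reads(reverse=True)
    track = compute_coverage(reads)
    (iv,) = extract_intervals(track, PARAMS)
    polarity, junction = infer_polarity(iv, track, PARAMS)
    assert polarity == "-" and junction == 600


def test_polarity_rectangular_plateau_ambiguous():
    reads = make_reads([(0, 500)] * 200)
    track = compute_coverage(reads)
    (iv,) = extract_intervals(track, PARAMS)
    polarity, junction = infer_polarity(iv, track, PARAMS)
    assert polarity == "ambiguous"
    assert junction in (0, 500)


def _site(junction, depth, individual="cat1", chrom="chr1"):
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


def test_merge_within_individual_keeps_deeper():
    sites = [_site(1000, 120), _site(1150, 300), _site(1500, 200)]
    merged = merge_within_individual(sites, PARAMS)
    assert [(s.junction, s.peak_depth) for s in merged] == [
        (1150, 300),
        (1500, 200),
    ]


def test_env_exclusion_window():
    env = [("chr1", 10_000, 16_000, "+")]
    near = _site(9_000, 200)  # 700 bp gap after its 300-bp span: flagged
    far = _site(5_000_000, 200)
    kept, flagged = exclude_env([near, far], env, PARAMS)
    assert [s.junction for s in flagged] == [9_000]
    assert all(s.env_flagged for s in flagged)
    assert [s.junction for s in kept] == [5_000_000]
    kept2, flagged2 = exclude_env([near, far], [], PARAMS)
    assert flagged2 == [] and len(kept2) == 2


def _recovery_cohort(depth, seed=0, n_sites=10):
    genome = GenomeModel(
        chromosomes=(("chr1", 2_000_000),),
        env_loci=(("chr1", 1_500_000, 1_506_000, "+"),),
    )
    cfg = CohortConfig(
        n_populations=1,
        individuals_per_population=(1,),
        shared_site_pool_size=(n_sites,),
        private_site_rate=0,
        inheritance_probability=1.0,
        target_junction_depth=depth,
        background_read_rate=0.0,
        seed=seed,
    )
    cohort = simulate_cohort(cfg, genome)
    ind = cohort.individuals[0]
    reads = simulate_enrichment_reads(cohort, ind, cfg)
    kept, flagged = call_sites(reads, genome.env_loci)
    return cohort.truth[ind], kept, flagged


def test_end_to_end_truth_sites_recovered_exactly():
    truth, kept, flagged = _recovery_cohort(depth=200)
    assert len(kept) == len(truth) == 10
    assert [(s.chrom, s.junction) for s in kept] == [
        (t.chrom, t.junction) for t in truth
    ]
    assert [s.polarity for s in kept] == [t.polarity for t in truth]
    # the env stack is reported only in the flagged secondary output
    assert len(flagged) == 1
    assert flagged[0].env_flagged


def test_shallow_sites_below_depth_cut_absent():
    truth, kept, _ = _recovery_cohort(depth=50)
    assert len(truth) == 10
    assert kept == []


def test_min_depth_monotonicity():
    """Raising min_depth never adds sites; lowering never removes them."""
    rng = np.random.default_rng(11)
    genome = GenomeModel(chromosomes=(("chr1", 500_000),))
    cfg = CohortConfig(
        n_populations=1,
        individuals_per_population=(1,),
        shared_site_pool_size=(5,),
        private_site_rate=0,
        inheritance_probability=1.0,
        target_junction_depth=120,
        background_read_rate=200.0,
        seed=13,
    )
    cohort = simulate_cohort(cfg, genome)
    reads = simulate_enrichment_reads(cohort, cohort.individuals[0], cfg)
    previous = None
    for min_depth in (150, 110, 80, 40):
        kept, _ = call_sites(
            reads, (), SiteCallingParams(min_depth=min_depth)
        )
        junctions = {(s.chrom, s.junction) for s in kept}
        if previous is not None:
            assert previous <= junctions
        previous = junctions
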