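"""Synthetic cohorts for LTR integration-site discovery.

Generates toy genomes, per-individual integration maps with known truth, and
aligned enrichment-read footprints that emulate a linker-mediated PCR
library: every junction read is anchored at the 5'-LTR/genome boundary (the
blunt edge) and extends into flanking sequence a sheared-fragment length,
so per-base depth is maximal at the junction and decays with distance.
Reference-fixed endogenous env loci emit the same junction signature so the
downstream env-exclusion stage has something to remove.

Reads are emitted directly as aligned genomic intervals (BED6 / minimal
SAM); base-level sequence, sequencing error and PCR duplicates are out of
scope — upstream trimming and alignment sit outside this pipeline's
boundary, which begins at coverage analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import READ_COLUMNS, AlignedReadSet

__all__ = [
    "GenomeModel",
    "TrueIntegration",
    "CohortConfig",
    "SyntheticCohort",
    "default_genome",
    "simulate_cohort",
    "simulate_enrichment_reads",
    "simulate_genes",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class GenomeModel:
    """A reference genome description: chromosome sizes plus fixed env loci.

    Stands in for a full assembly; only names, lengths and the coordinates
    of reference-fixed endogenous env proviruses are needed downstream.
    """

    chromosomes: tuple[tuple[str, int], ...]
    env_loci: tuple[tuple[str, int, int, str], ...] = ()

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        lengths = self.lengths
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has length {length}")
        for chrom, start, end, strand in self.env_loci:
            if chrom not in lengths:
                raise ValueError(f"env locus on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(
                    f"env locus {chrom}:{start}-{end} outside chromosome"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"bad env strand {strand!r}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True, order=True)
class TrueIntegration:
    """Latent truth: one LTR/genome junction in one individual's genome."""

    chrom: str
    junction: int
    polarity: str  # '+' or '-'
    origin: str  # 'inherited' or 'private'
    population_tag: str

    def __post_init__(self) -> None:
        if self.polarity not in ("+", "-"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.origin not in ("inherited", "private"):
            raise ValueError(f"bad origin {self.origin!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for the simulated cohort.

    Defaults mirror the source study's design: three cat populations of
    7, 6 and 7 individuals; sheared fragments averaging 400 bp (sd 80);
    ~200 enrichment reads per junction (Poisson); sparse uniform background.
    ``read_length`` is the mappable span per fragment (2x250 bp paired-end
    reads cover ~500 bp); footprints are clipped to it.
    ``background_read_rate`` is reads per Mbp (100/Mbp = 0.1 per kbp).
    ``min_separation`` keeps simulated sites at least this far from env loci
    and from other sites of the same individual, twice the downstream
    env-exclusion window so truth sites are never collaterally flagged.
    """

    n_populations: int = 3
    individuals_per_population: tuple[int, ...] = (7, 6, 7)
    shared_site_pool_size: tuple[int, ...] = (30, 30, 30)
    private_site_rate: int = 8
    inheritance_probability: float = 0.5
    fragment_mean: int = 400
    fragment_sd: int = 80
    read_length: int = 500
    target_junction_depth: int = 200
    background_read_rate: float = 100.0
    min_separation: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        for name in ("individuals_per_population", "shared_site_pool_size"):
            vals = getattr(self, name)
            if len(vals) != self.n_populations:
                raise ValueError(
                    f"{name} must have {self.n_populations} entries"
                )
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} entries must be >= 0")
        if not 0.0 <= self.inheritance_probability <= 1.0:
            raise ValueError("inheritance_probability must be in [0, 1]")
        if self.private_site_rate < 0 or self.target_junction_depth < 0:
            raise ValueError("counts must be >= 0")
        if self.fragment_mean <= 0 or self.read_length <= 0:
            raise ValueError("fragment_mean and read_length must be > 0")
        if self.background_read_rate < 0:
            raise ValueError("background_read_rate must be >= 0")


@dataclass(frozen=True)
class SyntheticCohort:
    """Genome + per-individual ground-truth integration maps."""

    genome: GenomeModel
    truth: dict[str, list[TrueIntegration]]
    populations: dict[str, str]  # individual -> population tag
    config: CohortConfig

    @property
    def individuals(self) -> list[str]:
        return list(self.truth)


def default_genome() -> GenomeModel:
    """Three-chromosome toy genome (15 Mbp) with two env loci per chromosome."""
    chroms = (("chrA1", 6_000_000), ("chrB1", 5_000_000), ("chrC1", 4_000_000))
    env = []
    for name, length in chroms:
        for frac, strand in ((0.25, "+"), (0.7, "-")):
            start = int(length * frac)
            env.append((name, start, start + 6_000, strand))
    return GenomeModel(chromosomes=chroms, env_loci=tuple(env))


# ---------------------------------------------------------------------------
# Truth simulation
# ---------------------------------------------------------------------------

def _blocked_positions(
    genome: GenomeModel, sep: int
) -> dict[str, list[tuple[int, int]]]:
    blocked: dict[str, list[tuple[int, int]]] = {
        c: [] for c, _ in genome.chromosomes
    }
    for chrom, start, end, _ in genome.env_loci:
        blocked[chrom].append((start - sep, end + sep))
    return blocked


def _place_site(
    rng: np.random.Generator,
    genome: GenomeModel,
    blocked: Mapping[str, Sequence[tuple[int, int]]],
    sep: int,
    max_tries: int = 10_000,
) -> tuple[str, int]:
    names = [c for c, _ in genome.chromosomes]
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    weights = lengths / lengths.sum()
    margin = 3 * 500  # keep the read tail inside the chromosome
    for _ in range(max_tries):
        chrom = names[rng.choice(len(names), p=weights)]
        length = genome.lengths[chrom]
        if length <= 2 * margin:
            raise ValueError(
                f"chromosome {chrom!r} (length {length}) is too short to "
                "place an integration site"
            )
        pos = int(rng.integers(margin, length - margin))
        if all(not (lo <= pos < hi) for lo, hi in blocked.get(chrom, ())):
            return chrom, pos
    shortest = min(genome.chromosomes, key=lambda c: c[1])[0]
    raise ValueError(
        "could not place an integration site after "
        f"{max_tries} attempts (genome too crowded; smallest chromosome "
        f"{shortest!r}); reduce site counts or min_separation"
    )


def simulate_cohort(
    config: CohortConfig, genome: GenomeModel | None = None
) -> SyntheticCohort:
    """Draw per-individual truth maps: inherited sites from each population's
    shared pool (Bernoulli per site) plus uniformly placed private sites.

    Deterministic for a fixed ``config.seed``. Placement rejects positions
    within ``min_separation`` of an env locus or of another site already on
    the same individual (pool sites respect the same spacing within their
    population).
    """
    if genome is None:
        genome = default_genome()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    sep = config.min_separation

    pools: list[list[TrueIntegration]] = []
    for p in range(config.n_populations):
        tag = f"pop{p + 1}"
        blocked = _blocked_positions(genome, sep)
        pool: list[TrueIntegration] = []
        for _ in range(config.shared_site_pool_size[p]):
            chrom, pos = _place_site(rng, genome, blocked, sep)
            blocked[chrom].append((pos - sep, pos + sep))
            polarity = "+" if rng.random() < 0.5 else "-"
            pool.append(TrueIntegration(chrom, pos, polarity, "inherited", tag))
        pools.append(pool)

    truth: dict[str, list[TrueIntegration]] = {}
    populations: dict[str, str] = {}
    for p in range(config.n_populations):
        tag = f"pop{p + 1}"
        for i in range(config.individuals_per_population[p]):
            ind = f"{tag}_ind{i + 1:02d}"
            populations[ind] = tag
            sites: list[TrueIntegration] = []
            for site in pools[p]:
                if rng.random() < config.inheritance_probability:
                    sites.append(site)
            blocked = _blocked_positions(genome, sep)
            for s in sites:
                blocked[s.chrom].append((s.junction - sep, s.junction + sep))
            for _ in range(config.private_site_rate):
                chrom, pos = _place_site(rng, genome, blocked, sep)
                blocked[chrom].append((pos - sep, pos + sep))
                polarity = "+" if rng.random() < 0.5 else "-"
                sites.append(
                    TrueIntegration(chrom, pos, polarity, "private", tag)
                )
            truth[ind] = sorted(sites)
    return SyntheticCohort(genome, truth, populations, config)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Resampling-based truncated normal draw (exact truncation)."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _junction_stack(
    rng: np.random.Generator,
    chrom: str,
    chrom_len: int,
    junction: int,
    polarity: str,
    n_reads: int,
    config: CohortConfig,
    prefix: str,
) -> list[tuple]:
    """Reads for one junction: blunt at the junction, fragment tail beyond."""
    if n_reads == 0:
        return []
    frags = _truncated_normal(
        rng,
        n_reads,
        config.fragment_mean,
        config.fragment_sd,
        1.0,
        3.0 * config.fragment_mean,
    )
    foot = np.minimum(np.rint(frags).astype(int), config.read_length)
    foot = np.maximum(foot, 1)
    rows = []
    for k, f in enumerate(foot):
        if polarity == "+":
            start, end = junction, min(junction + int(f), chrom_len)
        else:
            start, end = max(junction - int(f), 0), junction
        if start < end:
            rows.append((chrom, start, end, f"{prefix}_r{k}", 60, polarity))
    return rows


def simulate_enrichment_reads(
    cohort: SyntheticCohort,
    individual: str,
    config: CohortConfig | None = None,
) -> AlignedReadSet:
    """Emit aligned junction-anchored read footprints for one individual.

    Per true site the read count is Poisson(``target_junction_depth``); each
    read starts exactly at the junction on the LTR-primer side and extends a
    truncated-normal fragment length (clipped to ``read_length``) into
    flanking sequence, rightward for + polarity and leftward for −. Env loci
    emit the same junction-style stack; uniform background reads are added
    at ``background_read_rate`` per Mbp.
    """
    if config is None:
        config = cohort.config
    if individual not in cohort.truth:
        raise KeyError(f"unknown individual {individual!r}")
    idx = cohort.individuals.index(individual)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 23, idx])
    )
    genome = cohort.genome
    lengths = genome.lengths
    rows: list[tuple] = []

    for s_i, site in enumerate(cohort.truth[individual]):
        n = int(rng.poisson(config.target_junction_depth))
        rows.extend(
            _junction_stack(
                rng,
                site.chrom,
                lengths[site.chrom],
                site.junction,
                site.polarity,
                n,
                config,
                f"{individual}_s{s_i}",
            )
        )

    # env proviruses are captured through their 3'-LTR: a junction-style
    # stack anchored at the locus edge, tail running into flanking sequence
    for e_i, (chrom, start, end, strand) in enumerate(genome.env_loci):
        n = int(rng.poisson(config.target_junction_depth))
        junction = start if strand == "+" else end
        polarity = "-" if strand == "+" else "+"
        rows.extend(
            _junction_stack(
                rng,
                chrom,
                lengths[chrom],
                junction,
                polarity,
                n,
                config,
                f"{individual}_env{e_i}",
            )
        )

    if config.background_read_rate > 0:
        total_mbp = genome.total_length / 1e6
        n_bg = int(rng.poisson(config.background_read_rate * total_mbp))
        names = [c for c, _ in genome.chromosomes]
        lens = np.array([l for _, l in genome.chromosomes], dtype=float)
        weights = lens / lens.sum()
        for k in range(n_bg):
            chrom = names[rng.choice(len(names), p=weights)]
            clen = lengths[chrom]
            start = int(rng.integers(0, max(clen - config.read_length, 1)))
            end = min(start + config.read_length, clen)
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, start, end, f"{individual}_bg{k}", 60, strand))

    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    return AlignedReadSet(individual, df).sort()


def simulate_genes(
    genome: GenomeModel, genes_per_mbp: float = 10.0, seed: int = 0
) -> list:
    """Toy gene annotation: uniformly placed non-validated gene bodies.

    Sizes are log-normal around ~20 kb; used by the demo pipeline when no
    real annotation is supplied.
    """
    from .io import GeneRecord

    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    genes = []
    gid = 0
    for chrom, length in genome.chromosomes:
        n = int(rng.poisson(genes_per_mbp * length / 1e6))
        for _ in range(n):
            size = int(np.clip(rng.lognormal(np.log(2e4), 0.8), 500, 2e5))
            start = int(rng.integers(0, max(length - size, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(
                GeneRecord(f"GENE{gid:05d}", chrom, start, start + size, strand)
            )
    return sorted(genes, key=lambda g: (g.chrom, g.start))


# ---------------------------------------------------------------------------
# Truth serialization (BED6; score 1 = inherited, 0 = private)
# ---------------------------------------------------------------------------

def write_truth(cohort: SyntheticCohort, outdir: str | Path) -> list[Path]:
    """Write one BED6 truth file per individual; round-trips losslessly.

    Columns: chrom, junction, junction+1, ``<population_tag>.<i>`` site id,
    score 1 for inherited / 0 for private, strand = polarity.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ind, sites in cohort.truth.items():
        path = outdir / f"{ind}.truth.bed"
        with open(path, "w") as fh:
            for i, s in enumerate(sites):
                score = 1 if s.origin == "inherited" else 0
                fh.write(
                    f"{s.chrom}\t{s.junction}\t{s.junction + 1}\t"
                    f"{s.population_tag}.{i}\t{score}\t{s.polarity}\n"
                )
        paths.append(path)
    return paths


def read_truth(path: str | Path) -> list[TrueIntegration]:
    """Read one individual's truth BED back into TrueIntegration records."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path} line {lineno}: expected 6 fields")
            chrom, start, _end, name, score, strand = fields[:6]
            tag = name.rsplit(".", 1)[0]
            origin = "inherited" if int(score) == 1 else "private"
            sites.append(
                TrueIntegration(chrom, int(start), strand, origin, tag)
            )
    return sites
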