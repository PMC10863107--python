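"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start, end)`` — the BED
convention. The two places 1-based coordinates appear are at the parsing
boundary (SAM ``POS`` and GFF3 records are converted on input) and at the
display boundary (site tables carry a browser-style ``display`` label such
as ``chrB2:55,690,560`` alongside the 0-based columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

#: Column schema for site tables (see :func:`write_site_table`).
SITE_COLUMNS = [
    "individual",
    "chrom",
    "start",
    "end",
    "junction",
    "display",
    "polarity",
    "peak_depth",
    "n_reads",
    "env_flagged",
]


def display_label(chrom: str, junction: int) -> str:
    """Browser-style 1-based label for a junction, e.g. ``chrB2:55,690,560``."""
    return f"{chrom}:{junction + 1:,}"


@dataclass
class AlignedReadSet:
    """One individual's stranded read footprints from the enrichment assay.

    ``reads`` is a DataFrame with columns ``chrom, start, end, name, score,
    strand`` in 0-based half-open coordinates.
    """

    individual: str
    reads: pd.DataFrame
    is_sorted: bool = False

    def __post_init__(self) -> None:
        if list(self.reads.columns) != READ_COLUMNS:
            self.reads = self.reads.reindex(columns=READ_COLUMNS)
        if len(self.reads) and (self.reads["start"] >= self.reads["end"]).any():
            bad = self.reads[self.reads["start"] >= self.reads["end"]].iloc[0]
            raise ValueError(
                f"read {bad['name']!r}: start {bad.start} >= end {bad.end}"
            )

    def __len__(self) -> int:
        return len(self.reads)

    def sort(self) -> "AlignedReadSet":
        """Return a copy sorted by (chrom, start, end)."""
        if self.is_sorted:
            return self
        srt = self.reads.sort_values(
            ["chrom", "start", "end", "name"], kind="mergesort"
        ).reset_index(drop=True)
        return AlignedReadSet(self.individual, srt, is_sorted=True)

    def validate_against(self, chrom_lengths: Mapping[str, int]) -> None:
        for chrom, grp in self.reads.groupby("chrom", sort=False):
            if chrom not in chrom_lengths:
                raise ValueError(f"unknown chromosome {chrom!r} in reads")
            if (grp["end"] > chrom_lengths[chrom]).any():
                raise ValueError(
                    f"read extends past end of chromosome {chrom!r}"
                )


@dataclass(frozen=True)
class GeneRecord:
    """A gene body with its transcription start site.

    ``tss`` is the ``start`` coordinate for + strand genes and the (half-open)
    ``end`` coordinate for − strand genes.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.tss == -1:
            object.__setattr__(
                self, "tss", self.start if self.strand == "+" else self.end
            )
        if self.tss not in (self.start, self.end):
            raise ValueError(f"gene {self.gene_id}: tss must be start or end")


# ---------------------------------------------------------------------------
# Aligned reads
# ---------------------------------------------------------------------------

def read_aligned_reads(
    path: str | Path,
    fmt: str = "bed6",
    individual: str | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> AlignedReadSet:
    """Load aligned enrichment reads from BED6 or a minimal SAM file.

    SAM input keeps only mapped primary alignments; 1-based ``POS`` is
    converted to 0-based and FLAG bit 16 becomes strand ``-``.
    """
    path = Path(path)
    if individual is None:
        individual = path.stem.split(".")[0]
    if fmt == "bed6":
        rows = _parse_bed6(path)
    elif fmt == "sam":
        rows = _parse_sam(path)
    else:
        raise ValueError(f"unknown read format {fmt!r} (expected bed6 or sam)")
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    rs = AlignedReadSet(individual, df)
    if chrom_lengths is not None:
        rs.validate_against(chrom_lengths)
    return rs


def _parse_bed6(path: Path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path} line {lineno}: expected >= 6 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                score = int(float(fields[4]))
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from None
            if fields[5] not in ("+", "-"):
                raise ValueError(
                    f"{path} line {lineno}: bad strand {fields[5]!r}"
                )
            rows.append((fields[0], start, end, fields[3], score, fields[5]))
    return rows


def _parse_sam(path: Path) -> list[tuple]:
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            rows.append(
                (
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    aln.query_name,
                    aln.mapping_quality,
                    strand,
                )
            )
    return rows


def write_reads_bed(readset: AlignedReadSet, path: str | Path) -> None:
    """Write a read set as BED6 (score column = mapping quality placeholder)."""
    readset.sort().reads.to_csv(path, sep="\t", header=False, index=False)


def write_reads_sam(
    readset: AlignedReadSet,
    chrom_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write a minimal SAM file (FLAG 0/16, single-match CIGAR)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    srt = readset.sort()
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in srt.reads.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.name
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = tid[row.chrom]
            a.reference_start = int(row.start)
            a.mapping_quality = int(row.score)
            a.cigarstring = f"{int(row.end) - int(row.start)}M"
            a.query_sequence = "N" * (int(row.end) - int(row.start))
            out.write(a)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(
    path: str | Path, fmt: str = "gff3"
) -> list[GeneRecord]:
    """Load gene records from GFF3 (``gene`` features only) or BED.

    GFF3 1-based inclusive coordinates become 0-based half-open; the gene id
    is the ``ID`` attribute. BED input uses the name column as gene id.
    """
    path = Path(path)
    if fmt == "gff3":
        return _parse_gff3_genes(path)
    if fmt == "bed":
        genes = []
        for chrom, start, end, name, _score, strand in _parse_bed6(path):
            genes.append(GeneRecord(name, chrom, start, end, strand))
        return genes
    raise ValueError(f"unknown annotation format {fmt!r}")


def _parse_gff3_genes(path: Path) -> list[GeneRecord]:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if "ID" not in feat.attributes:
            raise ValueError(
                f"{path}: gene feature at {feat.seqid}:{feat.start} "
                "lacks an ID attribute"
            )
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(
            GeneRecord(
                gene_id=feat.attributes["ID"][0],
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=strand,
            )
        )
    return genes


def write_genes_gff3(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write gene records as minimal GFF3 ``gene`` lines."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tltrmap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

def write_site_table(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a called-site table as TSV.

    ``sites`` must carry the 0-based :data:`SITE_COLUMNS` schema (the
    ``display`` column is regenerated from chrom/junction). Round-trips
    losslessly through :func:`read_site_table`.
    """
    df = sites.reindex(columns=SITE_COLUMNS).copy()
    if len(df):
        df["display"] = [
            display_label(c, j) for c, j in zip(df["chrom"], df["junction"])
        ]
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "individual": str,
            "chrom": str,
            "polarity": str,
            "display": str,
        },
    )
    if len(df) == 0:
        df = pd.DataFrame(columns=SITE_COLUMNS)
    for col in ("start", "end", "junction", "peak_depth", "n_reads"):
        df[col] = df[col].astype(int)
    df["env_flagged"] = df["env_flagged"].astype(bool)
    return df.reindex(columns=SITE_COLUMNS)


# ---------------------------------------------------------------------------
# Coverage (bedGraph)
# ---------------------------------------------------------------------------

def write_bedgraph(
    runs_by_chrom: Mapping[str, Iterable[tuple[int, int, int]]],
    path: str | Path,
) -> None:
    """Write collapsed coverage runs as bedGraph (non-zero runs only)."""
    with open(path, "w") as fh:
        for chrom in runs_by_chrom:
            for start, end, depth in runs_by_chrom[chrom]:
                if depth > 0:
                    fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Read bedGraph into ``{chrom: array of (start, end, depth) rows}``."""
    out: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path} line {lineno}: expected 4 fields")
            out.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), int(float(fields[3])))
            )
    return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}
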