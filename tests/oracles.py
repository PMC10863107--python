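"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive per-base / all-pairs algorithms (or an
independent library routine) and never share code with the package paths
they verify.
"""

from __future__ import annotations

import numpy as np


def naive_pileup(reads_df, chrom_length: int, chrom: str) -> np.ndarray:
    """Per-base depth array for one chromosome by direct counting."""
    depth = np.zeros(chrom_length, dtype=np.int64)
    grp = reads_df[reads_df["chrom"] == chrom]
    for start, end in zip(grp["start"], grp["end"]):
        depth[start:end] += 1
    return depth


def runs_to_array(runs: np.ndarray, chrom_length: int) -> np.ndarray:
    """Expand collapsed (start, end, depth) runs to a per-base array."""
    depth = np.zeros(chrom_length, dtype=np.int64)
    for start, end, d in runs:
        depth[start:end] = d
    return depth


def naive_intervals(depth: np.ndarray, floor: int) -> list[tuple[int, int, int]]:
    """Maximal runs of consecutive bases with depth >= floor, with peak."""
    out = []
    start = None
    for i, d in enumerate(depth):
        if d >= floor and start is None:
            start = i
        elif d < floor and start is not None:
            out.append((start, i, int(depth[start:i].max())))
            start = None
    if start is not None:
        out.append((start, len(depth), int(depth[start:].max())))
    return out


def brute_force_proximity(
    genes, junction: int, chrom: str, window: int
) -> set[str]:
    """All-pairs scan: gene ids whose body is within `window` of junction."""
    hits = set()
    for g in genes:
        if g.chrom != chrom:
            continue
        dist = max(g.start - junction, junction - g.end + 1, 0)
        if dist <= window:
            hits.add(g.gene_id)
    return hits
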