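"""Writers/readers for the genomic track dialects the pipeline exchanges.

Everything is plain text: bedGraph for per-bin signal tracks, BED for interval
classes, BEDPE for bin-pair features (loops, differential pixels).  All
coordinates are 0-based, half-open, bin-aligned.
"""

from __future__ import annotations

import numpy as np

from .genome import BinnedGenome

__all__ = ["write_bedgraph", "write_bed", "read_bed", "write_bedpe", "read_bedpe"]


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def write_bedgraph(path, genome: BinnedGenome, values: dict[str, np.ndarray]) -> None:
    """Per-bin signal as bedGraph; NaN bins are skipped."""
    res = genome.resolution
    with open(path, "w") as fh:
        for chrom in genome.names:
            track = values[chrom]
            for i, v in enumerate(track):
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{i * res}\t{genome.bin_end(chrom, i)}\t{_fmt(v)}\n")


def write_bed(path, intervals) -> None:
    """Intervals as BED; each record is (chrom, start, end[, name[, score]])."""
    with open(path, "w") as fh:
        for rec in intervals:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            name = rec[3] if len(rec) > 3 else "."
            score = _fmt(rec[4]) if len(rec) > 4 else "0"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\n")


def read_bed(path) -> list[tuple]:
    """BED records as (chrom, start, end, name) tuples (name '.' if absent)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            out.append((p[0], int(p[1]), int(p[2]), p[3] if len(p) > 3 else "."))
    return out


def write_bedpe(path, records) -> None:
    """Bin pairs as BEDPE: (chrom1, s1, e1, chrom2, s2, e2, name, score, *extra)."""
    with open(path, "w") as fh:
        for rec in records:
            c1, s1, e1, c2, s2, e2 = rec[:6]
            name = rec[6] if len(rec) > 6 else "."
            score = _fmt(rec[7]) if len(rec) > 7 else "0"
            extra = "".join(f"\t{_fmt(x) if isinstance(x, float) else x}" for x in rec[8:])
            fh.write(f"{c1}\t{int(s1)}\t{int(e1)}\t{c2}\t{int(s2)}\t{int(e2)}\t{name}\t{score}{extra}\n")


def read_bedpe(path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            out.append(
                (p[0], int(p[1]), int(p[2]), p[3], int(p[4]), int(p[5]), *p[6:])
            )
    return out
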