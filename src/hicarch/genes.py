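"""Gene annotation and differential-expression tables.

A :class:`GeneTable` wraps a pandas DataFrame of gene intervals (BED-style,
0-based half-open) with a strand-aware transcription start site (TSS): the
interval start on ``+``, ``end - 1`` on ``-``.  A :class:`DEGTable` carries the
differential-expression summary consumed by the integration stage (gene id,
log2 fold change, FDR); it is an input, never fitted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinnedGenome

__all__ = ["GeneTable", "DEGTable"]


@dataclass
class GeneTable:
    """Gene intervals with unique ids and strand-aware TSS."""

    df: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("gene with start >= end")
        if not self.df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tss(self) -> pd.Series:
        """Strand-aware TSS position per gene."""
        return pd.Series(
            np.where(self.df["strand"] == "+", self.df["start"], self.df["end"] - 1),
            index=self.df.index,
        )

    def tss_bins(self, genome: BinnedGenome) -> pd.DataFrame:
        """Per gene: chromosome and bin index of the TSS (genes off the genome dropped)."""
        out = self.df[["gene_id", "chrom"]].copy()
        out["bin"] = self.tss // genome.resolution
        keep = [
            chrom in genome and b < genome.n_bins(chrom)
            for chrom, b in zip(out["chrom"], out["bin"])
        ]
        return out.loc[keep].reset_index(drop=True)

    def counts_per_bin(self, genome: BinnedGenome) -> dict[str, np.ndarray]:
        """Number of gene TSSs in every bin, per chromosome."""
        tb = self.tss_bins(genome)
        out = {}
        for chrom in genome.names:
            counts = np.zeros(genome.n_bins(chrom), dtype=int)
            bins = tb.loc[tb["chrom"] == chrom, "bin"].to_numpy()
            np.add.at(counts, bins, 1)
            out[chrom] = counts
        return out

    # -- I/O (BED6: chrom start end name score strand) --------------------

    @classmethod
    def read_bed(cls, path) -> "GeneTable":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: need BED6 (6 columns)")
                rows.append(
                    {
                        "gene_id": parts[3],
                        "chrom": parts[0],
                        "start": int(parts[1]),
                        "end": int(parts[2]),
                        "strand": parts[5],
                    }
                )
        return cls(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]))

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
                )


@dataclass
class DEGTable:
    """Differential-expression summary: gene id, log2 fold change, FDR."""

    df: pd.DataFrame  # columns: gene_id, log2fc, fdr

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "fdr"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"DEG table missing columns: {sorted(missing)}")
        fdr = self.df["fdr"]
        if ((fdr < 0) | (fdr > 1)).any():
            raise ValueError("FDR outside [0, 1]")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_tsv(cls, path) -> "DEGTable":
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={"gene": "gene_id"})
        return cls(df[["gene_id", "log2fc", "fdr"]])

    def write_tsv(self, path) -> None:
        out = self.df.rename(columns={"gene_id": "gene"})
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")
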