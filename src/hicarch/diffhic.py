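"""Differential-contact detection between two conditions.

The procedure mirrors joint MD normalisation: for every shared pixel the
log2 ratio M of the two conditions is plotted against the bin distance D, a
loess (tricube-weighted local linear) fit of M on D absorbs depth and
distance-dependent bias between the conditions, and the residual adjusted M
is converted to a robust Z-score per distance stratum (median/MAD), a
two-sided normal p-value, and a Benjamini-Hochberg adjusted p across all
pixels.  Pixels with adjusted p at or below the FDR are the differential
contacts; their anchor bins, merged when adjacent, form the 1-D
"differential contact regions" used by the integration stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import BinnedGenome
from .matrix import ContactMatrix
from .stats import bh_adjust

__all__ = [
    "PixelPairTable",
    "DifferentialContactSet",
    "md_table",
    "loess_joint_normalize",
    "detect_differential",
]


@dataclass
class PixelPairTable:
    """Per-pixel MD table for a pair of matrices.

    ``df`` columns: chrom, bin_i, bin_j, value1, value2, D (bin distance),
    M (log2 ratio with pseudocount), and after normalisation adj_M; after
    testing Z, pvalue, padj.
    """

    genome: BinnedGenome
    df: pd.DataFrame
    pseudocount: float = 1.0
    loess_fit: pd.Series | None = None  # fitted M per distance
    normalized: bool = False


@dataclass
class DifferentialContactSet:
    """Retained differential pixels and their merged 1-D anchor regions."""

    genome: BinnedGenome
    pixels: pd.DataFrame  # subset of PixelPairTable.df with Z, pvalue, padj
    fdr: float
    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def region_intervals_bp(self) -> list[tuple[str, int, int]]:
        res = self.genome.resolution
        out = []
        for chrom in self.genome.names:
            for s, e in self.regions.get(chrom, []):
                out.append((chrom, s * res, min(e * res, self.genome.length(chrom))))
        return out

    def anchor_bins(self) -> list[tuple[str, int]]:
        """Distinct (chrom, bin) anchors of the retained pixels."""
        seen = set()
        for r in self.pixels.itertuples(index=False):
            seen.add((r.chrom, int(r.bin_i)))
            seen.add((r.chrom, int(r.bin_j)))
        return sorted(seen)


def md_table(
    m1: ContactMatrix,
    m2: ContactMatrix,
    pseudocount: float = 1.0,
    max_distance: int | None = 100,
) -> PixelPairTable:
    """Build the MD table over the union of nonzero pixels of two matrices.

    ``M = log2((value2 + pseudocount) / (value1 + pseudocount))``,
    ``D = bin_j - bin_i``.  Pixels where both values are zero are excluded;
    ``max_distance`` (bins) limits the range of distances considered
    (``None`` keeps all).  Raises on genome mismatch.
    """
    if m1.genome != m2.genome:
        raise ValueError("matrices use different binned genomes")
    rows = []
    for chrom in m1.genome.names:
        a, b = m1.data[chrom], m2.data[chrom]
        n = a.shape[0]
        iu, ju = np.triu_indices(n)
        if max_distance is not None:
            keep = (ju - iu) <= max_distance
            iu, ju = iu[keep], ju[keep]
        va, vb = a[iu, ju], b[iu, ju]
        ok = np.isfinite(va) & np.isfinite(vb) & ((va != 0) | (vb != 0))
        iu, ju, va, vb = iu[ok], ju[ok], va[ok], vb[ok]
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_i": iu,
                    "bin_j": ju,
                    "value1": va,
                    "value2": vb,
                    "D": ju - iu,
                    "M": np.log2((vb + pseudocount) / (va + pseudocount)),
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    return PixelPairTable(m1.genome, df, pseudocount=pseudocount)


def loess_joint_normalize(t: PixelPairTable, span: float = 0.3) -> PixelPairTable:
    """Loess fit of M on D; adjusted M = M - fit(D).

    The tricube local-linear smoother is fitted on the per-distance mean M
    (every distance stratum pools all its pixels) and evaluated at each
    pixel's distance.  Requires at least 10 distinct distances; raises with a
    suggestion when ``span`` covers fewer than 4 of them.
    """
    df = t.df
    dist_means = df.groupby("D")["M"].mean()
    n_dist = len(dist_means)
    if n_dist < 10:
        raise ValueError(f"need >= 10 distinct distances, got {n_dist}")
    if span * n_dist < 4:
        raise ValueError(
            f"span {span} too small for {n_dist} distances; try span >= {4 / n_dist:.2f}"
        )
    x = dist_means.index.to_numpy(dtype=float)
    y = dist_means.to_numpy()
    fitted = lowess(y, x, frac=span, it=3, return_sorted=False)
    fit = pd.Series(fitted, index=dist_means.index)
    out = df.copy()
    out["adj_M"] = out["M"] - fit.reindex(out["D"]).to_numpy()
    return PixelPairTable(t.genome, out, t.pseudocount, loess_fit=fit, normalized=True)


def _pooled_strata(df: pd.DataFrame, min_pixels: int = 100) -> np.ndarray:
    """Assign each pixel a stratum id, pooling sparse distances into neighbours."""
    counts = df.groupby("D").size().sort_index()
    stratum_of: dict[int, int] = {}
    current: list[int] = []
    total = 0
    sid = 0
    for d, c in counts.items():
        current.append(d)
        total += c
        if total >= min_pixels:
            for dd in current:
                stratum_of[dd] = sid
            sid += 1
            current, total = [], 0
    if current:  # merge the tail into the previous stratum
        tail_sid = max(sid - 1, 0)
        for dd in current:
            stratum_of[dd] = tail_sid
    return df["D"].map(stratum_of).to_numpy()


def detect_differential(t: PixelPairTable, fdr: float = 0.05) -> DifferentialContactSet:
    """Robust Z-test of adjusted M per distance stratum, BH across pixels.

    Each pixel's adjusted M is first whitened by its delta-method standard
    deviation for a log2 count ratio, ``sqrt(1/(v1+pc) + 1/(v2+pc)) / ln 2``,
    so pixels of different intensity at the same distance are comparable;
    the whitened residuals are then centred on the stratum median and scaled
    by 1.4826 x stratum MAD (strata with fewer than 100 pixels pool into
    neighbours).  Pixels with BH-adjusted two-sided normal p <= ``fdr`` are
    retained; their anchor bins merged when adjacent give the differential
    contact regions.  Requires a loess-normalised table.
    """
    if not t.normalized:
        raise ValueError("table must be loess-normalised first")
    df = t.df
    if len(df) == 0:
        raise ValueError("no pixels to test")
    df = df.copy().reset_index(drop=True)
    df["_stratum"] = _pooled_strata(df)
    pc = t.pseudocount
    sd_pix = np.sqrt(
        1.0 / (df["value1"].to_numpy() + pc) + 1.0 / (df["value2"].to_numpy() + pc)
    ) / np.log(2.0)
    df["_w"] = df["adj_M"].to_numpy() / sd_pix
    z = np.zeros(len(df))
    for _, grp in df.groupby("_stratum"):
        vals = grp["_w"].to_numpy()
        med = np.median(vals)
        mad = np.median(np.abs(vals - med)) * 1.4826
        if mad == 0:
            mad = vals.std(ddof=0)
        if mad == 0:
            continue  # constant stratum: Z stays 0
        z[grp.index.to_numpy()] = (vals - med) / mad
    df["Z"] = z
    df["pvalue"] = 2.0 * sps.norm.sf(np.abs(z))
    df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    kept = df[df["padj"] <= fdr].drop(columns=["_stratum", "_w"]).reset_index(drop=True)

    regions: dict[str, list[tuple[int, int]]] = {}
    for chrom in t.genome.names:
        sub = kept[kept["chrom"] == chrom]
        bins = sorted(set(sub["bin_i"]).union(sub["bin_j"]))
        merged: list[tuple[int, int]] = []
        for bin_ in bins:
            if merged and bin_ == merged[-1][1]:
                merged[-1] = (merged[-1][0], bin_ + 1)
            else:
                merged.append((bin_, bin_ + 1))
        regions[chrom] = merged
    return DifferentialContactSet(t.genome, kept, fdr, regions)
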