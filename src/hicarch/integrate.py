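"""Integration of expression with chromatin architecture.

This is where the comparative analyses meet: DEG filtering, promoter
construction, interval overlap, per-bin architecture classes (common vs
changed compartments and domains), hypergeometric enrichment of gene sets and
differential-contact anchors in those classes, promoter density contrasts in
differential contact regions, and per-gene virtual-4C interaction profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compartments import CompartmentComparison
from .diffhic import DifferentialContactSet
from .domains import DomainComparison
from .genes import DEGTable, GeneTable
from .genome import BinnedGenome
from .matrix import ContactMatrix
from .stats import bh_adjust, hypergeom_pvalue

__all__ = [
    "RegionClassMap",
    "EnrichmentResult",
    "filter_degs",
    "promoters",
    "overlap_count",
    "hypergeom_enrichment",
    "enrich_genes_in_classes",
    "enrich_pixels_in_classes",
    "promoter_density_contrast",
    "gene_interaction_profile",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of k class hits among n draws (pop N, class K)."""

    N: int
    K: int
    n: int
    k: int
    fold: float
    pvalue: float


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Upper-tail hypergeometric test with fold enrichment (k/n)/(K/N)."""
    p = hypergeom_pvalue(N, K, n, k)
    if n == 0 or K == 0:
        raise ValueError("empty draw (n=0) or empty class (K=0)")
    fold = (k / n) / (K / N)
    return EnrichmentResult(N, K, n, k, fold, p)


@dataclass
class RegionClassMap:
    """Per-bin architecture classes from the two comparison layers.

    ``compartment[chrom]``: 'common-A', 'common-B', 'changed', or 'NA'.
    ``domain[chrom]``: 'common-TAD-interior', 'changed-TAD-interior',
    'common-boundary', 'changed-boundary', 'non-TAD'.
    """

    genome: BinnedGenome
    compartment: dict[str, np.ndarray]
    domain: dict[str, np.ndarray]

    @classmethod
    def from_comparisons(
        cls,
        comp: CompartmentComparison,
        doms: DomainComparison,
    ) -> "RegionClassMap":
        compartment = {}
        for chrom, arr in comp.classes.items():
            out = arr.copy()
            out[(arr == "A->B") | (arr == "B->A")] = "changed"
            compartment[chrom] = out
        domain = {c: a.copy() for c, a in doms.classes.items()}
        return cls(comp.genome, compartment, domain)

    def class_labels(self, dimension: str) -> list[str]:
        source = self.compartment if dimension == "compartment" else self.domain
        labels: set[str] = set()
        for arr in source.values():
            labels.update(str(x) for x in np.unique(arr))
        labels.discard("NA")
        return sorted(labels)

    def bins_of(self, dimension: str, label: str) -> dict[str, np.ndarray]:
        source = self.compartment if dimension == "compartment" else self.domain
        return {c: np.flatnonzero(arr == label) for c, arr in source.items()}


# ---------------------------------------------------------------------------
# DEGs and promoters


def filter_degs(t: DEGTable, max_fdr: float = 0.05, min_fold: float = 2.0) -> set[str]:
    """Gene ids with FDR <= max_fdr and |log2FC| >= log2(min_fold) (two-sided)."""
    df = t.df
    keep = (df["fdr"] <= max_fdr) & (df["log2fc"].abs() >= math.log2(min_fold))
    return set(df.loc[keep, "gene_id"])


def promoters(
    g: GeneTable,
    genome: BinnedGenome,
    upstream: int = 2000,
    downstream: int = 200,
) -> pd.DataFrame:
    """Strand-aware promoter intervals, clipped to the chromosome.

    ``[TSS - upstream, TSS + downstream)`` on '+', mirrored on '-'.  Returns
    a DataFrame (gene_id, chrom, start, end).
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if upstream == 0 and downstream == 0:
        raise ValueError("promoter window cannot be empty")
    tss = g.tss.to_numpy()
    plus = (g.df["strand"] == "+").to_numpy()
    start = np.where(plus, tss - upstream, tss - downstream + 1)
    end = np.where(plus, tss + downstream, tss + upstream + 1)
    out = pd.DataFrame(
        {"gene_id": g.df["gene_id"], "chrom": g.df["chrom"], "start": start, "end": end}
    )
    lens = out["chrom"].map(lambda c: genome.length(c) if c in genome else 0)
    out["start"] = np.maximum(out["start"], 0)
    out["end"] = np.minimum(out["end"], lens)
    return out[out["end"] > out["start"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Interval overlap


def overlap_count(a: pd.DataFrame, b: pd.DataFrame) -> tuple[int, int, list[tuple[int, int]]]:
    """Count interval overlaps between two half-open interval sets.

    ``a`` and ``b`` are DataFrames with chrom/start/end columns.  Returns
    (#a intervals hitting b, #b intervals hit, list of (a_index, b_index)
    pairs).  Overlap = nonempty intersection.
    """
    pairs: list[tuple[int, int]] = []
    b_by_chrom = {c: sub.sort_values("start") for c, sub in b.groupby("chrom")}
    for ai, arow in a.iterrows():
        sub = b_by_chrom.get(arow["chrom"])
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # candidates: b.start < a.end and b.end > a.start
        hi = np.searchsorted(starts, arow["end"], side="left")
        hit = np.flatnonzero(ends[:hi] > arow["start"])
        pairs.extend((ai, int(sub.index[h])) for h in hit)
    hit_a = len({p[0] for p in pairs})
    hit_b = len({p[1] for p in pairs})
    return hit_a, hit_b, pairs


# ---------------------------------------------------------------------------
# Enrichment


def _gene_bins(universe: GeneTable, genome: BinnedGenome) -> pd.DataFrame:
    tb = universe.tss_bins(genome)
    return tb.set_index("gene_id")


def enrich_genes_in_classes(
    gene_set: set[str],
    universe: GeneTable,
    classes: RegionClassMap,
    dimensions: tuple[str, ...] = ("compartment", "domain"),
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene set in each architecture class.

    Genes map to bins by TSS.  Per class: N = universe genes on classified
    bins of that dimension, K = those on class bins, n = gene-set members on
    classified bins, k = members on class bins.  Returns a DataFrame with a
    BH-adjusted p across the tested classes; empty classes are skipped with
    a warning.
    """
    genome = classes.genome
    gb = _gene_bins(universe, genome)
    unknown = gene_set - set(gb.index)
    if unknown:
        raise ValueError(f"gene set contains ids outside the universe: {sorted(unknown)[:5]}")
    rows = []
    for dim in dimensions:
        source = classes.compartment if dim == "compartment" else classes.domain
        gene_class = np.array(
            [str(source[c][b]) for c, b in zip(gb["chrom"], gb["bin"])], dtype=object
        )
        classified = gene_class != "NA"
        in_set = gb.index.isin(list(gene_set))
        N = int(classified.sum())
        n = int((classified & in_set).sum())
        for label in classes.class_labels(dim):
            on_class = gene_class == label
            K = int(on_class.sum())
            k = int((on_class & in_set).sum())
            if K == 0 or n == 0:
                warnings.warn(f"class {label}: empty class or gene set; skipped")
                continue
            r = hypergeom_enrichment(N, K, n, k)
            rows.append(
                {
                    "dimension": dim, "class": label,
                    "N": r.N, "K": r.K, "n": r.n, "k": r.k,
                    "fold": r.fold, "pvalue": r.pvalue,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def enrich_pixels_in_classes(
    dc: DifferentialContactSet,
    classes: RegionClassMap,
    dimensions: tuple[str, ...] = ("compartment", "domain"),
) -> pd.DataFrame:
    """Enrichment of differential-contact anchor bins in architecture classes.

    Unit = anchor bin: N = classified bins, K = class bins, n = distinct
    anchor bins of the differential pixels, k = anchors on class bins.
    """
    anchors = dc.anchor_bins()
    rows = []
    for dim in dimensions:
        source = classes.compartment if dim == "compartment" else classes.domain
        all_classes = np.concatenate([source[c] for c in classes.genome.names])
        classified = all_classes != "NA"
        N = int(classified.sum())
        anchor_class = np.array(
            [str(source[c][b]) for c, b in anchors], dtype=object
        )
        n = int((anchor_class != "NA").sum())
        for label in classes.class_labels(dim):
            K = int((all_classes == label).sum())
            k = int((anchor_class == label).sum())
            if K == 0 or n == 0:
                warnings.warn(f"class {label}: empty class or anchor set; skipped")
                continue
            r = hypergeom_enrichment(N, K, n, k)
            rows.append(
                {
                    "dimension": dim, "class": label,
                    "N": r.N, "K": r.K, "n": r.n, "k": r.k,
                    "fold": r.fold, "pvalue": r.pvalue,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Promoter density and interaction profiles


def promoter_density_contrast(
    promoter_intervals: pd.DataFrame,
    dc: DifferentialContactSet,
    genome: BinnedGenome,
) -> dict:
    """Promoter density (per Mb) inside vs outside differential contact regions.

    A promoter counts as inside when it overlaps any merged region.  Returns
    a dict with both densities and their ratio (``inf`` when the background
    density is zero).  Raises on an empty region set.
    """
    regions = dc.region_intervals_bp()
    if not regions:
        raise ValueError("empty differential contact region set")
    reg_df = pd.DataFrame(regions, columns=["chrom", "start", "end"])
    hit_a, _, _ = overlap_count(promoter_intervals, reg_df)
    inside_bp = sum(e - s for _, s, e in regions)
    total_bp = genome.total_length
    outside_bp = total_bp - inside_bp
    n_in = hit_a
    n_out = len(promoter_intervals) - hit_a
    dens_in = n_in / (inside_bp / 1e6)
    dens_out = n_out / (outside_bp / 1e6) if outside_bp > 0 else float("nan")
    if dens_out == 0:
        ratio = float("inf")
    else:
        ratio = dens_in / dens_out
    return {
        "n_inside": n_in,
        "n_outside": n_out,
        "density_inside_per_mb": dens_in,
        "density_outside_per_mb": dens_out,
        "ratio": ratio,
    }


def gene_interaction_profile(
    gene_id: str,
    oe: ContactMatrix,
    genes: GeneTable,
    flank: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Virtual-4C profile of a gene: the O/E row anchored at its TSS bin.

    Returns ``(offsets_bp, values)`` for bins within ``flank`` bp of the
    anchor; NaN at masked bins.  Raises when the gene is absent, its TSS bin
    is masked, or the flank is smaller than one bin.
    """
    res = oe.genome.resolution
    if flank < res:
        raise ValueError(f"flank {flank} smaller than one bin ({res})")
    row = genes.df[genes.df["gene_id"] == gene_id]
    if row.empty:
        raise ValueError(f"gene {gene_id!r} not in gene table")
    chrom = row.iloc[0]["chrom"]
    tss = int(genes.tss[row.index[0]])
    anchor = tss // res
    mat = oe.data[chrom]
    n = mat.shape[0]
    if anchor >= n or np.all(np.isnan(mat[anchor])):
        raise ValueError(f"gene {gene_id!r}: TSS bin {anchor} is masked")
    f = flank // res
    lo, hi = max(0, anchor - f), min(n, anchor + f + 1)
    offsets = (np.arange(lo, hi) - anchor) * res
    return offsets, mat[anchor, lo:hi].copy()
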