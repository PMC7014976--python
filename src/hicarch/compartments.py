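"""A/B compartment calling and between-condition compartment comparison.

Compartments are called per chromosome from the correlation structure of the
O/E matrix: the Pearson correlation matrix of O/E columns is computed over
unmasked bins and its first principal component assigns each bin a real value
whose sign separates the two compartments (the checkerboard eigenstructure of
Hi-C maps).  The sign is then oriented so that positive bins (compartment A)
carry the higher mean gene density, matching the active/gene-rich character
of A compartments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genes import GeneTable
from .genome import BinnedGenome
from .matrix import ContactMatrix
from .stats import WelchResult, welch_ttest

__all__ = [
    "EigenTrack",
    "CompartmentComparison",
    "call_compartments",
    "compare_compartments",
    "compartment_gene_stats",
]


@dataclass
class EigenTrack:
    """Per-bin leading-eigenvector values with A/B labels.

    ``values[chrom][i]`` is the oriented PC1 score of bin ``i`` (NaN = masked).
    Label A <=> value > 0, B <=> value < 0.  ``orientation_evidence`` records
    the mean gene count of positive vs negative bins used to fix the sign.
    """

    genome: BinnedGenome
    values: dict[str, np.ndarray]
    orientation_evidence: dict[str, tuple[float, float]] = field(default_factory=dict)

    def labels(self, chrom: str) -> np.ndarray:
        """Per-bin labels: 'A', 'B', or 'NA'."""
        v = self.values[chrom]
        out = np.full(v.shape, "NA", dtype=object)
        out[v > 0] = "A"
        out[v < 0] = "B"
        return out


@dataclass
class CompartmentComparison:
    """Per-bin joint classification of two oriented eigentracks.

    Classes: ``common-A``, ``common-B``, ``A->B``, ``B->A``, ``NA``.  A
    "changed region" is a maximal run of sign-discordant bins of length at
    least ``min_run``.
    """

    genome: BinnedGenome
    classes: dict[str, np.ndarray]
    min_run: int = 1

    @property
    def summary(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for arr in self.classes.values():
            labels, n = np.unique(arr, return_counts=True)
            for lab, c in zip(labels, n):
                counts[lab] = counts.get(lab, 0) + int(c)
        return counts

    def changed_bins(self, chrom: str) -> np.ndarray:
        """Boolean mask of bins inside changed regions (runs >= min_run)."""
        arr = self.classes[chrom]
        disc = (arr == "A->B") | (arr == "B->A")
        if self.min_run <= 1:
            return disc
        out = np.zeros_like(disc)
        i = 0
        n = len(disc)
        while i < n:
            if disc[i]:
                j = i
                while j < n and disc[j]:
                    j += 1
                if j - i >= self.min_run:
                    out[i:j] = True
                i = j
            else:
                i += 1
        return out

    def changed_regions(self, chrom: str) -> list[tuple[int, int]]:
        """Maximal runs of changed bins as half-open (start_bin, end_bin)."""
        mask = self.changed_bins(chrom)
        regions = []
        i = 0
        n = len(mask)
        while i < n:
            if mask[i]:
                j = i
                while j < n and mask[j]:
                    j += 1
                regions.append((i, j))
                i = j
            else:
                i += 1
        return regions


def _pc1(corr: np.ndarray) -> np.ndarray:
    """PC1 scores of a correlation matrix (rows as observations)."""
    centered = corr - corr.mean(axis=0, keepdims=True)
    # SVD of the centered matrix: leading left singular vector scaled by its
    # singular value = projection of each row on the first principal axis.
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    pc = u[:, 0] * s[0]
    return pc


def call_compartments(
    oe: ContactMatrix,
    genes: GeneTable | None = None,
    min_bins: int = 10,
) -> EigenTrack:
    """Call A/B compartments from an O/E matrix.

    Per chromosome: Pearson correlation matrix of O/E columns over unmasked
    bins, then its first principal component; the sign is oriented so that
    positive bins have the higher mean gene count (when a gene table is
    given).  Chromosomes with fewer than ``min_bins`` unmasked bins, or with
    degenerate (zero-variance) correlation structure, are marked NA with a
    warning.
    """
    gene_counts = genes.counts_per_bin(oe.genome) if genes is not None else None
    values: dict[str, np.ndarray] = {}
    evidence: dict[str, tuple[float, float]] = {}

    for chrom in oe.genome.names:
        mat = oe.data[chrom]
        n = mat.shape[0]
        track = np.full(n, np.nan)
        unmasked = ~np.all(np.isnan(mat), axis=1)
        idx = np.flatnonzero(unmasked)
        if idx.size < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} unmasked bins; marked NA")
            values[chrom] = track
            continue
        sub = mat[np.ix_(idx, idx)]
        sub = np.nan_to_num(sub, nan=0.0)
        sd = sub.std(axis=0)
        good = sd > 0
        if good.sum() < min_bins:
            warnings.warn(f"{chrom}: degenerate O/E (constant columns); marked NA")
            values[chrom] = track
            continue
        idx = idx[good]
        sub = sub[np.ix_(good, good)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        pc = _pc1(corr)
        track[idx] = pc

        if gene_counts is not None:
            gc = gene_counts[chrom]
            pos = track > 0
            neg = track < 0
            mean_pos = gc[pos].mean() if pos.any() else 0.0
            mean_neg = gc[neg].mean() if neg.any() else 0.0
            if mean_neg > mean_pos:
                track = -track
                mean_pos, mean_neg = mean_neg, mean_pos
            elif mean_neg == mean_pos:
                warnings.warn(f"{chrom}: orientation tie (equal gene densities); keeping sign")
            evidence[chrom] = (float(mean_pos), float(mean_neg))
        values[chrom] = track

    return EigenTrack(oe.genome, values, evidence)


def compare_compartments(
    t1: EigenTrack,
    t2: EigenTrack,
    min_run: int = 1,
) -> CompartmentComparison:
    """Classify every bin by its compartment status in two oriented tracks."""
    if t1.genome != t2.genome:
        raise ValueError("eigentracks use different binned genomes")
    classes: dict[str, np.ndarray] = {}
    for chrom in t1.genome.names:
        v1, v2 = t1.values[chrom], t2.values[chrom]
        out = np.full(v1.shape, "NA", dtype=object)
        ok = ~np.isnan(v1) & ~np.isnan(v2) & (v1 != 0) & (v2 != 0)
        out[ok & (v1 > 0) & (v2 > 0)] = "common-A"
        out[ok & (v1 < 0) & (v2 < 0)] = "common-B"
        out[ok & (v1 > 0) & (v2 < 0)] = "A->B"
        out[ok & (v1 < 0) & (v2 > 0)] = "B->A"
        classes[chrom] = out
    return CompartmentComparison(t1.genome, classes, min_run=min_run)


def compartment_gene_stats(t: EigenTrack, genes: GeneTable) -> WelchResult:
    """Welch's t-test of per-bin gene counts in A vs B compartment bins.

    Pools bins across chromosomes.  Raises if either compartment has fewer
    than two bins.
    """
    gene_counts = genes.counts_per_bin(t.genome)
    a_counts, b_counts = [], []
    for chrom in t.genome.names:
        v = t.values[chrom]
        gc = gene_counts[chrom]
        a_counts.append(gc[v > 0])
        b_counts.append(gc[v < 0])
    a = np.concatenate(a_counts)
    b = np.concatenate(b_counts)
    return welch_ttest(a, b)
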