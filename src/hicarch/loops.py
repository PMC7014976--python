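"""Focal chromatin-loop detection with a donut local background, plus APA.

A loop is a pixel whose contact count exceeds what its local neighbourhood
predicts at that genomic distance.  The caller scores every candidate pixel
against a donut background: the mean O/E ratio over a square annulus around
the pixel, excluding the central peak box and the same-row/column bands
(which share the anchors' biases).  The observed raw count is tested against
a Poisson rate equal to the donut-scaled local expectation mapped back to raw
units via the balancing biases; BH correction runs per distance stratum, and
adjacent significant pixels merge to their most significant representative.

Aggregate peak analysis (APA) validates a loop list: O/E submatrices centred
on the loop pixels are averaged, and the score is the centre value over the
mean of the 3x3 lower-left corner block (the corner nearest the diagonal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from scipy.signal import fftconvolve

from .genome import BinnedGenome
from .matrix import BalancedMatrix, ContactMatrix, ExpectedProfile
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["LoopSet", "ApaResult", "call_loops", "apa", "compare_loops"]


@dataclass
class LoopSet:
    """Called loops: one row per retained pixel.

    ``df`` columns: chrom, bin_i, bin_j, observed (raw count), expected_local
    (raw-unit donut expectation), fold, pvalue, padj.
    """

    genome: BinnedGenome
    df: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def pixels(self) -> list[tuple[str, int, int]]:
        return [
            (r.chrom, int(r.bin_i), int(r.bin_j)) for r in self.df.itertuples(index=False)
        ]


@dataclass
class ApaResult:
    """Aggregate O/E submatrix around loop pixels and its APA score."""

    aggregate: np.ndarray  # (2k+1, 2k+1)
    score: float
    n_used: int
    n_dropped: int


def _donut_kernel(peak_width: int, donut_width: int) -> np.ndarray:
    size = 2 * donut_width + 1
    k = np.ones((size, size))
    c = donut_width
    band = peak_width
    k[c - band : c + band + 1, :] = 0.0  # same-row band (shares anchor i bias)
    k[:, c - band : c + band + 1] = 0.0  # same-column band
    return k


def _lower_left_kernel(peak_width: int, donut_width: int) -> np.ndarray:
    """The corner block between the pixel and the diagonal.

    Rejects domain-corner pixels: at the corner of a contact domain this
    region lies inside the domain, so the local expectation is high and the
    corner is not called as a loop.
    """
    size = 2 * donut_width + 1
    k = np.zeros((size, size))
    c = donut_width
    # convolution flips the kernel, so rows below / columns left of the pixel
    # are addressed by the upper-right block of the kernel array
    k[: c - peak_width, c + peak_width + 1 :] = 1.0
    return k


def call_loops(
    b: BalancedMatrix,
    e: ExpectedProfile,
    peak_width: int = 1,
    donut_width: int = 5,
    fdr: float = 0.05,
    min_sep: int = 2,
    min_fold: float = 2.0,
    max_distance: int = 100,
) -> LoopSet:
    """Call focal loops from a balanced matrix and its expected profile.

    Candidates are nonzero upper-triangle pixels with separation in
    ``[min_sep, max_distance]`` bins whose donut fits inside the matrix
    (others are skipped and logged).  The local expectation is the larger of
    the donut mean and the lower-left corner-block mean (the latter rejects
    domain corners).  Retained pixels satisfy BH-adjusted Poisson p <=
    ``fdr`` (per distance stratum) and fold >= ``min_fold``; adjacent
    significant pixels collapse to their most significant member.
    """
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1")
    kernel = _donut_kernel(peak_width, donut_width)
    ll_kernel = _lower_left_kernel(peak_width, donut_width)
    rows = []
    n_skipped = 0
    for chrom in b.genome.names:
        bal = b.matrix.data[chrom]
        bias = b.bias[chrom]
        mask = b.mask[chrom]
        prof = e.values[chrom].copy()
        prof[prof == 0] = np.nan
        n = bal.shape[0]
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            oem = bal / prof[d]
        valid = np.isfinite(oem)
        oez = np.where(valid, oem, 0.0)
        num = fftconvolve(oez, kernel, mode="same")
        den = fftconvolve(valid.astype(float), kernel, mode="same")
        num_ll = fftconvolve(oez, ll_kernel, mode="same")
        den_ll = fftconvolve(valid.astype(float), ll_kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            local_ratio = num / den
            ll_ratio = np.where(den_ll >= ll_kernel.sum() / 2, num_ll / den_ll, np.nan)
        local_ratio = np.fmax(local_ratio, ll_ratio)

        raw = bal * np.outer(np.nan_to_num(bias, nan=0.0), np.nan_to_num(bias, nan=0.0))
        iu, ju = np.triu_indices(n, k=min_sep)
        keep = (ju - iu) <= max_distance
        iu, ju = iu[keep], ju[keep]
        obs_bal = bal[iu, ju]
        cand = np.isfinite(obs_bal) & (obs_bal > 0) & mask[iu] & mask[ju]
        iu, ju = iu[cand], ju[cand]
        inside = (
            (iu - donut_width >= 0)
            & (ju + donut_width < n)
            & (ju - iu > donut_width)
            & (iu + donut_width < n)
            & (ju - donut_width >= 0)
        )
        n_skipped += int((~inside).sum())
        iu, ju = iu[inside], ju[inside]
        if iu.size == 0:
            continue
        lr = local_ratio[iu, ju]
        ok = np.isfinite(lr) & (lr > 0) & (den[iu, ju] >= kernel.sum() / 2)
        iu, ju, lr = iu[ok], ju[ok], lr[ok]
        dist = ju - iu
        exp_bal = lr * prof[dist]
        lam = exp_bal * bias[iu] * bias[ju]
        obs = np.rint(raw[iu, ju]).astype(int)
        pvals = sps.poisson.sf(obs - 1, lam)
        fold = (bal[iu, ju] / prof[dist]) / lr
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_i": iu,
                    "bin_j": ju,
                    "observed": obs,
                    "expected_local": lam,
                    "fold": fold,
                    "pvalue": pvals,
                    "dist": dist,
                }
            )
        )
    if n_skipped:
        logger.info("call_loops: skipped %d candidates with out-of-range donut", n_skipped)

    params = {
        "peak_width": peak_width,
        "donut_width": donut_width,
        "fdr": fdr,
        "min_sep": min_sep,
        "min_fold": min_fold,
        "max_distance": max_distance,
    }
    if not rows:
        empty = pd.DataFrame(
            columns=[
                "chrom", "bin_i", "bin_j", "observed", "expected_local",
                "fold", "pvalue", "padj",
            ]
        )
        return LoopSet(b.genome, empty, params)

    table = pd.concat(rows, ignore_index=True)
    # BH per distance stratum
    table["padj"] = 1.0
    for _, idx in table.groupby("dist").groups.items():
        table.loc[idx, "padj"] = bh_adjust(table.loc[idx, "pvalue"].to_numpy())
    sig = table[(table["padj"] <= fdr) & (table["fold"] >= min_fold)].copy()

    # merge adjacent significant pixels (8-connectivity) to their best pixel
    merged_rows = []
    for chrom, sub in sig.groupby("chrom"):
        n = b.genome.n_bins(chrom)
        grid = np.zeros((n, n), dtype=bool)
        grid[sub["bin_i"], sub["bin_j"]] = True
        labels, n_lab = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
        lab_of = labels[sub["bin_i"], sub["bin_j"]]
        sub = sub.assign(_lab=lab_of)
        best = sub.loc[sub.groupby("_lab")["pvalue"].idxmin()]
        merged_rows.append(best.drop(columns=["_lab"]))
    merged = (
        pd.concat(merged_rows, ignore_index=True)
        if merged_rows
        else sig.iloc[0:0]
    )
    merged = merged.drop(columns=["dist"]).sort_values(
        ["chrom", "bin_i", "bin_j"], ignore_index=True
    )
    return LoopSet(b.genome, merged, params)


def apa(
    oe: ContactMatrix,
    loops,
    half_window: int = 5,
) -> ApaResult:
    """Aggregate peak analysis of a loop list over an O/E matrix.

    ``loops`` is a :class:`LoopSet` or an iterable of (chrom, bin_i, bin_j).
    Pixels whose submatrix would cross a matrix edge or the diagonal are
    dropped (count reported); raises when no usable pixel remains.
    """
    if isinstance(loops, LoopSet):
        pixels = loops.pixels()
    else:
        pixels = list(loops)
    k = half_window
    acc = np.zeros((2 * k + 1, 2 * k + 1))
    cnt = np.zeros_like(acc)
    used = dropped = 0
    for chrom, i, j in pixels:
        mat = oe.data[chrom]
        n = mat.shape[0]
        if i - k < 0 or j + k >= n or (j - k) - (i + k) < 1 or j - k < 0 or i + k >= n:
            dropped += 1
            continue
        sub = mat[i - k : i + k + 1, j - k : j + k + 1]
        ok = np.isfinite(sub)
        acc[ok] += sub[ok]
        cnt += ok
        used += 1
    if used == 0:
        raise ValueError("no usable loop pixel for APA (all dropped)")
    if dropped:
        logger.info("apa: dropped %d pixels too close to edge/diagonal", dropped)
    with np.errstate(invalid="ignore", divide="ignore"):
        agg = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    center = agg[k, k]
    corner = agg[2 * k - 2 : 2 * k + 1, 0:3]
    score = float(center / np.nanmean(corner))
    return ApaResult(agg, score, used, dropped)


def compare_loops(l1, l2, tol: int = 1) -> dict:
    """Match loops between two sets when both anchors agree within ``tol`` bins.

    Greedy one-to-one matching by anchor distance.  Accepts
    :class:`LoopSet` or pixel iterables; returns a dict with ``common``
    (pairs), ``specific_to_1`` and ``specific_to_2`` pixel lists.
    """
    p1 = l1.pixels() if isinstance(l1, LoopSet) else list(l1)
    p2 = l2.pixels() if isinstance(l2, LoopSet) else list(l2)
    cands = []
    for a_idx, (c1, i1, j1) in enumerate(p1):
        for b_idx, (c2, i2, j2) in enumerate(p2):
            if c1 != c2:
                continue
            if abs(i1 - i2) <= tol and abs(j1 - j2) <= tol:
                cands.append((abs(i1 - i2) + abs(j1 - j2), a_idx, b_idx))
    cands.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    common = []
    for _, a_idx, b_idx in cands:
        if a_idx in used1 or b_idx in used2:
            continue
        used1.add(a_idx)
        used2.add(b_idx)
        common.append((p1[a_idx], p2[b_idx]))
    spec1 = [p for k, p in enumerate(p1) if k not in used1]
    spec2 = [p for k, p in enumerate(p2) if k not in used2]
    return {"common": common, "specific_to_1": spec1, "specific_to_2": spec2}
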