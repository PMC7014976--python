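"""Contact-matrix data model: I/O, ICE balancing, expected-by-distance, O/E.

The universal input of the pipeline is a per-chromosome symmetric matrix of
intra-chromosomal (cis) contact counts at a fixed bin resolution.  On disk the
format is a sparse upper-triangle TSV (``chrom  start1  start2  count``); in
memory, matrices are kept dense per chromosome because every analysis here runs
at desk scale (hundreds to a few thousand bins per chromosome).

Normalisation follows the iterative-correction (ICE / Sinkhorn) contract:
multiplicative per-bin biases such that the marginal sums of the balanced
matrix are equal over unmasked bins, with ``balanced[i, j] =
raw[i, j] / (bias[i] * bias[j])``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .genome import BinnedGenome

__all__ = [
    "ContactMatrix",
    "BalancedMatrix",
    "ExpectedProfile",
    "read_contacts",
    "write_contacts",
    "balance",
    "expected_profile",
    "oe_transform",
    "replicate_correlation",
]


@dataclass
class ContactMatrix:
    """Symmetric cis contact values for every chromosome of a binned genome.

    ``data[chrom]`` is an ``(n, n)`` float array, symmetric, with ``n`` the
    chromosome's bin count.  Values are raw counts for observed matrices, or
    real-valued for derived matrices (balanced, O/E); NaN marks unavailable
    entries (masked bins, undefined O/E strata).
    """

    genome: BinnedGenome
    data: dict[str, np.ndarray]
    sample: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        for chrom in self.genome.names:
            if chrom not in self.data:
                n = self.genome.n_bins(chrom)
                self.data[chrom] = np.zeros((n, n))
        for chrom, mat in self.data.items():
            if chrom not in self.genome:
                raise ValueError(f"matrix chromosome {chrom!r} not in genome")
            n = self.genome.n_bins(chrom)
            if mat.shape != (n, n):
                raise ValueError(f"{chrom}: matrix shape {mat.shape} != ({n}, {n})")

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.genome,
            {c: m.copy() for c, m in self.data.items()},
            self.sample,
            self.condition,
        )

    def scaled(self, factor: float) -> "ContactMatrix":
        """Copy with every value multiplied by ``factor`` (depth scaling)."""
        out = self.copy()
        for mat in out.data.values():
            mat *= factor
        return out

    def triplets(self, chrom: str) -> np.ndarray:
        """Upper-triangle nonzero entries as an ``(m, 3)`` array (i, j, value)."""
        mat = self.data[chrom]
        iu, ju = np.triu_indices_from(mat)
        vals = mat[iu, ju]
        keep = np.isfinite(vals) & (vals != 0)
        return np.column_stack([iu[keep], ju[keep], vals[keep]])

    @property
    def total(self) -> float:
        """Sum of upper-triangle values (diagonal counted once)."""
        tot = 0.0
        for chrom in self.genome.names:
            mat = self.data[chrom]
            tot += np.nansum(np.triu(mat))
        return tot


@dataclass
class BalancedMatrix:
    """An ICE-balanced matrix plus its per-bin biases and coverage mask.

    ``mask[chrom]`` is True for usable bins; ``bias[chrom]`` is NaN on masked
    bins.  ``convergence[chrom]`` records ``(iterations, final_cv, converged)``.
    """

    matrix: ContactMatrix
    bias: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]
    convergence: dict[str, tuple[int, float, bool]] = field(default_factory=dict)

    @property
    def genome(self) -> BinnedGenome:
        return self.matrix.genome


@dataclass
class ExpectedProfile:
    """Mean balanced contact value at each bin distance, per chromosome.

    ``values[chrom][d]`` is the mean over unmasked pairs at distance ``d``
    (absent entries counted as zero); NaN where a distance stratum has no
    unmasked pair.
    """

    genome: BinnedGenome
    values: dict[str, np.ndarray]

    def at(self, chrom: str, d: int) -> float:
        return float(self.values[chrom][d])


# ---------------------------------------------------------------------------
# I/O


def read_contacts(
    path,
    genome: BinnedGenome,
    sample: str = "",
    condition: str = "",
) -> ContactMatrix:
    """Load a sparse bin-pair TSV (``chrom  start1  start2  count``).

    Starts must be bin-aligned multiples of the genome resolution; symmetric
    duplicate records ``(j, i)`` are collapsed into ``(i, j)`` by summation.
    Malformed lines raise :class:`ValueError` naming the 1-based line number.
    """
    res = genome.resolution
    data = {c: np.zeros((genome.n_bins(c), genome.n_bins(c))) for c in genome.names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            chrom, s1, s2, cnt = parts
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start1, start2 = int(s1), int(s2)
                count = float(cnt)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            if start1 % res or start2 % res:
                raise ValueError(
                    f"{path}:{lineno}: start not aligned to {res} bp bins"
                )
            if count < 0 or not np.isfinite(count):
                raise ValueError(f"{path}:{lineno}: invalid count {cnt}")
            i, j = start1 // res, start2 // res
            n = genome.n_bins(chrom)
            if i >= n or j >= n:
                raise ValueError(f"{path}:{lineno}: bin outside chromosome {chrom}")
            if i > j:
                i, j = j, i
            data[chrom][i, j] += count
            if i != j:
                data[chrom][j, i] += count
    return ContactMatrix(genome, data, sample=sample, condition=condition)


def write_contacts(m: ContactMatrix, path) -> None:
    """Write the upper triangle as a sparse bin-pair TSV."""
    res = m.genome.resolution
    with open(path, "w") as fh:
        fh.write("chrom\tstart1\tstart2\tcount\n")
        for chrom in m.genome.names:
            for i, j, v in m.triplets(chrom):
                v = int(v) if float(v).is_integer() else v
                fh.write(f"{chrom}\t{int(i) * res}\t{int(j) * res}\t{v}\n")


# ---------------------------------------------------------------------------
# Balancing


def _marginal_cv(mat: np.ndarray, mask: np.ndarray) -> float:
    s = mat[np.ix_(mask, mask)].sum(axis=1)
    if s.size == 0 or s.mean() == 0:
        return np.inf
    return float(s.std() / s.mean())


def balance(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-6,
    min_nnz: int = 1,
    mask_quantile: float = 0.02,
) -> BalancedMatrix:
    """Iterative correction (ICE) of a raw contact matrix, per chromosome.

    Bins with fewer than ``min_nnz`` nonzero entries, and bins in the lowest
    ``mask_quantile`` fraction of nonzero-entry counts, are masked before
    iteration.  Iterates until the coefficient of variation of the unmasked
    marginals drops below ``tol``; failure to converge within ``max_iter``
    emits a warning (the result is still returned with its final CV recorded).

    Raises :class:`ValueError` if every bin of a chromosome is masked.
    """
    out_data: dict[str, np.ndarray] = {}
    biases: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    convergence: dict[str, tuple[int, float, bool]] = {}

    for chrom in m.genome.names:
        raw = m.data[chrom]
        n = raw.shape[0]
        nnz = (raw > 0).sum(axis=1)
        mask = nnz >= max(min_nnz, 1)
        if mask_quantile > 0 and mask.any():
            thresh = np.quantile(nnz[mask], mask_quantile)
            mask &= nnz >= thresh
        if not mask.any():
            raise ValueError(f"{chrom}: all bins masked; cannot balance")

        work = raw.astype(float).copy()
        work[~mask, :] = 0.0
        work[:, ~mask] = 0.0
        bias = np.ones(n)
        cv = _marginal_cv(work, mask)
        it = 0
        while cv > tol and it < max_iter:
            s = work.sum(axis=1)
            mean_s = s[mask].mean()
            db = np.where(mask & (s > 0), s / mean_s, 1.0)
            work /= np.outer(db, db)
            bias *= db
            cv = _marginal_cv(work, mask)
            it += 1
        converged = cv <= tol
        if not converged:
            warnings.warn(
                f"{chrom}: balancing did not reach CV {tol:g} in {max_iter} "
                f"iterations (final CV {cv:.3g})",
                stacklevel=2,
            )
        # recompute from raw so balanced == raw / (b_i * b_j) holds exactly
        bal = raw / np.outer(bias, bias)
        bal[~mask, :] = np.nan
        bal[:, ~mask] = np.nan
        bias_out = np.where(mask, bias, np.nan)
        out_data[chrom] = bal
        biases[chrom] = bias_out
        masks[chrom] = mask
        convergence[chrom] = (it, cv, converged)

    bal_matrix = ContactMatrix(m.genome, out_data, sample=m.sample, condition=m.condition)
    return BalancedMatrix(bal_matrix, biases, masks, convergence)


# ---------------------------------------------------------------------------
# Expected profile and O/E


def expected_profile(b: BalancedMatrix) -> ExpectedProfile:
    """Mean balanced value at each bin distance, over unmasked pairs only."""
    values: dict[str, np.ndarray] = {}
    for chrom in b.genome.names:
        mat = b.matrix.data[chrom]
        mask = b.mask[chrom]
        n = mat.shape[0]
        prof = np.full(n, np.nan)
        for d in range(n):
            i = np.arange(0, n - d)
            j = i + d
            ok = mask[i] & mask[j]
            if ok.any():
                prof[d] = np.nanmean(mat[i[ok], j[ok]])
        values[chrom] = prof
    return ExpectedProfile(b.genome, values)


def oe_transform(b: BalancedMatrix, e: ExpectedProfile) -> ContactMatrix:
    """Observed/expected matrix: ``balanced[i, j] / expected[|i - j|]``.

    Masked bins and strata with zero or undefined expected value propagate as
    NaN.  Raises on genome/resolution mismatch between matrix and profile.
    """
    if e.genome != b.genome:
        raise ValueError("expected profile and matrix use different binned genomes")
    data: dict[str, np.ndarray] = {}
    for chrom in b.genome.names:
        mat = b.matrix.data[chrom]
        prof = e.values[chrom].copy()
        prof[prof == 0] = np.nan
        n = mat.shape[0]
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = mat / prof[d]
        data[chrom] = oe
    return ContactMatrix(b.genome, data, sample=b.matrix.sample, condition=b.matrix.condition)


def decay_exponent(e: ExpectedProfile, d_min: int = 1, d_max: int | None = None) -> float:
    """Power-law decay exponent: negated slope of log E(d) vs log d.

    Fitted by least squares over ``d_min <= d <= d_max`` pooling chromosomes.
    """
    xs, ys = [], []
    for chrom in e.genome.names:
        prof = e.values[chrom]
        hi = min(len(prof) - 1, d_max if d_max is not None else len(prof) - 1)
        d = np.arange(d_min, hi + 1)
        v = prof[d]
        ok = np.isfinite(v) & (v > 0)
        xs.append(np.log(d[ok] + 1.0))
        ys.append(np.log(v[ok]))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    slope, _ = np.polyfit(x, y, 1)
    return float(-slope)


# ---------------------------------------------------------------------------
# Replicate correlation


def replicate_correlation(
    m1: ContactMatrix,
    m2: ContactMatrix,
    max_distance: int | None = None,
) -> float:
    """Pearson correlation of log1p contact values between two samples.

    Computed on the union of nonzero upper-triangle pixels, restricted to bin
    distance ``<= max_distance`` bp when given.  Raises if fewer than three
    shared pixels remain.
    """
    if m1.genome != m2.genome:
        raise ValueError("matrices use different binned genomes")
    max_bins = None
    if max_distance is not None:
        max_bins = max_distance // m1.genome.resolution
    xs, ys = [], []
    for chrom in m1.genome.names:
        a, b = m1.data[chrom], m2.data[chrom]
        iu, ju = np.triu_indices_from(a)
        if max_bins is not None:
            keep = (ju - iu) <= max_bins
            iu, ju = iu[keep], ju[keep]
        va, vb = a[iu, ju], b[iu, ju]
        ok = np.isfinite(va) & np.isfinite(vb) & ((va != 0) | (vb != 0))
        xs.append(va[ok])
        ys.append(vb[ok])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 3:
        raise ValueError(f"only {x.size} shared pixels; need at least 3")
    r, _ = sps.pearsonr(np.log1p(x), np.log1p(y))
    return float(r)
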