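"""Binned genome coordinate system shared by every pipeline stage.

Hi-C analysis works on a genome partitioned into fixed-width bins.  Bins are
0-based, half-open, and bin ``i`` covers ``[i * resolution, (i+1) * resolution)``
(the last bin of a chromosome may be shorter).  All intra-chromosomal matrices,
tracks, and interval sets in this package are indexed against a
:class:`BinnedGenome`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class BinnedGenome:
    """An ordered set of chromosomes cut into fixed-width bins.

    Parameters
    ----------
    names
        Chromosome names, in display order.
    lengths
        Chromosome lengths in bp, parallel to ``names``.
    resolution
        Bin width in bp (> 0).
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    resolution: int
    _index: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(self.names, self.lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lengths", tuple(int(x) for x in self.lengths))
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    # -- lookups ----------------------------------------------------------

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def length(self, chrom: str) -> int:
        """Chromosome length in bp."""
        return self.lengths[self._index[chrom]]

    def n_bins(self, chrom: str) -> int:
        """Number of bins on ``chrom`` (= ceil(length / resolution))."""
        return math.ceil(self.length(chrom) / self.resolution)

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.names)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Bin containing bp position ``pos`` (0-based)."""
        if pos < 0 or pos >= self.length(chrom):
            raise ValueError(f"position {pos} outside {chrom} (length {self.length(chrom)})")
        return pos // self.resolution

    def bin_start(self, chrom: str, i: int) -> int:
        """Start bp of bin ``i``."""
        if i < 0 or i >= self.n_bins(chrom):
            raise ValueError(f"bin {i} outside {chrom} ({self.n_bins(chrom)} bins)")
        return i * self.resolution

    def bin_end(self, chrom: str, i: int) -> int:
        """End bp of bin ``i`` (clipped to the chromosome end)."""
        return min((i + 1) * self.resolution, self.length(chrom))

    def with_resolution(self, resolution: int) -> "BinnedGenome":
        """Same chromosomes re-binned at ``resolution``."""
        return BinnedGenome(self.names, self.lengths, resolution)

    # -- I/O --------------------------------------------------------------

    @classmethod
    def from_chromsizes(cls, path, resolution: int) -> "BinnedGenome":
        """Read a two-column ``chrom<TAB>length`` file."""
        names: list[str] = []
        lengths: list[int] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'chrom length', got {line!r}")
                names.append(parts[0])
                try:
                    lengths.append(int(parts[1]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from exc
        return cls(tuple(names), tuple(lengths), resolution)

    def write_chromsizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.names, self.lengths):
                fh.write(f"{name}\t{length}\n")
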