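"""Ground-truth generator for paired-condition Hi-C maps.

The generative model is a minimal multiplicative block model that exhibits
every structure the pipeline measures.  The Poisson mean of pixel (i, j) on a
chromosome is

    mu_ij = depth * (|i-j| + 1)^(-alpha)            power-law distance decay
            * (1 + c * s_i * s_j)                   compartment checkerboard
            * t^[i, j in the same domain]           TAD interior fold
            * lambda^[pixel is a loop]              focal loops
            * f^[pixel differential, condition 2]   programmed contact change

and condition 2 additionally applies compartment-block flips, domain-boundary
shifts, loop gains/losses, and a global depth ratio r.  Counts are drawn
independently Poisson(mu) on the upper triangle and mirrored, so matrices are
symmetric by construction.  A matched gene annotation is placed with
class-dependent density (compartment A and TAD boundaries gene-richer), and a
DEG table is generated whose programmed DEGs pass the standard thresholds
(FDR <= 0.05, fold >= 2) and sit preferentially in changed-architecture
regions.

Structure layout (blocks, domains, loops, alterations) lives in the config,
not in the random stream: different seeds give different counts but identical
truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .export import write_bed, write_bedpe
from .genes import DEGTable, GeneTable
from .genome import BinnedGenome
from .matrix import ContactMatrix

__all__ = ["SimulationConfig", "TruthRecord", "default_config", "simulate_pair", "write_truth"]

import pandas as pd


@dataclass
class SimulationConfig:
    """Everything that defines a paired-condition simulation.

    Coordinates are in bins.  ``domains`` / ``domains2`` are per-chromosome
    half-open intervals (condition 2 defaults to condition 1 plus the
    programmed boundary shifts already applied).  All folds are > 0.
    """

    seed: int = 0
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 400), ("chr2", 400)]
    )
    resolution: int = 10_000
    alpha: float = 1.0          # distance-decay exponent
    depth: float = 2000.0       # Poisson mean at distance 0; ~1000 at distance 1
    # compartments: alternating +/- blocks of this many bins, contrast c
    compartment_block: int = 100
    compartment_contrast: float = 0.15
    # domains: intervals per chromosome, interior fold t
    domains: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    domain_fold: float = 2.0
    # loops: (chrom, i, j) pixels, fold lambda
    loops: list[tuple[str, int, int]] = field(default_factory=list)
    loop_fold: float = 4.0
    # condition-2 alterations
    flipped_blocks: dict[str, list[int]] = field(default_factory=dict)  # block indices
    domains2: dict[str, list[tuple[int, int]]] | None = None
    gained_loops: list[tuple[str, int, int]] = field(default_factory=list)
    lost_loops: list[tuple[str, int, int]] = field(default_factory=list)
    differential_pixels: list[tuple[str, int, int]] = field(default_factory=list)
    differential_fold: float = 3.0
    depth_ratio: float = 1.5
    # genes / DEGs
    genes_per_bin: float = 2.5
    gene_density_A: float = 2.0       # relative to B
    gene_density_boundary: float = 2.0  # relative to interior
    gene_density_nontad: float = 1.5
    n_degs: int = 200
    deg_changed_fold: float = 3.0     # placement enrichment in changed bins
    deg_log2fc_mean: float = 2.0
    deg_log2fc_sd: float = 0.25

    def genome(self) -> BinnedGenome:
        names = tuple(c for c, _ in self.chromosomes)
        lengths = tuple(n * self.resolution for _, n in self.chromosomes)
        return BinnedGenome(names, lengths, self.resolution)

    def validate(self) -> None:
        for fold, name in (
            (self.domain_fold, "domain_fold"),
            (self.loop_fold, "loop_fold"),
            (self.differential_fold, "differential_fold"),
            (self.depth_ratio, "depth_ratio"),
        ):
            if fold <= 0:
                raise ValueError(f"{name} must be > 0")
        g = self.genome()
        for chrom, doms in self.effective_domains(2).items():
            for s, e in doms:
                if not (0 <= s < e <= g.n_bins(chrom)):
                    raise ValueError(f"domain {chrom}:{s}-{e} outside chromosome")
        for chrom, blocks in self.flipped_blocks.items():
            n_blocks = -(-g.n_bins(chrom) // self.compartment_block)
            for b in blocks:
                if not (0 <= b < n_blocks):
                    raise ValueError(f"flip of nonexistent block {b} on {chrom}")
        for chrom, i, j in self.loops + self.gained_loops + self.differential_pixels:
            if chrom not in g or not (0 <= i < j < g.n_bins(chrom)):
                raise ValueError(f"pixel {chrom}:{i},{j} outside chromosome")
        for pix in self.lost_loops:
            if pix not in self.loops:
                raise ValueError(f"lost loop {pix} is not a condition-1 loop")

    # -- derived structure ------------------------------------------------

    def compartment_signs(self, chrom: str, condition: int) -> np.ndarray:
        g = self.genome()
        n = g.n_bins(chrom)
        blocks = np.arange(n) // self.compartment_block
        signs = np.where(blocks % 2 == 0, 1, -1)
        if condition == 2:
            for b in self.flipped_blocks.get(chrom, []):
                signs[blocks == b] *= -1
        return signs

    def effective_domains(self, condition: int) -> dict[str, list[tuple[int, int]]]:
        if condition == 2 and self.domains2 is not None:
            return self.domains2
        return self.domains

    def effective_loops(self, condition: int) -> list[tuple[str, int, int]]:
        if condition == 1:
            return list(self.loops)
        kept = [p for p in self.loops if p not in self.lost_loops]
        return kept + list(self.gained_loops)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromosomes"] = [list(x) for x in d["chromosomes"]]
        for key in ("loops", "gained_loops", "lost_loops", "differential_pixels"):
            d[key] = [list(x) for x in d[key]]
        d["domains"] = {c: [list(x) for x in v] for c, v in d["domains"].items()}
        if d["domains2"] is not None:
            d["domains2"] = {c: [list(x) for x in v] for c, v in d["domains2"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["chromosomes"] = [tuple(x) for x in d["chromosomes"]]
        for key in ("loops", "gained_loops", "lost_loops", "differential_pixels"):
            d[key] = [tuple(x) for x in d.get(key, [])]
        d["domains"] = {c: [tuple(x) for x in v] for c, v in d.get("domains", {}).items()}
        if d.get("domains2") is not None:
            d["domains2"] = {c: [tuple(x) for x in v] for c, v in d["domains2"].items()}
        return cls(**d)

    def to_toml(self) -> str:
        return _emit_toml(self.to_dict())

    @classmethod
    def from_toml(cls, text: str) -> "SimulationConfig":
        import tomllib

        return cls.from_dict(_undo_toml(tomllib.loads(text)))


def _emit_toml(d: dict, prefix: str = "") -> str:
    """Minimal TOML emitter for the config schema (scalars, lists, str-keyed dicts)."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, str):
            return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
        if isinstance(v, (list, tuple)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise TypeError(f"cannot emit {type(v)} as TOML value")

    scalars, tables = [], []
    for key, val in d.items():
        if val is None:
            continue
        if isinstance(val, dict):
            tables.append((key, val))
        else:
            scalars.append(f"{key} = {fmt(val)}")
    out = ("\n".join(scalars) + "\n") if scalars else ""
    for key, val in tables:
        out += f"\n[{prefix}{key}]\n"
        for k2, v2 in val.items():
            out += f'"{k2}" = {fmt(v2)}\n'
    return out


def _undo_toml(d: dict) -> dict:
    if "domains2" not in d:
        d["domains2"] = None
    return d


@dataclass
class TruthRecord:
    """Ground truth of a simulated pair, derived deterministically from the config."""

    genome: BinnedGenome
    compartment_labels: dict[int, dict[str, np.ndarray]]  # condition -> chrom -> +/-1
    domains: dict[int, dict[str, list[tuple[int, int]]]]
    loops: dict[int, list[tuple[str, int, int]]]
    changed_compartment_bins: dict[str, np.ndarray]  # boolean per bin
    changed_domains: list[tuple[str, int, int]]
    differential_pixels: list[tuple[str, int, int]]
    deg_ids: list[str] = field(default_factory=list)
    deg_placement: dict[str, str] = field(default_factory=dict)  # gene -> 'changed'/'common'

    def changed_bins_any(self, chrom: str) -> np.ndarray:
        """Bins in changed compartments or changed domains (the 'altered' class)."""
        out = self.changed_compartment_bins[chrom].copy()
        for c, s, e in self.changed_domains:
            if c == chrom:
                out[s:e] = True
        return out


def default_config(seed: int = 0) -> SimulationConfig:
    """The study conditions used throughout the test-suite and examples.

    Two 4 Mb chromosomes at 10 kb (400 bins each); compartment checkerboard
    of 25-bin blocks at contrast 0.15; three runs of four adjacent domains
    (12 per chromosome) with interior fold 2 in the first half of each
    chromosome; ten loops per chromosome (fold 4) in the domain-free second
    half; condition 2 flips two compartment blocks per chromosome, shifts
    three domain boundaries on chr1 by 3 bins, gains five loops, loses two,
    scales thirty pixels threefold, and is sequenced 1.5x deeper.
    """
    domains_chr = (
        # three runs of four adjacent domains in the first chromosome half;
        # boundaries coincide with compartment block edges or keep >= 7 bins
        # clear of them, as TAD boundaries and compartment transitions
        # co-occur rather than sit a few bins apart
        [(50, 60), (60, 68), (68, 75), (75, 85)]
        + [(100, 110), (110, 117), (117, 125), (125, 135)]
        + [(150, 160), (160, 168), (168, 175), (175, 185)]
    )
    loops_chr1 = [
        (210, 240), (220, 260), (232, 300), (245, 285), (255, 330),
        (262, 310), (275, 345), (290, 352), (305, 365), (318, 382),
    ]
    loops_chr2 = [
        (212, 248), (224, 266), (236, 288), (248, 302), (258, 322),
        (268, 336), (282, 348), (296, 358), (308, 370), (322, 378),
    ]
    # condition-2 domain layout: three boundaries shifted by 3 bins on chr1
    domains2_chr1 = (
        [(50, 63), (63, 68), (68, 75), (75, 85)]
        + [(100, 110), (110, 114), (114, 125), (125, 135)]
        + [(150, 160), (160, 165), (165, 175), (175, 185)]
    )
    diff_pixels = [("chr1", 200 + 4 * k, 200 + 4 * k + 5 + (k % 7)) for k in range(15)] + [
        ("chr2", 200 + 4 * k, 200 + 4 * k + 8 + (k % 9)) for k in range(15)
    ]
    return SimulationConfig(
        seed=seed,
        domains={"chr1": domains_chr, "chr2": list(domains_chr)},
        domains2={"chr1": domains2_chr1, "chr2": list(domains_chr)},
        loops=[("chr1", i, j) for i, j in loops_chr1]
        + [("chr2", i, j) for i, j in loops_chr2],
        flipped_blocks={"chr1": [2], "chr2": [1]},
        gained_loops=[("chr1", 215, 275), ("chr1", 300, 340), ("chr2", 230, 275),
                      ("chr2", 260, 340), ("chr2", 310, 350)],
        lost_loops=[("chr1", 220, 260), ("chr2", 224, 266)],
        differential_pixels=diff_pixels,
    )


def null_config(seed: int = 0, depth_ratio: float = 1.5) -> SimulationConfig:
    """Paired conditions with identical structure, differing only in depth.

    The null for differential-contact testing: same compartments, domains,
    and loops in both conditions; condition 2 sequenced ``depth_ratio``
    deeper; no programmed alteration of any kind.
    """
    cfg = default_config(seed=seed)
    cfg.flipped_blocks = {}
    cfg.domains2 = None
    cfg.gained_loops = []
    cfg.lost_loops = []
    cfg.differential_pixels = []
    cfg.depth_ratio = depth_ratio
    return cfg


def power_config(seed: int = 0) -> SimulationConfig:
    """Null structure plus the thirty 3-fold differential pixels only."""
    cfg = null_config(seed=seed)
    cfg.differential_pixels = default_config().differential_pixels
    return cfg


def decay_only_config(seed: int = 0) -> SimulationConfig:
    """Pure power-law decay: no compartments, domains, loops, or alterations."""
    cfg = null_config(seed=seed, depth_ratio=1.0)
    cfg.compartment_contrast = 0.0
    cfg.domains = {}
    cfg.domain_fold = 1.0
    cfg.loops = []
    cfg.loop_fold = 1.0
    return cfg


# ---------------------------------------------------------------------------
# Mean model and sampling


def _domain_id_map(n: int, domains: list[tuple[int, int]]) -> np.ndarray:
    ids = np.full(n, -1, dtype=int)
    for k, (s, e) in enumerate(domains):
        ids[s:e] = k
    return ids


def mean_matrix(cfg: SimulationConfig, chrom: str, condition: int) -> np.ndarray:
    """Closed-form Poisson mean matrix for one chromosome and condition."""
    g = cfg.genome()
    n = g.n_bins(chrom)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    mu = cfg.depth * (d + 1.0) ** (-cfg.alpha)
    s = cfg.compartment_signs(chrom, condition)
    mu *= 1.0 + cfg.compartment_contrast * np.outer(s, s)
    ids = _domain_id_map(n, cfg.effective_domains(condition).get(chrom, []))
    same = (ids[:, None] == ids[None, :]) & (ids[:, None] >= 0)
    mu[same] *= cfg.domain_fold
    for c, i, j in cfg.effective_loops(condition):
        if c == chrom:
            mu[i, j] *= cfg.loop_fold
            mu[j, i] *= cfg.loop_fold
    if condition == 2:
        for c, i, j in cfg.differential_pixels:
            if c == chrom:
                mu[i, j] *= cfg.differential_fold
                mu[j, i] *= cfg.differential_fold
        mu *= cfg.depth_ratio
    return mu


def _sample_matrix(cfg: SimulationConfig, condition: int, rng: np.random.Generator) -> ContactMatrix:
    g = cfg.genome()
    data = {}
    for chrom in g.names:
        mu = mean_matrix(cfg, chrom, condition)
        n = mu.shape[0]
        iu, ju = np.triu_indices(n)
        counts = rng.poisson(mu[iu, ju]).astype(float)
        mat = np.zeros((n, n))
        mat[iu, ju] = counts
        mat[ju, iu] = counts
        data[chrom] = mat
    return ContactMatrix(g, data, sample=f"sim-cond{condition}", condition=f"cond{condition}")


def make_truth(cfg: SimulationConfig) -> TruthRecord:
    """Ground truth derived from the config alone (identical for every seed)."""
    g = cfg.genome()
    comp = {cond: {c: cfg.compartment_signs(c, cond) for c in g.names} for cond in (1, 2)}
    changed_comp = {
        c: comp[1][c] != comp[2][c] for c in g.names
    }
    doms = {cond: {c: list(cfg.effective_domains(cond).get(c, [])) for c in g.names} for cond in (1, 2)}
    changed_domains = []
    for c in g.names:
        set1, set2 = set(doms[1][c]), set(doms[2][c])
        for s, e in sorted(set1 ^ set2):
            changed_domains.append((c, s, e))
    loops = {cond: cfg.effective_loops(cond) for cond in (1, 2)}
    return TruthRecord(
        genome=g,
        compartment_labels=comp,
        domains=doms,
        loops=loops,
        changed_compartment_bins=changed_comp,
        changed_domains=changed_domains,
        differential_pixels=list(cfg.differential_pixels),
    )


def _place_genes(cfg: SimulationConfig, truth: TruthRecord, rng: np.random.Generator) -> GeneTable:
    g = truth.genome
    rows = []
    gene_no = 0
    for chrom in g.names:
        n = g.n_bins(chrom)
        s = cfg.compartment_signs(chrom, 1)
        comp_factor = np.where(s > 0, cfg.gene_density_A, 1.0)
        ids = _domain_id_map(n, cfg.effective_domains(1).get(chrom, []))
        tad_factor = np.full(n, cfg.gene_density_nontad)
        for s_, e_ in cfg.effective_domains(1).get(chrom, []):
            tad_factor[s_:e_] = 1.0
            tad_factor[s_] = cfg.gene_density_boundary
            tad_factor[e_ - 1] = cfg.gene_density_boundary
        weight = comp_factor * tad_factor
        lam = cfg.genes_per_bin * weight / weight.mean()
        counts = rng.poisson(lam)
        for b in range(n):
            for _ in range(counts[b]):
                start = b * cfg.resolution + int(rng.integers(0, cfg.resolution - 3000))
                length = int(rng.integers(1000, 3000))
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append(
                    {
                        "gene_id": f"g{gene_no:05d}",
                        "chrom": chrom,
                        "start": start,
                        "end": start + length,
                        "strand": strand,
                    }
                )
                gene_no += 1
    return GeneTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def _make_degs(
    cfg: SimulationConfig,
    truth: TruthRecord,
    genes: GeneTable,
    rng: np.random.Generator,
) -> DEGTable:
    g = truth.genome
    tb = genes.tss_bins(g)
    changed = {c: truth.changed_bins_any(c) for c in g.names}
    in_changed = np.array(
        [changed[c][b] for c, b in zip(tb["chrom"], tb["bin"])], dtype=bool
    )
    weights = np.where(in_changed, cfg.deg_changed_fold, 1.0).astype(float)
    n_deg = min(cfg.n_degs, len(tb))
    idx = rng.choice(len(tb), size=n_deg, replace=False, p=weights / weights.sum())
    is_deg = np.zeros(len(tb), dtype=bool)
    is_deg[idx] = True

    log2fc = rng.normal(0.0, 0.3, size=len(tb)).clip(-0.9, 0.9)
    fdr = rng.uniform(0.051, 1.0, size=len(tb))
    mag = np.maximum(rng.normal(cfg.deg_log2fc_mean, cfg.deg_log2fc_sd, size=n_deg), 1.0)
    sign = np.where(rng.random(n_deg) < 0.5, 1.0, -1.0)
    log2fc[idx] = sign * mag
    fdr[idx] = rng.uniform(1e-6, 0.05, size=n_deg)

    truth.deg_ids = list(tb.loc[is_deg, "gene_id"])
    truth.deg_placement = {
        gid: ("changed" if ch else "common")
        for gid, ch in zip(tb["gene_id"], in_changed)
        if gid in set(truth.deg_ids)
    }
    df = pd.DataFrame({"gene_id": tb["gene_id"], "log2fc": log2fc, "fdr": fdr})
    return DEGTable(df)


def simulate_pair(cfg: SimulationConfig):
    """Draw a full paired-condition data set.

    Returns ``(matrix1, matrix2, genes, degs, truth)``.  All randomness
    derives from ``cfg.seed``; truth structure is config-determined.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m1 = _sample_matrix(cfg, 1, rng)
    m2 = _sample_matrix(cfg, 2, rng)
    truth = make_truth(cfg)
    genes = _place_genes(cfg, truth, rng)
    degs = _make_degs(cfg, truth, genes, rng)
    return m1, m2, genes, degs, truth


def write_truth(truth: TruthRecord, outdir) -> None:
    """Write the ground truth in the same dialects the pipeline emits.

    Compartments, domains, and changed regions as BED; loops and differential
    pixels as BEDPE; DEG ids as a one-per-line list.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    g = truth.genome
    res = g.resolution
    for cond in (1, 2):
        recs = []
        for chrom in g.names:
            signs = truth.compartment_labels[cond][chrom]
            for i, s in enumerate(signs):
                recs.append((chrom, i * res, g.bin_end(chrom, i), "A" if s > 0 else "B"))
        write_bed(os.path.join(outdir, f"compartments_cond{cond}.bed"), recs)
        recs = [
            (chrom, s * res, e * res, f"domain{k}")
            for chrom in g.names
            for k, (s, e) in enumerate(truth.domains[cond][chrom])
        ]
        write_bed(os.path.join(outdir, f"domains_cond{cond}.bed"), recs)
        recs = [
            (c, i * res, (i + 1) * res, c, j * res, (j + 1) * res, f"loop{k}", 0)
            for k, (c, i, j) in enumerate(truth.loops[cond])
        ]
        write_bedpe(os.path.join(outdir, f"loops_cond{cond}.bedpe"), recs)

    recs = []
    for chrom in g.names:
        ch = truth.changed_compartment_bins[chrom]
        i = 0
        n = len(ch)
        while i < n:
            if ch[i]:
                j = i
                while j < n and ch[j]:
                    j += 1
                recs.append((chrom, i * res, j * res, "changed-compartment"))
                i = j
            else:
                i += 1
    write_bed(os.path.join(outdir, "changed_compartments.bed"), recs)
    write_bed(
        os.path.join(outdir, "changed_domains.bed"),
        [(c, s * res, e * res, "changed-domain") for c, s, e in truth.changed_domains],
    )
    write_bedpe(
        os.path.join(outdir, "differential_pixels.bedpe"),
        [
            (c, i * res, (i + 1) * res, c, j * res, (j + 1) * res, f"diff{k}", 0)
            for k, (c, i, j) in enumerate(truth.differential_pixels)
        ],
    )
    with open(os.path.join(outdir, "deg_ids.txt"), "w") as fh:
        for gid in truth.deg_ids:
            fh.write(gid + "\n")
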