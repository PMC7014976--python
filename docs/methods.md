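# Methods

`hicarch` implements a comparative Hi-C chromatin-architecture analysis:
matrix normalisation, A/B compartment calling, TAD-like domain calling,
focal loop detection with aggregate peak analysis (APA), differential-contact
testing between two conditions, and hypergeometric enrichment of gene sets
and differential contacts in changed architecture regions.  A paired-condition
synthetic generator with exact ground truth drives all validation.

## Contact matrices and balancing

Input matrices are per-chromosome symmetric binned raw counts (cis only;
bins 0-based, half-open).  Balancing uses iterative correction (ICE): per-bin
multiplicative biases are iterated until the coefficient of variation (CV) of
the unmasked marginal sums falls below `tol` (default 1e-6, max 200
iterations), with `balanced[i,j] = raw[i,j] / (bias_i * bias_j)` holding
exactly at return.  Bins with no nonzero entries, and bins in the lowest 2%
of nonzero-entry counts (configurable), are masked first.  The equal-marginal
contract is the tested property; KR balancing would satisfy the same
contract.

The expected profile E(d) is the mean balanced value over unmasked pairs at
each bin distance d (absent entries count as zero), and O/E = balanced/E(d).
Replicate correlation is the Pearson correlation of log(1+x) values on the
union of nonzero pixels, optionally restricted by distance; the log transform
makes it near-invariant to sequencing depth.

## Compartments

Per chromosome, the Pearson correlation matrix of O/E columns over unmasked
bins is computed and its first principal component (SVD of the
column-centred correlation matrix) assigns each bin a real value; the sign
partitions bins into two compartments.  The sign is oriented so that
positive (A) bins carry the higher mean gene density, reflecting the
gene-rich/active character of A compartments; the orientation evidence is
retained.  Comparing two oriented tracks classifies each bin as common-A,
common-B, A->B, or B->A; a changed region is a maximal run of
sign-discordant bins (minimum run length 1 by default).

Degenerate chromosomes (too few unmasked bins, or constant O/E) are marked
NA with a warning rather than failing the run.

## Domains

The default caller is insulation-based.  The raw statistic at bin i is the
mean balanced value in the square of pixels joining the `window` bins to the
left and right of i (default window 50 kb = 5 bins at 10 kb).  The score is
the log2 ratio of this statistic to its own 41-bin running mean.  The running
mean (rather than a chromosome-wide constant) removes the smooth positional
trend that ICE leaves on truncated decay matrices -- end bins receive
systematically smaller biases, which would otherwise bow the track by ~0.1
log2 units; the normaliser window (41 bins) is several times the dip width
(~2 x window) so genuine boundary minima are preserved.  Boundaries are
local minima with prominence >= 0.25 log2 units, a level above insulation
dips produced by compartment transitions at the default contrast
(|log2((1-c)/(1+c))| ~ 0.44 arises only when stacked with domain dips) yet
below the ~1 log2 dip of a twofold-enriched domain boundary.  Domains are
inter-boundary intervals of 2..50 bins whose mean interior O/E is at least
1.10 -- above the O/E plateau of a compartment block interior (~1.05) and
below the weakest genuine domain interiors observed at interior fold 2
(~1.15 after balancing attenuation).

The arrowhead caller uses the directional transform
`A(i,d) = (M(i,i-d) - M(i,i+d)) / (M(i,i-d) + M(i,i+d))` on the balanced
matrix (decay cancels at equal distance).  For a candidate interval the
corner score contrasts the mean of A over the right wing (left arm inside,
right arm beyond the end: positive for a true domain) against the left wing
(mirror: negative); candidates scoring >= 0.45 are selected greedily without
overlap.  For interior fold t the wings approach +-(t-1)/(t+1), so 0.45 sits
between the checkerboard-only signal (~0.3 at contrast 0.15) and the t=2
domain signal (~0.67).  Both callers emit a flat segmentation; nesting is out
of scope.

Domain comparison matches domains one-to-one greedily by reciprocal overlap
(threshold 0.8); unmatched domains are "changed".  Per-bin classes use a
boundary width of 1 bin inside each domain edge; where domains from the two
sets overlap, changed beats common and boundary beats interior.  Domain
statistics report count, median length, and union coverage.

## Loops

The caller tests every nonzero upper-triangle pixel with separation
2..100 bins.  The local background is the larger of two kernel means over
the O/E matrix: the donut -- a (2w+1)^2 square (w = 5) minus the rows and
columns within the peak width (p = 1) of the centre, which share the
anchors' biases -- and the lower-left corner block between the pixel and
the diagonal, which is the background that rejects contact-domain corners
(at a domain corner the donut is dominated by out-of-domain pixels and
underestimates the local level, so corners would otherwise be called as
loops).  The observed raw count is tested against Poisson(local mean O/E x
E(d) x bias_i x bias_j); BH correction runs per distance stratum; retained
pixels need adjusted p <= 0.05 and fold >= 2 over the local background, and
adjacent significant pixels collapse to the most significant one.  The
horizontal and vertical kernels of the full four-kernel scheme are not
implemented.

APA averages (2k+1)x(2k+1) O/E submatrices (k = 5) centred on loop pixels,
dropping pixels too close to an edge or the diagonal; the score is the
centre value over the mean of the 3x3 lower-left corner (the corner nearest
the diagonal, the conservative background choice).

## Differential contacts

For two conditions the MD table holds, for every pixel nonzero in either
matrix (distance <= 100 bins, mirroring common distance filtering),
M = log2((v2+1)/(v1+1)) and D = bin distance.  A loess (tricube local
linear) fit of M on D, fitted on the per-distance mean M -- each distance
pools hundreds of pixels, so the distance-level means carry the full signal
at a fraction of the cost -- is subtracted to absorb depth and
distance-dependent bias.  Each pixel's adjusted M is then whitened by its
delta-method standard deviation for a log2 count ratio,
`sqrt(1/(v1+1) + 1/(v2+1)) / ln 2`: at a fixed distance pixel intensities
vary severalfold (compartments, domains, loops), and without whitening the
common stratum scale understates the noise of dim pixels, producing
scattered false calls.  The whitened residuals are standardised per distance
stratum by median and 1.4826 x MAD (strata under 100 pixels pool into
neighbours), converted to two-sided normal p-values, and BH-adjusted across
all pixels.  Retained pixels (adjusted p <= FDR, default 0.05) define the
differential contacts; their anchor bins, merged when book-ended, form the
1-D differential contact regions.

## Integration

DEGs are genes with FDR <= 0.05 and |log2FC| >= 1 (fold >= 2, two-sided).
Promoters default to 2 kb upstream + 200 bp downstream of the strand-aware
TSS, clipped to the chromosome.  Genes map to bins by TSS.  Enrichment of a
gene set in an architecture class is the upper-tail hypergeometric
probability (the `phyper` convention) with population N = universe genes on
classified bins, class K = genes on class bins, draw n = set members on
classified bins, overlap k = members on class bins; the tail is accumulated
in log space and matches exact rational enumeration to ~1e-14 relative.
Differential-contact enrichment uses distinct anchor bins as the unit (a
documented choice; merged regions or raw pixels are alternative units).
BH adjustment across the tested classes is reported alongside raw p.
Promoter density contrasts count promoters overlapping the merged
differential regions per Mb against the genomic complement.  Per-gene
interaction profiles are virtual-4C rows of the O/E matrix anchored at the
TSS bin.

## Synthetic data

The generator is a multiplicative block model, the minimal generative model
exhibiting every structure the pipeline measures:

    mu_ij = depth * (|i-j|+1)^(-alpha) * (1 + c s_i s_j)
            * t^[same domain] * lambda^[loop] * f^[differential, cond 2]

with independent Poisson counts on the upper triangle, mirrored.  Defaults
(the study conditions for all tests): two chromosomes of 400 bins at 10 kb
(8 Mb genome); alpha = 1; depth 2000 (about 1000 expected counts at distance
1, typical of a deeply sequenced pooled 10 kb map and high enough that
boundary and loop recovery are signal- rather than noise-limited);
checkerboard blocks of 100 bins (1 Mb) at contrast c = 0.15; per chromosome
three runs of four adjacent domains (12 domains, lengths 7-10 bins, median
90 kb) with interior fold t = 2, laid out so domain boundaries either
coincide with compartment block edges or keep clear of them -- as in real
genomes, where TAD boundaries and compartment transitions co-occur rather
than sit a few bins apart; ten loops per chromosome at fold lambda = 4 in
the domain-free second half.  Condition 2 flips one compartment block per
chromosome, shifts three domain boundaries on chr1 by 3 bins, gains five
loops, loses two, scales thirty pixels by f = 3, and is sequenced 1.5x
deeper.  Genes are placed Poisson per bin with relative densities A:B = 2:1
and boundary:interior = 2:1 (non-domain bins 1.5); 200 DEGs are drawn with
threefold placement weight in changed bins, |log2FC| ~ N(2, 0.25^2) clipped
at 1, FDR ~ U(1e-6, 0.05); non-DEGs receive FDR > 0.05 so the filter
recovers exactly the programmed set (no count model is fitted -- the DEG
table is an input contract).

Structure layout lives in the config, not the random stream: different
seeds redraw counts and gene positions but never the truth.  `null_config`
(identical structure, depth ratio 1.5) and `power_config` (null plus the
thirty 3-fold pixels) define the calibration and power scenarios;
`decay_only_config` is the no-structure null.

What the generator does not emulate: restriction-fragment and mappability
bias (biases are flat, so balancing is exercised only through its contract),
trans contacts, TAD nesting and stripes, polymer-physics correlations
between neighbouring pixels, and count overdispersion beyond Poisson.
Passing tests therefore demonstrate correctness of the algorithms under the
stated generative model, not performance on real libraries, where extra
dispersion and bias structure would lower power and calibration margins.

## Numerical choices and degenerate inputs

Balancing recomputes the balanced matrix from the raw counts and final
biases, so conservation (raw = balanced x bias products) holds to machine
precision.  Welch's t-test defines the two-constant-group case 0/0 as t = 0,
p = 1 (and p = 0 when the means differ with zero variance).  Hypergeometric
tails at or below the support minimum are exactly 1.  Zero-expected distance
strata propagate as unavailable (NaN).  Empty domain sets report NaN median
length and zero coverage; profile and APA operations raise on empty usable
input rather than returning silent zeros.  All tie-breaks (greedy matching
of domains and loops) order by score/distance and then coordinate, making
runs deterministic; the full pipeline is byte-reproducible from config +
seed.

## Problem sizes

All shipped tests and the acceptance script run the default 2 x 400-bin
genome; multi-seed checks use 20 replicates (compartment flips,
differential-contact null) and 100 draws (enrichment calibration), sizes at
which every recovery statistic is stable to within a few percent across
seeds.
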