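# Methods

This note documents the models, parameter choices and known limitations
of the package, in the order data flows through it.

## The synthetic world

All cross-species statistics are exercised on a generated world rather
than deposited data. The generator (`archcompare.world.make_world`) draws
an ancestral genome (by default 2–5 chromosomes whose lengths are
multiples of 500 kb), a rooted random ultrametric phylogeny with leaf
depth 300 million years, and per-species chromosome rescaling factors in
[0.75, 1.3], so species differ in chromosome-length distributions while
sharing a coordinate ancestry. Structure elements evolve along the tree:
an element flips (compartment block sign), relocates (trans hub,
TAD-block gene translocation) or is lost/gained (TAD boundary) on a
branch with probability `(1 − conserved_fraction) · branch_length /
tree_depth`, capped at 0.5. `conserved_fraction = 1` is the exact
no-divergence limit; the default 0.8 gives a clear but incomplete
conservation gradient.

Planted truth, per species:

- **Decay exponent α** in [−0.45, −0.23], assigned by genome-size rank —
  species with longer chromosomes decay more steeply — plus a small
  jitter. This plants the cross-species association between genome size
  and long-range contact loss that several directional tests check.
- **Compartments**: alternating-sign blocks of 0.3–2.5 Mb on a 100-kb
  grid. Bounded block sizes keep the checkerboard balanced on every
  chromosome; heavy-tailed block sizes occasionally produce
  single-compartment chromosomes on which PC1 has nothing to find.
- **TADs**: domains of 0.4–1.2 Mb separated by 40-kb boundary gaps on a
  20-kb grid.
- **Trans hubs**: three 500-kb loci per chromosome with 12× trans-contact
  weight. The count is fixed per chromosome rather than proportional to
  length; a fixed set of strongly trans-interacting loci is what makes
  average degree and clustering of the significance network fall as
  genome size grows under a fixed sequencing budget.
- **Genes**: single-copy orthologs (default 2 per Mb; cross-species
  conservation analyses use 3 per Mb, the density of real vertebrate
  single-copy sets — several thousand genes over a few Gb). Genes are
  grouped into ancestral-TAD blocks that translocate as units, so
  rearrangement breakpoints respect domain integrity and within-domain
  adjacencies outlive cross-domain ones.

Hi-C counts are Poisson draws around a multiplicative expectation:
`(s/res)^α × (1 + 0.4·sign_i·sign_j) × 3 (same TAD)` for cis, with each
diagonal of the modulation renormalized to mean 1 so the expected P(s)
is exactly the planted power law (otherwise the decaying checkerboard
correlation steepens the apparent slope by ~0.05–0.1); and
`exp(−|len_A − len_B| / 20 Mb) × w_i w_j` for trans, where w carries the
hub weights. 70% of the depth is cis. Simulated depth in tests and the
pipeline is 84,000 contacts per Mb of genome, the per-Mb coverage of a
~230 M-contact library on a ~2.7 Gb genome; at 20-kb resolution this
gives the ~10³ contacts per bin that deep published maps report, which
is what boundary-level analyses need.

Auxiliary tracks tie to the same truth: CTCF clusters at boundary
midpoints (1 + Poisson(1) motifs per side at |N(8 kb, 6 kb)| offsets,
'−' upstream / '+' downstream, scores 0.8–1.0 over a uniform-score
background of 10 motifs per Mb); SINE coverage tracks compartment sign
with effect size 0.5 and LINE anti-tracks it; CNEs are Poisson-placed at
1.2 per 20-kb bin in TAD interiors vs 0.3 in boundary ±1 bins; enhancers
prefer A-compartment bins 4:1; expression loads genes of one TAD on a
shared latent factor with correlation 0.8 over 3 replicates.

What the generator does **not** emulate: sequence (no FASTA, no
restriction fragments, no mappability or GC bias), inversions or
fissions/fusions (translocation only), copy-number variation, replicate
batch structure, and distance-dependent noise beyond Poisson. Passing
tests therefore demonstrate correctness of the statistics and their
expected directions under planted structure, not robustness to the bias
structure of real libraries.

## Normalization and reproducibility

Iterative correction equalizes marginals to a relative tolerance of
1e-4 in ≤200 iterations, masking zero-coverage bins and the bottom 2% of
nonzero marginals (standard ICE practice; masked bins never re-enter any
statistic). `scope="cis"` balances on intra-chromosomal marginals only
and is used before cis scores (DI, insulation): trans hubs otherwise
leak into the weights and distort local cis ratios. Quantile
normalization operates per genomic-distance stratum (all trans pairs
form one stratum), rank-matching nonzero values to the cross-sample mean
quantile function, which preserves each sample's decay shape. SCC
smooths both maps with a uniform filter (window 2h+1, default h=1),
correlates per distance stratum to 5 Mb, and combines strata with
size-and-variance weights; the aggregate is the median over chromosomes.

P(s) is normalized per chromosome (strata sum to 1) and averaged
unweighted across chromosomes; the slope is least squares of log10 P on
log10 s. The default long-range fit window is 1–10 Mb; analyses on toy
genomes whose chromosomes are shorter than the upper end must shrink the
window (the pipeline default is 0.5–5 Mb), because chromosomes dropping
out of the top strata distort the average's composition.

## Trans significance and networks

Fragment counts per 500-kb bin are proxied by 10-kb sub-bin counts; only
the ratio structure of m_norm matters. The binomial tail is exact
(`scipy.stats.binom.sf`), matching a log-space summation oracle to
1e-12. BH families are per chromosome pair; the q-normalization factor
is len(chrA)·len(chrB) over the product of the two longest chromosome
lengths, and the BIN edge threshold is q_norm < 1e-6 (configurable).
The randomization reproduces the published recipe exactly: nodes
uniform in the unit cube, the |E| closest pairs as edges, then 10·|E|
random edge switches accepted only when transitivity increases. Degrees
are conserved by a switch, so the triad denominator is constant and
acceptance reduces to the triangle-count delta, computed incrementally
from adjacency sets. A caveat verified numerically: on small graphs the
cube's boundary layer inflates the degree variance of the closest-pairs
stage (mean network variance ≈ 1.35 at 200 nodes / 600 edges, falling
toward 1 as n grows; ≈ 0.98 under periodic distance), so "close to 1"
only holds at the scale of real bin networks with thousands of nodes.

## Compartments and conserved states

PC1 is taken from the eigendecomposition of the Pearson correlation of
the per-chromosome observed/expected matrix and oriented so it
correlates positively (Spearman) with gene density; the first three PCs
are kept for diagnostics. The AB index of a fine bin is
(meanA − meanB)/(meanA + meanB) over its cis contacts with A/B-labeled
100-kb bins. Insulation is the log2 ratio of the mean contact in the
500-kb sliding square crossing each bin over the chromosome mean of
those window means (the score itself is our choice of definition).
Conserved-state grouping is a documented stand-in for phylogenetic HMM
state discovery: K-means (k-means++ with fixed seed, default K 30; the
tests use K 12 at toy scale) on aligned per-bin cross-species vectors,
greedy merging of states whose means are pairwise cosine-similar
≥ 0.85 (earliest group wins ties), labels CA/CB when every member-state
mean is positive/negative in every species (above/below the per-species
median for insulation), NC/AI otherwise.

## TAD calling

DI uses a symmetric window (package default 2 Mb; toy-scale analyses use
400 kb — the window should not exceed the smallest domain of interest,
and the planted minimum is 400 kb). Before HMM fitting, DI is
rank-transformed to normal scores per chromosome: DI is quadratic in
count deviations and so heavy-tailed that Gaussian emissions otherwise
collapse onto the spikes; the transform preserves sign and order and
makes the call invariant to global scaling. The 3-state Gaussian HMM is
initialized at means (−1, 0, +1) with jittered restarts (≥5); states are
ranked by mean into upstream-bias / neutral / downstream-bias. A domain
opens at a downstream-bias run and closes at the next upstream-bias run
(biased runs must span ≥min_run bins; default 2 at toy scale as planted
boundary runs are short). Two refinements recover boundaries the decode
smooths over: long domains are split where a sustained strongly negative
normal-score stretch flips to a sustained positive one, and each
inter-domain gap contributes a boundary at every negative-to-positive DI
crossing whose contrast reaches 30% of the sharpest crossing in the gap
(gaps can contain more than one true boundary). Gaps below 400 kb are
boundaries, larger ones unorganized chromatin. The caller is tuned for
recall of planted boundaries (≥90% within ±1 bin at the default depth);
it overcalls domains by ~20% relative to planted truth, which the
conservation analyses tolerate.

Boundary conservation maps each query boundary midpoint to every other
species through ortholog anchors (piecewise-linear interpolation between
shared single-copy gene starts plus chromosome ends): conserved
strictly < 40 kb, non-conserved strictly > 100 kb, else unknown; gained =
non-conserved everywhere, lost-in-X = conserved in a majority (>50%,
configurable) but non-conserved in X.

## Conservation analytics

3DR filters motifs below the 70% score quantile, classifies every
contiguous surviving pair ((+,−) convergent, (−,+) divergent, like-strand
ignored) and takes the ratio of medians of start-to-start distances. The
TAD-border mode keeps motifs inside the boundary interval padded by
20 kb per side; padding the *interval* rather than windowing a bare
midpoint makes the statistic robust to one-bin boundary-call error
(with a ±20-kb window around a midpoint that is itself one bin off, only
one strand of the anchor cluster survives and the ratio collapses —
verified on the generator).

CNE profiles enlarge each TAD by 50% of its length per side and split
the enlarged span into 40 equal bins (10 flank + 20 interior + 10
flank); each filtered CNE (phastCons ≥ 0.95, length > 200 bp) is
assigned to the bin containing its midpoint, so one CNE contributes to
exactly one bin and counts are conserved.

TAD conservation uses consecutive single-copy ortholog pairs in
reference gene order (an all-pairs mode exists). The headline scores
are percentages of gene-bearing reference TADs containing (intra) or
participating in (inter) at least one qualifying pair. Because the
participation form of the inter score saturates near 100% in any genome
with few rearrangements, the result also reports pair-level fractions on
a common basis — % of intra-TAD pairs co-domiciled in the target vs % of
inter-TAD pairs still co-chromosomal — and cross-class comparisons use
those. Co-expression stratifies pairs by the number of intervening genes
(d = 0 adjacent), requires ≥3 replicates, and compares the fraction of
pairs with Pearson r > 0.9 between same-TAD pairs and all pairs.

## TE statistics

Within-family TE records are merged before coverage so overlapping
annotations never double-count a base; families other than
SINE/LINE/LTR/DNA are discarded. Contact filtering drops intra-
chromosomal pairs below the mean inter-domain frequency, then removes
integer frequency levels carried by fewer than 100 bin pairs. TE
"proportion" is the bp coverage fraction; per-pair TE proportion is the
mean of the two bins' coverage. Enhancer folds are bp-weighted means of
coverage inside vs outside merged enhancer intervals, with a seeded
bin-bootstrap CI; when enhancers tile everything the contrast is defined
as 1.

## Numerical and design choices

- Coordinates are 0-based half-open throughout; bin index = floor(pos /
  resolution).
- Classical (Torgerson) MDS is used for 3D embedding — deterministic,
  eigen-based — with shortest-path completion of unobserved distances;
  hull metrics are rigid-motion and vertex-subset invariant. Model units
  are arbitrary (the adjacent-bin distance ≈ 1), so only orderings and
  correlations of territory metrics are meaningful, not magnitudes.
- Degenerate inputs: all-zero DI yields zero domains; uniform matrices
  yield a low-confidence compartment flag; zero-variance tracks yield
  NA correlations; empty boundary classes are omitted with a warning.
- The gene-density input used to orient PC1 in the pipeline is derived
  from the planted compartment signs plus ortholog counts; in real use
  it would come from the annotation.
- Problem sizes: the default test world is 3 species × 2–3 chromosomes
  of 6–14 Mb at 84k contacts/Mb; P(s) recovery uses 2 × 25–40 Mb
  chromosomes at 1M contacts; the directional sign tests run 20 seeded
  replicates each at these scales.

## Known limitations

- The TAD caller's domain count overshoots planted truth by ~20%
  (recall-oriented refinements); precision-sensitive uses should raise
  `min_run` or the crossing-contrast threshold.
- The length–stretchiness anticorrelation of chromosome territories is
  weak within a species at fixed decay exponent and moderate depth; it
  emerges clearly only on ladders with a decay gradient or deeper maps.
- Cross-species alignment assumes shared chromosome names and no
  inversions; anchor interpolation can wobble by up to ~1.5 bins where
  both gene and TAD coordinates are grid-snapped.
- The randomization calibration caveat above: network variance of the
  unit-cube control is ≈1 only for large networks.
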