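# archcompare

Comparative analysis of 3D genome architecture across species, built as an
importable Python library with an end-to-end synthetic benchmark. It is
aimed at computational biologists who want the standard cross-species
Hi-C analyses — contact decay, chromosome-territory shape,
inter-chromosomal interaction networks, A/B compartments, TADs, CTCF
motif orientation, and transposable-element correlations — as tested,
composable functions, together with a seeded generator of multi-species
toy worlds with planted ground truth so every stage can be validated
without external data.

## What it computes

- **Contact matrices** (`archcompare.matrix`): binned symmetric counts
  M<sub>ij</sub> with ICE iterative correction (per-bin weights w so that
  the retained marginals of w<sub>i</sub>w<sub>j</sub>M<sub>ij</sub> are
  equal; genome-wide or cis-only scope), distance-stratified quantile
  normalization across samples, the stratum-adjusted correlation
  coefficient SCC for replicate reproducibility, and P(s) contact-decay
  curves with the log-log slope fitted over a long-range window
  (P(s) ∝ s<sup>α</sup>).
- **Trans networks** (`archcompare.transnet`): for each
  inter-chromosomal 500-kb bin pair, the upper-tail binomial probability
  P = Σ<sub>i=k</sub><sup>n</sup> C(n,i) m<sub>norm</sub><sup>i</sup>
  (1−m<sub>norm</sub>)<sup>n−i</sup> with m<sub>norm</sub> the
  fragment-count background, BH FDR per chromosome pair, and q-values
  normalized by chromosome-length products. Significant pairs form bin
  interaction networks whose network variance S²<sub>d</sub>/x̄<sub>d</sub>
  (sample degree variance over mean degree), clustering coefficient
  C<sub>n</sub> = 2e<sub>n</sub>/(k<sub>n</sub>(k<sub>n</sub>−1)),
  average degree, path length and degree power-law slope are compared
  against geometry-based randomized controls (unit-cube closest pairs
  plus transitivity-increasing edge switches).
- **3D territories** (`archcompare.structure`): classical metric MDS on
  d = contact<sup>−α</sup> distances, convex-hull volume/surface, and
  the territory metrics stretchiness = 1/VSR = S/V and condensation =
  1/VpM = Mb/V.
- **Compartments** (`archcompare.compartments`): PC1 of the
  observed/expected correlation matrix oriented by gene density, the
  20-kb AB index (normalized difference of mean contact with A- vs
  B-labeled bins, in [−1, 1]), sliding-square insulation scores, K-means
  state discovery over aligned cross-species tracks with cosine-similarity
  grouping into conserved-A / conserved-B / not-conserved, cross-tissue
  consistency tests, and similarity-vs-divergence-time correlations.
- **TADs** (`archcompare.tads`): the directionality index
  DI = sign(B−A)·((A−E)²/E + (B−E)²/E) with E=(A+B)/2 over a fixed
  window, 3-state Gaussian-HMM domain calling, insulation and TSS
  profiles around boundaries, and cross-species boundary conservation
  (conserved < 40 kb, non-conserved > 100 kb through ortholog-anchored
  coordinate mapping; gained/lost calls per species).
- **Sequence/expression conservation** (`archcompare.conservation`):
  3DR = median(d<sub>→←</sub>)/median(d<sub>←→</sub>) over contiguous
  CTCF motif pairs (genome-wide or restricted to TAD borders), CNE
  distribution profiles across 50%-enlarged TADs, intra- vs inter-TAD
  ortholog conservation scores, and co-expression of gene pairs
  stratified by gene distance and shared-TAD membership.
- **TE–chromatin statistics** (`archcompare.te`): per-family
  (SINE/LINE/LTR/DNA) coverage tracks, correlations with the AB index and
  with filtered contact frequencies, and enhancer/non-enhancer coverage
  folds with bootstrap CIs.
- **Synthetic worlds** (`archcompare.world`): seeded multi-species
  genomes evolved along a random ultrametric phylogeny — power-law cis
  decay modulated by a planted compartment checkerboard and intra-TAD
  enrichment, chromosome-length-dependent trans affinity with evolving
  hub loci, TAD-block translocations, CTCF boundary clusters, TE/CNE/
  enhancer tracks and TAD-correlated expression, all with known truth.

## Worked example

`examples/02_contact_decay.py` simulates three species and recovers each
planted decay exponent from the fitted P(s) slope:

```
sp1: fitted slope -0.322  (planted -0.323)
sp2: fitted slope -0.450  (planted -0.450)
sp3: fitted slope -0.230  (planted -0.230)
```

`examples/06_tads_conservation.py` calls TADs per species, classifies
boundaries across species, and contrasts CTCF orientation at borders:

```
sp1: 41 TADs called (35 planted), 41 boundaries
boundary conservation labels: {'unknown': 20, 'conserved': 13, 'gained': 8}
3DR genome-wide 26.39, TAD borders 56.02
CNEs per bin: interior 0.92 vs flank 0.75
```

The fitted slopes match the planted exponents to ~0.01; border 3DR well
above the genome-wide ratio reflects the planted convergent CTCF anchors
at TAD edges, and CNEs are depleted in boundary flanks relative to TAD
interiors. The remaining examples cover trans networks, 3D territories,
compartment-state grouping, TE/expression statistics, and the end-to-end
pipeline (`archcompare run --config cfg.yaml` from a shell, or
`archcompare.pipeline.run_all` from Python).

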