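# Methods

This note documents the models, algorithmic conventions and design
choices behind `motudiv`, in the spirit of the methods documentation of
packages such as scanpy or statsmodels: what is computed, under which
assumptions, and where the genuinely open choices were resolved.

## MOTU delimitation

Input is a fixed-length nucleotide alignment (the package refuses ragged
FASTA; aligning is an upstream responsibility, appropriate for a
length-conserved marker such as the D3 expansion segment of 28S rRNA).
For every sequence pair we count `bp_diff` (differing sites) and
`compared_sites`, and report `p_dist = bp_diff / compared_sites`.

* **Ambiguity policy** (default `pairwise_deletion`): positions where
  either residue is N are excluded from both counts.
* **Gap policy** (default `difference`): a gap aligned to a base counts
  as one difference; gap–gap counts as an identical compared site. An
  optional flag collapses a maximal run of same-side gap-vs-base
  positions into a single event (one difference, one compared site),
  treating an indel as one mutation. Explicit counting was preferred over
  silent exclusion because indels are rare in this marker; the published
  analyses this pipeline emulates do not state their gap handling, so the
  defaults are declared, not inferred.

MOTUs are single-linkage clusters: two sequences share a MOTU iff they
are connected by a chain of pairs each with `bp_diff < k`. The threshold
semantics encode "a difference of *k* bp assigns a specimen to a
different MOTU" literally: at *k* = 1 only identical sequences merge, so
linkage is moot; for the 2–3 bp sensitivity thresholds single linkage is
the only scheme under which the 1-bp rule generalises without
tie-breaking ambiguity. Cluster ids are assigned deterministically
(ordered by each cluster's smallest member id), so partitions are
invariant to input order. Thresholds are compared with integer bp counts,
never p-distances, so results do not depend on per-pair denominators.

## Neighbor joining

The MOTU summary tree uses Saitou–Nei agglomeration with the
Studier–Keppler criterion Q(i,j) = (r−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k) on
p-distances of one representative per MOTU (the member with the smallest
specimen id; at the 1-bp threshold all members are identical, so the
choice is immaterial). Ties in Q are broken on the lexicographically
smallest pair of node keys, a node's key being its smallest descendant
leaf id — output is deterministic and leaf-order invariant. Negative
branch lengths are preserved with a warning (faithful raw NJ); an
optional flag clamps them to zero for display. The final three nodes are
joined by solving the 3-leaf star exactly, leaving the customary root
trifurcation of an unrooted binary tree. Leaves carry the number of
pitfall traps the MOTU occupied. The tree is descriptive; no support
values are computed and no phylogenetic claims are intended.

## Concordance classification

Over sequenced specimens, morphospecies and MOTUs form a bipartite
overlap graph (edge = shared specimen). Each connected component is
classified: **consistent** (1 morphospecies, 1 MOTU), **splitting**
(1 MOTU, ≥2 morphospecies), **lumping** (1 morphospecies, ≥2 MOTUs),
**complex** (≥2 of each). The terminology follows threshold-MOTU field
usage, which inverts common systematic parlance. Component-wise
classification was chosen because per-MOTU phrasing is ambiguous for
many-to-many overlaps; *complex* components are reported separately
rather than double-counted so that individual counts are additive
(splitting + lumping + complex + consistent individuals = all sequenced
specimens) and the swap-duality holds exactly: exchanging the two
labelings swaps splitting and lumping counts. Whether published
"exactly consistent taxa" counts components or label pairs is not
decidable from the prose this mirrors; the component count is used and
reported as such.

## Diversity statistics

All sample-based statistics treat pitfall traps as samples.

* **Accumulation curves.** Default: mean cumulative richness over random
  trap orderings (1,000 by default), with a 95% band from the 2.5/97.5
  percentiles across orderings. The analytic hypergeometric expectation
  E[S_h] = S_obs − Σᵢ C(m−kᵢ, h)/C(m, h) is also implemented; it serves
  as the oracle in tests and as a deterministic option. Both coincide at
  h = m with S_obs exactly.
* **First-order jackknife.** S_jack1 = S_obs + f₁(m−1)/m, with the
  Heltshe–Forrester (1983) variance
  var = ((m−1)/m)(Σ_s r_s² − f₁²/m), r_s = number of uniques in sample s
  — the formula used by standard ecological software, adopted because the
  emulated analyses cite only "first-order jackknife" with an SE.
* **Richness and density.** Richness = taxa per transect; density = mean
  per-trap taxon count within a transect. Deployed traps that caught
  nothing count as zero-taxon traps, not missing data.
* **t tests.** Two-sided throughout. Degenerate inputs are defined rather
  than erroring: identical vectors give t = 0, p = 1; a constant nonzero
  paired difference reports p = 0 with a warning.

### Calibration caveat at the study's sample size

With 3 transects per habitat, the Welch test's t-approximation is only
approximate. Simulation under the generator's null (no habitat effect,
study-scale survey) puts its type-I error at ≈0.087 at nominal α = 0.05
(4,000 replicates), because per-transect richness is discrete with small
variance; on ideal normal data at n = 3 + 3 the same test is instead
conservative (≈0.034). This is a property of the Welch approximation at
tiny n, not of the implementation: the test suite verifies exact nominal
calibration at n = 15 per group and a bounded (< 2α) type-I error at the
study design. Habitat p-values at 6 units should therefore lean on the
exact permutation tests, which is how the ordination factor fit is
assessed.

## Community structure

* **Bray–Curtis** d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) among transect abundance
  vectors (transect level mirrors the emulated design; trap level is
  available). A pair of all-zero units is an error, not a silent 0.
* **Mantel test.** Pearson correlation of upper-triangle vectors;
  one-sided upper tail; rows/columns of one matrix permuted jointly. For
  ≤7 units all n! permutations are enumerated (exact p, floor 1/n!);
  otherwise Monte-Carlo with p = (1 + #{r* ≥ r})/(1 + n_perm).
* **DCA.** Correspondence analysis via SVD of the χ²-standardised matrix
  (sites in principal coordinates, weighted mean zero); axis 2 is
  detrended against axis 1 by segments — 26 equal-width bins by default,
  the de-facto standard of decorana-style implementations — subtracting
  within-bin means, then re-centred. Axis 1 is untouched by detrending.
  Hill's nonlinear rescaling is deliberately out of scope: the habitat
  fit uses only relative score geometry.
* **Habitat factor fit.** r² = 1 − SS_within/SS_total over the 2-D site
  scores; significance by label permutation, exhaustively enumerated when
  the number of distinct label arrangements is small (≤10,000). At 6
  units in two groups of 3 there are 20 arrangements and the attainable
  p floor is 2/20 = 0.1, because r² is invariant under swapping the two
  group labels. The r² definition is reported explicitly in outputs since
  "variance explained by habitat" admits several formalisations.

## Synthetic surveys

The generator emulates a standardized pitfall design: 3 transects per
habitat (primary/secondary), 10 traps per transect, morphospecies sorting
of every catch, one specimen per morphospecies per trap entering
sequencing, and amplification failure at 0.9% (each flagged specimen is
retained in the table so success rates are computable, and excluded from
all MOTU statistics).

Ground truth is engineered at the pool level. Prototype sequences
(default 180 bp) are drawn uniformly and re-drawn until every pair
differs by at least `min_interspecific_bp` (default 3) sites. Cryptic
pairs are two such species sharing one morphospecies label; dimorphic
species carry two labels, alternated deterministically across the
species' successive individuals (an even sex ratio), so any such species
caught twice expresses both labels and noiseless recovery is exact.
Intraspecific variants (rate 0.02 per specimen) mutate at most
⌊(min_interspecific_bp − 1)/2⌋ sites, keeping single-linkage ground truth
unambiguous: with variant rate 0 and failure rate 0, 1-bp MOTUs equal
true species exactly. Mutations are substitutions only; gap handling is
exercised by hand-built alignments in the tests instead.

Abundances: each species draws a Fisher log-series score (shape 0.999 per
habitat) in the habitats it occupies — the standard null for insect
pitfall data; a configurable fraction of species are habitat specialists,
assigned to habitats alternately so per-habitat pools stay balanced. Each
trap draws a Poisson(25) total catch split multinomially by the scores
multiplied by per-trap gamma noise (shape 0.1, mean 1), emulating the
strong spatial clumping of leaf-litter arthropods. These defaults were
calibrated to the emulated survey's design counts — with a 100-species
pool they yield ≈425 sequencing attempts, ≈70 observed morphospecies and
≈7 morphospecies per trap — and the acceptance script runs at exactly
this scale.

What the generator does *not* emulate: realistic molecular evolution (no
substitution-rate matrices, no coalescent within species), indels,
trap-level environmental covariates, or spatial autocorrelation between
neighbouring traps. Passing parameter-recovery tests therefore shows the
pipeline's logic is correct under known ground truth, not that the marker
itself delimits real species.

## Numerical and reproducibility conventions

* Alignment positions are 0-based internally, 1-based in messages.
* All Monte-Carlo p-values use the +1 correction; exhaustive enumerations
  include the identity, so no p-value is ever 0.
* Comparisons of permuted statistics against the observed value use an
  absolute tolerance of 1e−12 so exact ties count as exceedances.
* All pipeline randomness flows from one seed through fixed named
  substreams per stage; changing the permutation count of one stage does
  not perturb any other. Identical configurations give byte-identical
  JSON reports.
* The test suite and the acceptance script use scaled problem sizes
  (e.g. ≤50-sequence alignments for clustering oracles, 500 replicates
  for Mantel calibration, 1,000 null surveys for the Welch bound) chosen
  to make Monte-Carlo bands tight enough to be meaningful while keeping
  a full run inexpensive on one CPU.

## Known limitations

* Single linkage chains: at thresholds >1 bp a dense series of variants
  can bridge distinct species (the usual caveat of threshold clustering).
* The NJ tree reports raw branch lengths; negative values are possible
  and flagged, not hidden.
* DCA implements detrending-by-segments only; axis scalings follow the
  SVD conventions stated above and are not numerically identical to any
  particular legacy implementation, though axis-1 geometry is (tested
  against the reciprocal-averaging fixed point to 1e−8).
* Morphospecies statistics include sequencing failures by default
  (configurable); the emulated publications do not state their choice.
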