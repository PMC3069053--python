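# motudiv

Molecular biodiversity assessment from short nuclear marker sequences:
delimit MOTUs (molecular operational taxonomic units) by a basepair-
difference threshold, quantify their concordance with morphospecies
sorting, and compare diversity and community composition between habitats.

## The problem

Rapid biodiversity surveys of hyperdiverse insect groups (e.g. rove
beetles in tropical forest pitfall-trap transects) cannot afford full
taxonomic identification. Two pragmatic proxies are common: *morphospecies*
(parataxonomic sorting on external morphology) and *MOTUs* (clusters of
marker sequences, here a short ~180 bp expansion segment of nuclear 28S
rRNA). This package implements the complete analysis chain needed to ask
whether the two proxies tell the same ecological story:

1. **MOTU delimitation** — pairwise basepair differences on a fixed-length
   alignment; single-linkage clustering where two sequences share a MOTU
   iff they are connected by pairs differing by fewer than *k* bp. At the
   default *k* = 1, MOTUs are exactly the groups of identical sequences.
2. **Concordance** — connected components of the bipartite
   morphospecies↔MOTU overlap graph, classified as *consistent* (1:1),
   *splitting* (one MOTU, ≥2 morphospecies), *lumping* (one morphospecies,
   ≥2 MOTUs) or *complex*, with individual-level counts.
3. **Diversity** — sample-based species accumulation curves (permutation
   and analytic Mao-tau: E[S_h] = S_obs − Σᵢ C(m−kᵢ, h)/C(m, h)); the
   first-order jackknife S_jack1 = S_obs + f₁(m−1)/m with
   Heltshe–Forrester SE; per-transect richness and per-trap density;
   paired and Welch *t* tests.
4. **Community structure** — Bray–Curtis dissimilarity
   d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) among transects, a Mantel test between the
   morphospecies- and MOTU-based dissimilarity matrices, detrended
   correspondence analysis (DCA, detrending by segments), and a
   permutation test of habitat fitted to the first two ordination axes
   (r² = 1 − SS_within/SS_total). Mantel and factor-fit switch to
   exhaustive enumeration at small unit counts, so p-values are exact for
   a six-transect design.
5. **Synthetic surveys** — a generator that emulates the full sampling
   design (3 transects per habitat × 10 pitfall traps, one specimen per
   morphospecies per trap sequenced, ~1% amplification failure) with known
   ground truth: engineered cryptic species pairs (expected lumpings),
   sexually dimorphic species (expected splittings), habitat specialists,
   and log-series abundances with per-trap clumping. Every downstream
   stage therefore has a parameter-recovery test.

An NJ tree (Saitou–Nei, p-distances) of MOTU representatives annotated
with trap occupancy is produced as a descriptive summary — it is not a
phylogeny and carries no support values.

## Worked example

Run the whole pipeline on a simulated 30-species survey with one cryptic
pair and one dimorphic species:

```yaml
# pipe.yaml
seed: 42
n_permutations: 999
out_dir: demo/full
simulation:
  n_species: 30
  seed: 42
  n_cryptic_pairs: 1
  n_dimorphic_species: 1
  habitat_specialist_fraction: 0.7
```

```console
$ motudiv run --config pipe.yaml
sequencing success 99.5% (215/216); MOTUs: {'1': 33, '2': 29, '3': 29}
```

216 specimens entered sequencing (one per morphospecies per trap) and one
failed (99.5%). At the 1 bp threshold the 215 sequences fall into 33
MOTUs — more than the 30 true species because rare intraspecific variants
split off singleton MOTUs at this strict threshold; relaxing to 2–3 bp
merges them back (29). The output directory holds `motus_t*.tsv`,
`tree.nwk`, `concord.json`, `div.json`, `compare.json` and a consolidated
`report.json`. The same stages are available individually:

```console
$ motudiv cluster --fasta demo/seqs.fasta --specimens demo/specimens.tsv \
      --threshold 1 --out demo/motus.tsv
33 MOTUs at threshold 1 bp
$ motudiv concord --specimens demo/specimens.tsv --motus demo/motus.tsv \
      --out demo/concord.json
consistent taxa: 22; split individuals: 10; lumped individuals: 65
$ motudiv diversity --specimens demo/specimens.tsv --seed 1 --out demo/div.json
jackknife1 estimate 33.9 (SE 2.1)
$ motudiv compare --community demo/transects.tsv --meta demo/specimens.tsv \
      --seed 1 --out demo/compare.json
habitat fit r^2 = 0.964, p = 0.1
```

Here 10 individuals sit in splittings (the dimorphic species sorted into
two morphospecies sharing one MOTU), 65 in lumpings (the cryptic pair plus
variant-induced MOTU splits of single morphospecies), and habitat explains
96% of the ordination variance — at 6 transects the exhaustive permutation
p-value has a floor of 0.1 (2 of the 20 label arrangements, the observed
one and its mirror, always tie it). Everything is reproducible: the same
seeds give byte-identical reports.

The same functionality is available as a library (`motudiv.simulate`,
`motudiv.pairwise_distances`, `motudiv.cluster_motus`,
`motudiv.concordance_analysis`, `motudiv.jackknife1`, `motudiv.mantel`,
`motudiv.dca`, `motudiv.fit_factor`, `motudiv.run_pipeline`, ...).

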