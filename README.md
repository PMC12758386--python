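# stcap — subterminal heterochromatic cap analysis

African great apes (chimpanzee, bonobo, gorilla) carry megabase-scale
heterochromatic caps at many chromosome ends that humans lack.  Each cap is
built from tandem arrays of a 32 bp satellite unit (pCht/StSat) interleaved
with 32–34 kbp segmental-duplication "spacers" that are hypomethylated
relative to the surrounding satellite and are candidate hotspots of ectopic
(nonallelic) recombination.  `stcap` is a toolkit for analysing such
regions, aimed at researchers working with T2T-grade primate assemblies or
with simulated satellite architectures:

* **Satellite annotation** — detect every occurrence of the consensus unit
  (coverage > 90%, i.e. >28 of 32 bp retained), assign each a canonical
  variant signature (substitutions/insertions/deletions vs the consensus),
  and derive satellite arrays and SD spacers by subtraction.
* **Higher-order structure** — an arms × variants composition matrix
  (cells = count of variant in arm / total units in arm), hierarchical arm
  clustering on correlation distance with average linkage and bootstrap
  support, and two-step k-means block typing (variants → variant clusters →
  block types, k chosen by silhouette).
* **Spacer phylogeny** — length filtering (>90% of modal length),
  center-star MSA, neighbor-joining on JC69 distances
  (d = −¾ ln(1 − 4p/3)) with site-resampled bootstrap, and strict-clock
  time calibration against fixed ape divergence ages
  (6.4 / 8.6 / 15.2 / 19.5 MYA).
* **Ectopic exchange** — anchor-chained pairwise arm alignment, candidate
  calling from >99.5%-identity nonallelic blocks with refined breakpoints,
  a 1000-shuffle breakpoint-to-spacer proximity test, the half-alignment
  Robinson–Foulds shift test (null: bootstrap trees vs their majority-rule
  consensus), and allelic-vs-nonallelic window identity profiles.
* **Boundary epigenomics** — symmetric CpG merging (≥5 reads), methylation
  profiles across the heterochromatin–euchromatin transition, insertion
  calling from syntenic alignment gaps (≥50 bp) with source attribution,
  and one-sided permutation tests of SD/gene enrichment in boundary
  windows.
* **Synthetic genomes** — a generator of cap-like genomes with exact ground
  truth (unit positions and signatures, block types, spacer duplication
  tree, planted exchange breakpoints, beta-binomial methylation, boundary
  feature enrichment), so every analysis stage has a parameter-recovery
  test.

Real-genome dimensions (2 Mbp boundary windows, 20 kbp blocks, 32 kbp
spacers) are defaults where they apply; the synthetic mode scales everything
down (2048 bp spacers and blocks, 20 kbp windows) and is what the test
suite exercises.  See `docs/methods.md` for models and design choices.

## Worked example

Run the whole chain on one synthetic genome:

```python
from stcap.pipeline import run_pipeline
summary = run_pipeline(seed=1)
for k in ("genome_bp", "n_units_detected", "unit_count_ratio",
          "k_block_types", "block_type_ari", "n_exchange_candidates",
          "breakpoint_spacer_p", "methylation_satellite_mean",
          "methylation_spacer_mean", "sd_boundary_fold"):
    print(f"{k}: {summary[k]}")
```

prints (seed 1):

```
genome_bp: 1596544
n_units_detected: 22144
unit_count_ratio: 1.0
k_block_types: 4
block_type_ari: 1.0
n_exchange_candidates: 1
breakpoint_spacer_p: 0.02594810379241517
methylation_satellite_mean: 0.7995094392237189
methylation_spacer_mean: 0.39915661341907493
sd_boundary_fold: 4.833333333333333
```

Reading this: the detector found exactly the 22 144 planted units
(`unit_count_ratio` = detected/truth); two-step k-means chose k = 4 block
types and reassigned every block to its planted type (adjusted Rand index
1.0); the one planted conversion-like exchange was recovered and its
breakpoints fall in spacers often enough that uniform shuffles rarely do
better (p ≈ 0.026); merged CpG fractions reproduce the configured
satellite/spacer methylation means (0.80 / 0.40); and SD density in the
20 kbp boundary windows is ~4.8× the flank-wide density against a
configured 5-fold enrichment.

The same stages are available from the shell:

```sh
stcap simulate --seed 1 --out-prefix scratch/genome
stcap annotate --fasta scratch/genome.fa \
      --out-units scratch/units.bed --out-arrays scratch/arrays.bed \
      --out-spacers scratch/spacers.bed
stcap arm-tree --units scratch/units.bed --min-units 500 --min-count 20 \
      --out scratch/arms.nwk
```

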