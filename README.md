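# barcodekit

Assessment toolkit for DNA-barcode reference libraries.

DNA barcoding identifies specimens by comparing a query COI sequence
against a library of sequences from taxonomically verified vouchers, and
flags likely cryptic species where a named species contains deeply
divergent mitochondrial lineages. Whether that works for a given library —
say, a regional inventory of marine molluscs, a group rich in phenotypic
plasticity and misidentification — is an empirical question with a
standard battery of answers, all of which this package computes:

* **Distance summary** — Kimura two-parameter (K2P) distances with
  pairwise deletion, `d = -½ ln((1-2P-Q)√(1-2Q))`, summarised per
  taxonomic comparison level (within species, within genus between
  species, …) with min/mean/max/SE in percent, plus GC-content and
  chi-square composition homogeneity statistics and OLS regressions of
  divergence on sampling depth.
* **Barcode gap** — per species, maximum intraspecific divergence versus
  the nearest-neighbour (NN) distance; species where the NN distance does
  not exceed the intraspecific maximum lack a gap and are counted as
  overlaps.
* **Identification simulation** — leave-one-out matching of every record
  under Best Match, Best Close Match and All Species Barcodes criteria,
  with three threshold choices: fixed 0.01, a cumulative-error-optimised
  value (false positives = conspecifics available but none within the
  threshold; false negatives = more than one species within it), and the
  first local minimum of the kernel density of all pairwise distances.
* **Tree clustering** — neighbour-joining tree; per species: distinct
  cluster, paraphyletic, or shared cluster; haplotype collapsing with
  sharing flags; bootstrap support by site resampling.
* **Cryptic lineages** — average-linkage clustering within each species
  cut at mean divergence > 2%; per-family candidate-species summary and
  the implied percent increase in species diversity.
* **BIN concordance** — externally supplied Barcode Index Numbers
  classified as concordant / merged (with the taxonomic rank of the
  conflict) / singleton, and species split across BINs.
* **Synthetic libraries** — a seeded generator with controlled distance
  targets and planted singletons, shared haplotypes and deep lineages,
  plus a truth table, so the whole pipeline is testable offline.

## Worked example

```python
from barcodekit import SynthConfig, generate_dataset, pairwise_matrix
from barcodekit.distances import summarize_by_level, level_summary_frame
from barcodekit.identification import simulate_identification, summary_frame
from barcodekit.tree_clustering import deep_lineages

cfg = SynthConfig(seed=42, n_genera=4, species_per_genus=2,
                  specimens_per_species=4,
                  planted_deep_species=[(2, 0.08)])
dataset, truth = generate_dataset(cfg)
matrix = pairwise_matrix(dataset)

summaries, _ = summarize_by_level(matrix, dataset)
print(level_summary_frame(summaries).round(2).to_string(index=False))

sims, _ = simulate_identification(dataset, matrix, thresholds=(0.01, 0.05))
print(summary_frame(sims).to_string())
```

prints

```
                        level  n_pairs  min_pct  mean_pct  max_pct  se_pct
               within_species       48     0.33      1.72     9.24    0.33
 within_genus_between_species       64    17.74     21.01    24.62    0.24
 within_family_between_genera      128    21.90     26.00    32.96    0.26
within_order_between_families      256    22.93     27.64    33.10    0.16
  within_class_between_orders        0      NaN       NaN      NaN     NaN

                        BM       BCM 0.01         BCM 0.05       ASB 0.01         ASB 0.05
true       100.00 (100.00)  71.88 (71.88)  100.00 (100.00)  71.88 (71.88)  100.00 (100.00)
false          0.00 (0.00)    0.00 (0.00)      0.00 (0.00)    0.00 (0.00)      0.00 (0.00)
ambiguous      0.00 (0.00)    0.00 (0.00)      0.00 (0.00)    0.00 (0.00)      0.00 (0.00)
no_id          0.00 (0.00)  28.12 (28.12)      0.00 (0.00)  28.12 (28.12)      0.00 (0.00)
```

Reading it: conspecific distances average 1.7% (inflated by the planted
deep split — `deep_lineages(matrix, dataset, "Genus01 species01")` returns
its 2 lineages) against 21% between congeners, so every species keeps a
barcode gap and best-match identification is perfect. At the strict 0.01
threshold 28% of queries return no identification — their conspecific
neighbours sit just above it — while 0.05, inside the gap, identifies
everything; bracketed values repeat each rate after excluding singletons
(none here).

The same battery runs from the shell:

```sh
barcodekit simulate --seed 42 --fasta lib.fasta --metadata lib.tsv
barcodekit identify --fasta lib.fasta --metadata lib.tsv \
    --criterion bcm --threshold optimized
barcodekit all --config pipeline.cfg   # full report bundle + manifest.json
```

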