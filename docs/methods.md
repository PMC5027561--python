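# Methods

## Scope and model

`barcodekit` implements the standard assessment battery for a DNA-barcode
reference library: a set of aligned COI sequences, each tied to a
morphology-based Linnean identification, is interrogated for (i) the
hierarchical structure of its genetic distances, (ii) the presence of a
barcode gap per species, (iii) how well leave-one-out specimen
identification works under the common matching criteria, (iv) whether
species form exclusive clusters on a neighbour-joining tree, (v) deeply
divergent intraspecific lineages (candidate cryptic species), and (vi) the
concordance of externally computed Barcode Index Numbers (BINs) with the
species labels.

All genetic distances are Kimura two-parameter (K2P):

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))

with P and Q the transition and transversion fractions over the sites
compared for that pair. Sites where either sequence carries a gap, an `N`
or an IUPAC ambiguity code are excluded per pair (pairwise deletion —
the convention of the major barcode databases, which maximises usable
sites). When the logarithm's argument is non-positive (saturation) or no
sites overlap, the distance is undefined; undefined entries are stored as
NaN and excluded from every summary with their count reported, the only
treatment that keeps means finite.

Distances travel through the code as proportions and are converted to
percent only at the reporting layer, which avoids double-scaling.

## Identification criteria

Every record is in turn the query against all remaining references, using
the precomputed distance matrix:

* **BM (best match)** — the closest reference identifies the query
  regardless of distance; equally close references from two or more
  species give `ambiguous`.
* **BCM (best close match)** — BM restricted to references strictly below
  a threshold; an empty set gives `no_id`.
* **ASB (all species barcodes)** — every reference strictly below the
  threshold must belong to one species; two or more species give
  `ambiguous`, none gives `no_id`.

"Below the threshold" is implemented as strict `<`, and distance ties are
detected by exact float equality: distances are derived from rational
P, Q over fixed site sets, so engineered ties are representable exactly and
an epsilon tolerance would silently change outcome counts.

Three threshold choices are shipped: the fixed `0.01` used by BOLD's
identification engine; an optimised threshold minimising the cumulative
identification failure — false-positive error (queries with conspecifics
in the library but none within the threshold) plus false-negative error
(queries with more than one species within the threshold) — scanned over a
default grid of 0.001–0.20 in steps of 0.001 and resolved to the midpoint
of the first contiguous minimising interval; and the first local minimum of
a Gaussian kernel density estimate of all defined pairwise distances
(Silverman bandwidth, 512-point grid over [0, max]), the classical
transition point between intra- and interspecific divergence. Queries
whose species is a singleton are excluded from the false-positive error
(no conspecific is available to find).

## Barcode gap

For each multi-specimen species the maximum defined conspecific distance
is compared with the nearest-neighbour (NN) distance — the minimum defined
distance from any of its specimens to any heterospecific specimen. Ties
count as overlaps (a heterospecific sequence at exactly the maximum
intraspecific distance defeats identification), NN ties between species
are broken by lexicographic name for determinism, singletons are reported
but not assessed (they still serve as neighbours), and species with
NN ≤ 2% that nevertheless keep a gap are counted separately.

## Tree-based assessment

The NJ tree is the standard Saitou–Nei agglomeration (delegated to
scikit-bio; negative branch-length estimates are clamped to zero, standard
practice that keeps path lengths interpretable). On additive matrices the
reconstruction is exact to machine tolerance, which the tests exploit as
an oracle. Bootstrap support resamples alignment columns with replacement
from one seeded generator; support of an edge is the percentage of
replicate trees containing its bipartition.

For cluster assessment the tree is midpoint-rooted (deterministic and
label-free; no outgroup is assumed) and each multi-specimen species'
minimal containing clade is enumerated. Only conspecific leaves →
`distinct_cluster`. If two species' minimal clades contain each other, or
the species shares an identical haplotype with another, the species are
inseparably mixed → `shared_cluster`; this precedence mirrors the
empirical distinction between paraphyly without haplotype sharing and
genuine barcode sharing. Extra leaves without mutual overlap →
`paraphyletic`. Haplotypes are exact-identity classes after removing
columns that are gaps in every record; ambiguity codes must match
literally, so a single `N` separates haplotypes (conservative, never
invents sharing).

Deep intraspecific lineages use average-linkage agglomerative clustering
of each species' specimens on K2P distances, cut at 2%: clusters keep
merging while their mean pairwise divergence is ≤ 2%, so every surviving
between-cluster mean exceeds 2% and no further merge is possible without
violating the rule. Average linkage is the direct operationalisation of a
"mean divergence over 2%" criterion; a between-cluster mean of exactly 2%
merges (the rule is strictly "over"). The per-family summary counts
species barcoded, species indistinguishable by barcodes (shared clusters),
species with ≥2 lineages and their total lineages, and reports the implied
percent increase in species diversity,
`100 × (lineages − deep species) / species`, rounded to an integer.

## BIN concordance

BINs are consumed as opaque labels, never computed. A BIN with one
specimen is a singleton; one species, concordant; several species,
discordant-merged with a conflict rank — the label of the rank *below*
the lowest rank shared by all member species (congeneric species conflict
at species rank, congeners' genera at genus rank, and so on). The
metadata schema ends at class, so cross-class merges report `class`; a
phylum-rank conflict would need cross-phylum data this container does not
hold. A species spread over ≥2 BINs is split; merged and split views are
independent and a BIN may appear in both.

## Synthetic libraries

The generator emulates the *distance structure* of a regional mollusc COI
library, not its evolutionary history. Sequences evolve by the same
two-parameter substitution process the K2P estimator assumes
(transition:transversion rate ratio κ, default 3), so estimates are
consistent with planted branch lengths up to sampling error — a property
the tests verify by Monte Carlo at 10,000 sites. Defaults: 600-site
alignment, conspecific divergence expectation 1%, congeneric 19%,
confamilial ≈ 22.5%, matching the empirical hierarchy of such libraries.

Topology is nested stars: one order root; family and genus roots below it
on short connecting branches; species ancestors at half the congeneric
target below their genus root; specimens at half the conspecific target
below their species ancestor. Keeping all genera under one shared root is
deliberate: fully independent random genus roots would place between-genus
pairs at saturation, where K2P is undefined, which no real single-class
library exhibits. Planted features: deep species insert 2–4 lineage
ancestors at half the requested divergence (>2% required), each lineage
tagged with a distinct geographic label; shared pairs literally copy one
haplotype into a congeneric species, mimicking barcode sharing regardless
of its biological cause; singletons arise via a singleton fraction or by
subsetting. A truth table records lineage membership, partners, geography
and singleton status, and generation is byte-deterministic per seed.

What the generator does **not** emulate — coalescent genealogies, rate
variation among lineages and sites, codon structure, indels, unequal
sampling biases — bounds what passing tests show: they demonstrate that
the pipeline recovers structure *of the kind it models*, not that real
libraries are this clean. Two consequences observed in testing are worth
knowing: at 600 sites the K2P estimate of a 1% expectation scatters
enough that an unplanted species occasionally splits at the strict 2%
cutoff (a borderline case, not a defect — real libraries show the same
edge behaviour), and exact distance ties across species can turn a
singleton's best-match `false` into `ambiguous`. Tests and the acceptance
script therefore assert exact recovery for planted features and
errors-per-singleton rather than noise-free behaviour everywhere.

## Problem sizes and numerical choices

Test and acceptance runs use libraries of 3–6 genera × 2–3 species × 3–5
specimens (24–64 records) and 20 seeded replicates for recovery rates —
ample for exact recovery checks at these effect sizes while keeping the
whole battery in seconds. The KDE needs ≥10 distances; the cumulative
scan requires a strictly increasing grid; NJ requires a complete matrix
(callers drop or report undefined pairs); regressions require n ≥ 3 and
non-constant x, and a constant response reports R² = 0 with a flat slope.
All randomness in the generator, bootstrap and pipeline flows from one
configured seed.
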