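"""Neighbour-joining trees, species-cluster assessment and cryptic lineages.

The tree work asks three questions of a labelled barcode library:

1. Does each species form its own exclusive cluster on the NJ tree
   (distinct), does it wrap around other species' sequences (paraphyletic),
   or is it inseparably mixed with another species (shared cluster)?
2. Which haplotypes are shared between species (exact sequence identity)?
3. Which species contain deeply divergent intraspecific lineages — clusters
   of haplotypes whose mean divergence from every other cluster exceeds 2%
   — i.e. candidate cryptic species?

NJ itself is the standard Saitou–Nei agglomeration (delegated to
scikit-bio, negative branch estimates clamped to zero); lineage splitting is
average-linkage agglomerative clustering cut at the divergence threshold,
the direct operationalisation of a "mean divergence over 2%" rule.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .data_io import BarcodeDataset
from .distances import DistanceMatrix, pairwise_matrix

logger = logging.getLogger(__name__)

#: between-cluster mean divergence above which intraspecific lineages are
#: called deep (candidate cryptic species)
DEEP_LINEAGE_CUTOFF = 0.02

STATUSES = (
    "distinct_cluster",
    "paraphyletic",
    "shared_cluster",
    "singleton_unassessable",
)


@dataclass
class ClusterAssessment:
    status_of: dict[str, str]  # species -> status
    shared_groups: list[frozenset[str]]  # mixed-clade species sets

    def counts(self) -> dict[str, int]:
        c = {s: 0 for s in STATUSES}
        for st in self.status_of.values():
            c[st] += 1
        return c


@dataclass(frozen=True)
class LineagePartition:
    species: str
    clusters: list[frozenset[str]]  # specimen-id sets
    n_lineages: int
    inter_cluster_means: dict[tuple[int, int], float]


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    representative: str  # gap/ambiguity-stripped core sequence
    specimen_ids: frozenset[str]
    species_set: frozenset[str]

    @property
    def shared(self) -> bool:
        return len(self.species_set) >= 2


def _to_skbio(matrix: DistanceMatrix) -> _SkbioDM:
    if np.isnan(matrix.values).any():
        iu = np.triu_indices(len(matrix.ids), k=1)
        bad = [
            (matrix.ids[i], matrix.ids[j])
            for i, j in zip(*iu)
            if math.isnan(matrix.values[i, j])
        ]
        raise ValueError(f"undefined distances present for pairs: {bad[:10]}")
    return _SkbioDM(matrix.values, ids=matrix.ids)


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei NJ tree; negative branch-length estimates clamped to zero.

    On an additive matrix the leaf-to-leaf path lengths reproduce the input
    distances exactly.
    """
    if len(matrix.ids) < 3:
        raise ValueError("NJ needs at least 3 leaves")
    tree = _skbio_nj(_to_skbio(matrix), neg_as_zero=True)
    return tree


def bootstrap_support(
    dataset: BarcodeDataset, n_reps: int, seed: int
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree with per-edge bootstrap support from site resampling.

    Alignment columns are resampled with replacement ``n_reps`` times from
    one seeded generator; support of an internal edge is the percentage of
    replicate trees containing its bipartition.  Deterministic for a fixed
    seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(pairwise_matrix(dataset))
    target = _bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    length = dataset.alignment_length
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = _resample_columns(dataset, cols)
        rep_tree = neighbor_joining(pairwise_matrix(resampled))
        rep_bps = _bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    _annotate_support(tree, support)
    return tree, support


def _resample_columns(dataset: BarcodeDataset, cols: np.ndarray) -> BarcodeDataset:
    from dataclasses import replace

    records = []
    for r in dataset:
        arr = np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8)
        records.append(replace(r, sequence=arr[cols].tobytes().decode("ascii")))
    return BarcodeDataset(records)


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge bipartitions, canonicalised as the smaller leaf side."""
    all_leaves = frozenset(t.name for t in tree.tips())
    bps = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            other = all_leaves - side
            bps.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return bps


def _annotate_support(tree: TreeNode, support: dict[frozenset[str], float]) -> None:
    all_leaves = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            other = all_leaves - side
            key = min(side, other, key=lambda s: (len(s), sorted(s)))
            if key in support:
                node.name = f"{support[key]:.0f}"


def assess_species_clusters(
    tree: TreeNode, labels: dict[str, str], dataset: BarcodeDataset | None = None
) -> ClusterAssessment:
    """Classify every species by how its leaves cluster on the NJ tree.

    The tree is midpoint-rooted (deterministic, label-free) and for each
    multi-specimen species the minimal clade containing all its leaves is
    enumerated.  Only conspecific leaves: ``distinct_cluster``.  Two species
    whose minimal clades contain each other are inseparably mixed:
    ``shared_cluster`` (species sharing identical haplotypes are also
    shared, matching the distinction between paraphyly without haplotype
    sharing and genuine barcode sharing).  Extra leaves without mutual
    overlap: ``paraphyletic``.  Singletons are reported separately.
    """
    for leaf in tree.tips():
        if leaf.name not in labels:
            raise ValueError(f"unlabelled leaf {leaf.name!r}")
    rooted = tree.root_at_midpoint()

    by_species: dict[str, list[str]] = {}
    for leaf_name, sp in labels.items():
        by_species.setdefault(sp, []).append(leaf_name)

    tip_of = {t.name: t for t in rooted.tips()}
    clade_leaves: dict[str, frozenset[str]] = {}
    for sp, leaf_names in by_species.items():
        if len(leaf_names) == 1:
            continue
        mrca = rooted.lca([tip_of[n] for n in leaf_names])
        clade_leaves[sp] = frozenset(t.name for t in mrca.tips())

    shared_with: dict[str, set[str]] = {sp: set() for sp in by_species}
    if dataset is not None:
        for hap in collapse_haplotypes(dataset).values():
            if hap.shared:
                for a in hap.species_set:
                    shared_with[a].update(hap.species_set - {a})

    species_of = labels
    status: dict[str, str] = {}
    for sp, leaf_names in by_species.items():
        if len(leaf_names) == 1:
            status[sp] = "singleton_unassessable"
            continue
        clade = clade_leaves[sp]
        others = {species_of[n] for n in clade} - {sp}
        if not others and not shared_with[sp]:
            status[sp] = "distinct_cluster"
            continue
        mutual = {
            o
            for o in others
            if o in clade_leaves and set(leaf_names) <= clade_leaves[o]
        }
        if mutual or shared_with[sp]:
            status[sp] = "shared_cluster"
        else:
            status[sp] = "paraphyletic"

    groups: list[frozenset[str]] = []
    seen: set[str] = set()
    for sp, st in status.items():
        if st != "shared_cluster" or sp in seen:
            continue
        group = {sp}
        frontier = [sp]
        while frontier:
            cur = frontier.pop()
            partners = shared_with[cur] | {
                o
                for o in (
                    {species_of[n] for n in clade_leaves.get(cur, frozenset())} - {cur}
                )
                if status.get(o) == "shared_cluster"
            }
            for p in partners:
                if status.get(p) == "shared_cluster" and p not in group:
                    group.add(p)
                    frontier.append(p)
        seen |= group
        groups.append(frozenset(group))
    return ClusterAssessment(status_of=status, shared_groups=groups)


def collapse_haplotypes(dataset: BarcodeDataset) -> dict[str, Haplotype]:
    """Collapse specimens to exact-identity haplotypes.

    Columns that are gaps in every record are removed first; after that,
    sequences must match exactly (ambiguity codes included) to share a
    haplotype.  Haplotypes carrying two or more species names are flagged
    shared.
    """
    seqs = [r.sequence for r in dataset]
    arr = np.array([list(s) for s in seqs])
    keep = ~(arr == "-").all(axis=0)
    core = ["".join(row) for row in arr[:, keep]]
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(core):
        groups.setdefault(s, []).append(i)
    table: dict[str, Haplotype] = {}
    recs = dataset.records
    # stable numbering by first occurrence
    for k, (seq, idxs) in enumerate(
        sorted(groups.items(), key=lambda kv: kv[1][0]), start=1
    ):
        hid = f"H{k:04d}"
        table[hid] = Haplotype(
            haplotype_id=hid,
            representative=seq,
            specimen_ids=frozenset(recs[i].specimen_id for i in idxs),
            species_set=frozenset(recs[i].species for i in idxs),
        )
    return table


def haplotype_frame(table: dict[str, Haplotype]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                h.haplotype_id,
                len(h.specimen_ids),
                ";".join(sorted(h.specimen_ids)),
                ";".join(sorted(h.species_set)),
                h.shared,
            )
            for h in table.values()
        ],
        columns=["haplotype_id", "n_specimens", "specimen_ids", "species", "shared"],
    )


def deep_lineages(
    matrix: DistanceMatrix,
    dataset: BarcodeDataset,
    species: str,
    cutoff: float = DEEP_LINEAGE_CUTOFF,
) -> LineagePartition:
    """Split a species into lineages separated by mean divergence > cutoff.

    Average-linkage agglomerative clustering of the species' specimens on
    K2P distances, cut at the cutoff: clusters keep merging while their mean
    pairwise divergence is <= cutoff, so every surviving between-cluster
    mean exceeds it and no further merge is possible without violating the
    rule.  A between-cluster mean of exactly the cutoff is merged (the rule
    is strictly "over").
    """
    idx = [i for i, r in enumerate(dataset.records) if r.species == species]
    if not idx:
        raise KeyError(f"unknown species {species!r}")
    if len(idx) < 2:
        raise ValueError(f"species {species!r} is a singleton; not assessable")
    ids = [dataset.records[i].specimen_id for i in idx]
    sub = matrix.values[np.ix_(idx, idx)]
    if np.isnan(sub).any():
        raise ValueError(
            f"species {species!r} has undefined conspecific distances"
        )
    condensed = sub[np.triu_indices(len(idx), k=1)]
    link = hierarchy.linkage(condensed, method="average")
    assignment = hierarchy.fcluster(link, t=cutoff, criterion="distance")
    clusters: dict[int, set[str]] = {}
    for sid, c in zip(ids, assignment):
        clusters.setdefault(int(c), set()).add(sid)
    ordered = [frozenset(v) for _, v in sorted(clusters.items())]
    id_pos = {sid: k for k, sid in enumerate(ids)}
    means: dict[tuple[int, int], float] = {}
    for a in range(len(ordered)):
        for b in range(a + 1, len(ordered)):
            ia = [id_pos[s] for s in ordered[a]]
            ib = [id_pos[s] for s in ordered[b]]
            means[(a, b)] = float(sub[np.ix_(ia, ib)].mean())
    return LineagePartition(
        species=species,
        clusters=ordered,
        n_lineages=len(ordered),
        inter_cluster_means=means,
    )


def candidate_species_summary(
    partitions: list[LineagePartition],
    dataset: BarcodeDataset,
    assessment: ClusterAssessment | None = None,
) -> pd.DataFrame:
    """Per-family summary of barcoded / indistinguishable / deeply divergent
    species, with a totals row and the implied percent increase in diversity.

    ``candidate_lineages`` counts all lineages of species with >= 2
    lineages; the species-diversity increase is
    ``100 * (candidate_lineages - deep_species) / species_barcoded``,
    rounded to the nearest integer.
    """
    family_of_species: dict[str, str] = {}
    for r in dataset:
        family_of_species[r.species] = r.family
    lineages_of = {p.species: p.n_lineages for p in partitions}

    fam_rows: dict[str, dict[str, int]] = {}
    for sp, fam in family_of_species.items():
        row = fam_rows.setdefault(
            fam,
            {
                "species_barcoded": 0,
                "species_indistinguishable": 0,
                "species_deep_divergence": 0,
                "candidate_lineages": 0,
            },
        )
        row["species_barcoded"] += 1
        if assessment and assessment.status_of.get(sp) == "shared_cluster":
            row["species_indistinguishable"] += 1
        nl = lineages_of.get(sp, 1)
        if nl >= 2:
            row["species_deep_divergence"] += 1
            row["candidate_lineages"] += nl
    df = (
        pd.DataFrame.from_dict(fam_rows, orient="index")
        .rename_axis("family")
        .sort_values("species_barcoded", ascending=False)
        .reset_index()
    )
    totals = df.drop(columns="family").sum()
    totals["family"] = "Total"
    df = pd.concat([df, totals.to_frame().T], ignore_index=True)
    df.attrs["percent_increase"] = percent_increase(
        int(totals["species_deep_divergence"]),
        int(totals["candidate_lineages"]),
        int(totals["species_barcoded"]),
    )
    return df


def percent_increase(
    deep_species: int, candidate_lineages: int, total_species: int
) -> int:
    """Implied percent increase in species diversity, nearest integer."""
    if total_species <= 0:
        raise ValueError("total_species must be positive")
    return round(100.0 * (candidate_lineages - deep_species) / total_species)
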