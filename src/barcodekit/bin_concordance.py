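"""Concordance of externally assigned BINs with morphology-based species.

Barcode Index Numbers (BINs) are operational taxonomic units computed by
BOLD's clustering; this module never computes them, it only classifies a
supplied specimen-to-BIN mapping against the dataset's own taxonomy:

* a BIN containing one specimen is a **singleton**;
* a BIN whose members all carry one species name is **concordant**;
* a BIN merging two or more species names is **discordant (merged)**, with
  a conflict rank — the lowest taxonomic rank shared by all member
  species' lineages (congeneric species conflict at species rank, same
  family but different genera at genus rank, and so on up to phylum);
* a species whose specimens fall into two or more BINs is **split**.

A BIN can be merged while one of its species is also split; the two views
are independent and such cases appear in both tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_io import BarcodeDataset, ValidationError

CONFLICT_RANKS = ("species(congeneric)", "genus", "family", "order", "class", "phylum")


@dataclass(frozen=True)
class BinRecord:
    bin_id: str
    specimen_ids: frozenset[str]
    species_set: frozenset[str]
    status: str  # concordant | discordant_merged | singleton
    conflict_rank: str  # one of CONFLICT_RANKS or "none"


@dataclass
class BinReport:
    bins: dict[str, BinRecord]
    species_bins: dict[str, frozenset[str]]  # species -> BIN ids
    n_unassigned_specimens: int

    def split_species(self) -> dict[str, frozenset[str]]:
        return {sp: bs for sp, bs in self.species_bins.items() if len(bs) >= 2}

    def counts(self) -> dict[str, int]:
        c = {"concordant": 0, "discordant_merged": 0, "singleton": 0}
        for b in self.bins.values():
            c[b.status] += 1
        c["n_bins"] = len(self.bins)
        c["n_split_species"] = len(self.split_species())
        return c

    def concordant_fraction(self) -> tuple[float, int]:
        """Percentage of all BINs that are concordant, with its denominator
        made explicit so the figure cannot be misread."""
        n = len(self.bins)
        if n == 0:
            raise ValueError("no BINs in report")
        conc = sum(b.status == "concordant" for b in self.bins.values())
        return 100.0 * conc / n, n


def _conflict_rank(species_set: frozenset[str], dataset: BarcodeDataset) -> str:
    """Lowest rank shared by all member species' lineages."""
    if len(species_set) < 2:
        return "none"
    lineage: dict[str, tuple[str, str, str, str]] = {}
    for r in dataset:
        lineage[r.species] = (r.genus, r.family, r.order, r.class_name)
    rows = [lineage[sp] for sp in species_set]
    if len({g for g, _, _, _ in rows}) == 1:
        return "species(congeneric)"
    if len({f for _, f, _, _ in rows}) == 1:
        return "genus"
    if len({o for _, _, o, _ in rows}) == 1:
        return "family"
    if len({c for _, _, _, c in rows}) == 1:
        return "order"
    # datasets carry no phylum column; members of different classes share
    # the (implicit) phylum, so the conflict sits at class rank.  A true
    # phylum-rank conflict (e.g. a database typo) needs cross-phylum data
    # this container cannot hold.
    return "class"


def classify_bins(
    dataset: BarcodeDataset, bin_assignments: dict[str, str]
) -> BinReport:
    """Classify a specimen-to-BIN mapping against the dataset taxonomy."""
    known = set(dataset.ids)
    unknown = sorted(set(bin_assignments) - known)
    if unknown:
        raise ValidationError(f"BIN assignments for unknown specimens: {unknown}")
    members: dict[str, set[str]] = {}
    for sid, bid in bin_assignments.items():
        members.setdefault(bid, set()).add(sid)

    species_of = dataset.species_of
    bins: dict[str, BinRecord] = {}
    species_bins: dict[str, set[str]] = {}
    for bid, sids in sorted(members.items()):
        sp_set = frozenset(species_of[s] for s in sids)
        for sp in sp_set:
            species_bins.setdefault(sp, set()).add(bid)
        if len(sids) == 1:
            status = "singleton"
        elif len(sp_set) == 1:
            status = "concordant"
        else:
            status = "discordant_merged"
        rank = _conflict_rank(sp_set, dataset) if len(sp_set) >= 2 else "none"
        bins[bid] = BinRecord(bid, frozenset(sids), sp_set, status, rank)
    n_unassigned = len(known) - len(set(bin_assignments))
    return BinReport(
        bins=bins,
        species_bins={sp: frozenset(bs) for sp, bs in species_bins.items()},
        n_unassigned_specimens=n_unassigned,
    )


def merged_bin_frame(report: BinReport) -> pd.DataFrame:
    """One row per merged BIN: the species sharing it (BIN-sharing table)."""
    rows = [
        (b.bin_id, ";".join(sorted(b.species_set)), len(b.species_set), b.conflict_rank)
        for b in report.bins.values()
        if b.status == "discordant_merged"
    ]
    return pd.DataFrame(
        rows, columns=["bin_id", "species", "n_species", "conflict_rank"]
    )


def split_species_frame(report: BinReport) -> pd.DataFrame:
    """One row per split species: the BINs its specimens fall into."""
    rows = [
        (sp, ";".join(sorted(bs)), len(bs))
        for sp, bs in sorted(report.split_species().items())
    ]
    return pd.DataFrame(rows, columns=["species", "bins", "n_bins"])
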