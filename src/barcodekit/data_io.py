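"""Reading, validating and writing aligned barcode matrices and specimen metadata.

The on-disk dialect is a plain aligned FASTA (one record per specimen, all
rows the same length, IUPAC DNA alphabet with ``-`` as the only gap
character) plus a tab-separated metadata table with the fixed header

    specimen_id  species  genus  family  order  class  country_or_site

FASTA ids and metadata ``specimen_id`` must agree as sets.  An optional
specimen-to-BIN table (two tab-separated columns) maps specimens to
externally computed Barcode Index Numbers; BINs are consumed as opaque
labels, never computed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

logger = logging.getLogger(__name__)

METADATA_COLUMNS = (
    "specimen_id",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "country_or_site",
)

#: Unambiguous bases; everything else in the IUPAC DNA alphabet (ambiguity
#: codes, N, gaps) is treated as missing at every analysis site.
UNAMBIGUOUS = frozenset("ACGT")
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")


class ValidationError(ValueError):
    """A dataset violated a structural invariant; the message names the record."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One barcode sequence with its Linnean taxonomy and locality label."""

    specimen_id: str
    species: str
    genus: str
    family: str
    order: str
    class_name: str
    country_or_site: str
    sequence: str

    def __post_init__(self) -> None:
        for fld in ("species", "genus", "family", "order", "class_name"):
            if not getattr(self, fld).strip():
                raise ValidationError(
                    f"record {self.specimen_id!r}: taxonomy field {fld!r} is empty"
                )
        bad = set(self.sequence.upper()) - IUPAC_DNA
        if bad:
            raise ValidationError(
                f"record {self.specimen_id!r}: illegal characters {sorted(bad)!r}"
            )


@dataclass
class BarcodeDataset:
    """An ordered collection of equal-length aligned specimen records."""

    records: list[SpecimenRecord]
    alignment_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("dataset contains no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValidationError(
                f"unequal sequence lengths in alignment: {sorted(lengths)}"
            )
        self.alignment_length = lengths.pop()
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate specimen ids: {dup}")
        self._check_functional_taxonomy()
        self._by_id = {r.specimen_id: r for r in self.records}

    def _check_functional_taxonomy(self) -> None:
        # child taxon name -> exactly one parent at every rank
        for child, parent in (
            ("species", "genus"),
            ("genus", "family"),
            ("family", "order"),
            ("order", "class_name"),
        ):
            mapping: dict[str, str] = {}
            for r in self.records:
                c, p = getattr(r, child), getattr(r, parent)
                if mapping.setdefault(c, p) != p:
                    raise ValidationError(
                        f"{child} {c!r} maps to two parents: "
                        f"{mapping[c]!r} and {p!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, specimen_id: str) -> SpecimenRecord:
        return self._by_id[specimen_id]

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def species_of(self) -> dict[str, str]:
        return {r.specimen_id: r.species for r in self.records}

    def species_counts(self) -> pd.Series:
        return pd.Series([r.species for r in self.records]).value_counts()

    def singleton_species(self) -> set[str]:
        counts = self.species_counts()
        return set(counts.index[counts == 1])

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.specimen_id, r.species, r.genus, r.family, r.order,
                 r.class_name, r.country_or_site)
                for r in self.records
            ],
            columns=list(METADATA_COLUMNS),
        )


@dataclass(frozen=True)
class CompositionSummary:
    """Per-species nucleotide composition plus a chi-square homogeneity test."""

    per_species_gc: pd.Series
    per_species_base_counts: pd.DataFrame  # species x [A, C, G, T]
    chi2_statistic: float
    chi2_df: int
    chi2_p: float


def read_dataset(fasta_path: str | Path, metadata_path: str | Path) -> BarcodeDataset:
    """Read an aligned FASTA and its metadata TSV into a :class:`BarcodeDataset`.

    FASTA order is preserved.  The id sets of the two files must be equal;
    any discrepancy raises :class:`ValidationError` naming the offending id.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    if list(meta.columns) != list(METADATA_COLUMNS):
        raise ValidationError(
            f"metadata header must be {list(METADATA_COLUMNS)}, got {list(meta.columns)}"
        )
    if meta["specimen_id"].duplicated().any():
        dup = sorted(meta.loc[meta["specimen_id"].duplicated(), "specimen_id"])
        raise ValidationError(f"duplicate specimen ids in metadata: {dup}")
    meta = meta.rename(columns={"class": "class_name"})
    rows = {m.specimen_id: m for m in meta.itertuples(index=False)}

    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    fasta_ids = [s.id for s in seqs]
    if len(set(fasta_ids)) != len(fasta_ids):
        dup = sorted({i for i in fasta_ids if fasta_ids.count(i) > 1})
        raise ValidationError(f"duplicate specimen ids in FASTA: {dup}")
    missing_meta = [i for i in fasta_ids if i not in rows]
    if missing_meta:
        raise ValidationError(f"FASTA ids missing from metadata: {missing_meta}")
    extra_meta = sorted(set(rows) - set(fasta_ids))
    if extra_meta:
        raise ValidationError(f"metadata rows without FASTA sequence: {extra_meta}")

    records = []
    for s in seqs:
        seq = str(s.seq).upper()
        if "." in seq:
            raise ValidationError(
                f"record {s.id!r}: '.' is not an accepted gap character"
            )
        m = rows[s.id]
        records.append(
            SpecimenRecord(
                specimen_id=s.id,
                species=m.species.strip(),
                genus=m.genus.strip(),
                family=m.family.strip(),
                order=m.order.strip(),
                class_name=m.class_name.strip(),
                country_or_site=m.country_or_site,
                sequence=seq,
            )
        )
    return BarcodeDataset(records)


def write_dataset(dataset: BarcodeDataset, fasta_path: str | Path,
                  metadata_path: str | Path) -> None:
    """Write the dataset back to the FASTA + TSV dialect ``read_dataset`` accepts."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in dataset
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    dataset.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def gc_content(sequence: str) -> float:
    """GC fraction over unambiguous, ungapped positions.

    Raises :class:`ValueError` when no unambiguous base remains.
    """
    counts = {b: 0 for b in "ACGT"}
    for ch in sequence.upper():
        if ch in counts:
            counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / total


def base_counts(sequence: str) -> dict[str, int]:
    """Counts of A, C, G, T, ignoring gaps and ambiguity codes."""
    counts = {b: 0 for b in "ACGT"}
    for ch in sequence.upper():
        if ch in counts:
            counts[ch] += 1
    return counts


def composition_summary(dataset: BarcodeDataset) -> CompositionSummary:
    """Per-species GC content and a chi-square test of nucleotide homogeneity.

    Base counts are pooled over each species' specimens; species with zero
    countable bases are excluded with a warning.  The test is the standard
    homogeneity chi-square on the species-by-base count table, no continuity
    correction, expected counts from the margins.
    """
    table: dict[str, np.ndarray] = {}
    for r in dataset:
        c = base_counts(r.sequence)
        row = np.array([c["A"], c["C"], c["G"], c["T"]], dtype=float)
        table[r.species] = table.get(r.species, np.zeros(4)) + row
    dropped = [sp for sp, row in table.items() if row.sum() == 0]
    for sp in dropped:
        warnings.warn(f"species {sp!r} has no countable bases; excluded")
        del table[sp]
    if len(table) < 2:
        raise ValueError("composition summary needs at least 2 species with data")
    counts = pd.DataFrame.from_dict(table, orient="index", columns=list("ACGT"))
    gc = (counts["G"] + counts["C"]) / counts.sum(axis=1)

    # drop all-zero base columns so the contingency test is well-posed
    nonzero = counts.loc[:, counts.sum(axis=0) > 0]
    chi2, p, df, _ = stats.chi2_contingency(nonzero.to_numpy(), correction=False)
    return CompositionSummary(
        per_species_gc=gc,
        per_species_base_counts=counts,
        chi2_statistic=float(chi2),
        chi2_df=int(df),
        chi2_p=float(p),
    )


def read_bin_assignments(path: str | Path, dataset: BarcodeDataset) -> dict[str, str]:
    """Read a two-column specimen-id / BIN TSV into a partial mapping.

    Rows whose specimen id is not in the dataset are excluded with a warning
    (their count is logged).  A specimen mapped to two different BINs is an
    error; not every specimen needs a BIN.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ValidationError(
            f"BIN table must have exactly 2 columns, got {df.shape[1]}"
        )
    df.columns = ["specimen_id", "bin_id"]
    known = set(dataset.ids)
    mapping: dict[str, str] = {}
    n_unmatched = 0
    for row in df.itertuples(index=False):
        if row.specimen_id not in known:
            n_unmatched += 1
            continue
        prev = mapping.get(row.specimen_id)
        if prev is not None and prev != row.bin_id:
            raise ValidationError(
                f"specimen {row.specimen_id!r} mapped to two BINs: "
                f"{prev!r} and {row.bin_id!r}"
            )
        mapping[row.specimen_id] = row.bin_id
    if n_unmatched:
        warnings.warn(f"{n_unmatched} BIN rows referenced unknown specimens; excluded")
    return mapping
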