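"""Shared fixtures: tiny hand-built datasets and matrix builders."""

from __future__ import annotations

import numpy as np
import pytest

from barcodekit.data_io import BarcodeDataset, SpecimenRecord
from barcodekit.distances import DistanceMatrix


def make_record(
    specimen_id: str,
    species: str,
    sequence: str,
    genus: str | None = None,
    family: str = "FamA",
    order: str = "OrdA",
    class_name: str = "ClsA",
    site: str = "",
) -> SpecimenRecord:
    return SpecimenRecord(
        specimen_id=specimen_id,
        species=species,
        genus=genus if genus is not None else species.split()[0],
        family=family,
        order=order,
        class_name=class_name,
        country_or_site=site,
        sequence=sequence,
    )


def make_dataset(rows: list[tuple]) -> BarcodeDataset:
    """rows: (specimen_id, species, sequence[, genus[, family]])."""
    records = []
    for row in rows:
        records.append(make_record(*row))
    return BarcodeDataset(records)


def make_matrix(ids: list[str], entries: dict[tuple[str, str], float]) -> DistanceMatrix:
    """Symmetric matrix from an upper-triangle dict; missing pairs are NaN."""
    n = len(ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 0.0)
    pos = {sid: i for i, sid in enumerate(ids)}
    for (a, b), d in entries.items():
        values[pos[a], pos[b]] = d
        values[pos[b], pos[a]] = d
    return DistanceMatrix(ids, values)


def dummy_dataset_for(
    labels: dict[str, str], length: int = 8
) -> BarcodeDataset:
    """Dataset whose sequences are placeholders; only ids/labels matter."""
    return BarcodeDataset(
        [make_record(sid, sp, "A" * length) for sid, sp in labels.items()]
    )


@pytest.fixture
def two_genus_dataset() -> BarcodeDataset:
    """Two genera, three species, engineered small divergences.

    Gx spA: two identical specimens; Gx spB: two specimens one transition
    apart; Gy spC: singleton far from the Gx species.
    """
    base = "ACGT" * 150
    seq_b2 = "G" + base[1:]  # one transition from base at site 0 (A->G)
    far = ("TGCA" * 150)
    return make_dataset(
        [
            ("a1", "Gx spA", base, "Gx"),
            ("a2", "Gx spA", base, "Gx"),
            ("b1", "Gx spB", _mutate(base, {10: "C", 20: "G", 30: "T", 40: "C"}), "Gx"),
            ("b2", "Gx spB", _mutate(seq_b2, {10: "C", 20: "G", 30: "T", 40: "C"}), "Gx"),
            ("c1", "Gy spC", far, "Gy", "FamB"),
        ]
    )


def _mutate(seq: str, changes: dict[int, str]) -> str:
    chars = list(seq)
    for pos, b in changes.items():
        chars[pos] = b
    return "".join(chars)
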