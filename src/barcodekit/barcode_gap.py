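"""Barcode-gap analysis: maximum intraspecific divergence vs nearest neighbour.

A species has a barcode gap when the smallest distance from any of its
specimens to a heterospecific specimen (the nearest-neighbour distance)
exceeds its maximum intraspecific divergence.  Ties count as overlaps: a
heterospecific sequence at exactly the maximum intraspecific distance
defeats identification just as a closer one does.  Singletons have no
intraspecific divergence, so their gap is not assessable, but they remain
in the pool as potential neighbours of other species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import BarcodeDataset
from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

#: nearest-neighbour distances at or below this are flagged "low NN"
LOW_NN_THRESHOLD = 0.02


@dataclass(frozen=True)
class SpeciesGapRecord:
    species: str
    n_specimens: int
    max_intra: float  # NaN for singletons / all-undefined
    nn_species: str
    nn_distance: float
    has_gap: bool | None  # None = not assessable (singleton)
    low_nn_flag: bool


def _species_indices(dataset: BarcodeDataset) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i, r in enumerate(dataset.records):
        idx.setdefault(r.species, []).append(i)
    return idx


def max_intraspecific(
    matrix: DistanceMatrix, dataset: BarcodeDataset, species: str
) -> float:
    """Maximum defined conspecific pair distance; NaN for singletons."""
    idx = _species_indices(dataset).get(species)
    if idx is None:
        raise KeyError(f"unknown species {species!r}")
    if len(idx) < 2:
        return math.nan
    sub = matrix.values[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
    defined = sub[~np.isnan(sub)]
    return float(defined.max()) if defined.size else math.nan


def nearest_neighbor(
    matrix: DistanceMatrix, dataset: BarcodeDataset, species: str
) -> tuple[str, float]:
    """Closest heterospecific species and the minimal distance to it.

    Exact distance ties between candidate neighbour species are broken by
    lexicographic species name; all tied names are logged.
    """
    by_species = _species_indices(dataset)
    if species not in by_species:
        raise KeyError(f"unknown species {species!r}")
    if len(by_species) < 2:
        raise ValueError("nearest neighbour needs at least 2 species")
    own = by_species[species]
    best: dict[str, float] = {}
    for other, idx in by_species.items():
        if other == species:
            continue
        block = matrix.values[np.ix_(own, idx)]
        defined = block[~np.isnan(block)]
        if defined.size:
            best[other] = float(defined.min())
    if not best:
        raise ValueError(
            f"all heterospecific distances from {species!r} are undefined"
        )
    nn_distance = min(best.values())
    tied = sorted(sp for sp, d in best.items() if d == nn_distance)
    if len(tied) > 1:
        logger.info("NN tie at %.6f for %r: %s", nn_distance, species, tied)
    return tied[0], nn_distance


def gap_report(
    matrix: DistanceMatrix, dataset: BarcodeDataset
) -> tuple[list[SpeciesGapRecord], dict[str, int]]:
    """Per-species gap records plus overlap / zero-NN / low-NN counts.

    Only multi-specimen species enter the overlap counting (singletons get a
    record with ``has_gap=None``).  ``n_overlap`` counts species whose
    maximum intraspecific divergence reaches or exceeds the NN distance;
    ``n_zero_nn`` counts overlapping species whose NN distance is zero
    (shared or identical barcodes); ``n_low_nn`` counts species with NN
    distance <= 2% that nevertheless keep a gap.
    """
    records = []
    n_overlap = n_zero_nn = n_low_nn = 0
    for species in sorted(_species_indices(dataset)):
        nn_sp, nn_d = nearest_neighbor(matrix, dataset, species)
        mi = max_intraspecific(matrix, dataset, species)
        n_spec = len(_species_indices(dataset)[species])
        if math.isnan(mi):
            has_gap = None
        else:
            has_gap = nn_d > mi
            if not has_gap:
                n_overlap += 1
                if nn_d == 0.0:
                    n_zero_nn += 1
        low_nn = nn_d <= LOW_NN_THRESHOLD
        if low_nn and has_gap:
            n_low_nn += 1
        records.append(
            SpeciesGapRecord(species, n_spec, mi, nn_sp, nn_d, has_gap, low_nn)
        )
    counts = {"n_overlap": n_overlap, "n_zero_nn": n_zero_nn, "n_low_nn": n_low_nn}
    return records, counts


def gap_report_frame(records: list[SpeciesGapRecord]) -> pd.DataFrame:
    """Plottable gap table; distances in percent with 2 decimals."""

    def pct(x: float) -> float:
        return round(x * 100.0, 2) if not math.isnan(x) else math.nan

    return pd.DataFrame(
        [
            (
                r.species,
                r.n_specimens,
                pct(r.max_intra),
                r.nn_species,
                pct(r.nn_distance),
                {True: "gap", False: "overlap", None: "not_assessable"}[r.has_gap],
                r.low_nn_flag,
            )
            for r in records
        ],
        columns=[
            "species",
            "n_specimens",
            "max_intra_pct",
            "nn_species",
            "nn_distance_pct",
            "gap_status",
            "low_nn_flag",
        ],
    )


def write_gap_report(records: list[SpeciesGapRecord], path: str | Path) -> None:
    gap_report_frame(records).to_csv(path, sep="\t", index=False)
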