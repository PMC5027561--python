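"""Leave-one-out sequence-based specimen identification.

Three criteria, all operating on precomputed pairwise distances with each
record in turn used as the query against all remaining references:

* **BM** (best match) — the closest reference wins regardless of distance;
  equally close references from two or more species make the query
  ambiguous.
* **BCM** (best close match) — BM restricted to references strictly below a
  distance threshold; an empty reference set leaves the query unidentified.
* **ASB** (all species barcodes) — every reference strictly below the
  threshold must agree: one species means true/false by congruence with
  the query's label, two or more mean ambiguous, none means no
  identification.

Thresholds come in three flavours: the fixed 0.01 used by BOLD's
identification engine, a cumulative-error-optimised value, and the first
local minimum of the kernel density of all pairwise distances (the
transition between intra- and interspecific divergence).

Distance ties are detected by exact float equality: distances derive from
rational transition/transversion fractions over identical site sets, so
planted ties are representable exactly and an epsilon would silently change
the outcome counts.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import BarcodeDataset
from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

CRITERIA = ("BM", "BCM", "ASB")
OUTCOMES = ("true", "false", "ambiguous", "no_id")

#: default grid for the cumulative-error threshold scan
DEFAULT_GRID = np.round(np.arange(0.001, 0.2005, 0.001), 6)


@dataclass(frozen=True)
class QueryOutcome:
    query_id: str
    criterion: str
    threshold: float | None
    outcome: str
    best_match_species: str | None
    best_match_distance: float | None


@dataclass(frozen=True)
class SimulationSummary:
    """Outcome percentages for one criterion x threshold cell, with and
    without singleton queries."""

    criterion: str
    threshold: float | None
    n_queries: int
    n_singletons: int
    pct: dict[str, float]  # over all queries
    pct_excl_singletons: dict[str, float]


@dataclass
class ThresholdScan:
    grid: np.ndarray
    false_positive: np.ndarray  # per grid point
    false_negative: np.ndarray
    cumulative: np.ndarray = field(init=False)
    optimal_interval: tuple[float, float] = field(init=False)
    selected: float = field(init=False)

    def __post_init__(self) -> None:
        self.cumulative = self.false_positive + self.false_negative
        best = self.cumulative.min()
        at_best = np.flatnonzero(self.cumulative == best)
        # first contiguous run attaining the minimum
        run_end = at_best[0]
        for k in at_best[1:]:
            if k == run_end + 1:
                run_end = k
            else:
                break
        lo, hi = float(self.grid[at_best[0]]), float(self.grid[run_end])
        self.optimal_interval = (lo, hi)
        self.selected = (lo + hi) / 2.0


def _ref_distances(
    matrix: DistanceMatrix, query_id: str
) -> tuple[np.ndarray, np.ndarray]:
    """(reference indices, distances) for one query, undefined dropped."""
    qi = matrix.index_of(query_id)
    d = matrix.values[qi].copy()
    d[qi] = np.nan
    refs = np.flatnonzero(~np.isnan(d))
    return refs, d[refs]


def best_match(
    query_id: str, matrix: DistanceMatrix, labels: dict[str, str]
) -> QueryOutcome:
    """Closest-reference identification, no distance limit."""
    refs, d = _ref_distances(matrix, query_id)
    if refs.size == 0:
        raise ValueError(f"query {query_id!r}: all reference distances undefined")
    dmin = d.min()
    tied = refs[d == dmin]
    species = {labels[matrix.ids[i]] for i in tied}
    if len(species) >= 2:
        outcome, sp = "ambiguous", None
    else:
        sp = species.pop()
        outcome = "true" if sp == labels[query_id] else "false"
    return QueryOutcome(query_id, "BM", None, outcome, sp, float(dmin))


def _close_refs(
    matrix: DistanceMatrix, query_id: str, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    refs, d = _ref_distances(matrix, query_id)
    if refs.size == 0:
        raise ValueError(f"query {query_id!r}: all reference distances undefined")
    keep = d < threshold  # strictly below
    return refs[keep], d[keep]


def best_close_match(
    query_id: str, matrix: DistanceMatrix, labels: dict[str, str], threshold: float
) -> QueryOutcome:
    """BM restricted to references strictly below the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    refs, d = _close_refs(matrix, query_id, threshold)
    if refs.size == 0:
        return QueryOutcome(query_id, "BCM", threshold, "no_id", None, None)
    dmin = d.min()
    tied = refs[d == dmin]
    species = {labels[matrix.ids[i]] for i in tied}
    if len(species) >= 2:
        outcome, sp = "ambiguous", None
    else:
        sp = species.pop()
        outcome = "true" if sp == labels[query_id] else "false"
    return QueryOutcome(query_id, "BCM", threshold, outcome, sp, float(dmin))


def all_species_barcodes(
    query_id: str, matrix: DistanceMatrix, labels: dict[str, str], threshold: float
) -> QueryOutcome:
    """Every reference below the threshold must belong to one species."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    refs, d = _close_refs(matrix, query_id, threshold)
    if refs.size == 0:
        return QueryOutcome(query_id, "ASB", threshold, "no_id", None, None)
    species = {labels[matrix.ids[i]] for i in refs}
    dmin = float(d.min())
    if len(species) >= 2:
        return QueryOutcome(query_id, "ASB", threshold, "ambiguous", None, dmin)
    sp = species.pop()
    outcome = "true" if sp == labels[query_id] else "false"
    return QueryOutcome(query_id, "ASB", threshold, outcome, sp, dmin)


def _apply(criterion: str, query_id, matrix, labels, threshold) -> QueryOutcome:
    if criterion == "BM":
        return best_match(query_id, matrix, labels)
    if criterion == "BCM":
        return best_close_match(query_id, matrix, labels, threshold)
    if criterion == "ASB":
        return all_species_barcodes(query_id, matrix, labels, threshold)
    raise ValueError(f"unknown criterion {criterion!r}")


def simulate_identification(
    dataset: BarcodeDataset,
    matrix: DistanceMatrix,
    criteria: tuple[str, ...] = CRITERIA,
    thresholds: tuple[float, ...] = (0.01,),
) -> tuple[list[SimulationSummary], pd.DataFrame]:
    """Leave-one-out simulation over every record for each criterion/threshold.

    Returns the per-cell summaries and the full per-query outcome table.
    Queries whose entire reference row is undefined are skipped with a
    warning.  BM ignores the thresholds (one BM column total).
    """
    labels = dataset.species_of
    singleton_species = dataset.singleton_species()
    cells: list[tuple[str, float | None]] = []
    for c in criteria:
        if c == "BM":
            cells.append(("BM", None))
        else:
            cells.extend((c, t) for t in thresholds)

    rows = []
    summaries = []
    for criterion, threshold in cells:
        outcomes: list[QueryOutcome] = []
        n_skipped = 0
        for qid in matrix.ids:
            try:
                outcomes.append(_apply(criterion, qid, matrix, labels, threshold))
            except ValueError:
                n_skipped += 1
        if n_skipped:
            warnings.warn(
                f"{criterion}: {n_skipped} queries skipped (undefined distances)"
            )
        n = len(outcomes)
        singleton_mask = [labels[o.query_id] in singleton_species for o in outcomes]
        n_single = sum(singleton_mask)

        def pct_of(outs: list[QueryOutcome]) -> dict[str, float]:
            m = max(len(outs), 1)
            return {
                k: 100.0 * sum(o.outcome == k for o in outs) / m for k in OUTCOMES
            }

        non_single = [o for o, s in zip(outcomes, singleton_mask) if not s]
        summaries.append(
            SimulationSummary(
                criterion, threshold, n, n_single, pct_of(outcomes), pct_of(non_single)
            )
        )
        rows.extend(
            (
                o.query_id,
                o.criterion,
                o.threshold,
                o.outcome,
                o.best_match_species,
                o.best_match_distance,
            )
            for o in outcomes
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "criterion",
            "threshold",
            "outcome",
            "best_match_species",
            "best_match_distance",
        ],
    )
    return summaries, table


def summary_frame(summaries: list[SimulationSummary]) -> pd.DataFrame:
    """Wide identification-success table: outcome rows, criterion x threshold
    columns, singleton-excluded percentages in brackets."""
    cols = {}
    for s in summaries:
        name = s.criterion if s.threshold is None else f"{s.criterion} {s.threshold:g}"
        cols[name] = [
            f"{s.pct[k]:.2f} ({s.pct_excl_singletons[k]:.2f})" for k in OUTCOMES
        ]
    return pd.DataFrame(cols, index=list(OUTCOMES))


def optimize_threshold_cumulative(
    matrix: DistanceMatrix,
    labels: dict[str, str],
    grid: np.ndarray | None = None,
) -> ThresholdScan:
    """Scan thresholds for the minimum cumulative identification failure.

    At each threshold t the false-positive error counts queries with no
    conspecific reference strictly below t although conspecific references
    exist in the data set, and the false-negative error counts queries with
    more than one species among the references below t.  The selected
    threshold is the midpoint of the first contiguous grid interval
    attaining the minimum of their sum.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")

    ids = matrix.ids
    fp = np.zeros(grid.size, dtype=int)
    fn = np.zeros(grid.size, dtype=int)
    for qid in ids:
        refs, d = _ref_distances(matrix, qid)
        if refs.size == 0:
            continue
        ref_species = np.array([labels[ids[i]] for i in refs])
        conspecific = ref_species == labels[qid]
        has_conspecific = bool(conspecific.any())
        # smallest conspecific distance: fp error for thresholds <= it
        if has_conspecific:
            dmin_con = d[conspecific].min()
            fp += grid <= dmin_con  # no conspecific strictly below t
        # number of distinct species within t as t grows
        order = np.argsort(d, kind="stable")
        d_sorted = d[order]
        sp_sorted = ref_species[order]
        seen: set[str] = set()
        second_species_at = None
        for dist, sp in zip(d_sorted, sp_sorted):
            if sp not in seen:
                seen.add(sp)
                if len(seen) == 2:
                    second_species_at = dist
                    break
        if second_species_at is not None:
            fn += grid > second_species_at
    return ThresholdScan(grid, fp, fn)


def density_local_minima(
    distances: np.ndarray, n_grid: int = 512
) -> tuple[list[float], float | None]:
    """Local minima of the Gaussian KDE of all defined pairwise distances.

    Silverman's rule-of-thumb bandwidth, density evaluated on a fixed
    ``n_grid``-point grid over [0, max].  Returns all interior strict local
    minima in ascending order plus the first one — the designated transition
    between intra- and interspecific divergence — or None when the density
    is monotone/unimodal.
    """
    values = np.asarray(distances, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 10:
        raise ValueError("need at least 10 defined distances for the KDE")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    xs = np.linspace(0.0, float(values.max()), n_grid)
    dens = kde(xs)
    interior = np.flatnonzero(
        (dens[1:-1] < dens[:-2]) & (dens[1:-1] < dens[2:])
    ) + 1
    minima = [float(xs[i]) for i in interior]
    if not minima:
        warnings.warn("density has no interior local minimum")
        return [], None
    return minima, minima[0]
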