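"""Kimura two-parameter distances and taxonomic-level distance summaries.

The K2P distance corrects raw divergence separately for transitions (P) and
transversions (Q):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

P and Q are fractions over the sites compared after pairwise deletion: any
position where either sequence carries a gap, an N or an IUPAC ambiguity
code is excluded for that pair only.  When the logarithm's argument is
non-positive (saturation) or no sites overlap, the distance is undefined and
stored as NaN; undefined entries are excluded from every summary, with their
count reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import BarcodeDataset

# encoding: A=0, C=1, G=2, T=3, everything else (gap/N/ambiguity) = -1
_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i

_PURINE = np.array([True, False, True, False])  # A, G

LEVELS = (
    "within_species",
    "within_genus_between_species",
    "within_family_between_genera",
    "within_order_between_families",
    "within_class_between_orders",
)


@dataclass(frozen=True)
class K2PComponents:
    """Transition fraction P, transversion fraction Q and compared-site count."""

    p_transitions: float
    q_transversions: float
    n_sites: int


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with NaN marking undefined entries."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._index[id_a], self._index[id_b]])

    def row(self, specimen_id: str) -> np.ndarray:
        return self.values[self._index[specimen_id]]

    def index_of(self, specimen_id: str) -> int:
        return self._index[specimen_id]

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP-style matrix; 'NA' literal for undefined entries."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                cells = [
                    "NA" if math.isnan(v) else f"{v:.8f}" for v in self.values[i]
                ]
                fh.write(sid + "\t" + "\t".join(cells) + "\n")

    def write_lower_triangular(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, sid in enumerate(self.ids):
                cells = [
                    "NA" if math.isnan(v) else f"{v:.8f}"
                    for v in self.values[i, :i]
                ]
                fh.write("\t".join([sid] + cells).rstrip("\t") + "\n")


@dataclass(frozen=True)
class LevelSummary:
    """Distance statistics (in percent) for one taxonomic comparison level."""

    level: str
    n_pairs: int
    min_pct: float
    mean_pct: float
    max_pct: float
    se_pct: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def encode_sequence(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def k2p_components(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> K2PComponents:
    """P, Q and n over the pairwise-deleted site set of two aligned sequences."""
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else seq_b
    if a.shape != b.shape:
        raise ValueError(
            f"aligned sequences differ in length: {a.size} vs {b.size}"
        )
    mask = (a >= 0) & (b >= 0)
    n = int(mask.sum())
    if n == 0:
        return K2PComponents(0.0, 0.0, 0)
    aa, bb = a[mask], b[mask]
    diff = aa != bb
    ts = diff & (_PURINE[aa] == _PURINE[bb])  # purine<->purine or pyr<->pyr
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return K2PComponents(n_ts / n, n_tv / n, n)


def k2p_from_components(comp: K2PComponents) -> float:
    """Kimura's closed form; NaN when saturated or no sites compared."""
    if comp.n_sites == 0:
        return math.nan
    p, q = comp.p_transitions, comp.q_transversions
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    # the log argument never exceeds 1, so the distance is >= 0; max()
    # only normalises the -0.0 of identical sequences
    return max(0.0, -0.5 * math.log(w1 * math.sqrt(w2)))


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, K2PComponents]:
    """K2P distance between two aligned sequences (NaN when undefined)."""
    comp = k2p_components(seq_a, seq_b)
    return k2p_from_components(comp), comp


def pairwise_matrix(dataset: BarcodeDataset) -> DistanceMatrix:
    """K2P distances for all unordered specimen pairs, pairwise deletion."""
    if len(dataset) < 2:
        raise ValueError("pairwise matrix needs at least 2 records")
    encoded = [encode_sequence(r.sequence) for r in dataset]
    n = len(encoded)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = k2p_from_components(k2p_components(encoded[i], encoded[j]))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(dataset.ids, d)


def pair_level(rec_a, rec_b) -> str | None:
    """Comparison level of a specimen pair: the lowest shared taxonomic rank.

    Returns None for pairs sharing no rank up to class (possible only in
    multi-class datasets); such pairs are excluded from the level summary
    with a reported count.
    """
    if rec_a.species == rec_b.species:
        return "within_species"
    if rec_a.genus == rec_b.genus:
        return "within_genus_between_species"
    if rec_a.family == rec_b.family:
        return "within_family_between_genera"
    if rec_a.order == rec_b.order:
        return "within_order_between_families"
    if rec_a.class_name == rec_b.class_name:
        return "within_class_between_orders"
    return None


def summarize_by_level(
    matrix: DistanceMatrix, dataset: BarcodeDataset
) -> tuple[list[LevelSummary], dict[str, int]]:
    """Hierarchical distance summary in percent, one row per comparison level.

    Each defined pair contributes to exactly one level.  Undefined distances
    and between-class pairs are excluded; their counts come back in the
    second return value.  The SE is the standard error of the mean over pair
    distances, pairs treated as independent.
    """
    per_level: dict[str, list[float]] = {lv: [] for lv in LEVELS}
    n_undefined = 0
    n_between_class = 0
    recs = dataset.records
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            d = matrix.values[i, j]
            if math.isnan(d):
                n_undefined += 1
                continue
            lv = pair_level(recs[i], recs[j])
            if lv is None:
                n_between_class += 1
                continue
            per_level[lv].append(d)
    summaries = []
    for lv in LEVELS:
        vals = np.array(per_level[lv]) * 100.0
        if vals.size == 0:
            summaries.append(
                LevelSummary(lv, 0, math.nan, math.nan, math.nan, math.nan)
            )
            continue
        se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
        summaries.append(
            LevelSummary(
                lv,
                int(vals.size),
                float(vals.min()),
                float(vals.mean()),
                float(vals.max()),
                se,
            )
        )
    counts = {"n_undefined": n_undefined, "n_between_class": n_between_class}
    return summaries, counts


def level_summary_frame(summaries: list[LevelSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.level, s.n_pairs, s.min_pct, s.mean_pct, s.max_pct, s.se_pct)
            for s in summaries
        ],
        columns=["level", "n_pairs", "min_pct", "mean_pct", "max_pct", "se_pct"],
    )


def congeneric_conspecific_ratio(
    mean_congeneric_pct: float, mean_conspecific_pct: float
) -> float:
    """How many times more variable congeners are than conspecifics (2 dp)."""
    if mean_conspecific_pct == 0:
        raise ValueError("conspecific mean is zero; ratio undefined")
    return round(mean_congeneric_pct / mean_conspecific_pct, 2)


def ols_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with R² and a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    with np.errstate(invalid="ignore"):
        res = stats.linregress(x, y)
    # constant y: zero slope explains nothing; scipy leaves r undefined
    r2 = 0.0 if math.isnan(res.rvalue) else float(res.rvalue**2)
    p = 1.0 if math.isnan(res.pvalue) else float(res.pvalue)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=p,
        n=int(x.size),
    )
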