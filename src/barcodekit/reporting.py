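"""Report-level arithmetic and the packaged reference family summary.

Distances travel through the pipeline as proportions and become percent
only here; percentages render with 2 decimals, counts as plain integers in
anything machine-parsable.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: published per-family summary of the northwestern Pacific mollusc COI
#: library (species barcoded, species indistinguishable by barcodes,
#: species with deep (>2%) intraspecific divergence, candidate lineages)
FAMILY_SUMMARY_RESOURCE = "nwpac_mollusc_family_summary.tsv"


def percentage(count: int | float, total: int | float, decimals: int = 2) -> float:
    """100 * count / total, rounded; the workhorse behind every printed rate."""
    if total == 0:
        raise ValueError("zero denominator")
    return round(100.0 * count / total, decimals)


def mean_specimens_per_species(
    n_specimens: int, n_species: int, decimals: int = 1
) -> float:
    if n_species == 0:
        raise ValueError("zero species")
    return round(n_specimens / n_species, decimals)


def load_family_summary() -> pd.DataFrame:
    """The packaged reference family table (no totals row)."""
    with resources.files("barcodekit.data").joinpath(
        FAMILY_SUMMARY_RESOURCE
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def family_summary_totals(df: pd.DataFrame) -> dict[str, int]:
    """Column sums of a family summary table (the totals row of the report)."""
    cols = (
        "species_barcoded",
        "species_indistinguishable",
        "species_deep_divergence",
        "candidate_lineages",
    )
    return {c: int(df[c].sum()) for c in cols}
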