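"""Seeded generator of aligned COI-like barcode datasets with known truth.

The generator emulates the distance structure of a regional mollusc COI
library rather than its evolutionary history: star phylogenies within
genera and within species give direct control over the expected K2P
distances, and sequences evolve under the same two-parameter
transition/transversion process the K2P estimator assumes, so estimates
are consistent with the planted targets up to sampling error.

Planted features, all recorded in a machine-readable truth table:

* variable per-species sample sizes including singletons;
* low conspecific divergence (default expectation 1%) against high
  congeneric divergence (default 19%);
* species pairs sharing a literal haplotype copy (mimicking barcode
  sharing whatever its biological cause);
* species split into deeply divergent intraspecific lineages (>2%, default
  8%) carrying distinct geographic labels.

Everything is deterministic for a fixed config: same seed, byte-identical
FASTA and TSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import BarcodeDataset, SpecimenRecord

#: root base composition, COI-like (AT-rich)
ROOT_FREQS = {"A": 0.23, "C": 0.17, "G": 0.21, "T": 0.39}

_BASES = np.array(list("ACGT"))
#: transition partner of A, C, G, T
_TS_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}


@dataclass
class SynthConfig:
    """Parameters of the synthetic library; defaults mirror the empirical
    structure of a regional mollusc COI survey (intraspecific mean ~1%,
    congeneric mean ~19%, deep-lineage cutoff 2%)."""

    seed: int = 0
    alignment_length: int = 600
    n_genera: int = 6
    species_per_genus: int = 3
    specimens_per_species: int = 5
    singleton_fraction: float = 0.0
    kappa: float = 3.0  # transition/transversion rate ratio
    target_intra: float = 0.01
    target_inter_congeneric: float = 0.19
    target_confamilial: float = 0.225  # between genera, same family
    n_families: int = 2
    planted_shared_pairs: int = 0
    planted_deep_species: list[tuple[int, float]] = field(default_factory=list)
    geography_labels: tuple[str, ...] = ("China", "Japan", "Korea")

    def __post_init__(self) -> None:
        if not self.target_intra < self.target_inter_congeneric:
            raise ValueError("target_intra must be below target_inter_congeneric")
        if not self.target_inter_congeneric <= self.target_confamilial:
            raise ValueError(
                "target_inter_congeneric must not exceed target_confamilial"
            )
        if self.n_families < 1:
            raise ValueError("need at least one family")
        for n_lin, div in self.planted_deep_species:
            if n_lin < 2:
                raise ValueError("planted deep species need >= 2 lineages")
            if div <= 0.02:
                raise ValueError("planted lineage divergence must exceed 0.02")
        if self.planted_shared_pairs and self.species_per_genus < 2:
            raise ValueError("shared pairs need >= 2 species per genus")


@dataclass
class TruthTable:
    """Ground truth for every planted feature, keyed by species name."""

    n_lineages: dict[str, int]
    lineage_of: dict[str, str]  # specimen_id -> lineage label
    shared_partner: dict[str, str]  # species -> partner species
    singleton: dict[str, bool]
    geography: dict[str, str]  # specimen_id -> label

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_lineages": self.n_lineages,
                    "lineage_of": self.lineage_of,
                    "shared_partner": self.shared_partner,
                    "singleton": self.singleton,
                    "geography": self.geography,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sid, lin, self.geography.get(sid, ""))
            for sid, lin in sorted(self.lineage_of.items())
        ]
        return pd.DataFrame(rows, columns=["specimen_id", "lineage", "geography"])


def _substitution_probs(branch_length: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) after expected ``branch_length``
    substitutions per site under the two-parameter process."""
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    # per-unit-time rates normalised to one expected substitution
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    t = branch_length
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_ts, p_tv_each


def evolve_sequence(
    ancestor: str, branch_length: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve a sequence for ``branch_length`` expected substitutions/site.

    Per-site draws from the exact two-parameter transition probabilities, so
    the K2P distance estimated between ancestor and descendant is
    (asymptotically) the branch length.
    """
    p_ts, p_tv = _substitution_probs(branch_length, kappa)
    codes = np.frombuffer(ancestor.encode("ascii"), dtype=np.uint8)
    idx = np.zeros(codes.size, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        idx[codes == ord(b)] = i
    u = rng.random(codes.size)
    out = idx.copy()
    # event layout per site: [0,p_ts) transition, then two transversions
    ts_mask = u < p_ts
    tv1_mask = (u >= p_ts) & (u < p_ts + p_tv)
    tv2_mask = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    for i in range(4):
        here = idx == i
        out[here & ts_mask] = _TS_PARTNER[i]
        # the two pyrimidines are the transversion targets of purines & v.v.
        tv_targets = [j for j in range(4) if j != i and j != _TS_PARTNER[i]]
        out[here & tv1_mask] = tv_targets[0]
        out[here & tv2_mask] = tv_targets[1]
    return "".join(_BASES[out])


def _random_root(length: int, rng: np.random.Generator) -> str:
    bases = list(ROOT_FREQS)
    probs = np.array([ROOT_FREQS[b] for b in bases])
    return "".join(rng.choice(bases, size=length, p=probs))


def generate_dataset(config: SynthConfig) -> tuple[BarcodeDataset, TruthTable]:
    """Generate the aligned library and its truth table.

    Topology: a single order root; family roots, genus roots, species
    ancestors and specimens hang below it in nested stars with branch
    depths chosen so that the expected pairwise distances hit the targets
    (conspecific ``target_intra``, congeneric about
    ``target_inter_congeneric``, confamilial about ``target_confamilial``).
    Keeping every genus under one shared root keeps even between-family
    distances far from K2P saturation.  Deep species insert lineage
    ancestors at depth ``divergence / 2`` between species ancestor and
    specimens; shared pairs overwrite one specimen of the second species
    with a literal haplotype copy from the first.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SpecimenRecord] = []
    truth = TruthTable({}, {}, {}, {}, {})

    deep_plan = list(config.planted_deep_species)
    shared_remaining = config.planted_shared_pairs
    geo = config.geography_labels

    t_genus_below_family = max(
        0.0, (config.target_confamilial - config.target_inter_congeneric) / 2.0
    )
    t_family_below_order = 0.015

    order_root = _random_root(config.alignment_length, rng)
    n_families = min(config.n_families, config.n_genera)
    family_roots = [
        evolve_sequence(order_root, t_family_below_order, config.kappa, rng)
        for _ in range(n_families)
    ]

    species_counter = 0
    for g in range(config.n_genera):
        genus = f"Genus{g + 1:02d}"
        family_idx = g % n_families
        genus_root = evolve_sequence(
            family_roots[family_idx], t_genus_below_family, config.kappa, rng
        )
        prev_species_first_seq: str | None = None
        prev_species_name: str | None = None
        for s in range(config.species_per_genus):
            species_counter += 1
            species = f"{genus} species{s + 1:02d}"
            ancestor = evolve_sequence(
                genus_root, config.target_inter_congeneric / 2.0, config.kappa, rng
            )
            n_spec = config.specimens_per_species
            if config.singleton_fraction > 0 and rng.random() < config.singleton_fraction:
                n_spec = 1
            deep = deep_plan.pop(0) if deep_plan and s == 0 else None

            if deep is not None and n_spec < deep[0]:
                n_spec = deep[0] * 2  # enough specimens to populate lineages
            lineage_ancestors: list[tuple[str, str, str]] = []
            if deep is not None:
                n_lin, div = deep
                for k in range(n_lin):
                    lin_anc = evolve_sequence(ancestor, div / 2.0, config.kappa, rng)
                    lineage_ancestors.append(
                        (f"L{k + 1}", lin_anc, geo[k % len(geo)])
                    )
            else:
                lineage_ancestors.append(("L1", ancestor, geo[0]))

            truth.n_lineages[species] = len(lineage_ancestors)
            truth.singleton[species] = n_spec == 1
            for m in range(n_spec):
                lin_label, lin_anc, place = lineage_ancestors[
                    m % len(lineage_ancestors)
                ]
                sid = f"SP{species_counter:03d}-{m + 1:02d}"
                seq = evolve_sequence(
                    lin_anc, config.target_intra / 2.0, config.kappa, rng
                )
                records.append(
                    SpecimenRecord(
                        specimen_id=sid,
                        species=species,
                        genus=genus,
                        family=f"Family{family_idx + 1:02d}",
                        order="Order01",
                        class_name="Class01",
                        country_or_site=place,
                        sequence=seq,
                    )
                )
                truth.lineage_of[sid] = f"{species}/{lin_label}"
                truth.geography[sid] = place

            # plant haplotype sharing with the previous congener
            if (
                shared_remaining > 0
                and prev_species_first_seq is not None
                and n_spec >= 2
            ):
                donor = prev_species_first_seq
                last = records[-1]
                records[-1] = SpecimenRecord(
                    specimen_id=last.specimen_id,
                    species=last.species,
                    genus=last.genus,
                    family=last.family,
                    order=last.order,
                    class_name=last.class_name,
                    country_or_site=last.country_or_site,
                    sequence=donor,
                )
                truth.shared_partner[species] = prev_species_name
                truth.shared_partner[prev_species_name] = species
                shared_remaining -= 1
            prev_species_first_seq = records[-n_spec].sequence
            prev_species_name = species

    if shared_remaining > 0:
        raise ValueError(
            "could not plant all requested shared pairs; "
            "increase species_per_genus or specimens_per_species"
        )
    if deep_plan:
        raise ValueError(
            "could not plant all requested deep species; increase n_genera"
        )
    return BarcodeDataset(records), truth
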