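"""Non-indigenous species (NIS) detection and dataset curation.

MOTUs are matched against a curated reference database of invasive
species; a MOTU is labelled NIS when at least one hit reaches 97%
identity and 70% query coverage (both inclusive).  The nominal species
is taken from the best hit (highest identity, ties broken by coverage
then species name, so the assignment is independent of hit order).

The native (NAT) dataset is the species-level-assigned, non-NIS subset
of the community, minus an explicit exclusion list of problematic
entries (species complexes, dubious matches, cryptogenic species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .tables_io import HitTable, MOTUTable


@dataclass
class NISThresholds:
    min_identity: float = 97.0  # percent, inclusive
    min_coverage: float = 70.0  # percent, inclusive


def assign_nis(
    hits: HitTable, cfg: NISThresholds | None = None
) -> tuple[set[str], pd.Series]:
    """Return (NIS MOTU ids, per-MOTU nominal species from the best hit)."""
    cfg = cfg or NISThresholds()
    df = hits.data
    ok = df[
        (df["identity"] >= cfg.min_identity)
        & (df["coverage"] >= cfg.min_coverage)
    ]
    # deterministic best hit: identity desc, coverage desc, species name asc
    ranked = ok.sort_values(
        ["identity", "coverage", "subject_species"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("motu_id", keep="first")
    species = best.set_index("motu_id")["subject_species"]
    return set(species.index), species


ASSIGNMENT_CLASSES = (
    "coincident",
    "higher_rank_only",
    "different_species",
    "same_species_low_identity",
)


def compare_assignments(
    nis_species: pd.Series,
    general_species: pd.Series,
    general_identity: pd.Series | None = None,
    low_identity_cutoff: float = 97.0,
) -> pd.DataFrame:
    """Compare reference-database NIS assignments with a general-database
    taxonomic assignment for the same MOTUs.

    ``general_species`` holds the general assignment's species name per
    MOTU (empty string when the assignment stopped at genus or higher).
    Each NIS MOTU is classed as coincident, higher-rank-only,
    different-species, or same-species-low-identity (species agrees but
    the general assignment's identity is below the cutoff).
    """
    rows = []
    for motu_id, sp in nis_species.items():
        gen = general_species.get(motu_id, "")
        gen = "" if pd.isna(gen) else str(gen)
        if gen == "":
            cls = "higher_rank_only"
        elif gen == sp:
            ident = (
                None
                if general_identity is None
                else general_identity.get(motu_id)
            )
            if ident is not None and ident < low_identity_cutoff:
                cls = "same_species_low_identity"
            else:
                cls = "coincident"
        else:
            cls = "different_species"
        rows.append({"motu_id": motu_id, "nis_species": sp, "general_species": gen, "class": cls})
    return pd.DataFrame(rows)


def curate_nat(
    motus: MOTUTable,
    exclusion: set[str] | None = None,
    nis_ids: set[str] | None = None,
) -> set[str]:
    """Native MOTU set: species-level assigned, non-NIS, minus exclusions.

    Exclusion entries may be MOTU ids or binomial species names; an
    entry matching nothing raises a warning, not an error.
    """
    exclusion = set(exclusion or ())
    nis_ids = set(nis_ids or motus.ids_with_label("NIS"))
    species_level = motus.taxonomy["species"].fillna("") != ""
    candidates = set(motus.reads.index[species_level]) - nis_ids
    matched = set()
    nat = set()
    for motu_id in candidates:
        sp = motus.taxonomy.at[motu_id, "species"]
        if motu_id in exclusion or sp in exclusion:
            matched.update({motu_id, sp} & exclusion)
            continue
        nat.add(motu_id)
    unmatched = exclusion - matched
    # exclusion entries may also target non-candidate MOTUs; count those
    all_ids = set(motus.motu_ids)
    all_species = set(motus.taxonomy["species"])
    unmatched -= all_ids | all_species
    if unmatched:
        warnings.warn(
            f"exclusion entries matched nothing: {sorted(unmatched)}",
            stacklevel=2,
        )
    return nat


def pool_nominal_species(
    motus: MOTUTable, scope: str | None = None
) -> pd.DataFrame:
    """Sum reads of MOTUs sharing a nominal species (species x sample).

    ``scope`` restricts pooling to one dataset label (e.g. "NIS").
    MOTUs without a nominal species fall back to the species rank of
    their taxonomy, and failing that to their own id (identity pooling).
    """
    if scope is not None:
        motus = motus.subset_motus(motus.ids_with_label(scope))
    names = motus.nominal_species.copy()
    empty = names == ""
    names[empty] = motus.taxonomy.loc[empty, "species"]
    still = names == ""
    names[still] = pd.Series(motus.reads.index, index=motus.reads.index)[still]
    return motus.reads.groupby(names).sum()
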