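"""Post-denoising curation cascade for ESV/MOTU tables.

Four filters are applied, in order, to the denoised ESV table:

1. **Blank filter** — an ESV whose summed reads in blanks and PCR
   negatives exceed 10% of its summed reads in true samples is treated
   as a contaminant and deleted.  Control columns are dropped from all
   downstream analysis immediately afterwards.
2. **Dual abundance filter** — per sample, (i) ESV cells below 0.005%
   of the sample's total reads are zeroed, then (ii) cells below 5
   reads (evaluated on post-step-(i) values) are zeroed.  ESVs left
   with all-zero rows are dropped.
3. **Pseudogene filter** — an ESV is deleted if its translation carries
   a stop codon under *every* configured metazoan mitochondrial genetic
   code (an ESV plausibly functional under at least one code is kept),
   or if a configured conserved amino-acid position deviates from its
   allowed residues in the best stop-free translation.  NUMT-derived
   sequences typically fail this check.
4. **Sample depth filter** — true samples left with fewer than 9,500
   reads are discarded entirely.

All comparisons are strict inequalities, matching the "more than" /
"less than" phrasing of the rules.  Filters never increase any read
count, and every stage emits a removal log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .tables_io import (
    ESVTable,
    MOTUTable,
    SampleFrame,
    TableError,
    motu_table_from_esvs,
)

#: NCBI translation tables used by metazoan mitochondria.
METAZOAN_MITO_CODES = (2, 4, 5, 9, 13, 14, 21, 24, 33)

IUPAC_DNA = set("ACGTRYSWKMBDHVN")


@dataclass
class FilterConfig:
    """Thresholds and genetic-code settings for the curation cascade."""

    blank_fraction_threshold: float = 0.10
    rel_abundance_threshold: float = 0.00005  # 0.005% of sample reads
    min_reads_per_esv_sample: int = 5
    min_sample_depth: int = 9_500
    genetic_codes: tuple[int, ...] = METAZOAN_MITO_CODES
    #: (1-based amino-acid position within the translated fragment,
    #: string of allowed residues); empty = check disabled.
    conserved_positions: tuple[tuple[int, str], ...] = ()
    reading_frame: int = 2  # 0-based offset into the fragment
    #: If True, the blank-rule denominator is reads in true samples only
    #: (controls excluded); if False, reads in all samples.
    blank_denominator_true_samples_only: bool = True

    def __post_init__(self) -> None:
        if self.reading_frame not in (0, 1, 2):
            raise ValueError("reading_frame must be 0, 1 or 2")
        for name in (
            "blank_fraction_threshold",
            "rel_abundance_threshold",
            "min_reads_per_esv_sample",
            "min_sample_depth",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _log_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["esv_id", "stage", "reason", "reads_removed"]
    )


@dataclass
class FilterResult:
    esvs: ESVTable
    log: pd.DataFrame
    samples: SampleFrame | None = None
    motus: MOTUTable | None = None


# ---------------------------------------------------------------------------
# 1. blank filter


def blank_filter(
    esvs: ESVTable, samples: SampleFrame, cfg: FilterConfig | None = None
) -> FilterResult:
    """Remove contaminant ESVs using blank / PCR-negative read shares.

    Deletes any ESV whose summed reads in control samples are *more
    than* ``blank_fraction_threshold`` times its summed reads in true
    samples.  Control columns are excluded from the returned table; an
    ESV observed only in controls (true-sample total 0) is deleted.
    """
    cfg = cfg or FilterConfig()
    controls = [c for c in samples.control_ids if c in esvs.sample_ids]
    true_cols = [c for c in samples.true_sample_ids if c in esvs.sample_ids]
    if not controls:
        import warnings

        warnings.warn(
            "no blank or PCR-negative samples present; blank filter is a no-op",
            stacklevel=2,
        )
        return FilterResult(esvs.subset_samples(true_cols), _log_frame([]))

    in_controls = esvs.reads[controls].sum(axis=1)
    if cfg.blank_denominator_true_samples_only:
        denom = esvs.reads[true_cols].sum(axis=1)
    else:
        denom = esvs.reads[true_cols + controls].sum(axis=1)
    # strict "more than"; ESVs seen only in controls are contaminants
    contaminated = in_controls > cfg.blank_fraction_threshold * denom
    rows = [
        {
            "esv_id": e,
            "stage": "blank_filter",
            "reason": (
                f"control reads {int(in_controls[e])} > "
                f"{cfg.blank_fraction_threshold:.0%} of {int(denom[e])}"
            ),
            "reads_removed": int(esvs.reads.loc[e].sum()),
        }
        for e in esvs.reads.index[contaminated]
    ]
    kept = esvs.subset_esvs(esvs.reads.index[~contaminated])
    return FilterResult(kept.subset_samples(true_cols), _log_frame(rows))


# ---------------------------------------------------------------------------
# 2. dual abundance filter


def dual_abundance_filter(
    esvs: ESVTable, cfg: FilterConfig | None = None
) -> FilterResult:
    """Per-sample relative-abundance then minimum-count filter.

    Step (i) zeroes cells *below* ``rel_abundance_threshold`` of the
    sample total; step (ii) zeroes cells *below*
    ``min_reads_per_esv_sample``, evaluated on post-(i) values.  The
    order matters and is enforced here.
    """
    cfg = cfg or FilterConfig()
    reads = esvs.reads.to_numpy(dtype=np.int64, copy=True)
    totals = reads.sum(axis=0)  # per-sample totals before filtering
    cutoff = cfg.rel_abundance_threshold * totals  # per sample
    step1 = reads.copy()
    step1[reads < cutoff[None, :]] = 0
    step2 = step1.copy()
    step2[step1 < cfg.min_reads_per_esv_sample] = 0
    out = pd.DataFrame(step2, index=esvs.reads.index, columns=esvs.reads.columns)
    removed = esvs.reads.sum(axis=1) - out.sum(axis=1)
    dropped = out.sum(axis=1) == 0
    rows = [
        {
            "esv_id": e,
            "stage": "dual_abundance_filter",
            "reason": "all cells below abundance thresholds"
            if dropped[e]
            else "cells below abundance thresholds zeroed",
            "reads_removed": int(removed[e]),
        }
        for e in esvs.reads.index[removed > 0]
    ]
    kept = ESVTable(
        out.loc[~dropped],
        esvs.motu_ids.loc[~dropped],
        None if esvs.sequences is None else esvs.sequences.loc[~dropped],
    )
    return FilterResult(kept, _log_frame(rows))


# ---------------------------------------------------------------------------
# 3. pseudogene filter


def _translate(seq: str, frame: int, table: int) -> str:
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate(table=table))


def translation_has_stop(seq: str, frame: int, table: int) -> bool:
    return "*" in _translate(seq, frame, table)


def is_putative_pseudogene(
    seq: str,
    cfg: FilterConfig | None = None,
    esv_id: str = "?",
) -> tuple[bool, str]:
    """Classify one sequence; returns (is_pseudogene, reason)."""
    cfg = cfg or FilterConfig()
    if not seq:
        raise TableError(f"ESV {esv_id}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise TableError(
            f"ESV {esv_id}: non-IUPAC characters {sorted(bad)}"
        )
    stop_free = [
        t
        for t in cfg.genetic_codes
        if not translation_has_stop(seq, cfg.reading_frame, t)
    ]
    if not stop_free:
        return True, "stop codon under every configured genetic code"
    if cfg.conserved_positions:
        # check the conserved residues on the best (stop-free) translation;
        # accept the sequence if any stop-free code satisfies all positions
        for t in stop_free:
            aa = _translate(seq, cfg.reading_frame, t)
            ok = all(
                pos <= len(aa) and aa[pos - 1] in allowed
                for pos, allowed in cfg.conserved_positions
            )
            if ok:
                return False, ""
        return True, "conserved amino-acid position violated"
    return False, ""


def pseudogene_filter(
    esvs: ESVTable,
    cfg: FilterConfig | None = None,
    motus: MOTUTable | None = None,
) -> FilterResult:
    """Delete putative pseudogene (e.g. NUMT) ESVs by translation checks.

    If a MOTU table is given, MOTUs whose ESVs are all deleted are
    removed from it as well and the rebuilt table is returned.
    """
    cfg = cfg or FilterConfig()
    if esvs.sequences is None:
        raise TableError("pseudogene filter requires sequences")
    rows = []
    bad_ids = []
    for esv_id, seq in esvs.sequences.items():
        is_pg, reason = is_putative_pseudogene(seq, cfg, esv_id)
        if is_pg:
            bad_ids.append(esv_id)
            rows.append(
                {
                    "esv_id": esv_id,
                    "stage": "pseudogene_filter",
                    "reason": reason,
                    "reads_removed": int(esvs.reads.loc[esv_id].sum()),
                }
            )
    kept = esvs.subset_esvs([e for e in esvs.esv_ids if e not in set(bad_ids)])
    new_motus = None
    if motus is not None:
        new_motus = motu_table_from_esvs(kept, motus)
    return FilterResult(kept, _log_frame(rows), motus=new_motus)


# ---------------------------------------------------------------------------
# 4. sample depth filter


def sample_depth_filter(
    esvs: ESVTable, samples: SampleFrame, cfg: FilterConfig | None = None
) -> FilterResult:
    """Discard true samples with total reads below the depth threshold."""
    cfg = cfg or FilterConfig()
    cols = [c for c in esvs.sample_ids]
    depths = esvs.reads[cols].sum(axis=0)
    keep = [c for c in cols if depths[c] >= cfg.min_sample_depth]
    if not keep:
        raise TableError("sample depth filter removed every sample")
    dropped = [c for c in cols if c not in set(keep)]
    rows = [
        {
            "esv_id": "",
            "stage": "sample_depth_filter",
            "reason": f"sample {c} below {cfg.min_sample_depth} reads",
            "reads_removed": int(depths[c]),
        }
        for c in dropped
    ]
    kept = esvs.subset_samples(keep).drop_empty()
    return FilterResult(
        kept, _log_frame(rows), samples=samples.subset(keep)
    )


# ---------------------------------------------------------------------------
# taxonomy restriction


def restrict_to_marine_metazoa(
    motus: MOTUTable,
    esvs: ESVTable | None = None,
    keep: Callable[[pd.Series], bool] | None = None,
    metazoan_phyla: Sequence[str] | None = None,
) -> tuple[MOTUTable, ESVTable | None]:
    """Drop MOTUs (and their ESVs) whose taxonomy fails a predicate.

    By default a MOTU is kept when its phylum is in ``metazoan_phyla``
    (or when a custom ``keep`` predicate over the taxonomy row says so).
    """
    if keep is None:
        phyla = set(metazoan_phyla or ())
        if not phyla:
            raise ValueError("provide either a predicate or a phylum list")

        def keep(row: pd.Series) -> bool:  # noqa: F811
            return row["phylum"] in phyla

    mask = motus.taxonomy.apply(keep, axis=1)
    kept_motus = motus.subset_motus(motus.reads.index[mask])
    kept_esvs = None
    if esvs is not None:
        m = esvs.motu_ids.isin(set(kept_motus.motu_ids))
        kept_esvs = esvs.subset_esvs(esvs.reads.index[m])
    return kept_motus, kept_esvs


# ---------------------------------------------------------------------------
# full cascade


@dataclass
class CascadeResult:
    esvs: ESVTable
    motus: MOTUTable
    samples: SampleFrame
    log: pd.DataFrame
    stage_counts: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_cascade(
    esvs: ESVTable,
    motus: MOTUTable,
    samples: SampleFrame,
    cfg: FilterConfig | None = None,
) -> CascadeResult:
    """Apply blank, dual-abundance, pseudogene and depth filters in order."""
    cfg = cfg or FilterConfig()
    logs = []
    counts = []

    def record(stage: str, e: ESVTable) -> None:
        counts.append(
            {
                "stage": stage,
                "n_esvs": len(e.esv_ids),
                "n_motus": e.motu_ids.nunique(),
                "total_reads": int(e.reads.to_numpy().sum()),
            }
        )

    record("input", esvs)
    r1 = blank_filter(esvs, samples, cfg)
    logs.append(r1.log)
    record("blank_filter", r1.esvs)
    r2 = dual_abundance_filter(r1.esvs, cfg)
    logs.append(r2.log)
    record("dual_abundance_filter", r2.esvs)
    r3 = pseudogene_filter(r2.esvs, cfg, motus)
    logs.append(r3.log)
    record("pseudogene_filter", r3.esvs)
    r4 = sample_depth_filter(r3.esvs, samples, cfg)
    logs.append(r4.log)
    record("sample_depth_filter", r4.esvs)
    final_esvs = r4.esvs
    final_motus = motu_table_from_esvs(final_esvs, motus)
    return CascadeResult(
        final_esvs,
        final_motus,
        r4.samples,
        pd.concat(logs, ignore_index=True),
        pd.DataFrame(counts),
    )
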