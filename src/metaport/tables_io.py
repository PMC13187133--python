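"""Data model and TSV/FASTA I/O for ESV, MOTU, sample and BLAST-hit tables.

The package works on three linked tables: an ESV (exact sequence variant)
table holding read counts per denoised haplotype per sample, a MOTU table
holding read counts per species-proxy cluster per sample, and a sample
frame mapping samples to locality, sampling time, replicate and type
(true sample, field/extraction blank, PCR negative).  ESVs carry the id
of their parent MOTU, so MOTU read counts are always the per-sample sums
of their member ESVs.

Reads are stored as integers; relative abundances are computed on demand
and never stored.  Sample columns are identified by membership in the
SampleFrame — an unknown column in a read table is an error, which
prevents silent mishandling of blanks and negatives.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SAMPLE_TYPES = ("true_sample", "blank", "pcr_negative")
DATASET_LABELS = ("NIS", "NAT", "COMM_other", "excluded")

#: Ranks used when serialising taxonomy strings (semicolon-delimited,
#: absent ranks left empty rather than written as "NA").
TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus", "species")


class TableError(ValueError):
    """Raised when a table violates the data model."""


def _require_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise TableError(f"duplicate {what}: {dups}")


@dataclass
class SampleFrame:
    """Sample metadata: locality, time point, replicate and sample type."""

    data: pd.DataFrame

    REQUIRED = ("locality", "time_point", "replicate", "sample_type")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df = df.rename_axis("sample_id")
        _require_unique(df.index, "sample_id")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise TableError(f"sample frame missing columns: {missing}")
        bad_type = set(df["sample_type"].unique()) - set(SAMPLE_TYPES)
        if bad_type:
            raise TableError(f"unknown sample_type values: {sorted(bad_type)}")
        true = df[df["sample_type"] == "true_sample"]
        no_loc = true.index[true["locality"].isna() | (true["locality"] == "")]
        if len(no_loc):
            raise TableError(
                f"true samples without locality: {no_loc.tolist()}"
            )
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def true_sample_ids(self) -> list[str]:
        m = self.data["sample_type"] == "true_sample"
        return self.data.index[m].tolist()

    @property
    def control_ids(self) -> list[str]:
        """Blank and PCR-negative sample ids."""
        m = self.data["sample_type"].isin(("blank", "pcr_negative"))
        return self.data.index[m].tolist()

    @property
    def localities(self) -> list[str]:
        locs = self.data.loc[
            self.data["sample_type"] == "true_sample", "locality"
        ]
        return sorted(locs.dropna().unique().tolist())

    def samples_of(self, locality: str) -> list[str]:
        m = (self.data["sample_type"] == "true_sample") & (
            self.data["locality"] == locality
        )
        return self.data.index[m].tolist()

    def time_points(self) -> list:
        tp = self.data.loc[
            self.data["sample_type"] == "true_sample", "time_point"
        ]
        return sorted(tp.dropna().unique().tolist())

    def subset(self, sample_ids: Iterable[str]) -> "SampleFrame":
        keep = [s for s in self.data.index if s in set(sample_ids)]
        return SampleFrame(self.data.loc[keep].copy())


def _check_reads(reads: pd.DataFrame, what: str) -> pd.DataFrame:
    if reads.isna().any().any():
        raise TableError(f"{what} read matrix contains missing values")
    arr = reads.to_numpy()
    if (arr < 0).any():
        raise TableError(f"{what} read matrix contains negative counts")
    return reads.astype(np.int64)


@dataclass
class ESVTable:
    """Reads per ESV per sample, with MOTU membership and sequences.

    ``reads`` is indexed by esv_id with one integer column per sample;
    ``motu_ids`` maps esv_id -> motu_id; ``sequences`` (optional) maps
    esv_id -> IUPAC DNA string.
    """

    reads: pd.DataFrame
    motu_ids: pd.Series
    sequences: pd.Series | None = None

    def __post_init__(self) -> None:
        _require_unique(self.reads.index, "esv_id")
        self.reads = _check_reads(self.reads, "ESV")
        self.reads.index.name = "esv_id"
        self.motu_ids = self.motu_ids.reindex(self.reads.index)
        if self.motu_ids.isna().any():
            missing = self.motu_ids.index[self.motu_ids.isna()].tolist()
            raise TableError(f"ESVs without MOTU membership: {missing}")
        if self.sequences is not None:
            self.sequences = self.sequences.reindex(self.reads.index)

    @property
    def esv_ids(self) -> list[str]:
        return self.reads.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.reads.columns.tolist()

    def subset_esvs(self, esv_ids: Sequence[str]) -> "ESVTable":
        seqs = None if self.sequences is None else self.sequences.loc[list(esv_ids)]
        return ESVTable(
            self.reads.loc[list(esv_ids)].copy(),
            self.motu_ids.loc[list(esv_ids)].copy(),
            seqs,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ESVTable":
        return ESVTable(
            self.reads[list(sample_ids)].copy(),
            self.motu_ids.copy(),
            None if self.sequences is None else self.sequences.copy(),
        )

    def drop_empty(self) -> "ESVTable":
        keep = self.reads.sum(axis=1) > 0
        return self.subset_esvs(self.reads.index[keep])

    def motu_read_sums(self) -> pd.DataFrame:
        """Per-MOTU read totals per sample (sums over member ESVs)."""
        return self.reads.groupby(self.motu_ids).sum()


@dataclass
class MOTUTable:
    """Reads per MOTU per sample with taxonomy and dataset label."""

    reads: pd.DataFrame
    taxonomy: pd.DataFrame = field(default_factory=pd.DataFrame)
    nominal_species: pd.Series | None = None
    dataset_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        _require_unique(self.reads.index, "motu_id")
        self.reads = _check_reads(self.reads, "MOTU")
        self.reads.index.name = "motu_id"
        if self.taxonomy is None or self.taxonomy.empty:
            self.taxonomy = pd.DataFrame(
                "", index=self.reads.index, columns=list(TAXONOMY_RANKS)
            )
        else:
            self.taxonomy = self.taxonomy.reindex(self.reads.index).fillna("")
        if self.nominal_species is None:
            self.nominal_species = pd.Series("", index=self.reads.index)
        else:
            self.nominal_species = self.nominal_species.reindex(
                self.reads.index
            ).fillna("")
        if self.dataset_labels is None:
            self.dataset_labels = pd.Series(
                "COMM_other", index=self.reads.index
            )
        else:
            self.dataset_labels = self.dataset_labels.reindex(self.reads.index)
            bad = set(self.dataset_labels.dropna().unique()) - set(
                DATASET_LABELS
            )
            if bad:
                raise TableError(f"unknown dataset labels: {sorted(bad)}")

    @property
    def motu_ids(self) -> list[str]:
        return self.reads.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.reads.columns.tolist()

    def ids_with_label(self, label: str) -> list[str]:
        return self.reads.index[self.dataset_labels == label].tolist()

    def subset_motus(self, motu_ids: Sequence[str]) -> "MOTUTable":
        ids = list(motu_ids)
        return MOTUTable(
            self.reads.loc[ids].copy(),
            self.taxonomy.loc[ids].copy(),
            self.nominal_species.loc[ids].copy(),
            self.dataset_labels.loc[ids].copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MOTUTable":
        return MOTUTable(
            self.reads[list(sample_ids)].copy(),
            self.taxonomy.copy(),
            self.nominal_species.copy(),
            self.dataset_labels.copy(),
        )


@dataclass
class HitTable:
    """Per-MOTU best matches against a curated NIS reference database."""

    data: pd.DataFrame  # columns: motu_id, subject_species, identity, coverage

    REQUIRED = ("motu_id", "subject_species", "identity", "coverage")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise TableError(f"hit table missing columns: {missing}")
        for col in ("identity", "coverage"):
            vals = self.data[col].astype(float)
            if ((vals < 0) | (vals > 100)).any():
                raise TableError(f"{col} outside [0, 100]")
            self.data[col] = vals


# ---------------------------------------------------------------------------
# Linkage validation


@dataclass
class LinkageReport:
    """Result of cross-validating ESV and MOTU read tables."""

    mismatches: pd.DataFrame  # motu_id, sample_id, motu_reads, esv_sum

    @property
    def ok(self) -> bool:
        return self.mismatches.empty


def validate_linkage(esvs: ESVTable, motus: MOTUTable) -> LinkageReport:
    """Check that MOTU reads equal the per-sample sums of member ESVs.

    Orphan ESVs (motu_id absent from the MOTU table) are an error;
    numeric mismatches are collected in the report.
    """
    shared = [c for c in esvs.sample_ids if c in set(motus.sample_ids)]
    if set(esvs.sample_ids) != set(motus.sample_ids):
        raise TableError(
            "ESV and MOTU tables have different sample columns: "
            f"{sorted(set(esvs.sample_ids) ^ set(motus.sample_ids))}"
        )
    orphans = sorted(set(esvs.motu_ids) - set(motus.motu_ids))
    if orphans:
        raise TableError(f"ESVs reference unknown MOTUs: {orphans}")
    sums = esvs.motu_read_sums().reindex(
        index=motus.reads.index, columns=shared, fill_value=0
    )
    diff = motus.reads[shared] - sums
    rows = []
    for motu_id, sample_id in zip(*np.nonzero(diff.to_numpy())):
        rows.append(
            {
                "motu_id": diff.index[motu_id],
                "sample_id": diff.columns[sample_id],
                "motu_reads": int(motus.reads.iloc[motu_id, motus.reads.columns.get_loc(diff.columns[sample_id])]),
                "esv_sum": int(sums.iloc[motu_id, sample_id]),
            }
        )
    return LinkageReport(
        pd.DataFrame(rows, columns=["motu_id", "sample_id", "motu_reads", "esv_sum"])
    )


def motu_table_from_esvs(
    esvs: ESVTable, template: MOTUTable | None = None
) -> MOTUTable:
    """Rebuild a MOTU table by summing ESV reads, keeping metadata from
    ``template`` for surviving MOTUs."""
    sums = esvs.motu_read_sums()
    if template is None:
        return MOTUTable(sums)
    keep = [m for m in template.motu_ids if m in set(sums.index)]
    sums = sums.loc[keep]
    return MOTUTable(
        sums,
        template.taxonomy.loc[keep],
        template.nominal_species.loc[keep],
        template.dataset_labels.loc[keep],
    )


# ---------------------------------------------------------------------------
# Dataset partition


def partition_datasets(
    motus: MOTUTable, nis_ids: Iterable[str], nat_ids: Iterable[str]
) -> MOTUTable:
    """Label MOTUs as NIS / NAT / COMM_other.

    The COMM dataset of the analysis is everything that is not NIS, i.e.
    NAT plus COMM_other.  Relabeling never touches read counts.
    """
    nis, nat = set(nis_ids), set(nat_ids)
    both = nis & nat
    if both:
        raise TableError(f"MOTUs in both NIS and NAT sets: {sorted(both)}")
    labels = pd.Series("COMM_other", index=motus.reads.index)
    labels[labels.index.isin(nis)] = "NIS"
    labels[labels.index.isin(nat)] = "NAT"
    return MOTUTable(
        motus.reads.copy(),
        motus.taxonomy.copy(),
        motus.nominal_species.copy(),
        labels,
    )


def comm_ids(motus: MOTUTable) -> list[str]:
    """MOTU ids of the COMM dataset (all non-NIS MOTUs)."""
    return motus.reads.index[motus.dataset_labels != "NIS"].tolist()


# ---------------------------------------------------------------------------
# Readers / writers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={0: str})


def read_sample_frame(path: str | Path) -> SampleFrame:
    df = _read_tsv(path)
    if "sample_id" not in df.columns:
        raise TableError("sample frame TSV must have a sample_id column")
    return SampleFrame(df.set_index("sample_id"))


def write_sample_frame(samples: SampleFrame, path: str | Path) -> None:
    samples.data.to_csv(path, sep="\t")


def read_esv_table(
    path: str | Path,
    samples: SampleFrame,
    fasta: str | Path | None = None,
    column_map: Mapping[str, str] | None = None,
) -> ESVTable:
    """Read an ESV table from TSV (esv_id, motu_id, one column per sample).

    ``column_map`` renames supplier-specific column headers onto the
    canonical ones before validation (the layout of curated supplementary
    tables varies between studies).  Columns that are neither canonical
    metadata nor known sample ids are an error.
    """
    df = _read_tsv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("esv_id", "motu_id"):
        if col not in df.columns:
            raise TableError(f"ESV table missing column {col!r}")
    df = df.set_index("esv_id")
    _require_unique(df.index, "esv_id")
    meta_cols = [c for c in ("motu_id", "sequence") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    known = set(samples.sample_ids)
    unknown = [c for c in sample_cols if c not in known]
    if unknown:
        raise TableError(
            f"ESV table has columns that are not known samples: {unknown}"
        )
    if not sample_cols:
        raise TableError("ESV table has no sample columns")
    seqs = df["sequence"] if "sequence" in df.columns else None
    if fasta is not None:
        recs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta), "fasta")}
        missing = [e for e in df.index if e not in recs]
        if missing:
            raise TableError(f"FASTA lacks sequences for ESVs: {missing}")
        seqs = pd.Series({e: recs[e] for e in df.index})
    return ESVTable(df[sample_cols], df["motu_id"], seqs)


def write_esv_table(
    esvs: ESVTable, path: str | Path, fasta: str | Path | None = None
) -> None:
    out = pd.concat([esvs.motu_ids.rename("motu_id"), esvs.reads], axis=1)
    out.index.name = "esv_id"
    out.to_csv(path, sep="\t")
    if fasta is not None and esvs.sequences is not None:
        records = [
            SeqRecord(Seq(seq), id=esv_id, description="")
            for esv_id, seq in esvs.sequences.items()
        ]
        SeqIO.write(records, str(fasta), "fasta")


def read_motu_table(
    path: str | Path,
    samples: SampleFrame,
    column_map: Mapping[str, str] | None = None,
) -> MOTUTable:
    df = _read_tsv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "motu_id" not in df.columns:
        raise TableError("MOTU table missing column 'motu_id'")
    df = df.set_index("motu_id")
    _require_unique(df.index, "motu_id")
    tax = pd.DataFrame(index=df.index)
    if "taxonomy" in df.columns:
        parts = df["taxonomy"].fillna("").str.split(";", expand=True)
        parts = parts.reindex(columns=range(len(TAXONOMY_RANKS))).fillna("")
        tax = parts.set_axis(list(TAXONOMY_RANKS), axis=1)
    meta_cols = {"taxonomy", "nominal_species", "dataset_label"}
    sample_cols = [c for c in df.columns if c not in meta_cols]
    known = set(samples.sample_ids)
    unknown = [c for c in sample_cols if c not in known]
    if unknown:
        raise TableError(
            f"MOTU table has columns that are not known samples: {unknown}"
        )
    nominal = df["nominal_species"] if "nominal_species" in df.columns else None
    labels = df["dataset_label"] if "dataset_label" in df.columns else None
    return MOTUTable(df[sample_cols], tax, nominal, labels)


def write_motu_table(motus: MOTUTable, path: str | Path) -> None:
    tax_str = motus.taxonomy[list(TAXONOMY_RANKS)].agg(";".join, axis=1)
    out = pd.concat(
        [
            tax_str.rename("taxonomy"),
            motus.nominal_species.rename("nominal_species"),
            motus.dataset_labels.rename("dataset_label"),
            motus.reads,
        ],
        axis=1,
    )
    out.index.name = "motu_id"
    out.to_csv(path, sep="\t")


def read_hit_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> HitTable:
    """Read a BLAST-tabular-style hit table.

    Recognises the conventional qseqid/sseqid/pident/qcovs headers as
    well as the canonical names.
    """
    df = _read_tsv(path)
    default_map = {
        "qseqid": "motu_id",
        "sseqid": "subject_species",
        "pident": "identity",
        "qcovs": "coverage",
    }
    df = df.rename(columns=default_map)
    if column_map:
        df = df.rename(columns=dict(column_map))
    return HitTable(df)


def write_hit_table(hits: HitTable, path: str | Path) -> None:
    hits.data.to_csv(path, sep="\t", index=False)
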