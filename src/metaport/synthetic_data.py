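"""Synthetic metabarcoding datasets with known ground truth.

The generator emulates the structure of a multi-port COI metabarcoding
survey: several localities sampled at successive time points with
replicate collectors plus field blanks and PCR negatives; a community
of MOTUs split into widely shared, read-abundant non-indigenous
species (NIS), locality-restricted natives (NAT) and a remainder of
unassigned MOTUs; per-MOTU haplotype (ESV) counts higher in NIS;
within-MOTU haplotype frequencies with tunable between-locality
differentiation; contaminant ESVs concentrated in blanks; and
pseudogene spike-ins carrying in-frame stop codons.

Haplotype frequency model: each MOTU draws base frequencies from a
symmetric Dirichlet; the frequencies used in locality L are
(1 - theta) * base + theta * private Dirichlet draw, so theta = 0
yields identical frequencies everywhere and theta = 1 locality-private
compositions.  Read counts per sample are a single multinomial draw
over all (ESV, sample) cell probabilities, which keeps MOTU sums equal
to ESV sums by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import (
    ESVTable,
    HitTable,
    MOTUTable,
    SampleFrame,
    TAXONOMY_RANKS,
)

#: A 313-bp COI-like fragment whose reading frame (offset 2) is free of
#: stop codons under every metazoan mitochondrial genetic code.
COI_TEMPLATE = (
    "TTTTTGATGTACACGAGTCGCGCTTTGAACTAGCTTTCGGCGGGTGCTTAGGTACATGACAGGATAC"
    "AAAAGGTAGCCTGATATGTAGCTTAAAGCTCACCCTGAGCTGAACTCTGCCTTTATTGCGGTGGTCG"
    "CTACCAACCCGTACACGACGCACAAATCAACTGGTCTTTAACGATCGGAACTCGATGATGGAGCATA"
    "GTTTACCACCCGACCAGCGCGCAGGTCAAGATAAGATGTACCGGCCCACGGCGATCCGTTTCCCCAG"
    "CATGATGCGCTTGGAAACTTGGCGGCCCCCCGCGCACCTCCTAAC"
)

READING_FRAME = 2
#: codons that are stops (or vertebrate-mitochondrial stops) and must
#: not appear in frame in a clean sequence
_FORBIDDEN_CODONS = {"TAA", "TAG", "AGA", "AGG"}

_PHYLA = (
    "Arthropoda",
    "Cnidaria",
    "Chordata",
    "Annelida",
    "Mollusca",
    "Bryozoa",
    "Echinodermata",
    "Porifera",
)

_DEFAULT_LOCALITIES = ("RO", "BL", "VI", "LR")


@dataclass
class SimConfig:
    """Study-design and community parameters of the generator.

    Defaults mirror the surveyed conditions: 4 ports, 10 sampling
    times, 3 replicate collectors, 15 PCR blanks and 12 field
    negatives; 75 NIS, 244 NAT and 1,455 other MOTUs; lognormal
    per-sample read depths around one million reads.
    """

    n_localities: int = 4
    n_timepoints: int = 10
    n_replicates: int = 3
    n_blanks: int = 15
    n_negatives: int = 12
    n_nis_motus: int = 75
    n_nat_motus: int = 244
    n_other_motus: int = 1455
    depth_meanlog: float = 13.8  # ~1e6 reads per sample
    depth_sdlog: float = 0.35
    #: fraction of true samples given a shallow depth (below the 9,500
    #: read cutoff), emulating failed libraries
    shallow_sample_rate: float = 10 / 120
    occupancy_nis: float = 0.8
    occupancy_nat: float = 0.3
    occupancy_other: float = 0.3
    esv_mean_nis: float = 8.0
    esv_mean_nat: float = 3.0
    esv_mean_other: float = 3.0
    esv_dispersion: float = 2.0  # negative-binomial shape
    #: within-class power-law coupling of the expected haplotype number
    #: to MOTU abundance (larger populations carry more haplotypes)
    esv_abundance_exponent: float = 0.35
    #: NIS MOTUs carry more reads per occurrence than the rest
    abundance_scale_nis: float = 25.0
    #: lognormal sigma of per-MOTU base abundance; the wide spread makes
    #: rare haplotypes of read-poor MOTUs fall below detection, which is
    #: what couples ESV richness to read abundance in real surveys
    abundance_sdlog: float = 2.5
    #: symmetric Dirichlet concentration for within-MOTU haplotype
    #: frequencies; values < 1 give one dominant haplotype plus a tail
    #: of rare ones, as observed in denoised COI data
    dirichlet_alpha: float = 0.3
    #: lognormal sigma of per-(ESV, sample) patchiness: haplotypes are
    #: carried by few individuals, so a MOTU-wide rare haplotype can
    #: still dominate a single collector and pass per-sample detection
    esv_patchiness: float = 1.5
    theta_nis: float = 0.6
    theta_nat: float = 0.75
    theta_other: float = 0.75
    contamination_rate: float = 0.01
    pseudogene_rate: float = 0.02
    #: fraction of NIS MOTUs sharing a nominal species with another
    #: NIS MOTU (species complexes)
    species_complex_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "shallow_sample_rate",
            "occupancy_nis",
            "occupancy_nat",
            "occupancy_other",
            "theta_nis",
            "theta_nat",
            "theta_other",
            "contamination_rate",
            "pseudogene_rate",
            "species_complex_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.esv_mean_nis, self.esv_mean_nat, self.esv_mean_other) <= 0:
            raise ValueError("class ESV means must be positive")
        if (
            self.n_localities < 1
            or self.n_timepoints < 1
            or self.n_replicates < 1
        ):
            raise ValueError("need at least one locality/time/replicate")
        if self.n_nis_motus + self.n_nat_motus + self.n_other_motus < 1:
            raise ValueError("need at least one MOTU")


@dataclass
class SimBundle:
    """A complete synthetic dataset plus its ground-truth ledger."""

    esvs: ESVTable
    motus: MOTUTable
    samples: SampleFrame
    hits: HitTable
    truth: dict = field(default_factory=dict)


def _localities(cfg: SimConfig) -> list[str]:
    if cfg.n_localities <= len(_DEFAULT_LOCALITIES):
        return list(_DEFAULT_LOCALITIES[: cfg.n_localities])
    return [f"L{i+1:02d}" for i in range(cfg.n_localities)]


def _zt_negbin(
    rng: np.random.Generator, mean: np.ndarray | float, shape: float, size: int
) -> np.ndarray:
    """Zero-truncated negative binomial via rejection."""
    p = np.broadcast_to(shape / (shape + np.asarray(mean, float)), (size,))
    out = np.zeros(size, dtype=int)
    todo = np.arange(size)
    while len(todo):
        draw = rng.negative_binomial(shape, p[todo])
        ok = draw > 0
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _mutate_template(
    rng: np.random.Generator, used: set[str], n_sub_max: int = 6
) -> str:
    """A unique variant of the template with third-codon-position
    substitutions that never create an in-frame forbidden codon."""
    third_positions = list(range(READING_FRAME + 2, len(COI_TEMPLATE) - 2, 3))
    while True:
        seq = list(COI_TEMPLATE)
        n_sub = rng.integers(1, n_sub_max + 1)
        for pos in rng.choice(third_positions, size=n_sub, replace=False):
            for base in rng.permutation(["A", "C", "G", "T"]):
                if base == seq[pos]:
                    continue
                codon = "".join(seq[pos - 2 : pos]) + base
                if codon not in _FORBIDDEN_CODONS:
                    seq[pos] = base
                    break
        s = "".join(seq)
        if s not in used:
            used.add(s)
            return s


def _pseudogenize(rng: np.random.Generator, seq: str, used: set[str]) -> str:
    """Insert an in-frame TAG (a stop under every metazoan
    mitochondrial code) into a clean sequence."""
    starts = list(range(READING_FRAME, len(seq) - 4, 3))
    while True:
        pos = int(rng.choice(starts))
        s = seq[:pos] + "TAG" + seq[pos + 3 :]
        if s not in used:
            used.add(s)
            return s


def simulate(cfg: SimConfig | None = None) -> SimBundle:
    """Generate a full dataset bundle under the configured conditions."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    locs = _localities(cfg)

    # --- sample frame -----------------------------------------------------
    rows = []
    for loc in locs:
        for t in range(1, cfg.n_timepoints + 1):
            for r in range(1, cfg.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{loc}_T{t:02d}_R{r}",
                        "locality": loc,
                        "time_point": t,
                        "replicate": r,
                        "sample_type": "true_sample",
                    }
                )
    for i in range(cfg.n_blanks):
        rows.append(
            {
                "sample_id": f"BLK{i+1:02d}",
                "locality": "",
                "time_point": pd.NA,
                "replicate": i + 1,
                "sample_type": "blank",
            }
        )
    for i in range(cfg.n_negatives):
        rows.append(
            {
                "sample_id": f"NEG{i+1:02d}",
                "locality": "",
                "time_point": pd.NA,
                "replicate": i + 1,
                "sample_type": "pcr_negative",
            }
        )
    samples = SampleFrame(pd.DataFrame(rows).set_index("sample_id"))
    true_ids = samples.true_sample_ids
    control_ids = samples.control_ids

    # --- MOTU-level structure --------------------------------------------
    classes = (
        ["NIS"] * cfg.n_nis_motus
        + ["NAT"] * cfg.n_nat_motus
        + ["COMM_other"] * cfg.n_other_motus
    )
    n_motus = len(classes)
    motu_ids = [f"M{i+1:05d}" for i in range(n_motus)]
    occupancy = {
        "NIS": cfg.occupancy_nis,
        "NAT": cfg.occupancy_nat,
        "COMM_other": cfg.occupancy_other,
    }
    theta_of = {
        "NIS": cfg.theta_nis,
        "NAT": cfg.theta_nat,
        "COMM_other": cfg.theta_other,
    }
    esv_mean = {
        "NIS": cfg.esv_mean_nis,
        "NAT": cfg.esv_mean_nat,
        "COMM_other": cfg.esv_mean_other,
    }

    base_abund = rng.lognormal(0.0, cfg.abundance_sdlog, size=n_motus)
    base_abund[np.array(classes) == "NIS"] *= cfg.abundance_scale_nis
    # expected haplotype number grows with abundance within each class
    class_arr = np.array(classes)
    abund_rel = np.empty(n_motus)
    for c in set(classes):
        idx = class_arr == c
        geo = np.exp(np.mean(np.log(base_abund[idx])))
        abund_rel[idx] = base_abund[idx] / geo
    esv_mean_arr = np.array([esv_mean[c] for c in classes]) * np.clip(
        abund_rel**cfg.esv_abundance_exponent, None, 50.0
    )
    esv_counts = _zt_negbin(rng, esv_mean_arr, cfg.esv_dispersion, n_motus)
    occ = np.zeros((n_motus, len(locs)), dtype=bool)
    for i, c in enumerate(classes):
        row = rng.random(len(locs)) < occupancy[c]
        if not row.any():
            row[rng.integers(len(locs))] = True
        occ[i] = row

    # per-MOTU haplotype frequencies per locality
    esv_ids: list[str] = []
    esv_motu: list[str] = []
    loc_freqs: list[np.ndarray] = []  # (k, n_locs) per MOTU
    for i, motu_id in enumerate(motu_ids):
        k = int(esv_counts[i])
        base = rng.dirichlet(np.full(k, cfg.dirichlet_alpha))
        theta = theta_of[classes[i]]
        freqs = np.empty((k, len(locs)))
        for j in range(len(locs)):
            private = rng.dirichlet(np.full(k, cfg.dirichlet_alpha))
            freqs[:, j] = (1 - theta) * base + theta * private
        loc_freqs.append(freqs)
        for h in range(k):
            esv_ids.append(f"{motu_id}_E{h+1:03d}")
            esv_motu.append(motu_id)
    n_esvs = len(esv_ids)

    # cell probabilities per locality: motu weight x haplotype frequency
    motu_of_esv = np.repeat(np.arange(n_motus), esv_counts)
    weight_loc = np.zeros((n_esvs, len(locs)))
    row0 = np.concatenate([[0], np.cumsum(esv_counts)])
    for i in range(n_motus):
        sl = slice(row0[i], row0[i + 1])
        for j in range(len(locs)):
            if occ[i, j]:
                weight_loc[sl, j] = base_abund[i] * loc_freqs[i][:, j]

    # --- read counts ------------------------------------------------------
    depths = np.round(
        rng.lognormal(cfg.depth_meanlog, cfg.depth_sdlog, size=len(true_ids))
    ).astype(np.int64)
    n_shallow = int(round(cfg.shallow_sample_rate * len(true_ids)))
    if n_shallow:
        shallow_idx = rng.choice(len(true_ids), size=n_shallow, replace=False)
        depths[shallow_idx] = rng.integers(500, 5000, size=n_shallow)
    else:
        shallow_idx = np.array([], dtype=int)

    loc_index = {l: j for j, l in enumerate(locs)}
    reads = np.zeros((n_esvs, len(true_ids)), dtype=np.int64)
    # per-(MOTU, sample) lognormal wiggle emulating temporal turnover
    for s, sample_id in enumerate(true_ids):
        j = loc_index[samples.data.at[sample_id, "locality"]]
        wiggle = rng.lognormal(0.0, 0.7, size=n_motus)
        patch = rng.lognormal(0.0, cfg.esv_patchiness, size=n_esvs)
        w = weight_loc[:, j] * wiggle[motu_of_esv] * patch
        total = w.sum()
        if total == 0:
            continue
        reads[:, s] = rng.multinomial(depths[s], w / total)

    # --- pseudogene spike-ins --------------------------------------------
    n_pseudo = int(round(cfg.pseudogene_rate * n_esvs))
    pseudo_ids = []
    pseudo_rows = []
    for i in range(n_pseudo):
        host = int(rng.integers(n_motus))
        pid = f"{motu_ids[host]}_P{i+1:03d}"
        pseudo_ids.append(pid)
        esv_ids.append(pid)
        esv_motu.append(motu_ids[host])
        row = np.zeros(len(true_ids), dtype=np.int64)
        for s in rng.choice(len(true_ids), size=3, replace=False):
            row[s] = rng.integers(100, 400)
        pseudo_rows.append(row)
    if n_pseudo:
        reads = np.vstack([reads, np.array(pseudo_rows)])

    # --- control columns and contaminants --------------------------------
    control = np.zeros((len(esv_ids), len(control_ids)), dtype=np.int64)
    n_cont = int(round(cfg.contamination_rate * len(esv_ids)))
    true_totals = reads.sum(axis=1)
    candidates = np.flatnonzero(true_totals > 0)
    cont_ids: list[str] = []
    if n_cont and len(candidates):
        chosen = rng.choice(
            candidates, size=min(n_cont, len(candidates)), replace=False
        )
        for idx in chosen:
            cont_ids.append(esv_ids[idx])
            # controls collect ~30% of the true-sample reads: clearly
            # above the 10% contamination rule
            leak = max(1, int(0.3 * true_totals[idx]))
            split = rng.multinomial(
                leak, np.full(len(control_ids), 1 / len(control_ids))
            )
            control[idx] = split

    read_df = pd.DataFrame(
        np.hstack([reads, control]),
        index=pd.Index(esv_ids, name="esv_id"),
        columns=true_ids + control_ids,
    )

    # --- sequences --------------------------------------------------------
    used: set[str] = set()
    seqs = {}
    for esv_id in esv_ids:
        if esv_id in set(pseudo_ids):
            seqs[esv_id] = _pseudogenize(rng, _mutate_template(rng, used), used)
        else:
            seqs[esv_id] = _mutate_template(rng, used)
    sequences = pd.Series(seqs)

    esvs = ESVTable(
        read_df, pd.Series(esv_motu, index=read_df.index), sequences
    )
    esvs = esvs.subset_esvs(esvs.reads.index[esvs.reads.sum(axis=1) > 0])

    # --- MOTU table -------------------------------------------------------
    motu_reads = esvs.motu_read_sums().reindex(motu_ids, fill_value=0)
    motu_reads = motu_reads.loc[motu_reads.sum(axis=1) > 0]
    kept_ids = motu_reads.index.tolist()
    tax = pd.DataFrame("", index=motu_reads.index, columns=list(TAXONOMY_RANKS))
    label_of = dict(zip(motu_ids, classes))
    phyla = rng.choice(_PHYLA, size=len(kept_ids))
    species_names = {}
    nis_kept = [m for m in kept_ids if label_of[m] == "NIS"]
    n_complex = int(round(cfg.species_complex_rate * len(nis_kept)))
    for rank_i, motu_id in enumerate(kept_ids):
        tax.at[motu_id, "phylum"] = phyla[rank_i]
        if label_of[motu_id] in ("NIS", "NAT"):
            species_names[motu_id] = f"{label_of[motu_id]}_sp_{motu_id}"
            tax.at[motu_id, "genus"] = f"Genus_{motu_id}"
            tax.at[motu_id, "species"] = species_names[motu_id]
    # species complexes: some NIS MOTUs share a nominal species
    for i in range(n_complex):
        if len(nis_kept) >= 2:
            a, b = rng.choice(len(nis_kept), size=2, replace=False)
            shared = species_names[nis_kept[a]]
            species_names[nis_kept[b]] = shared
            tax.at[nis_kept[b], "species"] = shared
    labels = pd.Series([label_of[m] for m in kept_ids], index=motu_reads.index)
    nominal = pd.Series(
        [species_names.get(m, "") for m in kept_ids], index=motu_reads.index
    )
    motus = MOTUTable(motu_reads, tax, nominal, labels)

    # --- hit table --------------------------------------------------------
    hit_rows = []
    for motu_id in kept_ids:
        if label_of[motu_id] == "NIS":
            hit_rows.append(
                {
                    "motu_id": motu_id,
                    "subject_species": species_names[motu_id],
                    "identity": float(rng.uniform(97.0, 100.0)),
                    "coverage": float(rng.uniform(70.0, 100.0)),
                }
            )
        elif rng.random() < 0.05:  # spurious sub-threshold hits
            hit_rows.append(
                {
                    "motu_id": motu_id,
                    "subject_species": f"Spurious_sp_{motu_id}",
                    "identity": float(rng.uniform(80.0, 96.9)),
                    "coverage": float(rng.uniform(40.0, 100.0)),
                }
            )
    hits = HitTable(pd.DataFrame(hit_rows))

    truth = {
        "class_of": label_of,
        "theta_of": {k: theta_of[v] for k, v in label_of.items()},
        "theta_by_class": theta_of,
        "contaminant_esvs": sorted(cont_ids),
        "pseudogene_esvs": sorted(pseudo_ids),
        "shallow_samples": [true_ids[i] for i in np.sort(shallow_idx)],
        "template": COI_TEMPLATE,
        "config": cfg,
    }
    return SimBundle(esvs, motus, samples, hits, truth)


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced configuration (same structure, smaller community and
    shallower sequencing) convenient for fast exploratory runs."""
    base = dict(
        n_timepoints=4,
        n_blanks=3,
        n_negatives=2,
        n_nis_motus=20,
        n_nat_motus=40,
        n_other_motus=60,
        depth_meanlog=10.5,  # ~36k reads
        depth_sdlog=0.3,
        shallow_sample_rate=0.08,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# hand-auditable miniature dataset


def worked_fixture() -> SimBundle:
    """A miniature fixed dataset with every filter and statistic
    computable by hand.

    Two localities (A with samples A1-A3, B with B1-B3) and one blank.
    Constructed offenders:

    * ``M2_cont`` — 50 blank reads vs 400 true reads (12.5% > 10%):
      removed by the blank filter (and MOTU M2 with it).
    * ``M3_edge`` — 40 blank reads vs 400 (exactly 10%): retained.
    * ``M5_a`` — 4 reads in A1 (below 0.005% of the sample) zeroed in
      step (i); its 5 reads in A2 survive both steps.
    * ``M5_b`` — 4 reads in A2 (exactly 0.005% of 80,000) survives
      step (i) but is zeroed by the 5-read step (ii); dropped.
    * ``M4_pseudo`` — carries an in-frame TAG; removed by the
      pseudogene filter, deleting MOTU M4.
    * sample ``B3`` totals 3,000 reads (< 9,500): discarded.

    The one polymorphic shared MOTU, M1, ends with occurrence counts
    (3, 0) / (0, 2) across the pair (A, B), giving Jost's D = 1.
    """
    rows = [
        ("A1", "A", 1, 1, "true_sample"),
        ("A2", "A", 1, 2, "true_sample"),
        ("A3", "A", 2, 1, "true_sample"),
        ("B1", "B", 1, 1, "true_sample"),
        ("B2", "B", 1, 2, "true_sample"),
        ("B3", "B", 2, 1, "true_sample"),
        ("BLK1", "", pd.NA, 1, "blank"),
    ]
    samples = SampleFrame(
        pd.DataFrame(
            rows,
            columns=["sample_id", "locality", "time_point", "replicate", "sample_type"],
        ).set_index("sample_id")
    )
    cols = ["A1", "A2", "A3", "B1", "B2", "B3", "BLK1"]
    table = {
        #            A1      A2     A3     B1     B2    B3   BLK1
        "M1_a":   [6000,   5000,  4000,     0,     0,    0,    0],
        "M1_b":   [   0,      0,     0,  3000,  2000, 1000,    0],
        "M2_cont":[ 400,      0,     0,     0,     0,    0,   50],
        "M3_edge":[ 400,      0,     0,     0,     0,    0,   40],
        "M4_pseudo":[500,     0,     0,   500,     0,    0,    0],
        "M5_a":   [   4,      5,     0,     0,     0,    0,    0],
        "M5_b":   [   0,      4,     0,     0,     0,    0,    0],
        "M6_fill":[92696, 74991, 46000, 36500, 28000, 2000,    0],
    }
    reads = pd.DataFrame(table, index=cols).T
    reads.index.name = "esv_id"
    motu_of = pd.Series(
        {e: e.split("_")[0] for e in reads.index}, name="motu_id"
    )
    used: set[str] = {COI_TEMPLATE}
    rng = np.random.default_rng(12345)
    seqs = {}
    for esv_id in reads.index:
        if esv_id == "M4_pseudo":
            seqs[esv_id] = _pseudogenize(rng, _mutate_template(rng, used), used)
        else:
            seqs[esv_id] = _mutate_template(rng, used)
    esvs = ESVTable(reads, motu_of, pd.Series(seqs))
    motu_reads = esvs.motu_read_sums()
    labels = pd.Series("COMM_other", index=motu_reads.index)
    labels[["M1", "M3"]] = "NIS"
    labels[["M5", "M6"]] = "NAT"
    tax = pd.DataFrame("", index=motu_reads.index, columns=list(TAXONOMY_RANKS))
    tax["phylum"] = "Arthropoda"
    for m in motu_reads.index:
        if labels[m] in ("NIS", "NAT"):
            tax.at[m, "species"] = f"{labels[m]}_sp_{m}"
    nominal = tax["species"].copy()
    motus = MOTUTable(motu_reads, tax, nominal, labels)
    hits = HitTable(
        pd.DataFrame(
            [
                {"motu_id": "M1", "subject_species": "Nis_one", "identity": 99.0, "coverage": 95.0},
                {"motu_id": "M3", "subject_species": "Nis_three", "identity": 97.0, "coverage": 70.0},
                {"motu_id": "M5", "subject_species": "Not_nis", "identity": 98.0, "coverage": 60.0},
            ]
        )
    )
    truth = {
        "blank_removed": ["M2_cont"],
        "dual_removed": ["M5_b"],
        "dual_zeroed_cells": [("M5_a", "A1")],
        "pseudogene_removed": ["M4_pseudo"],
        "depth_removed_samples": ["B3"],
        "surviving_esvs": ["M1_a", "M1_b", "M3_edge", "M5_a", "M6_fill"],
        "surviving_motus": ["M1", "M3", "M5", "M6"],
        "jost_d_M1_pair_AB": 1.0,
    }
    return SimBundle(esvs, motus, samples, hits, truth)
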