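"""Intra-MOTU haplotype diversity and occurrence-based genetic
differentiation between localities.

ESVs (denoised exact sequence variants) are treated as haplotypes
within each MOTU (the species proxy).  The module provides:

* per-MOTU ESV richness and the NIS vs NAT rank comparisons;
* log-log regressions of ESV number on read number, with a slope
  homogeneity test, to assess the read-abundance confound;
* per-MOTU read rarefaction (without replacement, preserving per-sample
  proportions in expectation) to a common read number, removing that
  confound;
* a randomization test balancing unequal group sizes;
* pairwise Jost's D between localities computed from ESV occurrence
  frequencies (number of samples with a detection, not reads — read
  counts are a poor abundance proxy at haplotype level), using the
  bias-corrected estimator with harmonic-mean sample size; negative
  estimates are clamped to zero per MOTU before averaging.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .tables_io import ESVTable, MOTUTable, SampleFrame


# ---------------------------------------------------------------------------
# ESV richness


def motu_genetic_summaries(
    esvs: ESVTable, motus: MOTUTable, datasets: tuple[str, ...] = ("NIS", "NAT")
) -> pd.DataFrame:
    """Per-MOTU ESV count and total reads for the requested datasets."""
    rows = []
    grouped = esvs.reads.groupby(esvs.motu_ids)
    for label in datasets:
        for motu_id in motus.ids_with_label(label):
            if motu_id not in grouped.groups:
                continue
            block = grouped.get_group(motu_id)
            present = block.sum(axis=1) > 0
            rows.append(
                {
                    "motu_id": motu_id,
                    "dataset": label,
                    "n_esvs": int(present.sum()),
                    "total_reads": int(block.to_numpy().sum()),
                }
            )
    return pd.DataFrame(rows, columns=["motu_id", "dataset", "n_esvs", "total_reads"])


@dataclass
class RichnessComparison:
    stratum: str
    n_1: int
    n_2: int
    median_1: float
    median_2: float
    statistic: float
    p_value: float


def esv_richness(
    esvs: ESVTable,
    motus: MOTUTable,
    samples: SampleFrame | None = None,
    stratify: str = "none",
    datasets: tuple[str, str] = ("NIS", "NAT"),
) -> tuple[pd.DataFrame, list[RichnessComparison]]:
    """Per-MOTU ESV counts and two-sided Mann-Whitney NIS vs NAT tests.

    ``stratify`` may be "none", "locality" (ESV counts recomputed within
    each locality's samples) or "phylum".
    """
    reports: list[RichnessComparison] = []

    def compare(name: str, a: np.ndarray, b: np.ndarray) -> None:
        if len(a) == 0 or len(b) == 0:
            return  # empty stratum: skipped
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = len(a) * len(b) / 2, 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        reports.append(
            RichnessComparison(
                name, len(a), len(b),
                float(np.median(a)), float(np.median(b)),
                float(stat), float(p),
            )
        )

    summaries = motu_genetic_summaries(esvs, motus, datasets)
    if stratify == "none":
        a = summaries.loc[summaries["dataset"] == datasets[0], "n_esvs"]
        b = summaries.loc[summaries["dataset"] == datasets[1], "n_esvs"]
        compare("all", a.to_numpy(), b.to_numpy())
        return summaries, reports
    if stratify == "locality":
        if samples is None:
            raise ValueError("locality stratification needs a sample frame")
        frames = []
        for loc in samples.localities:
            cols = [c for c in samples.samples_of(loc) if c in esvs.sample_ids]
            sub = esvs.subset_samples(cols).drop_empty()
            s = motu_genetic_summaries(sub, motus, datasets)
            s["stratum"] = loc
            frames.append(s)
            compare(
                loc,
                s.loc[s["dataset"] == datasets[0], "n_esvs"].to_numpy(),
                s.loc[s["dataset"] == datasets[1], "n_esvs"].to_numpy(),
            )
        return pd.concat(frames, ignore_index=True), reports
    if stratify == "phylum":
        summaries = summaries.merge(
            motus.taxonomy["phylum"].rename("stratum"),
            left_on="motu_id",
            right_index=True,
        )
        for phylum, s in summaries.groupby("stratum"):
            compare(
                str(phylum),
                s.loc[s["dataset"] == datasets[0], "n_esvs"].to_numpy(),
                s.loc[s["dataset"] == datasets[1], "n_esvs"].to_numpy(),
            )
        return summaries, reports
    raise ValueError(f"unknown stratification {stratify!r}")


# ---------------------------------------------------------------------------
# reads-richness confound


@dataclass
class RegressionReport:
    slopes: dict
    intercepts: dict
    pearson_r: dict
    interaction_p: float


def reads_esvs_regression(summaries: pd.DataFrame) -> RegressionReport:
    """OLS of log(n_esvs) on log(total_reads) per dataset, with a slope
    homogeneity test via the dataset x log-reads interaction term."""
    slopes, intercepts, rs = {}, {}, {}
    for label, sub in summaries.groupby("dataset"):
        if len(sub) < 3:
            raise ValueError(f"dataset {label}: need >= 3 MOTUs")
        x = np.log(sub["total_reads"].to_numpy(float))
        y = np.log(sub["n_esvs"].to_numpy(float))
        if np.ptp(x) == 0:
            raise ValueError(f"dataset {label}: zero variance in log reads")
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        intercepts[label], slopes[label] = fit.params
        rs[label] = float(stats.pearsonr(x, y).statistic)
    x_all = np.log(summaries["total_reads"].to_numpy(float))
    y_all = np.log(summaries["n_esvs"].to_numpy(float))
    is_first = (
        summaries["dataset"] == sorted(summaries["dataset"].unique())[0]
    ).to_numpy(float)
    design = sm.add_constant(
        np.column_stack([x_all, is_first, x_all * is_first])
    )
    joint = sm.OLS(y_all, design).fit()
    return RegressionReport(slopes, intercepts, rs, float(joint.pvalues[3]))


def rarefy_motu_reads(
    esvs: ESVTable,
    summaries: pd.DataFrame,
    threshold: int | str = "mean",
    reference_dataset: str = "NAT",
    seed: int = 0,
) -> tuple[ESVTable, dict]:
    """Rarefy read-rich MOTUs to a common total read number.

    ``threshold`` is an integer, or "mean"/"median" of the reference
    dataset's per-MOTU read totals.  For each MOTU above the threshold,
    a without-replacement multivariate hypergeometric subsample of
    exactly ``threshold`` reads is drawn over its (ESV, sample) cells,
    so per-sample read proportions are preserved in expectation.  ESVs
    reduced to zero reads everywhere are eliminated; the returned
    report gives the elimination percentage per dataset.
    """
    ref = summaries.loc[
        summaries["dataset"] == reference_dataset, "total_reads"
    ]
    if threshold == "mean":
        t = int(round(float(ref.mean())))
    elif threshold == "median":
        t = int(round(float(ref.median())))
    else:
        t = int(threshold)
    if t < 1:
        raise ValueError("rarefaction threshold must be >= 1")
    rng = np.random.default_rng(seed)
    reads = esvs.reads.copy()
    dataset_of = summaries.set_index("motu_id")["dataset"]
    for motu_id, sub in esvs.reads.groupby(esvs.motu_ids):
        if motu_id not in dataset_of.index:
            continue
        total = int(sub.to_numpy().sum())
        if total <= t:
            continue
        flat = sub.to_numpy().ravel()
        drawn = rng.multivariate_hypergeometric(flat, t)
        reads.loc[sub.index, :] = drawn.reshape(sub.shape)
    before = esvs.reads.sum(axis=1) > 0
    after = reads.sum(axis=1) > 0
    report = {"threshold": t, "eliminated_pct": {}}
    esv_dataset = esvs.motu_ids.map(dataset_of)
    for label in summaries["dataset"].unique():
        in_label = (esv_dataset == label) & before
        n_before = int(in_label.sum())
        n_lost = int((in_label & ~after).sum())
        report["eliminated_pct"][label] = (
            100.0 * n_lost / n_before if n_before else np.nan
        )
    kept = ESVTable(
        reads.loc[after],
        esvs.motu_ids.loc[after],
        None if esvs.sequences is None else esvs.sequences.loc[after],
    )
    return kept, report


def randomization_balance_test(
    summaries: pd.DataFrame,
    target_size: int,
    n_resamples: int = 100,
    datasets: tuple[str, str] = ("NIS", "NAT"),
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Repeatedly subsample the larger (reference) group to
    ``target_size`` and rerun the Mann-Whitney comparison, to check
    that significance does not hinge on unequal group sizes."""
    a = summaries.loc[summaries["dataset"] == datasets[0], "n_esvs"].to_numpy()
    b = summaries.loc[summaries["dataset"] == datasets[1], "n_esvs"].to_numpy()
    if target_size > len(b):
        raise ValueError("target size exceeds reference group size")
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_resamples):
        sub = rng.choice(b, size=target_size, replace=False)
        if np.ptp(np.concatenate([a, sub])) == 0:
            pvals.append(1.0)
            continue
        pvals.append(
            float(stats.mannwhitneyu(a, sub, alternative="two-sided").pvalue)
        )
    pvals = np.array(pvals)
    return {
        "fraction_significant": float((pvals < alpha).mean()),
        "p_values": pvals,
    }


# ---------------------------------------------------------------------------
# Jost's D from occurrence frequencies


def occurrence_matrix(
    esvs: ESVTable,
    samples: SampleFrame,
    motu_id: str,
    pair: tuple[str, str],
) -> pd.DataFrame:
    """ESV x locality counts of samples-with-detection for one MOTU."""
    member = esvs.motu_ids == motu_id
    if not member.any():
        raise ValueError(f"MOTU {motu_id} has no ESVs")
    block = esvs.reads.loc[member]
    out = {}
    for loc in pair:
        cols = [c for c in samples.samples_of(loc) if c in block.columns]
        if not cols:
            raise ValueError(f"locality {loc} has no samples")
        out[loc] = (block[cols] > 0).sum(axis=1)
    occ = pd.DataFrame(out)
    if (occ.sum(axis=0) == 0).all():
        raise ValueError(f"MOTU {motu_id} absent from both localities")
    return occ


def jost_d_pair(
    occ: pd.DataFrame | np.ndarray,
    clamp: bool = True,
    bias_corrected: bool = True,
) -> float:
    """Jost's D between two localities from haplotype occurrence counts.

    Columns are the two subpopulations, rows the haplotypes.  With
    n = 2 subpopulations, N_j the column totals, p_ij = counts / N_j,
    and ñ the harmonic mean of the N_j:

        H_s  = mean_j (1 - sum_i p_ij^2)
        Ĥ_s  = (ñ / (ñ - 1)) H_s                 (small-sample correction)
        H_t  = 1 - sum_i p̄_i^2,  p̄_i = mean_j p_ij
        Ĥ_t  = H_t + Ĥ_s / (ñ n)
        D    = (n / (n - 1)) (Ĥ_t - Ĥ_s) / (1 - Ĥ_s)

    Sampling noise can push the estimate below zero; with ``clamp``
    such values are reported as 0.  ``bias_corrected=False`` skips the
    corrections (D from raw H_s, H_t).
    """
    counts = np.asarray(occ, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("need a haplotype x 2-locality count matrix")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a locality has zero occurrence counts")
    if (counts.sum(axis=1) > 0).sum() < 2:
        raise ValueError("need >= 2 haplotypes with nonzero counts")
    n_sub = 2
    p = counts / totals[None, :]
    h_s = float(np.mean(1.0 - (p**2).sum(axis=0)))
    h_t = float(1.0 - (p.mean(axis=1) ** 2).sum())
    if bias_corrected:
        n_harm = stats.hmean(totals)
        if n_harm <= 1:
            raise ValueError("harmonic mean sample size <= 1")
        h_s = (n_harm / (n_harm - 1.0)) * h_s
        h_t = h_t + h_s / (n_harm * n_sub)
    if h_s >= 1.0:
        raise ValueError("within-locality diversity estimate is 1; D undefined")
    d = (n_sub / (n_sub - 1.0)) * (h_t - h_s) / (1.0 - h_s)
    return max(0.0, d) if clamp else d


@dataclass
class DPairResult:
    locality_pair: tuple[str, str]
    dataset: str
    n_motus_used: int
    mean_d: float
    per_motu: pd.DataFrame = field(default_factory=pd.DataFrame)


def _eligible_occurrence(
    occ: pd.DataFrame, per_locality: bool
) -> bool:
    """Eligibility: MOTU present in both localities, and polymorphic.

    Default reading: >= 2 ESVs with nonzero occurrence summed over the
    pair; strict mode requires >= 2 ESVs in *each* locality.
    """
    present = occ.sum(axis=0) > 0
    if not present.all():
        return False
    if per_locality:
        return bool(((occ > 0).sum(axis=0) >= 2).all())
    return bool(((occ.sum(axis=1) > 0).sum()) >= 2)


def d_between_pair(
    esvs: ESVTable,
    samples: SampleFrame,
    motus: MOTUTable,
    dataset: str,
    pair: tuple[str, str],
    per_locality_eligibility: bool = False,
    clamp: bool = True,
) -> DPairResult:
    """Mean Jost's D over eligible MOTUs of a dataset for one pair."""
    rows = []
    for motu_id in motus.ids_with_label(dataset):
        member = esvs.motu_ids == motu_id
        if not member.any():
            continue
        try:
            occ = occurrence_matrix(esvs, samples, motu_id, pair)
        except ValueError:
            continue
        if not _eligible_occurrence(occ, per_locality_eligibility):
            continue
        try:
            d = jost_d_pair(occ, clamp=clamp)
        except ValueError:
            continue
        rows.append({"motu_id": motu_id, "d": d})
    per_motu = pd.DataFrame(rows, columns=["motu_id", "d"])
    mean_d = float(per_motu["d"].mean()) if len(per_motu) else np.nan
    return DPairResult(pair, dataset, len(per_motu), mean_d, per_motu)


@dataclass
class DConnectivityReport:
    pair_means: pd.DataFrame  # locality_1, locality_2, columns per dataset
    t_statistic: float
    p_value: float
    pearson_r: float
    pearson_p: float


def mean_d_between_localities(
    esvs: ESVTable,
    samples: SampleFrame,
    motus: MOTUTable,
    datasets: tuple[str, str] = ("NIS", "NAT"),
    per_locality_eligibility: bool = False,
) -> DConnectivityReport:
    """Mean D per locality pair for two datasets, compared pairwise.

    Across the locality pairs (6 for four localities) the two datasets'
    mean-D vectors are compared with a paired t-test, and their Pearson
    correlation quantifies whether they share a spatial pattern.  Pairs
    with no eligible MOTU in either dataset are excluded from the
    paired statistics.
    """
    pairs = list(itertools.combinations(samples.localities, 2))
    rows = []
    for pair in pairs:
        row = {"locality_1": pair[0], "locality_2": pair[1]}
        for ds in datasets:
            res = d_between_pair(
                esvs, samples, motus, ds, pair,
                per_locality_eligibility=per_locality_eligibility,
            )
            row[f"mean_d_{ds}"] = res.mean_d
            row[f"n_motus_{ds}"] = res.n_motus_used
        rows.append(row)
    table = pd.DataFrame(rows)
    a = table[f"mean_d_{datasets[0]}"].to_numpy()
    b = table[f"mean_d_{datasets[1]}"].to_numpy()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() >= 2 and not np.allclose(a[ok], b[ok]):
        t, p = stats.ttest_rel(a[ok], b[ok])
        if np.ptp(a[ok]) > 0 and np.ptp(b[ok]) > 0:
            r = stats.pearsonr(a[ok], b[ok])
            r_stat, r_p = float(r.statistic), float(r.pvalue)
        else:
            r_stat, r_p = np.nan, np.nan
    elif ok.sum() >= 2:
        t, p, r_stat, r_p = 0.0, 1.0, np.nan, np.nan
    else:
        t, p, r_stat, r_p = np.nan, np.nan, np.nan, np.nan
    return DConnectivityReport(table, float(t), float(p), r_stat, r_p)
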