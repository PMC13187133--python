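"""Alpha diversity: rarefied MOTU richness, Shannon diversity, and the
group comparisons used for port communities.

Richness is rarefied analytically (hypergeometric expectation of the
number of MOTUs in a without-replacement subsample at the common
depth); Shannon diversity (natural log) is computed on a seeded random
subsample at that depth, optionally averaged over several draws.  The
common depth defaults to the minimum total reads over retained samples.

Group comparisons follow the field's convention for these metrics:
one-way ANOVA with Tukey HSD post-hocs for Shannon, and Kruskal-Wallis
with Dunn post-hocs for richness (whose distribution typically violates
ANOVA assumptions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .tables_io import MOTUTable, SampleFrame


def rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Expected number of taxa in a without-replacement subsample.

    E[S] = sum_i [1 - C(N - N_i, depth) / C(N, depth)] with N the total
    count.  Computed with log-gammas for numerical stability.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    if depth > n_total:
        raise ValueError(f"depth {depth} exceeds total reads {n_total}")
    if depth < 0:
        raise ValueError("depth must be nonnegative")

    def log_comb(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = n_total - counts
    p_absent = np.zeros_like(counts, dtype=float)
    feasible = rest >= depth
    p_absent[feasible] = np.exp(
        log_comb(rest[feasible], depth) - log_comb(np.array(n_total), depth)
    )
    return float(np.sum(1.0 - p_absent))


def shannon(abundances: np.ndarray) -> float:
    """Shannon diversity H' in nats over nonzero relative abundances."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = a.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def rarefy_counts(
    counts: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """One without-replacement subsample of ``depth`` reads."""
    counts = np.asarray(counts, dtype=np.int64)
    if depth > counts.sum():
        raise ValueError("depth exceeds total reads")
    return rng.multivariate_hypergeometric(counts, depth)


@dataclass
class AlphaResult:
    table: pd.DataFrame  # sample_id, dataset, richness, shannon, depth_used


def alpha_table(
    motus: MOTUTable,
    samples: SampleFrame,
    scope_ids: list[str],
    dataset: str,
    depth: int | None = None,
    seed: int = 0,
    n_draws: int = 1,
) -> AlphaResult:
    """Per-sample rarefied richness and Shannon diversity for a dataset.

    ``depth`` defaults to the minimum per-sample total over true
    samples (computed on the scoped MOTU set).  Samples with fewer
    reads than the depth in the scoped set are skipped.
    """
    reads = motus.reads.loc[scope_ids, samples.true_sample_ids]
    totals = reads.sum(axis=0)
    if depth is None:
        depth = int(totals[totals > 0].min())
    rng = np.random.default_rng(seed)
    rows = []
    for sample_id in reads.columns:
        counts = reads[sample_id].to_numpy()
        if counts.sum() < depth or counts.sum() == 0:
            continue
        rich = rarefied_richness(counts, depth)
        hs = [
            shannon(rarefy_counts(counts, depth, rng)) for _ in range(n_draws)
        ]
        rows.append(
            {
                "sample_id": sample_id,
                "dataset": dataset,
                "locality": samples.data.at[sample_id, "locality"],
                "richness": rich,
                "shannon": float(np.mean(hs)),
                "depth_used": depth,
            }
        )
    return AlphaResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# group comparisons


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with T the tie correction sum(t^3 - t) / (12 (N - 1)).  Two-sided
    p-values, with Holm-adjusted values alongside.
    """
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n_total = len(all_vals)
    ranks = stats.rankdata(all_vals)
    mean_ranks, sizes = {}, {}
    pos = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[pos : pos + k].mean()
        sizes[g] = k
        pos += k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            se = np.sqrt(var_base * (1 / sizes[gi] + 1 / sizes[gj]))
            z = 0.0 if se == 0 else (mean_ranks[gi] - mean_ranks[gj]) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group1": gi, "group2": gj, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    return out


@dataclass
class GroupComparison:
    metric: str
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame


def compare_alpha(
    values: pd.DataFrame, metric: str, group: str = "locality"
) -> GroupComparison:
    """Compare an alpha metric across groups.

    Shannon -> one-way ANOVA + Tukey HSD; richness -> Kruskal-Wallis +
    Dunn pairwise tests.
    """
    grouped = {
        g: sub[metric].to_numpy() for g, sub in values.groupby(group)
    }
    if len(grouped) < 2 or any(len(v) < 2 for v in grouped.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = list(grouped.values())
    if metric == "shannon":
        stat, p = stats.f_oneway(*arrays)
        tukey = pairwise_tukeyhsd(
            values[metric].to_numpy(), values[group].to_numpy()
        )
        pairwise = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        return GroupComparison(metric, "anova_tukey", float(stat), float(p), pairwise)
    if np.ptp(np.concatenate(arrays)) == 0:
        stat, p = 0.0, 1.0  # tied constant data: no evidence of differences
    else:
        stat, p = stats.kruskal(*arrays)
    return GroupComparison(
        metric, "kruskal_dunn", float(stat), float(p), _dunn_posthoc(grouped)
    )


# ---------------------------------------------------------------------------
# composition summaries


def composition_summary(
    motus: MOTUTable,
    samples: SampleFrame,
    scope_ids: list[str],
    min_fraction: float = 0.05,
) -> pd.DataFrame:
    """Mean per-sample relative read proportions by phylum per locality.

    Phyla below ``min_fraction`` of a locality's reads are pooled as
    "Others"; MOTUs without phylum are reported as "Unidentified".
    Proportions sum to 1 within each locality.
    """
    reads = motus.reads.loc[scope_ids]
    phyla = motus.taxonomy.loc[scope_ids, "phylum"].replace("", "Unidentified")
    out = {}
    for loc in samples.localities:
        cols = [c for c in samples.samples_of(loc) if c in reads.columns]
        sub = reads[cols]
        totals = sub.sum(axis=0)
        keep = totals > 0
        rel = sub.loc[:, keep] / totals[keep]
        by_phylum = rel.groupby(phyla).sum().mean(axis=1)
        small = (by_phylum < min_fraction) & (by_phylum.index != "Unidentified")
        pooled = by_phylum[~small]
        if small.any():
            pooled = pd.concat(
                [pooled, pd.Series({"Others": by_phylum[small].sum()})]
            )
        out[loc] = pooled
    result = pd.DataFrame(out).fillna(0.0)
    result.index.name = "phylum"
    return result
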