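"""Beta diversity: Bray-Curtis dissimilarities on relative read
abundances, Sørensen sharing between localities, membership (upset)
counts, NMDS ordination, PERMANOVA / dispersion permutation tests, and
temporal turnover.

Bray-Curtis is computed on per-sample relative abundances without
rarefaction.  PERMANOVA follows Anderson's one-way pseudo-F on the
distance matrix with the (count + 1)/(n_perm + 1) permutation p-value;
the dispersion test computes distances to group centroids in
principal-coordinate space with the standard correction for negative
eigenvalues and permutes those distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS

from .tables_io import SampleFrame


def relative_abundance(reads: pd.DataFrame) -> pd.DataFrame:
    """Normalise a sample x taxon read matrix to row sums of 1."""
    totals = reads.sum(axis=1)
    if (totals == 0).any():
        zero = reads.index[totals == 0].tolist()
        raise ValueError(f"zero-sum rows: {zero}")
    return reads.div(totals, axis=0)


def bray_curtis(reads: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on internally normalised read rows.

    ``reads`` is sample x taxon; counts are converted to relative
    abundances first, so BC(x, y) = 1 - 2 sum(min(x, y)).
    """
    rel = relative_abundance(reads)
    condensed = pdist(rel.to_numpy(), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(reads.index))


# ---------------------------------------------------------------------------
# incidence-based sharing


def presence_by_locality(
    reads: pd.DataFrame, samples: SampleFrame
) -> pd.DataFrame:
    """Taxon x locality incidence (present iff any read in any sample)."""
    out = {}
    for loc in samples.localities:
        cols = [c for c in samples.samples_of(loc) if c in reads.columns]
        out[loc] = (reads[cols].sum(axis=1) > 0).astype(int)
    return pd.DataFrame(out)


def sorensen_between_localities(
    presence: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Sørensen similarity per locality pair and the mean over pairs.

    S(A, B) = 2|A ∩ B| / (|A| + |B|) on pooled incidence.
    """
    locs = list(presence.columns)
    rows = []
    for a, b in itertools.combinations(locs, 2):
        in_a = presence[a].to_numpy(bool)
        in_b = presence[b].to_numpy(bool)
        size_a, size_b = int(in_a.sum()), int(in_b.sum())
        if size_a == 0 or size_b == 0:
            raise ValueError(f"locality with no taxa: {a if size_a == 0 else b}")
        shared = int((in_a & in_b).sum())
        rows.append(
            {
                "locality_1": a,
                "locality_2": b,
                "shared": shared,
                "sorensen": 2 * shared / (size_a + size_b),
            }
        )
    table = pd.DataFrame(rows)
    return table, float(table["sorensen"].mean())


def sorensen_between_samples(reads: pd.DataFrame) -> DistanceMatrix:
    """Sample-pair Sørensen *dissimilarity* (1 - similarity) matrix."""
    inc = (reads.to_numpy() > 0).astype(float)
    condensed = pdist(inc, metric="dice")  # Dice distance = 1 - Sørensen
    return DistanceMatrix(squareform(condensed), ids=list(reads.index))


def membership_patterns(presence: pd.DataFrame) -> pd.DataFrame:
    """Exact upset counts: taxa present in exactly each locality subset.

    Returns one row per nonempty subset with its count, plus the
    derived summaries ``fraction_unique`` (taxa restricted to a single
    locality) and ``fraction_everywhere`` accessible via
    :func:`membership_summary`.
    """
    locs = list(presence.columns)
    inc = presence.to_numpy(bool)
    patterns: dict[frozenset, int] = {}
    for row in inc:
        key = frozenset(l for l, present in zip(locs, row) if present)
        if key:
            patterns[key] = patterns.get(key, 0) + 1
    rows = [
        {
            "localities": "+".join(sorted(k)),
            "n_localities": len(k),
            "count": v,
        }
        for k, v in patterns.items()
    ]
    return (
        pd.DataFrame(rows, columns=["localities", "n_localities", "count"])
        .sort_values(["n_localities", "localities"])
        .reset_index(drop=True)
    )


def membership_summary(patterns: pd.DataFrame, n_localities: int) -> dict:
    total = int(patterns["count"].sum())
    unique = int(patterns.loc[patterns["n_localities"] == 1, "count"].sum())
    everywhere = int(
        patterns.loc[patterns["n_localities"] == n_localities, "count"].sum()
    )
    shared = total - unique
    return {
        "total": total,
        "fraction_unique": unique / total if total else np.nan,
        "fraction_shared": shared / total if total else np.nan,
        "fraction_everywhere": everywhere / total if total else np.nan,
    }


# ---------------------------------------------------------------------------
# ordination


@dataclass
class NMDSResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool


def nmds(
    dm: DistanceMatrix, k: int = 2, seed: int = 0, n_starts: int = 8
) -> NMDSResult:
    """Non-metric MDS with multiple random starts; best stress kept.

    Stress is Kruskal's normalised stress-1; runs with the same seed
    return identical configurations.
    """
    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
        eps=1e-9,
    )
    coords = mds.fit_transform(dm.data)
    return NMDSResult(
        pd.DataFrame(
            coords, index=list(dm.ids), columns=[f"axis_{i+1}" for i in range(k)]
        ),
        float(mds.stress_),
        bool(mds.n_iter_ < 500),
    )


# ---------------------------------------------------------------------------
# permutation tests


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's one-way pseudo-F from squared distances and labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        return np.inf
    return (ss_among / df_among) / (ss_within / df_within)


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    test: str


def permanova(
    dm: DistanceMatrix,
    labels: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """One-way PERMANOVA; p = (#{F_perm >= F_obs} + 1) / (n_perm + 1)."""
    labels = pd.Series(np.asarray(labels), index=list(dm.ids))
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (np.bincount(codes) < 2).any():
        raise ValueError("every group needs at least two members")
    d2 = dm.data**2
    f_obs = _pseudo_f(d2, codes, len(uniques))
    rng = np.random.default_rng(seed)
    tol = 1e-12 * max(1.0, abs(f_obs))  # count float-tied permutations
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(uniques)) >= f_obs - tol:
            count += 1
    return PermutationTestResult(
        f_obs, (count + 1) / (n_perm + 1), n_perm, "permanova"
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    labels: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    labels = pd.Series(np.asarray(labels), index=list(dm.ids))
    rows = []
    for i, (a, b) in enumerate(
        itertools.combinations(sorted(labels.unique()), 2)
    ):
        ids = labels.index[labels.isin([a, b])].tolist()
        sub = dm.filter(ids)
        res = permanova(sub, labels.loc[ids], n_perm=n_perm, seed=seed + i)
        rows.append(
            {
                "group1": a,
                "group2": b,
                "pseudo_F": res.statistic,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def _centroid_distances(
    dm: DistanceMatrix, codes: np.ndarray, n_groups: int
) -> np.ndarray:
    """Distance of each point to its group centroid in PCoA space.

    All axes are kept; axes with negative eigenvalues contribute
    negatively to squared distances (Anderson's correction), and the
    squared distances are clamped at zero.
    """
    a = -0.5 * dm.data**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    coords = eigvecs * np.sqrt(np.abs(eigvals))[None, :]
    signs = np.sign(eigvals)
    d2 = np.zeros(n)
    for grp in range(n_groups):
        idx = np.flatnonzero(codes == grp)
        centroid = coords[idx].mean(axis=0)
        diff2 = (coords[idx] - centroid) ** 2
        d2[idx] = np.clip((diff2 * signs[None, :]).sum(axis=1), 0, None)
    return np.sqrt(d2)


def permdisp(
    dm: DistanceMatrix,
    labels: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of multivariate dispersion homogeneity."""
    labels = pd.Series(np.asarray(labels), index=list(dm.ids))
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise ValueError("dispersion test needs at least two groups")
    if (np.bincount(codes) < 2).any():
        raise ValueError("every group needs at least two members")
    dists = _centroid_distances(dm, codes, len(uniques))

    def anova_f(values: np.ndarray) -> float:
        groups = [values[codes == g] for g in range(len(uniques))]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = stats.f_oneway(*groups).statistic
        return float(f) if np.isfinite(f) else 0.0

    f_obs = anova_f(dists)
    rng = np.random.default_rng(seed)
    tol = 1e-12 * max(1.0, abs(f_obs))  # count float-tied permutations
    count = 0
    for _ in range(n_perm):
        if anova_f(rng.permutation(dists)) >= f_obs - tol:
            count += 1
    return PermutationTestResult(
        f_obs, (count + 1) / (n_perm + 1), n_perm, "permdisp"
    )


# ---------------------------------------------------------------------------
# temporal turnover and dataset comparison


def temporal_turnover(
    dm: DistanceMatrix, samples: SampleFrame
) -> pd.DataFrame:
    """Mean dissimilarity between consecutive time points.

    For each locality and each consecutive pair of time points, the
    mean over all cross-time sample pairs is taken; the returned series
    averages localities per consecutive pair.  Time points with no
    samples in a locality are flagged as gaps (NaN).
    """
    tps = samples.time_points()
    ids = list(dm.ids)
    rows = []
    for t_prev, t_next in zip(tps[:-1], tps[1:]):
        per_loc = []
        gap = False
        for loc in samples.localities:
            meta = samples.data
            prev_ids = [
                s
                for s in samples.samples_of(loc)
                if meta.at[s, "time_point"] == t_prev and s in ids
            ]
            next_ids = [
                s
                for s in samples.samples_of(loc)
                if meta.at[s, "time_point"] == t_next and s in ids
            ]
            if not prev_ids or not next_ids:
                gap = True
                continue
            vals = [dm[a, b] for a in prev_ids for b in next_ids]
            per_loc.append(np.mean(vals))
        rows.append(
            {
                "time_from": t_prev,
                "time_to": t_next,
                "mean_dissimilarity": float(np.mean(per_loc))
                if per_loc
                else np.nan,
                "gap": gap,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PairedComparison:
    mean_1: float
    mean_2: float
    t_statistic: float
    p_value: float


def compare_mean_dissimilarity(
    dm_1: DistanceMatrix, dm_2: DistanceMatrix
) -> PairedComparison:
    """Paired t-test over matching sample-pair dissimilarities."""
    if list(dm_1.ids) != list(dm_2.ids):
        raise ValueError("distance matrices cover different samples")
    v1 = dm_1.condensed_form()
    v2 = dm_2.condensed_form()
    if np.allclose(v1, v2):
        return PairedComparison(float(v1.mean()), float(v2.mean()), 0.0, 1.0)
    t, p = stats.ttest_rel(v1, v2)
    return PairedComparison(float(v1.mean()), float(v2.mean()), float(t), float(p))


def season_label(temperature: float, threshold: float = 20.0) -> str:
    """Warm/cold labelling utility (threshold in deg C)."""
    return "warm" if temperature >= threshold else "cold"
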