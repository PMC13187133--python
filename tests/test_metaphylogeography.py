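import itertools

import numpy as np
import pandas as pd
import pytest

from metaport.metaphylogeography import (
    d_between_pair,
    esv_richness,
    jost_d_pair,
    mean_d_between_localities,
    motu_genetic_summaries,
    occurrence_matrix,
    randomization_balance_test,
    rarefy_motu_reads,
    reads_esvs_regression,
)
from metaport.synthetic_data import simulate
from metaport.tables_io import partition_datasets

from conftest import make_esvs, make_samples, tiny_sim_config


def oracle_jost_d(counts) -> float:
    """Scalar-loop transcription of the bias-corrected D estimator,
    kept independent of the vectorised implementation."""
    counts = [[float(c) for c in row] for row in counts]
    n_hap = len(counts)
    totals = [sum(counts[i][j] for i in range(n_hap)) for j in range(2)]
    p = [[counts[i][j] / totals[j] for j in range(2)] for i in range(n_hap)]
    h_s = 0.0
    for j in range(2):
        h_s += (1.0 - sum(p[i][j] ** 2 for i in range(n_hap))) / 2.0
    n_harm = 2.0 / (1.0 / totals[0] + 1.0 / totals[1])
    hs_est = (n_harm / (n_harm - 1.0)) * h_s
    h_t = 1.0 - sum(((p[i][0] + p[i][1]) / 2.0) ** 2 for i in range(n_hap))
    ht_est = h_t + hs_est / (n_harm * 2.0)
    return 2.0 * (ht_est - hs_est) / (1.0 - hs_est)


class TestJostD:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([[5, 0], [0, 5]], 1.0),  # fixed alternative haplotypes
            ([[3, 3], [3, 3]], 0.0),  # raw -0.25, clamped
            ([[4, 1], [1, 4]], 0.4667),
        ],
    )
    def test_hand_values(self, counts, expected):
        assert jost_d_pair(np.array(counts)) == pytest.approx(expected, abs=5e-5)

    def test_clamping_preserves_raw_value_when_disabled(self):
        raw = jost_d_pair(np.array([[3, 3], [3, 3]]), clamp=False)
        assert raw == pytest.approx(-0.25)

    def test_uncorrected_estimator_flag(self):
        counts = np.array([[4, 1], [1, 4]])
        h_s = 0.32
        h_t = 0.5
        assert jost_d_pair(counts, bias_corrected=False) == pytest.approx(
            2 * (h_t - h_s) / (1 - h_s)
        )

    def test_matches_bruteforce_on_all_small_count_matrices(self):
        """Exhaustive oracle over 2-haplotype x 2-locality matrices with
        column totals up to 6."""
        checked = 0
        for t1, t2 in itertools.product(range(1, 7), repeat=2):
            if min(t1, t2) <= 1:
                continue  # harmonic-mean correction undefined at n=1
            for a in range(t1 + 1):
                for c in range(t2 + 1):
                    counts = np.array([[a, c], [t1 - a, t2 - c]])
                    if (counts.sum(axis=1) > 0).sum() < 2:
                        continue
                    try:
                        expected = oracle_jost_d(counts)
                    except ZeroDivisionError:
                        # within-locality diversity estimate hits 1:
                        # the estimator is undefined and must refuse
                        with pytest.raises(ValueError):
                            jost_d_pair(counts, clamp=False)
                        continue
                    got = jost_d_pair(counts, clamp=False)
                    assert got == pytest.approx(expected, abs=1e-12)
                    assert jost_d_pair(counts) == pytest.approx(
                        max(0.0, expected), abs=1e-12
                    )
                    checked += 1
        assert checked > 100

    def test_identical_frequencies_equal_totals_clamp_to_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            col = rng.integers(0, 5, size=4)
            if np.count_nonzero(col) < 2 or col.sum() < 2:
                continue
            counts = np.column_stack([col, col])
            assert jost_d_pair(counts, clamp=False) <= 1e-12
            assert jost_d_pair(counts) == 0.0

    def test_error_cases(self):
        with pytest.raises(ValueError):
            jost_d_pair(np.array([[1, 0], [1, 0]]))  # one locality empty
        with pytest.raises(ValueError):
            jost_d_pair(np.array([[4, 4], [0, 0]]))  # single haplotype


class TestOccurrenceMatrix:
    @pytest.fixture
    def setup(self):
        samples = make_samples(
            [
                ("a1", "A", 1, 1, "true_sample"),
                ("a2", "A", 1, 2, "true_sample"),
                ("a3", "A", 2, 1, "true_sample"),
                ("b1", "B", 1, 1, "true_sample"),
                ("b2", "B", 1, 2, "true_sample"),
            ]
        )
        esvs = make_esvs(
            {
                "m1_x": [9, 3, 0, 0, 0],
                "m1_y": [0, 2, 0, 5, 1],
                "m2_z": [0, 0, 0, 0, 4],
            },
            ["a1", "a2", "a3", "b1", "b2"],
            motu_of={"m1_x": "m1", "m1_y": "m1", "m2_z": "m2"},
        )
        return esvs, samples

    def test_counts_samples_with_detection(self, setup):
        esvs, samples = setup
        occ = occurrence_matrix(esvs, samples, "m1", ("A", "B"))
        assert occ.loc["m1_x", "A"] == 2
        assert occ.loc["m1_x", "B"] == 0
        assert occ.loc["m1_y", "A"] == 1
        assert occ.loc["m1_y", "B"] == 2

    def test_absent_motu_errors(self, setup):
        esvs, samples = setup
        with pytest.raises(ValueError):
            occurrence_matrix(esvs, samples, "m1", ("A", "C"))


class TestEsvRichness:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, 40) + 1
        summaries = pd.DataFrame(
            {
                "motu_id": [f"m{i}" for i in range(80)],
                "dataset": ["NIS"] * 40 + ["NAT"] * 40,
                "n_esvs": np.concatenate([counts, counts]),
                "total_reads": np.ones(80, int) * 100,
            }
        )
        res = randomization_balance_test(summaries, 40, n_resamples=50, seed=1)
        assert res["fraction_significant"] <= 0.1

    def test_threefold_shift_detected(self):
        rng = np.random.default_rng(1)
        nis = rng.poisson(9, 60) + 1
        nat = rng.poisson(3, 60) + 1
        from scipy import stats

        p = stats.mannwhitneyu(nis, nat, alternative="two-sided").pvalue
        assert p < 1e-3

    def test_per_locality_stratification(self, sim_cascade, sim_bundle):
        summaries, reports = esv_richness(
            sim_cascade.esvs,
            sim_cascade.motus,
            sim_cascade.samples,
            stratify="locality",
        )
        assert set(summaries["stratum"]) <= set(sim_cascade.samples.localities)
        assert all(r.stratum in sim_cascade.samples.localities for r in reports)

    def test_single_esv_motus_counted_as_invariant(self, sim_cascade):
        summaries, _ = esv_richness(sim_cascade.esvs, sim_cascade.motus)
        assert (summaries["n_esvs"] >= 1).all()
        assert (summaries["total_reads"] >= summaries["n_esvs"]).all()


class TestReadsEsvsRegression:
    def test_perfect_loglog_fixture(self):
        reads = np.array([10, 100, 1000, 10000])
        esvs = (reads**0.5).astype(float)
        summaries = pd.DataFrame(
            {
                "motu_id": list("abcdefgh"),
                "dataset": ["NIS"] * 4 + ["NAT"] * 4,
                "n_esvs": np.concatenate([esvs, esvs * 2]),
                "total_reads": np.concatenate([reads, reads]),
            }
        )
        rep = reads_esvs_regression(summaries)
        assert rep.pearson_r["NIS"] == pytest.approx(1.0)
        assert rep.slopes["NIS"] == pytest.approx(0.5)
        assert rep.slopes["NAT"] == pytest.approx(0.5)
        # equal slopes: interaction term far from significant
        assert rep.interaction_p > 0.5

    def test_different_slopes_detected(self):
        rng = np.random.default_rng(2)
        reads = np.exp(rng.uniform(3, 12, 80))
        y_nis = 0.8 * np.log(reads[:40]) + rng.normal(0, 0.2, 40)
        y_nat = 0.2 * np.log(reads[40:]) + rng.normal(0, 0.2, 40)
        summaries = pd.DataFrame(
            {
                "motu_id": [f"m{i}" for i in range(80)],
                "dataset": ["NIS"] * 40 + ["NAT"] * 40,
                "n_esvs": np.exp(np.concatenate([y_nis, y_nat])),
                "total_reads": reads,
            }
        )
        rep = reads_esvs_regression(summaries)
        assert rep.interaction_p < 0.01
        assert rep.slopes["NIS"] > rep.slopes["NAT"]


class TestRarefyMotuReads:
    def test_totals_exactly_threshold(self, sim_cascade):
        summaries = motu_genetic_summaries(sim_cascade.esvs, sim_cascade.motus)
        rarefied, report = rarefy_motu_reads(
            sim_cascade.esvs, summaries, threshold="median", seed=3
        )
        t = report["threshold"]
        totals = rarefied.reads.groupby(rarefied.motu_ids).sum().sum(axis=1)
        before = sim_cascade.esvs.reads.groupby(sim_cascade.esvs.motu_ids).sum().sum(axis=1)
        scoped = set(summaries["motu_id"])  # only NIS/NAT MOTUs are rarefied
        for motu_id, total in totals.items():
            if motu_id in scoped and before[motu_id] > t:
                assert total == t
            else:
                assert total == before[motu_id]

    def test_motu_at_or_below_threshold_untouched(self):
        esvs = make_esvs(
            {"m1_a": [30, 30], "m2_a": [10, 5]},
            ["s1", "s2"],
            motu_of={"m1_a": "m1", "m2_a": "m2"},
        )
        summaries = pd.DataFrame(
            {
                "motu_id": ["m1", "m2"],
                "dataset": ["NIS", "NAT"],
                "n_esvs": [1, 1],
                "total_reads": [60, 15],
            }
        )
        rarefied, _ = rarefy_motu_reads(esvs, summaries, threshold=15, seed=0)
        assert rarefied.reads.loc["m2_a"].tolist() == [10, 5]
        assert rarefied.reads.loc["m1_a"].sum() == 15

    def test_single_esv_motu_never_eliminated(self):
        esvs = make_esvs({"m1_a": [500, 500]}, ["s1", "s2"], motu_of={"m1_a": "m1"})
        summaries = pd.DataFrame(
            {"motu_id": ["m1"], "dataset": ["NIS"], "n_esvs": [1], "total_reads": [1000]}
        )
        rarefied, report = rarefy_motu_reads(esvs, summaries, threshold=1, seed=0)
        assert rarefied.reads.loc["m1_a"].sum() == 1
        assert report["eliminated_pct"]["NIS"] == 0.0

    def test_per_sample_proportions_preserved_in_expectation(self):
        # MOTU with 60/40 reads over two samples rarefied to 50:
        # expected split 30/20 by the multivariate hypergeometric
        esvs = make_esvs({"m1_a": [60, 40]}, ["s1", "s2"], motu_of={"m1_a": "m1"})
        summaries = pd.DataFrame(
            {"motu_id": ["m1"], "dataset": ["NIS"], "n_esvs": [1], "total_reads": [100]}
        )
        draws = np.array(
            [
                rarefy_motu_reads(esvs, summaries, threshold=50, seed=s)[0]
                .reads.loc["m1_a"]
                .to_numpy()
                for s in range(200)
            ]
        )
        assert (draws.sum(axis=1) == 50).all()
        # binomial-scale standard error of the mean of 200 draws
        se = np.sqrt(50 * 0.6 * 0.4 / 200)
        assert abs(draws[:, 0].mean() - 30) < 3 * se

    def test_threshold_below_one_errors(self, sim_cascade):
        summaries = motu_genetic_summaries(sim_cascade.esvs, sim_cascade.motus)
        with pytest.raises(ValueError):
            rarefy_motu_reads(sim_cascade.esvs, summaries, threshold=0)


class TestRandomizationBalance:
    def test_seeded_run_reproducible(self, sim_cascade):
        summaries = motu_genetic_summaries(sim_cascade.esvs, sim_cascade.motus)
        n = int((summaries["dataset"] == "NIS").sum())
        a = randomization_balance_test(summaries, n, n_resamples=20, seed=5)
        b = randomization_balance_test(summaries, n, n_resamples=20, seed=5)
        assert np.array_equal(a["p_values"], b["p_values"])

    def test_oversized_target_errors(self, sim_cascade):
        summaries = motu_genetic_summaries(sim_cascade.esvs, sim_cascade.motus)
        with pytest.raises(ValueError):
            randomization_balance_test(summaries, 10_000)


class TestMeanDBetweenLocalities:
    def test_single_eligible_motu_mean_equals_its_d(self):
        samples = make_samples(
            [
                ("a1", "A", 1, 1, "true_sample"),
                ("a2", "A", 1, 2, "true_sample"),
                ("b1", "B", 1, 1, "true_sample"),
                ("b2", "B", 1, 2, "true_sample"),
            ]
        )
        esvs = make_esvs(
            {"m1_x": [9, 9, 0, 8], "m1_y": [0, 7, 6, 6]},
            ["a1", "a2", "b1", "b2"],
            motu_of={"m1_x": "m1", "m1_y": "m1"},
        )
        from metaport.tables_io import motu_table_from_esvs

        motus = motu_table_from_esvs(esvs)
        motus.dataset_labels[:] = "NIS"
        res = d_between_pair(esvs, samples, motus, "NIS", ("A", "B"))
        occ = occurrence_matrix(esvs, samples, "m1", ("A", "B"))
        assert res.n_motus_used == 1
        assert res.mean_d == pytest.approx(jost_d_pair(occ))

    def test_zero_differentiation_gives_near_zero_mean_d(self):
        # enough occurrences per locality that the clamped estimator's
        # small-sample noise does not inflate the mean
        bundle = simulate(
            tiny_sim_config(
                21,
                theta_nis=0.0,
                theta_nat=0.0,
                theta_other=0.0,
                occupancy_nat=0.8,
                occupancy_other=0.8,
            )
        )
        rep = mean_d_between_localities(
            bundle.esvs, bundle.samples, bundle.motus
        )
        means = rep.pair_means.filter(like="mean_d").mean()
        assert (means < 0.08).all()

    def test_strict_per_locality_eligibility_uses_fewer_motus(self, sim_bundle):
        loose = mean_d_between_localities(
            sim_bundle.esvs, sim_bundle.samples, sim_bundle.motus
        )
        strict = mean_d_between_localities(
            sim_bundle.esvs,
            sim_bundle.samples,
            sim_bundle.motus,
            per_locality_eligibility=True,
        )
        for ds in ("NIS", "NAT"):
            assert (
                strict.pair_means[f"n_motus_{ds}"]
                <= loose.pair_means[f"n_motus_{ds}"]
            ).all()
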