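import itertools

import numpy as np
import pandas as pd
import pytest

from evotherm.stats import (
    DistanceMatrix,
    amova,
    dispersion_test,
    distance_matrix,
    pca,
    permanova,
    top_loading_associations,
    weighted_ks_enrichment,
)


def frame(array, prefix="s"):
    array = np.asarray(array, dtype=float)
    return pd.DataFrame(
        array,
        index=[f"L{i}" for i in range(array.shape[0])],
        columns=[f"{prefix}{j}" for j in range(array.shape[1])],
    )


class TestDistanceMatrix:
    def test_identical_columns_zero(self):
        df = frame(np.tile([[0.1], [0.9]], (1, 3)))
        dm = distance_matrix(df)
        assert np.all(dm.values == 0)

    def test_hand_arithmetic(self):
        df = frame(np.array([[0.0, 0.0], [0.5, 0.5], [1.0, 0.0]]))
        dm = distance_matrix(df)
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_diagonal(self, rng):
        df = frame(rng.uniform(size=(10, 5)))
        dm = distance_matrix(df)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_plain_is_sqrt_of_squared(self, rng):
        df = frame(rng.uniform(size=(8, 4)))
        sq = distance_matrix(df, squared=True)
        pl = distance_matrix(df, squared=False)
        assert np.allclose(pl.values**2, sq.values)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(frame(np.ones((3, 1))))

    def test_masked_cells_rejected(self):
        df = frame(np.array([[0.1, np.nan], [0.2, 0.3]]))
        with pytest.raises(ValueError):
            distance_matrix(df)


def brute_force_two_level(d2, groups):
    """Independent sums-of-squares AMOVA oracle (explicit pair loops)."""
    n = len(groups)
    ss_total = sum(d2[i, j] for i, j in itertools.combinations(range(n), 2)) / n
    ss_within = 0.0
    labels = sorted(set(groups))
    for g in labels:
        idx = [i for i in range(n) if groups[i] == g]
        ss_within += sum(
            d2[i, j] for i, j in itertools.combinations(idx, 2)
        ) / len(idx)
    ss_among = ss_total - ss_within
    g = len(labels)
    sizes = [groups.count(lab) for lab in labels]
    ms_within = ss_within / (n - g)
    n0 = (n - sum(s**2 for s in sizes) / n) / (g - 1)
    sigma_a = (ss_among / (g - 1) - ms_within) / n0
    return sigma_a, ms_within


class TestAmova:
    def toy(self, rng):
        x = rng.uniform(0, 1, (15, 6))
        x[:4, 3:] += 0.6
        return frame(x), ["A", "A", "A", "B", "B", "B"]

    def test_brute_force_oracle(self, rng):
        df, groups = self.toy(rng)
        dm = distance_matrix(df)
        res = amova(dm, groups, n_perm=99, seed=0)
        sigma_a, sigma_w = brute_force_two_level(dm.values, groups)
        assert res.components.loc["between_treatments", "sigma2"] == pytest.approx(sigma_a)
        assert res.components.loc["within_treatment", "sigma2"] == pytest.approx(sigma_w)

    def test_percentages_sum_to_100(self, rng):
        df, groups = self.toy(rng)
        res = amova(distance_matrix(df), groups, n_perm=49, seed=0)
        pct = res.components.drop(index="total")["pct"]
        assert pct.sum() == pytest.approx(100.0, abs=0.01)
        assert res.components.loc["total", "pct"] == pytest.approx(100.0)

    def test_identical_samples_zero_components(self):
        df = frame(np.tile([[0.5], [0.5], [0.5]], (1, 6)))
        res = amova(distance_matrix(df), ["A"] * 3 + ["B"] * 3, n_perm=49, seed=0)
        assert np.allclose(res.components["sigma2"], 0.0)
        assert res.components["pct"].isna().all()

    def test_structured_data_significant(self, rng):
        x = rng.normal(0, 0.05, (40, 8))
        x[:10, 4:] += 0.5
        res = amova(distance_matrix(frame(x)), ["A"] * 4 + ["B"] * 4, n_perm=199, seed=3)
        assert res.components.loc["between_treatments", "p_value"] < 0.05

    def test_single_group_rejected(self, rng):
        df, _ = self.toy(rng)
        with pytest.raises(ValueError):
            amova(distance_matrix(df), ["A"] * 6, n_perm=9)

    def test_seed_reproducible(self, rng):
        df, groups = self.toy(rng)
        dm = distance_matrix(df)
        a = amova(dm, groups, n_perm=99, seed=5)
        b = amova(dm, groups, n_perm=99, seed=5)
        assert a.components.equals(b.components)

    def test_null_pvalues_near_uniform(self, rng):
        # permute labels before analysis; rejection rate ~ alpha
        x = rng.normal(0, 1, (20, 8))
        dm = distance_matrix(frame(x))
        base = np.array(["A"] * 4 + ["B"] * 4)
        rejections = 0
        reps = 150
        for i in range(reps):
            groups = rng.permutation(base)
            res = amova(dm, groups, n_perm=99, seed=i)
            if res.components.loc["between_treatments", "p_value"] <= 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.0 <= rate <= 0.12  # binomial 99.9% envelope around 0.05

    def test_three_level_needs_subreplicates(self, rng):
        df, groups = self.toy(rng)
        pops = ["p1", "p2", "p3", "p4", "p5", "p6"]  # singleton populations
        with pytest.raises(ValueError):
            amova(distance_matrix(df), groups, pops, n_perm=9)

    def test_three_level_components(self, rng):
        # 2 treatments x 2 populations x 3 samples
        x = rng.normal(0, 0.1, (30, 12))
        x[:8, 6:] += 0.7  # treatment effect
        x[8:12, 3:6] += 0.3  # population effect
        df = frame(x)
        treatments = ["A"] * 6 + ["B"] * 6
        pops = ["a1"] * 3 + ["a2"] * 3 + ["b1"] * 3 + ["b2"] * 3
        res = amova(distance_matrix(df), treatments, pops, n_perm=99, seed=0)
        comp = res.components
        assert set(comp.index) == {
            "within_population",
            "among_populations_within_treatments",
            "between_treatments",
            "total",
        }
        pct = comp.drop(index="total")["pct"]
        assert pct.sum() == pytest.approx(100.0, abs=0.01)
        assert comp.loc["between_treatments", "p_value"] < 0.05
        # with balanced sizes the nested SS decomposition matches a direct
        # centered-data ANOVA on the underlying matrix
        samples = df.to_numpy().T
        grand = samples.mean(axis=0)
        ss_total = np.sum((samples - grand) ** 2)
        d2 = distance_matrix(df).values
        n = 12
        assert ss_total == pytest.approx(d2[np.triu_indices(n, 1)].sum() / n)


class TestPermanova:
    def test_identical_groups_f_near_zero(self):
        block = np.array([[0.1, 0.2, 0.3]])
        df = frame(np.tile(block.T, (1, 6)))
        dm = distance_matrix(df)
        res = permanova(dm, ["A"] * 3 + ["B"] * 3, n_perm=99, seed=0)
        assert res.pseudo_f == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.5

    def test_planted_shift_detected(self, rng):
        detected = 0
        for i in range(20):
            x = rng.normal(0, 0.1, (30, 12))
            x[:, 6:] += 0.3  # 3x noise shift
            res = permanova(
                distance_matrix(frame(x)), ["A"] * 6 + ["B"] * 6, n_perm=199, seed=i
            )
            detected += res.p_value < 0.05
        assert detected >= 19

    def test_requires_replication(self, rng):
        df = frame(rng.uniform(size=(5, 3)))
        with pytest.raises(ValueError):
            permanova(distance_matrix(df), ["A", "A", "B"], n_perm=9)

    def test_seed_reproducible(self, rng):
        df = frame(rng.uniform(size=(10, 8)))
        dm = distance_matrix(df)
        groups = ["A"] * 4 + ["B"] * 4
        assert (
            permanova(dm, groups, n_perm=99, seed=2).p_value
            == permanova(dm, groups, n_perm=99, seed=2).p_value
        )

    def test_agrees_with_amova_rank_order(self, rng):
        # stronger between-treatment structure -> larger in both frameworks
        groups = ["A"] * 4 + ["B"] * 4
        stats = []
        for shift in (0.0, 0.2, 0.6):
            x = rng.normal(0, 0.1, (30, 8))
            x[:, 4:] += shift
            dm = distance_matrix(frame(x))
            f = permanova(dm, groups, n_perm=9, seed=0).pseudo_f
            s = amova(dm, groups, n_perm=9, seed=0).components.loc[
                "between_treatments", "sigma2"
            ]
            stats.append((f, s))
        fs, sigmas = zip(*stats)
        assert list(fs) == sorted(fs)
        assert list(sigmas) == sorted(sigmas)


class TestDispersion:
    def test_singleton_group_flagged(self, rng):
        df = frame(rng.uniform(size=(10, 7)))
        res = dispersion_test(
            distance_matrix(df), ["A"] * 3 + ["B"] * 3 + ["C"], n_perm=49, seed=0
        )
        assert res.undefined_groups == ("C",)

    def test_unequal_spread_detected(self, rng):
        x = np.concatenate(
            [rng.normal(0, 0.02, (25, 6)), rng.normal(0, 0.6, (25, 6))], axis=1
        )
        res = dispersion_test(
            distance_matrix(frame(x)), ["tight"] * 6 + ["loose"] * 6,
            n_perm=199, seed=1,
        )
        assert res.p_value < 0.05
        assert res.group_means["loose"] > res.group_means["tight"]
        assert {"group1", "group2"} <= set(res.tukey.columns)

    def test_equal_dispersion_type_one_error(self, rng):
        rejections = 0
        reps = 100
        for i in range(reps):
            x = rng.normal(0, 0.3, (20, 10))
            res = dispersion_test(
                distance_matrix(frame(x)), ["A"] * 5 + ["B"] * 5, n_perm=99, seed=i
            )
            rejections += res.p_value <= 0.05
        assert rejections / reps <= 0.13  # ~5% nominal, binomial envelope


class TestPca:
    def test_two_sample_separation_equals_distance(self):
        df = frame(np.array([[0.0, 1.0], [0.0, 1.0], [0.5, 0.5]]))
        res = pca(df)
        gap = abs(res.scores.iloc[0, 0] - res.scores.iloc[1, 0])
        assert gap == pytest.approx(np.sqrt(2.0))
        assert res.explained[0] == pytest.approx(1.0)

    def test_variance_fractions_non_increasing_and_bounded(self, rng):
        res = pca(frame(rng.uniform(size=(30, 8))))
        assert np.all(np.diff(res.explained) <= 1e-12)
        assert res.explained.sum() <= 1.0 + 1e-9

    def test_scores_reproduce_distances(self, rng):
        from scipy.spatial.distance import pdist, squareform

        df = frame(rng.uniform(size=(25, 7)))
        res = pca(df)
        d_scores = squareform(pdist(res.scores.to_numpy()))
        d_plain = distance_matrix(df, squared=False).values
        assert np.allclose(d_scores, d_plain, atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        res = pca(frame(rng.uniform(size=(12, 6))))
        l = res.loadings.to_numpy()
        assert np.allclose(l.T @ l, np.eye(l.shape[1]), atol=1e-10)

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            pca(frame(rng.uniform(size=(5, 1))))


class TestTopLoadings:
    def test_diagnostic_locus_associated_with_its_treatment(self, rng):
        x = rng.uniform(0.4, 0.6, (20, 9))
        treatments = np.array(["X"] * 3 + ["Y"] * 3 + ["Z"] * 3)
        x[0, treatments == "X"] = 1.0  # fixed in and only in X
        res = pca(frame(x))
        assoc = top_loading_associations(res, treatments, n_top=20, components=1)
        by_locus = {a.locus_id: a for a in assoc}
        assert by_locus["L0"].treatment == "X"

    def test_planted_diagnostics_all_recovered(self, rng):
        x = rng.uniform(0.45, 0.55, (50, 8))
        treatments = np.array(["A", "A", "B", "B", "C", "C", "D", "D"])
        for i in range(5):
            x[i, treatments == "B"] = 1.0
        res = pca(frame(x))
        assoc = top_loading_associations(res, treatments, n_top=5, components=1)
        assert {a.locus_id for a in assoc} == {f"L{i}" for i in range(5)}
        assert all(a.treatment == "B" for a in assoc)

    def test_n_top_zero_empty(self, rng):
        res = pca(frame(rng.uniform(size=(10, 6))))
        assert top_loading_associations(res, ["A"] * 3 + ["B"] * 3, n_top=0) == []

    def test_n_top_truncated_to_locus_count(self, rng):
        res = pca(frame(rng.uniform(size=(4, 6))))
        assoc = top_loading_associations(
            res, ["A"] * 3 + ["B"] * 3, n_top=100, components=1
        )
        assert len(assoc) == 4

    def test_loading_scores_bounded(self, rng):
        res = pca(frame(rng.uniform(size=(15, 6))))
        assoc = top_loading_associations(res, ["A"] * 3 + ["B"] * 3, n_top=15)
        assert all(0.0 <= a.loading_score <= 1.0 for a in assoc)


class TestEnrichment:
    def universe(self, n=100):
        return {f"g{i}" for i in range(n)}

    def test_whole_universe_term_null(self):
        uni = self.universe()
        scores = {f"g{i}": 1.0 / (i + 1) for i in range(10)}
        res = weighted_ks_enrichment(scores, {"ALL": uni}, uni)
        assert res[0].ks_p == pytest.approx(1.0)
        assert res[0].ks_stat == pytest.approx(0.0)

    def test_top_scoring_term_enriched(self):
        uni = self.universe()
        scores = {f"g{i}": 1.0 - i / 100 for i in range(5)}
        res = weighted_ks_enrichment(
            scores, {"TOP": {f"g{i}" for i in range(5)}}, uni
        )
        assert res[0].ks_p < 0.01

    def test_exp_formula(self):
        uni = {f"g{i}" for i in range(6000)}
        term = {f"g{i}" for i in range(12)}
        sig = {f"g{i}" for i in range(10)}
        scores = {g: 1.0 for g in sig}
        res = weighted_ks_enrichment(scores, {"T": term}, uni, significant=sig)
        assert res[0].ann == 12
        assert res[0].sig == 10
        assert res[0].exp == pytest.approx(0.02)

    def test_term_outside_universe_skipped(self):
        uni = self.universe(10)
        res = weighted_ks_enrichment(
            {"g1": 1.0}, {"GHOST": {"z1", "z2"}, "OK": {"g1", "g2"}}, uni
        )
        assert [r.term for r in res] == ["OK"]

    def test_scores_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            weighted_ks_enrichment({"zz": 1.0}, {"T": {"g1"}}, self.universe(5))
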