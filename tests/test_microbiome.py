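"""Community typing, diversity, JS metric, LEfSe scoring, SFB regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from ileox import microbiome as mcb
from ileox.simulate import SFB_NAME, StudyConfig, generate_study


def _kl2(p, q):
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def _jsd2(p, q):
    """Independent brute-force base-2 Jensen-Shannon divergence."""
    m = (p + q) / 2
    return 0.5 * _kl2(p, m) + 0.5 * _kl2(q, m)


class TestRelativeAbundance:
    def test_examples(self):
        c = pd.DataFrame([[2, 2], [3, 0]], columns=["x", "y"])
        rel = mcb.relative_abundance(c)
        assert list(rel.iloc[0]) == [0.5, 0.5]
        assert list(rel.iloc[1]) == [1.0, 0.0]

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        c = pd.DataFrame(rng.integers(1, 100, size=(20, 10)))
        assert np.allclose(mcb.relative_abundance(c).sum(axis=1), 1.0, atol=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            mcb.relative_abundance(pd.DataFrame([[0, 0]]))


class TestShannon:
    def test_uniform_four_taxa(self):
        assert mcb.shannon_diversity(pd.Series([5, 5, 5, 5])) == pytest.approx(
            np.log(4), abs=1e-12
        )

    def test_single_taxon_zero(self):
        assert mcb.shannon_diversity(pd.Series([0, 9, 0])) == pytest.approx(0.0)

    def test_matches_bruteforce_and_zero_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 50, size=6).astype(float)
        p = counts / counts.sum()
        brute = -float(np.sum(p * np.log(p)))
        assert mcb.shannon_diversity(pd.Series(counts)) == pytest.approx(brute)
        padded = pd.Series(np.concatenate([counts, [0, 0]]))
        assert mcb.shannon_diversity(padded) == pytest.approx(brute)

    def test_uniform_is_maximal(self):
        rng = np.random.default_rng(2)
        n = 8
        h_uniform = mcb.shannon_diversity(pd.Series(np.ones(n)))
        for _ in range(50):
            h = mcb.shannon_diversity(pd.Series(rng.integers(1, 100, size=n)))
            assert h <= h_uniform + 1e-12


class TestJSMetric:
    def test_identical_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert mcb.js_metric(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_is_one(self):
        assert mcb.js_metric(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_hand_example(self):
        """p=[1,0], q=[0.5,0.5]: JSD2 = 0.3113, metric = 0.5579."""
        p, q = np.array([1.0, 0.0]), np.array([0.5, 0.5])
        jsd = _jsd2(p, q)
        assert jsd == pytest.approx(0.3113, abs=5e-5)
        assert mcb.js_metric(p, q) == pytest.approx(np.sqrt(jsd), abs=1e-12)
        assert mcb.js_metric(p, q) == pytest.approx(0.5579, abs=5e-5)

    def test_symmetry_and_bruteforce_agreement(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            d = mcb.js_metric(p, q)
            assert d == pytest.approx(mcb.js_metric(q, p), abs=1e-12)
            assert d == pytest.approx(np.sqrt(_jsd2(p, q)), abs=1e-9)
            assert 0.0 <= d <= 1.0

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(4)
        for _ in range(10_000):
            p, q, r = rng.dirichlet(np.ones(5), size=3)
            dpq = mcb.js_metric(p, q)
            dpr = mcb.js_metric(p, r)
            dqr = mcb.js_metric(q, r)
            assert dpq <= dpr + dqr + 1e-12


class TestWardTyping:
    def test_two_identical_composition_groups(self):
        c = pd.DataFrame(
            [[10, 0, 0]] * 4 + [[0, 5, 5]] * 4,
            index=[f"s{i}" for i in range(8)], columns=["a", "b", "c"],
        )
        res = mcb.ward_type_clusters(c, k=2)
        labels = res.labels
        assert len(set(labels.iloc[:4])) == 1
        assert len(set(labels.iloc[4:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]
        # numerals assigned by size: equal sizes -> first block is 'I'
        assert set(labels) == {"I", "II"}

    def test_planted_types_recovered(self, separable_typing_config):
        s = generate_study(separable_typing_config(31))
        res = mcb.ward_type_clusters(s.otu_table, k=5)
        truth = pd.Series(s.truth["type_labels"]).loc[res.labels.index]
        assert adjusted_rand_score(truth, res.labels) > 0.95

    def test_sample_order_invariance(self, separable_typing_config):
        s = generate_study(separable_typing_config(32))
        res = mcb.ward_type_clusters(s.otu_table, k=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(s.otu_table))
        res_p = mcb.ward_type_clusters(s.otu_table.iloc[perm], k=5)
        pd.testing.assert_series_equal(
            res.labels.sort_index(), res_p.labels.sort_index()
        )

    def test_scaling_a_sample_is_invariant(self):
        rng = np.random.default_rng(5)
        c = pd.DataFrame(rng.integers(1, 100, size=(10, 6)),
                         index=[f"s{i}" for i in range(10)])
        res = mcb.ward_type_clusters(c, k=3)
        c2 = c.copy()
        c2.iloc[0] *= 7
        res2 = mcb.ward_type_clusters(c2, k=3)
        pd.testing.assert_series_equal(res.labels, res2.labels)

    def test_k_exceeding_samples_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            mcb.CommunityTypingModel(pd.DataFrame([[1, 2]]), k=3)

    def test_newick_export_contains_all_samples(self, separable_typing_config):
        s = generate_study(separable_typing_config(33))
        res = mcb.ward_type_clusters(s.otu_table.iloc[:12], k=3)
        nwk = res.to_newick()
        assert nwk.endswith(";")
        for sid in res.distance.index:
            assert sid in nwk


class TestLefse:
    @staticmethod
    def _null_table(rng, n_per=10, n_taxa=20):
        counts = rng.integers(20, 200, size=(2 * n_per, n_taxa))
        idx = [f"s{i}" for i in range(2 * n_per)]
        classes = pd.Series(["A"] * n_per + ["B"] * n_per, index=idx)
        return pd.DataFrame(counts, index=idx), classes

    def test_null_type_one_rate(self):
        """Under the global null the KW pass fraction is ~alpha."""
        rng = np.random.default_rng(6)
        passed = total = 0
        for _ in range(60):
            counts, classes = self._null_table(rng)
            res = mcb.lefse_score(counts, classes, n_boot=5, seed=0)
            passed += int(res.table["passed_alpha"].sum())
            total += len(res.table)
        rate = passed / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) <= 3 * se

    def test_planted_enrichment_discriminative(self):
        rng = np.random.default_rng(7)
        counts, classes = self._null_table(rng, n_per=10, n_taxa=10)
        counts = counts.copy()
        counts.loc[classes == "A", counts.columns[0]] *= 100
        res = mcb.lefse_score(counts, classes, seed=1)
        row = res.table.loc[counts.columns[0]]
        assert row["discriminative"]
        assert row["lda_score"] >= 2.0
        assert row["enriched_class"] == "A"

    def test_filter_off_reports_everything(self):
        rng = np.random.default_rng(8)
        counts, classes = self._null_table(rng, n_per=5, n_taxa=8)
        res = mcb.lefse_score(counts, classes, alpha=1.0,
                              lda_threshold=-np.inf, n_boot=3)
        assert len(res.table) == 8
        assert res.table["discriminative"].all()

    def test_three_class_all_against_all(self):
        rng = np.random.default_rng(9)
        n = 8
        counts = pd.DataFrame(rng.integers(50, 100, size=(3 * n, 6)),
                              index=[f"s{i}" for i in range(3 * n)])
        classes = pd.Series(["A"] * n + ["B"] * n + ["C"] * n,
                            index=counts.index)
        counts.loc[classes == "C", 0] *= 50
        res = mcb.lefse_score(counts, classes, seed=2)
        assert res.table.loc[0, "enriched_class"] == "C"
        assert res.table.loc[0, "discriminative"]

    def test_too_small_class_errors(self):
        counts = pd.DataFrame([[1, 2]] * 4)
        classes = pd.Series(["A", "A", "A", "B"])
        with pytest.raises(ValueError, match="< 3 samples"):
            mcb.lefse_score(counts, classes)


class TestSfbRegression:
    def test_noiseless_planted_tie(self):
        oligo = pd.Series(np.linspace(0.5, 5.0, 12))
        log10_sfb = 1.0 + 0.8 * oligo
        counts = 10.0**log10_sfb - 1.0     # pseudocount-exact inverse
        slope, r2, p = mcb.sfb_oligo_regression(oligo, counts)
        assert slope == pytest.approx(0.8, abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_shuffled_pairing_ci_covers_zero(self):
        rng = np.random.default_rng(10)
        oligo = pd.Series(rng.normal(2.0, 0.5, size=30).clip(0.1))
        counts = pd.Series(rng.integers(1, 1000, size=30).astype(float))
        cover = 0
        n_shuffles = 500
        for _ in range(n_shuffles):
            perm = pd.Series(rng.permutation(counts.values), index=oligo.index)
            x = oligo.values
            ylog = np.log10(perm.values + 1)
            res = sps.linregress(x, ylog)
            half = sps.t.ppf(0.975, len(x) - 2) * res.stderr
            if res.slope - half <= 0 <= res.slope + half:
                cover += 1
        assert cover / n_shuffles >= 0.94

    def test_planted_positive_slope_recovered(self):
        hits = 0
        for seed in range(20):
            s = generate_study(StudyConfig(seed=400 + seed))
            scrape = s.otu_meta[(s.otu_meta["site"] == "ileum")
                                & (s.otu_meta["fraction"] == "scraping")]
            sfb = s.otu_table.loc[scrape.index, SFB_NAME].astype(float)
            sfb.index = scrape["animal"]
            oligo = pd.Series(s.truth["oligo_sum"])
            slope, _, _ = mcb.sfb_oligo_regression(oligo, sfb)
            hits += slope > 0
        assert hits == 20

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError, match="zero"):
            mcb.sfb_oligo_regression(pd.Series([1.0, 2.0]),
                                     pd.Series([0.0, 0.0]))
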