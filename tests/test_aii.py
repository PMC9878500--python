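"""Anti-inflammatory index: adjusted R², qualification, retention, regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from ileox import aii, metabolome as mb
from ileox.simulate import StudyConfig, generate_study


def _study_pieces(study):
    siv = mb.impute_and_scale(study.metabolite_table)
    groups = [mb.PathwayGroup(n, m) for n, m in study.truth["membership"].items()]
    sums = mb.sum_groups(siv, groups)
    nt = aii.NTTable.from_frame(study.nt_table)
    return siv, sums, nt


class TestNTTable:
    def test_density_and_log(self):
        t = aii.NTTable(pixels=pd.Series([500.0, 0.0], index=["a", "b"]),
                        nuclei=pd.Series([50, 10], index=["a", "b"]))
        assert t.density["a"] == 10.0
        # zero density floored at half the smallest positive density
        assert t.log10_nt["b"] == pytest.approx(np.log10(5.0))

    def test_missing_nt_dropped_listwise(self):
        t = aii.NTTable(pixels=pd.Series([500.0, np.nan, 20.0]),
                        nuclei=pd.Series([50, 10, 10]))
        assert len(t.log10_nt) == 2

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            aii.NTTable(pixels=pd.Series([1.0]), nuclei=pd.Series([0]))


class TestAdjustedR2:
    def test_perfect_fit_is_one(self):
        x = np.arange(10.0)
        assert aii.adjusted_r2(3 * x + 1, x) == pytest.approx(1.0)

    def test_matches_statsmodels_on_fixture(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        y = X @ [1.0, -2.0] + rng.normal(size=10)
        ours = aii.adjusted_r2(y, X)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        assert ours == pytest.approx(fit.rsquared_adj, abs=1e-12)

    def test_noise_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(1)
        vals = [aii.adjusted_r2(rng.normal(size=200), rng.normal(size=200))
                for _ in range(50)]
        assert abs(np.mean(vals)) < 0.01

    def test_pure_noise_column_no_gain_in_expectation(self):
        """Adding a noise column never increases adjusted R2 in expectation."""
        rng = np.random.default_rng(2)
        deltas = []
        for _ in range(1000):
            x = rng.normal(size=30)
            y = x + rng.normal(size=30)
            base = aii.adjusted_r2(y, x)
            noisy = aii.adjusted_r2(y, np.column_stack([x, rng.normal(size=30)]))
            deltas.append(noisy - base)
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert np.mean(deltas) <= 3 * se

    def test_errors(self):
        with pytest.raises(ValueError, match="rank"):
            aii.adjusted_r2(np.arange(5.0), np.ones((5, 2)))
        with pytest.raises(ValueError, match="n > p"):
            aii.adjusted_r2(np.arange(3.0), np.ones((3, 2)) * [[1, 2], [2, 1], [3, 3]])


class TestQualification:
    def test_literature_flag_gate(self, default_study):
        _, sums, _ = _study_pieces(default_study)
        meta = default_study.metabolite_table.animal_meta
        flags = {n: False for n in sums.sums.columns}
        cand = aii.qualify_candidates(sums, meta, flags)
        assert cand.names == []
        assert (cand.qualification["reason"] == "literature").all()

    def test_planted_effects_qualify(self, default_study):
        _, sums, _ = _study_pieces(default_study)
        meta = default_study.metabolite_table.animal_meta
        flags = {n: True for n in sums.sums.columns}
        cand = aii.qualify_candidates(sums, meta, flags)
        informative = set(default_study.truth["informative_groups"])
        assert informative <= set(cand.names)
        # inert noise groups fail the diet contrast
        for n in default_study.truth["noise_groups"]:
            assert n not in cand.names
            # inert groups fall at the contrast screen, or (by a chance
            # pooled hit) at the replication screen
            assert cand.qualification.loc[n, "reason"] in ("contrast", "replication")

    def test_single_replicate_effect_fails_replication(self):
        """An effect planted in replicate 1 only is excluded for
        non-replication."""
        rng = np.random.default_rng(3)
        n = 40
        meta = pd.DataFrame(
            {"diet": ["CON"] * 20 + ["BC"] * 20,
             "replicate": [1, 2] * 20},
            index=[f"a{i}" for i in range(n)],
        )
        x = pd.Series(rng.normal(size=n), index=meta.index)
        shift = (meta["diet"] == "BC") & (meta["replicate"] == 1)
        x[shift] += 5.0
        sums = mb.GroupSumTable(sums=x.to_frame("g"))
        from ileox.stats import ContrastSpec

        cand = aii.qualify_candidates(
            sums, meta, {"g": True},
            contrasts=[ContrastSpec("BC vs CON", {"CON": -1.0, "BC": 1.0})],
        )
        assert cand.names == []
        assert cand.qualification.loc["g", "reason"] == "replication"

    def test_missing_replicate_column_errors(self, default_study):
        _, sums, _ = _study_pieces(default_study)
        meta = default_study.metabolite_table.animal_meta.drop(columns="replicate")
        with pytest.raises(ValueError, match="replicate"):
            aii.qualify_candidates(sums, meta, {})


class TestForwardRetention:
    def test_single_perfect_candidate(self):
        rng = np.random.default_rng(4)
        x = pd.Series(rng.normal(size=20), index=range(20))
        y = 2.0 - 0.5 * x
        inc, steps, traj, order = aii.forward_retention(y, x.to_frame("g"))
        assert inc == ["g"]
        assert traj[0] == pytest.approx(1.0)

    def test_duplicate_candidate_rejected(self):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(size=20), index=range(20))
        y = -x + pd.Series(rng.normal(scale=0.1, size=20), index=range(20))
        X = pd.DataFrame({"g1": x, "g2": x})
        inc, steps, *_ = aii.forward_retention(y, X)
        assert len(inc) == 1  # the copy adds no adjusted-R2 gain

    def test_trajectory_strictly_increases(self, default_study):
        _, sums, nt = _study_pieces(default_study)
        inc, steps, traj, _ = aii.forward_retention(nt.log10_nt, sums.sums)
        assert all(b > a for a, b in zip(traj, traj[1:]))
        for s in steps:
            if s.included:
                assert s.adj_r2_with > s.adj_r2_without + aii.RETENTION_TOL

    def test_noiseless_recovers_planted_set(self, noiseless_study):
        """With no NT noise the retained set is exactly the planted
        informative groups (candidates: informative + inert noise groups)."""
        _, sums, nt = _study_pieces(noiseless_study)
        cand_cols = (noiseless_study.truth["informative_groups"]
                     + noiseless_study.truth["noise_groups"])
        inc, *_ = aii.forward_retention(nt.log10_nt, sums.sums[cand_cols])
        assert sorted(inc) == sorted(noiseless_study.truth["informative_groups"])

    def test_sensitivity_and_noise_rate_over_seeds(self):
        """Informative groups are recovered and inert ones rejected across
        independently generated noiseless studies."""
        sens, noise_hits, noise_total = [], 0, 0
        for seed in range(25):
            s = generate_study(StudyConfig(seed=200 + seed, nt_noise_sd=0.0))
            _, sums, nt = _study_pieces(s)
            cand = s.truth["informative_groups"] + s.truth["noise_groups"]
            inc, *_ = aii.forward_retention(nt.log10_nt, sums.sums[cand])
            informative = set(s.truth["informative_groups"])
            sens.append(len(informative & set(inc)) / len(informative))
            noise_hits += len(set(s.truth["noise_groups"]) & set(inc))
            noise_total += len(s.truth["noise_groups"])
        assert np.mean(sens) >= 0.9
        assert noise_hits / noise_total <= 0.2

    def test_explicit_order_respected_and_reported(self, default_study):
        _, sums, nt = _study_pieces(default_study)
        order = sorted(sums.sums.columns)
        model = aii.AiiModel(nt, sums.sums, order_rule="given", order=order)
        res = model.fit()
        assert res.order == order and res.order_rule == "given"

    def test_order_changes_can_change_inclusions(self, default_study):
        """Order sensitivity is real and surfaced: the report always records
        the order used."""
        _, sums, nt = _study_pieces(default_study)
        res_corr = aii.AiiModel(nt, sums.sums, order_rule="corr").fit()
        res_rev = aii.AiiModel(
            nt, sums.sums, order_rule="given",
            order=list(reversed(res_corr.order)),
        ).fit()
        assert res_corr.order != res_rev.order  # both recorded


class TestIndexAndRegression:
    def test_compute_index_examples(self):
        preds = pd.DataFrame({"a": [1.0], "b": [2.5]}, index=["x"])
        assert aii.compute_index(preds, ["a", "b"])["x"] == 3.5
        assert aii.compute_index(preds, ["a"])["x"] == 1.0
        with pytest.raises(ValueError):
            aii.compute_index(preds, [])

    def test_index_reconstruction_to_machine_precision(self, default_study):
        _, sums, nt = _study_pieces(default_study)
        res = aii.AiiModel(nt, sums.sums).fit()
        recomputed = sums.sums[res.included].sum(axis=1)
        assert np.allclose(res.index_per_animal, recomputed, atol=1e-12)

    def test_noiseless_regression_exact(self, noiseless_study):
        truth_idx = pd.Series(noiseless_study.truth["true_index"])
        nt = aii.NTTable.from_frame(noiseless_study.nt_table)
        slope, _, r2, p = aii.regress_nt_on_index(truth_idx, nt.log10_nt)
        assert slope == pytest.approx(noiseless_study.truth["nt_slope"], abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_permutation_pvalues_uniform(self, default_study):
        truth_idx = pd.Series(default_study.truth["true_index"])
        nt = aii.NTTable.from_frame(default_study.nt_table)
        y = nt.log10_nt
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(500):
            perm = pd.Series(rng.permutation(truth_idx.values),
                             index=truth_idx.index)
            ps.append(aii.regress_nt_on_index(perm, y)[3])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_index_errors(self):
        with pytest.raises(ValueError, match="variance"):
            aii.regress_nt_on_index(pd.Series([1.0, 1.0, 1.0]),
                                    pd.Series([1.0, 2.0, 3.0]))
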