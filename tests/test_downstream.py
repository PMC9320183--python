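"""Downstream stages: Kruskal-Wallis calibration, multi-class AUC sanity,
survival screening, cross-cohort validation and the drug-sensitivity
screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methspec import downstream as ds
from methspec import synthetic, diffmeth
from methspec.config import CohortConfig
from methspec.synthetic import DrugPanel

from conftest import make_sheet


class TestKruskalWallis:
    def test_null_rejection_near_alpha(self):
        rng = np.random.default_rng(0)
        sheet = make_sheet(["C1", "C2", "C3"], n_tumor=15)
        gb = pd.DataFrame(
            rng.normal(0.4, 0.05, size=(400, len(sheet))),
            index=[f"g{i}" for i in range(400)], columns=sheet.index,
        ).clip(0, 1)
        out = ds.kruskal_wallis_overview(gb, sheet)
        rate = (out["p_value"] < 0.05).mean()
        assert abs(rate - 0.05) < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 400)

    def test_planted_specific_gene_detected(self, default_cohort,
                                            default_gene_beta):
        _, _, sheet, truth = default_cohort
        out = ds.kruskal_wallis_overview(
            default_gene_beta.loc[list(truth.specific_gene_map)], sheet
        )
        assert (out["p_value"] < 0.05).all()

    def test_two_groups_agree_with_ranksum(self):
        rng = np.random.default_rng(3)
        sheet = make_sheet(["C1", "C2"], n_tumor=12)
        gb = pd.DataFrame(
            rng.uniform(size=(1, len(sheet))), index=["g"], columns=sheet.index
        )
        out = ds.kruskal_wallis_overview(gb, sheet)
        a = gb.loc["g", sheet.index[sheet["cancer_type"] == "C1"]]
        b = gb.loc["g", sheet.index[sheet["cancer_type"] == "C2"]]
        kw_from_scipy = stats.kruskal(a, b)
        assert out.loc["g", "p_value"] == pytest.approx(kw_from_scipy.pvalue)
        # two-group KW is the square of the normal rank-sum statistic
        mwu = stats.mannwhitneyu(
            a, b, alternative="two-sided", use_continuity=False,
            method="asymptotic",
        )
        z = stats.norm.isf(mwu.pvalue / 2)
        assert out.loc["g", "H_stat"] == pytest.approx(z**2, rel=1e-6)

    def test_all_tied_gene_warns_p1(self):
        sheet = make_sheet(["C1", "C2"], n_tumor=3)
        gb = pd.DataFrame([[0.5] * 6], index=["g"], columns=sheet.index)
        with pytest.warns(UserWarning, match="tied"):
            out = ds.kruskal_wallis_overview(gb, sheet)
        assert out.loc["g", "p_value"] == 1.0


class TestRfMulticlass:
    def _separable(self, n_per=20, n_classes=4, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        cancers = [f"C{i}" for i in range(n_classes)]
        sheet = make_sheet(cancers, n_tumor=n_per)
        sheet["split"] = np.where(
            np.arange(len(sheet)) % n_per < int(0.7 * n_per), "train", "test"
        )
        centers = np.linspace(0.1, 0.9, n_classes)
        gb = pd.DataFrame(
            np.zeros((3, len(sheet))), index=["g1", "g2", "g3"],
            columns=sheet.index,
        )
        for ci, cancer in enumerate(cancers):
            cols = sheet.index[sheet["cancer_type"] == cancer]
            gb.loc[:, cols] = centers[ci] + rng.normal(0, noise, (3, len(cols)))
        return gb.clip(0, 1), sheet

    def test_separable_classes_macro_auc_one(self):
        gb, sheet = self._separable()
        _, macro = ds.rf_multiclass_auc(gb, sheet, seed=1, n_trees=100)
        assert macro == 1.0

    def test_label_permutation_macro_auc_half(self):
        gb, sheet = self._separable(n_per=40, noise=0.02, seed=2)
        rng = np.random.default_rng(7)
        sheet = sheet.copy()
        sheet["cancer_type"] = rng.permutation(sheet["cancer_type"].to_numpy())
        _, macro = ds.rf_multiclass_auc(gb, sheet, seed=3, n_trees=100)
        assert abs(macro - 0.5) < 0.12

    def test_deterministic_under_seed(self):
        gb, sheet = self._separable(noise=0.2, seed=5)
        a = ds.rf_multiclass_auc(gb, sheet, seed=11, n_trees=50)
        b = ds.rf_multiclass_auc(gb, sheet, seed=11, n_trees=50)
        assert a == b


class TestKmLogrank:
    def test_identical_groups_give_p_one(self):
        sheet = make_sheet(["C1"], n_tumor=20)
        ids = sheet.index
        gb = pd.DataFrame(
            [np.r_[np.full(10, 0.2), np.full(10, 0.8)]], index=["g"], columns=ids
        )
        surv = pd.DataFrame(
            {
                "time": np.tile(np.arange(1, 11, dtype=float), 2),
                "event": 1,
                "cancer_type": "C1",
            },
            index=ids,
        )
        p, groups = ds.km_logrank_screen(gb, surv, "g", "C1")
        assert p == pytest.approx(1.0)
        assert set(groups) == {"high", "low"}

    def test_non_informative_threshold_warns(self):
        sheet = make_sheet(["C1"], n_tumor=6)
        gb = pd.DataFrame([[0.5] * 6], index=["g"], columns=sheet.index)
        surv = pd.DataFrame(
            {"time": np.arange(1.0, 7.0), "event": 1, "cancer_type": "C1"},
            index=sheet.index,
        )
        with pytest.warns(UserWarning, match="non-informative"):
            p, _ = ds.km_logrank_screen(gb, surv, "g", "C1")
        assert np.isnan(p)


class TestValidateGrsdm:
    def test_planted_gene_consistent_in_validation_cohort(self):
        cfg = CohortConfig(seed=17)
        ann = synthetic.generate_annotation(cfg)
        _, _, truth = synthetic.generate_cohort(cfg, ann)
        beta_v, sheet_v = synthetic.generate_validation_cohort(cfg, truth, ann)
        gb_v = diffmeth.aggregate_to_genes(beta_v, ann)
        n_ok = 0
        planted = list(truth.specific_gene_map.items())
        for gene, cancer in planted:
            verdict, p = ds.validate_grsdm(gene, cancer, gb_v, sheet_v)
            n_ok += verdict == "consistent"
        assert n_ok / len(planted) >= 0.9

    def test_noise_gene_rarely_consistent(self):
        rng = np.random.default_rng(0)
        sheet = make_sheet([f"C{i}" for i in range(6)], n_tumor=15)
        n_consistent = 0
        for rep in range(40):
            gb = pd.DataFrame(
                rng.uniform(0.2, 0.6, size=(1, len(sheet))),
                index=["g"], columns=sheet.index,
            )
            verdict, _ = ds.validate_grsdm("g", "C0", gb, sheet)
            n_consistent += verdict == "consistent"
        assert n_consistent <= 2

    def test_missing_cancer_untestable(self):
        sheet = make_sheet(["C1", "C2"], n_tumor=5)
        gb = pd.DataFrame(
            np.random.default_rng(1).uniform(size=(1, len(sheet))),
            index=["g"], columns=sheet.index,
        )
        verdict, p = ds.validate_grsdm("g", "C9", gb, sheet)
        assert verdict == "untestable" and np.isnan(p)


def _linear_panel(seed=0, n_genes=10, n_lines=50, n_samples=30, noise=0.0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    X = pd.DataFrame(
        rng.normal(size=(n_genes, n_lines)), index=genes,
        columns=[f"L{i}" for i in range(n_lines)],
    )
    w = rng.normal(size=(n_genes, 2))
    ic50 = X.T @ pd.DataFrame(w, index=genes, columns=["d1", "d2"])
    if noise:
        ic50 += rng.normal(0, noise, size=ic50.shape)
    S = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)), index=genes,
        columns=[f"S{i}" for i in range(n_samples)],
    )
    truth = S.T @ pd.DataFrame(w, index=genes, columns=["d1", "d2"])
    return DrugPanel(X, ic50, S, truth), truth


class TestRidge:
    def test_noise_free_linear_recovery_at_tiny_lambda(self):
        panel, truth = _linear_panel()
        pred = ds.ridge_ic50_predict(panel, ridge_lambda=1e-10)
        assert np.abs(pred - truth).to_numpy().max() < 1e-6

    def test_infinite_lambda_shrinks_to_training_mean(self):
        panel, _ = _linear_panel(seed=2)
        pred = ds.ridge_ic50_predict(panel, ridge_lambda=1e12)
        means = panel.ic50.mean(axis=0)
        assert np.allclose(pred, means.to_numpy()[None, :], atol=1e-6)

    def test_default_lambda_recovers_planted_sparse_model(self):
        panel, truth = _linear_panel(seed=3, noise=0.1)
        pred = ds.ridge_ic50_predict(panel, ridge_lambda=1.0)
        for drug in ["d1", "d2"]:
            r = np.corrcoef(pred[drug], truth[drug])[0, 1]
            assert r >= 0.8

    def test_negative_lambda_rejected(self):
        panel, _ = _linear_panel()
        with pytest.raises(ValueError, match="penalty"):
            ds.ridge_ic50_predict(panel, ridge_lambda=-1.0)


class TestSpearmanScreen:
    def test_perfect_monotone_pairings(self):
        x = np.arange(20, dtype=float)
        rho, p = ds.spearman_test(x, -x)
        assert rho == pytest.approx(-1.0)
        rho_up, _ = ds.spearman_test(x, x**3)
        assert rho_up == pytest.approx(1.0)

    def test_small_n_uses_exact_permutation_p(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([6.0, 5, 4, 3, 2, 1])
        rho, p = ds.spearman_test(x, y)
        # perfectly decreasing: 2 of 6! orderings reach |rho| = 1
        assert rho == -1.0
        assert p == pytest.approx(2 / 720, rel=1e-9)

    def test_hit_requires_strict_thresholds(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(30)]
        beta = pd.DataFrame(
            [np.linspace(0.1, 0.9, 30)], index=["g"], columns=samples
        )
        ic50 = pd.DataFrame(
            {"d": -beta.loc["g"].to_numpy() + rng.normal(0, 0.01, 30)},
            index=samples,
        )
        hits = ds.drug_correlation(beta, ic50)
        assert bool(hits["passes"].iloc[0])
        # a positive association is never a hit
        hits_up = ds.drug_correlation(beta, -ic50)
        assert not bool(hits_up["passes"].iloc[0])

    def test_boundary_rho_is_not_a_hit(self):
        beta = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4, 0.5]], index=["g"],
            columns=[f"s{i}" for i in range(5)],
        )
        ic50 = pd.DataFrame(
            {"d": [2.0, 3.0, 4.0, 1.0, 5.0]}, index=beta.columns
        )
        hits = ds.drug_correlation(beta, ic50)
        # rho is exactly +0.4 here; negate to land exactly on -0.4
        hits_neg = ds.drug_correlation(beta, -ic50)
        assert hits_neg["spearman_rho"].iloc[0] == pytest.approx(-0.4)
        assert not bool(hits_neg["passes"].iloc[0])

    def test_constant_vector_skipped_with_warning(self):
        beta = pd.DataFrame(
            [[0.5] * 6, np.linspace(0.1, 0.6, 6)], index=["flat", "ok"],
            columns=[f"s{i}" for i in range(6)],
        )
        ic50 = pd.DataFrame(
            {"d": np.linspace(1, 2, 6)}, index=beta.columns
        )
        with pytest.warns(UserWarning, match="degenerate"):
            hits = ds.drug_correlation(beta, ic50)
        assert list(hits["gene"]) == ["ok"]

    def test_null_hit_rate_controlled(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(100)]
        beta = pd.DataFrame(
            rng.uniform(size=(20, 100)),
            index=[f"g{i}" for i in range(20)], columns=samples,
        )
        ic50 = pd.DataFrame(
            rng.normal(size=(100, 5)),
            index=samples, columns=[f"d{i}" for i in range(5)],
        )
        hits = ds.drug_correlation(beta, ic50)
        n = len(hits)
        assert hits["passes"].mean() <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)
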