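"""LC-MS/MS feature screening, scaling, PCA, fold changes, target panel."""

import numpy as np
import pandas as pd
import pytest

from mrmsi import (
    FeatureTable,
    aggregate_isomers,
    bh_fdr,
    fold_change_stats,
    impute_and_scale,
    mann_whitney_u,
    merge_panels,
    run_pca,
    run_screen,
    screen_features,
    select_targets,
    simulate_lcms_table,
)


def make_table(conc, tissues=None, classes=None, snr=None):
    conc = pd.DataFrame(conc)
    n = conc.shape[1]
    classes = classes or ["sample"] * n
    tissues = tissues or [
        ("airways" if c == "sample" else np.nan) for c in classes
    ]
    meta = pd.DataFrame(
        {"class": classes, "tissue": tissues}, index=conc.columns
    )
    return FeatureTable(
        concentrations=conc,
        sample_meta=meta,
        snr=pd.DataFrame(snr, index=conc.index, columns=conc.columns)
        if snr is not None
        else None,
    )


class TestScreenRules:
    def _table(self, sample_vals, blank_vals, qc_vals):
        vals = np.array([sample_vals + blank_vals + qc_vals])
        classes = (
            ["sample"] * len(sample_vals)
            + ["blank"] * len(blank_vals)
            + ["QC"] * len(qc_vals)
        )
        conc = pd.DataFrame(
            vals, index=["c1"], columns=[f"s{i}" for i in range(vals.shape[1])]
        )
        meta = pd.DataFrame(
            {
                "class": classes,
                "tissue": ["airways" if c == "sample" else np.nan for c in classes],
            },
            index=conc.columns,
        )
        return FeatureTable(concentrations=conc, sample_meta=meta)

    def test_blank_rule_passes_above_fivefold(self):
        t = self._table([10.0, 10.0], [1.0], [10.0, 10.0])
        _, log = screen_features(t)
        assert log.loc["c1", "blank_pass"]

    def test_blank_rule_boundary_is_strict(self):
        # sample mean exactly 5x blank mean fails (strict >)
        t = self._table([5.0, 5.0], [1.0], [5.0, 5.0])
        _, log = screen_features(t)
        assert not log.loc["c1", "blank_pass"]
        t2 = self._table([5.0 + 1e-9, 5.0 + 1e-9], [1.0], [5.0, 5.0])
        _, log2 = screen_features(t2)
        assert log2.loc["c1", "blank_pass"]

    def test_qc_rsd_zero_passes(self):
        t = self._table([100.0, 100.0], [1.0], [10.0, 10.0, 10.0])
        _, log = screen_features(t)
        assert log.loc["c1", "qc_rsd"] == 0.0
        assert log.loc["c1", "qc_pass"]

    def test_qc_rsd_above_threshold_fails(self):
        t = self._table([100.0, 100.0], [1.0], [10.0, 20.0, 30.0])
        retained, log = screen_features(t)
        assert log.loc["c1", "qc_rsd"] > 15.0
        assert "c1" not in retained.compounds

    def test_sn_rule_removes_cells_not_compounds(self):
        conc = np.array([[10.0, 10.0, 1.0, 10.0, 10.0]])
        snr = np.array([[100.0, 100.0, 2.0, 100.0, 100.0]])
        classes = ["sample", "sample", "sample", "blank", "QC"]
        t = make_table(
            pd.DataFrame(conc, index=["c1"], columns=list("abcde")),
            classes=classes,
            snr=pd.DataFrame(snr, index=["c1"], columns=list("abcde")),
        )
        retained, _ = screen_features(t, blank_ratio=0.0)
        # the low-S/N sample cell became missing; the compound survives
        assert "c1" in retained.compounds
        assert np.isnan(retained.concentrations.loc["c1", "c"])

    def test_no_study_samples_is_error(self):
        t = self._table([1.0], [1.0], [1.0])
        t.sample_meta["class"] = ["blank", "blank", "QC"]
        with pytest.raises(ValueError, match="no study samples"):
            screen_features(t)

    def test_missing_blanks_skips_rule_with_warning(self):
        t = self._table([1.0, 1.0], [], [1.0, 1.0])
        with pytest.warns(UserWarning, match="blank"):
            retained, log = screen_features(t)
        assert "blank_pass" not in log.columns
        assert "c1" in retained.compounds


class TestMergePanels:
    def test_single_table_identity(self):
        t, _ = simulate_lcms_table(n_compounds=5, seed=0)
        merged = merge_panels([t])
        pd.testing.assert_frame_equal(merged.concentrations, t.concentrations)

    def test_panel_sizes_add(self):
        # 13 eicosanoids + 39 octadecanoids -> 52 compounds
        eic, _ = simulate_lcms_table(n_compounds=13, panel="eicosanoid", seed=1)
        oct_, _ = simulate_lcms_table(n_compounds=39, panel="octadecanoid", seed=2)
        merged = merge_panels([eic, oct_])
        assert merged.concentrations.shape[0] == 52
        assert set(merged.compound_meta["panel_source"]) == {
            "eicosanoid",
            "octadecanoid",
        }

    def test_duplicate_compound_rejected(self):
        a, _ = simulate_lcms_table(n_compounds=3, panel="eicosanoid", seed=1)
        b, _ = simulate_lcms_table(n_compounds=3, panel="eicosanoid", seed=2)
        with pytest.raises(ValueError, match="duplicate"):
            merge_panels([a, b])

    def test_sample_mismatch_rejected(self):
        a, _ = simulate_lcms_table(n_compounds=3, panel="eicosanoid", seed=1)
        b, _ = simulate_lcms_table(
            n_compounds=3, panel="octadecanoid", n_per_group=11, seed=2
        )
        with pytest.raises(ValueError, match="align"):
            merge_panels([a, b])


class TestImputeAndScale:
    def test_imputed_cell_is_fifth_of_minimum(self):
        t = make_table(
            pd.DataFrame(
                [[5.0, np.nan, 10.0]], index=["c1"], columns=["a", "b", "c"]
            )
        )
        # re-impute by inspecting the centered/scaled matrix via raw fill
        row = t.concentrations.loc["c1"]
        filled = row.fillna(0.2 * row.min(skipna=True))
        assert filled["b"] == pytest.approx(1.0)
        # and the library path produces a complete matrix
        scaled = impute_and_scale(t)
        assert np.isfinite(scaled.to_numpy()).all()

    def test_scaled_columns_have_zero_mean(self):
        t, _ = simulate_lcms_table(n_compounds=6, missing_rate=0.2, seed=3)
        scaled = impute_and_scale(t)
        np.testing.assert_allclose(
            scaled.mean(axis=0), 0.0, atol=1e-10
        )

    def test_pareto_variance_identity(self):
        # var(x / sqrt(s)) = s where s is the pre-scaling standard deviation
        t, _ = simulate_lcms_table(n_compounds=5, seed=4)
        filled = t.concentrations.T
        sd_before = filled.std(axis=0, ddof=1)
        scaled = impute_and_scale(t)
        np.testing.assert_allclose(
            scaled.var(axis=0, ddof=1), sd_before, rtol=1e-10
        )

    def test_observed_values_unchanged_up_to_affine_scaling(self):
        t = make_table(
            pd.DataFrame(
                [[5.0, np.nan, 10.0]], index=["c1"], columns=["a", "b", "c"]
            )
        )
        scaled = impute_and_scale(t)
        # de-scale: x = scaled*sqrt(sd) + mean must recover observed cells
        filled = t.concentrations.loc["c1"].fillna(1.0)
        mean, sd = filled.mean(), filled.std(ddof=1)
        recovered = scaled["c1"] * np.sqrt(sd) + mean
        assert recovered["a"] == pytest.approx(5.0)
        assert recovered["c"] == pytest.approx(10.0)

    def test_fully_missing_compound_is_error(self):
        t = make_table(
            pd.DataFrame(
                [[np.nan, np.nan]], index=["c1"], columns=["a", "b"]
            )
        )
        with pytest.raises(ValueError, match="c1"):
            impute_and_scale(t)


class TestPCA:
    def _matrix(self, seed=0, n=12, p=6):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        X -= X.mean(axis=0)
        return pd.DataFrame(
            X,
            index=[f"s{i}" for i in range(n)],
            columns=[f"c{j}" for j in range(p)],
        )

    def test_perfectly_correlated_features_single_component(self):
        x = np.linspace(-1, 1, 10)
        mat = pd.DataFrame({"a": x, "b": 2 * x})
        res = run_pca(mat, n_components=1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_from_all_components(self):
        mat = self._matrix()
        res = run_pca(mat, n_components=6)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, mat.to_numpy(), atol=1e-10)

    def test_scores_orthogonal(self):
        res = run_pca(self._matrix(1), n_components=4)
        S = res.scores.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_sign_convention(self):
        res = run_pca(self._matrix(2), n_components=3)
        L = res.loadings.to_numpy()
        for i in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, i])), i] > 0

    def test_matches_sklearn_variances(self):
        from sklearn.decomposition import PCA

        mat = self._matrix(3)
        ours = run_pca(mat, n_components=3)
        ref = PCA(n_components=3).fit(mat.to_numpy())
        np.testing.assert_allclose(
            ours.explained_variance_ratio,
            ref.explained_variance_ratio_,
            rtol=1e-8,
        )

    def test_rank_deficiency_reduces_with_warning(self):
        x = np.linspace(-1, 1, 8)
        mat = pd.DataFrame({"a": x, "b": 2 * x, "c": -x})
        with pytest.warns(UserWarning, match="rank"):
            res = run_pca(mat, n_components=3)
        assert res.scores.shape[1] == 1

    def test_group_separation_on_planted_effect(self):
        from sklearn.metrics import silhouette_score

        t, _ = simulate_lcms_table(
            n_compounds=15, planted_fc=3.0, cv=0.15, seed=7
        )
        res = run_screen([t])
        scores = res.pca.scores
        groups = t.sample_meta.loc[scores.index, "tissue"]
        sil = silhouette_score(scores[["PC1"]], groups)
        assert sil > 0


class TestFoldChange:
    def _two_group(self, air, par):
        cols = [f"a{i}" for i in range(len(air))] + [
            f"p{i}" for i in range(len(par))
        ]
        conc = pd.DataFrame([air + par], index=["c1"], columns=cols)
        meta = pd.DataFrame(
            {
                "class": ["sample"] * len(cols),
                "tissue": ["airways"] * len(air) + ["parenchyma"] * len(par),
            },
            index=cols,
        )
        return FeatureTable(concentrations=conc, sample_meta=meta)

    def test_simple_ratio(self):
        res = fold_change_stats(self._two_group([2.0, 2.0], [1.0, 1.0]))
        assert res.loc["c1", "fc"] == pytest.approx(2.0)

    def test_identical_groups(self):
        res = fold_change_stats(self._two_group([1.0, 2.0], [1.0, 2.0]))
        assert res.loc["c1", "fc"] == pytest.approx(1.0)
        assert res.loc["c1", "p"] == 1.0

    def test_zero_denominator_flagged(self):
        res = fold_change_stats(self._two_group([1.0, 1.0], [0.0, 0.0]))
        assert np.isinf(res.loc["c1", "fc"])
        assert res.loc["c1", "fc_flag"] == "zero-denominator"

    def test_agrees_with_primitives(self):
        t, _ = simulate_lcms_table(n_compounds=8, planted_fc=2.0, seed=5)
        res = fold_change_stats(t)
        meta = t.sample_meta
        air = meta.index[(meta["class"] == "sample") & (meta["tissue"] == "airways")]
        par = meta.index[
            (meta["class"] == "sample") & (meta["tissue"] == "parenchyma")
        ]
        ps = []
        for comp in t.concentrations.index:
            a = t.concentrations.loc[comp, air].dropna()
            b = t.concentrations.loc[comp, par].dropna()
            ps.append(mann_whitney_u(a, b).p)
        np.testing.assert_allclose(res["p"], ps)
        np.testing.assert_allclose(res["q"], bh_fdr(ps))

    def test_planted_fc_recovered_with_power(self):
        # planted FC 4, CV 15%, n = 12/group: FC within 25%, q < 0.05
        hits, fc_ok = 0, 0
        n_runs = 30
        for seed in range(n_runs):
            t, truth = simulate_lcms_table(
                n_compounds=5,
                planted_fc={"oct_cpd01": 4.0},
                cv=0.15,
                seed=seed,
            )
            res = fold_change_stats(t)
            if abs(res.loc["oct_cpd01", "fc"] - 4.0) <= 1.0:
                fc_ok += 1
            if res.loc["oct_cpd01", "q"] < 0.05:
                hits += 1
        assert hits >= 0.95 * n_runs
        assert fc_ok >= 0.95 * n_runs


class TestSelectTargets:
    def _stats(self):
        return pd.DataFrame(
            {
                "mean_a": [100.0, 100.0, 10.0, 500.0],
                "mean_b": [50.0, 25.0, 5.0, 400.0],
                "fc": [4.0, 1.1, 2.0, 1.25],
            },
            index=["big_fc", "small_fc", "low_conc", "abundant"],
        )

    def test_zero_targets_empty(self):
        assert len(select_targets(self._stats(), max_targets=0)) == 0

    def test_fc_breaks_concentration_ties(self):
        out = select_targets(self._stats(), max_targets=2)
        assert list(out.index[:1]) == ["abundant"]
        # big_fc and small_fc tie on concentration; larger |log2 FC| wins
        assert list(out.index[1:2]) == ["big_fc"]

    def test_min_concentration_excludes(self):
        out = select_targets(self._stats(), max_targets=10, min_concentration=20.0)
        assert "low_conc" not in out.index

    def test_panel_respects_transition_budget(self):
        stats = pd.concat([self._stats()] * 3)
        stats.index = [f"c{i}" for i in range(len(stats))]
        out = select_targets(stats, max_targets=100)
        assert len(out) <= 6


class TestAggregateIsomers:
    def _table(self):
        conc = pd.DataFrame(
            {
                "s1": [9.0, 1.0, 5.0],
                "s2": [18.0, 2.0, 5.0],
            },
            index=["threo", "erythro", "other"],
        )
        meta = pd.DataFrame(
            {"class": ["sample", "sample"], "tissue": ["airways", "airways"]},
            index=["s1", "s2"],
        )
        return FeatureTable(concentrations=conc, sample_meta=meta)

    def test_stereoisomers_summed(self):
        out = aggregate_isomers(
            self._table(), {"DiHOME": ["threo", "erythro"]}
        )
        assert out.concentrations.loc["DiHOME", "s1"] == 10.0
        # the threo stereoisomer carries ~90% of the combined quantity
        assert 9.0 / 10.0 == pytest.approx(0.9)

    def test_singleton_group_identity(self):
        out = aggregate_isomers(self._table(), {"only": ["other"]})
        np.testing.assert_array_equal(
            out.concentrations.loc["only"].to_numpy(), [5.0, 5.0]
        )

    def test_column_sums_preserved(self):
        t = self._table()
        out = aggregate_isomers(t, {"DiHOME": ["threo", "erythro"]})
        np.testing.assert_allclose(
            out.concentrations.sum(axis=0), t.concentrations.sum(axis=0)
        )

    def test_missing_treated_as_zero_and_flagged(self):
        t = self._table()
        t.concentrations.loc["erythro", "s1"] = np.nan
        out = aggregate_isomers(t, {"DiHOME": ["threo", "erythro"]})
        assert out.concentrations.loc["DiHOME", "s1"] == 9.0
        assert out.compound_meta.loc["DiHOME", "summed_with_missing"] == 1

    def test_unknown_member_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            aggregate_isomers(self._table(), {"g": ["nope"]})
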