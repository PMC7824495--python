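import numpy as np
import pandas as pd
import pytest

from metchalizer.core_io import FeatureTable, TransformSpec, make_feature_meta
from metchalizer.normalize import (
    apply_metchalizer,
    apply_transform,
    fit_metchalizer,
    invert_transform,
    normalize_anchor,
    normalize_best_correlated_is,
    normalize_pqn,
    select_latent_variables,
)

from conftest import small_table


def _plain_table(values, classes=None, batches=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sids = [f"s{i}" for i in range(n)]
    fids = [f"F{j}" for j in range(p)]
    sm = pd.DataFrame(
        {
            "batch_id": batches if batches is not None else ["b0"] * n,
            "age": 30.0,
            "sex": "M",
            "class": classes if classes is not None else ["control"] * n,
            "triplicate_id": None,
            "iem_label": None,
        },
        index=pd.Index(sids, name="sample_id"),
    )
    ab = pd.DataFrame(values, index=sm.index, columns=fids)
    return FeatureTable(ab, sm, make_feature_meta(fids))


class TestTransforms:
    @pytest.mark.parametrize(
        "y,expected",
        [(0.0, 0.0), (3.0, 2.0), (8.0, 4.0)],  # ((y+1)^0.5 - 1) / 0.5
    )
    def test_boxcox_closed_form(self, y, expected):
        t = _plain_table([[y]])
        out = apply_transform(t, TransformSpec(kind="boxcox", lambda1=0.5, lambda2=1.0))
        assert out.abundance.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_none_is_identity_and_log_matches_numpy(self, tiny_table):
        out = apply_transform(tiny_table, TransformSpec(kind="none"))
        pd.testing.assert_frame_equal(out.abundance, tiny_table.abundance)
        logged = apply_transform(tiny_table, TransformSpec(kind="log"))
        np.testing.assert_allclose(
            logged.abundance.to_numpy(), np.log(tiny_table.abundance.to_numpy())
        )

    def test_transform_invertible(self, tiny_table):
        for spec in (TransformSpec("log"), TransformSpec("boxcox", 0.5, 1.0)):
            out = apply_transform(tiny_table, spec)
            back = invert_transform(out.abundance.to_numpy(), spec)
            np.testing.assert_allclose(back, tiny_table.abundance.to_numpy(), rtol=1e-10)

    def test_log_domain_violation_names_cell(self):
        t = _plain_table([[1.0, -2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match=r"s0.*F1"):
            apply_transform(t, TransformSpec(kind="log"))

    def test_label_convention(self, tiny_table):
        assert apply_transform(tiny_table, TransformSpec("log")).label == "Log-Raw"
        assert apply_transform(tiny_table, TransformSpec("boxcox")).label == "BC-Raw"
        assert apply_transform(tiny_table, TransformSpec("none")).label == "None-Raw"


class TestLatentVariables:
    @staticmethod
    def _is_matrix(seed=0, n_per_batch=25, n_batches=2, n_is=6):
        rng = np.random.default_rng(seed)
        batches = np.repeat([f"b{i}" for i in range(n_batches)], n_per_batch)
        X = rng.normal(size=(n_per_batch * n_batches, n_is))
        X += np.where(batches == "b0", 1.0, -1.0)[:, None]  # batch separation
        idx = pd.Index([f"s{i}" for i in range(len(batches))])
        return pd.DataFrame(X, index=idx), pd.Series(batches, index=idx)

    def test_i_curve_nondecreasing(self):
        X, b = self._is_matrix()
        lv = select_latent_variables(X, b)
        assert np.all(np.diff(lv.i_curve) >= -1e-12)

    def test_i_curve_matches_brute_force_recomputation(self):
        """I(K) recomputed from the exported scores by explicit summation."""
        rng = np.random.default_rng(42)
        X = pd.DataFrame(rng.normal(size=(50, 10)),
                         index=pd.Index([f"s{i}" for i in range(50)]))
        b = pd.Series(rng.choice(["b0", "b1", "b2"], size=50), index=X.index)
        lv = select_latent_variables(X, b)
        brute = []
        for k in range(lv.scores.shape[1]):
            total = 0.0
            for batch in b.unique():
                sub = lv.scores.loc[b[b == batch].index].iloc[:, k]
                total += float(((sub - sub.mean()) ** 2).sum())
            brute.append(total)
        np.testing.assert_allclose(lv.i_curve, np.cumsum(brute), rtol=1e-10)

    def test_selected_k_is_smallest_reaching_75pct(self):
        X, b = self._is_matrix(seed=3)
        lv = select_latent_variables(X, b)
        target = 0.75 * lv.i_curve[-1]
        assert lv.i_curve[lv.selected_k - 1] >= target
        if lv.selected_k > 1:
            assert lv.i_curve[lv.selected_k - 2] < target

    def test_training_scores_reproducible_via_transform(self):
        X, b = self._is_matrix(seed=5)
        X.columns = [f"IS{i}" for i in range(X.shape[1])]
        lv = select_latent_variables(X, b)
        np.testing.assert_allclose(lv.transform(X), lv.scores.to_numpy(), atol=1e-10)

    def test_rejects_missing_and_single_batch(self):
        X, b = self._is_matrix()
        X2 = X.copy()
        X2.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            select_latent_variables(X2, b)
        with pytest.raises(ValueError, match="2 batches"):
            select_latent_variables(X, pd.Series("b0", index=X.index))


def _linear_lv_table(seed=0, n_batches=4, n_per_batch=20, noise=0.0):
    """Table whose feature is exactly beta0 + beta1*LV1 + gamma_b (+ noise)."""
    rng = np.random.default_rng(seed)
    n = n_batches * n_per_batch
    batches = np.repeat([f"b{i}" for i in range(n_batches)], n_per_batch)
    sids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    # internal standards driven by one latent direction + batch separation
    latent = rng.normal(size=n) + pd.Categorical(batches).codes * 1.5
    is_mat = np.column_stack([latent * w for w in (1.0, 0.8, 1.2)])
    is_mat += rng.normal(scale=0.01, size=is_mat.shape)
    is_ids = ["IS0", "IS1", "IS2"]
    sm = pd.DataFrame({"batch_id": batches, "age": 30.0, "sex": "M",
                       "class": "control", "triplicate_id": None, "iem_label": None},
                      index=sids)
    is_df = pd.DataFrame(is_mat, index=sids, columns=is_ids)
    lv = select_latent_variables(is_df, sm["batch_id"])
    scores = lv.scores.to_numpy()[:, 0]
    gamma = {f"b{i}": g for i, g in enumerate([0.5, -0.2, -0.4, 0.1])}
    beta0, beta1 = 2.0, 0.7
    y = beta0 + beta1 * scores + np.array([gamma[b] for b in batches])
    y = y + rng.normal(scale=noise, size=n)
    ab = pd.concat([pd.Series(y, index=sids, name="F0"), is_df], axis=1)
    fm = make_feature_meta(["F0"] + is_ids,
                           is_internal_standard=[False, True, True, True])
    table = FeatureTable(ab, sm, fm)
    return table, (beta0, beta1, gamma)


class TestMetchalizer:
    def test_noiseless_parameter_recovery(self):
        """Exactly linear data: beta and gamma recovered to 1e-6."""
        table, (beta0, beta1, gamma) = _linear_lv_table()
        fit = fit_metchalizer(table, transform_spec=TransformSpec("none"))
        assert fit.selected_k >= 1
        assert fit.coefficients.loc["F0", "beta0"] == pytest.approx(beta0, abs=1e-6)
        assert fit.coefficients.loc["F0", "beta1"] == pytest.approx(beta1, abs=1e-6)
        for b, g in gamma.items():
            assert fit.random_intercepts.loc["F0", b] == pytest.approx(g, abs=1e-6)

    def test_single_batch_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        n = 40
        sids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        is_df = pd.DataFrame(rng.normal(size=(n, 3)), index=sids,
                             columns=["IS0", "IS1", "IS2"])
        # two pseudo-batches required for PLS; merge into one for the fit check
        sm = pd.DataFrame({"batch_id": np.repeat(["b0", "b1"], n // 2), "age": 30.0,
                           "sex": "M", "class": "control", "triplicate_id": None,
                           "iem_label": None}, index=sids)
        y = 1.0 + rng.normal(scale=0.1, size=n)
        ab = pd.concat([pd.Series(y, index=sids, name="F0"), is_df], axis=1)
        fm = make_feature_meta(["F0", "IS0", "IS1", "IS2"],
                               is_internal_standard=[False, True, True, True])
        fit = fit_metchalizer(FeatureTable(ab, sm, fm), transform_spec=TransformSpec("none"))
        # with weak batch structure the intercepts stay near zero
        assert fit.random_intercepts.loc["F0"].abs().max() < 0.2

    def test_outlier_sample_does_not_move_beta(self):
        """A +10 SD sample is excluded by the |Z| > 2 pre-filter."""
        table, _ = _linear_lv_table(seed=2, n_per_batch=50, noise=0.05)
        spiked = table.copy()
        col = spiked.abundance["F0"].to_numpy().copy()
        col[3] += 10 * col.std()
        spiked.abundance["F0"] = col
        fit_clean = fit_metchalizer(table, transform_spec=TransformSpec("none"))
        fit_spiked = fit_metchalizer(spiked, transform_spec=TransformSpec("none"))
        assert "s3" in fit_spiked.outliers["F0"]
        diff = np.abs(
            fit_clean.coefficients.loc["F0"].to_numpy()
            - fit_spiked.coefficients.loc["F0"].to_numpy()
        )
        assert diff.max() < 1e-3 + 1e-9

    def test_apply_zero_noise_gives_constant_features(self):
        table, _ = _linear_lv_table()
        fit = fit_metchalizer(table, transform_spec=TransformSpec("none"))
        norm = apply_metchalizer(table, fit)
        vals = norm.abundance["F0"]
        assert vals.std() == pytest.approx(0.0, abs=1e-8)

    def test_corrected_median_equals_prediction_median(self):
        """The recentering constant added during correction equals the stored
        prediction median exactly: corrected - recenter must reproduce the
        raw residuals y - yhat."""
        table, _ = _linear_lv_table(noise=0.1, seed=4)
        fit = fit_metchalizer(table, transform_spec=TransformSpec("none"))
        norm = apply_metchalizer(table, fit)
        corrected = norm.abundance["F0"].to_numpy()
        resid_median = np.median(corrected - fit.recenter_global["F0"])
        # corrected - recenter = y - yhat: its median is the median residual
        y = table.abundance["F0"].to_numpy()
        scores = fit.latent.transform(table.abundance)
        pred = fit.predict(scores, table.sample_meta["batch_id"].to_numpy(), "F0")
        assert resid_median == pytest.approx(np.median(y - pred), abs=1e-9)

    def test_provenance_label(self):
        table, _ = _linear_lv_table()
        fit = fit_metchalizer(table, transform_spec=TransformSpec("none"))
        norm = apply_metchalizer(table, fit)
        assert norm.label == "None-Metchalizer"
        assert norm.provenance["method"] == "Metchalizer"

    def test_unknown_batch_rejected_at_apply(self):
        table, _ = _linear_lv_table()
        fit = fit_metchalizer(table, transform_spec=TransformSpec("none"))
        other = table.copy()
        other.sample_meta["batch_id"] = "never_seen"
        with pytest.raises(ValueError, match="never_seen"):
            apply_metchalizer(other, fit)


class TestBestCorrelatedIS:
    def test_exact_proportionality_gives_constant(self):
        rng = np.random.default_rng(0)
        n = 30
        is_vals = rng.lognormal(3, 0.4, size=n)
        feature = 2.5 * is_vals
        sids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        ab = pd.DataFrame({"F0": feature, "IS0": is_vals, "IS1": rng.lognormal(3, 0.4, n)},
                          index=sids)
        sm = pd.DataFrame({"batch_id": np.repeat(["b0", "b1", "b2"], 10), "age": 30.0,
                           "sex": "M", "class": "control", "triplicate_id": None,
                           "iem_label": None}, index=sids)
        fm = make_feature_meta(["F0", "IS0", "IS1"],
                               is_internal_standard=[False, True, True])
        out = normalize_best_correlated_is(FeatureTable(ab, sm, fm))
        assert out.provenance["selected_is"]["F0"] == "IS0"
        expected = 2.5 * np.median(is_vals)
        np.testing.assert_allclose(out.abundance["F0"].to_numpy(), expected, rtol=1e-12)

    def test_selection_matches_brute_force_enumeration(self):
        """Best IS equals argmax of per-batch Spearman means computed by hand."""
        from scipy import stats

        rng = np.random.default_rng(8)
        n = 45
        sids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        batches = np.repeat(["b0", "b1", "b2"], 15)
        is_cols = {f"IS{m}": rng.lognormal(3, 0.5, n) for m in range(4)}
        feature = is_cols["IS2"] ** 0.8 * rng.lognormal(0, 0.2, n)
        ab = pd.DataFrame({"F0": feature, **is_cols}, index=sids)
        sm = pd.DataFrame({"batch_id": batches, "age": 30.0, "sex": "M",
                           "class": "control", "triplicate_id": None,
                           "iem_label": None}, index=sids)
        fm = make_feature_meta(list(ab.columns),
                               is_internal_standard=[False] + [True] * 4)
        out = normalize_best_correlated_is(FeatureTable(ab, sm, fm))

        avg = {}
        for m in is_cols:
            rhos = []
            for b in ("b0", "b1", "b2"):
                mask = batches == b
                rhos.append(stats.spearmanr(feature[mask], is_cols[m][mask]).statistic)
            avg[m] = np.mean(rhos)
        assert out.provenance["selected_is"]["F0"] == max(avg, key=avg.get)


class TestAnchorAndPQN:
    def test_anchor_removes_multiplicative_batch_factor(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(4, 0.3, size=(6, 4))
        values = np.vstack([base, base * 2.0])  # second batch scaled 2x
        classes = (["qc", "qc"] + ["control"] * 4) * 2
        batches = ["b0"] * 6 + ["b1"] * 6
        t = _plain_table(values, classes=classes, batches=batches)
        out = normalize_anchor(t)
        qc = out.abundance.loc[out.sample_meta["class"] == "qc"]
        means = qc.groupby(out.sample_meta.loc[qc.index, "batch_id"]).mean()
        np.testing.assert_allclose(means.loc["b0"].to_numpy(), means.loc["b1"].to_numpy(),
                                   rtol=1e-12)

    def test_anchor_requires_anchors_per_batch(self):
        t = _plain_table(np.ones((4, 2)), classes=["control"] * 4,
                         batches=["b0", "b0", "b1", "b1"])
        with pytest.raises(ValueError, match="anchor"):
            normalize_anchor(t)

    def test_pqn_identical_samples_unchanged(self):
        row = np.array([3.0, 5.0, 7.0, 11.0])
        t = _plain_table(np.tile(row, (5, 1)))
        out = normalize_pqn(t)
        np.testing.assert_allclose(out.abundance.to_numpy(), t.abundance.to_numpy())

    def test_pqn_pure_dilution_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(3, 0.5, size=7)
        values = np.vstack([base, base, base * 3.0, base])
        t = _plain_table(values)
        out = normalize_pqn(t)
        assert out.provenance["dilution_factors"].iloc[2] == pytest.approx(3.0)
        np.testing.assert_allclose(out.abundance.iloc[2].to_numpy(), base, rtol=1e-12)

    def test_pqn_median_quotient_matches_brute_force(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(2, 0.6, size=(5, 7))
        t = _plain_table(values)
        out = normalize_pqn(t)
        ref = np.median(values, axis=0)
        for i in range(5):
            expected = np.median(values[i] / ref)
            assert out.provenance["dilution_factors"].iloc[i] == pytest.approx(expected)

    def test_pqn_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(2, 0.5, size=(6, 5))
        a = normalize_pqn(_plain_table(values))
        b = normalize_pqn(_plain_table(values * 100.0))
        np.testing.assert_allclose(b.abundance.to_numpy(), 100.0 * a.abundance.to_numpy(),
                                   rtol=1e-12)
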