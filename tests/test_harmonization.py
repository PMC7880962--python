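"""ComBat parameter recovery (incl. the R sva oracle) and SVD filtering."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radbatch.harmonization import combat, combat_apply, combat_fit, svd_correct
from radbatch.synthetic import BatchEffectSpec, make_clinical_cohort


def two_batch_table(
    n_per_batch=200, nf=30, shift=0.0, scale=1.0, seed=0, class_effect=0.0
):
    specs = [
        BatchEffectSpec("a", np.zeros(nf), np.ones(nf)),
        BatchEffectSpec("b", np.full(nf, shift), np.full(nf, scale)),
    ]
    return make_clinical_cohort(
        (n_per_batch, n_per_batch),
        nf,
        class_effect,
        specs,
        ["a"] * n_per_batch + ["b"] * n_per_batch,
        1.0,
        seed=seed,
    )


def feature_cols(df):
    return [c for c in df.columns if c.startswith("f")]


class TestComBatFit:
    def test_single_batch_rejected(self):
        t = two_batch_table(nf=4)
        t["batch"] = "only"
        with pytest.raises(ValueError, match="2 batches"):
            combat_fit(t, feature_cols(t), "batch")

    def test_one_sample_batch_rejected_by_name(self):
        t = two_batch_table(n_per_batch=5, nf=4)
        t.loc[t.index[-1], "batch"] = "tiny"
        with pytest.raises(ValueError, match="tiny"):
            combat_fit(t, feature_cols(t), "batch")

    def test_constant_feature_excluded_and_passed_through(self):
        t = two_batch_table(nf=4)
        t["f000"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            model = combat_fit(t, feature_cols(t), "batch")
        assert model.constant_features == ["f000"]
        corrected = combat_apply(model, t)
        assert (corrected["f000"] == 7.0).all()

    def test_null_batches_give_small_effects(self):
        t = two_batch_table(shift=0.0, scale=1.0, seed=4)
        model = combat_fit(t, feature_cols(t), "batch")
        gamma = model.gamma_star.to_numpy()
        delta = model.delta_star.to_numpy()
        assert (np.abs(gamma) < 0.05).mean() >= 0.90
        assert (np.abs(delta - 1.0) < 0.05).mean() >= 0.90

    def test_recovers_known_shift_and_scale(self):
        t = two_batch_table(shift=10.0, scale=2.0, seed=8)
        model = combat_fit(t, feature_cols(t), "batch")
        # gamma/delta live on the standardized scale; convert back
        sd = model.pooled_sd.to_numpy()
        shift_hat = (
            model.gamma_star.loc["b"].to_numpy() - model.gamma_star.loc["a"].to_numpy()
        ) * sd
        assert np.median(np.abs(shift_hat - 10.0)) / 10.0 < 0.05
        scale_hat = np.sqrt(
            model.delta_star.loc["b"].to_numpy() / model.delta_star.loc["a"].to_numpy()
        )
        assert np.median(np.abs(scale_hat - 2.0)) / 2.0 < 0.10

    def test_matches_r_sva_combat(self, tmp_path):
        """Corrected values agree with Bioconductor sva::ComBat."""
        nf = 8
        specs = [
            BatchEffectSpec("a", np.zeros(nf), np.ones(nf)),
            BatchEffectSpec("b", np.linspace(-3, 3, nf), np.full(nf, 1.8)),
        ]
        t = make_clinical_cohort(
            (12, 12), nf, 1.0, specs, ["a"] * 10 + ["b"] * 14, 1.0, seed=11
        )
        feats = feature_cols(t)
        mine = combat_apply(combat_fit(t, feats, "batch"), t)
        t[feats].T.to_csv(tmp_path / "dat.csv")
        t[["batch"]].to_csv(tmp_path / "batch.csv")
        script = textwrap.dedent(
            """
            suppressMessages(library(sva))
            dat <- as.matrix(read.csv("dat.csv", row.names = 1))
            batch <- read.csv("batch.csv", row.names = 1)$batch
            out <- ComBat(dat = dat, batch = batch, mod = NULL, par.prior = TRUE)
            write.csv(out, "r_corr.csv")
            """
        )
        subprocess.run(
            ["Rscript", "-e", script], cwd=tmp_path, check=True,
            capture_output=True, timeout=300,
        )
        ref = pd.read_csv(tmp_path / "r_corr.csv", index_col=0).to_numpy().T
        np.testing.assert_allclose(mine[feats].to_numpy(), ref, atol=1e-5)

    def test_nonparametric_mode_close_to_parametric_on_clean_data(self):
        t = two_batch_table(n_per_batch=60, nf=25, shift=4.0, scale=1.5, seed=3)
        feats = feature_cols(t)
        par = combat(t, feats, "batch", mode="parametric")
        nonpar = combat(t, feats, "batch", mode="nonparametric")
        resid = np.abs(par[feats].to_numpy() - nonpar[feats].to_numpy())
        assert np.median(resid) < 0.25  # same model, different shrinkage prior


class TestComBatApply:
    def test_unseen_batch_label_rejected(self):
        t = two_batch_table(nf=4)
        model = combat_fit(t, feature_cols(t), "batch")
        t2 = t.copy()
        t2.loc[t2.index[0], "batch"] = "new_scanner"
        with pytest.raises(ValueError, match="new_scanner"):
            combat_apply(model, t2)

    def test_near_identity_on_null_batches(self):
        t = two_batch_table(shift=0.0, scale=1.0, seed=5)
        feats = feature_cols(t)
        corrected = combat(t, feats, "batch")
        rms = np.sqrt(((corrected[feats] - t[feats]) ** 2).mean())
        pooled_sd = t[feats].std()
        assert (rms < 0.1 * pooled_sd).all()

    def test_location_shift_removed(self):
        t = two_batch_table(shift=10.0, seed=6)
        feats = feature_cols(t)
        corrected = combat(t, feats, "batch")
        before = np.abs(
            t[t.batch == "b"][feats].mean() - t[t.batch == "a"][feats].mean()
        )
        after = np.abs(
            corrected[corrected.batch == "b"][feats].mean()
            - corrected[corrected.batch == "a"][feats].mean()
        )
        assert ((before - after) / before > 0.90).all()

    def test_second_pass_estimates_near_zero(self):
        t = two_batch_table(shift=6.0, scale=1.5, seed=7)
        feats = feature_cols(t)
        once = combat(t, feats, "batch")
        refit = combat_fit(once, feats, "batch")
        assert np.abs(refit.gamma_star.to_numpy()).max() < 0.05

    def test_metadata_columns_preserved(self):
        t = two_batch_table(nf=4)
        corrected = combat(t, feature_cols(t), "batch")
        pd.testing.assert_frame_equal(
            corrected[["sample_id", "class_label", "batch"]],
            t[["sample_id", "class_label", "batch"]],
        )

    def test_between_batch_f_statistics_decrease(self):
        t = two_batch_table(shift=5.0, scale=1.5, seed=9)
        feats = feature_cols(t)
        corrected = combat(t, feats, "batch")
        improved = 0
        for f in feats:
            fa = stats.f_oneway(
                t[t.batch == "a"][f], t[t.batch == "b"][f]
            ).statistic
            fb = stats.f_oneway(
                corrected[corrected.batch == "a"][f],
                corrected[corrected.batch == "b"][f],
            ).statistic
            improved += fb < fa
        assert improved / len(feats) >= 0.95


class TestSVDCorrect:
    def test_no_removal_is_identity(self, rng):
        nf, n = 12, 50
        df = pd.DataFrame(rng.normal(size=(n, nf)), columns=[f"f{i}" for i in range(nf)])
        df["batch"] = rng.permutation(["a", "b"] * (n // 2))
        out, info = svd_correct(df, [f"f{i}" for i in range(nf)], ["batch"], alpha=1e-12)
        assert info.removed_components == []
        np.testing.assert_allclose(
            out[[f"f{i}" for i in range(nf)]].to_numpy(),
            df[[f"f{i}" for i in range(nf)]].to_numpy(),
            atol=1e-9,
        )

    def test_permuted_labels_remove_nothing(self, rng):
        nf, n = 10, 80
        feats = [f"f{i}" for i in range(nf)]
        df = pd.DataFrame(rng.normal(size=(n, nf)), columns=feats)
        df["batch"] = rng.permutation(["a"] * 40 + ["b"] * 40)
        out, info = svd_correct(df, feats, ["batch"], alpha=0.001)
        assert info.removed_components == []

    def test_rank_one_batch_structure_removed(self, rng):
        nf, n = 15, 60
        feats = [f"f{i}" for i in range(nf)]
        x = rng.normal(size=(n, nf))
        batch = np.array(["a"] * 30 + ["b"] * 30)
        direction = rng.normal(size=nf)
        x[batch == "b"] += 6.0 * direction  # strong rank-1 batch offset
        df = pd.DataFrame(x, columns=feats)
        df["batch"] = batch
        out, info = svd_correct(df, feats, ["batch"], alpha=0.001)
        assert 0 in info.removed_components
        assert info.association_p.iloc[0, 0] < 1e-6
        after = out.groupby("batch")[feats].mean()
        np.testing.assert_allclose(
            after.loc["a"].to_numpy(), after.loc["b"].to_numpy(), atol=0.6
        )

    def test_removing_all_components_leaves_grand_mean(self, rng):
        nf, n = 6, 30
        feats = [f"f{i}" for i in range(nf)]
        df = pd.DataFrame(rng.normal(size=(n, nf)), columns=feats)
        df["batch"] = ["a", "b"] * 15
        out, info = svd_correct(df, feats, ["batch"], alpha=1.1)  # p < 1.1 always
        assert len(info.removed_components) == min(n, nf)
        np.testing.assert_allclose(
            out[feats].to_numpy(),
            np.tile(df[feats].mean().to_numpy(), (n, 1)),
            atol=1e-9,
        )

    def test_variance_explained_sums_to_one(self, rng):
        nf, n = 8, 40
        feats = [f"f{i}" for i in range(nf)]
        df = pd.DataFrame(rng.normal(size=(n, nf)), columns=feats)
        df["batch"] = ["a", "b"] * 20
        _, info = svd_correct(df, feats, ["batch"])
        assert info.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
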