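import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofuse import CohortSpec, RunConfig, gen_cohort
from neurofuse.core_io import ValidationError, make_atlas_spec
from neurofuse.train_eval import (auc, confusion_metrics, extract_features,
                                  kfold_split, mc_dropout_predict,
                                  rank_biomarkers, train_model)


def _pair_count_auc(y, scores):
    """Independent oracle: concordant-pair fraction (ties count half)."""
    y = np.asarray(y)
    scores = np.asarray(scores)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return 100.0 * (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_printed_formula_example(self):
        # TP=9, TN=8, FP=2, FN=1 -> ACC 85, SEN 90, SPE 80
        y = np.array([1] * 10 + [0] * 10)
        y_hat = np.array([0.9] * 9 + [0.1] + [0.8] * 2 + [0.2] * 8)
        rep = confusion_metrics(y, y_hat)
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (9, 8, 2, 1)
        assert rep.acc == pytest.approx(85.0)
        assert rep.sen == pytest.approx(90.0)
        assert rep.spe == pytest.approx(80.0)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        rep = confusion_metrics(y, y.astype(float))
        assert rep.acc == rep.sen == rep.spe == 100.0

    def test_all_positive_predictor(self):
        y = np.array([0, 1] * 5)
        rep = confusion_metrics(y, np.ones(10))
        assert rep.sen == 100.0 and rep.spe == 0.0 and rep.acc == 50.0

    def test_ties_at_threshold_go_positive(self):
        rep = confusion_metrics(np.array([1]), np.array([0.5]))
        assert rep.tp == 1

    def test_absent_class_flagged_not_zero(self):
        rep = confusion_metrics(np.array([1, 1]), np.array([0.9, 0.2]))
        assert rep.spe is None
        assert "spe" in rep.undefined and "auc" in rep.undefined

    def test_acc_is_confusion_weighted_mean_of_sen_spe(self, rng):
        """Metric identity on random confusion tables."""
        for _ in range(100):
            y = rng.integers(0, 2, 50)
            if len(np.unique(y)) < 2:
                continue
            rep = confusion_metrics(y, rng.random(50))
            n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
            weighted = (rep.sen * n_pos + rep.spe * n_neg) / len(y)
            assert rep.acc == pytest.approx(weighted, abs=1e-9)


class TestAuc:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        assert auc(y, y.astype(float)) == pytest.approx(100.0)

    def test_four_point_hand_worked(self):
        # 3 of 4 label-discordant pairs are ranked correctly -> 75
        assert auc(np.array([0, 0, 1, 1]),
                   np.array([0.1, 0.4, 0.35, 0.8])) == pytest.approx(75.0)

    def test_random_scores_near_chance(self, rng):
        y = rng.integers(0, 2, 2000)
        assert auc(y, rng.random(2000)) == pytest.approx(50.0, abs=3.0)

    def test_single_class_undefined(self):
        assert auc(np.ones(5), np.linspace(0, 1, 5)) is None

    def test_matches_pair_counting_oracle(self, rng):
        """ROC-area equals the rank (Mann-Whitney) statistic."""
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)      # force occasional ties
            assert auc(y, scores) == pytest.approx(
                _pair_count_auc(y, scores), abs=1e-9)


class TestKfold:
    def test_fold_sizes_and_partition_at_cohort_scale(self):
        rng = np.random.default_rng(0)
        labels = np.zeros(871, dtype=int)
        labels[:403] = 1
        rng.shuffle(labels)
        masks = kfold_split(labels, k=10, seed=0)
        sizes = sorted(m.sum() for m in masks)
        assert set(sizes) <= {87, 88}
        total = np.zeros(871, dtype=int)
        for m in masks:
            total += m
        assert np.all(total == 1)          # every subject in exactly one test fold

    def test_stratification_preserves_class_ratio(self):
        labels = np.array([0] * 80 + [1] * 20)
        for m in kfold_split(labels, k=5, seed=1):
            assert labels[m].sum() == 4

    def test_same_seed_same_split(self):
        labels = np.arange(40) % 2
        a = kfold_split(labels, k=4, seed=3)
        b = kfold_split(labels, k=4, seed=3)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma, mb)

    def test_tiny_class_degrades_with_warning(self):
        labels = np.array([1, 1] + [0] * 18)
        with pytest.warns(UserWarning, match="unstratified"):
            masks = kfold_split(labels, k=5, seed=0)
        assert len(masks) == 5


@pytest.fixture(scope="module")
def trained_smoke():
    """One small planted cohort trained for a few epochs (shared)."""
    cohort = gen_cohort(CohortSpec(n_subjects=40, volume_shape=(12, 12, 12),
                                   blob_radius=2, pairs_per_atlas=5,
                                   n_timepoints=30, n_frames=3, seed=5))
    config = RunConfig(seed=5, folds=2, epochs=8, patience=8, min_epochs=1,
                       espm_hidden=16, gat_hidden=16, gat_heads=2, gat_out_dim=8)
    return cohort, config, train_model(cohort, config)


class TestTrainModel:
    def test_smoke_run_emits_wellformed_report(self, trained_smoke):
        cohort, config, result = trained_smoke
        assert len(result.report.folds) == 2
        frame = result.report.to_frame()
        assert list(frame["fold"])[:2] == [0, 1]
        assert len(result.predictions) == 40            # every subject predicted once
        assert set(result.predictions["fold"]) == {0, 1}
        assert result.predictions["y_hat"].between(0, 1).all()
        for rep in result.report.folds:
            assert rep.n == 20

    def test_loss_history_finite_and_nonempty(self, trained_smoke):
        _, _, result = trained_smoke
        assert all(len(h) > 0 for h in result.history)
        assert all(np.isfinite(h).all() for h in result.history)

    def test_fused_embedding_export_shape(self, trained_smoke):
        cohort, config, result = trained_smoke
        assert result.fused_embeddings.shape == (40, config.fusion_dim)


class TestMcDropout:
    def test_zero_dropout_rate_gives_zero_sd(self, trained_smoke):
        _, _, result = trained_smoke
        model = result.last_model
        saved = model.gat.dropout
        model.gat.dropout = 0.0
        try:
            mean, sd = mc_dropout_predict(model, passes=5,
                                          rng=np.random.default_rng(0))
        finally:
            model.gat.dropout = saved
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)
        assert np.all((mean > 0) & (mean < 1))

    def test_uncertainty_nonnegative_and_mean_in_unit_interval(self, trained_smoke):
        _, _, result = trained_smoke
        mean, sd = mc_dropout_predict(result.last_model, passes=10,
                                      rng=np.random.default_rng(1))
        assert np.all(sd >= 0)
        assert np.all((mean > 0) & (mean < 1))

    def test_too_few_passes_rejected(self, trained_smoke):
        _, _, result = trained_smoke
        with pytest.raises(ValidationError, match="2 passes"):
            mc_dropout_predict(result.last_model, passes=1)

    def test_mc_mean_converges_to_long_run_mean(self, trained_smoke):
        """Monte-Carlo mean at T=200 sits within 3 SE of a T=1500 estimate."""
        _, _, result = trained_smoke
        model = result.last_model
        mean_small, sd_small = mc_dropout_predict(
            model, passes=200, rng=np.random.default_rng(2))
        mean_big, _ = mc_dropout_predict(
            model, passes=1500, rng=np.random.default_rng(3))
        se = sd_small / np.sqrt(200)
        frac_inside = np.mean(np.abs(mean_small - mean_big) <= 3 * se + 1e-9)
        assert frac_inside > 0.95


class TestRankBiomarkers:
    def _atlas(self):
        return make_atlas_spec("toy", n_pairs=3)      # 6 regions + average node

    def test_uniform_alpha_ranks_by_index(self):
        atlas = self._atlas()
        alphas = {"toy": np.full((5, 7), 0.5)}
        report = rank_biomarkers(alphas, [atlas], k=3)
        assert list(report.top(3)["roi_index"]) == [0, 1, 2]

    def test_planted_importance_ranks_first(self, rng):
        atlas = self._atlas()
        alpha = rng.uniform(0.2, 0.4, size=(8, 7))
        alpha[:, 4] += 0.5                       # raise one ROI for every subject
        report = rank_biomarkers({"toy": alpha}, [atlas], k=6)
        assert report.top(1)["roi_index"].item() == 4

    def test_average_node_excluded(self, rng):
        atlas = self._atlas()
        alpha = rng.uniform(0.2, 0.4, size=(4, 7))
        alpha[:, 6] = 0.99                       # average node dominates raw alpha
        report = rank_biomarkers({"toy": alpha}, [atlas], k=6)
        assert len(report.table) == 6            # regions only
        assert not (report.table["roi_index"] == 6).any()

    def test_k_clamped_with_warning(self, rng):
        atlas = self._atlas()
        alphas = {"toy": rng.random((3, 7))}
        with pytest.warns(UserWarning, match="clamp"):
            report = rank_biomarkers(alphas, [atlas], k=50)
        assert len(report.top(50)) == 6

    def test_exactly_k_rows(self, rng):
        atlas = make_atlas_spec("big", n_pairs=20, n_unpaired=1)   # 41 regions
        alphas = {"big": rng.random((3, 42))}
        report = rank_biomarkers(alphas, [atlas], k=10)
        assert len(report.top(10)) == 10

    def test_ranks_are_a_permutation(self, rng):
        atlas = self._atlas()
        report = rank_biomarkers({"toy": rng.random((3, 7))}, [atlas], k=6)
        assert sorted(report.table["rank"]) == list(range(1, 7))


@pytest.fixture(scope="module")
def tiny_cohort():
    return gen_cohort(CohortSpec(n_subjects=16, volume_shape=(10, 10, 10),
                                 blob_radius=2, pairs_per_atlas=4,
                                 n_timepoints=24, n_frames=3, seed=9))


class TestAblationToggles:
    """Structural ablations all run end-to-end on a tiny cohort."""

    @pytest.mark.parametrize("toggle", ["use_acfe", "use_espm", "use_marl",
                                        "use_papg"])
    def test_disabled_component_still_trains(self, tiny_cohort, toggle):
        config = RunConfig(seed=9, folds=2, epochs=3, patience=3, min_epochs=1,
                           espm_hidden=8, gat_hidden=8, gat_heads=2,
                           gat_out_dim=4, **{toggle: False})
        result = train_model(tiny_cohort, config)
        assert len(result.predictions) == 16
        if toggle == "use_acfe":
            assert set(result.last_model.bundle.modalities) == {"ho", "ez"}

    def test_disabled_population_graph_has_no_edges(self, tiny_cohort):
        config = RunConfig(seed=9, folds=2, epochs=2, patience=2, min_epochs=1,
                           espm_hidden=8, gat_hidden=8, gat_heads=2,
                           gat_out_dim=4, use_papg=False)
        result = train_model(tiny_cohort, config)
        assert result.last_model.graph.adjacency.sum() == 0
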