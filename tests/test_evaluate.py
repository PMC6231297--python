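import numpy as np
import pytest

from mcipredict.evaluate import (
    ExperimentConfig,
    FusionConfig,
    FusionPipeline,
    compute_metrics,
    kfold_cv,
    loocv,
    roc_curve_points,
    run_experiment,
    run_patch_vote_comparison,
)
from mcipredict.cnn import CnnConfig
from mcipredict.synthetic import SyntheticConfig


def pairwise_auc(truth, scores):
    """Brute-force Mann-Whitney oracle: P(score_pos > score_neg) + ties/2."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    pos = scores[truth > 0]
    neg = scores[truth <= 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_count_arithmetic(self):
        # 8/10 converters and 6/10 non-converters correct
        truth = np.r_[np.ones(10), -np.ones(10)]
        pred = np.r_[np.ones(8), -np.ones(2), -np.ones(6), np.ones(4)]
        res = compute_metrics(truth, pred, np.linspace(1, 0, 20))
        assert res.accuracy == pytest.approx(0.70)
        assert res.sensitivity == pytest.approx(0.80)
        assert res.specificity == pytest.approx(0.60)

    def test_perfect_ranking_auc(self):
        truth = np.r_[np.ones(5), -np.ones(5)]
        scores = np.r_[np.arange(5, 10), np.arange(5)]
        res = compute_metrics(truth, np.sign(scores - 4.5), scores)
        assert res.auc == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = np.where(rng.random(30) > 0.5, 1, -1)
        if np.unique(truth).size < 2:
            truth[0] = -truth[0]
        scores = rng.integers(0, 6, size=30).astype(float)  # forces ties
        res = compute_metrics(truth, np.sign(scores - 2.5), scores)
        assert res.auc == pytest.approx(pairwise_auc(truth, scores), abs=1e-12)

    def test_single_class_truth_flagged(self):
        res = compute_metrics([1, 1, 1], [1, -1, 1], [0.3, 0.1, 0.5])
        assert np.isnan(res.specificity)
        assert np.isnan(res.auc)
        assert "no_negative_subjects" in res.flags
        assert res.sensitivity == pytest.approx(2 / 3)

    def test_roc_points_monotone(self, rng):
        truth = np.where(rng.random(50) > 0.4, 1, -1)
        scores = rng.normal(size=50)
        pts = roc_curve_points(truth, scores)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)
        np.testing.assert_allclose(pts[0], [0, 0])
        np.testing.assert_allclose(pts[-1], [1, 1])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([1, -1], [1], [0.1])


def _struct_pipeline(n_pos=10, n_neg=10, p_f=6, l_f=4, effect=2.0, seed=0, **cfg_kw):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    X = rng.normal(size=(n, 20))
    X[:n_pos, :5] += effect
    labels = np.r_[np.ones(n_pos), -np.ones(n_neg)]
    ids = [f"s{i}" for i in range(n)]
    cfg = FusionConfig(p_f=p_f, l_f=l_f, **cfg_kw)
    return FusionPipeline(ids, labels, struct_features=X, cfg=cfg)


class TestLoocv:
    def test_fold_structure_and_leakage(self):
        pipeline = _struct_pipeline()
        fit_log = []
        original_fit = FusionPipeline.fit

        def logging_fit(self, idx):
            out = original_fit(self, idx)
            fit_log.append(set(self.last_fit_ids))
            return out

        FusionPipeline.fit = logging_fit
        try:
            res = loocv(pipeline)
        finally:
            FusionPipeline.fit = original_fit
        assert len(fit_log) == 20  # n folds
        held_out = [set(pipeline.ids) - ids for ids in fit_log]
        # each subject held out exactly once, alone
        assert sorted(h.pop() for h in held_out) == sorted(pipeline.ids)

    def test_separable_data_high_accuracy(self):
        res = loocv(_struct_pipeline(effect=3.0))
        assert res.accuracy >= 0.9
        assert res.auc >= 0.95

    def test_fold_count_308(self):
        # 169 + 139 MCI subjects -> 308 folds
        res = loocv(_struct_pipeline(n_pos=169, n_neg=139, effect=1.0, seed=3))
        assert len(res.per_subject) == 308
        assert sorted(res.per_subject["id"]) == sorted(f"s{i}" for i in range(308))

    def test_single_class_fold_error(self):
        pipeline = _struct_pipeline(n_pos=1, n_neg=8)
        with pytest.raises(ValueError, match="lost one class"):
            loocv(pipeline)


class TestKfold:
    def test_k_equals_n_reduces_to_loocv(self):
        p1 = _struct_pipeline(seed=5)
        p2 = _struct_pipeline(seed=5)
        r_loo = loocv(p1)
        r_k = kfold_cv(p2, k=20)
        np.testing.assert_allclose(r_loo.per_subject["score"], r_k.per_subject["score"])

    def test_every_subject_tested_once(self):
        res = kfold_cv(_struct_pipeline(n_pos=12, n_neg=12), k=4, seed=1)
        assert sorted(res.per_subject["id"]) == sorted(f"s{i}" for i in range(24))

    def test_stratification_within_one(self):
        from sklearn.model_selection import StratifiedKFold

        labels = np.r_[np.ones(13), -np.ones(11)]
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        global_ratio = 13 / 24
        for _, test_idx in skf.split(np.zeros(24), labels):
            n_pos = (labels[test_idx] > 0).sum()
            expected = global_ratio * len(test_idx)
            assert abs(n_pos - expected) <= 1

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="exceeds"):
            kfold_cv(_struct_pipeline(n_pos=3, n_neg=3), k=10)


class TestPcaRefitModes:
    def test_global_pca_mode_runs(self):
        res = kfold_cv(_struct_pipeline(refit_pca_per_fold=False), k=4)
        assert 0.0 <= res.accuracy <= 1.0


class TestBaselineHarness:
    @pytest.mark.parametrize("classifier", ["elm", "svm", "rf"])
    def test_baselines_share_cv_harness(self, classifier):
        # same folds, same features, only the classifier differs
        res = kfold_cv(
            _struct_pipeline(effect=3.0, seed=9, classifier=classifier), k=4, seed=0
        )
        assert res.accuracy >= 0.8
        assert sorted(res.per_subject["id"]) == sorted(f"s{i}" for i in range(20))


def _tiny_experiment(seed=0, **overrides) -> ExperimentConfig:
    kwargs = dict(
        synthetic=SyntheticConfig(
            n_per_group={"AD": 8, "NC": 8, "MCIc": 6, "MCInc": 6},
            atrophy_effect={"AD": 0.6, "MCIc": 0.45, "MCInc": 0.1, "NC": 0.0},
            noise_sd=2.0,
            struct_effect_size=1.5,
            seed=seed,
        ),
        cnn=CnnConfig(epochs=1, batch_size=64, seed=seed),
        fusion=FusionConfig(p_c=6, p_f=6, l_c=5, l_f=4),
        n_patches=10,
        cv="kfold",
        k=3,
        seed=seed,
    )
    kwargs.update(overrides)
    return ExperimentConfig(**kwargs)


class TestRunExperiment:
    def test_ablation_rows(self):
        res = run_experiment(_tiny_experiment())
        assert set(res.results) == {"fused", "cnn_only", "struct_only"}
        for r in res.results.values():
            assert 0.0 <= r.accuracy <= 1.0

    def test_cnn_never_sees_mci(self):
        res = run_experiment(_tiny_experiment(ablations=("fused",)))
        assert res.artifacts["cnn_training_groups"] == ["AD", "NC"]
        assert res.artifacts["age_model_fit_groups"] == ["NC"]

    def test_determinism(self):
        cfg1 = _tiny_experiment(seed=4, ablations=("fused",))
        cfg2 = _tiny_experiment(seed=4, ablations=("fused",))
        r1 = run_experiment(cfg1).results["fused"]
        r2 = run_experiment(cfg2).results["fused"]
        assert r1.per_subject.equals(r2.per_subject)

    def test_no_age_correction_flag(self):
        res = run_experiment(
            _tiny_experiment(age_correction=False, ablations=("struct_only",))
        )
        assert "age_model_fit_groups" not in res.artifacts

    def test_unknown_cv_scheme(self):
        with pytest.raises(ValueError, match="unknown cv"):
            run_experiment(_tiny_experiment(cv="bootstrap", ablations=("struct_only",)))


class TestPatchVoteProtocol:
    def test_adnc_arm_at_least_matches_mci_arm(self):
        # AD/NC separation (0.8) strictly larger than MCIc/MCInc (0.3), with
        # per-subject severity jitter making MCI training labels noisy; the
        # direction is asserted on the mean over seeds (single runs are noisy
        # at n_test=10, like any small-sample patch-vote comparison).
        adnc, mci = [], []
        for seed in (0, 1, 2):
            cfg = ExperimentConfig(
                synthetic=SyntheticConfig(
                    n_per_group={"AD": 12, "NC": 12, "MCIc": 10, "MCInc": 10},
                    atrophy_effect={"AD": 0.8, "MCIc": 0.55, "MCInc": 0.25, "NC": 0.0},
                    noise_sd=2.0,
                    severity_jitter=0.25,
                    seed=seed,
                ),
                cnn=CnnConfig(epochs=4, batch_size=64, seed=seed),
                n_patches=15,
                seed=seed,
            )
            out = run_patch_vote_comparison(cfg)
            assert out["n_test"] == 10
            adnc.append(out["adnc_trained_accuracy"])
            mci.append(out["mci_trained_accuracy"])
        assert np.mean(adnc) >= np.mean(mci)
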