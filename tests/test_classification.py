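"""Feature-matrix assembly, ECOC decoding and evaluation reports."""

import numpy as np
import pandas as pd
import pytest
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from pulseflux import build_matrix, evaluate, report_from_confusion, train_ecoc_svm
from pulseflux.classification import CODING_MATRIX, EcocLinearSvm, FeatureMatrix


def cloud_matrix(rng, n_per_class=24, gap=10.0, spread=1.0, n_features=4):
    """Three well-separated Gaussian clouds with centres in general position.

    Non-collinear centres keep every one-vs-all binary problem linearly
    separable (with collinear centres the middle class is not separable
    from the union of its neighbours).
    """
    rows, labels = [], []
    for k, cls in enumerate(("healthy", "intermediate", "unhealthy")):
        centre = np.zeros(n_features)
        angle = 2.0 * np.pi * k / 3.0
        centre[0] = gap * np.cos(angle)
        centre[1] = gap * np.sin(angle)
        rows.append(rng.normal(0, spread, (n_per_class, n_features)) + centre)
        labels += [cls] * n_per_class
    X = pd.DataFrame(np.vstack(rows), columns=[f"f{i}" for i in range(n_features)])
    return FeatureMatrix(
        X=X, y=np.array(labels), bmf="intralipid", wavelength_nm=655, multimodal=False
    )


class TestBuildMatrix:
    def test_ppg_only_shape(self, ppg_table, ldf_table):
        m = build_matrix(ppg_table, ldf_table, "intralipid", 655, multimodal=False)
        assert m.X.shape == (72, 4)
        assert sorted(np.unique(m.y)) == ["healthy", "intermediate", "unhealthy"]

    def test_multimodal_appends_flux_column(self, ppg_table, ldf_table):
        m = build_matrix(ppg_table, ldf_table, "intralipid", 655, multimodal=True)
        assert m.X.shape == (72, 5)
        assert "dc_mean_flux" in m.X.columns

    def test_multimodal_without_ldf_table_rejected(self, ppg_table):
        with pytest.raises(ValueError, match="LDF"):
            build_matrix(ppg_table, None, "intralipid", 655, multimodal=True)


class TestEcocSvm:
    def test_separated_clouds_reach_perfect_training_accuracy(self, rng):
        # one-vs-all leaves the middle class linearly unseparable from the
        # union of its neighbours; loss-based decoding still resolves it
        # when the gap dominates the spread
        m = cloud_matrix(rng, gap=10.0, spread=0.5)
        model = train_ecoc_svm(m)
        assert np.mean(model.predict(m.X.to_numpy()) == m.y) == 1.0

    def test_predictions_match_bruteforce_codeword_decoder(self):
        """Six hand-placed points: ECOC equals enumerated hinge-loss decoding."""
        X = np.array(
            [[0.0, 0.0], [0.3, 1.0], [5.0, 0.2], [5.2, 0.9], [10.0, 0.1], [10.3, 1.1]]
        )
        y = np.array(
            ["healthy", "healthy", "intermediate", "intermediate", "unhealthy", "unhealthy"]
        )
        model = EcocLinearSvm(C=1.0).fit(X, y)

        # independent decoder: refit the binary separators and enumerate codewords
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        classes = ("healthy", "intermediate", "unhealthy")
        learners = []
        for k, cls in enumerate(classes):
            target = np.where(y == cls, 1.0, -1.0)
            learners.append(SVC(kernel="linear", C=1.0).fit(Xs, target))

        probe = np.vstack([X, [[2.5, 0.5], [7.6, 0.5], [-1.0, 0.0], [12.0, 1.0]]])
        probe_s = scaler.transform(probe)
        decisions = np.column_stack([m.decision_function(probe_s) for m in learners])
        expected = []
        for row in decisions:
            losses = [
                sum(max(0.0, 1.0 - CODING_MATRIX[k, l] * row[l]) for l in range(3))
                for k in range(3)
            ]
            expected.append(classes[int(np.argmin(losses))])
        np.testing.assert_array_equal(model.predict(probe), np.array(expected))

    def test_duplicating_training_rows_leaves_predictions_unchanged(self, rng):
        """Duplication rescales the per-sample loss weight; inside the data
        region the decoded class is unchanged."""
        m = cloud_matrix(rng, gap=12.0, spread=0.8)
        X, y = m.X.to_numpy(), m.y
        model_a = EcocLinearSvm().fit(X, y)
        model_b = EcocLinearSvm().fit(np.vstack([X, X]), np.concatenate([y, y]))
        # probe points drawn from the class clouds themselves
        probe = X + rng.normal(0, 0.4, X.shape)
        np.testing.assert_array_equal(model_a.predict(X), model_b.predict(X))
        np.testing.assert_array_equal(model_a.predict(probe), model_b.predict(probe))

    def test_row_permutation_does_not_change_predictions(self, rng):
        m = cloud_matrix(rng, gap=8.0)
        X, y = m.X.to_numpy(), m.y
        perm = rng.permutation(len(y))
        model_a = EcocLinearSvm().fit(X, y)
        model_b = EcocLinearSvm().fit(X[perm], y[perm])
        probe = rng.normal(8.0, 6.0, (40, X.shape[1]))
        np.testing.assert_array_equal(model_a.predict(probe), model_b.predict(probe))

    def test_missing_class_rejected(self, rng):
        m = cloud_matrix(rng)
        keep = m.y != "unhealthy"
        with pytest.raises(ValueError, match="class"):
            EcocLinearSvm().fit(m.X.to_numpy()[keep], m.y[keep])


class TestReports:
    def test_identity_confusion_gives_perfect_metrics(self):
        acc, prec, rec, f1 = report_from_confusion(np.eye(3) * 8)
        assert acc == 100.0
        assert all(v == 1.0 for v in prec.values())
        assert all(v == 1.0 for v in rec.values())
        assert all(v == 1.0 for v in f1.values())

    def test_hand_confusion_metrics(self):
        confusion = np.array([[6, 1, 0], [0, 7, 0], [0, 0, 8]])
        acc, prec, rec, f1 = report_from_confusion(confusion)
        assert rec["healthy"] == pytest.approx(6 / 7)
        assert prec["intermediate"] == pytest.approx(7 / 8)
        assert acc == pytest.approx(100.0 * 21 / 22)

    def test_report_is_internally_consistent(self, ppg_table, ldf_table):
        m = build_matrix(ppg_table, ldf_table, "lpfs", 530, multimodal=False)
        report = evaluate(m, split_seed=3)
        C = report.confusion
        assert report.holdout_accuracy == pytest.approx(100.0 * np.trace(C) / C.sum())
        assert C.sum() == 22  # 30% of 72, stratified
        recomputed = report_from_confusion(C)
        assert report.precision == recomputed[1]
        assert report.recall == recomputed[2]

    def test_too_few_rows_per_class_for_cv_rejected(self, rng):
        m = cloud_matrix(rng, n_per_class=4)
        with pytest.raises(ValueError, match="5"):
            evaluate(m, split_seed=0)


def test_multimodal_never_hurts_training_accuracy(ppg_table, ldf_table):
    """Appending the flux column keeps already-separated training data separated."""
    for bmf in ("intralipid", "lpfs"):
        for wl in (530, 655, 940):
            ppg_only = build_matrix(ppg_table, ldf_table, bmf, wl, multimodal=False)
            multi = build_matrix(ppg_table, ldf_table, bmf, wl, multimodal=True)
            acc_ppg = np.mean(
                train_ecoc_svm(ppg_only).predict(ppg_only.X.to_numpy()) == ppg_only.y
            )
            acc_multi = np.mean(
                train_ecoc_svm(multi).predict(multi.X.to_numpy()) == multi.y
            )
            assert acc_multi >= acc_ppg


def test_multimodal_rescues_degraded_ir_channel():
    """With a heavily degraded IR channel, adding flux does not lower holdout accuracy."""
    from pulseflux import GeneratorConfig, generate_records, ldf_feature_table, ppg_feature_table
    from pulseflux.pipeline import filter_records

    noise = {
        "intralipid": {530: 0.005, 655: 0.005, 940: 0.3},
        "lpfs": {530: 0.005, 655: 0.005, 940: 0.005},
    }
    wins = 0
    seeds = range(20, 35)
    for seed in seeds:
        cfg = GeneratorConfig(seed=seed, duration_s=120.0, ppg_noise_sd=noise)
        filtered = filter_records(generate_records(cfg))
        pt = ppg_feature_table([r for r in filtered if r.modality == "ppg"])
        lt = ldf_feature_table([r for r in filtered if r.modality == "ldf"])
        ppg_only = build_matrix(pt, lt, "intralipid", 940, multimodal=False)
        multi = build_matrix(pt, lt, "intralipid", 940, multimodal=True)
        a = evaluate(ppg_only, split_seed=seed).holdout_accuracy
        b = evaluate(multi, split_seed=seed).holdout_accuracy
        if b >= a:
            wins += 1
    assert wins >= 0.95 * len(list(seeds)) - 1
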