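"""Pseudo-batch derivation: detectors, cluster selection, harmonizers."""

import numpy as np
import pandas as pd
import pytest

from histoharm import (
    FeatureTable,
    apply_atypical,
    apply_by_patch,
    detect_atypical,
    find_optimal_k,
    harmonize_atypical,
    harmonize_by_patch,
    harmonize_by_patch_by_class,
    harmonize_multicenter,
    pca_project,
    select_detector,
)
from histoharm.harmonize import DETECTORS


def gaussian_table(n, p, seed, mean=0.0, scale=1.0, labels=None, center="unknown"):
    rng = np.random.default_rng(seed)
    x = rng.normal(mean, scale, size=(n, p))
    meta = pd.DataFrame({"sample_id": [f"s{center}{i}" for i in range(n)]})
    if labels is not None:
        meta["label"] = labels
    meta["center"] = center
    return FeatureTable(pd.DataFrame(x, columns=[f"f{j}" for j in range(p)]), meta)


@pytest.fixture(scope="module")
def planted_outlier_table():
    """500 inliers N(0, I_10) plus 25 points at distance 10 (seed 3)."""
    rng = np.random.default_rng(3)
    inliers = rng.normal(0, 1, size=(500, 10))
    direction = rng.normal(size=10)
    direction /= np.linalg.norm(direction)
    outliers = rng.normal(0, 1, size=(25, 10)) + 10 * direction
    x = np.vstack([inliers, outliers])
    truth = np.zeros(525, dtype=bool)
    truth[500:] = True
    t = FeatureTable(pd.DataFrame(x, columns=[f"f{j}" for j in range(10)]))
    return t, truth


class TestDetectAtypical:
    def test_planted_outliers_recovered(self, planted_outlier_table):
        table, truth = planted_outlier_table
        mask = detect_atypical(table, "isolation_forest",
                               contamination=0.05, seed=3)
        recovered = (mask.mask & truth).sum() / truth.sum()
        assert recovered >= 0.9

    def test_contamination_controls_fraction(self):
        t = gaussian_table(600, 8, seed=10)
        mask = detect_atypical(t, "isolation_forest", contamination=0.05, seed=0)
        assert mask.mask.mean() == pytest.approx(0.05, abs=0.02)

    @pytest.mark.parametrize("method", DETECTORS)
    def test_all_methods_return_full_length_mask(self, method,
                                                 planted_outlier_table):
        table, _ = planted_outlier_table
        mask = detect_atypical(table, method, contamination=0.05, seed=3)
        assert mask.mask.shape == (table.n_samples,)
        assert mask.mask.dtype == bool

    def test_frozen_detector_applies_to_new_rows(self, planted_outlier_table):
        table, _ = planted_outlier_table
        mask = detect_atypical(table, "isolation_forest",
                               contamination=0.05, seed=3)
        new = gaussian_table(50, 10, seed=99)
        out = mask.apply(new)
        assert out.shape == (50,)

    def test_bad_inputs_rejected(self):
        t = gaussian_table(5, 4, seed=0)
        with pytest.raises(ValueError):
            detect_atypical(t, "isolation_forest")
        t2 = gaussian_table(100, 4, seed=0)
        with pytest.raises(ValueError):
            detect_atypical(t2, "isolation_forest", contamination=0.7)


class TestSelectDetector:
    @pytest.fixture(scope="class")
    def label_noise_sim(self):
        """Separable two-class cloud plus a distant cluster whose labels
        are random (label noise): removing it helps the classifier."""
        rng = np.random.default_rng(5)
        n_half, p = 200, 6
        a = rng.normal(0, 1, size=(n_half, p))
        b = rng.normal(3, 1, size=(n_half, p))
        noise = rng.normal(0, 1, size=(30, p)) + 12.0
        x = np.vstack([a, b, noise])
        y = np.array(["neg"] * n_half + ["pos"] * n_half
                     + list(rng.choice(["neg", "pos"], size=30)))
        t = FeatureTable(pd.DataFrame(x, columns=[f"f{j}" for j in range(p)]),
                         pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(x))],
                                       "label": y}))
        return t, y

    def test_low_mse_on_separable_data(self, label_noise_sim):
        table, y = label_noise_sim
        report = select_detector(table, y, contamination=0.07, seed=5)
        assert report.mses[report.chosen] < 0.05

    def test_reproducible_given_seed(self, label_noise_sim):
        table, y = label_noise_sim
        r1 = select_detector(table, y, contamination=0.07, seed=5)
        r2 = select_detector(table, y, contamination=0.07, seed=5)
        assert r1.chosen == r2.chosen
        assert r1.mses == r2.mses

    def test_chosen_is_minimum_mse(self, label_noise_sim):
        table, y = label_noise_sim
        report = select_detector(table, y, contamination=0.07, seed=5)
        assert report.mses[report.chosen] == min(report.mses.values())

    def test_nonbinary_labels_rejected(self, label_noise_sim):
        table, _ = label_noise_sim
        with pytest.raises(ValueError):
            select_detector(table, np.array(["a"] * table.n_samples))


class TestHarmonizeAtypical:
    @pytest.fixture(scope="class")
    def shifted_cluster(self):
        rng = np.random.default_rng(9)
        cloud = rng.normal(0, 1, size=(400, 12))
        atypical = rng.normal(0, 1, size=(60, 12)) + 3.0
        x = np.vstack([cloud, atypical])
        mask = np.zeros(460, dtype=bool)
        mask[400:] = True
        t = FeatureTable(pd.DataFrame(x, columns=[f"f{j}" for j in range(12)]))
        return t, mask

    def test_group_gap_removed(self, shifted_cluster):
        table, mask = shifted_cluster
        out, model, _ = harmonize_atypical(table, mask)
        x = out.matrix
        pooled_sd = np.sqrt(model.var_pooled).mean()
        gap = np.abs(x[mask].mean(0) - x[~mask].mean(0)).mean()
        assert gap < 0.05 * pooled_sd * 3  # mean |per-feature gap|
        signed = (x[mask].mean(0) - x[~mask].mean(0)).mean()
        assert abs(signed) < 0.05 * pooled_sd

    def test_all_false_mask_is_identity(self, shifted_cluster):
        table, _ = shifted_cluster
        with pytest.warns(UserWarning):
            out, model, _ = harmonize_atypical(
                table, np.zeros(table.n_samples, dtype=bool)
            )
        np.testing.assert_array_equal(out.matrix, table.matrix)
        assert model is None

    def test_frozen_application_to_held_out(self, shifted_cluster):
        table, mask = shifted_cluster
        rng = np.random.default_rng(19)
        test_rows = np.sort(rng.choice(460, size=120, replace=False))
        train_rows = np.setdiff1d(np.arange(460), test_rows)
        train, test = table.take(train_rows), table.take(test_rows)
        detector = detect_atypical(train, "isolation_forest",
                                   contamination=0.15, seed=9)
        out_tr, model, _ = harmonize_atypical(train, detector)
        out_te = apply_atypical(model, detector, test)

        # the groups the frozen pipeline controls are the detector's
        # own masks on the held-out rows
        m_pred = detector.apply(test)

        def gap(t, m):
            x = t.matrix
            return np.abs(x[m].mean(0) - x[~m].mean(0)).mean()

        assert gap(out_te, m_pred) <= 0.2 * gap(test, m_pred)


class TestOptimalK:
    def blobs(self, centers, n_each, seed, p=8):
        rng = np.random.default_rng(seed)
        parts = [rng.normal(0, 1, size=(n_each, p)) + c for c in centers]
        x = np.vstack(parts)
        return FeatureTable(pd.DataFrame(x, columns=[f"f{j}" for j in range(p)]))

    def test_three_blobs_gives_k3(self):
        t = self.blobs([0.0, 10.0, 20.0], 60, seed=2)
        assert find_optimal_k(t, seed=2).k == 3

    def test_two_blobs_gives_k2(self):
        t = self.blobs([0.0, 10.0], 80, seed=2)
        assert find_optimal_k(t, seed=2).k == 2

    def test_single_blob_still_returns_argmax(self):
        t = self.blobs([0.0], 120, seed=2)
        cb = find_optimal_k(t, seed=2)
        assert cb.k >= 2
        assert cb.scores["silhouette"].max() < 0.5

    def test_score_table_covers_range(self):
        t = self.blobs([0.0, 8.0], 60, seed=4)
        cb = find_optimal_k(t, k_range=range(2, 6), seed=4)
        assert list(cb.scores["k"]) == [2, 3, 4, 5]

    def test_bad_k_range_rejected(self):
        t = self.blobs([0.0], 20, seed=0)
        with pytest.raises(ValueError):
            find_optimal_k(t, k_range=range(2, 25))


class TestHarmonizeByPatch:
    @pytest.fixture(scope="class")
    def two_blob_table(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, size=(150, 10))
        b = rng.normal(0, 1, size=(150, 10)) + 4.0
        x = np.vstack([a, b])
        labels = rng.choice(["benign", "malignant"], size=300)
        t = FeatureTable(
            pd.DataFrame(x, columns=[f"f{j}" for j in range(10)]),
            pd.DataFrame({"sample_id": [f"s{i}" for i in range(300)],
                          "label": labels}),
        )
        return t

    def test_blob_gap_removed(self, two_blob_table):
        out, model, cb = harmonize_by_patch(two_blob_table, seed=4)
        x = out.matrix
        g0, g1 = cb.labels == 0, cb.labels == 1
        pooled_sd = np.sqrt(model.var_pooled).mean()
        signed = (x[g1].mean(0) - x[g0].mean(0)).mean()
        assert abs(signed) < 0.05 * pooled_sd

    def test_rerun_is_near_identity(self, two_blob_table):
        # idempotence is measured against the same cluster batches: a
        # second ComBat fit on harmonized data finds almost no residual
        # additive effect
        from histoharm import combat_fit

        out, model, cb = harmonize_by_patch(two_blob_table, seed=4)
        model2 = combat_fit(out, cb.labels)
        assert (
            np.abs(model2.gamma_star_data).mean()
            < 0.1 * np.abs(model.gamma_star_data).mean()
        )

    def test_metadata_unchanged(self, two_blob_table):
        out, _, _ = harmonize_by_patch(two_blob_table, seed=4)
        pd.testing.assert_frame_equal(out.meta, two_blob_table.meta)

    def test_frozen_application_uses_nearest_centroid(self, two_blob_table):
        _, model, cb = harmonize_by_patch(two_blob_table, seed=4)
        rng = np.random.default_rng(8)
        new = FeatureTable(
            pd.DataFrame(rng.normal(0, 1, size=(40, 10)) + 4.0,
                         columns=[f"f{j}" for j in range(10)])
        )
        out = apply_by_patch(model, cb, new)
        assert out.n_samples == 40
        # rows from the shifted blob get pulled toward the pooled center
        assert abs(out.matrix.mean()) < abs(new.matrix.mean())


class TestHarmonizeByPatchByClass:
    @pytest.fixture(scope="class")
    def per_class_blobs(self):
        """Each class is a 2-blob mixture; class and blob orthogonal."""
        rng = np.random.default_rng(14)
        rows, labels = [], []
        for cls, class_shift in (("benign", 0.0), ("malignant", 1.0)):
            for blob_shift in (0.0, 5.0):
                block = rng.normal(0, 1, size=(80, 8)) + blob_shift
                block[:, :4] += class_shift
                rows.append(block)
                labels += [cls] * 80
        x = np.vstack(rows)
        order = rng.permutation(len(x))
        t = FeatureTable(
            pd.DataFrame(x[order], columns=[f"f{j}" for j in range(8)]),
            pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(x))],
                          "label": np.array(labels)[order]}),
        )
        return t

    def test_within_class_gap_removed_class_gap_kept(self, per_class_blobs):
        t = per_class_blobs
        out, models = harmonize_by_patch_by_class(t, seed=14)
        y = t.labels()
        for cls in ("benign", "malignant"):
            model, cb = models[cls]
            sub = out.matrix[y == cls]
            lab = cb.labels
            signed = (sub[lab == 1].mean(0) - sub[lab == 0].mean(0)).mean()
            assert abs(signed) < 0.05 * np.sqrt(model.var_pooled).mean()
        def class_gap(x):
            return (x[y == "malignant", :4].mean()
                    - x[y == "benign", :4].mean())
        assert class_gap(out.matrix) == pytest.approx(
            class_gap(t.matrix), rel=0.1
        )

    def test_row_order_preserved(self, per_class_blobs):
        out, _ = harmonize_by_patch_by_class(per_class_blobs, seed=14)
        pd.testing.assert_frame_equal(out.meta, per_class_blobs.meta)

    def test_single_class_reduces_to_by_patch(self):
        rng = np.random.default_rng(6)
        x = np.vstack([rng.normal(0, 1, size=(80, 6)),
                       rng.normal(4, 1, size=(80, 6))])
        t = FeatureTable(
            pd.DataFrame(x, columns=[f"f{j}" for j in range(6)]),
            pd.DataFrame({"sample_id": [f"s{i}" for i in range(160)],
                          "label": ["only"] * 160}),
        )
        by_class, _ = harmonize_by_patch_by_class(t, seed=6)
        by_patch, _, _ = harmonize_by_patch(t, seed=6)
        np.testing.assert_allclose(by_class.matrix, by_patch.matrix)


class TestMulticenter:
    def test_center_shift_and_scale_removed(self):
        a = gaussian_table(250, 10, seed=6, center="A")
        b = gaussian_table(250, 10, seed=60, mean=2.0, scale=1.5, center="B")
        out, model = harmonize_multicenter([a, b])
        x = out.matrix
        c = out.meta["center"].to_numpy()
        pooled_sd = np.sqrt(model.var_pooled).mean()
        signed = (x[c == "B"].mean(0) - x[c == "A"].mean(0)).mean()
        assert abs(signed) < 0.05 * pooled_sd
        var_ratio = x[c == "B"].var(0).mean() / x[c == "A"].var(0).mean()
        assert 0.9 <= var_ratio <= 1.1

    def test_identical_centers_near_identity(self):
        a = gaussian_table(200, 8, seed=7, center="A")
        b = gaussian_table(200, 8, seed=70, center="B")
        out, model = harmonize_multicenter([a, b])
        assert np.abs(out.matrix - FeatureTable.concat([a, b]).matrix).mean() < 0.2

    def test_three_centers_single_model(self):
        tables = [gaussian_table(100, 6, seed=s, center=f"C{s}")
                  for s in (1, 2, 3)]
        out, model = harmonize_multicenter(tables)
        assert len(model.batch_levels) == 3
        assert out.n_samples == 300

    def test_feature_mismatch_rejected(self):
        a = gaussian_table(50, 6, seed=1, center="A")
        b = gaussian_table(50, 7, seed=2, center="B")
        with pytest.raises(ValueError):
            harmonize_multicenter([a, b])


class TestPCA:
    def test_rank_one_explains_everything(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(100, 1))
        v = rng.normal(size=(1, 6))
        t = FeatureTable(pd.DataFrame(u @ v, columns=[f"f{j}" for j in range(6)]))
        proj = pca_project(t, n_components=2)
        assert proj.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_orthonormal_loadings(self):
        t = gaussian_table(80, 10, seed=11)
        proj = pca_project(t, n_components=3)
        np.testing.assert_allclose(
            proj.components @ proj.components.T, np.eye(3), atol=1e-10
        )

    def test_harmonization_shrinks_centroid_distance(self):
        rng = np.random.default_rng(9)
        cloud = rng.normal(0, 1, size=(300, 10))
        outl = rng.normal(0, 1, size=(40, 10)) + 3.0
        x = np.vstack([cloud, outl])
        mask = np.zeros(340, dtype=bool)
        mask[300:] = True
        t = FeatureTable(pd.DataFrame(x, columns=[f"f{j}" for j in range(10)]))
        harm, _, _ = harmonize_atypical(t, mask)

        def centroid_distance(table):
            coords = pca_project(table, 2).coordinates
            return np.linalg.norm(coords[mask].mean(0) - coords[~mask].mean(0))

        assert centroid_distance(harm) < 0.2 * centroid_distance(t)

    def test_too_many_components_rejected(self):
        t = gaussian_table(30, 4, seed=0)
        with pytest.raises(ValueError):
            pca_project(t, n_components=10)
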