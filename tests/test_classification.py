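"""Separability screening, SVM habitat mapping and map-quality metrics."""

import numpy as np
import pytest

import shallowsea as ss
from shallowsea.errors import ValidationError

# Printed confusion matrix of the reference benthic map (ground-truth percent;
# columns: stones, rock, sand, algae) with its "% of Total" row shares.
PUBLISHED_MATRIX = np.array([
    [93.56, 2.58, 0.09, 1.72],
    [5.76, 96.58, 0.00, 0.96],
    [0.69, 0.82, 92.31, 2.39],
    [0.00, 0.02, 7.60, 94.93],
])
PUBLISHED_ROW_TOTALS = np.array([19.03, 23.80, 50.88, 6.29])


def make_regions(labels, n_train=40, n_test=40, seed=0):
    """Disjoint train/test pixel sets drawn from a label raster."""
    rng = np.random.default_rng(seed)
    classes = [f"c{k}" for k in range(labels.max() + 1)]
    train, test = {}, {}
    for k, name in enumerate(classes):
        px = np.argwhere(labels == k)
        rng.shuffle(px)
        train[name] = px[:n_train]
        test[name] = px[n_train:n_train + n_test]
    return ss.LabeledRegions(classes=classes, train=train, test=test)


@pytest.fixture(scope="module")
def gaussian_scene():
    """Four well-separated Gaussian classes in a 3-feature stack."""
    rng = np.random.default_rng(5)
    ny = nx = 40
    labels = np.repeat(np.arange(4), ny * nx // 4).reshape(ny, nx)
    means = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [2, 2, 4]], float)
    feats = np.empty((3, ny, nx))
    for k in range(4):
        sel = labels == k
        feats[:, sel] = (means[k][:, None]
                         + rng.normal(0, 0.4, (3, int(sel.sum()))))
    return feats, labels


class TestJMSeparability:
    def test_identical_distributions_zero(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(0, 1, (2, 20, 20))
        labels = np.zeros((20, 20), int)
        labels[:, 10:] = 1   # same distribution on both halves
        jm = ss.jm_separability(feats, make_regions(labels, 30, 30))
        assert jm[0, 1] < 0.2

    def test_distant_means_saturate(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(0, 1, (2, 20, 20))
        labels = np.zeros((20, 20), int)
        labels[:, 10:] = 1
        feats[0, :, 10:] += 10.0   # 10 sigma separation
        jm = ss.jm_separability(feats, make_regions(labels, 30, 30))
        assert jm[0, 1] > 1.99

    def test_equal_covariance_closed_form(self):
        """Equal-covariance case: B = d^2/8 per unit variance, JM=2(1-e^-B)."""
        rng = np.random.default_rng(2)
        sigma, delta = 1.0, 3.0
        n = 4000
        a = rng.normal(0, sigma, (1, n))
        b = rng.normal(delta, sigma, (1, n))
        feats = np.concatenate([a, b], axis=1)[None]
        labels = np.concatenate([np.zeros(n, int), np.ones(n, int)])[None]
        regions = make_regions(labels.reshape(1, -1), n // 2, n // 4)
        jm = ss.jm_separability(feats.reshape(1, 1, -1), regions)
        expect = 2 * (1 - np.exp(-delta**2 / (8 * sigma**2)))
        assert jm[0, 1] == pytest.approx(expect, rel=0.1)

    def test_symmetry_and_monotone_in_separation(self, gaussian_scene):
        feats, labels = gaussian_scene
        jm = ss.jm_separability(feats, make_regions(labels))
        assert np.allclose(jm, jm.T)
        prev = None
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, (1, 2, 400))
        for delta in (0.5, 1.5, 3.0, 6.0):
            f = base.copy()
            f[0, 1, :] += delta
            labels2 = np.array([[0] * 400, [1] * 400])
            jm2 = ss.jm_separability(f.reshape(1, 2, 400),
                                     make_regions(labels2, 150, 100))
            if prev is not None:
                assert jm2[0, 1] >= prev - 1e-9
            prev = jm2[0, 1]


class TestSVM:
    def test_separable_scene_high_accuracy(self, gaussian_scene):
        feats, labels = gaussian_scene
        regions = make_regions(labels, 60, 60)
        jm = ss.jm_separability(feats, regions)
        assert jm[np.triu_indices_from(jm, 1)].min() > 1.9
        pred = ss.train_classify(feats, regions)
        report = ss.confusion_metrics(pred, regions)
        assert report.overall_accuracy > 95.0

    def test_duplicated_feature_column_stable(self, gaussian_scene):
        feats, labels = gaussian_scene
        regions = make_regions(labels, 60, 60)
        pred1 = ss.train_classify(feats, regions)
        feats_dup = np.concatenate([feats, feats[-1:]], axis=0)
        pred2 = ss.train_classify(feats_dup, regions)
        agree = (pred1 == pred2).mean()
        assert agree > 0.98

    def test_single_class_rejected(self, gaussian_scene):
        feats, labels = gaussian_scene
        px = np.argwhere(labels == 0)
        with pytest.raises(ValidationError):
            ss.train_classify(feats, ss.LabeledRegions(
                classes=["only"], train={"only": px[:20]}, test={"only": px[20:40]}))


class TestConfusionMetrics:
    def test_perfect_prediction(self, gaussian_scene):
        _, labels = gaussian_scene
        regions = make_regions(labels, 40, 40)
        report = ss.confusion_metrics(labels, regions)
        assert report.overall_accuracy == pytest.approx(100.0)
        assert report.kappa == pytest.approx(1.0)
        assert np.allclose(report.matrix_percent.sum(axis=0), 100.0, atol=0.1)

    def test_chance_prediction_kappa_near_zero(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 4, (60, 60))
        pred = rng.integers(0, 4, (60, 60))
        regions = make_regions(labels, 120, 120)
        report = ss.confusion_metrics(pred, regions)
        assert abs(report.kappa) < 0.08

    def test_po_pe_oracle(self):
        """kappa against a brute-force po/pe computation on random labels."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            labels = rng.integers(0, 3, (30, 30))
            pred = rng.integers(0, 3, (30, 30))
            regions = make_regions(labels, 40, 40, seed=int(rng.integers(1e6)))
            report = ss.confusion_metrics(pred, regions)
            pairs = [(pred[r, c], truth)
                     for truth, name in enumerate(regions.classes)
                     for r, c in regions.test[name]]
            p = np.array(pairs)
            n = len(p)
            po = np.mean(p[:, 0] == p[:, 1])
            pe = sum((np.mean(p[:, 0] == k)) * (np.mean(p[:, 1] == k))
                     for k in range(3))
            kappa = (po - pe) / (1 - pe)
            assert report.overall_accuracy == pytest.approx(100 * po, rel=1e-12)
            assert report.kappa == pytest.approx(kappa, rel=1e-12)
            assert report.kappa < po + 1e-12  # chance correction lowers score


class TestTruthReconstruction:
    def test_identity_matrix(self):
        r = np.array([10.0, 20.0, 30.0, 40.0])
        rec = ss.reconstruct_truth_proportions(100 * np.eye(4), r)
        assert np.allclose(rec.proportions_percent, r)
        assert rec.implied_oa == pytest.approx(100.0)

    def test_constructed_system_exact_recovery(self):
        rng = np.random.default_rng(9)
        M = 100 * np.eye(4) * 0.9
        M += rng.uniform(0, 5, (4, 4))
        M *= 100.0 / M.sum(axis=0)
        t = np.array([25.0, 15.0, 40.0, 20.0])
        r = M @ t / 100.0
        rec = ss.reconstruct_truth_proportions(M, r)
        assert np.allclose(rec.proportions_percent, t, atol=1e-10)
        assert rec.consistent
        assert rec.implied_oa == pytest.approx(np.diag(M) @ t / 100, abs=1e-10)

    def test_published_map_implies_over_90_percent(self):
        """The reference benthic map's printed matrix implies OA > 90%."""
        rec = ss.reconstruct_truth_proportions(PUBLISHED_MATRIX,
                                               PUBLISHED_ROW_TOTALS)
        assert rec.implied_oa > 90.0
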