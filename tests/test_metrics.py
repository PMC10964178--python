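"""FID, PHV and reader-study statistics."""

import numpy as np
import pytest
from scipy import linalg

from octstain.metrics import (ConfusionCounts, FeatureStats, PHVConfig,
                              TinyConvFeatures, fid, icc_absolute_agreement,
                              image_feature_stats, phv, pooled_feature_means,
                              reader_study_stats)

RNG = np.random.default_rng(11)


def _random_stats(rng, d=5):
    a = rng.standard_normal((d, d))
    return FeatureStats(mu=rng.standard_normal(d), sigma=a @ a.T + 0.1 * np.eye(d),
                        n=10)


# -- FID --------------------------------------------------------------------

def test_fid_identical_stats_is_zero():
    s = _random_stats(np.random.default_rng(0))
    assert fid(s, s) == pytest.approx(0.0, abs=1e-6)


def test_fid_scalar_closed_form():
    a = FeatureStats(mu=np.array([0.0]), sigma=np.array([[1.0]]), n=5)
    b = FeatureStats(mu=np.array([1.0]), sigma=np.array([[1.0]]), n=5)
    # 1-D Gaussians: (d mu)^2 + (sigma_a - sigma_b)^2
    assert fid(a, b) == pytest.approx(1.0, abs=1e-8)
    c = FeatureStats(mu=np.array([0.0]), sigma=np.array([[4.0]]), n=5)
    assert fid(a, c) == pytest.approx((2.0 - 1.0) ** 2, abs=1e-8)


def test_fid_matches_scipy_sqrtm_oracle():
    """Eigendecomposition route equals an independent matrix-square-root
    algorithm (Schur method via scipy) on random 5-D Gaussian stats."""
    for trial in range(20):
        rng = np.random.default_rng(trial)
        a, b = _random_stats(rng), _random_stats(rng)
        covmean = linalg.sqrtm(a.sigma @ b.sigma)
        if np.iscomplexobj(covmean):
            covmean = covmean.real
        want = (np.sum((a.mu - b.mu) ** 2) + np.trace(a.sigma) + np.trace(b.sigma)
                - 2.0 * np.trace(covmean))
        assert fid(a, b) == pytest.approx(want, abs=1e-4)


def test_fid_is_symmetric_and_nonnegative():
    for trial in range(5):
        rng = np.random.default_rng(100 + trial)
        a, b = _random_stats(rng), _random_stats(rng)
        assert fid(a, b) == pytest.approx(fid(b, a), rel=1e-6)
        assert fid(a, b) >= 0.0


def test_fid_rejects_dimension_mismatch():
    a = _random_stats(np.random.default_rng(0), d=4)
    b = _random_stats(np.random.default_rng(1), d=5)
    with pytest.raises(ValueError):
        fid(a, b)


def test_feature_stats_symmetrizes_and_validates():
    with pytest.raises(ValueError):
        FeatureStats(mu=np.zeros(2), sigma=np.eye(2), n=1)
    s = FeatureStats(mu=np.zeros(2), sigma=np.array([[1.0, 0.3], [0.1, 1.0]]), n=3)
    assert np.allclose(s.sigma, s.sigma.T)


def test_image_feature_stats_pipeline():
    imgs = RNG.random((6, 16, 16, 3)).astype(np.float32)
    s = image_feature_stats(imgs, level=1)
    assert s.n == 6
    assert s.mu.shape == (8,)          # level-1 channels of the tiny backbone


# -- PHV --------------------------------------------------------------------

class _StubExtractor:
    """Feature maps whose channel means are fully controlled by the test."""

    def __init__(self, channel_values):
        self.vals = np.asarray(channel_values, dtype=np.float32)

    def __call__(self, images, level):
        b = len(images)
        c = len(self.vals)
        return np.tile(self.vals.reshape(1, c, 1, 1), (b, 1, 2, 2))


def test_phv_identical_sets_scores_100():
    imgs = RNG.random((4, 16, 16, 3)).astype(np.float32)
    assert phv(imgs, imgs, PHVConfig(level=2, threshold=0.02)) == 100.0


def test_phv_counts_agreeing_channels():
    base = np.linspace(0.1, 1.0, 10)
    shifted = base.copy()
    shifted[:3] += 0.5                  # 3 of 10 channels differ by 0.5 > T
    cfg = PHVConfig(level=1, threshold=0.02)
    gen = np.zeros((2, 4, 4, 3), np.float32)
    real = np.zeros((3, 4, 4, 3), np.float32)
    cfg_gen = PHVConfig(level=1, threshold=0.02, extractor=_StubExtractor(base))
    mean_a = pooled_feature_means(gen, _StubExtractor(base), 1)
    mean_b = pooled_feature_means(real, _StubExtractor(shifted), 1)
    agree = np.abs(mean_a - mean_b) <= 0.02
    assert agree.sum() == 7
    # and through the public phv() with a paired stub
    class Pair:
        def __init__(self):
            self.first = True
        def __call__(self, images, level):
            vals = base if self.first else shifted
            self.first = False
            return _StubExtractor(vals)(images, level)
    assert phv(gen, real, PHVConfig(level=1, threshold=0.02,
                                    extractor=Pair())) == pytest.approx(70.0)


def test_phv_monotone_under_growing_offset():
    imgs = RNG.random((3, 16, 16, 3)).astype(np.float32)
    cfg = PHVConfig(level=1, threshold=0.02)
    prev = 101.0
    for off in (0.0, 0.01, 0.05, 0.2, 0.8):
        val = phv(imgs, np.clip(imgs + off, 0, 1), cfg)
        assert val <= prev + 1e-9
        prev = val


def test_phv_matches_literal_channel_loop():
    gen = RNG.random((3, 16, 16, 3)).astype(np.float32)
    real = RNG.random((4, 16, 16, 3)).astype(np.float32)
    ext = TinyConvFeatures()
    got = phv(gen, real, PHVConfig(level=2, threshold=0.02, extractor=ext))
    fg, fr = ext(gen, 2), ext(real, 2)
    agree = 0
    n_ch = fg.shape[1]
    for c in range(n_ch):
        a = np.mean([fg[i, c].mean() for i in range(len(gen))])
        b = np.mean([fr[i, c].mean() for i in range(len(real))])
        if abs(a - b) <= 0.02:
            agree += 1
    assert got == pytest.approx(100.0 * agree / n_ch, abs=1e-9)


def test_phv_validates_inputs():
    imgs = RNG.random((2, 8, 8, 3)).astype(np.float32)
    with pytest.raises(ValueError):
        phv(imgs[:0], imgs)
    with pytest.raises(ValueError):
        PHVConfig(level=5)
    with pytest.raises(ValueError):
        PHVConfig(threshold=0.0)


def test_tiny_backbone_is_deterministic():
    imgs = RNG.random((2, 16, 16, 3)).astype(np.float32)
    assert np.array_equal(TinyConvFeatures(seed=0)(imgs, 3),
                          TinyConvFeatures(seed=0)(imgs, 3))


# -- reader study -----------------------------------------------------------

# §-counts as printed: 60 images (30 real / 30 virtual) per reader;
# reader A called 42 "real" (19 of them virtual), reader B called 33 (15).
READER_A = ConfusionCounts(n_real_called_real=23, n_real_called_virtual=7,
                           n_virtual_called_real=19, n_virtual_called_virtual=11)
READER_B = ConfusionCounts(n_real_called_real=18, n_real_called_virtual=12,
                           n_virtual_called_real=15, n_virtual_called_virtual=15)


def test_reader_study_reproduces_published_averages():
    report = reader_study_stats([READER_A, READER_B])
    avg = report["average"]
    assert round(avg["sensitivity"], 2) == 0.68
    assert round(avg["specificity"], 2) == 0.43
    assert report["per_reader"][1]["accuracy"] == pytest.approx(0.55)
    assert report["per_reader"][0]["accuracy"] == pytest.approx(34 / 60)
    assert report["per_reader"][0]["accuracy"] == pytest.approx(0.56, abs=0.01)
    # published precision values (0.54 per reader) to the printed precision
    assert report["per_reader"][0]["precision"] == pytest.approx(0.54, abs=0.01)
    assert report["per_reader"][1]["precision"] == pytest.approx(0.54, abs=0.01)


def test_perfect_reader_scores_one_everywhere():
    perfect = ConfusionCounts(30, 0, 0, 30)
    r = reader_study_stats([perfect])["per_reader"][0]
    assert all(v == pytest.approx(1.0) for v in r.values())


def test_zero_denominator_reports_undefined():
    # a reader who never calls "real": precision undefined, not 0
    c = ConfusionCounts(0, 30, 0, 30)
    r = reader_study_stats([c])["per_reader"][0]
    assert r["precision"] is None
    assert r["sensitivity"] == 0.0


def test_icc_perfect_agreement_is_one():
    rows = []
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 2, 20)
    for i in range(20):
        for reader in ("A", "B"):
            rows.append({"image_id": i, "reader": reader,
                         "called_label": int(calls[i])})
    assert icc_absolute_agreement(rows) == pytest.approx(1.0, abs=1e-6)


def test_reader_study_includes_icc_when_ratings_given():
    rows = [{"image_id": i, "reader": r, "called_label": (i + len(r)) % 2}
            for i in range(10) for r in ("A", "B")]
    report = reader_study_stats([READER_A, READER_B], ratings=rows)
    assert "icc" in report and np.isfinite(report["icc"])


def test_counts_must_be_nonnegative():
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 0, 0)
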