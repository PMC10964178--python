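"""Reference-free image-set similarity metrics and reader-study statistics.

* **FID** — the Fréchet distance between Gaussian fits to deep-feature
  distributions of two image sets:
  ``|mu_A - mu_B|^2 + Tr(S_A + S_B - 2 (S_A S_B)^{1/2})``.
  The matrix square root is taken via symmetric eigendecomposition with
  small negative eigenvalues (numerical noise) clipped to zero.
* **PHV** — perceptual hash value: the percentage of pooled deep-feature
  channels whose set-mean activations agree between the two sets within a
  threshold ``T`` (default 0.02).  Higher = more similar.
* **Reader study** — accuracy/precision/sensitivity/specificity per reader
  from 2x2 real-vs-virtual confusion counts ("real" is the positive
  class), plus the two-way random-effects absolute-agreement single-rater
  ICC when per-image ratings are available.

The default feature extractor is a seeded fixed-weight convolutional
backbone with three stride-2 stages, so metric values are deterministic
and need no downloaded weights; any callable with the same signature
(e.g. a large pretrained residual network) can be plugged in instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .nn import Tensor, conv2d
from .nn.layers import _kaiming, Parameter

__all__ = [
    "FeatureStats", "PHVConfig", "ConfusionCounts", "TinyConvFeatures",
    "fid", "phv", "pooled_feature_means", "image_feature_stats",
    "reader_study_stats", "icc_absolute_agreement",
]

logger = logging.getLogger(__name__)


# -- feature extraction -----------------------------------------------------

class TinyConvFeatures:
    """Deterministic three-stage conv feature backbone (seeded fixed weights).

    ``__call__(images, level)`` maps a stack of images ((B, H, W) gray or
    (B, H, W, 3) RGB) to a (B, C, h, w) feature grid from stage ``level``
    (1, 2 or 3); grayscale inputs are replicated to three channels so both
    domains share one feature space.
    """

    CHANNELS = (8, 16, 32)

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = (3,) + self.CHANNELS
        self.weights = [Parameter(_kaiming(rng, chans[i] * 9,
                                           (chans[i + 1], chans[i], 3, 3)))
                        for i in range(3)]

    def __call__(self, images: np.ndarray, level: int) -> np.ndarray:
        if level not in (1, 2, 3):
            raise ValueError("level must be 1, 2 or 3")
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = np.repeat(arr[..., None], 3, axis=-1)
        x = Tensor(arr.transpose(0, 3, 1, 2))
        for i in range(level):
            x = conv2d(x, self.weights[i], None, stride=2, padding=1).relu()
        return x.data


def _extract(images, extractor, level: int) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float32)
    if arr.shape[0] == 0:
        raise ValueError("image set is empty")
    feats = extractor(arr, level)
    if feats.ndim != 4:
        raise ValueError("extractor must return (B, C, h, w) feature maps")
    return feats


def pooled_feature_means(images, extractor=None, level: int = 2) -> np.ndarray:
    """Per-channel global-average-pooled features, averaged over the set."""
    extractor = extractor or TinyConvFeatures()
    feats = _extract(images, extractor, level)
    return feats.mean(axis=(0, 2, 3))                      # (C,)


# -- FID --------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureStats:
    """Gaussian summary (mean vector, covariance, sample count) of features."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=np.float64)
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=np.float64))
        object.__setattr__(self, "sigma", 0.5 * (sigma + sigma.T))
        if self.n < 2:
            raise ValueError("FeatureStats needs at least 2 samples")

    @classmethod
    def from_features(cls, x: np.ndarray) -> "FeatureStats":
        x = np.asarray(x, dtype=np.float64)
        return cls(mu=x.mean(axis=0), sigma=np.cov(x, rowvar=False), n=x.shape[0])


def image_feature_stats(images, extractor=None, level: int = 2) -> FeatureStats:
    """Gaussian feature statistics of an image set (pooled per image)."""
    extractor = extractor or TinyConvFeatures()
    feats = _extract(images, extractor, level)
    return FeatureStats.from_features(feats.mean(axis=(2, 3)))


_NEG_EIG_TOL = -1e-6


def _sqrtm_psd(mat: np.ndarray) -> np.ndarray:
    """Square root of a symmetric PSD matrix via eigendecomposition."""
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    if vals.min() < _NEG_EIG_TOL * max(1.0, abs(vals).max()):
        logger.warning("covariance has a substantially negative eigenvalue "
                       "(%g); clipping", vals.min())
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(stats_a: FeatureStats, stats_b: FeatureStats) -> float:
    """Fréchet distance between two Gaussian feature summaries."""
    if stats_a.mu.shape != stats_b.mu.shape:
        raise ValueError("feature dimensions do not match")
    sa, sb = stats_a.sigma.copy(), stats_b.sigma.copy()
    for s in (sa, sb):
        if np.linalg.matrix_rank(s) < s.shape[0]:
            logger.info("singular covariance; applying diagonal loading 1e-10")
            s += 1e-10 * np.eye(s.shape[0])
    diff = stats_a.mu - stats_b.mu
    root_a = _sqrtm_psd(sa)
    inner = root_a @ sb @ root_a                           # symmetric PSD
    vals = np.clip(np.linalg.eigvalsh(0.5 * (inner + inner.T)), 0.0, None)
    tr_covmean = np.sqrt(vals).sum()
    val = float(diff @ diff + np.trace(sa) + np.trace(sb) - 2.0 * tr_covmean)
    return max(val, 0.0)


# -- PHV --------------------------------------------------------------------

@dataclass
class PHVConfig:
    """Which extractor stage to use and the channel-agreement threshold."""

    level: int = 2
    threshold: float = 0.02
    extractor: Callable | None = None

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise ValueError("level must be 1, 2 or 3")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def phv(set_gen, set_real, config: PHVConfig | None = None) -> float:
    """Percentage of feature channels agreeing within the threshold.

    Each image is average-pooled per channel, the pooled activations are
    averaged over each set, and a channel counts as agreeing when the
    absolute difference of the two set means is at most ``T``.
    """
    config = config or PHVConfig()
    extractor = config.extractor or TinyConvFeatures()
    mean_gen = pooled_feature_means(set_gen, extractor, config.level)
    mean_real = pooled_feature_means(set_real, extractor, config.level)
    agree = np.abs(mean_gen - mean_real) <= config.threshold
    return float(100.0 * agree.mean())


# -- reader study -----------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 table of one reader's real-vs-virtual calls."""

    n_real_called_real: int
    n_real_called_virtual: int
    n_virtual_called_real: int
    n_virtual_called_virtual: int

    def __post_init__(self) -> None:
        if min(self.n_real_called_real, self.n_real_called_virtual,
               self.n_virtual_called_real, self.n_virtual_called_virtual) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return (self.n_real_called_real + self.n_real_called_virtual
                + self.n_virtual_called_real + self.n_virtual_called_virtual)


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def _reader_stats(c: ConfusionCounts) -> dict[str, float | None]:
    tp, fn = c.n_real_called_real, c.n_real_called_virtual
    fp, tn = c.n_virtual_called_real, c.n_virtual_called_virtual
    return {
        "accuracy": _safe_div(tp + tn, c.total),
        "precision": _safe_div(tp, tp + fp),
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
    }


def icc_absolute_agreement(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a dataframe-like with columns ``image_id``, ``reader``
    and ``called_label`` (0/1 calls per image per reader).
    """
    import pandas as pd
    import pingouin as pg

    df = pd.DataFrame(ratings)
    res = pg.intraclass_corr(data=df, targets="image_id", raters="reader",
                             ratings="called_label")
    # absolute agreement, single rater: labelled ICC2 (Shrout-Fleiss) or
    # ICC(A,1) (McGraw-Wong) depending on the pingouin version
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    return float(res.loc[sel, "ICC"].iloc[0])


def reader_study_stats(counts_per_reader: Sequence[ConfusionCounts],
                       ratings=None) -> dict:
    """Visual-Turing-test report: per-reader statistics plus averages.

    "Real" is the positive class.  A statistic with a zero denominator is
    reported as ``None`` (undefined), never as 0.  Averages are unweighted
    means over the readers for which the statistic is defined.  When
    per-image ``ratings`` are supplied, the inter-reader ICC is included.
    """
    if not counts_per_reader:
        raise ValueError("need at least one reader")
    per_reader = [_reader_stats(c) for c in counts_per_reader]
    average: dict[str, float | None] = {}
    for key in ("accuracy", "precision", "sensitivity", "specificity"):
        vals = [r[key] for r in per_reader if r[key] is not None]
        average[key] = float(np.mean(vals)) if vals else None
    report = {"per_reader": per_reader, "average": average}
    if ratings is not None:
        report["icc"] = icc_absolute_agreement(ratings)
    return report
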