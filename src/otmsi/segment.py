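"""Univariate segmentation of deconvolved ion images.

Two segmenters are provided, both sklearn-style estimators over a single ion
image:

* :class:`KMeansSegmenter` — spatially naive 1-D K-means intensity
  thresholding; each pixel is treated as a scalar observation.
* :class:`SpatialGMMSegmenter` — a spatially aware univariate Gaussian
  mixture in the spirit of Cardinal's spatialDGMM: each pixel carries its own
  mixing weights, which are re-estimated every iteration from a
  Gaussian-kernel-weighted average of the posteriors over the pixel's
  Chebyshev neighborhood, with the smoothing strength ``beta`` interpolating
  between a plain GMM (beta = 0) and full neighborhood consensus.

Segments are always relabeled so that the component with the larger fitted
mean is "high"; accuracy against a binary ground-truth mask is therefore
well-defined (a perfectly inverted segmentation scores 0, not 100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .deconv import IonImage

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "KMeansSegmenter",
    "SpatialGMMSegmenter",
    "kmeans_threshold_segment",
    "spatial_dgmm_segment",
    "segmentation_accuracy",
    "label_change_fraction",
]


@dataclass(frozen=True)
class SegmentationConfig:
    k: int = 2
    r: int = 3
    beta: float = 6.0
    max_iter: int = 200
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.r < 0 or self.beta < 0:
            raise ValueError("r and beta must be nonnegative")


@dataclass
class SegmentationResult:
    """Hard labels (1..k, ascending by segment mean), posteriors and moments."""

    labels: np.ndarray  # (height, width) ints in 1..k; k = "high"
    posteriors: np.ndarray  # (height, width, k)
    means: np.ndarray
    variances: np.ndarray
    converged: bool = True
    n_iter: int = 0
    mask: np.ndarray | None = None

    @property
    def high_mask(self) -> np.ndarray:
        """Pixels assigned to the highest-mean segment."""
        return self.labels == len(self.means)


def _as_image(img) -> IonImage:
    if isinstance(img, IonImage):
        return img
    return IonImage(np.asarray(img, dtype=float))


class KMeansSegmenter(ClusterMixin, BaseEstimator):
    """Spatially naive 1-D K-means intensity thresholding of an ion image."""

    def __init__(self, k: int = 2, random_state: int | None = None, n_init: int = 10):
        self.k = k
        self.random_state = random_state
        self.n_init = n_init

    def fit(self, X, y=None) -> "KMeansSegmenter":
        img = _as_image(X)
        values = img.flat_valid
        if np.unique(values).size < self.k:
            raise ValueError("image has fewer distinct intensities than segments")
        km = KMeans(
            n_clusters=self.k, n_init=self.n_init, random_state=self.random_state
        ).fit(values.reshape(-1, 1))
        order = np.argsort(km.cluster_centers_.ravel())
        relabel = np.empty(self.k, dtype=int)
        relabel[order] = np.arange(1, self.k + 1)

        labels = np.zeros(img.values.shape, dtype=int)
        labels[img.mask] = relabel[km.labels_]
        posteriors = np.zeros(img.values.shape + (self.k,))
        for j in range(self.k):
            posteriors[..., j] = labels == j + 1
        self.means_ = km.cluster_centers_.ravel()[order]
        self.variances_ = np.array(
            [values[relabel[km.labels_] == j + 1].var() for j in range(self.k)]
        )
        self.labels_ = labels
        self.result_ = SegmentationResult(
            labels, posteriors, self.means_, self.variances_, True, km.n_iter_, img.mask
        )
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


class SpatialGMMSegmenter(ClusterMixin, BaseEstimator):
    """Spatially aware univariate Gaussian mixture segmentation.

    Parameters
    ----------
    k : number of segments.
    r : Chebyshev neighborhood radius in pixels; the smoothing kernel is a
        Gaussian with sigma = r/2 on the (2r+1)^2 square window, renormalized
        at image borders.
    beta : spatial smoothing strength; the per-pixel mixing weights are the
        smoothed posteriors raised to beta/(beta+1) and renormalized, so
        beta = 0 recovers a plain (flat-prior) GMM and beta -> inf uses the
        neighborhood consensus directly.
    tol : relative log-likelihood change declaring convergence.
    """

    def __init__(
        self,
        k: int = 2,
        r: int = 3,
        beta: float = 6.0,
        max_iter: int = 200,
        tol: float = 1e-6,
        random_state: int | None = None,
        kmeans_restarts: int = 5,
    ):
        self.k = k
        self.r = r
        self.beta = beta
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.kmeans_restarts = kmeans_restarts

    def _kernel(self) -> np.ndarray:
        if self.r == 0:
            return np.ones((1, 1))
        ax = np.arange(-self.r, self.r + 1)
        sigma = self.r / 2.0
        g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
        return g

    def _smooth(self, post: np.ndarray, mask: np.ndarray, kernel: np.ndarray):
        """Kernel-weighted average of posteriors over valid neighbors."""
        weight = ndimage.convolve(mask.astype(float), kernel, mode="constant")
        smoothed = np.empty_like(post)
        for j in range(post.shape[-1]):
            num = ndimage.convolve(post[..., j] * mask, kernel, mode="constant")
            smoothed[..., j] = np.divide(
                num, weight, out=np.zeros_like(num), where=weight > 0
            )
        # renormalize across components (guards border rounding)
        total = smoothed.sum(axis=-1, keepdims=True)
        np.divide(smoothed, total, out=smoothed, where=total > 0)
        return smoothed

    def fit(self, X, y=None) -> "SpatialGMMSegmenter":
        img = _as_image(X)
        mask = img.mask
        x = img.values
        values = x[mask]
        if np.unique(values).size < self.k:
            raise ValueError("image has fewer distinct intensities than segments")
        km = KMeans(
            n_clusters=self.k,
            n_init=self.kmeans_restarts,
            random_state=self.random_state,
        ).fit(values.reshape(-1, 1))
        order = np.argsort(km.cluster_centers_.ravel())
        means = km.cluster_centers_.ravel()[order]
        variances = np.array(
            [
                max(values[km.labels_ == c].var(), 1e-12 * max(values.var(), 1e-300))
                for c in order
            ]
        )
        var_floor = 1e-12 * max(values.var(), 1e-300)
        self.variance_floored_ = False

        kernel = self._kernel()
        exponent = self.beta / (self.beta + 1.0)
        weights = np.full(x.shape + (self.k,), 1.0 / self.k)
        loglik_prev = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # E-step: posteriors from current means/variances and pixel weights
            log_dens = -0.5 * (
                np.log(2 * np.pi * variances)
                + (x[..., None] - means) ** 2 / variances
            )
            log_num = np.log(np.maximum(weights, 1e-300)) + log_dens
            log_norm = np.logaddexp.reduce(log_num, axis=-1)
            post = np.exp(log_num - log_norm[..., None])

            loglik = float(log_norm[mask].sum())

            # spatial step: neighborhood consensus and tempered mixing weights
            smoothed = self._smooth(post, mask, kernel)
            if exponent > 0:
                w = np.maximum(smoothed, 1e-300) ** exponent
            else:
                w = np.ones_like(smoothed)
            w /= w.sum(axis=-1, keepdims=True)
            weights = w

            # M-step from the smoothed posteriors
            resp = smoothed[mask]
            totals = resp.sum(axis=0)
            totals = np.maximum(totals, 1e-300)
            means = (resp * values[:, None]).sum(axis=0) / totals
            variances = (resp * (values[:, None] - means) ** 2).sum(axis=0) / totals
            if np.any(variances < var_floor):
                self.variance_floored_ = True
                variances = np.maximum(variances, var_floor)

            if np.isfinite(loglik_prev) and abs(loglik - loglik_prev) <= self.tol * abs(
                loglik_prev
            ):
                converged = True
                break
            loglik_prev = loglik

        # final posteriors under the converged parameters, relabeled by mean
        order = np.argsort(means)
        means, variances = means[order], variances[order]
        weights = weights[..., order]
        log_dens = -0.5 * (
            np.log(2 * np.pi * variances) + (x[..., None] - means) ** 2 / variances
        )
        log_num = np.log(np.maximum(weights, 1e-300)) + log_dens
        post = np.exp(log_num - np.logaddexp.reduce(log_num, axis=-1)[..., None])

        labels = np.zeros(x.shape, dtype=int)
        labels[mask] = np.argmax(post[mask], axis=-1) + 1
        self.means_ = means
        self.variances_ = variances
        self.labels_ = labels
        self.posteriors_ = post
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.loglik_ = loglik
        self.result_ = SegmentationResult(
            labels, post, means, variances, converged, n_iter, mask
        )
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def kmeans_threshold_segment(
    img: IonImage, k: int = 2, seed: int | None = None
) -> SegmentationResult:
    """1-D K-means segmentation; segment k ("high") has the highest mean."""
    return KMeansSegmenter(k=k, random_state=seed).fit(img).result_


def spatial_dgmm_segment(
    img: IonImage, cfg: SegmentationConfig, seed: int | None = None
) -> SegmentationResult:
    """Spatially aware Gaussian-mixture segmentation of one ion image."""
    return (
        SpatialGMMSegmenter(
            k=cfg.k,
            r=cfg.r,
            beta=cfg.beta,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            random_state=seed,
        )
        .fit(img)
        .result_
    )


def segmentation_accuracy(result: SegmentationResult, truth_mask: np.ndarray) -> float:
    """Percent of pixels whose high/low label matches the binary truth mask."""
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if truth_mask.shape != result.labels.shape:
        raise ValueError("truth mask shape does not match the segmentation grid")
    return float(100.0 * np.mean(result.high_mask == truth_mask))


def label_change_fraction(a: SegmentationResult, b: SegmentationResult) -> float:
    """Percent of pixels whose high/low assignment differs between results."""
    if a.labels.shape != b.labels.shape:
        raise ValueError("segmentations are on different grids")
    return float(100.0 * np.mean(a.high_mask != b.high_mask))
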