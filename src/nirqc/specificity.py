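"""PCA identification library for specificity screening.

A principal-component model is fitted to the preprocessed spectra of genuine
capsule-blend samples.  A test spectrum is accepted only if it is close to the
calibration cloud both *within* the model plane (Mahalanobis distance of its
scores against the training score covariance, Hotelling-T²-style) and
*orthogonally* to it (norm of the residual outside the retained components,
Q-statistic-style).  Placebo, degraded (DHA-spiked) and pure-API blends fall
far from the cloud in one or both statistics and are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PCAModel", "fit_pca", "score_distance", "classify"]


@dataclass
class PCAModel:
    n_components: int
    loadings: np.ndarray  # (p, k), orthonormal columns
    eigenvalues: np.ndarray  # score variances, all components
    explained_variance: np.ndarray  # percent, all components
    mean: np.ndarray  # training feature mean
    score_mean: np.ndarray  # (k,)
    score_cov: np.ndarray  # (k, k), regularized if near-singular
    d_max: float  # score (Mahalanobis) distance threshold
    q_max: float  # orthogonal residual norm threshold

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained_variance)


def _project(model: PCAModel, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Fc = np.atleast_2d(F) - model.mean
    scores = Fc @ model.loadings
    residual = Fc - scores @ model.loadings.T
    return scores, np.linalg.norm(residual, axis=1)


def fit_pca(
    F: np.ndarray,
    n_components: int = 5,
    score_quantile: float = 0.999,
    residual_sds: float = 5.0,
) -> PCAModel:
    """Centered PCA by singular-value decomposition with acceptance thresholds.

    The default of five components retains the systematic variation of a
    two-API calibration set — two composition directions plus the three
    instrumental directions (scatter gain, baseline offset, baseline slope)
    that survive preprocessing in the raw spectral block — so the Q-style
    residual responds to out-of-model chemistry (e.g. a degradant) rather
    than to routine instrumental drift.  The first two components still carry
    essentially all variance and reproduce the familiar PC1/PC2 scores-plot
    separation of challenge blends.

    Sign convention: each loading vector is flipped so its largest-magnitude
    element is positive, making scores reproducible.  The score-distance
    threshold is the ``score_quantile`` point of a chi-square with
    ``n_components`` degrees of freedom (on the squared Mahalanobis distance);
    the residual threshold is mean + ``residual_sds``·SD of the training
    residual norms.
    """
    F = np.asarray(F, float)
    n, p = F.shape
    if n_components >= n:
        raise ValueError("n_components must be < number of samples")
    mean = F.mean(axis=0)
    Fc = F - mean
    U, s, Vt = np.linalg.svd(Fc, full_matrices=False)
    # deterministic sign: largest |element| of each loading positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
    eigenvalues = s**2 / (n - 1)
    explained = 100.0 * eigenvalues / eigenvalues.sum()
    loadings = Vt[:n_components].T
    scores = Fc @ loadings
    score_mean = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False).reshape(n_components, n_components)
    tr = np.trace(cov)
    if np.linalg.cond(cov) > 1e12 or tr == 0:
        cov = cov + 1e-10 * max(tr, 1e-30) * np.eye(n_components)
    residual = Fc - scores @ loadings.T
    rnorm = np.linalg.norm(residual, axis=1)
    model = PCAModel(
        n_components=n_components,
        loadings=loadings,
        eigenvalues=eigenvalues,
        explained_variance=explained,
        mean=mean,
        score_mean=score_mean,
        score_cov=cov,
        d_max=float(np.sqrt(stats.chi2.ppf(score_quantile, df=n_components))),
        q_max=float(rnorm.mean() + residual_sds * rnorm.std(ddof=1)),
    )
    return model


def score_distance(model: PCAModel, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (Mahalanobis score distance, orthogonal residual norm)."""
    scores, rnorm = _project(model, F)
    dev = scores - model.score_mean
    d2 = np.einsum("ij,ij->i", dev @ np.linalg.inv(model.score_cov), dev)
    return np.sqrt(np.maximum(d2, 0.0)), rnorm


def classify(
    model: PCAModel,
    F: np.ndarray,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Accept/reject verdict per sample: accept iff the score distance is
    within ``d_max`` and the residual norm within ``q_max``."""
    F = np.atleast_2d(np.asarray(F, float))
    if F.size == 0:
        return pd.DataFrame(columns=["label", "distance", "residual", "verdict"])
    d, q = score_distance(model, F)
    accept = (d <= model.d_max) & (q <= model.q_max)
    return pd.DataFrame(
        {
            "label": labels if labels is not None else [""] * len(d),
            "distance": d,
            "residual": q,
            "verdict": np.where(accept, "accept", "reject"),
        }
    )
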