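"""Stage 2 — Gaussian discriminant classifiers and the hybrid posterior.

Two Gaussian discriminant models are fitted on disjoint halves of the seed
samples: a linear one (LDA, pooled within-class covariance) and a quadratic
one (QDA, per-class covariances).  Their per-pixel posteriors are fused as

    p_k(y | x) = lambda_k * p_QDA(y | x) + (1 - lambda_k) * p_LDA(y | x)

with the mixing weight ``lambda_k`` re-selected at every iteration ``k`` by
a fine grid search maximizing the worse of the per-class accuracies on the
pooled seed samples; exact score ties go to the smallest lambda, privileging
the simpler linear model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientTrainingError, InvalidInputError, InvalidParameterError
from .imgproc import LuvImage
from .seeds import LESION, SKIN, TrainingSplit

__all__ = [
    "GaussianClassParams",
    "PosteriorMap",
    "fit_gaussian_classifier",
    "gaussian_posterior",
    "posterior_for_samples",
    "hybrid_posterior",
    "select_lambda",
]

CLASSES = (SKIN, LESION)
_COND_LIMIT = 1e12
# Posterior differences below this are numerical ties; ties label as skin
# (conservative: calling a pixel lesion requires actual evidence).
TIE_EPS = 1e-9


@dataclass
class GaussianClassParams:
    """Fitted parameters of one Gaussian discriminant model.

    ``covariances`` maps each class to its 3x3 covariance; in ``lda`` mode
    both entries are the same pooled matrix.  ``ridge`` records the diagonal
    loading actually added to keep the matrices well-conditioned.
    """

    mode: str
    class_means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    priors: dict[str, float]
    ridge: float = 0.0
    _chol: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def cholesky(self, cls: str) -> np.ndarray:
        if cls not in self._chol:
            self._chol[cls] = np.linalg.cholesky(self.covariances[cls])
        return self._chol[cls]


@dataclass
class PosteriorMap:
    """Per-pixel class posteriors; p_skin + p_lesion = 1 inside the field."""

    p_skin: np.ndarray
    p_lesion: np.ndarray
    lambda_used: float = float("nan")


def _regularize(covs: dict[str, np.ndarray]) -> tuple[dict[str, np.ndarray], float]:
    """Add diagonal loading until every covariance is well-conditioned."""
    ridge_total = 0.0
    eps = 1e-6
    covs = {c: m.copy() for c, m in covs.items()}
    for _ in range(60):
        worst = max(np.linalg.cond(m) for m in covs.values())
        if worst <= _COND_LIMIT and all(
            np.all(np.linalg.eigvalsh(m) > 0) for m in covs.values()
        ):
            break
        # floor keeps fully-degenerate (constant-feature) fits at a sane scale
        scale = max(max(np.trace(m) for m in covs.values()) / 3.0, 1e-6)
        ridge = eps * scale
        for m in covs.values():
            m[np.diag_indices_from(m)] += ridge
        ridge_total += ridge
        eps *= 10.0
    return covs, ridge_total


def fit_gaussian_classifier(
    samples: dict[str, np.ndarray],
    mode: str,
    priors: dict[str, float] | None = None,
) -> GaussianClassParams:
    """Maximum-likelihood fit of the linear or quadratic Gaussian model.

    LDA pools the within-class scatter weighted by class sizes; QDA keeps
    per-class covariances.  Near-singular covariances (condition number
    above 1e12, e.g. a constant feature in a homogeneous skin seed) are
    ridge-loaded by ``1e-6 * trace/3`` on the diagonal, escalating until
    positive definite, and the total loading is recorded.
    """
    if mode not in ("lda", "qda"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if set(samples) != set(CLASSES):
        raise InvalidInputError(f"samples must have classes {CLASSES}")
    for cls in CLASSES:
        if np.asarray(samples[cls]).shape[0] < 4:
            raise InsufficientTrainingError(
                f"class {cls!r} has fewer than 4 training samples"
            )
    if priors is None:
        priors = {cls: 0.5 for cls in CLASSES}
    means = {cls: np.asarray(samples[cls], dtype=float).mean(axis=0) for cls in CLASSES}
    scatters, ns = {}, {}
    for cls in CLASSES:
        x = np.asarray(samples[cls], dtype=float) - means[cls]
        scatters[cls] = x.T @ x
        ns[cls] = x.shape[0]
    if mode == "lda":
        pooled = sum(scatters.values()) / sum(ns.values())
        covs = {cls: pooled.copy() for cls in CLASSES}
    else:
        covs = {cls: scatters[cls] / ns[cls] for cls in CLASSES}
    covs, ridge = _regularize(covs)
    return GaussianClassParams(
        mode=mode, class_means=means, covariances=covs, priors=dict(priors), ridge=ridge
    )


def _log_density(params: GaussianClassParams, x: np.ndarray, cls: str) -> np.ndarray:
    chol = params.cholesky(cls)
    diff = x - params.class_means[cls]
    y = np.linalg.solve(chol, diff.T)
    maha = np.einsum("ij,ij->j", y, y)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    d = x.shape[1]
    return -0.5 * (maha + logdet + d * np.log(2.0 * np.pi))


def posterior_for_samples(
    params: GaussianClassParams, x: np.ndarray
) -> np.ndarray:
    """(n, 2) posteriors [p_skin, p_lesion] for feature rows ``x`` (log-space)."""
    x = np.asarray(x, dtype=float)
    logp = np.stack(
        [
            _log_density(params, x, cls) + np.log(params.priors[cls])
            for cls in CLASSES
        ],
        axis=1,
    )
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    return p


def gaussian_posterior(params: GaussianClassParams, luv: LuvImage) -> PosteriorMap:
    """Per-pixel Bayes posteriors inside the circular field.

    Pixels outside ``field_mask`` are never classified; their entries are
    left at 0 in both maps.
    """
    p_skin = np.zeros(luv.shape)
    p_lesion = np.zeros(luv.shape)
    mask = luv.field_mask
    feats = luv.stack()[mask]
    p = posterior_for_samples(params, feats)
    p_skin[mask] = p[:, 0]
    p_lesion[mask] = p[:, 1]
    return PosteriorMap(p_skin=p_skin, p_lesion=p_lesion)


def hybrid_posterior(
    p_qda: PosteriorMap, p_lda: PosteriorMap, lam: float
) -> PosteriorMap:
    """Convex combination lam * QDA + (1 - lam) * LDA of the posterior maps."""
    if not 0.0 <= lam <= 1.0:
        raise InvalidParameterError("lambda must lie in [0, 1]")
    if p_qda.p_skin.shape != p_lda.p_skin.shape:
        raise InvalidInputError("posterior maps are not aligned")
    return PosteriorMap(
        p_skin=lam * p_qda.p_skin + (1.0 - lam) * p_lda.p_skin,
        p_lesion=lam * p_qda.p_lesion + (1.0 - lam) * p_lda.p_lesion,
        lambda_used=lam,
    )


def select_lambda(
    split: TrainingSplit,
    lda: GaussianClassParams,
    qda: GaussianClassParams,
    grid_step: float = 0.01,
) -> float:
    """Grid search for the mixing weight on the pooled seed samples.

    For each lambda on the grid {0, grid_step, ..., 1} every pooled seed
    sample is classified by the hybrid rule (argmax posterior; exact 0.5
    ties count as skin) and the score is the minimum of the per-class
    accuracies.  The smallest lambda attaining the maximal score wins, so a
    perfectly separable seed set selects lambda = 0.
    """
    pooled = split.pooled()
    if any(pooled[cls].shape[0] == 0 for cls in CLASSES):
        raise InvalidInputError("empty lambda evaluation set")
    grid = np.arange(0.0, 1.0 + grid_step / 2.0, grid_step)
    grid = np.minimum(grid, 1.0)
    # Posterior of the lesion class per sample and base classifier.
    p_les = {
        cls: {
            "lda": posterior_for_samples(lda, pooled[cls])[:, 1],
            "qda": posterior_for_samples(qda, pooled[cls])[:, 1],
        }
        for cls in CLASSES
    }
    best_lam, best_score = 0.0, -1.0
    for lam in grid:
        accs = []
        for cls in CLASSES:
            p = lam * p_les[cls]["qda"] + (1.0 - lam) * p_les[cls]["lda"]
            pred_lesion = p > 0.5 + TIE_EPS  # ties -> skin
            correct = pred_lesion if cls == LESION else ~pred_lesion
            accs.append(correct.mean())
        score = min(accs)
        if score > best_score:
            best_score, best_lam = score, float(lam)
    return best_lam
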