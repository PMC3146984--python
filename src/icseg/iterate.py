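"""Stage 3 — iterative harvesting of high-confidence samples and convergence.

After the first classification, pixels whose hybrid posterior exceeds a
confidence threshold (0.98) become candidate training samples.  Skin
candidates are taken anywhere inside the field; lesion candidates are
additionally restricted to the opened connected region that best encloses
the initial lesion seed box, a safeguard against harvesting from artifacts.
That restriction applies only to training-sample selection, never to the
segmentation itself.  Per class, at most as many new samples as the
original seed contained are drawn uniformly, so each refreshed training set
is half original and half high-confidence pixels.  The loop stops when the
count ``m_k`` of high-confidence lesion pixels stabilises,

    |1 - m_{k+1} / m_k| < 0.01,

or after 30 iterations, whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .classify import (
    GaussianClassParams,
    PosteriorMap,
    fit_gaussian_classifier,
    gaussian_posterior,
    hybrid_posterior,
    select_lambda,
)
from .config import RunConfig
from .errors import InvalidParameterError
from .imgproc import Geometry, LuvImage, downsample_image, median_denoise, rgb_to_luv
from .postproc import Contour, morph_disk, postprocess
from .seeds import (
    LESION,
    SKIN,
    SeedRegion,
    TrainingSplit,
    prune_to_three,
    select_lesion_seed,
    select_skin_seeds,
    split_seed_samples,
)

__all__ = [
    "IterationState",
    "SegmentationResult",
    "high_confidence_map",
    "lesion_candidate_region",
    "refresh_training_set",
    "check_convergence",
    "run_ics",
]


@dataclass
class IterationState:
    """One row of the iteration trace."""

    k: int
    lambda_k: float
    m_k: int
    n_train_skin: int
    n_train_lesion: int
    converged: bool = False


@dataclass
class SegmentationResult:
    """Output of a full run: raw classification, final mask, contour, trace."""

    lesion_class_mask: np.ndarray
    final_mask: np.ndarray
    contour: Contour | None
    trace: list[IterationState]
    converged: bool
    geometry: Geometry
    skin_seeds: list[SeedRegion] = field(default_factory=list)
    lesion_seed: SeedRegion | None = None
    warning: str | None = None

    @property
    def lesion_found(self) -> bool:
        return bool(self.final_mask.any())

    @property
    def n_iterations(self) -> int:
        return len(self.trace)


def high_confidence_map(
    post: PosteriorMap, tau_conf: float = 0.98
) -> tuple[np.ndarray, np.ndarray]:
    """Masks of pixels with posterior strictly above the confidence threshold."""
    if not 0.0 < tau_conf < 1.0:
        raise InvalidParameterError("tau_conf must lie in (0, 1)")
    return post.p_skin > tau_conf, post.p_lesion > tau_conf


def lesion_candidate_region(
    lesion_class_mask: np.ndarray,
    seed_box: tuple[int, int, int],
    geom: Geometry,
    opening_diameter_mm: float = 1.0,
) -> np.ndarray:
    """Opened lesion subregion that best encloses the initial lesion seed box.

    The mask classified as lesion is opened with a 1-mm disk; among the
    resulting 8-connected components the one overlapping the seed box on the
    most pixels is returned (no overlap: the component whose centroid is
    nearest the box center).  Empty input yields empty output.
    """
    lesion_class_mask = np.asarray(lesion_class_mask, dtype=bool)
    opened = morph_disk(lesion_class_mask, opening_diameter_mm, geom, "open")
    if not opened.any():
        return opened
    labels, n = measure.label(opened, connectivity=2, return_num=True)
    top, left, side = seed_box
    box_labels = labels[top : top + side, left : left + side]
    overlaps = np.bincount(box_labels[box_labels > 0], minlength=n + 1)
    if overlaps.sum() > 0:
        best = int(np.argmax(overlaps[1:])) + 1  # ties -> lowest label id
        return labels == best
    box_center = np.array([top + (side - 1) / 2.0, left + (side - 1) / 2.0])
    centroids = ndarray_centroids(labels, n)
    d = np.linalg.norm(centroids - box_center, axis=1)
    return labels == int(np.argmin(d)) + 1


def ndarray_centroids(labels: np.ndarray, n: int) -> np.ndarray:
    """(n, 2) centroids of labels 1..n."""
    from scipy import ndimage as _ndi

    return np.asarray(_ndi.center_of_mass(labels > 0, labels, index=range(1, n + 1)))


def refresh_training_set(
    split: TrainingSplit,
    eligible_skin: np.ndarray,
    eligible_lesion: np.ndarray,
    luv: LuvImage,
    rng_seed,
) -> TrainingSplit:
    """Original seed samples plus a fresh uniform draw of high-confidence ones.

    ``split`` must be the original (iteration-0) seed split; per class
    ``min(|eligible|, origin_count)`` pixels are drawn without replacement
    with the seeded generator and assigned alternately to the linear and
    quadratic halves, keeping both halves balanced.
    """
    rng = np.random.default_rng(rng_seed)
    feats = luv.stack()
    lda = {c: split.lda_samples[c] for c in split.lda_samples}
    qda = {c: split.qda_samples[c] for c in split.qda_samples}
    for cls, eligible in ((SKIN, eligible_skin), (LESION, eligible_lesion)):
        coords = np.argwhere(np.asarray(eligible, dtype=bool))
        n_draw = min(coords.shape[0], split.origin_counts[cls])
        if n_draw == 0:
            continue
        idx = rng.choice(coords.shape[0], size=n_draw, replace=False)
        drawn = feats[coords[idx, 0], coords[idx, 1], :]
        lda[cls] = np.vstack([lda[cls], drawn[0::2]])
        qda[cls] = np.vstack([qda[cls], drawn[1::2]])
    return TrainingSplit(
        lda_samples=lda, qda_samples=qda, origin_counts=dict(split.origin_counts)
    )


def check_convergence(m_prev: int, m_next: int, tol: float = 0.01) -> bool:
    """Relative-change stop rule on the high-confidence lesion pixel count."""
    if m_prev <= 0:
        return False
    return abs(1.0 - m_next / m_prev) < tol


def _classify_field(post: PosteriorMap, field_mask: np.ndarray) -> np.ndarray:
    # Ties (within numerical precision) count as skin.
    from .classify import TIE_EPS

    return (post.p_lesion > post.p_skin + TIE_EPS) & field_mask


def run_ics(
    image: np.ndarray,
    geom: Geometry,
    config: RunConfig | None = None,
) -> SegmentationResult:
    """Full pipeline on one RGB dermoscopic frame.

    Preprocessing (median filter, optional bilinear downsampling to the
    working resolution, CIE L*u*v* conversion), seed selection, the
    iterative hybrid classification loop, and postprocessing down to the
    final single-region mask and contour.  Fully deterministic for a fixed
    configuration and ``rng_seed``.
    """
    cfg = config or RunConfig()
    denoised = median_denoise(image, cfg.median_window)
    if denoised.shape[0] > cfg.target_side_px:
        resized, scale = downsample_image(denoised, cfg.target_side_px)
        geom = geom.rescaled(scale)
    else:
        resized = denoised.astype(np.float64)
    if geom.d1_radius_mm != cfg.d1_radius_mm:
        geom = Geometry(
            center_px=geom.center_px,
            field_radius_mm=geom.field_radius_mm,
            px_per_mm=geom.px_per_mm,
            d1_radius_mm=cfg.d1_radius_mm,
        )
    field = geom.field_mask(resized.shape[:2])
    luv = rgb_to_luv(np.clip(resized, 0.0, 255.0) / 255.0, field_mask=field)

    skin4 = select_skin_seeds(luv, geom, cfg.w_skin_mm, stride=cfg.seed_scan_stride)
    skin3 = prune_to_three(skin4)
    skin_mean = float(
        np.mean(np.concatenate([luv.L[s.pixels[:, 0], s.pixels[:, 1]] for s in skin3]))
    )
    lesion_seed = select_lesion_seed(
        luv, skin_mean, geom, cfg.w_mole_mm, stride=cfg.seed_scan_stride
    )
    split0 = split_seed_samples(skin3, lesion_seed, luv)

    priors = cfg.priors_dict()
    split = split0
    trace: list[IterationState] = []
    post: PosteriorMap | None = None
    m_prev: int | None = None
    converged = False
    warning = None
    for k in range(1, cfg.max_iterations + 1):
        lda = fit_gaussian_classifier(split.lda_samples, "lda", priors)
        qda = fit_gaussian_classifier(split.qda_samples, "qda", priors)
        lam = select_lambda(split, lda, qda, cfg.lambda_grid_step)
        post = hybrid_posterior(
            gaussian_posterior(qda, luv), gaussian_posterior(lda, luv), lam
        )
        skin_hc, lesion_hc = high_confidence_map(post, cfg.tau_conf)
        m_k = int(lesion_hc.sum())
        conv_now = m_prev is not None and check_convergence(m_prev, m_k, cfg.conv_tol)
        trace.append(
            IterationState(
                k=k,
                lambda_k=lam,
                m_k=m_k,
                n_train_skin=split.lda_samples[SKIN].shape[0]
                + split.qda_samples[SKIN].shape[0],
                n_train_lesion=split.lda_samples[LESION].shape[0]
                + split.qda_samples[LESION].shape[0],
                converged=conv_now,
            )
        )
        if k == 1 and m_k == 0:
            warning = "no high-confidence lesion pixels at the first iteration"
            break
        if conv_now:
            converged = True
            break
        if k == cfg.max_iterations:
            break
        class_lesion = _classify_field(post, field)
        candidate = lesion_candidate_region(
            class_lesion, lesion_seed.box, geom, cfg.opening_mm
        )
        split = refresh_training_set(
            split0, skin_hc & field, lesion_hc & candidate, luv, (cfg.rng_seed, k)
        )
        m_prev = m_k

    class_mask = _classify_field(post, field)
    final_mask, contour = postprocess(
        class_mask,
        geom,
        erode_mm=cfg.erode_mm,
        dilate_mm=cfg.dilate_mm,
        gauss_bw_mm=cfg.connect_bw_mm,
        threshold=cfg.connect_threshold,
        sigma_score_mm=cfg.sigma_score_mm,
    )
    return SegmentationResult(
        lesion_class_mask=class_mask,
        final_mask=final_mask,
        contour=contour,
        trace=trace,
        converged=converged,
        geometry=geom,
        skin_seeds=skin3,
        lesion_seed=lesion_seed,
        warning=warning,
    )
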