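"""Border-evaluation metrics: sensitivity/specificity, Hausdorff distance,
tolerance-ratio contour agreement, majority-vote reference, seed accuracy and
contrast stratification.

Contour distances are computed between the two contour point sets (not
region distance transforms).  With contours M = {m_1..m_z} and
A = {a_1..a_n}:

    d(m_i, A) = min_j ||m_i - a_j||
    d_H       = max( max_i d(m_i, A), max_j d(a_j, M) )
    e(tau)    = [ sum_i I(d(m_i, A) <= tau) + sum_j I(d(a_j, M) <= tau) ] / (n + z)

``d_H`` is reported in millimetres; ``e(tau)`` counts matched contour points
with the inclusive comparison, so e(tau) = 1 whenever tau >= d_H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InvalidInputError
from .imgproc import Geometry
from .postproc import Contour
from .seeds import SeedRegion

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion_and_rates",
    "hausdorff_mm",
    "contour_agreement",
    "majority_vote",
    "seed_accuracy",
    "seed_accuracy_summary",
    "contrast_groups",
    "dice_coefficient",
    "evaluate_masks",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvaluationReport:
    sensitivity: float
    specificity: float
    hausdorff_mm: float
    e_tau: float
    tau_mm: float = 0.5
    dice: float = float("nan")


def _points(contour) -> np.ndarray:
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise InvalidInputError("contour must be a nonempty (N, 2) point set")
    return pts


def confusion_and_rates(
    candidate: np.ndarray,
    reference: np.ndarray,
    field_mask: np.ndarray | None = None,
) -> tuple[ConfusionCounts, float, float]:
    """Pixel confusion counts and sensitivity/specificity inside the field.

    Undefined rates (no lesion pixels, or no skin pixels, in the reference)
    are reported as NaN rather than 0.
    """
    candidate = np.asarray(candidate, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if candidate.shape != reference.shape:
        raise InvalidInputError("candidate and reference shapes differ")
    if field_mask is None:
        field_mask = np.ones_like(candidate)
    elif field_mask.shape != candidate.shape:
        raise InvalidInputError("field_mask shape differs from the masks")
    c, r = candidate[field_mask], reference[field_mask]
    counts = ConfusionCounts(
        tp=int((c & r).sum()),
        fp=int((c & ~r).sum()),
        tn=int((~c & ~r).sum()),
        fn=int((~c & r).sum()),
    )
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    return counts, sens, spec


def _min_dists(p: np.ndarray, q: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Distance from each point of p to its nearest point of q."""
    out = np.empty(p.shape[0])
    for start in range(0, p.shape[0], chunk):
        out[start : start + chunk] = cdist(p[start : start + chunk], q).min(axis=1)
    return out


def hausdorff_mm(a, b, geom: Geometry) -> float:
    """Symmetric Hausdorff distance between contour point sets, in mm."""
    pa, pb = _points(a), _points(b)
    d_px = max(_min_dists(pa, pb).max(), _min_dists(pb, pa).max())
    return float(d_px / geom.px_per_mm)


def contour_agreement(a, b, tau_mm: float = 0.5, geom: Geometry | None = None) -> float:
    """Fraction of contour points of both curves within ``tau_mm`` of the other."""
    pa, pb = _points(a), _points(b)
    px_per_mm = geom.px_per_mm if geom is not None else 1.0
    da = _min_dists(pa, pb) / px_per_mm
    db = _min_dists(pb, pa) / px_per_mm
    return float(((da <= tau_mm).sum() + (db <= tau_mm).sum()) / (len(da) + len(db)))


def majority_vote(masks: list[np.ndarray]) -> np.ndarray:
    """Pixelwise majority of an odd number (>= 3) of aligned binary masks."""
    if len(masks) < 3 or len(masks) % 2 == 0:
        raise InvalidInputError("majority_vote needs an odd count >= 3 of masks")
    stack = np.stack([np.asarray(m, dtype=bool) for m in masks])
    if any(m.shape != stack[0].shape for m in stack):
        raise InvalidInputError("masks must share one shape")
    return stack.sum(axis=0) > len(masks) / 2.0


def seed_accuracy(seed: SeedRegion, agreement_mask: np.ndarray) -> float:
    """Fraction of seed pixels lying inside the class-agreement region."""
    if seed.pixels.size == 0:
        raise InvalidInputError("empty seed region")
    agreement_mask = np.asarray(agreement_mask, dtype=bool)
    inside = agreement_mask[seed.pixels[:, 0], seed.pixels[:, 1]]
    return float(inside.mean())


def seed_accuracy_summary(skin_acc: float, mole_acc: float) -> float:
    """Combined skin+mole seed score: the mean of the two accuracies."""
    return (skin_acc + mole_acc) / 2.0


def _partition_sse_dp(x: np.ndarray, k: int) -> list[np.ndarray]:
    """Exact 1-D k-partition of sorted values minimizing within-cluster SSE.

    Dynamic programming over split points (clusters are contiguous in sorted
    order, which is optimal for squared-error clustering in 1-D); ties take
    the earliest split.
    """
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def cost(i: int, j: int) -> float:  # SSE of x[i..j] inclusive
        m = j - i + 1
        tot = s1[j + 1] - s1[i]
        return (s2[j + 1] - s2[i]) - tot * tot / m

    dp = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n - (k - m) + 1):
            for i in range(m - 1, j):
                c = dp[m - 1, i] + cost(i, j - 1)
                if c < dp[m, j]:
                    dp[m, j] = c
                    back[m, j] = i
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = back[m, j]
        bounds.append(j)
    bounds = bounds[::-1]
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(k)]


_GROUP_NAMES = {3: ["low", "intermediate", "high"]}


def contrast_groups(
    contrasts, k: int = 3
) -> tuple[list[str], np.ndarray]:
    """Exact minimum within-cluster-SSE partition of 1-D contrast values.

    Returns per-value group labels (for k = 3: low / intermediate / high,
    ordered by cluster center) and the sorted cluster centers.  Fewer
    distinct values than k degenerate gracefully: values group by distinct
    value and only those groups are nonempty.
    """
    x = np.asarray(list(contrasts), dtype=float)
    if x.ndim != 1 or len(x) < k:
        raise InvalidInputError(f"need at least {k} contrast values")
    names = _GROUP_NAMES.get(k, [f"group{i}" for i in range(k)])
    order = np.argsort(x, kind="stable")
    xs = x[order]
    uniq = np.unique(xs)
    group_of_sorted = np.empty(len(x), dtype=int)
    if len(uniq) < k:
        centers = uniq
        for gi, val in enumerate(uniq):
            group_of_sorted[xs == val] = gi
    else:
        clusters = _partition_sse_dp(xs, k)
        centers = np.array([xs[c].mean() for c in clusters])
        for gi, c in enumerate(clusters):
            group_of_sorted[c] = gi
    labels = [""] * len(x)
    for pos, gi in zip(order, group_of_sorted):
        labels[pos] = names[gi] if gi < len(names) else f"group{gi}"
    return labels, centers


def dice_coefficient(candidate: np.ndarray, reference: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    candidate = np.asarray(candidate, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    denom = candidate.sum() + reference.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (candidate & reference).sum() / denom)


def evaluate_masks(
    candidate: np.ndarray,
    reference: np.ndarray,
    geom: Geometry,
    tau_mm: float = 0.5,
    field_mask: np.ndarray | None = None,
) -> EvaluationReport:
    """Full report (sensitivity, specificity, d_H, e(tau), Dice) for one pair."""
    from .postproc import extract_contour, finalize_lesion_mask, score_regions

    _, sens, spec = confusion_and_rates(candidate, reference, field_mask)

    def _outer_contour(mask: np.ndarray) -> Contour:
        mask = np.asarray(mask, dtype=bool)
        single = finalize_lesion_mask(mask, score_regions(mask, geom))
        return extract_contour(single, geom)

    ca, cb = _outer_contour(candidate), _outer_contour(reference)
    return EvaluationReport(
        sensitivity=sens,
        specificity=spec,
        hausdorff_mm=hausdorff_mm(ca, cb, geom),
        e_tau=contour_agreement(ca, cb, tau_mm, geom),
        tau_mm=tau_mm,
        dice=dice_coefficient(candidate, reference),
    )
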