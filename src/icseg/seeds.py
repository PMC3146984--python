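"""Stage 1 — automatic placement of skin and lesion seed boxes.

The circular field is split into a central disk ``d1`` (assumed to contain
at least part of the lesion) and the surrounding annulus ``d2`` (assumed to
contain background skin).  One ``w_skin`` x ``w_skin`` box per axis-aligned
quadrant of ``d2`` is placed on the brightest (maximum mean luminance)
fully-contained position; the most dissimilar of the four is discarded; a
``w_mole`` x ``w_mole`` box is then placed inside ``d1`` at the position
whose mean luminance differs most from the merged skin seeds.  Seed pixels
form the initial training samples, split into two spatially disjoint halves
(one for the linear, one for the quadratic classifier).

Box scans are exhaustive at 1-px stride (configurable), implemented with an
integral image plus an exact re-summation of near-ties so that the selected
position is identical to a brute-force scan, with ties broken by the first
position in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, SeedPlacementError
from .imgproc import Geometry, LuvImage

__all__ = [
    "SeedRegion",
    "TrainingSplit",
    "select_skin_seeds",
    "prune_to_three",
    "select_lesion_seed",
    "split_seed_samples",
]

SKIN, LESION = "skin", "lesion"


@dataclass
class SeedRegion:
    """A class-labeled square seed box and its pixel samples."""

    label: str
    box: tuple[int, int, int]  # (top, left, side_px)
    pixels: np.ndarray  # (N, 2) (row, col), row-major order
    mean_L: float
    quadrant: int = -1

    @property
    def side_px(self) -> int:
        return self.box[2]

    def center(self) -> tuple[float, float]:
        top, left, side = self.box
        return (top + (side - 1) / 2.0, left + (side - 1) / 2.0)


@dataclass
class TrainingSplit:
    """Per-class training samples for the two disjoint classifier halves."""

    lda_samples: dict[str, np.ndarray]
    qda_samples: dict[str, np.ndarray]
    origin_counts: dict[str, int]

    def pooled(self) -> dict[str, np.ndarray]:
        """All samples per class (both halves), for lambda evaluation."""
        return {
            cls: np.vstack([self.lda_samples[cls], self.qda_samples[cls]])
            for cls in self.lda_samples
        }


def _box_pixels(top: int, left: int, side: int) -> np.ndarray:
    rr, cc = np.mgrid[top : top + side, left : left + side]
    return np.column_stack([rr.ravel(), cc.ravel()])


def _window_sums(arr: np.ndarray, side: int) -> np.ndarray:
    """Sums of all side x side windows via an integral image."""
    ii = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=ii[1:, 1:])
    return (
        ii[side:, side:] - ii[:-side, side:] - ii[side:, :-side] + ii[:-side, :-side]
    )


def _scan_best_box(
    L: np.ndarray,
    domain: np.ndarray,
    side: int,
    ref: float | None,
    stride: int = 1,
) -> tuple[int, int] | None:
    """Exhaustive scan for the best fully-contained box placement.

    Score is the box mean luminance (``ref is None``) or the absolute
    difference of the box mean from ``ref``.  Near-ties of the fast
    integral-image score are re-evaluated with an exact per-box summation so
    the winner matches a direct brute-force scan bit-for-bit; exact ties go
    to the first position in row-major order.
    """
    if side < 1 or side > min(L.shape):
        return None
    area = side * side
    sums = _window_sums(np.where(domain, L, 0.0), side)
    counts = _window_sums(domain.astype(np.float64), side)
    full = counts > area - 0.5
    if stride > 1:
        keep = np.zeros_like(full)
        keep[::stride, ::stride] = True
        full &= keep
    if not full.any():
        return None
    mean = np.where(full, sums / area, -np.inf)
    score = mean if ref is None else np.where(full, np.abs(mean - ref), -np.inf)
    best = score.max()
    # Integral-image rounding can perturb scores by ~1e-9 on this scale;
    # re-check every candidate within a generous margin exactly.
    cand = np.argwhere(score >= best - 1e-6)
    best_exact, best_pos = -np.inf, None
    for top, left in cand:  # row-major order from argwhere
        m = L[top : top + side, left : left + side].sum() / area
        s = m if ref is None else abs(m - ref)
        if s > best_exact:
            best_exact, best_pos = s, (int(top), int(left))
    return best_pos


def _make_seed(
    L: np.ndarray, label: str, top: int, left: int, side: int, quadrant: int = -1
) -> SeedRegion:
    pixels = _box_pixels(top, left, side)
    mean_L = float(L[top : top + side, left : left + side].mean())
    return SeedRegion(label=label, box=(top, left, side), pixels=pixels, mean_L=mean_L, quadrant=quadrant)


def select_skin_seeds(
    luv: LuvImage,
    geom: Geometry,
    w_skin_mm: float = 1.0,
    stride: int = 1,
) -> list[SeedRegion]:
    """Place one brightest skin box per quadrant of the annulus ``d2``.

    Quadrants are the four axis-aligned quadrants about the field center,
    ordered (top-left, top-right, bottom-left, bottom-right).  Every pixel of
    a box must lie inside the quadrant's part of ``d2``.
    """
    side = max(1, round(geom.mm_to_px(w_skin_mm)))
    r_mm = geom.radius_mm_map(luv.shape)
    annulus = (r_mm > geom.d1_radius_mm) & (r_mm <= geom.field_radius_mm)
    annulus &= luv.field_mask
    rr, cc = np.mgrid[0 : luv.shape[0], 0 : luv.shape[1]]
    cr, ccol = geom.center_px
    top_half, left_half = rr < cr, cc < ccol
    quadrant_masks = [
        top_half & left_half,
        top_half & ~left_half,
        ~top_half & left_half,
        ~top_half & ~left_half,
    ]
    names = ["top-left", "top-right", "bottom-left", "bottom-right"]
    seeds = []
    for q, qmask in enumerate(quadrant_masks):
        pos = _scan_best_box(luv.L, annulus & qmask, side, ref=None, stride=stride)
        if pos is None:
            raise SeedPlacementError(
                f"no valid skin seed placement in the {names[q]} quadrant"
            )
        seeds.append(_make_seed(luv.L, SKIN, pos[0], pos[1], side, quadrant=q))
    return seeds


def prune_to_three(seeds: list[SeedRegion]) -> list[SeedRegion]:
    """Drop the skin seed most dissimilar from the merged other three.

    For each leave-one-out split the distance is the absolute difference
    between the held-out seed's mean luminance and the pooled mean of the
    remaining three; the largest distance loses (ties: highest quadrant
    index), mirroring the all-three-vs-one robustness test.
    """
    if len(seeds) != 4:
        raise InvalidInputError("prune_to_three expects exactly 4 skin seeds")
    counts = np.array([s.pixels.shape[0] for s in seeds], dtype=float)
    sums = np.array([s.mean_L * n for s, n in zip(seeds, counts)])
    diffs = np.empty(4)
    for i in range(4):
        other = [j for j in range(4) if j != i]
        merged_mean = sums[other].sum() / counts[other].sum()
        diffs[i] = abs(seeds[i].mean_L - merged_mean)
    drop = max(i for i in range(4) if diffs[i] == diffs.max())
    return [s for i, s in enumerate(seeds) if i != drop]


def select_lesion_seed(
    luv: LuvImage,
    skin_mean_L: float,
    geom: Geometry,
    w_mole_mm: float = 1.5,
    stride: int = 1,
) -> SeedRegion:
    """Place the lesion box inside ``d1`` at the luminance most distant from skin.

    The criterion is the absolute difference of the box mean luminance from
    the merged skin-seed mean, so a lesion brighter than the surrounding
    skin is still found.
    """
    side = max(1, round(geom.mm_to_px(w_mole_mm)))
    r_mm = geom.radius_mm_map(luv.shape)
    d1 = (r_mm <= geom.d1_radius_mm) & luv.field_mask
    pos = _scan_best_box(luv.L, d1, side, ref=skin_mean_L, stride=stride)
    if pos is None:
        raise SeedPlacementError("no valid lesion seed placement inside d1")
    return _make_seed(luv.L, LESION, pos[0], pos[1], side)


def _split_box_pixels(seed: SeedRegion) -> tuple[np.ndarray, np.ndarray]:
    """Vertical split of a seed box into left/right pixel halves."""
    top, left, side = seed.box
    half = side // 2
    left_px = _box_pixels(top, left, side)[:, :]  # regenerate in row-major
    cols = left_px[:, 1]
    return left_px[cols < left + half], left_px[cols >= left + half]


def _features(luv: LuvImage, pixels: np.ndarray) -> np.ndarray:
    feats = luv.stack()
    return feats[pixels[:, 0], pixels[:, 1], :]


def split_seed_samples(
    skin_seeds: list[SeedRegion],
    lesion_seed: SeedRegion,
    luv: LuvImage,
) -> TrainingSplit:
    """Partition seed pixels into the two disjoint classifier halves.

    With the three skin seeds A, B, C ordered by quadrant index: A plus the
    left half of B train the linear classifier; C plus the right half of B
    train the quadratic one.  The lesion box is split left/right the same
    way.  The two subsets are spatially disjoint and together cover every
    seed pixel.
    """
    if len(skin_seeds) != 3:
        raise InvalidInputError("expected exactly 3 skin seeds")
    if any(s.pixels.size == 0 for s in [*skin_seeds, lesion_seed]):
        raise InvalidInputError("seed regions must be nonempty")
    ordered = sorted(skin_seeds, key=lambda s: s.quadrant)
    a, b, c = ordered
    b_left, b_right = _split_box_pixels(b)
    m_left, m_right = _split_box_pixels(lesion_seed)
    lda = {
        SKIN: np.vstack([_features(luv, a.pixels), _features(luv, b_left)]),
        LESION: _features(luv, m_left),
    }
    qda = {
        SKIN: np.vstack([_features(luv, c.pixels), _features(luv, b_right)]),
        LESION: _features(luv, m_right),
    }
    origin = {
        SKIN: sum(s.pixels.shape[0] for s in ordered),
        LESION: lesion_seed.pixels.shape[0],
    }
    return TrainingSplit(lda_samples=lda, qda_samples=qda, origin_counts=origin)
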