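"""Orchestration: file I/O around the segmentation loop, batch evaluation.

``run_pipeline`` reads an RGB frame, resolves the acquisition geometry,
runs the full iterative segmentation and writes deterministic artifacts
(mask PNG, contour CSV in px and mm, iteration log CSV, overlay PNG, JSON
summary).  ``evaluate_manifest`` scores candidate masks against reference
masks listed in a CSV manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import InvalidInputError
from .imgproc import build_geometry, embed_in_square
from .iterate import SegmentationResult, run_ics
from .metrics import evaluate_masks
from .synth import SynthSpec, synth_dataset

__all__ = ["run_pipeline", "evaluate_manifest", "simulate_dataset", "RunConfig"]

log = logging.getLogger("icseg")


def _load_rgb(path) -> np.ndarray:
    image = iio.imread(path)
    if image.ndim == 3 and image.shape[-1] == 4:
        image = image[..., :3]
    if image.ndim != 3 or image.shape[-1] != 3:
        raise InvalidInputError(f"{path}: expected an RGB image")
    return embed_in_square(image)


def _write_artifacts(result: SegmentationResult, out_dir: Path, stem: str) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    geom = result.geometry
    mask_path = out_dir / f"{stem}_mask.png"
    iio.imwrite(mask_path, result.final_mask.astype(np.uint8) * 255)

    trace_path = out_dir / f"{stem}_iterations.csv"
    pd.DataFrame(
        [
            {
                "k": t.k,
                "lambda_k": t.lambda_k,
                "m_k": t.m_k,
                "n_train_skin": t.n_train_skin,
                "n_train_lesion": t.n_train_lesion,
                "converged": t.converged,
            }
            for t in result.trace
        ]
    ).to_csv(trace_path, index=False)

    contour_path = None
    if result.contour is not None:
        contour_path = out_dir / f"{stem}_contour.csv"
        pts_px = result.contour.points
        pts_mm = result.contour.to_mm(geom).points
        pd.DataFrame(
            {
                "row_px": pts_px[:, 0],
                "col_px": pts_px[:, 1],
                "x_mm": pts_mm[:, 1],
                "y_mm": pts_mm[:, 0],
            }
        ).to_csv(contour_path, index=False)

    summary = {
        "converged": result.converged,
        "n_iterations": result.n_iterations,
        "lesion_found": result.lesion_found,
        "warning": result.warning,
        "px_per_mm": geom.px_per_mm,
        "lambda_trace": [t.lambda_k for t in result.trace],
        "m_trace": [t.m_k for t in result.trace],
        "final_mask_px": int(result.final_mask.sum()),
        "seed_boxes": [
            {"label": s.label, "top": s.box[0], "left": s.box[1], "side_px": s.box[2]}
            for s in [*result.skin_seeds, result.lesion_seed]
            if s is not None
        ],
    }
    summary_path = out_dir / f"{stem}_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {
        "mask": mask_path,
        "iterations": trace_path,
        "contour": contour_path,
        "summary": summary_path,
    }


def _write_overlay(
    image: np.ndarray, result: SegmentationResult, out_dir: Path, stem: str
) -> None:
    if result.contour is None:
        return
    overlay = np.array(image, dtype=np.uint8, copy=True)
    pts = np.round(result.contour.points).astype(int)
    pts = pts[(pts[:, 0] >= 0) & (pts[:, 0] < overlay.shape[0])
              & (pts[:, 1] >= 0) & (pts[:, 1] < overlay.shape[1])]
    overlay[pts[:, 0], pts[:, 1]] = (255, 0, 0)
    iio.imwrite(out_dir / f"{stem}_overlay.png", overlay)


def run_pipeline(
    image_path,
    config: RunConfig | None = None,
    px_per_mm: float | None = None,
    field_mm: float = 17.4,
    field_px: float | None = None,
    out_dir=None,
) -> SegmentationResult:
    """Segment one image file and (optionally) write all artifacts.

    Geometry resolution: explicit ``px_per_mm`` wins; otherwise the circular
    field is assumed to span ``field_px`` pixels (default: the image side)
    over ``field_mm`` millimetres.
    """
    cfg = config or RunConfig()
    image = _load_rgb(image_path)
    side = image.shape[0]
    if px_per_mm is not None:
        diameter_px = px_per_mm * field_mm
    else:
        diameter_px = field_px if field_px is not None else side
    geom = build_geometry(field_mm, diameter_px, image.shape[:2], cfg.d1_radius_mm)
    result = run_ics(image, geom, cfg)
    for t in result.trace:
        log.info(
            "k=%d lambda=%.2f m_k=%d train_skin=%d train_lesion=%d",
            t.k, t.lambda_k, t.m_k, t.n_train_skin, t.n_train_lesion,
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        stem = Path(image_path).stem
        _write_artifacts(result, out_dir, stem)
        # overlay uses the working-resolution image the contour refers to
        if side > cfg.target_side_px:
            from .imgproc import downsample_image, median_denoise

            work, _ = downsample_image(median_denoise(image, cfg.median_window),
                                       cfg.target_side_px)
            work = np.clip(np.round(work), 0, 255).astype(np.uint8)
        else:
            work = image
        _write_overlay(work, result, out_dir, stem)
    return result


def evaluate_manifest(
    manifest_path, tau_mm: float = 0.5, field_mm: float = 17.4
) -> pd.DataFrame:
    """Score (candidate, reference) mask pairs listed in a CSV manifest.

    Expected columns: ``candidate``, ``reference`` (paths to 0/255 PNG
    masks); optional ``image``.  Returns one report row per pair.
    """
    manifest = pd.read_csv(manifest_path)
    if not {"candidate", "reference"} <= set(manifest.columns):
        raise InvalidInputError("manifest needs 'candidate' and 'reference' columns")
    rows = []
    for _, rec in manifest.iterrows():
        cand = iio.imread(rec["candidate"]) > 127
        ref = iio.imread(rec["reference"]) > 127
        geom = build_geometry(field_mm, cand.shape[0], cand.shape)
        rep = evaluate_masks(cand, ref, geom, tau_mm, geom.field_mask(cand.shape))
        rows.append(
            {
                "candidate": rec["candidate"],
                "reference": rec["reference"],
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "hausdorff_mm": rep.hausdorff_mm,
                "e_tau": rep.e_tau,
                "tau_mm": rep.tau_mm,
                "dice": rep.dice,
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(
    out_dir, n: int = 9, contrast_levels=(40.0, 20.0, 9.0), seed: int = 0,
    image_side_px: int = 256,
) -> pd.DataFrame:
    """Generate a synthetic benchmark dataset with ground-truth masks."""
    base = SynthSpec(image_side_px=image_side_px)
    return synth_dataset(base, n, contrast_levels, seed, out_dir)
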