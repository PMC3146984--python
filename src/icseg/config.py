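"""Run configuration: every tunable of the pipeline with its default.

All length-denominated parameters are in millimetres and are converted to
pixels once per run through the acquisition :class:`~icseg.imgproc.Geometry`
(after optional downsampling), so the same configuration applies across
image resolutions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .errors import InvalidParameterError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    w_skin_mm: float = 1.0  # skin seed box side
    w_mole_mm: float = 1.5  # lesion seed box side
    d1_radius_mm: float = 5.0  # central disk assumed to contain the lesion
    tau_conf: float = 0.98  # posterior threshold for high-confidence pixels
    lambda_grid_step: float = 0.01
    opening_mm: float = 1.0  # opening disk for the lesion candidate region
    erode_mm: float = 0.12
    dilate_mm: float = 0.3
    connect_bw_mm: float = 0.06  # Gaussian bandwidth of the region-connect filter
    connect_threshold: float = 0.1
    sigma_score_mm: float = 2.5  # bandwidth of the centrality region score
    conv_tol: float = 0.01  # relative change of m_k declaring convergence
    max_iterations: int = 30
    target_side_px: int = 826
    median_window: int = 5
    priors: tuple[float, float] = (0.5, 0.5)  # (skin, lesion)
    rng_seed: int = 0
    tau_eval_mm: float = 0.5  # tolerance of the contour-agreement score
    seed_scan_stride: int = 1

    def __post_init__(self) -> None:
        for name in (
            "w_skin_mm", "w_mole_mm", "d1_radius_mm", "opening_mm", "erode_mm",
            "dilate_mm", "connect_bw_mm", "sigma_score_mm", "lambda_grid_step",
            "tau_eval_mm",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("tau_conf", "connect_threshold", "conv_tol"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise InvalidParameterError(f"{name} must lie in (0, 1)")
        if self.max_iterations < 1 or self.median_window % 2 == 0:
            raise InvalidParameterError("bad max_iterations or median_window")
        self.priors = tuple(float(p) for p in self.priors)
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise InvalidParameterError("priors must sum to 1")

    def priors_dict(self) -> dict[str, float]:
        return {"skin": self.priors[0], "lesion": self.priors[1]}

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["priors"] = list(d["priors"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "priors" in d:
            d["priors"] = tuple(d["priors"])
        return cls(**d)
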