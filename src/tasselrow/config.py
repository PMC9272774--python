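"""Pipeline configuration.

All tunables of the detection pipeline live in three small dataclasses —
:class:`PreprocessParams` (segmentation), :class:`TrackerParams` (multi-ROI
tracking) and :class:`FitParams` (feature extraction / line fitting) — plus
the :class:`PipelineConfig` aggregate, which round-trips losslessly through
YAML.  Defaults are the operating point of the underlying field study:
log-transform constant ``C = 48``, HSV thresholds H ∈ [80, 121],
S ∈ [250, 255], V ∈ [240, 255] (OpenCV-style half-degree hue scale), a
100 × 20 px bounding box (L1 = 45, L2 = 55, H = 20), eight 20-px search
strips, column-count threshold Y = 15, sparse threshold T0 = 20 with
correction offset d = 20, micro-ROI threshold H0 = 20, and dividing column
center = 260 on a 600 × 600 frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

from .errors import ConfigError

__all__ = [
    "PreprocessParams",
    "TrackerParams",
    "FitParams",
    "PipelineConfig",
]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class PreprocessParams:
    """Parameters of the segmentation front end (crop → log → HSV → Otsu → morphology)."""

    C: float = 48.0
    log_base: Literal["natural", "decimal"] = "natural"
    h_range: tuple[int, int] = (80, 121)
    s_range: tuple[int, int] = (250, 255)
    v_range: tuple[int, int] = (240, 255)
    dilation_kernel: int = 3
    dilation_iters: int = 1
    median_kernel: int = 9
    crop_fraction: float = 0.75
    target_size: int = 600

    def __post_init__(self) -> None:
        _check(self.C > 0, f"log-transform constant C must be > 0, got {self.C}")
        _check(self.log_base in ("natural", "decimal"), f"unknown log base {self.log_base!r}")
        for name, (lo, hi), top in (
            ("h_range", self.h_range, 179),
            ("s_range", self.s_range, 255),
            ("v_range", self.v_range, 255),
        ):
            _check(lo <= hi, f"{name}: empty range ({lo} > {hi})")
            _check(0 <= lo and hi <= top, f"{name} bounds must lie in [0, {top}]")
        for name, k in (("dilation_kernel", self.dilation_kernel), ("median_kernel", self.median_kernel)):
            _check(k >= 1 and k % 2 == 1, f"{name} must be odd and >= 1, got {k}")
        _check(self.dilation_iters >= 0, "dilation_iters must be >= 0")
        _check(0 < self.crop_fraction <= 1.0, "crop_fraction must lie in (0, 1]")
        _check(self.target_size >= 1, "target_size must be >= 1")


@dataclass
class TrackerParams:
    """Parameters of the bounding-box / multi-ROI tracker.

    ``delta_h`` is both the height of the initial-search strips and the
    vertical sliding step; ``L1``/``L2`` are the asymmetric half-widths of the
    box about its anchor; ``Y`` is the column-count threshold of the initial
    strip search; ``T0`` and ``d`` govern sparse-region correction; ``center``
    is the column splitting the frame into left/right halves.
    """

    delta_h: int = 20
    n_strips: int = 8
    Y: int = 15
    T0: int = 20
    d: int = 20
    L1: int = 45
    L2: int = 55
    box_h: int = 20
    center: int = 260
    max_corrections: int = 3
    deviation_limit: int = 40  # 2*d: max deviation from the two-anchor linear trend

    def __post_init__(self) -> None:
        for name in ("delta_h", "n_strips", "Y", "T0", "d", "L1", "L2", "box_h", "center"):
            _check(getattr(self, name) > 0, f"{name} must be positive")
        _check(self.max_corrections >= 0, "max_corrections must be >= 0")
        _check(self.deviation_limit > 0, "deviation_limit must be positive")

    @property
    def box_width(self) -> int:
        return self.L1 + self.L2


@dataclass
class FitParams:
    """Micro-ROI feature extraction and line-fit settings."""

    micro_cell: int = 10   # micro-ROI cell side, px
    micro_H0: int = 20     # strict white-pixel threshold per cell
    min_points: int = 4    # minimum feature points per side for a confident fit
    parallel_tol: float = 1e-9  # |a_l - a_r| below which lines count as parallel

    def __post_init__(self) -> None:
        _check(self.micro_cell >= 1, "micro_cell must be >= 1")
        _check(self.micro_H0 >= 0, "micro_H0 must be >= 0")
        _check(self.min_points >= 2, "min_points must be >= 2")
        _check(self.parallel_tol > 0, "parallel_tol must be positive")


@dataclass
class PipelineConfig:
    """Aggregate configuration for the full detection pipeline."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    fit: FitParams = field(default_factory=FitParams)
    seed: int = 0

    def __post_init__(self) -> None:
        _check(
            self.tracker.center < self.preprocess.target_size,
            "tracker.center must lie inside the processed frame",
        )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples → lists for clean YAML; restored on load
        for key in ("h_range", "s_range", "v_range"):
            d["preprocess"][key] = list(d["preprocess"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        pp = dict(d.get("preprocess", {}))
        for key in ("h_range", "s_range", "v_range"):
            if key in pp:
                pp[key] = tuple(pp[key])
        try:
            return cls(
                preprocess=PreprocessParams(**pp),
                tracker=TrackerParams(**d.get("tracker", {})),
                fit=FitParams(**d.get("fit", {})),
                seed=int(d.get("seed", 0)),
            )
        except TypeError as exc:  # unknown key
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
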