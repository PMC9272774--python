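"""Feature points, least-squares row lines and the bisector navigation line.

Accepted ROIs are diced into 10×10 px micro-ROIs; every cell holding more
than H0 white pixels contributes its geometric midpoint as a feature point.
Each side's points are fitted by ordinary least squares of x on y — rows are
near-vertical, so regressing x on y keeps the slope bounded — giving a line
``x = a·y + b`` whose angle from vertical is ``atan(a)``.  The navigation
line is the bisector of the acute angle at the intersection of the two row
lines; detection quality against a reference line is the acute angle θ
between the two directions, with θ < 5° the conventional accuracy criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import FitParams, PipelineConfig
from .errors import DetectionError, InsufficientPointsError
from .preprocess import preprocess_frame
from .roi_tracker import BoundingBox, RoiChain, extract_multi_roi

__all__ = [
    "FeaturePoint",
    "Line",
    "DetectionResult",
    "micro_roi_points",
    "fit_line",
    "bisector",
    "angular_error",
    "detect_mask",
    "detect_frame",
]


@dataclass(frozen=True)
class FeaturePoint:
    x: float
    y: float
    side: str = ""


@dataclass(frozen=True)
class Line:
    """Row/navigation line parameterised as x = a·y + b."""

    a: float
    b: float

    @property
    def angle_deg(self) -> float:
        """Signed angle from vertical, degrees, in (−90, 90)."""
        return math.degrees(math.atan(self.a))

    def x_at(self, y: float) -> float:
        return self.a * y + self.b

    def direction(self) -> np.ndarray:
        """Unit direction vector (dx, dy) with positive y-component."""
        d = np.array([self.a, 1.0])
        return d / np.linalg.norm(d)


@dataclass
class DetectionResult:
    """Row lines, navigation line and diagnostics for one frame."""

    left: Line
    right: Line
    navigation: Line
    points: dict[str, list[FeaturePoint]] = field(default_factory=dict)
    roi_counts: dict[str, int] = field(default_factory=dict)
    theta_deg: float | None = None  # vs an optional reference navigation line

    def to_record(self) -> dict:
        rec = {
            "left": {"a": self.left.a, "b": self.left.b, "angle_deg": self.left.angle_deg},
            "right": {"a": self.right.a, "b": self.right.b, "angle_deg": self.right.angle_deg},
            "navigation": {
                "a": self.navigation.a,
                "b": self.navigation.b,
                "angle_deg": self.navigation.angle_deg,
            },
            "n_points": {side: len(pts) for side, pts in self.points.items()},
            "roi_counts": dict(self.roi_counts),
        }
        if self.theta_deg is not None:
            rec["theta_deg"] = self.theta_deg
        return rec


def micro_roi_points(
    mask: np.ndarray,
    roi: BoundingBox,
    params: FitParams | None = None,
    side: str = "",
) -> list[FeaturePoint]:
    """Feature points from one accepted ROI via its micro-ROI grid.

    The box is gridded into ``micro_cell``-square cells (10 across × 2 down
    for the default 100×20 box).  A cell whose white-pixel count Hn strictly
    exceeds H0 emits its geometric midpoint.  Only complete cells fully
    inside the image are considered.
    """
    params = params or FitParams()
    h, w = mask.shape[:2]
    cell = params.micro_cell
    pts: list[FeaturePoint] = []
    for top in range(roi.top, roi.bottom - cell + 1, cell):
        for left in range(roi.left, roi.right - cell + 1, cell):
            if top < 0 or left < 0 or top + cell > h or left + cell > w:
                continue
            hn = int((mask[top : top + cell, left : left + cell] == 255).sum())
            if hn > params.micro_H0:
                pts.append(FeaturePoint(left + cell / 2.0, top + cell / 2.0, side))
    return pts


def fit_line(points: list[FeaturePoint], side: str = "") -> Line:
    """Ordinary least squares of x on y: minimise Σ(x − a·y − b)²."""
    if len(points) < 2:
        raise InsufficientPointsError(side, len(points))
    y = np.array([p.y for p in points], dtype=np.float64)
    x = np.array([p.x for p in points], dtype=np.float64)
    if np.ptp(y) == 0:
        raise InsufficientPointsError(
            side, len(points), f"side {side!r}: all feature points at one y, fit degenerate"
        )
    a, b = np.polyfit(y, x, 1)
    return Line(float(a), float(b))


def bisector(left: Line, right: Line, parallel_tol: float = 1e-9) -> Line:
    """Bisector of the acute angle between two lines, through their intersection.

    Directions are taken with positive y-component; if they subtend more
    than 90° one is flipped so the summed unit vectors bisect the acute
    angle.  An exact right angle ties toward the bisector closer to
    vertical.  Parallel lines yield the parallel line midway between them.
    """
    if abs(left.a - right.a) < parallel_tol:
        return Line((left.a + right.a) / 2.0, (left.b + right.b) / 2.0)
    y0 = (right.b - left.b) / (left.a - right.a)
    # averaging the two evaluations keeps the result exactly symmetric in
    # the argument order despite floating-point rounding
    x0 = (left.x_at(y0) + right.x_at(y0)) / 2.0
    d1 = left.direction()
    d2 = right.direction()
    if np.dot(d1, d2) < 0:
        d2 = -d2
    s = d1 + d2
    if abs(s[1]) < parallel_tol:
        # right-angle tie (or horizontal bisector): take the other bisector,
        # which is closer to vertical
        s = d1 - d2
    a = s[0] / s[1]
    return Line(a, x0 - a * y0)


def angular_error(line: Line, reference: Line) -> float:
    """Acute angle between two line directions, degrees in [0, 90]."""
    diff = abs(line.angle_deg - reference.angle_deg)
    return 180.0 - diff if diff > 90.0 else diff


# ---------------------------------------------------------------------------
# frame-level composition
# ---------------------------------------------------------------------------


def _points_from_chain(
    mask: np.ndarray, chain: RoiChain, params: FitParams
) -> list[FeaturePoint]:
    pts: list[FeaturePoint] = []
    for box in chain.contributing():
        pts.extend(micro_roi_points(mask, box, params, chain.side))
    return pts


def detect_mask(
    mask: np.ndarray,
    config: PipelineConfig | None = None,
    reference: Line | None = None,
) -> DetectionResult:
    """Row/navigation detection on an already-binarised mask."""
    config = config or PipelineConfig()
    left_chain, right_chain = extract_multi_roi(mask, config.tracker)
    lines: dict[str, Line] = {}
    points: dict[str, list[FeaturePoint]] = {}
    for chain in (left_chain, right_chain):
        if not chain.found:
            raise DetectionError("roi", chain.side, f"no crop row found on side {chain.side!r}")
        pts = _points_from_chain(mask, chain, config.fit)
        if len(pts) < config.fit.min_points:
            raise DetectionError(
                "features",
                chain.side,
                f"side {chain.side!r}: {len(pts)} feature points < {config.fit.min_points}",
            )
        points[chain.side] = pts
        try:
            lines[chain.side] = fit_line(pts, chain.side)
        except InsufficientPointsError as exc:
            raise DetectionError("fit", chain.side, str(exc)) from exc
    nav = bisector(lines["left"], lines["right"], config.fit.parallel_tol)
    result = DetectionResult(
        left=lines["left"],
        right=lines["right"],
        navigation=nav,
        points=points,
        roi_counts={
            "left": len(left_chain.rois),
            "right": len(right_chain.rois),
        },
    )
    if reference is not None:
        result.theta_deg = angular_error(nav, reference)
    return result


def detect_frame(
    img: np.ndarray,
    config: PipelineConfig | None = None,
    reference: Line | None = None,
) -> DetectionResult:
    """Full pipeline on a raw RGB frame: preprocess, track, fit, bisect."""
    config = config or PipelineConfig()
    pre = preprocess_frame(img, config.preprocess)
    if pre.degenerate:
        raise DetectionError("preprocess", message="segmentation produced an empty mask")
    return detect_mask(pre.mask, config, reference)
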