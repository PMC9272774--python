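"""Balance-function multi-ROI tracking of one crop row per image half.

The binary mask is split at the column ``x = center`` into a left and a
right half, each assumed to contain one of the two central crop rows.  Per
half the tracker:

1. scans eight horizontal strips of height Δh from the bottom up and anchors
   an initial bounding box in the first strip whose per-column white-pixel
   count reaches the threshold Y (the qualifying column closest to center
   wins);
2. refines the box horizontally with the *balance function*
   ``f(x) = |Σ_{v≤x} Z(v)(x−v) − Σ_{v>x} Z(v)(v−x)|`` — the absolute
   difference of the first moments of the column counts Z about candidate
   column x — whose minimiser centres the box mass-symmetrically on the row;
3. slides the box up by Δh per level.  A level with fewer than T0 white
   pixels is a sparse crop area: the box is nudged toward center in steps of
   d (the rows converge upward) and re-tested a bounded number of times.  A
   refined anchor that jumps off the linear trend of the previous two
   anchors is flagged *deviated* (a stray tassel) and contributes no feature
   points.

Coordinates are 0-based with the origin at the top-left and y growing
downward; bottom-up strip s occupies rows [size − s·Δh, size − (s−1)·Δh).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .config import TrackerParams
from .errors import ConfigError, DetectionError, NoCropRowError

__all__ = [
    "BoundingBox",
    "RoiStatus",
    "RoiChain",
    "split_strips",
    "strip_column_counts",
    "find_initial_box",
    "box_column_profile",
    "balance_function",
    "balance_curve",
    "update_box",
    "white_count",
    "slide_and_classify",
    "extract_multi_roi",
]


@dataclass(frozen=True)
class BoundingBox:
    """Fixed-size box anchored on its lower edge.

    The anchor (xr, yr) sits on the lower edge; the box spans columns
    [xr − L1, xr + L2) and rows [yr − height, yr).  At image borders the
    spans are clipped.
    """

    xr: int
    yr: int
    l1: int = 45
    l2: int = 55
    height: int = 20

    @property
    def left(self) -> int:
        return self.xr - self.l1

    @property
    def right(self) -> int:
        return self.xr + self.l2

    @property
    def top(self) -> int:
        return self.yr - self.height

    @property
    def bottom(self) -> int:
        return self.yr

    def clipped(self, shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) of the box intersected with the image."""
        h, w = shape
        return (
            max(0, self.top),
            min(h, self.bottom),
            max(0, self.left),
            min(w, self.right),
        )

    @classmethod
    def from_params(cls, xr: int, yr: int, params: TrackerParams) -> "BoundingBox":
        return cls(xr=xr, yr=yr, l1=params.L1, l2=params.L2, height=params.box_h)


class RoiStatus(str, enum.Enum):
    FEATURE = "feature"
    SPARSE_CORRECTED = "sparse-corrected"
    DEVIATED = "deviated"
    EMPTY = "empty"

    @property
    def contributes(self) -> bool:
        """Whether feature points may be extracted from a box in this state."""
        return self in (RoiStatus.FEATURE, RoiStatus.SPARSE_CORRECTED)


@dataclass
class RoiChain:
    """Ordered accepted ROIs for one image half (bottom to top)."""

    side: str  # "left" | "right"
    rois: list[tuple[BoundingBox, RoiStatus]] = field(default_factory=list)
    found: bool = True

    def anchors(self) -> list[tuple[int, int]]:
        return [(box.xr, box.yr) for box, _ in self.rois]

    def contributing(self) -> list[BoundingBox]:
        return [box for box, status in self.rois if status.contributes]


# ---------------------------------------------------------------------------
# strip search
# ---------------------------------------------------------------------------


def split_strips(
    mask: np.ndarray, params: TrackerParams | None = None
) -> tuple[tuple[int, int], tuple[int, int], list[tuple[int, int]]]:
    """Left/right column ranges and bottom-up strip row bounds.

    Returns ``(left_cols, right_cols, strip_bounds)`` where each entry is a
    half-open (lo, hi) range and ``strip_bounds[s-1]`` is strip Ks.
    """
    params = params or TrackerParams()
    h, w = mask.shape[:2]
    if not (0 < params.center < w):
        raise ConfigError(f"center={params.center} outside image of width {w}")
    if params.n_strips * params.delta_h > h:
        raise ConfigError(
            f"{params.n_strips} strips of height {params.delta_h} exceed image height {h}"
        )
    bounds = [
        (h - s * params.delta_h, h - (s - 1) * params.delta_h)
        for s in range(1, params.n_strips + 1)
    ]
    return (0, params.center), (params.center, w), bounds


def strip_column_counts(
    mask: np.ndarray, strip_rows: tuple[int, int], col_range: tuple[int, int]
) -> np.ndarray:
    """White-pixel count per column of a strip (the cumulative value M(j))."""
    r0, r1 = strip_rows
    c0, c1 = col_range
    return (mask[r0:r1, c0:c1] == 255).sum(axis=0)


def find_initial_box(
    mask: np.ndarray, side: str, params: TrackerParams | None = None
) -> BoundingBox:
    """Locate and refine the initial ROI for one image half.

    Scans strips bottom-up; in the first strip whose maximum column count
    reaches Y, the qualifying column closest to ``center`` anchors the box on
    the strip's lower boundary, and one balance-function update refines it.
    Equidistant ties go to the column on center's side of the region (the
    inner of the two rows is the one of interest).
    """
    params = params or TrackerParams()
    left_cols, right_cols, strips = split_strips(mask, params)
    cols = left_cols if side == "left" else right_cols
    c0, _ = cols
    for strip_rows in strips:
        counts = strip_column_counts(mask, strip_rows, cols)
        if counts.max(initial=0) >= params.Y:
            q = np.flatnonzero(counts >= params.Y) + c0
            dist = np.abs(q - params.center)
            best = dist.min()
            candidates = q[dist == best]
            # tie → the more central-side column: larger on the left half,
            # smaller on the right half
            js = int(candidates.max() if side == "left" else candidates.min())
            box = BoundingBox.from_params(js, strip_rows[1], params)
            refined, _empty = update_box(mask, box, params)
            return refined
    raise NoCropRowError(side)


# ---------------------------------------------------------------------------
# balance-function refinement
# ---------------------------------------------------------------------------


def box_column_profile(mask: np.ndarray, box: BoundingBox) -> tuple[np.ndarray, int]:
    """White-pixel count per box column (Z), plus the clipped left edge.

    The profile has length L1+L2 unless the box is clipped at an image
    border; a fully out-of-bounds box yields an empty profile.
    """
    r0, r1, c0, c1 = box.clipped(mask.shape[:2])
    if r0 >= r1 or c0 >= c1:
        return np.zeros(0, dtype=np.int64), c0
    return (mask[r0:r1, c0:c1] == 255).sum(axis=0).astype(np.int64), c0


def balance_function(Z: np.ndarray, xp: int) -> float:
    """Moment-balance value f(xp) = |Il − Ir| for one candidate column.

    ``xp`` is the 0-based column offset within the profile: Il sums
    Z(v)(xp−v) over v ≤ xp, Ir sums Z(v)(v−xp) over v > xp.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if not 0 <= xp < Z.size:
        raise ConfigError(f"xp={xp} outside profile of length {Z.size}")
    v = np.arange(Z.size)
    il = np.sum(Z[: xp + 1] * (xp - v[: xp + 1]))
    ir = np.sum(Z[xp + 1 :] * (v[xp + 1 :] - xp))
    return float(abs(il - ir))


def balance_curve(Z: np.ndarray) -> np.ndarray:
    """f(xp) for every candidate column at once, via prefix sums.

    With S(x) = Σ_{v≤x} Z(v) and W(x) = Σ_{v≤x} v·Z(v):
    Il(x) = x·S(x) − W(x) and Ir(x) = (W_tot − W(x)) − x·(S_tot − S(x)),
    identical to evaluating :func:`balance_function` at each x.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.size == 0:
        return np.zeros(0)
    v = np.arange(Z.size)
    s = np.cumsum(Z)
    w = np.cumsum(Z * v)
    il = v * s - w
    ir = (w[-1] - w) - v * (s[-1] - s)
    return np.abs(il - ir)


def update_box(
    mask: np.ndarray, box: BoundingBox, params: TrackerParams | None = None
) -> tuple[BoundingBox, bool]:
    """Move the anchor to the balance column of the box contents.

    Returns ``(new_box, empty)``.  The minimiser jk of f over all candidate
    columns (ties → smallest) becomes the new anchor column; the vertical
    coordinate is unchanged.  An empty profile leaves the box unchanged with
    ``empty=True``.
    """
    params = params or TrackerParams()
    Z, c0 = box_column_profile(mask, box)
    if Z.size == 0 or not Z.any():
        return box, True
    jk = int(np.argmin(balance_curve(Z)))
    return replace(box, xr=c0 + jk), False


def white_count(mask: np.ndarray, box: BoundingBox) -> int:
    """Total white pixels inside the (clipped) box — the T1 statistic."""
    r0, r1, c0, c1 = box.clipped(mask.shape[:2])
    if r0 >= r1 or c0 >= c1:
        return 0
    return int((mask[r0:r1, c0:c1] == 255).sum())


# ---------------------------------------------------------------------------
# sliding
# ---------------------------------------------------------------------------


def slide_and_classify(
    mask: np.ndarray,
    prev_box: BoundingBox,
    params: TrackerParams | None = None,
    trend: tuple[int, int] | None = None,
) -> tuple[BoundingBox, RoiStatus] | None:
    """Slide the box one level up and classify the new region.

    ``trend`` carries the anchor columns of the two previously accepted
    levels (older, newer) for the deviation check.  Returns ``None`` when the
    candidate's top edge would leave the image (chain termination).
    """
    params = params or TrackerParams()
    candidate = replace(prev_box, yr=prev_box.yr - params.delta_h)
    if candidate.top < 0:
        return None

    sign = 1 if candidate.xr < params.center else -1  # toward x = center
    probe = candidate
    for _ in range(params.max_corrections + 1):
        if white_count(mask, probe) >= params.T0:
            refined, empty = update_box(mask, probe, params)
            if empty:
                break
            status = (
                RoiStatus.FEATURE if probe.xr == candidate.xr else RoiStatus.SPARSE_CORRECTED
            )
            if trend is not None:
                x_prev2, x_prev1 = trend
                predicted = 2 * x_prev1 - x_prev2
                if abs(refined.xr - predicted) > params.deviation_limit:
                    # stray tassel off the row: keep the trend position
                    return candidate, RoiStatus.DEVIATED
            return refined, status
        probe = replace(probe, xr=probe.xr + sign * params.d)
    # sparse at every correction: record the level empty at the unshifted
    # candidate so the chain keeps following the row trend
    return candidate, RoiStatus.EMPTY


def extract_multi_roi(
    mask: np.ndarray, params: TrackerParams | None = None
) -> tuple[RoiChain, RoiChain]:
    """Build the full multi-ROI chain for both image halves.

    Each chain starts from :func:`find_initial_box` and slides up one Δh per
    level until the box would leave the frame.  A half with no qualifying
    initial strip yields an empty chain flagged ``found=False``; if both
    halves fail, the frame carries no detectable rows and a
    :class:`DetectionError` is raised.
    """
    params = params or TrackerParams()
    chains = []
    for side in ("left", "right"):
        chain = RoiChain(side=side)
        try:
            box = find_initial_box(mask, side, params)
        except NoCropRowError:
            chain.found = False
            chains.append(chain)
            continue
        chain.rois.append((box, RoiStatus.FEATURE))
        while True:
            accepted = [b.xr for b, s in chain.rois if s.contributes]
            trend = (accepted[-2], accepted[-1]) if len(accepted) >= 2 else None
            step = slide_and_classify(mask, chain.rois[-1][0], params, trend)
            if step is None:
                break
            chain.rois.append(step)
        chains.append(chain)
    left, right = chains
    if not left.found and not right.found:
        raise DetectionError("roi", message="no crop row found on either side")
    return left, right
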