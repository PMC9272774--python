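"""Seeded synthetic field scenes with exact ground-truth row lines.

The generator emulates the statistical structure the detector relies on in
a tasseled maize field, at the scale of the 600×600 working frame (i.e. the
navigation area after cropping): two crop rows of bright, vertically
elongated tassel blobs, one per image half, converging toward a vanishing
point above the frame; a darker soil background with leaf clutter; optional
stray (deviated) tassels off the row; impulse noise; and a global
illumination scale.  Every scene carries its exact row lines and the
acute-bisector navigation line as ground truth, so each pipeline stage and
the end-to-end θ accuracy criterion are testable without field footage.

Tassel colours are solved backwards: a target post-log-transform colour is
chosen inside the HSV tassel gamut (high V, saturation forced by a zero red
channel, blue-dominant hue) and inverted through ``p = exp(Out/C) − 1`` to
raw RGB, then re-checked forward through the actual preprocessing code at
generation time.

It does not attempt photorealism: no plant morphology, occlusion, shadows
or wind — only the features the algorithm actually measures.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse

from .config import PipelineConfig, PreprocessParams
from .errors import DetectionError, SceneGenerationError, TasselRowError
from .line_fitting import Line, angular_error, bisector, detect_frame, detect_mask
from .preprocess import hsv_mask, log_transform

__all__ = [
    "SceneParams",
    "GroundTruth",
    "scene_config",
    "generate_mask_scene",
    "generate_rgb_scene",
    "BatchSummary",
    "evaluate_batch",
]


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene; ``seed`` fully determines the output."""

    size: int = 600
    # bottom-edge x position ranges of the two rows, px
    left_base: tuple[int, int] = (140, 200)
    right_base: tuple[int, int] = (400, 460)
    # maximum row tilt from vertical, degrees; rows lean toward the center
    max_angle_deg: float = 15.0
    # minimum separation of the two rows at the top edge (rejection constraint)
    min_top_separation: float = 120.0
    blobs_per_row: int = 30
    # tassel blob half-axes, px: (rx_lo, rx_hi) across, (ry_lo, ry_hi) along the row
    blob_rx: tuple[float, float] = (4.0, 8.0)
    blob_ry: tuple[float, float] = (8.0, 12.0)
    blob_y_top: int = 30
    jitter_x: float = 3.0
    deviated_blobs: int = 0
    deviated_offset: float = 60.0
    impulse_noise: float = 0.01
    # per-scene illumination scale drawn uniformly from this interval,
    # emulating acquisition under different light levels
    illumination: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 200:
            raise SceneGenerationError("scene size must be >= 200 px")
        if not (0 <= self.impulse_noise < 1):
            raise SceneGenerationError("impulse_noise must lie in [0, 1)")
        for lo, hi in (self.left_base, self.right_base, self.illumination):
            if lo > hi:
                raise SceneGenerationError("parameter range is empty")
        if not (0 < self.left_base[1] < self.right_base[0] < self.size):
            raise SceneGenerationError("row base positions must be ordered inside the frame")
        if self.blobs_per_row < 0:
            raise SceneGenerationError("blobs_per_row must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact scene geometry: row lines, navigation line, blob footprint."""

    left: Line
    right: Line
    navigation: Line
    footprint: np.ndarray          # bool mask of on-row blob pixels
    deviated_footprint: np.ndarray  # bool mask of stray-blob pixels
    seed: int

    def swapped(self) -> "GroundTruth":
        return replace(self, left=self.right, right=self.left)


def scene_config(**overrides) -> PipelineConfig:
    """Pipeline configuration matched to synthetic scenes.

    Scenes are generated at working-frame scale, so the crop step is the
    identity (``crop_fraction = 1.0``); everything else keeps its default.
    """
    cfg = PipelineConfig(preprocess=PreprocessParams(crop_fraction=1.0))
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _sample_lines(params: SceneParams, rng: np.random.Generator) -> tuple[Line, Line]:
    """Draw the two row lines: tilts within ±max_angle toward the center,
    rejection-sampled so the rows stay min_top_separation apart at the top."""
    size = params.size
    amax = np.tan(np.radians(params.max_angle_deg))
    for _ in range(200):
        base_l = rng.uniform(*params.left_base)
        base_r = rng.uniform(*params.right_base)
        a_l = rng.uniform(-amax, 0.0)   # left row leans right (toward center) going up
        a_r = rng.uniform(0.0, amax)    # right row leans left going up
        b_l = base_l - a_l * size
        b_r = base_r - a_r * size
        if (b_r - b_l) >= params.min_top_separation:
            return Line(a_l, b_l), Line(a_r, b_r)
    raise SceneGenerationError(
        "could not place two non-crossing rows; relax angles or base ranges"
    )


def _blob_centers(
    line: Line, params: SceneParams, rng: np.random.Generator
) -> np.ndarray:
    """(y, x) centres of the on-row blobs, jittered about the true line."""
    size = params.size
    ys = np.linspace(size - 8, params.blob_y_top, params.blobs_per_row)
    ys = ys + rng.normal(0.0, 2.0, ys.size)
    xs = np.array([line.x_at(y) for y in ys]) + rng.normal(0.0, params.jitter_x, ys.size)
    return np.column_stack([ys, xs])


def _paint_blobs(
    canvas: np.ndarray, centers: np.ndarray, params: SceneParams, rng: np.random.Generator
) -> np.ndarray:
    """Fill vertically elongated ellipses; returns the painted bool footprint."""
    footprint = np.zeros(canvas.shape[:2], dtype=bool)
    for cy, cx in centers:
        rx = rng.uniform(*params.blob_rx)
        ry = rng.uniform(*params.blob_ry)
        rr, cc = ellipse(cy, cx, ry, rx, shape=canvas.shape[:2])
        footprint[rr, cc] = True
    return footprint


def _scene_geometry(
    params: SceneParams,
) -> tuple[np.random.Generator, GroundTruth, np.ndarray, np.ndarray]:
    """Shared setup: rng, truth lines, on-row and deviated footprints."""
    rng = np.random.default_rng(params.seed)
    left, right = _sample_lines(params, rng)
    shape = (params.size, params.size)
    dummy = np.zeros(shape, dtype=np.uint8)

    foot = np.zeros(shape, dtype=bool)
    for line in (left, right):
        centers = _blob_centers(line, params, rng)
        foot |= _paint_blobs(dummy[..., None], centers, params, rng)

    dev = np.zeros(shape, dtype=bool)
    if params.deviated_blobs > 0:
        for line, sign in ((left, 1.0), (right, -1.0)):
            for _ in range(params.deviated_blobs):
                y = rng.uniform(params.size * 0.25, params.size * 0.6)
                x = line.x_at(y) + sign * params.deviated_offset
                rr, cc = ellipse(y, x, rng.uniform(*params.blob_ry), rng.uniform(*params.blob_rx), shape=shape)
                dev[rr, cc] = True

    truth = GroundTruth(
        left=left,
        right=right,
        navigation=bisector(left, right),
        footprint=foot,
        deviated_footprint=dev,
        seed=params.seed,
    )
    return rng, truth, foot, dev


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------


def generate_mask_scene(params: SceneParams | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Binary-mask scene: white blobs on black, plus impulse noise.

    Bypasses colour segmentation entirely so the ROI tracking and fitting
    stages can be exercised in isolation.
    """
    params = params or SceneParams()
    rng, truth, foot, dev = _scene_geometry(params)
    mask = np.where(foot | dev, 255, 0).astype(np.uint8)
    if params.impulse_noise > 0:
        u = rng.random(mask.shape)
        mask[u < params.impulse_noise / 2] = 255                      # salt
        mask[(u >= 0.5) & (u < 0.5 + params.impulse_noise / 2)] = 0   # pepper
    return mask, truth


def _tassel_color(rng: np.random.Generator) -> np.ndarray:
    """Raw-RGB tassel colour whose log-transformed HSV stays in-gamut.

    The red channel is zero (forcing post-transform saturation to 255 at any
    illumination scale), blue is high enough that V ≥ 240 survives a 0.7×
    illumination dip, and green below blue keeps the hue in the blue-cyan
    band the thresholds select.
    """
    b = rng.integers(232, 251)
    g = rng.integers(60, max(61, b - 40))
    return np.array([0, g, b], dtype=np.float64)


def generate_rgb_scene(params: SceneParams | None = None) -> tuple[np.ndarray, GroundTruth]:
    """RGB scene: soil/leaf background, in-gamut tassel blobs, illumination, noise.

    The tassel gamut is self-checked at generation time by pushing the
    rendered (pre-noise) blobs through the actual log transform + HSV mask;
    a failure raises :class:`SceneGenerationError`.
    """
    params = params or SceneParams()
    rng, truth, foot, dev = _scene_geometry(params)
    size = params.size
    shape = (size, size)

    # soil background with per-pixel texture
    img = np.empty((size, size, 3), dtype=np.float64)
    img[..., 0] = rng.normal(105, 14, shape)
    img[..., 1] = rng.normal(85, 12, shape)
    img[..., 2] = rng.normal(60, 10, shape)

    # leaf clutter: dull green ellipses, deliberately outside the tassel gamut
    for _ in range(40):
        y, x = rng.uniform(0, size), rng.uniform(0, size)
        rr, cc = ellipse(y, x, rng.uniform(8, 25), rng.uniform(8, 25), shape=shape)
        leaf = np.array([45, 80, 40]) + rng.normal(0, 6, 3)
        img[rr, cc] = leaf

    # tassels: one colour per connected blob region, re-painted blob-wise
    blobs = foot | dev
    labels, n_lab = _label(blobs)
    for lab in range(1, n_lab + 1):
        region = labels == lab
        color = _tassel_color(rng)
        img[region] = color + np.concatenate([[0.0], rng.normal(0, 3, 2)])

    img = np.clip(np.rint(img), 0, 255)
    img[..., 0][blobs] = 0.0  # zero red is what pins post-transform saturation

    illum = rng.uniform(*params.illumination)
    img = np.clip(np.rint(img * illum), 0, 255).astype(np.uint8)

    _gamut_self_check(img, blobs, params)

    if params.impulse_noise > 0:
        u = rng.random(shape)
        salt = u < params.impulse_noise / 2
        pepper = (u >= 0.5) & (u < 0.5 + params.impulse_noise / 2)
        img[salt] = np.array([0, 90, 240], dtype=np.uint8)  # lands in-gamut post-transform
        img[pepper] = 0
    return img, truth


def _label(binary: np.ndarray) -> tuple[np.ndarray, int]:
    from scipy import ndimage

    labels, n = ndimage.label(binary)
    return labels, n


def _gamut_self_check(img: np.ndarray, blobs: np.ndarray, params: SceneParams) -> None:
    if not blobs.any():
        return
    pp = PreprocessParams(crop_fraction=1.0, target_size=params.size)
    masked = hsv_mask(log_transform(img, pp), pp)
    in_gamut = masked.any(axis=2)
    frac = in_gamut[blobs].mean()
    if frac < 0.95:
        raise SceneGenerationError(
            f"only {frac:.1%} of tassel pixels survive the segmentation gamut"
        )


# ---------------------------------------------------------------------------
# batch evaluation
# ---------------------------------------------------------------------------


@dataclass
class BatchSummary:
    """θ statistics over a batch of seeded scenes."""

    n: int
    thetas: list[float]          # degrees; NaN for failed frames
    mean_theta: float
    max_theta: float
    min_theta: float
    accuracy: float              # fraction of frames with θ < threshold (failures count as misses)
    threshold_deg: float
    n_failed: int
    mean_time_ms: float
    records: list[dict] = field(default_factory=list)


def evaluate_batch(
    n: int,
    params: SceneParams | None = None,
    config: PipelineConfig | None = None,
    kind: str = "rgb",
    threshold_deg: float = 5.0,
) -> BatchSummary:
    """Run the detector on ``n`` seeded scenes and score θ against ground truth.

    Scene i uses seed ``params.seed + i``; a failed detection counts as an
    inaccurate frame and contributes no θ statistic.  Per-frame wall time is
    reported informationally.
    """
    if n < 1:
        raise SceneGenerationError("n must be >= 1")
    params = params or SceneParams()
    config = config or scene_config()
    thetas: list[float] = []
    records: list[dict] = []
    times: list[float] = []
    n_failed = 0
    for i in range(n):
        sp = replace(params, seed=(params.seed + i) % (2**31))
        t0 = time.perf_counter()
        try:
            if kind == "mask":
                mask, truth = generate_mask_scene(sp)
                result = detect_mask(mask, config, reference=truth.navigation)
            elif kind == "rgb":
                img, truth = generate_rgb_scene(sp)
                result = detect_frame(img, config, reference=truth.navigation)
            else:
                raise SceneGenerationError(f"unknown scene kind {kind!r}")
        except (DetectionError, TasselRowError) as exc:
            if isinstance(exc, SceneGenerationError):
                raise
            elapsed = (time.perf_counter() - t0) * 1000
            times.append(elapsed)
            thetas.append(float("nan"))
            n_failed += 1
            records.append({"seed": sp.seed, "error": str(exc), "time_ms": elapsed})
            continue
        elapsed = (time.perf_counter() - t0) * 1000
        times.append(elapsed)
        thetas.append(result.theta_deg)
        rec = result.to_record()
        rec.update(
            {
                "seed": sp.seed,
                "time_ms": elapsed,
                "truth": {
                    "left_angle_deg": truth.left.angle_deg,
                    "right_angle_deg": truth.right.angle_deg,
                    "nav_angle_deg": truth.navigation.angle_deg,
                },
                "left_err_deg": angular_error(result.left, truth.left),
                "right_err_deg": angular_error(result.right, truth.right),
            }
        )
        records.append(rec)
    ok = np.array([t for t in thetas if not np.isnan(t)])
    hits = int((ok < threshold_deg).sum())
    return BatchSummary(
        n=n,
        thetas=thetas,
        mean_theta=float(ok.mean()) if ok.size else float("nan"),
        max_theta=float(ok.max()) if ok.size else float("nan"),
        min_theta=float(ok.min()) if ok.size else float("nan"),
        accuracy=hits / n,
        threshold_deg=threshold_deg,
        n_failed=n_failed,
        mean_time_ms=float(np.mean(times)) if times else 0.0,
        records=records,
    )
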