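"""Myelin-debris object detection in orientation-colormapped qBRM images.

The pieces mirror a standard small-object detection workflow on very large
microscopy mosaics: dual-annotator consensus merging, patch cropping for
training, geometric + "color rotation" augmentation (a cyclic RGB
permutation, equivalent to rotating the 180-degree optic-axis color wheel
by 60 degrees), a pluggable detector contract, and sliced whole-image
inference (overlapping tiles, optional test-time augmentation, global
non-max suppression).

The bundled reference detector is a rotational matched filter: myelin
debris renders as an annulus whose optic axis points radially outward from
the object center, so correlating the doubled-angle orientation field
against ring templates ``exp(2i * psi)`` gives a score that is high on
debris, cancels on coherently oriented fibers, and is invariant to color
rotation by construction.  Any detector honoring :class:`DetectorInterface`
(e.g. a trained neural network) can be substituted.
"""

from __future__ import annotations

import functools
import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

__all__ = [
    "BoundingBox",
    "Detection",
    "TilingConfig",
    "TrainConfig",
    "DetectorInterface",
    "BlobDetector",
    "GroundTruthDetector",
    "MatchedFilterDetector",
    "InferenceResult",
    "iou",
    "color_rotate",
    "merge_consensus",
    "tile_origins",
    "crop_training_patches",
    "augment",
    "transform_patch",
    "transform_box",
    "invert_geom",
    "train_reference_detector",
    "nms",
    "sliced_inference",
    "GEOM_VARIANTS",
]


# ---------------------------------------------------------------------------
# boxes


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, top-left origin, 0-based pixel coordinates."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"degenerate box {self}")

    @property
    def x2(self) -> float:
        return self.x + self.width

    @property
    def y2(self) -> float:
        return self.y + self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height

    def translate(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x + dx, self.y + dy, self.width, self.height)

    def clip(self, width: float, height: float) -> "BoundingBox | None":
        """Intersect with ``[0, width) x [0, height)``; None if empty."""
        x1, y1 = max(self.x, 0.0), max(self.y, 0.0)
        x2, y2 = min(self.x2, width), min(self.y2, height)
        if x2 <= x1 or y2 <= y1:
            return None
        return BoundingBox(x1, y1, x2 - x1, y2 - y1)


@dataclass(frozen=True)
class Detection:
    """A detector output: a box with a confidence in [0, 1]."""

    box: BoundingBox
    confidence: float = 1.0
    source_tile: int | None = None
    tta_variant: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    if inter <= 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TilingConfig:
    """Sliced-inference tiling: 128 px tiles with 50% overlap by default."""

    tile_px: int = 128
    overlap_frac: float = 0.5
    patch_channels: int = 3

    def __post_init__(self) -> None:
        if self.tile_px < 32:
            raise ValueError("tile_px must be >= 32")
        if not (0.0 <= self.overlap_frac < 1.0):
            raise ValueError("overlap_frac must be in [0, 1)")

    @property
    def stride(self) -> int:
        return max(1, int(round(self.tile_px * (1.0 - self.overlap_frac))))


@dataclass
class TrainConfig:
    """Training schedule and augmentation switches.

    Defaults follow the standard recipe for this task: 100 epochs of Adam
    at 0.005 halved every 10 epochs, mini-batch 256, with flips, rotations
    and color rotation as augmentations.  The matched-filter reference
    detector fits its few parameters in closed form and records (but does
    not iterate over) the schedule; a neural backend plugged in through
    :class:`DetectorInterface` would consume it fully.
    """

    epochs: int = 100
    initial_lr: float = 0.005
    lr_decay: float = 0.5
    lr_decay_every: int = 10
    batch_size: int = 256
    augmentations: tuple[str, ...] = ("flips", "rotations", "color_rotation")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# color rotation and geometric transforms


def color_rotate(rgb_image: np.ndarray, k: int) -> np.ndarray:
    """Cyclically permute the RGB channels ``k`` times: (R,G,B) -> (B,R,G).

    On an orientation-colormapped qBRM image one permutation equals
    shifting every optic-axis orientation by +60 degrees, so the image
    remains a physically valid rendering of the same tissue.  Bounding
    boxes are unaffected.
    """
    img = np.asarray(rgb_image)
    if img.ndim < 1 or img.shape[-1] != 3:
        raise ValueError("color_rotate requires a 3-channel image")
    return np.roll(img, k % 3, axis=-1)


#: Geometric test-time/augmentation variants (square patches only).
GEOM_VARIANTS = ("identity", "rot90", "rot180", "rot270", "hflip", "vflip")

_GEOM_INVERSE = {
    "identity": "identity",
    "rot90": "rot270",
    "rot180": "rot180",
    "rot270": "rot90",
    "hflip": "hflip",
    "vflip": "vflip",
}


def invert_geom(geom: str) -> str:
    return _GEOM_INVERSE[geom]


def transform_patch(patch: np.ndarray, geom: str) -> np.ndarray:
    """Apply a dihedral transform to a (square) image patch."""
    if geom == "identity":
        return patch
    if geom == "rot90":
        return np.rot90(patch, 1, axes=(0, 1))
    if geom == "rot180":
        return np.rot90(patch, 2, axes=(0, 1))
    if geom == "rot270":
        return np.rot90(patch, 3, axes=(0, 1))
    if geom == "hflip":
        return patch[:, ::-1]
    if geom == "vflip":
        return patch[::-1, :]
    raise ValueError(f"unknown geometric variant {geom!r}")


def transform_box(box: BoundingBox, geom: str, size: int) -> BoundingBox:
    """Transform box coordinates consistently with :func:`transform_patch`.

    ``size`` is the square patch side.  Conventions match ``np.rot90``
    (counterclockwise in array axes).
    """
    x, y, w, h = box.x, box.y, box.width, box.height
    if geom == "identity":
        return box
    if geom == "hflip":
        return BoundingBox(size - x - w, y, w, h)
    if geom == "vflip":
        return BoundingBox(x, size - y - h, w, h)
    if geom == "rot90":
        return BoundingBox(y, size - x - w, h, w)
    if geom == "rot180":
        return BoundingBox(size - x - w, size - y - h, w, h)
    if geom == "rot270":
        return BoundingBox(size - y - h, x, h, w)
    raise ValueError(f"unknown geometric variant {geom!r}")


# ---------------------------------------------------------------------------
# annotation consensus and patch preparation


def merge_consensus(
    annotations_a: list[BoundingBox],
    annotations_b: list[BoundingBox],
    iou_thr: float = 0.5,
) -> list[BoundingBox]:
    """Keep only debris both annotators agree on; average agreeing pairs.

    Pairs are claimed greedily by descending IoU, one-to-one; pairs with
    IoU >= ``iou_thr`` emit the coordinate-wise mean box; everything else
    is discarded.
    """
    pairs = sorted(
        (
            (iou(a, b), i, j)
            for i, a in enumerate(annotations_a)
            for j, b in enumerate(annotations_b)
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[BoundingBox] = []
    for score, i, j in pairs:
        if score < iou_thr:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = annotations_a[i], annotations_b[j]
        out.append(
            BoundingBox(
                (a.x + b.x) / 2.0,
                (a.y + b.y) / 2.0,
                (a.width + b.width) / 2.0,
                (a.height + b.height) / 2.0,
            )
        )
    return out


def tile_origins(height: int, width: int, tiling: TilingConfig) -> list[tuple[int, int]]:
    """Top-left corners of the overlapping tile grid covering the image.

    The grid is anchored at (0, 0); the last tile in each axis is shifted
    inward so every tile is full size and every pixel is covered.
    """
    t = tiling.tile_px
    if height < t or width < t:
        raise ValueError(f"image {height}x{width} smaller than tile {t}")

    def axis_positions(size: int) -> list[int]:
        ps = list(range(0, size - t + 1, tiling.stride))
        if ps[-1] != size - t:
            ps.append(size - t)
        return ps

    return [(x, y) for y in axis_positions(height) for x in axis_positions(width)]


def crop_training_patches(
    image: np.ndarray,
    boxes: list[BoundingBox],
    tiling: TilingConfig | None = None,
    min_visible_frac: float = 0.5,
) -> list[tuple[np.ndarray, list[BoundingBox], tuple[int, int]]]:
    """Cut an annotated image into overlapping training patches.

    Returns ``(patch, boxes_in_patch_coords, (x0, y0))`` triples.  Boxes
    are clipped to the patch; a clipped box retaining less than
    ``min_visible_frac`` of its original area is dropped.
    """
    tiling = tiling or TilingConfig()
    t = tiling.tile_px
    out = []
    for x0, y0 in tile_origins(image.shape[0], image.shape[1], tiling):
        patch = image[y0 : y0 + t, x0 : x0 + t]
        local: list[BoundingBox] = []
        for box in boxes:
            clipped = box.translate(-x0, -y0).clip(t, t)
            if clipped is not None and clipped.area >= min_visible_frac * box.area:
                local.append(clipped)
        out.append((patch, local, (x0, y0)))
    return out


def augment(
    patch: np.ndarray,
    boxes: list[BoundingBox],
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[BoundingBox]]:
    """Random training-time augmentation of a square patch and its boxes.

    Composes a random 0/90/180/270 rotation, horizontal/vertical flips and
    a color rotation, according to the switches in ``config.augmentations``.
    Geometric transforms are rigid, so box count and areas are preserved.
    """
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("augment requires a square patch")
    size = patch.shape[0]
    geoms: list[str] = []
    if "rotations" in config.augmentations:
        geoms.append(("identity", "rot90", "rot180", "rot270")[rng.integers(4)])
    if "flips" in config.augmentations:
        if rng.integers(2):
            geoms.append("hflip")
        if rng.integers(2):
            geoms.append("vflip")
    out = patch
    for geom in geoms:
        out = transform_patch(out, geom)
        boxes = [transform_box(b, geom, size) for b in boxes]
    if "color_rotation" in config.augmentations:
        out = color_rotate(out, int(rng.integers(3)))
    return out, boxes


# ---------------------------------------------------------------------------
# detectors


class DetectorInterface(ABC):
    """Contract for pluggable detectors.

    ``predict`` must be a pure, deterministic function of the patch and the
    detector's frozen state, returning detections in patch coordinates.
    The tile origin is supplied for traceability (most detectors ignore
    it; an oracle detector backed by global ground truth needs it).
    """

    @abstractmethod
    def predict(
        self, patch: np.ndarray, origin: tuple[int, int] = (0, 0)
    ) -> list[Detection]:
        ...


class BlobDetector(DetectorInterface):
    """Threshold + connected-component boxes on the brightness channel.

    Exactly equivariant to flips/rotations and invariant to color rotation
    (brightness is the channel maximum), which makes it a convenient
    reference for test-time-augmentation consistency checks.  Not debris
    specific: fibers light up too.
    """

    def __init__(self, threshold: float = 0.5, min_area: int = 1) -> None:
        self.threshold = threshold
        self.min_area = min_area

    def predict(self, patch, origin=(0, 0)):
        value = np.max(np.asarray(patch, dtype=float), axis=-1)
        labels, n = ndimage.label(value > self.threshold)
        out = []
        for sl in ndimage.find_objects(labels):
            if sl is None:
                continue
            h = sl[0].stop - sl[0].start
            w = sl[1].stop - sl[1].start
            if h * w < self.min_area:
                continue
            conf = float(min(1.0, value[sl].mean()))
            out.append(Detection(BoundingBox(sl[1].start, sl[0].start, w, h), conf))
        return out


class GroundTruthDetector(DetectorInterface):
    """Oracle that returns the known true boxes fully contained in a tile.

    Used to validate the sliced-inference plumbing independently of any
    learned model: with a perfect per-tile detector the merged global
    output must reproduce the ground truth.
    """

    def __init__(self, boxes: list[BoundingBox], tile_px: int = 128) -> None:
        self.boxes = list(boxes)
        self.tile_px = tile_px

    def predict(self, patch, origin=(0, 0)):
        x0, y0 = origin
        t = patch.shape[0]
        out = []
        for box in self.boxes:
            if box.x >= x0 and box.y >= y0 and box.x2 <= x0 + t and box.y2 <= y0 + t:
                out.append(Detection(box.translate(-x0, -y0), 1.0))
        return out


def _rgb_to_fields(patch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert the qBRM colormap: RGB -> (value, doubled-angle phase field).

    For full-saturation renderings the channel maximum is the retardance
    value and the hue encodes twice the optic-axis orientation.  Returns
    the value image and the complex field ``value * exp(i * hue_rad)``
    (hue = doubled orientation), which is the natural domain for
    orientation matched filtering: a cyclic channel permutation multiplies
    the field by a global unit phase, so any magnitude-based statistic is
    color-rotation invariant.
    """
    rgb = np.asarray(patch, dtype=float)
    v = rgb.max(axis=-1)
    c = rgb.min(axis=-1)
    delta = v - c
    safe = np.where(delta > 0, delta, 1.0)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    hue = np.zeros_like(v)
    is_r = (v == r) & (delta > 0)
    is_g = (v == g) & (delta > 0) & ~is_r
    is_b = (delta > 0) & ~is_r & ~is_g
    hue = np.where(is_r, np.mod((g - b) / safe, 6.0), hue)
    hue = np.where(is_g, (b - r) / safe + 2.0, hue)
    hue = np.where(is_b, (r - g) / safe + 4.0, hue)
    hue_rad = hue * (np.pi / 3.0)  # 60 deg sectors
    return v, v * np.exp(1j * hue_rad)


def _n_sectors(radius: float) -> int:
    """Angular sectors per ring: finer coverage test once the arc per
    sector is a few pixels (octants need ~2 px of arc each)."""
    return 8 if radius >= 3 else 4


@functools.lru_cache(maxsize=64)
def _ring_kernels(radius: float, halfwidth: float = 1.0):
    """Radial matched-filter kernels for one scale.

    Returns ``(sector_templates, weight)`` on a square support: ``weight``
    is a Gaussian ring at ``radius`` and each of the four sector templates
    is ``weight * exp(2i psi)`` (``psi`` the polar angle of the offset —
    the doubled-angle signature of a radial optic axis) restricted to one
    angular quadrant.  Scoring sectors separately and requiring all four
    to respond distinguishes a full annulus from a tangent arc, which
    lights only two opposite quadrants.
    """
    # tighter rings at small radii: a wide Gaussian around a 1-2 px ring
    # mostly integrates background
    halfwidth = min(halfwidth, 0.5 + 0.25 * radius)
    extent = int(math.ceil(radius + 3 * halfwidth))
    coords = np.arange(-extent, extent + 1, dtype=float)
    dx, dy = np.meshgrid(coords, coords)
    dist = np.hypot(dx, dy)
    weight = np.exp(-0.5 * ((dist - radius) / halfwidth) ** 2)
    weight[dist < 0.5] = 0.0  # exclude the center pixel (psi undefined)
    psi = np.arctan2(dy, dx)
    template = weight * np.exp(2j * psi)
    n = _n_sectors(radius)
    sector_of = np.floor(np.mod(psi, 2.0 * np.pi) / (2.0 * np.pi / n)).astype(int) % n
    sectors = [np.where(sector_of == k, template, 0.0) for k in range(n)]
    return sectors, weight


@functools.lru_cache(maxsize=64)
def _ideal_sector_responses(
    radius: float, halfwidth: float, amplitude: float
) -> list[float]:
    """Per-sector matched response of an ideal annulus at its own scale.

    Renders the annulus model the templates target (bright rim of width
    20% of the radius, ~1 px soft outer edge, radial optic axis; the core
    is ignored as it sits mostly outside the ring weight) and evaluates
    each sector correlation at the center, where every pixel phase
    matches the template phase, so each response is the weighted rim mass
    in that quadrant.  Used to normalize observed correlations to [0, 1].
    """
    sectors, weight = _ring_kernels(radius, halfwidth)
    extent = (weight.shape[0] - 1) // 2
    coords = np.arange(-extent, extent + 1, dtype=float)
    dx, dy = np.meshgrid(coords, coords)
    dist = np.hypot(dx, dy)
    inner = radius * 0.8
    rim = np.where(dist >= inner, amplitude, 0.0)
    rim = rim * np.clip(radius + 0.5 - dist, 0.0, 1.0)
    return [float(np.sum(np.abs(s) * rim)) for s in sectors]


@dataclass
class MatchedFilterDetector(DetectorInterface):
    """Rotational matched filter for annular debris with radial optic axis.

    The colormap is inverted to the background-subtracted, doubled-angle
    orientation field ``(v - v_floor)_+ * exp(2i * hue)`` and correlated
    against ring templates ``exp(2i psi)`` at each candidate scale.  At a
    debris center every pixel phase matches the template phase, so the
    correlation approaches the weighted rim mass of an ideal annulus with
    phase zero.  Fiber streaks are rejected twice over: a ring centered
    *on* a ridge responds with the opposite phase (the optic axis is
    perpendicular to the ridge, putting its second-harmonic modulation at
    exactly pi), and a ring tangent to a ridge lights only two opposite
    angular sectors.  The template is therefore split into sector kernels
    (quadrants; octants once the radius affords ~2 px of arc per sector)
    and the confidence is the *minimum* sector response (real part,
    normalized by the ideal-annulus sector response, clipped to [0, 1]):
    only a full radial annulus drives every sector positive at once.

    A color rotation multiplies the field by a global unit phase, which
    shifts the correlation phase; robustness to it is recovered exactly by
    test-time augmentation over the three color rotations (the stated
    purpose of that augmentation), rather than baked into the statistic.

    Frozen state: ``scales`` (ring radii, px), ``rim_retardance`` and
    ``threshold`` (calibrated from annotated training patches by
    :func:`train_reference_detector`), ``v_floor`` (background retardance
    subtracted before correlation).
    """

    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    rim_retardance: float = 0.8
    threshold: float = 0.5
    v_floor: float = 0.15
    ring_halfwidth: float = 1.0
    local_nms_iou: float = 0.4
    max_peaks_per_scale: int = 64
    dot_channel: bool = True
    #: separate decision threshold for the dot channel, whose raw scores
    #: saturate lower than the ring channels'; > 1 disables the channel
    dot_threshold: float = 0.5
    #: emit confidences rescaled so each channel's decision boundary maps
    #: to 0.5 (raw scores are not comparable across channels); training
    #: probes disable this to sweep thresholds in raw-score space
    calibrate_confidence: bool = True

    def score_maps(self, patch: np.ndarray) -> list[np.ndarray]:
        """Per-scale confidence maps (same shape as the patch)."""
        value, u = _rgb_to_fields(patch)
        damp = np.clip(value - self.v_floor, 0.0, None) / np.maximum(value, 1e-9)
        u = u * damp
        amplitude = max(self.rim_retardance - self.v_floor, 0.05)
        value_floored = np.abs(u)
        maps = []
        for r in self.scales:
            sectors, weight = _ring_kernels(r, self.ring_halfwidth)
            ideals = _ideal_sector_responses(r, self.ring_halfwidth, amplitude)
            conf = None
            for sector, ideal in zip(sectors, ideals):
                # correlation == convolution with conjugated, flipped kernel
                kern = np.conj(sector)[::-1, ::-1]
                num = fftconvolve(u, kern, mode="same")
                score = num.real / max(ideal, 1e-9)
                conf = score if conf is None else np.minimum(conf, score)
            # orientation diversity: a radial annulus contains every optic-
            # axis direction, so its doubled-angle mean over the ring
            # vanishes; fiber clutter (single ridges, flanks, gratings of
            # near-parallel fibers) is orientation-coherent no matter how
            # its brightness is arranged, and is suppressed here
            wk = weight[::-1, ::-1]
            mean_u = fftconvolve(u, wk, mode="same")
            mass = fftconvolve(value_floored, wk, mode="same")
            coherence = np.abs(mean_u) / np.maximum(mass, 1e-9)
            diversity = np.clip((1.0 - coherence) / 0.5, 0.0, 1.0)
            maps.append(np.clip(conf * diversity, 0.0, 1.0))
        return maps

    def dot_map(self, patch: np.ndarray) -> np.ndarray:
        """Contrast score for sub-resolution (1-2 px) debris dots.

        Ring templates need a resolvable annulus; the smallest debris is
        a bright isolated pixel or two.  The score is the minimum over
        four angular quadrants of (center brightness - quadrant ring
        brightness), normalized by the calibrated rim amplitude: an
        isolated dot is brighter than *all four* quadrants around it,
        while a pixel on (or at the end of) a fiber always has at least
        one bright quadrant.
        """
        value = np.max(np.asarray(patch, dtype=float), axis=-1)
        bright = np.clip(value - self.v_floor, 0.0, None)
        amplitude = max(self.rim_retardance - self.v_floor, 0.05)
        sectors, _ = _ring_kernels(1.5, 0.75)
        conf = None
        for sector in sectors:
            w = np.abs(sector)[::-1, ::-1]
            mean_k = fftconvolve(bright, w, mode="same") / w.sum()
            score = (bright - mean_k) / amplitude
            conf = score if conf is None else np.minimum(conf, score)
        return np.clip(conf, 0.0, 1.0)

    def predict(self, patch, origin=(0, 0)):
        h, w = patch.shape[:2]
        value = np.max(np.asarray(patch, dtype=float), axis=-1)
        bright = np.clip(value - self.v_floor, 0.0, None)
        raw: list[Detection] = []
        scored = [(r, m, self.threshold) for r, m in zip(self.scales, self.score_maps(patch))]
        if self.dot_channel and self.dot_threshold <= 1.0:
            scored.append((0.5, self.dot_map(patch), self.dot_threshold))
        for r, conf, thr in scored:
            peaks = (conf >= thr) & (
                conf >= ndimage.maximum_filter(conf, size=3, mode="nearest")
            )
            ys, xs = np.nonzero(peaks)
            if ys.size > self.max_peaks_per_scale:
                top = np.argsort(conf[ys, xs])[::-1][: self.max_peaks_per_scale]
                ys, xs = ys[top], xs[top]
            side = 2.0 * r + 1.0
            for py, px in zip(ys, xs):
                box = self._refine_box(bright, px, py, r) or BoundingBox(
                    px - side / 2.0, py - side / 2.0, side, side
                )
                box = box.clip(w, h)
                if box is None:
                    continue
                c = float(conf[py, px])
                if self.calibrate_confidence:
                    c = 0.5 + 0.5 * (c - thr) / max(1.0 - thr, 1e-9)
                raw.append(Detection(box, float(np.clip(c, 0.0, 1.0))))
        return self._merge_scales(raw)

    def _refine_box(
        self, bright: np.ndarray, px: int, py: int, r: float
    ) -> "BoundingBox | None":
        """Tighten the template box to the bright footprint near the peak.

        Sub-resolution debris renders as one or two bright pixels; the
        fixed ``2r+1`` template box then badly over-covers it.  The box is
        replaced by the bounding box of above-threshold pixels inside a
        window of ~the ring extent around the peak.
        """
        win = int(np.ceil(r + 2))
        y0, y1 = max(0, py - win), min(bright.shape[0], py + win + 1)
        x0, x1 = max(0, px - win), min(bright.shape[1], px + win + 1)
        sub = bright[y0:y1, x0:x1]
        mask = sub >= 0.4 * max(sub.max(), 1e-9)
        if not mask.any():
            return None
        ys, xs = np.nonzero(mask)
        return BoundingBox(
            float(x0 + xs.min()),
            float(y0 + ys.min()),
            float(xs.max() - xs.min() + 1),
            float(ys.max() - ys.min() + 1),
        )

    def _merge_scales(self, raw: list[Detection]) -> list[Detection]:
        """Cross-scale merge: IoU NMS plus containment suppression.

        A small-scale response centered inside an already-kept (larger)
        box is the same object seen at the wrong scale; plain IoU cannot
        catch it (a 3 px box inside an 11 px box has IoU ~0.07).  Ties in
        confidence are broken toward the larger scale, whose ring actually
        matched the rim.  Vectorized greedy pass (candidate lists can run
        to thousands on texture-heavy patches at low thresholds).
        """
        if not raw:
            return []
        order = sorted(range(len(raw)), key=lambda i: (-raw[i].confidence, -raw[i].box.area))
        boxes = np.array(
            [
                (raw[i].box.x, raw[i].box.y, raw[i].box.x2, raw[i].box.y2)
                for i in order
            ]
        )
        centers = np.array([raw[i].box.center for i in order])
        areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
        alive = np.ones(len(order), dtype=bool)
        kept: list[Detection] = []
        for i in range(len(order)):
            if not alive[i]:
                continue
            kept.append(raw[order[i]])
            rest = alive.copy()
            rest[: i + 1] = False
            if not rest.any():
                break
            bx = boxes[i]
            ix = np.maximum(
                0.0,
                np.minimum(bx[2], boxes[rest, 2]) - np.maximum(bx[0], boxes[rest, 0]),
            )
            iy = np.maximum(
                0.0,
                np.minimum(bx[3], boxes[rest, 3]) - np.maximum(bx[1], boxes[rest, 1]),
            )
            inter = ix * iy
            union = areas[i] + areas[rest] - inter
            overlap = inter / np.maximum(union, 1e-12)
            inside = (
                (centers[rest, 0] >= bx[0])
                & (centers[rest, 0] <= bx[2])
                & (centers[rest, 1] >= bx[1])
                & (centers[rest, 1] <= bx[3])
            )
            kill = overlap >= self.local_nms_iou
            kill |= inside
            idx = np.nonzero(rest)[0]
            alive[idx[kill]] = False
        return kept


def train_reference_detector(
    training_patches: list[tuple[np.ndarray, list[BoundingBox]]],
    config: TrainConfig | None = None,
    match_iou: float = 0.3,
    precision_floor: float | None = None,
) -> tuple[MatchedFilterDetector, dict]:
    """Fit the matched-filter reference detector on annotated patches.

    "Training" here is closed-form calibration: object scales are taken
    from the annotated box-size distribution, the rim retardance from the
    brightness inside boxes, and the confidence threshold is selected to
    maximize F1 (matching at IoU ``match_iou``) over the training patches.
    Deterministic given the inputs.  Returns the frozen detector and a
    training log (schedule echo, threshold sweep, chosen operating point).
    """
    from .stats import match_detections  # local import avoids a cycle

    config = config or TrainConfig()
    all_boxes = [b for _, boxes in training_patches for b in boxes]
    if not all_boxes:
        raise ValueError("training set contains no positive boxes")

    radii = np.array([max(b.width, b.height) / 2.0 for b in all_boxes])
    lo = max(1.0, float(np.floor(np.quantile(radii, 0.02))))
    hi = max(lo, float(np.ceil(np.quantile(radii, 0.98))))
    # half-integer steps below r=3: small objects fall between coarse rings
    fine = np.arange(lo, min(hi, 3.0) + 1e-9, 0.5)
    coarse = np.arange(np.ceil(min(hi, 3.0)) + 1, hi + 1e-9, 1.0)
    scales = tuple(np.concatenate([fine, coarse]).tolist())[:10]

    rims = []
    for patch, boxes in training_patches:
        value = np.max(np.asarray(patch, dtype=float), axis=-1)
        for b in boxes:
            y0, y1 = int(max(0, b.y)), int(min(patch.shape[0], np.ceil(b.y2)))
            x0, x1 = int(max(0, b.x)), int(min(patch.shape[1], np.ceil(b.x2)))
            if y1 > y0 and x1 > x0:
                rims.append(value[y0:y1, x0:x1].max())
    rim = float(np.median(rims)) if rims else 0.8

    # probes emit everything above the sweep floor; the peak cap must be
    # generous or marginal false positives get crowded out of the probe
    # output and the low-threshold precision estimates become optimistic
    sweep_floor = 0.26
    probe_ring = MatchedFilterDetector(
        scales=scales,
        rim_retardance=rim,
        threshold=sweep_floor,
        dot_threshold=2.0,
        calibrate_confidence=False,
        max_peaks_per_scale=512,
    )
    probe_dot = MatchedFilterDetector(
        scales=(),
        rim_retardance=rim,
        threshold=sweep_floor,
        dot_threshold=sweep_floor,
        calibrate_confidence=False,
        max_peaks_per_scale=512,
    )
    ring_dets = [probe_ring.predict(patch) for patch, _ in training_patches]
    dot_dets = [probe_dot.predict(patch) for patch, _ in training_patches]
    gt_boxes = [boxes for _, boxes in training_patches]

    def f_score(det_lists: list[list[Detection]]) -> dict:
        tp = fp = fn = 0
        for dets, boxes in zip(det_lists, gt_boxes):
            m = match_detections(dets, boxes, match_iou)
            tp += len(m.pairs)
            fp += len(m.unmatched_pred)
            fn += len(m.unmatched_gt)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return {"precision": prec, "recall": rec, "f1": f1}

    thresholds = np.round(np.arange(sweep_floor, 0.99, 0.04), 3)

    def pick(sweep: list[dict]) -> dict:
        """Operating point selection on the training sweep.

        Default: the F1 maximum (ties toward the higher, more precise
        threshold).  With ``precision_floor`` set, instead the highest
        recall whose training precision clears the floor.
        """
        if precision_floor is not None:
            ok = [
                r for r in sweep if r["precision"] >= precision_floor and r["recall"] > 0
            ]
            if ok:
                return max(ok, key=lambda r: (r["recall"], r["precision"]))
        return max(sweep, key=lambda r: (r["f1"], r["threshold"]))

    ring_sweep = []
    for thr in thresholds:
        row = f_score(
            [[d for d in dets if d.confidence >= thr] for dets in ring_dets]
        )
        ring_sweep.append({"threshold": float(thr), **row})
    best_ring = pick(ring_sweep)
    kept_ring = [
        [d for d in dets if d.confidence >= best_ring["threshold"]]
        for dets in ring_dets
    ]

    def outside_ring(dot: Detection, rings: list[Detection]) -> bool:
        cx, cy = dot.box.center
        return not any(
            k.box.x <= cx <= k.box.x2 and k.box.y <= cy <= k.box.y2 for k in rings
        )

    # the dot channel (sub-resolution debris) saturates lower: own sweep,
    # with the ring operating point held fixed
    dot_sweep = []
    for thr in thresholds:
        combined = [
            rings + [d for d in dots if d.confidence >= thr and outside_ring(d, rings)]
            for rings, dots in zip(kept_ring, dot_dets)
        ]
        dot_sweep.append({"threshold": float(thr), **f_score(combined)})
    best_dot = pick(dot_sweep)
    if (
        best_dot["recall"] <= best_ring["recall"]
        or best_dot["precision"] < best_ring["precision"] - 0.05
    ):
        best_dot = {**best_ring, "threshold": 2.0}  # channel off: no gain

    detector = replace(
        probe_ring,
        threshold=best_ring["threshold"],
        dot_threshold=best_dot["threshold"],
        calibrate_confidence=True,
        max_peaks_per_scale=64,
    )
    best = best_dot if best_dot["threshold"] <= 1.0 else best_ring
    log = {
        "schedule": {
            "epochs": config.epochs,
            "initial_lr": config.initial_lr,
            "lr_decay": config.lr_decay,
            "lr_decay_every": config.lr_decay_every,
            "batch_size": config.batch_size,
            "seed": config.seed,
        },
        "n_patches": len(training_patches),
        "n_boxes": len(all_boxes),
        "scales": list(scales),
        "rim_retardance": rim,
        "ring_sweep": ring_sweep,
        "dot_sweep": dot_sweep,
        "operating_point": {
            "threshold": best_ring["threshold"],
            "dot_threshold": best_dot["threshold"],
            **{k: best[k] for k in ("precision", "recall", "f1")},
        },
    }
    return detector, log


# ---------------------------------------------------------------------------
# NMS and sliced inference


def nms(detections: list[Detection], iou_thr: float = 0.5) -> list[Detection]:
    """Greedy non-max suppression: keep the highest-confidence box among
    overlapping detections, suppress the rest, repeat."""
    ordered = sorted(detections, key=lambda d: -d.confidence)
    kept: list[Detection] = []
    for det in ordered:
        if all(iou(det.box, k.box) < iou_thr for k in kept):
            kept.append(det)
    return kept


@dataclass
class InferenceResult:
    detections: list[Detection]
    n_tiles: int
    failed_tiles: list[tuple[int, str]] = field(default_factory=list)


def sliced_inference(
    image: np.ndarray,
    detector: DetectorInterface,
    tiling: TilingConfig | None = None,
    tta: bool = False,
    nms_iou: float = 0.5,
    confidence_thr: float = 0.25,
    tta_geoms: tuple[str, ...] = GEOM_VARIANTS,
    tta_colors: tuple[int, ...] = (0, 1, 2),
) -> InferenceResult:
    """Run a per-patch detector over a large image with overlapping tiles.

    For every tile (and, with ``tta``, every geometric x color-rotation
    variant) the detector runs on the transformed patch; returned boxes
    are mapped back through the inverse geometric transform and the tile
    origin, accumulated globally, filtered at ``confidence_thr`` and
    merged with a single greedy NMS at ``nms_iou``.  A detector failure on
    a tile skips that tile and is reported in the result.

    Detections whose center falls in a tile's overlap margin are dropped
    (unless that tile edge is the image border): with >= 50% overlap every
    object is seen well inside some tile, and the margin copies are the
    ones distorted by kernel truncation at tile edges.
    """
    tiling = tiling or TilingConfig()
    t = tiling.tile_px
    variants: list[tuple[str, int]] = (
        [(g, k) for g in tta_geoms for k in tta_colors] if tta else [("identity", 0)]
    )
    origins = tile_origins(image.shape[0], image.shape[1], tiling)
    margin = (t - tiling.stride) / 2.0 if tiling.overlap_frac > 0 else 0.0
    h_img, w_img = image.shape[0], image.shape[1]
    accumulated: list[Detection] = []
    failed: list[tuple[int, str]] = []
    for tile_idx, (x0, y0) in enumerate(origins):
        patch = image[y0 : y0 + t, x0 : x0 + t]
        try:
            for geom, k in variants:
                warped = transform_patch(color_rotate(patch, k), geom)
                inv = invert_geom(geom)
                for det in detector.predict(warped, origin=(x0, y0)):
                    local = transform_box(det.box, inv, t)
                    cx, cy = local.center
                    if (
                        (cx < margin and x0 > 0)
                        or (cx > t - margin and x0 + t < w_img)
                        or (cy < margin and y0 > 0)
                        or (cy > t - margin and y0 + t < h_img)
                    ):
                        continue
                    box = local.translate(x0, y0)
                    clipped = box.clip(w_img, h_img)
                    if clipped is None:
                        continue
                    accumulated.append(
                        Detection(
                            clipped,
                            det.confidence,
                            source_tile=tile_idx,
                            tta_variant=f"{geom}|color{k}",
                        )
                    )
        except Exception as exc:  # noqa: BLE001 - tile isolation by design
            failed.append((tile_idx, repr(exc)))
    retained = [d for d in accumulated if d.confidence >= confidence_thr]
    return InferenceResult(
        detections=nms(retained, nms_iou),
        n_tiles=len(origins),
        failed_tiles=failed,
    )
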