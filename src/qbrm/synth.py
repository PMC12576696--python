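"""Synthetic qBRM sections, polarization stacks and multi-animal cohorts.

Emulates the study system end to end so every downstream stage is testable
without external data: a corpus-callosum-like tract of coherently oriented
myelinated fibers, sparse "vesiculated" debris objects (1-10 um annuli
whose optic axis points radially outward, the signature of a myelin sphere
with no remaining axon), multi-angle polarization acquisition with shot/
read noise, and whole cohorts whose per-section debris density follows a
unimodal rostro-caudal damage profile with between-animal variability.

Because myelin's birefringent lipid layers wrap *around* the axon, the
optic axis of an intact fiber is perpendicular to the fiber direction;
fiber streaks therefore carry orientation = streak direction + 90 deg,
while debris carries the radial field.

All randomness flows from explicit seeds.  Cohort sections draw their
seeds from ``SeedSequence([cohort_seed, animal_index, section_index])`` so
each section is independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PolarizationStack, forward_intensity
from .detect import BoundingBox
from .quantify import ROI

__all__ = [
    "SectionSimConfig",
    "SectionTruth",
    "CohortSpec",
    "Cohort",
    "generate_section_truth",
    "generate_polarization_stack",
    "generate_cohort",
    "section_seed",
]

#: physically sensible debris-size limits (um); outside this the annulus
#: model stops making sense at ~1 um/px sampling
_DEBRIS_DIAMETER_LIMITS = (0.5, 20.0)


@dataclass
class SectionSimConfig:
    """Parameters of one simulated tract section.

    Defaults model the study's imaging regime: ~1 um pixels (10x), debris
    diameters uniform on 1-10 um, four illumination polarization angles,
    and a coherently oriented tract with mild orientation jitter.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    pixel_size_um: float = 1.0
    fiber_orientation_deg: float = 0.0
    fiber_orientation_jitter_deg: float = 6.0
    fiber_density: float = 0.3
    debris_density_per_mm2: float = 20.0
    debris_diameter_um_range: tuple[float, float] = (1.0, 10.0)
    noise_sd_frac: float = 0.02
    illumination_angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        lo, hi = self.debris_diameter_um_range
        if not (_DEBRIS_DIAMETER_LIMITS[0] <= lo <= hi <= _DEBRIS_DIAMETER_LIMITS[1]):
            raise ValueError(
                f"debris diameters must lie within {_DEBRIS_DIAMETER_LIMITS} um"
            )
        if self.fiber_density < 0 or self.debris_density_per_mm2 < 0:
            raise ValueError("densities must be >= 0")
        if not (0.0 <= self.fiber_density <= 1.0):
            raise ValueError("fiber_density must be in [0, 1]")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")
        angles = np.mod(np.asarray(self.illumination_angles_deg, float), 180.0)
        if len(angles) < 3:
            raise ValueError("need >= 3 illumination angles")
        srt = np.sort(angles)
        if np.min(np.diff(srt)) < 1e-9 or (180.0 - (srt[-1] - srt[0])) < 1e-9:
            raise ValueError("illumination angles must be distinct modulo 180")
        max_diam_px = hi / self.pixel_size_um
        if min(self.image_height_px, self.image_width_px) < max_diam_px + 2:
            raise ValueError(
                "image too small to hold one debris object at max diameter"
            )

    @property
    def area_mm2(self) -> float:
        return (
            self.image_height_px
            * self.image_width_px
            * (self.pixel_size_um / 1000.0) ** 2
        )


@dataclass
class SectionTruth:
    """Ground truth for one simulated section."""

    retardance_field: np.ndarray
    orientation_field_deg: np.ndarray
    debris_boxes: list[BoundingBox]
    roi: ROI
    manifest: dict

    def __post_init__(self) -> None:
        h, w = self.retardance_field.shape
        for box in self.debris_boxes:
            if box.x < 0 or box.y < 0 or box.x2 > w or box.y2 > h:
                raise ValueError(f"debris box {box} outside image bounds")
        if not np.all(np.isfinite(self.retardance_field)):
            raise ValueError("retardance field must be finite")
        if not np.all(np.isfinite(self.orientation_field_deg)):
            raise ValueError("orientation field must be finite")


# fixed rendering choices (documented in the methods note): background
# retardance, fiber amplitude range, debris rim amplitude, rim geometry
_BACKGROUND_RET = 0.03
_FIBER_AMP = (0.45, 0.70)
_FIBER_SIGMA = (0.8, 1.6)
_RIM_AMP = (0.80, 0.95)
_CORE_FRAC = 0.3  # core retardance relative to rim
_RIM_WIDTH_FRAC = 0.2  # rim width as a fraction of the radius


def _render_fibers(
    ret: np.ndarray, ori: np.ndarray, config: SectionSimConfig, rng: np.random.Generator
) -> None:
    """Paint anti-aliased fiber streaks with Gaussian cross-profile.

    Fibers are straight segments crossing the frame along the tract axis
    (+/- jitter); streaks are added until the target area fraction is
    covered.  The optic axis carried by a streak is perpendicular to it.
    """
    h, w = ret.shape
    if config.fiber_density <= 0:
        return
    target = config.fiber_density * h * w
    covered = np.zeros((h, w), dtype=bool)
    strength = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    diag = float(np.hypot(h, w))
    max_fibers = int(20 + 4 * target / max(diag, 1.0))
    for _ in range(max_fibers):
        if covered.sum() >= target:
            break
        theta = rng.normal(config.fiber_orientation_deg, config.fiber_orientation_jitter_deg)
        ux, uy = np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        half_len = 0.5 * diag * rng.uniform(0.6, 1.4)
        sigma = rng.uniform(*_FIBER_SIGMA)
        amp = rng.uniform(*_FIBER_AMP)
        # signed distance to the fiber axis and longitudinal coordinate
        dx, dy = xx - cx, yy - cy
        longi = dx * ux + dy * uy
        perp = -dx * uy + dy * ux
        profile = amp * np.exp(-0.5 * (perp / sigma) ** 2)
        profile *= np.clip((half_len - np.abs(longi)) / 3.0 + 1.0, 0.0, 1.0)
        stronger = profile > strength
        strength[stronger] = profile[stronger]
        ori[stronger] = (theta + 90.0) % 180.0
        covered |= profile > 0.25 * amp
    np.maximum(ret, strength, out=ret)


def _render_debris(
    ret: np.ndarray, ori: np.ndarray, config: SectionSimConfig, rng: np.random.Generator
) -> list[BoundingBox]:
    """Paint annular debris with a radially varying optic axis.

    Each object: bright rim (width 20% of radius), dim core, ~1 px soft
    outer edge; orientation at offset (dx, dy) from the center is the
    polar angle, i.e. the optic axis points radially outward.  Returns
    one tight bounding box per object (from the rendered footprint).
    """
    h, w = ret.shape
    count = rng.poisson(config.debris_density_per_mm2 * config.area_mm2)
    lo_um, hi_um = config.debris_diameter_um_range
    boxes: list[BoundingBox] = []
    for _ in range(count):
        diam_px = rng.uniform(lo_um, hi_um) / config.pixel_size_um
        r = diam_px / 2.0
        margin = r + 1.0
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        rim_amp = rng.uniform(*_RIM_AMP)
        ext = int(np.ceil(r + 1.5))
        x0, x1 = int(np.floor(cx)) - ext, int(np.floor(cx)) + ext + 1
        y0, y1 = int(np.floor(cy)) - ext, int(np.floor(cy)) + ext + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        dx, dy = xx - cx, yy - cy
        dist = np.hypot(dx, dy)
        inner = r * (1.0 - _RIM_WIDTH_FRAC)
        profile = np.where(dist <= inner, _CORE_FRAC * rim_amp, rim_amp)
        # ~1 px anti-aliased outer edge
        profile = profile * np.clip(r + 0.5 - dist, 0.0, 1.0)
        footprint = profile >= 0.5 * rim_amp * np.clip(r, 0.0, 1.0)
        if not footprint.any():
            # sub-pixel object: light the nearest pixel
            iy, ix = np.unravel_index(np.argmin(dist), dist.shape)
            footprint = np.zeros_like(profile, dtype=bool)
            footprint[iy, ix] = True
            profile[iy, ix] = max(profile[iy, ix], 0.5 * rim_amp)
        radial = np.mod(np.rad2deg(np.arctan2(dy, dx)), 180.0)
        paint = profile > ret[y0:y1, x0:x1]
        region_ret = ret[y0:y1, x0:x1]
        region_ori = ori[y0:y1, x0:x1]
        region_ret[paint] = profile[paint]
        # the whole vesicle (rim and core) carries the radial optic axis,
        # which identifies the object even where a fiber is brighter
        disk = dist <= r + 0.5
        region_ori[disk | footprint] = radial[disk | footprint]
        ys, xs = np.nonzero(footprint)
        bx0, bx1 = x0 + xs.min(), x0 + xs.max() + 1
        by0, by1 = y0 + ys.min(), y0 + ys.max() + 1
        boxes.append(BoundingBox(float(bx0), float(by0), float(bx1 - bx0), float(by1 - by0)))
    return boxes


def generate_section_truth(config: SectionSimConfig) -> SectionTruth:
    """Simulate one tract section: fields, debris boxes, ROI, manifest."""
    h, w = config.image_height_px, config.image_width_px
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    ret = np.full((h, w), _BACKGROUND_RET)
    ori = rng.uniform(0.0, 180.0, size=(h, w))  # isotropic background noise
    _render_fibers(ret, ori, config, rng)
    boxes = _render_debris(ret, ori, config, rng)
    roi = ROI(
        polygon=[(0.0, 0.0), (float(w), 0.0), (float(w), float(h)), (0.0, float(h))],
        pixel_size_um=config.pixel_size_um,
    )
    manifest = {
        "realized_count": len(boxes),
        "seed": int(config.seed),
        "config": dataclasses.asdict(config),
    }
    return SectionTruth(ret, ori, boxes, roi, manifest)


def generate_polarization_stack(
    truth: SectionTruth, config: SectionSimConfig, i0: float = 1.0
) -> PolarizationStack:
    """Forward-model the multi-angle acquisition of a simulated section.

    One frame per illumination angle via the Jones-calculus intensity
    model, plus additive Gaussian noise with s.d. ``noise_sd_frac`` times
    the mean intensity (clipped at zero, as a camera would).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    frames = np.stack(
        [
            forward_intensity(
                truth.retardance_field, truth.orientation_field_deg, ang, i0
            )
            for ang in config.illumination_angles_deg
        ]
    )
    if config.noise_sd_frac > 0:
        sd = config.noise_sd_frac * frames.mean()
        frames = np.clip(frames + rng.normal(0.0, sd, size=frames.shape), 0.0, None)
    return PolarizationStack(
        frames=frames,
        angles_deg=np.asarray(config.illumination_angles_deg, float),
        i0=i0,
        pixel_size_um=config.pixel_size_um,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """A multi-group, multi-animal serial-section experiment.

    ``groups`` lists ``(label, n_animals, mean_peak_density_per_mm2,
    between_animal_cv)``.  Each animal's peak density is the group mean
    times a lognormal multiplier (unit mean, the stated CV); per-section
    expected density follows a Gaussian rostro-caudal damage bump of
    full-width ``profile_fwhm_um`` centered at ``profile_peak_um`` plus a
    per-animal anatomical offset (s.d. ``peak_jitter_um``), on top of
    ``baseline_density_per_mm2``.
    """

    groups: list[tuple[str, int, float, float]] = field(
        default_factory=lambda: [
            ("6wk", 4, 40.0, 0.3),
            ("12wk", 4, 8.0, 0.3),
            ("control", 3, 5.0, 0.3),
        ]
    )
    sections_per_animal: int = 10
    section_spacing_um: float = 600.0
    profile_peak_um: float = 0.0
    profile_fwhm_um: float = 1800.0
    peak_jitter_um: float = 300.0
    baseline_density_per_mm2: float = 1.0
    section_area_mm2: float = 5.0
    seed: int = 0
    section_template: SectionSimConfig | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("empty group list")
        for label, n, dens, cv in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} needs n_animals >= 1")
            if dens < self.baseline_density_per_mm2:
                raise ValueError(
                    f"group {label!r} peak density below baseline density"
                )
            if cv < 0:
                raise ValueError("between_animal_cv must be >= 0")
        if self.section_spacing_um <= 0:
            raise ValueError("section_spacing_um must be > 0")
        if self.sections_per_animal < 1:
            raise ValueError("sections_per_animal must be >= 1")
        if self.section_area_mm2 <= 0:
            raise ValueError("section_area_mm2 must be > 0")


@dataclass
class Cohort:
    """Generated cohort: manifest of all true values, plus (optionally)
    full per-section image truths keyed by (animal_id, section_id)."""

    manifest: pd.DataFrame
    sections: dict[tuple[str, int], SectionTruth] | None = None


def section_seed(cohort_seed: int, animal_index: int, section_index: int) -> int:
    """Deterministic per-section seed derived from the cohort seed."""
    ss = np.random.SeedSequence([int(cohort_seed), int(animal_index), int(section_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal draw with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    sigma2 = np.log1p(cv**2)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2)))


def generate_cohort(spec: CohortSpec, mode: str = "fast") -> Cohort:
    """Simulate a cohort of animals with serial sections along the lesion.

    ``mode="fast"`` draws realized per-section debris counts directly from
    the Poisson law (no images); ``mode="images"`` additionally renders a
    full :class:`SectionTruth` per section with the section's expected
    debris density, using ``spec.section_template`` for imaging
    parameters.
    """
    if mode not in ("fast", "images"):
        raise ValueError(f"unknown mode {mode!r}")
    sigma = spec.profile_fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    rows = []
    sections: dict[tuple[str, int], SectionTruth] = {}
    animal_index = 0
    for label, n_animals, mean_density, cv in spec.groups:
        for _ in range(n_animals):
            animal_id = f"{label}_{animal_index:02d}"
            arng = np.random.default_rng(
                np.random.SeedSequence([int(spec.seed), animal_index])
            )
            peak_density = mean_density * _lognormal_multiplier(arng, cv)
            peak_density = max(peak_density, spec.baseline_density_per_mm2)
            peak_pos = spec.profile_peak_um + (
                arng.normal(0.0, spec.peak_jitter_um) if spec.peak_jitter_um > 0 else 0.0
            )
            n_sec = spec.sections_per_animal
            positions = (np.arange(n_sec) - (n_sec - 1) / 2.0) * spec.section_spacing_um
            for s_idx, pos in enumerate(positions):
                expected = spec.baseline_density_per_mm2 + (
                    peak_density - spec.baseline_density_per_mm2
                ) * np.exp(-0.5 * ((pos - peak_pos) / sigma) ** 2)
                seed = section_seed(spec.seed, animal_index, s_idx)
                if mode == "fast":
                    srng = np.random.default_rng(seed)
                    count = int(srng.poisson(expected * spec.section_area_mm2))
                    area = spec.section_area_mm2
                else:
                    template = spec.section_template or SectionSimConfig()
                    cfg = dataclasses.replace(
                        template, debris_density_per_mm2=float(expected), seed=seed
                    )
                    truth = generate_section_truth(cfg)
                    sections[(animal_id, s_idx)] = truth
                    count = truth.manifest["realized_count"]
                    area = truth.roi.area_mm2
                rows.append(
                    {
                        "group": label,
                        "animal_id": animal_id,
                        "section_id": s_idx,
                        "position_um": float(pos),
                        "true_density_per_mm2": float(expected),
                        "realized_count": count,
                        "realized_density_per_mm2": count / area,
                        "section_area_mm2": area,
                        "true_peak_um": float(peak_pos),
                        "animal_peak_density_per_mm2": float(peak_density),
                        "seed": seed,
                    }
                )
            animal_index += 1
    manifest = pd.DataFrame(rows)
    return Cohort(manifest=manifest, sections=sections if mode == "images" else None)
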