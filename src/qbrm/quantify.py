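"""ROI-normalized defect densities and rostro-caudal damage profiles.

Detections are reduced to one number per tissue section — debris count per
mm^2 inside a manually drawn region of interest (the corpus callosum) —
then ordered along the rostro-caudal axis and normalized so that the
maximum-damage section of each animal sits at position 0, which aligns
animals with different lesion projections before group comparison.
Positions are in micrometres, positive = anterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .detect import BoundingBox, Detection

__all__ = [
    "ROI",
    "SectionDensity",
    "DamageProfile",
    "filter_to_roi",
    "compute_density",
    "build_damage_profile",
    "summarize_max_damage",
    "sample_validation_regions",
    "densities_to_frame",
]


@dataclass
class ROI:
    """A region of interest: a simple polygon in pixel coordinates.

    ``area_mm2`` is derived from the polygon area (shoelace, via shapely)
    and the pixel pitch.  A binary mask may be given instead of a polygon,
    in which case the area is the pixel count.
    """

    polygon: list[tuple[float, float]] | None = None
    mask: np.ndarray | None = None
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.mask is None):
            raise ValueError("provide exactly one of polygon or mask")
        if self.polygon is not None:
            self._poly = shapely.Polygon(self.polygon)
            if not self._poly.is_valid or self._poly.is_empty:
                raise ValueError("polygon must be simple and non-degenerate")
            if self._poly.area <= 0:
                raise ValueError("polygon area must be > 0")
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                raise ValueError("mask is empty")
            self._poly = None

    @property
    def area_mm2(self) -> float:
        scale = (self.pixel_size_um / 1000.0) ** 2
        if self._poly is not None:
            return self._poly.area * scale
        return float(self.mask.sum()) * scale

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Membership test (boundary counts as inside for polygons)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self._poly is not None:
            return shapely.intersects_xy(self._poly, x, y)
        xi = np.clip(np.floor(x).astype(int), 0, self.mask.shape[1] - 1)
        yi = np.clip(np.floor(y).astype(int), 0, self.mask.shape[0] - 1)
        inside_frame = (x >= 0) & (y >= 0) & (x < self.mask.shape[1]) & (y < self.mask.shape[0])
        return inside_frame & self.mask[yi, xi]


@dataclass
class SectionDensity:
    """One section reduced to a single ROI-normalized defect density."""

    animal_id: str
    section_id: int
    position_um: float
    count: int
    roi_area_mm2: float

    def __post_init__(self) -> None:
        if self.roi_area_mm2 <= 0:
            raise ValueError("roi_area_mm2 must be > 0")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if not np.isfinite(self.position_um):
            raise ValueError("position must be finite")

    @property
    def density_per_mm2(self) -> float:
        return self.count / self.roi_area_mm2


@dataclass
class DamageProfile:
    """Per-animal damage profile, normalized to the maximum-damage plane."""

    animal_id: str
    group_label: str
    sections: list[SectionDensity]
    normalized_positions_um: np.ndarray
    max_density_per_mm2: float
    peak_position_um: float | None
    peak_tie: bool = False
    peak_undefined: bool = False


def filter_to_roi(detections: list[Detection], roi: ROI) -> list[Detection]:
    """Keep detections whose box *center* lies inside the ROI.

    The center-in criterion is unambiguous and count-stable for small
    objects: a box is either in or out, regardless of how much of its
    area straddles the boundary.
    """
    if not detections:
        return []
    centers = np.array([d.box.center for d in detections])
    keep = roi.contains_points(centers[:, 0], centers[:, 1])
    return [d for d, k in zip(detections, keep) if k]


def compute_density(
    detections: list[Detection],
    roi: ROI,
    animal_id: str = "",
    section_id: int = 0,
    position_um: float = 0.0,
) -> SectionDensity:
    """ROI-filter detections and normalize the count by the ROI area."""
    kept = filter_to_roi(detections, roi)
    return SectionDensity(
        animal_id=animal_id,
        section_id=section_id,
        position_um=position_um,
        count=len(kept),
        roi_area_mm2=roi.area_mm2,
    )


def build_damage_profile(
    sections: list[SectionDensity],
    animal_id: str | None = None,
    group_label: str = "",
) -> DamageProfile:
    """Order sections rostro-caudally and re-zero at the damage maximum.

    The argmax density section defines normalized position 0.  Ties are
    broken toward the most posterior (smallest position) section and
    flagged.  If every section has zero density the peak is undefined and
    normalization is skipped.
    """
    if len(sections) < 2:
        raise ValueError("need >= 2 sections to build a profile")
    ordered = sorted(sections, key=lambda s: s.position_um)
    positions = np.array([s.position_um for s in ordered])
    if len(np.unique(positions)) != len(positions):
        raise ValueError("section positions must be distinct")
    densities = np.array([s.density_per_mm2 for s in ordered])
    animal_id = animal_id if animal_id is not None else ordered[0].animal_id

    if np.all(densities == 0.0):
        return DamageProfile(
            animal_id=animal_id,
            group_label=group_label,
            sections=ordered,
            normalized_positions_um=positions.copy(),
            max_density_per_mm2=0.0,
            peak_position_um=None,
            peak_undefined=True,
        )
    max_density = densities.max()
    peak_candidates = np.nonzero(densities == max_density)[0]
    peak_idx = int(peak_candidates[0])  # sorted ascending: first = most posterior
    tie = len(peak_candidates) > 1
    peak_pos = float(positions[peak_idx])
    return DamageProfile(
        animal_id=animal_id,
        group_label=group_label,
        sections=ordered,
        normalized_positions_um=positions - peak_pos,
        max_density_per_mm2=float(max_density),
        peak_position_um=peak_pos,
        peak_tie=tie,
    )


def summarize_max_damage(
    profiles_by_group: dict[str, list[DamageProfile]],
) -> pd.DataFrame:
    """One row per animal: its peak density, grouped for statistics."""
    rows = []
    for group, profiles in profiles_by_group.items():
        if not profiles:
            warnings.warn(f"group {group!r} has no profiles; excluded", stacklevel=2)
            continue
        for prof in profiles:
            rows.append(
                {
                    "animal_id": prof.animal_id,
                    "group": group,
                    "max_density_per_mm2": prof.max_density_per_mm2,
                }
            )
    return pd.DataFrame(rows, columns=["animal_id", "group", "max_density_per_mm2"])


def sample_validation_regions(
    roi: ROI,
    fraction: float = 0.05,
    tile_px: int = 128,
    seed: int = 0,
) -> list[tuple[int, int, int, int]]:
    """Uniformly spaced tile-aligned rectangles covering ~``fraction`` of the ROI.

    Candidate tiles are the tile-aligned squares fully inside the ROI, in
    reading order; ``floor(fraction * roi_area / tile_area)`` of them are
    picked at even index spacing (a seeded cyclic start offset decorrelates
    repeated samplings).  Returns ``(x, y, w, h)`` rectangles in pixels.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    tile_area_mm2 = (tile_px * roi.pixel_size_um / 1000.0) ** 2
    if roi.area_mm2 < tile_area_mm2:
        raise ValueError("ROI smaller than one tile")
    if roi._poly is not None:
        minx, miny, maxx, maxy = roi._poly.bounds
    else:
        ys, xs = np.nonzero(roi.mask)
        minx, miny, maxx, maxy = xs.min(), ys.min(), xs.max() + 1, ys.max() + 1
    candidates = []
    for y in range(int(np.floor(miny)), int(np.ceil(maxy)) - tile_px + 1, tile_px):
        for x in range(int(np.floor(minx)), int(np.ceil(maxx)) - tile_px + 1, tile_px):
            if roi._poly is not None:
                if roi._poly.covers(shapely.box(x, y, x + tile_px, y + tile_px)):
                    candidates.append((x, y))
            else:
                if roi.mask[y : y + tile_px, x : x + tile_px].all():
                    candidates.append((x, y))
    if not candidates:
        raise ValueError("ROI cannot fit a single aligned tile")
    n_target = int(np.floor(fraction * roi.area_mm2 / tile_area_mm2))
    if n_target < 1:
        warnings.warn(
            "requested fraction smaller than one tile; sampling a single tile",
            stacklevel=2,
        )
        n_target = 1
    n = min(n_target, len(candidates))
    rng = np.random.default_rng(seed)
    start = int(rng.integers(len(candidates)))
    idx = (start + np.round(np.arange(n) * len(candidates) / n).astype(int)) % len(
        candidates
    )
    return [(candidates[i][0], candidates[i][1], tile_px, tile_px) for i in sorted(set(idx))]


def densities_to_frame(
    profiles_by_group: dict[str, list[DamageProfile]],
) -> pd.DataFrame:
    """Flatten profiles to the standard density CSV layout."""
    rows = []
    for group, profiles in profiles_by_group.items():
        for prof in profiles:
            for sec, npos in zip(prof.sections, prof.normalized_positions_um):
                rows.append(
                    {
                        "animal_id": prof.animal_id,
                        "group": group,
                        "section_id": sec.section_id,
                        "position_um": sec.position_um,
                        "normalized_position_um": float(npos),
                        "count": sec.count,
                        "roi_area_mm2": sec.roi_area_mm2,
                        "density_per_mm2": sec.density_per_mm2,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "group",
            "section_id",
            "position_um",
            "normalized_position_um",
            "count",
            "roi_area_mm2",
            "density_per_mm2",
        ],
    )
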