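"""Histological rim morphometry, BRL calling and semiquantitative scoring.

The interedge rim-width procedure resamples the outer myeloid-rim contour
at fixed arc-length intervals (100 um by default) and records, at every
sample, the shortest Euclidean distance to the inner (myelin) edge —
point-to-segment against the inner polyline, not point-to-vertex.  A
histological broad rim lesion (BRL) is a mixed active/inactive lesion
whose mean rim width reaches at least 1 mm.

Semiquantitative scores follow the standard neuropathology conventions:
remyelination 0-3 from the remyelinated area fraction, spinal cord
demyelination 0-5 in 20%-wide bins, cortical lesions as a per-block rate,
and the brain-stem lesion load as an area fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LinearRing, Point, Polygon

from .errors import (
    ContourError,
    GeometryError,
    NumericDomainError,
    SamplingError,
)

log = logging.getLogger("rimpet")

#: Fixed class vocabulary for 2D section label images.
SECTION_CLASSES = {
    "background": 0,
    "NAWM": 1,
    "lesion_core": 2,
    "myeloid_rim": 3,
    "remyelinated": 4,
    "cortex": 5,
}


@dataclass
class SectionImage2D:
    """A labelled 2D histology section with isotropic pixel size in um."""

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("SectionImage2D requires a 2D label array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        valid = set(SECTION_CLASSES.values())
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown section classes: {sorted(present - valid)}")

    def mask(self, name: str) -> np.ndarray:
        return self.labels == SECTION_CLASSES[name]


@dataclass
class Contour2D:
    """A closed, simple polyline in um coordinates."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError("contour points must be an (n, 2) array")
        # drop an explicit closing vertex; closure is implicit
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ContourError(f"contour needs >= 3 distinct points, got {len(pts)}")
        self.points = pts
        ring = LinearRing(pts)
        if not ring.is_valid or not ring.is_simple:
            raise ContourError("contour must be simple (non-self-intersecting)")

    @property
    def ring(self) -> LinearRing:
        return LinearRing(self.points)

    @property
    def perimeter(self) -> float:
        return float(self.ring.length)


@dataclass
class RimWidthProfile:
    """Interedge distances sampled along the outer rim edge."""

    sample_points: np.ndarray
    distances: np.ndarray
    mean_width: float
    n_samples: int
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("interedge distances must be non-negative")
        if self.valid is None:
            self.valid = np.ones(len(self.distances), dtype=bool)


@dataclass
class HistoScores:
    """Per-case semiquantitative histopathology summary."""

    remyelination_score: int
    demyelination_score: int
    cortical_lesion_rate: float
    brainstem_lesion_fraction: float

    def __post_init__(self) -> None:
        if self.remyelination_score not in range(4):
            raise ValueError("remyelination score must be 0-3")
        if self.demyelination_score not in range(6):
            raise ValueError("demyelination score must be 0-5")
        if not (0.0 <= self.brainstem_lesion_fraction <= 1.0):
            raise ValueError("brainstem lesion fraction must be in [0, 1]")


@dataclass
class CellCountResult:
    """Mean cell density over sampled visual fields in one ROI."""

    region: str
    n_fields: int
    density: float

    def __post_init__(self) -> None:
        if self.region not in ("center", "rim", "NAWM"):
            raise ValueError(f"unknown ROI {self.region!r}")
        if self.n_fields < 10:
            raise ValueError("protocol requires >= 10 visual fields per ROI")
        if self.density < 0:
            raise ValueError("density must be non-negative")


def resample_arc_length(contour: Contour2D, step: float) -> np.ndarray:
    """Sample points every `step` um of arc length, starting at vertex 0.

    Returns floor(perimeter / step) + 1 points at arc lengths
    0, step, 2*step, ... <= perimeter (the point at the full perimeter is
    the start vertex again and is not repeated).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    ring = contour.ring
    n = int(np.floor(ring.length / step))
    arcs = np.arange(n + 1) * step
    arcs = arcs[arcs < ring.length]  # avoid duplicating the start vertex
    pts = [ring.interpolate(float(s)) for s in arcs]
    return np.array([[p.x, p.y] for p in pts])


def interedge_rim_width(
    outer: Contour2D,
    inner: Contour2D,
    step: float = 100.0,
    valid_mask=None,
) -> RimWidthProfile:
    """Shortest distance from the outer to the inner edge every `step` um.

    Parameters
    ----------
    outer, inner : Contour2D
        Outer myeloid edge and inner myelin edge; `inner` must lie inside
        (or coincide with) `outer`.
    step : float
        Arc-length sampling interval along the outer edge, um.
    valid_mask : sequence of bool, optional
        Per-sample validity flags (borders that cannot be assigned
        unequivocally are excluded); invalid samples are dropped from the
        mean but kept in the profile.
    """
    outer_poly = Polygon(outer.points)
    inner_poly = Polygon(inner.points)
    if not outer_poly.covers(inner_poly):
        raise GeometryError("inner contour must lie inside the outer contour")
    samples = resample_arc_length(outer, step)
    inner_ring = inner.ring
    dists = np.array([inner_ring.distance(Point(x, y)) for x, y in samples])
    if valid_mask is None:
        valid = np.ones(len(dists), dtype=bool)
    else:
        valid = np.asarray(valid_mask, dtype=bool)
        if len(valid) != len(dists):
            raise ValueError(
                f"valid_mask length {len(valid)} != {len(dists)} samples"
            )
    if not valid.any():
        raise GeometryError("no valid samples remain on the outer contour")
    mean_width = float(dists[valid].mean())
    return RimWidthProfile(samples, dists, mean_width, len(dists), valid)


def call_brl(
    profile: RimWidthProfile,
    lesion_class: str,
    min_width: float = 1000.0,
    summary: str = "mean",
) -> bool:
    """Histological BRL call: a mixed lesion whose rim width reaches `min_width` um.

    `summary` selects the width statistic compared against the threshold:
    "mean" (default, matching the reported average rim sizes), "median",
    or "fraction_above" (true if >= half the samples exceed `min_width`).
    """
    if lesion_class not in ("mixed", "active", "inactive"):
        raise ValueError(f"unknown lesion class {lesion_class!r}")
    if min_width <= 0:
        raise ValueError("min_width must be positive")
    if lesion_class != "mixed":
        return False
    d = profile.distances[profile.valid]
    if summary == "mean":
        stat_ok = float(d.mean()) >= min_width
    elif summary == "median":
        stat_ok = float(np.median(d)) >= min_width
    elif summary == "fraction_above":
        stat_ok = float((d >= min_width).mean()) >= 0.5
    else:
        raise ValueError(f"unknown summary {summary!r}")
    return stat_ok


def remyelination_score(lesion_mask: np.ndarray, remyelinated_mask: np.ndarray) -> int:
    """Semiquantitative remyelination score 0-3 from area fractions.

    0: remyelination of <= 10% of the lesion area; 1: > 10% but <= 50%;
    2: > 50% but incompletely remyelinated; 3: (essentially) completely
    remyelinated, operationalised as >= 99% to tolerate pixelation.
    """
    lesion = np.asarray(lesion_mask) > 0
    remy = np.asarray(remyelinated_mask) > 0
    if not lesion.any():
        raise NumericDomainError("empty lesion mask")
    if (remy & ~lesion).any():
        raise NumericDomainError("remyelinated area must lie within the lesion")
    f = remy.sum() / lesion.sum()
    if f <= 0.10:
        return 0
    if f <= 0.50:
        return 1
    if f < 0.99:
        return 2
    return 3


def demyelination_score(demyelinated_fraction: float) -> int:
    """Spinal cord demyelination score 0-5 in 20%-wide bins.

    0 is reserved for exactly no demyelination; positive fractions bin as
    (0, 0.2] -> 1, (0.2, 0.4] -> 2, (0.4, 0.6] -> 3, (0.6, 0.8] -> 4,
    (0.8, 1.0] -> 5.
    """
    f = float(demyelinated_fraction)
    if not (0.0 <= f <= 1.0):
        raise NumericDomainError(f"fraction must be in [0, 1], got {f}")
    if f == 0.0:
        return 0
    return int(np.ceil(f / 0.2 - 1e-12))


def cell_density(
    points: np.ndarray,
    region_mask: np.ndarray,
    pixel_size: float,
    n_fields: int = 10,
    field_size: float = 500.0,
    region: str = "center",
    seed: int = 0,
) -> CellCountResult:
    """Mean cell density (cells/mm^2) over square visual fields in a ROI.

    `points` are cell coordinates in um; `region_mask` is the ROI on the
    section grid (`pixel_size` um/pixel); fields of side `field_size` um
    are placed uniformly at random with all four corners inside the ROI.
    Densities per field are count / field area; the result is their mean.
    """
    if n_fields < 10:
        raise ValueError("protocol requires >= 10 visual fields")
    mask = np.asarray(region_mask) > 0
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    half = field_size / 2.0
    if w * pixel_size < field_size or h * pixel_size < field_size:
        raise SamplingError(
            f"region ({h}x{w} px at {pixel_size} um) is smaller than one "
            f"{field_size} um field"
        )

    def inside(x_um: float, y_um: float) -> bool:
        i, j = int(y_um / pixel_size), int(x_um / pixel_size)
        return 0 <= i < h and 0 <= j < w and bool(mask[i, j])

    centers = []
    attempts = 0
    max_attempts = 20000
    while len(centers) < n_fields and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(half, w * pixel_size - half)
        y = rng.uniform(half, h * pixel_size - half)
        corners_ok = all(
            inside(x + dx, y + dy)
            for dx in (-half, half)
            for dy in (-half, half)
        )
        if corners_ok:
            centers.append((x, y))
    if len(centers) < n_fields:
        raise SamplingError(
            f"could not place {n_fields} fields of {field_size} um in the ROI"
        )
    area_mm2 = (field_size / 1000.0) ** 2
    densities = []
    for x, y in centers:
        in_field = (
            (pts[:, 0] >= x - half)
            & (pts[:, 0] < x + half)
            & (pts[:, 1] >= y - half)
            & (pts[:, 1] < y + half)
        )
        densities.append(in_field.sum() / area_mm2)
    return CellCountResult(region, n_fields, float(np.mean(densities)))


def cortical_lesion_rate(n_cortical_lesions, blocks_with_cortex: int) -> float:
    """Cortical lesions per tissue block with visible cortex."""
    if blocks_with_cortex < 1:
        raise NumericDomainError("need at least one block with visible cortex")
    counts = np.asarray(list(n_cortical_lesions), dtype=float)
    if np.any(counts < 0):
        raise NumericDomainError("lesion counts must be non-negative")
    return float(counts.sum()) / blocks_with_cortex


def area_fraction(lesion_mask: np.ndarray, total_mask: np.ndarray) -> float:
    """Lesion area as a fraction of the total area (pixel-size cancels)."""
    lesion = np.asarray(lesion_mask) > 0
    total = np.asarray(total_mask) > 0
    if not total.any():
        raise NumericDomainError("empty total-area mask")
    if (lesion & ~total).any():
        raise NumericDomainError("lesion area must lie within the total area")
    return float(lesion.sum()) / float(total.sum())
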