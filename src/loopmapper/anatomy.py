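"""Quantification of labeled-cell point clouds in stereotaxic coordinates.

Coordinates are millimetres relative to bregma: AP positive anterior, ML the
absolute (hemisphere-collapsed) lateral offset, DV positive ventral from the
dura.  The curved striatal outline of an atlas is replaced by a configurable
partition of axis-aligned boxes; the three border rules that the anatomical
workflow makes explicit are defaults: the tail of striatum (TS) begins 0.8 mm
posterior to bregma and captures every labeled cell posterior to that level,
the ventral striatum extends anterior of +0.7 mm AP, and the
medial/lateral splits (VMS|VLS, DMS|DLS) sit midway across each tier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellPoint",
    "RegionPartition",
    "RoiSpec",
    "assign_region",
    "count_in_roi",
    "normalized_distribution",
    "density_map",
    "snr_fraction",
    "luminance_profile",
    "DensityGrid",
]

logger = logging.getLogger(__name__)

STRIATAL_REGIONS = ("VMS", "VLS", "DMS", "DLS", "TS")

Box = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]


@dataclass
class CellPoint:
    """One labeled neuron: stereotaxic coordinates plus section and tracer label."""

    cell_id: str
    AP: float
    ML: float
    DV: float
    section_id: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite([self.AP, self.ML, self.DV]).all():
            raise ValueError("non-finite coordinates")


@dataclass
class RegionPartition:
    """Named, pairwise-disjoint unions of axis-aligned (AP, ML, DV) boxes.

    Membership intervals are treated as closed; where two regions share a
    boundary plane the region earlier in ``region_order`` wins, which with
    the default order (TS first, then medial before lateral, ventral before
    dorsal) implements the documented tie-breaks: a cell exactly on the ML
    midline is medial, one exactly at the TS border is TS.
    """

    regions: dict[str, list[Box]]
    region_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.region_order:
            self.region_order = tuple(self.regions)
        if set(self.region_order) != set(self.regions):
            raise ValueError("region_order must list exactly the region names")

    @staticmethod
    def default_mouse(
        ap_range: tuple[float, float] = (-2.4, 1.7),
        ml_range: tuple[float, float] = (0.0, 4.2),
        dv_range: tuple[float, float] = (1.0, 5.5),
        ts_start_ap: float = -0.8,
        vs_end_ap: float = 0.7,
        dv_split: float = 3.2,
        ml_split_ventral: float = 1.4,
        ml_split_dorsal: float = 2.1,
    ) -> "RegionPartition":
        """Box partition built from the standard border rules.

        ``ts_start_ap``: every cell at or posterior to this AP level is TS.
        ``vs_end_ap``: ventral striatum (VMS/VLS) spans from the anterior end
        of the striatum back to this level.  ``dv_split`` separates dorsal
        from ventral striatum (never given numerically in atlas terms; pure
        config).  ML splits are the midlines of the ventral and dorsal tiers.
        """
        ap0, ap1 = ap_range
        ml0, ml1 = ml_range
        dv0, dv1 = dv_range
        eps = 1e-9
        regions: dict[str, list[Box]] = {
            "TS": [((ap0, ts_start_ap), (ml0, ml1), (dv0, dv1))],
            "VMS": [((vs_end_ap, ap1), (ml0, ml_split_ventral), (dv_split, dv1))],
            "VLS": [((vs_end_ap, ap1), (ml_split_ventral + eps, ml1), (dv_split, dv1))],
            "DMS": [((ts_start_ap + eps, ap1), (ml0, ml_split_dorsal), (dv0, dv_split - eps))],
            "DLS": [((ts_start_ap + eps, ap1), (ml_split_dorsal + eps, ml1), (dv0, dv_split - eps))],
        }
        return RegionPartition(regions=regions,
                               region_order=("TS", "VMS", "VLS", "DMS", "DLS"))


@dataclass(frozen=True)
class RoiSpec:
    """A counting region of interest: a circle in the coronal plane.

    Cells are counted over ``n_sections`` adjacent sections centered on the
    section nearest the ROI's AP coordinate, within ``diameter``/2 of the
    (ML, DV) center; a cell exactly on the rim counts as inside.
    """

    region: str
    center: tuple[float, float, float]  # (AP, ML, DV) mm
    diameter_um: float = 600.0
    n_sections: int = 3
    section_interval_um: float = 160.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.n_sections < 1 or self.n_sections % 2 == 0:
            raise ValueError("n_sections must be odd (centered on the target section)")


# Rat ROI centers (AP, ML, DV from bregma and dura) used in the retrograde
# rabies counting workflow; species-specific defaults.
RAT_ROI_CENTERS: dict[str, tuple[float, float, float]] = {
    "VMS": (1.8, 1.1, 6.5),
    "VLS": (1.8, 2.5, 6.5),
    "DLS": (0.7, 3.7, 3.7),
    "DMS": (0.2, 2.3, 4.2),
    "TS": (-2.0, 4.7, 5.0),
}


def _in_box(p: CellPoint, box: Box) -> bool:
    (ap0, ap1), (ml0, ml1), (dv0, dv1) = box
    return (ap0 <= p.AP <= ap1) and (ml0 <= p.ML <= ml1) and (dv0 <= p.DV <= dv1)


def assign_region(point: CellPoint, partition: RegionPartition) -> str:
    """Name of the subregion containing ``point``, or ``"outside"``."""
    for name in partition.region_order:
        for box in partition.regions[name]:
            if _in_box(point, box):
                return name
    return "outside"


def count_in_roi(points: list[CellPoint], roi: RoiSpec) -> int:
    """Number of cells inside the ROI circle over its adjacent sections."""
    interval_mm = roi.section_interval_um / 1000.0
    center_section = int(round(roi.center[0] / interval_mm))
    half = (roi.n_sections - 1) // 2
    sections = {s for s in range(center_section - half, center_section + half + 1)}
    present = {p.section_id for p in points}
    if not (sections & present) and points:
        logger.warning("ROI %s: no points in sections %s", roi.region, sorted(sections))
    radius_mm = roi.diameter_um / 2000.0
    n = 0
    for p in points:
        if p.section_id not in sections:
            continue
        d = np.hypot(p.ML - roi.center[1], p.DV - roi.center[2])
        if d <= radius_mm:
            n += 1
    return n


def normalized_distribution(
    points: list[CellPoint],
    partition: RegionPartition | None = None,
    rois: list[RoiSpec] | None = None,
    regions: tuple[str, ...] = STRIATAL_REGIONS,
) -> pd.DataFrame:
    """Per-region counts and percentages of the five-region total.

    Two workflows: ROI counting (``rois`` given; the rat series) or
    whole-region assignment via the partition (the mouse series).  Percentages
    are 100 * count / total over the listed regions.
    """
    if rois is not None:
        counts = {r.region: count_in_roi(points, r) for r in rois}
        counts = {name: counts.get(name, 0) for name in regions}
    elif partition is not None:
        counts = {name: 0 for name in regions}
        for p in points:
            name = assign_region(p, partition)
            if name in counts:
                counts[name] += 1
    else:
        raise ValueError("provide either a partition or ROI specs")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no cells counted in any region; percentages undefined")
    return pd.DataFrame(
        {
            "region": list(regions),
            "count": [counts[r] for r in regions],
            "percent": [100.0 * counts[r] / total for r in regions],
        }
    )


@dataclass
class DensityGrid:
    """Cell density of one rostro-caudal part: counts and log-normalized values."""

    part_index: int  # 1-based
    ap_range: tuple[float, float]
    ml_edges: np.ndarray
    dv_edges: np.ndarray
    counts: np.ndarray  # shape (n_ml, n_dv)
    normalized: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def density_map(
    points: list[CellPoint],
    n_parts: int = 8,
    bin_size_um: float = 160.0,
) -> list[DensityGrid]:
    """Rostro-caudal series of coronal density grids.

    The AP extent of the cloud is split into ``n_parts`` equal slabs
    (anterior part first); cells of each slab are collapsed onto the coronal
    plane and binned into square ML-DV bins of side ``bin_size_um``.  Bin
    values are normalized relative to the densest bin on a log scale:
    ``log(1 + count) / log(1 + max count)``, so empty bins map to 0 and the
    densest bin to 1.
    """
    if not points:
        return []
    bin_mm = bin_size_um / 1000.0
    ap = np.array([p.AP for p in points])
    ml = np.array([p.ML for p in points])
    dv = np.array([p.DV for p in points])
    ap_min, ap_max = ap.min(), ap.max()
    span = max(ap_max - ap_min, 1e-9)
    # anterior part first: part 1 holds the most anterior slab
    part = np.clip(((ap_max - ap) / span * n_parts).astype(int), 0, n_parts - 1)
    ml_edges = np.arange(np.floor(ml.min() / bin_mm) * bin_mm,
                         ml.max() + bin_mm, bin_mm)
    dv_edges = np.arange(np.floor(dv.min() / bin_mm) * bin_mm,
                         dv.max() + bin_mm, bin_mm)
    if ml_edges.size < 2:
        ml_edges = np.array([ml_edges[0], ml_edges[0] + bin_mm])
    if dv_edges.size < 2:
        dv_edges = np.array([dv_edges[0], dv_edges[0] + bin_mm])
    grids = []
    for k in range(n_parts):
        sel = part == k
        counts, _, _ = np.histogram2d(ml[sel], dv[sel], bins=[ml_edges, dv_edges])
        cmax = counts.max()
        norm = np.log1p(counts) / np.log1p(cmax) if cmax > 0 else np.zeros_like(counts)
        grids.append(
            DensityGrid(
                part_index=k + 1,
                ap_range=(ap_max - (k + 1) / n_parts * span, ap_max - k / n_parts * span),
                ml_edges=ml_edges,
                dv_edges=dv_edges,
                counts=counts.astype(int),
                normalized=norm,
            )
        )
    return grids


def snr_fraction(
    points: list[CellPoint],
    edges_by_section: dict[int, tuple[float, float]],
    n_divisions: int = 2,
) -> np.ndarray:
    """Fraction of nigral cells per medio-lateral division, averaged over sections.

    Each cell's position is normalized by its section's medial and lateral
    edges, ``u = (ML - medial) / (lateral - medial)``; the division index is
    ``floor(u * n_divisions)`` clipped to the last division, so ``u`` exactly
    on an internal boundary falls in the more lateral division.  Per-section
    fractions are averaged with equal section weight (the per-animal
    convention); cells outside the edges are clipped with a warning.
    """
    if n_divisions < 1:
        raise ValueError("n_divisions must be >= 1")
    for sec, (med, lat) in edges_by_section.items():
        if not lat > med:
            raise ValueError(f"section {sec}: lateral edge must exceed medial edge")
    per_section = []
    for sec, (med, lat) in edges_by_section.items():
        pts = [p for p in points if p.section_id == sec]
        if not pts:
            continue
        u = np.array([(p.ML - med) / (lat - med) for p in pts])
        if np.any((u < 0) | (u > 1)):
            warnings.warn(f"section {sec}: {np.sum((u < 0) | (u > 1))} cells outside "
                          "the SNr edges; clipped", stacklevel=2)
            u = np.clip(u, 0.0, 1.0)
        idx = np.minimum((u * n_divisions).astype(int), n_divisions - 1)
        frac = np.bincount(idx, minlength=n_divisions) / u.size
        per_section.append(frac)
    if not per_section:
        raise ValueError("no cells in any analyzed section")
    return np.mean(per_section, axis=0)


def luminance_profile(
    raw: dict[str, float] | pd.Series,
    background: float,
    regions: tuple[str, ...] = STRIATAL_REGIONS,
) -> pd.DataFrame:
    """Background-subtracted fluorescence luminance, normalized to percentages."""
    raw = pd.Series(raw)
    if (raw < 0).any():
        raise ValueError("raw luminance must be non-negative")
    vals = (raw.reindex(regions) - background).clip(lower=0.0)
    total = vals.sum()
    if total <= 0:
        raise ValueError("all regions at or below background; profile undefined")
    return pd.DataFrame({"region": list(regions),
                         "luminance": vals.to_numpy(),
                         "percent": 100.0 * vals.to_numpy() / total})
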