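"""Hierarchical regions of interest.

Level 1 regions come from the functional localizer; Level 2 intersects them
with named anatomical parcels (disconnection allowed); Level 3 restricts to a
sphere of given volume around a lesion centroid and, for the homotopic
analysis, mirrors a region through the sagittal midplane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .headmodel import SourceSpace
from .silencemap import RegionOfInterest

__all__ = ["LesionSpec", "parcel_intersect", "spherical_roi", "mirror_roi", "roi_mean"]


@dataclass
class LesionSpec:
    """Lesion centroid (source-space coordinates, mm) and volume (mm^3).

    The centroid is taken to be already expressed in the source-space frame;
    aligning scanner/atlas coordinates to that frame is out of scope.
    """

    centroid: np.ndarray
    volume_mm3: float

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)
        if self.volume_mm3 <= 0:
            raise ValueError("lesion volume must be positive")

    @property
    def radius_mm(self) -> float:
        """Radius of the sphere with the lesion's volume: (3V / 4 pi)^(1/3)."""
        return float((3.0 * self.volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def parcel_intersect(
    level1: RegionOfInterest,
    sources: SourceSpace,
    wanted: Iterable[str],
) -> RegionOfInterest:
    """Level-2 ROI: intersect a functional region with named parcels.

    The result may be disconnected or empty (empty triggers a warning, not an
    error); an unknown parcel label raises listing the known labels.
    """
    wanted = set(wanted)
    known = set(np.unique(sources.parcels).tolist())
    unknown = wanted - known
    if unknown:
        raise ValueError(f"unknown parcel label(s) {sorted(unknown)}; known: {sorted(known)}")
    keep = [q for q in level1.indices if sources.parcels[q] in wanted]
    if not keep:
        warnings.warn("parcel intersection is empty")
    return RegionOfInterest(indices=np.asarray(keep, dtype=int),
                            hemisphere=level1.hemisphere, level=2, mode=level1.mode,
                            provenance={"parcels": sorted(wanted), "from_level1": True})


def spherical_roi(
    sources: SourceSpace,
    lesion: LesionSpec,
    within: RegionOfInterest,
) -> RegionOfInterest:
    """Level-3 ROI: sources of a region inside the lesion-volume sphere."""
    r = lesion.radius_mm
    pos = sources.positions[within.indices]
    d = np.linalg.norm(pos - lesion.centroid[None, :], axis=1)
    keep = within.indices[d <= r]
    if len(keep) == 0:
        raise ValueError(
            f"no sources within lesion sphere (radius {r:.2f} mm); "
            "check that the centroid is given in source-space coordinates")
    return RegionOfInterest(indices=keep, hemisphere=within.hemisphere, level=3,
                            mode=within.mode,
                            provenance={"centroid": lesion.centroid.tolist(),
                                        "volume_mm3": lesion.volume_mm3,
                                        "radius_mm": r})


def mirror_roi(
    roi: RegionOfInterest,
    sources: SourceSpace,
    tol_mm: float = None,
) -> RegionOfInterest:
    """Homotopic ROI: map each source to the nearest source at (-x, y, z).

    Requires a source space approximately mirror-symmetric about x = 0; any
    source without a match within ``tol_mm`` (default twice the grid spacing)
    raises.  On exactly symmetric grids the operation is an involution.
    """
    if tol_mm is None:
        tol_mm = 2.0 * sources.spacing
    tree = cKDTree(sources.positions)
    mirrored = sources.positions[roi.indices] * np.array([-1.0, 1.0, 1.0])
    d, idx = tree.query(mirrored)
    bad = np.where(d > tol_mm)[0]
    if len(bad):
        q = roi.indices[bad[0]]
        raise ValueError(f"no mirror match within {tol_mm:.1f} mm for source {q} "
                         f"(nearest at {d[bad[0]]:.1f} mm)")
    flip = {"L": "R", "R": "L", "both": "both"}[roi.hemisphere]
    return RegionOfInterest(indices=idx, hemisphere=flip, level=roi.level, mode=roi.mode,
                            provenance={"mirrored_from": roi.indices.tolist()})


def roi_mean(values: np.ndarray, roi: RegionOfInterest) -> Tuple[float, np.ndarray]:
    """Mean of a per-source map over an ROI, plus the per-source values."""
    if len(roi) == 0:
        raise ValueError("empty ROI")
    vals = np.asarray(values, dtype=float)[roi.indices]
    return float(vals.mean()), vals
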