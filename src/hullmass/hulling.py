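"""Minimal convex hulls of skeletal segments: volume and centroid.

The hull of each segment's vertex cloud is the smallest convex polytope
containing it.  Its volume is accumulated as signed tetrahedra spanned by
the (outward-oriented) hull facets and an interior reference point, and
the centroid is the volume-weighted mean of those tetrahedra's centroids.
Under the uniform within-segment density assumption the hull centroid is
the segment's centre of mass; the downstream volume-expansion step scales
volume but keeps this centroid fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .skeleton_io import SegmentClass, SegmentMesh, SkeletonManifest, SkeletonError

__all__ = ["SegmentHull", "compute_hull", "hull_all", "hulls_table"]

#: simplices with |signed volume| below this fraction of the total are
#: still accumulated; the tolerance only guards the degenerate-input check
DEGENERACY_TOL = 1e-12


@dataclass
class SegmentHull:
    """Convex hull of one segment: vertices, volume (m^3), centroid (m)."""

    segment_class: SegmentClass
    side: str
    hull_vertices: np.ndarray
    hull_volume: float
    hull_centroid: np.ndarray

    @property
    def label(self) -> str:
        base = self.segment_class.label
        return base if self.side == "midline" else f"{base}_{self.side}"


def _hull_volume_centroid(points: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Volume, centroid and hull vertex subset of a 3-D point cloud.

    Decomposes the hull into tetrahedra (facet + interior point); works
    for any facet orientation because the interior point makes all signed
    volumes positive up to round-off.
    """
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise SkeletonError(f"degenerate point set for hulling: {exc}") from exc
    verts = points[hull.vertices]
    ref = verts.mean(axis=0)
    simplices = points[hull.simplices]  # (nfacet, 3, 3)
    a = simplices[:, 0, :] - ref
    b = simplices[:, 1, :] - ref
    c = simplices[:, 2, :] - ref
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    vols = np.abs(signed)
    total = float(vols.sum())
    if total <= DEGENERACY_TOL:
        raise SkeletonError("hull volume vanishes (coplanar input)")
    tet_centroids = (simplices.sum(axis=1) + ref) / 4.0
    centroid = (vols[:, None] * tet_centroids).sum(axis=0) / total
    return total, centroid, verts


def compute_hull(segment: SegmentMesh) -> SegmentHull:
    """Minimal convex hull of one segment.

    Raises :class:`SkeletonError` (naming the segment) for coplanar or
    collinear input.  The volume is invariant under rigid transforms of
    the input, and the centroid lies strictly inside the hull.
    """
    try:
        volume, centroid, verts = _hull_volume_centroid(segment.vertices)
    except SkeletonError as exc:
        raise SkeletonError(f"segment {segment.label}: {exc}") from exc
    return SegmentHull(
        segment_class=segment.segment_class,
        side=segment.side,
        hull_vertices=verts,
        hull_volume=volume,
        hull_centroid=centroid,
    )


def hull_all(manifest: SkeletonManifest) -> list[SegmentHull]:
    """Hull every segment of a loaded skeleton, preserving segment order."""
    return [compute_hull(seg) for seg in manifest.segments]


def hulls_table(hulls: list[SegmentHull]) -> pd.DataFrame:
    """Summary table: one row per segment with volume and centroid."""
    return pd.DataFrame(
        {
            "segment": [h.label for h in hulls],
            "segment_class": [h.segment_class.name for h in hulls],
            "side": [h.side for h in hulls],
            "hull_volume_m3": [h.hull_volume for h in hulls],
            "centroid_x_m": [h.hull_centroid[0] for h in hulls],
            "centroid_y_m": [h.hull_centroid[1] for h in hulls],
            "centroid_z_m": [h.hull_centroid[2] for h in hulls],
        }
    )


def export_hull_obj(hull: SegmentHull, path) -> None:
    """Write the hull itself (re-hulled vertex subset) as an OBJ mesh."""
    import trimesh

    tm = trimesh.convex.convex_hull(hull.hull_vertices)
    tm.export(path)
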