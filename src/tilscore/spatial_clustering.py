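"""Density-based clustering of tumour nuclei and compartment geometry.

Tumour nuclei are clustered with DBSCAN (eps = 200 px, min_samples = 10 by
default; min_samples counts the point itself).  Each cluster's *inner region*
is a polygon built from the member centroids; dilating it by 60 px (the
cluster *expansion*) yields the expanded region, and the difference is the
*outer ring*.  Nuclei with centroids inside an inner region are
intratumoural; inside an outer ring only, stromal; otherwise outside.
Lymphocytes in the inner region or outer ring are the tumour-infiltrating
lymphocytes (TILs) the downstream features count.

Two inner-region constructions are available:

``closing`` (default)
    Union of r_pad-radius discs around member centroids, morphologically
    closed (dilate then erode) with radius eps/2.  Follows concave cluster
    shapes and fills intra-cluster gaps up to the DBSCAN reachability scale.
``convex_hull``
    Convex hull of member centroids, buffered by r_pad.  Simple and has
    closed-form areas for analytic fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Point
from shapely.ops import unary_union
from shapely.prepared import prep
from sklearn.cluster import DBSCAN

from .nuclei_io import CLASS_TUMOUR, SlideNucleiMap

# Default clustering parameters (pixels at 40x / 0.255 um/px).
DEFAULT_EPS = 200.0
DEFAULT_MIN_PTS = 10
DEFAULT_EXPANSION = 60.0
DEFAULT_R_PAD = 10.0
#: Circle-approximation fidelity for shapely buffers (segments per quadrant).
BUFFER_QUAD_SEGS = 16

NOISE = -1

COMPARTMENT_INTRA = "intratumoural"
COMPARTMENT_STROMAL = "stromal"
COMPARTMENT_OUTSIDE = "outside"
COMPARTMENTS = (COMPARTMENT_INTRA, COMPARTMENT_STROMAL, COMPARTMENT_OUTSIDE)


class ClusteringError(ValueError):
    """Invalid clustering/region parameters."""


def density_cluster(
    points: np.ndarray, eps: float = DEFAULT_EPS, min_pts: int = DEFAULT_MIN_PTS
) -> np.ndarray:
    """DBSCAN labels for tumour-nucleus centroids.

    A point is a core point when at least ``min_pts`` points (itself
    included) lie within ``eps``; clusters are maximal density-connected
    sets; unreachable points get label ``-1``.

    Parameters
    ----------
    points : (n, 2) array of pixel coordinates.
    eps : neighbourhood radius in px (> 0).
    min_pts : minimum neighbourhood size, self-inclusive (>= 1).
    """
    if eps <= 0:
        raise ClusteringError("eps must be > 0")
    if min_pts < 1:
        raise ClusteringError("min_pts must be >= 1")
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return np.empty(0, dtype=int)
    if not np.all(np.isfinite(points)):
        raise ClusteringError("non-finite coordinates")
    # sklearn's min_samples likewise counts the point itself.
    return DBSCAN(eps=eps, min_samples=min_pts).fit(points).labels_


@dataclass
class ClusterPartition:
    """DBSCAN labels plus inner/expanded/outer-ring geometry per cluster."""

    points: np.ndarray
    labels: np.ndarray
    inner_regions: list  # shapely (Multi)Polygon per cluster
    expanded_regions: list
    outer_rings: list
    eps: float = DEFAULT_EPS
    min_pts: int = DEFAULT_MIN_PTS
    expansion: float = DEFAULT_EXPANSION
    region_method: str = "closing"
    r_pad: float = DEFAULT_R_PAD
    # Global (union) geometries; ring union excludes every inner region so
    # overlap between neighbouring clusters is never double counted.
    inner_union: object = field(default=None, repr=False)
    expanded_union: object = field(default=None, repr=False)
    ring_union: object = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.inner_regions)

    def inner_areas(self) -> np.ndarray:
        return np.array([g.area for g in self.inner_regions])

    def expanded_areas(self) -> np.ndarray:
        return np.array([g.area for g in self.expanded_regions])

    def ring_areas(self) -> np.ndarray:
        return np.array([g.area for g in self.outer_rings])

    def total_inner_area(self) -> float:
        """Union area of all inner regions (overlap counted once)."""
        return self.inner_union.area

    def total_ring_area(self) -> float:
        return self.ring_union.area

    def total_expanded_area(self) -> float:
        return self.expanded_union.area


def _inner_geometry(
    pts: np.ndarray, method: str, r_pad: float, eps: float
):
    """Inner-region polygon for one cluster's member centroids."""
    if method == "convex_hull":
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        # buffer(0-area hulls of collinear points) so regions are never degenerate
        if hull.area == 0 or r_pad > 0:
            hull = hull.buffer(max(r_pad, 1e-9), quad_segs=BUFFER_QUAD_SEGS)
        return hull
    if method == "closing":
        discs = unary_union(
            [Point(*p).buffer(r_pad, quad_segs=BUFFER_QUAD_SEGS) for p in pts]
        )
        close_r = eps / 2.0
        return discs.buffer(close_r, quad_segs=BUFFER_QUAD_SEGS).buffer(
            -close_r, quad_segs=BUFFER_QUAD_SEGS
        )
    raise ClusteringError(f"unknown region_method {method!r}")


def build_cluster_regions(
    points: np.ndarray,
    labels: np.ndarray,
    expansion: float = DEFAULT_EXPANSION,
    *,
    region_method: str = "closing",
    r_pad: float = DEFAULT_R_PAD,
    eps: float = DEFAULT_EPS,
    min_pts: int = DEFAULT_MIN_PTS,
) -> ClusterPartition:
    """Build inner regions, 60-px expanded regions and outer rings.

    The expanded region is the Minkowski dilation of the inner region by a
    disc of radius ``expansion`` (a shapely buffer); the outer ring is the
    expanded region minus the inner region.
    """
    if expansion < 0:
        raise ClusteringError("expansion must be >= 0")
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cluster_ids = sorted(set(labels[labels != NOISE]))
    inner, expanded, rings = [], [], []
    for k in cluster_ids:
        pts = points[labels == k]
        region = _inner_geometry(pts, region_method, r_pad, eps)
        dil = region.buffer(expansion, quad_segs=BUFFER_QUAD_SEGS) if expansion > 0 else region
        inner.append(region)
        expanded.append(dil)
        rings.append(dil.difference(region))
    inner_union = unary_union(inner) if inner else MultiPoint([]).buffer(0)
    expanded_union = unary_union(expanded) if expanded else MultiPoint([]).buffer(0)
    ring_union = expanded_union.difference(inner_union)
    return ClusterPartition(
        points=points,
        labels=labels,
        inner_regions=inner,
        expanded_regions=expanded,
        outer_rings=rings,
        eps=eps,
        min_pts=min_pts,
        expansion=expansion,
        region_method=region_method,
        r_pad=r_pad,
        inner_union=inner_union,
        expanded_union=expanded_union,
        ring_union=ring_union,
    )


@dataclass
class CompartmentAssignment:
    """Per-nucleus compartment ('intratumoural'/'stromal'/'outside') and
    owning cluster index (-1 when none)."""

    compartment: np.ndarray  # dtype=object str codes, aligned with nuclei list
    cluster_index: np.ndarray

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.compartment == c)) for c in COMPARTMENTS}


def assign_compartments(
    partition: ClusterPartition, nuclei: SlideNucleiMap
) -> CompartmentAssignment:
    """Assign every nucleus on the slide to a spatial compartment.

    Centroid rule: a nucleus is intratumoural iff its centroid lies in (or
    on the boundary of) any inner region; stromal iff not intratumoural and
    inside any outer ring; otherwise outside.  Clustered tumour nuclei are
    intratumoural by construction.  A centroid covered by rings of several
    clusters is attributed to the cluster whose inner-region boundary is
    nearest.
    """
    n = len(nuclei.nuclei)
    compartment = np.array([COMPARTMENT_OUTSIDE] * n, dtype=object)
    cluster_index = np.full(n, -1, dtype=int)

    # map tumour nuclei back to their DBSCAN labels by exact centroid match
    # (robust to nucleus reordering between partition build and assignment)
    label_by_nucleus: dict[int, int] = {}
    if len(partition.points):
        from scipy.spatial import cKDTree

        tree = cKDTree(partition.points)
        for i, rec in enumerate(nuclei.nuclei):
            if rec.cls != CLASS_TUMOUR:
                continue
            dist, j = tree.query([rec.x, rec.y], k=1)
            if dist < 1e-9:
                label_by_nucleus[i] = int(partition.labels[j])

    prepared_inner = [prep(g) for g in partition.inner_regions]
    prepared_exp = [prep(g) for g in partition.expanded_regions]

    for i, rec in enumerate(nuclei.nuclei):
        lbl = label_by_nucleus.get(i, None)
        if lbl is not None and lbl != NOISE:
            compartment[i] = COMPARTMENT_INTRA
            cluster_index[i] = lbl
            continue
        pt = Point(rec.x, rec.y)
        inner_hits = [k for k, g in enumerate(prepared_inner) if g.covers(pt)]
        if inner_hits:
            compartment[i] = COMPARTMENT_INTRA
            cluster_index[i] = _nearest(inner_hits, partition, pt)
            continue
        ring_hits = [k for k, g in enumerate(prepared_exp) if g.covers(pt)]
        if ring_hits:
            compartment[i] = COMPARTMENT_STROMAL
            cluster_index[i] = _nearest(ring_hits, partition, pt)
    return CompartmentAssignment(compartment=compartment, cluster_index=cluster_index)


def _nearest(candidates: list[int], partition: ClusterPartition, pt: Point) -> int:
    """Tie-break overlapping regions: nearest inner-region boundary wins."""
    if len(candidates) == 1:
        return candidates[0]
    return min(candidates, key=lambda k: partition.inner_regions[k].boundary.distance(pt))


def partition_to_geojson(partition: ClusterPartition) -> dict:
    """Region geometries as a GeoJSON FeatureCollection for overlay QC."""
    from shapely.geometry import mapping

    features = []
    for k in range(partition.n_clusters):
        for kind, geom in (
            ("inner", partition.inner_regions[k]),
            ("outer_ring", partition.outer_rings[k]),
        ):
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(geom),
                    "properties": {"cluster": k, "kind": kind},
                }
            )
    return {"type": "FeatureCollection", "features": features}
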