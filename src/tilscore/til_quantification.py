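"""The 12 digital TIL features and 9 tumour nuclear-morphology features.

TIL features come in four families, each evaluated in three locations
(*combined* = inner + ring pooled, *intratumoural* = inner regions,
*stromal* = outer rings):

====================  =====================================================
til_ratio             N_TIL / N_tumour (counts)
til_density_cluster   N_TIL / region area (px^-2; region = inner, ring, or
                      expanded union depending on location)
til_density_tumour    N_TIL / summed tumour-nucleus area (px^-2)
til_area_ratio        summed TIL-nucleus area / summed tumour-nucleus area
====================  =====================================================

Combined-location features pool counts and areas (ratio of sums, not mean
of ratios).  Any feature whose denominator is zero is set to 0 and a QC
flag is raised, keeping the downstream model input rectangular.

The 9 morphology features (contour_area, convex_area, equivalent_diameter,
major_axis_length, minor_axis_length, perimeter, bounding_box_area,
solidity, eccentricity) are measured per tumour nucleus from its contour
polygon — axis lengths and eccentricity from the ellipse with matching
second central moments — and averaged over *intratumoural* tumour nuclei
only (nuclei in the expanded ring are excluded from morphology).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuclei_io import CLASS_LYMPHOCYTE, CLASS_TUMOUR, SlideNucleiMap
from .spatial_clustering import (
    COMPARTMENT_INTRA,
    COMPARTMENT_STROMAL,
    ClusterPartition,
    CompartmentAssignment,
)

logger = logging.getLogger("tilscore")

LOCATIONS = ("combined", "intratumoural", "stromal")
TIL_FAMILIES = ("til_ratio", "til_density_cluster", "til_density_tumour", "til_area_ratio")

#: Canonical order of the 12 digital TIL feature columns.
TIL_FEATURE_NAMES = tuple(
    f"{loc}_{fam}" if loc != "combined" else fam
    for fam in TIL_FAMILIES
    for loc in LOCATIONS
)

MORPH_FEATURE_NAMES = (
    "contour_area",
    "convex_area",
    "equivalent_diameter",
    "major_axis_length",
    "minor_axis_length",
    "perimeter",
    "bounding_box_area",
    "solidity",
    "eccentricity",
)


class MorphologyError(ValueError):
    """Contour unsuitable for morphometry (self-intersecting/degenerate)."""


# ---------------------------------------------------------------------------
# TIL features
# ---------------------------------------------------------------------------


@dataclass
class TilFeatureVector:
    """The 12 digital TIL features for one WSI plus QC flags."""

    values: dict[str, float]
    qc_flags: list[str] = field(default_factory=list)
    counts: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in TIL_FEATURE_NAMES})


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(f"zero denominator for {name}")
        return 0.0
    return num / den


def compute_til_features(
    assignment: CompartmentAssignment,
    partition: ClusterPartition,
    nuclei: SlideNucleiMap,
) -> TilFeatureVector:
    """Quantify the 12 digital TIL features on one slide.

    Counts and areas are accumulated per compartment over lymphocyte (TIL)
    and tumour nuclei; nuclei assigned "outside" never contribute.  Region
    areas use the union geometries so overlap between neighbouring clusters
    is counted once.
    """
    flags: list[str] = []
    if partition.n_clusters == 0:
        logger.warning("slide %s: no tumour clusters; all TIL features 0", nuclei.slide_id)
        return TilFeatureVector(
            values={k: 0.0 for k in TIL_FEATURE_NAMES},
            qc_flags=["no tumour clusters"],
        )

    acc = {
        loc: {"n_til": 0, "n_tum": 0, "til_area": 0.0, "tum_area": 0.0}
        for loc in ("intratumoural", "stromal")
    }
    n_missing_area = 0
    for rec, comp in zip(nuclei.nuclei, assignment.compartment):
        if comp not in (COMPARTMENT_INTRA, COMPARTMENT_STROMAL):
            continue
        if rec.cls == CLASS_TUMOUR:
            kind = "tum"
        elif rec.cls == CLASS_LYMPHOCYTE:
            kind = "til"
        else:
            continue
        a = acc[comp]
        a[f"n_{kind}"] += 1
        area = rec.effective_area()
        if area is None:
            n_missing_area += 1
        else:
            a[f"{kind}_area"] += area
    if n_missing_area:
        flags.append(f"{n_missing_area} nuclei without area excluded from area sums")

    region_area = {
        "intratumoural": partition.total_inner_area(),
        "stromal": partition.total_ring_area(),
        "combined": partition.total_expanded_area(),
    }
    pooled = {
        key: acc["intratumoural"][key] + acc["stromal"][key]
        for key in ("n_til", "n_tum", "til_area", "tum_area")
    }
    by_loc = {"intratumoural": acc["intratumoural"], "stromal": acc["stromal"], "combined": pooled}

    values: dict[str, float] = {}
    for loc in LOCATIONS:
        a = by_loc[loc]
        prefix = "" if loc == "combined" else f"{loc}_"
        values[f"{prefix}til_ratio"] = _safe_div(
            a["n_til"], a["n_tum"], f"{loc} til_ratio", flags
        )
        values[f"{prefix}til_density_cluster"] = _safe_div(
            a["n_til"], region_area[loc], f"{loc} til_density_cluster", flags
        )
        values[f"{prefix}til_density_tumour"] = _safe_div(
            a["n_til"], a["tum_area"], f"{loc} til_density_tumour", flags
        )
        values[f"{prefix}til_area_ratio"] = _safe_div(
            a["til_area"], a["tum_area"], f"{loc} til_area_ratio", flags
        )
    counts = {
        "n_til_intratumoural": acc["intratumoural"]["n_til"],
        "n_til_stromal": acc["stromal"]["n_til"],
        "n_tumour_intratumoural": acc["intratumoural"]["n_tum"],
        "n_tumour_stromal": acc["stromal"]["n_tum"],
    }
    return TilFeatureVector(values=values, qc_flags=flags, counts=counts)


def densities_per_mm2(vec: TilFeatureVector, mpp: float) -> dict[str, float]:
    """Convert the px^-2 density features to mm^-2 (1 mm = 1000/mpp px)."""
    px_per_mm2 = (1000.0 / mpp) ** 2
    return {
        k: v * px_per_mm2
        for k, v in vec.values.items()
        if "density" in k
    }


# ---------------------------------------------------------------------------
# Nuclear morphometry
# ---------------------------------------------------------------------------


def _polygon_moments(contour: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Signed area, centroid and second central moments of a polygon.

    Green's-theorem closed forms over the vertex list; orientation is
    normalised so the area is positive.
    """
    x = np.asarray(contour[:, 0], dtype=float)
    y = np.asarray(contour[:, 1], dtype=float)
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * cross.sum()
    if a < 0:  # clockwise ring: flip orientation
        x, y = x[::-1], y[::-1]
        x1, y1 = np.roll(x, -1), np.roll(y, -1)
        cross = x * y1 - x1 * y
        a = 0.5 * cross.sum()
    if a == 0:
        raise MorphologyError("zero-area polygon")
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    ixx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    iyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    # central second moments
    mu20 = ixx - a * cx * cx
    mu02 = iyy - a * cy * cy
    mu11 = ixy - a * cx * cy
    return a, cx, cy, mu20, mu02, mu11


def compute_morphology(contour: np.ndarray, nucleus_id: str = "?") -> dict[str, float]:
    """The 9 morphology features of one nucleus contour.

    Area by the shoelace formula, perimeter as polygon arc length, convex
    area from the convex hull, equivalent diameter ``sqrt(4A/pi)``,
    axis-aligned bounding-box area, solidity ``A / A_hull`` and major/minor
    axis lengths and eccentricity from the ellipse whose second central
    moments match the polygon region's.
    """
    from shapely.geometry import Polygon

    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or contour.shape[0] < 3:
        raise MorphologyError(f"nucleus {nucleus_id}: contour must be (n>=3, 2)")
    poly = Polygon(contour)
    if not poly.is_valid:
        raise MorphologyError(f"nucleus {nucleus_id}: self-intersecting contour")

    area, _, _, mu20, mu02, mu11 = _polygon_moments(contour)
    # normalised covariance of the uniform region; eigenvalues give the
    # matched-ellipse semi-axes a = 2 sqrt(l1), b = 2 sqrt(l2)
    cov = np.array([[mu20, mu11], [mu11, mu02]]) / area
    eigvals = np.linalg.eigvalsh(cov)
    l2, l1 = max(eigvals[0], 0.0), max(eigvals[1], 0.0)
    major = 4.0 * np.sqrt(l1)
    minor = 4.0 * np.sqrt(l2)
    eccentricity = np.sqrt(1.0 - l2 / l1) if l1 > 0 else 0.0

    hull_area = poly.convex_hull.area
    minx, miny, maxx, maxy = poly.bounds
    return {
        "contour_area": area,
        "convex_area": hull_area,
        "equivalent_diameter": float(np.sqrt(4.0 * area / np.pi)),
        "major_axis_length": float(major),
        "minor_axis_length": float(minor),
        "perimeter": poly.exterior.length,
        "bounding_box_area": (maxx - minx) * (maxy - miny),
        "solidity": area / hull_area if hull_area > 0 else 0.0,
        "eccentricity": float(eccentricity),
    }


@dataclass
class MorphFeatureVector:
    """Slide-level mean of the 9 morphology features (NaN when unavailable)."""

    values: dict[str, float]
    n_nuclei: int
    missing: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in MORPH_FEATURE_NAMES})


def slide_morphology_mean(
    partition: ClusterPartition,
    nuclei: SlideNucleiMap,
    assignment: CompartmentAssignment,
) -> MorphFeatureVector:
    """Mean morphology over *intratumoural* tumour nuclei with contours.

    Tumour nuclei in the expanded ring (stromal) or outside are excluded,
    as are nuclei without a stored contour (their count is logged).
    """
    rows = []
    n_skipped = 0
    for rec, comp in zip(nuclei.nuclei, assignment.compartment):
        if rec.cls != CLASS_TUMOUR or comp != COMPARTMENT_INTRA:
            continue
        if rec.contour is None:
            n_skipped += 1
            continue
        rows.append(compute_morphology(rec.contour, rec.id))
    if n_skipped:
        logger.info(
            "slide %s: %d intratumoural tumour nuclei without contour excluded "
            "from morphology", nuclei.slide_id, n_skipped,
        )
    if not rows:
        logger.warning("slide %s: no intratumoural tumour nuclei with contours", nuclei.slide_id)
        return MorphFeatureVector(
            values={k: float("nan") for k in MORPH_FEATURE_NAMES},
            n_nuclei=0,
            missing=True,
        )
    df = pd.DataFrame(rows)
    return MorphFeatureVector(
        values=df.mean().to_dict(), n_nuclei=len(rows), missing=False
    )


# ---------------------------------------------------------------------------
# Per-case aggregation
# ---------------------------------------------------------------------------

ALL_FEATURE_NAMES = TIL_FEATURE_NAMES + MORPH_FEATURE_NAMES


def aggregate_case(per_wsi: pd.DataFrame, case_col: str = "case_id") -> pd.DataFrame:
    """Average per-WSI feature rows into one row per case.

    Unweighted arithmetic mean per feature; a feature missing (NaN) on some
    WSIs is averaged over the WSIs where it is available.  ``n_wsis``
    records how many WSIs contributed to the case.
    """
    feature_cols = [c for c in per_wsi.columns if c in ALL_FEATURE_NAMES]
    grouped = per_wsi.groupby(case_col, sort=True)
    out = grouped[feature_cols].mean()
    out["n_wsis"] = grouped.size()
    n_partial = int((grouped[feature_cols].count().lt(out["n_wsis"], axis=0)).sum().sum())
    if n_partial:
        logger.info("aggregate_case: %d (case, feature) cells averaged over a "
                    "subset of WSIs", n_partial)
    return out.reset_index()
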