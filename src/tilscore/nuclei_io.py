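"""Data model and I/O for classified nuclei maps and clinical/survival tables.

A *nuclei map* is the output of an upstream nucleus detection/classification
model run on a whole-slide image (WSI): one record per nucleus with its
centroid in pixel coordinates (40x frame, default 0.255 um/px), a class label
collapsed to ``{tumour, lymphocyte, other}``, and optionally a contour polygon
and/or a precomputed area.  Two on-disk formats are supported: GeoJSON
FeatureCollection (RFC 7946, one Polygon Feature per nucleus) and flat CSV
with WKT contours.

The clinical table carries per-case covariates (age, sex, T, N, stage group,
plasma EBV-DNA group) and right-censorable survival endpoints.  Raw EBV-DNA
copy numbers are binarised at 4000 copies/mL (low: <=4000, high: >4000).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import wkt as _wkt
from shapely.geometry import Polygon

logger = logging.getLogger("tilscore")

# ---------------------------------------------------------------------------
# Constants and vocabularies
# ---------------------------------------------------------------------------

#: Canonical nucleus classes.
CLASS_TUMOUR = "tumour"
CLASS_LYMPHOCYTE = "lymphocyte"
CLASS_OTHER = "other"
NUCLEUS_CLASSES = (CLASS_TUMOUR, CLASS_LYMPHOCYTE, CLASS_OTHER)

#: Default alias map collapsing richer upstream vocabularies (HoverNet/PanNuke
#: style labels) onto the three classes the method needs.
DEFAULT_CLASS_ALIASES: dict[str, str] = {
    "tumour": CLASS_TUMOUR,
    "tumor": CLASS_TUMOUR,
    "neoplastic": CLASS_TUMOUR,
    "epithelial": CLASS_TUMOUR,
    "malignant": CLASS_TUMOUR,
    "lymphocyte": CLASS_LYMPHOCYTE,
    "inflammatory": CLASS_LYMPHOCYTE,
    "lymph": CLASS_LYMPHOCYTE,
    "immune": CLASS_LYMPHOCYTE,
    "other": CLASS_OTHER,
    "connective": CLASS_OTHER,
    "dead": CLASS_OTHER,
    "necrosis": CLASS_OTHER,
    "non-neoplastic epithelial": CLASS_OTHER,
}

#: Physical scan resolution of a 40x Aperio scan, microns per pixel.
DEFAULT_MPP = 0.255

#: Plasma EBV-DNA grouping threshold, copies/mL (low: <=, high: >).
EBV_THRESHOLD_COPIES = 4000.0

#: Survival endpoints: locoregional recurrence-free, distant metastasis-free,
#: progression-free and regional recurrence-free survival.
ENDPOINTS = ("lrfs", "dmfs", "pfs", "rrfs")

SEXES = ("male", "female")
T_STAGES = (1, 2, 3, 4)
N_STAGES = (0, 1, 2, 3)
STAGES = ("I", "II", "III", "IV")
EBV_GROUPS = ("low", "high")


class NucleiIOError(Exception):
    """Base class for nuclei/clinical I/O failures."""


class SchemaError(NucleiIOError):
    """A mandatory column or property is missing."""


class GeometryParseError(NucleiIOError):
    """A contour could not be parsed or is invalid; names the feature id."""


class ValidationError(NucleiIOError):
    """Record-level validation failed; lists offending ids."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def polygon_area(contour: np.ndarray) -> float:
    """Area of a closed polygon by the shoelace formula (px^2)."""
    x = contour[:, 0]
    y = contour[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


@dataclass
class NucleusRecord:
    """One classified nucleus.

    ``contour`` is an (n, 2) float array of polygon vertices (not repeating
    the first vertex); ``area`` may be given directly when no contour was
    stored.  If both are present they must agree to 1%.
    """

    id: str
    x: float
    y: float
    cls: str
    contour: np.ndarray | None = None
    area: float | None = None

    def effective_area(self) -> float | None:
        """Nucleus area in px^2: stored value, else from contour, else None."""
        if self.area is not None:
            return float(self.area)
        if self.contour is not None:
            return polygon_area(self.contour)
        return None

    def validate(self) -> None:
        if self.cls not in NUCLEUS_CLASSES:
            raise ValidationError(f"nucleus {self.id}: unknown class {self.cls!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"nucleus {self.id}: non-finite centroid")
        if self.contour is not None:
            c = np.asarray(self.contour, dtype=float)
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
                raise GeometryParseError(
                    f"nucleus {self.id}: contour must be an (n>=3, 2) polygon"
                )
            if not Polygon(c).is_valid:
                raise GeometryParseError(
                    f"nucleus {self.id}: self-intersecting or degenerate contour"
                )
        if self.area is not None and self.area <= 0:
            raise ValidationError(f"nucleus {self.id}: non-positive area")
        if self.area is not None and self.contour is not None:
            pa = polygon_area(self.contour)
            if pa > 0 and abs(self.area - pa) / pa > 0.01:
                raise ValidationError(
                    f"nucleus {self.id}: stored area {self.area:.2f} disagrees with "
                    f"contour area {pa:.2f} by more than 1%"
                )


@dataclass
class SlideNucleiMap:
    """All classified nuclei of one WSI, with the scan resolution."""

    slide_id: str
    nuclei: list[NucleusRecord]
    mpp: float = DEFAULT_MPP

    def validate(self) -> None:
        if not self.slide_id:
            raise ValidationError("slide_id must be non-empty")
        if self.mpp <= 0:
            raise ValidationError("mpp must be > 0")
        for rec in self.nuclei:
            rec.validate()

    def coords(self, cls: str | None = None) -> np.ndarray:
        """(n, 2) centroid array, optionally restricted to one class."""
        recs = self.nuclei if cls is None else [r for r in self.nuclei if r.cls == cls]
        if not recs:
            return np.empty((0, 2), dtype=float)
        return np.array([[r.x, r.y] for r in recs], dtype=float)

    def subset(self, cls: str) -> list[NucleusRecord]:
        return [r for r in self.nuclei if r.cls == cls]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in NUCLEUS_CLASSES}
        for r in self.nuclei:
            counts[r.cls] += 1
        return counts


@dataclass
class ClinicalRecord:
    """Per-case clinical covariates plus survival endpoints.

    ``endpoints`` maps endpoint name -> (time in months, event flag).
    """

    case_id: str
    age: float
    sex: str
    t_stage: int
    n_stage: int
    stage: str
    ebv_group: str
    endpoints: dict[str, tuple[float, int]] = field(default_factory=dict)


def ebv_group_from_copies(copies: float) -> str:
    """Binarise plasma EBV-DNA copies/mL: low <= 4000 < high."""
    return "low" if copies <= EBV_THRESHOLD_COPIES else "high"


# ---------------------------------------------------------------------------
# Nuclei map readers / writers
# ---------------------------------------------------------------------------


def _canonical_class(raw: str, aliases: dict[str, str]) -> tuple[str, bool]:
    """Map a raw label to the canonical vocabulary; flags unknown labels."""
    key = str(raw).strip().lower()
    if key in aliases:
        return aliases[key], True
    return CLASS_OTHER, False


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".geojson", ".json"):
        return "geojson"
    return "csv"


def read_nuclei_map(
    path: str | Path,
    format: str | None = None,
    *,
    alias_map: dict[str, str] | None = None,
    slide_id: str | None = None,
    mpp: float = DEFAULT_MPP,
) -> SlideNucleiMap:
    """Read a classified nuclei map from GeoJSON or CSV.

    Unknown class labels are mapped to ``other``; the number of such records
    is logged as a warning.  Raises :class:`SchemaError` for missing columns
    and :class:`GeometryParseError` for malformed contours (naming the id).
    """
    path = Path(path)
    if not path.exists():
        raise NucleiIOError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    aliases = dict(DEFAULT_CLASS_ALIASES if alias_map is None else alias_map)
    aliases = {k.lower(): v for k, v in aliases.items()}
    if fmt == "geojson":
        smap = _read_geojson(path, aliases, slide_id, mpp)
    elif fmt == "csv":
        smap = _read_csv(path, aliases, slide_id, mpp)
    else:
        raise NucleiIOError(f"unknown format {fmt!r}")
    smap.validate()
    return smap


def _read_geojson(
    path: Path, aliases: dict[str, str], slide_id: str | None, mpp: float
) -> SlideNucleiMap:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    meta = doc.get("properties") or {}
    records: list[NucleusRecord] = []
    n_unknown = 0
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        fid = str(props.get("id", feat.get("id", i)))
        if "class" not in props and "classification" not in props:
            raise SchemaError(f"{path}: feature {fid} has no classification property")
        raw_cls = props.get("class", props.get("classification"))
        if isinstance(raw_cls, dict):  # QuPath-style {"name": ...}
            raw_cls = raw_cls.get("name", "")
        cls, known = _canonical_class(raw_cls, aliases)
        n_unknown += not known
        geom = feat.get("geometry") or {}
        if geom.get("type") == "Polygon" and geom.get("coordinates"):
            ring = np.asarray(geom["coordinates"][0], dtype=float)
            if ring.shape[0] >= 2 and np.allclose(ring[0], ring[-1]):
                ring = ring[:-1]  # drop the closing vertex
            if ring.shape[0] < 3:
                raise GeometryParseError(f"{path}: feature {fid}: degenerate polygon")
            centroid = Polygon(ring).centroid
            x, y = float(props.get("x", centroid.x)), float(props.get("y", centroid.y))
        elif geom.get("type") == "Point" and geom.get("coordinates"):
            ring = None  # contour-free nucleus (centroid +/- area only)
            x, y = map(float, geom["coordinates"][:2])
        else:
            raise GeometryParseError(
                f"{path}: feature {fid}: expected Polygon or Point geometry"
            )
        records.append(
            NucleusRecord(
                id=fid,
                x=x,
                y=y,
                cls=cls,
                contour=ring,
                area=float(props["area"]) if "area" in props else None,
            )
        )
    if n_unknown:
        logger.warning("%s: %d nuclei with unknown class mapped to 'other'", path, n_unknown)
    return SlideNucleiMap(
        slide_id=slide_id or str(meta.get("slide_id", path.stem)),
        nuclei=records,
        mpp=float(meta.get("mpp", mpp)),
    )


_CSV_REQUIRED = ("id", "x", "y", "class")


def _read_csv(
    path: Path, aliases: dict[str, str], slide_id: str | None, mpp: float
) -> SlideNucleiMap:
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    has_area = "area" in df.columns
    has_contour = "contour_wkt" in df.columns
    records: list[NucleusRecord] = []
    n_unknown = 0
    for _, row in df.iterrows():
        cls, known = _canonical_class(row["class"], aliases)
        n_unknown += not known
        contour = None
        if has_contour and isinstance(row["contour_wkt"], str) and row["contour_wkt"]:
            try:
                poly = _wkt.loads(row["contour_wkt"])
                contour = np.asarray(poly.exterior.coords[:-1], dtype=float)
            except Exception as exc:
                raise GeometryParseError(
                    f"{path}: nucleus {row['id']}: bad WKT contour ({exc})"
                ) from exc
        area = None
        if has_area and pd.notna(row["area"]):
            area = float(row["area"])
        records.append(
            NucleusRecord(
                id=str(row["id"]), x=float(row["x"]), y=float(row["y"]),
                cls=cls, contour=contour, area=area,
            )
        )
    if n_unknown:
        logger.warning("%s: %d nuclei with unknown class mapped to 'other'", path, n_unknown)
    return SlideNucleiMap(slide_id=slide_id or path.stem, nuclei=records, mpp=mpp)


def write_nuclei_map(smap: SlideNucleiMap, path: str | Path, format: str | None = None) -> None:
    """Write a nuclei map as GeoJSON FeatureCollection or flat CSV."""
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "geojson":
        features = []
        for r in smap.nuclei:
            if r.contour is not None:
                ring = np.vstack([r.contour, r.contour[:1]]).tolist()
                geometry = {"type": "Polygon", "coordinates": [ring]}
            else:  # point-only nucleus: a degenerate 3-vertex triangle is not
                # honest, so store a Point geometry instead
                geometry = {"type": "Point", "coordinates": [r.x, r.y]}
            props: dict = {"id": r.id, "class": r.cls, "x": r.x, "y": r.y}
            if r.area is not None:
                props["area"] = r.area
            features.append({"type": "Feature", "geometry": geometry, "properties": props})
        doc = {
            "type": "FeatureCollection",
            "properties": {"slide_id": smap.slide_id, "mpp": smap.mpp},
            "features": features,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    elif fmt == "csv":
        rows = []
        for r in smap.nuclei:
            rows.append(
                {
                    "id": r.id,
                    "x": r.x,
                    "y": r.y,
                    "class": r.cls,
                    "area": r.area if r.area is not None else "",
                    "contour_wkt": (
                        Polygon(r.contour).wkt if r.contour is not None else ""
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise NucleiIOError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

_STAGE_MAP = {"1": "I", "2": "II", "3": "III", "4": "IV",
              "i": "I", "ii": "II", "iii": "III", "iv": "IV"}


def _parse_stage(v) -> str:
    s = str(v).strip()
    return _STAGE_MAP.get(s.lower(), s.upper())


def read_clinical_table(
    path: str | Path, *, drop_incomplete: bool = False
) -> list[ClinicalRecord]:
    """Read the per-case clinical/survival CSV.

    Columns: ``case_id, age, sex, t_stage, n_stage, stage`` plus either
    ``ebv_copies`` (binarised at 4000 copies/mL) or ``ebv_group``, then
    ``<endpoint>_months`` / ``<endpoint>_event`` per endpoint.  With
    ``drop_incomplete`` cases missing all endpoint data are dropped (with a
    logged count), mirroring exclusion of cases lacking clinical follow-up.
    """
    df = pd.read_csv(path, dtype={"case_id": str})
    required = ["case_id", "age", "sex", "t_stage", "n_stage", "stage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    if "ebv_group" not in df.columns and "ebv_copies" not in df.columns:
        raise SchemaError(f"{path}: need ebv_copies or ebv_group column")

    records: list[ClinicalRecord] = []
    bad_cases: list[str] = []
    n_dropped = 0
    for _, row in df.iterrows():
        cid = str(row["case_id"])
        endpoints: dict[str, tuple[float, int]] = {}
        ok = True
        for ep in ENDPOINTS:
            tcol, ecol = f"{ep}_months", f"{ep}_event"
            if tcol in df.columns and ecol in df.columns:
                t, e = row[tcol], row[ecol]
                if pd.isna(t) or pd.isna(e):
                    continue
                t, e = float(t), float(e)
                if t <= 0 or e not in (0.0, 1.0):
                    ok = False
                    continue
                endpoints[ep] = (t, int(e))
        if not ok:
            bad_cases.append(cid)
            continue
        if drop_incomplete and not endpoints:
            n_dropped += 1
            continue
        if "ebv_group" in df.columns and pd.notna(row.get("ebv_group")):
            ebv = str(row["ebv_group"]).strip().lower()
        else:
            ebv = ebv_group_from_copies(float(row["ebv_copies"]))
        records.append(
            ClinicalRecord(
                case_id=cid,
                age=float(row["age"]),
                sex=str(row["sex"]).strip().lower(),
                t_stage=int(row["t_stage"]),
                n_stage=int(row["n_stage"]),
                stage=_parse_stage(row["stage"]),
                ebv_group=ebv,
                endpoints=endpoints,
            )
        )
    if bad_cases:
        raise ValidationError(
            f"{path}: negative time or non-binary event for case(s) {bad_cases}"
        )
    if n_dropped:
        logger.warning("%s: dropped %d case(s) without any endpoint data", path, n_dropped)
    return records


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Flatten clinical records into a DataFrame (one row per case)."""
    rows = []
    for r in records:
        row: dict = {
            "case_id": r.case_id, "age": r.age, "sex": r.sex,
            "t_stage": r.t_stage, "n_stage": r.n_stage, "stage": r.stage,
            "ebv_group": r.ebv_group,
        }
        for ep, (t, e) in r.endpoints.items():
            row[f"{ep}_months"] = t
            row[f"{ep}_event"] = e
        rows.append(row)
    return pd.DataFrame(rows)
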