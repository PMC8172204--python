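"""Pose-invariant geometric facial metrics.

All measurements are evaluated in an intrinsic face frame anchored on the
two tragions, so "horizontal" and "vertical" directions are invariant to
head roll, translation, and image scale. Horizontal distances are
normalized by the inter-tragion (ear-to-ear) distance, vertical distances
by the distance from the oral-commissure midpoint to the nasion (nose
root), and angles are reported in degrees, unnormalized.

For bilaterally paired metrics the left/right mean forms the symmetric
feature ``geom.<name>.sym``, and the absolute left/right difference,
normalized by the left/right mean, forms the asymmetry feature
``geom.<name>.asym``. Midline metrics yield ``.sym`` only. Because every
ingredient (frame projections, reference lengths) transforms homogeneously
under similarity maps, the resulting feature vector is similarity-invariant.

The default metric catalog covers 23 measurements of the periocular,
nasal, and perioral regions (e.g. inner/outer intercanthal distance,
palpebral fissure dimensions and slant, nose length/width, philtrum and
lip measurements, mouth width); it is a reconstruction of a standard
frontal-face anthropometric set and is fully overridable via a catalog
file (see :func:`read_catalog`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .landmarks import LandmarkSet

METRIC_KINDS = ("horizontal_distance", "vertical_distance", "angle")
LATERALITIES = ("paired", "midline")
NORMALIZATIONS = ("horizontal_ref", "vertical_ref", "none")

#: guard for unstable asymmetry ratios, relative to the inter-tragion length
ASYM_DENOMINATOR_GUARD = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when the landmark configuration makes a measurement undefined."""


class CatalogResolutionError(KeyError):
    """Raised when a metric definition does not resolve against a landmark set."""


@dataclass(frozen=True)
class MetricDefinition:
    """Declarative definition of one geometric measurement.

    ``landmarks`` holds 2 names for distances and 3 for angles (vertex listed
    second). For ``paired`` metrics, side-less base names are resolved by
    suffixing ``_L``/``_R``; names that already exist verbatim in the landmark
    set (midline points such as ``nasion``) are used as-is on both sides.
    """

    name: str
    kind: str
    landmarks: tuple[str, ...]
    laterality: str
    normalization: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "landmarks", tuple(self.landmarks))
        if self.kind not in METRIC_KINDS:
            raise ValueError(f"metric {self.name!r}: unknown kind {self.kind!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"metric {self.name!r}: unknown laterality {self.laterality!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"metric {self.name!r}: unknown normalization {self.normalization!r}")
        n_expected = 3 if self.kind == "angle" else 2
        if len(self.landmarks) != n_expected:
            raise ValueError(
                f"metric {self.name!r}: {self.kind} needs {n_expected} landmarks, "
                f"got {len(self.landmarks)}"
            )
        if self.kind == "angle" and self.normalization != "none":
            raise ValueError(f"metric {self.name!r}: angles carry normalization 'none'")


def _metric(name, kind, landmarks, laterality, normalization) -> MetricDefinition:
    return MetricDefinition(name, kind, tuple(landmarks), laterality, normalization)


#: default catalog: 23 metrics (11 paired -> 34 features with asymmetries)
DEFAULT_CATALOG: tuple[MetricDefinition, ...] = (
    _metric("intercanthal_outer", "horizontal_distance",
            ("canthus_outer_L", "canthus_outer_R"), "midline", "horizontal_ref"),
    _metric("intercanthal_inner", "horizontal_distance",
            ("canthus_inner_L", "canthus_inner_R"), "midline", "horizontal_ref"),
    _metric("palpebral_fissure_length", "horizontal_distance",
            ("canthus_inner", "canthus_outer"), "paired", "horizontal_ref"),
    _metric("palpebral_fissure_height", "vertical_distance",
            ("eyelid_upper", "eyelid_lower"), "paired", "vertical_ref"),
    _metric("palpebral_fissure_slant", "angle",
            ("canthus_outer", "canthus_inner", "nose_tip"), "paired", "none"),
    _metric("orbital_rim_height", "vertical_distance",
            ("eyebrow_mid", "eyelid_upper"), "paired", "vertical_ref"),
    _metric("eyebrow_length", "horizontal_distance",
            ("eyebrow_inner", "eyebrow_outer"), "paired", "horizontal_ref"),
    _metric("intereyebrow_distance", "horizontal_distance",
            ("eyebrow_inner_L", "eyebrow_inner_R"), "midline", "horizontal_ref"),
    _metric("nasal_bridge_offset", "horizontal_distance",
            ("bridge", "nasion"), "paired", "horizontal_ref"),
    _metric("nose_length", "vertical_distance",
            ("nasion", "nose_tip"), "midline", "vertical_ref"),
    _metric("nose_width", "horizontal_distance",
            ("alare_L", "alare_R"), "midline", "horizontal_ref"),
    _metric("ala_length", "horizontal_distance",
            ("nose_tip", "alare"), "paired", "horizontal_ref"),
    _metric("ala_height", "vertical_distance",
            ("alare", "ala_base"), "paired", "vertical_ref"),
    _metric("philtrum_length", "vertical_distance",
            ("subnasale", "labiale_superius"), "midline", "vertical_ref"),
    _metric("cupid_bow_width", "horizontal_distance",
            ("cupid_bow_L", "cupid_bow_R"), "midline", "horizontal_ref"),
    _metric("cupid_bow_depth", "vertical_distance",
            ("cupid_bow", "labiale_superius"), "paired", "vertical_ref"),
    _metric("mouth_width", "horizontal_distance",
            ("oral_commissure_L", "oral_commissure_R"), "midline", "horizontal_ref"),
    _metric("upper_lip_thickness", "vertical_distance",
            ("labiale_superius", "stomion_upper"), "midline", "vertical_ref"),
    _metric("lower_lip_thickness", "vertical_distance",
            ("stomion_lower", "labiale_inferius"), "midline", "vertical_ref"),
    _metric("lower_lip_height_lateral", "vertical_distance",
            ("lower_lip", "stomion_lower"), "paired", "vertical_ref"),
    _metric("ear_canthus_angle", "angle",
            ("tragion", "canthus_outer", "canthus_inner"), "paired", "none"),
    _metric("midface_width", "horizontal_distance",
            ("zygion_L", "zygion_R"), "midline", "horizontal_ref"),
    _metric("jaw_width", "horizontal_distance",
            ("gonion_L", "gonion_R"), "midline", "horizontal_ref"),
)


# --- intrinsic face frame ---------------------------------------------------

def face_frame(ls: LandmarkSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid frame (origin, x-axis, y-axis) anchored on the tragions.

    Origin is the mid-tragion point, the x-axis the unit vector from the left
    to the right tragion, and the y-axis its 90-degree rotation oriented
    toward the chin (checked against the oral-commissure midpoint).
    """
    t_l, t_r = ls.points["tragion_L"], ls.points["tragion_R"]
    d = t_r - t_l
    n = float(np.hypot(*d))
    scale = max(np.abs(np.concatenate([t_l, t_r])).max(), 1.0)
    if n <= 1e-12 * scale:
        raise DegenerateGeometryError(
            f"subject {ls.subject_id!r}: coincident tragions, face frame undefined"
        )
    origin = 0.5 * (t_l + t_r)
    u = d / n
    v = np.array([-u[1], u[0]])
    mouth_mid = 0.5 * (ls.points["oral_commissure_L"] + ls.points["oral_commissure_R"])
    if float(np.dot(v, mouth_mid - origin)) < 0.0:
        v = -v
    return origin, u, v


def frame_coords(ls: LandmarkSet) -> dict[str, np.ndarray]:
    """All landmark positions expressed in the intrinsic face frame."""
    origin, u, v = face_frame(ls)
    return {
        name: np.array([float(np.dot(p - origin, u)), float(np.dot(p - origin, v))])
        for name, p in ls.points.items()
    }


def reference_lengths(ls: LandmarkSet) -> dict[str, float]:
    """Normalization references.

    ``horizontal_ref`` is the ear-to-ear (inter-tragion) distance;
    ``vertical_ref`` the distance from the oral-commissure midpoint to the
    nasion (nose root).
    """
    t_l, t_r = ls.points["tragion_L"], ls.points["tragion_R"]
    horizontal = float(np.linalg.norm(t_r - t_l))
    mouth_mid = 0.5 * (ls.points["oral_commissure_L"] + ls.points["oral_commissure_R"])
    vertical = float(np.linalg.norm(ls.points["nasion"] - mouth_mid))
    if horizontal <= 0.0:
        raise DegenerateGeometryError(
            f"subject {ls.subject_id!r}: zero inter-tragion reference length"
        )
    if vertical <= 0.0:
        raise DegenerateGeometryError(
            f"subject {ls.subject_id!r}: zero commissure-midpoint-to-nasion reference length"
        )
    return {"horizontal_ref": horizontal, "vertical_ref": vertical}


# --- metric evaluation ------------------------------------------------------

def _resolve(ls: LandmarkSet, name: str, side: str | None, metric: str) -> str:
    if side is not None and f"{name}_{side}" in ls.points:
        return f"{name}_{side}"
    if name in ls.points:
        return name
    raise CatalogResolutionError(
        f"metric {metric!r}: landmark {name!r} does not resolve for subject {ls.subject_id!r}"
    )


def _angle_deg(vertex: np.ndarray, a: np.ndarray, b: np.ndarray, metric: str) -> float:
    va, vb = a - vertex, b - vertex
    na, nb = float(np.linalg.norm(va)), float(np.linalg.norm(vb))
    if na <= 1e-12 or nb <= 1e-12:
        raise DegenerateGeometryError(f"metric {metric!r}: zero-length angle arm")
    c = float(np.dot(va, vb)) / (na * nb)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def evaluate_metric(
    ls: LandmarkSet,
    definition: MetricDefinition,
    frame: Mapping[str, np.ndarray] | None = None,
) -> tuple[float, ...]:
    """Raw (unnormalized) metric values: ``(left, right)`` if paired, else ``(value,)``.

    Distances are axis-aligned in the intrinsic face frame; angles are the
    interior angle at the vertex landmark (listed second), in degrees.
    """
    if frame is None:
        frame = frame_coords(ls)
    sides: tuple[str | None, ...] = ("L", "R") if definition.laterality == "paired" else (None,)
    values = []
    for side in sides:
        names = [_resolve(ls, n, side, definition.name) for n in definition.landmarks]
        pts = [frame[n] for n in names]
        if definition.kind == "horizontal_distance":
            values.append(abs(pts[0][0] - pts[1][0]))
        elif definition.kind == "vertical_distance":
            values.append(abs(pts[0][1] - pts[1][1]))
        else:
            values.append(_angle_deg(pts[1], pts[0], pts[2], definition.name))
    return tuple(float(v) for v in values)


def extract_geometric_features(
    ls: LandmarkSet,
    catalog: Sequence[MetricDefinition] | None = None,
) -> dict[str, float]:
    """Normalized geometric feature vector for one subject.

    Returns an ordered mapping with ``geom.<metric>.sym`` for every metric
    (left/right mean, or the midline value, divided by its normalization
    reference; angles undivided) and ``geom.<metric>.asym`` for paired
    metrics (``|L - R| / mean(L, R)``). Output order follows the catalog.
    """
    if catalog is None:
        catalog = DEFAULT_CATALOG
    refs = reference_lengths(ls)
    frame = frame_coords(ls)
    divisors = {
        "horizontal_ref": refs["horizontal_ref"],
        "vertical_ref": refs["vertical_ref"],
        "none": 1.0,
    }
    out: dict[str, float] = {}
    for d in catalog:
        raw = evaluate_metric(ls, d, frame)
        div = divisors[d.normalization]
        if d.laterality == "paired":
            left, right = raw
            mean = 0.5 * (left + right)
            if d.kind != "angle" and mean < ASYM_DENOMINATOR_GUARD * refs["horizontal_ref"]:
                raise DegenerateGeometryError(
                    f"metric {d.name!r}: left/right mean collapses to zero for "
                    f"subject {ls.subject_id!r}"
                )
            if mean <= 0.0:
                raise DegenerateGeometryError(
                    f"metric {d.name!r}: degenerate zero mean for subject {ls.subject_id!r}"
                )
            out[f"geom.{d.name}.sym"] = mean / div
            out[f"geom.{d.name}.asym"] = abs(left - right) / mean
        else:
            out[f"geom.{d.name}.sym"] = raw[0] / div
    return out


def feature_names(catalog: Sequence[MetricDefinition] | None = None) -> list[str]:
    """Feature-name order produced by :func:`extract_geometric_features`."""
    if catalog is None:
        catalog = DEFAULT_CATALOG
    names = []
    for d in catalog:
        names.append(f"geom.{d.name}.sym")
        if d.laterality == "paired":
            names.append(f"geom.{d.name}.asym")
    return names


# --- catalog files ----------------------------------------------------------

def write_catalog(catalog: Iterable[MetricDefinition], path: str | Path) -> None:
    """Write a metric catalog as YAML (round-trips bit-exactly)."""
    records = [
        {
            "name": d.name,
            "kind": d.kind,
            "landmarks": list(d.landmarks),
            "laterality": d.laterality,
            "normalization": d.normalization,
        }
        for d in catalog
    ]
    Path(path).write_text(yaml.safe_dump(records, sort_keys=False))


def read_catalog(path: str | Path) -> tuple[MetricDefinition, ...]:
    """Read a metric catalog written by :func:`write_catalog`."""
    records = yaml.safe_load(Path(path).read_text())
    return tuple(
        MetricDefinition(
            name=r["name"], kind=r["kind"], landmarks=tuple(r["landmarks"]),
            laterality=r["laterality"], normalization=r["normalization"],
        )
        for r in records
    )
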