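"""Facial landmark scheme and per-subject landmark containers.

The package works on a fixed 44-point frontal-face annotation scheme: 33
"inner" landmarks (periocular/eyebrow, nasal and perioral points) that are
used both for geometric metrics and for local texture descriptors, plus 11
"outer" landmarks (ears, cheekbones, jaw angles, chin) that serve as
geometric references only. Coordinates are 2-D pixel positions in image
coordinates: origin at the top-left corner, x rightward, y downward,
0-based. The ``_L``/``_R`` suffixes refer to the image side (the subject
faces the camera, so the subject's right side carries the ``_L`` suffix).

The module also publishes the canonical template layout used by the
synthetic cohort generator: a mirror-symmetric 44-point face on a 256x256
canvas with a 160-px inter-tragion distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

# --- the 44-point scheme ----------------------------------------------------

#: bilaterally paired inner landmarks (13 pairs = 26 points)
PAIRED_BASES_INNER: tuple[str, ...] = (
    "eyebrow_inner", "eyebrow_mid", "eyebrow_outer",
    "canthus_inner", "canthus_outer", "eyelid_upper", "eyelid_lower",
    "bridge", "alare", "ala_base",
    "oral_commissure", "cupid_bow", "lower_lip",
)
#: midline inner landmarks (7 points)
MIDLINE_INNER: tuple[str, ...] = (
    "nasion", "nose_tip", "subnasale",
    "labiale_superius", "stomion_upper", "stomion_lower", "labiale_inferius",
)
#: bilaterally paired outer landmarks (5 pairs = 10 points)
PAIRED_BASES_OUTER: tuple[str, ...] = (
    "tragion", "ear_superior", "ear_inferior", "gonion", "zygion",
)
#: midline outer landmarks (1 point)
MIDLINE_OUTER: tuple[str, ...] = ("menton",)

PAIRED_BASES: tuple[str, ...] = PAIRED_BASES_INNER + PAIRED_BASES_OUTER

#: left/right pairing table, (left-name, right-name)
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (f"{b}_L", f"{b}_R") for b in PAIRED_BASES
)

#: the 33 inner landmarks (texture subset), in canonical order
INNER_LANDMARKS: tuple[str, ...] = tuple(
    [f"{b}_{s}" for b in PAIRED_BASES_INNER for s in ("L", "R")]
) + MIDLINE_INNER

#: the 11 outer landmarks
OUTER_LANDMARKS: tuple[str, ...] = tuple(
    [f"{b}_{s}" for b in PAIRED_BASES_OUTER for s in ("L", "R")]
) + MIDLINE_OUTER

#: all 44 landmark names, canonical order (inner first)
LANDMARK_NAMES: tuple[str, ...] = INNER_LANDMARKS + OUTER_LANDMARKS

#: landmarks every analysis relies on (face frame + normalization references)
ANCHOR_LANDMARKS: tuple[str, ...] = (
    "tragion_L", "tragion_R", "nasion", "oral_commissure_L", "oral_commissure_R",
)

# --- canonical template layout (256x256 canvas, inter-tragion 160 px) -------

TEMPLATE_CANVAS: int = 256

#: mirror-symmetric about x = 128
TEMPLATE_POINTS: dict[str, tuple[float, float]] = {
    # eyebrows
    "eyebrow_inner_L": (108.0, 92.0), "eyebrow_inner_R": (148.0, 92.0),
    "eyebrow_mid_L": (94.0, 88.0), "eyebrow_mid_R": (162.0, 88.0),
    "eyebrow_outer_L": (80.0, 92.0), "eyebrow_outer_R": (176.0, 92.0),
    # eyes
    "canthus_inner_L": (110.0, 108.0), "canthus_inner_R": (146.0, 108.0),
    "canthus_outer_L": (84.0, 106.0), "canthus_outer_R": (172.0, 106.0),
    "eyelid_upper_L": (97.0, 103.0), "eyelid_upper_R": (159.0, 103.0),
    "eyelid_lower_L": (97.0, 112.0), "eyelid_lower_R": (159.0, 112.0),
    # nose
    "nasion": (128.0, 102.0),
    "bridge_L": (122.0, 118.0), "bridge_R": (134.0, 118.0),
    "nose_tip": (128.0, 140.0),
    "subnasale": (128.0, 150.0),
    "alare_L": (113.0, 138.0), "alare_R": (143.0, 138.0),
    "ala_base_L": (116.0, 144.0), "ala_base_R": (140.0, 144.0),
    # mouth
    "oral_commissure_L": (102.0, 172.0), "oral_commissure_R": (154.0, 172.0),
    "cupid_bow_L": (121.0, 163.0), "cupid_bow_R": (135.0, 163.0),
    "labiale_superius": (128.0, 167.0),
    "stomion_upper": (128.0, 173.0),
    "stomion_lower": (128.0, 176.0),
    "labiale_inferius": (128.0, 185.0),
    "lower_lip_L": (115.0, 179.0), "lower_lip_R": (141.0, 179.0),
    # outer
    "tragion_L": (48.0, 120.0), "tragion_R": (208.0, 120.0),
    "ear_superior_L": (46.0, 100.0), "ear_superior_R": (210.0, 100.0),
    "ear_inferior_L": (50.0, 140.0), "ear_inferior_R": (206.0, 140.0),
    "zygion_L": (58.0, 128.0), "zygion_R": (198.0, 128.0),
    "gonion_L": (74.0, 180.0), "gonion_R": (182.0, 180.0),
    "menton": (128.0, 218.0),
}


class LandmarkValidationError(ValueError):
    """Raised when a landmark set violates the 44-point scheme invariants."""


@dataclass
class LandmarkSet:
    """A named 44-point landmark configuration for one subject.

    Parameters
    ----------
    subject_id : str
        Identifier used to join against cohort metadata.
    points : mapping of str to array-like
        Landmark name -> (x, y) pixel position, image coordinates.
    laterality_pairs : sequence of (left, right) name pairs
        Defaults to the package's pairing table.
    inner_subset : sequence of str
        The 33 inner landmark names used for texture descriptors.
    """

    subject_id: str
    points: dict[str, np.ndarray]
    laterality_pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    inner_subset: tuple[str, ...] = INNER_LANDMARKS

    def __post_init__(self) -> None:
        self.points = {
            str(k): np.asarray(v, dtype=float).reshape(2) for k, v in self.points.items()
        }
        self.laterality_pairs = tuple((str(a), str(b)) for a, b in self.laterality_pairs)
        self.inner_subset = tuple(str(n) for n in self.inner_subset)

    # -- invariants ----------------------------------------------------------

    def validate(self) -> "LandmarkSet":
        """Check the scheme invariants, raising :class:`LandmarkValidationError`."""
        if len(self.points) != 44:
            raise LandmarkValidationError(
                f"subject {self.subject_id!r}: expected 44 landmarks, got {len(self.points)}"
            )
        for name, xy in self.points.items():
            if not np.all(np.isfinite(xy)):
                raise LandmarkValidationError(
                    f"subject {self.subject_id!r}: non-finite coordinates for {name!r}"
                )
        for left, right in self.laterality_pairs:
            if left not in self.points or right not in self.points:
                raise LandmarkValidationError(
                    f"subject {self.subject_id!r}: pairing ({left!r}, {right!r}) "
                    "does not resolve to present landmarks"
                )
            if left == right:
                raise LandmarkValidationError(
                    f"subject {self.subject_id!r}: degenerate pairing {left!r}"
                )
        for name in ANCHOR_LANDMARKS:
            if name not in self.points:
                raise LandmarkValidationError(
                    f"subject {self.subject_id!r}: anchor landmark {name!r} missing"
                )
        if len(self.inner_subset) != 33:
            raise LandmarkValidationError(
                f"subject {self.subject_id!r}: inner subset must have 33 names, "
                f"got {len(self.inner_subset)}"
            )
        outer = set(OUTER_LANDMARKS)
        for name in self.inner_subset:
            if name not in self.points:
                raise LandmarkValidationError(
                    f"subject {self.subject_id!r}: inner landmark {name!r} missing"
                )
            if name in outer:
                raise LandmarkValidationError(
                    f"subject {self.subject_id!r}: inner subset contains the "
                    f"ear/contour landmark {name!r}"
                )
        return self

    # -- convenience ---------------------------------------------------------

    def coords(self, names: Iterable[str] | None = None) -> np.ndarray:
        """Stack coordinates (n, 2) in the given (default canonical) order."""
        if names is None:
            names = [n for n in LANDMARK_NAMES if n in self.points]
        return np.stack([self.points[n] for n in names])

    def with_points(self, points: Mapping[str, np.ndarray], subject_id: str | None = None) -> "LandmarkSet":
        return LandmarkSet(
            subject_id=subject_id if subject_id is not None else self.subject_id,
            points={k: np.asarray(v, dtype=float) for k, v in points.items()},
            laterality_pairs=self.laterality_pairs,
            inner_subset=self.inner_subset,
        )

    def transformed(self, scale: float = 1.0, rotation_deg: float = 0.0,
                    translation: tuple[float, float] = (0.0, 0.0),
                    center: tuple[float, float] | None = None) -> "LandmarkSet":
        """Apply a similarity transform (about ``center``, default the centroid)."""
        theta = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        coords = self.coords(list(self.points))
        c = coords.mean(axis=0) if center is None else np.asarray(center, dtype=float)
        moved = (coords - c) @ rot.T * float(scale) + c + np.asarray(translation, dtype=float)
        return self.with_points(dict(zip(self.points, moved)))


def template_landmarks(subject_id: str = "template") -> LandmarkSet:
    """The canonical mirror-symmetric 44-point template layout."""
    return LandmarkSet(subject_id, {k: np.array(v) for k, v in TEMPLATE_POINTS.items()}).validate()


# --- file formats -----------------------------------------------------------

def read_landmark_file(path: str | Path, subject_id: str | None = None) -> LandmarkSet:
    """Read a per-subject landmark file.

    CSV files need a ``landmark,x,y`` header; JSON files map name -> [x, y].
    The subject id defaults to the file stem.
    """
    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        points = {str(k): np.asarray(v, dtype=float) for k, v in data.items()}
    else:
        points = {}
        lines = path.read_text().strip().splitlines()
        header = [h.strip() for h in lines[0].split(",")]
        if header[:3] != ["landmark", "x", "y"]:
            raise ValueError(f"{path}: expected header 'landmark,x,y', got {lines[0]!r}")
        for line in lines[1:]:
            if not line.strip():
                continue
            name, x, y = [t.strip() for t in line.split(",")]
            points[name] = np.array([float(x), float(y)])
    return LandmarkSet(sid, points).validate()


def write_landmark_csv(ls: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set as ``landmark,x,y`` CSV (canonical order)."""
    path = Path(path)
    rows = ["landmark,x,y"]
    for name in LANDMARK_NAMES:
        x, y = ls.points[name]
        rows.append(f"{name},{x:.9g},{y:.9g}")
    path.write_text("\n".join(rows) + "\n")
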