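"""Population-average appearance images.

A cohort's landmark sets are aligned by generalized Procrustes analysis
under similarity transforms (translation + rotation + uniform scale, no
reflection) into a consensus shape; each face image is then warped onto
the consensus with a piecewise-affine map over a Delaunay triangulation of
the 44 landmarks plus 8 fixed canvas-border anchors, and the warped images
are averaged pixel-wise. One atlas is typically built per diagnosis x
ethnicity selection; atlases built on a shared consensus are directly
comparable pixel by pixel.

The consensus is canonicalized (centroid at the origin, unit centroid
size, inter-tragion axis horizontal with the chin toward +y), which makes
it independent of subject ordering. The default canvas is 256x256 pixels
with the consensus scaled to a 160-px inter-tragion distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import PiecewiseAffineTransform, warp

from .landmarks import LandmarkSet
from .texture import to_grayscale

GPA_TOL = 1e-8
GPA_MAX_ITER = 100

DEFAULT_CANVAS = 256
DEFAULT_INTERTRAGION = 160.0


@dataclass
class ConsensusShape:
    """Mean landmark configuration in a canonical frame.

    ``coords`` has unit centroid size, centroid at the origin, and the
    inter-tragion axis along +x. ``transforms`` records, per input, the
    similarity parameters aligning that subject onto the consensus.
    """

    names: tuple[str, ...]
    coords: np.ndarray                      # (n_landmarks, 2)
    transforms: list[dict]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: self.coords[i] for i, n in enumerate(self.names)}

    def to_json_dict(self) -> dict:
        return {
            "names": list(self.names),
            "coords": self.coords.tolist(),
            "transforms": self.transforms,
        }


def _center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    c = coords.mean(axis=0)
    centered = coords - c
    size = float(np.sqrt((centered ** 2).sum()))
    if size <= 0:
        raise ValueError("degenerate landmark configuration (zero centroid size)")
    return centered / size, c, size


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) maximizing alignment of ``a @ R`` with ``b``."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    fix = np.diag([1.0, d])
    return u @ fix @ vt


def _align(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Similarity-align centered unit-size shape ``a`` onto shape ``b``."""
    rot = _rotation_onto(a, b)
    rotated = a @ rot
    s = float((rotated * b).sum()) / float((rotated ** 2).sum())
    return s * rotated


def _canonicalize(coords: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Centroid at origin, unit size, tragion axis along +x, chin toward +y."""
    shape, _, _ = _center_and_scale(coords)
    idx = {n: i for i, n in enumerate(names)}
    t = shape[idx["tragion_R"]] - shape[idx["tragion_L"]]
    theta = np.arctan2(t[1], t[0])
    rot = np.array([[np.cos(-theta), -np.sin(-theta)], [np.sin(-theta), np.cos(-theta)]])
    shape = shape @ rot.T
    return shape


def mean_shape(landmark_sets: Sequence[LandmarkSet]) -> ConsensusShape:
    """Generalized Procrustes consensus of two or more landmark sets.

    Iterates align-to-mean under similarity transforms until the consensus
    moves less than 1e-8 (or 100 iterations), then canonicalizes the frame;
    the result is order-independent up to numerical tolerance.
    """
    if len(landmark_sets) < 2:
        raise ValueError("mean_shape needs at least two landmark sets")
    names = tuple(sorted(landmark_sets[0].points))
    for ls in landmark_sets[1:]:
        if tuple(sorted(ls.points)) != names:
            raise ValueError(
                f"landmark names of subject {ls.subject_id!r} do not match the first subject"
            )
    raw = [ls.coords(names) for ls in landmark_sets]
    shapes = [_center_and_scale(c)[0] for c in raw]
    mean = _canonicalize(shapes[0], names)
    for _ in range(GPA_MAX_ITER):
        aligned = [_align(s, mean) for s in shapes]
        new_mean = _canonicalize(np.mean(aligned, axis=0), names)
        delta = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        if delta < GPA_TOL:
            break

    transforms = []
    for coords in raw:
        shape, centroid, size = _center_and_scale(coords)
        rot = _rotation_onto(shape, mean)
        rotated = shape @ rot
        s = float((rotated * mean).sum()) / float((rotated ** 2).sum())
        transforms.append(
            {
                "scale": s / size,
                "rotation_deg": float(np.degrees(np.arctan2(rot[1, 0], rot[0, 0]))),
                "source_centroid": centroid.tolist(),
            }
        )
    return ConsensusShape(names=names, coords=mean, transforms=transforms)


def consensus_to_canvas(
    shape: ConsensusShape,
    canvas: int = DEFAULT_CANVAS,
    intertragion: float = DEFAULT_INTERTRAGION,
) -> dict[str, np.ndarray]:
    """Place the consensus on a pixel canvas (centroid at the canvas center)."""
    idx = {n: i for i, n in enumerate(shape.names)}
    d = float(np.linalg.norm(shape.coords[idx["tragion_R"]] - shape.coords[idx["tragion_L"]]))
    s = intertragion / d
    center = np.array([canvas / 2.0, canvas / 2.0])
    return {n: shape.coords[idx[n]] * s + center for n in shape.names}


def _border_anchors(width: int, height: int) -> np.ndarray:
    w, h = width - 1.0, height - 1.0
    return np.array(
        [
            [0.0, 0.0], [w / 2, 0.0], [w, 0.0], [w, h / 2],
            [w, h], [w / 2, h], [0.0, h], [0.0, h / 2],
        ]
    )


def warp_to_shape(
    image: np.ndarray,
    src: LandmarkSet,
    dst_points: dict[str, np.ndarray],
    canvas: int = DEFAULT_CANVAS,
    background: float = 0.0,
) -> np.ndarray:
    """Piecewise-affine warp of ``image`` onto the destination landmark layout.

    Control points are the 44 landmarks plus 8 border anchors of the source
    image and of the destination canvas; sampling is bilinear and pixels
    outside all triangles take the ``background`` value.
    """
    gray = to_grayscale(image)
    h, w = gray.shape
    names = [n for n in sorted(src.points) if n in dst_points]
    src_pts = np.vstack([np.stack([src.points[n] for n in names]), _border_anchors(w, h)])
    dst_pts = np.vstack([np.stack([np.asarray(dst_points[n], dtype=float) for n in names]),
                         _border_anchors(canvas, canvas)])
    # the transform maps output (canvas) coordinates -> input coordinates
    if hasattr(PiecewiseAffineTransform, "from_estimate"):
        tform = PiecewiseAffineTransform.from_estimate(dst_pts, src_pts)
        if not tform:
            raise ValueError("degenerate triangulation: could not estimate piecewise-affine warp")
    else:  # scikit-image < 0.26
        tform = PiecewiseAffineTransform()
        if not tform.estimate(dst_pts, src_pts):
            raise ValueError("degenerate triangulation: could not estimate piecewise-affine warp")
    return warp(
        gray, tform, output_shape=(canvas, canvas), order=1,
        cval=background, preserve_range=True,
    )


def population_mean_image(
    subjects: Sequence[tuple[np.ndarray, LandmarkSet]],
    consensus: ConsensusShape | None = None,
    canvas: int = DEFAULT_CANVAS,
    intertragion: float = DEFAULT_INTERTRAGION,
    background: float = 0.0,
) -> tuple[np.ndarray, ConsensusShape]:
    """Pixel-wise mean of all subject images warped onto the consensus shape.

    ``subjects`` is a sequence of ``(image, landmark_set)`` pairs. A shared
    ``consensus`` may be passed so that several atlases (e.g. the two
    diagnostic classes) are directly comparable; by default the consensus is
    computed from the selection itself (a single subject is its own
    consensus). Returns ``(atlas, consensus)`` with the atlas as float in the
    input intensity range.
    """
    if len(subjects) == 0:
        raise ValueError("empty selection")
    if consensus is None:
        if len(subjects) == 1:
            ls = subjects[0][1]
            names = tuple(sorted(ls.points))
            coords = _canonicalize(ls.coords(names), names)
            consensus = ConsensusShape(names=names, coords=coords, transforms=[{}])
        else:
            consensus = mean_shape([ls for _, ls in subjects])
    dst = consensus_to_canvas(consensus, canvas, intertragion)
    acc = np.zeros((canvas, canvas))
    for image, ls in subjects:
        acc += warp_to_shape(image, ls, dst, canvas, background)
    return acc / len(subjects), consensus
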