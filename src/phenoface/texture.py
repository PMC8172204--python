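"""Multi-scale block local binary pattern (MB-LBP) texture descriptors.

Local appearance around each of the 33 inner facial landmarks is encoded by
comparing the mean intensity of the patch centered on the landmark with the
mean intensities of its eight neighboring patches, at three nested block
sizes R1 < R2 < R3. The comparisons are thresholded into an 8-bit code,
which makes the descriptor invariant to strictly increasing intensity
transforms (exactly so under the strict ``gt`` rule; under the default
``ge`` rule whenever no ties are created) while staying sensitive to lines,
shadows, and local intensity contrast.

Two representations are supported:

``bits`` (default)
    The raw 8 comparison bits per landmark per resolution
    (33 landmarks x 3 resolutions x 8 bits = 792 features), matching a
    single code per landmark and scale.
``histogram``
    The normalized 256-bin histogram of MB-LBP codes computed at every
    pixel of a ``(3 * block)``-sized window around the landmark.

Block sizes default to 3, 5, 9 pixels for a 200-px inter-tragion face and,
with ``scale_normalize`` on, are rescaled to each subject's inter-tragion
distance (rounded to the nearest odd integer, minimum 3) so that
descriptors are comparable across image resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.ndimage import uniform_filter

from .landmarks import LandmarkSet

#: neighbor patches enumerated clockwise from top-left, as (row, col) offsets
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)

GRAY_WEIGHTS = (0.299, 0.587, 0.114)


class LandmarkOutOfBoundsError(ValueError):
    """Raised when a landmark falls outside the image."""


@dataclass(frozen=True)
class TexturePatchConfig:
    """Configuration of the MB-LBP descriptor.

    ``block_sizes`` are pixel sizes for a face whose inter-tragion distance is
    ``reference_intertragion``; with ``scale_normalize`` they are treated as
    fractions of the inter-tragion distance and resolved per subject.
    """

    block_sizes: tuple[int, int, int] = (3, 5, 9)
    comparison_rule: str = "ge"
    representation: str = "bits"
    scale_normalize: bool = True
    reference_intertragion: float = 200.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        if self.comparison_rule not in ("ge", "gt"):
            raise ValueError(f"unknown comparison rule {self.comparison_rule!r}")
        if self.representation not in ("bits", "histogram"):
            raise ValueError(f"unknown representation {self.representation!r}")
        sizes = self.block_sizes
        if len(sizes) != 3 or not (sizes[0] < sizes[1] < sizes[2]):
            raise ValueError("block sizes must be three strictly increasing integers")
        if any(b < 3 or b % 2 == 0 for b in sizes):
            raise ValueError("block sizes must be odd and >= 3")

    def resolved_block_sizes(self, intertragion: float) -> tuple[int, int, int]:
        """Block sizes for a subject, after optional scale normalization."""
        if not self.scale_normalize:
            return self.block_sizes
        out = []
        for b in self.block_sizes:
            scaled = b * float(intertragion) / self.reference_intertragion
            odd = max(3, int(2 * round((scaled - 1) / 2) + 1))
            out.append(odd)
        return tuple(out)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance image, float.

    RGB(A) input is converted with Y = 0.299 R + 0.587 G + 0.114 B; grayscale
    input passes through unchanged (as float).
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        return arr.astype(float)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        r, g, b = (arr[..., i].astype(float) for i in range(3))
        return GRAY_WEIGHTS[0] * r + GRAY_WEIGHTS[1] * g + GRAY_WEIGHTS[2] * b
    raise ValueError(f"unsupported image shape {arr.shape}")


def block_means(image: np.ndarray, center: tuple[float, float], block_size: int) -> np.ndarray:
    """3x3 grid of mean intensities of blocks tiled around ``center``.

    ``center`` is (x, y) in image coordinates and is rounded to the nearest
    pixel; pixels outside the image are handled by edge replication.
    """
    gray = to_grayscale(image)
    h, w = gray.shape
    x, y = center
    col, row = int(round(float(x))), int(round(float(y)))
    if not (0 <= col < w and 0 <= row < h):
        raise LandmarkOutOfBoundsError(
            f"center ({x}, {y}) outside image bounds {w}x{h}"
        )
    b = int(block_size)
    half = b // 2
    pad = b + half
    padded = np.pad(gray, pad, mode="edge")
    out = np.empty((3, 3))
    for i, dr in enumerate((-1, 0, 1)):
        for j, dc in enumerate((-1, 0, 1)):
            r0 = row + pad + dr * b - half
            c0 = col + pad + dc * b - half
            out[i, j] = padded[r0:r0 + b, c0:c0 + b].mean()
    return out


def mblbp_code(grid: np.ndarray, rule: str = "ge") -> tuple[int, np.ndarray]:
    """8-bit MB-LBP code from a 3x3 grid of block means.

    Neighbors are enumerated clockwise from the top-left patch; bit ``i`` is 1
    iff the neighbor mean compares (``>=`` for rule ``ge``, ``>`` for ``gt``)
    against the center mean, and contributes ``2 ** (7 - i)`` to the code.
    Returns ``(code, bits)``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (3, 3) or not np.all(np.isfinite(grid)):
        raise ValueError("grid must be a finite 3x3 array")
    center = grid[1, 1]
    bits = np.empty(8, dtype=np.uint8)
    for i, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        nb = grid[1 + dr, 1 + dc]
        bits[i] = (nb >= center) if rule == "ge" else (nb > center)
    code = int(sum(int(bit) << (7 - i) for i, bit in enumerate(bits)))
    return code, bits


def _code_image(gray: np.ndarray, block: int, rule: str) -> np.ndarray:
    """MB-LBP code at every pixel (edge-replicated borders)."""
    h, w = gray.shape
    pad = block + block // 2
    padded = np.pad(gray, pad, mode="edge")
    means = uniform_filter(padded, size=block)
    center = means[pad:pad + h, pad:pad + w]
    codes = np.zeros((h, w), dtype=np.uint8)
    for i, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        nb = means[pad + dr * block: pad + dr * block + h,
                   pad + dc * block: pad + dc * block + w]
        bit = (nb >= center) if rule == "ge" else (nb > center)
        codes |= bit.astype(np.uint8) << (7 - i)
    return codes


def landmark_descriptor(
    image: np.ndarray,
    ls: LandmarkSet,
    cfg: TexturePatchConfig | None = None,
) -> dict[str, float]:
    """MB-LBP texture descriptor over the 33 inner landmarks.

    In ``bits`` mode, features are named ``lbp.<landmark>.R<k>.b<i>`` with
    ``k`` in 1..3 and ``i`` in 0..7; in ``histogram`` mode
    ``lbp.<landmark>.R<k>.h<j>`` with ``j`` in 0..255, each landmark-resolution
    histogram summing to 1.
    """
    if cfg is None:
        cfg = TexturePatchConfig()
    gray = to_grayscale(image)
    h, w = gray.shape
    intertragion = float(np.linalg.norm(ls.points["tragion_R"] - ls.points["tragion_L"]))
    sizes = cfg.resolved_block_sizes(intertragion)

    for name in ls.inner_subset:
        x, y = ls.points[name]
        if not (0 <= round(x) < w and 0 <= round(y) < h):
            raise LandmarkOutOfBoundsError(
                f"landmark {name!r} of subject {ls.subject_id!r} outside image bounds"
            )

    out: dict[str, float] = {}
    if cfg.representation == "bits":
        padded = {}
        for b in set(sizes):
            pad = b + b // 2
            padded[b] = (np.pad(gray, pad, mode="edge"), pad)
        for name in ls.inner_subset:
            x, y = ls.points[name]
            col, row = int(round(float(x))), int(round(float(y)))
            for k, b in enumerate(sizes, start=1):
                arr, pad = padded[b]
                half = b // 2
                grid = np.empty((3, 3))
                for gi, dr in enumerate((-1, 0, 1)):
                    for gj, dc in enumerate((-1, 0, 1)):
                        r0 = row + pad + dr * b - half
                        c0 = col + pad + dc * b - half
                        grid[gi, gj] = arr[r0:r0 + b, c0:c0 + b].mean()
                _, bits = mblbp_code(grid, cfg.comparison_rule)
                for i, bit in enumerate(bits):
                    out[f"lbp.{name}.R{k}.b{i}"] = float(bit)
    else:
        code_imgs = {b: _code_image(gray, b, cfg.comparison_rule) for b in set(sizes)}
        for name in ls.inner_subset:
            x, y = ls.points[name]
            col, row = int(round(float(x))), int(round(float(y)))
            for k, b in enumerate(sizes, start=1):
                win = 3 * b
                r0, r1 = max(0, row - win // 2), min(h, row - win // 2 + win)
                c0, c1 = max(0, col - win // 2), min(w, col - win // 2 + win)
                codes = code_imgs[b][r0:r1, c0:c1].ravel()
                hist = np.bincount(codes, minlength=256).astype(float)
                hist /= hist.sum()
                for j in range(256):
                    out[f"lbp.{name}.R{k}.h{j}"] = hist[j]
    return out


def descriptor_feature_names(ls: LandmarkSet, cfg: TexturePatchConfig | None = None) -> list[str]:
    """Feature-name order produced by :func:`landmark_descriptor` (bits mode)."""
    if cfg is None:
        cfg = TexturePatchConfig()
    if cfg.representation == "bits":
        return [
            f"lbp.{name}.R{k}.b{i}"
            for name in ls.inner_subset for k in (1, 2, 3) for i in range(8)
        ]
    return [
        f"lbp.{name}.R{k}.h{j}"
        for name in ls.inner_subset for k in (1, 2, 3) for j in range(256)
    ]
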