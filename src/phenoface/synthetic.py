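"""Synthetic face-cohort generator with planted, calibrated class structure.

The generator emulates a two-class (Noonan-like ``NS`` vs Williams-Beuren-
like ``WBS``) frontal-photograph cohort with four ethnicity strata, so that
every stage of the pipeline — landmark files, geometric metrics, texture
descriptors, selection, stratified evaluation, atlases — can be exercised
and validated without patient data. Strata are abstract signal-modulation
groups, not renderings of ethnic appearance.

Class structure is planted in *landmark space*, not feature space: each
configured geometric effect displaces specific template landmarks (e.g.
moving the inner canthi apart for a telecanthus-like effect), so the whole
extraction path is part of the loop. The displacement magnitude that
realizes a requested standardized effect size (class-mean difference in
units of the feature's jitter-induced noise SD) is calibrated numerically
per template: a directional derivative gives the feature-per-pixel slope,
and a Monte-Carlo run under the configured landmark jitter gives the noise
SD. Class-dependent local texture is planted by stamping high-frequency
patterns (stripes or spot grids) near designated inner landmarks of one
class. On top of the planted structure every subject receives independent
Gaussian landmark jitter, a random similarity transform (rotation, uniform
scale, translation), and Gaussian intensity noise.

The generator also emits a ground-truth object listing, per planted
signal, one primary feature with its per-stratum standardized effect size
(for texture stamps, the most responsive descriptor bit at calibration);
every further feature whose standardized class difference reaches 0.5 in
a calibration run of the full generative model is reported as a
correlated carrier (planting in landmark space necessarily echoes into
features that share landmarks, normalization references, or rendered
pixels). The approximate Bayes accuracy of the planted model is computed
as a Gaussian discriminant over primaries and carriers jointly, with a
shrinkage-estimated covariance and equal class priors.

Defaults mirror the reference study conditions: 286 WBS + 161 NS subjects
split 28/26/121/111 and 35/40/40/46 across African-descent, Asian,
Caucasian, and Latin-American strata; six geometric effects of
standardized size 1.5 (NS: wider inner-canthal spacing, higher brow;
WBS: wider mouth, thicker lower lip, shorter nose, more down-slanted
palpebral fissures) with some effects zeroed per stratum; and two texture
stamps (stripes at the nasion for WBS, a spot grid at the upper-lip
midpoint for NS).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon
from sklearn.covariance import LedoitWolf

from .geometry import DEFAULT_CATALOG, extract_geometric_features
from .landmarks import (
    LANDMARK_NAMES,
    TEMPLATE_CANVAS,
    TEMPLATE_POINTS,
    LandmarkSet,
    template_landmarks,
    write_landmark_csv,
)
from .texture import TexturePatchConfig, landmark_descriptor

logger = logging.getLogger(__name__)

DIAGNOSES = ("NS", "WBS")
ETHNICITIES = ("African", "Asian", "Caucasian", "LatinAmerican")
AGE_GROUPS = ("infant", "toddler", "child", "adolescent", "adult")

#: class-conditional age-group and sex proportions of the emulated cohort
AGE_PROPORTIONS = {
    "WBS": np.array([49, 47, 71, 28, 91]) / 286.0,
    "NS": np.array([45, 29, 47, 18, 22]) / 161.0,
}
SEX_PROPORTIONS = {"WBS": np.array([150, 136]) / 286.0, "NS": np.array([93, 68]) / 161.0}
SEXES = ("M", "F")

#: internal seed for calibration runs: ground truth depends on the config,
#: never on the cohort seed
_CALIBRATION_SEED = 20210327
_GEOM_CAL_N = 3000         # Monte-Carlo samples for jitter-induced feature SDs
_DRYRUN_PER_CLASS = 150    # calibration cohort size per class
_CARRIER_THRESHOLD = 0.5   # |standardized effect| listing threshold


@dataclass(frozen=True)
class GeometricEffect:
    """A planted geometric class difference.

    ``effect_size`` is the standardized mean difference (NS minus WBS) of
    ``geom.<metric>.sym`` in units of its jitter-induced noise SD.
    """

    metric: str
    effect_size: float


@dataclass(frozen=True)
class TextureEffect:
    """A planted local-texture class difference.

    A ``pattern`` ("stripes" or "spots") of the given intensity ``contrast``
    is stamped near ``landmark`` for a random fraction ``incidence`` of the
    subjects of ``target_class``, and never for the other class. Incidence
    below 1 emulates class-typical appearance features that are frequent but
    not universal, and keeps single descriptor bits from becoming
    deterministic class labels.
    """

    landmark: str
    pattern: str
    contrast: float
    target_class: str
    incidence: float = 0.75

    def __post_init__(self) -> None:
        if self.pattern not in ("stripes", "spots"):
            raise ValueError(f"unknown texture pattern {self.pattern!r}")
        if self.target_class not in DIAGNOSES:
            raise ValueError(f"unknown target class {self.target_class!r}")
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError("incidence must lie in [0, 1]")


DEFAULT_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("WBS", "African"): 28, ("WBS", "Asian"): 26,
    ("WBS", "Caucasian"): 121, ("WBS", "LatinAmerican"): 111,
    ("NS", "African"): 35, ("NS", "Asian"): 40,
    ("NS", "Caucasian"): 40, ("NS", "LatinAmerican"): 46,
}

DEFAULT_GEOMETRIC_EFFECTS: tuple[GeometricEffect, ...] = (
    GeometricEffect("intercanthal_inner", +1.5),       # NS: telecanthus
    GeometricEffect("orbital_rim_height", +1.5),       # NS: higher orbital rim
    GeometricEffect("mouth_width", -1.5),              # WBS: wider mouth
    GeometricEffect("lower_lip_thickness", -1.5),      # WBS: thicker lower lip
    GeometricEffect("nose_length", +1.5),              # WBS: shorter nose
    GeometricEffect("palpebral_fissure_slant", +1.5),  # WBS: more down-slanted fissures
)

#: stamp contrast must exceed the face's own local block contrast at the
#: stamped site (15-30 gray levels) to register in the comparison bits
DEFAULT_TEXTURE_EFFECTS: tuple[TextureEffect, ...] = (
    TextureEffect("nasion", "stripes", 60.0, "WBS"),
    TextureEffect("labiale_superius", "spots", 60.0, "NS"),
)

#: per-stratum multipliers on planted effects (absent metric -> 1.0);
#: zeroed entries emulate features that stop being discriminative in a stratum
DEFAULT_STRATUM_MODULATION: dict[str, dict[str, float]] = {
    "African": {"palpebral_fissure_slant": 0.0},
    "Asian": {"intercanthal_inner": 0.0, "orbital_rim_height": 0.0},
    "Caucasian": {},
    "LatinAmerican": {"palpebral_fissure_slant": 0.0},
}


@dataclass
class SyntheticCohortConfig:
    """Generator configuration; the defaults are the emulated study conditions."""

    group_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    geometric_effects: tuple[GeometricEffect, ...] = DEFAULT_GEOMETRIC_EFFECTS
    texture_effects: tuple[TextureEffect, ...] = DEFAULT_TEXTURE_EFFECTS
    stratum_modulation: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STRATUM_MODULATION.items()})
    landmark_jitter_sd: float = 1.5          # px
    rotation_deg: float = 10.0               # similarity transform: rotation in +-deg
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_px: float = 10.0             # +- px, each axis
    intensity_noise_sd: float = 4.0          # gray levels
    render_images: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for key, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for {key}")
        if self.landmark_jitter_sd < 0 or self.intensity_noise_sd < 0:
            raise ValueError("jitter and noise SDs must be >= 0")
        if not (0 < self.scale_range[0] <= self.scale_range[1]):
            raise ValueError("scale range must be positive and ordered")

    def modulation(self, ethnicity: str, key: str) -> float:
        return float(self.stratum_modulation.get(ethnicity, {}).get(key, 1.0))

    def cache_key(self) -> tuple:
        """Calibration cache key: everything except the cohort seed."""
        return (
            tuple(sorted((k, v) for k, v in self.group_sizes.items())),
            self.geometric_effects,
            self.texture_effects,
            tuple(sorted((s, tuple(sorted(m.items()))) for s, m in self.stratum_modulation.items())),
            self.landmark_jitter_sd,
            self.rotation_deg,
            self.scale_range,
            self.translation_px,
            self.intensity_noise_sd,
            self.render_images,
        )


@dataclass
class GroundTruth:
    """Planted signals, their correlated echoes, and the planted Bayes accuracy.

    ``features`` lists one primary feature per planted signal (the configured
    ``geom.<metric>.sym`` features, and per texture stamp the most responsive
    ``lbp.*`` bit at calibration) with per-stratum standardized effect sizes.
    ``carriers`` lists every further feature whose measured standardized
    class difference reaches the calibration threshold — correlated echoes
    of the planted signals through shared landmarks, normalization
    references, or rendering. ``signals`` maps each planted signal to the
    informative features mechanically attributable to it (metrics reading a
    displaced landmark; descriptor bits at a displaced or stamped landmark),
    which is the right granularity for judging whether a feature ranking
    found the signal: a redundancy-eliminating ranker keeps only one
    representative of a correlated group. ``bayes_accuracy`` is the
    Gaussian-discriminant accuracy over primaries and carriers jointly
    (shrinkage covariance, equal class priors).
    """

    features: dict[str, dict[str, float]]   # primary feature -> {stratum: effect}
    signals: dict[str, list[str]]           # signal -> attributed informative features
    carriers: dict[str, float]              # echo feature -> measured marginal effect
    bayes_accuracy: float                   # fraction, equal class priors

    def to_json_dict(self) -> dict:
        return {
            "features": self.features,
            "signals": self.signals,
            "carriers": self.carriers,
            "bayes_accuracy": self.bayes_accuracy,
        }


@dataclass
class SyntheticSubject:
    subject_id: str
    diagnosis: str
    ethnicity: str
    age_group: str
    sex: str
    landmarks: LandmarkSet
    image: np.ndarray | None


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    metadata: pd.DataFrame
    ground_truth: GroundTruth
    config: SyntheticCohortConfig


# --- effect appliers (landmark-space displacement, parameter in px) ---------

def _spread_x(left: str, right: str) -> Callable[[dict, float], None]:
    def apply(pts: dict, t: float) -> None:
        pts[left][0] -= t / 2.0
        pts[right][0] += t / 2.0
    return apply


def _shift_y(*names: str) -> Callable[[dict, float], None]:
    def apply(pts: dict, t: float) -> None:
        for n in names:
            pts[n][1] += t
    return apply


EFFECT_APPLIERS: dict[str, Callable[[dict, float], None]] = {
    "intercanthal_inner": _spread_x("canthus_inner_L", "canthus_inner_R"),
    "intercanthal_outer": _spread_x("canthus_outer_L", "canthus_outer_R"),
    "mouth_width": _spread_x("oral_commissure_L", "oral_commissure_R"),
    "nose_width": _spread_x("alare_L", "alare_R"),
    "orbital_rim_height": _shift_y("eyebrow_mid_L", "eyebrow_mid_R"),   # negative t raises brow
    "lower_lip_thickness": _shift_y("labiale_inferius"),
    "nose_length": _shift_y("nose_tip"),
    "palpebral_fissure_slant": _shift_y("canthus_outer_L", "canthus_outer_R"),
    "philtrum_length": _shift_y("labiale_superius"),
    "palpebral_fissure_height": lambda pts, t: (
        pts["eyelid_upper_L"].__setitem__(1, pts["eyelid_upper_L"][1] - t / 2),
        pts["eyelid_upper_R"].__setitem__(1, pts["eyelid_upper_R"][1] - t / 2),
        pts["eyelid_lower_L"].__setitem__(1, pts["eyelid_lower_L"][1] + t / 2),
        pts["eyelid_lower_R"].__setitem__(1, pts["eyelid_lower_R"][1] + t / 2),
    ) and None,
}

# --- rendering --------------------------------------------------------------

def _fill_ellipse(img: np.ndarray, center: np.ndarray, rx: float, ry: float, value: float) -> None:
    rr, cc = draw_ellipse(center[1], center[0], max(ry, 1.0), max(rx, 1.0), shape=img.shape)
    img[rr, cc] = value


def _fill_disk(img: np.ndarray, center: np.ndarray, radius: float, value: float) -> None:
    rr, cc = draw_disk((center[1], center[0]), max(radius, 1.0), shape=img.shape)
    img[rr, cc] = value


def _thick_line(img: np.ndarray, p: np.ndarray, q: np.ndarray, width: float, value: float) -> None:
    d = q - p
    n = float(np.hypot(*d))
    if n < 1e-9:
        _fill_disk(img, p, width / 2, value)
        return
    perp = np.array([-d[1], d[0]]) / n * (width / 2.0)
    corners = np.array([p + perp, q + perp, q - perp, p - perp])
    rr, cc = draw_polygon(corners[:, 1], corners[:, 0], shape=img.shape)
    img[rr, cc] = value


def render_face(
    points: Mapping[str, np.ndarray],
    size: int = TEMPLATE_CANVAS,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    stamps: Sequence[tuple[np.ndarray, str, float]] = (),
) -> np.ndarray:
    """Render a smooth face-like grayscale image from a 44-landmark layout.

    The rendering is schematic (ellipsoidal head shading with darkened
    brow/eye/nostril/lip regions, Gaussian-blurred) but entirely driven by
    the landmark positions, so planted landmark displacements are visible in
    the image. ``stamps`` are ``(position, pattern, contrast)`` texture marks
    applied after blurring; Gaussian intensity noise (``noise_sd`` > 0 needs
    ``rng``) is added last. Deterministic given identical inputs.
    """
    pts = {k: np.asarray(v, dtype=float) for k, v in points.items()}
    yy, xx = np.mgrid[0:size, 0:size]
    img = 150.0 + 25.0 * (yy / size)

    t_l, t_r = pts["tragion_L"], pts["tragion_R"]
    center = 0.5 * (t_l + t_r)
    itd = float(np.linalg.norm(t_r - t_l))
    rx = 0.51 * itd
    ry = 1.05 * abs(pts["menton"][1] - center[1])
    r2 = ((xx - center[0]) / rx) ** 2 + ((yy - center[1]) / ry) ** 2
    face = r2 <= 1.0
    img[face] = 205.0 - 45.0 * r2[face]

    # ears
    for side in ("L", "R"):
        _fill_ellipse(img, pts[f"tragion_{side}"], 0.045 * itd, 0.12 * itd, 150.0)
        _fill_disk(img, pts[f"tragion_{side}"], 0.02 * itd, 95.0)

    # eyebrows
    for side in ("L", "R"):
        _thick_line(img, pts[f"eyebrow_inner_{side}"], pts[f"eyebrow_mid_{side}"], 4.0, 80.0)
        _thick_line(img, pts[f"eyebrow_mid_{side}"], pts[f"eyebrow_outer_{side}"], 4.0, 80.0)

    # eyes
    for side in ("L", "R"):
        ci, co = pts[f"canthus_inner_{side}"], pts[f"canthus_outer_{side}"]
        eu, el = pts[f"eyelid_upper_{side}"], pts[f"eyelid_lower_{side}"]
        eye_center = 0.25 * (ci + co + eu + el)
        erx = 0.5 * abs(co[0] - ci[0])
        ery = max(0.5 * abs(el[1] - eu[1]), 2.0)
        _fill_ellipse(img, eye_center, erx, ery, 65.0)
        _fill_disk(img, eye_center, 0.6 * ery, 25.0)

    # nose
    _thick_line(img, pts["nasion"], pts["nose_tip"], 3.0, 135.0)
    for side in ("L", "R"):
        _thick_line(img, pts[f"bridge_{side}"], pts[f"alare_{side}"], 2.0, 120.0)
        _thick_line(img, pts[f"alare_{side}"], pts[f"ala_base_{side}"], 2.0, 100.0)
        _fill_disk(img, pts[f"ala_base_{side}"], 2.5, 55.0)

    # philtrum
    _thick_line(img, pts["subnasale"], pts["labiale_superius"], 2.0, 170.0)

    # lips
    upper = np.array([
        pts["oral_commissure_L"], pts["cupid_bow_L"], pts["cupid_bow_R"],
        pts["oral_commissure_R"], pts["stomion_upper"],
    ])
    rr, cc = draw_polygon(upper[:, 1], upper[:, 0], shape=img.shape)
    img[rr, cc] = 95.0
    lower = np.array([
        pts["oral_commissure_L"], pts["stomion_lower"],
        pts["oral_commissure_R"], pts["labiale_inferius"],
    ])
    rr, cc = draw_polygon(lower[:, 1], lower[:, 0], shape=img.shape)
    img[rr, cc] = 105.0
    stomion = 0.5 * (pts["stomion_upper"] + pts["stomion_lower"])
    _thick_line(img, pts["oral_commissure_L"], stomion, 1.5, 50.0)
    _thick_line(img, stomion, pts["oral_commissure_R"], 1.5, 50.0)

    # chin crease
    _thick_line(img, pts["menton"] + np.array([-8.0, -6.0]),
                pts["menton"] + np.array([8.0, -6.0]), 1.5, 165.0)

    img = gaussian_filter(img, sigma=1.2)

    for pos, pattern, contrast in stamps:
        pos = np.asarray(pos, dtype=float)
        if contrast == 0.0:
            continue
        if pattern == "stripes":
            # period ~2x the descriptor block size so block means resolve the bands
            mask = (xx - pos[0]) ** 2 + (yy - pos[1]) ** 2 <= 8.0 ** 2
            bands = np.sign(np.sin(2.0 * np.pi * (yy - pos[1]) / 8.0))
            img[mask] += 0.5 * contrast * bands[mask]
        else:  # spots
            for dy in (-4.0, 0.0, 4.0):
                for dx in (-4.0, 0.0, 4.0):
                    rr, cc = draw_disk((pos[1] + dy, pos[0] + dx), 1.5, shape=img.shape)
                    img[rr, cc] -= contrast

    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, 255.0)


def template_face() -> tuple[LandmarkSet, np.ndarray]:
    """The canonical landmark template and its deterministic rendering."""
    ls = template_landmarks()
    return ls, render_face(ls.points)


# --- calibration ------------------------------------------------------------

@dataclass
class CalibrationResult:
    displacement: dict[str, float]   # metric -> class-separation in applier units
    feature_sd: dict[str, float]     # geom feature -> jitter-induced SD
    ground_truth: GroundTruth


_CALIBRATION_CACHE: dict[tuple, CalibrationResult] = {}


def _geom_features_of_points(pts: Mapping[str, np.ndarray]) -> dict[str, float]:
    ls = LandmarkSet("cal", {k: np.array(v) for k, v in pts.items()})
    return extract_geometric_features(ls, DEFAULT_CATALOG)


def _effect_slopes(effects: Sequence[GeometricEffect]) -> dict[str, float]:
    slopes = {}
    for eff in effects:
        if eff.metric not in EFFECT_APPLIERS:
            raise ValueError(
                f"no landmark-space applier for metric {eff.metric!r}; "
                f"available: {sorted(EFFECT_APPLIERS)}"
            )
        feature = f"geom.{eff.metric}.sym"
        vals = []
        for t in (+1.0, -1.0):
            pts = {k: np.array(v, dtype=float) for k, v in TEMPLATE_POINTS.items()}
            EFFECT_APPLIERS[eff.metric](pts, t)
            vals.append(_geom_features_of_points(pts)[feature])
        slope = (vals[0] - vals[1]) / 2.0
        if abs(slope) < 1e-12:
            raise ValueError(f"applier for {eff.metric!r} does not move its feature")
        slopes[eff.metric] = slope
    return slopes


def _jitter_feature_sd(jitter_sd: float, rng: np.random.Generator) -> dict[str, float]:
    samples = []
    for _ in range(_GEOM_CAL_N):
        pts = {
            k: np.array(v, dtype=float) + rng.normal(0.0, jitter_sd, 2)
            for k, v in TEMPLATE_POINTS.items()
        }
        samples.append(_geom_features_of_points(pts))
    df = pd.DataFrame(samples)
    sd = df.std(ddof=1)
    return {k: float(max(v, 1e-12)) for k, v in sd.items()}


def _stratum_allocation(cfg: SyntheticCohortConfig, diagnosis: str, n: int) -> list[str]:
    """Allocate ``n`` calibration subjects across strata, proportional to the config."""
    weights = np.array(
        [cfg.group_sizes.get((diagnosis, e), 0) for e in ETHNICITIES], dtype=float
    )
    if weights.sum() == 0:
        weights = np.ones(len(ETHNICITIES))
    counts = np.floor(weights / weights.sum() * n).astype(int)
    frac = weights / weights.sum() * n - counts
    for i in np.argsort(-frac)[: n - counts.sum()]:
        counts[i] += 1
    out: list[str] = []
    for e, c in zip(ETHNICITIES, counts):
        out.extend([e] * int(c))
    return out


def _subject_features(
    subject: SyntheticSubject, texture_cfg: TexturePatchConfig | None = None
) -> dict[str, float]:
    feats = extract_geometric_features(subject.landmarks, DEFAULT_CATALOG)
    if subject.image is not None:
        feats.update(landmark_descriptor(subject.image, subject.landmarks, texture_cfg))
    return feats


def calibrate(cfg: SyntheticCohortConfig) -> CalibrationResult:
    """Numeric calibration of the planted model; cached per configuration.

    Uses a fixed internal seed, so two cohorts differing only in their
    ``seed`` share the same displacements and the same ground truth.
    """
    key = cfg.cache_key()
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    slopes = _effect_slopes(cfg.geometric_effects)
    feature_sd = (
        _jitter_feature_sd(cfg.landmark_jitter_sd, rng)
        if (cfg.landmark_jitter_sd > 0 and cfg.geometric_effects)
        else {}
    )

    displacement = {}
    for eff in cfg.geometric_effects:
        feature = f"geom.{eff.metric}.sym"
        sd = feature_sd.get(feature)
        if sd is None:
            # jitter-free generator: fall back to a 1-px-scale displacement
            sd = abs(slopes[eff.metric])
        displacement[eff.metric] = eff.effect_size * sd / slopes[eff.metric]

    ground_truth = _calibrate_ground_truth(cfg, displacement, rng)
    result = CalibrationResult(displacement, feature_sd, ground_truth)
    _CALIBRATION_CACHE[key] = result
    return result


def _moved_landmarks(metric: str) -> set[str]:
    """Landmarks displaced by a metric's effect applier (template diff)."""
    base = {k: np.array(v, dtype=float) for k, v in TEMPLATE_POINTS.items()}
    moved = {k: v.copy() for k, v in base.items()}
    EFFECT_APPLIERS[metric](moved, 1.0)
    return {k for k in base if not np.array_equal(base[k], moved[k])}


def _metric_landmarks(metric_name: str) -> set[str]:
    """All landmark names a catalog metric reads (both sides for paired)."""
    for d in DEFAULT_CATALOG:
        if d.name == metric_name:
            out: set[str] = set()
            for n in d.landmarks:
                if n in TEMPLATE_POINTS:
                    out.add(n)
                else:
                    out.update({f"{n}_L", f"{n}_R"})
            return out
    return set()


def _attributed(signal_landmarks: set[str], informative: Sequence[str]) -> list[str]:
    """Informative features mechanically attributable to a planted signal:
    geometric metrics reading a displaced landmark, and descriptor bits at a
    displaced or stamped landmark."""
    out = []
    for f in informative:
        parts = f.split(".")
        if parts[0] == "geom":
            if _metric_landmarks(parts[1]) & signal_landmarks:
                out.append(f)
        elif parts[0] == "lbp":
            if parts[1] in signal_landmarks:
                out.append(f)
    return out


def _calibrate_ground_truth(
    cfg: SyntheticCohortConfig, displacement: dict[str, float], rng: np.random.Generator
) -> GroundTruth:
    if not cfg.geometric_effects and not (cfg.texture_effects and cfg.render_images):
        return GroundTruth(features={}, signals={}, carriers={}, bayes_accuracy=0.5)

    rows, labels = [], []
    for dx in DIAGNOSES:
        for eth in _stratum_allocation(cfg, dx, _DRYRUN_PER_CLASS):
            subj = _generate_subject(cfg, dx, eth, "cal", rng, displacement)
            rows.append(_subject_features(subj))
            labels.append(dx)
    X = pd.DataFrame(rows)
    y = np.asarray(labels)
    ns, wbs = X[y == "NS"], X[y == "WBS"]
    n1, n2 = len(ns), len(wbs)
    pooled_var = ((n1 - 1) * ns.var(ddof=1) + (n2 - 1) * wbs.var(ddof=1)) / (n1 + n2 - 2)
    pooled_sd = np.sqrt(pooled_var).replace(0.0, np.nan)
    d = ((ns.mean() - wbs.mean()) / pooled_sd).fillna(0.0)

    # one primary feature per planted signal
    features: dict[str, dict[str, float]] = {}
    signal_landmarks: dict[str, set[str]] = {}
    for eff in cfg.geometric_effects:
        f = f"geom.{eff.metric}.sym"
        features[f] = {
            eth: eff.effect_size * cfg.modulation(eth, eff.metric) for eth in ETHNICITIES
        }
        signal_landmarks[eff.metric] = _moved_landmarks(eff.metric)
    if cfg.render_images:
        for eff in cfg.texture_effects:
            stamped = d[[c for c in d.index if c.startswith(f"lbp.{eff.landmark}.")]]
            if len(stamped) and stamped.abs().max() >= _CARRIER_THRESHOLD:
                f = stamped.abs().idxmax()
                features[f] = {eth: float(d[f]) for eth in ETHNICITIES}
                signal_landmarks[f"tex:{eff.landmark}"] = {eff.landmark}

    # correlated echoes of the planted signals (shared landmarks, references,
    # rendering): everything else above the threshold
    carriers = {
        f: float(d[f])
        for f in d.index[d.abs() >= _CARRIER_THRESHOLD]
        if f not in features
    }

    informative = sorted(set(features) | set(carriers))
    signals = {
        name: sorted(set(_attributed(lms, informative)))
        for name, lms in signal_landmarks.items()
    }
    if not informative:
        return GroundTruth(features=features, signals=signals, carriers={}, bayes_accuracy=0.5)

    Z = X[informative].to_numpy(dtype=float)
    resid = np.vstack([
        Z[y == "NS"] - Z[y == "NS"].mean(axis=0),
        Z[y == "WBS"] - Z[y == "WBS"].mean(axis=0),
    ])
    cov = LedoitWolf().fit(resid).covariance_
    delta = Z[y == "NS"].mean(axis=0) - Z[y == "WBS"].mean(axis=0)
    d2 = float(delta @ np.linalg.solve(cov, delta))
    bayes = float(stats.norm.cdf(np.sqrt(max(d2, 0.0)) / 2.0))
    return GroundTruth(
        features=features, signals=signals, carriers=carriers, bayes_accuracy=bayes
    )


# --- subject and cohort generation ------------------------------------------

def _generate_subject(
    cfg: SyntheticCohortConfig,
    diagnosis: str,
    ethnicity: str,
    subject_id: str,
    rng: np.random.Generator,
    displacement: dict[str, float],
) -> SyntheticSubject:
    pts = {k: np.array(v, dtype=float) for k, v in TEMPLATE_POINTS.items()}

    # planted class offsets (symmetric about the template: NS +t/2, WBS -t/2)
    for eff in cfg.geometric_effects:
        t = displacement[eff.metric] * cfg.modulation(ethnicity, eff.metric)
        EFFECT_APPLIERS[eff.metric](pts, 0.5 * t if diagnosis == "NS" else -0.5 * t)

    # independent landmark jitter
    jitter = rng.normal(0.0, cfg.landmark_jitter_sd, (len(LANDMARK_NAMES), 2))
    for i, name in enumerate(LANDMARK_NAMES):
        pts[name] = pts[name] + jitter[i]

    # random similarity transform about the canvas center
    theta = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    scale = rng.uniform(*cfg.scale_range)
    shift = rng.uniform(-cfg.translation_px, cfg.translation_px, 2)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    c = np.array([TEMPLATE_CANVAS / 2.0, TEMPLATE_CANVAS / 2.0])
    pts = {k: c + scale * (rot @ (p - c)) + shift for k, p in pts.items()}

    age_group = AGE_GROUPS[rng.choice(len(AGE_GROUPS), p=AGE_PROPORTIONS[diagnosis])]
    sex = SEXES[rng.choice(2, p=SEX_PROPORTIONS[diagnosis])]

    image = None
    if cfg.render_images:
        stamps = []
        for eff in cfg.texture_effects:
            if eff.target_class != diagnosis:
                continue
            if rng.uniform() >= eff.incidence:
                continue
            stamps.append(
                (pts[eff.landmark], eff.pattern,
                 eff.contrast * cfg.modulation(ethnicity, f"tex:{eff.landmark}"))
            )
        image = render_face(
            pts, noise_sd=cfg.intensity_noise_sd,
            rng=rng if cfg.intensity_noise_sd > 0 else None, stamps=stamps,
        )

    ls = LandmarkSet(subject_id, pts).validate()
    return SyntheticSubject(subject_id, diagnosis, ethnicity, age_group, sex, ls, image)


def generate_subject(
    cfg: SyntheticCohortConfig, diagnosis: str, ethnicity: str,
    rng: np.random.Generator, subject_id: str = "subject",
) -> SyntheticSubject:
    """Generate one subject (image, landmarks, metadata) under the config."""
    calib = calibrate(cfg)
    return _generate_subject(cfg, diagnosis, ethnicity, subject_id, rng, calib.displacement)


def generate_cohort(cfg: SyntheticCohortConfig | None = None, outdir: str | Path | None = None) -> SyntheticCohort:
    """Generate a full cohort (and optionally write it to a dataset directory).

    The directory layout is ``images/<sid>.png``, ``landmarks/<sid>.csv``,
    ``metadata.csv``, and ``ground_truth.json``. Counts match the configured
    group sizes exactly; the ground-truth feature list is independent of the
    cohort seed.
    """
    if cfg is None:
        cfg = SyntheticCohortConfig()
    calib = calibrate(cfg)
    rng = np.random.default_rng(cfg.seed)

    subjects: list[SyntheticSubject] = []
    for (dx, eth) in sorted(cfg.group_sizes):
        for i in range(cfg.group_sizes[(dx, eth)]):
            sid = f"{dx}_{eth}_{i:04d}"
            subjects.append(_generate_subject(cfg, dx, eth, sid, rng, calib.displacement))

    metadata = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "diagnosis": [s.diagnosis for s in subjects],
            "ethnicity": [s.ethnicity for s in subjects],
            "age_group": [s.age_group for s in subjects],
            "sex": [s.sex for s in subjects],
        }
    )
    cohort = SyntheticCohort(subjects, metadata, calib.ground_truth, cfg)

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "landmarks").mkdir(parents=True, exist_ok=True)
        if cfg.render_images:
            (outdir / "images").mkdir(parents=True, exist_ok=True)
        for s in subjects:
            write_landmark_csv(s.landmarks, outdir / "landmarks" / f"{s.subject_id}.csv")
            if s.image is not None:
                Image.fromarray(np.round(s.image).astype(np.uint8)).save(
                    outdir / "images" / f"{s.subject_id}.png"
                )
        metadata.to_csv(outdir / "metadata.csv", index=False)
        (outdir / "ground_truth.json").write_text(
            json.dumps(
                {"seed": cfg.seed, **calib.ground_truth.to_json_dict()}, indent=2
            )
        )
    return cohort
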