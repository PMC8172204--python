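"""Cohort file formats, run configuration, and the end-to-end pipeline.

A dataset directory consists of one image (PNG/JPEG) and one landmark file
(CSV ``landmark,x,y`` or JSON) per subject, plus a metadata CSV with the
columns ``subject_id, diagnosis, ethnicity, age_group, sex``. Feature
extraction joins geometric and texture features into a single subjects x
features table (``geom.*`` columns first, then ``lbp.*``), written as
comma-separated UTF-8 CSV with 9-significant-digit floats so that reruns
are bit-identical.

Every written report embeds the configuration hash and the seed, making
output artifacts traceable to the run that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import geometry, selection, texture
from .landmarks import LandmarkSet, read_landmark_file
from .synthetic import SyntheticCohort

logger = logging.getLogger(__name__)

DIAGNOSES = ("NS", "WBS")
ETHNICITIES = ("African", "Asian", "Caucasian", "LatinAmerican")
METADATA_COLUMNS = ("subject_id", "diagnosis", "ethnicity", "age_group", "sex")
FLOAT_FORMAT = "%.9g"


class MetadataError(ValueError):
    """Raised for malformed cohort metadata."""


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-serializable)."""

    images_dir: str = "images"
    landmarks_dir: str = "landmarks"
    metadata: str = "metadata.csv"
    output_dir: str = "output"
    catalog_file: str | None = None
    texture: texture.TexturePatchConfig = field(default_factory=texture.TexturePatchConfig)
    selection: selection.SelectionConfig = field(default_factory=selection.SelectionConfig)
    stratify: bool = True
    with_texture: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["texture"] = dataclasses.asdict(self.texture)
        d["selection"] = dataclasses.asdict(self.selection)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        tex = texture.TexturePatchConfig(**data.pop("texture", {}))
        sel = selection.SelectionConfig(**data.pop("selection", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(texture=tex, selection=sel, **data)


# --- metadata ---------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the cohort metadata table."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing metadata columns {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dup:
        raise MetadataError(f"{path}: duplicate subject ids {sorted(set(dup))}")
    for row_idx, row in df.iterrows():
        if row["diagnosis"] not in DIAGNOSES:
            raise MetadataError(
                f"{path}: row {row_idx + 2}: unknown diagnosis {row['diagnosis']!r} "
                f"(expected one of {DIAGNOSES})"
            )
        if row["ethnicity"] not in ETHNICITIES:
            raise MetadataError(
                f"{path}: row {row_idx + 2}: unknown ethnicity {row['ethnicity']!r} "
                f"(expected one of {ETHNICITIES})"
            )
    return df


# --- feature extraction -----------------------------------------------------

def _load_image(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path))


def extract_subject_features(
    image: np.ndarray | None,
    ls: LandmarkSet,
    catalog: Sequence[geometry.MetricDefinition] | None = None,
    texture_cfg: texture.TexturePatchConfig | None = None,
) -> dict[str, float]:
    """Geometric (and, if an image is given, texture) features for one subject."""
    feats = geometry.extract_geometric_features(ls, catalog)
    if image is not None:
        feats.update(texture.landmark_descriptor(image, ls, texture_cfg))
    return feats


def extract_features(
    metadata: pd.DataFrame,
    images_dir: str | Path | None,
    landmarks_dir: str | Path,
    catalog: Sequence[geometry.MetricDefinition] | None = None,
    texture_cfg: texture.TexturePatchConfig | None = None,
) -> pd.DataFrame:
    """Feature table for a cohort on disk: one row per metadata subject.

    ``images_dir=None`` extracts geometric features only. Raises with the
    subject id on missing files and propagates landmark-validation errors.
    """
    landmarks_dir = Path(landmarks_dir)
    images_dir = Path(images_dir) if images_dir is not None else None
    rows = []
    for sid in metadata["subject_id"]:
        lm_path = None
        for ext in (".csv", ".json"):
            cand = landmarks_dir / f"{sid}{ext}"
            if cand.exists():
                lm_path = cand
                break
        if lm_path is None:
            raise FileNotFoundError(f"no landmark file for subject {sid!r} in {landmarks_dir}")
        ls = read_landmark_file(lm_path, subject_id=sid)
        image = None
        if images_dir is not None:
            img_path = None
            for ext in (".png", ".jpg", ".jpeg"):
                cand = images_dir / f"{sid}{ext}"
                if cand.exists():
                    img_path = cand
                    break
            if img_path is None:
                raise FileNotFoundError(f"no image for subject {sid!r} in {images_dir}")
            image = _load_image(img_path)
        rows.append(extract_subject_features(image, ls, catalog, texture_cfg))
    X = pd.DataFrame(rows, index=pd.Index(metadata["subject_id"], name="subject_id"))
    meta = metadata.set_index("subject_id")
    return pd.concat([meta, X], axis=1)


def feature_table_from_cohort(
    cohort: SyntheticCohort,
    catalog: Sequence[geometry.MetricDefinition] | None = None,
    texture_cfg: texture.TexturePatchConfig | None = None,
) -> pd.DataFrame:
    """In-memory feature table for a synthetic cohort (no disk round-trip)."""
    rows = [
        extract_subject_features(s.image, s.landmarks, catalog, texture_cfg)
        for s in cohort.subjects
    ]
    X = pd.DataFrame(
        rows, index=pd.Index([s.subject_id for s in cohort.subjects], name="subject_id")
    )
    meta = cohort.metadata.set_index("subject_id")
    return pd.concat([meta, X], axis=1)


def split_feature_table(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Split a joined table into (features, diagnosis labels, ethnicity strata)."""
    feature_cols = [c for c in table.columns if c.startswith(("geom.", "lbp."))]
    return table[feature_cols], table["diagnosis"], table["ethnicity"]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, float_format=FLOAT_FORMAT)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


# --- pipeline ---------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """extract -> (stratified) selection/evaluation -> report bundle on disk.

    Writes ``features.csv``, ``report.json``, an accuracy table CSV
    (ethnicity, global/specific accuracy, improvement, Fisher p), and ROC
    curve points for the global model at its operating feature count.
    """
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = geometry.read_catalog(cfg.catalog_file) if cfg.catalog_file else None

    logger.info("reading metadata from %s", cfg.metadata)
    metadata = read_metadata(cfg.metadata)
    logger.info("extracting features for %d subjects", len(metadata))
    table = extract_features(
        metadata,
        cfg.images_dir if cfg.with_texture else None,
        cfg.landmarks_dir,
        catalog,
        cfg.texture,
    )
    write_feature_table(table, out / "features.csv")

    X, y, strata = split_feature_table(table)
    logger.info("running %s evaluation on %d features", cfg.selection.protocol, X.shape[1])
    if cfg.stratify:
        report = selection.stratified_evaluation(X, y, strata, cfg.selection)
    else:
        report = {"global": selection.loocv_curve(X, y, cfg.selection).to_dict()}

    report["config_hash"] = cfg.config_hash()
    report["seed"] = int(cfg.selection.seed)
    report["elapsed_s"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2))

    if "comparison" in report:
        rows = []
        for s, c in report["comparison"].items():
            if s.startswith("overall"):
                continue
            rows.append(
                {
                    "ethnicity": s,
                    "n": c["n"],
                    "global_accuracy_pct": c["global_accuracy_pct"],
                    "specific_accuracy_pct": c["specific_accuracy_pct"],
                    "improvement_pct": c["improvement_pct"],
                    "p_value": c["fisher_p"],
                }
            )
        if "overall" in report["comparison"]:
            c = report["comparison"]["overall"]
            rows.append(
                {
                    "ethnicity": "Global",
                    "n": c["n"],
                    "global_accuracy_pct": c["global_accuracy_pct"],
                    "specific_accuracy_pct": c["specific_accuracy_pct"],
                    "improvement_pct": c["improvement_pct"],
                    "p_value": c["fisher_p"],
                }
            )
        pd.DataFrame(rows).to_csv(out / "accuracy_table.csv", index=False,
                                  float_format=FLOAT_FORMAT)

    # ROC points of the global model at k*
    from sklearn.metrics import roc_curve

    g = report["global"]
    preds = pd.DataFrame(g["predictions"])
    pos = sorted(set(preds["true"]))[1]
    fpr, tpr, thr = roc_curve((preds["true"] == pos).astype(int), preds["decision"])
    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
        out / "roc_global.csv", index=False, float_format=FLOAT_FORMAT
    )
    logger.info("pipeline finished in %.1f s", report["elapsed_s"])
    return report
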