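import numpy as np
import pandas as pd
import pytest

from phenoface.landmarks import LANDMARK_NAMES, TEMPLATE_POINTS
from phenoface.synthetic import (
    DEFAULT_GROUP_SIZES,
    GeometricEffect,
    SyntheticCohortConfig,
    generate_cohort,
    generate_subject,
    render_face,
    template_face,
)


def _null_config(**kw):
    base = dict(
        group_sizes={("NS", "Caucasian"): 2, ("WBS", "Caucasian"): 2},
        geometric_effects=(),
        texture_effects=(),
        landmark_jitter_sd=0.0,
        rotation_deg=0.0,
        scale_range=(1.0, 1.0),
        translation_px=0.0,
        intensity_noise_sd=0.0,
    )
    base.update(kw)
    return SyntheticCohortConfig(**base)


class TestTemplate:
    def test_template_validates_and_renders_deterministically(self):
        ls, img = template_face()
        ls.validate()
        _, img2 = template_face()
        assert np.array_equal(img, img2)
        assert img.shape == (256, 256)
        assert 0.0 <= img.min() and img.max() <= 255.0

    def test_template_asymmetry_features_are_zero(self):
        from phenoface.geometry import extract_geometric_features

        ls, _ = template_face()
        feats = extract_geometric_features(ls)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for k, v in feats.items() if k.endswith(".asym"))

    def test_rendering_has_texture_at_inner_landmarks(self):
        """The rendering is not flat: descriptor bits vary across landmarks."""
        from phenoface.texture import landmark_descriptor

        ls, img = template_face()
        desc = landmark_descriptor(img, ls)
        values = np.array(list(desc.values()))
        assert 0.05 < values.mean() < 0.95


class TestGenerateSubject:
    def test_null_config_reproduces_template(self):
        cfg = _null_config()
        rng = np.random.default_rng(0)
        subj = generate_subject(cfg, "NS", "Caucasian", rng)
        for name in LANDMARK_NAMES:
            assert subj.landmarks.points[name] == pytest.approx(
                np.asarray(TEMPLATE_POINTS[name]), abs=1e-12
            )
        _, template_img = template_face()
        assert np.array_equal(subj.image, template_img)

    def test_features_invariant_to_extra_similarity_transform(self):
        from phenoface.geometry import extract_geometric_features

        cfg = SyntheticCohortConfig(
            group_sizes={("NS", "Caucasian"): 2, ("WBS", "Caucasian"): 2},
            texture_effects=(), render_images=False,
        )
        rng = np.random.default_rng(5)
        subj = generate_subject(cfg, "WBS", "Caucasian", rng)
        moved = subj.landmarks.transformed(scale=1.4, rotation_deg=25.0, translation=(30.0, -12.0))
        f1 = extract_geometric_features(subj.landmarks)
        f2 = extract_geometric_features(moved)
        for k in f1:
            assert abs(f1[k] - f2[k]) < 1e-9


class TestGenerateCohort:
    def test_default_counts_match_study_conditions(self):
        cfg = SyntheticCohortConfig()
        assert sum(n for (dx, _), n in cfg.group_sizes.items() if dx == "WBS") == 286
        assert sum(n for (dx, _), n in cfg.group_sizes.items() if dx == "NS") == 161
        assert cfg.group_sizes == DEFAULT_GROUP_SIZES

    def test_counts_and_zero_cells(self):
        cfg = _null_config(
            group_sizes={("NS", "Asian"): 3, ("WBS", "Asian"): 4, ("WBS", "African"): 0},
            render_images=False,
        )
        cohort = generate_cohort(cfg)
        counts = cohort.metadata.groupby(["diagnosis", "ethnicity"]).size()
        assert counts[("NS", "Asian")] == 3
        assert counts[("WBS", "Asian")] == 4
        assert ("WBS", "African") not in counts.index
        assert len(cohort.subjects) == 7

    def test_fixed_seed_bitwise_reproducible(self):
        cfg = SyntheticCohortConfig(
            group_sizes={("NS", "Caucasian"): 3, ("WBS", "Caucasian"): 3}, seed=9
        )
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        for s1, s2 in zip(c1.subjects, c2.subjects):
            assert np.array_equal(s1.image, s2.image)
            for n in LANDMARK_NAMES:
                assert np.array_equal(s1.landmarks.points[n], s2.landmarks.points[n])
        assert c1.metadata.equals(c2.metadata)

    def test_seed_changes_jitter_not_ground_truth(self):
        kw = dict(
            group_sizes={("NS", "Caucasian"): 3, ("WBS", "Caucasian"): 3},
            texture_effects=(), render_images=False,
        )
        c1 = generate_cohort(SyntheticCohortConfig(seed=1, **kw))
        c2 = generate_cohort(SyntheticCohortConfig(seed=2, **kw))
        assert c1.ground_truth.features == c2.ground_truth.features
        assert c1.ground_truth.bayes_accuracy == c2.ground_truth.bayes_accuracy
        p1 = c1.subjects[0].landmarks.points["nasion"]
        p2 = c2.subjects[0].landmarks.points["nasion"]
        assert not np.allclose(p1, p2)

    def test_dataset_directory_layout(self, tmp_path, small_rendered_cohort):
        import json

        from phenoface.synthetic import SyntheticCohortConfig, generate_cohort

        out = tmp_path / "ds"
        generate_cohort(small_rendered_cohort.config, out)
        meta = pd.read_csv(out / "metadata.csv")
        assert len(meta) == 12
        assert (out / "images").exists() and (out / "landmarks").exists()
        assert len(list((out / "images").glob("*.png"))) == 12
        gt = json.loads((out / "ground_truth.json").read_text())
        assert "features" in gt and "bayes_accuracy" in gt and "seed" in gt


class TestPlantedEffects:
    def test_planted_effect_size_realized_within_ten_percent(self):
        """Sample standardized effect of a planted metric matches its config."""
        from phenoface.io import feature_table_from_cohort, split_feature_table

        cfg = SyntheticCohortConfig(
            group_sizes={("NS", "Caucasian"): 400, ("WBS", "Caucasian"): 400},
            geometric_effects=(GeometricEffect("intercanthal_inner", 1.5),),
            texture_effects=(), render_images=False, seed=0,
        )
        table = feature_table_from_cohort(generate_cohort(cfg))
        X, y, _ = split_feature_table(table)
        f = X["geom.intercanthal_inner.sym"]
        ns, wbs = f[y == "NS"], f[y == "WBS"]
        pooled_sd = np.sqrt(
            ((len(ns) - 1) * ns.var() + (len(wbs) - 1) * wbs.var())
            / (len(ns) + len(wbs) - 2)
        )
        d = (ns.mean() - wbs.mean()) / pooled_sd
        assert d == pytest.approx(1.5, rel=0.10)

    def test_ground_truth_features_exist_in_feature_table(self, small_rendered_cohort):
        from phenoface.io import feature_table_from_cohort

        table = feature_table_from_cohort(small_rendered_cohort)
        for f in small_rendered_cohort.ground_truth.features:
            assert f in table.columns
        for f in small_rendered_cohort.ground_truth.carriers:
            assert f in table.columns

    def test_null_cohort_auc_is_chance_level(self):
        """Without planted effects, the selection pipeline finds nothing.

        Judged on the full-model AUC and the curve median: the AUC at the
        selected k* is the maximum over the evaluated grid and therefore
        carries a bounded winner's-curse offset even without any leakage.
        """
        from phenoface.io import feature_table_from_cohort, split_feature_table
        from phenoface.selection import SelectionConfig, loocv_curve

        full_aucs, median_aucs = [], []
        for seed in range(10):
            cfg = SyntheticCohortConfig(
                group_sizes={("NS", "Caucasian"): 20, ("WBS", "Caucasian"): 20},
                geometric_effects=(), texture_effects=(),
                render_images=False, seed=200 + seed,
            )
            table = feature_table_from_cohort(generate_cohort(cfg))
            X, y, _ = split_feature_table(table)
            res = loocv_curve(
                X, y,
                SelectionConfig(protocol="nested", k_grid=(1, 2, 4, 8, 16, 34),
                                coarse_step=0.3, fine_threshold=0),
            )
            full_aucs.append(float(res.curves["auc"].iloc[-1]))
            median_aucs.append(float(res.curves["auc"].median()))
        assert 0.4 <= np.mean(full_aucs) <= 0.6
        assert 0.4 <= np.mean(median_aucs) <= 0.6


def test_render_face_noise_requires_rng():
    ls, _ = template_face()
    with pytest.raises(ValueError, match="rng"):
        render_face(ls.points, noise_sd=2.0)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticCohortConfig(group_sizes={("NS", "Asian"): -1})
    with pytest.raises(ValueError):
        SyntheticCohortConfig(landmark_jitter_sd=-0.1)
    with pytest.raises(ValueError):
        SyntheticCohortConfig(scale_range=(0.0, 1.0))
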