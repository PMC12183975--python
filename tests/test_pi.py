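"""MRNet structure, Progressive Index contract and threshold metrics."""

import numpy as np
import pandas as pd
import pytest

from roiprog.nn import (BackboneSpec, TrainConfig, backbone_forward,
                        build_mrnet, forward_probs)
from roiprog.pi import (progressive_index, score_cohort, subject_patches,
                        threshold_metrics, train_mrnet, stage_sorted_table)
from roiprog.screening import ROIRanking, compute_auc
from roiprog.synthetic import (EffectSpec, make_phantom_atlas,
                               simulate_cohort, simulate_subject)
from roiprog.volumes import Volume3D

TINY = BackboneSpec(channels=(2, 3))


class TestBuildMRNet:
    def test_fc_input_is_k_times_feature_length(self):
        m = build_mrnet(list(range(1, 11)), BackboneSpec(), init_seed=0)
        assert m.fc_w.shape == (640, 2)  # 10 branches x 64 features
        assert m.k == 10

    def test_k1_degenerates_to_single_roi_net(self):
        m = build_mrnet([7], BackboneSpec(), init_seed=0)
        assert m.fc_w.shape == (64, 2)

    def test_duplicate_rois_rejected(self):
        with pytest.raises(ValueError):
            build_mrnet([1, 2, 1], TINY)

    def test_branches_share_one_parameter_set(self):
        """Identical patches in different branches give identical features,
        and the stacked forward equals manual per-branch evaluation."""
        m = build_mrnet([1, 2], TINY, init_seed=3)
        rng = np.random.default_rng(0)
        pa = rng.normal(size=(8, 8, 8))
        pb = rng.normal(size=(8, 8, 8))
        fa = backbone_forward(m, pa)
        fb = backbone_forward(m, pb)
        X = np.stack([pa, pb])[None].astype(np.float32)
        probs = forward_probs(m, X)
        concat = np.r_[fa, fb].astype(np.float32)
        logits = concat @ m.fc_w + m.fc_b
        e = np.exp(logits - logits.max())
        np.testing.assert_allclose(probs[0], e / e.sum(), rtol=1e-5)
        # same patch through both branches -> identical branch features
        np.testing.assert_array_equal(backbone_forward(m, pa), fa)

    def test_perturbing_shared_backbone_changes_every_branch(self):
        m = build_mrnet([1, 2], TINY, init_seed=3)
        rng = np.random.default_rng(1)
        p = rng.normal(size=(8, 8, 8))
        before = backbone_forward(m, p)
        m.backbone["W1"] = m.backbone["W1"] + 0.5
        after = backbone_forward(m, p)
        assert not np.allclose(before, after)


@pytest.fixture(scope="module")
def file_cohort(tmp_path_factory):
    """A small on-disk cohort with a strong planted effect in ROIs 1 and 2."""
    d = tmp_path_factory.mktemp("cohort")
    eff = EffectSpec(informative_labels=frozenset({1, 2}), intensity_shift=0.6,
                     erosion_fraction=0.1, noise_sd=0.15)
    man = simulate_cohort(d, (24, 24, 24), 4, eff,
                          {"sNC": 8, "pNC": 8, "rNC": 4}, roi_radius=3,
                          seed=31)
    from roiprog.volumes import load_label_volume
    return man, load_label_volume(man.atlas_path)


class TestSubjectPatches:
    def test_order_and_labels_follow_selection(self, file_cohort):
        man, atlas = file_cohort
        vol = simulate_subject(atlas, 0, EffectSpec(
            informative_labels=frozenset({1}), intensity_shift=0.1), seed=0)
        pats = subject_patches(vol, atlas, [3, 1, 2], size=8)
        assert [p.roi_label for p in pats] == [3, 1, 2]
        again = subject_patches(vol, atlas, [3, 1, 2], size=8)
        for a, b in zip(pats, again):
            np.testing.assert_array_equal(a.data, b.data)

    def test_missing_label_raises(self, file_cohort):
        _, atlas = file_cohort
        vol = Volume3D(data=np.zeros(atlas.shape))
        with pytest.raises(KeyError):
            subject_patches(vol, atlas, [99], size=8)

    def test_border_roi_patch_zero_padded(self):
        # an ROI hugging the volume corner still yields a full-size patch
        labs = np.zeros((12, 12, 12), dtype=np.int32)
        labs[0:2, 0:2, 0:2] = 1
        from roiprog.volumes import LabelVolume
        atlas = LabelVolume(labels=labs)
        vol = Volume3D(data=np.ones((12, 12, 12)))
        (p,) = subject_patches(vol, atlas, [1], size=8, standardize=False)
        assert p.data.shape == (8, 8, 8)
        assert p.data[0, 0, 0] == 0.0  # out-of-bounds fill


class TestProgressiveIndex:
    def test_equal_logits_give_half(self):
        m = build_mrnet([1], TINY, init_seed=0)
        m.fc_w = np.zeros_like(m.fc_w)
        m.fc_b = np.zeros_like(m.fc_b)
        patch = np.random.default_rng(0).normal(size=(1, 8, 8, 8))
        assert progressive_index(m, patch) == pytest.approx(0.5, abs=1e-7)

    def test_bounds_over_random_draws(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            m = build_mrnet([1, 2], TINY, init_seed=trial)
            X = rng.normal(scale=3.0, size=(2, 8, 8, 8))
            pi = progressive_index(m, X)
            assert 0.0 <= pi <= 1.0

    def test_wrong_patch_count_rejected(self):
        m = build_mrnet([1, 2], TINY, init_seed=0)
        with pytest.raises(ValueError):
            progressive_index(m, np.zeros((3, 8, 8, 8)))


@pytest.fixture(scope="module")
def trained(file_cohort):
    man, atlas = file_cohort
    ranking = ROIRanking(ordered=[1, 2, 3, 4], k=2,
                         aucs={1: 0.9, 2: 0.8, 3: 0.5, 4: 0.4})
    model, report = train_mrnet(
        man.records, atlas, ranking, TINY,
        TrainConfig(epochs=6, seed=2, batch_size=8, learning_rate=2e-3),
        patch_size=8)
    return model, report


class TestScoreCohort:

    def test_all_subjects_scored_in_unit_interval(self, file_cohort, trained):
        man, atlas = file_cohort
        model, _ = trained
        table = score_cohort(model, man.records, atlas, patch_size=8)
        assert len(table) == 20
        assert table["pi"].between(0, 1).all()
        # unknown-label rows are present but flagged NA
        assert table["label"].isna().sum() == 4

    def test_scoring_is_deterministic(self, file_cohort, trained):
        man, atlas = file_cohort
        model, _ = trained
        t1 = score_cohort(model, man.records, atlas, patch_size=8)
        t2 = score_cohort(model, man.records, atlas, patch_size=8)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unreadable_image_marks_row_failed(self, file_cohort, trained):
        man, atlas = file_cohort
        model, _ = trained
        rows = man.records.copy()
        rows.loc[0, "image_path"] = "/nonexistent/broken.nii"
        table = score_cohort(model, rows, atlas, patch_size=8)
        assert np.isnan(table.loc[0, "pi"]) and table.loc[0, "error"] != ""
        assert table["pi"].notna().sum() == 19  # pipeline continued

    def test_positives_score_higher_on_average(self, file_cohort, trained):
        man, atlas = file_cohort
        model, _ = trained
        table = score_cohort(model, man.records, atlas, patch_size=8)
        known = table[table["label"].notna()]
        gap = known.loc[known["label"] == 1, "pi"].mean() - \
            known.loc[known["label"] == 0, "pi"].mean()
        assert gap > 0

    def test_stage_sorted_table_structure(self, file_cohort, trained):
        man, atlas = file_cohort
        model, _ = trained
        table = score_cohort(model, man.records, atlas, patch_size=8)
        plot = stage_sorted_table(table, group_order=["sNC", "pNC", "rNC"])
        assert list(plot.columns) == ["group", "index_in_group", "subject_id", "pi"]
        for _, sub in plot.groupby("group"):
            assert sub["pi"].is_monotonic_increasing


class TestThresholdMetrics:
    @staticmethod
    def _table(pis, labels, groups=None):
        n = len(pis)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": groups or ["g"] * n,
            "label": pd.array(labels, dtype="Int64"),
            "pi": pis})

    def test_hand_counted_2x2(self):
        m = threshold_metrics(self._table([0.2, 0.3, 0.6, 0.7], [0, 0, 1, 1]))
        assert m.threshold == pytest.approx(0.45)
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert (m.tp, m.fp, m.tn, m.fn) == (2, 0, 2, 0)

    def test_overall_mean_includes_unknown_label_rows(self):
        t = self._table([0.2, 0.3, 0.6, 0.7, 1.0], [0, 0, 1, 1, pd.NA])
        m = threshold_metrics(t)
        assert m.threshold == pytest.approx(0.56)  # mean over all 5 rows
        assert m.tp + m.fn + m.tn + m.fp == 4      # counts over known only

    def test_all_equal_pi_calls_everyone_positive(self):
        m = threshold_metrics(self._table([0.4] * 4, [0, 0, 1, 1]))
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_all_unknown_labels_undefined(self):
        with pytest.raises(ValueError):
            threshold_metrics(self._table([0.1, 0.2], [pd.NA, pd.NA]))

    def test_auc_consistent_with_rank_sum(self):
        rng = np.random.default_rng(0)
        pis = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        m = threshold_metrics(self._table(pis.tolist(), labels.tolist()))
        assert m.auc == compute_auc(pis, labels)

    def test_fixed_threshold_mode(self):
        m = threshold_metrics(self._table([0.2, 0.3, 0.6, 0.7], [0, 0, 1, 1]),
                              threshold_mode=0.65)
        assert m.sensitivity == 0.5 and m.specificity == 1.0
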