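"""LNM scoring: seed maps, lesion scores, matrices, volumetrics, coupling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wmhlnm as w
from wmhlnm.lnm import CLIP, SeedMap, _score_block, build_lnm_matrix, lnm_score
from wmhlnm.synthetic import FunctionalConnectome

from conftest import make_mask, make_volume


def _seed_from_values(values, template_mask):
    """SeedMap whose voxel values inside the mask are `values` (C order)."""
    data = np.zeros(template_mask.shape)
    data.ravel()[template_mask.flat_indices()] = values
    return SeedMap(1, "functional", make_volume(data))


def _mask_of(n, shape=(4, 4, 4)):
    data = np.zeros(shape)
    data.ravel()[:n] = 1
    return make_mask(data)


class TestFunctionalSeedMap:
    def _tiny_connectome(self, series_by_voxel, template_shape=(3, 3, 3)):
        """(S, V, T) array over all voxels of a tiny grid."""
        arr = np.asarray(series_by_voxel, dtype=np.float32)
        S, V, T = arr.shape
        template = make_volume(np.zeros(template_shape, dtype=np.int16))
        return FunctionalConnectome(arr, np.arange(V), template, np.zeros(V, int))

    def test_matches_brute_force_oracle(self):
        """Map value equals mean over subjects of atanh(pearson r) computed
        directly from the raw series."""
        rng = np.random.default_rng(5)
        S, V, T = 3, 27, 5
        fc = self._tiny_connectome(rng.normal(size=(S, V, T)))
        roi = np.zeros((3, 3, 3))
        roi.ravel()[[0, 5, 9]] = 1
        zmap = w.functional_seed_map(make_mask(roi), fc)
        # independent oracle: direct formula evaluation per subject
        expected = np.zeros(V)
        for s in range(S):
            ref = fc.series[s, [0, 5, 9]].astype(float).mean(axis=0)
            for v in range(V):
                r = np.corrcoef(ref, fc.series[s, v].astype(float))[0, 1]
                expected[v] += math.atanh(np.clip(r, -CLIP, CLIP))
        np.testing.assert_allclose(zmap, expected / S, atol=1e-10)

    def test_self_correlated_voxel_hits_clipping_ceiling(self):
        base = np.random.default_rng(6).normal(size=(1, 1, 8))
        series = np.repeat(base, 27, axis=1)  # every voxel equals the ROI mean
        fc = self._tiny_connectome(series)
        roi = np.zeros((3, 3, 3))
        roi.ravel()[0] = 1
        zmap = w.functional_seed_map(make_mask(roi), fc)
        assert zmap[5] == pytest.approx(math.atanh(CLIP))

    def test_single_subject_mean_is_that_subject(self):
        rng = np.random.default_rng(7)
        fc = self._tiny_connectome(rng.normal(size=(1, 27, 10)))
        roi = np.zeros((3, 3, 3))
        roi.ravel()[3] = 1
        zmap = w.functional_seed_map(make_mask(roi), fc)
        r = np.corrcoef(fc.series[0, 3].astype(float), fc.series[0, 10].astype(float))[0, 1]
        assert zmap[10] == pytest.approx(math.atanh(np.clip(r, -CLIP, CLIP)))

    def test_zero_variance_voxel_gets_zero(self):
        rng = np.random.default_rng(8)
        series = rng.normal(size=(2, 27, 10))
        series[:, 4, :] = 1.0  # flat series
        fc = self._tiny_connectome(series)
        roi = np.zeros((3, 3, 3))
        roi.ravel()[0] = 1
        assert w.functional_seed_map(make_mask(roi), fc)[4] == 0.0

    def test_too_few_timepoints_and_empty_roi(self):
        fc = self._tiny_connectome(np.zeros((1, 27, 2)))
        roi = np.zeros((3, 3, 3))
        roi.ravel()[0] = 1
        with pytest.raises(ValueError):
            w.functional_seed_map(make_mask(roi), fc)
        fc2 = self._tiny_connectome(np.zeros((1, 27, 5)))
        with pytest.raises(ValueError):
            w.functional_seed_map(make_mask(np.zeros((3, 3, 3))), fc2)


class TestStructuralSeedMap:
    def test_zero_map_valid_negative_and_mismatch_rejected(self, toy_parc):
        template = toy_parc.label_volume
        zero = {1: template.with_data(np.zeros(template.shape, dtype=np.int64))}
        sm = w.structural_seed_map(1, zero, toy_parc)
        assert np.asarray(sm.map.data).sum() == 0
        neg = {1: template.with_data(np.full(template.shape, -1))}
        with pytest.raises(ValueError):
            w.structural_seed_map(1, neg)
        other = make_volume(np.zeros((4, 4, 4)))
        with pytest.raises(Exception):
            w.structural_seed_map(1, {1: other}, toy_parc)
        with pytest.raises(KeyError):
            w.structural_seed_map(99, zero)


class TestLnmScore:
    @pytest.mark.parametrize(
        "values,polarity,f,expected",
        [
            ([0.2, -0.1, 0.4], "positive", 1.0, 0.3),
            ([-0.3, -0.1, 0.5], "negative", 1.0, -0.2),
            ([0.1, 0.2, 0.3, 0.4], "positive", 0.5, 0.35),
        ],
    )
    def test_functional_worked_examples(self, values, polarity, f, expected):
        mask = _mask_of(len(values))
        seed = _seed_from_values(values, mask)
        score, n, flag = lnm_score(seed, mask, polarity, f)
        assert score == pytest.approx(expected)
        assert not flag

    def test_structural_mean_of_all_values(self):
        mask = _mask_of(3)
        seed = SeedMap(1, "structural", _seed_from_values([0, 3, 5], mask).map)
        score, n, flag = lnm_score(seed, mask)
        assert score == pytest.approx(8 / 3)
        assert n == 3

    def test_no_voxel_of_requested_sign_returns_flagged_zero(self):
        mask = _mask_of(3)
        seed = _seed_from_values([-0.2, -0.1, -0.5], mask)
        score, n, flag = lnm_score(seed, mask, "positive")
        assert score == 0.0 and n == 0 and flag

    def test_empty_mask_is_missing_not_zero(self):
        mask = make_mask(np.zeros((4, 4, 4)))
        seed = SeedMap(1, "functional", make_volume(np.ones((4, 4, 4))))
        score, n, flag = lnm_score(seed, mask)
        assert math.isnan(score) and flag

    def test_structural_rejects_negative_polarity_and_bad_threshold(self):
        mask = _mask_of(2)
        seed = SeedMap(1, "structural", _seed_from_values([1, 2], mask).map)
        with pytest.raises(ValueError):
            lnm_score(seed, mask, "negative")
        with pytest.raises(ValueError):
            lnm_score(_seed_from_values([1, 2], mask), mask, "positive", 0.3)

    @settings(deadline=None, max_examples=50)
    @given(
        values=st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=30),
        polarity=st.sampled_from(["positive", "negative"]),
        f=st.sampled_from([1.0, 0.5, 0.25]),
    )
    def test_matches_brute_force_oracle(self, values, polarity, f):
        """Value-by-value reimplementation agrees to 1e-12."""
        mask = _mask_of(len(values))
        seed = _seed_from_values(values, mask)
        score, n, flag = lnm_score(seed, mask, polarity, f)
        # brute force: sort, threshold, sign-filter, average
        idx = mask.flat_indices()
        pairs = sorted(zip(values, idx), key=lambda p: (p[0], -p[1]), reverse=(polarity == "positive"))
        if polarity == "negative":
            pairs = sorted(zip(values, idx), key=lambda p: (p[0], p[1]))
        k = math.ceil(f * len(values))
        kept = [v for v, _ in pairs[:k]]
        sel = [v for v in kept if (v > 0 if polarity == "positive" else v < 0)]
        if sel:
            assert score == pytest.approx(sum(sel) / len(sel), abs=1e-12)
        else:
            assert score == 0.0 and flag

    def test_threshold_nesting_for_positive_maps(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(0.01, 1.0, 20)  # all positive
        mask = _mask_of(20)
        seed = _seed_from_values(values, mask)
        s = {f: lnm_score(seed, mask, "positive", f)[0] for f in (1.0, 0.5, 0.25)}
        assert s[0.25] >= s[0.5] >= s[1.0]

    def test_monotone_toward_added_voxel_value(self):
        mask_small = _mask_of(3)
        values4 = [0.2, 0.2, 0.2, 0.9]
        mask_big = _mask_of(4)
        seed = _seed_from_values(values4, mask_big)
        s_small = lnm_score(seed, mask_small)[0]
        s_big = lnm_score(seed, mask_big)[0]
        assert s_small < s_big < 0.9  # grew toward the added value

    def test_structural_scale_equivariance(self):
        rng = np.random.default_rng(10)
        values = rng.integers(0, 30, 10).astype(float)
        mask = _mask_of(10)
        base = SeedMap(1, "structural", _seed_from_values(values, mask).map)
        scaled = SeedMap(1, "structural", _seed_from_values(values * 3.5, mask).map)
        assert lnm_score(scaled, mask)[0] == pytest.approx(3.5 * lnm_score(base, mask)[0])


class TestLnmMatrix:
    def test_matrix_shape_and_determinism(self, toy_parc, seed_maps, small_cohort):
        mat = build_lnm_matrix(small_cohort.patients.masks[:5], seed_maps)
        assert mat.scores.shape == (5, 52)
        assert mat.modality == "fLNM"

    def test_identical_masks_give_identical_rows(self, seed_maps, small_cohort):
        m = small_cohort.patients.masks[0]
        mat = build_lnm_matrix([m, m], seed_maps)
        assert np.allclose(mat.scores.iloc[0], mat.scores.iloc[1])

    def test_vectorised_block_matches_scalar_scores(self, toy_parc, seed_maps, small_cohort):
        mask = small_cohort.patients.masks[1]
        for f in (1.0, 0.5):
            mat = build_lnm_matrix([mask], seed_maps, threshold_fraction=f)
            for rid in [1, 17, toy_parc.tract_ids[0]]:
                expected = lnm_score(seed_maps[rid], mask, "positive", f)[0]
                assert mat.scores.loc[0, rid] == pytest.approx(expected, abs=1e-12)

    def test_hemisphere_restriction_drops_other_side(self, toy_parc, seed_maps, small_cohort):
        tab = toy_parc.roi_table
        n_left = ((tab["class"] == "cortical") & (tab["hemisphere"] == "L")).sum()
        mat = build_lnm_matrix(
            small_cohort.patients.masks[:3], seed_maps, hemisphere="L", parc=toy_parc
        )
        kept = tab[tab.roi_id.isin(mat.scores.columns)]
        assert (kept["hemisphere"] == "L").all()
        assert (kept["class"] == "cortical").sum() == n_left

    def test_empty_mask_row_flagged_missing(self, seed_maps, toy_parc):
        empty = w.BinaryMask(
            np.zeros(toy_parc.label_volume.shape),
            toy_parc.label_volume.voxel_size,
            toy_parc.label_volume.origin,
        )
        mat = build_lnm_matrix([empty], seed_maps)
        assert mat.scores.iloc[0].isna().all()
        assert mat.empty_selection.iloc[0].all()

    def test_penumbra_enlarges_selection(self, seed_maps, small_cohort):
        m = small_cohort.patients.masks[0]
        plain = build_lnm_matrix([m], seed_maps)
        pen = build_lnm_matrix([m], seed_maps, penumbra_mm=2.0)
        assert pen.n_voxels_used.iloc[0].sum() > plain.n_voxels_used.iloc[0].sum()


class TestVolumetricFeatures:
    def test_lesion_inside_one_tract(self, toy_parc):
        tid = toy_parc.tract_ids[0]
        tract = toy_parc.roi_mask(tid)
        idx = tract.flat_indices()[:10]
        data = np.zeros(tract.shape).ravel()
        data[idx] = 1
        lesion = w.BinaryMask(data.reshape(tract.shape), tract.voxel_size, tract.origin)
        feats = w.volumetric_features([lesion], toy_parc.tract_masks)
        assert feats.total_wmh_ml.iloc[0] == pytest.approx(0.01)
        assert feats.tract_wmh_ml.loc[0, tid] == pytest.approx(0.01)

    def test_lesion_disjoint_from_tracts(self, toy_parc):
        union = np.zeros(toy_parc.label_volume.shape, dtype=bool)
        for tm in toy_parc.tract_masks.values():
            union |= tm.data.astype(bool)
        outside = np.flatnonzero(~union.ravel() & (np.asarray(toy_parc.label_volume.data).ravel() == 0))
        data = np.zeros(union.shape).ravel()
        data[outside[:5]] = 1
        lesion = w.BinaryMask(
            data.reshape(union.shape),
            toy_parc.label_volume.voxel_size,
            toy_parc.label_volume.origin,
        )
        feats = w.volumetric_features([lesion], toy_parc.tract_masks)
        assert feats.total_wmh_ml.iloc[0] > 0
        assert (feats.tract_wmh_ml.iloc[0] == 0).all()

    def test_overlapping_tracts_both_count_full_lesion(self):
        shape = (6, 6, 6)
        lesion_data = np.zeros(shape)
        lesion_data[2:4, 2:4, 2:4] = 1
        lesion = make_mask(lesion_data)
        tract = make_mask(np.ones(shape))
        feats = w.volumetric_features([lesion], {101: tract, 102: tract})
        total = feats.total_wmh_ml.iloc[0]
        assert feats.tract_wmh_ml.loc[0, 101] == pytest.approx(total)
        assert feats.tract_wmh_ml.loc[0, 102] == pytest.approx(total)


class TestCoupling:
    def test_affine_relation_gives_unit_correlation(self, small_cohort):
        f = small_cohort.flnm
        s = w.LNMScoreMatrix("sLNM", "positive", 1.0, 2 * f.scores + 1,
                             f.n_voxels_used, f.empty_selection)
        summary = w.structure_function_coupling(f, s)
        assert summary.mean_across_rois == pytest.approx(1.0)
        assert summary.sd_across_rois == pytest.approx(0.0, abs=1e-12)

    def test_independent_scores_have_null_coupling(self, small_cohort):
        rng = np.random.default_rng(11)
        f = small_cohort.flnm
        s = w.LNMScoreMatrix(
            "sLNM", "positive", 1.0,
            f.scores * 0 + rng.normal(size=f.scores.shape),
            f.n_voxels_used, f.empty_selection,
        )
        summary = w.structure_function_coupling(f, s)
        assert abs(summary.mean_across_rois) < 3 / np.sqrt(f.scores.shape[1])

    def test_single_roi_flags_undefined_across_roi_correlations(self, small_cohort):
        f = small_cohort.flnm
        one = w.LNMScoreMatrix("fLNM", "positive", 1.0, f.scores.iloc[:, :1],
                               f.n_voxels_used.iloc[:, :1], f.empty_selection.iloc[:, :1])
        s_one = w.LNMScoreMatrix("sLNM", "positive", 1.0, f.scores.iloc[:, :1] * 2,
                                 f.n_voxels_used.iloc[:, :1], f.empty_selection.iloc[:, :1])
        summary = w.structure_function_coupling(one, s_one)
        assert summary.n_across_rois == 0
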