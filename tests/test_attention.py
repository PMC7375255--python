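"""Region attribution: scores, resampling, K-groups, t-maps, FDR, Dice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroattn.attention import (
    ROIAttentionScores,
    _kgroup_partition,
    attention_mmse_map,
    dice,
    kgroup_validation,
    map_correlation,
    mask_cohort_to_regions,
    mean_attention_map,
    region_tmap,
    resample_to_input_grid,
    roi_attention_scores,
    top_fraction_regions,
)
from neuroattn.io import Parcellation

from conftest import make_cohort_from_arrays


def bh_stepup_oracle(pvals, alpha):
    """Textbook Benjamini-Hochberg step-up: reject p_(i) <= i/m * alpha."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    k = 0
    for i, idx in enumerate(order, start=1):
        if pvals[idx] <= alpha * i / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestMeanMap:
    def test_single_subject_is_identity(self, rng):
        m = rng.uniform(size=(1, 3, 3, 3))
        np.testing.assert_array_equal(mean_attention_map(None, m), m[0])

    def test_complementary_maps_average_to_half(self, rng):
        m = rng.uniform(size=(3, 3, 3))
        stack = np.stack([m, 1.0 - m])
        np.testing.assert_allclose(mean_attention_map(None, stack), 0.5, atol=1e-12)

    def test_matches_elementwise_mean_oracle(self, rng):
        stack = rng.uniform(size=(10, 4, 4, 4))
        ref = sum(stack[i] for i in range(10)) / 10.0
        np.testing.assert_allclose(mean_attention_map(None, stack), ref, atol=1e-12)


class TestResample:
    def test_constant_map_stays_constant(self):
        out = resample_to_input_grid(np.full((3, 4, 3), 0.7), (9, 16, 9))
        np.testing.assert_allclose(out, 0.7, atol=1e-12)

    def test_identity_resample_is_exact(self, rng):
        m = rng.uniform(size=(5, 6, 5))
        np.testing.assert_allclose(resample_to_input_grid(m, (5, 6, 5)), m,
                                   atol=1e-12)

    def test_2cube_to_4cube_matches_hand_trilinear(self):
        m = np.zeros((2, 2, 2))
        m[1, 0, 0] = 1.0  # corner source; align-corners weights are 0, 1/3, 2/3, 1
        out = resample_to_input_grid(m, (4, 4, 4))
        w = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        expected = (w[:, None, None]) * (1 - w)[None, :, None] * (1 - w)[None, None, :]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_bounded_by_input_range(self, rng):
        m = rng.uniform(0.2, 0.9, size=(4, 5, 4))
        out = resample_to_input_grid(m, (13, 17, 13))
        assert out.min() >= m.min() - 1e-12
        assert out.max() <= m.max() + 1e-12

    def test_zero_sized_target_rejected(self):
        with pytest.raises(ValueError):
            resample_to_input_grid(np.ones((3, 3, 3)), (0, 4, 4))


class TestROIScores:
    def _two_region_parc(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[:2] = 1
        labels[2:] = 2
        return Parcellation(labels=labels, region_ids=[1, 2])

    def test_piecewise_constant_map(self):
        parc = self._two_region_parc()
        m = np.where(parc.labels == 1, 0.5, 0.2)
        scores = roi_attention_scores(m, parc)
        np.testing.assert_allclose(scores.scores, [0.5, 0.2])

    def test_constant_map_gives_constant_scores(self, tiny_parcellation):
        m = np.full((16, 16, 16), 0.37)
        scores = roi_attention_scores(m, tiny_parcellation)
        np.testing.assert_allclose(scores.scores, 0.37)

    def test_matches_masked_mean_oracle(self, rng):
        from neuroattn.simulate import make_toy_parcellation
        parc = make_toy_parcellation((10, 10, 10), 5, seed=3)
        m = rng.uniform(size=(10, 10, 10))
        scores = roi_attention_scores(m, parc)
        for rid, s in zip(parc.region_ids, scores.scores):
            assert s == pytest.approx(m[parc.labels == rid].mean(), abs=1e-12)

    def test_shape_mismatch_raises(self, tiny_parcellation):
        with pytest.raises(ValueError):
            roi_attention_scores(np.ones((4, 4, 4)), tiny_parcellation)


class TestTopFraction:
    def test_full_fraction_selects_all(self):
        s = ROIAttentionScores(scores=np.arange(7.0), region_ids=list(range(1, 8)))
        assert top_fraction_regions(s, 1.0) == set(range(1, 8))

    def test_thirty_percent_of_273_is_82(self, rng):
        s = ROIAttentionScores(scores=rng.random(273),
                               region_ids=list(range(1, 274)))
        assert len(top_fraction_regions(s, 0.30)) == 82

    def test_rounding_rule_at_half(self):
        s = ROIAttentionScores(scores=np.arange(1.0, 11.0),
                               region_ids=list(range(1, 11)))
        # round(0.25 * 10) = round(2.5) = 2 -> the two top scorers
        assert top_fraction_regions(s, 0.25) == {9, 10}

    def test_ties_break_by_ascending_region_id(self):
        s = ROIAttentionScores(scores=np.ones(4), region_ids=[4, 1, 3, 2])
        assert top_fraction_regions(s, 0.5) == {1, 2}


class TestKGroup:
    def test_partition_sizes(self):
        s6 = ROIAttentionScores(scores=np.arange(6.0), region_ids=list(range(1, 7)))
        assert [len(g) for g in _kgroup_partition(s6, 3)] == [2, 2, 2]
        s7 = ROIAttentionScores(scores=np.arange(7.0), region_ids=list(range(1, 8)))
        assert [len(g) for g in _kgroup_partition(s7, 3)] == [2, 2, 3]

    def test_sorted_descending_with_id_tiebreak(self):
        s = ROIAttentionScores(scores=np.array([1.0, 3.0, 1.0, 2.0]),
                               region_ids=[1, 2, 3, 4])
        groups = _kgroup_partition(s, 2)
        assert groups == [[2, 4], [1, 3]]

    def test_constant_scores_partition_by_region_id(self):
        s = ROIAttentionScores(scores=np.zeros(6), region_ids=[6, 5, 4, 3, 2, 1])
        groups = _kgroup_partition(s, 3)
        assert groups == [[1, 2], [3, 4], [5, 6]]

    def test_k_larger_than_regions_rejected(self):
        s = ROIAttentionScores(scores=np.zeros(3), region_ids=[1, 2, 3])
        with pytest.raises(ValueError):
            _kgroup_partition(s, 4)

    def test_masking_zeroes_out_other_regions(self, tiny_cohort, tiny_parcellation):
        masked = mask_cohort_to_regions(tiny_cohort, tiny_parcellation, [1, 2])
        keep = np.isin(tiny_parcellation.labels, [1, 2])
        for sid in tiny_cohort.ids[:3]:
            vals = masked.volumes[sid].values
            assert np.all(vals[~keep] == 0)
            np.testing.assert_array_equal(vals[keep],
                                          tiny_cohort.volumes[sid].values[keep])

    def test_kgroup_correlation_with_mock_trainer(self, tiny_cohort,
                                                  tiny_parcellation):
        """A trainer rewarding high-attention groups yields r close to 1."""
        rng = np.random.default_rng(0)
        s = ROIAttentionScores(scores=rng.random(12), region_ids=list(range(1, 13)))
        by_id = dict(zip(s.region_ids, s.scores))

        def fake_train(masked):
            present = {rid for rid in s.region_ids
                       if masked.volumes[masked.ids[0]].values[
                           tiny_parcellation.labels == rid].any()}
            return 0.5 + 0.5 * np.mean([by_id[r] for r in present])

        binning = kgroup_validation(s, 4, tiny_cohort, tiny_parcellation, fake_train)
        assert binning.K == 4
        assert [len(g) for g in binning.group_members] == [3, 3, 3, 3]
        assert binning.r > 0.99


class TestRegionTmap:
    def _flat_parc(self):
        labels = np.ones((4, 4, 4), dtype=np.int32)
        labels[2:] = 2
        return Parcellation(labels=labels, region_ids=[1, 2])

    def test_identical_groups_give_zero_t(self):
        parc = self._flat_parc()
        base = np.random.default_rng(0).uniform(0.4, 0.6, size=(4, 4, 4))
        cohort = make_cohort_from_arrays([base] * 6, ["AD"] * 3 + ["NC"] * 3,
                                         age=70.0, sex=0)
        t = region_tmap(cohort, parc, covariates=())
        np.testing.assert_allclose(t, 0.0, atol=1e-10)

    def test_matches_textbook_pooled_t(self):
        parc = self._flat_parc()
        rng = np.random.default_rng(1)
        vols, means = [], []
        for i in range(8):
            v = np.full((4, 4, 4), 0.5) + (0.05 if i < 4 else 0.0)
            v += rng.normal(0, 0.01, size=(4, 4, 4))
            vols.append(np.clip(v, 0, 1))
        cohort = make_cohort_from_arrays(vols, ["AD"] * 4 + ["NC"] * 4)
        t = region_tmap(cohort, parc, covariates=())
        # closed-form pooled t on the region means
        for j, rid in enumerate(parc.region_ids):
            x = np.array([v[parc.labels == rid].mean() for v in vols])
            a, b = x[:4] - x.mean(), x[4:] - x.mean()  # demeaned (intercept only)
            sp = np.sqrt(((a - a.mean()) ** 2).sum() / 3 + ((b - b.mean()) ** 2).sum() / 3)
            sp = np.sqrt((((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 6)
            ref = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 4 + 1 / 4))
            assert t[j] == pytest.approx(ref, rel=1e-10)

    def test_planted_region_has_largest_magnitude(self, tiny_cohort,
                                                  tiny_parcellation):
        t = region_tmap(tiny_cohort, tiny_parcellation)
        assert int(np.argmax(np.abs(t))) == 4  # planted region id 5

    def test_rank_deficient_covariates_rejected(self, tiny_cohort,
                                                tiny_parcellation):
        with pytest.raises(ValueError, match="rank"):
            region_tmap(tiny_cohort, tiny_parcellation,
                        covariates=("age", "age"))


class TestMMSEMap:
    def test_exact_linear_relation_gives_r_one(self, rng):
        n, R = 20, 5
        mmse = rng.integers(10, 30, n).astype(float)
        attn = rng.uniform(size=(n, R))
        attn[:, 2] = 0.01 * mmse + 0.3
        cmap = attention_mmse_map(attn, mmse)
        assert cmap.r[2] == pytest.approx(1.0)
        assert cmap.significant[2]

    def test_bh_example_rejects_first_three(self):
        pvals = np.array([0.001, 0.01, 0.02, 0.2, 0.9])
        # feed via precomputed correlations: check the BH mask directly
        reject = bh_stepup_oracle(pvals, 0.05)
        np.testing.assert_array_equal(reject, [True, True, True, False, False])
        from statsmodels.stats.multitest import multipletests
        np.testing.assert_array_equal(
            multipletests(pvals, alpha=0.05, method="fdr_bh")[0], reject)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=50))
    def test_bh_matches_stepup_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests
        p = np.asarray(pvals)
        np.testing.assert_array_equal(
            multipletests(p, alpha=0.05, method="fdr_bh")[0],
            bh_stepup_oracle(p, 0.05))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            attention_mmse_map(np.ones((2, 3)), np.array([1.0, 2.0]))

    def test_null_data_controls_discoveries(self):
        """Mean BH discovery proportion under the null stays near alpha."""
        rng = np.random.default_rng(0)
        n, R = 30, 20
        fdp = []
        for _ in range(300):
            attn = rng.uniform(size=(n, R))
            mmse = rng.integers(0, 31, n).astype(float)
            cmap = attention_mmse_map(attn, mmse, alpha=0.05)
            fdp.append(cmap.significant.mean())
        assert np.mean(fdp) <= 0.05 * 1.3


class TestDiceAndMapCorrelation:
    def test_identical_sets_give_one(self):
        assert dice({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert dice({1, 2}, {3, 4}) == 0.0

    def test_half_overlap(self):
        assert dice({1, 2, 3, 4}, {3, 4, 5, 6}) == 0.5

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            dice(set(), set())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 20), min_size=1),
           st.sets(st.integers(0, 20), min_size=1))
    def test_symmetric_and_bounded(self, a, b):
        assert dice(a, b) == dice(b, a)
        assert 0.0 <= dice(a, b) <= 1.0

    def test_identical_vectors_r_one(self, rng):
        v = rng.normal(size=10)
        r, _ = map_correlation(v, v)
        assert r == pytest.approx(1.0)

    def test_negated_vector_r_minus_one(self, rng):
        v = rng.normal(size=10)
        r, _ = map_correlation(v, -v)
        assert r == pytest.approx(-1.0)

    def test_closed_form_example(self):
        r, _ = map_correlation([1, 2, 3, 4], [1, 2, 4, 3])
        assert r == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            map_correlation([1, 1, 1, 1], [1, 2, 3, 4])


# The planted-effect attention-recovery property (graded effects vs mean ROI
# attention across seeds) trains full networks and lives in the acceptance
# suite (tests/test_acceptance.py), which shares one set of trained models
# between the recovery and K-group analyses.
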