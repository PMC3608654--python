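import math

import numpy as np
import pytest
from scipy import stats as sps

from ezmap import (cluster_inference, count_abnormal, detect_abnormalities,
                   ellipsoid_mask, estimate_smoothness, fwer_pseudo_t,
                   grf_cluster_p, reference_stats, smoothness_from_fwhm,
                   voxel_threshold, z_map, ez_map, bootstrap_sd_map)
from ezmap.clusters import (AbnormalityResult, Cluster, ClusterSet,
                            drop_small_clusters, PseudoTFWERScorer)
from ezmap.exceptions import ContractError, ValidationError
from ezmap.scoring import ScoreMap
from ezmap.simulate import smooth_unit_field

from conftest import make_cohort


def _score(vals, mask, kind="EZ", null=None):
    return ScoreMap(np.asarray(vals, float), kind,
                    null or {"kind": "gaussian"}, 20, mask)


class TestVoxelThreshold:
    def test_zero_map_nothing_supra(self, small_mask):
        high, low = voxel_threshold(_score(np.zeros(small_mask.shape), small_mask), 0.05)
        assert not high.any() and not low.any()

    def test_gaussian_null_rate_matches_alpha(self, rng):
        mask = np.ones((40, 40, 40), bool)
        high, low = voxel_threshold(_score(rng.standard_normal(mask.shape), mask), 0.05)
        frac = (high.sum() + low.sum()) / mask.sum()
        assert frac == pytest.approx(0.05, abs=0.003)  # binomial 5 sigma ~ 0.0014

    def test_far_tail_voxel_is_detected(self, small_mask):
        vals = np.zeros(small_mask.shape)
        idx = tuple(np.argwhere(small_mask)[0])
        vals[idx] = 5.0
        high, low = voxel_threshold(_score(vals, small_mask), 0.05)
        assert high[idx] and high.sum() == 1 and not low.any()

    def test_t_null_uses_t_quantile(self, small_mask):
        vals = np.full(small_mask.shape, 2.05)  # between z and t(19) criticals
        sm = _score(vals, small_mask, "T", {"kind": "t", "df": 19})
        high, _ = voxel_threshold(sm, 0.05)
        assert not high.any()  # t(19) critical is 2.093 > 2.05
        high, _ = voxel_threshold(_score(vals, small_mask), 0.05)
        assert high[small_mask].all()  # Gaussian critical is 1.96

    def test_invalid_alpha(self, small_mask):
        with pytest.raises(ValidationError):
            voxel_threshold(_score(np.zeros(small_mask.shape), small_mask), 1.5)


class TestSmoothness:
    def test_white_noise_hits_resolution_floor(self, rng, small_mask):
        cohort = make_cohort(rng, 30, small_mask)
        sm = estimate_smoothness(cohort)
        floor = math.sqrt(2 * math.log(2))  # sqrt(4 ln 2 / 2) ~ 1.18 voxels
        for f in sm.fwhm:
            assert f == pytest.approx(floor, rel=0.1)

    def test_recovers_known_kernel_fwhm(self, rng):
        mask = ellipsoid_mask((28, 28, 28))
        arrays = [0.45 + 0.05 * smooth_unit_field(rng, mask.shape, 4.0)
                  for _ in range(25)]
        from ezmap import cohort_from_arrays
        cohort = cohort_from_arrays(arrays, mask)
        sm = estimate_smoothness(cohort)
        for f in sm.fwhm:
            assert f == pytest.approx(4.0, rel=0.15)

    def test_resels_proportional_to_mask_volume(self):
        a = smoothness_from_fwhm(3.0, 1000)
        b = smoothness_from_fwhm(3.0, 2000)
        assert b.resel_count == pytest.approx(2 * a.resel_count)


class TestGRFInference:
    def test_empty_supra_gives_empty_clusterset(self, small_mask):
        sm = smoothness_from_fwhm(3.0, int(small_mask.sum()))
        cs = cluster_inference((np.zeros(small_mask.shape, bool),
                                np.zeros(small_mask.shape, bool)), sm, 0.05, 0.05)
        assert len(cs) == 0

    def test_cluster_p_decreases_with_size(self):
        sm = smoothness_from_fwhm(3.0, 10_000)
        u = sps.norm.ppf(0.975)
        p = [grf_cluster_p(k, u, sm)[1] for k in (10, 50, 200, 800)]
        assert all(a > b for a, b in zip(p, p[1:]))
        assert 0 <= p[-1] <= p[0] <= 1

    def test_tightening_thresholds_never_adds_voxels(self, rng):
        """The suprathreshold sets are nested in alpha1, and at fixed
        alpha1 the surviving clusters/counts are monotone in alpha2.
        (Corrected cluster counts need not be monotone in alpha1: a
        tighter voxel threshold makes a given cluster size rarer.)"""
        mask = ellipsoid_mask((24, 24, 24))
        vals = smooth_unit_field(rng, mask.shape, 3.0)
        vals[9:15, 9:15, 9:15] -= 4.0
        sm = smoothness_from_fwhm(3.0, int(mask.sum()))
        score = _score(vals, mask)
        h1, l1 = voxel_threshold(score, 0.05)
        h2, l2 = voxel_threshold(score, 0.01)
        assert (h2 <= h1).all() and (l2 <= l1).all()
        counts, nclusters = {}, {}
        for a2 in (0.05, 0.01):
            res = detect_abnormalities(score, sm, 0.05, a2, True)
            counts[a2] = res.metrics["n_all"]
            nclusters[a2] = len(res.surviving_clusters)
        assert nclusters[0.01] <= nclusters[0.05]
        assert counts[0.01] <= counts[0.05]
        assert counts[0.05] > 0  # the inserted focal drop survives

    def test_sign_partition_is_disjoint(self, rng):
        mask = ellipsoid_mask((24, 24, 24))
        vals = 2.0 * smooth_unit_field(rng, mask.shape, 3.0)
        sm = smoothness_from_fwhm(3.0, int(mask.sum()))
        res = detect_abnormalities(_score(vals, mask), sm, 0.2, 0.5, False)
        assert not (res.abnormal_high & res.abnormal_low).any()
        n_all, n_low, n_high = count_abnormal(res)
        assert n_all == n_low + n_high

    def test_lesion_cluster_survives(self, rng):
        mask = ellipsoid_mask((24, 24, 24))
        sm = smoothness_from_fwhm(3.0, int(mask.sum()))
        hits = 0
        for _ in range(20):
            vals = smooth_unit_field(rng, mask.shape, 3.0)
            vals[8:15, 8:15, 8:15] -= 3.0  # strong focal drop
            res = detect_abnormalities(_score(vals, mask), sm, 0.05, 0.05, True)
            hits += any(c.sign == "low" and c.size > 100
                        for c in res.surviving_clusters.clusters)
        assert hits >= 18

    def test_zero_resels_contract(self):
        with pytest.raises(ValidationError):
            smoothness_from_fwhm(3.0, 0)


def test_count_abnormal_additivity(small_mask):
    high = np.zeros(small_mask.shape, bool)
    low = np.zeros(small_mask.shape, bool)
    coords = np.argwhere(small_mask)
    high[tuple(coords[:150].T)] = True
    low[tuple(coords[150:200].T)] = True
    res = AbnormalityResult(high, low, ClusterSet([]), {})
    assert count_abnormal(res) == (200, 50, 150)


def test_drop_small_clusters_strict_inequality():
    vol = np.zeros((10, 10, 10), bool)
    vol[0, 0, :5] = True   # size 5
    vol[5, 5, :6] = True   # size 6
    kept = drop_small_clusters(vol, gate=5, connectivity=26)
    assert kept.sum() == 6  # only the size-6 component is "more than 5"


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(31)
    return make_cohort(rng, 15, ellipsoid_mask((16, 16, 16)))


class TestFwerPseudoT:
    def test_reference_mean_subject_is_clean(self, reference):
        stats = reference_stats(reference)
        subject = reference.grid.with_data(stats.mean_map)
        res = fwer_pseudo_t(subject, reference)
        assert res.metrics["n_all"] == 0

    def test_null_subject_family_rate(self, reference, rng):
        hits = 0
        for _ in range(40):
            subject = reference.grid.with_data(
                0.45 + 0.05 * rng.standard_normal(reference.grid.shape))
            res = fwer_pseudo_t(subject, reference, alpha_per_tail=0.05)
            hits += res.metrics["n_all"] > 0
        # two tails at 5% each -> ~10% of null subjects flag something
        assert hits / 40 <= 0.3

    def test_more_conservative_than_ez(self, smooth_study):
        _, reference, _, patients, _ = smooth_study
        stats = reference_stats(reference)
        sm = estimate_smoothness(reference, stats)
        boot = bootstrap_sd_map(reference, n=20, B=400, seed=8)
        ez_counts, fw_counts = [], []
        for vol in patients.volumes:
            em = ez_map(z_map(vol, stats), boot)
            ez_counts.append(detect_abnormalities(em, sm, 0.05, 0.05, True).metrics["n_all"])
            fw_counts.append(fwer_pseudo_t(vol, reference).metrics["n_all"])
        assert np.mean(fw_counts) <= np.mean(ez_counts)

    def test_smoothed_sd_calibration_attributes(self, reference):
        est = PseudoTFWERScorer(mask=reference.mask,
                                voxel_size=reference.grid.voxel_size).fit(
            reference.as_matrix())
        assert est.threshold_high_ > 0 and est.threshold_low_ > 0
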