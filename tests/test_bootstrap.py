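import numpy as np
import pytest
from scipy import stats as sps

from ezmap import (EZScorer, bootstrap_sd_map, classify_dispersion, ez_map,
                   tail_probability, uncoverage_rate, z_map, reference_stats)
from ezmap.bootstrap import CLASS_CLOSE, CLASS_OVER, CLASS_UNDER, _bootstrap_sd
from ezmap.exceptions import (ContractError, GridCompatibilityError,
                              InsufficientCohortError, ValidationError)
from ezmap.scoring import ScoreMap

from conftest import make_cohort


@pytest.fixture(scope="module")
def boot_cohort():
    rng = np.random.default_rng(77)
    from ezmap import ellipsoid_mask
    mask = ellipsoid_mask((14, 14, 14))
    return make_cohort(rng, 30, mask)


@pytest.fixture(scope="module")
def boot(boot_cohort):
    return bootstrap_sd_map(boot_cohort, n=20, B=2000, seed=5)


class TestBootstrapSD:
    def test_matches_held_out_z_oracle(self, boot, boot_cohort):
        """Under iid Gaussian data the Z-score of a held-out control is
        sqrt(1 + 1/n) * t(n-1); its SD for n=20 is ~1.083.  (Oracle:
        closed form, cross-checked by direct simulation below.)"""
        target = np.sqrt(1 + 1 / 20) * np.sqrt(19 / 17)
        med = np.median(boot.sd_star[boot_cohort.mask])
        assert med == pytest.approx(target, abs=0.03)
        # independent simulation oracle for the same quantity
        rng = np.random.default_rng(1)
        d = rng.standard_normal((20_000, 21))
        z = (d[:, 20] - d[:, :20].mean(1)) / d[:, :20].std(1, ddof=1)
        assert np.std(z) == pytest.approx(target, abs=0.02)

    def test_ratio_centers_on_theoretical_t_sd(self, boot, boot_cohort):
        ratio = boot.sd_star[boot_cohort.mask] / np.sqrt(1 + 1 / 20)
        assert np.median(ratio) == pytest.approx(1.06, abs=0.03)

    def test_mean_z_bias_is_small(self, boot, boot_cohort):
        assert np.median(np.abs(boot.mean_z[boot_cohort.mask])) < 0.1

    def test_reproducible_with_same_seed(self, boot_cohort):
        a = bootstrap_sd_map(boot_cohort, n=20, B=200, seed=9)
        b = bootstrap_sd_map(boot_cohort, n=20, B=200, seed=9)
        assert np.array_equal(a.sd_star, b.sd_star, equal_nan=True)

    def test_spread_shrinks_with_reference_size(self, rng, small_mask):
        cohort = make_cohort(rng, 60, small_mask)
        iqrs = []
        for i, n in enumerate((10, 20, 40)):
            b = bootstrap_sd_map(cohort, n=n, B=800, seed=50 + i)
            v = b.sd_star[small_mask]
            q1, q3 = np.percentile(v[np.isfinite(v)], [25, 75])
            iqrs.append(q3 - q1)
        assert iqrs[0] > iqrs[1] > iqrs[2]

    def test_holdout_scheme_runs_and_differs(self, boot_cohort):
        a = bootstrap_sd_map(boot_cohort, n=20, B=200, seed=9, scheme="holdout")
        b = bootstrap_sd_map(boot_cohort, n=20, B=200, seed=9, scheme="resample")
        assert not np.array_equal(a.sd_star, b.sd_star, equal_nan=True)

    def test_insufficient_controls(self, boot_cohort):
        with pytest.raises(InsufficientCohortError):
            bootstrap_sd_map(boot_cohort, n=len(boot_cohort), B=100)

    def test_degenerate_replicates_dropped_voxelwise(self):
        # one constant voxel: every replicate has zero reference SD there
        X = np.random.default_rng(0).standard_normal((10, 4))
        X[:, 2] = 0.7
        sd, mz, dropped = _bootstrap_sd(X, n=5, B=50, rng=np.random.default_rng(1))
        assert np.isnan(sd[2]) and dropped == 50
        assert np.isfinite(sd[[0, 1, 3]]).all()


class TestEZMap:
    def _zmap(self, cohort, rng):
        stats = reference_stats(cohort)
        subject = cohort.grid.with_data(
            0.45 + 0.05 * rng.standard_normal(cohort.grid.shape))
        return z_map(subject, stats)

    def test_unit_sd_star_is_identity(self, boot, boot_cohort, rng):
        zm = self._zmap(boot_cohort, rng)
        unit = type(boot)(np.ones_like(boot.sd_star), boot.mean_z, boot.B,
                          boot.n, boot.seed, boot.mask, boot.voxel_size)
        em = ez_map(zm, unit)
        ok = np.isfinite(zm.values)
        assert np.allclose(em.values[ok], zm.values[ok])

    def test_simple_arithmetic(self, boot, boot_cohort):
        vals = np.full(boot.mask.shape, np.nan); vals[boot.mask] = 3.0
        zm = ScoreMap(vals, "Z", {"kind": "gaussian"}, 20, boot.mask)
        half = type(boot)(np.full_like(boot.sd_star, 1.5), boot.mean_z, boot.B,
                          boot.n, boot.seed, boot.mask)
        em = ez_map(zm, half)
        assert em.values[boot.mask] == pytest.approx(2.0)
        assert em.statistic_kind == "EZ"

    def test_ez_is_more_conservative_when_sd_star_exceeds_one(self, boot, boot_cohort, rng):
        zm = self._zmap(boot_cohort, rng)
        em = ez_map(zm, boot)
        ok = boot.mask & np.isfinite(em.values) & (boot.sd_star > 1)
        assert np.all(np.abs(em.values[ok]) < np.abs(zm.values[ok]) + 1e-12)
        c = sps.norm.ppf(0.975)
        assert (np.abs(em.values[ok]) > c).sum() <= (np.abs(zm.values[ok]) > c).sum()

    def test_requires_z_map(self, boot, boot_cohort, rng):
        stats = reference_stats(boot_cohort)
        from ezmap import t_map
        subject = boot_cohort.grid.with_data(np.full(boot.mask.shape, 0.45))
        with pytest.raises(ContractError):
            ez_map(t_map(subject, stats), boot)

    def test_grid_mismatch(self, boot):
        vals = np.zeros((4, 4, 4))
        zm = ScoreMap(vals, "Z", {"kind": "gaussian"}, 20, np.ones((4, 4, 4), bool))
        with pytest.raises(GridCompatibilityError):
            ez_map(zm, boot)

    def test_estimator_transform_matches_wrapper(self, boot_cohort, rng):
        X = boot_cohort.as_matrix()
        est = EZScorer(B=300, n_reference=20, seed=5).fit(X)
        subject = 0.45 + 0.05 * rng.standard_normal(X.shape[1])
        ez_est = est.transform(subject)
        boot2 = bootstrap_sd_map(boot_cohort, n=20, B=300, seed=5)
        stats = reference_stats(boot_cohort.subset(range(20)))
        zm = z_map(boot_cohort.grid.with_masked_values(subject), stats)
        em = ez_map(zm, boot2)
        assert np.allclose(ez_est, em.values[boot_cohort.mask], equal_nan=True)


class TestTailProbability:
    def _score(self, value, mask):
        vals = np.full(mask.shape, np.nan); vals[mask] = value
        return ScoreMap(vals, "EZ", {"kind": "gaussian"}, 20, mask)

    @pytest.mark.parametrize("value, expected, tol", [
        (0.0, 1.0, 1e-12),
        (1.959964, 0.05, 1e-6),
        (-1.959964, 0.05, 1e-6),
        (3.0, 0.0026998, 1e-6),
    ])
    def test_two_sided_gaussian_tail(self, small_mask, value, expected, tol):
        tp = tail_probability(self._score(value, small_mask))
        assert tp.data[small_mask] == pytest.approx(expected, abs=tol)

    def test_rejects_t_null(self, small_mask):
        vals = np.zeros(small_mask.shape)
        tm = ScoreMap(vals, "T", {"kind": "t", "df": 19}, 20, small_mask)
        with pytest.raises(ContractError):
            tail_probability(tm)


class TestDispersionClasses:
    def test_band_closed_form(self, boot):
        disp = classify_dispersion(boot, df=19, delta=10)
        assert disp.psi_L == pytest.approx(np.sqrt(29 / 27), abs=1e-9)
        assert disp.psi_U == pytest.approx(np.sqrt(9 / 7), abs=1e-9)
        assert disp.psi_L < np.sqrt(19 / 17) < disp.psi_U

    def test_class_assignment(self, boot):
        ratio = 1.06  # inside the band
        fake = type(boot)(np.full_like(boot.sd_star, ratio * np.sqrt(1 + 1 / 20)),
                          boot.mean_z, boot.B, 20, None, boot.mask)
        assert (classify_dispersion(fake, 19, 10).classes[boot.mask] == CLASS_CLOSE).all()
        fake.sd_star = np.full_like(boot.sd_star, 1.20 * np.sqrt(1 + 1 / 20))
        assert (classify_dispersion(fake, 19, 10).classes[boot.mask] == CLASS_OVER).all()
        fake.sd_star = np.full_like(boot.sd_star, 1.00 * np.sqrt(1 + 1 / 20))
        assert (classify_dispersion(fake, 19, 10).classes[boot.mask] == CLASS_UNDER).all()

    def test_undefined_variance_guard(self, boot):
        with pytest.raises(ContractError):
            classify_dispersion(boot, df=11, delta=10)


class TestUncoverage:
    def test_zero_map_has_zero_uncoverage(self, small_mask):
        vals = np.zeros(small_mask.shape)
        sm = ScoreMap(vals, "Z", {"kind": "gaussian"}, 20, small_mask)
        assert uncoverage_rate(sm, 0.05) == 0.0

    def test_standard_gaussian_matches_nominal(self, rng):
        mask = np.ones((50, 50, 40), bool)  # 1e5 voxels
        vals = rng.standard_normal(mask.shape)
        sm = ScoreMap(vals, "Z", {"kind": "gaussian"}, 20, mask)
        assert uncoverage_rate(sm, 0.05) == pytest.approx(0.05, abs=0.005)

    def test_invalid_lambda(self, small_mask):
        sm = ScoreMap(np.zeros(small_mask.shape), "Z", {"kind": "gaussian"}, 20, small_mask)
        with pytest.raises(ValidationError):
            uncoverage_rate(sm, 1.5)
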