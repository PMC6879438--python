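import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mclrad.radiomics import extract_all
from mclrad.synthdata import (
    CohortConfig,
    ScannerBatch,
    generate_cohort,
    generate_lesion_volume,
    inject_batch_effects,
)


def small_config(**kw):
    defaults = dict(
        n_patients=4,
        grid_shape=(32, 32, 24),
        lesion_radius_mm=(8.0, 14.0),
        suvmean_range=(3.0, 8.0),
        seed=7,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestLesionVolumes:
    def test_same_seed_bit_identical(self):
        cfg = small_config()
        v1, m1, s1 = generate_lesion_volume(cfg, 2)
        v2, m2, s2 = generate_lesion_volume(cfg, 2)
        np.testing.assert_array_equal(v1.grid, v2.grid)
        np.testing.assert_array_equal(m1.mask, m2.mask)
        pd.testing.assert_frame_equal(s1, s2)

    def test_homogeneous_limit_constant_interior_zero_entropy(self):
        cfg = small_config(noise_sd=0.0)
        vol, mask, _ = generate_lesion_volume(cfg, 0)
        interior = vol.grid[mask.mask]
        assert np.allclose(interior, interior[0])
        row = extract_all(vol, mask.mask, min_pairs=1)
        assert row["entropy"] == pytest.approx(0.0, abs=1e-12)
        assert row["angular_second_moment"] == pytest.approx(1.0)

    def test_hottest_voxel_exceeds_41pct_of_lesion_mean(self):
        cfg = small_config()
        for i in range(5):
            vol, mask, _ = generate_lesion_volume(cfg, i)
            vals = vol.grid[mask.mask]
            assert vals.max() > 0.41 * vals.mean()

    def test_oversized_lesion_rejected(self):
        cfg = small_config(grid_shape=(8, 8, 8), lesion_radius_mm=(60.0, 80.0))
        with pytest.raises(ValueError, match="field of view"):
            generate_lesion_volume(cfg, 0)

    def test_short_correlation_raises_entropy_vs_long(self):
        # Monte-Carlo over 50 patients per arm: finer texture (short
        # correlation length) must raise the mean co-occurrence Entropy
        def mean_entropy(corr_range, seed):
            cfg = small_config(
                n_patients=50, texture_corr_length_mm=corr_range,
                lesions_per_patient=(1, 1), seed=seed,
            )
            vals = []
            for i in range(cfg.n_patients):
                vol, mask, _ = generate_lesion_volume(cfg, i)
                vals.append(extract_all(vol, mask.mask, min_pairs=1)["entropy"])
            return np.mean(vals)

        short = mean_entropy((3.0, 4.0), seed=11)
        long = mean_entropy((14.0, 15.0), seed=11)
        assert short > long


class TestCohortOutcomes:
    def test_cohort_determinism(self):
        cfg = small_config(n_patients=20)
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.patients, c2.patients)
        pd.testing.assert_frame_equal(c1.features, c2.features)
        pd.testing.assert_frame_equal(c1.truth, c2.truth)

    def test_null_logit_model_matches_intercept_probability(self):
        # all slopes zero: the two-year progression fraction is
        # expit(intercept) up to binomial error at n = 1000
        p_target = 0.3
        cfg = CohortConfig(
            n_patients=1000,
            outcome_logit_coeffs=(np.log(p_target / (1 - p_target)), 0.0, 0.0),
            censor_rate=0.0,
            seed=3,
        )
        co = generate_cohort(cfg)
        frac = co.patients.pfs2y_event.mean()
        sd = np.sqrt(p_target * (1 - p_target) / 1000)
        assert abs(frac - p_target) < 3 * sd

    def test_intercept_calibrated_to_study_progression_rate(self):
        # defaults target ~37.2% two-year progression; check at n=107
        cfg = CohortConfig(n_patients=107, seed=42)
        co = generate_cohort(cfg)
        frac = co.patients.pfs2y_event.mean()
        sd = np.sqrt(0.372 * 0.628 / 107)
        assert abs(frac - 0.372) < 3 * sd

    def test_hazard_log_hr_recovered_by_cox(self):
        from mclrad.survival import cox_hr

        # two risk steps (entropy cut-off unreachable), true HR = 2
        cfg = CohortConfig(
            n_patients=2000,
            outcome_logit_coeffs=None,
            baseline_hazard=0.03,
            hazard_log_hr=np.log(2.0),
            censor_rate=0.0,
            suvmean_cutoff=4.0,
            entropy_cutoff=1e9,
            suvmean_range=(1.0, 7.0),
            seed=9,
        )
        co = generate_cohort(cfg)
        steps = co.truth.risk_step.to_numpy()
        assert set(steps) == {0, 1}
        res = cox_hr(
            co.patients.pfs_months, co.patients.progressed, steps, reference=0
        )
        assert res.hazard_ratios[1] == pytest.approx(2.0, rel=0.10)

    def test_censoring_rate_roughly_requested(self):
        cfg = CohortConfig(n_patients=2000, censor_rate=0.3, seed=5)
        co = generate_cohort(cfg)
        assert abs((~co.patients.progressed).mean() - 0.3) < 0.05

    def test_event2y_consistent_with_true_times(self):
        co = generate_cohort(small_config(n_patients=50))
        np.testing.assert_array_equal(
            co.patients.pfs2y_event.to_numpy(), co.truth.time_true.to_numpy() <= 24.0
        )
        # progressed patients with an early event always satisfy the 2y flag
        obs = co.patients
        early = obs.progressed & (obs.pfs_months <= 24)
        assert np.all(obs.pfs2y_event[early])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=0).validate()
        with pytest.raises(ValueError):
            CohortConfig(censor_rate=1.5).validate()
        with pytest.raises(ValueError):
            CohortConfig(lesion_radius_mm=(5.0, 2.0)).validate()


class TestBatchEffects:
    def _table(self, rng, n=300):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "scanner": rng.choice(["A", "B"], size=n),
                "f1": rng.normal(10, 2, n),
                "f2": rng.normal(-3, 1, n),
            }
        )

    def test_identity_map_leaves_table_unchanged(self, rng):
        tbl = self._table(rng)
        out = inject_batch_effects(tbl, {"A": (0.0, 1.0), "B": (0.0, 1.0)})
        pd.testing.assert_frame_equal(out, tbl)

    def test_shift_moves_only_target_batch_mean(self, rng):
        tbl = self._table(rng, n=2000)
        out = inject_batch_effects(tbl, {"A": (0.0, 1.0), "B": (5.0, 1.0)})
        gap = out[out.scanner == "B"].f1.mean() - out[out.scanner == "A"].f1.mean()
        base_gap = tbl[tbl.scanner == "B"].f1.mean() - tbl[tbl.scanner == "A"].f1.mean()
        assert gap - base_gap == pytest.approx(5.0, abs=1e-9)

    def test_scale_two_quadruples_batch_variance(self, rng):
        tbl = self._table(rng, n=1000)
        out = inject_batch_effects(tbl, {"A": (0.0, 1.0), "B": (0.0, 2.0)})
        ratio = out[out.scanner == "B"].f1.var() / out[out.scanner == "A"].f1.var()
        base = tbl[tbl.scanner == "B"].f1.var() / tbl[tbl.scanner == "A"].f1.var()
        assert ratio / base == pytest.approx(4.0, rel=0.02)

    def test_unknown_batch_label_rejected(self, rng):
        tbl = self._table(rng)
        with pytest.raises(ValueError, match="missing"):
            inject_batch_effects(tbl, {"A": (0.0, 1.0)})

    def test_scanner_batch_objects_accepted(self, rng):
        tbl = self._table(rng, n=50)
        out = inject_batch_effects(
            tbl,
            {"A": ScannerBatch("A", 1.0), "B": ScannerBatch("B", 1.0, shift=1.0)},
        )
        assert (out[out.scanner == "B"].f1 - tbl[tbl.scanner == "B"].f1).mean() == pytest.approx(1.0)


def test_monotone_association_with_logit_coefficient():
    """Stronger true SUVmean effect -> larger estimated logistic slope."""
    from mclrad.predict import logistic_univariate

    def slope(b1, seed):
        cfg = CohortConfig(
            n_patients=800,
            outcome_logit_coeffs=(-2.0, b1, 0.0),
            censor_rate=0.0,
            seed=seed,
        )
        co = generate_cohort(cfg)
        fit = logistic_univariate(
            co.truth.suvmean_true, co.patients.pfs2y_event.astype(int)
        )
        return fit.coef

    est = [np.mean([slope(b1, s) for s in range(8)]) for b1 in (0.0, 0.3, 0.6)]
    assert est[0] < est[1] < est[2]
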