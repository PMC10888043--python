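"""Phantom cohort generator: geometry, covariates, and hazard ground truth."""

import numpy as np
import pytest
from scipy.special import expit

from petctsurv.survival import harrell_c
from petctsurv.synthetic import (ClinicalRecord, HazardModel, PhantomParams,
                                 generate_cohort, overall_stage_from_tn,
                                 simulate_clinical, simulate_phantom_pair,
                                 simulate_survival, write_cohort)


class TestPhantoms:
    def test_pet_peak_is_gain_times_sigmoid_of_risk(self):
        params = PhantomParams(noise_sd=0.0)
        _, pet, _ = simulate_phantom_pair(params, 0.0, seed=7)
        assert pet.voxels.max() == pytest.approx(params.pet_hotspot_gain * 0.5)

    def test_same_seed_is_bit_identical(self):
        params = PhantomParams()
        a = simulate_phantom_pair(params, 0.3, seed=11)
        b = simulate_phantom_pair(params, 0.3, seed=11)
        for x, y in zip(a, b):
            assert np.array_equal(x.voxels, y.voxels)

    def test_tumor_pet_intensity_increases_with_risk(self):
        params = PhantomParams(noise_sd=0.0)
        means = []
        for lr in (-3.0, 3.0):
            _, pet, mask = simulate_phantom_pair(params, lr, seed=5)
            means.append(pet.voxels[mask.voxels > 0].mean())
        assert means[1] > means[0]

    def test_oversized_tumor_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            PhantomParams(tumor_radius_range=(4.0, 40.0), image_side=64)

    def test_shared_grid_and_modalities(self):
        ct, pet, mask = simulate_phantom_pair(PhantomParams(), 0.0, seed=1)
        assert ct.voxels.shape == pet.voxels.shape == mask.voxels.shape
        assert (ct.modality, pet.modality) == ("CT", "PET")


class TestClinical:
    def test_marginals_match_cohort_demographics(self):
        # male fraction 0.79, ages inside [18, 90]
        recs = [simulate_clinical(0.0, seed=s) for s in range(10_000)]
        male = np.mean([r.sex == "male" for r in recs])
        assert male == pytest.approx(0.79, abs=0.02)
        ages = np.array([r.age for r in recs])
        assert ages.min() >= 18 and ages.max() <= 90

    def test_stage_iv_saturates_at_high_risk(self):
        recs = [simulate_clinical(25.0, seed=s) for s in range(300)]
        frac_iv = np.mean([r.overall_stage == "IV" for r in recs])
        assert frac_iv == pytest.approx(1.0, abs=0.02)

    def test_overall_stage_map_is_monotone(self):
        order = {"I": 0, "II": 1, "III": 2, "IV": 3}
        for t in range(4):
            for n in range(4):
                s = order[overall_stage_from_tn(f"T{t+1}", f"N{n}")]
                if t < 3:
                    assert s <= order[overall_stage_from_tn(f"T{t+2}", f"N{n}")]
                if n < 3:
                    assert s <= order[overall_stage_from_tn(f"T{t+1}", f"N{n+1}")]

    def test_record_validation(self):
        with pytest.raises(ValueError, match="age"):
            ClinicalRecord(17, "male", "T1", "N0", "M0", "I")
        with pytest.raises(ValueError, match="M0"):
            ClinicalRecord(50, "male", "T1", "N0", "M1", "I")
        with pytest.raises(ValueError, match="inconsistent"):
            ClinicalRecord(50, "male", "T4", "N0", "M0", "I")


class TestSurvivalSimulation:
    def test_exponential_special_case_mean(self):
        # kappa=1, beta=0, rho=0.01/day, negligible censoring -> mean 100 days
        model = HazardModel(weibull_shape=1.0, weibull_rate=0.01,
                            beta=np.zeros(3), censor_rate=1e-12)
        times = [simulate_survival(model, np.zeros(3), "OS", seed=s).time
                 for s in range(20_000)]
        assert np.mean(times) == pytest.approx(100.0, rel=0.02)

    def test_no_signal_gives_chance_concordance(self, rng):
        model = HazardModel(beta=np.zeros(3))
        n = 5000
        covs = rng.normal(size=(n, 3))
        outs = [simulate_survival(model, covs[i], "OS", seed=i) for i in range(n)]
        from petctsurv.survival import SurvivalTable
        tab = SurvivalTable([str(i) for i in range(n)],
                            [o.time for o in outs], [o.event for o in outs])
        assert harrell_c(tab, covs[:, 0]) == pytest.approx(0.5, abs=0.02)

    def test_hazard_ratio_two_gives_mean_ratio_two(self):
        # exponential baseline: group B with beta'x = ln 2 fails twice as fast
        model = HazardModel(weibull_shape=1.0, weibull_rate=0.01,
                            beta=np.array([1.0]), censor_rate=1e-12)
        a = [simulate_survival(model, np.array([0.0]), "OS", seed=s).time
             for s in range(20_000)]
        b = [simulate_survival(model, np.array([np.log(2.0)]), "OS", seed=s).time
             for s in range(20_000)]
        assert np.mean(a) / np.mean(b) == pytest.approx(2.0, rel=0.04)

    def test_uncensored_survival_curve_matches_analytic_deciles(self):
        model = HazardModel(censor_rate=1e-12, beta=np.zeros(3))
        times = np.array([simulate_survival(model, np.zeros(3), "OS", seed=s).time
                          for s in range(20_000)])
        rho, kappa = model.weibull_rate, model.weibull_shape
        for q in np.arange(0.1, 1.0, 0.1):
            # analytic decile: S(t)=exp(-(rho t)^kappa) = 1-q
            t_q = (1.0 / rho) * (-np.log(1 - q)) ** (1 / kappa)
            assert np.mean(times <= t_q) == pytest.approx(q, abs=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HazardModel(weibull_shape=-1.0)
        with pytest.raises(ValueError):
            simulate_survival(HazardModel(), np.zeros(5), "OS", seed=0)


class TestCohorts:
    def test_concordance_grows_with_effect_size(self, rng):
        # C is 0.5 at beta=0 and increases monotonically with |beta|
        cs = []
        for scale in (0.0, 1.0, 3.0):
            model = HazardModel(beta=np.array([scale, 0.0, 0.0]))
            n = 2000
            covs = rng.normal(size=(n, 3))
            outs = [simulate_survival(model, covs[i], "OS", seed=10_000 + i)
                    for i in range(n)]
            from petctsurv.survival import SurvivalTable
            tab = SurvivalTable([str(i) for i in range(n)],
                                [o.time for o in outs], [o.event for o in outs])
            cs.append(harrell_c(tab, covs[:, 0]))
        assert cs[0] == pytest.approx(0.5, abs=0.03)
        assert cs[0] < cs[1] < cs[2]

    def test_cohort_is_pure_function_of_seed(self):
        a = generate_cohort(6, seed=3)
        b = generate_cohort(6, seed=3)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.pet.voxels, sb.pet.voxels)
            assert sa.outcomes["OS"].time == sb.outcomes["OS"].time
            assert sa.clinical == sb.clinical

    def test_write_cohort_layout_and_determinism(self, tmp_path):
        import hashlib
        import os
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            os.makedirs(d)
            write_cohort(10, out_dir=str(d), seed=5)
        files = os.listdir(d1 / "images")
        assert sum(f.endswith("_pet.nii.gz") for f in files) == 10
        assert sum(f.endswith("_ct.nii.gz") for f in files) == 10
        csum = lambda p: hashlib.sha256(open(p, "rb").read()).hexdigest()
        assert csum(d1 / "clinical.csv") == csum(d2 / "clinical.csv")
        assert csum(d1 / "survival_os.csv") == csum(d2 / "survival_os.csv")
        import pandas as pd
        assert len(pd.read_csv(d1 / "clinical.csv")) == 10
        with pytest.raises(FileExistsError):
            write_cohort(10, out_dir=str(d1), seed=5)

    def test_event_fraction_near_calibrated_target(self):
        # hazard + censoring defaults were calibrated to ~30% censoring
        cohort = generate_cohort(500, seed=9)
        frac_event = cohort.survival_table("OS").event.mean()
        assert frac_event == pytest.approx(0.70, abs=0.05)

    def test_true_predictor_concordance_at_default_signal(self):
        cohort = generate_cohort(500, seed=4)
        tab = cohort.survival_table("OS")
        assert harrell_c(tab, cohort.true_linear_predictor("OS")) >= 0.75
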