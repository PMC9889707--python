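"""Generator behaviour: seeded determinism, status-conditional latent
separation, dose laws, assay round-trips and cohort assembly."""

import json

import numpy as np
import pandas as pd
import pytest

import carstim as cs
from carstim.panel import child_rng
from carstim.synthetic import (
    DEFAULT_STATUS_LATENTS,
    CompartmentLaw,
    PhenotypeLaw,
    build_blood_law,
    build_product_law,
    expected_fractions,
    sample_events,
    true_class_fractions,
)


def _donor(status="healthy", threshold=0.22, cd8=0.0, eff=0.0):
    return cs.DonorProfile(
        donor_id="T01",
        status=status,
        latent_cd8_bias=cd8,
        latent_effector_bias=eff,
        latent_activation_threshold=threshold,
        random_effect_sd=0.15,
    )


class TestDonors:
    def test_seeded_determinism(self):
        a = cs.generate_donor("healthy", 1)
        b = cs.generate_donor("healthy", 1)
        assert a == b

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError, match="status"):
            cs.generate_donor("zombie", 1)

    def test_patient_latents_exceed_healthy_by_three_se(self):
        rng = np.random.default_rng(0)
        healthy = [cs.generate_donor("healthy", rng) for _ in range(1000)]
        patient = [cs.generate_donor("patient", rng) for _ in range(1000)]
        for attr in ("latent_cd8_bias", "latent_effector_bias"):
            h = np.array([getattr(d, attr) for d in healthy])
            p = np.array([getattr(d, attr) for d in patient])
            se = np.sqrt(h.var() / len(h) + p.var() / len(p))
            assert p.mean() - h.mean() > 3 * se
        th = np.array([d.latent_activation_threshold for d in healthy])
        tp = np.array([d.latent_activation_threshold for d in patient])
        assert tp.mean() < th.mean()
        assert (tp > 0).all()

    def test_zero_noise_profile_equals_distribution_means(self):
        config = cs.GenerationConfig(noise_sd=0.0)
        d = cs.generate_donor("patient", 1, config)
        lat = DEFAULT_STATUS_LATENTS["patient"]
        assert d.latent_cd8_bias == lat.cd8_bias_mean
        assert d.latent_effector_bias == lat.effector_bias_mean
        assert d.latent_activation_threshold == lat.threshold_mean

    def test_status_separable_from_true_blood_fractions(self):
        """A held-out linear discriminator on *true* blood fractions should
        separate healthy from patient donors with accuracy > 0.9."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        config = cs.GenerationConfig(seed=5)
        rows, ys = [], []
        for i in range(30):
            for status in ("healthy", "patient"):
                donor = cs.generate_donor(
                    status, child_rng(5, "sep", status, i), config, donor_id=f"{status}{i}"
                )
                law = build_blood_law(donor, child_rng(5, "sep-law", status, i))
                fr = expected_fractions(law)
                rows.append([fr[k] for k in sorted(fr)])
                ys.append(status)
        acc = cross_val_score(
            LogisticRegression(max_iter=2000), np.array(rows), np.array(ys), cv=5
        ).mean()
        assert acc > 0.9


class TestBloodSamples:
    def test_gated_fractions_within_binomial_error_at_zero_noise(self):
        config = cs.GenerationConfig(noise_sd=0.0, n_events_per_sample=2000)
        donor = cs.generate_donor("patient", 1, config)
        mat, truth = cs.generate_blood_sample(donor, 2000, 3, config)
        vec = cs.apply_gating(mat, cs.GatingStrategy())
        for key in ("pct_CD3", "pct_CD8", "pct_CD8_CD45RA+CCR7-"):
            p = truth.fractions[key]
            se = 100.0 * np.sqrt(p * (1 - p) / 2000)
            assert abs(vec[key] - 100.0 * p) < 4 * se + 1e-9

    def test_degenerate_mixture_routes_every_event_to_one_subpopulation(self):
        comp = CompartmentLaw(
            mem=(1.0, 0.0, 0.0, 0.0), exh=(0.0, 0.0, 0.0, 1.0),
            p_cd25=0.0, p_cd137=0.0, p_cd95=0.0,
        )
        law = PhenotypeLaw(
            p_viable=1.0, p_cd3=1.0, p_cd8=1.0, p_car=0.0, cd4=comp, cd8=comp
        )
        data, _ = sample_events(law, 100, np.random.default_rng(0), noise_sd=0.0)
        vec = cs.apply_gating(
            cs.SingleCellMatrix(sample_id="t", data=data), cs.GatingStrategy()
        )
        assert vec["pct_CD3"] == 100.0
        assert vec["pct_CD8"] == 100.0
        assert vec["pct_CD8_CD45RA+CCR7+"] == 100.0
        assert vec["pct_CD8_PD1-TIM3-"] == 100.0
        assert vec["pct_CD8_PD1+TIM3+"] == 0.0

    def test_same_seed_same_matrix(self):
        donor = cs.generate_donor("healthy", 2)
        a, _ = cs.generate_blood_sample(donor, 150, 9)
        b, _ = cs.generate_blood_sample(donor, 150, 9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="n_events"):
            cs.generate_blood_sample(cs.generate_donor("healthy", 2), 50, 1)


class TestDoseLaws:
    def test_healthy_high_fraction_declines_linearly(self):
        donor = _donor("healthy")
        doses = [0.05, 0.1, 0.15, 0.2, 0.3]
        h = [true_class_fractions(donor, d)["high"] for d in doses]
        # second divided differences vanish for an exactly linear law
        for i in range(len(doses) - 2):
            d0, d1, d2 = doses[i : i + 3]
            first = (h[i + 1] - h[i]) / (d1 - d0)
            second = (h[i + 2] - h[i + 1]) / (d2 - d1)
            assert abs(second - first) < 1e-12

    def test_patient_decline_accelerates_past_threshold(self):
        donor = _donor("patient", threshold=0.1)
        f = lambda d: true_class_fractions(donor, d)["high"]
        assert f(0.1) - f(0.2) > f(0.02) - f(0.1)

    def test_class_fractions_sum_to_one_and_stay_in_range(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            donor = cs.generate_donor(rng.choice(["healthy", "patient"]), rng)
            fr = true_class_fractions(donor, rng.uniform(0.02, 0.3))
            assert abs(sum(fr.values()) - 1.0) < 1e-9
            assert all(0.0 <= v <= 1.0 for v in fr.values())

    def test_exhaustion_activation_and_cd4_cd8_shift_with_dose(self):
        """Expected PD1+TIM3+, CD25+, CD137+ fractions rise and the CD4:CD8
        ratio rises from 0.1 to 0.3 mol%, across 200 seeded donors."""
        for i in range(200):
            status = "healthy" if i % 2 else "patient"
            donor = cs.generate_donor(status, child_rng(0, "mono", i))
            rng_a, rng_b = child_rng(1, "a", i), child_rng(1, "b", i)
            lo = expected_fractions(
                build_product_law(donor, 0.1, rng_a, noise_sd=0.0).marginal
            )
            hi = expected_fractions(
                build_product_law(donor, 0.3, rng_b, noise_sd=0.0).marginal
            )
            assert hi["pct_CD8_PD1+TIM3+"] > lo["pct_CD8_PD1+TIM3+"]
            assert hi["pct_CD8_CD25+"] > lo["pct_CD8_CD25+"]
            assert hi["pct_CD8_CD137+"] > lo["pct_CD8_CD137+"]
            assert hi["ratio_CD4_CD8"] > lo["ratio_CD4_CD8"]

    def test_patient_naive_fraction_collapses_past_threshold(self):
        donor = _donor("patient", threshold=0.1)
        rng = np.random.default_rng(0)
        naive = [
            expected_fractions(build_product_law(donor, d, rng, 0.0).marginal)[
                "pct_CD8_CD45RA+CCR7+"
            ]
            for d in (0.05, 0.1, 0.2, 0.3)
        ]
        assert naive[2] < naive[1] and naive[3] < naive[2]

    def test_out_of_range_dose_rejected(self):
        donor = _donor()
        dose = cs.StimulationDose("APC-ms", 50.0, mol_pct_biotin=0.5)
        with pytest.raises(ValueError, match="range"):
            cs.generate_product(donor, dose, 150, 0)


class TestCytotoxReadings:
    def _truth(self, pct):
        return cs.GroundTruth(
            sample_id="t",
            fractions={},
            class_fractions={"high": 0.3, "moderate": 0.4, "low": 0.3},
            cytotoxicity={0.0: 0.0, 1.25: pct, 100.0: 100.0},
        )

    def test_noiseless_roundtrip_recovers_truth(self):
        readings = cs.generate_cytotox_readings(
            self._truth(37.0), [0.0, 1.25], 0, noise_sd=0.0
        )
        curve = cs.build_curve(readings)
        assert curve.at(1.25) == pytest.approx(37.0, abs=1e-9)

    def test_control_identities_at_zero_noise(self):
        readings = cs.generate_cytotox_readings(
            self._truth(37.0), [0.0, 100.0], 0, noise_sd=0.0
        ).set_index("et_ratio")
        assert readings.loc[0.0, "lum_sample"] == pytest.approx(
            readings.loc[0.0, "lum_target_only"]
        )
        assert readings.loc[100.0, "lum_sample"] == pytest.approx(
            readings.loc[100.0, "lum_max_lysis"]
        )

    def test_missing_control_ratio_rejected(self):
        with pytest.raises(ValueError, match="0:1"):
            cs.generate_cytotox_readings(self._truth(10.0), [1.25], 0)


class TestCohort:
    def test_dropout_and_extra_conditions_hit_printed_patient_count(self):
        """8 patient donors x 6 APC-ms doses plus one extra Dynabead 1:1
        condition emit exactly 49 patient products."""
        config = cs.GenerationConfig(
            n_healthy=0,
            n_patient=8,
            n_events_per_sample=100,
            seed=1,
            extra_dynabead={"P01": (1.0,)},
        )
        cohort = cs.generate_cohort(config)
        products = cohort.manifest[cohort.manifest.stage == "product"]
        assert len(products) == 49
        assert (cohort.manifest.status == "patient").all()

    def test_ground_truth_class_fractions_sum_to_one(self, small_cohort):
        for gt in small_cohort.ground_truth.values():
            if gt.class_fractions is not None:
                assert sum(gt.class_fractions.values()) == pytest.approx(1.0)
            for key, val in gt.fractions.items():
                if key.startswith("pct_"):
                    assert 0.0 <= val <= 1.0

    def test_serialized_cohort_is_byte_identical_across_runs(self, tmp_path):
        config = cs.GenerationConfig(
            n_healthy=1, n_patient=1, n_events_per_sample=100, seed=3
        )
        dirs = []
        for name in ("a", "b"):
            out = tmp_path / name
            cs.generate_cohort(config).to_dir(out)
            dirs.append(out)
        files_a = sorted(p.name for p in dirs[0].iterdir())
        assert files_a == sorted(p.name for p in dirs[1].iterdir())
        for name in files_a:
            assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()

    def test_adding_a_donor_leaves_existing_samples_unchanged(self):
        base = cs.generate_cohort(
            cs.GenerationConfig(n_healthy=1, n_patient=1, n_events_per_sample=100, seed=4)
        )
        bigger = cs.generate_cohort(
            cs.GenerationConfig(n_healthy=2, n_patient=1, n_events_per_sample=100, seed=4)
        )
        for sid, mat in base.samples.items():
            pd.testing.assert_frame_equal(mat.data, bigger.samples[sid].data)

    def test_manifest_roundtrip_through_disk(self, tmp_path, small_cohort):
        small_cohort.to_dir(tmp_path / "c")
        samples, meta = cs.Cohort.load_events_dir(tmp_path / "c")
        assert len(samples) == len(small_cohort.samples)
        manifest = json.loads((tmp_path / "c" / "cohort_manifest.json").read_text())
        assert manifest["seed"] == small_cohort.config.seed
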