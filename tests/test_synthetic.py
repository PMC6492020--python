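import numpy as np
import pandas as pd
import pytest

from xylemct import synthetic
from xylemct.errors import PackingError, ValidationError
from xylemct.synthetic import (DiameterDistribution, OrganSimConfig, XylemRegion,
                               generate_cross_section, generate_final_scan,
                               generate_plc_observations, organ_preset)
from xylemct.vulnerability import fit_weibull, threshold_psi


class TestDiameterDistribution:
    def test_calibration_hits_targets(self):
        dist = DiameterDistribution.from_targets(18.36, 23.72, 6.0, 38.0)
        assert dist.mean_um == pytest.approx(18.36, abs=1e-6)
        assert dist.hydraulic_mean_um == pytest.approx(23.72, abs=1e-6)

    def test_samples_respect_truncation(self, rng):
        dist = DiameterDistribution.from_targets(16.0, 22.0, 10.0, 40.0)
        d = dist.sample(rng, 5000)
        assert d.min() >= 10.0 and d.max() <= 40.0
        assert np.mean(d) == pytest.approx(16.0, rel=0.05)

    def test_invalid_bounds(self):
        with pytest.raises(ValidationError):
            DiameterDistribution(mu=2.0, sigma=0.3, min_um=20.0, max_um=10.0)
        with pytest.raises(ValidationError):
            DiameterDistribution(mu=2.0, sigma=-1.0, min_um=5.0, max_um=10.0)


class TestConfigValidation:
    def test_air_must_be_darker_than_water(self, small_config):
        import dataclasses
        with pytest.raises(ValidationError, match="darker"):
            dataclasses.replace(small_config, gray_levels=(0.45, 0.10, 0.75))

    def test_overdense_config_rejected(self, small_config):
        import dataclasses
        with pytest.raises(ValidationError, match="packing"):
            dataclasses.replace(small_config, vessel_density_per_mm2=4000.0)

    def test_region_must_fit_image(self, small_config):
        import dataclasses
        with pytest.raises(ValidationError, match="fit"):
            dataclasses.replace(
                small_config, xylem_region=XylemRegion(outer_radius_um=5000.0))


class TestGenerateCrossSection:
    def test_no_tension_no_embolism(self, small_config):
        _, truth = generate_cross_section(small_config, 0.0)
        assert all(c.state == "water" for c in truth.conduits)

    def test_extreme_tension_all_embolised_and_equals_final(self, small_config):
        image, truth = generate_cross_section(small_config, -1e6)
        assert all(c.state == "air" for c in truth.conduits)
        final = generate_final_scan(truth, small_config)
        np.testing.assert_array_equal(image, final)

    def test_positive_psi_rejected(self, small_config):
        with pytest.raises(ValidationError):
            generate_cross_section(small_config, 0.5)

    def test_determinism_bit_exact(self, small_config):
        img1, t1 = generate_cross_section(small_config, -2.0)
        img2, t2 = generate_cross_section(small_config, -2.0)
        np.testing.assert_array_equal(img1, img2)
        pd.testing.assert_frame_equal(t1.to_frame(), t2.to_frame())

    def test_geometry_independent_of_psi(self, small_config):
        _, t1 = generate_cross_section(small_config, -1.0)
        _, t2 = generate_cross_section(small_config, -4.0)
        f1, f2 = t1.to_frame(), t2.to_frame()
        pd.testing.assert_frame_equal(f1.drop(columns="state"),
                                      f2.drop(columns="state"))

    def test_embolism_monotone_in_psi(self, small_config):
        _, mild = generate_cross_section(small_config, -1.5)
        _, severe = generate_cross_section(small_config, -3.5)
        air_mild = {c.id for c in mild.conduits if c.state == "air"}
        air_severe = {c.id for c in severe.conduits if c.state == "air"}
        assert air_mild <= air_severe

    def test_conduits_do_not_overlap(self, small_config):
        _, truth = generate_cross_section(small_config, -2.0)
        centres = np.array([c.centre_um for c in truth.conduits])
        radii = np.array([c.diameter_um / 2 for c in truth.conduits])
        dist = np.hypot(*(centres[:, None, :] - centres[None, :, :]).T)
        need = radii[:, None] + radii[None, :]
        off_diag = ~np.eye(len(radii), dtype=bool)
        assert np.all(dist.T[off_diag] >= need[off_diag])

    def test_embolised_fraction_matches_weibull_cdf(self, small_config):
        import dataclasses
        psi = -2.0
        b, c = small_config.weibull_scale_mpa, small_config.weibull_shape
        p_true = 1.0 - np.exp(-((abs(psi) / b) ** c))
        n_air = n_tot = 0
        for seed in range(40):
            cfg = dataclasses.replace(small_config, seed=seed)
            _, truth = generate_cross_section(cfg, psi)
            n_air += sum(c_.state == "air" for c_ in truth.conduits)
            n_tot += len(truth)
        se = np.sqrt(p_true * (1 - p_true) / n_tot)
        assert abs(n_air / n_tot - p_true) <= 3 * se

    def test_vessel_density_recovery(self):
        # published beech stem density 314.4 per mm2: realised within 10%
        vds = []
        for seed in range(20):
            cfg = organ_preset("beech_stem", image_size_px=(400, 400), seed=seed)
            _, truth = generate_cross_section(cfg, -2.0)
            vds.append(len(truth) / truth.xylem_area_mm2)
        assert np.mean(vds) == pytest.approx(314.4, rel=0.10)

    def test_anatomy_converges_with_area(self):
        cfg = organ_preset("beech_stem", image_size_px=(700, 700), seed=2)
        _, truth = generate_cross_section(cfg, -2.0)
        d = truth.diameters_um()
        assert np.mean(d) == pytest.approx(18.36, rel=0.05)
        assert np.sum(d**5) / np.sum(d**4) == pytest.approx(23.72, rel=0.05)

    def test_packing_failure_is_explicit(self, small_config, monkeypatch):
        monkeypatch.setattr(synthetic, "_MAX_ATTEMPTS_PER_CONDUIT", 1)
        with pytest.raises(PackingError, match="placed"):
            generate_cross_section(small_config, -2.0)


class TestGenerateFinalScan:
    def test_all_air(self, section_pair, small_config):
        _, truth, final = section_pair
        bg, water, air = small_config.gray_levels
        assert not np.any(final == water)

    def test_zero_conduit_truth(self, small_config):
        truth = synthetic.GroundTruth([], 0.1, -1.0)
        img = generate_final_scan(truth, small_config)
        assert np.all(img == small_config.gray_levels[0])

    def test_byte_identical_across_runs(self, section_pair, small_config):
        _, truth, final = section_pair
        np.testing.assert_array_equal(final, generate_final_scan(truth, small_config))


class TestGeneratePlcObservations:
    def test_psi50_point_is_50(self):
        b, c = 2.0, 3.0
        psi50 = -b * np.log(2.0) ** (1.0 / c)
        df = generate_plc_observations(b, c, 10, (psi50, psi50 - 1e-12), 0.0, seed=0)
        assert df["plc_pct"].iloc[0] == pytest.approx(50.0, abs=1e-9)

    def test_noiseless_roundtrip(self):
        df = generate_plc_observations(3.0, 4.0, 30, (-6.0, 0.0), 0.0, seed=1)
        fit = fit_weibull(df["psi_mpa"], df["plc_pct"])
        assert fit.converged
        assert fit.scale_mpa == pytest.approx(3.0, rel=1e-6)
        assert fit.shape == pytest.approx(4.0, rel=1e-6)

    def test_seed_reproducibility(self):
        a = generate_plc_observations(3.0, 4.0, 12, (-5.0, 0.0), 5.0, seed=9)
        b = generate_plc_observations(3.0, 4.0, 12, (-5.0, 0.0), 5.0, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_plc_clamped(self):
        df = generate_plc_observations(1.0, 1.0, 50, (-8.0, 0.0), 50.0, seed=3)
        assert df["plc_pct"].between(0.0, 100.0).all()

    @pytest.mark.parametrize(
        "kwargs",
        [dict(scale_mpa=-1.0), dict(shape=0.0), dict(n=3),
         dict(psi_range=(-12.0, 0.0)), dict(psi_range=(-3.0, 1.0)),
         dict(noise_sd_plc=-1.0)],
    )
    def test_invalid_inputs(self, kwargs):
        base = dict(scale_mpa=3.0, shape=4.0, n=10, psi_range=(-5.0, 0.0),
                    noise_sd_plc=0.0, seed=0)
        base.update(kwargs)
        with pytest.raises(ValidationError):
            generate_plc_observations(**base)

    def test_monte_carlo_recovery_of_published_stem_curve(self):
        # scaled-down version of the 100-seed recovery exercised in
        # tests/test_acceptance.py; generating thresholds psi50 = -2.51,
        # psi88 = -4.69
        from xylemct.vulnerability import solve_weibull_parameters
        gen = solve_weibull_parameters(-2.51, 50.0, -4.69, 88.0)
        p50s = []
        for seed in range(30):
            df = generate_plc_observations(gen.scale_mpa, gen.shape, 15,
                                           (-5.0, 0.0), 5.0, seed=seed)
            fit = fit_weibull(df["psi_mpa"], df["plc_pct"])
            assert fit.converged
            p50s.append(threshold_psi(fit, 50.0))
        assert np.mean(p50s) == pytest.approx(-2.51, abs=0.15)


def test_presets_all_buildable():
    for name in synthetic.ORGAN_PRESETS:
        cfg = organ_preset(name, image_size_px=(400, 400))
        assert isinstance(cfg, OrganSimConfig)
    with pytest.raises(ValidationError):
        organ_preset("nonexistent_organ")
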