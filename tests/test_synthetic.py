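"""Synthetic-data generators: determinism, round trips, truncation."""

import numpy as np
import pytest

from biosorb import study
from biosorb.calibration import fit_calibration
from biosorb.errors import ConfigError
from biosorb.isotherms import fit_linear_origin
from biosorb.kinetics import fit_first_order, fit_second_order
from biosorb.synthetic import (
    GeneratorConfig,
    generate_calibration,
    generate_isotherm,
    generate_ph_screen,
    generate_time_course,
    stream,
)


class TestDeterminism:
    def test_equal_configs_give_identical_output(self):
        cfg = GeneratorConfig(seed=5, design="time_course", noise_sd=1.0)
        a = generate_time_course(cfg)
        b = generate_time_course(cfg)
        np.testing.assert_array_equal(a.values, b.values)
        cal = GeneratorConfig(seed=5, design="calibration")
        assert generate_calibration(cal).equals(generate_calibration(cal))

    def test_streams_are_independent_per_design(self):
        """Generating one design never perturbs another (named streams)."""
        cfg_tc = GeneratorConfig(seed=5, design="time_course", noise_sd=1.0)
        first = generate_time_course(cfg_tc)
        generate_calibration(GeneratorConfig(seed=5, design="calibration"))
        generate_ph_screen(GeneratorConfig(seed=5, design="ph_screen"))
        again = generate_time_course(cfg_tc)
        np.testing.assert_array_equal(first.values, again.values)

    def test_replication_index_changes_draws(self):
        cfg = GeneratorConfig(seed=5, design="time_course", noise_sd=1.0)
        a = generate_time_course(cfg, index=0)
        b = generate_time_course(cfg, index=1)
        assert not np.array_equal(a.values, b.values)

    def test_stream_seeding_is_stable(self):
        a = stream(1, "time_course").integers(0, 1 << 30, 4)
        b = stream(1, "time_course").integers(0, 1 << 30, 4)
        np.testing.assert_array_equal(a, b)


class TestNoiselessRoundTrips:
    """Noiseless generation followed by the matching fit recovers the
    generating parameters to <= 1e-8 relative error."""

    def test_calibration(self):
        cfg = GeneratorConfig(seed=1, design="calibration", noise_sd=0.0)
        curve = fit_calibration(generate_calibration(cfg))
        assert curve.slope == pytest.approx(study.CALIBRATION_SLOPE, rel=1e-8)
        assert curve.intercept == pytest.approx(study.CALIBRATION_INTERCEPT, rel=1e-8)

    @pytest.mark.parametrize("value_kind", ["remaining", "adsorbed"])
    def test_first_order(self, value_kind):
        cfg = GeneratorConfig(
            seed=1, design="time_course", noise_sd=0.0,
            params={"model": "first_order", "ci": 50.0, "rate_constant": 0.052,
                    "value_kind": value_kind},
        )
        fit = fit_first_order(generate_time_course(cfg))
        assert fit.rate_constant == pytest.approx(0.052, rel=1e-8)

    @pytest.mark.parametrize("value_kind", ["remaining", "adsorbed"])
    def test_second_order(self, value_kind):
        cfg = GeneratorConfig(
            seed=1, design="time_course", noise_sd=0.0,
            params={"model": "second_order", "ci": 50.0, "rate_constant": 0.0018,
                    "value_kind": value_kind},
        )
        fit = fit_second_order(generate_time_course(cfg))
        assert fit.rate_constant == pytest.approx(0.0018, rel=1e-8)

    def test_isotherm(self):
        cfg = GeneratorConfig(
            seed=1, design="isotherm", noise_sd=0.0, params={"slope": 10.22}
        )
        ds = generate_isotherm(cfg)
        # truth geometry: Ce = Ci/(1 + b_o), qe = b_o * Ce
        i100 = np.where(ds.initial_concentrations == 100.0)[0][0]
        assert ds.ce[i100] == pytest.approx(8.913, abs=5e-4)
        assert ds.qe[i100] == pytest.approx(91.087, abs=5e-4)
        assert fit_linear_origin(ds).slope == pytest.approx(10.22, rel=1e-10)

    def test_ph_screen(self):
        cfg = GeneratorConfig(seed=1, design="ph_screen", noise_sd=0.0)
        df = generate_ph_screen(cfg)
        peak = df.loc[df["removal_percent"].idxmax()]
        assert peak["ph"] == study.PH_OPTIMUM
        assert peak["removal_percent"] == pytest.approx(46.84, abs=1e-9)


class TestDesigns:
    def test_calibration_covers_the_standard_range(self):
        df = generate_calibration(GeneratorConfig(seed=2, design="calibration"))
        conc = set(df["concentration_mg_per_L"])
        assert {50.0, 800.0} <= conc

    def test_ph_peak_is_configurable(self):
        cfg = GeneratorConfig(
            seed=2, design="ph_screen", noise_sd=0.0,
            params={"peak_ph": 7.5, "ph_grid": tuple(np.arange(4.0, 10.5, 0.5))},
        )
        df = generate_ph_screen(cfg)
        assert df.loc[df["removal_percent"].idxmax(), "ph"] == 7.5

    def test_ph_peak_outside_grid_rejected(self):
        with pytest.raises(ConfigError):
            generate_ph_screen(
                GeneratorConfig(seed=2, design="ph_screen", params={"peak_ph": 2.0})
            )

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigError):
            generate_time_course(
                GeneratorConfig(seed=2, design="time_course", params={"model": "elovich"})
            )

    def test_unknown_design_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(seed=2, design="weber_morris")

    def test_replicate_mean_tracks_generating_curve(self):
        """At t = 96 h the replicate mean of q sits within 3*sd/sqrt(n) of
        the closed-form generator mean 0.91*50*(1 - e^{-0.052*96})."""
        cfg = GeneratorConfig(
            seed=8, design="time_course", noise_sd=1.0, n_replicates=3,
            params={"model": "first_order", "ci": 50.0, "rate_constant": 0.052,
                    "value_kind": "adsorbed"},
        )
        tc = generate_time_course(cfg)
        expected = 0.91 * 50.0 * (1.0 - np.exp(-0.052 * 96.0))
        observed = tc.adsorbed()[:, -1].mean()
        assert abs(observed - expected) < 3.0 * 1.0 / np.sqrt(3)

    def test_truncation_rare_at_default_noise(self):
        """Default designs floor noise at zero; at the default noise scales
        fewer than 1% of points are affected."""
        total = trunc = 0
        for i in range(50):
            cfg = GeneratorConfig(seed=13, design="time_course")  # defaults
            tc = generate_time_course(cfg, index=i)
            trunc += tc.n_truncated
            total += tc.values.size
        assert trunc / total < 0.01
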