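"""DMA yields, radiant exposure, Hill EC50 fitting, selectivity, bands."""
import numpy as np
import pytest

from photonet import bioassay
from photonet.bioassay import (
    C_MAX,
    DOSE_LADDER,
    classify_photocytotoxicity,
    dma_relative_yield,
    fit_hill,
    hill_curve,
    radiant_exposure,
    selectivity_index,
    type1_protection,
)
from photonet.exceptions import ComputationError, FitError, ParameterError
from photonet.types import DMAKinetics, DoseResponse, EC50Result


class TestRadiantExposure:
    @pytest.mark.parametrize(
        "irradiance,time,expected",
        [(1.24, 7.5, 9.3), (1.34, 15.0, 20.1), (1.24, 0.0, 0.0)],
    )
    def test_light_doses(self, irradiance, time, expected):
        assert round(radiant_exposure(irradiance, time), 1) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ParameterError):
            radiant_exposure(-1.0, 5.0)


def kinetics(k, extract="x", light="blue", condition="DMA", a0=1.0, rep="r1"):
    t = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
    return DMAKinetics(extract, light, condition, t, a0 * (1.0 - k * t), rep)


class TestDMAYield:
    def test_control_against_itself_is_100_percent(self):
        c = kinetics(0.004)
        assert dma_relative_yield(c, c).percent == pytest.approx(100.0)

    def test_flat_sample_yields_zero(self):
        s = kinetics(0.0)
        c = kinetics(0.004)
        assert dma_relative_yield(s, c).percent == pytest.approx(0.0, abs=1e-9)

    def test_half_rate_yields_50_percent(self):
        s = kinetics(0.002)
        c = kinetics(0.004)
        assert dma_relative_yield(s, c).percent == pytest.approx(50.0, abs=1e-9)

    def test_scale_invariance(self):
        s, c = kinetics(0.003), kinetics(0.004)
        y1 = dma_relative_yield(s, c).percent
        s2 = DMAKinetics("x", "blue", "DMA", s.times, 7.3 * s.a377)
        c2 = DMAKinetics("x", "blue", "DMA", c.times, 7.3 * c.a377)
        assert dma_relative_yield(s2, c2).percent == pytest.approx(y1, abs=1e-9)

    def test_inactive_control_raises(self):
        s = kinetics(0.002)
        flat = kinetics(0.0)
        with pytest.raises(ComputationError, match="inactive positive control"):
            dma_relative_yield(s, flat)

    def test_mixed_light_sources_rejected(self):
        with pytest.raises(ParameterError):
            dma_relative_yield(kinetics(0.002, light="blue"), kinetics(0.004, light="green"))

    def test_yields_can_exceed_100_percent(self):
        s = kinetics(0.008)
        c = kinetics(0.004)
        assert dma_relative_yield(s, c).percent == pytest.approx(200.0, abs=1e-9)

    def test_replicates_produce_standard_error(self):
        samples = [kinetics(0.0030, rep="r1"), kinetics(0.0034, rep="r2")]
        c = kinetics(0.004)
        result = dma_relative_yield(samples, c)
        assert result.n_replicates == 2
        assert result.se > 0.0
        assert result.percent == pytest.approx(80.0, abs=1e-6)


class TestProtection:
    def test_identical_kinetics_no_protection(self):
        w = kinetics(0.004)
        assert type1_protection(w, kinetics(0.004, condition="DMA+AA")) == pytest.approx(0.0)

    def test_full_quench_gives_one(self):
        w = kinetics(0.004)
        aa = kinetics(0.0, condition="DMA+AA")
        assert type1_protection(w, aa) == pytest.approx(1.0)

    def test_inactive_sample_gives_missing(self):
        w = kinetics(0.0)
        assert type1_protection(w, kinetics(0.0, condition="DMA+AA")) is None

    def test_planted_quench_recovered_from_bundle(self, bundle_dir, truth):
        from photonet import msio

        wells = msio.read_dma_kinetics(bundle_dir[0] / "dma_kinetics.csv")
        idx = {(w.extract_id, w.light, w.condition, w.replicate): w for w in wells}
        w = idx[("xanthophyllus", "blue", "DMA", "r1")]
        aa = idx[("xanthophyllus", "blue", "DMA+AA", "r1")]
        assert type1_protection(w, aa) == pytest.approx(truth.dma_protection, abs=0.05)


def ladder_response(ec50, hill=1.0, top=100.0, bottom=0.0, reps=1, noise_sd=0.0, rng=None):
    conc = np.tile(np.array(DOSE_LADDER), reps)
    v = hill_curve(conc, top, bottom, ec50, hill)
    if noise_sd and rng is not None:
        v = v + rng.normal(0.0, noise_sd, conc.size)
    return DoseResponse("A549", "x", "blue", conc, v)


class TestHillFit:
    def test_noise_free_exact_recovery(self):
        r = fit_hill(ladder_response(10.0))
        assert not r.censored
        assert r.ec50 == pytest.approx(10.0, abs=1e-6)
        assert r.hill_slope == pytest.approx(1.0, abs=1e-6)
        assert r.ci95[0] <= r.ec50 <= r.ci95[1]

    def test_high_viability_everywhere_censored(self, rng):
        conc = np.array(DOSE_LADDER)
        v = 90.0 + rng.normal(0.0, 2.0, conc.size)
        r = fit_hill(DoseResponse("A549", "x", "dark", conc, v))
        assert r.censored
        assert r.ec50 == C_MAX

    def test_too_few_distinct_doses_rejected(self):
        conc = np.array([1.0, 1.0, 10.0, 20.0])
        v = hill_curve(conc, 100, 0, 5.0, 1.0)
        with pytest.raises(FitError):
            fit_hill(DoseResponse("A549", "x", "blue", conc, v))

    def test_simulation_bias_and_coverage(self, rng):
        """At the standard dose ladder with 5% noise, the estimator is
        unbiased (median relative bias within ±5%) and the 95% CI covers the
        truth at a nominal rate."""
        n, cover, biases = 150, 0, []
        for _ in range(n):
            dr = ladder_response(5.0, noise_sd=5.0, rng=rng)
            r = fit_hill(dr)
            biases.append((r.ec50 - 5.0) / 5.0)
            cover += r.ci95[0] <= 5.0 <= r.ci95[1]
        assert abs(float(np.median(biases))) <= 0.05
        assert 0.88 <= cover / n <= 0.995

    def test_replicate_fits_aggregate(self, rng):
        dr = ladder_response(5.0, reps=3, noise_sd=3.0, rng=rng)
        dr.replicates = ["r1"] * 6 + ["r2"] * 6 + ["r3"] * 6
        fits, mean, se = bioassay.fit_hill_by_replicate(dr)
        assert len(fits) == 3
        assert se > 0.0
        assert mean == pytest.approx(5.0, rel=0.5)


class TestSelectivityIndex:
    def censored(self):
        return EC50Result(C_MAX, (C_MAX, float("inf")), 1.0, True, C_MAX)

    def fitted(self, ec50):
        return EC50Result(ec50, (0.5 * ec50, 2.0 * ec50), 1.0, False, C_MAX)

    @pytest.mark.parametrize(
        "irr,expected", [(0.8, 46.9), (1.6, 23.4), (2.1, 17.9)]
    )
    def test_lower_bound_worked_examples(self, irr, expected):
        """Dark censored at the 37.5 µg/mL top dose reproduces the published
        green-light selectivity bounds."""
        si = selectivity_index(self.censored(), self.fitted(irr))
        assert round(si.value, 1) == expected
        assert si.lower_bound

    def test_identical_results_give_unity(self):
        x = self.fitted(7.0)
        si = selectivity_index(x, x)
        assert si.value == 1.0 and not si.lower_bound

    def test_monotone_decreasing_in_irradiated_ec50(self):
        dark = self.fitted(30.0)
        values = [selectivity_index(dark, self.fitted(e)).value for e in (1.0, 2.0, 4.0)]
        assert values == sorted(values, reverse=True)

    def test_nonpositive_irradiated_rejected(self):
        with pytest.raises(ParameterError):
            selectivity_index(self.censored(), self.fitted(0.0))

    def test_presentation_rounds_to_one_decimal(self):
        si = selectivity_index(self.censored(), self.fitted(0.8))
        assert str(si) == "≥46.9"


class TestActivityBands:
    @pytest.mark.parametrize(
        "ec50,band",
        [
            (3.7, "very high"),
            (11.1, "high"),
            (25.0, "no/low"),
            (5.0, "high"),
            (20.0, "high"),
            (20.001, "no/low"),
        ],
    )
    def test_band_boundaries(self, ec50, band):
        assert classify_photocytotoxicity(ec50) == band

    def test_nonpositive_ec50_rejected(self):
        with pytest.raises(ParameterError):
            classify_photocytotoxicity(0.0)
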