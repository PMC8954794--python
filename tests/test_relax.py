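"""Exponential rate fitting, hetNOE, flexibility flags and tumbling time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssbnmr import simulate as sim
from ssbnmr.relax import (NU_N_600MHZ, R1_DELAYS_S, R2_DELAYS_S, DecaySeries,
                          compute_hetnoe, estimate_tau_c, fit_exponential,
                          profile_tau_c, summarize_profile)

from _oracles import grid_search_rate


def make_series(rate, delays=R1_DELAYS_S, i0=100.0, rid=1):
    t = np.asarray(delays)
    return DecaySeries(residue_id=rid, delays=t, heights=i0 * np.exp(-rate * t))


class TestFitExponential:
    def test_exact_on_noiseless_decay(self):
        fit = fit_exponential(make_series(2.0), n_resamples=0)
        assert fit.converged
        assert fit.rate == pytest.approx(2.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-6)

    def test_matches_grid_search_oracle(self):
        series = make_series(6.862, delays=R2_DELAYS_S)
        fit = fit_exponential(series, n_resamples=0)
        oracle = grid_search_rate(series.delays, series.heights)
        # same minimizer within the grid resolution (~5e-3 Hz)
        assert abs(fit.rate - oracle) < 50.0 / 10_000 * 2

    @given(rate=st.floats(0.5, 30.0), i0=st.floats(10.0, 1000.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_noiseless_roundtrip_any_rate(self, rate, i0):
        fit = fit_exponential(make_series(rate, i0=i0), n_resamples=0)
        assert fit.converged
        assert fit.rate == pytest.approx(rate, rel=1e-5)

    def test_constant_series_pins_rate_at_clip_with_warning(self):
        t = np.asarray(R1_DELAYS_S)
        series = DecaySeries(residue_id=1, delays=t, heights=np.full_like(t, 50.0))
        with pytest.warns(UserWarning, match="all heights equal"):
            fit = fit_exponential(series)
        assert fit.converged
        assert fit.rate == pytest.approx(1e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            DecaySeries(residue_id=1, delays=[0.1, 0.1, 0.2], heights=[3, 2, 1])
        with pytest.raises(ValueError, match="at least 3"):
            DecaySeries(residue_id=1, delays=[0.1, 0.5], heights=[81.87, 36.79])

    def test_recovery_at_one_percent_noise(self, truth, cfg):
        """Rates near the study averages recover within 2% at 1% noise."""
        series = sim.make_decay_series(truth, R1_DELAYS_S, cfg, which="r1")
        errs = []
        for s, r_true in zip(series, truth.r1):
            fit = fit_exponential(s, n_resamples=0)
            assert fit.converged
            errs.append(abs(fit.rate - r_true) / r_true)
        assert np.median(errs) < 0.02

    def test_monte_carlo_rate_error_is_sensible(self, truth, cfg):
        series = sim.make_decay_series(truth, R1_DELAYS_S, cfg, which="r1")[0]
        fit = fit_exponential(series)  # default 200 resamples
        assert 0 < fit.rate_error < 0.2 * fit.rate


class TestHetnoe:
    def test_direct_ratio(self):
        out = compute_hetnoe({1: 78.0}, {1: 100.0})
        assert out.loc[0, "hetnoe"] == pytest.approx(0.78)

    def test_identical_spectra_give_unity(self):
        heights = {i: 100.0 + i for i in range(1, 21)}
        out = compute_hetnoe(heights, heights)
        assert np.allclose(out["hetnoe"], 1.0)

    def test_zero_unsaturated_marks_invalid(self):
        out = compute_hetnoe({1: 50.0, 2: 50.0}, {1: 0.0, 2: 100.0})
        assert not out.loc[0, "valid"]
        assert np.isnan(out.loc[0, "hetnoe"])
        assert out.loc[1, "valid"]

    def test_error_propagation_in_quadrature(self):
        out = compute_hetnoe({1: 80.0}, {1: 100.0}, {1: 4.0}, {1: 3.0})
        expected = 0.8 * np.sqrt((4 / 80) ** 2 + (3 / 100) ** 2)
        assert out.loc[0, "hetnoe_err"] == pytest.approx(expected)

    def test_mean_recovery_uniform_truth(self):
        """Pairs generated at hetNOE=0.766 with 1% noise average back to 0.766."""
        cfg = sim.SimulationConfig(noise_sd=0.01)
        truth = sim.default_ground_truth(cfg)
        truth.hetnoe = np.full_like(truth.hetnoe, 0.766)
        pairs = sim.make_hetnoe_pairs(truth, cfg)
        out = compute_hetnoe(pairs.set_index("residue_id")["sat_height"],
                             pairs.set_index("residue_id")["unsat_height"])
        assert out["hetnoe"].mean() == pytest.approx(0.766, rel=0.01)


class TestSummarizeProfile:
    @staticmethod
    def profile_from(truth, cfg):
        r1 = [fit_exponential(s, n_resamples=0)
              for s in sim.make_decay_series(truth, R1_DELAYS_S, cfg, "r1")]
        r2 = [fit_exponential(s, n_resamples=0)
              for s in sim.make_decay_series(truth, R2_DELAYS_S, cfg, "r2")]
        pairs = sim.make_hetnoe_pairs(truth, cfg)
        noe = compute_hetnoe(pairs.set_index("residue_id")["sat_height"],
                             pairs.set_index("residue_id")["unsat_height"])
        return summarize_profile(r1, r2, noe)

    def test_uniform_profile_has_no_flags(self, quiet_cfg):
        truth = sim.default_ground_truth(quiet_cfg)
        truth.r1[:] = 1.9
        truth.r2[:] = 6.8
        truth.hetnoe[:] = 0.8
        prof = self.profile_from(truth, quiet_cfg)
        assert prof.flagged_residues == set()
        assert prof.stats["r1_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_constructed_outlier_is_the_only_flag(self, quiet_cfg):
        truth = sim.default_ground_truth(quiet_cfg)
        # tight deterministic jitter plus one deep outlier
        truth.r1 = 1.9 + 0.01 * np.sin(truth.residue_ids.astype(float))
        truth.r2[:] = 6.8
        truth.hetnoe[:] = 0.8
        truth.r1[9] = 1.8
        prof = self.profile_from(truth, quiet_cfg)
        assert prof.flagged_residues == {int(truth.residue_ids[9])}
        assert bool(prof.table.loc[9, "low_r1"])

    def test_recovers_planted_flexible_residues(self, truth, cfg):
        """At 1% noise the 2-SD / 0.6 rules flag exactly the planted set."""
        prof = self.profile_from(truth, cfg)
        assert prof.flagged_residues == truth.flexible_residues

    def test_overlapped_residues_excluded_from_statistics(self, quiet_cfg):
        truth = sim.default_ground_truth(quiet_cfg)
        truth.r1[:] = 1.9
        truth.r2[:] = 6.8
        truth.hetnoe[:] = 0.8
        truth.r1[0] = 10.0  # would dominate the SD if included
        r1 = [fit_exponential(s, n_resamples=0)
              for s in sim.make_decay_series(truth, R1_DELAYS_S, quiet_cfg, "r1")]
        r2 = [fit_exponential(s, n_resamples=0)
              for s in sim.make_decay_series(truth, R2_DELAYS_S, quiet_cfg, "r2")]
        pairs = sim.make_hetnoe_pairs(truth, quiet_cfg)
        noe = compute_hetnoe(pairs.set_index("residue_id")["sat_height"],
                             pairs.set_index("residue_id")["unsat_height"])
        prof = summarize_profile(r1, r2, noe, overlapped={1})
        assert prof.stats["r1_mean"] == pytest.approx(1.9, abs=1e-6)
        assert not prof.table.loc[0, "usable"]

    def test_refuses_tiny_profiles(self):
        fits = [fit_exponential(make_series(2.0, rid=i), n_resamples=0)
                for i in range(1, 4)]
        noe = compute_hetnoe({i: 80.0 for i in range(1, 4)},
                             {i: 100.0 for i in range(1, 4)})
        with pytest.raises(ValueError, match="usable residues"):
            summarize_profile(fits, fits, noe)


class TestTauC:
    def test_root_of_radicand_gives_zero(self):
        est = estimate_tau_c(6.0, 7.0)  # R2/R1 = 7/6 exactly
        assert est.defined
        assert est.tau_c == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("r1, r2, expected_ns", [
        (1.078, 17.66, 12.5036), (1.928, 6.862, 4.9581),
    ])
    def test_direct_evaluation_on_mean_rates(self, r1, r2, expected_ns):
        est = estimate_tau_c(r1, r2, NU_N_600MHZ)
        assert est.tau_c_ns == pytest.approx(expected_ns, abs=5e-4)

    def test_undefined_below_root_is_flagged_not_nan(self):
        est = estimate_tau_c(6.0, 6.9)
        assert not est.defined
        assert est.tau_c is None

    def test_monotone_in_r2_over_r1(self):
        ratios = np.linspace(1.2, 30.0, 50)
        taus = [estimate_tau_c(1.0, r).tau_c for r in ratios]
        assert np.all(np.diff(taus) > 0)

    def test_uniform_profile_both_methods_agree(self, quiet_cfg):
        truth = sim.default_ground_truth(quiet_cfg)
        truth.r1[:] = 1.9
        truth.r2[:] = 6.8
        truth.hetnoe[:] = 0.8
        prof = TestSummarizeProfile.profile_from(truth, quiet_cfg)
        per_res, from_means = profile_tau_c(prof)
        assert per_res.tau_c == pytest.approx(from_means.tau_c, rel=1e-9)

    def test_recovery_of_isotropic_tumbling(self):
        """Rigid rates consistent with tau_c = 5.0 ns recover it within 3%."""
        tau, nu = 5.0e-9, NU_N_600MHZ
        r1_true = 1.9
        r2_true = r1_true * ((4 * np.pi * nu * tau) ** 2 + 7) / 6
        cfg = sim.SimulationConfig(noise_sd=0.01)
        truth = sim.default_ground_truth(cfg)
        truth.r1[:] = r1_true
        truth.r2[:] = r2_true
        truth.hetnoe[:] = 0.8
        prof = TestSummarizeProfile.profile_from(truth, cfg)
        per_res, from_means = profile_tau_c(prof)
        assert per_res.tau_c_ns == pytest.approx(5.0, rel=0.03)
        assert from_means.tau_c_ns == pytest.approx(5.0, rel=0.03)

    def test_residue_below_root_is_excluded_and_counted(self, quiet_cfg):
        truth = sim.default_ground_truth(quiet_cfg)
        truth.r1[:] = 1.9
        truth.r2[:] = 6.8
        truth.hetnoe[:] = 0.8
        truth.r2[4] = truth.r1[4] * 1.1  # below the 7/6 root
        r1 = [fit_exponential(s, n_resamples=0)
              for s in sim.make_decay_series(truth, R1_DELAYS_S, quiet_cfg, "r1")]
        r2 = [fit_exponential(s, n_resamples=0)
              for s in sim.make_decay_series(truth, R2_DELAYS_S, quiet_cfg, "r2")]
        pairs = sim.make_hetnoe_pairs(truth, quiet_cfg)
        noe = compute_hetnoe(pairs.set_index("residue_id")["sat_height"],
                             pairs.set_index("residue_id")["unsat_height"])
        # wide outlier band so the low-R2 residue stays unflagged and the
        # radicand rule alone excludes it
        prof = summarize_profile(r1, r2, noe, sd_multiple=50.0)
        per_res, _ = profile_tau_c(prof)
        assert per_res.n_excluded == 1
        assert per_res.n_residues == truth.r1.size - 1
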