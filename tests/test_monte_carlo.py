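"""Ensemble determinism, point-mass degeneracy, convergence, sweeps."""

import copy

import numpy as np
import pandas as pd
import pytest

from nsafarm import (
    EnsembleError,
    ParameterDistribution,
    ParameterError,
    run_ensemble,
    sensitivity_sweep,
)
from nsafarm.monte_carlo import realize_farm


class TestDistributions:
    def test_point_mass_reproduces_value_exactly(self):
        dist = ParameterDistribution("d", "point", {"value": 12.5})
        rng = np.random.default_rng(0)
        assert all(dist.draw(rng) == 12.5 for _ in range(5))

    @pytest.mark.parametrize(
        "family,params",
        [
            ("uniform", {"low": -1.0, "high": 2.0}),
            ("point", {"value": -3.0}),
            ("truncnormal", {"mean": 5.0, "sd": -1.0}),
            ("nope", {"value": 1.0}),
        ],
    )
    def test_invalid_specifications_rejected(self, family, params):
        with pytest.raises(ParameterError):
            ParameterDistribution("x", family, params)

    def test_draws_respect_nonnegativity(self):
        rng = np.random.default_rng(3)
        dist = ParameterDistribution("x", "truncnormal", {"mean": 1.0, "sd": 5.0})
        draws = [dist.draw(rng) for _ in range(200)]
        assert min(draws) >= 0.0


class TestEnsemble:
    def test_point_masses_give_zero_sd_and_match_single_solve(
        self, uncalibrated_config
    ):
        """Degenerate distributions: every realization within a quality is
        the same farm, so per-quality SD vanishes and the mean equals the
        single deterministic solve."""
        summary = run_ensemble(uncalibrated_config, n_realizations=4, seed=7)
        means = {k: d.mean_value for k, d in uncalibrated_config.distributions.items()}
        for quality, per_q in summary.per_quality.items():
            # SD of identical members is pure mean-subtraction round-off,
            # so compare against the output's own scale
            scale = per_q["mean"].abs().clip(lower=1.0)
            assert (per_q["sd"] <= 1e-12 * scale).all()
            single = realize_farm(uncalibrated_config, quality, means)
            assert per_q.loc["yield_vegetal", "mean"] == pytest.approx(
                single["yield_vegetal"], rel=1e-12
            )
            assert per_q.loc["protein_kg", "mean"] == pytest.approx(
                single["protein_kg"], rel=1e-12
            )

    def test_same_seed_is_bitwise_identical(self, calibrated_config):
        a = run_ensemble(calibrated_config, n_realizations=10, seed=11)
        b = run_ensemble(calibrated_config, n_realizations=10, seed=11)
        pd.testing.assert_frame_equal(a.raw, b.raw, check_exact=True)

    def test_different_seeds_differ(self, calibrated_config):
        a = run_ensemble(calibrated_config, n_realizations=5, seed=1)
        b = run_ensemble(calibrated_config, n_realizations=5, seed=2)
        assert not a.raw["yield_vegetal"].equals(b.raw["yield_vegetal"])

    def test_uniform_deposition_mean_matches_central_solve(
        self, uncalibrated_config
    ):
        """Constant retention makes yields linear in deposition, so the
        ensemble mean must sit within 3 SE of the solve at the central
        deposition value."""
        cfg = copy.deepcopy(uncalibrated_config)
        cfg.distributions["deposition"] = ParameterDistribution(
            "deposition", "uniform", {"low": 5.0, "high": 15.0}
        )
        summary = run_ensemble(cfg, n_realizations=300, qualities=["medium"], seed=5)
        central = realize_farm(
            cfg, "medium", {k: d.mean_value for k, d in cfg.distributions.items()}
        )
        se = summary.sd("yield_vegetal") / np.sqrt(len(summary.raw))
        assert abs(summary.mean("yield_vegetal") - central["yield_vegetal"]) < 3 * se

    def test_mean_converges_at_root_n_rate(self, uncalibrated_config):
        """|ensemble mean - central solve| scales like 1/sqrt(n) in the
        all-linear configuration."""
        cfg = copy.deepcopy(uncalibrated_config)
        cfg.distributions["deposition"] = ParameterDistribution(
            "deposition", "uniform", {"low": 0.0, "high": 20.0}
        )
        central = realize_farm(
            cfg, "medium", {k: d.mean_value for k, d in cfg.distributions.items()}
        )["yield_vegetal"]
        for n in (250, 4000):
            s = run_ensemble(cfg, n_realizations=n, qualities=["medium"], seed=9)
            err = abs(s.mean("yield_vegetal") - central)
            bound = 4.0 * s.sd("yield_vegetal") / np.sqrt(n)
            assert err < bound, f"n={n}: err {err} vs bound {bound}"

    @staticmethod
    def _feedback_prone_config(base, low, high):
        """gamma = 0 routes all manure to the forage loop; with full manure
        recovery and high forage retention the loop gain crosses 1 for
        sufficiently dilute forage-N draws."""
        from dataclasses import replace

        from nsafarm import FarmGeometry, RetentionCurve

        cfg = copy.deepcopy(base)
        cfg.geometry = FarmGeometry(1.0, 3.0 / 7.0, gamma=0.0)
        cfg.physiology_params = replace(
            cfg.physiology_params, plant_available_fraction=1.0
        )
        cfg.retention_forage = RetentionCurve.constant(0.95)
        cfg.distributions["forage_n_scale"] = ParameterDistribution(
            "forage_n_scale", "uniform", {"low": low, "high": high}
        )
        return cfg

    def test_too_many_failures_abort_the_ensemble(self, uncalibrated_config):
        cfg = self._feedback_prone_config(uncalibrated_config, 0.05, 0.35)
        with pytest.raises(EnsembleError, match="divergent manure feedback"):
            run_ensemble(cfg, n_realizations=40, qualities=["medium"], seed=3)

    def test_sparse_failures_recorded_and_excluded(self, uncalibrated_config):
        """Below the 10% threshold, failed realizations are logged with
        their error and dropped from the summaries, not resampled."""
        cfg = self._feedback_prone_config(uncalibrated_config, 0.25, 0.45)
        summary = run_ensemble(cfg, n_realizations=200, qualities=["medium"], seed=3)
        assert 0 < summary.n_failures <= 0.10 * summary.population_size
        assert len(summary.raw) + summary.n_failures == summary.population_size
        assert all(
            "divergent manure feedback" in f["error"] for f in summary.failures
        )

    def test_unknown_distribution_name_rejected(self, uncalibrated_config):
        cfg = copy.deepcopy(uncalibrated_config)
        cfg.distributions["bogus"] = ParameterDistribution(
            "bogus", "point", {"value": 1.0}
        )
        with pytest.raises(ParameterError, match="bogus"):
            run_ensemble(cfg, n_realizations=1, seed=0)


class TestSensitivitySweep:
    def test_yield_penalty_monotonically_cuts_protein(self, calibrated_config):
        """A deeper yield penalty lowers the mass caps and hence protein,
        strictly, since the fixture's fruit item is always cap-bound."""
        sweeps = sensitivity_sweep(
            calibrated_config, "yield_penalty", [0.0, 0.15, 0.30],
            n_realizations=12, seed=2,
        )
        proteins = [s.mean("protein_kg") for s in sweeps.values()]
        assert proteins[0] > proteins[1] > proteins[2]

    def test_single_value_equals_plain_ensemble(self, calibrated_config):
        sweep = sensitivity_sweep(
            calibrated_config, "yield_penalty", [0.15], n_realizations=6, seed=4
        )
        plain = run_ensemble(calibrated_config, n_realizations=6, seed=4)
        pd.testing.assert_frame_equal(sweep[0.15].raw, plain.raw, check_exact=True)

    def test_distribution_parameter_path(self, calibrated_config):
        sweeps = sensitivity_sweep(
            calibrated_config, "distributions.fixation_forage.mean",
            [100.0, 300.0], n_realizations=8, seed=6,
        )
        assert (
            sweeps[100.0].mean("yield_forage") < sweeps[300.0].mean("yield_forage")
        )

    def test_empty_values_rejected(self, calibrated_config):
        with pytest.raises(ParameterError):
            sensitivity_sweep(calibrated_config, "yield_penalty", [])

    def test_unknown_parameter_rejected(self, calibrated_config):
        with pytest.raises(ParameterError, match="unknown"):
            sensitivity_sweep(calibrated_config, "no.such.knob", [1.0])
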