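"""Tests for the synthetic-data generators and their ground truth."""

import numpy as np
import pytest

from seedfate.escape import distance_trend_test, escape_curve
from seedfate.estimators import germination_rate, seed_fate_profile, visitation_rate
from seedfate.kernels import kernel_summary
from seedfate.model_core import recruitment_success
from seedfate.synthetic_data import (
    KernelTruth,
    default_truth,
    defecated_treatment,
    simulate_camera_traps,
    simulate_dispersal_distances,
    simulate_focal_observations,
    simulate_germination_trials,
    simulate_survival_experiment,
    truth_escape_curve,
    truth_kernel,
    truth_model,
    write_synthetic_tables,
)


@pytest.fixture(scope="module")
def truth():
    return default_truth()


class TestDefaultTruth:
    def test_profiles_sum_to_one(self, truth):
        for st in truth.sites.values():
            total = sum(st.fate.swallowed_by.values()) + st.fate.spat_out + st.fate.undispersed
            assert total == pytest.approx(1.0)

    def test_kernel_moments_match_field_targets(self, truth):
        for d, (mean, sd) in {
            "muriqui": (59.7, 35.7),
            "howler": (9.7, 3.4),
            "jacutinga": (10.5, 7.3),
        }.items():
            dist = truth.kernels[d].distribution()
            assert dist.mean() == pytest.approx(mean, abs=1e-9)
            assert dist.std() == pytest.approx(sd, abs=1e-9)

    def test_swallowed_totals_along_gradient(self, truth):
        assert truth.sites["intact"].fate.swallowed_total == pytest.approx(0.83)
        assert truth.sites["moderate"].fate.swallowed_total == pytest.approx(0.63)
        assert truth.sites["defaunated"].fate.swallowed_total == pytest.approx(0.41)

    def test_truth_kernel_is_proper_distribution(self, truth):
        k = truth_kernel(truth, "muriqui")
        assert sum(k.probs) == pytest.approx(1.0, abs=1e-12)
        # analytic class mass: most muriqui seeds land beyond 40 m
        mids = k.midpoints
        far = sum(p for m, p in zip(mids, k.probs) if m >= 40)
        assert far > 0.5

    def test_truth_models_are_valid_and_ordered(self, truth):
        rs = {s: recruitment_success(truth_model(truth, s)).rs_percent for s in truth.sites}
        # intact disperser community coincides with the most depleted
        # predator community: lowest RS despite the best dispersers
        assert rs["intact"] < rs["defaunated"] < rs["moderate"]

    def test_gamma_family_also_matches_moments(self):
        dist = KernelTruth("gamma", 20.0, 10.0).distribution()
        assert dist.mean() == pytest.approx(20.0)
        assert dist.std() == pytest.approx(10.0)


class TestFocalSimulation:
    def test_deterministic_under_seed(self, truth):
        a = simulate_focal_observations(truth, "intact", 500, rng_seed=3)
        b = simulate_focal_observations(truth, "intact", 500, rng_seed=3)
        assert a == b

    def test_fraction_recovery_within_3se(self, truth):
        n = 10_000
        records = simulate_focal_observations(truth, "intact", n, rng_seed=1)
        profile = seed_fate_profile(records, "intact")
        for d, p_true in truth.sites["intact"].fate.swallowed_by.items():
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(profile.swallowed_by[d] - p_true) <= 3 * se

    def test_sole_disperser_profile(self, truth):
        from dataclasses import replace
        from seedfate.estimators import SeedFateProfile
        from seedfate.synthetic_data import SiteTruth, SyntheticTruth

        solo = SyntheticTruth(
            sites={
                "x": SiteTruth(
                    fate=SeedFateProfile("x", {"A": 1.0}, 0.0, 0.0),
                    escape_baseline_5m=0.2,
                    escape_log_slope_per_m=0.0,
                )
            },
            germination={"defecated-by-A": 0.5, "with_pulp": 0.3, "without_pulp": 0.4},
            kernels={"A": KernelTruth("lognormal", 10.0, 5.0)},
        )
        records = simulate_focal_observations(solo, "x", 200, rng_seed=0)
        assert all(r.n_spat == 0 and r.n_dropped == 0 for r in records)
        assert seed_fate_profile(records, "x").swallowed_by == {"A": 1.0}

    def test_spreads_over_at_least_three_trees(self, truth):
        records = simulate_focal_observations(truth, "intact", 1000, rng_seed=2)
        assert len({r.tree_id for r in records}) >= 3


class TestGerminationSimulation:
    def test_certain_outcomes(self, truth):
        from seedfate.synthetic_data import SyntheticTruth

        t = SyntheticTruth(
            sites=truth.sites,
            germination={"with_pulp": 1.0, "without_pulp": 0.0},
            kernels=truth.kernels,
            block_sd_logit=0.0,
        )
        trials = simulate_germination_trials(t, rng_seed=0)
        assert all(
            tr.n_germinated == (5 if tr.treatment == "with_pulp" else 0) for tr in trials
        )

    def test_rate_recovery_with_many_blocks(self, truth):
        trials = simulate_germination_trials(truth, n_blocks=200, rng_seed=4)
        est = germination_rate(trials, defecated_treatment("muriqui"))
        n = 200 * 5
        se = np.sqrt(0.8 * 0.2 / n)
        # the logit-normal block effect slightly attenuates the marginal mean
        assert abs(est.rate - 0.8) <= 3 * se + 0.02

    def test_block_effect_shared_within_block(self, truth):
        a = simulate_germination_trials(truth, rng_seed=5)
        blocks = {t.block_id for t in a}
        assert len(blocks) == 10
        treatments_per_block = {
            b: sorted(t.treatment for t in a if t.block_id == b) for b in blocks
        }
        assert len({tuple(v) for v in treatments_per_block.values()}) == 1


class TestDistanceSimulation:
    def test_moment_recovery(self, truth):
        sample = simulate_dispersal_distances(truth, "muriqui", 50_000, rng_seed=6)
        mean, sd = kernel_summary(sample)
        assert abs(mean - 59.7) <= 3 * 35.7 / np.sqrt(50_000)

    def test_zero_sd_degenerates_to_mean(self, truth):
        from seedfate.synthetic_data import SyntheticTruth

        t = SyntheticTruth(
            sites=truth.sites,
            germination=truth.germination,
            kernels={"muriqui": KernelTruth("lognormal", 59.7, 0.0)},
        )
        sample = simulate_dispersal_distances(t, "muriqui", 20, rng_seed=0)
        assert set(sample.distances_m) == {59.7}

    def test_unknown_disperser_rejected(self, truth):
        with pytest.raises(KeyError):
            simulate_dispersal_distances(truth, "tapir", 10)

    def test_reproducible(self, truth):
        a = simulate_dispersal_distances(truth, "howler", 100, rng_seed=7)
        b = simulate_dispersal_distances(truth, "howler", 100, rng_seed=7)
        assert a == b


class TestSurvivalSimulation:
    def test_truth_curve_recovery_within_3se(self, truth):
        records = simulate_survival_experiment(
            truth, "moderate", n_per_distance=2000, rng_seed=8
        )
        curve = escape_curve(records, "moderate")
        true = truth_escape_curve(truth, "moderate")
        for t_hat, t_true in zip(curve.survival, true.survival):
            se = np.sqrt(t_true * (1 - t_true) / 4000)  # 2 years pooled
            # the log-normal tree effect inflates the mean slightly (Jensen)
            assert abs(t_hat - t_true) <= 3 * se + 0.03

    def test_zero_baseline_kills_everything(self, truth):
        from seedfate.synthetic_data import SiteTruth, SyntheticTruth

        st = truth.sites["moderate"]
        t = SyntheticTruth(
            sites={
                "moderate": SiteTruth(
                    fate=st.fate, escape_baseline_5m=0.0, escape_log_slope_per_m=0.015
                )
            },
            germination=truth.germination,
            kernels=truth.kernels,
        )
        records = simulate_survival_experiment(t, "moderate", rng_seed=0)
        assert all(r.n_surviving == 0 for r in records)

    def test_impossible_parameters_rejected(self, truth):
        from seedfate.synthetic_data import SiteTruth, SyntheticTruth

        st = truth.sites["moderate"]
        t = SyntheticTruth(
            sites={
                "x": SiteTruth(
                    fate=st.fate, escape_baseline_5m=0.5, escape_log_slope_per_m=0.1
                )
            },
            germination=truth.germination,
            kernels=truth.kernels,
        )
        with pytest.raises(ValueError, match="survival > 1"):
            simulate_survival_experiment(t, "x", rng_seed=0)

    def test_trend_recovery_loop(self, truth):
        records = simulate_survival_experiment(
            truth, "defaunated", n_per_distance=1200, n_trees=20, rng_seed=10
        )
        res = distance_trend_test(records, "defaunated")
        se = res.slope / res.z_statistic
        assert abs(res.slope - 0.012) <= 3 * abs(se)


class TestCameraSimulation:
    def test_zero_rate_zero_counts(self, truth):
        from seedfate.synthetic_data import SiteTruth, SyntheticTruth

        st = truth.sites["intact"]
        t = SyntheticTruth(
            sites={
                "intact": SiteTruth(
                    fate=st.fate,
                    escape_baseline_5m=st.escape_baseline_5m,
                    escape_log_slope_per_m=0.0,
                    visitation_rates={"small_rodent": 0.0},
                )
            },
            germination=truth.germination,
            kernels=truth.kernels,
        )
        records = simulate_camera_traps(t, "intact", 500, rng_seed=0)
        assert all(r.n_visits == 0 for r in records)

    def test_rate_recovery(self, truth):
        records = simulate_camera_traps(truth, "intact", 10_000, rng_seed=11)
        rate = visitation_rate(records, "small_rodent", "intact")
        se = 100 * np.sqrt(70.0 * 10_000 / 100) / 10_000
        assert abs(rate - 70.0) <= 3 * se

    def test_rodent_release_ratio(self, truth):
        """The intact-disperser site shows the ~14-fold rodent release."""
        rec_hi = simulate_camera_traps(truth, "intact", 20_000, rng_seed=12)
        rec_lo = simulate_camera_traps(truth, "moderate", 20_000, rng_seed=13)
        ratio = visitation_rate(rec_hi, "small_rodent", "intact") / visitation_rate(
            rec_lo, "small_rodent", "moderate"
        )
        assert ratio == pytest.approx(14.0, rel=0.15)


class TestTableExport:
    def test_writes_all_tables_and_truth(self, truth, tmp_path):
        paths = write_synthetic_tables(truth, tmp_path, rng_seed=1, n_fruits=200)
        assert set(paths) == {"focal", "germination", "survival", "cameras", "distances", "truth"}
        for p in paths.values():
            assert (tmp_path / p.split("/")[-1]).exists()

    def test_byte_identical_under_fixed_seed(self, truth, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        write_synthetic_tables(truth, a, rng_seed=2, n_fruits=300)
        write_synthetic_tables(truth, b, rng_seed=2, n_fruits=300)
        for name in ("focal", "germination", "survival", "cameras", "distances"):
            assert (a / f"{name}.tsv").read_bytes() == (b / f"{name}.tsv").read_bytes()
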