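"""Process-model steps, closed forms, and small-scale simulations."""

import numpy as np
import pytest
from scipy import stats

from relicdna import (
    Community,
    ProcessParams,
    ScenarioSpec,
    assign_protection_susceptibilities,
    bias_from_simulation,
    build_lognormal_pool,
    decay_rate_for_target,
    equilibrium_relic_size,
    residence_time,
    run_process_simulation,
)
from relicdna.exceptions import (
    InsufficientIndividualsError,
    InvalidParameterError,
    UndefinedRatioError,
)
from relicdna.process_model import (
    step_birth,
    step_death,
    step_degradation,
    step_immigration,
)

# small but dynamically faithful configuration for fast tests
SMALL = dict(
    n_species=400,
    initial_intact_size=2_000,
    immigration=200,
    birth_rate=0.1,
    mortality_rate=0.1,
    n_steps=400,
)


class TestClosedForms:
    @pytest.mark.parametrize("m", [0.05, 0.1, 0.3])
    @pytest.mark.parametrize("p", [0.05, 0.1, 0.5, 0.9, 0.95, 1.0])
    def test_decay_rate_inverts_to_target_proportion(self, m, p):
        d = decay_rate_for_target(m, p)
        assert m / (m + d) == pytest.approx(p, rel=1e-12)

    def test_decay_rate_printed_values(self):
        assert decay_rate_for_target(0.1, 0.5) == pytest.approx(0.1)
        assert decay_rate_for_target(0.1, 0.95) == pytest.approx(0.1 / 0.95 - 0.1)
        assert decay_rate_for_target(0.1, 1.0) == 0.0

    def test_equilibrium_relic_size_formula(self):
        assert equilibrium_relic_size(0.1, 20_000, 0.1) == pytest.approx(20_000)
        # R = I * p / (1 - p) when d is chosen for target p
        d = decay_rate_for_target(0.1, 0.95)
        assert equilibrium_relic_size(0.1, 20_000, d) == pytest.approx(
            20_000 * 0.95 / 0.05
        )

    def test_equilibrium_monotone_in_decay(self):
        sizes = [equilibrium_relic_size(0.1, 20_000, d) for d in (0.05, 0.1, 0.5, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_residence_time_printed_formula(self):
        assert residence_time(20_000, 0.1) == pytest.approx(200_000)
        assert residence_time(0, 0.1) == 0.0
        assert residence_time(2 * 20_000, 0.1) == 2 * residence_time(20_000, 0.1)

    def test_degenerate_rates_rejected(self):
        with pytest.raises(InvalidParameterError):
            decay_rate_for_target(0.1, 0.0)
        with pytest.raises(UndefinedRatioError):
            equilibrium_relic_size(0.1, 1_000, 0.0)
        with pytest.raises(UndefinedRatioError):
            residence_time(1_000, 0.0)


class TestSusceptibilities:
    def test_u_shape_at_default_parameters(self):
        w = assign_protection_susceptibilities(4_000, 0.7, 0.7, seed=1)
        assert np.all((w >= 0) & (w <= 1))
        tails = np.mean(w <= 0.1) + np.mean(w >= 0.9)
        middle = np.mean((w >= 0.45) & (w <= 0.55))
        assert np.mean(w <= 0.1) > middle and np.mean(w >= 0.9) > middle
        assert tails > 2 * middle

    def test_concentrated_limit(self):
        w = assign_protection_susceptibilities(1_000, 500, 500, seed=2)
        assert np.all(np.abs(w - 0.5) < 0.1)

    def test_mean_matches_beta_moment(self):
        alpha, beta, n = 2.0, 5.0, 10_000
        w = assign_protection_susceptibilities(n, alpha, beta, seed=3)
        mean = alpha / (alpha + beta)
        se = np.sqrt(stats.beta.var(alpha, beta) / n)
        assert abs(w.mean() - mean) <= 3 * se

    def test_invalid_shapes_rejected(self):
        with pytest.raises(InvalidParameterError):
            assign_protection_susceptibilities(10, 0.0, 0.7, seed=0)


class TestSteps:
    @pytest.fixture
    def pool(self):
        return build_lognormal_pool(50, 0.98, seed=7)

    def test_immigration_adds_exactly_j(self, pool):
        intact = Community(np.full(50, 10))
        out, _ = step_immigration(intact, pool, 2_000, seed=1)
        assert out.size == intact.size + 2_000

    def test_immigration_zero_noop(self, pool):
        intact = Community(np.full(50, 10))
        out, _ = step_immigration(intact, pool, 0, seed=1)
        np.testing.assert_array_equal(out.counts, intact.counts)

    def test_immigrant_death_routes_to_relic(self, pool):
        intact = Community(np.full(50, 10))
        relic = Community(np.zeros(50, dtype=int))
        out_i, out_r = step_immigration(intact, pool, 300, 1.0, relic, seed=2)
        np.testing.assert_array_equal(out_i.counts, intact.counts)
        assert out_r.size == 300

    def test_birth_zero_rate_noop(self):
        intact = Community(np.array([5, 5]))
        assert step_birth(intact, 0.0, seed=1) is intact

    def test_birth_single_species(self):
        intact = Community(np.array([100, 0]))
        out = step_birth(intact, 0.2, seed=1)
        np.testing.assert_array_equal(out.counts, [120, 0])

    def test_birth_expected_gains_proportional_to_abundance(self, rng):
        intact = Community(np.array([300, 100]))
        gains = np.array(
            [step_birth(intact, 0.5, rng).counts - intact.counts for _ in range(1_000)]
        )
        expected = 200 * np.array([0.75, 0.25])
        se = np.sqrt(200 * 0.75 * 0.25 / 1_000)
        assert np.all(np.abs(gains.mean(axis=0) - expected) <= 4 * se)

    def test_death_conserves_individuals(self, rng):
        intact = Community(np.array([100, 100]))
        relic = Community(np.array([7, 3]))
        out_i, out_r = step_death(intact, relic, 0.5, 0, rng)
        assert out_i.size + out_r.size == intact.size + relic.size
        np.testing.assert_array_equal(out_i.counts + out_r.counts,
                                      intact.counts + relic.counts)
        assert np.all(out_i.counts >= 0)

    def test_death_mean_split_is_hypergeometric(self, rng):
        intact = Community(np.array([100, 100]))
        relic = Community(np.zeros(2, dtype=int))
        moved = np.array(
            [step_death(intact, relic, 0.5, 0, rng)[1].counts for _ in range(1_000)]
        )
        assert abs(moved[:, 0].mean() - 50) <= 3 * np.sqrt(25 / 1_000) * 5
        assert np.all(moved <= 100)

    def test_death_overdraw_rejected(self):
        intact = Community(np.array([5, 5]))
        relic = Community(np.zeros(2, dtype=int))
        with pytest.raises(InsufficientIndividualsError):
            step_death(intact, relic, 0.5, 100, seed=1)

    def test_degradation_zero_noop(self):
        relic = Community(np.array([10, 10]))
        out = step_degradation(relic, 0.0, 0, ScenarioSpec("neutral"), seed=1)
        np.testing.assert_array_equal(out.counts, relic.counts)

    def test_degradation_overdraw_rejected(self):
        relic = Community(np.array([2, 2]))
        with pytest.raises(InsufficientIndividualsError):
            step_degradation(relic, 1.0, 100, ScenarioSpec("neutral"), seed=1)

    def test_equal_susceptibility_protection_matches_neutral(self, rng):
        """Uniform protection weights are statistically neutral removal."""
        relic = Community(np.array([600, 400]))
        flat = ScenarioSpec("protection", susceptibilities=np.full(2, 0.5))
        neutral = ScenarioSpec("neutral")
        rem_p = np.array(
            [relic.counts - step_degradation(relic, 0.3, 0, flat, rng).counts
             for _ in range(400)]
        )[:, 0]
        rem_n = np.array(
            [relic.counts - step_degradation(relic, 0.3, 0, neutral, rng).counts
             for _ in range(400)]
        )[:, 0]
        assert stats.ks_2samp(rem_p, rem_n).pvalue > 0.01

    def test_hotspot_removes_dominant_species_faster(self, rng):
        relic = Community(np.array([900, 100]))
        removals = np.array(
            [900 - step_degradation(relic, 0.1, 0, ScenarioSpec("hotspot"), rng).counts[0]
             for _ in range(1_000)]
        )
        assert removals.mean() > 90  # neutral expectation is 90 of 100

    def test_protection_spares_low_susceptibility_species(self, rng):
        relic = Community(np.array([500, 500]))
        scenario = ScenarioSpec("protection", susceptibilities=np.array([0.05, 0.95]))
        survivors = np.array(
            [step_degradation(relic, 0.5, 0, scenario, rng).counts for _ in range(200)]
        )
        assert survivors[:, 0].mean() > survivors[:, 1].mean()


class TestRunProcessSimulation:
    def test_frozen_dynamics(self):
        params = ProcessParams(
            n_species=50, initial_intact_size=500, immigration=0,
            birth_rate=0.0, mortality_rate=0.0, decay_rate=0.5, n_steps=20, seed=1,
        )
        rec = run_process_simulation(params)
        assert np.all(rec.relic_trajectory == 0)
        assert np.all(rec.intact_trajectory == 500)

    def test_intact_size_stationary_when_birth_equals_death(self):
        params = ProcessParams(**SMALL, decay_rate=0.1, seed=3)
        rec = run_process_simulation(params)
        drift = np.abs(rec.intact_trajectory / params.initial_intact_size - 1)
        assert drift.max() <= 0.05

    def test_trajectory_lengths_include_initial_state(self):
        params = ProcessParams(**SMALL, decay_rate=0.1, seed=3)
        rec = run_process_simulation(params)
        assert rec.intact_trajectory.size == params.n_steps + 1
        assert rec.relic_trajectory.size == params.n_steps + 1

    def test_determinism(self):
        params = ProcessParams(**SMALL, decay_rate=0.2, seed=9)
        a, b = run_process_simulation(params), run_process_simulation(params)
        np.testing.assert_array_equal(a.relic_trajectory, b.relic_trajectory)
        np.testing.assert_array_equal(a.final_intact.counts, b.final_intact.counts)

    @pytest.mark.parametrize("p", [0.05, 0.5, 0.95])
    def test_equilibrium_recovery_across_proportions(self, p):
        """Tail-averaged relic size approaches m*I/d.

        Run length scales with the relic pool's relaxation time 1/d so the
        tail window sits past the transient at every target proportion.
        """
        d = decay_rate_for_target(0.1, p)
        config = dict(SMALL, n_steps=max(400, int(np.ceil(6.0 / d))))
        sizes = []
        for seed in range(3):
            rec = run_process_simulation(ProcessParams(**config, decay_rate=d, seed=seed))
            sizes.append(rec.tail_relic_size)
        expected = equilibrium_relic_size(0.1, SMALL["initial_intact_size"], d)
        assert np.mean(sizes) == pytest.approx(expected, rel=0.05)
        rec_p = rec.tail_relic_proportion
        assert rec_p == pytest.approx(p, abs=0.03)

    def test_neutral_relic_sad_tracks_intact_sad(self):
        """Neutral degradation keeps the relic SAD close to the intact SAD.

        The relic pool integrates a rolling window of death events, so its
        abundance distribution is a smoothed copy of the intact one: the KS
        distance stays small and well below the hotspot scenario's, which
        actively reshapes the relic SAD.
        """
        d = decay_rate_for_target(0.1, 0.5)

        def ks_distance(kind, seed):
            rec = run_process_simulation(
                ProcessParams(**SMALL, decay_rate=d, seed=seed,
                              scenario=ScenarioSpec(kind=kind))
            )
            i = rec.final_intact.counts / rec.final_intact.size
            rl = rec.final_relic.counts / rec.final_relic.size
            return stats.ks_2samp(i[i > 0], rl[rl > 0]).statistic

        neutral = np.mean([ks_distance("neutral", s) for s in range(3)])
        hotspot = np.mean([ks_distance("hotspot", s) for s in range(3)])
        assert neutral < 0.25
        assert neutral < hotspot

    def test_scenarios_shift_relic_evenness(self):
        """Protection lowers relic evenness vs neutral; hotspot raises it."""
        from relicdna.bias_metrics import simpson_evenness

        d = decay_rate_for_target(0.1, 0.8)
        evenness = {}
        for kind in ("neutral", "protection", "hotspot"):
            values = []
            for seed in range(3):
                rec = run_process_simulation(
                    ProcessParams(**SMALL, decay_rate=d, seed=seed,
                                  scenario=ScenarioSpec(kind=kind))
                )
                values.append(simpson_evenness(rec.final_relic.counts))
            evenness[kind] = np.mean(values)
        assert evenness["protection"] < evenness["neutral"] < evenness["hotspot"]


class TestBiasFromSimulation:
    def test_empty_relic_gives_exact_unit_ratio(self):
        params = ProcessParams(
            n_species=100, initial_intact_size=1_000, immigration=0,
            birth_rate=0.0, mortality_rate=0.0, decay_rate=0.5, n_steps=10, seed=2,
        )
        rec = run_process_simulation(params)
        out = bias_from_simulation(rec, seed=3)
        assert out["richness_ratio"] == 1.0
        assert out["bray_curtis"] == 0.0

    def test_scenario_bias_directions_small_scale(self):
        d = decay_rate_for_target(0.1, 0.8)
        ratios = {}
        for kind in ("protection", "hotspot"):
            values = []
            for seed in range(3):
                rec = run_process_simulation(
                    ProcessParams(**SMALL, decay_rate=d, seed=seed,
                                  scenario=ScenarioSpec(kind=kind))
                )
                values.append(bias_from_simulation(rec, seed=seed)["richness_ratio"])
            ratios[kind] = np.mean(values)
        assert ratios["protection"] < 1.0 < ratios["hotspot"]

    def test_invalid_scenario_kind_rejected(self):
        with pytest.raises(InvalidParameterError):
            ScenarioSpec("meteor")
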