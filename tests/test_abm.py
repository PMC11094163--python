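"""Agent-based simulation: schedules, hazard calibration, dynamics."""

import math

import numpy as np
import pytest
from scipy import stats

from pdtsim.abm import (
    ProtocolSchedule,
    SimulationConfig,
    build_schedule,
    compare_protocols,
    hazard_per_step,
    run_simulation,
)
from pdtsim.datasets import (
    Protocol,
    ResponseSurfaceParams,
    TreatmentCondition,
    generate_dataset,
)
from pdtsim.surrogate import ViabilitySurrogate


class TestBuildSchedule:
    def test_405_580_kills_in_second_phase(self):
        s = build_schedule(Protocol.SEQ_405_580, 60.0)
        assert s.phases == ((405, 30.0), (580, 30.0))
        assert s.kill_phase_index == 1

    def test_580_405_kills_in_first_phase(self):
        s = build_schedule(Protocol.SEQ_580_405, 60.0)
        assert s.phases == ((580, 30.0), (405, 30.0))
        assert s.kill_phase_index == 0

    def test_minimal_two_step_schedule(self):
        s = build_schedule(Protocol.SEQ_405_580, 2.0, dt=1.0)
        assert s.phases == ((405, 1.0), (580, 1.0))

    def test_rejects_indivisible_time(self):
        with pytest.raises(ValueError):
            build_schedule(Protocol.SEQ_405_580, 5.0, dt=2.0)

    def test_schedule_requires_unique_kill_phase(self):
        with pytest.raises(ValueError):
            ProtocolSchedule(phases=((405, 30.0), (405, 30.0)), kill_phase_index=0)


class TestHazardPerStep:
    @pytest.mark.parametrize(
        "survival,steps,expected",
        [
            (0.25, 2, 0.5),
            (1.0, 30, 0.0),
            (0.45, 30, 1.0 - 0.45 ** (1 / 30)),  # ~0.02627
        ],
    )
    def test_closed_form(self, survival, steps, expected):
        assert hazard_per_step(survival, steps) == pytest.approx(expected, rel=1e-12)

    def test_zero_survival_gives_certain_death(self):
        assert hazard_per_step(0.0, 10) == 1.0

    @pytest.mark.parametrize("survival,steps", [(-0.1, 10), (0.5, 0), (1.5, 10)])
    def test_rejects_invalid(self, survival, steps):
        with pytest.raises(ValueError):
            hazard_per_step(survival, steps)


class TestRunSimulation:
    def test_trajectory_shape_and_monotonicity(self, default_fit):
        cond = TreatmentCondition(2.0, Protocol.SEQ_405_580, 60.0, 400.0)
        config = SimulationConfig(n_cells=500, replicates=5, seed=3)
        sim = run_simulation(default_fit, cond, config)
        assert sim.trajectory[0] == 1.0
        assert sim.final_viability == sim.trajectory[-1]
        assert len(sim.trajectory) == 61
        assert (np.diff(sim.replicate_trajectories, axis=1) <= 0).all()

    def test_cell_count_conserved_each_step(self, default_fit):
        # Surviving fractions must always be whole-cell counts in [0, n]:
        # active + dead = n_cells at every step of every replicate.
        cond = TreatmentCondition(1.5, Protocol.SEQ_580_405, 40.0, 500.0)
        config = SimulationConfig(n_cells=300, replicates=4, seed=9)
        sim = run_simulation(default_fit, cond, config)
        counts = sim.replicate_trajectories * config.n_cells
        assert np.allclose(counts, np.round(counts))
        assert ((counts >= 0) & (counts <= config.n_cells)).all()

    def test_no_deaths_outside_kill_phase(self, default_fit):
        config = SimulationConfig(n_cells=400, replicates=3, seed=2)
        # 405-580: deaths only in the second half of the run
        cond = TreatmentCondition(2.0, Protocol.SEQ_405_580, 60.0, 400.0)
        sim = run_simulation(default_fit, cond, config)
        assert np.allclose(sim.replicate_trajectories[:, :31], 1.0)
        # 580-405: the second (405 nm) half is flat
        cond2 = TreatmentCondition(2.0, Protocol.SEQ_580_405, 60.0, 400.0)
        sim2 = run_simulation(default_fit, cond2, config)
        tail = sim2.replicate_trajectories[:, 30:]
        assert np.allclose(tail, tail[:, :1])

    def test_mean_final_within_binomial_ci_of_prediction(self, default_fit):
        cond = TreatmentCondition(2.0, Protocol.SEQ_405_580, 60.0, 400.0)
        config = SimulationConfig(n_cells=1000, replicates=20, seed=7)
        sim = run_simulation(default_fit, cond, config)
        target = sim.target_viability
        n = config.n_cells * config.replicates
        half = stats.norm.ppf(0.995) * math.sqrt(target * (1 - target) / n)
        assert abs(sim.final_viability - target) <= half

    def test_inert_surface_gives_flat_trajectory(self, noiseless_fit):
        # zero concentration -> predicted survival ~1 -> essentially no kill
        cond = TreatmentCondition(1e-9, Protocol.SEQ_405_580, 60.0, 400.0)
        config = SimulationConfig(n_cells=200, replicates=3, seed=1)
        sim = run_simulation(noiseless_fit, cond, config)
        assert sim.final_viability >= 0.99

    def test_deterministic_given_config(self, default_fit):
        cond = TreatmentCondition(2.0, Protocol.SEQ_580_405, 60.0, 400.0)
        config = SimulationConfig(n_cells=500, replicates=5, seed=13)
        a = run_simulation(default_fit, cond, config)
        b = run_simulation(default_fit, cond, config)
        assert np.array_equal(a.replicate_trajectories, b.replicate_trajectories)

    def test_photosensitizer_bookkeeping(self, default_fit):
        cond = TreatmentCondition(2.0, Protocol.SEQ_405_580, 60.0, 400.0)
        sim = run_simulation(default_fit, cond, SimulationConfig(n_cells=10,
                                                                replicates=1, seed=0))
        assert sim.n_photosensitizers == 200
        assert sim.ps_states[0] == "inactive"
        assert set(sim.ps_states[1:]) == {"activated-405-580"}


class TestCompareProtocols:
    def test_benchmark_endpoints_match_study_values(self, default_fit):
        cmp_ = compare_protocols(default_fit, 2.0, 60.0, 400.0,
                                 SimulationConfig(n_cells=1000, replicates=20, seed=7))
        assert cmp_.result_580_405.final_viability == pytest.approx(0.45, abs=0.05)
        assert cmp_.result_405_580.final_viability == pytest.approx(0.20, abs=0.05)
        assert cmp_.difference == pytest.approx(0.2, abs=0.05)

    def test_difference_non_negative_across_grid(self, default_fit):
        config = SimulationConfig(n_cells=400, replicates=5, seed=3)
        for c in np.arange(0.25, 2.26, 0.5):
            cmp_ = compare_protocols(default_fit, float(c), 60.0, 400.0, config)
            assert cmp_.difference >= -0.03

    def test_near_inert_protocol_gives_near_zero_difference(self):
        params = ResponseSurfaceParams(emax_405_580=0.93, emax_580_405=0.9299,
                                       noise_sd=0.0)
        res = ViabilitySurrogate(generate_dataset(params, seed=1)).fit(seed=1)
        cmp_ = compare_protocols(res, 2.0, 60.0, 400.0,
                                 SimulationConfig(n_cells=1000, replicates=10, seed=5))
        assert abs(cmp_.difference) <= 0.05


class TestSimulationConfig:
    @pytest.mark.parametrize(
        "kwargs", [dict(n_cells=0), dict(replicates=0), dict(dt=0.0)]
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
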