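"""Agent-based simulation of sequential dual-wavelength PDT.

Cell agents (ACTIVE/DEAD) and photosensitizer agents (INACTIVE or
activated by one of the two sequential protocols) evolve over discrete
time steps under a two-phase light schedule.  Cytotoxicity is confined
to the 580 nm phase — the wavelength that photoactivates the released
photosensitizer — where each active cell dies independently with a
constant per-step hazard.  The hazard is calibrated so that the expected
surviving fraction at the end of the run equals the fitted surrogate's
viability prediction for the condition: the ABM realizes, as a
stochastic population process, the endpoint the surrogate predicts.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import Protocol, TreatmentCondition
from .surrogate import SurrogateResults

__all__ = [
    "CellState",
    "PhotosensitizerState",
    "ProtocolSchedule",
    "SimulationConfig",
    "SimulationResult",
    "ProtocolComparison",
    "build_schedule",
    "hazard_per_step",
    "run_simulation",
    "compare_protocols",
]

KILL_WAVELENGTH_NM = 580


class CellState(enum.Enum):
    ACTIVE = "active"
    DEAD = "dead"  # absorbing


class PhotosensitizerState(enum.Enum):
    INACTIVE = "inactive"
    ACTIVATED_405_580 = "activated-405-580"
    ACTIVATED_580_405 = "activated-580-405"


ACTIVATED_STATE = {
    Protocol.SEQ_405_580: PhotosensitizerState.ACTIVATED_405_580,
    Protocol.SEQ_580_405: PhotosensitizerState.ACTIVATED_580_405,
}


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered light phases (wavelength nm, duration min) and kill phase.

    Exactly one phase — the 580 nm phase — photoactivates cytotoxicity.
    """

    phases: tuple[tuple[int, float], ...]
    kill_phase_index: int

    def __post_init__(self) -> None:
        kills = [i for i, (wl, _) in enumerate(self.phases) if wl == KILL_WAVELENGTH_NM]
        if kills != [self.kill_phase_index]:
            raise ValueError("exactly one 580 nm phase must be the kill phase")

    @property
    def total_time(self) -> float:
        return sum(d for _, d in self.phases)


def build_schedule(protocol: Protocol | str, pdt_time: float, dt: float = 1.0
                   ) -> ProtocolSchedule:
    """Two equal phases of pdt_time/2 in protocol order.

    The kill phase is the 580 nm phase: second for 405-580, first for
    580-405.  Each phase duration must be a whole number of ``dt`` steps.
    """
    protocol = Protocol.from_label(protocol)
    half = pdt_time / 2.0
    steps = half / dt
    if abs(steps - round(steps)) > 1e-9 or steps < 1:
        raise ValueError(
            f"pdt_time {pdt_time} min does not split into whole dt={dt} phases"
        )
    if protocol is Protocol.SEQ_405_580:
        phases = ((405, half), (580, half))
        kill = 1
    else:
        phases = ((580, half), (405, half))
        kill = 0
    return ProtocolSchedule(phases=phases, kill_phase_index=kill)


def hazard_per_step(target_survival: float, kill_steps: int) -> float:
    """Per-step death probability realizing a target survival fraction.

    p = 1 - target_survival**(1/kill_steps): after ``kill_steps``
    independent Bernoulli steps the expected surviving fraction is
    exactly ``target_survival``.
    """
    if kill_steps < 1:
        raise ValueError(f"kill_steps must be >= 1, got {kill_steps}")
    if target_survival < 0 or target_survival > 1:
        raise ValueError(f"target_survival must be in [0, 1], got {target_survival}")
    if target_survival == 0.0:
        return 1.0
    return 1.0 - target_survival ** (1.0 / kill_steps)


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings: agent counts, step size, seeding, replicates.

    Photosensitizer agents are display bookkeeping, scaled to
    concentration (``ps_per_unit_conc`` per mg/mL); they do not modulate
    the hazard, which is calibrated to the surrogate endpoint.
    """

    n_cells: int = 1000
    dt: float = 1.0
    seed: int = 7
    replicates: int = 20
    ps_per_unit_conc: float = 100.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class SimulationResult:
    """Trajectories and endpoint of a replicated ABM run.

    ``trajectory`` is the mean viability fraction per step (starting at
    1.0 before any light); ``replicate_finals`` the final surviving
    fraction of each replicate; ``ps_states`` the photosensitizer state
    label per step.
    """

    condition: TreatmentCondition
    schedule: ProtocolSchedule
    config: SimulationConfig
    target_viability: float
    trajectory: np.ndarray
    replicate_trajectories: np.ndarray
    replicate_finals: np.ndarray
    ps_states: list[str]
    n_photosensitizers: int

    @property
    def final_viability(self) -> float:
        return float(self.trajectory[-1])

    @property
    def final_sd(self) -> float:
        return float(np.std(self.replicate_finals, ddof=1)) if len(
            self.replicate_finals) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "condition": {
                "concentration_mg_ml": self.condition.concentration,
                "protocol": self.condition.protocol.value,
                "pdt_time_min": self.condition.pdt_time,
                "input_power_mw": self.condition.input_power,
            },
            "target_viability": self.target_viability,
            "trajectory": self.trajectory.tolist(),
            "replicate_finals": self.replicate_finals.tolist(),
            "mean_final_viability": self.final_viability,
            "sd_final_viability": self.final_sd,
            "n_photosensitizers": self.n_photosensitizers,
            "config": {
                "n_cells": self.config.n_cells,
                "dt": self.config.dt,
                "seed": self.config.seed,
                "replicates": self.config.replicates,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    def plot_trajectory(self, ax=None):
        """Plot real-time viability during the simulated treatment."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(len(self.trajectory)) * self.config.dt
        ax.plot(t, self.trajectory, label=self.condition.protocol.value)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("cell viability")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax


def run_simulation(
    results: SurrogateResults,
    condition: TreatmentCondition,
    config: SimulationConfig | None = None,
) -> SimulationResult:
    """Run the replicated agent-based simulation at one condition.

    Photosensitizer agents flip from INACTIVE to the protocol's
    activated state at the onset of the first light phase.  During the
    kill (580 nm) phase each active cell dies independently per step
    with probability ``hazard_per_step(predicted viability, kill
    steps)``; outside the kill phase no deaths occur.  Replicate k uses
    seed ``config.seed + k``.  Deterministic given (results, condition,
    config).
    """
    if config is None:
        config = SimulationConfig()
    schedule = build_schedule(condition.protocol, condition.pdt_time, config.dt)
    target = results.predict_viability(condition)

    phase_steps = [int(round(d / config.dt)) for _, d in schedule.phases]
    total_steps = sum(phase_steps)
    kill_steps = phase_steps[schedule.kill_phase_index]
    p = hazard_per_step(target, kill_steps)

    # kill mask per step index (0-based step during which deaths may occur)
    kill_mask = np.zeros(total_steps, dtype=bool)
    start = sum(phase_steps[: schedule.kill_phase_index])
    kill_mask[start : start + kill_steps] = True

    trajs = np.empty((config.replicates, total_steps + 1))
    for k in range(config.replicates):
        rng = np.random.default_rng(config.seed + k)
        alive = config.n_cells
        trajs[k, 0] = 1.0
        for step in range(total_steps):
            if kill_mask[step] and alive > 0 and p > 0:
                deaths = rng.binomial(alive, p)
                alive -= deaths
            trajs[k, step + 1] = alive / config.n_cells

    activated = ACTIVATED_STATE[condition.protocol].value
    ps_states = [PhotosensitizerState.INACTIVE.value] + [activated] * total_steps
    n_ps = int(round(config.ps_per_unit_conc * condition.concentration))

    return SimulationResult(
        condition=condition,
        schedule=schedule,
        config=config,
        target_viability=target,
        trajectory=trajs.mean(axis=0),
        replicate_trajectories=trajs,
        replicate_finals=trajs[:, -1].copy(),
        ps_states=ps_states,
        n_photosensitizers=n_ps,
    )


@dataclass
class ProtocolComparison:
    """Paired simulation of both protocols on common replicate seeds."""

    result_405_580: SimulationResult
    result_580_405: SimulationResult

    @property
    def difference(self) -> float:
        """Mean final viability, 580-405 minus 405-580 (positive when
        the 405-580 order kills more)."""
        return self.result_580_405.final_viability - self.result_405_580.final_viability

    def to_dict(self) -> dict:
        return {
            "result_405_580": self.result_405_580.to_dict(),
            "result_580_405": self.result_580_405.to_dict(),
            "difference_580_405_minus_405_580": self.difference,
        }


def compare_protocols(
    results: SurrogateResults,
    concentration: float,
    pdt_time: float,
    input_power: float,
    config: SimulationConfig | None = None,
) -> ProtocolComparison:
    """Simulate both sequential protocols at one (c, t, P) setting.

    Both runs share the same replicate seeds so the comparison is paired.
    """
    if config is None:
        config = SimulationConfig()
    sims = {}
    for proto in (Protocol.SEQ_405_580, Protocol.SEQ_580_405):
        cond = TreatmentCondition(concentration, proto, pdt_time, input_power)
        sims[proto] = run_simulation(results, cond, config)
    return ProtocolComparison(
        result_405_580=sims[Protocol.SEQ_405_580],
        result_580_405=sims[Protocol.SEQ_580_405],
    )
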