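"""Synthetic factorial cell-viability dataset for dual-wavelength PDT.

The in vitro screen behind the surrogate model — 378 viability
measurements over a four-factor treatment space (photosensitizer-micelle
concentration, sequential lighting protocol, PDT time, transmitter input
power) — is not publicly deposited.  This module generates a stand-in
dataset from a parametric ground-truth response surface:

    V(c, p, t, P) = 1 - Emax(p) * c^h / (EC50^h + c^h) * D / (D50 + D)

with light dose D = P * t (mW * min).  Concentration follows a Hill
curve; light dose saturates; the protocol enters only through Emax, with
the 405-580 order (release first, then photoactivation) the more potent
one.  Additive truncated Gaussian noise emulates assay variability, and
records are randomly split 252 train / 126 validation.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "Protocol",
    "TreatmentCondition",
    "ResponseSurfaceParams",
    "ViabilityDataset",
    "dbm_to_milliwatts",
    "true_viability",
    "generate_dataset",
    "CONCENTRATION_LEVELS",
    "TIME_LEVELS",
    "POWER_LEVELS_DBM",
]

#: dB offset linking the transmitter's dBm setting to emitted power in mW.
DBM_OFFSET_DB = 43.0

#: Factorial grid levels: 9 concentrations x 2 protocols x 3 times x 7 powers = 378.
CONCENTRATION_LEVELS: tuple[float, ...] = tuple(0.25 * k for k in range(1, 10))
TIME_LEVELS: tuple[float, ...] = (20.0, 40.0, 60.0)
POWER_LEVELS_DBM: tuple[float, ...] = (-18.0, -17.0, -16.0, -15.0, -14.0, -13.0, -12.0)

TRAIN = "TRAIN"
VALIDATION = "VALIDATION"

N_TRAIN = 252
N_VALIDATION = 126

CSV_COLUMNS = [
    "concentration_mg_ml",
    "protocol",
    "pdt_time_min",
    "input_power_mw",
    "viability",
    "split",
]


class Protocol(str, enum.Enum):
    """Sequential lighting protocol: wavelength order of the two phases.

    405-580 degrades the micelle first (405 nm) then photoactivates the
    released photosensitizer (580 nm); 580-405 is the reverse order.
    """

    SEQ_405_580 = "405-580"
    SEQ_580_405 = "580-405"

    @classmethod
    def from_label(cls, label: "Protocol | str") -> "Protocol":
        if isinstance(label, Protocol):
            return label
        try:
            return cls(label)
        except ValueError:
            raise ValueError(
                f"unknown protocol {label!r}; expected '405-580' or '580-405'"
            ) from None


@dataclass(frozen=True)
class TreatmentCondition:
    """One point in the four-factor treatment space.

    Parameters
    ----------
    concentration : float
        RB-M concentration in mg/mL, >= 0.
    protocol : Protocol
        Sequential lighting protocol.
    pdt_time : float
        Total PDT time in minutes, > 0.
    input_power : float
        Transmitter input power in mW, > 0.
    """

    concentration: float
    protocol: Protocol
    pdt_time: float
    input_power: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "protocol", Protocol.from_label(self.protocol))
        for name in ("concentration", "pdt_time", "input_power"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")
        if self.pdt_time <= 0:
            raise ValueError(f"pdt_time must be > 0, got {self.pdt_time}")
        if self.input_power <= 0:
            raise ValueError(f"input_power must be > 0, got {self.input_power}")

    @property
    def light_dose(self) -> float:
        """Nominal light dose P*t in mW*min."""
        return self.input_power * self.pdt_time


@dataclass(frozen=True)
class ResponseSurfaceParams:
    """Ground-truth response-surface constants of the synthetic generator.

    Defaults are calibrated so the surface reproduces the study's printed
    simulation endpoints: viability ~0.21 under 405-580 and ~0.45 under
    580-405 at (2 mg/mL, 60 min, 400 mW), with an inter-protocol gap of
    ~0.2 at concentrations >= 1 mg/mL.

    Parameters
    ----------
    ec50 : float
        Half-effect concentration of the Hill term, mg/mL.
    hill : float
        Hill coefficient (dimensionless).
    emax_405_580, emax_580_405 : float
        Maximal kill fraction per protocol; 405-580 is the more potent.
    d50 : float
        Half-saturation light dose, mW*min.
    noise_sd : float
        SD of additive Gaussian assay noise (viability fraction).
    """

    ec50: float = 0.8
    hill: float = 2.0
    emax_405_580: float = 0.93
    emax_580_405: float = 0.65
    d50: float = 500.0
    noise_sd: float = 0.08

    def __post_init__(self) -> None:
        if not (0.0 < self.emax_580_405 < self.emax_405_580 <= 1.0):
            raise ValueError(
                "require 0 < emax_580_405 < emax_405_580 <= 1, got "
                f"{self.emax_580_405}, {self.emax_405_580}"
            )
        for name in ("ec50", "hill", "d50"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def emax(self, protocol: Protocol | str) -> float:
        protocol = Protocol.from_label(protocol)
        return (
            self.emax_405_580
            if protocol is Protocol.SEQ_405_580
            else self.emax_580_405
        )

    def to_json(self, path: str | Path, *, seed: int | None = None) -> None:
        payload = asdict(self)
        if seed is not None:
            payload["seed"] = seed
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ResponseSurfaceParams":
        payload = json.loads(Path(path).read_text())
        payload.pop("seed", None)
        return cls(**payload)


def dbm_to_milliwatts(level: float) -> float:
    """Convert a transmitter dBm setting to emitted power in mW.

    The mapping is 10**((level + 43)/10): each +1 dBm multiplies power by
    10**0.1, with a fixed +43 dB system offset (so -43 dBm -> 1 mW and
    -13 dBm -> 1000 mW).
    """
    level = float(level)
    if not math.isfinite(level):
        raise ValueError(f"dBm level must be finite, got {level!r}")
    return 10.0 ** ((level + DBM_OFFSET_DB) / 10.0)


def true_viability(
    condition: TreatmentCondition,
    params: ResponseSurfaceParams | None = None,
) -> float:
    """Noise-free viability fraction at a treatment condition.

    V = 1 - Emax(protocol) * c^h/(ec50^h + c^h) * D/(d50 + D), D = P*t.
    Exactly 1 at zero concentration; non-increasing in concentration,
    time, and power; always within [0, 1].
    """
    if params is None:
        params = ResponseSurfaceParams()
    c = condition.concentration
    if c == 0.0:
        return 1.0
    hill_term = c**params.hill / (params.ec50**params.hill + c**params.hill)
    dose = condition.light_dose
    dose_term = dose / (params.d50 + dose)
    v = 1.0 - params.emax(condition.protocol) * hill_term * dose_term
    return float(min(1.0, max(0.0, v)))


@dataclass
class ViabilityDataset:
    """The 378-record factorial viability dataset with its provenance.

    ``frame`` has the columns ``concentration_mg_ml, protocol,
    pdt_time_min, input_power_mw, viability, split`` (protocol serialized
    as ``405-580`` / ``580-405``; split ``TRAIN`` / ``VALIDATION``).
    """

    frame: pd.DataFrame
    seed: int | None = None
    surface: ResponseSurfaceParams | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset frame missing columns {missing}")
        bad = set(self.frame["split"]) - {TRAIN, VALIDATION}
        if bad:
            raise ValueError(f"unknown split labels {sorted(bad)}")
        v = self.frame["viability"].to_numpy()
        if (v < 0).any() or (v > 1).any():
            raise ValueError("viability values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def train(self) -> pd.DataFrame:
        return self.frame[self.frame["split"] == TRAIN]

    @property
    def validation(self) -> pd.DataFrame:
        return self.frame[self.frame["split"] == VALIDATION]

    def conditions(self) -> list[TreatmentCondition]:
        return [
            TreatmentCondition(
                row.concentration_mg_ml,
                Protocol(row.protocol),
                row.pdt_time_min,
                row.input_power_mw,
            )
            for row in self.frame.itertuples()
        ]

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.8g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ViabilityDataset":
        frame = pd.read_csv(path)
        return cls(frame=frame)


def _factorial_grid() -> pd.DataFrame:
    powers_mw = [dbm_to_milliwatts(d) for d in POWER_LEVELS_DBM]
    rows = [
        (c, p.value, t, pw)
        for c in CONCENTRATION_LEVELS
        for p in (Protocol.SEQ_405_580, Protocol.SEQ_580_405)
        for t in TIME_LEVELS
        for pw in powers_mw
    ]
    return pd.DataFrame(
        rows,
        columns=["concentration_mg_ml", "protocol", "pdt_time_min", "input_power_mw"],
    )


def generate_dataset(
    params: ResponseSurfaceParams | None = None,
    seed: int = 0,
) -> ViabilityDataset:
    """Generate the full factorial dataset with noise and a seeded split.

    Builds the 9 x 2 x 3 x 7 grid, evaluates the ground-truth surface,
    adds Gaussian noise (``params.noise_sd``) clipped to [0, 1], and
    assigns a uniform random 252/126 train/validation split.
    Deterministic given (params, seed).
    """
    if params is None:
        params = ResponseSurfaceParams()
    rng = np.random.default_rng(seed)
    frame = _factorial_grid()
    truth = np.array(
        [
            true_viability(
                TreatmentCondition(
                    row.concentration_mg_ml,
                    Protocol(row.protocol),
                    row.pdt_time_min,
                    row.input_power_mw,
                ),
                params,
            )
            for row in frame.itertuples()
        ]
    )
    noisy = truth + rng.normal(0.0, params.noise_sd, size=len(frame))
    frame["viability"] = np.clip(noisy, 0.0, 1.0)
    split = np.array([TRAIN] * N_TRAIN + [VALIDATION] * N_VALIDATION)
    frame["split"] = rng.permutation(split)
    return ViabilityDataset(frame=frame, seed=seed, surface=params)
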