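"""Neural surrogate of cell viability versus the four treatment factors.

A single-hidden-layer network (4 inputs -> 20 tanh units -> 1 affine
output) is fitted to the training split of a viability dataset and then
queried at arbitrary treatment conditions — in particular at simulation
runtime by the agent-based model.  The API follows the model/results
convention: build a :class:`ViabilitySurrogate` from a dataset, call
``fit()``, and work with the returned :class:`SurrogateResults`.

Continuous features (concentration, time, power) are z-scored on the
training split; the protocol enters as a binary code (580-405 -> 0,
405-580 -> 1).  Predictions are clipped to [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .datasets import Protocol, TreatmentCondition, ViabilityDataset

__all__ = ["FeatureCodec", "ViabilitySurrogate", "SurrogateResults", "FitReport"]

N_HIDDEN = 20

#: L2 weight penalty of the network fit.  A 20-unit tanh layer on 252
#: noisy points interpolates assay noise without shrinkage; this mild
#: decay holds validation R^2 at the noise ceiling while leaving the
#: noiseless-surface fit essentially exact (MAE < 0.01).
L2_ALPHA = 0.05
FACTORS = ("concentration", "protocol", "pdt_time", "input_power")
_CONT_COLS = ["concentration_mg_ml", "pdt_time_min", "input_power_mw"]
PROTOCOL_CODE = {Protocol.SEQ_580_405: 0.0, Protocol.SEQ_405_580: 1.0}


@dataclass(frozen=True)
class FeatureCodec:
    """Standardization constants mapping a condition to the 4-vector input.

    Feature order: concentration, protocol code, pdt_time, input_power.
    Continuous features are z-scored with training-split means/SDs.
    """

    means: tuple[float, float, float]
    sds: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sds):
            raise ValueError("codec sds must be strictly positive")

    @classmethod
    def fit(cls, train: pd.DataFrame) -> "FeatureCodec":
        cont = train[_CONT_COLS].to_numpy(float)
        return cls(
            means=tuple(cont.mean(axis=0)),
            sds=tuple(cont.std(axis=0, ddof=0)),
        )

    def encode_frame(self, frame: pd.DataFrame) -> np.ndarray:
        cont = frame[_CONT_COLS].to_numpy(float)
        if not np.isfinite(cont).all():
            raise ValueError("non-finite feature values")
        z = (cont - np.asarray(self.means)) / np.asarray(self.sds)
        code = frame["protocol"].map(lambda p: PROTOCOL_CODE[Protocol.from_label(p)])
        return np.column_stack([z[:, 0], code.to_numpy(float), z[:, 1], z[:, 2]])

    def encode(self, condition: TreatmentCondition) -> np.ndarray:
        frame = pd.DataFrame(
            {
                "concentration_mg_ml": [condition.concentration],
                "pdt_time_min": [condition.pdt_time],
                "input_power_mw": [condition.input_power],
                "protocol": [condition.protocol.value],
            }
        )
        return self.encode_frame(frame)


@dataclass(frozen=True)
class FitReport:
    """Goodness of fit on both splits: R^2 = 1 - SSE/SST and raw SSE.

    SST uses each split's own mean.  ``r2_*`` is NaN (flagged by
    ``r2_*_defined``) when the split's viability is constant (SST = 0).
    """

    r2_train: float
    sse_train: float
    r2_validation: float
    sse_validation: float
    n_train: int
    n_validation: int

    @property
    def r2_train_defined(self) -> bool:
        return not math.isnan(self.r2_train)

    @property
    def r2_validation_defined(self) -> bool:
        return not math.isnan(self.r2_validation)

    def to_dict(self) -> dict:
        return {
            "r2_train": self.r2_train,
            "sse_train": self.sse_train,
            "r2_validation": self.r2_validation,
            "sse_validation": self.sse_validation,
            "n_train": self.n_train,
            "n_validation": self.n_validation,
        }


def _r2_sse(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return r2, sse


class ViabilitySurrogate:
    """Single-hidden-layer tanh regression of viability on treatment factors.

    Parameters
    ----------
    dataset : ViabilityDataset or pandas.DataFrame
        Factorial viability data carrying both TRAIN and VALIDATION
        records (a DataFrame must use the dataset CSV schema).

    Examples
    --------
    >>> from pdtsim.datasets import generate_dataset
    >>> res = ViabilitySurrogate(generate_dataset(seed=1)).fit(seed=1)
    >>> 0 <= res.predict_viability(
    ...     TreatmentCondition(2.0, "405-580", 60, 400)) <= 1
    True
    """

    def __init__(self, dataset: ViabilityDataset | pd.DataFrame):
        if isinstance(dataset, pd.DataFrame):
            dataset = ViabilityDataset(frame=dataset)
        if len(dataset.train) == 0 or len(dataset.validation) == 0:
            raise ValueError("dataset must carry non-empty TRAIN and VALIDATION splits")
        self.dataset = dataset

    @classmethod
    def from_csv(cls, path: str | Path) -> "ViabilitySurrogate":
        return cls(ViabilityDataset.from_csv(path))

    def fit(
        self, seed: int = 0, epochs: int = 5000, alpha: float = L2_ALPHA
    ) -> "SurrogateResults":
        """Fit the 4->20(tanh)->1 network by penalized SSE on TRAIN.

        Deterministic given (dataset, seed, epochs, alpha).  ``epochs``
        bounds the optimizer's iteration count; ``alpha`` is the L2
        weight penalty.
        """
        train = self.dataset.train
        codec = FeatureCodec.fit(train)
        x_train = codec.encode_frame(train)
        y_train = train["viability"].to_numpy(float)
        net = MLPRegressor(
            hidden_layer_sizes=(N_HIDDEN,),
            activation="tanh",
            solver="lbfgs",
            alpha=float(alpha),
            max_iter=int(epochs),
            tol=1e-9,
            random_state=int(seed),
        )
        if np.ptp(y_train) == 0.0:
            # Degenerate constant target: lbfgs may stop at iteration 0
            # with arbitrary output scale; the exact fit is the constant.
            w1 = np.zeros((4, N_HIDDEN))
            b1 = np.zeros(N_HIDDEN)
            w2 = np.zeros(N_HIDDEN)
            b2 = float(y_train[0])
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # ConvergenceWarning at max_iter
                net.fit(x_train, y_train)
            w1 = np.asarray(net.coefs_[0], float)
            b1 = np.asarray(net.intercepts_[0], float)
            w2 = np.asarray(net.coefs_[1], float).ravel()
            b2 = float(np.asarray(net.intercepts_[1]).ravel()[0])
        return SurrogateResults(
            model=self,
            codec=codec,
            hidden_weights=w1,
            hidden_biases=b1,
            output_weights=w2,
            output_bias=b2,
            training_seed=int(seed),
            epochs=int(epochs),
        )


class SurrogateResults:
    """Fitted surrogate: weights, fit report, prediction, diagnostics."""

    def __init__(
        self,
        model: ViabilitySurrogate | None,
        codec: FeatureCodec,
        hidden_weights: np.ndarray,
        hidden_biases: np.ndarray,
        output_weights: np.ndarray,
        output_bias: float,
        training_seed: int,
        epochs: int,
    ):
        hidden_weights = np.asarray(hidden_weights, float)
        if hidden_weights.shape != (4, N_HIDDEN):
            raise ValueError(
                f"hidden_weights must be 4x{N_HIDDEN}, got {hidden_weights.shape}"
            )
        self.model = model
        self.codec = codec
        self.hidden_weights = hidden_weights
        self.hidden_biases = np.asarray(hidden_biases, float)
        self.output_weights = np.asarray(output_weights, float).ravel()
        self.output_bias = float(output_bias)
        self.training_seed = training_seed
        self.epochs = epochs
        self._report: FitReport | None = None

    # -- prediction -----------------------------------------------------

    def _forward(self, x: np.ndarray) -> np.ndarray:
        hidden = np.tanh(x @ self.hidden_weights + self.hidden_biases)
        raw = hidden @ self.output_weights + self.output_bias
        return np.clip(raw, 0.0, 1.0)

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """Predicted viability for each row of a dataset-schema frame."""
        return self._forward(self.codec.encode_frame(frame))

    def predict_viability(self, condition: TreatmentCondition) -> float:
        """Predicted viability fraction at one condition, clipped to [0, 1]."""
        return float(self._forward(self.codec.encode(condition))[0])

    # -- fit quality ----------------------------------------------------

    @property
    def report(self) -> FitReport:
        if self._report is None:
            if self.model is None:
                raise ValueError("results restored without data carry no fit report")
            ds = self.model.dataset
            parts = {}
            for name, frame in (("train", ds.train), ("validation", ds.validation)):
                y = frame["viability"].to_numpy(float)
                r2, sse = _r2_sse(y, self.predict_frame(frame))
                parts[name] = (r2, sse, len(frame))
            self._report = FitReport(
                r2_train=parts["train"][0],
                sse_train=parts["train"][1],
                r2_validation=parts["validation"][0],
                sse_validation=parts["validation"][1],
                n_train=parts["train"][2],
                n_validation=parts["validation"][2],
            )
        return self._report

    def summary(self) -> str:
        """Plain-text fit summary table."""
        r = self.report
        lines = [
            "Viability surrogate (4 -> 20 tanh -> 1)",
            "=" * 46,
            f"{'training seed':<24}{self.training_seed}",
            f"{'epochs':<24}{self.epochs}",
            f"{'n train / validation':<24}{r.n_train} / {r.n_validation}",
            f"{'R2 train':<24}{r.r2_train:.4f}",
            f"{'SSE train':<24}{r.sse_train:.4f}",
            f"{'R2 validation':<24}{r.r2_validation:.4f}",
            f"{'SSE validation':<24}{r.sse_validation:.4f}",
        ]
        return "\n".join(lines)

    # -- diagnostics ----------------------------------------------------

    def factor_importance(self, seed: int = 0, reps: int = 20) -> pd.DataFrame:
        """Permutation importance of the four factors on VALIDATION.

        For each factor, the mean increase in validation SSE over
        ``reps`` independent shuffles of that factor's column.  Returns
        a frame sorted by descending importance; deterministic given
        ``seed``.
        """
        if reps < 1:
            raise ValueError(f"reps must be >= 1, got {reps}")
        if self.model is None:
            raise ValueError("factor_importance requires the training dataset")
        frame = self.model.dataset.validation.reset_index(drop=True)
        y = frame["viability"].to_numpy(float)
        base_sse = float(np.sum((y - self.predict_frame(frame)) ** 2))
        rng = np.random.default_rng(seed)
        cols = {
            "concentration": "concentration_mg_ml",
            "protocol": "protocol",
            "pdt_time": "pdt_time_min",
            "input_power": "input_power_mw",
        }
        rows = []
        for factor, col in cols.items():
            deltas = []
            for _ in range(reps):
                shuffled = frame.copy()
                shuffled[col] = rng.permutation(shuffled[col].to_numpy())
                sse = float(np.sum((y - self.predict_frame(shuffled)) ** 2))
                deltas.append(sse - base_sse)
            rows.append((factor, float(np.mean(deltas))))
        out = pd.DataFrame(rows, columns=["factor", "delta_sse"])
        return out.sort_values("delta_sse", ascending=False, ignore_index=True)

    def protocol_curve(
        self,
        time: float,
        power: float,
        concentrations: Sequence[float],
    ) -> pd.DataFrame:
        """Predicted viability vs concentration for both protocols.

        Returns a frame with columns ``concentration_mg_ml``,
        ``viability_405_580``, ``viability_580_405`` at fixed (time,
        power) — the protocol-comparison profile.
        """
        conc = np.asarray(list(concentrations), float)
        if conc.size == 0:
            raise ValueError("concentration grid must be non-empty")
        curves = {}
        for proto in (Protocol.SEQ_405_580, Protocol.SEQ_580_405):
            frame = pd.DataFrame(
                {
                    "concentration_mg_ml": conc,
                    "protocol": proto.value,
                    "pdt_time_min": time,
                    "input_power_mw": power,
                }
            )
            curves[proto] = self.predict_frame(frame)
        return pd.DataFrame(
            {
                "concentration_mg_ml": conc,
                "viability_405_580": curves[Protocol.SEQ_405_580],
                "viability_580_405": curves[Protocol.SEQ_580_405],
            }
        )

    def plot_protocol_curve(self, time: float, power: float,
                            concentrations: Sequence[float], ax=None):
        """Plot the per-protocol viability-vs-concentration curves."""
        import matplotlib.pyplot as plt

        curve = self.protocol_curve(time, power, concentrations)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["concentration_mg_ml"], curve["viability_405_580"],
                label="405-580", marker="o")
        ax.plot(curve["concentration_mg_ml"], curve["viability_580_405"],
                label="580-405", marker="s")
        ax.set_xlabel("RB-M concentration (mg/mL)")
        ax.set_ylabel("predicted viability")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax

    # -- serialization --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "codec": {"means": list(self.codec.means), "sds": list(self.codec.sds)},
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
            "training_seed": self.training_seed,
            "epochs": self.epochs,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateResults":
        payload = json.loads(Path(path).read_text())
        codec = FeatureCodec(
            means=tuple(payload["codec"]["means"]),
            sds=tuple(payload["codec"]["sds"]),
        )
        return cls(
            model=None,
            codec=codec,
            hidden_weights=np.asarray(payload["hidden_weights"]),
            hidden_biases=np.asarray(payload["hidden_biases"]),
            output_weights=np.asarray(payload["output_weights"]),
            output_bias=payload["output_bias"],
            training_seed=payload["training_seed"],
            epochs=payload["epochs"],
        )
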