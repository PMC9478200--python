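"""Model-evaluation metric suite and report container.

The metrics mirror standard NIR calibration practice: RMSE (of
cross-validation or prediction), R² in percent, RPD (reference SD over
RMSEP), signed bias (prediction minus reference), and ARD (mean absolute
relative deviation in percent).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "rmse",
    "r2_percent",
    "rpd",
    "bias",
    "ard_percent",
    "EvaluationReport",
]


def _pair(y_ref, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_ref.size != y_pred.size or y_ref.size == 0:
        raise ValueError(
            f"length mismatch: {y_ref.size} reference vs {y_pred.size} predicted")
    return y_ref, y_pred


def rmse(y_ref, y_pred) -> float:
    """Root-mean-square error, sqrt(sum((yhat - y)^2)/n), in mg/g."""
    y_ref, y_pred = _pair(y_ref, y_pred)
    return float(np.sqrt(np.mean((y_pred - y_ref) ** 2)))


def r2_percent(y_ref, y_pred) -> float:
    """100 * (1 - SSE/SST) with SST about the mean of the reference values.

    Can be negative when predictions are worse than the mean.
    """
    y_ref, y_pred = _pair(y_ref, y_pred)
    sst = float(((y_ref - y_ref.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("reference values are constant; R^2 undefined")
    sse = float(((y_pred - y_ref) ** 2).sum())
    return 100.0 * (1.0 - sse / sst)


def rpd(reference_sd: float, rmsep: float) -> float:
    """Ratio of performance to deviation: reference-set SD / RMSEP.

    By the textbook definition the SD is that of the *calibration* set;
    pass the evaluated set's SD instead to use the other convention.
    """
    if reference_sd <= 0:
        raise ValueError("reference SD must be > 0")
    if rmsep <= 0:
        raise ValueError("RMSEP must be > 0")
    return float(reference_sd) / float(rmsep)


def bias(y_ref, y_pred) -> float:
    """Signed mean deviation, mean(yhat - y): positive = over-prediction."""
    y_ref, y_pred = _pair(y_ref, y_pred)
    return float(np.mean(y_pred - y_ref))


def ard_percent(y_ref, y_pred) -> float:
    """Average relative deviation, 100 * mean(|yhat - y| / y)."""
    y_ref, y_pred = _pair(y_ref, y_pred)
    if np.any(y_ref <= 0):
        raise ValueError("ARD needs strictly positive reference values")
    return float(100.0 * np.mean(np.abs(y_pred - y_ref) / y_ref))


@dataclass(frozen=True)
class EvaluationReport:
    """The metric bundle for one model on one dataset context."""

    model_id: str
    context: str          # "loocv" | "external" | "test"
    rmse: float
    r2: float             # percent
    rpd: float
    bias: float
    ard: float            # percent; nan when a reference value is <= 0
    rank: int | None = None
    hidden_nodes: int | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.rpd <= 0 or self.n < 1:
            raise ValueError("invalid report: rmse >= 0, rpd > 0, n >= 1 required")

    @classmethod
    def from_predictions(cls, model_id: str, context: str, y_ref, y_pred,
                         reference_sd: float, rank: int | None = None,
                         hidden_nodes: int | None = None) -> "EvaluationReport":
        y_ref = np.asarray(y_ref, dtype=float).ravel()
        err = rmse(y_ref, y_pred)
        return cls(
            model_id=model_id,
            context=context,
            rmse=err,
            r2=r2_percent(y_ref, y_pred),
            rpd=rpd(reference_sd, err),
            bias=bias(y_ref, y_pred),
            ard=ard_percent(y_ref, y_pred) if np.all(y_ref > 0) else float("nan"),
            rank=rank,
            hidden_nodes=hidden_nodes,
            n=int(y_ref.size),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "EvaluationReport":
        return cls(**data)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls.from_dict(json.loads(text))
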