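"""Evaluation measures for affinity regression.

Five measures: root mean squared error, mean absolute error, the standard
deviation of residuals about the least-squares line mapping predictions to
truth (SD), the concordance index (CI, pairwise ranking agreement with the
0.5 tie rule), and the Pearson correlation coefficient.  Plus a per-complex
top-1 tally for comparing several models on the same records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


def _check(y, y_hat):
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("y and y_hat must be equal-length nonempty 1-D arrays")
    return y, y_hat


def rmse(y, y_hat) -> float:
    """Root mean squared error."""
    y, y_hat = _check(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mae(y, y_hat) -> float:
    """Mean absolute error."""
    y, y_hat = _check(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def concordance_index(y, y_hat) -> float:
    """Fraction of pairs with y_i > y_j whose predictions agree in order.

    Tied predictions score 0.5; pairs tied in y contribute nothing to the
    normalizer.  Raises if all y are equal (no qualifying pair).
    """
    y, y_hat = _check(y, y_hat)
    diff_y = y[:, None] - y[None, :]
    diff_p = y_hat[:, None] - y_hat[None, :]
    qual = diff_y > 0
    z = int(qual.sum())
    if z == 0:
        raise ValueError("concordance index undefined: no pair with y_i > y_j")
    score = np.where(diff_p > 0, 1.0, np.where(diff_p == 0, 0.5, 0.0))
    return float(score[qual].sum() / z)


def pearson_r(y, y_hat) -> float:
    """Pearson correlation coefficient."""
    y, y_hat = _check(y, y_hat)
    yc = y - y.mean()
    pc = y_hat - y_hat.mean()
    denom = np.sqrt((yc**2).sum() * (pc**2).sum())
    if denom == 0:
        raise ValueError("pearson r undefined for constant input")
    return float((yc * pc).sum() / denom)


def sd_metric(y, y_hat) -> float:
    """Residual standard deviation about the least-squares line y ~ a*y_hat + b.

    Uses the N-1 denominator.  Raises for constant predictions (the
    regression slope is undefined).
    """
    y, y_hat = _check(y, y_hat)
    if y.size < 2:
        raise ValueError("sd metric requires at least 2 points")
    if np.ptp(y_hat) == 0:
        raise ValueError("sd metric undefined for constant predictions")
    a, b = np.polyfit(y_hat, y, 1)
    resid = y - (a * y_hat + b)
    return float(np.sqrt((resid**2).sum() / (y.size - 1)))


@dataclass
class MetricReport:
    """All five measures for one prediction set."""

    rmse: float
    mae: float
    sd: float
    ci: float
    r: float
    n: int

    @classmethod
    def from_predictions(cls, y, y_hat) -> "MetricReport":
        y, y_hat = _check(y, y_hat)
        return cls(rmse=rmse(y, y_hat), mae=mae(y, y_hat),
                   sd=sd_metric(y, y_hat), ci=concordance_index(y, y_hat),
                   r=pearson_r(y, y_hat), n=int(y.size))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def to_table(self) -> str:
        rows = [("RMSE", self.rmse), ("MAE", self.mae), ("SD", self.sd),
                ("CI", self.ci), ("R", self.r)]
        width = max(len(k) for k, _ in rows)
        lines = [f"{k:<{width}}  {v:8.4f}" for k, v in rows]
        lines.append(f"{'n':<{width}}  {self.n:8d}")
        return "\n".join(lines)


def top1_tally(per_model_predictions: dict, y) -> dict:
    """Count, per model, the records where it is closest to the truth.

    Ties go to the first-listed model; tied records are reported under the
    ``"_ties"`` key.  Counts sum to ``len(y)``.
    """
    y = np.asarray(y, dtype=np.float64)
    names = list(per_model_predictions)
    preds = np.vstack([np.asarray(per_model_predictions[m], dtype=np.float64)
                       for m in names])
    if preds.shape[1] != y.size:
        raise ValueError("prediction lengths must match y")
    err = np.abs(preds - y[None, :])
    winners = err.argmin(axis=0)  # first-listed wins ties
    tally = {m: int((winners == i).sum()) for i, m in enumerate(names)}
    n_tied = int((np.sum(err == err.min(axis=0, keepdims=True), axis=0) > 1).sum())
    tally["_ties"] = n_tied
    return tally
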