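"""Regression evaluation: concordance index, MSE, Pearson correlation.

The concordance index (CI) scores how well predictions preserve the
ordering of true affinities:

    CI = (1/Z) * sum over pairs with y_i > y_j of h(p_i - p_j),

with h(m) = 1 for m > 0, 0.5 for m = 0, 0 for m < 0, and Z the number of
strictly ordered truth pairs (ties in the truths are excluded from Z).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd


def _pair(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=np.float64).ravel()
    pred = np.asarray(pred, dtype=np.float64).ravel()
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: truth {truth.size} vs pred {pred.size}")
    return truth, pred


def concordance_index(truth, pred) -> float:
    """Fraction of strictly ordered truth pairs ranked correctly (ties = 0.5)."""
    truth, pred = _pair(truth, pred)
    if truth.size < 2:
        raise ValueError("concordance index needs at least 2 points")
    order_mask = truth[:, None] > truth[None, :]
    z = int(order_mask.sum())
    if z == 0:
        raise ValueError("all truths tied: concordance index undefined (Z = 0)")
    pred_diff = pred[:, None] - pred[None, :]
    h = np.where(pred_diff > 0, 1.0, np.where(pred_diff == 0, 0.5, 0.0))
    return float(h[order_mask].sum() / z)


def mean_squared_error(truth, pred) -> float:
    truth, pred = _pair(truth, pred)
    if truth.size < 1:
        raise ValueError("mean squared error needs at least 1 point")
    return float(np.mean((truth - pred) ** 2))


def pearson(truth, pred) -> float:
    """Pearson correlation cov(p, y) / (sigma(p) * sigma(y))."""
    truth, pred = _pair(truth, pred)
    if truth.size < 2:
        raise ValueError("pearson correlation needs at least 2 points")
    ty = truth - truth.mean()
    py = pred - pred.mean()
    denom = np.sqrt((ty**2).mean() * (py**2).mean())
    if denom == 0:
        raise ValueError("pearson correlation undefined for a constant vector")
    return float((ty * py).mean() / denom)


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    ci: float
    pearson: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def format_table(self) -> str:
        return (
            f"{'metric':<10}{'value':>10}\n"
            f"{'MSE':<10}{self.mse:>10.4f}\n"
            f"{'CI':<10}{self.ci:>10.4f}\n"
            f"{'Pearson':<10}{self.pearson:>10.4f}\n"
            f"{'n':<10}{self.n:>10d}"
        )


def evaluate(truth, pred) -> MetricsReport:
    """Bundle MSE, CI and Pearson correlation for one prediction vector."""
    truth, pred = _pair(truth, pred)
    return MetricsReport(
        mse=mean_squared_error(truth, pred),
        ci=concordance_index(truth, pred),
        pearson=pearson(truth, pred),
        n=int(truth.size),
    )
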