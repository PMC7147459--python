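"""Descriptive statistics and random-forest variable importance for encodings.

``feature_stats`` summarizes an encoded (proteins x features) matrix with
columnwise means, variances and quartiles plus a fixed-width histogram of
all values.  ``compute_vim`` fits a seeded random-forest regressor and
reports per-feature variable-importance-measure (VIM) scores, normalized to
sum to 1, labelled with peptide strings; ``rank_features`` filters the
ranking at a contribution threshold (default 0.5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .alphabet import DEFAULT_ALPHABET, PeptideAlphabet

HIST_BIN_WIDTH = 0.025  # matches the score-interval granularity discussed for WF dipeptides


@dataclass(frozen=True)
class FeatureStats:
    means: np.ndarray
    variances: np.ndarray  # population convention
    q1: np.ndarray
    q3: np.ndarray
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    n_rows: int


def feature_stats(matrix, *, bin_width: float = HIST_BIN_WIDTH) -> FeatureStats:
    """Columnwise mean/variance/quartiles and a value histogram.

    Histogram bins are fixed-width starting at 0 and extended to cover the
    data, so counts always conserve the total number of cells.
    """
    values = np.asarray(matrix, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] < 1:
        raise ValueError("need a 2-D matrix with at least one row")
    n_bins = max(1, int(np.ceil((values.max() + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values.ravel(), bins=edges)
    return FeatureStats(
        means=values.mean(axis=0),
        variances=values.var(axis=0),
        q1=np.quantile(values, 0.25, axis=0),
        q3=np.quantile(values, 0.75, axis=0),
        hist_edges=edges,
        hist_counts=counts,
        n_rows=values.shape[0],
    )


@dataclass(frozen=True)
class VIMReport:
    """Per-feature importance scores, normalized to sum to 1."""

    importance: np.ndarray
    labels: tuple[str, ...]
    n_trees: int
    seed: int
    importance_kind: str = "impurity"
    rf_params: dict = field(default_factory=dict)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.importance))

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.importance, kind="stable")
        return pd.DataFrame(
            {
                "label": [self.labels[i] for i in order],
                "importance": self.importance[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_vim(
    features,
    affinities,
    n_trees: int = 10_000,
    seed: int = 0,
    *,
    labels: tuple[str, ...] | None = None,
    alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
    importance_kind: str = "impurity",
) -> VIMReport:
    """Random-forest variable importance of encoded features for affinities.

    Importance is the forest's mean impurity decrease by default
    (``importance_kind="permutation"`` uses permutation importance with
    negative values clipped to zero); scores are normalized to sum to 1.
    Feature labels default to peptide strings when the width is 25**n.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(affinities, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be 2-D with one row per affinity")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if np.all(y == y[0]):
        raise ValueError("affinities are constant: importance undefined")
    if labels is None:
        for n in (1, 2, 3):
            if X.shape[1] == 25**n:
                labels = tuple(alphabet.peptide_labels(n))
                break
        else:
            labels = tuple(f"f{i}" for i in range(X.shape[1]))
    if len(labels) != X.shape[1]:
        raise ValueError("label count must match feature count")

    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    if importance_kind == "impurity":
        raw = rf.feature_importances_
    elif importance_kind == "permutation":
        perm = permutation_importance(rf, X, y, n_repeats=5, random_state=seed, n_jobs=1)
        raw = np.clip(perm.importances_mean, 0.0, None)
    else:
        raise ValueError(f"unknown importance_kind {importance_kind!r}")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all importances are zero; nothing to normalize")
    return VIMReport(
        importance=raw / total,
        labels=labels,
        n_trees=n_trees,
        seed=seed,
        importance_kind=importance_kind,
        rf_params=rf.get_params(),
    )


def rank_features(report: VIMReport, threshold: float = 0.005) -> list[tuple[str, float]]:
    """Features with importance above ``threshold``, descending."""
    order = np.argsort(-report.importance, kind="stable")
    return [
        (report.labels[i], float(report.importance[i]))
        for i in order
        if report.importance[i] > threshold
    ]


def vim_grid(report: VIMReport, alphabet: PeptideAlphabet = DEFAULT_ALPHABET) -> pd.DataFrame:
    """Dipeptide importances laid out as a 25 x 25 grid (first x second residue)."""
    if len(report.labels) != 625:
        raise ValueError("grid layout is defined for dipeptide (625-feature) reports")
    letters = list(alphabet.letters)
    grid = report.importance.reshape(25, 25)
    return pd.DataFrame(grid, index=letters, columns=letters)
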