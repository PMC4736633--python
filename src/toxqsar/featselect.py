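"""Chi-squared / Cramér's V filter feature selection.

Each feature is cross-tabulated against the (binned) activity target;
the chi-squared statistic

    chi2 = sum_ij (O_ij - E_ij)^2 / E_ij,   E_ij = row_i * col_j / n

is transformed to Cramér's V = sqrt((chi2/n) / min(r-1, c-1)), a
[0, 1]-scaled association measure that is comparable across features
with different numbers of levels.  Features are ranked by V (descending,
ties broken lexicographically by name) and the top k are selected.

This is a ranking heuristic, not inference: no p-values are attached,
and small expected counts only trigger a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from toxqsar.chemfeat import FeatureTable

__all__ = [
    "discretize",
    "contingency_table",
    "chi2_stat",
    "cramers_v",
    "feature_association",
    "rank_and_select",
    "FeatureRanking",
]


def discretize(values, n_bins: int, strategy: str = "equal_frequency") -> np.ndarray:
    """Bin a numeric vector into integer labels 0..(bins-1).

    ``equal_frequency`` bins by quantiles (sizes differ by <= 1 before
    tie handling; duplicate quantile edges collapse bins), ``equal_width``
    by a uniform grid over the observed range.  A constant vector yields
    a single bin with a warning.
    """
    values = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if values.ndim != 1 or values.size < n_bins:
        raise ValueError("need a 1-D vector with length >= n_bins")
    if np.ptp(values) == 0:
        warnings.warn("constant vector: single bin", stacklevel=2)
        return np.zeros(values.size, dtype=int)
    if strategy == "equal_frequency":
        # rank-based assignment keeps bin sizes within one of each other;
        # exact ties share the bin of their first occurrence.
        order = np.argsort(values, kind="stable")
        raw = np.empty(values.size, dtype=int)
        raw[order] = (np.arange(values.size) * n_bins) // values.size
        # ties must not straddle a bin boundary: align to first occurrence
        first_label: dict[float, int] = {}
        for idx in order:
            v = values[idx]
            if v not in first_label:
                first_label[v] = raw[idx]
            raw[idx] = first_label[v]
        labels = raw
    elif strategy == "equal_width":
        edges = np.linspace(values.min(), values.max(), n_bins + 1)
        labels = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    # drop empty bins so labels are contiguous
    uniq = np.unique(labels)
    remap = {u: i for i, u in enumerate(uniq)}
    return np.array([remap[v] for v in labels], dtype=int)


def contingency_table(feature_labels, target_labels) -> np.ndarray:
    """Observed-count table O_ij (feature bins x target classes)."""
    f = np.asarray(feature_labels, dtype=int)
    t = np.asarray(target_labels, dtype=int)
    if f.shape != t.shape:
        raise ValueError("label vectors must align")
    table = np.zeros((f.max() + 1, t.max() + 1), dtype=np.int64)
    np.add.at(table, (f, t), 1)
    # all-zero marginals are impossible by construction of the labels
    return table


def chi2_stat(table) -> float:
    """Pearson chi-squared statistic of a contingency table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(row, col) / n
    if (expected < 5).any():
        warnings.warn("expected cell count < 5; chi2 is a ranking heuristic here",
                      stacklevel=2)
    return float(((obs - expected) ** 2 / expected).sum())


def cramers_v(chi2: float, n: int, r: int, c: int) -> float:
    """Cramér's V = sqrt((chi2/n) / min(r-1, c-1)), in [0, 1]."""
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    if r < 2 or c < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    v = float(np.sqrt((chi2 / n) / min(r - 1, c - 1)))
    return min(v, 1.0)


def feature_association(
    feature, target_labels, feature_bins: int = 10, is_binary: bool | None = None
) -> tuple[float, float]:
    """(chi2, V) between one feature and pre-binned target labels.

    Binary {0,1} fingerprint columns use their native two levels;
    continuous features are discretized into equal-frequency bins first.
    A feature that is constant carries no association: (0, 0).
    """
    x = np.asarray(feature, dtype=float)
    t = np.asarray(target_labels, dtype=int)
    uniq = np.unique(x)
    if is_binary is None:
        is_binary = uniq.size <= 2 and set(uniq) <= {0.0, 1.0}
    if uniq.size < 2:
        return 0.0, 0.0
    if is_binary or uniq.size <= feature_bins:
        remap = {u: i for i, u in enumerate(uniq)}
        labels = np.array([remap[v] for v in x], dtype=int)
    else:
        labels = discretize(x, feature_bins)
    if labels.max() == 0 or t.max() == 0:
        return 0.0, 0.0
    table = contingency_table(labels, t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        chi2 = chi2_stat(table)
    v = cramers_v(chi2, int(table.sum()), table.shape[0], table.shape[1])
    return chi2, v


@dataclass
class FeatureRanking:
    """Per-feature chi2/V scores with ranks and the selected flag."""

    table: pd.DataFrame  # columns: feature, chi2, V, rank, selected

    def selected_features(self) -> list[str]:
        sel = self.table[self.table["selected"]]
        return list(sel["feature"])


def rank_and_select(
    table: FeatureTable,
    target,
    k: int,
    target_bins: int = 5,
    feature_bins: int = 10,
) -> FeatureRanking:
    """Rank all features by Cramér's V against the binned target; select top k.

    The continuous target is discretized into ``target_bins``
    equal-frequency classes; ties in V break lexicographically on the
    feature name so the selection is deterministic.
    """
    features = table.columns
    if k > len(features):
        raise ValueError(f"k={k} exceeds feature count {len(features)}")
    y = np.asarray(target, dtype=float)
    if y.size != len(table.data):
        raise ValueError("target length must match the feature table")
    t_labels = discretize(y, target_bins)
    rows = []
    for name in features:
        is_bin = table.provenance.get(name) == "fingerprint"
        chi2, v = feature_association(
            table.data[name].to_numpy(), t_labels, feature_bins, is_binary=is_bin or None
        )
        rows.append((name, chi2, v))
    df = pd.DataFrame(rows, columns=["feature", "chi2", "V"])
    df = df.sort_values(["V", "feature"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    df["selected"] = df["rank"] <= k
    return FeatureRanking(df.reset_index(drop=True))
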