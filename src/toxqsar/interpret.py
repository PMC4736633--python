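"""Model interpretation: descriptor importance, fragment alerts, scaffolds.

Four complementary views of a fitted model and its data:

* one-dimensional sensitivity — vary one feature over its observed
  range with all others at their medians; the variance of the model
  response, normalized across features, is the importance score;
* fragment contribution — for each fingerprint bit, count molecules
  carrying the fragment above/below an activity threshold (default
  pLD50 = 3); a strict majority above marks a positive alert, below a
  negative one, a tie is flagged undetermined;
* stepwise adjusted-R2 gain of adding one fragment column to an OLS
  base model;
* Murcko-scaffold tabulation of molecules with large prediction errors,
  reporting scaffolds occurring at least twice together with their
  training/test-set abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from toxqsar.chemfeat import FeatureTable, MoleculeSet, murcko_framework
from toxqsar.metrics import r2_adj
from toxqsar.pipeline import DatasetSplit

__all__ = [
    "sensitivity_1d",
    "FragmentAlert",
    "fragment_contribution",
    "stepwise_r2adj_delta",
    "error_scaffold_table",
]


def sensitivity_1d(model, data: FeatureTable | pd.DataFrame, features=None,
                   levels: int = 7) -> pd.Series:
    """Normalized one-dimensional sensitivity importance per feature.

    Each feature in turn is swept over an equally spaced grid of
    ``levels`` values spanning its observed range while every other
    feature is held at its median; the variance of the model responses
    is the raw score.  Scores are normalized to sum to 1 (constant
    features score 0).  The result is invariant to affine rescaling of
    the model response.
    """
    if levels < 3:
        raise ValueError("levels must be >= 3")
    df = data.data if isinstance(data, FeatureTable) else data
    features = list(features) if features is not None else list(df.columns)
    base = df.median(axis=0)
    raw = {}
    for name in features:
        lo, hi = float(df[name].min()), float(df[name].max())
        if lo == hi:
            raw[name] = 0.0
            continue
        grid = pd.DataFrame([base] * levels)
        grid[name] = np.linspace(lo, hi, levels)
        resp = np.asarray(model.predict(grid[df.columns]), dtype=float)
        raw[name] = float(np.var(resp))
    scores = pd.Series(raw, dtype=float)
    total = scores.sum()
    return scores / total if total > 0 else scores


@dataclass
class FragmentAlert:
    """One fingerprint bit's association with high/low activity."""

    feature: str
    count_high: int  # molecules with the fragment and activity >= threshold
    count_low: int
    sign: str  # positive | negative | undetermined
    n_present: int
    threshold: float
    cramers_v: float | None = None
    delta_r2_adj: float | None = None

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "count_high": self.count_high,
            "count_low": self.count_low,
            "sign": self.sign,
            "n_present": self.n_present,
            "threshold": self.threshold,
            "cramers_v": self.cramers_v,
            "delta_r2_adj": self.delta_r2_adj,
        }


def fragment_contribution(bits, activity, threshold: float = 3.0,
                          feature: str = "fragment") -> FragmentAlert | None:
    """Sign a fragment by the strict-majority activity rule.

    Counts are over molecules where the bit is 1; sign is positive iff
    strictly more of them sit at or above the threshold than below, and
    vice versa; an exact tie is flagged undetermined.  A fragment absent
    from every molecule is suppressed (returns None, with a warning).
    """
    b = np.asarray(bits)
    if not set(np.unique(b)) <= {0, 1}:
        raise ValueError("bits must be binary")
    y = np.asarray(activity, dtype=float)
    if b.shape != y.shape:
        raise ValueError("bits and activity must align")
    present = b == 1
    n_present = int(present.sum())
    if n_present == 0:
        warnings.warn(f"fragment {feature!r} present in no molecule; alert suppressed",
                      stacklevel=2)
        return None
    count_high = int(np.sum(y[present] >= threshold))
    count_low = n_present - count_high
    if count_high > count_low:
        sign = "positive"
    elif count_low > count_high:
        sign = "negative"
    else:
        sign = "undetermined"
    return FragmentAlert(feature, count_high, count_low, sign, n_present, threshold)


def _ols_r2adj(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """(adjusted R2, rank of the design) for intercept + X."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    yhat = design @ coef
    p = X.shape[1]
    return r2_adj(y, yhat, p), int(rank)


def stepwise_r2adj_delta(base_features, candidate, activity) -> tuple[float, bool]:
    """Adjusted-R2 gain from adding one candidate column to an OLS base.

    Returns (delta, collinear) where ``collinear`` is True when the
    augmented design is rank deficient (the delta is still reported).
    """
    Xb = base_features.data if isinstance(base_features, FeatureTable) else base_features
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    c = np.asarray(candidate, dtype=float).reshape(-1, 1)
    y = np.asarray(activity, dtype=float).ravel()
    if Xb.shape[0] != y.size or c.shape[0] != y.size:
        raise ValueError("shapes must align")
    if y.size <= Xb.shape[1] + 2:
        raise ValueError("need n > p + 2 for the augmented fit")
    r2a_base, _ = _ols_r2adj(Xb, y)
    r2a_full, rank = _ols_r2adj(np.hstack([Xb, c]), y)
    collinear = rank < Xb.shape[1] + 2  # intercept + base + candidate
    return r2a_full - r2a_base, collinear


def error_scaffold_table(mols: MoleculeSet, abs_errors, split: DatasetSplit | None = None,
                         mae_threshold: float = 1.0) -> pd.DataFrame:
    """Murcko-framework frequency table for poorly predicted molecules.

    Molecules whose absolute prediction error exceeds ``mae_threshold``
    are selected; their frameworks are tabulated and only scaffolds with
    frequency >= 2 are reported, sorted by frequency descending (ties by
    scaffold SMILES).  Columns: scaffold, frequency, n_train, n_test,
    mean_abs_error.
    """
    err = np.asarray(abs_errors, dtype=float)
    if err.size != len(mols):
        raise ValueError("errors must align with molecules")
    frameworks = [murcko_framework(m) for m in mols.mols]
    ids = mols.ids()
    train_ids = set(split.train_ids) if split is not None else set()
    test_ids = set(split.test_ids) if split is not None else set()

    selected = err > mae_threshold
    rows: dict[str, dict] = {}
    for i, sel in enumerate(selected):
        if not sel:
            continue
        scaf = frameworks[i]
        entry = rows.setdefault(scaf, {"frequency": 0, "errors": []})
        entry["frequency"] += 1
        entry["errors"].append(err[i])

    out = []
    for scaf, entry in rows.items():
        if entry["frequency"] < 2:
            continue
        n_train = sum(1 for i, f in enumerate(frameworks) if f == scaf and ids[i] in train_ids)
        n_test = sum(1 for i, f in enumerate(frameworks) if f == scaf and ids[i] in test_ids)
        out.append(
            {
                "scaffold": scaf,
                "frequency": entry["frequency"],
                "n_train": n_train,
                "n_test": n_test,
                "mean_abs_error": float(np.mean(entry["errors"])),
            }
        )
    df = pd.DataFrame(out, columns=["scaffold", "frequency", "n_train", "n_test", "mean_abs_error"])
    if len(df):
        df = df.sort_values(["frequency", "scaffold"], ascending=[False, True]).reset_index(drop=True)
    return df
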