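"""QSAR validation statistics.

Adjusted R-squared, cross-validated q2 from PRESS, external-test q2,
MAE/RMSE, the 0.3 over-fit rule and the paired Wilcoxon comparison of
absolute errors.

Conventions: R2 = 1 - SSE/SST (coefficient of determination),
R2adj = 1 - (1 - R2)(n - 1)/(n - p - 1) with p the number of model
parameters — taken, for kernel/forest learners, as the number of
selected features.  q2 = (SST - PRESS)/SST with PRESS accumulated from
out-of-fold predictions over decile-stratified folds.  Acceptability
thresholds q2 >= 0.5 and q2ext >= 0.5 are reported as flags; a model is
flagged over-fitted when R2adj - q2ext > 0.3.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from toxqsar.learners import LearnerSpec, fit_learner

__all__ = [
    "r2_score",
    "r2_adj",
    "q2_from_press",
    "q2_cv",
    "q2_ext",
    "mae",
    "rmse",
    "wilcoxon_compare",
    "MetricsReport",
    "evaluate_predictions",
    "OVERFIT_GAP",
    "ACCEPTABILITY_THRESHOLD",
]

OVERFIT_GAP = 0.3
ACCEPTABILITY_THRESHOLD = 0.5


def _check(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("need equal-length non-empty vectors")
    return y, yhat


def r2_score(y, yhat) -> float:
    """Coefficient of determination 1 - SSE/SST."""
    y, yhat = _check(y, yhat)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero-variance reference values (SST = 0)")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def r2_adj(y, yhat, p: int) -> float:
    """Adjusted R2 penalizing the parameter count p."""
    y, yhat = _check(y, yhat)
    n = y.size
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    r2 = r2_score(y, yhat)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def q2_from_press(sst: float, press: float) -> float:
    """q2 = (SST - PRESS)/SST."""
    if sst <= 0:
        raise ValueError("SST must be positive")
    return (sst - press) / sst


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold labels stratified by target order (decile-style)."""
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    labels = np.empty(y.size, dtype=int)
    for start in range(0, y.size, folds):
        chunk = order[start:start + folds]
        fl = rng.permutation(folds)[: chunk.size]
        labels[chunk] = fl
    return labels


def q2_cv(X, y, spec: LearnerSpec, folds: int = 10, seed: int = 0) -> float:
    """Cross-validated q2 from out-of-fold PRESS.

    Folds are stratified along the sorted target so each fold sees the
    full activity range; the partition is a pure function of the seed.
    """
    y = np.asarray(y, dtype=float).ravel()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if y.size < folds:
        raise ValueError("need at least one molecule per fold")
    import pandas as pd

    is_frame = isinstance(X, pd.DataFrame)
    Xa = X if is_frame else np.atleast_2d(np.asarray(X, dtype=float))
    labels = _stratified_folds(y, folds, seed)
    press = 0.0
    for f in range(folds):
        test_mask = labels == f
        if not test_mask.any():
            continue
        Xtr = Xa.loc[~test_mask] if is_frame else Xa[~test_mask]
        Xte = Xa.loc[test_mask] if is_frame else Xa[test_mask]
        reg = fit_learner(spec, Xtr, y[~test_mask], seed=seed)
        press += float(np.sum((y[test_mask] - reg.predict(Xte)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return q2_from_press(sst, press)


def q2_ext(y_test, yhat_test) -> float:
    """Conventional determination coefficient on an external test set."""
    return r2_score(y_test, yhat_test)


def mae(y, yhat) -> float:
    y, yhat = _check(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    y, yhat = _check(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def wilcoxon_compare(abs_err_a, abs_err_b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value on absolute errors.

    Zero differences are dropped; the null distribution is exact for
    n <= 25 and a continuity-corrected normal approximation above.
    All differences zero returns p = 1 with a warning.
    """
    a, b = _check(abs_err_a, abs_err_b)
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    if nz.size < 6:
        raise ValueError("need >= 6 non-zero paired differences")
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method, correction=True)
    return float(min(res.pvalue, 1.0))


@dataclass
class MetricsReport:
    """One model's training/test statistics and quality flags."""

    n_train: int
    n_test: int
    p: int
    r2: float
    r2_adj: float
    q2: float | None
    q2_ext: float
    rmse_train: float
    mae_train: float
    rmse_test: float
    mae_test: float
    sse: float
    sst: float
    press: float | None
    overfit: bool
    q2_acceptable: bool | None
    q2_ext_acceptable: bool

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_predictions(
    y_train, yhat_train, y_test, yhat_test, p: int, q2: float | None = None,
    press: float | None = None,
) -> MetricsReport:
    """Assemble the standard report from train/test predictions."""
    y_train, yhat_train = _check(y_train, yhat_train)
    y_test, yhat_test = _check(y_test, yhat_test)
    r2 = r2_score(y_train, yhat_train)
    radj = r2_adj(y_train, yhat_train, p)
    q2e = q2_ext(y_test, yhat_test)
    return MetricsReport(
        n_train=y_train.size,
        n_test=y_test.size,
        p=p,
        r2=r2,
        r2_adj=radj,
        q2=q2,
        q2_ext=q2e,
        rmse_train=rmse(y_train, yhat_train),
        mae_train=mae(y_train, yhat_train),
        rmse_test=rmse(y_test, yhat_test),
        mae_test=mae(y_test, yhat_test),
        sse=float(np.sum((y_train - yhat_train) ** 2)),
        sst=float(np.sum((y_train - y_train.mean()) ** 2)),
        press=press,
        overfit=(radj - q2e) > OVERFIT_GAP,
        q2_acceptable=None if q2 is None else q2 >= ACCEPTABILITY_THRESHOLD,
        q2_ext_acceptable=q2e >= ACCEPTABILITY_THRESHOLD,
    )
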