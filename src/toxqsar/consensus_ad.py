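"""Consensus averaging and STD-DM applicability domain.

Consensus prediction is the unweighted arithmetic mean of the
per-model predictions (all members contribute equally).  The
applicability domain (AD) is estimated from ensemble disagreement:
STD-DM(J) is the sample standard deviation of the member predictions
for molecule J; a molecule is in-domain when its STD-DM does not exceed
``multiplier`` (default 3) times a calibration constant, taken here as
the mean STD-DM of the training set.  The fraction of test molecules
in-domain is the data-set coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["consensus_predict", "std_dm", "ad_assess", "ADReport"]


def _as_frame(preds) -> pd.DataFrame:
    if isinstance(preds, pd.DataFrame):
        return preds
    return pd.DataFrame(np.atleast_2d(np.asarray(preds, dtype=float)))


def consensus_predict(preds, exclude: Sequence[str] = ()) -> pd.Series:
    """Unweighted mean across model columns, after exclusions.

    Raises if fewer than two models remain (a single model is not a
    consensus) or if any prediction is missing.
    """
    frame = _as_frame(preds)
    unknown = [m for m in exclude if m not in frame.columns]
    if unknown:
        raise KeyError(f"cannot exclude unknown models {unknown}")
    kept = frame.drop(columns=list(exclude))
    if kept.shape[1] < 2:
        raise ValueError("consensus needs at least 2 models after exclusion")
    if kept.isna().any().any():
        raise ValueError("missing predictions in consensus input")
    return kept.mean(axis=1)


def std_dm(preds) -> pd.Series:
    """Per-molecule sample standard deviation (M-1 divisor) across models."""
    frame = _as_frame(preds)
    if frame.shape[1] < 2:
        raise ValueError("STD-DM needs at least 2 model columns")
    if frame.isna().any().any():
        raise ValueError("missing predictions in STD-DM input")
    return frame.std(axis=1, ddof=1)


@dataclass
class ADReport:
    """Applicability-domain assessment of a test set."""

    std_dm: pd.Series
    in_domain: pd.Series
    coverage: float  # percent of test molecules in-domain
    calibration: float  # reference STD-DM level (mean over the training set)
    multiplier: float

    @property
    def threshold(self) -> float:
        return self.multiplier * self.calibration


def ad_assess(train_std, test_std, multiplier: float = 3.0) -> ADReport:
    """Flag test molecules against the training-calibrated STD-DM margin.

    Molecule J is in-domain iff STD-DM(J) <= multiplier * mean(training
    STD-DM); coverage is reported in percent.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    train = pd.Series(train_std, dtype=float)
    test = pd.Series(test_std, dtype=float)
    if train.empty:
        raise ValueError("training STD-DM vector is empty")
    calibration = float(train.mean())
    in_domain = test <= multiplier * calibration
    coverage = 100.0 * float(in_domain.sum()) / len(test) if len(test) else 0.0
    return ADReport(test, in_domain, coverage, calibration, float(multiplier))
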