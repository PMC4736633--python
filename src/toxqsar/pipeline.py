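"""Dataset assembly and workflow orchestration.

Covers the plumbing around the modelling core: zero-variance and
correlation filtering of feature tables, activity-stratified train/test
splitting, deterministic per-stage seed derivation, a flat-text
workflow configuration, and ``run_workflow`` — the end-to-end driver
(featurize -> filter -> select -> split -> train -> consensus ->
metrics -> applicability domain -> interpretation) producing a JSON-able
report bundle.

Determinism rules: the correlation filter scans columns in descending
variance order (names break ties) and removes the later, lower-variance
member of an offending pair; all stage randomness is derived from the
single config seed through a splitmix64-style hash, so identical
(config, data) reruns are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from toxqsar import consensus_ad, featselect, metrics
from toxqsar.chemfeat import (
    FeatureTable,
    MoleculeRecord,
    MoleculeSet,
    DEFAULT_2D_DESCRIPTORS,
    bundled_dictionary,
    descriptor_table,
    fingerprint_table,
    load_dictionary,
    parse_and_clean,
    read_molecule_csv,
)
from toxqsar.learners import LearnerSpec, default_spec, fit_learner

__all__ = [
    "filter_features",
    "split_dataset",
    "DatasetSplit",
    "WorkflowConfig",
    "WorkflowError",
    "ReportBundle",
    "run_workflow",
    "derive_seed",
]


# ---------------------------------------------------------------------------
# Seed derivation: one master seed -> one independent stream per stage.


def _splitmix64(z: int) -> int:
    z = (z + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return z ^ (z >> 31)


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 (splitmix64 on a stage hash)."""
    h = 1469598103934665603  # FNV-1a over the stage name
    for byte in stage.encode():
        h = ((h ^ byte) * 1099511628211) & 0xFFFFFFFFFFFFFFFF
    return _splitmix64(master ^ h) % (2**31)


# ---------------------------------------------------------------------------
# Feature filtering


def filter_features(
    table: FeatureTable, corr_threshold: float = 0.95
) -> tuple[FeatureTable, list[dict]]:
    """Drop constant columns, then greedily break |r| > threshold pairs.

    Columns are scanned in descending variance order (ties by name); a
    column correlated above the threshold with any already-kept column is
    removed, so the higher-variance member of each redundant pair
    survives.  The result is invariant to input column order.
    """
    df = table.data
    if df.shape[1] < 1:
        raise ValueError("feature table has no columns")
    removal_log: list[dict] = []
    variances = df.var(axis=0, ddof=0)
    constant = [
        c for c in df.columns
        if df[c].nunique(dropna=False) <= 1 or df[c].isna().any()
    ]
    for c in constant:
        removal_log.append({"feature": c, "reason": "zero_variance", "detail": ""})
    candidates = sorted(
        (c for c in df.columns if c not in constant),
        key=lambda c: (-variances[c], c),
    )
    if not candidates:
        raise ValueError("all features removed (every column constant)")

    values = df[candidates].to_numpy(dtype=float)
    std = values.std(axis=0, ddof=0)
    z = (values - values.mean(axis=0)) / std
    n = values.shape[0]
    kept_cols: list[int] = []
    for j in range(len(candidates)):
        if kept_cols:
            r = np.abs(z[:, kept_cols].T @ z[:, j]) / n
            hit = np.argmax(r)
            if r[hit] > corr_threshold:
                removal_log.append(
                    {
                        "feature": candidates[j],
                        "reason": "correlated",
                        "detail": f"|r|={r[hit]:.4f} with {candidates[kept_cols[hit]]}",
                    }
                )
                continue
        kept_cols.append(j)
    kept_names = [c for c in table.columns if c in {candidates[j] for j in kept_cols}]
    return table.subset(kept_names), removal_log


# ---------------------------------------------------------------------------
# Stratified splitting


@dataclass(frozen=True)
class DatasetSplit:
    """A train/test partition of molecule ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    test_fraction: float
    n_bins: int


def split_dataset(
    ids: Sequence[str],
    activities,
    test_fraction: float = 0.325,
    n_bins: int = 10,
    seed: int = 0,
) -> DatasetSplit:
    """Activity-stratified random split.

    The activity is cut into ``n_bins`` equal-frequency bins; within each
    bin, round(test_fraction * bin size) molecules are sampled without
    replacement into the test set.  Identical seeds give identical
    splits.  Bins that would end up with fewer than 2 molecules are
    merged into their lower neighbour with a warning.
    """
    ids = list(ids)
    y = np.asarray(activities, dtype=float)
    if len(ids) != y.size:
        raise ValueError("ids and activities must align")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if len(ids) < 2 * n_bins:
        raise ValueError("need at least 2 molecules per bin")

    order = np.argsort(y, kind="stable")
    raw_bins = [list(chunk) for chunk in np.array_split(order, n_bins)]
    bins: list[list[int]] = []
    for b in raw_bins:
        if len(b) < 2 and bins:
            warnings.warn("bin with < 2 molecules merged with neighbour", stacklevel=2)
            bins[-1].extend(b)
        else:
            bins.append(b)

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for b in bins:
        n_test = int(np.floor(test_fraction * len(b) + 0.5))
        n_test = min(max(n_test, 0), len(b) - 1)
        chosen = rng.choice(len(b), size=n_test, replace=False)
        test_idx.extend(b[i] for i in chosen)
    test_set = set(test_idx)
    train_ids = tuple(ids[i] for i in range(len(ids)) if i not in test_set)
    test_ids = tuple(ids[i] for i in sorted(test_set))
    return DatasetSplit(train_ids, test_ids, seed, test_fraction, n_bins)


# ---------------------------------------------------------------------------
# Workflow configuration


@dataclass
class WorkflowConfig:
    """Everything a run needs; serializes to a flat key=value text file."""

    descriptor_set: tuple[str, ...] = DEFAULT_2D_DESCRIPTORS
    fingerprint_dict: str = "subfp"  # subfp | pubchem | path | none
    corr_threshold: float = 0.95
    k_features: int = 120
    target_bins: int = 5
    feature_bins: int = 10
    test_fraction: float = 0.325
    split_bins: int = 10
    learners: tuple[str, ...] = ("knn", "rf", "svm", "gbm", "rvm")
    learner_overrides: dict = field(default_factory=dict)
    consensus_exclude: tuple[str, ...] = ()
    ad_multiplier: float = 3.0
    activity_min: float = 0.0
    activity_max: float = 7.0
    alert_threshold: float = 3.0
    error_mae_threshold: float = 1.0
    cv_folds: int = 10  # 0 disables cross-validation
    seed: int = 0

    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, (tuple, list)):
                value = ",".join(str(v) for v in value)
            elif isinstance(value, dict):
                value = json.dumps(value, sort_keys=True)
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "WorkflowConfig":
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key in ("descriptor_set", "learners", "consensus_exclude"):
                kwargs[key] = tuple(v for v in raw.split(",") if v)
            elif key == "learner_overrides":
                kwargs[key] = json.loads(raw) if raw else {}
            elif key in ("k_features", "target_bins", "feature_bins", "split_bins",
                         "cv_folds", "seed"):
                kwargs[key] = int(raw)
            elif key == "fingerprint_dict":
                kwargs[key] = raw
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


class WorkflowError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"workflow stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    """The workflow's outputs: a JSON-able report plus raw predictions."""

    report: dict
    predictions: pd.DataFrame

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.report, indent=2))
        self.predictions.to_csv(outdir / "predictions.csv", index_label="id")


def _load_fp_dictionary(name: str):
    if name in ("", "none"):
        return None
    if name in ("subfp", "pubchem"):
        return bundled_dictionary(name)
    return load_dictionary(name)


def run_workflow(config: WorkflowConfig, data) -> ReportBundle:
    """Execute the full modelling workflow on a molecule dataset.

    ``data`` is a CSV path (id, smiles, pLD50) or a list of
    MoleculeRecord.  Stages run in order; any failure aborts with a
    WorkflowError naming the stage.  Reruns with identical config and
    data are byte-identical.
    """

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, WorkflowError):
                    raise WorkflowError(name, exc) from exc
                return False

        return _Ctx()

    report: dict = {"config": json.loads(json.dumps(asdict(config)))}

    with stage("load"):
        records = read_molecule_csv(data) if isinstance(data, (str, Path)) else list(data)

    with stage("clean"):
        molset, rejections = parse_and_clean(
            records, config.activity_min, config.activity_max
        )

    with stage("featurize"):
        table, desc_rej = descriptor_table(molset, config.descriptor_set)
        rejections.extend(desc_rej)
        if desc_rej:
            molset = molset.subset(table.data.index)
        fp_dict = _load_fp_dictionary(config.fingerprint_dict)
        if fp_dict is not None:
            table = table.join(fingerprint_table(molset, fp_dict))
    report["cleaning"] = {
        "n_molecules": len(molset),
        "rejections": [
            {"id": r.id, "reason": r.reason, "detail": r.detail} for r in rejections
        ],
    }

    with stage("filter"):
        table, removal_log = filter_features(table, config.corr_threshold)
    report["filter"] = {"n_features": len(table.columns), "removed": removal_log}

    activities = molset.activities()

    with stage("select"):
        k = min(config.k_features, len(table.columns))
        ranking = featselect.rank_and_select(
            table, activities, k, config.target_bins, config.feature_bins
        )
        selected = ranking.selected_features()
        table = table.subset(selected)
    report["selection"] = {
        "k": k,
        "selected": selected,
        "ranking": ranking.table.to_dict(orient="list"),
    }

    with stage("split"):
        split = split_dataset(
            molset.ids(),
            activities,
            config.test_fraction,
            config.split_bins,
            derive_seed(config.seed, "split"),
        )
    report["split"] = {
        "n_train": len(split.train_ids),
        "n_test": len(split.test_ids),
        "seed": split.seed,
    }

    ids = molset.ids()
    y = pd.Series(activities, index=ids)
    X_train = table.data.loc[list(split.train_ids)]
    X_test = table.data.loc[list(split.test_ids)]
    y_train = y.loc[list(split.train_ids)].to_numpy()
    y_test = y.loc[list(split.test_ids)].to_numpy()

    preds_train = pd.DataFrame(index=X_train.index)
    preds_test = pd.DataFrame(index=X_test.index)
    report["models"] = {}
    regressors = {}
    for name in config.learners:
        with stage(f"train:{name}"):
            spec = LearnerSpec(
                name,
                {**default_spec(name).hyperparameters,
                 **config.learner_overrides.get(name, {})},
            )
            seed = derive_seed(config.seed, f"train:{name}")
            reg = fit_learner(spec, X_train, y_train, seed=seed)
            regressors[name] = reg
            preds_train[name] = reg.predict(X_train)
            preds_test[name] = reg.predict(X_test)
            q2 = (
                metrics.q2_cv(X_train, y_train, spec, config.cv_folds,
                              derive_seed(config.seed, f"cv:{name}"))
                if config.cv_folds >= 2
                else None
            )
            m = metrics.evaluate_predictions(
                y_train, preds_train[name], y_test, preds_test[name],
                p=len(selected), q2=q2,
            )
        report["models"][name] = {"metrics": m.to_dict(), "metadata": _jsonable(reg.metadata)}

    with stage("consensus"):
        cons_train = consensus_ad.consensus_predict(preds_train, config.consensus_exclude)
        cons_test = consensus_ad.consensus_predict(preds_test, config.consensus_exclude)
        cons_metrics = metrics.evaluate_predictions(
            y_train, cons_train, y_test, cons_test, p=len(selected)
        )
    report["consensus"] = {
        "members": [c for c in preds_test.columns if c not in config.consensus_exclude],
        "excluded": list(config.consensus_exclude),
        "metrics": cons_metrics.to_dict(),
    }

    with stage("applicability_domain"):
        member_cols = [c for c in preds_test.columns if c not in config.consensus_exclude]
        ad = consensus_ad.ad_assess(
            consensus_ad.std_dm(preds_train[member_cols]),
            consensus_ad.std_dm(preds_test[member_cols]),
            config.ad_multiplier,
        )
    report["applicability_domain"] = {
        "coverage_percent": ad.coverage,
        "calibration": ad.calibration,
        "multiplier": ad.multiplier,
    }

    with stage("interpretation"):
        from toxqsar import interpret

        alerts = []
        fp_cols = [c for c in table.columns if table.provenance.get(c) == "fingerprint"]
        t_labels = featselect.discretize(activities, config.target_bins)
        for col in fp_cols:
            bits = table.data[col].to_numpy()
            alert = interpret.fragment_contribution(
                bits, activities, config.alert_threshold, feature=col
            )
            if alert is None:
                continue
            _, alert.cramers_v = featselect.feature_association(
                bits, t_labels, config.feature_bins, is_binary=True
            )
            base_cols = [c for c in table.columns if c != col]
            if len(activities) > len(base_cols) + 2:
                alert.delta_r2_adj, _ = interpret.stepwise_r2adj_delta(
                    table.data[base_cols], bits, activities
                )
            alerts.append(alert.to_dict())

        sens_model = regressors.get("rvm") or next(iter(regressors.values()))
        sensitivity = interpret.sensitivity_1d(sens_model, table.data)

        cons_err = np.abs(y.loc[preds_test.index].to_numpy() - cons_test.to_numpy())
        scaffolds = interpret.error_scaffold_table(
            molset.subset(preds_test.index),
            cons_err,
            split,
            config.error_mae_threshold,
        )
    report["interpretation"] = {
        "alerts": alerts,
        "sensitivity": {k: float(v) for k, v in sensitivity.items()},
        "error_scaffolds": scaffolds.to_dict(orient="list"),
    }

    predictions = pd.concat([preds_train.assign(subset="train"),
                             preds_test.assign(subset="test")])
    predictions["consensus"] = pd.concat([cons_train, cons_test])
    predictions["observed"] = y.loc[predictions.index]
    return ReportBundle(report=_jsonable(report), predictions=predictions)


def _jsonable(obj):
    """Recursively coerce numpy scalars/arrays so json.dumps round-trips."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
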