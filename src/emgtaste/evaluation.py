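"""Cross-validated random-forest experiments on the feature table.

Three experiments: stratified five-fold cross-validation with a row-
normalized confusion matrix, an incremental feature-type sweep (accuracy as
feature types are added in a seeded random order), and participant grouping
(accuracy averaged over every non-empty participant subset, per subset size).
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .errors import ConfigError, EmptyDatasetError
from .features import N_FEATURE_TYPES, feature_names
from .synthetic_data import TASTES_6

logger = logging.getLogger(__name__)

_FEATURE_COL = re.compile(r"^ch(\d+)_F(\d+)$")


@dataclass
class EvalConfig:
    n_folds: int = 5
    rf_n_trees: int = 100
    rf_max_features: str | int | float = "sqrt"
    seed: int = 0
    #: "stratified_random" splits windows stratified by label (default);
    #: "by_session" keeps whole (participant, session) groups in one fold to
    #: avoid within-session leakage.
    fold_scheme: str = "stratified_random"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("need at least 2 folds")
        if self.fold_scheme not in ("stratified_random", "by_session"):
            raise ConfigError(f"unknown fold scheme {self.fold_scheme!r}")


@dataclass
class DatasetTable:
    """Feature matrix with labels and provenance, the unit of evaluation."""

    X: np.ndarray  # [N x D]
    y: np.ndarray  # labels, length N
    participants: np.ndarray
    sessions: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] == 0:
            raise EmptyDatasetError("feature matrix is empty")
        if not np.all(np.isfinite(self.X)):
            raise ConfigError("feature matrix contains missing/non-finite values")
        if self.X.shape[1] != len(self.feature_names):
            raise ConfigError("feature_names do not match matrix width")
        if len(self.y) != self.X.shape[0]:
            raise ConfigError("label count does not match row count")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DatasetTable":
        if df.empty:
            raise EmptyDatasetError("empty feature table")
        cols = [c for c in df.columns if _FEATURE_COL.match(c)]
        if not cols:
            raise ConfigError("no ch{c}_F{n} feature columns found")
        # keep channel-major order regardless of frame column order
        cols.sort(key=lambda c: tuple(map(int, _FEATURE_COL.match(c).groups())))
        return cls(
            X=df[cols].to_numpy(dtype=float),
            y=df["label"].to_numpy(),
            participants=df["participant"].to_numpy(),
            sessions=df["session"].to_numpy(),
            feature_names=cols,
        )

    @property
    def labels(self) -> list[str]:
        """Distinct labels in canonical taste order (unknown labels sorted last)."""
        present = set(map(str, self.y))
        ordered = [t for t in TASTES_6 if t in present]
        ordered += sorted(present - set(ordered))
        return ordered

    def subset_rows(self, mask: np.ndarray) -> "DatasetTable":
        return DatasetTable(
            X=self.X[mask],
            y=self.y[mask],
            participants=self.participants[mask],
            sessions=self.sessions[mask],
            feature_names=self.feature_names,
        )


@dataclass
class EvalReport:
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: np.ndarray  # [K x K], row-normalized
    labels: list[str]
    sweep: list[dict] | None = None
    grouping: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "labels": list(self.labels),
            "confusion": np.asarray(self.confusion).tolist(),
        }
        if self.sweep is not None:
            d["sweep"] = self.sweep
        if self.grouping is not None:
            d["grouping"] = self.grouping.to_dict(orient="records")
        return d


def _make_forest(config: EvalConfig) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.rf_n_trees,
        max_features=config.rf_max_features,
        random_state=config.seed,
        n_jobs=1,
    )


def _fold_indices(data: DatasetTable, config: EvalConfig):
    if config.fold_scheme == "by_session":
        groups = np.array(
            [f"{p}|{s}" for p, s in zip(data.participants, data.sessions)]
        )
        if len(np.unique(groups)) < config.n_folds:
            raise ConfigError("fewer (participant, session) groups than folds")
        splitter = GroupKFold(n_splits=config.n_folds)
        return list(splitter.split(data.X, data.y, groups))
    splitter = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    return list(splitter.split(data.X, data.y))


def five_fold_cv(data: DatasetTable, config: EvalConfig | None = None) -> EvalReport:
    """Stratified k-fold cross-validation of a random forest.

    Returns per-fold and mean accuracy plus the confusion matrix accumulated
    over all test folds and row-normalized.  Deterministic for fixed
    (data, config.seed).
    """
    config = config or EvalConfig()
    labels = data.labels
    counts = pd.Series(data.y).value_counts()
    if counts.min() < config.n_folds:
        raise ConfigError(
            f"class {counts.idxmin()!r} has only {counts.min()} samples for "
            f"{config.n_folds} folds; use stratification-compatible data or "
            "generate more windows"
        )
    fold_acc: list[float] = []
    conf = np.zeros((len(labels), len(labels)), dtype=float)
    for train_idx, test_idx in _fold_indices(data, config):
        clf = _make_forest(config)
        clf.fit(data.X[train_idx], data.y[train_idx])
        pred = clf.predict(data.X[test_idx])
        truth = data.y[test_idx]
        fold_acc.append(float(np.mean(pred == truth)))
        conf += confusion_matrix(truth, pred, labels=labels)
    row_sums = conf.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return EvalReport(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        confusion=conf / row_sums,
        labels=labels,
    )


def columns_for_feature_types(names: list[str], types: list[int]) -> list[int]:
    """Column indices whose F-number belongs to ``types`` (1-based)."""
    wanted = set(types)
    return [
        i
        for i, c in enumerate(names)
        if int(_FEATURE_COL.match(c).group(2)) in wanted
    ]


def feature_sweep(
    data: DatasetTable,
    order_seed: int,
    config: EvalConfig | None = None,
    order: list[int] | None = None,
) -> list[dict]:
    """Accuracy as feature types are added one by one in random order.

    The 21 feature types are shuffled with ``order_seed``; step k evaluates a
    forest on the columns of the first k types across all channels.  Returns
    21 records {n_features, feature_types, mean_accuracy}.  An explicit
    ``order`` (1-based type numbers) overrides the shuffle.
    """
    config = config or EvalConfig()
    if order is None:
        order = (np.random.default_rng(order_seed).permutation(N_FEATURE_TYPES) + 1).tolist()
    if sorted(order) != list(range(1, N_FEATURE_TYPES + 1)):
        raise ConfigError("order must be a permutation of feature types 1..21")
    curve = []
    for k in range(1, N_FEATURE_TYPES + 1):
        cols = columns_for_feature_types(data.feature_names, order[:k])
        sub = DatasetTable(
            X=data.X[:, cols],
            y=data.y,
            participants=data.participants,
            sessions=data.sessions,
            feature_names=[data.feature_names[i] for i in cols],
        )
        rep = five_fold_cv(sub, config)
        curve.append(
            {
                "n_features": k,
                "feature_types": list(order[:k]),
                "mean_accuracy": rep.mean_accuracy,
            }
        )
    return curve


def participant_grouping(
    data: DatasetTable, config: EvalConfig | None = None
) -> pd.DataFrame:
    """Mean CV accuracy over every non-empty participant subset, by size.

    For P participants this evaluates all 2^P - 1 subsets (guarded at
    P <= 12) and averages accuracy within each subset size; subsets with too
    few rows per class for stratified folding are skipped with a log entry.
    Returns a frame with columns size / n_subsets / n_evaluated /
    mean_accuracy / n_rows_mean.
    """
    config = config or EvalConfig()
    pids = sorted(set(map(str, data.participants)))
    P = len(pids)
    if P > 12:
        raise ConfigError(f"{P} participants means 2^{P}-1 subsets; refusing > 12")
    rows = []
    for size in range(1, P + 1):
        accs, nrows = [], []
        n_subsets = 0
        for subset in itertools.combinations(pids, size):
            n_subsets += 1
            mask = np.isin(data.participants.astype(str), subset)
            try:
                rep = five_fold_cv(data.subset_rows(mask), config)
            except (ConfigError, EmptyDatasetError) as exc:
                logger.warning("skipping subset %s: %s", subset, exc)
                continue
            accs.append(rep.mean_accuracy)
            nrows.append(int(mask.sum()))
        rows.append(
            {
                "size": size,
                "n_subsets": n_subsets,
                "n_evaluated": len(accs),
                "mean_accuracy": float(np.mean(accs)) if accs else np.nan,
                "n_rows_mean": float(np.mean(nrows)) if nrows else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    logger.info(
        "participant grouping: %d subsets over %d participants",
        int(table["n_subsets"].sum()),
        P,
    )
    return table


def scenario_compare(
    dataset_a: DatasetTable, dataset_b: DatasetTable, config: EvalConfig | None = None
) -> dict[str, EvalReport]:
    """Side-by-side CV reports for two acquisition scenarios.

    Both datasets must use the same label set (e.g. the four-state
    no/sour/bitter/salty comparison of electronic against actual tastants).
    """
    config = config or EvalConfig()
    if dataset_a.labels != dataset_b.labels:
        raise ConfigError(
            f"label sets differ: {dataset_a.labels} vs {dataset_b.labels}"
        )
    return {"a": five_fold_cv(dataset_a, config), "b": five_fold_cv(dataset_b, config)}
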