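"""Fracture classification benchmark.

Stratified 70/30 splits, SMOTE balancing of the training set to 200
samples per class, and repeated training/evaluation of logistic
regression, seven support-vector variants, a decision tree and a random
forest.  Metrics are sensitivity, specificity and accuracy with the
fractured class coded 1 (positive).

SMOTE is implemented directly from its definition: each synthetic point
is x + u (x_nn - x) with u uniform on [0, 1] and x_nn one of the k
nearest same-class neighbours in standardised feature space; synthetic
rows never reach a test set.

"Posterior probability region" (PPR) variants classify by thresholding
calibrated class posteriors (Platt scaling for SVMs) instead of the raw
decision function; the "bayesian" kernel machine is a Gaussian-process
classifier with a squared-exponential kernel, which yields posteriors
natively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SplitSpec",
    "SmoteSpec",
    "ModelSpec",
    "EvalReport",
    "ClassifyError",
    "MODEL_NAMES",
    "split",
    "smote_augment",
    "train_model",
    "evaluate",
    "benchmark",
]

log = logging.getLogger(__name__)

POSITIVE = "fractured"
NEGATIVE = "control"

MODEL_NAMES: tuple[str, ...] = (
    "lr",
    "svm-linear", "svm-linear-ppr",
    "svm-sigmoid", "svm-sigmoid-ppr",
    "svm-gaussian", "svm-gaussian-ppr",
    "svm-bayesian-ppr",
    "dt", "rf",
)


class ClassifyError(ValueError):
    """Raised for invalid benchmarking inputs."""


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    n_runs: int = 1000
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ClassifyError("train fraction must lie in (0, 1)")
        if self.n_runs < 1:
            raise ClassifyError("n_runs must be >= 1")


@dataclass(frozen=True)
class SmoteSpec:
    target_per_class: int = 200
    k_neighbours: int = 5

    def __post_init__(self) -> None:
        if self.k_neighbours < 1:
            raise ClassifyError("k must be >= 1")
        if self.target_per_class < 1:
            raise ClassifyError("target must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    family: str                     # LR | SVM | DT | RF
    kernel: str | None = None       # linear | sigmoid | gaussian | bayesian
    posterior_probability: bool = False
    threshold: float = 0.5
    rf_trees: int = 1000
    rf_max_depth: int | None = 12
    dt_criterion: str = "gini"

    def __post_init__(self) -> None:
        if self.family not in ("LR", "SVM", "DT", "RF"):
            raise ClassifyError(f"unknown model family {self.family!r}")
        if self.kernel is not None and self.family != "SVM":
            raise ClassifyError("kernel only applies to SVM")
        if self.family == "SVM" and self.kernel not in (
                "linear", "sigmoid", "gaussian", "bayesian"):
            raise ClassifyError(f"unknown SVM kernel {self.kernel!r}")
        if self.rf_trees < 1:
            raise ClassifyError("rf_trees must be >= 1")

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        if name == "lr":
            return cls(family="LR")
        if name == "dt":
            return cls(family="DT")
        if name == "rf":
            return cls(family="RF")
        if name.startswith("svm-"):
            parts = name.split("-")
            kernel = parts[1]
            ppr = name.endswith("-ppr")
            if kernel == "bayesian" and not ppr:
                raise ClassifyError("the bayesian kernel machine is "
                                    "posterior-probability only")
            return cls(family="SVM", kernel=kernel, posterior_probability=ppr)
        raise ClassifyError(f"unknown model name {name!r}")


@dataclass
class EvalReport:
    """Per model x feature-set metric summaries over repeated runs."""

    table: pd.DataFrame             # model, feature_set, metric, mean, sd, best, n_runs
    per_run: pd.DataFrame           # model, feature_set, run, se, sp, acc


# --------------------------------------------------------------------------

def split(table: pd.DataFrame, spec: SplitSpec, run_index: int
          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified split: per class, floor(fraction * n) rows to train."""
    groups = table["group"].unique()
    if len(groups) < 2:
        raise ClassifyError("both classes must be present")
    rng = np.random.default_rng(int(spec.base_seed) + int(run_index))
    train_idx = []
    for g in sorted(groups):
        idx = table.index[table["group"] == g].to_numpy()
        if len(idx) < 2:
            raise ClassifyError(f"class {g!r} has fewer than 2 members")
        n_train = int(np.floor(spec.train_fraction * len(idx)))
        perm = rng.permutation(len(idx))
        train_idx.append(idx[perm[:n_train]])
    train_idx = np.concatenate(train_idx)
    train = table.loc[train_idx]
    test = table.drop(index=train_idx)
    return train, test


def smote_augment(X: np.ndarray, y: np.ndarray, spec: SmoteSpec,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample every class to the target count by convex interpolation.

    Returns (X_aug, y_aug, synthetic_flag); original rows come first and
    are preserved verbatim.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X_out, y_out, flags = [X], [y], [np.zeros(len(y), dtype=bool)]
    for cls in np.unique(y):
        Xc = X[y == cls]
        n = len(Xc)
        if spec.target_per_class < n:
            raise ClassifyError(
                f"SMOTE target {spec.target_per_class} below class size {n}")
        n_new = spec.target_per_class - n
        if n_new == 0:
            continue
        k = spec.k_neighbours
        if n <= k:
            k = max(n - 1, 1)
            log.warning("SMOTE: class %r has %d members; k reduced to %d",
                        cls, n, k)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, nbr = nn.kneighbors(Xc)
        base = rng.integers(0, n, size=n_new)
        pick = rng.integers(1, k + 1, size=n_new)     # skip self at column 0
        lam = rng.uniform(0.0, 1.0, size=n_new)
        x0 = Xc[base]
        x1 = Xc[nbr[base, pick]]
        X_new = x0 + lam[:, None] * (x1 - x0)
        X_out.append(X_new)
        y_out.append(np.full(n_new, cls, dtype=y.dtype))
        flags.append(np.ones(n_new, dtype=bool))
    return np.vstack(X_out), np.concatenate(y_out), np.concatenate(flags)


def _estimator(spec: ModelSpec, seed: int):
    if spec.family == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if spec.family == "DT":
        return DecisionTreeClassifier(criterion=spec.dt_criterion,
                                      random_state=seed)
    if spec.family == "RF":
        return RandomForestClassifier(n_estimators=spec.rf_trees,
                                      max_depth=spec.rf_max_depth,
                                      random_state=seed)
    kernel = {"linear": "linear", "sigmoid": "sigmoid",
              "gaussian": "rbf"}.get(spec.kernel)
    if kernel is not None:
        svc = SVC(kernel=kernel, C=1.0, gamma="scale", random_state=seed)
        if spec.posterior_probability:
            # Platt-style sigmoid calibration of the SVM decision values
            return CalibratedClassifierCV(svc, method="sigmoid", cv=5,
                                          ensemble=False)
        return svc
    if spec.kernel == "bayesian":
        return GaussianProcessClassifier(kernel=1.0 * RBF(length_scale=1.0),
                                         random_state=seed)
    raise ClassifyError(f"unknown SVM kernel {spec.kernel!r}")


def train_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit the requested classifier; fractured coded 1."""
    if len(np.unique(y)) < 2:
        raise ClassifyError("training set contains a single class")
    model = _estimator(spec, seed)
    model.fit(X, y)
    return model


def _predict(model, spec: ModelSpec, X: np.ndarray) -> np.ndarray:
    uses_posterior = spec.posterior_probability or spec.family in ("LR", "RF") \
        or (spec.family == "SVM" and spec.kernel == "bayesian")
    if uses_posterior and hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)[:, list(model.classes_).index(1)]
        return (proba >= spec.threshold).astype(int)
    return model.predict(X)


def evaluate(model, spec: ModelSpec, X: np.ndarray, y: np.ndarray
             ) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and confusion counts."""
    if len(y) == 0:
        raise ClassifyError("empty test set")
    pred = _predict(model, spec, X)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    out = {"tp": tp, "fn": fn, "tn": tn, "fp": fp,
           "acc": (tp + tn) / len(y)}
    out["se"] = tp / (tp + fn) if tp + fn > 0 else np.nan
    out["sp"] = tn / (tn + fp) if tn + fp > 0 else np.nan
    if np.isnan(out["se"]) or np.isnan(out["sp"]):
        log.warning("a class is absent from the test set; metric undefined")
    return out


def _one_run(table, features, spec, split_spec, smote_spec, run):
    train, test = split(table, split_spec, run)
    y_train = (train["group"] == POSITIVE).astype(int).to_numpy()
    y_test = (test["group"] == POSITIVE).astype(int).to_numpy()
    scaler = StandardScaler().fit(train[features].to_numpy())
    X_train = scaler.transform(train[features].to_numpy())
    X_test = scaler.transform(test[features].to_numpy())
    rng = np.random.default_rng(split_spec.base_seed + 7919 * (run + 1))
    X_aug, y_aug, _ = smote_augment(X_train, y_train, smote_spec, rng)
    model = train_model(spec, X_aug, y_aug,
                        seed=(split_spec.base_seed + run) % (2 ** 31))
    return evaluate(model, spec, X_test, y_test)


def benchmark(table: pd.DataFrame, feature_sets: dict[str, list[str]],
              model_names: list[str] | None = None,
              split_spec: SplitSpec | None = None,
              smote_spec: SmoteSpec | None = None) -> EvalReport:
    """Repeated split -> SMOTE -> train -> evaluate cycles.

    The random forest is evaluated on a single seeded run (its internal
    ensemble already averages over resamples); every other model runs
    ``split_spec.n_runs`` times and reports mean, SD and best per metric.
    """
    split_spec = split_spec if split_spec is not None else SplitSpec()
    smote_spec = smote_spec if smote_spec is not None else SmoteSpec()
    names = model_names if model_names is not None else list(MODEL_NAMES)
    rows, run_rows = [], []
    for fs_name, features in feature_sets.items():
        missing = [f for f in features if f not in table.columns]
        if missing:
            raise ClassifyError(f"feature set {fs_name!r} lacks {missing}")
        for name in names:
            spec = ModelSpec.from_name(name)
            n_runs = 1 if spec.family == "RF" else split_spec.n_runs
            metrics = {"se": [], "sp": [], "acc": []}
            for run in range(n_runs):
                res = _one_run(table, features, spec, split_spec,
                               smote_spec, run)
                for m in metrics:
                    metrics[m].append(res[m])
                run_rows.append({"model": name, "feature_set": fs_name,
                                 "run": run, **{m: res[m] for m in metrics}})
            for m, vals in metrics.items():
                vals = np.asarray(vals, dtype=float)
                rows.append({
                    "model": name, "feature_set": fs_name, "metric": m,
                    "mean": float(np.nanmean(vals)),
                    "sd": float(np.nanstd(vals, ddof=0)) if n_runs > 1 else 0.0,
                    "best": float(np.nanmax(vals)),
                    "n_runs": n_runs,
                })
    return EvalReport(table=pd.DataFrame(rows), per_run=pd.DataFrame(run_rows))
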