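"""Regression harness over competing-site pair vectors.

Small-data chemistry regression: tens to a few hundred pair vectors, so the
evaluation protocol is leave-one-out (LOO) — each pair predicted by a model
trained on all others — with Pearson R and MAE computed over the
concatenated held-out predictions (LOO folds have size one, so per-fold
correlation is undefined).  Two splitting units are exposed:

* ``mode="pair"`` (default): leave one pair vector out at a time;
* ``mode="arene"``: leave all pairs of one arene out together, which is the
  unit of real prospective prediction (a new substrate arrives whole).

On top of LOO sit an algorithm comparison grid (tree ensembles, kernel and
linear baselines), greedy forward feature selection, impurity/permutation
feature importance, and an out-of-sample (OOS) evaluator that withholds
entire arenes from training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .sites import PairFeatureVector
from .selectivity import PairTarget

__all__ = [
    "PairDataset",
    "ModelReport",
    "build_model",
    "registry_names",
    "loo_evaluate",
    "compare_algorithms",
    "greedy_feature_selection",
    "feature_importance",
    "oos_evaluate",
]


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class PairDataset:
    """Feature matrix + DDG targets + arene grouping for pair vectors."""

    X: np.ndarray                    # (n, p)
    y: np.ndarray                    # (n,) kcal/mol
    arene_ids: list[str]             # (n,) grouping key for leakage control
    feature_names: tuple[str, ...]
    pair_ids: list[tuple[str, str, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise ValueError(f"X shape {self.X.shape} inconsistent with {n} targets")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match X columns")
        if len(self.arene_ids) != n:
            raise ValueError("every row needs an arene id")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite features or targets")
        if not self.pair_ids:
            self.pair_ids = [(a, "?", "?") for a in self.arene_ids]

    @property
    def n_rows(self) -> int:
        return len(self.y)

    def select_features(self, names: Sequence[str]) -> "PairDataset":
        """Column subset by feature name, order preserved as given."""
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise KeyError(f"unknown features {missing}")
        cols = [self.feature_names.index(n) for n in names]
        return PairDataset(
            X=self.X[:, cols],
            y=self.y.copy(),
            arene_ids=list(self.arene_ids),
            feature_names=tuple(names),
            pair_ids=list(self.pair_ids),
            metadata=dict(self.metadata),
        )

    @classmethod
    def from_pairs(
        cls,
        vectors: Sequence[PairFeatureVector],
        targets: Sequence[PairTarget | float],
        metadata: dict | None = None,
    ) -> "PairDataset":
        if len(vectors) != len(targets):
            raise ValueError("vectors and targets length mismatch")
        if not vectors:
            raise ValueError("empty dataset")
        names = vectors[0].names
        for v in vectors:
            if v.names != names:
                raise ValueError("inconsistent feature layouts")
        y = np.array([t.ddg_app if isinstance(t, PairTarget) else float(t)
                      for t in targets])
        pair_ids = [
            (v.arene_id,
             t.class_a if isinstance(t, PairTarget) else str(v.site_a),
             t.class_b if isinstance(t, PairTarget) else str(v.site_b))
            for v, t in zip(vectors, targets)
        ]
        return cls(
            X=np.vstack([v.values for v in vectors]),
            y=y,
            arene_ids=[v.arene_id for v in vectors],
            feature_names=names,
            pair_ids=pair_ids,
            metadata=metadata or {},
        )


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

# Fixed documented defaults; no nested hyperparameter tuning.  Tree counts
# are sized for datasets of a few hundred rows.
_N_TREES = 100


def _registry(seed: int) -> dict[str, object]:
    return {
        "extra_trees": ExtraTreesRegressor(
            n_estimators=_N_TREES, random_state=seed, n_jobs=1),
        "random_forest": RandomForestRegressor(
            n_estimators=_N_TREES, random_state=seed, n_jobs=1),
        "gradient_boosting": GradientBoostingRegressor(random_state=seed),
        "svr": make_pipeline(StandardScaler(), SVR(C=10.0, epsilon=0.05)),
        "knn": make_pipeline(StandardScaler(), KNeighborsRegressor(n_neighbors=5)),
        # near-OLS ridge: the tiny alpha is for numerical conditioning only
        "ridge": make_pipeline(StandardScaler(), Ridge(alpha=1e-6)),
    }


def registry_names() -> tuple[str, ...]:
    return tuple(sorted(_registry(0)))


def build_model(algorithm: str, seed: int = 0):
    """Fresh estimator from the registry; KeyError for unknown names."""
    reg = _registry(seed)
    try:
        return clone(reg[algorithm])
    except KeyError:
        raise KeyError(
            f"unknown algorithm {algorithm!r}; registry: {sorted(reg)}"
        )


def _config_hash(algorithm: str, mode: str, seed: int,
                 feature_names: Sequence[str], n: int) -> str:
    model = build_model(algorithm, seed)
    params = {k: repr(v) for k, v in model.get_params(deep=False).items()}
    blob = json.dumps(
        {"algorithm": algorithm, "mode": mode, "seed": seed, "n": n,
         "features": list(feature_names), "params": params},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Evaluation record for one algorithm on one dataset."""

    algorithm: str
    mode: str
    pearson_r: float            # NaN when undefined (constant predictions/targets)
    mae: float                  # kcal/mol by default
    predictions: np.ndarray     # held-out prediction per evaluated row
    actual: np.ndarray
    seed: int
    config_hash: str
    n_rows: int
    selected_features: tuple[str, ...] | None = None
    importances: list[tuple[str, float]] | None = None
    flags: list[str] = field(default_factory=list)
    train_arenes: tuple[str, ...] | None = None   # populated by grouped/OOS modes
    test_arenes: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "mode": self.mode,
            "pearson_r": None if np.isnan(self.pearson_r) else float(self.pearson_r),
            "mae": float(self.mae),
            "n_rows": self.n_rows,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "selected_features": (
                list(self.selected_features) if self.selected_features else None),
            "importances": self.importances,
            "flags": self.flags,
            "predictions": [float(p) for p in self.predictions],
            "actual": [float(a) for a in self.actual],
        }


def _metrics(actual: np.ndarray, pred: np.ndarray) -> tuple[float, float, list[str]]:
    flags: list[str] = []
    mae = float(np.mean(np.abs(actual - pred)))
    if len(actual) < 2 or np.ptp(actual) == 0 or np.ptp(pred) == 0:
        flags.append("pearson_undefined")
        return float("nan"), mae, flags
    r = float(stats.pearsonr(actual, pred).statistic)
    return r, mae, flags


# ---------------------------------------------------------------------------
# leave-one-out evaluation
# ---------------------------------------------------------------------------

def loo_evaluate(
    data: PairDataset,
    algorithm: str = "extra_trees",
    seed: int = 0,
    mode: str = "pair",
) -> ModelReport:
    """Leave-one-out metrics for one algorithm.

    ``mode="pair"`` holds out one pair vector per fold; ``mode="arene"``
    holds out all pairs sharing an arene id per fold (grouped LOO, the
    no-leakage protocol).  Every fold refits from scratch with the same
    seed; Pearson R and MAE are computed over the concatenated held-out
    predictions.
    """
    if data.n_rows < 3:
        raise ValueError("need at least 3 rows for leave-one-out")
    if mode not in ("pair", "arene"):
        raise ValueError(f"unknown mode {mode!r}")
    arenes = np.array(data.arene_ids)
    if mode == "pair":
        folds = [np.array([i]) for i in range(data.n_rows)]
    else:
        folds = [np.nonzero(arenes == a)[0] for a in sorted(set(data.arene_ids))]

    pred = np.empty(data.n_rows)
    for test_idx in folds:
        train = np.ones(data.n_rows, dtype=bool)
        train[test_idx] = False
        if mode == "arene":
            # structural no-leakage assertion: no shared arene across the split
            assert not set(arenes[train]) & set(arenes[test_idx])
        model = build_model(algorithm, seed)
        model.fit(data.X[train], data.y[train])
        pred[test_idx] = model.predict(data.X[test_idx])

    r, mae, flags = _metrics(data.y, pred)
    return ModelReport(
        algorithm=algorithm,
        mode=mode,
        pearson_r=r,
        mae=mae,
        predictions=pred,
        actual=data.y.copy(),
        seed=seed,
        config_hash=_config_hash(algorithm, mode, seed, data.feature_names,
                                 data.n_rows),
        n_rows=data.n_rows,
        flags=flags,
    )


def compare_algorithms(
    data: PairDataset,
    algorithms: Sequence[str] | None = None,
    seed: int = 0,
    mode: str = "pair",
) -> list[ModelReport]:
    """LOO reports for every registry algorithm, best first.

    Ranking: Pearson R descending, ties broken by lower MAE; undefined R
    sorts last.  Deterministic given the seed.
    """
    names = list(algorithms) if algorithms is not None else list(registry_names())
    reports = [loo_evaluate(data, name, seed=seed, mode=mode) for name in names]
    reports.sort(key=lambda r: (
        -(r.pearson_r if np.isfinite(r.pearson_r) else -np.inf), r.mae))
    return reports


# ---------------------------------------------------------------------------
# feature selection and importance
# ---------------------------------------------------------------------------

def greedy_feature_selection(
    data: PairDataset,
    algorithm: str = "extra_trees",
    seed: int = 0,
    mode: str = "pair",
    tolerance: float = 1e-3,
    max_features: int | None = None,
) -> tuple[tuple[str, ...], list[ModelReport]]:
    """Forward selection maximizing LOO Pearson R.

    Starts from the empty set; each step adds the feature with the largest
    LOO Pearson R (ties broken by lexicographic feature name) and stops when
    the best addition improves R by no more than ``tolerance``.  Returns the
    selected subset and the per-step report trajectory, whose R values are
    non-decreasing by construction.
    """
    if len(data.feature_names) < 2:
        raise ValueError("need at least 2 features to select among")
    selected: list[str] = []
    trajectory: list[ModelReport] = []
    best_r = -np.inf
    limit = max_features or len(data.feature_names)
    while len(selected) < limit:
        candidates = sorted(set(data.feature_names) - set(selected))
        if not candidates:
            break
        step_best: tuple[float, str, ModelReport] | None = None
        for name in candidates:
            rep = loo_evaluate(
                data.select_features(selected + [name]), algorithm,
                seed=seed, mode=mode)
            r = rep.pearson_r if np.isfinite(rep.pearson_r) else -np.inf
            # strict > keeps the lexicographically first name on ties
            if step_best is None or r > step_best[0]:
                step_best = (r, name, rep)
        assert step_best is not None
        r, name, rep = step_best
        if r <= best_r + tolerance:
            break
        selected.append(name)
        best_r = r
        rep.selected_features = tuple(selected)
        trajectory.append(rep)
    if not trajectory:
        # nothing beat the empty model by tolerance; keep the single best step
        raise ValueError("no feature improved LOO Pearson R; check the data")
    return tuple(selected), trajectory


def feature_importance(
    data: PairDataset,
    algorithm: str = "extra_trees",
    seed: int = 0,
    method: str = "impurity",
    n_repeats: int = 10,
) -> list[tuple[str, float]]:
    """Ranked feature importances from a model fit on the full dataset.

    ``method="impurity"`` uses the tree ensemble's normalized impurity
    importances (errors for non-tree models); ``method="permutation"``
    reports the mean Pearson-R degradation over ``n_repeats`` shuffles of
    each column, clipped at zero.  Returned sorted descending, ties broken
    lexicographically.
    """
    model = build_model(algorithm, seed)
    model.fit(data.X, data.y)
    if method == "impurity":
        if not hasattr(model, "feature_importances_"):
            raise ValueError(
                f"impurity importances need a tree ensemble, not {algorithm!r}"
            )
        imps = np.asarray(model.feature_importances_, dtype=float)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        base_r, _, _ = _metrics(data.y, model.predict(data.X))
        if np.isnan(base_r):
            raise ValueError("permutation importance undefined for constant output")
        imps = np.zeros(data.X.shape[1])
        for j in range(data.X.shape[1]):
            drops = []
            for _ in range(n_repeats):
                Xp = data.X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                r, _, _ = _metrics(data.y, model.predict(Xp))
                drops.append(base_r - (r if np.isfinite(r) else 0.0))
            imps[j] = max(0.0, float(np.mean(drops)))
    else:
        raise ValueError(f"unknown importance method {method!r}")
    ranked = sorted(
        zip(data.feature_names, imps.tolist()),
        key=lambda t: (-t[1], t[0]),
    )
    return [(n, float(v)) for n, v in ranked]


# ---------------------------------------------------------------------------
# out-of-sample (leave-arene-out) evaluation
# ---------------------------------------------------------------------------

def oos_evaluate(
    data: PairDataset,
    holdout_arene_ids: Iterable[str],
    algorithm: str = "extra_trees",
    seed: int = 0,
) -> ModelReport:
    """Prospective-style validation: whole arenes withheld from training.

    Every pair involving a held-out arene is removed from the training set;
    the model, refit on the remainder, is scored on the held-out pairs only.
    A holdout that matches zero pairs yields an empty, flagged report (with
    a warning); a holdout covering every arene is an error.
    """
    import warnings

    holdout = set(holdout_arene_ids)
    known = set(data.arene_ids)
    unknown = holdout - known
    if unknown:
        warnings.warn(
            f"holdout arenes with no pairs in the dataset: {sorted(unknown)}",
            stacklevel=2,
        )
    if holdout >= known:
        raise ValueError("holdout covers every arene; nothing left to train on")
    arenes = np.array(data.arene_ids)
    test = np.isin(arenes, sorted(holdout))
    train = ~test
    # structural no-leakage guarantee
    assert not set(arenes[train]) & set(arenes[test])

    chash = _config_hash(algorithm, "oos", seed, data.feature_names, data.n_rows)
    train_arenes = tuple(sorted(set(arenes[train])))
    test_arenes = tuple(sorted(set(arenes[test])))
    if not test.any():
        return ModelReport(
            algorithm=algorithm, mode="oos", pearson_r=float("nan"), mae=float("nan"),
            predictions=np.array([]), actual=np.array([]), seed=seed,
            config_hash=chash, n_rows=0, flags=["empty_holdout"],
            train_arenes=train_arenes, test_arenes=test_arenes,
        )
    model = build_model(algorithm, seed)
    model.fit(data.X[train], data.y[train])
    pred = model.predict(data.X[test])
    r, mae, flags = _metrics(data.y[test], pred)
    return ModelReport(
        algorithm=algorithm, mode="oos", pearson_r=r, mae=mae,
        predictions=pred, actual=data.y[test].copy(), seed=seed,
        config_hash=chash, n_rows=int(test.sum()), flags=flags,
        train_arenes=train_arenes, test_arenes=test_arenes,
    )
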