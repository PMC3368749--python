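"""Cross-validation and external-validation harness.

Implements the benchmark protocol: random 10-fold cross-validation with
grid-tuned classifiers (SVM with RBF or polynomial kernel, kNN, Random
Forest), the similarity-matrix column-deletion rule (reference columns of
held-out entries are removed before training so the model never sees the
test entries' identities), per-training-fold z-scaling for the count and
engineered descriptor sets, Random Forest out-of-bag accuracy, and the
third-level-non-redundant external test split.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .descriptors import (
    DescriptorMatrix,
    FeatureRegistry,
    build_descriptor_matrix,
    zscale_apply,
    zscale_fit,
)
from .evaluation import (
    ConfusionMatrix,
    FoldOutcome,
    accuracy,
    confusion_matrix,
    gorodkin_rk,
)
from .reaction_model import ReactionEntry
from .similarity import delete_test_columns, similarity_matrix

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "ExternalSplit",
    "DESCRIPTOR_KINDS",
    "default_classifier_spec",
    "make_folds",
    "tune",
    "cross_validate",
    "rf_oob_accuracy",
    "external_split",
    "external_validate",
    "build_benchmark_matrix",
]

N_CLASSES = 6

# The five descriptor sets of the benchmark, keyed by CLI-style names.
DESCRIPTOR_KINDS = ("human", "overall-bond", "composite-bond", "overall-sim", "mech-sim")
_SIMILARITY_KINDS = ("overall-sim", "mech-sim")


@dataclass
class ClassifierSpec:
    """A classifier family plus its hyperparameter grid.

    Grid values are lists; for Random Forest, ``mtry`` may be the string
    ``"auto"``, expanded at fit time to {floor(sqrt(M)/2), ceil(sqrt(M)),
    2 ceil(sqrt(M))} where M is the number of descriptors.
    """

    family: str
    grid: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("svm_rbf", "svm_poly", "knn", "rf"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if not self.grid:
            self.grid = default_classifier_spec(self.family).grid

    def resolved_grid(self, n_features: int) -> Dict[str, List]:
        out: Dict[str, List] = {}
        for name, values in self.grid.items():
            if name == "mtry" and values == "auto":
                root = np.sqrt(n_features)
                vals = sorted({max(1, int(np.floor(root / 2))),
                               max(1, int(np.ceil(root))),
                               max(1, 2 * int(np.ceil(root)))})
                out[name] = vals
            else:
                out[name] = list(values)  # type: ignore[arg-type]
        if any(len(v) == 0 for v in out.values()):
            raise ValueError("hyperparameter grids must be non-empty")
        return out


def default_classifier_spec(family: str) -> ClassifierSpec:
    """Fixed-step default grids in the spirit of CARET's train()."""
    grids = {
        "svm_rbf": {"C": [0.25, 1, 4, 16, 64, 256],
                    "sigma": [2 ** -6, 2 ** -4, 2 ** -2, 1.0, 4.0]},
        "svm_poly": {"C": [0.25, 1, 4, 16, 64, 256],
                     "scale": [0.01, 0.1, 1.0],
                     "degree": [2, 3]},
        "knn": {"k": [1, 3, 5, 7, 9, 11]},
        "rf": {"mtry": "auto", "n_trees": [500]},
    }
    if family not in grids:
        raise ValueError(f"unknown classifier family {family!r}")
    return ClassifierSpec(family=family, grid=grids[family])


class _NearestTieKNN:
    """kNN with majority vote; ties go to the class of the nearest tied member.

    sklearn's KNeighborsClassifier resolves vote ties by class index, which
    would make tie-breaking depend on label numbering; here the tied class
    whose member is closest to the query wins, keeping the rule local and
    deterministic.
    """

    def __init__(self, k: int):
        self.k = int(k)
        self._nn = NearestNeighbors()

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_NearestTieKNN":
        self._nn.fit(x)
        self._y = np.asarray(y)
        self._k = min(self.k, len(self._y))
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        idx = self._nn.kneighbors(x, n_neighbors=self._k, return_distance=False)
        out = np.empty(len(x), dtype=self._y.dtype)
        for i, row in enumerate(idx):
            votes: Dict[object, int] = {}
            for j in row:  # row is ordered nearest-first
                votes[self._y[j]] = votes.get(self._y[j], 0) + 1
            best = max(votes.values())
            tied = {c for c, v in votes.items() if v == best}
            for j in row:
                if self._y[j] in tied:
                    out[i] = self._y[j]
                    break
        return out


def _make_estimator(family: str, params: Dict, seed: int):
    if family == "svm_rbf":
        # kernel width sigma -> sklearn's gamma = 1 / (2 sigma^2)
        return SVC(kernel="rbf", C=params["C"],
                   gamma=1.0 / (2.0 * params["sigma"] ** 2))
    if family == "svm_poly":
        # kernlab-style polynomial kernel (scale <x,y> + 1)^degree
        return SVC(kernel="poly", C=params["C"], gamma=params["scale"],
                   degree=params["degree"], coef0=1.0)
    if family == "knn":
        return _NearestTieKNN(params["k"])
    if family == "rf":
        return RandomForestClassifier(n_estimators=int(params.get("n_trees", 500)),
                                      max_features=params["mtry"],
                                      random_state=seed)
    raise ValueError(f"unknown classifier family {family!r}")


def make_folds(entry_ids: Sequence[str], n_folds: int, seed: int,
               labels: Optional[Sequence[int]] = None,
               stratified: bool = False) -> List[List[str]]:
    """Random partition into folds whose sizes differ by at most one.

    Plain random by default, matching the benchmark protocol; a stratified
    option is available but off by default.
    """
    ids = list(entry_ids)
    if n_folds < 1 or n_folds > len(ids):
        raise ValueError(f"cannot make {n_folds} folds from {len(ids)} entries")
    rng = np.random.default_rng(seed)
    folds: List[List[str]] = [[] for _ in range(n_folds)]
    if stratified:
        if labels is None:
            raise ValueError("stratified folds require labels")
        order = np.arange(len(ids))
        rng.shuffle(order)
        order = order[np.argsort(np.asarray(labels)[order], kind="stable")]
        for pos, i in enumerate(order):
            folds[pos % n_folds].append(ids[i])
    else:
        perm = rng.permutation(len(ids))
        for pos, i in enumerate(perm):
            folds[pos % n_folds].append(ids[i])
    return folds


def _grid_points(grid: Dict[str, List]) -> List[Dict]:
    names = list(grid)
    return [dict(zip(names, combo))
            for combo in itertools.product(*(grid[n] for n in names))]


def tune(spec: ClassifierSpec, train_x: np.ndarray, train_y: np.ndarray,
         inner_folds: int = 5, seed: int = 0) -> Dict:
    """Choose hyperparameters by inner cross-validated accuracy.

    Every grid point is scored by ``inner_folds``-fold CV on the training
    data only; the argmax is returned with ties broken by grid order.
    """
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("cannot tune on single-class training data")
    points = _grid_points(spec.resolved_grid(train_x.shape[1]))
    if len(points) == 1:
        return points[0]
    k = min(inner_folds, len(train_y))
    fold_ids = make_folds([str(i) for i in range(len(train_y))], k, seed)
    splits = [np.array([int(s) for s in fold], dtype=int) for fold in fold_ids]
    best_params, best_acc = None, -1.0
    for params in points:
        correct = 0
        for test_idx in splits:
            mask = np.ones(len(train_y), dtype=bool)
            mask[test_idx] = False
            if len(np.unique(train_y[mask])) < 2:
                continue
            est = _make_estimator(spec.family, params, seed)
            est.fit(train_x[mask], train_y[mask])
            correct += int(np.sum(est.predict(train_x[test_idx]) == train_y[test_idx]))
        acc = correct / len(train_y)
        if acc > best_acc:
            best_acc, best_params = acc, params
    return best_params


@dataclass
class CVResult:
    """Everything one cross-validation run produces."""

    fold_outcome: FoldOutcome
    confusion: ConfusionMatrix
    accuracy: float
    rk: float
    chosen_params: List[Dict]
    seed: int
    fold_test_ids: List[List[str]]
    fold_feature_counts: List[int]


def cross_validate(matrix: DescriptorMatrix, labels: Sequence[int],
                   spec: ClassifierSpec, n_folds: int = 10, seed: int = 0,
                   is_similarity: bool = False, scale: Optional[bool] = None,
                   inner_folds: int = 5) -> CVResult:
    """Run the full cross-validation protocol on one descriptor matrix.

    For similarity matrices the reference columns of each fold's held-out
    entries are deleted before tuning and training.  Count and engineered
    descriptor matrices are z-scaled with parameters fitted on the training
    fold only (similarity values already live in [0, 1] and are left
    unscaled unless ``scale=True``).
    """
    ids = matrix.entry_ids
    y = np.asarray(labels, dtype=int)
    if len(y) != len(ids):
        raise ValueError("labels do not match matrix rows")
    if scale is None:
        scale = not is_similarity

    rng = np.random.default_rng(seed)
    folds = make_folds(ids, n_folds, seed)
    label_of = dict(zip(ids, y))

    all_true: List[int] = []
    all_pred: List[int] = []
    fold_correct: List[int] = []
    fold_sizes: List[int] = []
    chosen: List[Dict] = []
    feature_counts: List[int] = []

    for fold_idx, test_ids in enumerate(folds):
        test_set = set(test_ids)
        train_ids = [i for i in ids if i not in test_set]
        work = delete_test_columns(matrix, test_ids) if is_similarity else matrix
        train_m = work.rows(train_ids)
        test_m = work.rows(test_ids)
        if scale:
            params = zscale_fit(train_m)
            train_m = zscale_apply(train_m, params)
            test_m = zscale_apply(test_m, params)
        y_train = np.array([label_of[i] for i in train_ids])
        y_test = np.array([label_of[i] for i in test_ids])
        if len(np.unique(y_test)) < 2:
            warnings.warn(f"fold {fold_idx} holds a single class; predicting anyway")

        fold_seed = int(rng.integers(2 ** 31))
        params_hp = tune(spec, train_m.values, y_train,
                         inner_folds=inner_folds, seed=fold_seed)
        est = _make_estimator(spec.family, params_hp, fold_seed)
        est.fit(train_m.values, y_train)
        pred = np.asarray(est.predict(test_m.values), dtype=int)

        all_true.extend(y_test.tolist())
        all_pred.extend(pred.tolist())
        fold_correct.append(int(np.sum(pred == y_test)))
        fold_sizes.append(len(y_test))
        chosen.append(params_hp)
        feature_counts.append(train_m.values.shape[1])

    cm = confusion_matrix(all_true, all_pred, N_CLASSES)
    return CVResult(fold_outcome=FoldOutcome(correct=fold_correct, sizes=fold_sizes),
                    confusion=cm, accuracy=accuracy(cm), rk=gorodkin_rk(cm),
                    chosen_params=chosen, seed=seed, fold_test_ids=folds,
                    fold_feature_counts=feature_counts)


def rf_oob_accuracy(matrix: DescriptorMatrix, labels: Sequence[int],
                    rf_params: Optional[Dict] = None, seed: int = 0) -> float:
    """Out-of-bag accuracy of one forest grown on the full matrix.

    Each tree votes on the entries left out of its own bootstrap sample
    (about e^-1 of the data per tree).  Note this is an internal training
    measure: for similarity sets it does not apply the column deletions
    that the cross-validated results do.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("out-of-bag accuracy needs at least two classes")
    rf_params = dict(rf_params or {})
    mtry = rf_params.get("mtry", "sqrt")
    if mtry == "auto":
        mtry = "sqrt"
    forest = RandomForestClassifier(
        n_estimators=int(rf_params.get("n_trees", 500)),
        max_features=mtry, oob_score=True, bootstrap=True, random_state=seed)
    forest.fit(matrix.values, y)
    return float(forest.oob_score_)


@dataclass
class ExternalSplit:
    """Outcome of the third-level-non-redundant external split."""

    training: List[ReactionEntry]
    test: List[ReactionEntry]
    moved: List[ReactionEntry]


def _ec3(entry: ReactionEntry) -> str:
    return ".".join(entry.ec.split(".")[:3])


def external_split(base_training: Sequence[ReactionEntry],
                   new_entries: Sequence[ReactionEntry],
                   also_dedup_vs_training: bool = False) -> ExternalSplit:
    """Split new entries into a test set non-redundant at EC level three.

    New entries are scanned in input order; an entry repeating the
    first-three-level EC code of an already kept test entry (or, with the
    flag, of a base training entry) is moved to the training set.
    """
    seen = {_ec3(e) for e in base_training} if also_dedup_vs_training else set()
    test: List[ReactionEntry] = []
    moved: List[ReactionEntry] = []
    for e in new_entries:
        key = _ec3(e)
        if key in seen:
            moved.append(e)
        else:
            seen.add(key)
            test.append(e)
    return ExternalSplit(training=list(base_training) + moved, test=test, moved=moved)


def build_benchmark_matrix(entries: Sequence[ReactionEntry], kind: str,
                           reference_entries: Optional[Sequence[ReactionEntry]] = None,
                           registry: Optional[FeatureRegistry] = None,
                           feature_names: Optional[Sequence[str]] = None,
                           gap_penalty: float = 0.0) -> DescriptorMatrix:
    """Build the descriptor matrix for any of the five benchmark sets."""
    if kind not in DESCRIPTOR_KINDS:
        raise ValueError(f"kind must be one of {DESCRIPTOR_KINDS}, got {kind!r}")
    if kind in _SIMILARITY_KINDS:
        refs = reference_entries if reference_entries is not None else entries
        mode = "overall" if kind == "overall-sim" else "mechanism"
        return similarity_matrix(entries, refs, mode=mode, gap_penalty=gap_penalty)
    base_kind = {"human": "human", "overall-bond": "overall",
                 "composite-bond": "composite"}[kind]
    return build_descriptor_matrix(entries, base_kind, registry=registry,
                                   feature_names=feature_names)


def external_validate(split: ExternalSplit, kind: str, spec: ClassifierSpec,
                      seed: int = 0, registry: Optional[FeatureRegistry] = None,
                      gap_penalty: float = 0.0, inner_folds: int = 5) -> Dict:
    """Train on the split's training set, predict its external test set.

    Descriptors are defined by the training set: similarity matrices have
    one column per training entry (for test rows too), token matrices use
    the training token universe, and scaling of the count/engineered sets
    uses the training distributions.
    """
    if not split.test:
        raise ValueError("external split has an empty test set")
    train, test = split.training, split.test
    if kind in _SIMILARITY_KINDS:
        train_m = build_benchmark_matrix(train, kind, reference_entries=train,
                                         gap_penalty=gap_penalty)
        test_m = build_benchmark_matrix(test, kind, reference_entries=train,
                                        gap_penalty=gap_penalty)
        scale = False
    else:
        train_m = build_benchmark_matrix(train, kind, registry=registry)
        test_m = build_benchmark_matrix(test, kind, registry=registry,
                                        feature_names=train_m.feature_names)
        scale = True
    if scale:
        params = zscale_fit(train_m)
        train_m = zscale_apply(train_m, params)
        test_m = zscale_apply(test_m, params)

    y_train = np.array([e.ec_class for e in train])
    y_test = np.array([e.ec_class for e in test])
    params_hp = tune(spec, train_m.values, y_train, inner_folds=inner_folds, seed=seed)
    est = _make_estimator(spec.family, params_hp, seed)
    est.fit(train_m.values, y_train)
    pred = np.asarray(est.predict(test_m.values), dtype=int)
    cm = confusion_matrix(y_test.tolist(), pred.tolist(), N_CLASSES)
    return {
        "accuracy": accuracy(cm),
        "rk": gorodkin_rk(cm),
        "confusion": cm,
        "chosen_params": params_hp,
        "n_features": train_m.values.shape[1],
        "n_train": len(train),
        "n_test": len(test),
    }
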