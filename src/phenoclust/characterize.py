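"""Classifier-based cluster validation and Shapley-value characterization.

Cluster labels are validated with a stratified cross-validated gradient
boosted tree classifier; membership is then explained with exact
interventional Shapley attributions computed directly from the tree
ensembles (marginal-expectation value function over a background sample),
with a seeded permutation-sampling fallback for arbitrary models.

The exact method rests on the leaf decomposition of a tree: for a foreground
x and one background z, the coalition game walks a hybrid input through the
tree, so each leaf contributes value * indicator(U subset of S, V disjoint
from S) where U (V) are the path features where only x (only z) satisfies
the splits. The Shapley value of such a game is available in closed form,
and the full attribution is the background-averaged sum over leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .preprocess import FeatureMatrix

__all__ = [
    "ClassifierReport",
    "AttributionMatrix",
    "crossval_classifier",
    "select_best_run",
    "shapley_attributions",
    "rank_features",
]

DEFAULT_HYPERPARAMS = {"n_estimators": 200, "max_depth": 4, "learning_rate": 0.1}


@dataclass
class ClassifierReport:
    fold_accuracies: np.ndarray
    mean_accuracy: float  # pooled out-of-fold accuracy
    confusion: np.ndarray  # rows = true cluster, cols = predicted
    per_cluster_sensitivity: np.ndarray
    per_cluster_specificity: np.ndarray
    run_id: int = 0
    n_folds: int = 10
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "n_folds": self.n_folds,
            "fold_accuracies": self.fold_accuracies.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "confusion": self.confusion.tolist(),
            "per_cluster_sensitivity": self.per_cluster_sensitivity.tolist(),
            "per_cluster_specificity": self.per_cluster_specificity.tolist(),
            "notes": self.notes,
        }


@dataclass
class AttributionMatrix:
    """Signed per-sample, per-feature attributions for each model score column.

    ``phi`` has shape (n_score_columns, n_samples, n_features); for binary
    models sklearn exposes a single score column for the positive class and
    the negative class is its mirror image.
    """

    phi: np.ndarray
    base_values: np.ndarray
    feature_names: list[str]
    class_labels: np.ndarray
    feature_values: np.ndarray  # the explained matrix, for directionality
    binary: bool = False

    def for_class(self, cluster: int) -> tuple[np.ndarray, float]:
        """Attributions and base value on the score scale for one class."""
        classes = list(self.class_labels.tolist())
        if cluster not in classes:
            raise ValueError(f"unknown class {cluster!r}")
        if self.binary:
            sign = 1.0 if cluster == classes[1] else -1.0
            return sign * self.phi[0], float(sign * self.base_values[0])
        idx = classes.index(cluster)
        return self.phi[idx], float(self.base_values[idx])


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    k = classes.size
    lut = {c: i for i, c in enumerate(classes.tolist())}
    M = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[lut[t], lut[p]] += 1
    return M


def crossval_classifier(
    fm,
    labels,
    n_folds: int = 10,
    seed: int = 0,
    hyperparams: dict | None = None,
    run_id: int = 0,
) -> tuple[GradientBoostingClassifier, ClassifierReport]:
    """Stratified F-fold CV of a gradient-boosted tree multiclass classifier.

    Out-of-fold predictions are pooled into a single confusion matrix;
    ``mean_accuracy`` is the pooled out-of-fold accuracy. The returned model
    is refit on the full data.
    """
    X = np.asarray(getattr(fm, "values", fm), dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels describe a single cluster; nothing to predict")
    notes = []
    min_count = int(np.bincount(np.searchsorted(classes, y)).min())
    folds = n_folds
    if min_count < n_folds:
        folds = max(2, min_count)
        notes.append(
            f"smallest cluster has {min_count} members; folds reduced {n_folds}->{folds}"
        )
    hp = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_pred = np.empty(y.shape, dtype=y.dtype)
    fold_acc = []
    for train_idx, test_idx in skf.split(X, y):
        clf = GradientBoostingClassifier(random_state=seed, **hp)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        oof_pred[test_idx] = pred
        fold_acc.append(float(np.mean(pred == y[test_idx])))
    confusion = _confusion(y, oof_pred, classes)
    pooled_acc = float(np.trace(confusion) / confusion.sum())
    tp = np.diag(confusion).astype(float)
    fn = confusion.sum(axis=1) - tp
    fp = confusion.sum(axis=0) - tp
    tn = confusion.sum() - tp - fn - fp
    report = ClassifierReport(
        fold_accuracies=np.asarray(fold_acc),
        mean_accuracy=pooled_acc,
        confusion=confusion,
        per_cluster_sensitivity=tp / np.maximum(tp + fn, 1),
        per_cluster_specificity=tn / np.maximum(tn + fp, 1),
        run_id=run_id,
        n_folds=folds,
        notes=notes,
    )
    model = GradientBoostingClassifier(random_state=seed, **hp)
    model.fit(X, y)
    return model, report


def select_best_run(reports: list[ClassifierReport]) -> int:
    """run_id of the highest pooled accuracy; ties resolve to the lowest run_id."""
    if not reports:
        raise ValueError("no classifier reports supplied")
    ordered = sorted(reports, key=lambda r: (-r.mean_accuracy, r.run_id))
    return ordered[0].run_id


# --- exact interventional tree Shapley -------------------------------------

def _leaf_paths(tree) -> list[tuple[float, list[tuple[int, float, bool]]]]:
    """(leaf value, [(feature, threshold, goes_left), ...]) for every leaf."""
    t = tree.tree_
    out = []

    def walk(node: int, path: list[tuple[int, float, bool]]):
        if t.children_left[node] == -1:
            out.append((float(t.value[node].ravel()[0]), list(path)))
            return
        f, thr = int(t.feature[node]), float(t.threshold[node])
        walk(t.children_left[node], path + [(f, thr, True)])
        walk(t.children_right[node], path + [(f, thr, False)])

    walk(0, [])
    return out


def _tree_shap_interventional(
    tree, X: np.ndarray, Z: np.ndarray
) -> np.ndarray:
    """Exact Shapley attributions of one regression tree, background-averaged.

    Returns phi with shape (n, p); sum over features equals
    tree.predict(X) - mean(tree.predict(Z)) exactly.
    """
    n, p = X.shape
    B = Z.shape[0]
    phi = np.zeros((n, p))
    max_path = 64
    fact = np.array([factorial(i) for i in range(max_path + 2)], dtype=float)
    for value, path in _leaf_paths(tree):
        if not path:
            continue  # constant tree: contributes equally to f(x) and f(z)
        feats = sorted({f for f, _, _ in path})
        m = len(feats)
        pos = {f: i for i, f in enumerate(feats)}
        A = np.ones((n, m), dtype=bool)
        Bm = np.ones((B, m), dtype=bool)
        for f, thr, left in path:
            cx = X[:, f] <= thr if left else X[:, f] > thr
            cz = Z[:, f] <= thr if left else Z[:, f] > thr
            A[:, pos[f]] &= cx
            Bm[:, pos[f]] &= cz
        IU = A[:, None, :] & ~Bm[None, :, :]        # feature must join S
        IV = ~A[:, None, :] & Bm[None, :, :]        # feature must stay out
        ok = (A[:, None, :] | Bm[None, :, :]).all(axis=2)
        u = IU.sum(axis=2)
        v = IV.sum(axis=2)
        tot = u + v
        w_in = np.zeros_like(u, dtype=float)
        w_out = np.zeros_like(u, dtype=float)
        has_u = u >= 1
        has_v = v >= 1
        w_in[has_u] = fact[u[has_u] - 1] * fact[v[has_u]] / fact[tot[has_u]]
        w_out[has_v] = fact[u[has_v]] * fact[v[has_v] - 1] / fact[tot[has_v]]
        contrib = (
            IU * (w_in * ok)[:, :, None] - IV * (w_out * ok)[:, :, None]
        ).sum(axis=1) * (value / B)
        phi[:, feats] += contrib
    return phi


def _sampling_shapley(
    score_fn, X: np.ndarray, Z: np.ndarray, n_permutations: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded permutation-sampling Shapley with a marginal background."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    n_cols = score_fn(Z[:1]).shape[1]
    phi = np.zeros((n_cols, n, p))
    base = np.zeros(n_cols)
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        z = Z[int(rng.integers(0, Z.shape[0]))]
        hybrid = np.tile(z, (n, 1))
        prev = score_fn(hybrid)
        base += prev[0]  # every row identical before any feature is set
        for f in perm:
            hybrid[:, f] = X[:, f]
            cur = score_fn(hybrid)
            phi[:, :, f] += (cur - prev).T
            prev = cur
    phi /= n_permutations
    # telescoping makes sum(phi) + base equal the model score exactly
    return phi, base / n_permutations


def _score_matrix(model, X: np.ndarray) -> np.ndarray:
    s = model.decision_function(X)
    return s[:, None] if s.ndim == 1 else s


def shapley_attributions(
    model,
    fm,
    background: np.ndarray | None = None,
    max_background: int = 100,
    n_permutations: int = 64,
    seed: int = 0,
) -> AttributionMatrix:
    """Per-class signed attributions of the model's raw scores.

    For gradient-boosted tree ensembles the attributions are exact (local
    accuracy to numerical precision); other models with a decision_function
    or predict_proba fall back to seeded permutation sampling. The value
    function is the marginal (interventional) expectation over ``background``
    (default: a seeded subsample of the explained matrix itself).
    """
    X = np.asarray(getattr(fm, "values", fm), dtype=float)
    names = (
        list(fm.feature_names)
        if isinstance(fm, FeatureMatrix)
        else [f"x{i}" for i in range(X.shape[1])]
    )
    if background is None:
        if X.shape[0] > max_background:
            rng = np.random.default_rng(seed)
            background = X[rng.choice(X.shape[0], max_background, replace=False)]
        else:
            background = X
    Z = np.asarray(background, dtype=float)

    if isinstance(model, GradientBoostingClassifier):
        lr = model.learning_rate
        n_cols = model.estimators_.shape[1]
        phi = np.zeros((n_cols, X.shape[0], X.shape[1]))
        for stage in model.estimators_:
            for c in range(n_cols):
                phi[c] += lr * _tree_shap_interventional(stage[c], X, Z)
        base = _score_matrix(model, Z).mean(axis=0)
        return AttributionMatrix(
            phi=phi,
            base_values=base,
            feature_names=names,
            class_labels=model.classes_,
            feature_values=X,
            binary=(n_cols == 1),
        )

    if hasattr(model, "decision_function"):
        score_fn = lambda M: _score_matrix(model, M)  # noqa: E731
    elif hasattr(model, "predict_proba"):
        score_fn = model.predict_proba
    else:
        raise TypeError(
            "model supports neither exact tree attribution nor score sampling"
        )
    phi, base = _sampling_shapley(score_fn, X, Z, n_permutations, seed)
    classes = getattr(model, "classes_", np.arange(phi.shape[0]))
    return AttributionMatrix(
        phi=phi,
        base_values=base,
        feature_names=names,
        class_labels=np.asarray(classes),
        feature_values=X,
        binary=(phi.shape[0] == 1 and np.asarray(classes).size == 2),
    )


def rank_features(
    attr: AttributionMatrix, cluster: int, top_m: int | None = None
) -> list[tuple[str, float, int]]:
    """Features ordered by mean |attribution| for one cluster, with direction.

    Direction is the sign of the correlation between the feature's value and
    its attribution: +1 means high values push towards membership. Features
    with zero mean absolute attribution are dropped.
    """
    phi, _ = attr.for_class(cluster)
    X = attr.feature_values
    mean_abs = np.abs(phi).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    out = []
    for j in order:
        if mean_abs[j] <= 0:
            continue
        xj, pj = X[:, j], phi[:, j]
        if np.std(xj) > 0 and np.std(pj) > 0:
            direction = int(np.sign(np.corrcoef(xj, pj)[0, 1]))
        else:
            direction = 0
        out.append((attr.feature_names[j], float(mean_abs[j]), direction))
        if top_m is not None and len(out) >= top_m:
            break
    return out
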