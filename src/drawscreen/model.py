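"""Linear-SVM screening model: LOOCV evaluation, joint feature-subset and
cost selection, Platt probabilities, and confusion metrics.

The classifier is a linear soft-margin SVM (high-trait group = positive
class). Performance is estimated by leave-one-out cross-validation with
the z-score standardization refit inside every fold. Model selection
jointly searches feature subsets (greedy sequential floating forward
selection by default, exhaustive enumeration for small candidate pools)
and the soft-margin cost over a log grid, maximizing LOOCV accuracy with
ties broken by higher sensitivity, then fewer features, then lower cost.

Because the selection criterion *is* the reported LOOCV estimate, that
estimate is optimistically biased; :func:`nested_loocv` wraps the entire
search in an outer leave-one-out loop to measure the bias
(selection optimism), and :func:`selection_optimism` reports both numbers
side by side.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import svm
from .recording_io import FEATURE_NAMES

POSITIVE_CLASS = "high"

DEFAULT_COST_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0)

#: Table-style suffixes used for the pooled "all features" model.
SHAPE_SUFFIX = {
    "equilateral_triangle": "Equilateraltriangle",
    "inverted_triangle": "Invertedtriangle",
    "square": "Square",
    "sun": "Sun",
}


class ModelError(ValueError):
    pass


class UndefinedMetricError(ModelError):
    """A confusion metric's denominator is zero."""


@dataclass(frozen=True)
class ModelSpec:
    """A selected screening model: feature subset + SVM cost."""

    shape_id: str
    selected_features: tuple[str, ...]
    cost: float
    standardization: str = "zscore"  # or "none"

    def __post_init__(self) -> None:
        if not self.selected_features:
            raise ModelError("selected feature subset must be non-empty")
        if self.cost <= 0:
            raise ModelError(f"cost must be > 0, got {self.cost}")
        if self.standardization not in ("zscore", "none"):
            raise ModelError(f"unknown standardization {self.standardization!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ModelError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from confusion counts.

    sensitivity = recall of the high-trait class, specificity = recall of
    the low-trait class. Raises :class:`UndefinedMetricError` naming the
    first metric whose denominator is zero.
    """
    if counts.n == 0:
        raise UndefinedMetricError("accuracy undefined: no samples")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    return (
        (counts.tp + counts.tn) / counts.n,
        counts.tp / (counts.tp + counts.fn),
        counts.tn / (counts.tn + counts.fp),
    )


@dataclass
class CVResult:
    """Outcome of leave-one-out cross-validation for one model spec."""

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    predictions: pd.DataFrame  # participant_id, true, predicted, probability
    n_degenerate_folds: int = 0


def _encode_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    unknown = set(np.unique(lab)) - {POSITIVE_CLASS, "low"}
    if unknown:
        raise ModelError(f"unknown group label(s) {sorted(unknown)}")
    return np.where(lab == POSITIVE_CLASS, 1.0, -1.0)


def _platt_fit(dec: np.ndarray, y: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Platt sigmoid calibration P(high|f) = 1/(1+exp(A f + B)).

    Newton's method with backtracking on the regularized maximum-likelihood
    problem (targets smoothed toward 1/2 to keep A finite on separable
    data). ``y`` in {-1, +1}. Deterministic.
    """
    prior1 = float(np.sum(y > 0))
    prior0 = float(np.sum(y < 0))
    hi_t = (prior1 + 1.0) / (prior1 + 2.0)
    lo_t = 1.0 / (prior0 + 2.0)
    t = np.where(y > 0, hi_t, lo_t)
    a, b = 0.0, np.log((prior0 + 1.0) / (prior1 + 1.0))
    eps = 1e-12

    def nll(a_, b_):
        # sum t*z + log(1+exp(-z)), computed stably for large |z|
        z = a_ * dec + b_
        return float(
            np.sum(t * z + np.where(z >= 0, np.log1p(np.exp(-z)), -z + np.log1p(np.exp(z))))
        )

    f_old = nll(a, b)
    for _ in range(max_iter):
        z = a * dec + b
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
        d1 = p * (1.0 - p)
        g_a = float(np.sum(dec * (t - p)))
        g_b = float(np.sum(t - p))
        if abs(g_a) < 1e-10 and abs(g_b) < 1e-10:
            break
        h_aa = float(np.sum(dec * dec * d1)) + eps
        h_bb = float(np.sum(d1)) + eps
        h_ab = float(np.sum(dec * d1))
        det = h_aa * h_bb - h_ab * h_ab
        da = -(h_bb * g_a - h_ab * g_b) / det
        db = -(-h_ab * g_a + h_aa * g_b) / det
        step = 1.0
        while step >= 1e-10:
            f_new = nll(a + step * da, b + step * db)
            if f_new < f_old + 1e-12:
                a, b = a + step * da, b + step * db
                f_old = f_new
                break
            step /= 2.0
        else:
            break
    return a, b


def predict_probability(A: float, B: float, decision_values: np.ndarray) -> np.ndarray:
    """Platt-calibrated probability of the high-trait group.

    Strictly increasing in the decision value whenever ``A < 0`` (the
    fitted slope is negative for any model better than chance).
    """
    z = A * np.asarray(decision_values, float) + B
    return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


def _design_matrix(features: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    missing = [n for n in names if n not in features.columns]
    if missing:
        raise ModelError(f"feature table missing column(s) {missing}")
    return np.ascontiguousarray(features[list(names)].to_numpy(dtype=np.float64))


def loocv_confusion(
    features: pd.DataFrame,
    labels,
    spec: ModelSpec,
    with_probabilities: bool = True,
) -> CVResult:
    """Leave-one-out evaluation of a fixed model spec.

    Each participant is predicted by an SVM trained on the other n-1,
    standardized with those n-1 rows only. Probabilities come from a
    Platt sigmoid fitted per fold on the fold's own training decision
    values. Deterministic given inputs.
    """
    y = _encode_labels(labels)
    if len(y) < 3:
        raise ModelError(f"need n >= 3 participants, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise ModelError("both classes must be present overall")
    X = _design_matrix(features, spec.selected_features)
    if spec.standardization == "none":
        # bypass per-fold scaling by pre-standardizing to identity stats
        dec, degen = _loocv_nostd(X, y, spec.cost)
    else:
        dec, degen = svm.loocv_decisions(X, y, spec.cost)
    if degen.any():
        warnings.warn(
            f"{int(degen.sum())} degenerate single-class training fold(s); "
            "those folds predict the training class",
            stacklevel=2,
        )
    pred = np.where(dec > 0, 1.0, -1.0)
    tp = int(np.sum((pred > 0) & (y > 0)))
    fn = int(np.sum((pred < 0) & (y > 0)))
    tn = int(np.sum((pred < 0) & (y < 0)))
    fp = int(np.sum((pred > 0) & (y < 0)))
    counts = ConfusionCounts(tp, fn, tn, fp)
    acc, sens, spc = confusion_metrics(counts)

    probs = np.full(len(y), np.nan)
    if with_probabilities:
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            ytr = y[mask]
            if len(np.unique(ytr)) < 2:
                probs[i] = 1.0 if dec[i] > 0 else 0.0
                continue
            m = svm.LinearSVM(C=spec.cost, standardize=spec.standardization == "zscore")
            m.fit(X[mask], ytr)
            A, B = _platt_fit(m.decision_function(X[mask]), ytr)
            probs[i] = predict_probability(A, B, np.array([dec[i]]))[0]

    pid = (
        features["participant_id"].to_numpy()
        if "participant_id" in features.columns
        else np.arange(len(y))
    )
    predictions = pd.DataFrame(
        {
            "participant_id": pid,
            "true": np.where(y > 0, "high", "low"),
            "predicted": np.where(pred > 0, "high", "low"),
            "probability_high": probs,
        }
    )
    return CVResult(counts, acc, sens, spc, predictions, int(degen.sum()))


def _loocv_nostd(X: np.ndarray, y: np.ndarray, cost: float):
    """LOOCV without standardization (for sensitivity analyses)."""
    n = len(y)
    dec = np.empty(n)
    degen = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = np.arange(n) != i
        ytr = y[mask]
        if len(np.unique(ytr)) < 2:
            degen[i] = True
            dec[i] = float(ytr[0]) * 1e6
            continue
        m = svm.LinearSVM(C=cost, standardize=False).fit(X[mask], ytr)
        dec[i] = m.decision_function(X[i : i + 1])[0]
    return dec, degen


# ---------------------------------------------------------------------------
# Joint feature-subset + cost selection


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of the wrapper search.

    strategy:
        ``"greedy"`` (sequential floating forward selection, default) or
        ``"exhaustive"`` (all subsets up to ``max_features``; only
        sensible for <= ~10 candidates).
    cost_grid:
        Soft-margin costs to try (log grid by default).
    max_features:
        Upper bound on subset size; the published shape models used four
        to eight variables, so 8 is the default cap.
    candidates:
        Candidate feature names; ``None`` = the 16 canonical variables
        present in the table (or every non-id column for pooled tables).
    """

    strategy: str = "greedy"
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    max_features: int = 8
    candidates: tuple[str, ...] | None = None


@dataclass
class SelectionResult:
    spec: ModelSpec
    cv: CVResult
    n_evaluations: int
    #: (accuracy, sensitivity, -n_features, -cost) of the winning model
    score: tuple[float, float, float, float] = field(default=None)


def _score_tuple(counts: tuple[int, int, int, int], nfeat: int, cost: float):
    tp, fn, tn, fp = counts
    n = tp + fn + tn + fp
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else 0.0
    return (acc, sens, -nfeat, -cost)


def _resolve_candidates(features: pd.DataFrame, search: SearchConfig) -> list[str]:
    if search.candidates is not None:
        return list(search.candidates)
    canon = [n for n in FEATURE_NAMES if n in features.columns]
    if canon:
        return canon
    return [c for c in features.columns if c not in ("participant_id", "group")]


def select_model(
    features: pd.DataFrame,
    labels,
    search: SearchConfig = SearchConfig(),
    shape_id: str = "unknown",
) -> SelectionResult:
    """Jointly select a feature subset and cost maximizing LOOCV accuracy.

    Ties are broken by higher sensitivity, then fewer features, then lower
    cost. Deterministic: candidates are scanned in column order, costs in
    ascending order, and a candidate replaces the incumbent only on a
    strictly better score tuple.
    """
    y = _encode_labels(labels)
    candidates = _resolve_candidates(features, search)
    if len(candidates) < 1:
        raise ModelError("no candidate features")
    X_all = _design_matrix(features, tuple(candidates))
    col_of = {name: k for k, name in enumerate(candidates)}
    cache: dict[tuple[tuple[int, ...], float], tuple[int, int, int, int]] = {}
    n_eval = 0

    def evaluate(subset: tuple[str, ...], cost: float):
        nonlocal n_eval
        key = (tuple(sorted(col_of[f] for f in subset)), cost)
        if key not in cache:
            Xs = np.ascontiguousarray(X_all[:, list(key[0])])
            cache[key] = svm.loocv_confusion_counts(Xs, y, cost)
            n_eval += 1
        return cache[key]

    costs = tuple(sorted(search.cost_grid))
    max_k = min(search.max_features, len(candidates))

    def best_over_costs(subset: tuple[str, ...]):
        best = None
        for c in costs:
            sc = _score_tuple(evaluate(subset, c), len(subset), c)
            if best is None or sc > best[0]:
                best = (sc, c)
        return best

    if search.strategy == "exhaustive":
        best_sc, best_subset, best_cost = None, None, None
        for k in range(1, max_k + 1):
            for combo in itertools.combinations(candidates, k):
                sc, c = best_over_costs(combo)
                if best_sc is None or sc > best_sc:
                    best_sc, best_subset, best_cost = sc, combo, c
        spec = ModelSpec(shape_id, best_subset, best_cost)
        cv = loocv_confusion(features, labels, spec)
        return SelectionResult(spec, cv, n_eval, best_sc)

    if search.strategy != "greedy":
        raise ModelError(f"unknown search strategy {search.strategy!r}")

    # Sequential floating forward selection.
    current: list[str] = []
    best_by_size: dict[int, tuple[tuple, tuple[str, ...], float]] = {}
    overall: tuple | None = None

    while len(current) < max_k:
        step_best = None
        for f in candidates:
            if f in current:
                continue
            subset = tuple(current) + (f,)
            sc, c = best_over_costs(subset)
            if step_best is None or sc > step_best[0]:
                step_best = (sc, subset, c)
        if step_best is None:
            break
        if overall is not None and step_best[0] <= overall[0]:
            break  # no strict improvement from growing the subset
        current = list(step_best[1])
        best_by_size[len(current)] = step_best
        overall = step_best if overall is None or step_best[0] > overall[0] else overall
        # floating: drop features while a smaller subset improves its record
        while len(current) > 2:
            drop_best = None
            for f in current:
                subset = tuple(x for x in current if x != f)
                sc, c = best_over_costs(subset)
                if drop_best is None or sc > drop_best[0]:
                    drop_best = (sc, subset, c)
            k = len(current) - 1
            if k in best_by_size and drop_best[0] <= best_by_size[k][0]:
                break
            best_by_size[k] = drop_best
            current = list(drop_best[1])
            if drop_best[0] > overall[0]:
                overall = drop_best

    if overall is None:  # single-candidate pool or max_features = 0
        sc, c = best_over_costs((candidates[0],))
        overall = (sc, (candidates[0],), c)

    spec = ModelSpec(shape_id, overall[1], overall[2])
    cv = loocv_confusion(features, labels, spec)
    return SelectionResult(spec, cv, n_eval, overall[0])


# ---------------------------------------------------------------------------
# Nested cross-validation (selection-optimism audit)


def nested_loocv(
    features: pd.DataFrame,
    labels,
    search: SearchConfig = SearchConfig(),
    outer_folds: int | None = None,
    seed: int = 0,
) -> dict:
    """Nested LOOCV: the whole search is re-run inside every outer fold.

    The outer estimate is unbiased by selection because each held-out
    participant never influences the subset/cost chosen for them.
    ``outer_folds`` optionally evaluates a stratified random subsample of
    outer folds (a Monte Carlo estimate of the same accuracy) to bound
    runtime; ``None`` runs all n folds.
    """
    y = _encode_labels(labels)
    n = len(y)
    idx = np.arange(n)
    if outer_folds is not None and outer_folds < n:
        rng = np.random.default_rng(seed)
        pos, neg = idx[y > 0], idx[y < 0]
        k_pos = max(1, int(round(outer_folds * len(pos) / n)))
        k_neg = outer_folds - k_pos
        chosen = np.concatenate(
            [rng.choice(pos, size=min(k_pos, len(pos)), replace=False),
             rng.choice(neg, size=min(k_neg, len(neg)), replace=False)]
        )
        outer = np.sort(chosen)
    else:
        outer = idx

    correct = 0
    records = []
    for i in outer:
        mask = idx != i
        inner = select_model(
            features.iloc[mask].reset_index(drop=True),
            np.asarray(labels)[mask],
            search,
        )
        m = svm.LinearSVM(
            C=inner.spec.cost, standardize=inner.spec.standardization == "zscore"
        )
        Xtr = _design_matrix(features.iloc[mask], inner.spec.selected_features)
        Xte = _design_matrix(features.iloc[[i]], inner.spec.selected_features)
        m.fit(Xtr, y[mask])
        pred = 1.0 if m.decision_function(Xte)[0] > 0 else -1.0
        correct += int(pred == y[i])
        records.append(
            {"index": int(i), "true": "high" if y[i] > 0 else "low",
             "predicted": "high" if pred > 0 else "low",
             "n_selected": len(inner.spec.selected_features)}
        )
    return {
        "nested_accuracy": correct / len(outer),
        "n_outer_folds": int(len(outer)),
        "folds": records,
    }


def selection_optimism(
    features: pd.DataFrame,
    labels,
    search: SearchConfig = SearchConfig(),
    outer_folds: int | None = None,
    seed: int = 0,
) -> dict:
    """Selection-optimized LOOCV accuracy vs nested LOOCV accuracy.

    The difference (``optimism_gap``) measures how much the reported
    estimate is inflated by letting selection optimize the very estimate
    being reported.
    """
    sel = select_model(features, labels, search)
    nested = nested_loocv(features, labels, search, outer_folds=outer_folds, seed=seed)
    return {
        "selected_loocv_accuracy": sel.cv.accuracy,
        "selected_features": list(sel.spec.selected_features),
        "selected_cost": sel.spec.cost,
        "nested_accuracy": nested["nested_accuracy"],
        "n_outer_folds": nested["n_outer_folds"],
        "optimism_gap": sel.cv.accuracy - nested["nested_accuracy"],
    }


def build_all_features_table(per_shape: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Join per-shape sheets into one wide table with shape-suffixed names.

    ``Mpenpressure`` from the square sheet becomes ``MpenpressureSquare``,
    matching the naming style of the pooled published model.
    """
    wide = None
    for shape, df in per_shape.items():
        suffix = SHAPE_SUFFIX.get(shape, shape.title().replace("_", ""))
        renamed = df.rename(columns={n: f"{n}{suffix}" for n in FEATURE_NAMES})
        wide = renamed if wide is None else wide.merge(
            renamed, on=[c for c in ("participant_id", "group") if c in renamed.columns],
            how="inner",
        )
    return wide
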