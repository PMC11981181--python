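"""Exact Shapley-value attributions for fitted linear screening models.

For a linear decision function ``f(x) = w . x + b`` with an independent
(interventional) background distribution, the Shapley value of feature j
for case i has the closed form

    phi_ij = w_j * (x_ij - E_bg[x_j]),

and local accuracy holds exactly: ``base_value + sum_j phi_ij = f(x_i)``
with ``base_value = E_bg[f(x)]``. Attributions are computed on the
decision function (not the calibrated probability) so that this exactness
is preserved; the background set is the full training cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import svm
from .model import ModelSpec, _design_matrix, _encode_labels


@dataclass
class ShapMatrix:
    """Per-participant, per-feature Shapley contributions (decision units)."""

    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    feature_names: tuple[str, ...]
    decision_values: np.ndarray  # (n_samples,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.feature_names))


def linear_shap(
    w: np.ndarray,
    b: float,
    background: np.ndarray,
    X: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
) -> ShapMatrix:
    """Exact Shapley attributions of ``f(x) = w.x + b`` against a background.

    ``background`` supplies the expectation; ``X`` are the cases to
    explain. Feature-dimension mismatches raise ``ValueError``.
    """
    w = np.asarray(w, float)
    background = np.atleast_2d(np.asarray(background, float))
    X = np.atleast_2d(np.asarray(X, float))
    if background.shape[1] != w.size or X.shape[1] != w.size:
        raise ValueError(
            f"feature-dimension mismatch: w has {w.size}, background "
            f"{background.shape[1]}, X {X.shape[1]}"
        )
    if background.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    mu = background.mean(axis=0)
    phi = (X - mu) * w
    base = float(w @ mu + b)
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{j}" for j in range(w.size)
    )
    return ShapMatrix(phi, base, names, X @ w + b)


def explain_model(
    features: pd.DataFrame,
    labels,
    spec: ModelSpec,
) -> ShapMatrix:
    """Refit ``spec`` on the full cohort and attribute every participant.

    The SVM is fit (with its standardization) on all rows; attributions
    are taken in standardized-feature space, which equals the raw-space
    form ``(w_j / sd_j)(x_ij - mean_j)`` because z-scoring is affine.
    """
    y = _encode_labels(labels)
    X = _design_matrix(features, spec.selected_features)
    m = svm.LinearSVM(C=spec.cost, standardize=spec.standardization == "zscore")
    m.fit(X, y)
    Z = (X - m.mean_) / m.scale_
    return linear_shap(m.coef_, m.intercept_, Z, Z, spec.selected_features)


def feature_impact_ranking(shap: ShapMatrix) -> list[tuple[str, float]]:
    """Features ordered by mean absolute contribution, descending.

    Ties (exactly equal impacts) are broken alphabetically.
    """
    impact = np.mean(np.abs(shap.values), axis=0)
    order = sorted(zip(shap.feature_names, impact), key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(v)) for name, v in order]


def beeswarm_summary(shap: ShapMatrix, X: np.ndarray, path) -> None:
    """Write a summary plot: one row per feature (impact-ordered), points
    jittered vertically, colored by the (min-max scaled) feature value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = np.atleast_2d(np.asarray(X, float))
    ranking = feature_impact_ranking(shap)
    names = [n for n, _ in ranking][::-1]
    idx = {n: j for j, n in enumerate(shap.feature_names)}
    rng = np.random.default_rng(0)
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(names) + 1.5))
    for row, name in enumerate(names):
        j = idx[name]
        vals = X[:, j]
        span = np.ptp(vals)
        color = (vals - vals.min()) / span if span > 0 else np.full_like(vals, 0.5)
        ax.scatter(
            shap.values[:, j],
            row + rng.uniform(-0.18, 0.18, size=len(vals)),
            c=color, cmap="coolwarm", s=12, linewidths=0,
        )
    ax.axvline(0.0, color="gray", lw=0.8)
    ax.set_yticks(range(len(names)))
    ax.set_yticklabels(names, fontsize=8)
    ax.set_xlabel("Shapley contribution to decision value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
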