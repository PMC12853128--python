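"""Group-level feature selection: Yeo–Johnson preprocessing, greedy
incremental feature selection (IFS) over feature groups, and the two
normalized group scores used to rank groups under RFE and Elastic Net.

IFS starts from the best single group by cross-validated F1 and adds the
group that most improves the score, stopping when no addition strictly
improves it; ties are resolved toward the smaller set (Occam's razor).  The
group scores normalize a selected-feature count by the square root of the
group width so that large groups are not over-penalized:

    rfe_score   = (count in top 100) / sqrt(group width)
    enet_score  = n_g / (n_s * sqrt(f_g))

with n_g the group's selected features, n_s the total selected and f_g the
group width.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import PowerTransformer


@dataclass(frozen=True)
class FeatureGroup:
    """A named, contiguous column range of a combined design matrix."""

    name: str
    start: int
    stop: int

    @property
    def width(self) -> int:
        return self.stop - self.start

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"group {self.name}: empty column range")


@dataclass
class SelectionResult:
    chosen_groups: list[str]
    trace: list[dict] = field(default_factory=list)


def yeo_johnson_fit_apply(
    matrix: np.ndarray, fit_rows: np.ndarray | Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Yeo–Johnson power transform.

    Lambdas are maximum-likelihood estimates on ``fit_rows`` only (all rows by
    default); the transform is then applied to every row.  Constant columns
    pass through unchanged with a warning.  Returns (transformed, lambdas);
    pass-through columns report lambda = 1.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("design matrix contains non-finite entries")
    fit = matrix if fit_rows is None else matrix[np.asarray(fit_rows)]
    constant = fit.std(axis=0) == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s): identity transform applied"
        )
    out = matrix.copy()
    lambdas = np.ones(matrix.shape[1])
    varying = np.flatnonzero(~constant)
    if varying.size:
        pt = PowerTransformer(method="yeo-johnson", standardize=False)
        pt.fit(fit[:, varying])
        out[:, varying] = pt.transform(matrix[:, varying])
        lambdas[varying] = pt.lambdas_
    return out, lambdas


def yeo_johnson_invert(
    transformed: np.ndarray, lambdas: np.ndarray
) -> np.ndarray:
    """Inverse of :func:`yeo_johnson_fit_apply` given the fitted lambdas.

    The transform is sign-preserving, so the positive/negative branches of
    the closed-form inverse are selected by the sign of the transformed value.
    """
    Y = np.asarray(transformed, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    out = np.empty_like(Y)
    for j, lam in enumerate(lambdas):
        y = Y[:, j]
        pos = y >= 0
        if abs(lam) > 1e-12:
            out[pos, j] = np.power(lam * y[pos] + 1.0, 1.0 / lam) - 1.0
        else:
            out[pos, j] = np.expm1(y[pos])
        if abs(2.0 - lam) > 1e-12:
            out[~pos, j] = 1.0 - np.power(
                -(2.0 - lam) * y[~pos] + 1.0, 1.0 / (2.0 - lam)
            )
        else:
            out[~pos, j] = 1.0 - np.exp(-y[~pos])
    return out


def cv_f1_scorer(
    design: np.ndarray,
    labels: np.ndarray,
    groups: Mapping[str, FeatureGroup],
    learner,
    folds: int = 10,
    seed: int = 0,
) -> Callable[[frozenset[str]], float]:
    """Build a subset → stratified-CV-F1 scorer around a sklearn-style learner."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate labels: only one class present")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    def score(subset: frozenset[str]) -> float:
        cols = np.concatenate(
            [np.arange(groups[g].start, groups[g].stop) for g in sorted(subset)]
        )
        X = design[:, cols]
        f1s = []
        for train_idx, test_idx in cv.split(X, labels):
            model = clone(learner)
            model.fit(X[train_idx], labels[train_idx])
            f1s.append(f1_score(labels[test_idx], model.predict(X[test_idx])))
        return float(np.mean(f1s))

    return score


def ifs_greedy(
    group_names: Sequence[str],
    score_fn: Callable[[frozenset[str]], float],
) -> SelectionResult:
    """Greedy forward selection over feature groups.

    ``score_fn`` maps a set of group names to a cross-validated score.  The
    search starts with the best single group and keeps adding the best next
    group while the score strictly improves; a tie stops the search with the
    smaller set.
    """
    if not group_names:
        raise ValueError("no feature groups to select from")
    remaining = set(group_names)
    singles = {g: score_fn(frozenset({g})) for g in sorted(remaining)}
    current = max(sorted(singles), key=lambda g: singles[g])
    chosen = [current]
    best = singles[current]
    trace = [{"candidates": dict(singles), "chosen": list(chosen), "score": best}]
    remaining.discard(current)
    while remaining:
        scores = {
            g: score_fn(frozenset(chosen) | {g}) for g in sorted(remaining)
        }
        candidate = max(sorted(scores), key=lambda g: scores[g])
        if scores[candidate] <= best:  # tie → keep the smaller set
            trace.append(
                {"candidates": scores, "chosen": list(chosen), "score": best,
                 "stopped": True}
            )
            break
        chosen.append(candidate)
        best = scores[candidate]
        remaining.discard(candidate)
        trace.append({"candidates": scores, "chosen": list(chosen), "score": best})
    return SelectionResult(chosen_groups=chosen, trace=trace)


def rfe_group_score(count_in_top100: int, group_width: int) -> float:
    """RFE group score: top-100 feature count over sqrt(group width)."""
    if group_width < 1:
        raise ValueError("group width must be >= 1")
    if not 0 <= count_in_top100 <= min(100, group_width):
        raise ValueError(
            f"count {count_in_top100} impossible for width {group_width}"
        )
    return count_in_top100 / math.sqrt(group_width)


def enet_group_score(n_g: int, n_s: int, f_g: int) -> float:
    """Elastic-Net group score: n_g / (n_s * sqrt(f_g))."""
    if n_s < 1:
        raise ValueError("total selected feature count must be >= 1")
    if not 0 <= n_g <= min(n_s, f_g):
        raise ValueError(f"n_g={n_g} impossible for n_s={n_s}, f_g={f_g}")
    return n_g / (n_s * math.sqrt(f_g))
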