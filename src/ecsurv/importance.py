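"""Fussell-Vesely-style variable importance and rank-based selection.

For every predictor V with states j = 1..m the table reports the empirical
state distribution P(V=j), the conditional 5-year survival P(Alive|V=j),
and a mean multi-state Fussell-Vesely (MMFV) importance computed from the
fitted network: with P(D) the model's marginal death probability and
P(D|V=j) obtained by exact inference,

    MMFV(V) = (1/m) * sum_j max(0, P(D|V=j) - min_k P(D|V=k)) / P(D),

i.e. the average over states of the positive part of the relative excess
death probability of state j over the variable's most favorable state. A
variable that is independent of the outcome in the model scores 0.
Variables are ranked by descending MMFV (ties broken by codebook order),
and the forward selection fits the classifier on the top-k ranked variables,
choosing k by stratified cross-validated accuracy (ties to the smaller k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import Cohort
from .tan import (
    ALIVE,
    DEAD,
    TanModel,
    class_conditional_marginals,
    fit_tan,
    posterior_alive_many,
)

__all__ = [
    "ImportanceRow",
    "ImportanceTable",
    "state_distribution",
    "conditional_survival",
    "mmfv",
    "rank_variables",
    "build_importance_table",
    "select_top_k",
]


def state_distribution(cohort: Cohort, v: str) -> np.ndarray:
    """Empirical relative frequency of each level of ``v``."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    j = cohort.codebook.index_of(v)
    k = cohort.codebook[v].n_levels
    counts = np.bincount(cohort.levels[:, j], minlength=k)
    return counts / counts.sum()


def conditional_survival(cohort: Cohort, v: str) -> np.ndarray:
    """Fraction of 5-year survivors at each level of ``v``.

    Computed over determinate records only; a level with no determinate
    record is undefined and reported as NaN (with a warning).
    """
    det = cohort.determinate()
    if len(det) == 0:
        raise ValueError("cohort has no determinate records")
    j = det.codebook.index_of(v)
    k = det.codebook[v].n_levels
    x = det.levels[:, j]
    alive = (det.label_array() == 1).astype(float)
    totals = np.bincount(x, minlength=k).astype(float)
    survivors = np.bincount(x, weights=alive, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = survivors / totals
    if np.isnan(out).any():
        warnings.warn(
            f"variable {v!r}: level(s) {np.flatnonzero(totals == 0).tolist()} "
            "have no determinate records; conditional survival undefined",
            stacklevel=2,
        )
    return out


def mmfv(model: TanModel, v: str) -> float:
    """Mean multi-state Fussell-Vesely importance of ``v`` under the model."""
    if v not in model.structure.attributes:
        raise KeyError(f"variable {v!r} is not an attribute of the model")
    marg = class_conditional_marginals(model)[v]  # (2, k)
    joint = model.class_prior[:, None] * marg  # P(c, V=j)
    p_dead_given = joint[DEAD] / joint.sum(axis=0)
    p_dead = float(model.class_prior[DEAD])
    best = p_dead_given.min()
    return float(np.mean(np.maximum(0.0, p_dead_given - best)) / p_dead)


def rank_variables(values: dict[str, float]) -> list[str]:
    """Variables ordered by descending importance; ties keep input order.

    Rank 1 is the largest value. The input mapping's order (codebook order
    in normal use) is the documented tie-break.
    """
    if not values:
        raise ValueError("need at least one value")
    names = list(values)
    return sorted(names, key=lambda n: (-values[n], names.index(n)))


@dataclass(frozen=True)
class ImportanceRow:
    variable: str
    state_probabilities: tuple[float, ...]
    conditional_survival: tuple[float, ...]
    mmfv: float
    rank: int


@dataclass(frozen=True)
class ImportanceTable:
    rows: tuple[ImportanceRow, ...]

    def __post_init__(self) -> None:
        ranks = sorted(r.rank for r in self.rows)
        if ranks != list(range(1, len(self.rows) + 1)):
            raise ValueError("ranks must be a permutation of 1..#variables")

    def ranked_names(self) -> list[str]:
        return [r.variable for r in sorted(self.rows, key=lambda r: r.rank)]

    def to_frame(self, codebook=None) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            levels = (
                codebook[row.variable].levels
                if codebook is not None
                else [str(j) for j in range(len(row.state_probabilities))]
            )
            for j, level in enumerate(levels):
                recs.append(
                    {
                        "variable": row.variable,
                        "level": level,
                        "p_state": row.state_probabilities[j],
                        "p_alive_given_state": row.conditional_survival[j],
                        "mmfv": row.mmfv,
                        "rank": row.rank,
                    }
                )
        return pd.DataFrame(recs)


def build_importance_table(cohort: Cohort, model: TanModel) -> ImportanceTable:
    """Per-variable state probabilities, conditional survival, MMFV, rank."""
    attrs = list(model.structure.attributes)
    values = {v: mmfv(model, v) for v in attrs}
    order = rank_variables(values)
    rank_of = {name: i + 1 for i, name in enumerate(order)}
    rows = tuple(
        ImportanceRow(
            variable=v,
            state_probabilities=tuple(state_distribution(cohort, v)),
            conditional_survival=tuple(conditional_survival(cohort, v)),
            mmfv=values[v],
            rank=rank_of[v],
        )
        for v in attrs
    )
    return ImportanceTable(rows)


def select_top_k(
    train: Cohort,
    ranked: list[str],
    k_grid: list[int],
    folds: int = 5,
    seed: int = 0,
    *,
    alpha: float = 1.0,
) -> list[str]:
    """Forward selection along the importance ranking.

    For each candidate k, fits the classifier on the top-k ranked variables
    with stratified ``folds``-fold cross-validation on the training
    determinate records and scores mean fold accuracy at threshold 0.5;
    returns the top-k variable list for the best k (ties to the smaller k).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ks = sorted(set(k_grid))
    if not ks or ks[0] < 1 or ks[-1] > len(ranked):
        raise ValueError("k_grid must be a subset of 1..#ranked variables")
    if len(ks) == 1:
        return ranked[: ks[0]]
    det = train.determinate()
    y = det.label_array()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(det)), y))
    best_k, best_acc = None, -np.inf
    for k in ks:
        attrs = ranked[:k]
        accs = []
        for tr_idx, va_idx in splits:
            fold_train = det.take(tr_idx)
            if len(np.unique(fold_train.label_array())) < 2:
                raise ValueError("cross-validation fold contains a single class")
            model = fit_tan(fold_train, attrs, alpha=alpha)
            post = posterior_alive_many(model, det.levels[va_idx])
            pred = (post >= 0.5).astype(np.int64)
            accs.append(float(np.mean(pred == y[va_idx])))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc + 1e-12:
            best_k, best_acc = k, mean_acc
    return ranked[:best_k]
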