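"""Feature standardization, Fisher discriminant ranking and top-N selection.

Every feature is standardized to mean 0 / sd 1 using *training-row*
statistics only, then weighted by its Fisher discriminant score

    W_f = [ (1/(C-1)) sum_c (m_fc - m_f)^2 ] / [ (1/C) sum_c v_fc + eps ]

the ratio of inter-group variance (of the class means around their grand
mean) to the mean intra-group variance.  Features are ranked by descending
score; ties break by manifest (column) order so the ranking is
deterministic.  By default ranking uses training rows only; an opt-in
``on_all_rows`` mode ranks on the full table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StandardizationParams",
    "FisherRanking",
    "standardize",
    "fisher_scores",
    "select_top",
    "sweep_feature_counts",
]

FISHER_EPS = 1e-12


@dataclass
class StandardizationParams:
    """Per-feature mean/sd learned from training rows (sample sd, ddof=1)."""

    mean: pd.Series
    sd: pd.Series
    zero_sd_features: list[str] = field(default_factory=list)

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        safe_sd = self.sd.replace(0.0, 1.0)
        out = (data - self.mean) / safe_sd
        if self.zero_sd_features:
            out[self.zero_sd_features] = 0.0
        return out


def standardize(
    data: pd.DataFrame, fit_rows: np.ndarray | list | None = None
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Column-wise (x - mean) / sd using statistics of ``fit_rows`` only.

    ``fit_rows`` is a positional index of training rows (default: all).
    Test rows are transformed with the training parameters — no leakage.
    Zero-sd columns map to 0 and are flagged.
    """
    if fit_rows is None:
        fit = data
    else:
        fit = data.iloc[np.asarray(fit_rows)]
    if len(fit) < 2:
        raise ValueError("need >= 2 fit rows to estimate a standard deviation")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=1)
    zero = sd.index[sd <= 0].tolist()
    params = StandardizationParams(mean, sd, zero)
    return params.transform(data), params


@dataclass
class FisherRanking:
    """Per-feature Fisher scores and the induced descending ordering."""

    scores: pd.Series  # indexed by feature name, manifest order
    ordering: np.ndarray  # permutation of positional feature indices
    tie_rule: str = "manifest_order"

    def __post_init__(self) -> None:
        if sorted(self.ordering.tolist()) != list(range(len(self.scores))):
            raise ValueError("ordering is not a permutation")

    def to_frame(self) -> pd.DataFrame:
        ranks = np.empty(len(self.scores), dtype=int)
        ranks[self.ordering] = np.arange(1, len(self.scores) + 1)
        return pd.DataFrame(
            {"fisher_score": self.scores.values, "rank": ranks},
            index=self.scores.index,
        )


def fisher_scores(
    data: pd.DataFrame, labels: pd.Series | np.ndarray
) -> FisherRanking:
    """Fisher discriminant score per feature, and the descending ranking."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    X = data.to_numpy(dtype=np.float64)
    C = classes.size
    means = np.empty((C, X.shape[1]))
    variances = np.empty((C, X.shape[1]))
    for ci, c in enumerate(classes):
        block = X[y == c]
        if block.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
        means[ci] = block.mean(axis=0)
        variances[ci] = block.var(axis=0, ddof=1)
    grand = means.mean(axis=0)
    between = ((means - grand) ** 2).sum(axis=0) / (C - 1)
    within = variances.mean(axis=0)
    scores = between / (within + FISHER_EPS)
    # stable mergesort: ties keep manifest (column) order
    ordering = np.argsort(-scores, kind="stable")
    return FisherRanking(pd.Series(scores, index=data.columns), ordering)


def select_top(ranking: FisherRanking, n: int) -> np.ndarray:
    """First ``n`` feature indices of the ranking (order preserved)."""
    total = len(ranking.scores)
    if not 1 <= n <= total:
        raise ValueError(f"n must be in 1..{total}")
    return ranking.ordering[:n].copy()


DEFAULT_GRID = (10, 25, 50, 75, 100, 200, 300)


def sweep_feature_counts(
    data: pd.DataFrame,
    labels: pd.Series,
    grid: tuple[int, ...] = DEFAULT_GRID,
    classifier_factory=None,
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy / entropy-R^2 / -2logL as a function of the top-N cutoff.

    For each N in the grid: standardize and rank on training rows, keep the
    top N features, fit the classifier (default DA-PC), and record train and
    test metrics.  Returns a tidy table, one row per (n, split).
    """
    import warnings

    from .dapc import DAPC, holdback_split

    if train_idx is None or test_idx is None:
        train_idx, test_idx = holdback_split(labels, seed=seed)
    rows = []
    for n in grid:
        if n > data.shape[1]:
            warnings.warn(f"grid entry {n} exceeds width {data.shape[1]}; skipped",
                          stacklevel=2)
            continue
        if classifier_factory is None:
            model = DAPC(data, labels, n_top=n)
        else:
            model = classifier_factory(data, labels, n)
        res = model.fit(train_idx=train_idx, test_idx=test_idx)
        for split in ("train", "test"):
            m = res.metrics[split]
            rows.append(
                {
                    "n_features": n,
                    "split": split,
                    "accuracy": m.accuracy,
                    "r2_entropy": m.r2_entropy,
                    "minus2_loglik": m.minus2_loglik,
                    "n_selected_pcs": len(res.selected_pc_indices),
                }
            )
    return pd.DataFrame(rows)
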