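"""DA-PC: PCA, significance-gated PC selection, quadratic discriminant
analysis with Mahalanobis membership probabilities, and spectral+image fusion.

The classifier follows the DA-PC recipe: standardized features are
decomposed by PCA; principal components are admitted to the discriminant
only if their approximate F (forward-stepwise partial Wilks' Lambda) is
significant at ``alpha`` (default 0.001); quadratic DA then models each
class as a Gaussian with its own covariance, and a point ``x`` is assigned
by the largest membership probability

    p_c(x)  propto  pi_c |Sigma_c|^(-1/2) exp(-d_c(x)/2),
    d_c(x) = (x - mu_c)^T Sigma_c^{-1} (x - mu_c)   (Mahalanobis).

Model quality is tracked by accuracy, entropy R^2 (1 - l_model/l_null) and
-2 logLikelihood.  ``DAPC`` / ``FusedDAPC`` are Model classes whose
``fit()`` returns a Results object with metrics, predictions and
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features.extract import FeatureTable
from .selection import FisherRanking, fisher_scores, select_top, standardize

__all__ = [
    "PCAModel",
    "QDAParams",
    "Metrics",
    "fit_pca",
    "select_pcs",
    "fit_qda",
    "predict_qda",
    "evaluate",
    "holdback_split",
    "DAPC",
    "DAPCResults",
    "FusedDAPC",
    "comparator_fit_predict",
]

PROB_FLOOR = 1e-12
COND_LIMIT = 1e8
GAMMA_LADDER = (0.1, 0.3, 0.5, 1.0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Column-centered SVD PCA with a deterministic sign convention."""

    loadings: np.ndarray  # (p, q), orthonormal columns
    explained_variance: np.ndarray  # (q,), non-increasing
    mean: np.ndarray  # (p,)
    n_samples: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) @ self.loadings

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(X: np.ndarray) -> PCAModel:
    """PCA by SVD of the centered matrix; retains ``min(n-1, p)`` components.

    Sign convention: in every loading column the element of largest
    magnitude is made positive, so loadings are reproducible across runs.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    n, p = X.shape
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    q = min(n - 1, p)
    loadings = Vt[:q].T
    var = (s[:q] ** 2) / (n - 1)
    # deterministic sign: largest-|.| element of each loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(q)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    return PCAModel(loadings, var, mean, n)


# ---------------------------------------------------------------------------
# Stepwise PC selection by partial Wilks' Lambda approximate F
# ---------------------------------------------------------------------------


def _scatter_matrices(S: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    total = S - S.mean(axis=0)
    T = total.T @ total
    W = np.zeros_like(T)
    for c in classes:
        block = S[y == c]
        centered = block - block.mean(axis=0)
        W += centered.T @ centered
    return W, T


def select_pcs(
    scores: np.ndarray,
    labels: np.ndarray | pd.Series,
    alpha: float = 0.001,
    criterion: str = "wilks",
) -> list[int]:
    """Forward-stepwise selection of discriminating PCs at level ``alpha``.

    ``wilks``/``hotelling``: at each step, for every candidate PC the
    partial Wilks' Lambda given the already-selected PCs is converted to an
    approximate F (for a single added variable the Wilks and
    Hotelling-Lawley partial tests coincide); the candidate with the
    smallest p enters if p < alpha, otherwise selection stops.
    ``anova``: marginal one-way F per PC, no conditioning.
    Returns the selected column indices in entry order (possibly empty).
    """
    S = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    g = classes.size
    if g < 2:
        raise ValueError("need >= 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
    N, q = S.shape

    if criterion == "anova":
        selected = []
        for j in range(q):
            groups = [S[y == c, j] for c in classes]
            _, p = stats.f_oneway(*groups)
            if np.isfinite(p) and p < alpha:
                selected.append(j)
        return selected
    if criterion not in ("wilks", "hotelling"):
        raise ValueError(f"unknown criterion {criterion!r}")

    W, T = _scatter_matrices(S, y)
    selected: list[int] = []
    lambda_sel = 1.0
    while True:
        s = len(selected)
        df2 = N - g - s
        if df2 < 1 or s == q:
            break
        best_j, best_p, best_lambda = -1, np.inf, None
        for j in range(q):
            if j in selected:
                continue
            V = selected + [j]
            idx = np.ix_(V, V)
            detW, detT = np.linalg.det(W[idx]), np.linalg.det(T[idx])
            if detT <= 0 or detW < 0:
                continue  # collinear with already-selected PCs
            lam_V = detW / detT
            partial = lam_V / lambda_sel
            partial = min(max(partial, 1e-300), 1.0)
            F = (1.0 - partial) / partial * df2 / (g - 1)
            p = stats.f.sf(F, g - 1, df2)
            if p < best_p:
                best_j, best_p, best_lambda = j, p, lam_V
        if best_j < 0 or best_p >= alpha:
            break
        selected.append(best_j)
        lambda_sel = best_lambda
    return selected


# ---------------------------------------------------------------------------
# Quadratic discriminant analysis with Mahalanobis membership probabilities
# ---------------------------------------------------------------------------


@dataclass
class QDAParams:
    """Per-class Gaussian parameters of the quadratic discriminant."""

    classes: np.ndarray
    means: np.ndarray  # (C, d)
    covariances: np.ndarray  # (C, d, d), regularized
    precisions: np.ndarray  # (C, d, d)
    log_dets: np.ndarray  # (C,)
    priors: np.ndarray  # (C,), sums to 1
    gamma: float


def fit_qda(
    pcs: np.ndarray,
    labels: np.ndarray | pd.Series,
    reg_gamma: float = 0.1,
    pool_lambda: float = 0.25,
) -> QDAParams:
    """Per-class mean/covariance with pooled and diagonal shrinkage.

    Each class covariance is first shrunk toward the pooled (sample-size
    weighted) covariance, ``Sigma_c <- (1-lambda) Sigma_c + lambda
    Sigma_pooled`` — with a handful of training cells per class the raw
    per-class scatter badly underestimates some directions, and a class
    whose covariance is too tight rejects its own held-out members while a
    wide neighbour swallows them; borrowing strength from the pooled
    estimate (Friedman-style regularized DA) stabilizes exactly those
    directions while keeping the covariances class-specific.  Then the
    diagonal shrinkage ``Sigma <- (1-gamma) Sigma + gamma diag(Sigma)``
    is applied; gamma starts at ``reg_gamma`` and escalates through
    {0.1, 0.3, 0.5, 1.0} until every class covariance has condition number
    < 1e8.  Class priors are the training proportions.
    """
    X = np.asarray(pcs, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        raise ValueError("no PCs were selected; discriminant cannot be fit")
    y = np.asarray(labels)
    classes = np.unique(y)
    C, d = classes.size, X.shape[1]
    means = np.empty((C, d))
    raw_covs = np.empty((C, d, d))
    priors = np.empty(C)
    for ci, c in enumerate(classes):
        block = X[y == c]
        if block.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
        means[ci] = block.mean(axis=0)
        raw_covs[ci] = np.atleast_2d(np.cov(block, rowvar=False, ddof=1))
        priors[ci] = block.shape[0] / X.shape[0]

    if not 0.0 <= pool_lambda <= 1.0:
        raise ValueError("pool_lambda must be in [0, 1]")
    if pool_lambda > 0.0:
        pooled = np.einsum("c,cij->ij", priors, raw_covs)
        raw_covs = (1.0 - pool_lambda) * raw_covs + pool_lambda * pooled

    ladder = [g for g in GAMMA_LADDER if g >= reg_gamma] or [1.0]
    if reg_gamma not in ladder:
        ladder = [reg_gamma] + ladder
    last_err = None
    for gamma in ladder:
        covs = (1.0 - gamma) * raw_covs + gamma * np.stack(
            [np.diag(np.diag(S)) for S in raw_covs]
        )
        try:
            conds = [np.linalg.cond(S) for S in covs]
            if max(conds) >= COND_LIMIT:
                last_err = f"condition number {max(conds):.3g}"
                continue
            precisions = np.stack([np.linalg.inv(S) for S in covs])
            log_dets = np.array([np.linalg.slogdet(S)[1] for S in covs])
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            last_err = str(exc)
            continue
        return QDAParams(classes, means, covs, precisions, log_dets, priors, gamma)
    raise np.linalg.LinAlgError(
        f"class covariance singular even at gamma=1 ({last_err}); "
        "reduce the number of selected PCs or pool classes"
    )


def predict_qda(
    params: QDAParams, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and membership probabilities for rows of ``X`` in PC space."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != params.means.shape[1]:
        raise ValueError(
            f"dimension mismatch: x has {X.shape[1]}, model has "
            f"{params.means.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    C = params.classes.size
    log_p = np.empty((X.shape[0], C))
    for ci in range(C):
        diff = X - params.means[ci]
        d2 = np.einsum("ni,ij,nj->n", diff, params.precisions[ci], diff)
        log_p[:, ci] = (
            np.log(params.priors[ci]) - 0.5 * params.log_dets[ci] - 0.5 * d2
        )
    log_p -= log_p.max(axis=1, keepdims=True)
    probs = np.exp(log_p)
    probs /= probs.sum(axis=1, keepdims=True)
    # argmax breaks ties by class order
    labels = params.classes[np.argmax(probs, axis=1)]
    return labels, probs


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class Metrics:
    """Accuracy, entropy R^2, -2 logLikelihood and the confusion matrix."""

    accuracy: float
    r2_entropy: float
    minus2_loglik: float
    confusion: pd.DataFrame
    n: int


def evaluate(
    y_true: np.ndarray,
    probs: np.ndarray,
    classes: np.ndarray,
    null_priors: np.ndarray,
) -> Metrics:
    """Score a set of membership-probability predictions.

    ``minus2_loglik = -2 sum ln p(true class)`` with probabilities floored
    at 1e-12; ``r2_entropy = 1 - l_model / l_null`` where the null model
    always emits ``null_priors`` (training class proportions).
    """
    y_true = np.asarray(y_true)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] != y_true.size:
        raise ValueError("probability matrix shape does not match labels")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    class_index = {c: i for i, c in enumerate(classes)}
    idx = np.array([class_index[c] for c in y_true])
    p_true = np.clip(probs[np.arange(y_true.size), idx], PROB_FLOOR, 1.0)
    ll_model = float(np.log(p_true).sum())
    p_null = np.clip(null_priors[idx], PROB_FLOOR, 1.0)
    ll_null = float(np.log(p_null).sum())
    minus2 = max(0.0, -2.0 * ll_model)  # log-probs are <= 0; avoid -0.0
    r2 = 1.0 - ll_model / ll_null if ll_null != 0 else 1.0
    pred = classes[np.argmax(probs, axis=1)]
    conf = pd.DataFrame(
        0, index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted"),
    )
    for t, p in zip(y_true, pred):
        conf.loc[t, p] += 1
    acc = float(np.trace(conf.to_numpy())) / y_true.size
    return Metrics(acc, r2, minus2, conf, int(y_true.size))


# ---------------------------------------------------------------------------
# Hold-back split
# ---------------------------------------------------------------------------


def holdback_split(
    labels: pd.Series | np.ndarray,
    fraction: float = 0.25,
    by: str = "stratified",
    seed: int = 0,
    day_tags: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Positional (train, test) indices with a held-back test fraction.

    ``stratified`` (default): ``round(fraction * n_class)`` test rows drawn
    per class.  ``day_tag``: entire acquisition batches (values of
    ``day_tags``) are held out until the test fraction is reached,
    emulating a test set measured on a different day.
    """
    y = np.asarray(labels)
    n = y.size
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if by == "stratified":
        test = []
        for c in np.unique(y):
            rows = np.nonzero(y == c)[0]
            n_test = int(round(fraction * rows.size))
            if n_test < 1 or n_test >= rows.size:
                raise ValueError(
                    f"class {c!r} has too few rows ({rows.size}) for a "
                    f"{fraction:.0%} hold-back"
                )
            test.append(rng.permutation(rows)[:n_test])
        test_idx = np.sort(np.concatenate(test))
    elif by == "day_tag":
        if day_tags is None:
            raise ValueError("day_tag split requires day_tags")
        tags = np.asarray(day_tags)
        order = rng.permutation(np.unique(tags))
        chosen, count = [], 0
        for tag in order:
            chosen.append(tag)
            count += int((tags == tag).sum())
            if count >= fraction * n:
                break
        test_idx = np.sort(np.nonzero(np.isin(tags, chosen))[0])
        if test_idx.size in (0, n):
            raise ValueError("day_tag split left an empty train or test set")
    else:
        raise ValueError(f"unknown split mode {by!r}")
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return train_idx, test_idx


# ---------------------------------------------------------------------------
# The DA-PC model / results objects
# ---------------------------------------------------------------------------


def _as_frame(data) -> tuple[pd.DataFrame, pd.Series | None]:
    if isinstance(data, FeatureTable):
        return data.data, data.labels
    return data, None


@dataclass
class DAPCResults:
    """Fitted DA-PC model: estimates, predictions, metrics, ``summary()``."""

    model: "DAPC"
    standardization: object
    ranking: FisherRanking | None
    feature_subset: list[str]
    pca: PCAModel
    selected_pc_indices: list[int]
    qda: QDAParams
    train_idx: np.ndarray
    test_idx: np.ndarray
    predictions: pd.DataFrame
    metrics: dict[str, Metrics]

    def predict(self, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Classify new rows given in the original feature space."""
        Z = self.standardization.transform(data[list(data.columns)])
        Z = Z[self.feature_subset].to_numpy()
        scores = self.pca.transform(Z)[:, self.selected_pc_indices]
        return predict_qda(self.qda, scores)

    def summary(self) -> str:
        lines = [
            "DA-PC classification results",
            "=" * 60,
            f"classes:            {', '.join(map(str, self.qda.classes))}",
            f"features used:      {len(self.feature_subset)}"
            + (" (Fisher top-N)" if self.ranking is not None else ""),
            f"PCs selected:       {len(self.selected_pc_indices)} "
            f"of {self.pca.n_components} (alpha={self.model.alpha})",
            f"covariance gamma:   {self.qda.gamma}",
            f"train/test rows:    {self.train_idx.size}/{self.test_idx.size}",
            "-" * 60,
            f"{'split':<8}{'accuracy':>10}{'R2 entropy':>12}{'-2logL':>12}",
        ]
        for split in ("train", "test"):
            m = self.metrics[split]
            lines.append(
                f"{split:<8}{m.accuracy:>10.3f}{m.r2_entropy:>12.3f}"
                f"{m.minus2_loglik:>12.3f}"
            )
        lines.append("-" * 60)
        lines.append("test confusion matrix:")
        lines.append(self.metrics["test"].confusion.to_string())
        return "\n".join(lines)


class DAPC:
    """DA-PC classifier model over a feature table.

    Parameters
    ----------
    data : DataFrame or FeatureTable
        Cells x features.  Standardized internally on training rows.
    labels : Series
        Class label per row (required unless ``data`` is a FeatureTable).
    n_top : int, optional
        Keep only the N features with highest Fisher score (ranked on
        training rows unless ``rank_on_all``).
    alpha : float
        Significance level of the stepwise PC gate (default 0.001).
    criterion : str
        ``wilks`` (default, partial stepwise), ``hotelling`` or ``anova``.
    reg_gamma : float
        Initial diagonal-shrinkage weight of the class covariances.
    rank_on_all : bool
        Rank features on all rows (the split-leaky variant) instead of the
        default training-rows-only ranking.
    """

    def __init__(
        self,
        data,
        labels: pd.Series | None = None,
        *,
        n_top: int | None = None,
        alpha: float = 0.001,
        criterion: str = "wilks",
        reg_gamma: float = 0.1,
        pool_lambda: float = 0.25,
        rank_on_all: bool = False,
        max_pcs: int | None = None,
    ) -> None:
        frame, table_labels = _as_frame(data)
        labels = labels if labels is not None else table_labels
        if labels is None:
            raise ValueError("labels are required")
        self.data = frame
        self.labels = pd.Series(np.asarray(labels), index=frame.index)
        self.n_top = n_top
        self.alpha = alpha
        self.criterion = criterion
        self.reg_gamma = reg_gamma
        self.pool_lambda = pool_lambda
        self.rank_on_all = rank_on_all
        self.max_pcs = max_pcs

    @classmethod
    def from_feature_table(cls, table: FeatureTable, **kwargs) -> "DAPC":
        return cls(table.data, table.labels, **kwargs)

    def fit(
        self,
        train_idx: np.ndarray | None = None,
        test_idx: np.ndarray | None = None,
        holdback: float = 0.25,
        seed: int = 0,
    ) -> DAPCResults:
        if train_idx is None or test_idx is None:
            train_idx, test_idx = holdback_split(
                self.labels, fraction=holdback, seed=seed
            )
        train_idx = np.asarray(train_idx)
        test_idx = np.asarray(test_idx)
        y = self.labels.to_numpy()

        Z, std_params = standardize(self.data, train_idx)

        ranking = None
        subset = list(self.data.columns)
        if self.n_top is not None:
            rank_rows = Z if self.rank_on_all else Z.iloc[train_idx]
            rank_labels = y if self.rank_on_all else y[train_idx]
            ranking = fisher_scores(rank_rows, rank_labels)
            keep = select_top(ranking, self.n_top)
            subset = [self.data.columns[i] for i in keep]

        Zs = Z[subset].to_numpy()
        pca = fit_pca(Zs[train_idx])
        scores = pca.transform(Zs)
        if self.max_pcs is not None:
            scores = scores[:, : self.max_pcs]
        selected = select_pcs(
            scores[train_idx], y[train_idx], self.alpha, self.criterion
        )
        if not selected:
            raise ValueError(
                f"no PC reached p < {self.alpha}; the discriminant refuses "
                "to fit on zero components"
            )
        qda = fit_qda(scores[train_idx][:, selected], y[train_idx],
                      self.reg_gamma, self.pool_lambda)

        preds, metrics = _score_splits(
            scores[:, selected], y, qda, train_idx, test_idx, self.data.index
        )
        return DAPCResults(
            self, std_params, ranking, subset, pca, selected, qda,
            train_idx, test_idx, preds, metrics,
        )


def _score_splits(
    selected_scores: np.ndarray,
    y: np.ndarray,
    qda: QDAParams,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    index: pd.Index,
) -> tuple[pd.DataFrame, dict[str, Metrics]]:
    pred_labels, probs = predict_qda(qda, selected_scores)
    split = np.full(y.size, "", dtype=object)
    split[train_idx], split[test_idx] = "train", "test"
    frame = pd.DataFrame(
        {"true": y, "predicted": pred_labels, "split": split}, index=index
    )
    for ci, c in enumerate(qda.classes):
        frame[f"p_{c}"] = probs[:, ci]
    metrics = {
        name: evaluate(y[idx], probs[idx], qda.classes, qda.priors)
        for name, idx in (("train", train_idx), ("test", test_idx))
    }
    return frame, metrics


# ---------------------------------------------------------------------------
# Spectral + image fusion
# ---------------------------------------------------------------------------


@dataclass
class FusedDAPCResults(DAPCResults):
    """Fusion results; adds which block each selected PC came from."""

    block_of_selected: list[str] = field(default_factory=list)

    @property
    def selected_per_block(self) -> dict[str, int]:
        return {
            b: self.block_of_selected.count(b)
            for b in ("spectral", "image")
        }

    def predict(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError(
            "use FusedDAPC.predict_blocks with both new-data blocks"
        )

    def summary(self) -> str:
        base = super().summary()
        per = self.selected_per_block
        return base + (
            f"\nselected components: {per['spectral']} spectral, "
            f"{per['image']} image"
        )


class FusedDAPC:
    """Fusion of spectral and image information through independent PC blocks.

    PCA is fit separately on the standardized spectral block and the
    standardized image-feature block; both blocks' PC scores are
    standardized to unit (training) variance, pooled, and passed through the
    joint stepwise PC selection, so the discriminant is free to draw
    components from either modality.
    """

    def __init__(
        self,
        spectral: pd.DataFrame,
        image: pd.DataFrame,
        labels: pd.Series,
        *,
        alpha: float = 0.001,
        criterion: str = "wilks",
        reg_gamma: float = 0.1,
        pool_lambda: float = 0.25,
        n_top_image: int | None = None,
        max_pcs_per_block: int | None = None,
    ) -> None:
        if len(spectral) != len(image) or not spectral.index.equals(image.index):
            raise ValueError("spectral and image tables must share row identity")
        self.spectral = spectral
        self.image = image
        self.labels = pd.Series(np.asarray(labels), index=spectral.index)
        self.alpha = alpha
        self.criterion = criterion
        self.reg_gamma = reg_gamma
        self.pool_lambda = pool_lambda
        self.n_top_image = n_top_image
        self.max_pcs_per_block = max_pcs_per_block

    def fit(
        self,
        train_idx: np.ndarray | None = None,
        test_idx: np.ndarray | None = None,
        holdback: float = 0.25,
        seed: int = 0,
    ) -> FusedDAPCResults:
        if train_idx is None or test_idx is None:
            train_idx, test_idx = holdback_split(
                self.labels, fraction=holdback, seed=seed
            )
        train_idx = np.asarray(train_idx)
        test_idx = np.asarray(test_idx)
        y = self.labels.to_numpy()

        block_scores, block_tags, fitted = [], [], {}
        for name, frame in (("spectral", self.spectral), ("image", self.image)):
            Z, std_params = standardize(frame, train_idx)
            subset = list(frame.columns)
            ranking = None
            if name == "image" and self.n_top_image is not None:
                ranking = fisher_scores(Z.iloc[train_idx], y[train_idx])
                keep = select_top(ranking, self.n_top_image)
                subset = [frame.columns[i] for i in keep]
            Zs = Z[subset].to_numpy()
            pca = fit_pca(Zs[train_idx])
            s = pca.transform(Zs)
            if self.max_pcs_per_block is not None:
                s = s[:, : self.max_pcs_per_block]
            sd = s[train_idx].std(axis=0, ddof=1)
            sd[sd <= 0] = 1.0
            s = s / sd  # unit training variance per PC
            block_scores.append(s)
            block_tags.extend([name] * s.shape[1])
            fitted[name] = (std_params, subset, pca, sd, ranking)

        pooled = np.hstack(block_scores)
        selected = select_pcs(
            pooled[train_idx], y[train_idx], self.alpha, self.criterion
        )
        if not selected:
            raise ValueError(
                f"no pooled PC reached p < {self.alpha}; fusion refuses to fit"
            )
        qda = fit_qda(pooled[train_idx][:, selected], y[train_idx],
                      self.reg_gamma, self.pool_lambda)
        preds, metrics = _score_splits(
            pooled[:, selected], y, qda, train_idx, test_idx,
            self.spectral.index,
        )
        spectral_std, spectral_subset, spectral_pca, _, _ = fitted["spectral"]
        res = FusedDAPCResults(
            self, spectral_std, fitted["image"][4], spectral_subset,
            spectral_pca, selected, qda, train_idx, test_idx, preds, metrics,
            block_of_selected=[block_tags[j] for j in selected],
        )
        res._fitted_blocks = fitted  # kept for predict_blocks
        return res

    @staticmethod
    def predict_blocks(
        results: FusedDAPCResults,
        spectral: pd.DataFrame,
        image: pd.DataFrame,
    ) -> tuple[np.ndarray, np.ndarray]:
        fitted = results._fitted_blocks
        cols = []
        for name, frame in (("spectral", spectral), ("image", image)):
            std_params, subset, pca, sd, _ = fitted[name]
            Z = std_params.transform(frame)[subset].to_numpy()
            s = pca.transform(Z)[:, : sd.size] / sd
            cols.append(s)
        pooled = np.hstack(cols)
        return predict_qda(results.qda, pooled[:, results.selected_pc_indices])


# ---------------------------------------------------------------------------
# Comparator classifiers (thin adapters over scikit-learn)
# ---------------------------------------------------------------------------


def _venetian_blind_folds(n: int, n_splits: int = 10):
    idx = np.arange(n)
    for k in range(n_splits):
        test = idx[idx % n_splits == k]
        if test.size == 0:
            continue
        yield np.setdiff1d(idx, test), test


def comparator_fit_predict(
    data: pd.DataFrame,
    labels: pd.Series,
    method: str,
    n_splits: int = 10,
    seed: int = 0,
) -> Metrics:
    """PLS-DA (2 components), K-means (3 clusters) or SVM comparators.

    Delegates to scikit-learn with venetian-blind cross-validation
    (interleaved folds, default 10 splits).  Probabilities are not available
    from these adapters, so ``r2_entropy``/``minus2_loglik`` are NaN and the
    probability matrix is the one-hot prediction.
    """
    from scipy.optimize import linear_sum_assignment
    from sklearn.cluster import KMeans
    from sklearn.cross_decomposition import PLSRegression
    from sklearn.svm import SVC

    X = data.to_numpy(dtype=np.float64)
    y = np.asarray(labels)
    classes = np.unique(y)
    onehot = (y[:, None] == classes[None, :]).astype(float)
    pred = np.empty(y.size, dtype=object)

    for train, test in _venetian_blind_folds(y.size, n_splits):
        if method == "plsda":
            model = PLSRegression(n_components=2)
            model.fit(X[train], onehot[train])
            pred[test] = classes[np.argmax(model.predict(X[test]), axis=1)]
        elif method == "svm":
            model = SVC(kernel="rbf", random_state=seed)
            model.fit(X[train], y[train])
            pred[test] = model.predict(X[test])
        elif method == "kmeans":
            km = KMeans(n_clusters=classes.size, n_init=10, random_state=seed)
            km.fit(X[train])
            # map clusters to labels by maximum train agreement
            train_clusters = km.predict(X[train])
            cost = np.zeros((classes.size, classes.size))
            for ci, c in enumerate(classes):
                for k in range(classes.size):
                    cost[k, ci] = -np.sum((train_clusters == k) & (y[train] == c))
            rows, cols = linear_sum_assignment(cost)
            mapping = {k: classes[c] for k, c in zip(rows, cols)}
            pred[test] = [mapping[k] for k in km.predict(X[test])]
        else:
            raise ValueError(f"unknown comparator {method!r}")

    conf = pd.DataFrame(
        0, index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted"),
    )
    for t, p in zip(y, pred):
        conf.loc[t, p] += 1
    acc = float(np.trace(conf.to_numpy())) / y.size
    return Metrics(acc, float("nan"), float("nan"), conf, int(y.size))
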