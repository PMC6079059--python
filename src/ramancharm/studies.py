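"""Reproducible simulation studies over the synthetic cohort.

These drive the full pipeline — cube generation, preprocessing, compound-map
reconstruction, descriptor extraction, Fisher ranking, DA-PC / fusion — over
many seeded replicates and summarize classifier performance.  They are the
package's standing experiments: the accuracy study mirrors the comparison of
the three analysis approaches (average spectrum vs image descriptors vs
fusion), and the null-calibration study verifies that with identically
distributed classes neither the stepwise PC gate nor the Fisher ranking
manufactures signal.

Replicates run at a reduced problem size (80 px field, 320-point spectra,
10 cells per class by default) so a 20-seed study completes on a laptop; the
spatial densities of the default classes are preserved by the scaling.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .dapc import DAPC, FusedDAPC, QDAParams, fit_pca, holdback_split, select_pcs
from .pipeline import build_tables
from .selection import fisher_scores, standardize
from .simulate import SyntheticConfig

__all__ = [
    "accuracy_study",
    "null_calibration_study",
    "min_pairwise_separation",
    "study_seeds",
]


def study_seeds(base_seed: int, n_seeds: int) -> np.ndarray:
    """Deterministic replicate seeds derived from one master seed (< 2^31)."""
    rng = np.random.default_rng(base_seed)
    return rng.integers(0, 2 ** 31 - 1, size=n_seeds)


def min_pairwise_separation(qda: QDAParams) -> float:
    """Smallest pairwise Mahalanobis distance between class means.

    Measured in the selected-PC space with the pooled (average) class
    covariance — the planted between-class separation the classifier
    actually sees.
    """
    pooled = qda.covariances.mean(axis=0)
    P = np.linalg.inv(pooled)
    dists = []
    for i, j in itertools.combinations(range(qda.classes.size), 2):
        d = qda.means[i] - qda.means[j]
        dists.append(float(np.sqrt(d @ P @ d)))
    return min(dists)


def accuracy_study(
    base_seed: int,
    n_seeds: int = 20,
    cells_per_class: int = 10,
    field_px: int = 80,
    k: int = 320,
    n_top: int = 100,
    holdback: float = 0.25,
) -> pd.DataFrame:
    """Test accuracy of the three approaches over seeded replicates.

    Each replicate generates a fresh cohort (equal-mean-spectra, distinct
    spatial patterns — the regime where image descriptors are expected to
    win), holds back ``holdback`` of the cells per class, and fits the
    spectral, image and fused DA-PC models on the same split.  When no
    spectral PC passes the significance gate the spectral model cannot be
    fit; its accuracy is then that of the priors-only classifier.

    Returns a tidy frame: one row per (seed, approach) with test accuracy,
    the number of selected PCs, and the planted minimum pairwise Mahalanobis
    separation seen by the image model.
    """
    rows = []
    for seed in study_seeds(base_seed, n_seeds):
        seed = int(seed)
        cfg = SyntheticConfig.scaled(
            seed=seed, field_px=field_px, k=k, cells_per_class=cells_per_class
        )
        spectral, table = build_tables(cfg)
        labels = table.labels
        train_idx, test_idx = holdback_split(labels, fraction=holdback, seed=seed)
        null_acc = float(
            (labels.iloc[test_idx] == labels.iloc[train_idx].mode()[0]).mean()
        )

        img_res = DAPC(table.data, labels, n_top=n_top).fit(
            train_idx=train_idx, test_idx=test_idx
        )
        rows.append(
            {
                "seed": seed,
                "approach": "image",
                "test_accuracy": img_res.metrics["test"].accuracy,
                "n_pcs": len(img_res.selected_pc_indices),
                "min_separation": min_pairwise_separation(img_res.qda),
            }
        )
        try:
            spec_res = DAPC(spectral, labels).fit(
                train_idx=train_idx, test_idx=test_idx
            )
            spec_acc = spec_res.metrics["test"].accuracy
            spec_pcs = len(spec_res.selected_pc_indices)
        except ValueError:  # no significant spectral PC: priors-only model
            spec_acc, spec_pcs = null_acc, 0
        rows.append(
            {
                "seed": seed,
                "approach": "spectral",
                "test_accuracy": spec_acc,
                "n_pcs": spec_pcs,
                "min_separation": np.nan,
            }
        )
        fused_res = FusedDAPC(
            spectral, table.data, labels, n_top_image=n_top
        ).fit(train_idx=train_idx, test_idx=test_idx)
        per_block = fused_res.selected_per_block
        rows.append(
            {
                "seed": seed,
                "approach": "combined",
                "test_accuracy": fused_res.metrics["test"].accuracy,
                "n_pcs": len(fused_res.selected_pc_indices),
                "min_separation": np.nan,
                "n_pcs_spectral": per_block["spectral"],
                "n_pcs_image": per_block["image"],
            }
        )
    return pd.DataFrame(rows)


def null_calibration_study(
    base_seed: int,
    n_seeds: int = 20,
    cells_per_class: int = 6,
    field_px: int = 48,
    k: int = 256,
    alpha: float = 0.001,
    n_permutations: int = 99,
) -> pd.DataFrame:
    """Selector calibration with identically distributed classes.

    ``pattern_separation = 0`` collapses all class parameters onto their
    mean, so labels carry no information.  Per replicate the study records
    (a) how many PCs the stepwise gate admits at ``alpha`` and (b) a
    permutation-calibrated Kolmogorov-Smirnov p-value comparing the
    observed Fisher scores (cytochrome channel, 1025 features) with scores
    under label permutations of the same table.

    The KS p-value must be calibrated by permutation: descriptor columns
    are strongly correlated, so the nominal two-sample KS null (which
    assumes independent observations) is wildly anticonservative here.
    The observed score vector and the ``n_permutations`` permuted ones are
    exchangeable under the null, so the rank of the observed KS distance
    (each vector vs the pool of the others) among the permuted distances
    is a valid p-value regardless of the correlation structure.
    """
    rows = []
    for seed in study_seeds(base_seed, n_seeds):
        seed = int(seed)
        cfg = SyntheticConfig.scaled(
            seed=seed, field_px=field_px, k=k, cells_per_class=cells_per_class,
            pattern_separation=0.0,
        )
        _, table = build_tables(cfg, channels_subset=("cytochrome",))
        z, _ = standardize(table.data)
        y = table.labels.to_numpy()

        rng = np.random.default_rng(seed)
        vectors = [fisher_scores(z, y).scores.to_numpy()]
        vectors += [
            fisher_scores(z, rng.permutation(y)).scores.to_numpy()
            for _ in range(n_permutations)
        ]
        distances = []
        for i, v in enumerate(vectors):
            rest = np.concatenate([u for j, u in enumerate(vectors) if j != i])
            distances.append(stats.ks_2samp(v, rest).statistic)
        d_obs, d_null = distances[0], np.asarray(distances[1:])
        ks_p = float((1 + (d_null >= d_obs).sum()) / (1 + d_null.size))

        pca = fit_pca(z.to_numpy())
        scores = pca.transform(z.to_numpy())
        n_selected = len(select_pcs(scores, y, alpha=alpha))
        rows.append({"seed": seed, "n_pcs_selected": n_selected, "ks_p": ks_p})
    return pd.DataFrame(rows)
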