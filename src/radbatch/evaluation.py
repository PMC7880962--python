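"""Unsupervised validation: K-means clustering purity and PCA diagnostics.

Purity scores a clustering against known classes: each cluster is assigned
its majority class and purity is the fraction of samples that land in their
cluster's majority class.  Because K-means with random initialization is
multi-modal, the clustering is repeated many times (default 1000) and the
reported value is the highest purity observed in more than a fixed fraction
of the iterations (default 20%) — a mode-seeking rule that ignores rare
lucky initializations.  Purities are rounded to 4 decimals before frequency
counting so that numerically identical partitions bin together.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .harmonization import _anova_p

__all__ = ["PurityResult", "purity", "kmeans_purity", "pca_diagnostics"]


@dataclass
class PurityResult:
    """Outcome of the repeated-K-means purity evaluation."""

    purities: np.ndarray  # one purity per iteration, rounded to 4 decimals
    selected_purity: float
    selected_frequency: float  # fraction of iterations attaining it
    k: int
    seed: int
    frequency_table: dict[float, int] = field(default_factory=dict)


def purity(cluster_assignments, true_labels) -> float:
    """Fraction of samples whose cluster's majority class is their own class."""
    clusters = np.asarray(cluster_assignments)
    labels = np.asarray(true_labels)
    if clusters.shape != labels.shape or clusters.ndim != 1:
        raise ValueError("cluster assignments and labels must be equal-length 1D")
    if clusters.size == 0:
        raise ValueError("need at least one sample")
    correct = 0
    for c in np.unique(clusters):
        members = labels[clusters == c]
        correct += int(Counter(members.tolist()).most_common(1)[0][1])
    return correct / clusters.size


def kmeans_purity(
    table: pd.DataFrame,
    feature_cols: list[str],
    class_column: str = "class_label",
    k: int = 2,
    iterations: int = 1000,
    freq_threshold: float = 0.2,
    seed: int = 0,
    max_iter: int = 300,
) -> PurityResult:
    """Repeated random-restart K-means purity with the frequency rule.

    Features are z-scored internally.  Returns the maximum purity value whose
    empirical frequency across iterations strictly exceeds ``freq_threshold``.
    When the restart distribution is so diffuse that no single (4-decimal
    rounded) value reaches that frequency, the rule falls back to its
    cumulative form: the highest purity level *attained or exceeded* in more
    than ``freq_threshold`` of the iterations.  Both readings coincide with
    the plain maximum at ``freq_threshold=0``.
    """
    x = table[feature_cols].to_numpy(dtype=float)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    labels = table[class_column].to_numpy()
    sd = x.std(axis=0)
    z = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=iterations)
    purities = np.empty(iterations)
    for i, s in enumerate(sub_seeds):
        km = KMeans(
            n_clusters=k, init="random", n_init=1, max_iter=max_iter,
            random_state=int(s),
        ).fit(z)
        purities[i] = round(purity(km.labels_, labels), 4)
    freq = Counter(purities.tolist())
    eligible = [v for v, c in freq.items() if c / iterations > freq_threshold]
    if eligible:
        selected = max(eligible)
        selected_frequency = freq[selected] / iterations
    else:
        # cumulative fallback: highest level reached in > threshold of runs
        selected = max(
            v for v in freq if np.mean(purities >= v) > freq_threshold
        )
        selected_frequency = float(np.mean(purities >= selected))
    return PurityResult(
        purities=purities,
        selected_purity=float(selected),
        selected_frequency=selected_frequency,
        k=k,
        seed=seed,
        frequency_table={float(v): int(c) for v, c in sorted(freq.items())},
    )


def pca_diagnostics(
    table: pd.DataFrame,
    feature_cols: list[str],
    label_columns: list[str],
) -> pd.DataFrame:
    """Variance explained per principal component plus label associations.

    Features are z-scored; components come from SVD of the standardized
    matrix.  For each metadata column, the one-way ANOVA p-value of the
    component scores across label levels is reported (1.0 for degenerate
    single-level labels).  Variance-explained fractions sum to 1.
    """
    x = table[feature_cols].to_numpy(dtype=float)
    sd = x.std(axis=0)
    z = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u * s
    total = float((s**2).sum())
    out = pd.DataFrame(
        {
            "component": np.arange(1, len(s) + 1),
            "variance_explained": s**2 / total if total > 0 else np.zeros_like(s),
        }
    )
    for col in label_columns:
        out[f"p_{col}"] = [
            _anova_p(scores[:, c], table[col].astype(str)) for c in range(len(s))
        ]
    return out
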