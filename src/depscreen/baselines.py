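"""Baseline clustering comparison.

Runs alternative unsupervised clustering models (k-means, Gaussian mixture
without transitions, agglomerative/Ward, spectral) on the same standardized
features and quantifies whether any produces an effective division of the
CES score, using exactly the same exclusive-range extraction as the HMM
pipeline. The *separation score* -- the fraction of participants falling
inside any state's exclusive CES range -- is this package's own
operationalisation of "effective division" and is flagged as such in
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.mixture import GaussianMixture

from .exceptions import ValidationError
from .patterning import SortedSequence, exclusive_ranges

__all__ = ["ClusterComparison", "run_baselines", "separation_score", "comparison_table"]

DEFAULT_METHODS = ("kmeans", "gmm", "agglomerative", "spectral")


@dataclass
class ClusterComparison:
    method: str
    labels: np.ndarray | None
    coverage: dict[int, set[int]] = field(default_factory=dict)
    exclusive: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    group_sizes: dict[int, list[int]] = field(default_factory=dict)
    separation: float = np.nan
    low_tail_purity: float = np.nan
    high_tail_purity: float = np.nan
    error: str | None = None


def separation_score(labels: np.ndarray, ces: np.ndarray) -> float:
    """Fraction of participants whose CES falls in some cluster-exclusive range."""
    labels = np.asarray(labels)
    ces = np.asarray(ces)
    if len(labels) != len(ces):
        raise ValidationError("labels and CES vector lengths differ")
    _, sizes, _ = exclusive_ranges(labels, ces)
    inside = sum(sum(v) for v in sizes.values())
    return inside / len(ces)


def _tail_purity(labels: np.ndarray, ces: np.ndarray, quantile: float, high: bool) -> float:
    cut = np.quantile(ces, 1 - quantile if high else quantile)
    mask = ces >= cut if high else ces <= cut
    if mask.sum() == 0:
        return np.nan
    _, counts = np.unique(labels[mask], return_counts=True)
    return counts.max() / mask.sum()


def _cluster(method: str, X: np.ndarray, K: int, seed: int) -> np.ndarray:
    if method == "kmeans":
        return KMeans(n_clusters=K, n_init=10, random_state=seed).fit_predict(X)
    if method == "gmm":
        return GaussianMixture(n_components=K, n_init=5, random_state=seed).fit(X).predict(X)
    if method == "agglomerative":
        return AgglomerativeClustering(n_clusters=K, linkage="ward").fit_predict(X)
    if method == "spectral":
        return SpectralClustering(
            n_clusters=K, random_state=seed, assign_labels="kmeans", n_neighbors=20,
            affinity="nearest_neighbors",
        ).fit_predict(X)
    raise ValidationError(f"unknown baseline method {method!r}")


def run_baselines(
    seq: SortedSequence,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    n_clusters: int = 3,
    seed: int = 0,
    tail_quantile: float = 0.1,
) -> list[ClusterComparison]:
    """Apply each baseline with shared K and seed; score with the HMM's own range extractor.

    A method that fails is recorded with its error and the comparison
    continues.
    """
    X = seq.observations
    ces = seq.ces_sorted
    out: list[ClusterComparison] = []
    for method in methods:
        try:
            labels = _cluster(method, X, n_clusters, seed)
        except ValidationError:
            raise
        except Exception as exc:  # convergence or solver failure: record and move on
            out.append(ClusterComparison(method=method, labels=None, error=str(exc)))
            continue
        excl, sizes, cov = exclusive_ranges(labels, ces)
        out.append(
            ClusterComparison(
                method=method,
                labels=labels,
                coverage=cov,
                exclusive=excl,
                group_sizes=sizes,
                separation=separation_score(labels, ces),
                low_tail_purity=_tail_purity(labels, ces, tail_quantile, high=False),
                high_tail_purity=_tail_purity(labels, ces, tail_quantile, high=True),
            )
        )
    return out


def comparison_table(
    comparisons: list[ClusterComparison], hmm_labels: np.ndarray | None = None,
    ces: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabular report; optionally prepends an HMM row scored identically."""
    rows = []
    if hmm_labels is not None and ces is not None:
        rows.append(
            {
                "method": "hmm",
                "separation": separation_score(hmm_labels, ces),
                "low_tail_purity": _tail_purity(hmm_labels, ces, 0.1, high=False),
                "high_tail_purity": _tail_purity(hmm_labels, ces, 0.1, high=True),
                "error": "",
            }
        )
    for c in comparisons:
        rows.append(
            {
                "method": c.method,
                "separation": c.separation,
                "low_tail_purity": c.low_tail_purity,
                "high_tail_purity": c.high_tail_purity,
                "error": c.error or "",
            }
        )
    return pd.DataFrame(rows)
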