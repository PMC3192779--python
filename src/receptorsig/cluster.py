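"""Binary status calling by 2-means clustering in signature space.

Samples are points in the space spanned by the signature's probes; k-means
with k=2 splits them, and the cluster whose centroid sits high on positively
correlated probes (and low on negatively correlated ones) is labelled
positive. Clustering is re-run independently on every dataset — only the
signature itself transfers from training to validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .data import DataError, ExpressionMatrix, Signature

__all__ = ["PredictionResult", "predict_status", "predict_with_best_probe_em", "N_INIT"]

#: seeded k-means restarts; lowest within-cluster sum of squares wins
N_INIT = 25


@dataclass(frozen=True)
class PredictionResult:
    """Per-sample binary calls plus the clustering that produced them."""

    sample_ids: tuple[str, ...]
    predicted: tuple[str, ...]  # "positive" / "negative"
    cluster_centroids: np.ndarray  # (2, n_signature_probes)
    orientation_scores: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.predicted):
            raise DataError("sample_ids and predicted lengths differ")
        bad = set(self.predicted) - {"positive", "negative"}
        if bad:
            raise DataError(f"invalid predicted statuses: {sorted(bad)}")

    def binary(self) -> np.ndarray:
        """0/1 array (positive=1) in sample order."""
        return np.array([1 if p == "positive" else 0 for p in self.predicted])


def _orientation_scores(centroids: np.ndarray, signs: np.ndarray) -> tuple[float, float]:
    # score = mean over signature entries of sign(rho) * centroid coordinate;
    # generalizes "positives overexpress positively correlated probes"
    return float(np.mean(signs * centroids[0])), float(np.mean(signs * centroids[1]))


def predict_status(expr: ExpressionMatrix, sig: Signature, seed: int = 0) -> PredictionResult:
    """2-means call of every sample's status in signature space.

    Euclidean k-means with ``N_INIT`` seeded restarts; the positive cluster
    is the one with the greater sign-weighted centroid mean. An exact tie of
    orientation scores (no consistent direction) is an error, as are missing
    probes and degenerate (all-identical) sample sets.
    """
    missing = [p for p in sig.probe_ids if p not in expr.frame.index]
    if missing:
        raise DataError(f"signature probes missing from matrix: {missing}")
    if expr.n_samples < 2:
        raise DataError("at least 2 samples required for clustering")
    points = expr.frame.loc[sig.probe_ids].to_numpy(dtype=float).T  # samples x probes
    if np.allclose(points, points[0]):
        raise DataError("degenerate clustering: all samples identical in signature space")

    km = KMeans(n_clusters=2, n_init=N_INIT, random_state=seed)
    assignment = km.fit_predict(points)
    centroids = km.cluster_centers_
    score0, score1 = _orientation_scores(centroids, sig.signs)
    if score0 == score1:
        raise DataError("orientation tie: clusters score identically against the signature")
    positive_cluster = 0 if score0 > score1 else 1
    predicted = tuple(
        "positive" if a == positive_cluster else "negative" for a in assignment
    )
    return PredictionResult(
        sample_ids=tuple(expr.sample_ids),
        predicted=predicted,
        cluster_centroids=centroids,
        orientation_scores=(score0, score1),
    )


def predict_with_best_probe_em(
    expr: ExpressionMatrix, probe_id: str, seed: int = 0
) -> PredictionResult:
    """Single-probe baseline: EM mixture call on one probe's expression.

    Delegates to the two-component Gaussian mixture; exists so both
    predictors present the same interface to the pipeline.
    """
    from .mixture import TwoComponentMixture

    if probe_id not in expr.frame.index:
        raise DataError(f"probe {probe_id!r} not present in matrix")
    values = expr.frame.loc[probe_id].to_numpy(dtype=float)
    fit = TwoComponentMixture(values).fit(seed=seed)
    labels = fit.classify(values)
    hi = np.argmax(fit.means)
    centroids = np.array([[fit.means[1 - hi]], [fit.means[hi]]])
    return PredictionResult(
        sample_ids=tuple(expr.sample_ids),
        predicted=tuple(labels),
        cluster_centroids=centroids,
        orientation_scores=(float(centroids[0, 0]), float(centroids[1, 0])),
    )
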