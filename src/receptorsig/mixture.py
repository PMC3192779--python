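"""Two-component univariate Gaussian mixture fitted by EM.

The single-probe-set baseline: receptor status is called from one marker
probe's bimodal expression distribution by fitting a 2-component mixture with
unequal variances and assigning each sample to the component with the higher
posterior, positives being the higher-mean component.

EM is initialized from a seeded 2-means split of the values, iterates until
the log-likelihood gain drops below ``TOL`` (or ``MAX_ITER``), and records
the full log-likelihood trace, which is non-decreasing by construction.
A variance floor prevents likelihood blow-up when a component collapses onto
replicated values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.cluster import KMeans

from .data import DataError

__all__ = [
    "TwoComponentMixture",
    "MixtureResults",
    "fit_two_gaussians",
    "classify",
    "VARIANCE_FLOOR",
]

VARIANCE_FLOOR = 1e-4  # log-intensity^2
TOL = 1e-8
MAX_ITER = 500


@dataclass(frozen=True)
class MixtureResults:
    """Fitted mixture parameters and diagnostics.

    ``means``/``variances``/``weights`` are length-2 arrays in component
    order (no sorting applied); ``loglik_trace`` holds the log-likelihood
    after every EM iteration.
    """

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    variance_floored: bool
    loglik_trace: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise DataError("mixture weights must sum to 1")
        if (self.variances < VARIANCE_FLOOR - 1e-12).any():
            raise DataError("variance below floor")

    @property
    def higher_component(self) -> int:
        return int(np.argmax(self.means))

    def posterior_positive(self, values: np.ndarray) -> np.ndarray:
        """Posterior probability of the higher-mean component per value."""
        values = np.asarray(values, dtype=float)
        dens = np.stack(
            [
                w * norm.pdf(values, m, np.sqrt(v))
                for m, v, w in zip(self.means, self.variances, self.weights)
            ]
        )
        total = dens.sum(axis=0)
        hi = self.higher_component
        with np.errstate(invalid="ignore", divide="ignore"):
            post = np.where(total > 0, dens[hi] / total, 0.5)
        return post

    def classify(self, values: np.ndarray) -> list[str]:
        """positive iff posterior of the higher-mean component >= 0.5."""
        post = self.posterior_positive(values)
        return ["positive" if p >= 0.5 else "negative" for p in post]

    def summary(self) -> str:
        lo, hi = np.argsort(self.means)
        lines = [
            "Two-component Gaussian mixture (EM)",
            "=" * 46,
            f"{'component':<12}{'mean':>10}{'sd':>10}{'weight':>10}",
            f"{'negative':<12}{self.means[lo]:>10.4f}{np.sqrt(self.variances[lo]):>10.4f}"
            f"{self.weights[lo]:>10.4f}",
            f"{'positive':<12}{self.means[hi]:>10.4f}{np.sqrt(self.variances[hi]):>10.4f}"
            f"{self.weights[hi]:>10.4f}",
            "-" * 46,
            f"log-likelihood {self.log_likelihood:.4f}   iterations {self.n_iterations}"
            f"   converged {self.converged}",
        ]
        if self.variance_floored:
            lines.append(f"note: a component variance hit the floor ({VARIANCE_FLOOR:g})")
        return "\n".join(lines)


class TwoComponentMixture:
    """Model object for the univariate 2-component Gaussian mixture."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float).ravel()
        if not np.isfinite(values).all():
            raise DataError("mixture input contains non-finite values")
        if len(np.unique(values)) < 4:
            raise DataError("at least 4 distinct values required to fit a 2-component mixture")
        self.values = values

    def fit(self, seed: int = 0) -> MixtureResults:
        x = self.values
        n = len(x)

        # initialize from a seeded 2-means split
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        assign = km.fit_predict(x.reshape(-1, 1))
        means = np.empty(2)
        variances = np.empty(2)
        weights = np.empty(2)
        for k in (0, 1):
            mask = assign == k
            means[k] = x[mask].mean()
            variances[k] = max(x[mask].var(), VARIANCE_FLOOR)
            weights[k] = mask.mean()
        weights = np.clip(weights, 1e-6, None)
        weights /= weights.sum()

        floored = False
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, MAX_ITER + 1):
            # E step
            log_dens = np.stack(
                [
                    np.log(weights[k]) + norm.logpdf(x, means[k], np.sqrt(variances[k]))
                    for k in (0, 1)
                ]
            )
            log_total = np.logaddexp(log_dens[0], log_dens[1])
            loglik = float(log_total.sum())
            resp = np.exp(log_dens - log_total)  # (2, n)

            # M step
            nk = resp.sum(axis=1)
            nk = np.clip(nk, 1e-10, None)
            means = (resp @ x) / nk
            for k in (0, 1):
                var = float(resp[k] @ (x - means[k]) ** 2 / nk[k])
                if var < VARIANCE_FLOOR:
                    var = VARIANCE_FLOOR
                    floored = True
                variances[k] = var
            weights = nk / n

            trace.append(loglik)
            if len(trace) >= 2 and trace[-1] - trace[-2] < TOL:
                converged = True
                break

        return MixtureResults(
            means=means.copy(),
            variances=variances.copy(),
            weights=weights.copy(),
            log_likelihood=trace[-1],
            n_iterations=it,
            converged=converged,
            variance_floored=floored,
            loglik_trace=np.array(trace),
        )


def fit_two_gaussians(values: np.ndarray, seed: int = 0) -> MixtureResults:
    """Functional wrapper: fit the mixture to a value vector."""
    return TwoComponentMixture(values).fit(seed=seed)


def classify(values: np.ndarray, fit: MixtureResults) -> list[str]:
    """Functional wrapper around :meth:`MixtureResults.classify`."""
    return fit.classify(values)
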