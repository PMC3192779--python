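"""Synthetic expression data with planted receptor-signature structure.

Emulates the features of receptor-status microarray data the pipeline relies
on: marker probes whose expression is bimodal across samples, with the high
mode tracking a latent binary molecular state (both positively and negatively
tracking marker blocks), a large background of status-independent probes, and
clinical labels that are the molecular state corrupted by assay noise
(modelling inter-pathologist discordance in IHC/FISH scoring).

The model is a pure mean shift with homoscedastic Gaussian noise:

* positive marker:  x ~ N(baseline + delta * state,   sigma^2)
* negative marker:  x ~ N(baseline + delta * (1-state), sigma^2)
* background:       x ~ N(baseline, sigma^2)

with state ~ Bernoulli(prevalence) per sample and clinical label = state
flipped with probability ``label_noise``. This is the minimal structure
under which both the 2-means signature predictor and the single-probe EM
baseline are consistent, and it admits a closed-form ideal operating point
(:func:`expected_operating_point`) used as an oracle in recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import ClinicalTable, DataError, ExpressionMatrix, Signature

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "expected_operating_point"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults give a well-powered two-class cohort.

    ``delta`` is the between-class mean shift and ``sigma`` the within-class
    SD, both in log-intensity units; ``delta/sigma`` is the per-marker effect
    size. ``label_noise`` is the probability a clinical label disagrees with
    the molecular state.
    """

    n_samples: int = 300
    prevalence: float = 0.6
    n_pos_markers: int = 12
    n_neg_markers: int = 8
    n_background: int = 2000
    delta: float = 3.0
    sigma: float = 1.0
    label_noise: float = 0.05
    baseline: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos_markers + self.n_neg_markers < 1:
            raise DataError("at least one marker probe required")
        if self.n_background < 0:
            raise DataError("n_background must be non-negative")
        if not (0.0 < self.prevalence < 1.0):
            raise DataError("prevalence must lie in (0, 1)")
        if not (0.0 <= self.label_noise < 0.5):
            raise DataError("label_noise must lie in [0, 0.5)")
        if self.sigma <= 0:
            raise DataError("sigma must be positive")
        if self.n_samples < 2:
            raise DataError("at least 2 samples required")


@dataclass(frozen=True)
class GroundTruth:
    """Latent state and planted signature behind a generated dataset."""

    molecular_state: pd.Series  # 0/1 per sample
    planted_signature: Signature
    config: SyntheticConfig


def _probe_ids(cfg: SyntheticConfig) -> tuple[list[str], list[str], list[str]]:
    n_total = cfg.n_pos_markers + cfg.n_neg_markers + cfg.n_background
    width = max(6, len(str(n_total)))
    ids = [f"SYN_{i:0{width}d}" for i in range(1, n_total + 1)]
    pos = ids[: cfg.n_pos_markers]
    neg = ids[cfg.n_pos_markers : cfg.n_pos_markers + cfg.n_neg_markers]
    background = ids[cfg.n_pos_markers + cfg.n_neg_markers :]
    return pos, neg, background


def generate(
    cfg: SyntheticConfig, receptor: str = "ER"
) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Draw one dataset; fully reproducible from ``cfg.seed``.

    If a drawn cohort ends up single-class (possible at small n or extreme
    prevalence), redraws up to 10 times with a warning before giving up.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    state = None
    for attempt in range(10):
        candidate = (rng.random(n) < cfg.prevalence).astype(int)
        if 0 < candidate.sum() < n:
            state = candidate
            break
        warnings.warn("generated cohort was single-class; redrawing")
    if state is None:
        raise DataError("could not generate a two-class cohort in 10 attempts")

    pos_ids, neg_ids, bg_ids = _probe_ids(cfg)
    sample_ids = [f"SAMP_{i:04d}" for i in range(1, n + 1)]

    rows = []
    if cfg.n_pos_markers:
        shift = cfg.baseline + cfg.delta * state
        rows.append(shift + cfg.sigma * rng.standard_normal((cfg.n_pos_markers, n)))
    if cfg.n_neg_markers:
        shift = cfg.baseline + cfg.delta * (1 - state)
        rows.append(shift + cfg.sigma * rng.standard_normal((cfg.n_neg_markers, n)))
    if cfg.n_background:
        rows.append(cfg.baseline + cfg.sigma * rng.standard_normal((cfg.n_background, n)))
    values = np.vstack(rows)
    frame = pd.DataFrame(values, index=pos_ids + neg_ids + bg_ids, columns=sample_ids)
    expr = ExpressionMatrix(frame, platform_tag="synthetic")

    flips = rng.random(n) < cfg.label_noise
    clinical_state = np.where(flips, 1 - state, state)
    status = pd.Series(
        np.where(clinical_state == 1, "positive", "negative"), index=sample_ids
    )
    clin = ClinicalTable(status, receptor=receptor, assay="synthetic")

    planted = Signature.from_pairs(
        receptor,
        cutoff=0.5,  # nominal; planted signs are exact +/-1
        pairs=[(p, 1.0) for p in pos_ids] + [(p, -1.0) for p in neg_ids],
        source_tag="planted",
    )
    truth = GroundTruth(
        molecular_state=pd.Series(state, index=sample_ids),
        planted_signature=planted,
        config=cfg,
    )
    return expr, clin, truth


def expected_operating_point(cfg: SyntheticConfig) -> tuple[float, float]:
    """Closed-form (sensitivity, specificity), percent, of the ideal caller.

    An ideal midpoint threshold on the mean of the k marker probes (signs
    aligned) misclassifies the molecular state with probability
    ``1 - Phi(d/2)`` where ``d = delta * sqrt(k) / sigma``; composing with
    label noise ``eps`` (labels flip independently of the call) gives

        expected = (1 - eps) * Phi(d/2) + eps * (1 - Phi(d/2))

    for both sensitivity and specificity (the construction is symmetric in
    the two classes).
    """
    k = cfg.n_pos_markers + cfg.n_neg_markers
    d = cfg.delta * np.sqrt(k) / cfg.sigma
    p_correct = float(norm.cdf(d / 2.0))
    eps = cfg.label_noise
    expected = (1 - eps) * p_correct + eps * (1 - p_correct)
    return 100.0 * expected, 100.0 * expected
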