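"""Group-average and noisy group-average FC predictors.

These are the package's central null models. The group-average predictor
(avgFC) assigns every validation subject the mean empirical FC of the
training folds — a predictor that uses no data from the subject it
predicts. The noisy group-average predictor (navgFC) adds independent
symmetric Gaussian noise per subject, which lowers prediction performance
in a tunable way while still carrying zero subject-specific information;
with its noise sd tuned, it mimics the reported performance of published
individual-level prediction models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Cohort, FoldAssignment, devectorize, n_edges


@dataclass(frozen=True)
class NavgConfig:
    """sigma is in FC correlation units; 0.1 mimics the published
    individual-level deep-learning performance regime."""

    sigma: float = 0.1
    seed: int = 0
    clip: bool = False  # clip predictions into [-1, 1] (off by default)

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class PredictorOutput:
    """Per-subject predicted FC, aligned with the cohort subject order.

    ``edge_predictions`` has shape (n_subjects, p(p-1)/2); every subject's
    row was produced by a model or average fitted without that subject.
    """

    predictor_name: str
    folds: FoldAssignment
    edge_predictions: np.ndarray
    subject_ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.edge_predictions.shape[0]

    def matrices(self) -> list:
        return [devectorize(e, diagonal=1.0) for e in self.edge_predictions]


def _check(cohort: Cohort, folds: FoldAssignment):
    if folds.n != len(cohort):
        raise ValueError("fold assignment does not match cohort size")
    if folds.k < 2:
        raise ValueError("need at least 2 folds (single-fold input is invalid)")
    for s in cohort:
        if s.efc is None:
            raise ValueError(f"subject {s.subject_id} has no empirical FC")


def avg_predictor(cohort: Cohort, folds: FoldAssignment) -> PredictorOutput:
    """Training-fold group-average FC as the prediction for every
    validation subject (the zero-noise null predictor)."""
    _check(cohort, folds)
    efc = cohort.efc_edges()
    preds = np.empty_like(efc)
    for f, train, val in folds.folds():
        preds[val] = efc[train].mean(axis=0)
    return PredictorOutput("avgFC", folds, preds, cohort.subject_ids)


def navg_predictor(
    cohort: Cohort, folds: FoldAssignment, cfg: NavgConfig | None = None
) -> PredictorOutput:
    """Training-fold average plus independent per-subject Gaussian noise.

    Noise is drawn i.i.d. N(0, sigma^2) on the upper-triangle edges (then
    mirrored by construction of the edge representation), independently
    across subjects; the diagonal stays 1. Each subject's noise stream is
    derived from (seed, subject index), so predictions are reproducible
    subject-by-subject.
    """
    cfg = cfg or NavgConfig()
    out = avg_predictor(cohort, folds)
    preds = out.edge_predictions
    if cfg.sigma > 0:
        for i in range(preds.shape[0]):
            rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, i)))
            preds[i] = preds[i] + cfg.sigma * rng.standard_normal(preds.shape[1])
    if cfg.clip:
        np.clip(preds, -1.0, 1.0, out=preds)
    return PredictorOutput("navgFC", folds, preds, cohort.subject_ids)


def tune_sigma(
    cohort: Cohort,
    folds: FoldAssignment,
    target_performance: float,
    seed: int = 0,
    tol: float = 0.01,
    max_iter: int = 40,
) -> float:
    """Find the navgFC noise sd whose mean per-subject prediction
    correlation matches ``target_performance`` (within ``tol``).

    The zero-noise performance of the group average is a ceiling ("glass
    ceiling"): targets above it raise a ValueError. Below the ceiling the
    performance is monotone decreasing in sigma, so plain bisection works.
    """
    from .evaluation import per_subject_correlation

    def perf(sigma):
        out = navg_predictor(cohort, folds, NavgConfig(sigma=sigma, seed=seed))
        return float(np.nanmean(per_subject_correlation(out, cohort)))

    ceiling = perf(0.0)
    if target_performance > ceiling + 1e-9:
        raise ValueError(
            f"target {target_performance:.3f} is above the group-average "
            f"ceiling {ceiling:.3f}; no amount of noise can raise performance"
        )
    if ceiling - target_performance <= tol:
        return 0.0
    lo, hi = 0.0, 0.5
    while perf(hi) > target_performance and hi < 64:
        hi *= 2
    if perf(hi) > target_performance:
        raise ValueError(f"target {target_performance:.3f} unreachable even at sigma={hi}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        pm = perf(mid)
        if abs(pm - target_performance) <= tol:
            return mid
        if pm > target_performance:
            lo = mid
        else:
            hi = mid
    warnings.warn("tune_sigma hit the iteration limit; returning midpoint")
    return 0.5 * (lo + hi)
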