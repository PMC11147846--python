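"""Performance statistics for FC predictors.

Four complementary views:

* per-subject Pearson correlation between predicted and empirical FC edge
  vectors (the distribution usually reported as "individual-level
  performance");
* concatenated variance explained — squared Pearson correlation after
  concatenating all subjects' edge vectors (the "whole data set R^2"
  convention some studies use; note it is sign-blind);
* the preservation correlation — across subject pairs, the correlation
  between inter-subject eFC similarity and inter-subject prediction
  similarity, which tests whether a predictor preserves the *geometry* of
  individual differences rather than just their spread;
* per-parcel prediction errors log(1 - r), aggregated over the seven
  canonical functional systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Atlas, Cohort, devectorize

_R_CLIP = 1.0 - 1e-9


def correlation_from_variance_explained(r2: float) -> float:
    """|R| implied by a univariate variance explained: sqrt(R^2).

    Studies reporting a single R^2 over the concatenated data and studies
    reporting mean per-subject correlations are on different scales; this
    converts the former to a correlation magnitude so the two can be put
    side by side (the sign is not recoverable from R^2).
    """
    if not (0.0 <= r2 <= 1.0):
        raise ValueError("variance explained must lie in [0, 1]")
    return float(np.sqrt(r2))


def _edge_matrix(predictions) -> np.ndarray:
    from .baselines import PredictorOutput

    if isinstance(predictions, PredictorOutput):
        return predictions.edge_predictions
    return np.asarray(predictions, dtype=float)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    # tolerance-based degeneracy check: a vector of identical values can
    # carry rounding jitter ~1e-17 and still has no usable variance
    if x.std() <= 1e-12 * (1 + np.abs(x).max()) or y.std() <= 1e-12 * (1 + np.abs(y).max()):
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def per_subject_correlation(predictions, cohort: Cohort) -> np.ndarray:
    """Pearson correlation of predicted vs empirical edge vectors, one per
    subject. Constant prediction vectors yield NaN (flagged by a warning)."""
    P = _edge_matrix(predictions)
    E = cohort.efc_edges()
    if P.shape != E.shape:
        raise ValueError(f"prediction shape {P.shape} != eFC shape {E.shape}")
    out = np.array([_safe_corr(P[i], E[i]) for i in range(P.shape[0])])
    if np.isnan(out).any():
        warnings.warn(
            f"{int(np.isnan(out).sum())} subject(s) had a constant prediction "
            "vector; their correlation is undefined (NaN)"
        )
    return out


def concatenated_r2(predictions, cohort: Cohort) -> float:
    """Squared Pearson correlation between the concatenation over subjects
    of predicted and empirical edge vectors. Sign-blind: a perfectly
    anti-correlated prediction also scores 1."""
    P = _edge_matrix(predictions).ravel()
    E = cohort.efc_edges().ravel()
    r = _safe_corr(P, E)
    return float(r**2)


def pairwise_correlations(edge_rows: np.ndarray) -> np.ndarray:
    """Condensed vector of Pearson correlations over all row pairs i<j."""
    R = np.corrcoef(edge_rows)
    iu = np.triu_indices(edge_rows.shape[0], k=1)
    return R[iu]


def preservation_correlation(predictions, cohort: Cohort) -> float:
    """Correlation, across subject pairs, of inter-eFC vs inter-prediction
    similarity.

    Returns NaN (with a warning) when the inter-prediction similarities
    have no variance — e.g. for the noise-free group-average predictor,
    where all predictions within a fold are identical.
    """
    P = _edge_matrix(predictions)
    if P.shape[0] < 3:
        raise ValueError("need at least 3 subjects for the preservation statistic")
    x = pairwise_correlations(cohort.efc_edges())
    y = pairwise_correlations(P)
    if np.std(y) < 1e-12 or np.isnan(y).any() and np.nanstd(y) < 1e-12:
        warnings.warn(
            "inter-prediction similarities are constant; preservation "
            "correlation is undefined (NaN)"
        )
        return np.nan
    return _safe_corr(x, y)


def parcel_error_matrix(predictions, cohort: Cohort) -> np.ndarray:
    """Per-subject, per-parcel prediction error log(1 - r).

    r is the Pearson correlation between a parcel's row of the predicted
    and of the empirical FC matrix (that parcel's diagonal entry excluded);
    r is clipped at 1 - 1e-9 so perfect rows stay finite. Natural log.
    Shape (n_subjects, p); undefined rows (constant) are NaN.
    """
    P = _edge_matrix(predictions)
    n = P.shape[0]
    p = cohort.atlas.p
    errors = np.empty((n, p))
    mask = ~np.eye(p, dtype=bool)
    for i in range(n):
        pm = devectorize(P[i], diagonal=1.0)
        em = cohort[i].efc.values
        for a in range(p):
            r = _safe_corr(pm[a][mask[a]], em[a][mask[a]])
            errors[i, a] = np.log(1.0 - min(r, _R_CLIP)) if np.isfinite(r) else np.nan
    return errors


def network_error_map(predictions, cohort: Cohort, atlas: Atlas | None = None) -> dict:
    """Mean log(1 - r) per functional system: parcel errors averaged within
    each network, then across subjects."""
    atlas = atlas or cohort.atlas
    errors = parcel_error_matrix(predictions, cohort)
    out = {}
    for net in sorted(set(atlas.networks)):
        idx = atlas.parcels_in(net)
        out[net] = float(np.nanmean(errors[:, idx]))
    return out


@dataclass
class EvaluationReport:
    predictor_name: str
    per_subject_r: np.ndarray
    concatenated_r2: float
    preservation_r: float
    network_errors: dict
    summary: dict = field(default_factory=dict)

    def __post_init__(self):
        r = self.per_subject_r[~np.isnan(self.per_subject_r)]
        self.summary = {
            "mean_r": float(r.mean()) if r.size else np.nan,
            "sd_r": float(r.std(ddof=1)) if r.size > 1 else np.nan,
            "q25_r": float(np.percentile(r, 25)) if r.size else np.nan,
            "median_r": float(np.percentile(r, 50)) if r.size else np.nan,
            "q75_r": float(np.percentile(r, 75)) if r.size else np.nan,
        }


def evaluate(predictions, cohort: Cohort, name: str | None = None) -> EvaluationReport:
    """All statistics in one report."""
    from .baselines import PredictorOutput

    if name is None:
        name = (
            predictions.predictor_name
            if isinstance(predictions, PredictorOutput)
            else "predictor"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pres = preservation_correlation(predictions, cohort)
        psr = per_subject_correlation(predictions, cohort)
    return EvaluationReport(
        predictor_name=name,
        per_subject_r=psr,
        concatenated_r2=concatenated_r2(predictions, cohort),
        preservation_r=pres,
        network_errors=network_error_map(predictions, cohort),
    )
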