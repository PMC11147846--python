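"""Cognition-prediction control battery.

The battery asks whether a predicted FC carries usable individual
information: cognition is predicted by lasso regression (nested-CV penalty
selection) from ten feature variants — empirical FC, SC, predicted FC
(pFC), pFC shuffled between subjects (rpFC), noisy and noise-free group
averages — each with and without the subject's own SC regressed out
(suffix "\\SC"). The key dissociation: if a variant only becomes predictive
after regressing out the *correct* subject's SC, the predictive power came
from the regression step (which injects the subject's SC into the
residuals), not from the predictor itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LassoCV

from .core import Cohort, DegenerateInputError, make_folds

LASSO_ALPHAS = np.logspace(-3, 0.5, 8)


@dataclass
class CognitionResult:
    predictor_name: str
    r_per_loop: np.ndarray
    p_per_loop: np.ndarray
    degenerate: bool = False
    summary: dict = field(default_factory=dict)

    def __post_init__(self):
        r = np.asarray(self.r_per_loop, float)
        p = np.asarray(self.p_per_loop, float)
        ok = ~np.isnan(r)
        self.summary = {
            "mean_r": float(r[ok].mean()) if ok.any() else np.nan,
            "var_r": float(r[ok].var(ddof=1)) if ok.sum() > 1 else np.nan,
            "median_p": float(np.median(p[ok])) if ok.any() else 1.0,
            "n_loops": int(r.size),
        }

    @property
    def significant(self) -> bool:
        """Median p over outer loops below 0.05 *and* positive mean
        correlation. The sign requirement matters at desk scale: a
        predictor whose lasso collapses to fold-wise intercepts produces
        out-of-fold predictions anti-correlated with the outcome (each
        training mean is anti-correlated with its held-out fold mean), a
        cross-validation artifact that can reach nominal significance with
        a *negative* r. Predicting cognition means correlating positively
        with it. The 10-test family of the battery is annotated, not
        corrected, in reports."""
        return bool(self.summary["median_p"] < 0.05 and self.summary["mean_r"] > 0)


def regress_out_sc(fc_edges: np.ndarray, sc_edges: np.ndarray) -> np.ndarray:
    """OLS residuals of a subject's FC edge vector on [1, SC edge vector].

    Computed per subject across edges; the residuals are mean-zero and
    exactly orthogonal to the centered SC vector.
    """
    fc = np.asarray(fc_edges, float).ravel()
    sc = np.asarray(sc_edges, float).ravel()
    if fc.size != sc.size:
        raise ValueError("FC and SC edge vectors must have equal length")
    if sc.std() == 0:
        raise DegenerateInputError("constant SC edge vector; regression undefined")
    X = np.column_stack([np.ones_like(sc), sc])
    beta, *_ = np.linalg.lstsq(X, fc, rcond=None)
    return fc - X @ beta


def regress_out_sc_rows(fc_rows: np.ndarray, sc_rows: np.ndarray) -> np.ndarray:
    """Row-wise (per-subject) regress-out for stacked edge matrices."""
    return np.vstack(
        [regress_out_sc(f, s) for f, s in zip(fc_rows, sc_rows)]
    )


def regress_out_sc_per_edge(fc_rows: np.ndarray, sc_rows: np.ndarray) -> np.ndarray:
    """Alternative convention, behind this explicit name: residualize each
    *edge* across subjects instead of each subject across edges."""
    return regress_out_sc_rows(fc_rows.T, sc_rows.T).T


def shuffle_pfc(edge_rows: np.ndarray, seed: int = 0) -> np.ndarray:
    """Reassign predicted FC across subjects by a fixed-point-free
    permutation (Sattolo's algorithm: a single seeded cycle), so no subject
    keeps its own prediction; the multiset of rows is preserved."""
    X = np.asarray(edge_rows)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects to shuffle predictions")
    rng = np.random.default_rng(seed)
    perm = np.arange(n)
    for i in range(n - 1, 0, -1):  # Sattolo: cyclic, hence derangement
        j = rng.integers(0, i)
        perm[i], perm[j] = perm[j], perm[i]
    return X[perm]


def predict_cognition(
    features: np.ndarray,
    y: np.ndarray,
    k_inner: int = 10,
    n_outer: int = 10,
    seed: int = 0,
    name: str = "predictor",
) -> CognitionResult:
    """Cross-validated lasso prediction of cognition from edge features.

    Per outer loop: a fresh seeded k-fold split; on each training split a
    lasso is fitted with its penalty chosen by nested cross-validation
    (log-spaced grid) on the training data only; out-of-fold predictions
    are concatenated and correlated with the true scores, giving one (r, p)
    pair per loop. Degenerate designs (features constant within training
    folds, as for the group-average predictor) yield constant predictions;
    those loops are flagged and reported as undefined.
    """
    X = np.asarray(features, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("feature rows must match number of subjects")
    if n < 20:
        raise ValueError("need at least 20 subjects for the nested-CV design")
    if y.std() == 0:
        raise DegenerateInputError("cognition scores are constant")
    rs, ps, degenerate = [], [], False
    for loop in range(n_outer):
        folds = make_folds(n, k_inner, seed=int(np.random.SeedSequence((seed, loop)).generate_state(1)[0] % (2**31)))
        pred = np.empty(n)
        fold_constant = []
        for f, train, val in folds.folds():
            Xt, Xv = X[train], X[val]
            mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
            sd[sd == 0] = 1.0
            Xt = (Xt - mu) / sd
            Xv = (Xv - mu) / sd
            if np.ptp(Xt, axis=0).max() == 0:
                pred[val] = y[train].mean()
                fold_constant.append(True)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = LassoCV(alphas=LASSO_ALPHAS, cv=3, max_iter=5000).fit(
                    Xt, y[train]
                )
            pred[val] = model.predict(Xv)
            fold_constant.append(np.ptp(pred[val]) <= 1e-12)
        # a loop whose every fold predicts a constant (intercept-only lasso)
        # has no within-fold information; its correlation with the outcome
        # reflects only fold-mean offsets and is reported as undefined
        if np.std(pred) < 1e-12 or all(fold_constant):
            rs.append(np.nan)
            ps.append(1.0)
            degenerate = True
            continue
        r, p = stats.pearsonr(pred, y)
        rs.append(float(r))
        ps.append(float(p))
    if degenerate:
        warnings.warn(
            f"{name}: constant out-of-fold predictions in some loops "
            "(intercept-only lasso); those loops are undefined"
        )
    return CognitionResult(name, np.array(rs), np.array(ps), degenerate=degenerate)


BATTERY_VARIANTS = (
    "eFC", "SC", "pFC", "pFC\\SC", "rpFC", "rpFC\\SC",
    "navgFC", "navgFC\\SC", "avgFC", "avgFC\\SC",
)


def run_battery(
    cohort: Cohort,
    sc_edges: np.ndarray,
    predictions_by_method: dict,
    seed: int = 0,
    k_inner: int = 10,
    n_outer: int = 10,
) -> list:
    """Run the full ten-variant battery.

    Parameters
    ----------
    sc_edges : (n, E) array
        The SC feature representation used both as the "SC" predictor and
        as the regressor in the "\\SC" variants (typically the
        rank-Gaussian-resampled SC edges, which carry the linear FC-SC
        dependence the regress-out step targets).
    predictions_by_method : dict
        Edge-prediction matrices (or PredictorOutput) keyed by "pFC",
        "navgFC", "avgFC". A missing "pFC" drops the pFC/rpFC variants
        with a warning instead of failing.
    """
    from .baselines import PredictorOutput

    def edges_of(x):
        return x.edge_predictions if isinstance(x, PredictorOutput) else np.asarray(x, float)

    y = cohort.cognition_scores()
    efc = cohort.efc_edges()
    feature_sets = {"eFC": efc, "SC": sc_edges}
    preds = {k: edges_of(v) for k, v in predictions_by_method.items()}
    if "pFC" in preds:
        feature_sets["pFC"] = preds["pFC"]
        feature_sets["rpFC"] = shuffle_pfc(preds["pFC"], seed=seed)
    else:
        warnings.warn("no pFC predictions supplied; battery runs without pFC/rpFC")
    for k in ("navgFC", "avgFC"):
        if k in preds:
            feature_sets[k] = preds[k]
    results = []
    for variant in BATTERY_VARIANTS:
        base = variant.split("\\")[0]
        if base not in feature_sets:
            continue
        F = feature_sets[base]
        if variant.endswith("\\SC"):
            F = regress_out_sc_rows(F, sc_edges)
        results.append(
            predict_cognition(
                F, y, k_inner=k_inner, n_outer=n_outer, seed=seed, name=variant
            )
        )
    return results


def battery_table(results) -> "pandas.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "predictor": r.predictor_name,
                "mean_r": r.summary["mean_r"],
                "var_r": r.summary["var_r"],
                "median_p": r.summary["median_p"],
                "significant": r.significant,
            }
            for r in results
        ]
    )
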