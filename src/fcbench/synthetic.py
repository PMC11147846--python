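"""Synthetic connectome cohorts with controllable inter-subject structure.

The generator produces, for each subject, a latent correlation target

    C_i = (u u^T) o G  +  (v v^T) o R_i ,      u_a^2 + v_a^2 = 1,

where ``o`` is the elementwise (Schur) product, ``G`` is a shared
network-structured group template, ``R_i`` is a subject-specific low-rank
random correlation matrix, and ``v_a`` is a per-parcel deviation amplitude
scaled by that parcel's functional network. Because both Schur factors are
valid correlation matrices and the amplitudes satisfy u_a^2 + v_a^2 = 1,
every ``C_i`` is a valid (unit-diagonal, PSD) correlation matrix by
construction — no projection step is needed. Gaussian time series of length
T are then drawn with covariance ``C_i`` and empirical FC is computed as
pairwise Pearson correlation, so within-subject estimation noise scales as
1/sqrt(T) exactly as in real BOLD-derived FC.

The global deviation amplitude is auto-calibrated (bisection on a pilot
batch) so that the realized mean pairwise inter-subject FC correlation
("inter-eFC") hits a requested target; human-connectome cohorts at
anatomical (~68-parcel) granularity center around 0.7, which makes the mean
correlation of an individual FC with the group average come out near
sqrt(0.7) ~ 0.84 — a consistency that emerges from the model rather than
being imposed.

Structural connectivity is generated as heavy-tailed streamline-like counts
whose individual deviations partially share the FC deviations, and a
cognition score is a sparse linear function of standardized SC edges plus
noise. Defaults emulate a regime where individual-level edgewise SC-FC
coupling is weak: most of the across-subject SC variance is SC-private, so
a predictor of FC from SC gains little over the group average — the regime
observed in large human cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import SimpleNamespace

import numpy as np
from scipy import stats

from .core import (
    FC,
    SC_COUNTS,
    Atlas,
    Cohort,
    ConnectivityMatrix,
    Subject,
    compute_efc,
    devectorize,
    vectorize,
)
from .atlases import get_atlas

#: per-network multipliers on individual deviation *variance*; ordering
#: limbic > frontoparietal ~ default mode > attention > visual ~ somatomotor
#: mirrors where individual FC deviates most from the group average.
DEFAULT_NETWORK_DEVIATION = {
    "LSN": 2.2,
    "FPN": 1.5,
    "DMN": 1.5,
    "VAN": 1.1,
    "DAN": 1.1,
    "VN": 0.7,
    "SMN": 0.7,
}


class CalibrationError(RuntimeError):
    """Requested inter-subject similarity is unreachable for this config."""


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Attributes
    ----------
    n_subjects, atlas, T : cohort size, parcellation preset, time points.
    rho_target : target mean pairwise inter-subject eFC correlation in [0, 1].
    network_deviation_scale : map network -> variance multiplier for
        individual deviations of parcels in that network.
    deviation_rank : rank of each subject's random deviation matrix R_i;
        controls how structured (low-rank) individual deviations are.
    sc_coupling : weight in [0, 1] of the shared template vs the subject's
        FC-linked deviation in the latent SC strength.
    sc_log_sd, sc_log_base, sc_log_noise_sd : scale, offset and private
        noise of log streamline counts; sc_log_sd ~ 1.5 spans several
        orders of magnitude in the counts.
    cognition_beta : effect sizes on the selected standardized SC edge
        features (None -> 0.6 per feature); all-zero decouples cognition
        from connectivity entirely.
    cognition_noise_sd : sd of the additive noise on the cognition score.
    deviation_amplitude : optional override of the calibrated global
        deviation amplitude (skips calibration when set).
    """

    n_subjects: int = 100
    atlas: str | Atlas = "dk_like"
    T: int = 1000
    rho_target: float = 0.70
    network_deviation_scale: dict = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_DEVIATION)
    )
    deviation_rank: int = 5
    sc_coupling: float = 0.8
    sc_log_sd: float = 1.5
    sc_log_base: float = 2.5
    sc_log_noise_sd: float = 0.5
    cognition_n_features: int = 5
    cognition_beta: np.ndarray | None = None
    cognition_noise_sd: float = 0.5
    deviation_amplitude: float | None = None
    calibration_tol: float = 0.008
    calibration_pilot: int = 30
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rho_target <= 1.0):
            raise ValueError("rho_target must lie in [0, 1]")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if any(v < 0 for v in self.network_deviation_scale.values()):
            raise ValueError("network deviation scales must be nonnegative")
        if not (0.0 <= self.sc_coupling <= 1.0):
            raise ValueError("sc_coupling must lie in [0, 1]")
        if self.cognition_noise_sd < 0:
            raise ValueError("cognition_noise_sd must be nonnegative")

    def resolve_atlas(self) -> Atlas:
        return get_atlas(self.atlas) if isinstance(self.atlas, str) else self.atlas


# ---------------------------------------------------------------------------
# template and subject-level latent structure


def _rngs(seed: int) -> SimpleNamespace:
    root = np.random.SeedSequence(seed)
    names = ("template", "subjects", "pilot", "sc", "cognition")
    children = root.spawn(len(names))
    return SimpleNamespace(**{n: np.random.default_rng(c) for n, c in zip(names, children)})


def make_group_template(atlas: Atlas, rng: np.random.Generator) -> np.ndarray:
    """Network-structured group correlation template.

    Built from factor loadings: one global factor (positive baseline
    coupling everywhere), one factor per functional system (within-network
    correlations are elevated), plus parcel-specific noise. The loading
    Gram matrix is normalized to a correlation matrix.
    """
    p = atlas.p
    nets = sorted(set(atlas.networks))
    q = 1 + len(nets) + 3
    L = np.zeros((p, q))
    L[:, 0] = 0.50 + 0.10 * rng.standard_normal(p)  # global factor
    for k, net in enumerate(nets):
        idx = atlas.parcels_in(net)
        L[idx, 1 + k] = 0.55 + 0.10 * rng.standard_normal(idx.size)
    L[:, 1 + len(nets):] = 0.25 * rng.standard_normal((p, 3))
    sigma = L @ L.T + np.diag(0.35 + 0.1 * rng.random(p))
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _subject_deviation(p: int, rank: int, rng: np.random.Generator) -> np.ndarray:
    """Random low-rank correlation matrix (the subject's deviation R_i)."""
    W = rng.standard_normal((p, rank))
    sigma = W @ W.T + 1e-6 * np.eye(p)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _parcel_amplitudes(atlas: Atlas, scales: dict, amplitude: float) -> np.ndarray:
    """Per-parcel deviation amplitude v_a = amplitude * s_a, clipped below 1.

    s_a is the network sd multiplier, normalized so mean(s_a^2) = 1; the
    clipping keeps u_a^2 = 1 - v_a^2 positive.
    """
    s2 = np.array([scales.get(n, 0.0) for n in atlas.networks], dtype=float)
    if s2.max() == 0:
        return np.zeros(atlas.p)
    s2 = s2 / s2.mean()
    return np.clip(amplitude * np.sqrt(s2), 0.0, 0.95)


def _latent_correlation(G, R_i, v) -> np.ndarray:
    u2 = 1.0 - v**2
    C = np.sqrt(np.outer(u2, u2)) * G + np.outer(v, v) * R_i
    np.fill_diagonal(C, 1.0)
    return C


def _sample_efc(C: np.ndarray, T: int, rng: np.random.Generator,
                atlas: Atlas | None = None) -> tuple:
    """Draw Gaussian time series with covariance C and return (ts, efc)."""
    try:
        A = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(C)
        A = V * np.sqrt(np.clip(w, 0, None))
    ts = rng.standard_normal((T, len(C))) @ A.T
    return ts, compute_efc(ts, atlas)


def mean_inter_subject_correlation(edge_rows: np.ndarray) -> float:
    """Mean Pearson correlation over all pairs of rows (subject pairs)."""
    n = edge_rows.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    R = np.corrcoef(edge_rows)
    iu = np.triu_indices(n, k=1)
    return float(R[iu].mean())


# ---------------------------------------------------------------------------
# calibration


def _realized_rho(G, atlas, cfg, amplitude, rng) -> float:
    v = _parcel_amplitudes(atlas, cfg.network_deviation_scale, amplitude)
    edges = []
    for _ in range(cfg.calibration_pilot):
        R_i = _subject_deviation(atlas.p, cfg.deviation_rank, rng)
        C = _latent_correlation(G, R_i, v)
        _, efc = _sample_efc(C, cfg.T, rng)
        edges.append(efc.edges())
    return mean_inter_subject_correlation(np.vstack(edges))


def calibrate_deviation_amplitude(config: GeneratorConfig) -> float:
    """Bisection on the global deviation amplitude so that the realized mean
    inter-eFC (measured on a pilot batch) hits ``rho_target``.

    Raises
    ------
    CalibrationError
        If the target is above the finite-T ceiling (reachable only with
        zero deviations) or below the floor at maximal deviations; the
        message suggests which parameter to change.
    """
    atlas = config.resolve_atlas()
    scales = config.network_deviation_scale
    if all(v == 0 for v in scales.values()):
        if config.rho_target < 0.9:
            raise CalibrationError(
                "all network deviation scales are zero, so inter-eFC is pinned "
                "near 1; lower rho_target is unreachable — set nonzero "
                "network_deviation_scale"
            )
        return 0.0
    rngs = _rngs(config.seed)
    G = make_group_template(atlas, rngs.template)

    def rho_at(b):
        # common random numbers across evaluations: the same pilot draws are
        # reused for every amplitude, so rho_at is a smooth, strictly
        # monotone function of b and bisection converges cleanly
        return _realized_rho(G, atlas, config, b, np.random.default_rng(
            np.random.SeedSequence((config.seed, 104729))
        ))

    s_max = max(np.sqrt(np.array(list(scales.values())) / np.mean(list(scales.values()))))
    b_hi = 0.95 / s_max
    rho_ceiling = rho_at(0.0)
    rho_floor = rho_at(b_hi)
    if config.rho_target > rho_ceiling - 0.005:
        raise CalibrationError(
            f"rho_target={config.rho_target} exceeds the finite-T ceiling "
            f"({rho_ceiling:.3f}); increase T or reduce rho_target"
        )
    if config.rho_target < rho_floor + 0.005:
        raise CalibrationError(
            f"rho_target={config.rho_target} is below the floor "
            f"({rho_floor:.3f}) at maximal deviations; increase "
            "network_deviation_scale or reduce rho_target"
        )
    lo, hi = 0.0, b_hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        rho = rho_at(mid)
        if abs(rho - config.rho_target) <= config.calibration_tol:
            return mid
        if rho > config.rho_target:
            lo = mid  # too similar -> need larger deviations
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: GeneratorConfig, store_time_series: bool = False) -> Cohort:
    """Generate a cohort of coupled time series and empirical FC.

    The returned cohort carries a ``latents`` attribute (group template edge
    vector and per-subject deviation edge vectors) consumed by
    :func:`generate_sc`. Deterministic for a fixed config seed.
    """
    atlas = config.resolve_atlas()
    amplitude = config.deviation_amplitude
    if amplitude is None:
        scales = config.network_deviation_scale
        amplitude = (
            0.0
            if all(v == 0 for v in scales.values())
            else calibrate_deviation_amplitude(config)
        )
    rngs = _rngs(config.seed)
    G = make_group_template(atlas, rngs.template)
    v = _parcel_amplitudes(atlas, config.network_deviation_scale, amplitude)

    cohort = Cohort(atlas=atlas)
    r_edges = np.empty((config.n_subjects, atlas.p * (atlas.p - 1) // 2))
    for i in range(config.n_subjects):
        R_i = _subject_deviation(atlas.p, config.deviation_rank, rngs.subjects)
        C = _latent_correlation(G, R_i, v)
        ts, efc = _sample_efc(C, config.T, rngs.subjects, atlas)
        r_edges[i] = vectorize(R_i)
        cohort.add(
            Subject(
                subject_id=f"sub-{i:04d}",
                time_series=ts if store_time_series else None,
                efc=efc,
            )
        )
    cohort.latents = SimpleNamespace(
        template_edges=vectorize(G),
        deviation_edges=r_edges,
        deviation_amplitude=amplitude,
        parcel_amplitudes=v,
    )
    return cohort


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom-type, across edges)."""
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def generate_sc(cohort: Cohort, config: GeneratorConfig) -> None:
    """Attach heavy-tailed streamline-count SC matrices to a cohort.

    Latent SC strength mixes the shared template with the subject's FC
    deviation (weight ``sc_coupling`` on the shared part); counts are
    ``round(exp(a * normal-scores(latent) + base + noise))``, giving
    nonnegative, symmetric, zero-diagonal counts spanning orders of
    magnitude, with zeros for the weakest edges.
    """
    if not hasattr(cohort, "latents"):
        raise ValueError(
            "cohort has no latent templates; generate it with generate_cohort"
        )
    rng = _rngs(config.seed).sc
    g = cohort.latents.template_edges
    g_std = (g - g.mean()) / g.std()
    w = config.sc_coupling
    for i, subject in enumerate(cohort):
        d = cohort.latents.deviation_edges[i]
        d_std = (d - d.mean()) / d.std()
        latent = w * g_std + (1.0 - w) * d_std
        z = _normal_scores(latent)
        log_counts = (
            config.sc_log_sd * z
            + config.sc_log_base
            + config.sc_log_noise_sd * rng.standard_normal(z.size)
        )
        counts = np.round(np.exp(log_counts))
        subject.sc = ConnectivityMatrix(
            devectorize(counts, diagonal=0.0), SC_COUNTS, cohort.atlas
        )


def generate_cognition(cohort: Cohort, config: GeneratorConfig) -> None:
    """Attach a cognition score: sparse linear function of standardized SC
    edge features plus Gaussian noise.

    Features are a seeded subset of edges with above-median group-mean
    count (avoiding all-zero edges), on the log(1 + count) scale — the
    scale on which streamline counts are approximately Gaussian, so the
    trait loads on connection *strength* rather than being dominated by
    the heaviest-tailed counts; each feature is z-scored across subjects.
    With an all-zero ``cognition_beta`` the score is pure noise,
    independent of all connectivity.
    """
    if any(s.sc is None for s in cohort):
        raise ValueError("generate SC before cognition (generate_sc)")
    rng = _rngs(config.seed).cognition
    X = np.log1p(cohort.sc_edges())
    strong = np.flatnonzero(X.mean(axis=0) > np.median(X.mean(axis=0)))
    k = min(config.cognition_n_features, strong.size)
    features = rng.choice(strong, size=k, replace=False)
    beta = (
        np.full(k, 0.6)
        if config.cognition_beta is None
        else np.asarray(config.cognition_beta, dtype=float)[:k]
    )
    F = X[:, features]
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    F_std = (F - F.mean(axis=0)) / sd
    y = F_std @ beta + config.cognition_noise_sd * rng.standard_normal(len(cohort))
    for subject, yi in zip(cohort, y):
        subject.cognition = float(yi)
    cohort.latents.cognition_features = features
    cohort.latents.cognition_beta = beta


def generate_full_cohort(config: GeneratorConfig, store_time_series: bool = False) -> Cohort:
    """Convenience wrapper: FC + SC + cognition in one call."""
    cohort = generate_cohort(config, store_time_series=store_time_series)
    generate_sc(cohort, config)
    generate_cognition(cohort, config)
    return cohort
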