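"""Rank-based Gaussian resampling of streamline-count matrices.

Raw streamline counts span orders of magnitude and are heavily zero-inflated.
The resampling replaces the counts by standard-normal draws assigned in rank
order (smallest draw to smallest count, and so on), which preserves the rank
structure while normalizing the marginal distribution; the result is then
rescaled so the off-diagonal entries have mean 0.5 and standard deviation 0.1
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    SC_COUNTS,
    SC_RESAMPLED,
    ConnectivityMatrix,
    DegenerateInputError,
    devectorize,
    vectorize,
)


@dataclass(frozen=True)
class ResampleConfig:
    target_mean: float = 0.5
    target_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")


def _rank_assign(values: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """Assign sorted draws to values in rank order.

    Tied values receive the mean of the Gaussian order statistics their rank
    group spans, so equal inputs stay equal in the output and the assignment
    is deterministic given the draws.
    """
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    sorted_draws = np.sort(draws)
    out_sorted = sorted_draws.astype(float).copy()
    # group boundaries of ties in the sorted values
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [len(values)]))
    for a, b in zip(starts, stops):
        if b - a > 1:
            out_sorted[a:b] = sorted_draws[a:b].mean()
    out = np.empty_like(out_sorted)
    out[order] = out_sorted
    return out


def gaussian_resample(
    sc: ConnectivityMatrix, cfg: ResampleConfig | None = None
) -> ConnectivityMatrix:
    """Replace streamline counts by rank-ordered Gaussian weights.

    One standard-normal draw is made per upper-triangle edge; draws are
    sorted and matched to the sorted edge values, then mirrored to the lower
    triangle. A final affine map standardizes the off-diagonal entries to the
    target mean and standard deviation *exactly* (population sd, diagonal
    excluded), rather than relying on the sample moments of the draws.
    The diagonal stays 0 and is excluded from the moments.
    """
    cfg = cfg or ResampleConfig()
    if sc.kind not in (SC_COUNTS, SC_RESAMPLED):
        raise ValueError(f"expected a structural matrix, got kind {sc.kind!r}")
    edges = vectorize(sc.values)
    if np.ptp(edges) == 0:
        raise DegenerateInputError(
            "all off-diagonal entries are equal; sd rescaling is undefined"
        )
    rng = np.random.default_rng(cfg.seed)
    draws = rng.standard_normal(edges.size)
    assigned = _rank_assign(edges, draws)
    z = (assigned - assigned.mean()) / assigned.std()
    rescaled = cfg.target_mean + cfg.target_sd * z
    out = devectorize(rescaled, diagonal=0.0)
    return ConnectivityMatrix(out, SC_RESAMPLED, sc.atlas)
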