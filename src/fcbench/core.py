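"""Core containers and operations for parcellated connectome data.

The objects here are deliberately thin: a connectivity matrix is a symmetric
``p x p`` numpy array plus a *kind* tag (functional correlation, streamline
counts, or rank-resampled structural weights) and an optional atlas reference.
All edge-level statistics in this package operate on the canonical
upper-triangle edge vector (row-major, diagonal excluded), so that every
correlation between two connectivity objects counts each edge exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

YEO7_NETWORKS = ("VN", "SMN", "DAN", "VAN", "LSN", "FPN", "DMN")

FC = "FC"
SC_COUNTS = "SC_counts"
SC_RESAMPLED = "SC_resampled"
_KINDS = (FC, SC_COUNTS, SC_RESAMPLED)


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but statistically degenerate
    (e.g. a zero-variance region, or a constant edge vector)."""


@dataclass(frozen=True)
class Atlas:
    """A cortical parcellation with one Yeo-7 network label per parcel.

    Parameters
    ----------
    labels : tuple of str
        Unique parcel names, in matrix row/column order.
    networks : tuple of str
        One of the seven canonical functional-system codes
        (VN, SMN, DAN, VAN, LSN, FPN, DMN) per parcel.
    """

    labels: tuple
    networks: tuple
    name: str = "custom"

    def __post_init__(self):
        if len(self.labels) != len(self.networks):
            raise ValueError("labels and networks must have equal length")
        if len(self.labels) < 2:
            raise ValueError("an atlas needs at least 2 parcels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("parcel labels must be unique")
        bad = sorted(set(self.networks) - set(YEO7_NETWORKS))
        if bad:
            raise ValueError(f"unknown network codes: {bad}")

    @property
    def p(self) -> int:
        return len(self.labels)

    def network_of(self, parcel) -> str:
        """Network code of a parcel given by index or label."""
        if isinstance(parcel, str):
            parcel = self.labels.index(parcel)
        return self.networks[parcel]

    def parcels_in(self, network: str) -> np.ndarray:
        """Indices of all parcels assigned to ``network``."""
        return np.flatnonzero(np.asarray(self.networks) == network)


@dataclass
class ConnectivityMatrix:
    """Symmetric parcel-by-parcel connectivity matrix."""

    values: np.ndarray
    kind: str
    atlas: Atlas | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"expected a square matrix, got shape {v.shape}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if self.atlas is not None and self.atlas.p != v.shape[0]:
            raise ValueError(
                f"matrix is {v.shape[0]}x{v.shape[0]} but atlas has {self.atlas.p} parcels"
            )
        if self.kind == FC:
            off = v[~np.eye(v.shape[0], dtype=bool)]
            if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
                raise ValueError("FC off-diagonal entries must lie in [-1, 1]")
        elif self.kind == SC_COUNTS:
            if (v < 0).any():
                raise ValueError("streamline counts must be nonnegative")
            if not np.allclose(np.diag(v), 0):
                raise ValueError("streamline-count diagonal must be zero")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def edges(self) -> np.ndarray:
        return vectorize(self.values)


def vectorize(matrix) -> np.ndarray:
    """Extract the canonical edge vector of a symmetric matrix.

    Ordering is row-major over the strict upper triangle: (0,1), (0,2), ...,
    (0,p-1), (1,2), ... — length p(p-1)/2. The diagonal is dropped.
    """
    if isinstance(matrix, ConnectivityMatrix):
        matrix = matrix.values
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("vectorize expects a square matrix")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("vectorize expects a symmetric matrix")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def devectorize(edges, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix whose upper triangle is ``edges``.

    Inverse of :func:`vectorize` off the diagonal; the diagonal is filled
    with ``diagonal`` (1 for correlation matrices, 0 for count matrices).
    """
    e = np.asarray(edges, dtype=float).ravel()
    # p(p-1)/2 = len  =>  p = (1 + sqrt(1 + 8 len)) / 2
    p = int(round((1 + np.sqrt(1 + 8 * e.size)) / 2))
    if p * (p - 1) // 2 != e.size:
        raise ValueError(f"edge vector of length {e.size} is not triangular")
    m = np.full((p, p), float(diagonal))
    iu = np.triu_indices(p, k=1)
    m[iu] = e
    m[(iu[1], iu[0])] = e
    return m


def n_edges(p: int) -> int:
    return p * (p - 1) // 2


def compute_efc(time_series, atlas: Atlas | None = None) -> ConnectivityMatrix:
    """Empirical functional connectivity from regional BOLD time series.

    FC is the pairwise Pearson correlation between each pair of regional
    time series; the result is symmetric, has unit diagonal, and — being a
    sample correlation matrix — is positive semidefinite.

    Parameters
    ----------
    time_series : (T, p) array
        Rows are time points, columns are parcels. Requires T >= 3.
    """
    ts = np.asarray(time_series, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a T x p array")
    T, p = ts.shape
    if T < 3:
        raise ValueError(f"need at least 3 time points, got {T}")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateInputError(
            f"zero-variance time series for parcel(s) {dead.tolist()}; "
            "Pearson correlation is undefined"
        )
    fc = np.corrcoef(ts, rowvar=False)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return ConnectivityMatrix(fc, FC, atlas)


def group_average(fcs: Sequence) -> ConnectivityMatrix:
    """Elementwise mean of a collection of FC matrices (the avgFC template)."""
    fcs = list(fcs)
    if not fcs:
        raise ValueError("cannot average an empty list of matrices")
    arrs = []
    atlas = None
    for m in fcs:
        if isinstance(m, ConnectivityMatrix):
            atlas = atlas or m.atlas
            m = m.values
        arrs.append(np.asarray(m, dtype=float))
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"matrices have mismatched shapes: {sorted(shapes)}")
    mean = np.mean(arrs, axis=0)
    np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix(mean, FC, atlas)


@dataclass(frozen=True)
class FoldAssignment:
    """A k-fold partition of subject indices 0..n-1.

    Built by a seeded shuffle followed by contiguous blocks; the remainder
    subjects (n mod k) are distributed one per fold, so fold sizes differ by
    at most one.
    """

    k: int
    assignment: np.ndarray  # fold index in 0..k-1 per subject
    seed: int

    @property
    def n(self) -> int:
        return len(self.assignment)

    def validation_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def training_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)

    def folds(self) -> Iterable[tuple]:
        """Yield (fold, training_indices, validation_indices) triples."""
        for f in range(self.k):
            yield f, self.training_indices(f), self.validation_indices(f)


def make_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Deterministic near-equal-size k-fold split of ``n`` subjects."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, extra = divmod(n, k)
    assignment = np.empty(n, dtype=int)
    start = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        assignment[order[start : start + size]] = f
        start += size
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


@dataclass
class Subject:
    """One cohort member: identifier plus whatever modalities exist."""

    subject_id: str
    time_series: np.ndarray | None = None  # (T, p)
    efc: ConnectivityMatrix | None = None
    sc: ConnectivityMatrix | None = None
    cognition: float | None = None


@dataclass
class Cohort:
    """An ordered set of subjects sharing one atlas."""

    atlas: Atlas
    subjects: list = field(default_factory=list)

    def __post_init__(self):
        for s in self.subjects:
            self._check(s)

    def _check(self, s: Subject):
        p = self.atlas.p
        if s.time_series is not None and s.time_series.shape[1] != p:
            raise ValueError(f"{s.subject_id}: time series has wrong parcel count")
        for m in (s.efc, s.sc):
            if m is not None and m.p != p:
                raise ValueError(f"{s.subject_id}: matrix dimension != atlas size")

    def add(self, subject: Subject):
        self._check(subject)
        self.subjects.append(subject)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def __getitem__(self, i) -> Subject:
        return self.subjects[i]

    @property
    def subject_ids(self) -> list:
        return [s.subject_id for s in self.subjects]

    def efc_edges(self) -> np.ndarray:
        """Stack of all subjects' FC edge vectors, shape (n, p(p-1)/2)."""
        return np.vstack([s.efc.edges() for s in self.subjects])

    def sc_edges(self) -> np.ndarray:
        return np.vstack([s.sc.edges() for s in self.subjects])

    def cognition_scores(self) -> np.ndarray:
        return np.array([s.cognition for s in self.subjects], dtype=float)
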