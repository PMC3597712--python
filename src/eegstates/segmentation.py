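"""Windowed polynomial-map modelling of single-channel signals.

A signal is divided into (by default half-) overlapping windows.  Within each
window the dynamics are approximated by a polynomial map over a delay
embedding,

    x[t] = F(x[t-tau], x[t-2*tau], ..., x[t-m*tau])

where ``F`` is a full polynomial of total degree <= ``p`` in the ``m`` lagged
values and ``tau`` is the embedding delay in samples (``tau=1`` recovers the
plain one-step map).  At high sampling rates consecutive samples are nearly
collinear and carry little dynamical information; spacing the lags about a
quarter period of the rhythms of interest apart is the usual delay-embedding
remedy.  The fitted coefficient vector is the window's dynamical fingerprint;
windows are later compared by the Euclidean distance between those vectors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "EpochRecord",
    "SegmentGrid",
    "SegmentModelSet",
    "DistanceMatrix",
    "segment_series",
    "monomial_exponents",
    "design_matrix",
    "fit_poly_map",
    "fit_segments",
    "coef_distance",
    "distance_matrix",
    "n_poly_coefs",
]


@dataclass
class EpochRecord:
    """One epoch of one subject/condition/visit.

    ``data`` is a channels x samples array in signal units.  Epochs are
    expected to be mean-free per channel (mean removal is the only
    preprocessing the pipeline itself performs; see :meth:`demeaned`).
    """

    data: np.ndarray
    fs: float
    subject_id: str = ""
    group: str = ""
    condition: str = ""
    epoch_index: int = 0
    channel_names: list[str] = field(default_factory=list)
    age: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[None, :]
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def demeaned(self) -> "EpochRecord":
        """Return a copy with the per-channel epoch mean subtracted."""
        out = EpochRecord(
            data=self.data - self.data.mean(axis=1, keepdims=True),
            fs=self.fs,
            subject_id=self.subject_id,
            group=self.group,
            condition=self.condition,
            epoch_index=self.epoch_index,
            channel_names=list(self.channel_names),
            age=self.age,
        )
        return out


@dataclass(frozen=True)
class SegmentGrid:
    """Window layout over an epoch: 0-based, half-open ``[start, start+window_len)``."""

    window_len: int
    step: int
    starts: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def window(self, x: np.ndarray, i: int) -> np.ndarray:
        s = self.starts[i]
        return x[s : s + self.window_len]

    def duration_samples(self, n_windows: int) -> int:
        """Temporal support of a run of ``n_windows`` consecutive windows."""
        if n_windows < 1:
            raise ValueError("need at least one window")
        return (n_windows - 1) * self.step + self.window_len


@dataclass
class SegmentModelSet:
    """Per-window polynomial-map fits for one channel of one epoch."""

    embed_dim: int
    poly_order: int
    coefs: np.ndarray  # n_windows x n_coefs
    residual_var: np.ndarray  # n_windows
    degenerate: np.ndarray  # n_windows, bool
    grid: SegmentGrid
    tau: int = 1
    normalized: bool = False

    @property
    def n_windows(self) -> int:
        return self.coefs.shape[0]


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix of coefficient distances between windows."""

    d: np.ndarray
    degenerate_windows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n(self) -> int:
        return self.d.shape[0]


def segment_series(x: np.ndarray | int, window_len: int, overlap_fraction: float = 0.5) -> SegmentGrid:
    """Lay half-open windows over a series (or a series length).

    Trailing samples that do not fill a whole window are dropped.
    """
    n = int(x) if np.isscalar(x) else len(np.asarray(x))
    if window_len < 3:
        raise ValueError("window_len must be at least 3 samples")
    if n < window_len:
        raise ValueError(f"series of length {n} is shorter than one window ({window_len})")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    step = int(round(window_len * (1.0 - overlap_fraction)))
    step = max(step, 1)
    n_windows = (n - window_len) // step + 1
    starts = np.arange(n_windows) * step
    return SegmentGrid(window_len=window_len, step=step, starts=starts)


def n_poly_coefs(m: int, p: int) -> int:
    """Number of monomials of total degree <= p in m variables: C(m+p, p)."""
    return math.comb(m + p, p)


def monomial_exponents(m: int, p: int) -> list[tuple[int, ...]]:
    """Exponent tuples (one per lag) of all monomials of degree <= p.

    Ordered by total degree, then with lower lags first, e.g. for m=2, p=2:
    1, x[t], x[t-1], x[t]^2, x[t]*x[t-1], x[t-1]^2.
    """
    exps: list[tuple[int, ...]] = []
    for deg in range(p + 1):
        for combo in itertools.combinations_with_replacement(range(m), deg):
            e = [0] * m
            for j in combo:
                e[j] += 1
            exps.append(tuple(e))
    return exps


def design_matrix(
    segment: np.ndarray, m: int, p: int, tau: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Regression design for the delay-embedded polynomial map.

    One row per predictable time point.  Columns are all monomials of total
    degree <= p in the m lagged values (x[t-tau], ..., x[t-m*tau]), including
    the constant; the target is x[t].  With ``tau=1`` the rows run over
    t = m ... len-1, i.e. the plain one-step map predicting x[t+1] from
    (x[t], ..., x[t-m+1]).
    """
    segment = np.asarray(segment, dtype=float)
    n = len(segment)
    if tau < 1:
        raise ValueError("embedding delay tau must be >= 1")
    if n <= m * tau + 1:
        raise ValueError(
            f"segment of length {n} too short for embedding (m={m}, tau={tau})"
        )
    n_rows = n - m * tau
    lags = np.empty((n_rows, m))
    for j in range(m):
        lags[:, j] = segment[(m - 1 - j) * tau : n - (1 + j) * tau]
    exps = monomial_exponents(m, p)
    X = np.empty((n_rows, len(exps)))
    for c, e in enumerate(exps):
        col = np.ones(n_rows)
        for j, ej in enumerate(e):
            if ej:
                col = col * lags[:, j] ** ej
        X[:, c] = col
    y = segment[m * tau :]
    return X, y


def fit_poly_map(
    segment: np.ndarray,
    m: int = 2,
    p: int = 3,
    ridge: float = 1e-8,
    tau: int = 1,
    normalize: bool = False,
) -> tuple[np.ndarray, float, bool]:
    """Least-squares fit of the polynomial map to one window.

    Returns ``(coefs, residual_var, degenerate)``.  A constant (zero-variance)
    window cannot identify any dynamics; it is flagged degenerate and receives
    the constant-only solution.  With ``normalize=True`` the window is
    z-scored before fitting, which removes the window's offset and amplitude
    from the coefficient fingerprint so that only the dynamics are compared.
    A small ridge penalty on the normal equations stabilises near-collinear
    monomial columns.
    """
    segment = np.asarray(segment, dtype=float)
    n_coef = n_poly_coefs(m, p)
    if len(segment) < 2 * n_coef:
        raise ValueError(
            f"segment length {len(segment)} < 2 x coefficient count ({2 * n_coef}); "
            "fit would be under-determined"
        )
    if np.ptp(segment) == 0.0:
        coefs = np.zeros(n_coef)
        coefs[0] = segment[0] if not normalize else 0.0
        return coefs, 0.0, True
    if normalize:
        segment = (segment - segment.mean()) / segment.std()
    X, y = design_matrix(segment, m, p, tau)
    G = X.T @ X
    G[np.diag_indices_from(G)] += ridge
    try:
        coefs = np.linalg.solve(G, X.T @ y)
    except np.linalg.LinAlgError:
        coefs = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ coefs
    residual_var = float(np.mean(resid**2))
    return coefs, max(residual_var, 0.0), False


def fit_segments(
    x: np.ndarray,
    grid: SegmentGrid,
    m: int = 2,
    p: int = 3,
    ridge: float = 1e-8,
    tau: int = 1,
    normalize: bool = False,
) -> SegmentModelSet:
    """Fit the polynomial map to every window of ``grid`` over series ``x``."""
    x = np.asarray(x, dtype=float)
    n_coef = n_poly_coefs(m, p)
    coefs = np.empty((grid.n_windows, n_coef))
    rvar = np.empty(grid.n_windows)
    degen = np.zeros(grid.n_windows, dtype=bool)
    for i in range(grid.n_windows):
        coefs[i], rvar[i], degen[i] = fit_poly_map(
            grid.window(x, i), m, p, ridge, tau=tau, normalize=normalize
        )
    return SegmentModelSet(
        embed_dim=m,
        poly_order=p,
        coefs=coefs,
        residual_var=rvar,
        degenerate=degen,
        grid=grid,
        tau=tau,
        normalized=normalize,
    )


def coef_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two model-coefficient vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coefficient vectors differ in length: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def distance_matrix(models: SegmentModelSet) -> DistanceMatrix:
    """Pairwise coefficient distances between all windows of one epoch/channel.

    Degenerate (flat-window) fits enter the matrix like any other window but
    are recorded so downstream reports can flag them.
    """
    if models.n_windows < 2:
        raise ValueError("need at least 2 windows for a distance matrix")
    d = squareform(pdist(models.coefs, metric="euclidean"))
    return DistanceMatrix(d=d, degenerate_windows=np.flatnonzero(models.degenerate))
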