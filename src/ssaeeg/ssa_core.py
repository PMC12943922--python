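"""Singular spectrum analysis of short EEG epochs.

One epoch is embedded into an L x K Hankel trajectory matrix (rows are
lagged windows of the series), decomposed by SVD into rank-one elementary
matrices ("eigentriples"), and reconstructed group-by-group via diagonal
averaging.  With the defaults — a 383-sample embedded series and a 2-s
window of K = 256 samples at 128 Hz — the trajectory matrix is exactly
128 x 256 and yields d = 128 eigentriples, grouped into six intrinsic mode
functions (IMFs) that sum back to the embedded series.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
from scipy.linalg import hankel

from .errors import DegenerateInputError, DimensionError, NumericError
from .io_eeg import Epoch, EpochingConfig

__all__ = [
    "TrajectoryMatrix",
    "Eigentriple",
    "Grouping",
    "SSADecomposition",
    "build_trajectory_matrix",
    "svd_decompose",
    "contribution_profile",
    "diagonal_average",
    "reconstruct_group",
    "ssa_decompose_epoch",
    "DEFAULT_WINDOW_SAMPLES",
]

DEFAULT_WINDOW_SAMPLES = 256


@dataclasses.dataclass(frozen=True)
class TrajectoryMatrix:
    """L x K Hankel matrix of lagged windows; entry (p, q) = series[p + q]."""

    values: np.ndarray
    L: int
    K: int
    source_length: int


@dataclasses.dataclass(frozen=True)
class Eigentriple:
    """One (sigma, u, v) triple of the trajectory-matrix SVD.

    ``sigma * outer(u, v)`` is the rank-one elementary matrix at
    ``rank_index`` in the non-increasing singular-value ordering.
    """

    sigma: float
    u: np.ndarray
    v: np.ndarray
    rank_index: int


class Grouping:
    """Ordered, disjoint eigentriple index ranges defining the IMFs.

    Ranges are inclusive; the default six-group split is
    0-1, 2-3, 4-6, 7-9, 10-19, 20-127.  When the decomposition has d != 128
    triples, ranges are clipped to d and the last group extends to d - 1, so
    the six-IMF contract holds for any window length.  Ranges that fall
    entirely beyond d produce zero IMFs.
    """

    DEFAULT_RANGES: tuple[tuple[int, int], ...] = (
        (0, 1), (2, 3), (4, 6), (7, 9), (10, 19), (20, 127),
    )

    def __init__(self, ranges: Sequence[tuple[int, int]] | None = None):
        ranges = tuple(tuple(r) for r in (ranges or self.DEFAULT_RANGES))
        for a, b in ranges:
            if a < 0 or b < a:
                raise ValueError(f"invalid eigentriple range {a}-{b}")
        for (_, b0), (a1, _) in zip(ranges, ranges[1:]):
            if a1 <= b0:
                raise ValueError("eigentriple ranges must be disjoint and ordered")
        self.ranges = ranges

    @classmethod
    def parse(cls, text: str) -> "Grouping":
        """Parse a comma-separated list like ``"0-1,2-3,4-6,7-9,10-19,20-127"``."""
        ranges = []
        for part in text.split(","):
            part = part.strip()
            if "-" in part:
                a, b = part.split("-")
                ranges.append((int(a), int(b)))
            else:
                ranges.append((int(part), int(part)))
        return cls(ranges)

    @property
    def n_groups(self) -> int:
        return len(self.ranges)

    def resolve(self, d: int) -> list[np.ndarray]:
        """Concrete index sets for a decomposition with d eigentriples."""
        out = []
        for g, (a, b) in enumerate(self.ranges):
            if g == len(self.ranges) - 1:
                b = max(b, d - 1)  # last group soaks up any remaining triples
            b = min(b, d - 1)
            out.append(np.arange(a, b + 1) if a <= b else np.empty(0, dtype=int))
        return out

    def __repr__(self) -> str:
        return "Grouping(%s)" % ",".join(f"{a}-{b}" for a, b in self.ranges)


@dataclasses.dataclass
class SSADecomposition:
    """Full SSA result for one epoch.

    ``imfs`` has one row per group, each of length ``source_length``; the
    rows sum to the embedded series.  ``degenerate`` marks all-zero epochs,
    whose contribution profile is undefined (NaN) rather than an error.
    """

    sigmas: np.ndarray
    U: np.ndarray
    Vt: np.ndarray
    relative_contrib: np.ndarray
    cumulative_contrib: np.ndarray
    grouping: Grouping
    imfs: np.ndarray
    source_length: int
    degenerate: bool = False

    @property
    def d(self) -> int:
        return int(self.sigmas.size)

    @property
    def eigentriples(self) -> list[Eigentriple]:
        return [
            Eigentriple(sigma=float(self.sigmas[i]), u=self.U[:, i], v=self.Vt[i], rank_index=i)
            for i in range(self.d)
        ]


def build_trajectory_matrix(series: np.ndarray, K: int) -> TrajectoryMatrix:
    """Embed a series of length N into the L x K Hankel matrix, L = N - K + 1."""
    series = np.asarray(series, dtype=float)
    N = series.size
    if K < 2:
        raise DimensionError(f"window length K={K} must be at least 2")
    if K > N:
        raise DimensionError(f"window length K={K} exceeds series length {N}")
    L = N - K + 1
    values = hankel(series[:L], series[L - 1:])
    return TrajectoryMatrix(values=values, L=L, K=K, source_length=N)


def _svd_arrays(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not np.all(np.isfinite(values)):
        raise NumericError("trajectory matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    # Deterministic sign convention: largest-|entry| of each u non-negative.
    for i in range(s.size):
        j = np.argmax(np.abs(U[:, i]))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            Vt[i] = -Vt[i]
    return U, s, Vt


def svd_decompose(X: TrajectoryMatrix | np.ndarray) -> list[Eigentriple]:
    """SVD of the trajectory matrix into d = min(L, K) eigentriples.

    Singular values are non-increasing and the sum of the rank-one
    elementary matrices reconstructs the input.
    """
    values = X.values if isinstance(X, TrajectoryMatrix) else np.asarray(X, dtype=float)
    U, s, Vt = _svd_arrays(values)
    return [
        Eigentriple(sigma=float(s[i]), u=U[:, i], v=Vt[i], rank_index=i)
        for i in range(s.size)
    ]


def contribution_profile(sigmas) -> tuple[np.ndarray, np.ndarray]:
    """Relative (sigma_i^2 / sum sigma_k^2) and cumulative contribution series.

    Accepts a singular-value array, an eigentriple list, or an
    :class:`SSADecomposition`.
    """
    if isinstance(sigmas, SSADecomposition):
        sigmas = sigmas.sigmas
    elif isinstance(sigmas, (list, tuple)) and sigmas and isinstance(sigmas[0], Eigentriple):
        sigmas = np.array([et.sigma for et in sigmas])
    sigmas = np.asarray(sigmas, dtype=float)
    total = np.sum(sigmas**2)
    if total == 0:
        raise DegenerateInputError("all singular values are zero (zero signal)")
    relative = sigmas**2 / total
    cumulative = np.cumsum(relative)
    return relative, cumulative


def diagonal_average(M: np.ndarray) -> np.ndarray:
    """Average an L x K matrix along anti-diagonals into a length L+K-1 series.

    ``out[s] = mean{ M[p, q] : p + q = s }``; applied to a Hankel matrix of
    a series F this returns F exactly, making the map a left inverse of
    :func:`build_trajectory_matrix`.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise NumericError("matrix contains non-finite entries")
    L, K = M.shape
    idx = (np.arange(L)[:, None] + np.arange(K)[None, :]).ravel()
    sums = np.bincount(idx, weights=M.ravel(), minlength=L + K - 1)
    counts = np.bincount(idx, minlength=L + K - 1)
    return sums / counts


def reconstruct_group(eigentriples: Sequence[Eigentriple], index_set: Iterable[int]) -> np.ndarray:
    """Diagonal-average the summed elementary matrices of one index set.

    The map is linear in the group: reconstructing a union of disjoint sets
    equals the sum of the individual reconstructions.  An empty set yields a
    zero series.
    """
    index_set = np.asarray(sorted(set(int(i) for i in index_set)), dtype=int)
    d = len(eigentriples)
    if index_set.size and (index_set.min() < 0 or index_set.max() >= d):
        raise IndexError(f"eigentriple index out of range 0..{d - 1}")
    L = eigentriples[0].u.size
    K = eigentriples[0].v.size
    if index_set.size == 0:
        return np.zeros(L + K - 1)
    M = np.zeros((L, K))
    for i in index_set:
        et = eigentriples[i]
        M += et.sigma * np.outer(et.u, et.v)
    return diagonal_average(M)


def ssa_decompose_epoch(
    epoch: Epoch | np.ndarray,
    cfg: EpochingConfig | None = None,
    grouping: Grouping | None = None,
    K: int = DEFAULT_WINDOW_SAMPLES,
) -> SSADecomposition:
    """Full SSA of one epoch: embed, SVD, group, reconstruct the IMFs.

    Only the first ``cfg.embed_length`` samples of the epoch are embedded
    (383 by default, giving the 128 x 256 trajectory matrix for 3-s epochs
    at 128 Hz).  An all-zero epoch is not an error: it returns zero IMFs
    with a NaN contribution profile and ``degenerate=True``.
    """
    cfg = cfg or EpochingConfig()
    grouping = grouping or Grouping()
    series = epoch.values if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    if series.size < cfg.embed_length:
        raise DimensionError(
            f"epoch of {series.size} samples shorter than embed_length={cfg.embed_length}"
        )
    embedded = np.asarray(series[: cfg.embed_length], dtype=float)
    X = build_trajectory_matrix(embedded, min(K, embedded.size))
    d = min(X.L, X.K)
    N = X.source_length

    if not np.any(embedded):
        nan = np.full(d, np.nan)
        return SSADecomposition(
            sigmas=np.zeros(d),
            U=np.zeros((X.L, d)),
            Vt=np.zeros((d, X.K)),
            relative_contrib=nan,
            cumulative_contrib=nan.copy(),
            grouping=grouping,
            imfs=np.zeros((grouping.n_groups, N)),
            source_length=N,
            degenerate=True,
        )

    U, s, Vt = _svd_arrays(X.values)
    relative, cumulative = contribution_profile(s)
    imfs = np.empty((grouping.n_groups, N))
    for g, idx in enumerate(grouping.resolve(d)):
        if idx.size == 0:
            imfs[g] = 0.0
            continue
        # sum of rank-one terms for the group, then Hankelization
        M = (U[:, idx] * s[idx]) @ Vt[idx]
        imfs[g] = diagonal_average(M)
    return SSADecomposition(
        sigmas=s,
        U=U,
        Vt=Vt,
        relative_contrib=relative,
        cumulative_contrib=cumulative,
        grouping=grouping,
        imfs=imfs,
        source_length=N,
    )
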