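"""Recurrence matrices, line-length histograms and the recurrence network.

The recurrence matrix of a trajectory is R_ij = Theta(eps - ||x_i - x_j||)
with the Euclidean norm; a distance exactly equal to eps counts as
recurrent.  The threshold is calibrated per trajectory to a target
recurrence rate (default 10%), which makes the line-structure measures
comparable across windows of differing amplitude.  Diagonal measures
exclude the line of identity (LOI, the main diagonal); vertical runs keep
the main-diagonal cells.  No Theiler window beyond the LOI exclusion is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .embedding import Trajectory


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Binary symmetric recurrence structure plus its threshold."""

    R: np.ndarray
    epsilon: float
    norm: str = "euclidean"

    def __post_init__(self) -> None:
        R = np.asarray(self.R)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("R must be a square matrix")
        R = (R != 0)
        if not np.array_equal(R, R.T):
            raise ValueError("R must be symmetric")
        if not np.all(np.diagonal(R)):
            raise ValueError("R must have a unit main diagonal (LOI)")
        object.__setattr__(self, "R", R)

    @property
    def n(self) -> int:
        return self.R.shape[0]


@dataclass(frozen=True)
class LineHistogram:
    """Counts of maximal runs of recurrences by length.

    ``counts[l]`` is the number of maximal runs of exactly ``l``
    consecutive recurrence points along the given orientation.  Off-LOI
    diagonal lines appear once per triangle (the matrix is symmetric).
    """

    orientation: str              # "diagonal" | "vertical"
    counts: dict[int, int]
    loi_excluded: bool = False

    def total_points(self, min_len: int = 1) -> int:
        """Sum of l * P(l) over runs of length >= min_len."""
        return sum(l * c for l, c in self.counts.items() if l >= min_len)

    def total_lines(self, min_len: int = 1) -> int:
        return sum(c for l, c in self.counts.items() if l >= min_len)

    def max_length(self) -> int:
        return max(self.counts, default=0)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Recurrence-network adjacency A = R - I (zero diagonal, symmetric)."""

    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        A = (A != 0)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if np.any(np.diagonal(A)):
            raise ValueError("A must have a zero diagonal")
        if not np.array_equal(A, A.T):
            raise ValueError("A must be symmetric")
        object.__setattr__(self, "A", A)


def recurrence_matrix(traj: Trajectory, epsilon: float) -> RecurrenceMatrix:
    """Threshold the Euclidean distance matrix at ``epsilon`` (closed)."""
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if len(traj) < 1:
        raise ValueError("trajectory is empty")
    d = cdist(traj.points, traj.points, metric="euclidean")
    return RecurrenceMatrix(d <= epsilon, epsilon=float(epsilon))


def calibrate_epsilon(traj: Trajectory, target_rr: float = 0.10) -> float:
    """Threshold achieving a target off-diagonal recurrence rate.

    Returns the ``target_rr``-quantile (inverted-CDF, so the realized
    rate is within one rank unit of the target) of the off-diagonal
    pairwise Euclidean distance distribution.
    """
    if not 0 < target_rr <= 1:
        raise ValueError(f"target_rr must be in (0, 1], got {target_rr}")
    if len(traj) < 2:
        raise ValueError("epsilon calibration needs at least 2 points")
    d = np.sort(pdist(traj.points, metric="euclidean"))
    if d[-1] == 0:
        raise ValueError("all trajectory points are identical; "
                         "epsilon is undefined")
    k = int(np.round(target_rr * d.size))
    k = min(max(k, 1), d.size)
    return float(d[k - 1])


def _run_lengths(flat: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    if flat.size == 0:
        return np.empty(0, dtype=int)
    padded = np.concatenate(([False], flat, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return ends - starts


def _counts_dict(lengths: np.ndarray) -> dict[int, int]:
    vals, counts = np.unique(lengths, return_counts=True)
    return {int(l): int(c) for l, c in zip(vals, counts)}


def diagonal_histogram(R: RecurrenceMatrix,
                       exclude_loi: bool = True) -> LineHistogram:
    """Histogram of maximal diagonal runs over the full symmetric matrix.

    Each off-LOI line is counted in both triangles; lines touching the
    matrix border count at their visible length.
    """
    M = R.R
    n = R.n
    pieces = []
    for k in range(-(n - 1), n):
        if k == 0 and exclude_loi:
            continue
        diag = np.diagonal(M, offset=k)
        pieces.append(diag)
        pieces.append(np.zeros(1, dtype=bool))  # separator between diagonals
    flat = np.concatenate(pieces) if pieces else np.empty(0, dtype=bool)
    return LineHistogram("diagonal", _counts_dict(_run_lengths(flat)),
                         loi_excluded=exclude_loi)


def vertical_histogram(R: RecurrenceMatrix) -> LineHistogram:
    """Histogram of maximal vertical runs in every column (LOI cells kept)."""
    M = R.R
    n = R.n
    sep = np.zeros((1, n), dtype=bool)
    flat = np.vstack([M, sep]).flatten(order="F")
    return LineHistogram("vertical", _counts_dict(_run_lengths(flat)))


def adjacency(R: RecurrenceMatrix) -> AdjacencyMatrix:
    """Recurrence-network adjacency: A = R - I."""
    A = R.R.copy()
    np.fill_diagonal(A, False)
    return AdjacencyMatrix(A)


def save_rp_png(R: RecurrenceMatrix, path, title: str | None = None) -> None:
    """Export a recurrence-plot image for visual inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(R.R, cmap="binary", origin="lower", interpolation="nearest")
    ax.set_xlabel("time index j")
    ax.set_ylabel("time index i")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
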