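"""The twelve recurrence-quantification complexity measures.

From a thresholded recurrence plot and its underlying trajectory this
module computes

* point density: recurrence rate ``RR`` (LOI included, per definition);
* diagonal-line measures (LOI excluded): determinism ``DET``, mean line
  length ``L``, maximum line length ``Lmax``, line-length entropy
  ``ENTR``;
* vertical-line measures: laminarity ``LAM``, trapping time ``TT``,
  maximum vertical length ``Vmax``;
* recurrence-time measures: mean first-type time ``T1`` (sojourn points
  included), mean second-type time ``T2`` (entry events only), and the
  recurrence period density entropy ``RPDE``;
* recurrence-network transitivity ``Trans``.

Zero-denominator cases (empty histograms, empty recurrence-time sets)
return 0 and record a quality flag instead of raising, so no signal block
silently drops out of a feature table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import EmbeddingParams, Trajectory, embed, estimate_embedding
from .recurrence import (AdjacencyMatrix, LineHistogram, RecurrenceMatrix,
                         adjacency, calibrate_epsilon, diagonal_histogram,
                         recurrence_matrix, vertical_histogram)
from .signals import TimeSeries

FEATURE_NAMES = ("rr", "det", "l_mean", "l_max", "entr", "lam", "tt",
                 "v_max", "t1", "t2", "rpde", "trans")

#: Display names used in reports, matching the field order above.
FEATURE_DISPLAY = ("RR", "DET", "L", "Lmax", "ENTR", "LAM", "TT",
                   "Vmax", "T1", "T2", "RPDE", "Trans")


@dataclass(frozen=True)
class RQAConfig:
    """Measure-level settings.

    ``l_min``/``v_min`` are the minimal diagonal/vertical line lengths
    entering DET/L/ENTR and LAM/TT (default 2 for both).  The
    recurrence-time measures (T1, T2, RPDE) use their own close-return
    neighborhood: by default (``rpde_radius_mode="calibrated"``) its
    radius is calibrated to a small return rate ``rpde_target_rr`` —
    recurrence-time statistics want sparse, well-separated return events,
    and a tight neighborhood sharpens the periodic-vs-aperiodic contrast
    that RPDE measures.  ``"matrix_eps"`` reuses the recurrence plot's
    epsilon instead, and ``"fixed"`` takes ``rpde_radius`` literally.
    """

    l_min: int = 2
    v_min: int = 2
    rpde_radius_mode: str = "calibrated"   # calibrated | matrix_eps | fixed
    rpde_target_rr: float = 0.02
    rpde_radius: float | None = None
    t_max_cap: int | None = None

    def __post_init__(self) -> None:
        if self.l_min < 1 or self.v_min < 1:
            raise ValueError("l_min and v_min must be >= 1")
        if self.rpde_radius_mode not in ("calibrated", "matrix_eps", "fixed"):
            raise ValueError(
                f"unknown rpde_radius_mode {self.rpde_radius_mode!r}")
        if self.rpde_radius_mode == "fixed" and (
                self.rpde_radius is None or not self.rpde_radius > 0):
            raise ValueError("fixed rpde_radius_mode needs a positive radius")
        if not 0 < self.rpde_target_rr <= 1:
            raise ValueError("rpde_target_rr must be in (0, 1]")


@dataclass(frozen=True)
class EmbeddingOptions:
    """Per-block embedding-estimation settings (see the embedding module)."""

    max_lag: int | None = None     # None: min(N // 4, 64)
    n_bins: int | None = None      # None: ceil(sqrt(N)) capped at 32
    m_max: int = 10
    saturation_tol: float = 0.05
    mode: str = "per_block"        # "per_block" | "global"
    tau: int | None = None         # fixed (tau, m) used when mode == "global"
    m: int | None = None


@dataclass(frozen=True)
class RecurrenceOptions:
    """Threshold-selection settings for the recurrence matrix."""

    target_rr: float = 0.10
    epsilon_mode: str = "fixed_rr"  # "fixed_rr" | "fixed_eps"
    epsilon_frac: float = 0.10      # fraction of max extent for fixed_eps
    exclude_loi: bool = True


@dataclass(frozen=True)
class FeatureConfig:
    """Bundle of everything ``extract_features`` needs."""

    embedding: EmbeddingOptions = field(default_factory=EmbeddingOptions)
    recurrence: RecurrenceOptions = field(default_factory=RecurrenceOptions)
    rqa: RQAConfig = field(default_factory=RQAConfig)


@dataclass(frozen=True)
class RQAFeatureVector:
    """The twelve measures for one signal block, plus provenance."""

    rr: float
    det: float
    l_mean: float
    l_max: float
    entr: float
    lam: float
    tt: float
    v_max: float
    t1: float
    t2: float
    rpde: float
    trans: float
    segment_id: int | None = None
    block_idx: int | None = None
    label: str | None = None
    flags: tuple[str, ...] = ()

    def values(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)
             if f.name != "flags"}
        d["flags"] = ";".join(self.flags)
        return d


@dataclass(frozen=True)
class RecurrenceTimeSets:
    """Recurrence-time multisets aggregated over all reference points.

    ``t1_times`` are gaps between consecutive neighborhood members
    (sojourn points included); ``t2_times`` are gaps between consecutive
    entries into the neighborhood from outside.
    """

    t1_times: np.ndarray
    t2_times: np.ndarray


# ---------------------------------------------------------------------------
# point density and line measures


def rr(R: RecurrenceMatrix) -> float:
    """Recurrence rate: density of recurrence points, LOI included."""
    n = R.n
    return float(R.R.sum()) / (n * n)


def det(hist: LineHistogram, l_min: int = 2) -> float:
    """Determinism: fraction of recurrence points on diagonals >= l_min."""
    denom = hist.total_points(1)
    if denom == 0:
        return 0.0
    return hist.total_points(l_min) / denom


def l_mean(hist: LineHistogram, l_min: int = 2) -> float:
    """Mean diagonal line length over lines >= l_min (mean prediction time)."""
    lines = hist.total_lines(l_min)
    if lines == 0:
        return 0.0
    return hist.total_points(l_min) / lines


def l_max(hist: LineHistogram) -> int:
    """Length of the longest diagonal line (0 if none)."""
    return hist.max_length()


def entr(hist: LineHistogram, l_min: int = 2) -> float:
    """Shannon entropy (nats) of the diagonal line-length distribution."""
    total = hist.total_lines(l_min)
    if total == 0:
        return 0.0
    h = 0.0
    for length, count in hist.counts.items():
        if length >= l_min and count > 0:
            p = count / total
            h -= p * math.log(p)
    return h


def lam(hist: LineHistogram, v_min: int = 2) -> float:
    """Laminarity: fraction of recurrence points on verticals >= v_min."""
    denom = hist.total_points(1)
    if denom == 0:
        return 0.0
    return hist.total_points(v_min) / denom


def tt(hist: LineHistogram, v_min: int = 2) -> float:
    """Trapping time: mean vertical line length over lines >= v_min."""
    lines = hist.total_lines(v_min)
    if lines == 0:
        return 0.0
    return hist.total_points(v_min) / lines


def v_max(hist: LineHistogram) -> int:
    """Length of the longest vertical line (0 if none)."""
    return hist.max_length()


# ---------------------------------------------------------------------------
# recurrence-time measures


def recurrence_times_from_matrix(inside: np.ndarray) -> RecurrenceTimeSets:
    """Recurrence times from a boolean membership matrix.

    Row i of ``inside`` flags which trajectory points lie inside the
    neighborhood of reference point i.  First-type times are index gaps
    between consecutive members of each row (sojourn points produce gaps
    of 1); second-type times are gaps between consecutive entry events
    (a member whose predecessor index is outside; the first point of the
    series counts as an entry when inside).
    """
    inside = np.asarray(inside, dtype=bool)
    rows, cols = np.nonzero(inside)           # row-major order
    gaps = np.diff(cols)
    same_row = np.diff(rows) == 0
    t1_times = gaps[same_row]
    entries = inside.copy()
    entries[:, 1:] &= ~inside[:, :-1]
    rows2, cols2 = np.nonzero(entries)
    gaps2 = np.diff(cols2)
    t2_times = gaps2[np.diff(rows2) == 0]
    return RecurrenceTimeSets(t1_times.astype(int), t2_times.astype(int))


def recurrence_times(traj: Trajectory, r: float) -> RecurrenceTimeSets:
    """Recurrence times of every reference point at neighborhood radius r."""
    if not r > 0:
        raise ValueError("radius must be positive")
    if len(traj) < 2:
        raise ValueError("recurrence times need at least 2 points")
    d = cdist(traj.points, traj.points, metric="euclidean")
    return recurrence_times_from_matrix(d <= r)


def t1(times: RecurrenceTimeSets) -> float:
    """Mean first-type recurrence time (0 for an empty set)."""
    return float(times.t1_times.mean()) if times.t1_times.size else 0.0


def t2(times: RecurrenceTimeSets) -> float:
    """Mean second-type recurrence time (0 for an empty set)."""
    return float(times.t2_times.mean()) if times.t2_times.size else 0.0


def rpde(t2_times: np.ndarray, t_max_cap: int | None = None) -> float:
    """Recurrence period density entropy, normalized to [0, 1].

    The Shannon entropy of the second-type recurrence-time distribution
    divided by ln(T_max): near 0 for periodic signals (one dominant
    period), near 1 for aperiodic ones (flat period density).
    """
    times = np.asarray(t2_times, dtype=int)
    if t_max_cap is not None:
        times = times[times <= t_max_cap]
    if times.size == 0:
        warnings.warn("empty recurrence-time set: RPDE undefined, returning 0")
        return 0.0
    t_max = int(t_max_cap) if t_max_cap is not None else int(times.max())
    if t_max <= 1:
        return 0.0
    counts = np.bincount(times, minlength=t_max + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(t_max))


# ---------------------------------------------------------------------------
# recurrence-network measure


def transitivity(A: AdjacencyMatrix) -> float:
    """Network transitivity: closed triples over connected triples.

    trace(A^3) / sum_i k_i (k_i - 1); 0 when the network has no paths of
    length two.
    """
    M = A.A.astype(float)
    deg = M.sum(axis=1)
    denom = float((deg * (deg - 1)).sum())
    if denom == 0:
        return 0.0
    closed = float(((M @ M) * M).sum())
    return closed / denom


# ---------------------------------------------------------------------------
# full feature extraction for one block


def extract_features(block: TimeSeries, cfg: FeatureConfig | None = None,
                     params: EmbeddingParams | None = None,
                     segment_id: int | None = None,
                     block_idx: int | None = None) -> RQAFeatureVector:
    """Embed a block, calibrate the threshold, and compute all 12 measures.

    ``params`` overrides per-block embedding estimation (used by the
    pipeline's global-embedding mode).  A constant block is handled as a
    degenerate but defined case: every point coincides, so the plot is
    all-recurrent (RR = 1, Trans = 1, RPDE = 0) and the vector carries a
    ``degenerate`` flag.
    """
    if cfg is None:
        cfg = FeatureConfig()
    flags: list[str] = []
    emb = cfg.embedding
    if params is None:
        if emb.mode == "global" and emb.tau is not None and emb.m is not None:
            params = EmbeddingParams(tau=emb.tau, m=emb.m)
        else:
            params = estimate_embedding(
                block, max_lag=emb.max_lag, n_bins=emb.n_bins,
                m_max=emb.m_max, saturation_tol=emb.saturation_tol)
    traj = embed(block, params)

    rec = cfg.recurrence
    extent = float(np.ptp(traj.points, axis=0).max()) if len(traj) else 0.0
    if extent == 0.0:
        flags.append("degenerate")
        epsilon = 1.0
    elif rec.epsilon_mode == "fixed_eps":
        epsilon = rec.epsilon_frac * float(
            np.linalg.norm(np.ptp(traj.points, axis=0)))
    else:
        epsilon = calibrate_epsilon(traj, target_rr=rec.target_rr)
        if epsilon == 0.0:
            # duplicated points can force a zero quantile; fall back to the
            # smallest positive pairwise distance
            flags.append("zero_quantile_epsilon")
            from scipy.spatial.distance import pdist
            d = pdist(traj.points)
            epsilon = float(d[d > 0].min())
    R = recurrence_matrix(traj, epsilon)

    dhist = diagonal_histogram(R, exclude_loi=rec.exclude_loi)
    vhist = vertical_histogram(R)
    q = cfg.rqa

    if q.rpde_radius_mode == "fixed":
        radius = q.rpde_radius
    elif q.rpde_radius_mode == "calibrated" and extent > 0:
        radius = calibrate_epsilon(traj, target_rr=q.rpde_target_rr)
        if radius == 0.0:
            radius = epsilon
    else:
        radius = epsilon
    if radius == epsilon:
        times = recurrence_times_from_matrix(R.R)
    else:
        times = recurrence_times(traj, radius)
    if times.t2_times.size == 0:
        flags.append("empty_t2")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rpde_val = rpde(times.t2_times, t_max_cap=q.t_max_cap)

    return RQAFeatureVector(
        rr=rr(R),
        det=det(dhist, q.l_min),
        l_mean=l_mean(dhist, q.l_min),
        l_max=float(l_max(dhist)),
        entr=entr(dhist, q.l_min),
        lam=lam(vhist, q.v_min),
        tt=tt(vhist, q.v_min),
        v_max=float(v_max(vhist)),
        t1=t1(times),
        t2=t2(times),
        rpde=rpde_val,
        trans=transitivity(adjacency(R)),
        segment_id=segment_id,
        block_idx=block_idx,
        label=block.label,
        flags=tuple(flags),
    )
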