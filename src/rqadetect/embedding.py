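"""Phase-space reconstruction by time-delay embedding.

A scalar series (u_1, ..., u_N) is embedded as the trajectory
x_t = (u_t, u_{t+tau}, ..., u_{t+(m-1)tau}).  The delay ``tau`` is chosen
as the first local minimum of the average mutual information (AMI) between
the series and its lagged copy, and the dimension ``m`` by Cao's E1
saturation criterion (with E2 available to screen stochastic signals, for
which E2(m) stays near 1 at every m).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .signals import TimeSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay ``tau`` (samples) and embedding dimension ``m``."""

    tau: int
    m: int

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")

    def n_points(self, series_len: int) -> int:
        """Number of trajectory points an N-sample series yields."""
        return series_len - (self.m - 1) * self.tau


@dataclass(frozen=True)
class Trajectory:
    """Delay-embedded point cloud: ``points`` is (n_points, m)."""

    points: np.ndarray
    params: EmbeddingParams
    source_len: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2:
            raise ValueError("trajectory points must be a 2-D array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trajectory coordinates must be finite")
        expected = self.params.n_points(self.source_len)
        if pts.shape != (expected, self.params.m):
            raise ValueError(
                f"trajectory shape {pts.shape} inconsistent with "
                f"N={self.source_len}, tau={self.params.tau}, m={self.params.m}"
            )
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class AMICurve:
    """Average mutual information (nats) at lags 0..max_lag."""

    lags: np.ndarray
    mi: np.ndarray
    degenerate: bool = False  # set when the series had no variability

    def __post_init__(self) -> None:
        if len(self.lags) != len(self.mi):
            raise ValueError("lags and mi must be aligned")


def _hist_mi(x: np.ndarray, y: np.ndarray, edges: np.ndarray) -> float:
    """Plug-in MI (nats) of two samples on a shared equal-width grid."""
    joint, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    n = joint.sum()
    if n == 0:
        return 0.0
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def default_n_bins(n: int) -> int:
    """Equal-width bin count: ceil(sqrt(N)) capped at 32."""
    return int(min(32, np.ceil(np.sqrt(n))))


def ami_curve(series: TimeSeries, max_lag: int,
              n_bins: int | None = None) -> AMICurve:
    """Histogram-based average mutual information at lags 0..max_lag.

    Bin edges are equal-width over the series range and shared across all
    lags, so the curve is comparable lag to lag.  A constant series has no
    variability: the curve is all zero and flagged degenerate.
    """
    x = series.samples
    n = x.size
    if not 0 < max_lag < n:
        raise ValueError(f"max_lag must be in [1, {n - 1}], got {max_lag}")
    if n_bins is None:
        n_bins = default_n_bins(n)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lags = np.arange(max_lag + 1)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        warnings.warn("constant series: mutual information is degenerate")
        return AMICurve(lags, np.zeros(max_lag + 1), degenerate=True)
    edges = np.linspace(lo, hi, n_bins + 1)
    mi = np.array([_hist_mi(x[: n - k] if k else x, x[k:], edges)
                   for k in lags])
    return AMICurve(lags, mi)


def select_delay(curve: AMICurve, smooth_window: int = 3) -> int:
    """Delay = lag of the first local minimum of the AMI curve.

    A plateau followed by a rise counts as a minimum (taken at the lag
    where the curve turns up).  Long curves (>= 16 lags) are first
    smoothed by a centered moving average of ``smooth_window`` points:
    the histogram estimator's sampling jitter otherwise creates shallow
    spurious dips well before the true minimum.  If no local minimum
    exists, falls back to the first lag where AMI drops below AMI(0)/e,
    then to the largest lag.
    """
    mi = curve.mi
    if len(mi) < 3:
        raise ValueError("AMI curve needs at least 3 lags to select a delay")
    if len(mi) >= 16 and smooth_window > 1:
        sm = np.convolve(mi, np.ones(smooth_window) / smooth_window,
                         mode="valid")
        offset = (smooth_window - 1) // 2  # sm[i] is centered on lag i+offset
        for k in range(1, len(sm) - 1):
            if sm[k] <= sm[k - 1] and sm[k] < sm[k + 1]:
                return int(curve.lags[k + offset])
    for k in range(1, len(mi) - 1):
        if mi[k] <= mi[k - 1] and mi[k] < mi[k + 1]:
            return int(curve.lags[k])
    threshold = mi[0] / np.e
    below = np.nonzero(mi[1:] < threshold)[0]
    if below.size:
        return int(curve.lags[below[0] + 1])
    logger.warning("AMI curve has no local minimum and never falls below "
                   "AMI(0)/e; using max lag")
    return int(curve.lags[-1])


def embed(series: TimeSeries, params: EmbeddingParams) -> Trajectory:
    """Build the delay-embedded trajectory x_t = (u_t, ..., u_{t+(m-1)tau})."""
    x = series.samples
    n = x.size
    n_pts = params.n_points(n)
    if n_pts < 1:
        raise ValueError(
            f"series of length {n} too short to embed at m={params.m}, "
            f"tau={params.tau}: needs >= {(params.m - 1) * params.tau + 1} "
            f"samples ({(params.m - 1) * params.tau + 1 - n} missing)")
    cols = [x[i * params.tau: i * params.tau + n_pts]
            for i in range(params.m)]
    return Trajectory(np.column_stack(cols), params, n)


def _nn_stats(series: np.ndarray, tau: int, m: int) -> tuple[float, float]:
    """Cao statistics at dimension m.

    Returns (E(m), E*(m)): the mean over reference points of the
    (m+1)-dim/(m)-dim Chebyshev distance ratio to the m-dim nearest
    neighbor, and the mean extra-coordinate distance to that neighbor.
    Reference points whose nearest-neighbor distance is zero are skipped.
    """
    n = series.size
    n_pts = n - m * tau  # points that also exist in dimension m+1
    if n_pts < 2:
        raise ValueError(
            f"series too short for Cao statistic at m={m}, tau={tau}")
    cols = [series[i * tau: i * tau + n_pts] for i in range(m)]
    y = np.column_stack(cols)
    extra = series[m * tau: m * tau + n_pts]  # the (m+1)-th coordinate
    d = cdist(y, y, metric="chebyshev")
    np.fill_diagonal(d, np.inf)
    # ties broken by smallest index: argmin returns the first minimum
    nn = d.argmin(axis=1)
    dmin = d[np.arange(n_pts), nn]
    ok = dmin > 0
    if not np.all(ok):
        logger.info("Cao m=%d: skipped %d reference points with duplicate "
                    "nearest neighbors", m, int((~ok).sum()))
    if not np.any(ok):
        raise ValueError("all nearest-neighbor distances are zero "
                         "(degenerate series)")
    extra_gap = np.abs(extra - extra[nn])
    # Chebyshev distance in m+1 dims over the valid (nonzero-dmin) points
    ratio = np.maximum(dmin[ok], extra_gap[ok]) / dmin[ok]
    return float(ratio.mean()), float(extra_gap[ok].mean())


def cao_curves(series: TimeSeries, tau: int,
               m_max: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Cao's E1 and E2 curves for m = 1..m_max-1.

    E1(m) = E(m+1)/E(m) saturates near 1 once m reaches the attractor's
    embedding dimension; E2(m) ~= 1 at every m signals a stochastic
    series.  Requires the series to be embeddable at dimension m_max + 1.
    """
    if m_max < 2:
        raise ValueError("m_max must be >= 2")
    e = np.empty(m_max)
    e_star = np.empty(m_max)
    for m in range(1, m_max + 1):
        e[m - 1], e_star[m - 1] = _nn_stats(series.samples, tau, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = e[1:] / e[:-1]
        # E*(m) = 0 (all extra coordinates tie, heavily quantized data)
        # makes the ratio meaningless; report it as saturated
        e2 = np.where(e_star[:-1] > 0, e_star[1:] / e_star[:-1], 1.0)
    return e1, e2


def select_dim(e1: np.ndarray, saturation_tol: float = 0.05) -> int:
    """Smallest m with |E1(m) - 1| < tol; falls back to the largest m."""
    e1 = np.asarray(e1, dtype=float)
    if e1.size == 0:
        raise ValueError("E1 curve is empty")
    hits = np.nonzero(np.abs(e1 - 1.0) < saturation_tol)[0]
    if hits.size:
        return int(hits[0]) + 1
    # expected for stochastic signals, whose E1 keeps creeping toward 1
    logger.debug("E1 never saturates within tol=%g; using m_max=%d",
                 saturation_tol, e1.size)
    return int(e1.size)


def estimate_embedding(series: TimeSeries, max_lag: int | None = None,
                       n_bins: int | None = None, m_max: int = 10,
                       saturation_tol: float = 0.05,
                       min_points: int = 20) -> EmbeddingParams:
    """Full delay/dimension estimation for one signal block.

    ``tau`` comes from the first AMI minimum (capped so the trajectory
    keeps at least ``min_points`` points at the largest candidate
    dimension); ``m`` from Cao's E1 saturation.
    """
    n = len(series)
    if max_lag is None:
        max_lag = max(2, min(n // 4, 64))
    curve = ami_curve(series, max_lag=max_lag, n_bins=n_bins)
    if curve.degenerate:
        return EmbeddingParams(tau=1, m=1)
    tau = select_delay(curve)
    # keep the Cao search feasible: need n - (m_max+1) tau >= min_points
    m_cap = max(2, min(m_max, (n - min_points) // max(tau, 1) - 1))
    tau = min(tau, max(1, (n - min_points) // (m_cap + 1)))
    e1, _ = cao_curves(series, tau=tau, m_max=m_cap)
    m = select_dim(e1, saturation_tol=saturation_tol)
    return EmbeddingParams(tau=tau, m=m)
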