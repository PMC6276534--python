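"""Synthetic test signals and EEG surrogate datasets.

Provides deterministic fixtures with known dynamics (periodic, chaotic,
stochastic) for validating recurrence-based measures, plus a three-class
EEG surrogate generator that emulates the five-subset single-channel
scalp/intracranial recording layout (100 segments of 23.6 s sampled at
173.61 Hz per subset): irregular broadband activity for the healthy
subsets, colored noise with sporadic spike transients for the interictal
subsets, and a high-amplitude quasi-periodic 3.5 Hz oscillation for the
ictal subset.  Also reads and writes the plain-ASCII one-integer-per-line
segment format in which such recordings are commonly distributed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

DEFAULT_RATE = 173.61
"""Sampling rate in Hz of the emulated recordings."""

SEGMENT_LEN = 4097
"""Samples per segment (23.6 s at 173.61 Hz)."""

SUBSET_LABELS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    samples
        The signal values, in arbitrary units.
    rate
        Sampling rate in Hz.
    label
        Optional subset tag ("A".."E") or synthetic class name.
    """

    samples: np.ndarray
    rate: float = DEFAULT_RATE
    label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("TimeSeries requires a 1-D array with >= 1 sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("TimeSeries samples must all be finite")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self) / self.rate


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_sine(freq: float, rate: float, n: int, noise_sd: float = 0.0,
             amplitude: float = 1.0, phase: float = 0.0,
             rng: int | np.random.Generator | None = None) -> TimeSeries:
    """Sinusoid of ``freq`` Hz sampled at ``rate`` Hz, optionally noisy.

    Raises
    ------
    ValueError
        If ``freq`` is at or above the Nyquist frequency ``rate / 2``.
    """
    if not 0 < freq < rate / 2:
        raise ValueError(
            f"frequency {freq} Hz is not below the Nyquist limit {rate / 2} Hz")
    if n < 1:
        raise ValueError("n must be >= 1")
    t = np.arange(n) / rate
    x = amplitude * np.sin(2 * np.pi * freq * t + phase)
    if noise_sd > 0:
        x = x + _as_rng(rng).normal(0.0, noise_sd, size=n)
    return TimeSeries(x, rate=rate, label="sine")


def gen_logistic(r: float, x0: float, n: int) -> TimeSeries:
    """Logistic-map orbit x_{t+1} = r x_t (1 - x_t); chaotic for r = 4."""
    if not 0 < x0 < 1:
        raise ValueError(f"x0 must lie in (0, 1), got {x0}")
    if n < 1:
        raise ValueError("n must be >= 1")
    x = np.empty(n)
    x[0] = x0
    for t in range(1, n):
        x[t] = r * x[t - 1] * (1.0 - x[t - 1])
    return TimeSeries(x, rate=1.0, label="logistic")


def gen_noise(kind: str, n: int, param: float = 1.0,
              seed: int | np.random.Generator | None = None) -> TimeSeries:
    """Stochastic fixture: Gaussian white noise or a stationary AR(1).

    For ``kind="white"`` ``param`` is the standard deviation; for
    ``kind="ar1"`` it is the lag-1 coefficient (|param| < 1, unit-variance
    Gaussian innovations, stationary start).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    kind = kind.lower()
    if kind == "white":
        x = rng.normal(0.0, param, size=n)
    elif kind == "ar1":
        if not abs(param) < 1:
            raise ValueError(
                f"AR(1) coefficient must satisfy |a| < 1, got {param}")
        # stationary marginal variance 1 / (1 - a^2)
        x = _ar1_from_innovations(rng.normal(0.0, 1.0, size=n), param)
    else:
        raise ValueError(f"unknown noise kind {kind!r}; use 'white' or 'ar1'")
    return TimeSeries(x, rate=1.0, label=kind)


@dataclass(frozen=True)
class ClassParams:
    """Per-class generator settings for one surrogate subset."""

    kind: str                      # "broadband" | "interictal" | "ictal"
    amplitude: float = 50.0        # overall scale, arbitrary units
    ar_coeff: float = 0.6          # coloring of the noise floor
    noise_sd: float = 1.0          # innovation scale relative to amplitude
    osc_freq: float = 3.5          # Hz, ictal rhythm
    am_freq: float = 0.3           # Hz, slow amplitude modulation of the rhythm
    am_depth: float = 0.4
    spike_rate: float = 0.0        # Hz, Poisson rate of transients
    spike_amp: float = 0.0
    spike_width: float = 0.05      # seconds (Gaussian sd of the transient)


#: Default per-subset dynamics.  A/B: irregular broadband activity (weakly
#: colored noise); C/D: strongly colored noise with sporadic spike
#: transients (lower-amplitude, more regular morphology between events);
#: E: large-amplitude amplitude-modulated 3.5 Hz quasi-periodic rhythm.
DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    "A": ClassParams(kind="broadband", amplitude=40.0, ar_coeff=0.55),
    "B": ClassParams(kind="broadband", amplitude=50.0, ar_coeff=0.62),
    "C": ClassParams(kind="interictal", amplitude=45.0, ar_coeff=0.90,
                     spike_rate=0.6, spike_amp=140.0),
    "D": ClassParams(kind="interictal", amplitude=50.0, ar_coeff=0.92,
                     spike_rate=1.0, spike_amp=160.0),
    "E": ClassParams(kind="ictal", amplitude=300.0, noise_sd=0.1),
}


@dataclass(frozen=True)
class SurrogateSpec:
    """Specification of a synthetic five-subset dataset.

    ``seed`` fixed implies byte-identical output on regeneration.
    """

    n_segments: int = 100
    segment_len: int = SEGMENT_LEN
    rate: float = DEFAULT_RATE
    seed: int = 0
    class_params: dict[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.segment_len < 2:
            raise ValueError("segment_len must be >= 2")
        for label, cp in self.class_params.items():
            if cp.kind not in ("broadband", "interictal", "ictal"):
                raise ValueError(
                    f"subset {label}: unknown class kind {cp.kind!r}")


def _ar1_from_innovations(eps: np.ndarray, a: float) -> np.ndarray:
    """x_t = a x_{t-1} + eps_t with a stationary start (x_0 scaled up)."""
    x0 = eps[0] / np.sqrt(1.0 - a * a)
    rest, _ = lfilter([1.0], [1.0, -a], eps[1:], zi=np.array([a * x0]))
    return np.concatenate(([x0], rest))


def _ar1(rng: np.random.Generator, n: int, a: float, sd: float) -> np.ndarray:
    return _ar1_from_innovations(rng.normal(0.0, sd, size=n), a)


def _gen_segment(cp: ClassParams, n: int, rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / rate
    if cp.kind == "ictal":
        # amplitude-modulated quasi-periodic oscillation with a weak second
        # harmonic (sharpened waveform) plus a small broadband floor
        phase = rng.uniform(0, 2 * np.pi)
        am_phase = rng.uniform(0, 2 * np.pi)
        am = 1.0 + cp.am_depth * np.sin(2 * np.pi * cp.am_freq * t + am_phase)
        rhythm = (np.sin(2 * np.pi * cp.osc_freq * t + phase)
                  + 0.3 * np.sin(4 * np.pi * cp.osc_freq * t + 2 * phase))
        x = cp.amplitude * am * rhythm
        x = x + _ar1(rng, n, 0.5, cp.noise_sd * cp.amplitude)
        return x
    # noise floor for healthy and interictal classes
    a = cp.ar_coeff
    sd = cp.amplitude * np.sqrt(1.0 - a * a)  # marginal sd ~= amplitude
    x = _ar1(rng, n, a, sd)
    if cp.kind == "interictal" and cp.spike_rate > 0:
        n_spikes = rng.poisson(cp.spike_rate * n / rate)
        width = cp.spike_width * rate
        for _ in range(n_spikes):
            center = rng.uniform(0, n)
            sign = rng.choice([-1.0, 1.0])
            amp = cp.spike_amp * rng.uniform(0.7, 1.3)
            idx = np.arange(max(0, int(center - 4 * width)),
                            min(n, int(center + 4 * width)))
            x[idx] += sign * amp * np.exp(-0.5 * ((idx - center) / width) ** 2)
    return x


def gen_surrogate_subsets(spec: SurrogateSpec) -> dict[str, list[TimeSeries]]:
    """Generate the full surrogate dataset, one segment list per subset.

    Each subset draws from its own child RNG stream so that subsets are
    independent yet jointly reproducible from ``spec.seed``.
    """
    out: dict[str, list[TimeSeries]] = {}
    root = np.random.default_rng(spec.seed)
    children = root.spawn(len(spec.class_params))
    for (label, cp), rng in zip(sorted(spec.class_params.items()), children):
        segs = []
        for _ in range(spec.n_segments):
            x = _gen_segment(cp, spec.segment_len, spec.rate, rng)
            segs.append(TimeSeries(x, rate=spec.rate, label=label))
        out[label] = segs
    return out


def read_bonn_ascii(path: str | Path, rate: float = DEFAULT_RATE,
                    label: str | None = None) -> TimeSeries:
    """Read a one-integer-per-line ASCII segment file."""
    path = Path(path)
    values: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(int(line))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: not an integer sample: "
                    f"{line!r}") from exc
    if not values:
        raise ValueError(f"{path}: empty segment file")
    return TimeSeries(np.asarray(values, dtype=float), rate=rate, label=label)


def write_bonn_ascii(series: TimeSeries, path: str | Path) -> None:
    """Write a series as one integer per line (samples rounded to nearest)."""
    path = Path(path)
    ints = np.rint(series.samples).astype(int)
    with open(path, "w") as fh:
        for v in ints:
            fh.write(f"{v}\n")


def read_bonn_dir(root: str | Path,
                  rate: float = DEFAULT_RATE) -> dict[str, list[TimeSeries]]:
    """Read a directory laid out as ``root/<subset>/<segment>.txt``.

    Subset subdirectory names are matched case-insensitively against
    A-E; files within a subset are read in sorted order.
    """
    root = Path(root)
    out: dict[str, list[TimeSeries]] = {}
    for sub in sorted(root.iterdir()):
        if not sub.is_dir():
            continue
        label = sub.name.upper()
        if label not in SUBSET_LABELS:
            warnings.warn(f"ignoring unrecognized subset directory {sub.name}")
            continue
        segs = [read_bonn_ascii(p, rate=rate, label=label)
                for p in sorted(sub.iterdir()) if p.is_file()]
        if segs:
            out[label] = segs
    if not out:
        raise ValueError(f"{root}: no subset directories (A-E) with segments")
    return out
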