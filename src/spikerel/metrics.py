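"""Spike-train and subthreshold reliability metrics.

The central statistic is the *matching-spike fraction*: for an ordered pair
of repetitions of the same frozen stimulus, the fraction of spikes in one
repetition that fall within a coincidence window (default 1 ms) of at least
one spike of the other.  Averaging over all ordered pairs of a sweep set
yields the raw spiking reliability of a neuron; because it is a per-pair
average it is not biased by the number of trials (only its variance shrinks
with more trials).

A high firing rate inflates the raw value by chance coincidences, so a
firing-rate correction subtracts the same metric computed on surrogate sweep
sets in which each sweep keeps its spike count but the spike times are
redrawn uniformly within the stimulus window (default 100 surrogates).  The
corrected value is ~0 for Poisson-like trains regardless of rate and
approaches 1 for millisecond-precise repetition.

Nearest-spike latency pools (for cumulative latency distributions) and
subthreshold reliability (mean pairwise Spearman correlation of voltage
traces at the sub-rheobase intensity) complete the per-neuron description.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SweepSet",
    "ReliabilityResult",
    "nearest_spike_latencies",
    "latency_cdf",
    "matching_fraction",
    "spiking_reliability",
    "corrected_reliability",
    "subthreshold_reliability",
    "InsufficientRepetitionsError",
]


class InsufficientRepetitionsError(ValueError):
    """Fewer than two usable (spike-containing) sweeps in a sweep set."""


@dataclass
class SweepSet:
    """Repeated responses of one neuron to one frozen noise at one intensity.

    Spike times are in seconds relative to stimulus-segment onset and must be
    sorted; ``stimulus_window_s`` is the (start, end) of the stimulus segment
    the spikes belong to (normally (0, 3)).
    """

    neuron_id: str
    noise_id: str
    intensity_pct: int
    sweeps: list[np.ndarray]
    stimulus_window_s: tuple[float, float] = (0.0, 3.0)
    voltage: list[np.ndarray] | None = None
    sampling_rate_hz: float | None = None

    def __post_init__(self) -> None:
        self.sweeps = [np.asarray(s, dtype=float) for s in self.sweeps]
        lo, hi = self.stimulus_window_s
        for s in self.sweeps:
            if s.size and (np.any(np.diff(s) < 0)):
                raise ValueError("spike times must be sorted ascending")
            if s.size and (s[0] < lo or s[-1] > hi):
                raise ValueError(
                    f"spike times outside stimulus window {self.stimulus_window_s}"
                )

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)


@dataclass
class ReliabilityResult:
    """Raw and firing-rate-corrected matching-spike reliability of one neuron."""

    neuron_id: str
    window_ms: float
    raw_reliability: float
    shuffled_mean: float
    corrected_reliability: float
    n_pairs: int
    n_permutations: int
    latencies_s: np.ndarray = field(default_factory=lambda: np.empty(0))


def nearest_spike_latencies(train_a: np.ndarray, train_b: np.ndarray) -> np.ndarray:
    """Latency from each spike of ``train_a`` to its closest spike in ``train_b``.

    ``train_b`` must be non-empty and sorted; returns one non-negative value
    per spike of ``train_a``.  Aggregation over both directions of a pair is
    the caller's job.
    """
    train_a = np.asarray(train_a, dtype=float)
    train_b = np.asarray(train_b, dtype=float)
    if train_b.size == 0:
        raise ValueError("reference train is empty")
    if train_a.size == 0:
        return np.empty(0)
    idx = np.searchsorted(train_b, train_a)
    left = np.clip(idx - 1, 0, train_b.size - 1)
    right = np.clip(idx, 0, train_b.size - 1)
    return np.minimum(np.abs(train_a - train_b[left]), np.abs(train_a - train_b[right]))


def latency_cdf(
    latencies: np.ndarray,
    grid: np.ndarray,
    method: str = "empirical",
) -> np.ndarray:
    """Cumulative probability of nearest-spike latencies on a grid.

    ``method='empirical'`` returns the fraction of latencies <= each grid
    point; ``method='gaussian-kernel'`` returns a Gaussian-kernel CDF
    estimate with Silverman plug-in bandwidth (the kernel analogue of a
    smoothed cumulative density).  Both are non-decreasing and bounded by
    [0, 1].
    """
    latencies = np.asarray(latencies, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if latencies.size == 0:
        raise ValueError("latencies must be non-empty")
    if method == "empirical":
        return np.searchsorted(np.sort(latencies), grid, side="right") / latencies.size
    if method == "gaussian-kernel":
        sd = latencies.std(ddof=1) if latencies.size > 1 else 0.0
        if sd == 0.0:
            # degenerate sample: step CDF at the common value
            return (grid >= latencies[0]).astype(float)
        iqr = np.subtract(*np.percentile(latencies, [75, 25]))
        spread = min(sd, iqr / 1.349) if iqr > 0 else sd
        h = 0.9 * spread * latencies.size ** (-1 / 5)
        z = (grid[:, None] - latencies[None, :]) / h
        return stats.norm.cdf(z).mean(axis=1)
    raise ValueError(f"unknown method {method!r}")


def matching_fraction(
    train_a: np.ndarray, train_b: np.ndarray, window_ms: float
) -> float:
    """Fraction of spikes in ``train_a`` with a spike of ``train_b`` within
    ``window_ms`` (inclusive boundary).

    Spike times are in seconds; the window is in milliseconds.
    """
    if window_ms <= 0:
        raise ValueError(f"window_ms must be positive, got {window_ms}")
    train_a = np.asarray(train_a, dtype=float)
    if train_a.size == 0:
        raise ValueError("train_a is empty: matching fraction undefined")
    lat = nearest_spike_latencies(train_a, train_b)
    return float(np.mean(lat <= window_ms * 1e-3))


def _usable_sweeps(sweeps: list[np.ndarray]) -> list[np.ndarray]:
    usable = [s for s in sweeps if len(s) > 0]
    n_empty = len(sweeps) - len(usable)
    if n_empty:
        logger.info("excluded %d empty sweep(s) from pair formation", n_empty)
    return usable


def spiking_reliability(sweeps: SweepSet, window_ms: float = 1.0) -> float:
    """Mean matching-spike fraction over all ordered pairs of repetitions.

    Sweeps with zero spikes are excluded from pair formation; fewer than two
    usable sweeps raises :class:`InsufficientRepetitionsError`.
    """
    usable = _usable_sweeps(sweeps.sweeps)
    if len(usable) < 2:
        raise InsufficientRepetitionsError(
            f"{sweeps.neuron_id}: need >= 2 sweeps with spikes, got {len(usable)}"
        )
    fracs = [
        matching_fraction(a, b, window_ms)
        for a, b in itertools.permutations(usable, 2)
    ]
    return float(np.mean(fracs))


def pooled_latencies(sweeps: SweepSet) -> np.ndarray:
    """Nearest-spike latencies pooled over both directions of every pair."""
    usable = _usable_sweeps(sweeps.sweeps)
    out = [
        nearest_spike_latencies(a, b)
        for a, b in itertools.permutations(usable, 2)
    ]
    return np.concatenate(out) if out else np.empty(0)


def corrected_reliability(
    sweeps: SweepSet,
    window_ms: float = 1.0,
    n_permutations: int = 100,
    rng_seed: int | np.random.SeedSequence | None = 0,
) -> ReliabilityResult:
    """Firing-rate-corrected spiking reliability.

    The raw reliability is reduced by its chance level, estimated as the mean
    reliability over ``n_permutations`` surrogate sweep sets in which each
    sweep keeps its spike count but the spike times are redrawn uniformly
    within the stimulus window.  The corrected value can be slightly negative
    for unstructured trains.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    raw = spiking_reliability(sweeps, window_ms)
    usable = _usable_sweeps(sweeps.sweeps)
    counts = [len(s) for s in usable]
    lo, hi = sweeps.stimulus_window_s
    rng = np.random.default_rng(rng_seed)
    shuffled = np.empty(n_permutations)
    for p in range(n_permutations):
        surrogate = [np.sort(rng.uniform(lo, hi, size=c)) for c in counts]
        fracs = [
            matching_fraction(a, b, window_ms)
            for a, b in itertools.permutations(surrogate, 2)
        ]
        shuffled[p] = np.mean(fracs)
    n_pairs = len(usable) * (len(usable) - 1)
    shuffled_mean = float(shuffled.mean())
    return ReliabilityResult(
        neuron_id=sweeps.neuron_id,
        window_ms=window_ms,
        raw_reliability=raw,
        shuffled_mean=shuffled_mean,
        corrected_reliability=raw - shuffled_mean,
        n_pairs=n_pairs,
        n_permutations=n_permutations,
        latencies_s=pooled_latencies(sweeps),
    )


def subthreshold_reliability(
    voltages: list[np.ndarray],
    window: tuple[float, float] | None = None,
    sampling_rate_hz: float | None = None,
) -> float:
    """Mean pairwise Spearman correlation of voltage traces.

    Intended for the sub-rheobase (75 %) intensity where the response stays
    below threshold.  ``window`` (start, end in seconds, requires
    ``sampling_rate_hz``) restricts each trace before correlating; constant
    traces are excluded from pair formation with a warning.
    """
    arrs = [np.asarray(v, dtype=float) for v in voltages]
    if len(arrs) < 2:
        raise ValueError("need at least 2 voltage traces")
    if window is not None:
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz required when window is given")
        i0 = int(round(window[0] * sampling_rate_hz))
        i1 = int(round(window[1] * sampling_rate_hz))
        arrs = [v[i0:i1] for v in arrs]
    lengths = {v.size for v in arrs}
    if len(lengths) != 1:
        raise ValueError(f"traces have mismatched lengths after windowing: {lengths}")
    keep = [v for v in arrs if np.ptp(v) > 0]
    if len(keep) < len(arrs):
        warnings.warn(
            f"excluded {len(arrs) - len(keep)} constant trace(s) from pairing",
            stacklevel=2,
        )
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant traces")
    rhos = [
        stats.spearmanr(a, b).statistic
        for a, b in itertools.combinations(keep, 2)
    ]
    return float(np.mean(rhos))
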