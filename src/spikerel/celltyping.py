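"""Electrophysiological and transcriptomic cell typing.

Fast-spiking vs regular-spiking classification follows the standard
waveform-width criterion: the spikes a neuron fired during noise stimulation
are averaged (peak-aligned), the width of the average spike is measured at
half of the peak-to-baseline amplitude, and neurons narrower than 400 µs are
labelled *fast*, the rest *regular*.

Transcriptomic Cre-line labels are collapsed into four display groups
(PV inhibitory, non-PV inhibitory, mixed, excitatory) through a
user-editable CSV mapping shipped with the package; unknown labels fail
loudly rather than defaulting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "SpikeWaveform",
    "average_spike",
    "spike_width_half_amplitude",
    "classify_ephys",
    "group_transcriptomic",
    "load_group_mapping",
    "UnmappedLabelError",
]

FAST_SPIKING_THRESHOLD_US = 400.0

GROUPS = ("PV", "non-PV inhibitory", "mixed", "excitatory")


class UnmappedLabelError(KeyError):
    """A transcriptomic line label absent from the mapping table."""


@dataclass(frozen=True)
class SpikeWaveform:
    """A (possibly averaged) action-potential waveform in mV."""

    samples: np.ndarray
    sampling_rate_hz: float
    aligned: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))


def average_spike(waveforms: list[SpikeWaveform]) -> SpikeWaveform:
    """Elementwise mean of peak-aligned waveforms of equal length."""
    if len(waveforms) == 0:
        raise ValueError("need at least one waveform")
    if not all(w.aligned for w in waveforms):
        raise ValueError("all waveforms must be peak-aligned before averaging")
    lengths = {w.samples.size for w in waveforms}
    if len(lengths) != 1:
        raise ValueError(f"waveform length mismatch: {lengths}")
    rates = {w.sampling_rate_hz for w in waveforms}
    if len(rates) != 1:
        raise ValueError(f"sampling rate mismatch: {rates}")
    mean = np.mean([w.samples for w in waveforms], axis=0)
    return SpikeWaveform(mean, waveforms[0].sampling_rate_hz, aligned=True)


def estimate_baseline(
    waveform: SpikeWaveform, pre_window_ms: float = 2.0
) -> float:
    """Median voltage over a window ending at the start of the upstroke.

    Used when no explicit baseline is supplied; takes the median of the
    samples preceding the last sub-half-maximum sample before the peak,
    within ``pre_window_ms``.
    """
    v = waveform.samples
    peak = int(np.argmax(v))
    n_pre = int(round(pre_window_ms * 1e-3 * waveform.sampling_rate_hz))
    start = max(0, peak - n_pre)
    if start == peak:
        raise ValueError("waveform too short to estimate a baseline")
    return float(np.median(v[start:peak]))


def spike_width_half_amplitude(
    waveform: SpikeWaveform, baseline: float | None = None
) -> float:
    """Spike width (µs) at half of the peak-to-baseline amplitude.

    Width is measured between the first upward and the last downward crossing
    of ``baseline + (peak - baseline)/2``, with linear interpolation between
    samples.  A waveform that never crosses the half level (e.g. flat) is
    malformed and raises.
    """
    v = waveform.samples
    if v.size < 3:
        raise ValueError("waveform too short")
    if baseline is None:
        baseline = estimate_baseline(waveform)
    peak = float(v.max())
    if not peak > baseline:
        raise ValueError(f"peak ({peak}) must exceed baseline ({baseline})")
    half = baseline + (peak - baseline) / 2.0
    above = v >= half
    if not above.any() or above.all():
        raise ValueError("waveform does not cross the half-amplitude level")
    crossings = np.flatnonzero(np.diff(above.astype(int)))
    ups = crossings[~above[crossings]]       # below -> above between i and i+1
    downs = crossings[above[crossings]]      # above -> below
    if ups.size == 0 or downs.size == 0:
        raise ValueError("missing an upward or downward half-amplitude crossing")
    i = int(ups[0])
    j = int(downs[-1])
    # linear interpolation of the crossing instants
    t_up = i + (half - v[i]) / (v[i + 1] - v[i])
    t_down = j + (v[j] - half) / (v[j] - v[j + 1])
    width_samples = t_down - t_up
    return float(width_samples / waveform.sampling_rate_hz * 1e6)


def classify_ephys(width_us: float, threshold_us: float = FAST_SPIKING_THRESHOLD_US) -> str:
    """``'fast'`` if the spike width is strictly below the threshold, else
    ``'regular'`` (a width of exactly 400 µs is regular)."""
    if width_us <= 0:
        raise ValueError(f"width must be positive, got {width_us}")
    return "fast" if width_us < threshold_us else "regular"


def load_group_mapping(path: str | Path | None = None) -> dict[str, str]:
    """Load the line-label -> group mapping table (default: packaged CSV)."""
    if path is None:
        source = resources.files("spikerel.data").joinpath("transcriptomic_groups.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[str, str] = {}
    for row in csv.DictReader(text.splitlines()):
        group = row["group"]
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r} in mapping table")
        mapping[row["line_label"]] = group
    return mapping


def group_transcriptomic(
    line_label: str, mapping: dict[str, str] | None = None
) -> str:
    """Collapse a transcriptomic line label into one of the four display
    groups.  Matching is by the Cre-driver prefix (text before the first
    ``-``) with a full-label fallback; an unknown label raises
    :class:`UnmappedLabelError`.
    """
    if mapping is None:
        mapping = load_group_mapping()
    if line_label in mapping:
        return mapping[line_label]
    prefix = line_label.split("-")[0]
    if prefix in mapping:
        return mapping[prefix]
    raise UnmappedLabelError(
        f"line label {line_label!r} not in mapping table; add it to the CSV"
    )
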