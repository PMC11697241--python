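"""Frozen pink-noise stimulation protocol.

The protocol mimics the noise sweeps of the Allen Cell Types dataset: a 1 s
pink-noise template is built by summing sinusoids from ``f_min`` to ``f_max``
(1 Hz steps) with random phases and amplitudes proportional to 1/sqrt(f), so
power falls as 1/f.  The mean is removed, the trace is rescaled to a target
coefficient of variation relative to a unit DC offset, the template is
concatenated three times into a 3 s stimulus template, and intensity-scaled
copies (75/100/150 % of rheobase, ascending, separated by recovery windows of
zero current) form the full injected trace.  Because every quantity derives
from one seeded generator, the same seed reproduces the identical waveform —
the "frozen noise" contract that makes cross-repetition reliability
meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "NoiseTemplate",
    "StimulusProtocol",
    "generate_pink_noise",
    "build_protocol",
    "autocorrelate",
    "write_protocol",
    "read_protocol",
]

DEFAULT_SAMPLING_RATE_HZ = 25_000.0


@dataclass(frozen=True)
class NoiseTemplate:
    """One 1 s frozen-noise template, DC included (mean 1, std = cv)."""

    seed: int
    samples: np.ndarray
    duration_s: float
    sampling_rate_hz: float
    cv: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def zero_mean(self) -> np.ndarray:
        """The template with its DC offset removed."""
        return self.samples - 1.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Full injected current trace with per-segment bookkeeping.

    ``segment_table`` rows are ``(intensity_pct, start_s, end_s)`` in
    ascending intensity order; between segments the trace holds
    ``recovery_s`` of zero current.
    """

    trace: np.ndarray
    segment_table: list[tuple[int, float, float]]
    rheobase_pa: float
    recovery_s: float
    sampling_rate_hz: float
    noise_id: str = "Noise1"
    seed: int | None = None
    cv: float | None = None
    lead_s: float = 0.0
    trail_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trace", np.asarray(self.trace, dtype=float))

    @property
    def duration_s(self) -> float:
        return self.trace.size / self.sampling_rate_hz

    def segment_trace(self, intensity_pct: int) -> np.ndarray:
        """Return the current samples of one intensity segment."""
        for pct, start, end in self.segment_table:
            if pct == intensity_pct:
                i0 = int(round(start * self.sampling_rate_hz))
                i1 = int(round(end * self.sampling_rate_hz))
                return self.trace[i0:i1]
        raise KeyError(f"no segment at intensity {intensity_pct}%")


def generate_pink_noise(
    seed: int,
    duration_s: float = 1.0,
    f_min_hz: float = 1.0,
    f_max_hz: float = 100.0,
    f_step_hz: float = 1.0,
    cv: float = 0.2,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> NoiseTemplate:
    """Generate a frozen pink-noise template.

    Sinusoids at ``f_min..f_max`` (step ``f_step``) with amplitudes
    proportional to 1/sqrt(f) and i.i.d. uniform phases are summed, the time
    average is removed, and the residual is rescaled so that after adding the
    unit DC offset the trace has ``std/mean == cv`` exactly.  The 1/sqrt(f)
    amplitudes fix only the relative spectral weights; the absolute scale is
    set by the CV constraint.

    Parameters
    ----------
    seed
        Seeds the phase generator; identical seeds give bit-identical
        templates.
    cv
        Target coefficient of variation of the DC-offset trace (0.2 for the
        standard protocol).

    Returns
    -------
    NoiseTemplate
        ``samples`` has mean 1 and standard deviation ``cv``.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if cv <= 0:
        raise ValueError(f"cv must be positive, got {cv}")
    if f_min_hz < 1.0:
        raise ValueError(f"f_min_hz must be >= 1, got {f_min_hz}")
    if f_max_hz > sampling_rate_hz / 2:
        raise ValueError(
            f"f_max_hz={f_max_hz} exceeds Nyquist ({sampling_rate_hz / 2})"
        )
    if f_max_hz < f_min_hz:
        raise ValueError("f_max_hz must be >= f_min_hz")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    freqs = np.arange(f_min_hz, f_max_hz + f_step_hz / 2, f_step_hz)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    amps = 1.0 / np.sqrt(freqs)
    # trace = sum_f a_f sin(2 pi f t + phi_f); outer product kept vectorized
    x = (amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(axis=0)
    x -= x.mean()
    sd = x.std()
    if sd == 0.0:
        raise ValueError("degenerate template: zero variance before scaling")
    # mean after DC addition is 1, so std must equal cv exactly
    samples = x * (cv / sd) + 1.0
    return NoiseTemplate(
        seed=seed,
        samples=samples,
        duration_s=duration_s,
        sampling_rate_hz=sampling_rate_hz,
        cv=cv,
    )


def build_protocol(
    template: NoiseTemplate,
    rheobase_pa: float,
    intensities: list[float] | None = None,
    recovery_s: float = 5.0,
    noise_id: str = "Noise1",
    n_concat: int = 3,
    lead_s: float = 0.0,
    trail_s: float = 0.0,
) -> StimulusProtocol:
    """Assemble the full stimulation trace from one noise template.

    The template (DC included) is concatenated ``n_concat`` times into the
    stimulus template, copies are scaled by ``intensity * rheobase_pa``,
    sorted ascending and separated by ``recovery_s`` of zero current.
    Optional ``lead_s``/``trail_s`` pad the trace with zero current before the
    first and after the last segment.
    """
    if rheobase_pa <= 0:
        raise ValueError(f"rheobase_pa must be positive, got {rheobase_pa}")
    if intensities is None:
        intensities = [0.75, 1.0, 1.5]
    if len(intensities) == 0:
        raise ValueError("intensities must be non-empty")
    if any(i <= 0 for i in intensities):
        raise ValueError(f"intensities must be positive, got {intensities}")

    fs = template.sampling_rate_hz
    stim_template = np.tile(template.samples, n_concat)
    seg_dur = stim_template.size / fs
    recovery = np.zeros(int(round(recovery_s * fs)))

    pieces: list[np.ndarray] = []
    table: list[tuple[int, float, float]] = []
    cursor = 0.0
    if lead_s > 0:
        pieces.append(np.zeros(int(round(lead_s * fs))))
        cursor += lead_s
    for k, intensity in enumerate(sorted(intensities)):
        if k > 0:
            pieces.append(recovery)
            cursor += recovery_s
        pieces.append(stim_template * (intensity * rheobase_pa))
        table.append((int(round(intensity * 100)), cursor, cursor + seg_dur))
        cursor += seg_dur
    if trail_s > 0:
        pieces.append(np.zeros(int(round(trail_s * fs))))

    return StimulusProtocol(
        trace=np.concatenate(pieces),
        segment_table=table,
        rheobase_pa=rheobase_pa,
        recovery_s=recovery_s,
        sampling_rate_hz=fs,
        noise_id=noise_id,
        seed=template.seed,
        cv=template.cv,
        lead_s=lead_s,
        trail_s=trail_s,
    )


def autocorrelate(
    trace: np.ndarray, max_lag_s: float, sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized autocorrelation of a current trace.

    The mean is removed and the (biased) autocorrelation is normalized to 1
    at zero lag.  A constant trace has zero variance and raises rather than
    returning NaNs.

    Returns
    -------
    (lags_s, values)
        Lags from ``-max_lag_s`` to ``+max_lag_s`` at the sampling step.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace must be non-empty")
    max_lag = int(round(max_lag_s * sampling_rate_hz))
    if max_lag >= trace.size:
        raise ValueError(
            f"max_lag_s={max_lag_s} exceeds trace duration "
            f"{trace.size / sampling_rate_hz}"
        )
    x = trace - trace.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("autocorrelation undefined for a constant trace")
    full = signal.correlate(x, x, mode="full", method="fft") / denom
    mid = trace.size - 1
    sl = slice(mid - max_lag, mid + max_lag + 1)
    lags = np.arange(-max_lag, max_lag + 1) / sampling_rate_hz
    return lags, full[sl]


def write_protocol(protocol: StimulusProtocol, prefix: str | Path) -> tuple[Path, Path]:
    """Write a protocol as ``<prefix>.csv`` (time_s, current_pa) plus a JSON
    sidecar holding the segment table and generation metadata.

    The CSV stores full float64 hex-free repr via ``%.17g`` so a read-back
    round-trips bit-exactly.
    """
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    t = np.arange(protocol.trace.size) / protocol.sampling_rate_hz
    np.savetxt(
        csv_path,
        np.column_stack([t, protocol.trace]),
        delimiter=",",
        header="time_s,current_pa",
        comments="",
        fmt="%.17g",
    )
    meta = {
        "segment_table": [list(row) for row in protocol.segment_table],
        "seed": protocol.seed,
        "cv": protocol.cv,
        "rheobase_pa": protocol.rheobase_pa,
        "recovery_s": protocol.recovery_s,
        "sampling_rate_hz": protocol.sampling_rate_hz,
        "noise_id": protocol.noise_id,
        "lead_s": protocol.lead_s,
        "trail_s": protocol.trail_s,
    }
    json_path.write_text(json.dumps(meta, indent=2))
    return csv_path, json_path


def read_protocol(prefix: str | Path) -> StimulusProtocol:
    """Read a protocol written by :func:`write_protocol`."""
    prefix = Path(prefix)
    data = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", skiprows=1)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return StimulusProtocol(
        trace=data[:, 1],
        segment_table=[(int(p), float(s), float(e)) for p, s, e in meta["segment_table"]],
        rheobase_pa=meta["rheobase_pa"],
        recovery_s=meta["recovery_s"],
        sampling_rate_hz=meta["sampling_rate_hz"],
        noise_id=meta["noise_id"],
        seed=meta["seed"],
        cv=meta["cv"],
        lead_s=meta.get("lead_s", 0.0),
        trail_s=meta.get("trail_s", 0.0),
    )
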