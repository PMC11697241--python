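"""Synthetic neuron populations with known reliability structure.

The generator emulates the repeated-sweep layout of frozen-noise
current-clamp experiments: per neuron, each of two frozen noises is
presented at 75/100/150 % of rheobase, 2-8 times each.  Rather than a
biophysical model, every neuron carries one latent "template" spike train
per (noise, intensity) condition — an inhomogeneous Poisson train whose
intensity follows the positive part of the stimulus current — and each
recorded sweep is the template passed through three independent corruption
knobs:

* Gaussian spike-time jitter (SD ``jitter_sd_ms``),
* independent spike deletion (``spike_deletion_prob``),
* homogeneous extra spikes (``extra_spike_rate_hz``).

Because jitter/deletion/extras are the *only* sources of across-sweep
variability, the corrected reliability a downstream analysis recovers is a
direct, interpretable function of the class parameters — classes differing
only in jitter SD must rank accordingly.  Intrinsic features (membrane tau,
rheobase, ...) are drawn around class-dependent means tied monotonically to
the jitter SD, so feature-reliability correlations of known sign are
embedded for recovery tests.

Optionally the generator emits voltage traces: a shared filtered-stimulus
component plus per-sweep independent noise (the shared-variance fraction
sets the expected pairwise rank correlation) plus stereotyped Gaussian spike
waveforms of class-dependent width, enabling subthreshold-reliability and
spike-width tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from spikerel.metrics import SweepSet
from spikerel.stimulus import StimulusProtocol, build_protocol, generate_pink_noise

__all__ = [
    "SyntheticCellClass",
    "NeuronRecord",
    "make_template_train",
    "jitter_train",
    "simulate_population",
    "synthesize_voltage",
    "make_spike_waveform",
    "write_dataset",
    "read_dataset",
    "PV_LIKE",
    "EXCITATORY_LIKE",
]

INTENSITIES = (75, 100, 150)
NOISE_IDS = ("Noise1", "Noise2")


@dataclass(frozen=True)
class SyntheticCellClass:
    """Parameters of one simulated cell class."""

    name: str
    jitter_sd_ms: float = 1.0
    spike_deletion_prob: float = 0.1
    extra_spike_rate_hz: float = 0.5
    mean_rate_hz: float = 10.0
    membrane_tau_ms: float = 15.0
    rheobase_pa: float = 150.0
    spike_width_us: float = 500.0
    n_repetitions_range: tuple[int, int] = (2, 8)
    transcriptomic_group: str = "excitatory"
    morpho_type: str = "spiny"
    species: str = "mouse"

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_deletion_prob <= 1.0:
            raise ValueError("spike_deletion_prob must be in [0, 1]")
        if self.jitter_sd_ms < 0 or self.extra_spike_rate_hz < 0:
            raise ValueError("jitter and extra-spike rate must be >= 0")
        if self.mean_rate_hz <= 0 or self.membrane_tau_ms <= 0 or self.rheobase_pa <= 0:
            raise ValueError("rates, taus and rheobase must be positive")
        lo, hi = self.n_repetitions_range
        if not (2 <= lo <= hi <= 8):
            raise ValueError("n_repetitions_range must lie within [2, 8]")


# Reference classes: a PV-like fast/reliable cell and an excitatory-like
# regular/jittery cell.  The jitter SDs (0.2 vs 5 ms) bracket the 1 ms
# coincidence window so corrected reliability separates them strongly.
PV_LIKE = SyntheticCellClass(
    name="PV-like",
    jitter_sd_ms=0.2,
    spike_deletion_prob=0.05,
    extra_spike_rate_hz=0.5,
    mean_rate_hz=15.0,
    membrane_tau_ms=8.0,
    rheobase_pa=220.0,
    spike_width_us=300.0,
    transcriptomic_group="PV",
    morpho_type="aspiny",
)
EXCITATORY_LIKE = SyntheticCellClass(
    name="excitatory-like",
    jitter_sd_ms=5.0,
    spike_deletion_prob=0.1,
    extra_spike_rate_hz=0.5,
    mean_rate_hz=8.0,
    membrane_tau_ms=25.0,
    rheobase_pa=120.0,
    spike_width_us=700.0,
    transcriptomic_group="excitatory",
    morpho_type="spiny",
)


@dataclass
class NeuronRecord:
    """One simulated (or ingested) neuron: sweep sets plus annotations."""

    neuron_id: str
    species: str
    morpho_type: str
    transcriptomic_group: str
    intrinsic_features: dict[str, float]
    sweep_sets: list[SweepSet]
    ephys_type: str | None = None
    class_name: str | None = None

    def __post_init__(self) -> None:
        for ss in self.sweep_sets:
            if ss.neuron_id != self.neuron_id:
                raise ValueError(
                    f"sweep set neuron_id {ss.neuron_id!r} != {self.neuron_id!r}"
                )
            if ss.intensity_pct not in INTENSITIES:
                raise ValueError(f"intensity must be one of {INTENSITIES}")

    def sweep_set(self, noise_id: str, intensity_pct: int) -> SweepSet:
        for ss in self.sweep_sets:
            if ss.noise_id == noise_id and ss.intensity_pct == intensity_pct:
                return ss
        raise KeyError(f"no sweep set for ({noise_id}, {intensity_pct})")


def make_template_train(
    protocol: StimulusProtocol,
    mean_rate_hz: float,
    rng_seed: int | np.random.SeedSequence | None = 0,
    intensity_pct: int = 100,
) -> np.ndarray:
    """Ground-truth inhomogeneous Poisson train for one stimulus segment.

    The instantaneous rate follows the positive part of the segment current,
    normalized so the expected spike count is ``mean_rate_hz`` times the
    segment duration.  Times are in seconds relative to segment onset.
    """
    if mean_rate_hz <= 0:
        raise ValueError(f"mean_rate_hz must be positive, got {mean_rate_hz}")
    rng = np.random.default_rng(rng_seed)
    seg = protocol.segment_trace(intensity_pct)
    fs = protocol.sampling_rate_hz
    drive = np.clip(seg, 0.0, None)
    if drive.sum() == 0.0:
        return np.empty(0)
    duration = seg.size / fs
    lam = drive / drive.sum() * mean_rate_hz * duration  # expected count per sample
    counts = rng.poisson(lam)
    idx = np.repeat(np.arange(seg.size), counts)
    times = (idx + rng.uniform(0.0, 1.0, size=idx.size)) / fs
    return np.sort(times)


def jitter_train(
    template: np.ndarray,
    cell_class: SyntheticCellClass,
    rng_seed: int | np.random.SeedSequence | None = 0,
    window_s: tuple[float, float] = (0.0, 3.0),
) -> np.ndarray:
    """Corrupt a template train into one recorded sweep.

    Each template spike is deleted with ``spike_deletion_prob``, survivors
    are shifted by Gaussian(0, jitter_sd) (reflected at the window edges so
    counts are preserved), and homogeneous extra spikes are added at
    ``extra_spike_rate_hz`` within the window.
    """
    rng = np.random.default_rng(rng_seed)
    template = np.asarray(template, dtype=float)
    lo, hi = window_s
    keep = rng.uniform(size=template.size) >= cell_class.spike_deletion_prob
    times = template[keep]
    if cell_class.jitter_sd_ms > 0 and times.size:
        times = times + rng.normal(0.0, cell_class.jitter_sd_ms * 1e-3, size=times.size)
        # reflect at the window boundaries to preserve spike counts
        span = hi - lo
        times = np.abs((times - lo) % (2 * span))
        times = lo + np.where(times > span, 2 * span - times, times)
    n_extra = rng.poisson(cell_class.extra_spike_rate_hz * (hi - lo))
    extras = rng.uniform(lo, hi, size=n_extra)
    return np.sort(np.concatenate([times, extras]))


def make_spike_waveform(
    width_us: float,
    sampling_rate_hz: float,
    amplitude_mv: float = 80.0,
    support_ms: float = 4.0,
) -> np.ndarray:
    """Stereotyped Gaussian-shaped spike of a given full width at half
    maximum (µs), peak ``amplitude_mv`` above baseline 0."""
    sd_s = width_us * 1e-6 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(round(support_ms * 1e-3 / 2 * sampling_rate_hz))
    t = np.arange(-half, half + 1) / sampling_rate_hz
    return amplitude_mv * np.exp(-0.5 * (t / sd_s) ** 2)


def synthesize_voltage(
    protocol: StimulusProtocol,
    intensity_pct: int,
    spike_times_s: np.ndarray,
    cell_class: SyntheticCellClass,
    rng: np.random.Generator,
    sampling_rate_hz: float = 2_500.0,
    shared_fraction: float = 0.8,
    shared_seed: int | None = None,
    noise_sd_mv: float = 2.0,
    rest_mv: float = -70.0,
) -> tuple[np.ndarray, float]:
    """One sweep's voltage trace: low-pass filtered stimulus (membrane-tau
    RC filter) + shared and private Gaussian noise + spike waveforms.

    ``shared_fraction`` of the noise variance comes from a component derived
    deterministically from ``shared_seed`` (common to all sweeps of the
    neuron), tuning the expected pairwise rank correlation; the rest is
    per-sweep.  The stimulus is decimated by an integer factor, so the
    returned effective sampling rate can differ slightly from the request.

    Returns
    -------
    (voltage_mv, effective_sampling_rate_hz)
    """
    seg = protocol.segment_trace(intensity_pct)
    # decimate the stimulus to (approximately) the voltage sampling rate
    step = max(1, int(round(protocol.sampling_rate_hz / sampling_rate_hz)))
    eff_rate = protocol.sampling_rate_hz / step
    drive = seg[::step]
    tau_samples = cell_class.membrane_tau_ms * 1e-3 * eff_rate
    alpha = 1.0 / max(tau_samples, 1.0)
    filtered = _signal.lfilter([alpha], [1.0, alpha - 1.0], drive - drive.mean())
    v = rest_mv + 10.0 * filtered / max(filtered.std(), 1e-12)  # ~10 mV modulation
    if shared_seed is not None and shared_fraction > 0:
        shared = np.random.default_rng(shared_seed).standard_normal(v.size)
    else:
        shared = np.zeros_like(v)
    private = rng.normal(0.0, 1.0, size=v.size)
    v = (
        v
        + noise_sd_mv * np.sqrt(shared_fraction) * shared
        + noise_sd_mv * np.sqrt(1.0 - shared_fraction) * private
    )
    if spike_times_s.size:
        wf = make_spike_waveform(cell_class.spike_width_us, eff_rate)
        half = wf.size // 2
        for t_spk in spike_times_s:
            k = int(round(t_spk * eff_rate))
            a, b = max(0, k - half), min(v.size, k + half + 1)
            if a < b:
                v[a:b] += wf[half - (k - a): half + (b - k)]
    return v, eff_rate


def _intrinsic_features(
    cell_class: SyntheticCellClass, rng: np.random.Generator
) -> dict[str, float]:
    """Class-dependent intrinsic features with multiplicative noise.

    Means are monotone in the class jitter SD so that, across classes,
    reliability correlates negatively with membrane tau and ramp time and
    positively with rheobase and upstroke/downstroke ratio — fixed-sign
    dependencies for recovery tests.
    """
    j = cell_class.jitter_sd_ms

    def lognoise(scale: float = 0.15) -> float:
        return float(np.exp(rng.normal(0.0, scale)))

    return {
        "membrane_tau_ms": cell_class.membrane_tau_ms * lognoise(),
        "rheobase_pa": cell_class.rheobase_pa * lognoise(),
        "upstroke_downstroke_ratio": (4.0 / (1.0 + j)) * lognoise(),
        "ramp_time_to_spike_s": (2.0 + 0.5 * j) * lognoise(),
        "capacitance_pf": (60.0 + 10.0 * j) * lognoise(),
        "conductance_ns": (8.0 / (1.0 + 0.3 * j)) * lognoise(),
    }


def simulate_population(
    classes: list[SyntheticCellClass],
    n_per_class: int,
    rng_seed: int | np.random.SeedSequence = 0,
    protocol_seeds: tuple[int, int] = (11, 23),
    sampling_rate_hz: float = 5_000.0,
    intensities: tuple[int, ...] = INTENSITIES,
    with_voltage: bool = False,
    voltage_rate_hz: float = 2_500.0,
    shared_fraction: float = 0.8,
) -> list[NeuronRecord]:
    """Simulate a population of neurons with known reliability structure.

    Per neuron: a repetition count is drawn uniformly from the class range,
    one template train is built per (noise, intensity) condition, and each
    sweep is an independently corrupted copy of the condition's template.
    All neurons see the same two frozen-noise protocols (``protocol_seeds``),
    scaled to the class rheobase.  One master ``rng_seed`` derives per-neuron
    seeds through a seed sequence, so populations are reproducible.

    With ``with_voltage=True`` the 75 % sweeps also carry synthetic voltage
    traces (shared-variance fraction ``shared_fraction``).
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    master = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    templates = {
        nid: generate_pink_noise(seed, sampling_rate_hz=sampling_rate_hz)
        for nid, seed in zip(NOISE_IDS, protocol_seeds)
    }
    records: list[NeuronRecord] = []
    neuron_seeds = master.spawn(len(classes) * n_per_class)
    k = 0
    for cls in classes:
        protocols = {
            nid: build_protocol(tpl, rheobase_pa=cls.rheobase_pa, noise_id=nid)
            for nid, tpl in templates.items()
        }
        for i in range(n_per_class):
            rng = np.random.default_rng(neuron_seeds[k])
            neuron_id = f"{cls.name}-{i:03d}"
            lo, hi = cls.n_repetitions_range
            sweep_sets: list[SweepSet] = []
            for nid in NOISE_IDS:
                protocol = protocols[nid]
                n_rep = int(rng.integers(lo, hi + 1))
                for pct in intensities:
                    seg = protocol.segment_trace(pct)
                    window = (0.0, seg.size / protocol.sampling_rate_hz)
                    template = make_template_train(
                        protocol, cls.mean_rate_hz, rng, intensity_pct=pct
                    )
                    sweeps = [
                        jitter_train(template, cls, rng, window_s=window)
                        for _ in range(n_rep)
                    ]
                    voltage = None
                    eff_rate = None
                    if with_voltage and pct == 75:
                        shared_seed = int(rng.integers(2**31))
                        out = [
                            synthesize_voltage(
                                protocol, pct, s, cls, rng,
                                sampling_rate_hz=voltage_rate_hz,
                                shared_fraction=shared_fraction,
                                shared_seed=shared_seed,
                            )
                            for s in sweeps
                        ]
                        voltage = [v for v, _ in out]
                        eff_rate = out[0][1]
                    sweep_sets.append(
                        SweepSet(
                            neuron_id=neuron_id,
                            noise_id=nid,
                            intensity_pct=pct,
                            sweeps=sweeps,
                            stimulus_window_s=window,
                            voltage=voltage,
                            sampling_rate_hz=eff_rate,
                        )
                    )
            records.append(
                NeuronRecord(
                    neuron_id=neuron_id,
                    species=cls.species,
                    morpho_type=cls.morpho_type,
                    transcriptomic_group=cls.transcriptomic_group,
                    intrinsic_features=_intrinsic_features(cls, rng),
                    sweep_sets=sweep_sets,
                    class_name=cls.name,
                )
            )
            k += 1
    return records


def write_dataset(
    records: list[NeuronRecord], out_dir: str | Path, with_voltage: bool = False
) -> Path:
    """Write a population as a JSON index plus one spikes CSV per neuron;
    with ``with_voltage=True`` voltage traces go into one HDF5 sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h5 = None
    if with_voltage:
        import h5py

        h5 = h5py.File(out_dir / "voltages.h5", "w")
    index = []
    for rec in records:
        rows = []
        for ss in rec.sweep_sets:
            for sweep_id, spikes in enumerate(ss.sweeps):
                for t in spikes:
                    rows.append((sweep_id, ss.noise_id, ss.intensity_pct, t))
        df = pd.DataFrame(
            rows, columns=["sweep_id", "noise_id", "intensity", "spike_time_s"]
        )
        csv_name = f"{rec.neuron_id}.csv"
        df.to_csv(out_dir / csv_name, index=False, float_format="%.9f")
        if h5 is not None:
            for ss in rec.sweep_sets:
                if ss.voltage is None:
                    continue
                grp = h5.create_group(
                    f"{rec.neuron_id}/{ss.noise_id}/{ss.intensity_pct}"
                )
                grp.attrs["sampling_rate_hz"] = ss.sampling_rate_hz
                for sweep_id, v in enumerate(ss.voltage):
                    grp.create_dataset(str(sweep_id), data=v, compression="gzip")
        index.append(
            {
                "neuron_id": rec.neuron_id,
                "species": rec.species,
                "morpho_type": rec.morpho_type,
                "transcriptomic_group": rec.transcriptomic_group,
                "ephys_type": rec.ephys_type,
                "class_name": rec.class_name,
                "intrinsic_features": rec.intrinsic_features,
                "spikes_csv": csv_name,
                "sweep_sets": [
                    {
                        "noise_id": ss.noise_id,
                        "intensity_pct": ss.intensity_pct,
                        "n_sweeps": ss.n_sweeps,
                        "stimulus_window_s": list(ss.stimulus_window_s),
                    }
                    for ss in rec.sweep_sets
                ],
            }
        )
    if h5 is not None:
        h5.close()
    index_path = out_dir / "index.json"
    index_path.write_text(json.dumps(index, indent=2))
    return index_path


def read_dataset(data_dir: str | Path) -> list[NeuronRecord]:
    """Read a population written by :func:`write_dataset` (voltage traces
    are loaded from the HDF5 sidecar when present)."""
    data_dir = Path(data_dir)
    index = json.loads((data_dir / "index.json").read_text())
    h5 = None
    if (data_dir / "voltages.h5").exists():
        import h5py

        h5 = h5py.File(data_dir / "voltages.h5", "r")
    records = []
    for entry in index:
        df = pd.read_csv(data_dir / entry["spikes_csv"])
        sweep_sets = []
        for meta in entry["sweep_sets"]:
            sub = df[
                (df["noise_id"] == meta["noise_id"])
                & (df["intensity"] == meta["intensity_pct"])
            ]
            sweeps = [
                np.sort(sub.loc[sub["sweep_id"] == sid, "spike_time_s"].to_numpy())
                for sid in range(meta["n_sweeps"])
            ]
            voltage = None
            rate = None
            key = f"{entry['neuron_id']}/{meta['noise_id']}/{meta['intensity_pct']}"
            if h5 is not None and key in h5:
                grp = h5[key]
                voltage = [grp[str(i)][...] for i in range(meta["n_sweeps"])]
                rate = float(grp.attrs["sampling_rate_hz"])
            sweep_sets.append(
                SweepSet(
                    neuron_id=entry["neuron_id"],
                    noise_id=meta["noise_id"],
                    intensity_pct=meta["intensity_pct"],
                    sweeps=sweeps,
                    stimulus_window_s=tuple(meta["stimulus_window_s"]),
                    voltage=voltage,
                    sampling_rate_hz=rate,
                )
            )
        records.append(
            NeuronRecord(
                neuron_id=entry["neuron_id"],
                species=entry["species"],
                morpho_type=entry["morpho_type"],
                transcriptomic_group=entry["transcriptomic_group"],
                intrinsic_features=entry["intrinsic_features"],
                sweep_sets=sweep_sets,
                ephys_type=entry["ephys_type"],
                class_name=entry["class_name"],
            )
        )
    if h5 is not None:
        h5.close()
    return records
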