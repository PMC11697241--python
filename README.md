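# spikerel

Spike-timing reliability analysis for frozen-noise current-clamp
recordings, with a downstream-neuron simulation.

When the same "frozen" noise current is injected repeatedly into a neuron,
some cell types (notably parvalbumin-positive interneurons) repeat their
spike times with millisecond precision while others do not. `spikerel`
implements the full analysis pipeline for quantifying this:

* **Stimulus generation** — pink-noise templates (sum of 1/√f-weighted
  sinusoids, 1–100 Hz, CV 0.2), concatenated 3 × 1 s and scaled to
  75/100/150 % of each neuron's rheobase with 5 s recovery gaps.
* **Reliability metrics** — for each pair of repetitions, the fraction of
  spikes matched within a 1 ms window, averaged over all ordered pairs:

      R_raw = mean over pairs (i,j), i≠j of  #{t ∈ s_i : min_{t'∈s_j} |t−t'| ≤ w} / |s_i|

  corrected for firing rate by subtracting the same statistic on 100
  surrogate sweep sets with spike counts preserved and spike times redrawn
  uniformly in the stimulus window:

      R = R_raw − mean_k R_shuffled^(k)

  plus nearest-spike latency CDFs and subthreshold reliability (mean
  pairwise Spearman ρ of 75 %-rheobase voltage traces).
* **Cell typing** — spike width at half amplitude from the averaged
  waveform; fast vs regular spiking at the 400 µs boundary; transcriptomic
  line → group mapping (PV / non-PV inhibitory / mixed / excitatory).
* **Downstream model** — an Izhikevich neuron receiving N delta-current
  inputs with Gaussian timing jitter σ; sweeps of σ and N measure
  inhibition depth (inhibitory volleys) and spike count (excitatory).
* **Synthetic populations** — simulated neurons with known jitter /
  deletion / extra-spike structure emulating the repeated-sweep layout of
  the Allen Cell Types dataset, so every estimator is testable by
  parameter recovery.
* **Reports** — Kruskal-Wallis + pairwise KS group comparisons, Spearman
  feature correlations, species × type two-way ANOVA, CDF and boxplot
  figures.

## Worked example

```python
import numpy as np
from spikerel import (
    generate_pink_noise, build_protocol, corrected_reliability,
)
from spikerel.synthetic_data import PV_LIKE, EXCITATORY_LIKE, simulate_population
from spikerel.report import build_reliability_table, compare_groups

records = simulate_population([PV_LIKE, EXCITATORY_LIKE], 30, rng_seed=7)
table = build_reliability_table(records, intensity_pct=100,
                                n_permutations=100, rng_seed=1)
print(table.groupby("class_name")[["raw", "shuffled_mean", "corrected"]].mean())
res = compare_groups(table, "class_name")
print(f"Kruskal-Wallis H = {res.statistic_value:.1f}, p = {res.p_value:.2e}")
```

prints

```
                      raw  shuffled_mean  corrected
class_name
PV-like          0.919511       0.028821   0.890690
excitatory-like  0.109216       0.015222   0.093994
Kruskal-Wallis H = 44.3, p = 2.87e-11
```

The PV-like class (0.2 ms spike-time jitter) recovers a corrected
reliability of ≈ 0.89 — nearly every spike is repeated within 1 ms across
sweeps, far above its ≈ 0.03 chance level — while the excitatory-like
class (5 ms jitter) recovers ≈ 0.09, and the omnibus test separates the
two decisively.

The downstream simulation:

```python
from spikerel.downstream_model import IzhikevichParams, sweep_sigma
print(sweep_sigma(IzhikevichParams(), "inhibitory", n_iter=500, rng_seed=1))
```

```
   sigma_ms       mean        sd  n_iter              measure
0       0.0  40.000000  0.000000     500  inhibition_depth_mv
1      10.0   6.076449  1.222073     500  inhibition_depth_mv
2      50.0   3.712419  0.697025     500  inhibition_depth_mv
```

A synchronous inhibitory volley (σ = 0, like highly reliable PV input)
hyperpolarizes the downstream neuron 40 mV deep; jittering the same inputs
by 10 or 50 ms collapses the depth to ~6 and ~4 mV.

A CLI mirrors the library (`spikerel stimulus|synth|reliability|celltype|
model|report --help`).

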