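"""Group statistics, feature correlations and summary figures.

These routines are deliberately thin glue around standard statistical
machinery (Kruskal-Wallis, pairwise two-sample Kolmogorov-Smirnov, Spearman
correlation, two-way ANOVA): the bespoke quantity they operate on is the
firing-rate-corrected reliability from :mod:`spikerel.metrics`.  Because no
multiple-testing correction is prescribed for the pairwise tests, both raw
and Holm-adjusted p-values are reported, clearly labelled.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from spikerel.metrics import (
    InsufficientRepetitionsError,
    corrected_reliability,
    pooled_latencies,
)

__all__ = [
    "GroupComparison",
    "build_reliability_table",
    "compare_groups",
    "feature_correlations",
    "species_type_anova",
    "plot_latency_cdfs",
    "plot_reliability_boxplots",
]

FEATURES = (
    "membrane_tau_ms",
    "rheobase_pa",
    "upstroke_downstroke_ratio",
    "ramp_time_to_spike_s",
    "capacitance_pf",
    "conductance_ns",
)


@dataclass
class GroupComparison:
    """Omnibus + pairwise comparison of corrected reliability across groups."""

    grouping: str
    statistic_name: str
    statistic_value: float
    p_value: float
    group_medians: dict[str, float]
    n_per_group: dict[str, int]
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_reliability_table(
    records,
    intensity_pct: int = 100,
    window_ms: float = 1.0,
    n_permutations: int = 100,
    rng_seed: int | np.random.SeedSequence = 0,
    collect_latencies: bool = False,
) -> pd.DataFrame:
    """Per-neuron corrected reliability at one intensity.

    Reliability is computed per (noise, intensity) sweep set and averaged
    across the two noises per neuron.  Neurons with no usable sweep set at
    the requested intensity are dropped.  Annotations and intrinsic features
    are carried along as columns.
    """
    master = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    rows = []
    seeds = master.spawn(len(records))
    for rec, seed in zip(records, seeds):
        raws, shuf, corr, n_pairs, pooled = [], [], [], 0, []
        for ss in rec.sweep_sets:
            if ss.intensity_pct != intensity_pct:
                continue
            try:
                res = corrected_reliability(
                    ss, window_ms=window_ms, n_permutations=n_permutations,
                    rng_seed=seed,
                )
            except InsufficientRepetitionsError:
                continue
            raws.append(res.raw_reliability)
            shuf.append(res.shuffled_mean)
            corr.append(res.corrected_reliability)
            n_pairs += res.n_pairs
            if collect_latencies:
                pooled.append(res.latencies_s)
        if not corr:
            continue
        row = {
            "neuron_id": rec.neuron_id,
            "species": rec.species,
            "morpho_type": rec.morpho_type,
            "transcriptomic_group": rec.transcriptomic_group,
            "ephys_type": rec.ephys_type,
            "class_name": rec.class_name,
            "window_ms": window_ms,
            "raw": float(np.mean(raws)),
            "shuffled_mean": float(np.mean(shuf)),
            "corrected": float(np.mean(corr)),
            "n_pairs": n_pairs,
        }
        row.update(rec.intrinsic_features)
        if collect_latencies:
            row["latencies_s"] = np.concatenate(pooled) if pooled else np.empty(0)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame, grouping: str, value: str = "corrected"
) -> GroupComparison:
    """Kruskal-Wallis omnibus test plus all pairwise two-sample KS tests on
    corrected reliability across the levels of ``grouping``."""
    groups = {
        name: sub[value].to_numpy()
        for name, sub in table.groupby(grouping, observed=True)
        if len(sub) >= 2
    }
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 groups with >= 2 neurons each, got {len(groups)}"
        )
    names = sorted(groups)
    stat, p = stats.kruskal(*(groups[n] for n in names))
    pair_rows = []
    for a, b in itertools.combinations(names, 2):
        ks = stats.ks_2samp(groups[a], groups[b])
        pair_rows.append(
            {"group_a": a, "group_b": b, "ks_statistic": ks.statistic, "p_raw": ks.pvalue}
        )
    pairwise = pd.DataFrame(pair_rows)
    if len(pairwise):
        pairwise["p_holm"] = multipletests(pairwise["p_raw"], method="holm")[1]
    return GroupComparison(
        grouping=grouping,
        statistic_name="kruskal_wallis_H",
        statistic_value=float(stat),
        p_value=float(p),
        group_medians={n: float(np.median(groups[n])) for n in names},
        n_per_group={n: int(groups[n].size) for n in names},
        pairwise=pairwise,
    )


def feature_correlations(
    table: pd.DataFrame,
    features: tuple[str, ...] = FEATURES,
    value: str = "corrected",
) -> pd.DataFrame:
    """Spearman correlation of corrected reliability with each intrinsic
    feature; all-missing features are skipped with a warning."""
    rows = []
    for feat in features:
        if feat not in table.columns:
            warnings.warn(f"feature {feat!r} missing, skipped", stacklevel=2)
            continue
        sub = table[[value, feat]].dropna()
        if len(sub) < 3:
            warnings.warn(f"feature {feat!r} has < 3 paired values, skipped", stacklevel=2)
            continue
        res = stats.spearmanr(sub[value], sub[feat])
        rows.append({"feature": feat, "rho": float(res.statistic), "p": float(res.pvalue), "n": len(sub)})
    return pd.DataFrame(rows)


def species_type_anova(
    table: pd.DataFrame,
    type_column: str = "ephys_type",
    value: str = "corrected",
) -> pd.DataFrame:
    """Two-way ANOVA of corrected reliability on species x cell type.

    Returns the type-II ANOVA table with F statistics and p-values for both
    main effects and the interaction.
    """
    for factor in ("species", type_column):
        levels = table[factor].dropna().unique()
        if len(levels) < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels, got {list(levels)}")
    df = table.rename(columns={value: "y", type_column: "cell_type"})
    model = smf.ols("y ~ C(species) * C(cell_type)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def plot_latency_cdfs(
    table: pd.DataFrame,
    grouping: str,
    grid_ms: np.ndarray | None = None,
    ax=None,
):
    """Empirical CDF of pooled nearest-spike latencies per group (requires a
    table built with ``collect_latencies=True``)."""
    import matplotlib.pyplot as plt
    from spikerel.metrics import latency_cdf

    if "latencies_s" not in table.columns:
        raise ValueError("table lacks pooled latencies; rebuild with collect_latencies=True")
    if grid_ms is None:
        grid_ms = np.linspace(0.0, 50.0, 501)
    if ax is None:
        _, ax = plt.subplots()
    for name, sub in table.groupby(grouping, observed=True):
        lat = np.concatenate([v for v in sub["latencies_s"] if len(v)])
        if lat.size == 0:
            continue
        ax.plot(grid_ms, latency_cdf(lat * 1e3, grid_ms), label=str(name))
    ax.set_xlabel("nearest-spike latency (ms)")
    ax.set_ylabel("cumulative probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title=grouping)
    return ax


def plot_reliability_boxplots(table: pd.DataFrame, grouping: str, ax=None):
    """Boxplots of corrected reliability by group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = sorted(table[grouping].dropna().unique())
    data = [table.loc[table[grouping] == n, "corrected"] for n in names]
    ax.boxplot(data, tick_labels=[str(n) for n in names], sym="+")
    ax.set_ylabel("corrected reliability")
    ax.set_xlabel(grouping)
    return ax
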