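"""Monte-Carlo calibration experiments on scaled-down synthetic cohorts.

Two questions the pipeline must answer correctly before it is trusted on
real data:

* **Type-I error** — on null cohorts where both groups share identical
  connectivity dynamics, how often does the group test reject at alpha?
* **Effect recovery** — when one group's state-switching rate is halved
  (the generator's encoding of a reduced repertoire of dynamic network
  states), how often is the induced *dynamic* (CV) group difference
  detected, and does the *static* (mean) summary stay quiet?

Both experiments run the full pipeline (simulate -> windowed Spearman FC
-> binarize -> graph metric -> summaries -> group test) on scaled-down
cohorts: 8 ROIs in two 4-ROI networks, 5 s epochs at 250 Hz, 2000 ms
windows with 75% overlap (7 windows per epoch), the default 6-threshold
sweep, and mean degree of the all-ROI network as the probe metric.  The
state repertoire is made deliberately coarse (3 states, within-network
correlation spread +/-0.3, mean dwell 2.5 s) so that 5 s epochs carry a
usable dynamic signature; the type-I experiment uses 2 epochs per
participant (test calibration does not depend on epoch count), the
recovery experiment the full 20 epochs the emulated design provides.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fc import SlidingWindowConnectivity
from .graph import GraphMetricsExtractor
from .networks import NetworkDefinition
from .stats import GroupThresholdAnova
from .summarize import WindowSummarizer
from .synth import CohortSpec, null_state_params, simulate_cohort, with_switch_rate

#: scaled study conditions used by the calibration experiments
SMALL_ROI_COUNT = 8
SMALL_EPOCH_S = 5.0
SMALL_FS_HZ = 250.0
SMALL_WINDOW_MS = 2000.0
SMALL_OVERLAP = 0.75
NULL_EPOCHS_PER_CONDITION = 2
RECOVERY_EPOCHS_PER_CONDITION = 20
PROBE_METRIC = "degree"
PROBE_NETWORK = "brain"
#: coarse state repertoire for the 5 s scaled epochs
SMALL_STATE_KW = dict(n_states=3, rho_jitter=0.3, mean_dwell_s=2.5)


def scaled_cohort_summary(
    seed: int,
    n_per_group: int,
    sz_switch_scale: float,
    epochs_per_condition: int = NULL_EPOCHS_PER_CONDITION,
) -> pd.DataFrame:
    """Simulate one scaled cohort and carry it to participant summaries."""
    net = NetworkDefinition.evenly_partitioned(SMALL_ROI_COUNT, names=("netA", "netB"))
    params = null_state_params(conditions=("OT",), **SMALL_STATE_KW)
    if sz_switch_scale != 1.0:
        params = with_switch_rate(params, "SZ", sz_switch_scale)
    spec = CohortSpec(
        network_map=net,
        n_per_group=n_per_group,
        conditions=("OT",),
        epochs_per_condition=epochs_per_condition,
        epoch_duration_s=SMALL_EPOCH_S,
        sampling_rate_hz=SMALL_FS_HZ,
        state_params=params,
        seed=seed,
    )
    epochs, _ = simulate_cohort(spec)
    fc = SlidingWindowConnectivity(SMALL_WINDOW_MS, SMALL_OVERLAP).transform(epochs)
    metrics = (
        GraphMetricsExtractor(net, networks=(PROBE_NETWORK,), metrics=(PROBE_METRIC,))
        .fit()
        .transform(fc)
    )
    return WindowSummarizer().fit().transform(metrics)


def _group_p(summary: pd.DataFrame, engine: str, seed: int,
             summary_type: str, n_perm: int) -> float:
    anova = GroupThresholdAnova(
        engine=engine,
        n_perm=n_perm,
        summary_types=(summary_type,),
        random_state=seed,
    ).fit(summary)
    rows = anova.results_
    row = rows[rows["effect"] == "group"]
    return float(row["p_value"].iloc[0])


@dataclass
class RejectionRates:
    """Fraction of replicates with group-effect p < alpha, per engine."""

    mixed: float
    permutation: float
    n_replicates: int
    alpha: float


def null_rejection_rates(
    n_cohorts: int = 200,
    seed: int = 0,
    n_per_group: int = 10,
    alpha: float = 0.05,
    n_perm: int = 199,
    summary_type: str = "dynamic",
) -> RejectionRates:
    """Type-I error of the group test on null cohorts (identical state
    parameters in both groups), for both inference engines."""
    rej = {"mixed": 0, "permutation": 0}
    base = int(seed) % (2**20)
    for r in range(n_cohorts):
        cohort_seed = base * 1000 + r
        summary = scaled_cohort_summary(cohort_seed, n_per_group, sz_switch_scale=1.0)
        for engine in rej:
            p = _group_p(summary, engine, cohort_seed, summary_type, n_perm)
            rej[engine] += p < alpha
    return RejectionRates(
        mixed=rej["mixed"] / n_cohorts,
        permutation=rej["permutation"] / n_cohorts,
        n_replicates=n_cohorts,
        alpha=alpha,
    )


@dataclass
class EffectRecovery:
    """Detection rates when one group's switching rate is scaled down."""

    dynamic_detection_rate: float  # group effect found on the CV summary
    dynamic_lower_rate: float  # ... with the scaled group's CV being lower
    static_rejection_rate: float  # false alarms on the static summary
    n_replicates: int
    alpha: float


def switch_rate_recovery(
    n_cohorts: int = 200,
    seed: int = 0,
    n_per_group: int = 14,
    sz_switch_scale: float = 0.5,
    alpha: float = 0.05,
) -> EffectRecovery:
    """Parameter recovery: halving one group's state-switching rate should
    lower its dynamic CV (detected by the mixed-model group test) while the
    static mean stays unaffected."""
    dyn_hits = 0
    dyn_lower = 0
    stat_hits = 0
    base = int(seed) % (2**20)
    for r in range(n_cohorts):
        cohort_seed = base * 1000 + 500_000 + r
        summary = scaled_cohort_summary(
            cohort_seed, n_per_group, sz_switch_scale,
            epochs_per_condition=RECOVERY_EPOCHS_PER_CONDITION,
        )
        p_dyn = _group_p(summary, "mixed", cohort_seed, "dynamic", n_perm=199)
        p_stat = _group_p(summary, "mixed", cohort_seed, "static", n_perm=199)
        means = summary.groupby("group")["dynamic_cv"].mean()
        lower = means["SZ"] < means["HC"]
        if p_dyn < alpha:
            dyn_hits += 1
            dyn_lower += bool(lower)
        stat_hits += p_stat < alpha
    return EffectRecovery(
        dynamic_detection_rate=dyn_hits / n_cohorts,
        dynamic_lower_rate=dyn_lower / max(dyn_hits, 1),
        static_rejection_rate=stat_hits / n_cohorts,
        n_replicates=n_cohorts,
        alpha=alpha,
    )
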