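# dynconn

Static and dynamic graph-theoretic functional-connectivity analysis of
task-based, source-parcellated EEG — from ROI time series to group-level
statistics — plus a synthetic cohort generator so the whole pipeline is
testable end to end without access to clinical recordings.

## Who this is for

Researchers comparing brain-network organization between groups (e.g.
patients with schizophrenia vs. healthy controls) across attentional
conditions (mind wandering vs. on task), who want both the *time-averaged*
("static") and the *time-varying* ("dynamic") view of functional
connectivity, and who need every methodological convention — window
plans, threshold tie rules, disconnected-graph conventions, CV
denominators, FDR families — pinned down and tested.

## The method

For each epoch (50 s of ROI time series at 500 Hz by default):

1. **Sliding-window FC** — windows of 2000 ms with 90% overlap (241
   windows per epoch); within each window the Spearman rank correlation
   ρ between every ROI pair.
2. **Binarization sweep** — unweighted undirected graphs with an edge
   iff ρ > τ, for τ ∈ {0.1, …, 0.6}; negative correlations never form
   edges.
3. **Ten graph measures** per window, threshold and network (DMN, DAN,
   SAN, VIS, and "brain" = all ROIs): clustering coefficient,
   transitivity; global efficiency, characteristic path length; degree,
   betweenness, eccentricity, diameter; assortativity, k-core coreness.
4. **Summaries** per participant × condition × network × threshold ×
   metric: static = mean over windows, dynamic = CV = (σ/μ)·100 over
   windows (sample σ), averaged across a participant's epochs.
5. **Inference** — REML mixed model
   `value ~ group * threshold + (1 | participant)` per condition,
   network, metric and summary type; estimated-marginal-mean group
   contrasts at each threshold; Benjamini–Hochberg FDR; a
   participant-level permutation test as nonparametric cross-check. A
   cell is "significant" (diamond rule) when ≥ 1 threshold's adjusted
   contrast clears α = 0.05.

The synthetic generator draws each epoch from a latent Markov repertoire
of connectivity states; a *reduced state-switching rate* in the simulated
patient group lowers window-to-window variability (the dynamic CV)
without shifting time-averaged connectivity — so static and dynamic
indicators are dissociable by construction. See `docs/methods.md` for
the model, conventions and limitations.

## Worked example

Simulate a scaled cohort (14 participants/group, one condition, 20 five-
second epochs each, 8 ROIs in two networks) in which the patient group's
state-switching rate is halved, and test for group differences:

```python
from dynconn.calibration import scaled_cohort_summary
from dynconn.stats import GroupThresholdAnova

summary = scaled_cohort_summary(seed=42, n_per_group=14, sz_switch_scale=0.5,
                                epochs_per_condition=20)
model = GroupThresholdAnova(engine="mixed").fit(summary)
print(model.results_[model.results_.effect == "group"]
      [["metric", "summary_type", "statistic", "p_value"]].round(4))
print(summary.groupby("group")[["static_mean", "dynamic_cv"]].mean().round(3))
```

```
metric summary_type  statistic  p_value
degree       static     0.5563   0.4624
degree      dynamic    18.1936   0.0002

       static_mean  dynamic_cv
group
HC           2.213      32.802
SZ           2.233      25.247
```

The halved switching rate shows up exactly where it should: the
simulated patients' dynamic CV of mean degree is lower (25.2 vs 32.8,
group F = 18.2, p = 0.0002) while static mean degree is indistinguishable
(2.23 vs 2.21, p = 0.46). The per-threshold post hoc contrasts
(`model.posthoc_`) localize the dynamic effect to the sparser
high-threshold graphs.

The same pipeline runs from the shell:

```bash
dynconn simulate --out epochs/ --seed 1
dynconn run-all --config cohort.yaml --out results/ --seed 1
```

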