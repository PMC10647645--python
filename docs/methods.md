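# Methods

`dynconn` implements a static-versus-dynamic graph-theoretic analysis of
task-based, source-parcellated EEG: ROI time series are cut into sliding
windows, each window's Spearman correlation matrix is binarized over a
sweep of thresholds, ten graph measures are computed per window and
network, and each measure is summarized per participant as a *static*
indicator (the mean across windows) and a *dynamic* indicator (the
coefficient of variation across windows) before group-level mixed-model
inference. Because the clinical recordings the design targets are not
publicly deposited, the package ships a synthetic cohort generator that
serves as first-class, tested code: every downstream stage is exercised
end to end against cohorts with known ground truth.

## Pipeline model

**Windowing.** An epoch of `n` samples at rate `fs` is covered by
half-open, 0-based windows `[i*step, i*step + w)` with
`w = round(window_ms * fs / 1000)` and
`step = round(w * (1 - overlap))`; trailing samples that do not fill a
window are dropped. The defaults (2000 ms, 90% overlap) give `w = 1000`,
`step = 100` and exactly 241 windows for a 50 s epoch at 500 Hz. Window
length trades temporal resolution against correlation estimation noise
(the standard error of a window correlation scales roughly as
`1/sqrt(w)`).

**Functional connectivity.** Within each window, FC is the Spearman rank
correlation (midranks on ties) between every ROI pair, computed once over
all ROIs and restricted to networks by principal submatrix — identical to
per-network computation because Spearman is pairwise. An ROI with zero
variance inside a window yields NaN for its pairs; the value is logged,
never an edge, and the epoch is retained.

**Binarization.** An edge exists iff `rho > tau` (strict inequality, a
deterministic tie rule; ties have measure zero in real data). Negative
and NaN correlations never form edges. The sweep uses
`tau in {0.1, ..., 0.6}` so that results are not hostage to a single
arbitrary cutoff; edge sets are nested across increasing `tau` by
construction.

**Graph measures.** Ten binary undirected measures in four families:
segregation (mean nodal clustering coefficient, transitivity),
integration (global efficiency, characteristic path length), centrality
(mean degree, mean unnormalized betweenness, mean eccentricity,
diameter), resilience (degree assortativity, mean k-core coreness). All
are authored from first principles (level-synchronous BFS, Brandes
betweenness, minimum-degree peeling for coreness) and verified against
independent brute-force oracles and a general-purpose graph library in
the test suite. Low thresholds on small networks disconnect graphs
routinely, so the disconnection conventions are explicit:

* characteristic path length averages finite distances only and is NaN
  when no pair of distinct nodes is reachable;
* efficiency counts unreachable pairs as 0 (`1/inf`);
* eccentricity is the largest finite distance from a node (0 when
  isolated); the diameter is the largest eccentricity;
* assortativity is NaN for edgeless or regular graphs (zero end-degree
  variance);
* nodes of degree < 2 contribute clustering 0 and stay in the mean;
* betweenness is unnormalized — the constant would cancel in group
  contrasts.

Nodal measures are reduced to one network value by the mean; `max` and
`sum` reductions exist as options but are non-default. The reported
results cannot adjudicate these conventions, which is why each is pinned
by tests rather than inferred.

**Summaries.** For each (participant, condition, network, threshold,
metric): static = mean of the metric across windows, dynamic =
`CV = (sigma/mu) * 100` across windows, with the sample (n−1) standard
deviation (a population-σ switch exists for sensitivity analysis).
`|mu| < 1e-12` yields NaN rather than an infinity so downstream models
drop the cell explicitly. The default computes both indicators within
each epoch and averages across a participant's epochs of the same
condition; a pooled mode (one CV over all windows of all epochs) is
available, but note that pooling deliberately mixes between-epoch state
differences into the CV and therefore dilutes slow-switching effects.

**Inference.** Per (condition, network, metric) and summary type, a REML
linear mixed model `value ~ group * threshold + (1 | participant)` with
threshold categorical (6 levels). Fixed effects are tested by
Type-III-style Wald F (sum coding) with containment denominator degrees
of freedom — between-participant effect: `N − g`; within effects:
`(N − g)(T − 1)` — which reduces to the classical split-plot ANOVA in the
balanced case and keeps the group test honest at small `N` where a
residual-df Wald test would be anticonservative. Post hoc group
contrasts at each threshold are estimated-marginal-mean differences from
the fitted fixed effects. A participant-level permutation test (group
labels permuted across participants, each participant's threshold profile
kept intact; exact enumeration when the label assignments number fewer
than `n_perm`) is the nonparametric cross-check and the automatic
fallback for singular mixed fits. Multiple testing uses
Benjamini–Hochberg FDR within each (condition, summary type) stratum;
post hoc contrasts are adjusted across thresholds within a cell by
default (a whole-stratum mode exists — the appropriate family is a
judgment call, so both are exposed). The "diamond" indicator marks a
(network, metric, summary) cell significant when at least one threshold's
adjusted contrast falls below alpha. Static and dynamic responses, and
the two attentional conditions, are modeled separately.

## Synthetic cohort generator

The generator emulates the target study design: two groups (SZ patients
and HC controls, 20 participants each by default), two attentional
conditions (mind wandering, on task), up to 20 clean 50 s epochs per
participant at 500 Hz, and a whole-cortex 68-ROI parcellation whose ROIs
are partitioned into DMN/DAN/SAN/VIS by a shipped, editable mapping (the
"brain" network is always the union). Every epoch is a pure function of
`(master seed, participant, condition, epoch index)`, so cohorts are
bit-reproducible under partial regeneration.

**Generative model.** A latent repertoire of connectivity states: state
`s` is a unit-diagonal correlation matrix with within-network blocks at
`within_network_rho + offset(s, network)` and cross-network entries at
`between_network_rho`. The offsets spread evenly over
`[-rho_jitter, +rho_jitter]` in a per-network shuffled order, so the
repertoire always contains genuinely distinct states; matrices failing a
PSD check are shrunk toward the identity (hard error after 200
iterations). The state sequence is a Markov chain at sample resolution
with exponential dwell times of mean
`mean_dwell_s / switch_rate_scale`; emissions are IID Gaussian draws from
the active state's covariance plus white noise of SD `noise_sd`. Defaults:
4 states, within 0.6, between 0.1, dwell 2 s, jitter 0.2, noise 0.5.

**Effect injection.** The simulated patient group differs only in
`switch_rate_scale` (0.5 by default): slower switching means each epoch
visits fewer states, lowering window-to-window metric variability — the
dynamic CV — while leaving time-averaged connectivity nearly unchanged.
Mean-level group effects are deliberately not injected, so static and
dynamic summaries are dissociable and a pipeline that confuses them fails
the tests.

**What the generator does not emulate.** No raw-sensor EEG, forward or
inverse modeling, 1/f spectra, within-state temporal autocorrelation,
volume conduction, or artifacts. Passing tests therefore demonstrate that
the pipeline recovers connectivity-dynamics effects from parcellated time
series under the stated generative model — not that source
reconstruction or artifact removal on real recordings is correct.

## Calibration experiments (scaled study conditions)

The `calibration` module answers two questions by full pipeline runs on
scaled-down cohorts, with every stage identical to the production path:

* conditions: 8 ROIs in two 4-ROI networks, 5 s epochs at 250 Hz,
  2000 ms windows at 75% overlap (7 windows/epoch), the 6-threshold
  sweep, mean degree of the all-ROI network as probe metric, one
  condition. The state repertoire is coarsened for 5 s epochs (3 states,
  jitter 0.3, dwell 2.5 s) so that short epochs carry a usable dynamic
  signature.
* **Type-I error**: null cohorts with identical group dynamics, 10
  participants/group, 2 epochs each (test calibration does not depend on
  epoch count); rejection rates of both engines should sit near alpha.
* **Effect recovery**: one group's switching rate halved, 20 epochs per
  participant (the emulated design's full segment count) and 14
  participants/group — a size chosen by power analysis so the injected
  effect is detected in well over 80% of replicates while the static
  channel stays near the false-alarm floor.

The probe metric, window plan and cohort sizes here are the package's
scaled study conditions; they were fixed during generator design, before
freezing the test suite, and are not tuning knobs.

## Numerical choices and degenerate inputs

* PSD tolerance 1e-10 with 5% shrinkage steps; Cholesky factors get a
  1e-9 diagonal bump.
* Spearman via rank transform + correlation of ranks; values clipped to
  [−1, 1]; NaN propagation as absent edges.
* Constant responses, all-NaN cells, and singular mixed fits are
  skipped/fallen back with logging, never silently imputed.
* Permutation p-values use the add-one estimator
  `(1 + #{perm >= obs}) / (1 + n_perm)` with a 1e-9 relative tolerance in
  the comparison so label-swapped assignments count as ties.
* The CV guard (`|mu| < 1e-12 -> NaN`) keeps signed near-zero means from
  producing explosive CVs.

## Known limitations

* Sampling noise in short windows inflates every CV; dynamic indicators
  are therefore comparable only across groups measured under the same
  window plan, not as absolute quantities.
* The mixed model assumes exchangeable participants and a random
  intercept only; threshold-specific participant slopes are not modeled.
* Between-threshold responses are strongly dependent (nested edge sets),
  so per-threshold post hoc tests are correlated; FDR is applied, but the
  contrasts are not independent evidence.
* The generator's Gaussian, temporally-white emissions understate the
  autocorrelation of real EEG; effective sample sizes per window are
  optimistic relative to real recordings.
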