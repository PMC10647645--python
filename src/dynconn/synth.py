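"""Synthetic cohorts of parcellated ROI time series.

The generator emulates the study design the pipeline is built for: two
groups (patients ``SZ`` and healthy controls ``HC``), two attentional
conditions (mind wandering ``MW`` and on task ``OT``), up to 20 clean
50 s epochs per participant sampled at 500 Hz, parcellated into ROIs that
belong to named functional networks.

The generative model is a latent Markov chain over a small repertoire of
connectivity *states*: each state is a correlation matrix with elevated
within-network and low between-network correlation (state-specific jitter
makes the states distinct), dwell times are exponential, and samples are
Gaussian draws from the active state's covariance plus white noise.
Group and condition effects are injected through the state-switching rate:
a reduced ``switch_rate_scale`` lengthens dwell times, so each epoch visits
fewer states and the window-to-window variability of functional
connectivity (the "dynamic" CV indicator downstream) drops, while
time-averaged ("static") connectivity is approximately unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .networks import NetworkDefinition, default_network_map

logger = logging.getLogger(__name__)

_PSD_TOL = 1e-10
_MAX_SHRINK_ITER = 200


@dataclass(frozen=True)
class ConnectivityStateParams:
    """Parameters of the latent connectivity-state repertoire for one
    group x condition cell.

    Parameters
    ----------
    n_states
        Number of latent connectivity states.
    within_network_rho
        Target correlation between ROIs of the same network, in [0, 1).
    between_network_rho
        Baseline correlation between ROIs of different networks.
    mean_dwell_s
        Mean state dwell time in seconds at ``switch_rate_scale == 1``.
    switch_rate_scale
        Multiplier on the state-switching rate; effective mean dwell is
        ``mean_dwell_s / switch_rate_scale``.  Values below 1 produce fewer
        state transitions per epoch (the simulated patient effect).
    noise_sd
        Standard deviation of additive white measurement noise.
    rho_jitter
        Half-width of the uniform state-specific perturbation applied to
        each network's within-network correlation, making states distinct.
    """

    n_states: int = 4
    within_network_rho: float = 0.6
    between_network_rho: float = 0.1
    mean_dwell_s: float = 2.0
    switch_rate_scale: float = 1.0
    noise_sd: float = 0.5
    rho_jitter: float = 0.15

    def __post_init__(self):
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if not (0.0 <= self.between_network_rho <= self.within_network_rho < 1.0):
            raise ValueError(
                "require 0 <= between_network_rho <= within_network_rho < 1, got "
                f"between={self.between_network_rho}, within={self.within_network_rho}"
            )
        if self.mean_dwell_s <= 0:
            raise ValueError("mean_dwell_s must be positive")
        if self.switch_rate_scale <= 0:
            raise ValueError("switch_rate_scale must be positive")
        if self.noise_sd < 0 or self.rho_jitter < 0:
            raise ValueError("noise_sd and rho_jitter must be non-negative")


def default_state_params() -> dict[tuple[str, str], ConnectivityStateParams]:
    """Default per-(group, condition) state parameters.

    The patient group's switching rate is halved in both conditions, which
    is the generator's encoding of a reduced repertoire of dynamic network
    states; controls keep the baseline rate.
    """
    hc = ConnectivityStateParams(switch_rate_scale=1.0)
    sz = ConnectivityStateParams(switch_rate_scale=0.5)
    return {
        ("SZ", "MW"): sz,
        ("SZ", "OT"): sz,
        ("HC", "MW"): hc,
        ("HC", "OT"): hc,
    }


@dataclass(frozen=True)
class RoiEpoch:
    """One recording segment: an ROI x sample matrix plus metadata."""

    participant_id: str
    group: str
    condition: str
    roi_labels: tuple[str, ...]
    data: np.ndarray
    sampling_rate_hz: float
    epoch_index: int = 0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("epoch data must be a 2-D ROI x sample matrix")
        if data.shape[0] != len(self.roi_labels):
            raise ValueError(
                f"data has {data.shape[0]} rows but {len(self.roi_labels)} ROI labels"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("epoch data contains non-finite values")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; the cohort is a pure
    function of this object (including ``seed``)."""

    network_map: NetworkDefinition = field(default_factory=default_network_map)
    n_per_group: int = 20
    groups: tuple[str, str] = ("SZ", "HC")
    conditions: tuple[str, ...] = ("MW", "OT")
    epochs_per_condition: int = 10
    epoch_duration_s: float = 50.0
    sampling_rate_hz: float = 500.0
    state_params: Mapping[tuple[str, str], ConnectivityStateParams] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.epochs_per_condition < 1:
            raise ValueError("epochs_per_condition must be >= 1")
        n_samples = self.epoch_duration_s * self.sampling_rate_hz
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError(
                "epoch_duration_s x sampling_rate_hz must be an integer sample count, "
                f"got {n_samples}"
            )
        if self.state_params is None:
            object.__setattr__(self, "state_params", self._default_params())
        missing = [
            (g, c)
            for g in self.groups
            for c in self.conditions
            if (g, c) not in self.state_params
        ]
        if missing:
            raise ValueError(f"state_params missing cells: {missing}")

    def _default_params(self) -> dict[tuple[str, str], ConnectivityStateParams]:
        base = default_state_params()
        out = {}
        for g in self.groups:
            for c in self.conditions:
                # unseen labels inherit the healthy-control baseline
                out[(g, c)] = base.get((g, c), ConnectivityStateParams())
        return out

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return self.network_map.roi_labels

    @property
    def roi_count(self) -> int:
        return len(self.roi_labels)

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration_s * self.sampling_rate_hz))

    @property
    def participant_ids(self) -> list[str]:
        return [
            f"{g}{i + 1:02d}" for g in self.groups for i in range(self.n_per_group)
        ]


def build_state_covariances(
    params: ConnectivityStateParams, network_map: NetworkDefinition
) -> list[np.ndarray]:
    """Construct one unit-diagonal PSD correlation matrix per latent state.

    Within-network blocks sit near ``within_network_rho`` with a
    deterministic state-specific jitter; cross-network entries sit at
    ``between_network_rho``.  Matrices failing a positive-semi-definiteness
    check are shrunk toward the identity until PSD.
    """
    labels = network_map.roi_labels
    n = len(labels)
    membership = np.array(
        [list(network_map.names).index(network_map.network_of(r)) for r in labels]
    )
    n_nets = len(network_map.names)
    # deterministic state-specific jitter: per network, the states receive an
    # even spread of within-network correlation offsets in a shuffled order,
    # so the repertoire is guaranteed to contain genuinely distinct states
    jitter_rng = np.random.default_rng([0x5EED, params.n_states, n_nets])
    if params.n_states > 1:
        offsets = np.linspace(-1.0, 1.0, params.n_states) * params.rho_jitter
    else:
        offsets = np.zeros(1)
    perm = np.stack(
        [jitter_rng.permutation(params.n_states) for _ in range(n_nets)]
    )
    covs = []
    for s in range(params.n_states):
        rho = np.full((n, n), params.between_network_rho)
        for k in range(n_nets):
            idx = np.where(membership == k)[0]
            r = params.within_network_rho + offsets[perm[k, s]]
            r = float(np.clip(r, params.between_network_rho, 0.995))
            rho[np.ix_(idx, idx)] = r
        np.fill_diagonal(rho, 1.0)
        covs.append(_make_psd(rho, state=s))
    return covs


def _make_psd(cov: np.ndarray, state: int) -> np.ndarray:
    for _ in range(_MAX_SHRINK_ITER):
        if np.linalg.eigvalsh(cov)[0] >= -_PSD_TOL:
            return cov
        cov = 0.95 * cov + 0.05 * np.eye(cov.shape[0])
    raise ValueError(
        f"state {state}: covariance not positive semi-definite after "
        f"{_MAX_SHRINK_ITER} shrinkage iterations"
    )


def _epoch_rng(seed: int, p_idx: int, c_idx: int, epoch_index: int) -> np.random.Generator:
    # one independent stream per epoch so cohorts are reproducible under
    # partial regeneration
    return np.random.default_rng([int(seed) % (2**31), p_idx, c_idx, epoch_index])


def _sample_state_sequence(
    rng: np.random.Generator,
    n_samples: int,
    n_states: int,
    mean_dwell_samples: float,
) -> np.ndarray:
    states = np.empty(n_samples, dtype=np.int64)
    t = 0
    state = int(rng.integers(n_states))
    while t < n_samples:
        dwell = max(1, int(round(rng.exponential(mean_dwell_samples))))
        states[t : t + dwell] = state
        t += dwell
        if n_states > 1:
            step = int(rng.integers(1, n_states))
            state = (state + step) % n_states
    return states


def simulate_epoch(
    spec: CohortSpec,
    participant_id: str,
    group: str,
    condition: str,
    epoch_index: int = 0,
    *,
    state_covs: list[np.ndarray] | None = None,
    return_states: bool = False,
):
    """Simulate one ROI x sample epoch.

    Deterministic given ``(spec.seed, participant, condition, epoch_index)``.
    With ``return_states=True`` also returns the latent per-sample state
    sequence (used by calibration tests).
    """
    params = spec.state_params[(group, condition)]
    if state_covs is None:
        state_covs = build_state_covariances(params, spec.network_map)
    p_idx = spec.participant_ids.index(participant_id)
    c_idx = list(spec.conditions).index(condition)
    rng = _epoch_rng(spec.seed, p_idx, c_idx, epoch_index)

    n = spec.roi_count
    n_samples = spec.n_samples
    dwell_samples = params.mean_dwell_s / params.switch_rate_scale * spec.sampling_rate_hz
    if dwell_samples < 1:
        logger.warning(
            "mean dwell (%.3f samples) is below one sample; states will switch "
            "almost every sample",
            dwell_samples,
        )
    states = _sample_state_sequence(rng, n_samples, params.n_states, dwell_samples)

    chols = [np.linalg.cholesky(c + _PSD_TOL * 10 * np.eye(n)) for c in state_covs]
    data = np.empty((n, n_samples))
    # draw contiguous same-state segments in blocks
    boundaries = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n_samples]])
    for a, b in zip(starts, ends):
        z = rng.standard_normal((b - a, n))
        data[:, a:b] = (z @ chols[states[a]].T).T
    if params.noise_sd > 0:
        data += params.noise_sd * rng.standard_normal((n, n_samples))

    epoch = RoiEpoch(
        participant_id=participant_id,
        group=group,
        condition=condition,
        roi_labels=spec.roi_labels,
        data=data,
        sampling_rate_hz=spec.sampling_rate_hz,
        epoch_index=epoch_index,
    )
    if return_states:
        return epoch, states
    return epoch


def simulate_cohort(spec: CohortSpec) -> tuple[list[RoiEpoch], pd.DataFrame]:
    """Simulate the full cohort; returns epochs plus a manifest table."""
    ids = spec.participant_ids
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids in cohort")
    # covariances depend only on (group, condition): build each cell once
    covs = {
        (g, c): build_state_covariances(spec.state_params[(g, c)], spec.network_map)
        for g in spec.groups
        for c in spec.conditions
    }
    epochs: list[RoiEpoch] = []
    rows = []
    for g in spec.groups:
        for i in range(spec.n_per_group):
            pid = f"{g}{i + 1:02d}"
            for c in spec.conditions:
                for e in range(spec.epochs_per_condition):
                    ep = simulate_epoch(
                        spec, pid, g, c, e, state_covs=covs[(g, c)]
                    )
                    epochs.append(ep)
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": g,
                            "condition": c,
                            "epoch_index": e,
                            "n_rois": ep.n_rois,
                            "n_samples": ep.n_samples,
                            "sampling_rate_hz": spec.sampling_rate_hz,
                            "path": "",
                        }
                    )
    return epochs, pd.DataFrame(rows)


class CohortSimulator(BaseEstimator):
    """Estimator-style front end for the cohort generator.

    Parameters mirror :class:`CohortSpec`; ``simulate`` returns the epochs
    and manifest for the configured cohort.
    """

    def __init__(
        self,
        network_map: NetworkDefinition | None = None,
        n_per_group: int = 20,
        groups: tuple[str, str] = ("SZ", "HC"),
        conditions: tuple[str, ...] = ("MW", "OT"),
        epochs_per_condition: int = 10,
        epoch_duration_s: float = 50.0,
        sampling_rate_hz: float = 500.0,
        state_params: Mapping[tuple[str, str], ConnectivityStateParams] | None = None,
        seed: int = 0,
    ):
        self.network_map = network_map
        self.n_per_group = n_per_group
        self.groups = groups
        self.conditions = conditions
        self.epochs_per_condition = epochs_per_condition
        self.epoch_duration_s = epoch_duration_s
        self.sampling_rate_hz = sampling_rate_hz
        self.state_params = state_params
        self.seed = seed

    def spec(self, seed: int | None = None) -> CohortSpec:
        return CohortSpec(
            network_map=self.network_map
            if self.network_map is not None
            else default_network_map(),
            n_per_group=self.n_per_group,
            groups=tuple(self.groups),
            conditions=tuple(self.conditions),
            epochs_per_condition=self.epochs_per_condition,
            epoch_duration_s=self.epoch_duration_s,
            sampling_rate_hz=self.sampling_rate_hz,
            state_params=self.state_params,
            seed=self.seed if seed is None else seed,
        )

    def simulate(self, seed: int | None = None):
        return simulate_cohort(self.spec(seed))


def with_switch_rate(
    params: Mapping[tuple[str, str], ConnectivityStateParams],
    group: str,
    scale: float,
) -> dict[tuple[str, str], ConnectivityStateParams]:
    """Return a copy of a state-parameter table with one group's
    switching-rate multiplier replaced in every condition."""
    return {
        key: (replace(p, switch_rate_scale=scale) if key[0] == group else p)
        for key, p in params.items()
    }


def null_state_params(
    groups: tuple[str, str] = ("SZ", "HC"),
    conditions: tuple[str, ...] = ("OT",),
    **overrides,
) -> dict[tuple[str, str], ConnectivityStateParams]:
    """State parameters with *identical* dynamics in every group x condition
    cell — the null cohort used for type-I-error calibration."""
    p = ConnectivityStateParams(**overrides)
    return {(g, c): p for g in groups for c in conditions}
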