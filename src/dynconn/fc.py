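"""Sliding-window Spearman functional connectivity and binarization.

Each epoch is cut into overlapping windows (default 2000 ms with 90%
overlap, which yields 241 windows for a 50 s epoch at 500 Hz); within each
window the Spearman rank correlation between every pair of ROI series is
computed, and each correlation matrix is binarized over a sweep of
thresholds (default 0.1–0.6 in steps of 0.1).  Negative correlations never
form edges; graphs are unweighted and undirected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .networks import NetworkDefinition
from .synth import RoiEpoch

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


@dataclass(frozen=True)
class WindowPlan:
    """Half-open, 0-based sample ranges ``[i*step, i*step + window)``.

    Trailing samples that do not fill a complete window are dropped.
    """

    window_samples: int
    step_samples: int
    n_windows: int
    window_ms: float
    overlap_fraction: float

    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.step_samples

    def __post_init__(self):
        if self.step_samples < 1:
            raise ValueError("window step computed as 0 samples; reduce overlap")
        if self.n_windows < 1:
            raise ValueError("plan yields no windows")


def plan_windows(
    n_samples: int,
    sampling_rate_hz: float,
    window_ms: float = 2000.0,
    overlap_fraction: float = 0.9,
) -> WindowPlan:
    """Build the sliding-window plan for an epoch.

    With the default 2000 ms / 90% overlap parameters a 25,000-sample epoch
    (50 s at 500 Hz) yields a 1000-sample window, 100-sample step and 241
    windows.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    window_samples = int(round(window_ms * sampling_rate_hz / 1000.0))
    if window_samples < 2:
        raise ValueError(f"window of {window_samples} samples is too short")
    if window_samples > n_samples:
        raise ValueError(
            f"window ({window_samples} samples) longer than epoch ({n_samples})"
        )
    step = int(round(window_samples * (1.0 - overlap_fraction)))
    if step < 1:
        raise ValueError("window step computed as 0 samples; reduce overlap")
    n_windows = (n_samples - window_samples) // step + 1
    return WindowPlan(
        window_samples=window_samples,
        step_samples=step,
        n_windows=n_windows,
        window_ms=window_ms,
        overlap_fraction=overlap_fraction,
    )


def spearman_matrix(window_data: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix of an ROI x sample window.

    Computed as the Pearson correlation of midrank-transformed series.
    ROIs with zero variance inside the window yield NaN rows/columns
    (the diagonal stays 1); such entries never become graph edges.
    """
    x = np.asarray(window_data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("window must be a 2-D matrix with >= 2 ROIs")
    if x.shape[1] < 3:
        raise ValueError("window must contain >= 3 samples")
    ranks = rankdata(x, axis=1)
    sd = ranks.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    if degenerate.any():
        rho[degenerate, :] = np.nan
        rho[:, degenerate] = np.nan
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass(frozen=True)
class FcWindowSeries:
    """Per-epoch sequence of windowed ROI x ROI Spearman matrices."""

    participant_id: str
    group: str
    condition: str
    epoch_index: int
    roi_labels: tuple[str, ...]
    windows: np.ndarray  # (n_windows, n_rois, n_rois)
    plan: WindowPlan
    nan_pair_count: int = 0

    def __post_init__(self):
        w = np.asarray(self.windows, dtype=float)
        if w.ndim != 3 or w.shape[1] != w.shape[2]:
            raise ValueError("windows must be a (n_windows, n_rois, n_rois) array")
        if w.shape[0] != self.plan.n_windows:
            raise ValueError(
                f"{w.shape[0]} matrices but plan prescribes {self.plan.n_windows}"
            )
        object.__setattr__(self, "windows", w)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_rois(self) -> int:
        return self.windows.shape[1]


def compute_fc_series(epoch: RoiEpoch, plan: WindowPlan | None = None) -> FcWindowSeries:
    """Windowed Spearman FC for one epoch, in window order."""
    if plan is None:
        plan = plan_windows(epoch.n_samples, epoch.sampling_rate_hz)
    if plan.starts()[-1] + plan.window_samples > epoch.n_samples:
        raise ValueError("window plan extends beyond the epoch")
    mats = np.empty((plan.n_windows, epoch.n_rois, epoch.n_rois))
    for i, start in enumerate(plan.starts()):
        try:
            mats[i] = spearman_matrix(
                epoch.data[:, start : start + plan.window_samples]
            )
        except ValueError as err:
            raise ValueError(f"window {i} (start sample {start}): {err}") from err
    nan_pairs = int(np.isnan(mats).sum() // 2)
    if nan_pairs:
        logger.warning(
            "epoch %s/%s/%d: %d NaN ROI pairs across windows (zero-variance "
            "windows); treated as absent edges",
            epoch.participant_id,
            epoch.condition,
            epoch.epoch_index,
            nan_pairs,
        )
    return FcWindowSeries(
        participant_id=epoch.participant_id,
        group=epoch.group,
        condition=epoch.condition,
        epoch_index=epoch.epoch_index,
        roi_labels=epoch.roi_labels,
        windows=mats,
        plan=plan,
        nan_pair_count=nan_pairs,
    )


@dataclass(frozen=True)
class BinaryGraph:
    """Unweighted undirected adjacency at one (window, threshold)."""

    adjacency: np.ndarray
    threshold: float
    window_index: int = 0
    roi_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", a.astype(np.int8))


def binarize(fc: np.ndarray, threshold: float, window_index: int = 0,
             roi_labels: tuple[str, ...] = ()) -> BinaryGraph:
    """Threshold an FC matrix into an unweighted undirected graph.

    An edge (i, j), i != j, exists iff ``fc[i, j] > threshold`` (strict).
    Negative and NaN correlations never form edges.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    fc = np.asarray(fc, dtype=float)
    with np.errstate(invalid="ignore"):
        adj = (fc > threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj = np.minimum(adj, adj.T)  # enforce symmetry against asymmetric NaN input
    return BinaryGraph(adjacency=adj, threshold=threshold,
                       window_index=window_index, roi_labels=tuple(roi_labels))


def extract_network_subgraph(obj, network: str, network_map: NetworkDefinition):
    """Restrict an FC matrix or :class:`BinaryGraph` to one network's ROIs.

    Returns the principal submatrix in the network's own ROI order;
    ``"brain"`` returns the input unchanged (up to ROI reordering when the
    epoch order differs from the map order).
    """
    if isinstance(obj, BinaryGraph):
        idx = network_map.indices(network, obj.roi_labels)
        sub = obj.adjacency[np.ix_(idx, idx)]
        return BinaryGraph(
            adjacency=sub,
            threshold=obj.threshold,
            window_index=obj.window_index,
            roi_labels=tuple(network_map[network]),
        )
    mat = np.asarray(obj)
    idx = network_map.indices(network, network_map.roi_labels)
    if mat.shape[0] != len(network_map.roi_labels):
        raise ValueError(
            "matrix size does not match the network map; pass a BinaryGraph "
            "with roi_labels for reordered inputs"
        )
    return mat[np.ix_(idx, idx)]


class SlidingWindowConnectivity(BaseEstimator, TransformerMixin):
    """Transformer from epochs to windowed Spearman FC series.

    Parameters
    ----------
    window_ms
        Sliding-window length in milliseconds.
    overlap_fraction
        Fractional overlap between consecutive windows, in [0, 1).
    """

    def __init__(self, window_ms: float = 2000.0, overlap_fraction: float = 0.9):
        self.window_ms = window_ms
        self.overlap_fraction = overlap_fraction

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> list[FcWindowSeries]:
        epochs = [X] if isinstance(X, RoiEpoch) else list(X)
        out = []
        for ep in epochs:
            plan = plan_windows(
                ep.n_samples, ep.sampling_rate_hz, self.window_ms, self.overlap_fraction
            )
            out.append(compute_fc_series(ep, plan))
        return out
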