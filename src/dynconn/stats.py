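"""Group-level inference on static/dynamic connectivity summaries.

The primary engine is a linear mixed-effects model fitted by REML with
group, binarization threshold (categorical) and their interaction as
fixed effects and a random intercept per participant:

    value ~ group * threshold + (1 | participant)

Fixed effects are tested with Type-III-style Wald F statistics (sum-coded
factors) using containment denominator degrees of freedom (between-
participant effect: N - g; within effects: (N - g)(T - 1)).  Post hoc
group contrasts at each threshold are estimated-marginal-mean differences
from the fitted fixed effects.

A participant-level permutation test is provided as a self-contained
nonparametric alternative (and as the automatic fallback when the mixed
model fails to converge): group labels are permuted across participants,
keeping each participant's threshold profile intact, and the observed
F-of-group from an ordinary two-way fit is compared with its permutation
distribution.

Multiple testing is controlled by Benjamini–Hochberg FDR, by default
within each (condition, summary_type) stratum across network x metric x
effect rows.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = {"static": "static_mean", "dynamic": "dynamic_cv"}
EFFECTS = ("group", "threshold", "group:threshold")

_FORMULA = "value ~ C(group, Sum) * C(threshold, Sum)"


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at
    1); NaN entries are passed through unadjusted."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# single-cell engines


def _term_slices(design_info) -> dict[str, slice]:
    slices = {}
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        if ":" in term:
            slices["group:threshold"] = sl
        elif "group" in term:
            slices["group"] = sl
        else:
            slices["threshold"] = sl
    return slices


def fit_mixed_anova_cell(df: pd.DataFrame) -> tuple[list[dict], list[dict]]:
    """REML mixed model for one (condition, network, metric, summary) cell.

    ``df`` needs columns participant_id, group, threshold, value (NaN rows
    already dropped).  Returns (effect rows, post hoc rows).  Raises
    RuntimeError on convergence failure so the caller can fall back to the
    permutation engine.
    """
    df = df.copy()
    df["threshold"] = df["threshold"].astype(str)
    groups = sorted(df["group"].unique())
    thresholds = sorted(df["threshold"].unique())
    n_part = df["participant_id"].nunique()
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, got {groups}")
    if df.groupby("group")["participant_id"].nunique().min() < 2:
        raise ValueError("need >= 2 participants per group")
    if np.ptp(df["value"].to_numpy()) < 1e-12:
        raise ValueError("response is constant; no variance to model")

    model = smf.mixedlm(_FORMULA, df, groups=df["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(reml=True)
        except Exception as err:  # singular fits raise LinAlgError etc.
            raise RuntimeError(f"mixed model failed: {err}") from err
    if not np.all(np.isfinite(res.fe_params)):
        raise RuntimeError("mixed model produced non-finite fixed effects")

    k_fe = len(res.fe_params)
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    design_info = model.data.design_info
    slices = _term_slices(design_info)

    df_between = n_part - len(groups)
    df_within = df_between * (len(thresholds) - 1)
    dendf = {
        "group": df_between,
        "threshold": max(df_within, 1),
        "group:threshold": max(df_within, 1),
    }

    effect_rows = []
    for effect in EFFECTS:
        sl = slices[effect]
        b = beta[sl]
        v = cov[sl, sl]
        q = len(b)
        try:
            chi2 = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"singular covariance for effect {effect}") from err
        fstat = chi2 / q
        p = float(sps.f.sf(fstat, q, dendf[effect]))
        effect_rows.append(
            {"effect": effect, "statistic": fstat, "p_value": p, "engine": "mixed"}
        )

    # post hoc: marginal-mean group contrast at each threshold
    posthoc_rows = []
    g1, g2 = groups
    for t in thresholds:
        (mats,) = build_design_matrices(
            [design_info], pd.DataFrame({"group": [g1, g2], "threshold": [t, t]})
        )
        x = np.asarray(mats)
        c = x[0] - x[1]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        tval = est / se if se > 0 else float("nan")
        p = float(2 * sps.t.sf(abs(tval), df_between)) if se > 0 else float("nan")
        posthoc_rows.append(
            {
                "threshold": float(t),
                "contrast": f"{g1} - {g2}",
                "estimate": est,
                "se": se,
                "statistic": tval,
                "p_value": p,
            }
        )
    return effect_rows, posthoc_rows


def _group_permutations(
    participants: list[str],
    group_of: dict[str, str],
    n_perm: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Permuted group-indicator vectors over participants.

    Enumerates all distinct assignments when there are no more than
    ``n_perm``; otherwise draws ``n_perm`` random permutations.
    """
    n = len(participants)
    n1 = sum(1 for p in participants if group_of[p] == sorted(set(group_of.values()))[0])
    total = math.comb(n, n1)
    if total <= n_perm:
        perms = []
        for combo in itertools.combinations(range(n), n1):
            ind = np.zeros(n)
            ind[list(combo)] = 1.0
            perms.append(ind)
        return perms
    perms = []
    base = np.zeros(n)
    base[:n1] = 1.0
    for _ in range(n_perm):
        perms.append(rng.permutation(base))
    return perms


def permutation_group_test_cell(
    df: pd.DataFrame, n_perm: int = 999, seed: int = 0
) -> tuple[list[dict], list[dict]]:
    """Participant-level permutation test of the group effect.

    Statistic: F of group from an ordinary additive two-way (group +
    threshold) least-squares fit.  Group labels are permuted across
    participants, keeping each participant's threshold profile intact;
    p = (1 + #{perm >= obs}) / (1 + #perms).  Per-threshold post hoc
    p-values reuse the same permutation set with the absolute group mean
    difference as statistic.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    df = df.copy()
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, got {groups}")
    participants = sorted(df["participant_id"].unique())
    group_of = dict(
        df.drop_duplicates("participant_id")[["participant_id", "group"]].values
    )
    p_index = {p: i for i, p in enumerate(participants)}
    rows_part = df["participant_id"].map(p_index).to_numpy()

    y = df["value"].to_numpy(dtype=float)
    thr = df["threshold"].to_numpy(dtype=float)
    thr_levels = np.unique(thr)
    # residual maker for [1, threshold dummies]
    T = np.column_stack(
        [np.ones_like(y)] + [(thr == t).astype(float) for t in thr_levels[1:]]
    )
    Q, _ = np.linalg.qr(T)
    y_r = y - Q @ (Q.T @ y)
    rank_t = T.shape[1]
    df2 = len(y) - rank_t - 1
    if df2 < 1:
        raise ValueError("not enough observations for the permutation F statistic")

    obs_ind = np.array([1.0 if group_of[p] == groups[0] else 0.0 for p in participants])

    def f_of(ind_part: np.ndarray) -> float:
        g = ind_part[rows_part]
        g_r = g - Q @ (Q.T @ g)
        ss_g = g_r @ g_r
        if ss_g < 1e-12:
            return 0.0
        b = (g_r @ y_r) / ss_g
        rss_full = y_r @ y_r - b * b * ss_g
        if rss_full <= 0:
            return float("inf")
        return float((b * b * ss_g) / (rss_full / df2))

    def mean_diffs(ind_part: np.ndarray) -> np.ndarray:
        g = ind_part[rows_part].astype(bool)
        out = np.empty(len(thr_levels))
        for i, t in enumerate(thr_levels):
            sel = thr == t
            out[i] = y[sel & g].mean() - y[sel & ~g].mean()
        return out

    rng = np.random.default_rng(seed)
    perms = _group_permutations(participants, group_of, n_perm, rng)
    f_obs = f_of(obs_ind)
    d_obs = np.abs(mean_diffs(obs_ind))
    # tolerance so label-swapped assignments (identical F up to rounding)
    # count as >= the observed statistic
    tol = 1e-9
    f_ge = 0
    d_ge = np.zeros(len(thr_levels))
    for ind in perms:
        f_ge += f_of(ind) >= f_obs * (1 - tol)
        d_ge += np.abs(mean_diffs(ind)) >= d_obs * (1 - tol)
    n_eff = len(perms)
    p_group = (1 + f_ge) / (1 + n_eff)
    effect_rows = [
        {
            "effect": "group",
            "statistic": f_obs,
            "p_value": float(p_group),
            "engine": "permutation",
        }
    ]
    g1, g2 = groups
    posthoc_rows = [
        {
            "threshold": float(t),
            "contrast": f"{g1} - {g2}",
            "estimate": float(mean_diffs(obs_ind)[i]),
            "se": float("nan"),
            "statistic": float(d_obs[i]),
            "p_value": float((1 + d_ge[i]) / (1 + n_eff)),
        }
        for i, t in enumerate(thr_levels)
    ]
    return effect_rows, posthoc_rows


# ---------------------------------------------------------------------------
# table-level driver


def significance_matrix(posthoc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Diamond-rule indicator: one row per (condition, network, metric,
    summary_type), marked significant iff the FDR-adjusted group contrast
    falls below ``alpha`` at one or more thresholds."""
    keys = ["condition", "network", "metric", "summary_type"]
    rows = []
    for key, sub in posthoc.groupby(keys, sort=False, observed=True):
        sig = bool((sub["p_adjusted"] < alpha).any())
        rows.append((*key, sig))
    return pd.DataFrame(rows, columns=keys + ["significant"])


class GroupThresholdAnova(BaseEstimator):
    """Group x threshold inference over participant-level summaries.

    ``fit`` expects the long summary table from :class:`WindowSummarizer`
    (columns participant_id, group, condition, network, threshold, metric,
    static_mean, dynamic_cv) and analyzes every (condition, network,
    metric) cell separately for the static and dynamic responses, mirroring
    the segregation of analyses by attentional condition.

    Parameters
    ----------
    engine
        ``"mixed"`` (REML mixed model, permutation fallback on singular
        fits) or ``"permutation"``.
    alpha
        Significance level for the diamond indicator matrix.
    n_perm
        Number of label permutations for the permutation engine.
    summary_types
        Which responses to analyze (subset of ``("static", "dynamic")``).
    posthoc_fdr_scope
        ``"within_cell"``: BH across the thresholds of one cell (default);
        ``"stratum"``: BH across all post hoc rows of one
        (condition, summary_type) stratum.
    random_state
        Seed for the permutation engine.

    Attributes
    ----------
    results_
        Effect rows with FDR-adjusted p-values.
    posthoc_
        Per-threshold group contrasts with adjusted p-values.
    significance_
        Diamond-rule indicator table at ``alpha``.
    """

    def __init__(
        self,
        engine: str = "mixed",
        alpha: float = 0.05,
        n_perm: int = 999,
        summary_types: tuple[str, ...] = ("static", "dynamic"),
        posthoc_fdr_scope: str = "within_cell",
        random_state: int = 0,
    ):
        self.engine = engine
        self.alpha = alpha
        self.n_perm = n_perm
        self.summary_types = summary_types
        self.posthoc_fdr_scope = posthoc_fdr_scope
        self.random_state = random_state

    def fit(self, table: pd.DataFrame, y=None):
        if self.engine not in ("mixed", "permutation"):
            raise ValueError("engine must be 'mixed' or 'permutation'")
        if self.posthoc_fdr_scope not in ("within_cell", "stratum"):
            raise ValueError("posthoc_fdr_scope must be 'within_cell' or 'stratum'")
        bad = set(self.summary_types) - set(SUMMARY_COLUMNS)
        if bad:
            raise ValueError(f"unknown summary types: {sorted(bad)}")

        effect_frames = []
        posthoc_frames = []
        cells = table.groupby(["condition", "network", "metric"], sort=False,
                              observed=True)
        for (condition, network, metric), sub in cells:
            for stype in self.summary_types:
                col = SUMMARY_COLUMNS[stype]
                cell = sub[
                    ["participant_id", "group", "threshold", col]
                ].rename(columns={col: "value"})
                n_nan = int(cell["value"].isna().sum())
                if n_nan:
                    logger.info(
                        "%s/%s/%s/%s: dropping %d NaN responses",
                        condition, network, metric, stype, n_nan,
                    )
                cell = cell.dropna(subset=["value"])
                key = dict(
                    condition=condition, network=network, metric=metric,
                    summary_type=stype,
                )
                try:
                    eff, post = self._fit_cell(cell)
                except (ValueError, RuntimeError) as err:
                    logger.warning("cell %s skipped: %s", key, err)
                    continue
                effect_frames.append(pd.DataFrame([{**key, **r} for r in eff]))
                posthoc_frames.append(pd.DataFrame([{**key, **r} for r in post]))

        if not effect_frames:
            raise ValueError("no analyzable cells in the summary table")
        results = pd.concat(effect_frames, ignore_index=True)
        posthoc = pd.concat(posthoc_frames, ignore_index=True)

        # FDR over effects within each (condition, summary_type) stratum
        results["p_adjusted"] = np.nan
        for _, idx in results.groupby(["condition", "summary_type"],
                                      observed=True).groups.items():
            results.loc[idx, "p_adjusted"] = fdr_adjust(
                results.loc[idx, "p_value"].to_numpy()
            )
        # FDR over post hoc contrasts
        posthoc["p_adjusted"] = np.nan
        scope_keys = (
            ["condition", "network", "metric", "summary_type"]
            if self.posthoc_fdr_scope == "within_cell"
            else ["condition", "summary_type"]
        )
        for _, idx in posthoc.groupby(scope_keys, observed=True).groups.items():
            posthoc.loc[idx, "p_adjusted"] = fdr_adjust(
                posthoc.loc[idx, "p_value"].to_numpy()
            )

        self.results_ = results
        self.posthoc_ = posthoc
        self.significance_ = significance_matrix(posthoc, self.alpha)
        return self

    def _fit_cell(self, cell: pd.DataFrame):
        if self.engine == "permutation":
            return permutation_group_test_cell(
                cell, n_perm=self.n_perm, seed=self.random_state
            )
        try:
            return fit_mixed_anova_cell(cell)
        except RuntimeError as err:
            logger.warning(
                "mixed model failed (%s); falling back to permutation test", err
            )
            return permutation_group_test_cell(
                cell, n_perm=self.n_perm, seed=self.random_state
            )


def fit_mixed_anova(table: pd.DataFrame, **kwargs) -> GroupThresholdAnova:
    """Fit the mixed-model engine over a summary table (thin wrapper)."""
    return GroupThresholdAnova(engine="mixed", **kwargs).fit(table)


def permutation_group_test(table: pd.DataFrame, **kwargs) -> GroupThresholdAnova:
    """Fit the permutation engine over a summary table (thin wrapper)."""
    return GroupThresholdAnova(engine="permutation", **kwargs).fit(table)
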