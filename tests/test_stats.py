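"""Mixed-model and permutation inference, FDR, and the diamond rule."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dynconn.stats import (
    GroupThresholdAnova,
    fdr_adjust,
    fit_mixed_anova_cell,
    permutation_group_test_cell,
    significance_matrix,
)

THRESHOLDS = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]


def make_cell(n_per_group=8, group_shift=0.0, seed=0, participant_sd=1.0,
              noise_sd=0.5):
    """Balanced group x threshold table with a random participant effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, shift in (("SZ", group_shift), ("HC", 0.0)):
        for i in range(n_per_group):
            pid = f"{g}{i:02d}"
            u = rng.normal(0, participant_sd)
            for t in THRESHOLDS:
                rows.append(
                    {
                        "participant_id": pid,
                        "group": g,
                        "threshold": t,
                        "value": 10 + shift + u + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


class TestFdr:
    def test_hand_worked_example(self):
        # BH step-up: [0.001, 0.02, 0.03, 0.5] -> [0.004, 0.04, 0.04, 0.5]
        np.testing.assert_allclose(
            fdr_adjust([0.001, 0.02, 0.03, 0.5]), [0.004, 0.04, 0.04, 0.5]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.37]), [0.37])

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert fdr_adjust([]).size == 0

    def test_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(np.argsort(np.argsort(p)) == np.argsort(np.argsort(q))) or (
            # ties in q are allowed; ranks of q must be weakly monotone in p
            np.all(np.diff(q[np.argsort(p)]) >= -1e-15)
        )


class TestMixedModelCell:
    def test_detects_large_group_shift(self):
        eff, post = fit_mixed_anova_cell(make_cell(group_shift=3.0, seed=2))
        p = {r["effect"]: r["p_value"] for r in eff}
        assert p["group"] < 0.01
        # every per-threshold HC - SZ contrast points the same way (SZ was
        # shifted upward)
        assert all(r["estimate"] < 0 for r in post)

    def test_null_shift_usually_not_significant(self):
        eff, _ = fit_mixed_anova_cell(make_cell(group_shift=0.0, seed=3))
        p = {r["effect"]: r["p_value"] for r in eff}
        assert p["group"] > 0.01

    def test_three_effects_reported(self):
        eff, post = fit_mixed_anova_cell(make_cell(seed=4))
        assert {r["effect"] for r in eff} == {"group", "threshold", "group:threshold"}
        assert len(post) == len(THRESHOLDS)

    def test_constant_response_rejected(self):
        df = make_cell(seed=5)
        df["value"] = 7.0
        with pytest.raises(ValueError, match="constant"):
            fit_mixed_anova_cell(df)

    def test_posthoc_estimate_matches_observed_difference(self):
        # balanced design: the marginal-mean contrast at a threshold equals
        # the raw group mean difference there
        df = make_cell(group_shift=1.0, seed=6)
        _, post = fit_mixed_anova_cell(df)
        for r in post:
            sel = df[df["threshold"] == r["threshold"]]
            obs = (
                sel[sel["group"] == "HC"]["value"].mean()
                - sel[sel["group"] == "SZ"]["value"].mean()
            )
            assert r["estimate"] == pytest.approx(obs, abs=1e-6)


class TestPermutationCell:
    def test_exact_enumeration_for_three_vs_three(self):
        df = make_cell(n_per_group=3, group_shift=5.0, seed=7)
        eff, _ = permutation_group_test_cell(df, n_perm=999, seed=0)
        # C(6,3) = 20 distinct assignments; the observed labeling is the
        # most extreme, so p = 1/20 exactly... including the +1 guard the
        # attainable minimum is (1 + #{perm >= obs}) / (1 + 20)
        assert math.comb(6, 3) == 20
        p = eff[0]["p_value"]
        assert p == pytest.approx((1 + 2) / (1 + 20))

    def test_same_seed_same_p(self):
        df = make_cell(seed=8)
        p1 = permutation_group_test_cell(df, n_perm=199, seed=5)[0][0]["p_value"]
        p2 = permutation_group_test_cell(df, n_perm=199, seed=5)[0][0]["p_value"]
        assert p1 == p2

    def test_detects_large_shift(self):
        df = make_cell(group_shift=3.0, seed=9)
        eff, post = permutation_group_test_cell(df, n_perm=499, seed=0)
        assert eff[0]["p_value"] < 0.01
        assert len(post) == len(THRESHOLDS)

    def test_n_perm_floor(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_group_test_cell(make_cell(seed=1), n_perm=10)


def result_table(cells):
    rows = []
    for (cond, net, metric, stype), ps in cells.items():
        for t, (p, padj) in zip(THRESHOLDS, ps):
            rows.append(
                {
                    "condition": cond,
                    "network": net,
                    "metric": metric,
                    "summary_type": stype,
                    "threshold": t,
                    "p_value": p,
                    "p_adjusted": padj,
                }
            )
    return pd.DataFrame(rows)


class TestSignificanceMatrix:
    def test_single_threshold_marks_cell(self):
        ps = [(0.5, 0.9)] * 6
        ps[2] = (0.001, 0.01)
        table = result_table({("OT", "DMN", "degree", "dynamic"): ps})
        out = significance_matrix(table, alpha=0.05)
        assert bool(out.loc[0, "significant"])

    def test_no_threshold_significant(self):
        table = result_table({("OT", "DMN", "degree", "dynamic"): [(0.5, 0.9)] * 6})
        out = significance_matrix(table, alpha=0.05)
        assert not bool(out.loc[0, "significant"])


def summary_table(seed=0, dyn_shift=0.0, stat_shift=0.0, n_per_group=8):
    """Participant-level summary table for two metrics on one network."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("SZ", "HC"):
        for i in range(n_per_group):
            pid = f"{g}{i:02d}"
            u = rng.normal(0, 1.0)
            for metric in ("degree", "efficiency"):
                for t in THRESHOLDS:
                    dyn = 50 + u + rng.normal(0, 2)
                    stat = 5 + 0.3 * u + rng.normal(0, 0.3)
                    if g == "SZ" and metric == "degree":
                        dyn -= dyn_shift
                        stat -= stat_shift
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": g,
                            "condition": "OT",
                            "network": "brain",
                            "threshold": t,
                            "metric": metric,
                            "static_mean": stat,
                            "dynamic_cv": dyn,
                            "n_windows_used": 9,
                        }
                    )
    return pd.DataFrame(rows)


class TestGroupThresholdAnova:
    def test_dynamic_only_effect_lands_in_dynamic_rows(self):
        table = summary_table(seed=1, dyn_shift=4.0)
        model = GroupThresholdAnova(engine="mixed").fit(table)
        sig = model.significance_.set_index(["metric", "summary_type"])["significant"]
        assert bool(sig.loc[("degree", "dynamic")])
        assert not bool(sig.loc[("degree", "static")])

    def test_engines_agree_on_strong_effect(self):
        table = summary_table(seed=2, dyn_shift=4.0)
        pm = (
            GroupThresholdAnova(engine="mixed").fit(table).results_
        )
        pp = (
            GroupThresholdAnova(engine="permutation", n_perm=499).fit(table).results_
        )
        row_m = pm[(pm.metric == "degree") & (pm.summary_type == "dynamic")
                   & (pm.effect == "group")]
        row_p = pp[(pp.metric == "degree") & (pp.summary_type == "dynamic")
                   & (pp.effect == "group")]
        assert float(row_m["p_value"].iloc[0]) < 0.05
        assert float(row_p["p_value"].iloc[0]) < 0.05

    def test_adjusted_p_never_below_raw(self):
        model = GroupThresholdAnova(engine="mixed").fit(summary_table(seed=3))
        r = model.results_
        assert np.all(r["p_adjusted"] >= r["p_value"] - 1e-12)
        assert r["p_value"].between(0, 1).all()
        assert r["p_adjusted"].between(0, 1).all()

    def test_one_row_per_cell_effect(self):
        model = GroupThresholdAnova(engine="mixed").fit(summary_table(seed=4))
        counts = model.results_.groupby(
            ["condition", "network", "metric", "summary_type", "effect"],
            observed=True,
        ).size()
        assert (counts == 1).all()

    def test_nan_responses_dropped(self):
        table = summary_table(seed=5)
        table.loc[table.index[:12], "dynamic_cv"] = np.nan
        model = GroupThresholdAnova(engine="mixed").fit(table)
        assert len(model.results_) > 0
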