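"""Period assignment, mixed ANOVA against a sums-of-squares oracle, post-hocs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from meloinfo.lifetime import (
    DEFAULT_PERIOD_MAP,
    DesignError,
    assign_periods,
    bonferroni_posthoc,
    mixed_anova,
    tp_entropy_correlation,
)


def long_table(values):
    """values: dict (piece, period, order) -> value."""
    rows = [
        dict(piece_no=pn, period=period, order=order, value=v)
        for (pn, period, order), v in values.items()
    ]
    return pd.DataFrame(rows)


def split_plot_oracle(df):
    """Explicit sums-of-squares decomposition of a balanced-within mixed design.

    Independent of the implementation: works directly from cell means.
    Returns dict effect -> (df1, df2, F, partial_eta_sq).
    """
    y = df.pivot(index="piece_no", columns="order", values="value")
    groups = df.groupby("piece_no")["period"].first()
    k = y.shape[1]
    subjects = y.index
    n = len(subjects)
    levels = list(y.columns)
    glabels = sorted(groups.unique())
    g_count = {g: (groups == g).sum() for g in glabels}
    grand = y.values.mean()

    subj_mean = y.mean(axis=1)
    group_mean = {g: y.loc[groups == g].values.mean() for g in glabels}
    level_mean = y.mean(axis=0)
    cell_mean = {(g, w): y.loc[groups == g, w].mean() for g in glabels for w in levels}

    ss_between_subj = k * ((subj_mean - grand) ** 2).sum()
    ss_a = k * sum(g_count[g] * (group_mean[g] - grand) ** 2 for g in glabels)
    ss_subj_within = ss_between_subj - ss_a
    ss_b = n * ((level_mean - grand) ** 2).sum()
    ss_ab = sum(
        g_count[g] * (cell_mean[(g, w)] - group_mean[g] - level_mean[w] + grand) ** 2
        for g in glabels
        for w in levels
    )
    ss_total = ((y.values - grand) ** 2).sum()
    ss_err_within = ss_total - ss_a - ss_subj_within - ss_b - ss_ab

    G = len(glabels)
    df_a, df_sw = G - 1, n - G
    df_b = k - 1
    df_ab = (G - 1) * (k - 1)
    df_ew = (n - G) * (k - 1)
    out = {
        "period": (df_a, df_sw, (ss_a / df_a) / (ss_subj_within / df_sw),
                   ss_a / (ss_a + ss_subj_within)),
        "order": (df_b, df_ew, (ss_b / df_b) / (ss_err_within / df_ew),
                  ss_b / (ss_b + ss_err_within)),
        "period x order": (df_ab, df_ew, (ss_ab / df_ab) / (ss_err_within / df_ew),
                           ss_ab / (ss_ab + ss_err_within)),
    }
    return out


class TestAssignPeriods:
    @pytest.mark.parametrize("piece, period", [(1, "early"), (12, "early"), (19, "early"),
                                               (20, "early"), (13, "middle"), (27, "middle"),
                                               (28, "late"), (32, "late")])
    def test_default_mapping(self, piece, period):
        assert assign_periods([piece])[piece] == period

    def test_default_mapping_partitions_all_32(self):
        labels = [DEFAULT_PERIOD_MAP[p] for p in range(1, 33)]
        assert len(DEFAULT_PERIOD_MAP) == 32
        assert labels.count("early") == 14
        assert labels.count("middle") == 13
        assert labels.count("late") == 5

    def test_unmapped_piece_is_an_error(self):
        with pytest.raises(ValueError, match="33"):
            assign_periods([1, 33])

    def test_override_mapping(self):
        assert assign_periods([99], {99: "late"})[99] == "late"


class TestMixedAnova:
    def _toy_design(self):
        # 6 subjects, 2 groups x 2 within levels; values chosen non-degenerate
        vals = {
            (1, "early", 0): 3.0, (1, "early", 1): 5.0,
            (2, "early", 0): 4.0, (2, "early", 1): 6.5,
            (3, "early", 0): 2.5, (3, "early", 1): 5.5,
            (4, "late", 0): 6.0, (4, "late", 1): 7.0,
            (5, "late", 0): 7.5, (5, "late", 1): 8.0,
            (6, "late", 0): 6.5, (6, "late", 1): 9.0,
        }
        return long_table(vals)

    def test_matches_sums_of_squares_oracle(self):
        table = self._toy_design()
        oracle = split_plot_oracle(table)
        results = {r.effect: r for r in mixed_anova(table)}
        assert set(results) == set(oracle)
        for effect, (df1, df2, F, np2) in oracle.items():
            r = results[effect]
            assert r.df_num == pytest.approx(df1, abs=1e-8)
            assert r.df_den == pytest.approx(df2, abs=1e-8)
            assert r.F == pytest.approx(F, abs=1e-8)
            assert r.partial_eta_sq == pytest.approx(np2, abs=1e-8)

    def test_oracle_agreement_on_random_three_group_designs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            vals = {}
            pn = 0
            for period, count in [("early", 4), ("middle", 3), ("late", 3)]:
                for _ in range(count):
                    pn += 1
                    for order in range(3):
                        vals[(pn, period, order)] = float(rng.normal())
            table = long_table(vals)
            oracle = split_plot_oracle(table)
            results = {r.effect: r for r in mixed_anova(table)}
            for effect, (_, _, F, np2) in oracle.items():
                assert results[effect].F == pytest.approx(F, abs=1e-8)
                assert results[effect].partial_eta_sq == pytest.approx(np2, abs=1e-8)

    def test_no_between_effect_when_period_means_equal(self):
        vals = {}
        for pn, period in [(1, "early"), (2, "early"), (3, "late"), (4, "late")]:
            base = 1.0 if pn % 2 else 2.0  # identical value sets in both periods
            for order in range(2):
                vals[(pn, period, order)] = base + order
        results = {r.effect: r for r in mixed_anova(long_table(vals))}
        assert results["period"].F == pytest.approx(0.0, abs=1e-12)

    def test_missing_cell_is_design_error(self):
        table = self._toy_design().iloc[:-1]
        with pytest.raises(DesignError):
            mixed_anova(table)

    def test_single_period_is_design_error(self):
        vals = {(pn, "early", order): float(pn + order) for pn in (1, 2, 3) for order in (0, 1)}
        with pytest.raises(DesignError):
            mixed_anova(long_table(vals))

    def test_three_within_levels_adjust_dfs(self):
        rng = np.random.default_rng(1)
        vals = {}
        pn = 0
        for period, count in [("early", 5), ("late", 5)]:
            for _ in range(count):
                pn += 1
                for order in (1, 2, 3):  # MI design: three within levels
                    vals[(pn, period, order)] = float(rng.normal())
        results = {r.effect: r for r in mixed_anova(long_table(vals))}
        r = results["order"]
        if not r.sphericity_corrected:
            assert (r.df_num, r.df_den) == (2, 16)
        assert results["period x order"].df_num == 2

    def test_greenhouse_geisser_on_sphericity_violation(self):
        # one dominant within level driven by the subject factor produces a
        # strongly non-spherical covariance
        rng = np.random.default_rng(2)
        vals = {}
        pn = 0
        scale = {0: 0.1, 1: 0.1, 2: 0.1, 3: 4.0}
        for period, count in [("early", 8), ("late", 8)]:
            for _ in range(count):
                pn += 1
                u = rng.normal()
                for order in range(4):
                    vals[(pn, period, order)] = u * scale[order] + rng.normal(0, 0.05)
        table = long_table(vals)
        uncorrected = split_plot_oracle(table)
        results = {r.effect: r for r in mixed_anova(table)}
        r = results["order"]
        k = 4
        assert r.sphericity_corrected
        assert 1 / (k - 1) < r.gg_epsilon <= 1.0
        assert r.df_num < k - 1  # fractional, shrunk dfs
        assert r.df_num == pytest.approx((k - 1) * r.gg_epsilon)
        # F itself is unchanged by the correction
        assert r.F == pytest.approx(uncorrected["order"][2], abs=1e-8)

    def test_permuting_period_labels_calibrates_to_alpha(self):
        rng = np.random.default_rng(3)
        pieces = list(range(1, 13))
        base = {pn: rng.normal(2.0 if pn <= 6 else 0.0, 1.0) for pn in pieces}
        within = {pn: rng.normal(0, 0.5, size=2) for pn in pieces}
        rejections = 0
        n_perm = 200
        for _ in range(n_perm):
            perm = rng.permutation(pieces)
            labels = {pn: ("early" if i < 6 else "late") for i, pn in enumerate(perm)}
            vals = {
                (pn, labels[pn], order): base[pn] + within[pn][order]
                for pn in pieces
                for order in range(2)
            }
            results = {r.effect: r for r in mixed_anova(long_table(vals))}
            if results["period"].p < 0.05:
                rejections += 1
        assert 0.005 <= rejections / n_perm <= 0.105


class TestBonferroniPosthoc:
    def _table(self, shift_late=0.0, seed=4):
        rng = np.random.default_rng(seed)
        vals = {}
        pn = 0
        for period, count in [("early", 5), ("middle", 5), ("late", 5)]:
            for _ in range(count):
                pn += 1
                for order in range(2):
                    bump = shift_late if period == "late" else 0.0
                    vals[(pn, period, order)] = float(rng.normal() + bump)
        return long_table(vals)

    def test_adjustment_is_raw_p_times_comparisons_capped(self):
        comps = bonferroni_posthoc(self._table(shift_late=1.0), "period")
        assert len(comps) == 3
        for c in comps:
            assert c.n_comparisons == 3
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 3))

    def test_identical_groups_adjust_to_one(self):
        vals = {}
        for pn, period in [(1, "early"), (2, "early"), (3, "late"), (4, "late")]:
            for order in range(2):
                vals[(pn, period, order)] = float(pn % 2 + order)
        comps = bonferroni_posthoc(long_table(vals), "period")
        assert all(c.p_adjusted == 1.0 for c in comps)

    def test_direction_reported(self):
        comps = bonferroni_posthoc(self._table(shift_late=5.0), "period")
        late_vs_early = [c for c in comps if {c.level_a, c.level_b} == {"early", "late"}][0]
        assert "late" in late_vs_early.direction and ">" in late_vs_early.direction.replace("<", ">")

    def test_interaction_family_corrects_over_all_pairs(self):
        comps = bonferroni_posthoc(self._table(shift_late=1.0), "period x order")
        # 3 period pairs x 2 order levels
        assert len(comps) == 6
        assert all(c.n_comparisons == 6 for c in comps)

    def test_single_level_rejected(self):
        vals = {(pn, "early", order): float(pn + order) for pn in (1, 2) for order in (0, 1)}
        with pytest.raises(ValueError):
            bonferroni_posthoc(long_table(vals), "period")


class TestCorrelation:
    def test_perfectly_collinear_decreasing(self):
        tp = {1: 0.9, 2: 0.6, 3: 0.3}
        ent = {1: 1.0, 2: 2.0, 3: 3.0}
        res = tp_entropy_correlation(tp, ent, order=2)
        assert res.r == pytest.approx(-1.0)
        assert res.n == 3

    def test_two_pieces_rejected(self):
        with pytest.raises(ValueError):
            tp_entropy_correlation({1: 0.5, 2: 0.6}, {1: 1.0, 2: 2.0}, order=1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            tp_entropy_correlation({1: 0.5, 2: 0.5, 3: 0.5}, {1: 1.0, 2: 2.0, 3: 3.0}, order=1)

    def test_null_simulation_rarely_significant(self):
        rng = np.random.default_rng(6)
        significant = 0
        for _ in range(100):
            tp = {i: float(rng.normal()) for i in range(32)}
            ent = {i: float(rng.normal()) for i in range(32)}
            res = tp_entropy_correlation(tp, ent, order=1)
            assert abs(res.r) <= 1.0
            if res.p < 0.05:
                significant += 1
        assert significant <= 10
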