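import numpy as np
import pingouin as pg
import pandas as pd
import pytest
from scipy import stats

import reachcond as rc
from reachcond import effects as fx


def _pre_from_delta(delta_values, labels, phase="acquisition"):
    """Minimal PreprocessedSeries whose theta realizes the requested deltas
    over a schedule with the requested CS labels."""
    n = len(labels)
    theta = np.concatenate([[0.0], np.cumsum(delta_values)])
    assert len(theta) == n
    trials = []
    for i, lab in enumerate(labels):
        cs = frozenset({"tone"}) if lab == "+" else frozenset({"light"})
        us = None if phase == "probe" else (15.0 if lab == "+" else 0.0)
        trials.append(rc.Trial(index=i + 1, phase=phase, cs_set=cs, us=us))
    sched = rc.TrialSchedule(trials=trials, design="exp1_differential", seed=0)
    mask = np.zeros(n, bool)
    delta, valid = rc.delta_heading(theta, mask, sched.phases)
    return rc.PreprocessedSeries(
        theta=theta, outlier_mask=mask, slow_mask=mask.copy(), delta=delta,
        delta_valid=valid, correction=np.zeros(n), schedule=sched,
    )


class TestCellStats:
    def test_singleton_cells(self):
        # labels: + + - + - -  -> pairs (+,+),(+,-),(-,+),(+,-),(-,-)
        pre = _pre_from_delta([1.0, 1.0, 2.0, 2.0, 3.0],
                              ["+", "+", "-", "+", "-", "-"])
        cells = fx.cell_stats(pre)
        assert cells[0, 0] == 1.0  # + after +
        assert cells[0, 1] == pytest.approx((1.0 + 2.0) / 2)  # - after +
        assert cells[1, 0] == 2.0  # + after -
        assert cells[1, 1] == 3.0  # - after -

    def test_all_equal_deltas_equal_cells(self):
        pre = _pre_from_delta([0.5] * 7, ["+", "-", "+", "+", "-", "-", "+",
                                          "-"])
        cells = fx.cell_stats(pre)
        assert np.all(cells == 0.5)

    def test_matches_grouping_oracle(self, exp1_schedule):
        rng = np.random.default_rng(0)
        n = len(exp1_schedule)
        theta = rng.normal(0, 3, n)
        mask = rng.random(n) < 0.1
        delta, valid = rc.delta_heading(theta, mask, exp1_schedule.phases)
        pre = rc.PreprocessedSeries(
            theta=theta, outlier_mask=mask, slow_mask=np.zeros(n, bool),
            delta=delta, delta_valid=valid, correction=np.zeros(n),
            schedule=exp1_schedule)
        cells = fx.cell_stats(pre, "acquisition")
        labels = exp1_schedule.cs_labels()
        groups = {(p, c): [] for p in "+-" for c in "+-"}
        for i in range(1, 600):
            if valid[i]:
                groups[(labels[i - 1], labels[i])].append(theta[i] - theta[i - 1])
        for i, p in enumerate("+-"):
            for j, c in enumerate("+-"):
                assert cells[i, j] == pytest.approx(np.mean(groups[(p, c)]))

    def test_conservation_of_overall_mean(self, exp1_schedule):
        """The count-weighted mean of the four cell means equals the overall
        mean of the valid deltas entering the analysis."""
        rng = np.random.default_rng(1)
        n = len(exp1_schedule)
        theta = rng.normal(0, 3, n)
        delta, valid = rc.delta_heading(theta, np.zeros(n, bool),
                                        exp1_schedule.phases)
        pre = rc.PreprocessedSeries(
            theta=theta, outlier_mask=np.zeros(n, bool),
            slow_mask=np.zeros(n, bool), delta=delta, delta_valid=valid,
            correction=np.zeros(n), schedule=exp1_schedule)
        cells = fx.cell_stats(pre, "acquisition")
        labels = exp1_schedule.cs_labels()
        counts = np.zeros((2, 2))
        for i in range(1, 600):
            if valid[i]:
                counts["+-".index(labels[i - 1]), "+-".index(labels[i])] += 1
        weighted = (cells * counts).sum() / counts.sum()
        overall = np.nanmean(delta[:600][valid[:600]])
        assert weighted == pytest.approx(overall, abs=1e-10)

    def test_empty_cell_error(self):
        pre = _pre_from_delta([1.0, 1.0], ["+", "+", "-"])
        with pytest.raises(ValueError, match="previous"):
            fx.cell_stats(pre)


class TestRmAnova2x2:
    @pytest.fixture()
    def random_cells(self):
        rng = np.random.default_rng(3)
        return rng.normal(0.5, 1.0, size=(12, 2, 2))

    def test_f_equals_paired_t_squared(self, random_cells):
        res = fx.rm_anova_2x2(random_cells)
        y = random_cells
        for effect, contrast in (
            ("previous", y[:, 0, :].mean(1) - y[:, 1, :].mean(1)),
            ("current", y[:, :, 0].mean(1) - y[:, :, 1].mean(1)),
            ("interaction", (y[:, 0, 0] - y[:, 0, 1]) - (y[:, 1, 0] - y[:, 1, 1])),
        ):
            t, p = stats.ttest_1samp(contrast, 0.0)
            eff = getattr(res, effect)
            assert abs(eff.F - t ** 2) < 1e-8
            assert eff.p == pytest.approx(p)

    def test_matches_pingouin_oracle(self, random_cells):
        res = fx.rm_anova_2x2(random_cells)
        n = random_cells.shape[0]
        rows = []
        for i in range(n):
            for a, pa in enumerate("+-"):
                for b, pb in enumerate("+-"):
                    rows.append(dict(subject=i, prev=pa, cur=pb,
                                     y=random_cells[i, a, b]))
        df = pd.DataFrame(rows)
        table = pg.rm_anova(data=df, dv="y", within=["prev", "cur"],
                            subject="subject", detailed=True)
        by = {r["Source"]: r for _, r in table.iterrows()}
        assert res.previous.F == pytest.approx(by["prev"]["F"])
        assert res.current.F == pytest.approx(by["cur"]["F"])
        assert res.interaction.F == pytest.approx(by["prev * cur"]["F"])
        assert res.previous.p == pytest.approx(by["prev"]["p_unc"])
        assert res.current.p == pytest.approx(by["cur"]["p_unc"])
        # partial eta^2 for a 1-df within effect: F / (F + df2)
        for eff in (res.previous, res.current, res.interaction):
            assert eff.eta_p2 == pytest.approx(eff.F / (eff.F + eff.df[1]))

    def test_hand_constructed_table_longhand(self):
        """4-participant table checked against the sums-of-squares
        decomposition evaluated longhand."""
        y = np.array([
            [[2.0, 1.0], [3.0, 0.0]],
            [[3.0, 1.5], [2.5, 0.5]],
            [[2.5, 0.5], [3.5, 1.0]],
            [[1.5, 2.0], [2.0, 0.5]],
        ])
        res = fx.rm_anova_2x2(y)
        # longhand: current-CS contrast per subject
        c = y[:, :, 0].mean(1) - y[:, :, 1].mean(1)  # [2.0, 1.75, 2.25, 0.5]
        t = c.mean() / (c.std(ddof=1) / np.sqrt(4))
        assert res.current.F == pytest.approx(t ** 2)
        ss_eff = 4 * 2 * 2 * (c.mean() / 2) ** 2
        ss_err = ((c - c.mean()) ** 2).sum()
        assert res.current.eta_p2 == pytest.approx(ss_eff / (ss_eff + ss_err))
        assert res.current.mean_diff == pytest.approx(c.mean())

    def test_cohen_d_definition(self, random_cells):
        res = fx.rm_anova_2x2(random_cells)
        c = res.contrasts["current"]
        assert res.current.cohen_d == pytest.approx(
            c.mean() / c.std(ddof=1))

    def test_identical_cells_degenerate_error(self):
        y = np.tile(np.array([[1.0, 2.0], [3.0, 4.0]]), (5, 1, 1))
        with pytest.raises(ValueError, match="zero error variance"):
            fx.rm_anova_2x2(y)

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            fx.rm_anova_2x2(np.zeros((2, 2, 2)))


class TestBinnedDynamics:
    def test_exact_linear_deltas_recovered(self):
        rng = np.random.default_rng(5)
        labels = list(rng.choice(["+", "-"], size=101))
        code = np.array([1.0 if l == "+" else -1.0 for l in labels])
        a, b, c, d = 0.7, -0.4, 0.2, 0.05
        deltas = [d + a * code[i - 1] + b * code[i] + c * code[i - 1] * code[i]
                  for i in range(1, 101)]
        pre = _pre_from_delta(deltas, labels)
        w = fx.binned_dynamics_participant(pre, bin_width=50)
        np.testing.assert_allclose(w, [[a, b, c], [a, b, c]], atol=1e-10)

    def test_rank_deficient_bin_is_nan(self):
        labels = ["+"] * 50 + list(np.random.default_rng(0).choice(
            ["+", "-"], size=51))
        pre = _pre_from_delta([0.1] * 100, labels)
        w = fx.binned_dynamics_participant(pre, bin_width=50)
        assert np.all(np.isnan(w[0]))

    def test_too_short_phase(self):
        pre = _pre_from_delta([0.1] * 59, ["+", "-"] * 30)
        with pytest.raises(ValueError):
            fx.binned_dynamics_participant(pre, bin_width=50)

    def test_group_slopes_sign_for_rw_cohort(self):
        cfg = rc.noiseless(rc.SyntheticConfig(master_seed=13))
        cohort = rc.generate_cohort("exp1_differential", 8, cfg)
        pres = [rc.preprocess(p) for p in cohort]
        dyn = fx.binned_dynamics(pres)
        assert np.all(dyn.slopes[:, 1] > 0)  # Pavlovian weight grows
        assert np.all(dyn.slopes[:, 0] < 0)  # adaptation weight declines
        t, p = dyn.slope_contrast
        assert t > 0 and p < 0.01


def _friedman_longhand(table):
    """Friedman statistic from the rank-sum formula (no tie handling; the
    table must be tie-free within rows)."""
    n, k = table.shape
    ranks = np.argsort(np.argsort(table, axis=1), axis=1) + 1
    R = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * (R ** 2).sum() - 3 * n * (k + 1)


@pytest.fixture(scope="module")
def exp4_pres():
    cfg = rc.SyntheticConfig(model="rw", params=dict(rc.EXP4_RW),
                             master_seed=17)
    cohort = rc.generate_cohort("exp4_compound", 12, cfg)
    return [rc.preprocess(p) for p in cohort]


class TestCompoundProbe:
    def test_noiseless_compound_exceeds_elements(self):
        cfg = rc.noiseless(rc.SyntheticConfig(model="rw",
                                              params=dict(rc.EXP4_RW),
                                              master_seed=2))
        cohort = rc.generate_cohort("exp4_compound", 8, cfg)
        pres = [rc.preprocess(p) for p in cohort]
        med = np.stack([fx.compound_probe_medians(p) for p in pres])
        assert np.all(med[:, 0] > med[:, 1])  # compound > tone alone
        assert np.all(med[:, 0] > med[:, 2])  # compound > light alone

    def test_friedman_matches_rank_formula_oracle(self):
        table = np.array([[0.4, -0.1, -0.2],
                          [0.1, 0.3, -0.4],
                          [0.5, 0.2, -0.3]])
        chi2, _ = stats.friedmanchisquare(*table.T)
        assert chi2 == pytest.approx(_friedman_longhand(table))

    def test_kendall_w_definition(self, exp4_pres):
        res = fx.compound_probe_analysis(exp4_pres)
        n, k = res.medians.shape
        assert res.kendall_w == pytest.approx(res.chi2 / (n * (k - 1)))

    def test_identical_conditions_zero_statistic(self):
        """All three probe conditions identical for every participant: the
        Friedman statistic is 0 and no pairwise test survives."""
        labels = ["compound", "tone", "light"] * 6
        trials = [
            rc.Trial(index=i + 1, phase="probe",
                     cs_set=frozenset({"tone", "light"}) if lab == "compound"
                     else frozenset({lab}), us=None)
            for i, lab in enumerate(labels)
        ]
        sched = rc.TrialSchedule(trials=trials, design="exp4_compound", seed=0)
        n = len(trials)
        theta = 1.0 * np.arange(n)  # exactly constant delta everywhere
        mask = np.zeros(n, bool)
        delta, valid = rc.delta_heading(theta, mask, sched.phases)
        pre = rc.PreprocessedSeries(theta=theta, outlier_mask=mask,
                                    slow_mask=mask.copy(), delta=delta,
                                    delta_valid=valid,
                                    correction=np.zeros(n), schedule=sched)
        res = fx.compound_probe_analysis([pre] * 4)
        assert res.chi2 == pytest.approx(0.0)
        assert all(p == 1.0 for p in res.pairwise.values())

    def test_bonferroni_capped(self, exp4_pres):
        res = fx.compound_probe_analysis(exp4_pres)
        assert all(0.0 <= p <= 1.0 for p in res.pairwise.values())


class TestOvershadowCorrelation:
    def test_perfect_tradeoff(self):
        a = np.array([0.1, 0.4, 0.25, 0.7])
        r, p = fx.overshadow_correlation(a, 1.0 - a)
        assert r == pytest.approx(-1.0)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(8)
        rs = [fx.overshadow_correlation(rng.normal(size=20),
                                        rng.normal(size=20))[0]
              for _ in range(200)]
        assert abs(np.mean(rs)) < 0.05

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            fx.overshadow_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestPooledSingleton:
    def test_noiseless_positive_current_type_effect(self):
        cfg = rc.noiseless(rc.SyntheticConfig(model="rw",
                                              params=dict(rc.EXP4_RW),
                                              master_seed=23))
        cohort = rc.generate_cohort("exp4_compound", 8, cfg)
        pres = [rc.preprocess(p) for p in cohort]
        res = fx.pooled_singleton_anova(pres)
        assert res.current.mean_diff > 0

    def test_matches_manual_pooling_oracle(self, exp4_pres):
        res = fx.pooled_singleton_anova(exp4_pres)
        tables = []
        for pre in exp4_pres:
            sl = pre.schedule.phase_slice("probe")
            labels = pre.schedule.cs_labels()[sl]
            pooled = np.where(labels == "compound", "compound", "singleton")
            d = pre.delta[sl]
            v = pre.delta_valid[sl]
            cells = np.empty((2, 2))
            for i, p in enumerate(("compound", "singleton")):
                for j, c in enumerate(("compound", "singleton")):
                    sel = np.zeros(len(d), bool)
                    sel[1:] = v[1:] & (pooled[:-1] == p) & (pooled[1:] == c)
                    cells[i, j] = d[sel].mean()
            tables.append(cells)
        oracle = fx.rm_anova_2x2(np.stack(tables),
                                 levels=("compound", "singleton"))
        assert res.current.F == pytest.approx(oracle.current.F)
        assert res.previous.F == pytest.approx(oracle.previous.F)
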