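"""Scale scoring, effect sizes, gated tests, correlations, mixed ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from breathloop import stats as bs


def oracle_scs12(items, negative=(1, 4, 8, 9, 11, 12)):
    """Item-by-item reference scorer, written independently."""
    csr_items, usr_items, rev = [], [], []
    for idx, r in enumerate(items, start=1):
        if idx in negative:
            usr_items.append(r)
            rev.append(6 - r)
        else:
            csr_items.append(r)
            rev.append(r)
    return (
        sum(rev) / 12.0,
        sum(csr_items) / 6.0,
        sum(usr_items) / 6.0,
    )


class TestScoreSCS12:
    def test_midpoint_fixed_point(self):
        assert bs.score_scs12([3] * 12) == (3.0, 3.0, 3.0)

    def test_extremes(self):
        items = [1 if i in bs.SCS12_NEGATIVE_ITEMS else 5 for i in range(1, 13)]
        total, csr, usr = bs.score_scs12(items)
        assert (total, csr, usr) == (5.0, 5.0, 1.0)

    def test_matches_item_by_item_oracle(self, rng):
        for _ in range(100):
            items = rng.integers(1, 6, size=12).tolist()
            got = bs.score_scs12(items)
            exp = oracle_scs12(items)
            assert got == pytest.approx(exp)

    @pytest.mark.parametrize(
        "bad", [[3] * 11, [3] * 13, [3] * 11 + [np.nan], [3] * 11 + [6]]
    )
    def test_invalid_sheets_rejected(self, bad):
        with pytest.raises(ValueError):
            bs.score_scs12(bad)


class TestCohenD:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected",
        [
            # published within-group values reproduced from printed summaries
            (2.69, 0.57, 3.02, 0.58, 0.57),    # self-compassion post
            (2.69, 0.57, 3.14, 0.55, 0.80),    # self-compassion follow-up
            (2.94, 0.79, 3.37, 0.85, 0.52),    # state mindfulness post
            (2.94, 0.79, 3.41, 1.08, 0.50),    # state mindfulness follow-up
            (16.27, 4.45, 15.0, 5.86, -0.24),  # emotional exhaustion
            (11.92, 12.55, 1.44, 11.66, -0.87),  # DMN, training group
            (4.94, 7.10, 10.26, 15.43, 0.44),    # DMN, control group
            (3.45, 3.39, 1.08, 3.08, -0.73),     # FPN, control group
            (2.55, 2.18, 1.44, 1.76, -0.56),     # CON, training group
        ],
    )
    def test_pooled_sd_effect_sizes(self, m1, s1, m2, s2, expected):
        assert round(bs.cohen_d_within(m1, s1, m2, s2), 2) == expected

    def test_equal_means_zero(self):
        assert bs.cohen_d_within(3.0, 0.5, 3.0, 0.5) == 0.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            bs.cohen_d_within(1.0, 0.0, 2.0, 1.0)

    @given(
        st.floats(-10, 10), st.floats(0.1, 5), st.floats(-10, 10),
        st.floats(0.1, 5), st.floats(0.1, 20),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_antisymmetry_and_scale_invariance(self, m1, s1, m2, s2, k):
        d = bs.cohen_d_within(m1, s1, m2, s2)
        assert bs.cohen_d_within(m2, s2, m1, s1) == pytest.approx(-d)
        assert bs.cohen_d_within(k * m1, k * s1, k * m2, k * s2) == pytest.approx(
            d, rel=1e-9
        )

    def test_between_group_change_score_d(self, rng):
        da = rng.normal(0.5, 1.0, 30)
        db = rng.normal(0.0, 1.0, 30)
        d = bs.cohen_d_between(da, db)
        pooled = np.sqrt(
            (29 * da.var(ddof=1) + 29 * db.var(ddof=1)) / 58
        )
        assert d == pytest.approx((da.mean() - db.mean()) / pooled)


class TestPairedTestGate:
    def test_shifted_normal_pairs_use_t_and_detect(self):
        hits = 0
        t_used = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            pre = rng.normal(0, 1, 22)
            post = pre + rng.normal(0.5, 0.5, 22)
            p, test = bs.choose_and_run_paired_test(pre, post)
            t_used += test == "paired-t"
            hits += p < 0.05
        assert t_used >= 30
        assert hits >= 28  # high power for a within-subject dz = 1 shift

    def test_heavy_tailed_differences_use_signed_rank(self):
        wilcox = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            pre = rng.normal(0, 1, 22)
            post = pre + rng.standard_cauchy(22)
            _, test = bs.choose_and_run_paired_test(pre, post)
            wilcox += test == "wilcoxon-signed-rank"
        assert wilcox >= 21

    def test_identical_vectors_degenerate(self):
        p, test = bs.choose_and_run_paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0 and test == "degenerate"

    def test_levene_gate_option_runs(self, rng):
        pre = rng.normal(0, 1, 22)
        post = pre + rng.normal(0.3, 0.5, 22)
        p, test = bs.choose_and_run_paired_test(pre, post, gate="levene")
        assert 0 <= p <= 1 and test in ("paired-t", "wilcoxon-signed-rank")


class TestCronbachAlpha:
    def test_duplicated_items_perfect_reliability(self, rng):
        col = rng.normal(0, 1, 50)
        assert bs.cronbach_alpha(np.column_stack([col, col, col])) == pytest.approx(1.0)

    def test_hand_computed_three_item_matrix(self):
        x = np.array([[1, 2, 3], [2, 4, 5], [3, 3, 4], [5, 5, 5]], dtype=float)
        # item variances 35/12, 5/3, 11/12; total variance 41/3
        # alpha = 3/2 * (1 - 5.5 / (41/3))
        assert bs.cronbach_alpha(x) == pytest.approx(1.5 * (1 - 5.5 / (41 / 3)))

    def test_independent_items_near_zero(self, rng):
        x = rng.normal(0, 1, size=(5000, 6))
        assert abs(bs.cronbach_alpha(x)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bs.cronbach_alpha(np.ones((10, 3)))


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.linspace(-2, 2, 25)
        rho, p = bs.spearman(x, x**3)
        assert rho == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            bs.spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_partial_with_no_covariates_equals_plain(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 40))
            x, y = rng.normal(size=(2, n))
            rho1, p1 = bs.spearman(x, y)
            rho2, p2 = bs.spearman_partial(x, y)
            assert rho2 == pytest.approx(rho1, abs=1e-12)
            assert p2 == pytest.approx(p1, rel=1e-6)

    def test_partial_removes_additive_covariate(self, rng):
        n = 200
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = x + z
        rho, _ = bs.spearman_partial(x, y, z)
        assert rho > 0.9

    def test_matches_pingouin_partial(self, rng):
        import pingouin as pg

        n = 40
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "c1": rng.normal(size=n),
                "c2": rng.integers(0, 2, size=n).astype(float),
            }
        )
        res = pg.partial_corr(
            data=df, x="x", y="y", covar=["c1", "c2"], method="spearman"
        )
        rho, p = bs.spearman_partial(
            df["x"], df["y"], df[["c1", "c2"]].to_numpy()
        )
        p_col = "p_val" if "p_val" in res.columns else "p-val"
        assert rho == pytest.approx(float(res["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(res[p_col].iloc[0]), rel=1e-6)


def _long_2x2(rng, n_a=10, n_b=10, interaction=0.0, group_eff=0.0,
              session_eff=0.0):
    rows = []
    for g, n in (("a", n_a), ("b", n_b)):
        for i in range(n):
            pid = f"{g}{i}"
            subj = rng.normal(0, 1)
            for s_idx, s in enumerate(("T1", "T2")):
                val = (
                    subj
                    + group_eff * (g == "a")
                    + session_eff * s_idx
                    + interaction * s_idx * (g == "a")
                    + rng.normal(0, 0.5)
                )
                rows.append((pid, g, s, val))
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "session", "value"]
    )


class TestMixedAnova:
    def test_group_label_symmetry(self, rng):
        df = _long_2x2(rng, interaction=1.0)
        rep1 = bs.mixed_anova(df)
        swapped = df.assign(group=df["group"].map({"a": "b", "b": "a"}))
        rep2 = bs.mixed_anova(swapped)
        assert rep1.F == pytest.approx(rep2.F)
        assert rep1.gg_epsilon == 1.0

    def test_interaction_f_equals_t_squared_on_change_scores(self, rng):
        """With 2x2 cells the interaction F is the squared two-sample t
        comparing change scores between groups (textbook identity)."""
        df = _long_2x2(rng, interaction=0.8, group_eff=0.5, session_eff=0.3)
        rep = bs.mixed_anova(df)
        wide = df.pivot_table(
            index=["participant_id", "group"], columns="session", values="value"
        ).reset_index()
        delta = wide["T2"] - wide["T1"]
        t = sps.ttest_ind(
            delta[wide["group"] == "a"], delta[wide["group"] == "b"]
        )
        assert rep.F == pytest.approx(t.statistic**2, rel=1e-9)
        assert rep.p == pytest.approx(t.pvalue, rel=1e-9)
        assert rep.df == (1.0, 18.0)

    def test_interaction_only_data(self, rng):
        df = _long_2x2(rng, n_a=40, n_b=40, interaction=1.5)
        rep = bs.mixed_anova(df)
        assert rep.p < 0.001
        assert 0 < rep.partial_eta_sq <= 1

    def test_too_small_group_rejected(self, rng):
        df = _long_2x2(rng, n_a=1, n_b=10)
        with pytest.raises(ValueError, match="fewer than 2"):
            bs.mixed_anova(df)


class TestAnalyzeTrial:
    def test_full_report_structure(self):
        from breathloop import cohort

        out, act, _ = cohort.generate_cohort(
            seed=0, include_training_logs=False
        )
        rep = bs.analyze_trial(out, act)
        assert set(rep["baseline"]) >= {"self_compassion", "mbi_ee"}
        assert any(
            w["outcome"] == "self_compassion" and w["contrast"] == "T3-T1"
            for w in rep["within_group"]
        )
        assert "DMN" in rep["networks"]
        assert "anova" in rep["networks"]["DMN"]
        assert "dDMN~d_self_compassion" in rep["neurobehavioral"]
        md = bs.format_report_markdown(rep)
        assert "Within-group changes" in md

    def test_missing_group_rejected(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a1"],
                "group": ["training"],
                "timepoint": ["T1"],
                "self_compassion": [3.0],
            }
        )
        with pytest.raises(ValueError, match="group"):
            bs.analyze_trial(df)

    def test_dropout_is_complete_case_not_fatal(self):
        from breathloop import cohort

        out, act, _ = cohort.generate_cohort(
            seed=3, include_training_logs=False
        )
        rep = bs.analyze_trial(out, act)
        t3 = [w for w in rep["within_group"]
              if w["contrast"] == "T3-T1" and w["outcome"] == "self_compassion"]
        ns = {w["group"]: w["n"] for w in t3}
        assert ns == {"training": 20, "control": 20}
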