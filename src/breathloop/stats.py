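"""Inferential machinery for the two-group, three-timepoint trial.

Covers scale scoring (12-item self-compassion short form with its
compassionate / uncompassionate halves), internal-consistency reliability,
pooled-SD Cohen d effect sizes, distribution-gated paired tests, Spearman
and Spearman partial correlations, and the 2 (group) x 2 (session) mixed
ANOVA with the Greenhouse-Geisser sphericity note.

Conventions
-----------
* Cohen d (within-group, summary form): d = (m2 - m1) / sqrt((s1^2 + s2^2)/2),
  the mean difference in pooled-SD units.  0.2/0.5/0.8 read as
  small/medium/large.
* Between-group d: difference of mean change scores divided by the pooled SD
  of the change scores.
* The paired test is a two-tailed paired t when the difference scores pass
  the normality gate, otherwise the Wilcoxon signed-rank test.  The gate is
  Shapiro-Wilk by default; a Levene-style option is provided.
* Rounding to 2 decimals happens only in report formatting, never inside
  computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "score_scs12",
    "cohen_d_within",
    "cohen_d_from_samples",
    "cohen_d_between",
    "choose_and_run_paired_test",
    "cronbach_alpha",
    "spearman",
    "spearman_partial",
    "mixed_anova",
    "analyze_trial",
    "EffectSizeReport",
    "AnovaReport",
    "SCS12_NEGATIVE_ITEMS",
    "MBI_MIDSCORES",
]

# 12-item self-compassion short form: reverse-keyed (uncompassionate) items.
SCS12_NEGATIVE_ITEMS = (1, 4, 8, 9, 11, 12)

# Interpretive subscale midpoints for the three burnout subscales
# (emotional exhaustion, personal accomplishment, depersonalization).
MBI_MIDSCORES = {"mbi_ee": 18, "mbi_pa": 16, "mbi_dp": 10}


def score_scs12(item_responses, negative_items=SCS12_NEGATIVE_ITEMS):
    """Score a 12-item self-compassion sheet -> (total, csr, usr).

    Items are Likert 1-5.  CSR (compassionate self-responding: self-kindness,
    common humanity, mindfulness items) is the mean of the 6 positively keyed
    items; USR (uncompassionate self-responding: self-judgment, isolation,
    overidentification) is the mean of the 6 negatively keyed items left
    unreversed; the total is the mean of all 12 with negative items
    reverse-scored as 6 - response.  Missing items are an error.
    """
    items = np.asarray(item_responses, dtype=float)
    if items.shape != (12,):
        raise ValueError("expected exactly 12 item responses")
    if np.any(~np.isfinite(items)):
        raise ValueError("missing item responses are not imputed")
    if np.any((items < 1) | (items > 5)):
        raise ValueError("item responses must lie in 1..5")
    neg = np.zeros(12, dtype=bool)
    neg[[i - 1 for i in negative_items]] = True
    csr = float(items[~neg].mean())
    usr = float(items[neg].mean())
    reversed_items = np.where(neg, 6.0 - items, items)
    total = float(reversed_items.mean())
    return total, csr, usr


def cohen_d_within(m1: float, s1: float, m2: float, s2: float) -> float:
    """Pooled-SD effect size from summary statistics: (m2-m1)/sqrt((s1²+s2²)/2)."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    return (m2 - m1) / math.sqrt((s1 * s1 + s2 * s2) / 2.0)


def cohen_d_from_samples(x1, x2) -> float:
    """Pooled-SD d computed from the two samples themselves (ddof=1)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return cohen_d_within(
        float(x1.mean()), float(x1.std(ddof=1)), float(x2.mean()), float(x2.std(ddof=1))
    )


def cohen_d_between(delta_a, delta_b) -> float:
    """Between-group d: difference of mean change scores over their pooled SD."""
    da = np.asarray(delta_a, dtype=float)
    db = np.asarray(delta_b, dtype=float)
    na, nb = da.size, db.size
    pooled = math.sqrt(
        ((na - 1) * da.var(ddof=1) + (nb - 1) * db.var(ddof=1)) / (na + nb - 2)
    )
    if pooled <= 0:
        raise ValueError("pooled SD of change scores is zero")
    return float((da.mean() - db.mean()) / pooled)


def _normality_gate(diffs: np.ndarray, gate: str, alpha: float) -> bool:
    """True if the difference scores look normal enough for the t test."""
    if gate == "shapiro":
        return sps.shapiro(diffs).pvalue > alpha
    if gate == "levene":
        # Variance-homogeneity check between the lower and upper halves of
        # the sorted differences: a symmetric, light-tailed (normal-like)
        # sample has comparable spread in both halves.
        d = np.sort(diffs)
        half = d.size // 2
        return sps.levene(d[:half], d[-half:]).pvalue > alpha
    raise ValueError("gate must be 'shapiro' or 'levene'")


def choose_and_run_paired_test(
    x_pre, x_post, gate: str = "shapiro", gate_alpha: float = 0.05
):
    """Two-tailed paired comparison with a distribution-gated test choice.

    Returns ``(p, test_used)`` where ``test_used`` is ``'paired-t'`` or
    ``'wilcoxon-signed-rank'``.  All-zero differences are degenerate:
    ``(1.0, 'degenerate')``.
    """
    pre = np.asarray(x_pre, dtype=float)
    post = np.asarray(x_post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 3:
        raise ValueError("paired samples of equal length >= 3 required")
    diffs = post - pre
    if np.allclose(diffs, 0.0):
        return 1.0, "degenerate"
    if _normality_gate(diffs, gate, gate_alpha):
        p = float(sps.ttest_rel(post, pre).pvalue)
        return p, "paired-t"
    p = float(sps.wilcoxon(post, pre, zero_method="wilcox").pvalue)
    return p, "wilcoxon-signed-rank"


def cronbach_alpha(item_matrix) -> float:
    """Cronbach alpha of an items matrix (rows = respondents, cols = items)."""
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 respondents and >= 2 items")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def spearman(x, y):
    """Spearman rank correlation -> (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_partial(x, y, covariates=None):
    """Spearman partial correlation of x and y given covariates -> (rho, p).

    All variables (including covariates, which may contain binary group
    indicators) are rank-transformed; x and y ranks are then residualized on
    the covariate ranks plus an intercept, and the Pearson correlation of
    the residuals is taken.  With no covariates this reduces exactly to the
    plain Spearman correlation.  The p value uses the t approximation with
    n - 2 - k degrees of freedom for k covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((x.size, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != x.size:
            cov = cov.T
    if cov.shape[0] != x.size or y.size != x.size:
        raise ValueError("x, y and covariates must share the first dimension")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if cov.shape[1] == 0:
        r = float(np.corrcoef(rx, ry)[0, 1])
    else:
        rc = np.column_stack([sps.rankdata(c) for c in cov.T])
        design = np.column_stack([np.ones(x.size), rc])
        beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
        beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
        ex = rx - design @ beta_x
        ey = ry - design @ beta_y
        r = float(np.corrcoef(ex, ey)[0, 1])
    n = x.size
    df = n - 2 - cov.shape[1]
    if df <= 0:
        raise ValueError("not enough observations for the covariate set")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)


@dataclass(frozen=True)
class AnovaReport:
    """Group x session interaction of the mixed repeated-measures ANOVA."""

    F: float
    df: tuple[float, float]
    p: float
    partial_eta_sq: float
    gg_epsilon: float
    note: str = ""


def mixed_anova(values: pd.DataFrame, dv="value", within="session",
                between="group", subject="participant_id") -> AnovaReport:
    """2-group x 2-session mixed ANOVA on complete cases.

    ``values`` is long-format with one row per participant x session.
    Returns the group x session interaction with Greenhouse-Geisser epsilon
    noted; with only two within-subject levels sphericity holds trivially
    and epsilon = 1, so the corrected and uncorrected p coincide.
    """
    import pingouin as pg

    df = values.dropna(subset=[dv]).copy()
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == df[within].nunique()].index
    df = df[df[subject].isin(complete)]
    for g, sub in df.groupby(between):
        if sub[subject].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 complete cases")
    aov = pg.mixed_anova(
        data=df, dv=dv, within=within, between=between, subject=subject
    )
    inter = aov[aov["Source"] == "Interaction"].iloc[0]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    n_within = df[within].nunique()
    eps = 1.0 if n_within == 2 else float(aov.get("eps", pd.Series([np.nan])).iloc[-1])
    note = (
        "Greenhouse-Geisser epsilon = 1 (two within-subject levels; "
        "sphericity trivially satisfied)"
        if n_within == 2
        else "Greenhouse-Geisser corrected"
    )
    return AnovaReport(
        F=float(inter["F"]),
        df=(float(inter["DF1"]), float(inter["DF2"])),
        p=float(inter[p_col]),
        partial_eta_sq=float(inter["np2"]),
        gg_epsilon=eps,
        note=note,
    )


@dataclass(frozen=True)
class EffectSizeReport:
    outcome: str
    contrast: str
    cohen_d: float
    p_value: float
    test_used: str
    n: int


# ---------------------------------------------------------------------------
# Whole-trial analysis
# ---------------------------------------------------------------------------

_BEHAVIORAL_OUTCOMES = (
    "self_compassion",
    "csr",
    "usr",
    "state_mindfulness",
    "mbi_ee",
    "mbi_pa",
    "mbi_dp",
)


def _pivot(outcomes: pd.DataFrame, col: str) -> pd.DataFrame:
    return outcomes.pivot_table(
        index=["participant_id", "group"], columns="timepoint", values=col,
        aggfunc="first",
    ).reset_index()


def _within_group_block(wide, group, col, t_ref, t_cmp):
    sub = wide[wide["group"] == group].dropna(subset=[t_ref, t_cmp])
    n = len(sub)
    if n < 3:
        return None
    pre = sub[t_ref].to_numpy()
    post = sub[t_cmp].to_numpy()
    p, test = choose_and_run_paired_test(pre, post)
    try:
        d = cohen_d_from_samples(pre, post)
    except ValueError:
        d = 0.0
    return EffectSizeReport(col, f"{t_cmp}-{t_ref}", d, p, test, n)


def analyze_trial(
    outcomes: pd.DataFrame,
    activity: pd.DataFrame | None = None,
    group_labels=("training", "control"),
    apply_fdr: bool = False,
) -> dict:
    """Full trial report from an outcome table (+ optional network activity).

    ``outcomes``: long format, columns participant_id, group, timepoint
    (T1/T2/T3) plus scale-score columns, and per-participant
    ``sessions_completed`` / ``final_level`` for the training group.
    ``activity``: long format, columns participant_id, group, timepoint
    (T1/T2), network (FPN/CON/DMN), activity (1e-4 source units).

    The report contains baseline group comparisons, within-group change
    tests and pooled-SD d per outcome and contrast, between-group d of the
    change scores, the adherence correlations, the network ANOVA, and the
    change-DMN vs change-self-compassion partial rank correlation adjusted
    for group and baseline burnout.  Missing timepoints drop an outcome from
    that contrast only (complete-case analysis); skipped blocks are listed
    under ``skipped``.  ``apply_fdr`` optionally Benjamini-Hochberg-adjusts
    the within-group p values (off by default; primary report is unadjusted).
    """
    ga, gb = group_labels
    present = set(outcomes["group"].unique())
    if not {ga, gb} <= present:
        raise ValueError(f"both groups {group_labels} must be present")
    if activity is not None and "condition" in activity.columns:
        # keep one value per participant x timepoint x network: the 'mean'
        # condition if present, else the mean of attended and distracted
        if (activity["condition"] == "mean").any():
            activity = activity[activity["condition"] == "mean"]
        else:
            keep = activity[activity["condition"].isin(
                ["attended", "distracted"])]
            group_cols = [
                c for c in ("participant_id", "group", "timepoint", "network")
                if c in keep.columns
            ]
            activity = (
                keep.groupby(group_cols, as_index=False)["activity"].mean()
            )
    cols = [c for c in _BEHAVIORAL_OUTCOMES if c in outcomes.columns]
    report: dict = {"groups": list(group_labels), "skipped": []}

    # --- baseline comparisons --------------------------------------------
    baseline = {}
    t1 = outcomes[outcomes["timepoint"] == "T1"]
    for col in cols:
        a = t1.loc[t1["group"] == ga, col].dropna().to_numpy()
        b = t1.loc[t1["group"] == gb, col].dropna().to_numpy()
        if a.size < 3 or b.size < 3:
            report["skipped"].append(f"baseline:{col}")
            continue
        normal = (
            sps.shapiro(a).pvalue > 0.05 and sps.shapiro(b).pvalue > 0.05
        )
        if normal:
            p = float(sps.ttest_ind(a, b).pvalue)
            test = "t"
        else:
            p = float(sps.ranksums(a, b).pvalue)
            test = "rank-sum"
        baseline[col] = {
            "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
            "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
            "p": p, "test": test,
        }
    report["baseline"] = baseline

    # --- within-group changes and effect sizes ---------------------------
    within: list[dict] = []
    between: dict = {}
    p_values = []
    for col in cols:
        wide = _pivot(outcomes, col)
        for t_cmp in ("T2", "T3"):
            if t_cmp not in wide.columns:
                report["skipped"].append(f"{col}:{t_cmp}")
                continue
            deltas = {}
            for grp in group_labels:
                blk = _within_group_block(wide, grp, col, "T1", t_cmp)
                if blk is None:
                    report["skipped"].append(f"{col}:{t_cmp}:{grp}")
                    continue
                sub = wide[wide["group"] == grp].dropna(subset=["T1", t_cmp])
                deltas[grp] = (sub[t_cmp] - sub["T1"]).to_numpy()
                within.append(
                    {"group": grp, **blk.__dict__}
                )
                p_values.append(blk.p_value)
            if len(deltas) == 2:
                between[f"{col}:{t_cmp}-T1"] = cohen_d_between(
                    deltas[ga], deltas[gb]
                )
    if apply_fdr and p_values:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([w["p_value"] for w in within], method="fdr_bh")[1]
        for w, q in zip(within, adj):
            w["p_fdr"] = float(q)
    report["within_group"] = within
    report["between_group_d"] = between

    # --- adherence correlations (training group only) ---------------------
    adherence = {}
    if "sessions_completed" in outcomes.columns:
        for col in ("self_compassion", "state_mindfulness"):
            if col not in outcomes.columns:
                continue
            wide = _pivot(outcomes, col)
            sess = outcomes.groupby("participant_id")["sessions_completed"].first()
            sub = wide[wide["group"] == ga].dropna(subset=["T1", "T2"])
            s = sess.reindex(sub["participant_id"]).to_numpy(dtype=float)
            delta = (sub["T2"] - sub["T1"]).to_numpy()
            ok = np.isfinite(s)
            if ok.sum() >= 4 and np.ptp(delta[ok]) > 0 and np.ptp(s[ok]) > 0:
                rho, p = spearman(s[ok], delta[ok])
                adherence[f"sessions~d_{col}"] = {"rho": rho, "p": p}
        if "final_level" in outcomes.columns:
            lvl = outcomes.groupby("participant_id")["final_level"].first()
            sess = outcomes.groupby("participant_id")["sessions_completed"].first()
            mask = outcomes.groupby("participant_id")["group"].first() == ga
            s = sess[mask].dropna()
            l = lvl[mask].reindex(s.index).dropna()
            s = s.reindex(l.index)
            if len(s) >= 4 and s.nunique() > 1 and l.nunique() > 1:
                rho, p = spearman(s.to_numpy(), l.to_numpy())
                adherence["sessions~final_level"] = {"rho": rho, "p": p}
    report["adherence"] = adherence

    # --- network activity: ANOVA + neurobehavioral coupling ---------------
    if activity is not None and len(activity):
        networks = {}
        for net, sub in activity.groupby("network"):
            wide = sub.pivot_table(
                index=["participant_id", "group"], columns="timepoint",
                values="activity", aggfunc="first",
            ).reset_index().dropna(subset=["T1", "T2"])
            nets: dict = {}
            for grp in group_labels:
                g = wide[wide["group"] == grp]
                if len(g) < 3:
                    continue
                p, test = choose_and_run_paired_test(
                    g["T1"].to_numpy(), g["T2"].to_numpy()
                )
                nets[grp] = {
                    "d": cohen_d_from_samples(g["T1"], g["T2"]),
                    "p": p,
                    "test": test,
                    "n": len(g),
                }
            deltas = {
                grp: (wide[wide["group"] == grp]["T2"]
                      - wide[wide["group"] == grp]["T1"]).to_numpy()
                for grp in group_labels
            }
            if all(v.size >= 2 for v in deltas.values()):
                nets["between_group_d"] = cohen_d_between(deltas[ga], deltas[gb])
            long = wide.melt(
                id_vars=["participant_id", "group"], value_vars=["T1", "T2"],
                var_name="session", value_name="value",
            )
            try:
                aov = mixed_anova(long)
                nets["anova"] = {
                    "F": aov.F, "df": list(aov.df), "p": aov.p,
                    "partial_eta_sq": aov.partial_eta_sq,
                    "gg_epsilon": aov.gg_epsilon,
                }
            except (ValueError, KeyError):
                report["skipped"].append(f"anova:{net}")
            networks[net] = nets
        report["networks"] = networks

        # DMN change vs self-compassion change, partialling group and
        # baseline emotional exhaustion.
        neuro = {}
        dmn = activity[activity["network"] == "DMN"].pivot_table(
            index=["participant_id", "group"], columns="timepoint",
            values="activity", aggfunc="first",
        ).reset_index().dropna(subset=["T1", "T2"])
        for col in ("self_compassion", "usr", "csr", "state_mindfulness"):
            if col not in outcomes.columns:
                continue
            wide = _pivot(outcomes, col).dropna(subset=["T1", "T2"])
            merged = dmn.merge(
                wide, on=["participant_id", "group"], suffixes=("_dmn", "_beh")
            )
            if len(merged) < 6:
                report["skipped"].append(f"neurobehavioral:{col}")
                continue
            covs = [(merged["group"] == ga).to_numpy(dtype=float)]
            if "mbi_ee" in outcomes.columns:
                ee = outcomes[outcomes["timepoint"] == "T1"].set_index(
                    "participant_id"
                )["mbi_ee"]
                covs.append(
                    ee.reindex(merged["participant_id"]).to_numpy(dtype=float)
                )
            d_dmn = (merged["T2_dmn"] - merged["T1_dmn"]).to_numpy()
            d_beh = (merged["T2_beh"] - merged["T1_beh"]).to_numpy()
            rho, p = spearman_partial(d_dmn, d_beh, np.column_stack(covs))
            neuro[f"dDMN~d_{col}"] = {"rho": rho, "p": p, "n": len(merged)}

        # baseline DMN vs DMN change within the training group
        g = dmn[dmn["group"] == ga]
        if len(g) >= 4:
            rho, p = spearman(g["T1"].to_numpy(), (g["T2"] - g["T1"]).to_numpy())
            neuro["baselineDMN~dDMN(training)"] = {"rho": rho, "p": p, "n": len(g)}
        report["neurobehavioral"] = neuro

    return report


def format_report_markdown(report: dict) -> str:
    """Render the trial report as Markdown tables (2-decimal convention)."""
    lines = ["# Trial report", "", "## Baseline", ""]
    lines.append("| outcome | group A mean (SD) | group B mean (SD) | p | test |")
    lines.append("|---|---|---|---|---|")
    for col, b in report.get("baseline", {}).items():
        lines.append(
            f"| {col} | {b['mean_a']:.2f} ({b['sd_a']:.2f}) "
            f"| {b['mean_b']:.2f} ({b['sd_b']:.2f}) | {b['p']:.3f} | {b['test']} |"
        )
    lines += ["", "## Within-group changes", ""]
    lines.append("| outcome | group | contrast | d | p | test | n |")
    lines.append("|---|---|---|---|---|---|---|")
    for w in report.get("within_group", []):
        lines.append(
            f"| {w['outcome']} | {w['group']} | {w['contrast']} "
            f"| {w['cohen_d']:.2f} | {w['p_value']:.3f} | {w['test_used']} | {w['n']} |"
        )
    if report.get("between_group_d"):
        lines += ["", "## Between-group effect sizes", "", "| contrast | d |", "|---|---|"]
        for k, v in report["between_group_d"].items():
            lines.append(f"| {k} | {v:.2f} |")
    if report.get("networks"):
        lines += ["", "## Network activity", ""]
        for net, n in report["networks"].items():
            lines.append(f"### {net}")
            for k, v in n.items():
                lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"
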