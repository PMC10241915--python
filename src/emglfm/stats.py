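"""Statistical battery for the training study.

Covers the full inferential chain: group-balance and learning-effect
t-tests, two-way mixed (within Time × between Group) repeated-measures
ANOVAs on amplitude and similarity, within-group S1-vs-S6 paired tests, the
three regression hypotheses relating similarity to behavioral improvement,
Benjamini–Hochberg FDR control over the 9 phase × muscle regressions, and
the 9-predictor multiple regression.

Conventions: two-sided tests, α = 0.05; two-sample t-tests pool variances by
default (between-group df = n1 + n2 − 2, i.e. 70 for full 36+36 cohorts),
with Welch available by flag; the mixed ANOVA applies no sphericity
correction by default (Time df = (m−1, (N−g)(m−1)), e.g. (5, 350) for
72 × 6), with Greenhouse–Geisser by flag; standardized regression β is
computed on z-scored variables, so β² = R² for a simple regression.
Subjects with an unstable electrode are dropped only from that muscle's
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05

HYPOTHESES = ("H1", "H2", "H3")  # see run_regressions


@dataclass(frozen=True)
class StatsResult:
    """One test's outcome: statistic, degrees of freedom, p, effect size."""

    label: str
    stat_name: str
    stat: float
    df: tuple
    p: float
    effect_size: float | None = None
    context: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "label": self.label,
            "stat_name": self.stat_name,
            "stat": self.stat,
            "df": list(self.df),
            "p": self.p,
        }
        if self.effect_size is not None:
            d["effect_size"] = self.effect_size
        if self.context:
            d["context"] = dict(self.context)
        return d


def cohens_d_independent(x, y) -> float:
    """Cohen's d with the pooled standard deviation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def two_sample_t(x, y, label: str = "", pooled: bool = True, **context) -> StatsResult:
    """Independent two-sample t-test (pooled variances unless ``pooled=False``)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = x.size + y.size - 2
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        # degenerate but well-defined cases (e.g. identical groups)
        t = 0.0 if x.mean() == y.mean() else np.inf * np.sign(x.mean() - y.mean())
        return StatsResult(label, "t", float(t), (df,),
                           1.0 if t == 0 else 0.0, effect_size=0.0, context=context)
    res = sps.ttest_ind(x, y, equal_var=pooled)
    if not pooled:
        df = float(res.df)
    return StatsResult(label, "t", float(res.statistic), (df,), float(res.pvalue),
                       effect_size=cohens_d_independent(x, y), context=context)


def one_sample_t(x, popmean: float = 0.0, label: str = "", **context) -> StatsResult:
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if x.std(ddof=1) == 0:
        t = 0.0 if x.mean() == popmean else np.inf * np.sign(x.mean() - popmean)
        return StatsResult(label, "t", float(t), (x.size - 1,),
                           1.0 if t == 0 else 0.0, effect_size=0.0, context=context)
    res = sps.ttest_1samp(x, popmean)
    d = float((x.mean() - popmean) / x.std(ddof=1))
    return StatsResult(label, "t", float(res.statistic), (x.size - 1,),
                       float(res.pvalue), effect_size=d, context=context)


def paired_t(x, y, label: str = "", **context) -> StatsResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    if diff.std(ddof=1) == 0:
        t = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
        return StatsResult(label, "t", float(t), (x.size - 1,),
                           1.0 if t == 0 else 0.0, effect_size=0.0, context=context)
    res = sps.ttest_rel(x, y)
    d = float(diff.mean() / diff.std(ddof=1))
    return StatsResult(label, "t", float(res.statistic), (x.size - 1,),
                       float(res.pvalue), effect_size=d, context=context)


# ---------------------------------------------------------------------------
# two-way mixed (split-plot) ANOVA
# ---------------------------------------------------------------------------

def mixed_anova(
    df: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    within: str = "session",
    between: str = "group",
    correction: str | None = None,
) -> pd.DataFrame:
    """Classical mixed repeated-measures ANOVA (Group between, Time within).

    Requires a complete within-subject design (every subject observed at
    every level of ``within``); group sizes may differ.  The between-subject
    sum of squares splits into Group and subject-within-group error; the
    within-subject sum of squares into Time, Time×Group and residual.  Pass
    ``correction="gg"`` for Greenhouse–Geisser-adjusted Time/interaction
    p-values; by default dfs are uncorrected.

    Returns a table with one row per effect (Group, within, interaction):
    SS, df pairs, F and p.
    """
    data = df[[subject, within, between, dv]].dropna()
    counts = data.groupby(subject)[within].nunique()
    m = data[within].nunique()
    if (counts != m).any():
        bad = counts[counts != m].index.tolist()
        raise ValueError(f"incomplete within-subject data for subjects: {bad}")
    groups = data.groupby(subject)[between].first()
    g = groups.nunique()
    subjects = counts.index
    N = len(subjects)
    y = data[dv].to_numpy(float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = data.groupby(subject)[dv].mean()
    ss_between_subj = float(m * ((subj_means - grand) ** 2).sum())
    group_sizes = groups.value_counts()
    group_means = data.groupby(between)[dv].mean()
    ss_group = float(m * (group_sizes * (group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group

    time_means = data.groupby(within)[dv].mean()
    ss_time = float(N * ((time_means - grand) ** 2).sum())
    cell_means = data.groupby([between, within])[dv].mean()
    ss_cells = float(
        sum(group_sizes[gl] * (cell_means[gl, t] - grand) ** 2
            for gl, t in cell_means.index)
    )
    ss_inter = ss_cells - ss_group - ss_time
    ss_resid = ss_total - ss_between_subj - ss_time - ss_inter

    df_group, df_subj = g - 1, N - g
    df_time, df_inter = m - 1, (g - 1) * (m - 1)
    df_resid = (N - g) * (m - 1)

    def fratio(ss_eff, df_eff, ss_err, df_err):
        ms_eff = ss_eff / df_eff if df_eff > 0 else np.nan
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        if ms_err == 0:  # degenerate (noise-free) data
            return 0.0 if ms_eff == 0 else np.inf
        return ms_eff / ms_err

    f_group = fratio(ss_group, df_group, ss_subj_within, df_subj)
    f_time = fratio(ss_time, df_time, ss_resid, df_resid)
    f_inter = fratio(ss_inter, df_inter, ss_resid, df_resid)

    eps = 1.0
    if correction == "gg":
        eps = _greenhouse_geisser_epsilon(data, dv, subject, within)
    rows = [
        {"effect": between, "ss": ss_group, "df1": df_group, "df2": df_subj,
         "F": f_group, "p": float(sps.f.sf(f_group, df_group, df_subj))},
        {"effect": within, "ss": ss_time, "df1": df_time, "df2": df_resid,
         "F": f_time,
         "p": float(sps.f.sf(f_time, eps * df_time, eps * df_resid))},
        {"effect": f"{within}*{between}", "ss": ss_inter, "df1": df_inter,
         "df2": df_resid, "F": f_inter,
         "p": float(sps.f.sf(f_inter, eps * df_inter, eps * df_resid))},
        {"effect": "subject_within_group", "ss": ss_subj_within,
         "df1": df_subj, "df2": np.nan, "F": np.nan, "p": np.nan},
        {"effect": "residual", "ss": ss_resid, "df1": df_resid, "df2": np.nan,
         "F": np.nan, "p": np.nan},
    ]
    out = pd.DataFrame(rows)
    out.attrs["epsilon"] = eps
    return out


def _greenhouse_geisser_epsilon(data, dv, subject, within) -> float:
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    S = np.cov(wide.to_numpy(float), rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    num = (k * (mean_diag - S.mean())) ** 2
    den = (k - 1) * ((S ** 2).sum() - 2 * k * (S.mean(axis=0) ** 2).sum()
                     + k * k * S.mean() ** 2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# multiple-comparison control
# ---------------------------------------------------------------------------

def fdr_adjust(p_values, q: float = 0.05, method: str = "bh"):
    """Benjamini–Hochberg step-up FDR control (Benjamini–Yekutieli by flag).

    Returns ``(rejected, p_adjusted, threshold)`` where ``threshold`` is the
    largest raw p-value declared significant (0.0 if none are).
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    rejected, p_adj, _, _ = multipletests(p, alpha=q, method=sm_method)
    threshold = float(p[rejected].max()) if rejected.any() else 0.0
    return rejected, p_adj, threshold


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def simple_regression(x, y, label: str = "", **context) -> StatsResult:
    """Simple OLS with standardized β (z-scored variables), R² = β²."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations for a regression")
    res = sps.linregress(x, y)
    beta = float(res.rvalue)  # slope of z(y) on z(x) equals Pearson r
    out = StatsResult(label, "beta_standardized", beta, (1, n - 2),
                      float(res.pvalue), effect_size=beta ** 2, context=context)
    return out


def multiple_regression(X: pd.DataFrame, y, label: str = "") -> dict:
    """OLS of ``y`` on all columns of ``X`` (z-scored, with intercept).

    Reports multiple R, overall F and p on (k, n − k − 1) df, and per-
    predictor standardized β with t-based p-values.  Raises on rank-deficient
    predictor matrices, naming the collinear columns.
    """
    import statsmodels.api as sm

    Xz = (X - X.mean()) / X.std(ddof=1)
    yz = (np.asarray(y, float) - np.mean(y)) / np.std(y, ddof=1)
    n, k = Xz.shape
    if n <= k + 1:
        raise ValueError("need n > number of predictors + 1")
    rank = np.linalg.matrix_rank(Xz.to_numpy())
    if rank < k:
        corr = Xz.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = corr.stack().idxmax()
        raise ValueError(f"rank-deficient predictors (collinear: {pair})")
    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    return {
        "label": label,
        "multiple_r": float(np.sqrt(model.rsquared)),
        "r_squared": float(model.rsquared),
        "F": float(model.fvalue),
        "df": (int(model.df_model), int(model.df_resid)),
        "p": float(model.f_pvalue),
        "beta": {c: float(model.params[c]) for c in Xz.columns},
        "beta_p": {c: float(model.pvalues[c]) for c in Xz.columns},
    }


# ---------------------------------------------------------------------------
# study-level batteries
# ---------------------------------------------------------------------------

def balance_tests(baseline: pd.DataFrame, variables, group_col: str = "group",
                  pooled: bool = True) -> list:
    """Two-sample t per baseline variable (group homogeneity checks)."""
    groups = sorted(baseline[group_col].unique())
    if len(groups) != 2:
        raise ValueError("balance tests require exactly two groups")
    a, b = groups
    out = []
    for var in variables:
        x = baseline.loc[baseline[group_col] == a, var].dropna()
        y = baseline.loc[baseline[group_col] == b, var].dropna()
        out.append(two_sample_t(x, y, label=f"balance:{var}", pooled=pooled,
                                variable=var))
    return out


def learning_tests(corrected: pd.DataFrame, metrics=("ga", "fl", "md"),
                   final_session: int = 6, pooled: bool = True) -> list:
    """Learning-effect tests on baseline-corrected final-session scores.

    One-sample t against 0 within each group (did the group improve?) and a
    two-sample t between groups (did one group improve more?), per metric.
    """
    s6 = corrected[corrected["session"] == final_session]
    if s6.empty:
        raise ValueError(f"no rows for session {final_session}")
    out = []
    for metric in metrics:
        col = f"{metric}_corrected"
        by_group = {g: v[col].to_numpy(float) for g, v in s6.groupby("group")}
        for g, vals in sorted(by_group.items()):
            out.append(one_sample_t(vals, 0.0, label=f"learning:{metric}:{g}",
                                    metric=metric, group=g))
        (ga_, a), (gb_, b) = sorted(by_group.items())
        out.append(two_sample_t(a, b, label=f"learning:{metric}:between",
                                pooled=pooled, metric=metric))
    return out


def paired_s1_s6_tests(scores: pd.DataFrame, value_col: str = "r_squared",
                       scope: str = "full_trial", first: int = 1,
                       last: int = 6) -> list:
    """Within-group paired t between initial and final similarity scores."""
    sub = scores[scores["scope"] == scope] if "scope" in scores else scores
    out = []
    for (group, muscle), chunk in sub.groupby(["group", "muscle"]):
        wide = chunk.pivot_table(index="subject", columns="session",
                                 values=value_col)
        wide = wide[[first, last]].dropna()
        out.append(
            paired_t(wide[first], wide[last],
                     label=f"paired_s1_s6:{group}:{muscle}",
                     group=group, muscle=muscle, scope=scope)
        )
    return out


def run_regressions(
    hypothesis: str,
    behavior_deltas: pd.DataFrame,
    similarity: pd.DataFrame,
    similarity_deltas: pd.DataFrame,
    baseline_behavior: pd.DataFrame | None = None,
    response: str = "delta_ga",
    scopes=("full_trial",),
    q: float = 0.05,
) -> pd.DataFrame:
    """The three regression hypotheses, run per group × muscle × scope.

    * ``H1`` — initial similarity (S1) predicting initial performance (S1 GA);
    * ``H2`` — initial similarity (S1) predicting the standardized behavioral
      improvement Δ;
    * ``H3`` — the similarity gain (S6 − S1) predicting the improvement Δ.

    Returns one row per cell with standardized β, R², raw and BH-adjusted p
    (adjustment within each group across the tested cells).
    """
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"hypothesis must be one of {HYPOTHESES}")
    rows = []
    for group in sorted(similarity["group"].unique()):
        cells = []
        for muscle in sorted(similarity["muscle"].unique()):
            for scope in scopes:
                if hypothesis in ("H1", "H2"):
                    pred = similarity[
                        (similarity["group"] == group)
                        & (similarity["muscle"] == muscle)
                        & (similarity["scope"] == scope)
                        & (similarity["session"] == 1)
                    ].set_index("subject")["r_squared"]
                else:
                    pred = similarity_deltas[
                        (similarity_deltas["group"] == group)
                        & (similarity_deltas["muscle"] == muscle)
                        & (similarity_deltas["scope"] == scope)
                    ].set_index("subject")["delta_r_squared"]
                if hypothesis == "H1":
                    if baseline_behavior is None:
                        raise ValueError("H1 needs the baseline behavior table")
                    resp = baseline_behavior[baseline_behavior["session"] == 1] \
                        .set_index("subject")["ga"]
                else:
                    resp = behavior_deltas[behavior_deltas["group"] == group] \
                        .set_index("subject")[response]
                common = pred.index.intersection(resp.index)
                res = simple_regression(
                    pred.loc[common], resp.loc[common],
                    label=f"{hypothesis}:{group}:{muscle}:{scope}")
                cells.append({
                    "hypothesis": hypothesis, "group": group, "muscle": muscle,
                    "scope": scope, "n": len(common), "beta": res.stat,
                    "r_squared": res.effect_size, "p": res.p,
                })
        pvals = [c["p"] for c in cells]
        rejected, p_adj, _ = fdr_adjust(pvals, q=q)
        for c, rej, pa in zip(cells, rejected, p_adj):
            c["p_fdr"] = float(pa)
            c["significant_fdr"] = bool(rej)
        rows.extend(cells)
    return pd.DataFrame(rows)
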