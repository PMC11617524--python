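"""Two-factor mixed-design ANOVA, trial-level t tests and table rendering.

The gaze metrics are analysed with a classical mixed-design ANOVA:
experience (expert/novice) as the between-subjects factor, AOI as the
within-subjects factor, one value per participant x AOI. With a groups of
sizes n1, n2 and b AOIs the design degrees of freedom are (a-1, N-a) for
the between factor and (b-1, (b-1)(N-a)) for the within factor and the
interaction - (1, 22) and (5, 110) at the default cohort size. No
sphericity correction is applied by default (Greenhouse-Geisser is
available behind a flag). Simple main effects of experience at each AOI
use a pooled error term (subjects-within-groups + its interaction),
consistent with the omnibus decomposition.

Kinematic indices are compared with two-sample pooled-variance t tests on
trial-level observations (df = n1 + n2 - 2 = 118 at the default 35 + 85
trials). Pooling trials ignores within-participant correlation; that
choice replicates the reported analysis rather than best practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import AOI_NAMES, ValidationError


@dataclass
class MixedAnovaResult:
    """Omnibus table, simple main effects and pairwise comparisons."""

    anova: pd.DataFrame
    simple_main_effects: pd.DataFrame
    pairwise: pd.DataFrame
    n_subjects: dict
    dropped_subjects: list
    dv: str

    def df_pair(self, source: str) -> tuple[int, int]:
        row = self.anova.set_index("source").loc[source]
        return int(row["df1"]), int(row["df2"])


@dataclass
class GroupComparison:
    """Two-sample pooled-variance t test on trial-level observations."""

    index: str
    t: float
    df: int
    p: float
    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int
    cohens_d: float


def _pivot(table: pd.DataFrame, dv: str, subject: str, within: str,
           between: str):
    wide = table.pivot_table(index=[subject, between], columns=within,
                             values=dv, aggfunc="mean")
    complete = wide.dropna()
    dropped = sorted(set(wide.index.get_level_values(0))
                     - set(complete.index.get_level_values(0)))
    return complete, dropped


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "total_duration_pct",
    subject: str = "participant",
    within: str = "aoi",
    between: str = "group",
    correction: str | None = None,
) -> MixedAnovaResult:
    """Classical mixed-design ANOVA with unbalanced group sizes.

    ``table`` is long-format with one value per subject x within level
    (trials are averaged if repeated). Subjects with any missing cell are
    excluded listwise and reported. ``correction='gg'`` applies the
    Greenhouse-Geisser epsilon to the within-factor dfs.
    """
    wide, dropped = _pivot(table, dv, subject, within, between)
    groups = wide.index.get_level_values(1)
    glabels = list(pd.unique(groups))
    a = len(glabels)
    if a < 2 or any((groups == g).sum() < 2 for g in glabels):
        raise ValidationError("need >= 2 groups with >= 2 subjects each")
    Y = wide.to_numpy(dtype=float)
    N, b = Y.shape
    n_j = np.array([(groups == g).sum() for g in glabels])

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = np.array([Y[groups == g].mean() for g in glabels])
    level_means = Y.mean(axis=0)
    cell_means = np.stack([Y[groups == g].mean(axis=0) for g in glabels])

    ss_total = ((Y - grand) ** 2).sum()
    ss_between_subj = b * ((subj_means - grand) ** 2).sum()
    ss_a = b * (n_j * (group_means - grand) ** 2).sum()
    ss_s = ss_between_subj - ss_a
    ss_b = N * ((level_means - grand) ** 2).sum()
    ss_cells_within = (
        n_j[:, None] * (cell_means - group_means[:, None]) ** 2
    ).sum()
    ss_ab = ss_cells_within - ss_b
    ss_bs = ss_total - ss_between_subj - ss_cells_within

    df_a, df_s = a - 1, N - a
    df_b, df_ab, df_bs = b - 1, (a - 1) * (b - 1), (b - 1) * (N - a)
    eps = 1.0
    if correction == "gg":
        eps = _gg_epsilon(Y, groups, glabels)

    def row(src, ss, df1, df2, err_ss, eps_=1.0):
        ms, mse = ss / df1, err_ss / df2
        f = ms / mse
        p = stats.f.sf(f, df1 * eps_, df2 * eps_)
        return {"source": src, "ss": ss, "df1": df1 * eps_, "df2": df2 * eps_,
                "ms": ms, "F": f, "p": p}

    anova = pd.DataFrame([
        row(between, ss_a, df_a, df_s, ss_s),
        {"source": f"subjects({between})", "ss": ss_s, "df1": df_s,
         "df2": np.nan, "ms": ss_s / df_s, "F": np.nan, "p": np.nan},
        row(within, ss_b, df_b, df_bs, ss_bs, eps),
        row(f"{between}*{within}", ss_ab, df_ab, df_bs, ss_bs, eps),
        {"source": f"{within}*subjects", "ss": ss_bs, "df1": df_bs,
         "df2": np.nan, "ms": ss_bs / df_bs, "F": np.nan, "p": np.nan},
    ])

    # simple main effects of the between factor at each within level,
    # pooled error term: (SS_s + SS_bs) / (df_s + df_bs)
    ms_pool = (ss_s + ss_bs) / (df_s + df_bs)
    df_pool = df_s + df_bs
    sme_rows = []
    for k, lvl in enumerate(wide.columns):
        lvl_group_means = cell_means[:, k]
        lvl_mean = Y[:, k].mean()
        ss_k = (n_j * (lvl_group_means - lvl_mean) ** 2).sum()
        f = (ss_k / df_a) / ms_pool
        sme_rows.append({
            within: lvl,
            "F": f,
            "df1": df_a,
            "df2": df_pool,
            "p": stats.f.sf(f, df_a, df_pool),
            **{f"mean_{g}": cell_means[j, k] for j, g in enumerate(glabels)},
        })
    sme = pd.DataFrame(sme_rows)

    # Bonferroni-adjusted within-group pairwise AOI comparisons (paired t)
    pw_rows = []
    pairs = list(combinations(range(b), 2))
    m = len(pairs)
    for j, g in enumerate(glabels):
        sub = Y[groups == g]
        for k1, k2 in pairs:
            t, p = stats.ttest_rel(sub[:, k1], sub[:, k2])
            pw_rows.append({
                "group": g,
                "level_1": wide.columns[k1],
                "level_2": wide.columns[k2],
                "t": float(t), "df": sub.shape[0] - 1, "p": float(p),
                "p_bonferroni": float(min(1.0, m * p)),
            })
    pairwise = pd.DataFrame(pw_rows)

    return MixedAnovaResult(
        anova, sme, pairwise,
        {g: int(n) for g, n in zip(glabels, n_j)}, dropped, dv,
    )


def _gg_epsilon(Y, groups, glabels) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    b = Y.shape[1]
    S = np.zeros((b, b))
    dof = 0
    for g in glabels:
        sub = Y[groups == g]
        S += (sub.shape[0] - 1) * np.cov(sub, rowvar=False)
        dof += sub.shape[0] - 1
    S /= dof
    mean_diag = np.trace(S) / b
    mean_all = S.mean()
    num = (b * (mean_diag - mean_all)) ** 2
    den = (b - 1) * ((S ** 2).sum() - 2 * b * (S.mean(axis=1) ** 2).sum()
                     + b * b * mean_all ** 2)
    return float(np.clip(num / den, 1.0 / (b - 1), 1.0))


def trial_t_test(
    indices: pd.DataFrame,
    index: str,
    between: str = "group",
    groups: tuple[str, str] = ("expert", "novice"),
) -> GroupComparison:
    """Pooled two-sample t test on trial-level index observations.

    With the default cohort (7 x 5 vs 17 x 5 trials) df = 118.
    """
    x1 = indices.loc[indices[between] == groups[0], index].dropna().to_numpy()
    x2 = indices.loc[indices[between] == groups[1], index].dropna().to_numpy()
    if x1.size < 2 or x2.size < 2:
        raise ValidationError("need >= 2 observations per group")
    t, p = stats.ttest_ind(x1, x2, equal_var=True)
    sp = np.sqrt(((x1.size - 1) * x1.var(ddof=1) + (x2.size - 1) * x2.var(ddof=1))
                 / (x1.size + x2.size - 2))
    return GroupComparison(
        index=index, t=float(t), df=x1.size + x2.size - 2, p=float(p),
        mean_1=float(x1.mean()), sd_1=float(x1.std(ddof=1)), n_1=int(x1.size),
        mean_2=float(x2.mean()), sd_2=float(x2.std(ddof=1)), n_2=int(x2.size),
        cohens_d=float((x1.mean() - x2.mean()) / sp) if sp > 0 else 0.0,
    )


def bonferroni(pvalues, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.atleast_1d(np.asarray(pvalues, dtype=float))
    m = m if m is not None else p.size
    if m < 1:
        raise ValidationError("m must be >= 1")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# reports


def render_report(
    metrics: pd.DataFrame,
    indices: pd.DataFrame,
    out_dir: str | Path,
) -> dict:
    """Write gaze-metric and kinematic-index summary tables plus a text report.

    ``table1.csv``: group x AOI mean (sd) of the four gaze metrics,
    aggregated participant-first. ``table2.csv``: per kinematic index and
    group the range, mean (sd) and median (Q1-Q3) over trial-level
    observations. Raises on an empty cohort.
    """
    if metrics.empty or indices.empty:
        raise ValidationError("cannot render a report for an empty cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    metric_cols = ["total_duration_pct", "n_fixations",
                   "mean_fixation_per_visit_ms", "latency_first_fixation_ms"]
    per_part = metrics.groupby(["group", "participant", "aoi"], sort=False)[
        metric_cols].mean().reset_index()
    rows = []
    for (g, aoi), sub in per_part.groupby(["group", "aoi"], sort=False):
        row = {"group": g, "aoi": aoi}
        for c in metric_cols:
            vals = sub[c].dropna()
            row[f"{c}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{c}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    table1 = pd.DataFrame(rows)
    table1.to_csv(out_dir / "table1.csv", index=False)

    index_cols = [c for c in ("deepest_trunk_flexion_deg", "com_bos_distance_m",
                              "com_velocity_ms") if c in indices.columns]
    rows = []
    for g, sub in indices.groupby("group", sort=False):
        for c in index_cols:
            v = sub[c].dropna().to_numpy()
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append({
                "group": g, "index": c, "n_trials": v.size,
                "min": v.min(), "max": v.max(),
                "mean": v.mean(), "sd": v.std(ddof=1),
                "median": med, "q1": q1, "q3": q3,
            })
    table2 = pd.DataFrame(rows)
    table2.to_csv(out_dir / "table2.csv", index=False)

    lines = ["Assisted sit-to-stand: gaze and kinematic summary", ""]
    lines.append("Gaze metrics (participant means, mean (sd) per group x AOI)")
    for _, r in table1.iterrows():
        lines.append(
            f"  {r['group']:<7s} {r['aoi']:<6s} "
            f"dwell {r['total_duration_pct_mean']:6.2f} "
            f"({r['total_duration_pct_sd']:5.2f}) %   "
            f"fixations {r['n_fixations_mean']:6.2f} "
            f"({r['n_fixations_sd']:5.2f})"
        )
    lines.append("")
    lines.append("Kinematic indices (trial-level)")
    for _, r in table2.iterrows():
        lines.append(
            f"  {r['group']:<7s} {r['index']:<26s} "
            f"range {r['min']:.3f} to {r['max']:.3f}   "
            f"mean (sd) {r['mean']:.3f} ({r['sd']:.3f})   "
            f"median (Q1-Q3) {r['median']:.3f} ({r['q1']:.3f}-{r['q3']:.3f})"
        )
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return {"table1": table1, "table2": table2,
            "summary": out_dir / "summary.txt"}
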