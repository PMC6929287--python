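"""Pattern-level descriptive tables and univariate tests.

Covers the reporting layer: per-pattern service-use and demographic
summaries with a prevalence-weighted total row, Pearson chi-square tests
with adjusted standardized residuals, one-way ANOVA with Bonferroni
post-hoc comparisons rendered as a compact letter display, clinical-cutoff
flags (T >= 65) with a three-level comorbidity category, and the rule-based
mapping from latent-class indices to the five substantive pattern names.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CLASS_NAMES, SCALES

__all__ = [
    "pattern_summary", "prevalence_weighted", "contingency_test",
    "oneway_anova_bonferroni", "clinical_cutoffs", "assign_pattern_names",
    "ChiSquareResult", "AnovaResult",
]


def prevalence_weighted(values, weights) -> float:
    """Prevalence-weighted overall of per-pattern statistics: sum(w v)/sum(w).

    With class sizes as weights this equals the pooled child-level value of
    any per-pattern percentage or mean.
    """
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    return float((w * v).sum() / w.sum())


def pattern_summary(summaries: pd.DataFrame, labels: pd.Series,
                    covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-pattern service-use/demographic table plus a Total row.

    ``summaries`` is the per-child frame from
    :func:`caretraj.trajectories.summarize_cohort`; ``labels`` maps child_id
    to a pattern name or class index; ``covariates`` supplies age and sex.
    """
    cov = covariates.set_index("child_id") if "child_id" in covariates \
        else covariates
    df = summaries.join(labels.rename("pattern")).join(
        cov[["age_at_index", "sex"]])
    if df["pattern"].isna().any():
        raise ValueError("labels must cover every summarized child")
    grand_visits = df["total_visits"].sum()
    rows = {}
    groups = list(df.groupby("pattern"))
    for name, grp in groups + [("Total", df)]:
        if len(grp) == 0:
            raise ValueError(f"empty pattern {name!r}")
        cat = grp["episode_category"].value_counts(normalize=True) * 100
        rows[name] = {
            "n": len(grp),
            "pct": len(grp) / len(df) * 100,
            "pct_male": (grp["sex"] == "M").mean() * 100,
            "age_mean": grp["age_at_index"].mean(),
            "age_sd": grp["age_at_index"].std(),
            "ep0_pct": cat.get("0", 0.0),
            "ep1_pct": cat.get("1", 0.0),
            "ep2plus_pct": cat.get("2+", 0.0),
            "duration_mean": grp["duration_years"].mean(),
            "duration_sd": grp["duration_years"].std(),
            "pct_over_2y": grp["over_two_years"].mean() * 100,
            "visits_mean": grp["total_visits"].mean(),
            "visits_sd": grp["total_visits"].std(),
            "volume_pct": grp["total_visits"].sum() / grand_visits * 100,
        }
    return pd.DataFrame(rows).T


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    adjusted_residuals: pd.DataFrame
    #: squared adjusted residuals, each a 1-df chi-square per cell
    cell_chi2: pd.DataFrame


def contingency_test(labels, factor) -> ChiSquareResult:
    """Pearson chi-square with adjusted standardized residuals
    (O-E)/sqrt(E(1-row/n)(1-col/n)); cells with expected counts below 1 are
    tolerated but flagged via a warning-free report (the caller sees E)."""
    table = pd.crosstab(pd.Series(labels, name="group"),
                        pd.Series(factor, name="factor"))
    obs = table.to_numpy(float)
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("each margin level needs >= 1 observation")
    expected = row * col / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    denom = np.sqrt(expected * (1 - row / n) * (1 - col / n))
    adj = (obs - expected) / denom
    adj_df = pd.DataFrame(adj, index=table.index, columns=table.columns)
    return ChiSquareResult(chi2=chi2, df=df,
                           p=float(stats.chi2.sf(chi2, df)),
                           expected=expected, adjusted_residuals=adj_df,
                           cell_chi2=adj_df ** 2)


def _compact_letters(names, not_different) -> dict:
    """Insert-and-absorb compact letter display: groups sharing a letter are
    not significantly different."""
    letter_sets: list[set] = [set(names)]
    for a, b in combinations(names, 2):
        if not_different[(a, b)]:
            continue
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            sa, sb = s - {b}, s - {a}
            for cand in (sa, sb):
                if not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
    # drop sets absorbed by (subset of) another set
    letter_sets = [s for s in letter_sets
                   if not any(s < other for other in letter_sets)]
    names = list(names)
    letters = {}
    for i, s in enumerate(sorted(letter_sets,
                                 key=lambda s: sorted(names.index(x)
                                                      for x in s))):
        for g in s:
            letters.setdefault(g, "")
            letters[g] += chr(ord("A") + i)
    return letters


@dataclass
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    group_means: pd.Series
    #: Bonferroni-adjusted pairwise p-values (pooled-MSE t tests)
    pairwise_p: dict
    #: groups sharing a letter are not significantly different
    letters: dict


def oneway_anova_bonferroni(values, labels, alpha: float = 0.05
                            ) -> AnovaResult:
    """One-way ANOVA with Bonferroni pairwise t-tests on the pooled MSE and
    a compact letter display of homogeneous groups."""
    df = pd.DataFrame({"y": np.asarray(values, float),
                       "g": np.asarray(labels)})
    groups = [g for g, _ in df.groupby("g")]
    parts = [grp["y"].to_numpy() for _, grp in df.groupby("g")]
    if len(parts) < 2 or min(len(p) for p in parts) < 2:
        raise ValueError("need >= 2 groups with >= 2 values each")
    n = len(df)
    g = len(parts)
    grand = df["y"].mean()
    ss_between = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
    ss_within = sum(((p - p.mean()) ** 2).sum() for p in parts)
    df1, df2 = g - 1, n - g
    if ss_within <= 0:
        raise ValueError("zero within-group variance")
    mse = ss_within / df2
    f = (ss_between / df1) / mse
    p_val = float(stats.f.sf(f, df1, df2))
    m = g * (g - 1) // 2
    pairwise = {}
    not_diff = {}
    for (i, a), (j, b) in combinations(enumerate(groups), 2):
        se = np.sqrt(mse * (1 / len(parts[i]) + 1 / len(parts[j])))
        t = (parts[i].mean() - parts[j].mean()) / se
        praw = 2 * stats.t.sf(abs(t), df2)
        padj = min(1.0, praw * m)
        pairwise[(a, b)] = padj
        not_diff[(a, b)] = padj >= alpha
    letters = _compact_letters(groups, not_diff)
    means = pd.Series({a: p.mean() for a, p in zip(groups, parts)})
    return AnovaResult(f=float(f), df1=df1, df2=df2, p=p_val,
                       group_means=means, pairwise_p=pairwise,
                       letters=letters)


def clinical_cutoffs(covariates: pd.DataFrame, cutoff: float = 65.0
                     ) -> pd.DataFrame:
    """Clinical flags (T >= cutoff) per scale and the three-level
    comorbidity category: 'subclinical' (both Ext and Int below cutoff),
    'either' (exactly one at/above), 'both'."""
    out = pd.DataFrame(index=covariates.index)
    for col in SCALES:
        if covariates[col].isna().any():
            raise ValueError("cutoffs require imputed (complete) covariates")
        out[f"{col}_ge{int(cutoff)}"] = covariates[col] >= cutoff
    ext = out[f"ext_t_ge{int(cutoff)}"]
    internal = out[f"int_t_ge{int(cutoff)}"]
    out["comorbidity"] = np.where(
        ext & internal, "both", np.where(ext | internal, "either",
                                         "subclinical"))
    return out


def assign_pattern_names(summaries: pd.DataFrame, class_labels: pd.Series
                         ) -> dict:
    """Map latent-class indices to the five pattern names from their
    descriptives: the class with the highest mean visit count is
    Ongoing/Intensive-Episodic and the lowest is Minimal; of the remaining
    three, the one whose modal episode category is '2+' is Brief Episodic,
    and the higher-visit of the final two is Intensive, the other Acute.
    """
    df = summaries.join(class_labels.rename("cls"))
    mean_visits = df.groupby("cls")["total_visits"].mean()
    if len(mean_visits) != 5:
        raise ValueError("pattern naming expects exactly 5 classes")
    names = {}
    names[mean_visits.idxmax()] = CLASS_NAMES[4]   # Ongoing/Intensive-Episodic
    names[mean_visits.idxmin()] = CLASS_NAMES[0]   # Minimal
    rest = [c for c in mean_visits.index if c not in names]
    modal = df[df["cls"].isin(rest)].groupby("cls")["episode_category"] \
        .agg(lambda s: s.mode().iloc[0])
    share = df[df["cls"].isin(rest)].groupby("cls")["episode_category"] \
        .agg(lambda s: (s == "2+").mean())
    episodic = [c for c in rest if modal[c] == "2+"]
    if len(episodic) != 1:
        # zero or several candidates: take the largest share of 2+ episodes
        episodic = [share.idxmax()]
    names[episodic[0]] = CLASS_NAMES[2]            # Brief Episodic
    last = [c for c in rest if c not in names]
    last.sort(key=lambda c: mean_visits[c])
    names[last[0]] = CLASS_NAMES[1]                # Acute
    names[last[1]] = CLASS_NAMES[3]                # Intensive
    return names
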