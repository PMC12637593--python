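"""Group statistics used throughout the intrinsic and synaptic analyses.

Wraps the classical tests the figures report: one-way ANOVA with
Tukey-Kramer post hoc comparisons (studentized-range based, Kramer
standard error for unequal group sizes), a two-way mixed (split-plot)
repeated-measures ANOVA with Greenhouse-Geisser correction of the
within-subject terms, unpaired two-tailed t-tests, seeded bootstrap of
sample means, and mean +/- SEM summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "one_way_anova",
    "tukey_kramer",
    "mixed_rm_anova",
    "unpaired_t",
    "bootstrap_means",
    "summarize",
]


@dataclass
class StatResult:
    test: str
    statistic: float
    df: tuple
    p_value: float
    pairwise: Optional[pd.DataFrame] = None
    epsilon: Optional[float] = None
    effects: Optional[pd.DataFrame] = None


def _as_groups(groups) -> list:
    if isinstance(groups, dict):
        return [np.asarray(v, dtype=float) for v in groups.values()]
    return [np.asarray(g, dtype=float) for g in groups]


def one_way_anova(groups) -> StatResult:
    """Classical between-groups F test (unequal n supported).

    ``groups``: dict name -> values, or sequence of arrays.
    """
    gs = _as_groups(groups)
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.ptp(g) == 0 for g in gs) and np.ptp([g[0] for g in gs]) == 0:
        raise ValueError("zero variance everywhere; F undefined")
    f, p = sps.f_oneway(*gs)
    k = len(gs)
    n = sum(len(g) for g in gs)
    return StatResult("one-way ANOVA", float(f), (k - 1, n - k), float(p))


def tukey_kramer(groups) -> StatResult:
    """Tukey-Kramer pairwise comparisons after a one-way design.

    For groups i, j the studentized-range statistic is
    ``q = |mean_i - mean_j| / sqrt(MSE/2 (1/n_i + 1/n_j))`` referred to the
    studentized-range distribution with k groups and N - k error df; with
    equal n this is exactly Tukey's HSD.
    """
    if isinstance(groups, dict):
        names = list(groups.keys())
    else:
        names = [f"group{i}" for i in range(len(groups))]
    gs = _as_groups(groups)
    k = len(gs)
    ns = np.array([len(g) for g in gs])
    n_tot = ns.sum()
    means = np.array([g.mean() for g in gs])
    sse = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_err = n_tot - k
    mse = sse / df_err
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            p = float(sps.studentized_range.sf(q, k, df_err))
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": means[i] - means[j],
                    "q": q,
                    "p_value": min(1.0, p),
                }
            )
    table = pd.DataFrame(rows)
    anova = one_way_anova(groups)
    return StatResult(
        "Tukey-Kramer",
        anova.statistic,
        anova.df,
        anova.p_value,
        pairwise=table,
    )


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-factor sample covariance
    (box epsilon; equals 1 only under perfect sphericity, lower bound
    1/(k-1))."""
    k = wide.shape[1]
    if k < 2:
        raise ValueError("need >= 2 within levels")
    if k == 2:
        return 1.0
    S = np.cov(wide, rowvar=False)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2)
                     + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (k - 1), num / den)))


def mixed_rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
    gg_correction: bool = True,
) -> StatResult:
    """Two-way mixed (split-plot) ANOVA: between-subject factor (e.g.
    genotype), within-subject factor (e.g. interstimulus interval).

    Subjects with incomplete within-factor data are dropped listwise.
    Within-subject effects (condition and interaction) have their df
    multiplied by the Greenhouse-Geisser epsilon when ``gg_correction``.
    Returns the interaction effect as the headline statistic, with all
    three effects in ``effects``.
    """
    df = table[[subject, between, within, dv]].dropna().copy()
    counts = df.groupby(subject)[within].nunique()
    k = df[within].nunique()
    keep = counts[counts == k].index
    dropped = set(counts.index) - set(keep)
    if dropped:
        warnings.warn(
            f"{len(dropped)} subject(s) dropped for incomplete designs",
            stacklevel=2,
        )
    df = df[df[subject].isin(keep)]
    if k < 2:
        raise ValueError("within factor needs >= 2 levels")
    if df[between].nunique() < 2:
        raise ValueError("between factor needs >= 2 levels")

    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("duplicated or missing cells after pivot")
    groups = wide.index.get_level_values(1)
    y = wide.to_numpy()
    n, _ = y.shape
    grand = y.mean()

    subj_means = y.mean(axis=1)
    group_levels = pd.unique(groups)
    a = len(group_levels)
    n_per = np.array([(groups == g).sum() for g in group_levels])

    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    group_means = np.array([subj_means[groups == g].mean() for g in group_levels])
    ss_a = k * (n_per * (group_means - grand) ** 2).sum()
    ss_subj_w = ss_between_subj - ss_a

    col_means = y.mean(axis=0)
    # weighted cell means for the within and interaction terms
    ss_b = 0.0
    ss_ab = 0.0
    for j in range(k):
        for gi, g in enumerate(group_levels):
            cell = y[groups == g, j]
            ss_ab += len(cell) * (
                cell.mean() - group_means[gi] - col_means[j] + grand
            ) ** 2
    ss_b = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err_w = ss_total - ss_between_subj - ss_b - ss_ab

    df_a, df_subj = a - 1, n - a
    df_b, df_ab = k - 1, (a - 1) * (k - 1)
    df_err_w = (n - a) * (k - 1)

    eps = _gg_epsilon(y) if gg_correction else 1.0

    def f_p(ss_num, df_num, ss_den, df_den, corr=1.0):
        F = (ss_num / df_num) / (ss_den / df_den)
        p = float(sps.f.sf(F, df_num * corr, df_den * corr))
        return float(F), p

    F_a, p_a = f_p(ss_a, df_a, ss_subj_w, df_subj)
    F_b, p_b = f_p(ss_b, df_b, ss_err_w, df_err_w, eps)
    F_ab, p_ab = f_p(ss_ab, df_ab, ss_err_w, df_err_w, eps)

    effects = pd.DataFrame(
        [
            {"effect": between, "F": F_a, "df1": df_a, "df2": df_subj,
             "p_value": p_a, "corrected": False},
            {"effect": within, "F": F_b, "df1": df_b * eps,
             "df2": df_err_w * eps, "p_value": p_b, "corrected": gg_correction},
            {"effect": f"{between} x {within}", "F": F_ab, "df1": df_ab * eps,
             "df2": df_err_w * eps, "p_value": p_ab,
             "corrected": gg_correction},
        ]
    )
    return StatResult(
        "mixed RM-ANOVA (GG)" if gg_correction else "mixed RM-ANOVA",
        F_ab,
        (df_ab * eps, df_err_w * eps),
        p_ab,
        epsilon=eps,
        effects=effects,
    )


def unpaired_t(a, b, equal_var: bool = True) -> StatResult:
    """Two-tailed unpaired t-test (pooled variance by default; Welch with
    ``equal_var=False``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        raise ValueError("zero variance and equal means; t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        dof = len(a) + len(b) - 2
    else:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        dof = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
    return StatResult(
        "unpaired t (pooled)" if equal_var else "Welch t",
        float(t),
        (dof,),
        float(p),
    )


def bootstrap_means(
    values, n_iter: int = 1000, seed: Optional[int] = None
) -> np.ndarray:
    """Bootstrap distribution of the sample mean: ``n_iter`` resamples with
    replacement at the original n.  Deterministic given ``seed``."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_iter, x.size))
    return x[idx].mean(axis=1)


def summarize(groups) -> pd.DataFrame:
    """Per-group mean and SEM (s/sqrt(n)); SEM is NaN for n = 1."""
    if isinstance(groups, dict):
        items = groups.items()
    else:
        items = ((f"group{i}", g) for i, g in enumerate(groups))
    rows = []
    for name, vals in items:
        x = np.asarray(vals, dtype=float)
        if x.size < 1:
            raise ValueError(f"group {name!r} is empty")
        sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
        rows.append({"group": name, "n": x.size, "mean": float(x.mean()),
                     "sem": sem})
    return pd.DataFrame(rows)
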