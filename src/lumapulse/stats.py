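"""Group statistics: Wilcoxon rank sum, mixed two-way RM-ANOVA, Sidak.

The Wilcoxon rank-sum test is exact (full enumeration of rank assignments)
for small tie-free samples and switches to the tie- and continuity-corrected
normal approximation otherwise. The repeated-measures ANOVA is the classical
mixed design (between factor: group; within factor: epoch) computed by the
standard sums-of-squares decomposition, with a Greenhouse-Geisser-corrected
p reported alongside the sphericity-assuming one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RankSumResult",
    "RmAnovaResult",
    "wilcoxon_rank_sum",
    "rm_two_way_anova",
    "sidak_adjust",
    "EXACT_MAX_COMBINED_N",
]

# Full enumeration of C(12, 6) = 924 assignments is instant; beyond that the
# normal approximation is already excellent.
EXACT_MAX_COMBINED_N = 12


@dataclass
class RankSumResult:
    statistic: float      # rank sum of the smaller group
    p_value: float        # two-tailed
    method: str           # "exact" | "normal-approximation"
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value,
                "method": self.method, "n1": self.n1, "n2": self.n2}


@dataclass
class RmAnovaResult:
    """Mixed-design ANOVA table plus per-epoch Sidak-adjusted comparisons."""

    f_group: float
    p_group: float
    df_group: tuple[int, int]
    f_epoch: float
    p_epoch: float
    df_epoch: tuple[int, int]
    f_interaction: float
    p_interaction: float
    df_interaction: tuple[int, int]
    gg_epsilon: float
    p_epoch_gg: float
    p_interaction_gg: float
    pairwise: pd.DataFrame  # columns: epoch, p_raw, p_sidak
    n_subjects: dict[str, int] = field(default_factory=dict)
    ss: dict[str, float] = field(default_factory=dict)  # SS decomposition

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("group", self.f_group, self.p_group, *self.df_group, np.nan),
            ("epoch", self.f_epoch, self.p_epoch, *self.df_epoch, self.p_epoch_gg),
            ("interaction", self.f_interaction, self.p_interaction,
             *self.df_interaction, self.p_interaction_gg),
        ]
        return pd.DataFrame(rows, columns=["effect", "F", "p", "df1", "df2",
                                           "p_gg"])


def _exact_two_tailed_p(w_small: float, n_small: int, n_total: int) -> float:
    """Exact two-tailed p by enumerating all rank assignments."""
    ranks = range(1, n_total + 1)
    sums = np.array([sum(c) for c in combinations(ranks, n_small)], dtype=float)
    n_assign = sums.size
    p_le = np.count_nonzero(sums <= w_small) / n_assign
    p_ge = np.count_nonzero(sums >= w_small) / n_assign
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_rank_sum(x, y) -> RankSumResult:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when the combined sample size is at most ``EXACT_MAX_COMBINED_N``
    and the data are tie-free; otherwise a normal approximation with tie
    correction and continuity correction. Identical samples give p = 1 with
    a warning (the statistic carries no information).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.unique(combined).size == 1:
        warnings.warn("all values identical across both groups; p = 1",
                      stacklevel=2)
        n_small = min(n1, n2)
        return RankSumResult(statistic=n_small * (n1 + n2 + 1) / 2.0,
                             p_value=1.0, method="normal-approximation",
                             n1=n1, n2=n2)
    ranks = sps.rankdata(combined)
    rx, ry = ranks[:n1], ranks[n1:]
    if n1 <= n2:
        w_small, n_small = float(rx.sum()), n1
    else:
        w_small, n_small = float(ry.sum()), n2
    has_ties = np.unique(combined).size < combined.size
    n_total = n1 + n2
    if n_total <= EXACT_MAX_COMBINED_N and not has_ties:
        p = _exact_two_tailed_p(w_small, n_small, n_total)
        return RankSumResult(statistic=w_small, p_value=p, method="exact",
                             n1=n1, n2=n2)
    # normal approximation with tie and continuity corrections
    n_other = n_total - n_small
    mean = n_small * (n_total + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n_total * (n_total - 1))
    var = n_small * n_other / 12.0 * (n_total + 1 - tie_term)
    if var <= 0:
        return RankSumResult(statistic=w_small, p_value=1.0,
                             method="normal-approximation", n1=n1, n2=n2)
    z = (abs(w_small - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return RankSumResult(statistic=w_small, p_value=p,
                         method="normal-approximation", n1=n1, n2=n2)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: 1 - (1 - p)^m, clipped to [0, 1]."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError("comparison count m must be >= 1")
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def _gg_epsilon(wide: pd.DataFrame, groups: pd.Series) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    p = wide.shape[1]
    if p < 2:
        return 1.0
    pooled = np.zeros((p, p))
    dof = 0
    for g in groups.unique():
        sub = wide[groups == g].to_numpy()
        if sub.shape[0] < 2:
            continue
        pooled += np.cov(sub, rowvar=False) * (sub.shape[0] - 1)
        dof += sub.shape[0] - 1
    if dof == 0:
        return 1.0
    s = pooled / dof
    # double-centered covariance
    row = s.mean(axis=0, keepdims=True)
    col = s.mean(axis=1, keepdims=True)
    m = s - row - col + s.mean()
    num = np.trace(m) ** 2
    den = (p - 1) * np.sum(m * m)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (p - 1))))


def rm_two_way_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject_id",
    within: str = "epoch",
    between: str = "group",
) -> RmAnovaResult:
    """Mixed two-way ANOVA: between-subject group, within-subject epoch.

    Expects a tidy table with one row per subject x epoch. Subjects missing
    any epoch are dropped with a warning (the design must be balanced over
    epochs within subject). Sphericity is assumed for the primary p-values;
    Greenhouse-Geisser-corrected p's for the within and interaction effects
    are reported alongside. Per-epoch two-sample comparisons (Welch t),
    Sidak-adjusted over epochs, are included when there are exactly two
    groups.
    """
    df = table[[subject, between, within, dv]].dropna()
    epochs = np.sort(df[within].unique())
    p = epochs.size
    if p < 2:
        raise ValueError("need at least 2 within-factor levels")
    # enforce balanced epochs within subject
    counts = df.groupby(subject)[within].nunique()
    incomplete = counts[counts < p].index
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} subject(s) with missing epochs: "
            f"{sorted(map(str, incomplete))}", stacklevel=2)
        df = df[~df[subject].isin(incomplete)]
    wide = df.pivot_table(index=subject, columns=within, values=dv)
    subj_groups = df.drop_duplicates(subject).set_index(subject)[between]
    subj_groups = subj_groups.loc[wide.index]
    group_sizes = subj_groups.value_counts()
    if (group_sizes < 2).any() or group_sizes.size < 2:
        raise ValueError(
            "each group needs at least 2 subjects with complete epochs; "
            f"got {group_sizes.to_dict()}"
        )
    y = wide.to_numpy()            # subjects x epochs
    n_subj, _ = y.shape
    k = group_sizes.size
    grand = y.mean()

    subj_means = y.mean(axis=1)
    epoch_means = y.mean(axis=0)
    g_of = subj_groups.to_numpy()
    group_names = group_sizes.index.to_numpy()

    ss_total = np.sum((y - grand) ** 2)
    ss_between_subj = p * np.sum((subj_means - grand) ** 2)
    ss_group = 0.0
    ss_inter = 0.0
    for g in group_names:
        sel = g_of == g
        n_g = sel.sum()
        gm = y[sel].mean()
        ss_group += p * n_g * (gm - grand) ** 2
        cell = y[sel].mean(axis=0)  # group x epoch means
        ss_inter += n_g * np.sum((cell - gm - epoch_means + grand) ** 2)
    ss_err_b = ss_between_subj - ss_group
    ss_within = ss_total - ss_between_subj
    ss_epoch = n_subj * np.sum((epoch_means - grand) ** 2)
    ss_err_w = ss_within - ss_epoch - ss_inter

    df_group = (k - 1, n_subj - k)
    df_epoch = (p - 1, (n_subj - k) * (p - 1))
    df_inter = ((k - 1) * (p - 1), (n_subj - k) * (p - 1))
    ms_err_b = ss_err_b / df_group[1]
    ms_err_w = ss_err_w / df_epoch[1]

    def _f_p(ss, df1, ms_err, df2):
        if ms_err <= 0:
            return 0.0, 1.0
        f = (ss / df1) / ms_err
        return float(f), float(sps.f.sf(f, df1, df2))

    f_g, p_g = _f_p(ss_group, df_group[0], ms_err_b, df_group[1])
    f_e, p_e = _f_p(ss_epoch, df_epoch[0], ms_err_w, df_epoch[1])
    f_i, p_i = _f_p(ss_inter, df_inter[0], ms_err_w, df_inter[1])

    eps = _gg_epsilon(wide, subj_groups)
    p_e_gg = float(sps.f.sf(f_e, df_epoch[0] * eps, df_epoch[1] * eps)) \
        if f_e > 0 else 1.0
    p_i_gg = float(sps.f.sf(f_i, df_inter[0] * eps, df_inter[1] * eps)) \
        if f_i > 0 else 1.0

    pairwise_rows = []
    if k == 2:
        ga, gb = group_names[:2]
        for e in epochs:
            a = wide.loc[subj_groups[subj_groups == ga].index, e]
            b = wide.loc[subj_groups[subj_groups == gb].index, e]
            if a.nunique() <= 1 and b.nunique() <= 1 and a.iloc[0] == b.iloc[0]:
                p_raw = 1.0
            else:
                p_raw = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
            pairwise_rows.append({"epoch": e, "p_raw": p_raw,
                                  "p_sidak": sidak_adjust(p_raw, p)})
    pairwise = pd.DataFrame(pairwise_rows, columns=["epoch", "p_raw", "p_sidak"])

    return RmAnovaResult(
        f_group=f_g, p_group=p_g, df_group=df_group,
        f_epoch=f_e, p_epoch=p_e, df_epoch=df_epoch,
        f_interaction=f_i, p_interaction=p_i, df_interaction=df_inter,
        gg_epsilon=eps, p_epoch_gg=p_e_gg, p_interaction_gg=p_i_gg,
        pairwise=pairwise,
        n_subjects={str(g): int(n) for g, n in group_sizes.items()},
        ss={"total": float(ss_total), "group": float(ss_group),
            "error_between": float(ss_err_b), "epoch": float(ss_epoch),
            "interaction": float(ss_inter), "error_within": float(ss_err_w)},
    )
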