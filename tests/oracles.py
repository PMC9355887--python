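"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's own code paths: plain arithmetic
on cell means and sorted lists, so that the implementations under test
are checked against a second, independent route.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def integration_oracle(go_rts, n_omissions, p_respond, mean_ssd, mode="ceil"):
    """Sort-and-index reference for the integration method.

    Appends one copy of max(go_rts) per omission, sorts, picks the
    rank = ceil(N*p) smallest (clamped to [1, N]) and subtracts the
    mean SSD.
    """
    pool = sorted(list(go_rts) + [max(go_rts)] * n_omissions)
    n = len(pool)
    pick = {"ceil": math.ceil, "floor": math.floor, "round": round}[mode]
    rank = min(max(pick(n * p_respond), 1), n)
    return pool[rank - 1] - mean_ssd


def staircase_oracle(initial, step, lo, hi, outcomes):
    """Track one SSD staircase through a sequence of inhibited flags,
    returning the list of SSDs *used* on each trial."""
    ssd = initial
    used = []
    for inhibited in outcomes:
        used.append(ssd)
        ssd = ssd + step if inhibited else ssd - step
        ssd = min(hi, max(lo, ssd))
    return used


def mixed_anova_oracle(df, dv="value", subject="subject", within="condition", between="group"):
    """Cell-means sums-of-squares decomposition for a balanced design
    with one within factor and one between factor.

    Returns {"between": F, "within": F, "interaction": F} plus the
    partial eta squared values under the same keys suffixed ``_np2``.
    """
    y = df[dv].to_numpy(float)
    grand = y.mean()
    m = df[within].nunique()
    groups = sorted(df[between].unique())
    n_subj = df[subject].nunique()
    n_per_group = n_subj // len(groups)

    subj_means = df.groupby(subject)[dv].mean()
    group_means = df.groupby(between)[dv].mean()
    cond_means = df.groupby(within)[dv].mean()
    gc_means = df.groupby([between, within])[dv].mean()
    subj_group = df.groupby(subject)[between].first()

    ss_between = m * n_per_group * sum((group_means[g] - grand) ** 2 for g in groups)
    ss_subj = m * sum(
        (subj_means[s] - group_means[subj_group[s]]) ** 2 for s in subj_means.index
    )
    ss_within = n_subj * sum((cm - grand) ** 2 for cm in cond_means)
    ss_inter = n_per_group * sum(
        (gc_means[(g, c)] - group_means[g] - cond_means[c] + grand) ** 2
        for g in groups
        for c in cond_means.index
    )
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_between - ss_subj - ss_within - ss_inter

    df_b, df_s = len(groups) - 1, n_subj - len(groups)
    df_w = m - 1
    df_i = df_b * df_w
    df_e = df_s * df_w
    f_b = (ss_between / df_b) / (ss_subj / df_s)
    f_w = (ss_within / df_w) / (ss_err / df_e)
    f_i = (ss_inter / df_i) / (ss_err / df_e)
    return {
        "between": f_b,
        "within": f_w,
        "interaction": f_i,
        "between_np2": ss_between / (ss_between + ss_subj),
        "within_np2": ss_within / (ss_within + ss_err),
        "interaction_np2": ss_inter / (ss_inter + ss_err),
    }


def rm_anova_oracle(df, dv="value", subject="subject", factors=("emotion", "stimulus")):
    """Sums-of-squares decomposition of a balanced two-way fully
    within-subjects design; each effect is tested against its own
    subject-by-effect interaction."""
    fa, fb = factors
    grand = df[dv].mean()
    a = df[fa].nunique()
    b = df[fb].nunique()
    n = df[subject].nunique()

    def means(*keys):
        return df.groupby(list(keys))[dv].mean()

    m_a, m_b, m_s = means(fa), means(fb), means(subject)
    m_ab, m_sa, m_sb = means(fa, fb), means(subject, fa), means(subject, fb)

    ss_a = n * b * sum((v - grand) ** 2 for v in m_a)
    ss_b = n * a * sum((v - grand) ** 2 for v in m_b)
    ss_ab = n * sum(
        (m_ab[(i, j)] - m_a[i] - m_b[j] + grand) ** 2 for i in m_a.index for j in m_b.index
    )
    ss_sa = b * sum(
        (m_sa[(s, i)] - m_s[s] - m_a[i] + grand) ** 2 for s in m_s.index for i in m_a.index
    )
    ss_sb = a * sum(
        (m_sb[(s, j)] - m_s[s] - m_b[j] + grand) ** 2 for s in m_s.index for j in m_b.index
    )
    ss_total = ((df[dv] - grand) ** 2).sum()
    ss_s = b * a * sum((v - grand) ** 2 for v in m_s)
    ss_sab = ss_total - ss_s - ss_a - ss_b - ss_ab - ss_sa - ss_sb

    f_a = (ss_a / (a - 1)) / (ss_sa / ((n - 1) * (a - 1)))
    f_b = (ss_b / (b - 1)) / (ss_sb / ((n - 1) * (b - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_sab / ((n - 1) * (a - 1) * (b - 1)))
    return {fa: f_a, fb: f_b, "interaction": f_ab}


def one_way_anova_oracle(values, groups):
    """Between/within sums-of-squares for a one-way layout."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    grand = values.mean()
    labels = sorted(set(groups))
    ss_b = sum(
        (values[groups == g].mean() - grand) ** 2 * (groups == g).sum() for g in labels
    )
    ss_w = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum() for g in labels)
    df_b = len(labels) - 1
    df_w = len(values) - len(labels)
    return (ss_b / df_b) / (ss_w / df_w)


def make_records(
    go_rts=(),
    n_omissions=0,
    stops=(),
    subject="s001",
    group="SARS-CoV-2",
):
    """Hand-build a minimal trial-log DataFrame.

    ``stops`` is an iterable of (condition, ssd, rt_or_None, premature)
    tuples; go trials all respond correctly with the given RTs.
    """
    rows = []
    trial = 0
    for rt in go_rts:
        rows.append(
            dict(subject=subject, group=group, block=1, trial=trial, trial_type="go",
                 condition="none", arrow="left", ssd=np.nan, response="left", rt=float(rt),
                 premature=False, correct=True, practice=False)
        )
        trial += 1
    for _ in range(n_omissions):
        rows.append(
            dict(subject=subject, group=group, block=1, trial=trial, trial_type="go",
                 condition="none", arrow="left", ssd=np.nan, response="none", rt=np.nan,
                 premature=False, correct=False, practice=False)
        )
        trial += 1
    for cond, ssd, rt, premature in stops:
        responded = rt is not None
        rows.append(
            dict(subject=subject, group=group, block=1, trial=trial, trial_type="stop",
                 condition=cond, arrow="left", ssd=float(ssd),
                 response="left" if responded else "none",
                 rt=float(rt) if responded else np.nan,
                 premature=bool(premature), correct=not responded, practice=False)
        )
        trial += 1
    return pd.DataFrame(rows)
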