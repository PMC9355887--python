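"""Full inferential battery over a cohort's per-subject SST summaries.

Runs the standard analysis sequence for a three-group, two-condition
stop-signal cohort: race-model verification, inhibition-rate ANOVA,
go-accuracy checks, go-RT group comparison, SSD and SSRT mixed ANOVAs
with Bonferroni post hocs, per-group paired t tests with JZS Bayes
factors, and the SSRT-index regression with the >2-sigma outlier pass.
The result is an ordered bundle that :func:`sstlab.io.write_report`
renders to text and CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as st
from .errors import ZeroVarianceError

__all__ = ["PREDICTOR_COLUMNS", "run_battery", "long_condition_table"]

#: Personality predictors entering the SSRT-index regression.
PREDICTOR_COLUMNS = ["STAI-Y2", "BIS-motor", "BIS-attentional", "BIS-nonplanning"]


def long_condition_table(summary: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Wide per-condition columns (``<measure>_emotional`` / ``_neutral``)
    to a long (subject, group, condition, value) table."""
    frames = []
    for cond in ("emotional", "neutral"):
        frames.append(
            pd.DataFrame(
                {
                    "subject": summary["subject"],
                    "group": summary["group"],
                    "condition": cond,
                    "value": summary[f"{measure}_{cond}"],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.dropna(subset=["value"])


def _group_paired_tests(summary: pd.DataFrame, measure: str, seed: int) -> pd.DataFrame:
    """Per-group emotional-vs-neutral paired t with a JZS Bayes factor."""
    rows = []
    for group, frame in summary.groupby("group", sort=True):
        x = frame[f"{measure}_emotional"].to_numpy(float)
        y = frame[f"{measure}_neutral"].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        try:
            res = st.paired_t(x, y)
            bf = st.jzs_bf_ttest(res.statistic, len(x), design="paired")
            rows.append(
                {
                    "group": group,
                    "n": len(x),
                    "t": res.statistic,
                    "df": res.df[0],
                    "p": res.p,
                    "bf10": bf.bf10,
                }
            )
        except ZeroVarianceError:
            rows.append(
                {"group": group, "n": len(x), "t": np.nan, "df": len(x) - 1, "p": np.nan, "bf10": np.nan}
            )
    return pd.DataFrame(rows)


def run_battery(
    summary: pd.DataFrame, covariates: pd.DataFrame, seed: int = 0
) -> dict:
    """Run the full statistical sequence on a cohort summary table.

    ``summary`` is the output of :func:`sstlab.ssrt.summarize_cohort`;
    ``covariates`` carries one row per subject with the questionnaire
    scores.  ``seed`` fixes the Monte-Carlo stream of the g-prior ANOVA
    Bayes factors.  Returns an ordered dict of named results.
    """
    bundle: dict = {}
    merged = summary.merge(covariates, on="subject", how="inner", suffixes=("", "_cov"))

    race = pd.DataFrame(
        {
            "subject": summary["subject"],
            "mean_unsuccessful_stop_rt": summary["mean_unsuccessful_stop_rt"],
            "mean_go_rt": summary["mean_go_rt"],
            "assumption_met": summary["race_assumption_met"],
        }
    )
    bundle["race_check"] = {
        "table": race,
        "fraction_met": float(race["assumption_met"].fillna(False).mean()),
    }

    for measure, label in (("inhibition_rate", "inhibition rate"), ("mean_ssd", "SSD"), ("ssrt", "SSRT")):
        long = long_condition_table(summary, measure)
        complete = long.groupby("subject")["value"].count() == 2
        long = long[long["subject"].map(complete)]
        anova = st.mixed_anova_2x3(long, posthoc=True)
        wide = long.pivot(index="subject", columns="condition", values="value")
        groups = summary.set_index("subject").loc[wide.index, "group"]
        bf_group = st.default_bf_anova(
            wide.mean(axis=1).to_numpy(), groups.to_numpy(), seed=seed
        )
        entry = {"anova": anova, "bf_group": bf_group}
        if measure == "ssrt":
            entry["paired_by_group"] = _group_paired_tests(summary, "ssrt", seed)
        bundle[f"{label} analysis"] = entry

    acc = summary.dropna(subset=["correct_go"])
    correct = acc["correct_go"].to_numpy(float)
    bundle["go accuracy analysis"] = {
        "anova": {
            "between": st.one_way_anova(correct, acc["group"].to_numpy())
        },
        "paired_correct_vs_incorrect": _safe_paired(correct, 1.0 - correct),
        "bf_group": st.default_bf_anova(correct, acc["group"].to_numpy(), seed=seed),
    }

    rt = summary.dropna(subset=["go_rt"])
    bundle["go RT analysis"] = {
        "anova": {"between": st.one_way_anova(rt["go_rt"].to_numpy(float), rt["group"].to_numpy())},
        "bf_group": st.default_bf_anova(
            rt["go_rt"].to_numpy(float), rt["group"].to_numpy(), seed=seed
        ),
    }

    reg_data = merged.dropna(subset=["ssrt_index"] + PREDICTOR_COLUMNS)
    if len(reg_data) > len(PREDICTOR_COLUMNS) + 1:
        bundle["ssrt index regression"] = st.regress_ssrt_index(
            reg_data["ssrt_index"].to_numpy(float), reg_data[PREDICTOR_COLUMNS]
        )
    return bundle


def _safe_paired(x: np.ndarray, y: np.ndarray):
    try:
        return st.paired_t(x, y)
    except ZeroVarianceError:
        return None
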