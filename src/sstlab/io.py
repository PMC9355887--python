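"""File formats, schema validation, report rendering and run manifests.

All files are plain CSV (comma-separated, UTF-8, mandatory header,
missing values as empty fields) or JSON/YAML; durations are
milliseconds.  Trial logs use the column set of
:data:`sstlab.simulate.TRIAL_COLUMNS` and are validated row by row on
read so that invariant violations name the offending row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .protocol import SessionConfig
from .simulate import TRIAL_COLUMNS, CohortSpec
from .stats import BayesResult, RegressionResult, StatResult

__all__ = [
    "read_trial_log",
    "write_trial_log",
    "validate_trial_frame",
    "read_config",
    "RunManifest",
    "write_report",
    "format_stat",
]


# --------------------------------------------------------------------------
# trial logs
# --------------------------------------------------------------------------


def write_trial_log(records: pd.DataFrame, path) -> None:
    """Write a trial log CSV in canonical column order."""
    records[TRIAL_COLUMNS].to_csv(path, index=False)


def validate_trial_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate trial-record invariants, raising :class:`SchemaError`
    naming the first offending row (0-based data row)."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    ttype = df["trial_type"].astype(str)
    bad_type = ~ttype.isin(["go", "stop"])
    if bad_type.any():
        raise SchemaError("trial_type must be 'go' or 'stop'", int(np.flatnonzero(bad_type)[0]))
    response = df["response"].astype(str)
    rt = pd.to_numeric(df["rt"], errors="coerce")
    ssd = pd.to_numeric(df["ssd"], errors="coerce")
    premature = df["premature"].astype(bool)
    is_go = ttype == "go"
    responded = response != "none"

    checks = [
        (is_go & ssd.notna(), "go trial carries an SSD"),
        (is_go & (df["condition"].astype(str) != "none"), "go trial has a stop condition"),
        (~is_go & ssd.isna(), "stop trial is missing its SSD"),
        (~responded & rt.notna(), "trial without a response carries an RT"),
        (responded & rt.isna(), "responded trial is missing its RT"),
        (~is_go & premature & (rt >= ssd), "premature stop response has rt >= ssd"),
        (~is_go & responded & rt.notna() & (rt < ssd) & ~premature,
         "stop response before the stop signal is not flagged premature"),
        (is_go & premature, "go trial flagged premature"),
    ]
    for mask, msg in checks:
        mask = mask.fillna(False)
        if mask.any():
            raise SchemaError(msg, int(np.flatnonzero(mask.to_numpy())[0]))
    return df


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Returns the validated frame with a ``row`` column (0-based position
    in the file body) attached for error reporting downstream.
    """
    df = pd.read_csv(path, dtype={"response": str, "condition": str})
    df = df.reset_index().rename(columns={"index": "row"})
    for col in ("premature", "correct", "practice"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().isin(["true", "1", "1.0"])
    validate_trial_frame(df)
    return df


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def read_config(path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)


def session_config_from_file(path) -> SessionConfig:
    data = read_config(path) or {}
    session = data.get("session", data)
    fields = {f.name for f in dataclasses.fields(SessionConfig)}
    kwargs = {k: v for k, v in session.items() if k in fields}
    if "stop_stimuli" in kwargs:
        kwargs["stop_stimuli"] = tuple(kwargs["stop_stimuli"])
    return SessionConfig(**kwargs)


def cohort_spec_from_file(path) -> CohortSpec:
    data = read_config(path) or {}
    cohort = data.get("cohort", {})
    fields = {f.name for f in dataclasses.fields(CohortSpec)}
    kwargs = {k: v for k, v in cohort.items() if k in fields}
    for key in ("groups", "conditions"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return CohortSpec(**kwargs)


# --------------------------------------------------------------------------
# run manifest
# --------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance of one pipeline stage: config hash, master seed,
    package version, timestamp, and the stage's file paths.  Identical
    config + seed yield byte-identical trial logs."""

    stage: str
    seed: int | None
    config_hash: str
    inputs: dict[str, str]
    outputs: dict[str, str]
    version: str = ""
    timestamp: str = ""

    @staticmethod
    def config_digest(config) -> str:
        if dataclasses.is_dataclass(config):
            config = dataclasses.asdict(config)
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def create(cls, stage, seed, config, inputs, outputs):
        from . import __version__

        return cls(
            stage=stage,
            seed=seed,
            config_hash=cls.config_digest(config),
            inputs={k: str(v) for k, v in inputs.items()},
            outputs={k: str(v) for k, v in outputs.items()},
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


# --------------------------------------------------------------------------
# report rendering
# --------------------------------------------------------------------------


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "p = n/a"
    return "p < 0.001" if p < 0.001 else f"p = {p:.3f}"


def _fmt_df(v: float) -> str:
    return f"{v:.0f}" if float(v).is_integer() else f"{v:.2f}"


def format_stat(result: StatResult) -> str:
    """Render a StatResult in the conventional reporting style, e.g.
    ``F(1,87) = 15.08, p < 0.001, np2 = 0.147``."""
    letter = {1: "t", 2: "F"}.get(len(result.df), "stat")
    if result.name.startswith("chi"):
        letter = "chi2"
    dfs = ",".join(_fmt_df(d) for d in result.df)
    parts = [f"{letter}({dfs}) = {result.statistic:.3f}", _fmt_p(result.p)]
    if result.eta_p2 is not None:
        parts.append(f"np2 = {result.eta_p2:.3f}")
    return ", ".join(parts)


def _fmt_bayes(b: BayesResult) -> str:
    line = f"BF10 = {b.bf10:.3f}, BF01 = {b.bf01:.3f} [{b.prior}]"
    if b.mc_error is not None:
        line += f" (MC SE {b.mc_error:.2e})"
    return line


def _fmt_regression(reg: RegressionResult, lines: list[str]) -> None:
    ini, fin = reg.initial, reg.final
    lines.append(
        f"  initial fit: R2 = {ini.r2:.3f}, F({_fmt_df(ini.df[0])},{_fmt_df(ini.df[1])})"
        f" = {ini.f:.3f}, {_fmt_p(ini.f_p)}"
    )
    lines.append(
        f"  outliers removed (|std resid| > 2): {len(reg.removed)}"
        + (f" -> rows {list(reg.removed)}" if reg.removed else "")
    )
    lines.append(
        f"  final fit (n = {fin.n}): R2 = {fin.r2:.3f},"
        f" F({_fmt_df(fin.df[0])},{_fmt_df(fin.df[1])}) = {fin.f:.3f}, {_fmt_p(fin.f_p)}"
    )
    for _, row in fin.coef.iterrows():
        lines.append(
            f"    {row['term']}: b = {row['b']:.3f}, t = {row['t']:.3f}, {_fmt_p(row['p'])}"
        )


def write_report(bundle: dict, path, csv_dir=None) -> str:
    """Render an analysis bundle to a deterministic plain-text report,
    optionally writing each tabular result as CSV next to it.

    Sections follow the canonical analysis order (race check first,
    regression last).  Rendering the same bundle twice yields identical
    bytes.  Returns the report text.
    """
    lines = ["Stop-signal task analysis report", "=" * 34, ""]
    for section, content in bundle.items():
        lines.append(section)
        lines.append("-" * len(section))
        if section == "race_check":
            frac = content["fraction_met"]
            lines.append(f"  race-model assumption met for {frac * 100:.1f}% of subjects")
        elif isinstance(content, RegressionResult):
            _fmt_regression(content, lines)
        elif isinstance(content, dict):
            anova = content.get("anova", {})
            for key in ("within", "between", "interaction"):
                if key in anova:
                    lines.append(f"  {key}: {format_stat(anova[key])}")
            if content.get("paired_correct_vs_incorrect") is not None:
                lines.append(
                    "  paired correct vs incorrect: "
                    + format_stat(content["paired_correct_vs_incorrect"])
                )
            if "bf_group" in content:
                lines.append("  group Bayes factor: " + _fmt_bayes(content["bf_group"]))
            if "paired_by_group" in content:
                for _, row in content["paired_by_group"].iterrows():
                    lines.append(
                        f"  {row['group']}: t({_fmt_df(row['df'])}) = {row['t']:.3f}, "
                        f"{_fmt_p(row['p'])}, BF10 = {row['bf10']:.3f}"
                    )
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    if csv_dir is not None:
        csv_dir = Path(csv_dir)
        csv_dir.mkdir(parents=True, exist_ok=True)
        for section, content in bundle.items():
            slug = section.replace(" ", "_")
            if section == "race_check":
                content["table"].to_csv(csv_dir / f"{slug}.csv", index=False)
            elif isinstance(content, RegressionResult):
                content.final.coef.to_csv(csv_dir / f"{slug}_coefficients.csv", index=False)
            elif isinstance(content, dict) and "paired_by_group" in content:
                content["paired_by_group"].to_csv(csv_dir / f"{slug}_paired.csv", index=False)
    return text
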