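"""CSV readers/writers for the pipeline's tabular artifacts.

All files are UTF-8, comma-separated with a header row and "." decimal
separator.  Dialects:

* trial log — participant_id, delay_label, delay_days, trial_index,
  immediate_offer, choice (I|D)
* indifference points — participant_id, delay_days, subjective_value
* cohort — one row per participant (see ``write_codebook`` for the fields);
  missing values as empty cells
* model report — one row per coefficient, plus a human-readable text mirror
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .inference import LrtResult, ModelFit

__all__ = [
    "write_trial_log",
    "read_trial_log",
    "indifference_frame",
    "write_indifference",
    "write_cohort",
    "read_cohort",
    "write_codebook",
    "write_model_report",
]

_CSV_KW = dict(index=False, encoding="utf-8")

TRIAL_LOG_COLUMNS = ["participant_id", "delay_label", "delay_days", "trial_index",
                     "immediate_offer", "choice"]

CODEBOOK = {
    "participant_id": "opaque identifier",
    "country": "residence country (grouping factor, 13 levels)",
    "age": "years",
    "gender": "category: female / male / ...",
    "education": "category: secondary / undergraduate / postgraduate",
    "essential_worker": "1 = essential worker during the pandemic",
    "relative_income": "self-rated income relative to own country, 0-100",
    "gad7_total": "GAD-7 item sum, 0-21",
    "phq9_total": "PHQ-9 item sum, 0-27",
    "ius12_total": "IUS-12 item sum, 0-60",
    "distress_index": "z(GAD-7) + z(PHQ-9), analytic-sample standardization",
    "auc": "delay-discounting area under the normalized curve, (0, 1]",
    "vaccination_status": "raw code 1-5 (1/2 vaccinated, 3/4 not, 5 prefer not to say)",
    "vaccinated": "binary recode of vaccination_status (empty = missing)",
    "booster_raw": "raw booster response 0 = no, 1 = yes, 2 = prefer not to say",
    "booster_willing": "binary outcome (empty = missing)",
    "attention_pass": "1 = passed all attention checks",
}


def write_trial_log(log: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    log.reindex(columns=TRIAL_LOG_COLUMNS).to_csv(path, **_CSV_KW)
    return path


def read_trial_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"choice": str}, float_precision="round_trip")


def indifference_frame(participant_ids, profiles) -> pd.DataFrame:
    rows = [
        (pid, pt.delay.days, pt.subjective_value)
        for pid, profile in zip(participant_ids, profiles)
        for pt in profile.points
    ]
    return pd.DataFrame(rows, columns=["participant_id", "delay_days", "subjective_value"])


def write_indifference(points: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    points.to_csv(path, **_CSV_KW)
    return path


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, **_CSV_KW)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    # exact float round-trip keeps a rerun from disk bit-identical to the
    # in-memory pipeline
    return pd.read_csv(path, float_precision="round_trip")


def write_codebook(path: str | Path) -> Path:
    path = Path(path)
    width = max(len(k) for k in CODEBOOK)
    lines = [f"{name:<{width}}  {desc}" for name, desc in CODEBOOK.items()]
    path.write_text("Cohort CSV codebook\n" + "\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_model_report(
    fit: ModelFit,
    csv_path: str | Path,
    txt_path: str | Path | None = None,
    lrt_result: LrtResult | None = None,
) -> Path:
    """Serialize a fit as CSV (one row per coefficient) and a text table."""
    csv_path = Path(csv_path)
    fit.params.reset_index().to_csv(csv_path, **_CSV_KW)
    if txt_path is not None:
        tab = fit.params.copy()
        tab.columns = ["b", "SE", "z", "p", "OR", "CI low", "CI high"]
        lines = [
            "Multilevel logistic regression: fixed effects",
            tab.round(3).to_string(),
            "",
            "Random effects",
            f"  intercept error variance (group): {fit.intercept_variance:.3f}"
            f"   SD: {fit.intercept_sd:.3f}",
            "",
            f"log-likelihood: {fit.loglik:.2f}   n_obs: {fit.n_obs}   "
            f"n_groups: {fit.n_groups}",
            f"method: {fit.diagnostics.get('method', '?')} "
            f"({fit.diagnostics.get('n_nodes', '?')} nodes), "
            f"converged: {fit.diagnostics.get('converged')}",
        ]
        if fit.scaling:
            lines.append("scaled predictors (mean, sd): " + ", ".join(
                f"{k}=({m:.3f}, {s:.3f})" for k, (m, s) in fit.scaling.items()
            ))
        if lrt_result is not None:
            lines += [
                "",
                f"LRT vs random-intercept-only null: chi2({lrt_result.df}) = "
                f"{lrt_result.statistic:.2f}, p = {lrt_result.p:.4g}",
            ]
        Path(txt_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return csv_path
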