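"""Questionnaire scoring, outcome coding, exclusions, and rater agreement.

Covers the measurement side of the study: GAD-7 / PHQ-9 / IUS-12 item sums, a
psychological distress index (z-scored GAD-7 + z-scored PHQ-9 totals),
recoding of raw vaccination / booster responses to binary-or-missing
variables, the two-step analytic-sample exclusion pipeline (unvaccinated
first, then missing booster response), and percent agreement / Cohen's kappa
for categorical rater tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "INSTRUMENTS",
    "QuestionnaireResponse",
    "AgreementTable",
    "score_instrument",
    "attention_pass",
    "distress_index",
    "code_vaccination",
    "code_booster",
    "code_outcomes",
    "analytic_sample",
    "agreement",
    "GENDER_CODES",
    "EDUCATION_LEVELS",
    "encode_gender",
    "encode_education",
]

#: instrument -> (n_items, min rating, max rating)
INSTRUMENTS: dict[str, tuple[int, int, int]] = {
    "GAD7": (7, 0, 3),
    "PHQ9": (9, 0, 3),
    "IUS12": (12, 0, 5),
}

#: default numeric codings for the regression (configurable at the call site)
GENDER_CODES: dict[str, float] = {"female": 1.0, "male": 0.0}
EDUCATION_LEVELS: dict[str, int] = {"secondary": 0, "undergraduate": 1, "postgraduate": 2}


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One participant's ratings on a single instrument."""

    instrument: str
    items: tuple[int, ...]


@dataclass(frozen=True)
class AgreementTable:
    """Square contingency matrix of category counts between two raters."""

    counts: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValidationError(f"agreement table must be square, got shape {c.shape}")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValidationError("agreement table cells must be nonnegative integers")
        if self.labels and len(self.labels) != c.shape[0]:
            raise ValidationError("label count must match table dimension")


def score_instrument(resp: QuestionnaireResponse) -> int:
    """Sum of item ratings; validates item count and per-item range."""
    try:
        n_items, lo, hi = INSTRUMENTS[resp.instrument]
    except KeyError:
        raise ValidationError(
            f"unknown instrument {resp.instrument!r}; expected one of {sorted(INSTRUMENTS)}"
        ) from None
    if len(resp.items) != n_items:
        raise ValidationError(
            f"{resp.instrument} requires {n_items} items, got {len(resp.items)}"
        )
    for i, rating in enumerate(resp.items, start=1):
        if rating is None or not float(rating).is_integer() or not lo <= rating <= hi:
            raise ValidationError(
                f"{resp.instrument} item {i} rating {rating!r} outside [{lo}, {hi}]"
            )
    return int(sum(resp.items))


def attention_pass(pairs: Iterable[tuple[object, object]]) -> bool:
    """True iff every (expected, given) attention-check pair matches."""
    return all(expected == given for expected, given in pairs)


def distress_index(gad7_totals, phq9_totals) -> np.ndarray:
    """z(GAD-7 total) + z(PHQ-9 total), sample sd with n−1 denominator.

    Standardization uses the sample the vectors describe; by construction the
    index has sample mean 0.  The index is invariant to affine rescaling of
    the raw totals.
    """
    gad = np.asarray(gad7_totals, dtype=float)
    phq = np.asarray(phq9_totals, dtype=float)
    if gad.shape != phq.shape or gad.ndim != 1:
        raise ValidationError("gad7 and phq9 totals must be equal-length 1-d vectors")
    if gad.size < 2:
        raise DegenerateInputError("need at least 2 participants to standardize")
    out = np.zeros_like(gad)
    for name, v in (("GAD7", gad), ("PHQ9", phq)):
        sd = v.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError(f"{name} totals have zero variance; z-score undefined")
        out += (v - v.mean()) / sd
    return out


def code_vaccination(code: int):
    """Raw 1–5 vaccination code -> True (vaccinated), False, or pd.NA.

    1 = all necessary doses, 2 = requires another dose (both vaccinated);
    3 = planning to, 4 = not planning to (both unvaccinated);
    5 = prefer not to say (missing).
    """
    if code in (1, 2):
        return True
    if code in (3, 4):
        return False
    if code == 5:
        return pd.NA
    raise ValidationError(f"unknown vaccination code {code!r}; expected 1..5")


def code_booster(code: int):
    """Raw booster code -> 1 (yes), 0 (no), or pd.NA (prefer not to say)."""
    if code == 0:
        return 0
    if code == 1:
        return 1
    if code == 2:
        return pd.NA
    raise ValidationError(f"unknown booster code {code!r}; expected 0, 1 or 2")


def code_outcomes(roster: pd.DataFrame) -> pd.DataFrame:
    """Add binary-or-missing ``vaccinated`` and ``booster_willing`` columns.

    Expects raw columns ``vaccination_status`` (1–5) and ``booster_raw``
    (0/1/2, NaN if never asked).  Returns a new frame; the input is untouched.
    """
    out = roster.copy()
    out["vaccinated"] = pd.array(
        [code_vaccination(int(c)) for c in roster["vaccination_status"]], dtype="boolean"
    )
    out["booster_willing"] = pd.array(
        [pd.NA if pd.isna(c) else code_booster(int(c)) for c in roster["booster_raw"]],
        dtype="Int64",
    )
    return out


def analytic_sample(roster: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Two-step exclusion: drop unvaccinated, then missing booster response.

    Records whose vaccination status is missing ("prefer not to say") were
    never asked the booster question, so they fall out at the second step with
    the non-responders.  Returns the kept rows and a count table whose entries
    sum to the input n.
    """
    if "vaccinated" not in roster.columns or "booster_willing" not in roster.columns:
        roster = code_outcomes(roster)
    # missing vaccination status (code 5) survives step 1 and is dropped with
    # the booster non-responders in step 2
    unvaccinated = (roster["vaccinated"] == False).fillna(False)  # noqa: E712
    after_vax = roster.loc[~unvaccinated.to_numpy(dtype=bool)]
    missing = after_vax["booster_willing"].isna()
    kept = after_vax.loc[~missing]
    counts = {
        "input": int(len(roster)),
        "excluded_unvaccinated": int(unvaccinated.sum()),
        "excluded_missing_booster": int(missing.sum()),
        "kept": int(len(kept)),
    }
    return kept, counts


def agreement(table: AgreementTable | np.ndarray) -> tuple[float, float]:
    """Percent agreement and Cohen's kappa from a rater contingency table.

    kappa = (p_o − p_e) / (1 − p_e), with observed agreement p_o = trace/total
    and chance agreement p_e from the product of the marginals.
    """
    counts = np.asarray(table.counts if isinstance(table, AgreementTable) else table, dtype=float)
    if isinstance(table, np.ndarray) and (counts.ndim != 2 or counts.shape[0] != counts.shape[1]):
        raise ValidationError(f"agreement table must be square, got shape {counts.shape}")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("agreement table is empty")
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) / total) @ (counts.sum(axis=0) / total))
    if p_e >= 1.0 - 1e-15:
        raise DegenerateInputError("chance agreement p_e = 1; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return float(p_o), float(kappa)


def encode_gender(values: Sequence[str], mapping: Mapping[str, float] = GENDER_CODES) -> pd.Series:
    """Map gender categories to model codes; unmapped categories become NA."""
    return pd.Series([mapping.get(v, np.nan) for v in values], dtype=float)


def encode_education(values: Sequence[str], mapping: Mapping[str, int] = EDUCATION_LEVELS) -> pd.Series:
    """Ordinal 0/1/2 education score (secondary/undergraduate/postgraduate)."""
    try:
        return pd.Series([mapping[v] for v in values], dtype=float)
    except KeyError as e:
        raise ValidationError(f"unknown education level {e.args[0]!r}") from None
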