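"""Gold-standard ethnicity from multi-response survey questions.

The reference ("gold standard") against which surname-derived ethnicity is
validated is self-reported ethnicity from a weighted cross-sectional health
survey.  Each respondent answers two multi-response questions — one about
ancestral ethnic groups and one about current cultural/racial background.
A respondent is resolved to a target group G when at least one of the two
questions has *exactly one* response and that response is G's token; every
other pattern (multiple responses, no target token, conflicting single
responses) falls to the residual group.

Person-level weights give the number of population members each respondent
represents.  When cycles from several survey years are pooled, each weight
is divided by the number of cycles so the pooled weights still sum to one
population.  All downstream test characteristics are ratios of weighted
sums, so this rescaling leaves them unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Respondent",
    "resolve_self_report",
    "resolve_respondents",
    "pool_weights",
    "read_survey",
    "write_survey",
    "SURVEY_COLUMNS",
]

SURVEY_COLUMNS = [
    "person_id",
    "cycle",
    "weight",
    "q_ancestry",
    "q_background",
    "sex",
    "age_band",
    "immigration",
]


@dataclass(frozen=True)
class Respondent:
    """One survey respondent.

    ``answers_ancestry`` / ``answers_background`` hold the multi-response
    tokens of the two ethnicity questions (set semantics: a duplicated
    identical answer is still one response).  ``weight`` is the person-level
    survey weight, strictly positive.
    """

    person_id: str
    cycle: str
    weight: float
    answers_ancestry: frozenset[str]
    answers_background: frozenset[str]
    sex: str = ""
    age_band: str = ""
    immigration: str = ""

    def __post_init__(self):
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        object.__setattr__(self, "answers_ancestry", frozenset(self.answers_ancestry))
        object.__setattr__(self, "answers_background", frozenset(self.answers_background))


def _single_response(answers: Iterable[str]) -> str | None:
    toks = {str(a).strip().casefold() for a in answers if str(a).strip()}
    if len(toks) == 1:
        return next(iter(toks))
    return None


def resolve_self_report(
    answers_ancestry: Iterable[str],
    answers_background: Iterable[str],
    target_groups: Sequence[str],
    default_label: str,
    *,
    conflict_precedence: bool = False,
) -> str:
    """Resolve the two multi-response answers into one group label.

    A target group G is *triggered* when either question, after collapsing
    repeated identical tokens, has exactly one response equal
    (case-insensitively) to G's token.  Exactly one trigger → that group;
    no trigger → ``default_label``.  If distinct target groups are each
    triggered (one question a single "South Asian", the other a single
    "Chinese"), the conservative default assigns ``default_label`` with a
    logged warning; pass ``conflict_precedence=True`` to resolve by the
    order of ``target_groups`` instead.

    Total function: every answer pattern yields exactly one label, and the
    two questions are interchangeable ("either question").
    """
    singles = {
        s
        for s in (_single_response(answers_ancestry), _single_response(answers_background))
        if s is not None
    }
    triggered = [g for g in target_groups if g.strip().casefold() in singles]
    if not triggered:
        return default_label
    if len(triggered) == 1:
        return triggered[0]
    if conflict_precedence:
        return triggered[0]
    logger.warning(
        "conflicting single responses %s resolved to %s", triggered, default_label
    )
    return default_label


def resolve_respondents(
    survey: pd.DataFrame,
    target_groups: Sequence[str],
    default_label: str,
    *,
    conflict_precedence: bool = False,
) -> pd.DataFrame:
    """Resolve every survey row; returns columns ``person_id, gold``.

    ``survey`` uses the standard schema (see :data:`SURVEY_COLUMNS`) with
    semicolon-delimited multi-responses in ``q_ancestry``/``q_background``.
    """
    gold = [
        resolve_self_report(
            str(anc).split(";") if pd.notna(anc) else [],
            str(bkg).split(";") if pd.notna(bkg) else [],
            target_groups,
            default_label,
            conflict_precedence=conflict_precedence,
        )
        for anc, bkg in zip(survey["q_ancestry"], survey["q_background"])
    ]
    return pd.DataFrame({"person_id": survey["person_id"].values, "gold": gold})


def pool_weights(survey: pd.DataFrame, cycles: Iterable[str]) -> pd.DataFrame:
    """Divide each person-level weight by the number of pooled cycles.

    With one cycle the weights are untouched.  A respondent whose cycle is
    outside the declared set is an error: it would silently change the
    divisor's meaning.
    """
    cycles = {str(c) for c in cycles}
    if not cycles:
        raise ValueError("cycles must be non-empty")
    seen = set(survey["cycle"].astype(str))
    stray = seen - cycles
    if stray:
        raise ValueError(f"respondents from undeclared cycles: {sorted(stray)}")
    out = survey.copy()
    out["weight"] = out["weight"] / len(cycles)
    return out


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read a survey CSV with the standard schema."""
    df = pd.read_csv(path, dtype={c: str for c in SURVEY_COLUMNS if c != "weight"})
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: survey is missing columns {sorted(missing)}")
    df["weight"] = df["weight"].astype(float)
    if (df["weight"] <= 0).any():
        raise ValueError(f"{path}: non-positive weights present")
    return df


def write_survey(survey: pd.DataFrame, path: str | Path) -> None:
    survey.to_csv(path, index=False, columns=SURVEY_COLUMNS)
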