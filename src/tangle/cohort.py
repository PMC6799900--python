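"""Cohort construction from pharmacy claim tables.

Subjects enter the diabetes cohort when they make habitual use of
glucose-lowering drugs; subjects with gestational diabetes are excluded,
and the analysis is restricted to stable concession-card holders (card used
in at least 75% of observed years and, within those years, for at least 75%
of annual claims). Each remaining subject is labeled 1 if an initial
metformin-only period was followed by a second drug class (with or without
continued metformin), 0 if metformin-only throughout, and is not eligible
when never metformin-only at the start (e.g. starts on insulin).

Input tables are pandas DataFrames with columns
``subject_id, year, item_code, drug_class, concessional, gestational_flag``
where ``drug_class`` is one of ``metformin``, ``other_dm_drug``, ``non_dm``.
Row order within a subject-year defines claim order.
"""

from __future__ import annotations

from typing import Iterable, Literal, Union

import pandas as pd

__all__ = [
    "NOT_ELIGIBLE",
    "habitual_dm_users",
    "exclude_gestational",
    "select_stable_concessional",
    "label_therapy_transition",
    "build_labeled_cohort",
]

NOT_ELIGIBLE = "not_eligible"
DM_CLASSES = {"metformin", "other_dm_drug"}


def habitual_dm_users(claims: pd.DataFrame, min_years: int = 2) -> set[str]:
    """Subjects with DM-drug claims in at least ``min_years`` distinct years."""
    dm = claims[claims["drug_class"].isin(DM_CLASSES)]
    years_per_subject = dm.groupby("subject_id")["year"].nunique()
    return set(years_per_subject[years_per_subject >= min_years].index)


def exclude_gestational(claims: pd.DataFrame) -> pd.DataFrame:
    """Drop every subject carrying a gestational-diabetes flag."""
    flagged = set(claims.loc[claims["gestational_flag"].astype(bool), "subject_id"])
    return claims[~claims["subject_id"].isin(flagged)]


def select_stable_concessional(claims: pd.DataFrame, year_frac: float = 0.75,
                               claim_frac: float = 0.75) -> set[str]:
    """Subjects whose concession card is used consistently.

    A year counts as concessional when >= ``claim_frac`` of that year's
    claims carry the concession flag; a subject is retained when at least
    ``year_frac`` of their observed years are concessional. Both bounds are
    inclusive.
    """
    if not (0.0 < year_frac <= 1.0 and 0.0 < claim_frac <= 1.0):
        raise ValueError("fractions must lie in (0, 1]")
    if claims.empty:
        return set()
    per_year = claims.groupby(["subject_id", "year"])["concessional"].mean()
    conc_year = per_year >= claim_frac
    frac_years = conc_year.groupby(level="subject_id").mean()
    return set(frac_years[frac_years >= year_frac].index)


def label_therapy_transition(history: pd.DataFrame) -> Union[int, str]:
    """Label one subject's drug history.

    ``history`` holds the claims of a single subject in temporal order
    (sorted by year, ties broken by row order). Returns 1 when a leading
    metformin-only phase is followed by any other DM drug class, 0 when
    metformin-only throughout, and ``NOT_ELIGIBLE`` when the subject was
    never on metformin alone at the start.
    """
    dm = history[history["drug_class"].isin(DM_CLASSES)]
    if dm.empty:
        return NOT_ELIGIBLE
    dm = dm.sort_values("year", kind="stable")
    classes = dm["drug_class"].tolist()
    try:
        first_other = classes.index("other_dm_drug")
    except ValueError:
        return 0  # metformin-only throughout
    # eligible only if some metformin claim strictly precedes the first
    # other-class claim (initial metformin-only phase)
    if "metformin" in classes[:first_other]:
        return 1
    return NOT_ELIGIBLE


def build_labeled_cohort(claims: pd.DataFrame, year_frac: float = 0.75,
                         claim_frac: float = 0.75, min_years: int = 2) -> pd.DataFrame:
    """Run the full filter/label pipeline; returns (subject_id, label) rows.

    Pipeline: habitual DM use -> gestational exclusion -> stable
    concession-card filter -> therapy-transition labeling; non-eligible
    subjects are dropped from the output.
    """
    habitual = habitual_dm_users(claims, min_years=min_years)
    claims = claims[claims["subject_id"].isin(habitual)]
    claims = exclude_gestational(claims)
    stable = select_stable_concessional(claims, year_frac, claim_frac)
    claims = claims[claims["subject_id"].isin(stable)]
    rows = []
    for sid, hist in claims.groupby("subject_id", sort=True):
        label = label_therapy_transition(hist)
        if label in (0, 1):
            rows.append({"subject_id": sid, "label": int(label)})
    return pd.DataFrame(rows, columns=["subject_id", "label"])
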