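"""Scoring of the survey instruments and derivation of analysis covariates.

Three instruments are scored:

* WHO-5 wellbeing: five items on 0-5, raw total 0-25, flagged "low" when the
  total is under half the possible score (< 12.5).
* Household Hunger Scale: three occurrence/frequency questions aggregated to a
  0-6 score; 0-1 none/low, 2-3 moderate, 4-6 high.  The analysis covariate is
  the moderate-or-high flag.
* Nine-item HIV knowledge: count of correct items; 9/9 is "very high",
  under 6 "low", otherwise "mid".

`derive_covariates` appends the eight fixed regression covariates to a
respondent table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RespondentProfile",
    "score_who5",
    "score_hiv_knowledge",
    "score_household_hunger",
    "derive_covariates",
    "REGISTERED_OCCUPATIONS",
    "COVARIATE_COLUMNS",
    "OUTCOME_COLUMNS",
]

#: occupations in the registered, formal tourist sector
REGISTERED_OCCUPATIONS = frozenset(
    {"Tour guide (registered)", "Tourist taxi driver (registered)"}
)

#: the eight fixed covariates used by every risk-correlate regression
COVARIATE_COLUMNS = [
    "age",
    "registered_occupation",
    "difficulty_350_bill",
    "months_in_industry",
    "months_per_year",
    "poor_wellbeing",
    "hunger_flag",
    "hiv_knowledge",
]

OUTCOME_COLUMNS = ["ever_tourist_sex", "condom_last_sex", "sti_12m", "alcohol_30d", "drugs_3m"]

WHO5_LOW_THRESHOLD = 12.5  # half of the possible 0-25 total
HIV_LOW_BELOW = 6
HIV_VERY_HIGH = 9
# standard Household Hunger Scale cut points on the 0-6 score (overridable)
HHS_CUTS = {"none_low": (0, 1), "moderate": (2, 3), "high": (4, 6)}


def score_who5(items) -> tuple[int, bool]:
    """Raw WHO-5 total (0-25) and the low-wellbeing flag (total under half).

    ``items`` are the five responses, each an integer in [0, 5].
    """
    items = list(items)
    if len(items) != 5:
        raise ValueError(f"WHO-5 needs exactly 5 items, got {len(items)}")
    for v in items:
        if not (isinstance(v, (int, np.integer)) or float(v).is_integer()) or not 0 <= v <= 5:
            raise ValueError(f"WHO-5 item out of range [0, 5]: {v!r}")
    total = int(sum(items))
    return total, total < WHO5_LOW_THRESHOLD


def score_hiv_knowledge(items) -> tuple[int, str]:
    """Count of correct items among 9 and the knowledge category.

    Categories: ``very_high`` iff 9/9 correct, ``low`` iff under 6, else ``mid``.
    ``items`` are truthy/falsy correctness indicators.
    """
    items = list(items)
    if len(items) != 9:
        raise ValueError(f"HIV knowledge tool has 9 items, got {len(items)}")
    count = int(sum(bool(v) for v in items))
    if count == HIV_VERY_HIGH:
        category = "very_high"
    elif count < HIV_LOW_BELOW:
        category = "low"
    else:
        category = "mid"
    return count, category


def score_household_hunger(items, cuts: dict | None = None) -> tuple[str | None, bool | None]:
    """Household Hunger Scale category and the moderate-or-high analysis flag.

    ``items`` are the three frequency responses, each 0 (never), 1 (rarely or
    sometimes) or 2 (often); their sum is the 0-6 HHS score.  Missing items
    (None/NaN) yield ``(None, None)`` so the record drops out by listwise
    deletion downstream.
    """
    items = list(items)
    if len(items) != 3:
        raise ValueError(f"Household Hunger Scale has 3 items, got {len(items)}")
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in items):
        return None, None
    for v in items:
        if v not in (0, 1, 2):
            raise ValueError(f"HHS item must be 0, 1 or 2, got {v!r}")
    score = int(sum(items))
    cuts = cuts or HHS_CUTS
    for category, (lo, hi) in cuts.items():
        if lo <= score <= hi:
            return category, category != "none_low"
    raise ValueError(f"HHS score {score} not covered by cut points {cuts}")


@dataclass
class RespondentProfile:
    """One survey record: demographics, instrument items and risk outcomes."""

    respondent_id: int
    age: float
    occupation: str
    income_monthly: float
    months_in_industry: float
    months_per_year: float
    difficulty_350_bill: bool
    who5_items: tuple[int, ...]
    hunger_items: tuple[int, ...]
    hiv_items: tuple[int, ...]
    ever_tourist_sex: bool | None = None
    condom_last_sex: bool | None = None
    sti_12m: bool | None = None
    alcohol_30d: bool | None = None
    ever_drugs: bool | None = None
    drugs_3m: bool | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.months_per_year <= 12:
            raise ValueError("months_per_year must lie in [0, 12]")

    @property
    def registered(self) -> bool:
        return self.occupation in REGISTERED_OCCUPATIONS

    def scored_row(self) -> dict:
        who5_total, who5_low = score_who5(self.who5_items)
        hiv_count, hiv_cat = score_hiv_knowledge(self.hiv_items)
        hunger_cat, hunger_flag = score_household_hunger(self.hunger_items)
        return {
            "respondent_id": self.respondent_id,
            "age": self.age,
            "occupation": self.occupation,
            "registered_occupation": int(self.registered),
            "income_monthly": self.income_monthly,
            "months_in_industry": self.months_in_industry,
            "months_per_year": self.months_per_year,
            "difficulty_350_bill": int(self.difficulty_350_bill),
            "who5_total": who5_total,
            "poor_wellbeing": int(who5_low),
            "hunger_category": hunger_cat,
            "hunger_flag": None if hunger_flag is None else int(hunger_flag),
            "hiv_knowledge": hiv_count,
            "hiv_knowledge_category": hiv_cat,
            "ever_tourist_sex": self.ever_tourist_sex,
            "condom_last_sex": self.condom_last_sex,
            "sti_12m": self.sti_12m,
            "alcohol_30d": self.alcohol_30d,
            "ever_drugs": self.ever_drugs,
            "drugs_3m": self.drugs_3m,
        }


def derive_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Append scored covariates to a raw respondent table.

    Expects item columns ``who5_1..who5_5``, ``hhs_1..hhs_3``,
    ``hiv_1..hiv_9``, plus ``occupation`` and the demographic fields; returns
    a copy with the eight analysis covariates and score/category columns.
    """
    out = df.copy()
    who5_cols = [f"who5_{i}" for i in range(1, 6)]
    hhs_cols = [f"hhs_{i}" for i in range(1, 4)]
    hiv_cols = [f"hiv_{i}" for i in range(1, 10)]

    totals, lows = zip(*(score_who5(row) for row in out[who5_cols].to_numpy()))
    out["who5_total"] = totals
    out["poor_wellbeing"] = np.array(lows, dtype=int)

    cats, flags = zip(*(score_household_hunger(row) for row in out[hhs_cols].to_numpy()))
    out["hunger_category"] = cats
    out["hunger_flag"] = [None if f is None else int(f) for f in flags]

    counts, hcats = zip(*(score_hiv_knowledge(row) for row in out[hiv_cols].to_numpy()))
    out["hiv_knowledge"] = counts
    out["hiv_knowledge_category"] = hcats

    out["registered_occupation"] = (
        out["occupation"].isin(REGISTERED_OCCUPATIONS).astype(int)
    )
    if out["difficulty_350_bill"].dtype == bool:
        out["difficulty_350_bill"] = out["difficulty_350_bill"].astype(int)
    return out
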