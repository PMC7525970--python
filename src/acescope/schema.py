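"""Survey schema: ACE item definitions, response levels, covariates.

The 11 self-reported adverse-childhood-experience (ACE) items follow the
BRFSS ACE module. Items 1-5 are household-dysfunction items answered
yes/no; items 6-11 are frequency items answered never / once / more than
once. Seven categorical covariates with declared reference levels (first
level listed) are carried by every model.
"""

from __future__ import annotations

# response levels
YES = "yes"
NO = "no"
NEVER = "never"
ONCE = "once"
MORE_THAN_ONCE = "more_than_once"

BINARY_LEVELS = (NO, YES)
FREQUENCY_LEVELS = (NEVER, ONCE, MORE_THAN_ONCE)

# exposure thresholds for frequency items
THRESHOLD_ONCE = "once"            # any occurrence counts as exposed
THRESHOLD_MORE_THAN_ONCE = "more_than_once"  # only repeated occurrence
THRESHOLDS = (THRESHOLD_ONCE, THRESHOLD_MORE_THAN_ONCE)

# items, in the canonical order used for multiple-individual-risk models
BINARY_ITEMS = (
    "household_mental_illness",
    "household_alcoholism",
    "household_drug_abuse",
    "household_criminal",
    "divorce",
)
FREQUENCY_ITEMS = (
    "household_violence",
    "physical_abuse",
    "emotional_abuse",
    "sexually_touched",
    "sexual_touching",
    "forced_sex",
)
ITEMS = BINARY_ITEMS + FREQUENCY_ITEMS

# the three sexual-adversity items collapsed to one indicator in 9-item scoring
SEXUAL_ITEMS = ("sexually_touched", "sexual_touching", "forced_sex")
SEXUAL_ABUSE = "sexual_abuse"

NINE_ITEMS = tuple(i for i in ITEMS if i not in SEXUAL_ITEMS) + (SEXUAL_ABUSE,)

DISPLAY_LABELS = {
    "household_mental_illness": "Household Mental Illness",
    "household_alcoholism": "Household Alcoholism",
    "household_drug_abuse": "Household Drug Abuse",
    "household_criminal": "Household Criminal",
    "divorce": "Divorce",
    "household_violence": "Household Violence",
    "physical_abuse": "Physical Abuse",
    "emotional_abuse": "Emotional Abuse",
    "sexually_touched": "Sexually Touched",
    "sexual_touching": "Sexual Touching",
    "forced_sex": "Forced Sex",
    "sexual_abuse": "Sexual Abuse",
}

# covariates: name -> ordered levels, first level is the reference
COVARIATES = {
    "sex": ("female", "male"),
    "age": ("18-29", "30-39", "40-49", "50-59", "60+"),
    "education": ("less_than_hs", "hs_grad", "some_college", "college_grad"),
    "income": ("<15k", "15-25k", "25-35k", "35-50k", "50k+"),
    "insurance": ("insured", "uninsured"),
    "race": ("white", "black", "other"),
    "marital": ("married", "divorced_widowed", "never_married"),
}

OUTCOME = "outcome"


def item_levels(item: str) -> tuple[str, ...]:
    """Declared response levels for an item column."""
    if item in BINARY_ITEMS:
        return BINARY_LEVELS
    if item in FREQUENCY_ITEMS:
        return FREQUENCY_LEVELS
    if item == SEXUAL_ABUSE:
        return BINARY_LEVELS
    raise KeyError(f"unknown ACE item {item!r}")


def unexposed_level(item: str) -> str:
    """The 'no adversity' level an imputed missing response is set to."""
    return NO if item in BINARY_ITEMS else NEVER
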