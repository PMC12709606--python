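"""Mass-cohort accounting: eligibility filters and analysis subgroup.

Cohort tables are pandas DataFrames with one row per sonographic mass.
Required columns: ``mass_id`` (unique), ``patient_id``,
``truth_category`` (one of the five reference-standard categories) and
``exclusion_reason`` (empty/NaN for eligible masses). Optional columns
such as per-arm gCNR scores pass through the filters untouched.

The statistical analysis subgroup keeps complicated cysts (the fluid
positives) and solid masses (negatives). Mixed-content masses are
dropped because they contain both fluid and solid components, and
simple cysts are dropped because B-mode features already classify them
confidently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TRUTH_CATEGORIES",
    "EXCLUSION_REASONS",
    "FLUID_POSITIVE_CATEGORIES",
    "SOLID_NEGATIVE_CATEGORIES",
    "STUDY_CATEGORY_COUNTS",
    "STUDY_EXCLUSION_COUNTS",
    "apply_eligibility_filters",
    "select_statistical_subgroup",
    "binary_truth_labels",
]

TRUTH_CATEGORIES = (
    "simple_cyst",
    "complicated_cyst",
    "solid_benign",
    "solid_malignant",
    "mixed",
)

EXCLUSION_REASONS = (
    "hyperechoic",
    "unknown_content",
    "incomplete_followup",
    "no_screenshots",
    "superficial",
    "not_in_fov",
)

FLUID_POSITIVE_CATEGORIES = frozenset({"complicated_cyst"})
SOLID_NEGATIVE_CATEGORIES = frozenset({"solid_benign", "solid_malignant"})

#: Eligible-mass composition of the clinical cohort this package
#: emulates: 145 masses = 16 complicated cysts + 11 simple cysts +
#: 22 mixed + 96 solid (71 benign, 25 malignant).
STUDY_CATEGORY_COUNTS = {
    "complicated_cyst": 16,
    "simple_cyst": 11,
    "mixed": 22,
    "solid_benign": 71,
    "solid_malignant": 25,
}

#: The 30 exclusions that reduce 175 potentially eligible masses to 145.
STUDY_EXCLUSION_COUNTS = {
    "hyperechoic": 2,
    "unknown_content": 16,
    "incomplete_followup": 2,
    "no_screenshots": 2,
    "superficial": 4,
    "not_in_fov": 4,
}


def _validate_cohort(df: pd.DataFrame) -> None:
    for col in ("mass_id", "truth_category"):
        if col not in df.columns:
            raise ValueError(f"cohort table is missing required column {col!r}")
    if df["mass_id"].duplicated().any():
        dup = df.loc[df["mass_id"].duplicated(), "mass_id"].iloc[0]
        raise ValueError(f"duplicate mass_id {dup!r}")
    bad = set(df["truth_category"]) - set(TRUTH_CATEGORIES)
    if bad:
        raise ValueError(f"unknown truth categories: {sorted(bad)}")


def _exclusion_series(df: pd.DataFrame) -> pd.Series:
    if "exclusion_reason" not in df.columns:
        return pd.Series("", index=df.index)
    return df["exclusion_reason"].fillna("").astype(str)


def apply_eligibility_filters(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop excluded masses and account for them per reason.

    Returns the eligible table and a report mapping each exclusion
    reason to its count (plus ``"eligible"`` and ``"input"`` totals).
    Unknown reason labels raise.
    """
    _validate_cohort(cohort)
    reasons = _exclusion_series(cohort)
    unknown = set(reasons.unique()) - set(EXCLUSION_REASONS) - {""}
    if unknown:
        raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")
    report = {r: int((reasons == r).sum()) for r in EXCLUSION_REASONS}
    eligible = cohort.loc[reasons == ""].copy()
    report["input"] = int(len(cohort))
    report["eligible"] = int(len(eligible))
    return eligible, report


def select_statistical_subgroup(eligible: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep complicated cysts and solid masses for ROC analysis.

    The input must already be eligibility-filtered. Returns the
    subgroup and per-category retained counts.
    """
    _validate_cohort(eligible)
    if (_exclusion_series(eligible) != "").any():
        raise ValueError("subgroup selection expects an eligibility-filtered table")
    keep = eligible["truth_category"].isin(
        FLUID_POSITIVE_CATEGORIES | SOLID_NEGATIVE_CATEGORIES
    )
    subgroup = eligible.loc[keep].copy()
    counts = subgroup["truth_category"].value_counts().to_dict()
    counts = {k: int(counts.get(k, 0)) for k in ("complicated_cyst", "solid_benign", "solid_malignant")}
    counts["total"] = int(len(subgroup))
    return subgroup, counts


def binary_truth_labels(subgroup: pd.DataFrame) -> np.ndarray:
    """Binary labels (1 = fluid positive, 0 = solid negative) per mass.

    Raises if any mass outside the analysis taxonomy (mixed, simple
    cyst) is still present — those must be filtered first.
    """
    _validate_cohort(subgroup)
    cats = subgroup["truth_category"]
    allowed = FLUID_POSITIVE_CATEGORIES | SOLID_NEGATIVE_CATEGORIES
    stray = set(cats) - allowed
    if stray:
        raise ValueError(
            f"categories {sorted(stray)} must be excluded before binary labelling"
        )
    return cats.isin(FLUID_POSITIVE_CATEGORIES).to_numpy().astype(int)
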