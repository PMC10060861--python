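"""Scoring of the pain instruments and the composite pain-experience outcome.

Covers the Brief Pain Inventory short form (intensity plus seven interference
items split into affective and activity subdimensions), the 13-item Pain
Catastrophizing Scale (total plus rumination / magnification / helplessness
subscales), the pain-experience composite (mean of intensity and affective
interference at a timepoint, T2 - T1 as the longitudinal outcome; positive
means worsening), and the four-way chronic-pain group classification from the
two screening answers. No imputation is performed anywhere: a missing item is
an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: BPI interference items by subdimension. Sleep sits in the affective
#: subdimension (the three-domain alternative moves it to its own domain).
BPI_AFFECTIVE_ITEMS = ("relations", "enjoyment", "sleep", "mood")
BPI_ACTIVITY_ITEMS = ("walking", "general_activity", "work")
BPI_INTERFERENCE_ITEMS = BPI_AFFECTIVE_ITEMS + BPI_ACTIVITY_ITEMS

#: Standard 13-item catastrophizing-scale keying (1-based item numbers).
#: Subscale maxima: helplessness 24, rumination 16, magnification 12.
PCS_KEYING = {
    "helplessness": (1, 2, 3, 4, 5, 12),
    "magnification": (6, 7, 13),
    "rumination": (8, 9, 10, 11),
}


@dataclass(frozen=True)
class BpiRecord:
    """One subject's BPI short-form responses at one timepoint (0-10 ratings)."""

    intensity_mean_last_week: float
    general_activity: float
    mood: float
    walking: float
    work: float
    relations: float
    sleep: float
    enjoyment: float
    n_pain_sites: int | None = None
    duration_category: str | None = None
    medication: bool | None = None

    def __post_init__(self):
        for name in ("intensity_mean_last_week",) + BPI_INTERFERENCE_ITEMS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"missing BPI item {name!r} (no imputation performed)")
            if not 0 <= v <= 10:
                raise ValueError(f"BPI item {name!r}={v} outside the 0-10 rating scale")


@dataclass(frozen=True)
class PcsRecord:
    """One subject's 13 catastrophizing items, each rated 0-4."""

    items: tuple

    def __post_init__(self):
        if len(self.items) != 13:
            raise ValueError(f"expected 13 items, got {len(self.items)}")
        for k, v in enumerate(self.items, start=1):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"missing item {k} (no imputation performed)")
            if not 0 <= v <= 4:
                raise ValueError(f"item {k}={v} outside the 0-4 scale")


def score_bpi_interference(record: BpiRecord) -> tuple:
    """(affective, activity, total) interference composites.

    Each composite is the arithmetic mean of its items; total averages all
    seven interference items.
    """
    affective = float(np.mean([getattr(record, it) for it in BPI_AFFECTIVE_ITEMS]))
    activity = float(np.mean([getattr(record, it) for it in BPI_ACTIVITY_ITEMS]))
    total = float(np.mean([getattr(record, it) for it in BPI_INTERFERENCE_ITEMS]))
    return affective, activity, total


def score_pcs(record: PcsRecord, keying: dict | None = None) -> tuple:
    """(total, rumination, magnification, helplessness) catastrophizing scores.

    Total is the sum of all 13 items (0-52). Subscales sum the items given by
    ``keying`` (1-based item numbers; defaults to the standard keying, under
    which the three subscale sums partition the total).
    """
    keying = PCS_KEYING if keying is None else keying
    items = np.asarray(record.items, dtype=float)
    total = float(items.sum())
    sub = {name: float(items[np.asarray(nums) - 1].sum()) for name, nums in keying.items()}
    return total, sub["rumination"], sub["magnification"], sub["helplessness"]


def pain_experience(
    intensity: float, affective_interference: float, variant: str = "mean"
) -> float:
    """Pain-experience composite at one timepoint.

    The default combines pain intensity and affective interference as their
    arithmetic mean on the shared 0-10 scale. ``variant="difference"``
    computes (intensity - affective) / 2 instead, for sensitivity analyses.
    """
    if variant == "mean":
        return (intensity + affective_interference) / 2.0
    if variant == "difference":
        return (intensity - affective_interference) / 2.0
    raise ValueError(f"unknown variant {variant!r}; use 'mean' or 'difference'")


def pain_experience_longitudinal(pe_t1: float, pe_t2: float) -> float:
    """T2 - T1 change in the pain-experience composite (positive = worsening)."""
    return pe_t2 - pe_t1


def classify_pain_group(cp_t1, cp_t2) -> str:
    """Classify by the two chronic-pain screening answers.

    yes-yes -> ``pain``; no-no -> ``no_pain``; yes-no -> ``recovered`` and
    no-yes -> ``developed`` (both excluded from the main analysis);
    a missing answer -> ``unclassifiable``.
    """

    def as_bool(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        if isinstance(v, str):
            s = v.strip().lower()
            if s in {"yes", "y", "true", "1"}:
                return True
            if s in {"no", "n", "false", "0"}:
                return False
            return None
        return bool(v)

    t1, t2 = as_bool(cp_t1), as_bool(cp_t2)
    if t1 is None or t2 is None:
        return "unclassifiable"
    return {
        (True, True): "pain",
        (False, False): "no_pain",
        (True, False): "recovered",
        (False, True): "developed",
    }[(t1, t2)]


# ---------------------------------------------------------------------------
# Table-level scoring
# ---------------------------------------------------------------------------

def score_phenotypes(df: pd.DataFrame, variant: str = "mean") -> pd.DataFrame:
    """Score a phenotype table: one output row per subject.

    Expects columns ``cp_t1``/``cp_t2``, per-timepoint BPI columns
    ``bpi_intensity_t{1,2}`` and ``bpi_<item>_t{1,2}`` for the seven
    interference items, and 13 ``pcs_item_<k>`` columns. Rows whose group is
    not ``pain`` keep NaN pain scores (those instruments are only administered
    to the pain group). Pass-through columns are preserved.
    """
    out = df.copy()
    out["group"] = [classify_pain_group(a, b) for a, b in zip(df["cp_t1"], df["cp_t2"])]

    score_cols = [
        "pcs_total", "pcs_rumination", "pcs_magnification", "pcs_helplessness",
    ]
    for t in (1, 2):
        score_cols += [
            f"intensity_t{t}", f"affective_interference_t{t}",
            f"activity_interference_t{t}", f"total_interference_t{t}",
            f"pain_experience_t{t}",
        ]
    score_cols += ["pain_experience_longitudinal"]
    for c in score_cols:
        out[c] = np.nan

    for i, row in df.iterrows():
        if out.at[i, "group"] != "pain":
            continue
        pcs = PcsRecord(tuple(row[f"pcs_item_{k}"] for k in range(1, 14)))
        total, rum, mag, helpless = score_pcs(pcs)
        out.at[i, "pcs_total"] = total
        out.at[i, "pcs_rumination"] = rum
        out.at[i, "pcs_magnification"] = mag
        out.at[i, "pcs_helplessness"] = helpless
        pe = {}
        for t in (1, 2):
            rec = BpiRecord(
                intensity_mean_last_week=row[f"bpi_intensity_t{t}"],
                **{it: row[f"bpi_{it}_t{t}"] for it in BPI_INTERFERENCE_ITEMS},
            )
            affective, activity, tot = score_bpi_interference(rec)
            out.at[i, f"intensity_t{t}"] = rec.intensity_mean_last_week
            out.at[i, f"affective_interference_t{t}"] = affective
            out.at[i, f"activity_interference_t{t}"] = activity
            out.at[i, f"total_interference_t{t}"] = tot
            pe[t] = pain_experience(rec.intensity_mean_last_week, affective, variant)
            out.at[i, f"pain_experience_t{t}"] = pe[t]
        out.at[i, "pain_experience_longitudinal"] = pain_experience_longitudinal(pe[1], pe[2])
    return out
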