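"""Clinical cohort table: column vocabulary, validation and CSV round trip.

One row per patient. ``time_months`` counts from histological confirmation
of the index tumor; ``event`` is 1 for a locoregional neoplastic
manifestation (local recurrence, second primary tumor or nodal metastasis)
and 0 for censoring at last follow-up.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: Categorical factor -> allowed levels (first level is the reference).
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("Male", "Female"),
    "site": (
        "Tongue", "Floor of mouth", "Cheek", "Soft palate",
        "Superior gum/hard palate", "Inferior gum", "Lip",
    ),
    "grade": ("G1", "G2", "G3"),
    "t_stage": ("T1-2", "T3-4"),
    "n_positive": ("N0", "N+"),
    "perineural": ("No", "Yes"),
    "vascular": ("No", "Yes"),
    "margin": ("Clear", "Close", "Dysplasia"),
    "opmd": ("No", "Oral Lichen Planus", "Leukoplakia"),
    "radiotherapy": ("No", "Yes"),
    "flap": ("No", "Yes"),
}

COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    *FACTOR_LEVELS.keys(),
    "age",
    "score_positive",
    "time_months",
    "event",
)


class CohortError(ValueError):
    """Raised when a cohort table violates the declared vocabulary."""


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check columns, factor vocabularies and positivity of follow-up times."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"cohort table missing columns: {missing}")
    for factor, levels in FACTOR_LEVELS.items():
        bad = set(df[factor].dropna().unique()) - set(levels)
        if bad:
            raise CohortError(f"factor {factor!r} has unknown levels: {sorted(bad)}")
    if len(df) and not (df["time_months"] > 0).all():
        raise CohortError("time_months must be strictly positive")
    if len(df) and not df["event"].isin([0, 1, True, False]).all():
        raise CohortError("event must be 0/1")
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df)
    df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df):
        df["score_positive"] = df["score_positive"].astype(bool)
        df["event"] = df["event"].astype(int)
    return validate_cohort(df)
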