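"""Survey data container and column conventions.

A :class:`SurveyDataset` is a thin wrapper around a wide pandas DataFrame
holding one row per respondent:

===================  ========================================================
column               meaning
===================  ========================================================
``resp_id``          integer respondent identifier (unique)
``group``            group label (language of the questionnaire)
``gender``           0 = male, 1 = female
``age_band``         ordered band label, one of :data:`AGE_BANDS`
``education``        one of :data:`EDUCATION_LEVELS` (may be missing)
``insurance``        0/1 flag for holding an electronic health-insurance card
``self_<ind>``       self-report rating, 1 = very bad ... 5 = very good
``vignette_set``     id (1..5) of the randomly assigned vignette set
``vig_<ind>_L<j>``   rating of the level-*j* vignette for indicator ``<ind>``
                     (present only for indicator/level pairs of the assigned
                     set; 1 = bottom/very bad ... 5 = top/very good)
===================  ========================================================

Missing entries (item nonresponse and "cannot say") are ``NaN``; ``education``
uses ``NaN`` as well.  Ratings, when present, are integers in 1..5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The seven health-system-responsiveness indicators, in questionnaire order.
INDICATORS: tuple[str, ...] = (
    "attention",
    "respect",
    "communication",
    "autonomy",
    "confidentiality",
    "choice",
    "amenities",
)

#: Number of response categories of the fully verbalised rating scale.
N_CATEGORIES: int = 5

#: Vignette levels, bottom (1 = very bad) to top (5 = very good).
VIGNETTE_LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5)

AGE_BANDS: tuple[str, ...] = ("18-25", "26-30", "31-35", "36-40", "41+")
EDUCATION_LEVELS: tuple[str, ...] = ("none", "mandatory", "high_school")

#: Socio-demographic covariates usable in model design matrices.
COVARIATES: tuple[str, ...] = ("gender", "age_band", "education", "insurance")


def self_col(indicator: str) -> str:
    return f"self_{indicator}"


def vignette_col(indicator: str, level: int) -> str:
    return f"vig_{indicator}_L{level}"


def _check_ratings(df: pd.DataFrame, columns: Iterable[str]) -> None:
    for col in columns:
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = vals[(vals < 1) | (vals > N_CATEGORIES) | (vals != np.round(vals))]
        if len(bad):
            row = int(bad.index[0])
            raise ValueError(
                f"invalid rating {bad.iloc[0]!r} in column {col!r}, row {row}: "
                f"ratings must be integers in 1..{N_CATEGORIES}"
            )


@dataclass
class SurveyDataset:
    """Respondent-level survey table plus provenance metadata."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"resp_id", "group"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"survey table lacks required columns: {sorted(missing)}")
        _check_ratings(self.df, self.rating_columns())

    # -- column helpers -------------------------------------------------
    def rating_columns(self) -> list[str]:
        cols = [self_col(s) for s in INDICATORS if self_col(s) in self.df.columns]
        cols += [c for c in self.df.columns if c.startswith("vig_")]
        return cols

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.df["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def n_per_group(self) -> dict[str, int]:
        return {g: int((self.df["group"] == g).sum()) for g in self.groups}

    def self_reports(self) -> pd.DataFrame:
        """Self-report block indexed by ``resp_id`` (columns = indicators)."""
        out = self.df.set_index("resp_id")[[self_col(s) for s in INDICATORS]]
        out.columns = list(INDICATORS)
        return out

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(self.df.copy(), dict(self.meta))


def design_matrix(
    df: pd.DataFrame,
    covariates: Sequence[str],
    intercept: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """One-hot design matrix for the requested covariates.

    Categorical covariates (``age_band``, ``education``, ``group``) are
    expanded into dummies with the first level as reference; binary flags
    pass through.  Rows with any missing covariate yield NaN entries, so
    callers can apply listwise deletion.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(len(df)))
        names.append("const")
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        if cov == "age_band":
            levels: Sequence[str] = AGE_BANDS
        elif cov == "education":
            levels = EDUCATION_LEVELS
        elif cov == "group":
            levels = list(dict.fromkeys(df["group"]))
        else:
            vals = pd.to_numeric(df[cov], errors="coerce").to_numpy(float)
            cols.append(vals)
            names.append(cov)
            continue
        raw = df[cov]
        for lev in levels[1:]:
            dummy = np.where(raw.isna(), np.nan, (raw == lev).astype(float))
            cols.append(dummy)
            names.append(f"{cov}[{lev}]")
    return np.column_stack(cols) if cols else np.empty((len(df), 0)), names


def threshold_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Covariate vector V for the threshold model: intercept, gender,
    age-band dummies, insurance.  Education is excluded (its missingness
    would otherwise shrink the estimation sample) and language enters
    separately (group-specific parameters or an explicit group dummy)."""
    X, names = design_matrix(df, ["gender", "age_band", "insurance"], intercept=True)
    return X, names


def group_dummy(df: pd.DataFrame, groups: Sequence[str] | None = None) -> np.ndarray:
    groups = list(groups) if groups is not None else list(dict.fromkeys(df["group"]))
    return (df["group"] != groups[0]).astype(float).to_numpy()
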