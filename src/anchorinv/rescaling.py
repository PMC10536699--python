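"""Non-parametric anchoring-vignette rescaling.

Each self-report ``y`` is re-expressed relative to the respondent's (or the
pooled) anchor ratings ``z_1 .. z_J`` of vignettes of increasing intended
severity, producing the rescaled category ``C`` on the 1..2J+1 scale:

    C = 1      if y < z_1
        2      if y = z_1
        3      if z_1 < y < z_2
        ...
        2J+1   if y > z_J

When the anchors are tied or misordered the comparison is ambiguous and C
becomes an integer interval [Cs, Ce].  The semantics implemented here: a
*resolution* keeps every inclusion-maximal subset of anchors whose ratings
are weakly increasing in the intended order (the anchors left out are the
ones contradicting that reading and their comparisons with y are treated as
unknown); each resolution pins C to an interval on the full ladder, and
[Cs, Ce] is the hull over resolutions.  For strictly ordered anchors this
reduces exactly to the scalar rule above; for two anchors tied with y it
yields {2, 3, 4}.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import INDICATORS, SurveyDataset, self_col, vignette_col

__all__ = [
    "AnchorSet",
    "CInterval",
    "NotRescalable",
    "rescale_one",
    "pooled_anchor_means",
    "rescale_dataset",
    "ordering_accuracy",
    "OrderingAccuracy",
]

#: tolerance for equality between a rating and a non-integer anchor
EQ_TOL = 1e-9


class NotRescalable(ValueError):
    """Raised when a self-report cannot be rescaled (missing y or anchors),
    as opposed to structurally invalid input."""


@dataclass(frozen=True)
class CInterval:
    """Rescaled self-report as an integer interval on 1..2J+1."""

    cs: int
    ce: int
    j: int

    def __post_init__(self) -> None:
        if not (1 <= self.cs <= self.ce <= 2 * self.j + 1):
            raise ValueError(f"invalid C interval [{self.cs}, {self.ce}] for J={self.j}")

    @property
    def is_scalar(self) -> bool:
        return self.cs == self.ce

    def values(self) -> range:
        return range(self.cs, self.ce + 1)


@dataclass
class AnchorSet:
    """Ordered anchor values (bottom -> top) for one indicator."""

    indicator: str
    z: np.ndarray
    source: str = "per-respondent"  # or "pooled-mean"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        if self.z.ndim != 1 or len(self.z) < 1:
            raise ValueError("anchor set needs J >= 1 values")

    @property
    def j(self) -> int:
        return len(self.z)


def _eq(a: float, b: float) -> bool:
    if float(a).is_integer() and float(b).is_integer():
        return a == b
    return abs(a - b) <= EQ_TOL


def _consistent(z: Sequence[float], slots: tuple[int, ...]) -> bool:
    vals = [z[i] for i in slots]
    return all(v2 >= v1 - EQ_TOL for v1, v2 in zip(vals, vals[1:]))


def _maximal_consistent_subsets(z: Sequence[float]) -> list[tuple[int, ...]]:
    J = len(z)
    consistent = [
        slots
        for r in range(1, J + 1)
        for slots in combinations(range(J), r)
        if _consistent(z, slots)
    ]
    out = []
    for T in consistent:
        sT = set(T)
        if not any(sT < set(U) for U in consistent):
            out.append(T)
    return out


def _subset_interval(y: float, z: Sequence[float], slots: tuple[int, ...]) -> tuple[int, int]:
    """C interval implied by reading only the anchors at ``slots`` (0-based)
    as trustworthy; dropped anchors leave y's position between the retained
    neighbours undetermined on the full 1..2J+1 ladder."""
    J = len(z)
    eq_slots = [i + 1 for i in slots if _eq(z[i], y)]
    below = [i + 1 for i in slots if z[i] < y and not _eq(z[i], y)]
    above = [i + 1 for i in slots if z[i] > y and not _eq(z[i], y)]
    a = max(below) if below else 0
    b = min(above) if above else J + 1
    if eq_slots:
        # dropped slots between the strict neighbours may tie with y too,
        # so the equality run spans slots a+1 .. b-1
        return 2 * (a + 1), 2 * (b - 1)
    return 2 * a + 1, 2 * b - 1


def rescale_one(y: float, z: AnchorSet | Sequence[float]) -> CInterval:
    """Rescale one self-report against one anchor set."""
    zvals = z.z if isinstance(z, AnchorSet) else np.asarray(z, float)
    if y is None or (isinstance(y, float) and np.isnan(y)) or pd.isna(y):
        raise NotRescalable("self-report is missing; not rescalable")
    if np.any(pd.isna(zvals)):
        raise NotRescalable("anchor set contains missing values; not rescalable")
    y = float(y)
    J = len(zvals)
    lo, hi = 2 * J + 1, 1
    for T in _maximal_consistent_subsets(zvals):
        tlo, thi = _subset_interval(y, zvals, T)
        lo, hi = min(lo, tlo), max(hi, thi)
    return CInterval(cs=lo, ce=hi, j=J)


# ---------------------------------------------------------------------------
# pooled anchors
# ---------------------------------------------------------------------------
def pooled_anchor_means(
    data: SurveyDataset,
    levels: Sequence[int] = (1, 3, 5),
    by_group: bool = False,
) -> dict[str, AnchorSet] | dict[str, dict[str, AnchorSet]]:
    """Mean rating of each requested vignette level per indicator, pooled
    over every respondent who rated it (both language groups jointly by
    default, matching the study's pooling)."""
    if by_group:
        out: dict[str, dict[str, AnchorSet]] = {}
        for g in data.groups:
            sub = SurveyDataset(data.df[data.df["group"] == g].reset_index(drop=True))
            out[g] = pooled_anchor_means(sub, levels=levels, by_group=False)
        return out

    anchors: dict[str, AnchorSet] = {}
    for ind in INDICATORS:
        means = []
        for lev in sorted(levels):
            col = vignette_col(ind, lev)
            vals = data.df[col].dropna() if col in data.df.columns else pd.Series(dtype=float)
            if len(vals) == 0:
                raise ValueError(
                    f"no ratings for indicator {ind!r} at vignette level {lev}"
                )
            means.append(float(vals.mean()))
        anchors[ind] = AnchorSet(indicator=ind, z=np.array(means), source="pooled-mean")
    return anchors


def rescale_dataset(
    data: SurveyDataset,
    anchors: Mapping[str, AnchorSet],
    mode: str = "lowest",
    per_respondent: bool = False,
    levels: Sequence[int] = (1, 3, 5),
) -> pd.DataFrame:
    """Apply :func:`rescale_one` to every self-report, keeping Cs
    (``mode='lowest'``) or Ce (``mode='highest'``).  Missing self-reports
    stay missing.  Returns a table indexed by ``resp_id`` with one column
    per indicator on the 1..2J+1 scale; metadata lives in ``.attrs``.

    With ``per_respondent`` the respondent's own vignette ratings at the
    requested ``levels`` are used as anchors where fully available (ties
    and misorderings then produce genuine Cs < Ce intervals); the pooled
    ``anchors`` serve as the fallback.
    """
    if mode not in {"lowest", "highest"}:
        raise ValueError(f"mode must be 'lowest' or 'highest', got {mode!r}")
    missing = [s for s in INDICATORS if s not in anchors]
    if missing:
        raise ValueError(f"anchors missing for indicators: {missing}")
    out = pd.DataFrame(index=data.df["resp_id"].to_numpy())
    out.index.name = "resp_id"
    for ind in INDICATORS:
        ys = data.df[self_col(ind)].to_numpy(float)
        own = None
        if per_respondent:
            cols = [vignette_col(ind, lev) for lev in sorted(levels)]
            present = [c for c in cols if c in data.df.columns]
            own = (
                data.df[present].to_numpy(float)
                if len(present) == len(cols)
                else None
            )
        vals = np.full(len(ys), np.nan)
        for i, y in enumerate(ys):
            if np.isnan(y):
                continue
            z: AnchorSet | np.ndarray = anchors[ind]
            if own is not None and not np.isnan(own[i]).any():
                z = own[i]
            ci = rescale_one(y, z)
            vals[i] = ci.cs if mode == "lowest" else ci.ce
        out[ind] = vals
    out["group"] = data.df["group"].to_numpy()
    out.attrs["J"] = {s: anchors[s].j for s in INDICATORS}
    out.attrs["mode"] = mode
    out.attrs["anchors"] = {s: anchors[s].z.tolist() for s in INDICATORS}
    return out


# ---------------------------------------------------------------------------
# ordering accuracy
# ---------------------------------------------------------------------------
@dataclass
class OrderingAccuracy:
    overall: float
    per_group: dict[str, float]
    flags: pd.DataFrame  # resp_id, group, indicator, accurate


def ordering_accuracy(data: SurveyDataset, strict: bool = False) -> OrderingAccuracy:
    """Proportion of respondent-indicator pairs whose rated vignette levels
    are (weakly, by default) increasing in intended level."""
    recs = []
    for ind in INDICATORS:
        cols = [
            (lev, vignette_col(ind, lev))
            for lev in range(1, 6)
            if vignette_col(ind, lev) in data.df.columns
        ]
        if len(cols) < 2:
            continue
        block = data.df[[c for _, c in cols]].to_numpy(float)
        for i in range(len(data.df)):
            rated = block[i][~np.isnan(block[i])]
            if len(rated) < 2:
                continue
            diffs = np.diff(rated)
            ok = bool(np.all(diffs > 0) if strict else np.all(diffs >= 0))
            recs.append(
                {
                    "resp_id": data.df["resp_id"].iloc[i],
                    "group": data.df["group"].iloc[i],
                    "indicator": ind,
                    "accurate": ok,
                }
            )
    if not recs:
        raise ValueError("no respondent-indicator pair has >= 2 rated vignette levels")
    flags = pd.DataFrame(recs)
    per_group = {
        g: float(sub["accurate"].mean()) for g, sub in flags.groupby("group", sort=False)
    }
    return OrderingAccuracy(
        overall=float(flags["accurate"].mean()), per_group=per_group, flags=flags
    )
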