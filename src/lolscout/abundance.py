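"""Differential outer-membrane proteome filtering and tallying.

Label-free quantification software reports, per protein, a linear-scale
fold change (mutant/WT) and a significance score defined as -10*log10 of
the testing p-value, so that p = 0.01 corresponds to a score of 20. The
standard screen keeps proteins with fold change >= 1.5 (applied two-sidedly
via max(FC, 1/FC), so 2-fold depletions count) and significance >= 20, then
tallies the survivors by predicted localization class (NO_SP / SPI / SPII /
SPII_LES) and functional category, and intersects the filtered sets of two
mutant-vs-WT comparisons.

Quantitation itself (spectrum matching, normalization, rollup) is out of
scope; this module consumes summary tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

LOC_CLASSES = ("NO_SP", "SPI", "SPII", "SPII_LES")

UP = "UP"
DOWN = "DOWN"


def significance_from_p(p):
    """Significance score ``-10*log10(p)``; strictly decreasing in p.

    Accepts a scalar or array; p must lie in (0, 1].
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    out = -10.0 * np.log10(arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def p_from_significance(s):
    """Inverse of :func:`significance_from_p`."""
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0):
        raise ValueError("significance scores must be >= 0")
    out = 10.0 ** (-arr / 10.0)
    return float(out) if np.isscalar(s) or arr.ndim == 0 else out


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds of the abundance screen; both inclusive (>=)."""

    fc_min: float = 1.5
    sig_min: float = 20.0

    def __post_init__(self) -> None:
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1 (applied to max(FC, 1/FC))")
        if self.sig_min < 0:
            raise ValueError("sig_min must be >= 0")


def prepare_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a summary table and derive significance and direction.

    Requires ``protein_id`` and ``fold_change`` plus at least one of
    ``p_value`` / ``significance`` per row; when both are present their
    consistency is checked to 1e-6. Adds ``direction`` (UP if FC > 1).
    """
    df = df.copy()
    for col in ("protein_id", "fold_change"):
        if col not in df.columns:
            raise ValueError(f"summary table missing column {col!r}")
    if not (df["fold_change"] > 0).all():
        bad = df.loc[~(df["fold_change"] > 0), "protein_id"].iloc[0]
        raise ValueError(f"non-positive fold_change for protein {bad!r}")
    has_p = "p_value" in df.columns
    has_s = "significance" in df.columns
    if not has_p and not has_s:
        raise ValueError("summary table needs a p_value or significance column")
    p = df["p_value"] if has_p else pd.Series(np.nan, index=df.index)
    s = df["significance"] if has_s else pd.Series(np.nan, index=df.index)
    missing = p.isna() & s.isna()
    if missing.any():
        bad = df.loc[missing, "protein_id"].iloc[0]
        raise ValueError(f"protein {bad!r} has neither p_value nor significance")
    both = p.notna() & s.notna()
    if both.any():
        expected = -10.0 * np.log10(p[both].astype(float))
        if not np.allclose(expected, s[both].astype(float), atol=1e-6, rtol=0):
            bad = df.loc[both, "protein_id"][
                ~np.isclose(expected, s[both].astype(float), atol=1e-6, rtol=0)
            ].iloc[0]
            raise ValueError(
                f"protein {bad!r}: significance inconsistent with -10*log10(p)"
            )
    sig = s.astype(float).copy()
    fill = s.isna()
    sig[fill] = -10.0 * np.log10(p[fill].astype(float))
    df["significance"] = sig
    df["direction"] = np.where(df["fold_change"] > 1.0, UP, DOWN)
    if "loc_class" in df.columns:
        unknown = ~df["loc_class"].isin(LOC_CLASSES)
        if unknown.any():
            bad = df.loc[unknown].iloc[0]
            raise ValueError(
                f"protein {bad['protein_id']!r}: unknown loc_class "
                f"{bad['loc_class']!r} (expected one of {list(LOC_CLASSES)})"
            )
    return df


def apply_filter(df: pd.DataFrame, spec: FilterSpec = FilterSpec()) -> pd.DataFrame:
    """Keep rows with max(FC, 1/FC) >= fc_min AND significance >= sig_min.

    Order-stable; input rows lacking derived columns are prepared first.
    """
    if "significance" not in df.columns or "direction" not in df.columns:
        df = prepare_records(df)
    fc = df["fold_change"].astype(float)
    ratio = np.maximum(fc, 1.0 / fc)
    keep = (ratio >= spec.fc_min) & (df["significance"] >= spec.sig_min)
    return df.loc[keep].reset_index(drop=True)


def _percent_half_up(fraction: float) -> int:
    return int(math.floor(fraction * 100.0 + 0.5))


@dataclass(frozen=True)
class TallyReport:
    """Counts of filtered proteins by localization class and category."""

    total_significant: int
    by_loc_class: Mapping[str, int]
    by_category: Mapping[str, tuple[int, int]]  # category -> (up, down)
    no_sp_fraction: float
    no_sp_percent: int = field(default=0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"loc_class": c, "count": self.by_loc_class.get(c, 0)}
            for c in LOC_CLASSES
        ]
        return pd.DataFrame(rows)


def tally(filtered: pd.DataFrame) -> TallyReport:
    """Tally a filtered table by loc_class and by category (up/down split).

    ``no_sp_fraction`` is the share of NO_SP entries among all significant
    entries; it is also reported as a half-up-rounded integer percentage.
    """
    total = len(filtered)
    if total and "loc_class" not in filtered.columns:
        raise ValueError("tally requires a loc_class column")
    by_class = {c: 0 for c in LOC_CLASSES}
    by_cat: dict[str, tuple[int, int]] = {}
    if total:
        for c, n in filtered["loc_class"].value_counts().items():
            by_class[c] = int(n)
        if "category" in filtered.columns:
            grp = filtered.groupby("category")["direction"]
            for cat, dirs in grp:
                ups = int((dirs == UP).sum())
                by_cat[str(cat)] = (ups, len(dirs) - ups)
    frac = by_class["NO_SP"] / total if total else 0.0
    return TallyReport(
        total_significant=total,
        by_loc_class=by_class,
        by_category=by_cat,
        no_sp_fraction=frac,
        no_sp_percent=_percent_half_up(frac),
    )


@dataclass(frozen=True)
class OverlapReport:
    """Set comparison of two filtered mutant-vs-WT protein lists."""

    shared: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    shared_concordant: frozenset[str]
    shared_discordant: frozenset[str]
    shared_both_up: frozenset[str]
    shared_both_down: frozenset[str]


def compare_conditions(
    filtered_a: pd.DataFrame, filtered_b: pd.DataFrame
) -> OverlapReport:
    """Intersect two filtered sets keyed by protein_id, split by direction."""

    def _directions(df: pd.DataFrame) -> dict[str, str]:
        if "direction" in df.columns:
            return dict(zip(df["protein_id"], df["direction"]))
        return {
            pid: (UP if fc > 1.0 else DOWN)
            for pid, fc in zip(df["protein_id"], df["fold_change"])
        }

    dir_a = _directions(filtered_a)
    dir_b = _directions(filtered_b)
    a_ids, b_ids = set(dir_a), set(dir_b)
    shared = a_ids & b_ids
    concordant = {p for p in shared if dir_a[p] == dir_b[p]}
    return OverlapReport(
        shared=frozenset(shared),
        only_a=frozenset(a_ids - b_ids),
        only_b=frozenset(b_ids - a_ids),
        shared_concordant=frozenset(concordant),
        shared_discordant=frozenset(shared - concordant),
        shared_both_up=frozenset(p for p in concordant if dir_a[p] == UP),
        shared_both_down=frozenset(p for p in concordant if dir_a[p] == DOWN),
    )


def add_bh_qvalues(df: pd.DataFrame, p_col: str = "p_value") -> pd.DataFrame:
    """Append a Benjamini-Hochberg ``q_value`` column (optional utility;
    the standard screen itself applies no multiplicity correction)."""
    df = df.copy()
    p = df[p_col].astype(float).to_numpy()
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    df["q_value"] = out
    return df
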