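"""Sequence-level physico-chemical profiling of lipoprotein-transfer partners.

A periplasmic chaperone hands its lipoprotein cargo to an outer-membrane
acceptor only if the acceptor's binding cavity offers a more hydrophobic
environment — a *favorable hydrophobic gradient*. This module provides the
sequence/residue-set surrogates used to compare candidate donor/acceptor
pairs:

* residue composition over a user-supplied selection (e.g. the residues a
  structure viewer assigns to the concave cavity side),
* mean Eisenberg normalized-consensus hydrophobicity,
* Henderson-Hasselbalch net charge with a fixed textbook pKa table, and
* a thresholded donor-to-acceptor gradient call
  (FAVORABLE / NEUTRAL / UNFAVORABLE).

Structure prediction, surface-patch extraction and Poisson-Boltzmann
electrostatics are out of scope: selections are inputs, the charge model is
sequence-level.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._scales import (
    AMINO_ACIDS,
    EISENBERG,
    HYDROPHOBIC_RESIDUES,
    PKA_CTERM,
    PKA_NEGATIVE,
    PKA_NTERM,
    PKA_POSITIVE,
)

FAVORABLE = "FAVORABLE"
UNFAVORABLE = "UNFAVORABLE"
NEUTRAL = "NEUTRAL"

_VALID = set(AMINO_ACIDS)


@dataclass(frozen=True)
class ResidueSelection:
    """A labelled set of 1-based positions in a sequence (None = all)."""

    protein_id: str
    label: str = "full"
    positions: frozenset[int] | None = None

    def resolve(self, seq: str) -> str:
        """Return the selected residues of ``seq`` in sequence order."""
        if self.positions is None:
            sub = seq
        else:
            bad = [p for p in self.positions if not 1 <= p <= len(seq)]
            if bad:
                raise ValueError(
                    f"{self.protein_id}/{self.label}: positions out of range "
                    f"for length {len(seq)}: {sorted(bad)[:5]}"
                )
            sub = "".join(seq[p - 1] for p in sorted(self.positions))
        if not sub:
            raise ValueError(f"{self.protein_id}/{self.label}: empty selection")
        return sub


def parse_positions(text: str) -> frozenset[int] | None:
    """Parse ``"1-10,15,20-30"`` (1-based, inclusive) or ``"ALL"``."""
    text = text.strip()
    if text.upper() == "ALL":
        return None
    positions: set[int] = set()
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        m = re.fullmatch(r"(\d+)-(\d+)", part)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo > hi:
                raise ValueError(f"descending range {part!r}")
            positions.update(range(lo, hi + 1))
        elif part.isdigit():
            positions.add(int(part))
        else:
            raise ValueError(f"cannot parse position token {part!r}")
    if not positions:
        raise ValueError(f"empty position list {text!r}")
    return frozenset(positions)


def net_charge(seq: str, pH: float = 7.0, include_termini: bool = False) -> float:
    """Henderson-Hasselbalch net charge of a residue set at a given pH.

    Sums signed protonation occupancies over the ionizable side chains
    (K, R, H positive; D, E, C, Y negative), optionally adding the free
    termini. The physiologically meaningful range is pH 0-14, but the model
    is defined for any real pH, which is convenient for limit checks.
    Monotonically non-increasing in pH.
    """
    seq = str(seq).upper()
    charge = 0.0
    for aa in seq:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (pH - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - pH))
    if include_termini and seq:
        charge += 1.0 / (1.0 + 10.0 ** (pH - PKA_NTERM))
        charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - pH))
    return charge


@dataclass(frozen=True)
class CompositionProfile:
    """Residue-composition summary of one selection."""

    protein_id: str
    label: str
    n_residues: int
    fractions: Mapping[str, float]
    hydrophobic_fraction: float
    leu_ile_fraction: float
    lys_fraction: float
    arg_fraction: float
    mean_eisenberg: float
    net_charge_pH7: float


def composition_profile(
    seq: str, selection: ResidueSelection | None = None
) -> CompositionProfile:
    """Compute the composition profile of ``seq`` over ``selection``.

    Fractions are relative frequencies over the 20 canonical residues within
    the selected positions only; ``hydrophobic_fraction`` sums the residues
    with positive Eisenberg value; net charge is evaluated at pH 7 without
    termini (selections are usually internal patches).
    """
    seq = str(seq).upper()
    bad = [(i, aa) for i, aa in enumerate(seq, 1) if aa not in _VALID]
    if bad:
        i, aa = bad[0]
        raise ValueError(f"non-canonical residue {aa!r} at position {i}")
    if selection is None:
        selection = ResidueSelection(protein_id="query")
    sub = selection.resolve(seq)
    n = len(sub)
    fractions = {aa: sub.count(aa) / n for aa in AMINO_ACIDS}
    return CompositionProfile(
        protein_id=selection.protein_id,
        label=selection.label,
        n_residues=n,
        fractions=fractions,
        hydrophobic_fraction=sum(fractions[aa] for aa in HYDROPHOBIC_RESIDUES),
        leu_ile_fraction=fractions["L"] + fractions["I"],
        lys_fraction=fractions["K"],
        arg_fraction=fractions["R"],
        mean_eisenberg=sum(EISENBERG[aa] for aa in sub) / n,
        net_charge_pH7=net_charge(sub, pH=7.0, include_termini=False),
    )


@dataclass(frozen=True)
class GradientCall:
    """Donor-to-acceptor hydrophobic-gradient verdict."""

    donor_id: str
    acceptor_id: str
    delta_hydrophobic_fraction: float
    delta_mean_eisenberg: float
    call: str
    neutral_band: float


def gradient_call(
    donor: CompositionProfile,
    acceptor: CompositionProfile,
    epsilon: float = 0.01,
) -> GradientCall:
    """Call the transfer gradient: FAVORABLE when the acceptor's hydrophobic
    fraction exceeds the donor's by more than ``epsilon``."""
    delta_h = acceptor.hydrophobic_fraction - donor.hydrophobic_fraction
    delta_e = acceptor.mean_eisenberg - donor.mean_eisenberg
    if delta_h > epsilon:
        call = FAVORABLE
    elif delta_h < -epsilon:
        call = UNFAVORABLE
    else:
        call = NEUTRAL
    return GradientCall(
        donor_id=donor.protein_id,
        acceptor_id=acceptor.protein_id,
        delta_hydrophobic_fraction=delta_h,
        delta_mean_eisenberg=delta_e,
        call=call,
        neutral_band=epsilon,
    )


_PROFILE_FIELDS = (
    "hydrophobic_fraction",
    "leu_ile_fraction",
    "lys_fraction",
    "arg_fraction",
    "mean_eisenberg",
    "net_charge_pH7",
)


def profiles_table(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """One row per profile, ordered by (protein_id, label)."""
    rows = [
        {
            "protein_id": p.protein_id,
            "label": p.label,
            "n_residues": p.n_residues,
            **{f: getattr(p, f) for f in _PROFILE_FIELDS},
        }
        for p in profiles
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["protein_id", "label"], kind="stable").reset_index(drop=True)


def compare_profiles(
    profiles: Sequence[CompositionProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate profiles plus all pairwise deltas (B minus A).

    Returns ``(profiles_df, deltas_df)``; requires at least two profiles.
    Pair order follows the sorted profile table, so output is stable.
    """
    if len(profiles) < 2:
        raise ValueError("compare_profiles requires >= 2 profiles")
    ordered = sorted(profiles, key=lambda p: (p.protein_id, p.label))
    prof_df = profiles_table(ordered)
    delta_rows = []
    for a, b in itertools.combinations(ordered, 2):
        row = {
            "profile_a": f"{a.protein_id}/{a.label}",
            "profile_b": f"{b.protein_id}/{b.label}",
        }
        for f in _PROFILE_FIELDS:
            row[f"delta_{f}"] = getattr(b, f) - getattr(a, f)
        delta_rows.append(row)
    return prof_df, pd.DataFrame(delta_rows)
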