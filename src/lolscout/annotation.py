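"""Rule-based signal-peptide classification for envelope proteins.

Classifies each protein as NONE / SPI / SPII and, for SPII lipoproteins,
flags the Bacteroidota lipoprotein export signal (LES) that directs surface
exposure. The classes mirror the localization bins used for outer-membrane
proteome triage: cytoplasmic (no signal peptide), integral-OM/periplasmic
(SPI), periplasm-facing lipoprotein (SPII), surface-exposed lipoprotein
(SPII-LES).

The classifier is a transparent surrogate for neural signal-peptide
predictors: SPII is called from a lipobox consensus motif ending in the
lipidated Cys, SPI from a hydrophobic h-region (Eisenberg-scored) followed
by an A-X-A-style cleavage motif. Precedence is SPII > SPI. The LES motif
is fully configurable; the shipped default is a placeholder used by the
synthetic sequence generator, not a curated biological consensus.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from ._scales import AMINO_ACIDS, EISENBERG

SP_NONE = "NONE"
SP_I = "SPI"
SP_II = "SPII"

_VALID = set(AMINO_ACIDS)


@dataclass(frozen=True)
class AnnotationRules:
    """Tunable motif rules for the SPI/SPII/LES classifier.

    lipobox_pattern
        Residue-class motif ending in the lipidated Cys.
    lipobox_search_window
        1-based inclusive residue interval the whole lipobox match must lie in.
    spi_h_region_min_hydrophobicity
        Minimum mean Eisenberg value over a 7-residue window for an SPI
        h-region (must occur within residues 1-35).
    spi_cleavage_motif
        Signal-peptidase-I cleavage motif; its final residue must fall within
        residues 15-45 and after the h-region.
    les_pattern / les_window_length
        Motif searched within the first ``les_window_length`` mature residues
        after the lipidated Cys. Placeholder default.
    """

    lipobox_pattern: str = "[LVIFMSTAG][ASTVIG][GAS]C"
    lipobox_search_window: tuple[int, int] = (10, 40)
    spi_h_region_min_hydrophobicity: float = 1.0
    spi_h_region_length: int = 7
    spi_cleavage_motif: str = "A[^PC]A"
    les_pattern: str = "[DE][DE]"
    les_window_length: int = 6

    def __post_init__(self) -> None:
        if self.lipobox_search_window[0] > self.lipobox_search_window[1]:
            raise ValueError("lipobox_search_window must be a non-empty interval")
        if not self.lipobox_pattern or not self.spi_cleavage_motif:
            raise ValueError("motif patterns must be non-empty")
        if self.les_window_length < 1:
            raise ValueError("les_window_length must be >= 1")


DEFAULT_RULES = AnnotationRules()

# SPI motif geometry: h-region must start within residues 1-35, the cleavage
# motif's final residue within residues 15-45.
_SPI_H_REGION_LAST_START = 35
_SPI_CLEAVAGE_SPAN = (15, 45)


@dataclass(frozen=True)
class SignalAnnotation:
    """Per-protein signal class with cleavage-site coordinates (1-based)."""

    protein_id: str
    sp_class: str
    cleavage_pos: int | None = None
    lipobox_window: tuple[int, int] | None = None
    les_present: bool = False

    def __post_init__(self) -> None:
        if self.sp_class == SP_NONE and (
            self.cleavage_pos is not None or self.les_present
        ):
            raise ValueError("NONE class cannot carry cleavage_pos or les_present")


def _check_sequence(seq: str) -> None:
    for i, aa in enumerate(seq, start=1):
        if aa not in _VALID:
            raise ValueError(f"non-canonical residue {aa!r} at position {i}")


def _find_lipobox(seq: str, rules: AnnotationRules) -> re.Match | None:
    lo, hi = rules.lipobox_search_window
    for m in re.finditer(rules.lipobox_pattern, seq):
        start_1b, end_1b = m.start() + 1, m.end()
        if start_1b >= lo and end_1b <= hi:
            return m  # leftmost in-window match wins
    return None


def _find_spi(seq: str, rules: AnnotationRules) -> int | None:
    """Return 1-based first mature residue if the SPI rule matches."""
    k = rules.spi_h_region_length
    h_end = None  # 0-based index one past the h-region
    limit = min(_SPI_H_REGION_LAST_START, len(seq))
    for i in range(0, limit - k + 1):
        window = seq[i : i + k]
        mean_h = sum(EISENBERG[aa] for aa in window) / k
        if mean_h >= rules.spi_h_region_min_hydrophobicity:
            h_end = i + k
            break
    if h_end is None:
        return None
    lo, hi = _SPI_CLEAVAGE_SPAN
    for m in re.finditer(rules.spi_cleavage_motif, seq):
        if m.start() >= h_end and lo <= m.end() <= hi and m.end() < len(seq):
            return m.end() + 1
    return None


def classify_signal(
    seq: str, rules: AnnotationRules = DEFAULT_RULES, protein_id: str = "query"
) -> SignalAnnotation:
    """Classify a sequence as NONE / SPI / SPII (precedence SPII > SPI).

    Sequences shorter than 30 residues are classified NONE with a warning;
    non-canonical residues raise ``ValueError`` naming the position.
    """
    seq = str(seq).upper()
    _check_sequence(seq)
    if len(seq) < 30:
        warnings.warn(
            f"{protein_id}: sequence shorter than 30 residues, classified NONE",
            stacklevel=2,
        )
        return SignalAnnotation(protein_id, SP_NONE)
    m = _find_lipobox(seq, rules)
    if m is not None:
        return SignalAnnotation(
            protein_id,
            SP_II,
            cleavage_pos=m.end(),  # 1-based position of the lipidated Cys
            lipobox_window=(m.start() + 1, m.end()),
        )
    spi_pos = _find_spi(seq, rules)
    if spi_pos is not None:
        return SignalAnnotation(protein_id, SP_I, cleavage_pos=spi_pos)
    return SignalAnnotation(protein_id, SP_NONE)


def flag_les(
    annotation: SignalAnnotation, seq: str, rules: AnnotationRules = DEFAULT_RULES
) -> SignalAnnotation:
    """Set ``les_present`` on an SPII annotation from the post-Cys window."""
    if annotation.sp_class != SP_II:
        raise ValueError(
            f"flag_les requires an SPII annotation, got {annotation.sp_class}"
        )
    seq = str(seq).upper()
    window = seq[annotation.cleavage_pos : annotation.cleavage_pos + rules.les_window_length]
    present = re.search(rules.les_pattern, window) is not None
    return dataclasses.replace(annotation, les_present=present)


def annotate(
    seq: str, rules: AnnotationRules = DEFAULT_RULES, protein_id: str = "query"
) -> SignalAnnotation:
    """Classify and, for SPII, flag the LES in one call."""
    ann = classify_signal(seq, rules, protein_id)
    if ann.sp_class == SP_II:
        ann = flag_les(ann, seq, rules)
    return ann


ANNOTATION_COLUMNS = (
    "protein_id",
    "sp_class",
    "cleavage_pos",
    "lipobox_start",
    "lipobox_end",
    "les_present",
)


def annotate_records(
    records: Iterable, rules: AnnotationRules = DEFAULT_RULES
) -> pd.DataFrame:
    """Annotate an iterable of (id, seq) pairs or Bio SeqRecords."""
    rows = []
    seen: set[str] = set()
    for rec in records:
        pid, seq = (rec.id, str(rec.seq)) if hasattr(rec, "seq") else rec
        if pid in seen:
            raise ValueError(f"duplicate FASTA id {pid!r}")
        seen.add(pid)
        ann = annotate(seq, rules, protein_id=pid)
        lo, hi = ann.lipobox_window or (pd.NA, pd.NA)
        rows.append(
            {
                "protein_id": pid,
                "sp_class": ann.sp_class,
                "cleavage_pos": ann.cleavage_pos if ann.cleavage_pos else pd.NA,
                "lipobox_start": lo,
                "lipobox_end": hi,
                "les_present": ann.les_present,
            }
        )
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    for col in ("cleavage_pos", "lipobox_start", "lipobox_end"):
        df[col] = df[col].astype("Int64")
    return df


def annotate_fasta(
    path: str | Path,
    rules: AnnotationRules = DEFAULT_RULES,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Annotate every record of a FASTA file; optionally write the TSV."""
    df = annotate_records(SeqIO.parse(str(path), "fasta"), rules)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df
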