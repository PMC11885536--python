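"""Embedded residue-level constants: hydrophobicity scale and pKa table.

Two lookup tables drive every sequence-level physico-chemical surrogate in
this package:

* the Eisenberg normalized consensus hydrophobicity scale (Eisenberg et al.,
  J Mol Biol 1984), in the per-residue form popularised by PyMOL's
  ``color_h`` colouring script, and
* a fixed textbook pKa set for the Henderson-Hasselbalch net-charge model.

Keeping them as plain module constants makes the surrogates transparent and
trivially testable; no environment-dependent (PROPKA-style) adjustment is
attempted.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Eisenberg normalized consensus hydrophobicity, one value per residue.
EISENBERG: dict[str, float] = {
    "A": 0.620, "R": -2.530, "N": -0.780, "D": -0.900, "C": 0.290,
    "Q": -0.850, "E": -0.740, "G": 0.480, "H": -0.400, "I": 1.380,
    "L": 1.060, "K": -1.500, "M": 0.640, "F": 1.190, "P": 0.120,
    "S": -0.180, "T": -0.050, "W": 0.810, "Y": 0.260, "V": 1.080,
}

#: Residues counted as hydrophobic: positive Eisenberg consensus value.
HYDROPHOBIC_RESIDUES: frozenset[str] = frozenset(
    aa for aa, v in EISENBERG.items() if v > 0
)

#: Side-chain pKa values (standard textbook set).
PKA_POSITIVE: dict[str, float] = {"K": 10.53, "R": 12.48, "H": 6.0}
PKA_NEGATIVE: dict[str, float] = {"D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.07}
PKA_NTERM: float = 9.0
PKA_CTERM: float = 2.0
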