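"""Cross-species conservation profiling of homolog families.

Builds a phylogenetic-profile matrix (species x query family, cell =
homolog count) from homology-search hit tables thresholded at E <= 1e-3.
A subject protein hitting several query families below the cutoff is
assigned to the family with the smallest E-value; exact ties go to the
lexicographically first family and are flagged ambiguous so they can be
reviewed manually (the automated rule stands in for the manual
structure/synteny curation used to resolve paralogy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

DEFAULT_E_CUTOFF = 1e-3

HIT_COLUMNS = ("species_id", "subject_protein_id", "query_id", "e_value")


def read_species_hits(path) -> pd.DataFrame:
    """Read a species-hits TSV (species_id, subject_protein_id, query_id, e_value)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hits table missing columns {missing}")
    if not (df["e_value"] > 0).all():
        raise ValueError("e_value must be > 0")
    return df


def assign_families(
    hits: pd.DataFrame, e_cutoff: float = DEFAULT_E_CUTOFF
) -> pd.DataFrame:
    """Assign each subject protein to its best-E query family at the cutoff.

    Drops hits with E > cutoff; per (species, subject), keeps the family with
    the smallest E-value (ties: lexicographically first family, flagged
    ``ambiguous``). The result is a partition: one row per assigned subject.
    """
    if not e_cutoff > 0:
        raise ValueError("e_cutoff must be > 0")
    kept = hits.loc[hits["e_value"] <= e_cutoff]
    if kept.empty:
        return pd.DataFrame(
            columns=["species_id", "subject_protein_id", "family", "e_value", "ambiguous"]
        )
    rows = []
    for (species, subject), grp in kept.groupby(
        ["species_id", "subject_protein_id"], sort=True
    ):
        best_e = grp["e_value"].min()
        best = sorted(grp.loc[grp["e_value"] == best_e, "query_id"])
        rows.append(
            {
                "species_id": species,
                "subject_protein_id": subject,
                "family": best[0],
                "e_value": best_e,
                "ambiguous": len(set(best)) > 1,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PresenceMatrix:
    """Species x family homolog-count matrix."""

    counts: pd.DataFrame  # index: species, columns: families, values: int
    total_homologs: int

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence view (count > 0)."""
        return self.counts > 0


def build_matrix(
    assigned: pd.DataFrame,
    species: Sequence[str],
    families: Sequence[str],
    include_unlisted_species: bool = False,
) -> PresenceMatrix:
    """Count distinct assigned subjects per (species, family) cell.

    Species with no hits appear as zero rows. A hit from a species not in
    ``species`` raises unless ``include_unlisted_species`` is set, in which
    case the species is appended. Unknown families always raise.
    """
    if not len(species) or not len(families):
        raise ValueError("species and family lists must be non-empty")
    species = list(dict.fromkeys(species))
    families = list(dict.fromkeys(families))
    if len(assigned):
        extra_sp = sorted(set(assigned["species_id"]) - set(species))
        if extra_sp:
            if include_unlisted_species:
                species = species + extra_sp
            else:
                raise ValueError(
                    f"hits reference species not in the species list: {extra_sp}"
                )
        extra_fam = sorted(set(assigned["family"]) - set(families))
        if extra_fam:
            raise ValueError(
                f"hits reference families not in the family list: {extra_fam}"
            )
    counts = pd.DataFrame(0, index=species, columns=families, dtype=int)
    if len(assigned):
        dedup = assigned.drop_duplicates(["species_id", "subject_protein_id"])
        tab = dedup.groupby(["species_id", "family"]).size()
        for (sp, fam), n in tab.items():
            counts.loc[sp, fam] = int(n)
    return PresenceMatrix(counts=counts, total_homologs=int(counts.to_numpy().sum()))


@dataclass(frozen=True)
class MatrixSummary:
    """Per-family species coverage and fully-equipped species."""

    coverage: Mapping[str, float]  # family -> fraction of species with count > 0
    missing_species: Mapping[str, tuple[str, ...]]  # family -> species lacking it
    complete_species: tuple[str, ...]  # species with all core families present
    core_families: tuple[str, ...]


def matrix_summary(
    matrix: PresenceMatrix, core_families: Sequence[str] | None = None
) -> MatrixSummary:
    """Summarise a presence matrix.

    ``core_families`` defaults to all families; ``complete_species`` lists the
    species carrying at least one homolog of every core family (e.g. the full
    chaperone + insertase complement when the core pair is supplied).
    """
    pres = matrix.presence()
    n_species = len(matrix.species)
    core = list(core_families) if core_families is not None else matrix.families
    unknown = [f for f in core if f not in matrix.families]
    if unknown:
        raise ValueError(f"core families not in matrix: {unknown}")
    coverage = {
        f: (pres[f].sum() / n_species if n_species else 0.0) for f in matrix.families
    }
    missing = {
        f: tuple(sp for sp in matrix.species if not pres.loc[sp, f])
        for f in matrix.families
    }
    complete = tuple(
        sp for sp in matrix.species if all(pres.loc[sp, f] for f in core)
    )
    return MatrixSummary(
        coverage=coverage,
        missing_species=missing,
        complete_species=complete,
        core_families=tuple(core),
    )


def write_matrix(matrix: PresenceMatrix, path) -> None:
    matrix.counts.rename_axis("species_id").to_csv(path, sep="\t")


def write_summary(summary: MatrixSummary, path) -> None:
    rows = [
        {
            "family": f,
            "coverage": f"{summary.coverage[f]:.6g}",
            "missing_species": ";".join(summary.missing_species[f]),
        }
        for f in summary.coverage
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
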