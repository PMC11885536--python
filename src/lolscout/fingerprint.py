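"""Remote-homolog discovery by shared structural-template hit lists.

A profile/structure search (e.g. HHsearch) assigns every query protein a
*hit list*: known structural templates with E-values. Two proteins whose
hit lists share significant templates are candidate remote homologs even
when direct sequence similarity is undetectable. This module ingests such
hit lists from a 3-column TSV dialect, thresholds them at an E-value
cutoff (default 1e-3), intersects each proteome protein's significant
template set with a reference protein's set, and ranks the candidates.

Running the profile search itself is out of scope; the module consumes its
tabular output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DEFAULT_CUTOFF = 1e-3

HIT_TABLE_COLUMNS = ("query_id", "template_id", "e_value")


class HitTableFormatError(ValueError):
    """Raised when a hit-table TSV does not match the documented dialect."""


@dataclass(frozen=True)
class TemplateHit:
    """One template assignment for a query protein."""

    template_id: str
    e_value: float
    rank: int | None = None

    def __post_init__(self) -> None:
        if not self.e_value > 0:
            raise ValueError(
                f"e_value must be > 0, got {self.e_value!r} "
                f"for template {self.template_id!r}"
            )


@dataclass
class HitProfile:
    """A protein's template hit list; template ids unique (best E kept)."""

    protein_id: str
    hits: list[TemplateHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        best: dict[str, TemplateHit] = {}
        for hit in self.hits:
            prev = best.get(hit.template_id)
            if prev is None or hit.e_value < prev.e_value:
                best[hit.template_id] = hit
        self.hits = list(best.values())

    def significant_templates(self, cutoff: float = DEFAULT_CUTOFF) -> frozenset[str]:
        """Template ids with E-value <= cutoff (inclusive threshold)."""
        if not cutoff > 0:
            raise ValueError(f"cutoff must be > 0, got {cutoff}")
        return frozenset(h.template_id for h in self.hits if h.e_value <= cutoff)

    def template_ids(self) -> frozenset[str]:
        return frozenset(h.template_id for h in self.hits)


@dataclass(frozen=True)
class CandidateMatch:
    """A proteome protein scored against the reference by shared templates."""

    protein_id: str
    reference_id: str
    shared_templates: frozenset[str]
    overlap: int
    jaccard: float
    identical_sets: bool

    def sort_key(self) -> tuple:
        return (-self.overlap, -self.jaccard, self.protein_id)


def significant_templates(
    profile: HitProfile, cutoff: float = DEFAULT_CUTOFF
) -> frozenset[str]:
    """Functional alias for :meth:`HitProfile.significant_templates`."""
    return profile.significant_templates(cutoff)


def parse_hit_table(path: str | Path) -> dict[str, HitProfile]:
    """Parse a hit-table TSV into one :class:`HitProfile` per query.

    Dialect: UTF-8, tab-separated, header ``query_id  template_id  e_value``,
    ``#`` comment lines ignored. Duplicate (query, template) rows collapse to
    the minimum E-value. Errors name the offending line.
    """
    path = Path(path)
    profiles: dict[str, dict[str, float]] = {}
    header_seen = False
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(f.strip() for f in fields) != HIT_TABLE_COLUMNS:
                    raise HitTableFormatError(
                        f"{path}:{lineno}: unexpected header {fields!r}; "
                        f"expected columns {list(HIT_TABLE_COLUMNS)}"
                    )
                header_seen = True
                continue
            if len(fields) != 3:
                raise HitTableFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            query_id, template_id, e_raw = (f.strip() for f in fields)
            try:
                e_value = float(e_raw)
            except ValueError:
                raise HitTableFormatError(
                    f"{path}:{lineno}: malformed e_value {e_raw!r}"
                ) from None
            if not e_value > 0:
                raise HitTableFormatError(
                    f"{path}:{lineno}: e_value must be > 0, got {e_value}"
                )
            hits = profiles.setdefault(query_id, {})
            if template_id not in hits or e_value < hits[template_id]:
                hits[template_id] = e_value
    if not header_seen:
        raise HitTableFormatError(
            f"{path}: empty file; expected header {list(HIT_TABLE_COLUMNS)}"
        )
    return {
        qid: HitProfile(qid, [TemplateHit(t, e) for t, e in hits.items()])
        for qid, hits in profiles.items()
    }


def write_hit_table(
    profiles: Iterable[HitProfile], path: str | Path, reference: HitProfile | None = None
) -> None:
    """Write profiles (optionally prepended by a reference) in the TSV dialect."""
    path = Path(path)
    rows: list[HitProfile] = []
    if reference is not None:
        rows.append(reference)
    rows.extend(profiles)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(HIT_TABLE_COLUMNS) + "\n")
        for prof in rows:
            for hit in sorted(prof.hits, key=lambda h: (h.e_value, h.template_id)):
                fh.write(f"{prof.protein_id}\t{hit.template_id}\t{hit.e_value:.6g}\n")


def shared_template_candidates(
    proteome: Iterable[HitProfile] | Mapping[str, HitProfile],
    reference: HitProfile,
    cutoff: float = DEFAULT_CUTOFF,
    min_overlap: int = 1,
    exclude_self: bool = True,
    threshold_both: bool = True,
) -> list[CandidateMatch]:
    """Rank proteome proteins by significant-template overlap with a reference.

    Both hit lists are thresholded at ``cutoff`` by default; set
    ``threshold_both=False`` to threshold only the reference list. Candidates
    with ``overlap >= min_overlap`` are ranked by overlap descending, then
    Jaccard descending, then protein id ascending. ``identical_sets`` flags
    the strict reading of template-set identity.
    """
    if isinstance(proteome, Mapping):
        proteome = proteome.values()
    ref_set = reference.significant_templates(cutoff)
    if not ref_set:
        raise ValueError(
            f"reference hit list empty at cutoff {cutoff:g} "
            f"(reference {reference.protein_id!r})"
        )
    matches: list[CandidateMatch] = []
    for prof in proteome:
        if exclude_self and prof.protein_id == reference.protein_id:
            continue
        prot_set = (
            prof.significant_templates(cutoff) if threshold_both else prof.template_ids()
        )
        shared = prot_set & ref_set
        overlap = len(shared)
        if overlap < min_overlap:
            continue
        union = len(prot_set | ref_set)
        jaccard = overlap / union if union else 0.0
        matches.append(
            CandidateMatch(
                protein_id=prof.protein_id,
                reference_id=reference.protein_id,
                shared_templates=frozenset(shared),
                overlap=overlap,
                jaccard=jaccard,
                identical_sets=(jaccard == 1.0 and overlap > 0),
            )
        )
    matches.sort(key=CandidateMatch.sort_key)
    return matches


def write_candidates(matches: Sequence[CandidateMatch], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            "protein_id\treference_id\toverlap\tjaccard\t"
            "identical_sets\tshared_template_ids\n"
        )
        for m in matches:
            shared = ";".join(sorted(m.shared_templates))
            fh.write(
                f"{m.protein_id}\t{m.reference_id}\t{m.overlap}\t"
                f"{m.jaccard:.6g}\t{str(m.identical_sets).lower()}\t{shared}\n"
            )


@dataclass(frozen=True)
class RecoveryReport:
    """How well the ranking recovers planted homologs in a simulation."""

    recovered_top_k: float
    top_k: int
    n_planted: int
    background_above_worst_planted: int
    indistinguishable: bool


def recovery_benchmark(
    spec, cutoff: float = DEFAULT_CUTOFF, top_k: int = 5
) -> RecoveryReport:
    """Generate a synthetic proteome from ``spec`` and measure planted recovery.

    ``spec`` is a :class:`lolscout.synthetic.HitProfileSimSpec` with at least
    one planted homolog. Deterministic given the spec seed.
    """
    from .synthetic import gen_hit_profiles  # local import: avoid cycle

    if not spec.planted_ids:
        raise ValueError("recovery_benchmark requires >= 1 planted homolog")
    sim = gen_hit_profiles(spec)
    matches = shared_template_candidates(
        sim.proteome, sim.reference, cutoff=cutoff, min_overlap=0
    )
    planted = set(spec.planted_ids)
    rank_of = {m.protein_id: i for i, m in enumerate(matches)}
    in_top = sum(1 for pid in planted if rank_of.get(pid, math.inf) < top_k)
    planted_ranks = [rank_of[pid] for pid in planted if pid in rank_of]
    if planted_ranks:
        worst = max(planted_ranks)
        background_above = sum(
            1
            for m in matches[:worst]
            if m.protein_id not in planted
        )
    else:
        background_above = len(matches)
    indistinguishable = bool((sim.truth["warning"] != "").any())
    return RecoveryReport(
        recovered_top_k=in_top / len(planted),
        top_k=top_k,
        n_planted=len(planted),
        background_above_worst_planted=background_above,
        indistinguishable=indistinguishable,
    )
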