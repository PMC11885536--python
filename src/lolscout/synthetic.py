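"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs to this pipeline are bulky and external: whole-proteome
structure-search hit lists, proteome FASTA files, label-free MS abundance
tables, and cross-species homology-search hits. Each generator here emits
the same tabular shape the pipeline consumes, together with a truth table
recording what was planted, so recovery can be measured exactly:

* :func:`gen_hit_profiles` — a reference template set plus a proteome in
  which planted homologs share a controlled fraction of the reference's
  significant templates and background proteins hit templates at random.
* :func:`gen_sequences` — protein sequences with planted SPI / SPII /
  SPII-LES N-termini (rejection-sampled against the same rule set the
  classifier uses, so truth and rules cannot drift apart).
* :func:`gen_abundance_table` — two-condition replicate LFQ-style tables
  with log-normal abundances, planted log2 shifts, and Welch-test p-values.
* :func:`gen_species_hits` — species x family homolog hit tables with
  planted presence/absence and copy counts.

All randomness flows from one ``numpy`` Generator per spec seed; identical
spec + seed gives byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._scales import AMINO_ACIDS
from .annotation import DEFAULT_RULES, SP_II, SP_NONE, AnnotationRules, annotate
from .fingerprint import HitProfile, TemplateHit

_MAX_ATTEMPTS = 1000


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


# ---------------------------------------------------------------------------
# hit-list profiles


@dataclass(frozen=True)
class HitProfileSimSpec:
    """Parameters of the shared-template homolog simulation.

    ``overlap_fraction`` (rho) controls how many of the reference's
    significant templates each planted homolog shares (ceil(rho * ref set
    size), drawn without replacement); background proteins draw a
    Poisson(``background_rate``) number of significant templates uniformly
    from the whole universe, so chance overlap with the reference is
    possible but unplanted. Every protein additionally receives a
    Poisson(``nonsig_rate``) tail of non-significant hits to exercise
    E-value thresholding.
    """

    n_proteins: int = 100
    n_templates: int = 1000
    ref_template_count: int = 20
    planted_ids: tuple[str, ...] = ()
    overlap_fraction: float = 0.5
    background_rate: float = 2.0
    nonsig_rate: float = 1.0
    evalue_sig_range: tuple[float, float] = (1e-30, 1e-4)
    evalue_nonsig_range: tuple[float, float] = (2e-3, 10.0)
    seed: int = 0
    reference_id: str = "REF"

    def protein_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(1, self.n_proteins + 1)]

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.ref_template_count > self.n_templates:
            raise ValueError("ref_template_count exceeds template universe")
        if self.background_rate < 0 or self.nonsig_rate < 0:
            raise ValueError("rates must be >= 0")
        lo_s, hi_s = self.evalue_sig_range
        lo_n, hi_n = self.evalue_nonsig_range
        if not (0 < lo_s <= hi_s < lo_n <= hi_n):
            raise ValueError(
                "evalue_sig_range must lie entirely below evalue_nonsig_range"
            )
        unknown = set(self.planted_ids) - set(self.protein_ids())
        if unknown:
            raise ValueError(f"planted_ids not in generated ids: {sorted(unknown)}")


@dataclass(frozen=True)
class HitProfileSimResult:
    reference: HitProfile
    proteome: list[HitProfile]
    truth: pd.DataFrame  # protein_id, planted, n_shared_templates, warning


def gen_hit_profiles(spec: HitProfileSimSpec) -> HitProfileSimResult:
    """Simulate a reference hit list and a proteome with planted homologs."""
    rng = np.random.default_rng(spec.seed)
    templates = np.array([f"T{i:05d}" for i in range(spec.n_templates)])
    ref_idx = rng.choice(spec.n_templates, size=spec.ref_template_count, replace=False)
    ref_set = set(ref_idx.tolist())
    lo_s, hi_s = spec.evalue_sig_range
    lo_n, hi_n = spec.evalue_nonsig_range
    ref_evals = _log_uniform(rng, lo_s, hi_s, spec.ref_template_count)
    reference = HitProfile(
        spec.reference_id,
        [TemplateHit(templates[i], e) for i, e in zip(ref_idx, ref_evals)],
    )
    n_shared = math.ceil(spec.overlap_fraction * spec.ref_template_count)
    warning = ""
    if spec.planted_ids and n_shared == 0:
        warning = "indistinguishable"  # rho rounds to zero shared templates

    non_ref = np.array(sorted(set(range(spec.n_templates)) - ref_set))
    planted = set(spec.planted_ids)
    proteome: list[HitProfile] = []
    truth_rows = []
    for pid in spec.protein_ids():
        is_planted = pid in planted
        if is_planted:
            shared_idx = rng.choice(ref_idx, size=n_shared, replace=False)
            n_extra = rng.poisson(spec.background_rate)
            extra_idx = (
                rng.choice(non_ref, size=min(n_extra, len(non_ref)), replace=False)
                if len(non_ref)
                else np.array([], dtype=int)
            )
            sig_idx = np.concatenate([shared_idx, extra_idx])
        else:
            n_bg = rng.poisson(spec.background_rate)
            sig_idx = rng.choice(
                spec.n_templates, size=min(n_bg, spec.n_templates), replace=False
            )
        sig_evals = _log_uniform(rng, lo_s, hi_s, len(sig_idx))
        hits = [TemplateHit(templates[i], e) for i, e in zip(sig_idx, sig_evals)]
        n_nonsig = rng.poisson(spec.nonsig_rate)
        if n_nonsig:
            ns_idx = rng.choice(
                spec.n_templates, size=min(n_nonsig, spec.n_templates), replace=False
            )
            ns_evals = _log_uniform(rng, lo_n, hi_n, len(ns_idx))
            hits.extend(
                TemplateHit(templates[i], e)
                for i, e in zip(ns_idx, ns_evals)
                if templates[i] not in {h.template_id for h in hits}
            )
        proteome.append(HitProfile(pid, hits))
        truth_rows.append(
            {
                "protein_id": pid,
                "planted": is_planted,
                "n_shared_templates": n_shared if is_planted else 0,
                "warning": warning if is_planted else "",
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["protein_id", "planted", "n_shared_templates", "warning"]
    )
    return HitProfileSimResult(reference=reference, proteome=proteome, truth=truth)


# ---------------------------------------------------------------------------
# sequences with planted signal peptides

CLASS_NONE = "NONE"
CLASS_SPI = "SPI"
CLASS_SPII = "SPII"
CLASS_SPII_LES = "SPII_LES"
SEQ_CLASSES = (CLASS_NONE, CLASS_SPI, CLASS_SPII, CLASS_SPII_LES)


@dataclass(frozen=True)
class SequenceSimSpec:
    """Parameters of the signal-peptide sequence simulation."""

    n_seqs: int = 100
    class_probabilities: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    length_range: tuple[int, int] = (120, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.class_probabilities
        if len(p) != 4 or any(x < 0 for x in p):
            raise ValueError("class_probabilities must be 4 non-negative values")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("class_probabilities must sum to 1")
        if self.length_range[0] < 50 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be ascending with minimum >= 50")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n)) if n > 0 else ""


def _pick(rng: np.random.Generator, pool: str, n: int = 1) -> str:
    return "".join(rng.choice(list(pool), size=n))


def _build_prefix(rng: np.random.Generator, cls: str) -> tuple[str, int]:
    """Signal-peptide prefix and 1-based cleavage position for SPI/SPII."""
    n_region = "M" + _pick(rng, "KR", int(rng.integers(2, 5)))
    if cls in (CLASS_SPII, CLASS_SPII_LES):
        h_region = _pick(rng, "LIVF", int(rng.integers(7, 13)))
        lipobox = _pick(rng, "LVIFMSTAG") + _pick(rng, "ASTVIG") + _pick(rng, "GAS") + "C"
        prefix = n_region + h_region + lipobox
        return prefix, len(prefix)  # Cys is the first mature (lipidated) residue
    h_region = _pick(rng, "LIVF", int(rng.integers(8, 13)))
    linker = _pick(rng, "STGQN", int(rng.integers(1, 4)))
    x = _pick(rng, AMINO_ACIDS.replace("P", "").replace("C", ""))
    prefix = n_region + h_region + linker + "A" + x + "A"
    return prefix, len(prefix) + 1  # first mature residue follows the A-X-A


def _build_sequence(
    rng: np.random.Generator, cls: str, length: int, rules: AnnotationRules
) -> tuple[str, int | None]:
    """Rejection-sample one sequence of class ``cls`` (truth by construction)."""
    for _ in range(_MAX_ATTEMPTS):
        if cls == CLASS_NONE:
            seq, planted_pos = _rand_seq(rng, length), None
        else:
            prefix, planted_pos = _build_prefix(rng, cls)
            mature_len = max(length - len(prefix), 10)
            if cls == CLASS_SPII_LES:
                les = _pick(rng, "DE", 2)  # instance of the placeholder LES motif
                mature = les + _rand_seq(rng, mature_len - len(les))
            else:
                mature = _rand_seq(rng, mature_len)
            seq = prefix + mature
        ann = annotate(seq, rules)
        want_class = SP_II if cls == CLASS_SPII_LES else (
            cls if cls != CLASS_NONE else SP_NONE
        )
        if ann.sp_class != want_class:
            continue
        if planted_pos is not None and ann.cleavage_pos != planted_pos:
            continue
        if cls == CLASS_SPII and ann.les_present:
            continue
        if cls == CLASS_SPII_LES and not ann.les_present:
            continue
        return seq, planted_pos
    raise RuntimeError(
        f"could not generate a {cls} sequence under the supplied rules "
        f"after {_MAX_ATTEMPTS} attempts"
    )


@dataclass(frozen=True)
class SequenceSimResult:
    records: list[SeqRecord]
    truth: pd.DataFrame  # protein_id, class_label, sp_class, cleavage_pos, les


def gen_sequences(
    spec: SequenceSimSpec, rules: AnnotationRules = DEFAULT_RULES
) -> SequenceSimResult:
    """Simulate sequences with planted signal-peptide classes.

    Every sequence is rejection-sampled until the classifier (with the same
    ``rules``) reproduces the planted class, cleavage site, and LES flag, so
    agreement between generator truth and classifier output is exact by
    construction.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SeqRecord] = []
    truth_rows = []
    probs = np.asarray(spec.class_probabilities, dtype=float)
    probs = probs / probs.sum()
    for i in range(1, spec.n_seqs + 1):
        cls = SEQ_CLASSES[int(rng.choice(4, p=probs))]
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq, cleavage = _build_sequence(rng, cls, length, rules)
        pid = f"S{i:04d}"
        records.append(SeqRecord(Seq(seq), id=pid, description=""))
        truth_rows.append(
            {
                "protein_id": pid,
                "class_label": cls,
                "sp_class": SP_II if cls == CLASS_SPII_LES else (
                    cls if cls != CLASS_NONE else SP_NONE
                ),
                "cleavage_pos": cleavage,
                "les": cls == CLASS_SPII_LES,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["protein_id", "class_label", "sp_class", "cleavage_pos", "les"],
    )
    truth["cleavage_pos"] = truth["cleavage_pos"].astype("Int64")
    return SequenceSimResult(records=records, truth=truth)


# ---------------------------------------------------------------------------
# two-condition abundance tables


@dataclass(frozen=True)
class AbundanceSimSpec:
    """Parameters of the LFQ-style differential-abundance simulation.

    Per-protein baseline log2 abundance ~ Normal(25, 1) across proteins;
    replicate log2 values ~ Normal(baseline [+ log2_shift in condition B for
    planted-DE proteins], replicate_sd). Fold change is the ratio of linear
    replicate means (B/A); the p-value is a two-sample Welch t-test on log2
    values (two-group surrogate for the quantitation software's ANOVA).
    """

    n_proteins: int = 1000
    n_replicates_per_group: int = 5
    de_fraction: float = 0.1
    log2_shift: float = 2.0
    replicate_sd: float = 0.25
    class_probabilities: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    category_labels: tuple[str, ...] = (
        "C", "E", "G", "M", "N", "O", "P", "T", "U", "UNKNOWN",
    )
    de_protein_ids: tuple[str, ...] | None = None
    baseline_mean: float = 25.0
    seed: int = 0

    def protein_ids(self) -> list[str]:
        return [f"Q{i:04d}" for i in range(1, self.n_proteins + 1)]

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.replicate_sd <= 0:
            raise ValueError("replicate_sd must be > 0")
        if self.n_replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        p = self.class_probabilities
        if len(p) != 4 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("class_probabilities must be 4 values summing to 1")
        if self.de_protein_ids is not None:
            unknown = set(self.de_protein_ids) - set(self.protein_ids())
            if unknown:
                raise ValueError(f"de_protein_ids not generated: {sorted(unknown)}")


@dataclass(frozen=True)
class AbundanceSimResult:
    replicates: pd.DataFrame  # protein_id, A1..Ar, B1..Br (linear scale)
    summary: pd.DataFrame  # protein_id, fold_change, p_value, significance, ...
    truth: pd.DataFrame  # protein_id, is_de, log2_shift, loc_class, category


def gen_abundance_table(spec: AbundanceSimSpec) -> AbundanceSimResult:
    """Simulate a two-condition replicate abundance experiment."""
    from .abundance import LOC_CLASSES, significance_from_p

    rng = np.random.default_rng(spec.seed)
    n, r = spec.n_proteins, spec.n_replicates_per_group
    ids = spec.protein_ids()
    if spec.de_protein_ids is not None:
        de_mask = np.isin(np.array(ids), np.array(spec.de_protein_ids))
    else:
        n_de = int(round(spec.de_fraction * n))
        de_mask = np.zeros(n, dtype=bool)
        if n_de:
            de_mask[rng.choice(n, size=n_de, replace=False)] = True
    baseline = rng.normal(spec.baseline_mean, 1.0, size=n)
    log_a = rng.normal(baseline[:, None], spec.replicate_sd, size=(n, r))
    shift = np.where(de_mask, spec.log2_shift, 0.0)
    log_b = rng.normal((baseline + shift)[:, None], spec.replicate_sd, size=(n, r))
    lin_a, lin_b = 2.0 ** log_a, 2.0 ** log_b

    loc_class = rng.choice(
        LOC_CLASSES, size=n, p=np.asarray(spec.class_probabilities)
    )
    category = rng.choice(spec.category_labels, size=n)

    rep_cols = {f"A{j + 1}": lin_a[:, j] for j in range(r)}
    rep_cols.update({f"B{j + 1}": lin_b[:, j] for j in range(r)})
    replicates = pd.DataFrame({"protein_id": ids, **rep_cols})

    if n:
        fold_change = lin_b.mean(axis=1) / lin_a.mean(axis=1)
        p_value = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False).pvalue
        p_value = np.clip(p_value, np.finfo(float).tiny, 1.0)
        significance = significance_from_p(p_value)
    else:
        fold_change = p_value = significance = np.array([])
    summary = pd.DataFrame(
        {
            "protein_id": ids,
            "fold_change": fold_change,
            "p_value": p_value,
            "significance": significance,
            "loc_class": loc_class,
            "category": category,
        }
    )
    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "is_de": de_mask,
            "log2_shift": shift,
            "loc_class": loc_class,
            "category": category,
        }
    )
    return AbundanceSimResult(replicates=replicates, summary=summary, truth=truth)


# ---------------------------------------------------------------------------
# species x family conservation hits


@dataclass(frozen=True)
class ConservationSimSpec:
    """Parameters of the cross-species homolog-hit simulation.

    Each (species, family) cell is present with ``presence_prob``; present
    cells carry 1 + Poisson(``extra_copy_rate``) homolog copies. Every copy
    hits its own family with a strong E-value and, with ``cross_hit_prob``,
    one other family with a strictly weaker (but still significant) E-value
    to exercise best-E assignment. Decoy hits above the cutoff are added per
    species at ``decoy_rate``.
    """

    species: tuple[str, ...] = tuple(f"sp{i:02d}" for i in range(1, 11))
    families: tuple[str, ...] = ("LolA1", "LolA2", "LolA3", "LolB1", "LolB2")
    presence_prob: float = 0.8
    extra_copy_rate: float = 0.2
    cross_hit_prob: float = 0.3
    decoy_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species or not self.families:
            raise ValueError("species and families must be non-empty")
        for p in (self.presence_prob, self.cross_hit_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ConservationSimResult:
    hits: pd.DataFrame  # species_id, subject_protein_id, query_id, e_value
    truth_counts: pd.DataFrame  # species rows x family columns


def gen_species_hits(spec: ConservationSimSpec) -> ConservationSimResult:
    """Simulate species x family homology hits with planted counts."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    counts = pd.DataFrame(
        0, index=list(spec.species), columns=list(spec.families), dtype=int
    )
    for sp in spec.species:
        subject_no = 0
        for fam in spec.families:
            if rng.random() >= spec.presence_prob:
                continue
            n_copies = 1 + rng.poisson(spec.extra_copy_rate)
            counts.loc[sp, fam] = n_copies
            for _ in range(n_copies):
                subject_no += 1
                subject = f"{sp}_g{subject_no:03d}"
                e_primary = float(_log_uniform(rng, 1e-30, 1e-6, 1)[0])
                rows.append((sp, subject, fam, e_primary))
                if len(spec.families) > 1 and rng.random() < spec.cross_hit_prob:
                    other = str(
                        rng.choice([f for f in spec.families if f != fam])
                    )
                    e_cross = float(_log_uniform(rng, 1e-5, 9e-4, 1)[0])
                    rows.append((sp, subject, other, e_cross))
        for _ in range(rng.poisson(spec.decoy_rate)):
            subject_no += 1
            subject = f"{sp}_g{subject_no:03d}"
            fam = str(rng.choice(list(spec.families)))
            e_decoy = float(_log_uniform(rng, 2e-3, 10.0, 1)[0])
            rows.append((sp, subject, fam, e_decoy))
    hits = pd.DataFrame(
        rows, columns=["species_id", "subject_protein_id", "query_id", "e_value"]
    )
    return ConservationSimResult(hits=hits, truth_counts=counts)


# ---------------------------------------------------------------------------
# file output helpers (fixed formatting so identical seeds give identical bytes)


def write_fasta(records, path: str | Path) -> None:
    from Bio import SeqIO

    SeqIO.write(records, str(path), "fasta")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
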