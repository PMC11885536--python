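"""Brute-force reference implementations used as independent oracles.

These deliberately re-derive results from first principles (materialising
every pairwise intersection with plain set arithmetic) and share no code
with the package paths they check.
"""

from __future__ import annotations


def brute_force_candidates(
    proteome,
    reference,
    cutoff: float = 1e-3,
    min_overlap: int = 1,
    exclude_self: bool = True,
):
    """Rank candidates by materialising every pairwise intersection.

    ``proteome``/``reference`` are iterables of objects with ``protein_id``
    and ``hits`` (template_id, e_value). Returns tuples
    (protein_id, overlap, jaccard, sorted shared ids, identical_sets).
    """
    ref_sig = {h.template_id for h in reference.hits if h.e_value <= cutoff}
    results = []
    for prof in proteome:
        if exclude_self and prof.protein_id == reference.protein_id:
            continue
        prot_sig = {h.template_id for h in prof.hits if h.e_value <= cutoff}
        shared = prot_sig & ref_sig
        if len(shared) < min_overlap:
            continue
        union = prot_sig | ref_sig
        jaccard = len(shared) / len(union) if union else 0.0
        results.append(
            (
                prof.protein_id,
                len(shared),
                jaccard,
                tuple(sorted(shared)),
                jaccard == 1.0 and len(shared) > 0,
            )
        )
    results.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return results


def brute_force_set_candidates(named_sets: dict, ref_set: set, min_overlap: int = 1):
    """Same ranking, but over pre-thresholded significant-template sets."""
    results = []
    for pid, s in named_sets.items():
        shared = s & ref_set
        if len(shared) < min_overlap:
            continue
        union = s | ref_set
        jaccard = len(shared) / len(union) if union else 0.0
        results.append((pid, len(shared), jaccard, tuple(sorted(shared))))
    results.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return results
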