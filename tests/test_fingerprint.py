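"""Shared-template candidate detection: parsing, thresholding, ranking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lolscout.fingerprint import (
    HitProfile,
    HitTableFormatError,
    TemplateHit,
    parse_hit_table,
    recovery_benchmark,
    shared_template_candidates,
    significant_templates,
    write_hit_table,
)
from lolscout.synthetic import HitProfileSimSpec

from oracle import brute_force_candidates


# --- parsing -----------------------------------------------------------------


def test_parse_collapses_duplicate_templates_to_best_evalue(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "query_id\ttemplate_id\te_value\n"
        "Q1\tT1\t1e-5\n"
        "Q1\tT1\t1e-4\n"
        "Q1\tT2\t1e-2\n"
    )
    profiles = parse_hit_table(path)
    assert set(profiles) == {"Q1"}
    hits = {h.template_id: h.e_value for h in profiles["Q1"].hits}
    assert hits == {"T1": 1e-5, "T2": 1e-2}


def test_parse_header_only_gives_empty_collection(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("query_id\ttemplate_id\te_value\n# a comment\n")
    assert parse_hit_table(path) == {}


def test_parse_malformed_evalue_names_line(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("query_id\ttemplate_id\te_value\nQ1\tT1\tabc\n")
    with pytest.raises(HitTableFormatError, match=r":2: malformed e_value 'abc'"):
        parse_hit_table(path)


def test_parse_unknown_header_lists_expected_columns(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("protein\ttemplate\tscore\nQ1\tT1\t1e-5\n")
    with pytest.raises(HitTableFormatError, match="query_id.*template_id.*e_value"):
        parse_hit_table(path)


def test_hit_table_roundtrip(tmp_path, make_profile):
    profiles = [make_profile("A", sig=["T1", "T2"], nonsig=["T3"]), make_profile("B", sig=["T4"])]
    path = tmp_path / "out.tsv"
    write_hit_table(profiles, path)
    back = parse_hit_table(path)
    assert {p: prof.template_ids() for p, prof in back.items()} == {
        "A": frozenset({"T1", "T2", "T3"}),
        "B": frozenset({"T4"}),
    }


def test_nonpositive_evalue_rejected():
    with pytest.raises(ValueError, match="e_value must be > 0"):
        TemplateHit("T1", 0.0)


# --- significance thresholding ----------------------------------------------


@pytest.mark.parametrize(
    "hits, cutoff, expected",
    [
        ([("T1", 1e-5), ("T2", 5e-3)], 1e-3, {"T1"}),
        ([("T1", 1e-3)], 1e-3, {"T1"}),  # boundary hit included (<= convention)
        ([], 1e-3, set()),
    ],
)
def test_significant_templates_threshold(hits, cutoff, expected):
    prof = HitProfile("Q", [TemplateHit(t, e) for t, e in hits])
    assert significant_templates(prof, cutoff) == frozenset(expected)


def test_significant_templates_monotone_in_cutoff():
    prof = HitProfile("Q", [TemplateHit(f"T{i}", 10.0 ** (-i)) for i in range(1, 9)])
    prev = frozenset()
    for cutoff in (1e-8, 1e-6, 1e-4, 1e-2, 1.0):
        cur = prof.significant_templates(cutoff)
        assert prev <= cur
        prev = cur


# --- candidate ranking -------------------------------------------------------


def test_candidates_worked_example(make_profile):
    proteome = [make_profile("P1", sig=["T1", "T2", "T3"]), make_profile("P2", sig=["T4"])]
    reference = make_profile("REF", sig=["T2", "T3", "T5"])
    matches = shared_template_candidates(proteome, reference)
    assert len(matches) == 1
    m = matches[0]
    assert m.protein_id == "P1"
    assert m.shared_templates == frozenset({"T2", "T3"})
    assert m.overlap == 2
    assert m.jaccard == pytest.approx(0.5)
    assert not m.identical_sets


def test_exact_copy_ranks_first_with_identical_sets(make_profile):
    reference = make_profile("REF", sig=["T1", "T2"])
    proteome = [
        make_profile("COPY", sig=["T1", "T2"]),
        make_profile("PART", sig=["T1", "T9"]),
    ]
    matches = shared_template_candidates(proteome, reference)
    assert [m.protein_id for m in matches] == ["COPY", "PART"]
    assert matches[0].identical_sets and matches[0].jaccard == 1.0


def test_reference_empty_at_cutoff_raises(make_profile):
    reference = make_profile("REF", nonsig=["T1"])
    with pytest.raises(ValueError, match="reference hit list empty at cutoff"):
        shared_template_candidates([], reference)


def test_self_exclusion_toggle(make_profile):
    reference = make_profile("REF", sig=["T1"])
    proteome = [make_profile("REF", sig=["T1"])]
    assert shared_template_candidates(proteome, reference) == []
    kept = shared_template_candidates(proteome, reference, exclude_self=False)
    assert [m.protein_id for m in kept] == ["REF"]


def test_overlap_symmetric_under_role_swap(make_profile):
    a = make_profile("A", sig=["T1", "T2", "T3"])
    b = make_profile("B", sig=["T2", "T3", "T4"])
    ab = shared_template_candidates([a], b)[0]
    ba = shared_template_candidates([b], a)[0]
    assert ab.overlap == ba.overlap == 2
    assert ab.jaccard == ba.jaccard


# --- property tests against the brute-force oracle ---------------------------

TEMPLATES = [f"T{i}" for i in range(8)]

profile_strategy = st.lists(
    st.tuples(
        st.sampled_from(TEMPLATES),
        st.one_of(
            st.floats(min_value=1e-30, max_value=1e-3),
            st.floats(min_value=2e-3, max_value=10.0),
        ),
    ),
    max_size=10,
)
proteome_strategy = st.lists(profile_strategy, min_size=0, max_size=6)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(proteome=proteome_strategy, reference=profile_strategy)
def test_ranking_matches_bruteforce_oracle(proteome, reference):
    """Ranked candidates equal a from-scratch pairwise-intersection oracle."""
    ref = HitProfile("REF", [TemplateHit(t, e) for t, e in reference])
    profs = [
        HitProfile(f"P{i}", [TemplateHit(t, e) for t, e in hits])
        for i, hits in enumerate(proteome)
    ]
    if not ref.significant_templates():
        return
    got = shared_template_candidates(profs, ref)
    expected = brute_force_candidates(profs, ref)
    assert [
        (m.protein_id, m.overlap, m.jaccard, tuple(sorted(m.shared_templates)), m.identical_sets)
        for m in got
    ] == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(profile=profile_strategy)
def test_lowering_cutoff_never_increases_overlap(profile):
    ref = HitProfile("REF", [TemplateHit(t, 1e-12) for t in TEMPLATES])
    prof = HitProfile("P", [TemplateHit(t, e) for t, e in profile])
    overlaps = []
    for cutoff in (1.0, 1e-2, 1e-4, 1e-6, 1e-8):
        m = shared_template_candidates([prof], ref, cutoff=cutoff, min_overlap=0)
        overlaps.append(m[0].overlap if m else 0)
    assert overlaps == sorted(overlaps, reverse=True)


# --- recovery benchmark ------------------------------------------------------


def test_recovery_perfect_when_planted_sets_equal_reference():
    spec = HitProfileSimSpec(
        n_proteins=20,
        planted_ids=("P0003", "P0007"),
        overlap_fraction=1.0,
        background_rate=0.0,
        seed=11,
    )
    report = recovery_benchmark(spec, top_k=2)
    assert report.recovered_top_k == 1.0
    assert report.background_above_worst_planted == 0
    assert not report.indistinguishable


def test_recovery_propagates_indistinguishability_warning():
    spec = HitProfileSimSpec(
        n_proteins=10,
        planted_ids=("P0001", "P0002", "P0003"),
        overlap_fraction=0.0,
        background_rate=0.5,
        seed=3,
    )
    report = recovery_benchmark(spec, top_k=3)
    assert report.indistinguishable


def test_recovery_requires_planted_homologs():
    spec = HitProfileSimSpec(n_proteins=5, planted_ids=())
    with pytest.raises(ValueError, match="planted"):
        recovery_benchmark(spec)
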