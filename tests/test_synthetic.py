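"""Synthetic generators: planted ground truth, determinism, recovery."""

import numpy as np
import pytest

from lolscout import synthetic as syn
from lolscout.annotation import annotate
from lolscout.fingerprint import write_hit_table


# --- hit-profile simulation --------------------------------------------------


def test_full_overlap_planted_set_equals_reference():
    spec = syn.HitProfileSimSpec(
        n_proteins=5,
        planted_ids=("P0002",),
        overlap_fraction=1.0,
        background_rate=0.0,
        nonsig_rate=0.0,
        seed=4,
    )
    sim = syn.gen_hit_profiles(spec)
    planted = next(p for p in sim.proteome if p.protein_id == "P0002")
    assert planted.significant_templates() == sim.reference.significant_templates()


def test_no_planted_rows_when_planted_list_empty():
    spec = syn.HitProfileSimSpec(n_proteins=10, planted_ids=(), overlap_fraction=0.0)
    sim = syn.gen_hit_profiles(spec)
    assert not sim.truth["planted"].any()
    assert len(sim.truth) == 10


def test_planted_share_exact_half_of_reference_templates():
    spec = syn.HitProfileSimSpec(
        n_proteins=50,
        n_templates=1000,
        ref_template_count=20,
        planted_ids=("P0001", "P0002", "P0003"),
        overlap_fraction=0.5,
        seed=7,
    )
    sim = syn.gen_hit_profiles(spec)
    ref_set = sim.reference.significant_templates()
    for prof in sim.proteome:
        if prof.protein_id in spec.planted_ids:
            assert len(prof.significant_templates() & ref_set) == 10


def test_indistinguishable_warning_when_rho_rounds_to_zero():
    spec = syn.HitProfileSimSpec(
        n_proteins=5, planted_ids=("P0001",), overlap_fraction=0.0
    )
    sim = syn.gen_hit_profiles(spec)
    row = sim.truth.set_index("protein_id").loc["P0001"]
    assert row["warning"] == "indistinguishable"


def test_reference_has_exact_count_in_sig_range():
    spec = syn.HitProfileSimSpec(n_proteins=3, ref_template_count=15, seed=1)
    sim = syn.gen_hit_profiles(spec)
    lo, hi = spec.evalue_sig_range
    assert len(sim.reference.hits) == 15
    assert all(lo <= h.e_value <= hi for h in sim.reference.hits)


def test_hit_profiles_byte_identical_given_seed(tmp_path):
    spec = syn.HitProfileSimSpec(n_proteins=20, planted_ids=("P0001",), seed=42)
    paths = []
    for tag in ("a", "b"):
        sim = syn.gen_hit_profiles(spec)
        path = tmp_path / f"{tag}.tsv"
        write_hit_table(sim.proteome, path, reference=sim.reference)
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="overlap_fraction"):
        syn.HitProfileSimSpec(overlap_fraction=1.5)
    with pytest.raises(ValueError, match="planted_ids"):
        syn.HitProfileSimSpec(n_proteins=2, planted_ids=("P0099",))
    with pytest.raises(ValueError, match="below"):
        syn.HitProfileSimSpec(evalue_sig_range=(1e-4, 1e-2), evalue_nonsig_range=(1e-3, 1.0))


# --- sequence simulation -----------------------------------------------------


def test_all_spii_sequences_match_planted_cleavage():
    spec = syn.SequenceSimSpec(n_seqs=5, class_probabilities=(0, 0, 1, 0), seed=9)
    sim = syn.gen_sequences(spec)
    assert (sim.truth["sp_class"] == "SPII").all()
    for rec, (_, row) in zip(sim.records, sim.truth.iterrows()):
        ann = annotate(str(rec.seq))
        assert ann.sp_class == "SPII"
        assert ann.cleavage_pos == row["cleavage_pos"]
        assert str(rec.seq)[ann.cleavage_pos - 1] == "C"


def test_pure_none_spec_yields_only_none():
    spec = syn.SequenceSimSpec(n_seqs=10, class_probabilities=(1, 0, 0, 0), seed=2)
    sim = syn.gen_sequences(spec)
    for rec in sim.records:
        assert annotate(str(rec.seq)).sp_class == "NONE"


def test_zero_sequences_gives_empty_outputs():
    sim = syn.gen_sequences(syn.SequenceSimSpec(n_seqs=0))
    assert sim.records == [] and sim.truth.empty


def test_negative_class_probability_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        syn.SequenceSimSpec(class_probabilities=(-0.1, 0.4, 0.4, 0.3))


def test_truth_rows_one_per_record():
    sim = syn.gen_sequences(syn.SequenceSimSpec(n_seqs=25, seed=5))
    assert list(sim.truth["protein_id"]) == [rec.id for rec in sim.records]
    assert sim.truth["protein_id"].is_unique


# --- abundance simulation ----------------------------------------------------


def test_single_protein_table_has_one_summary_row():
    spec = syn.AbundanceSimSpec(
        n_proteins=1, de_fraction=0.0, replicate_sd=0.1, seed=3
    )
    sim = syn.gen_abundance_table(spec)
    assert len(sim.summary) == 1
    assert len(sim.replicates) == 1
    assert set(sim.replicates.columns) == {"protein_id"} | {
        f"{g}{i}" for g in "AB" for i in range(1, 6)
    }


def test_planted_log2_shift_recovered_in_mean_fold_change():
    spec = syn.AbundanceSimSpec(
        n_proteins=200, de_fraction=0.5, log2_shift=1.0, replicate_sd=0.25,
        n_replicates_per_group=10, seed=8,
    )
    sim = syn.gen_abundance_table(spec)
    de = sim.truth["is_de"].to_numpy()
    observed = np.log2(sim.summary.loc[de, "fold_change"]).mean()
    tol = 3 * spec.replicate_sd / np.sqrt(spec.n_proteins * spec.n_replicates_per_group)
    assert observed == pytest.approx(spec.log2_shift, abs=max(tol, 0.05))


def test_abundance_truth_and_summary_consistent():
    sim = syn.gen_abundance_table(syn.AbundanceSimSpec(n_proteins=50, seed=1))
    assert list(sim.summary["protein_id"]) == list(sim.truth["protein_id"])
    assert (sim.summary["loc_class"] == sim.truth["loc_class"]).all()
    # significance column is the -10log10 transform of the p column
    assert np.allclose(
        sim.summary["significance"], -10 * np.log10(sim.summary["p_value"])
    )


def test_explicit_de_protein_ids_are_honoured():
    spec = syn.AbundanceSimSpec(
        n_proteins=20, de_protein_ids=("Q0002", "Q0005"), seed=6
    )
    sim = syn.gen_abundance_table(spec)
    assert set(sim.truth.loc[sim.truth["is_de"], "protein_id"]) == {"Q0002", "Q0005"}


def test_fewer_than_two_replicates_rejected():
    with pytest.raises(ValueError, match="replicates"):
        syn.AbundanceSimSpec(n_replicates_per_group=1)


def test_abundance_byte_identical_given_seed(tmp_path):
    spec = syn.AbundanceSimSpec(n_proteins=30, seed=12)
    files = []
    for tag in ("a", "b"):
        sim = syn.gen_abundance_table(spec)
        path = tmp_path / f"{tag}.tsv"
        syn.write_table(sim.summary, path)
        files.append(path.read_bytes())
    assert files[0] == files[1]


# --- species-hits simulation -------------------------------------------------


def test_species_hits_truth_counts_match_strong_hits():
    spec = syn.ConservationSimSpec(seed=13)
    sim = syn.gen_species_hits(spec)
    strong = sim.hits[sim.hits["e_value"] <= 1e-6]
    for sp in spec.species:
        for fam in spec.families:
            n = len(
                strong[(strong["species_id"] == sp) & (strong["query_id"] == fam)]
            )
            assert n == sim.truth_counts.loc[sp, fam]


def test_species_hits_deterministic():
    spec = syn.ConservationSimSpec(seed=21)
    a, b = syn.gen_species_hits(spec), syn.gen_species_hits(spec)
    assert a.hits.equals(b.hits)
    assert a.truth_counts.equals(b.truth_counts)
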