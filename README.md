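# lolscout

Lipoproteins reach the outer membrane (OM) of diderm bacteria through the
Lol pathway: a periplasmic chaperone (LolA) carries the acylated protein
across the periplasm and hands it to an OM insertase (LolB). In the phylum
Bacteroidota, LolB homologs are so diverged that ordinary sequence searches
miss them — yet they can be found because remote homologs still hit the
*same known structural templates* in a profile/structure search.

`lolscout` is a tested, reusable implementation of that in-silico workflow:

1. **Template-fingerprint homolog discovery** (`lolscout.fingerprint`) —
   parse per-protein template hit lists, threshold at E ≤ 10⁻³, and rank
   proteome proteins by the significant templates they share with a
   reference (overlap, Jaccard, and a strict set-identity flag).
2. **Envelope signal classification** (`lolscout.annotation`) — a
   transparent rule-based classifier for signal peptides: SPII when a
   lipobox (`[LVIFMSTAG][ASTVIG][GAS]C`) lies in residues 10–40 (the Cys
   becomes the lipidated mature N-terminus), else SPI when an
   Eisenberg-scored hydrophobic h-region is followed by an A-X-A cleavage
   motif, else NONE; SPII lipoproteins are additionally screened for a
   configurable lipoprotein export signal (LES) that marks surface exposure.
3. **Physico-chemical profiling** (`lolscout.physchem`) — residue
   composition, Leu/Ile and Lys/Arg fractions, mean Eisenberg
   hydrophobicity, Henderson–Hasselbalch net charge, and a donor→acceptor
   hydrophobic-gradient call (FAVORABLE / NEUTRAL / UNFAVORABLE) for
   candidate chaperone–insertase pairs.
4. **Differential OM proteomics** (`lolscout.abundance`) — the label-free
   quantification screen: significance = −10·log₁₀(p) (so p = 0.01 ⇔ 20),
   keep proteins with max(FC, 1/FC) ≥ 1.5 **and** significance ≥ 20, tally
   by localization class (NO_SP / SPI / SPII / SPII_LES) and functional
   category, and intersect two mutant-vs-WT comparisons.
5. **Conservation profiling** (`lolscout.conservation`) — species × family
   homolog-count matrices from homology-search hits at E ≤ 10⁻³, with
   best-E family assignment and ambiguity flags.
6. **Synthetic data** (`lolscout.synthetic`) — generators for all of the
   above with planted ground truth, so every stage is testable end to end
   without external databases.

## Worked example

Plant two remote homologs that share 60 % of a 20-template reference
fingerprint in a 50-protein proteome, then recover them:

```python
from lolscout import synthetic as syn, fingerprint as fp

spec = syn.HitProfileSimSpec(
    n_proteins=50, n_templates=1000, ref_template_count=20,
    planted_ids=("P0007", "P0023"), overlap_fraction=0.6,
    background_rate=2.0, seed=1,
)
sim = syn.gen_hit_profiles(spec)
for m in fp.shared_template_candidates(sim.proteome, sim.reference)[:3]:
    print(f"{m.protein_id}  overlap={m.overlap}  jaccard={m.jaccard:.3f}")
```

```
P0023  overlap=12  jaccard=0.600
P0007  overlap=12  jaccard=0.545
P0027  overlap=1  jaccard=0.048
```

Both planted proteins rank first with 12 shared significant templates
(⌈0.6·20⌉ = 12); the best background protein shares one template by chance.
The same workflow is available from the shell:

```bash
lolscout simulate hits --spec spec.yaml --out sim/
lolscout find-homologs --hits sim/proteome.tsv --reference sim/reference.tsv \
    --cutoff 1e-3 --out candidates.tsv
```

And the abundance screen on a simulated two-condition experiment
(500 proteins, 10 % with a planted 3-log₂ shift):

```python
from lolscout import abundance as ab
lfq = syn.gen_abundance_table(syn.AbundanceSimSpec(
    n_proteins=500, de_fraction=0.1, log2_shift=3.0, replicate_sd=0.2, seed=1))
report = ab.tally(ab.apply_filter(lfq.summary))
print(report.total_significant, report.no_sp_percent)
```

```
50 36
```

All 50 planted proteins (and no others) pass the FC ≥ 1.5 / significance
≥ 20 screen; 36 % of them carry no signal peptide, matching the planted
localization mix.

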