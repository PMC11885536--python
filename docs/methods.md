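# Methods

This note documents the models and procedures implemented in `lolscout`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions.

## Template-fingerprint homolog discovery

A profile/structure search assigns each query protein a hit list of known
structural templates with E-values. The discovery method treats the set of
*significant* templates (E ≤ cutoff, default 10⁻³, threshold inclusive) as
a structural fingerprint and compares each proteome protein's fingerprint
with a reference protein's. For every candidate we report the shared
template set, its size (overlap), the Jaccard index over the union of the
two significant sets, and an `identical_sets` flag.

Two conventions are deliberate:

* **Intersection, not identity.** "Sharing templates" is read permissively:
  any candidate with overlap ≥ `min_overlap` (default 1) is reported,
  ranked by overlap, then Jaccard, then protein id (deterministic
  tie-break). The strict set-identity reading remains recoverable from the
  `identical_sets` flag. The permissive reading is the one consistent with
  hunting *distant* homologs, whose hit lists are rarely literally equal.
* **Both lists thresholded.** Both the reference and proteome hit lists are
  thresholded at the cutoff before intersection; `threshold_both=False`
  relaxes this to reference-only thresholding for sensitivity analyses.

Validation is two-pronged: an independent brute-force oracle (plain set
arithmetic, shared with no package code) is compared against the ranking
(i) exhaustively over every reference-subset/protein-subset pair of an
8-template universe (255 reference sets × 256 protein sets — exhaustive at
the pairwise level, since the ranking is a per-protein function of the
pair), plus full rankings over seeded random proteomes of ≤ 6 proteins;
and (ii) a recovery benchmark measures the fraction of planted homologs
ranked in the top k of a simulated proteome.

## Signal-peptide classification

The classifier is a deliberately transparent rule set (a surrogate for
neural signal-peptide predictors, which cannot be embedded in a small
reproducible package):

* **SPII (lipoprotein):** the lipobox consensus `[LVIFMSTAG][ASTVIG][GAS]C`
  must match with the whole 4-mer inside residues 10–40; the leftmost
  in-window match wins and its Cys is the cleavage position (first mature,
  lipidated residue).
* **SPI:** a 7-residue window within residues 1–35 with mean Eisenberg
  hydrophobicity ≥ 1.0 (h-region), followed by an `A[^PC]A` cleavage motif
  whose final residue lies in residues 15–45 and after the h-region. The
  threshold 1.0 sits between the mean of a Leu/Ile/Val/Phe stretch
  (≥ 1.06) and what random windows reach (mean ≈ 0, sd ≈ 0.38), so false
  h-regions are rare.
* **Precedence SPII > SPI**; anything else is NONE. Sequences shorter than
  30 residues are NONE with a warning; non-canonical residues are errors
  naming the position.
* **LES (surface-export signal):** searched within `les_window_length`
  (default 6) residues after the lipidated Cys. The motif itself is fully
  configurable and the shipped default `[DE][DE]` is a **placeholder** used
  by the synthetic generator — the biological LES consensus is defined in
  the surface-lipoprotein literature, and hard-coding a guess here would
  invent biology. Users studying real proteomes must supply their own
  motif.

All rules inspect only the first ~50 residues, so classification is stable
under C-terminal extension — a property the tests enforce.

## Physico-chemical surrogates

Residue-level surrogates replace 3-D structure calculations (structure
prediction, surface extraction, Poisson–Boltzmann electrostatics are out of
scope):

* **Hydrophobicity** uses the Eisenberg normalized consensus scale, in the
  per-residue form used by structure-viewer colouring scripts (Ala 0.62 …
  Ile 1.38, Arg −2.53), embedded as constants. The *hydrophobic set* is
  defined as the residues with positive scale value, tying the definition
  to the scale rather than an arbitrary list; the Leu+Ile fraction is
  reported separately because transfer-cavity enrichment is dominated by
  those two residues.
* **Net charge** is a Henderson–Hasselbalch sum with a fixed textbook pKa
  table (D 3.65, E 4.25, C 8.3, Y 10.07, K 10.53, R 12.48, H 6.0; termini
  9.0/2.0, off by default since selections are usually internal patches).
  The model is a closed form defined for any real pH; limit checks are run
  at pH −2 and 16, where every group is ≥ 3.5 pH units from its pKa and the
  charge provably reaches the signed ionizable counts within 0.01 (inside
  pH 0–14 an Arg residue alone leaves a +0.03 residual at pH 14, so the
  physiological boundary is not a meaningful limit point).
* **Gradient call:** for a donor/acceptor pair the difference in
  hydrophobic fraction (acceptor − donor) is thresholded at ε = 0.01:
  FAVORABLE above +ε, UNFAVORABLE below −ε, else NEUTRAL. ε = 0.01 is below
  the composition sampling noise of domains ≥ 100 residues, so NEUTRAL
  effectively means "indistinguishable at sequence level". The call is
  antisymmetric under role swap (tested). Mean-Eisenberg difference is
  reported alongside for context.
* **Selections** (e.g. concave/convex cavity sides) are user-supplied
  1-based index sets; the assignments come from manual inspection of
  structural models and are inputs, not computed quantities.

## Differential-abundance screen

The quantitation software's conventions are reproduced exactly:
significance = −10·log₁₀(p) (p = 0.01 ⇔ 20, verified to machine
precision), and the screen keeps proteins with max(FC, 1/FC) ≥ 1.5 and
significance ≥ 20, both thresholds inclusive. The fold-change condition is
two-sided because depleted proteins (FC < 1) count as significant hits. No
multiplicity correction is applied — the screen thresholds a per-protein
score, as the upstream software does — but a Benjamini–Hochberg q-value
column is available as an optional utility. Localization shares are
reported both as fractions and as half-up-rounded integer percentages
(402/609 → 66 %). Condition comparisons intersect filtered sets keyed by
protein id and split the intersection by fold-change direction
concordance.

## Conservation profiling

Homology-search hits are thresholded at E ≤ 10⁻³; each subject protein is
assigned to the query family with the smallest E-value, with exact ties
going to the lexicographically first family and flagged `ambiguous`. This
deterministic rule replaces the manual structure/synteny curation used to
resolve paralogy in practice; flagged cases are surfaced for review rather
than silently resolved. Cells hold counts (not booleans) so multi-copy
families remain visible; presence is derived as count > 0. Assignment is a
partition (each subject counted once), the matrix total equals the number
of distinct assigned subjects, and raising the cutoff can only grow cells
— all tested invariants.

## Synthetic generators

All generators draw every random quantity from a single `numpy` Generator
seeded by the spec, so identical spec + seed gives byte-identical output
files (writers use fixed float formatting).

* **Hit profiles:** the reference receives exactly `ref_template_count`
  templates with E-values log-uniform in the significant range (log-uniform
  spans magnitudes the way real search scores do). Each planted homolog
  shares ⌈ρ·ref_count⌉ reference templates (drawn without replacement) plus
  a Poisson(`background_rate`) tail outside the reference set; background
  proteins draw Poisson(`background_rate`) significant templates uniformly
  from the whole universe, so chance overlap is possible but unplanted.
  Every protein also gets a Poisson(`nonsig_rate`) tail of hits above the
  cutoff to exercise thresholding. If ρ·ref_count rounds to zero while
  homologs are planted, the truth table carries an `indistinguishable`
  warning that propagates into recovery reports.
* **Sequences:** signal-peptide prefixes are built from grammar (Met +
  2–4 Lys/Arg n-region, 7–12 Leu/Ile/Val/Phe h-region, then lipobox or
  linker + A-X-A), and every sequence is rejection-sampled until the
  classifier — run with the same rules — reproduces the planted class,
  cleavage site and LES flag. Agreement between generator truth and
  classifier is therefore exactly 1.0 by construction; the corresponding
  test checks internal consistency of generator and classifier, not
  real-proteome accuracy. The alphabet is the 20 canonical residues with
  uniform background frequencies — enough for composition statistics,
  but real proteome composition, domain structure and homology are not
  emulated.
* **Abundance tables:** per-protein baseline log₂ abundance ~
  Normal(25, 1) across proteins; replicate log₂ values ~ Normal(baseline
  [+ δ in condition B for planted proteins], σ) with σ default 0.25
  (a typical label-free replicate CV of ~20 %) and 5 replicates per group,
  the usual biological-replicate count. Fold change is the ratio of linear
  replicate means; the p-value is a two-sample Welch t-test on log₂ values
  — a two-group surrogate for the quantitation software's ANOVA, with
  which it coincides up to the pooling choice. Missing values, peptide
  rollup and normalization artefacts of real LFQ data are not simulated,
  so calibration results speak to the screen's arithmetic, not to raw-data
  preprocessing.
* **Species hits:** each species × family cell is present with probability
  0.8 and carries 1 + Poisson(0.2) copies; every copy hits its own family
  strongly (E log-uniform 10⁻³⁰–10⁻⁶) and, with probability 0.3, one other
  family at a strictly weaker but still significant E (10⁻⁵–9·10⁻⁴) to
  exercise best-E assignment; per-species decoy hits above the cutoff are
  added at rate 0.5.

## Problem sizes and numerical conventions

The validation runs use desk-scale sizes chosen to make the statistics
stable: oracle equivalence over all 255 × 256 subset pairs of an
8-template universe plus 200 random proteomes; recovery over 50 seeds of a
200-protein proteome with a 1000-template universe, 20 reference
templates, ρ = 0.5 and background rate 2 (expected recovery ≈ 1 because a
background protein's chance of sharing ≥ 10 of 20 reference templates is
astronomically small); filter calibration over 50 null tables of 1000
proteins and power over 2500 planted proteins at δ = 3, σ = 0.2;
classifier agreement over 200 sequences per class. Full-scale discovery
counts (numbers of candidate homologs in a real proteome, of significant
proteins in the deletion-mutant OM proteomes, of conserved homologs across
30 species) depend on external proteome databases, search-tool snapshots
and deposited raw data and are documented as workflow expectations, not
desk-scale results.

Ties are always broken deterministically (Jaccard, then lexicographic id;
first family on E-value ties). Thresholds are inclusive throughout.
Percentages are rounded half-up. The Welch p-value is clipped away from
zero at the smallest positive double before the −10·log₁₀ transform.

## Known limitations

* The signal-peptide rules are consensus regular expressions; they do not
  model cleavage-site probability landscapes and will misclassify atypical
  real signal peptides that a neural predictor would catch.
* The LES default motif is a placeholder (see above).
* Best-E family assignment cannot reproduce manual curation of deep
  paralogy; ambiguous flags mark where curation would intervene.
* Sequence-level charge ignores structural micro-environment (fixed pKa
  table); gradient calls compare compositions, not binding-pocket
  geometry.
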