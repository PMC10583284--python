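# Methods

## Scope and model

`sigpepvar` classifies protein-level missense variants that fall inside
annotated signal peptides. It does not predict signal peptides or their
region boundaries (those arrive as input annotation, e.g. from a
SignalP-style predictor), does not lift genomic coordinates to protein
coordinates, and assigns no probabilistic pathogenicity score: each rule
is a deterministic predicate, and each flagged variant carries exactly
one mechanism determined by the region it hits.

A stored record is the signal peptide **plus the first mature residue**
(the "+1" position). All positions are 1-based; cleavage-relative
coordinates run −sp_len..−1 for signal-peptide residues and +1 for the
first mature residue, with no zero. Variants beyond +1 are labelled
OUTSIDE and pass through unclassified, so whole-protein variant tables
can be fed in without pre-filtering.

## Scales

**Kyte–Doolittle hydropathy** values are transcribed into
`data/kyte_doolittle.tsv`. The hydrophobicity change of a substitution
is ΔKD = KD(mut) − KD(wt); the package stores all deltas in the
mut − wt convention (negative = hydrophobicity decrease).

**Boman (binding-potential) values** (`data/boman.tsv`) are the
per-residue solubility values derived from side-chain water→cyclohexane
transfer free energies (kcal/mol), signed so hydrophilic residues are
positive (R = +14.92 … L/I = −4.92). Proline has no measured value in
the source data and is assigned 0.0. The Boman index of a sequence is
the arithmetic mean of these values; the score used by the H-rule is

    scaled ΔBoman = (BomanIndex(mutant sequence) − BomanIndex(wild type)) × 100

computed over the full stored sequence *including* the +1 residue. The
normalization length matters: with a 16-residue record (CTSK) a single
L→P substitution moves the scaled index by +30.8, while the same
substitution in a 25-residue record (LHCGR L10P) moves it only +19.7 —
on opposite sides of the cutoff, and both in agreement with the
measured outcomes. Case is normalized to upper; ambiguity codes
(B/Z/X) and U are rejected rather than imputed.

## Classification rules

* **H-rule (RAPP_MRNA_DECAY).** Flag when ΔKD < `kd_decrease_threshold`
  (default 0, i.e. any strict decrease) **and** scaled ΔBoman ≥
  `boman_cutoff` (default +20). The cutoff value comes from prior
  experimental calibration of decay-inducing signal-peptide mutations
  and is bracketed by the bundled validation set: CTSK L7P (+30.8)
  flagged, LHCGR L10P (+19.7) and SERPINE1 A15T (+18.3) not. The
  default zero hydrophobicity threshold is the weakest filter that
  reproduces the validation set (POMC A15G passes it and is then
  correctly rejected by the Boman cutoff); it is configurable for users
  who want a stricter notion of "significant decrease".
* **C-rule (PROCESSING_FAILURE).** Evaluated at the peptidase-critical
  cleavage-relative positions `c_positions` (default {−3, −1, +1},
  following the (−3,−1) rule plus the +1 residue). Flag when the
  *incoming* residue's frequency at that position — taken from a
  wild-type position-frequency table, normally built from the very
  collection being analysed — is below `c_rarity_threshold`. The
  default 2.5 % is half the uniform expectation of 5 %; published
  anchor examples fall well clear of it on both sides (tyrosine < 0.5 %
  at −3/−1/+1 → flagged; alanine > 25 % at −1/−3 → not). Set
  `c_all_positions` to evaluate every C-region position in the table's
  window instead.
* **N-rule (TRANSLOCATION_DEFECT).** Flag when the substitution
  introduces aspartate or glutamate at a position whose wild-type
  residue is not already acidic. Loss of K/R without gaining D/E is
  deliberately not flagged: the rule targets charge reversal, the case
  with the clearest mechanistic link to translocon misorientation.

Sequence-pair input (WT/mutant strings, no region annotation) is scored
by `classify_pair`, which applies the decay-rule arithmetic directly.
This mirrors how literature validation sets of signal-peptide pairs are
evaluated; region dispatch requires annotated records.

## Frequency tables and information content

Position-frequency tables are anchored at the cleavage site with an
inclusive window (default −6..+1; windows naming the nonexistent
position 0 are rejected). Peptides shorter than the window contribute
only where defined, so denominators are per-position. No pseudocounts
are added — the C-rule needs exact zeros to flag never-observed
residues. Information content is IC(pos) = log2 20 + Σ p log2 p with
0·log 0 ≡ 0, giving 0 bits for a uniform column and log2 20 ≈ 4.32 bits
for a conserved one; `plot_logo` renders letter heights p × IC with
matplotlib if installed.

Medians of even-length samples are midpoints (half-integers allowed).
Pearson r/r² for score-vs-expression comparisons is delegated to
`scipy.stats.pearsonr` and requires ≥ 3 pairs with nonzero variance.

## Synthetic data

The generator emulates human signal-peptide architecture so the whole
pipeline is testable without external downloads. Region lengths are
drawn uniformly from median ± jitter (defaults 3±1 / 14±3 / 5±1,
clipped at 1) — a bounded discrete distribution whose median equals the
configured value; real length distributions are longer-tailed, and no
claim is made about tail behaviour. Residue profiles
(`data/region_profiles.tsv`) embed published human composition
percentages where stated — N-region: 16.5 % K+R at ~3:1 R:K, A 9.78 %,
G 8.24 %, P 9.22 %, Y 0.28 %; H-region: L 36.93 %, A 9.68 %, V 8.8 %,
D 0.21 %, N 0.39 %, K 0.41 %; C-region: A 20.14 %, G 16.16 %, S 11.06 %,
M 0.9 %, F 0.99 %, N 1.0 % — and spread the remainder uniformly over
the unstated residues. Position 1 is always the initiator methionine,
so composition-convergence checks exclude it. The +1 profile is uniform
(no published composition to embed). Positions are sampled i.i.d.
within a region; real peptides have positional correlations (e.g. the
(−3,−1) motif), so passing recovery tests demonstrates correct wiring
and coordinates, not realism of any particular peptide.

Variant planting constructs, per requested truth label, substitutions
that satisfy (or for NONE, verifiably violate) the corresponding rule
under the active configuration, recording `rule_margin` — the decisive
score's distance from its threshold, positive iff flagged. The N-rule
is categorical, so its margin is the indicator value 1. Because the
rules are deterministic, recovery of planted labels is exact by
construction; the recovery test validates coordinates, dispatch and
threshold handling end to end, and says nothing about sensitivity or
specificity on real variants.

## Problem sizes

The test suite and the acceptance script use 500–10,000 generated
peptides: 10,000 for architecture statistics (median stability,
chi-square composition check), 1,000 peptides with 200 planted variants
per label for recovery, and an exhaustive 19 × 23 substitution scan
against the brute-force oracle. These sizes make every statistic stable
to well under the asserted tolerances while keeping a full run in
seconds.

## Known limitations

* Region boundaries are trusted as given; predictors disagree on
  H/C-boundary placement for a sizeable minority of human signal
  peptides, and a boundary shift can move a variant between rules.
* The H-rule is calibrated for hydrophobicity *decreases*;
  hydrophobicity-increasing variants (a minority with unclear clinical
  interpretation) are never flagged.
* The C-rule's frequency table is only as good as the collection it is
  built from; for small collections the zero-frequency criterion is
  noisy, and users should supply a table built from a large wild-type
  set.
* Binary calls only: no allele frequencies, zygosity, or downstream
  protein features enter the rules.
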