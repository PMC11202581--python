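# Methods

## Indel channel classification (ID83)

Every indel is assigned to one of 83 channels in the COSMIC decomposition
12 + 12 + 24 + 24 + 11:

1. **1 bp events** are pyrimidine-normalised (A→T, G→C) and binned by
   homopolymer context. For a deletion of base *b* the run *containing*
   the deleted base is counted (bins 1…6+); for an insertion the longer of
   the two runs adjacent to the insertion point (bins 0…5+). The numeric
   label suffix follows COSMIC (deletion suffix = run − 1).
2. **Length ≥ 2 events** use the full indel sequence as the repeat unit —
   no sub-unit decomposition — and count exact tandem copies scanning
   rightward from the (left-aligned) locus; deletions include the deleted
   copy. Deletions with ≥ 2 copies and insertions with ≥ 1 pre-existing
   copy (or none) fall in the repeat classes, size bins {2,3,4,5+} ×
   repeat bins.
3. **Deletions with exactly one copy** are checked for flanking
   microhomology: the maximum over the longest proper prefix of the
   deleted sequence matching the start of the right flank and the longest
   proper suffix matching the end of the left flank. The search is
   double-sided because left-side homology is the same biological signal
   after left-alignment, even though published channel examples are
   right-side only. Homology ≥ 1 gives the microhomology classes (11
   labels: MH bins respect mh < length); otherwise the event is a
   repeat-class deletion with count 1.

Sequences of length ≥ 2 are never strand-normalised (COSMIC convention).
Run/repeat counting is exact up to 20 before capping into bins. Indels are
assumed left-aligned on input, but a defensive canonicalisation pass
(shift left while the base preceding the event equals the event's last
base) runs before every assignment, so channel calls never depend on the
caller's normalisation; a property test asserts that any member of a
slippage equivalence class classifies identically. Events whose decisive
context contains an N are excluded and counted.

A note on naming: ID1 denotes the 1 bp-*insertion* slippage signature and
ID2 the 1 bp-*deletion* one, the COSMIC v3 assignment. Literature
descriptions of MSI subtypes occasionally swap the two in prose; this
package follows COSMIC throughout.

## SBS96 catalogs

SNVs are assigned to 6 substitution classes × 16 trinucleotide contexts,
reverse-complementing purine-reference sites so the mutated base is a
pyrimidine. The channel ordering is the COSMIC block layout, but all
alignment between catalogs and signature files is by label, never by
position. A reference-mismatch at the site is a hard error (it indicates
the wrong genome build), while an N in the triplet or a contig-edge site
is counted as unclassifiable.

## Signature refitting

Exposures solve the non-negative least-squares problem
min ‖S·e − c‖₂, e ≥ 0, per sample (Lawson–Hanson via
`scipy.optimize.nnls`). One solver serves both the ID and SBS refits so
behaviour stays auditable; the deconstructSigs-style proportion floor is
exposed as `min_contribution` but defaults to 0. Residuals are reported in
count units so samples of different depth can be compared by
residual/row-sum. Group spectra normalise each sample's catalog row to
proportions first and then take channel-wise medians, which keeps deep
samples from dominating the group profile; cosine similarity against each
reference column summarises the comparison.

**Bundled references.** The canonical COSMIC v3 ID/SBS matrices are
distribution-restricted downloads, so the package bundles *synthetic*
stand-ins (generated deterministically by
`synthetic_data.synthetic_*_signatures`, fixed internal seed): each column
is 85% characteristic mass on the channels that define the signature's
published shape (ID1 on long-homopolymer 1 bp insertions, ID2 on the
matching deletions, SBS10-like spikes at T[C>A]T and T[C>T]C, T>C-heavy
SBS26-like columns, a flat SBS5-like background, …) plus 15% Dirichlet
smoothing that guarantees full column rank. The ID matrix carries 18
columns (ID1–ID18). These are fixtures with realistic structure, not
biological estimates; any channel-compatible COSMIC-format TSV can be
substituted.

## Subtype decision tree

Samples first pass the indel-burden filter: ≥ 10 indels per exome (the
count MSI-H status requires) and strictly > 1000 per genome; both
thresholds are configurable. The dominance score is raw (count-scale)
ID1 exposure minus raw ID2 exposure — raw rather than proportional,
because the routing is meant to reflect absolute slippage abundance; a
flag-level switch to proportions is available through the exposure table.
Routing order:

1. zero exposure on both ID signatures → excluded (`zero_id_signal`);
2. MSS annotation → excluded (`microsatellite_stable`);
3. hotspot ∧ dominance > 0 → PPd;
4. hotspot ∧ dominance ≤ 0 ∧ MSI-H → MMRd-del (deletion-dominant
   proofreading mutants ride with the MMRd-del group);
5. MSI-H → MMRd-ins if dominance > 0 (the hotspot cases were consumed
   above, so MMRd-ins implies no functional POLE/POLD1 hotspot), else
   MMRd-del — exact balance routes to MMRd-del, the majority prior;
6. otherwise excluded (`unknown_status`).

Because the MSS archetype carries essentially no ID1/ID2 mass, simulated
MSS samples may be excluded at step 1 rather than step 2; both routes are
correct exclusions and tests accept either reason. PPd tumors are not
required to be MSI-H: the simulator annotates them `msi_status="unknown"`
so they route through the hotspot rule rather than the MSS exclusion.
Cohort ordering is by descending dominance with lexicographic tie-breaks
for determinism.

## Downstream statistics

* **Gene enrichment**: per-gene 2×2 tables (truncating indel present ×
  group), two-sided Fisher exact test under the standard
  point-probability rule, no multiple-testing correction by default
  (mirroring a plain p < 0.05 gate); a Benjamini–Hochberg option exists.
  The tests do not condition on coding length or per-sample burden — a
  known confounder, noted here deliberately.
* **Differential expression**: Welch's t-test on log2-scale input (a
  documented contract, not checked), selected at p < 0.05 and
  |log2FC| > 1 — the fold-change gate is read on the log2 scale.
  Zero-variance genes get p = 1 when means agree, p = 0 flagged
  degenerate otherwise.
* **Neoantigens**: a record counts iff IC50 < 50 nM *strictly* and the
  gene is expressed; recurrence requires strictly more than 40% of the
  subtype's samples.
* **SVs**: deletion/duplication size bins are half-open, (0, 1 Mb],
  (1 Mb, 10 Mb], (10 Mb, ∞) — a 1 Mb deletion is "small". Inversion and
  translocation subtypes (reciprocal/fold-back, reciprocal/unbalanced)
  require breakpoint-cluster context and are consumed as input
  annotations; records without one land in an `unresolved` bucket.
  Alternative bin edges (e.g. 100 kb) are a parameter. Rank-sum
  comparisons use the exact Wilcoxon distribution for groups up to 25
  (falling back to the normal approximation on ties) and the
  approximation above that.

## Synthetic-data generator

The generator defines the study conditions and doubles as the ground-truth
oracle for the classifiers.

**Planting.** For each requested channel a minimal witness is synthesised:
exact homopolymer runs, exact tandem copies, or exact microhomology, with
single guard bases at both ends drawn to *not* extend the witness (guard ≠
run base; guard ≠ unit's first/last base; guard ≠ the base that would
lengthen the homology). Guards make loci self-contained, and ≥ 100 bp of
random spacer separates them, so planted contexts cannot interact. "6+"
and "5+" bins draw a random extent above the cap. 1 bp and SNV witnesses
are written on the purine strand half the time to exercise
pyrimidine normalisation.

**Archetypes** (loose caricatures, not biological claims): MMRd-del puts
65% of indel mass on the ID2-like column and 5% on ID1-like; MMRd-ins the
reverse (60/10); PPd is insertion-dominant (55/5) with fewer indels
(30–120 per sample) but far more SNVs (600–2000) dominated by the
SBS10-like column; MSS sits just above the exome burden filter (12–40
indels) with no ID1/ID2 mass. MMRd samples draw 50–300 indels and 100–400
SNVs. With these profiles every non-MSS sample's |dominance| exceeds 10 by
construction, which is what makes the 100%-recovery check meaningful.
The default cohort is 40 MMRd-del, 8 MMRd-ins, 10 PPd and 20 MSS exomes
(callable territory 38 Mb; 2800 Mb for genome platform) — MMRd-ins kept a
minor fraction of the MSI-H group, as observed in real cohorts.

Planted downstream effects: 25 expression genes shifted +2 log2 units in
MMRd-ins (per-gene noise σ = 0.5); 4 genes per indel kind relabelled onto
sample records at 0.8 vs 0.05 carrier probability between the target and
off-target subtypes; 5 neoantigen genes given qualifying records in 75% of
MMRd-ins samples vs 10% elsewhere over a lognormal IC50 background; SV
category rates elevated for small deletions/duplications in MMRd-ins.

**What the simulation does not emulate:** real indel-length and repeat
spectra beyond the planted witnesses, mappability and calling artefacts,
subclonality, gene length (enrichment tests in real data are confounded by
it), linkage between mutation burden and expression, and real HLA binding.
Passing tests therefore demonstrate correctness of the *computations* on
inputs with known truth, not biological validity on consortium data.

## Numerical and testing choices

* Left-alignment, not right-alignment, is canonical everywhere; rightward
  repeat scanning relies on it.
* Fisher p-values are checked against full hypergeometric enumeration to
  1e−12 (margins ≤ 30); exact Wilcoxon against enumeration of all group
  assignments for sizes ≤ 8.
* The ID83 classifier is checked three ways on the same planted loci:
  against the generator's construction, and against an independent
  brute-force linear-scan/regex classifier kept in the test suite.
* Problem sizes: the oracle-equivalence check uses 10,043 planted indels
  (121 per channel); refit recovery uses 100 multinomial replicates at
  n = 1000 (mean cosine ≥ 0.95) and noise-free recovery to 1e−6; the
  default cohort (~40k mutations) runs the full pipeline in a few
  seconds. Sizes were chosen so the whole suite stays interactive while
  estimates remain stable.
* Determinism: one `numpy` Generator seeded per entry point; identical
  seeds give byte-identical output bundles.

## Known limitations

* Complex indels (delins) are unsupported and dropped with a count.
* MSI-H status and POLE/POLD1 hotspot flags are *inputs*; no attempt is
  made to call them from sequence.
* The bundled signature matrices are synthetic stand-ins (above); cosine
  similarities against them are not comparable to values computed against
  the canonical COSMIC matrices.
* Fisher enrichment ignores gene length and per-sample burden.
* Exposure uncertainty is not propagated into the dominance score; samples
  with near-zero dominance are routed deterministically rather than
  flagged.
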