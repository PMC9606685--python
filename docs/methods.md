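# Methods

This note documents the models and procedures implemented in `phylowave`,
their assumptions, parameter choices, and the design decisions that were
genuinely open.

## Sequence curation

Pairwise identity is computed from a global alignment with affine gaps
(BLOSUM62, gap open 11, gap extension 1 — the common protein-search
default). Identity is the count of identical aligned residue pairs divided
by the number of alignment columns; in a pairwise global alignment no column
carries a gap in both rows, so no column is excluded from the denominator.
Internal gap columns therefore count as mismatches, and 'X' (unknown)
matches nothing, including another 'X'. The literature rarely states which
identity convention a curation pipeline used; this one is deterministic and
close to the convention BLAST reports. Where an optimal alignment is not
unique the aligner's first traceback is used, so reported identity is a
property of one optimal alignment; the alignment *score* is unique and is
what the test suite checks against an independent dynamic-programming
oracle.

Greedy identity-tier filtering visits sequences longest-first (ties broken
by id) and retains a sequence iff its identity to every already-retained
representative is below the threshold — the CD-HIT-style procedure behind
non-redundant tiers such as <95%, <70% and <60% identity. The procedure is
idempotent, and the retained set satisfies two exact invariants: retained
sequences are pairwise below the threshold, and every discarded sequence
has identity ≥ threshold to some representative.

A column is parsimony-informative when it shows at least two distinct
non-gap states, each in at least two sequences; 'X' counts literally as a
state here (the counting rule is purely symbolic), whereas the conservation
profile used for rate-shift typing excludes 'X' as unknown.

## Pattern profiling

Per-group logos tally residues over selected alignment segments; gaps are
excluded from frequencies but reported as a per-column gap fraction, and
information content is log2(20) − Shannon entropy (bits), undefined (and
flagged) for columns with no usable residues. A logo collapses to a
PROSITE-verbose pattern: each column becomes the class of residues observed
above `min_freq` (default 0, i.e. every observed substitution — patterns are
deliberately permissive), and adjacent segments are joined by bounded
wildcards `x(min,max)` from the declared inter-segment spacings. Classes
serialize alphabetically so pattern text is byte-stable.

The scanner reports every match at a distinct start position (overlaps
included); for variable-length wildcards the leftmost-then-shortest
expansion is reported per start. PROSITE semantics do not prescribe hit
enumeration, so both policies are fixed for determinism; the test suite
checks the scanner against an independent regex-translation oracle whose
lazy quantifiers realize the same expansion order.

Iterative refinement re-derives a pattern from its own database matches:
scan, extract the matched segment instances (the pattern match itself
localizes the segments — no profile-HMM re-alignment step is involved, by
design, which keeps the loop closed-form), drop exact duplicate segment
tuples, rebuild the logo, reassemble, and stop at a fixed point of the
pattern text. Curation against outliers is available as the `min_freq`
frequency floor; no structural outlier detection is attempted. A round with
zero hits returns the last pattern with a warning status rather than
failing.

## Rate-shift typing and significance

Types follow the classical functional-divergence taxonomy, operationalized
on per-group modal frequencies (gaps and 'X' excluded): type II = both
groups conserved (modal frequency ≥ c_hi) with modal residues whose
Grantham distance ≥ `grantham_min`; type I = conserved on one side
(≥ c_hi), variable on the other (≤ c_lo); type I/II = the mixed cases
(fixed-but-conservative difference, or conserved vs intermediate with a
different residue). "Differ radically" is deliberately pluggable — the
Grantham matrix is bundled as static data and any other physicochemical
distance can be substituted.

Defaults: c_hi = 0.9, c_lo = 0.6, Grantham ≥ 60, per-group gap fraction
≤ 0.5 and ≥ 2 usable residues for a column to be callable, B = 999
permutations, BH FDR at q ≤ 0.05. These are conventional values, exposed in
the API and the pipeline configuration; the typing thresholds interact with
group sizes (with 20 sequences per group, c_hi = 0.9 tolerates 2
non-modal residues).

The permutation test shuffles group labels among a column's usable residues
and recomputes the divergence score D = (1 − f_A(r_B)) + (1 − f_B(r_A)).
The p-value (1 + #{D* ≥ D − 1e-12}) / (B + 1) is exact and conservative
under exchangeability; its floor is 1/(B+1) and degenerate single-residue
columns return p = 1. The 1e-12 slack makes the ≥ comparison robust to
floating-point noise in tied scores. A site is *called* only when the
categorical type and BH-adjusted permutation significance agree —
mirroring the practice of requiring agreement between two independent
divergence criteria.

Fixation stage = earliest group of the ordered succession from which the
column's modal residue stays identical and conserved (≥ c_hi) through every
later group; a column conserved family-wide maps to the outgroup stage, and
a group that is uncallable at the column blocks every suffix containing it.
Raising c_hi can only move a stage later (monotonicity), which the property
tests check. Significant sites are partitioned by stage into coevolution
collections; when a residue contact network is supplied, each stage is
further split into the network's connected components (the spatial waves),
with unmapped columns as singletons.

## Structures

CA-only models are read from PDB (first MODEL, first chain by default,
altloc ' ' or 'A', insertion codes retained). MSA columns map to residue
indices through a gapped query/structure alignment; mismatched letters are
mapped but reported. Contact networks use a CA–CA cutoff of 10 Å — a common
residue-interaction heuristic, configurable — and conformational
rearrangement is reported per site as the Jaccard similarity of its
neighbor sets in the two conformations (1.0 when both are empty; any value
< 1 flags the site).

Model-to-model distance is the minimal RMSD over proper rotations and
translation. The rotation comes from `scipy`'s Kabsch solver, but the RMSD
itself is recomputed from the residuals because the solver's reported
residual loses ~sqrt(machine-epsilon) precision to cancellation when the
point sets nearly coincide; the recomputation makes rigid-motion pairs
return RMSD at the 1e-14 level. Conformer maps use classical (Torgerson)
MDS — double-center the squared distance matrix, eigendecompose, embed on
the top-2 non-negative eigenvalues — which reproduces rank-≤2 Euclidean
matrices exactly; sklearn's SMACOF-based MDS is not a substitute here, and
scikit-bio's principal-coordinates analysis serves as an independent
cross-check in the tests. Each model is labelled by its nearest reference
in the *full* RMSD matrix, never the 2D projection, to avoid projection
artifacts. RMSD over the common CA set is a declared analogue of structure-
comparison Z-scores: the acceptance surface is the topology of the
conformer map (ordering, nearest-reference labels), not absolute distances.

## Transmembrane segment counting

Kyte–Doolittle hydropathy is smoothed with a centered 19-residue window
(shrunken at the ends) and maximal runs ≥ 1.6 are candidate segments; runs
separated by ≤ 3 positions merge, and runs shorter than `min_len` = 4 are
dropped. The floor applies to the *smoothed run*, which is much shorter
than the physical helix: a 19–23-residue hydrophobic stretch yields a run
of roughly L + 20 − 2k positions, where the window must overlap the stretch
by k ≈ 14–18 residues (composition-dependent) before the average clears
1.6. Simulating 20 000 stretches of the generator's composition shows the
shortest genuine run is 4; polar linkers can never cross the 1.6 threshold
(their window mean is ≈ −2.6), so the low floor admits no spurious
segments. Counting is invariant to appended polar tails and monotone
non-increasing in the threshold.

## What the synthetic data emulates — and what it does not

The generators reproduce the *statistical structure* the analyses assume,
with planted, exactly-verifiable truth:

* **Grouped MSAs** — background columns share one consensus residue across
  groups, copied per cell with a probability solved (by root-finding) to
  hit the requested expected within-group identity (default 0.35), so they
  are exact exchangeable nulls for the permutation test. Planted columns
  receive their modal residue by *exact count* (⌈conservation·n⌉ copies,
  default 0.95), so advertised frequencies hold by construction; type I
  variable sides draw uniformly from a ≥4-residue set disjoint from the
  conserved residue (recovery tests need contrast, not realism); gaps are
  i.i.d. per cell (default 2%, 5% in the succession study) and never fall
  in planted columns, keeping truth exact.
* **Scan databases** — members embed their group's six-segment motif with
  linker lengths drawn inside the declared bounds; groups draw from
  disjoint residue alphabets so cross-group specificity is decidable;
  decoys are shuffled-composition copies of members.
* **TMS architectures** — 19–23-residue stretches from {L,I,V,F,A,M}
  between ≥10-residue polar linkers.
* **Structures** — ideal α-helical CA traces (rise 1.5 Å, 100°/residue,
  radius 2.3 Å) in a spaced bundle with 0.02 Å jitter; planted clusters are
  runs of ≤ 7 consecutive residues, which helix geometry keeps within 10 Å
  of each other; conformation B rigidly rotates a declared helix subset.

Not emulated: real amino-acid compositions and site-rate heterogeneity,
indel evolution, phylogenetic correlation within groups (sequences are
exchangeable given the column model), helix packing geometry, and database
noise. Passing the recovery studies therefore demonstrates that the
*machinery* is correct and calibrated under its stated assumptions — not
that real families exhibit signals this clean. In particular the
exchangeability of synthetic null columns is exactly the permutation null,
so the null calibration checks the test's validity, not robustness to
phylogenetic autocorrelation (a known limitation of label-permutation
tests on trees).

## Study sizes and determinism

The default recovery study uses 2 groups × 20 sequences with 10 type II,
10 type I and 80 null columns over 100 seeded replicates (B = 999); the
succession study uses 5 ordered groups × 12 sequences with 3 columns
planted per stage; the scan study 50 members per group with 50 decoys; the
topology study 100 seeds of 11- and 12-TMS architectures. These sizes give
the recovery fractions tight denominators (1000 planted sites per type,
8000 null p-values) while the whole study remains a desk-scale computation.

All generators are pure functions of spec + seed. The pipeline fans a
single global seed out to per-stage seeds by stable hashing, writes each
stage's outputs before the next starts, and emits a versioned JSON report
with no timestamps, so a rerun under the same configuration is
byte-identical. Unknown configuration keys are rejected before any stage
runs.

## Known limitations

* Permutation significance assumes within-column exchangeability across
  sequences; phylogenetic structure within groups inflates the effective
  false-positive rate on real data.
* The typing thresholds (c_hi, c_lo, Grantham ≥ 60) are conventions, not
  estimates; they are exposed precisely because no canonical values exist.
* Pattern scanning implements the match stage only — no alignment
  extension, no E-values — so hit counts are not comparable to
  database-search outputs.
* The identity convention (denominator, gap treatment) affects tier
  membership near thresholds; results at a tier boundary should be read
  with that in mind.
* Nearest-reference conformer labels depend on the reference set supplied;
  with references from a single basin every model maps there.
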