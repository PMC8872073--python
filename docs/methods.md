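# Methods

`dupshift` implements a survey procedure for frameshift mutations between
duplicate genes: detecting paralog pairs from coding sequences, deciding
which copy carries the frameshift (the *derived* copy), partitioning the pair
into common-frame and frameshifted regions, and measuring selection (Ka/Ks)
per region and per lineage against a reconstructed ancestor.  A synthetic
generator provides duplicate pairs with known ground truth, so every stage is
validated by parameter recovery rather than by eye.

## The frameshift-aware aligner

The core primitive aligns the protein of one copy to the CDS of the other
with a dynamic program whose step set is:

| step            | aa | nt      | score                                        |
|-----------------|----|---------|----------------------------------------------|
| codon match     | 1  | 3       | BLOSUM62(aa, translation of the codon)       |
| aa insertion    | 1  | 0       | affine gap (−11 open, −1 extend)             |
| codon deletion  | 0  | 3       | affine gap (−11 open, −1 extend)             |
| frameshift-k    | 1  | 1,2,4,5 | −15 + best *consistent* codon score          |

The alignment is **global in the protein and local in the CDS**, so a derived
copy with a novel terminus (a new upstream start, or a tail read past a
premature stop) does not force terminal gap penalties on the CDS side.
Scores are integer BLOSUM62 half-bits.

A frameshift step consuming k nucleotides emits the substitution score of the
best codon *consistent with the consumed bases*: for insertions (k = 4, 5)
any codon obtained by deleting the inserted run; for deletions (k = 1, 2) any
codon obtained by restoring the missing bases.  This anchors the step at the
true indel junction — with a context-free emission the step drifts toward
nearby substitutions, which it can absorb for free.  The frameshift penalty
(−15) exceeds any single mismatch cost, so frameshifts are not invoked
spuriously, yet one is payable whenever at least ~5 shifted codons follow.
Traceback ties prefer match > deletion > insertion > frameshift, which places
indels at their 5'-most equivalent DP position.

Adjacent frameshift/gap steps within two codons are merged into net events;
an event whose net size is a multiple of 3 is an in-frame indel and is
discarded.  Event sizes are signed relative to the CDS being aligned to
(insertion positive); consequently, swapping the roles of the two copies
negates sizes and maps phases φ → (3 − φ) mod 3.

**Nucleotide-level position refinement.**  Codon-level scoring leaves the
junction position ambiguous up to wobble-equivalent codons (±1 codon in
roughly 15% of simulated events at 5% divergence).  When both underlying
nucleotide sequences are available, each event's changepoint is re-located by
maximizing direct base agreement of the upstream (old frame) and downstream
(new frame) flanks over a ±12 nt window.  Score-maximal changepoints form an
interval when the junction sits in a repeat or next to chance base
coincidences; the true junction always belongs to that interval, so its
median is reported, halving the worst-case placement error.  On simulated
data this raises the fraction of events placed within ±3 nt from ~86% to
~98%.

## Detection of duplicate pairs

Candidate pairs are found by translated similarity: all 3×3 reading-frame
pairs of the canonical transcripts are compared by local Smith–Waterman
(BLOSUM62, −11/−1).  A pair must clear three thresholds: identity ≥ 0.70
(fraction of identical aligned columns of the best-scoring frame pair),
overlap ≥ 0.70, and raw score ≥ 50 half-bits (the raw-score threshold
replaces a database-size-dependent E-value, which is meaningless on
simulated sets).  Because a frameshifted pair aligns its common and shifted
segments in *different* frame pairs, overlap is the union coverage of the
shorter copy over all frame-pair alignments scoring at least
min(best/2, 25) — multi-HSP reporting, in effect.  An all-three-frame
shared-5-mer seed prefilter (≥ 3 shared translated 5-mers) gates the
quadratic Smith–Waterman stage; it is a pure performance heuristic that
cannot remove a pair able to clear a 70% identity filter.

A transcript-consistency filter then requires every transcript-vs-transcript
comparison of a candidate pair to yield the same multiset of events
(equal phases; positions within 2 aa), which removes frameshifts introduced
by alternative transcripts rather than by mutation.

## Polarization and typing

With an outgroup (the closest relative lacking the duplication), the copy
whose full reading frame matches the outgroup is the original.  This is
decided by frameshift-event counts: the outgroup protein is aligned to each
copy's CDS, and the copy requiring no frameshift step retains the ancestral
frame.  A raw score margin (> 5 half-bits wins, else unresolved) is the
fallback when event counts tie.  Event counts are used first because the
score margin is swamped by branch-specific substitution noise (σ ≈ 35
half-bits on 200-codon genes at 5% divergence) whenever the frameshifted
region is short.  Without an outgroup, the copy with the shorter canonical
protein is assumed derived; an explicit override supports curated
exceptions.  Outgroups are vetted for Ka/Ks work: the synonymous distance
from the original copy to the outgroup must exceed 1.5× the copies'
common-frame Ks, so that the outgroup divergence safely predates the
duplication.

The canonical alignment maps the original protein (global) onto the derived
CDS (local).  A frame-tracking walk partitions the alignment into maximal
runs: where the derived CDS is consumed on its own codon grid the copies
share a frame (*common region*); elsewhere the derived copy is read in a new
frame (*frameshifted region*), and the aligned counterpart on the original
copy is the *original-frame region*.  Type labels follow region geometry: a
frameshifted region that is last in the partition runs into the derived stop
(type C), one that is first abuts the derived start (type N), and a strictly
internal one is type M.  Multiple disjoint frameshifted regions produce
composite labels (e.g. "N&C").  Consecutive runs in different shifted frames
(two non-compensating indels) merge into a single frameshifted region, so a
two-hit C-terminal case is still type C with two events.

Relative event location is the first event's position projected on the
original copy, divided by the original CDS length.  Relative region lengths
are normalized by the original copy's protein length by default; because the
frameshifted region lives on the derived copy while the text anchor is the
original copy's unit interval, normalization by the derived copy is provided
behind a flag.  Stop codons are excluded from all aa lengths.

## Ka/Ks machinery

Substitutions are counted by Nei–Gojobori (1986) pathway counting.  Each
codon position contributes its fraction of synonymous single-nucleotide
changes to the synonymous site count; changes to stop codons count as
nonsynonymous, so La + Ls = 3 per codon exactly.  Multi-hit codon pairs are
averaged over all minimal substitution paths with equal weights, excluding
paths through stop codons whenever a stop-free path exists.  Proportions are
Jukes–Cantor corrected; p ≥ 3/4 flags saturation and reports an infinite
rate.  This self-contained estimator is exactly testable against a
path-enumeration oracle; it is not expected to agree bit-for-bit with
likelihood-based codon models, which weight transversions and codon
frequencies differently.

The duplicates' ancestor is reconstructed column-wise by parsimony on a star
alignment (original copy as the centre, built from two global nucleotide
alignments): where the duplicates agree the ancestor takes their state;
where they disagree, the outgroup state when it matches either duplicate;
where all three differ, the outgroup state.  A gap in exactly one duplicate
is resolved toward the outgroup.  At 5% divergence per branch the
reconstruction matches the true ancestor at ≥ 99.8% of sites.

All comparisons — between copies, and from the ancestor to each copy — read
codons on the **original copy's frame**, including inside frameshifted
regions, even though the derived copy is translated differently in vivo.
Region × lineage rates are reported per case and in pooled mode (Na/Ns/La/Ls
summed across cases before rates are formed).  Two count-based tests
accompany the rates: Fisher's exact test (two-sided) on the lineage ×
(nonsynonymous, synonymous) table for equality of Ka/Ks between lineages,
and a one-sided binomial test of Na against the site-count expectation
La/(La+Ls) for within-lineage positive selection.  Fractional pathway counts
are rounded half-up for the exact tests; raw fractional counts are retained
in all outputs.

## Survey statistics

The type-C vs type-N enrichment test is an exact binomial test with success
probability 1/2, two-sided by doubling the smaller tail (capped at 1).  The
region-length comparison uses a paired sign-flip permutation test on
per-case differences (frameshifted − original-frame relative length),
one-sided for "frameshifted is shorter", with the observed permutation
included (add-one); a pooled label-permutation variant is available, the
paired variant is the default because the two lengths are paired within a
case.  Distributions (event location, region length, Ks, Ka/Ks) are binned
with exact width-0.1 bins on (0,1), last bin closed.  No multiple-testing
correction is applied; raw p-values are reported.

## The synthetic generator

Each pair descends from a random ancestor CDS (uniform sense codons, ATG
start, one stop; 90-nt flanks, the 3' flank seeded with stop codons in all
three frames so any shifted ORF terminates).  An outgroup branch evolves for
`t_pre` expected substitutions/site and two post-duplication branches for
`t_post` each.  Evolution proposes Poisson(t·L) single-nucleotide changes;
a nonsynonymous proposal is accepted with probability min(1, ω) and a
synonymous one with min(1, 1/ω), so the realized dN/dS equals ω on both
sides of 1 (an acceptance capped only on the nonsynonymous side cannot
produce dN/dS > 1).  Proposals that destroy the start, the stop, or create
an internal in-frame stop are rejected.

One duplicate receives a frameshift scenario before its branch evolves:

* **C** — an indel (size not divisible by 3) at a placement quantile; the ORF
  is re-called through the first stop in the running frame, extending into
  the 3' flank if necessary.  *multi-C* adds a second, non-compensating
  indel downstream.
* **N** — an indel near the 5' end plus a new ATG written into the 5' flank
  at a frame-compatible offset, giving an ORF that reads through the indel
  back into the original frame.
* **M** — two compensating indels; the interior region between them is
  shifted, and the protein ends at the original stop.

The scenario type is drawn once per pair from `scenario_mix`; degenerate
draws (a premature stop inside a shifted region, or a frameshifted region
shorter than 8 codons — a handful of shifted codons cannot outweigh any
aligner's frameshift penalty, and observed frameshifted regions in real
surveys are ≥ 9 aa) redraw only the ancestor and placement, so the realized
mix follows the configured one.  Inside the simulated frameshifted region of
the derived branch, ω-acceptance classifies changes in the *original*
reading frame (the frame the estimator measures in), while stop-codon
protection uses the derived copy's own frame; this makes
`omega_frameshifted` exactly the quantity the pipeline estimates.

Default study conditions: 80 pairs of 300 codons; `t_post` = 0.1 per branch
(paralog synonymous divergence ≈ 0.2, matching a survey dominated by young
duplicates with Ks below 0.3); `t_pre` = 0.25 (outgroup clearly older than
the duplication); background ω = 0.5 (duplicates under relaxed but real
constraint, with typical common-frame Ka/Ks below 1); ω = 1.1 inside
frameshifted regions (mildly elevated, matching a pooled derived-lineage
frameshifted-region ratio just above 1); indel sizes {−4, −2, −1, +1, +2};
scenario mix C 0.64 / N 0.22 / M 0.09 / multi-C 0.05, the observed
composition of such surveys.  Event placement is uniform over a quantile
range (default (0.05, 0.95)); the observed C-terminal skew of real events
can be emulated by narrowing the range, but the default stays uniform so
location-recovery tests are not biased toward easy cases.

**What the generator does not emulate:** intron/exon structure and
alternative splicing (multi-transcript mode duplicates identical CDSs only,
to exercise the consistency filter); gene conversion between duplicates
(which retards divergence); base-composition and codon-usage bias;
rate variation among sites; segmental duplications of more than two copies.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under a clean neutral-ish model, not robustness to every
complication of real genomes.

## Numerical and interface conventions

Coordinates are 0-based half-open throughout.  Reported event position is
the first nucleotide read in the new frame.  Determinism: every stochastic
component takes a seed or NumPy `Generator`; identical configurations give
byte-identical outputs, and per-pair seeds are spawned with
`SeedSequence(seed).spawn()`.  Problem sizes used by the shipped validation
runs — 500 pairs for end-to-end recovery, 200 replicates per ω for estimator
recovery, 150–200 pairs for the pooled region contrast — give binomial
standard errors comfortably below the margins being checked.  The survey
pipeline skips Ka/Ks work on pairs without a vetted outgroup; cases with an
unresolved polarity are dropped and counted in the log.

## Known limitations

* The aligner models frameshift steps of ±1 and ±2 nt per residue; a single
  indel larger than 5 nt is recovered as a merged cluster of steps, but very
  large indels (tens of nt) inside otherwise-alignable regions will surface
  as gap runs, not frameshift events (their net size is a multiple of 3 or
  they exceed the merge window).
* Event placement inside long repeats is ambiguous in principle; the median
  tie-break bounds but cannot eliminate the error.
* NG86 with Jukes–Cantor correction underestimates rates at high divergence
  and ignores transition/transversion bias; pooled ratios at ω = 2 are
  recovered within ~7% at t = 0.1 but degrade with saturation.
* Ancestor reconstruction assumes the outgroup is frameshift-free over the
  aligned span; a frameshifted outgroup would mis-polarize columns near its
  own lesion.
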