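# Methods

This note documents the models and numerical choices behind `rnaikit`, what
the synthetic data emulate, and the limits of what the tests demonstrate.

## Sequence model

All sequences are held internally in the RNA alphabet (T→U on input, case
folded), since the silencing machinery operates on RNA even though triggers
are cloned as DNA; each record remembers its input alphabet for output.
IUPAC ambiguity codes are retained in transcripts but have no defined
pairing energy, so any siRNA window containing one is excluded from
enumeration (counted and logged) and any such position is treated as
unpairable by the folding model. A dsRNA trigger is represented by its
sense (mRNA-polarity) strand; 2-nt 3′ overhangs and the Dicer processing
register are not modeled — every k-mer window is a candidate duplex.

## siRNA matching

Matching is exact by construction rather than heuristic. For perfect
matches, a hash index over all transcript k-mers is queried; for 1–2
mismatches the query is split into `m+1` segments, so by pigeonhole at least
one segment of any true hit matches exactly, and exact segment lookups
generate candidates verified by Hamming distance. The test suite proves
set-equality against a naive sliding-window Hamming scan on randomized
instances (property-based, both orientations, m ∈ {0,1,2}) and subset
monotonicity in m. Both duplex strands are searched: a sense-orientation
match means the antisense guide can pair that transcript (the
silencing-relevant case); orientation is carried through all reports.
Coordinates are 0-based half-open internally and 1-based in all output
tables. Indels and spliced alignment are out of scope.

## Duplex-end thermodynamics and strand selection

Which strand RISC retains is predicted from duplex-end asymmetry. End
stability at a strand's 5′ terminus is the sum of the `n_terminal − 1`
nearest-neighbor stacking free energies (ΔG°37, kcal/mol) of the terminal
base pairs, read into the duplex; `n_terminal` defaults to 3 (two stacks)
and is configurable from 2 to 5. The Watson–Crick parameters are the
standard Xia/Turner ΔG°37 stacking set, shipped as a plain-text table
(`data/rna_stack_dg37.tsv`) expanded to all 16 top-dinucleotide keys via
the 180° rotational symmetry of a helix; GU wobble parameters are included
for the folding model only (siRNA duplexes are fully complementary by
construction). Dangling ends, terminal-AU penalties and salt corrections
are deliberately omitted: the quantity is a local end-stability score with
a simple, exactly testable definition, not a hybridization energy.

Rules, for guide = antisense strand and ΔMFE = ΔG(guide 5′) − ΔG(passenger
5′) (antisymmetric under strand swap):

* sequence rule — guide 5′-terminal nucleotide ∈ {U, A};
* opposite-end rule — passenger 5′-terminal ∈ {G, C} (reinforcing signal,
  optional in both modes, off by default);
* thermodynamic rule — ΔMFE > 0 (guide 5′ end less stable);
* strict thermodynamic rule — ΔMFE > 1 kcal/mol.

The predicted guide is the antisense strand iff the sequence OR
thermodynamic rule favors it; the sense strand iff the mirror conditions
hold for it and none for the antisense; otherwise undecided.

## Local accessibility (LAP)

The accessibility of position i is the probability that the u-nt stretch
ending at i is completely unpaired at equilibrium. Within every folding
window of length `min(W, len)` sliding by 1 nt, a McCaskill-style partition
function restricted to pairs of span ≤ L is computed; the stretch
probability is the ratio of the pair-forbidden to the unconstrained
partition function, and probabilities are averaged with equal weight over
all windows fully containing the stretch. Values are assigned to the
stretch's 3′-most position (positions < u−1 are undefined); a target site's
scalar is the maximum defined LAP inside the site, compared against the
threshold. Max-over-site and 3′-assignment are design choices of this
package. Defaults: u = 8, L = 40, W = 80, threshold 0.1.

The energy model is intentionally reduced: allowed pairs are Watson–Crick
plus GU; a pair stacked directly on its interior neighbor contributes the
nearest-neighbor stacking term; every other pair closes a loop (hairpin,
bulge/interior or multibranch alike) and contributes one constant
`loop_penalty` (default 5.0 kcal/mol, chosen so that a 4-bp GC stem hairpin,
~−9.8 kcal/mol of stacks, decisively beats the open chain at 37 °C);
hairpin loops enclose ≥ 3 unpaired nucleotides; pseudoknots are excluded.
This keeps the algorithmic core — windowed partition function, span
restriction, stretch probabilities, window averaging — exact and bit-
testable: the suite verifies agreement to ≤ 1e−9 with exhaustive
enumeration of all secondary structures under the same model, plus the
structural invariants (probabilities in [0,1], containment monotonicity,
window invariance for short sequences, monotone response to the loop
penalty). The reduced model reproduces the *shape* of accessibility
profiles (stems low, loops and tails high) but its absolute values are not
comparable to RNAplfold's full Turner-model output; conclusions that depend
on calibrated absolute accessibilities should not be drawn from it.

Complexity is O(windows × stretches × W²·L) with the per-window constrained
recomputation strategy; the kernel is compiled with numba, making a 500-nt
transcript profile a few seconds of work at default parameters.

## Classification modes

* **HS (high sensitivity)** — a hit passes iff the strand-selection call
  predicts the antisense guide (sequence rule OR thermodynamic rule). Used
  by the off-target workflow, which must miss as few functional siRNAs as
  possible; accessibility is never computed there.
* **HE (high efficiency)** — a sense-orientation hit passes iff sequence
  rule AND thermodynamic rule AND strict (>1 kcal/mol) rule AND site
  accessibility ≥ threshold. Every failed conjunct is reported. HE ⊆ HS
  holds identically because the HE strand conditions imply the HS
  disjunction.

The exact boolean composition of the "stringent" rule set was an open
design choice; this conjunction is the package's documented
interpretation, with the opposite-end G/C condition scored but optional
(its textual status is reinforcing rather than necessary).

## Pipeline, zoning and region recommendation

Per-position curves count the hits of every siRNA covering a position
(total, HS, HE). In design mode a position is **red** iff at least one
covering siRNA has an HS hit on a transcript outside the declared
main-target set — several main targets are allowed, gene families being the
canonical use case. Off-target mode reports all positions green: zoning is
meaningful only relative to a declared set of intended targets, which
off-target search does not take. The recommended design region is the
window (default 100 nt, mirroring a practical cloning-fragment size) with
the most HE hits among windows with zero red positions, ties to the 5′
end; it is absent when no red-free window contains an HE siRNA. Reports
(TSV/JSON) are byte-deterministic for identical inputs and parameters.

## Synthetic constructs

The generator reproduces the two validation designs used for tools of this
kind, at their published scale (500-nt triggers, 100-nt windows):

* **molecular-clock series** — `round(p·len/100)` distinct positions drawn
  without replacement and re-drawn uniformly from {A,C,G,U} (original
  allowed), so expected identity is `100 − 0.75p` percent; the standard
  series runs 0–100% in steps named after simulated divergence time (2% per
  million years). The suite checks Monte-Carlo identity recovery against
  the analytic binomial 99% CI and the monotone decay of perfect-match hit
  counts with p.
* **window constructs** — one 100-nt block copied from the base sequence at
  its original coordinates into a fully randomized backbone (the 100%
  clock construct), giving triggers that match the target only inside the
  window; barring chance 21-mers in the backbone (the generator's
  evaluation path detects and resamples these), a first-window construct
  yields exactly 80 perfect 21-mer matches.

Identity is ungapped positional identity — simple and analytically
tractable. Alignment-based identity, which published tables of such series
appear to use for heavily diverged constructs (it saturates near ~34%
rather than 25%), is intentionally not implemented.

What the synthetic data do **not** emulate: real transcriptome composition
(GC bias, repeats, UTR structure), expression levels, and any biological
variation in silencing response. Passing tests demonstrate algorithmic
correctness under the stated models, not predictive accuracy on real
transcriptomes; the packaged benchmark table (published per-construct
counts with the measured mean log2 susceptibility index, used by
`rnaikit evaluate`) is the external anchor, and its strongest correlation
with silencing strength is the HE-mode count (Pearson r = −0.61).

## Degenerate inputs and tie-breaks

Triggers shorter than k produce an empty report with a warning rather than
an error. Empty databases, duplicate FASTA identifiers, unknown main-target
identifiers and parameter combinations violating u ≤ L ≤ W are hard errors.
Transcript rankings sort by HS count, then total count, then identifier;
region ties break 5′-most; hit tables sort by (siRNA start, database order,
position, orientation).

## Known limitations

* The reduced fold model omits the Turner loop tables; absolute LAP values
  differ from RNAplfold's.
* No position-specific efficacy scoring (Reynolds/Ui-Tei-style matrices) or
  machine-learned efficacy prediction.
* Matching ignores indels and overhangs; guide-target wobble pairing is not
  considered in hit finding.
* The per-window constrained recomputation is quadratic in the number of
  stretches per window; very long transcripts (≫10 kb) are better profiled
  with a larger stride or a dedicated outside-algorithm implementation.
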