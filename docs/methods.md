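# Methods

This note documents the procedures srnapipe implements, the parameters
that matter, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Read processing and classification

Reads arrive adapter-trimmed (the pipeline validates and filters only).
The length window is [18, 30] nt: 18 is the conventional computational
minimum for plant small RNAs, 30 the PAGE size-selection ceiling; both are
configurable. Reads containing any base outside A/C/G/T/U are discarded
and tallied separately, because ambiguous bases would break the exact
matching used downstream. U is normalised to T internally; serialisation
back to the RNA alphabet is the exact inverse.

Known-miRNA matching allows at most 2 substitutions over an ungapped
full-length overlap of the shorter sequence — a deterministic,
reproducible stand-in for heuristic seeded alignment, with no indels and
no E-value model. All other annotation classes match by exact substring
containment against their reference set. Classes are assigned in a fixed
precedence order (known miRNA first, then the structural-RNA classes,
repeats, protein-coding); each read receives exactly one class, so the
class table is conservative by construction: per library, class totals
plus the unclassified remainder equal the clean-read totals. Genome
matching is an independent flag, never a class.

RPTM (reads per ten million) is `count / library_clean_total x 1e7`. The
denominator is the per-library clean-read total; it can be switched to the
genome-matched total in configuration.

## Genome mapping

Mapping is exact and exhaustive: every substitution-free occurrence of a
read or its reverse complement is reported, in forward coordinates with a
strand flag, and multi-mapping reads keep their full count at every site
(no fractional apportioning — this keeps locus counts reproducible).
The index is a seed table of 18-mers verified by direct string
comparison, so results are provably identical to a naive full scan (the
test suite asserts this against an independent scan oracle). Hits on the
same chromosome and strand within 200 nt of each other merge transitively
into read loci; 200 nt keeps both arms of a typical plant pre-miRNA in
one locus. The locus summit is the position with the deepest
count-weighted stack of read 5' ends (minus-strand 5' ends are the
rightmost forward coordinate).

## Hairpin mining and the acceptance rules

Candidate precursor windows are cut around the locus summit with flank
pairs {(20,180), (60,140), (100,100), (140,60), (180,20)} (upstream,
downstream in read orientation; minus-strand windows are
reverse-complemented before folding). Windows must be 50-400 nt and at
most 10% N. Folding uses the ViennaRNA thermodynamic engine when its
python bindings are importable; otherwise a Nussinov-style base-pair
maximisation with a 3-nt minimum loop stands behind the same contract
(deterministic single nested structure plus a score, lower = better).
The best-scoring window is evaluated; ties break to the shorter window,
then the leftmost. All duplex geometry is computed from the dot-bracket
string alone, so the geometry logic is engine-independent and the duplex
tests run on hand-written structures.

The mature candidate is the most abundant read in the window stack. The
star interval is derived from the pairing partners of the mature with
both ends shifted to produce 2-nt 3' overhangs (partners of unpaired
anchor positions are extrapolated along the helix). A mature interval
whose paired positions straddle the terminal loop is rejected as
loop-spanning.

Duplex scoring conventions (the acceptance rules state limits, not
definitions, so these are fixed here):

* the 2-nt 3' overhang of the mature is excluded from the duplex body;
* a mismatch is an unpaired mature-body position inside an internal loop
  (unpaired bases on both arms count one mismatch per unpaired mature
  base);
* an asymmetric bulge is a contiguous unpaired run on exactly one arm,
  one event per run, sized by its length — bulge positions are not also
  counted as mismatches. This makes duplex evaluation symmetric: swapping
  the mature and star roles yields identical mismatch and bulge counts,
  which the suite property-tests.

Acceptance is `rule1 AND (rule2 OR rule3)`:

* rule 1 — the candidate set (reads whose 5' ends lie within +-2 nt of
  the mature or star 5' end) exceeds 95% of precursor-mapped reads, and
  reliable reads (collapsed count >= 5) exceed 75% of the candidate set.
  Both comparisons are strict; the candidate-set definition (+-2 nt) is
  this package's convention, as is counting reliability on the collapsed
  total count across libraries.
* rule 2 — a read is observed whose 5' end coincides exactly with the
  computed star 5' end (tolerance configurable, default 0).
* rule 3 — mismatches < 5, every bulge <= 2 nt, at most 2 bulges.

Because the reverse complement of a stem-loop is itself a stem-loop, a
planted hairpin is typically called on both strands with the same mature
sequence; calls are therefore collapsed by mature sequence, with the per-
locus calls retained (the analog of multi-locus miRNA families).

Loci whose total read count is below the reliable-count threshold are
skipped: they cannot satisfy rule 1.

## Known-family profiling

Reads matching the known set are grouped by the family label of their
minimal-mismatch hit; equal-distance ties resolve toward the family more
abundant in the dataset, then lexicographically. The per-library
representative is the most abundant member (ties lexicographic, making
the choice scale-invariant); the divergence flag is set when
representatives differ between libraries with nonzero counts. A member
equal to a family reference plus 1-2 extra 3' nucleotides (exact body) is
annotated as a tail variant — it remains a single member, never counted
both as a variant and an independent member. Precursors are located by
exact mature placement in each supplied database (genome/EST/GSS), +-180
nt extension, folding, and the rule-3 geometry check; the 5p/3p arm
annotation comes from the validated structure.

## tasiRNA phasing

Trigger-site complementarity is scored over the full trigger length:
+1 per mismatch, +0.5 per G:U wobble, sites kept at penalty <= 4.0
(common plant-miRNA target practice; fully configurable). Cleavage is
placed between the transcript nucleotides pairing trigger positions 10
and 11, so for a site ending at 1-based position e the cut falls after
e-10. Phase windows are `Dk = [t+1+21(k-1), t+21k]` downstream of the cut
t. A TAS call requires two sites; the register anchors at the 5' site's
cleavage point and the cluster is the sense reads between the cut and the
3' site. A read is in phase iff its 5' end is within +-1 nt (default) of
a window start; the per-position profile assigns every cluster read to
the window containing its 5' end, so the profile conserves the cluster
total. Reporting requires in-phase fraction >= 0.5 over >= 4 distinct
D-positions (defaults chosen here; no published numeric cutoffs exist for
this step). The dominant position label carries the sense-strand sign,
e.g. `5'D7(+)`. Antisense phased reads are out of the default acceptance
path.

## Differential expression and temporal typing

Families with maximum RPTM strictly above 100 (with a 1e-9 relative
guard so a value exactly at the threshold up to float rounding is
excluded) are tested with Fisher's exact test on the 2x2 table
[[count, total-count]] of the highest- vs lowest-RPTM libraries.
An exact count test is used because the libraries are unreplicated
sequencing pools — there is no within-group variance for a t-type test.
Significance is plain p < 0.01 with no multiplicity correction on top of
the stringent threshold. Profiles are transformed to
log2(RPTM / row mean) with a pseudo-RPTM floor of 0.1 against zeros, and
clustered with complete linkage on Euclidean distance (correlation
distance available) on both axes. Temporal types are operationalised as
the peak position: A iff the argmax is the last library, C iff the
first, B otherwise; argmax ties break toward the earlier library, and a
constant profile is type C flagged "flat".

## The synthetic-data generator

The generator emulates the statistical structure of a four-time-point
fiber elongation experiment on a 100-kb random genome:

* 8 known-family hairpins with temporal archetypes (rising A, mid-peaking
  B, declining C, one flat family), including a family whose 3'-adenylated
  variant dominates the first three libraries and a family whose
  representative switches in the last library;
* 10 novel hairpins (21/22/24/20-nt matures with fixed 5' nucleotides)
  engineered to pass the rules with wide margins: extended 31-bp stems,
  candidate-set fraction about 0.99 (one fixed-count off-candidate read),
  reliable fraction about 0.9 (nine fixed-count 5'-jitter reads below the
  reliable threshold), three of them with star reads at the exact
  2-nt-overhang position at 0.15x the mature abundance;
* 6 decoy hairpins violating exactly one rule each: candidate fraction
  about 0.77, all-reads-below-5 stacks, 7 planted duplex mismatches, one
  4-nt bulge, four 1-nt bulges. Geometry decoys are at least two units
  beyond their threshold so count noise cannot flip them. Every planted
  region is re-validated at generation time with the pipeline's own
  folding and duplex evaluator (regenerating random flanks until the
  planted property holds), so the truth ledger is honest for any seed;
* a TAS3-like transcript with a perfect 5' trigger site and a two-wobble
  3' site exactly 11 phase windows apart, phased 21-nt reads at 8
  D-positions with D7 at 4x weight and a mid-peaking library profile;
* annotation decoy reference sets (rRNA, tRNA, snRNA, snoRNA, repeat,
  protein-coding) with 24-nt reads, and 1200 background reads per library
  drawn uniformly from non-feature genome regions with a 24-nt-dominated
  length spectrum.

Counts are drawn per library from a gamma-Poisson model
(var = mu + phi mu^2, phi = 0.01) around the planted means; the
structurally critical low-count reads are emitted at fixed counts so rule
margins cannot drift. The truth ledger records every entity's expected
mean and standard deviation, and the suite checks realised counts within
three standard deviations.

What the generator does **not** emulate: sequencing errors and quality
variation, adapter remnants, polyploid subgenomes, repeat-driven
multi-mapping ambiguity, realistic genome composition, antisense phased
reads, and library-size imbalance. Passing the recovery suite therefore
demonstrates the correctness of the pipeline's logic under its stated
definitions, not its robustness to noisy real libraries.

Problem sizes are chosen so a full generate-run-score cycle takes tens of
seconds: a 100-kb genome, about 5,000-8,000 reads per library, and about
45 evaluated loci — large enough that every stage is exercised with
planted and background material, small enough for routine testing.

## Degenerate inputs and tie-breaks

Empty libraries yield empty distributions with a warning rather than
errors; a zero-read precursor fails rule 1 with reason "no reads"; a
homopolymer folds to an all-unpaired structure and is rejected as
mature-unpaired; clustering refuses fewer than two rows. Ties everywhere
resolve deterministically (leftmost position, shorter window,
lexicographic sequence, earlier library), so identical inputs give
byte-identical outputs, which the manifest checksums assert end to end.
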