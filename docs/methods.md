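# Methods

## Coordinate conventions

Alignment columns are 0-based half-open spans; reference core positions
are 1-based. An insert's location is its *flank pair* (p5, p3 = p5 + 1):
the reference core nucleotides immediately 5′ and 3′ of the insertion
point, written `p5–p3` in reports. Distinct flank pairs are distinct
locations even when they lie one position apart; no merging is done,
because adjacent sites genuinely host independent introns in these
genes.

## Insert detection

Given an alignment containing an intron-free reference row, a column is
an *insert column* when the reference is gapped there and the fraction
of rows with a residue is at most `presence_max_frac` (default 0.5 —
inserts are carried by a minority of sequences; the threshold is exposed
because no canonical value exists, only the qualitative rule that
insert columns are gaps in nearly all rows). Maximal runs of insert
columns become spans. Runs touching the alignment ends are treated as
frayed termini and excluded. A reference gap in a non-insert column is
tolerated with a warning (fraying, or an insert shared by most rows,
which is undetectable without an external reference and out of scope).

Completeness: an insert record is flagged incomplete when its span
touches an alignment end, when its residues contain `N` (unsequenced
fill), or when the carrying row has no residues at all before or after
the span (a read that started or stopped inside the insert). Observed
length counts all non-gap characters in the span, including `N`s, so a
truncated implant's recorded and detected lengths agree exactly.

Core extraction deletes the insert-column spans; the operation is
invertible (re-inserting each removed segment at its flank pair
reconstructs every input sequence), which the tests verify on every
generated dataset.

## Splice-site grammar

An insert is accepted as spliceosomal when all of the following hold:
donor hexamer at offset 0 matching `GTDHNN`; acceptor pentamer flush
with the 3′ terminus matching `YNHAG` (for 28S the terminal hexamer is
additionally checked against `YTAMAG`); a branch pentamer `YTRAC`
strictly between donor and acceptor; and a pyrimidine-rich window
(default 10 nt at ≥ 0.6 C+T — "CT-rich" has no canonical numeric
definition, so both parameters are exposed) between the branch and the
acceptor. Among branch candidates the 3′-most one with a qualifying CT
window downstream is chosen, matching the biological expectation that
branch points lie near the 3′ end and making the scan deterministic.
Inserts shorter than 25 nt cannot contain the grammar and are rejected
outright. In strict mode (default) an `N` in the window matches only
pattern `N`; lenient mode lets `N` match anything.

Classification of a complete insert: spliceosomal (SP) if the full
grammar is present; otherwise *ambiguous* when a spliceosomal donor
opens an insert longer than 300 nt (the signature of a possible SP
nested inside another SP — this check precedes the group-I length rule,
otherwise such inserts could never be flagged); otherwise group-I (GI)
when at least `gi_min_len` = 350 nt, a threshold chosen below the
shortest complete group-I insert observed in these genes (399 nt) and
above the longest spliceosomal ones; otherwise ambiguous. Truncated
inserts are *partial*, or *partial(SP-like)* when their surviving 5′
end shows the donor. Group-I confirmation against external reference
profiles is out of scope (no network); length plus grammar absence is
the operational criterion, with optional user-supplied conserved-block
profiles.

## Conserved blocks, distances, trees

For aligned group-I inserts, per-column mean pairwise identity
(gap/N-excluded pairs) is smoothed with a centred 10-column window;
maximal runs of columns at ≥ 0.7 smoothed identity are retained and
concatenated per sequence. The 0.7 default separates the ~1.0 identity
of conserved blocks from the 0.25 expectation of unalignable random
DNA; it is a documented choice, not a published constant.

Dissimilarities are p-distances (mismatches over compared sites,
skipping `-`/`N`; a Jukes–Cantor-corrected variant is available). The
tree engine is classical neighbor-joining (Saitou–Nei Q criterion,
standard branch-length formulas), implemented in-package so its
tie-break is fully specified: ties on Q go to the smallest index pair in
the current label order, making output deterministic even on star-like
inputs. Negative branch-length estimates are clamped to zero with a
warning. The implementation is cross-checked in the test suite against
an independent NJ implementation and against generating additive trees.
Maximum-likelihood and Bayesian inference are deliberately out of scope;
NJ is the desk-scale tree engine for intron clustering and marker
comparison.

## Primer audit

Primers are matched IUPAC-aware at every offset of a core sequence;
reverse primers are reverse-complemented first, so reported intervals
are always forward-strand, and mismatch offsets are counted from the
primer's 3′ end (offset 0 = terminal base; for a reverse primer that is
the leftmost base of its forward-strand site). An `N` in the target is
matched leniently — an unknown base is not evidence of a mismatch. The
critical window defaults to the 3 terminal bases, where polymerase
extension is most sensitive to mismatches; the audit standardises on
the 3′ end throughout. `max_mismatch` defaults to 2 across the whole
primer.

An amplicon audit classifies each sequence: an intron whose insertion
point lies strictly inside a primer's annealing interval (both flanking
bases within it — a flank pair abutting the interval's outer edge does
not block annealing) gives `primer_disrupted`; otherwise a critical or
super-threshold mismatch gives `critical_mismatch`; otherwise
`amplifiable`. When a primer's best site still shows more than 6
mismatches, the target region is considered absent from the core
(truncated sequence) and the status is `region_incomplete`; 6 is far
above any plausible real binding site for the ~15–20-nt primers
involved and far below the ~3/4-mismatch expectation of random
placement. Amplicon total length adds the lengths of introns strictly
between the two primer intervals to the core amplicon span. When
several equally good reverse sites exist, the smallest start coordinate
is used; region extraction takes the substring strictly between the
intervals unless primers are requested.

## Terminal taxa and marker evaluation

Terminal taxa — species-level units of identical or near-identical
sequences — are delineated by single-linkage clustering of core
sequences end-trimmed to the shortest length, linking at ≤ `max_diff`
Hamming differences (skipping `N`). The default `max_diff` = 2 is our
numeric rendering of "near-identical"; no published value exists. Labels
are deterministic (`taxon_001`… by lexicographically smallest member).
Single linkage makes the partition well-defined and monotone: larger
tolerances never increase the number of taxa.

A marker's collapse report groups taxa sharing any identical
full-length region haplotype; taxa whose haplotypes are unique are
discriminable. Haplotypes containing `N` (incomplete regions) are
excluded from equality testing and listed separately rather than
padded. Region NJ trees are built over dereplicated haplotypes with
duplicates re-attached as zero-length sibling leaves. Monophyly on
unrooted trees is evaluated as bipartition membership: a group is
monophyletic iff some edge splits exactly that group.

## Synthetic data generator

The generator's defaults are the study conditions the pipeline is
validated under:

* **Cores.** 18S core length drawn uniformly from 1669–1703 nt (28S:
  760 nt of a 680–765 nt range); 7 clades × 3 taxa; Jukes–Cantor
  substitution only (expected substitutions/site: 0.02 between clades,
  0.0005 within), no indels, so every alignment gap is attributable to
  an implant. An intron-free `REF` row (the root sequence) is emitted as
  the detection reference.
* **Spliceosomal introns.** Length uniform in 96–199 nt; donor sampled
  from `GTDHNN` (80 % the modal `GTAAGT`, else uniform over the class),
  branch from `YTRAC` (modal `TTAAC`), CT tract of 10–20 nt at ~0.85
  pyrimidine, acceptor from `YNHAG` (modal `TACAG`; 28S terminal hexamer
  from `YTAMAG`, modal `TTAAAG`). The 80/20 modal weighting renders
  "usually"/"commonly" without stated frequencies. Construction is
  verified against the scanner and resampled on the rare failure, so
  sampler output is accepted by the scanner by construction.
* **Group-I introns.** Length uniform in 399–547 nt; four 45-nt blocks
  copied from a per-location ancestral template at 3 % mutation,
  alternating with fresh random spacers; the first hexamer is forced
  not to match the donor consensus, so the spliceosomal grammar never
  fires on them.
* **Implantation.** The default 18S scenario has 19 intron locations
  (group-I at the 4th and 12th) carried only by clades 1 and 7,
  mirroring the observed confinement of introns to two clades; the
  published flank positions above ~1470 are mapped into the simulated
  core's coordinate range (a 1669-nt core cannot host a site at 1760).
  Three locations sit inside the V4-style reverse-primer interval and
  two inside V9-style primer intervals, so primer disruption has known
  truth. Carriers at one location share a base intron differentiated at
  2 % substitutions (intron sharing across related taxa). One location
  is presence-polymorphic: its carrier is emitted as two copies, with
  and without the intron, mirroring the two-band PCR observation. The
  3′-most location is always truncated: the implant becomes a
  5′-anchored prefix whose last three bases are `N`, so completeness
  detection and length bookkeeping agree exactly. The 28S scenario has
  a single spliceosomal location.
* **Primer targets.** Exact concrete expansions of the configured
  primers are stamped into every sequence at fixed coordinates, so
  audit outcomes are known a priori. The bundled primers are
  placeholders, not a published set.

What the generator does **not** emulate: alignment error (its alignment
is exact by construction, so detection tests exclude realignment
noise), rRNA secondary structure and covariation, indels in the core,
homing-endonuclease ORFs inside group-I introns, chimeras, and
sequencing error beyond clean truncation. Passing the round-trip suites
therefore shows the bookkeeping and grammar logic are exact on clean
data, not that detection is robust to alignment artefacts in real
datasets — for real data the gap-fraction threshold and a careful
alignment remain the user's responsibility.

## Problem sizes and determinism

All randomised checks are seeded. The test and acceptance suites use
desk-scale sizes: 20-seed round-trips on the default scenario (23
sequences × ~1700-nt cores, 44 implants per seed), 1000-draw
sampler/scanner agreement per intron family, 20 random 5–8-taxon
additive matrices for NJ, 200 random primer/core recounts, and a
20-seed marker contrast comparing a 125-column and a 390-column region
on 21 taxa (clade divergence 0.01, within-clade 0.0003). The marker
contrast is statistical: the short region is expected to collapse at
least as many taxon groups as the long one in nearly all seeds, and the
acceptance script reports the observed fraction rather than asserting
each seed.

## Known limitations

* Insert detection requires an intron-free reference row; inserts shared
  by (nearly) all sequences are invisible by design.
* The spliceosomal/group-I decision for grammar-free inserts between
  ~200 and 350 nt is "ambiguous" by construction; no external profile
  matching is attempted without user-supplied profiles.
* The published insert table transcribed as the fixture contains one
  internal inconsistency (one taxon's printed per-column length sum
  omits its location-19 partial insert); the tabulation reports the sum
  of the printed cells and does not reproduce that one printed total.
* NJ is the only tree engine; branch support is not computed.
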