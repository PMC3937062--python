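# Methods

## Scope and data model

`vitismir` analyses exactly two small-RNA libraries — a hormone treatment
and a control — the classic design of early plant sRNA-seq surveys. All
sequence comparison happens in a single canonical DNA alphabet
({A,C,G,T,N}; U→T on ingest, U restored only in reports), coordinates are
0-based half-open internally and 1-based inclusive in GFF3, and N never
matches anything. The unit of analysis after preprocessing is the *tag*: a
unique insert sequence with one raw count per library ("redundant" mass);
the number of distinct tags is the "unique" mass. Both weightings are
carried through profiles and category breakdowns because they answer
different questions (diversity vs. expression).

## Preprocessing

Adapter trimming takes the left-most position where a prefix of the 3'
adapter of length ≥ `min_seed` (default 8) matches with ≤ 1 mismatch; a hit
at position 0 rejects the read as adapter-only. Defaults are ordinary
small-RNA practice; both are configurable because adapter chemistry varies
by protocol. Reads outside 18–30 nt, reads containing N (exact collapsing
and mismatch counting need a clean alphabet), and reads with ≥ 80% A
(poly-A carry-over; threshold configurable) are dropped. Collapsing
conserves read mass by construction.

## Annotation

Contaminant classes are matched by exact substring membership against class
reference sequences — the conservative semantics of "removal" — with
structural classes (rRNA, tRNA, snRNA, snoRNA, repeat) matched on either
strand and exon/intron features strand-aware. Classification uses a fixed
priority (known miRNA > rRNA > tRNA > snRNA > snoRNA > repeat > exon sense
> exon antisense > intron sense > intron antisense > unannotated), the
standard convention of putting structural RNA first; this makes categories
mutually exclusive and exhaustive, so per-category counts sum exactly to
the library totals. Genome mapping is reported as a separate non-exclusive
tally: a tag can both map and be, say, rRNA, so folding it into the
partition would double-count.

## Known-miRNA matching

Matching is ungapped with a signed offset between tag and reference starts
(|offset| ≤ 4). The cost of an alignment is internal mismatches within the
overlap plus the unaligned overhang of the shorter sequence; a tag is a
known miRNA when its best cost is ≤ 3. Charging overhangs to the same
budget lets genuine isomiR end-variants (families whose printed members
range 20–24 nt) match while keeping the 0–3 budget meaningful — a pure
overlap-mismatch count would let an 8-nt-shifted tag match any reference.
Ties break by cost, then |offset| (positive first), then reference
identifier, and each tag's abundance is attributed to its single best
reference only, never double-counted. Two routes implement the same
contract: a per-tag reference scorer and a numpy-vectorised bulk scorer
used by the pipeline; the test suite asserts their equivalence, tie-breaks
included, on random data.

## Folding and novel-miRNA discovery

Folding maximizes the number of Watson–Crick + G:U pairs under the
non-crossing constraint with hairpin loops ≥ 3 (Nussinov dynamic program).
Maximum pairing — rather than free-energy minimization — is a deliberate
choice: it is dependency-free, exactly checkable against brute-force
oracles, and sufficient for the perfect or near-perfect stems that define
annotatable plant miRNA precursors. An energy-based backend can be plugged
in behind the same `fold` contract. Two numerical details matter:

- **Traceback tie-break.** Max-pairing is heavily degenerate. Whenever
  pairing position *i* attains the optimum, *i* is paired with the
  *largest* admissible *j*: among co-optimal structures this continues
  enclosing helices outside-in and keeps clean stems intact, where the
  opposite preference scatters ties into loop-internal pairs and can break
  a perfect planted stem. Pair *counts* are identical under any tie rule.
- **Duplex identification.** Even so, a co-optimal fold may attach a few
  stray pairs to the mature (loop-internal hairpins, edge slippage along
  homopolymer runs). `evaluate_hairpin` therefore takes the duplex to be
  the largest same-side subset of mature pairs sharing a near-constant
  anti-diagonal i + partner(i) (within 2 × `max_bulge`), the signature of
  one antiparallel stem; stray pairs count as unpaired. The star region is
  anchored on the *median* duplex diagonal — robust to edge slippage — and
  held at the mature's length with the canonical 2-nt 3' overhang shift.

The hairpin acceptance thresholds (defaults, all configurable)
operationalize the community's annotation standard for plant miRNAs: mature entirely on one
arm (at most 2 stray cross-loop pairs tolerated), ≥ 16 of 21 mature bases
in the duplex, ≤ 4 unpaired mature bases, no internal bulge run > 3 nt,
precursor 50–300 nt. They are this package's own operating points: the
tools used by the original surveys publish no numeric thresholds, so no
equivalence is claimed.

Discovery maps each unannotated tag exactly to both genome strands and
folds a ladder of candidate precursor windows around each locus (3' and 5'
extents of 40–150 nt with a 15-nt pad, inside the flank-150 windows),
accepting the first window that passes. Folding small windows first keeps
the duplex local: a global max-pairing fold of a full 190-nt window need
not isolate a local stem even when one exists. Tags below a total count of
5, or outside 20–24 nt, are not folded — singleton background fragments are
never annotatable as miRNAs, and real pipelines apply the same economy —
and tags hitting > 20 loci are set aside as repeats. Each distinct locus of
a surviving tag yields its own candidate with shared (not multiplied)
abundance, which is how identical mature sequences can legitimately carry
several candidate identifiers. A locus overlapping an already-accepted
precursor (isomiR variants, the star, or the opposite-strand reading of the
same inverted repeat) folds into that candidate rather than creating a new
one; tags are processed in decreasing abundance so the dominant variant
names the locus. Star detection accepts tags equal to the predicted star
within ± 2 nt end shifts (Dicer processing is not base-precise).

## Differential classification

NC (normalized count) is reads-per-million within each library, carried at
full precision and rounded to 2 decimals only in reports. The bundled
published tables are consumed exactly as printed: their original
normalization constant is not recoverable from the printed values (it is
demonstrably not reads-per-million for at least one high-abundance
family), and nothing downstream depends on it — the response classes need
only zeros and ratios.

The five-way classification puts presence/absence above the ratio:
zero-in-one-library calls (▲/▼) are exact statements about the observed
libraries and independent of any threshold. The fold threshold for ↑/↓
defaults to 1.5; the published tables' printed arrows are not perfectly
consistent with any single ratio cutoff (nor are the two published totals
for ↑/↓ consistent with each other), so the package's self-checks assert
only the threshold-free presence/absence counts. Both-zero records are
"unchanged" (degenerate-input decision). With one library per condition
there is no replicate dispersion to model, and the package deliberately
offers no p-values: the calls are descriptive.

A related note on family counts: the published survey's prose member
counts for several families disagree with its own printed table (e.g. the
prose names five families while listing four member counts); the bundled
fixtures and all derived summaries follow the printed table.

## Target prediction and cleavage validation

The scan is exhaustive and ungapped: every transcript window of the
miRNA's length is scored against the miRNA with complementary = 0, G:U
wobble = 0.5, other = 1, budget ≤ 3. BLAST-style seeding is unnecessary at
these lengths and an exhaustive scan is deterministic and exactly
oracle-checkable. The positional rules for functional plant sites (perfect
pairing opposite positions 10–11, ≤ 1 mismatch within 2–12) are applied by
default and individually switchable, since published surveys are often
ambiguous about whether they applied them or only the raw mismatch cut.
Cleavage validation reads the RACE convention: the observed coordinate is
the 5' end of the downstream fragment, and the site is supported when that
nucleotide pairs with miRNA position 9, 10 or 11 — the hallmark of
slicer-mediated cleavage. Position indexing is invariant under shifting
the transcript coordinate system.

## Synthetic data: what it emulates, what it does not

The generator plants perfect-stem precursors (mature + 6–12 nt loop +
reverse complement) in a random genome, with a 5'U probability of 0.6 on
matures, contaminant class sequences, and per-condition Poisson read
counts: eight-fold changes for up/down plantings, zero-in-one-condition
extremes for ▲/▼, equal means for ●. Reads carry the 3' adapter, ± 1-nt
end jitter with probability 0.1 (to exercise isomiR-tolerant matching and
star detection), substitution errors at 0.005/base, and a 21/24-nt-peaked
background length profile (0.38/0.32, echoing the size distribution real
grapevine libraries show). Default study size is 20 hairpins with means
20–200 and ≈ 50,000 reads per condition — large enough for stable
presence/absence and ratio recovery, small enough that the full recovery
suite runs in seconds. Background fragments are drawn outside planted loci
so presence/absence ground truth cannot be corrupted by collisions.

Passing these tests shows the machinery is correct on data matching its
assumptions: perfect stems, modest error rates, clean adapter. It does not
show robustness to energy-suboptimal precursors with large asymmetric
bulges, ligation bias, realistic error profiles, multi-mapping repeat
families, or cross-species contamination — real-data features the
generator deliberately does not model. Random contaminant fragments
folding into chance hairpins are possible under a max-pairing objective;
in the pipeline they are excluded beforehand by annotation, and the
shuffled-genome negative control stays empty because unmappable tags are
never folded.

## Determinism

Every stage is deterministic given inputs and configuration: iteration is
sorted, tie-breaks are total, simulation uses a single seeded generator,
and reports format floats at fixed precision — identical seeds give
byte-identical bundles. Degenerate inputs have defined behaviour: empty
FASTA → empty collection; empty library → error for profiles; empty
reference set → no match; locus at a contig edge → clamped window;
sequences too short to fold → error.

## Known limitations

- Max-pairing folding over-pairs random sequence; hairpin criteria, not
  the fold itself, carry the specificity.
- One library per condition: no replicate variance, no significance.
- Exact substring annotation misses diverged contaminant copies; an
  interval-overlap mode against genome annotations covers classes supplied
  as coordinates rather than sequences.
- Ungapped matching and target scanning ignore indel isomiRs and bulged
  target sites.
- C-number assignment for novel candidates is discovery-order within a
  run, not a stable nomenclature across datasets.
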