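# Methods

This note documents the models and procedures implemented in `pseudoref`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Scope and coordinate conventions

The package compares two genomes at ~1% nucleotide divergence: a *donor*
available only as draft contigs plus reads, and a finished *reference*.
All internal coordinates are 0-based half-open on the forward reference
strand; 1-based coordinates appear only in emitted VCF/GFF3/AGP, per those
standards. Alignment query coordinates are kept on the *oriented* query
(reverse complement for minus-strand placements) so query and reference
positions increase together within a chain; conversion helpers return
forward-contig coordinates where downstream consumers (read-based
breakpoint validation) need them.

## Contig polishing

Reads aligned to the draft contigs are tallied into dense per-position
pileups (allele counts and summed Phred qualities for A/C/G/T/deletion,
plus an inserted-sequence tally per junction). Records that are unmapped,
secondary, supplementary or duplicate-flagged are skipped; reads below
mapping quality 20 and bases below base quality 20 are excluded — the
defaults mirror common practice for consensus calling from short reads.

A position is corrected when the majority non-contig allele is effectively
homozygous: frequency ≥ 0.70 of quality-filtered coverage, depth ≥ 10, and
consensus quality ≥ 30. "Consensus quality" here is a deliberately simple
monotone surrogate for a genotype-likelihood model:
`min(999, Σ supporting base qualities − Σ conflicting base qualities)`.
It preserves the intended behavior of a Phred-scaled variant quality
threshold (weak or contradicted evidence scores low) without reproducing
any particular caller's likelihood arithmetic; the difference is
documented rather than hidden. The frequency is computed over
quality-filtered reads, since those are the observations the caller
actually sees. A two-allele exact 50/50 tie yields no call.

The procedure runs for a fixed number of rounds (default 2), round *r+1*
operating on round-*r* output. With a static SAM this is exact as long as
corrections are substitutions (coordinates unchanged); after an indel
correction, positions downstream are not re-examined unless a re-mapping
callable is supplied — a logged, documented limitation.

## Whole-genome alignment (seed–chain–extend)

**Seeding.** Maximal exact matches (MEMs) of length ≥ 20 bp are found
through a sorted k-mer index (k = 20, 2-bit codes in int64): k-mer hits are
grouped per diagonal, merged into runs (hits ≤ k apart on one diagonal are
provably contiguous matches), and extended to maximality. k = 20 is small
enough that 1% divergence leaves a seed between most adjacent SNPs
(expected spacing 100 bp) and large enough that random 20-mer collisions
are negligible at the genome sizes involved. K-mers occurring more than
`max_occ` (default 64) times are skipped for cost control; the BES mapper
raises the cap to 512 because clone-end reads must map inside repeat
tracts where a k-mer legitimately occurs once per repeat copy.

**Chaining.** Per contig × chromosome × strand, a maximum-weight collinear
subset of anchors (weight = summed anchor length; starts and ends strictly
increasing in both sequences; same-coordinate gaps ≤ 100 kb so paralogous
hits far apart are not chained) is selected by O(n²) dynamic programming
with vectorized inner loops. The best chain is peeled off and the DP
repeated, so secondary candidates at other loci exist for uniqueness
assessment; no anchor joins two chains.

**Gap closure.** Consecutive anchors whose query or reference gap exceeds
`max_join_gap` start separate alignment blocks; smaller gaps are closed by
Needleman–Wunsch with match +1, mismatch −1, gap −2 (configurable).
`max_join_gap` defaults to 90 bp — just under the 100 bp floor of the
large-indel definition — so that every event the indel classifier must see
appears as an inter-block junction, while smaller indels are absorbed into
blocks as gap columns. Identity is matches over alignment columns
*including* gap columns, a fixed documented convention (the alternative,
excluding gaps, inflates identity across small indels).

**Junction refinement.** After block construction, block edges facing an
inter-block junction are extended greedily along the diagonal with an
X-drop rule (match +1, mismatch −3, stop when 8 below the running
maximum, keep the best-scoring prefix). Without this, a substitution
within ~20 bp of a true breakpoint strands an unaligned sliver that both
inflates the "other side" gap past its 10 bp tolerance and shifts the
breakpoint estimate; with it, breakpoints land within a few bp of truth at
1% divergence. Mismatches consumed by refinement are recorded as
substitution columns (they are real SNPs near breakpoints).

**Filtering.** A placement candidate passes at weighted identity ≥ 0.90
and query coverage ≥ 0.80, coverage being the union of query intervals
over all blocks of the candidate — a split contig spanning a large indel
keeps full coverage credit. A contig is rejected as non-unique when a
second candidate at a *distinct locus* scores within 5% of the best;
shifted self-alignments inside a tandem repeat overlap the same reference
span (≥ 50% of the shorter) and are deliberately not read as ambiguity.
Accepted candidates are tiled greedily by score so no reference interval
is claimed twice, with 100 bp of slack before a contig is dropped;
residual overlaps are trimmed at pseudomolecule construction. Contigs
under 500 bp are never placed.

## Rescue anchoring

BES reads are mapped with the same engine; contig-side hits are kept at
≥ 90% identity and ≥ 95% coverage, reference-side at ≥ 90%/90%, only
uniquely aligned reads are used, and reference-side pairs must map at
< 300 kb separation. Two rescue rules place alignment-orphaned contigs:

- **Rule (i)** — the contig carries a unique BES whose own unique
  reference hit falls in a region no aligned contig claims: place the
  contig at that hit, oriented by the BES strands. These placements claim
  precise reference intervals, so contested regions go to the rescue with
  more BES support.
- **Rule (ii)** — the contig carries one end of a clone whose mate lies on
  an already placed contig: place it at the mate's reference position
  offset by the clone insert mean (median over supporting clones).
  These coordinates are clone-distance *estimates* (±insert SD plus the
  mate's position within its contig), so several contigs from one inserted
  segment legitimately cluster at one flank; they stack with staggered
  offsets instead of evicting each other, and downstream they receive
  fixed-size "U" gaps in the AGP rather than reference-projected gaps.

Paired-end anchoring places a remaining contig when ≥ 3 uniquely mapped
read-pair links agree on chromosome, a 50 kb position window, and
orientation; a 50/50 orientation split leaves the contig unplaced rather
than guessed. Rescues never displace alignment placements.

## Pseudomolecule construction

Per chromosome, placed contigs are sorted by reference start, minus-strand
contigs reverse-complemented, and joined with gaps of
max(reference-projected distance, 100) N characters (estimated rescues:
fixed 100 N "U" gaps). Overlapping placements are resolved by trimming the
later, lower-score placement's leading bases; a trimmed junction is
emitted gap-free since the two contigs abut by construction. The AGP v2.0
rows are written alongside and reconstruct the FASTA byte-for-byte — an
invariant the test suite asserts on every simulated assembly. Assembly
statistics use the standard N50: the minimum contig length such that
contigs at or above it hold 50% of the total.

## Variant calling from split alignments

SNPs are the substitution columns of accepted one-to-one blocks
(N-containing columns are never counted as matches or SNPs); the aligned
length for frequency computation counts reference columns of those blocks.
Large indels come from inter-block junctions of a single placement:

- **insertion** — query gap ≥ 100 bp, reference gap ≤ 10 bp, both
  flanking blocks ≥ 200 aligned columns; size = query gap; the inserted
  donor sequence is captured from the contig. Contig-terminal unaligned
  tails are never called.
- **deletion** — reference gap in [100, 50,000] bp, query gap ≤ 10 bp,
  same flank rule; size = reference gap.
- junctions with ≥ 100 bp gaps on *both* sides are classified COMPLEX and
  excluded from both counts, keeping the summary's INS/DEL arithmetic
  clean.

The 10 bp "other side" tolerance absorbs residual junction slack after
X-drop refinement; the flank requirement is measured in aligned columns of
the adjacent blocks. Breakpoint validation counts, per breakpoint
expressed in contig coordinates, reads whose alignments cross it (≥ 5
required) and properly paired fragments straddling the whole event (≥ 1
required); calls failing validation are kept but flagged, and regions with
no data at all are flagged NO_DATA. Validation runs on the polished
contigs — the same evidence as validating on the rebuilt pseudomolecule,
one coordinate transformation fewer.

Summaries report per-chromosome SNP and indel counts, totals, SNP
frequency as a percentage with two decimals (total SNPs / aligned bp ×
100) and mean indel length as integer bp (indel nucleotides / indel
sites). The same arithmetic functions back the fixture verifier, so the
packaged per-chromosome tables reproduce the published totals (2,787,250
and 2,216,251 SNPs; 7,393 and 3,780 indel sites), frequencies (1.00%,
0.86%) and mean lengths (1999 bp, 735 bp) exactly. Two printed values are
internally inconsistent in the source tables and are reported
informationally rather than as exact targets: the mapped-row mean length
(printed 7847; total/count gives 7846) and the total contig count
(mapped + unmapped rows sum to 51,758 against a printed assembly total of
51,550, although the total length reconciles to 330.55 Mb).

## Gene-level analysis

Exon coverage intersects each model's exons with the union of
reference-aligned block intervals (two-pointer sweep over merged
intervals; the test suite checks it against per-base bitmap counting). A
gene is called absent below 5% exon coverage; multi-transcript genes
reduce to the best-covered transcript by default, with a per-transcript
mode exposed since the reduction convention is a genuine open choice.

SNP effects are classified positionally (intergenic / intron / UTRs) and,
inside CDS, by in-frame translation on the coding strand using an
explicit standard-code table (kept separate from the translation library
the tests use as an oracle). Splice-site means a change within the first
or last 2 intron bases (the GT..AG motif). Nonsense and splice-site
changes are flagged harmful. A SNP hitting several transcripts takes the
most severe category. Start-loss and stop-loss are classified but not
flagged harmful, matching the definition under test (premature stops and
splice motif changes).

Transcript uniqueness: mapped at best-alignment identity ≥ 0.90 and
coverage ≥ 0.70; unmapped otherwise; unmapped with best coverage < 0.50 is
donor-unique. Transcript alignment splits blocks at reference gaps > 60 bp
so introns (≥ ~67 bp in the rice annotation that motivates the setting)
delimit exon blocks instead of being charged as gap columns.

## Unique mapping rate

A read counts as uniquely mapped when its primary alignment is mapped
with MAPQ ≥ 20 and no secondary or supplementary record exists for it;
mates are classified independently; unique + multi + unmapped partitions
the total (asserted on every report). The bundled read mapper seeds and
chains each read, reports MAPQ 60 when the best chain covers ≥ 90% of the
read in exact anchors and the runner-up locus scores < 95% of it, and
emits the runner-up as a secondary record otherwise — enough selectivity
that donor reads map at ~100% against the donor and in the 70s (%) against
a 1%-divergent reference with planted indels, reproducing the directional
contrast that motivates using a within-group reference.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed from
the observed inter-cultivar statistics:

| parameter | default | basis |
|---|---|---|
| snp_rate | 0.01 /bp | observed 1.00% SNP frequency between the cultivar pair |
| large_del_rate | 1.8e-5 /bp | 5,026 deletions over 278.75 Mb aligned |
| large_ins_rate | 0.85e-5 /bp | 2,367 insertions over the same length |
| deletion sizes | 0.55·N(4 kb, 0.5 kb) + 0.30·N(12.5 kb, 1 kb) + 0.15·lognormal(7, 1), truncated [100, 50,000] bp | the bimodal size distribution with modes at 4 kb and 12–13 kb; mixture weights are this package's choice |
| insertion sizes | lognormal(6.0, 0.8) truncated [100, 5,000] bp | mean ≈ 550 bp, matching 1.29 Mb over 2,367 insertions |
| repeat_fraction | 0.585 | fraction of large-deletion nucleotides classified repetitive |
| repeat_divergence | 0.10 | copy-to-copy substitution divergence within a tandem tract |
| small_indel_rate | 1e-4 /bp, sizes 1–50 bp | unreported; a realistic small-indel background |
| contig_n50 | 20 kb | the draft-assembly regime (observed mapped N50 13.7 kb; 20 kb keeps most contigs informatively long) |
| read_length / depth / insert | 100 bp / 30× / 350 ± 35 bp | short-read library geometry of the study era |
| bes_insert | 100 ± 10 kb, 500 bp end reads | BAC clone geometry (< 300 kb mate rule) |
| base qualities | Q35 correct, Q15 injected errors | makes the Q30 polish rule exercisable deterministically |

Repeat-tagged deletions remove exactly the tandem-repeat tracts the
reference generator planted (sized from the deletion mixture), so deleted
bases are genuinely repetitive; repeat-tagged insertions insert fresh
tandem tracts. Copies within a tract carry 10% substitution divergence —
real repeat families are similar, not identical, and perfect copies would
make every window of a tract exactly ambiguous, which both mismodels the
biology and makes clone-end rescue of inserted contigs structurally
impossible. Event positions are drawn by rejection sampling with a 600 bp
separation margin and a 100× retry cap; collisions beyond the cap fail
loudly. Contigs are sheared with exponential lengths (mean N50/1.678, the
length-weighted-median relation), so the empirical N50 lands within 20% of
target at realistic scales; sub-500 bp fragments are emitted for the
length filter to remove. Reads are uniform over each chromosome, which
implies a coverage ramp over the first and last ~insert length of every
chromosome — errors planted there sit below the polish depth floor, a
property of uniform sampling, not of the correction rule. Gene models are
installed into a copy of the reference (random sequence cannot carry valid
ORFs): multi-exon, UTR-flanked, ATG-to-stop CDS without internal stops,
GT..AG introns of 80–400 bp, both strands, non-overlapping.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: nested or truncated transposon structure and
target-site duplications (repeat tracts are uniform tandem arrays),
segmental duplication and paralogy (each repeat unit is unique to its
event, so cross-locus ambiguity is rarer than in a real genome),
heterozygosity (the donor is a single haplotype), GC- or
chromatin-dependent coverage bias, sequencing error profiles beyond
uniform substitutions, RNA-Seq evidence, and genuine misassembly of input
contigs (shear fragments are always colinear with the donor).

## Benchmark scenario sizes

The recovery benchmarks (shared by the acceptance tests and
`scripts/acceptance.py`) use problem sizes chosen as the smallest at which
the measured quantities are stable: SNP recovery on one 2 Mb chromosome at
default divergence (~18,000 planted SNPs); large-indel recovery on 2 × 3 Mb
chromosomes with deletion/insertion rates raised to 4e-5 and 1.2e-5 per bp
so ≥ 200 deletions and ≥ 50 insertions are planted in 6 Mb (per-event
recovery behavior is rate-independent; the counts are what the histogram
and recall need); polishing on a 300 kb donor at 30× with 0.1% planted
contig errors (~300 errors); BES rescue on 1.5 Mb with contig N50 5 kb,
8–25 kb insertions and 2,500 clones of 100 kb, so that a useful number of
whole contigs fall inside insertions and nearly every such contig carries
a clone end. A rescue counts as correct when the placed midpoint lies
within 3 clone-insert lengths of the true insertion flank — the precision
rule-(ii) geometry supports.

## Known limitations

- Alignment-terminal contig tails are left unaligned (no semi-global
  terminal extension); coverage and SNP recall lose a few tens of bp per
  contig end, immaterial at the thresholds used but visible in per-contig
  coverage near 1.0.
- Insertions longer than ~20% of their host contig push query coverage
  below the 0.80 acceptance floor and the contig goes unplaced — the
  method's intrinsic blind spot for large insertions relative to contig
  size, shared with the thresholded-coverage design it implements.
- The chain DP is O(n²) per contig×chromosome×strand group; extremely
  repeat-dense contigs are bounded by the k-mer occurrence cap rather
  than by an optimized chaining structure.
- `polish` trusts the provided SAM (no duplicate marking or indel
  realignment of its own), and static-SAM multi-round polishing is exact
  only for substitution corrections.
- The COMPLEX indel category (both-side gaps) is excluded from INS/DEL
  summaries by design; on simulated data without complex events this is a
  no-op, on real data those junctions would need manual review.
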