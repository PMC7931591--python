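# Methods

## Coordinate and annotation model

All gene structures live in a single convention: 0-based, half-open,
CDS-forward coordinates. GenBank (1-based inclusive, possibly
minus-strand `join(...)`) and GFF3 are converted at read time; after
that no code sees a strand. An intron is located by its `cds_offset`,
the number of coding nucleotides 5′ of it (signal-peptide exons
included), and its phase is `cds_offset mod 3` — 0, 1 or 2 for an intron
falling before the first, after the first, or after the second
nucleotide of a codon. Functional-unit (FU) spans are recorded exactly
as annotated; they may split codons.

**Linker-intron detection.** An intron is a linker intron iff it is
phase 1 and lies within ±6 nt (two codons) of the boundary between two
consecutive FUs (the signal peptide does not participate). The slack is
needed because annotation conventions for where an FU "ends" vary by a
few codons. If several phase-1 introns fall in one window, the one
nearest the downstream FU start wins and the rest stay internal; a
non-phase-1 intron in the window is classified internal with a warning,
never silently accepted as linker. Introns inside the signal-peptide
region count as internal.

**Medians** are the lower middle element for even-sized samples, so all
reported exon-size medians are actual observed lengths.

## Spliced inference

The reconstruction of an architecture from (cDNA, genomic) is a
deterministic seed-and-chain spliced alignment: exact k-mer matches
(k = 20 by default) are merged into maximal exact blocks per diagonal,
and a sparse dynamic program selects the colinear chain maximizing cDNA
coverage, where any diagonal jump is an intron and must fall within
[`min_intron_len` = 30, `max_intron_len` = 50 000] nt. The default
minimum is deliberately far below realistic intron sizes (the shortest
introns reported for these genes are ~118 bp) so that true short introns
are never force-merged; it exists to stop two exons from being bridged
across a trivial gap.

At each junction the split point can slide wherever cDNA and genomic
sequence agree on both sides. Within that window the boundary is chosen
by (1) boundary class — GT..AG first, then GC..AG (flagged `gc_ag`) when
`allow_gc_ag`, else `noncanonical`; (2) a fixed donor/acceptor consensus
score (donor GTAAG weighted 3/3/1/1/1, acceptor YAG weighted 1/3/3) to
break ties between equally canonical placements; (3) the leftmost donor.
Exon content is reported in cDNA coordinates, so for complete inferences
the concatenated exons equal the cDNA *by construction* — genomic slices
are used only for boundaries and confidence. Genomic N runs act as
wildcards during extension; exons overlapping them are flagged
`low_confidence` with a reduced per-exon confidence score. A cDNA
interval that cannot be placed produces an explicit gap record and an
incomplete result, never a silent truncation.

## FU overlay

FU peptides are translated from the first full codon of each span (a
mid-codon FU start moves to the next codon boundary; the offset is kept
so projections stay consistent). The overlay alignment is a
deterministic star alignment: rows sorted by (gene, FU), the first row
is the reference, every other row is globally aligned to it (Biopython
PairwiseAligner, BLOSUM62, gap open −11 / extend −1) and merged on
reference coordinates. An externally supplied aligned FASTA can replace
the built-in aligner. A splice site maps to (column of the hosting
codon, phase): `residue = floor((cds_offset − fu_codon_start)/3)`, then
the row's residue→column map. "Identical position" is operationalized as
*same column and same phase*; a ±1-column tolerance mode exists but is
off by default — intron sliding should be reported, not merged away.

Positions with introns from ≥ 2 distinct FUs or ≥ 2 lineages are
*multiple*; a position shared at the same FU by ≥ 2 lineages is flagged
*ortholog*. Fractions are computed over placements by default (a
`count="groups"` switch reports per-position fractions instead), over
one representative architecture per lineage (per-gene counting is a
flag), and linker introns are excluded throughout.

## Gain/loss parsimony

Each presence/absence pattern over (lineage, FU) is scored per FU by
binary-state Sankoff dynamic programming on the rooted lineage tree,
with a *stem branch* above the root representing the segment between the
completed multi-FU ancestor and the radiation. The two scenarios fix the
state at the top of the stem:

- **ancestral_gain** — stem-top *present* for every FU, gains prohibited
  (gain cost ∞), and exactly one gain (the origin in the mono-domain
  precursor) added to the tally regardless of FU count. Losses placed on
  the stem set the radiation-root state, which is how "lost in a common
  ancestor" is counted once.
- **free_gains** — stem-top *absent*, gains and losses both cost 1.

`missing` leaf states (an FU that does not exist in a lineage, e.g. FU-h
in cephalopods) are unconstrained. Costs are configurable (gain cost ∞
with free root state recovers classic Dollo parsimony). Backtracking
prefers the parent's state on ties; co-optimal labelings can differ in
their gain/loss split, so the invariant checked against the exhaustive
enumeration oracle is the *total* event count, while the emitted
per-branch event list is separately verified to reproduce the leaf
pattern. `compare_scenarios` reports both totals and flags the smaller
(ties reported as ties). The FU-b/f/g worked example evaluates to 12
events (1 gain + 5 stem losses + 3 × 2 lineage losses) versus 3 gains.

## Splice motifs

Boundary contexts are the 5-nt windows on each side of both splice
sites, clipped (and flagged) at sequence ends. Dinucleotide classes use
the first/last two intronic nucleotides; contexts with N in a decisive
position leave the denominator. Position-frequency matrices have 10
columns (5 exonic + 5 intronic for donors, mirrored for acceptors) with
per-column denominators (N excluded column-wise, not context-wise);
information content is 2 − Shannon entropy in bits. The proto-splice
site AG|G means: upstream exon ends in AG *and* downstream exon begins
with G. The multiple-vs-unique comparison uses a two-sided Fisher exact
test on the 2×2 (position class × AG|G) table; Fisher was chosen because
the strata are small and the test is exact.

## Ortholog exon-count comparison

The 5% protein-length filter is relative to the longer protein and
inclusive at the boundary ("not more than 5%" keeps exactly 5%). Within
a paralog group, pairs with identical exon counts collapse to one
representative (first by sorted gene id). Quantiles of |Δ exon count|
are over pairs (a switch exists for genes). The hemocyanin comparison
restricts both architectures to the [FU-a start, FU-g end] slice and
counts introns-in-slice + 1 exons, making genes with and without FU-h
comparable.

## The synthetic-data generator

The simulator emulates the system under study: a CDS of signal peptide
(20 codons, ATG first) plus `fu_count` = 8 FUs of `fu_len_codons` = 150
random non-stop codons each, ending in a stop. The eight FUs derive from
one ancestral FU by per-copy substitutions (`fu_divergence` = 0.15 per
site, stops avoided) applied once at setup — the tandem-duplication
history — and are then frozen: no along-tree substitution model and no
exonic indels, so homology labels remain exact and FU peptides align
ungapped. Linker introns (phase 1, at each inter-FU boundary) are
present at the root and immortal by default. Internal-intron gains are
Poisson(`gain_rate` × branch length) per FU at uniformly sampled coding
offsets inside the FU (≥ `min_gain_spacing` = 30 nt from existing
introns and FU edges, so no unrealistically short exon arises); a gain
offset with exonic context AG|G is up-weighted by
`proto_site_preference` ≥ 1. Losses remove an existing internal intron
with probability 1 − exp(−`loss_rate` × t). Intron sequences are drawn
once per gain event (shared by all descendants): GT donor with
probability `canonical_prob` = 0.993, else GC; AG acceptor; lognormal
length (meanlog 5.9, sdlog 0.7, resampled below `intron_min_len` = 118),
consistent with reported intron-length ranges for these genes
(minimum 118 bp, mean ~531 bp). After drawing, terminal interior bases
are resampled until no alternative shift within ±12 nt both preserves
the cDNA and looks canonical — emitted gene structures are therefore
unambiguous for a spliced aligner, which is what makes the 100%-recovery
test meaningful rather than luck-dependent.

Default tree: `(Cephalopoda:2,(Vetigastropoda:1,Tectipleura:1):1)` with
a stem of length 1; rates default to `gain_rate` = 1 per FU per unit and
`loss_rate` = 0.1 per intron per unit, which put Tectipleura-path genes
in the tens of internal introns at desk scale. FU length (150 codons vs
~400 in the real proteins) and intron counts are scaled down so a full
family simulates in ~0.1 s; the statistics exercised by the tests
(phases, boundary classes, overlay classes, event counts) are
scale-free.

Two switches support specific experiments: `unique_gain_positions`
forbids two gain events from sharing an FU-relative offset
(operationalizing "position-unique gains" for the overlay-truth check),
and `min_gain_spacing` can be lowered to make repeated gains at the same
position common. The proto-splice-site experiment uses the latter: 16
near-independent lineages (tiny internal branches), 40-codon FUs,
`gain_rate` = 6 and spacing 6, so that each replicate carries hundreds of
multiply-hit positions — enough statistical power for a per-replicate
directional comparison of AG|G frequency at repeatedly- versus
once-gained positions. With `proto_site_preference` = 3 the probability
that a position is hit twice scales like the square of its weight, so
multiply-gained positions are AG|G-enriched roughly ninefold over the
base rate.

**What the simulator does not model** — nucleotide substitution along
the tree, selection, exonic indels, splice-site mutation/decay, intron
sequence homology between sites, multi-gene families within a lineage.
Tests passing on this generator therefore certify the *bookkeeping and
inference machinery* (coordinates, phases, classes, alignment
projection, event counting, motif recovery), not robustness to
alignment ambiguity or annotation noise in real genomes; the
low-confidence flags and the external-alignment ingestion path are the
hooks for such data.

## Event-log invariant

Replaying the simulator's event log from the root intron set down the
tree must reproduce every leaf architecture exactly; this is asserted in
the suite and is the ground truth against which overlay grouping and
parsimony tallies are compared.

## Numerical and degenerate-input choices

- Phase fractions are reported raw and rounded to integer percent; the
  rounded values may sum to 99–101.
- `classify_positions` on an empty placement list returns empty groups
  and NaN fractions rather than failing; empty PFM subsets raise with
  the offending filter named.
- The spliced aligner is deterministic for fixed inputs and parameters;
  chain ties break toward fewer introns, then leftmost placement.
- `brute_force_events` refuses trees with more than 8 leaves (its state
  space is exponential); `simulate_family` refuses configurations headed
  past 10 000 introns per gene before doing the work.
- Known limitation: the paper-scale phase split (52/24/24 in real
  Tectipleura hemocyanins) is *not* reproduced by the default generator,
  whose gain offsets are phase-uniform by design; reproducing observed
  phase biases would require a phase- or context-dependent gain model
  that the data here cannot constrain.
- Known limitation: `read_architecture` expects one gene per file;
  multi-gene loci must be split upstream.
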