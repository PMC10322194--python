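# Methods

This note documents the models and procedures implemented in `mitoscribe`,
the parameters that matter, the numerical conventions, and what the
synthetic data do and do not establish.

## Coordinates and sequence conventions

All external files and reports use 1-based inclusive intervals (GenBank
convention). Sequences are uppercase DNA over {A,C,G,T,N}; GC content is
(G+C)/(A+C+G+T) with N excluded from both numerator and denominator. N is
allowed in sequences but never inside an SSR or dispersed-repeat call.
Edited cytidines are written as T (the cDNA equivalent of U). Only the
GenBank location operators `join`, `complement` and plain ranges are
supported; `order()` and fuzzy positions are rejected with a clear error.

## Assembly-graph resolution

A mitochondrial assembly graph collapses each repeated segment into one
node whose read depth is proportional to its copy number. Resolution
proceeds in three steps.

**Copy number.** The baseline is the *length-weighted median* node depth —
the median resists inflation by repeat nodes, which are few and short
relative to unique sequence. A node's multiplicity is round-half-up of
depth/baseline, floored at 1; nodes with multiplicity ≥ 2 are repeat nodes.

**Junction support.** Long reads enter as node paths. For every repeat
node `r`, each read traversal `in → r → out` increments a counter keyed in
`r`'s plus frame, so a reverse-strand traversal counts toward the same
junction. Reads whose path uses a non-existent edge are skipped (and
counted). How reads mapping equally well to several repeat copies were
assigned is inherently ambiguous; counting every observed traversal of the
collapsed node is the one consistent reading and is what the simulator
also emulates.

**Resolution.** Each repeat node is duplicated into multiplicity-many
copies; (in, out) edge pairings are chosen greedily by descending support
(ties broken lexicographically), discarding pairings below `min_support`
(default 2 — the evidence threshold when no number is otherwise
specified; one spanning read could be chimeric, two independent reads
cannot). When the surviving candidates leave exactly one in-end and one
out-end open, the pairing is forced by elimination; any other leftover
raises an unresolved-junction error naming the node. The rewritten graph
must decompose into simple cycles; paths that remain linear are returned
with `circular=false` and fail the completeness audit. Sequences are
spelled by concatenating oriented node sequences, trimming each junction's
overlap once. Total output length therefore equals
Σ multiplicity(n)·len(n) − Σ overlap over used junctions.

**Canonical form.** A circular sequence is reported via its canonical
form: the lexicographically smaller of the least rotations (Booth's
algorithm) of its two strands. This makes outputs comparable across runs
and is how recovered chromosomes are compared with planted truth.

**Completeness audit.** Two principles: all 24 core genes present
somewhere on the paths, and every path circular (fully extended). Gene-less
circular components are retained when their mean node depth is within ±50%
of baseline; an optional caller-supplied homology flag can rescue others —
no database query belongs in the pipeline, so the external best-hit check
is the caller's responsibility.

**Plastid-like nodes.** Nodes whose sequence aligns to the plastome over
≥ 90% of their length at ≥ 95% identity (both configurable) are flagged as
advisory annotations only. They are never removed: genuine mitochondrial
regions of plastid origin are part of the mitogenome.

## Repeats

**SSRs.** A hit is a maximal tandem run of a primitive 1–6 bp motif with
at least 10/5/4/3/3/3 copies (mono- through hexanucleotide). Maximality is
per tandem region: one SSR per region, leftmost phase, counting complete
motif copies only. Primitivity prevents re-reporting a dimer run as a
tetramer run. Runs are split at N. Only perfect (simple) SSRs are
reported; compound-SSR merging is not replicated because per-class counts
of simple SSRs are what the analyses consume. Reported motifs are
canonicalized to the lexicographically least rotation.

**Dispersed repeats.** Chromosomes are concatenated with a 100-N spacer
(so no hit can span two chromosomes — N never matches anything) and
compared against four transforms of themselves: identity (forward),
reverse, complement, and reverse complement (palindromic). Along every
diagonal, a window with j mismatches is *maximal* when each end abuts the
next mismatch or a boundary/N wall. Detection is seed-and-extend: by the
pigeonhole principle any qualifying window (≥ 30 bp, ≤ 3 mismatches)
contains an exact stretch of ≥ ⌈(30−3)/4⌉ = 7 bp, so exact 7-mer seed
matches are extended outward past up to 4 mismatches each way and all
maximal windows for j = 0..3 are enumerated.

Overlapping maximal windows on one diagonal describe a single repeat locus
(the mismatch budget can be split between the two ends many ways), so each
locus is reported once, represented by the window with the fewest
mismatches, then the longest, then the leftmost — a planted exact repeat
is thus reported exactly once with 0 mismatches even when chance flank
matches would admit mismatched extensions. Each unordered pair is stored
once, ordered lexicographically by (record id, start), which makes the
result independent of chromosome input order (tested). Self-identical
interval pairs are dropped. Pairs whose two intervals both lie mostly
(> 50%) within one reported SSR run are dropped as tandem shadows — the
budgeted extension means such shadows can poke a few bases past the run,
so strict containment would be too weak a filter. A reverse-complement
pair whose intervals overlap (an inverted repeat around a center) is
reported once with the two arms as the intervals.

**E-value.** The chance expectation of a pair of length L with ≤ m
mismatches in a search space of N bases under a uniform i.i.d. model:
`E = N² Σ_{j=0..m} C(L,j) 3^j 4^{-L}`, computed in log space (underflow
returns 0). Pairs with E ≥ 10⁻⁵ are removed; N is the genome length
without spacers. This binomial model approximates the repeat-finder
literature's E-value family; counts on real data can deviate slightly from
tools using a different dialect.

## MTPT detection

Local alignment is delegated to NCBI BLAST+ `blastn` (`-task blastn`) with
reward +2, penalty −3, gap open 5, gap extend 2, word size 9,
E-value 10⁻⁵ — the standard permissive nucleotide scheme for cross-genome
organelle homology. Low-complexity masking is off by default: organelle
DNA is AT-rich and masking would hide genuine transfers. HSPs carry the
spelled alignment rows so identity can be independently recomputed column
by column (tested).

HSPs on one mitochondrial record whose mito intervals overlap or abut
within 10 bp are merged into one MTPT regardless of strand. This both
produces discrete transfer events rather than raw HSPs and handles the
plastome inverted repeat: a mitochondrial segment homologous to both IR
copies hits the same mito locus twice (on opposite strands) and collapses
to one MTPT. A helper locates the IR itself as the largest ≥ 1 kb
reverse-complement self-match of the plastome, for reporting. Each MTPT's
length counts every mitochondrial base once (interval union); identity is
that of the best-scoring HSP; bins are 70–80, 80–90, 90–100 % (hits below
70% are binned "<70"). MTPTs are numbered MTPT1..n in mitochondrial
coordinate order. Transferred genes are listed from plastome features
overlapping the MTPT's plastome interval; "complete" requires ≥ 95%
exonic coverage ("complete"/"partial" is otherwise undefined, and 95%
tolerates a trimmed terminal codon without admitting truncated genes).
Genome fractions count plastome bases via interval union, i.e. the
IR-deduplicated locus once.

## RNA-editing effects

Edit-site tables (gene, cds_position, probability) are filtered at
probability ≥ 0.9 at ingestion. `apply_edits` validates every site (C at
the stated position, in range, no duplicates, CDS length divisible by 3 —
partial codons are rejected rather than silently truncated) and writes
C→T. `classify_edits` evaluates each site against the original codon
under the standard genetic code (translation table 1, correct for
land-plant mitochondria; configurable in principle via Biopython tables);
when several accepted sites share a codon the effect is evaluated on the
jointly edited codon and all of them are flagged co-edited. A site creates
a start when codon 1 goes ACG→ATG, and a stop when the edited codon is a
stop and the original was not. The summary reports per-gene counts, the
codon-position distribution, the non-synonymous fraction, and the ranked
amino-acid transition tally; the top-3 share is taken relative to the
non-synonymous events, the standard way these transitions are tabulated.
Predicting edit sites de novo is out of scope — tables come from an
external predictor or the simulator.

## Intron markers

Introns are named `geneiNNN`, NNN being the cumulative spliced-CDS length
upstream of the insertion point; sequences are reported in gene
orientation (reverse-complemented for minus-strand genes). In a
cross-species alignment, a variable locus is a maximal run of
non-conserved columns whose 20 flanking columns on each side are gap-free
in every species (a primer-able anchor; substitutions in the flanks are
tolerated, gaps are not). Locus size is the footprint in alignment
columns; loci under 5 columns are dropped by default (real marker loci run
8–15 bp; single substitutions are not scorable on a gel). A species'
allele is its exact pattern string over the locus columns, so two species
differing only by substitutions still count as distinguishable. The
minimal discriminating set is found by exhaustive subset search in
increasing size with lexicographic tie-breaking — locus counts are small,
so exactness is cheap — and is verified against an independent exhaustive
oracle in tests. In-silico PCR finds all (forward, reverse-complement)
primer site pairs with a configurable mismatch allowance, an exact
3′-terminal base, non-overlapping sites and products ≤ 5 kb; circular
templates are searched across the origin; zero amplicons is a valid
result. Primer thermodynamics are out of scope.

## Synthetic data

The generators emulate the target system at desk scale: 19 circular
chromosomes of 2.5–4 kb (≈ 61 kb total — the structure of the real
537 kb genome at a size where the pure-Python searches stay instant) at
46% GC, next to a 20 kb quadripartite plastome (35% GC) with 1.5 kb IR
arms and planted tRNA/rRNA/PCG annotations. Planted features: SSRs of
every motif length (runs bordered by period-breaking bases so they are
exactly maximal), dispersed repeats of all four classes with 0–2
mismatches (interior, spaced, ends kept exact), and eight plastome
fragments inserted at identities 100/95/85/75 % — two per identity bin,
one copied from inside the IR arm so the plastome carries it twice.
Backgrounds are scrubbed of accidental SSR runs by resampling single
bases (a ~60 kb random sequence would otherwise contain a handful of
chance dimer runs); accidental ≥ 30 bp dispersed pairs are vanishingly
rare at this scale and additionally suppressed by the E-value filter.
MTPT sources are non-overlapping plastome loci so fragments never create
mito–mito repeats.

The graph generator builds chromosomes from unique segments with shared
repeat segments (each assigned to `repeat_multiplicity` chromosomes,
always flanked by unique segments), blunt-joined (overlap 0), node depths
baseline × copy-number with ±10% noise (baseline 30, a typical
organelle short-read depth), and some nodes stored reverse-complemented to
exercise orientation handling. Reads are windows of the true circular
node paths: two systematic tiling passes guarantee every junction is
supported at the default `min_support=2`, plus random reads on either
strand; with zero reads the ledger lists the repeats as
expected-unresolved. Read-level sequencing error is not simulated — paths
are exact or (optionally) corrupted wholesale, which the threader must
skip.

The intron generator plants four indel loci of 14/8/12/15 bp across two
regions. The per-species allele matrix is constructed so that each locus
uniquely separates one species pair — hence all four loci are required
and the minimal-set search must return the full set. The real study's
exact allele patterns are published only as figure images; this
construction preserves its testable claims (four loci, full five-species
discrimination, the nad2i156 pair separating *A. albus* from
*A. paeoniifolius*) while making the minimality property sharp. Background
substitutions (rate 0.005, kept 2 columns clear of planted loci) create
sub-threshold single-column variation.

The edit-table generator plants 676 sites across the 36 genes (24 core +
12 variable) with a realistic land-plant composition: 61 on nad4, 40 on ccmB and
nad7, 1 on rps14, the remainder distributed; transitions 146 Ser→Leu,
145 Pro→Leu, 107 Ser→Phe, 25 synonymous, the start codons of nad1/nad4L
planted as genomic ACG and the stop codons of atp6/ccmFC as CAA/CGA edited
at the last codon; the rest is spread over seven other C→T-editable
transitions. Filler codons contain no C, so decoy rows (probability
< 0.9) and planted sites can never collide. The summary consequently
reproduces 96.3% non-synonymous and a 61.14% top-3 share — these numbers
test the classifier and summarizer against a known composition, not the
external neural predictor, which is out of scope.

Every generator draws from `default_rng([seed, crc32(name)])`, so adding a
generator never perturbs the others and identical configs are
byte-identical (tested).

**What passing these tests shows — and does not.** Recovery of planted
truth demonstrates correctness of the algorithms under clean, in-model
conditions: no assembly artifacts, no read error, substitution-only
divergence for MTPTs (no indels), indel-only marker alleles. Real data add
alignment ambiguity, tool-dialect differences (REPuter/BLAST versions),
and annotation noise; counts there depend on the documented conventions
(unordered pairs counted once, locus-level representatives, IR
deduplication) and may differ from other tools' tallies accordingly.

## Problem sizes

Default scales were chosen so the whole suite and the acceptance script
run in a few minutes on one CPU: 61 kb genome for repeat/MTPT scans,
19-circle graphs with ~50 nodes, 200-sequence oracle-equivalence batches
at 50–120 bp (the exhaustive oracle is cubic-ish in sequence length).
All are configuration, not constants; the same code paths run unchanged on
full-size organelle genomes.This construction makes the minimality property sharp while
exhibiting the headline behaviour: four loci, full five-species
discrimination, and the nad2i156 loci separating *A. albus* from
*A. paeoniifolius*.hods

This note documents the models and procedures implemented in `mitoscribe`,
the parameters that matter, the numerical conventions, and what the
synthetic data do and do not establish.

## Coordinates and sequence conventions

All external files and reports use 1-based inclusive intervals (GenBank
convention). Sequences are uppercase DNA over {A,C,G,T,N}; GC content is
(G+C)/(A+C+G+T) with N excluded from both numerator and denominator. N is
allowed in sequences but never inside an SSR or dispersed-repeat call.
Edited cytidines are written as T (the cDNA equivalent of U). Only the
GenBank location operators `join`, `complement` and plain ranges are
supported; `order()` and fuzzy positions are rejected with a clear error.

## Assembly-graph resolution

A mitochondrial assembly graph collapses each repeated segment into one
node whose read depth is proportional to its copy number. Resolution
proceeds in three steps.

**Copy number.** The baseline is the *length-weighted median* node depth —
the median resists inflation by repeat nodes, which are few and short
relative to unique sequence. A node's multiplicity is round-half-up of
depth/baseline, floored at 1; nodes with multiplicity ≥ 2 are repeat nodes.

**Junction support.** Long reads enter as node paths. For every repeat
node `r`, each read traversal `in → r → out` increments a counter keyed in
`r`'s plus frame, so a reverse-strand traversal counts toward the same
junction. Reads whose path uses a non-existent edge are skipped (and
counted). How reads mapping equally well to several repeat copies were
assigned is inherently ambiguous; counting every observed traversal of the
collapsed node is the one consistent reading and is what the simulator
also emulates.

**Resolution.** Each repeat node is duplicated into multiplicity-many
copies; (in, out) edge pairings are chosen greedily by descending support
(ties broken lexicographically), discarding pairings below `min_support`
(default 2 — the evidence threshold when no number is otherwise
specified; one spanning read could be chimeric, two independent reads
cannot). When the surviving candidates leave exactly one in-end and one
out-end open, the pairing is forced by elimination; any other leftover
raises an unresolved-junction error naming the node. The rewritten graph
must decompose into simple cycles; paths that remain linear are returned
with `circular=false` and fail the completeness audit. Sequences are
spelled by concatenating oriented node sequences, trimming each junction's
overlap once. Total output length therefore equals
Σ multiplicity(n)·len(n) − Σ overlap over used junctions.

**Canonical form.** A circular sequence is reported via its canonical
form: the lexicographically smaller of the least rotations (Booth's
algorithm) of its two strands. This makes outputs comparable across runs
and is how recovered chromosomes are compared with planted truth.

**Completeness audit.** Two principles: all 24 core genes present
somewhere on the paths, and every path circular (fully extended). Gene-less
circular components are retained when their mean node depth is within ±50%
of baseline; an optional caller-supplied homology flag can rescue others —
no database query belongs in the pipeline, so the external best-hit check
is the caller's responsibility.

**Plastid-like nodes.** Nodes whose sequence aligns to the plastome over
≥ 90% of their length at ≥ 95% identity (both configurable) are flagged as
advisory annotations only. They are never removed: genuine mitochondrial
regions of plastid origin are part of the mitogenome.

## Repeats

**SSRs.** A hit is a maximal tandem run of a primitive 1–6 bp motif with
at least 10/5/4/3/3/3 copies (mono- through hexanucleotide). Maximality is
per tandem region: one SSR per region, leftmost phase, counting complete
motif copies only. Primitivity prevents re-reporting a dimer run as a
tetramer run. Runs are split at N. Only perfect (simple) SSRs are
reported; compound-SSR merging is not replicated because per-class counts
of simple SSRs are what the analyses consume. Reported motifs are
canonicalized to the lexicographically least rotation.

**Dispersed repeats.** Chromosomes are concatenated with a 100-N spacer
(so no hit can span two chromosomes — N never matches anything) and
compared against four transforms of themselves: identity (forward),
reverse, complement, and reverse complement (palindromic). Along every
diagonal, a window with j mismatches is *maximal* when each end abuts the
next mismatch or a boundary/N wall. Detection is seed-and-extend: by the
pigeonhole principle any qualifying window (≥ 30 bp, ≤ 3 mismatches)
contains an exact stretch of ≥ ⌈(30−3)/4⌉ = 7 bp, so exact 7-mer seed
matches are extended outward past up to 4 mismatches each way and all
maximal windows for j = 0..3 are enumerated.

Overlapping maximal windows on one diagonal describe a single repeat locus
(the mismatch budget can be split between the two ends many ways), so each
locus is reported once, represented by the window with the fewest
mismatches, then the longest, then the leftmost — a planted exact repeat
is thus reported exactly once with 0 mismatches even when chance flank
matches would admit mismatched extensions. Each unordered pair is stored
once, ordered lexicographically by (record id, start), which makes the
result independent of chromosome input order (tested). Self-identical
interval pairs are dropped. Pairs whose two intervals both lie mostly
(> 50%) within one reported SSR run are dropped as tandem shadows — the
budgeted extension means such shadows can poke a few bases past the run,
so strict containment would be too weak a filter. A reverse-complement
pair whose intervals overlap (an inverted repeat around a center) is
reported once with the two arms as the intervals.

**E-value.** The chance expectation of a pair of length L with ≤ m
mismatches in a search space of N bases under a uniform i.i.d. model:
`E = N² Σ_{j=0..m} C(L,j) 3^j 4^{-L}`, computed in log space (underflow
returns 0). Pairs with E ≥ 10⁻⁵ are removed; N is the genome length
without spacers. This binomial model approximates the repeat-finder
literature's E-value family; counts on real data can deviate slightly from
tools using a different dialect.

## MTPT detection

Local alignment is delegated to NCBI BLAST+ `blastn` (`-task blastn`) with
reward +2, penalty −3, gap open 5, gap extend 2, word size 9,
E-value 10⁻⁵ — the standard permissive nucleotide scheme for cross-genome
organelle homology. Low-complexity masking is off by default: organelle
DNA is AT-rich and masking would hide genuine transfers. HSPs carry the
spelled alignment rows so identity can be independently recomputed column
by column (tested).

HSPs on one mitochondrial record whose mito intervals overlap or abut
within 10 bp are merged into one MTPT regardless of strand. This both
produces discrete transfer events rather than raw HSPs and handles the
plastome inverted repeat: a mitochondrial segment homologous to both IR
copies hits the same mito locus twice (on opposite strands) and collapses
to one MTPT. A helper locates the IR itself as the largest ≥ 1 kb
reverse-complement self-match of the plastome, for reporting. Each MTPT's
length counts every mitochondrial base once (interval union); identity is
that of the best-scoring HSP; bins are 70–80, 80–90, 90–100 % (hits below
70% are binned "<70"). MTPTs are numbered MTPT1..n in mitochondrial
coordinate order. Transferred genes are listed from plastome features
overlapping the MTPT's plastome interval; "complete" requires ≥ 95%
exonic coverage ("complete"/"partial" is otherwise undefined, and 95%
tolerates a trimmed terminal codon without admitting truncated genes).
Genome fractions count plastome bases via interval union, i.e. the
IR-deduplicated locus once.

## RNA-editing effects

Edit-site tables (gene, cds_position, probability) are filtered at
probability ≥ 0.9 at ingestion. `apply_edits` validates every site (C at
the stated position, in range, no duplicates, CDS length divisible by 3 —
partial codons are rejected rather than silently truncated) and writes
C→T. `classify_edits` evaluates each site against the original codon
under the standard genetic code (translation table 1, correct for
land-plant mitochondria; configurable in principle via Biopython tables);
when several accepted sites share a codon the effect is evaluated on the
jointly edited codon and all of them are flagged co-edited. A site creates
a start when codon 1 goes ACG→ATG, and a stop when the edited codon is a
stop and the original was not. The summary reports per-gene counts, the
codon-position distribution, the non-synonymous fraction, and the ranked
amino-acid transition tally; the top-3 share is taken relative to the
non-synonymous events, the standard way these transitions are tabulated.
Predicting edit sites de novo is out of scope — tables come from an
external predictor or the simulator.

## Intron markers

Introns are named `geneiNNN`, NNN being the cumulative spliced-CDS length
upstream of the insertion point; sequences are reported in gene
orientation (reverse-complemented for minus-strand genes). In a
cross-species alignment, a variable locus is a maximal run of
non-conserved columns whose 20 flanking columns on each side are gap-free
in every species (a primer-able anchor; substitutions in the flanks are
tolerated, gaps are not). Locus size is the footprint in alignment
columns; loci under 5 columns are dropped by default (real marker loci run
8–15 bp; single substitutions are not scorable on a gel). A species'
allele is its exact pattern string over the locus columns, so two species
differing only by substitutions still count as distinguishable. The
minimal discriminating set is found by exhaustive subset search in
increasing size with lexicographic tie-breaking — locus counts are small,
so exactness is cheap — and is verified against an independent exhaustive
oracle in tests. In-silico PCR finds all (forward, reverse-complement)
primer site pairs with a configurable mismatch allowance, an exact
3′-terminal base, non-overlapping sites and products ≤ 5 kb; circular
templates are searched across the origin; zero amplicons is a valid
result. Primer thermodynamics are out of scope.

## Synthetic data

The generators emulate the target system at desk scale: 19 circular
chromosomes of 2.5–4 kb (≈ 61 kb total — the structure of the real
537 kb genome at a size where the pure-Python searches stay instant) at
46% GC, next to a 20 kb quadripartite plastome (35% GC) with 1.5 kb IR
arms and planted tRNA/rRNA/PCG annotations. Planted features: SSRs of
every motif length (runs bordered by period-breaking bases so they are
exactly maximal), dispersed repeats of all four classes with 0–2
mismatches (interior, spaced, ends kept exact), and eight plastome
fragments inserted at identities 100/95/85/75 % — two per identity bin,
one copied from inside the IR arm so the plastome carries it twice.
Backgrounds are scrubbed of accidental SSR runs by resampling single
bases (a ~60 kb random sequence would otherwise contain a handful of
chance dimer runs); accidental ≥ 30 bp dispersed pairs are vanishingly
rare at this scale and additionally suppressed by the E-value filter.
MTPT sources are non-overlapping plastome loci so fragments never create
mito–mito repeats.

The graph generator builds chromosomes from unique segments with shared
repeat segments (each assigned to `repeat_multiplicity` chromosomes,
always flanked by unique segments), blunt-joined (overlap 0), node depths
baseline × copy-number with ±10% noise (baseline 30, a typical
organelle short-read depth), and some nodes stored reverse-complemented to
exercise orientation handling. Reads are windows of the true circular
node paths: two systematic tiling passes guarantee every junction is
supported at the default `min_support=2`, plus random reads on either
strand; with zero reads the ledger lists the repeats as
expected-unresolved. Read-level sequencing error is not simulated — paths
are exact or (optionally) corrupted wholesale, which the threader must
skip.

The intron generator plants four indel loci of 14/8/12/15 bp across two
regions. The per-species allele matrix is constructed so that each locus
uniquely separates one species pair — hence all four loci are required
and the minimal-set search must return the full set. The real study's
exact allele patterns are published only as figure images; this
construction preserves its testable claims (four loci, full five-species
discrimination, the nad2i156 pair separating *A. albus* from
*A. paeoniifolius*) while making the minimality property sharp. Background
substitutions (rate 0.005, kept 2 columns clear of planted loci) create
sub-threshold single-column variation.

The edit-table generator plants 676 sites across the 36 genes (24 core +
12 variable) with a realistic land-plant composition: 61 on nad4, 40 on ccmB and
nad7, 1 on rps14, the remainder distributed; transitions 146 Ser→Leu,
145 Pro→Leu, 107 Ser→Phe, 25 synonymous, the start codons of nad1/nad4L
planted as genomic ACG and the stop codons of atp6/ccmFC as CAA/CGA edited
at the last codon; the rest is spread over seven other C→T-editable
transitions. Filler codons contain no C, so decoy rows (probability
< 0.9) and planted sites can never collide. The summary consequently
reproduces 96.3% non-synonymous and a 61.14% top-3 share — these numbers
test the classifier and summarizer against a known composition, not the
external neural predictor, which is out of scope.

Every generator draws from `default_rng([seed, crc32(name)])`, so adding a
generator never perturbs the others and identical configs are
byte-identical (tested).

**What passing these tests shows — and does not.** Recovery of planted
truth demonstrates correctness of the algorithms under clean, in-model
conditions: no assembly artifacts, no read error, substitution-only
divergence for MTPTs (no indels), indel-only marker alleles. Real data add
alignment ambiguity, tool-dialect differences (REPuter/BLAST versions),
and annotation noise; counts there depend on the documented conventions
(unordered pairs counted once, locus-level representatives, IR
deduplication) and may differ from other tools' tallies accordingly.

## Problem sizes

Default scales were chosen so the whole suite and the acceptance script
run in a few minutes on one CPU: 61 kb genome for repeat/MTPT scans,
19-circle graphs with ~50 nodes, 200-sequence oracle-equivalence batches
at 50–120 bp (the exhaustive oracle is cubic-ish in sequence length).
All are configuration, not constants; the same code paths run unchanged on
full-size organelle genomes.
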