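# Methods

## The marker system

The CPD marker is a cephalopod-specific mitochondrial amplicon running from
cytochrome *b* into ND6 across their intergenic spacer. The primer pair is
degenerate — CPDfwd `GAYATYTGNCCYCADGG` (5 degenerate positions, 96-fold)
and CPDrvs `ATTTGYTAYTAYTGTGANGG` (4 degenerate positions, 32-fold) — with
all degeneracy confined to codon third (wobble) positions and a fully
conserved codon at each 3′ terminus, so the polymerase always extends from
an exact match. Across the 36 complete cephalopod mitogenomes the pair was
designed from, predicted products are 465–471 bp, which fits a 2 × 300 bp
paired-end run with a wide (~130 bp) overlap. Nextera adapter prefixes
(33 and 34 nt) put library molecules at 532–538 bp.

## One identity definition

The published procedure mixes BLASTN local identity (assignment),
clustering identity (UCHIME/centroids) and unspecified screening identities.
This package uses a single definition everywhere: global alignment
(edit-distance optimal, via edlib), identity = matching columns / aligned
columns with terminal gap runs excluded, internal gaps counting as
non-match columns. Optimal alignments are not unique, so arguments are
order-canonicalized before aligning; identity and the p/K2P site counts are
then exactly symmetric. One definition keeps every threshold (99.6 %,
99 %, 98 %, 90 %) mutually coherent and testable.

## Distances

p-distance and K2P are computed over columns where both sequences have a
concrete base (pairwise deletion; gaps, N and ambiguity codes excluded).
K2P: `d = −½·ln((1−2P−Q)·√(1−2Q))` with P the transition and Q the
transversion fraction; a non-positive logarithm argument is reported as
saturation, not as zero or infinity. Rank summaries average over all
unordered pairs whose labels differ at the requested rank (between-group
mean); an all-pairs variant exists because published summaries sometimes
include within-group duplicates (their minima of 0 suggest so). Note the
between-family pair set is a subset of the between-genus set — records in
different families are necessarily in different genera — so coarser ranks
summarize fewer pairs.

## Pipeline stages and their parameters

All defaults live in `PipelineConfig`; identities are fractions, lengths in
nucleotides.

* **Quality trimming** (`q_min=20`, `len_min=100`): truncate at the first
  base below Q20, discard mates shorter than 100 nt. Truncation (rather
  than masking or sliding windows) is deterministic and conservative.
* **Merging** (`min_overlap=7`, `merge_min_identity=0.8`): mate 2 is
  reverse-complemented; the overlap maximizing a +1/−1 score with at least
  7 bases and 80 % identity wins. Agreements keep the higher quality;
  disagreements keep the higher-quality base with quality |q1−q2|; ties
  become N (quality 2). Because both mates' error-prone 3′ ends fall inside
  the overlap, merging corrects most sequencing errors.
* **Size/primer screen** (`size_window=(465, 471)`): orientation is
  normalized by locating the forward primer at a 5′ terminus of either
  strand; both termini must match with zero mismatches under IUPAC
  semantics (template N never matches — unknown is not a wildcard), then
  primers are trimmed off. Inserts with more than 2 N are rejected as
  unresolved merge conflicts.
* **Dereplication**: exact-string collapse with per-group counts, ordered
  by total abundance then sequence — all later stages are deterministic.
* **Chimera flagging** (`skew=2.0`, `parent_identity=0.995`): processed in
  abundance order. Candidate parents must be ≥ 2× as abundant as the query
  (chimeras arise late in PCR). A query below the species identity to every
  candidate is flagged when some parent-prefix + parent-suffix
  concatenation reconstructs it at ≥ 99.5 % identity over the whole query.
  Assessing the reconstruction over the whole query, not per segment, is a
  deliberate choice: a fixed per-segment fraction allows zero mismatches on
  any segment shorter than 200 nt, so one sequencing error near the
  breakpoint would defeat the test. Three structural rules keep the
  reference pool clean: flagged chimeras never serve as parents; sequences
  within the 0.996 error radius of an already-flagged, at least equally
  abundant chimera are flagged as its error satellites; and shortlisted
  parents (up to 8) must be mutually below the 98 % clustering identity, so
  error copies of one parent cannot crowd the second parent off the
  shortlist. The species-identity guard means only sequences below 99 % to
  everything abundant can ever be flagged, which keeps false flags on real
  templates at zero.
* **Clustering**: greedy centroid clustering in abundance order — a
  sequence joins the first centroid at or above the cutoff, else founds a
  cluster. Run once at 0.996 (representative selection) and once at 0.98
  (tabulation), always per sample group.
* **Representative haplotypes** (`rep_min_proportion=0.10`): per group,
  clusters holding ≥ 10 % of that group's post-chimera reads qualify; the
  denominator is the group (monthly) library because pooling across groups
  would hide seasonal taxa. Qualifying centroids are deduplicated across
  groups at 0.996, assigned, and numbered "Type k" per assigned taxon in
  descending abundance (the original study's Type numbering is unstated, so
  labels will not reproduce theirs).
* **Assignment**: top hit by identity (ties: longer aligned span, then id).
  ≥ 99 % → species; ≥ 90 % → "<Genus> sp."; below → "unidentified
  <Family>". The published rules leave [98 %, 99 %) undefined ("between 90
  and 98" vs "≥ 99"); identities there are assigned to genus (continuity).
* **Tabulation** (`rep_match_identity=0.98`, `min_contigs=2`): 98 %-cluster
  centroids at ≥ 98 % to a representative take its name, else "others";
  clusters with fewer than 2 reads (contigs = merged reads, the published
  usage) are removed per group first. Percentages are printed to 3
  decimals, matching the published table precision byte for byte.

Every read pair ends in exactly one ledger bucket (discarded / unmerged /
primer-rejected / chimeric / below-min-contigs / tabulated), so the ledger
sums to the input count — an invariant the tests assert on every run.

## The synthetic-data generator

`simulate_references` builds genome-like records: 500 nt random flanks, one
concrete expansion of each primer at the binding sites, and a 428–434 nt
insert evolved from a shared ancestor (genera at half the target 0.12
between-taxon divergence from the ancestor, species at 0.01 within-genus;
substitutions are half transitions, as in mitochondrial markers; insert
lengths sweep the range deterministically so ≥ 7 taxa realize the full
465–471 bp span). The 0.12 default reproduces the magnitude of genus-level
divergence reported for this marker class. Taxonomy nests two genera per
family, two families per order.

`simulate_reads` draws read pairs multinomially (or by largest-remainder
apportionment in "exact" mode, for deterministic end-to-end checks), takes
the first/last 300 bases of the amplicon, assigns Phred values from a
linear decay (37 − 0.03·i ± 2 jitter) and distributes substitution errors
across positions proportionally to the per-base error probability implied
by those qualities — so errors cluster at 3′ ends, as on a real instrument,
and merging corrects most of them. Chimeric pairs (at `chimera_rate`)
splice two proportion-weighted parents at a breakpoint uniform in the
middle half of the amplicon, where template switching leaves a detectable
segment from each parent. Read ids encode nothing; truth lives only in the
returned table.

What the generator does **not** emulate: indels (the primer screen rejects
indel-bearing termini by design and substitutions dominate MiSeq errors),
learned quality/error profiles, PCR-cycle amplification bias, index
hopping, and cross-taxon contamination. Passing tests therefore demonstrate
the pipeline's logic and thresholds, not robustness to every failure mode
of real libraries.

## Problem sizes and numerical choices

The test suite and acceptance script run communities of 10,000 read pairs
over 3-taxon panels (and 36-record panels for design/distance checks) —
large enough that multinomial noise is well below the tolerances being
asserted, small enough for a single CPU. Thresholds are compared with a
1e−9 slack where exact boundary identities (99.0 %, 90.0 %) must land on
the inclusive side. Ties everywhere break deterministically
(lexicographic); all randomness flows from explicit seeds; pipeline output
is bit-reproducible for fixed input and configuration.

## Known limitations

* Identity is end-gap-free global, not BLAST local: assignments against
  references much longer than the query are ill-defined — the reference
  database should hold the marker region, not whole genomes.
* Greedy clustering is input-order dependent by definition; the
  dereplication order makes it deterministic but it is not an optimal
  clustering.
* The chimera model is single-breakpoint/two-parent; multi-breakpoint
  chimeras at realistic rates mostly surface as "others" or fall below the
  two-contig rule rather than being flagged.
* Representative "Type" numbering is abundance-ranked and will not match
  historical labels.
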