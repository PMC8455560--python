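# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one reading was defensible.

## Coordinates and formats

All internal coordinates are 0-based half-open. UCSC-style region
strings are 1-based inclusive and converted on parsing (so
`chr2:113326224-113894862` denotes a 568,639-bp interval). Genomic
output is plain text: BED, bedGraph (4 columns, one record per
informative fragment), FASTA at a fixed 60-column width (making
write∘read byte-identical), FASTQ with constant quality, JASPAR count
matrices, and tab-delimited tables.

## 4C-seq profiling

**Digestion.** Fragment boundaries are placed at every occurrence start
of the primary motif. DpnII cuts `^GATC` (blunt at the motif start), so
each fragment begins with a motif occurrence; `GATC` and `CATG` are
palindromic, so a forward-strand scan covers both strands. Fragments
tile each chromosome exactly. A fragment is *valid* when it contains at
least one secondary-enzyme site (`CATG`) and is at least `min_length`
(default 20 bp) long — the secondary site is required for the
re-circularisation step of the 4C protocol, and very short fragments
cannot be mapped reliably. Validity is monotone: raising `min_length`
never validates a fragment.

**Read counting.** Reads are primer-filtered (prefix match with
`max_mismatch`, default 0, primer trimmed from kept reads; too-short
reads are tallied separately). A trimmed read is assigned to the valid
fragment whose DpnII boundary it matches exactly — both fragment ends
are eligible, the 3′ end being read back on the reverse strand. The
lookup uses a 20-bp boundary-anchored key; reads matching boundaries of
more than one fragment are counted ambiguous and dropped (conservative
and deterministic; no fractional assignment).

**Informative mask.** Excluded from quantification are: invalid
fragments; the viewpoint fragment plus one undigested neighbour per
side ("adjacent undigested fragments" is read as exactly one per side —
a configurable count); every fragment overlapping viewpoint ±
`exclusion_radius` (default 10 kb, the self-ligation zone); and
fragments outside the analysis interval when one is set.

**RPM smoothing.** The value at informative fragment *i* is the mean of
raw counts over a window of `window_width` (default 5, odd) informative
fragments centred on *i*, scaled by 10⁶/total. The window shrinks
symmetrically at the edges (edge handling is not pinned by the
protocol; symmetric shrinkage keeps the estimator unbiased for constant
profiles). The RPM denominator is the total of raw counts on
informative fragments of the profiled region, not the sequencing
library size — this makes profiles comparable after exclusion; a
library-wide denominator would differ only by a constant factor and is
available by normalising counts upstream.

**Subtraction** operates on normalised RPM values (normalise first,
then subtract), positive values meaning gain in the first profile. It
is exactly antisymmetric and exactly zero on self-subtraction.

**ATAC binning.** Both 5′-ends of each sequenced fragment (positions
`start` and `end − 1`) are counted into fixed-width bins (default
10 bp); RPKM_bin = count/(library_size · bin_size) · 10⁹ with
library_size the sum over all bins. RPKM is invariant under uniform
count scaling.

## Orthology detection (BBH)

The built-in local search is seed-and-extend: exact `word_size`-mers
(default 11) seed ungapped X-drop extensions (X = 30) under
match +1 / mismatch −2; both query strands are searched and reported on
the forward frame. E-values follow E = K·m·n·exp(−λS): λ is solved
exactly from the scoring scheme and background
((1/4)e^λ + (3/4)e^{−2λ} = 1 for the defaults, λ ≈ 1.34), while K is an
order-of-magnitude constant (0.35): only the fixed 10⁻⁵ threshold
semantics matter here, not BLAST-calibrated E-values. The engine is a
pluggable callable so an external search tool can be substituted
without touching the BBH logic.

The BBH call: (1) the CRM sequence is searched in the target genome and
all hits under the E-value cap are collected, but only the top-scoring
hit seeds the reciprocal step (deterministic, and the closest reading
of common BBH practice); (2) the target interval of that hit is
extracted together with flanks sized by the unaligned query portions,
then extended by 20 nt per side (applied after flank addition) and
clipped to chromosome bounds; (3) the extract is searched against the
source genome; (4) *detected* iff the genome-wide best reciprocal hit
overlaps the original CRM interval by ≥ 1 bp. Using only the best
reciprocal hit makes a higher-identity paralog elsewhere in the source
a genuine trap — exactly the discriminative behaviour reciprocal
schemes are meant to provide. Searching a CRM against its own source
genome always returns *detected* with overlap equal to the CRM length.

## Alignment trimming and conservation

Column trimming follows the Gblocks parameterisation: columns with gap
fraction > 0.5 are removed, surviving columns are partitioned into
maximal runs of consecutive input columns, and runs shorter than 10 are
removed entirely. The operation is idempotent and returns the map from
kept output columns to input columns.

Windowed conservation mirrors identity-versus-reference plotting: the
window holds 100 reference (non-gap) positions and is clamped at the
sequence edges so it always contains the full window; within its
alignment-column span, columns where the reference carries a gap count
as mismatches. Positions at ≥ 70% identity merge into calls; calls
shorter than `min_call_length` are dropped (default: one window length
— the upstream tool's default is not enumerated, and a call shorter
than the window is not resolvable at that smoothing scale).

Global alignment (used to build desk-scale pairwise alignments where a
whole-locus aligner would be used at genome scale) is affine-gap
Needleman–Wunsch via Biopython's PairwiseAligner with deterministic
first-alignment selection; intended for sequences of at most a few tens
of kb.

## Motif scanning and mutagenesis

A PWM holds base counts per column; frequencies are
(count + pseudocount·background)/(column sum + pseudocount) with
pseudocount 0.1 (a standard choice; the source analysis does not state
one), and scores are log₂ odds against the background (uniform by
default; a genome-derived background is a constructor option).

**Exact p-values.** The null score distribution is built by dynamic
programming over motif columns, merging equal partial sums accumulated
left to right — the same float operations an exhaustive k-mer
enumeration performs, so the two agree bit-for-bit. The attainable-sum
state space is at most 4^L, so this exact route is used for motif
lengths up to 12 (4^12 ≈ 1.7·10⁷ worst case, far fewer in practice
after merging); longer motifs fall back to a discretised-grid DP
(default width 10⁻³ log-odds units). A window is a hit when
P(random background window scores ≥ observed) < 0.01; the scan
evaluates this through the smallest attainable score whose tail
probability clears the cutoff. The p < 0.01 cutoff is applied per
window per strand (whether the original scan tool pooled strands is
unstated; per-strand is the stricter reading and matches the reported
strand-resolved sites). Minus-strand scanning scans the
reverse-complemented sequence with the same matrix, which keeps the
float arithmetic identical on both strands; hits are reported on the
forward frame.

**Overlapping sites** between two motif sets are ≥ 1 bp interval
intersections, strand-agnostic; each overlapping pair spans the union
of its two intervals and overlapping spans merge into maximal regions.

**Conserved columns** are alignment columns where every sequence
carries the same base and none carries a gap (a gap disqualifies: the
strict reading of 100% base-pair conservation).

**Mutagenesis design** is a greedy repair loop. For each outstanding
hit, the highest-information motif column (ties: leftmost) is set to
its lowest-log-odds base (ties: alphabetical), applied as the
complement on the forward frame for minus-strand hits. Two refinements
make the loop terminate on dense, AT-rich or mutually overlapping
sites: (1) among the score-lowering candidate edits in preference
order, the first whose local neighbourhood (the hit ± one motif length)
rescans without creating any *new* hit is chosen, falling back to the
candidate creating the fewest; (2) an offset, once edited, is frozen
for the rest of the plan, which provably rules out the oscillations in
which two overlapping sites keep reverting each other's edits. After
each round the full mutant is rescanned with every matrix on both
strands; the loop ends at zero hits or fails explicitly after
`max_rounds` (default 10) listing the offending hits. An accepted plan
stores the final edits as the diff against the original (so applying
them reproduces the mutant exactly) and embeds a verification report;
plans are accepted only when the verification rescan is clean. The
specific published edits for a construct can alternatively be supplied
by the user and checked with `verify_mutagenesis` alone.

## Expression statistics

Per sample, ΔCq = Cq_target − Cq_reference; ΔΔCq centres ΔCq on the
control group's arithmetic mean (the centring statistic is not stated
upstream; the arithmetic mean is the convention of the 2^−ΔΔCq method);
fold = 2^−ΔΔCq. The group summary reports the fold of the group-mean
ΔΔCq — so the control group's summary fold is exactly 1 — alongside the
SEM of per-sample folds.

The exact two-tailed Mann–Whitney test defines U as the count of
cross-group pair dominances and enumerates all C(n₁+n₂, n₁) rank
assignments (limited to 24 combined observations); the two-tailed
p-value doubles the smaller tail and caps at 1. This tail-doubling
convention reproduces all three p-values the study prints at n = 7 vs 7
(0.000583, 0.011072, 0.017483), which is why it is canonical here. Ties
across groups are an error rather than silently mid-ranked — the exact
null assumes continuous data — and a seeded Monte-Carlo permutation
fallback (add-one-corrected, ½ per tie in U) covers tied or larger
samples.

## Synthetic data: what it does and does not emulate

Generators draw from a single integer seed, split deterministically per
stage, so any stage can be rerun independently and all outputs are
bit-reproducible.

* Genomes are i.i.d. bases at a set GC fraction (default 0.42,
  mammalian-like). At that composition a 4-cutter site occurs roughly
  every 256 bp, giving realistic DpnII fragment-length spacing; real
  genomes' repeat structure, isochores and CpG depletion are not
  modelled.
* CRM families evolve by Jukes–Cantor per-site substitution along a
  rooted newick tree (per-branch transition matrices compose exactly,
  so pairwise divergence is the analytic JC function of path length).
  Indels and rate heterogeneity are not modelled by default, which
  keeps divergence checkable in closed form; BBH flank extraction is
  still exercised because local hits rarely span the full CRM at higher
  divergence.
* 4C reads follow a distance-decaying capture distribution over
  informative fragments, P(fragment) ∝ (1 + |d|)^−α with d the
  midpoint-to-viewpoint distance and α = 1 by default (a power-law
  contact decay with exponent near 1 is the standard shape for
  intra-TAD contact frequency). Reads are primer + 30 bp anchored at a
  fragment boundary (either end); a configurable decoy fraction
  carries a primer mismatching at every position. Ligation-junction
  chimeras, sequencing error and PCR duplicates are not modelled — so
  passing tests demonstrate the correctness of the counting and
  normalisation arithmetic, not robustness to mapping noise.
* Cq tables use target baseline 22 cycles, reference baseline 18,
  Gaussian cycle noise (default SD 0.2, a typical technical-replicate
  spread), group sizes 7 per genotype and a default true fold change of
  0.5 — the sample size and effect magnitude of the motivating
  experiments.
* The Gli-like (`GACCACCCA`) and Hox13-like (`CTAATAAAA`) matrices are
  synthetic consensus-based stand-ins (consensus count 20, off-base 1)
  with the class-typical consensus shapes, not the experimentally
  derived matrices; tests that need an exact published matrix would
  load it from JASPAR format instead.

## Problem sizes

Defaults used by the test suite and pipeline were chosen to keep each
stage's statistical check well-powered at desk scale: digestion oracles
run on 200 × 2 kb genomes; RPM recovery uses one 100 kb genome and 10⁵
reads (rank correlation > 0.9 against true capture probabilities); BBH
recovery uses 600 bp CRMs in 50 kb genomes over 20 replicates per
divergence rate; mutagenesis closure uses 100 × 300 bp sequences with
two planted sites per matrix; exact-test enumeration is C(14,7) = 3,432
assignments.

## Known limitations

* The local search is ungapped; true indel-rich orthologs are detected
  through multiple collinear segments rather than one gapped alignment,
  and detection degrades faster than gapped BLAST would at high
  divergence.
* Exact-match read assignment stands in for alignment: it is the
  correct inverse of the fragment-end read model but cannot absorb
  sequencing errors.
* The exact Mann–Whitney enumerator is limited to 24 combined
  observations by design; beyond that the permutation fallback applies.
* `global_align` materialises the full dynamic-programming matrix and
  is not suitable for chromosome-scale inputs.
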