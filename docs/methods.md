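# Methods

## The model

satlib analyses a single satellite family at a time. Its working model is the
satDNA "library": an ancestral species carries a pool of related monomer
variants; each descendant species amplifies some variants and lets others
decay, while intragenomic homogenization (concerted evolution) keeps copies
within an array similar. Consequences the pipeline is built to measure:

* per-species monomer pools differ mainly in the *relative abundance* of
  shared variants, not only in private mutations;
* a recently amplified, efficiently homogenized family shows low nucleotide
  diversity (π ~ 0.01), a relictual, unhomogenized family high diversity
  (π up to ~0.2);
* haplotypes linked in a minimum spanning tree group by species, except where
  a species retains much of the ancestral variation.

## Simulator (`satsim`)

`simulate_library(n, L, divergence, seed)` draws a uniform root monomer of
length L (default 177 nt) and derives each other haplotype by i.i.d. per-site
substitution at rate `divergence` (substitutions always change the base, so
the root distance is exactly Binomial(L, divergence)). The root doubles as
the family consensus in simulated pipelines.

`amplify_species` draws `total_copies` monomers multinomially from the
library according to normalized amplification weights, then applies per-copy
substitutions (`mutation_rate`) and, with probability `indel_rate`, one
1–9 nt indel. `exact_proportions=True` replaces the multinomial draw with
largest-remainder rounding of weights × copies, for experiments that need
exact haplotype counts. Copies keep their true ancestral label for recovery
tests.

`build_tandem_array` concatenates the pool in a seeded shuffled order;
`generate_reads` samples fragment start positions uniformly on the
*circularized* array (real arrays are far longer than simulated ones, so edge
under-coverage would be an artifact), with Gaussian fragment lengths, mate1 =
fragment prefix, mate2 = reverse-complemented suffix, substitution-only read
errors, and constant Q37 qualities. Read indels are deliberately excluded
(substitutions dominate the error mode of the targeted platform, and monomer
indels are injected at the amplification stage instead); qualities only
matter at merge mismatch resolution. All stages are pure functions of their
seed; the pipeline derives stage seeds from one master seed by fixed offsets.

What the simulator does **not** emulate: unequal crossing-over dynamics,
higher-order repeat structure, PCR chimeras, GC/coverage bias, quality decay
along reads. Passing tests therefore demonstrate correctness of the
*analysis* under the library model's statistical structure, not robustness to
every artifact of real libraries.

## Read preparation (`readprep`)

Subsampling is reservoir sampling (uniform without replacement), emitted in
input order. Merging reverse-complements mate2 and scans every overlap length
≥ `min_overlap` (default 20), choosing the overlap with the lowest mismatch
fraction (ties → longest); pairs whose best overlap exceeds
`max_mismatch_frac` (default 0.10) or that carry >10% Ns return a typed
no-merge result. Overlap conflicts resolve to the higher-quality base, ties
to mate1. N never counts as agreement. With fragments shorter than about
read_length + unit the merge is unambiguous; in deep 2×250 data with
fragments ≳ read_length + unit, a locally periodic array can make a
unit-shifted overlap equally mismatch-free — the resulting merged fragment is
still a valid array substring, so monomer content is unaffected.

Homology selection aligns each merged fragment locally (match +1, mismatch
−1, gap open −2, gap extend −1) against the doubled consensus on both
strands; a hit needs identity ≥ 0.70 over ≥ 50 columns (identity =
matches/columns, gaps count as columns). The published workflow names a tool
for this step but no thresholds; these defaults are permissive enough to keep
variants diverged up to π ≈ 0.18 while rejecting random sequence (measured
false-positive rate < 1% on 10,000 random 100-nt queries; in practice ~0).

## Monomer mining (`monomers`)

A merged read is phased onto the consensus and cut at unit origins. Phasing
prefers a **gapless tiling**: the Hamming cost of laying the read on an
infinite tandem of the consensus is computed for every phase r ∈ [0, unit);
the best phase determines all origins at exact unit spacing. A gapless
1-base phase error would misalign the entire read, so this estimate is very
robust. Only when the gapless cost exceeds the optimal (edlib) edit distance
by more than max(4, 2% of read length) — i.e. the read genuinely contains
indels — are origins taken from the minimum-edit alignment path. Boundary
placement for units carrying indels is inherently ambiguous (an indel next to
a unit junction can be assigned to either unit); with substitution-only
variation the gapless path makes extraction exact, which the test suite
checks (100% precision/recall against the simulated pool at zero rates).

Segments must span one full unit within ±10% of the unit length (covering
the printed 166–186 bp monomer range around a 177-bp reference) and reach
identity ≥ 0.60 to the consensus (1 − edit distance / unit scale) — more
permissive than read selection so relictual, diverged units survive. Each
segment is rotated to canonical phase: the rotation minimizing edit distance
to the consensus, ties broken by the lexicographically smallest rotation
string. The string tie-break (rather than smallest rotation offset) makes
canonicalization idempotent and invariant to the input's rotation even when
distinct rotations tie, and reduces to the offset rule whenever tied
rotations are identical strings.

Tallying collapses identical sequences per (species, origin); with the
singleton filter on, Illumina-derived haplotypes seen exactly once are
discarded (sequencing-error suppression) while PCR clones are always kept —
sequenced clones are few and legitimately unique.

In-silico PCR matches degenerate primers under IUPAC semantics (R=A/G,
Y=C/T, N=any) with a mismatch budget, forward sites on the plus strand and
reverse sites as the reverse-complemented reverse primer; on a tandem array
the products form the expected unit-spaced ladder. Primer thermodynamics are
out of scope.

## Diversity statistics (`popstats`)

Haplotype diversity uses Nei's unbiased estimator Hd = n/(n−1)(1 − Σ pᵢ²),
which reproduces the printed two-decimal values for every (N, Hap)
configuration in the clone tables (the biased form does not). One printed
value, 0.66 for counts (2,1), appears truncated — the estimator gives
2/3 = 0.67 at two decimals.

Nucleotide diversity is computed per pair and weighted by haplotype counts:
π = Σ_{i<j} nᵢnⱼ (dᵢⱼ/Lᵢⱼ) / C(n,2). Under the default `gap_as_event` policy
("considering indels") each maximal run of columns gapped in exactly one of
the two rows counts as one difference and one compared site; under
`complete_deletion` every column containing any gap is dropped first. The
per-pair normalization is used because a single global effective length is
ill-defined when pairs share different numbers of comparable sites (indels,
Ns); the two coincide whenever compared lengths are equal, and the
implementation is verified against a literal all-pairs expansion. Ns are
treated as missing (columns compared only where both symbols are bases).
Exact DnaSP multi-residue-indel behaviour is version-dependent, hence both
policies are exposed.

Monomer alignment is an anchored star alignment: each sequence is
pairwise-aligned (edit distance) to a common anchor — the consensus when
available, else the longest input — and gap patterns are merged, insertions
left-justified. This is adequate for monomers that are all small
perturbations of one repeat unit and guarantees that removing gaps recovers
the inputs; it is not a general progressive MSA and will be poor for
sequence sets without a common template.

Logo matrices report count-weighted per-column base frequencies, Shannon
entropy H of the non-gap distribution and information content R = 2 − H
(bits), without small-sample correction; all-gap columns are emitted as
missing.

## Haplotype network (`hapnet`)

Clustering is greedy and incremental in CD-HIT order (abundance desc, length
desc, sequence): a sequence joins the first representative with global
identity ≥ threshold (default 0.99, matches/alignment columns), else founds
a cluster; abundance is summed over members. At threshold 1.0 this is exact
deduplication.

Distances between representatives are substitutions (both symbols bases)
plus single-row gap-run events over a common alignment. The MST is Kruskal
with deterministic tie-breaking (weight, then lexicographic node pair) — the
published tree is not unique under ties, so reproducibility takes precedence
over matching any particular tool's internal order. Edges of weight k are
expanded through k−1 step nodes so drawn edges are single mutational steps;
node attributes carry species, origin (Illumina circles vs PCR squares in
the classic display) and abundance. A same-sequence haplotype found in both
Illumina and PCR data is displayed as one Illumina node with summed
abundance. `species_coherence_test` permutes species labels across haplotype
nodes (999 shuffles by default) to test whether same-species edges are
over-represented.

## Pipeline (`pipeline` / CLI)

`run_pipeline` executes simulate/load → subsample → merge → select → mine →
tally → per-species stats/logos → cluster → MST, writes a report bundle
(TSV tables, GML tree, funnel counts, run log) and serializes the full config
for provenance. Stage failures abort with the stage name; funnel counts are
monotone non-increasing along the read funnel. The CLI (`satlib`) is a thin
wrapper exposing each stage and the full run; exit codes are 0 (success),
2 (config error), 3 (data error), 4 (internal error). The subsample default
is 5,000,000 pairs, matching the published workflow's stated subsampling;
desk-scale simulations simply fall below it.

## Problem sizes and numerical choices

Tests and examples run at desk scale by design: libraries of 3–12 haplotypes,
60–200 copies per species, 150–1500 read pairs (2×250, fragment 400±25, which
gives every merged fragment at least one full unit and ~20–40× monomer
coverage). These sizes make all statistical checks (binomial/chi-square
sampling checks, π ordering across mutation rates, Hd recovery within ±0.05
of the closed form) comfortably powered while keeping the full suite under a
few minutes on one CPU. Reported Hd/π are rounded to 4 decimals in TSV
output only; full precision is kept internally.

## Known limitations

* Unit-boundary assignment is ambiguous for monomers with indels adjacent to
  junctions; a small number of shifted variants can appear in indel-rich
  simulations (and presumably real data).
* The star alignment assumes a common template; deep structural variation
  between monomers would need a full MSA tool.
* Homology selection identity is computed from the single best-scoring local
  alignment; co-optimal alignments with different identities are possible in
  principle.
* The cluster-count reductions and tree of the original genome-scale study
  depend on its SRA read sets and are not reproduced here; the pipeline's
  correctness is instead established by oracle-backed properties and
  simulated ground truth.
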