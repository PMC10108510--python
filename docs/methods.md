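# Methods

This note documents the models and procedures implemented in `gtbkit`, the
defaults they use, the numerical and design choices that were genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Genotype codec

A diploid genotype `a|b` (allele indices, reference = 0) of a variant with
n_v ∈ [2, 15] alleles is encoded to one byte by the quadratic pairing
`(a+1)² − b` when `a ≥ b`, else `b² + a + 1`; code 0 means missing. The
pairing is injective over all 15×15 ordered pairs (verified exhaustively in
the tests) and its largest value, for 14|0, is 225 — comfortably one byte.
Encoding and decoding go through precomputed forward/backward tables built
once per process.

Conventions, chosen where the encoding alone does not force them:

- **Unphased storage.** Unphased genotypes are folded to `min|max` before
  encoding, so unphased biallelic codes occupy {0..3} and pack four to a
  byte. Phase is a file-level flag, not per-genotype data; a round trip of
  unphased data therefore returns `1/0` as `0/1`, which is the same
  genotype under unphased semantics.
- **Haploid calls** are doubled to `a|a` internally; the contig's declared
  ploidy (not the data) decides whether a single allele is emitted on
  output.
- **Partial missing** (`./1`) is treated as fully missing, because the
  encoding defines no half-missing code.

Biallelic packing uses base 5 (3 codes/byte, phased) or base 4
(4 codes/byte, unphased); incomplete trailing groups repeat the previous
code, and decoders ignore everything past the subject count, so padding
can never alter decoded genotypes.

## Blocks, AMDO, boundary model

Block capacity is the largest power of two 2ⁿ (7 ≤ n ≤ 14) with
2ⁿ·M ≤ 2³¹ − 2 genotype codes; this caps per-worker decoded memory at one
block regardless of cohort size and fails explicitly beyond 16,777,215
subjects (the 3-byte subject-count ceiling of the container).

AMDO summarizes each variant by `s` windowed features of its per-subject
reference-allele counts: window i accumulates `Σ_j Σ_{k≤j} c_k`, i.e.
weights count `c_k` by its distance to the window end. `s = 24` by default
(configurable); the window width is ⌈N/s⌉ with trailing empty windows
zero. Missing genotypes contribute 0 to the counts — they carry no
reference allele, and this keeps the feature well-defined without
imputation. Biallelic variants are sorted so lexicographically larger
feature vectors come first; multiallelic variants follow as a second group
with the inverted comparator. Ties keep input order (stable sort) so
builds are deterministic. Keeping the biallelic group first is required by
the pointer arithmetic of the addressing algorithm, which indexes
fixed-width biallelic rows before variable multiallelic ones.

One printed worked example of the accumulation is internally inconsistent
with the formula it illustrates (the mirrored vector [2,1,1,0] yields 13,
not 9, under the double sum); the formula as defined is implemented and
only the consistent value (7 for [0,1,1,2]) is asserted.

The compression boundary model E_s = max{α·s, β} upper-bounds a
compressor's output for buffer pre-allocation. Shipped constants: ZSTD
max{1.0014·s, 7168}, LZMA max{1.0167·s, 7680}, GZIP max{1.0031·s, 7680}.
`calibrate_boundary` re-fits (α, β) on random trial inputs by grid search
— β on 512, 1024, 1536, …, α on 1.0000..1.1000 in steps of 0.0001 (the α
grid is this package's choice) — minimizing the infeasibility indicator
plus α + β/10 MiB subject to the bound dominating every trial.

## Container layout

Big-endian throughout (documented for interoperability; no binary
compatibility with other GTB producers is claimed). Magic byte 0 packs
compression level (bits 7–5), ordered flag (4), phased flag (3) and
compressor id (2–0: 0 ZSTD, 1 LZMA, 2 GZIP); byte 1 packs a
max-decompressed-block-size class (bits 4–3, {8,16,32,64} MB) and
log₂(variant cap) − 7 (bits 2–0). Meta and subject sections are 4-byte
length-prefixed UTF-8; subjects are tab-joined; contig declarations
(label, ploidy, length — at most 256 entries, 1-byte chromosome index)
are embedded in the meta as `##contig=` lines so files are
self-describing. Each block entity is B̂1‖B̂2‖B̂3 with an optional
length-prefixed variant-ID stream flagged in the block magic; the
trailing index holds exactly 25 bytes per block. The ordered flag is
computed from the abstract records after the last block is written
(non-overlap of per-chromosome ranges), never assumed from the input.

Writers stream: five placeholder bytes are written first and back-patched
with the final block count and ordered flag, so a build needs no second
pass over the data.

## Build pipeline

Inputs are parsed with cyvcf2; chunking splits the decompressed text into
byte-even, record-aligned ranges, and the pipeline parallelizes at block
granularity (a producer parses, workers encode/AMDO/compress, the
cyclic-locking executor writes blocks in order), which keeps multi-thread
builds byte-deterministic. Blocks never span chromosomes, input files, or
the capacity limit. With multiple input files the largest-sample file
defines the subject order; other files' columns are matched by name,
absent subjects become missing, and subjects unknown to the major file are
an error rather than silently dropped. Duplicate (chrom, pos, alleles)
records are kept as separate variants. A compressed stream overflowing
its record field triggers a split-and-retry of the batch.

QC is a pluggable hook with three built-in, default-off rules (genotype
GQ/DP thresholds that set failing genotypes to missing; a variant
missing-rate cap that drops the variant). Rules whose FORMAT field is
absent disable themselves.

Within a block the on-disk variant order is the AMDO order; extraction
emits a block's variants in stable position order. A coordinate-sorted
input with unique positions therefore round-trips in input order; inputs
with duplicate positions round-trip as the same record multiset.

## Queries

Region queries walk the per-chromosome index (nodes sorted by coordinate
bounds), collect every block whose range intersects the query — overlaps
included, so unsorted files work — and verify candidates against the
decompressed position stream only. Multi-region extractions visit each
block once, in file order. Subject extraction decodes exactly the
requested columns via the pointer arithmetic above. Allele frequency is
alternative-allele count over called alleles (missing excluded); for
multiallelic variants the default aggregates all alternative alleles, and
a per-allele mode is available. Variants with zero called alleles are
excluded from AF filters with a warning. Output is VCF text or BGZF
(via pysam) with a GT-only FORMAT; coordinates are 1-based inclusive.
B̂1 is decompressed whole per block before addressing; sub-range
decompression of the genotype stream is not attempted.

## Management

Sorting builds a per-chromosome two-level index table (position, source
node, within-block index) from position streams only, sorts it (ties keep
source order — deterministic and required for the decompression bound),
re-blocks consecutive variants, and pulls rows grouped by source node so
each old block is decompressed at most once per new block (instrumented;
the tests assert the exact count). Concat and split byte-copy entities
and re-offset records; they require identical subject lists, compressor,
phase and contig. Merge pops the two lightest files (weight = subject
count) from a min-heap until one remains; variants match on (chromosome,
position, unordered allele set) with allele-index remapping when label
order differs; union mode fills unmatched records with missing genotypes.
The merged subject order is heap-pop order (lighter cohorts first).

Three consistency checks flag label problems between batches: |ΔAF| < 0.1
(configurable; useful when the minor allele frequency is well below 0.5),
a Pearson chi-square on the 2×2 ref/alt count table (no continuity
correction, α = 0.05 — the test statistic is prescribed, the significance
level is this package's default), and an LD-sign check that collects
nearby variants with |r| > 0.8 in both batches and votes: a majority of
shared partners changing correlation sign means "flip". "Nearby" defaults
to the same decoded window; the majority rule operationalizes "very
different sign counts", which is otherwise unspecified.

## Ordered parallelism

The cyclic locking model is implemented as an ordering contract — result i
may be emitted only after result i−1 — rather than a mandated lock-ring
primitive; a bounded-window thread pool with an in-order drain satisfies
it, and the determinism suite is the arbiter. The timing formula (see
README) was checked against an independent discrete-event simulation of
the literal lock ring and agrees exactly on the whole grid k ≤ 50,
n ≤ 8 for all tested (t_o, t_p) combinations, including degenerate zero
times. The planner's thread-switch cost t_ε defaults to 0; the efficient
thread set {1, …, ⌈t_p/t_o⌉+1} always reaches 2, since overlapping one
task's processing with the predecessor's write is free.

## Synthetic data

The generator emulates cohort genotypes by sampling each subject's
haplotypes from T template haplotypes with per-site mutation noise —
producing the haplotype-sharing redundancy (LD) that AMDO and the block
compressor exploit — plus configurable allele-count distribution,
missingness, haploid contigs, and coordinate disorder (a displaced-record
fraction). Defaults: 100 subjects, 1000 variants, 10 templates, 1%
mutation noise, 1% missingness, 90/7/3% bi/tri/quad-allelic, sorted
output. It does **not** model recombination hotspots, realistic
allele-frequency spectra, genotyping-error structure, or INFO/FORMAT
metadata; passing tests demonstrate format and algorithm correctness on
LD-structured matrices, not compression ratios on real cohorts.

Test and acceptance problem sizes (hundreds of subjects, hundreds to a
thousand variants, 20-seed sweeps) are the package's chosen desk-scale
conditions; the format limits themselves (2³¹−2 codes per block, 2²⁴−1
blocks, 256 contigs, 16,777,215 subjects) are enforced and unit-tested at
the boundary arithmetic rather than by materializing extreme inputs.

## Known limitations

- No genotype likelihoods, dosages, ploidy > 2, or more than 15 alleles.
- INFO and non-GT FORMAT fields are not stored (variant IDs optionally
  are); decompressed VCF is GT-only.
- Files are not binary-compatible with other implementations of
  block-compressed genotype formats.
- LD is genotypic (dosage) correlation; haplotype-level D/D′ is out of
  scope even for phased data.
- Python-level parallelism relies on the compression backends releasing
  the GIL; speedups are workload-dependent, but output bytes are
  thread-count-invariant by construction.
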