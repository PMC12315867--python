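# Methods

## Trio consistency model

At a biallelic or multiallelic site with alleles indexed 0 (reference),
1, 2, …, a diploid trio genotype (child *c₁/c₂*, father, mother) is
**Mendelian-consistent** when the child's alleles can be ordered so that
one is an element of the father's allele multiset and the other of the
mother's. The rule operates on allele indices in the caller's
representation; no decomposition or left-alignment is applied, so two
representations of the same indel are distinct alleles. The check ignores
phase and is symmetric in the parents.

Verdicts are three-valued: *consistent*, *discordant*, or *unassessed*.
Any missing allele or non-diploid genotype makes the trio unassessed —
curation removes only demonstrable violations, never sites it cannot
judge. De novo variants are deliberately not whitelisted: in short-read
trio callsets, genotyping error outnumbers true de novo mutation by
orders of magnitude (germline SNV de novo rates are ~10⁻⁸ per base per
generation), so a transmission violation is treated as error. Diploid
rules are applied uniformly on all contigs including X, because the
upstream callers this toolkit targets emit diploid genotypes there;
sex-aware hemizygous handling is a documented divergence to revisit if
inputs change.

`enumerate_consistent(n_alt)` exposes the exhaustive consistent-triple
table (unordered genotypes over ≤ 4 alleles) as a public oracle; the
pairwise rule and the enumeration are checked against each other and
against an independent transmission-enumeration oracle in the tests.

## Curation procedure

1. **Merge**: three single-sample callsets are joined per
   (contig, pos, ref, alt-set). A member lacking a site is assigned a
   hom-ref genotype with *absent* GQ — single-sample truth VCFs omit
   hom-ref records, so absence means hom-ref *within that member's
   callable regions*. Records at one position with different ref alleles
   are an input error. A non-PASS FILTER in any member taints the joined
   record.
2. **FILTER**: only records whose FILTER set is exactly `{PASS}` survive.
   The tranche threshold that defines PASS (e.g. 99.7) is a property of
   the upstream filtering run and is carried as metadata only.
3. **Discordance removal**: every (contig, pos) showing a discordant
   verdict is dropped from all three individuals, including co-located
   multiallelic splits — a position-level rule. Unassessed records are
   retained. FILTER is applied before the discordance scan because both
   criteria are per-record except the position-level drop; the audit
   makes the order visible and the retained set is insensitive to it for
   records that pass both.
4. **Finalize**: per-sample outputs are restricted to autosomes + X (by
   genome-index annotation: integer-named contigs and X, with explicit
   overrides available), intersected with that sample's callable BED, and
   stripped of hom-ref genotypes.

Every input record is accounted to exactly one bin of a `CurationAudit`,
and curation is idempotent.

Coordinates follow the formats: VCF positions 1-based, BED half-open
0-based. A variant's region membership is decided by its anchor (first
ref) base only; a multi-base deletion need not fit inside an interval.
Contig order is the FASTA `.fai` order, never lexicographic. Absent GQ is
distinct from GQ 0 and sorts last in calibration curves.

## Region planning and shuffling

Examples must reach the trainer in randomized order, but shuffling a
genome of examples in one process is infeasible on a batch scheduler.
The plan: N = ⌈total truth variants / examples-per-region⌉ region files;
the callable genome is tiled into fixed windows (default 10 kb, a CLI
flag); windows are sorted by descending truth-variant count and dealt to
regions round-robin, with a fresh seeded permutation of the regions for
each block of N windows. Because blocks are count-sorted, the per-region
totals differ by at most the largest single window's count (the
block-wise max−min telescopes), and the permutations scatter every
contig's windows across all regions. Ties in window counts break on
(contig order, start). This is one admissible reading of an
under-specified scheme; the window size and target are parameters, not
constants.

Within-region shuffling is a seeded Fisher–Yates permutation; shards are
JSON-lines files (payload base64), a neutral stand-in for the binary
tensor format a training stack consumes; concatenation records split
boundaries so it is invertible; and the final cross-region interleave
draws the next source shard with probability proportional to its
remaining count — a uniform random interleave that preserves each
shard's internal order. Every stage is deterministic from (inputs, seed),
and per-region shuffles are independent of execution order, which is
what makes the region jobs embarrassingly parallel.

## Benchmarking definitions

*Concordance* is exact-match: the key is (contig, pos, ref, alt-set,
unordered genotype). A truth-only site is a FN, a query-only site a FP,
and a shared site+alleles with a different genotype is one FP plus one
FN plus a separate `gt_mismatch` tally (default), so precision and
recall are both penalized; a FP-only accounting is available via
`gt_mismatch_mode="fp_only"`. No indel normalization is attempted —
genuinely identical indels represented differently will not match, a
known cost of exact-match semantics. Strata are variant type (SNV =
all alleles length 1; indel = length-changing alleles < 50 bp; other =
MNPs and ≥ 50 bp) × genotype class × optional region label; stratified
counts sum to the pooled tally by construction.

F1 = TP / (TP + ½(FP + FN)), undefined (not zero) when nothing was
assessed. *Checkpoint selection* maximizes pooled-strata F1 on the shared
offspring truth, ties to the earliest checkpoint; per-stratum selection
(e.g. SNV-only) is available since pooling is a choice, not a law.

*MIE rate* = discordant / assessed over PASS autosome+X sites where all
three genotypes are called diploid; an SNV-only mode matches
discordant-SNV reporting. The *calibration curve* ranks assessed sites by
offspring GQ descending (absent GQ last, ties by contig order then
position) and accumulates (variants, errors); its terminal point equals
the flat MIE totals. If GQ is informative, errors concentrate at the
tail and the cumulative-error area falls below a GQ-permuted control.

*QC summary*: SNV/indel counts, Het:HomAlt, Ti:Tv (transitions A↔G,
C↔T, counted once per carried alt per record, not per haplotype), and
variant density per Mb. Genome-wide mammalian Ti:Tv is ≈ 2.0–2.3; uniform
random substitution gives 0.5 (one transition target versus two
transversion targets per base), which the simulator reproduces.

*PopVCF*: genotypes are dropped and per-alt AF = called alt alleles /
called alleles is retained, missing alleles excluded from the
denominator; a site with no called alleles is kept with AF absent.

## The simulator

`SimConfig` defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| genome | 3 contigs × 1 Mb (third named X) | desk-scale; exercises autosome+X logic |
| `n_loci` | 10,000 | ~3.3 variants/kb, enough for sub-percent rate estimates |
| site AF | Beta(0.8, 0.8) | U-shaped folded frequency spectrum |
| `genotype_error_rate` | 0.02 per member | the label-noise regime trio curation is for |
| `de_novo_rate` | 0.001 | rare relative to error, so violations ≈ error |
| `indel_fraction` | 0.15 | SNV:indel ≈ 5.7, typical of mammal short-read callsets |
| `multiallelic_fraction` | 0.02 | occasional third allele to exercise index logic |
| `n_cohort_samples` | 200 | stable AF estimates for the PopVCF channel |
| GQ model | N(50, 10) concordant, N(20, 10) erroneous, clipped [0, 99] | makes GQ informative so calibration curves have signal |
| `tranche_fraction` | 0.05 | a FILTER stratum for the PASS rule |
| `callable_gap_fraction` | 0.10 at 1 kb tiles | per-sample callable-region gaps |

Parents are drawn under Hardy–Weinberg at each site's frequency vector;
the child inherits one uniformly chosen allele per parent; a de novo
event mutates one child allele to a novel alt; an error event replaces a
member's genotype with a uniformly chosen *different* genotype over the
site's alleles. The uniform error model is the simplest that exposes the
crucial distinction between *detectable* errors (producing a transmission
violation) and undetectable ones (error configurations that remain
consistent); the per-locus truth table records both, with detectability
computed by the same consistency rule the pipeline uses, so tests can
require that curation removes exactly the detectable set.

What the simulator does **not** emulate: reads, coverage, alignment or
base-quality artifacts (error is injected at the genotype level);
linkage, recombination maps, or population structure (sites are
independent); caller-specific error correlations (errors are i.i.d.
across sites and members); realistic Ti:Tv (alt bases are uniform, so
SNV Ti:Tv ≈ 0.5 rather than ≈ 2.1). Passing tests therefore demonstrate
the correctness of the bookkeeping, the curation logic, and the
statistical identities — not performance on real sequencing data. The
synthetic-diploid constructor likewise works at the variant level:
combining one haplotype from each parent into a pseudo-offspring, with
no read simulation, because imperfect assemblies turned into synthetic
reads inject their own noise signature.

All randomness flows from a single integer seed through per-component
`numpy` generators (`[seed, k]` spawn keys), so reruns are bit-identical
and distinct components are independent.

## Numerical and interface choices

- VCF I/O is htslib-backed (pysam), plain or bgzipped; symbolic alleles
  (`<NON_REF>`, `*`, breakends) are rejected at read with a counter,
  since curation has no defined semantics for them. Writing refuses
  unsorted input rather than silently re-sorting. AF survives a write/read
  round trip to float32 precision (relative ~10⁻⁷).
- Interval sets are stored sorted and merged per contig (normalization is
  idempotent by construction); membership is a binary search.
- Non-diploid genotypes are tolerated on read, counted, and excluded from
  all trio assessments.
- The command-line layer is a thin wrapper: exit 0 on success, 1 on usage
  errors, 2 on data errors; logs to stderr; every output begins with a
  fixed-version provenance header so byte-identical reruns are possible.

## Known limitations

- Exact-match concordance understates agreement when indel
  representations differ; haplotype-aware matching is out of scope.
- The X chromosome is treated as diploid for all samples; hemizygous
  male X calls from a sex-aware caller would need masking upstream.
- Merge joins on identical alt-sets; overlapping records with different
  alt representations stay separate family records rather than being
  re-indexed onto a common allele set.
- Sites absent from a member are read as hom-ref at merge time, which is
  only sound inside that member's callable mask; the finalization step
  applies the masks, but the family-level MIE assessment of merged
  single-sample inputs inherits the convention.
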