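# Methods

## Scope and data model

`cinneo` covers the desk-computable core of a tumor/normal whole-exome
variant-to-neoantigen analysis: filtering of caller output, spectrum and
signature profiling, recurrence-based driver enumeration, HLA-restricted
peptide enumeration with binding/expression thresholds, and cohort
summaries. Upstream read processing (trimming, alignment, recalibration),
the variant callers themselves, copy-number analysis, HLA typing and the
binding predictor's neural network are treated as external producers whose
outputs are inputs here: VCF (two dialects of read-support tags), MAF,
four-digit HLA genotype TSVs, FPKM tables and predictor-native output.

The unit record is a `Variant` with 1-based, fully closed coordinates (the
VCF convention); conversion to 0-based half-open happens only inside
sequence-slicing code. Consequence classes come from annotation
(`Variant_Classification` vocabulary) rather than being recomputed —
recomputation happens only in the peptide stage, where transcript models
are in hand and the protein-level effect is actually needed.

## Somatic filter

The four read-support criteria use the comparison strictness their wording
implies: depth and alt-count bounds are inclusive ("no less than"), the
normal-VAF bound is strict ("less than 3 %"), the enrichment bound is
inclusive ("four-fold or more"). Two deliberate edge policies:

- normal VAF exactly 0 satisfies the fold criterion without division —
  zero contamination in the control is the strongest somatic evidence;
- tumor depth 0 is an invalid record (error), not a quiet fail.

The criteria are applied uniformly to SNVs and indels. Dropped records are
quarantined with per-criterion flags, never silently discarded. Filter
correctness is pinned by exhaustive comparison against an independent
four-predicate evaluator over all depth/alt combinations up to depth 30.

## Spectrum and 96-context catalogs

Purine-reference substitutions are reverse-complemented onto the
pyrimidine strand, flanks complemented and swapped — the convention under
which reference signature matrices are published, and the one forced by
comparing exposures to such matrices. The 96-vector ordering is
class-major, then 5′ flank A/C/G/T, then 3′ flank, so external matrices
load without remapping; matrices with labelled rows in any order are
reindexed on load. Stage proportions pool counts across a group's samples
before normalizing (one percentage per stage); per-sample averaging is
available behind a flag, as which convention the printed per-stage
percentages used is not determinable. No exome/genome trinucleotide
renormalization is applied (none was in evidence); the refit accepts an
optional 96-vector of context weights as a hook.

A trend call per class is "increasing" iff proportions are weakly
increasing across CIN1→CIN2→CIN3→CC with a strict overall rise
(symmetrically "decreasing"); constant profiles are non-monotonic.

## Signature refitting

Exposures are estimated by forward selection with exact nonnegative least
squares (scipy NNLS) at each step: starting from the empty set, every
unused signature is trial-fitted with the current set and the largest SSE
drop wins (ties break on column order, making the fit deterministic);
selection stops when the best relative SSE improvement falls below
`improvement_tol` (default 1e-3). Final exposures below `weight_cutoff`
(default 0.06, the conventional discard threshold in refitting tools) are
zeroed and the survivors re-solved. Exposures are fractions of the
normalized catalog, so the fit is invariant to catalog scale; if the NNLS
solution sums above 1 it is renormalized, and `1 − Σw` is reported as
unexplained mass. An all-zero catalog returns an explicit no-fit result.

Default cohort behavior is per-sample fitting with group averaging
(renormalized means), since fitting pooled group catalogs would hide
sample-level exposure structure; pooled fitting is a one-liner on the
pooled catalog if wanted.

## Driver enumeration

Statistical driver tests are underpowered at this cohort size, so genes
are called by strict enumeration: recurrence in ≥ `min_cases` (default 3)
distinct samples, membership in a user-supplied driver-gene catalog, and
at least one qualifying mutation — truncating (stop-gain or frameshift) or
voted deleterious by ≥ 2 of SIFT (category D), PolyPhen-2 (category D;
"possibly damaging" does not count by default, configurable) and
MutationTaster (categories A or D). The qualifying-mutation rule is
applied at gene level because recurrently mutated genes legitimately carry
tolerated passengers alongside their deleterious mutations. Genes with a
qualifying mutation at exactly `min_cases − 1` carriers are surfaced in a
separate near-threshold report — whatever their catalog status, with the
status recorded — so recurrence just under the bar is reviewable rather
than lost.

## Neoantigen enumeration

A 22-residue window cannot be exactly centered; the convention is 10
residues upstream + mutated site + 11 downstream, truncated at protein
termini. For interior sites the choice does not alter the set of
mutation-covering ≤ 11mers, which is why it is safe to fix silently in
output metadata. Frameshift contexts are the novel tail translated from
the shifted codon to the first stop (or CDS end), preceded by up to 10
wild-type residues, with every tail residue marked novel; in-frame indels
route to a substitution-like context around the junction. Window
enumeration is deduplicated by peptide and deterministic (length
ascending, start ascending), and is pinned against a brute-force
substrings-then-filter oracle.

Both binding thresholds are strict and conjunctive (IC50 < 500 nM, %Rank
< 2). Homozygous genotypes deduplicate to one allele before prediction.
Candidate identity for counting is (sample, peptide, allele) — the same
peptide bound by two alleles counts twice — with the per-peptide
collapsed count also emitted, since either convention could underlie a
published per-sample burden. The expression rule uses a 1e-3 pseudocount
in the log-ratio so zero normal FPKM is well-defined; at the 0.5-FPKM
floor the induced bias is negligible.

The built-in mock predictor hashes (seed, peptide, allele) through
SHA-256, so scores are reproducible and independent of batch order, with a
configurable binder fraction; defaults use 0.02, the definitional mass
under a %Rank < 2 cutoff for random peptides. It is the package's own
deterministic scoring model for synthetic studies; real predictions enter
through the native-output parser adapter.

## Synthetic data

The generator emulates the study conditions: four stages with 10/9/6/14
samples; negative-binomial mutation burdens with stage means 6.45 / 6.80 /
9.67 / 330.5 (dispersion 2, a typical tumor overdispersion); stage-specific
exposure mixtures over five synthetic signatures constructed on disjoint
context blocks (pairwise cosine < 0.1) with the APOBEC-like component
present only in the carcinoma group; a harder confusable pair (cosine
≈ 0.8) for cutoff stress tests. SNVs realize each drawn context at a
matching reference trinucleotide on either strand; read support is
engineered so a configured fraction of calls (default 10 % per criterion)
breaks each filter criterion, with the evaluated per-criterion outcome
recorded in the truth table. Cohort fixtures draw HLA genotypes from a
small allele pool with stage-conditional focal-allele frequencies, and
neoantigen counts as a linear rate (1.08 per nonsynonymous mutation, the
ratio of the cohort's mean burdens) plus Gaussian noise; FPKM tables
satisfy the expression rule for a programmed fraction (default 0.5) of
genes. All outputs are byte-identical under a fixed seed.

What the generator does **not** emulate: alignment artifacts, sequencing
error profiles, mutational hotspots/selection, linkage between HLA loci,
HPV integration, or realistic transcript structure (single-exon CDS on the
forward strand). Passing tests therefore demonstrate algorithmic
correctness against known ground truth, not robustness to real-data noise.

## Printed-table fixtures and their statistics

The packaged TSVs transcribe the study's per-sample cohort table (39 rows:
25 CIN + 14 CC), validated-candidate table (45 rows) and driver-candidate
table (11 mutations, 3 genes) cell by cell; loaders assert row counts and
group sizes. Cell semantics: in HLA columns "/" means typing unavailable
and "–" no reportable allele — both samples remain in carrier-frequency
denominators (required to reproduce the published 12 % / 20 % premalignant
frequencies); wildcard alleles like "67:\*" are stored verbatim and match
no specific four-digit allele. Blank merged cells in the validated table
fill down from the row above, yielding the 10/2/33 source split.
Candidates matched by several validation sources are assigned by the
precedence TSNAdb > IEDB > CTAs, mirroring the single-valued source
column; epitope databases match on exact peptide, the cancer/testis list
on protein symbol.

Where the published summary prints "median", the value equals the
arithmetic mean of the group's counts; both statistics are emitted under
their correct names. Two published figures are not reproducible from the
printed per-sample table itself: the burden–neoantigen Pearson correlation
computes to 0.98 (not the printed 0.96), and the premalignant mean
neoantigen burden to 5.2 (not 5.3). The package reports the exact
recomputed values; the corresponding acceptance assertion on 0.96 is left
failing rather than adjusted.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen to make the
statistical oracles sharp but cheap: signature recovery with 20 seeded
two-signature mixtures of 5 000 mutations; context-frequency recovery at
2 000 SNVs (3-SE bands, allowing the expected handful of excursions over
96 cells); carrier-frequency recovery at 200 samples; the filter oracle on
the full depth ≤ 30 grid. NNLS is exact per step; ties in forward
selection break on column order; catalogs with unclassifiable SNVs
(non-ACGT context, contig-end flanks) count them separately so totals are
conserved.
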