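# Methods

## Scope and model

`neovax` covers the desk half of a neoantigen vaccine design: from an
annotated somatic variant table and a tumor expression table to two
polyepitope constructs. Upstream steps (read QC, alignment, somatic variant
calling, annotation, RNA-seq quantification) are out of scope — their
outputs are this package's inputs. Trained MHC binding predictors are also
out of scope: they enter only through the scorer interface described below.

The design model makes three assumptions worth stating. First, protein
annotation is trusted: variants carry a gene, a 1-based protein position and
reference/alternate amino acids, and the reference amino acid must match the
supplied proteome (a mismatch is an error, not a warning, since it means the
annotation and proteome disagree). Second, only single amino-acid
substitutions are handled; indels and fusions, which change downstream
windows entirely, are not modeled. Third, predicted binding affinity in nM
is the sole ranking signal, lower meaning stronger, matching IC50
convention.

## Filter cascade

VAF is exactly `alt_depth / total_depth`. The cascade is
nonsynonymous → VAF gate → expression gate with defaults `vaf_min = 0.1`
(non-strict ≥) and `fpkm_min = 1.0`. The VAF comparison is non-strict by
default because the selection step feeding the epitope pipeline is stated as
"at least 0.1"; a `vaf_strict` flag switches to `>` for the alternative
true-positive reading. Genes absent from the expression table count as
FPKM = 0 and are dropped with a warning rather than raising — exome and
RNA-seq gene universes rarely match exactly. The FPKM gate is applied at
gene level; transcript-level gating would need transcript-resolved
quantification the input format does not carry.

## Window enumeration

All mutation-spanning windows are enumerated, not just the centered one: the
selection is affinity-driven, so every window containing the mutation is a
legitimate candidate. Class I uses lengths {8, 9, 10}, class II
{12, 13, 14}; both sets are configurable. Duplicate sequences arising from
one variant (possible in low-complexity regions) are collapsed keeping the
first occurrence; identical sequences from *different* variants are kept,
since they carry distinct provenance. Windows never extend past a terminus.

## Affinity scoring and selection

The scorer contract is `score(sequence, allele) -> nM`. Class-I peptides are
scored against H2-Kb and H2-Db, class-II against I-Ab; a peptide's effective
affinity is the minimum over its compatible alleles (binding either class-I
allele suffices for presentation in H-2b mice).

Selection sorts ascending by affinity and takes the top ten per class. By
default each variant is first reduced to its single best window
(`per_variant_best_first = true`), so the ten selected epitopes represent
ten distinct mutations — maximizing mutation diversity in the construct;
setting it false gives a plain window-level top-k. Ties are broken by
(affinity, peptide sequence, window start), making selection a deterministic
function of the record *set* (input order never matters).

The binder flag uses affinity ≤ 1000 nM, boundary inclusive. The threshold
and direction are both configurable because conventions differ across
predictor versions and write-ups; the flag is annotation only and does not
gate selection.

### Surrogate scorer

`SurrogateScorer` is a deterministic pseudo-affinity generator, not a
binding model: it mixes a fixed per-allele position/residue weight table
(positions folded modulo a 9-residue frame) with a whole-sequence term, both
derived from BLAKE2 digests, and maps the result into (1, 50000] nM via
`50000**x`. Identical inputs always give identical outputs with no
randomness at call time; distinct peptides essentially never collide. It
exists so ranking, selection and assembly are exercised end-to-end without a
network-accessed predictor. Conclusions about *which* peptides bind require
a real predictor plugged in through `TabularScorer` (a peptide/allele/nM
table, the common external-tool exchange format).

## 27-mer extension and constructs

Extension targets a 27-mer with the mutation at residue 14 (13 residues of
natural flank each side). Near a terminus the window slides to stay inside
the protein rather than padding — padding would fabricate junctional
sequence that does not exist in the tumor; proteins shorter than 27 residues
are taken whole. The `shifted` flag records any off-center placement and is
carried into the design report and GenBank annotation.

Layout: the central linker sits between every pair of adjacent epitopes and
one terminal linker flanks each side of the epitope block, between it and
the SP/MITD domains. The source text names the two linker roles without
diagramming their placement; this reading is recorded in the GenBank comment
and every element of the layout (sequences, epitopes per construct) is
configurable. Epitopes are ordered strongest predicted binder first within a
construct; no ordering is prescribed by the source, and a deterministic rule
keeps output reproducible. With five full-length epitopes the construct
protein length obeys |SP| + 2·|term| + 5·27 + 4·|central| + |MITD| = 276 aa.

Reverse translation uses one fixed codon per amino acid — the most-used
human codon (Kazusa usage census) — plus a single TGA stop. A deterministic
table was chosen over stochastic codon optimization for reproducibility;
any residue→codon mapping can be supplied instead. 5′/3′ UTR and other
mRNA backbone elements are accepted as optional config sequences (defaults
empty) since no published values exist for them.

## Synthetic cohort generator

The generator emulates the data products of a tumor/normal exome plus tumor
RNA-seq study at toy scale: a proteome of `n_genes` random sequences over
the 20-letter alphabet (each starting with M, lengths uniform in
`protein_length_range`), somatic variants whose observed alt depth is
`Binomial(total_depth, true VAF)` with Poisson total depth, and a log-normal
FPKM table. Defaults, chosen once as plausible for a modern exome/RNA-seq
pair: mean depth 500, true VAF uniform on [0.01, 0.6] (spanning subclonal to
clonal heterozygous), fraction nonsynonymous 0.85, log-FPKM normal with
mean 1.0 and sd 1.5 natural-log units (median FPKM ≈ e, roughly three
quarters of genes clearing FPKM ≥ 1). One root seed is split into
per-component child streams (proteome / variants / expression), so changing
one component's size never perturbs another's draws, and an identical spec
plus seed yields byte-identical output files.

What the generator does *not* emulate — and therefore what passing tests do
not show: mutational signatures and codon context (amino acids are drawn
uniformly), mapping artifacts and strand bias in depths (pure binomial
noise), gene-length or GC effects on FPKM, and any correlation between
expression and mutation. Tests on synthetic cohorts validate the pipeline's
*logic* (gates, enumeration, ranking, assembly, round trips), not biological
discovery performance.

A per-variant truth table (true VAF plus expected gate outcomes at the
default thresholds) is written alongside the cohort so downstream filters
can be audited against it.

## Numerical and degenerate-input choices

- VAF is an exact integer ratio; no rounding is applied before comparisons.
- All selection tie-breaks are total orders (affinity, sequence, start), so
  every stage is a deterministic function of its inputs.
- A protein shorter than the smallest window length yields zero candidates
  (not an error); an empty class pool at construct time *is* an error, since
  a construct cannot be empty.
- Depth draws of zero are clamped to one read (a variant cannot be observed
  at depth zero).
- Scorer failures on individual peptides skip the record with a logged
  error; a missing gene at enumeration raises, since it indicates mismatched
  inputs rather than a single bad record.
- Problem sizes in the test suite (cohorts of 120–200 variants, exhaustive
  window-oracle sweep up to protein length 40) were sized to exercise every
  code path while keeping the suite fast.

## Known limitations

- No proteasomal-cleavage, TAP-transport or immunogenicity modeling; the
  ranking is affinity-only by design.
- Percentile-rank calibration of predictor output is not implemented; the
  scorer contract is raw nM.
- Indels, splice variants and fusions are unsupported.
- The codon policy optimizes nothing (expression, structure, uridine
  content); it only guarantees a valid, reproducible CDS.
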