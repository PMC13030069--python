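# neovax

Neoantigen prioritization and pentatope mRNA vaccine construct design for
mouse (H-2b) tumor models.

Personalized cancer mRNA vaccines encode short tumor-specific peptides
(neoantigens) arising from somatic missense mutations. `neovax` implements
the computational arm of that design for the C57BL/6 / Lewis lung carcinoma
setting: it takes an annotated somatic variant table (from a tumor/normal
exome comparison), a tumor gene-expression table and a reference proteome,
and produces ready-to-synthesize polyepitope constructs as protein and
coding-nucleotide sequences. It is aimed at computational immunologists and
vaccine engineers who have variant calls in hand and need a reproducible,
auditable path from VCF to construct.

## The procedure

1. **Variant gating.** For each somatic variant the variant allele frequency
   is computed as VAF = alt reads / total reads. The cascade keeps variants
   that are (i) nonsynonymous, (ii) confidently somatic (VAF ≥ 0.1), and
   (iii) expressed in the tumor (gene FPKM ≥ 1). All gates are per-record
   predicates: they commute and are monotone in their thresholds.
2. **Window enumeration.** Each surviving mutation is substituted into its
   protein and every peptide window containing the mutant residue is
   enumerated at MHC class I lengths (8–10 aa) and class II lengths
   (12–14 aa). For a mutation at interior position *p* of a protein of
   length *n*, the number of windows of length *L* is
   min(*p*, *L*, *n*−*L*+1, *n*−*p*+1).
3. **Affinity ranking.** Windows are scored against the H-2b alleles —
   H2-Kb and H2-Db (class I), I-Ab (class II) — through a pluggable scorer
   returning predicted binding affinity in nM (lower = stronger). External
   predictors (netMHCpan-style tables) plug in via `TabularScorer`; a
   deterministic hash-based `SurrogateScorer` serves tests and dry runs.
   Records are sorted ascending by affinity; each variant keeps its best
   window/allele, and the ten strongest per class are selected.
4. **Construct assembly.** Each selected core epitope is extended to a
   27-mer with the mutation at residue 14 (sliding, never padding, near
   termini). Five epitopes per class are joined — central linker GGSGGGGSGG
   between adjacent epitopes, terminal linker GGSLGGGGSG on each side of the
   block — and framed by a signal peptide and an MHC class I trafficking
   signal domain (MITD):

   ```
   SP — term — e1 — central — e2 — central — e3 — central — e4 — central — e5 — term — MITD
   ```

   With five 27-mers the protein is 26 + 10 + 5·27 + 4·10 + 10 + 55 = 276 aa.
   The protein is reverse-translated with a deterministic most-frequent
   human codon policy and emitted as FASTA (protein + CDS), an annotated
   GenBank record, and a per-epitope design report.

A synthetic-cohort generator (toy proteome, binomially sampled read depths
at known true VAFs, log-normal FPKM) makes the whole pipeline runnable and
testable with no external data.

## Worked example

```bash
neovax simulate --out demo/cohort --seed 42
# wrote cohort with 200 variants to demo/cohort

neovax design \
  --variants demo/cohort/variants.vcf \
  --expression demo/cohort/expression.tsv \
  --proteome demo/cohort/proteome.fasta \
  --out demo/design
# design complete: 200 variants read, 112 passed all gates,
# 10+10 epitopes selected, 2 constructs written to demo/design
```

Of the 200 simulated variants, 173 are nonsynonymous, 152 clear the VAF
gate, and 112 are also expressed (the counts are in
`demo/design/manifest.json` and shrink monotonically through the cascade).
The 112 survivors yield 2,909 class-I and 4,122 class-II mutation-spanning
windows, 9,940 (peptide, allele) affinity records, and ten selected epitopes
per class. The top of `demo/design/design_report.tsv`:

```
construct        mhc_class  rank  gene      mutation  core_peptide  allele  affinity_nm
pentatope_mhc_i  I          1     gene0048  M240V     WYGVFQPYLT    H2-Kb   5.89
pentatope_mhc_i  I          2     gene0021  S144G     QKFYQTQGS     H2-Db   6.07
```

Each row is one encoded epitope: the source mutation, the core peptide that
won the ranking with its allele and predicted affinity (nM, surrogate
scorer here), and the 27-mer actually encoded. Both 276-aa constructs and
their 831-nt CDSs are in `constructs_protein.fasta`, `constructs_cds.fasta`
and the annotated `constructs.gb`. Every stage is also available as a
library call (`neovax.run_design`, `neovax.rank_and_select`, ...) and as
individual subcommands (`filter`, `enumerate`, `score`, `select`,
`construct`).

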