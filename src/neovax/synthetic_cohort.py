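"""Synthetic tumor cohort generator.

Emulates the data products of a tumor/normal exome + tumor RNA-seq study at
toy scale so the whole design pipeline runs with no external data: a random
proteome, somatic missense variants with binomially sampled alt-read depths
at known true VAFs, and a log-normal gene-level FPKM table. The per-variant
truth (true VAF and the expected outcome of every filter gate) is carried
alongside so downstream filters can be checked against it.

Randomness comes from one root seed; per-component child streams are spawned
from it so, e.g., enlarging the proteome does not perturb variant sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variant_intake import (
    AMINO_ACIDS,
    NONSYNONYMOUS,
    SYNONYMOUS,
    ExpressionTable,
    FilterThresholds,
    SomaticVariant,
    read_variants_tsv,
)

_NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``true_vaf_distribution`` and ``depth_distribution`` are
    ``(name, params)`` pairs; supported names are ``uniform``/``beta``/
    ``fixed`` for VAF and ``poisson``/``fixed`` for total depth.
    """

    n_genes: int = 100
    protein_length_range: tuple[int, int] = (100, 600)
    n_variants: int = 200
    true_vaf_distribution: tuple[str, Mapping[str, float]] = (
        "uniform", {"low": 0.01, "high": 0.6},
    )
    depth_distribution: tuple[str, Mapping[str, float]] = ("poisson", {"mean": 500})
    fpkm_log_mean: float = 1.0
    fpkm_log_sd: float = 1.5
    fraction_nonsynonymous: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.protein_length_range
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_variants < 0:
            raise ValueError("n_variants must be non-negative")
        if not (1 <= lo <= hi):
            raise ValueError(f"protein_length_range must satisfy 1 <= low <= high, got {lo, hi}")
        if not 0 <= self.fraction_nonsynonymous <= 1:
            raise ValueError("fraction_nonsynonymous must lie in [0, 1]")
        if self.fpkm_log_sd <= 0:
            raise ValueError("fpkm_log_sd must be positive")
        name, params = self.true_vaf_distribution
        if name == "uniform" and not (0 <= params["low"] <= params["high"] <= 1):
            raise ValueError("uniform VAF bounds must satisfy 0 <= low <= high <= 1")

    def _streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "proteome": np.random.default_rng(children[0]),
            "variants": np.random.default_rng(children[1]),
            "expression": np.random.default_rng(children[2]),
        }


@dataclass
class SyntheticCohort:
    """A generated cohort: proteome, variants with truth, expression."""

    proteome: dict[str, str]
    variants: list[SomaticVariant]
    expression: ExpressionTable
    truth: pd.DataFrame  # one row per variant, aligned with `variants`

    def validate(self) -> None:
        for v in self.variants:
            if v.gene not in self.proteome:
                raise ValueError(f"variant gene {v.gene} missing from proteome")
            prot = self.proteome[v.gene]
            if v.protein_pos > len(prot):
                raise ValueError(f"{v.label}: protein_pos beyond sequence length")
            if prot[v.protein_pos - 1] != v.aa_ref:
                raise ValueError(f"{v.label}: reference amino acid mismatch")


def _sample_vaf(rng: np.random.Generator, dist: tuple[str, Mapping[str, float]]) -> float:
    name, p = dist
    if name == "uniform":
        return float(rng.uniform(p["low"], p["high"]))
    if name == "beta":
        return float(rng.beta(p["a"], p["b"]))
    if name == "fixed":
        return float(p["value"])
    raise ValueError(f"unknown VAF distribution {name!r}")


def _sample_depth(rng: np.random.Generator, dist: tuple[str, Mapping[str, float]]) -> int:
    name, p = dist
    if name == "poisson":
        return int(max(1, rng.poisson(p["mean"])))
    if name == "fixed":
        return int(p["value"])
    raise ValueError(f"unknown depth distribution {name!r}")


def generate_proteome(spec: CohortSpec) -> dict[str, str]:
    """Random toy proteome: ``n_genes`` sequences over the 20-aa alphabet,
    each starting with M, lengths uniform within ``protein_length_range``."""
    rng = spec._streams()["proteome"]
    lo, hi = spec.protein_length_range
    aa = np.array(list(AMINO_ACIDS))
    proteome: dict[str, str] = {}
    for i in range(spec.n_genes):
        length = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(aa, size=max(0, length - 1)))
        proteome[f"gene{i + 1:04d}"] = ("M" + body)[:length]
    return proteome


def simulate_variants(
    spec: CohortSpec, proteome: Mapping[str, str]
) -> tuple[list[SomaticVariant], pd.DataFrame]:
    """Simulate somatic single-amino-acid variants with read-depth evidence.

    Each variant draws a true VAF, a total depth, and
    alt_depth ~ Binomial(total_depth, true VAF). The reference amino acid is
    read from the proteome; nonsynonymous records get a different alternate
    residue. Returns the variants and a truth table (true VAF per variant).
    """
    if not proteome:
        raise ValueError("proteome is empty")
    rng = spec._streams()["variants"]
    genes = sorted(proteome)
    variants: list[SomaticVariant] = []
    truth_rows = []
    for i in range(spec.n_variants):
        gene = genes[int(rng.integers(len(genes)))]
        prot = proteome[gene]
        ppos = int(rng.integers(1, len(prot) + 1))
        aa_ref = prot[ppos - 1]
        nonsyn = bool(rng.random() < spec.fraction_nonsynonymous)
        if nonsyn:
            choices = [a for a in AMINO_ACIDS if a != aa_ref]
            aa_alt = choices[int(rng.integers(len(choices)))]
            csq = NONSYNONYMOUS
        else:
            aa_alt = aa_ref
            csq = SYNONYMOUS
        true_vaf = _sample_vaf(rng, spec.true_vaf_distribution)
        depth = _sample_depth(rng, spec.depth_distribution)
        alt = int(rng.binomial(depth, true_vaf))
        ref_nt = _NUCLEOTIDES[int(rng.integers(4))]
        alt_nt = [n for n in _NUCLEOTIDES if n != ref_nt][int(rng.integers(3))]
        variants.append(
            SomaticVariant(
                gene=gene, chrom="1", pos=(i + 1) * 100, ref=ref_nt, alt=alt_nt,
                aa_ref=aa_ref, aa_alt=aa_alt, protein_pos=ppos,
                alt_depth=alt, total_depth=depth, consequence=csq,
            )
        )
        truth_rows.append(
            {"variant": variants[-1].label, "gene": gene, "protein_pos": ppos,
             "true_vaf": true_vaf}
        )
    return variants, pd.DataFrame(truth_rows, columns=["variant", "gene", "protein_pos", "true_vaf"])


def simulate_expression(spec: CohortSpec, proteome: Mapping[str, str]) -> ExpressionTable:
    """One log-normal FPKM per gene: log FPKM ~ N(fpkm_log_mean, fpkm_log_sd)."""
    if not proteome:
        raise ValueError("proteome is empty")
    rng = spec._streams()["expression"]
    genes = sorted(proteome)
    fpkm = rng.lognormal(spec.fpkm_log_mean, spec.fpkm_log_sd, size=len(genes))
    return ExpressionTable(dict(zip(genes, map(float, fpkm))))


def simulate_cohort(
    spec: CohortSpec, thresholds: FilterThresholds = FilterThresholds()
) -> SyntheticCohort:
    """Generate a full cohort, with truth flags for every filter gate.

    The flags record the expected outcome of each gate at ``thresholds``:
    ``nonsynonymous``, ``pass_vaf`` (observed VAF clears the gate) and
    ``pass_expression`` (gene FPKM clears the gate *and* VAF passes).
    """
    proteome = generate_proteome(spec)
    variants, truth = simulate_variants(spec, proteome)
    expression = simulate_expression(spec, proteome)
    truth = truth.assign(
        observed_vaf=[v.vaf for v in variants],
        nonsynonymous=[v.consequence == NONSYNONYMOUS for v in variants],
        pass_vaf=[thresholds.vaf_passes(v.vaf) for v in variants],
        pass_expression=[
            thresholds.vaf_passes(v.vaf) and expression.fpkm(v.gene) >= thresholds.fpkm_min
            for v in variants
        ],
    )
    cohort = SyntheticCohort(proteome, variants, expression, truth)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# on-disk layout

PROTEOME_FASTA = "proteome.fasta"
VARIANTS_VCF = "variants.vcf"
VARIANTS_TSV = "variants.tsv"
EXPRESSION_TSV = "expression.tsv"
TRUTH_TSV = "truth.tsv"


def _vcf_header(samples: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=1,length=536870911>")
    header.info.add("GENE", 1, "String", "Annotated gene symbol")
    header.info.add("TRANSCRIPT", 1, "String", "Annotated transcript id")
    header.info.add("PPOS", 1, "Integer", "1-based protein residue position")
    header.info.add("AAREF", 1, "String", "Reference amino acid")
    header.info.add("AAALT", 1, "String", "Alternate amino acid")
    header.info.add("CSQ", 1, "String", "Consequence class")
    header.formats.add("AD", 1, "Integer", "Alternate allele read depth")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    for s in samples:
        header.add_sample(s)
    return header


def write_variants_vcf(variants: list[SomaticVariant], path: str | Path) -> None:
    """Write the minimal VCF dialect (AD/DP per tumor sample, annotation in INFO)."""
    header = _vcf_header(["TUMOR"])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.info["GENE"] = v.gene
            if v.transcript:
                rec.info["TRANSCRIPT"] = v.transcript
            rec.info["PPOS"] = v.protein_pos
            rec.info["AAREF"] = v.aa_ref
            rec.info["AAALT"] = v.aa_alt
            rec.info["CSQ"] = v.consequence
            rec.samples["TUMOR"]["AD"] = v.alt_depth
            rec.samples["TUMOR"]["DP"] = v.total_depth
            out.write(rec)


def write_proteome_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="") for gene, seq in proteome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_proteome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Emit the cohort file set; all files round-trip losslessly.

    Returns a name -> path map for proteome FASTA, variant VCF + TSV mirror,
    expression TSV and truth TSV.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": directory / PROTEOME_FASTA,
        "variants_vcf": directory / VARIANTS_VCF,
        "variants_tsv": directory / VARIANTS_TSV,
        "expression": directory / EXPRESSION_TSV,
        "truth": directory / TRUTH_TSV,
    }
    write_proteome_fasta(cohort.proteome, paths["proteome"])
    write_variants_vcf(cohort.variants, paths["variants_vcf"])
    from .variant_intake import write_variants_tsv

    write_variants_tsv(cohort.variants, paths["variants_tsv"])
    cohort.expression.to_tsv(paths["expression"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Re-read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    proteome = read_proteome_fasta(directory / PROTEOME_FASTA)
    variants = read_variants_tsv(directory / VARIANTS_TSV)
    expression = ExpressionTable.from_tsv(directory / EXPRESSION_TSV)
    truth = pd.read_csv(directory / TRUTH_TSV, sep="\t")
    return SyntheticCohort(proteome, variants, expression, truth)
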