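"""Somatic variant intake and the selection cascade.

Reads annotated somatic variant tables (a minimal VCF dialect or its TSV
mirror) together with a gene-level FPKM table, and applies the three gates
used to nominate vaccine candidates from a tumor/normal comparison:

1. keep nonsynonymous (missense) variants,
2. keep variants whose variant allele frequency (VAF = alt reads / total
   reads) clears the true-positive threshold (default >= 0.1),
3. keep variants on genes expressed in the tumor (FPKM >= 1 by default).

All filters are pure per-record predicates: they preserve input order,
commute with each other, and are monotone in their thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

NONSYNONYMOUS = "nonsynonymous"
SYNONYMOUS = "synonymous"
OTHER = "other"
CONSEQUENCES = (NONSYNONYMOUS, SYNONYMOUS, OTHER)

#: columns of the TSV mirror of the variant VCF
VARIANT_TSV_COLUMNS = [
    "gene", "transcript", "chrom", "pos", "ref", "alt",
    "aa_ref", "aa_alt", "protein_pos", "alt_depth", "total_depth",
    "consequence",
]


def compute_vaf(alt_depth: int, total_depth: int) -> float:
    """Variant allele frequency: mutated-allele read depth over total depth.

    Parameters
    ----------
    alt_depth : int
        Reads supporting the alternate (mutant) allele.
    total_depth : int
        Total sequencing depth at the locus; must be positive.

    Returns
    -------
    float in [0, 1]
    """
    if total_depth <= 0:
        raise ValueError(f"total_depth must be positive, got {total_depth}")
    if alt_depth < 0 or alt_depth > total_depth:
        raise ValueError(
            f"alt_depth must lie in [0, total_depth]; got alt_depth={alt_depth}, "
            f"total_depth={total_depth}"
        )
    return alt_depth / total_depth


@dataclass(frozen=True)
class SomaticVariant:
    """One annotated somatic mutation with read-depth evidence.

    ``protein_pos`` is the 1-based residue index in the annotated protein;
    ``aa_ref``/``aa_alt`` are single-letter amino acids. ``vaf`` is computed
    from the depths, never read from the input.
    """

    gene: str
    chrom: str
    pos: int
    aa_ref: str
    aa_alt: str
    protein_pos: int
    alt_depth: int
    total_depth: int
    consequence: str
    transcript: str | None = None
    ref: str = "N"
    alt: str = "N"

    def __post_init__(self) -> None:
        if self.total_depth <= 0:
            raise ValueError(f"{self.gene}: total_depth must be positive")
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"{self.gene}: alt depth exceeds total depth "
                f"({self.alt_depth} > {self.total_depth})"
                if self.alt_depth > self.total_depth
                else f"{self.gene}: negative alt_depth"
            )
        if self.protein_pos < 1:
            raise ValueError(f"{self.gene}: protein_pos must be >= 1")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"{self.gene}: unknown consequence {self.consequence!r}")
        if self.consequence == NONSYNONYMOUS and self.aa_ref == self.aa_alt:
            raise ValueError(
                f"{self.gene}:{self.protein_pos}: nonsynonymous variant with "
                "identical reference and alternate amino acids"
            )

    @property
    def vaf(self) -> float:
        return compute_vaf(self.alt_depth, self.total_depth)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Stable identity of the mutation (gene, residue, ref, alt)."""
        return (self.gene, self.protein_pos, self.aa_ref, self.aa_alt)

    @property
    def label(self) -> str:
        """Human-readable protein change, e.g. ``Kras_G12D``."""
        return f"{self.gene}_{self.aa_ref}{self.protein_pos}{self.aa_alt}"


@dataclass(frozen=True)
class ExpressionTable:
    """Gene -> FPKM mapping used for the expression gate."""

    records: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [g for g, v in self.records.items() if v < 0]
        if bad:
            raise ValueError(f"negative FPKM for genes: {bad[:5]}")

    def fpkm(self, gene: str) -> float:
        """FPKM for ``gene``; genes absent from the table count as 0."""
        return float(self.records.get(gene, 0.0))

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        if not {"gene", "fpkm"} <= set(df.columns):
            raise ValueError(f"{path}: expression TSV needs columns 'gene' and 'fpkm'")
        if df["gene"].duplicated().any():
            raise ValueError(f"{path}: duplicate gene ids in expression table")
        return cls(dict(zip(df["gene"].astype(str), df["fpkm"].astype(float))))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"gene": list(self.records), "fpkm": list(self.records.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds for the true-positive and expression gates.

    ``vaf_strict`` switches the VAF comparison from the default non-strict
    ``>=`` to strict ``>``.
    """

    vaf_min: float = 0.1
    fpkm_min: float = 1.0
    vaf_strict: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.vaf_min <= 1:
            raise ValueError(f"vaf_min must be in (0, 1], got {self.vaf_min}")
        if self.fpkm_min < 0:
            raise ValueError(f"fpkm_min must be non-negative, got {self.fpkm_min}")

    def vaf_passes(self, vaf: float) -> bool:
        return vaf > self.vaf_min if self.vaf_strict else vaf >= self.vaf_min


def filter_nonsynonymous(variants: Iterable[SomaticVariant]) -> list[SomaticVariant]:
    """Retain exactly the nonsynonymous records, order preserved."""
    return [v for v in variants if v.consequence == NONSYNONYMOUS]


def filter_true_positive(
    variants: Iterable[SomaticVariant],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[SomaticVariant]:
    """True-positive gate on VAF (default: VAF >= 0.1)."""
    return [v for v in variants if thresholds.vaf_passes(v.vaf)]


def filter_expressed(
    variants: Iterable[SomaticVariant],
    expression: ExpressionTable,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[SomaticVariant]:
    """Joint VAF/expression gate (default: VAF >= 0.1 and FPKM >= 1).

    Genes absent from the expression table are treated as unexpressed
    (FPKM = 0) and dropped with a warning.
    """
    kept: list[SomaticVariant] = []
    for v in variants:
        if v.gene not in expression.records:
            logger.warning(
                "gene %s absent from expression table; treated as FPKM=0 and dropped",
                v.gene,
            )
            continue
        if expression.fpkm(v.gene) >= thresholds.fpkm_min and thresholds.vaf_passes(v.vaf):
            kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# I/O


def _variant_from_row(row: Mapping, line_no: int) -> SomaticVariant:
    try:
        transcript = row.get("transcript")
        if transcript is not None and (pd.isna(transcript) or transcript == ""):
            transcript = None
        return SomaticVariant(
            gene=str(row["gene"]),
            transcript=None if transcript is None else str(transcript),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row.get("ref", "N")),
            alt=str(row.get("alt", "N")),
            aa_ref=str(row["aa_ref"]),
            aa_alt=str(row["aa_alt"]),
            protein_pos=int(row["protein_pos"]),
            alt_depth=int(row["alt_depth"]),
            total_depth=int(row["total_depth"]),
            consequence=str(row["consequence"]),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"line {line_no}: missing or malformed field: {exc}") from exc


def read_variants_tsv(path: str | Path) -> list[SomaticVariant]:
    """Read the TSV mirror; invalid rows are rejected with a logged reason."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in df.columns and c != "transcript"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    variants: list[SomaticVariant] = []
    for i, row in enumerate(df.to_dict("records"), start=2):  # 1 header line
        if any(
            pd.isna(row.get(c))
            for c in ("alt_depth", "total_depth", "protein_pos", "aa_ref", "aa_alt")
        ):
            logger.warning("%s line %d rejected: missing depth or protein annotation", path, i)
            continue
        try:
            variants.append(_variant_from_row(row, i))
        except ValueError as exc:
            logger.warning("%s line %d rejected: %s", path, i, exc)
    return variants


def read_variants_vcf(path: str | Path) -> list[SomaticVariant]:
    """Read the minimal VCF dialect (AD/DP in FORMAT, annotation in INFO)."""
    variants: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample column carrying AD/DP")
        sample = samples[0]
        for rec in vcf:
            info = rec.info
            fmt = rec.samples[sample]
            try:
                gene = info["GENE"]
                transcript = info.get("TRANSCRIPT")
                variants.append(
                    SomaticVariant(
                        gene=str(gene),
                        transcript=None if transcript is None else str(transcript),
                        chrom=str(rec.chrom),
                        pos=int(rec.pos),
                        ref=str(rec.ref),
                        alt=str(rec.alts[0]) if rec.alts else "N",
                        aa_ref=str(info["AAREF"]),
                        aa_alt=str(info["AAALT"]),
                        protein_pos=int(info["PPOS"]),
                        alt_depth=int(fmt["AD"]),
                        total_depth=int(fmt["DP"]),
                        consequence=str(info["CSQ"]),
                    )
                )
            except (KeyError, TypeError) as exc:
                logger.warning(
                    "%s %s:%d rejected: missing depth or protein annotation (%s)",
                    path, rec.chrom, rec.pos, exc,
                )
            except ValueError as exc:
                logger.warning("%s %s:%d rejected: %s", path, rec.chrom, rec.pos, exc)
    return variants


def read_variants(path: str | Path, dialect: str | None = None) -> list[SomaticVariant]:
    """Read variants from a minimal VCF or its TSV mirror.

    ``dialect`` is ``"vcf"`` or ``"tsv"``; when omitted it is inferred from
    the file suffix.
    """
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if dialect == "vcf":
        return read_variants_vcf(path)
    if dialect == "tsv":
        return read_variants_tsv(path)
    raise ValueError(f"unknown variant dialect {dialect!r}")


def variants_to_frame(variants: Iterable[SomaticVariant], with_vaf: bool = False) -> pd.DataFrame:
    rows = []
    for v in variants:
        row = {
            "gene": v.gene, "transcript": v.transcript or "", "chrom": v.chrom,
            "pos": v.pos, "ref": v.ref, "alt": v.alt, "aa_ref": v.aa_ref,
            "aa_alt": v.aa_alt, "protein_pos": v.protein_pos,
            "alt_depth": v.alt_depth, "total_depth": v.total_depth,
            "consequence": v.consequence,
        }
        if with_vaf:
            row["vaf"] = v.vaf
        rows.append(row)
    cols = VARIANT_TSV_COLUMNS + (["vaf"] if with_vaf else [])
    return pd.DataFrame(rows, columns=cols)


def write_variants_tsv(
    variants: Iterable[SomaticVariant], path: str | Path, with_vaf: bool = False
) -> None:
    variants_to_frame(variants, with_vaf=with_vaf).to_csv(path, sep="\t", index=False)
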