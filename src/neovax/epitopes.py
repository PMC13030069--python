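"""Mutation-spanning peptide enumeration.

For each surviving missense variant, builds the mutant protein and
enumerates every peptide window that contains the mutated residue, at the
MHC-I lengths (8-10 aa, scored against H2-Kb/H2-Db) and the MHC-II lengths
(12-14 aa, scored against I-Ab). For a mutation at interior position p of a
protein of length n, the number of valid windows of length L is
min(p, L, n - L + 1, n - p + 1) when positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variant_intake import AMINO_ACIDS, SomaticVariant

CLASS_I = "I"
CLASS_II = "II"
CLASS_I_LENGTHS = frozenset({8, 9, 10})
CLASS_II_LENGTHS = frozenset({12, 13, 14})


@dataclass(frozen=True)
class CandidatePeptide:
    """A mutation-spanning peptide tied to its source variant and MHC class.

    ``start`` is the 1-based index of the window in the mutant protein;
    ``mutation_offset`` is the 1-based index of the mutated residue within
    the peptide.
    """

    sequence: str
    start: int
    mutation_offset: int
    mhc_class: str
    source_variant: SomaticVariant

    def __post_init__(self) -> None:
        if not 1 <= self.mutation_offset <= len(self.sequence):
            raise ValueError("mutation_offset outside the peptide")
        if self.sequence[self.mutation_offset - 1] != self.source_variant.aa_alt:
            raise ValueError(
                f"{self.source_variant.label}: peptide residue at mutation_offset "
                "does not equal the alternate amino acid"
            )
        if self.mhc_class not in (CLASS_I, CLASS_II):
            raise ValueError(f"unknown MHC class {self.mhc_class!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def mutate_protein(protein: str, protein_pos: int, aa_ref: str, aa_alt: str) -> str:
    """Apply a single amino-acid substitution at 1-based ``protein_pos``.

    Raises a consistency error when the protein does not carry ``aa_ref``
    at that position (annotation/proteome mismatch).
    """
    if not 1 <= protein_pos <= len(protein):
        raise ValueError(
            f"protein_pos {protein_pos} outside protein of length {len(protein)}"
        )
    found = protein[protein_pos - 1]
    if found != aa_ref:
        raise ValueError(
            f"reference mismatch at position {protein_pos}: proteome has {found}, "
            f"annotation says {aa_ref}"
        )
    return protein[: protein_pos - 1] + aa_alt + protein[protein_pos:]


def enumerate_windows(
    mutant_protein: str,
    protein_pos: int,
    lengths: Iterable[int],
    mhc_class: str,
    source_variant: SomaticVariant,
) -> list[CandidatePeptide]:
    """All windows of the given lengths that lie inside the protein and
    contain ``protein_pos``; duplicates within the variant collapsed keeping
    the first occurrence; output sorted by (length, start)."""
    n = len(mutant_protein)
    if not 1 <= protein_pos <= n:
        raise ValueError(f"protein_pos {protein_pos} outside protein of length {n}")
    out: list[CandidatePeptide] = []
    seen: set[str] = set()
    for L in sorted(set(lengths)):
        lo = max(1, protein_pos - L + 1)
        hi = min(protein_pos, n - L + 1)
        for start in range(lo, hi + 1):
            seq = mutant_protein[start - 1 : start - 1 + L]
            if seq in seen:
                continue
            seen.add(seq)
            out.append(
                CandidatePeptide(
                    sequence=seq,
                    start=start,
                    mutation_offset=protein_pos - start + 1,
                    mhc_class=mhc_class,
                    source_variant=source_variant,
                )
            )
    return out


def enumerate_candidates(
    variants: Sequence[SomaticVariant],
    proteome: Mapping[str, str],
    class_i_lengths: Iterable[int] = CLASS_I_LENGTHS,
    class_ii_lengths: Iterable[int] = CLASS_II_LENGTHS,
) -> list[CandidatePeptide]:
    """Enumerate class-I and class-II candidates for every variant."""
    candidates: list[CandidatePeptide] = []
    for v in variants:
        if v.gene not in proteome:
            raise KeyError(f"no protein sequence for gene {v.gene}")
        mutant = mutate_protein(proteome[v.gene], v.protein_pos, v.aa_ref, v.aa_alt)
        candidates += enumerate_windows(mutant, v.protein_pos, class_i_lengths, CLASS_I, v)
        candidates += enumerate_windows(mutant, v.protein_pos, class_ii_lengths, CLASS_II, v)
    return candidates


def candidates_to_frame(candidates: Iterable[CandidatePeptide]) -> pd.DataFrame:
    rows = [
        {
            "sequence": c.sequence,
            "mhc_class": c.mhc_class,
            "start": c.start,
            "mutation_offset": c.mutation_offset,
            "gene": c.source_variant.gene,
            "chrom": c.source_variant.chrom,
            "pos": c.source_variant.pos,
            "protein_pos": c.source_variant.protein_pos,
            "aa_ref": c.source_variant.aa_ref,
            "aa_alt": c.source_variant.aa_alt,
            "alt_depth": c.source_variant.alt_depth,
            "total_depth": c.source_variant.total_depth,
            "consequence": c.source_variant.consequence,
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sequence", "mhc_class", "start", "mutation_offset", "gene", "chrom",
            "pos", "protein_pos", "aa_ref", "aa_alt", "alt_depth", "total_depth",
            "consequence",
        ],
    )


def frame_to_candidates(df: pd.DataFrame) -> list[CandidatePeptide]:
    out = []
    for row in df.to_dict("records"):
        variant = SomaticVariant(
            gene=str(row["gene"]), chrom=str(row["chrom"]), pos=int(row["pos"]),
            aa_ref=str(row["aa_ref"]), aa_alt=str(row["aa_alt"]),
            protein_pos=int(row["protein_pos"]), alt_depth=int(row["alt_depth"]),
            total_depth=int(row["total_depth"]), consequence=str(row["consequence"]),
        )
        out.append(
            CandidatePeptide(
                sequence=str(row["sequence"]), start=int(row["start"]),
                mutation_offset=int(row["mutation_offset"]),
                mhc_class=str(row["mhc_class"]), source_variant=variant,
            )
        )
    return out


def write_candidates(
    candidates: Sequence[CandidatePeptide], tsv_path: str | Path, fasta_path: str | Path | None = None
) -> None:
    """Candidate TSV plus a FASTA of unique peptide sequences for external
    binding predictors."""
    candidates_to_frame(candidates).to_csv(tsv_path, sep="\t", index=False)
    if fasta_path is not None:
        seen: set[str] = set()
        records = []
        for c in candidates:
            if c.sequence in seen:
                continue
            seen.add(c.sequence)
            records.append(
                SeqRecord(
                    Seq(c.sequence),
                    id=f"{c.source_variant.label}_{c.mhc_class}_{c.start}",
                    description="",
                )
            )
        SeqIO.write(records, str(fasta_path), "fasta")
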