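"""Pentatope vaccine construct assembly.

Selected core epitopes are extended to 27-mers with the mutation at residue
14 (sliding to fit near protein termini, never padding), joined five at a
time by glycine/serine linkers — the central linker GGSGGGGSGG between
adjacent epitopes and the terminal linker GGSLGGGGSG on each side of the
epitope block — and framed by an N-terminal signal peptide (SP) and a
C-terminal MHC class I trafficking signal domain (MITD):

    SP + term + e1 + central + e2 + ... + central + e5 + term + MITD

With five full-length epitopes and the default sequences the protein is
26 + 10 + 5*27 + 4*10 + 10 + 55 = 276 aa. The protein is reverse-translated
with a deterministic per-residue codon policy and emitted as protein FASTA,
CDS FASTA, an annotated GenBank record and a per-epitope design report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codon_tables import HUMAN_HIGH_FREQUENCY_CODONS
from .epitopes import CLASS_I, CLASS_II
from .variant_intake import AMINO_ACIDS, SomaticVariant

EXTENDED_LENGTH = 27
MUTATION_ANCHOR = 14  # 1-based target offset of the mutation in the 27-mer

DEFAULT_SIGNAL_PEPTIDE = "MRVTAPRTLILLLSGALALTETWAGS"
DEFAULT_MITD = "IVGIVAGLAVLAVVVIGAVVATVMCRRKSSGGKGGSYSQAASSDSAQGSDVSLTA"
DEFAULT_CENTRAL_LINKER = "GGSGGGGSGG"
DEFAULT_TERMINAL_LINKER = "GGSLGGGGSG"


@dataclass(frozen=True)
class ExtendedEpitope:
    """A core epitope extended for encoding (27 aa nominal, mutation at 14).

    ``shifted`` is set when a protein terminus forced the mutation off
    residue 14 (the window slides to stay inside the protein) or when the
    whole protein is shorter than 27 residues.
    """

    sequence: str
    mutation_offset: int
    source_variant: SomaticVariant
    shifted: bool
    core_sequence: str | None = None
    allele: str | None = None
    affinity_nm: float | None = None
    mhc_class: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.mutation_offset <= len(self.sequence):
            raise ValueError("mutation_offset outside epitope")
        if self.sequence[self.mutation_offset - 1] != self.source_variant.aa_alt:
            raise ValueError(
                f"{self.source_variant.label}: mutant residue not at recorded offset"
            )


@dataclass(frozen=True)
class ConstructLayout:
    """Sequence elements and geometry of one polyepitope construct."""

    signal_peptide: str = DEFAULT_SIGNAL_PEPTIDE
    mitd: str = DEFAULT_MITD
    central_linker: str = DEFAULT_CENTRAL_LINKER
    terminal_linker: str = DEFAULT_TERMINAL_LINKER
    epitopes_per_construct: int = 5
    utr5: str = ""  # optional nucleotide elements, prepended/appended verbatim
    utr3: str = ""

    def __post_init__(self) -> None:
        for name in ("signal_peptide", "mitd", "central_linker", "terminal_linker"):
            seq = getattr(self, name)
            if any(ch not in AMINO_ACIDS for ch in seq):
                raise ValueError(f"{name} contains non-amino-acid characters")
        if self.epitopes_per_construct < 1:
            raise ValueError("epitopes_per_construct must be >= 1")

    def protein_length(self, n_epitopes: int, epitope_length: int = EXTENDED_LENGTH) -> int:
        """Closed-form construct length for n full-length epitopes."""
        return (
            len(self.signal_peptide)
            + 2 * len(self.terminal_linker)
            + n_epitopes * epitope_length
            + (n_epitopes - 1) * len(self.central_linker)
            + len(self.mitd)
        )


@dataclass
class VaccineConstruct:
    """One assembled polyepitope construct (protein and, once reverse-
    translated, CDS). ``feature_map`` holds 1-based inclusive protein
    coordinates of every segment, in order, partitioning the protein."""

    name: str
    mhc_class: str
    epitopes: list[ExtendedEpitope]
    protein: str
    feature_map: list[tuple[str, int, int]]
    cds: str | None = None


def extend_to_27mer(
    mutant_protein: str,
    protein_pos: int,
    source_variant: SomaticVariant,
    **core_info,
) -> ExtendedEpitope:
    """Extend around the mutation to 27 aa with the mutation at residue 14.

    If the mutation lies within 13 residues of a terminus the 27-residue
    window slides to stay inside the protein (``shifted=True``); a protein
    shorter than 27 residues is returned whole.
    """
    n = len(mutant_protein)
    if not 1 <= protein_pos <= n:
        raise ValueError(f"protein_pos {protein_pos} outside protein of length {n}")
    if n < EXTENDED_LENGTH:
        start, end = 1, n
    else:
        start = protein_pos - (MUTATION_ANCHOR - 1)
        if start < 1:
            start = 1
        end = start + EXTENDED_LENGTH - 1
        if end > n:
            end = n
            start = end - EXTENDED_LENGTH + 1
    offset = protein_pos - start + 1
    return ExtendedEpitope(
        sequence=mutant_protein[start - 1 : end],
        mutation_offset=offset,
        source_variant=source_variant,
        shifted=(offset != MUTATION_ANCHOR) or (end - start + 1 != EXTENDED_LENGTH),
        **core_info,
    )


def assemble_construct(
    epitopes: Sequence[ExtendedEpitope],
    layout: ConstructLayout = ConstructLayout(),
    name: str = "construct",
    mhc_class: str = CLASS_I,
    strict: bool = False,
) -> VaccineConstruct:
    """Concatenate SP, linkers, epitopes and MITD, recording the feature map."""
    if not epitopes:
        raise ValueError("cannot assemble a construct with zero epitopes")
    if len(epitopes) != layout.epitopes_per_construct:
        msg = (
            f"{name}: {len(epitopes)} epitopes supplied but layout expects "
            f"{layout.epitopes_per_construct}"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)

    segments: list[tuple[str, str]] = [("SP", layout.signal_peptide),
                                       ("terminal_linker", layout.terminal_linker)]
    for i, epi in enumerate(epitopes):
        if i:
            segments.append(("central_linker", layout.central_linker))
        segments.append((f"epitope_{i + 1}_{epi.source_variant.label}", epi.sequence))
    segments.append(("terminal_linker", layout.terminal_linker))
    segments.append(("MITD", layout.mitd))

    protein = ""
    feature_map: list[tuple[str, int, int]] = []
    cursor = 1
    for seg_name, seq in segments:
        feature_map.append((seg_name, cursor, cursor + len(seq) - 1))
        protein += seq
        cursor += len(seq)
    return VaccineConstruct(name, mhc_class, list(epitopes), protein, feature_map)


def reverse_translate(
    protein: str, codon_policy: Mapping[str, str] = HUMAN_HIGH_FREQUENCY_CODONS
) -> str:
    """Deterministic CDS for ``protein`` plus a single stop codon.

    The default policy picks the most-used human codon for every residue;
    any amino-acid -> codon mapping covering the 20 residues and ``*`` can
    be supplied instead.
    """
    try:
        cds = "".join(codon_policy[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc} in protein") from exc
    return cds + codon_policy["*"]


def _strength_key(epi: ExtendedEpitope) -> tuple:
    nm = epi.affinity_nm if epi.affinity_nm is not None else float("inf")
    return (nm, epi.sequence)


def build_vaccine_pair(
    class_i_epitopes: Sequence[ExtendedEpitope],
    class_ii_epitopes: Sequence[ExtendedEpitope],
    layout: ConstructLayout = ConstructLayout(),
    names: tuple[str, str] = ("pentatope_mhc_i", "pentatope_mhc_ii"),
    codon_policy: Mapping[str, str] = HUMAN_HIGH_FREQUENCY_CODONS,
    strict: bool = False,
) -> tuple[VaccineConstruct, VaccineConstruct]:
    """One construct per MHC class, epitopes ordered strongest binder first,
    reverse-translated under the shared layout."""
    pools = {CLASS_I: list(class_i_epitopes), CLASS_II: list(class_ii_epitopes)}
    for mhc_class, pool in pools.items():
        if not pool:
            raise ValueError(f"no epitopes supplied for MHC class {mhc_class}")
    constructs = []
    for mhc_class, construct_name in zip((CLASS_I, CLASS_II), names):
        ordered = sorted(pools[mhc_class], key=_strength_key)
        construct = assemble_construct(ordered, layout, construct_name, mhc_class, strict)
        construct.cds = reverse_translate(construct.protein, codon_policy)
        constructs.append(construct)
    return constructs[0], constructs[1]


# ---------------------------------------------------------------------------
# output files


def construct_to_genbank_record(construct: VaccineConstruct) -> SeqRecord:
    record = SeqRecord(
        Seq(construct.protein),
        id=construct.name,
        name=construct.name[:16],
        description=f"polyepitope construct, MHC class {construct.mhc_class}",
        annotations={
            "molecule_type": "protein",
            "comment": (
                "Layout: SP + terminal linker + epitope block (central linker "
                "between adjacent epitopes) + terminal linker + MITD; terminal "
                "linkers one per side of the epitope block."
            ),
        },
    )
    epitope_iter = iter(construct.epitopes)
    for seg_name, start, end in construct.feature_map:
        qualifiers: dict[str, list[str]] = {"label": [seg_name]}
        if seg_name.startswith("epitope_"):
            epi = next(epitope_iter)
            qualifiers["note"] = [
                f"gene={epi.source_variant.gene} "
                f"mutation={epi.source_variant.aa_ref}{epi.source_variant.protein_pos}"
                f"{epi.source_variant.aa_alt} mutation_offset={epi.mutation_offset} "
                f"shifted={epi.shifted}"
            ]
        record.features.append(
            SeqFeature(FeatureLocation(start - 1, end), type="Region", qualifiers=qualifiers)
        )
    return record


def design_report(constructs: Iterable[VaccineConstruct]) -> pd.DataFrame:
    """Per-epitope design report: one row per encoded epitope."""
    rows = []
    for construct in constructs:
        for rank, epi in enumerate(construct.epitopes, start=1):
            v = epi.source_variant
            rows.append(
                {
                    "construct": construct.name,
                    "mhc_class": construct.mhc_class,
                    "rank": rank,
                    "gene": v.gene,
                    "mutation": f"{v.aa_ref}{v.protein_pos}{v.aa_alt}",
                    "core_peptide": epi.core_sequence or "",
                    "allele": epi.allele or "",
                    "affinity_nm": epi.affinity_nm,
                    "epitope_27mer": epi.sequence,
                    "mutation_offset": epi.mutation_offset,
                    "shifted": epi.shifted,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "construct", "mhc_class", "rank", "gene", "mutation", "core_peptide",
            "allele", "affinity_nm", "epitope_27mer", "mutation_offset", "shifted",
        ],
    )


def write_outputs(
    constructs: Sequence[VaccineConstruct], directory: str | Path
) -> dict[str, Path]:
    """Emit protein FASTA, CDS FASTA, annotated GenBank and the design report."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_fasta": directory / "constructs_protein.fasta",
        "cds_fasta": directory / "constructs_cds.fasta",
        "genbank": directory / "constructs.gb",
        "report": directory / "design_report.tsv",
    }
    SeqIO.write(
        [SeqRecord(Seq(c.protein), id=c.name, description=f"MHC class {c.mhc_class} protein")
         for c in constructs],
        str(paths["protein_fasta"]), "fasta",
    )
    missing_cds = [c.name for c in constructs if c.cds is None]
    if missing_cds:
        raise ValueError(f"constructs lack a CDS (run reverse_translate): {missing_cds}")
    SeqIO.write(
        [SeqRecord(Seq(c.cds), id=c.name, description=f"MHC class {c.mhc_class} CDS")
         for c in constructs],
        str(paths["cds_fasta"]), "fasta",
    )
    SeqIO.write(
        [construct_to_genbank_record(c) for c in constructs], str(paths["genbank"]), "genbank"
    )
    design_report(constructs).to_csv(paths["report"], sep="\t", index=False)
    return paths
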