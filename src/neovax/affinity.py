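"""Affinity scoring, ranking and top-k epitope selection.

Candidate peptides are scored against the C57BL/6 (H-2b) allele set —
H2-Kb and H2-Db for MHC class I, I-Ab for class II — through a pluggable
scorer interface (``score(sequence, allele) -> affinity in nM``, lower is
stronger). Records are sorted ascending by predicted affinity and the ten
strongest per class are selected. Trained external predictors (netMHCpan-
style tools) plug in through :class:`TabularScorer`; the deterministic
:class:`SurrogateScorer` serves tests and dry runs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import pandas as pd

from .epitopes import CLASS_I, CLASS_II, CandidatePeptide
from .variant_intake import AMINO_ACIDS

logger = logging.getLogger(__name__)

CLASS_I_ALLELES = ("H2-Kb", "H2-Db")
CLASS_II_ALLELES = ("I-Ab",)
DEFAULT_ALLELES = CLASS_I_ALLELES + CLASS_II_ALLELES

_ALLELE_CLASS = {"H2-Kb": CLASS_I, "H2-Db": CLASS_I, "I-Ab": CLASS_II}


def allele_class(allele: str) -> str:
    try:
        return _ALLELE_CLASS[allele]
    except KeyError:
        raise ValueError(
            f"unknown allele {allele!r}; known: {sorted(_ALLELE_CLASS)}"
        ) from None


class Scorer(Protocol):
    """Pluggable binding-affinity predictor contract."""

    scorer_id: str

    def score(self, sequence: str, allele: str) -> float:
        """Predicted binding affinity in nM (positive; lower = stronger)."""
        ...


@dataclass(frozen=True)
class AffinityRecord:
    """Predicted affinity of one (peptide, allele) pair."""

    peptide: CandidatePeptide
    allele: str
    affinity_nm: float
    scorer_id: str
    binder: bool | None = None

    def __post_init__(self) -> None:
        if self.affinity_nm <= 0:
            raise ValueError(f"affinity must be positive nM, got {self.affinity_nm}")
        if allele_class(self.allele) != self.peptide.mhc_class:
            raise ValueError(
                f"allele {self.allele} is class {allele_class(self.allele)} but "
                f"peptide {self.peptide.sequence} is class {self.peptide.mhc_class}"
            )


@dataclass(frozen=True)
class SelectionConfig:
    """How the ranked list is reduced to the vaccine shortlist.

    ``binder_threshold_nm`` flags binders at affinity <= threshold
    (boundary inclusive, lower-is-stronger IC50 convention); set
    ``binder_above_threshold`` to invert the direction.
    ``per_variant_best_first`` reduces each variant to its single best
    window/allele before the top-k cut, maximizing mutation diversity in
    the construct; switching it off gives a plain window-level top-k.
    """

    top_k: int = 10
    binder_threshold_nm: float = 1000.0
    per_variant_best_first: bool = True
    binder_above_threshold: bool = False

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.binder_threshold_nm <= 0:
            raise ValueError("binder_threshold_nm must be positive")


class SurrogateScorer:
    """Deterministic pseudo-affinity predictor.

    Combines a fixed per-allele position/residue weight table with a stable
    whole-sequence hash term; both derive from BLAKE2 digests of the inputs,
    so identical (sequence, allele) pairs always map to the identical value
    in (1, 50000] nM with no randomness at call time. It carries no binding
    biology — it exists to exercise the ranking machinery reproducibly.
    """

    scorer_id = "surrogate-blake2-v1"

    _MAX_NM = 50_000.0
    _FRAME = 9  # positions folded modulo a 9-residue frame

    @staticmethod
    def _unit(material: str) -> float:
        digest = hashlib.blake2b(material.encode(), digest_size=8).digest()
        return int.from_bytes(digest, "big") / 2**64

    def score(self, sequence: str, allele: str) -> float:
        allele_class(allele)  # validates allele
        if not sequence or any(ch not in AMINO_ACIDS for ch in sequence):
            raise ValueError(f"invalid residue in peptide {sequence!r}")
        positional = sum(
            self._unit(f"{allele}|{i % self._FRAME}|{res}")
            for i, res in enumerate(sequence)
        ) / len(sequence)
        whole = self._unit(f"{allele}||{sequence}")
        x = 0.6 * positional + 0.4 * whole
        return self._MAX_NM ** max(x, 1e-9)


class TabularScorer:
    """Adapter for external predictor output (netMHCpan-style tables).

    Reads a tab-separated table with columns ``peptide``, ``allele`` and
    ``affinity_nm`` and serves lookups from it; peptides absent from the
    table raise ``KeyError`` (and are skipped with a logged error by
    :func:`score_candidates`).
    """

    def __init__(self, path: str | Path):
        df = pd.read_csv(path, sep="\t")
        required = {"peptide", "allele", "affinity_nm"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: scorer table needs columns {sorted(required)}")
        self._table = {
            (str(r["peptide"]), str(r["allele"])): float(r["affinity_nm"])
            for r in df.to_dict("records")
        }
        self.scorer_id = f"external:{Path(path).name}"

    def score(self, sequence: str, allele: str) -> float:
        return self._table[(sequence, allele)]


def score_candidates(
    peptides: Iterable[CandidatePeptide],
    alleles: Sequence[str],
    scorer: Scorer,
) -> list[AffinityRecord]:
    """One record per (peptide, class-compatible allele) pair.

    A scorer failure on a single pair skips that record with a logged error
    rather than aborting the run.
    """
    by_class: dict[str, list[str]] = {CLASS_I: [], CLASS_II: []}
    for a in alleles:
        by_class[allele_class(a)].append(a)
    records: list[AffinityRecord] = []
    for pep in peptides:
        for allele in by_class[pep.mhc_class]:
            try:
                nm = float(scorer.score(pep.sequence, allele))
            except Exception as exc:  # scorer plugins may fail per peptide
                logger.error(
                    "scorer %s failed on (%s, %s): %s",
                    getattr(scorer, "scorer_id", "?"), pep.sequence, allele, exc,
                )
                continue
            records.append(AffinityRecord(pep, allele, nm, getattr(scorer, "scorer_id", "?")))
    return records


def classify_binders(
    records: Iterable[AffinityRecord], config: SelectionConfig = SelectionConfig()
) -> list[AffinityRecord]:
    """Flag each record binder/non-binder against the affinity threshold."""
    out = []
    for r in records:
        if config.binder_above_threshold:
            flag = r.affinity_nm >= config.binder_threshold_nm
        else:
            flag = r.affinity_nm <= config.binder_threshold_nm
        out.append(replace(r, binder=flag))
    return out


def _sort_key(record: AffinityRecord) -> tuple:
    # deterministic total order: affinity, then peptide sequence, then start
    return (record.affinity_nm, record.peptide.sequence, record.peptide.start)


def rank_and_select(
    records: Iterable[AffinityRecord],
    config: SelectionConfig = SelectionConfig(),
) -> dict[str, list[AffinityRecord]]:
    """Ascending-affinity selection of the top-k epitopes per MHC class.

    Per class: each peptide window keeps its best (lowest-nM) allele; with
    ``per_variant_best_first`` each variant is then reduced to its single
    best window; the survivors are sorted ascending by affinity (ties broken
    by peptide sequence, then start) and the first ``top_k`` are returned.
    Returns ``{"I": [...], "II": [...]}``; each record carries the winning
    allele and affinity.
    """
    per_class: dict[str, list[AffinityRecord]] = {CLASS_I: [], CLASS_II: []}
    for r in records:
        per_class[r.peptide.mhc_class].append(r)

    selected: dict[str, list[AffinityRecord]] = {}
    for mhc_class, recs in per_class.items():
        # best allele per window
        best_window: dict[tuple, AffinityRecord] = {}
        for r in recs:
            key = (r.peptide.source_variant.key, r.peptide.sequence, r.peptide.start)
            cur = best_window.get(key)
            if cur is None or _sort_key(r) < _sort_key(cur):
                best_window[key] = r
        pool = list(best_window.values())
        if config.per_variant_best_first:
            best_variant: dict[tuple, AffinityRecord] = {}
            for r in pool:
                key = r.peptide.source_variant.key
                cur = best_variant.get(key)
                if cur is None or _sort_key(r) < _sort_key(cur):
                    best_variant[key] = r
            pool = list(best_variant.values())
        pool.sort(key=_sort_key)
        selected[mhc_class] = pool[: config.top_k]
    return selected


def records_to_frame(records: Iterable[AffinityRecord]) -> pd.DataFrame:
    from .epitopes import candidates_to_frame

    recs = list(records)
    peptide_frame = candidates_to_frame([r.peptide for r in recs])
    peptide_frame.insert(0, "allele", [r.allele for r in recs])
    peptide_frame.insert(1, "affinity_nm", [r.affinity_nm for r in recs])
    peptide_frame["scorer_id"] = [r.scorer_id for r in recs]
    peptide_frame["binder"] = [r.binder for r in recs]
    return peptide_frame


def frame_to_records(df: pd.DataFrame) -> list[AffinityRecord]:
    from .epitopes import frame_to_candidates

    peptides = frame_to_candidates(df)
    out = []
    for pep, row in zip(peptides, df.to_dict("records")):
        binder = row.get("binder")
        if pd.isna(binder):
            binder = None
        else:
            binder = bool(binder)
        out.append(
            AffinityRecord(
                pep, str(row["allele"]), float(row["affinity_nm"]),
                str(row.get("scorer_id", "?")), binder,
            )
        )
    return out
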