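"""End-to-end orchestration: simulate -> filter -> enumerate -> score ->
select -> construct, with a validated configuration and a run manifest.

The manifest records the per-stage record counts (which are monotonically
non-increasing through the filter cascade) and every threshold, so a run is
auditable and exactly reproducible from its config, inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import affinity, constructs, epitopes, synthetic_cohort, variant_intake
from .affinity import DEFAULT_ALLELES, SelectionConfig, SurrogateScorer, TabularScorer
from .constructs import ConstructLayout
from .epitopes import CLASS_I, CLASS_II, CLASS_I_LENGTHS, CLASS_II_LENGTHS
from .synthetic_cohort import CohortSpec
from .variant_intake import ExpressionTable, FilterThresholds

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_INPUT_ERROR = 3
EXIT_STAGE_FAILURE = 4


class ConfigError(ValueError):
    """Raised when a configuration file violates the schema."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    thresholds: FilterThresholds = FilterThresholds()
    selection: SelectionConfig = SelectionConfig()
    layout: ConstructLayout = ConstructLayout()
    alleles: tuple[str, ...] = DEFAULT_ALLELES
    class_i_lengths: frozenset[int] = CLASS_I_LENGTHS
    class_ii_lengths: frozenset[int] = CLASS_II_LENGTHS
    scorer: str = "surrogate"
    seed: int = 0

    def make_scorer(self) -> affinity.Scorer:
        if self.scorer == "surrogate":
            return SurrogateScorer()
        if self.scorer.startswith("external:"):
            return TabularScorer(self.scorer.split(":", 1)[1])
        raise ConfigError(f"unknown scorer {self.scorer!r}")


_SECTION_FIELDS = {
    "thresholds": {"vaf_min", "fpkm_min", "vaf_strict"},
    "selection": {"top_k", "binder_threshold_nm", "per_variant_best_first",
                  "binder_above_threshold"},
    "layout": {"signal_peptide", "mitd", "central_linker", "terminal_linker",
               "epitopes_per_construct", "utr5", "utr3"},
}
_TOP_KEYS = set(_SECTION_FIELDS) | {
    "alleles", "class_i_lengths", "class_ii_lengths", "scorer", "seed",
}


def validate_config(source: str | Path | Mapping[str, Any] | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file or mapping.

    Missing keys take the standard defaults (VAF >= 0.1, FPKM >= 1, top 10
    per class, 8-10/12-14 aa windows, H2-Kb/H2-Db/I-Ab, 27-mer extension
    with the mutation at residue 14, the standard SP/linker/MITD layout).
    Unknown keys are rejected by name.
    """
    if source is None:
        raw: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{source}: config must be a key-value mapping")

    unknown = sorted(set(raw) - _TOP_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {unknown}")
    for section, allowed in _SECTION_FIELDS.items():
        sub = raw.get(section) or {}
        if not isinstance(sub, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        bad = sorted(set(sub) - allowed)
        if bad:
            raise ConfigError(f"unknown keys in section {section!r}: {bad}")

    try:
        return PipelineConfig(
            thresholds=FilterThresholds(**(raw.get("thresholds") or {})),
            selection=SelectionConfig(**(raw.get("selection") or {})),
            layout=ConstructLayout(**(raw.get("layout") or {})),
            alleles=tuple(raw.get("alleles", DEFAULT_ALLELES)),
            class_i_lengths=frozenset(raw.get("class_i_lengths", CLASS_I_LENGTHS)),
            class_ii_lengths=frozenset(raw.get("class_ii_lengths", CLASS_II_LENGTHS)),
            scorer=str(raw.get("scorer", "surrogate")),
            seed=int(raw.get("seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _write_manifest(manifest: dict, out_dir: Path) -> Path:
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def run_simulate(
    spec: CohortSpec, out_dir: str | Path, thresholds: FilterThresholds = FilterThresholds()
) -> dict:
    """Generate a synthetic cohort and write its file set plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic_cohort.simulate_cohort(spec, thresholds)
    paths = synthetic_cohort.write_cohort(cohort, out_dir)
    manifest = {
        "stage": "simulate",
        "spec": asdict(spec),
        "counts": {
            "genes": len(cohort.proteome),
            "variants": len(cohort.variants),
            "expressed_genes": len(cohort.expression),
        },
        "files": {k: str(p) for k, p in paths.items()},
    }
    _write_manifest(manifest, out_dir)
    return manifest


def run_design(
    variants_path: str | Path,
    expression_path: str | Path,
    proteome_path: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Run the full design chain and write all artifacts plus the manifest.

    Stages: read inputs, nonsynonymous filter, VAF true-positive gate,
    VAF/FPKM expression gate, window enumeration, affinity scoring,
    top-k selection per class, 27-mer extension, pentatope assembly.
    Re-running with identical config and inputs reproduces identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "stage": "design",
        "config": {
            "thresholds": asdict(config.thresholds),
            "selection": asdict(config.selection),
            "layout": asdict(config.layout),
            "alleles": list(config.alleles),
            "class_i_lengths": sorted(config.class_i_lengths),
            "class_ii_lengths": sorted(config.class_ii_lengths),
            "scorer": config.scorer,
            "seed": config.seed,
        },
        "counts": {},
    }
    counts = manifest["counts"]
    stage = "read_inputs"
    try:
        variants = variant_intake.read_variants(variants_path)
        expression = ExpressionTable.from_tsv(expression_path)
        proteome = synthetic_cohort.read_proteome_fasta(proteome_path)
        counts["variants_read"] = len(variants)

        stage = "filter_nonsynonymous"
        nonsyn = variant_intake.filter_nonsynonymous(variants)
        counts["nonsynonymous"] = len(nonsyn)

        stage = "filter_true_positive"
        true_pos = variant_intake.filter_true_positive(nonsyn, config.thresholds)
        counts["true_positive"] = len(true_pos)

        stage = "filter_expressed"
        expressed = variant_intake.filter_expressed(true_pos, expression, config.thresholds)
        counts["expressed"] = len(expressed)
        variant_intake.write_variants_tsv(expressed, out_dir / "filtered_variants.tsv", with_vaf=True)

        stage = "enumerate_candidates"
        candidates = epitopes.enumerate_candidates(
            expressed, proteome, config.class_i_lengths, config.class_ii_lengths
        )
        counts["candidates_class_i"] = sum(c.mhc_class == CLASS_I for c in candidates)
        counts["candidates_class_ii"] = sum(c.mhc_class == CLASS_II for c in candidates)
        epitopes.write_candidates(
            candidates, out_dir / "candidates.tsv", out_dir / "candidates.fasta"
        )

        stage = "score_candidates"
        scorer = config.make_scorer()
        records = affinity.score_candidates(candidates, config.alleles, scorer)
        records = affinity.classify_binders(records, config.selection)
        counts["scored"] = len(records)
        affinity.records_to_frame(records).to_csv(
            out_dir / "affinities.tsv", sep="\t", index=False
        )

        stage = "rank_and_select"
        selected = affinity.rank_and_select(records, config.selection)
        counts["selected_class_i"] = len(selected[CLASS_I])
        counts["selected_class_ii"] = len(selected[CLASS_II])
        selected_records = selected[CLASS_I] + selected[CLASS_II]
        affinity.records_to_frame(selected_records).to_csv(
            out_dir / "selected_epitopes.tsv", sep="\t", index=False
        )

        stage = "assemble_constructs"
        per_construct = config.layout.epitopes_per_construct
        extended: dict[str, list[constructs.ExtendedEpitope]] = {}
        for mhc_class in (CLASS_I, CLASS_II):
            extended[mhc_class] = [
                extend_selected(rec, proteome, mhc_class) for rec in selected[mhc_class][:per_construct]
            ]
        pair = constructs.build_vaccine_pair(
            extended[CLASS_I], extended[CLASS_II], config.layout
        )
        counts["constructs"] = len(pair)
        paths = constructs.write_outputs(pair, out_dir)
        manifest["files"] = {k: str(p) for k, p in paths.items()}
    except Exception as exc:
        manifest["FAILED"] = {"stage": stage, "error": str(exc)}
        _write_manifest(manifest, out_dir)
        raise StageError(stage, exc) from exc

    _write_manifest(manifest, out_dir)
    return manifest


def extend_selected(
    record: affinity.AffinityRecord,
    proteome: Mapping[str, str],
    mhc_class: str,
) -> constructs.ExtendedEpitope:
    """27-mer extension of one selected core epitope, carrying its core
    peptide, winning allele and affinity into the design report."""
    v = record.peptide.source_variant
    mutant = epitopes.mutate_protein(proteome[v.gene], v.protein_pos, v.aa_ref, v.aa_alt)
    return constructs.extend_to_27mer(
        mutant,
        v.protein_pos,
        v,
        core_sequence=record.peptide.sequence,
        allele=record.allele,
        affinity_nm=record.affinity_nm,
        mhc_class=mhc_class,
    )
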