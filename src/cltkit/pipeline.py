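"""End-to-end pipeline orchestration from a declarative config.

Stages: classify -> select -> (validate | proximity | survival | orf ->
export). Each stage writes TSV/JSON under ``outdir/<stage>/`` plus a run
manifest recording the seed, config hash and record counts, so outputs from
different configurations are distinguishable and reruns are idempotent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import annotation_io as aio
from . import clt_selection as sel
from . import ere_classification as ere
from . import orf_uniqueness as orf
from . import regulatory_proximity as prox
from . import survival as surv
from .expression_summary import ExpressionMatrix, summarize_groups

log = logging.getLogger("cltkit.pipeline")

ALL_STAGES = ("classify", "select", "validate", "proximity", "survival", "orf", "export")
_STAGE_DEPS = {
    "select": ("classify",),
    "validate": ("select",),
    "proximity": ("select",),
    "survival": ("select",),
    "orf": ("select",),
    "export": ("orf",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    gtf: str = ""
    repeats: str = ""
    reference_gtf: str = ""
    matrix: str = ""
    metadata: str = ""
    fasta: str = ""
    coding_fasta: str = ""
    background_fasta: str = ""
    peaks: str = ""
    clinical: str = ""
    outdir: str = "cltkit_out"
    seed: int = 0
    selection: dict = field(default_factory=dict)
    uniqueness: dict = field(default_factory=dict)
    proximity: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _require(config: PipelineConfig, *attrs: str) -> None:
    for a in attrs:
        path = getattr(config, a)
        if not path:
            raise PipelineError(f"config field {a!r} is required for this stage")
        if not Path(path).exists():
            raise PipelineError(f"config path {a}={path!r} does not exist")


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str] | None = None,
) -> dict:
    """Run the requested stages in order; returns the machine-readable report."""
    stages = list(stages or ALL_STAGES)
    for s in stages:
        if s not in ALL_STAGES:
            raise PipelineError(f"unknown stage {s!r}")
        for dep in _STAGE_DEPS.get(s, ()):
            if dep not in stages:
                raise PipelineError(f"stage {s!r} requires stage {dep!r}")
    stages = [s for s in ALL_STAGES if s in stages]

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    state: dict = {}
    for stage in stages:
        log.info("stage=%s starting", stage)
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        counts = _STAGE_FUNCS[stage](config, stage_dir, state)
        report["stages"][stage] = counts
        log.info("stage=%s done %s", stage, counts)

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# stages

def _stage_classify(config: PipelineConfig, stage_dir: Path, state: dict) -> dict:
    _require(config, "gtf", "repeats")
    transcripts = aio.read_gtf(config.gtf)
    repeats = aio.read_repeatmasker(config.repeats, dialect="bed")
    reference = aio.read_gtf(config.reference_gtf) if config.reference_gtf else None
    table = ere.classification_table(transcripts, repeats, reference=reference)
    table.to_csv(stage_dir / "classification.tsv", sep="\t", index=False)
    state["transcripts"] = transcripts
    state["repeats"] = repeats
    state["classification"] = table
    return {
        "n_transcripts": len(transcripts),
        "n_repeats": len(repeats),
        "n_ltr_overlapping": int((table["ere_class"] == "LTR").sum()),
    }


def _stage_select(config: PipelineConfig, stage_dir: Path, state: dict) -> dict:
    _require(config, "matrix", "metadata")
    matrix = ExpressionMatrix.from_tsv(config.matrix, config.metadata)
    criteria = sel.SelectionCriteria(**config.selection)
    table = state["classification"]
    ltr_ids = set(table.loc[table["ere_class"] == "LTR", "transcript_id"])
    records = sel.select_cancer_specific(matrix, criteria, ltr_ids)
    df = sel.records_to_frame(records)
    df.to_csv(stage_dir / "clt_records.tsv", sep="\t", index=False)
    per_type = (
        df[df["selected"]].groupby("cancer_type")["transcript_id"].count().to_dict()
    )
    sharing = sel.sharing_across_types(records)
    with open(stage_dir / "summary.json", "w") as fh:
        json.dump(
            {"clts_per_cancer_type": per_type,
             "sharing_histogram": {str(k): v for k, v in sharing.items()},
             "config_hash": config.config_hash()},
            fh, indent=1, sort_keys=True,
        )
    state["matrix"] = matrix
    state["records"] = records
    state["selected"] = sorted({r.transcript_id for r in records if r.selected})
    return {"n_candidates": len(ltr_ids), "n_selected": len(state["selected"])}


def _stage_validate(config: PipelineConfig, stage_dir: Path, state: dict) -> dict:
    matrix: ExpressionMatrix = state["matrix"]
    if not matrix.validation_groups:
        log.warning("no validation groups in metadata; stage skipped")
        return {"skipped": "no validation groups"}
    healthy_medians = {
        g: matrix.group_values(g).median(axis=1) for g in matrix.healthy_groups
    }
    results = sel.validate_prevalence(matrix, state["selected"], healthy_medians)
    rows = [
        {"transcript_id": r.transcript_id, "validation_group": r.validation_group,
         "positive_fraction": r.positive_fraction, "validated": r.validated}
        for r in results
    ]
    pd.DataFrame(rows).to_csv(stage_dir / "validation.tsv", sep="\t", index=False)
    n_ok, n_eval, pct = sel.validation_rate(results)
    with open(stage_dir / "summary.json", "w") as fh:
        json.dump({"validated": n_ok, "evaluable": n_eval, "percent": pct,
                   "config_hash": config.config_hash()}, fh, indent=1)
    return {"n_validated": n_ok, "n_evaluable": n_eval}


def _stage_proximity(config: PipelineConfig, stage_dir: Path, state: dict) -> dict:
    _require(config, "peaks")
    peaks = aio.read_bed(config.peaks)
    by_id = {t.transcript_id: t for t in state["transcripts"]}
    tss = [
        (by_id[tid].chrom, by_id[tid].tss)
        for tid in state["selected"]
        if tid in by_id and by_id[tid].tss is not None
    ]
    if not tss:
        log.warning("no strand-known selected CLTs; proximity stage skipped")
        return {"skipped": "no TSSs"}
    ltr_elements = [r for r in state["repeats"] if r.repeat_class == "LTR"]
    params = dict(config.proximity)
    result = prox.proximity_test(
        tss, peaks, ltr_elements,
        n_sets=int(params.get("n_sets", 10)),
        seed=int(params.get("seed", config.seed)),
    )
    with open(stage_dir / "proximity.json", "w") as fh:
        json.dump(prox.result_to_dict(result), fh, indent=1)
    return {"n_tss": len(tss), "p_value": result.p_value}


def _stage_survival(config: PipelineConfig, stage_dir: Path, state: dict) -> dict:
    if not config.clinical or not Path(config.clinical).exists():
        log.warning("no clinical table; survival stage skipped")
        return {"skipped": "no clinical table"}
    clinical = pd.read_csv(config.clinical, sep="\t")
    records = surv.build_survival_records(
        clinical, reference_year=int(config.survival.get("reference_year", 2017))
    )
    if "expression" in clinical.columns:
        expr = pd.DataFrame(
            [clinical.set_index("patient_id")["expression"]],
            index=["clinical_expression"],
        )
    else:
        matrix: ExpressionMatrix = state["matrix"]
        patients = [r.patient_id for r in records if r.patient_id in matrix.tpm.columns]
        expr = matrix.tpm.loc[
            [t for t in state["selected"] if t in matrix.tpm.index], patients
        ]
    screen = surv.prognostic_screen(
        expr, records, alpha=float(config.survival.get("alpha", 0.05))
    )
    screen.to_csv(stage_dir / "survival.tsv", sep="\t", index=False)
    n_sig = int(screen["significant"].sum()) if not screen.empty else 0
    return {"n_transcripts": len(screen), "n_significant": n_sig}


def _stage_orf(config: PipelineConfig, stage_dir: Path, state: dict) -> dict:
    _require(config, "fasta", "coding_fasta", "background_fasta")
    sequences = aio.read_fasta(config.fasta)
    model = orf.train_hexamer_model(
        aio.read_fasta(config.coding_fasta), aio.read_fasta(config.background_fasta)
    )
    model.to_tsv(stage_dir / "hexamer_model.tsv")
    criteria = orf.UniquenessCriteria(**config.uniqueness)
    matrix: ExpressionMatrix = state["matrix"]
    summary = summarize_groups(matrix)
    healthy_cols = [g for g in matrix.healthy_groups]
    max_healthy = summary.median[healthy_cols].max(axis=1).to_dict()
    candidates = orf.select_coding_clts(
        state["selected"], sequences, model, max_healthy, criteria
    )
    universe = orf.build_orf_universe(sequences, criteria.orf_universe_min)
    status = {}
    selected = set(state["selected"])
    for tid in sequences:
        if tid in selected:
            status[tid] = "cancer_specific"
        elif max_healthy.get(tid, 0.0) >= criteria.healthy_median_cutoff:
            status[tid] = "healthy"
        else:
            status[tid] = "other"
    calls = orf.uniqueness_filter(candidates, universe, status, criteria)
    rows = [
        {"transcript_id": c.transcript_id, "unique": c.unique, "retained": c.retained,
         "n_partners": len(c.partners)}
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(stage_dir / "orf_candidates.tsv", sep="\t", index=False)
    state["final_clts"] = [c.transcript_id for c in calls if c.retained]
    state["sequences"] = sequences
    return {
        "n_candidates": len(candidates),
        "n_universe_orfs": len(universe),
        "n_final": len(state["final_clts"]),
    }


def _stage_export(config: PipelineConfig, stage_dir: Path, state: dict) -> dict:
    final = state.get("final_clts", [])
    if not final:
        log.warning("no final CLTs; export stage skipped")
        return {"skipped": "no final CLTs"}
    criteria = orf.UniquenessCriteria(**config.uniqueness)
    n = orf.export_peptide_db(
        final, state["sequences"], stage_dir / "peptides.fa", criteria.peptide_db_min
    )
    return {"n_peptides": n}


_STAGE_FUNCS = {
    "classify": _stage_classify,
    "select": _stage_select,
    "validate": _stage_validate,
    "proximity": _stage_proximity,
    "survival": _stage_survival,
    "orf": _stage_orf,
    "export": _stage_export,
}
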