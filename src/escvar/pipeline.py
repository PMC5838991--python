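"""End-to-end orchestration: blacklist -> cascade -> CNV -> TMB -> cohort ->
actionability, with a machine-readable run manifest.

The manifest checks record-count conservation per patient: kept plus the
removals attributed to the first failing filter (in the printed cascade
order) equal the input count.  Attribution to the first failing filter is
for accounting only — the cascade's semantics are order-free.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .actionability import load_knowledge_base, match_alterations, matches_to_frame
from .blacklist import build_blacklist, write_blacklist
from .cnv import compute_log2_ratios, write_segments
from .cohort import build_matrix, frequency_table, triage_mmr_variants, write_matrix
from .filters import FILTER_ORDER, CascadeConfig, run_cascade
from .io import write_variant_table
from .model import GeneGroupCatalog
from .simulate import load_bundle
from .tmb import compute_tmb, write_tmb

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "PipelineConfig", "run_all"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold of the run, defaulting to the published values."""

    recurrence_fraction: float = 0.20
    detection_min_reads: int = 3
    detection_min_vaf: float = 0.01
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    cnv_cutoff: float = 0.6
    knowledge_base: str = "default"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cascade_keys = CascadeConfig.__dataclass_fields__.keys()
        cascade = CascadeConfig(**{k: v for k, v in raw.items() if k in cascade_keys})
        own = {k: v for k, v in raw.items()
               if k in cls.__dataclass_fields__ and k != "cascade"}
        return cls(cascade=cascade, **own)


@dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: dict[str, str]
    per_patient: dict[str, dict]
    outputs: dict[str, str]
    error: Optional[str] = None

    def check_conservation(self) -> None:
        for pid, rec in self.per_patient.items():
            removed = sum(rec["removed"].values())
            if rec["kept"] + removed != rec["input"]:
                raise AssertionError(
                    f"count conservation violated for {pid}: "
                    f"{rec['kept']} kept + {removed} removed != {rec['input']}"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "input_checksums": self.input_checksums,
                "per_patient": self.per_patient,
                "outputs": self.outputs,
                "error": self.error,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksums(bundle_dir: Path) -> dict[str, str]:
    out = {}
    for p in sorted(bundle_dir.rglob("*.tsv")) + sorted(bundle_dir.rglob("*.bed")):
        out[str(p.relative_to(bundle_dir))] = _sha256(p)
    return out


def run_all(
    bundle_dir: Union[str, Path],
    out_dir: Union[str, Path],
    config: PipelineConfig = PipelineConfig(),
) -> RunManifest:
    """Run every stage on a cohort bundle directory; write outputs + manifest.

    Any stage failure aborts the run with the stage name, recorded in the
    manifest (written even on failure).
    """
    bundle_dir = Path(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config={
            "recurrence_fraction": config.recurrence_fraction,
            "detection_min_reads": config.detection_min_reads,
            "detection_min_vaf": config.detection_min_vaf,
            "popfreq_max": config.cascade.popfreq_max,
            "cosmic_tier": [config.cascade.cosmic_min_vaf, config.cascade.cosmic_min_reads],
            "noncosmic_tier": [config.cascade.noncosmic_min_vaf,
                               config.cascade.noncosmic_min_reads],
            "keep_splice": config.cascade.keep_splice,
            "min_depth": config.cascade.min_depth,
            "cnv_cutoff": config.cnv_cutoff,
            "knowledge_base": config.knowledge_base,
        },
        input_checksums=_checksums(bundle_dir),
        per_patient={},
        outputs={},
    )

    stage = "load_inputs"
    try:
        data = load_bundle(bundle_dir)
        panel, repeats = data["panel"], data["repeats"]
        if repeats is None:
            stage = "filter_repeat_regions"
            raise FileNotFoundError(f"repeats BED missing in {bundle_dir}")

        stage = "pon_blacklist"
        bl = build_blacklist(
            data["normal_tables"].values(),
            recurrence_fraction=config.recurrence_fraction,
            min_reads=config.detection_min_reads,
            min_vaf=config.detection_min_vaf,
        )
        write_blacklist(bl, out / "blacklist.tsv")
        manifest.outputs["blacklist"] = "blacklist.tsv"

        stage = "filter_cascade"
        kept_all = []
        for pid, table in sorted(data["tumor_tables"].items()):
            kept, traces = run_cascade(table, bl, repeats, config.cascade)
            kept_all.extend(kept)
            removed: dict[str, int] = {name: 0 for name in FILTER_ORDER}
            for tr in traces:
                if not tr.final_kept:
                    removed.setdefault(tr.first_failed, 0)
                    removed[tr.first_failed] += 1
            manifest.per_patient[pid] = {
                "input": len(table),
                "removed": removed,
                "kept": len(kept),
            }
        write_variant_table(kept_all, out / "kept.tsv")
        manifest.outputs["kept"] = "kept.tsv"
        manifest.check_conservation()

        stage = "cnv_calls"
        segments = []
        for pid, cov in sorted(data["tumor_coverage"].items()):
            segments.extend(
                compute_log2_ratios(cov, data["reference_coverage"],
                                    patient_id=pid, cutoff=config.cnv_cutoff)
            )
        write_segments(segments, out / "cnv.tsv")
        manifest.outputs["cnv"] = "cnv.tsv"

        stage = "mutation_burden"
        patients = [c.patient_id for c in data["clinical"]]
        tmb = compute_tmb(kept_all, panel, patients=patients)
        write_tmb(tmb, out / "tmb.tsv")
        manifest.outputs["tmb"] = "tmb.tsv"

        stage = "cohort_profile"
        groups = GeneGroupCatalog()
        matrix = build_matrix(kept_all, segments, data["clinical"], groups=groups)
        write_matrix(matrix, out / "matrix.tsv")
        frequency_table(matrix).to_csv(out / "frequencies.tsv", sep="\t", index=False)
        triage_mmr_variants(kept_all, groups=groups).to_csv(
            out / "mmr_triage.tsv", sep="\t", index=False
        )
        manifest.outputs.update(
            {"matrix": "matrix.tsv", "frequencies": "frequencies.tsv",
             "mmr_triage": "mmr_triage.tsv"}
        )

        stage = "actionability"
        rules = load_knowledge_base(config.knowledge_base)
        matches = match_alterations(kept_all, segments, rules)
        matches_to_frame(matches).to_csv(out / "actionable.tsv", sep="\t", index=False)
        manifest.outputs["actionable"] = "actionable.tsv"
    except Exception as exc:
        manifest.error = f"stage {stage}: {exc}"
        (out / "manifest.json").write_text(manifest.to_json())
        raise RuntimeError(manifest.error) from exc

    (out / "manifest.json").write_text(manifest.to_json())
    manifest.outputs["manifest"] = "manifest.json"
    return manifest
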