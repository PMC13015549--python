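"""End-to-end classification pipeline over a directory of model ensembles.

Scans a directory of predicted-model PDB files, groups them per
sequence (ColabFold-style ``<id>_rank<k>*.pdb`` stems, or a manifest
TSV mapping ``model_file → sequence_id``), classifies every model's
CTD fold, measures the mapped salt-bridge distance, and emits
deterministic TSV/JSON reports.  Fractions are reported both per model
(all models pooled) and per sequence (majority and best-model
conventions), since large-scale structure surveys use both framings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
from Bio import SeqIO

from metamorphscan.foldclass import (
    ClassifierThresholds,
    FoldClassLabel,
    classify_ensemble,
)
from metamorphscan.seqmap import (
    SaltBridgePair,
    global_align,
    map_equivalent_positions,
    salt_bridge_distance,
    summarize_distances,
)
from metamorphscan.structures import ProteinStructure, RegionSpec, read_pdb_models

logger = logging.getLogger("metamorphscan")

_RANK_RE = re.compile(r"^(?P<id>.+?)_rank\d+")

# Study-scale bookkeeping constants for the survey this pipeline emulates:
# sequence counts of the three source databases, models predicted per
# sequence, and the trajectory sampling scheme of the steered simulations.
DATABASE_SEQUENCE_COUNTS = {"colabfolddb": 468, "interpro": 3058, "genomic_cluster": 416}
MODELS_PER_SEQUENCE = 5
TRAJECTORY_LENGTH_PS = 100
FRAME_INTERVAL_PS = 2


def total_predicted_models(
    counts: Dict[str, int] = DATABASE_SEQUENCE_COUNTS,
    models_per_sequence: int = MODELS_PER_SEQUENCE,
) -> int:
    """Total model count of the survey: models per sequence × Σ sequences."""
    return models_per_sequence * sum(counts.values())


def frames_per_trajectory(
    length_ps: int = TRAJECTORY_LENGTH_PS, interval_ps: int = FRAME_INTERVAL_PS
) -> int:
    """Frames saved per trajectory at a fixed sampling interval."""
    return length_ps // interval_ps


@dataclass
class RunConfig:
    """Configuration of one classification run (serialised for provenance)."""

    models_dir: Path
    reference_fasta: Path
    reference_region: RegionSpec = RegionSpec(110, 162)
    pair: SaltBridgePair = SaltBridgePair(48, 138)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    distance_mode: str = "all"  # 'all' models or 'best' model per sequence
    manifest: Optional[Path] = None
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        self.models_dir = Path(self.models_dir)
        self.reference_fasta = Path(self.reference_fasta)
        if not self.models_dir.is_dir():
            raise FileNotFoundError(self.models_dir)
        if not self.reference_fasta.is_file():
            raise FileNotFoundError(self.reference_fasta)
        if self.distance_mode not in ("all", "best"):
            raise ValueError("distance_mode must be 'all' or 'best'")

    def as_dict(self) -> Dict[str, object]:
        return {
            "models_dir": str(self.models_dir),
            "reference_fasta": str(self.reference_fasta),
            "reference_region": [self.reference_region.start, self.reference_region.end],
            "pair": [self.pair.ref_pos_a, self.pair.ref_pos_b],
            "thresholds": vars(self.thresholds).copy(),
            "distance_mode": self.distance_mode,
            "manifest": str(self.manifest) if self.manifest else None,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def read_reference(path: Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return str(records[0].seq)


def group_model_files(
    models_dir: Path, manifest: Optional[Path] = None
) -> Dict[str, List[Path]]:
    """Group PDB files per sequence id.

    With a manifest TSV (columns: model_file, sequence_id) the grouping
    is explicit; otherwise the ColabFold stem pattern ``<id>_rank<k>``
    is used, and files without it each form their own group.
    """
    files = sorted(models_dir.glob("*.pdb"))
    if not files:
        raise ValueError(f"no .pdb files in {models_dir}")
    groups: Dict[str, List[Path]] = {}
    if manifest is not None:
        table = pd.read_csv(manifest, sep="\t")
        mapping = dict(zip(table["model_file"], table["sequence_id"]))
        for f in files:
            groups.setdefault(str(mapping.get(f.name, f.stem)), []).append(f)
        return groups
    for f in files:
        m = _RANK_RE.match(f.stem)
        key = m.group("id") if m else f.stem
        groups.setdefault(key, []).append(f)
    return groups


def run_classification_pipeline(config: RunConfig) -> Dict[str, object]:
    """Classify every ensemble under ``config.models_dir``.

    Returns a report dict with per-model rows, per-sequence summaries,
    per-class distance summaries and per-class counts/fractions; writes
    classes.tsv, distances.tsv and summary.json when out_dir is set.
    Stage errors are recorded per sequence and the run continues.
    """
    reference_seq = read_reference(config.reference_fasta)
    groups = group_model_files(config.models_dir, config.manifest)
    logger.info(
        "classification run %s: %d sequences", config.digest(), len(groups)
    )

    model_rows: List[Dict[str, object]] = []
    distance_rows: List[Dict[str, object]] = []
    sequence_rows: List[Dict[str, object]] = []
    errors: Dict[str, str] = {}

    for seq_id in sorted(groups):
        try:
            models: List[ProteinStructure] = []
            for path in groups[seq_id]:
                models.extend(read_pdb_models(path))
            results, summary = classify_ensemble(
                models, reference_seq, config.reference_region, config.thresholds
            )
            alignment = global_align(reference_seq, models[0].sequence)
            qa, qb = map_equivalent_positions(alignment, config.pair)
            for model, res in zip(models, results):
                is_best = res.model_id == summary.best_model_id
                model_rows.append(
                    {
                        "sequence_id": seq_id,
                        "model_id": res.model_id,
                        "ctd_start": res.ctd_region.start if res.ctd_region else None,
                        "ctd_end": res.ctd_region.end if res.ctd_region else None,
                        "pct_H": round(res.content.percent_helix, 3) if res.content else None,
                        "pct_E": round(res.content.percent_strand, 3) if res.content else None,
                        "label": res.label.value,
                        "ctd_mean_plddt": round(res.ctd_mean_plddt, 3),
                        "is_best": is_best,
                    }
                )
                if config.distance_mode == "best" and not is_best:
                    continue
                if qa is None or qb is None:
                    distance_rows.append(
                        {
                            "sequence_id": seq_id, "model_id": res.model_id,
                            "label": res.label.value, "query_pos_a": qa,
                            "query_pos_b": qb, "distance": None,
                        }
                    )
                    continue
                try:
                    dist = salt_bridge_distance(model, qa, qb)
                except ValueError:
                    dist = None
                distance_rows.append(
                    {
                        "sequence_id": seq_id, "model_id": res.model_id,
                        "label": res.label.value, "query_pos_a": qa,
                        "query_pos_b": qb,
                        "distance": round(dist, 3) if dist is not None else None,
                    }
                )
            sequence_rows.append(
                {
                    "sequence_id": seq_id,
                    "n_models": summary.n_models,
                    **{
                        f"n_{lab.value.lower()}": summary.counts.get(lab, 0)
                        for lab in FoldClassLabel
                    },
                    "majority_label": summary.majority_label.value,
                    "best_model_id": summary.best_model_id,
                    "best_model_label": summary.best_model_label.value,
                }
            )
        except Exception as exc:  # recorded, run continues
            logger.error("sequence %s failed: %s", seq_id, exc)
            errors[seq_id] = str(exc)

    n_models = len(model_rows)
    class_counts = {
        lab.value: sum(1 for r in model_rows if r["label"] == lab.value)
        for lab in FoldClassLabel
    }
    class_fractions = {
        lab: (count / n_models if n_models else 0.0)
        for lab, count in class_counts.items()
    }
    majority_counts = {
        lab.value: sum(1 for r in sequence_rows if r["majority_label"] == lab.value)
        for lab in FoldClassLabel
    }
    distance_summaries = {}
    for lab in FoldClassLabel:
        vals = [
            r["distance"]
            for r in distance_rows
            if r["label"] == lab.value and r["distance"] is not None
        ]
        if vals:
            distance_summaries[lab.value] = vars(summarize_distances(vals)).copy()
    n_missing = sum(1 for r in distance_rows if r["distance"] is None)

    report = {
        "config": config.as_dict(),
        "config_digest": config.digest(),
        "n_sequences": len(sequence_rows),
        "n_models": n_models,
        "class_counts_per_model": class_counts,
        "class_fractions_per_model": class_fractions,
        "majority_counts_per_sequence": majority_counts,
        "distance_summaries": distance_summaries,
        "n_distances_missing": n_missing,
        "n_distances_used": len(distance_rows) - n_missing,
        "errors": errors,
        "model_rows": model_rows,
        "sequence_rows": sequence_rows,
        "distance_rows": distance_rows,
    }
    if config.out_dir is not None:
        write_report(report, Path(config.out_dir))
    return report


def write_report(report: Dict[str, object], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report["model_rows"]).to_csv(
        out_dir / "classes.tsv", sep="\t", index=False
    )
    pd.DataFrame(report["distance_rows"]).to_csv(
        out_dir / "distances.tsv", sep="\t", index=False
    )
    summary = {k: v for k, v in report.items() if not k.endswith("_rows")}
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
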