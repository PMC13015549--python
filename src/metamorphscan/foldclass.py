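"""Locate the fold-switching C-terminal domain and classify its fold.

A query model's CTD is found by global alignment to a reference
sequence (default region: residues 110–162 of the reference), the
helix/strand content of the located region is measured from the
secondary-structure string, and a four-way label is assigned:

* ALPHA  — metamorphic state: helix > 32.5 % and strand < 2.5 %
* BETA   — monomorphic state: strand > 30.0 % and helix < 2.5 %
* MIXED  — both contents > 2.5 % and neither rule above fires
* NONE   — everything else

All inequalities are strict.  Content percentages are computed over the
full located CTD window, including coil/turn residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence

from metamorphscan.secstruct import SSContent, assign_secondary_structure, ss_content
from metamorphscan.seqmap import PairwiseAlignment, global_align
from metamorphscan.structures import ProteinStructure, RegionSpec, mean_confidence

DEFAULT_REFERENCE_REGION = RegionSpec(110, 162)


class FoldClassLabel(str, Enum):
    ALPHA = "ALPHA"
    BETA = "BETA"
    MIXED = "MIXED"
    NONE = "NONE"


# deterministic tie-break precedence for majority labels
_LABEL_PRECEDENCE = [
    FoldClassLabel.ALPHA,
    FoldClassLabel.BETA,
    FoldClassLabel.MIXED,
    FoldClassLabel.NONE,
]


@dataclass(frozen=True)
class ClassifierThresholds:
    """Percent cutoffs of the four-way fold rule (all strict inequalities)."""

    helix_min_alpha: float = 32.5
    strand_max_alpha: float = 2.5
    strand_min_beta: float = 30.0
    helix_max_beta: float = 2.5
    mixed_min: float = 2.5

    def __post_init__(self) -> None:
        for name in (
            "helix_min_alpha", "strand_max_alpha", "strand_min_beta",
            "helix_max_beta", "mixed_min",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.helix_min_alpha <= self.mixed_min:
            raise ValueError("helix_min_alpha must exceed mixed_min")
        if self.strand_min_beta <= self.mixed_min:
            raise ValueError("strand_min_beta must exceed mixed_min")


class CTDUnresolvedError(ValueError):
    """The alignment covers too little of the reference region."""

    def __init__(self, coverage: float):
        self.coverage = coverage
        super().__init__(
            f"CTD unresolved: alignment covers only {coverage:.1%} of the "
            "reference region (need >= 50%)"
        )


def locate_ctd(
    query_seq: str,
    reference_seq: str,
    reference_region: RegionSpec = DEFAULT_REFERENCE_REGION,
    alignment: Optional[PairwiseAlignment] = None,
) -> RegionSpec:
    """Smallest query region containing every residue aligned to the
    reference region; the alignment must cover >= 50% of that region."""
    if alignment is None:
        alignment = global_align(reference_seq, query_seq)
    mapped = [
        alignment.map_a_to_b[p]
        for p in reference_region.indices()
        if p in alignment.map_a_to_b
    ]
    coverage = len(mapped) / len(reference_region)
    if coverage < 0.5:
        raise CTDUnresolvedError(coverage)
    return RegionSpec(min(mapped), max(mapped))


def classify_fold(
    content: SSContent, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> FoldClassLabel:
    """The four-way fold label; the rule is total and unambiguous."""
    h, e = content.percent_helix, content.percent_strand
    t = thresholds
    if h > t.helix_min_alpha and e < t.strand_max_alpha:
        return FoldClassLabel.ALPHA
    if e > t.strand_min_beta and h < t.helix_max_beta:
        return FoldClassLabel.BETA
    if h > t.mixed_min and e > t.mixed_min:
        return FoldClassLabel.MIXED
    return FoldClassLabel.NONE


@dataclass
class ModelClassification:
    """Per-model result: located CTD, its content, label and confidence."""

    model_id: str
    ctd_region: Optional[RegionSpec]
    content: Optional[SSContent]
    label: FoldClassLabel
    ctd_mean_plddt: float
    ctd_resolved: bool = True


@dataclass
class EnsembleSummary:
    """Per-sequence aggregate over an ensemble of predicted models."""

    counts: Dict[FoldClassLabel, int]
    majority_label: FoldClassLabel
    best_model_id: str
    best_model_label: FoldClassLabel
    n_models: int

    def labels_with_min_count(self, min_count: int) -> List[FoldClassLabel]:
        """Labels supported by at least `min_count` models (e.g. the
        "at least 2 of 5 models" ortholog-selection convention)."""
        return [
            lab for lab in _LABEL_PRECEDENCE if self.counts.get(lab, 0) >= min_count
        ]


def classify_model(
    model: ProteinStructure,
    reference_seq: str,
    reference_region: RegionSpec = DEFAULT_REFERENCE_REGION,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    alignment: Optional[PairwiseAlignment] = None,
) -> ModelClassification:
    """Classify one model; an unresolved CTD yields label NONE, not a drop."""
    try:
        ctd = locate_ctd(model.sequence, reference_seq, reference_region, alignment)
    except CTDUnresolvedError:
        return ModelClassification(
            model.model_id, None, None, FoldClassLabel.NONE, 0.0, ctd_resolved=False
        )
    codes = assign_secondary_structure(model)
    content = ss_content(codes, ctd)
    label = classify_fold(content, thresholds)
    plddt = mean_confidence(model, ctd)
    return ModelClassification(model.model_id, ctd, content, label, plddt)


def classify_ensemble(
    models: Sequence[ProteinStructure],
    reference_seq: str,
    reference_region: RegionSpec = DEFAULT_REFERENCE_REGION,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
):
    """Classify every model of one sequence and summarise the ensemble.

    Returns (per-model classifications, EnsembleSummary).  The best
    model is the one with the highest CTD mean pLDDT; majority ties are
    broken by the precedence ALPHA > BETA > MIXED > NONE.
    """
    if not models:
        raise ValueError("need at least one model")
    seqs = {m.sequence for m in models}
    if len(seqs) > 1:
        raise ValueError("all models of an ensemble must share one sequence")
    alignment = global_align(reference_seq, models[0].sequence)
    results = [
        classify_model(m, reference_seq, reference_region, thresholds, alignment)
        for m in models
    ]
    counts: Dict[FoldClassLabel, int] = {}
    for r in results:
        counts[r.label] = counts.get(r.label, 0) + 1
    max_count = max(counts.values())
    majority = next(
        lab for lab in _LABEL_PRECEDENCE if counts.get(lab, 0) == max_count
    )
    best = max(results, key=lambda r: r.ctd_mean_plddt)
    summary = EnsembleSummary(
        counts=counts,
        majority_label=majority,
        best_model_id=best.model_id,
        best_model_label=best.label,
        n_models=len(results),
    )
    return results, summary
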