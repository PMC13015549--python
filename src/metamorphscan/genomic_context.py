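"""Long-operon detection and focal-gene proximity classification.

A "long operon" in a gene neighborhood is a maximal run of >= 2
consecutive genes that (i) share the transcriptional direction,
(ii) have successive intergenic distances <= 200 bp, and (iii) span
more than 5,000 bp of the genome.  A focal gene (an RfaH-family
homolog) is then classified against each called operon:

* INSIDE — the focal gene lies within the operon span (automatically
  adjacent);
* otherwise, the distance to the operon promoter end is measured:
  |focal.end − start of first gene| for a '+' operon, or
  |focal.start − end of last gene| for a '−' operon (whose last gene,
  in coordinate order, is nearest the promoter);
* NEAR_SAME_DIRECTION / NEAR_OPPOSITE_DIRECTION when that distance is
  < 1,000 bp, split on strand equality; DISTANT otherwise.

Coordinates are 1-based inclusive (GFF/GenBank convention); intergenic
distance is next.start − prev.end − 1, clipped at 0 for overlaps.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence

LPS_KEYWORDS = ("lipopolysaccharide", "lps", "o-antigen", "polysaccharide")


@dataclass(frozen=True)
class GeneRecord:
    """One gene: id, 1-based inclusive coordinates, strand, free product text."""

    gene_id: str
    start: int
    end: int
    strand: str
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class OperonCriteria:
    """Step-1/Step-2 cutoffs: gap <= 200 bp, span > 5,000 bp, near < 1,000 bp."""

    max_intergenic: int = 200
    min_operon_length: int = 5000
    proximity_cutoff: int = 1000
    min_genes: int = 2

    def __post_init__(self) -> None:
        for name in ("max_intergenic", "min_operon_length", "proximity_cutoff", "min_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class OperonCall:
    gene_ids: List[str]
    span_start: int
    span_end: int
    strand: str

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start + 1


class ProximityCategory(str, Enum):
    INSIDE = "INSIDE"
    NEAR_SAME_DIRECTION = "NEAR_SAME_DIRECTION"
    NEAR_OPPOSITE_DIRECTION = "NEAR_OPPOSITE_DIRECTION"
    DISTANT = "DISTANT"


# ranking for "best" proximity: INSIDE beats NEAR beats DISTANT
_CATEGORY_RANK = {
    ProximityCategory.INSIDE: 0,
    ProximityCategory.NEAR_SAME_DIRECTION: 1,
    ProximityCategory.NEAR_OPPOSITE_DIRECTION: 1,
    ProximityCategory.DISTANT: 2,
}


@dataclass
class ProximityResult:
    category: ProximityCategory
    distance: Optional[int]
    operon: Optional[OperonCall]


def intergenic_distance(prev: GeneRecord, nxt: GeneRecord) -> int:
    return max(0, nxt.start - prev.end - 1)


def find_long_operons(
    genes: Sequence[GeneRecord], criteria: OperonCriteria = OperonCriteria()
) -> List[OperonCall]:
    """Maximal same-strand small-gap runs passing all three criteria.

    Input must already be sorted by start coordinate; unsorted input is
    an error rather than silently reordered.
    """
    genes = list(genes)
    for a, b in zip(genes, genes[1:]):
        if b.start < a.start:
            raise ValueError("gene table must be sorted by start coordinate")
    operons: List[OperonCall] = []
    run: List[GeneRecord] = []

    def flush() -> None:
        if len(run) >= criteria.min_genes:
            span_start = run[0].start
            span_end = max(g.end for g in run)
            if span_end - span_start + 1 > criteria.min_operon_length:
                operons.append(
                    OperonCall(
                        gene_ids=[g.gene_id for g in run],
                        span_start=span_start,
                        span_end=span_end,
                        strand=run[0].strand,
                    )
                )

    for gene in genes:
        if run and (
            gene.strand != run[-1].strand
            or intergenic_distance(run[-1], gene) > criteria.max_intergenic
        ):
            flush()
            run = []
        run.append(gene)
    flush()
    return operons


def classify_proximity(
    focal: GeneRecord,
    operon: OperonCall,
    criteria: OperonCriteria = OperonCriteria(),
) -> ProximityResult:
    """Proximity of a focal gene to one called operon (see module docs)."""
    if operon.span_start <= focal.start and focal.end <= operon.span_end:
        return ProximityResult(ProximityCategory.INSIDE, None, operon)
    if operon.strand == "+":
        distance = abs(focal.end - operon.span_start)
    else:
        distance = abs(focal.start - operon.span_end)
    if distance < criteria.proximity_cutoff:
        category = (
            ProximityCategory.NEAR_SAME_DIRECTION
            if focal.strand == operon.strand
            else ProximityCategory.NEAR_OPPOSITE_DIRECTION
        )
    else:
        category = ProximityCategory.DISTANT
    return ProximityResult(category, distance, operon)


@dataclass
class NeighborhoodReport:
    operons: List[OperonCall]
    proximities: List[ProximityResult]
    best_proximity: ProximityResult
    flags: Dict[str, bool]  # operon key -> contains-LPS-keyword flag


def operon_has_keyword(
    operon: OperonCall, genes_by_id: Dict[str, GeneRecord],
    keywords: Sequence[str] = LPS_KEYWORDS,
) -> bool:
    for gid in operon.gene_ids:
        product = (genes_by_id[gid].product or "").lower()
        if any(kw in product for kw in keywords):
            return True
    return False


def analyze_neighborhood(
    genes: Sequence[GeneRecord],
    focal_id: str,
    criteria: OperonCriteria = OperonCriteria(),
) -> NeighborhoodReport:
    """Call operons over the neighborhood (focal gene included) and rank
    the focal gene's proximity: INSIDE, then NEAR by increasing distance,
    then DISTANT; no operon at all reports DISTANT-by-absence."""
    by_id = {g.gene_id: g for g in genes}
    if focal_id not in by_id:
        raise ValueError(f"focal gene {focal_id!r} not in the neighborhood")
    focal = by_id[focal_id]
    operons = find_long_operons(sorted(genes, key=lambda g: (g.start, g.end)), criteria)
    proximities = [classify_proximity(focal, op, criteria) for op in operons]
    if proximities:
        best = min(
            proximities,
            key=lambda p: (_CATEGORY_RANK[p.category], p.distance or 0),
        )
    else:
        best = ProximityResult(ProximityCategory.DISTANT, None, None)
    flags = {
        ",".join(op.gene_ids): operon_has_keyword(op, by_id) for op in operons
    }
    return NeighborhoodReport(operons, proximities, best, flags)


# ---------------------------------------------------------------------------
# gene table I/O: 4/5-column TSV or GFF3 gene features


def read_gene_table(path: str | Path) -> List[GeneRecord]:
    """Read gene records from a TSV (gene_id, start, end, strand[, product])
    or a GFF3 file (gene/CDS features; gene_id from ID= or locus_tag=)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".gff", ".gff3") or text.startswith("##gff"):
        return _read_gff3(text)
    records = []
    reader = csv.reader(
        (ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")),
        delimiter="\t",
    )
    for row in reader:
        if row[0] == "gene_id":  # header
            continue
        product = row[4] if len(row) > 4 and row[4] else None
        records.append(GeneRecord(row[0], int(row[1]), int(row[2]), row[3], product))
    return records


def _read_gff3(text: str) -> List[GeneRecord]:
    records = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9 or cols[2] not in ("gene", "CDS"):
            continue
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
        )
        gid = attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name")
        if gid is None:
            continue
        records.append(
            GeneRecord(
                gid, int(cols[3]), int(cols[4]), cols[6],
                attrs.get("product"),
            )
        )
    return records


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    lines = ["gene_id\tstart\tend\tstrand\tproduct"]
    for g in genes:
        lines.append(f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.product or ''}")
    Path(path).write_text("\n".join(lines) + "\n")
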