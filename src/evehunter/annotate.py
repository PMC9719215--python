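"""Branch A step 4: genome-wide annotation with the selected library.

Re-implements the repeat-masking contract: nucleotide search of the
selected consensus library against the whole genome, per-library-sequence
merging of overlapping matches, and a union-based genome coverage
estimate (double-annotated bases count once).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .config import PipelineConfig
from .homsearch import search
from .locate import _merge_spans
from .seqio import SequenceRecord


@dataclass
class Annotation:
    subject_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    library_id: str
    identity_pct: float
    score: int


def mask_genome(genome: dict[str, SequenceRecord], library: list[SequenceRecord],
                cfg: PipelineConfig) -> list[Annotation]:
    """Annotate genome copies of the library consensi.

    Overlapping matches of the *same* library sequence are merged;
    overlaps between different library sequences stay separate records.
    """
    if not library:
        warnings.warn("empty annotation library: no annotations produced", stacklevel=2)
        return []
    hits = search(library, list(genome.values()), "nt_nt", cfg.search,
                  min_aln_len=cfg.mask_min_len,
                  min_identity=cfg.mask_min_identity)
    grouped: dict[tuple[str, str], list] = {}
    for h in hits:
        grouped.setdefault((h.subject_id, h.query_id), []).append(h)
    annotations = []
    for (sid, lid) in sorted(grouped):
        hs = grouped[(sid, lid)]
        for s, e in _merge_spans([(h.s_start, h.s_end) for h in hs]):
            sub = [h for h in hs if h.s_start < e and h.s_end > s]
            top = max(sub, key=lambda h: h.score)
            annotations.append(Annotation(sid, s, e, top.strand, lid,
                                          top.identity_pct, top.score))
    annotations.sort(key=lambda a: (a.subject_id, a.start, a.end, a.library_id))
    return annotations


def coverage_percent(annotations: list[Annotation],
                     genome: dict[str, SequenceRecord]) -> float:
    """100 x |union of annotated positions| / total genome length."""
    total = sum(len(r) for r in genome.values())
    if total == 0:
        return 0.0
    covered = 0
    by_subject: dict[str, list] = {}
    for a in annotations:
        by_subject.setdefault(a.subject_id, []).append((a.start, a.end))
    for sid, spans in by_subject.items():
        covered += sum(e - s for s, e in _merge_spans(spans))
    return 100.0 * covered / total


def write_gff3(annotations: list[Annotation], path) -> None:
    """GFF3 output: 1-based inclusive coordinates, type dispersed_repeat."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = f"Target={a.library_id} {a.start + 1} {a.end};identity={a.identity_pct:.2f}"
            fh.write(
                f"{a.subject_id}\teve-hunter\tdispersed_repeat\t{a.start + 1}\t{a.end}\t"
                f"{a.score}\t{a.strand}\t.\t{attrs}\n"
            )


def write_bed(annotations: list[Annotation], path) -> None:
    """BED output: 0-based half-open."""
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.subject_id}\t{a.start}\t{a.end}\t{a.library_id}\t"
                     f"{a.score}\t{a.strand}\n")


def coverage_table(annotations: list[Annotation], genome: dict[str, SequenceRecord]) -> list[dict]:
    """Per-library-sequence and total coverage summary rows."""
    total_len = sum(len(r) for r in genome.values())
    rows = []
    by_lib: dict[str, list] = {}
    for a in annotations:
        by_lib.setdefault(a.library_id, []).append(a)
    for lid in sorted(by_lib):
        sub = by_lib[lid]
        bases = 0
        per_subj: dict[str, list] = {}
        for a in sub:
            per_subj.setdefault(a.subject_id, []).append((a.start, a.end))
        for spans in per_subj.values():
            bases += sum(e - s for s, e in _merge_spans(spans))
        rows.append({"library_id": lid, "n_annotations": len(sub), "bases": bases,
                     "coverage_pct": round(100.0 * bases / total_len, 4) if total_len else 0.0})
    rows.append({"library_id": "TOTAL", "n_annotations": len(annotations),
                 "bases": None, "coverage_pct": round(coverage_percent(annotations, genome), 4)})
    return rows
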