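"""Branch A step 1: build the candidate-enriched "sub-genome".

A translated search of the genome with a library of reference viral
genomes yields hits; hits are merged into loci, extracted, competitively
classified against a mixed protein bait library (viral proteins vs
retroelement RT/RNaseH), filtered, merged across short gaps and extended
to capture ORF remnants and element/host junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PipelineConfig
from .homsearch import Hit, search
from .seqio import SequenceRecord


@dataclass
class Locus:
    """A merged genomic interval presumed to derive from one integration event."""

    subject_id: str
    start: int
    end: int
    source_hits: list = field(default_factory=list)
    extended: bool = False
    best_bait: tuple | None = None  # (bait_id, klass, score)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty locus {self.subject_id}:{self.start}-{self.end}")


@dataclass
class SubGenomeSegment:
    """An extracted genome slice; segment_id encodes its origin coordinates."""

    segment_id: str
    residues: str
    origin: tuple  # (subject_id, start, end)
    best_bait: tuple | None = None

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(self.segment_id, self.residues, "nt")


def _merge_spans(spans: list[tuple[int, int]], max_gap: int = 0) -> list[tuple[int, int]]:
    """Union of half-open spans; spans whose gap is <= max_gap are joined.

    Touching spans (gap 0) always merge: they are contiguous sequence.
    """
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for s, e in spans[1:]:
        if s - out[-1][1] <= max_gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def merge_overlapping_hits(hits: list[Hit]) -> list[Locus]:
    """Partition the union of hit subject spans into maximal connected loci.

    Strand is ignored: plus- and minus-strand hits to the same region
    belong to the same putative integration.
    """
    by_subject: dict[str, list[Hit]] = {}
    for h in hits:
        by_subject.setdefault(h.subject_id, []).append(h)
    loci = []
    for sid in sorted(by_subject):
        hs = by_subject[sid]
        merged = _merge_spans([(h.s_start, h.s_end) for h in hs])
        for s, e in merged:
            src = [h for h in hs if h.s_start < e and h.s_end > s]
            loci.append(Locus(sid, s, e, source_hits=src))
    return loci


def merge_nearby(loci: list[Locus], max_gap: int) -> list[Locus]:
    """Merge consecutive per-subject loci separated by <= max_gap bp (inclusive)."""
    by_subject: dict[str, list[Locus]] = {}
    for l in loci:
        by_subject.setdefault(l.subject_id, []).append(l)
    out = []
    for sid in sorted(by_subject):
        ls = sorted(by_subject[sid], key=lambda l: l.start)
        cur = ls[0]
        cur_hits = list(cur.source_hits)
        cur_span = [cur.start, cur.end]
        for nxt in ls[1:]:
            if nxt.start - cur_span[1] <= max_gap:
                cur_span[1] = max(cur_span[1], nxt.end)
                cur_hits.extend(nxt.source_hits)
            else:
                out.append(Locus(sid, cur_span[0], cur_span[1], source_hits=cur_hits))
                cur_span = [nxt.start, nxt.end]
                cur_hits = list(nxt.source_hits)
        out.append(Locus(sid, cur_span[0], cur_span[1], source_hits=cur_hits))
    return out


def extract_segments(genome: dict[str, SequenceRecord], loci: list[Locus]) -> list[SubGenomeSegment]:
    """Extract locus slices verbatim; ids encode subject:start-end (0-based half-open)."""
    segs = []
    for l in loci:
        seq = genome[l.subject_id].residues[l.start : l.end]
        segs.append(SubGenomeSegment(f"{l.subject_id}:{l.start}-{l.end}", seq,
                                     (l.subject_id, l.start, l.end)))
    return segs


def extend_and_extract(genome: dict[str, SequenceRecord], loci: list[Locus],
                       extension_bp: int) -> list[SubGenomeSegment]:
    """Grow each locus by extension_bp both sides (clamped), re-merge, extract."""
    by_subject: dict[str, list[tuple[int, int]]] = {}
    for l in loci:
        L = len(genome[l.subject_id])
        s = max(0, l.start - extension_bp)
        e = min(L, l.end + extension_bp)
        by_subject.setdefault(l.subject_id, []).append((s, e))
    out = []
    for sid in sorted(by_subject):
        for s, e in _merge_spans(by_subject[sid]):
            out.append(SubGenomeSegment(f"{sid}:{s}-{e}", genome[sid].residues[s:e], (sid, s, e)))
    return out


def _bait_class(rec: SequenceRecord) -> str:
    klass = rec.tags().get("class", "")
    if klass not in ("caulimovirid", "retroelement"):
        raise ValueError(f"bait {rec.id!r} lacks a class=caulimovirid|retroelement tag")
    return klass


def best_hit_per_target(hits: list[Hit], baits_by_id: dict[str, SequenceRecord],
                        target_is_subject: bool = False) -> dict[str, tuple]:
    """Competitive best bait per target sequence.

    Ties on score break by longer alignment, then caulimovirid class,
    then lexicographic bait id — deterministic and conservative toward
    sensitivity.
    """
    best: dict[str, tuple] = {}
    for h in hits:
        target = h.subject_id if target_is_subject else h.query_id
        bait = h.query_id if target_is_subject else h.subject_id
        klass = _bait_class(baits_by_id[bait])
        rank = (h.score, h.aln_len, klass == "caulimovirid", bait)
        prev = best.get(target)
        if prev is None or rank > prev[0]:
            best[target] = (rank, bait, klass, h.score)
    return {t: (b, k, s) for t, (r, b, k, s) in best.items()}


def bait_filter(segments: list[SubGenomeSegment], baits: list[SequenceRecord],
                cfg: PipelineConfig) -> list[SubGenomeSegment]:
    """Keep a segment iff its single best bait hit is caulimovirid.

    Segments with no bait hit at all are discarded: the pipeline keeps
    only sequences positively classified by best hit.
    """
    if not baits:
        raise ValueError("empty bait library: cannot classify segments")
    baits_by_id = {b.id: b for b in baits}
    if not segments:
        return []
    seg_records = [s.to_record() for s in segments]
    # protein baits as queries against six-frame-translated segments
    hits = search(baits, seg_records, "aa_vs_txnt", cfg.search)
    best = best_hit_per_target(hits, baits_by_id, target_is_subject=True)
    kept = []
    for seg in segments:
        b = best.get(seg.segment_id)
        if b is not None and b[1] == "caulimovirid":
            seg.best_bait = b
            kept.append(seg)
    return kept


def segments_to_loci(segments: list[SubGenomeSegment]) -> list[Locus]:
    out = []
    for seg in segments:
        sid, s, e = seg.origin
        l = Locus(sid, s, e)
        l.best_bait = seg.best_bait
        out.append(l)
    return out


def build_subgenome(genome: dict[str, SequenceRecord], virus_refs: list[SequenceRecord],
                    baits: list[SequenceRecord], cfg: PipelineConfig):
    """Full step-1 composition.

    search -> merge overlapping hits -> extract -> bait filter ->
    merge nearby -> extend and extract. Returns (segments, stage_counts).
    """
    counts = {}
    hits = search(virus_refs, list(genome.values()), "txnt_vs_txnt", cfg.search)
    counts["step1_hits"] = len(hits)
    loci = merge_overlapping_hits(hits)
    counts["step1_merged_loci"] = len(loci)
    raw_segments = extract_segments(genome, loci)
    kept = bait_filter(raw_segments, baits, cfg)
    counts["step1_bait_kept"] = len(kept)
    merged = merge_nearby(segments_to_loci(kept), cfg.merge_gap_bp)
    counts["step1_nearby_merged"] = len(merged)
    segments = extend_and_extract(genome, merged, cfg.extension_bp)
    counts["step1_segments"] = len(segments)
    return segments, counts
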