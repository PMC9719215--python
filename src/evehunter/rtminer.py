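"""Branch B steps 1-2: mine, translate, filter and dereplicate RT proteins.

Reverse transcriptase is the most conserved marker in the order, so the
branch works at protein level throughout: translated search with RT
probes, 120 bp extension to bridge alignment breaks, conceptual
translation with a 200 aa floor, competitive best-hit filtering against
a mixed caulimovirid/retroelement RT library, then 80% greedy centroid
clustering to one representative per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .config import PipelineConfig
from .homsearch import search, global_identity
from .locate import best_hit_per_target
from .seqio import SequenceRecord, reverse_complement, translate


@dataclass
class RTLocus:
    subject_id: str
    start: int
    end: int
    frame: int  # dominant frame: frame of the highest-scoring source hit
    score: int


@dataclass
class RTCandidate:
    candidate_id: str
    origin: tuple  # (subject_id, start, end, frame)
    protein: str
    best_hit_class: str = "none"  # caulimovirid | retroelement | none
    best_hit_genus: str | None = None
    cluster_id: str | None = None
    representative: bool = False

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(self.candidate_id, self.protein, "aa")


def find_rt_loci(genome: dict[str, SequenceRecord], rt_refs: list[SequenceRecord],
                 cfg: PipelineConfig) -> list[RTLocus]:
    """Translated search with RT probes; extend +-rt_flank_bp; merge overlaps."""
    hits = search(rt_refs, list(genome.values()), "aa_vs_txnt", cfg.search)
    spans: dict[str, list] = {}
    for h in hits:
        L = len(genome[h.subject_id])
        s = max(0, h.s_start - cfg.rt_flank_bp)
        e = min(L, h.s_end + cfg.rt_flank_bp)
        spans.setdefault(h.subject_id, []).append((s, e, h.frame_s, h.score))
    loci = []
    for sid in sorted(spans):
        items = sorted(spans[sid])
        cur_s, cur_e, cur_f, cur_sc = items[0]
        for s, e, f, sc in items[1:]:
            if s <= cur_e:  # overlapping extended spans merge
                cur_e = max(cur_e, e)
                if sc > cur_sc:
                    cur_f, cur_sc = f, sc
            else:
                loci.append(RTLocus(sid, cur_s, cur_e, cur_f, cur_sc))
                cur_s, cur_e, cur_f, cur_sc = s, e, f, sc
        loci.append(RTLocus(sid, cur_s, cur_e, cur_f, cur_sc))
    return loci


def _translate_region(seq: str, start: int, end: int, frame: int) -> tuple[str, int]:
    """Translate genome[start:end) in a genome-anchored frame.

    Returns (aa string, nt position of the first translated codon on the
    strand read); the frame phase is that of the whole sequence, so the
    first full codon inside the window is located first.
    """
    L = len(seq)
    if frame > 0:
        phase = frame - 1
        first = start + ((phase - start) % 3)
        sub = seq[first:end]
        return translate(sub), first
    phase = -frame - 1
    # coordinates on the reverse complement strand
    r_start, r_end = L - end, L - start
    first = r_start + ((phase - r_start) % 3)
    rc = reverse_complement(seq)
    sub = rc[first:r_end]
    return translate(sub), first


def extract_rt_proteins(genome: dict[str, SequenceRecord], loci: list[RTLocus],
                        cfg: PipelineConfig) -> list[RTCandidate]:
    """Translate each locus in its dominant frame; keep stop-free segments >= 200 aa."""
    out = []
    n = 0
    for loc in loci:
        seq = genome[loc.subject_id].residues
        aa, first = _translate_region(seq, loc.start, loc.end, loc.frame)
        pos = 0
        for seg in aa.split("*"):
            if len(seg) >= cfg.min_protein_aa:
                n += 1
                # nt span of the segment on the read strand
                nt_s = first + 3 * pos
                nt_e = nt_s + 3 * len(seg)
                if loc.frame < 0:
                    L = len(seq)
                    nt_s, nt_e = L - nt_e, L - nt_s
                out.append(RTCandidate(f"rt{n:04d}_{loc.subject_id}",
                                       (loc.subject_id, nt_s, nt_e, loc.frame), seg))
            pos += len(seg) + 1
    return out


def rt_best_hit_filter(candidates: list[RTCandidate], rt_library: list[SequenceRecord],
                       cfg: PipelineConfig) -> list[RTCandidate]:
    """Keep candidates whose top-scoring library RT is caulimovirid."""
    if not candidates:
        return []
    lib_by_id = {r.id: r for r in rt_library}
    recs = [c.to_record() for c in candidates]
    hits = search(recs, rt_library, "aa_aa", cfg.search)
    best = best_hit_per_target(hits, lib_by_id, target_is_subject=False)
    kept = []
    for c in candidates:
        b = best.get(c.candidate_id)
        if b is None:
            c.best_hit_class = "none"
            continue
        bait_id, klass, score = b
        c.best_hit_class = klass
        c.best_hit_genus = lib_by_id[bait_id].tags().get("genus")
        if klass == "caulimovirid":
            kept.append(c)
    return kept


def cluster_greedy_centroid(candidates: list[RTCandidate],
                            identity_pct: float = 80.0) -> list[RTCandidate]:
    """Greedy length-sorted centroid clustering (80% aa identity default).

    Each sequence joins the first centroid (in founding order) reached at
    >= identity on a global alignment, else founds a new cluster; the
    centroid is the cluster representative. Returns the representatives.
    """
    ordered = sorted(candidates, key=lambda c: (-len(c.protein), c.candidate_id))
    centroids: list[RTCandidate] = []
    for c in ordered:
        placed = False
        for cen in centroids:
            if global_identity(c.protein, cen.protein) >= identity_pct:
                c.cluster_id = cen.cluster_id
                c.representative = False
                placed = True
                break
        if not placed:
            c.cluster_id = f"RC{len(centroids) + 1:03d}"
            c.representative = True
            centroids.append(c)
    return centroids


def mine_rt_proteins(genome: dict[str, SequenceRecord], rt_refs: list[SequenceRecord],
                     rt_library: list[SequenceRecord], cfg: PipelineConfig):
    """Steps 1-2 composition; returns (representatives, all_candidates, counts)."""
    counts = {}
    loci = find_rt_loci(genome, rt_refs, cfg)
    counts["rt_loci"] = len(loci)
    candidates = extract_rt_proteins(genome, loci, cfg)
    counts["rt_orfs"] = len(candidates)
    kept = rt_best_hit_filter(candidates, rt_library, cfg)
    counts["rt_best_hit_kept"] = len(kept)
    reps = cluster_greedy_centroid(kept, cfg.rt_cluster_identity_pct)
    counts["rt_representatives"] = len(reps)
    return reps, candidates, counts
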