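"""Branch A step 3: characterize, filter, classify and cluster consensi.

Domain detection uses bundled position-specific scoring models (one per
conserved domain: RT core with its YxDD motif, RNaseH, aspartyl
protease, movement protein, Gag-like CCHC zinc finger, integrase,
transposase). A consensus containing a TE-specific domain (integrase or
transposase) is a chimera candidate and is removed when the chimera
filter is on; the zinc finger is shared with caulimovirids and never
triggers removal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .config import PipelineConfig
from .consensus import ConsensusRecord, _UnionFind
from .homsearch import AA_MATRIX, encode_aa, infix_align, search
from .locate import best_hit_per_target
from .seqio import SequenceRecord, reverse_complement, translate_frames

TE_SPECIFIC = {"integrase", "transposase"}


@dataclass
class DomainProfile:
    name: str
    klass: str  # caulimovirid_associated | te_specific | shared
    consensus: str
    cutoff: float  # absolute score threshold

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass
class DomainHit:
    name: str
    start: int  # aa coordinates on the translated frame
    end: int
    frame: int
    score: float
    klass: str


def load_profiles() -> dict[str, DomainProfile]:
    """Load the bundled domain profile set; cutoff = cutoff_frac x self-score."""
    text = resources.files("evehunter.data").joinpath("domain_profiles.json").read_text()
    raw = json.loads(text)
    out = {}
    for name, p in raw.items():
        codes = encode_aa(p["consensus"])
        self_score = float(AA_MATRIX[codes, codes].sum())
        out[name] = DomainProfile(name, p["klass"], p["consensus"],
                                  cutoff=p["cutoff_frac"] * self_score)
    return out


def _scan_profile(seq_codes: np.ndarray, profile: DomainProfile) -> list[tuple[int, float]]:
    """Ungapped PSSM scan; returns (offset, score) above the profile cutoff."""
    L = profile.length
    n = len(seq_codes) - L + 1
    if n <= 0:
        return []
    cons = encode_aa(profile.consensus)
    win = np.lib.stride_tricks.sliding_window_view(seq_codes, L)
    scores = AA_MATRIX[cons[np.newaxis, :], win].sum(axis=1)
    idx = np.flatnonzero(scores >= profile.cutoff)
    return [(int(i), float(scores[i])) for i in idx]


def scan_domains(record: ConsensusRecord | SequenceRecord,
                 profiles: dict[str, DomainProfile] | None = None) -> list[DomainHit]:
    """Scan all six frames of a nucleotide record for conserved domains.

    Overlapping candidate hits within a frame are resolved by greedy
    best-score selection.
    """
    if profiles is None:
        profiles = load_profiles()
    if not profiles:
        raise ValueError("empty profile set")
    residues = record.residues
    hits: list[DomainHit] = []
    for frame, aa in translate_frames(residues).items():
        codes = encode_aa(aa)
        candidates = []
        for prof in profiles.values():
            for off, score in _scan_profile(codes, prof):
                candidates.append(DomainHit(prof.name, off, off + prof.length,
                                            frame, score, prof.klass))
        candidates.sort(key=lambda d: (-d.score, d.start, d.name))
        chosen: list[DomainHit] = []
        for c in candidates:
            if all(c.end <= k.start or c.start >= k.end for k in chosen):
                chosen.append(c)
        hits.extend(chosen)
    hits.sort(key=lambda d: (d.frame, d.start))
    if isinstance(record, ConsensusRecord):
        record.domains = hits
    return hits


def filter_chimeras(consensi: list[ConsensusRecord], enabled: bool = True) -> list[ConsensusRecord]:
    """Remove records carrying a TE-specific domain (when enabled)."""
    if not enabled:
        return list(consensi)
    return [c for c in consensi if not any(d.klass == "te_specific" for d in c.domains)]


def classify_best_hit(consensi: list[ConsensusRecord], baits: list[SequenceRecord],
                      cfg: PipelineConfig) -> None:
    """Competitive best-hit classification of each consensus against the baits.

    Sets best_bait = (bait_id, class, genus, score); records whose best
    hit is a retroelement protein, or which have no bait hit, are left
    flagged non-caulimovirid (best_bait None or retroelement class).
    """
    if not consensi:
        return
    baits_by_id = {b.id: b for b in baits}
    recs = [c.to_record() for c in consensi]
    hits = search(baits, recs, "aa_vs_txnt", cfg.search)
    best = best_hit_per_target(hits, baits_by_id, target_is_subject=True)
    for c in consensi:
        b = best.get(c.id)
        if b is None:
            c.best_bait = None
        else:
            bait_id, klass, score = b
            genus = baits_by_id[bait_id].tags().get("genus", "")
            c.best_bait = (bait_id, klass, genus, score)


def is_caulimovirid(c: ConsensusRecord) -> bool:
    return c.best_bait is not None and c.best_bait[1] == "caulimovirid"


@dataclass
class Cluster:
    cluster_id: str
    member_ids: list[str]
    has_caulimovirid_best_hit: bool = False


def cluster_identity_coverage(seqs: list, S: float = 90.0, L: float = 0.9,
                              coverage_mode: str = "both") -> list[Cluster]:
    """Single-linkage clustering on pairwise identity and coverage.

    Two sequences link iff their best containment alignment reaches
    identity >= S with aligned coverage >= L of both sequences (the
    shorter is fully aligned by construction, so the binding condition
    is on the longer; coverage_mode "either" drops that condition).
    The partition is independent of input order.
    """
    items = sorted(seqs, key=lambda r: r.id if hasattr(r, "id") else r)
    ids = [r.id for r in items]
    res = {r.id: r.residues for r in items}
    uf = _UnionFind()
    for i in ids:
        uf.find(i)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = res[ids[i]], res[ids[j]]
            short, long = (a, b) if len(a) <= len(b) else (b, a)
            # consensi are strand-arbitrary: take the better orientation
            identity, cov_long, _ = infix_align(short, long)
            if set(short) <= set("ACGTNRYSWKMBDHV"):
                ident_rc, cov_rc, _ = infix_align(reverse_complement(short), long)
                if ident_rc > identity:
                    identity, cov_long = ident_rc, cov_rc
            if identity < S:
                continue
            if coverage_mode == "both" and cov_long < L:
                continue
            uf.union(ids[i], ids[j])
    comps: dict[str, list[str]] = {}
    for i in ids:
        comps.setdefault(uf.find(i), []).append(i)
    clusters = []
    for n, root in enumerate(sorted(comps, key=lambda r: min(comps[r])), start=1):
        clusters.append(Cluster(f"C{n:03d}", sorted(comps[root])))
    return clusters


def select_library(clusters: list[Cluster], consensi: list[ConsensusRecord],
                   supplementation: bool = False) -> list[ConsensusRecord]:
    """Select consensi with caulimovirid best hits; optionally whole clusters.

    Redundancy is intentionally kept: structural variants and bipartite
    components must all survive selection.
    """
    by_id = {c.id: c for c in consensi}
    for cl in clusters:
        cl.has_caulimovirid_best_hit = any(
            is_caulimovirid(by_id[m]) for m in cl.member_ids if m in by_id
        )
        for m in cl.member_ids:
            if m in by_id:
                by_id[m].cluster_id = cl.cluster_id
    selected_ids = {c.id for c in consensi if is_caulimovirid(c)}
    if supplementation:
        for cl in clusters:
            if cl.has_caulimovirid_best_hit:
                selected_ids.update(m for m in cl.member_ids if m in by_id)
    out = []
    for c in consensi:
        c.selected = c.id in selected_ids
        if c.selected:
            out.append(c)
    return out


def flag_concatemers(record: ConsensusRecord, cfg: PipelineConfig) -> tuple[bool, tuple | None]:
    """Detect tandem multimers of a genome unit by self-comparison.

    A same-strand off-diagonal self-hit of >= concatemer_min_hit columns
    at >= concatemer_min_identity implies >= 2 tandem unit copies; the
    monomer is read off the smallest diagonal offset.
    """
    record.concatemer = False
    record.monomer_span = None
    if len(record.residues) < cfg.concatemer_min_len:
        return False, None
    rec = record.to_record()
    hits = search([rec], [rec], "nt_nt", cfg.search,
                  min_aln_len=cfg.concatemer_min_hit,
                  min_identity=cfg.concatemer_min_identity)
    offsets = []
    for h in hits:
        if h.strand != "+":
            continue
        off = h.s_start - h.q_start
        if abs(off) >= 500 and h.aln_len >= cfg.concatemer_min_hit:
            offsets.append((abs(off), min(h.q_start, h.s_start)))
    if not offsets:
        return False, None
    unit, start = min(offsets)
    record.concatemer = True
    record.monomer_span = (start, start + unit)
    return True, record.monomer_span
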