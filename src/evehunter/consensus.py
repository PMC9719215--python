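"""Branch A step 2: group repetitive sub-genome sequences, build consensi.

The de novo repeat-discovery stage is a defined, testable procedure:
all-vs-all nucleotide search of the sub-genome at a high identity
threshold, a span graph whose nodes are HSP end intervals (near-duplicate
spans on the same segment fused), connected components as repeat groups,
and a star alignment with extent-aware majority calling as the consensus
builder. Repeats with >=85% identity and >= hsp_min copies yield a
consensus, which is the contract the original multi-program clustering
stage provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .config import PipelineConfig
from .homsearch import Hit, search, _cigar_ops
from .locate import SubGenomeSegment
from .seqio import SequenceRecord, reverse_complement

IUPAC_FROM_SET = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class GroupMember:
    segment_id: str
    start: int
    end: int
    orient: str = "+"  # orientation relative to the group root

    def length(self) -> int:
        return self.end - self.start


@dataclass
class HspGroup:
    group_id: str
    members: list[GroupMember]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusRecord:
    id: str
    residues: str
    group_id: str
    domains: list = field(default_factory=list)
    best_bait: tuple | None = None
    cluster_id: str | None = None
    concatemer: bool = False
    monomer_span: tuple | None = None
    selected: bool = False

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(self.id, self.residues, "nt")


def find_subgenome_hsps(segments: list[SubGenomeSegment], cfg: PipelineConfig) -> list[Hit]:
    """All-vs-all nt search of the sub-genome.

    Self-hits (main diagonal) and mirror duplicates are excluded; only
    HSPs with identity >= subgenome_identity_pct over >= 100 columns are
    admitted. Off-diagonal self-hits are kept: they reveal tandem
    structure within a segment.
    """
    if len(segments) < 2 and not segments:
        return []
    recs = [s.to_record() for s in segments]
    hits = search(recs, recs, "nt_nt", cfg.search,
                  min_aln_len=cfg.subgenome_min_hsp_len,
                  min_identity=cfg.subgenome_identity_pct)
    kept = []
    for h in hits:
        if h.query_id == h.subject_id:
            if h.strand == "+" and abs(h.q_start - h.s_start) < 50:
                continue  # trivial self-match
            if h.q_start >= h.s_start:
                continue  # mirror duplicate of an off-diagonal self-hit
        elif h.query_id > h.subject_id:
            continue  # mirror duplicate across the symmetric pair
        kept.append(h)
    return kept


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        if p != x:
            self.parent[x] = p = self.find(p)
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _mutual_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return False
    return ov / (a[1] - a[0]) >= 0.8 and ov / (b[1] - b[0]) >= 0.8


def group_hsps(hits: list[Hit], cfg: PipelineConfig) -> list[HspGroup]:
    """Build repeat groups from HSP span graph connected components.

    Each hit contributes its query-side and subject-side span as nodes;
    spans on the same segment with >=80% mutual overlap fuse into one
    member; hits connect members; components with >= hsp_min members of
    >=100 bp become groups. Member orientation relative to the component
    root is propagated along hit edges (minus-strand hits flip).
    """
    nodes = []  # (segment_id, start, end)
    edges = []  # (node_idx_a, node_idx_b, flip)
    for h in hits:
        ia = len(nodes)
        nodes.append((h.query_id, h.q_start, h.q_end))
        ib = len(nodes)
        nodes.append((h.subject_id, h.s_start, h.s_end))
        edges.append((ia, ib, h.strand == "-"))
    if not nodes:
        return []

    # fuse near-duplicate spans per segment
    fuse = _UnionFind()
    by_seg: dict[str, list[int]] = {}
    for i, (sid, s, e) in enumerate(nodes):
        by_seg.setdefault(sid, []).append(i)
    for sid, idxs in by_seg.items():
        idxs.sort(key=lambda i: nodes[i][1])
        for ai in range(len(idxs)):
            a = idxs[ai]
            for bi in range(ai + 1, len(idxs)):
                b = idxs[bi]
                if nodes[b][1] >= nodes[a][2]:
                    break
                if _mutual_overlap(nodes[a][1:], nodes[b][1:]):
                    fuse.union(a, b)

    # member representative: longest raw span in each fused set
    rep: dict[int, int] = {}
    for i in range(len(nodes)):
        r = fuse.find(i)
        if r not in rep or (nodes[i][2] - nodes[i][1]) > (nodes[rep[r]][2] - nodes[rep[r]][1]):
            rep[r] = i

    # connect members through hit edges, tracking orientation parity
    comp = _UnionFind()
    adj: dict[int, list[tuple[int, bool]]] = {}
    for ia, ib, flip in edges:
        ma, mb = fuse.find(ia), fuse.find(ib)
        comp.union(ma, mb)
        adj.setdefault(ma, []).append((mb, flip))
        adj.setdefault(mb, []).append((ma, flip))
    # containment edges: spans on one segment overlapping >= 80% of the
    # smaller span belong to the same repeat family even when they are
    # too unequal in length to fuse (e.g. a tandem double-unit span and
    # its single units, or a fragment match inside a full-length match)
    for sid, idxs in by_seg.items():
        for ai in range(len(idxs)):
            a = fuse.find(idxs[ai])
            sa, ea = nodes[idxs[ai]][1:]
            for bi in range(ai + 1, len(idxs)):
                b = fuse.find(idxs[bi])
                if b == a:
                    continue
                sb, eb = nodes[idxs[bi]][1:]
                if sb >= ea:
                    break
                ov = min(ea, eb) - max(sa, sb)
                if ov > 0 and ov / min(ea - sa, eb - sb) >= 0.8:
                    comp.union(a, b)
                    adj.setdefault(a, []).append((b, False))
                    adj.setdefault(b, []).append((a, False))

    members_by_comp: dict[int, list[int]] = {}
    for r in rep:
        members_by_comp.setdefault(comp.find(r), []).append(r)

    groups = []
    gnum = 0
    for croot in sorted(members_by_comp, key=lambda r: min(members_by_comp[r])):
        member_roots = members_by_comp[croot]
        # orientation by BFS over hit edges
        orient: dict[int, bool] = {}
        start_root = min(member_roots)
        orient[start_root] = False
        queue = [start_root]
        while queue:
            cur = queue.pop()
            for nxt, flip in adj.get(cur, []):
                want = orient[cur] ^ flip
                if nxt not in orient:
                    orient[nxt] = want
                    queue.append(nxt)
        members = []
        for r in sorted(member_roots):
            sid, s, e = nodes[rep[r]]
            if e - s < 100:
                continue
            members.append(GroupMember(sid, s, e, "-" if orient.get(r, False) else "+"))
        if len(members) >= cfg.hsp_min:
            gnum += 1
            groups.append(HspGroup(f"G{gnum:03d}", members))
    return groups


def _star_align_columns(backbone: str, others: list[str]):
    """Align each sequence to the backbone; return per-row extents and cells.

    Rows are (extent_start, extent_end, base_cells, ins_cells) where
    base_cells maps backbone positions to residues and ins_cells maps
    (boundary_pos, offset) to inserted residues.
    """
    rows = []
    L = len(backbone)
    rows.append((0, L, dict(enumerate(backbone)), {}))
    for seq in others:
        base: dict[int, str] = {}
        ins: dict[tuple[int, int], str] = {}
        first = last = None
        if len(seq) <= L:
            # compact infix placement of the member within the backbone;
            # a global alignment would smear short members across the
            # backbone and corrupt per-column occupancy
            res = edlib.align(seq, backbone, mode="HW", task="path")
            ti = res["locations"][0][0]
            qi = 0
            for n, op in _cigar_ops(res["cigar"]):
                if op in "=XM":
                    for j in range(n):
                        base[ti + j] = seq[qi + j]
                    if first is None:
                        first = ti
                    last = ti + n
                    qi += n
                    ti += n
                elif op == "I":  # member residues absent from backbone
                    for j in range(n):
                        ins[(ti, j)] = seq[qi + j]
                    qi += n
                else:  # D: backbone positions deleted in the member
                    for j in range(n):
                        base[ti + j] = "-"
                    ti += n
        else:
            # member longer than backbone: place the backbone inside the
            # member; member overhangs beyond the backbone are dropped
            res = edlib.align(backbone, seq, mode="HW", task="path")
            qi = res["locations"][0][0]  # position in the member
            ti = 0
            for n, op in _cigar_ops(res["cigar"]):
                if op in "=XM":
                    for j in range(n):
                        base[ti + j] = seq[qi + j]
                    if first is None:
                        first = ti
                    last = ti + n
                    qi += n
                    ti += n
                elif op == "I":  # backbone positions with no member residue
                    for j in range(n):
                        base[ti + j] = "-"
                    ti += n
                else:  # D: extra member residues -> insertion columns
                    for j in range(n):
                        ins[(ti, j)] = seq[qi + j]
                    qi += n
        if first is None:
            first, last = 0, 0
        rows.append((first, last, base, ins))
    return rows


def build_group_consensus(group: HspGroup, segments: dict[str, str],
                          cfg: PipelineConfig) -> ConsensusRecord:
    """Majority-call consensus over up to group_cap members (longest first).

    Column occupancy is measured against rows whose aligned extent spans
    the column: leading/trailing gaps are missing data, not deletions,
    so a long (e.g. tandem) backbone is not truncated by shorter members.
    Columns with <50% occupancy are dropped; ties emit IUPAC codes.
    """
    usable = [m for m in group.members if m.length() >= 100]
    if len(usable) < 2:
        raise ValueError(f"group {group.group_id}: fewer than 2 usable members")
    usable.sort(key=lambda m: (-m.length(), m.segment_id, m.start))
    usable = usable[: cfg.group_cap]
    seqs = []
    for m in usable:
        s = segments[m.segment_id][m.start : m.end]
        seqs.append(reverse_complement(s) if m.orient != usable[0].orient else s)
    backbone, others = seqs[0], seqs[1:]
    rows = _star_align_columns(backbone, others)

    L = len(backbone)
    out = []
    ins_keys: dict[int, set[int]] = {}
    for _, _, _, ins in rows:
        for (p, j) in ins:
            ins_keys.setdefault(p, set()).add(j)

    def call(column_residues: list[str], spanning: int) -> str | None:
        non_gap = [c for c in column_residues if c != "-"]
        if spanning == 0 or len(non_gap) / spanning < 0.5:
            return None
        counts: dict[str, int] = {}
        for c in non_gap:
            counts[c] = counts.get(c, 0) + 1
        top = max(counts.values())
        winners = frozenset(c for c, n in counts.items() if n == top)
        if len(winners) == 1:
            return next(iter(winners))
        return IUPAC_FROM_SET.get(frozenset().union(*[set(w) for w in winners]), "N")

    for p in range(L + 1):
        # insertion columns at boundary p, in offset order
        for j in sorted(ins_keys.get(p, ())):
            col = []
            spanning = 0
            for (a, b, base, ins) in rows:
                if a <= p <= b:
                    spanning += 1
                    col.append(ins.get((p, j), "-"))
            c = call(col, spanning)
            if c is not None:
                out.append(c)
        if p == L:
            break
        col = []
        spanning = 0
        for (a, b, base, ins) in rows:
            if a <= p < b:
                spanning += 1
                col.append(base.get(p, "-"))
        c = call(col, spanning)
        if c is not None:
            out.append(c)

    return ConsensusRecord(id=f"{group.group_id}_cons", residues="".join(out),
                           group_id=group.group_id)


def build_consensus_library(segments: list[SubGenomeSegment], cfg: PipelineConfig):
    """Step-2 composition: HSPs -> groups -> consensi. Returns (consensi, groups, counts)."""
    counts = {}
    hsps = find_subgenome_hsps(segments, cfg)
    counts["step2_hsps"] = len(hsps)
    groups = group_hsps(hsps, cfg)
    counts["step2_groups"] = len(groups)
    seq_by_id = {s.segment_id: s.residues for s in segments}
    consensi = []
    for g in groups:
        try:
            rec = build_group_consensus(g, seq_by_id, cfg)
        except ValueError:
            continue
        if len(rec.residues) >= 100:
            consensi.append(rec)
    counts["step2_consensi"] = len(consensi)
    return consensi, groups, counts
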