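"""Built-in seed-and-extend local homology search.

Provides the four comparison modes the pipeline needs (nt-nt, aa-aa,
protein vs six-frame-translated nucleotide, six-frame vs six-frame)
behind one :func:`search` entry point, plus pairwise global alignment
utilities. Significance is a raw score + identity threshold — the engine
is deterministic and independent of database size.

Any external engine producing :class:`Hit` records with the same
semantics can be substituted by the caller; this built-in engine is the
default and the only one exercised by the shipped tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio.Align import substitution_matrices

from . import _kernels
from .config import SearchParams
from .seqio import SequenceRecord, frame_to_genome_span, reverse_complement, translate_frames

# ---------------------------------------------------------------------------
# Alphabet encodings

NT_ORDER = "ACGT"
NT_AMBIG = 4
NT_SENT = 5
NT_NCODES = 6

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_X = 20
AA_STOP = 21
AA_SENT = 22
AA_NCODES = 23

_NT_LUT = np.full(256, NT_AMBIG, dtype=np.uint8)
for _i, _c in enumerate(NT_ORDER):
    _NT_LUT[ord(_c)] = _i
_NT_LUT[ord("a")] = 0
_NT_LUT[ord("c")] = 1
_NT_LUT[ord("g")] = 2
_NT_LUT[ord("t")] = 3

_AA_LUT = np.full(256, AA_X, dtype=np.uint8)
for _i, _c in enumerate(AA_ORDER):
    _AA_LUT[ord(_c)] = _i
_AA_LUT[ord("*")] = AA_STOP


def encode_nt(s: str) -> np.ndarray:
    return _NT_LUT[np.frombuffer(s.encode(), dtype=np.uint8)]


def encode_aa(s: str) -> np.ndarray:
    return _AA_LUT[np.frombuffer(s.encode(), dtype=np.uint8)]


def _build_nt_matrix(match: int, mismatch: int) -> np.ndarray:
    m = np.full((NT_NCODES, NT_NCODES), mismatch, dtype=np.int64)
    for i in range(4):
        m[i, i] = match
    m[NT_SENT, :] = -10000
    m[:, NT_SENT] = -10000
    return m


def _build_aa_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((AA_NCODES, AA_NCODES), dtype=np.int64)
    letters = AA_ORDER + "X"
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            m[i, j] = int(blosum[a][b])
    # Stop codons terminate homology: heavily penalized against everything.
    m[AA_STOP, :] = -8
    m[:, AA_STOP] = -8
    m[AA_SENT, :] = -10000
    m[:, AA_SENT] = -10000
    return m


AA_MATRIX = _build_aa_matrix()

MODES = ("nt_nt", "aa_aa", "aa_vs_txnt", "txnt_vs_txnt")


@dataclass
class Hit:
    """One local homology match (an HSP).

    Coordinates are 0-based half-open on the *forward strand* of the
    untranslated query/subject sequences, regardless of match strand or
    frame. ``strand`` is the subject strand of the match.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"
    frame_q: int | None = None
    frame_s: int | None = None
    identity_pct: float = 0.0
    score: int = 0
    aln_len: int = 0

    def s_span(self) -> tuple[int, int]:
        return self.s_start, self.s_end


# ---------------------------------------------------------------------------
# Pairwise alignment utilities (edlib-backed)

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


def _walk_cigar(q: str, t: str, cigar: str, matrix: np.ndarray, lut: np.ndarray,
                gap_open: int, gap_extend: int) -> tuple[int, int, int]:
    """Return (matches, columns, score) for an edlib path.

    edlib convention: 'I' consumes query only, 'D' consumes target only.
    """
    qc = lut[np.frombuffer(q.encode(), dtype=np.uint8)]
    tc = lut[np.frombuffer(t.encode(), dtype=np.uint8)]
    qi = ti = 0
    matches = cols = 0
    score = 0
    for n, op in _cigar_ops(cigar):
        cols += n
        if op in "=XM":
            score += int(matrix[qc[qi : qi + n], tc[ti : ti + n]].sum())
            if op == "=":
                matches += n
            elif op == "M":
                matches += int((qc[qi : qi + n] == tc[ti : ti + n]).sum())
            qi += n
            ti += n
        elif op == "I":
            score += gap_open + gap_extend * n
            qi += n
        else:  # D
            score += gap_open + gap_extend * n
            ti += n
    return matches, cols, score


@dataclass
class PairAlignment:
    identity_pct: float
    coverage_a: float
    coverage_b: float
    aln_len: int
    matches: int
    cigar: str


def align_pair(a: SequenceRecord | str, b: SequenceRecord | str,
               alphabet: str = "nt") -> PairAlignment:
    """Global pairwise alignment of two same-alphabet sequences.

    identity = matches / alignment columns; coverage_of_x = extent of x
    aligned opposite non-gap residues of the partner, as a fraction of
    len(x).
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    res = edlib.align(sa, sb, mode="NW", task="path")
    cigar = res["cigar"]
    lut = _NT_LUT if alphabet == "nt" else _AA_LUT
    matrix = _build_nt_matrix(1, -2) if alphabet == "nt" else AA_MATRIX
    matches, cols, _ = _walk_cigar(sa, sb, cigar, matrix, lut, -5, -2)
    # aligned extent in each sequence: first..last column where both consume
    qi = ti = 0
    qa0 = qa1 = ta0 = ta1 = None
    for n, op in _cigar_ops(cigar):
        if op in "=XM":
            if qa0 is None:
                qa0, ta0 = qi, ti
            qa1, ta1 = qi + n, ti + n
            qi += n
            ti += n
        elif op == "I":
            qi += n
        else:
            ti += n
    cov_a = 0.0 if qa0 is None else (qa1 - qa0) / len(sa)
    cov_b = 0.0 if ta0 is None else (ta1 - ta0) / len(sb)
    return PairAlignment(
        identity_pct=100.0 * matches / cols if cols else 0.0,
        coverage_a=cov_a,
        coverage_b=cov_b,
        aln_len=cols,
        matches=matches,
        cigar=cigar,
    )


def infix_align(short: str, long: str) -> tuple[float, float, int]:
    """Best alignment of ``short`` inside ``long`` (containment semantics).

    Returns (identity_pct over the aligned region, coverage of the longer
    sequence, aligned columns). Used by the identity/coverage clustering
    steps, whose reference semantics score a contained sequence against
    the region of the longer sequence it matches rather than against
    end-to-end global columns.
    """
    if not short or not long:
        raise ValueError("cannot align an empty sequence")
    res = edlib.align(short, long, mode="HW", task="path")
    start, end = res["locations"][0]
    cigar = res["cigar"]
    t_sub = long[start : end + 1]
    matches, cols, _ = _walk_cigar(short, t_sub, cigar, _build_nt_matrix(1, -2), _NT_LUT, -5, -2)
    identity = 100.0 * matches / cols if cols else 0.0
    coverage_long = (end + 1 - start) / len(long)
    return identity, coverage_long, cols


def global_identity(a: str, b: str) -> float:
    """Identity over all columns of a global (NW) alignment."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    res = edlib.align(a, b, mode="NW", task="path")
    matches, cols, _ = _walk_cigar(a, b, res["cigar"], _build_nt_matrix(1, -2), _NT_LUT, -5, -2)
    return 100.0 * matches / cols if cols else 0.0


# ---------------------------------------------------------------------------
# Search engine

class _Unit:
    """One searchable strand/frame of an input record."""

    __slots__ = ("rec_id", "text", "codes", "kind", "frame", "nt_len", "rev")

    def __init__(self, rec_id, text, codes, kind, frame, nt_len):
        self.rec_id = rec_id
        self.text = text
        self.codes = codes
        self.kind = kind  # "nt+", "nt-", "aa", "frame"
        self.frame = frame
        self.nt_len = nt_len
        self.rev = None  # reversed codes, built lazily

    def reversed_codes(self) -> np.ndarray:
        if self.rev is None:
            self.rev = self.codes[::-1].copy()
        return self.rev


def _nt_units(records, with_minus: bool):
    units = []
    for rec in records:
        units.append(_Unit(rec.id, rec.residues, encode_nt(rec.residues), "nt+", None, len(rec)))
        if with_minus:
            rc = reverse_complement(rec.residues)
            units.append(_Unit(rec.id, rc, encode_nt(rc), "nt-", None, len(rec)))
    return units


def _aa_units(records):
    return [_Unit(r.id, r.residues, encode_aa(r.residues), "aa", None, len(r)) for r in records]


def _frame_units(records):
    units = []
    for rec in records:
        for f, aa in translate_frames(rec.residues).items():
            if aa:
                units.append(_Unit(rec.id, aa, encode_aa(aa), "frame", f, len(rec)))
    return units


def _concat(units, sentinel):
    parts = []
    offsets = np.empty(len(units), dtype=np.int64)
    pos = 0
    for i, u in enumerate(units):
        offsets[i] = pos
        parts.append(u.codes)
        parts.append(np.array([sentinel], dtype=np.uint8))
        pos += len(u.codes) + 1
    if not parts:
        return np.array([], dtype=np.uint8), offsets
    return np.concatenate(parts), offsets


def _kmer_keys(codes: np.ndarray, k: int, base: int, max_code: int):
    """Rolling k-mer keys and validity mask over a code array."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.array([], dtype=np.int64), np.array([], dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = base ** np.arange(k - 1, -1, -1, dtype=np.int64)
    keys = win.astype(np.int64) @ powers
    valid = (win < max_code).all(axis=1)
    return keys, valid


def _skip_homopolymers(codes: np.ndarray, k: int, valid: np.ndarray) -> None:
    if len(codes) < k:
        return
    eq = codes[1:] == codes[:-1]
    if len(eq) >= k - 1:
        runs = np.lib.stride_tricks.sliding_window_view(eq, k - 1).all(axis=1)
        valid[: len(runs)] &= ~runs


def _gather_pairs(q_keys, q_valid, s_keys, s_valid):
    """All (query_pos, subject_pos) exact k-mer matches, vectorized."""
    s_pos = np.flatnonzero(s_valid)
    if len(s_pos) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    sk = s_keys[s_pos]
    order = np.argsort(sk, kind="stable")
    sk_sorted = sk[order]
    sp_sorted = s_pos[order]
    q_pos = np.flatnonzero(q_valid)
    if len(q_pos) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    qk = q_keys[q_pos]
    left = np.searchsorted(sk_sorted, qk, side="left")
    right = np.searchsorted(sk_sorted, qk, side="right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    start_offsets = np.cumsum(counts) - counts
    flat = np.arange(total, dtype=np.int64) - np.repeat(start_offsets, counts) + np.repeat(left, counts)
    return np.repeat(q_pos, counts), sp_sorted[flat]


def _unit_of(offsets, lengths, gpos):
    idx = int(np.searchsorted(offsets, gpos, side="right")) - 1
    local = int(gpos - offsets[idx])
    return idx, local


def _search_units(q_units, s_units, params: SearchParams, aa: bool,
                  min_score: int, min_identity: float, min_aln_len: int):
    """Core engine: seed, extend, realign. Returns unit-level hit tuples."""
    if not q_units or not s_units:
        return []
    if aa:
        k, base, max_code = params.aa_seed_len, 32, AA_X  # exclude X and * from seeds
        matrix = AA_MATRIX
        lut = _AA_LUT
        gap_open, gap_extend = params.aa_gap_open, params.aa_gap_extend
        xd_u, xd_g = params.xdrop_ungapped_aa, params.xdrop_gapped_aa
        trigger = params.ungapped_trigger_aa
        sentinel = AA_SENT
    else:
        k, base, max_code = params.nt_seed_len, 4, 4
        matrix = _build_nt_matrix(params.nt_match, params.nt_mismatch)
        lut = _NT_LUT
        gap_open, gap_extend = params.nt_gap_open, params.nt_gap_extend
        xd_u, xd_g = params.xdrop_ungapped_nt, params.xdrop_gapped_nt
        trigger = params.ungapped_trigger_nt
        sentinel = NT_SENT

    q_cat, q_off = _concat(q_units, sentinel)
    s_cat, s_off = _concat(s_units, sentinel)
    q_keys, q_valid = _kmer_keys(q_cat, k, base, max_code)
    s_keys, s_valid = _kmer_keys(s_cat, k, base, max_code)
    _skip_homopolymers(q_cat, k, q_valid)
    _skip_homopolymers(s_cat, k, s_valid)
    if aa and params.aa_seed_self_score_min > 0:
        diag = matrix.diagonal().astype(np.int64)
        per_pos = diag[q_cat]
        cs = np.concatenate(([0], np.cumsum(per_pos)))
        self_scores = cs[k:] - cs[:-k]
        q_valid &= self_scores >= params.aa_seed_self_score_min

    qg, sg = _gather_pairs(q_keys, q_valid, s_keys, s_valid)
    if len(qg) == 0:
        return []

    diag = sg - qg
    order = np.lexsort((sg, diag))
    d_s, s_s, q_s = diag[order], sg[order], qg[order]
    # unit indices: a run must not straddle two different unit pairs even
    # when they happen to share a global diagonal
    qu_s = np.searchsorted(q_off, q_s, side="right") - 1
    su_s = np.searchsorted(s_off, s_s, side="right") - 1
    new_run = np.empty(len(d_s), dtype=bool)
    new_run[0] = True
    new_run[1:] = ((np.diff(d_s) != 0) | (np.diff(s_s) > 64)
                   | (np.diff(qu_s) != 0) | (np.diff(su_s) != 0))
    starts = np.flatnonzero(new_run)
    run_lens = np.diff(np.append(starts, len(d_s)))
    if aa and params.aa_two_hit:
        keep = run_lens >= 2
        starts, run_lens = starts[keep], run_lens[keep]
    if len(starts) == 0:
        return []
    # Process long runs first so dominant homologies claim coverage early.
    by_len = np.argsort(-run_lens, kind="stable")

    boxes: dict[tuple[int, int], list] = {}
    results = []
    for ridx in by_len:
        start = int(starts[ridx])
        mid = start + int(run_lens[ridx]) // 2
        aq, asb = int(q_s[mid]), int(s_s[mid])
        qu, ql = _unit_of(q_off, None, aq)
        su, sl = _unit_of(s_off, None, asb)
        U, S = q_units[qu], s_units[su]
        pair_boxes = boxes.setdefault((qu, su), [])
        covered = False
        adiag = sl - ql
        for (b0, b1, c0, c1, bd) in pair_boxes:
            if b0 <= ql < b1 and c0 <= sl < c1 and abs(adiag - bd) <= 48:
                covered = True
                break
        if covered:
            continue
        # ungapped X-drop both ways
        r_len, r_sc = _kernels.ungapped_extend_right(U.codes, S.codes, ql, sl, matrix, xd_u)
        l_len, l_sc = _kernels.ungapped_extend_right(
            U.reversed_codes(), S.reversed_codes(), len(U.codes) - ql, len(S.codes) - sl, matrix, xd_u
        )
        if r_sc + l_sc < trigger:
            continue
        # gapped adaptive-band extension anchored at the seed
        dq_r, ds_r, _ = _kernels.banded_extend_right(
            U.codes, S.codes, ql, sl, matrix, gap_open, gap_extend, xd_g, params.band
        )
        dq_l, ds_l, _ = _kernels.banded_extend_right(
            U.reversed_codes(), S.reversed_codes(), len(U.codes) - ql, len(S.codes) - sl,
            matrix, gap_open, gap_extend, xd_g, params.band
        )
        q0, q1 = ql - dq_l, ql + dq_r
        s0, s1 = sl - ds_l, sl + ds_r
        if q1 - q0 < 1 or s1 - s0 < 1:
            continue
        qtext, stext = U.text[q0:q1], S.text[s0:s1]
        res = edlib.align(qtext, stext, mode="NW", task="path")
        matches, cols, score = _walk_cigar(qtext, stext, res["cigar"], matrix, lut, gap_open, gap_extend)
        identity = 100.0 * matches / cols if cols else 0.0
        pair_boxes.append((q0, q1, s0, s1, s0 - q0))
        if score >= min_score and identity >= min_identity and cols >= min_aln_len:
            results.append((qu, su, q0, q1, s0, s1, identity, score, cols))
    return results


def search(queries: Sequence[SequenceRecord], subjects: Sequence[SequenceRecord],
           mode: str, params: SearchParams | None = None,
           min_aln_len: int | None = None,
           min_identity: float | None = None) -> list[Hit]:
    """Local homology search between two record sets.

    Hits carry coordinates on the forward strand of the untranslated
    sequences and are sorted by (subject_id, s_start).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    params = params or SearchParams()
    if not queries or not subjects:
        return []

    q_alpha = queries[0].alphabet
    s_alpha = subjects[0].alphabet
    expect = {
        "nt_nt": ("nt", "nt"), "aa_aa": ("aa", "aa"),
        "aa_vs_txnt": ("aa", "nt"), "txnt_vs_txnt": ("nt", "nt"),
    }[mode]
    if (q_alpha, s_alpha) != expect:
        raise ValueError(f"mode {mode} expects alphabets {expect}, got ({q_alpha}, {s_alpha})")

    aa = mode != "nt_nt"
    if mode == "nt_nt":
        q_units = _nt_units(queries, with_minus=True)
        s_units = _nt_units(subjects, with_minus=False)
    elif mode == "aa_aa":
        q_units = _aa_units(queries)
        s_units = _aa_units(subjects)
    elif mode == "aa_vs_txnt":
        q_units = _aa_units(queries)
        s_units = _frame_units(subjects)
    else:
        q_units = _frame_units(queries)
        s_units = _frame_units(subjects)

    min_score = params.min_score_aa if aa else params.min_score_nt
    if min_identity is None:
        min_identity = params.min_identity_aa if aa else params.min_identity_nt
    if min_aln_len is None:
        min_aln_len = params.min_aln_len

    raw = _search_units(q_units, s_units, params, aa, min_score, min_identity, min_aln_len)

    hits = []
    for qu, su, q0, q1, s0, s1, identity, score, cols in raw:
        U, S = q_units[qu], s_units[su]
        frame_q = frame_s = None
        strand = "+"
        if U.kind == "nt-":
            q0, q1 = U.nt_len - q1, U.nt_len - q0
            strand = "-"
        elif U.kind == "frame":
            frame_q = U.frame
            q0, q1 = frame_to_genome_span(q0, q1, U.frame, U.nt_len)
        if S.kind == "frame":
            frame_s = S.frame
            s0, s1 = frame_to_genome_span(s0, s1, S.frame, S.nt_len)
            strand = "+" if S.frame > 0 else "-"
        hits.append(Hit(U.rec_id, S.rec_id, q0, q1, s0, s1, strand,
                        frame_q, frame_s, round(identity, 2), score, cols))
    hits.sort(key=lambda h: (h.subject_id, h.s_start, h.s_end, h.query_id, h.q_start))
    return hits


def hits_to_tsv(hits: Iterable[Hit], path) -> None:
    """Debug export: 12 tab-separated columns in the familiar tabular layout."""
    with open(path, "w") as fh:
        for h in hits:
            frame = f"{h.frame_q or 0}/{h.frame_s or 0}"
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.2f}\t{h.aln_len}\t"
                f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t{h.strand}\t"
                f"{frame}\t{h.score}\t.\n"
            )
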