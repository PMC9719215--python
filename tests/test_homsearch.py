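"""The built-in seed-and-extend search engine and pairwise alignment."""

import numpy as np
import pytest

from evehunter.config import SearchParams
from evehunter.homsearch import Hit, align_pair, global_identity, infix_align, search
from evehunter.seqio import SequenceRecord, reverse_complement, translate
from .conftest import mutate_subs, random_nt


def _nt(i, s):
    return SequenceRecord(f"s{i}", s, "nt")


def test_exact_substring_found_at_full_identity(rng):
    ins = random_nt(rng, 60)
    bg = random_nt(rng, 2000)
    genome = bg[:900] + ins + bg[900:]
    hits = search([SequenceRecord("q", ins)], [_nt(0, genome)], "nt_nt")
    top = max(hits, key=lambda h: h.score)
    assert top.identity_pct == 100.0
    assert (top.q_start, top.q_end) == (0, 60)
    assert (top.s_start, top.s_end) == (900, 960)
    assert top.strand == "+"


def test_minus_strand_hit_reported_on_forward_coordinates(rng):
    ins = random_nt(rng, 200)
    bg = random_nt(rng, 3000)
    genome = bg[:1500] + reverse_complement(ins) + bg[1500:]
    hits = search([SequenceRecord("q", ins)], [_nt(0, genome)], "nt_nt")
    top = max(hits, key=lambda h: h.score)
    assert top.strand == "-"
    assert (top.s_start, top.s_end) == (1500, 1700)
    assert (top.q_start, top.q_end) == (0, 200)


def test_protein_vs_translated_genome_maps_orf_span(rng):
    orf = "ATG" + "".join(rng.choice(
        ["GCT", "GAA", "TTA", "AAA", "GAT", "TGG", "CCT"], 150)) + "TAA"
    prot = translate(orf)[:-1]
    bg = random_nt(rng, 4000)
    genome = bg[:2000] + orf + bg[2000:]
    hits = search([SequenceRecord("p", prot, "aa")], [_nt(0, genome)], "aa_vs_txnt")
    top = max(hits, key=lambda h: h.score)
    assert top.frame_s is not None
    assert top.s_start >= 2000 - 3 and top.s_end <= 2000 + len(orf)
    assert top.s_end - top.s_start >= 3 * len(prot) * 0.95


def test_planted_mutated_copies_recovered(rng):
    found = 0
    for _ in range(50):
        q = random_nt(rng, 400)
        copy = mutate_subs(rng, q, 0.10)
        bg = random_nt(rng, 3000)
        pos = int(rng.integers(0, 2500))
        genome = bg[:pos] + copy + bg[pos:]
        hits = search([SequenceRecord("q", q)], [_nt(0, genome)], "nt_nt")
        if hits:
            top = max(hits, key=lambda h: h.score)
            span = min(top.s_end, pos + len(copy)) - max(top.s_start, pos)
            if span >= 0.9 * len(copy):
                found += 1
    assert found >= 45


def test_symmetric_modes_swap(rng):
    a = SequenceRecord("a", random_nt(rng, 500))
    b = SequenceRecord("b", a.residues[100:400] + random_nt(rng, 100))
    fwd = search([a], [b], "nt_nt")
    rev = search([b], [a], "nt_nt")
    fset = {(h.q_start, h.q_end, h.s_start, h.s_end, h.score) for h in fwd}
    rset = {(h.s_start, h.s_end, h.q_start, h.q_end, h.score) for h in rev}
    assert fset == rset and fset


def test_threshold_monotonicity(rng):
    q = random_nt(rng, 300)
    genome = random_nt(rng, 1000) + mutate_subs(rng, q, 0.08) + random_nt(rng, 1000)
    loose = search([SequenceRecord("q", q)], [_nt(0, genome)], "nt_nt",
                   min_identity=60.0)
    tight = search([SequenceRecord("q", q)], [_nt(0, genome)], "nt_nt",
                   min_identity=90.0)
    loose_keys = {(h.q_start, h.s_start) for h in loose}
    assert {(h.q_start, h.s_start) for h in tight} <= loose_keys


def test_empty_inputs_and_bad_mode(rng):
    assert search([], [_nt(0, "ACGT")], "nt_nt") == []
    with pytest.raises(ValueError):
        search([_nt(0, "ACGT")], [_nt(1, "ACGT")], "no_such_mode")
    with pytest.raises(ValueError):
        search([SequenceRecord("p", "MKV", "aa")], [_nt(0, "ACGTACGT")], "nt_nt")


def test_align_pair_identity_and_coverage():
    a = SequenceRecord("a", "AAAA")
    b = SequenceRecord("b", "AAAATTTT")
    pa = align_pair(a, a)
    assert pa.identity_pct == 100.0 and pa.coverage_a == 1.0 and pa.coverage_b == 1.0
    pb = align_pair(a, b)
    assert pb.coverage_b == pytest.approx(0.5)
    with pytest.raises(ValueError):
        align_pair(SequenceRecord("x", "A"), SequenceRecord("y", ""))


def _edit_distance_dp(a: str, b: str) -> int:
    """Independent quadratic DP oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def test_global_alignment_agrees_with_dp_oracle(rng):
    import edlib
    for _ in range(100):
        a = random_nt(rng, int(rng.integers(5, 200)))
        b = mutate_subs(rng, a, float(rng.uniform(0, 0.3)))
        assert edlib.align(a, b, mode="NW")["editDistance"] == _edit_distance_dp(a, b)


def test_infix_align_containment(rng):
    long = random_nt(rng, 1000)
    short = long[300:600]
    ident, cov_long, cols = infix_align(short, long)
    assert ident == 100.0
    assert cov_long == pytest.approx(0.3, abs=0.01)
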