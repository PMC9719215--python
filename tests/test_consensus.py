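"""Repeat grouping and consensus reconstruction."""

import numpy as np
import pytest

from evehunter.config import PipelineConfig
from evehunter.consensus import (HspGroup, GroupMember, build_group_consensus,
                                 find_subgenome_hsps, group_hsps)
from evehunter.locate import SubGenomeSegment
from evehunter.homsearch import global_identity, infix_align
from evehunter.synthetic import mutate_nt
from .conftest import mutate_subs, random_nt


def _seg(i, seq):
    return SubGenomeSegment(f"seg{i}", seq, (f"seg{i}", 0, len(seq)))


def test_identical_pair_gives_full_span_hit(rng):
    s = random_nt(rng, 1000)
    cfg = PipelineConfig()
    hsps = find_subgenome_hsps([_seg(0, s), _seg(1, s)], cfg)
    assert hsps
    top = max(hsps, key=lambda h: h.aln_len)
    assert top.identity_pct == 100.0
    assert top.aln_len >= 950


def test_low_identity_pairs_excluded(rng):
    s = random_nt(rng, 1000)
    t = mutate_subs(rng, s, 0.20)  # ~80% identity, below the 85% admission
    cfg = PipelineConfig()
    hsps = find_subgenome_hsps([_seg(0, s), _seg(1, t)], cfg)
    assert all(h.identity_pct >= 85.0 for h in hsps)
    assert not any(h.aln_len > 500 for h in hsps)


def test_unrelated_segments_no_hits(rng):
    cfg = PipelineConfig()
    misses = 0
    for _ in range(20):
        hsps = find_subgenome_hsps([_seg(0, random_nt(rng, 2000)),
                                    _seg(1, random_nt(rng, 2000))], cfg)
        if not hsps:
            misses += 1
    assert misses >= 19


def _plant_family(rng, n, divergence, anc=None, length=2000):
    anc = anc or random_nt(rng, length)
    segs = []
    for i in range(n):
        copy = mutate_subs(rng, anc, divergence)
        seq = random_nt(rng, 200) + copy + random_nt(rng, 200)
        segs.append(_seg(i, seq))
    return anc, segs


def test_six_copies_form_one_group_four_do_not(rng):
    cfg = PipelineConfig()
    _, segs = _plant_family(rng, 6, 0.05)
    groups = group_hsps(find_subgenome_hsps(segs, cfg), cfg)
    assert len(groups) == 1 and groups[0].size >= 5

    _, segs4 = _plant_family(rng, 4, 0.05)
    groups4 = group_hsps(find_subgenome_hsps(segs4, cfg), cfg)
    assert groups4 == []


def test_two_families_stay_separate(rng):
    cfg = PipelineConfig()
    _, fam1 = _plant_family(rng, 6, 0.04)
    _, fam2 = _plant_family(rng, 6, 0.04)
    segs = fam1 + [_seg(i + 10, s.residues) for i, s in enumerate(fam2)]
    groups = group_hsps(find_subgenome_hsps(segs, cfg), cfg)
    assert len(groups) == 2
    for g in groups:
        members = {m.segment_id for m in g.members}
        assert members <= {f"seg{i}" for i in range(6)} or \
               members <= {f"seg{i+10}" for i in range(6)}


def test_unanimous_copies_reproduce_sequence(rng):
    cfg = PipelineConfig()
    s = random_nt(rng, 600)
    group = HspGroup("G", [GroupMember(f"m{i}", 0, 600) for i in range(5)])
    rec = build_group_consensus(group, {f"m{i}": s for i in range(5)}, cfg)
    assert rec.residues == s


def test_majority_and_tie_calls(rng):
    cfg = PipelineConfig()
    base = random_nt(rng, 300)
    variants = [base, base, base, base[:150] + "C" + base[151:], base]
    # force position 150 disagreement in one member only -> majority wins
    seqs = {f"m{i}": v for i, v in enumerate(variants)}
    group = HspGroup("G", [GroupMember(f"m{i}", 0, 300) for i in range(5)])
    rec = build_group_consensus(group, seqs, cfg)
    assert rec.residues == base
    assert "-" not in rec.residues


def test_ancestor_recovery_from_mutated_copies(rng):
    cfg = PipelineConfig()
    anc = random_nt(rng, 2000)
    seqs = {f"m{i}": mutate_nt(anc, 5.0, rng) for i in range(10)}
    group = HspGroup("G", [GroupMember(k, 0, len(v)) for k, v in seqs.items()])
    rec = build_group_consensus(group, seqs, cfg)
    ident, cov, _ = infix_align(*((rec.residues, anc) if len(rec.residues) <= len(anc)
                                  else (anc, rec.residues)))
    assert ident >= 98.0
    assert min(len(rec.residues), len(anc)) / len(anc) >= 0.95


def test_recovery_degrades_monotonically_with_divergence(rng):
    cfg = PipelineConfig()
    means = []
    for rate in (2.0, 10.0, 25.0):
        idents = []
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            anc = "".join(r2.choice(list("ACGT"), 1500))
            seqs = {f"m{i}": mutate_nt(anc, rate, r2) for i in range(8)}
            group = HspGroup("G", [GroupMember(k, 0, len(v)) for k, v in seqs.items()])
            rec = build_group_consensus(group, seqs, cfg)
            short, long = ((rec.residues, anc) if len(rec.residues) <= len(anc)
                           else (anc, rec.residues))
            idents.append(infix_align(short, long)[0])
        means.append(np.mean(idents))
    assert means[0] >= means[1] >= means[2]


def test_too_few_usable_members_raises(rng):
    cfg = PipelineConfig()
    group = HspGroup("G", [GroupMember("a", 0, 500), GroupMember("b", 0, 50)])
    with pytest.raises(ValueError):
        build_group_consensus(group, {"a": random_nt(rng, 500),
                                      "b": random_nt(rng, 50)}, cfg)
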