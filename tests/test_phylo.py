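"""Alignment machinery, trimming, blocks, NJ, bootstrap, classification."""

import math

import numpy as np
import pytest

from evehunter.phylo import (Msa, PhyloTree, bootstrap_support, classify_leaves,
                             distance_matrix, iterative_align_trim, nj_tree,
                             progressive_align, select_blocks, trim_msa)
from evehunter.seqio import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_prot(rng, n):
    return "".join(rng.choice(list(AA), n))


def _mut_prot(rng, s, d):
    return "".join(AA.replace(c, "")[rng.integers(0, 19)] if rng.random() < d else c
                   for c in s)


# ---------------------------------------------------------------- alignment

def test_identical_pair_aligns_gap_free(rng):
    p = _rand_prot(rng, 80)
    msa = progressive_align([SequenceRecord("a", p, "aa"), SequenceRecord("b", p, "aa")])
    assert msa.rows == [p, p]


def test_single_gap_optimum():
    msa = progressive_align([SequenceRecord("a", "MKV", "aa"),
                             SequenceRecord("b", "MV", "aa")])
    assert msa.columns == 3
    rows = dict(zip(msa.ids, msa.rows))
    assert rows["a"] == "MKV"
    assert rows["b"].count("-") == 1 and rows["b"].replace("-", "") == "MV"


def _sp_score(rows):
    from evehunter.homsearch import AA_MATRIX, encode_aa
    total = 0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            for a, b in zip(rows[i], rows[j]):
                if a != "-" and b != "-":
                    total += AA_MATRIX[encode_aa(a)[0], encode_aa(b)[0]]
    return total


def test_sum_of_pairs_beats_naive_stacking(rng):
    wins = 0
    for t in range(20):
        anc = _rand_prot(rng, 60)
        seqs = []
        for _ in range(4):
            s = _mut_prot(rng, anc, 0.10)
            # one indel per sequence so that naive stacking loses register
            pos = int(rng.integers(5, 55))
            if rng.random() < 0.5:
                s = s[:pos] + s[pos + 2:]
            else:
                s = s[:pos] + _rand_prot(rng, 2) + s[pos:]
            seqs.append(s)
        recs = [SequenceRecord(f"s{i}", s, "aa") for i, s in enumerate(seqs)]
        msa = progressive_align(recs)
        width = max(len(s) for s in seqs)
        stacked = [s + "-" * (width - len(s)) for s in seqs]
        if _sp_score(msa.rows) >= _sp_score(stacked):
            wins += 1
    assert wins >= 18


# ---------------------------------------------------------------- trimming

def test_trim_noop_on_gapfree(rng):
    p = _rand_prot(rng, 50)
    msa = Msa(["a", "b"], [p, p])
    out, removed = trim_msa(msa)
    assert out.rows == [p, p] and removed == []


def test_trim_drops_gappy_row():
    rows = ["ACDEFGHIKL", "ACDEFGHIKL", "A---------"]
    msa = Msa(["a", "b", "c"], rows)
    out, removed = trim_msa(msa, col_gap_max=0.8, seq_occupancy_min=0.5)
    assert removed == ["c"]
    out2, removed2 = trim_msa(msa, protected=("c",))
    assert removed2 == []


def test_trim_matches_bruteforce_on_random_alignments(rng):
    for _ in range(100):
        n = int(rng.integers(2, 8))
        L = int(rng.integers(6, 40))
        rows = ["".join(rng.choice(list(AA + "----"), L)) for _ in range(n)]
        # ensure no all-gap rows for stability of the brute force
        rows = [r if r.replace("-", "") else "A" * L for r in rows]
        msa = Msa([f"s{i}" for i in range(n)], rows)
        mat = np.array([list(r) for r in rows])
        keep_cols = (mat == "-").mean(axis=0) <= 0.8
        if not keep_cols.any():
            with pytest.raises(ValueError):
                trim_msa(msa)
            continue
        sub = mat[:, keep_cols]
        occ = (sub != "-").mean(axis=1)
        expect_ids = [f"s{i}" for i in range(n) if occ[i] >= 0.5]
        if len(expect_ids) < 2:
            with pytest.raises(ValueError):
                trim_msa(msa)
            continue
        out, removed = trim_msa(msa)
        assert out.ids == expect_ids
        expect_rows = ["".join(sub[i]) for i in range(n) if occ[i] >= 0.5]
        assert out.rows == expect_rows


def test_select_blocks_run_scan(rng):
    p = _rand_prot(rng, 30)
    msa = Msa(["a", "b", "c"], [p, p, p])
    out = select_blocks(msa)
    assert out.rows == [p, p, p]
    # 4-column good run flanked by bad columns is dropped at min_block=5
    good = "AAAA"
    rows = ["--" + good + "--", "--" + good + "--", "CC" + "AAAA" + "GG"]
    msa2 = Msa(["a", "b", "c"], rows)
    with pytest.raises(ValueError):
        select_blocks(msa2, min_block=5)


def test_select_blocks_matches_bruteforce(rng):
    for _ in range(100):
        n = int(rng.integers(2, 7))
        L = int(rng.integers(10, 60))
        rows = ["".join(rng.choice(list("ACDE--"), L)) for _ in range(n)]
        msa = Msa([f"s{i}" for i in range(n)], rows)
        mat = np.array([list(r) for r in rows])
        good = []
        for j in range(L):
            col = mat[:, j]
            gaps = (col == "-").sum() / n
            vals, counts = np.unique(col[col != "-"], return_counts=True)
            modal = counts.max() / n if len(counts) else 0
            good.append(gaps <= 0.5 and modal >= 0.5)
        keep = np.zeros(L, dtype=bool)
        run = 0
        for j in range(L + 1):
            if j < L and good[j]:
                run += 1
            else:
                if run >= 5:
                    keep[j - run:j] = True
                run = 0
        if not keep.any():
            with pytest.raises(ValueError):
                select_blocks(msa)
            continue
        out = select_blocks(msa)
        assert out.rows == ["".join(mat[i][keep]) for i in range(n)]


def test_iterative_align_trim_contract(rng):
    anc = _rand_prot(rng, 100)
    related = [SequenceRecord(f"s{i}", _mut_prot(rng, anc, 0.1), "aa") for i in range(10)]
    kept = iterative_align_trim(related, rounds=2)
    assert len(kept) == 10
    outlier = SequenceRecord("junk", _rand_prot(rng, 30), "aa")
    kept2 = iterative_align_trim(related + [outlier], rounds=2)
    assert "junk" not in {r.id for r in kept2}
    kept0 = iterative_align_trim(related, rounds=0)
    assert len(kept0) == 10


# ---------------------------------------------------------------- distances & trees

def test_distance_examples():
    msa = Msa(["a", "b"], ["ACDEF", "ACDEF"])
    assert distance_matrix(msa)[0, 1] == 0.0
    # strictly increasing in p below the cap
    ps = np.linspace(0.01, 0.8, 20)
    ds = [-math.log(1 - p - p * p / 5) for p in ps]
    assert all(d2 > d1 for d1, d2 in zip(ds, ds[1:]))


def test_distance_formula_oracle(rng):
    for _ in range(50):
        L = 200
        p_target = float(rng.uniform(0, 0.5))
        a = _rand_prot(rng, L)
        b = list(a)
        flip = rng.choice(L, size=int(p_target * L), replace=False)
        for i in flip:
            b[i] = AA.replace(a[i], "")[rng.integers(0, 19)]
        msa = Msa(["a", "b"], [a, "".join(b)])
        p = len(flip) / L
        expect = 10.0 if p >= 0.85 else -math.log(1 - p - p * p / 5)
        assert distance_matrix(msa)[0, 1] == pytest.approx(expect)
    with pytest.raises(ValueError):
        distance_matrix(Msa(["a", "b"], ["A---", "---C"]))


def _random_additive(rng, labels):
    """Random binary tree -> additive distance matrix (the NJ oracle)."""
    import itertools
    nodes = [(l,) for l in labels]
    children = {}
    lengths = {}
    for l in labels:
        lengths[(l,)] = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = tuple(sorted(a + b))
        children[parent] = (a, b)
        lengths[parent] = float(rng.uniform(0.1, 1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    lengths[root] = 0.0
    # path lengths between leaves
    def paths(node, acc, out):
        if node in children:
            for ch in children[node]:
                paths(ch, acc + [ch], out)
        else:
            out[node[0]] = acc
    out = {}
    paths(root, [], out)
    n = len(labels)
    D = np.zeros((n, n))
    for x, y in itertools.combinations(range(n), 2):
        px, py = out[labels[x]], out[labels[y]]
        shared = 0
        for u, v in zip(px, py):
            if u == v:
                shared += 1
            else:
                break
        d = sum(lengths[e] for e in px[shared:]) + sum(lengths[e] for e in py[shared:])
        D[x, y] = D[y, x] = d
    splits = set()
    all_l = frozenset(labels)
    anchor = min(labels)
    for parent in children:
        side = frozenset(parent)
        if anchor in side:
            side = all_l - side
        if 1 < len(side) < n - 1:
            splits.add(side)
    return D, splits


def test_nj_three_taxa_branch_lengths():
    D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    tree = nj_tree(["a", "b", "c"], D)
    lengths = {l.name: l.length for l in tree.root.leaves()}
    assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}
    with pytest.raises(ValueError):
        nj_tree(["a", "b"], D[:2, :2])


def test_nj_recovers_random_additive_topologies(rng):
    labels = [f"t{i}" for i in range(6)]
    for _ in range(100):
        D, expect = _random_additive(rng, labels)
        tree = nj_tree(labels, D)
        got = {frozenset(bp) for bp in tree.bipartitions()}
        assert got == expect


def test_nj_agrees_with_independent_implementation(rng):
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj
    labels = [f"t{i}" for i in range(8)]
    for _ in range(10):
        D, _ = _random_additive(rng, labels)
        mine = {frozenset(bp) for bp in nj_tree(labels, D).bipartitions()}
        sk = skbio_nj(DistanceMatrix(D, labels))
        theirs = set()
        all_l = frozenset(labels)
        anchor = min(labels)
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = all_l - side
            if 1 < len(side) < len(labels) - 1:
                theirs.add(side)
        assert mine == theirs


# ---------------------------------------------------------------- bootstrap & classification

def _family_msa(rng):
    anc1, anc2 = _rand_prot(rng, 120), _rand_prot(rng, 120)
    rows = [_mut_prot(rng, anc1, 0.05) for _ in range(3)] + \
           [_mut_prot(rng, anc2, 0.05) for _ in range(3)]
    return Msa([f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)], rows)


def test_bootstrap_deep_split_and_determinism(rng):
    msa = _family_msa(rng)
    t1 = bootstrap_support(msa, replicates=100, seed=5)
    split_support = {frozenset(n.leaf_names()): n.support
                     for n in t1.root.walk() if not n.is_leaf() and n is not t1.root}
    deep = [s for side, s in split_support.items()
            if {l[0] for l in side} in ({"a"}, {"b"})]
    assert deep and max(deep) >= 95
    t2 = bootstrap_support(msa, replicates=100, seed=5)
    assert t1.newick() == t2.newick()
    t3 = bootstrap_support(msa, replicates=1, seed=5)
    sups = [n.support for n in t3.root.walk()
            if n.support is not None]
    assert set(sups) <= {0.0, 100.0}


def test_newick_roundtrip_with_supports(rng):
    msa = _family_msa(rng)
    tree = bootstrap_support(msa, replicates=10, seed=2)
    text = tree.newick()
    back = PhyloTree.from_newick(text)
    assert back.leaf_names() == tree.leaf_names()
    assert back.newick() == text
    import dendropy
    dt = dendropy.Tree.get(data=text, schema="newick")
    assert {l.taxon.label for l in dt.leaf_node_iter()} == set(tree.leaf_names())


def test_classify_leaves_rules(rng):
    # candidate sister to a single genus-G reference with full support
    msa = _family_msa(rng)
    tree = bootstrap_support(msa, replicates=100, seed=3)
    refs = {"a0": "GenA", "b0": "GenB", "b1": "Outgroup_outgroup"}
    out = classify_leaves(tree, refs, min_support=70)
    assert out["a1"][0] == "GenA" and out["a2"][0] == "GenA"
    with pytest.raises(ValueError):
        classify_leaves(PhyloTree.from_newick("(a:1,b:1,c:1);"), {"zz": "G"})


def test_classify_ambiguous_clade_is_unclassified():
    # candidate whose smallest supported clade spans two genera
    text = "((cand:0.1,(r1:0.1,r2:0.1)90:0.1)95:0.2,out:0.5,x:0.4);"
    tree = PhyloTree.from_newick(text)
    refs = {"r1": "GenA", "r2": "GenB", "out": "Out_outgroup"}
    res = classify_leaves(tree, refs, min_support=70)
    assert res["cand"][0] == "unclassified"
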