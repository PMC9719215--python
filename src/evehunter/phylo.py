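"""Branch B step 3 and shared alignment machinery.

Progressive profile alignment (k-mer guide tree + BLOSUM62 profiles),
alignment trimming, conserved-block curation, protein distances with the
Kimura correction, neighbor-joining with column-bootstrap support, Newick
serialization, and clade-based genus assignment. Neighbor joining plus
bootstrap stands in for maximum-likelihood inference: genus assignment
consumes only topology and support, and a config-gated hook allows an
external ML engine to produce the tree instead.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {c: i for i, c in enumerate(_AA20)}


def _blosum20() -> np.ndarray:
    b = substitution_matrices.load("BLOSUM62")
    m = np.zeros((20, 20))
    for i, a in enumerate(_AA20):
        for j, c in enumerate(_AA20):
            m[i, j] = b[a][c]
    return m


_S20 = _blosum20()


@dataclass
class Msa:
    """A multiple sequence alignment: parallel id and aligned-row lists."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs >= 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows have unequal lengths")

    @property
    def columns(self) -> int:
        return len(self.rows[0])

    def matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])

    def degapped(self) -> list[SequenceRecord]:
        return [SequenceRecord(i, r.replace("-", ""), "aa")
                for i, r in zip(self.ids, self.rows)]


# ---------------------------------------------------------------------------
# Trees

@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


class PhyloTree:
    """Tree with branch lengths and internal support values; Newick I/O."""

    def __init__(self, root: TreeNode):
        self.root = root

    def leaf_names(self) -> frozenset:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each reported as the side not containing the
        alphabetically first leaf (canonical orientation for unrooted trees)."""
        all_leaves = self.leaf_names()
        anchor = min(all_leaves)
        splits = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf():
                continue
            side = node.leaf_names()
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        text = text.strip().rstrip(";")
        pos = 0

        def parse() -> TreeNode:
            nonlocal pos
            node = TreeNode()
            if text[pos] == "(":
                pos += 1
                node.children.append(parse())
                while text[pos] == ",":
                    pos += 1
                    node.children.append(parse())
                assert text[pos] == ")"
                pos += 1
            m = re.match(r"[^(),:;]*", text[pos:])
            label = m.group(0)
            pos += len(label)
            if label:
                if node.children:
                    node.support = float(label)
                else:
                    node.name = label
            if pos < len(text) and text[pos] == ":":
                pos += 1
                m = re.match(r"[-+0-9.eE]+", text[pos:])
                node.length = float(m.group(0))
                pos += len(m.group(0))
            return node

        return cls(parse())


def nj_tree(labels: list[str], dist: np.ndarray) -> PhyloTree:
    """Standard neighbor joining; negative branch lengths clamped to 0.

    Ties in the Q matrix break on the lexicographically smallest joined
    label pair, making the topology deterministic.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    nodes = [TreeNode(name=l) for l in labels]
    keys = [(l,) for l in labels]  # sorted leaf tuples for tie-breaking
    D = dist.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                key = tuple(sorted((keys[idx[a]][0], keys[idx[b]][0])))
                cand = (q, key, a, b)
                if best is None or cand < best:
                    best = cand
        _, _, a, b = best
        ia, ib = idx[a], idx[b]
        d_ab = sub[a, b]
        la = 0.5 * d_ab + (r[a] - r[b]) / (2 * (m - 2))
        lb = d_ab - la
        nodes[ia].length = max(la, 0.0)
        nodes[ib].length = max(lb, 0.0)
        parent = TreeNode(children=[nodes[ia], nodes[ib]])
        new_row = np.zeros(D.shape[0] + 1)
        for c in range(m):
            if c in (a, b):
                continue
            ic = idx[c]
            new_row[ic] = 0.5 * (D[ia, ic] + D[ib, ic] - d_ab)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(tuple(sorted(keys[ia] + keys[ib]))[:1])
        active = [x for x in active if x not in (ia, ib)] + [len(nodes) - 1]

    # final three-way join
    i, j, k = active
    d_ij, d_ik, d_jk = D[i, j], D[i, k], D[j, k]
    nodes[i].length = max(0.5 * (d_ij + d_ik - d_jk), 0.0)
    nodes[j].length = max(0.5 * (d_ij + d_jk - d_ik), 0.0)
    nodes[k].length = max(0.5 * (d_ik + d_jk - d_ij), 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Progressive alignment

def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    """1 - fractional shared k-mer count, the classic guide-tree distance."""
    counts = []
    for s in seqs:
        d: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            d[w] = d.get(w, 0) + 1
        counts.append(d)
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum(min(c, counts[j].get(w, 0)) for w, c in counts[i].items())
            denom = max(1, min(len(seqs[i]), len(seqs[j])) - k + 1)
            D[i, j] = D[j, i] = 1.0 - shared / denom
    return D


def _profile(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue frequencies (over 20 aa) and occupancies."""
    L = len(rows[0])
    freq = np.zeros((L, 20))
    occ = np.zeros(L)
    for r in rows:
        for i, c in enumerate(r):
            if c in _AA_IDX:
                freq[i, _AA_IDX[c]] += 1
                occ[i] += 1
    nz = occ > 0
    freq[nz] /= occ[nz, None]
    occ /= len(rows)
    return freq, occ


def _align_profiles(rows_a: list[str], rows_b: list[str],
                    gap_open: float = -10.0, gap_extend: float = -1.0):
    """Affine-gap profile-profile alignment; returns gapped row groups.

    End gaps are free (semi-global): fragments and partial-domain
    sequences must not be stretched to full overlap with longer
    profiles, or downstream distances are corrupted.
    """
    fa, oa = _profile(rows_a)
    fb, ob = _profile(rows_b)
    La, Lb = fa.shape[0], fb.shape[0]
    P = (fa @ _S20 @ fb.T) * np.outer(oa, ob)
    NEG = -1e18
    go = gap_open + gap_extend
    M = np.full((La + 1, Lb + 1), NEG)
    X = np.full((La + 1, Lb + 1), NEG)  # gap in B (consume A)
    Y = np.full((La + 1, Lb + 1), NEG)  # gap in A (consume B)
    ptr = np.zeros((La + 1, Lb + 1, 3), dtype=np.int8)
    M[0, 0] = 0.0
    X[1:, 0] = 0.0  # free leading gaps
    Y[0, 1:] = 0.0
    ptr[2:, 0, 1] = 1
    ptr[0, 2:, 2] = 2
    for i in range(1, La + 1):
        diag_prev = np.stack([M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
        dbest = diag_prev.argmax(axis=0)
        M[i, 1:] = diag_prev.max(axis=0) + P[i - 1, :]
        ptr[i, 1:, 0] = dbest
        x_open = M[i - 1, 1:] + go
        x_ext = X[i - 1, 1:] + gap_extend
        X[i, 1:] = np.maximum(x_open, x_ext)
        ptr[i, 1:, 1] = (x_ext > x_open).astype(np.int8)
        # Y must be filled left-to-right
        for j in range(1, Lb + 1):
            y_open = M[i, j - 1] + go
            y_ext = Y[i, j - 1] + gap_extend
            if y_ext > y_open:
                Y[i, j] = y_ext
                ptr[i, j, 2] = 2
            else:
                Y[i, j] = y_open
                ptr[i, j, 2] = 0
    # free trailing gaps: best end point on the last row or column
    end_candidates = []
    for j in range(Lb + 1):
        end_candidates.append((M[La, j], La, j, 0))
    for i in range(La + 1):
        end_candidates.append((M[i, Lb], i, Lb, 0))
    end_candidates.append((X[La, Lb], La, Lb, 1))
    end_candidates.append((Y[La, Lb], La, Lb, 2))
    _, ei, ej, state = max(end_candidates, key=lambda t: (t[0], t[1] + t[2]))
    ops = []
    # pad the unaligned tail with terminal gaps
    for _ in range(La - ei):
        ops.append("X")
    for _ in range(Lb - ej):
        ops.append("Y")
    i, j = ei, ej
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            prev = ptr[i, j, 0]
            ops.append("M")
            i -= 1
            j -= 1
            state = int(prev)
        elif state == 1 and i > 0:
            prev = ptr[i, j, 1]
            ops.append("X")
            i -= 1
            state = 1 if prev else 0
        elif state == 2 and j > 0:
            prev = ptr[i, j, 2]
            ops.append("Y")
            j -= 1
            state = 2 if prev else 0
        elif i > 0:
            ops.append("X")
            i -= 1
            state = 0
        else:
            ops.append("Y")
            j -= 1
            state = 0
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "M":
            for t, r in enumerate(rows_a):
                out_a[t] += r[ia]
            for t, r in enumerate(rows_b):
                out_b[t] += r[ib]
            ia += 1
            ib += 1
        elif op == "X":
            for t, r in enumerate(rows_a):
                out_a[t] += r[ia]
            for t in range(len(rows_b)):
                out_b[t] += "-"
            ia += 1
        else:
            for t in range(len(rows_a)):
                out_a[t] += "-"
            for t, r in enumerate(rows_b):
                out_b[t] += r[ib]
            ib += 1
    return out_a, out_b


def progressive_align(proteins: list[SequenceRecord]) -> Msa:
    """Progressive MSA: 3-mer guide distances, NJ guide tree, BLOSUM62
    profile merges with affine gaps (open -10, extend -1). Deterministic
    given the input set (inputs are sorted by id internally)."""
    if len(proteins) < 2:
        raise ValueError("progressive alignment needs >= 2 sequences")
    recs = sorted(proteins, key=lambda r: r.id)
    if len(recs) == 2:
        a, b = _align_profiles([recs[0].residues], [recs[1].residues])
        return Msa([recs[0].id, recs[1].id], [a[0], b[0]])
    D = _kmer_distance([r.residues for r in recs])
    guide = nj_tree([r.id for r in recs], D)
    by_id = {r.id: r for r in recs}

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            return [node.name], [by_id[node.name].residues]
        ids, rows = merge(node.children[0])
        for child in node.children[1:]:
            cid, crows = merge(child)
            rows, crows = _align_profiles(rows, crows)
            ids = ids + cid
            rows = rows + crows
        return ids, rows

    ids, rows = merge(guide.root)
    return Msa(ids, rows)


# ---------------------------------------------------------------------------
# Trimming and block curation

def trim_msa(msa: Msa, col_gap_max: float = 0.8, seq_occupancy_min: float = 0.5,
             protected: tuple = ()) -> tuple[Msa, list[str]]:
    """Drop columns with gap fraction > col_gap_max, then sequences whose
    residues occupy < seq_occupancy_min of the surviving columns.
    Protected ids (e.g. the reference panel) are never removed."""
    mat = msa.matrix()
    gap_frac = (mat == "-").mean(axis=0)
    keep_cols = gap_frac <= col_gap_max
    if not keep_cols.any():
        raise ValueError("trimming removed every column")
    sub = mat[:, keep_cols]
    occ = (sub != "-").mean(axis=1)
    removed = []
    keep_ids, keep_rows = [], []
    for i, rid in enumerate(msa.ids):
        if occ[i] >= seq_occupancy_min or rid in protected:
            keep_ids.append(rid)
            keep_rows.append("".join(sub[i]))
        else:
            removed.append(rid)
    if len(keep_ids) < 2:
        raise ValueError("trimming removed all but one sequence")
    return Msa(keep_ids, keep_rows), removed


def iterative_align_trim(proteins: list[SequenceRecord], rounds: int,
                         col_gap_max: float = 0.8, seq_occupancy_min: float = 0.5,
                         protected: tuple = ()) -> list[SequenceRecord]:
    """Initial align+trim, then `rounds` realign-survivors+trim passes.

    Terminates early at a fixed point (no sequence removed). Survivors
    are returned unaligned.
    """
    current = list(proteins)
    for _ in range(rounds + 1):
        msa = progressive_align(current)
        msa, removed = trim_msa(msa, col_gap_max, seq_occupancy_min, protected)
        current = [SequenceRecord(i, r.replace("-", ""), "aa")
                   for i, r in zip(msa.ids, msa.rows)]
        if not removed:
            break
    return current


def select_blocks(msa: Msa, min_block: int = 5, col_gap_max: float = 0.5,
                  col_conservation_min: float = 0.5) -> Msa:
    """Keep maximal runs of >= min_block consecutive well-behaved columns.

    A column is good iff its gap fraction is <= col_gap_max and its modal
    residue frequency (over all rows) is >= col_conservation_min.
    """
    mat = msa.matrix()
    n, L = mat.shape
    good = np.zeros(L, dtype=bool)
    for j in range(L):
        col = mat[:, j]
        gaps = (col == "-").sum()
        if gaps / n > col_gap_max:
            continue
        vals, counts = np.unique(col[col != "-"], return_counts=True)
        if len(counts) and counts.max() / n >= col_conservation_min:
            good[j] = True
    keep = np.zeros(L, dtype=bool)
    run = 0
    for j in range(L + 1):
        if j < L and good[j]:
            run += 1
        else:
            if run >= min_block:
                keep[j - run : j] = True
            run = 0
    if not keep.any():
        raise ValueError("no conserved block survives curation")
    return Msa(msa.ids, ["".join(row[keep]) for row in mat])


# ---------------------------------------------------------------------------
# Distances, bootstrap, classification

def distance_matrix(msa: Msa) -> np.ndarray:
    """Kimura-corrected protein distances: d = -ln(1 - p - p^2/5).

    p is the p-distance over mutually non-gap columns; p >= 0.85 (or a
    non-positive log argument) is capped at d = 10.
    """
    mat = msa.matrix()
    n = len(msa.ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (mat[i] != "-") & (mat[j] != "-")
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"{msa.ids[i]} and {msa.ids[j]} share no aligned columns")
            p = float((mat[i][both] != mat[j][both]).sum()) / m
            if p >= 0.85:
                d = 10.0
            else:
                arg = 1.0 - p - p * p / 5.0
                d = 10.0 if arg <= 0 else -math.log(arg)
            D[i, j] = D[j, i] = d
    return D


def bootstrap_support(msa: Msa, replicates: int = 100, seed: int = 1) -> PhyloTree:
    """NJ tree from the full alignment, with column-bootstrap supports.

    Support of each internal bipartition of the point-estimate tree is
    the percentage of replicate trees containing it.
    """
    tree = nj_tree(msa.ids, distance_matrix(msa))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    mat = msa.matrix()
    L = msa.columns
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep = Msa(msa.ids, ["".join(row[cols]) for row in mat])
        try:
            rep_tree = nj_tree(rep.ids, distance_matrix(rep))
        except ValueError:
            continue
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    all_leaves = tree.leaf_names()
    anchor = min(all_leaves)
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf():
            continue
        side = node.leaf_names()
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.support = round(100.0 * counts[side] / replicates, 1)
        else:
            node.support = None
    return tree


def _reroot_at_leaf(tree: PhyloTree, leaf_name: str) -> TreeNode:
    """Return the tree re-oriented so that ``leaf_name`` hangs off the root."""
    parent: dict[int, TreeNode] = {}
    target = None
    for node in tree.root.walk():
        for c in node.children:
            parent[id(c)] = node
        if node.is_leaf() and node.name == leaf_name:
            target = node
    if target is None:
        raise ValueError(f"leaf {leaf_name!r} not in tree")
    path = [target]
    while id(path[-1]) in parent:
        path.append(parent[id(path[-1])])
    # reverse the parent chain above the outgroup leaf; edge attributes
    # (support, length) stay with their edge, so snapshot them first
    orig = {id(n): (n.support, n.length) for n in path}
    for child, par in zip(path[1:], path[2:]):
        par.children.remove(child)
        child.children.append(par)
        par.support, par.length = orig[id(child)]
    new_root = TreeNode(children=[target, path[1]] if len(path) > 1 else [target])
    if len(path) > 1:
        path[1].children = [c for c in path[1].children if c is not target]
        path[1].support, path[1].length = None, 0.0
    return new_root


def classify_leaves(tree: PhyloTree, reference_labels: dict[str, str],
                    min_support: float = 70.0,
                    outgroup: str | None = None) -> dict[str, tuple[str, float]]:
    """Assign each non-reference leaf a genus from its smallest supported
    clade containing at least one reference.

    The tree is re-rooted at the outgroup leaf (default: the first
    reference whose genus contains "outgroup", else the alphabetically
    first reference). A clade counts if its support is >= min_support
    (the root counts as fully supported); if the clade's references span
    more than one genus the candidate is "unclassified".
    """
    leaf_names = tree.leaf_names()
    candidates = sorted(leaf_names - set(reference_labels))
    for c in candidates:
        if c not in leaf_names:
            raise ValueError(f"candidate {c} missing from tree")
    if outgroup is None:
        outs = sorted(l for l, g in reference_labels.items()
                      if "outgroup" in g.lower() and l in leaf_names)
        refs_in = sorted(l for l in reference_labels if l in leaf_names)
        if not refs_in:
            raise ValueError("no reference leaf present in the tree")
        outgroup = outs[0] if outs else refs_in[0]
    root = _reroot_at_leaf(tree, outgroup)

    parent: dict[int, TreeNode] = {}
    leaf_node: dict[str, TreeNode] = {}
    for node in root.walk():
        for ch in node.children:
            parent[id(ch)] = node
        if node.is_leaf():
            leaf_node[node.name] = node

    out = {}
    for cand in candidates:
        node = parent.get(id(leaf_node[cand]))
        assigned = ("unclassified", 0.0)
        while node is not None:
            sup = 100.0 if node is root or node.support is None else node.support
            refs = [l for l in node.leaf_names() if l in reference_labels]
            if refs and sup >= min_support:
                genera = {reference_labels[r] for r in refs}
                if len(genera) == 1:
                    assigned = (genera.pop(), sup)
                else:
                    assigned = ("unclassified", sup)
                break
            node = parent.get(id(node))
        out[cand] = assigned
    return out
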