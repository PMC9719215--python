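"""Synthetic genomes with known planted EVE/TE content, plus evaluators.

The generator emulates the input landscape the pipeline is built for: a
neutral background genome carrying mutationally decayed copies of
caulimovirid-like ancestors (full length, fragmented, tandem
concatemers, optionally bipartite) together with Gypsy/Copia-like LTR
retrotransposon decoys that share the RT/RNaseH core but carry an
integrase. Every ancestor embeds a long polyprotein ORF whose domain
proteins are drawn from the same bundled profiles the classifier scans
with, so planted truth and detection machinery are mutually consistent.
All matching reference sets (viral genome library, protein baits, RT
probes/library, phylogeny reference panel) are emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .classify import load_profiles, TE_SPECIFIC
from .consensus import ConsensusRecord
from .homsearch import infix_align, global_identity, _cigar_ops
from .locate import _merge_spans
from .seqio import SequenceRecord, reverse_complement, CODON_TABLE

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, []).append(_codon)

# Default ORF layouts: (token, aa length); domain tokens take their
# profile length, "spacer" segments are genus-specific random protein.
VIRAL_LAYOUT = [
    ("spacer", 200), ("MP", 0), ("spacer", 400), ("zf_CCHC", 0), ("spacer", 250),
    ("AP", 0), ("spacer", 350), ("RT_core", 0), ("spacer", 60), ("RNaseH", 0),
    ("spacer", 560),
]
DECOY_LAYOUT = [
    ("spacer", 250), ("RT_core", 0), ("spacer", 30), ("RNaseH", 0),
    ("spacer", 150), ("integrase", 0), ("spacer", 100),
]
BIPARTITE_B_LAYOUT = [("spacer", 30), ("MP", 0), ("zf_CCHC", 0), ("spacer", 20)]


@dataclass
class AncestorSpec:
    name: str
    kind: str  # caulimovirid | gypsy_decoy | bipartite_A | bipartite_B
    genus: str
    length: int = 7500
    genus_divergence: float = 0.20  # aa divergence of domains from the family consensus
    layout: list | None = None
    shared_region: int = 500  # nt shared between bipartite components
    partner: str | None = None  # name of the other bipartite component


@dataclass
class PlantedElement:
    """Ground truth for one insertion."""

    element_id: str
    ancestor_id: str
    start: int  # final genome coordinates, 0-based half-open
    end: int
    identity_to_ancestor: float  # requested, percent
    form: str  # full | fragment | tandem_k
    strand: str
    kind: str = "caulimovirid"


@dataclass
class AncestorLibrary:
    genomes: list[SequenceRecord]        # viral reference genome library (queries)
    baits: list[SequenceRecord]          # mixed protein baits with class/genus tags
    rt_probes: list[SequenceRecord]      # caulimovirid RT probes (branch B step 1)
    rt_library: list[SequenceRecord]     # probes + retroelement RTs (best-hit filter)
    reference_panel: list[SequenceRecord]  # genus references + outgroups for the tree
    info: dict = field(default_factory=dict)  # per-ancestor metadata

    def genome_of(self, name: str) -> SequenceRecord:
        return self.info[name]["record"]


def _rand_protein(rng, n: int) -> str:
    return "".join(rng.choice(list(_AA20), n))


def _rand_nt(rng, n: int, gc: float = 0.36) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(_NT), n, p=p))


def mutate_protein(s: str, d: float, rng) -> str:
    out = list(s)
    for i, c in enumerate(out):
        if rng.random() < d:
            alt = _AA20.replace(c, "") if c in _AA20 else _AA20
            out[i] = alt[rng.integers(0, len(alt))]
    return "".join(out)


def _reverse_translate(prot: str, rng) -> str:
    return "".join(
        _CODONS_FOR[aa][rng.integers(0, len(_CODONS_FOR[aa]))] for aa in prot
    )


def mutate_nt(seq: str, divergence_pct: float, rng) -> str:
    """Per-site substitution at rate = divergence, indels at 10% of that
    (insert/delete equally, geometric lengths with mean 2)."""
    d = divergence_pct / 100.0
    out = []
    for c in seq:
        if c in _NT and rng.random() < d:
            alt = _NT.replace(c, "")
            out.append(alt[rng.integers(0, 3)])
        else:
            out.append(c)
    n_indels = rng.binomial(len(seq), 0.1 * d)
    for _ in range(n_indels):
        pos = int(rng.integers(0, len(out)))
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5:
            del out[pos : pos + length]
        else:
            out.insert(pos, _rand_nt(rng, length, 0.5))
    return "".join(out)


def default_specs() -> list[AncestorSpec]:
    """The flagship study conditions: three caulimovirid genera plus
    Gypsy- and Copia-like decoys."""
    return [
        AncestorSpec("CaV", "caulimovirid", "Caulimovirus"),
        AncestorSpec("BaV", "caulimovirid", "Badnavirus"),
        AncestorSpec("PeV", "caulimovirid", "Petuvirus"),
        AncestorSpec("GyT", "gypsy_decoy", "Gypsy", length=5000, genus_divergence=0.35),
        AncestorSpec("CoT", "gypsy_decoy", "Copia", length=5000, genus_divergence=0.35),
    ]


def bipartite_specs(shared_region: int = 500) -> list[AncestorSpec]:
    return [
        AncestorSpec("FlVA", "bipartite_A", "Florendovirus", shared_region=shared_region,
                     partner="FlVB"),
        AncestorSpec("FlVB", "bipartite_B", "Florendovirus", length=6000,
                     shared_region=shared_region, partner="FlVA"),
    ]


def make_ancestors(specs: list[AncestorSpec], seed: int) -> AncestorLibrary:
    """Build ancestor genomes and all matching reference/bait/panel sets.

    Each ancestor embeds a readable ORF whose domain translations score
    above cutoff on their assigned profiles; viral ancestors carry no
    TE-specific domain (requesting one is an error), decoys carry an
    integrase. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    profiles = load_profiles()
    genomes, baits, rt_probes, rt_lib_extra, panel = [], [], [], [], []
    info: dict[str, dict] = {}
    shared_by_partner: dict[str, str] = {}

    for spec in specs:
        viral = spec.kind != "gypsy_decoy"
        layout = spec.layout
        if layout is None:
            layout = {"caulimovirid": VIRAL_LAYOUT, "bipartite_A": VIRAL_LAYOUT,
                      "bipartite_B": BIPARTITE_B_LAYOUT,
                      "gypsy_decoy": DECOY_LAYOUT}[spec.kind]
        tokens = [t for t, _ in layout if t != "spacer"]
        if viral and (set(tokens) & TE_SPECIFIC):
            raise ValueError(f"{spec.name}: viral ancestor may not carry a TE-specific domain")

        pieces = []
        domain_prots = {}
        domain_spans = {}
        pos = 0
        for token, n in layout:
            if token == "spacer":
                pieces.append(_rand_protein(rng, n))
                pos += n
            else:
                prot = mutate_protein(profiles[token].consensus, spec.genus_divergence, rng)
                domain_prots[token] = prot
                domain_spans[token] = (pos, pos + len(prot))
                pieces.append(prot)
                pos += len(prot)
        polyprotein = "".join(pieces)
        orf_nt = _reverse_translate(polyprotein, rng) + "TAA"

        utr5 = _rand_nt(rng, 200 if spec.kind == "bipartite_B" else 300)
        rest = spec.length - len(utr5) - len(orf_nt)
        if rest < 0:
            raise ValueError(f"{spec.name}: layout longer than genome length")
        utr3 = _rand_nt(rng, rest)
        genome_seq = utr5 + orf_nt + utr3

        # bipartite components share a non-coding region (3' UTR segment)
        if spec.kind in ("bipartite_A", "bipartite_B") and spec.shared_region > 0:
            if spec.partner in shared_by_partner:
                shared = shared_by_partner[spec.partner]
            else:
                shared = _rand_nt(rng, spec.shared_region)
                shared_by_partner[spec.name] = shared
            genome_seq = genome_seq[: spec.length - len(shared)] + shared

        rec = SequenceRecord(spec.name, genome_seq, "nt",
                             description=f"genus={spec.genus} kind={spec.kind}")
        klass = "caulimovirid" if viral else "retroelement"
        bait = SequenceRecord(f"{spec.name}_pol", polyprotein, "aa",
                              description=f"class={klass} genus={spec.genus}")
        baits.append(bait)
        rt_prot = None
        if "RT_core" in domain_prots:
            # the contiguous RT..RNaseH region as encoded in the genome
            # (the natural RT-RH1 marker used for phylogeny)
            rt_s = domain_spans["RT_core"][0]
            rt_e = domain_spans.get("RNaseH", domain_spans["RT_core"])[1]
            rt_prot = polyprotein[rt_s:rt_e]
            rt_rec = SequenceRecord(f"{spec.name}_RT", rt_prot, "aa",
                                    description=f"class={klass} genus={spec.genus}")
            if viral:
                # probes are the RT core domain alone: a compact marker
                # maximises the chance that a decayed copy still carries
                # an uninterrupted ORF across the probed window
                rt_probes.append(SequenceRecord(
                    f"{spec.name}_RTcore", domain_prots["RT_core"], "aa",
                    description=f"class={klass} genus={spec.genus}"))
                panel.append(SequenceRecord(f"REF_{spec.genus}", rt_prot, "aa",
                                            description=f"genus={spec.genus}"))
            else:
                panel.append(SequenceRecord(f"REF_{spec.genus}", rt_prot, "aa",
                                            description=f"genus={spec.genus}_outgroup"))
            rt_lib_extra.append(rt_rec)
        if viral:
            genomes.append(rec)
        info[spec.name] = {
            "record": rec, "genus": spec.genus, "kind": spec.kind,
            "polyprotein": polyprotein, "rt_protein": rt_prot,
            "rt_core": domain_prots.get("RT_core"),
            "orf_span": (len(utr5), len(utr5) + len(orf_nt)),
            "domains": domain_prots,
        }

    # a deeper retroviral RT for the best-hit filter library only: at
    # near-saturation divergence it would destabilise the distance tree,
    # so it is not part of the default reference panel
    retro_rt = (mutate_protein(profiles["RT_core"].consensus, 0.45, rng)
                + _rand_protein(rng, 45)
                + mutate_protein(profiles["RNaseH"].consensus, 0.45, rng))
    rt_library = rt_lib_extra + [
        SequenceRecord("Retro_RT", retro_rt, "aa",
                       description="class=retroelement genus=Retrovirus")
    ]
    return AncestorLibrary(genomes, baits, rt_probes, rt_library, panel, info)


@dataclass
class CopyPlan:
    """One planting instruction; several entries may target one ancestor.

    divergence_pct may be a single value or a (lo, hi) pair, in which
    case the copies of this entry get evenly spaced divergences across
    the band (insertion ages vary in real EVE populations).
    """

    ancestor_id: str
    n_full: int = 0
    n_fragment: int = 0
    n_tandem: int = 0
    tandem_k: int = 3
    divergence_pct: float | tuple = 10.0

    def divergences(self, n: int) -> list[float]:
        if isinstance(self.divergence_pct, (tuple, list)):
            lo, hi = self.divergence_pct
            if n == 1:
                return [(lo + hi) / 2]
            return [lo + (hi - lo) * i / (n - 1) for i in range(n)]
        return [float(self.divergence_pct)] * n


def default_copy_plan() -> list[CopyPlan]:
    """Flagship conditions: per ancestor, 10 full copies spanning the
    5-15% divergence band and 8 recent (1%) fragments; one triple tandem
    at 3%; 30 decoy copies."""
    return [
        CopyPlan("CaV", n_full=10, divergence_pct=(5.0, 15.0)),
        CopyPlan("BaV", n_full=10, divergence_pct=(5.0, 15.0)),
        CopyPlan("PeV", n_full=10, divergence_pct=(5.0, 15.0)),
        CopyPlan("CaV", n_fragment=8, divergence_pct=1.0),
        CopyPlan("BaV", n_fragment=8, divergence_pct=1.0),
        CopyPlan("PeV", n_fragment=8, divergence_pct=1.0),
        CopyPlan("CaV", n_tandem=1, tandem_k=3, divergence_pct=3.0),
        CopyPlan("GyT", n_full=15, divergence_pct=10.0),
        CopyPlan("CoT", n_full=15, divergence_pct=10.0),
    ]


def plant_elements(background_len: int, gc: float, library: AncestorLibrary,
                   copy_plan: list[CopyPlan], seed: int,
                   min_separation: int = 6000, chrom_id: str = "chr1"):
    """Insert mutated ancestor copies into an i.i.d. background.

    Returns ({chrom_id: SequenceRecord}, truth table). Insertion points
    are non-overlapping (separated by >= min_separation in background
    coordinates); both strands are used; the truth table is exact in
    final genome coordinates.
    """
    rng = np.random.default_rng(seed)
    pieces = []  # (ancestor_id, seq, identity, form, strand, kind)
    for plan in copy_plan:
        meta = library.info[plan.ancestor_id]
        anc = meta["record"].residues
        kind = "caulimovirid" if meta["kind"] != "gypsy_decoy" else "decoy"
        for d in plan.divergences(plan.n_full):
            pieces.append((plan.ancestor_id, mutate_nt(anc, d, rng),
                           100.0 - d, "full", kind))
        for d in plan.divergences(plan.n_fragment):
            frac = rng.uniform(0.2, 0.6)
            flen = int(len(anc) * frac)
            s = int(rng.integers(0, len(anc) - flen + 1))
            pieces.append((plan.ancestor_id, mutate_nt(anc[s : s + flen], d, rng),
                           100.0 - d, "fragment", kind))
        for d in plan.divergences(plan.n_tandem):
            units = [mutate_nt(anc, d, rng) for _ in range(plan.tandem_k)]
            pieces.append((plan.ancestor_id, "".join(units), 100.0 - d,
                           f"tandem_{plan.tandem_k}", kind))

    total_planted = sum(len(p[1]) for p in pieces)
    if total_planted >= background_len / 2:
        raise ValueError("planted content exceeds half the background length")

    # separated insertion points: draw in the slack space, then re-inflate,
    # which guarantees >= min_separation between consecutive points
    n = len(pieces)
    slack = background_len - n * min_separation
    if slack <= 0:
        raise ValueError("could not place elements with the requested separation")
    points = np.sort(rng.integers(0, slack, size=n)) + np.arange(n) * min_separation

    order = rng.permutation(n)
    background = _rand_nt(rng, background_len, gc)
    segments = []
    truth: list[PlantedElement] = []
    prev = 0
    offset = 0
    for slot, piece_idx in enumerate(order):
        aid, seq, ident, form, kind = pieces[piece_idx]
        strand = "+" if rng.random() < 0.5 else "-"
        placed = seq if strand == "+" else reverse_complement(seq)
        p = int(points[slot])
        segments.append(background[prev:p])
        start = p + offset
        segments.append(placed)
        truth.append(PlantedElement(f"e{slot + 1:03d}_{aid}_{form}", aid, start,
                                    start + len(placed), ident, form, strand, kind))
        offset += len(placed)
        prev = p
    segments.append(background[prev:])
    genome = SequenceRecord(chrom_id, "".join(segments), "nt")
    truth.sort(key=lambda e: e.start)
    return {chrom_id: genome}, truth


def write_truth(truth: list[PlantedElement], tsv_path, bed_path=None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("element_id\tancestor_id\tstart\tend\tidentity_to_ancestor\t"
                 "form\tstrand\tkind\n")
        for e in truth:
            fh.write(f"{e.element_id}\t{e.ancestor_id}\t{e.start}\t{e.end}\t"
                     f"{e.identity_to_ancestor}\t{e.form}\t{e.strand}\t{e.kind}\n")
    if bed_path:
        with open(bed_path, "w") as fh:
            for e in truth:
                fh.write(f"chr1\t{e.start}\t{e.end}\t{e.element_id}\t0\t{e.strand}\n")


def read_truth(tsv_path) -> list[PlantedElement]:
    out = []
    with open(tsv_path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(PlantedElement(f[0], f[1], int(f[2]), int(f[3]), float(f[4]),
                                      f[5], f[6], f[7]))
    return out


def benchmark_cluster(output_seqs: list[SequenceRecord],
                      reference_seqs: list[SequenceRecord],
                      identity: float = 85.0, coverage: float = 0.85) -> dict:
    """The evaluation clustering: pool outputs and references, link pairs
    at >= identity with >= coverage of the shorter (target) sequence,
    take single-linkage components. Reports, per reference, whether its
    cluster contains at least one output sequence, plus singletons."""
    from .consensus import _UnionFind

    pool = sorted(output_seqs + reference_seqs, key=lambda r: r.id)
    uf = _UnionFind()
    for r in pool:
        uf.find(r.id)
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            a, b = pool[i].residues, pool[j].residues
            short, long = (a, b) if len(a) <= len(b) else (b, a)
            best = None
            for cand in (short, reverse_complement(short)):
                ident, _, _ = infix_align(cand, long)
                # coverage of the shorter/target sequence: its aligned fraction
                res = edlib.align(cand, long, mode="HW", task="path")
                q_aln = sum(n for n, op in _cigar_ops(res["cigar"]) if op in "=XM")
                cov_short = q_aln / len(short)
                if best is None or ident > best[0]:
                    best = (ident, cov_short)
            ident, cov_short = best
            if ident >= identity and cov_short >= coverage:
                uf.union(pool[i].id, pool[j].id)
    comps: dict[str, list[str]] = {}
    for r in pool:
        comps.setdefault(uf.find(r.id), []).append(r.id)
    out_ids = {r.id for r in output_seqs}
    ref_ids = {r.id for r in reference_seqs}
    per_ref = {}
    for rid in sorted(ref_ids):
        members = comps[uf.find(rid)]
        per_ref[rid] = any(m in out_ids for m in members)
    singletons = sorted(m[0] for m in comps.values() if len(m) == 1)
    clusters = sorted(sorted(m) for m in comps.values())
    return {"per_reference_covered": per_ref, "singletons": singletons,
            "clusters": clusters}


def ancestor_embedding(ancestor: str, consensus: str,
                       both_strands: bool = True) -> tuple[float, float]:
    """How well a consensus reconstructs an ancestor.

    Aligns the ancestor inside the consensus (or vice versa when the
    consensus is shorter) and returns (identity over the aligned region,
    fraction of the ancestor covered). Tolerant of concatemeric consensi;
    a consensus is strand-arbitrary, so both orientations are tried for
    nucleotide inputs.
    """

    def one(anc: str, cons: str) -> tuple[float, float]:
        if len(cons) >= len(anc):
            res = edlib.align(anc, cons, mode="HW", task="path")
            aligned = sum(n for n, op in _cigar_ops(res["cigar"]) if op in "=XM")
            matches = sum(n for n, op in _cigar_ops(res["cigar"]) if op == "=")
            cols = sum(n for n, _ in _cigar_ops(res["cigar"]))
            identity = 100.0 * matches / cols if cols else 0.0
            return identity, aligned / len(anc)
        identity, cov_long, _ = infix_align(cons, anc)
        return identity, cov_long

    fwd = one(ancestor, consensus)
    if not both_strands or not set(consensus) <= set("ACGTNRYSWKMBDHV"):
        return fwd
    rev = one(ancestor, reverse_complement(consensus))
    return max(fwd, rev, key=lambda t: t[0] * max(t[1], 1e-9))


def score_recovery(truth: list[PlantedElement], annotations=(), consensi=(),
                   rt_representatives=(), library: AncestorLibrary | None = None) -> dict:
    """Score pipeline output against planted truth.

    A planted element is recovered when annotated bases cover >= 50% of
    its span. Best-consensus identity per ancestor is measured by
    aligning the ancestor inside the consensus (concatemer-tolerant).
    """
    spans_by_subject: dict[str, list] = {}
    for a in annotations:
        spans_by_subject.setdefault(a.subject_id, []).append((a.start, a.end))
    merged = {sid: _merge_spans(sp) for sid, sp in spans_by_subject.items()}
    all_spans = [sp for v in merged.values() for sp in v]

    def covered_frac_any(e: PlantedElement) -> float:
        total = 0
        for s, x in all_spans:
            ov = min(x, e.end) - max(s, e.start)
            if ov > 0:
                total += ov
        return total / (e.end - e.start)

    recovered = {e.element_id: covered_frac_any(e) >= 0.5 for e in truth}
    viral = [e for e in truth if e.kind != "decoy"]
    decoy = [e for e in truth if e.kind == "decoy"]
    metrics = {
        "n_elements": len(truth),
        "sensitivity_viral": (sum(recovered[e.element_id] for e in viral) / len(viral))
        if viral else 0.0,
        "decoy_recovery": (sum(recovered[e.element_id] for e in decoy) / len(decoy))
        if decoy else 0.0,
        "mean_span_overlap_viral": float(np.mean([covered_frac_any(e) for e in viral]))
        if viral else 0.0,
    }
    chimera = sum(
        1 for c in consensi if any(d.klass == "te_specific" for d in getattr(c, "domains", []))
    )
    metrics["chimera_count"] = chimera

    if library is not None and consensi:
        per_anc = {}
        for aid, meta in library.info.items():
            if meta["kind"] == "gypsy_decoy":
                continue
            anc = meta["record"].residues
            best = None
            for c in consensi:
                cons = c.residues if hasattr(c, "residues") else str(c)
                ident, cov_anc = ancestor_embedding(anc, cons)
                entry = (round(cov_anc, 3) >= 0.8, round(ident, 2), round(cov_anc, 3),
                         getattr(c, "id", "?"))
                if best is None or entry > best:
                    best = entry
            per_anc[aid] = {"identity_pct": best[1], "ancestor_coverage": best[2],
                            "consensus_id": best[3]}
        metrics["best_consensus_per_ancestor"] = per_anc

    if library is not None and rt_representatives:
        from .config import SearchParams
        from .homsearch import search

        per_anc_rt = {}
        loose = SearchParams(min_score_aa=30, min_identity_aa=20.0, aa_two_hit=False)
        for aid, meta in library.info.items():
            if meta["kind"] == "gypsy_decoy" or not meta["rt_protein"]:
                continue
            marker = meta.get("rt_core") or meta["rt_protein"]
            rt_ref = SequenceRecord(f"__rt_{aid}", marker, "aa")
            best = None
            for r in rt_representatives:
                prot = r.protein if hasattr(r, "protein") else r.residues
                rid = getattr(r, "candidate_id", getattr(r, "id", "?"))
                # local alignment: the mined protein carries polyprotein
                # flanks that must not count against RT identity
                hits = search([SequenceRecord("__cand", prot, "aa")], [rt_ref],
                              "aa_aa", loose)
                for h in hits:
                    cov = (h.s_end - h.s_start) / len(marker)
                    entry = (round(cov, 3) >= 0.8, round(h.identity_pct, 2),
                             round(cov, 3), rid)
                    if best is None or entry > best:
                        best = entry
            if best is None:
                per_anc_rt[aid] = {"identity_pct": 0.0, "rt_coverage": 0.0,
                                   "representative": None}
            else:
                per_anc_rt[aid] = {"identity_pct": best[1], "rt_coverage": best[2],
                                   "representative": best[3]}
        metrics["best_rt_per_ancestor"] = per_anc_rt
    return metrics
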