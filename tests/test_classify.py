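"""Domain scanning, chimera filtering, clustering, concatemer flagging."""

import numpy as np
import pytest

from evehunter.config import PipelineConfig
from evehunter.consensus import ConsensusRecord
from evehunter.classify import (Cluster, cluster_identity_coverage, filter_chimeras,
                                flag_concatemers, load_profiles, scan_domains,
                                select_library, classify_best_hit, is_caulimovirid)
from evehunter.seqio import SequenceRecord
from evehunter.synthetic import _reverse_translate, mutate_nt
from .conftest import random_nt


@pytest.fixture(scope="module")
def profiles():
    return load_profiles()


def _cons(i, seq):
    return ConsensusRecord(f"c{i}", seq, "G")


def test_exact_rt_orf_detected(profiles, rng):
    seq = random_nt(rng, 500) + _reverse_translate(profiles["RT_core"].consensus, rng) \
        + random_nt(rng, 500)
    hits = scan_domains(_cons(0, seq), profiles)
    assert any(d.name == "RT_core" for d in hits)


def test_random_sequence_rarely_fires(profiles, rng):
    fired = 0
    for _ in range(20):
        hits = scan_domains(_cons(0, random_nt(rng, 7000)), profiles)
        if hits:
            fired += 1
    assert fired <= 1  # <5% firing rate per profile, calibrated cutoffs


def test_decoy_carries_te_specific_integrase(profiles, rng):
    from evehunter.synthetic import mutate_protein
    ig = mutate_protein(profiles["integrase"].consensus, 0.10, rng)
    seq = random_nt(rng, 300) + _reverse_translate(ig, rng) + random_nt(rng, 300)
    hits = scan_domains(_cons(0, seq), profiles)
    assert any(d.name == "integrase" and d.klass == "te_specific" for d in hits)


def test_chimera_filter_semantics(profiles, rng):
    from evehunter.synthetic import mutate_protein
    ig = mutate_protein(profiles["integrase"].consensus, 0.05, rng)
    chim = _cons(0, random_nt(rng, 200) + _reverse_translate(ig, rng) + random_nt(rng, 200))
    clean = _cons(1, random_nt(rng, 1000))
    for c in (chim, clean):
        scan_domains(c, profiles)
    assert filter_chimeras([chim, clean], enabled=True) == [clean]
    assert filter_chimeras([chim, clean], enabled=False) == [chim, clean]


def test_best_hit_classification(profiles, rng):
    from evehunter.synthetic import mutate_protein
    cfg = PipelineConfig()
    viral = profiles["RT_core"].consensus
    gypsy = mutate_protein(viral, 0.35, rng)
    baits = [SequenceRecord("v", viral, "aa", "class=caulimovirid genus=GenX"),
             SequenceRecord("g", gypsy, "aa", "class=retroelement genus=Gypsy")]
    viral_cons = _cons(0, _reverse_translate(viral, rng))
    gypsy_cons = _cons(1, _reverse_translate(gypsy, rng))
    noise_cons = _cons(2, random_nt(rng, 800))
    classify_best_hit([viral_cons, gypsy_cons, noise_cons], baits, cfg)
    assert is_caulimovirid(viral_cons) and viral_cons.best_bait[2] == "GenX"
    assert not is_caulimovirid(gypsy_cons)
    assert noise_cons.best_bait is None


def test_cluster_identity_coverage_examples(rng):
    s = random_nt(rng, 1000)
    a, b = SequenceRecord("a", s), SequenceRecord("b", s)
    assert len(cluster_identity_coverage([a, b])) == 1
    frag = SequenceRecord("f", s[:500])
    clusters = cluster_identity_coverage([a, frag], S=90, L=0.9)
    assert len(clusters) == 2  # coverage of the longer is only 0.5


def test_clustering_matches_transitive_closure_and_is_order_invariant(rng):
    # random family structure with known link relation
    fams = []
    for f in range(4):
        anc = random_nt(rng, 600)
        for i in range(3):
            fams.append(SequenceRecord(f"f{f}_{i}", anc))
    clusters = cluster_identity_coverage(fams, S=90, L=0.9)
    assert len(clusters) == 4
    shuffled = list(fams)
    np.random.default_rng(3).shuffle(shuffled)
    clusters2 = cluster_identity_coverage(shuffled, S=90, L=0.9)
    assert [c.member_ids for c in clusters] == [c.member_ids for c in clusters2]


def test_select_library_supplementation(rng):
    a = _cons(0, random_nt(rng, 500))
    b = _cons(1, random_nt(rng, 500))
    a.id, b.id = "A", "B"
    a.best_bait = ("bait", "caulimovirid", "G", 100)
    b.best_bait = None
    cl = [Cluster("C001", ["A", "B"])]
    sel_default = select_library(cl, [a, b], supplementation=False)
    assert [c.id for c in sel_default] == ["A"]
    sel_suppl = select_library(cl, [a, b], supplementation=True)
    assert {c.id for c in sel_suppl} == {"A", "B"}
    assert {c.id for c in sel_default} <= {c.id for c in sel_suppl}
    # redundancy is kept
    b2 = _cons(2, random_nt(rng, 500))
    b2.id = "A2"
    b2.best_bait = ("bait", "caulimovirid", "G", 90)
    cl2 = [Cluster("C001", ["A", "A2"])]
    assert len(select_library(cl2, [a, b2], supplementation=False)) == 2


def test_concatemer_flagging(rng):
    cfg = PipelineConfig()
    unit = random_nt(rng, 3000)
    double = _cons(0, unit + unit)
    flagged, span = flag_concatemers(double, cfg)
    assert flagged and abs((span[1] - span[0]) - 3000) <= 150

    single = _cons(1, random_nt(rng, 7000))
    assert flag_concatemers(single, cfg) == (False, None)

    units = [mutate_nt(unit, 3.0, rng) for _ in range(3)]
    triple = _cons(2, "".join(units))
    flagged3, span3 = flag_concatemers(triple, cfg)
    assert flagged3
    assert abs((span3[1] - span3[0]) - 3000) <= 300  # within +-10% of the unit
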