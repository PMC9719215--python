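"""Generator self-consistency, planting arithmetic and evaluators."""

import numpy as np
import pytest

from evehunter import synthetic as syn
from evehunter.annotate import Annotation
from evehunter.classify import load_profiles, scan_domains
from evehunter.consensus import ConsensusRecord
from evehunter.homsearch import global_identity
from evehunter.seqio import SequenceRecord


@pytest.fixture(scope="module")
def lib():
    return syn.make_ancestors(syn.default_specs(), 11)


def test_ancestor_domain_self_consistency(lib):
    profiles = load_profiles()
    viral = scan_domains(lib.info["CaV"]["record"], profiles)
    names = {d.name for d in viral}
    assert {"RT_core", "zf_CCHC", "MP", "AP", "RNaseH"} <= names
    assert "integrase" not in names and "transposase" not in names
    decoy = scan_domains(lib.info["GyT"]["record"], profiles)
    assert any(d.name == "integrase" and d.klass == "te_specific" for d in decoy)


def test_make_ancestors_deterministic():
    a = syn.make_ancestors(syn.default_specs(), 42)
    b = syn.make_ancestors(syn.default_specs(), 42)
    assert [(r.id, r.residues) for r in a.genomes] == [(r.id, r.residues) for r in b.genomes]
    assert [(r.id, r.residues) for r in a.baits] == [(r.id, r.residues) for r in b.baits]
    c = syn.make_ancestors(syn.default_specs(), 43)
    assert a.genomes[0].residues != c.genomes[0].residues


def test_viral_spec_with_te_domain_rejected():
    bad = syn.AncestorSpec("X", "caulimovirid", "G",
                           layout=[("spacer", 50), ("integrase", 0), ("spacer", 50)])
    with pytest.raises(ValueError):
        syn.make_ancestors([bad], 1)


def test_plant_zero_copies_pure_background(lib):
    genome, truth = syn.plant_elements(50_000, 0.36, lib, [], 5)
    assert truth == [] and len(genome["chr1"]) == 50_000


def test_plant_zero_divergence_verbatim(lib):
    plan = [syn.CopyPlan("CaV", n_full=1, divergence_pct=0.0)]
    genome, truth = syn.plant_elements(60_000, 0.36, lib, plan, 5)
    e = truth[0]
    anc = lib.info["CaV"]["record"].residues
    got = genome["chr1"].residues[e.start:e.end]
    if e.strand == "-":
        from evehunter.seqio import reverse_complement
        got = reverse_complement(got)
    assert got == anc


def test_realized_divergence_within_tolerance(lib):
    plan = [syn.CopyPlan("CaV", n_full=2, divergence_pct=5.0),
            syn.CopyPlan("BaV", n_full=2, divergence_pct=15.0)]
    genome, truth = syn.plant_elements(120_000, 0.36, lib, plan, 6)
    from evehunter.seqio import reverse_complement
    for e in truth:
        anc = lib.info[e.ancestor_id]["record"].residues
        got = genome["chr1"].residues[e.start:e.end]
        if e.strand == "-":
            got = reverse_complement(got)
        ident = global_identity(got, anc)
        assert abs(ident - e.identity_to_ancestor) <= 3.0


def test_forms_and_strands(lib):
    plan = [syn.CopyPlan("CaV", n_full=2, n_fragment=3, divergence_pct=2.0),
            syn.CopyPlan("CaV", n_tandem=1, tandem_k=3, divergence_pct=2.0)]
    genome, truth = syn.plant_elements(200_000, 0.36, lib, plan, 7)
    forms = sorted(e.form for e in truth)
    assert forms == ["fragment", "fragment", "fragment", "full", "full", "tandem_3"]
    anc_len = len(lib.info["CaV"]["record"])
    for e in truth:
        L = e.end - e.start
        if e.form == "full":
            assert abs(L - anc_len) < 0.05 * anc_len
        elif e.form == "fragment":
            assert 0.15 * anc_len <= L <= 0.65 * anc_len
        else:
            assert abs(L - 3 * anc_len) < 0.1 * anc_len


def test_same_seed_byte_identical_genomes(lib):
    plan = [syn.CopyPlan("CaV", n_full=3, divergence_pct=(5.0, 15.0)),
            syn.CopyPlan("GyT", n_full=3, divergence_pct=10.0)]
    g1, t1 = syn.plant_elements(200_000, 0.36, lib, plan, 9)
    g2, t2 = syn.plant_elements(200_000, 0.36, lib, plan, 9)
    assert g1["chr1"].residues == g2["chr1"].residues
    assert [(e.element_id, e.start, e.end) for e in t1] == \
           [(e.element_id, e.start, e.end) for e in t2]


def test_benchmark_cluster_references_covered(rng):
    from .conftest import random_nt
    refs = [SequenceRecord(f"ref{i}", random_nt(rng, 800)) for i in range(3)]
    outputs = [SequenceRecord(f"out{i}", r.residues) for i, r in enumerate(refs)]
    rep = syn.benchmark_cluster(outputs, refs)
    assert all(rep["per_reference_covered"].values())
    lonely = [SequenceRecord(f"r{i}", random_nt(rng, 700)) for i in range(4)]
    rep2 = syn.benchmark_cluster(lonely[:2], lonely[2:])
    assert not any(rep2["per_reference_covered"].values())
    assert len(rep2["singletons"]) == 4


def test_score_recovery_bitmap_semantics(lib, rng):
    truth = [syn.PlantedElement("e1", "CaV", 100, 200, 95.0, "full", "+"),
             syn.PlantedElement("e2", "CaV", 400, 500, 95.0, "full", "+")]
    perfect = [Annotation("chr1", 100, 200, "+", "x", 99.0, 1),
               Annotation("chr1", 400, 500, "+", "x", 99.0, 1)]
    m = syn.score_recovery(truth, perfect)
    assert m["sensitivity_viral"] == 1.0
    assert syn.score_recovery(truth, [])["sensitivity_viral"] == 0.0
    half = [Annotation("chr1", 100, 149, "+", "x", 99.0, 1)]
    m2 = syn.score_recovery(truth, half)
    assert m2["sensitivity_viral"] == 0.0  # 49% overlap is below the 50% rule
    assert m2["mean_span_overlap_viral"] == pytest.approx(0.245)
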