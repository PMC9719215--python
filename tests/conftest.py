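"""Shared fixtures: the flagship synthetic study and small helpers.

The flagship fixture is the package's reference benchmark: a ~2 Mb
genome carrying three caulimovirid genera (10 full copies each across
the 5-15% divergence band, 8 recent 1% fragments, one triple tandem)
plus 30 LTR-retrotransposon decoys. It is session-scoped because both
branch end-to-end tests consume it.
"""

from __future__ import annotations

import numpy as np
import pytest

from evehunter import synthetic as syn
from evehunter.config import PipelineConfig
from evehunter.pipeline import run_branch_a, run_branch_b


@pytest.fixture(scope="session")
def flagship(tmp_path_factory):
    lib = syn.make_ancestors(syn.default_specs(), 1)
    genome, truth = syn.plant_elements(1_600_000, 0.36, lib, syn.default_copy_plan(), 2)
    return {"lib": lib, "genome": genome, "truth": truth, "cfg": PipelineConfig()}


@pytest.fixture(scope="session")
def flagship_branch_a(flagship, tmp_path_factory):
    out = tmp_path_factory.mktemp("branch_a")
    res = run_branch_a(flagship["genome"], flagship["lib"].genomes,
                       flagship["lib"].baits, flagship["cfg"], out)
    res["outdir"] = out
    return res


@pytest.fixture(scope="session")
def flagship_branch_b(flagship, tmp_path_factory):
    out = tmp_path_factory.mktemp("branch_b")
    lib = flagship["lib"]
    res = run_branch_b(flagship["genome"], lib.rt_probes, lib.rt_library,
                       lib.reference_panel, flagship["cfg"], out)
    res["outdir"] = out
    return res


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_nt(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


def mutate_subs(rng, s: str, rate: float) -> str:
    out = []
    for c in s:
        if rng.random() < rate:
            out.append("ACGT".replace(c, "")[rng.integers(0, 3)])
        else:
            out.append(c)
    return "".join(out)
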