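"""Stage orchestration for both branches, with run manifests.

Each run writes its declared outputs plus a ``manifest.json`` recording
the command, the full config snapshot, input digests, the seed and
per-stage record counts, so that identical inputs and config provably
produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .annotate import coverage_percent, coverage_table, mask_genome, write_bed, write_gff3
from .classify import (classify_best_hit, cluster_identity_coverage, filter_chimeras,
                       flag_concatemers, is_caulimovirid, load_profiles, scan_domains,
                       select_library)
from .config import PipelineConfig
from .consensus import build_consensus_library
from .locate import build_subgenome
from .phylo import (Msa, bootstrap_support, classify_leaves, iterative_align_trim,
                    progressive_align, select_blocks, trim_msa)
from .rtminer import mine_rt_proteins
from .seqio import SequenceRecord, write_fasta


def _digest(records) -> str:
    h = hashlib.sha256()
    for r in sorted(records, key=lambda r: r.id):
        h.update(r.id.encode())
        h.update(r.residues.encode())
    return h.hexdigest()[:16]


def _write_manifest(outdir: Path, command: str, cfg: PipelineConfig,
                    inputs: dict, counts: dict, outputs: list[str], status: str) -> dict:
    manifest = {
        "command": command,
        "status": status,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "inputs": inputs,
        "stage_counts": counts,
        "outputs": sorted(outputs),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def run_branch_a(genome: dict[str, SequenceRecord], virus_refs, baits,
                 cfg: PipelineConfig, outdir) -> dict:
    """Locate -> consensus -> classify -> annotate; returns a result dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {"genome_sequences": len(genome),
                    "genome_bp": sum(len(r) for r in genome.values())}
    inputs = {"genome": _digest(genome.values()), "virus_refs": _digest(virus_refs),
              "baits": _digest(baits)}
    outputs = []

    segments, c1 = build_subgenome(genome, virus_refs, baits, cfg)
    counts.update(c1)
    counts["subgenome_bp"] = sum(len(s.residues) for s in segments)
    write_fasta([s.to_record() for s in segments], outdir / "subgenome.fasta")
    outputs.append("subgenome.fasta")
    with open(outdir / "loci.bed", "w") as fh:
        for s in segments:
            sid, st, en = s.origin
            fh.write(f"{sid}\t{st}\t{en}\t{s.segment_id}\n")
    outputs.append("loci.bed")

    result = {"segments": segments, "consensi": [], "selected": [], "clusters": [],
              "annotations": [], "coverage_pct": 0.0, "chimeras_removed": 0}

    if not segments:
        for name in ("consensus_library.fasta", "selected_library.fasta",
                     "annotations.gff3", "annotations.bed"):
            (outdir / name).touch()
            outputs.append(name)
        result["manifest"] = _write_manifest(outdir, "branch-a", cfg, inputs, counts,
                                             outputs, "no candidate loci")
        return result

    consensi, groups, c2 = build_consensus_library(segments, cfg)
    counts.update(c2)
    write_fasta([c.to_record() for c in consensi], outdir / "consensus_library.fasta")
    outputs.append("consensus_library.fasta")
    with open(outdir / "groups.tsv", "w") as fh:
        fh.write("group_id\tsegment_id\tstart\tend\torient\n")
        for g in groups:
            for m in g.members:
                fh.write(f"{g.group_id}\t{m.segment_id}\t{m.start}\t{m.end}\t{m.orient}\n")
    outputs.append("groups.tsv")

    profiles = load_profiles()
    for c in consensi:
        scan_domains(c, profiles)
    kept = filter_chimeras(consensi, cfg.filter_chimeras)
    result["chimeras_removed"] = len(consensi) - len(kept)
    counts["step3_chimeras_removed"] = result["chimeras_removed"]
    classify_best_hit(kept, baits, cfg)
    clusters = cluster_identity_coverage(kept, cfg.cluster_S_pct, cfg.cluster_L_frac,
                                         cfg.cluster_L_mode)
    counts["step3_clusters"] = len(clusters)
    selected = select_library(clusters, kept, cfg.blastclust_supplementation)
    counts["step3_selected"] = len(selected)
    for c in selected:
        flag_concatemers(c, cfg)
    write_fasta([c.to_record() for c in selected], outdir / "selected_library.fasta")
    outputs.append("selected_library.fasta")

    rows = []
    for c in consensi:
        rows.append({
            "consensus_id": c.id, "length": len(c.residues), "group_id": c.group_id,
            "domains": ",".join(sorted({d.name for d in c.domains})),
            "best_bait": c.best_bait[0] if c.best_bait else "",
            "best_bait_class": c.best_bait[1] if c.best_bait else "none",
            "genus": c.best_bait[2] if c.best_bait else "",
            "cluster_id": c.cluster_id or "", "concatemer": c.concatemer,
            "monomer_span": f"{c.monomer_span[0]}-{c.monomer_span[1]}" if c.monomer_span else "",
            "selected": c.selected,
        })
    pd.DataFrame(rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    outputs.append("summary.tsv")

    annotations = mask_genome(genome, [c.to_record() for c in selected], cfg)
    counts["step4_annotations"] = len(annotations)
    cov = coverage_percent(annotations, genome)
    counts["step4_coverage_pct"] = round(cov, 4)
    write_gff3(annotations, outdir / "annotations.gff3")
    write_bed(annotations, outdir / "annotations.bed")
    pd.DataFrame(coverage_table(annotations, genome)).to_csv(
        outdir / "coverage.tsv", sep="\t", index=False)
    outputs += ["annotations.gff3", "annotations.bed", "coverage.tsv"]

    result.update({"consensi": consensi, "selected": selected, "clusters": clusters,
                   "annotations": annotations, "coverage_pct": cov})
    status = "ok" if selected else "no consensus selected"
    result["manifest"] = _write_manifest(outdir, "branch-a", cfg, inputs, counts,
                                         outputs, status)
    return result


def run_branch_b(genome: dict[str, SequenceRecord], rt_probes, rt_library,
                 reference_panel, cfg: PipelineConfig, outdir) -> dict:
    """RT mining -> dereplication -> iterative alignment -> phylogeny."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    inputs = {"genome": _digest(genome.values()), "rt_probes": _digest(rt_probes),
              "rt_library": _digest(rt_library), "reference_panel": _digest(reference_panel)}
    outputs = []
    result = {"representatives": [], "tree": None, "classification": {},
              "candidates": []}

    reps, candidates, c1 = mine_rt_proteins(genome, rt_probes, rt_library, cfg)
    counts.update(c1)
    result["candidates"] = candidates

    pd.DataFrame([{
        "candidate_id": c.candidate_id, "subject_id": c.origin[0],
        "start": c.origin[1], "end": c.origin[2], "frame": c.origin[3],
        "length_aa": len(c.protein), "best_hit_class": c.best_hit_class,
        "best_hit_genus": c.best_hit_genus or "", "cluster_id": c.cluster_id or "",
        "representative": c.representative,
    } for c in candidates]).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    outputs.append("candidates.tsv")

    if not reps:
        for name in ("representatives.fasta", "msa.fasta", "tree.nwk",
                     "classification.tsv"):
            (outdir / name).touch()
            outputs.append(name)
        result["manifest"] = _write_manifest(outdir, "branch-b", cfg, inputs, counts,
                                             outputs, "no RT candidates")
        return result

    # step-2 quality loop on the representatives alone
    rep_records = [r.to_record() for r in reps]
    if len(rep_records) >= 2:
        rep_records = iterative_align_trim(rep_records, cfg.trim_rounds_initial,
                                           cfg.trim_col_gap_max, cfg.trim_seq_occupancy_min)
    counts["rt_after_initial_loop"] = len(rep_records)
    write_fasta(rep_records, outdir / "representatives.fasta")
    outputs.append("representatives.fasta")
    result["representatives"] = [r for r in reps
                                 if r.candidate_id in {x.id for x in rep_records}]

    # step 3: merge with the reference panel, iterate, curate, infer
    panel_ids = tuple(r.id for r in reference_panel)
    pool = rep_records + list(reference_panel)
    survivors = iterative_align_trim(pool, cfg.trim_rounds_final,
                                     cfg.trim_col_gap_max, cfg.trim_seq_occupancy_min,
                                     protected=panel_ids)
    counts["taxa_after_final_loop"] = len(survivors)
    msa = progressive_align(survivors)
    try:
        msa = select_blocks(msa, cfg.block_min_len, cfg.block_col_gap_max,
                            cfg.block_col_conservation_min)
    except ValueError:
        result["manifest"] = _write_manifest(outdir, "branch-b", cfg, inputs, counts,
                                             outputs, "no conserved blocks")
        return result
    counts["msa_columns"] = msa.columns
    with open(outdir / "msa.fasta", "w") as fh:
        for i, row in zip(msa.ids, msa.rows):
            fh.write(f">{i}\n{row}\n")
    outputs.append("msa.fasta")

    if len(msa.ids) < 3:
        result["manifest"] = _write_manifest(outdir, "branch-b", cfg, inputs, counts,
                                             outputs, "fewer than 3 taxa")
        return result
    tree = bootstrap_support(msa, cfg.bootstrap_replicates, cfg.seed)
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(tree.newick() + "\n")
    outputs.append("tree.nwk")
    result["tree"] = tree

    ref_labels = {r.id: r.tags().get("genus", "") for r in reference_panel}
    classification = classify_leaves(tree, ref_labels, cfg.support_threshold)
    result["classification"] = classification
    pd.DataFrame([{"candidate_id": k, "genus": v[0], "support": v[1]}
                  for k, v in sorted(classification.items())]).to_csv(
        outdir / "classification.tsv", sep="\t", index=False)
    outputs.append("classification.tsv")
    counts["classified"] = sum(1 for v in classification.values()
                               if v[0] != "unclassified")
    result["manifest"] = _write_manifest(outdir, "branch-b", cfg, inputs, counts,
                                         outputs, "ok")
    return result
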