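"""End-to-end orchestration: simulate -> scan -> phylo -> classify ->
annotate -> motifs -> promoters -> expression, with a content-hash manifest.

Every stage is a thin wrapper over the library modules; all randomness is
funneled through named seeds derived from the run seed, so a rerun with the
same config is hash-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import (alignment_phylo, classification, expression, gene_annotation,
               io_formats, kinase_scan, motif_discovery, promoter_scan,
               synthetic_data)

log = logging.getLogger("kinafam")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "kinafam_run"
    bootstrap_reps: int = 200
    motif_width: int = 12
    n_motifs: int = 20
    motif_restarts: int = 3
    promoter_len: int = 1500
    synth: synthetic_data.SynthConfig | None = None

    def __post_init__(self):
        if self.synth is None:
            self.synth = synthetic_data.SynthConfig(
                seed=self.seed, promoter_len=self.promoter_len)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "outputs": {}}
    written: list[Path] = []

    def emit(stage, name, path):
        written.append(path)
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
        manifest["stages"].setdefault(stage, []).append(str(path.name))

    elements = promoter_scan.packaged_element_table()

    # ---- simulate
    log.info("stage simulate: generating toy genome")
    toy = synthetic_data.generate_toy_genome(config.synth, elements)
    promoters, element_truth = synthetic_data.plant_promoter_elements(
        toy, elements)
    ct_table, fold_truth = synthetic_data.simulate_ct_table(toy)
    io_formats.write_fasta(toy.genome_records, out / "genome.fasta")
    io_formats.write_gff3(toy.annotation, out / "annotation.gff3")
    io_formats.write_fasta(toy.proteins, out / "proteins.fasta")
    io_formats.write_fasta(toy.references, out / "references.fasta")
    toy.truth.members.to_csv(out / "truth_members.tsv", sep="\t", index=False)
    element_truth.to_csv(out / "truth_elements.tsv", sep="\t")
    ct_table.to_csv(out / "ct_table.tsv", sep="\t", index=False)
    for name in ("genome.fasta", "annotation.gff3", "proteins.fasta",
                 "references.fasta", "truth_members.tsv",
                 "truth_elements.tsv", "ct_table.tsv"):
        emit("simulate", name, out / name)

    # ---- scan
    log.info("stage scan: %d candidate proteins", len(toy.proteins))
    scan_cfg = kinase_scan.ScanConfig()
    refs = {r.id: r.sequence for r in toy.references}
    scan_rows, accepted = [], []
    signatures = {}
    for rec in toy.proteins:
        rid, score, e = kinase_scan.best_hit(rec.sequence, refs, scan_cfg)
        sig = kinase_scan.find_signature(rec.sequence)
        ok, reasons = kinase_scan.validate_candidate(
            rec.sequence, hit_evalue=e, config=scan_cfg, signature=sig)
        signatures[rec.id] = sig
        if ok:
            accepted.append(rec.id)
        scan_rows.append({
            "id": rec.id, "best_ref": rid, "score": score, "evalue": e,
            "tloop": sig.tloop_type, "tloop_pos": sig.tloop_pos,
            "cd_span": "" if sig.cd_span is None
            else f"{sig.cd_span[0]}-{sig.cd_span[1]}",
            "anchors": ",".join(sorted(sig.anchors_found)),
            "accepted": ok, "reasons": "; ".join(reasons)})
    pd.DataFrame(scan_rows).to_csv(out / "scan.tsv", sep="\t", index=False)
    emit("scan", "scan.tsv", out / "scan.tsv")
    log.info("stage scan: accepted %d / %d", len(accepted), len(toy.proteins))

    # ---- phylo
    proteins = {r.id: r.sequence for r in toy.proteins}
    phylo_seqs = {gid: proteins[gid] for gid in accepted}
    phylo_seqs.update(refs)
    log.info("stage phylo: aligning %d sequences", len(phylo_seqs))
    msa = alignment_phylo.progressive_msa(phylo_seqs)
    io_formats.write_fasta(
        [io_formats.SeqRecord(id=i, sequence=msa.rows[i]) for i in msa.ids],
        out / "aligned.fasta")
    dmat = alignment_phylo.p_distance(msa)
    pd.DataFrame(dmat.matrix, index=dmat.ids, columns=dmat.ids).to_csv(
        out / "distances.tsv", sep="\t")
    tree = alignment_phylo.bootstrap_support(
        msa, n_reps=config.bootstrap_reps, seed=config.seed)
    (out / "tree.nwk").write_text(io_formats.write_newick(tree) + "\n")
    for name in ("aligned.fasta", "distances.tsv", "tree.nwk"):
        emit("phylo", name, out / name)

    # ---- classify
    tloops = {gid: signatures[gid].tloop_type for gid in accepted}
    groups = classification.assign_all(tree, tloops, toy.ref_groups)

    # ---- annotate
    annotations = {g.gene_id: g for g in toy.annotation}
    extracted = {}
    for gid in accepted:
        cds = gene_annotation.extract_cds(annotations[gid], toy.genome)
        extracted[gid] = gene_annotation.translate(cds)
    table = classification.build_family_table(
        accepted, annotations, extracted, tloops, groups)
    io_formats.write_family_table(table, out / "family_table.tsv")
    structure = gene_annotation.gene_structure_table(
        [annotations[gid] for gid in accepted])
    pd.DataFrame(structure).to_csv(out / "gene_structure.tsv", sep="\t",
                                   index=False)
    for name in ("family_table.tsv", "gene_structure.tsv"):
        emit("annotate", name, out / name)

    # ---- motifs
    log.info("stage motifs: EM search, %d motifs", config.n_motifs)
    family_proteins = {gid: proteins[gid] for gid in accepted}
    motifs = motif_discovery.em_motif_search(
        family_proteins, width=config.motif_width, n_motifs=config.n_motifs,
        restarts=config.motif_restarts, seed=config.seed)
    bg = motif_discovery._background(motif_discovery._encode(family_proteins))
    motif_discovery.write_meme_minimal(motifs, bg, out / "motifs.meme")
    presence, shared = motif_discovery.motif_architecture(
        family_proteins, motifs, groups=groups)
    arch = pd.DataFrame([
        {"gene_id": gid, "group": groups.get(gid, ""),
         "motifs": ";".join(f"{mi}@{off}" for mi, off in hits)}
        for gid, hits in presence.items()])
    arch.to_csv(out / "motif_architecture.tsv", sep="\t", index=False)
    for name in ("motifs.meme", "motif_architecture.tsv"):
        emit("motifs", name, out / name)

    # ---- promoters
    counts, totals = promoter_scan.count_elements(promoters, elements)
    counts.to_csv(out / "element_counts.tsv", sep="\t")
    totals.to_csv(out / "element_category_totals.tsv", sep="\t")
    for name in ("element_counts.tsv", "element_category_totals.tsv"):
        emit("promoters", name, out / name)

    # ---- expression
    fcm = expression.delta_delta_ct(ct_table)
    fcm.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
    log2m = expression.log2_matrix(fcm)
    order, _ = expression.cluster_rows(log2m)
    expression.heatmap_export(log2m, order, out / "log2_heatmap.tsv")
    for name in ("fold_changes.tsv", "log2_heatmap.tsv"):
        emit("expression", name, out / name)

    manifest["params"] = {
        "bootstrap_reps": config.bootstrap_reps,
        "motif_width": config.motif_width, "n_motifs": config.n_motifs,
        "motif_restarts": config.motif_restarts,
        "synth": {k: v for k, v in asdict(config.synth).items()
                  if k != "fold_changes"},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
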