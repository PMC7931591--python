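"""End-to-end pipeline: architectures in, consolidated report out.

Orchestrates the stages — parse/simulate, descriptive statistics, FU
overlay, gain/loss parsimony, splice motifs, optional ortholog comparison
— and writes one JSON report plus the per-stage TSV artifacts, each number
traceable to a stage output file.  Re-running with identical inputs and
seed yields identical report bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import fu_overlay, ortholog_exon_compare, parsimony, splice_motifs
from .gene_models import (
    GeneArchitecture,
    architecture_statistics,
    read_architecture,
    write_architecture_tsv,
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Manifest-driven configuration for one pipeline run.

    ``genes`` maps gene_id -> {gff3, fus, genomic, cdna, lineage, species};
    paths are relative to ``base_dir``.
    """

    genes: dict[str, dict[str, str]]
    out_dir: str | Path
    base_dir: str | Path = "."
    tree_newick: str = parsimony.DEFAULT_TREE_NEWICK
    scenarios: Sequence[str] = ("ancestral_gain", "free_gains")
    ortholog_table: str | Path | None = None
    alignment_file: str | Path | None = None
    tectipleura_lineages: frozenset[str] = frozenset({"Tectipleura"})
    one_per_lineage: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        doc.setdefault("base_dir", str(Path(path).parent))
        if "tectipleura_lineages" in doc:
            doc["tectipleura_lineages"] = frozenset(doc["tectipleura_lineages"])
        return cls(**doc)


def _read_fasta_one(path: Path) -> str:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise ValueError(f"{path}: empty FASTA")
    return str(rec.seq).upper()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the consolidated report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = Path(config.base_dir)

    # --- stage: parse -----------------------------------------------------
    archs: list[GeneArchitecture] = []
    genomic: dict[str, str] = {}
    cdna: dict[str, str] = {}
    for gene_id, entry in sorted(config.genes.items()):
        try:
            gff = base / entry["gff3"]
            if not gff.exists():
                raise FileNotFoundError(f"missing annotation file: {gff}")
            arch = read_architecture(
                gff,
                fmt="gff3",
                fu_table=(base / entry["fus"]) if entry.get("fus") else None,
                gene_id=gene_id,
                species=entry.get("species", ""),
                lineage=entry.get("lineage", ""),
            )
            archs.append(arch)
            genomic[gene_id] = _read_fasta_one(base / entry["genomic"])
            cdna[gene_id] = _read_fasta_one(base / entry["cdna"])
        except (OSError, ValueError, KeyError) as exc:
            raise PipelineError("parse", f"{gene_id}: {exc}") from exc
    write_architecture_tsv(archs, out / "architectures.tsv")

    # --- stage: statistics ------------------------------------------------
    try:
        stats = architecture_statistics(archs)
    except ValueError as exc:
        raise PipelineError("statistics", str(exc)) from exc

    # --- stage: overlay ---------------------------------------------------
    have_internal = any(
        i.klass == "internal" for a in archs for i in a.introns
    )
    overlay_summary: dict = {}
    groups: list[fu_overlay.PositionGroup] = []
    peptides: list[fu_overlay.FUPeptide] = []
    try:
        for arch in archs:
            peptides.extend(fu_overlay.extract_fu_peptides(arch, cdna[arch.gene_id]))
        if len(peptides) >= 2:
            if config.alignment_file is not None:
                alignment = fu_overlay.align_fus(external=base / config.alignment_file)
            else:
                alignment = fu_overlay.align_fus(peptides)
            fu_overlay.write_alignment_fasta(alignment, out / "fu_alignment.fasta")
            placements = fu_overlay.project_splice_sites(
                archs, alignment, peptides, one_per_lineage=config.one_per_lineage
            )
            groups, overlay_summary = fu_overlay.classify_positions(placements)
            fu_overlay.placements_to_tsv(groups, out / "placements.tsv")
        else:
            overlay_summary = {"n_placements": 0, "n_groups": 0}
    except ValueError as exc:
        raise PipelineError("overlay", str(exc)) from exc

    # --- stage: parsimony -------------------------------------------------
    scenario_block: dict = {}
    try:
        tree = parsimony.LineageTree.from_newick(config.tree_newick)
        lineage_fus = sorted(
            {
                i.flanking_fus[0]
                for a in archs
                for i in a.introns
                if i.klass == "internal" and i.flanking_fus
            }
        )
        # score each multiply-shared ortholog-candidate position; fall back
        # to the overall per-position pattern set
        for g in groups:
            if g.klass != "multiple":
                continue
            states: dict[tuple[str, str], str] = {}
            lineages_in_tree = set(tree.leaf_names)
            fus_all = sorted({p.fu_id for a in archs for p in a.fus if p.fu_id != "S"})
            for ln in lineages_in_tree:
                for fu in fus_all:
                    states[(ln, fu)] = parsimony.ABSENT
            for m in g.members:
                if m.lineage in lineages_in_tree:
                    states[(m.lineage, m.fu_id)] = parsimony.PRESENT
            try:
                pattern = parsimony.PresencePattern(states)
            except ValueError:
                continue
            comp = parsimony.compare_scenarios(pattern, tree)
            scenario_block[f"col{g.key[0]}_phase{g.key[1]}"] = {
                "totals": comp["totals"],
                "preferred": comp["preferred"],
            }
    except ValueError as exc:
        raise PipelineError("parsimony", str(exc)) from exc

    # --- stage: motifs ----------------------------------------------------
    motifs_block: dict = {}
    try:
        contexts: list[splice_motifs.BoundaryContext] = []
        for arch in archs:
            contexts.extend(
                splice_motifs.extract_boundary_contexts(arch, genomic[arch.gene_id])
            )
        internal_ctx = [c for c in contexts if c.klass == "internal"]
        if internal_ctx:
            klass_by_intron = {
                (m.gene_id, m.cds_offset): g.klass
                for g in groups
                for m in g.members
            }
            lineage_by_gene = {a.gene_id: a.lineage for a in archs}
            splice_motifs.label_contexts(
                internal_ctx,
                klass_by_intron,
                tectipleura_lineages=set(config.tectipleura_lineages),
                lineage_by_gene=lineage_by_gene,
            )
            splice_motifs.contexts_to_tsv(internal_ctx, out / "contexts.tsv")
            motifs_block["dinucleotides"] = splice_motifs.classify_dinucleotides(
                internal_ctx
            )
            for side in ("donor", "acceptor"):
                pfm = splice_motifs.build_pfm(internal_ctx, side)
                pfm.to_tsv(out / f"pfm_{side}.tsv")
                motifs_block[f"pfm_{side}_information"] = pfm.information
            motifs_block["proto_splice"] = splice_motifs.proto_splice_frequency(
                internal_ctx
            )
    except ValueError as exc:
        raise PipelineError("motifs", str(exc)) from exc

    # --- stage: orthologs (optional) --------------------------------------
    ortho_block: dict | None = None
    try:
        if config.ortholog_table is not None:
            pairs = ortholog_exon_compare.read_pairs(base / config.ortholog_table)
            filtered, filt_report = ortholog_exon_compare.filter_pairs(pairs)
            dist = ortholog_exon_compare.exon_count_differences(filtered)
            ortholog_exon_compare.histogram_to_tsv(
                dist, out / "ortholog_histogram.tsv"
            )
            ortho_block = {"filter": filt_report, "distribution": dist}
    except (OSError, ValueError) as exc:
        raise PipelineError("orthologs", str(exc)) from exc

    report = {
        "genes": {
            a.gene_id: {
                "lineage": a.lineage,
                "species": a.species,
                "exons": len(a.exons),
                "introns": len(a.introns),
                "linker": sum(1 for i in a.introns if i.klass == "linker"),
                "internal": sum(1 for i in a.introns if i.klass == "internal"),
            }
            for a in archs
        },
        "statistics": {
            "exon_length_min": stats["exon_length_min"],
            "exon_length_max": stats["exon_length_max"],
            "exon_length_median": stats["exon_length_median"],
            "phase_fractions_pct": stats["phase_fractions_pct"],
            "phase_fractions_raw": stats["phase_fractions_raw"],
            "n_internal_introns": stats["n_internal_introns"],
        },
        "overlay": overlay_summary,
        "ortholog_positions": [
            list(g.key) for g in groups if g.ortholog
        ],
        "scenarios": scenario_block,
        "motifs": motifs_block,
        "orthologs": ortho_block,
        "have_internal_introns": have_internal,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
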