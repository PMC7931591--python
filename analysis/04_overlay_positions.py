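#!/usr/bin/env python
"""Overlay all internal splice sites in FU-alignment coordinates.

Projects every internal intron into (alignment column, phase) space,
classifies positions as unique / multiple / ortholog and writes
results/overlay_summary.json + results/placements.tsv.
"""

import json
from pathlib import Path

from intronarch.fu_overlay import (
    align_fus,
    classify_positions,
    extract_fu_peptides,
    placements_to_tsv,
    project_splice_sites,
    write_alignment_fasta,
)
from intronarch.gene_models import read_architecture

BASE = Path(__file__).resolve().parent.parent / "results"
FAMILY = BASE / "family"


def read_fasta(path):
    lines = path.read_text().splitlines()
    return "".join(l for l in lines if not l.startswith(">"))


def main() -> None:
    manifest = json.loads((FAMILY / "manifest.json").read_text())
    archs, peptides = [], []
    for gid, files in sorted(manifest.items()):
        arch = read_architecture(
            FAMILY / files["gff3"], fmt="gff3", gene_id=gid,
            lineage=files["lineage"],
        )
        archs.append(arch)
        peptides.extend(extract_fu_peptides(arch, read_fasta(FAMILY / files["cdna"])))
    alignment = align_fus(peptides)
    write_alignment_fasta(alignment, BASE / "fu_alignment.fasta")
    placements = project_splice_sites(archs, alignment, peptides)
    groups, summary = classify_positions(placements)
    placements_to_tsv(groups, BASE / "placements.tsv")
    (BASE / "overlay_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"{summary['n_placements']} placements in {summary['n_groups']} "
        f"positions: {summary['multiple_pct']}% multiple, "
        f"{summary['unique_pct']}% unique"
    )
    if summary["ortholog_groups"]:
        print(f"ortholog positions (same FU, >=2 lineages): "
              f"{summary['ortholog_groups']}")
    else:
        print("no ortholog positions in this family")


if __name__ == "__main__":
    main()
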