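#!/usr/bin/env python
"""Splice-site motifs: boundary classes, PFMs, proto-splice sites.

Extracts the 5-nt windows around every splice site of the simulated
family, classifies boundary dinucleotides (GT-AG / GC-AG / other), builds
donor and acceptor position-frequency matrices, and compares AG|G
proto-splice-site frequency between multiple and unique positions
(two-sided Fisher exact test).  Results to results/motifs/.
"""

import json
from pathlib import Path

from intronarch.gene_models import read_architecture
from intronarch.splice_motifs import (
    build_pfm,
    classify_dinucleotides,
    contexts_to_tsv,
    extract_boundary_contexts,
    label_contexts,
    proto_splice_frequency,
)

BASE = Path(__file__).resolve().parent.parent / "results"
FAMILY = BASE / "family"
OUT = BASE / "motifs"


def read_fasta(path):
    lines = path.read_text().splitlines()
    return "".join(l for l in lines if not l.startswith(">"))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((FAMILY / "manifest.json").read_text())
    contexts, lineage_by_gene = [], {}
    for gid, files in sorted(manifest.items()):
        arch = read_architecture(
            FAMILY / files["gff3"], fmt="gff3", gene_id=gid,
            lineage=files["lineage"],
        )
        lineage_by_gene[gid] = files["lineage"]
        genomic = read_fasta(FAMILY / files["genomic"])
        contexts.extend(
            c for c in extract_boundary_contexts(arch, genomic)
            if c.klass == "internal"
        )

    klass_by_intron = {}
    for line in (BASE / "placements.tsv").read_text().splitlines()[1:]:
        gene, lineage, fu, col, phase, off, klass, orth = line.split("\t")
        klass_by_intron[(gene, int(off))] = klass
    label_contexts(
        contexts, klass_by_intron,
        tectipleura_lineages={"Tectipleura"},
        lineage_by_gene=lineage_by_gene,
    )
    contexts_to_tsv(contexts, OUT / "contexts.tsv")

    dinuc = classify_dinucleotides(contexts)
    print(
        f"{dinuc['n']} internal splice sites: "
        f"{100 * dinuc['canonical_gt_ag']['fraction']:.1f}% GT-AG, "
        f"{dinuc['gc_ag']['count']} GC-AG, {len(dinuc['other'])} other"
    )
    for side in ("donor", "acceptor"):
        pfm = build_pfm(contexts, side)
        pfm.to_tsv(OUT / f"pfm_{side}.tsv")
        peak = max(pfm.information)
        print(f"{side} PFM: peak information {peak:.2f} bits "
              f"({pfm.n_contexts} contexts)")

    proto = proto_splice_frequency(contexts)
    (OUT / "motifs.json").write_text(
        json.dumps({"dinucleotides": dinuc, "proto_splice": proto}, indent=2)
    )
    for stratum, v in proto["strata"].items():
        print(f"AG|G frequency [{stratum}]: {v['frequency']:.3f} (n={v['n']})")
    if proto["fisher_2x2"]:
        print(f"multiple-vs-unique Fisher p = {proto['fisher_2x2']['p_value']:.3g}")


if __name__ == "__main__":
    main()
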