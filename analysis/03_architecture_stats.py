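#!/usr/bin/env python
"""Descriptive statistics of the simulated family's architectures.

Per-gene intron counts, exon-size range/median and the internal-intron
phase split, written to results/architecture_stats.json.
"""

import json
from pathlib import Path

from intronarch.gene_models import architecture_statistics, read_architecture

BASE = Path(__file__).resolve().parent.parent / "results"
FAMILY = BASE / "family"


def main() -> None:
    manifest = json.loads((FAMILY / "manifest.json").read_text())
    archs = [
        read_architecture(
            FAMILY / files["gff3"], fmt="gff3", gene_id=gid,
            lineage=files["lineage"],
        )
        for gid, files in sorted(manifest.items())
    ]
    stats = architecture_statistics(archs)
    out = BASE / "architecture_stats.json"
    out.write_text(json.dumps(stats, indent=2, sort_keys=True))
    print(f"wrote {out}")
    print(
        "exon sizes: min {exon_length_min} / median {exon_length_median} / "
        "max {exon_length_max} nt".format(**stats)
    )
    pct = stats["phase_fractions_pct"]
    print(
        f"phase split over {stats['n_internal_introns']} internal introns: "
        f"{pct[0]}% phase 0, {pct[1]}% phase 1, {pct[2]}% phase 2"
    )


if __name__ == "__main__":
    main()
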