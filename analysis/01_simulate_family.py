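#!/usr/bin/env python
"""Simulate the reference gene family and write its fixtures.

One multi-FU gene family (signal peptide + 8 tandem-duplicated FUs with
phase-1 linker introns, internal introns gained/lost along the
Cephalopoda/Vetigastropoda/Tectipleura tree) under the default
configuration, seed 1.  All later steps read from results/family/.
"""

from pathlib import Path

from intronarch.synthetic_data import SimulationConfig, simulate_family, write_fixtures

OUT = Path(__file__).resolve().parent.parent / "results" / "family"


def main() -> None:
    truth = simulate_family(SimulationConfig(), seed=1)
    write_fixtures(truth, OUT)
    print(f"wrote fixtures for {len(truth.architectures)} genes to {OUT}")
    for gid, arch in sorted(truth.architectures.items()):
        linker = sum(1 for i in arch.introns if i.klass == "linker")
        internal = sum(1 for i in arch.introns if i.klass == "internal")
        print(
            f"  {gid}: {len(arch.exons)} exons, {linker} linker + "
            f"{internal} internal introns, genomic {len(truth.genomic[gid])} nt"
        )
    n_gain = sum(1 for e in truth.events if e.kind == "gain")
    n_loss = sum(1 for e in truth.events if e.kind == "loss")
    print(f"event log: {n_gain} gains, {n_loss} losses")


if __name__ == "__main__":
    main()
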