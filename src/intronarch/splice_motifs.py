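"""Splice-site boundary sequences, motifs and proto-splice sites.

Canonical spliceosomal introns begin with GT and end with AG (the
GT-AG / Chambon's rule); GC-AG is the most common minor variant.  The
*proto-splice site* AG|G — upstream exon ending in AG, downstream exon
beginning with G — marks exonic contexts associated with preferential
intron insertion; if multiply-occupied splice positions arose by
convergent gains, they should be enriched for AG|G relative to unique
positions.  This module extracts five-nucleotide windows around each
splice site, classifies boundary dinucleotides, builds position-frequency
matrices (with per-column information content) and tests the AG|G
enrichment with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .gene_models import GeneArchitecture

WINDOW = 5
ALPHABET = "ACGT"


@dataclass
class BoundaryContext:
    gene_id: str
    cds_offset: int
    phase: int
    klass: str | None  # linker/internal
    fu_id: str | None
    exon_5p: str  # last 5 exonic nt before the donor
    intron_5p: str  # first 5 intronic nt
    intron_3p: str  # last 5 intronic nt
    exon_3p: str  # first 5 exonic nt after the acceptor
    clipped: bool = False
    position_klass: str | None = None  # "multiple" | "unique"
    lineage_set_klass: str | None = None  # "tectipleura" | "non_tectipleura"

    @property
    def proto_splice(self) -> bool:
        """AG|G: upstream exon ends in AG and downstream exon starts with G."""
        return self.exon_5p.endswith("AG") and self.exon_3p.startswith("G")


@dataclass
class PositionFrequencyMatrix:
    labels: list[str]
    counts: dict[str, list[int]]  # base -> per-column counts
    frequencies: dict[str, list[float]]
    information: list[float]  # bits per column, 2 - Shannon entropy
    n_contexts: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("base\t" + "\t".join(self.labels) + "\n")
            for base in ALPHABET:
                fh.write(
                    base
                    + "\t"
                    + "\t".join(f"{f:.6g}" for f in self.frequencies[base])
                    + "\n"
                )
            fh.write(
                "info\t" + "\t".join(f"{i:.6g}" for i in self.information) + "\n"
            )


def extract_boundary_contexts(
    arch: GeneArchitecture, genomic: str
) -> list[BoundaryContext]:
    """One context per intron; windows clipped at sequence ends are flagged."""
    if not arch.exons:
        raise ValueError(f"{arch.gene_id}: architecture has no exons")
    genomic = genomic.upper()
    contexts = []
    for idx, intr in enumerate(arch.introns):
        donor = arch.exons[idx].end
        acceptor = arch.exons[idx + 1].start
        exon_5p = genomic[max(0, donor - WINDOW) : donor]
        intron_5p = genomic[donor : donor + WINDOW]
        intron_3p = genomic[max(donor, acceptor - WINDOW) : acceptor]
        exon_3p = genomic[acceptor : acceptor + WINDOW]
        clipped = not (
            len(exon_5p) == len(intron_5p) == len(intron_3p) == len(exon_3p) == WINDOW
        )
        contexts.append(
            BoundaryContext(
                gene_id=arch.gene_id,
                cds_offset=intr.cds_offset,
                phase=intr.phase,
                klass=intr.klass,
                fu_id=intr.flanking_fus[0] if intr.flanking_fus else None,
                exon_5p=exon_5p,
                intron_5p=intron_5p,
                intron_3p=intron_3p,
                exon_3p=exon_3p,
                clipped=clipped,
            )
        )
    return contexts


def label_contexts(
    contexts: Sequence[BoundaryContext],
    position_klass_by_intron: dict[tuple[str, int], str],
    tectipleura_lineages: set[str] | None = None,
    lineage_by_gene: dict[str, str] | None = None,
) -> list[BoundaryContext]:
    """Attach overlay position classes (and lineage-set labels) to contexts."""
    for c in contexts:
        c.position_klass = position_klass_by_intron.get((c.gene_id, c.cds_offset))
        if lineage_by_gene is not None and tectipleura_lineages is not None:
            c.lineage_set_klass = (
                "tectipleura"
                if lineage_by_gene.get(c.gene_id) in tectipleura_lineages
                else "non_tectipleura"
            )
    return list(contexts)


def classify_dinucleotides(contexts: Sequence[BoundaryContext]) -> dict:
    """Classify intron boundary pairs: GT..AG canonical, GC..AG minor, other.

    Contexts with N in a decisive dinucleotide are excluded from the
    denominator and reported.
    """
    usable = []
    excluded = 0
    for c in contexts:
        if len(c.intron_5p) < 2 or len(c.intron_3p) < 2:
            excluded += 1
            continue
        pair = (c.intron_5p[:2], c.intron_3p[-2:])
        if "N" in pair[0] or "N" in pair[1]:
            excluded += 1
            continue
        usable.append(pair)
    if not usable:
        raise ValueError("no context with a complete boundary dinucleotide pair")
    n = len(usable)
    canonical = sum(1 for p in usable if p == ("GT", "AG"))
    gc_ag = sum(1 for p in usable if p == ("GC", "AG"))
    other = sorted(
        f"{a}-{b}" for (a, b) in usable if (a, b) not in {("GT", "AG"), ("GC", "AG")}
    )
    return {
        "n": n,
        "excluded": excluded,
        "canonical_gt_ag": {"count": canonical, "fraction": canonical / n},
        "gc_ag": {"count": gc_ag, "fraction": gc_ag / n},
        "other": other,
    }


def build_pfm(
    contexts: Sequence[BoundaryContext],
    side: str,
    *,
    position_klass: str | None = None,
    lineage_set_klass: str | None = None,
) -> PositionFrequencyMatrix:
    """10-column position-frequency matrix for donor or acceptor windows.

    Donor: 5 exonic + 5 intronic columns; acceptor: 5 intronic + 5 exonic.
    N (and clipped-short positions) are excluded per column, so each
    column's frequencies sum to 1 over its own denominator.  Information
    content is 2 - Shannon entropy in bits.
    """
    if side not in {"donor", "acceptor"}:
        raise ValueError("side must be 'donor' or 'acceptor'")
    chosen = [
        c
        for c in contexts
        if (position_klass is None or c.position_klass == position_klass)
        and (lineage_set_klass is None or c.lineage_set_klass == lineage_set_klass)
    ]
    if not chosen:
        raise ValueError(
            f"no contexts match filters position_klass={position_klass!r}, "
            f"lineage_set_klass={lineage_set_klass!r}"
        )

    def window10(c: BoundaryContext) -> str:
        if side == "donor":
            return c.exon_5p.rjust(WINDOW, "N") + c.intron_5p.ljust(WINDOW, "N")
        return c.intron_3p.rjust(WINDOW, "N") + c.exon_3p.ljust(WINDOW, "N")

    if side == "donor":
        labels = [f"E{-i}" for i in range(WINDOW, 0, -1)] + [
            f"I+{i}" for i in range(1, WINDOW + 1)
        ]
    else:
        labels = [f"I{-i}" for i in range(WINDOW, 0, -1)] + [
            f"E+{i}" for i in range(1, WINDOW + 1)
        ]

    counts = {b: [0] * (2 * WINDOW) for b in ALPHABET}
    for c in chosen:
        for col, nt in enumerate(window10(c)):
            if nt in ALPHABET:
                counts[nt][col] += 1

    freqs = {b: [0.0] * (2 * WINDOW) for b in ALPHABET}
    info = []
    for col in range(2 * WINDOW):
        denom = sum(counts[b][col] for b in ALPHABET)
        h = 0.0
        for b in ALPHABET:
            f = counts[b][col] / denom if denom else 0.0
            freqs[b][col] = f
            if f > 0:
                h -= f * math.log2(f)
        info.append(2.0 - h if denom else 0.0)
    return PositionFrequencyMatrix(
        labels=labels,
        counts=counts,
        frequencies=freqs,
        information=info,
        n_contexts=len(chosen),
    )


def proto_splice_frequency(contexts: Sequence[BoundaryContext]) -> dict:
    """AG|G frequency per (position class x lineage set) stratum + 2x2 test.

    The test compares multiple vs unique positions on AG|G-vs-not counts
    (two-sided Fisher exact, lineage sets pooled); it is skipped when
    either position class is empty.
    """
    from scipy.stats import fisher_exact

    labelled = [c for c in contexts if c.position_klass in {"multiple", "unique"}]
    strata: dict[tuple[str, str | None], dict] = {}
    keys = sorted(
        {(c.position_klass, c.lineage_set_klass) for c in labelled},
        key=lambda t: (t[0], t[1] or ""),
    )
    for key in keys:
        sub = [
            c
            for c in labelled
            if (c.position_klass, c.lineage_set_klass) == key
        ]
        n_proto = sum(1 for c in sub if c.proto_splice)
        strata[key] = {
            "n": len(sub),
            "proto": n_proto,
            "frequency": n_proto / len(sub) if sub else None,
        }

    mult = [c for c in labelled if c.position_klass == "multiple"]
    uniq = [c for c in labelled if c.position_klass == "unique"]
    result: dict = {
        "strata": {
            f"{pk}/{lk or 'all'}": v for (pk, lk), v in strata.items()
        }
    }
    if mult and uniq:
        table = [
            [sum(c.proto_splice for c in mult), sum(not c.proto_splice for c in mult)],
            [sum(c.proto_splice for c in uniq), sum(not c.proto_splice for c in uniq)],
        ]
        odds, p = fisher_exact(table, alternative="two-sided")
        result["fisher_2x2"] = {
            "table": table,
            "odds_ratio": None if math.isinf(odds) else odds,
            "p_value": p,
        }
    else:
        result["fisher_2x2"] = None
    return result


def contexts_to_tsv(contexts: Sequence[BoundaryContext], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tcds_offset\tphase\tklass\tfu\texon_5p\tintron_5p\t"
            "intron_3p\texon_3p\tclipped\tposition_klass\tlineage_set_klass\t"
            "proto_splice\n"
        )
        for c in contexts:
            fh.write(
                f"{c.gene_id}\t{c.cds_offset}\t{c.phase}\t{c.klass or ''}\t"
                f"{c.fu_id or ''}\t{c.exon_5p}\t{c.intron_5p}\t{c.intron_3p}\t"
                f"{c.exon_3p}\t{c.clipped}\t{c.position_klass or ''}\t"
                f"{c.lineage_set_klass or ''}\t{c.proto_splice}\n"
            )
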