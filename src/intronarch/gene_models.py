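"""Gene architectures: exons, functional units, introns, phases and classes.

A molluscan hemocyanin subunit is built from eight paralogous ~50 kDa
functional units (FU-a ... FU-h) preceded by a signal peptide (S).  Each FU
is encoded by one or more exons; the phase-1 intron sitting between
consecutive FU-coding regions, just upstream of the linker-peptide codons,
is the *linker intron*, conserved across molluscs.  Every other intron is an
*internal intron*.  Intron phase is 0, 1 or 2 when the intron falls before
the first, after the first, or after the second nucleotide of a codon —
equivalently ``(coding nucleotides 5' of the intron) mod 3``.

All coordinates in this package are 0-based, half-open, and CDS-forward:
minus-strand annotations are flipped at read time so that downstream code
never sees a strand.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

FU_ORDER = ["S", "a", "b", "c", "d", "e", "f", "g", "h"]

#: slack (nt) around annotated FU boundaries when deciding whether a phase-1
#: intron sits in the inter-FU linker window (2 codons each side)
LINKER_WINDOW_SLACK = 6


class ArchitectureError(ValueError):
    """Raised for malformed or inconsistent gene-structure annotations."""


@dataclass
class ExonSpan:
    """One exon in CDS-forward genomic coordinates (0-based, half-open)."""

    start: int
    end: int
    cds_offset: int  # coding nucleotides preceding this exon
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ArchitectureError(
                f"exon end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FUAnnotation:
    """A functional-unit span in coding-nucleotide offsets.

    Boundaries are recorded as annotated and may split codons.
    """

    fu_id: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.fu_id not in FU_ORDER:
            raise ArchitectureError(f"unknown FU id {self.fu_id!r}")
        if self.cds_end <= self.cds_start:
            raise ArchitectureError(f"empty FU span for {self.fu_id}")


@dataclass
class IntronRecord:
    """A single intron located by its coding-nucleotide offset."""

    cds_offset: int
    phase: int
    klass: str | None = None  # "linker" | "internal" | None (unclassified)
    flanking_fus: tuple[str, ...] = ()
    length: int | None = None
    donor_context: str | None = None
    acceptor_context: str | None = None
    boundary_class: str | None = None  # "canonical" | "gc_ag" | "noncanonical"
    position_id: str | None = None  # homology label when known (simulations)

    def __post_init__(self) -> None:
        if self.phase != self.cds_offset % 3:
            raise ArchitectureError(
                f"phase {self.phase} inconsistent with cds_offset {self.cds_offset}"
            )


@dataclass
class GeneArchitecture:
    """One gene's exon/intron layout with FU sub-annotations."""

    gene_id: str
    species: str = ""
    lineage: str = ""
    full_length: bool = True
    exons: list[ExonSpan] = field(default_factory=list)
    fus: list[FUAnnotation] = field(default_factory=list)
    introns: list[IntronRecord] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def intron_count(self) -> int:
        return len(self.introns)

    def validate(self) -> None:
        exons = self.exons
        if not exons:
            raise ArchitectureError(f"{self.gene_id}: no exons")
        if exons != sorted(exons, key=lambda e: e.cds_offset):
            raise ArchitectureError(f"{self.gene_id}: exons not sorted by cds_offset")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ArchitectureError(f"{self.gene_id}: overlapping exons")
            if b.cds_offset != a.cds_offset + a.length:
                raise ArchitectureError(f"{self.gene_id}: cds_offset not cumulative")
        fus = [f for f in self.fus]
        for a, b in zip(fus, fus[1:]):
            if b.cds_start < a.cds_end:
                raise ArchitectureError(f"{self.gene_id}: overlapping FU spans")
        if len(self.introns) != len(exons) - 1:
            raise ArchitectureError(
                f"{self.gene_id}: {len(self.introns)} introns for {len(exons)} exons"
            )


def compute_phase(cds_offset: int, cds_length: int | None = None) -> int:
    """Phase of an intron after ``cds_offset`` coding nucleotides.

    Phase 0/1/2 = intron before the first / after the first / after the
    second nucleotide of a codon.
    """
    if cds_offset <= 0:
        raise ValueError(f"cds_offset must be positive, got {cds_offset}")
    if cds_length is not None and cds_offset >= cds_length:
        raise ValueError(
            f"cds_offset {cds_offset} not inside CDS of length {cds_length}"
        )
    return cds_offset % 3


def derive_introns(exons: Sequence[ExonSpan]) -> list[IntronRecord]:
    """Introns implied by consecutive exons; length = genomic gap."""
    introns = []
    for a, b in zip(exons, exons[1:]):
        off = b.cds_offset
        introns.append(
            IntronRecord(
                cds_offset=off,
                phase=off % 3,
                length=b.start - a.end,
            )
        )
    return introns


def classify_introns(arch: GeneArchitecture) -> tuple[GeneArchitecture, dict]:
    """Label each intron as linker or internal.

    An intron is a linker intron iff it is phase 1 *and* its cds_offset lies
    in the window ``[FU_n.cds_end - 6, FU_{n+1}.cds_start + 6]`` for a pair
    of consecutive FUs (signal peptide excluded).  At most one linker is
    accepted per FU pair — the candidate nearest the downstream FU start;
    the rest stay internal.  A non-phase-1 intron inside an inter-FU window
    is classified internal with a warning, never silently linker.
    """
    fus = [f for f in arch.fus if f.fu_id != "S"]
    fus = sorted(fus, key=lambda f: f.cds_start)
    if not arch.fus:
        raise ArchitectureError(f"{arch.gene_id}: FU annotations required")

    new_introns = [replace(i, klass="internal", flanking_fus=()) for i in arch.introns]

    for up, down in zip(fus, fus[1:]):
        lo = up.cds_end - LINKER_WINDOW_SLACK
        hi = down.cds_start + LINKER_WINDOW_SLACK
        candidates = []
        for idx, intr in enumerate(new_introns):
            if lo <= intr.cds_offset <= hi:
                if intr.phase == 1:
                    candidates.append(idx)
                else:
                    warnings.warn(
                        f"{arch.gene_id}: intron at {intr.cds_offset} lies in the "
                        f"{up.fu_id}-{down.fu_id} linker window but has phase "
                        f"{intr.phase}; classified internal"
                    )
        if candidates:
            best = min(
                candidates,
                key=lambda i: (abs(new_introns[i].cds_offset - down.cds_start), i),
            )
            new_introns[best] = replace(
                new_introns[best],
                klass="linker",
                flanking_fus=(up.fu_id, down.fu_id),
            )

    # attach hosting FU for internal introns
    for idx, intr in enumerate(new_introns):
        if intr.klass == "internal":
            host = [
                f.fu_id
                for f in arch.fus
                if f.cds_start < intr.cds_offset < f.cds_end
            ]
            new_introns[idx] = replace(intr, flanking_fus=tuple(host[:1]))

    out = replace(arch, introns=new_introns)
    counts = {
        "linker_count": sum(1 for i in new_introns if i.klass == "linker"),
        "internal_count": sum(1 for i in new_introns if i.klass == "internal"),
    }
    return out, counts


def _lower_median(values: Sequence[int]) -> int:
    """Median as the lower middle element for even-sized samples."""
    s = sorted(values)
    if not s:
        raise ValueError("median of empty sequence")
    return s[(len(s) - 1) // 2]


def architecture_statistics(archs: Sequence[GeneArchitecture]) -> dict:
    """Descriptive statistics over a set of classified architectures.

    Phase fractions are computed over internal introns only and reported
    both raw and rounded to the nearest integer percent.  Exon lengths are
    in nucleotides; the median is the lower middle value for even counts.
    """
    if not archs:
        raise ValueError("architecture_statistics needs at least one architecture")

    exon_lengths: list[int] = []
    phase_counts = {0: 0, 1: 0, 2: 0}
    per_gene: dict[str, dict] = {}
    per_fu_exons: dict[str, list[int]] = {}

    for arch in archs:
        exon_lengths.extend(e.length for e in arch.exons)
        linker = sum(1 for i in arch.introns if i.klass == "linker")
        internal = sum(1 for i in arch.introns if i.klass == "internal")
        per_gene[arch.gene_id] = {
            "total_introns": len(arch.introns),
            "linker": linker,
            "internal": internal,
            "exons": len(arch.exons),
        }
        for i in arch.introns:
            if i.klass == "internal":
                phase_counts[i.phase] += 1
        for fu in arch.fus:
            n_int = sum(
                1
                for i in arch.introns
                if i.klass == "internal" and fu.cds_start < i.cds_offset < fu.cds_end
            )
            per_fu_exons.setdefault(fu.fu_id, []).append(n_int + 1)

    n_internal = sum(phase_counts.values())
    if n_internal:
        raw = {p: 100.0 * c / n_internal for p, c in phase_counts.items()}
    else:
        raw = {p: float("nan") for p in phase_counts}
    return {
        "per_gene": per_gene,
        "per_fu_exon_counts": per_fu_exons,
        "exon_length_min": min(exon_lengths),
        "exon_length_max": max(exon_lengths),
        "exon_length_median": _lower_median(exon_lengths),
        "phase_counts": dict(phase_counts),
        "phase_fractions_raw": raw,
        "phase_fractions_pct": {p: round(v) for p, v in raw.items()}
        if n_internal
        else {},
        "n_internal_introns": n_internal,
    }


# ---------------------------------------------------------------------------
# readers


def _flip_interval(start: int, end: int, seqlen: int) -> tuple[int, int]:
    return seqlen - end, seqlen - start


def read_architecture(
    path: str | Path,
    fmt: str | None = None,
    *,
    fasta: str | Path | None = None,
    fu_table: str | Path | None = None,
    gene_id: str | None = None,
    species: str = "",
    lineage: str = "",
) -> GeneArchitecture:
    """Read one annotated gene structure from GenBank or GFF3(+FASTA).

    The file must contain exactly one gene whose CDS is a join of >= 1
    segments.  FU spans are taken from ``misc_feature`` notes (GenBank),
    ``region`` features (GFF3), or a sidecar TSV (columns fu_id, cds_start,
    cds_end).  Output coordinates are CDS-forward 0-based half-open; introns
    are derived and classified when FU annotations are present.
    """
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "gff3"

    if fmt == "genbank":
        arch = _read_genbank(path, gene_id=gene_id, species=species, lineage=lineage)
    elif fmt == "gff3":
        arch = _read_gff3(path, gene_id=gene_id, species=species, lineage=lineage)
    else:
        raise ArchitectureError(f"unknown format {fmt!r}")

    if fu_table is not None:
        df = pd.read_csv(fu_table, sep="\t")
        arch.fus = [
            FUAnnotation(str(r.fu_id), int(r.cds_start), int(r.cds_end))
            for r in df.itertuples()
        ]
    arch.introns = derive_introns(arch.exons)
    arch.validate()
    if arch.fus:
        arch, _ = classify_introns(arch)
    return arch


def _segments_to_exons(
    segments: list[tuple[int, int]], strand: int, seqlen: int
) -> list[ExonSpan]:
    if strand < 0:
        segments = [_flip_interval(s, e, seqlen) for (s, e) in segments]
    segments = sorted(segments)
    for (s1, e1), (s2, e2) in zip(segments, segments[1:]):
        if s2 < e1:
            raise ArchitectureError("overlapping exon segments")
    exons, off = [], 0
    for s, e in segments:
        exons.append(ExonSpan(start=s, end=e, cds_offset=off))
        off += e - s
    return exons


def _read_genbank(path: Path, gene_id, species, lineage) -> GeneArchitecture:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "genbank"), None)
    if record is None:
        raise ArchitectureError(f"{path}: empty GenBank file")
    cds = [f for f in record.features if f.type == "CDS"]
    if len(cds) != 1:
        raise ArchitectureError(f"{path}: expected exactly one CDS, found {len(cds)}")
    feat = cds[0]
    strand = feat.location.strand or 1
    seqlen = len(record.seq)
    segments = [(int(p.start), int(p.end)) for p in feat.location.parts]
    exons = _segments_to_exons(segments, strand, seqlen)

    genomic_to_cds = _GenomicCdsMap(exons)
    fus = []
    for f in record.features:
        if f.type != "misc_feature":
            continue
        note = " ".join(f.qualifiers.get("note", []))
        fu_id = _parse_fu_note(note)
        if fu_id is None:
            continue
        s, e = int(f.location.start), int(f.location.end)
        if strand < 0:
            s, e = _flip_interval(s, e, seqlen)
        fus.append(
            FUAnnotation(fu_id, genomic_to_cds(s), genomic_to_cds(e - 1) + 1)
        )
    fus.sort(key=lambda f: f.cds_start)
    return GeneArchitecture(
        gene_id=gene_id or record.id,
        species=species or record.annotations.get("organism", ""),
        lineage=lineage,
        exons=exons,
        fus=fus,
    )


def _parse_fu_note(note: str) -> str | None:
    note = note.strip()
    low = note.lower()
    if "signal" in low:
        return "S"
    if low.startswith("fu-") and len(note) >= 4:
        cand = note[3]
        if cand in FU_ORDER:
            return cand
    return None


class _GenomicCdsMap:
    """Map CDS-forward genomic coordinates to coding-nucleotide offsets."""

    def __init__(self, exons: Sequence[ExonSpan]):
        self.exons = exons

    def __call__(self, pos: int) -> int:
        for e in self.exons:
            if e.start <= pos < e.end:
                return e.cds_offset + (pos - e.start)
        raise ArchitectureError(f"genomic position {pos} not exonic")


def _read_gff3(path: Path, gene_id, species, lineage) -> GeneArchitecture:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    cds_feats = list(db.features_of_type("CDS"))
    if not cds_feats:
        raise ArchitectureError(f"{path}: no CDS features")
    strand = -1 if cds_feats[0].strand == "-" else 1
    seqlen = None
    for d in db.directives:
        if d.startswith("sequence-region"):
            seqlen = int(d.split()[-1])
    if seqlen is None:
        seqlen = max(f.end for f in db.all_features())
    # GFF3 is 1-based inclusive
    segments = [(f.start - 1, f.end) for f in cds_feats]
    exons = _segments_to_exons(segments, strand, seqlen)

    genomic_to_cds = _GenomicCdsMap(exons)
    fus = []
    for f in db.features_of_type("region"):
        name = (f.attributes.get("Name") or [""])[0]
        fu_id = _parse_fu_note(name if name.lower().startswith("fu-") else "fu-" + name)
        if name.lower().startswith("signal"):
            fu_id = "S"
        if fu_id is None:
            continue
        s, e = f.start - 1, f.end
        if strand < 0:
            s, e = _flip_interval(s, e, seqlen)
        fus.append(FUAnnotation(fu_id, genomic_to_cds(s), genomic_to_cds(e - 1) + 1))
    fus.sort(key=lambda f: f.cds_start)

    gid = gene_id
    if gid is None:
        genes = list(db.features_of_type("gene"))
        gid = genes[0].id if genes else cds_feats[0].id
    return GeneArchitecture(
        gene_id=gid, species=species, lineage=lineage, exons=exons, fus=fus
    )


# ---------------------------------------------------------------------------
# writers


def architecture_to_frame(archs: Iterable[GeneArchitecture]) -> pd.DataFrame:
    rows = []
    for arch in archs:
        for i, exon in enumerate(arch.exons):
            rows.append(
                {
                    "gene_id": arch.gene_id,
                    "species": arch.species,
                    "lineage": arch.lineage,
                    "record": "exon",
                    "index": i,
                    "start": exon.start,
                    "end": exon.end,
                    "cds_offset": exon.cds_offset,
                    "phase": "",
                    "klass": "",
                    "low_confidence": exon.low_confidence,
                }
            )
        for i, intr in enumerate(arch.introns):
            rows.append(
                {
                    "gene_id": arch.gene_id,
                    "species": arch.species,
                    "lineage": arch.lineage,
                    "record": "intron",
                    "index": i,
                    "start": "",
                    "end": "",
                    "cds_offset": intr.cds_offset,
                    "phase": intr.phase,
                    "klass": intr.klass or "",
                    "low_confidence": "",
                }
            )
    return pd.DataFrame(rows)


def write_architecture_tsv(archs: Iterable[GeneArchitecture], path: str | Path) -> None:
    architecture_to_frame(archs).to_csv(path, sep="\t", index=False)


def write_architecture_json(arch: GeneArchitecture, path: str | Path) -> None:
    doc = {
        "gene_id": arch.gene_id,
        "species": arch.species,
        "lineage": arch.lineage,
        "full_length": arch.full_length,
        "exons": [
            {
                "start": e.start,
                "end": e.end,
                "cds_offset": e.cds_offset,
                "low_confidence": e.low_confidence,
            }
            for e in arch.exons
        ],
        "fus": [
            {"fu_id": f.fu_id, "cds_start": f.cds_start, "cds_end": f.cds_end}
            for f in arch.fus
        ],
        "introns": [
            {
                "cds_offset": i.cds_offset,
                "phase": i.phase,
                "klass": i.klass,
                "length": i.length,
                "position_id": i.position_id,
            }
            for i in arch.introns
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))
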