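"""Project splice sites of all genes into one functional-unit overlay.

All internal introns are mapped into a shared coordinate system — an
alignment of FU peptides — so that splice sites from different FUs and
different lineages can be compared at homologous positions.  A position is
the pair (alignment column of the hosting codon, intron phase).  Positions
carrying introns from two or more distinct FUs or lineages are *multiple*;
positions seen exactly once are *unique*.  A position shared at the same
FU across different lineages is an *ortholog* position (candidate common
descent rather than paralogous duplication).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .gene_models import GeneArchitecture

RowKey = tuple[str, str]  # (gene_id, fu_id)


@dataclass
class FUPeptide:
    gene_id: str
    fu_id: str
    seq: str
    codon_start_offset: int  # CDS offset of the first translated codon
    truncated: bool = False


@dataclass
class FUAlignment:
    rows: dict[RowKey, str]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("ragged alignment: rows differ in length")
        self.width = lengths.pop() if lengths else 0
        self._maps: dict[RowKey, list[int]] = {}
        for key, row in self.rows.items():
            self._maps[key] = [i for i, ch in enumerate(row) if ch != "-"]

    def column_of(self, key: RowKey, residue_index: int) -> int:
        m = self._maps[key]
        if residue_index >= len(m):
            return m[-1]
        return m[residue_index]

    def n_residues(self, key: RowKey) -> int:
        return len(self._maps[key])


@dataclass
class SplicePlacement:
    gene_id: str
    lineage: str
    fu_id: str
    column: int
    phase: int
    cds_offset: int  # original coordinate, kept for joining back to introns


@dataclass
class PositionGroup:
    key: tuple[int, int]  # (column, phase)
    members: list[SplicePlacement]
    klass: str  # "unique" | "multiple"
    ortholog: bool


# ---------------------------------------------------------------------------
# FU peptide extraction


def extract_fu_peptides(
    arch: GeneArchitecture, cdna: str, *, include_signal: bool = False
) -> list[FUPeptide]:
    """Translate each annotated FU span of one gene.

    Spans starting mid-codon are translated from the next codon boundary
    (the recorded ``codon_start_offset`` keeps the projection consistent);
    an internal stop truncates the peptide with a warning.
    """
    from Bio.Seq import Seq

    peptides = []
    for fu in arch.fus:
        if fu.fu_id == "S" and not include_signal:
            continue
        codon_start = ((fu.cds_start + 2) // 3) * 3
        codon_end = (fu.cds_end // 3) * 3
        if codon_end <= codon_start:
            continue
        pep = str(Seq(cdna[codon_start:codon_end]).translate())
        truncated = False
        if "*" in pep:
            warnings.warn(
                f"{arch.gene_id} FU-{fu.fu_id}: internal stop codon; truncating"
            )
            pep = pep[: pep.index("*")]
            truncated = True
        peptides.append(
            FUPeptide(
                gene_id=arch.gene_id,
                fu_id=fu.fu_id,
                seq=pep,
                codon_start_offset=codon_start,
                truncated=truncated,
            )
        )
    return peptides


# ---------------------------------------------------------------------------
# alignment


def _pairwise_blocks(ref: str, seq: str):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    aln = aligner.align(ref, seq)[0]
    return aln.aligned  # (ref_blocks, seq_blocks)


def align_fus(
    peptides: Sequence[FUPeptide] | Mapping[RowKey, str] | None = None,
    *,
    external: str | Path | None = None,
) -> FUAlignment:
    """Deterministic star alignment of FU peptides.

    The reference is the lexicographically first row key; every other
    sequence is globally aligned to it (BLOSUM62, gap open -11 / extend -1)
    and the pairwise alignments are merged on reference coordinates.
    Alternatively ingests an aligned FASTA (row ids ``gene_id|fu_id``) and
    validates row lengths.
    """
    if external is not None:
        from Bio import SeqIO

        rows: dict[RowKey, str] = {}
        for rec in SeqIO.parse(str(external), "fasta"):
            if "|" not in rec.id:
                raise ValueError(f"alignment row id {rec.id!r} not gene_id|fu_id")
            gene_id, fu_id = rec.id.split("|", 1)
            rows[(gene_id, fu_id)] = str(rec.seq).upper()
        return FUAlignment(rows=rows)

    if isinstance(peptides, Mapping):
        seqs = dict(peptides)
    else:
        seqs = {(p.gene_id, p.fu_id): p.seq for p in peptides}
    if len(seqs) < 2:
        raise ValueError("alignment needs at least two peptides")
    keys = sorted(seqs)
    ref_key, other_keys = keys[0], keys[1:]
    ref = seqs[ref_key]

    # per sequence: insertions before each ref residue index + aligned pairs
    ins_before: dict[RowKey, dict[int, list[int]]] = {}
    pair_map: dict[RowKey, dict[int, int]] = {}
    for key in other_keys:
        seq = seqs[key]
        ref_blocks, seq_blocks = _pairwise_blocks(ref, seq)
        ins: dict[int, list[int]] = {}
        pairs: dict[int, int] = {}
        prev_r = prev_s = 0
        for (rs, re), (ss, se) in zip(ref_blocks, seq_blocks):
            if ss > prev_s:
                ins.setdefault(rs, []).extend(range(prev_s, ss))
            for k in range(re - rs):
                pairs[rs + k] = ss + k
            prev_r, prev_s = re, se
        if len(seq) > prev_s:
            ins.setdefault(len(ref), []).extend(range(prev_s, len(seq)))
        ins_before[key] = ins
        pair_map[key] = pairs

    max_ins = [0] * (len(ref) + 1)
    for key in other_keys:
        for r, residues in ins_before[key].items():
            max_ins[r] = max(max_ins[r], len(residues))

    rows = {}
    for key in keys:
        out = []
        if key == ref_key:
            for r in range(len(ref) + 1):
                out.append("-" * max_ins[r])
                if r < len(ref):
                    out.append(ref[r])
        else:
            seq = seqs[key]
            ins = ins_before[key]
            pairs = pair_map[key]
            for r in range(len(ref) + 1):
                residues = ins.get(r, [])
                chunk = "".join(seq[i] for i in residues)
                out.append(chunk + "-" * (max_ins[r] - len(residues)))
                if r < len(ref):
                    out.append(seq[pairs[r]] if r in pairs else "-")
        rows[key] = "".join(out)
    return FUAlignment(rows=rows)


# ---------------------------------------------------------------------------
# projection & classification


def project_splice_sites(
    archs: Sequence[GeneArchitecture],
    alignment: FUAlignment,
    peptides: Sequence[FUPeptide] | None = None,
    *,
    one_per_lineage: bool = True,
) -> list[SplicePlacement]:
    """Project every internal intron into (alignment column, phase) space.

    The hosting residue is ``floor((cds_offset - fu_codon_start)/3)``; the
    column comes from the row's residue->column map.  Introns outside any
    annotated FU span or without an alignment row are skipped with a
    warning.  With ``one_per_lineage`` (the default) a single representative
    architecture per lineage contributes, mirroring a per-lineage-structure
    overlay; pass False to count every gene.
    """
    codon_starts: dict[RowKey, int] = {}
    if peptides is not None:
        codon_starts = {(p.gene_id, p.fu_id): p.codon_start_offset for p in peptides}

    chosen: list[GeneArchitecture] = []
    if one_per_lineage:
        seen: dict[str, str] = {}
        for arch in sorted(archs, key=lambda a: a.gene_id):
            if arch.lineage not in seen:
                seen[arch.lineage] = arch.gene_id
                chosen.append(arch)
    else:
        chosen = list(archs)

    placements: list[SplicePlacement] = []
    for arch in chosen:
        for intr in arch.introns:
            if intr.klass != "internal":
                continue
            host = next(
                (
                    f
                    for f in arch.fus
                    if f.fu_id != "S"
                    and f.cds_start < intr.cds_offset < f.cds_end
                ),
                None,
            )
            if host is None:
                warnings.warn(
                    f"{arch.gene_id}: internal intron at {intr.cds_offset} "
                    "outside any FU span; skipped"
                )
                continue
            key = (arch.gene_id, host.fu_id)
            if key not in alignment.rows:
                warnings.warn(f"{arch.gene_id}: no alignment row for FU-{host.fu_id}")
                continue
            codon_start = codon_starts.get(
                key, ((host.cds_start + 2) // 3) * 3
            )
            residue = (intr.cds_offset - codon_start) // 3
            residue = max(residue, 0)
            placements.append(
                SplicePlacement(
                    gene_id=arch.gene_id,
                    lineage=arch.lineage,
                    fu_id=host.fu_id,
                    column=alignment.column_of(key, residue),
                    phase=intr.phase,
                    cds_offset=intr.cds_offset,
                )
            )
    return placements


def classify_positions(
    placements: Sequence[SplicePlacement],
    *,
    count: str = "placements",
    column_tolerance: int = 0,
) -> tuple[list[PositionGroup], dict]:
    """Partition placements by (column, phase) and classify positions.

    A group is *multiple* iff its members span >= 2 distinct FUs or >= 2
    distinct lineages; *ortholog* iff >= 2 members share an FU but differ in
    lineage.  Fractions are over placements (default) or over groups.  With
    ``column_tolerance`` > 0 groups whose columns differ by at most that
    many columns (same phase) are merged — off by default; intron sliding
    should be reported, not merged.
    """
    if count not in {"placements", "groups"}:
        raise ValueError("count must be 'placements' or 'groups'")
    buckets: dict[tuple[int, int], list[SplicePlacement]] = {}
    for p in placements:
        buckets.setdefault((p.column, p.phase), []).append(p)

    if column_tolerance > 0:
        merged: dict[tuple[int, int], list[SplicePlacement]] = {}
        for (col, phase) in sorted(buckets):
            target = None
            for (mc, mp) in merged:
                if mp == phase and abs(mc - col) <= column_tolerance:
                    target = (mc, mp)
                    break
            if target is None:
                merged[(col, phase)] = list(buckets[(col, phase)])
            else:
                merged[target].extend(buckets[(col, phase)])
        buckets = merged

    groups = []
    for key in sorted(buckets):
        members = buckets[key]
        fus = {m.fu_id for m in members}
        lineages = {m.lineage for m in members}
        multiple = len(fus) >= 2 or len(lineages) >= 2
        ortholog = any(
            len({m.lineage for m in members if m.fu_id == fu}) >= 2 for fu in fus
        )
        groups.append(
            PositionGroup(
                key=key,
                members=members,
                klass="multiple" if multiple else "unique",
                ortholog=ortholog,
            )
        )

    if count == "placements":
        denom = sum(len(g.members) for g in groups)
        n_multiple = sum(len(g.members) for g in groups if g.klass == "multiple")
    else:
        denom = len(groups)
        n_multiple = sum(1 for g in groups if g.klass == "multiple")
    if denom:
        raw_multiple = 100.0 * n_multiple / denom
        raw_unique = 100.0 * (denom - n_multiple) / denom
    else:
        raw_multiple = raw_unique = float("nan")
    summary = {
        "n_placements": len(placements),
        "n_groups": len(groups),
        "counting": count,
        "multiple_raw_pct": raw_multiple,
        "unique_raw_pct": raw_unique,
        "multiple_pct": round(raw_multiple) if denom else None,
        "unique_pct": round(raw_unique) if denom else None,
        "ortholog_groups": [g.key for g in groups if g.ortholog],
    }
    return groups, summary


def placements_to_tsv(
    groups: Sequence[PositionGroup], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlineage\tfu\tcolumn\tphase\tcds_offset\tklass\tortholog\n")
        for g in groups:
            for m in g.members:
                fh.write(
                    f"{m.gene_id}\t{m.lineage}\t{m.fu_id}\t{m.column}\t{m.phase}\t"
                    f"{m.cds_offset}\t{g.klass}\t{g.ortholog}\n"
                )


def write_alignment_fasta(alignment: FUAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (gene_id, fu_id), row in sorted(alignment.rows.items()):
            fh.write(f">{gene_id}|{fu_id}\n{row}\n")
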