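"""Infer an exon-intron architecture from a cDNA and a genomic sequence.

Deterministic seed-and-chain spliced alignment at desk scale: exact k-mer
anchors between cDNA and genomic sequence are merged into maximal exact
blocks, chained by sparse dynamic programming (maximal cDNA coverage;
diagonal jumps are introns and must respect the intron length bounds), and
each exon junction is then refined within the sequence-ambiguous window so
that the intron boundary pair is GT..AG where possible, GC..AG as a flagged
minor alternative, otherwise flagged noncanonical.

Exon content is reported in cDNA coordinates, so for a complete inference
the concatenated exon sequences equal the input cDNA by construction.
Genomic N runs are treated as wildcards during extension and the affected
exons are flagged ``low_confidence``.  cDNA intervals that cannot be placed
are returned as explicit gap records, never silently dropped.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .gene_models import ExonSpan, GeneArchitecture, derive_introns

# fixed splice-consensus weight tables used only for tie-breaking between
# equally sequence-consistent canonical placements
DONOR_CONSENSUS = (("G", 3), ("T", 3), ("A", 1), ("A", 1), ("G", 1))
ACCEPTOR_CONSENSUS = (("Y", 1), ("A", 3), ("G", 3))  # last 3 intronic nt


@dataclass
class InferenceParams:
    seed_k: int = 20
    min_intron_len: int = 30
    max_intron_len: int = 50_000
    boundary_shift_window: int = 12
    allow_gc_ag: bool = True

    def __post_init__(self) -> None:
        if min(self.seed_k, self.min_intron_len, self.max_intron_len,
               self.boundary_shift_window) <= 0:
            raise ValueError("all parameters must be positive")
        if self.min_intron_len >= self.max_intron_len:
            raise ValueError("min_intron_len must be below max_intron_len")


@dataclass
class Anchor:
    """Maximal exact-match block between cDNA and genomic sequence."""

    cdna_start: int
    genomic_start: int
    length: int

    @property
    def diag(self) -> int:
        return self.genomic_start - self.cdna_start

    @property
    def cdna_end(self) -> int:
        return self.cdna_start + self.length


@dataclass
class InferenceResult:
    architecture: GeneArchitecture
    complete: bool
    gaps: list[tuple[int, int]] = field(default_factory=list)  # uncovered cDNA
    exon_confidence: list[float] = field(default_factory=list)
    boundary_classes: list[str] = field(default_factory=list)


def _match(c: str, g: str) -> bool:
    return c == g or g == "N"


def _build_anchors(cdna: str, genomic: str, k: int) -> list[Anchor]:
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(genomic) - k + 1):
        kmer = genomic[j : j + k]
        if "N" not in kmer:
            index[kmer].append(j)
    by_diag: dict[int, list[int]] = defaultdict(list)
    for i in range(len(cdna) - k + 1):
        for j in index.get(cdna[i : i + k], ()):
            by_diag[j - i].append(i)
    anchors = []
    for d, iis in by_diag.items():
        iis.sort()
        start = prev = iis[0]
        for i in iis[1:]:
            if i == prev + 1:
                prev = i
            else:
                anchors.append(Anchor(start, start + d, prev + k - start))
                start = prev = i
        anchors.append(Anchor(start, start + d, prev + k - start))
    anchors.sort(key=lambda a: (a.cdna_start, a.genomic_start))
    return anchors


def _chain(anchors: list[Anchor], params: InferenceParams) -> list[Anchor]:
    """Max-coverage colinear chain; intron jumps must fit the length bounds."""
    n = len(anchors)
    if n == 0:
        return []
    score = [0.0] * n
    back = [-1] * n
    for b in range(n):
        B = anchors[b]
        score[b] = float(B.length)
        for a in range(b):
            A = anchors[a]
            if B.cdna_start < A.cdna_start:
                continue
            jump = B.diag - A.diag
            if jump < 0:
                continue
            if jump > 0 and not (
                params.min_intron_len <= jump <= params.max_intron_len
            ):
                continue
            if jump == 0 and B.cdna_start <= A.cdna_end:
                continue  # contiguous same-diagonal runs were merged already
            new_cov = max(0, B.cdna_end - max(B.cdna_start, A.cdna_end))
            cand = score[a] + new_cov - (1e-6 if jump > 0 else 0.0)
            if cand > score[b] + 1e-12:
                score[b] = cand
                back[b] = a
    best = max(range(n), key=lambda b: (score[b], -anchors[b].cdna_start))
    chain = []
    while best != -1:
        chain.append(anchors[best])
        best = back[best]
    return chain[::-1]


def _score_consensus(intron: str) -> int:
    s = 0
    for (base, w), nt in zip(DONOR_CONSENSUS, intron[:5]):
        if base == nt or (base == "Y" and nt in "CT"):
            s += w
    for (base, w), nt in zip(ACCEPTOR_CONSENSUS, intron[-3:]):
        if base == nt or (base == "Y" and nt in "CT"):
            s += w
    return s


def _boundary_rank(intron: str, allow_gc_ag: bool) -> int:
    if intron[:2] == "GT" and intron[-2:] == "AG":
        return 0
    if allow_gc_ag and intron[:2] == "GC" and intron[-2:] == "AG":
        return 1
    return 2


def refine_boundary(
    cdna: str,
    genomic: str,
    split_lo: int,
    split_hi: int,
    diag_left: int,
    diag_right: int,
    params: InferenceParams,
) -> tuple[int, str]:
    """Choose the exon/intron split among sequence-consistent placements.

    ``split_lo..split_hi`` (inclusive) is the cDNA range over which the
    junction can slide without changing the spliced product.  Preference:
    GT..AG, then GC..AG (if allowed), then noncanonical; ties broken by the
    fixed donor/acceptor consensus score, then by the leftmost donor.
    Returns (split, boundary_class).
    """
    best: tuple[int, int, int] | None = None  # (rank, -consensus, split)
    for s in range(split_lo, split_hi + 1):
        intron = genomic[s + diag_left : s + diag_right]
        if len(intron) < 4:
            continue
        rank = _boundary_rank(intron, params.allow_gc_ag)
        key = (rank, -_score_consensus(intron), s)
        if best is None or key < best:
            best = key
    if best is None:
        return split_hi, "noncanonical"
    rank = best[0]
    klass = ("canonical", "gc_ag", "noncanonical")[rank]
    return best[2], klass


def infer_architecture(
    cdna: str,
    genomic: str,
    params: InferenceParams | None = None,
    *,
    gene_id: str = "inferred",
    species: str = "",
    lineage: str = "",
) -> InferenceResult:
    """Infer the exon-intron architecture placing ``cdna`` in ``genomic``.

    Deterministic for fixed inputs and parameters.  The locus must be on
    the forward strand (the caller reverse-complements if needed).
    """
    params = params or InferenceParams()
    cdna = cdna.upper()
    genomic = genomic.upper()
    if len(cdna) < 3:
        raise ValueError("cDNA must be at least 3 nt")

    anchors = _build_anchors(cdna, genomic, params.seed_k)
    chain = _chain(anchors, params)
    if not chain:
        return InferenceResult(
            architecture=GeneArchitecture(
                gene_id=gene_id, species=species, lineage=lineage, exons=[]
            ),
            complete=False,
            gaps=[(0, len(cdna))],
        )

    # merge chained anchors on the same diagonal into segments
    segments: list[list[int]] = []  # [i_start, i_end, diag]
    for a in chain:
        if segments and a.diag == segments[-1][2]:
            segments[-1][1] = a.cdna_end
        else:
            segments.append([a.cdna_start, a.cdna_end, a.diag])

    gaps: list[tuple[int, int]] = []

    # head: extend the first segment back toward cDNA position 0
    i0, _, d0 = segments[0]
    while i0 > 0 and i0 + d0 > 0 and _match(cdna[i0 - 1], genomic[i0 - 1 + d0]):
        i0 -= 1
    segments[0][0] = i0
    if i0 > 0:
        gaps.append((0, i0))

    # tail: extend the last segment to the cDNA end
    _, e_last, d_last = segments[-1]
    while (
        e_last < len(cdna)
        and e_last + d_last < len(genomic)
        and _match(cdna[e_last], genomic[e_last + d_last])
    ):
        e_last += 1
    segments[-1][1] = e_last
    if e_last < len(cdna):
        gaps.append((e_last, len(cdna)))

    # resolve each junction
    splits: list[int] = []
    boundary_classes: list[str] = []
    for (s1, e1, d1), (s2, e2, d2) in zip(segments, segments[1:]):
        # maximal N-tolerant extension on both diagonals
        a_end = e1
        while a_end < len(cdna) and a_end + d1 < len(genomic) and _match(
            cdna[a_end], genomic[a_end + d1]
        ):
            a_end += 1
        b_start = s2
        while b_start > 0 and b_start + d2 > 0 and _match(
            cdna[b_start - 1], genomic[b_start - 1 + d2]
        ):
            b_start -= 1
        if b_start > a_end:
            # uncovered cDNA between the exons: record the gap, keep the
            # anchor-maximal boundaries
            gaps.append((a_end, b_start))
            splits.append(a_end)
            boundary_classes.append("unknown")
            # the right exon will start at b_start via a synthetic split —
            # encode by a second split entry handled below
            splits.append(b_start)
            boundary_classes.append("unknown")
            continue
        lo = max(b_start, a_end - params.boundary_shift_window)
        hi = min(a_end, b_start + params.boundary_shift_window)
        if lo > hi:
            lo, hi = b_start, a_end
        split, klass = refine_boundary(cdna, genomic, lo, hi, d1, d2, params)
        splits.append(split)
        boundary_classes.append(klass)

    # build exons; junction t sits between segment t and t+1
    exons: list[ExonSpan] = []
    diag_per_exon: list[int] = []
    bounds: list[tuple[int, int]] = []  # cDNA (start, end) per exon
    cursor = segments[0][0]
    si = 0
    j = 0
    seg_diags = [s[2] for s in segments]
    # reconstruct exon intervals from splits: for the unknown-gap case two
    # split entries delimit the uncovered region
    exon_starts = [segments[0][0]]
    exon_diags = [seg_diags[0]]
    exon_ends: list[int] = []
    k = 0
    for idx in range(len(segments) - 1):
        if boundary_classes[k] == "unknown":
            exon_ends.append(splits[k])
            exon_starts.append(splits[k + 1])
            exon_diags.append(seg_diags[idx + 1])
            k += 2
        else:
            exon_ends.append(splits[k])
            exon_starts.append(splits[k])
            exon_diags.append(seg_diags[idx + 1])
            k += 1
    exon_ends.append(segments[-1][1])

    confidences: list[float] = []
    for (cs, ce, d) in zip(exon_starts, exon_ends, exon_diags):
        if ce <= cs:
            raise RuntimeError("degenerate exon during inference")
        gslice = genomic[cs + d : ce + d]
        n_frac = gslice.count("N") / len(gslice)
        mismatches = sum(
            1 for a, b in zip(cdna[cs:ce], gslice) if not _match(a, b)
        )
        exons.append(
            ExonSpan(
                start=cs + d,
                end=ce + d,
                cds_offset=cs,
                low_confidence=(n_frac > 0.0),
            )
        )
        confidences.append(1.0 - n_frac - mismatches / len(gslice))

    complete = not gaps
    arch = GeneArchitecture(
        gene_id=gene_id, species=species, lineage=lineage, exons=exons
    )
    if complete:
        arch.introns = derive_introns(exons)
        # note: exon cds_offset is cDNA position, so derive_introns offsets
        # are correct; attach boundary classes (unknown-gap entries collapse)
        jclasses = [c for c in boundary_classes if c != "unknown"]
        for intr, klass in zip(arch.introns, jclasses):
            intr.boundary_class = klass
        arch.validate()
    else:
        arch.introns = []
    return InferenceResult(
        architecture=arch,
        complete=complete,
        gaps=sorted(gaps),
        exon_confidence=confidences,
        boundary_classes=boundary_classes,
    )
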