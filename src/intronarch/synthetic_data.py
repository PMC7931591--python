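"""Seeded simulator of multi-FU gene-family evolution with intron gain/loss.

The generative model mirrors the architecture of molluscan hemocyanin
genes: a signal peptide followed by eight tandem-duplicated functional
units (FUs), with an immortal phase-1 linker intron between consecutive
FUs and lineage-variable internal introns gained and lost along a species
tree.  The eight FU copies derive from one ancestral FU by per-copy
nucleotide substitutions applied once at setup (the duplication history);
no along-tree substitution model and no exonic indels are simulated, so
homology labels stay exact.

Internal-intron gains are Poisson events per FU per unit branch length at
uniformly sampled coding offsets inside the FU, up-weighted by a factor
``w >= 1`` at proto-splice sites (exon context AG|G); losses remove an
existing internal intron.  Introns start with GT (rarely GC, per
``canonical_prob``) and end with AG, with lognormal lengths truncated at a
minimum.  Every emitted leaf gene comes with its cDNA, genomic sequence,
exact architecture, per-intron homology labels and the full event log, so
that downstream modules can be tested against known truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gene_models import (
    ExonSpan,
    FUAnnotation,
    GeneArchitecture,
    IntronRecord,
    classify_introns,
)
from .parsimony import DEFAULT_TREE_NEWICK, LineageTree, TreeNode

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"

#: default distance (nt) gains keep from existing introns and FU edges so
#: that no pathologically short exon arises (observed real exon minimum ~97)
DEFAULT_GAIN_SPACING = 30


@dataclass
class SimulationConfig:
    tree_newick: str = DEFAULT_TREE_NEWICK
    fu_count: int = 8
    fu_len_codons: int = 150
    signal_codons: int = 20
    fu_divergence: float = 0.15  # per-site substitution prob per FU copy
    gain_rate: float = 1.0  # gains per FU per unit branch length
    loss_rate: float = 0.1  # loss rate per intron per unit branch length
    proto_site_preference: float = 1.0  # weight w at AG|G positions
    canonical_prob: float = 0.993  # GT donor; else GC
    intron_meanlog: float = 5.9
    intron_sdlog: float = 0.7
    intron_min_len: int = 118
    unique_gain_positions: bool = False  # no two gains share an FU-relative offset
    linker_introns_immortal: bool = True
    boundary_shift_window: int = 12
    min_gain_spacing: int = DEFAULT_GAIN_SPACING

    def __post_init__(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be nonnegative")
        if not (0.0 <= self.canonical_prob <= 1.0):
            raise ValueError("canonical_prob must be a probability")
        if self.proto_site_preference < 1.0:
            raise ValueError("proto_site_preference must be >= 1")
        if self.intron_min_len < 4:
            raise ValueError("introns must be at least 4 nt (GT..AG)")


@dataclass
class GainEvent:
    branch: str  # child-node name of the branch the event happened on
    fu_id: str
    kind: str  # "gain" | "loss"
    position_id: str
    cds_offset: int


@dataclass
class TruthSet:
    config: SimulationConfig
    seed: int
    cds: str
    fus: list[FUAnnotation]
    architectures: dict[str, GeneArchitecture]  # gene_id -> architecture
    genomic: dict[str, str]
    cdna: dict[str, str]
    events: list[GainEvent]
    intron_seqs: dict[str, str]  # position_id -> spliced-out sequence
    root_introns: list[tuple[int, str]]  # (cds_offset, position_id)
    tree: LineageTree = field(repr=False, default=None)

    def gene_lineage(self, gene_id: str) -> str:
        return self.architectures[gene_id].lineage

    def homology(self, gene_id: str) -> dict[int, str]:
        return {
            i.cds_offset: i.position_id
            for i in self.architectures[gene_id].introns
        }


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if codon not in STOP_CODONS:
            return codon


def _mutate_fu(seq: str, p: float, rng: np.random.Generator) -> str:
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    out = []
    for codon in codons:
        while True:
            cand = "".join(
                (
                    BASES[(BASES.index(b) + int(rng.integers(1, 4))) % 4]
                    if rng.random() < p
                    else b
                )
                for b in codon
            )
            if cand not in STOP_CODONS:
                out.append(cand)
                break
    return "".join(out)


def _draw_intron_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    for _ in range(1000):
        ln = int(round(rng.lognormal(cfg.intron_meanlog, cfg.intron_sdlog)))
        if ln >= cfg.intron_min_len:
            return ln
    return cfg.intron_min_len


def _draw_intron_seq(cfg: SimulationConfig, rng: np.random.Generator) -> str:
    ln = _draw_intron_length(cfg, rng)
    donor = "GT" if rng.random() < cfg.canonical_prob else "GC"
    interior = "".join(BASES[i] for i in rng.integers(0, 4, size=ln - 4))
    return donor + interior + "AG"


def _alt_canonical_shifts(
    cds: str, offset: int, intron: str, window: int
) -> list[int]:
    """Nonzero shifts within +-window that both preserve the cDNA and yield a
    GT/GC..AG intron — i.e. placements a spliced aligner could not tell apart
    from the truth."""
    shifts = []
    n = len(intron)
    for s in range(-window, window + 1):
        if s == 0:
            continue
        if s > 0:
            if offset + s > len(cds):
                continue
            if intron[:s] != cds[offset : offset + s]:
                continue
            moved = intron[s:] + cds[offset : offset + s]
        else:
            k = -s
            if offset - k < 0:
                continue
            if intron[n - k :] != cds[offset - k : offset]:
                continue
            moved = cds[offset - k : offset] + intron[: n - k]
        if moved[:2] in {"GT", "GC"} and moved[-2:] == "AG":
            shifts.append(s)
    return shifts


def _disambiguate_intron(
    cds: str, offset: int, intron: str, window: int, rng: np.random.Generator
) -> str:
    """Resample terminal interior bases until the true placement is the only
    canonical-looking one in the shift window."""
    for _ in range(200):
        if not _alt_canonical_shifts(cds, offset, intron, window):
            return intron
        if len(intron) >= 4 + 2 * window:
            head = "".join(BASES[i] for i in rng.integers(0, 4, size=window))
            tail = "".join(BASES[i] for i in rng.integers(0, 4, size=window))
            intron = (
                intron[:2] + head + intron[2 + window : -2 - window] + tail + intron[-2:]
            )
        else:
            mid = "".join(BASES[i] for i in rng.integers(0, 4, size=len(intron) - 4))
            intron = intron[:2] + mid + intron[-2:]
    raise RuntimeError("could not disambiguate intron boundaries")


def simulate_family(config: SimulationConfig, seed: int) -> TruthSet:
    """Simulate one gene family; deterministic for fixed (config, seed)."""
    rng = np.random.default_rng(seed)
    tree = LineageTree.from_newick(config.tree_newick)

    # --- root gene: signal peptide + tandem-duplicated FUs + stop codon
    signal = "ATG" + "".join(
        _random_codon(rng) for _ in range(config.signal_codons - 1)
    )
    ancestral_fu = "".join(_random_codon(rng) for _ in range(config.fu_len_codons))
    fu_seqs = [
        _mutate_fu(ancestral_fu, config.fu_divergence, rng)
        for _ in range(config.fu_count)
    ]
    cds = signal + "".join(fu_seqs) + "TAA"

    fu_len = 3 * config.fu_len_codons
    fus = [FUAnnotation("S", 0, len(signal))]
    fu_ids = [chr(ord("a") + i) for i in range(config.fu_count)]
    for i, fu_id in enumerate(fu_ids):
        start = len(signal) + i * fu_len
        fus.append(FUAnnotation(fu_id, start, start + fu_len))

    intron_seqs: dict[str, str] = {}
    window = config.boundary_shift_window

    def new_intron_seq(pos_id: str, offset: int) -> None:
        seq = _draw_intron_seq(config, rng)
        intron_seqs[pos_id] = _disambiguate_intron(cds, offset, seq, window, rng)

    # linker introns: phase 1, one per inter-FU boundary, present at the root
    root_introns: list[tuple[int, str]] = []
    for i, fu_id in enumerate(fu_ids[1:], start=1):
        offset = len(signal) + i * fu_len + 1
        pos_id = f"L{i}"
        new_intron_seq(pos_id, offset)
        root_introns.append((offset, pos_id))

    # --- evolve internal introns along the tree
    events: list[GainEvent] = []
    gain_counter = 0
    used_rel_offsets: set[int] = set()  # for unique_gain_positions

    def fu_of(offset: int) -> FUAnnotation | None:
        for f in fus[1:]:
            if f.cds_start < offset < f.cds_end:
                return f
        return None

    def evolve(node: TreeNode, introns: dict[int, str]) -> None:
        nonlocal gain_counter
        t = node.length
        # losses first (inherited introns), then gains; same-branch gains
        # cannot be lost on the branch that created them
        if t > 0 and config.loss_rate > 0:
            p_loss = 1.0 - math.exp(-config.loss_rate * t)
            for offset in sorted(introns):
                pos_id = introns[offset]
                is_linker = pos_id.startswith("L")
                if is_linker and config.linker_introns_immortal:
                    continue
                if rng.random() < p_loss:
                    fu = fu_of(offset)
                    del introns[offset]
                    events.append(
                        GainEvent(node.name, fu.fu_id if fu else "S", "loss",
                                  pos_id, offset)
                    )
        if t > 0 and config.gain_rate > 0:
            # draw all gain counts first so runaway configurations abort
            # before any expensive position sampling
            branch_gains = [
                (f, int(rng.poisson(config.gain_rate * t))) for f in fus[1:]
            ]
            if len(introns) + sum(n for _, n in branch_gains) > 10_000:
                raise RuntimeError(
                    "runaway configuration: > 10,000 introns in one gene"
                )
            for f, n_gains in branch_gains:
                for _ in range(n_gains):
                    spacing = config.min_gain_spacing
                    lo = f.cds_start + spacing
                    hi = f.cds_end - spacing
                    candidates = [
                        o
                        for o in range(lo, hi)
                        if all(abs(o - e) >= spacing for e in introns)
                        and (
                            not config.unique_gain_positions
                            or (o - f.cds_start) not in used_rel_offsets
                        )
                    ]
                    if not candidates:
                        continue
                    weights = np.array(
                        [
                            config.proto_site_preference
                            if cds[o - 2 : o] == "AG" and cds[o] == "G"
                            else 1.0
                            for o in candidates
                        ]
                    )
                    o = int(rng.choice(candidates, p=weights / weights.sum()))
                    gain_counter += 1
                    pos_id = f"g{gain_counter}"
                    new_intron_seq(pos_id, o)
                    introns[o] = pos_id
                    used_rel_offsets.add(o - f.cds_start)
                    events.append(GainEvent(node.name, f.fu_id, "gain", pos_id, o))
        if node.is_leaf:
            leaf_intron_sets[node.name] = dict(introns)
        else:
            for child in node.children:
                evolve(child, dict(introns))

    # the root's edge length is the stem branch: events on it happen between
    # the completed multi-FU ancestor and the radiation
    leaf_intron_sets: dict[str, dict[int, str]] = {}
    tree.root.length = tree.stem_length
    evolve(tree.root, dict(root_introns))

    if any(len(s) > 10_000 for s in leaf_intron_sets.values()):
        raise RuntimeError("runaway configuration: > 10,000 introns in one gene")

    # --- emit sequences + architectures
    architectures: dict[str, GeneArchitecture] = {}
    genomic: dict[str, str] = {}
    cdna: dict[str, str] = {}
    for leaf, introns in leaf_intron_sets.items():
        gene_id = f"{leaf}_hc"
        offsets = sorted(introns)
        parts, exons, gpos, prev = [], [], 0, 0
        for off in offsets:
            parts.append(cds[prev:off])
            exons.append(ExonSpan(start=gpos, end=gpos + (off - prev), cds_offset=prev))
            gpos += off - prev
            iseq = intron_seqs[introns[off]]
            parts.append(iseq)
            gpos += len(iseq)
            prev = off
        parts.append(cds[prev:])
        exons.append(ExonSpan(start=gpos, end=gpos + len(cds) - prev, cds_offset=prev))
        gseq = "".join(parts)

        intr_records = []
        for off in offsets:
            pos_id = introns[off]
            intr_records.append(
                IntronRecord(
                    cds_offset=off,
                    phase=off % 3,
                    length=len(intron_seqs[pos_id]),
                    position_id=pos_id,
                    boundary_class=(
                        "canonical"
                        if intron_seqs[pos_id].startswith("GT")
                        else "gc_ag"
                    ),
                )
            )
        arch = GeneArchitecture(
            gene_id=gene_id,
            species=leaf,
            lineage=leaf,
            exons=exons,
            fus=list(fus),
            introns=intr_records,
        )
        arch.validate()
        arch, _ = classify_introns(arch)
        # classification must agree with construction: linkers are the Lx ids
        for i in arch.introns:
            expected = "linker" if i.position_id.startswith("L") else "internal"
            if i.klass != expected:
                raise RuntimeError(
                    f"{gene_id}: intron {i.position_id} classified {i.klass}"
                )
        architectures[gene_id] = arch
        genomic[gene_id] = gseq
        cdna[gene_id] = cds

    return TruthSet(
        config=config,
        seed=seed,
        cds=cds,
        fus=fus,
        architectures=architectures,
        genomic=genomic,
        cdna=cdna,
        events=events,
        intron_seqs=intron_seqs,
        root_introns=root_introns,
        tree=tree,
    )


def replay_events(truth: TruthSet) -> dict[str, dict[int, str]]:
    """Re-apply the event log from the root intron set down the tree.

    Returns per-leaf ``{cds_offset: position_id}``; must reproduce every
    leaf architecture exactly (hard simulator invariant).
    """
    by_branch: dict[str, list[GainEvent]] = {}
    for ev in truth.events:
        by_branch.setdefault(ev.branch, []).append(ev)

    out: dict[str, dict[int, str]] = {}

    def walk(node: TreeNode, introns: dict[int, str]) -> None:
        for ev in by_branch.get(node.name, []):
            if ev.kind == "loss":
                del introns[ev.cds_offset]
            else:
                introns[ev.cds_offset] = ev.position_id
        if node.is_leaf:
            out[f"{node.name}_hc"] = dict(introns)
        else:
            for child in node.children:
                walk(child, dict(introns))

    walk(truth.tree.root, dict(truth.root_introns))
    return out


# ---------------------------------------------------------------------------
# fixture writing


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fixtures(truth: TruthSet, outdir: str | Path) -> dict[str, dict[str, str]]:
    """Write genomic/cDNA FASTA, GFF3 + FU sidecar TSV and truth TSVs.

    Returns a manifest mapping gene_id -> file paths (also saved as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}

    for gene_id, arch in truth.architectures.items():
        gseq = truth.genomic[gene_id]
        files = {
            "genomic": f"{gene_id}.genomic.fa",
            "cdna": f"{gene_id}.cdna.fa",
            "gff3": f"{gene_id}.gff3",
            "fus": f"{gene_id}.fus.tsv",
            "lineage": arch.lineage,
        }
        _write_fasta(outdir / files["genomic"], {gene_id: gseq})
        _write_fasta(outdir / files["cdna"], {f"{gene_id}_cdna": truth.cdna[gene_id]})

        with open(outdir / files["gff3"], "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {gene_id} 1 {len(gseq)}\n")
            end = len(gseq)
            fh.write(
                f"{gene_id}\tintronarch_sim\tgene\t1\t{end}\t.\t+\t.\t"
                f"ID=gene:{gene_id}\n"
            )
            fh.write(
                f"{gene_id}\tintronarch_sim\tmRNA\t1\t{end}\t.\t+\t.\t"
                f"ID=mrna:{gene_id};Parent=gene:{gene_id}\n"
            )
            for i, e in enumerate(arch.exons):
                fh.write(
                    f"{gene_id}\tintronarch_sim\tCDS\t{e.start + 1}\t{e.end}\t.\t+\t"
                    f"{(3 - e.cds_offset % 3) % 3}\t"
                    f"ID=cds:{gene_id}.{i};Parent=mrna:{gene_id}\n"
                )
            cds_to_genomic = _cds_to_genomic_map(arch)
            for f in arch.fus:
                gs = cds_to_genomic(f.cds_start)
                ge = cds_to_genomic(f.cds_end - 1) + 1
                name = "signal_peptide" if f.fu_id == "S" else f"FU-{f.fu_id}"
                fh.write(
                    f"{gene_id}\tintronarch_sim\tregion\t{gs + 1}\t{ge}\t.\t+\t.\t"
                    f"ID=region:{gene_id}.{f.fu_id};Name={name}\n"
                )

        with open(outdir / files["fus"], "w") as fh:
            fh.write("fu_id\tcds_start\tcds_end\n")
            for f in arch.fus:
                fh.write(f"{f.fu_id}\t{f.cds_start}\t{f.cds_end}\n")
        manifest[gene_id] = files

    with open(outdir / "architectures.tsv", "w") as fh:
        fh.write("gene_id\tlineage\tcds_offset\tphase\tklass\tposition_id\tlength\n")
        for gene_id, arch in truth.architectures.items():
            for i in arch.introns:
                fh.write(
                    f"{gene_id}\t{arch.lineage}\t{i.cds_offset}\t{i.phase}\t"
                    f"{i.klass}\t{i.position_id}\t{i.length}\n"
                )
    with open(outdir / "events.tsv", "w") as fh:
        fh.write("branch\tfu\tkind\tposition_id\tcds_offset\n")
        for ev in truth.events:
            fh.write(
                f"{ev.branch}\t{ev.fu_id}\t{ev.kind}\t{ev.position_id}\t"
                f"{ev.cds_offset}\n"
            )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _cds_to_genomic_map(arch: GeneArchitecture):
    def conv(off: int) -> int:
        for e in arch.exons:
            if e.cds_offset <= off < e.cds_offset + e.length:
                return e.start + (off - e.cds_offset)
        raise ValueError(f"cds offset {off} outside CDS")

    return conv
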