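"""Exon-count comparison between ortholog pairs of two genomes.

Given a table of ortholog pairs (protein lengths and exon counts, e.g. an
OrthoVenn2 export), keep pairs whose polypeptide lengths differ by at most
5% (relative to the longer protein, boundary inclusive), collapse paralog
groups whose members have identical exon counts to one representative, and
summarize the distribution of absolute exon-count differences.  The
contrast of interest: most orthologs differ by at most a handful of exons,
whereas hemocyanin orthologs between Tectipleura and Octopus differ by
tens — intron accumulation is gene-specific, not genome-wide.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .gene_models import GeneArchitecture

REQUIRED_COLUMNS = ["gene_a", "gene_b", "len_a", "len_b", "exons_a", "exons_b"]
LENGTH_TOLERANCE = 0.05


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ortholog table lacks columns: {missing}")
    return df


def filter_pairs(pairs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the length filter and paralog-deduplication rules.

    Keeps pairs with both exon counts present and
    ``|len_a - len_b| / max(len_a, len_b) <= 0.05`` (inclusive).  Within a
    paralog group, pairs with identical exon count collapse to one
    representative — the first by sorted gene_a id.  Returns the surviving
    pairs and a drop report.
    """
    df = pairs.copy()
    n0 = len(df)
    has_counts = df["exons_a"].notna() & df["exons_b"].notna()
    dropped_missing = int((~has_counts).sum())
    df = df[has_counts]

    rel = (df["len_a"] - df["len_b"]).abs() / df[["len_a", "len_b"]].max(axis=1)
    keep = rel <= LENGTH_TOLERANCE
    dropped_length = int((~keep).sum())
    df = df[keep]

    dropped_paralog = 0
    if "paralog_group" in df.columns:
        df = df.sort_values(["gene_a", "gene_b"]).copy()
        key_cols = ["paralog_group", "exons_a", "exons_b"]
        grouped = df.groupby("paralog_group", dropna=True, sort=False)
        survivors = []
        for _, g in grouped:
            first = g.drop_duplicates(subset=["exons_a", "exons_b"], keep="first")
            dropped_paralog += len(g) - len(first)
            survivors.append(first)
        no_group = df[df["paralog_group"].isna()] if df["paralog_group"].isna().any() else None
        parts = survivors + ([no_group] if no_group is not None else [])
        df = pd.concat(parts).sort_index() if parts else df.iloc[0:0]

    report = {
        "input_pairs": n0,
        "dropped_missing_exon_count": dropped_missing,
        "dropped_length_filter": dropped_length,
        "dropped_paralog_duplicates": dropped_paralog,
        "surviving_pairs": len(df),
    }
    return df.reset_index(drop=True), report


def exon_count_differences(
    pairs: pd.DataFrame,
    thresholds: Sequence[int] = (1, 4, 6),
    large_cutoff: int = 25,
) -> dict:
    """Distribution of |exon_a - exon_b| over surviving pairs."""
    if len(pairs) == 0:
        raise ValueError("no pairs to summarize")
    delta = (pairs["exons_a"] - pairs["exons_b"]).abs().astype(int)
    n = len(delta)
    hist = delta.value_counts().sort_index()
    return {
        "n_pairs": n,
        "fraction_le": {
            int(t): float((delta <= t).sum()) / n for t in thresholds
        },
        "count_gt_large": int((delta > large_cutoff).sum()),
        "large_cutoff": large_cutoff,
        "histogram": {int(k): int(v) for k, v in hist.items()},
        "median": float(delta.median()),
        "max": int(delta.max()),
    }


def fu_slice_exon_count(
    arch: GeneArchitecture, fu_from: str = "a", fu_to: str = "g"
) -> int:
    """Exon count of the architecture restricted to [FU_from, FU_to].

    Counted as introns inside the slice plus one, making Tectipleura genes
    (which have FU-h) comparable to cephalopod genes (which lack it).
    """
    fus = {f.fu_id: f for f in arch.fus}
    if fu_from not in fus or fu_to not in fus:
        raise ValueError(f"architecture lacks FU-{fu_from} or FU-{fu_to}")
    lo = fus[fu_from].cds_start
    hi = fus[fu_to].cds_end
    n_introns = sum(1 for i in arch.introns if lo < i.cds_offset < hi)
    return n_introns + 1


def hemocyanin_delta(
    arch_tectipleura: GeneArchitecture,
    arch_octopus: GeneArchitecture,
    fu_from: str = "a",
    fu_to: str = "g",
) -> int:
    """|exon-count difference| between two hemocyanins over FU-a..FU-g."""
    return abs(
        fu_slice_exon_count(arch_tectipleura, fu_from, fu_to)
        - fu_slice_exon_count(arch_octopus, fu_from, fu_to)
    )


def histogram_to_tsv(dist: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("delta\tcount\n")
        for k, v in sorted(dist["histogram"].items()):
            fh.write(f"{k}\t{v}\n")
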