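"""FU overlay: peptide extraction, alignment, projection, position classes."""

from __future__ import annotations

import itertools

import pytest

from intronarch import fu_overlay
from intronarch.fu_overlay import (
    FUAlignment,
    SplicePlacement,
    align_fus,
    classify_positions,
    extract_fu_peptides,
    project_splice_sites,
)
from intronarch.gene_models import ExonSpan, FUAnnotation, GeneArchitecture


def place(gene, lineage, fu, col, phase, off=0):
    return SplicePlacement(
        gene_id=gene, lineage=lineage, fu_id=fu, column=col, phase=phase,
        cds_offset=off,
    )


class TestExtractPeptides:
    def test_codon_aligned_span(self):
        cdna = "ATG" + "GCT" * 10 + "TAA"  # FU = 10 alanines
        arch = GeneArchitecture(
            gene_id="g",
            exons=[ExonSpan(0, len(cdna), 0)],
            fus=[FUAnnotation("a", 3, 33)],
            introns=[],
        )
        peps = extract_fu_peptides(arch, cdna)
        assert len(peps) == 1
        assert peps[0].seq == "A" * 10
        assert peps[0].codon_start_offset == 3

    def test_mid_codon_span_starts_next_codon(self):
        cdna = "ATG" + "GCT" * 10 + "TAA"
        arch = GeneArchitecture(
            gene_id="g",
            exons=[ExonSpan(0, len(cdna), 0)],
            fus=[FUAnnotation("a", 4, 33)],  # starts mid-codon
            introns=[],
        )
        peps = extract_fu_peptides(arch, cdna)
        assert peps[0].codon_start_offset == 6
        assert peps[0].seq == "A" * 9

    def test_internal_stop_truncates_with_warning(self):
        cdna = "ATG" + "GCT" * 3 + "TAA" + "GCT" * 3 + "TGA"
        arch = GeneArchitecture(
            gene_id="g",
            exons=[ExonSpan(0, len(cdna), 0)],
            fus=[FUAnnotation("a", 3, 24)],
            introns=[],
        )
        with pytest.warns(UserWarning, match="stop"):
            peps = extract_fu_peptides(arch, cdna)
        assert peps[0].truncated
        assert peps[0].seq == "AAA"

    def test_simulator_peptides_translate_cleanly(self, default_truth):
        gid = sorted(default_truth.architectures)[0]
        arch = default_truth.architectures[gid]
        peps = extract_fu_peptides(arch, default_truth.cdna[gid])
        assert len(peps) == 8
        assert all(not p.truncated for p in peps)
        assert all(len(p.seq) == 150 for p in peps)


class TestAlignment:
    def test_identical_sequences_align_without_gaps(self):
        aln = align_fus({("g1", "a"): "MKLV", ("g2", "a"): "MKLV"})
        assert set(aln.rows.values()) == {"MKLV"}

    def test_single_insertion_creates_one_gap_column(self):
        aln = align_fus(
            {("g1", "a"): "MKWWLVMKWWLV", ("g2", "a"): "MKWWLVAMKWWLV"}
        )
        assert aln.width == 13
        rows = aln.rows
        assert rows[("g1", "a")].count("-") == 1
        assert rows[("g2", "a")].count("-") == 0

    def test_realigning_ungapped_rows_is_idempotent(self, default_truth):
        gid = sorted(default_truth.architectures)[0]
        arch = default_truth.architectures[gid]
        peps = extract_fu_peptides(arch, default_truth.cdna[gid])
        aln1 = align_fus(peps)
        ungapped = {k: v.replace("-", "") for k, v in aln1.rows.items()}
        aln2 = align_fus(ungapped)
        assert aln1.rows == aln2.rows

    def test_external_ragged_alignment_rejected(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">g1|a\nMK-LV\n>g2|a\nMKLV\n")
        with pytest.raises(ValueError, match="ragged"):
            align_fus(external=p)

    def test_external_alignment_ingested(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">g1|a\nMK-LV\n>g2|a\nMKWLV\n")
        aln = align_fus(external=p)
        assert aln.width == 5
        assert aln.column_of(("g1", "a"), 2) == 3  # L sits after the gap


class TestProjection:
    def _two_gene_setup(self):
        cdna = "ATG" + "GCT" * 20 + "TAA"
        fus = [FUAnnotation("a", 3, 63)]

        def arch(gene, lineage, intron_offsets):
            exons, prev, gpos = [], 0, 0
            for off in intron_offsets:
                exons.append(ExonSpan(gpos, gpos + off - prev, prev))
                gpos += off - prev + 200
                prev = off
            exons.append(ExonSpan(gpos, gpos + len(cdna) - prev, prev))
            from intronarch.gene_models import classify_introns, derive_introns

            a = GeneArchitecture(
                gene_id=gene, lineage=lineage, exons=exons, fus=fus,
                introns=derive_introns(exons),
            )
            a, _ = classify_introns(a)
            return a

        return cdna, arch

    def test_phase0_intron_after_residue_ten(self):
        cdna, arch = self._two_gene_setup()
        a = arch("g1", "Tect", [33])  # 30 coding nt into FU-a: after residue 10
        peps = extract_fu_peptides(a, cdna)
        aln = FUAlignment(rows={("g1", "a"): peps[0].seq})
        pls = project_splice_sites([a], aln, peps)
        assert len(pls) == 1
        assert (pls[0].column, pls[0].phase) == (10, 0)

    def test_same_offset_same_sequence_projects_identically(self):
        cdna, arch = self._two_gene_setup()
        a1, a2 = arch("g1", "Tect", [34]), arch("g2", "Lep", [34])
        peps = extract_fu_peptides(a1, cdna) + extract_fu_peptides(a2, cdna)
        aln = align_fus(peps)
        pls = project_splice_sites([a1, a2], aln, peps)
        assert len(pls) == 2
        assert (pls[0].column, pls[0].phase) == (pls[1].column, pls[1].phase)

    def test_intron_outside_fu_spans_is_skipped(self):
        cdna, arch = self._two_gene_setup()
        a = arch("g1", "Tect", [2])  # inside the start codon, outside FU-a
        peps = extract_fu_peptides(a, cdna)
        aln = FUAlignment(rows={("g1", "a"): peps[0].seq})
        with pytest.warns(UserWarning, match="outside"):
            pls = project_splice_sites([a], aln, peps)
        assert pls == []

    def test_simulator_truth_groups_by_position_id(self, unique_positions_truth):
        truth = unique_positions_truth
        archs = sorted(truth.architectures.values(), key=lambda a: a.gene_id)
        peps = []
        for a in archs:
            peps.extend(extract_fu_peptides(a, truth.cdna[a.gene_id]))
        aln = align_fus(peps)
        placements = project_splice_sites(archs, aln, peps)
        groups, _ = classify_positions(placements)
        pid = {
            (g, i.cds_offset): i.position_id
            for g, a in truth.architectures.items()
            for i in a.introns
        }
        for g in groups:
            ids = {pid[(m.gene_id, m.cds_offset)] for m in g.members}
            assert len(ids) == 1, f"false merge at {g.key}: {ids}"
        seen: dict[str, tuple] = {}
        for g in groups:
            for m in g.members:
                i = pid[(m.gene_id, m.cds_offset)]
                assert seen.setdefault(i, g.key) == g.key, f"false split of {i}"


class TestClassifyPositions:
    def test_all_distinct_keys_zero_multiple(self):
        pls = [place("g", "T", "a", c, 0) for c in range(5)]
        _, summary = classify_positions(pls)
        assert summary["multiple_pct"] == 0
        assert summary["unique_pct"] == 100

    def test_shared_key_across_fus_is_multiple(self):
        pls = [place("g", "T", "a", 7, 1), place("g", "T", "b", 7, 1)]
        groups, summary = classify_positions(pls)
        assert groups[0].klass == "multiple"
        assert not groups[0].ortholog
        assert summary["multiple_pct"] == 100

    def test_same_fu_two_lineages_is_ortholog(self):
        pls = [place("g1", "Tect", "a", 3, 2), place("g2", "Lep", "a", 3, 2)]
        groups, summary = classify_positions(pls)
        assert groups[0].klass == "multiple"
        assert groups[0].ortholog
        assert summary["ortholog_groups"] == [(3, 2)]

    def test_same_column_different_phase_not_grouped(self):
        pls = [place("g", "T", "a", 7, 0), place("g", "T", "b", 7, 1)]
        groups, _ = classify_positions(pls)
        assert len(groups) == 2
        assert all(g.klass == "unique" for g in groups)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairwise_oracle_on_random_sets(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        pls = [
            place(
                f"g{rng.integers(3)}",
                ["T", "L", "C"][rng.integers(3)],
                "abcd"[rng.integers(4)],
                int(rng.integers(6)),
                int(rng.integers(3)),
                off=int(i),
            )
            for i in range(25)
        ]
        groups, _ = classify_positions(pls)
        got = {
            id(m): (g.klass, g.ortholog) for g in groups for m in g.members
        }
        # O(n^2) oracle: compare every placement against every other
        for p in pls:
            mates = [
                q
                for q in pls
                if (q.column, q.phase) == (p.column, p.phase)
            ]
            fus = {q.fu_id for q in mates}
            lineages = {q.lineage for q in mates}
            multiple = len(fus) >= 2 or len(lineages) >= 2
            ortholog = any(
                len({q.lineage for q in mates if q.fu_id == fu}) >= 2
                for fu in fus
            )
            assert got[id(p)] == (
                "multiple" if multiple else "unique",
                ortholog,
            )

    def test_partition_and_percent_sum(self, default_truth):
        truth = default_truth
        archs = sorted(truth.architectures.values(), key=lambda a: a.gene_id)
        peps = []
        for a in archs:
            peps.extend(extract_fu_peptides(a, truth.cdna[a.gene_id]))
        aln = align_fus(peps)
        placements = project_splice_sites(archs, aln, peps)
        groups, summary = classify_positions(placements)
        assert sum(len(g.members) for g in groups) == len(placements)
        assert summary["multiple_raw_pct"] + summary["unique_raw_pct"] == (
            pytest.approx(100.0)
        )

    def test_order_permutation_invariance(self):
        pls = [
            place("g1", "T", "a", 1, 0),
            place("g2", "L", "a", 1, 0),
            place("g1", "T", "b", 2, 1),
        ]
        base = classify_positions(pls)[1]
        for perm in itertools.permutations(pls):
            assert classify_positions(list(perm))[1] == base

    def test_duplicate_architecture_deduplicated_by_lineage(self, default_truth):
        truth = default_truth
        archs = sorted(truth.architectures.values(), key=lambda a: a.gene_id)
        peps = []
        for a in archs:
            peps.extend(extract_fu_peptides(a, truth.cdna[a.gene_id]))
        aln = align_fus(peps)
        base = project_splice_sites(archs, aln, peps)
        doubled = project_splice_sites(archs + archs, aln, peps)
        assert len(doubled) == len(base)

    def test_group_counting_switch(self):
        pls = [
            place("g", "T", "a", 1, 0),
            place("g", "T", "b", 1, 0),
            place("g", "T", "c", 5, 0),
        ]
        _, by_placement = classify_positions(pls, count="placements")
        _, by_group = classify_positions(pls, count="groups")
        assert by_placement["multiple_raw_pct"] == pytest.approx(200 / 3)
        assert by_group["multiple_raw_pct"] == pytest.approx(50.0)
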