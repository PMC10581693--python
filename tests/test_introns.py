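"""Intron-column mapping, the conserved-intron filter and GFF3 extraction."""

import numpy as np
import pandas as pd
import pytest

from splicemap.introns import (
    IntronRecord,
    OrthogroupAlignment,
    extract_intron_table,
    filter_conserved_introns,
    map_intron_to_column,
    read_intron_table,
    write_intron_table,
)

DONOR = "CAGGTAAGTAT"
ACCEPTOR = "TTTCAGG"


def rec(species, residue_index=0, phase=0, protein=None, og="OG1"):
    return IntronRecord(
        species=species,
        protein=protein or f"p_{species}",
        orthogroup=og,
        residue_index=residue_index,
        phase=phase,
        donor_window=DONOR,
        acceptor_window=ACCEPTOR,
    )


def aln(rows, og="OG1"):
    return OrthogroupAlignment(
        og, {f"p_{sp}": seq for sp, seq in rows.items()}, {f"p_{sp}": sp for sp in rows}
    )


class TestMapIntronToColumn:
    def test_ungapped_identity(self):
        a = aln({"s1": "MKLV", "s2": "MKLV"})
        assert map_intron_to_column(a, rec("s1", 2, 1)) == (2, 1)

    def test_gap_shifts_column(self):
        a = aln({"s1": "M-KL", "s2": "MMKL"})
        assert map_intron_to_column(a, rec("s1", 1)) == (2, 0)

    def test_gap_prefix_shifts_all(self):
        a = aln({"s1": "--MK", "s2": "AAMK"})
        assert map_intron_to_column(a, rec("s1", 0)) == (2, 0)

    def test_out_of_range_raises(self):
        a = aln({"s1": "MK--", "s2": "MKLV"})
        with pytest.raises(IndexError):
            map_intron_to_column(a, rec("s1", 2))


class TestFilter:
    def test_shared_column_and_phase_kept(self):
        a = {"OG1": aln({"s1": "MKL", "s2": "MKL"})}
        kept = filter_conserved_introns(a, [rec("s1", 1, 0), rec("s2", 1, 0)])
        assert len(kept) == 2

    def test_phase_mismatch_dropped(self):
        a = {"OG1": aln({"s1": "MKL", "s2": "MKL"})}
        kept = filter_conserved_introns(a, [rec("s1", 1, 0), rec("s2", 1, 1)])
        assert kept == []

    def test_singleton_dropped(self):
        a = {"OG1": aln({"s1": "MKL", "s2": "MKL"})}
        assert filter_conserved_introns(a, [rec("s1", 1, 0)]) == []

    def test_paralogs_do_not_count_as_two_species(self):
        a = {
            "OG1": OrthogroupAlignment(
                "OG1", {"p1": "MKL", "p2": "MKL"}, {"p1": "s1", "p2": "s1"}
            )
        }
        records = [rec("s1", 1, 0, protein="p1"), rec("s1", 1, 0, protein="p2")]
        assert filter_conserved_introns(a, records, skip_large_orthogroups=False) == []

    def test_idempotent_and_order_invariant(self, rng):
        from splicemap.simulate import (
            SimulationConfig,
            simulate_dollo_genotype,
            simulate_intron_dataset,
            simulate_tree,
        )

        t = simulate_tree(8, seed=1)
        g = simulate_dollo_genotype(t, 0.4, seed=2)
        cfg = SimulationConfig(n_introns_per_species=60, n_intron_orthogroups=4)
        alignments, records, _ = simulate_intron_dataset(t, g, cfg, seed=3)
        kept = filter_conserved_introns(alignments, records)
        assert filter_conserved_introns(alignments, kept) == kept
        import random

        shuffled = list(records)
        random.Random(0).shuffle(shuffled)
        assert filter_conserved_introns(alignments, shuffled) == kept

    def test_matches_generator_ground_truth(self):
        from splicemap.simulate import (
            SimulationConfig,
            simulate_dollo_genotype,
            simulate_intron_dataset,
            simulate_tree,
        )

        for seed in range(5):
            t = simulate_tree(10, seed=seed)
            g = simulate_dollo_genotype(t, 0.4, seed=seed)
            cfg = SimulationConfig(n_introns_per_species=80, n_intron_orthogroups=4)
            alignments, records, truth = simulate_intron_dataset(t, g, cfg, seed=seed)
            kept = filter_conserved_introns(alignments, records)
            keys = {(r.orthogroup, r.species, r.residue_index, r.phase) for r in kept}
            assert keys == truth["conserved"]

    def test_large_orthogroups_skipped(self):
        a = {
            "OG1": OrthogroupAlignment(
                "OG1",
                {"p1": "MKL", "p2": "MKL", "p3": "MKL", "p4": "MKL", "p5": "MKL"},
                {"p1": "s1", "p2": "s1", "p3": "s1", "p4": "s2", "p5": "s2"},
            )
        }
        records = [rec("s1", 1, 0, protein="p1"), rec("s2", 1, 0, protein="p4")]
        assert filter_conserved_introns(a, records) == []
        assert len(filter_conserved_introns(a, records, skip_large_orthogroups=False)) == 2


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestExtraction:
    # exon1 = 9 nt, intron = 20 nt (GT...AG), exon2 = 6 nt
    EXON1 = "ATGGCCAAA"
    INTRON = "GTAAGTATCCCCCTTTTCAG"
    EXON2 = "GGCTAA"

    def genome_plus(self):
        return {"chr1": self.EXON1 + self.INTRON + self.EXON2}

    def test_single_exon_no_introns(self):
        cds = pd.DataFrame(
            [{"seqid": "chr1", "start": 1, "end": 9, "strand": "+", "protein": "m1"}]
        )
        assert extract_intron_table(self.genome_plus(), cds, "sp") == []

    def test_plus_strand_coordinates_and_windows(self):
        cds = pd.DataFrame(
            [
                {"seqid": "chr1", "start": 1, "end": 9, "strand": "+", "protein": "m1"},
                {"seqid": "chr1", "start": 30, "end": 35, "strand": "+", "protein": "m1"},
            ]
        )
        (r,) = extract_intron_table(self.genome_plus(), cds, "sp")
        assert (r.residue_index, r.phase) == (2, 0)  # 9 nt = 3 complete codons
        assert r.donor_window == self.EXON1[-3:] + self.INTRON[:8]
        assert r.acceptor_window == self.INTRON[-6:] + self.EXON2[0]

    def test_minus_strand_reverse_complement(self):
        seq = self.EXON1 + self.INTRON + self.EXON2
        genome = {"chr1": _revcomp(seq)}
        L = len(seq)
        # original [1..9] maps to [L-8..L], original [30..35] to [L-34..L-29]
        cds = pd.DataFrame(
            [
                {"seqid": "chr1", "start": L - 8, "end": L, "strand": "-", "protein": "m1"},
                {"seqid": "chr1", "start": L - 34, "end": L - 29, "strand": "-", "protein": "m1"},
            ]
        )
        (r,) = extract_intron_table(genome, cds, "sp")
        assert (r.residue_index, r.phase) == (2, 0)
        assert r.donor_window == self.EXON1[-3:] + self.INTRON[:8]
        assert r.donor_window[3:5] == "GT"
        assert r.acceptor_window == self.INTRON[-6:] + self.EXON2[0]

    def test_phase_one_intron(self):
        # 10 coding nt before the intron: interrupts codon 4 (index 3)
        genome = {"chr1": "ATGGCCAAAG" + self.INTRON + "GCTAA"}
        cds = pd.DataFrame(
            [
                {"seqid": "chr1", "start": 1, "end": 10, "strand": "+", "protein": "m1"},
                {"seqid": "chr1", "start": 31, "end": 35, "strand": "+", "protein": "m1"},
            ]
        )
        (r,) = extract_intron_table(genome, cds, "sp")
        assert (r.residue_index, r.phase) == (3, 1)

    def test_window_padded_at_contig_edge(self):
        genome = {"chr1": "AT" + self.INTRON + "GG"}
        cds = pd.DataFrame(
            [
                {"seqid": "chr1", "start": 1, "end": 2, "strand": "+", "protein": "m1"},
                {"seqid": "chr1", "start": 23, "end": 24, "strand": "+", "protein": "m1"},
            ]
        )
        (r,) = extract_intron_table(genome, cds, "sp")
        assert r.donor_window.startswith("N")

    def test_gff3_fasta_front_end(self, tmp_path):
        from splicemap.introns import extract_from_files

        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\n" + self.genome_plus()["chr1"] + "\n")
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tmRNA\t1\t35\t.\t+\t.\tID=m1\n"
            "chr1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=c1;Parent=m1\n"
            "chr1\tsrc\tCDS\t30\t35\t.\t+\t0\tID=c2;Parent=m1\n"
        )
        (r,) = extract_from_files(fasta, gff, "sp")
        assert (r.residue_index, r.phase) == (2, 0)
        assert r.donor_window[3:5] == "GT"


def test_tsv_round_trip(tmp_path):
    records = [rec("s1", 3, 1), rec("s2", 5, 0)]
    path = tmp_path / "introns.tsv"
    write_intron_table(records, path)
    assert read_intron_table(path) == records
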