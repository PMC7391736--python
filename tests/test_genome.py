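"""Parsing and directon segmentation."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from acrminer.genome import (
    Assembly,
    GeneRecord,
    build_directons,
    directon_stats,
    parse_assembly,
)

from conftest import make_gene, oracle_directon_partition, random_contig_genes


class TestGeneRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_gene("bad", 100, -5)
        with pytest.raises(ValueError):
            GeneRecord("g", "g", "c", 10, 5, "+", 10)
        with pytest.raises(ValueError):
            GeneRecord("g", "g", "c", 1, 100, "+", 5, aa_sequence="AAA")

    def test_sequence_length_must_match(self):
        g = GeneRecord("g", "g", "c", 1, 11, "+", 3, aa_sequence="MKL")
        assert g.aa_length == 3


class TestBuildDirectons:
    @pytest.mark.parametrize(
        "gap,expected_sizes",
        [(0, [2]), (50, [2]), (100, [2]), (101, [1, 1]), (500, [1, 1])],
    )
    def test_gap_boundary_inclusive_at_100(self, gap, expected_sizes):
        """Two co-directional genes join iff their gap is at most 100 bp."""
        a = make_gene("a", 100, 50)
        b = make_gene("b", a.end + gap + 1, 50)
        sizes = [d.size for d in build_directons([a, b])]
        assert sizes == expected_sizes

    def test_strand_switch_breaks_run(self):
        a = make_gene("a", 100, 50, "+")
        b = make_gene("b", a.end + 10, 50, "-")
        assert [d.size for d in build_directons([a, b])] == [1, 1]

    def test_overlapping_same_strand_genes_merge(self):
        """Overlap is treated as gap 0: stronger co-transcription evidence."""
        a = make_gene("a", 100, 100)
        b = make_gene("b", a.end - 30, 100)
        ds = build_directons([a, b])
        assert len(ds) == 1 and ds[0].size == 2

    def test_directons_never_span_contigs(self):
        a = make_gene("a", 100, 50, contig="c1")
        b = make_gene("b", a.end + 5, 50, contig="c2")
        assert len(build_directons([a, b])) == 2

    def test_partition_matches_bruteforce_oracle(self, rng):
        """On random gene layouts the partition equals an independent
        adjacent-pair grouping oracle, every gene lands in exactly one
        directon, and runs are maximal."""
        for _ in range(50):
            genes = random_contig_genes(rng, int(rng.integers(2, 25)))
            ds = build_directons(genes)
            got = [tuple(g.protein_id for g in d.genes) for d in ds]
            assert got == oracle_directon_partition(genes)
            # partition property
            flat = [pid for grp in got for pid in grp]
            assert sorted(flat) == sorted(g.protein_id for g in genes)
            # maximality: adjacent same-strand directons must violate the gap
            for d1, d2 in zip(ds, ds[1:]):
                if d1.contig_id == d2.contig_id and d1.strand == d2.strand:
                    gap = d2.genes[0].start - d1.genes[-1].end - 1
                    assert gap > 100

    def test_empty_and_invalid_gap(self):
        assert build_directons([]) == []
        with pytest.raises(ValueError):
            build_directons([], max_gap_bp=-1)


class TestDirectonStats:
    def test_singleton_convention(self):
        d = build_directons([make_gene("a", 10, 150)])[0]
        assert directon_stats(d) == (1, 150.0, 0.0)

    def test_two_gene_arithmetic(self):
        a = make_gene("a", 100, 100)
        b = make_gene("b", a.end + 51, 200)  # gap 50
        d = build_directons([a, b])[0]
        assert directon_stats(d) == (2, 150.0, 50.0)

    def test_random_directon_matches_hand_summed_oracle(self, rng):
        genes, pos = [], 100
        for i in range(5):
            aa = int(rng.integers(30, 200))
            genes.append(make_gene(f"g{i}", pos, aa))
            pos = genes[-1].end + 1 + int(rng.integers(0, 100))
        d = build_directons(genes)[0]
        assert d.size == 5
        size, mean_len, mean_sp = directon_stats(d)
        exp_len = sum(g.aa_length for g in genes) / 5
        gaps = [b.start - a.end - 1 for a, b in zip(genes, genes[1:])]
        assert mean_len == pytest.approx(exp_len)
        assert mean_sp == pytest.approx(sum(gaps) / 4)


def _write_gff3(genes, path):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\tsim\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}"
                f"\t0\tID={g.gene_id};protein_id={g.protein_id}\n"
            )


def _write_gene_tsv(genes, path, assembly="toy"):
    with open(path, "w") as fh:
        fh.write("assembly\tcontig\tgene_id\tstart\tend\tstrand\taa_length\n")
        for g in genes:
            fh.write(
                f"{assembly}\t{g.contig_id}\t{g.gene_id}\t{g.start}\t{g.end}"
                f"\t{g.strand}\t{g.aa_length}\n"
            )


def _write_genbank(genes, path, contig="c1"):
    end = max(g.end for g in genes) + 100
    rec = SeqRecord(Seq("A" * end), id=contig, name=contig,
                    annotations={"molecule_type": "DNA"})
    for g in genes:
        rec.features.append(
            SeqFeature(
                FeatureLocation(g.start - 1, g.end,
                                strand=1 if g.strand == "+" else -1),
                type="CDS",
                qualifiers={"protein_id": [g.protein_id],
                            "locus_tag": [g.gene_id]},
            )
        )
    SeqIO.write([rec], str(path), "genbank")


class TestParseAssembly:
    def test_gff3_toy_roundtrip(self, tmp_path):
        genes = [make_gene("g1", 100, 99), make_gene("g2", 500, 99, "-"),
                 make_gene("g3", 1200, 99)]
        p = tmp_path / "toy.gff3"
        _write_gff3(genes, p)
        asm = parse_assembly(p, "gff3")
        assert len(asm.genes) == 3
        assert [g.gene_id for g in asm.genes] == ["g1", "g2", "g3"]
        assert asm.genes[0].aa_length == 99  # (300/3)-1

    def test_gff3_and_tsv_routes_agree(self, tmp_path):
        """The same toy genome rendered in both dialects parses to the
        same genes and hence identical directons."""
        genes = [make_gene("g1", 100, 99), make_gene("g2", 450, 99),
                 make_gene("g3", 2000, 49, "-")]
        pg, pt = tmp_path / "a.gff3", tmp_path / "a.tsv"
        _write_gff3(genes, pg)
        _write_gene_tsv(genes, pt)
        a1, a2 = parse_assembly(pg, "gff3"), parse_assembly(pt, "gene_tsv")
        key = lambda g: (g.contig_id, g.start, g.end, g.strand, g.aa_length)
        assert [key(g) for g in a1.genes] == [key(g) for g in a2.genes]
        d1 = [[g.gene_id for g in d.genes] for d in build_directons(a1)]
        d2 = [[g.gene_id for g in d.genes] for d in build_directons(a2)]
        assert d1 == d2

    def test_genbank_route_matches_gff3(self, tmp_path):
        genes = [make_gene("g1", 100, 99), make_gene("g2", 450, 99),
                 make_gene("g3", 2000, 49, "-")]
        pg, pb = tmp_path / "a.gff3", tmp_path / "a.gbk"
        _write_gff3(genes, pg)
        _write_genbank(genes, pb)
        a1, a2 = parse_assembly(pg, "gff3"), parse_assembly(pb, "genbank")
        key = lambda g: (g.start, g.end, g.strand, g.aa_length)
        assert sorted(map(key, a1.genes)) == sorted(map(key, a2.genes))

    def test_empty_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(ValueError):
            parse_assembly(p, "gene_tsv")

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("toy\tc1\tg1\t100\n")
        with pytest.raises(ValueError, match=":1"):
            parse_assembly(p, "gene_tsv")

    def test_duplicate_protein_id_rejected(self, tmp_path):
        genes = [make_gene("g1", 100, 50), make_gene("g1", 900, 50)]
        p = tmp_path / "dup.tsv"
        _write_gene_tsv(genes, p)
        with pytest.raises(ValueError, match="duplicate"):
            parse_assembly(p, "gene_tsv")

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "x.bin"
        p.write_text("x")
        with pytest.raises(ValueError, match="unknown format"):
            parse_assembly(p, "bam")


class TestAssembly:
    def test_genes_sorted_on_construction(self):
        genes = [make_gene("b", 900, 50), make_gene("a", 100, 50)]
        asm = Assembly(assembly_id="x", genes=genes)
        assert [g.gene_id for g in asm.genes] == ["a", "b"]

    def test_gene_beyond_contig_length_rejected(self):
        with pytest.raises(ValueError):
            Assembly(
                assembly_id="x",
                genes=[make_gene("a", 100, 50)],
                contig_lengths={"c1": 120},
            )
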