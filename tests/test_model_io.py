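"""Data-model contracts and round-trips through the file formats."""

import pytest

from genecontext import io as gio
from genecontext.model import (
    Gene,
    GeneContextError,
    Genome,
    GenomePanel,
    PipelineConfig,
)
from genecontext.simulate import emit


def make_gene(**kw):
    base = dict(
        gene_id="g1", genome_id="G", contig_id="c", start=10, end=100, strand="+"
    )
    base.update(kw)
    return Gene(**base)


class TestGeneInvariants:
    @pytest.mark.parametrize(
        "kw",
        [
            {"start": 0},
            {"start": 100, "end": 10},
            {"strand": "?"},
            {"strand": "."},
        ],
    )
    def test_invalid_coordinates_or_strand_rejected(self, kw):
        with pytest.raises(GeneContextError):
            make_gene(**kw)

    def test_length_is_inclusive(self):
        assert make_gene(start=10, end=10).length == 1
        assert make_gene(start=10, end=100).length == 91


class TestGenomePanel:
    def test_genes_sorted_by_start_within_contig(self):
        genome = Genome(genome_id="G", species_id="s")
        for start in (500, 10, 200):
            genome.add_gene(make_gene(gene_id=f"g{start}", start=start, end=start + 50))
        assert [g.start for g in genome.contigs["c"]] == [10, 200, 500]

    def test_duplicate_gene_id_rejected(self):
        g1 = Genome(genome_id="A", species_id="s", contigs={"c": [make_gene()]})
        g2 = Genome(
            genome_id="B", species_id="s",
            contigs={"c": [make_gene(genome_id="B")]},
        )
        panel = GenomePanel([g1])
        with pytest.raises(GeneContextError, match="g1"):
            panel.add_genome(g2)

    def test_empty_species_rejected(self):
        with pytest.raises(GeneContextError):
            Genome(genome_id="G", species_id="")


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"evalue_max": 0.0},
            {"family_size_max": 0},
            {"fc_min_for_code": 0},
            {"derep_identity": 0.0},
            {"derep_identity": 1.2},
            {"cluster_mode": "nearest"},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(GeneContextError):
            PipelineConfig(**kw)


class TestGff3Reading:
    def test_empty_gff3_gives_empty_genome(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("##gff-version 3\n# nothing here\n")
        panel = gio.read_genome_panel([path])
        assert panel.genomes["empty"].n_genes == 0

    def test_out_of_order_cds_sorted_by_start(self, tmp_path):
        path = tmp_path / "g.gff3"
        rows = [
            ("c1", 900, 1400, "a"),
            ("c1", 10, 500, "b"),
            ("c1", 600, 850, "c"),
        ]
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for contig, start, end, gid in rows:
                fh.write(
                    f"{contig}\tsrc\tCDS\t{start}\t{end}\t.\t+\t0\tID={gid}\n"
                )
        panel = gio.read_genome_panel([path])
        assert [g.gene_id for g in panel.genomes["g"].genes()] == ["b", "c", "a"]

    def test_end_before_start_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text(
            "##gff-version 3\nc1\tsrc\tCDS\t500\t100\t.\t+\t0\tID=x\n"
        )
        with pytest.raises(Exception):
            gio.read_genome_panel([path])

    def test_emitted_fixture_round_trips_identically(self, tmp_path):
        res = emit("tiny", tmp_path / "run", seed=5)
        inputs = gio.load_run_dir(tmp_path / "run")
        assert sorted(inputs.panel.genomes) == sorted(res.panel.genomes)
        for gid, genome in res.panel.genomes.items():
            read_back = inputs.panel.genomes[gid]
            assert [
                (g.gene_id, g.start, g.end, g.strand, g.function, g.protein)
                for g in genome.genes()
            ] == [
                (g.gene_id, g.start, g.end, g.strand, g.function, g.protein)
                for g in read_back.genes()
            ]
            assert read_back.species_id == genome.species_id
            assert read_back.strain_group_id == genome.strain_group_id
        fams_orig = {
            f.family_id: (frozenset(f.member_gene_ids), f.status)
            for f in res.families
        }
        fams_read = {
            f.family_id: (frozenset(f.member_gene_ids), f.status)
            for f in inputs.families
        }
        assert fams_orig == fams_read


class TestBlastTabular:
    HEADER_ROW = "q1\ts1\t85.0\t100\t15\t0\t1\t100\t1\t100\t{ev}\t180.0"

    def test_evalue_parsed(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.HEADER_ROW.format(ev="1e-30") + "\n")
        hits = gio.read_hits(path)
        assert len(hits) == 1
        assert hits[0].evalue == pytest.approx(1e-30)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert gio.read_hits(path) == []

    def test_rows_preserved_in_order(self, tmp_path):
        path = tmp_path / "hits.tsv"
        rows = [
            f"q{i}\ts{i}\t50.0\t100\t50\t0\t1\t100\t1\t100\t1e-{10 + i}\t99.0"
            for i in range(5)
        ]
        path.write_text("\n".join(rows) + "\n")
        hits = gio.read_hits(path)
        assert [h.query_id for h in hits] == [f"q{i}" for i in range(5)]

    def test_malformed_row_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "only\tthree\tcols\n" + self.HEADER_ROW.format(ev="1e-20") + "\n"
        )
        import logging

        with caplog.at_level(logging.WARNING):
            hits = gio.read_hits(path)
        assert len(hits) == 1
        assert any("row 1" in r.message for r in caplog.records)

    def test_non_numeric_evalue_is_hard_error(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.HEADER_ROW.format(ev="abc") + "\n")
        with pytest.raises(GeneContextError, match="evalue"):
            gio.read_hits(path)

    def test_query_coverage_from_lengths(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\ts1\t85.0\t50\t5\t0\t11\t60\t1\t50\t1e-20\t90.0\n")
        hits = gio.read_hits(path, query_lengths={"q1": 100})
        assert hits[0].aln_query_cov == pytest.approx(0.5)
        hits = gio.read_hits(path)
        assert hits[0].aln_query_cov is None


class TestWriteTables:
    def test_same_records_written_twice_are_byte_identical(
        self, tmp_path, default_pipeline
    ):
        gio.write_tables(default_pipeline.candidates, tmp_path / "a")
        gio.write_tables(default_pipeline.candidates, tmp_path / "b")
        assert (tmp_path / "a" / "candidates.tsv").read_bytes() == (
            tmp_path / "b" / "candidates.tsv"
        ).read_bytes()

    def test_empty_record_list_gives_header_only(self, tmp_path):
        paths = gio.write_tables([], tmp_path)
        lines = paths["candidates"].read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("rank\t")

    def test_row_count_matches_records(self, tmp_path, default_pipeline):
        records = default_pipeline.candidates[:3]
        paths = gio.write_tables(records, tmp_path)
        assert len(paths["candidates"].read_text().splitlines()) == 4
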