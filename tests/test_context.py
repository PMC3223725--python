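"""Dereplication, run detection, FC scores, evidence codes, CBSS."""

import numpy as np
import pytest

from genecontext.context import (
    CouplingEdge,
    build_cbss,
    cluster_length,
    compute_fc,
    dereplicate,
    detect_runs,
    detect_runs_panel,
    evidence_codes,
)
from genecontext.model import (
    FamilyAssignment,
    Gene,
    GeneContextError,
    Genome,
    GenomePanel,
    PipelineConfig,
)

from conftest import brute_force_fc, random_panel


def linear_genome(genome_id, spec, species=None, gap=100, group=None):
    """Build a genome from a strand/family spec like [('+','A'),('-','B')]."""
    genome = Genome(
        genome_id=genome_id,
        species_id=species or genome_id,
        strain_group_id=group,
    )
    pos = 1
    for i, (strand, fam) in enumerate(spec):
        genome.add_gene(
            Gene(
                gene_id=f"{genome_id}:{i}:{fam}", genome_id=genome_id,
                contig_id="c", start=pos, end=pos + 899, strand=strand,
            )
        )
        pos += 900 + gap
    return genome


def families_from_panel(panel, statuses=None):
    members = {}
    for gene in panel.genes():
        fam = gene.gene_id.split(":")[-1]
        members.setdefault(fam, set()).add(gene.gene_id)
    return [
        FamilyAssignment(
            family_id=f, member_gene_ids=m,
            status=(statuses or {}).get(f, "hypothetical"),
        )
        for f, m in sorted(members.items())
    ]


class TestDereplicate:
    def _panel(self, n, labels=None):
        return GenomePanel(
            [
                linear_genome(
                    f"G{i}", [("+", "A")],
                    group=(labels[i] if labels else None),
                )
                for i in range(n)
            ]
        )

    @pytest.mark.parametrize(
        "identity,n_groups", [(1.0, 1), (0.96, 1), (0.94, 2)]
    )
    def test_identity_threshold(self, identity, n_groups, config):
        panel = self._panel(2)
        ident = {frozenset(("G0", "G1")): identity}
        assert len(dereplicate(panel, ident, config)) == n_groups

    def test_close_strains_counted_once_plus_distant(self, config):
        panel = self._panel(4)
        ident = {}
        for i in range(3):
            for j in range(i + 1, 3):
                ident[frozenset((f"G{i}", f"G{j}"))] = 0.99
        for i in range(3):
            ident[frozenset((f"G{i}", "G3"))] = 0.6
        groups = dereplicate(panel, ident, config)
        assert len(groups) == 2
        sizes = sorted(len(g.member_genome_ids) for g in groups)
        assert sizes == [1, 3]
        assert all(g.representative_genome_id in g.member_genome_ids for g in groups)

    def test_labels_take_precedence(self, config):
        panel = self._panel(3, labels=["x", "x", "y"])
        groups = dereplicate(panel, None, config)
        assert sorted(g.group_id for g in groups) == ["x", "y"]

    def test_missing_identity_is_hard_error(self, config):
        panel = self._panel(2)
        with pytest.raises(GeneContextError, match="identity"):
            dereplicate(panel, {}, config)


class TestDetectRuns:
    def test_alternating_strands_large_gaps_no_runs(self, config):
        genome = linear_genome(
            "G", [("+", "A"), ("-", "B"), ("+", "C"), ("-", "D")], gap=500
        )
        assert detect_runs(genome, config, "same_strand_run") == []

    def test_four_same_strand_genes_small_gaps_one_run(self, config):
        genome = linear_genome(
            "G", [("+", "A"), ("+", "B"), ("+", "C"), ("+", "D")], gap=100
        )
        runs = detect_runs(genome, config, "same_strand_run")
        assert len(runs) == 1
        assert runs[0].length == 4

    def test_gap_boundary_is_strict(self, config):
        tight = linear_genome("G", [("+", "A"), ("+", "B")], gap=299)
        exact = linear_genome("H", [("+", "A"), ("+", "B")], gap=300)
        assert len(detect_runs(tight, config, "same_strand_run")) == 1
        assert detect_runs(exact, config, "same_strand_run") == []

    def test_window_pairs_bounded_by_position_distance(self, config):
        genome = linear_genome("G", [("+", f"F{i}") for i in range(8)], gap=500)
        runs = detect_runs(genome, config, "window")
        pairs = set()
        for run in runs:
            ids = run.gene_ids
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    pairs.add(frozenset((ids[i], ids[j])))
        genes = list(genome.genes())
        expected = {
            frozenset((genes[i].gene_id, genes[j].gene_id))
            for i in range(8)
            for j in range(i + 1, 8)
            if j - i <= config.neighbor_window_genes
        }
        assert pairs == expected

    def test_planted_cluster_in_one_run_everywhere_retained(
        self, default_sim, config
    ):
        res = default_sim
        for cid, fams in res.truth.planted_clusters.items():
            for genome in res.panel.prokaryotic_genomes():
                if genome.species_id not in res.truth.cluster_retention[cid]:
                    continue
                runs = detect_runs(genome, config, "same_strand_run")
                member_ids = {
                    g.gene_id
                    for g in genome.genes()
                    if g.gene_id.split("|")[-1] in fams
                }
                assert any(
                    member_ids <= set(run.gene_ids) for run in runs
                ), (cid, genome.genome_id)


class TestComputeFc:
    def make_three_strain_case(self):
        """Pair A-B co-localized in 3 strains of one group + 4 other groups."""
        genomes = []
        for s in range(3):
            genomes.append(
                linear_genome(
                    f"EC{s}", [("+", "A"), ("+", "B"), ("-", "X")],
                    species="ecoli", group="ecoli",
                )
            )
        for k in range(4):
            genomes.append(
                linear_genome(
                    f"D{k}", [("+", "A"), ("+", "B"), ("+", f"Z{k}")],
                    species=f"dist{k}", group=f"dist{k}",
                )
            )
        return GenomePanel(genomes)

    def test_strains_counted_once(self, config):
        panel = self.make_three_strain_case()
        families = families_from_panel(panel)
        groups = dereplicate(panel, None, config)
        runs = detect_runs_panel(panel, config, "same_strand_run")
        edges = compute_fc(runs, families, groups, config)
        edge = next(
            e for e in edges if {e.family_a, e.family_b} == {"A", "B"}
        )
        assert edge.fc_score == 5
        assert len(edge.supporting_group_ids) == 5

    def test_never_colocalized_pair_absent(self, config):
        panel = GenomePanel(
            [linear_genome("G", [("+", "A"), ("-", "B")], gap=500, group="g")]
        )
        edges = compute_fc(
            detect_runs_panel(panel, config, "same_strand_run"),
            families_from_panel(panel),
            dereplicate(panel, None, config),
            config,
        )
        assert edges == []

    def test_symmetry_under_family_relabeling(self, config):
        panel = self.make_three_strain_case()
        families = families_from_panel(panel)
        groups = dereplicate(panel, None, config)
        runs = detect_runs_panel(panel, config)
        edges_fwd = compute_fc(runs, families, groups, config)
        edges_rev = compute_fc(runs, list(reversed(families)), groups, config)
        as_set = lambda edges: {
            (e.family_a, e.family_b, e.fc_score) for e in edges
        }
        assert as_set(edges_fwd) == as_set(edges_rev)

    @pytest.mark.parametrize("mode", ["same_strand_run", "window", "either"])
    def test_matches_brute_force_on_random_panels(self, mode):
        rng = np.random.default_rng(2024)
        config = PipelineConfig(cluster_mode=mode)
        for _ in range(10):
            panel, families = random_panel(rng)
            groups = dereplicate(panel, None, config)
            runs = detect_runs_panel(panel, config, mode)
            edges = compute_fc(runs, families, groups, config)
            got = {
                frozenset((e.family_a, e.family_b)): e.fc_score for e in edges
            }
            assert got == brute_force_fc(panel, families, groups, config)

    def test_exact_copy_genome_changes_no_score(self, config):
        panel = self.make_three_strain_case()
        families = families_from_panel(panel)

        def scores(p, fams):
            return {
                frozenset((e.family_a, e.family_b)): e.fc_score
                for e in compute_fc(
                    detect_runs_panel(p, config),
                    fams,
                    dereplicate(p, None, config),
                    config,
                )
            }

        base = scores(panel, families)
        clone = linear_genome(
            "EC9", [("+", "A"), ("+", "B"), ("-", "X")],
            species="ecoli", group="ecoli",
        )
        bigger = GenomePanel(
            list(panel.genomes.values()) + [clone]
        )
        fams2 = families_from_panel(bigger)
        assert scores(bigger, fams2) == base

    def test_widening_gap_threshold_never_decreases_scores(self):
        rng = np.random.default_rng(7)
        panel, families = random_panel(rng)
        narrow = PipelineConfig(cluster_gap_bp=150, cluster_mode="same_strand_run")
        wide = PipelineConfig(cluster_gap_bp=600, cluster_mode="same_strand_run")
        groups = dereplicate(panel, None, narrow)

        def scores(cfg):
            return {
                frozenset((e.family_a, e.family_b)): e.fc_score
                for e in compute_fc(
                    detect_runs_panel(panel, cfg, "same_strand_run"),
                    families, groups, cfg,
                )
            }

        s_narrow, s_wide = scores(narrow), scores(wide)
        for pair, score in s_narrow.items():
            assert s_wide.get(pair, 0) >= score


def make_edge(a, b, fc, status_a="hypothetical", status_b="hypothetical"):
    return CouplingEdge(
        family_a=a, family_b=b, fc_score=fc,
        supporting_group_ids=frozenset(f"g{i}" for i in range(fc)),
        status_a=status_a, status_b=status_b,
    )


class TestEvidenceCodes:
    FAMS = [
        FamilyAssignment(family_id="H", member_gene_ids={"h1"}),
        FamilyAssignment(
            family_id="K", member_gene_ids={"k1"}, status="non_hypothetical"
        ),
        FamilyAssignment(family_id="H2", member_gene_ids={"h2"}),
    ]

    def test_fc_five_to_known_sets_cwn(self, config):
        edges = [make_edge("H", "K", 5, status_b="non_hypothetical")]
        codes = evidence_codes(edges, self.FAMS, config)
        assert codes["H"] == (True, False, 5)

    def test_fc_four_sets_nothing(self, config):
        edges = [make_edge("H", "K", 4, status_b="non_hypothetical")]
        codes = evidence_codes(edges, self.FAMS, config)
        assert codes["H"] == (False, False, 4)

    def test_partner_status_routes_codes(self, config):
        edges = [
            make_edge("H", "H2", 6),
            make_edge("H", "K", 2, status_b="non_hypothetical"),
        ]
        codes = evidence_codes(edges, self.FAMS, config)
        assert codes["H"] == (False, True, 6)

    def test_boundary_inclusive_both_codes(self, config):
        edges = [
            make_edge("H", "K", 5, status_b="non_hypothetical"),
            make_edge("H", "H2", 5),
        ]
        codes = evidence_codes(edges, self.FAMS, config)
        assert codes["H"] == (True, True, 5)


class TestClusterLength:
    def _runs(self, panel, config, mode="same_strand_run"):
        return detect_runs_panel(panel, config, mode)

    def test_isolated_family_length_one(self, config):
        panel = GenomePanel(
            [linear_genome("G", [("+", "A"), ("-", "B")], gap=500, group="g")]
        )
        fam = families_from_panel(panel)[0]
        assert cluster_length(self._runs(panel, config), fam) == 1

    def test_max_over_genomes(self, config):
        g1 = linear_genome(
            "G1", [("+", "A")] + [("+", f"F{i}") for i in range(5)],
            gap=100, group="g1",
        )
        g2 = linear_genome(
            "G2", [("+", "A"), ("+", "B"), ("+", "C")], gap=100, group="g2"
        )
        panel = GenomePanel([g1, g2])
        fam_a = next(
            f for f in families_from_panel(panel) if f.family_id == "A"
        )
        assert cluster_length(self._runs(panel, config), fam_a) == 6

    def test_absent_family_zero_with_warning(self, config, caplog):
        import logging

        panel = GenomePanel([linear_genome("G", [("+", "A")], group="g")])
        ghost = FamilyAssignment(family_id="ZZ", member_gene_ids={"nope"})
        with caplog.at_level(logging.WARNING):
            out = cluster_length(
                self._runs(panel, config), ghost,
                {g.gene_id for g in panel.genes()},
            )
        assert out == 0
        assert any("ZZ" in r.message for r in caplog.records)


class TestCbss:
    def test_no_qualifying_edges_empty(self, config):
        assert build_cbss([], TestEvidenceCodes.FAMS, config) == []

    def test_hypothetical_component_forms_one_cbss(self, config):
        fams = [
            FamilyAssignment(family_id=f, member_gene_ids={f.lower()})
            for f in ("A", "B", "C")
        ]
        edges = [make_edge("A", "B", 6), make_edge("B", "C", 7)]
        cbss = build_cbss(edges, fams, config)
        assert cbss == [("CBSS_A", frozenset({"A", "B", "C"}))]

    def test_known_endpoint_breaks_membership(self, config):
        fams = [
            FamilyAssignment(family_id="A", member_gene_ids={"a"}),
            FamilyAssignment(
                family_id="K", member_gene_ids={"k"}, status="non_hypothetical"
            ),
        ]
        edges = [make_edge("A", "K", 9, status_b="non_hypothetical")]
        assert build_cbss(edges, fams, config) == []

    def test_disjoint_planted_clusters_give_two_cbss(self, config):
        fams = [
            FamilyAssignment(family_id=f, member_gene_ids={f.lower()})
            for f in ("A", "B", "C", "D")
        ]
        edges = [make_edge("A", "B", 6), make_edge("C", "D", 8)]
        cbss = build_cbss(edges, fams, config)
        assert len(cbss) == 2
        assert {cid for cid, _ in cbss} == {"CBSS_A", "CBSS_C"}
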