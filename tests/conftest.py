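"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from genecontext.model import (
    FamilyAssignment,
    Gene,
    Genome,
    GenomePanel,
    PipelineConfig,
)
from genecontext.pipeline import run_pipeline
from genecontext.simulate import SimParams, preset_params, simulate

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# independent brute-force co-localization oracle (used against compute_fc)

def colocalized(genes: list[Gene], i: int, j: int, config: PipelineConfig) -> bool:
    """Direct pairwise co-localization predicate for coordinate-sorted genes.

    Same-strand: every gene between i and j shares the strand and every
    consecutive intergenic gap is under the threshold. Window: positional
    distance at most the window half-width, any strand.
    """
    ok = False
    if config.cluster_mode in ("same_strand_run", "either"):
        same_strand = all(
            genes[k].strand == genes[i].strand for k in range(i, j + 1)
        )
        gaps_ok = all(
            genes[k + 1].start - genes[k].end - 1 < config.cluster_gap_bp
            for k in range(i, j)
        )
        ok = same_strand and gaps_ok
    if not ok and config.cluster_mode in ("window", "either"):
        ok = (j - i) <= config.neighbor_window_genes
    return ok


def brute_force_fc(
    panel: GenomePanel,
    families: list[FamilyAssignment],
    groups,
    config: PipelineConfig,
) -> dict[frozenset, int]:
    """Exhaustive FC: enumerate every gene pair in every genome and count the
    distinct genome groups per co-localized family pair."""
    gene_fam = {
        gid: f.family_id for f in families for gid in f.member_gene_ids
    }
    genome_group = {
        gid: grp.group_id for grp in groups for gid in grp.member_genome_ids
    }
    pair_groups: dict[frozenset, set] = {}
    for genome in panel.prokaryotic_genomes():
        group = genome_group.get(genome.genome_id)
        if group is None:
            continue
        for genes in genome.contigs.values():
            for i in range(len(genes)):
                fa = gene_fam.get(genes[i].gene_id)
                if fa is None:
                    continue
                for j in range(i + 1, len(genes)):
                    fb = gene_fam.get(genes[j].gene_id)
                    if fb is None or fb == fa:
                        continue
                    if colocalized(genes, i, j, config):
                        pair_groups.setdefault(
                            frozenset((fa, fb)), set()
                        ).add(group)
    return {pair: len(gr) for pair, gr in pair_groups.items()}


def random_panel(
    rng: np.random.Generator,
    max_genomes: int = 10,
    max_genes: int = 40,
    n_family_pool: int = 12,
    n_groups: int = 4,
) -> tuple[GenomePanel, list[FamilyAssignment]]:
    """A structurally random panel: random strands, gaps, family labels and
    strain-group labels — stress input for the FC oracle comparison."""
    panel = GenomePanel()
    members: dict[str, set] = {f"RF{k:02d}": set() for k in range(n_family_pool)}
    n_genomes = int(rng.integers(2, max_genomes + 1))
    for g in range(n_genomes):
        genome_id = f"G{g:02d}"
        genome = Genome(
            genome_id=genome_id,
            species_id=f"spp{g:02d}",
            strain_group_id=f"grp{int(rng.integers(0, n_groups)):02d}",
        )
        n_genes = int(rng.integers(5, max_genes + 1))
        pos = 1
        for i in range(n_genes):
            length = int(rng.integers(200, 1500))
            gid = f"{genome_id}:g{i:03d}"
            fam = f"RF{int(rng.integers(0, n_family_pool)):02d}"
            genome.add_gene(
                Gene(
                    gene_id=gid,
                    genome_id=genome_id,
                    contig_id="c",
                    start=pos,
                    end=pos + length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    function="",
                )
            )
            members[fam].add(gid)
            pos += length + int(rng.integers(0, 600)) + 1
        panel.add_genome(genome)
    families = [
        FamilyAssignment(
            family_id=fid,
            member_gene_ids=m,
            status="hypothetical" if rng.random() < 0.5 else "non_hypothetical",
        )
        for fid, m in sorted(members.items())
        if m
    ]
    return panel, families


# ---------------------------------------------------------------------------
# shared simulations (session-scoped: generated once)

@pytest.fixture(scope="session")
def tiny_sim():
    return simulate(preset_params("tiny", seed=11))


@pytest.fixture(scope="session")
def default_sim():
    return simulate(preset_params("default", seed=1))


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    res = default_sim
    return run_pipeline(res.panel, res.euk_genes, res.hits, res.families)


@pytest.fixture()
def config():
    return PipelineConfig()


def small_recovery_params(seed: int) -> SimParams:
    """A scaled-down panel for invariance tests (fast, still structured)."""
    return SimParams(
        n_species=6,
        strains_per_species=(1, 2),
        genes_per_genome=60,
        n_families=80,
        n_planted_clusters=2,
        cluster_size=(2, 2),
        cluster_retention_prob=0.9,
        euk_shared_family_count=12,
        euk_only_gene_count=8,
        seed=seed,
    )
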