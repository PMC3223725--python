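"""Genomic-context evidence engine.

This module computes the chromosomal co-localization evidence the
prioritization rests on:

* **dereplication** — near-identical genomes (pairwise identity strictly
  above 0.95 by default) collapse into strain groups so that, say, dozens of
  sequenced strains of one species count once;
* **gene runs** — operon-like runs of consecutive same-strand genes with
  intergenic gaps under ``cluster_gap_bp``, and/or strand-blind windows of
  ``neighbor_window_genes`` positions (capturing divergently transcribed
  pairs and near-neighbours);
* **functional coupling (FC)** — for a pair of families, the number of
  distinct dereplicated genome groups containing at least one genome where
  members of both families share a run; multiple strains or runs within one
  group count once;
* **evidence codes** — ``cwn`` ("in cluster with non-hypothetical") and
  ``cwh`` ("in cluster with hypothetical"), which require FC >= 5 (inclusive)
  to a partner family of the respective status;
* **cluster length** — the maximum run length (gene count) over all runs
  containing a family member;
* **CBSS** — clustering-based subsystems: connected components of the
  coupling graph restricted to strong (FC >= threshold) edges between
  hypothetical families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .model import (
    FamilyAssignment,
    Gene,
    GeneContextError,
    Genome,
    GenomePanel,
    PipelineConfig,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeGroup:
    """A dereplicated group of near-identical genomes."""

    group_id: str
    member_genome_ids: frozenset[str]
    representative_genome_id: str

    def __post_init__(self) -> None:
        if self.representative_genome_id not in self.member_genome_ids:
            raise GeneContextError(
                f"group {self.group_id}: representative not a member"
            )


@dataclass(frozen=True)
class GeneRun:
    """An ordered stretch of co-localized genes on one contig."""

    genome_id: str
    contig_id: str
    gene_ids: tuple[str, ...]
    mode: str  # same_strand_run | window

    @property
    def length(self) -> int:
        return len(self.gene_ids)


@dataclass
class CouplingEdge:
    """Functional coupling between two families (unordered pair).

    ``fc_score`` counts dereplicated genome groups exhibiting co-localization
    and always equals ``len(supporting_group_ids)``.
    """

    family_a: str
    family_b: str
    fc_score: int
    supporting_group_ids: frozenset[str]
    status_a: str = "hypothetical"
    status_b: str = "hypothetical"

    def __post_init__(self) -> None:
        if self.family_a > self.family_b:
            self.family_a, self.family_b = self.family_b, self.family_a
            self.status_a, self.status_b = self.status_b, self.status_a
        if self.fc_score != len(self.supporting_group_ids):
            raise GeneContextError(
                f"edge {self.family_a}-{self.family_b}: fc_score inconsistent "
                "with supporting groups"
            )

    def partner_of(self, family_id: str) -> tuple[str, str]:
        """Return (partner family id, partner status)."""
        if family_id == self.family_a:
            return self.family_b, self.status_b
        if family_id == self.family_b:
            return self.family_a, self.status_a
        raise GeneContextError(f"{family_id} not on edge")


@dataclass
class EvidenceSummary:
    """Per-family bundle of genomic-context evidence."""

    family_id: str
    fc_max: int = 0
    cwn: bool = False
    cwh: bool = False
    cluster_length_max: int = 0
    phyletic_spread: int = 0
    in_model_organism: bool = False
    cbss_ids: set[str] = field(default_factory=set)


def dereplicate(
    panel: GenomePanel,
    pairwise_identity: Optional[Mapping[frozenset, float]] = None,
    config: Optional[PipelineConfig] = None,
) -> list[GenomeGroup]:
    """Collapse near-identical prokaryotic genomes into strain groups.

    Pre-assigned ``strain_group_id`` labels win when every prokaryotic genome
    carries one. Otherwise genomes are grouped by single linkage over pairs
    with identity strictly greater than ``derep_identity`` (default 0.95:
    genomes at 95% identity or less stay distinct). The representative is the
    lexicographically smallest member. Missing identity for any pair when
    labels are absent is a hard error.
    """
    config = config or PipelineConfig()
    genomes = panel.prokaryotic_genomes()
    if not genomes:
        return []

    if all(g.strain_group_id for g in genomes):
        by_label: dict[str, list[str]] = {}
        for g in genomes:
            by_label.setdefault(g.strain_group_id, []).append(g.genome_id)
        groups = [
            GenomeGroup(label, frozenset(members), min(members))
            for label, members in sorted(by_label.items())
        ]
        return sorted(groups, key=lambda g: g.group_id)

    if pairwise_identity is None:
        raise GeneContextError(
            "dereplicate: need strain_group_id labels on every prokaryotic "
            "genome or a pairwise identity matrix"
        )
    graph = nx.Graph()
    ids = [g.genome_id for g in genomes]
    graph.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            key = frozenset((a, b))
            if key not in pairwise_identity:
                raise GeneContextError(
                    f"dereplicate: missing pairwise identity for {a!r}, {b!r}"
                )
            if pairwise_identity[key] > config.derep_identity:
                graph.add_edge(a, b)
    groups = []
    for comp in nx.connected_components(graph):
        rep = min(comp)
        groups.append(GenomeGroup(f"GRP_{rep}", frozenset(comp), rep))
    return sorted(groups, key=lambda g: g.group_id)


def _intergenic_gap(left: Gene, right: Gene) -> int:
    """Gap in bp between two coordinate-sorted genes (negative if overlapping)."""
    return right.start - left.end - 1


def detect_runs(
    genome: Genome,
    config: PipelineConfig,
    mode: Optional[str] = None,
) -> list[GeneRun]:
    """Detect co-localization runs in one genome.

    ``same_strand_run``: maximal runs of >= 2 consecutive same-strand genes
    whose intergenic gaps are all strictly under ``cluster_gap_bp``.
    ``window``: for each gene, the strand-blind stretch from it to the next
    ``neighbor_window_genes`` genes, so two genes share a window run iff they
    are within that many positions of each other. ``either``: both run sets.
    """
    mode = mode or config.cluster_mode
    runs: list[GeneRun] = []
    if mode in ("same_strand_run", "either"):
        for contig_id in sorted(genome.contigs):
            genes = genome.contigs[contig_id]
            i = 0
            while i < len(genes):
                j = i
                while (
                    j + 1 < len(genes)
                    and genes[j + 1].strand == genes[i].strand
                    and _intergenic_gap(genes[j], genes[j + 1]) < config.cluster_gap_bp
                ):
                    j += 1
                if j > i:
                    runs.append(
                        GeneRun(
                            genome.genome_id,
                            contig_id,
                            tuple(g.gene_id for g in genes[i : j + 1]),
                            "same_strand_run",
                        )
                    )
                i = j + 1
    if mode in ("window", "either"):
        k = config.neighbor_window_genes
        for contig_id in sorted(genome.contigs):
            genes = genome.contigs[contig_id]
            for i in range(len(genes)):
                stretch = genes[i : i + k + 1]
                if len(stretch) >= 2:
                    runs.append(
                        GeneRun(
                            genome.genome_id,
                            contig_id,
                            tuple(g.gene_id for g in stretch),
                            "window",
                        )
                    )
    return runs


def detect_runs_panel(
    panel: GenomePanel, config: PipelineConfig, mode: Optional[str] = None
) -> dict[str, list[GeneRun]]:
    return {
        gid: detect_runs(panel.genomes[gid], config, mode)
        for gid in sorted(panel.genomes)
        if panel.genomes[gid].is_prokaryote
    }


def compute_fc(
    runs_by_genome: Mapping[str, Sequence[GeneRun]],
    families: Sequence[FamilyAssignment],
    groups: Sequence[GenomeGroup],
    config: Optional[PipelineConfig] = None,
) -> list[CouplingEdge]:
    """Compute functional-coupling scores for co-localized family pairs.

    For each unordered family pair, the FC score is the number of genome
    groups containing at least one genome in which members of both families
    share a run; co-occurrence is counted once per group no matter how many
    strains or runs show it. Pairs never co-localized are omitted. The edge
    set is symmetric by construction and independent of run or gene order.
    """
    gene_to_family: dict[str, str] = {}
    status_of: dict[str, str] = {}
    for fam in families:
        status_of[fam.family_id] = fam.status
        for gid in fam.member_gene_ids:
            gene_to_family[gid] = fam.family_id

    genome_to_group = {
        gid: grp.group_id for grp in groups for gid in grp.member_genome_ids
    }

    pair_groups: dict[tuple[str, str], set[str]] = {}
    for genome_id in sorted(runs_by_genome):
        group_id = genome_to_group.get(genome_id)
        if group_id is None:
            continue
        for run in runs_by_genome[genome_id]:
            fams_in_run = sorted(
                {
                    gene_to_family[g]
                    for g in run.gene_ids
                    if g in gene_to_family
                }
            )
            for i, fa in enumerate(fams_in_run):
                for fb in fams_in_run[i + 1 :]:
                    pair_groups.setdefault((fa, fb), set()).add(group_id)

    edges = [
        CouplingEdge(
            family_a=fa,
            family_b=fb,
            fc_score=len(supp),
            supporting_group_ids=frozenset(supp),
            status_a=status_of.get(fa, "hypothetical"),
            status_b=status_of.get(fb, "hypothetical"),
        )
        for (fa, fb), supp in sorted(pair_groups.items())
    ]
    return edges


def _counts_for_cwh(status: str) -> bool:
    # vague families are unknowns for evidence purposes
    return status in ("hypothetical", "vague")


def evidence_codes(
    edges: Sequence[CouplingEdge],
    families: Sequence[FamilyAssignment],
    config: PipelineConfig,
) -> dict[str, tuple[bool, bool, int]]:
    """Derive (cwn, cwh, fc_max) per family from the coupling edges.

    cwn requires an edge with FC >= ``fc_min_for_code`` (inclusive) to a
    non-hypothetical partner; cwh the same to a hypothetical (or vague)
    partner; fc_max is the maximum FC over all edges, 0 if none.
    """
    out = {f.family_id: [False, False, 0] for f in families}
    for edge in edges:
        for fid in (edge.family_a, edge.family_b):
            if fid not in out:
                continue
            partner, partner_status = edge.partner_of(fid)
            rec = out[fid]
            rec[2] = max(rec[2], edge.fc_score)
            if edge.fc_score >= config.fc_min_for_code:
                if partner_status == "non_hypothetical":
                    rec[0] = True
                elif _counts_for_cwh(partner_status):
                    rec[1] = True
    return {fid: (cwn, cwh, fc) for fid, (cwn, cwh, fc) in out.items()}


def cluster_length(
    runs_by_genome: Mapping[str, Sequence[GeneRun]],
    family: FamilyAssignment,
    panel_gene_ids: Optional[set[str]] = None,
) -> int:
    """Maximum run length over all runs containing a member of the family.

    Returns 1 when the family occurs in the panel but never inside a run, and
    0 (with a warning) when it is absent from the panel entirely. Length is
    measured over operon-like (same-strand) runs when present; window runs
    are positional neighborhoods, not clusters, and only bound the length
    when no same-strand runs were supplied.
    """
    members = set(family.member_gene_ids)
    if panel_gene_ids is not None and not members & panel_gene_ids:
        logger.warning(
            "cluster_length: family %s absent from panel", family.family_id
        )
        return 0

    any_same_strand_runs = False
    best_ss = 0
    best_window = 0
    for runs in runs_by_genome.values():
        for run in runs:
            if run.mode == "same_strand_run":
                any_same_strand_runs = True
            if members.intersection(run.gene_ids):
                if run.mode == "same_strand_run":
                    best_ss = max(best_ss, run.length)
                else:
                    best_window = max(best_window, run.length)
    if best_ss:
        return best_ss
    if not any_same_strand_runs and best_window:
        return best_window
    return 1


def build_cbss(
    edges: Sequence[CouplingEdge],
    families: Sequence[FamilyAssignment],
    config: PipelineConfig,
) -> list[tuple[str, frozenset[str]]]:
    """Group hypothetical families into clustering-based subsystems.

    Connected components of the coupling graph restricted to edges with
    FC >= ``fc_min_for_code`` and both endpoints hypothetical (or vague);
    components of >= 2 families become CBSS with deterministic ids
    (``CBSS_`` + smallest member family id). Sorted by id.
    """
    status_of = {f.family_id: f.status for f in families}
    graph = nx.Graph()
    for edge in edges:
        if edge.fc_score < config.fc_min_for_code:
            continue
        if _counts_for_cwh(status_of.get(edge.family_a, "")) and _counts_for_cwh(
            status_of.get(edge.family_b, "")
        ):
            graph.add_edge(edge.family_a, edge.family_b)
    cbss = [
        (f"CBSS_{min(comp)}", frozenset(comp))
        for comp in nx.connected_components(graph)
        if len(comp) >= 2
    ]
    return sorted(cbss)
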