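"""Protein family construction by single-linkage clustering of homology hits.

Families are connected components of the hit graph restricted to edges with
``evalue < evalue_max``. Single-linkage components reproduce the semantics of
the size filter the analysis needs (drop eukaryote families with four or more
members) with a single parameter; no Markov-style clustering is attempted, so
one spurious inter-family edge will merge two true families — a documented
property of single linkage. Family IDs are deterministic: ``FAM_`` plus the
lexicographically smallest member gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .model import (
    FamilyAssignment,
    Gene,
    GeneContextError,
    PipelineConfig,
    validate_partition,
)
from . import status as status_mod

logger = logging.getLogger(__name__)

SIZE_CLASSES = ("singleton", "duplet", "triplet", "large")


def size_class_of(size: int) -> str:
    if size <= 0:
        raise GeneContextError(f"family size must be positive, got {size}")
    return {1: "singleton", 2: "duplet", 3: "triplet"}.get(size, "large")


@dataclass(frozen=True)
class EukFamily:
    """A eukaryote (within-proteome) protein family."""

    family_id: str
    member_gene_ids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)

    @property
    def size_class(self) -> str:
        return size_class_of(self.size)


def family_id_for(members: Iterable[str]) -> str:
    return "FAM_" + min(members)


def _components(
    node_ids: Iterable[str], hits, evalue_max: float
) -> list[set[str]]:
    graph = nx.Graph()
    graph.add_nodes_from(node_ids)
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        if hit.evalue < evalue_max and hit.query_id in graph and hit.subject_id in graph:
            graph.add_edge(hit.query_id, hit.subject_id)
    return [set(c) for c in nx.connected_components(graph)]


def build_euk_families(
    euk_genes: Sequence[Gene], within_proteome_hits, config: PipelineConfig
) -> list[EukFamily]:
    """Cluster the eukaryote proteome into families via single linkage.

    Hits must be eukaryote-eukaryote; edges require ``evalue < evalue_max``.
    Every gene lands in exactly one family; genes with no qualifying edge are
    singletons. Output sorted by family_id.
    """
    euk_ids = {g.gene_id for g in euk_genes}
    for hit in within_proteome_hits:
        if hit.query_id not in euk_ids or hit.subject_id not in euk_ids:
            raise GeneContextError(
                f"within-proteome hit {hit.query_id}->{hit.subject_id} references "
                "a non-eukaryote gene"
            )
    comps = _components(euk_ids, within_proteome_hits, config.evalue_max)
    families = [
        EukFamily(family_id_for(c), frozenset(c)) for c in comps
    ]
    families.sort(key=lambda f: f.family_id)
    return families


def filter_small_families(
    families: Sequence[EukFamily], config: PipelineConfig
) -> list[EukFamily]:
    """Retain families with at most ``family_size_max`` members (default 3).

    Families with more members are excluded because large families mix
    functions. Idempotent; retained/excluded counts are logged per size class.
    """
    retained = [f for f in families if f.size <= config.family_size_max]
    excluded = [f for f in families if f.size > config.family_size_max]
    for cls in SIZE_CLASSES:
        n_ret = sum(1 for f in retained if f.size_class == cls)
        n_exc = sum(1 for f in excluded if f.size_class == cls)
        if n_ret or n_exc:
            logger.info(
                "family size filter: %s retained=%d excluded=%d", cls, n_ret, n_exc
            )
    return retained


def assign_cross_genome_families(
    all_genes: Sequence[Gene],
    hits,
    curated: Optional[list[FamilyAssignment]],
    config: PipelineConfig,
    subsystems: Optional[dict[str, dict[str, str]]] = None,
    puf_list: Optional[set[str]] = None,
) -> list[FamilyAssignment]:
    """Assign every gene (prokaryotic and eukaryotic) to a cross-genome family.

    Curated assignments win unchanged when supplied (a gene in two curated
    families is a hard error). Otherwise families are single-linkage
    components over ``evalue < evalue_max`` edges; ``subsystems`` optionally
    maps a family id to ``{subsystem_id: class}`` by the deterministic id the
    component would receive, and family status is derived from subsystem
    classes and member function strings (see :mod:`genecontext.status`).
    """
    if curated is not None:
        validate_partition(curated)
        return list(curated)

    genes_by_id = {g.gene_id: g for g in all_genes}
    comps = _components(genes_by_id, hits, config.evalue_max)
    families = []
    for comp in comps:
        fid = family_id_for(comp)
        classes = dict((subsystems or {}).get(fid, {}))
        fam = FamilyAssignment(
            family_id=fid,
            member_gene_ids=set(comp),
            subsystem_classes=classes,
        )
        fam.status = status_mod.derive_family_status(fam, genes_by_id, puf_list)
        families.append(fam)
    families.sort(key=lambda f: f.family_id)
    return families
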