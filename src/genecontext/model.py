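"""Core data model: genes, genomes, families, homology hits, pipeline configuration.

Coordinates are GFF3-style throughout: 1-based, inclusive on both ends.
No operation in this package interprets coordinates as half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Mapping, Optional

Strand = Literal["+", "-"]
Domain = Literal["bacteria", "archaea", "eukaryote"]

#: Family / gene annotation statuses. ``vague`` marks generic annotations
#: ("ATPase", "putative") that are treated as unknown during candidate selection.
Status = Literal["non_hypothetical", "hypothetical", "vague"]

#: Subsystem classes. Only ``non_hypothetical`` subsystems encode established
#: biology; ``experimental`` and ``clustering_based`` group uncharacterized genes.
SubsystemClass = Literal["non_hypothetical", "experimental", "clustering_based"]

PROKARYOTE_DOMAINS = frozenset({"bacteria", "archaea"})


class GeneContextError(ValueError):
    """Raised for malformed inputs and contract violations."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene anchored on a contig.

    ``start``/``end`` are 1-based inclusive base-pair coordinates with
    ``end >= start``; ``strand`` is ``+`` or ``-``. ``function`` is a free-text
    annotation string (empty means unannotated); ``protein`` optionally carries
    the amino-acid sequence.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    function: str = ""
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise GeneContextError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise GeneContextError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise GeneContextError(
                f"gene {self.gene_id}: unknown strand symbol {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """One genome: ordered, stranded gene lists per contig plus panel metadata.

    ``strain_group_id`` optionally pre-assigns the genome to a dereplication
    group of near-identical strains (>95% overall sequence identity); when
    absent, grouping falls back on a pairwise identity matrix.
    """

    genome_id: str
    species_id: str
    domain: str = "bacteria"
    is_model_organism: bool = False
    strain_group_id: Optional[str] = None
    contigs: dict[str, list[Gene]] = field(default_factory=dict)
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.species_id:
            raise GeneContextError(f"genome {self.genome_id}: empty species_id")
        if self.domain not in ("bacteria", "archaea", "eukaryote"):
            raise GeneContextError(
                f"genome {self.genome_id}: unknown domain {self.domain!r}"
            )
        for contig_id, genes in self.contigs.items():
            self.contigs[contig_id] = sorted(genes, key=lambda g: (g.start, g.end))
            self.circular.setdefault(contig_id, False)

    @property
    def is_prokaryote(self) -> bool:
        return self.domain in PROKARYOTE_DOMAINS

    def genes(self) -> Iterator[Gene]:
        for contig_id in sorted(self.contigs):
            yield from self.contigs[contig_id]

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.contigs.values())

    def add_gene(self, gene: Gene) -> None:
        genes = self.contigs.setdefault(gene.contig_id, [])
        genes.append(gene)
        genes.sort(key=lambda g: (g.start, g.end))
        self.circular.setdefault(gene.contig_id, False)


class GenomePanel:
    """A collection of genomes with a panel-wide unique gene index."""

    def __init__(self, genomes: Optional[list[Genome]] = None):
        self.genomes: dict[str, Genome] = {}
        self._gene_index: dict[str, Gene] = {}
        for g in genomes or []:
            self.add_genome(g)

    def add_genome(self, genome: Genome) -> None:
        if genome.genome_id in self.genomes:
            raise GeneContextError(f"duplicate genome_id {genome.genome_id!r}")
        for gene in genome.genes():
            if gene.gene_id in self._gene_index:
                raise GeneContextError(f"duplicate gene_id {gene.gene_id!r}")
        self.genomes[genome.genome_id] = genome
        for gene in genome.genes():
            self._gene_index[gene.gene_id] = gene

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def __len__(self) -> int:
        return len(self.genomes)

    def gene(self, gene_id: str) -> Gene:
        return self._gene_index[gene_id]

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def genes(self) -> Iterator[Gene]:
        for genome_id in sorted(self.genomes):
            yield from self.genomes[genome_id].genes()

    def genome_of(self, gene_id: str) -> Genome:
        return self.genomes[self._gene_index[gene_id].genome_id]

    def species_of(self, gene_id: str) -> str:
        return self.genome_of(gene_id).species_id

    def prokaryotic_genomes(self) -> list[Genome]:
        return [g for _, g in sorted(self.genomes.items()) if g.is_prokaryote]

    def prokaryotic_species(self) -> list[str]:
        return sorted({g.species_id for g in self.prokaryotic_genomes()})

    def is_prokaryotic_gene(self, gene_id: str) -> bool:
        gene = self._gene_index.get(gene_id)
        return gene is not None and self.genomes[gene.genome_id].is_prokaryote


@dataclass
class FamilyAssignment:
    """A cross-genome protein family (approximate isofunctional group).

    ``subsystem_classes`` maps each subsystem the family belongs to onto its
    class; family ``status`` is derived deterministically from those classes
    and member function strings (see :mod:`genecontext.status`).
    """

    family_id: str
    member_gene_ids: set[str]
    status: str = "hypothetical"
    subsystem_ids: set[str] = field(default_factory=set)
    subsystem_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.member_gene_ids = set(self.member_gene_ids)
        self.subsystem_ids = set(self.subsystem_ids) | set(self.subsystem_classes)

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


def validate_partition(families: list[FamilyAssignment]) -> dict[str, str]:
    """Check families are disjoint; return gene_id -> family_id map."""
    gene_to_family: dict[str, str] = {}
    for fam in families:
        for gid in fam.member_gene_ids:
            if gid in gene_to_family:
                raise GeneContextError(
                    f"gene {gid!r} assigned to both family "
                    f"{gene_to_family[gid]!r} and {fam.family_id!r}"
                )
            gene_to_family[gid] = fam.family_id
    return gene_to_family


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise homology hit (BLAST-tabular semantics).

    ``aln_query_cov`` is the aligned fraction of the query (0-1) or ``None``
    when the query length is unknown.
    """

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    pct_identity: float = 0.0
    aln_query_cov: Optional[float] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise GeneContextError(
                f"hit {self.query_id}->{self.subject_id}: negative evalue"
            )
        if not 0.0 <= self.pct_identity <= 100.0:
            raise GeneContextError(
                f"hit {self.query_id}->{self.subject_id}: pct_identity out of range"
            )


DEFAULT_PRIORITY_WEIGHTS: Mapping[str, float] = {
    "cwn": 3.0,
    "cwh": 1.0,
    "fc": 2.0,
    "length": 1.0,
    "spread": 2.0,
    "model": 1.0,
}


@dataclass
class PipelineConfig:
    """All tunable thresholds of the prioritization pipeline.

    evalue_max
        Homology screen threshold; a hit passes only if its E-value is
        strictly better (smaller) than this. Default 1e-10.
    family_size_max
        Largest eukaryote family retained; families with more members are
        dropped because large families mix functions. Default 3.
    fc_min_for_code
        Minimum functional-coupling score (dereplicated genome groups with
        co-localization) for the cwn/cwh evidence codes; inclusive. Default 5.
    derep_identity
        Genomes with pairwise identity strictly above this fraction collapse
        into one strain group when computing FC. Default 0.95.
    cluster_gap_bp
        Maximum intergenic gap (exclusive) inside a same-strand gene run.
        Default 300 bp, the classic operon-run heuristic.
    neighbor_window_genes
        Half-width, in gene positions, of the strand-blind vicinity window.
        Default 5.
    cluster_mode
        Which co-localization relation defines "vicinity": ``same_strand_run``,
        ``window``, or ``either`` (union; the pipeline default).
    projection_min_identity / projection_min_cov
        Similarity guards for annotation projection: members whose best
        within-family hit falls below either floor go to the uncertain list.
    priority_weights
        Weights of the linear priority score (see pipeline.score_candidate).
    """

    evalue_max: float = 1e-10
    family_size_max: int = 3
    fc_min_for_code: int = 5
    derep_identity: float = 0.95
    cluster_gap_bp: int = 300
    neighbor_window_genes: int = 5
    cluster_mode: str = "either"
    projection_min_identity: float = 30.0
    projection_min_cov: float = 0.7
    priority_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRIORITY_WEIGHTS)
    )
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise GeneContextError("evalue_max must be > 0")
        if self.family_size_max < 1:
            raise GeneContextError("family_size_max must be >= 1")
        if self.fc_min_for_code < 1:
            raise GeneContextError("fc_min_for_code must be >= 1")
        if not 0 < self.derep_identity <= 1:
            raise GeneContextError("derep_identity must be in (0, 1]")
        if self.cluster_mode not in ("same_strand_run", "window", "either"):
            raise GeneContextError(f"unknown cluster_mode {self.cluster_mode!r}")
        for key in DEFAULT_PRIORITY_WEIGHTS:
            self.priority_weights.setdefault(key, DEFAULT_PRIORITY_WEIGHTS[key])

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
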