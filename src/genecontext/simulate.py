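"""Seeded synthetic pangenome generator with planted ground truth.

The generator emulates the statistical structure the genomic-context analysis
assumes, at desk scale:

* a panel of prokaryotic species, each with 1-3 near-identical strains that
  share gene content and order up to small shuffles (within-species emulated
  identity above the 95% dereplication threshold, between-species below it);
* operon-like planted gene clusters — contiguous, same-strand, tight
  intergenic gaps — whose retention across species is Bernoulli, so cluster
  conservation decays across the panel; planted families model the conserved
  unknown operons the analysis is designed to find and are always
  hypothetical;
* a background of unplanted families at random positions, a configurable
  fraction hypothetical (the decoys), the rest annotated; a fraction of the
  annotated "metabolic" families is grouped into per-species background
  operons that are NOT conserved across species, so run structure is
  realistic without adding coupling signal;
* a eukaryote proteome sharing a subset of prokaryotic families with family
  sizes drawn over {1, 2, 3, 4+} (the 4+ families exist to be dropped by the
  size filter), plus eukaryote-only genes;
* homology hits generated directly from true family co-membership (a star
  within each prokaryotic family, all pairs within eukaryote families, and
  eukaryote-to-prokaryote hits to the mapped family), with optional false
  positives and dropped true hits.

Family membership — not sequence — is the simulation's primary truth, so no
aligner is needed downstream; protein sequences are optional decorations
(mutated copies of a per-family core).

Emulated "overall DNA sequence identity" between genomes is drawn directly:
0.955-0.995 within a species, 0.55-0.85 between species. This is a documented
proxy; the artifact never stores genomic DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as gio
from .model import (
    FamilyAssignment,
    Gene,
    GeneContextError,
    Genome,
    GenomePanel,
    HomologyHit,
)

GENE_LEN_BP = 900
GAP_BG_BP = (50, 500)       # intergenic gaps outside clusters
GAP_CLUSTER_BP = (10, 250)  # within planted / background clusters
IDENT_WITHIN = (0.955, 0.995)
IDENT_BETWEEN = (0.55, 0.85)
VAGUE_FRAC_OF_HYPOTHETICAL = 0.25
MODEL_ORGANISM_FRAC = 0.1
EXPERIMENTAL_SS_FRAC = 0.1

_KNOWN_TEMPLATES = [
    "{fid} dehydratase (EC 4.2.1.{n})",
    "{fid} aminotransferase (EC 2.6.1.{n})",
    "{fid} synthase subunit A (EC 2.5.1.{n})",
    "{fid} ABC transporter substrate-binding protein",
    "{fid} carboxylase (EC 6.4.1.{n})",
]
_METABOLIC_TEMPLATES = [
    "{fid} biosynthesis protein (EC 2.7.1.{n})",
    "{fid} reductase, NADPH-dependent (EC 1.1.1.{n})",
    "{fid} cofactor salvage enzyme (EC 3.5.4.{n})",
]
_VAGUE_FUNCTIONS = ["ATPase", "putative protein", "membrane protein", "kinase"]


@dataclass
class SimParams:
    """Parameters of one synthetic pangenome.

    Defaults are the study conditions exercised by the parameter-recovery
    analysis: 30 species with 1-3 strains each, five planted two-family
    hypothetical clusters retained in 70% of species, and a eukaryote
    proteome sharing 60 prokaryotic families (the 10 planted ones, 40
    hypothetical decoys, 10 annotated).
    """

    n_species: int = 30
    strains_per_species: tuple[int, int] = (1, 3)
    genes_per_genome: int = 400
    n_families: int = 500
    n_planted_clusters: int = 5
    cluster_size: tuple[int, int] = (2, 2)
    cluster_retention_prob: float = 0.7
    frac_hypothetical: float = 0.3
    frac_metabolic_in_clusters: float = 0.35
    euk_shared_family_count: int = 60
    euk_family_size_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.08}
    )
    euk_only_gene_count: int = 30
    hit_false_positive_rate: float = 0.0
    hit_false_negative_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in [
            ("cluster_retention_prob", self.cluster_retention_prob),
            ("frac_hypothetical", self.frac_hypothetical),
            ("frac_metabolic_in_clusters", self.frac_metabolic_in_clusters),
            ("hit_false_positive_rate", self.hit_false_positive_rate),
            ("hit_false_negative_rate", self.hit_false_negative_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise GeneContextError(f"{name} must be in [0, 1], got {p}")
        if self.cluster_size[0] < 2:
            raise GeneContextError("cluster_size minimum must be >= 2")
        if min(
            self.n_species, self.genes_per_genome, self.n_families,
            self.n_planted_clusters, self.euk_shared_family_count,
            self.euk_only_gene_count,
        ) < 0:
            raise GeneContextError("all counts must be >= 0")
        total = sum(self.euk_family_size_dist.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise GeneContextError("euk_family_size_dist must sum to 1")


@dataclass(frozen=True)
class FamilyTruth:
    family_id: str
    planted_cluster_id: Optional[str]
    true_status: str  # non_hypothetical | hypothetical
    true_partner_families: frozenset[str]


@dataclass
class GroundTruth:
    """Planted truth emitted alongside the panel, for parameter-recovery tests."""

    family_truth: dict[str, FamilyTruth]
    genome_truth: dict[str, str]  # genome_id -> true strain group (species)
    euk_truth: dict[str, Optional[str]]  # euk gene -> mapped prok family
    euk_family_members: dict[str, tuple[str, ...]]  # true euk family -> genes
    planted_clusters: dict[str, tuple[str, ...]]
    cluster_retention: dict[str, tuple[str, ...]]  # cluster -> retaining species
    pairwise_identity: dict[frozenset, float]

    def planted_family_ids(self) -> set[str]:
        return {
            fid for fid, t in self.family_truth.items()
            if t.planted_cluster_id is not None
        }

    def hypothetical_family_ids(self) -> set[str]:
        return {
            fid for fid, t in self.family_truth.items()
            if t.true_status == "hypothetical"
        }

    def expected_candidate_families(self, family_size_max: int = 3) -> set[frozenset]:
        """Eukaryote families (as member-gene sets) the sieve should select
        at zero hit noise: size <= max, mapped to a hypothetical prokaryotic
        family. Computed from truth only, independent of the pipeline."""
        out = set()
        for members in self.euk_family_members.values():
            if len(members) > family_size_max:
                continue
            target = self.euk_truth.get(members[0])
            if target is None:
                continue
            if self.family_truth[target].true_status == "hypothetical":
                out.add(frozenset(members))
        return out


@dataclass
class SimResult:
    panel: GenomePanel
    euk_genes: list[Gene]
    hits: list[HomologyHit]
    families: list[FamilyAssignment]
    truth: GroundTruth
    params: SimParams


def _loguniform(rng: np.random.Generator, lo_exp: float, hi_exp: float) -> float:
    return float(10.0 ** rng.uniform(lo_exp, hi_exp))


def simulate(params: SimParams) -> SimResult:
    """Generate a synthetic pangenome; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)

    n_planted = 0
    cluster_families: dict[str, list[str]] = {}
    sizes = []
    for c in range(params.n_planted_clusters):
        size = int(rng.integers(params.cluster_size[0], params.cluster_size[1] + 1))
        sizes.append(size)
        n_planted += size
    if n_planted > params.genes_per_genome:
        raise GeneContextError(
            f"infeasible placement: {n_planted} planted genes exceed "
            f"genes_per_genome={params.genes_per_genome}; increase "
            "genes_per_genome or reduce clusters"
        )
    if n_planted > params.n_families:
        raise GeneContextError(
            "infeasible placement: planted clusters need more families than "
            f"n_families={params.n_families}"
        )

    fam_ids = [f"F{i:04d}" for i in range(params.n_families)]
    cursor = 0
    for c, size in enumerate(sizes):
        cid = f"C{c + 1:02d}"
        cluster_families[cid] = fam_ids[cursor : cursor + size]
        cursor += size
    planted_ids = set(fam_ids[:n_planted])
    nonplanted_ids = fam_ids[n_planted:]

    # statuses: planted clusters are always hypothetical (they model the
    # conserved unknown operons the analysis hunts); unplanted draw Bernoulli
    status: dict[str, str] = {fid: "hypothetical" for fid in planted_ids}
    for fid in nonplanted_ids:
        status[fid] = (
            "hypothetical"
            if rng.random() < params.frac_hypothetical
            else "non_hypothetical"
        )
    hypo_ids = [f for f in fam_ids if status[f] == "hypothetical"]
    known_ids = [f for f in fam_ids if status[f] == "non_hypothetical"]

    # function strings
    functions: dict[str, str] = {}
    metabolic: set[str] = set()
    for i, fid in enumerate(known_ids):
        if rng.random() < 0.5:
            metabolic.add(fid)
            tpl = _METABOLIC_TEMPLATES[i % len(_METABOLIC_TEMPLATES)]
        else:
            tpl = _KNOWN_TEMPLATES[i % len(_KNOWN_TEMPLATES)]
        functions[fid] = tpl.format(fid=fid, n=(i % 97) + 1)
    for i, fid in enumerate(hypo_ids):
        if rng.random() < VAGUE_FRAC_OF_HYPOTHETICAL:
            functions[fid] = _VAGUE_FUNCTIONS[i % len(_VAGUE_FUNCTIONS)]
        else:
            functions[fid] = "hypothetical protein"

    # subsystems: known families sit in non-hypothetical subsystem areas;
    # a small fraction of hypotheticals in experimental subsystems
    subsystem_classes: dict[str, dict[str, str]] = {fid: {} for fid in fam_ids}
    for i, fid in enumerate(known_ids):
        area = f"SS_area{i % 12:02d}"
        subsystem_classes[fid][area] = "non_hypothetical"
    for fid in hypo_ids:
        if fid not in planted_ids and rng.random() < EXPERIMENTAL_SS_FRAC:
            subsystem_classes[fid][f"EXP_{fid}"] = "experimental"

    # per-family presence probability across species
    base_p = params.genes_per_genome / max(params.n_families, 1)
    presence_p = {
        fid: float(np.clip(base_p + rng.uniform(-0.15, 0.15), 0.05, 0.95))
        for fid in nonplanted_ids
    }

    n_model = max(1, round(MODEL_ORGANISM_FRAC * params.n_species))

    panel = GenomePanel()
    family_members: dict[str, list[str]] = {fid: [] for fid in fam_ids}
    retention_by_cluster: dict[str, list[str]] = {
        cid: [] for cid in cluster_families
    }

    for si in range(params.n_species):
        species_id = f"sp{si:03d}"
        retained = [
            cid for cid in sorted(cluster_families)
            if rng.random() < params.cluster_retention_prob
        ]
        for cid in retained:
            retention_by_cluster[cid].append(species_id)
        present_nonplanted = [
            fid for fid in nonplanted_ids if rng.random() < presence_p[fid]
        ]

        # background operons: group a fraction of present metabolic families
        # into per-species blocks (not conserved across species)
        present_metabolic = [f for f in present_nonplanted if f in metabolic]
        n_bg = int(round(params.frac_metabolic_in_clusters * len(present_metabolic)))
        bg_pool = list(
            np.array(present_metabolic, dtype=object)[
                rng.permutation(len(present_metabolic))
            ][:n_bg]
        )
        bg_blocks: list[list[str]] = []
        while len(bg_pool) >= 2:
            take = int(rng.integers(2, 4))
            take = min(take, len(bg_pool))
            bg_blocks.append(bg_pool[:take])
            bg_pool = bg_pool[take:]
        grouped = {f for blk in bg_blocks for f in blk}

        tokens: list[tuple[str, str, tuple[str, ...]]] = []
        for cid in retained:
            strand = "+" if rng.random() < 0.5 else "-"
            tokens.append(("cluster", strand, tuple(cluster_families[cid])))
        unretained_planted = [
            fid
            for cid in sorted(cluster_families)
            if cid not in retained
            for fid in cluster_families[cid]
        ]
        for blk in bg_blocks:
            strand = "+" if rng.random() < 0.5 else "-"
            tokens.append(("bg", strand, tuple(blk)))
        for fid in unretained_planted + [
            f for f in present_nonplanted if f not in grouped
        ]:
            strand = "+" if rng.random() < 0.5 else "-"
            tokens.append(("single", strand, (fid,)))
        order = rng.permutation(len(tokens))
        base_tokens = [tokens[i] for i in order]

        n_strains = int(
            rng.integers(
                params.strains_per_species[0], params.strains_per_species[1] + 1
            )
        )
        for strain in range(1, n_strains + 1):
            genome_id = f"{species_id}.{strain}"
            strain_tokens = list(base_tokens)
            if strain > 1:
                for _ in range(int(rng.integers(0, 4))):
                    if len(strain_tokens) > 1:
                        k = int(rng.integers(0, len(strain_tokens) - 1))
                        strain_tokens[k], strain_tokens[k + 1] = (
                            strain_tokens[k + 1],
                            strain_tokens[k],
                        )
            genome = Genome(
                genome_id=genome_id,
                species_id=species_id,
                domain="bacteria",
                is_model_organism=si < n_model,
                strain_group_id=species_id,
            )
            pos = 1
            contig = "c1"
            for kind, strand, fams in strain_tokens:
                for k, fid in enumerate(fams):
                    if k > 0:
                        pos += int(rng.integers(*GAP_CLUSTER_BP)) + 1
                    gene_id = f"{genome_id}|{fid}"
                    genome.add_gene(
                        Gene(
                            gene_id=gene_id,
                            genome_id=genome_id,
                            contig_id=contig,
                            start=pos,
                            end=pos + GENE_LEN_BP - 1,
                            strand=strand,
                            function=functions[fid],
                        )
                    )
                    family_members[fid].append(gene_id)
                    pos += GENE_LEN_BP - 1
                pos += int(rng.integers(*GAP_BG_BP)) + 1
            panel.add_genome(genome)

    # pairwise emulated identity
    identity: dict[frozenset, float] = {}
    genome_ids = sorted(panel.genomes)
    for i, a in enumerate(genome_ids):
        for b in genome_ids[i + 1 :]:
            same = panel.genomes[a].species_id == panel.genomes[b].species_id
            lo, hi = IDENT_WITHIN if same else IDENT_BETWEEN
            identity[frozenset((a, b))] = float(rng.uniform(lo, hi))

    # ---- eukaryote proteome ----
    # shared eukaryote families must map to families actually present in the
    # panel (low-presence families can miss every species by chance)
    present_fams = {fid for fid in fam_ids if family_members[fid]}
    sorted_planted = sorted(planted_ids & present_fams)
    hypo_decoys = sorted((set(hypo_ids) - planted_ids) & present_fams)
    known_sorted = sorted(set(known_ids) & present_fams)
    targets = list(sorted_planted[: params.euk_shared_family_count])
    remaining = params.euk_shared_family_count - len(targets)
    n_decoy = min(len(hypo_decoys), int(round(remaining * 0.8)))
    n_known = min(len(known_sorted), remaining - n_decoy)
    targets += [
        hypo_decoys[i]
        for i in sorted(rng.choice(len(hypo_decoys), size=n_decoy, replace=False))
    ]
    targets += [
        known_sorted[i]
        for i in sorted(rng.choice(len(known_sorted), size=n_known, replace=False))
    ]

    size_values = sorted(params.euk_family_size_dist)
    size_probs = [params.euk_family_size_dist[s] for s in size_values]

    euk_genes: list[Gene] = []
    euk_truth: dict[str, Optional[str]] = {}
    euk_family_members: dict[str, tuple[str, ...]] = {}
    euk_counter = 0
    epos = 1

    def _new_euk_gene(function: str) -> Gene:
        nonlocal euk_counter, epos
        gid = f"EUK{euk_counter:05d}"
        euk_counter += 1
        gene = Gene(
            gene_id=gid,
            genome_id="eukaryote",
            contig_id="chrE",
            start=epos,
            end=epos + GENE_LEN_BP - 1,
            strand="+",
            function=function,
        )
        epos += GENE_LEN_BP + 200
        return gene

    for t_idx, target in enumerate(targets):
        size = int(size_values[rng.choice(len(size_values), p=size_probs)])
        if status[target] == "non_hypothetical":
            func = functions[target]
        else:
            func = functions[target]  # hypothetical / vague string of the family
        members = []
        for _ in range(size):
            gene = _new_euk_gene(func)
            euk_genes.append(gene)
            euk_truth[gene.gene_id] = target
            members.append(gene.gene_id)
        euk_family_members[f"EFAM_{t_idx:04d}"] = tuple(members)

    # eukaryote-only genes: two larger decoy families, rest singletons
    eo_left = params.euk_only_gene_count
    eo_idx = 0
    for decoy_size in (4, 5):
        if eo_left >= decoy_size + 3:
            members = []
            for _ in range(decoy_size):
                gene = _new_euk_gene("hypothetical protein")
                euk_genes.append(gene)
                euk_truth[gene.gene_id] = None
                members.append(gene.gene_id)
            euk_family_members[f"EONLY_{eo_idx:04d}"] = tuple(members)
            eo_idx += 1
            eo_left -= decoy_size
    for j in range(eo_left):
        func = (
            "hypothetical protein"
            if rng.random() < 0.5
            else f"eukaryote-specific regulator {j}"
        )
        gene = _new_euk_gene(func)
        euk_genes.append(gene)
        euk_truth[gene.gene_id] = None
        euk_family_members[f"EONLY_{eo_idx:04d}"] = (gene.gene_id,)
        eo_idx += 1

    # ---- curated family assignments (prokaryote families absorb their
    # mapped eukaryote genes; eukaryote-only families stand alone) ----
    euk_by_target: dict[str, list[str]] = {}
    for gid, target in euk_truth.items():
        if target is not None:
            euk_by_target.setdefault(target, []).append(gid)

    families: list[FamilyAssignment] = []
    for fid in fam_ids:
        members = set(family_members[fid]) | set(euk_by_target.get(fid, []))
        if not members:
            continue
        fam_status = status[fid]
        if fam_status == "hypothetical" and functions[fid] in _VAGUE_FUNCTIONS:
            fam_status = "vague"
        families.append(
            FamilyAssignment(
                family_id=fid,
                member_gene_ids=members,
                status=fam_status,
                subsystem_classes=dict(subsystem_classes[fid]),
            )
        )
    for efid, members in euk_family_members.items():
        if efid.startswith("EONLY_"):
            families.append(
                FamilyAssignment(
                    family_id=efid,
                    member_gene_ids=set(members),
                    status="hypothetical",
                )
            )

    # ---- homology hits from true co-membership ----
    true_hits: list[HomologyHit] = []

    def _true_hit(q: str, s: str) -> HomologyHit:
        return HomologyHit(
            query_id=q,
            subject_id=s,
            evalue=_loguniform(rng, -50, -12),
            bitscore=float(rng.uniform(80, 400)),
            pct_identity=float(rng.uniform(40, 90)),
            aln_query_cov=float(rng.uniform(0.75, 1.0)),
        )

    for fid in fam_ids:
        members = sorted(family_members[fid])
        if len(members) > 1:
            center = members[0]
            for other in members[1:]:
                true_hits.append(_true_hit(center, other))
        for egid in sorted(euk_by_target.get(fid, [])):
            for prok_gid in members:
                true_hits.append(_true_hit(egid, prok_gid))

    for members in euk_family_members.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                true_hits.append(_true_hit(members[i], members[j]))

    if params.hit_false_negative_rate > 0:
        keep = rng.random(len(true_hits)) >= params.hit_false_negative_rate
        hits = [h for h, k in zip(true_hits, keep) if k]
    else:
        hits = list(true_hits)

    n_fp = int(round(params.hit_false_positive_rate * len(true_hits)))
    if n_fp:
        all_gene_ids = sorted(g.gene_id for g in panel.genes()) + sorted(
            g.gene_id for g in euk_genes
        )
        for _ in range(n_fp):
            q, s = rng.choice(len(all_gene_ids), size=2, replace=False)
            hits.append(
                HomologyHit(
                    query_id=all_gene_ids[int(q)],
                    subject_id=all_gene_ids[int(s)],
                    evalue=_loguniform(rng, -9, 0),
                    bitscore=float(rng.uniform(20, 45)),
                    pct_identity=float(rng.uniform(15, 30)),
                    aln_query_cov=float(rng.uniform(0.1, 0.5)),
                )
            )

    truth = GroundTruth(
        family_truth={
            fid: FamilyTruth(
                family_id=fid,
                planted_cluster_id=next(
                    (
                        cid
                        for cid, fams in cluster_families.items()
                        if fid in fams
                    ),
                    None,
                ),
                true_status=(
                    "hypothetical" if status[fid] == "hypothetical" else
                    "non_hypothetical"
                ),
                true_partner_families=frozenset(
                    other
                    for cid, fams in cluster_families.items()
                    for other in fams
                    if fid in fams and other != fid
                ),
            )
            for fid in fam_ids
        },
        genome_truth={
            gid: panel.genomes[gid].species_id for gid in sorted(panel.genomes)
        },
        euk_truth=euk_truth,
        euk_family_members=euk_family_members,
        planted_clusters={
            cid: tuple(fams) for cid, fams in sorted(cluster_families.items())
        },
        cluster_retention={
            cid: tuple(species) for cid, species in sorted(
                retention_by_cluster.items()
            )
        },
        pairwise_identity=identity,
    )
    return SimResult(
        panel=panel,
        euk_genes=euk_genes,
        hits=hits,
        families=families,
        truth=truth,
        params=params,
    )


# ---------------------------------------------------------------------------
# presets and file emission

PRESETS: dict[str, SimParams] = {}


def _register_presets() -> None:
    PRESETS["tiny"] = SimParams(
        n_species=2,
        strains_per_species=(1, 2),
        genes_per_genome=28,
        n_families=40,
        n_planted_clusters=2,
        cluster_size=(2, 3),
        cluster_retention_prob=1.0,
        frac_hypothetical=0.3,
        euk_shared_family_count=8,
        euk_only_gene_count=8,
    )
    PRESETS["default"] = SimParams()
    PRESETS["table1-like"] = SimParams(
        n_species=6,
        strains_per_species=(1, 2),
        genes_per_genome=250,
        n_families=400,
        n_planted_clusters=3,
        cluster_size=(2, 2),
        cluster_retention_prob=0.8,
        euk_shared_family_count=300,
        euk_family_size_dist={1: 0.60, 2: 0.27, 3: 0.13},
        euk_only_gene_count=30,
    )


_register_presets()


def preset_params(fixture_name: str, seed: Optional[int] = None) -> SimParams:
    if fixture_name not in PRESETS:
        raise GeneContextError(
            f"unknown preset {fixture_name!r}; available: {sorted(PRESETS)}"
        )
    params = PRESETS[fixture_name]
    if seed is not None:
        params = SimParams(**{**params.__dict__, "seed": seed})
    return params


def attach_proteins(result: SimResult, length: int = 120) -> None:
    """Decorate genes with protein sequences: per-family random core with
    per-member point mutations (10%). Seeded from the simulation seed."""
    rng = np.random.default_rng(result.params.seed + 1)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    cores: dict[str, np.ndarray] = {}
    gene_family: dict[str, str] = {}
    for fam in result.families:
        cores[fam.family_id] = aas[rng.integers(0, 20, size=length)]
        for gid in fam.member_gene_ids:
            gene_family[gid] = fam.family_id

    def _mutate(core: np.ndarray) -> str:
        seq = core.copy()
        n_mut = max(1, int(0.1 * length))
        pos = rng.choice(length, size=n_mut, replace=False)
        seq[pos] = aas[rng.integers(0, 20, size=n_mut)]
        return "".join(seq)

    new_euk = []
    for gene in result.euk_genes:
        fid = gene_family.get(gene.gene_id)
        seq = _mutate(cores[fid]) if fid else "".join(
            aas[rng.integers(0, 20, size=length)]
        )
        new_euk.append(Gene(**{**gene.__dict__, "protein": seq}))
    result.euk_genes = new_euk

    for genome in result.panel.genomes.values():
        for contig_id, genes in genome.contigs.items():
            genome.contigs[contig_id] = [
                Gene(
                    **{
                        **g.__dict__,
                        "protein": _mutate(cores[gene_family[g.gene_id]])
                        if g.gene_id in gene_family
                        else None,
                    }
                )
                for g in genes
            ]


def emit(
    fixture_name: str,
    out_dir: str | Path,
    seed: Optional[int] = None,
    with_proteins: Optional[bool] = None,
) -> SimResult:
    """Generate a preset fixture and write it as the formats the readers load.

    Layout: ``genomes/*.gff3`` (one per genome, plus ``eukaryote.gff3``),
    ``metadata.tsv``, ``proteins.faa``, ``hits.tsv`` (BLAST tabular),
    ``families.tsv`` (curated assignments) and ``ground_truth/*.tsv``.
    """
    params = preset_params(fixture_name, seed)
    result = simulate(params)
    if with_proteins is None:
        with_proteins = fixture_name == "tiny"
    if with_proteins:
        attach_proteins(result)
    write_run_dir(result, out_dir)
    return result


def write_run_dir(result: SimResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    full_panel = GenomePanel(list(result.panel.genomes.values()))
    euk_genome = Genome(
        genome_id="eukaryote", species_id="eukaryote", domain="eukaryote"
    )
    for gene in result.euk_genes:
        euk_genome.add_gene(gene)
    full_panel.add_genome(euk_genome)
    gio.write_genome_panel(full_panel, out)

    gio.write_hits(result.hits, out / "hits.tsv")
    gio.write_families_tsv(result.families, out / "families.tsv")

    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    truth = result.truth
    gio.write_tsv(
        pd.DataFrame(
            [
                {
                    "family_id": fid,
                    "planted_cluster_id": t.planted_cluster_id or "",
                    "true_status": t.true_status,
                    "true_partner_families": ",".join(
                        sorted(t.true_partner_families)
                    ),
                }
                for fid, t in sorted(truth.family_truth.items())
            ]
        ),
        gt_dir / "families.tsv",
    )
    gio.write_tsv(
        pd.DataFrame(
            [
                {"genome_id": gid, "strain_group_id": grp}
                for gid, grp in sorted(truth.genome_truth.items())
            ]
        ),
        gt_dir / "genomes.tsv",
    )
    gio.write_tsv(
        pd.DataFrame(
            [
                {"euk_gene_id": gid, "prok_family_id": fam or ""}
                for gid, fam in sorted(truth.euk_truth.items())
            ]
        ),
        gt_dir / "euk_genes.tsv",
    )
    gio.write_tsv(
        pd.DataFrame(
            [
                {"cluster_id": cid, "families": ",".join(fams)}
                for cid, fams in sorted(truth.planted_clusters.items())
            ]
        ),
        gt_dir / "clusters.tsv",
    )
    gio.write_tsv(
        pd.DataFrame(
            [
                {
                    "genome_a": min(pair),
                    "genome_b": max(pair),
                    "identity": f"{ident:.6f}",
                }
                for pair, ident in sorted(
                    truth.pairwise_identity.items(),
                    key=lambda kv: (min(kv[0]), max(kv[0])),
                )
            ]
        ),
        gt_dir / "identity.tsv",
    )
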