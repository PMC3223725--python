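"""End-to-end prioritization: sieves, evidence, scoring, ranking, projection.

The stage order is: build eukaryote families -> drop families with more than
three members -> screen for prokaryotic homologs (E < 1e-10, strict) ->
drop families with any known member -> assign cross-genome families ->
dereplicate the panel -> detect gene runs -> functional coupling -> evidence
codes -> phyletic profiles -> score -> rank. Everything is deterministic
given the inputs and configuration.

In practice this kind of triage is often done by expert judgement over
precomputed evidence tables; this module replaces that manual step with an
explicit, reproducible linear score

    S = w_cwn*[cwn] + w_cwh*[cwh] + w_fc*min(fc_max,10)/10
      + w_len*min(cluster_length_max,10)/10 + w_spread*spread/N_species
      + w_model*[model organism]

with default weights (3, 1, 2, 1, 2, 1), plus a lexicographic alternative
(cwn, fc_max, cwh, spread, model organism, cluster length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import io as gio
from .context import (
    CouplingEdge,
    EvidenceSummary,
    GenomeGroup,
    build_cbss,
    cluster_length,
    compute_fc,
    dereplicate,
    detect_runs_panel,
    evidence_codes,
)
from .families import (
    EukFamily,
    assign_cross_genome_families,
    build_euk_families,
    filter_small_families,
)
from .homology import HomologScreenResult, screen_homologs
from .model import (
    FamilyAssignment,
    Gene,
    GeneContextError,
    GenomePanel,
    HomologyHit,
    PipelineConfig,
)
from .profiles import PhyleticProfile, build_profiles
from .status import StatusDecision, classify_gene, select_unknown_families

logger = logging.getLogger(__name__)

SIZE_CLASS_ORDER = ("singleton", "duplet", "triplet")


@dataclass
class StageRow:
    screened: int
    with_homolog: int
    pct_with_homolog: float
    selected: int


@dataclass
class StageSummary:
    """Per-size-class funnel counts plus a totals row (key ``total``)."""

    rows: dict[str, StageRow]

    def to_frame(self) -> pd.DataFrame:
        order = [k for k in (*SIZE_CLASS_ORDER, "total") if k in self.rows] + [
            k for k in self.rows if k not in (*SIZE_CLASS_ORDER, "total")
        ]
        return pd.DataFrame(
            [
                {
                    "size_class": k,
                    "screened_genes": self.rows[k].screened,
                    "with_prokaryote_homolog": self.rows[k].with_homolog,
                    "pct_with_homolog": self.rows[k].pct_with_homolog,
                    "selected_for_analysis": self.rows[k].selected,
                }
                for k in order
            ]
        )


def percent_1dp(count: int, total: int) -> float:
    """Printed-style percentage: 1 decimal, half rounded away from zero."""
    if total == 0:
        if count:
            raise GeneContextError("percent undefined: zero denominator")
        return 0.0
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_stages(
    stage_counts: Mapping[str, tuple[int, int, int]],
    totals: Optional[tuple[int, int, int]] = None,
) -> StageSummary:
    """Build the funnel summary from (screened, with_homolog, selected) counts.

    Percentages are rounded half-away-from-zero to one decimal. The totals
    row uses the provided totals when given (printed tables sometimes carry
    their own totals), otherwise the column sums. A nonzero count against a
    zero screened denominator is a hard error.
    """
    rows: dict[str, StageRow] = {}
    for cls, (screened, with_hom, selected) in stage_counts.items():
        if min(screened, with_hom, selected) < 0:
            raise GeneContextError(f"stage counts for {cls!r} must be >= 0")
        rows[cls] = StageRow(
            screened, with_hom, percent_1dp(with_hom, screened), selected
        )
    if totals is None:
        totals = (
            sum(v[0] for v in stage_counts.values()),
            sum(v[1] for v in stage_counts.values()),
            sum(v[2] for v in stage_counts.values()),
        )
    rows["total"] = StageRow(
        totals[0], totals[1], percent_1dp(totals[1], totals[0]), totals[2]
    )
    return StageSummary(rows=rows)


@dataclass
class CandidateRecord:
    euk_family_id: str
    euk_gene_ids: tuple[str, ...]
    size_class: str
    prokaryotic_family_id: str
    evidence: EvidenceSummary
    best_hit_identity: float
    split_homology: bool = False
    priority_score: float = 0.0
    rank: int = 0


CANDIDATE_COLUMNS = [
    "rank", "euk_family_id", "euk_gene_ids", "size_class",
    "prokaryotic_family_id", "split_homology", "priority_score",
    "fc_max", "cwn", "cwh", "cluster_length_max", "phyletic_spread",
    "in_model_organism", "cbss_ids", "best_hit_identity",
]


def candidate_to_row(rec: CandidateRecord) -> dict:
    ev = rec.evidence
    return {
        "rank": rec.rank,
        "euk_family_id": rec.euk_family_id,
        "euk_gene_ids": ",".join(sorted(rec.euk_gene_ids)),
        "size_class": rec.size_class,
        "prokaryotic_family_id": rec.prokaryotic_family_id,
        "split_homology": rec.split_homology,
        "priority_score": round(rec.priority_score, 6),
        "fc_max": ev.fc_max,
        "cwn": ev.cwn,
        "cwh": ev.cwh,
        "cluster_length_max": ev.cluster_length_max,
        "phyletic_spread": ev.phyletic_spread,
        "in_model_organism": ev.in_model_organism,
        "cbss_ids": ",".join(sorted(ev.cbss_ids)),
        "best_hit_identity": round(rec.best_hit_identity, 2),
    }


def score_candidate(
    evidence: EvidenceSummary, config: PipelineConfig, n_species: int
) -> float:
    """Linear priority score over the evidence bundle (see module docstring).

    Monotone in every term; fc and cluster length saturate at 10, spread is
    normalized by the number of prokaryotic species in the panel.
    """
    w = config.priority_weights
    spread_frac = evidence.phyletic_spread / n_species if n_species else 0.0
    return (
        w["cwn"] * (1.0 if evidence.cwn else 0.0)
        + w["cwh"] * (1.0 if evidence.cwh else 0.0)
        + w["fc"] * min(evidence.fc_max, 10) / 10.0
        + w["length"] * min(evidence.cluster_length_max, 10) / 10.0
        + w["spread"] * spread_frac
        + w["model"] * (1.0 if evidence.in_model_organism else 0.0)
    )


def rank_candidates(
    records: list[CandidateRecord], method: str = "score"
) -> list[CandidateRecord]:
    """Assign 1-based ranks; ties broken lexicographically by family ids."""
    if method == "score":
        key = lambda r: (-r.priority_score, r.euk_family_id, r.prokaryotic_family_id)
    elif method == "lexicographic":
        key = lambda r: (
            -int(r.evidence.cwn),
            -r.evidence.fc_max,
            -int(r.evidence.cwh),
            -r.evidence.phyletic_spread,
            -int(r.evidence.in_model_organism),
            -r.evidence.cluster_length_max,
            r.euk_family_id,
            r.prokaryotic_family_id,
        )
    else:
        raise GeneContextError(f"unknown ranking method {method!r}")
    records = sorted(records, key=key)
    for i, rec in enumerate(records, start=1):
        rec.rank = i
    return records


@dataclass
class PipelineResult:
    candidates: list[CandidateRecord]
    stage_summary: StageSummary
    euk_families: list[EukFamily]
    retained_families: list[EukFamily]
    screen: HomologScreenResult
    assignments: list[FamilyAssignment]
    groups: list[GenomeGroup]
    edges: list[CouplingEdge]
    evidence: dict[str, EvidenceSummary]
    profiles: list[PhyleticProfile]
    cbss: list[tuple[str, frozenset]]
    decisions: dict[str, StatusDecision] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        try:
            return fn()
        except GeneContextError as exc:
            raise GeneContextError(f"stage {name!r}: {exc}") from exc

    return wrap


def run_pipeline(
    panel: GenomePanel,
    euk_genes: Sequence[Gene],
    hits: Sequence[HomologyHit],
    annotations: Optional[list[FamilyAssignment]] = None,
    config: Optional[PipelineConfig] = None,
    subsystems: Optional[dict[str, dict[str, str]]] = None,
    puf_list: Optional[set[str]] = None,
    pairwise_identity: Optional[Mapping[frozenset, float]] = None,
    ranking: str = "score",
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run the full prioritization pipeline.

    ``annotations`` optionally supplies curated cross-genome family
    assignments (with subsystem classes); otherwise families are built from
    the hit graph and ``subsystems`` / ``puf_list`` feed the status rules.
    Deterministic given inputs and config; stage failures propagate with the
    stage name. When ``out_dir`` is given all output tables are written.
    """
    config = config or PipelineConfig()
    euk_ids = {g.gene_id for g in euk_genes}

    euk_euk_hits = [
        h for h in hits if h.query_id in euk_ids and h.subject_id in euk_ids
    ]

    euk_families = _stage("build_euk_families")(
        lambda: build_euk_families(euk_genes, euk_euk_hits, config)
    )
    retained = _stage("filter_small_families")(
        lambda: filter_small_families(euk_families, config)
    )
    retained_ids = {g for f in retained for g in f.member_gene_ids}
    retained_genes = [g for g in euk_genes if g.gene_id in retained_ids]
    logger.info(
        "stage counts: proteome=%d families=%d retained_families=%d "
        "retained_genes=%d",
        len(euk_genes), len(euk_families), len(retained), len(retained_genes),
    )

    screen = _stage("screen_homologs")(
        lambda: screen_homologs(retained_genes, hits, panel, config)
    )
    logger.info("stage counts: genes_with_homolog=%d", len(screen.passing_genes()))

    all_genes = list(panel.genes()) + [
        g for g in euk_genes if not panel.has_gene(g.gene_id)
    ]
    assignments = _stage("assign_cross_genome_families")(
        lambda: assign_cross_genome_families(
            all_genes, hits, annotations, config, subsystems, puf_list
        )
    )
    gene_to_assignment: dict[str, FamilyAssignment] = {}
    for fam in assignments:
        for gid in fam.member_gene_ids:
            gene_to_assignment[gid] = fam

    decisions = _stage("classify_genes")(
        lambda: {
            g.gene_id: classify_gene(
                g, gene_to_assignment.get(g.gene_id), puf_list
            )
            for g in retained_genes
        }
    )
    candidate_fams = _stage("select_unknown_families")(
        lambda: select_unknown_families(retained, screen, decisions)
    )
    logger.info("stage counts: candidate_families=%d", len(candidate_fams))

    groups = _stage("dereplicate")(
        lambda: dereplicate(panel, pairwise_identity, config)
    )
    runs_fc = _stage("detect_runs")(
        lambda: detect_runs_panel(panel, config, config.cluster_mode)
    )
    prok_assignments = [
        f
        for f in assignments
        if any(panel.is_prokaryotic_gene(g) for g in f.member_gene_ids)
    ]
    edges = _stage("compute_fc")(
        lambda: compute_fc(runs_fc, prok_assignments, groups, config)
    )
    codes = _stage("evidence_codes")(
        lambda: evidence_codes(edges, prok_assignments, config)
    )
    profiles = _stage("build_profiles")(
        lambda: build_profiles(prok_assignments, panel)
    )
    spread_of = {p.family_id: p.spread for p in profiles}
    cbss = _stage("build_cbss")(lambda: build_cbss(edges, prok_assignments, config))
    cbss_of: dict[str, set[str]] = {}
    for cbss_id, members in cbss:
        for fid in members:
            cbss_of.setdefault(fid, set()).add(cbss_id)

    prok_gene_ids = {
        g.gene_id for g in panel.genes() if panel.genomes[g.genome_id].is_prokaryote
    }
    evidence: dict[str, EvidenceSummary] = {}
    for fam in prok_assignments:
        cwn, cwh, fc_max = codes.get(fam.family_id, (False, False, 0))
        in_model = any(
            panel.has_gene(g) and panel.genome_of(g).is_model_organism
            for g in fam.member_gene_ids
        )
        evidence[fam.family_id] = EvidenceSummary(
            family_id=fam.family_id,
            fc_max=fc_max,
            cwn=cwn,
            cwh=cwh,
            cluster_length_max=cluster_length(runs_fc, fam, prok_gene_ids),
            phyletic_spread=spread_of.get(fam.family_id, 0),
            in_model_organism=in_model,
            cbss_ids=cbss_of.get(fam.family_id, set()),
        )

    n_species = len(panel.prokaryotic_species())
    # per eukaryote gene: best passing-hit identity to each prokaryotic family
    partner_ident: dict[str, dict[str, float]] = {}
    for h in hits:
        if (
            h.query_id in retained_ids
            and h.subject_id in prok_gene_ids
            and h.evalue < config.evalue_max
        ):
            target = gene_to_assignment.get(h.subject_id)
            if target is not None:
                d = partner_ident.setdefault(h.query_id, {})
                d[target.family_id] = max(
                    d.get(target.family_id, 0.0), h.pct_identity
                )

    records: list[CandidateRecord] = []
    for fam in candidate_fams:
        partner_best: dict[str, float] = {}
        for gid in fam.member_gene_ids:
            for prok_fid, ident in partner_ident.get(gid, {}).items():
                partner_best[prok_fid] = max(partner_best.get(prok_fid, 0.0), ident)
        split = len(partner_best) > 1
        for prok_fid in sorted(partner_best):
            ev = evidence.get(prok_fid, EvidenceSummary(family_id=prok_fid))
            records.append(
                CandidateRecord(
                    euk_family_id=fam.family_id,
                    euk_gene_ids=tuple(sorted(fam.member_gene_ids)),
                    size_class=fam.size_class,
                    prokaryotic_family_id=prok_fid,
                    evidence=ev,
                    best_hit_identity=partner_best[prok_fid],
                    split_homology=split,
                    priority_score=score_candidate(ev, config, n_species),
                )
            )
    records = rank_candidates(records, ranking)

    candidate_gene_ids = {g for f in candidate_fams for g in f.member_gene_ids}
    stage_counts = {}
    for cls in SIZE_CLASS_ORDER:
        fams_cls = [f for f in retained if f.size_class == cls]
        genes_cls = {g for f in fams_cls for g in f.member_gene_ids}
        stage_counts[cls] = (
            len(genes_cls),
            sum(1 for g in genes_cls if screen.passes(g)),
            len(genes_cls & candidate_gene_ids),
        )
    summary = summarize_stages(stage_counts)

    result = PipelineResult(
        candidates=records,
        stage_summary=summary,
        euk_families=euk_families,
        retained_families=retained,
        screen=screen,
        assignments=assignments,
        groups=groups,
        edges=edges,
        evidence=evidence,
        profiles=profiles,
        cbss=cbss,
        decisions=decisions,
    )
    if out_dir is not None:
        write_outputs(result, out_dir, config, n_species)
    return result


def write_outputs(
    result: PipelineResult,
    out_dir: str | Path,
    config: PipelineConfig,
    n_species: int,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_tables(result.candidates, out)
    gio.write_tsv(result.stage_summary.to_frame(), out / "stage_summary.tsv")
    gio.write_tsv(
        pd.DataFrame(
            [
                {
                    "family_a": e.family_a,
                    "family_b": e.family_b,
                    "fc_score": e.fc_score,
                    "supporting_groups": ",".join(sorted(e.supporting_group_ids)),
                }
                for e in result.edges
            ],
            columns=["family_a", "family_b", "fc_score", "supporting_groups"],
        ),
        out / "edges.tsv",
    )
    gio.write_tsv(
        pd.DataFrame(
            [
                {
                    "family_id": ev.family_id,
                    "fc_max": ev.fc_max,
                    "cwn": ev.cwn,
                    "cwh": ev.cwh,
                    "cluster_length_max": ev.cluster_length_max,
                    "phyletic_spread": ev.phyletic_spread,
                    "in_model_organism": ev.in_model_organism,
                    "cbss_ids": ",".join(sorted(ev.cbss_ids)),
                }
                for _, ev in sorted(result.evidence.items())
            ],
            columns=[
                "family_id", "fc_max", "cwn", "cwh", "cluster_length_max",
                "phyletic_spread", "in_model_organism", "cbss_ids",
            ],
        ),
        out / "evidence.tsv",
    )
    gio.write_tsv(
        pd.DataFrame(
            [
                {"cbss_id": cid, "families": ",".join(sorted(members))}
                for cid, members in result.cbss
            ],
            columns=["cbss_id", "families"],
        ),
        out / "cbss.tsv",
    )
    species = sorted({s for p in result.profiles for s in p.presence})
    gio.write_tsv(
        pd.DataFrame(
            [
                {
                    "family_id": p.family_id,
                    **{s: int(p.presence[s]) for s in species},
                }
                for p in result.profiles
            ],
            columns=["family_id", *species],
        ),
        out / "profiles.tsv",
    )
    with open(out / "run_header.txt", "w") as fh:
        w = config.priority_weights
        fh.write(
            "priority score S = "
            f"{w['cwn']}*[cwn] + {w['cwh']}*[cwh] + {w['fc']}*min(fc_max,10)/10 "
            f"+ {w['length']}*min(cluster_length_max,10)/10 "
            f"+ {w['spread']}*spread/{n_species} + {w['model']}*[model_organism]\n"
        )


def project_annotation(
    confirmed_family_id: str,
    annotation_text: str,
    assignments: Sequence[FamilyAssignment],
    hits: Iterable[HomologyHit],
    config: Optional[PipelineConfig] = None,
) -> tuple[list[str], list[str]]:
    """Project a confirmed annotation to every member of a family.

    Members whose best within-family hit falls below the identity or coverage
    guard — or who have no within-family hit at all — go to the uncertain
    list instead of receiving the annotation. Returns
    ``(projected_gene_ids, uncertain_gene_ids)``, both sorted.
    """
    config = config or PipelineConfig()
    if not annotation_text.strip():
        raise GeneContextError("annotation text must be non-empty")
    family = next(
        (f for f in assignments if f.family_id == confirmed_family_id), None
    )
    if family is None:
        raise GeneContextError(f"unknown family {confirmed_family_id!r}")
    members = family.member_gene_ids

    best: dict[str, tuple[float, Optional[float]]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.query_id in members and h.subject_id in members:
            for member, cov in ((h.query_id, h.aln_query_cov), (h.subject_id, None)):
                prev = best.get(member)
                if prev is None or h.pct_identity > prev[0]:
                    best[member] = (h.pct_identity, cov)

    projected, uncertain = [], []
    for gid in sorted(members):
        entry = best.get(gid)
        if entry is None:
            uncertain.append(gid)
            continue
        identity, cov = entry
        if identity < config.projection_min_identity or (
            cov is not None and cov < config.projection_min_cov
        ):
            uncertain.append(gid)
        else:
            projected.append(gid)
    return projected, uncertain
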