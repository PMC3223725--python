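"""Cross-kingdom homology screen and a desk-scale pairwise aligner.

The screen retains eukaryote genes with at least one prokaryotic hit whose
E-value is strictly better (smaller) than the threshold — "better than 1e-10"
is read literally, so a hit at exactly 1e-10 fails.

The built-in aligner is a convenience for small fixtures: Smith-Waterman
local alignment under BLOSUM62 with BLAST-convention affine gaps (open 11,
extend 1), bit scores from fixed gapped Karlin-Altschul parameters
(lambda = 0.267, K = 0.041), and a per-pair E-value E = m * n * 2**(-bits).
Unlike BLAST, the search-space correction uses only the pair's own lengths,
not a whole database — adequate for pass/fail at a 1e-10 threshold on toy
data. The supported production path is precomputed BLAST tabular input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .model import Gene, GeneContextError, GenomePanel, HomologyHit, PipelineConfig

logger = logging.getLogger(__name__)

GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041
PREFILTER_KMER = 4  # pairs sharing no exact 4-mer are skipped

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZXJUO*")


@dataclass
class ScreenRecord:
    gene_id: str
    passes: bool
    best_hit: Optional[HomologyHit]
    prokaryotic_hit_genes: set[str] = field(default_factory=set)
    n_hit_genomes: int = 0


@dataclass
class HomologScreenResult:
    """Per-eukaryote-gene outcome of the prokaryotic homolog screen."""

    records: dict[str, ScreenRecord]
    evalue_max: float

    def passes(self, gene_id: str) -> bool:
        rec = self.records.get(gene_id)
        return rec is not None and rec.passes

    def passing_genes(self) -> set[str]:
        return {g for g, r in self.records.items() if r.passes}


def _better(a: HomologyHit, b: Optional[HomologyHit]) -> bool:
    """True if a beats b: smaller evalue, then higher bitscore, then subject id."""
    if b is None:
        return True
    return (a.evalue, -a.bitscore, a.subject_id) < (b.evalue, -b.bitscore, b.subject_id)


def screen_homologs(
    euk_genes: Sequence[Gene],
    hits: Iterable[HomologyHit],
    panel: GenomePanel,
    config: PipelineConfig,
) -> HomologScreenResult:
    """Screen eukaryote genes for prokaryotic homologs.

    Only hits from a eukaryote query to a prokaryotic subject count; self-hits
    and hits to eukaryote subjects are ignored, and hits referencing unknown
    genes are dropped with a warning. A gene passes iff some counted hit has
    ``evalue < config.evalue_max`` (strict).
    """
    euk_ids = {g.gene_id for g in euk_genes}
    records = {
        g.gene_id: ScreenRecord(g.gene_id, False, None) for g in euk_genes
    }
    for hit in hits:
        if hit.query_id not in euk_ids:
            continue
        if hit.query_id == hit.subject_id or hit.subject_id in euk_ids:
            continue
        if not panel.has_gene(hit.subject_id):
            logger.warning(
                "hit %s->%s references unknown subject; dropped",
                hit.query_id, hit.subject_id,
            )
            continue
        if not panel.is_prokaryotic_gene(hit.subject_id):
            continue
        if hit.evalue >= config.evalue_max:
            continue
        rec = records[hit.query_id]
        rec.passes = True
        rec.prokaryotic_hit_genes.add(hit.subject_id)
        if _better(hit, rec.best_hit):
            rec.best_hit = hit
    for rec in records.values():
        rec.n_hit_genomes = len(
            {panel.genome_of(g).genome_id for g in rec.prokaryotic_hit_genes}
        )
    return HomologScreenResult(records=records, evalue_max=config.evalue_max)


def _validate_sequence(name: str, seq: str) -> None:
    bad = set(seq.upper()) - _AA_ALPHABET
    if bad:
        raise GeneContextError(
            f"sequence {name!r} contains non-amino-acid characters: {sorted(bad)}"
        )


def _kmers(seq: str, k: int = PREFILTER_KMER) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST "open 11 / extend 1": a gap of length g costs 11 + g
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def raw_score(seq_a: str, seq_b: str) -> float:
    """Smith-Waterman raw score (BLOSUM62, open 11 / extend 1); symmetric."""
    _validate_sequence("a", seq_a)
    _validate_sequence("b", seq_b)
    return float(_make_aligner().score(seq_a.upper(), seq_b.upper()))


def bitscore_from_raw(score: float) -> float:
    return (GAPPED_LAMBDA * score - math.log(GAPPED_K)) / math.log(2.0)


def evalue_from_bitscore(bits: float, m: int, n: int) -> float:
    return m * n * math.pow(2.0, -bits)


def align_pair(
    query_id: str, query: str, subject_id: str, subject: str
) -> HomologyHit:
    aligner = _make_aligner()
    aln = aligner.align(query.upper(), subject.upper())[0]
    score = float(aln.score)
    bits = bitscore_from_raw(score)
    evalue = evalue_from_bitscore(bits, len(query), len(subject))
    matches = 0
    columns = 0
    qspan = 0
    blocks_q, blocks_s = aln.aligned
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        for i in range(qe - qs):
            columns += 1
            if query.upper()[qs + i] == subject.upper()[ss + i]:
                matches += 1
        qspan += qe - qs
    pident = 100.0 * matches / columns if columns else 0.0
    cov = qspan / len(query) if query else 0.0
    return HomologyHit(
        query_id=query_id,
        subject_id=subject_id,
        evalue=evalue,
        bitscore=bits,
        pct_identity=pident,
        aln_query_cov=cov,
    )


def align_all(
    euk_records: dict[str, str],
    prok_records: dict[str, str],
    config: PipelineConfig,
) -> list[HomologyHit]:
    """All-vs-all local alignment of two small protein sets.

    A quick exact k-mer prefilter (shared 4-mer required) skips obviously
    unrelated pairs; surviving pairs are aligned and reported regardless of
    E-value, so callers can apply their own threshold.
    """
    for name, seq in list(euk_records.items()) + list(prok_records.items()):
        _validate_sequence(name, seq)
    prok_kmers = {
        pid: _kmers(seq.upper()) for pid, seq in prok_records.items()
    }
    hits: list[HomologyHit] = []
    for qid in sorted(euk_records):
        qseq = euk_records[qid].upper()
        qk = _kmers(qseq)
        for sid in sorted(prok_records):
            if not qk & prok_kmers[sid]:
                continue
            hits.append(align_pair(qid, qseq, sid, prok_records[sid].upper()))
    return hits
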