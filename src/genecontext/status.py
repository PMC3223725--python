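"""Known-versus-hypothetical classification of genes and families.

The selection sieve treats a gene as "known" — and excludes its whole family
from the candidate pool — if the gene or any member of its cross-genome family
sits in a subsystem of class ``non_hypothetical`` (established pathways,
processes, complexes). Genes whose only evidence is an experimental or
clustering-based subsystem, genes on a proteins-of-unknown-function (PUF)
list, and genes whose annotation matches a vague pattern ("hypothetical
protein", "DUF1234", a bare "ATPase") all count as unknown.

Rule order (first decisive rule wins):

1. family in a ``non_hypothetical`` subsystem  -> known
2. family only in experimental / clustering_based subsystems -> hypothetical
3. gene on the PUF list                        -> hypothetical
4. function string matches a vague pattern     -> vague (selected as unknown)
5. non-empty specific function -> known; empty -> hypothetical

The vague-pattern list ships as an editable text file
(``genecontext/data/vague_patterns.txt``); pass extra patterns through
``load_vague_patterns``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from .model import FamilyAssignment, Gene, GeneContextError

RULE_FAMILY_NON_HYPOTHETICAL_SUBSYSTEM = "family_in_non_hypothetical_subsystem"
RULE_ONLY_UNCHARACTERIZED_SUBSYSTEMS = "only_uncharacterized_subsystems"
RULE_PUF_LIST = "on_puf_list"
RULE_VAGUE_FUNCTION = "vague_function_string"
RULE_SPECIFIC_FUNCTION = "specific_function_string"
RULE_EMPTY_FUNCTION = "empty_function_string"


@dataclass(frozen=True)
class StatusDecision:
    gene_id: str
    status: str  # known | hypothetical | vague
    reasons: tuple[str, ...]

    @property
    def is_unknown(self) -> bool:
        """Vague annotations are treated as unknown during selection."""
        return self.status in ("hypothetical", "vague")


#: (compiled regex, match anywhere?) — full-line patterns flag only bare
#: generic annotations ("ATPase"), search patterns flag substrings ("DUF1234").
VaguePattern = tuple[re.Pattern, bool]


def load_vague_patterns(extra: Iterable[str] = ()) -> list[VaguePattern]:
    """Compile the shipped vague-annotation patterns plus any user additions."""
    text = (
        resources.files("genecontext").joinpath("data/vague_patterns.txt").read_text()
    )
    patterns: list[VaguePattern] = []
    for line in list(text.splitlines()) + list(extra):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("~"):
            patterns.append((re.compile(line[1:], re.IGNORECASE), True))
        else:
            patterns.append((re.compile(line, re.IGNORECASE), False))
    return patterns


_DEFAULT_PATTERNS: Optional[list[VaguePattern]] = None


def _default_patterns() -> list[VaguePattern]:
    global _DEFAULT_PATTERNS
    if _DEFAULT_PATTERNS is None:
        _DEFAULT_PATTERNS = load_vague_patterns()
    return _DEFAULT_PATTERNS


def is_vague_function(
    function: str, patterns: Optional[Sequence[VaguePattern]] = None
) -> bool:
    function = function.strip()
    if not function:
        return False
    for pat, anywhere in patterns if patterns is not None else _default_patterns():
        if anywhere:
            if pat.search(function):
                return True
        elif pat.fullmatch(function):
            return True
    return False


def classify_gene(
    gene: Gene,
    family: Optional[FamilyAssignment],
    puf_list: Optional[set[str]] = None,
    patterns: Optional[Sequence[VaguePattern]] = None,
) -> StatusDecision:
    """Classify one gene as known / hypothetical / vague.

    ``family`` is the cross-genome family containing the gene (subsystem
    membership is family-level, so "any same-family member in a subsystem"
    reduces to the family's subsystem classes). A gene without a family is a
    contract violation.
    """
    if family is None:
        raise GeneContextError(f"gene {gene.gene_id!r} has no family assignment")

    classes = set(family.subsystem_classes.values())
    if "non_hypothetical" in classes:
        return StatusDecision(
            gene.gene_id, "known", (RULE_FAMILY_NON_HYPOTHETICAL_SUBSYSTEM,)
        )
    if classes and classes <= {"experimental", "clustering_based"}:
        return StatusDecision(
            gene.gene_id, "hypothetical", (RULE_ONLY_UNCHARACTERIZED_SUBSYSTEMS,)
        )
    if puf_list and gene.gene_id in puf_list:
        return StatusDecision(gene.gene_id, "hypothetical", (RULE_PUF_LIST,))
    if is_vague_function(gene.function, patterns):
        return StatusDecision(gene.gene_id, "vague", (RULE_VAGUE_FUNCTION,))
    if gene.function.strip():
        return StatusDecision(gene.gene_id, "known", (RULE_SPECIFIC_FUNCTION,))
    return StatusDecision(gene.gene_id, "hypothetical", (RULE_EMPTY_FUNCTION,))


def derive_family_status(
    family: FamilyAssignment,
    genes_by_id: dict[str, Gene],
    puf_list: Optional[set[str]] = None,
    patterns: Optional[Sequence[VaguePattern]] = None,
) -> str:
    """Derive the family's status from subsystem classes and member functions.

    A single known member makes the family ``non_hypothetical`` (functions are
    shared within isofunctional families); otherwise the family is ``vague``
    if every resolvable member is vague, else ``hypothetical``. Deterministic
    and independent of member listing order.
    """
    statuses = set()
    for gid in sorted(family.member_gene_ids):
        gene = genes_by_id.get(gid)
        if gene is None:
            continue
        statuses.add(classify_gene(gene, family, puf_list, patterns).status)
    if "known" in statuses:
        return "non_hypothetical"
    if statuses == {"vague"}:
        return "vague"
    return "hypothetical"


def select_unknown_families(
    euk_families,
    screen_result,
    decisions: dict[str, StatusDecision],
):
    """Apply the candidate sieve to eukaryote families.

    A family is a candidate iff (a) at least one member passed the
    cross-kingdom homolog screen and (b) no member is classified known —
    either directly or through its prokaryotic orthologs (which the
    family-level classification already folds in).
    """
    candidates = []
    for fam in euk_families:
        passes = any(
            screen_result.passes(gid) for gid in fam.member_gene_ids
        )
        if not passes:
            continue
        if any(
            gid in decisions and decisions[gid].status == "known"
            for gid in fam.member_gene_ids
        ):
            continue
        candidates.append(fam)
    return candidates
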