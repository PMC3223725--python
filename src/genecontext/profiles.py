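"""Phyletic presence/absence profiles, co-occurrence, and signature queries.

Phyletic spread counts distinct prokaryotic *species* harboring a family —
intentionally a different base than functional coupling, which counts
dereplicated genome groups: a species with several near-identical strains
contributes one either way, but a species with two divergent strains counts
once here and may count twice for FC. Eukaryote genomes are excluded from
prokaryotic spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import FamilyAssignment, GeneContextError, GenomePanel


@dataclass(frozen=True)
class PhyleticProfile:
    """Presence/absence of one family across the species of a panel."""

    family_id: str
    presence: Mapping[str, bool]  # species_id -> present

    @property
    def spread(self) -> int:
        return sum(bool(v) for v in self.presence.values())

    def present_species(self) -> frozenset[str]:
        return frozenset(s for s, v in self.presence.items() if v)


def build_profiles(
    families: Sequence[FamilyAssignment], panel: GenomePanel
) -> list[PhyleticProfile]:
    """Build species-level profiles: any member in any strain marks presence."""
    species = panel.prokaryotic_species()
    profiles = []
    for fam in sorted(families, key=lambda f: f.family_id):
        present = set()
        for gid in fam.member_gene_ids:
            if panel.has_gene(gid) and panel.genome_of(gid).is_prokaryote:
                present.add(panel.species_of(gid))
        profiles.append(
            PhyleticProfile(
                family_id=fam.family_id,
                presence={s: s in present for s in species},
            )
        )
    return profiles


def cooccurrence(profile_a: PhyleticProfile, profile_b: PhyleticProfile) -> float:
    """Jaccard index of two presence profiles over the same species universe.

    Defined as 0.0 when both profiles are empty.
    """
    if set(profile_a.presence) != set(profile_b.presence):
        raise GeneContextError(
            "cooccurrence: profiles span different species universes"
        )
    a = profile_a.present_species()
    b = profile_b.present_species()
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def signature_families(
    profiles: Sequence[PhyleticProfile],
    in_group: set[str],
    out_group: set[str],
    min_in_frac: float = 1.0,
    max_out_frac: float = 0.0,
) -> list[PhyleticProfile]:
    """Families common to ``in_group`` species and absent from ``out_group``.

    A family is reported iff its presence fraction over the in-group is at
    least ``min_in_frac`` and over the out-group at most ``max_out_frac``.
    Groups must be disjoint; an empty in-group is a hard error. Output sorted
    by descending in-fraction, then family id.
    """
    if not in_group:
        raise GeneContextError("signature_families: empty in_group")
    if in_group & out_group:
        raise GeneContextError(
            f"signature_families: groups overlap: {sorted(in_group & out_group)}"
        )
    scored = []
    for prof in profiles:
        present = prof.present_species()
        in_frac = len(present & in_group) / len(in_group)
        out_frac = len(present & out_group) / len(out_group) if out_group else 0.0
        if in_frac >= min_in_frac and out_frac <= max_out_frac:
            scored.append((-in_frac, prof.family_id, prof))
    return [p for _, _, p in sorted(scored)]
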