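"""Readers and writers for the standard formats the pipeline consumes.

Formats: GFF3 (CDS features with an ``ID`` attribute), protein FASTA whose
record IDs are gene IDs, 12-column BLAST tabular hits, and tab-separated
metadata / annotation / output tables. GFF3 parsing goes through ``gffutils``;
FASTA through Biopython; tables through pandas.
"""

from __future__ import annotations

import logging
import os
import urllib.parse
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import (
    FamilyAssignment,
    Gene,
    GeneContextError,
    Genome,
    GenomePanel,
    HomologyHit,
)

logger = logging.getLogger(__name__)

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

METADATA_COLUMNS = [
    "genome_id", "species_id", "domain", "is_model_organism",
    "strain_group_id", "circular",
]


def _quote(value: str) -> str:
    return urllib.parse.quote(value, safe=" ()/.:'+-*^$@!?|")


def _gff3_has_features(path: str | Path) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line and not line.startswith("#"):
                return True
    return False


def read_metadata(metadata_tsv: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_tsv, sep="\t", dtype=str, keep_default_na=False)
    missing = {"genome_id", "species_id", "domain"} - set(meta.columns)
    if missing:
        raise GeneContextError(f"metadata TSV missing columns: {sorted(missing)}")
    return meta.set_index("genome_id", drop=False)


def read_genome_panel(
    gff3_paths: Sequence[str | Path],
    fasta_paths: Sequence[str | Path] = (),
    metadata_tsv: str | Path | None = None,
) -> GenomePanel:
    """Load a genome panel from per-genome GFF3 files plus shared metadata.

    Each GFF3 file holds one genome; its genome_id is the file stem. Only CDS
    features are modeled (RNA genes and pseudogenes are ignored). The metadata
    TSV is the single source of species / domain / model-organism truth.
    Protein sequences are attached when FASTA record IDs match gene IDs; genes
    without a sequence are retained.
    """
    proteins: dict[str, str] = {}
    for fasta in fasta_paths:
        for rec in SeqIO.parse(str(fasta), "fasta"):
            proteins[rec.id] = str(rec.seq)

    meta = read_metadata(metadata_tsv) if metadata_tsv is not None else None

    panel = GenomePanel()
    for gff3 in gff3_paths:
        genome_id = Path(gff3).stem
        if meta is not None:
            if genome_id not in meta.index:
                raise GeneContextError(
                    f"genome {genome_id!r} absent from metadata TSV"
                )
            row = meta.loc[genome_id]
            genome = Genome(
                genome_id=genome_id,
                species_id=row["species_id"],
                domain=row["domain"],
                is_model_organism=str(row.get("is_model_organism", "false")).lower()
                in ("1", "true", "yes"),
                strain_group_id=row.get("strain_group_id") or None,
            )
            circular_default = str(row.get("circular", "false")).lower() in (
                "1", "true", "yes",
            )
        else:
            genome = Genome(genome_id=genome_id, species_id=genome_id)
            circular_default = False

        if _gff3_has_features(gff3):
            db = gffutils.create_db(
                str(gff3), dbfn=":memory:", force=True, keep_order=True,
                merge_strategy="error",
            )
            for feat in db.features_of_type("CDS"):
                if "ID" not in feat.attributes:
                    raise GeneContextError(
                        f"{gff3}: CDS at {feat.seqid}:{feat.start}-{feat.end} "
                        "lacks an ID attribute"
                    )
                gene_id = feat.attributes["ID"][0]
                function = urllib.parse.unquote(
                    feat.attributes.get("product", [""])[0]
                )
                gene = Gene(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    function=function,
                    protein=proteins.get(gene_id),
                )
                genome.add_gene(gene)
                genome.circular[feat.seqid] = circular_default
        panel.add_genome(genome)
    return panel


def write_genome_gff3(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genome.genes():
            attrs = f"ID={_quote(gene.gene_id)}"
            if gene.function:
                attrs += f";product={_quote(gene.function)}"
            fh.write(
                f"{gene.contig_id}\tgenecontext\tCDS\t{gene.start}\t{gene.end}"
                f"\t.\t{gene.strand}\t0\t{attrs}\n"
            )


def write_genome_panel(panel: GenomePanel, out_dir: str | Path) -> dict[str, Path]:
    """Write one GFF3 per genome plus metadata.tsv and proteins.faa.

    Returns the paths written. Inverse of :func:`read_genome_panel` up to
    protein attachment (genes without sequences stay sequence-free).
    """
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for genome_id in sorted(panel.genomes):
        genome = panel.genomes[genome_id]
        gff_path = out / "genomes" / f"{genome_id}.gff3"
        write_genome_gff3(genome, gff_path)
        paths[genome_id] = gff_path
        rows.append(
            {
                "genome_id": genome_id,
                "species_id": genome.species_id,
                "domain": genome.domain,
                "is_model_organism": str(genome.is_model_organism).lower(),
                "strain_group_id": genome.strain_group_id or "",
                "circular": str(any(genome.circular.values())).lower(),
            }
        )
    meta_path = out / "metadata.tsv"
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        meta_path, sep="\t", index=False
    )
    paths["metadata"] = meta_path

    faa_path = out / "proteins.faa"
    with open(faa_path, "w") as fh:
        for gene in panel.genes():
            if gene.protein:
                fh.write(f">{gene.gene_id}\n{gene.protein}\n")
    paths["proteins"] = faa_path
    return paths


def read_hits(
    blast_tab_path: str | Path,
    query_lengths: Optional[dict[str, int]] = None,
) -> list[HomologyHit]:
    """Parse 12-column BLAST tabular output into homology hits.

    Malformed rows are skipped with a logged warning naming the row number;
    a non-numeric E-value is a hard error. Query coverage is computed as
    aligned query span over query length when ``query_lengths`` supplies the
    length, otherwise left unknown (``None``).
    """
    hits: list[HomologyHit] = []
    with open(blast_tab_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                logger.warning(
                    "%s: row %d malformed (%d columns, expected 12); skipped",
                    blast_tab_path, lineno, len(fields),
                )
                continue
            try:
                evalue = float(fields[10])
            except ValueError as exc:
                raise GeneContextError(
                    f"{blast_tab_path}: row {lineno}: non-numeric evalue "
                    f"{fields[10]!r}"
                ) from exc
            try:
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                bitscore = float(fields[11])
            except ValueError:
                logger.warning(
                    "%s: row %d malformed numeric field; skipped",
                    blast_tab_path, lineno,
                )
                continue
            cov = None
            if query_lengths and fields[0] in query_lengths:
                qlen = query_lengths[fields[0]]
                if qlen > 0:
                    cov = min(1.0, (abs(qend - qstart) + 1) / qlen)
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    evalue=evalue,
                    bitscore=bitscore,
                    pct_identity=pident,
                    aln_query_cov=cov,
                )
            )
    return hits


def write_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits as 12-column BLAST tabular (alignment columns synthesized)."""
    with open(path, "w") as fh:
        for h in hits:
            length = 100
            qend = int(round((h.aln_query_cov or 1.0) * length))
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.1f}\t{length}"
                f"\t0\t0\t1\t{max(qend, 1)}\t1\t{max(qend, 1)}"
                f"\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def write_families_tsv(families: list[FamilyAssignment], path: str | Path) -> None:
    rows = [
        {
            "family_id": f.family_id,
            "status": f.status,
            "subsystems": ",".join(
                f"{s}:{f.subsystem_classes.get(s, '')}" for s in sorted(f.subsystem_ids)
            ),
            "members": ",".join(sorted(f.member_gene_ids)),
        }
        for f in sorted(families, key=lambda f: f.family_id)
    ]
    pd.DataFrame(rows, columns=["family_id", "status", "subsystems", "members"]).to_csv(
        path, sep="\t", index=False
    )


def read_families_tsv(path: str | Path) -> list[FamilyAssignment]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    families = []
    for _, row in df.iterrows():
        classes = {}
        if row.get("subsystems"):
            for item in row["subsystems"].split(","):
                ss, _, cls = item.partition(":")
                classes[ss] = cls
        families.append(
            FamilyAssignment(
                family_id=row["family_id"],
                member_gene_ids=set(filter(None, row["members"].split(","))),
                status=row.get("status") or "hypothetical",
                subsystem_classes=classes,
            )
        )
    return families


def write_tables(records, out_dir: str | Path) -> dict[str, Path]:
    """Write candidate records as a deterministic TSV (rank, then family id).

    Columns are fixed and documented in the header; writing the same records
    twice produces byte-identical files.
    """
    from .pipeline import CANDIDATE_COLUMNS, candidate_to_row  # local: avoid cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "candidates.tsv"
    rows = [candidate_to_row(r) for r in records]
    rows.sort(key=lambda r: (r["rank"], r["euk_family_id"]))
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise GeneContextError(f"cannot write {path}: {exc}") from exc
    return {"candidates": path}


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    os.makedirs(path.parent, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


@dataclass
class RunInputs:
    """Inputs loaded from an emitted run directory."""

    panel: GenomePanel          # prokaryotic genomes only
    euk_genes: list
    hits: list
    families: Optional[list]    # curated assignments, if families.tsv present


def load_run_dir(run_dir: str | Path) -> RunInputs:
    """Load the directory layout the simulator emits (see simulate.emit)."""
    run = Path(run_dir)
    gff3_paths = sorted((run / "genomes").glob("*.gff3"))
    fasta = run / "proteins.faa"
    full = read_genome_panel(
        gff3_paths,
        [fasta] if fasta.exists() and fasta.stat().st_size else [],
        run / "metadata.tsv",
    )
    panel = GenomePanel(
        [g for g in full.genomes.values() if g.is_prokaryote]
    )
    euk_genes = [
        gene
        for g in full.genomes.values()
        if not g.is_prokaryote
        for gene in g.genes()
    ]
    hits_path = run / "hits.tsv"
    hits = read_hits(hits_path) if hits_path.exists() else []
    fam_path = run / "families.tsv"
    families = read_families_tsv(fam_path) if fam_path.exists() else None
    return RunInputs(panel=panel, euk_genes=euk_genes, hits=hits, families=families)
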