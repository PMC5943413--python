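"""Readers and writers for the standard formats the pipeline touches.

FASTA in/out via Biopython, GFF3 via gffutils (in-memory db).  All
coordinate conversion between file dialects and the internal 0-based
half-open convention happens here and only here.
"""
from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils

from .models import DNA_ALPHABET, GeneModel, GuideSite, StrainGenome

logger = logging.getLogger(__name__)

GUIDE_TSV_COLUMNS = [
    "target_23",
    "protospacer",
    "pam",
    "genome",
    "contig",
    "start",
    "strand",
    "gene_id",
    "conservation_level",
    "genomes_present",
]


def read_fasta(path: Union[str, os.PathLike]) -> dict[str, str]:
    """Read a FASTA file into ``{contig_id: sequence}``.

    Headers are truncated at the first whitespace; sequences are
    uppercased.  RNA (U) and any character outside A/C/G/T/N are
    rejected with the offending contig and 1-based position named.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: contig {rec.id!r} has empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            what = "RNA base 'U'" if seq[pos] == "U" else f"character {seq[pos]!r}"
            raise ValueError(
                f"{path}: invalid {what} in contig {rec.id!r} at position {pos + 1}"
            )
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(contigs: dict[str, str], path: Union[str, os.PathLike], width: int = 70) -> None:
    """Write ``{id: sequence}`` as wrapped FASTA (deterministic byte output)."""
    with open(path, "w") as fh:
        for cid in contigs:
            fh.write(f">{cid}\n")
            seq = contigs[cid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genome(
    fasta_path: Union[str, os.PathLike],
    gff3_path: Union[str, os.PathLike, None] = None,
    strain_id: str | None = None,
) -> StrainGenome:
    """Load one strain assembly, optionally with its GFF3 annotation."""
    if strain_id is None:
        strain_id = os.path.splitext(os.path.basename(str(fasta_path)))[0]
    genome = StrainGenome(strain_id=strain_id, contigs=read_fasta(fasta_path))
    if gff3_path is not None:
        genome.genes = read_gff3(gff3_path, genome)
    genome.validate()
    return genome


def _cds_chain(db: gffutils.FeatureDB, parent) -> list[tuple[int, int]]:
    """CDS intervals of one parent feature, 0-based half-open, sorted."""
    ivals = [(f.start - 1, f.end) for f in db.children(parent, featuretype="CDS")]
    return sorted(ivals)


def read_gff3(path: Union[str, os.PathLike], genome: StrainGenome) -> list[GeneModel]:
    """Parse gene models from GFF3.

    GFF3 coordinates (1-based closed) become 0-based half-open.  Genes
    with several mRNAs collapse to the isoform with the longest total
    CDS; genes without any CDS are skipped with a log message.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        chains = [_cds_chain(db, mrna) for mrna in db.children(gene, featuretype="mRNA")]
        chains = [c for c in chains if c]
        if not chains:
            direct = _cds_chain(db, gene)
            chains = [direct] if direct else []
        if not chains:
            logger.info("read_gff3: gene %s has no CDS, skipped", gene.id)
            continue
        best = max(chains, key=lambda c: sum(e - s for s, e in c))
        if gene.seqid not in genome.contigs:
            raise ValueError(f"{path}: gene {gene.id} references unknown contig {gene.seqid!r}")
        if best[-1][1] > len(genome.contigs[gene.seqid]):
            raise ValueError(f"{path}: gene {gene.id} exceeds contig {gene.seqid!r} bounds")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig_id=gene.seqid,
                strand=gene.strand,
                cds_intervals=tuple(best),
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: Union[str, os.PathLike], source: str = "panguide") -> None:
    """Write gene models as GFF3 (gene + CDS features, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            fh.write(
                f"{g.contig_id}\t{source}\tgene\t{start + 1}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_intervals):
                fh.write(
                    f"{g.contig_id}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def _guide_rows(guides: Iterable) -> list[dict]:
    """Flatten GuideSite or ConservedGuide objects to TSV rows."""
    rows = []
    for g in guides:
        if isinstance(g, GuideSite):
            rows.append(
                dict(
                    target_23=g.target_23,
                    protospacer=g.protospacer,
                    pam=g.pam,
                    genome=g.genome_id,
                    contig=g.contig_id,
                    start=g.start,
                    strand=g.strand,
                    gene_id=g.gene_id or "",
                    conservation_level="",
                    genomes_present="",
                )
            )
        else:  # ConservedGuide-like: has .occurrences / .conservation_level
            present = ",".join(sorted(g.occurrences))
            for genome_id in sorted(g.occurrences):
                for site in g.occurrences[genome_id]:
                    rows.append(
                        dict(
                            target_23=g.target_23,
                            protospacer=site.protospacer,
                            pam=site.pam,
                            genome=genome_id,
                            contig=site.contig_id,
                            start=site.start,
                            strand=site.strand,
                            gene_id=site.gene_id or "",
                            conservation_level=g.conservation_level,
                            genomes_present=present,
                        )
                    )
    return rows


def write_guides(guides: Sequence, path: Union[str, os.PathLike], fmt: str = "tsv") -> None:
    """Write guides as ``tsv``, ``bed`` (BED6, 23-nt spans) or ``fasta``.

    TSV columns are fixed (``GUIDE_TSV_COLUMNS``); BED spans are 0-based
    half-open; FASTA records are keyed by the 23-nt target sequence.
    """
    rows = _guide_rows(guides)
    if fmt == "tsv":
        df = pd.DataFrame(rows, columns=GUIDE_TSV_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        with open(path, "w") as fh:
            for r in rows:
                score = r["conservation_level"] if r["conservation_level"] != "" else 0
                fh.write(
                    f"{r['contig']}\t{r['start']}\t{r['start'] + 23}\t"
                    f"{r['target_23']}\t{score}\t{r['strand']}\n"
                )
    elif fmt == "fasta":
        seen: dict[str, str] = {}
        for r in rows:
            desc = f"{r['genome']}:{r['contig']}:{r['start']}:{r['strand']}"
            seen.setdefault(r["target_23"], desc)
        records = [
            SeqRecord(Seq(t), id=t, description=seen[t]) for t in seen
        ]
        SeqIO.write(records, str(path), "fasta")
    else:
        raise ValueError(f"unknown guide output format {fmt!r}")


def read_guides_tsv(path: Union[str, os.PathLike]) -> list[GuideSite]:
    """Re-parse a guide TSV written by :func:`write_guides`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    guides = []
    for _, r in df.iterrows():
        guides.append(
            GuideSite(
                target_23=r["target_23"],
                protospacer=r["protospacer"],
                pam=r["pam"],
                genome_id=r["genome"],
                contig_id=r["contig"],
                start=int(r["start"]),
                strand=r["strand"],
                gene_id=r["gene_id"] or None,
            )
        )
    return guides
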