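"""Enumeration of candidate gRNA target sites (20-nt protospacer + NGG PAM).

SpCas9 cuts next to an NGG protospacer-adjacent motif, so every 23-nt
window whose last two bases are GG is a candidate on the forward strand,
and every window starting with CC is a candidate on the reverse strand
(read as its reverse complement).  Windows containing N are never sites:
an ambiguous base can satisfy neither an identity nor a mismatch count.
"""
from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from intervaltree import IntervalTree

from .models import DesignParams, GuideSite, StrainGenome, revcomp


def _scan_sites(
    sequence: str,
    genome_id: str = "",
    contig_id: str = "",
    pam_suffixes: tuple[str, ...] = ("GG",),
) -> list[GuideSite]:
    """All PAM-adjacent 23-nt windows on both strands, sorted by (start, strand).

    ``pam_suffixes`` are the allowed last-two PAM bases in guide
    orientation ("GG" for NGG; add "AG" for the non-canonical NAG class).
    """
    sites: list[GuideSite] = []
    L = len(sequence)
    if L < 23:
        return sites
    fwd_marks = set(pam_suffixes)
    rev_marks = {revcomp(sfx) for sfx in pam_suffixes}  # e.g. GG -> CC at window start
    for i in range(L - 22):
        window = sequence[i : i + 23]
        if window[21:23] in fwd_marks and "N" not in window:
            sites.append(
                GuideSite(
                    target_23=window,
                    protospacer=window[:20],
                    pam=window[20:23],
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=i,
                    strand="+",
                )
            )
        if window[0:2] in rev_marks and "N" not in window:
            target = revcomp(window)
            sites.append(
                GuideSite(
                    target_23=target,
                    protospacer=target[:20],
                    pam=target[20:23],
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=i,
                    strand="-",
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def scan_pams(
    sequence: str,
    params: DesignParams | None = None,
    genome_id: str = "",
    contig_id: str = "",
) -> list[GuideSite]:
    """Enumerate all NGG guide sites in one sequence (both strands).

    Sequences shorter than 23 nt yield an empty list.  Output is sorted
    by (start, strand) and each site's ``target_23`` re-locates exactly
    to its coordinates (orientation-aware).
    """
    return _scan_sites(sequence, genome_id=genome_id, contig_id=contig_id)


def gene_interval_trees(genome: StrainGenome) -> dict[str, IntervalTree]:
    """Per-contig interval trees over gene spans (data = gene_id)."""
    trees: dict[str, IntervalTree] = {}
    for gene in genome.genes:
        start, end = gene.span
        trees.setdefault(gene.contig_id, IntervalTree()).addi(start, end, gene.gene_id)
    return trees


def guides_in_genes(
    genome: StrainGenome, params: DesignParams | None = None
) -> list[GuideSite]:
    """Guide sites whose 23-nt span intersects an annotated gene.

    A site belongs to a gene iff its span overlaps that gene's annotated
    region (intersection, not containment).  With
    ``allow_overlapping_genes = False`` (default), sites touching two or
    more distinct genes are discarded — they cannot knock out a single
    gene cleanly.  ``in_gene_fraction`` records how much of the 23-nt
    span lies inside the assigned gene.
    """
    params = params or DesignParams()
    if not genome.is_annotated:
        raise ValueError(
            f"genome {genome.strain_id} has no gene models; run "
            "annotation_transfer.transfer_annotations first or supply a GFF3"
        )
    trees = gene_interval_trees(genome)
    out: list[GuideSite] = []
    for contig_id, seq in genome.contigs.items():
        tree = trees.get(contig_id)
        if tree is None:
            continue
        for site in _scan_sites(seq, genome_id=genome.strain_id, contig_id=contig_id):
            hits = tree[site.start : site.end]
            gene_ids = {h.data for h in hits}
            if not gene_ids:
                continue
            if len(gene_ids) >= 2 and not params.allow_overlapping_genes:
                continue
            for h in sorted(hits, key=lambda h: (h.data,)):
                ov = min(site.end, h.end) - max(site.start, h.begin)
                out.append(
                    replace(site, gene_id=h.data, in_gene_fraction=round(ov / 23.0, 4))
                )
                if not params.allow_overlapping_genes:
                    break
    out.sort(key=lambda s: (s.contig_id, s.start, s.strand, s.gene_id or ""))
    return out
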