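"""Homology-based transfer of protein-coding annotation between strains.

The reference strain's proteins are searched against each unannotated
assembly by an internal translated search: exact 5-mer amino-acid seeds
over the six-frame translation of the target, ungapped X-drop extension
under BLOSUM62, and a Karlin-Altschul e-value with standard ungapped
parameters (lambda = 0.3176, K = 0.134).  The best-scoring locus with
e-value at or below the threshold (default 1e-10) becomes a transferred
gene model spanning the aligned nucleotide interval.  No intron
reconstruction is attempted: downstream guide discovery only needs the
gene's target region.

A loader for precomputed 12-column tabular homology hits is provided so
an external search program can be substituted without touching the rest
of the pipeline.
"""
from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from typing import Sequence, Union

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .models import GeneModel, StrainGenome, revcomp

logger = logging.getLogger(__name__)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# Karlin-Altschul ungapped parameters for BLOSUM62
_LAMBDA = 0.3176
_K = 0.134
_SEED_K = 5
_XDROP = 20.0


@dataclass(frozen=True)
class ProteinQuery:
    """One reference protein used as a transfer query (terminal stop removed)."""

    gene_id: str
    aa_sequence: str

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError(f"{self.gene_id}: empty protein sequence")
        if self.aa_sequence.endswith("*"):
            raise ValueError(f"{self.gene_id}: terminal stop must be removed")


@dataclass(frozen=True)
class HomologyHit:
    """Best alignment of one query protein onto a target genome."""

    gene_id: str
    target_contig: str
    target_interval: tuple[int, int]  # nucleotide, 0-based half-open, forward strand
    strand: str
    score: float  # raw ungapped BLOSUM62 score
    bits: float
    evalue: float
    aligned_aa: int


def translate_cds(gene: GeneModel, genome: StrainGenome) -> str:
    """Translate a gene model with the standard genetic code (table 1).

    Minus-strand genes are reverse complemented before translation; a
    trailing stop is dropped.  An internal stop in a complete model is
    reported as a warning and the translation truncated there.
    """
    seq = genome.contigs[gene.contig_id]
    cds = "".join(seq[s:e] for s, e in gene.cds_intervals)
    if len(cds) < 3:
        raise ValueError(f"gene {gene.gene_id}: CDS shorter than one codon")
    if gene.strand == "-":
        cds = revcomp(cds)
    aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        logger.warning(
            "translate_cds: internal stop in gene %s; translation truncated", gene.gene_id
        )
        aa = aa.split("*")[0]
    return aa


def proteome(genome: StrainGenome) -> list[ProteinQuery]:
    """All translatable proteins of an annotated genome."""
    queries = []
    for gene in genome.genes:
        aa = translate_cds(gene, genome)
        if aa:
            queries.append(ProteinQuery(gene_id=gene.gene_id, aa_sequence=aa))
    return queries


def _six_frames(seq: str) -> list[tuple[str, int, str]]:
    """(aa_string, frame_offset, strand) for all six reading frames."""
    frames = []
    rc = revcomp(seq)
    for src, strand in ((seq, "+"), (rc, "-")):
        for f in range(3):
            sub = src[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) >= 3:
                frames.append((str(Seq(sub).translate(table=1)), f, strand))
    return frames


def _seed_table(frames: Sequence[tuple[str, int, str]]) -> dict[str, list[tuple[int, int]]]:
    """Exact amino-acid k-mer -> list of (frame_index, aa_position)."""
    table: dict[str, list[tuple[int, int]]] = {}
    for fi, (aa, _f, _s) in enumerate(frames):
        for p in range(len(aa) - _SEED_K + 1):
            kmer = aa[p : p + _SEED_K]
            if "*" in kmer or "X" in kmer:
                continue
            table.setdefault(kmer, []).append((fi, p))
    return table


def _pair_score(a: str, b: str) -> float:
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return -4.0


def _extend(query: str, target: str, qpos: int, tpos: int) -> tuple[float, int, int, int, int]:
    """Ungapped X-drop extension around a seed.

    Returns (score, q_start, q_end, t_start, t_end) of the best-scoring
    segment containing the seed (half-open in both sequences).
    """
    # right extension (including the seed columns themselves)
    score = 0.0
    best = 0.0
    best_right = 0
    i = 0
    while qpos + i < len(query) and tpos + i < len(target):
        score += _pair_score(query[qpos + i], target[tpos + i])
        i += 1
        if score > best:
            best, best_right = score, i
        if best - score > _XDROP:
            break
    # left extension
    score = 0.0
    best_l = 0.0
    best_left = 0
    j = 1
    while qpos - j >= 0 and tpos - j >= 0:
        score += _pair_score(query[qpos - j], target[tpos - j])
        if score > best_l:
            best_l, best_left = score, j
        if best_l - score > _XDROP:
            break
        j += 1
    total = best + best_l
    return total, qpos - best_left, qpos + best_right, tpos - best_left, tpos + best_right


def _frame_to_forward_nt(
    frame_offset: int, strand: str, aa_start: int, aa_end: int, contig_len: int
) -> tuple[int, int]:
    """Map an aa interval in one reading frame to forward-strand nucleotides."""
    nt_lo = frame_offset + 3 * aa_start
    nt_hi = frame_offset + 3 * aa_end
    if strand == "+":
        return nt_lo, nt_hi
    return contig_len - nt_hi, contig_len - nt_lo


def _best_hit_for_query(
    query: ProteinQuery,
    contig_id: str,
    contig_len: int,
    frames: Sequence[tuple[str, int, str]],
    seeds: dict[str, list[tuple[int, int]]],
    search_space: float,
) -> HomologyHit | None:
    qaa = query.aa_sequence
    best: tuple[float, int, int, int, int, int] | None = None  # score,fi,qs,qe,ts,te
    seen: set[tuple[int, int]] = set()  # (frame, diagonal) already extended
    for qp in range(len(qaa) - _SEED_K + 1):
        kmer = qaa[qp : qp + _SEED_K]
        for fi, tp in seeds.get(kmer, ()):
            diag = (fi, tp - qp)
            if diag in seen:
                continue
            seen.add(diag)
            taa = frames[fi][0]
            score, qs, qe, ts, te = _extend(qaa, taa, qp, tp)
            if best is None or score > best[0]:
                best = (score, fi, qs, qe, ts, te)
    if best is None:
        return None
    score, fi, qs, qe, ts, te = best
    bits = (_LAMBDA * score - math.log(_K)) / math.log(2.0)
    evalue = search_space * math.pow(2.0, -bits)
    _aa, f_off, strand = frames[fi]
    nt = _frame_to_forward_nt(f_off, strand, ts, te, contig_len)
    return HomologyHit(
        gene_id=query.gene_id,
        target_contig=contig_id,
        target_interval=nt,
        strand=strand,
        score=score,
        bits=bits,
        evalue=evalue,
        aligned_aa=qe - qs,
    )


def search_proteins(
    queries: Sequence[ProteinQuery], target: StrainGenome
) -> list[HomologyHit]:
    """Best translated hit per query protein over all target contigs."""
    per_contig = []
    total_aa = 0
    for contig_id, seq in target.contigs.items():
        frames = _six_frames(seq)
        total_aa += sum(len(f[0]) for f in frames)
        per_contig.append((contig_id, len(seq), frames, _seed_table(frames)))
    hits: list[HomologyHit] = []
    for q in queries:
        # K is folded into the bit score, so E = m * n * 2^-bits
        search_space = float(len(q.aa_sequence)) * max(total_aa, 1)
        best: HomologyHit | None = None
        for contig_id, clen, frames, seeds in per_contig:
            h = _best_hit_for_query(q, contig_id, clen, frames, seeds, search_space)
            if h is not None and (best is None or h.score > best.score):
                best = h
        if best is not None:
            hits.append(best)
    return hits


def hits_to_models(
    hits: Sequence[HomologyHit], evalue_threshold: float = 1e-10
) -> list[GeneModel]:
    """Turn qualifying hits into transferred gene models, one gene per locus.

    Hits above the e-value threshold are dropped.  When the intervals of
    two genes' best hits overlap on the same contig, the higher raw
    score wins; ties break by longer alignment, then lexicographic
    gene_id.  Displaced secondary hits are logged.
    """
    kept = [h for h in hits if h.evalue <= evalue_threshold]
    kept.sort(key=lambda h: (-h.score, -h.aligned_aa, h.gene_id))
    accepted: list[HomologyHit] = []
    for h in kept:
        clash = any(
            a.target_contig == h.target_contig
            and h.target_interval[0] < a.target_interval[1]
            and a.target_interval[0] < h.target_interval[1]
            for a in accepted
        )
        if clash:
            logger.info(
                "transfer: secondary hit for %s at %s:%s displaced by a better gene",
                h.gene_id, h.target_contig, h.target_interval,
            )
            continue
        accepted.append(h)
    models = [
        GeneModel(
            gene_id=h.gene_id,
            contig_id=h.target_contig,
            strand=h.strand,
            cds_intervals=(h.target_interval,),
            source="transferred",
        )
        for h in accepted
    ]
    models.sort(key=lambda m: (m.contig_id, m.span[0], m.gene_id))
    return models


def transfer_annotations(
    reference: StrainGenome,
    target: StrainGenome,
    evalue_threshold: float = 1e-10,
) -> list[GeneModel]:
    """Transfer the reference's protein-coding annotation onto a target.

    Deterministic: identical inputs give identical models, and lowering
    the e-value threshold can only remove transferred genes.
    """
    if not reference.is_annotated:
        raise ValueError(f"reference genome {reference.strain_id} has no annotation")
    queries = proteome(reference)
    hits = search_proteins(queries, target)
    return hits_to_models(hits, evalue_threshold=evalue_threshold)


def read_blast_tab(path: Union[str, os.PathLike]) -> list[HomologyHit]:
    """Load precomputed homology hits in the 12-column tabular dialect.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Subject coordinates are 1-based closed
    and reversed for minus-strand hits.  Only the best hit per query is
    retained (highest bitscore).
    """
    best: dict[str, HomologyHit] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ValueError(f"{path}: expected 12 tab-separated columns, got {len(f)}")
            qid, sid = f[0], f[1]
            length = int(f[3])
            sstart, send = int(f[8]), int(f[9])
            evalue, bits = float(f[10]), float(f[11])
            if sstart <= send:
                strand, interval = "+", (sstart - 1, send)
            else:
                strand, interval = "-", (send - 1, sstart)
            hit = HomologyHit(
                gene_id=qid,
                target_contig=sid,
                target_interval=interval,
                strand=strand,
                score=bits,  # raw score unavailable in the tabular dialect
                bits=bits,
                evalue=evalue,
                aligned_aa=length,
            )
            if qid not in best or bits > best[qid].bits:
                best[qid] = hit
    return [best[q] for q in sorted(best)]
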