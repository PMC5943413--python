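"""Locus-directed guide selection for gene knockouts.

Covers the bookkeeping a knockout experiment needs: offsets of each
guide relative to the ATG start codon in gene-sense coordinates, sense
versus antisense strand classification, the blunt SpCas9 cut site
(3 bp from the PAM, between protospacer positions 17 and 18), and the
deletion predicted when two guides cut the same locus.

It also handles identical paralog pairs (the Matalpha3/HMLalpha3
situation in *Kluyveromyces*): when two loci carry byte-identical gene
sequences, no guide can distinguish them, so a knockout guide is
accepted only if *all* of its perfect matches fall inside the allowed
loci and it hits every allowed copy that contains the target, with no
near-matches elsewhere in the genome.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .guide_discovery import guides_in_genes
from .models import DesignParams, GeneModel, GuideSite, StrainGenome, revcomp
from .offtarget import SiteIndex, find_near_matches

Scorer = Callable[[str], float]


@dataclass
class LocusGuide:
    """A guide annotated for a specific target gene.

    Offsets are 1-based positions in gene-sense coordinates with the A
    of the ATG start codon at position 1.  Two conventions circulate for
    "bp downstream of ATG" and both are carried: the protospacer 5'
    start and the PAM start (which for sense guides differ by exactly
    20 nt).  Antisense offsets anchor to the protospacer base closest to
    the ATG (its 5'-most base in gene-sense coordinates).
    """

    site: GuideSite
    gene_id: str
    offset_protospacer_start: int
    offset_pam_start: int
    guide_strand_vs_gene: str  # "sense" | "antisense"
    cut_position: int  # forward-strand boundary coordinate of the blunt cut
    context_30: str = ""
    rank_score: float = 0.0

    @property
    def offset_reported(self) -> int:
        """The conventional single 'downstream of ATG' figure: PAM start
        for sense guides, protospacer start for antisense guides."""
        if self.guide_strand_vs_gene == "sense":
            return self.offset_pam_start
        return self.offset_protospacer_start


@dataclass
class DeletionPrediction:
    """Blunt-cut deletion between two guides on one contig.

    Real NHEJ junctions often show additional end resection, so the
    observed deletion can exceed this blunt-cut arithmetic; the ``note``
    field flags that explicitly.
    """

    guide_a: LocusGuide
    guide_b: LocusGuide
    predicted_interval: tuple[int, int]
    predicted_length: int
    junction: str = ""
    note: str = (
        "blunt-cut arithmetic only; NHEJ end processing may enlarge the observed deletion"
    )


def classify_strand(guide: GuideSite | LocusGuide, gene: GeneModel) -> str:
    """'sense' iff the guide strand equals the gene strand."""
    site = guide.site if isinstance(guide, LocusGuide) else guide
    return "sense" if site.strand == gene.strand else "antisense"


def _gene_sense_coord(forward_pos: int, gene: GeneModel) -> int:
    """1-based gene-sense coordinate of a forward-strand position (ATG A = 1)."""
    start, end = gene.span
    if gene.strand == "+":
        return forward_pos - start + 1
    return end - forward_pos


def cut_site(guide: GuideSite | LocusGuide) -> int:
    """Forward-strand boundary coordinate of the blunt Cas9 cut.

    The cut falls between protospacer positions 17 and 18 (3 nt from
    the PAM).  Returned as the index of the first base 3' of the cut on
    the forward strand, so reverse complementing the contig maps the
    coordinate by reflection (cut' = L - cut).
    """
    site = guide.site if isinstance(guide, LocusGuide) else guide
    if site.strand == "+":
        return site.start + 17
    return site.start + 6


def guide_offsets(site: GuideSite, gene: GeneModel) -> tuple[int, int]:
    """(protospacer-start, PAM-start) offsets in gene-sense coordinates.

    Sense guides: protospacer 5' base and first PAM base (= protospacer
    offset + 20).  Antisense guides: the 5'-most protospacer base and
    5'-most PAM base in gene-sense coordinates (PAM offset = protospacer
    offset - 3, the PAM lying between the cut and the ATG side).
    """
    if classify_strand(site, gene) == "sense":
        if site.strand == "+":
            proto = _gene_sense_coord(site.start, gene)
        else:
            proto = _gene_sense_coord(site.start + 22, gene)
        return proto, proto + 20
    # antisense: anchor to the protospacer base nearest the gene 5' end
    if site.strand == "-":  # gene '+'
        proto = _gene_sense_coord(site.start + 3, gene)
    else:  # gene '-', guide '+'
        proto = _gene_sense_coord(site.start + 19, gene)
    return proto, proto - 3


def guide_context_30(site: GuideSite, genome: StrainGenome) -> str:
    """30-nt scoring context: 4 nt upstream + 23-nt target + 3 nt downstream
    in guide orientation, N-padded at contig edges."""
    seq = genome.contigs[site.contig_id]
    if site.strand == "+":
        lo, hi = site.start - 4, site.start + 26
        padded = ("N" * max(0, -lo)) + seq[max(0, lo) : hi] + ("N" * max(0, hi - len(seq)))
        return padded
    lo, hi = site.start - 3, site.start + 27
    window = ("N" * max(0, -lo)) + seq[max(0, lo) : hi] + ("N" * max(0, hi - len(seq)))
    return revcomp(window)


def default_scorer(context_30: str) -> float:
    """Deterministic composite on-target score in [0, 1].

    Penalises protospacer GC fraction outside [0.4, 0.7] and any
    homopolymer run of four or more bases.  A pluggable hook with the
    same 30-nt-context signature can replace it (e.g. a trained
    on-target efficacy model).
    """
    proto = context_30[4:24]
    gc = sum(1 for c in proto if c in "GC") / 20.0
    score = 1.0
    if gc < 0.4:
        score -= min(0.5, 2.0 * (0.4 - gc))
    elif gc > 0.7:
        score -= min(0.5, 2.0 * (gc - 0.7))
    run, longest, prev = 0, 0, ""
    for c in proto:
        run = run + 1 if c == prev else 1
        prev = c
        longest = max(longest, run)
    if longest >= 4:
        score -= 0.25
    return round(score, 6)


def annotate_locus_guide(
    site: GuideSite,
    gene: GeneModel,
    genome: StrainGenome,
    scorer: Scorer | None = None,
) -> LocusGuide:
    """Attach offsets, strand class, cut site and score to one guide."""
    proto_off, pam_off = guide_offsets(site, gene)
    ctx = guide_context_30(site, genome)
    return LocusGuide(
        site=site,
        gene_id=gene.gene_id,
        offset_protospacer_start=proto_off,
        offset_pam_start=pam_off,
        guide_strand_vs_gene=classify_strand(site, gene),
        cut_position=cut_site(site),
        context_30=ctx,
        rank_score=(scorer or default_scorer)(ctx),
    )


def rank_guides(guides: Sequence[LocusGuide], scorer: Scorer | None = None) -> list[LocusGuide]:
    """Score and order guides: score descending, then offset ascending."""
    use = scorer or default_scorer
    rescored = []
    for g in guides:
        g2 = LocusGuide(**{**g.__dict__, "rank_score": use(g.context_30)})
        rescored.append(g2)
    rescored.sort(key=lambda g: (-g.rank_score, g.offset_protospacer_start))
    return rescored


def _target_in_span(target_23: str, genome: StrainGenome, gene: GeneModel) -> bool:
    start, end = gene.span
    region = genome.contigs[gene.contig_id][start:end]
    return target_23 in region or revcomp(target_23) in region


def select_guides_for_locus(
    target_gene_ids: set[str] | Sequence[str],
    genome: StrainGenome,
    index: SiteIndex,
    params: DesignParams | None = None,
    scorer: Scorer | None = None,
) -> list[LocusGuide]:
    """Guides that cut all and only the allowed loci.

    A guide is retained iff (i) every perfect match of its target lies
    within one of the allowed gene loci, (ii) it hits every allowed
    locus that contains the target (paralog-complete — identical copies
    are all cut), and (iii) it has no 1-5-mismatch site outside the
    allowed loci.  Retained guides are annotated and ordered by rank
    score, ties broken by offset.
    """
    params = params or DesignParams()
    target_gene_ids = set(target_gene_ids)
    if not target_gene_ids:
        raise ValueError("no target gene ids supplied")
    loci = {gid: genome.gene(gid) for gid in target_gene_ids}  # raises on missing gene

    def in_allowed(contig_id: str, start: int, end: int) -> bool:
        for g in loci.values():
            s, e = g.span
            if g.contig_id == contig_id and start < e and s < end:
                return True
        return False

    candidates = [
        g for g in guides_in_genes(genome, params) if g.gene_id in target_gene_ids
    ]
    selected: list[LocusGuide] = []
    seen_targets: set[str] = set()
    for cand in candidates:
        if cand.target_23 in seen_targets:
            continue
        hits = find_near_matches(cand, index, params.offtarget_max_mismatches)
        perfect = [h for h in hits if h.mismatches == 0]
        near = [h for h in hits if h.mismatches > 0]
        if any(not in_allowed(h.contig_id, h.start, h.start + 23) for h in perfect):
            continue
        n_expected = sum(
            1 for g in loci.values() if _target_in_span(cand.target_23, genome, g)
        )
        if len(perfect) != n_expected:
            continue
        if any(not in_allowed(h.contig_id, h.start, h.start + 23) for h in near):
            continue
        seen_targets.add(cand.target_23)
        selected.append(
            annotate_locus_guide(cand, loci[cand.gene_id], genome, scorer=scorer)
        )
    selected.sort(key=lambda g: (-g.rank_score, g.offset_protospacer_start))
    return selected


def predict_deletion(
    a: LocusGuide, b: LocusGuide, genome: StrainGenome | None = None, flank: int = 20
) -> DeletionPrediction:
    """Deletion between the blunt cut sites of two guides.

    Symmetric in its arguments; both guides must lie on the same contig.
    When the genome is supplied, the predicted junction (flanking
    sequence spliced across the deleted interval) is exported for primer
    design.
    """
    if a.site.contig_id != b.site.contig_id:
        raise ValueError("guides lie on different contigs; no simple deletion is predicted")
    lo, hi = sorted((a.cut_position, b.cut_position))
    junction = ""
    if genome is not None:
        seq = genome.contigs[a.site.contig_id]
        junction = seq[max(0, lo - flank) : lo] + "|" + seq[hi : hi + flank]
    return DeletionPrediction(
        guide_a=a,
        guide_b=b,
        predicted_interval=(lo, hi),
        predicted_length=hi - lo,
        junction=junction,
    )
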