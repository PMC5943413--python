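"""The published Matalpha3 knockout guide set and a synthetic test locus.

In *Kluyveromyces marxianus* the alpha3 gene at the MATalpha locus
encodes a transposase that drives mating-type switching; knocking it
out stabilises haploids.  Six guide RNAs were used for that knockout,
listed here with their published offsets downstream of the ATG start
codon.  Offsets follow the mixed convention of the original report:
PAM start for sense guides, protospacer start (the base nearest the
ATG) for antisense guides; both are 1-based with the A of ATG at
position 1.

``synthetic_matalpha3_locus`` builds a SYNTHETIC gene that embeds the
six real target sequences at their published offsets inside random
filler — it reproduces the guides' geometry (offsets, strands, cut
spacing) but is NOT the real Matalpha3 gene sequence, which is not
bundled with the package.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import GeneModel, StrainGenome, revcomp


@dataclass(frozen=True)
class PublishedGuide:
    guide_id: str
    offset_downstream_atg: int  # PAM start (sense) / protospacer start (antisense)
    sequence_23: str
    strand_class: str  # "sense" | "antisense"


MATALPHA3_GUIDES: tuple[PublishedGuide, ...] = (
    PublishedGuide("gRNA1", 291, "CAGCATTGTATTTGCTAAATGGG", "antisense"),
    PublishedGuide("gRNA2", 513, "ACTGGATACATCTTTGTGAGAGG", "sense"),
    PublishedGuide("gRNA3", 328, "GATATTTTTTCATTAAGAAAGGG", "antisense"),
    PublishedGuide("gRNA4", 177, "AAGAATTGGCTTTTGAAAAACGG", "sense"),
    PublishedGuide("gRNA5", 64, "GATCCTTTGAATTTGAAGAGAGG", "sense"),
    PublishedGuide("gRNA6", 42, "AAATGGATAATCCATCCAAAAGG", "sense"),
)

_GENE_LEN = 540  # nt, multiple of 3, long enough for the deepest guide (offset 513)
_FLANK = 100


def _gene0_window(g: PublishedGuide) -> tuple[int, str]:
    """(0-based gene-sense start of the 23-nt window, gene-sense window sequence)."""
    if g.strand_class == "sense":
        # offset is the 1-based PAM start; protospacer begins 20 nt earlier
        start = g.offset_downstream_atg - 21
        return start, g.sequence_23
    # antisense: offset is the protospacer base nearest the ATG; on the
    # gene-sense strand the window reads PAM-revcomp first
    start = g.offset_downstream_atg - 4
    return start, revcomp(g.sequence_23)


def synthetic_matalpha3_locus(
    strand: str = "+", seed: int = 7, strain_id: str = "synthetic"
) -> tuple[StrainGenome, GeneModel]:
    """A synthetic single-gene genome carrying the six real guide targets.

    The gene body is deterministic random filler with the six 23-nt
    windows written at their published offsets (one pair of adjacent
    windows shares a base; the real sequences are compatible there).
    ``strand`` places the gene on the forward or reverse strand of the
    contig to exercise strand-aware coordinate logic.
    """
    rng = np.random.default_rng(seed)
    body = list("".join(rng.choice(list("ACGT"), size=_GENE_LEN)))
    body[0:3] = "ATG"
    for g in MATALPHA3_GUIDES:
        start, window = _gene0_window(g)
        if start < 0 or start + 23 > _GENE_LEN:
            raise AssertionError(f"{g.guide_id}: window outside the synthetic gene")
        for i, base in enumerate(window):
            body[start + i] = base
    gene_seq = "".join(body)
    for g in MATALPHA3_GUIDES:  # overlapping windows must have written consistently
        start, window = _gene0_window(g)
        assert gene_seq[start : start + 23] == window, f"{g.guide_id}: planting conflict"

    flank_l = "".join(rng.choice(list("ACGT"), size=_FLANK))
    flank_r = "".join(rng.choice(list("ACGT"), size=_FLANK))
    if strand == "+":
        contig = flank_l + gene_seq + flank_r
    else:
        contig = flank_l + revcomp(gene_seq) + flank_r
    gene = GeneModel(
        gene_id="MATALPHA3",
        contig_id="chr_syn",
        strand=strand,
        cds_intervals=((_FLANK, _FLANK + _GENE_LEN),),
    )
    genome = StrainGenome(strain_id=strain_id, contigs={"chr_syn": contig}, genes=[gene])
    genome.validate()
    return genome, gene
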