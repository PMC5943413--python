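"""Core domain types shared across the guide-design pipeline.

Coordinate convention: every interval stored in memory is 0-based,
half-open ``[start, end)`` on the forward strand of its contig.  File
formats that use other conventions (GFF3: 1-based closed) are converted
at the I/O boundary and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene on one contig.

    ``gene_id`` is the reference identifier and is shared across strains
    once annotations have been transferred.  ``cds_intervals`` are sorted,
    non-overlapping 0-based half-open intervals; for transferred models
    there is a single interval covering the aligned region.
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    source: str = "native_annotation"  # or "transferred"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_intervals:
            raise ValueError(f"gene {self.gene_id}: no CDS intervals")
        prev_end = -1
        for start, end in self.cds_intervals:
            if start < 0 or end <= start:
                raise ValueError(f"gene {self.gene_id}: bad interval ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"gene {self.gene_id}: intervals overlap or are unsorted")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint: first CDS start to last CDS end."""
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


@dataclass
class StrainGenome:
    """A named strain assembly: contig sequences plus gene models."""

    strain_id: str
    contigs: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def validate(self) -> None:
        """Check alphabet, non-emptiness and gene/contig consistency."""
        if not self.contigs:
            raise ValueError(f"{self.strain_id}: no contigs")
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"{self.strain_id}/{cid}: empty sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"{self.strain_id}/{cid}: non-IUPAC-DNA character "
                    f"{seq[pos]!r} at position {pos + 1}"
                )
        for gene in self.genes:
            if gene.contig_id not in self.contigs:
                raise ValueError(f"gene {gene.gene_id}: unknown contig {gene.contig_id}")
            start, end = gene.span
            if end > len(self.contigs[gene.contig_id]):
                raise ValueError(f"gene {gene.gene_id}: interval exceeds contig bounds")

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"{self.strain_id}: no gene {gene_id!r}")

    @property
    def is_annotated(self) -> bool:
        return bool(self.genes)


@dataclass
class DesignParams:
    """All design thresholds in one place.

    ``offtarget_max_mismatches = 5`` encodes the off-target definition of
    "fewer than six mismatches" over the 20-nt protospacer; a genomic NGG
    site within that distance disqualifies a guide.  A guide is conserved
    when its full 23-nt target (protospacer + PAM) occurs identically in
    at least ``min_conservation_genomes`` strain genomes.
    """

    pam_motif: str = "NGG"
    guide_length: int = 20
    offtarget_max_mismatches: int = 5
    min_conservation_genomes: int = 2
    evalue_threshold: float = 1e-10
    allow_overlapping_genes: bool = False
    pam_required_at_offtarget: bool = True
    allow_nag_offtargets: bool = False

    def __post_init__(self) -> None:
        if self.guide_length != 20:
            raise ValueError("only 20-nt protospacers are supported")
        if self.pam_motif != "NGG":
            raise ValueError("only the SpCas9 NGG PAM is supported")
        if self.min_conservation_genomes < 2:
            raise ValueError("min_conservation_genomes must be >= 2")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class GuideSite:
    """One 23-nt Cas9 target occurrence.

    ``target_23`` is protospacer + PAM in guide-strand orientation; for
    ``strand == '-'`` it equals the reverse complement of the forward
    strand window ``[start, start + 23)``.
    """

    target_23: str
    protospacer: str
    pam: str
    genome_id: str
    contig_id: str
    start: int
    strand: str
    gene_id: Optional[str] = None
    in_gene_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20 or len(self.pam) != 3:
            raise ValueError("protospacer must be 20 nt and PAM 3 nt")
        if self.target_23 != self.protospacer + self.pam:
            raise ValueError("target_23 must equal protospacer + pam")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + 23
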