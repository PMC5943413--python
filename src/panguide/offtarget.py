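"""Genome-wide near-match search for guide specificity assessment.

An off-target is an NGG-adjacent genomic site whose 20-nt protospacer
differs from the guide by fewer than six mismatches (PAM bases are never
counted).  A guide is *specific* when its target occurs at exactly one
perfect site (single copy) and has no 1-5-mismatch neighbours anywhere
in the genome.

The index enumerates every PAM-adjacent window once, packs the
protospacers into a byte matrix and answers queries by a full vectorised
Hamming scan over that matrix.  This is complete by construction —
nothing is pruned, so no seed-and-verify bookkeeping can lose hits —
and fast enough because the candidate set is the (sparse) set of
PAM-adjacent windows, not every genomic position.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .guide_discovery import _scan_sites
from .models import DesignParams, GuideSite, StrainGenome

_LUT = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _onehot(mat: np.ndarray) -> np.ndarray:
    """(n, w) ASCII byte matrix -> (n, 4*w) float32 one-hot."""
    n, w = mat.shape
    idx = _LUT[mat]
    out = np.zeros((n, w, 4), dtype=np.float32)
    np.put_along_axis(out, idx[:, :, None], 1.0, axis=2)
    return out.reshape(n, 4 * w)


@dataclass(frozen=True)
class OffTargetHit:
    """One near-match site for a queried guide."""

    genome_id: str
    contig_id: str
    start: int  # 0-based start of the 23-nt span on the forward strand
    strand: str
    mismatches: int  # over the 20-nt protospacer only
    pam_at_site: str


@dataclass
class SpecificityVerdict:
    """Perfect and near sites for one guide, plus the single-copy call."""

    target_23: str
    perfect_sites: list[OffTargetHit]
    near_sites: list[OffTargetHit]

    @property
    def is_specific(self) -> bool:
        return len(self.perfect_sites) == 1 and not self.near_sites


class SiteIndex:
    """Index of every PAM-adjacent 23-nt window in one genome.

    ``include_nag=True`` additionally indexes non-canonical NAG sites;
    they are reported only when a query asks for them.
    """

    def __init__(self, genome: StrainGenome, include_nag: bool = False):
        self.genome_id = genome.strain_id
        self.genome = genome
        suffixes = ("GG", "AG") if include_nag else ("GG",)
        sites: list[GuideSite] = []
        for contig_id, seq in genome.contigs.items():
            sites.extend(
                _scan_sites(seq, genome_id=genome.strain_id, contig_id=contig_id,
                            pam_suffixes=suffixes)
            )
        self.sites = sites
        n = len(sites)
        if n:
            buf = "".join(s.target_23 for s in sites)
            self.targets = _encode(buf).reshape(n, 23)
        else:
            self.targets = np.zeros((0, 23), dtype=np.uint8)
        self.protospacers = self.targets[:, :20]
        self._is_ngg = np.array([s.pam[1:] == "GG" for s in sites], dtype=bool)
        self._exact: dict[str, list[int]] | None = None
        self._oh: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sites)

    # -- exact 23-mer lookup (conservation uses this) ------------------
    def exact_lookup(self, target_23: str) -> list[int]:
        """Row indices of sites whose full 23-mer equals ``target_23``."""
        if self._exact is None:
            table: dict[str, list[int]] = {}
            for i, s in enumerate(self.sites):
                table.setdefault(s.target_23, []).append(i)
            self._exact = table
        return self._exact.get(target_23, [])

    # -- Hamming queries ----------------------------------------------
    def query(
        self, protospacer: str, max_mismatches: int, include_nag: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Row indices and mismatch counts of sites within the distance bound."""
        if len(self.sites) == 0:
            return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        q = _encode(protospacer)
        mm = (self.protospacers != q[None, :]).sum(axis=1)
        keep = mm <= max_mismatches
        if not include_nag:
            keep &= self._is_ngg
        idx = np.nonzero(keep)[0]
        return idx, mm[idx]

    def onehot(self) -> np.ndarray:
        if self._oh is None:
            self._oh = _onehot(self.protospacers)
        return self._oh

    def count_matches_batch(
        self,
        protospacers: Sequence[str],
        max_mismatches: int = 5,
        include_nag: bool = False,
        block: int = 1024,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Perfect-site and near-site counts for many queries at once.

        Returns ``(perfect_counts, near_counts)`` where near counts cover
        mismatch distances 1..max_mismatches.  Uses a one-hot matrix
        product per block: matches = q_onehot @ site_onehot^T.
        """
        m = len(protospacers)
        perfect = np.zeros(m, dtype=np.int64)
        near = np.zeros(m, dtype=np.int64)
        if m == 0 or len(self.sites) == 0:
            return perfect, near
        site_oh = self.onehot()
        valid = (self._is_ngg | include_nag).astype(np.float32)
        buf = "".join(protospacers)
        qmat = _encode(buf).reshape(m, 20)
        for lo in range(0, m, block):
            hi = min(lo + block, m)
            q_oh = _onehot(qmat[lo:hi])
            matches = q_oh @ site_oh.T  # (b, n_sites)
            mm = 20.0 - matches
            ok = mm <= max_mismatches + 0.5
            is_perfect = mm < 0.5
            perfect[lo:hi] = ((is_perfect & (valid > 0))).sum(axis=1)
            near[lo:hi] = ((ok & ~is_perfect) * valid).sum(axis=1).astype(np.int64)
        return perfect, near


def build_site_index(genome: StrainGenome, include_nag: bool = False) -> SiteIndex:
    """Build the near-match index over one genome."""
    return SiteIndex(genome, include_nag=include_nag)


def find_near_matches(
    guide: Union[GuideSite, str],
    index: SiteIndex,
    max_mismatches: int = 5,
    include_nag: bool = False,
) -> list[OffTargetHit]:
    """All sites within ``max_mismatches`` of the guide's protospacer.

    Complete over both strands; PAM positions are never counted as
    mismatches; windows containing N were excluded at enumeration.
    """
    if max_mismatches > 5:
        warnings.warn(
            "max_mismatches > 5 exceeds the off-target definition "
            "(fewer than six mismatches); proceeding anyway",
            stacklevel=2,
        )
    protospacer = guide.protospacer if isinstance(guide, GuideSite) else guide
    if len(protospacer) != 20:
        raise ValueError("query protospacer must be 20 nt")
    idx, mm = index.query(protospacer, max_mismatches, include_nag=include_nag)
    hits = [
        OffTargetHit(
            genome_id=index.genome_id,
            contig_id=index.sites[i].contig_id,
            start=index.sites[i].start,
            strand=index.sites[i].strand,
            mismatches=int(d),
            pam_at_site=index.sites[i].pam,
        )
        for i, d in zip(idx, mm)
    ]
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return hits


def assess_specificity(
    guide: GuideSite,
    index: SiteIndex,
    max_mismatches: int = 5,
) -> SpecificityVerdict:
    """Classify a guide's genome-wide matches and call single-copy status.

    The guide's own locus counts among the perfect sites, so a
    single-copy target has exactly one perfect site.  Raises if the
    guide was discovered in this genome but its own locus is missing
    from the hit list (internal inconsistency).
    """
    hits = find_near_matches(guide, index, max_mismatches)
    perfect = [h for h in hits if h.mismatches == 0]
    near = [h for h in hits if h.mismatches > 0]
    if guide.genome_id == index.genome_id:
        own = any(
            h.contig_id == guide.contig_id
            and h.start == guide.start
            and h.strand == guide.strand
            for h in perfect
        )
        if not own:
            raise RuntimeError(
                f"internal consistency error: own locus of guide {guide.target_23} "
                f"at {guide.contig_id}:{guide.start}:{guide.strand} not among perfect sites"
            )
    return SpecificityVerdict(
        target_23=guide.target_23, perfect_sites=perfect, near_sites=near
    )
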