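"""Shared fixtures: small deterministic genomes and an independent
brute-force near-match oracle (sliding-window Hamming scan over the raw
sequence, built without the package's site index)."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from panguide.models import GeneModel, StrainGenome, revcomp

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("fixed")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def brute_force_near_matches(genome: StrainGenome, protospacer: str, max_mm: int):
    """Position-by-position Hamming scan over every PAM-adjacent window.

    Returns {(contig, start, strand, mismatches)}.  Independent of the
    package's SiteIndex: it walks the raw sequence directly.
    """
    hits = set()
    for contig_id, seq in genome.contigs.items():
        for start in range(len(seq) - 22):
            w = seq[start : start + 23]
            if "N" in w:
                continue
            if w[21:23] == "GG":
                mm = sum(a != b for a, b in zip(w[:20], protospacer))
                if mm <= max_mm:
                    hits.add((contig_id, start, "+", mm))
            if w[0:2] == "CC":
                t = revcomp(w)
                mm = sum(a != b for a, b in zip(t[:20], protospacer))
                if mm <= max_mm:
                    hits.add((contig_id, start, "-", mm))
    return hits


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome(rng) -> StrainGenome:
    """A 5-kb single-contig genome with one gene spanning most of it."""
    seq = random_dna(rng, 5000)
    gene = GeneModel(
        gene_id="gA", contig_id="c1", strand="+", cds_intervals=((100, 4600),)
    )
    g = StrainGenome(strain_id="small", contigs={"c1": seq}, genes=[gene])
    g.validate()
    return g
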