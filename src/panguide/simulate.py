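"""Deterministic multi-strain genome simulator with planted ground truth.

Emulates the input of a pan-genome guide-design study — several strain
assemblies of one yeast species — at desk scale: a random ancestor
genome with ORF-like single-exon genes, per-strain point divergence,
and a set of planted features whose fate through the pipeline is known
exactly:

* a segmental duplication private to the first strain (defeats the
  single-copy requirement),
* an overlapping gene pair (triggers overlap exclusion),
* an identical gene pair present in all strains (the
  Matalpha3/HMLalpha3 analogue for paralog-aware selection),
* engineered guide targets conserved in exactly j strains for
  j = 1..n_strains.

Planted 23-mers are verified to occur the expected number of times in
the ancestor and to sit at protospacer Hamming distance >= 8 from every
other PAM-adjacent site, so random divergence cannot plausibly create
confounding near-matches; offending candidates are re-rolled during
construction.  Divergence is substitution-only, which keeps planted
coordinates valid in every strain.
"""
from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np

from .guide_discovery import _scan_sites
from .models import DesignParams, GeneModel, GuideSite, StrainGenome, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_LUT = np.zeros(256, dtype=np.int64)
for _bi, _bb in enumerate(_BASES):
    _BASE_LUT[_bb] = _bi
_STOPS = {"TAA", "TAG", "TGA"}
_MIN_PLANT_DISTANCE = 8
_CONTIG = "chr1"


@dataclass(frozen=True)
class PlantedGuide:
    """One engineered guide target and its expected pipeline fate."""

    target_23: str
    contig_id: str
    start: int  # ancestor forward-strand coordinates (shared by all strains)
    gene_id: str
    expected_conservation_level: int
    expected_specific: bool  # specific in every genome where the target occurs
    reason: str  # tier | paralog_pair | duplicated_segment | overlap_excluded


@dataclass
class StrainSetTruth:
    """A simulated strain set plus the truth table of planted features."""

    ancestor: StrainGenome
    strains: list[StrainGenome]
    planted_guides: list[PlantedGuide]
    paralog_pair: tuple[str, str]
    duplicated_segment: tuple[str, int, int]
    overlapping_pair: tuple[str, str]
    seed: int


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """ATG + random non-stop codons + TAA, total ``length`` nt."""
    n_codons = length // 3 - 2
    codons = []
    while len(codons) < n_codons:
        c = "".join(chr(b) for b in rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def _random_protospacer(rng: np.random.Generator) -> str:
    return "".join(chr(b) for b in rng.choice(_BASES, size=20))


def _count_occurrences(seq: str, target: str) -> int:
    def count(hay: str, needle: str) -> int:
        n, i = 0, hay.find(needle)
        while i != -1:
            n += 1
            i = hay.find(needle, i + 1)
        return n

    return count(seq, target) + count(seq, revcomp(target))


def simulate_strain_set(
    n_strains: int = 3,
    n_genes: int = 24,
    genome_length: int = 30_000,
    divergence: float = 0.02,
    seed: int = 0,
) -> StrainSetTruth:
    """Simulate ``n_strains`` genomes descending from one ancestor.

    ``divergence`` is the per-site substitution probability applied
    independently to each strain (0 to 0.2).  Identical seeds reproduce
    byte-identical genomes and truth tables.
    """
    if n_strains < 1:
        raise ValueError("need at least one strain")
    if not 0.0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    if n_genes < 3 + n_strains:
        raise ValueError(f"need at least {3 + n_strains} genes for the planted features")
    rng = np.random.default_rng(seed)

    seq = rng.choice(_BASES, size=genome_length).copy()

    # ---- gene placement -------------------------------------------------
    genes: list[GeneModel] = []
    pos = 200
    for i in range(n_genes):
        length = int(rng.integers(100, 200)) * 3  # 300..597 nt
        gap = int(rng.integers(150, 250))
        if pos + length > genome_length - 1200:
            raise ValueError(
                "genome too short to plant the requested genes; "
                "increase genome_length or reduce n_genes"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        orf = _random_orf(rng, length)
        if strand == "-":
            orf = revcomp(orf)
        seq[pos : pos + length] = np.frombuffer(orf.encode(), dtype=np.uint8)
        genes.append(
            GeneModel(
                gene_id=f"g{i:03d}",
                contig_id=_CONTIG,
                strand=strand,
                cds_intervals=((pos, pos + length),),
            )
        )
        pos += length + gap

    paralog_src = genes[0]
    dup_gene = genes[1]
    tier_hosts = [genes[3 + j] for j in range(n_strains)]
    last = genes[-1]

    # ---- overlapping gene pair -----------------------------------------
    ls, le = last.span
    ovl_gene = GeneModel(
        gene_id="g_overlap",
        contig_id=_CONTIG,
        strand="-" if last.strand == "+" else "+",
        cds_intervals=((le - 30, le + 90),),
    )
    genes.append(ovl_gene)

    # ---- planted guide targets ------------------------------------------
    # (position, host gene, reason, expected level, expected specificity)
    plant_plan: list[tuple[int, GeneModel, str, int, bool]] = []
    for j, host in enumerate(tier_hosts, start=1):
        plant_plan.append((host.span[0] + 60, host, "tier", j, True))
    plant_plan.append(
        (paralog_src.span[0] + 60, paralog_src, "paralog_pair", n_strains, False)
    )
    plant_plan.append(
        (dup_gene.span[0] + 60, dup_gene, "duplicated_segment", n_strains, False)
    )
    plant_plan.append((le - 26, last, "overlap_excluded", n_strains, True))

    protos = [_random_protospacer(rng) for _ in plant_plan]

    # ---- identical paralog copy placed after the overlap gene -----------
    ps, pe = paralog_src.span
    par_len = pe - ps
    par_start = le + 200
    if par_start + par_len > genome_length - 50:
        raise ValueError("genome too short for the identical paralog copy")
    par_gene = GeneModel(
        gene_id=f"{paralog_src.gene_id}_hml",
        contig_id=_CONTIG,
        strand=paralog_src.strand,
        cds_intervals=((par_start, par_start + par_len),),
    )
    genes.append(par_gene)

    def build_ancestor_seq() -> np.ndarray:
        s = seq.copy()
        for (p, _g, _r, _lvl, _spec), proto in zip(plant_plan, protos):
            window = proto + "TGG"
            s[p : p + 23] = np.frombuffer(window.encode(), dtype=np.uint8)
        # paralog copy AFTER planting so the engineered guide is duplicated too
        s[par_start : par_start + par_len] = s[ps:pe]
        return s

    # verify planted targets and re-roll confusable ones
    for _attempt in range(50):
        anc = build_ancestor_seq()
        anc_str = anc.tobytes().decode()
        sites = _scan_sites(anc_str, contig_id=_CONTIG)
        if sites:
            proto_mat = np.frombuffer(
                "".join(s.protospacer for s in sites).encode(), dtype=np.uint8
            ).reshape(len(sites), 20)
        offenders = []
        for k, ((p, _g, reason, _lvl, _spec), proto) in enumerate(zip(plant_plan, protos)):
            target = proto + "TGG"
            expected_n = 2 if reason == "paralog_pair" else 1
            if _count_occurrences(anc_str, target) != expected_n:
                offenders.append(k)
                continue
            q = np.frombuffer(proto.encode(), dtype=np.uint8)
            mm = (proto_mat != q[None, :]).sum(axis=1)
            mm = mm[mm > 0]
            if mm.size and mm.min() < _MIN_PLANT_DISTANCE:
                offenders.append(k)
        if not offenders:
            break
        for k in offenders:
            protos[k] = _random_protospacer(rng)
    else:
        raise RuntimeError("could not plant distinguishable guide targets; try another seed")

    ancestor = StrainGenome(
        strain_id="ancestor", contigs={_CONTIG: anc_str}, genes=list(genes)
    )
    ancestor.validate()

    # ---- divergence shield: planted windows and both paralog copies -----
    shield = np.zeros(genome_length, dtype=bool)
    for (p, _g, _r, _lvl, _spec), _proto in zip(plant_plan, protos):
        shield[p : p + 23] = True
    shield[ps:pe] = True
    shield[par_start : par_start + par_len] = True

    # ---- per-strain genomes ---------------------------------------------
    strains: list[StrainGenome] = []
    for i in range(n_strains):
        s = anc.copy()
        if divergence > 0:
            mut = (rng.random(genome_length) < divergence) & ~shield
            idx = np.nonzero(mut)[0]
            if idx.size:
                shifts = rng.integers(1, 4, size=idx.size)
                s[idx] = _BASES[(_BASE_LUT[s[idx]] + shifts) % 4]
        # tier edits: destroy the PAM of tier-j targets in strains j..n-1
        for (p, _g, reason, lvl, _spec), _proto in zip(plant_plan, protos):
            if reason == "tier" and i >= lvl:
                s[p + 21] = ord("A")
                s[p + 22] = ord("T")
        contigs = {_CONTIG: s.tobytes().decode()}
        if i == 0:  # private segmental duplication around the dup gene
            ds, de = dup_gene.span
            lo, hi = max(0, ds - 20), min(genome_length, de + 20)
            contigs[f"{_CONTIG}_dup"] = contigs[_CONTIG][lo:hi]
        strains.append(
            StrainGenome(
                strain_id=f"strain_{i + 1:02d}", contigs=contigs, genes=list(genes)
            )
        )
        strains[-1].validate()

    planted = [
        PlantedGuide(
            target_23=proto + "TGG",
            contig_id=_CONTIG,
            start=p,
            gene_id=g.gene_id,
            expected_conservation_level=lvl,
            expected_specific=spec,
            reason=reason,
        )
        for (p, g, reason, lvl, spec), proto in zip(plant_plan, protos)
    ]
    ds, de = dup_gene.span
    return StrainSetTruth(
        ancestor=ancestor,
        strains=strains,
        planted_guides=planted,
        paralog_pair=(paralog_src.gene_id, par_gene.gene_id),
        duplicated_segment=(_CONTIG, max(0, ds - 20), min(genome_length, de + 20)),
        overlapping_pair=(last.gene_id, ovl_gene.gene_id),
        seed=seed,
    )


def mutate_guide_site(genome: StrainGenome, site: GuideSite, kind: str) -> StrainGenome:
    """Targeted perturbation of one guide site (returns a modified copy).

    ``protospacer_snp`` substitutes one mid-protospacer base (the site
    becomes a 1-mismatch neighbour of the original guide);
    ``pam_break`` destroys the NGG motif (the window is no longer a
    site at all); ``duplicate`` appends a contig carrying a second
    perfect copy (defeats the single-copy requirement).
    """
    contigs = dict(genome.contigs)
    seq = list(contigs[site.contig_id])
    flip = str.maketrans("ACGT", "CATG")
    if kind == "protospacer_snp":
        pos = site.start + 10 if site.strand == "+" else site.start + 12
        seq[pos] = seq[pos].translate(flip)
        contigs[site.contig_id] = "".join(seq)
    elif kind == "pam_break":
        pos = site.start + 21 if site.strand == "+" else site.start + 1
        seq[pos] = "A" if seq[pos] != "A" else "T"
        contigs[site.contig_id] = "".join(seq)
    elif kind == "duplicate":
        src = contigs[site.contig_id]
        lo, hi = max(0, site.start - 10), min(len(src), site.start + 33)
        n = sum(1 for c in contigs if c.startswith(f"{site.contig_id}_dup"))
        contigs[f"{site.contig_id}_dup{n + 1}"] = src[lo:hi]
    else:
        raise ValueError(f"unknown mutation kind {kind!r}")
    out = StrainGenome(strain_id=genome.strain_id, contigs=contigs, genes=list(genome.genes))
    out.validate()
    return out


def evaluate_planted_fates(
    truth: StrainSetTruth,
    per_genome_specific: Mapping[str, Sequence[GuideSite]],
    conserved_targets: Mapping[str, int],
    params: DesignParams | None = None,
) -> dict[str, bool]:
    """Did the pipeline assign each planted guide its declared fate?

    ``per_genome_specific`` maps genome id to the guides that passed
    in-gene discovery and home-genome specificity;
    ``conserved_targets`` maps conserved 23-mers (strict mode) to their
    conservation level.  Returns target -> fate-recovered flag.
    """
    params = params or DesignParams()
    home = truth.strains[0].strain_id
    specific_targets = {
        gid: {g.target_23 for g in guides} for gid, guides in per_genome_specific.items()
    }
    results: dict[str, bool] = {}
    for pg in truth.planted_guides:
        t = pg.target_23
        in_conserved = t in conserved_targets
        if pg.reason == "tier":
            should_conserve = pg.expected_conservation_level >= params.min_conservation_genomes
            ok = t in specific_targets.get(home, set())
            if should_conserve:
                ok = ok and in_conserved and conserved_targets[t] == pg.expected_conservation_level
            else:
                ok = ok and not in_conserved
        elif pg.reason == "paralog_pair":
            ok = not in_conserved and all(t not in s for s in specific_targets.values())
        elif pg.reason == "duplicated_segment":
            ok = not in_conserved and t not in specific_targets.get(home, set())
        elif pg.reason == "overlap_excluded":
            ok = not in_conserved and all(t not in s for s in specific_targets.values())
        else:  # pragma: no cover - generator only emits the four reasons
            ok = False
        results[t] = ok
    return results
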