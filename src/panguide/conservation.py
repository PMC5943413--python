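"""Cross-genome comparison of guide targets and the design summary.

A guide is keyed by its full 23-nt target (protospacer + PAM).
Identity is read strictly: a substitution anywhere in the 23-mer —
including one that breaks the PAM — de-conserves the guide, because a
changed PAM abolishes targeting.  The conservation level of a guide is
the number of strain genomes containing at least one perfect occurrence
of the 23-mer (home genome included).

Strict mode (default) additionally demands that the guide be specific
(single perfect copy, no 1-5-mismatch neighbours) in *every* genome
where it occurs; lenient mode only requires specificity in the genome
where the guide was discovered.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .guide_discovery import gene_interval_trees
from .models import DesignParams, GuideSite, StrainGenome
from .offtarget import SiteIndex

logger = logging.getLogger(__name__)


@dataclass
class ConservedGuide:
    """A guide target with its per-genome occurrence map."""

    target_23: str
    occurrences: dict[str, list[GuideSite]]
    gene_ids: dict[str, Optional[str]]
    passes_strict: bool

    @property
    def conservation_level(self) -> int:
        return len(self.occurrences)


@dataclass
class DesignReport:
    """Per-tier summary of the conserved guide set."""

    n_genomes: int
    reference_id: str
    n_reference_genes: int
    tiers: dict[int, dict]  # k -> {n_guides, n_genes, pct_genes}
    totals_per_genome: dict[str, int]
    params: dict
    input_checksums: dict[str, str]

    def to_json(self) -> str:
        payload = dict(
            n_genomes=self.n_genomes,
            reference_id=self.reference_id,
            n_reference_genes=self.n_reference_genes,
            tiers={str(k): v for k, v in self.tiers.items()},
            totals_per_genome=self.totals_per_genome,
            params=self.params,
            input_checksums=self.input_checksums,
        )
        return json.dumps(payload, indent=2, sort_keys=True)


def genome_checksum(genome: StrainGenome) -> str:
    """MD5 over the sorted contig sequences (assembly identity record)."""
    h = hashlib.md5()
    for cid in sorted(genome.contigs):
        h.update(cid.encode())
        h.update(genome.contigs[cid].encode())
    return h.hexdigest()


def _gene_at(trees, contig_id: str, start: int, end: int) -> Optional[str]:
    tree = trees.get(contig_id)
    if tree is None:
        return None
    hits = sorted(tree[start:end], key=lambda h: h.data)
    return hits[0].data if hits else None


def cross_compare(
    per_genome_guides: Mapping[str, Sequence[GuideSite]],
    indexes: Mapping[str, SiteIndex],
    params: DesignParams | None = None,
    strict: bool = True,
) -> list[ConservedGuide]:
    """Group specific guides by target and score their conservation.

    ``per_genome_guides`` holds, per genome, the guides that already
    passed specificity in their home genome; ``indexes`` must cover
    every genome being compared.  Guides whose conservation level falls
    below ``params.min_conservation_genomes`` are dropped, as are (in
    strict mode) guides that are non-specific in any genome where their
    target occurs.
    """
    params = params or DesignParams()
    if len(indexes) < params.min_conservation_genomes:
        logger.warning(
            "cross_compare: only %d genome(s) supplied but conservation in "
            ">= %d genomes is required; result is empty",
            len(indexes), params.min_conservation_genomes,
        )
        return []

    targets = sorted({g.target_23 for guides in per_genome_guides.values() for g in guides})
    home_gene: dict[str, dict[str, str]] = {}
    for genome_id, guides in per_genome_guides.items():
        for g in guides:
            if g.gene_id:
                home_gene.setdefault(g.target_23, {})[genome_id] = g.gene_id

    genome_ids = sorted(indexes)
    trees = {gid: gene_interval_trees(indexes[gid].genome) for gid in genome_ids}

    # batch specificity of every candidate target in every genome
    protospacers = [t[:20] for t in targets]
    perfect_counts: dict[str, tuple] = {}
    for gid in genome_ids:
        perfect_counts[gid] = indexes[gid].count_matches_batch(
            protospacers, max_mismatches=params.offtarget_max_mismatches
        )

    conserved: list[ConservedGuide] = []
    for ti, target in enumerate(targets):
        occurrences: dict[str, list[GuideSite]] = {}
        gene_ids: dict[str, Optional[str]] = {}
        strict_ok = True
        for gid in genome_ids:
            rows = indexes[gid].exact_lookup(target)
            if not rows:
                continue
            sites = []
            for r in rows:
                s = indexes[gid].sites[r]
                gene = home_gene.get(target, {}).get(gid) or _gene_at(
                    trees[gid], s.contig_id, s.start, s.end
                )
                sites.append(
                    GuideSite(
                        target_23=s.target_23,
                        protospacer=s.protospacer,
                        pam=s.pam,
                        genome_id=gid,
                        contig_id=s.contig_id,
                        start=s.start,
                        strand=s.strand,
                        gene_id=gene,
                    )
                )
            occurrences[gid] = sites
            gene_ids[gid] = sites[0].gene_id
            n_perfect = int(perfect_counts[gid][0][ti])
            n_near = int(perfect_counts[gid][1][ti])
            if n_perfect != 1 or n_near != 0:
                strict_ok = False
        if len(occurrences) < params.min_conservation_genomes:
            continue
        if strict and not strict_ok:
            continue
        discord = {g for g in gene_ids.values() if g is not None}
        if len(discord) > 1:
            logger.info(
                "cross_compare: target %s maps to discordant genes %s", target, sorted(discord)
            )
        conserved.append(
            ConservedGuide(
                target_23=target,
                occurrences=occurrences,
                gene_ids=gene_ids,
                passes_strict=strict_ok,
            )
        )
    return conserved


def summarize(
    conserved: Sequence[ConservedGuide],
    reference: StrainGenome,
    tiers: Sequence[int] = (2,),
    n_genomes: int | None = None,
    params: DesignParams | None = None,
    checksums: Mapping[str, str] | None = None,
) -> DesignReport:
    """Per-tier counts of guides and of distinct reference genes targeted.

    Tier k counts guides with conservation level >= k; gene percentages
    are taken against the reference's annotated protein-coding gene
    count and rounded to whole percent.
    """
    params = params or DesignParams()
    n_ref_genes = len(reference.genes)
    tier_rows: dict[int, dict] = {}
    for k in sorted(tiers):
        at_k = [c for c in conserved if c.conservation_level >= k]
        genes = set()
        for c in at_k:
            gid = c.gene_ids.get(reference.strain_id)
            if gid is None:
                others = sorted(g for g in c.gene_ids.values() if g is not None)
                gid = others[0] if others else None
            if gid is not None:
                genes.add(gid)
        pct = round(100.0 * len(genes) / n_ref_genes) if n_ref_genes else 0
        tier_rows[k] = dict(n_guides=len(at_k), n_genes=len(genes), pct_genes=pct)

    totals: dict[str, int] = {}
    for c in conserved:
        for gid in c.occurrences:
            totals[gid] = totals.get(gid, 0) + 1

    return DesignReport(
        n_genomes=n_genomes if n_genomes is not None else len(totals),
        reference_id=reference.strain_id,
        n_reference_genes=n_ref_genes,
        tiers=tier_rows,
        totals_per_genome=dict(sorted(totals.items())),
        params=params.to_dict(),
        input_checksums=dict(checksums or {}),
    )
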