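"""End-to-end workflow: annotate, find guides, filter, conserve, report.

The funnel per genome is logged stage by stage (all sites in genes ->
overlap-excluded -> specificity-filtered) so the filtering behaviour is
auditable, and every output file is written deterministically: running
the pipeline twice on identical inputs produces byte-identical files.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__
from .annotation_transfer import transfer_annotations
from .conservation import (
    ConservedGuide,
    DesignReport,
    cross_compare,
    genome_checksum,
    summarize,
)
from .genome_io import read_genome, write_guides
from .guide_discovery import guides_in_genes
from .models import DesignParams, GuideSite, StrainGenome
from .offtarget import SiteIndex

logger = logging.getLogger(__name__)


@dataclass
class StrainInput:
    """One strain's input files (annotation optional)."""

    strain_id: str
    fasta: str
    gff3: Optional[str] = None


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    strains: list[StrainInput]
    reference_id: str
    out_dir: str
    params: DesignParams = field(default_factory=DesignParams)
    tiers: tuple[int, ...] = (2,)
    strict: bool = True

    def validate(self) -> None:
        ids = [s.strain_id for s in self.strains]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate strain ids")
        if self.reference_id not in ids:
            raise ValueError(f"reference strain {self.reference_id!r} not among inputs")
        ref = next(s for s in self.strains if s.strain_id == self.reference_id)
        if ref.gff3 is None:
            raise ValueError("the reference strain must have a GFF3 annotation")
        for s in self.strains:
            if not os.path.exists(s.fasta):
                raise ValueError(f"missing FASTA: {s.fasta}")
            if s.gff3 is not None and not os.path.exists(s.gff3):
                raise ValueError(f"missing GFF3: {s.gff3}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = DesignParams(**raw.get("params", {}))
        strains = [StrainInput(**s) for s in raw["strains"]]
        return cls(
            strains=strains,
            reference_id=raw["reference"],
            out_dir=raw.get("out_dir", "panguide_out"),
            params=params,
            tiers=tuple(raw.get("tiers", [2])),
            strict=bool(raw.get("strict", True)),
        )


@dataclass
class RunResult:
    """Everything a run produced, in memory plus on disk."""

    report: DesignReport
    conserved: list[ConservedGuide]
    per_genome_specific: dict[str, list[GuideSite]]
    genomes: dict[str, StrainGenome]
    output_files: dict[str, str]


def _specific_guides(
    genome: StrainGenome, index: SiteIndex, params: DesignParams
) -> list[GuideSite]:
    """In-gene guides that are single-copy with no near-matches, via one
    batched Hamming pass over the site index."""
    candidates = guides_in_genes(genome, params)
    if not candidates:
        return []
    perfect, near = index.count_matches_batch(
        [g.protospacer for g in candidates],
        max_mismatches=params.offtarget_max_mismatches,
    )
    kept = []
    for g, np_, nn in zip(candidates, perfect, near):
        if np_ < 1:
            raise RuntimeError(
                f"internal consistency error: own locus of {g.target_23} not indexed"
            )
        if np_ == 1 and nn == 0:
            kept.append(g)
    logger.info(
        "%s: %d in-gene guide sites, %d specific (single-copy, no off-targets)",
        genome.strain_id, len(candidates), len(kept),
    )
    return kept


def run_pipeline_on_genomes(
    genomes: dict[str, StrainGenome],
    reference_id: str,
    params: DesignParams | None = None,
    tiers: Sequence[int] = (2,),
    strict: bool = True,
    out_dir: str | None = None,
) -> RunResult:
    """Run the full workflow on already-loaded genomes.

    Unannotated genomes receive transferred annotations from the
    reference first; guides are then enumerated in genes, filtered for
    specificity per genome, cross-compared across genomes and
    summarised per conservation tier.
    """
    params = params or DesignParams()
    reference = genomes[reference_id]
    if not reference.is_annotated:
        raise ValueError("reference genome must be annotated")

    for gid in sorted(genomes):
        g = genomes[gid]
        if not g.is_annotated and gid != reference_id:
            logger.info("annotating %s by transfer from %s", gid, reference_id)
            g.genes = transfer_annotations(reference, g, params.evalue_threshold)

    indexes = {gid: SiteIndex(genomes[gid]) for gid in sorted(genomes)}
    per_genome = {
        gid: _specific_guides(genomes[gid], indexes[gid], params)
        for gid in sorted(genomes)
    }
    conserved = cross_compare(per_genome, indexes, params, strict=strict)
    logger.info("conserved guide targets (strict=%s): %d", strict, len(conserved))
    checksums = {gid: genome_checksum(genomes[gid]) for gid in genomes}
    report = summarize(
        conserved,
        reference,
        tiers=tiers,
        n_genomes=len(genomes),
        params=params,
        checksums=checksums,
    )

    outputs: dict[str, str] = {}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for gid in sorted(per_genome):
            path = os.path.join(out_dir, f"guides_{gid}.tsv")
            write_guides(per_genome[gid], path, "tsv")
            outputs[f"guides_{gid}"] = path
        for fmt in ("tsv", "bed", "fasta"):
            path = os.path.join(out_dir, f"conserved.{fmt}")
            write_guides(conserved, path, fmt)
            outputs[f"conserved_{fmt}"] = path
        report_path = os.path.join(out_dir, "report.json")
        with open(report_path, "w") as fh:
            fh.write(report.to_json() + "\n")
        outputs["report"] = report_path

    return RunResult(
        report=report,
        conserved=conserved,
        per_genome_specific=per_genome,
        genomes=genomes,
        output_files=outputs,
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Load the configured inputs and run the workflow end to end."""
    config.validate()
    genomes: dict[str, StrainGenome] = {}
    for s in config.strains:
        genomes[s.strain_id] = read_genome(s.fasta, s.gff3, strain_id=s.strain_id)
    return run_pipeline_on_genomes(
        genomes,
        config.reference_id,
        params=config.params,
        tiers=config.tiers,
        strict=config.strict,
        out_dir=config.out_dir,
    )
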