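"""Cross-genome conservation tiers and the design summary."""
import numpy as np
import pytest

from panguide.conservation import ConservedGuide, cross_compare, summarize
from panguide.models import DesignParams, GeneModel, GuideSite, StrainGenome
from panguide.offtarget import SiteIndex
from panguide.simulate import mutate_guide_site, simulate_strain_set

from conftest import brute_force_near_matches, random_dna


def _plant(rng, n_guides=2, length=4000):
    """Genome with ``n_guides`` engineered specific guides, verified clean."""
    while True:
        seq = random_dna(rng, length)
        sites = []
        for k in range(n_guides):
            pos = 500 + 800 * k
            proto = random_dna(rng, 20)
            seq = seq[:pos] + proto + "TGG" + seq[pos + 23 :]
            sites.append((pos, proto))
        genome = StrainGenome("A", {"c1": seq})
        if all(
            len(brute_force_near_matches(genome, proto, 5)) == 1 for _, proto in sites
        ):
            guides = [
                GuideSite(
                    target_23=proto + "TGG", protospacer=proto, pam="TGG",
                    genome_id="A", contig_id="c1", start=pos, strand="+",
                )
                for pos, proto in sites
            ]
            return genome, guides


def test_single_genome_cannot_reach_conservation_threshold(rng):
    genome, guides = _plant(rng, 1)
    out = cross_compare({"A": guides}, {"A": SiteIndex(genome)}, DesignParams())
    assert out == []


def test_planted_conservation_levels(rng):
    genome_a, guides = _plant(rng, 2)
    shared, private = guides
    genome_b = StrainGenome("B", dict(genome_a.contigs))
    # strain B keeps the shared guide but loses the private one (PAM break)
    genome_b = mutate_guide_site(genome_b, private, "pam_break")
    # strain C lost both
    genome_c = StrainGenome("C", dict(genome_a.contigs))
    for g in guides:
        genome_c = mutate_guide_site(genome_c, g, "pam_break")
    indexes = {g.strain_id: SiteIndex(g) for g in (genome_a, genome_b, genome_c)}
    out = cross_compare({"A": guides}, indexes, DesignParams())
    by_target = {c.target_23: c for c in out}
    assert shared.target_23 in by_target
    assert by_target[shared.target_23].conservation_level == 2
    assert sorted(by_target[shared.target_23].occurrences) == ["A", "B"]
    # the strain-private guide (level 1) is dropped
    assert private.target_23 not in by_target


def test_pam_break_lowers_conservation_level(rng):
    genome_a, guides = _plant(rng, 1)
    genome_b = StrainGenome("B", dict(genome_a.contigs))
    indexes = {"A": SiteIndex(genome_a), "B": SiteIndex(genome_b)}
    before = cross_compare({"A": guides}, indexes, DesignParams())
    assert before[0].conservation_level == 2
    broken = mutate_guide_site(genome_b, guides[0], "pam_break")
    indexes["B"] = SiteIndex(broken)
    after = cross_compare({"A": guides}, indexes, DesignParams())
    assert after == []  # level fell from 2 to 1, below the threshold


def test_nested_threshold_subset(rng):
    truth = simulate_strain_set(n_strains=3, divergence=0.01, seed=5)
    genomes = {s.strain_id: s for s in truth.strains}
    indexes = {gid: SiteIndex(g) for gid, g in genomes.items()}
    from panguide.guide_discovery import guides_in_genes

    per_genome = {gid: guides_in_genes(g) for gid, g in genomes.items()}
    at2 = cross_compare(per_genome, indexes, DesignParams(min_conservation_genomes=2))
    at3 = cross_compare(per_genome, indexes, DesignParams(min_conservation_genomes=3))
    t2 = {c.target_23 for c in at2}
    t3 = {c.target_23 for c in at3}
    assert t3 <= t2
    # partition property: every conserved target appears exactly once
    all_t = [c.target_23 for c in at2]
    assert len(all_t) == len(set(all_t))


def _mk_conserved(target, genomes, gene_map):
    occ = {
        g: [
            GuideSite(
                target_23=target, protospacer=target[:20], pam=target[20:],
                genome_id=g, contig_id="c1", start=0, strand="+",
                gene_id=gene_map.get(g),
            )
        ]
        for g in genomes
    }
    return ConservedGuide(
        target_23=target, occurrences=occ,
        gene_ids={g: gene_map.get(g) for g in genomes}, passes_strict=True,
    )


def test_summarize_hand_enumerated_fixture(rng):
    """10 guides over a 5-gene reference; 6 reach level >= 2 and span 3
    genes -> the tier-2 row reads (6, 3, 60%)."""
    ref_genes = [GeneModel(f"g{i}", "c1", "+", ((i * 100, i * 100 + 90),)) for i in range(5)]
    ref = StrainGenome("ref", {"c1": random_dna(rng, 1000)}, ref_genes)
    conserved = []
    specs = [  # (genomes carrying the target, reference gene)
        (["ref", "B"], "g0"), (["ref", "B"], "g0"), (["ref", "C"], "g1"),
        (["ref", "B", "C"], "g1"), (["ref", "C"], "g2"), (["ref", "B"], "g2"),
        (["ref"], "g3"), (["ref"], "g3"), (["ref"], "g0"), (["ref"], "g4"),
    ]
    for i, (genomes, gene) in enumerate(specs):
        target = random_dna(rng, 20) + "TGG"
        conserved.append(_mk_conserved(target, genomes, {"ref": gene}))
    report = summarize(conserved, ref, tiers=(1, 2, 3), n_genomes=3)
    assert report.tiers[2] == {"n_guides": 6, "n_genes": 3, "pct_genes": 60}
    assert report.tiers[1]["n_guides"] == 10
    assert report.tiers[3] == {"n_guides": 1, "n_genes": 1, "pct_genes": 20}
    # tier monotonicity
    assert report.tiers[1]["n_guides"] >= report.tiers[2]["n_guides"] >= report.tiers[3]["n_guides"]
    assert report.tiers[1]["n_genes"] >= report.tiers[2]["n_genes"] >= report.tiers[3]["n_genes"]


def test_summarize_empty():
    ref = StrainGenome("ref", {"c1": "ACGT" * 20}, [GeneModel("g", "c1", "+", ((0, 30),))])
    report = summarize([], ref, tiers=(2,), n_genomes=2)
    assert report.tiers[2] == {"n_guides": 0, "n_genes": 0, "pct_genes": 0}
    assert report.totals_per_genome == {}


def test_tier_counts_decrease_with_divergence():
    """More divergence erodes full-panel conservation (stochastic, fixed seeds)."""
    counts = []
    for div in (0.0, 0.05):
        totals = 0
        for seed in (11, 12):
            truth = simulate_strain_set(
                n_strains=3, n_genes=8, genome_length=12_000, divergence=div, seed=seed
            )
            genomes = {s.strain_id: s for s in truth.strains}
            indexes = {gid: SiteIndex(g) for gid, g in genomes.items()}
            from panguide.guide_discovery import guides_in_genes

            per_genome = {gid: guides_in_genes(g) for gid, g in genomes.items()}
            out = cross_compare(
                per_genome, indexes, DesignParams(min_conservation_genomes=3)
            )
            totals += len(out)
        counts.append(totals)
    assert counts[1] < counts[0]
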