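"""Near-match search: completeness against a brute-force oracle,
single-copy verdicts, symmetry and monotonicity."""
import numpy as np
import pytest

from panguide.guide_discovery import scan_pams
from panguide.models import GeneModel, GuideSite, StrainGenome, revcomp
from panguide.offtarget import (
    SiteIndex,
    assess_specificity,
    build_site_index,
    find_near_matches,
)
from panguide.simulate import mutate_guide_site

from conftest import brute_force_near_matches, random_dna


def _genome(seq: str, strain="s", contig="c1", genes=None) -> StrainGenome:
    return StrainGenome(strain, {contig: seq}, genes or [])


def test_every_indexed_site_finds_itself_at_zero_mismatches(rng):
    genome = _genome(random_dna(rng, 2000))
    index = build_site_index(genome)
    for site in index.sites[::7]:  # sample for speed; behaviour is uniform
        hits = find_near_matches(site, index, 0)
        assert (site.contig_id, site.start, site.strand) in {
            (h.contig_id, h.start, h.strand) for h in hits
        }
        assert all(h.mismatches == 0 for h in hits)


def test_all_a_genome_has_no_sites():
    index = build_site_index(_genome("A" * 500))
    assert len(index) == 0


@pytest.mark.parametrize("max_mm", [0, 1, 3, 5])
def test_hits_equal_brute_force_oracle(rng, max_mm):
    genome = _genome(random_dna(rng, 10_000))
    index = build_site_index(genome)
    queries = [s.protospacer for s in rng.choice(index.sites, size=25)] + [
        random_dna(rng, 20) for _ in range(25)
    ]
    for q in queries:
        got = {
            (h.contig_id, h.start, h.strand, h.mismatches)
            for h in find_near_matches(q, index, max_mm)
        }
        assert got == brute_force_near_matches(genome, q, max_mm)


def test_monotonic_in_mismatch_bound(rng):
    genome = _genome(random_dna(rng, 5000))
    index = build_site_index(genome)
    q = index.sites[3].protospacer
    prev = set()
    for m in range(6):
        cur = {(h.contig_id, h.start, h.strand) for h in find_near_matches(q, index, m)}
        assert prev <= cur
        prev = cur


def test_minus_strand_hits_mirror_reverse_complemented_genome(rng):
    seq = random_dna(rng, 3000)
    L = len(seq)
    q = random_dna(rng, 20)
    fwd = brute_force_near_matches(_genome(seq), q, 5)
    rev = brute_force_near_matches(_genome(revcomp(seq)), q, 5)
    reflected = {(c, L - 23 - p, "+" if s == "-" else "-", m) for c, p, s, m in fwd}
    assert rev == reflected
    # and the index agrees with the oracle on both orientations
    for genome, truth in ((_genome(seq), fwd), (_genome(revcomp(seq)), rev)):
        idx = build_site_index(genome)
        got = {
            (h.contig_id, h.start, h.strand, h.mismatches)
            for h in find_near_matches(q, idx, 5)
        }
        assert got == truth


def test_max_mismatches_above_definition_warns(rng):
    index = build_site_index(_genome(random_dna(rng, 200)))
    with pytest.warns(UserWarning, match="fewer than six"):
        find_near_matches(random_dna(rng, 20), index, 6)


def _planted_clean_genome(rng, n=8000):
    """Background scrubbed of near-matches, one planted unique guide."""
    guide20 = random_dna(rng, 20)
    while True:
        seq = random_dna(rng, n)
        pos = 4000
        seq = seq[:pos] + guide20 + "TGG" + seq[pos + 23 :]
        genome = _genome(seq)
        if len(brute_force_near_matches(genome, guide20, 5)) == 1:
            site = GuideSite(
                target_23=guide20 + "TGG", protospacer=guide20, pam="TGG",
                genome_id="s", contig_id="c1", start=pos, strand="+",
            )
            return genome, site


def test_unique_planted_guide_is_specific(rng):
    genome, site = _planted_clean_genome(rng)
    verdict = assess_specificity(site, build_site_index(genome))
    assert verdict.is_specific
    assert len(verdict.perfect_sites) == 1 and verdict.near_sites == []


def test_duplicated_target_fails_single_copy(rng):
    genome, site = _planted_clean_genome(rng)
    dup = mutate_guide_site(genome, site, "duplicate")
    verdict = assess_specificity(site, build_site_index(dup))
    assert not verdict.is_specific
    assert len(verdict.perfect_sites) == 2


def test_three_mismatch_decoy_defeats_specificity(rng):
    genome, site = _planted_clean_genome(rng)
    decoy = list(site.protospacer)
    for i in (2, 9, 15):
        decoy[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[decoy[i]]
    seq = genome.contigs["c1"]
    seq = seq[:200] + "".join(decoy) + "CGG" + seq[223:]
    verdict = assess_specificity(site, build_site_index(_genome(seq)))
    assert not verdict.is_specific
    assert any(h.mismatches == 3 for h in verdict.near_sites)


def test_protospacer_snp_creates_single_one_mismatch_hit(rng):
    genome, site = _planted_clean_genome(rng)
    mutated = mutate_guide_site(genome, site, "protospacer_snp")
    hits = find_near_matches(site, build_site_index(mutated), 5)
    assert [h.mismatches for h in hits] == [1]


def test_own_locus_missing_raises_consistency_error(rng):
    genome, site = _planted_clean_genome(rng)
    broken = mutate_guide_site(genome, site, "pam_break")
    with pytest.raises(RuntimeError, match="consistency"):
        assess_specificity(site, build_site_index(broken))


def test_batch_counts_agree_with_per_query_hits(rng):
    genome = _genome(random_dna(rng, 6000))
    index = build_site_index(genome)
    protos = [s.protospacer for s in index.sites[:100]]
    perfect, near = index.count_matches_batch(protos, max_mismatches=5)
    for p, np_, nn in zip(protos, perfect, near):
        hits = find_near_matches(p, index, 5)
        assert np_ == sum(1 for h in hits if h.mismatches == 0)
        assert nn == sum(1 for h in hits if h.mismatches > 0)
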