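"""Knockout design: offsets, strand classes, cut sites, paired-guide
deletions and paralog-aware guide selection."""
import numpy as np
import pytest

from panguide.guide_discovery import scan_pams
from panguide.knockout import (
    LocusGuide,
    annotate_locus_guide,
    classify_strand,
    cut_site,
    default_scorer,
    guide_context_30,
    predict_deletion,
    rank_guides,
    select_guides_for_locus,
)
from panguide.matalpha3 import MATALPHA3_GUIDES, synthetic_matalpha3_locus
from panguide.models import DesignParams, GeneModel, GuideSite, StrainGenome, revcomp
from panguide.offtarget import SiteIndex

from conftest import random_dna


def _locus_guides(strand="+"):
    genome, gene = synthetic_matalpha3_locus(strand=strand)
    sites = {
        s.target_23: s
        for s in scan_pams(genome.contigs["chr_syn"], genome_id=genome.strain_id,
                           contig_id="chr_syn")
    }
    out = {}
    for pg in MATALPHA3_GUIDES:
        out[pg.guide_id] = annotate_locus_guide(sites[pg.sequence_23], gene, genome)
    return genome, gene, out


def test_published_guides_are_valid_ngg_targets():
    for pg in MATALPHA3_GUIDES:
        assert len(pg.sequence_23) == 23
        assert pg.sequence_23[21:23] == "GG"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_strand_classes_match_published_marks(strand):
    _, gene, guides = _locus_guides(strand)
    classes = {gid: g.guide_strand_vs_gene for gid, g in guides.items()}
    assert classes["gRNA1"] == "antisense" and classes["gRNA3"] == "antisense"
    for gid in ("gRNA2", "gRNA4", "gRNA5", "gRNA6"):
        assert classes[gid] == "sense"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_offsets_reproduce_published_values(strand):
    """Both offset conventions are carried: the PAM start (sense) or
    protospacer start (antisense) matches the published figure, and for
    sense guides the two conventions differ by exactly 20 nt."""
    _, gene, guides = _locus_guides(strand)
    for pg in MATALPHA3_GUIDES:
        lg = guides[pg.guide_id]
        assert lg.offset_reported == pg.offset_downstream_atg, pg.guide_id
        if lg.guide_strand_vs_gene == "sense":
            assert lg.offset_pam_start - lg.offset_protospacer_start == 20


def test_classify_strand_basic():
    gene_plus = GeneModel("g", "c1", "+", ((0, 100),))
    site = GuideSite("A" * 20 + "TGG", "A" * 20, "TGG", "s", "c1", 10, "+")
    assert classify_strand(site, gene_plus) == "sense"
    site_m = GuideSite("A" * 20 + "TGG", "A" * 20, "TGG", "s", "c1", 10, "-")
    assert classify_strand(site_m, gene_plus) == "antisense"


def test_cut_site_arithmetic_and_reflection(rng):
    seq = random_dna(rng, 300)
    for site in scan_pams(seq):
        cut = cut_site(site)
        assert site.start < cut < site.start + 23  # inside the 23-nt span
        if site.strand == "+":
            assert cut == site.start + 17
        else:
            assert cut == site.start + 6
    # reverse complementing the contig reflects every cut coordinate
    L = len(seq)
    fwd = {(s.start, s.strand): cut_site(s) for s in scan_pams(seq)}
    rev = {(s.start, s.strand): cut_site(s) for s in scan_pams(revcomp(seq))}
    for (start, strand), cut in fwd.items():
        mirrored = rev[(L - 23 - start, "-" if strand == "+" else "+")]
        assert mirrored == L - cut


def test_deletion_arithmetic_on_published_offsets():
    genome, _, guides = _locus_guides("+")
    d25 = predict_deletion(guides["gRNA2"], guides["gRNA5"], genome)
    d45 = predict_deletion(guides["gRNA4"], guides["gRNA5"], genome)
    assert d25.predicted_length == 449
    assert d45.predicted_length == 113
    # the blunt-cut caveat is flagged on the prediction itself
    assert "blunt-cut" in d25.note
    # symmetry
    assert predict_deletion(guides["gRNA5"], guides["gRNA2"]).predicted_length == 449
    # identical guides predict no deletion
    assert predict_deletion(guides["gRNA2"], guides["gRNA2"]).predicted_length == 0


def test_deletion_between_planted_guides_is_their_cut_distance(rng):
    seq = random_dna(rng, 2000)
    a20, b20 = random_dna(rng, 20), random_dna(rng, 20)
    seq = seq[:100] + a20 + "TGG" + seq[123:]
    seq = seq[:1100] + b20 + "TGG" + seq[1123:]
    genome = StrainGenome("s", {"c1": seq})
    sa = GuideSite(a20 + "TGG", a20, "TGG", "s", "c1", 100, "+")
    sb = GuideSite(b20 + "TGG", b20, "TGG", "s", "c1", 1100, "+")
    gene = GeneModel("g", "c1", "+", ((50, 1500),))
    la = annotate_locus_guide(sa, gene, genome)
    lb = annotate_locus_guide(sb, gene, genome)
    assert predict_deletion(la, lb).predicted_length == 1000
    j = predict_deletion(la, lb, genome, flank=5).junction
    left, right = j.split("|")
    assert left == seq[112:117] and right == seq[1117:1122]


def test_deletion_across_contigs_is_an_error():
    genome, _, guides = _locus_guides("+")
    other = LocusGuide(
        site=GuideSite("A" * 20 + "TGG", "A" * 20, "TGG", "s", "other", 0, "+"),
        gene_id="g", offset_protospacer_start=1, offset_pam_start=21,
        guide_strand_vs_gene="sense", cut_position=17,
    )
    with pytest.raises(ValueError, match="different contigs"):
        predict_deletion(guides["gRNA2"], other)


def test_default_scorer_penalizes_poly_a_and_ties_break_by_offset():
    poly_a_ctx = "N" * 4 + "A" * 20 + "TGGNNN"
    balanced_ctx = "N" * 4 + "ACGTACGTACGTACGTACGT" + "TGGNNN"
    assert default_scorer(poly_a_ctx) < default_scorer(balanced_ctx)
    genome, gene, guides = _locus_guides("+")
    ranked = rank_guides(list(guides.values()), scorer=lambda ctx: 0.5)
    offsets = [g.offset_protospacer_start for g in ranked]
    assert offsets == sorted(offsets)  # constant scorer -> pure offset order


def _paralog_fixture(rng):
    """Two identical gene copies plus one diverged decoy gene."""
    while True:
        seq = random_dna(rng, 6000)
        core = random_dna(rng, 300)
        body = "ATG" + core + "TAA"
        seq = seq[:500] + body + seq[500 + len(body):]
        seq = seq[:3000] + body + seq[3000 + len(body):]
        genes = [
            GeneModel("mat_a3", "c1", "+", ((500, 500 + len(body)),)),
            GeneModel("hml_a3", "c1", "+", ((3000, 3000 + len(body)),)),
            GeneModel("decoy", "c1", "+", ((4500, 4800),)),
        ]
        genome = StrainGenome("s", {"c1": seq}, genes)
        genome.validate()
        index = SiteIndex(genome)
        sel = select_guides_for_locus({"mat_a3", "hml_a3"}, genome, index)
        if sel:
            return genome, index, sel


def test_paralog_pair_guides_hit_both_copies_and_nothing_else(rng):
    genome, index, selected = _paralog_fixture(rng)
    from panguide.offtarget import find_near_matches

    for lg in selected:
        hits = find_near_matches(lg.site, index, 5)
        perfect = [h for h in hits if h.mismatches == 0]
        assert len(perfect) == 2  # identical copies force co-occurrence
        for h in perfect:
            assert 500 <= h.start < 806 or 3000 <= h.start < 3306
        assert all(h.mismatches == 0 for h in hits)  # no near-sites elsewhere


def test_guide_with_extra_copy_outside_allowed_loci_is_rejected(rng):
    genome, index, selected = _paralog_fixture(rng)
    lg = selected[0]
    seq = genome.contigs["c1"]
    window = seq[lg.site.start : lg.site.start + 23]
    poisoned = StrainGenome(
        "s", {"c1": seq[:5500] + window + seq[5523:]}, genome.genes
    )
    poisoned.validate()
    sel2 = select_guides_for_locus({"mat_a3", "hml_a3"}, poisoned, SiteIndex(poisoned))
    assert lg.site.target_23 not in {g.site.target_23 for g in sel2}


def test_unknown_allowed_locus_is_an_error(rng):
    genome, index, _ = _paralog_fixture(rng)
    with pytest.raises(KeyError, match="no gene"):
        select_guides_for_locus({"mat_a3", "missing"}, genome, index)


def test_selection_is_subset_of_in_gene_guides(rng):
    from panguide.guide_discovery import guides_in_genes

    genome, index, selected = _paralog_fixture(rng)
    allowed_targets = {
        g.target_23 for g in guides_in_genes(genome, DesignParams())
        if g.gene_id in ("mat_a3", "hml_a3")
    }
    assert {g.site.target_23 for g in selected} <= allowed_targets
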