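"""Bin-taxonomy voting and LCA scaffold labelling."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binquant.io import Lineage
from binquant.taxonomy import (
    EXCLUDED_LABELS, lca_assign, lineage_lca, vote_bin_taxonomy,
)
from .conftest import make_hit

LIN_A = "Bacteria;Terrabacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus;Bacillus thermoamylovorans"
LIN_B = "Bacteria;Gracilicutes;Proteobacteria;Gammaproteobacteria;Xanthomonadales;Xanthomonadaceae;Luteimonas;Luteimonas sp."


class TestVoting:
    def test_modal_lineage_and_winner_only_aai(self):
        hits = [make_hit(LIN_A, "g1", 90.0), make_hit(LIN_A, "g2", 80.0),
                make_hit(LIN_B, "g3", 99.0)]
        t = vote_bin_taxonomy("bin1", hits)
        assert str(t.lineage) == LIN_A
        assert t.vote_fraction == pytest.approx(2 / 3)
        # AAI averages over the two winner-voting genes only, not the 99% outlier
        assert t.mean_aai == pytest.approx(85.0)
        assert not t.is_eukaryote

    def test_unanimous_vote(self):
        t = vote_bin_taxonomy("b", [make_hit(LIN_A, f"g{i}") for i in range(4)])
        assert t.vote_fraction == 1.0

    def test_no_hits_is_unassigned(self):
        t = vote_bin_taxonomy("b", [])
        assert t.label == "unassigned"
        assert t.mean_aai is None and t.vote_fraction is None

    def test_tie_broken_by_higher_mean_identity(self):
        hits = [make_hit(LIN_A, "g1", 70.0), make_hit(LIN_B, "g2", 95.0)]
        t = vote_bin_taxonomy("b", hits)
        assert str(t.lineage) == LIN_B

    def test_eukaryote_winner_flagged(self):
        t = vote_bin_taxonomy("b", [make_hit("Eukaryota;Fungi;Ascomycota", "g1")])
        assert t.is_eukaryote

    def test_voting_is_permutation_invariant(self):
        hits = [make_hit(LIN_A, "g1", 90.0), make_hit(LIN_B, "g2", 80.0),
                make_hit(LIN_A, "g3", 70.0)]
        results = {str(vote_bin_taxonomy("b", list(p)).lineage)
                   for p in itertools.permutations(hits)}
        assert results == {LIN_A}

    def test_high_identity_bin_call(self):
        """A bin voted to Bacillus thermoamylovorans at 98.9% mean AAI."""
        hits = [make_hit(LIN_A, f"g{i}", ident) for i, ident in
                enumerate([98.9, 99.4, 98.4, 98.9])]
        t = vote_bin_taxonomy("bin132", hits)
        assert t.lineage.at_rank("species") == "Bacillus thermoamylovorans"
        assert t.mean_aai == pytest.approx(98.9)


# --- LCA ------------------------------------------------------------------

# 3-phylum toy taxonomy plus out-of-domain and shallow entries
TOY_LINEAGES = [
    "Bacteria;Terrabacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus;Bacillus coagulans",
    "Bacteria;Terrabacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus;Bacillus subtilis",
    "Bacteria;Gracilicutes;Proteobacteria;Gammaproteobacteria;Xanthomonadales;Xanthomonadaceae;Luteimonas;Luteimonas terrae",
    "Bacteria;Terrabacteria;Actinobacteria;Actinomycetia;Streptosporangiales;Streptosporangiaceae;Streptosporangium;Streptosporangium roseum",
    "Bacteria",
    "Eukaryota;Fungi;Ascomycota",
    "Archaea;Euryarchaeota",
]


def oracle_label(lineage_strings):
    """Brute-force LCA: intersect rank lists position by position, then apply
    the labelling vocabulary.  Written independently of lca_assign."""
    split = [s.split(";") for s in lineage_strings]
    shared = []
    for labels in zip(*split):
        if len(set(labels)) == 1:
            shared.append(labels[0])
        else:
            break
    if not shared:
        return "cellular organisms"
    if shared[0] == "Eukaryota":
        return "eukaryotes"
    if shared == ["Bacteria"]:
        return "unclassified bacteria"
    return ";".join(shared)


class TestLca:
    def test_uniform_genus_keeps_lineage(self):
        hits = [make_hit(TOY_LINEAGES[0], "g1"), make_hit(TOY_LINEAGES[1], "g2")]
        lab = lca_assign("scf", hits)
        assert lab.label.endswith("Bacillus")
        assert lab.include_in_transcriptomics

    def test_phylum_split_is_unclassified_bacteria(self):
        hits = [make_hit(TOY_LINEAGES[0]), make_hit(TOY_LINEAGES[2])]
        lab = lca_assign("scf", hits)
        assert lab.label == "unclassified bacteria"
        assert lab.include_in_transcriptomics

    def test_domain_split_is_cellular_organisms_excluded(self):
        hits = [make_hit(TOY_LINEAGES[0]), make_hit(TOY_LINEAGES[5])]
        lab = lca_assign("scf", hits)
        assert lab.label == "cellular organisms"
        assert not lab.include_in_transcriptomics

    def test_no_hits_unassigned_excluded(self):
        lab = lca_assign("scf", [])
        assert lab.label == "unassigned"
        assert not lab.include_in_transcriptomics

    def test_eukaryote_lca_excluded(self):
        lab = lca_assign("scf", [make_hit(TOY_LINEAGES[5])])
        assert lab.label == "eukaryotes"
        assert not lab.include_in_transcriptomics

    def test_include_flag_mirrors_excluded_vocabulary(self):
        for lineages in itertools.combinations(TOY_LINEAGES, 2):
            lab = lca_assign("s", [make_hit(lin) for lin in lineages])
            assert lab.include_in_transcriptomics == (lab.label not in EXCLUDED_LABELS)

    def test_low_score_hits_fall_outside_window(self):
        # the eukaryote hit is far weaker: LCA should use only the strong hits
        hits = [make_hit(TOY_LINEAGES[0], evalue=1e-100),
                make_hit(TOY_LINEAGES[1], evalue=1e-98),
                make_hit(TOY_LINEAGES[5], evalue=1e-10)]
        lab = lca_assign("scf", hits, top_percent=10.0)
        assert lab.label.endswith("Bacillus")

    @pytest.mark.parametrize("size", [1, 2, 3, 4, 5, 6])
    def test_matches_bruteforce_oracle_on_all_small_inputs(self, size):
        """Exhaustive LCA equivalence over the toy taxonomy (equal scores)."""
        for combo in itertools.combinations_with_replacement(TOY_LINEAGES, size):
            hits = [make_hit(lin, f"g{i}", evalue=1e-30) for i, lin in enumerate(combo)]
            assert lca_assign("s", hits).label == oracle_label(combo), combo


@settings(deadline=None, max_examples=200)
@given(st.lists(st.sampled_from(TOY_LINEAGES), min_size=1, max_size=8))
def test_lineage_lca_is_a_prefix_of_every_input(lineage_strings):
    lca = lineage_lca([Lineage.from_string(s) for s in lineage_strings])
    for s in lineage_strings:
        assert s.split(";")[: len(lca)] == list(lca.ranks)
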