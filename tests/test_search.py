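"""Target-pair enumeration, proposal generation, grafting, clash screening."""

import math

import numpy as np
import pytest

from triadmut.errors import ProvenanceError, TriadmutError
from triadmut.fixtures import (FixtureSpec, PlantedInteraction, make_fixture,
                               _database_from_structures, strip_pair_to_alanine)
from triadmut.interactions import detect_sidechain_interactions
from triadmut.search import (SearchCounts, SearchParams, detect_clash,
                             enumerate_target_pairs, graft_sidechains,
                             label_pair, propose_mutations, summarize_by_sites)
from triadmut.signatures import fit_database_signatures
from triadmut.triads import TriadDatabase


@pytest.fixture
def hb_db(planted_hb):
    db = _database_from_structures([planted_hb])
    fit_database_signatures(db)
    return db


class TestEnumeration:
    def test_neighbours_and_out_of_range_pairs_excluded(self, helix10):
        pairs = {(i, j) for i, j, _ in enumerate_target_pairs(helix10)}
        assert all(j - i >= 3 for i, j in pairs)
        # terminal residues have no flanks, so they never appear
        assert all(0 < i and j < len(helix10) - 1 for i, j in pairs)

    def test_ca_window_respected(self, helix10):
        residues = list(helix10)
        for i, j, _ in enumerate_target_pairs(helix10):
            d = np.linalg.norm(residues[i].ca.coords - residues[j].ca.coords)
            assert 3.35 <= d <= 16.40

    def test_already_interacting_pair_excluded(self, planted_hb):
        inter = detect_sidechain_interactions(planted_hb)[0]
        pair = (inter.res_a[1] - 1, inter.res_b[1] - 1)  # 0-based positions
        pairs = {(i, j) for i, j, _ in enumerate_target_pairs(planted_hb)}
        assert pair not in pairs
        # the same backbone with the side chains stripped re-admits the pair
        stripped = strip_pair_to_alanine(planted_hb, inter.res_a[1], inter.res_b[1])
        assert pair in {(i, j) for i, j, _ in enumerate_target_pairs(stripped)}

    def test_region_search_keeps_pairs_near_center(self, helix10):
        center = ("A", 5, "")
        params = SearchParams(region_center=center, region_radius=6.0)
        residues = list(helix10)
        c = helix10.get_residue(center).ca.coords
        for i, j, _ in enumerate_target_pairs(helix10, params):
            near = min(np.linalg.norm(residues[i].ca.coords - c),
                       np.linalg.norm(residues[j].ca.coords - c))
            assert near <= 6.0

    def test_missing_region_center_raises(self, helix10):
        with pytest.raises(TriadmutError):
            enumerate_target_pairs(helix10, SearchParams(region_center=("A", 99, "")))


class TestProposals:
    def test_planted_template_recovered_with_notation(self, recovery_pair, hb_db):
        _, target = recovery_pair
        proposals = propose_mutations(target, hb_db)
        assert proposals, "expected at least one proposal"
        best = proposals[0]
        assert best.rmsd <= 1e-6
        assert (best.proposed_a, best.proposed_b) == ("SER", "THR")
        assert best.notation == "A4S/A8T"
        assert best.categories == frozenset()
        assert all(p.rmsd <= 0.5 for p in proposals)

    def test_empty_database_yields_no_proposals(self, recovery_pair):
        _, target = recovery_pair
        assert propose_mutations(target, TriadDatabase()) == []

    def test_rmsd_gate_rejects_dissimilar_backbones(self, hb_db):
        # a strand target has no helix-like triads: nothing passes 0.5 Å
        strand = make_fixture(FixtureSpec(n_residues=12, secondary_structure="strand",
                                          seed=9))
        assert propose_mutations(strand, hb_db, check_clash=False) == []

    def test_finite_filter_is_subset_of_unfiltered(self, recovery_pair, hb_db):
        _, target = recovery_pair
        unfiltered = propose_mutations(target, hb_db, SearchParams(), check_clash=False)
        filtered = propose_mutations(target, hb_db, SearchParams(ssv_cutoff=1.0),
                                     check_clash=False)
        key = lambda p: (p.site_a, p.site_b, p.template_id)
        assert {key(p) for p in filtered} <= {key(p) for p in unfiltered}

    def test_stage_counts_are_monotone(self, recovery_pair, hb_db):
        _, target = recovery_pair
        counts = SearchCounts()
        proposals = propose_mutations(target, hb_db, SearchParams(), counts=counts,
                                      check_clash=False)
        assert counts.pairs_enumerated * len(hb_db) >= counts.alignments_after_filter
        assert counts.alignments_after_filter >= counts.proposals == len(proposals)

    def test_summarize_keeps_best_rmsd_per_site_pair(self, recovery_pair, hb_db):
        _, target = recovery_pair
        proposals = propose_mutations(target, hb_db, check_clash=False)
        summary = summarize_by_sites(proposals)
        seen = {(p.site_a, p.site_b, p.proposed_a, p.proposed_b) for p in summary}
        assert len(seen) == len(summary)
        for p in summary:
            rivals = [q for q in proposals
                      if (q.site_a, q.site_b, q.proposed_a, q.proposed_b)
                      == (p.site_a, p.site_b, p.proposed_a, p.proposed_b)]
            assert p.rmsd == min(q.rmsd for q in rivals)


class TestGraft:
    def test_backbone_conserved_and_sidechains_transplanted(self, recovery_pair, hb_db):
        template, target = recovery_pair
        prop = propose_mutations(target, hb_db)[0]
        mutant = graft_sidechains(target, prop, hb_db)
        for res_w, res_m in zip(target, mutant):
            for name in ("N", "CA", "C", "O"):
                assert np.allclose(res_w.atoms[name].coords, res_m.atoms[name].coords)
        # identities updated and template geometry reproduced: the planted
        # hydrogen bond is detectable again in the mutant at its distance
        assert mutant.get_residue(prop.site_a).res_name == "SER"
        assert mutant.get_residue(prop.site_b).res_name == "THR"
        found = detect_sidechain_interactions(mutant)
        tpl_inter = detect_sidechain_interactions(template)[0]
        assert any(i.kind == "hydrogen_bond"
                   and i.distance == pytest.approx(tpl_inter.distance, abs=1e-4)
                   for i in found)

    def test_grafted_sidechain_matches_template_through_transform(self, planted_hb, hb_db):
        import numpy as np
        from triadmut.fixtures import random_rigid_motion
        rng = np.random.default_rng(3)
        target = random_rigid_motion(strip_pair_to_alanine(planted_hb, 4, 8), rng)
        target.id = "moved"
        prop = propose_mutations(target, hb_db)[0]
        mutant = graft_sidechains(target, prop, hb_db)
        # rigid invariant: the grafted OG keeps the template OG's distances to
        # every corresponding backbone atom (positions differ by the motion)
        tpl_og = planted_hb.get_residue(("A", 4, "")).atoms["OG"].coords
        mut_og = mutant.get_residue(("A", 4, "")).atoms["OG"].coords
        for seq in (3, 4, 5, 8):
            for name in ("N", "CA", "C", "O"):
                ref_t = planted_hb.get_residue(("A", seq, "")).atoms[name].coords
                ref_m = target.get_residue(("A", seq, "")).atoms[name].coords
                assert np.linalg.norm(mut_og - ref_m) == pytest.approx(
                    np.linalg.norm(tpl_og - ref_t), abs=1e-6)

    def test_proposal_applied_to_mismatching_structure_raises_provenance(
            self, recovery_pair, hb_db):
        template, target = recovery_pair
        prop = propose_mutations(target, hb_db)[0]
        # the template structure has SER/THR at the sites, not the proposal's
        # recorded ALA wild identities
        with pytest.raises(ProvenanceError):
            graft_sidechains(template, prop, hb_db)


class TestClash:
    @pytest.fixture
    def mutant_and_prop(self, recovery_pair, hb_db):
        _, target = recovery_pair
        prop = propose_mutations(target, hb_db)[0]
        return graft_sidechains(target, prop, hb_db), prop

    def test_own_residue_atoms_never_clash(self, mutant_and_prop):
        mutant, prop = mutant_and_prop
        res = mutant.get_residue(prop.site_a)
        # move the inserted OG on top of its own CA: still no self-clash pair
        res.atoms["OG"].coords = res.atoms["CA"].coords + np.array([1.0, 0, 0])
        report = detect_clash(mutant, prop, cutoff=2.0)
        assert not any(a[0] in (prop.site_a, prop.site_b)
                       and b[0] in (prop.site_a, prop.site_b)
                       for a, b, _ in report.pairs)

    def test_inserted_atom_near_neighbourhood_flags_clash(self, mutant_and_prop):
        mutant, prop = mutant_and_prop
        og = mutant.get_residue(prop.site_a).atoms["OG"].coords
        far = mutant.get_residue(("A", 14, ""))
        far.atoms["CB"].coords = og + np.array([1.5, 0.0, 0.0])
        report = detect_clash(mutant, prop, cutoff=2.0)
        assert report.clash
        assert any(b == (("A", 14, ""), "CB") for _, b, _ in report.pairs)


class TestLabels:
    @pytest.mark.parametrize("pair,expected", [
        (("ASP", "ARG"), {"negative", "positive"}),
        (("CYS", "CYS"), {"disulfide"}),
        (("SER", "THR"), set()),
        (("TRP", "LYS"), {"aromatic", "positive"}),
        (("HIS", "GLU"), {"positive", "aromatic", "negative"}),
    ])
    def test_fixed_property_table(self, pair, expected):
        assert label_pair(*pair) == frozenset(expected)
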