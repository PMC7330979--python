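"""Triad extraction, clustering, grouping, and database persistence."""

import numpy as np
import pytest

from _helpers import random_triad, union_find_clusters
from triadmut.errors import DatabaseError
from triadmut.fixtures import FixtureSpec, make_fixture
from triadmut.interactions import Interaction, detect_sidechain_interactions
from triadmut.structure import write_structure
from triadmut.triads import (TriadDatabase, build_database, cluster_triads,
                             enumerate_categories, enumerate_groups,
                             extract_triad_pairs, load_database, save_database,
                             single_linkage_clusters, triad_distance_matrix)


def _interaction(s, seq_a, seq_b, kind="hydrogen_bond", atoms=("OG", "OG1")):
    ra, rb = s.get_residue(("A", seq_a, "")), s.get_residue(("A", seq_b, ""))
    return Interaction(kind=kind, res_a=ra.key, res_b=rb.key,
                       res_name_a=ra.res_name, res_name_b=rb.res_name,
                       atom_a=atoms[0], atom_b=atoms[1], distance=3.0)


class TestExtraction:
    def test_triads_span_flanking_residues(self):
        s = make_fixture(FixtureSpec(n_residues=60, seed=2))
        triads = extract_triad_pairs(s, [_interaction(s, 2, 50)])
        assert len(triads) == 1
        seqs = [k[1] for k in triads[0].keys]
        assert seqs == [1, 2, 3, 49, 50, 51]
        assert triads[0].backbone_coords.shape == (24, 3)

    def test_chain_terminal_interaction_skipped(self):
        s = make_fixture(FixtureSpec(n_residues=20, seed=2))
        assert extract_triad_pairs(s, [_interaction(s, 1, 10)]) == []

    def test_missing_backbone_atom_skips_triad(self):
        s = make_fixture(FixtureSpec(n_residues=60, seed=2))
        del s.get_residue(("A", 49, "")).atoms["O"]
        assert extract_triad_pairs(s, [_interaction(s, 2, 50)]) == []

    def test_overlapping_triads_skipped(self):
        s = make_fixture(FixtureSpec(n_residues=20, seed=2))
        assert extract_triad_pairs(s, [_interaction(s, 5, 7)]) == []


class TestClustering:
    def test_transitive_chain_merges_into_one_cluster(self):
        # rmsd(A,B)=0.3, rmsd(B,C)=0.3, rmsd(A,C)=0.6: single linkage at 0.5
        # joins all three (brute-force oracle on the 3x3 matrix agrees)
        d = np.array([[0.0, 0.3, 0.6], [0.3, 0.0, 0.3], [0.6, 0.3, 0.0]])
        assert single_linkage_clusters(d, 0.5) == [[0, 1, 2]]
        assert union_find_clusters(d, 0.5) == [[0, 1, 2]]

    def test_identical_triads_cluster_with_first_source_as_representative(self, rng):
        base = random_triad(rng, "bbb")
        twin = random_triad(rng, "aaa", base=base.backbone_coords, noise=0.0)
        clusters, reps = cluster_triads([base, twin], cutoff=0.5)
        assert len(clusters) == 1 and len(reps) == 1
        assert reps[0].source_id == "aaa:A"
        assert reps[0].cluster_size == 2

    def test_distant_triads_stay_singletons(self, rng):
        a, b = random_triad(rng, "a"), random_triad(rng, "b")
        assert triad_rmsd_between(a, b) > 0.5
        clusters, reps = cluster_triads([a, b], cutoff=0.5)
        assert len(clusters) == 2
        assert all(r.cluster_size == 1 for r in reps)

    def test_matches_union_find_oracle_on_random_sets(self, rng):
        for _ in range(20):
            base = random_triad(rng, "base")
            triads = [random_triad(rng, f"t{i:02d}", base=base.backbone_coords,
                                   noise=rng.uniform(0, 0.6)) for i in range(8)]
            cutoff = float(rng.uniform(0.2, 0.8))
            triads_sorted = sorted(triads, key=lambda t: (t.source_id, t.keys))
            d = triad_distance_matrix(triads_sorted)
            expected = union_find_clusters(d, cutoff)
            clusters, _ = cluster_triads(triads, cutoff)
            got = [[triads_sorted.index(t) for t in c] for c in clusters]
            assert sorted(map(sorted, got)) == sorted(map(sorted, expected))

    def test_raising_cutoff_never_increases_cluster_count(self, rng):
        base = random_triad(rng, "base")
        triads = [random_triad(rng, f"t{i:02d}", base=base.backbone_coords,
                               noise=rng.uniform(0, 0.5)) for i in range(10)]
        counts = [len(cluster_triads(triads, c)[0]) for c in (0.1, 0.3, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_every_triad_in_exactly_one_cluster(self, rng):
        base = random_triad(rng, "base")
        triads = [random_triad(rng, f"t{i:02d}", base=base.backbone_coords,
                               noise=rng.uniform(0, 0.5)) for i in range(9)]
        clusters, reps = cluster_triads(triads, 0.4)
        members = [t.rep_id for c in clusters for t in c]
        assert sorted(members) == sorted(t.rep_id for t in triads)
        assert len(reps) <= len(triads)


def triad_rmsd_between(a, b):
    from triadmut.superpose import triad_rmsd
    return triad_rmsd(a, b)[0]


class TestDatabase:
    def test_category_enumeration(self):
        cats = enumerate_categories()
        assert len(cats) == len(set(cats)) == 122
        assert "CYS-CYS" in cats
        assert len(enumerate_groups()) == 12

    def test_planted_disulfide_lands_in_cys_group(self, tmp_path, planted_disulfide):
        p = tmp_path / "ss.pdb"
        write_structure(planted_disulfide, p)
        db = build_database([p])
        assert len(db) == 1
        assert db.representatives[0].group == "CYS"
        assert db.representatives[0].category == "CYS-CYS"
        assert db.group_counts()["CYS"] == 1

    def test_planted_ser_thr_hb_lands_in_ser_group(self, tmp_path, planted_hb):
        p = tmp_path / "hb.pdb"
        write_structure(planted_hb, p)
        db = build_database([p])
        assert len(db) == 1
        rep = db.representatives[0]
        assert rep.group == "SER"
        assert rep.category == "SER-THR"

    def test_input_order_does_not_change_index(self, tmp_path, planted_hb, planted_disulfide):
        pa, pb = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_structure(planted_hb, pa)
        write_structure(planted_disulfide, pb)
        idx1 = build_database([pa, pb]).index()
        idx2 = build_database([pb, pa]).index()
        assert idx1.equals(idx2)

    def test_save_load_roundtrip(self, tmp_path, planted_hb, planted_disulfide):
        pa, pb = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_structure(planted_hb, pa)
        write_structure(planted_disulfide, pb)
        db = build_database([pa, pb])
        from triadmut.signatures import fit_database_signatures
        fit_database_signatures(db)
        out = tmp_path / "db"
        save_database(db, out)
        back = load_database(out)
        assert back.index().equals(db.index())
        for t0, t1 in zip(db.representatives, back.representatives):
            assert np.allclose(t0.backbone_coords, t1.backbone_coords, atol=1.1e-3)
            assert {a.name for a in t0.sidechain_atoms} == {a.name for a in t1.sidechain_atoms}
        assert np.array_equal(back.signature_matrix, db.signature_matrix)
        assert back.svd_model.k == db.svd_model.k

    def test_missing_fragment_file_is_named_in_error(self, tmp_path, planted_hb):
        p = tmp_path / "a.pdb"
        write_structure(planted_hb, p)
        db = build_database([p])
        out = tmp_path / "db"
        save_database(db, out)
        victim = next((out / "fragments").glob("*.pdb"))
        victim.unlink()
        with pytest.raises(DatabaseError, match=victim.name):
            load_database(out)

    def test_empty_database_roundtrip(self, tmp_path, helix10):
        p = tmp_path / "plain.pdb"
        write_structure(helix10, p)  # all-alanine: no interactions
        db = build_database([p])
        assert len(db) == 0
        out = tmp_path / "db"
        save_database(db, out)
        assert len(load_database(out)) == 0

    def test_fragment_roundtrip_preserves_detectability(self, tmp_path, planted_hb):
        p = tmp_path / "a.pdb"
        write_structure(planted_hb, p)
        db = build_database([p])
        out = tmp_path / "db"
        save_database(db, out)
        from triadmut.structure import read_structure
        frag = read_structure(next((out / "fragments").glob("*.pdb")))
        kinds = [i.kind for i in detect_sidechain_interactions(frag)]
        assert kinds == ["hydrogen_bond"]
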