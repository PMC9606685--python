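"""PDB CA I/O, column mapping, contact networks, Kabsch RMSD, classical MDS."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phylowave.structmap import (
    ColumnResidueMap,
    StructureModel,
    StructureResidue,
    classical_mds,
    compare_conformations,
    kabsch_rmsd,
    map_columns,
    mds_map,
    neighbor_network,
    read_pdb_ca,
    write_pdb_ca,
)
from phylowave.synthetic import StructureSpec, generate_structures, make_morphs

from helpers import rmsd_minimization_oracle


def _model(coords, model_id="m", aa="A"):
    residues = [
        StructureResidue(number=i + 1, aa=aa, xyz=tuple(c))
        for i, c in enumerate(coords)
    ]
    return StructureModel(model_id=model_id, residues=residues)


def _rigid(coords, rng):
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(scale=10.0, size=3)
    return coords @ rot.T + shift


class TestPdbIO:
    def test_minimal_file_in_order(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C\n"
            "ATOM      3  CA  ARG A   3       7.000   8.000   9.000  1.00  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "mini.pdb"
        p.write_text(text)
        model = read_pdb_ca(p)
        assert model.sequence == "AGR"
        assert np.allclose(model.coords, [[1, 2, 3], [4, 5, 6], [7, 8, 9]])

    def test_roundtrip_three_decimals(self, tmp_path, rng):
        coords = rng.normal(scale=20.0, size=(10, 3))
        model = _model(coords, "rt")
        p = tmp_path / "rt.pdb"
        write_pdb_ca(model, p)
        back = read_pdb_ca(p)
        assert np.allclose(back.coords, np.round(coords, 3), atol=5e-4)

    def test_hetatm_only_is_an_error(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(
            "HETATM    1  CA  CA  A   1       1.000   2.000   3.000  1.00  0.00          CA\n"
            "END\n"
        )
        with pytest.raises(ValueError, match="no CA atoms|no chains"):
            read_pdb_ca(p)


class TestMapColumns:
    def test_identity_map_for_ungapped_rows(self):
        model = _model(np.zeros((4, 3)), aa="A")
        cmap = map_columns("AAAA", "AAAA", model)
        assert cmap.mapping == {1: 0, 2: 1, 3: 2, 4: 3}
        assert cmap.mismatches == []

    def test_query_gap_unmapped(self):
        model = _model(np.zeros((3, 3)), aa="A")
        cmap = map_columns("A-AA", "AAA-", model)
        assert 2 not in cmap.mapping
        assert cmap.mapping == {1: 0, 3: 2}

    def test_random_gapped_pair_matches_coordinate_walk(self, rng):
        n = 30
        q = rng.choice(list("ACDE-"), size=n)
        t = rng.choice(list("ACDE-"), size=n)
        n_struct = int((t != "-").sum())
        if n_struct == 0:
            t[0] = "A"
            n_struct = 1
        model = _model(np.zeros((n_struct, 3)), aa="A")
        cmap = map_columns("".join(q), "".join(t), model)
        expected = {}
        walk = -1
        for col0 in range(n):
            if t[col0] != "-":
                walk += 1
            if q[col0] != "-" and t[col0] != "-":
                expected[col0 + 1] = walk
        assert cmap.mapping == expected

    def test_injective(self, rng):
        model = _model(np.zeros((5, 3)), aa="A")
        cmap = map_columns("AA-AA-A", "A-AAA-A", model)
        vals = list(cmap.mapping.values())
        assert len(vals) == len(set(vals))


class TestNeighborNetwork:
    def test_close_pair_edge(self):
        model = _model([[0, 0, 0], [5, 0, 0], [50, 0, 0]])
        cmap = ColumnResidueMap(mapping={10: 0, 20: 1, 30: 2})
        net = neighbor_network(model, cmap, [10, 20, 30], cutoff=10.0)
        assert set(net.graph.edges) == {(10, 20)}

    def test_zero_cutoff_no_edges(self):
        model = _model([[0, 0, 0], [5, 0, 0], [8, 0, 0]])
        cmap = ColumnResidueMap(mapping={1: 0, 2: 1, 3: 2})
        net = neighbor_network(model, cmap, [1, 2, 3], cutoff=0.0)
        assert net.graph.number_of_edges() == 0

    def test_unmapped_sites_listed(self):
        model = _model([[0, 0, 0], [5, 0, 0]])
        cmap = ColumnResidueMap(mapping={1: 0, 2: 1})
        net = neighbor_network(model, cmap, [1, 2, 99], cutoff=10.0)
        assert net.unmapped == (99,)

    def test_invariant_under_rigid_motion(self, rng):
        coords = rng.normal(scale=8.0, size=(12, 3))
        cmap = ColumnResidueMap(mapping={i + 1: i for i in range(12)})
        sites = list(range(1, 13))
        net1 = neighbor_network(_model(coords), cmap, sites, cutoff=9.0)
        net2 = neighbor_network(_model(_rigid(coords, rng)), cmap, sites, cutoff=9.0)
        assert set(net1.graph.edges) == set(net2.graph.edges)

    def test_planted_clusters_recovered_as_components(self):
        import networkx as nx

        model_a, _, cmap, truth = generate_structures(StructureSpec(), seed=4)
        net = neighbor_network(model_a, cmap, sorted(cmap.mapping), cutoff=10.0)
        got = sorted(tuple(sorted(c)) for c in nx.connected_components(net.graph))
        planted: dict[int, list[int]] = {}
        for col, cid in truth.structure_clusters.items():
            planted.setdefault(cid, []).append(col)
        assert got == sorted(tuple(sorted(v)) for v in planted.values())


class TestCompareConformations:
    def test_identical_structures_nothing_flagged(self, rng):
        coords = rng.normal(scale=8.0, size=(10, 3))
        cmap = ColumnResidueMap(mapping={i + 1: i for i in range(10)})
        sites = list(range(1, 11))
        net = neighbor_network(_model(coords), cmap, sites, cutoff=9.0)
        report = compare_conformations(net, net)
        assert all(not r.rearranged for r in report)
        assert all(r.jaccard == 1.0 for r in report)

    def test_symmetric_flagging(self, rng):
        c1 = rng.normal(scale=8.0, size=(10, 3))
        c2 = c1 + rng.normal(scale=3.0, size=(10, 3))
        cmap = ColumnResidueMap(mapping={i + 1: i for i in range(10)})
        sites = list(range(1, 11))
        na = neighbor_network(_model(c1), cmap, sites, cutoff=9.0)
        nb = neighbor_network(_model(c2), cmap, sites, cutoff=9.0)
        ab = compare_conformations(na, nb)
        ba = compare_conformations(nb, na)
        assert [r.column for r in ab if r.rearranged] == [
            r.column for r in ba if r.rearranged
        ]
        for x, y in zip(ab, ba):
            assert x.neighbors_a == y.neighbors_b and x.neighbors_b == y.neighbors_a

    def test_moved_helix_flags_only_adjacent_sites(self):
        """With clusters on three tightly packed helices and one helix
        rotated away, rearranged sites lie on or adjacent to the moved helix."""
        spec = StructureSpec(
            n_helices=3,
            spacing=9.0,
            clusters=((0, 5, 5), (1, 5, 5), (2, 5, 5)),
            moved_helices=(2,),
            rotation_deg=60.0,
        )
        model_a, model_b, cmap, _ = generate_structures(spec, seed=8)
        sites = sorted(cmap.mapping)
        na = neighbor_network(model_a, cmap, sites, cutoff=10.0)
        nb = neighbor_network(model_b, cmap, sites, cutoff=10.0)
        flagged = {r.column for r in compare_conformations(na, nb) if r.rearranged}
        assert flagged  # the rotation does rearrange something
        helix_of = {col: cmap.mapping[col] // spec.helix_length for col in sites}
        # moved helix 2, adjacent helix 1
        assert all(helix_of[c] in (1, 2) for c in flagged)


class TestKabschRmsd:
    def test_self_zero(self, rng):
        x = rng.normal(size=(20, 3))
        assert kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_self_zero_large_scale(self, rng):
        x = rng.normal(scale=100.0, size=(200, 3))
        assert kabsch_rmsd(x, x) <= 1e-9

    def test_rigid_motion_zero(self, rng):
        x = rng.normal(scale=10.0, size=(25, 3))
        assert kabsch_rmsd(x, _rigid(x, rng)) <= 1e-9

    def test_symmetric_and_rigid_invariant(self, rng):
        x = rng.normal(scale=5.0, size=(15, 3))
        y = rng.normal(scale=5.0, size=(15, 3))
        assert kabsch_rmsd(x, y) == pytest.approx(kabsch_rmsd(y, x), abs=1e-9)
        assert kabsch_rmsd(_rigid(x, rng), y) == pytest.approx(
            kabsch_rmsd(x, y), abs=1e-9
        )

    def test_matches_numerical_minimization_oracle(self, rng):
        for _ in range(3):
            x = rng.normal(scale=10.0, size=(50, 3))
            y = x + rng.normal(scale=2.0, size=(50, 3))
            assert kabsch_rmsd(x, y) == pytest.approx(
                rmsd_minimization_oracle(x, y), abs=1e-6
            )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestClassicalMds:
    def test_rank_two_euclidean_matrix_reproduced(self, rng):
        pts = rng.normal(scale=4.0, size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, eigvals = classical_mds(d, k=2)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.max(np.abs(d2 - d)) < 1e-6

    def test_euclidean_eigenvalues_nonnegative(self, rng):
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        _, eigvals = classical_mds(d, k=2)
        assert eigvals.min() >= -1e-8

    def test_agrees_with_pcoa_cross_check(self, rng):
        """Embedded 2D distances match scikit-bio's principal coordinate
        analysis of the same matrix."""
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(scale=3.0, size=(7, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ours, _ = classical_mds(d, k=2)
        res = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d), number_of_dimensions=2
        )
        theirs = res.samples.values[:, :2]
        d_ours = np.linalg.norm(ours[:, None] - ours[None, :], axis=2)
        d_theirs = np.linalg.norm(theirs[:, None] - theirs[None, :], axis=2)
        assert np.allclose(d_ours, d_theirs, atol=1e-8)


class TestMdsMap:
    def _conformers(self, seed=1, n_morphs=6):
        model_a, model_b, _, _ = generate_structures(StructureSpec(), seed)
        return make_morphs(model_a, model_b, n_morphs)

    def test_reference_model_labels_itself(self):
        models = self._conformers()
        emb = mds_map(models, ["confA", "confB"])
        assert emb.nearest_reference["confA"] == ("confA", 0.0)
        assert emb.nearest_reference["confB"] == ("confB", 0.0)

    def test_morph_series_orders_monotonically_along_pc1(self):
        models = self._conformers()
        emb = mds_map(models, ["confA", "confB"])
        pc1 = emb.coords[:, 0]
        diffs = np.diff(pc1)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_nearest_reference_uses_full_distance_matrix(self):
        models = self._conformers(n_morphs=5)
        emb = mds_map(models, ["confA", "confB"])
        labels = [emb.nearest_reference[i][0] for i in emb.ids]
        # first half labelled A, second half B (odd count -> clean split)
        assert labels == ["confA"] * 4 + ["confB"] * 3 or \
            labels == ["confA"] * 3 + ["confB"] * 4

    def test_too_few_models_rejected(self):
        models = self._conformers(n_morphs=0)
        with pytest.raises(ValueError):
            mds_map({k: models[k] for k in list(models)[:2]}, ["confA"])
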