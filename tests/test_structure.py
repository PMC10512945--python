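"""SASA, exposure classification, masking neighbors, ideal-helix builder."""

import numpy as np
import pytest

from lpfoot.structure import (
    Atom,
    Residue,
    StructureModel,
    VDW_RADII,
    build_ideal_helix,
    classify_exposure,
    compute_sasa,
    find_masking_neighbors,
    read_structure,
    relative_sasa,
    residue_context,
    sphere_points,
)
from lpfoot.structure import ConfigurationError


def single_atom_residue(position, name="GLY", coord=(0.0, 0.0, 0.0), element="C"):
    return Residue(position=position, name=name, atoms=[Atom("CA", element, coord)])


def naive_sasa(structure, probe=1.4, n_points=960):
    """Brute-force point-rejection oracle: plain double loop, no spatial index."""
    atoms = [
        (np.array(a.coord), VDW_RADII[a.element.upper()] + probe, res.position)
        for res in structure.residues
        for a in res.atoms
    ]
    unit = sphere_points(n_points)
    per_residue = {res.position: 0.0 for res in structure.residues}
    for i, (ci, ri, pos) in enumerate(atoms):
        pts = ci + ri * unit
        accessible = np.ones(n_points, dtype=bool)
        for j, (cj, rj, _) in enumerate(atoms):
            if i != j:
                accessible &= np.sum((pts - cj) ** 2, axis=1) > rj**2
        per_residue[pos] += 4 * np.pi * ri**2 * accessible.mean()
    return per_residue


class TestComputeSasa:
    def test_isolated_residue_full_sphere(self):
        model = StructureModel([single_atom_residue(1)])
        sasa = compute_sasa(model)[1]
        assert sasa == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2)

    def test_distant_residues_unoccluded(self):
        model = StructureModel(
            [single_atom_residue(1), single_atom_residue(2, coord=(100.0, 0, 0))]
        )
        sasa = compute_sasa(model)
        assert sasa[1] == pytest.approx(sasa[2])
        assert sasa[1] == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2)

    def test_helix_matches_brute_force_oracle(self):
        helix = build_ideal_helix("ACDEFGHIKL")
        mine = compute_sasa(helix, 1.4, 960)
        oracle = naive_sasa(helix, 1.4, 960)
        for pos in mine:
            assert mine[pos] == pytest.approx(oracle[pos], rel=0.01)

    def test_cross_check_against_biotite(self):
        """Independent SASA engine, matched per-atom radii."""
        import biotite.structure as bst

        helix = build_ideal_helix("ACDEFGHIKLMNPQRSTVWY")
        coords, owner = [], []
        for res in helix.residues:
            for a in res.atoms:
                coords.append(a.coord)
                owner.append(res.position)
        arr = bst.AtomArray(len(coords))
        arr.coord = np.array(coords, dtype=np.float32)
        arr.chain_id[:] = "A"
        arr.res_id = np.array(owner)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        ref = bst.sasa(arr, probe_radius=1.4, point_number=2000,
                       vdw_radii=np.full(len(coords), 1.70))
        expected = {p: float(ref[arr.res_id == p].sum()) for p in set(owner)}
        mine = compute_sasa(helix, 1.4, 2000)
        for pos, value in mine.items():
            assert value == pytest.approx(expected[pos], rel=0.02)

    def test_occlusion_never_increases_sasa(self):
        lone = StructureModel([single_atom_residue(1)])
        crowded = StructureModel(
            [single_atom_residue(1), single_atom_residue(10, coord=(3.0, 0, 0))]
        )
        assert compute_sasa(crowded)[1] <= compute_sasa(lone)[1]
        assert all(v >= 0 for v in compute_sasa(crowded).values())

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            compute_sasa(StructureModel([]))


class TestExposure:
    def test_threshold_classes(self):
        assert classify_exposure(0.9) == "surface-exposed"
        assert classify_exposure(0.0) == "buried"
        assert classify_exposure(0.25) == "surface-exposed"  # boundary inclusive

    def test_monotone_in_threshold(self):
        helix = build_ideal_helix("ACDEFGHIKLMNQRSTVWYA")
        sasa = compute_sasa(helix)
        rels = {
            res.position: relative_sasa(sasa[res.position], res.one_letter)
            for res in helix.residues
        }
        exposed_counts = [
            sum(classify_exposure(r, t) == "surface-exposed" for r in rels.values())
            for t in (0.1, 0.25, 0.5, 0.9)
        ]
        assert exposed_counts == sorted(exposed_counts, reverse=True)

    def test_unknown_residue_type(self):
        with pytest.raises(ConfigurationError):
            relative_sasa(50.0, "X")


class TestMaskingNeighbors:
    def test_direct_construction(self):
        model = StructureModel(
            [single_atom_residue(10), single_atom_residue(100, coord=(4.0, 0, 0))]
        )
        contacts = find_masking_neighbors(model, 10, distance_cutoff=5.0)
        assert [(c.position, c.min_distance) for c in contacts] == [(100, 4.0)]
        assert find_masking_neighbors(model, 10, distance_cutoff=3.0) == []

    def test_sequence_exclusion(self):
        model = StructureModel(
            [single_atom_residue(10), single_atom_residue(12, coord=(3.0, 0, 0))]
        )
        assert find_masking_neighbors(model, 10, sequence_exclusion=4) == []
        assert len(find_masking_neighbors(model, 10, sequence_exclusion=1)) == 1

    def test_missing_position(self):
        model = StructureModel([single_atom_residue(1)])
        with pytest.raises(KeyError):
            find_masking_neighbors(model, 99)

    def test_matches_all_pairs_brute_force(self, rng):
        residues = [
            single_atom_residue(i + 1, coord=tuple(rng.uniform(0, 15, 3)))
            for i in range(30)
        ]
        model = StructureModel(residues)
        cutoff, excl = 6.0, 4
        for pos in (1, 15, 30):
            got = {c.position for c in
                   find_masking_neighbors(model, pos, cutoff, excl)}
            expected = set()
            for other in residues:
                if abs(other.position - pos) <= excl:
                    continue
                d = np.linalg.norm(
                    np.array(other.atoms[0].coord)
                    - np.array(model.residue_at(pos).atoms[0].coord)
                )
                if d <= cutoff:
                    expected.add(other.position)
            assert got == expected

    def test_symmetry(self, rng):
        residues = [
            single_atom_residue(i + 1, coord=tuple(rng.uniform(0, 12, 3)))
            for i in range(20)
        ]
        model = StructureModel(residues)
        for i in range(1, 21):
            for c in find_masking_neighbors(model, i, 6.0, 2):
                back = {n.position for n in find_masking_neighbors(model, c.position, 6.0, 2)}
                assert i in back


class TestIdealHelix:
    def test_rise_per_residue(self):
        helix = build_ideal_helix("A" * 12, rise=1.5)
        z = [res.atoms[0].coord[2] for res in helix.residues]
        assert np.allclose(np.diff(z), 1.5)

    def test_periodicity_18_residues(self):
        helix = build_ideal_helix("A" * 20, twist=100.0)
        c0 = np.array(helix.residues[0].atoms[0].coord[:2])
        c18 = np.array(helix.residues[18].atoms[0].coord[:2])
        assert np.allclose(c0, c18, atol=1e-9)  # 1800 deg = 0 mod 360

    def test_constant_ca_ca_distance(self):
        helix = build_ideal_helix("A" * 15)
        coords = np.array([res.atoms[0].coord for res in helix.residues])
        dists = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        assert np.allclose(dists, dists[0])

    def test_glycine_has_no_cb(self):
        helix = build_ideal_helix("AGA")
        assert [len(r.atoms) for r in helix.residues] == [2, 1, 2]


class TestStructureIO:
    def test_pdb_round_trip(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        lines = []
        for i, (aa, x) in enumerate([("ALA", 0.0), ("GLY", 3.8), ("LYS", 7.6)], 1):
            lines.append(
                f"ATOM  {i:5d}  CA  {aa} A{i:4d}    {x:8.3f}{0.0:8.3f}{0.0:8.3f}"
                f"  1.00  0.00           C"
            )
        pdb.write_text("\n".join(lines) + "\nEND\n")
        model = read_structure(pdb)
        assert model.positions == [1, 2, 3]
        assert [r.name for r in model.residues] == ["ALA", "GLY", "LYS"]

    def test_validate_against_sequence(self):
        from lpfoot.proteins import ProteinRecord

        model = StructureModel([single_atom_residue(1, name="ALA"),
                                single_atom_residue(2, name="GLY")])
        assert model.validate_against(ProteinRecord("x", "AG")) == []
        issues = model.validate_against(ProteinRecord("x", "AC"))
        assert len(issues) == 1 and "residue 2" in issues[0]
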