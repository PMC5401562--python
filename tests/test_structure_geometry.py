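"""Helix-axis fitting, C3 axis, tilt angles, pore classification, contacts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from tricchan import (
    classify_pore_profile,
    coordination_contacts,
    fit_helix_axis,
    read_structure,
    tilt_angle,
    tilt_table,
    trimer_c3_axis,
)
from tricchan.structure_geometry import StructureModel

from conftest import ideal_helix, make_trimer, rotation_about_x


class TestFitHelixAxis:
    def test_ideal_helix_axis_is_z(self):
        axis, centroid = fit_helix_axis(ideal_helix(20))
        assert tilt_angle(axis, [0, 0, 1]) < 1.0
        np.testing.assert_allclose(centroid[2], 1.5 * 19 / 2, atol=1e-9)

    def test_rotated_helix_recovers_tilt(self):
        coords = ideal_helix(20) @ rotation_about_x(30.0).T
        axis, _ = fit_helix_axis(coords)
        assert tilt_angle(axis, [0, 0, 1]) == pytest.approx(30.0, abs=1.0)

    def test_invariant_to_residue_order_reversal(self):
        coords = ideal_helix(18) @ rotation_about_x(40.0).T
        a1, _ = fit_helix_axis(coords)
        a2, _ = fit_helix_axis(coords[::-1])
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_helix_axis(np.array([[0.0, 0, 0], [1, 0, 0]]))

    def test_sign_normalized_along_reference(self):
        axis, _ = fit_helix_axis(ideal_helix(20), reference_axis=(0, 0, -1))
        assert axis[2] < 0


class TestTrimerC3Axis:
    def test_constructed_trimer_axis_is_z(self):
        axis, point = trimer_c3_axis(make_trimer())
        assert tilt_angle(axis, [0, 0, 1]) < 1e-6
        # the joint centroid of an exact C3 trimer lies on the z axis
        np.testing.assert_allclose(point[:2], [0.0, 0.0], atol=1e-9)

    def test_equivariance_under_rigid_rotation(self):
        trimer = make_trimer()
        rot = Rotation.from_rotvec([0.4, -0.3, 0.8])
        rotated = StructureModel(
            atoms=trimer.atoms.assign(
                **dict(zip("xyz", rot.apply(trimer.coords()).T))
            ),
            source_id="rotated",
        )
        axis, _ = trimer_c3_axis(rotated)
        expected = rot.apply([0.0, 0.0, 1.0])
        assert tilt_angle(axis, expected) < 1e-6

    def test_jittered_trimer_axis_within_1_degree(self):
        axis, _ = trimer_c3_axis(make_trimer(jitter_sd=0.2, seed=3))
        assert tilt_angle(axis, [0, 0, 1]) < 1.0

    def test_insufficient_matched_residues_rejected(self):
        with pytest.raises(ValueError):
            trimer_c3_axis(make_trimer(n_res=20))

    def test_wrong_chain_count_rejected(self):
        with pytest.raises(ValueError):
            trimer_c3_axis(make_trimer(), chains=("A", "B"))


class TestTiltAngle:
    def test_parallel_is_zero(self):
        assert tilt_angle([0, 0, 1], [0, 0, 1]) == pytest.approx(0.0)

    def test_orthogonal_is_ninety(self):
        assert tilt_angle([1, 0, 0], [0, 0, 1]) == pytest.approx(90.0)

    def test_antiparallel_folds_to_zero(self):
        assert tilt_angle([0, 0, -1], [0, 0, 1]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            tilt_angle([0, 0, 0], [0, 0, 1])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(min_value=0.0, max_value=90.0))
    def test_invariant_under_global_rotation(self, seed, angle):
        a = np.array([0.0, 0.0, 1.0])
        b = rotation_about_x(angle) @ a
        rot = Rotation.random(rng=np.random.default_rng(seed))
        assert tilt_angle(rot.apply(a), rot.apply(b)) == pytest.approx(
            tilt_angle(a, b), abs=1e-6
        )


class TestTiltTable:
    def test_known_span_tilts(self):
        trimer = make_trimer()
        table = tilt_table(trimer, [("M1", "A", 1, 20), ("M1", "B", 1, 20)])
        # the protomer helix was tilted 25 degrees off the C3 axis
        np.testing.assert_allclose(table["eta_deg"], 25.0, atol=1.0)
        assert list(table.columns) == ["helix", "chain", "first", "last", "eta_deg"]


class TestClassifyPoreProfile:
    def _profile(self, radii):
        return pd.DataFrame({"z_A": np.arange(len(radii), dtype=float), "radius_A": radii})

    def test_all_wide_no_constrictions(self):
        labeled, cons = classify_pore_profile(self._profile([3.0, 3.0, 3.0]))
        assert (labeled["class"] == "wide").all()
        assert len(cons) == 0

    def test_two_constriction_runs(self):
        labeled, cons = classify_pore_profile(self._profile([3.0, 1.0, 3.0, 0.9, 0.8, 3.0]))
        assert len(cons) == 2
        assert cons["min_radius_A"].tolist() == [1.0, 0.8]
        assert cons.iloc[1]["z_at_min_A"] == 4.0

    def test_boundary_values_are_intermediate(self):
        labeled, _ = classify_pore_profile(self._profile([1.15, 2.30, 1.5]))
        assert (labeled["class"] == "intermediate").all()

    def test_non_monotone_axis_rejected(self):
        bad = pd.DataFrame({"z_A": [0.0, 2.0, 1.0], "radius_A": [3.0, 3.0, 3.0]})
        with pytest.raises(ValueError):
            classify_pore_profile(bad)

    def test_descending_axis_accepted(self):
        prof = pd.DataFrame({"z_A": [5.0, 3.0, 1.0], "radius_A": [3.0, 1.0, 3.0]})
        _, cons = classify_pore_profile(prof)
        assert len(cons) == 1
        assert cons.iloc[0]["z_start_A"] == 3.0


class TestCoordinationContacts:
    def _structure(self, positions):
        rows = [
            ("O", "HOH", i + 1, "A", "O", *xyz) for i, xyz in enumerate(positions)
        ]
        atoms = pd.DataFrame(
            rows,
            columns=["atom_name", "residue_name", "residue_number", "chain_id", "element", "x", "y", "z"],
        )
        return StructureModel(atoms=atoms, source_id="synthetic-contacts")

    def test_single_contact_distance(self):
        st_model = self._structure([[2.7, 0.0, 0.0]])
        out = coordination_contacts(st_model, [0.0, 0.0, 0.0], 3.5)
        assert len(out) == 1
        assert out["distance_A"].iloc[0] == pytest.approx(2.7)

    def test_atom_at_exact_cutoff_included(self):
        st_model = self._structure([[3.5, 0.0, 0.0]])
        out = coordination_contacts(st_model, [0.0, 0.0, 0.0], 3.5)
        assert len(out) == 1

    def test_trigonal_shell_sorted_ascending(self):
        angles = np.radians([0.0, 120.0, 240.0])
        shells = [2.9, 2.7, 2.8]
        pos = [[r * np.cos(a), r * np.sin(a), 0.0] for r, a in zip(shells, angles)]
        out = coordination_contacts(self._structure(pos), [0.0, 0.0, 0.0], 3.5)
        np.testing.assert_allclose(out["distance_A"], [2.7, 2.8, 2.9])

    def test_hydrogens_excluded(self):
        atoms = pd.DataFrame(
            [
                ("O", "HOH", 1, "A", "O", 2.0, 0.0, 0.0),
                ("H1", "HOH", 1, "A", "H", 1.0, 0.0, 0.0),
            ],
            columns=["atom_name", "residue_name", "residue_number", "chain_id", "element", "x", "y", "z"],
        )
        out = coordination_contacts(StructureModel(atoms=atoms), [0, 0, 0], 3.0)
        assert out["atom"].tolist() == ["A/HOH 1/O"]


class TestReadStructure:
    def test_pdb_roundtrip(self, tmp_path):
        """A synthetic trimer written as PDB reads back with intact geometry."""
        import gemmi

        trimer = make_trimer(n_res=60)
        st_g = gemmi.Structure()
        model = gemmi.Model("1")
        for chain_id, chain_df in trimer.atoms.groupby("chain_id"):
            chain = gemmi.Chain(chain_id)
            for _, row in chain_df.iterrows():
                res = gemmi.Residue()
                res.name = row["residue_name"]
                res.seqid = gemmi.SeqId(int(row["residue_number"]), " ")
                atom = gemmi.Atom()
                atom.name = row["atom_name"]
                atom.element = gemmi.Element(row["element"])
                atom.pos = gemmi.Position(row["x"], row["y"], row["z"])
                res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st_g.add_model(model)
        path = tmp_path / "synthetic_trimer.pdb"
        st_g.write_pdb(str(path))

        loaded = read_structure(path)
        assert loaded.chain_ids() == ["A", "B", "C"]
        axis, _ = trimer_c3_axis(loaded)
        assert tilt_angle(axis, [0, 0, 1]) < 0.1
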