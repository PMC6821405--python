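import numpy as np
import pytest

from gt2spec.geometry import rotation_about_y
from gt2spec.io_formats import AtomRecord
from gt2spec.synthetic_data import TrajParams, gen_interaction_traj
from gt2spec.traj_metrics import (
    Selection,
    Trajectory,
    align_to_channel_axis,
    detect_hbond,
    glc_orientation,
    glc_position,
    hbond_occupancy,
    preset_selection,
    resolve_window,
    rmsd_series,
    rmsf_per_residue,
    stacking_contacts,
    stacking_occupancy,
)


def atom(serial, name, resnum, pos, resname="ALA", chain="A", element=None):
    return AtomRecord(
        serial=serial, atom_name=name, residue_name=resname, chain_id=chain,
        residue_number=resnum, element=element or name[0],
        position=np.asarray(pos, float),
    )


def single_frame(atoms):
    return Trajectory(topology=atoms, coords=np.array([[a.position for a in atoms]]))


def random_rigid(rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = rng.uniform(0, 2 * np.pi)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * K @ K
    t = rng.uniform(-20, 20, size=3)
    return R, t


class TestChannelAlignment:
    def test_already_aligned_structure_unchanged(self, clean_trajectory):
        traj, _ = clean_trajectory
        aligned = align_to_channel_axis(traj, ("A", 1, "CA"), ("A", 2, "CA"))
        np.testing.assert_allclose(aligned.coords, traj.coords, atol=1e-9)

    def test_x_axis_anchors_rotated_onto_y(self):
        atoms = [
            atom(1, "CA", 1, [0, 0, 0]),
            atom(2, "CA", 2, [10, 0, 0]),
            atom(3, "CB", 1, [1, 2, 0]),
        ]
        traj = single_frame(atoms)
        aligned = align_to_channel_axis(traj, ("A", 1, "CA"), ("A", 2, "CA"))
        top = aligned.coords[0, 1]
        assert top == pytest.approx([0.0, 10.0, 0.0], abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_rigid_motions_removed(self, seed, clean_trajectory):
        traj, _ = clean_trajectory
        reference = align_to_channel_axis(traj, ("A", 1, "CA"), ("A", 2, "CA"))
        rng = np.random.default_rng(seed)
        moved = traj.coords.copy()
        for f in range(traj.n_frames):
            R, t = random_rigid(rng)
            moved[f] = moved[f] @ R.T + t
        realigned = align_to_channel_axis(
            Trajectory(topology=traj.topology, coords=moved),
            ("A", 1, "CA"), ("A", 2, "CA"),
        )
        np.testing.assert_allclose(realigned.coords, reference.coords, atol=1e-6)

    def test_coincident_anchors_error(self):
        atoms = [atom(1, "CA", 1, [0, 0, 0]), atom(2, "CA", 2, [0, 0, 0]),
                 atom(3, "CB", 1, [1, 0, 0])]
        with pytest.raises(ValueError, match="coincident"):
            align_to_channel_axis(single_frame(atoms), ("A", 1, "CA"), ("A", 2, "CA"))


def hbond_system(d_da, angle_dha):
    """Donor O with one H; acceptor placed to realise the requested
    donor-acceptor distance and donor-H-acceptor angle."""
    donor = np.zeros(3)
    h = np.array([0.96, 0.0, 0.0])
    # place acceptor in the xy plane at the requested geometry
    theta = np.radians(180.0 - angle_dha)  # deviation of H->A from D->H extension
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # solve |donor - (h + r*direction)| = d_da for r > 0
    b = h - donor
    pb = float(np.dot(direction, b))
    r = -pb + np.sqrt(pb**2 - (np.dot(b, b) - d_da**2))
    acceptor = h + r * direction
    atoms = [
        atom(1, "OG", 1, donor, resname="SER"),
        atom(2, "HG", 1, h, resname="SER", element="H"),
        atom(3, "O", 2, acceptor, resname="HOH", chain="W"),
    ]
    return single_frame(atoms)


class TestHbondDetection:
    def test_short_and_linear_is_bonded(self):
        traj = hbond_system(2.9, 165.0)
        res = detect_hbond(traj.topology, traj.coords[0], 0, 2)
        assert res.bonded and res.used_angle
        assert res.angle == pytest.approx(165.0, abs=0.5)

    def test_long_distance_fails_regardless_of_angle(self):
        traj = hbond_system(3.5, 179.0)
        assert not detect_hbond(traj.topology, traj.coords[0], 0, 2).bonded

    def test_bent_geometry_fails_angle_cut(self):
        traj = hbond_system(3.0, 115.0)  # deviation 65 > 60
        assert not detect_hbond(traj.topology, traj.coords[0], 0, 2).bonded

    def test_angle_cut_180_degenerates_to_distance_only(self):
        for d, ang in [(2.0, 95.0), (3.3, 100.0), (3.6, 178.0)]:
            traj = hbond_system(d, ang)
            got = detect_hbond(traj.topology, traj.coords[0], 0, 2, angle_cut=180.0)
            assert got.bonded == (d <= 3.4)

    def test_missing_hydrogen_falls_back_with_warning(self):
        atoms = [atom(1, "OG", 1, [0, 0, 0], resname="SER"),
                 atom(2, "O", 2, [3.0, 0, 0], resname="HOH", chain="W")]
        traj = single_frame(atoms)
        with pytest.warns(UserWarning, match="no bonded hydrogen"):
            res = detect_hbond(traj.topology, traj.coords[0], 0, 1)
        assert res.bonded and not res.used_angle


class TestOccupancies:
    def test_always_bonded_pair_is_100(self):
        traj, truth = gen_interaction_traj(TrajParams(n_frames=50, p_hbond=1.0), seed=1)
        rec = hbond_occupancy(traj, truth.donor, truth.acceptor)
        assert rec.occupancy == 100.0

    def test_never_bonded_pair_is_0(self):
        traj, truth = gen_interaction_traj(TrajParams(n_frames=50, p_hbond=0.0), seed=1)
        assert hbond_occupancy(traj, truth.donor, truth.acceptor).occupancy == 0.0

    def test_hbond_occupancy_matches_planted_states_exactly(self, toy_trajectory):
        traj, truth = toy_trajectory
        rec = hbond_occupancy(traj, truth.donor, truth.acceptor)
        np.testing.assert_array_equal(rec.series, truth.hbond_states)

    def test_stacking_occupancy_matches_planted_states_exactly(self, toy_trajectory):
        traj, truth = toy_trajectory
        rec = stacking_occupancy(traj, truth.phe, truth.stack_glc)
        np.testing.assert_array_equal(rec.series, truth.stack_states)

    def test_window_restricts_frames(self, toy_trajectory):
        traj, truth = toy_trajectory
        rec = hbond_occupancy(traj, truth.donor, truth.acceptor, window=(0, 100))
        assert rec.series.size == 100

    def test_empty_window_is_error(self, toy_trajectory):
        traj, truth = toy_trajectory
        with pytest.raises(ValueError, match="empty"):
            hbond_occupancy(traj, truth.donor, truth.acceptor, window=(100, 100))

    def test_ns_window_uses_frame_times(self, toy_trajectory):
        traj, truth = toy_trajectory
        idx = resolve_window(traj, (10.0, 20.0), ns=True)
        assert idx.size == 100  # 0.1 ns per frame


class TestStacking:
    def test_distant_residues_have_no_contacts(self, clean_trajectory):
        traj, truth = clean_trajectory
        # Trp at the channel centre vs the stacking glucose 20 A away
        assert stacking_contacts(traj, 0, truth.trp, truth.stack_glc) == 0

    def test_parallel_stacked_glucose_exceeds_25_contacts(self, clean_trajectory):
        traj, truth = clean_trajectory
        on_frame = int(np.nonzero(truth.stack_states)[0][0])
        count = stacking_contacts(traj, on_frame, truth.phe, truth.stack_glc)
        assert count > 25

    def test_symmetric_in_argument_order(self, clean_trajectory):
        traj, truth = clean_trajectory
        a = stacking_contacts(traj, 0, truth.phe, truth.stack_glc)
        b = stacking_contacts(traj, 0, truth.stack_glc, truth.phe)
        assert a == b

    def test_non_aromatic_pair_is_error(self, clean_trajectory):
        traj, _ = clean_trajectory
        with pytest.raises(ValueError, match="aromatic"):
            stacking_contacts(traj, 0, ("A", 20), ("S", 1))

    def test_pair_at_exactly_cutoff_not_counted(self):
        atoms = [atom(1, "CG", 1, [0, 0, 0], resname="PHE"),
                 atom(2, "C1", 2, [5.5, 0, 0], resname="BGC", chain="S")]
        traj = single_frame(atoms)
        assert stacking_contacts(traj, 0, ("A", 1), ("S", 2)) == 0

    def test_exactly_25_contacts_is_not_stacking(self):
        # 5 x 5 atoms all within the cutoff: exactly 25 contacts, which
        # the strict > 25 criterion must reject
        aromatic = [atom(i + 1, f"CD{i}", 1, [0.1 * i, 0, 0], resname="PHE")
                    for i in range(5)]
        glc = [atom(i + 6, f"C{i}", 2, [1.0 + 0.1 * i, 0, 0], resname="BGC", chain="S")
               for i in range(5)]
        traj = single_frame(aromatic + glc)
        assert stacking_contacts(traj, 0, ("A", 1), ("S", 2)) == 25
        rec = stacking_occupancy(traj, ("A", 1), ("S", 2))
        assert rec.occupancy == 0.0


class TestOrientationAndPosition:
    def test_planted_orientations_recovered_noiselessly(self, clean_trajectory):
        traj, truth = clean_trajectory
        for j, theta in enumerate(truth.orientations, start=1):
            got = glc_orientation(traj, 0, ("G", j), truth.trp)
            delta = abs((got - theta + 180.0) % 360.0 - 180.0)
            assert delta < 0.5

    def test_quarter_turn_measured_as_90(self, clean_trajectory):
        traj, truth = clean_trajectory
        coords = traj.coords.copy()
        idx = traj.residue_indices(("G", 1))
        center = coords[0, idx].mean(axis=0)
        coords[0, idx] = (coords[0, idx] - center) @ rotation_about_y(90.0).T + center
        rotated = Trajectory(topology=traj.topology, coords=coords)
        base = glc_orientation(traj, 0, ("G", 1), truth.trp)
        got = glc_orientation(rotated, 0, ("G", 1), truth.trp)
        assert (got - base + 360.0) % 360.0 == pytest.approx(90.0, abs=1e-6)

    def test_position_is_y_offset_from_trp_calpha(self, clean_trajectory):
        traj, truth = clean_trajectory
        idx = traj.residue_indices(("G", 1))
        com_y = traj.coords[0, idx, 1].mean()
        ca_y = traj.coords[0, traj.atom_index(("A", 10, "CA")), 1]
        assert glc_position(traj, 0, ("G", 1), truth.trp) == pytest.approx(com_y - ca_y)

    def test_translation_along_axis_shifts_position(self, clean_trajectory):
        traj, truth = clean_trajectory
        coords = traj.coords.copy()
        idx = traj.residue_indices(("G", 1))
        coords[0, idx, 1] += 4.0
        shifted = Trajectory(topology=traj.topology, coords=coords)
        base = glc_position(traj, 0, ("G", 1), truth.trp)
        assert glc_position(shifted, 0, ("G", 1), truth.trp) == pytest.approx(base + 4.0)

    def test_positions_increase_along_the_chain(self, clean_trajectory):
        traj, truth = clean_trajectory
        ys = [
            glc_position(traj, 0, ("G", j), truth.trp)
            for j in range(1, len(truth.orientations) + 1)
        ]
        assert ys == sorted(ys)

    def test_unit_vs_atomic_masses_differ_below_tenth_angstrom(self, clean_trajectory):
        traj, truth = clean_trajectory
        a = glc_position(traj, 0, ("G", 1), truth.trp, use_masses=False)
        b = glc_position(traj, 0, ("G", 1), truth.trp, use_masses=True)
        assert abs(a - b) < 0.1


class TestRmsd:
    def test_reference_against_itself_is_zero(self, clean_trajectory):
        traj, _ = clean_trajectory
        sel = np.arange(len(traj.topology))
        assert rmsd_series(traj, sel)[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_removed_by_fit(self, clean_trajectory, rng):
        traj, _ = clean_trajectory
        coords = traj.coords.copy()
        R, t = random_rigid(rng)
        coords[1] = coords[0] @ R.T + t
        moved = Trajectory(topology=traj.topology, coords=coords)
        series = rmsd_series(moved, np.arange(len(traj.topology)), fit=True)
        assert series[1] == pytest.approx(0.0, abs=1e-6)

    def test_single_displaced_atom_closed_form(self):
        n = 100
        atoms = [atom(i + 1, "CA", i + 1, [float(i), 0, 0]) for i in range(n)]
        base = np.array([[a.position for a in atoms]])
        moved = base.copy()
        moved[0, 0] += [0.0, 1.0, 0.0]
        traj = Trajectory(topology=atoms, coords=np.concatenate([base, moved]))
        series = rmsd_series(traj, np.arange(n), fit=False)
        assert series[1] == pytest.approx(0.1, abs=1e-12)

    def test_fit_needs_three_atoms(self, clean_trajectory):
        traj, _ = clean_trajectory
        with pytest.raises(ValueError, match="3 atoms"):
            rmsd_series(traj, np.array([0, 1]), fit=True)

    def test_selection_presets_resolve(self):
        sel = preset_selection("RsBcsA", "gating_loop")
        atoms = [atom(i + 1, "CA", 500 + i, [0, 0, float(i)]) for i in range(5)]
        assert sel.resolve(atoms).size == 5
        with pytest.raises(KeyError):
            preset_selection("RsBcsA", "nonexistent")

    def test_empty_selection_is_error(self):
        atoms = [atom(1, "CA", 1, [0, 0, 0])]
        with pytest.raises(ValueError, match="no atoms"):
            Selection(residue_ranges=((10, 20),)).resolve(atoms)


class TestRmsf:
    def test_static_trajectory_gives_zero(self):
        # both interactions pinned 'on' and no jitter: frames identical
        traj, _ = gen_interaction_traj(
            TrajParams(n_frames=5, sigma=0.0, p_hbond=1.0, p_stack=1.0), seed=3
        )
        with pytest.warns(UserWarning):
            rmsf = rmsf_per_residue(traj)
        values = [v for v in rmsf.values() if v is not None]
        assert max(values) == pytest.approx(0.0, abs=1e-9)

    def test_residue_without_representative_atom_is_none(self, clean_trajectory):
        traj, _ = clean_trajectory
        with pytest.warns(UserWarning, match="representative"):
            rmsf = rmsf_per_residue(traj)
        assert rmsf[("W", 21)] is None  # water has neither CA nor C1

    def test_jittered_atom_fluctuates_as_sigma_root_three(self, rng):
        # enough static atoms that the superposition fit absorbs only a
        # ~sqrt(1 - 2/N) sliver of the jittered atom's fluctuation
        sigma, n_frames, n_atoms = 0.3, 2000, 50
        atoms = [atom(i + 1, "CA", i + 1, [3.0 * i, float(i % 7), 0.5 * (i % 5)])
                 for i in range(n_atoms)]
        base = np.array([a.position for a in atoms])
        coords = np.repeat(base[None], n_frames, axis=0)
        coords[:, 4, :] += rng.normal(0, sigma, size=(n_frames, 3))
        traj = Trajectory(topology=atoms, coords=coords)
        rmsf = rmsf_per_residue(traj)
        assert rmsf[("A", 5)] == pytest.approx(sigma * np.sqrt(3), rel=0.10)
        others = [v for k, v in rmsf.items() if k != ("A", 5)]
        assert max(others) < 0.05

    def test_rigid_body_motion_only_gives_zero_with_fit(self, rng):
        atoms = [atom(i + 1, "CA", i + 1, [2.0 * i, float(i**2 % 5), 0.0])
                 for i in range(8)]
        base = np.array([a.position for a in atoms])
        coords = np.empty((20, 8, 3))
        for f in range(20):
            R, t = random_rigid(rng)
            coords[f] = base @ R.T + t
        traj = Trajectory(topology=atoms, coords=coords)
        rmsf = rmsf_per_residue(traj, fit=True)
        assert max(rmsf.values()) == pytest.approx(0.0, abs=1e-6)
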