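"""Descriptor correctness: superposition against an independent quaternion
oracle, the B-factor closed form and identity, distance modes against brute
force, and the canonical panel on planted ensembles."""

import numpy as np
import pytest

from kinastate.descriptors import (
    B_CONST,
    DescriptorSeries,
    bfactor_profile,
    contact_occupancy,
    descriptor_panel,
    distance_series,
    rmsd_series,
    superpose,
)
from kinastate.io import Selection, Trajectory, subset_topology
from kinastate.synthetic import GeneratorConfig, simulate_state

from conftest import make_topology


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def horn_rmsd(x, y):
    """Independent superposition oracle: Horn's closed-form quaternion
    method (largest eigenvector of the 4x4 correlation matrix), no SVD."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    s = xc.T @ yc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(xc**2) + np.sum(yc**2) - 2.0 * lam) / len(x)
    return np.sqrt(max(msd, 0.0))


class TestSuperpose:
    def setup_method(self):
        self.rng = np.random.default_rng(7)

    def test_identity(self):
        x = self.rng.normal(size=(10, 3))
        sel = Selection("all", np.arange(10))
        _, rmsd = superpose(x, x, sel)
        assert rmsd < 1e-10

    def test_rigid_motion_removed(self):
        x = self.rng.normal(size=(12, 3))
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        y = x @ rot.T + np.array([5.0, 5.0, 5.0])
        _, rmsd = superpose(y, x, Selection("all", np.arange(12)))
        assert rmsd < 1e-8

    def test_agrees_with_quaternion_oracle(self):
        sel = Selection("all", np.arange(4))
        for _ in range(25):
            x = self.rng.normal(size=(4, 3)) * 3.0
            y = self.rng.normal(size=(4, 3)) * 3.0
            _, rmsd = superpose(x, y, sel)
            assert rmsd == pytest.approx(horn_rmsd(x, y), abs=1e-6)

    def test_proper_rotation(self):
        x = self.rng.normal(size=(6, 3))
        y = x.copy()
        y[:, 0] *= -1  # mirrored target must not induce a reflection
        tf, _ = superpose(x, y, Selection("all", np.arange(6)))
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_underdetermined_rejected(self):
        x = np.zeros((2, 3))
        with pytest.raises(ValueError, match=">= 3"):
            superpose(x, x, Selection("two", np.arange(2)))


class TestRmsdSeries:
    def test_identical_frames_zero(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 8, 3)), (5, 1, 1))
        traj = Trajectory(coords, np.arange(5.0) + 1.0)
        sel = Selection("all", np.arange(8))
        assert np.allclose(rmsd_series(traj, fit_sel=sel).values, 0.0, atol=1e-10)

    def test_single_displaced_atom_alternates(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(9, 3)) * 4.0
        coords = np.tile(base, (6, 1, 1))
        coords[1::2, 8, 0] += 3.0
        traj = Trajectory(coords, np.arange(6.0) + 1.0)
        fit = Selection("fit", np.arange(8))
        calc = Selection("calc", np.array([8]))
        vals = rmsd_series(traj, fit_sel=fit, calc_sel=calc).values
        assert np.allclose(vals[::2], 0.0, atol=1e-9)
        assert np.allclose(vals[1::2], 3.0, atol=1e-9)

    def test_invariant_under_per_frame_rotation(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(4, 10, 3)) * 2.0
        traj = Trajectory(coords, np.arange(4.0) + 1.0)
        sel = Selection("all", np.arange(10))
        ref_vals = rmsd_series(traj, fit_sel=sel).values
        rotated = np.stack([c @ random_rotation(rng).T + rng.normal(size=3)
                            for c in coords])
        rot_vals = rmsd_series(
            Trajectory(rotated, traj.times), reference=coords[0], fit_sel=sel
        ).values
        assert np.allclose(ref_vals, rot_vals, atol=1e-8)


class TestBFactors:
    def test_static_trajectory_zero(self):
        top = make_topology(6)
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 6, 3)),
                         (20, 1, 1))
        prof = bfactor_profile(Trajectory(coords, np.arange(20.0) + 1), top,
                               n_segments=4)
        assert np.allclose(prof.b_full, 0.0, atol=1e-12)
        assert np.allclose(prof.segment_variance, 0.0, atol=1e-12)

    def test_gaussian_jitter_closed_form(self):
        """Isotropic per-axis σ ⇒ B = 8π²σ² (no rigid motion to remove)."""
        rng = np.random.default_rng(3)
        top = make_topology(20)
        base = rng.normal(size=(20, 3)) * 12.0
        sigma = 0.5
        coords = base[None] + rng.normal(scale=sigma, size=(3000, 20, 3))
        prof = bfactor_profile(Trajectory(coords, np.arange(3000.0) + 1), top,
                               prealigned=True)
        expected = 8 * np.pi**2 * sigma**2
        se = expected * np.sqrt(2.0 / (3 * 3000))
        assert np.abs(prof.b_full - expected).max() < 3 * se

    def test_alignment_absorbs_jitter_on_small_systems(self):
        """The fitted path must sit slightly below the closed form — the
        documented 6-degree-of-freedom absorption, not a defect."""
        rng = np.random.default_rng(30)
        top = make_topology(20)
        base = rng.normal(size=(20, 3)) * 12.0
        coords = base[None] + rng.normal(scale=0.5, size=(2000, 20, 3))
        traj = Trajectory(coords, np.arange(2000.0) + 1)
        fitted = bfactor_profile(traj, top).b_full.mean()
        raw = bfactor_profile(traj, top, prealigned=True).b_full.mean()
        assert fitted < raw
        assert fitted > 0.8 * raw

    def test_brute_force_variance_oracle(self):
        """B equals 8π²/3 × summed per-coordinate variances, atom by atom."""
        from kinastate.descriptors import align_to_mean

        rng = np.random.default_rng(4)
        top = make_topology(12)
        coords = rng.normal(size=(50, 12, 3)) * 2.0 + 30.0
        traj = Trajectory(coords, np.arange(50.0) + 1)
        prof = bfactor_profile(traj, top)
        aligned = align_to_mean(coords, np.arange(12), passes=2)
        brute = np.empty(12)
        for a in range(12):
            msd = 0.0
            mean = aligned[:, a, :].mean(axis=0)
            for f in range(50):
                msd += np.sum((aligned[f, a] - mean) ** 2)
            brute[a] = B_CONST * msd / 50
        assert np.abs(prof.b_full - brute).max() < 1e-8

    def test_b_equals_rmsf_identity(self, scaffold, small_panel):
        top, _, _ = scaffold
        prof = bfactor_profile(small_panel["Y0Y0"], top)
        assert np.abs(prof.b_full - B_CONST * prof.rmsf**2).max() < 1e-8

    def test_segment_remainder_goes_last(self):
        top = make_topology(4)
        coords = np.random.default_rng(5).normal(size=(55, 4, 3))
        prof = bfactor_profile(Trajectory(coords, np.arange(55.0) + 1), top,
                               n_segments=10)
        assert prof.b_segments.shape == (4, 10)

    def test_invalid_segment_count(self):
        top = make_topology(4)
        coords = np.random.default_rng(6).normal(size=(12, 4, 3))
        with pytest.raises(ValueError, match="n_segments"):
            bfactor_profile(Trajectory(coords, np.arange(12.0) + 1), top,
                            n_segments=1)

    def test_segment_variance_shrinks_with_longer_segments(self):
        """For a stationary process, fewer/longer segments give smaller
        across-segment B variance on average (3-seed repetition)."""
        top = make_topology(10)
        wins = []
        for seed in (11, 12, 13):
            rng = np.random.default_rng(seed)
            coords = rng.normal(scale=0.5, size=(2000, 10, 3))
            traj = Trajectory(coords, np.arange(2000.0) + 1)
            v_many = bfactor_profile(traj, top, n_segments=20).segment_variance
            v_few = bfactor_profile(traj, top, n_segments=5).segment_variance
            wins.append(v_few.mean() < v_many.mean())
        assert sum(wins) >= 2


class TestDistanceSeries:
    def test_pythagorean_atom_mode(self):
        top = make_topology(2)
        coords = np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]])
        traj = Trajectory(coords, np.array([0.0]))
        d = distance_series(traj, top, Selection("a", np.array([0])),
                            Selection("b", np.array([1])), mode="atom")
        assert d.values[0] == pytest.approx(5.0)

    def test_com_mode(self):
        top = make_topology(3)
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0], [1.0, 4.0, 0]]])
        traj = Trajectory(coords, np.array([0.0]))
        d = distance_series(traj, top, Selection("ab", np.array([0, 1])),
                            Selection("c", np.array([2])), mode="com")
        assert d.values[0] == pytest.approx(4.0)

    def test_min_mode_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        top = make_topology(20)
        coords = rng.normal(size=(3, 20, 3)) * 6.0
        traj = Trajectory(coords, np.arange(3.0) + 1)
        a = Selection("a", np.arange(8))
        b = Selection("b", np.arange(8, 20))
        got = distance_series(traj, top, a, b, mode="min").values
        for f in range(3):
            brute = min(
                np.linalg.norm(coords[f, i] - coords[f, j])
                for i in range(8) for j in range(8, 20)
            )
            assert got[f] == pytest.approx(brute, abs=1e-12)

    def test_min_mode_ignores_hydrogens(self):
        top = make_topology(3, names=["CA", "H", "CA"], resids=[1, 1, 2])
        object.__setattr__(top, "elements",
                           np.asarray(["C", "H", "C"], dtype=object))
        coords = np.array([[[0.0, 0, 0], [1.0, 0, 0], [6.0, 0, 0]]])
        traj = Trajectory(coords, np.array([0.0]))
        d = distance_series(traj, top, Selection("a", np.array([0, 1])),
                            Selection("b", np.array([2])), mode="min")
        assert d.values[0] == pytest.approx(6.0)

    def test_atom_mode_requires_singletons(self):
        top = make_topology(3)
        traj = Trajectory(np.zeros((1, 3, 3)) + np.arange(3)[None, :, None],
                          np.array([0.0]))
        with pytest.raises(ValueError, match="singleton"):
            distance_series(traj, top, Selection("ab", np.array([0, 1])),
                            Selection("c", np.array([2])), mode="atom")

    def test_rigid_motion_leaves_distances_unchanged(self, scaffold,
                                                     small_panel):
        top, roles, _ = scaffold
        traj = small_panel["STA"].slice_frames(slice(0, 10))
        rng = np.random.default_rng(9)
        rot = random_rotation(rng)
        moved = Trajectory(traj.coordinates @ rot.T + np.array([3.0, -8.0, 2.0]),
                           traj.times)
        a = roles.selection(top, "SB_K")
        b = roles.selection(top, "SB_E")
        d0 = distance_series(traj, top, a, b, mode="min").values
        d1 = distance_series(moved, top, a, b, mode="min").values
        assert np.allclose(d0, d1, atol=1e-9)


class TestContactOccupancy:
    def test_always_formed(self):
        top = make_topology(2)
        coords = np.tile(np.array([[[0.0, 0, 0], [2.5, 0, 0]]]), (10, 1, 1))
        traj = Trajectory(coords, np.arange(10.0) + 1)
        occ, series = contact_occupancy(
            traj, top, Selection("a", np.array([0])),
            Selection("b", np.array([1])), cutoff=4.0)
        assert occ == 1.0 and series.all()

    def test_alternating_half(self):
        top = make_topology(2)
        coords = np.zeros((10, 2, 3))
        coords[:, 1, 0] = np.where(np.arange(10) % 2 == 0, 3.0, 9.0)
        occ, _ = contact_occupancy(
            Trajectory(coords, np.arange(10.0) + 1), top,
            Selection("a", np.array([0])), Selection("b", np.array([1])),
            cutoff=4.0)
        assert occ == 0.5

    def test_bad_cutoff(self):
        top = make_topology(2)
        traj = Trajectory(np.zeros((1, 2, 3)) + np.arange(2)[None, :, None],
                          np.array([0.0]))
        with pytest.raises(ValueError, match="cutoff"):
            contact_occupancy(traj, top, Selection("a", np.array([0])),
                              Selection("b", np.array([1])), cutoff=0.0)


class TestDescriptorPanel:
    def test_canonical_names_and_lengths(self, scaffold, small_panel):
        top, roles, _ = scaffold
        panel = descriptor_panel(small_panel["STA"], top, roles)
        names = [s.name for s in panel]
        assert names == list(
            ("dfg_cyclization", "alphaC_clobe", "sb_K369_E386", "f480_m390",
             "sb_D379_R496", "hb_N348_S497", "hb_R514_Y493", "gate_W505")
        )
        assert all(s.n_frames == 400 for s in panel)

    def test_planted_dfg_mean_recovered(self, scaffold, profiles):
        top, roles, _ = scaffold
        cfg = GeneratorConfig(n_frames=5000, seed=31)
        tr = simulate_state(profiles["STA"], cfg)
        panel = {s.name: s for s in descriptor_panel(tr, top, roles)}
        se = 0.3 * np.sqrt(2 * cfg.ou_tau / (cfg.n_frames * cfg.dt))
        assert abs(panel["dfg_cyclization"].values.mean() - 3.0) < 3 * se
        assert abs(panel["alphaC_clobe"].values.mean() - 15.0) < 3 * se

    def test_anchor_fallback_flagged(self, scaffold, small_panel):
        top, roles, _ = scaffold
        panel = {s.name: s for s in descriptor_panel(small_panel["STA"], top,
                                                     roles)}
        assert panel["gate_W505"].metadata["anchor_fallback"] is True

    def test_hydrogen_fallback_on_h_free_topology(self, scaffold, small_panel):
        top, roles, _ = scaffold
        keep = np.flatnonzero(~((top.resids == 481) & (top.names == "H")))
        sub_top = subset_topology(top, keep)
        tr = small_panel["STA"]
        sub = Trajectory(tr.coordinates[:, keep, :], tr.times, tr.state_label)
        panel = {s.name: s for s in descriptor_panel(sub, sub_top, roles)}
        assert panel["dfg_cyclization"].metadata["hydrogen_fallback"] is True
        # the N-based distance minus the 1.0 Å bond correction approximates
        # the H-based distance to within the N-H geometry error
        full = {s.name: s for s in descriptor_panel(tr, top, roles)}
        diff = np.abs(panel["dfg_cyclization"].values
                      - full["dfg_cyclization"].values)
        assert np.median(diff) < 0.5

    def test_missing_role_named(self, scaffold, small_panel):
        from kinastate.io import ResidueRoles, default_role_map

        top, _, _ = scaffold
        roles = default_role_map()
        stripped = {k: v for k, v in roles.roles.items() if k != "ALPHAC_M"}
        with pytest.raises(ValueError, match="ALPHAC_M"):
            descriptor_panel(small_panel["STA"], top,
                             ResidueRoles(stripped))
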