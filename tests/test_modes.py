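"""Collective-mode analysis: spectral invariants, planted-direction
recovery, state discrimination against a permutation null."""

import numpy as np
import pytest

from kinastate.io import Selection, Trajectory, select_atoms, subset_topology, write_trajectory, read_trajectory
from kinastate.modes import (
    compute_modes,
    concat_align,
    mode_animation,
    permutation_pvalues,
    state_amplitude_stats,
    subspace_angle_deg,
)
from kinastate.synthetic import (
    GeneratorConfig,
    StateProfile,
    planted_mode_directions,
    simulate_state,
)


def _unit(rng, n):
    v = rng.normal(size=3 * n)
    return v / np.linalg.norm(v)


class TestConcatAlign:
    def test_counts_and_labels(self, small_panel, scaffold):
        top, _, _ = scaffold
        ca = select_atoms(top, "name CA")
        two = {k: small_panel[k] for k in ("STA", "YP_YP")}
        coords, labels = concat_align(two, ca)
        assert coords.shape[0] == 800
        assert list(np.unique(labels)) == ["STA", "YP_YP"]
        assert (labels == "STA").sum() == 400

    def test_invariant_to_rigid_premotion(self, small_panel, scaffold):
        top, _, _ = scaffold
        ca = select_atoms(top, "name CA")
        sta = small_panel["STA"].slice_frames(slice(0, 30))
        ypyp = small_panel["YP_YP"].slice_frames(slice(0, 30))
        base, _ = concat_align({"STA": sta, "YP_YP": ypyp}, ca)
        rot = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = Trajectory(ypyp.coordinates @ rot.T + 7.0, ypyp.times, "YP_YP")
        shifted, _ = concat_align({"STA": sta, "YP_YP": moved}, ca)
        assert np.abs(base - shifted).max() < 1e-6

    def test_topology_mismatch_rejected(self, small_panel):
        bad = Trajectory(np.zeros((5, 3, 3)) + np.arange(3)[None, :, None],
                         np.arange(5.0) + 1)
        with pytest.raises(ValueError, match="share a topology"):
            concat_align({"a": small_panel["STA"], "b": bad},
                         Selection("ca", np.arange(3)))


class TestComputeModes:
    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(0)
        n_atoms = 40
        base = rng.normal(size=(n_atoms, 3)) * 8.0
        u = _unit(rng, n_atoms)
        amps = 3.0 * np.sin(np.linspace(0, 40 * np.pi, 4000))
        coords = (base.ravel()[None]
                  + amps[:, None] * u[None]
                  + rng.normal(scale=0.1, size=(4000, 3 * n_atoms)))
        ms = compute_modes(coords.reshape(4000, n_atoms, 3), n_modes=3)
        assert abs(float(ms.vectors[0] @ u)) > 0.99

    def test_spectral_invariants(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(300, 15, 3)).cumsum(axis=0) * 0.05
        ms = compute_modes(coords, n_modes=10)
        gram = ms.vectors @ ms.vectors.T
        assert np.abs(gram - np.eye(10)).max() < 1e-8
        assert np.all(np.diff(ms.all_eigenvalues) <= 1e-12)
        x = coords - coords.mean(axis=0)
        total = (x**2).sum() / coords.shape[0]
        assert ms.total_variance == pytest.approx(total, rel=1e-6)

    def test_reconstruction_residual_equals_discarded_spectrum(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(200, 10, 3)) * 2.0
        k = 5
        ms = compute_modes(coords, n_modes=k)
        x = (coords - coords.mean(axis=0)).reshape(200, -1)
        recon = ms.projections @ ms.vectors
        residual = ((x - recon) ** 2).sum() / 200
        discarded = ms.all_eigenvalues[k:].sum()
        assert residual == pytest.approx(discarded, rel=1e-6)

    def test_isotropic_data_has_flat_spectrum(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(10000, 30, 3))
        ms = compute_modes(coords, n_modes=5)
        ratio = ms.all_eigenvalues[0] / ms.all_eigenvalues.mean()
        assert ratio < 1.5

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="2 aligned frames"):
            compute_modes(np.zeros((1, 5, 3)))

    def test_n_modes_bounds(self):
        coords = np.random.default_rng(4).normal(size=(10, 5, 3))
        with pytest.raises(ValueError, match="n_modes"):
            compute_modes(coords, n_modes=30)


class TestStateStats:
    def test_planted_amplitude_difference_tops_ranking(self, scaffold):
        top, _, _ = scaffold
        ca = select_atoms(top, "name CA")
        quiet = StateProfile("quiet", dfg_sd=0.1, alphaC_sd=0.1)
        loud = StateProfile("loud", dfg_sd=0.1, alphaC_sd=0.1,
                            mode_amplitudes=((1, 3.0),))
        trajs = {
            "quiet": simulate_state(quiet, GeneratorConfig(n_frames=1200, seed=5)),
            "loud": simulate_state(loud, GeneratorConfig(n_frames=1200, seed=6)),
        }
        coords, labels = concat_align(trajs, ca)
        ms = compute_modes(coords[:, ca.indices, :], n_modes=5, labels=labels)
        stats = state_amplitude_stats(ms)
        u = planted_mode_directions()[1].ravel()
        planted_pc = int(np.abs(ms.vectors @ u).argmax())
        assert stats.ranking[0] == planted_pc

    def test_identical_states_within_null(self):
        """Statistically identical states must not produce a discriminative
        mode: jointly over the four modes, none clears the stringent
        (family-wise) 0.005 permutation level."""
        rng = np.random.default_rng(7)
        proj = rng.normal(size=(600, 4))
        labels = np.asarray(["a"] * 300 + ["b"] * 300, dtype=object)
        ms = compute_modes(rng.normal(size=(600, 6, 3)), n_modes=4,
                           labels=labels)
        ms.projections = proj
        pvals = permutation_pvalues(ms, n_permutations=200, seed=11)
        assert (pvals <= 0.005).sum() == 0

    def test_rms_amplitude_of_pure_sinusoid(self):
        a = 2.5
        n = 5000
        proj = a * np.sin(np.linspace(0, 123.4, n))[:, None]
        labels = np.asarray(["s"] * n, dtype=object)
        rows = []
        ms = compute_modes(np.random.default_rng(8).normal(size=(n, 2, 3)),
                           n_modes=1, labels=labels)
        ms.projections = proj
        stats = state_amplitude_stats(ms)
        amp = stats.table.loc[0, "amplitude"]
        assert amp == pytest.approx(a / np.sqrt(2), rel=0.02)

    def test_small_state_rejected(self):
        labels = np.asarray(["a"] * 5 + ["b"], dtype=object)
        ms = compute_modes(np.random.default_rng(9).normal(size=(6, 4, 3)),
                           n_modes=2, labels=labels)
        with pytest.raises(ValueError, match="fewer than 2"):
            state_amplitude_stats(ms)


class TestAnimation:
    def test_endpoints_and_linearity(self):
        coords = np.random.default_rng(10).normal(size=(50, 8, 3))
        ms = compute_modes(coords, n_modes=2)
        anim = mode_animation(ms, 0, scale=2.0, n_frames=20)
        v = ms.vectors[0].reshape(8, 3)
        assert np.allclose(anim.coordinates[0], ms.mean - 2.0 * v)
        assert np.allclose(anim.coordinates[-1], ms.mean + 2.0 * v)
        tiny = mode_animation(ms, 0, scale=0.001)
        disp = np.abs(tiny.coordinates[-1] - ms.mean).max()
        assert disp == pytest.approx(0.001 * np.abs(v).max())

    def test_roundtrip_through_pdb(self, tmp_path, scaffold, small_panel):
        top, _, _ = scaffold
        ca = select_atoms(top, "name CA")
        sub_top = subset_topology(top, ca.indices)
        coords = small_panel["STA"].coordinates[:60, ca.indices, :]
        ms = compute_modes(coords, n_modes=2)
        anim = mode_animation(ms, 1, scale=3.0)
        path = tmp_path / "anim.pdb"
        write_trajectory(anim, sub_top, path)
        back = read_trajectory(path, sub_top)
        assert back.n_frames == 20

    def test_bad_arguments(self):
        ms = compute_modes(np.random.default_rng(11).normal(size=(20, 4, 3)),
                           n_modes=2)
        with pytest.raises(ValueError, match="scale"):
            mode_animation(ms, 0, scale=0.0)
        with pytest.raises(ValueError, match="mode id"):
            mode_animation(ms, 5, scale=1.0)


def test_subspace_angle_of_identical_spans_is_zero():
    rng = np.random.default_rng(12)
    basis = rng.normal(size=(3, 30))
    mixed = np.array([[2.0, 1.0, 0.0], [0.0, 1.0, 1.0], [1.0, 0.0, 1.0]]) @ basis
    assert subspace_angle_deg(mixed, basis) < 1e-4
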