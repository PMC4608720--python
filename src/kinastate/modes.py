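"""Quasi-harmonic collective-mode analysis of concatenated state ensembles.

"Normal modes" here are principal components of the Cα coordinate
covariance of trajectories concatenated across states (essential dynamics /
quasi-harmonic analysis), not Hessian eigenmodes: eigenvectors are
orthonormal collective directions, eigenvalues their variances (Å²), and
per-frame projections carry the state label so per-state amplitude
statistics can identify state-correlated motions.  Rigid-body motion is
removed by least-squares alignment beforehand, not by discarding six modes;
near-zero residual modes are reported, never dropped.

The discrimination score formalises "mode correlated with state" as a
one-way ANOVA F statistic over state-wise projection means, calibrated
against a label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import Selection, superpose
from .io import Trajectory

__all__ = [
    "ModeSet",
    "ModeStateStats",
    "concat_align",
    "compute_modes",
    "state_amplitude_stats",
    "permutation_pvalues",
    "mode_animation",
    "subspace_angle_deg",
]


@dataclass
class ModeSet:
    """Mean structure, orthonormal mode vectors, eigenvalues, projections."""

    mean: np.ndarray             # (n_atoms, 3)
    vectors: np.ndarray          # (n_modes, 3*n_atoms), unit norm, sorted
    eigenvalues: np.ndarray      # (n_modes,), Å², non-increasing
    all_eigenvalues: np.ndarray  # full spectrum, for trace checks
    projections: np.ndarray      # (n_frames, n_modes), Å
    labels: np.ndarray           # (n_frames,) state label per frame

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[0]

    @property
    def total_variance(self) -> float:
        return float(self.all_eigenvalues.sum())


@dataclass
class ModeStateStats:
    """Per-(mode, state) projection statistics and per-mode discrimination."""

    table: pd.DataFrame          # mode, state, mean, variance, amplitude
    scores: np.ndarray           # ANOVA-style F per mode
    ranking: np.ndarray          # mode indices, most discriminative first


def concat_align(
    trajs: dict, fit_sel: Selection
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate state trajectories and align to the global mean structure.

    Every frame is superposed (Kabsch on ``fit_sel``) first onto the first
    frame, then twice onto the recomputed global mean.  Labels are preserved
    per frame; concatenation follows the mapping's insertion order.
    """
    n_atoms = None
    pieces, labels = [], []
    for label, traj in trajs.items():
        if n_atoms is None:
            n_atoms = traj.n_atoms
        elif traj.n_atoms != n_atoms:
            raise ValueError(
                f"trajectory {label!r} has {traj.n_atoms} atoms, expected "
                f"{n_atoms}: all states must share a topology"
            )
        pieces.append(traj.coordinates)
        labels.extend([traj.state_label if traj.state_label != "custom" else label]
                      * traj.n_frames)
    coords = np.concatenate(pieces, axis=0)
    labels = np.asarray(labels, dtype=object)
    ref = coords[0]
    for _ in range(3):  # first-frame pass + two mean passes
        for i in range(coords.shape[0]):
            tf, _ = superpose(coords[i], ref, fit_sel)
            coords[i] = tf.apply(coords[i])
        ref = coords.mean(axis=0)
    return coords, labels


def compute_modes(
    coordinates: np.ndarray,
    n_modes: int = 10,
    labels: np.ndarray | None = None,
) -> ModeSet:
    """Eigendecompose the coordinate covariance and project every frame.

    ``coordinates`` are aligned frames of the analysis selection (typically
    Cα atoms), shaped ``(n_frames, n_atoms, 3)``.  The top ``n_modes``
    eigenvectors are retained; the full eigenvalue spectrum is kept so the
    trace identity (Σλ = total coordinate variance) can be checked.
    """
    coords = np.asarray(coordinates, dtype=np.float64)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValueError("need at least 2 aligned frames of (n_atoms, 3)")
    f, m, _ = coords.shape
    if not 1 <= n_modes <= min(f - 1, 3 * m):
        raise ValueError(
            f"n_modes must be in [1, min(n_frames-1, 3*n_atoms)] = "
            f"[1, {min(f - 1, 3 * m)}], got {n_modes}"
        )
    mean = coords.mean(axis=0)
    x = (coords - mean).reshape(f, 3 * m)
    cov = (x.T @ x) / f
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals[::-1], 0.0, None)
    evecs = evecs[:, ::-1]
    vectors = evecs[:, :n_modes].T.copy()
    projections = x @ vectors.T
    if labels is None:
        labels = np.asarray(["custom"] * f, dtype=object)
    return ModeSet(
        mean=mean,
        vectors=vectors,
        eigenvalues=evals[:n_modes].copy(),
        all_eigenvalues=evals.copy(),
        projections=projections,
        labels=np.asarray(labels, dtype=object),
    )


def _anova_f(projections: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA F per mode on squared projections.

    State-correlated modes may be zero-mean oscillations whose *amplitude*
    differs by state, so the statistic compares state means of the squared
    projection (amplitude energy), which is also sensitive to plain mean
    shifts.
    """
    projections = projections**2
    states, inverse = np.unique(labels, return_inverse=True)
    n_total, n_modes = projections.shape
    s = len(states)
    if s < 2:
        raise ValueError("discrimination needs at least two states")
    grand = projections.mean(axis=0)
    ssb = np.zeros(n_modes)
    ssw = np.zeros(n_modes)
    for k in range(s):
        grp = projections[inverse == k]
        if grp.shape[0] < 2:
            raise ValueError(
                f"state {states[k]!r} has fewer than 2 frames"
            )
        gm = grp.mean(axis=0)
        ssb += grp.shape[0] * (gm - grand) ** 2
        ssw += ((grp - gm) ** 2).sum(axis=0)
    msb = ssb / (s - 1)
    msw = ssw / (n_total - s)
    return msb / np.where(msw > 0, msw, np.finfo(float).tiny)


def state_amplitude_stats(modes: ModeSet) -> ModeStateStats:
    """Per-state projection mean/variance/RMS amplitude and mode ranking."""
    states = np.unique(modes.labels)
    rows = []
    for state in states:
        grp = modes.projections[modes.labels == state]
        if grp.shape[0] < 2:
            raise ValueError(f"state {state!r} has fewer than 2 frames")
        for mode_id in range(modes.n_modes):
            v = grp[:, mode_id]
            rows.append({
                "mode": mode_id, "state": state,
                "mean": float(v.mean()),
                "variance": float(v.var(ddof=1)),
                "amplitude": float(np.sqrt(np.mean(v**2))),
                "n_frames": int(v.size),
            })
    if len(states) > 1:
        scores = _anova_f(modes.projections, modes.labels)
    else:
        scores = np.zeros(modes.n_modes)  # nothing to discriminate
    ranking = np.argsort(scores)[::-1]
    return ModeStateStats(pd.DataFrame(rows), scores, ranking)


def permutation_pvalues(
    modes: ModeSet, n_permutations: int = 200, seed: int = 0
) -> np.ndarray:
    """Per-mode p-value of the discrimination score under a label shuffle.

    p = (1 + #{F_perm >= F_obs}) / (n_permutations + 1).
    """
    rng = np.random.default_rng(seed)
    obs = _anova_f(modes.projections, modes.labels)
    exceed = np.zeros(modes.n_modes)
    labels = modes.labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(labels)
        exceed += _anova_f(modes.projections, labels) >= obs
    return (1.0 + exceed) / (n_permutations + 1.0)


def mode_animation(modes: ModeSet, mode_id: int, scale: float = 3.0,
                   n_frames: int = 20) -> Trajectory:
    """Interpolate mean − scale·v … mean + scale·v for visualisation."""
    if not 0 <= mode_id < modes.n_modes:
        raise ValueError(f"mode id {mode_id} outside [0, {modes.n_modes})")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    v = modes.vectors[mode_id].reshape(modes.mean.shape)
    alphas = np.linspace(-1.0, 1.0, n_frames)
    coords = modes.mean[None] + scale * alphas[:, None, None] * v[None]
    return Trajectory(coords, np.arange(n_frames) * 0.1, state_label="animation")


def subspace_angle_deg(
    vectors: np.ndarray, reference: np.ndarray
) -> float:
    """Largest principal angle (degrees) between two mode subspaces.

    Rows of each array are (not necessarily orthonormal) 3N-dimensional
    directions.
    """
    qa, _ = np.linalg.qr(np.asarray(vectors, dtype=np.float64).T)
    qb, _ = np.linalg.qr(np.asarray(reference, dtype=np.float64).T)
    sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
    sv = np.clip(sv, -1.0, 1.0)
    return float(np.degrees(np.arccos(sv.min())))


def write_modeset(modes: ModeSet, prefix) -> list[Path]:
    """Persist a ModeSet as binary-free CSVs (vectors/eigenvalues + projections)."""
    prefix = Path(prefix)
    vec_path = prefix.with_name(prefix.name + "_modes.csv")
    n_atoms = modes.mean.shape[0]
    cols = {"component": np.arange(3 * n_atoms)}
    for k in range(modes.n_modes):
        cols[f"mode{k + 1}"] = modes.vectors[k]
    pd.DataFrame(cols).to_csv(vec_path, index=False, float_format="%.8f")
    eig_path = prefix.with_name(prefix.name + "_eigenvalues.csv")
    pd.DataFrame({
        "mode": np.arange(len(modes.all_eigenvalues)) + 1,
        "eigenvalue_A2": modes.all_eigenvalues,
    }).to_csv(eig_path, index=False, float_format="%.8f")
    proj_path = prefix.with_name(prefix.name + "_projections.csv")
    rows = {"frame": np.arange(modes.projections.shape[0]),
            "state": modes.labels}
    for k in range(modes.n_modes):
        rows[f"mode{k + 1}"] = modes.projections[:, k]
    pd.DataFrame(rows).to_csv(proj_path, index=False, float_format="%.6f")
    return [vec_path, eig_path, proj_path]
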