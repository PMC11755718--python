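"""Rigid superposition (Kabsch), RMSD series versus the first frame, and
fixed-interval time sampling.

RMSD here is plain (unweighted) coordinate RMSD after optimal rigid
superposition.  The trajectory-stability readout defaults to backbone heavy
atoms of the whole complex; Cα, heavy or all-atom selections are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Frame, Trajectory, select_atoms, StructureError


class DegenerateGeometryError(Exception):
    pass


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation, with rotation a proper orthonormal matrix."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant must be +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class RmsdSeries:
    values: np.ndarray
    time_ns: np.ndarray
    selection: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        if self.values.shape != self.time_ns.shape:
            raise ValueError("values and time_ns must have equal length")
        if np.any(self.values < -1e-12):
            raise ValueError("rmsd values must be non-negative")

    def __len__(self):
        return len(self.values)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"time_ns": self.time_ns, "rmsd_A": self.values}).to_csv(
            path, index=False)


def _paired_coords(mobile, reference, pairing):
    mob = mobile.coords if isinstance(mobile, Frame) else np.asarray(mobile, float)
    ref = reference.coords if isinstance(reference, Frame) else np.asarray(reference, float)
    if pairing is not None:
        pairing = np.asarray(pairing, dtype=int)
        mob = mob[pairing[:, 0]]
        ref = ref[pairing[:, 1]]
    if len(mob) != len(ref):
        raise ValueError("mobile and reference must pair the same number of atoms")
    return mob, ref


def kabsch_superpose(mobile, reference, pairing=None) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Accepts Frames or (N,3) arrays; ``pairing`` is an optional (M,2) array of
    (mobile_index, reference_index) pairs, identity order otherwise.  Returns
    the transform attaining the global-minimum RMSD, and that RMSD (Å).
    """
    mob, ref = _paired_coords(mobile, reference, pairing)
    n = len(mob)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 paired atoms")
    ref_c = ref - ref.mean(axis=0)
    # collinear references leave a free rotation about the common axis
    if np.linalg.matrix_rank(ref_c, tol=1e-6) < 2:
        raise DegenerateGeometryError("paired atoms are collinear")
    mob_centroid = mob.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref_c, mob - mob_centroid)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob_centroid
    rmsd = float(rssd / np.sqrt(n))
    return RigidTransform(R, t), rmsd


def rmsd(a, b, pairing=None, superpose: bool = True) -> float:
    """RMSD between two coordinate sets, optionally after superposition."""
    mob, ref = _paired_coords(a, b, pairing)
    if superpose:
        return kabsch_superpose(mob, ref)[1]
    return float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))


def rmsd_to_first_frame(trajectory: Trajectory, chains=None,
                        atom_class: str = "backbone") -> RmsdSeries:
    """RMSD of each frame against frame 0 after superposing the selection."""
    if not trajectory.frames:
        raise StructureError("empty trajectory")
    if not trajectory.topology_constant:
        raise StructureError("trajectory topology is not constant; refusing")
    first = trajectory.frames[0]
    if chains is None:
        chains = set(np.unique(first.chain_id))
    sel_mask_frame = select_atoms(first, chains, atom_class=atom_class)
    # indices valid for all frames (constant topology)
    ids = {t: i for i, t in enumerate(first.identity_tuples())}
    idx = np.array([ids[t] for t in sel_mask_frame.identity_tuples()])
    ref = first.coords[idx]
    values = [0.0]
    for f in trajectory.frames[1:]:
        values.append(rmsd(f.coords[idx], ref, superpose=True))
    times = trajectory.times
    if times is None:
        times = np.arange(len(trajectory.frames), dtype=float)
    sel = f"{atom_class}:{'+'.join(sorted(map(str, chains)))}"
    return RmsdSeries(np.asarray(values), times, selection=sel)


def sample_every(values, time_ns, interval_ns: float):
    """Subsample a timed series at ticks 0, interval, 2·interval, …

    For each tick the nearest frame at-or-after the tick is kept; t=0 is
    always retained.  Returns (sampled values, sampled times).
    """
    if interval_ns <= 0:
        raise ValueError("interval_ns must be positive")
    values = np.asarray(values, dtype=float)
    time_ns = np.asarray(time_ns, dtype=float)
    if values.shape != time_ns.shape:
        raise ValueError("values and time_ns must have equal length")
    eps = 1e-9
    idx = []
    tick = time_ns[0]
    while tick <= time_ns[-1] + eps:
        i = int(np.searchsorted(time_ns, tick - eps, side="left"))
        if not idx or i != idx[-1]:
            idx.append(i)
        tick += interval_ns
    idx = np.asarray(idx, dtype=int)
    return values[idx], time_ns[idx]


def sample_series(series: RmsdSeries, interval_ns: float) -> RmsdSeries:
    v, t = sample_every(series.values, series.time_ns, interval_ns)
    return RmsdSeries(v, t, selection=series.selection)
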