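"""Solvent-accessible surface area (Shrake–Rupley), buried interface area
and Coulombic surface potential.

SASA uses a deterministic golden-spiral point lattice on each atom's
solvent-expanded sphere (no RNG — results are exactly reproducible for a
given point count).  Buried interface area is

    buried = sasa(A) + sasa(B) − sasa(A∪B)

optionally halved (``half_sum``, the default), since interface-size
conventions differ between tools; both conventions are first-class outputs.
The Coulombic potential at a point p is

    φ(p) = k · Σ_i  q_i / (ε(d_i) · d_i),   k = 332.0636 kcal·Å/(mol·e²)

with a constant dielectric by default (ε = 4) or a distance-dependent
ε = c·d.  Partial charges come from a pluggable formal-charge residue
template (±1 split over the charged-group oxygens/nitrogens), so potential
values are qualitative (sign and pattern) rather than force-field-accurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Frame

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)

#: Bondi-style van der Waals radii (Å) by element
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90,
}


class RadiusLookupError(Exception):
    pass


class SingularPointError(Exception):
    pass


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (Fibonacci spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_radii(frame: Frame) -> np.ndarray:
    radii = np.empty(len(frame))
    for i, el in enumerate(frame.element):
        key = str(el).upper()
        if key not in VDW_RADII:
            raise RadiusLookupError(
                f"no van der Waals radius for atom {frame.name[i]!r} "
                f"(element {el!r}) in {frame.residue_key(i)}")
        radii[i] = VDW_RADII[key]
    return radii


@dataclass
class SasaResult:
    per_atom: np.ndarray
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())

    def to_csv(self, frame: Frame, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "chain": frame.chain_id, "res_seq": frame.res_seq,
            "res_name": frame.res_name, "atom": frame.name,
            "sasa_A2": np.round(self.per_atom, 4),
        }).to_csv(path, index=False)


def _accessible_point_mask(frame: Frame, probe: float, n_points: int,
                           include_hydrogens: bool):
    """Per-atom boolean mask of accessible lattice points.

    Returns (frame used, expanded radii, list of point masks).
    """
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    if not include_hydrogens:
        mask = frame.element != "H"
        frame = frame.subset(mask)
    if len(frame) == 0:
        raise ValueError("no atoms to compute SASA for")
    radii = atom_radii(frame) + probe
    unit = golden_spiral_points(n_points)
    coords = frame.coords
    tree = cKDTree(coords)
    max_r = radii.max()
    masks = []
    for i in range(len(frame)):
        pts = coords[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                     if j != i]
        acc = np.ones(n_points, dtype=bool)
        if neighbors:
            nb = np.asarray(neighbors)
            # point is buried if inside any neighbour's expanded sphere
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            acc = ~(d2 < (radii[nb] ** 2)[None, :] - 1e-12).any(axis=1)
        masks.append(acc)
    return frame, radii, masks


def sasa(frame: Frame, probe: float = 1.4, n_points: int = 960,
         include_hydrogens: bool = False) -> SasaResult:
    """Shrake–Rupley SASA: per-atom area = (accessible/total points)·4π(r+p)²."""
    used, radii, masks = _accessible_point_mask(frame, probe, n_points,
                                                include_hydrogens)
    frac = np.array([m.mean() for m in masks])
    per_atom = frac * 4.0 * np.pi * radii ** 2
    # map back onto the original atom order (hydrogens get zero)
    if len(used) != len(frame):
        full = np.zeros(len(frame))
        full[frame.element != "H"] = per_atom
        per_atom = full
    return SasaResult(per_atom=per_atom, probe=probe, n_points=n_points)


def surface_points(frame: Frame, probe: float = 1.4, n_points: int = 960,
                   include_hydrogens: bool = False) -> np.ndarray:
    """The accessible Shrake–Rupley lattice points (solvent-accessible dots)."""
    used, radii, masks = _accessible_point_mask(frame, probe, n_points,
                                                include_hydrogens)
    unit = golden_spiral_points(n_points)
    out = []
    for i, acc in enumerate(masks):
        if acc.any():
            out.append(used.coords[i] + radii[i] * unit[acc])
    return np.vstack(out) if out else np.empty((0, 3))


def buried_sasa(frameA: Frame, frameB: Frame, probe: float = 1.4,
                n_points: int = 960, convention: str = "half_sum") -> float:
    """Interface area buried on complexation: sasaA + sasaB − sasaAB.

    ``half_sum`` (default) halves the raw sum — one face's worth of area;
    ``full_sum`` returns the raw two-face total.
    """
    if convention not in ("half_sum", "full_sum"):
        raise ValueError(f"unknown convention {convention!r}")
    ids_a = set(frameA.identity_tuples())
    ids_b = set(frameB.identity_tuples())
    if ids_a & ids_b:
        raise ValueError("frames share atom identities; groups must be disjoint")
    merged = _concat_frames(frameA, frameB)
    raw = (sasa(frameA, probe, n_points).total
           + sasa(frameB, probe, n_points).total
           - sasa(merged, probe, n_points).total)
    return raw / 2.0 if convention == "half_sum" else raw


def _concat_frames(a: Frame, b: Frame) -> Frame:
    return Frame(
        serial=np.concatenate([a.serial, b.serial]),
        name=np.concatenate([a.name, b.name]),
        element=np.concatenate([a.element, b.element]),
        alt_loc=np.concatenate([a.alt_loc, b.alt_loc]),
        res_name=np.concatenate([a.res_name, b.res_name]),
        res_seq=np.concatenate([a.res_seq, b.res_seq]),
        insertion_code=np.concatenate([a.insertion_code, b.insertion_code]),
        chain_id=np.concatenate([a.chain_id, b.chain_id]),
        coords=np.vstack([a.coords, b.coords]),
        occupancy=np.concatenate([a.occupancy, b.occupancy]),
        b_factor=np.concatenate([a.b_factor, b.b_factor]),
    )


# ---------------------------------------------------------------------------
# Coulombic potential

# formal charge templates: ±1 split over the charged-group heteroatoms
_FORMAL_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): +1.0,
    ("ARG", "NH1"): +0.5, ("ARG", "NH2"): +0.5,
}


@dataclass
class ChargeRadiusModel:
    """Pluggable per-atom charge/radius model with a dielectric policy.

    ``dielectric``: constant value (``epsilon``) by default; set
    ``distance_dependent=True`` for ε(d) = epsilon·d.
    """

    charges: dict = field(default_factory=lambda: dict(_FORMAL_CHARGES))
    radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    epsilon: float = 4.0
    distance_dependent: bool = False
    coulomb_constant: float = COULOMB_CONSTANT

    def charge(self, res_name: str, atom_name: str) -> float:
        return self.charges.get((str(res_name), str(atom_name)), 0.0)

    def frame_charges(self, frame: Frame) -> np.ndarray:
        q = np.array([self.charge(r, n)
                      for r, n in zip(frame.res_name, frame.name)])
        # C-terminal carboxylate when OXT is present
        if "OXT" in frame.name:
            for chain in np.unique(frame.chain_id):
                sel = np.flatnonzero((frame.chain_id == chain) & (frame.name == "OXT"))
                for i in sel:
                    q[i] = -0.5
                    mate = np.flatnonzero((frame.chain_id == chain)
                                          & (frame.res_seq == frame.res_seq[i])
                                          & (frame.name == "O"))
                    if len(mate):
                        q[mate[0]] = -0.5
        return q


@dataclass
class PotentialMap:
    points: np.ndarray
    phi: np.ndarray        # kcal/(mol·e)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "x": self.points[:, 0], "y": self.points[:, 1],
            "z": self.points[:, 2], "phi": self.phi,
        }).to_csv(path, index=False)


def coulomb_potential(points: np.ndarray, frame: Frame,
                      model: ChargeRadiusModel | None = None) -> PotentialMap:
    """Coulomb potential φ(p) = k·Σ q_i/(ε(d_i)·d_i) at each point (kcal/(mol·e))."""
    if model is None:
        model = ChargeRadiusModel()
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    q = model.frame_charges(frame)
    d = np.sqrt(((points[:, None, :] - frame.coords[None, :, :]) ** 2).sum(axis=2))
    if np.any(d < 1e-6):
        bad = int(np.argwhere(d < 1e-6)[0][0])
        raise SingularPointError(f"point {bad} coincides with an atom center")
    if model.distance_dependent:
        phi = model.coulomb_constant * (q[None, :] / (model.epsilon * d * d)).sum(axis=1)
    else:
        phi = model.coulomb_constant * (q[None, :] / (model.epsilon * d)).sum(axis=1)
    return PotentialMap(points=points, phi=phi)
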