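"""Geometric detection and typing of inter-chain residue–residue contacts.

Four interaction types are detected between two disjoint chain groups:

* hydrogen bond — H···acceptor distance plus donor and acceptor angle tests
  (or a heavy-atom donor–acceptor distance fallback when the structure
  carries no hydrogens);
* salt bridge — anionic carboxylate/terminal oxygen within cutoff of a
  cationic nitrogen;
* hydrophobic — closest carbon–carbon distance between apolar side-chain
  carbons within cutoff (arginine's aliphatic CB/CG/CD participate);
* π-cation — cation center within cutoff of an aromatic ring centroid and
  within an angular cone about the ring normal.

Cutoffs follow literature-standard ranges for interaction diagrams and are
fully configurable through :class:`InteractionCriteria`.  Detection reports
one record per residue pair per type per frame, so a pair engaging through
several simultaneous contact types yields several records — summed
persistence above 100% is expected and meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import logging

import numpy as np
from scipy.spatial.distance import cdist

from .structures import Frame, ResidueKey

logger = logging.getLogger(__name__)

ITYPES = ("hbond", "salt_bridge", "hydrophobic", "pi_cation")


class ConfigurationError(Exception):
    pass


class GeometryError(Exception):
    pass


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric cutoffs; distances in Å, angles in degrees."""

    hbond_h_acceptor_max: float = 2.8
    hbond_donor_angle_min: float = 120.0
    hbond_acceptor_angle_min: float = 90.0
    hbond_heavy_fallback_max: float | None = 3.5
    salt_bridge_max: float = 4.0
    hydrophobic_cc_max: float = 4.5
    pication_max: float = 6.0
    pication_axis_angle_max: float = 45.0

    def __post_init__(self):
        for name in ("hbond_h_acceptor_max", "salt_bridge_max",
                     "hydrophobic_cc_max", "pication_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_donor_angle_min", "hbond_acceptor_angle_min",
                     "pication_axis_angle_max"):
            v = getattr(self, name)
            if not 0 < v < 180:
                raise ValueError(f"{name} must be in (0, 180)")

    def scaled(self, factor: float) -> "InteractionCriteria":
        """All distance cutoffs multiplied by ``factor`` (angles unchanged)."""
        return replace(
            self,
            hbond_h_acceptor_max=self.hbond_h_acceptor_max * factor,
            hbond_heavy_fallback_max=(None if self.hbond_heavy_fallback_max is None
                                      else self.hbond_heavy_fallback_max * factor),
            salt_bridge_max=self.salt_bridge_max * factor,
            hydrophobic_cc_max=self.hydrophobic_cc_max * factor,
            pication_max=self.pication_max * factor,
        )


# ---------------------------------------------------------------------------
# residue templates

# donor heavy atom -> names of its bonded hydrogens (standard PDB v3 naming)
_SIDECHAIN_DONORS = {
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "TYR": {"OH": ("HH",)},
    "CYS": {"SG": ("HG",)},
    "TRP": {"NE1": ("HE1",)},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")},
    "HIS": {"NE2": ("HE2",)},  # neutral Nε tautomer
}

# acceptor atom -> its covalent antecedent (for the acceptor-angle test)
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1": "CG", "OD2": "CG"},
    "GLU": {"OE1": "CD", "OE2": "CD"},
    "ASN": {"OD1": "CG"},
    "GLN": {"OE1": "CD"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "HIS": {"ND1": "CG"},
    "MET": {"SD": "CG"},
    "CYS": {"SG": "CB"},
}

_ANIONIC = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# atoms carrying the positive charge in salt bridges (nitrogens)
_CATIONIC_N = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}

# point charge centers for π-cation geometry
_CATION_CENTER = {
    "ARG": "CZ",   # guanidinium center
    "LYS": "NZ",
}

_HYDROPHOBIC_SIDECHAIN_C = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "PRO": ("CB", "CG", "CD"),
    # tyrosine contributes its ring carbons; arginine its aliphatic stem
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "ARG": ("CB", "CG", "CD"),
}

_AROMATIC_RINGS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
}

_STANDARD_RES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass
class RoleAssignment:
    """Per-frame role tables, as atom indices into the frame.

    ``donors``: list of (donor_idx, h_idx or None); ``acceptors``: list of
    (acceptor_idx, antecedent_idx); ``cationic_n``/``anionic_o``: index
    arrays; ``cation_centers``: list of (residue-local label, atom_idx);
    ``hydrophobic_c``: index array; ``rings``: list of (res_index_key,
    tuple of atom idx).
    """

    donors: list
    acceptors: list
    cationic_n: np.ndarray
    anionic_o: np.ndarray
    cation_centers: list
    hydrophobic_c: np.ndarray
    rings: list
    residue_of_atom: list


def assign_roles(frame: Frame, his_cationic: bool = False) -> RoleAssignment:
    """Build role tables from bundled residue templates.

    Unknown residue names contribute no roles (logged at warning level).
    With ``his_cationic`` both ring nitrogens of His become donors/charged.
    """
    # index atoms per residue for template lookup
    atoms_by_res: dict[ResidueKey, dict[str, int]] = {}
    order: list[ResidueKey] = []
    residue_of_atom = []
    for i in range(len(frame)):
        key = frame.residue_key(i)
        if key not in atoms_by_res:
            atoms_by_res[key] = {}
            order.append(key)
        atoms_by_res[key][str(frame.name[i])] = i
        residue_of_atom.append(key)

    donors, acceptors, cation_centers, rings = [], [], [], []
    cationic_n, anionic_o, hydrophobic_c = [], [], []

    chain_first: dict[str, ResidueKey] = {}
    chain_last: dict[str, ResidueKey] = {}
    for key in order:
        chain_first.setdefault(key.chain_id, key)
        chain_last[key.chain_id] = key

    unknown = set()
    for key in order:
        res = key.res_name
        atoms = atoms_by_res[key]
        if res not in _STANDARD_RES:
            unknown.add(res)
            continue

        # backbone donor N–H (proline has no amide H)
        if "N" in atoms and res != "PRO":
            hs = [atoms[h] for h in ("H", "H1", "H2", "H3", "HN") if h in atoms]
            if hs:
                for h in hs:
                    donors.append((atoms["N"], h))
            else:
                donors.append((atoms["N"], None))
        # backbone carbonyl acceptor
        if "O" in atoms and "C" in atoms:
            acceptors.append((atoms["O"], atoms["C"]))
        if "OXT" in atoms and "C" in atoms:
            acceptors.append((atoms["OXT"], atoms["C"]))
            anionic_o.extend([atoms["OXT"]] + ([atoms["O"]] if "O" in atoms else []))

        for donor, h_names in _SIDECHAIN_DONORS.get(res, {}).items():
            if res == "HIS" and not his_cationic and donor == "ND1":
                continue
            if donor in atoms:
                hs = [atoms[h] for h in h_names if h in atoms]
                if hs:
                    for h in hs:
                        donors.append((atoms[donor], h))
                else:
                    donors.append((atoms[donor], None))
        if res == "HIS" and his_cationic and "ND1" in atoms:
            hs = [atoms[h] for h in ("HD1",) if h in atoms]
            donors.extend((atoms["ND1"], h) for h in hs or (None,))

        for acc, ante in _SIDECHAIN_ACCEPTORS.get(res, {}).items():
            if res == "HIS" and his_cationic:
                continue  # protonated His no longer accepts
            if acc in atoms and ante in atoms:
                acceptors.append((atoms[acc], atoms[ante]))

        anionic_o.extend(atoms[a] for a in _ANIONIC.get(res, ()) if a in atoms)
        cationic_n.extend(atoms[a] for a in _CATIONIC_N.get(res, ()) if a in atoms)
        if res == "HIS" and his_cationic:
            cationic_n.extend(atoms[a] for a in ("ND1", "NE2") if a in atoms)

        center = _CATION_CENTER.get(res)
        if center and center in atoms:
            cation_centers.append((key, atoms[center]))
        if res == "HIS" and his_cationic:
            ring = [atoms[a] for a in _AROMATIC_RINGS["HIS"][0] if a in atoms]
            if len(ring) == 5:
                cation_centers.append((key, ("ring",) + tuple(ring)))

        # N-terminal amine is protonated at physiological pH
        if key == chain_first[key.chain_id] and "N" in atoms and res != "PRO":
            cationic_n.append(atoms["N"])

        hydrophobic_c.extend(atoms[a] for a in _HYDROPHOBIC_SIDECHAIN_C.get(res, ())
                             if a in atoms)

        for ring_names in _AROMATIC_RINGS.get(res, ()):
            idx = tuple(atoms[a] for a in ring_names if a in atoms)
            if len(idx) >= 5:
                rings.append((key, idx))

    if unknown:
        logger.warning("unknown residues skipped in role assignment: %s",
                       sorted(unknown))
    return RoleAssignment(
        donors=donors, acceptors=acceptors,
        cationic_n=np.asarray(sorted(set(cationic_n)), dtype=int),
        anionic_o=np.asarray(sorted(set(anionic_o)), dtype=int),
        cation_centers=cation_centers,
        hydrophobic_c=np.asarray(sorted(set(hydrophobic_c)), dtype=int),
        rings=rings, residue_of_atom=residue_of_atom,
    )


# ---------------------------------------------------------------------------
# primitive geometric tests


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbond(donor_xyz, h_xyz, acceptor_xyz, antecedent_xyz,
                 criteria: InteractionCriteria):
    """Hydrogen-bond test with explicit hydrogen.

    True iff  d(H, A) ≤ cutoff  and  angle(D–H–A) ≥ donor min  and
    angle(H–A–antecedent) ≥ acceptor min.  Returns (bool, geometry dict).
    """
    d_ha = float(np.linalg.norm(np.asarray(acceptor_xyz) - np.asarray(h_xyz)))
    geom = {"distance": d_ha}
    if d_ha > criteria.hbond_h_acceptor_max:
        return False, geom
    ang_d = _angle(np.asarray(donor_xyz), np.asarray(h_xyz), np.asarray(acceptor_xyz))
    ang_a = _angle(np.asarray(h_xyz), np.asarray(acceptor_xyz), np.asarray(antecedent_xyz))
    geom.update(donor_angle=ang_d, acceptor_angle=ang_a)
    ok = ang_d >= criteria.hbond_donor_angle_min and ang_a >= criteria.hbond_acceptor_angle_min
    return ok, geom


def ring_normal(ring_coords: np.ndarray, planarity_tol: float = 0.5):
    """Centroid and unit normal of a planar ring (SVD plane fit).

    Raises :class:`GeometryError` when any ring atom is further than
    ``planarity_tol`` Å from the best-fit plane.
    """
    ring_coords = np.asarray(ring_coords, dtype=float)
    if len(ring_coords) < 5:
        raise GeometryError("ring must have at least 5 atoms")
    centroid = ring_coords.mean(axis=0)
    _, s, vt = np.linalg.svd(ring_coords - centroid)
    normal = vt[2]
    dev = np.abs((ring_coords - centroid) @ normal)
    if dev.max() > planarity_tol:
        raise GeometryError(f"ring deviates {dev.max():.2f} Å from planarity")
    return centroid, normal


def detect_pi_cation(ring_coords, cation_xyz, criteria: InteractionCriteria):
    """π-cation test: distance to ring centroid and cone angle about the normal."""
    centroid, normal = ring_normal(ring_coords)
    v = np.asarray(cation_xyz, dtype=float) - centroid
    dist = float(np.linalg.norm(v))
    geom = {"distance": dist}
    if dist > criteria.pication_max or dist == 0.0:
        return False, geom
    cosang = abs(np.dot(v / dist, normal))  # normal sign is arbitrary
    angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    geom["axis_angle"] = angle
    return angle <= criteria.pication_axis_angle_max, geom


# ---------------------------------------------------------------------------
# per-frame detection


@dataclass(frozen=True)
class InteractionRecord:
    """One typed inter-group residue-pair contact in one frame."""

    frame_index: int
    pair: tuple[ResidueKey, ResidueKey]  # (groupA residue, groupB residue)
    itype: str
    atoms: tuple[str, ...]
    distance: float
    geometry: dict = field(default_factory=dict, compare=False, hash=False)

    @property
    def key(self):
        return (self.pair, self.itype)


def _group_mask(frame: Frame, chains) -> np.ndarray:
    return np.isin(frame.chain_id, list(chains))


def detect_interactions(frame: Frame, groupA, groupB,
                        criteria: InteractionCriteria | None = None,
                        roles: RoleAssignment | None = None,
                        his_cationic: bool = False) -> list[InteractionRecord]:
    """All typed inter-group contacts in one frame.

    ``groupA``/``groupB`` are disjoint chain-id sets; records are ordered
    (groupA residue, groupB residue) regardless of which side donates.
    One record per (pair, type); the reported distance is the closest
    qualifying one.
    """
    groupA, groupB = set(groupA), set(groupB)
    if not groupA or not groupB:
        raise ValueError("both chain groups must be nonempty")
    if groupA & groupB:
        raise ValueError(f"chain groups overlap: {sorted(groupA & groupB)}")
    if criteria is None:
        criteria = InteractionCriteria()
    if roles is None:
        roles = assign_roles(frame, his_cationic=his_cationic)

    in_a = _group_mask(frame, groupA)
    in_b = _group_mask(frame, groupB)
    coords = frame.coords
    reskeys = roles.residue_of_atom

    has_hydrogens = bool(np.any(frame.element == "H"))

    found: dict[tuple, InteractionRecord] = {}

    def emit(res_i: ResidueKey, res_j: ResidueKey, a_side_first: bool, itype: str,
             atoms: tuple, dist: float, geometry: dict):
        pair = (res_i, res_j) if a_side_first else (res_j, res_i)
        rec = InteractionRecord(frame.frame_index, pair, itype, atoms, dist, geometry)
        old = found.get(rec.key)
        if old is None or dist < old.distance:
            found[rec.key] = rec

    def cross(i: int, j: int):
        """True plus orientation if atoms i, j sit in opposite groups."""
        if in_a[i] and in_b[j]:
            return True, True
        if in_b[i] and in_a[j]:
            return True, False
        return False, None

    # --- hydrogen bonds ---------------------------------------------------
    no_h_donors = [d for d, h in roles.donors if h is None]
    if no_h_donors and criteria.hbond_heavy_fallback_max is None and not has_hydrogens:
        raise ConfigurationError(
            "structure has no hydrogens and hbond_heavy_fallback_max is unset")
    for d_idx, h_idx in roles.donors:
        for a_idx, ante_idx in roles.acceptors:
            inter, a_first = cross(d_idx, a_idx)
            if not inter or reskeys[d_idx] == reskeys[a_idx]:
                continue
            if h_idx is not None:
                ok, geom = detect_hbond(coords[d_idx], coords[h_idx],
                                        coords[a_idx], coords[ante_idx], criteria)
                names = (str(frame.name[d_idx]), str(frame.name[h_idx]),
                         str(frame.name[a_idx]))
            elif criteria.hbond_heavy_fallback_max is not None:
                d_da = float(np.linalg.norm(coords[a_idx] - coords[d_idx]))
                ok, geom = d_da <= criteria.hbond_heavy_fallback_max, {"distance": d_da}
                names = (str(frame.name[d_idx]), str(frame.name[a_idx]))
            else:
                continue
            if ok:
                ri, rj = reskeys[d_idx], reskeys[a_idx]
                if not a_first:
                    ri, rj = rj, ri
                    a_first = True
                emit(ri, rj, True, "hbond", names, geom["distance"], geom)

    # --- salt bridges -----------------------------------------------------
    if len(roles.anionic_o) and len(roles.cationic_n):
        d = cdist(coords[roles.anionic_o], coords[roles.cationic_n])
        for ii, jj in zip(*np.nonzero(d <= criteria.salt_bridge_max)):
            i, j = int(roles.anionic_o[ii]), int(roles.cationic_n[jj])
            inter, a_first = cross(i, j)
            if not inter:
                continue
            ri, rj = reskeys[i], reskeys[j]
            if not a_first:
                ri, rj = rj, ri
            emit(ri, rj, True, "salt_bridge",
                 (str(frame.name[i]), str(frame.name[j])), float(d[ii, jj]),
                 {"distance": float(d[ii, jj])})

    # --- hydrophobic ------------------------------------------------------
    hyd = roles.hydrophobic_c
    if len(hyd):
        hyd_a = hyd[in_a[hyd]]
        hyd_b = hyd[in_b[hyd]]
        if len(hyd_a) and len(hyd_b):
            d = cdist(coords[hyd_a], coords[hyd_b])
            for ii, jj in zip(*np.nonzero(d <= criteria.hydrophobic_cc_max)):
                i, j = int(hyd_a[ii]), int(hyd_b[jj])
                emit(reskeys[i], reskeys[j], True, "hydrophobic",
                     (str(frame.name[i]), str(frame.name[j])), float(d[ii, jj]),
                     {"distance": float(d[ii, jj])})

    # --- π-cation ---------------------------------------------------------
    for ring_key, ring_idx in roles.rings:
        ring_xyz = coords[list(ring_idx)]
        ring_in_a = bool(in_a[ring_idx[0]])
        ring_in_b = bool(in_b[ring_idx[0]])
        if not (ring_in_a or ring_in_b):
            continue
        for cat_key, cat_idx in roles.cation_centers:
            if isinstance(cat_idx, tuple):  # ring-center cation (cationic His)
                cat_xyz = coords[list(cat_idx[1:])].mean(axis=0)
                cat_atom_idx = cat_idx[1]
            else:
                cat_xyz = coords[cat_idx]
                cat_atom_idx = cat_idx
            cat_in_a = bool(in_a[cat_atom_idx])
            cat_in_b = bool(in_b[cat_atom_idx])
            if not ((ring_in_a and cat_in_b) or (ring_in_b and cat_in_a)):
                continue
            ok, geom = detect_pi_cation(ring_xyz, cat_xyz, criteria)
            if ok:
                if ring_in_a:
                    emit(ring_key, cat_key, True, "pi_cation",
                         (str(frame.name[ring_idx[0]]), "ring",
                          str(frame.name[cat_atom_idx])),
                         geom["distance"], geom)
                else:
                    emit(cat_key, ring_key, True, "pi_cation",
                         (str(frame.name[cat_atom_idx]), "ring",
                          str(frame.name[ring_idx[0]])),
                         geom["distance"], geom)

    return sorted(found.values(),
                  key=lambda r: (str(r.pair[0]), str(r.pair[1]), r.itype))


def detect_trajectory(trajectory, groupA, groupB,
                      criteria: InteractionCriteria | None = None,
                      his_cationic: bool = False) -> list[InteractionRecord]:
    """Concatenated records over all frames (roles computed per frame)."""
    records: list[InteractionRecord] = []
    for frame in trajectory.frames:
        records.extend(detect_interactions(frame, groupA, groupB, criteria,
                                           his_cationic=his_cationic))
    return records


def records_to_dataframe(records):
    """Tidy table: frame, chainA, resA, chainB, resB, type, distance."""
    import pandas as pd
    rows = [
        {
            "frame": r.frame_index,
            "chainA": r.pair[0].chain_id, "resA": f"{r.pair[0].res_name}{r.pair[0].res_seq}",
            "chainB": r.pair[1].chain_id, "resB": f"{r.pair[1].res_name}{r.pair[1].res_seq}",
            "type": r.itype, "distance": round(r.distance, 3),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["frame", "chainA", "resA", "chainB",
                                       "resB", "type", "distance"])


def criteria_from_config(path) -> InteractionCriteria:
    """Read criteria overrides from a flat ``key = value`` file."""
    overrides = {}
    fields = {f for f in InteractionCriteria.__dataclass_fields__}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"line {lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ConfigurationError(f"line {lineno}: unknown criterion {key!r}")
            overrides[key] = None if val.lower() == "none" else float(val)
    return InteractionCriteria(**overrides)
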