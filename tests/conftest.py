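"""Shared fixtures: synthetic complexes and brute-force oracles.

All structural fixtures are generated programmatically by the synthetic
module; the brute-force interaction checker re-derives records from first
principles (nested loops over residue pairs using the same role templates)
and serves as the independent oracle for the vectorised detector.
"""

import numpy as np
import pytest

from cardkit import synth
from cardkit.interactions import (InteractionCriteria, InteractionRecord,
                                  assign_roles, detect_hbond, detect_pi_cation)
from cardkit.structures import Frame


@pytest.fixture(scope="session")
def default_dimer():
    return synth.build_dimer()


@pytest.fixture(scope="session")
def mixed_dimer():
    """Five planted contacts covering all four interaction types."""
    spec = synth.DimerSpec(contacts=synth.default_contacts(5))
    return synth.build_dimer(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_toy_frame(rng, n_res_per_chain=6, separation=9.0) -> Frame:
    """Random small two-chain frame with charged/polar/apolar residues.

    Residues are placed with randomised side-chain-like atoms so that
    contacts of every type can arise by chance; geometry is deliberately
    arbitrary (the oracle and detector must agree on whatever it is).
    """
    menu = [
        ("ASP", [("CB", "C"), ("CG", "C"), ("OD1", "O"), ("OD2", "O")]),
        ("ARG", [("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"),
                 ("CZ", "C"), ("NH1", "N"), ("NH2", "N")]),
        ("LEU", [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C")]),
        ("SER", [("CB", "C"), ("OG", "O")]),
        ("LYS", [("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")]),
        ("PHE", [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C"),
                 ("CE1", "C"), ("CE2", "C"), ("CZ", "C")]),
        ("GLU", [("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")]),
        ("ILE", [("CB", "C"), ("CG1", "C"), ("CG2", "C"), ("CD1", "C")]),
    ]
    rows = {k: [] for k in ("serial", "name", "element", "alt_loc", "res_name",
                            "res_seq", "insertion_code", "chain_id", "coords",
                            "occupancy", "b_factor")}

    def add(chain, seq, res, name, element, xyz):
        rows["serial"].append(len(rows["serial"]) + 1)
        rows["name"].append(name)
        rows["element"].append(element)
        rows["alt_loc"].append("")
        rows["res_name"].append(res)
        rows["res_seq"].append(seq)
        rows["insertion_code"].append("")
        rows["chain_id"].append(chain)
        rows["coords"].append(xyz)
        rows["occupancy"].append(1.0)
        rows["b_factor"].append(0.0)

    ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    for chain, x0 in (("A", 0.0), ("B", separation)):
        for i in range(n_res_per_chain):
            res, sidechain = menu[rng.integers(len(menu))]
            base = np.array([x0, 4.0 * i, 0.0]) + rng.normal(scale=1.0, size=3)
            add(chain, i + 1, res, "N", "N", base + [0.0, -0.8, 0.5])
            add(chain, i + 1, res, "CA", "C", base)
            add(chain, i + 1, res, "C", "C", base + [0.6, 0.8, -0.4])
            add(chain, i + 1, res, "O", "O", base + [0.6, 0.8, 0.8])
            # side chain drifts toward the other chain with noise;
            # aromatic rings are placed as planar hexagons at a random
            # orientation (the detector requires planarity)
            toward = 1.0 if chain == "A" else -1.0
            for k, (name, element) in enumerate(sidechain):
                if res == "PHE" and name in ring_names:
                    continue
                xyz = base + np.array([toward * (1.0 + 1.2 * k), 0.0, 0.0]) \
                    + rng.normal(scale=1.2, size=3)
                add(chain, i + 1, res, name, element, xyz)
            if res == "PHE":
                centroid = base + np.array([toward * 3.0, 0.0, 0.0]) \
                    + rng.normal(scale=1.0, size=3)
                q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
                p1, p2 = q[:, 0], q[:, 1]
                for k, name in enumerate(ring_names):
                    th = np.radians(60.0 * k)
                    add(chain, i + 1, res, name, "C",
                        centroid + 1.39 * (np.cos(th) * p1 + np.sin(th) * p2))
    rows["coords"] = np.vstack(rows["coords"])
    return Frame(**rows)


def brute_force_records(frame: Frame, groupA, groupB,
                        criteria: InteractionCriteria):
    """Independent all-pairs record enumeration (set of (pairA, pairB, type)).

    Walks every donor/acceptor, anionic/cationic, carbon/carbon and
    ring/cation combination with plain Python loops and the primitive
    geometric tests, independent of the production detector's indexing.
    """
    roles = assign_roles(frame)
    res_of = roles.residue_of_atom
    coords = frame.coords
    in_a = np.isin(frame.chain_id, list(groupA))
    in_b = np.isin(frame.chain_id, list(groupB))

    def side(i):
        return "A" if in_a[i] else ("B" if in_b[i] else None)

    def ordered(i, j):
        si, sj = side(i), side(j)
        if si is None or sj is None or si == sj:
            return None
        return (res_of[i], res_of[j]) if si == "A" else (res_of[j], res_of[i])

    out = set()
    has_h = bool(np.any(frame.element == "H"))
    for d_idx, h_idx in roles.donors:
        for a_idx, ante_idx in roles.acceptors:
            pair = ordered(d_idx, a_idx)
            if pair is None or res_of[d_idx] == res_of[a_idx]:
                continue
            if h_idx is not None:
                ok, _ = detect_hbond(coords[d_idx], coords[h_idx],
                                     coords[a_idx], coords[ante_idx], criteria)
            elif criteria.hbond_heavy_fallback_max is not None:
                ok = (np.linalg.norm(coords[a_idx] - coords[d_idx])
                      <= criteria.hbond_heavy_fallback_max)
            else:
                ok = False
            if ok:
                out.add((pair[0], pair[1], "hbond"))
    for i in roles.anionic_o:
        for j in roles.cationic_n:
            pair = ordered(int(i), int(j))
            if pair is None:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= criteria.salt_bridge_max:
                out.add((pair[0], pair[1], "salt_bridge"))
    for i in roles.hydrophobic_c:
        for j in roles.hydrophobic_c:
            pair = ordered(int(i), int(j))
            if pair is None:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= criteria.hydrophobic_cc_max:
                out.add((pair[0], pair[1], "hydrophobic"))
    for ring_key, ring_idx in roles.rings:
        for cat_key, cat_idx in roles.cation_centers:
            if isinstance(cat_idx, tuple):
                cat_xyz = coords[list(cat_idx[1:])].mean(axis=0)
                cat_atom = cat_idx[1]
            else:
                cat_xyz = coords[cat_idx]
                cat_atom = cat_idx
            pair = ordered(ring_idx[0], cat_atom)
            if pair is None:
                continue
            ok, _ = detect_pi_cation(coords[list(ring_idx)], cat_xyz, criteria)
            if ok:
                out.add((pair[0], pair[1], "pi_cation"))
    return out


def record_set(records):
    return {(r.pair[0], r.pair[1], r.itype) for r in records}
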