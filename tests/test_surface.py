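"""SASA (analytic sphere oracles, cross-check), buried area, potential."""

import numpy as np
import pytest

from cardkit.structures import Frame
from cardkit.surface import (sasa, buried_sasa, surface_points,
                             coulomb_potential, ChargeRadiusModel,
                             golden_spiral_points, COULOMB_CONSTANT,
                             RadiusLookupError, SingularPointError)

R_C = 1.70
PROBE = 1.4
R = R_C + PROBE   # expanded sphere radius


def atoms_frame(positions, elements=None, res_name="ALA", names=None):
    n = len(positions)
    elements = elements or ["C"] * n
    names = names or [f"C{i}" for i in range(n)]
    return Frame(
        serial=np.arange(1, n + 1), name=names, element=elements,
        alt_loc=[""] * n, res_name=[res_name] * n, res_seq=[1] * n,
        insertion_code=[""] * n, chain_id=["A"] * n,
        coords=np.asarray(positions, float), occupancy=np.ones(n),
        b_factor=np.zeros(n))


def two_sphere_buried_analytic(d):
    """Closed-form lost area for two equal spheres of radius R at distance d."""
    if d >= 2 * R:
        return 0.0
    h = R - d / 2.0
    return 2 * (2 * np.pi * R * h)   # one cap lost per sphere


class TestSasa:
    def test_isolated_sphere_matches_analytic(self):
        s = sasa(atoms_frame([[0, 0, 0]]), probe=PROBE, n_points=960)
        analytic = 4 * np.pi * R ** 2
        assert abs(s.total - analytic) / analytic < 0.01

    def test_tangent_spheres_have_no_burial(self):
        d = 2 * R
        s = sasa(atoms_frame([[0, 0, 0], [d, 0, 0]]), probe=PROBE, n_points=960)
        assert s.total == pytest.approx(2 * 4 * np.pi * R ** 2, rel=0.01)

    @pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
    def test_overlapping_spheres_match_cap_formula(self, d):
        frame = atoms_frame([[0, 0, 0], [d, 0, 0]])
        lost = 2 * 4 * np.pi * R ** 2 - sasa(frame, probe=PROBE, n_points=960).total
        assert lost == pytest.approx(two_sphere_buried_analytic(d), rel=0.015)

    def test_monotone_under_added_atom(self):
        f2 = atoms_frame([[0, 0, 0], [3.0, 0, 0]])
        f3 = atoms_frame([[0, 0, 0], [3.0, 0, 0], [1.5, 2.0, 0]])
        s2 = sasa(f2, PROBE, 960).per_atom
        s3 = sasa(f3, PROBE, 960).per_atom[:2]
        assert np.all(s3 <= s2 + 1e-9)

    def test_deterministic(self):
        frame = atoms_frame([[0, 0, 0], [2.5, 0.5, -0.5]])
        assert sasa(frame, PROBE, 960).per_atom.tolist() == \
            sasa(frame, PROBE, 960).per_atom.tolist()

    def test_unknown_element_reports_atom(self):
        frame = atoms_frame([[0, 0, 0]], elements=["XX"])
        with pytest.raises(RadiusLookupError):
            sasa(frame, PROBE, 960)

    def test_cross_check_against_biotite(self, mixed_dimer):
        """Independent Shrake–Rupley implementation agrees on a real complex."""
        import biotite.structure as bst
        frame = mixed_dimer.frame
        heavy = frame.subset(frame.element != "H")
        ours = sasa(heavy, probe=1.4, n_points=1000).total
        arr = bst.AtomArray(len(heavy))
        arr.coord = heavy.coords.astype(np.float32)
        arr.chain_id = heavy.chain_id
        arr.res_id = heavy.res_seq
        arr.res_name = heavy.res_name
        arr.atom_name = heavy.name
        arr.element = heavy.element
        theirs = float(np.nansum(bst.sasa(arr, probe_radius=1.4, point_number=1000,
                                          vdw_radii="Single")))
        assert ours == pytest.approx(theirs, rel=0.03)


class TestBuried:
    def test_far_chains_bury_nothing(self):
        a = atoms_frame([[0, 0, 0]])
        b = atoms_frame([[50.0, 0, 0]], names=["C9"])
        assert buried_sasa(a, b, PROBE, 960) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self, mixed_dimer):
        frame = mixed_dimer.frame
        fa = frame.subset((frame.chain_id == "A") & (frame.element != "H"))
        fb = frame.subset((frame.chain_id == "B") & (frame.element != "H"))
        ab = buried_sasa(fa, fb, PROBE, 400)
        ba = buried_sasa(fb, fa, PROBE, 400)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert ab > 0

    def test_half_is_half_of_full(self):
        a = atoms_frame([[0, 0, 0]])
        b = atoms_frame([[3.0, 0, 0]], names=["C9"])
        full = buried_sasa(a, b, PROBE, 960, convention="full_sum")
        half = buried_sasa(a, b, PROBE, 960, convention="half_sum")
        assert full == pytest.approx(2 * half)
        assert full == pytest.approx(two_sphere_buried_analytic(3.0), rel=0.015)

    def test_monotone_on_approach(self):
        a = atoms_frame([[0, 0, 0]])
        prev = -1.0
        for d in (6.0, 5.0, 4.0, 3.0):
            b = atoms_frame([[d, 0, 0]], names=["C9"])
            cur = buried_sasa(a, b, PROBE, 960)
            assert cur >= prev - 1e-9
            prev = cur

    def test_shared_atoms_rejected(self):
        a = atoms_frame([[0, 0, 0]])
        with pytest.raises(ValueError):
            buried_sasa(a, a, PROBE, 960)


class TestSurfacePoints:
    def test_isolated_atom_keeps_all_points(self):
        pts = surface_points(atoms_frame([[0, 0, 0]]), PROBE, n_points=240)
        assert len(pts) == 240
        assert np.allclose(np.linalg.norm(pts, axis=1), R, atol=1e-9)

    def test_buried_atom_contributes_none(self):
        # center atom fully enclosed by a tight shell of neighbours
        shell = golden_spiral_points(40) * 1.8
        frame = atoms_frame(np.vstack([[0, 0, 0], shell]))
        s = sasa(frame, PROBE, 400)
        assert s.per_atom[0] == 0.0


class TestPotential:
    def test_unit_charge_definition(self):
        frame = atoms_frame([[0, 0, 0]], elements=["N"], res_name="LYS",
                            names=["NZ"])
        model = ChargeRadiusModel(epsilon=1.0)
        pm = coulomb_potential([[1.0, 0, 0]], frame, model)
        assert pm.phi[0] == pytest.approx(COULOMB_CONSTANT)

    def test_dipole_midpoint_is_zero(self):
        frame = atoms_frame([[0, 0, 0], [2.0, 0, 0]],
                            elements=["O", "N"], res_name="ASP",
                            names=["OD1", "NZ"])
        # override: one -1, one +1
        model = ChargeRadiusModel(charges={("ASP", "OD1"): -1.0,
                                           ("ASP", "NZ"): +1.0}, epsilon=1.0)
        pm = coulomb_potential([[1.0, 0, 0]], frame, model)
        assert pm.phi[0] == pytest.approx(0.0, abs=1e-12)

    def test_random_configs_match_direct_sum(self, rng):
        n = 20
        coords = rng.normal(scale=5, size=(n, 3))
        charges = rng.choice([-0.5, 0.0, 0.5, 1.0], size=n)
        frame = atoms_frame(coords, elements=["N"] * n, res_name="XXX",
                            names=[f"N{i}" for i in range(n)])
        model = ChargeRadiusModel(
            charges={("XXX", f"N{i}"): float(charges[i]) for i in range(n)},
            epsilon=4.0)
        points = rng.normal(scale=12, size=(15, 3)) + 20.0
        pm = coulomb_potential(points, frame, model)
        for p, phi in zip(points, pm.phi):
            direct = COULOMB_CONSTANT * sum(
                q / (4.0 * np.linalg.norm(p - c))
                for q, c in zip(charges, coords))
            assert phi == pytest.approx(direct, rel=1e-10)

    def test_linearity_and_sign_antisymmetry(self, rng):
        coords = rng.normal(scale=4, size=(5, 3))
        frame = atoms_frame(coords, elements=["O"] * 5, res_name="GLU",
                            names=[f"O{i}" for i in range(5)])
        q = {("GLU", f"O{i}"): float(v)
             for i, v in enumerate(rng.uniform(-1, 1, 5))}
        neg = {k: -v for k, v in q.items()}
        pts = rng.normal(scale=10, size=(4, 3)) + 15
        a = coulomb_potential(pts, frame, ChargeRadiusModel(charges=q)).phi
        b = coulomb_potential(pts, frame, ChargeRadiusModel(charges=neg)).phi
        assert np.allclose(a, -b, atol=1e-12)

    def test_singular_point_rejected(self):
        frame = atoms_frame([[0, 0, 0]])
        with pytest.raises(SingularPointError):
            coulomb_potential([[0, 0, 0]], frame)
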