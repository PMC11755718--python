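"""Synthetic two-chain complexes with planted, verifiable ground truth.

The generator emulates the geometry of a two-helix-bundle CARD–CARD
interface at the level the analysis stages care about: an ideal α-helix
backbone per chain (1.5 Å rise, 100°/residue, 2.3 Å Cα radius), schematic
template side chains placed so that each planted contact satisfies its
interaction type's geometric criteria with margin, trajectories whose
contact presence follows a programmed per-frame schedule, pose ensembles
drawn from a known number of rigid-transform clusters, and seeded numeric
samples for the statistics stage.

Every planted contact is verified against the interaction detector before
a structure is returned, so generator and analyzer are in closure by
construction: what the generator plants is exactly what the detector must
recover.  No physical force field is involved — side chains are placed
geometrically, which is a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Frame, Trajectory, ResidueKey
from .geometry import RigidTransform
from .interactions import InteractionCriteria, detect_interactions

HELIX_RISE = 1.5          # Å per residue
HELIX_TWIST = 100.0       # degrees per residue
HELIX_CA_RADIUS = 2.3     # Å

#: planted geometry per type: (residue for chain A, residue for chain B, target distance Å)
_CONTACT_TEMPLATES = {
    "salt_bridge": ("ASP", "ARG", 3.0),
    "hbond": ("SER", "ASN", 2.0),       # H···acceptor distance
    "hydrophobic": ("LEU", "ILE", 4.0),
    "pi_cation": ("TYR", "ARG", 4.5),   # ring centroid to cation center
}


class BuildError(Exception):
    pass


class GenerationError(Exception):
    pass


@dataclass(frozen=True)
class PlantedContact:
    res_a: int          # residue index within chain A (0-based)
    res_b: int          # residue index within chain B
    itype: str

    def __post_init__(self):
        if self.itype not in _CONTACT_TEMPLATES:
            raise ValueError(f"unknown interaction type {self.itype!r}")


@dataclass
class DimerSpec:
    chain_a_length: int = 24
    chain_b_length: int = 24
    contacts: tuple[PlantedContact, ...] = ()
    separation: float = 13.0      # inter-axis distance, Å
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)
    chain_a_id: str = "A"
    chain_b_id: str = "B"


@dataclass
class Dimer:
    frame: Frame
    spec: DimerSpec
    contact_pairs: list          # (ResidueKey A, ResidueKey B, itype)
    mobile_atoms: list           # per contact: B-side side-chain atom indices


def default_contacts(n: int = 5) -> tuple[PlantedContact, ...]:
    """A mixed-type contact set spread along the interface."""
    types = ["salt_bridge", "hbond", "hydrophobic", "pi_cation", "salt_bridge",
             "hydrophobic", "hbond"]
    return tuple(PlantedContact(3 + 4 * k, 3 + 4 * k, types[k % len(types)])
                 for k in range(n))


# ---------------------------------------------------------------------------
# structure assembly


class _FrameBuilder:
    def __init__(self):
        self.rows = {k: [] for k in ("serial", "name", "element", "alt_loc",
                                     "res_name", "res_seq", "insertion_code",
                                     "chain_id", "coords", "occupancy", "b_factor")}

    def add(self, chain, res_seq, res_name, name, element, xyz):
        r = self.rows
        r["serial"].append(len(r["serial"]) + 1)
        r["name"].append(name)
        r["element"].append(element)
        r["alt_loc"].append("")
        r["res_name"].append(res_name)
        r["res_seq"].append(res_seq)
        r["insertion_code"].append("")
        r["chain_id"].append(chain)
        r["coords"].append(np.asarray(xyz, dtype=float))
        r["occupancy"].append(1.0)
        r["b_factor"].append(0.0)
        return len(r["serial"]) - 1

    def build(self) -> Frame:
        return Frame(**{k: (np.vstack(v) if k == "coords" else v)
                        for k, v in self.rows.items()})


def _helix_backbone(builder, chain_id, n_res, origin, res_names):
    """Ideal-helix backbone with amide H; returns CA positions."""
    origin = np.asarray(origin, dtype=float)
    cas = []
    for i in range(n_res):
        phi = np.radians(HELIX_TWIST * i)
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        z = np.array([0.0, 0.0, HELIX_RISE * i])
        ca = origin + HELIX_CA_RADIUS * radial + z
        n_pos = origin + 1.6 * np.array([np.cos(phi - 0.45), np.sin(phi - 0.45), 0]) \
            + z + np.array([0, 0, -0.9])
        c_pos = origin + 1.7 * np.array([np.cos(phi + 0.45), np.sin(phi + 0.45), 0]) \
            + z + np.array([0, 0, 0.7])
        o_pos = c_pos + np.array([0, 0, 1.23])
        h_pos = n_pos + np.array([0, 0, -1.0])
        res = res_names[i]
        seq = i + 1
        builder.add(chain_id, seq, res, "N", "N", n_pos)
        if res != "PRO":
            builder.add(chain_id, seq, res, "H", "H", h_pos)
        builder.add(chain_id, seq, res, "CA", "C", ca)
        builder.add(chain_id, seq, res, "C", "C", c_pos)
        builder.add(chain_id, seq, res, "O", "O", o_pos)
        cas.append(ca)
    return cas


def _perp_frame(u):
    """Two unit vectors orthogonal to u and to each other."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(u, ref)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(u, p1)
    return p1, p2


def _place_contact(builder, chain_a, chain_b, seq_a, seq_b, itype, ca_a, ca_b,
                   criteria: InteractionCriteria):
    """Place schematic side chains realising one contact; returns mobile atom idx."""
    res_a, res_b, d_target = _CONTACT_TEMPLATES[itype]
    gap = ca_b - ca_a
    g = float(np.linalg.norm(gap))
    u = gap / g
    p1, p2 = _perp_frame(u)
    arm = (g - d_target) / 2.0
    if arm < 2.5:
        raise BuildError(f"chains too close to plant {itype} (arm {arm:.1f} Å)")
    key_a = ca_a + arm * u                 # A-side key position
    key_b = key_a + d_target * u           # B-side key position
    mobile = []
    planted = []

    def A(name, element, xyz):
        i = builder.add(chain_a, seq_a, res_a, name, element, xyz)
        planted.append(i)
        return i

    def B(name, element, xyz):
        i = builder.add(chain_b, seq_b, res_b, name, element, xyz)
        planted.append(i)
        mobile.append(i)
        return i

    if itype == "salt_bridge":            # ASP(A) OD1 ··· ARG(B) NH1
        A("CB", "C", ca_a + 0.35 * arm * u + 0.4 * p1)
        A("CG", "C", ca_a + 0.72 * arm * u)
        A("OD1", "O", key_a)
        A("OD2", "O", key_a - 0.5 * u + 1.1 * p1)
        B("CB", "C", ca_b - 0.30 * arm * u + 0.4 * p1)
        B("CG", "C", ca_b - 0.52 * arm * u)
        B("CD", "C", ca_b - 0.74 * arm * u)
        ne = B("NE", "N", key_b + 2.4 * u + 0.4 * p1)
        B("HE", "H", builder.rows["coords"][ne] + 1.0 * p2)
        cz = B("CZ", "C", key_b + 1.2 * u)
        B("NH1", "N", key_b)
        B("HH11", "H", key_b + 1.0 * p2)
        B("HH12", "H", key_b - 1.0 * p2)
        nh2 = B("NH2", "N", builder.rows["coords"][cz] + 1.2 * p1)
        B("HH21", "H", builder.rows["coords"][nh2] + 1.0 * p2)
        B("HH22", "H", builder.rows["coords"][nh2] - 1.0 * p2)
    elif itype == "hbond":                # SER(A) OG–HG ··· OD1=CG ASN(B)
        A("CB", "C", ca_a + 0.5 * arm * u + 0.4 * p1)
        A("OG", "O", key_a)
        A("HG", "H", key_a + 0.96 * u)
        # acceptor O at 0.96 + d_target from OG along u
        acc = key_a + (0.96 + d_target) * u
        B("OD1", "O", acc)
        B("CG", "C", acc + 1.40 * u)
        B("CB", "C", acc + 2.70 * u + 0.3 * p1)
        nd2 = B("ND2", "N", acc + 1.40 * u + 1.3 * p1)
        B("HD21", "H", builder.rows["coords"][nd2] + 1.0 * p1)
        B("HD22", "H", builder.rows["coords"][nd2] + 1.0 * p2)
    elif itype == "hydrophobic":          # LEU(A) CD1 ··· CD1 ILE(B)
        A("CB", "C", ca_a + 0.35 * arm * u + 0.4 * p1)
        A("CG", "C", ca_a + 0.70 * arm * u)
        A("CD1", "C", key_a)
        A("CD2", "C", key_a - 0.8 * u + 1.3 * p1)
        B("CD1", "C", key_b)
        B("CG1", "C", key_b + 1.5 * u)
        B("CG2", "C", key_b + 1.5 * u + 1.3 * p1)
        B("CB", "C", key_b + 2.8 * u)
    elif itype == "pi_cation":            # TYR(A) ring ··· CZ ARG(B)
        ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        centroid = key_a
        ring_pos = {}
        for k, nm in enumerate(ring_names):
            th = np.radians(60.0 * k)
            ring_pos[nm] = centroid + 1.39 * (np.cos(th) * p1 + np.sin(th) * p2)
            A(nm, "C", ring_pos[nm])
        A("CB", "C", ring_pos["CG"] + 1.5 * p1)
        oh = A("OH", "O", ring_pos["CZ"] - 1.3 * p1)
        A("HH", "H", builder.rows["coords"][oh] + 0.96 * p2)
        cat = key_b  # guanidinium center CZ
        B("CB", "C", cat + 3.4 * u + 0.4 * p1)
        B("CG", "C", cat + 2.9 * u)
        B("CD", "C", cat + 2.4 * u)
        ne = B("NE", "N", cat + 1.2 * u + 0.4 * p1)
        B("HE", "H", builder.rows["coords"][ne] + 1.0 * p2)
        B("CZ", "C", cat)
        nh1 = B("NH1", "N", cat + 1.2 * p1)
        B("HH11", "H", builder.rows["coords"][nh1] + 1.0 * p2)
        B("HH12", "H", builder.rows["coords"][nh1] - 1.0 * p2)
        nh2 = B("NH2", "N", cat - 1.2 * p1)
        B("HH21", "H", builder.rows["coords"][nh2] + 1.0 * p2)
        B("HH22", "H", builder.rows["coords"][nh2] - 1.0 * p2)
    return planted, mobile


def build_dimer(spec: DimerSpec | None = None) -> Dimer:
    """Build a two-chain all-atom complex realising every planted contact.

    The returned structure is verified with the interaction detector: each
    planted (pair, type) must be detected, and no planted pair may be
    missing.  Raises :class:`BuildError` on unsatisfiable geometry or on
    steric clashes (< 2 Å between non-contact inter-chain atoms).
    """
    if spec is None:
        spec = DimerSpec(contacts=default_contacts())
    for c in spec.contacts:
        if not (0 <= c.res_a < spec.chain_a_length):
            raise BuildError(f"contact residue {c.res_a} outside chain A")
        if not (0 <= c.res_b < spec.chain_b_length):
            raise BuildError(f"contact residue {c.res_b} outside chain B")
    if len({c.res_a for c in spec.contacts}) != len(spec.contacts) or \
       len({c.res_b for c in spec.contacts}) != len(spec.contacts):
        raise BuildError("each residue may carry at most one planted contact")

    res_a_names = ["GLY"] * spec.chain_a_length
    res_b_names = ["GLY"] * spec.chain_b_length
    for c in spec.contacts:
        ra, rb, _ = _CONTACT_TEMPLATES[c.itype]
        res_a_names[c.res_a] = ra
        res_b_names[c.res_b] = rb

    builder = _FrameBuilder()
    ca_a = _helix_backbone(builder, spec.chain_a_id, spec.chain_a_length,
                           (0.0, 0.0, 0.0), res_a_names)
    ca_b = _helix_backbone(builder, spec.chain_b_id, spec.chain_b_length,
                           (spec.separation, 0.0, 0.0), res_b_names)

    contact_pairs, mobile_atoms, planted_sets = [], [], []
    for c in spec.contacts:
        planted, mobile = _place_contact(
            builder, spec.chain_a_id, spec.chain_b_id,
            c.res_a + 1, c.res_b + 1, c.itype, ca_a[c.res_a], ca_b[c.res_b],
            spec.criteria)
        ra, rb, _ = _CONTACT_TEMPLATES[c.itype]
        contact_pairs.append((
            ResidueKey(spec.chain_a_id, c.res_a + 1, "", ra),
            ResidueKey(spec.chain_b_id, c.res_b + 1, "", rb),
            c.itype))
        mobile_atoms.append(mobile)
        planted_sets.append(set(planted))

    frame = builder.build()
    frame.check_unique_identity()
    _check_clashes(frame, spec, planted_sets)
    _verify_contacts(frame, spec, contact_pairs,
                     present=[True] * len(contact_pairs))
    return Dimer(frame=frame, spec=spec, contact_pairs=contact_pairs,
                 mobile_atoms=mobile_atoms)


def _check_clashes(frame: Frame, spec: DimerSpec, planted_sets, min_dist=2.0):
    """Reject inter-chain clashes, exempting atom pairs of one planted contact
    (the planted geometry itself may legitimately approach the cutoff)."""
    from scipy.spatial.distance import cdist
    idx_a = np.flatnonzero(frame.chain_id == spec.chain_a_id)
    idx_b = np.flatnonzero(frame.chain_id == spec.chain_b_id)
    d = cdist(frame.coords[idx_a], frame.coords[idx_b])
    for ii, jj in zip(*np.nonzero(d < min_dist)):
        ia, ib = int(idx_a[ii]), int(idx_b[jj])
        if any(ia in ps and ib in ps for ps in planted_sets):
            continue
        raise BuildError(
            f"inter-chain clash {frame.residue_key(ia)}/{frame.name[ia]} — "
            f"{frame.residue_key(ib)}/{frame.name[ib]} at {d[ii, jj]:.2f} Å")


def _verify_contacts(frame: Frame, spec: DimerSpec, contact_pairs, present):
    records = detect_interactions(frame, {spec.chain_a_id}, {spec.chain_b_id},
                                  spec.criteria)
    got = {(r.pair[0], r.pair[1], r.itype) for r in records}
    for (ka, kb, t), want in zip(contact_pairs, present):
        if want and (ka, kb, t) not in got:
            raise GenerationError(f"planted contact not detected: {ka}–{kb} {t}")
        if not want and (ka, kb, t) in got:
            raise GenerationError(f"broken contact still detected: {ka}–{kb} {t}")


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectorySpec:
    """Per-contact presence schedules over a fixed-step trajectory.

    ``schedules``: one entry per planted contact — ``True`` (always
    present), a float p in (0,1] (independent Bernoulli presence per
    frame), or ``("break_at", f)`` (present before frame f, broken from f
    on).  Rigid-body jitter is applied to the whole complex so planted
    geometries are preserved exactly.
    """

    n_frames: int = 100
    dt_ns: float = 3.0
    schedules: tuple = ()
    jitter_translation: float = 0.1    # Å, whole-complex
    jitter_rotation_deg: float = 1.0   # whole-complex
    seed: int = 0
    verify: bool = True


def presence_matrix(spec: TrajectorySpec, n_contacts: int,
                    rng: np.random.Generator) -> np.ndarray:
    schedules = spec.schedules or (True,) * n_contacts
    if len(schedules) != n_contacts:
        raise GenerationError("one schedule per planted contact required")
    present = np.ones((spec.n_frames, n_contacts), dtype=bool)
    for j, sched in enumerate(schedules):
        if sched is True:
            continue
        if isinstance(sched, (int, float)) and not isinstance(sched, bool):
            p = float(sched)
            if not 0 < p <= 1:
                raise GenerationError(f"bernoulli p out of range: {p}")
            present[:, j] = rng.random(spec.n_frames) < p
        elif isinstance(sched, tuple) and sched[0] == "break_at":
            present[int(sched[1]):, j] = False
        else:
            raise GenerationError(f"unrecognised schedule: {sched!r}")
    return present


def _random_rigid(rng: np.random.Generator, trans_sigma: float,
                  rot_sigma_deg: float, about: np.ndarray) -> RigidTransform:
    from scipy.spatial.transform import Rotation
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.normal(scale=rot_sigma_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.normal(scale=trans_sigma, size=3)
    # rotate about the given pivot, then translate
    return RigidTransform(R, about - R @ about + t)


def build_trajectory(dimer: Dimer, spec: TrajectorySpec | None = None):
    """Trajectory realising each contact exactly when its schedule says so.

    A broken contact displaces the mobile (chain-B) side chain well beyond
    1.5× the largest cutoff; whole-complex rigid jitter is added per frame.
    Returns (Trajectory, presence matrix of shape n_frames × n_contacts).
    """
    if spec is None:
        spec = TrajectorySpec()
    rng = np.random.default_rng(spec.seed)
    n_contacts = len(dimer.contact_pairs)
    present = presence_matrix(spec, n_contacts, rng)

    base = dimer.frame
    u = np.array([1.0, 0.0, 0.0])  # interface axis: chain A at x=0, B at x=sep
    delta = 1.5 * dimer.spec.criteria.pication_max
    pivot = base.coords.mean(axis=0)

    frames = []
    for f in range(spec.n_frames):
        coords = base.coords.copy()
        for j in np.flatnonzero(~present[f]):
            coords[dimer.mobile_atoms[j]] += delta * u
        jig = _random_rigid(rng, spec.jitter_translation,
                            spec.jitter_rotation_deg, pivot)
        coords = jig.apply(coords)
        frames.append(base.with_coords(coords, frame_index=f,
                                       time_ns=f * spec.dt_ns))
        if spec.verify:
            _verify_contacts(frames[-1], dimer.spec, dimer.contact_pairs,
                             present[f])
    return Trajectory(frames=frames), present


# ---------------------------------------------------------------------------
# pose ensembles


@dataclass
class PoseEnsembleSpec:
    n_clusters: int = 3
    poses_per_cluster: int = 10
    engines: tuple = ("engineA", "engineB", "engineC", "engineD", "engineE")
    cluster_translation: float = 15.0   # Å between cluster centers
    cluster_rotation_deg: float = 50.0  # between clusters
    jitter_translation: float = 0.5     # within-cluster σ, Å
    jitter_rotation_deg: float = 2.0    # within-cluster σ
    seed: int = 0

    @property
    def separation_ratio(self) -> float:
        within = max(self.jitter_translation, 1e-9)
        return self.cluster_translation / within


def build_pose_ensemble(dimer: Dimer, spec: PoseEnsembleSpec | None = None):
    """Pose set drawn from K planted rigid-transform clusters of the ligand.

    The receptor chain stays fixed; the ligand chain is moved by one of K
    well-separated rigid transforms plus within-cluster jitter.  Returns
    (list of Frames, engine labels, true cluster labels).  Warns when the
    separation ratio drops below 2.
    """
    import logging
    if spec is None:
        spec = PoseEnsembleSpec()
    if spec.n_clusters < 2:
        raise ValueError("need K >= 2 planted clusters")
    if spec.separation_ratio < 2:
        logging.getLogger(__name__).warning(
            "separation ratio %.1f < 2: cluster recovery may be unstable",
            spec.separation_ratio)
    rng = np.random.default_rng(spec.seed)
    base = dimer.frame
    ligand_mask = base.chain_id == dimer.spec.chain_b_id
    pivot = base.coords[ligand_mask].mean(axis=0)

    from scipy.spatial.transform import Rotation
    # deterministic cluster transforms: full-magnitude translations along
    # well-spread directions, plus distinct rotations, so the planted
    # between-cluster separation honours the requested ratio
    directions = golden_directions(spec.n_clusters)
    cluster_tf = []
    for k in range(spec.n_clusters):
        axis = directions[(k + 1) % spec.n_clusters]
        R = Rotation.from_rotvec(
            np.radians(spec.cluster_rotation_deg * (k + 1)) * axis).as_matrix()
        t = spec.cluster_translation * directions[k]
        cluster_tf.append(RigidTransform(R, pivot - R @ pivot + t))

    poses, engines, labels = [], [], []
    idx = 0
    for k, tf in enumerate(cluster_tf):
        for _ in range(spec.poses_per_cluster):
            jig = _random_rigid(rng, spec.jitter_translation,
                                spec.jitter_rotation_deg, pivot)
            coords = base.coords.copy()
            coords[ligand_mask] = jig.apply(tf.apply(coords[ligand_mask]))
            poses.append(base.with_coords(coords, frame_index=idx))
            engines.append(spec.engines[idx % len(spec.engines)])
            labels.append(k)
            idx += 1
    return poses, engines, np.asarray(labels)


def golden_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (deterministic golden-spiral directions)."""
    from .surface import golden_spiral_points
    return golden_spiral_points(max(n, 2))[:n]


# ---------------------------------------------------------------------------
# numeric samples


def sample_distribution(kind: str, params: dict, n: int, seed: int) -> np.ndarray:
    """Seeded draws from normal / uniform / lognormal distributions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "normal":
        return rng.normal(params.get("loc", 0.0), _positive(params.get("scale", 1.0)), n)
    if kind == "uniform":
        lo, hi = params.get("low", 0.0), params.get("high", 1.0)
        if hi <= lo:
            raise ValueError("uniform needs high > low")
        return rng.uniform(lo, hi, n)
    if kind == "lognormal":
        return rng.lognormal(params.get("mean", 0.0),
                             _positive(params.get("sigma", 1.0)), n)
    raise ValueError(f"unknown distribution kind {kind!r}")


def _positive(v: float) -> float:
    if v <= 0:
        raise ValueError("scale parameters must be positive")
    return float(v)
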