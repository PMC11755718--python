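"""Coordinate data model and multi-model PDB reading/writing.

The in-memory model is a struct-of-arrays :class:`Frame` (one conformation)
and a :class:`Trajectory` (an ordered list of frames, e.g. the MODEL blocks
of a multi-model PDB file).  Reading resolves alternate locations with the
highest-occupancy convention used when preparing crystal structures: for
atoms with multiple occupancies, the position maintaining the highest
occupancy is kept (ties broken by the lowest altloc letter).

Parsing and serialisation are delegated to biotite's PDB support; this
module owns the altloc policy, hetero filtering, selection semantics and
the identity invariants downstream stages rely on.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile


class StructureError(Exception):
    """Base class for structure-model errors."""


class ParseError(StructureError):
    """Raised when a PDB file cannot be parsed; carries a line number when known."""


class EmptyStructureError(StructureError):
    pass


class EmptySelectionError(StructureError):
    pass


class FormatError(StructureError):
    pass


BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: waters and common ions excluded from analysis by default
_SOLVENT_RES = frozenset({"HOH", "WAT", "DOD", "NA", "CL", "K", "MG", "CA", "ZN", "SO4", "PO4"})


@dataclass(frozen=True)
class ResidueKey:
    """Hashable identity of one residue (author numbering, no renumbering)."""

    chain_id: str
    res_seq: int
    insertion_code: str = ""
    res_name: str = ""

    def __str__(self) -> str:  # e.g. "A:ASP27"
        return f"{self.chain_id}:{self.res_name}{self.res_seq}{self.insertion_code}"


@dataclass(frozen=True)
class Atom:
    """Lightweight per-atom view; the canonical storage is array-based in Frame."""

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    res_seq: int
    insertion_code: str
    chain_id: str
    coords: np.ndarray
    occupancy: float
    b_factor: float


class Frame:
    """One conformation: parallel arrays over atoms, in file order."""

    __slots__ = (
        "serial", "name", "element", "alt_loc", "res_name", "res_seq",
        "insertion_code", "chain_id", "coords", "occupancy", "b_factor",
        "frame_index", "time_ns",
    )

    def __init__(self, *, serial, name, element, alt_loc, res_name, res_seq,
                 insertion_code, chain_id, coords, occupancy, b_factor,
                 frame_index=0, time_ns=None):
        n = len(name)
        self.serial = np.asarray(serial, dtype=int)
        self.name = np.asarray(name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.alt_loc = np.asarray(alt_loc, dtype="U1")
        self.res_name = np.asarray(res_name, dtype="U3")
        self.res_seq = np.asarray(res_seq, dtype=int)
        self.insertion_code = np.asarray(insertion_code, dtype="U1")
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.occupancy = np.asarray(occupancy, dtype=float)
        self.b_factor = np.asarray(b_factor, dtype=float)
        self.frame_index = int(frame_index)
        self.time_ns = time_ns
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.name)

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serial[i]), name=str(self.name[i]),
            element=str(self.element[i]), alt_loc=str(self.alt_loc[i]),
            res_name=str(self.res_name[i]), res_seq=int(self.res_seq[i]),
            insertion_code=str(self.insertion_code[i]),
            chain_id=str(self.chain_id[i]), coords=self.coords[i].copy(),
            occupancy=float(self.occupancy[i]), b_factor=float(self.b_factor[i]),
        )

    def __iter__(self):
        return (self.atom(i) for i in range(len(self)))

    def residue_key(self, i: int) -> ResidueKey:
        return ResidueKey(str(self.chain_id[i]), int(self.res_seq[i]),
                          str(self.insertion_code[i]), str(self.res_name[i]))

    def identity_tuples(self) -> list[tuple]:
        """(chain, res_seq, icode, atom name) per atom — the topology identity."""
        return list(zip(self.chain_id.tolist(), self.res_seq.tolist(),
                        self.insertion_code.tolist(), self.name.tolist()))

    def residue_keys(self) -> list[ResidueKey]:
        """Unique residues in order of first appearance."""
        seen: dict[ResidueKey, None] = {}
        for i in range(len(self)):
            seen.setdefault(self.residue_key(i), None)
        return list(seen)

    def subset(self, mask_or_indices) -> "Frame":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Frame(
            serial=self.serial[idx], name=self.name[idx],
            element=self.element[idx], alt_loc=self.alt_loc[idx],
            res_name=self.res_name[idx], res_seq=self.res_seq[idx],
            insertion_code=self.insertion_code[idx], chain_id=self.chain_id[idx],
            coords=self.coords[idx], occupancy=self.occupancy[idx],
            b_factor=self.b_factor[idx], frame_index=self.frame_index,
            time_ns=self.time_ns,
        )

    def with_coords(self, coords: np.ndarray, frame_index: int | None = None,
                    time_ns=None) -> "Frame":
        f = self.subset(np.arange(len(self)))
        f.coords = np.asarray(coords, dtype=float).reshape(len(self), 3)
        if frame_index is not None:
            f.frame_index = int(frame_index)
        f.time_ns = time_ns if time_ns is not None else self.time_ns
        return f

    def check_unique_identity(self) -> None:
        ids = self.identity_tuples()
        if len(set(ids)) != len(ids):
            dup = sorted({t for t in ids if ids.count(t) > 1})[:3]
            raise StructureError(f"duplicate atom identities after altloc resolution: {dup}")


@dataclass
class Trajectory:
    """Ordered frames; ``topology_constant`` means identical atom identity lists."""

    frames: list[Frame]
    topology_constant: bool = field(default=True)

    def __post_init__(self):
        if self.frames:
            ref = self.frames[0].identity_tuples()
            self.topology_constant = all(f.identity_tuples() == ref for f in self.frames[1:])
        times = self.times
        if times is not None and len(times) > 1 and not np.all(np.diff(times) > 0):
            raise StructureError("time_ns must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self):
        ts = [f.time_ns for f in self.frames]
        if any(t is None for t in ts):
            return None
        return np.asarray(ts, dtype=float)

    def set_times(self, times) -> "Trajectory":
        times = np.asarray(times, dtype=float)
        if len(times) != len(self.frames):
            raise StructureError("one time stamp per frame required")
        for f, t in zip(self.frames, times):
            f.time_ns = float(t)
        return self


# ---------------------------------------------------------------------------
# reading / writing


def _resolve_altloc(frame: Frame, policy: str) -> Frame:
    """Keep exactly one altloc variant per atom identity.

    ``highest_occupancy``: keep the variant with maximal occupancy, ties by the
    lowest altloc letter. ``first``: keep the first variant in file order.
    """
    ids = frame.identity_tuples()
    keep: dict[tuple, int] = {}
    for i, key in enumerate(ids):
        if key not in keep:
            keep[key] = i
            continue
        if policy == "first":
            continue
        j = keep[key]
        better = (round(float(frame.occupancy[i]), 6), _altloc_rank(frame.alt_loc[i]))
        incumbent = (round(float(frame.occupancy[j]), 6), _altloc_rank(frame.alt_loc[j]))
        # maximise occupancy, then minimise altloc letter
        if better[0] > incumbent[0] or (better[0] == incumbent[0] and better[1] < incumbent[1]):
            keep[key] = i
    idx = np.array(sorted(keep.values()))
    return frame.subset(idx)


def _altloc_rank(letter: str) -> int:
    letter = str(letter).strip()
    return string.ascii_uppercase.index(letter) if letter in string.ascii_uppercase else -1


def _frame_from_atom_array(arr: bst.AtomArray, frame_index: int) -> Frame:
    n = arr.array_length()
    serial = (arr.get_annotation("atom_id") if "atom_id" in arr.get_annotation_categories()
              else np.arange(1, n + 1))
    occ = (arr.get_annotation("occupancy") if "occupancy" in arr.get_annotation_categories()
           else np.ones(n))
    bf = (arr.get_annotation("b_factor") if "b_factor" in arr.get_annotation_categories()
          else np.zeros(n))
    alt = (arr.get_annotation("altloc_id") if "altloc_id" in arr.get_annotation_categories()
           else np.full(n, ""))
    alt = np.char.strip(np.char.replace(alt.astype("U1"), ".", ""))
    return Frame(
        serial=serial, name=arr.atom_name, element=arr.element, alt_loc=alt,
        res_name=arr.res_name, res_seq=arr.res_id, insertion_code=arr.ins_code,
        chain_id=arr.chain_id, coords=arr.coord, occupancy=occ, b_factor=bf,
        frame_index=frame_index,
    )


def _locate_bad_atom_line(path) -> int | None:
    """Best-effort line number of the first malformed ATOM/HETATM record."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                        int(line[22:26])
                    except (ValueError, IndexError):
                        return lineno
    except OSError:
        return None
    return None


def read_structure(path, altloc_policy: str = "highest_occupancy",
                   exclude_hetero: bool = True) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    One frame per MODEL block (a single frame if the file has none).  Waters
    and common ions (HETATM solvent) are excluded unless ``exclude_hetero``
    is False.  Altloc variants are resolved per ``altloc_policy``.
    """
    if altloc_policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc policy: {altloc_policy!r}")
    try:
        pdb = PDBFile.read(path)
        n_models = pdb.get_model_count()
    except Exception as exc:
        lineno = _locate_bad_atom_line(path)
        at = f" at line {lineno}" if lineno else ""
        raise ParseError(f"cannot parse PDB file {path}{at}: {exc}") from exc

    frames = []
    for m in range(1, n_models + 1):
        try:
            arr = pdb.get_structure(
                model=m, altloc="all",
                extra_fields=["atom_id", "occupancy", "b_factor"],
            )
        except Exception as exc:
            lineno = _locate_bad_atom_line(path)
            at = f" at line {lineno}" if lineno else ""
            raise ParseError(f"cannot parse PDB model {m} of {path}{at}: {exc}") from exc
        if exclude_hetero:
            keep = ~(arr.hetero & np.isin(arr.res_name, list(_SOLVENT_RES)))
            arr = arr[keep]
        raw = _frame_from_atom_array(arr, frame_index=m - 1)
        frame = _resolve_altloc(raw, altloc_policy)
        frame.check_unique_identity()
        frames.append(frame)

    if not frames or all(len(f) == 0 for f in frames):
        raise EmptyStructureError(f"no atoms read from {path}")
    return Trajectory(frames=frames)


def _atom_array_from_frame(frame: Frame) -> bst.AtomArray:
    n = len(frame)
    arr = bst.AtomArray(n)
    arr.coord = frame.coords.astype(np.float32)
    arr.chain_id = frame.chain_id
    arr.res_id = frame.res_seq
    arr.ins_code = frame.insertion_code
    arr.res_name = frame.res_name
    arr.atom_name = frame.name
    arr.element = frame.element
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("atom_id", np.arange(1, n + 1))
    arr.set_annotation("occupancy", frame.occupancy)
    arr.set_annotation("b_factor", frame.b_factor)
    return arr


def write_structure(trajectory: Trajectory | Frame, path) -> None:
    """Write frames as PDB MODEL blocks (plain ATOM records, no MODEL if single)."""
    if isinstance(trajectory, Frame):
        trajectory = Trajectory(frames=[trajectory])
    if not trajectory.frames:
        raise EmptyStructureError("cannot write an empty trajectory")
    for f in trajectory.frames:
        too_long = [c for c in np.unique(f.chain_id) if len(str(c)) > 1]
        if too_long:
            raise FormatError(f"chain ids longer than the PDB field: {too_long}")

    blocks = []
    multi = len(trajectory.frames) > 1
    for k, f in enumerate(trajectory.frames, start=1):
        pdbf = PDBFile()
        pdbf.set_structure(_atom_array_from_frame(f))
        lines = [ln for ln in pdbf.lines if not ln.startswith(("END", "MODEL", "ENDMDL"))]
        if multi:
            blocks.append(f"MODEL     {k:4d}")
        blocks.extend(lines)
        if multi:
            blocks.append("ENDMDL")
    blocks.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# selection


def select_atoms(frame: Frame, chains, residue_range=None,
                 atom_class: str = "all") -> Frame:
    """Subset a frame by chain set, optional residue-number range, atom class.

    ``atom_class``: ``all`` | ``heavy`` (element != H) | ``backbone``
    (N, CA, C, O) | ``c_alpha``.
    """
    chains = set(chains)
    if not chains:
        raise ValueError("chains must be nonempty")
    mask = np.isin(frame.chain_id, list(chains))
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (frame.res_seq >= lo) & (frame.res_seq <= hi)
    if atom_class == "heavy":
        mask &= frame.element != "H"
    elif atom_class == "backbone":
        mask &= np.isin(frame.name, list(BACKBONE_NAMES)) & (frame.element != "H")
    elif atom_class == "c_alpha":
        mask &= frame.name == "CA"
    elif atom_class != "all":
        raise ValueError(f"unknown atom class: {atom_class!r}")
    if not mask.any():
        raise EmptySelectionError(
            f"no atoms match chains={sorted(chains)} class={atom_class}")
    return frame.subset(mask)
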