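"""Geometric observables from trajectory coordinates.

This module holds the trajectory container (:class:`FrameSet`), the labeled
distance definitions used for the H-bond network analysis, and the geometry
kernels: inter-atomic distances, side-chain dihedrals, and ring RMSD after a
rigid backbone superposition.

Distances are always heavy-atom distances; hydrogens never enter the H-bond
network features.  A frame that fails a geometric precondition (e.g. a
collinear dihedral triple) yields a flagged missing value (NaN) rather than
aborting the whole trajectory.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DefinitionError, FormatError, GeometryError, UsageError

__all__ = [
    "FrameSet",
    "DistanceDefinition",
    "read_frames",
    "write_frames",
    "read_distance_definitions",
    "compute_distances",
    "compute_dihedral",
    "compute_ring_rmsd",
]


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class FrameSet:
    """An ordered trajectory of labeled atoms.

    Parameters
    ----------
    coords:
        Array of shape ``(n_frames, n_atoms, 3)`` in angstrom.
    atom_name, res_name, element:
        Per-atom string annotations, length ``n_atoms``.
    res_id:
        Per-atom integer residue numbers, length ``n_atoms``.
    """

    coords: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    element: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.res_name = np.asarray(self.res_name, dtype=object)
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.element = np.asarray(self.element, dtype=object)
        n_atoms = self.coords.shape[1]
        for name, arr in (
            ("atom_name", self.atom_name),
            ("res_name", self.res_name),
            ("res_id", self.res_id),
            ("element", self.element),
        ):
            if len(arr) != n_atoms:
                raise FormatError(f"{name} has length {len(arr)}, expected {n_atoms}")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates in FrameSet")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def resolve_atom(self, res_id: int, atom_name: str) -> int:
        """Return the unique atom index matching ``(res_id, atom_name)``."""
        hits = np.flatnonzero((self.res_id == int(res_id)) & (self.atom_name == atom_name))
        if len(hits) != 1:
            raise DefinitionError(
                f"selector (residue {res_id}, atom {atom_name!r}) resolves to "
                f"{len(hits)} atoms, expected exactly 1"
            )
        return int(hits[0])

    def resolve_selection(self, selectors: Iterable[tuple[int, str]]) -> np.ndarray:
        """Resolve a list of ``(res_id, atom_name)`` pairs to atom indices."""
        return np.array([self.resolve_atom(r, a) for r, a in selectors], dtype=int)

    def frame(self, i: int) -> "FrameSet":
        """Single-frame view (a new FrameSet with one frame)."""
        return FrameSet(
            self.coords[i : i + 1].copy(),
            self.atom_name,
            self.res_name,
            self.res_id,
            self.element,
        )


# ---------------------------------------------------------------------------
# distance definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceDefinition:
    """A labeled donor/acceptor heavy-atom distance (e.g. ``d1`` ... ``d22``)."""

    label: str
    res_a: int
    atom_a: str
    res_b: int
    atom_b: str


def read_distance_definitions(path: str | os.PathLike) -> list[DistanceDefinition]:
    """Read distance definitions from CSV (label, resid_a, atom_a, resid_b, atom_b)."""
    df = pd.read_csv(path, comment="#")
    required = {"label", "resid_a", "atom_a", "resid_b", "atom_b"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"definition file missing columns: {sorted(missing)}")
    return [
        DistanceDefinition(
            str(r.label), int(r.resid_a), str(r.atom_a), int(r.resid_b), str(r.atom_b)
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _pdb_to_frameset(path: str | os.PathLike) -> FrameSet:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on roster mismatch between models
        raise FormatError(f"cannot parse multi-model PDB {path}: {exc}") from exc
    if stack.array_length() == 0 or stack.stack_depth() == 0:
        raise FormatError(f"no atoms found in {path}")
    return FrameSet(
        np.asarray(stack.coord, dtype=float),
        stack.atom_name.astype(object),
        stack.res_name.astype(object),
        stack.res_id.astype(int),
        stack.element.astype(object),
    )


def _xyz_to_frameset(path: str | os.PathLike) -> FrameSet:
    # Minimal multi-frame XYZ: repeated blocks of "natoms / comment / elem x y z".
    # XYZ carries no residue labels; atoms get res_id = 1-based file order,
    # atom_name = element, res_name = "UNK".
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    frames: list[np.ndarray] = []
    elements_ref: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"bad XYZ atom count at line {i + 1}: {lines[i]!r}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError("truncated XYZ frame")
        elems, xyz = [], []
        for ln in block:
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"bad XYZ atom line: {ln!r}")
            elems.append(parts[0].upper())
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if elements_ref is None:
            elements_ref = elems
        elif elems != elements_ref:
            raise FormatError("atom roster differs between XYZ frames")
        frames.append(np.asarray(xyz))
        i += 2 + n
    if not frames:
        raise FormatError(f"no frames found in {path}")
    n_atoms = len(elements_ref)
    return FrameSet(
        np.stack(frames),
        np.array(elements_ref, dtype=object),
        np.array(["UNK"] * n_atoms, dtype=object),
        np.arange(1, n_atoms + 1),
        np.array(elements_ref, dtype=object),
    )


def read_frames(path: str | os.PathLike, fmt: str | None = None) -> FrameSet:
    """Read a trajectory from a multi-model PDB or an XYZ file.

    ``fmt`` is inferred from the file extension when omitted.
    """
    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    fmt = fmt.lower()
    if not os.path.exists(path):
        raise FormatError(f"file not found: {path}")
    if os.path.getsize(path) == 0:
        raise FormatError(f"empty file: {path}")
    if fmt == "pdb":
        return _pdb_to_frameset(path)
    if fmt == "xyz":
        return _xyz_to_frameset(path)
    raise UsageError(f"unknown trajectory format {fmt!r} (expected 'pdb' or 'xyz')")


def write_frames(frames: FrameSet, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame) or XYZ."""
    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        stack = struc.AtomArrayStack(frames.n_frames, frames.n_atoms)
        stack.coord = np.asarray(frames.coords, dtype=np.float32)
        stack.atom_name = frames.atom_name.astype("U6")
        stack.res_name = frames.res_name.astype("U5")
        stack.res_id = frames.res_id
        stack.element = frames.element.astype("U2")
        stack.chain_id = np.full(frames.n_atoms, "A", dtype="U4")
        stack.hetero = np.full(frames.n_atoms, True)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    elif fmt == "xyz":
        buf = io.StringIO()
        for f in range(frames.n_frames):
            buf.write(f"{frames.n_atoms}\nframe {f}\n")
            for a in range(frames.n_atoms):
                x, y, z = frames.coords[f, a]
                buf.write(f"{frames.element[a]:<3s} {x:15.8f} {y:15.8f} {z:15.8f}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    else:
        raise UsageError(f"unknown trajectory format {fmt!r} (expected 'pdb' or 'xyz')")


# ---------------------------------------------------------------------------
# geometry kernels
# ---------------------------------------------------------------------------

def compute_distances(frames: FrameSet, defs: Sequence[DistanceDefinition]) -> pd.DataFrame:
    """Per-frame Euclidean distances for every labeled definition.

    Returns a DataFrame indexed by frame number with one column per label (angstrom).
    """
    cols: dict[str, np.ndarray] = {}
    for d in defs:
        try:
            ia = frames.resolve_atom(d.res_a, d.atom_a)
            ib = frames.resolve_atom(d.res_b, d.atom_b)
        except DefinitionError as exc:
            raise DefinitionError(f"distance {d.label}: {exc}") from exc
        delta = frames.coords[:, ia, :] - frames.coords[:, ib, :]
        cols[d.label] = np.linalg.norm(delta, axis=1)
    out = pd.DataFrame(cols, index=pd.RangeIndex(frames.n_frames, name="frame"))
    return out


def _dihedral_angles(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (degrees) per frame; NaN where a triple is collinear.

    Positive when, looking down the p1->p2 bond, the p2->p3 bond is rotated
    clockwise from the p1->p0 bond (the standard IUPAC sign convention).
    """
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = np.linalg.norm(b1, axis=1, keepdims=True)
    bad = (np.linalg.norm(np.cross(b0, b1), axis=1) < 1e-10) | (
        np.linalg.norm(np.cross(b1, b2), axis=1) < 1e-10
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        b1u = b1 / np.where(b1n == 0, np.nan, b1n)
        v = b0 - np.einsum("ij,ij->i", b0, b1u)[:, None] * b1u
        w = b2 - np.einsum("ij,ij->i", b2, b1u)[:, None] * b1u
        x = np.einsum("ij,ij->i", v, w)
        y = np.einsum("ij,ij->i", np.cross(b1u, v), w)
        ang = np.degrees(np.arctan2(y, x))
    ang[bad] = np.nan
    # map -180 into the (-180, 180] convention
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return ang


def compute_dihedral(
    frames: FrameSet, selectors: Sequence[tuple[int, str]], label: str = "dihedral"
) -> pd.Series:
    """Per-frame signed dihedral angle for four atoms, in degrees, (-180, 180].

    Frames with a collinear atom triple are flagged NaN.
    """
    if len(selectors) != 4:
        raise UsageError("compute_dihedral needs exactly four atom selectors")
    idx = frames.resolve_selection(selectors)
    p = frames.coords[:, idx, :]
    ang = _dihedral_angles(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
    return pd.Series(ang, index=pd.RangeIndex(frames.n_frames, name="frame"), name=label)


def superpose(
    mobile: np.ndarray, ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    Returns (rotation matrix, mobile centroid, ref centroid).  The rotation is
    determinant-corrected (a proper rotation, never a reflection).
    """
    from scipy.spatial.transform import Rotation

    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot.as_matrix(), mc, rc


def compute_ring_rmsd(
    frames: FrameSet,
    fit_selectors: Sequence[tuple[int, str]],
    target_selectors: Sequence[tuple[int, str]],
    reference: FrameSet,
) -> pd.Series:
    """RMSD of the target atoms after rigidly fitting the fit atoms to a reference.

    The superposition (rotation + translation) is computed on the fit set only;
    the RMSD is then evaluated over the target set without refitting, so residual
    target motion relative to the fitted scaffold is what is measured.
    """
    if len(fit_selectors) < 3:
        raise GeometryError("ring RMSD needs at least 3 fit atoms")
    if reference.n_frames != 1:
        raise UsageError("reference must contain exactly one frame")
    fit_idx = frames.resolve_selection(fit_selectors)
    tgt_idx = frames.resolve_selection(target_selectors)
    ref_fit = reference.coords[0, reference.resolve_selection(fit_selectors), :]
    ref_tgt = reference.coords[0, reference.resolve_selection(target_selectors), :]
    out = np.empty(frames.n_frames)
    for f in range(frames.n_frames):
        R, mc, rc = superpose(frames.coords[f, fit_idx, :], ref_fit)
        moved_tgt = (frames.coords[f, tgt_idx, :] - mc) @ R.T + rc
        out[f] = float(np.sqrt(np.mean(np.sum((moved_tgt - ref_tgt) ** 2, axis=1))))
    return pd.Series(out, index=pd.RangeIndex(frames.n_frames, name="frame"), name="rmsd")
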