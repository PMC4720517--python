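"""Structures, crystal-lattice protofilaments, and interface geometry.

This module holds the atomic-coordinate containers used throughout the
toolkit, reads and writes PDB files, expands crystallographic symmetry
(P1 and P2₁) into neighbor copies, derives protofilament models from a
lattice, and measures the geometric quantities that characterize an
ESCRT-III protofilament: repeat distance, helix lengths, hairpin tilt,
and buried solvent-accessible surface area between protomers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ParameterError,
    ParseError,
    SpaceGroupError,
    UnknownElementError,
)

# Chain identifiers used when flattening a filament to a single structure.
_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)

#: van der Waals radii (Å) for SASA; standard values.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}

#: Space-group numbers the lattice code is validated for (P1, P2₁).
SUPPORTED_SPACE_GROUPS = {1, 4}


# --------------------------------------------------------------------------
# containers


@dataclass
class Structure:
    """Atomic coordinates with minimal PDB-style bookkeeping.

    Coordinates are in Ångström, residue indices are 1-based.  ``helices``
    holds ``(chain_id, first_residue, last_residue)`` annotations taken from
    HELIX records or assigned by the caller.
    """

    names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    occupancy: np.ndarray
    helices: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.names = np.asarray(self.names, dtype="U4")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="U3")
        self.chain_ids = np.asarray(self.chain_ids, dtype="U1")
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        for arr in (self.names, self.elements, self.res_ids,
                    self.res_names, self.chain_ids, self.occupancy):
            if len(arr) != n:
                raise ParameterError("field lengths inconsistent")
        if n and not np.all(np.isfinite(self.coords)):
            raise ParameterError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def from_arrays(cls, coords, *, names="CA", elements="C", res_ids=None,
                    res_names="ALA", chain_ids="A", occupancy=1.0, **kw):
        """Build a structure broadcasting scalar bookkeeping fields."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(coords)

        def _b(x, dtype):
            a = np.asarray(x)
            return np.full(n, x, dtype=dtype) if a.ndim == 0 else a.astype(dtype)

        if res_ids is None:
            res_ids = np.arange(1, n + 1)
        return cls(_b(names, "U4"), _b(elements, "U2"),
                   np.asarray(res_ids, dtype=int) if np.ndim(res_ids) else _b(res_ids, int),
                   _b(res_names, "U3"), _b(chain_ids, "U1"), coords,
                   _b(occupancy, float), **kw)

    def copy(self) -> "Structure":
        return Structure(self.names.copy(), self.elements.copy(),
                         self.res_ids.copy(), self.res_names.copy(),
                         self.chain_ids.copy(), self.coords.copy(),
                         self.occupancy.copy(), list(self.helices),
                         dict(self.meta))

    def select(self, mask) -> "Structure":
        mask = np.asarray(mask)
        return Structure(self.names[mask], self.elements[mask],
                         self.res_ids[mask], self.res_names[mask],
                         self.chain_ids[mask], self.coords[mask],
                         self.occupancy[mask], list(self.helices),
                         dict(self.meta))

    def transformed(self, rotation=None, translation=None) -> "Structure":
        """Return a rigidly transformed copy (rotation acts first)."""
        out = self.copy()
        xyz = out.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        out.coords = xyz
        return out

    # -- lookups ----------------------------------------------------------

    def ca_mask(self) -> np.ndarray:
        return self.names == "CA"

    def ca_coords(self, chain: str | None = None) -> np.ndarray:
        m = self.ca_mask()
        if chain is not None:
            m &= self.chain_ids == chain
        return self.coords[m]

    def atom_index(self, chain: str, res_id: int, name: str = "CA") -> int:
        hits = np.flatnonzero((self.chain_ids == chain)
                              & (self.res_ids == int(res_id))
                              & (self.names == name))
        if len(hits) == 0:
            raise ParameterError(
                f"atom {name} of residue {chain}/{res_id} not found")
        return int(hits[0])

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @staticmethod
    def concatenate(parts: Iterable["Structure"]) -> "Structure":
        parts = list(parts)
        return Structure(
            np.concatenate([p.names for p in parts]),
            np.concatenate([p.elements for p in parts]),
            np.concatenate([p.res_ids for p in parts]),
            np.concatenate([p.res_names for p in parts]),
            np.concatenate([p.chain_ids for p in parts]),
            np.concatenate([p.coords for p in parts]),
            np.concatenate([p.occupancy for p in parts]),
        )


@dataclass
class CrystalCell:
    """Unit-cell parameters plus Hermann-Mauguin space-group symbol."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group: str = "P 1"

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ParameterError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ParameterError("cell angles must be in (0, 180)")

    def orth_matrix(self) -> np.ndarray:
        """Fractional → Cartesian matrix (standard PDB convention)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta,
                                                self.gamma))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        v = math.sqrt(max(1 - ca * ca - cb * cb - cg * cg
                          + 2 * ca * cb * cg, 0.0))
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])


@dataclass
class FilamentModel:
    """A protomer plus ordered rigid transforms placing copies 0..n-1.

    ``transforms[k]`` is a ``(rotation, translation)`` pair; for a pure
    translational protofilament the k-th transform is k times the generator
    translation.  ``axis`` is the unit filament direction.
    """

    protomer: Structure
    transforms: list
    axis: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.transforms) < 1:
            raise ParameterError("filament needs at least one protomer")
        self.axis = np.asarray(self.axis, dtype=float)
        nrm = np.linalg.norm(self.axis)
        if nrm > 0:
            self.axis = self.axis / nrm

    @property
    def n_protomers(self) -> int:
        return len(self.transforms)

    def protomer_structure(self, k: int) -> Structure:
        rot, tr = self.transforms[k]
        return self.protomer.transformed(rot, tr)

    def protomer_coords(self, k: int) -> np.ndarray:
        return self.protomer_structure(k).coords

    def centroids(self) -> np.ndarray:
        return np.array([self.protomer_coords(k).mean(axis=0)
                         for k in range(self.n_protomers)])

    def to_structure(self) -> Structure:
        """Flatten to one structure with distinct chain ids per protomer."""
        parts = []
        for k in range(self.n_protomers):
            s = self.protomer_structure(k)
            s.chain_ids = np.full(len(s), _CHAIN_ALPHABET[k % len(_CHAIN_ALPHABET)],
                                  dtype="U1")
            parts.append(s)
        return Structure.concatenate(parts)


# --------------------------------------------------------------------------
# PDB I/O (gemmi-backed parsing, minimal hand-rolled writing)


def parse_structure(pdb_text: str):
    """Parse PDB text into ``(Structure, CrystalCell | None)``.

    Uses gemmi underneath; HELIX records become ``Structure.helices``
    annotations, and a CRYST1 record other than the placeholder P1 cell
    populates the crystal cell.
    """
    import gemmi

    if not pdb_text.strip():
        raise ParseError("empty PDB input")
    if "ATOM" not in pdb_text and "HETATM" not in pdb_text:
        raise ParseError("no ATOM/HETATM records found")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports line numbers
        raise ParseError(f"PDB parse failure: {exc}") from exc

    names, elements, res_ids, res_names, chain_ids, xyz, occ = \
        [], [], [], [], [], [], []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                names.append(atom.name)
                elements.append(atom.element.name)
                res_ids.append(residue.seqid.num)
                res_names.append(residue.name)
                chain_ids.append(chain.name[:1] or "A")
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                occ.append(atom.occ)
    if not xyz:
        raise ParseError("no atoms parsed")
    helices = []
    for hel in st.helices:
        try:
            helices.append((hel.start.chain_name,
                            hel.start.res_id.seqid.num,
                            hel.end.res_id.seqid.num))
        except AttributeError:  # pragma: no cover - gemmi API drift guard
            pass
    s = Structure(np.array(names), np.array(elements), np.array(res_ids),
                  np.array(res_names), np.array(chain_ids), np.array(xyz),
                  np.array(occ), helices=helices)

    cell = None
    c = st.cell
    placeholder = (abs(c.a - 1) < 1e-6 and abs(c.b - 1) < 1e-6
                   and abs(c.c - 1) < 1e-6)
    if c.a > 0 and not placeholder:
        cell = CrystalCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma,
                           st.spacegroup_hm or "P 1")
    return s, cell


def write_structure(s: Structure, cell: CrystalCell | None = None) -> str:
    """Serialize to minimal PDB text (CRYST1, HELIX, ATOM, TER, END)."""
    lines = []
    if cell is not None:
        lines.append(
            f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
            f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} "
            f"{cell.space_group:<11s}{1:4d}")
    for i, (ch, first, last) in enumerate(s.helices, start=1):
        lines.append(
            f"HELIX  {i:3d} {i:3d} ALA {ch}{first:5d}  ALA {ch}{last:5d}"
            f"  1{'':30s}{last - first + 1:6d}")
    for i in range(len(s)):
        name = s.names[i]
        pname = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = s.coords[i]
        lines.append(
            f"ATOM  {min(i + 1, 99999):5d} {pname}{s.res_names[i]:>4s} "
            f"{s.chain_ids[i]}{s.res_ids[i]:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{s.occupancy[i]:6.2f}{0.0:6.2f}"
            f"          {s.elements[i]:>2s}")
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# crystal symmetry


def _space_group_ops(symbol: str):
    import gemmi

    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise SpaceGroupError(f"cannot resolve space group {symbol!r}")
    if sg.number not in SUPPORTED_SPACE_GROUPS:
        raise SpaceGroupError(
            f"space group {sg.hm} (NO. {sg.number}) not supported; "
            f"supported numbers: {sorted(SUPPORTED_SPACE_GROUPS)}")
    ops = []
    for op in sg.operations():
        den = op.DEN
        rot = np.array(op.rot, dtype=float) / den
        tran = np.array(op.tran, dtype=float) / den
        ops.append((rot, tran))
    return ops


def expand_symmetry(s: Structure, cell: CrystalCell, radius: float):
    """Generate symmetry/lattice neighbor copies within ``radius``.

    Applies every space-group operator combined with lattice translations
    over a block of cells large enough to cover ``radius``, returning the
    copies that place at least one atom within ``radius`` of the input.
    The identity copy is excluded.  Each returned structure carries
    ``meta['symmetry_op']`` with the fractional operator and lattice shift,
    and ``meta['is_pure_translation']``.
    """
    if radius <= 0:
        raise ParameterError("radius must be positive")
    ops = _space_group_ops(cell.space_group)
    M = cell.orth_matrix()
    Minv = np.linalg.inv(M)
    frac = s.coords @ Minv.T

    nmax = [int(math.ceil(radius / edge)) + 1
            for edge in (cell.a, cell.b, cell.c)]
    tree = cKDTree(s.coords)
    neighbors = []
    for rot, tran in ops:
        base = frac @ rot.T + tran
        is_identity_op = np.allclose(rot, np.eye(3))
        for na in range(-nmax[0], nmax[0] + 1):
            for nb in range(-nmax[1], nmax[1] + 1):
                for nc in range(-nmax[2], nmax[2] + 1):
                    shift = np.array([na, nb, nc], dtype=float)
                    total_t = tran + shift
                    if is_identity_op and np.allclose(total_t, 0):
                        continue  # the input itself
                    xyz = (base + shift) @ M.T
                    d, _ = tree.query(xyz, k=1)
                    if d.min() <= radius:
                        cp = s.copy()
                        cp.coords = xyz
                        cp.meta = dict(s.meta)
                        cp.meta["symmetry_op"] = (rot.tolist(),
                                                  total_t.tolist())
                        cp.meta["is_pure_translation"] = bool(is_identity_op)
                        neighbors.append(cp)
    return neighbors


def protofilament_from_lattice(s: Structure, cell: CrystalCell,
                               axis_hint=None, n: int = 7,
                               contact_radius: float = 5.0,
                               sasa_points: int = 240) -> FilamentModel:
    """Derive the protofilament generator from the crystal lattice.

    Among translation-related lattice neighbors in contact with the input,
    the one burying the largest interface area defines the filament
    generator.  ``axis_hint`` preferentially selects translations with a
    component along it; when the hint is orthogonal to every candidate the
    max-interface rule applies and the model is flagged
    (``meta['axis_hint_ignored']``).
    """
    neighbors = expand_symmetry(s, cell, contact_radius)
    candidates = {}
    for nb in neighbors:
        if not nb.meta.get("is_pure_translation"):
            continue
        t_cart = nb.coords[0] - s.coords[0]
        key = tuple(np.round(np.abs(t_cart), 3))  # fold +-t together
        if key not in candidates:
            candidates[key] = (t_cart, nb)
    if not candidates:
        raise ParameterError("no translation-related neighbor in contact")

    scored = []
    for t_cart, nb in candidates.values():
        area = buried_interface_area(s, nb, n_points=sasa_points)
        scored.append((area, t_cart))
    scored.sort(key=lambda x: -x[0])
    if scored[0][0] <= 0:
        raise ParameterError("no neighbor with a nonzero interface")

    flagged = False
    chosen = scored[0]
    if axis_hint is not None:
        hint = np.asarray(axis_hint, dtype=float)
        hint = hint / np.linalg.norm(hint)
        proj = [(area, t, abs(t @ hint) / np.linalg.norm(t))
                for area, t in scored]
        best_cos = max(p[2] for p in proj)
        if best_cos < 1e-6:
            flagged = True  # hint orthogonal to all candidates
        else:
            aligned = [p for p in proj if p[2] >= 0.8 * best_cos]
            aligned.sort(key=lambda x: -x[0])
            chosen = (aligned[0][0], aligned[0][1])

    gen = chosen[1]
    if axis_hint is not None and not flagged and gen @ hint < 0:
        gen = -gen
    axis = gen / np.linalg.norm(gen)
    transforms = [(np.eye(3), k * gen) for k in range(n)]
    return FilamentModel(protomer=s, transforms=transforms, axis=axis,
                         meta={"generator": gen.tolist(),
                               "interface_area": float(chosen[0]),
                               "axis_hint_ignored": flagged})


# --------------------------------------------------------------------------
# geometry


def repeat_distance(f: FilamentModel) -> float:
    """Centroid spacing of adjacent protomers (Å)."""
    if f.n_protomers < 2:
        raise ParameterError("repeat distance needs at least two protomers")
    cents = f.centroids()
    return float(np.mean(np.linalg.norm(np.diff(cents, axis=0), axis=1)))


def helix_end_to_end(s: Structure, chain: str, first: int, last: int) -> float:
    """Cα–Cα distance between the first and last residue of a helix."""
    missing = []
    pts = []
    for rid in (first, last):
        try:
            pts.append(s.coords[s.atom_index(chain, rid)])
        except ParameterError:
            missing.append(rid)
    if missing:
        raise ParameterError(f"missing Cα for residues {missing} "
                             f"in chain {chain}")
    return float(np.linalg.norm(pts[1] - pts[0]))


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """Dominant principal axis of a point set (unit vector).

    Raises if the two leading singular values are degenerate (no unique
    long axis).
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ParameterError("need at least two points for an axis")
    centered = coords - coords.mean(axis=0)
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if len(sv) > 1 and sv[0] - sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ParameterError("degenerate principal axes")
    return vt[0]


def hairpin_tilt(f: FilamentModel, chain: str, first: int, last: int) -> float:
    """Angle (degrees, folded to [0, 90]) between the hairpin principal
    axis and the filament axis."""
    if f.n_protomers < 2:
        raise ParameterError("tilt needs a filament of >= 2 protomers")
    s = f.protomer_structure(0)
    mask = (s.ca_mask() & (s.chain_ids == chain)
            & (s.res_ids >= first) & (s.res_ids <= last))
    coords = s.coords[mask]
    axis = principal_axis(coords)
    cosang = abs(float(axis @ f.axis))
    return math.degrees(math.acos(min(cosang, 1.0)))


# --------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(s: Structure, override: dict | None) -> np.ndarray:
    table = dict(VDW_RADII)
    if override:
        table.update(override)
    radii = np.empty(len(s))
    for i, el in enumerate(s.elements):
        key = el.strip().capitalize()
        if key not in table:
            raise UnknownElementError(
                f"no vdW radius for element {el!r}; pass radii_override")
        radii[i] = table[key]
    return radii


def sasa(s: Structure, probe: float = 1.4, n_points: int = 960,
         radii_override: dict | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere sampling.

    Each atom's accessible surface is sampled at ``n_points`` test points
    on a sphere of radius ``r_vdw + probe``; points inside any neighbor's
    expanded sphere are occluded.  Returns per-atom areas (Å²).
    """
    if len(s) == 0:
        return np.zeros(0)
    radii = _radii_for(s, radii_override) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(s.coords)
    rmax = radii.max()
    areas = np.zeros(len(s))
    for i in range(len(s)):
        ri = radii[i]
        pts = s.coords[i] + ri * unit
        nbr = [j for j in tree.query_ball_point(s.coords[i], ri + rmax)
               if j != i]
        if nbr:
            nbr = np.array(nbr)
            keep = np.ones(n_points, dtype=bool)
            d2 = np.sum((pts[:, None, :] - s.coords[nbr][None, :, :]) ** 2,
                        axis=2)
            keep &= ~np.any(d2 < (radii[nbr] ** 2)[None, :] - 1e-12, axis=1)
            frac = keep.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * ri * ri * frac
    return areas


def buried_interface_area(a: Structure, b: Structure, probe: float = 1.4,
                          n_points: int = 960,
                          radii_override: dict | None = None) -> float:
    """Buried SASA per protomer for the a-b interface (Å²).

    Symmetrized convention: ``(SASA(a) + SASA(b) - SASA(a+b)) / 2``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both structures must be nonempty")
    kw = dict(probe=probe, n_points=n_points, radii_override=radii_override)
    sa = sasa(a, **kw).sum()
    sb = sasa(b, **kw).sum()
    sab = sasa(Structure.concatenate([a, b]), **kw).sum()
    return float((sa + sb - sab) / 2.0)
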