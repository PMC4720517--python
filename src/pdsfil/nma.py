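"""Elastic-network normal modes and superhelix generation.

A Cα anisotropic network model (uniform springs between residues within
a cutoff) captures the low-frequency collective motions of a
protofilament.  A connected three-dimensional network has exactly six
zero-frequency rigid-body modes, so the first nontrivial mode is mode 7.
Perturbing a straight filament along that mode bends it; splicing the
middle segment head-to-tail propagates the bend into a long polymer
whose protomer centroids trace a superhelix, which is then fitted for
diameter, turn length (pitch) and handedness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import least_squares
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.spatial import cKDTree

from .errors import ParameterError, SegmentDeformedError, StraightFilamentError
from .filament import FilamentModel


# --------------------------------------------------------------------------
# elastic network


@dataclass
class ElasticNetwork:
    """Hookean network on residue nodes (anisotropic network model)."""

    nodes: np.ndarray          # (n, 3) Å
    edges: np.ndarray          # (m, 2) index pairs, i < j
    spring_constant: float = 1.0
    cutoff: float = 10.0
    n_components: int = 1

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def hessian(self) -> sp.csr_matrix:
        """Standard ANM Hessian: 3x3 super-elements −k·d̂d̂ᵀ/|d|⁰ per edge."""
        n = self.n_nodes
        rows, cols, vals = [], [], []
        diag = np.zeros((n, 3, 3))
        for i, j in self.edges:
            d = self.nodes[j] - self.nodes[i]
            d2 = float(d @ d)
            if d2 == 0:
                continue
            block = -self.spring_constant * np.outer(d, d) / d2
            for a in range(3):
                for b in range(3):
                    rows.append(3 * i + a)
                    cols.append(3 * j + b)
                    vals.append(block[a, b])
                    rows.append(3 * j + a)
                    cols.append(3 * i + b)
                    vals.append(block[a, b])
            diag[i] -= block
            diag[j] -= block
        for i in range(n):
            for a in range(3):
                for b in range(3):
                    if diag[i, a, b] != 0.0:
                        rows.append(3 * i + a)
                        cols.append(3 * i + b)
                        vals.append(diag[i, a, b])
        return sp.csr_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n))


def build_enm(coords, cutoff: float = 10.0,
              spring_constant: float = 1.0) -> ElasticNetwork:
    """Connect all node pairs within ``cutoff`` Å with uniform springs."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    if len(coords) < 2:
        raise ParameterError("elastic network needs at least two nodes")
    if cutoff <= 0:
        pairs = np.zeros((0, 2), dtype=int)
    else:
        tree = cKDTree(coords)
        pairs = np.array(sorted(tree.query_pairs(cutoff)), dtype=int)
        pairs = pairs.reshape(-1, 2)
    n = len(coords)
    if len(pairs):
        adj = sp.coo_matrix((np.ones(len(pairs)),
                             (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
    else:
        ncomp = n
    if ncomp > 1:
        warnings.warn(f"elastic network is disconnected "
                      f"({ncomp} components); expect {6 * ncomp} zero modes",
                      stacklevel=2)
    return ElasticNetwork(coords, pairs, spring_constant, cutoff, ncomp)


@dataclass
class ModeSet:
    """Lowest eigenpairs of the ANM Hessian, ascending."""

    frequencies: np.ndarray    # squared-frequency eigenvalues
    vectors: np.ndarray        # (3n, k), orthonormal columns
    zero_tolerance: float

    def __post_init__(self):
        if np.any(self.frequencies < -self.zero_tolerance):
            raise ParameterError("Hessian produced significantly negative "
                                 "eigenvalues")

    @property
    def n_zero(self) -> int:
        return int(np.sum(self.frequencies < self.zero_tolerance))

    @property
    def first_nontrivial(self) -> int:
        """1-based index of the lowest nontrivial mode (7 when connected)."""
        return self.n_zero + 1


def compute_modes(net: ElasticNetwork, n_modes: int = 12) -> ModeSet:
    """Lowest ``n_modes`` eigenpairs of the network Hessian.

    Small problems are solved densely; larger ones by shift-invert
    Lanczos about a small negative shift (the Hessian is positive
    semidefinite).
    """
    H = net.hessian()
    dim = H.shape[0]
    n_modes = min(n_modes, dim)
    scale = float(H.diagonal().mean()) or 1.0
    if dim <= 600 or n_modes >= dim - 1:
        w, v = np.linalg.eigh(H.toarray())
        w, v = w[:n_modes], v[:, :n_modes]
    else:
        sigma = -1e-3 * scale
        # deterministic start vector: no dependence on global RNG state
        v0 = np.ones(dim) / math.sqrt(dim)
        w, v = eigsh(H.tocsc(), k=n_modes, sigma=sigma, which="LM", v0=v0)
        order = np.argsort(w)
        w, v = w[order], v[:, order]
    tol = 1e-8 * scale
    w = np.where(np.abs(w) < tol, np.abs(w), w)
    return ModeSet(w, v, tol)


def perturb_along_mode(coords, modes: ModeSet, mode_index: int, dq: float,
                       dq_reference: float = 10000.0,
                       reference_max_displacement: float = 15.0) -> np.ndarray:
    """Displace coordinates along one normal mode.

    ``mode_index`` is 1-based and counts zero modes (the first nontrivial
    mode of a connected network is 7).  The amplitude convention maps
    ``|dq| = dq_reference`` to a maximum per-node displacement of
    ``reference_max_displacement`` Å; displacement is linear in dq and
    dq = 0 is the identity.
    """
    coords = np.asarray(coords, float).reshape(-1, 3)
    k = modes.vectors.shape[1]
    if not 1 <= mode_index <= k:
        raise ParameterError(f"mode index {mode_index} out of range 1..{k}")
    if mode_index <= modes.n_zero:
        raise ParameterError(
            f"mode {mode_index} is a rigid-body (zero) mode; first "
            f"nontrivial mode is {modes.first_nontrivial}")
    vec = modes.vectors[:, mode_index - 1].reshape(-1, 3)
    if len(vec) != len(coords):
        raise ParameterError("mode vector does not match coordinates")
    max_disp = np.linalg.norm(vec, axis=1).max()
    if max_disp == 0:
        return coords.copy()
    scale = (dq / dq_reference) * reference_max_displacement / max_disp
    return coords + scale * vec


# --------------------------------------------------------------------------
# head-to-tail extension


def _kabsch(P, Q):
    """Rotation R, translation t minimizing ||R P + t − Q||; returns rmsd."""
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - Pc).T @ (Q - Qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


def extend_head_to_tail(protomer_coords, segment, n_copies: int,
                        rmsd_threshold: float = 5.0):
    """Splice a bent segment head-to-tail into a long polymer.

    ``protomer_coords`` has shape (n_protomers, n_residues, 3);
    ``segment = (first, last)`` selects protomer indices (inclusive,
    0-based).  Copy k's leading protomer is superimposed onto copy k−1's
    trailing protomer (one-protomer overlap, so m protomers extend by
    m − 1 per copy).  Raises when the superposition RMSD exceeds
    ``rmsd_threshold`` (segment too deformed to tile).

    Returns ``(coords, centroids)`` with coords of shape
    (total_protomers, n_residues, 3).
    """
    arr = np.asarray(protomer_coords, float)
    if arr.ndim != 3:
        raise ParameterError("expected (n_protomers, n_residues, 3) coords")
    first, last = segment
    if not 0 <= first < last < arr.shape[0]:
        raise ParameterError("segment out of range or shorter than 2")
    if n_copies < 1:
        raise ParameterError("need at least one copy")
    seg = arr[first:last + 1]
    chain = [seg[i] for i in range(len(seg))]
    template = seg
    for _ in range(n_copies - 1):
        R, t, rmsd = _kabsch(template[0], chain[-1])
        if rmsd > rmsd_threshold:
            raise SegmentDeformedError(
                f"head-to-tail overlap RMSD {rmsd:.2f} Å exceeds "
                f"{rmsd_threshold} Å")
        placed = template @ R.T + t
        chain.extend(placed[i] for i in range(1, len(placed)))
        template = placed
    coords = np.array(chain)
    centroids = coords.mean(axis=1)
    return coords, centroids


# --------------------------------------------------------------------------
# superhelix fitting


class SuperhelixFit(NamedTuple):
    diameter_nm: float
    turn_length_nm: float
    residual_nm: float
    handedness: int
    axis: np.ndarray


def fit_superhelix(centroids) -> SuperhelixFit:
    """Least-squares helix through an ordered 3-D point sequence.

    Optimizes the helix axis so the points project onto a circle,
    then reads the pitch from the unwrapped azimuth versus axial
    coordinate.  Input in Å; output diameter/turn length in nm.
    Collinear input raises ``StraightFilamentError``; a planar circle
    yields turn length 0.
    """
    P = np.asarray(centroids, float).reshape(-1, 3)
    if len(P) < 6:
        raise ParameterError("need at least six centroids")
    center = P.mean(axis=0)
    X = P - center
    _, sv, Vt = np.linalg.svd(X, full_matrices=False)
    if sv[1] < 1e-7 * sv[0]:
        raise StraightFilamentError("centroids are collinear: straight "
                                    "filament, no superhelix to fit")

    def axis_from_angles(th, ph):
        return np.array([math.sin(th) * math.cos(ph),
                         math.sin(th) * math.sin(ph), math.cos(th)])

    def frame(u):
        ref = np.array([1.0, 0.0, 0.0])
        if abs(u @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, ref)
        e1 /= np.linalg.norm(e1)
        return e1, np.cross(u, e1)

    def residuals(params):
        th, ph, cx, cy = params
        u = axis_from_angles(th, ph)
        e1, e2 = frame(u)
        q = np.column_stack([X @ e1 - cx, X @ e2 - cy])
        rho = np.linalg.norm(q, axis=1)
        return rho - rho.mean()

    # candidate axes: principal directions of the points and of the
    # per-step displacement normals (robust for < 1 turn of helix)
    inits = []
    for v in (Vt[0], Vt[2], np.cross(Vt[0], Vt[1])):
        v = v / np.linalg.norm(v)
        th = math.acos(np.clip(v[2], -1, 1))
        ph = math.atan2(v[1], v[0])
        inits.append((th, ph))
    best = None
    for th0, ph0 in inits:
        sol = least_squares(residuals, x0=[th0, ph0, 0.0, 0.0],
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    th, ph, cx, cy = best.x
    u = axis_from_angles(th, ph)
    e1, e2 = frame(u)
    q1, q2 = X @ e1 - cx, X @ e2 - cy
    rho = np.hypot(q1, q2)
    radius = float(rho.mean())
    z = X @ u
    phi = np.unwrap(np.arctan2(q2, q1))
    span = abs(phi[-1] - phi[0])

    if span < 1e-8:
        raise StraightFilamentError("no azimuthal progression along axis")
    # z(φ) regression: slope = pitch / 2π; robust for planar circles (slope 0)
    A = np.column_stack([phi, np.ones_like(phi)])
    (slope, _), *_ = np.linalg.lstsq(A, z, rcond=None)
    pitch = 2.0 * math.pi * slope
    z_fit = A @ np.array([slope, z.mean() - slope * phi.mean()])
    # point-to-helix residual: radial + axial mismatch components
    helix_angle_cos = (2.0 * math.pi * radius /
                       math.hypot(2.0 * math.pi * radius, pitch))
    res = np.sqrt(np.mean((rho - radius) ** 2
                          + ((z - z_fit) * helix_angle_cos) ** 2))
    handedness = int(np.sign(slope)) if abs(pitch) > 1e-9 else 0
    if u[2] < 0:  # report a consistent axis orientation
        u = -u
    return SuperhelixFit(float(2.0 * radius / 10.0),
                         float(abs(pitch) / 10.0),
                         float(res / 10.0), handedness, u)


# --------------------------------------------------------------------------
# end-to-end bending pipeline


@dataclass
class BendResult:
    fit: SuperhelixFit
    coords: np.ndarray          # (total_protomers, n_residues, 3)
    modes: ModeSet
    mode_used: int
    dq: float


def bend_filament_pipeline(filament: FilamentModel, cutoff: float = 10.0,
                           dq: float = 10000.0, n_modes: int = 10,
                           segment_length: int = 12, n_copies: int = 8,
                           dq_reference: float = 10000.0,
                           reference_max_displacement: float = 15.0,
                           rmsd_threshold: float = 5.0) -> BendResult:
    """Bend a straight filament along its first nontrivial mode.

    Chains ENM construction, mode computation, perturbation at amplitude
    ``dq``, head-to-tail extension of the middle ``segment_length``
    protomers, and superhelix fitting of the protomer centroids.
    """
    n_prot = filament.n_protomers
    if n_prot < segment_length + 2:
        raise ParameterError("filament too short for the requested segment")
    ca = [filament.protomer_structure(k).ca_coords()
          for k in range(n_prot)]
    n_res = len(ca[0])
    flat = np.concatenate(ca)
    net = build_enm(flat, cutoff=cutoff)
    modes = compute_modes(net, n_modes=max(n_modes, 8))
    mode_used = modes.first_nontrivial
    bent = perturb_along_mode(
        flat, modes, mode_used, dq, dq_reference=dq_reference,
        reference_max_displacement=reference_max_displacement)
    per_prot = bent.reshape(n_prot, n_res, 3)
    first = (n_prot - segment_length) // 2
    coords, centroids = extend_head_to_tail(
        per_prot, (first, first + segment_length - 1), n_copies,
        rmsd_threshold=rmsd_threshold)
    fit = fit_superhelix(centroids)
    return BendResult(fit, coords, modes, mode_used, dq)
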