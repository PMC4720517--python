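"""Synthetic structures, filaments and DEER datasets.

Every downstream stage of the toolkit — spin-label modelling, DEER
inversion, lattice geometry, normal-mode bending — is exercised on data
generated here, so the generators encode the statistical structure the
analysis assumes: ideal α-helix geometry (1.5 Å rise, 100° twist per
residue), an open/closed two-state protomer surrogate whose reference
site pair sits at 45 Å (open) or 20 Å (closed), parallel protofilaments
with a ~30 Å repeat and ~27° hairpin tilt, and dipolar traces with an
exponential intermolecular background, multispin modulation depth and
additive Gaussian noise.

The protomer surrogate is deliberately coarse (one pseudo-Cα per
residue): it exists to exercise geometry and spectroscopy code, not to
model side-chain chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .deer import (
    DEFAULT_R_GRID,
    DEFAULT_TIME_GRID,
    DeerTrace,
    DistanceDistribution,
    form_factor,
)
from .errors import ParameterError
from .filament import FilamentModel, Structure, principal_axis

#: Textbook ideal α-helix geometry.
ALPHA_RISE = 1.5        # Å per residue
ALPHA_TWIST = 100.0     # degrees per residue
ALPHA_RADIUS = 2.3      # Å, Cα helix radius


# --------------------------------------------------------------------------
# specifications


@dataclass
class HelixSpec:
    n_residues: int
    rise_per_residue: float = ALPHA_RISE
    twist_per_residue: float = ALPHA_TWIST
    backbone_radius: float = ALPHA_RADIUS

    def __post_init__(self):
        if self.n_residues < 1:
            raise ParameterError("helix needs at least one residue")
        if self.rise_per_residue <= 0:
            raise ParameterError("rise must be positive")
        if not 0 < self.twist_per_residue < 360:
            raise ParameterError("twist must be in (0, 360) degrees")
        if self.backbone_radius < 0:
            raise ParameterError("backbone radius must be non-negative")


@dataclass
class SyntheticProtomerSpec:
    """Coarse open/closed protomer surrogate.

    The open form mimics the activated conformation: a long hairpin (two
    antiparallel helices, ``hairpin_length`` Å) plus a continuous helix of
    ``a23_length`` Å carrying the reference site pair at
    ``reference_pair_distance`` Å (default 45).  The closed form packs four
    short helices with the reference pair at 20 Å.
    """

    conformation: str = "open"
    hairpin_length: float = 100.0
    a23_length: float = 90.0
    reference_pair_distance: float | None = None

    def __post_init__(self):
        if self.conformation not in ("open", "closed"):
            raise ParameterError("conformation must be 'open' or 'closed'")
        if min(self.hairpin_length, self.a23_length) <= 0:
            raise ParameterError("lengths must be positive")
        if self.reference_pair_distance is None:
            self.reference_pair_distance = (
                45.0 if self.conformation == "open" else 20.0)
        if self.reference_pair_distance <= 0:
            raise ParameterError("reference pair distance must be positive")


@dataclass
class SyntheticDeerSpec:
    """Gaussian-mixture ground truth plus acquisition parameters.

    ``distribution_components`` is a list of ``(mean Å, sd Å, weight)``;
    the modulation depth is 1 − (1 − λ)^(n_spins − 1) for pump efficiency
    λ = ``pump_efficiency``.
    """

    distribution_components: Sequence = ((45.0, 1.5, 1.0),)
    time_grid: np.ndarray | None = None
    r_grid: np.ndarray | None = None
    pump_efficiency: float = 0.3
    n_spins: int = 2
    background_decay: float = 0.05   # 1/μs
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        comps = [(float(m), float(sd), float(w))
                 for m, sd, w in self.distribution_components]
        if not comps:
            raise ParameterError("need at least one mixture component")
        wsum = sum(w for _, _, w in comps)
        if abs(wsum - 1.0) > 1e-6:
            raise ParameterError("component weights must sum to 1")
        if any(sd <= 0 for _, sd, _ in comps):
            raise ParameterError("component sd must be positive")
        self.distribution_components = comps
        if not 0 <= self.pump_efficiency <= 1:
            raise ParameterError("pump efficiency must be in [0, 1]")
        if self.n_spins < 2:
            raise ParameterError("need at least two spins")
        if self.noise_sd < 0:
            raise ParameterError("noise sd must be non-negative")
        if self.background_decay < 0:
            raise ParameterError("background decay must be non-negative")
        self.time_grid = (DEFAULT_TIME_GRID.copy() if self.time_grid is None
                          else np.asarray(self.time_grid, float))
        self.r_grid = (DEFAULT_R_GRID.copy() if self.r_grid is None
                       else np.asarray(self.r_grid, float))
        for m, _, _ in comps:
            if not self.r_grid[0] <= m <= self.r_grid[-1]:
                raise ParameterError(
                    f"component mean {m} Å outside the grid "
                    f"[{self.r_grid[0]}, {self.r_grid[-1]}] Å")


# --------------------------------------------------------------------------
# structural generators


def ideal_helix(spec: HelixSpec, chain: str = "A",
                first_residue: int = 1) -> Structure:
    """One pseudo-Cα per residue on an ideal helix along +z."""
    k = np.arange(spec.n_residues)
    theta = np.radians(spec.twist_per_residue) * k
    coords = np.column_stack([
        spec.backbone_radius * np.cos(theta),
        spec.backbone_radius * np.sin(theta),
        spec.rise_per_residue * k,
    ])
    s = Structure.from_arrays(
        coords, chain_ids=chain,
        res_ids=np.arange(first_residue, first_residue + spec.n_residues))
    s.helices = [(chain, first_residue,
                  first_residue + spec.n_residues - 1)]
    return s


def _helix_segment(n, first_res, origin, direction, phase=0.0,
                   radius=ALPHA_RADIUS):
    """Helix along an arbitrary unit direction starting at ``origin``."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    # orthonormal frame around the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    k = np.arange(n)
    theta = np.radians(ALPHA_TWIST) * k + phase
    coords = (np.asarray(origin, float)[None, :]
              + np.outer(ALPHA_RISE * k, direction)
              + radius * (np.outer(np.cos(theta), e1)
                          + np.outer(np.sin(theta), e2)))
    return coords, np.arange(first_res, first_res + n)


def synthetic_protomer(spec: SyntheticProtomerSpec, seed: int = 0) -> Structure:
    """Build the coarse open/closed protomer surrogate.

    The returned structure carries ``meta['sites']`` mapping ``site_a`` /
    ``site_b`` (the E88/H118 surrogates) to ``(chain, residue)``, placed so
    their Cα separation matches ``reference_pair_distance`` within 1 Å, and
    ``meta['segments']`` with hairpin and α2/3 residue ranges.
    """
    rng = np.random.default_rng(seed)
    jitter_sd = 0.05
    if spec.conformation == "open":
        n_leg = int(round(spec.hairpin_length / ALPHA_RISE))
        n_a23 = int(round(spec.a23_length / ALPHA_RISE))
        z = np.array([0.0, 0.0, 1.0])
        leg1, res1 = _helix_segment(n_leg, 1, (0, 0, 0), z)
        leg2, res2 = _helix_segment(n_leg, n_leg + 1,
                                    (6.0, 0.0, spec.hairpin_length), -z)
        a23, res3 = _helix_segment(n_a23, 2 * n_leg + 1, (12.0, 0.0, 0.0), z)
        coords = np.concatenate([leg1, leg2, a23])
        res_ids = np.concatenate([res1, res2, res3])
        # reference pair on the continuous α2/3 helix, 45 Å ≈ 30 rises apart
        sep = int(round(spec.reference_pair_distance / ALPHA_RISE))
        if sep >= n_a23 - 10:
            raise ParameterError("α2/3 too short for the reference pair")
        site_a = int(res3[5])
        site_b = int(res3[5 + sep])
        segments = {"hairpin": (1, 2 * n_leg),
                    "a23": (int(res3[0]), int(res3[-1]))}
        helices = [("A", 1, n_leg), ("A", n_leg + 1, 2 * n_leg),
                   ("A", int(res3[0]), int(res3[-1]))]
    else:
        n_h = 17  # ~25 Å helices
        z = np.array([0.0, 0.0, 1.0])
        offsets = [(0.0, 0.0), (6.0, 0.0), (0.0, 6.0), (6.0, 6.0)]
        parts, res_parts = [], []
        for i, (ox, oy) in enumerate(offsets):
            c, r = _helix_segment(n_h, i * n_h + 1, (ox, oy, 0.0),
                                  z if i % 2 == 0 else -z)
            if i % 2 == 1:
                c = c + np.array([0.0, 0.0, n_h * ALPHA_RISE])
            parts.append(c)
            res_parts.append(r)
        coords = np.concatenate(parts)
        res_ids = np.concatenate(res_parts)
        site_a = 3                 # helix 1
        site_b = 2 * n_h + 3       # helix 3 (offset (0, 6))
        segments = {"hairpin": (1, 2 * n_h),
                    "a23": (2 * n_h + 1, 4 * n_h)}
        helices = [("A", i * n_h + 1, (i + 1) * n_h) for i in range(4)]
        # shift helix 3 along z so the reference pair lands exactly
        ia = site_a - 1
        ib = site_b - 1
        d = coords[ib] - coords[ia]
        dperp2 = d[0] ** 2 + d[1] ** 2
        target = spec.reference_pair_distance
        if dperp2 >= target ** 2:
            raise ParameterError("reference pair distance shorter than "
                                 "the helix-bundle spacing")
        shift = -d[2] + np.sqrt(target ** 2 - dperp2)
        h3 = slice(2 * n_h, 3 * n_h)
        coords[h3, 2] += shift

    coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
    s = Structure.from_arrays(coords, chain_ids="A", res_ids=res_ids)
    s.helices = helices
    s.meta["sites"] = {"site_a": ("A", site_a), "site_b": ("A", site_b)}
    s.meta["segments"] = segments
    s.meta["conformation"] = spec.conformation

    got = np.linalg.norm(coords[s.atom_index("A", site_b)]
                         - coords[s.atom_index("A", site_a)])
    if abs(got - spec.reference_pair_distance) > 1.0:
        raise ParameterError(
            f"surrogate pair landed at {got:.2f} Å, outside ±1 Å of "
            f"{spec.reference_pair_distance} Å")
    return s


def synthetic_filament(protomer: Structure, repeat: float = 30.0,
                       tilt: float = 27.0, n: int = 7) -> FilamentModel:
    """Parallel protofilament: n copies along +z, ``repeat`` Å apart.

    The protomer is first rotated so its long (principal) axis makes the
    requested ``tilt`` angle with the filament axis; every copy then shares
    the same orientation (parallel packing, no alternation).
    """
    if n < 1:
        raise ParameterError("need at least one protomer")
    if repeat <= 0:
        raise ParameterError("repeat must be positive")
    axis = np.array([0.0, 0.0, 1.0])
    # orient by the hairpin's long axis when annotated, else all Cα
    seg = protomer.meta.get("segments", {}).get("hairpin")
    if seg is not None:
        mask = (protomer.ca_mask() & (protomer.res_ids >= seg[0])
                & (protomer.res_ids <= seg[1]))
        ref_coords = protomer.coords[mask]
    else:
        ref_coords = (protomer.ca_coords() if protomer.ca_mask().any()
                      else protomer.coords)
    v = principal_axis(ref_coords)
    if v[2] < 0:
        v = -v
    target = np.array([np.sin(np.radians(tilt)), 0.0,
                       np.cos(np.radians(tilt))])
    rot = _rotation_between(v, target)
    base = protomer.transformed(rot, -rot @ protomer.centroid())
    transforms = [(np.eye(3), k * repeat * axis) for k in range(n)]
    fil = FilamentModel(protomer=base, transforms=transforms, axis=axis,
                        meta={"repeat": float(repeat), "tilt": float(tilt)})
    return fil


def _rotation_between(a, b) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate π about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a @ perp) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


# --------------------------------------------------------------------------
# DEER trace generator


def mixture_distribution(components, r_grid=None) -> DistanceDistribution:
    """Truncated, renormalized Gaussian mixture on the distance grid."""
    r = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, float)
    dens = np.zeros_like(r)
    for m, sd, w in components:
        dens += w * np.exp(-0.5 * ((r - m) / sd) ** 2) / (
            sd * np.sqrt(2 * np.pi))
    return DistanceDistribution(r, dens)


def synthetic_deer(spec: SyntheticDeerSpec):
    """Simulate a raw DEER trace plus its ground-truth distribution.

    V(t) = B(t)·[1 − Δ(1 − F(t))] + ε with B an exponential background,
    F the kernel-averaged form factor of the ground truth, Δ the
    modulation depth implied by pump efficiency and spin count, and ε
    additive Gaussian noise.  Bitwise reproducible for a fixed seed.
    """
    truth = mixture_distribution(spec.distribution_components, spec.r_grid)
    t = spec.time_grid
    F = form_factor(truth, t)
    depth = 1.0 - (1.0 - spec.pump_efficiency) ** (spec.n_spins - 1)
    B = np.exp(-spec.background_decay * t)
    v = B * (1.0 - depth * (1.0 - F))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, v.shape)
    trace = DeerTrace(t, v, "raw", metadata={
        "pump_efficiency": spec.pump_efficiency,
        "n_spins": spec.n_spins,
        "modulation_depth": depth,
        "background_decay": spec.background_decay,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "truth_components": list(spec.distribution_components),
    })
    return trace, truth


def trace_from_distribution(dist: DistanceDistribution, depth: float,
                            time_grid=None, background_decay: float = 0.05,
                            noise_sd: float = 0.0, seed: int = 0) -> DeerTrace:
    """Raw trace for an arbitrary distribution at a given modulation depth."""
    t = DEFAULT_TIME_GRID if time_grid is None else np.asarray(time_grid,
                                                               float)
    if not 0 <= depth < 1:
        raise ParameterError("depth must be in [0, 1)")
    F = form_factor(dist, t)
    v = np.exp(-background_decay * t) * (1.0 - depth * (1.0 - F))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, v.shape)
    return DeerTrace(t, v, "raw", metadata={"modulation_depth": depth,
                                            "background_decay": background_decay,
                                            "noise_sd": noise_sd,
                                            "seed": seed})
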