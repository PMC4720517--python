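"""Forward simulation and inversion of DEER time-domain data.

The dipolar signal of a pair of nitroxide spin labels separated by a
distance r oscillates at the powder-averaged dipolar frequency
ν(r, θ) = ν₀/r³ · (1 − 3cos²θ), with ν₀ = 52.04 MHz·nm³ for free-electron
g-values.  A measured trace V(t) is the product of an intermolecular
background B(t) and the intramolecular form factor, modulated to depth Δ:

    V(t) = B(t) · [1 − Δ(1 − F(t))],        F(t) = ∫ K(r, t) P(r) dr

Recovering the distance distribution P(r) from V(t) is ill-posed; the
standard chain implemented here is background removal on ln V over the
trace tail, normalization to the form factor, Tikhonov regularization with
non-negativity and an L-curve choice of the penalty weight, and an optional
maximum-entropy refinement step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks
from scipy.special import fresnel

from .errors import DegenerateInputError, GridError, ParameterError

#: Nitroxide dipolar constant, MHz·nm³ (free-electron g).
DIPOLAR_CONSTANT_MHZ_NM3 = 52.04

#: Default reconstruction range, Å (reliable PDS window) and grids.
DEFAULT_R_GRID = np.arange(10.0, 90.0 + 1e-9, 0.5)
DEFAULT_TIME_GRID = np.arange(0.0, 3.0 + 1e-12, 0.008)  # μs, 8 ns steps

STAGES = ("raw", "background_free", "form_factor")


# --------------------------------------------------------------------------
# containers


@dataclass
class DeerTrace:
    """Time-domain dipolar signal with acquisition/processing metadata."""

    time: np.ndarray        # μs, strictly increasing, starts at 0
    amplitude: np.ndarray
    stage: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.amplitude.shape:
            raise ParameterError("time and amplitude must be equal 1-D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("time grid must be strictly increasing")
        if self.stage not in STAGES:
            raise ParameterError(f"unknown stage {self.stage!r}")
        if self.stage == "form_factor" and abs(self.amplitude[0] - 1) > 1e-6:
            raise ParameterError("form factor must start at 1")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class DistanceDistribution:
    """Probability density P(r) on a distance grid (Å, density in 1/Å)."""

    r: np.ndarray
    density: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.r.shape != self.density.shape or self.r.ndim != 1:
            raise ParameterError("grid/density shape mismatch")
        if np.any(self.density < -1e-9):
            raise ParameterError("density must be non-negative")
        self.density = np.clip(self.density, 0.0, None)
        norm = np.trapezoid(self.density, self.r)
        if norm <= 0:
            raise ParameterError("density integrates to zero")
        if abs(norm - 1.0) > 1e-6:
            self.density = self.density / norm

    @classmethod
    def from_weights(cls, r, weights, **kw):
        return cls(np.asarray(r, float), np.asarray(weights, float), **kw)

    @property
    def mode(self) -> float:
        """Location of the global density maximum (Å)."""
        return float(self.r[int(np.argmax(self.density))])

    def modes(self, rel_height: float = 0.05):
        """Peak positions sorted by decreasing height."""
        idx, props = find_peaks(self.density,
                                height=rel_height * self.density.max())
        order = np.argsort(-props["peak_heights"])
        return [float(self.r[i]) for i in idx[order]]

    def mean(self) -> float:
        return float(np.trapezoid(self.r * self.density, self.r))

    def fwhm(self) -> float:
        """Full width at half maximum of the dominant peak (Å)."""
        half = self.density.max() / 2.0
        above = self.density >= half
        i = int(np.argmax(self.density))
        lo = i
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = i
        while hi < len(self.r) - 1 and above[hi + 1]:
            hi += 1

        def _cross(j, k):
            d0, d1 = self.density[j], self.density[k]
            if d1 == d0:
                return self.r[j]
            return self.r[j] + (half - d0) * (self.r[k] - self.r[j]) / (d1 - d0)

        left = _cross(lo, lo - 1) if lo > 0 else self.r[0]
        right = _cross(hi, hi + 1) if hi < len(self.r) - 1 else self.r[-1]
        return float(right - left)

    def total_variation(self, other: "DistanceDistribution") -> float:
        if not np.allclose(self.r, other.r):
            raise GridError("distributions on different grids")
        return 0.5 * float(np.trapezoid(np.abs(self.density - other.density),
                                        self.r))


@dataclass
class BackgroundFit:
    """Low-order polynomial fit to ln V(t) over the record tail."""

    polynomial_order: int
    tail_fraction: float
    coefficients: np.ndarray  # numpy polyval convention, highest power first

    def __post_init__(self):
        if not 0 <= self.polynomial_order <= 3:
            raise ParameterError("background polynomial order must be <= 3")
        if not 0 < self.tail_fraction <= 1:
            raise ParameterError("tail fraction must be in (0, 1]")
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients,
                                                     dtype=float))

    def evaluate(self, t) -> np.ndarray:
        return np.exp(np.polyval(self.coefficients, np.asarray(t, float)))


# --------------------------------------------------------------------------
# dipolar kernel


def dipolar_kernel(r, t):
    """Powder-averaged dipolar kernel K(r, t).

    ``r`` in Å, ``t`` in μs; broadcasts over both.  K(r, 0) = 1 and
    |K| <= 1 everywhere; the closed form uses Fresnel integrals,

        K = sqrt(π/(6φ)) [cos φ · C(z) + sin φ · S(z)],  z = sqrt(6φ/π)

    with φ = ω_dd(r)·t and ω_dd = 2π·52.04 MHz·nm³ / r³.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("distance must be positive")
    t = np.abs(np.asarray(t, dtype=float))
    r_nm = r / 10.0
    omega = 2.0 * np.pi * DIPOLAR_CONSTANT_MHZ_NM3 / r_nm ** 3  # rad/μs
    phi = omega * t
    small = phi < 1e-8
    phi_safe = np.where(small, 1.0, phi)
    z = np.sqrt(6.0 * phi_safe / np.pi)
    s_f, c_f = fresnel(z)
    k = np.sqrt(np.pi / (6.0 * phi_safe)) * (np.cos(phi_safe) * c_f
                                             + np.sin(phi_safe) * s_f)
    return np.where(small, 1.0, k)


def kernel_matrix(time, r_grid) -> np.ndarray:
    """Design matrix mapping a density P(r) to the form factor F(t).

    Row i, column j holds K(r_j, t_i) times the trapezoid quadrature weight
    of r_j, so ``K @ density`` approximates ∫K(r,t)P(r)dr.
    """
    time = np.asarray(time, dtype=float)
    r = np.asarray(r_grid, dtype=float)
    K = dipolar_kernel(r[None, :], time[:, None])
    w = np.gradient(r)  # trapezoid weights: half spacing at the ends
    w[0] = 0.5 * (r[1] - r[0])
    w[-1] = 0.5 * (r[-1] - r[-2])
    return K * w[None, :]


def form_factor(dist: DistanceDistribution, time) -> np.ndarray:
    """Noise-free form factor of a distance distribution."""
    return kernel_matrix(time, dist.r) @ dist.density


# --------------------------------------------------------------------------
# processing chain


def remove_background(trace: DeerTrace, order: int = 1,
                      tail_fraction: float = 0.5):
    """Fit/remove the intermolecular background from a raw trace.

    A polynomial of the given order is fitted to ln V(t) over the last
    ``tail_fraction`` of the record and divided out (subtracted on the log
    scale), yielding the background-free u(t).  Returns
    ``(DeerTrace, BackgroundFit)``.
    """
    if trace.stage != "raw":
        raise ParameterError("remove_background expects a raw trace")
    n = len(trace)
    start = int(np.floor(n * (1.0 - tail_fraction)))
    start = min(start, n - 2)
    t_tail = trace.time[start:]
    v_tail = trace.amplitude[start:]
    if len(t_tail) < 5:
        raise ParameterError("tail contains fewer than 5 points")
    if np.any(v_tail <= 0):
        raise ParameterError("non-positive amplitudes in tail; "
                             "log-background undefined")
    coeffs = np.polyfit(t_tail, np.log(v_tail), order)
    fit = BackgroundFit(order, tail_fraction, coeffs)
    u = trace.amplitude / fit.evaluate(trace.time)
    meta = dict(trace.metadata)
    meta["background"] = {"order": order, "tail_fraction": tail_fraction,
                          "coefficients": coeffs.tolist()}
    return DeerTrace(trace.time, u, "background_free", meta), fit


def normalize_form_factor(trace: DeerTrace) -> DeerTrace:
    """Normalize a background-free trace so u(0) = 1."""
    u0 = trace.amplitude[0]
    if u0 <= 0:
        raise ParameterError("u(0) must be positive")
    return DeerTrace(trace.time, trace.amplitude / u0, "form_factor",
                     dict(trace.metadata))


def modulation_depth(trace: DeerTrace, tail_window: float = 0.1) -> float:
    """Modulation depth 1 − V(∞), with V(∞) the mean of the final tail.

    The asymptote is estimated over the last ``tail_window`` fraction of
    the record; a short record triggers a warning and a best-effort value.
    """
    if trace.stage != "form_factor":
        raise ParameterError("modulation depth expects a normalized trace")
    n = len(trace)
    m = max(int(round(n * tail_window)), 1)
    if m < 3 or n < 10:
        warnings.warn("record too short for a reliable asymptote; "
                      "best-effort modulation depth", stacklevel=2)
    v_inf = float(np.mean(trace.amplitude[-m:]))
    return float(np.clip(1.0 - v_inf, 0.0, 1.0))


# --------------------------------------------------------------------------
# Tikhonov inversion with L-curve selection


def _second_difference(n: int) -> np.ndarray:
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i:i + 3] = (1.0, -2.0, 1.0)
    return L


def _tikhonov_solve(K, s, L, alpha):
    """Non-negative LS with offset: s ≈ c + K q, penalty α||Lq||.

    Returns (q, c, residual_norm, penalty_norm).  The constant c absorbs
    the unmodulated fraction 1 − Δ so the depth need not be known first.
    """
    nt, nr = K.shape
    A = np.concatenate([np.column_stack([K, np.ones(nt)]),
                        np.column_stack([alpha * L, np.zeros(len(L))])])
    b = np.concatenate([s, np.zeros(len(L))])
    x, _ = nnls(A, b, maxiter=50 * nr)
    q, c = x[:nr], x[nr]
    resid = float(np.linalg.norm(K @ q + c - s))
    pen = float(np.linalg.norm(L @ q))
    return q, c, resid, pen


class AlphaSelection(NamedTuple):
    alpha: float
    flagged: bool
    alphas: np.ndarray
    residual_norms: np.ndarray
    penalty_norms: np.ndarray


def default_alpha_candidates(n: int = 20, lo: float = 1e-4,
                             hi: float = 1e2) -> np.ndarray:
    """Log-spaced regularization-weight candidates spanning six decades."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def select_alpha(trace: DeerTrace, alpha_candidates=None,
                 r_grid=None) -> AlphaSelection:
    """L-curve corner selection of the Tikhonov weight.

    Solves the regularized problem at each candidate, parametrizes the
    (log residual, log penalty) curve by log α and returns the candidate of
    maximum discrete curvature.  A degenerate (monotone, curvature-free)
    curve falls back to the smallest candidate whose residual is within 10%
    of the minimum, with ``flagged=True``.
    """
    if trace.stage != "form_factor":
        raise ParameterError("select_alpha expects a normalized trace")
    alphas = (default_alpha_candidates() if alpha_candidates is None
              else np.sort(np.asarray(alpha_candidates, dtype=float)))
    if len(alphas) < 3:
        raise ParameterError("need at least 3 alpha candidates")
    if np.log10(alphas[-1] / alphas[0]) < 2:
        raise ParameterError("alpha candidates must span >= 2 decades")
    r = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, float)
    K = kernel_matrix(trace.time, r)
    L = _second_difference(len(r))
    res, pen = [], []
    for a in alphas:
        _, _, rn, pn = _tikhonov_solve(K, trace.amplitude, L, a)
        res.append(max(rn, 1e-14))
        pen.append(max(pn, 1e-14))
    res = np.array(res)
    pen = np.array(pen)

    x = np.log10(alphas)
    rho = np.log(res)
    eta = np.log(pen)
    drho, deta = np.gradient(rho, x), np.gradient(eta, x)
    d2rho, d2eta = np.gradient(drho, x), np.gradient(deta, x)
    denom = (drho ** 2 + deta ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (drho * d2eta - deta * d2rho) / denom
    kappa = np.where(np.isfinite(kappa), kappa, -np.inf)

    if np.all(kappa <= 1e-12):
        ok = res <= 1.1 * res.min()
        idx = int(np.flatnonzero(ok)[0])
        return AlphaSelection(float(alphas[idx]), True, alphas, res, pen)
    idx = int(np.argmax(kappa))
    return AlphaSelection(float(alphas[idx]), False, alphas, res, pen)


def tikhonov_invert(trace: DeerTrace, r_grid=None,
                    alpha: float | None = None) -> DistanceDistribution:
    """Invert a normalized trace into a distance distribution.

    Non-negative least squares with a second-derivative (smoothness)
    penalty; the unmodulated baseline is fitted jointly, so the result does
    not depend on a prior modulation-depth estimate.  ``alpha=None``
    triggers L-curve selection.
    """
    if trace.stage != "form_factor":
        raise ParameterError("tikhonov_invert expects a normalized trace")
    r = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, float)
    if alpha is None:
        alpha = select_alpha(trace, r_grid=r).alpha
    K = kernel_matrix(trace.time, r)
    L = _second_difference(len(r))
    q, c, resid, _ = _tikhonov_solve(K, trace.amplitude, L, alpha)
    mass = np.trapezoid(q, r)
    if mass <= 0:
        raise DegenerateInputError("inversion returned an all-zero density")
    return DistanceDistribution(r, q / mass,
                                meta={"alpha": float(alpha),
                                      "fitted_offset": float(c),
                                      "fitted_mass": float(mass),
                                      "depth_estimate": float(1.0 - c),
                                      "residual_norm": resid})


# --------------------------------------------------------------------------
# maximum-entropy refinement


class MemResult(NamedTuple):
    distribution: DistanceDistribution
    converged: bool
    n_iterations: int
    misfit: float


def _misfit(K, s, p, r):
    """Best-fit scale/offset misfit of density p against signal s."""
    f = K @ p
    A = np.column_stack([f, np.ones_like(s)])
    coef, *_ = np.linalg.lstsq(A, s, rcond=None)
    a, c = max(coef[0], 0.0), float(np.clip(coef[1], 0.0, 1.0))
    return float(np.linalg.norm(a * f + c - s)), a, c


def _entropy(p, r):
    w = np.gradient(r)
    q = np.clip(p, 1e-300, None)
    return float(-np.sum(w * q * np.log(q)))


def mem_refine(initial: DistanceDistribution, trace: DeerTrace,
               max_iter: int = 500, misfit_slack: float = 0.05) -> MemResult:
    """Maximum-entropy refinement of a Tikhonov solution.

    Seeks a higher-entropy density whose data misfit stays within
    ``(1 + misfit_slack)`` of the initial solution's misfit (plus an
    absolute floor tied to the tail-residual noise estimate).  Candidate
    steps mix the current density toward the smooth exponential-family
    update implied by the entropy prior; steps violating the misfit budget
    are rejected, so a noiseless already-optimal input is a fixed point.
    """
    if trace.stage != "form_factor":
        raise ParameterError("mem_refine expects a normalized trace")
    r = initial.r
    K = kernel_matrix(trace.time, r)
    s = trace.amplitude
    p = initial.density.copy()
    m0, a, c = _misfit(K, s, p, r)
    budget = max(m0 * (1.0 + misfit_slack), m0 + 1e-12)

    best = p
    best_entropy = _entropy(p, r)
    n_done = 0
    converged = True
    for n_done in range(1, max_iter + 1):
        resid = a * (K @ best) + c - s
        grad = a * (K.T @ resid)  # data-misfit gradient wrt density
        # exponential-family target: density ∝ exp(-grad/τ); τ from scale
        tau = max(np.abs(grad).max(), 1e-12)
        target = np.exp(-grad / tau)
        target = target / np.trapezoid(target, r)
        accepted = False
        eps = 0.5
        while eps >= 1e-4:
            cand = (1.0 - eps) * best + eps * target
            cand = cand / np.trapezoid(cand, r)
            m_c, a_c, c_c = _misfit(K, s, cand, r)
            if m_c <= budget and _entropy(cand, r) > best_entropy + 1e-12:
                best, best_entropy, a, c = cand, _entropy(cand, r), a_c, c_c
                accepted = True
                break
            eps *= 0.5
        if not accepted:
            break
    else:
        converged = False

    m_final, _, _ = _misfit(K, s, best, r)
    dist = DistanceDistribution(r, best, meta=dict(initial.meta))
    dist.meta["mem_converged"] = converged
    return MemResult(dist, converged, n_done, m_final)


# --------------------------------------------------------------------------
# composed pipeline


@dataclass
class ReconstructionResult:
    distribution: DistanceDistribution
    background: BackgroundFit
    depth: float
    alpha: float
    alpha_flagged: bool
    form_factor_trace: DeerTrace
    mem: MemResult | None = None


def full_reconstruction(trace: DeerTrace, r_grid=None,
                        background_order: int = 1,
                        tail_fraction: float = 0.5,
                        alpha: float | None = None,
                        alpha_candidates=None,
                        background_refine: int = 1,
                        use_mem: bool = True) -> ReconstructionResult:
    """Raw trace → distance distribution, background fit and depth.

    Chains background removal, normalization, modulation depth, L-curve
    Tikhonov inversion and (optionally) maximum-entropy refinement.

    A tail-only background fit absorbs part of a slowly decaying form
    factor (long distances), biasing the reconstruction; each
    ``background_refine`` pass divides the fitted foreground model out of
    the raw trace and refits the background polynomial over the whole
    record, then re-inverts.  Deterministic for fixed input.
    """
    r = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, float)
    bg_free, fit = remove_background(trace, background_order, tail_fraction)
    ff = normalize_form_factor(bg_free)

    def _invert(ff_trace):
        flagged = False
        a = alpha
        if a is None:
            sel = select_alpha(ff_trace, alpha_candidates, r_grid=r)
            a, flagged = sel.alpha, sel.flagged
        return tikhonov_invert(ff_trace, r_grid=r, alpha=a), a, flagged

    dist, a_used, flagged = _invert(ff)
    for _ in range(background_refine):
        c = dist.meta["fitted_offset"]
        m = dist.meta["fitted_mass"]
        foreground = c + m * (kernel_matrix(trace.time, r) @ dist.density)
        b_est = trace.amplitude / np.clip(foreground, 1e-12, None)
        if np.any(b_est <= 0):
            break
        coeffs = np.polyfit(trace.time, np.log(b_est), background_order)
        fit = BackgroundFit(background_order, 1.0, coeffs)
        u = trace.amplitude / fit.evaluate(trace.time)
        ff = normalize_form_factor(
            DeerTrace(trace.time, u, "background_free",
                      dict(trace.metadata)))
        dist, a_used, flagged = _invert(ff)

    depth = modulation_depth(ff)
    mem = None
    if use_mem:
        mem = mem_refine(dist, ff)
        dist = mem.distribution
    return ReconstructionResult(dist, fit, depth, float(a_used), flagged,
                                ff, mem)


# --------------------------------------------------------------------------
# TSV I/O


def write_trace(trace: DeerTrace, path) -> None:
    import json
    import pandas as pd

    pd.DataFrame({"time_us": trace.time,
                  "amplitude": trace.amplitude}).to_csv(
        path, sep="\t", index=False)
    if trace.metadata:
        with open(str(path) + ".json", "w") as fh:
            json.dump(_jsonable(trace.metadata), fh, indent=1)


def read_trace(path, stage: str = "raw") -> DeerTrace:
    import json
    import os
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    meta = {}
    sidecar = str(path) + ".json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
    return DeerTrace(df["time_us"].to_numpy(), df["amplitude"].to_numpy(),
                     stage, meta)


def write_distribution(dist: DistanceDistribution, path) -> None:
    import pandas as pd

    pd.DataFrame({"r_angstrom": dist.r,
                  "density": dist.density}).to_csv(path, sep="\t", index=False)


def read_distribution(path) -> DistanceDistribution:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return DistanceDistribution(df["r_angstrom"].to_numpy(),
                                df["density"].to_numpy())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
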