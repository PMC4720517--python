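# Methods

This note documents the models implemented in `pdsfil`, the parameter
choices that matter, and what the synthetic-data generators do and do
not emulate.

## Dipolar kernel and forward model

The powder-averaged dipolar kernel is evaluated in closed form with
Fresnel integrals,

    K(r, t) = √(π/6φ) [cos φ · C(z) + sin φ · S(z)],   z = √(6φ/π),

with φ = ω_dd t and ω_dd = 2π · 52.04 MHz·nm³ / r³ (free-electron
g-values; the dipolar constant is fixed at 52.04 MHz·nm³). The kernel is
validated against brute-force quadrature over cos θ to < 1e-6.

A raw trace is modelled as V(t) = B(t)·[1 − Δ(1−F(t))] + ε with
exponential intermolecular background B, additive Gaussian noise ε, and
modulation depth Δ = 1 − (1−λ)^(N−1) for pump efficiency λ and N coupled
spins. λ defaults to 0.3, typical for 16 ns pump pulses; it is a free
parameter of the multispin model, not a measured quantity. Noise is
additive Gaussian on V(t), the standard assumption for averaged DEER
records.

Default grids: distances 10–90 Å at 0.5 Å (the reliable PDS window);
time 0–3 μs at 8 ns. **Record-length rule:** the analysis assumes the
record covers at least ~2.5 dipolar periods of the longest distance of
interest (3 μs suffices for ~30 Å; 45 Å-class measurements use 5 μs,
and the tests scale t_max as 2.5·r³/52.04 μs). Shorter records leave the
form factor decaying throughout the tail, and the background fit then
absorbs part of the dipolar signal — the dominant failure mode of the
chain, not a numerical artifact.

## Inversion chain

1. **Background removal** — polynomial (default order 1, i.e. a straight
   line) fitted to ln V over the last half of the record and divided
   out. One **refinement pass** (default) divides the fitted foreground
   model out of the raw trace and refits the background over the whole
   record; this removes most of the residual form-factor leakage.
2. **Normalization** — u(t)/u(0), giving a form factor with V(0) = 1.
3. **Modulation depth** — 1 minus the mean of the last 10% of the
   record. The 10% window is a design choice; the paper-standard
   definition 1 − V(∞) does not fix an estimator.
4. **Tikhonov inversion** — non-negative least squares on the stacked
   system [K; αL] with L the second-difference operator, solved with an
   *additional fitted constant* that absorbs the unmodulated fraction
   1 − Δ, so the inversion does not depend on a prior depth estimate.
   The density is renormalized to integrate to 1.
5. **L-curve selection** — 20 log-spaced α candidates over six decades
   (1e-4–1e2); the corner is the maximum discrete curvature of
   (log residual, log penalty) parametrized by log α. A degenerate
   monotone curve falls back to the smallest α within 10% of the minimum
   residual and is flagged.
6. **Maximum-entropy refinement** — greedy ascent that mixes the current
   density toward the exponential-family update exp(−g/τ) implied by the
   entropy prior (g the data-misfit gradient), accepting a step only if
   the misfit stays within 5% of the initial solution's misfit and the
   entropy increases; capped at 500 iterations. An already-optimal
   noiseless solution is therefore an exact fixed point. MEM raises the
   smooth entropy floor of the distribution; it does not amplify
   discrete spurious side peaks, but neither does it remove all of the
   floor it introduces.

## Spin-label surrogate

Labels are modelled as weighted point clouds: directions drawn uniformly
in a 60° half-angle cone about the local outward normal (Cα minus the
centroid of atoms within 12 Å), tether radii uniform in 4.5–7.5 Å, and
candidates within 2.5 Å of any atom rejected (600 samples, seeded). The
cone/tether values are calibrated against the two observables a rotamer
library provides at this resolution: the cloud centroid sits 4–10 Å from
the Cα, and pair distributions between exposed helix sites have FWHMs in
the experimentally reported 0.4–1.2 nm range. An isotropic spherical
shell cannot satisfy either bound (its centroid coincides with the Cα
and its pair FWHM is ~1.5 nm), which is why the cone model is used. The
surrogate carries no rotamer energetics, no temperature dependence, and
no orientation correlation between labels.

Because the cone axis is radial, two labels on the same helix acquire a
small lateral offset set by their azimuthal separation; for sites 29
residues apart (azimuth 20°) the modal inter-label distance is
~43.5–44 Å, fractionally below the 45 Å of the 30-rise Cα separation of
the reference construct. This ~1–1.5 Å scale is the accuracy limit of
the surrogate.

## Filaments, dilution, and multispin bookkeeping

A filament is a protomer plus rigid transforms (pure translations for
the parallel ~30 Å-repeat protofilament; the protomer is pre-tilted so
its hairpin axis makes the requested angle, default 27°, with the
filament axis). The expected DEER signal of a labeled filament is a
mixture over spin pairs seen from the middle (reference) protomer:
intra-protomer pairs with weight 1 and pairs to neighbor-protomer sites
strictly inside the 60 Å neighbor shell, each weighted by the labeled
fraction 1/(1+k) for a 1:k dilution (ideal, independent mixing). Sites
at exactly the shell boundary are excluded (with a 1e-6 Å tolerance, so
the decision is stable against roundoff — relevant because the i±2
neighbor of a 30 Å filament sits at exactly 60 Å). The expected depth is
1 − (1−λ)^(E[N]−1) with E[N] = 1 + (sites per protomer − 1) +
f·(neighbor sites in shell); `effective_spin_count` inverts this
relation and reports the nearest integer.

The dilution-series analysis reconstructs each trace independently,
reports per-ratio modes and depths, uses the most-diluted distribution
as the intra-subunit estimate, and flags convergence to the
infinite-dilution limit when the two most-diluted distributions agree
within 0.10 total variation — a design choice; no quantitative
convergence criterion exists for this, and dilutions beyond ~1:15 are
impractical experimentally.

## Lattice geometry and interfaces

PDB parsing goes through gemmi; space-group operators are taken from its
tables, restricted to P1 and P2₁ (the validated cases; the table is
extensible). Symmetry expansion enumerates operators × lattice
translations over a block large enough to cover the contact radius and
is verified against brute-force enumeration. The protofilament generator
is the translation-related neighbor burying the largest interface area.

SASA is Shrake–Rupley sphere sampling: golden-spiral test points
(default 960 per atom), probe 1.4 Å, radii C 1.70 / N 1.55 / O 1.52 /
S 1.80 / H 1.20 / P 1.80 Å; unknown elements require an explicit
override. A single atom reproduces its analytic sphere to ≪ 0.5%.
"Buried area per protomer" is the symmetrized convention
(SASA(a)+SASA(b)−SASA(a∪b))/2 — the literature rarely states its
convention, and this one is symmetric in the partners by construction.

## Elastic-network bending

The Cα anisotropic network model uses uniform springs within a 10 Å
cutoff (a standard stand-in for rotation-translation-block schemes,
adequate at the ~3000-node scale used here). Eigenpairs come from dense
diagonalization below 600 degrees of freedom and shift-invert Lanczos
above it, with a deterministic start vector so results are independent
of global RNG state; zero modes are eigenvalues below 1e-8 × the mean
Hessian diagonal. A connected filament has exactly six, making mode 7
the first nontrivial mode — for a straight filament a transverse,
planar bend.

Mode amplitudes follow an explicit convention: |dq| = 10000 maps to a
maximum per-node displacement of 15 Å (the reference amplitude is a
package calibration constant; external NMA servers do not publish their
normalization, so superhelix dimensions are only defined up to this
scale). Head-to-tail extension superimposes the leading protomer of each
new copy of the bent middle 12-mer onto the trailing protomer of the
chain (one-protomer overlap: 12 + 11k protomers after k splices; the
default 7 splices give an 89-mer) and rejects splices whose overlap RMSD
exceeds 5 Å. The superhelix fit optimizes the axis so the protomer
centroids project onto a circle (trust-region least squares from three
principal-direction starts), then reads pitch and handedness from the
axial-coordinate-versus-unwrapped-azimuth regression; it inverts exact
helix constructions to machine precision and reports collinear input as
a straight filament.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the analysis
assumes: ideal α-helix geometry (1.5 Å rise, 100° twist, 2.3 Å radius —
textbook values), an open protomer with a ~100 Å two-leg hairpin and a
~90 Å continuous helix carrying a 45 Å reference site pair, a closed
four-helix bundle with the pair at 20 Å (placed exactly by a
deterministic axial shift), parallel filaments with exact repeat, and
traces with exponential background, multispin depth and Gaussian noise.
Coordinates carry a 0.05 Å seeded jitter so seeds are meaningful.

They do **not** emulate real side-chain packing, sequence, membrane
geometry, orientation-selective DEER, excitation-bandwidth effects, or
instrument artifacts. Passing round-trip tests therefore demonstrates
the correctness and stability of the inference chain under its own
model assumptions, not performance on spectrometer data; on real traces
the background model and label surrogate are the first places to expect
systematic error.

## Problem sizes

Tests and the acceptance script run on desk-scale problems chosen to
exercise every code path: 375–625-point time grids, a 161-point distance
grid, 7-mer filaments with ~320-residue protomers for spectroscopy, and
15–25-mer filaments (~4800 nodes) for normal modes with an 89-mer
extension.
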