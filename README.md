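# pdsfil

Pulsed-dipolar ESR (DEER) distance reconstruction and filament modelling
for membrane-remodelling ESCRT-III polymers.

ESCRT-III subunits such as Snf7 convert from a closed four-helix monomer
into an open, elongated conformation that polymerizes into membrane-bound
protofilaments with a ~30 Å repeat. Pulsed dipolar spectroscopy (PDS/DEER)
between nitroxide spin labels reports distances of ~10–90 Å and is the
main experimental handle on both the subunit conformation (intra-molecular
distances) and the polymer packing (inter-molecular distances). This
package implements the complete computational chain around such an
experiment:

- **`pdsfil.deer`** — forward simulation and inversion of DEER traces.
  The powder-averaged dipolar kernel
  `K(r,t) = ∫₀¹ cos[(1−3cos²θ) ω_dd(r) t] d cosθ` with
  `ω_dd = 2π·52.04 MHz·nm³ / r³` links a distance distribution `P(r)` to
  the form factor `F(t) = ∫K(r,t)P(r)dr`. A measured trace
  `V(t) = B(t)[1 − Δ(1−F(t))]` is processed by polynomial background
  removal on `ln V` over the record tail, normalization, modulation-depth
  estimation `Δ = 1 − V(∞)`, non-negative Tikhonov inversion with
  L-curve selection of the regularization weight, and maximum-entropy
  refinement.
- **`pdsfil.spin_labels`** — a tether-and-clash surrogate spin-label
  model (weighted point clouds), predicted distance mixtures for labeled
  filaments under magnetic dilution (labeled:unlabeled = 1:k), and the
  multispin relation `Δ = 1 − (1−λ)^(N−1)` linking modulation depth,
  pump efficiency λ and the number of coupled spins N.
- **`pdsfil.filament`** — PDB I/O, crystal-symmetry expansion (P1, P2₁),
  protofilament derivation from a lattice, repeat distance, helix
  lengths, hairpin tilt, and Shrake–Rupley buried-interface areas.
- **`pdsfil.nma`** — Cα elastic-network normal modes; a connected
  network has six rigid-body modes, so mode 7 is the first nontrivial
  (bending) mode. Perturbing a straight filament along it and splicing
  the middle protomers head-to-tail yields a superhelix whose diameter
  and turn length are fitted by least squares.
- **`pdsfil.synthetic_data`** — generators for ideal helices, open and
  closed protomer surrogates, parallel filaments, and DEER traces with
  known ground truth, so every stage is testable without downloads.
- **`pdsfil.pipeline` / CLI `pds`** — validated configuration, four
  end-to-end workflows, and provenance records.

## Worked example

Simulate a noisy two-component trace (a 30 Å inter-subunit contact plus a
45 Å intra-subunit pair), invert it, and read off the multispin content:

```python
import pdsfil as p

spec = p.SyntheticDeerSpec(
    distribution_components=[(30.0, 1.5, 0.4), (45.0, 1.5, 0.6)],
    pump_efficiency=0.3, noise_sd=0.005, seed=11)
trace, truth = p.synthetic_deer(spec)
result = p.full_reconstruction(trace)
print("modulation depth :", round(result.depth, 3))
print("recovered modes  :", result.distribution.modes()[:2], "Å")
n = p.effective_spin_count(result.depth, 0.3)
print("effective spins  :", round(n.n_effective, 2), "->", n.n_nearest)
```

prints

```
modulation depth : 0.293
recovered modes  : [45.0, 30.0] Å
effective spins  : 1.97 -> 2
```

i.e. both distance components are recovered on the 0.5 Å grid, and the
depth of 0.29 at pump efficiency 0.3 corresponds to a two-spin (single
pair) system. The same chain is available from the shell:

```bash
pds simulate --mean 45 --noise 0.005 --out out/
pds dilution-series --ratios 0,2,8 --out out/
pds nma-bend --nmer 25 --dq 10000 --out out/
```

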