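# gelfront

Reaction–diffusion simulation and analysis of barium–alginate gelation
fronts.  When an ultra-high-viscosity alginate droplet meets a BaCl₂ bath,
cations diffuse inward and cross-link the polymer; a thin reaction front
travels from the rim to the core.  `gelfront` models this with four coupled
fields — free polymer, free barium, cross-linked polymer, and a binding-
occupancy fraction — on radially symmetric grids (slab, disc, sphere), and
mirrors the experimental measurement pipeline end to end:

* **kinetics** – pointwise reaction source terms and cross-link-hindered
  diffusivities (`D = D0·exp(−K·ρ_cross)`).
* **solver** – conservative finite-volume spatial operator plus stiff BDF
  method-of-lines integration (SciPy, analytic Jacobian sparsity).
* **scenarios** – disc (droplet under a spacer, R0 ≈ 2.52 mm) and sphere
  (beads, 0.5–3 mm) setups with the bath as a Dirichlet barium boundary.
* **front_analysis** – front radius = sub-grid-refined peak of the
  cross-link production rate; two-phase piecewise-linear velocity fits;
  gelation time.
* **imaging** – synthetic phase-contrast-like time-lapse stacks (bright
  shrinking ring + noise), difference-of-Gaussians bandpass, azimuthal
  radial-profile front detection, stack tracking.
* **calibration** – joint SSE over observed front trajectories,
  Nelder-Mead in log-parameter space.
* **interface / cli** – YAML run configs, CSV/JSON/TIFF artifacts.

Model units: mm, s; a 10 mM bath maps to barium density 1.0 and the initial
0.65 % w/v alginate solution to polymer density 1.0 (see
`gelfront/scenarios.py` for the one place this is defined).

## CLI

```sh
# simulate a disc in a 40 mM bath, write fields/trajectory/summary
gelfront simulate --geometry disc --bath-mM 40 --out-dir out/

# ... or from a config file
gelfront simulate --config examples/disc40.yaml

# render a synthetic time-lapse TIFF from a simulation
gelfront synth --geometry sphere --diameter-um 1500 --bath-mM 20 --out-dir out/

# measure front diameters in a stack (expects a .json metadata sidecar)
gelfront track-front out/synthetic_stack.tiff --out traj.csv

# fit parameters to observed trajectories (disc: "bath_mM:csv")
gelfront fit --observed 10:t10.csv --observed 20:t20.csv --observed 40:t40.csv \
    --free Cpoly,D0ba --out fit.json
```

A minimal config:

```yaml
geometry: disc
bath_mM: 40
parameters:
  D0_ba_m2_s: 6.78e-9   # physical units in configs; mm^2/s internally
solver:
  rtol: 1.0e-6
```

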