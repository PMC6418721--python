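# monofilm

Analysis toolkit for Langmuir monolayer experiments on lipid–polymer
films, together with seeded synthetic-data generators that emulate the
trough phenomenology so the whole pipeline can be validated end to end
without instrument data.

What it does:

- **Isotherm analysis** (`monofilm.isotherm`): pressure–area curve model
  with per-molecule / per-lipid conventions, monotonization (running-max
  pressure, plateau ties collapsed to first attainment), strictly
  interpolating `area_at_pressure` (never extrapolates), lift-off area,
  compression modulus `Cs⁻¹ = −A·dΠ/dA`, and LE–LC transition-onset
  detection from the compression-modulus dip.
- **Mixing analysis** (`monofilm.mixing`): ideal-additivity isotherm
  `A_calc(Π) = x_lipid·A_lipid(Π) + x_polymer·A_polymer(Π)`, per-lipid
  rescaling, area shift versus the pure lipid, excess area of mixing
  versus the calculated ideal curve, and the convergence (squeeze-out)
  pressure where mixture and pure lipid coincide within tolerance.
- **Adsorption analysis** (`monofilm.adsorption`): ΔΠ extraction (max or
  fitted-equilibrium mode), one/two-exponential kinetics fits with AICc
  order selection, and maximum-insertion-pressure (MIP) extrapolation by
  ordinary least squares on (Π_ini, ΔΠ) points.
- **Domain imaging** (`monofilm.imaging`): dark-domain segmentation
  (Otsu or fixed threshold, invertible for bright-domain probes), area
  fraction and 8-connected domain counts, and the isotherm-predicted
  condensed coverage `φ = A_lipid(Π) / A_mix_per_lipid(Π)`.
- **Synthetic data** (`monofilm.simulate`): Volmer-based lipid isotherms
  (presets tuned to lift-off 110 Å²/molecule and transition onset
  9 mN/m), pancake→brush→squeeze-out polymer isotherms (`gp_like` at
  32.5 mN/m, `fgp_like` at 42.4 mN/m), mixed films with a prescribed
  excess-area profile, two-regime adsorption traces whose equilibrium ΔΠ
  declines linearly to zero at a set exclusion pressure, and
  binary-contrast micrographs with a known domain area fraction.  Every
  generator is a pure function of (parameters, seed) and returns a
  ground-truth record.

## Command line

The `monofilm` entry point exposes generator and analysis subcommands,
all taking uniform `--seed`, `--out`, `--config` (YAML) and
`--log-level` options, with precedence CLI > config > defaults.  Every
run writes a `summary.json` embedding the effective configuration and
package version, so runs are bitwise reproducible from their summaries.

```sh
monofilm simulate-isotherm --preset fdppc_like --seed 1 --out run/
monofilm analyze-isotherm run/fdppc_like.csv --out analysis/
monofilm simulate-adsorption --pi-ini 10 --noise-sd 0.1 --seed 2 --out ads/
monofilm kinetics ads/trace.csv --out kin/
monofilm mip series.csv --out mip/               # series.csv: pi_ini,delta_pi
monofilm mix --lipid lipid.csv --polymer polymer.csv --mixed mixed.csv \
    --ratio 10:1 --pressures 4,9,15,25 --out mix/
monofilm simulate-image --phi 0.5 --seed 3 --out img/
monofilm image-stats img/micrograph.png --out stats/
```

File formats are plain comma-separated text with `#`-prefixed metadata
lines (see `monofilm/io.py`); images are 8-bit grayscale PNG/TIFF.
Generated files carry a `<name>.truth.json` ground-truth sidecar.

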