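# betaburn

Characterization of radiation damage in macromolecular X-ray crystallography.

At 100 K the dominant global symptom of radiation damage is a linear growth
of the overall isotropic B-factor with absorbed dose,

```
B(D) = B0 + β·D ,
```

with a decay rate β ≈ 1 Å² MGy⁻¹ for typical protein crystals.  Diffracted
intensities fall off accordingly as exp(−2·β·D·s²), s = sinθ/λ, so high
resolution fades first.  Measuring β for a sample (or verifying a beamline's
flux/beam-size calibration against crystals of known sensitivity) requires a
controlled "sacrificial" experiment: collect a narrow wedge of data, burn
the crystal with a long exposure, collect again, and repeat until the high
resolution shell has lost most of its intensity.

`betaburn` implements that experiment in software, for beamline scientists
and crystallographers who want to plan such a measurement, analyse its
output, or validate analysis code against a controlled truth:

* **dose model** — absorbed dose rate (MGy s⁻¹) from photon flux, beam FWHM
  sizes, crystal dimensions and chemical composition (photoabsorption from
  Cromer–Liberman f″ plus a Compton energy-transfer term), including the
  default "average protein crystal" composition (47% solvent, 0.05 S per
  residue, 300 mM buffer sulfur) and composition-correction factors for β;
* **protocol generator** — 11 collecting cycles (≤ 0.1 MGy each, 3–5°
  wedges, d_min ≥ 2.0 Å, first-set last-shell ⟨J⟩/⟨σ_J⟩ = 5) interleaved
  with 10 burns; the total dose reduces the last-shell intensity by a factor
  of ~3 (≈ 8.8 MGy at 2.0 Å for β = 1), tolerating up to ~3× error in the
  assumed sensitivity;
* **simulator** — Wilson (acentric exponential) shell intensities, linear
  B-growth with dose, optional scale drift, calibrated counting noise;
* **scaling** — per-wedge relative scale k and isotropic B by iterative
  weighted log-linear shell regression against a generalized reference
  curve built from all wedges;
* **β fit** — (weighted) linear fit of B versus nominal dose, multi-position
  summaries (mean, population standard deviation) and composition-corrected
  β values, with plots (B solid, relative scale dashed, versus dose).

## Worked example

Plan, simulate and analyse a complete experiment for a strongly diffracting
crystal on a 0.09 MGy s⁻¹ beamline (all defaults; seed 11):

```bash
python -c "from betaburn.config import RunConfig, save_config; save_config(RunConfig(seed=11), 'run.yaml')"
betaburn plan -c run.yaml -o protocol.json
betaburn simulate -c run.yaml -p protocol.json -o wedges
betaburn fit wedges/wedge_*.tsv -o scales.tsv --result decay.json
betaburn plot -i scales.tsv -o decay.png
```

which prints

```
betaburn: dose rate 0.08957 MGy/s (composition=default average protein crystal; profile=gaussian; ...)
betaburn: protocol: 11 collections at d_min 2.00 A, total dose 8.79 MGy -> protocol.json
betaburn: wrote 11 wedges to wedges
betaburn: beta = 0.9940 +/- 0.0181 A^2/MGy (r^2 = 0.9970) over 11 wedges
```

The simulation truth was β = 1.0 Å² MGy⁻¹: the fitted decay rate 0.994 ±
0.018 recovers it, the protocol delivered the design total dose of 8.79 MGy
(ln 3 / (2·β·s_min²) at the 2.0 Å floor), and r² = 0.997 confirms the
linearity of B against dose.  `scales.tsv` lists per-wedge nominal dose,
relative scale, B and the last-shell signal-to-noise (≈ 4.8 on the first
wedge, decaying over the series).

Multi-position measurements are summarized with `betaburn report`, which
turns a TSV of per-position β values into a table of averages, population
standard deviations and composition-corrected rates.

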