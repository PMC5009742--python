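# exparkit

Kinetic modelling, simulation and quantitation for asymmetric EXPAR
microRNA assays.

## What this is for

EXPAR (isothermal exponential amplification reaction) detects short
oligonucleotides — typically microRNAs such as let-7a — by cycling
polymerase extension and single-strand nicking on a DNA template that
carries two copies of the target's reverse complement.  Quantitation is
read off a real-time fluorescence curve: the **POI** (point of inflection,
the time of maximum slope) plays the role qPCR's Cq does, and it falls
linearly with the decadic log of input copies,

    POI = a − b · lg(copies).

The efficiency of each amplification cycle is governed by φ, the fraction
of annealed target that forms an extensible duplex at the template's
3′ terminus: the mean outcome per starting molecule after *n* cycles is
(1 + φ)ⁿ, and the continuous-time growth rate is

    β = ( γλ² / (ε(λ+1)) − (1−φ) / (φ(λ+1)) − α ) · c_T0,

with c_X(t) = c_X0·e^{βt}.  Asymmetric templates (a biotin tag near the
5′ terminus, a toehold-exchange hairpin at the 3′ terminus) raise φ toward
1 and suppress cross-reaction from closely related sequences.

`exparkit` is aimed at assay developers and computational scientists who
want to model, simulate and analyse such assays at the desk: it implements
the kinetic model (closed forms, a stochastic branching simulator, a
mass-action ODE), a synthetic generator for instrument-like plate and melt
data, POI/Tm extraction, single- and two-segment calibration with inverse
quantitation, template assembly with nicking-site validation,
nearest-neighbor duplex ranking, cross-reactivity accounting, and an
end-to-end deterministic pipeline with a CLI.

## Worked example

```python
import numpy as np
from exparkit import (
    CalibrationTruth, CurveModel, PlateSpec, WellSpec,
    estimate_phi_from_quench, expected_cycle_outcome,
    generate_plate, extract_poi, fit_calibration, invert_poi,
)

# cycle efficiency from a two-fluorophore quench partition
print(f"phi (standard template): {estimate_phi_from_quench(51, 54):.3f}")
print(f"phi (biotin template):   {estimate_phi_from_quench(93.1, 36.8):.3f}")
print(f"mean outcome of 10 cycles at phi=0.5: {expected_cycle_outcome(0.5, 10):.1f}")
print(f"mean outcome of 10 cycles at phi=1.0: {expected_cycle_outcome(1.0, 10):.0f}")

# simulate a 10-decade dilution plate, extract POIs, refit the calibration
truth = CalibrationTruth(28.3, 2.09, (0.602, 6.02e11))
wells = [WellSpec(f"C{d:02d}", "let-7a", 10.0**d) for d in range(1, 11)]
plate = generate_plate(PlateSpec(wells, read_interval=1.0, duration=60.0, seed=0),
                       truth, CurveModel(noise_sd=20.0))
pois = {w: extract_poi(plate.curve(w)).poi for w in plate.truth["well"]}
fit = fit_calibration([(r.copies, pois[r.well]) for r in plate.truth.itertuples()])
print(f"calibration: POI = {fit.intercept:.2f} {fit.slope:+.2f} lg(copies)"
      f"   (|r| = {abs(fit.r):.4f})")
poi = pois["C06"]
print(f"well C06 (truth 1e6 copies): POI {poi:.2f} min -> {invert_poi(fit, poi):.3g} copies")
```

prints

```
phi (standard template): 0.486
phi (biotin template):   0.717
mean outcome of 10 cycles at phi=0.5: 57.7
mean outcome of 10 cycles at phi=1.0: 1024
calibration: POI = 28.28 -2.09 lg(copies)   (|r| = 0.9999)
well C06 (truth 1e6 copies): POI 15.86 min -> 8.8e+05 copies
```

The quench partition says a symmetric template wastes about half of each
cycle's annealing events (φ ≈ 0.49) while the biotin-tagged template keeps
φ ≈ 0.72; at φ = 0.5 ten cycles yield 1.5¹⁰ ≈ 57.7 copies per molecule
against the ideal 2¹⁰ = 1024.  The plate round trip recovers the injected
calibration truth (a = 28.3, b = 2.09) from noisy simulated traces, and
inverse prediction returns the unknown well's input to within the noise of
a single read.

The same stages are available from a shell:

```sh
exparkit simulate --seed 3 --out plate.csv
exparkit analyze plate.csv --out results.csv
exparkit calibrate results.csv plate.truth.csv --out fit.json
exparkit quantify fit.json results.csv --out quantified.csv
exparkit design --template toehold_biotin
exparkit report --seed 3 --out run_report/
```

## Layout

- `src/exparkit/kinetics.py` — reduced consecutive-reaction model, branching simulator, mass-action ODE
- `src/exparkit/synthetic.py` — plate/melt/method-table generators with known truth
- `src/exparkit/curves.py` — POI extraction, Tm calling, baseline correction
- `src/exparkit/quant.py` — calibration fits, inverse prediction, conversions, φ, RE/RSD, LOD
- `src/exparkit/design.py` — template assembly, nicking validation, NN duplex Tm, interference
- `src/exparkit/io.py`, `pipeline.py`, `cli.py` — CSV/FASTA/config IO, orchestration, console script

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
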