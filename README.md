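# raddkit

Quantitative analysis for real-time coupled deaminase–endonuclease FRET
reporter assays.

## The problem

APOBEC3-family cytosine deaminases (notably A3A and A3B) mutate
single-stranded DNA in tumours, making them drug targets — but classical
deaminase assays are multi-step, gel-based, and blind to kinetics.  A
real-time alternative couples the deamination step to an excess of a
uridine-directed endonuclease (*Pyrococcus furiosus* EndoQ) acting on a
self-quenched fluorescent ssDNA reporter: deamination of the single target
cytosine (rate constant k₁) creates a uridine that the endonuclease cleaves
(rate constant k₂), releasing the 5′ fluorophore from its 3′ quencher.
Fluorescence read every 30–60 s for an hour traces product formation
directly.

`raddkit` implements the complete quantitative analysis for this assay
family, plus a seeded synthetic-plate generator so every stage is testable
without instrument data.

## The models

Product formation follows the consecutive irreversible reaction
S →(k₁)→ I →(k₂)→ P with closed-form species

```
S(t) = A₀ e^(−k₁t)
I(t) = A₀ · k₁/(k₂−k₁) · (e^(−k₁t) − e^(−k₂t))
P(t) = A₀ − S(t) − I(t)
```

(the analytic k₁ = k₂ limit is used near rate degeneracy).  On top of this
sit:

* **Two-stage single-turnover inference** — k₂ from cleavage-only controls
  via one-phase association `plateau·(1 − e^(−kt))`, then k₁ with k₂ fixed.
  With enzyme in excess over substrate and above K_M, k₁ ≈ k_cat.
* **Michaelis–Menten fitting** — sliding-window maximum-slope initial
  velocities across a substrate dilution series, fit to
  `v = V_max·S/(K_M + S)`; k_cat = V_max/[E].
* **Inhibitor potency** — percent activity vs. inhibitor fit to the
  constrained variable-slope logistic (top = 100 %, bottom = 0 %) in
  log₁₀-concentration space, yielding IC50 and Hill slope.
* **Screening statistics** — Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|, signal-to-noise
  (μ₊−μ₋)/σ₋ and signal-to-background μ₊/μ₋ from endpoint reads.

All fits are unweighted least squares with asymptotic t-based 95 %
confidence intervals; the two-stage procedure propagates stage-1
uncertainty into the k₁ interval.

## Worked example

```sh
python examples/02_single_turnover_rates.py
```

```
stage 1  cleavage rate   k2 = 2.961e-03 /s  95% CI [2.93e-03, 2.99e-03]  R2 = 0.997
stage 2  deamination rate k1 = 5.499e-03 /s  95% CI [5.38e-03, 5.62e-03]  R2 = 0.998
single-turnover condition: True -> k1 reported as kcat
(plate generated at k2 = 2.970e-03, k1 = 5.500e-03 /s)
```

A synthetic plate built at k₂ = 2.97×10⁻³ s⁻¹ and k₁ = 5.5×10⁻³ s⁻¹ with
realistic read noise is refit by the two-stage procedure; both rates are
recovered inside their 95 % intervals, and because the deaminase (5 µM) is
in excess over the reporter (1 µM) and above K_M, k₁ is reported as k_cat.
The other examples cover plate simulation/IO, Michaelis–Menten kinetics,
IC50 fitting, and screening statistics, e.g. `05_assay_quality.py` prints

```
Z' = 0.73   S:N = 109   S:B = 4.8
```

for the 18 + 18-well screening-window plate.

The same analyses are available from the shell:

```sh
radd simulate --preset single_turnover --seed 7 --outdir plate/
radd fit-single-turnover plate/single_turnover_plate.csv --out report.json
```

## Layout

```
src/raddkit/      models, traces, fitting, screening, simulate, pipelines, io, config, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   models, assumptions, numerical choices, limitations
```
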