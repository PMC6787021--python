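# pentaspin

Pulsed-EPR analysis for C5-symmetric spin-labeled membrane channels:
DEER/PELDOR distance-distribution inversion with an ensemble validation
protocol, multispin modulation-depth stoichiometry, pentagon distance
geometry with pore-diameter conversion, 3-pulse ESEEM solvent-accessibility
fitting, and lipid nano-pocket occupancy counting over coordinate
trajectories — plus a synthetic-data generator with exact ground truth so
every stage is testable without spectrometer or MD data.

## Who this is for

Spectroscopists and structural biologists studying homo-pentameric membrane
proteins (the motivating system is the mechanosensitive channel MscL, one
nitroxide label per protomer) who need a scriptable, reproducible pipeline
from time-domain dipolar traces to distances, stoichiometry and
conformational readouts.

## The science in brief

**Dipolar inversion.** Two labels a distance *r* apart couple at
ν<sub>dd</sub> = D/r³ (D = 52.04 MHz·nm³). Orientation averaging gives the
kernel K(t, r), and the background-corrected form factor is

    f(t) = (1 − Δ) + Δ ∫ K(t, r) P(r) dr,

inverted for P(r) by non-negative Tikhonov regularization (second-derivative
penalty, NNLS on the stacked augmented system). Confidence bands come from
an 800-member validation ensemble: the mono-exponential background-fit start
point is stepped from 5% to 80% of the trace in 16 steps, 50 noise trials
per step at half the estimated trace noise, members more than 15% above the
best RMSD excluded, mean ± 2σ per distance bin over the survivors.

**C5 geometry.** A pentamer places one label per protomer at pentagon
vertices, so exactly two distances exist — the side D1 = 2R sin 36° and the
diagonal D2 = 2R sin 72° — with D2/D1 = 2 cos 36° = φ ≈ 1.618. Observing
both is a built-in control for C5 symmetry. Under uniform ring expansion, a
D1 shift δ maps to an inner-diameter change δ/sin 36° and a D2 shift φ·δ: a
3 Å D1 shift means a ~5 Å wider ring and, added to a ~4 Å closed pore, a
~9 Å expanded pore.

**Stoichiometry.** For n equivalent sites labeled with probability f and
pump inversion probability λ, the modulation depth obeys
Δ = 1 − (1 − λf)<sup>n−1</sup>. Fitting across mutants yields λ;
resubstituting back-calculates labeling degrees from depths.

**ESEEM accessibility.** Deuterium echo-envelope modulation is fitted as a
stretched-exponential baseline times 1 + k·e^(−T/T_d)·cos(2πνT + φ); the
amplitude k is the relative solvent-accessibility metric, and ratios between
samples report relative water exposure.

**Nano-pocket occupancy.** A lipid acyl chain is resident in a pocket when
at least one atom lies within 5 Å (inclusive) of the pocket's reference
atoms; chains near two pockets are assigned to the nearest, and per-frame
counts form the occupancy series correlated against structural metrics.

## Worked example

Simulate a fully labeled pentamer (D1 = 25 Å) and invert it with a reduced
80-member validation ensemble:

```bash
pentaspin simulate deer --seed 11 --out demo_deer.dat
# wrote demo_deer.dat (D1=25.00 A, D2=40.45 A, Delta_theory=0.9150)
```

```python
import numpy as np
from pentaspin import (io, InversionSettings, ValidationSettings,
                       validate_ensemble, distance_ratio)

trace = io.read_trace("demo_deer.dat", declared_unit="us").with_noise_estimate()
inv = InversionSettings(r_min=15, r_max=60, n_r=91,
                        alpha_grid=tuple(np.logspace(-3, 2, 10)))
val = ValidationSettings(n_steps=8, trials_per_step=10, seed=11)
res = validate_ensemble(trace, inv, val)
ratio, d1, d2 = distance_ratio(res.best)
print(d1, d2, round(ratio, 3), round(res.best.meta["fitted_depth"], 3))
# 25.0 40.5 1.62 0.913
```

The two recovered modes sit at the generator's pentagon side and diagonal
(25.0 and 40.5 Å), their ratio 1.62 matches the golden-ratio expectation for
C5 symmetry, and the fitted modulation depth 0.913 reproduces the multispin
prediction 1 − (1 − 0.46)⁴ = 0.915 for λ = 0.46, f = 1, n = 5.

Converting an observed 3 Å D1 shift to pore dimensions:

```bash
pentaspin geometry diameter --delta-d1 3
# diameter_change_A   5.10
# d2_shift_A          4.85
# pore_diameter_total_A  9.10
```

Other subcommands: `simulate eseem|traj`, `fit deer`, `stoichiometry`,
`geometry ratio|predict`, `eseem`, `occupancy`, and `run` for the full
configured pipeline (YAML config, JSON report).

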