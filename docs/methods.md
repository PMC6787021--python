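# Methods

This note documents the models, numerical choices and deliberate
simplifications behind each stage of the pipeline, in the order data flows
through it.

## Dipolar model

The secular electron–electron dipolar coupling between two nitroxide labels
at distance *r* (Å) is ν_dd(r) = D·(10/r)³ MHz with D = 52.04 MHz·nm³, the
standard value for a pair of g ≈ 2 electron spins (configurable in
`DipolarSettings`). Averaging the modulation cos[(1 − 3cos²θ)·2πν_dd t]
over an isotropic orientation distribution gives the Fredholm kernel

    K(t, r) = ∫₀¹ cos[(1 − 3x²)·2π ν_dd(r) t] dx ,  x = cos θ.

Two evaluators are provided and must agree to 1e−8 (tested): Gauss–Legendre
quadrature, which serves as the oracle, and the Fresnel-integral closed form

    K = √(π/6θ)·[cos θ·C(z) + sin θ·S(z)],  θ = 2π ν_dd t,  z = √(6θ/π),

which is the fast vectorised path used by the generator and the inversion
design matrix. The quadrature node count grows with the maximum phase
excursion (≈1.5·θ_max + 64, floor 201): a fixed node count under-resolves
the integrand once θ exceeds a few hundred radians.

Two numerical facts shape the tests downstream:

- K(t) decays only as t^(−1/2) (stationary phase at the magic angle), so the
  form-factor plateau approaches 1 − Δ slowly; depth-law checks therefore
  evaluate the generator at very long evolution times (t ~ 10⁶ µs) where the
  kernel tail is below the Monte-Carlo error, while analysis-facing tests
  use realistic windows and tolerances.
- Background fits over the final portion of a realistic trace inherit a
  small rate bias from the same tail; the synthetic fixtures use an 8 µs
  window so the recovered rate lands within 5% of truth for start fractions
  around 0.55–0.60.

## Background correction and form factor

The intermolecular background is a pure mono-exponential a·e^(−kt), fitted
by least squares to the trace tail from a chosen start fraction (allowed
range 5%–80% of the trace). A best-fit with k < 0 is returned flagged
`rising` rather than rejected: rising backgrounds accompany truncated
dipolar oscillations and are data, not errors. The form factor is the
pointwise quotient renormalised to f(0) = 1; the modulation depth Δ is read
as 1 minus the mean of the final 10% of f (the plateau window is
configurable; no standard definition exists for reading Δ off a finite
trace). No phase or zero-time correction is implemented — traces are
assumed phased with t = 0 on the grid.

## Tikhonov inversion

P(r) is discretised on a uniform grid (default 15–80 Å; the lower bound
reflects the ~18 Å detection floor of the technique). Writing q = Δ·P, the
model f = 1 + (K − 1)·q·dr turns joint depth-and-distribution fitting into a
single non-negative least-squares problem on the stacked system
[A; αL₂]q = [f − 1; 0], solved by `scipy.optimize.nnls` (iteration cap
10⁴; non-convergence raises, never silently). Δ = Σq·dr, and P = q
normalised to unit integral. A fitted depth below 1e−3 flags
`no_dipolar_signal`. The solver is cross-checked in the tests against an
independent bounded least-squares solve (`scipy.optimize.lsq_linear`) of the
same objective on a 30-point problem, to 1e−6.

α is chosen at the L-curve corner — maximum curvature of
(log‖residual‖, log‖L₂q‖) parametrised by log α — with a generalized
cross-validation fallback (computed on the unconstrained problem) when the
curvature has no interior maximum; the method used is recorded in the
diagnostics. On noise-free inputs the corner degenerates and GCV correctly
drives α to the bottom of the grid.

## Validation ensemble

The confidence-band protocol follows the established validation procedure
for dipolar spectroscopy: 16 equally spaced background start fractions
between 5% and 80% of the trace × 50 trials of added white Gaussian noise
per step = 800 members; members with full-trace RMSD more than 15% above
the best member are excluded; bands are the per-bin mean ± 2σ over
survivors. Choices the protocol's description leaves open, fixed here:

- "50% random noise" is interpreted as added noise with sd = 0.5 × the
  trace's estimated noise sd (second-difference estimator). This is the
  noise-level reading; the alternative (a fraction of signal amplitude)
  would swamp low-noise traces.
- The regularization parameter is selected once, on the form factor from
  the mid-range start fraction, and reused for all members: per-member
  reselection would multiply runtime ~tenfold and conflate smoothing
  variability with background variability.
- The headline distribution re-applies the best member's start fraction to
  the original (no extra noise) trace, so the reported P(r) always comes
  from the full measured trace.
- RMSD ties break toward the earliest start fraction (iteration order).

Reliability zones translate a finite window t_max into distance labels via
the covered-periods heuristic r_k = 10·(D·t_max/k)^(1/3) Å with k = 2
(shape reliable), 1 (mean + width), 0.5 (mean only), else no quantification.
The constants are configurable; they reproduce the conventional rainbow
annotation but are not a published standard.

## Synthetic DEER generator

One label per protomer sits at a pentagon vertex (ring radius R, so
D1 = 2R sin 36°, D2 = 2R sin 72°, D2/D1 = φ exactly); per-label isotropic
Gaussian jitter emulates rotamer spread. Sites are labeled independently
Bernoulli(f); the pump inverts each labeled spin with probability λ; a
molecule's echo amplitude scales with its label count, so configurations are
weighted accordingly and the observer-averaged pair product

    V_intra(t) = ⟨ Π_{j≠i, labeled} [1 − λ(1 − K(t, r_ij))] ⟩_{i labeled}

has plateau (1 − λf)^(n−1), reproducing the multispin depth law by
construction. Monte-Carlo sampling (default 4096 configurations) handles
jitter, which has no closed form; for zero jitter an exact enumeration over
all 2⁵ labeling patterns is provided and the MC path must match it (for
f = 1 they are identical configuration-by-configuration). White Gaussian
noise is added on the real channel only — the analysis operates on
phase-corrected real traces, and the true spectrometer noise model is not
known; this assumption is the main idealisation. Not modeled: orientation
selection, excitation-bandwidth effects, exchange coupling, multispin ghost
artifacts beyond the pair product.

Defaults emulate the study conditions: n = 5, λ = 0.46, mono-exponential
background, D1 = 25 Å (a mid-range inter-label distance well inside the
shape-reliable zone of a 4–8 µs window).

## Stoichiometry

Δ = 1 − (1 − λf)^(n−1) is fitted for λ ∈ [0, 1] by bounded scalar
minimisation of the unweighted squared loss (no weights are published for
this protocol; inverse-variance weighting is available but off by default).
A single (Δ, f) record uses the closed-form inversion. Back-calculated
labeling degrees f = (1 − (1 − Δ)^(1/(n−1)))/λ are clipped to [0, 1] with a
flag rather than raising — experimental depth noise can overshoot the model
range. The quadratic-loss picture behind the formula is exact only for
two-spin systems; for n = 5 it is used as the working model without
higher-order correction, as is standard.

## C5 geometry and pore diameter

"Inner diameter" is mapped to the circumscribed-circle diameter of the
label pentagon: under uniform ring expansion a D1 shift δ gives a diameter
change δ/sin 36° and a D2 shift φ·δ. This interpretation reproduces the
observed 3 Å → ~5 Å diameter relation (3/sin 36° = 5.10) and the ~9 Å
expanded pore over a 4 Å closed pore, and ties the two distance shifts
together as a consistency check (3 Å → 4.85 ≈ 5 Å on D2).

The pseudo-label predictor replaces rotamer-library modeling at desk scale:
labels sit at Cα + 7 Å along the Cα→Cβ unit vector with 2.5 Å isotropic
Gaussian spread (both configurable; 7 Å is a typical Cα-to-nitroxide
midpoint distance for the MTSSL side chain, 2.5 Å a typical rotamer-cloud
width). PDB reading uses the first model, altloc 'A', chain order as subunit
order. Anchors are ordered by angle in their best-fit plane; a consecutive
gap ratio above 3 marks the anchor set as not forming a single ring and the
neighbour classes as undefined.

## ESEEM

The fit is staged: stretched-exponential baseline a·e^(−(T/T_b)^β) first,
then the damped cosine k·e^(−T/T_d)·cos(2πνT + φ) on the normalised
residual y/baseline − 1, with ν initialised at the deuterium Larmor
frequency (2.26 MHz at 0.346 T, configurable) and bounded to [0.2, 12] MHz
(hitting a bound is flagged). A global joint refinement (default on) then
removes the bias the staged baseline inherits from the oscillation; with it,
noiseless round trips recover all parameters to machine precision. The
exact damped-harmonic parameterisation is a package choice — none is
standard — and is documented here. Parameter uncertainties come from the
local curvature (covariance) of the least-squares fit; accessibility ratios
propagate them to first order, and a denominator within 2σ of zero raises
rather than returning an unstable ratio. The frequency-domain display
(Hamming window, 4× zero-fill, magnitude FFT) is for inspection; the
fitted k is the accessibility metric, with the spectrum's deuterium peak
amplitude available alongside. τ (proton blind spot) is carried as metadata;
no blind-spot correction is applied to k.

## Occupancy

Residency uses the inclusive ≤ 5 Å criterion with a configurable atom
quorum (default: any single chain atom suffices — which atoms count is not
standardised, so it is configuration, not a guess). Multi-pocket ambiguity
resolves to the nearest pocket (minimum of minimum distances), making the
per-frame assignment a partition. Counting is plain `cdist` over small
frames, verified against an O(N²) pair scan. No periodic-boundary handling:
inputs are assumed whole/unwrapped (documented limitation). The toy
trajectory generator moves chains between bulk and pocket slots with Markov
dwell/entry probabilities (defaults: dwell 0.9, entry 0.1 per frame, two
slots per pocket — i.e. up to two acyl chains per nano-pocket, ten per
pentamer), placing resident beads within 3 Å of the anchor and bulk chains
beyond 10 Å, so the 5 Å counter must reproduce the constructed series
exactly; correlation against per-frame structural metrics is plain Pearson
with a ±lag profile and no significance claim.

## Problem sizes and determinism

Test and pipeline problem sizes are chosen for a single CPU: inversion
grids of 61–131 distance points, traces of 100–400 samples, ensembles of
12–800 members, 10⁴ Monte-Carlo configurations for depth checks. The full
800-member protocol runs in seconds at these sizes. Every stochastic
component takes an explicit integer seed (`numpy.random.default_rng`);
fixed seed means bit-identical traces, trajectories and reports (timestamps
are written to a separate file).

## Known limitations

- The pair-product multispin model omits ghost-peak artifacts real
  multi-spin systems show at high λ.
- The white-noise assumption is untested against real spectrometer noise.
- The pseudo-label model cannot capture rotamer multi-modality; predicted
  widths are symmetric by construction.
- Reliability-zone constants are a heuristic convention, not calibrated
  against a reference implementation.
- Occupancy counting has no PBC support and assumes pocket reference atoms
  are provided (or taken from a named residue per subunit in PDB input).
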