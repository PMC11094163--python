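# Methods

This note documents the models, calibration constants, and numerical
choices behind `pdtsim`, and what its synthetic benchmarks do and do not
demonstrate about real treatment data.

## The scientific setting

A sequential two-wavelength PDT program drives two distinct photochemical
events in an RB-loaded light-responsive micelle (RB-M): a 405 nm phase
degrades the micelle and releases the photosensitizer, and a 580 nm phase
photoactivates the released RB to generate singlet oxygen. The package
simulates the comparison of the two possible phase orders (405–580 vs
580–405) over a four-factor treatment space: RB-M concentration (mg/mL),
protocol, total PDT time (min), and transmitter input power (mW, set in
dBm on the generator).

## Synthetic viability dataset

The in vitro viability measurements that would anchor the surrogate are
not publicly available; `pdtsim.datasets` generates a synthetic stand-in
with a known ground truth. The generating surface is

```
V(c, p, t, P) = 1 − E_max(p) · c^h / (EC50^h + c^h) · D/(D50 + D),  D = P·t
```

- **Hill-in-concentration** captures a saturating dose–response in the
  photosensitizer; **saturating-in-light-dose** captures the diminishing
  return of added fluence once most activatable RB has reacted.
- **Protocol enters only through E_max**: the release-first order
  accesses more free photosensitizer, hence a larger maximal kill.

Defaults: `EC50 = 0.8 mg/mL`, `h = 2`, `E_max(405–580) = 0.93`,
`E_max(580–405) = 0.65`, `D50 = 500 mW·min`, noise SD `σ = 0.08`
(viability fraction). The two E_max values are pinned by the benchmark
endpoints the surface must reproduce — viability ≈ 0.21 and ≈ 0.45 at
(2 mg/mL, 60 min, 400 mW) — which also fixes the inter-protocol
viability gap at ≈ 0.2 for concentrations ≥ 1 mg/mL. The noise level is
chosen so a well-regularized fit attains a held-out R² in the mid-0.8
range, the fit quality regime this workflow operates in.

The factorial grid is 9 concentrations (0.25–2.25 mg/mL in 0.25 steps) ×
2 protocols × 3 times (20/40/60 min) × 7 power levels (−18…−12 dBm,
converted by `10^((dBm+43)/10)` mW, i.e. 316.2–1258.9 mW). The grid
size 9·2·3·7 = 378 splits exactly into the 252/126 train/validation
design. The split is uniform random without stratification; noisy
viability is clipped to [0, 1] (deterministic, no resampling). All
randomness flows through one `numpy` Generator seeded by the caller.

What the generator does **not** emulate: cell-line identity, spheroid
geometry, uptake kinetics, plate/batch effects, or heteroscedastic
assay error. Tests passing on this dataset show the pipeline recovers a
known smooth four-factor surface under additive noise — not that the
network would fit any particular laboratory dataset.

## Viability surrogate

A single-hidden-layer network, 4 inputs → 20 tanh units → affine output,
predictions clipped to [0, 1]. Continuous inputs are z-scored on the
training split; protocol is a binary code (580–405 → 0, 405–580 → 1).

Fitting minimizes the training SSE plus an L2 weight penalty
(`alpha = 0.05`), using scikit-learn's seeded L-BFGS solver
(`max_iter = epochs`, default 5000, `tol = 1e-9`); the fit is
deterministic given (dataset, seed, epochs, alpha). The penalty matters:
a 20-unit tanh layer on 252 points interpolates the σ = 0.08 assay noise
if left unpenalized, dropping held-out R² to ~0.6–0.7, well below the
~0.87 noise ceiling `1 − σ²/(Var(signal)+σ²)`. Any alpha in ~0.03–0.2
sits on the noise-ceiling plateau; 0.05 keeps the noiseless-surface fit
essentially exact (grid MAE ≈ 0.005) while giving the most stable
held-out performance across seeds. Prediction uses the package's own
forward pass from the stored weights, so serialized models are
self-contained.

Fit quality is reported as R² = 1 − SSE/SST (each split's own mean) and
raw SSE. When a split's response is constant, SST = 0 and R² is reported
as NaN with an explicit `r2_*_defined` flag rather than raising.
Degenerate constant-target datasets short-circuit to the exact constant
fit (zero weights, bias = the constant) since the optimizer's behavior
at zero gradient variance is solver-dependent.

Factor importance is permutation importance on the validation split —
the mean increase in SSE over seeded reshuffles of one factor column —
chosen because it is model-agnostic and directly testable (an inert
factor must score ≈ 0; concentration, the dominant factor of the
surface, must rank first).

## Agent-based simulation

Cell agents are ACTIVE or DEAD (absorbing); photosensitizer agents are
INACTIVE until the first light phase, then permanently in the activated
state matching the run's protocol. The schedule splits total PDT time
into two equal phases in protocol order (the split is a config choice;
only total time is physically constrained). Step size dt = 1 min.

Cytotoxicity is confined to the 580 nm phase (k steps): each active
cell dies independently per step with probability

```
p = 1 − V̂^(1/k)
```

where V̂ is the surrogate's predicted viability for the condition. The
expected surviving fraction after k steps is then exactly V̂, making the
ABM's calibration provable: over R replicates of n cells, the mean final
viability must lie within a 99% binomial confidence interval of V̂ with
n·R trials (a standing test). Replicate r uses seed `seed + r`, so runs
are reproducible and protocol comparisons can share replicate seeds
(paired design). Whether a real implementation would spread hazard over
both phases is not determinable from endpoint data; confining it to the
photoactivation phase is the minimal mechanistic reading and is exposed
by the schedule's `kill_phase_index`.

Photosensitizer agents are bookkeeping for visualization (count
proportional to concentration, 100 per mg/mL); the concentration effect
on killing lives entirely in the surrogate. No spatial arrangement or
movement is modeled; the trajectory (viability per step) is the output.

Benchmark problem size: 1000 cells × 20 replicates (20 000 Bernoulli
chains), which resolves the endpoint to a Monte-Carlo SE of ~0.003 —
far below the ±0.05 tolerance of the endpoint checks — in well under a
second.

## Photophysics calibration

- **Degree of polymerization**: DP = (Ib/6)/(Ia/180) from the methoxy
  (Ib) and PEG-block (Ia) proton integrals; scale-invariant; reported
  raw and rounded. Measured integrals give DP = 33 vs the theoretical 30.
- **Loading/encapsulation efficiency**: LE = loaded RB / loaded-carrier
  mass, EE = loaded RB / RB charged, both ×100%. The formulas are
  implemented as defined; the measured values reported for this
  formulation (LE 14.2%, EE 41.4%) are not mutually recoverable from
  the printed charge masses and are treated as data, not derivations.
  Note one arithmetic consistency limit: 14.2% of a 1 mg/mL solution is
  0.142 mg/mL, though the source text quotes 0.014 mg/mL at that point;
  `loaded_rb_concentration` follows the arithmetic.
- **Release kinetics**: first-order to a plateau,
  `f(t) = plateau·(1−e^{−kt})`. Plateaus (0.75 irradiated / 0.45 dark)
  are calibration constants chosen between the 5-h anchors and 1.0;
  the rates are solved at construction so the curves pass exactly
  through the anchors (68% and 30% released at 5 h), giving
  k = 0.4743 h⁻¹ and 0.2197 h⁻¹. Overridable via config.
- **SOSG singlet-oxygen fold**: linear, `1 + slope·t`, slopes anchored
  at the 40-min folds (6.6× free RB at 580 nm, 1.37× encapsulated RB at
  580 nm, 2.58× concurrent 405+580 nm). The 405-only condition is
  described qualitatively as minimal; its slope defaults to the
  encapsulated-580 value — an explicit assumption, enforced only as
  `RBM_580 ≥ RBM_405` in the ordering invariant. Real SOSG curves
  saturate; the linear form is valid near the calibrated window only.
- **Dosimetry**: fluence = irradiance (mW/cm²) × minutes × 60/1000
  (J/cm²); generator mapping dBm → mW with a fixed +43 dB offset
  inferred from the printed seven-pair table.

## Agreement statistics

Tumor volume V = L·W²/2 (mm³), with the convention length ≥ width
enforced. Bland–Altman agreement: bias = mean(a−b), limits of agreement
bias ± 1.96·SD(a−b) with the sample (n−1) SD and the normal 95%
multiplier (not a t-quantile). The result object exposes bias, SD, both
limits, and the half-width so any single-number summary convention can
be recovered.

## Known limitations

- The surrogate's R² is plain 1 − SSE/SST; likelihood-based generalized
  R² variants would differ and are not implemented.
- Endpoint quantities inherited from a single fitted surrogate carry
  its prediction error at that grid point (SD ≈ 0.03 under the default
  noise level); replicated ABM runs average over death randomness but
  not over dataset/fit randomness.
- The concurrent (both wavelengths at once) program appears only in the
  SOSG calibration, not as a simulation mode; the ABM covers the two
  sequential protocols.
- No spectral, thermal, or tissue-optics modeling; power is the nominal
  transmitter input, not delivered irradiance at depth.
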