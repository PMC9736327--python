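# Methods

Model assumptions, parameter defaults, and numerical choices for each
`cavlipid` module.  Nothing here asserts an empirical result the code does
not compute.

## Sequence and motifs

Sequences are uppercase one-letter amino acids; `X` (unknown) is accepted
in input and may occupy motif gap positions but never an anchor position.
Coordinates are 1-based inclusive; `numbering_offset` maps a fragment onto
full-length numbering (the bundled caveolin-2 α isoform is 162 residues).

Motif definitions (gap consensus, scanned left to right):

| motif | pattern | anchors |
| --- | --- | --- |
| CRAC | `(L/V)-X1–5-(Y/F)-X1–5-(K/R)` | aliphatic / aromatic / basic |
| CARC | `(K/R)-X1–5-(Y/F)-X1–5-(L/V)` | basic / aromatic / aliphatic (CRAC mirrored) |
| CBM | `Φ-X4-Φ-X2-Φ`, Φ ∈ {F, W, Y} | three aromatics, fixed gaps |

The scanner enumerates every gap combination and reports each distinct
`(start, end)` span once.  When several gap parses give the same span, the
representative parse minimizes the first gap, then the second, which keeps
anchor reports deterministic.  `anchor_string` renders anchors as e.g.
`K81/Y85/L88`.  An optional widened CARC center (`wide_center=True`)
admits W at the aromatic anchor for exploratory scans; the default is the
strict Y/F consensus.  Overlap reports give intersection length and
containment for hits of different classes on the same sequence.

Correctness is tested against a brute-force regex oracle
(`re.fullmatch` per candidate span) on random sequences.

## Hydropathy (Wimley–White interfacial scan)

The per-window free energy is the plain sum of Wimley–White
water-to-POPC-interface transfer free energies (kcal·mol⁻¹; charged
D/E/K/R, neutral H) over a sliding window, assigned to the window's
central residue.  Negative values mean favorable interface partitioning.

| parameter | default | rationale |
| --- | --- | --- |
| `window_length` | 19 | standard interfacial-scan window; must be odd |
| `threshold` | 0.0 kcal·mol⁻¹ | a window is "favorable" when its summed ΔG < threshold |
| `min_centers` | 1 | a segment is any maximal run of favorable window centers |
| `impute_unknown` | False | unknown residues abort the profile unless imputation (scale mean) is requested |

Segment calls report the centre-run span, its mean and minimum ΔG.  For
the bundled 162-residue caveolin-2 sequence the calibrated setting
`min_centers=2` (segments must persist over at least two consecutive
window centres, suppressing single-window blips) yields exactly three
favorable segments — 70–71, 73–127, and 148–150 — whose union covers the
CARC at 81–88.  This run-persistence value was fixed as a documented
calibration of the segment rule, not fitted per input; the function
default stays at 1.

Disorder profiles (per-residue scores in [0, 1] from an external
predictor) are ingested or synthesized, never predicted here.
`fraction_disordered` counts residues with score ≥ threshold (default
0.5) and reports contiguous above-threshold regions.

## Circular dichroism

* Mean residue ellipticity: `MRE = mdeg / (10 · l_cm · c_M · N_res)` in
  deg·cm²·dmol⁻¹.
* θ222/θ208 ratio: both ellipticities from linear interpolation on the
  measured grid (grids are ≤ 2 nm, so curvature is negligible); both must
  be negative for the ratio to be meaningful; classification is
  `coiled_coil` iff ratio > 1 strictly.
* Shape classification: spectra are smoothed with a width-3 moving
  average (one grid point each side — enough to kill single-point noise
  without moving band minima), then local minima are sought in the
  205–235 nm band.  "w" requires a minimum in 206–212 nm followed by one
  in 218–226 nm; "v" requires exactly one minimum in 215–222 nm.
* Deconvolution: non-negative least squares (`scipy.optimize.nnls`)
  against a basis matrix, coefficients renormalized to fractions summing
  to 1.  A condition-number check (`np.linalg.cond`, limit 1e8) rejects
  collinear bases.  The shipped `default_basis` is a synthetic
  Gaussian-band construction (regular helix 192+/208−/222−, distorted
  helix, right-twisted strand 217−, turn, other 198−), unit-tested by
  recovering random simplex mixtures at 2 % noise to a mean absolute
  fraction error below 0.05; user-supplied basis files are accepted via
  TSV.  Deconvolution of real spectra against this synthetic basis gives
  qualitative fractions only.

## Fluorescence

* Grating factor `G = I90/0 / I90/90`; anisotropy
  `r = (I∥ − G·I⊥)/(I∥ + 2G·I⊥)`; the inverse
  (`polarized_from_anisotropy`) emits intensities realizing a target r
  exactly.
* Binding fits: `y = baseline ± P1·x/(Kd + x)` with the sign set by the
  series' declared observable kind.  Bounded least squares (lmfit,
  `leastsq`) with P1 ≥ 0 and Kd > 0; initialization: baseline = y(0),
  P1 = |Δy|, Kd from half-amplitude interpolation
  `np.interp(0.5, |y − y(0)|/P1, x)`; three seeded random restarts guard
  against poor starts.  A flat series returns `kd=None` with
  `amplitude_zero=True`; a fitted amplitude below 1e−9 of the data scale
  or below its own standard error is likewise flagged (with a warning)
  rather than reported as a binding constant.
* FRET efficiency `E = 1 − F_DA/F_D`.  Apparent donor enhancement
  (F_DA > F_D) yields E = 0 with a warning rather than an error so noisy
  pipelines keep running.
* Quenching: `q(x) = 1 − F(x)/F(0)` fitted to `P1·x/(Kd + x)` with the
  zero intercept fixed; `evaluate` returns percent quenching at a given
  concentration.
* x units are μM throughout the CLI; converters are the caller's job.

## DSC

Input is excess molar heat capacity (kJ·mol⁻¹·K⁻¹) on a strictly
increasing temperature grid (°C); `molar_normalize` converts raw per-cell
heat capacity when concentration and cell volume are known.

* Baseline: a line through (window centre, window mean cp) of disjoint
  pre- and post-transition windows; a window whose internal slope exceeds
  5× the global baseline slope triggers an "overlaps the transition"
  warning.
* `analyze` requires ≥ 50 points, demands the peak clear a noise floor
  (mean + 5σ of the edge 10 % of the scan), refines the apex with a
  parabola through the maximum and its neighbours (`tm_c`), and
  integrates cp trapezoidally for the calorimetric enthalpy `dh_cal_kj`.
* Two-state fit: `cp(T) = ΔH²K / (R·T²·(1+K)²)` with
  `K(T) = exp[(ΔH/R)(1/Tm − 1/T)]`, ΔCp fixed at 0 (exposed as an
  option), R = 8.314462618×10⁻³ kJ·mol⁻¹·K⁻¹.  The fit returns the
  van 't Hoff enthalpy `dh_vh_kj` and the thermodynamic `tm_fit_c`.  Note
  the apex of a two-state cp curve sits ~0.1–0.2 °C below the
  thermodynamic Tm (the 1/T² factor skews the peak), so `tm_c` (apex) and
  `tm_fit_c` (fit parameter) are both reported and deliberately not
  identical; self-consistency tests assert `tm_fit_c` to 0.1 °C and
  `dh_vh/dh_cal ≈ 1` for synthetic two-state data.

## Synthetic generators

`cavlipid.synth` emits every input kind the analysis modules consume, from
a frozen `GeneratorConfig(seed, scenario, overrides)`.  Defaults (constants
table version 1.0) encode the bundled study conditions and are never
adjusted by callers implicitly — only explicit `overrides` change them.

| scenario | defaults | artifact choices |
| --- | --- | --- |
| `fret_titration` | Kd 0.75 μM, 8 points over 0–3 μM | baseline 100, P1 50 (arbitrary intensity units) |
| `anisotropy_titration` | r = 0.21 − 0.04·x/(0.48 + x) at 30 % cholesterol; flat r = 0.12 otherwise | — |
| `dph_quenching` | max quenching 0.75, Kd 0.5 μM (⇒ 60 % at 2 μM), 9 points over 0–4 μM | F₀ = 100 |
| `fret_saturation` | efficiency 0.16 at saturation | F_D = 100 |
| `polarized_baseline` | target r 0.21, G 1.2 | total intensity 300, I90/90 = 50 |
| `dsc_three_condition` | Tm 55/60/65 °C, ΔH 250/300/350 kJ·mol⁻¹ (buffer / +SUV / +SUV+chol) | grid 20–95 °C, step 0.25 |
| `motif_plant` | CARC `KYVMYKFL` planted at 81 in a 120-residue background | background alphabet excludes all anchor residues so planted spans are the only hits |
| `cd_mixture` | fractions 0.551/0.211/0.002/0.077/0.158 over the default basis | Gaussian noise scaled to max ellipticity |
| `disorder_profile` | length 162, above-threshold fraction 0.46, peak region 30–50 | beta-distributed scores |

Noise is Gaussian with `noise_sigma_fraction` of the relevant amplitude
(default 0 — noiseless).  Every artifact carries a `truth` record of its
generating parameters, and `write_artifact` serializes data plus
`truth.json` in the package's own text formats.

Scope and limits: generators emulate the *shape* of each measurement
(hyperbolic saturation, two-state cp peaks, basis mixtures, planted
motifs), not instrument physics — no photobleaching, scattering,
scan-rate, or baseline-drift models, and DSC noise is white rather than
1/f.  They exist for round-trip validation of the analysis code.

## Pipeline and reproducibility

`cavlipid run --config run.yaml` validates the configuration (unknown keys
and missing inputs are rejected before any work, with stage and path
named), executes the enabled stages, and writes per-stage reports plus a
`summary.json` that logs every default in effect.  Reruns with identical
inputs produce byte-identical reports; table floats are rendered at four
significant digits, while TSV data writers use `repr` so values round-trip
exactly (readers parse with `float_precision="round_trip"`).

`scripts/acceptance.py --seed S --out f.json` recomputes the reference
numbers end to end; `--seed` feeds a single `numpy.random.default_rng`
stream that derives all fit-restart and replicate seeds.

## Limitations

* Disorder and CD-fraction *predictors* are out of scope; only their
  outputs are handled.
* The CD basis is synthetic; absolute secondary-structure percentages
  from real spectra require a user-supplied experimental basis.
* DSC analysis is single-transition; no multi-peak deconvolution.
* Binding fits assume a single-site hyperbola; cooperativity or
  depletion (ligand ≈ receptor concentration) is not modelled.
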