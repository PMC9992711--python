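# Methods

## Model

The receptor population is described by occupancy fractions over eight
lumped states:

| state | meaning |
|---|---|
| `R` | unliganded receptor; the heterotrimeric Gq(GDP) pool is treated as non-depleting (G subunits are overexpressed and membrane-tethered), so resting preassembly is represented only through FRET coefficients, not a separate species |
| `RL` | agonist-bound, not G-coupled |
| `RLG` | agonist-bound receptor·heterotrimer complex |
| `RLGx` | as `RLG` but permanently locked by YM-254890 that was not released at inhibitor washout |
| `RLSep` | Gα-GTP and Gβγ separated, both still receptor-associated |
| `RLSepPLC` | `RLSep` with PLCβ recruited to Gα-GTP |
| `RGa`, `RGaPLC` | post-washout receptor holding Gα-GTP without Gβγ, without/with PLCβ |

Transitions are first order.  Activation is the irreversible chain
`RL → RLG` (rate `k_couple`) followed by `RLG → RLSep` (rate `k_exch`,
lumping GDP release, GTP binding and subunit separation into one
exponential step — the slow activation phase is empirically
single-exponential, so the sub-steps are not separately identifiable).
Agonist binding `R ⇌ RL` uses `k_L_off = ln 2 / 0.05 s⁻¹` (sub-sampling-
interval equilibration at 10 Hz) and `k_L_on = k_L_off / K_d` with the
agonist affinity taken from the construct's functional EC50 (0.112 µM
Oxo-M, 0.007 µM ACh, ~2 µM for the coupling pair).  Deactivation
transitions — Gβγ release (`k_bg_off`), hydrolysis-driven Gα release
(`k_hyd`), PLCβ release (`k_plc_off`) — are multiplied by a smooth gate
`1 − C/(C + c₀)` with `c₀ = 10⁻³ µM`, which keeps the complexes stable
while agonist is present (leak < 0.2 % of the rate at 10 µM) yet opens
within the ~20 ms solution exchange after washout.  The observed onset
delay is attributed to the exchange filter plus a bounded free delay in
the step-1 fit.

Condition modifiers: GDPβS multiplies `k_exch` by 0.2 (the slow step is
about five-fold slower); YM-254890 forces the exchange rate to zero while
present, and on inhibitor washout only a fraction (default 0.31) of the
blocked complexes resumes cycling — the remainder moves to `RLGx`, which
can only release on agonist washout; Q209L, R183C and GTPγS share a
"pre-separated G pool" initialization in which `RL → RLSep` proceeds
directly at `k_couple`, hydrolysis is disabled, and washout releases
everything in the fast step (hence single-step ON, ~100 % single-step
recovery, no slow OFF component); the 3A and R166L receptors set
`k_couple = 0`, leaving only agonist binding (which is FRET-silent for
every construct).

Integration uses LSODA (`scipy.integrate.solve_ivp`, rtol 1e-7,
atol 1e-9), restarted at every stimulus segment boundary, sampled onto the
protocol grid and renormalized against accumulated round-off; occupancy
conservation is enforced to 1e-8.  Wherever the active subnetwork is a
linear chain the integrator is checked against the closed-form sequential
decay solution (repeated-root limit handled continuously) to 1e-6.

## Calibration

Rates are the reciprocals of the reported macroscopic time constants, per
construct: the intramolecular sensor uses τ = 0.22 / 1.92 / 0.47 / 20.02 s
(coupling / separation / Gβγ release / hydrolysis), the receptor–Gβγ pair
0.23 / 0.53 s, and the Gα–Gβγ pair 1.45 / 21.37 s for its separation and
hydrolysis steps.  A `refined` calibration mode additionally adjusts
(`k_couple`, `k_exch`) by simulation-based least squares so that the
*pipeline-fitted* noiseless time constants hit the targets within 5 %.

PLCβ recruitment is not quantified beyond being slower than receptor–Gα
coupling with a release time between the two deactivation steps;
`k_plc_on = 0.7 s⁻¹` and `k_plc_off = 1/8 s⁻¹` are fixed once to satisfy
that ordering and are only active in the effector-pair presets.

## FRET rendering

Each construct has a per-state true-ratio coefficient table ε (in the
preset registry, not in code).  The true ratio is Σ ε_s·occupancy_s(t) and
the channels are rendered as

    CFPc = D·e^(−bt) + N(0, σ_d),   YFPc = (ratio + cFactor)·D·e^(−bt) + N(0, σ_a)

with `cFactor = 0.45`, so the ratio computation inverts the render exactly
in the noiseless limit, and shared bleaching cancels in the ratio (a
non-cancelling differential-bleach mode exists, default off).  Noise is
i.i.d. Gaussian per channel per sample — the narrowest assumption
consistent with the published summary statistics, which give no noise
spectrum; per-channel SDs are solved from the target SNR by first-order
error propagation through the ratio.  Target SNRs: 169 (intramolecular),
90 / 69 (receptor–Gβγ with GTP / GDPβS), 150 for the Gα–Gβγ pair (only
reported as indistinguishable from the intramolecular slow step).  Because
SNR uses the *maximum* response deviation, the measured SNR of a
calibrated trace sits a few percent above the target — expected behaviour
of a max-statistic, tolerated in the calibration check.

One deliberate calibration detail: for the intramolecular sensor the ε
drop is split 0.557 / 0.443 between `RLG` and `RLSep`, not 50/50.  The
observable reported as "both steps ≈ 50 %" is the *fitted biexponential
amplitude split*, and for an irreversible chain the trace decomposes
additively as A_fast·e^(−k₁t) + A_slow·e^(−k₂t) with
A_fast = s − (1 − s)·k₂/(k₁ − k₂) for coefficient share s; equal observed
amplitudes at the calibrated rates therefore require s = 0.557.  Post-
washout Gα-holding states sit halfway so the two recovery steps carry
roughly equal amplitude.

Per-cell variability is lognormal (mean 1) on every kinetic rate with
CV 0.2 — chosen so the across-cell dispersion of recovered τ matches the
scale of the published SEMs — plus a CV 0.10 lognormal amplitude factor.
All randomness derives from one `numpy` `SeedSequence`, so datasets are
byte-reproducible from (preset, n, seed).

## Dose–response generation

Simulating the full ODE at sub-saturating agonist would kinetically trap
receptors in the coupled states (k_couple·t ≫ 1 over a 15-s application),
pushing the apparent response EC50 orders of magnitude below the binding
constant — a regime the mean-field chain is not meant to describe.  The
dose-series generator therefore uses a fast-equilibrium amplitude model:
the saturating response is scaled by the equilibrium occupancy
c/(c + K_d) at each concentration, with K_d equal to the construct's
functional EC50.  Recovering that EC50 through the Hill fit then validates
the dose–response analysis, not the occupancy model.

## Fitting

All fits are unweighted nonlinear least squares (lmfit/MINPACK) with
three log-spaced initial time constants; the best residual wins.  The
windowed two-step decomposition (ON 0–1.2 s and 1.3–15 s; OFF 0–3.6 s and
3.7–30 s after the mark) fits the slow window first and then removes its
backcast from the fast window before fitting step 1 (exponential
peeling), iterating the strip until both τ settle (≤30 rounds, needed
only when the τ ratio is small).  Stripping is skipped when the fitted
"slow" constant would explode under backcasting
(e^(gap/τ₂) ≥ 5 — i.e. the slow window only caught a fast tail), in which
case step 1 falls back to a single exponential plus linear drift.  On
noiseless additive biexponential traces the recovered τ bias is below 2 %
across τ₁ ∈ [0.1, 0.5] s, τ₂ ∈ [1, 4] s at 10 Hz.  Step-1 fits include a
delay bounded to [0, 0.5] s; step-2 fits are anchored at their window
start with zero delay; windows are anchored at the stimulus mark, not the
fitted delay.  τ at a bound and amplitudes under 5 residual SDs are
flagged (`tau_at_bound`, `unidentifiable`) rather than rejected.  100-Hz
traces are fitted on their native grid.

For τ₂ well beyond the ON window (GDPβS, true τ ≈ 9.6 s inside a 13.7-s
window) the step-2 fit remains finite with a bias that stays within the
±30 % band used for the slowdown-ratio comparison.

"Standard error of the baseline" in the SNR is read literally as
SD/√n over the 5-s baseline window; an SD-only mode is available
(`compute_snr(..., mode="sd")`) since the published definition is
ambiguous.  The single-step percent-ON metric mixes per-cell and
group-average quantities; it is implemented exactly as defined, taking
the group-average normalized trace as an explicit argument.

Dose–response fits are 4-parameter logistic with the bottom fixed to 0 on
normalized responses (free behind a flag); an EC50 outside the tested
concentration range is flagged as extrapolated.  T50 is the midpoint of a
logistic fit to ROI-intensity-style traces; a residual RMS above 15 % of
the fitted amplitude flags a non-sigmoid input.

## Problem sizes

Registered-value recovery uses 20 cells per condition at 10 Hz (protocol
lengths 45–170 s depending on the slowest time constant present: the
GDPβS separation pair records ≥60 s of agonist, the Gα–Gβγ washout ≥90 s)
and a 7-concentration dose series with 10 cells each — the same order as
the published per-condition cell counts (n = 5–24).

## What the generator does and does not emulate

Emulated: two-channel photometry with donor bleed-through, calibrated
channel noise, shared (cancelling) photobleaching, the ~20 ms solution
exchange, per-cell kinetic and amplitude heterogeneity, and every
perturbation condition's kinetic signature.  Not emulated: shot
noise/photon counting, detector saturation, spatial imaging, receptor
internalization and arrestin pathways, stochastic single-complex dynamics
(the mean-field ODE is exact only for large receptor numbers), GRK2
mechanism (a pure amplitude scaling on the Gα–Gβγ pair), and any
hypothesis testing (only mean ± SEM summaries are produced).  Passing
recovery tests therefore demonstrates the internal consistency of model +
renderer + analysis under these assumptions, not the fidelity of the
model to cellular reality beyond the calibrated time constants.

## Known limitations

- The sequential-chain trace is mathematically biexponential with an
  amplitude split fixed by the rate ratio; the ε split was calibrated to
  reproduce the observed ~50/50 distribution (see above), so the percent
  split is a consistency check of the analysis, not an independent
  prediction.
- The washout gate is a phenomenological occupancy switch; sub-second
  structure of deactivation immediately around the exchange (< ~50 ms) is
  not meaningful.
- The YM washout unblocked fraction (0.31) is an exposed configuration
  constant, not a mechanistic prediction.
- Percent metrics for two-step fits use the normalized full amplitude
  (= 1) as the denominator; with fit amplitudes this can total slightly
  under 100 %, and the remainder is reported.
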