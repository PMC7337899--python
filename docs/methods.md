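# Methods

## Substrates

A substrate is a partial duplex (default 18 bp) with a 3' single-stranded
extension consisting of an optional G4 block and a poly-dT tail. Only
lengths, topology (non-parallel vs parallel), ligand state and buffer
cation enter the computations; sequence identity is kept for naming. The
default G4 block is four TTAGGG repeats (24 nt), so the G4-T15 construct
tracks 39 nt — the same length as the T40 control. The parallel
(c-Myc-type) block is modeled by a 24-nt parallel-topology placeholder
with a synthetic stand-in sequence, since no computation depends on its
bases. Derived competence flags: helicase loading requires a tail at
least the ~8-nt Rep footprint; stable RecA nucleation requires
`site_nt × nucleus_monomers` = 3 × 6 = 18 nt of free single strand.

## Helicase kinetic model

Stage II (G4 resolution) is the minimal alternating two-state scheme
that produces the observed repetitive FRET fluctuation: folded → (rate
`k_unfold`) transiently unfolded, which either commits to duplex
unwinding (probability `p_commit` per attempt) or refolds (rate
`k_refold`). The attempt count is geometric, giving the closed form

    tau_II = 1/(p k_unfold) + (1 − p)/(p k_refold),

which is verified against a vectorized Monte-Carlo sampler (10^6
replicates, <1% deviation) and against the event-driven simulator. All
waiting times are exponential with the state's total exit rate (checked
by Kolmogorov–Smirnov at n = 10^4).

Because only stage durations, not microscopic rates, are observable, the
defaults fix `p_commit = 0.2` and `k_refold = 1 /s` and solve `k_unfold`
per protein so that the ATP-scaled stage-II mean at 2 mM ATP equals the
calibration targets: 40 s (UvrD), 20 s (Rep), 10 s (Rep-X). Stage III is
a single exponential dwell (not per-bp stepping) with an ATP-scaled rate
of 3 /s shared by all three proteins; stage IV (strand release) uses
`k_rel = 0.5 /s`; binding uses a shared `k_bind = 0.2 /s` at the working
100 nM protein concentration. ATP dependence enters microscopically as
`a/(K_m + a)` on `k_unfold` and `k_dup`, sharing the ensemble `K_m`;
only the ensemble Michaelis–Menten behavior is empirically constrained.

Molecules fail to complete unwinding with probability `1 − f_active`
(they bind and cycle indefinitely), which also models tail-length
effects: `f_active = 0.4` for T9 substrates, 0.75 for Rep-X on the
parallel G4. Rep and UvrD never commit on a parallel G4
(`parallel_competent = False`). Multiple/successive protein loading is
absorbed into `k_bind` and `f_active`; oligomer counting is out of
scope.

Ensemble survival assays use a shortcut: each active molecule disappears
with the ensemble rate `r = V_max a/(K_m + a)`; each scheduled time
point images fresh fields of view (as in the real protocol, which moves
to new areas to avoid photobleaching), so per-time counts are
independent binomial draws around `N0 (f e^{−rt} + 1 − f)`. Calibrated
`V_max` values: derived from printed loss fractions (75/50/25% at 2 min
for Rep-X/Rep/UvrD on G4-T15; 25/65/85% at 10 min for the BRACO-19
conditions) or taken directly where printed (2.86 /min T40, 1.37 T15,
1.32 G4-duplex, 0.44 parallel c-Myc with Rep-X; T9 rates
0.157/0.163/0.184 /min). `K_m` is 215 µM for the parallel G4, one third
of that (~72 µM) for non-parallel substrates, and a quarter of the
non-parallel value (~18 µM) for T40.

The BRACO-19 protocol inserts a dislodging lag (`LIGAND_LAG`) between
binding and the first unfolding cycle. Its mean defaults to
`(ligand_stage2_slowdown − 1) × tau_II` with slowdown 2, so the expected
total G4-resolution stage is exactly twice the ligand-free value —
the slowdown is the extra ligand-removal time, after which cycling
proceeds at normal rates.

## RecA lattice model

One monomer occludes 3 nt; a nucleus of 6 monomers (18 nt of free
strand) is required for stability. Shorter stretches support only
transient sub-nucleus clusters that dissolve at `k_sub_off`. Stable
filaments gain/lose end monomers at `k_ext`/`k_off`; a filament trimmed
below the nucleus collapses. A filament filling the tail against a
non-parallel G4 opens it at `k_invade` (divided by `ligand_slowdown`
while a ligand is bound) and may extend into the freed nucleotides; G4
reclosure at `k_g4_refold` displaces monomers inside the G4 region.
Parallel G4s never open. A bound ligand is ejected once the cumulative
open-G4 dwell reaches `eject_dwell_s` (2 s). Defaults
(`k_nuc = 0.2 /s`, `k_ext = 1 /s`, `k_off = 0.01 /s`,
`k_sub_off = 0.3 /s`, `k_invade = 0.3 /s`, `k_g4_refold = 0.3 /s` in K⁺,
0.002 /s in Na⁺) were chosen once to reproduce the qualitative trace
classes: stable full coverage on T40, persistent open/close fluctuation
on G4-T15 in K⁺, tail-limited transient binding on parallel substrates,
and stable complete unfolding in Na⁺ buffer.

Population (histogram-series) kinetics are parameterized directly by a
per-substrate plateau (fraction of molecules that ever assemble) and a
mean assembly time: T40 (1.0, 72 s), G4-T15 (0.75, 150 s), T15 (0.8,
240 s), ligand-bound G4-T15 (0.6, 480 s), Na-buffer G4-T15 (0.95,
150 s), parallel c-Myc-T15 (0.05, 600 s). These reproduce the plateau
ordering and the half-time ranking T40 < G4-T15 < T15 < ligand-bound.

## Photophysics and rendering

Green-excitation frames follow

    I_D = i_total (1 − E) · pife · q_D,   I_A = i_total E · q_A + l · I_D,

plus background and noise; red-excitation frames report direct acceptor
excitation (independent of E), which is what the ALEX filter exploits.
Frame values are time averages over the 100-ms integration window
(supersampled 8×), so mid-frame transitions render as partial frames.
State FRET values: folded G4 0.50, transiently unfolded 0.35 (chosen
between the folded and unwound levels so stage-II fluctuation is visible
above noise; not an observed value), unwinding ramp 0.35 → 0.10 (linear),
unwound 0.10, ligand-bound 0.20, bare tails interpolated 0.75 (T15) to
0.30 (T40), RecA coverage-interpolated down to 0.20 (tail-only filament)
and 0.05 (full filament). The ligand histogram shift 0.5 → 0.2 is
rendered phenomenologically as a distinct apparent E plus intensity
reduction: an equal quench of both dyes cannot move an intensity ratio,
so whatever the physical mechanism, the observable shift requires an
apparent-efficiency change. The detection-efficiency (gamma) factor is
fixed at 1 and no gamma correction is applied.

Noise: Poisson photon noise on signal + background (20 counts/frame),
Gaussian read noise (σ = 3), photobleaching with lifetimes of 3000 s
(Cy3) and 4000 s (Cy5) — the gentle-excitation regime the
oxygen-scavenger/Trolox buffer is designed to reach, so that bleaching
is visible in long traces without confounding the kinetics (bleaching
preferentially removes long-stage-II traces and would otherwise bias the
recovered mean low) — and a 15% acceptor-dark fraction so the ALEX
filter has real work. Flow-trace data sets are rendered without the
dark-acceptor subpopulation: real flow analysis selects molecules that
show FRET before the experiment starts.

Movies render each molecule as a symmetric 2-D Gaussian (σ = 1.2 px) in
both channels on a jittered grid with a minimum separation, 16-bit, with
pixel-level Poisson and read noise and an optional acceptor-channel
offset transform.

## Detection and trace extraction

The detection image is the mean of the first ten green-excitation
frames. Background is a 15-px median filter; the noise scale is the
median absolute deviation (×1.4826); spots are local maxima above
`k = 5` noise scales with a minimum separation, at integer-pixel
precision (sub-pixel localization is unnecessary for aperture extraction
at this PSF). Traces are aperture sums (9×9 px) minus a local
background estimated from the surrounding 2-px ring. Spot-count series
apply the field rule of averaging consecutive groups of three counts and
their times (rolling window 3), so the smoothed series is two points
shorter.

## FRET statistics

Per-molecule E uses the first ten green frames:
`E = (I_A − l I_D) / ((I_A − l I_D) + I_D)`, clipped to [−0.1, 1.1] so
correction overshoot survives into the edge bins. The leakage `l` is
either supplied or estimated by inverting the mean apparent E of the
donor-only population (`E_donor-only = l/(1+l)`); the estimate converges
to the rendering value within ±0.01 by a few hundred donor-only
molecules. Donor-only molecules are excluded when their red-excitation
acceptor signal is below threshold; traces without red frames cannot be
filtered and are kept with a warning. Histograms are area-normalized
with bin width 0.02. Gaussian mixtures are least-squares fits on the
binned density with free or restrained centers (restrained fits hold
supplied centers fixed, used for RecA-bound series); requesting more
components than the occupied support flags the fit ill-conditioned.

## Segmentation

Segmentation works in leakage-corrected apparent-FRET space; because
PIFE multiplies the donor, a bound state with true FRET E appears at
`E/(E + (1−E)·pife)`, and all thresholds are derived from the rendering
parameters through this map. Binding is the earliest run of five green
frames with donor ≥ 1.2× the pre-flow median (the PIFE step); release is
the sustained donor drop below a quarter of that median. The stage-II/III
boundary is anchored at the last down-crossing of the folded/unfolded
midlevel — after the final commitment the trace never returns to the
folded level — and cross-checked against the last down-crossing of the
ramp midlevel; when the two disagree by more than 1.2 s the final folded
dwell was sub-frame and the ramp crossing re-anchors the search.

The commit time and stage-III duration are then refined by least-squares
fitting the frame-averaged piecewise model (free constant pre-commit
level, linear apparent-FRET decline of duration d, unwound plateau) on a
window around the anchor. This matters because at `k_dup = 3 /s` and
100-ms frames roughly a quarter of stage-III dwells complete within a
single frame, where threshold crossings alone are biased; the fit keeps
the recovered mean dwell unbiased to within ~1%. Frames with total
signal below 30 counts carry no FRET information and are zeroed.

Traces are rejected, with reason codes, when binding or commitment is
not found, boundaries are disordered, the post-decline FRET tail sits at
zero instead of the unwound level (acceptor lost before release), or no
unwound-level frame exists between commitment and donor loss (donor
bleached mid-fluctuation masquerading as release). Acceptor bleach
during stage II is thereby rejected rather than truncated. On
default-noise scenarios the rejection rate is 3–5%.

Stage rates are inverse mean dwells with first-order error propagation
(`sem_rate = sem_dwell / mean²`); fewer than 150 contributing traces
sets a low-n flag. The stage-II dwell histogram's Gaussian fit is
constrained to the observed range; note that under the alternating
scheme the dwell distribution is right-skewed (geometric cycle count),
so the fitted mode lies below the mean — rates and recovery comparisons
use the mean, which is the calibrated quantity.

## Ensemble estimators

`fit_decay` fits `N(t) = N0 (f e^{−kt} + 1 − f)` by nonlinear least
squares, initialized from a log-linear regression of the early decay and
the terminal fraction; the plateau term activates automatically when the
terminal fraction exceeds 0.2 (T9- and ligand-style data cannot be fit
without it). The fit uses the raw aggregated counts: fitting the
window-3 smoothed series (which remains the plotted representation)
correlates neighboring residuals and makes the covariance-based
confidence intervals overconfident; with raw counts the 95% CI for k
covers the truth in ~95% of 200 simulated runs. Fits are unweighted.
`fit_mm` fits `r = V_max a/(K_m + a)` with initialization from the
maximum rate and the interpolated half-maximum; it requires at least
three distinct ATP concentrations. RecA assembly kinetics reduce each
histogram to the mass below E = 0.15, apply an isotonic (nondecreasing)
envelope, define the plateau as its final value and t_1/2 as the linear
interpolation crossing of half the plateau. Rates are reported in
min⁻¹ for ensemble quantities and s⁻¹ for stage rates, matching the
field's mixed conventions.

## Problem sizes and reproducibility

Default analysis scales: 300–1000 flow traces per condition (the
stage-II mean is heavy-tailed, sd ≈ 17 s at a 20 s mean, so its
recovery benefits from the larger samples), 3000–6000 molecules per
histogram, 20 views × 350 spots per survival time point, 1000–2000
molecules per RecA population. Every simulation takes one seed (or an
explicit generator); no global random state is used, and identical
(name, seed) pairs produce byte-identical generated data sets.

## What the generator does and does not emulate

The synthetic data carry the statistical structure the analysis relies
on — exponential state dwells, PIFE and quenching amplitudes, ALEX
structure, leakage, shot and read noise, bleaching, acceptor-dark
molecules, diffraction-limited spot images, binomially thinned spot
counts. They do not emulate flow artifacts, stage drift, triplet
blinking, spectral crosstalk beyond a single leakage term, EMCCD gain
statistics, chamber geometry, or sequence-dependent G4 energetics; and
the c-Myc block is a length/topology placeholder. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every artifact of real movies.

## CLI

`g4fret` exposes `list-scenarios`, `simulate` (write a scenario's data
plus a JSON ground-truth sidecar; traces as CSV, movies via the
photophysics API as TIFF) and `run` (full pipeline, JSON report with
truth-vs-estimate deltas). Reports are reproducible from the archived
configuration and seed.
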