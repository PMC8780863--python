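# Methods

## The model

`frqclock` implements a delay-differential model of the *Neurospora
crassa* core circadian oscillator — the FRQ/WC-based oscillator (FWO)
— driven by blue light through the White Collar Complex (WCC) and
photoadapted by VVD, together with the analysis operations needed to
ask how the clock responds to short symmetric light-dark cycles
(T-cycles).

Six state variables (arbitrary concentration units, time in hours):
cytosolic *frq* mRNA (`M_frq`), nuclear FRQ protein (`F`), *wc-1* mRNA
(`M_wc1`), phosphorylated dark-state nuclear WCC (`W_dark`),
light-activated WCC (`W_light`) and VVD (`V`).  With `L(t)` the light
intensity in [0, 1] and `M_tau` the mRNA a delay `tau` ago:

    dM_frq/dt = v_dark·W_dark·K_I^h/(K_I^h + F^h) + v_light·W_light − d_M·M_frq
    dF/dt     = k_s·M_tau − d_F·F
    dM_wc1/dt = v_w + k_fw·F − d_Mw·M_wc1
    dW_dark/dt= k_w·M_wc1 − A(t) + k_rel·W_light − d_Wd·W_dark
    dW_light/dt = A(t) − k_rel·W_light − d_Wl·W_light
    dV/dt     = k_v·W_light − d_V·V

    A(t) = k_act·L(t)·W_dark / (1 + V/K_V)      (photoactivation)

The model realizes five structural commitments: (1) *frq* mRNA is made
in the nucleus and degraded in the cytosol (one lumped pool; transport
is absorbed into `tau`); (2-3) translation, progressive
phosphorylation and nuclear import of FRQ are lumped into the single
delay `tau`, so FRQ synthesis follows the mRNA several hours earlier;
(4) nuclear WCC exists in a phosphorylated dark state and a
light-activated state, the latter transcriptionally hyperactive on
*frq*; (5) VVD, itself induced by light-activated WCC, divisively
inhibits photoactivation — the photoadaptation loop.  FRQ closes the
negative loop as a Hill repressor of the dark-state *frq*
transcription, and supports *wc-1* expression (`k_fw`, the positive
limb; `k_fw = 0` is a supported configuration).

**Why the light channel is additive.**  Acute light induction of *frq*
runs through dedicated light-response promoter elements and fires at
every circadian phase, so `v_light·W_light` enters the mRNA balance
outside the FRQ repression term.  This is not merely cosmetic: if the
repression multiplies the light term as well, the circadian repression
envelope modulates the (large) light drive, which amplifies the
endogenous loop parametrically under forcing — in an extensive
parameter search (`h` 2-6, `K_I` 0.5-3, `tau` 4-8 h, turnover rates
0.15-0.7/h, drive strengths spanning a decade) the FRQ series then
always locks subharmonically near 22-24 h and never shows the
masked-at-long-T / free-running-at-short-T pattern that motivates the
model.  With the additive channel the pattern emerges robustly.

**Knockouts.** `frq_null` zeroes `k_s` (frq^10-like), `wc_null` zeroes
`k_w` (wc-1^RIP-like), `vvd_null` zeroes `k_v` (vvd^KO).  The
FRQ-stability point mutants are mapped to FRQ clearance: frq^7 scales
`d_F` by 0.7 (stabilized, long period), frq^2 by 1.4 (destabilized,
short period); the factors were fixed during calibration so the two
dark periods straddle 22 h (24.0 h and 20.7 h with the committed set).

**Light units.** Intensity 1.0 represents the 5000 lux white light of
the standard entrainment conditions, 0.2 the 1000 lux condition
(linear lux map; only these two intensities are meaningful here).
Red-light channels are not modeled: clock strains do not entrain in
red light, so light enters only through the blue-light WCC channel.

## Committed parameters

The committed wild-type set (`frqclock/data/default_parameters.json`)
was produced by `frqclock.scan.calibrate` — seeded multi-start local
refinement (seed 17, budget 40, dt 0.02 h, 15 cycles per condition)
over the loss described below — and is returned bit-identically by a
re-run of that search, since no perturbation improves it.

| parameter | value | units | role |
|---|---|---|---|
| v_dark | 1.0 | a.u./h | dark-state WCC drive of *frq* |
| v_light | 1.5 | a.u./h | light-state WCC drive of *frq* |
| K_I, h | 0.8, 3.0 | a.u., — | FRQ repression half-constant, Hill exponent |
| d_M | 0.85 | 1/h | *frq* mRNA turnover (~49 min half-life) |
| k_s | 1.0 | 1/h | FRQ synthesis per delayed mRNA |
| tau | 8.0 | h | translation/phosphorylation/import delay |
| d_F | 0.42 | 1/h | FRQ clearance (FWD-1 pathway proxy) |
| v_w, k_fw, d_Mw | 0.3, 0.15, 0.3 | — | *wc-1* expression and FRQ support |
| k_w, d_Wd, d_Wl | 0.3, 0.3, 0.4 | 1/h | WCC production and clearance |
| k_act, k_rel | 5.0, 0.25 | 1/h | photoactivation and reversion |
| K_V, k_v, d_V | 0.05, 2.0, 0.25 | — | VVD inhibition, induction, clearance |

The loss treats the categorical claims as hard penalties (entrained at
half-periods {12, 8, 6, 4, 3}; free-running in the 20-24 h band at
half-period 2 with nonzero forcing-band sawtooth; acute mRNA light
response strictly decreasing with cycle length; protein-vs-mRNA
smoothness ratio < 1 at half-periods ≤ 3 h) and the single
quantitative anchor — a 22 h dark free-running period — quadratically.
The committed set gives a DD period of 22.09 h.

**Why fast turnover and a long delay.**  The oscillation period of the
delayed loop is roughly `2·(tau + 1/d_M + 1/d_F)` plus smaller lags,
so a 22 h period can be built from a long delay with fast turnover or
a short delay with slow turnover.  The choice matters for light: the
mean light drive passes the mRNA/protein stages at their DC gain while
the forcing-frequency ripple is attenuated by `1/|d + iω|`.  With slow
turnover (poles well below the forcing frequencies) the ripple is
filtered away and only the mean survives — but VVD is an integral-type
controller that equalizes the mean drive across equal-duty cycles, so
nothing then distinguishes LD3:3 from LD2:2.  With turnover rates near
the forcing band (d_M = 0.85/h, d_F = 0.42/h, tau = 8 h) the
ripple-to-mean ratio survives filtering, and the T-cycle boundary is
set by the ripple, which genuinely shrinks as T falls.  These mRNA
half-lives (~50 min) are also the biologically natural order for
*frq*.

## How the T-cycle pattern arises

Under forcing, VVD adaptation turns the light input into a dawn spike
whose size grows with the dark-phase duration (V recovery, time
constant 1/d_V = 4 h).  The spike train raises mean FRQ and superposes
a period-T ripple.  Both push the delayed loop toward its repression
bifurcation; the ripple contribution falls steeply with T, so long
cycles (T ≥ 6 h) suppress the endogenous ~22 h oscillation and the FRQ
series becomes the driven response — period T, stable phase: the
masked regime.  At LD2:2 (T = 4 h) the ripple is too small, and the
endogenous rhythm persists with the light-driven sawtooth superimposed
on it.

One property of this realization should be stated plainly: at LD2:2
the committed drive sits slightly above the asymptotic quench
threshold, so the superimposed endogenous component damps out on a
multi-week timescale (amplitude e-folding ~70 h).  Within the windows
matching the experimental records — a 96 h transient discard followed
by 150-400 h of record, versus 48 h blot time courses and week-long
race tubes — the LD2:2 series is robustly classified free-running;
after several simulated weeks the weak 4 h drive finally masks it.
Lowering the drive enough to make the T = 4 free run asymptotically
permanent (~v_light ≤ 1.25) destroys entrainment at T = 6-24 in the
same windows, so within this model structure the printed pattern is an
observation-window statement, and all committed analysis windows are
inside it.

## Numerics

Integration is method-of-steps: classical fixed-step RK4 with the
single retarded term (`M_frq(t − tau)`) evaluated by cubic Lagrange
interpolation on the already-computed grid; `dt ≤ tau/20` guarantees
every delayed lookup lies at least 19 steps behind the front.  Light
forcing is discontinuous, so the step is snapped down (rational GCD of
the phase durations) to make every transition a grid point, and the
light level within a step is taken at the step midpoint — each RK4
step therefore integrates a smooth system.  The default dt is 0.01 h;
trajectories at dt = 0.02-0.05 h are inside the convergence regime
(halving dt changes the FRQ trajectory by < 1e-4 relative sup-norm and
dominant periods by < 0.05 h), which the test suite exploits for
speed.  States are clipped at zero (clipping absorbs only
integration-error excursions; the dynamics are nonnegative).
The constant pre-zero history defaults to 0.1 a.u. in every component;
transient handling is the analysis layer's job (default discard: 96 h
or 5 forcing cycles, whichever is longer).

## Rhythm quantification

* **Peaks** — `scipy.signal.find_peaks` with prominence expressed as a
  fraction of the series range (default 0.1), plateau ties resolved to
  the earliest sample, endpoints excluded, and sub-sample quadratic
  refinement of peak times.
* **Period** — mean ± SD of successive peak intervals, cross-checked
  against the dominant period of a mean-removed Lomb-Scargle
  periodogram over 0.5-48 h (4000-point grid; dense series are
  decimated to ~5000 samples first, lossless above the 0.5 h floor).
  Before peak picking, the series is smoothed with a moving average of
  one-eighth of the spectral period — peak intervals are unaffected
  but single-sample noise maxima are suppressed.
* **Phase angles** — `phase_angle` returns per-cycle lights-on →
  event offsets for a peak/trough/onset reference.  The classifier
  instead fits the forcing-frequency fundamental cycle by cycle
  (widening the fit window up to 3 cycles when sampling is sparse) and
  uses the fitted phase: on a superimposed series every local maximum
  is ripple-locked, so event-referenced phases cannot detect a free
  run, while the fundamental fit is robust down to ~4 samples per
  cycle.
* **Classification** — *entrained* requires (i) the forcing-frequency
  power not to be outweighed by the best circadian-band (16-32 h)
  peak, (ii) per-cycle fundamental phases with circular SD ≤
  max(0.5 h, 0.1·T), and (iii) phase drift ≤ 5% of T per cycle (drift
  is the per-cycle period excess).  Otherwise *free-running* if the
  best circadian-band peak is ≥ 3× the median periodogram power and is
  not outweighed by the forcing peak (the forcing bin is ignored when
  the sampling cannot resolve it — below Nyquist its power is pure
  aliasing).  Otherwise *arrhythmic*.  Thresholds are declared
  defaults; the experiments report categories, not numbers.
* **Light response** — per cycle, max of *frq* mRNA during the light
  phase minus its value at lights-on, averaged after the transient.
* **Smoothness ratio** — variance-normalized Lomb-Scargle power of
  protein vs mRNA at 1/T; < 1 means the protein tracks the forcing
  less, i.e. the delayed protein stage low-pass filters.

## Phenotype analysis

Race tubes: growth-front marks every 24 h from inoculation; a position
maps to a time by piecewise-linear interpolation between marks, and a
band period is the growth time between adjacent band centers (band
"position" is declared to be the center).  Periods are invariant to
uniform rescaling of positions.  Growth is reported in mm/day (marks
are daily; ratios and normalized values are unit-free anyway).
Conidia: a length/width ratio strictly below 1.5 classifies a
microconidium; the proportion is micro over total.  Statistics follow
the conventions of the source experiments: Pearson correlation of a
phenotype against cycle length (Spearman available behind a flag),
two-sided two-sample Student's t tests, and the p ≤ 0.05/0.01/0.001
star labels.

## Synthetic data

The generators produce every fixture the analyses consume, seeded and
deterministic:

* **Densitometry** — the calibrated model simulated through its
  transient, sampled every 3 h (the assumed blot sampling; two-day
  windows by default, longer for classification studies),
  multiplicative log-normal noise (blot intensities are positive and
  errors scale with signal), rescaled to max = 1.
* **Race tubes** — marks at 24 h intervals, band centers at multiples
  of the *forcing* period through the inverse growth map, Gaussian
  positional jitter.  Band timing deliberately follows the forcing
  clock rather than the FWO model: conidiation banding under short LD
  cycles persists in clock-null strains and stops in constant
  darkness — it is an hourglass read-out, not an FWO output.
* **Morphometry** — a two-population mixture: microconidia with aspect
  ratio uniform in [1.0, 1.4] (nearly round), macroconidia log-uniform
  in [2.0, 5.0], log-normal widths (medians 3 and 4 µm); the expected
  classified proportion equals the mixture weight.
* **Condition panels** — per-cycle-length growth and morphometry with
  a configurable micro-fraction effect (default: rising with cycle
  length, maximal at the 12 h half-period) and flat growth speed,
  sized so the cycle-length/micro-proportion correlation has high
  power while growth stays non-significant.

What the generators do *not* emulate: band merging/ambiguity at very
short cycles, gel saturation and background subtraction, heteroscedastic
counting error at the hemocytometer, or any coupling of growth speed
to the clock.  Passing round-trip tests therefore shows the analysis
operations are correct on data with the assumed statistical structure,
not that they are robust to every artifact of real race tubes or blots.

## Problem sizes used by the tests and the acceptance script

Simulations in the acceptance script run at dt = 0.01 h (LD3:3 for
480 h; DD for 600 h; the six-condition scan with a 96 h transient plus
≥ 240 h of record per condition).  The test suite reuses cached
trajectories at dt = 0.02 h and runs scans and calibration smoke tests
at dt = 0.05 h — all inside the integrator's convergence regime (see
Numerics).  Robustness checks use 20 seeds per condition; fixtures for
sampled-data classification are 168 h at 3 h sampling.

## Known limitations

* One lumped *frq* mRNA pool (no separate nuclear/cytosolic pools);
  nucleocytoplasmic transport lives inside `tau`.
* The divisive VVD inhibition `1/(1 + V/K_V)` is one of several
  closures consistent with photoadaptation; subtractive forms were not
  explored.
* The LD2:2 free run is sustained over experiment-scale windows but
  not asymptotically (see above).
* No stochastic (molecular-noise) version, no temperature input, no
  conidiation output model, and no second oscillator (the
  CRY-dependent system) — the conidiation generators are deliberately
  hourglass-driven instead.
* Entrainment here is the operational sense used for T-cycle work — a
  rhythm at the forcing period with a stable phase angle — which does
  not distinguish true limit-cycle locking from masking; the
  classifier's dominance condition is precisely what separates "the
  output follows T" from "T rides on a free-running rhythm".
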