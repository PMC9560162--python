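# Methods

This note records the model conventions, parameter defaults, and numerical
choices behind `segclock`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## The oscillator model (ERICA)

ERICA generalizes the Radial Isochron Cycle (RIC).  The limit cycle is the
ellipse (x, y) = (a cos θ, b sin θ) with a = 1 and b = 1 − λ; λ ∈ [0, 1)
is the eccentricity parameter (an `axis_ratio` override is available).
θ is the *parametric* angle of the ellipse.  Its level sets,
(x, y) ∝ (a cos θ, b sin θ), are rays through the origin, so defining the
asymptotic phase as a function of θ makes the isochrons radial; for any
plane point, θ = atan2(y/b, x/a).

The cycle is traversed at a piecewise-constant angular speed: ω = s\*·ω_b
inside the sector [θ_on, θ_off) and ω_b outside, with ω_b normalized so a
full circuit takes T_osc.  The phase is the normalized traversal time,

    Φ(θ) = 2π · t(θ) / T_osc,   t(θ) = ∫₀^θ dθ'/ω(θ'),

a monotone bijection of [0, 2π) with Φ(0) = 0 (θ = 0 is the x-maximum, so
phase 0 coincides with the signal-peak convention of the data pipeline).
With s\* = 1, Φ is the identity; with λ = 0 and s\* = 1 the model is the
RIC.  Both Φ and its inverse are evaluated exactly (piecewise-linear in
θ), so the analytic PRC of an instantaneous displacement ε·a·k̂ is

    PRC(φ) = Φ(θ′) − φ,  θ′ = atan2(y′/b, x′/a) of the kicked point,

wrapped to (−π, π].  For the RIC with kick (σ, 0) this reduces to the
closed form atan2(sin φ, cos φ + εσ) − φ, which serves as the oracle in
the tests.

### Default geometry: sector and kick direction

The accelerated sector defaults to the half cycle (π/2, 3π/2) — the x < 0
half is the fast "reset", the x > 0 half the slow decay — and the kick
direction to 250° from +x (mostly −y with a −x component).  Two facts
drove this choice:

* **PRC shape.**  At the reference parameters (λ = 0.5, s\* = 5.6,
  ε = 0.4) this geometry yields a PRC with a deep negative lobe
  (min ≈ −1.5 rad), a small positive bump (max ≈ +0.26 rad), and < 20 % of
  the phase circle above +0.05 rad — the predominantly non-positive,
  strongly asymmetric response this system exhibits — together with a
  stable 1:1 fixed point at T_zeit = 170 min and 2:1 locking at 300 min.
  Axis-aligned kicks with other sector placements produce predominantly
  positive PRCs or no locking at all.

* **Identifiability.**  With radial isochrons, an axis-aligned kick makes
  the PRC depend on (λ, ε) only through ε·k_y/(1 − λ) (pure y-kick) or
  ε·k_x alone (pure x-kick): the two parameters are exactly degenerate and
  no fitter can separate them.  An oblique kick contributes both
  ε·k_x and ε·k_y/(1 − λ) and restores separate identifiability.  The 250°
  default keeps a substantial x-component (cos 250° ≈ −0.34) without
  leaving the PRC-shape regime above.

Both the sector offset and (optionally) the kick direction are Monte
Carlo fit parameters; the defaults only seed the optimization.

### ODE variant

For validation the planar flow θ̇ = ω(θ), ρ̇ = relax_rate·(1 − ρ) (with
ρ the elliptic-radial coordinate, cycle at ρ = 1) is integrated with
`scipy.solve_ivp`; it preserves the radial isochrons exactly, so phase
advances uniformly at 2π/T_osc everywhere and kicked trajectories must
reproduce the analytic PRC — the tests check agreement to 1e-3 rad, and
pulse-to-pulse phases against the stroboscopic map to 0.02 rad when
relax_rate·T_zeit ≥ 50.  Pulses are instantaneous displacements at onset;
the 30-minute experimental pulse duration is represented in the schedule
but not in the dynamics (a stated limitation of the phase-map formalism).

## Signal processing

* **Detrending** — Kaiser-windowed (β = 8.6) sinc FIR low-pass with
  cutoff period 240 min; the trend is subtracted.  The kernel defaults to
  the largest odd length ≤ the series length (sharpest attainable
  transition); edges are reflection-padded.  Points within half a kernel
  of an edge are influenced by the padding, so exactness claims
  (idempotency to 1e-6) hold on the kernel-supported interior.
* **Wavelet spectrum** — complex Morlet CWT (ω₀ = 6, via PyWavelets
  `cmor` with bandwidth 2 and center frequency ω₀/2π) over 200 log-spaced
  periods in [100, 350] min.  Stored power is bias-rectified (|W|²/scale);
  without the 1/scale factor the ridge of a pure sinusoid lands one to two
  grid steps long.
* **Phase** — `hilbert`: angle of the analytic signal of the standardized
  trace (a pure cosine maps to φ = 2πt/T, so peaks are φ = 0);
  `ridge`: angle of the complex wavelet coefficient along the ridge.  The
  pipeline uses the ridge phase: at the generator's default noise the
  Hilbert stroboscopic steps jitter by ~0.4 rad and misclassify most
  truly-locked samples under the π/8 rule, whereas the wavelet coherently
  averages ~6 cycles (19/20 correct in the validation run).  Low-power or
  negative-velocity points are masked, never interpolated.
* **Stroboscopic sampling** — "just before a pulse" is the last sample
  strictly before onset.  For PRC inference the pipeline additionally
  advances that phase over the sub-sample lag using the local ridge
  period (`advance_to_onset`): at a 10-min cadence the raw convention
  lags the onset by up to ~0.45 rad, which would shift the inferred PRC
  horizontally — a systematic the model family cannot absorb.

## Inference chain

PRC samples come from inverting the stroboscopic map with an assumed
T_osc of 140 min (the free-running period).  Samples are pooled per
condition with optional 16-bin circular-mean binning, which de-biases the
oversampling of phases near each condition's entrainment phase.

**Vertical-shift collapse.**  Entraining at T_zeit ≠ 140 min changes the
intrinsic period, so per-condition PRCs are vertical shifts of a common
curve; the reported shifts are estimated by alternating a Fourier fit
(order 5) of the merged points with per-condition re-estimation (the
one-shot estimate against the reference fit alone is biased by the
condition-specific phase coverage).  Order 5 is the smallest with RMS
residual < 0.05 rad on the model PRC — the kink at the sector boundary
defeats order 3 (RMS 0.099).

**Monte Carlo fit.**  Annealed random-walk over (λ, s\*, ε, sector
offset): Gaussian proposals with scales (0.05, 0.3, 0.03, 0.2 rad),
reflection at the bounds λ ∈ [0, 0.9], s\* ∈ [1, 12], ε ∈ [0, 0.9],
offset ∈ [−π, π], Metropolis acceptance with geometric cooling ×0.999
per iteration, 20 000 iterations × 3 restarts (first restart from the
initial guess, later ones from seeded random draws).  In
`profile_shifts` mode the fit takes the per-condition sample lists and
profiles their vertical offsets analytically inside the objective
(optimal offset = weighted mean residual); this removes the smoother
bias of the Fourier collapse from the fit path and is what the pipeline
uses.  Because the ERICA family has no free vertical offset, profiling
does not create a flat direction.

**Intrinsic-period modulation.**  At a 1:1 fixed point,
PRC(φ_ent) + 2π T_zeit/T_osc ≡ 2π, so T_osc = 2π T_zeit/(2π − PRC(φ_ent));
the per-condition values are interpolated with a cubic spline (natural
`CubicSpline`, ≥ 4 knots; linear fallback at 2–3) and clamped to the knot
span — the modulation is only constrained where entrainment data exist.

## Arnold tongues

Locking is classified on the *unwrapped* map (increments
PRC + 2π T_zeit/T_osc accumulated without the modulo), making the
rotation number ρ (oscillator cycles per pulse) exact at fixed points.
A cell is n:m locked iff every one of 32 starts has |ρ − n/m| < 1e-3
after a 200-pulse transient, the m-fold composed map has converged
(m-step increment within 1e-5 of 2πn), and a 1e-3 perturbation of the
attractor contracts under the m-fold map (this excludes neutral
resonances such as ε = 0 at exact rational detuning).  Candidate ratios
default to {1:1, 2:1, 1:2, 3:2, 2:3}; ambiguities resolve to the smallest
m.  Period modulation is OFF in tongue scans by default; when enabled it
is evaluated at the *effective entrained rhythm* m/n · T_zeit — under 2:1
locking at T_zeit = 350 min the oscillator adopts a 175-min rhythm and
the intrinsic period follows that rhythm, not the pulse interval.  (With
a fixed 140-min intrinsic period, 350/140 = 2.5 sits exactly on the
2:1/3:1 tongue boundary and never locks; the modulated period ~154 min
yields robust 2:1 locking for ε ≥ 0.45, matching the need for stronger
pulses in that condition.)

Isophase contours are zero-level sets of wrap(φ_ent − level) via
marching squares (`skimage.measure.find_contours`); unlocked cells and
cells more than π/2 from the level are masked to NaN so the antipodal
wrap discontinuity cannot generate spurious crossings.

## Synthetic data: what it emulates, and what it does not

Each sample is a phase oscillator integrated on a 1-min grid: φ̇ =
2π/T_osc(t) between pulses, an instantaneous jump by the analytic PRC at
each pulse onset, optional phase diffusion.  The emitted intensity is

    y(t) = baseline + slope·t + A e^{−decay·t} (1 + cos φ)/2 + N(0, (0.1 A)²),

sampled every 10 min over 1500 min (2000 min for the slow 2:1
conditions), A = 1, slope 2e-4·A/min, decay 5e-4/min, first pulse at
100 min, pulse duration 30 min in the schedule.  Initial phases are
uniform; per-sample substreams derive from `SeedSequence(seed, index)`,
so ensembles are byte-reproducible.  Ground truth (pre-pulse phases,
per-pulse PRC increments — exact by construction — and locking flags) is
emitted alongside.

The default study suite comprises unpulsed controls, 1:1 conditions at
T_zeit ∈ {120, …, 180} min with ε = 0.4, and 2:1 conditions at 300 min
(ε = 0.4) and 350 min (ε = 0.6, emulating the stronger pulses used
there).  The intrinsic-period truth T_osc(T_zeit) is constructed from the
system's reported entrainment-phase behavior: φ_ent shifts monotonically
across the 1:1 range spanning close to half a cycle, so the knots are
obtained by prescribing a monotone φ_ent ramp of 0.85π anchored at the
PRC zero crossing for the 140-min condition (hence T_osc(140) = 140
exactly — the reference condition of the collapse really runs free) and
just past the PRC maximum on the fast side (so every fixed point is
stably attracting), then applying the fixed-point identity.  The
resulting knots run from ~125 min at T_zeit = 120 to ~156 min at 180.

The generator reproduces coarse-grained features only: it has no spatial
structure (no period gradient along the tissue, no phase waves), no
reporter maturation or bleaching kinetics beyond exponential decay, noise
is white and additive (no 1/f or shot noise), and pulses act as
instantaneous phase kicks.  Passing tests therefore validate the
*analysis chain* — detrending, period/phase extraction, stroboscopic
construction, PRC inference, model fitting, tongue computation — under
controlled conditions, not the biological fidelity of the oscillator
model itself.

## Problem sizes and known limitations

* Test and acceptance runs use 10–20 samples per condition, 1500-min
  traces at 10-min sampling, 20 000 × 3 MC iterations, and tongue grids
  up to ~21 × 10 cells; the full default suite runs in well under two
  minutes per stage on one CPU.
* **λ is weakly identified from noisy coarse-grained data.**  The
  model-level refit (exact map inversion) recovers λ = 0.5 within ±0.1,
  but through the full noisy measurement chain the residual ridge-phase
  smoothing around kicks biases λ low (≈ 0.25 at noise SD 0.1·A) while
  the collapsed PRC *shape* (correlation > 0.9 with truth) and ε (within
  ±30 %) remain robust.  Conclusions that depend on λ alone should rest
  on the model-level fit, not the end-to-end chain.
* The π/8 locking rule judges only the final pulse pair, as defined; a
  sample drifting slowly through the diagonal can be misclassified as
  locked in short recordings.
* `circ_sd` returns −2 ln R by default (the convention used throughout
  this analysis); the textbook √(−2 ln R) is available via
  `conventional=True`.
* Fourier fitting of sharply kinked PRCs needs order ≥ 5; the default is
  documented above and reduced automatically (with a warning) when a
  condition has too few points.
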