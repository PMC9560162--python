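# segclock

Coarse-grained entrainment analysis of the embryonic somite segmentation
clock — and of pulse-entrained biological oscillators generally.

The mouse segmentation clock (readable through dynamic Notch-signaling
reporters such as LuVeLu) is a tissue-level oscillator with a free-running
period near 140 minutes.  When the tissue is exposed to periodic drug
pulses (a *zeitgeber*), the clock can period- and phase-lock to the pulses
across a wide range of zeitgeber periods, including higher-order 2:1
locking.  `segclock` implements the full analysis chain that turns raw
reporter timeseries into a dynamical characterization of the oscillator:

1. **signal** — windowed-sinc detrending, instantaneous period from the
   ridge of a continuous Morlet wavelet spectrum, instantaneous phase with
   φ = 0 at oscillation peaks;
2. **circstats** — the first Kuramoto order parameter
   R = |⟨e^{iφ_k}⟩| (R = 1 ⇔ in-phase ensemble), circular SD (−2 ln R),
   and stroboscopic (Poincaré) maps: the phase just before pulse *n*
   plotted against the phase just before pulse *n+1*; a sample is
   phase-locked when its final step is smaller than π/8, and the
   entrainment phase φ_ent is the vectorial average of the locked samples'
   final phases;
3. **erica** — the ERICA oscillator (Elliptic Radial Isochron Cycle with
   Acceleration): an elliptic limit cycle (eccentricity λ), a sector of
   the cycle traversed s\* times faster, radial isochrons so the phase
   response curve (PRC) to an instantaneous kick of amplitude ε is
   analytic, plus a planar ODE twin for validation;
4. **inference** — PRC inference by inverting the stroboscopic map,

       PRC(φ_n) = (φ_{n+1} − φ_n − 2π T_zeit / T_osc) mod 2π,

   Fourier-series fits, vertical-shift collapse of per-condition PRCs onto
   the reference condition (T_zeit = 140 min), annealed Monte Carlo fitting
   of ERICA, intrinsic-period inference
   T_osc = 2π T_zeit / (2π − PRC(φ_ent)) with cubic-spline interpolation of
   T_osc(T_zeit), and φ_ent prediction from the fitted model;
5. **tongues** — numerically derived Arnold tongues: n:m locking from
   rotation numbers of the unwrapped stroboscopic map plus a contraction
   test, and isophase contours of φ_ent over the (T_zeit, ε) plane;
6. **synthdata** — a ground-truthed generator of LuVeLu-like global-ROI
   reporter ensembles (slow trends, amplitude decay, additive noise, pulse
   responses driven by the analytic PRC) so the whole chain is testable
   without microscopy data;
7. **cli/pipeline** — tidy-CSV interfaces, a YAML-configurable end-to-end
   pipeline, and a `segclock` command with per-stage subcommands.

The stroboscopic map of the phase-oscillator model is

    φ_{n+1} = (φ_n + PRC(φ_n, ε) + 2π T_zeit / T_osc) mod 2π,

whose stable fixed point is the entrainment phase.  The reference fitted
configuration used throughout the tests is λ = 0.5, s\* = 5.6, ε = 0.4,
T_osc = 140 min, giving the strongly asymmetric, predominantly
non-positive PRC characteristic of this system.

## Worked example

Entrain a synthetic ensemble with 170-min pulses and quantify locking:

```python
import numpy as np
from segclock.circstats import PulseTrain, build_strobo_map, entrainment_phase
from segclock.signal import extract_phase, mean_period_window, sinc_detrend
from segclock.synthdata import (Condition, default_period_modulation,
                                fitted_params, generate_sample)

p = fitted_params()                      # lambda=0.5, s*=5.6, eps=0.4, T_osc=140
mod = default_period_modulation(p)       # intrinsic period tracks the zeitgeber
pulses = PulseTrain(t_first=100.0, T_zeit=170.0, n_pulses=9, strength=0.4)
cond = Condition(label="dapt_170", p=p, pulses=pulses, period_drift=mod,
                 noise_sd=0.1, n_samples=12, seed=0)

maps, periods = [], []
for k in range(cond.n_samples):
    ts, truth = generate_sample(cond, k)
    det = sinc_detrend(ts, cutoff_period=240.0)
    phase = extract_phase(det, method="ridge")
    periods.append(mean_period_window(phase, 650.0, 850.0))
    maps.append(build_strobo_map(phase, pulses, advance_to_onset=True))

ent = entrainment_phase(maps)
print(f"mean period 650-850 min : {np.median(periods):.1f} min (zeitgeber 170)")
print(f"locked samples          : {ent.n_locked}/{ent.n_total}")
print(f"entrainment phase       : {ent.phi_ent:.2f} rad (circSD {ent.spread:.3f})")
```

which prints

    mean period 650-850 min : 172.3 min (zeitgeber 170)
    locked samples          : 12/12
    entrainment phase       : 4.59 rad (circSD 0.003)

— the clock, free-running at ~140 min, has been slowed to the 170-min
zeitgeber rhythm, and all samples converge to a common entrainment phase.
The full chain (including the Monte Carlo ERICA fit and Arnold-tongue
scan) runs as `segclock pipeline --seed 0 --out runs/demo`.

## Layout

    src/segclock/      signal, circstats, erica, inference, tongues,
                       synthdata, io, pipeline, cli
    tests/             pytest suite (unit, property, acceptance)
    docs/methods.md    model conventions, parameter choices, limitations
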