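"""From stroboscopic maps to a fitted oscillator model.

The chain implemented here mirrors the data-to-model path of the analysis:

1. invert the stroboscopic map to phase-response samples,
   PRC(phi_n) = wrap(phi_{n+1} - phi_n - 2 pi T_zeit / T_osc);
2. fit Fourier series to the per-condition PRCs;
3. collapse the per-condition PRCs onto a reference curve by vertical
   shifts (the shifts encode a change of intrinsic period during
   entrainment);
4. infer the intrinsic period per condition from the entrainment phase,
   T_osc = 2 pi T_zeit / (2 pi - PRC(phi_ent)), and interpolate
   T_osc(T_zeit) with cubic splines;
5. fit the ERICA oscillator to the collapsed PRC by annealed Monte Carlo;
6. predict the entrainment phase phi_ent(T_zeit) from the fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

from .circstats import TWO_PI, StroboscopicMap, kuramoto_R, wrap_2pi, wrap_pi
from .erica import EricaParams, iterate_strobo, prc_analytic

__all__ = [
    "PRCSamples",
    "FourierPRC",
    "PeriodModulation",
    "MCFitResult",
    "prc_from_map",
    "pool_prc_samples",
    "fit_fourier",
    "collapse_shift",
    "infer_intrinsic_period",
    "build_period_modulation",
    "fit_erica_mc",
    "predict_entrainment_phase",
]


@dataclass
class PRCSamples:
    """Phase-response samples inferred from stroboscopic pairs."""

    phi: np.ndarray  # phase at the pulse, [0, 2pi)
    dphi: np.ndarray  # inferred response, (-pi, pi]
    T_zeit: float
    T_osc_assumed: float
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.dphi = np.atleast_1d(np.asarray(self.dphi, dtype=float))
        if len(self.phi) != len(self.dphi):
            raise ValueError("phi and dphi must have equal length")

    def __len__(self):
        return len(self.phi)


@dataclass
class FourierPRC:
    """Truncated Fourier series dphi(phi) = a0 + sum_k a_k cos + b_k sin."""

    a0: float
    a: np.ndarray  # (K,)
    b: np.ndarray  # (K,)
    sse: float = np.nan

    @property
    def order(self) -> int:
        return len(self.a)

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        out = np.full_like(phi, self.a0, dtype=float)
        for k in range(1, self.order + 1):
            out = out + self.a[k - 1] * np.cos(k * phi) + self.b[k - 1] * np.sin(k * phi)
        return out


@dataclass
class PeriodModulation:
    """Intrinsic period as a function of zeitgeber period, spline-interpolated.

    Evaluation outside the knot span is clamped to the span (no
    extrapolation): the modulation is only constrained where entrainment
    data exist.
    """

    T_zeit_knots: np.ndarray
    T_osc_values: np.ndarray
    _f: object = field(default=None, repr=False)

    def __call__(self, T_zeit):
        lo, hi = self.T_zeit_knots[0], self.T_zeit_knots[-1]
        x = np.clip(np.asarray(T_zeit, dtype=float), lo, hi)
        out = self._f(x)
        return float(out) if np.isscalar(T_zeit) else np.asarray(out)


def prc_from_map(m: StroboscopicMap, T_zeit: float, T_osc: float = 140.0) -> PRCSamples:
    """Invert the stroboscopic map into PRC samples.

    For each observed pair, dphi = wrap(phi_new - phi_old - 2 pi T_zeit /
    T_osc); the sample abscissa is phi_old.
    """
    if T_osc <= 0:
        raise ValueError("T_osc must be positive")
    if len(m) == 0:
        raise ValueError("empty stroboscopic map")
    drift = TWO_PI * T_zeit / T_osc
    dphi = wrap_pi(m.phi_new - m.phi_old - drift)
    return PRCSamples(phi=wrap_2pi(m.phi_old), dphi=dphi,
                      T_zeit=T_zeit, T_osc_assumed=T_osc)


def pool_prc_samples(samples: list, n_bins: int = 0) -> PRCSamples:
    """Pool PRC samples from several maps at the same T_zeit.

    With ``n_bins > 0`` the pooled points are reduced to per-bin circular
    means over a uniform phase binning, which de-biases the oversampling of
    phases near the entrainment phase.
    """
    if not samples:
        raise ValueError("no PRC samples to pool")
    T_zeit = samples[0].T_zeit
    T_osc = samples[0].T_osc_assumed
    phi = np.concatenate([s.phi for s in samples])
    dphi = np.concatenate([s.dphi for s in samples])
    if n_bins <= 0:
        return PRCSamples(phi=phi, dphi=dphi, T_zeit=T_zeit, T_osc_assumed=T_osc)
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    which = np.clip(np.digitize(phi, edges) - 1, 0, n_bins - 1)
    phi_b, dphi_b, w_b = [], [], []
    for b in range(n_bins):
        sel = which == b
        if not np.any(sel):
            continue
        _, ang = kuramoto_R(phi[sel])
        phi_b.append(ang)
        dphi_b.append(float(np.mean(dphi[sel])))
        w_b.append(int(np.count_nonzero(sel)))
    return PRCSamples(phi=np.array(phi_b), dphi=np.array(dphi_b),
                      T_zeit=T_zeit, T_osc_assumed=T_osc,
                      weights=np.array(w_b, dtype=float))


def fit_fourier(s: PRCSamples, K: int = 3) -> FourierPRC:
    """Least-squares Fourier fit of order K to PRC samples."""
    if K < 0:
        raise ValueError("K must be >= 0")
    n = len(s)
    if n < 2 * K + 1:
        raise ValueError(f"need >= {2 * K + 1} points for order {K}, got {n}")
    if K == 0:
        z = np.mean(np.exp(1j * s.dphi))
        # circular-aware mean of responses (responses live on (-pi, pi])
        a0 = float(np.angle(z))
        resid = wrap_pi(s.dphi - a0)
        return FourierPRC(a0=a0, a=np.empty(0), b=np.empty(0),
                          sse=float(np.sum(resid ** 2)))
    cols = [np.ones(n)]
    for k in range(1, K + 1):
        cols.append(np.cos(k * s.phi))
        cols.append(np.sin(k * s.phi))
    X = np.column_stack(cols)
    w = s.weights if s.weights is not None else np.ones(n)
    Xw = X * np.sqrt(w)[:, None]
    yw = s.dphi * np.sqrt(w)
    if np.linalg.cond(Xw.T @ Xw) > 1e10:
        warnings.warn(
            "phase coverage is clustered: Fourier design is near rank-"
            "deficient, using a regularized solve", RuntimeWarning,
        )
        coef = np.linalg.solve(Xw.T @ Xw + 1e-6 * np.eye(X.shape[1]), Xw.T @ yw)
    else:
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = s.dphi - X @ coef
    return FourierPRC(a0=float(coef[0]), a=coef[1::2].copy(), b=coef[2::2].copy(),
                      sse=float(np.sum(w * resid ** 2)))


def collapse_shift(prcs: list, ref_T_zeit: float = 140.0, K: int = 5,
                   n_refine: int = 5):
    """Collapse per-condition PRCs onto the reference curve by vertical shifts.

    The reference is the PRC measured at ``ref_T_zeit`` (the condition whose
    zeitgeber period coincides with the free-running period); its shift is 0
    by definition.  For every other condition the shift delta minimizing the
    SSE between (dphi - delta) and the current consensus Fourier curve at
    the observed phases is the weighted mean residual.  Because each
    condition oversamples the neighbourhood of its own entrainment phase,
    shifts estimated against the reference fit alone are biased; the
    estimate is therefore refined by alternating "fit Fourier to the merged,
    shifted points" and "re-estimate the shifts" (``n_refine`` rounds).

    Returns ``(shifts, merged)``: a dict T_zeit -> delta and the pooled
    shifted samples.
    """
    ref = [s for s in prcs if np.isclose(s.T_zeit, ref_T_zeit)]
    if not ref:
        raise ValueError(f"no PRC at the reference T_zeit = {ref_T_zeit}")
    max_K = (min(len(s) for s in prcs) - 1) // 2
    if max_K < K:
        warnings.warn(
            f"only {min(len(s) for s in prcs)} points in the sparsest "
            f"condition: Fourier order reduced {K} -> {max_K}", RuntimeWarning,
        )
        K = max_K
    for s in prcs:
        if np.isclose(s.T_zeit, ref_T_zeit):
            continue
        cover = np.ptp(np.sort(wrap_2pi(s.phi)))
        if cover < np.pi:
            warnings.warn(
                f"T_zeit={s.T_zeit}: phase coverage spans only "
                f"{cover:.2f} rad; shift computed on the overlap",
                RuntimeWarning,
            )

    def weights_of(s):
        return s.weights if s.weights is not None else np.ones(len(s))

    shifts = {float(s.T_zeit): 0.0 for s in prcs}
    fit = fit_fourier(ref[0], K=K)
    for _ in range(max(1, n_refine)):
        for s in prcs:
            if np.isclose(s.T_zeit, ref_T_zeit):
                continue
            w = weights_of(s)
            resid = s.dphi - fit(s.phi)
            shifts[float(s.T_zeit)] = float(np.sum(w * resid) / np.sum(w))
        merged = PRCSamples(
            phi=np.concatenate([s.phi for s in prcs]),
            dphi=np.concatenate([wrap_pi(s.dphi - shifts[float(s.T_zeit)])
                                 for s in prcs]),
            T_zeit=ref_T_zeit, T_osc_assumed=ref[0].T_osc_assumed,
            weights=np.concatenate([weights_of(s) for s in prcs]),
        )
        fit = fit_fourier(merged, K=K)
    return shifts, merged


def infer_intrinsic_period(phi_ent: float, T_zeit: float, prc) -> float:
    """Intrinsic period solving the 1:1 fixed-point identity.

    At a 1:1 fixed point, PRC(phi_ent) + 2 pi T_zeit / T_osc = 2 pi, hence
    T_osc = 2 pi T_zeit / (2 pi - PRC(phi_ent)).  ``prc`` is any callable
    (Fourier fit or analytic PRC).
    """
    v = float(prc(phi_ent))
    if v >= TWO_PI:
        raise ValueError(f"PRC(phi_ent) = {v} >= 2 pi: no valid period")
    return float(TWO_PI * T_zeit / (TWO_PI - v))


def build_period_modulation(points) -> PeriodModulation:
    """Cubic-spline interpolation of (T_zeit, T_osc) points.

    Falls back to linear interpolation when fewer than 4 knots are given
    (at least 2 required).  Duplicate knots are an error.
    """
    pts = sorted((float(a), float(b)) for a, b in points)
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if len(x) < 2:
        raise ValueError("need at least 2 (T_zeit, T_osc) points")
    if np.any(np.diff(x) == 0):
        raise ValueError("duplicate T_zeit knots")
    if np.any(y <= 0):
        raise ValueError("T_osc values must be positive")
    f = CubicSpline(x, y) if len(x) >= 4 else interp1d(x, y)
    return PeriodModulation(T_zeit_knots=x, T_osc_values=y, _f=f)


@dataclass
class MCFitResult:
    """Best parameters and diagnostics of the Monte Carlo ERICA fit."""

    params: EricaParams
    sse: float
    seed: int
    n_iter: int
    n_restarts: int
    accept_rate: float
    sse_trace: np.ndarray  # best-so-far SSE, subsampled

    def __iter__(self):  # allows: params, sse = fit_erica_mc(...)
        return iter((self.params, self.sse))


_MC_BOUNDS = {"lam": (0.0, 0.9), "s_star": (1.0, 12.0),
              "eps": (0.0, 0.9), "off": (-np.pi, np.pi)}
_MC_SCALES = np.array([0.05, 0.3, 0.03, 0.2])


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    x = (x - lo) % (2 * span)
    return lo + (x if x <= span else 2 * span - x)


def fit_erica_mc(merged, init: EricaParams | None = None,
                 n_iter: int = 20000, n_restarts: int = 3, seed: int = 0,
                 cooling: float = 0.999, fit_sector: bool = True,
                 profile_shifts: bool = False) -> MCFitResult:
    """Fit ERICA to PRC samples by annealed random-walk Monte Carlo.

    The free parameters are (lambda, s*, epsilon) and, with
    ``fit_sector=True``, the angular offset of the accelerated half-cycle
    sector.  Proposals are Gaussian with fixed per-parameter scales,
    accepted on SSE decrease or by a Metropolis rule under a geometrically
    cooled temperature.  Out-of-bounds proposals are reflected.  The first
    restart starts from ``init``; subsequent restarts from random draws of
    the seeded stream.  The best of all restarts is returned.

    ``merged`` is either a single PRCSamples (e.g. the output of
    :func:`collapse_shift`) or, with ``profile_shifts=True``, a list of
    per-condition PRCSamples whose vertical offsets are profiled out
    analytically inside the objective (for fixed model parameters the
    SSE-optimal offset of a condition is its mean residual).  Profiling
    avoids the smoothing bias a Fourier-based collapse can introduce when
    each condition oversamples its own entrainment phase.
    """
    if profile_shifts:
        groups = list(merged)
        phi = wrap_2pi(np.concatenate([s.phi for s in groups]))
        dphi = np.concatenate([s.dphi for s in groups])
        w = np.concatenate([
            s.weights if s.weights is not None else np.ones(len(s))
            for s in groups
        ])
        edges = np.cumsum([0] + [len(s) for s in groups])
        slices = [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]
    else:
        if len(merged) < 5:
            raise ValueError("too few PRC points to fit")
        phi = wrap_2pi(merged.phi)
        dphi = merged.dphi
        w = merged.weights if merged.weights is not None else np.ones(len(merged))
        slices = None
    if len(phi) < 5:
        raise ValueError("too few PRC points to fit")
    if init is None:
        init = EricaParams(lam=0.3, s_star=3.0, eps=0.3)
    rng = np.random.default_rng(seed)

    sector_width = init.sector[1] - init.sector[0]
    sector_mid0 = 0.5 * (init.sector[0] + init.sector[1])

    def make_params(x):
        lam, s_star, eps, off = x
        lo = sector_mid0 + off - sector_width / 2
        return replace(init, lam=lam, s_star=s_star, eps=eps,
                       sector=(lo, lo + sector_width))

    def objective(x):
        try:
            model = prc_analytic(phi, make_params(x), eps=x[2])
        except ValueError:  # kick through the origin
            return np.inf
        r = wrap_pi(model - dphi)
        if slices is not None:
            r = r.copy()
            for sl in slices:
                r[sl] -= np.sum(w[sl] * r[sl]) / np.sum(w[sl])
        return float(np.sum(w * r ** 2))

    names = ["lam", "s_star", "eps", "off"]
    n_par = 4 if fit_sector else 3
    best_x, best_sse = None, np.inf
    trace = []
    n_acc = 0
    n_tot = 0
    for restart in range(n_restarts):
        if restart == 0:
            x = np.array([init.lam, init.s_star, init.eps, 0.0])
        else:
            x = np.array([rng.uniform(*_MC_BOUNDS[k]) for k in names])
        sse = objective(x)
        temp = max(sse / max(len(merged), 1), 1e-3)
        for it in range(n_iter):
            prop = x.copy()
            j = rng.integers(n_par)
            prop[j] += rng.normal() * _MC_SCALES[j]
            lo, hi = _MC_BOUNDS[names[j]]
            prop[j] = _reflect(prop[j], lo, hi)
            new_sse = objective(prop)
            n_tot += 1
            if new_sse <= sse or rng.random() < np.exp(-(new_sse - sse) / temp):
                x, sse = prop, new_sse
                n_acc += 1
            temp *= cooling
            if sse < best_sse:
                best_sse, best_x = sse, x.copy()
            if it % 500 == 0:
                trace.append(best_sse)
    return MCFitResult(
        params=make_params(best_x), sse=best_sse, seed=seed, n_iter=n_iter,
        n_restarts=n_restarts, accept_rate=n_acc / max(n_tot, 1),
        sse_trace=np.asarray(trace),
    )


def predict_entrainment_phase(T_zeit: float, p: EricaParams,
                              mod: PeriodModulation | float | None = None,
                              n_starts: int = 32, n_pulses: int = 500,
                              n_transient: int = 200, tol: float = 1e-4):
    """Entrainment phase predicted by iterating the stroboscopic map.

    The map is iterated from ``n_starts`` phases uniform on the circle; the
    system counts as 1:1 locked iff every start converges to a fixed point
    (final increment below ``tol``).  ``mod`` may be a PeriodModulation, a
    fixed T_osc, or None (use p.T_osc).  Returns ``(phi_ent, locked)`` with
    phi_ent the vectorial average of the reached fixed points (NaN when not
    locked).
    """
    if mod is None:
        T_osc = p.T_osc
    elif callable(mod):
        T_osc = float(mod(T_zeit))
    else:
        T_osc = float(mod)
    p_eff = replace(p, T_osc=T_osc)
    # small irrational offset keeps the grid off symmetry points (e.g. an
    # unstable fixed point exactly at pi/2 would otherwise never leave)
    starts = np.linspace(0.0, TWO_PI, n_starts, endpoint=False) + 0.0123456

    seq = iterate_strobo(starts, T_zeit, n_pulses, p_eff)
    tail = seq[n_transient:]
    last_steps = wrap_pi(tail[-1] - tail[-2])
    converged = np.all(np.abs(last_steps) < tol)
    if not converged:
        # distinguish a period-2+ orbit from drift for the caller
        two_step = wrap_pi(tail[-1] - tail[-3])
        if np.all(np.abs(two_step) < tol):
            warnings.warn(
                f"T_zeit={T_zeit}: stroboscopic map converges to a period-2 "
                "orbit, not a fixed point", RuntimeWarning,
            )
        return np.nan, False
    _, ang = kuramoto_R(tail[-1])
    return float(ang), True
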