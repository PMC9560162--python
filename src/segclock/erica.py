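"""ERICA: Elliptic Radial Isochron Cycle with Acceleration.

A minimal planar limit-cycle oscillator family used to model the
segmentation clock's entrainment response.  The limit cycle is an ellipse
(semi-axes a = 1 along the kick axis, b = 1 - lambda), traversed at a
piecewise-constant angular speed: within an angular sector the speed is
multiplied by s* >= 1 ("acceleration"), producing relaxation-type dynamics
and a strongly asymmetric phase response curve.  Isochrons are radial, i.e.
rays through the origin, so the phase of any point in the plane — and hence
the phase response to an instantaneous displacement (kick) of amplitude
epsilon — is available in closed form.

Conventions
-----------
The cycle is parametrized by the elliptic angle theta: the cycle point is
(a cos theta, b sin theta).  Level sets of theta are rays through the
origin (a point (x, y) has theta = atan2(y/b, x/a)), so theta is the radial
isochron coordinate.  The phase Phi(theta) in [0, 2pi) is the normalized
traversal time from theta = 0; with s* = 1 it reduces to Phi = theta, and
with lambda = 0, s* = 1 the model is the classical Radial Isochron Cycle
(RIC).  Phase 0 sits at theta = 0, the maximum of x, matching the
peak-referenced phase convention of the signal pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp

from .circstats import TWO_PI, PulseTrain, wrap_2pi, wrap_pi

__all__ = [
    "EricaParams",
    "phase_of_angle",
    "angle_of_phase",
    "prc_analytic",
    "iterate_strobo",
    "simulate_ode",
]


@dataclass(frozen=True)
class EricaParams:
    """Parameters of the ERICA oscillator.

    lam : eccentricity parameter in [0, 1); semi-axis ratio b/a = 1 - lam.
    s_star : sector speed factor >= 1.
    eps : kick amplitude (dimensionless, in units of the semi-axis a).
    sector : (theta_on, theta_off) accelerated angular sector, rad; the
        default covers the half cycle [pi/2, 3 pi/2), i.e. the x < 0 half of
        the cycle is traversed fast (the "reset"), the x > 0 half slowly.
    kick_dir : unit vector of the kick in the plane; the default points
        250 degrees from +x (mostly -y with a -x component), modeling
        pulse-wise pathway inhibition.  With the default sector this
        geometry yields the predominantly non-positive, strongly
        asymmetric response curve characteristic of the entrained
        segmentation clock.  The kick must be oblique to the ellipse axes
        for (lam, eps) to be separately identifiable from the PRC: an
        axis-aligned kick enters the response only through eps * k_y /
        (1 - lam) (or eps * k_x alone), collapsing the two parameters
        onto one.  Both sector and kick are fit parameters and only seed
        the Monte Carlo optimization.
    T_osc : intrinsic (free-running) period, minutes.
    relax_rate : radial relaxation rate of the ODE variant, 1/min.
    axis_ratio : optional override of b/a (else 1 - lam).
    """

    lam: float = 0.0
    s_star: float = 1.0
    eps: float = 0.0
    sector: tuple = (np.pi / 2, 3 * np.pi / 2)
    kick_dir: tuple = (np.cos(np.deg2rad(250.0)), np.sin(np.deg2rad(250.0)))
    T_osc: float = 140.0
    relax_rate: float = 0.5
    axis_ratio: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.lam < 1.0):
            raise ValueError(f"lam must be in [0, 1), got {self.lam}")
        if self.s_star < 1.0:
            raise ValueError(f"s_star must be >= 1, got {self.s_star}")
        if self.eps < 0.0:
            raise ValueError(f"eps must be >= 0, got {self.eps}")
        width = self.sector[1] - self.sector[0]
        if not (0.0 < width <= TWO_PI):
            raise ValueError("sector width must be in (0, 2*pi]")
        if self.T_osc <= 0:
            raise ValueError("T_osc must be positive")
        if self.axis_ratio is not None and self.axis_ratio <= 0:
            raise ValueError("axis_ratio must be positive")
        nrm = float(np.hypot(*self.kick_dir))
        if nrm == 0:
            raise ValueError("kick_dir must be a nonzero vector")

    @property
    def semi_axes(self) -> tuple:
        """(a, b) with a = 1 along x (the default kick axis)."""
        b = self.axis_ratio if self.axis_ratio is not None else 1.0 - self.lam
        return 1.0, float(b)

    @property
    def kick_unit(self) -> np.ndarray:
        v = np.asarray(self.kick_dir, dtype=float)
        return v / np.hypot(*v)


@lru_cache(maxsize=64)
def _segments(sector: tuple, s_star: float, T_osc: float):
    """Piecewise-constant angular-speed segments over [0, 2pi).

    Returns (lo, hi, speed, t_lo, phi_lo): segment bounds, angular speed
    (rad/min) per segment, cumulative traversal time and cumulative phase at
    each segment's lower bound.  The base speed is normalized so one full
    circuit takes exactly T_osc minutes.
    """
    on = float(np.mod(sector[0], TWO_PI))
    width = float(sector[1] - sector[0])
    width = min(width, TWO_PI)
    off = on + width

    # base angular speed so that (2pi - width)/w_b + width/(s* w_b) = T_osc
    w_base = ((TWO_PI - width) + width / s_star) / T_osc
    w_fast = s_star * w_base

    cuts = {0.0, TWO_PI, on}
    cuts.add(off if off <= TWO_PI else off - TWO_PI)
    bounds = np.array(sorted(c for c in cuts if 0.0 <= c <= TWO_PI))
    lo, hi = bounds[:-1], bounds[1:]
    keep = hi - lo > 1e-15
    lo, hi = lo[keep], hi[keep]

    mid = 0.5 * (lo + hi)
    if off <= TWO_PI:
        in_sector = (mid >= on) & (mid < off)
    else:  # sector wraps through 0
        in_sector = (mid >= on) | (mid < off - TWO_PI)
    speed = np.where(in_sector, w_fast, w_base)

    seg_t = (hi - lo) / speed
    t_lo = np.concatenate([[0.0], np.cumsum(seg_t)[:-1]])
    phi_lo = TWO_PI * t_lo / T_osc
    return lo, hi, speed, t_lo, phi_lo


def phase_of_angle(theta, p: EricaParams):
    """Phase Phi(theta) in [0, 2pi): normalized traversal time from theta = 0.

    Monotone bijection of [0, 2pi) with Phi(0) = 0; identity when s* = 1.
    """
    lo, hi, speed, t_lo, _ = _segments(p.sector, p.s_star, p.T_osc)
    theta = wrap_2pi(np.asarray(theta, dtype=float))
    idx = np.clip(np.searchsorted(lo, theta, side="right") - 1, 0, len(lo) - 1)
    t = t_lo[idx] + (theta - lo[idx]) / speed[idx]
    out = TWO_PI * t / p.T_osc
    return out if out.ndim else float(out)


def angle_of_phase(phi, p: EricaParams):
    """Inverse of :func:`phase_of_angle` (piecewise-linear inversion)."""
    lo, hi, speed, t_lo, phi_lo = _segments(p.sector, p.s_star, p.T_osc)
    phi = wrap_2pi(np.asarray(phi, dtype=float))
    idx = np.clip(np.searchsorted(phi_lo, phi, side="right") - 1, 0, len(lo) - 1)
    t_local = (phi - phi_lo[idx]) * p.T_osc / TWO_PI
    theta = lo[idx] + t_local * speed[idx]
    return theta if theta.ndim else float(theta)


def prc_analytic(phi, p: EricaParams, eps: float | None = None):
    """Analytic phase response curve, wrapped to (-pi, pi].

    The oscillator sits ON the cycle at phase ``phi``; the pulse displaces it
    instantaneously by eps * a along ``kick_dir``; the new phase is read off
    the radial isochron through the displaced point.  With lam = 0, s* = 1
    and kick (sigma, 0) this reduces to the RIC closed form
    wrap(atan2(sin phi, cos phi + eps * sigma) - phi).
    """
    if eps is None:
        eps = p.eps
    a, b = p.semi_axes
    kx, ky = p.kick_unit
    phi_arr = np.asarray(phi, dtype=float)
    theta = angle_of_phase(phi_arr, p)
    x = a * np.cos(theta) + eps * a * kx
    y = b * np.sin(theta) + eps * a * ky
    if np.any(np.hypot(x, y) < 1e-12):
        raise ValueError(
            "kicked point lands at the origin: phase undefined "
            "(kick amplitude matches the cycle radius at this phase)"
        )
    theta_new = np.arctan2(y / b, x / a)
    out = wrap_pi(phase_of_angle(theta_new, p) - phi_arr)
    return out if np.asarray(phi).ndim else float(out)


def iterate_strobo(phi0, T_zeit: float, n: int, p: EricaParams,
                   eps: float | None = None, unwrap: bool = False) -> np.ndarray:
    """Iterate the stroboscopic map for n pulses.

    phi_{k+1} = (phi_k + PRC(phi_k) + 2 pi T_zeit / T_osc) mod 2 pi.

    Assumes fast relaxation back to the cycle between pulses.  ``phi0`` may
    be a scalar or an array of initial phases (iterated in parallel); the
    result has shape (n+1,) or (n+1, len(phi0)).  With ``unwrap=True`` the
    increments are accumulated without the modulo, which makes rotation
    numbers and n:m locking exact for fixed points.
    """
    phi0_arr = np.atleast_1d(np.asarray(phi0, dtype=float))
    seq = np.empty((n + 1, phi0_arr.size))
    seq[0] = phi0_arr
    drift = TWO_PI * T_zeit / p.T_osc
    for k in range(n):
        cur = seq[k] if unwrap else wrap_2pi(seq[k])
        step = prc_analytic(wrap_2pi(cur), p, eps=eps) + drift
        seq[k + 1] = seq[k] + step
    if not unwrap:
        seq = wrap_2pi(seq)
    if np.isscalar(phi0) or np.asarray(phi0).ndim == 0:
        return seq[:, 0]
    return seq


def _polar_state(x: float, y: float, p: EricaParams):
    a, b = p.semi_axes
    theta = np.arctan2(y / b, x / a)
    rho = np.hypot(x / a, y / b)
    return theta, rho


def _cartesian_state(theta: float, rho: float, p: EricaParams):
    a, b = p.semi_axes
    return rho * a * np.cos(theta), rho * b * np.sin(theta)


def _angular_speed(theta: float, p: EricaParams) -> float:
    lo, hi, speed, _, _ = _segments(p.sector, p.s_star, p.T_osc)
    th = wrap_2pi(theta)
    idx = np.clip(np.searchsorted(lo, th, side="right") - 1, 0, len(lo) - 1)
    return speed[idx]


def simulate_ode(state0, t_span, pulses: PulseTrain | None, p: EricaParams,
                 dt_out: float = 1.0, rtol: float = 1e-9, atol: float = 1e-11):
    """Integrate the planar ERICA flow with instantaneous pulse kicks.

    In elliptic-polar coordinates (theta, rho), with the cycle at rho = 1:
    d theta/dt = omega(theta), d rho/dt = relax_rate * (1 - rho) — a flow
    that preserves the radial isochrons.  Pulses displace the state by
    eps * a * kick_dir in Cartesian coordinates at their onset times.

    Returns ``(t, x, y)`` sampled every ``dt_out`` minutes.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    theta, rho = _polar_state(float(state0[0]), float(state0[1]), p)

    onsets = []
    if pulses is not None:
        onsets = [float(s) for s in pulses.onsets if t0 < s < t1]
    eps_kick = pulses.strength if pulses is not None else 0.0

    def rhs(t, s):
        return [_angular_speed(s[0], p), p.relax_rate * (1.0 - s[1])]

    t_out = np.arange(t0, t1 + 1e-9, dt_out)
    xs = np.empty_like(t_out)
    ys = np.empty_like(t_out)

    seg_starts = [t0] + onsets
    seg_ends = onsets + [t1]
    pos = 0
    state = [theta, rho]
    for s_t0, s_t1, is_last in zip(seg_starts, seg_ends,
                                   [False] * len(onsets) + [True]):
        # each output time belongs to exactly one segment; a sample that
        # coincides with a pulse onset reports the post-kick state
        if is_last:
            mask = (t_out >= s_t0) & (t_out <= s_t1 + 1e-9)
        else:
            mask = (t_out >= s_t0) & (t_out < s_t1)
        t_eval = t_out[mask]
        sol = solve_ivp(rhs, (s_t0, s_t1), state, t_eval=t_eval,
                        rtol=rtol, atol=atol, max_step=p.T_osc / 20.0,
                        dense_output=False, method="RK45")
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on [{s_t0}, {s_t1}]: {sol.message}"
            )
        n_here = len(sol.t)
        for j in range(n_here):
            x_j, y_j = _cartesian_state(sol.y[0, j], sol.y[1, j], p)
            xs[pos + j], ys[pos + j] = x_j, y_j
        pos += n_here
        # endpoint state, then apply the kick (if this segment ends at a pulse)
        sol_end = solve_ivp(rhs, (s_t0, s_t1), state, rtol=rtol, atol=atol,
                            max_step=p.T_osc / 20.0, method="RK45")
        if not sol_end.success:
            raise RuntimeError(
                f"ODE integration failed on [{s_t0}, {s_t1}]: {sol_end.message}"
            )
        th_e, rho_e = sol_end.y[0, -1], sol_end.y[1, -1]
        if not is_last:
            a, _ = p.semi_axes
            kx, ky = p.kick_unit
            x_e, y_e = _cartesian_state(th_e, rho_e, p)
            th_e, rho_e = _polar_state(x_e + eps_kick * a * kx,
                                       y_e + eps_kick * a * ky, p)
        state = [th_e, rho_e]

    # de-duplicate boundary points if t_eval overlapped at segment joints
    if pos != len(t_out):
        # rebuild outputs by exact time matching
        raise RuntimeError("internal sampling mismatch in simulate_ode")
    return t_out, xs, ys


def phase_of_point(x, y, p: EricaParams):
    """Phase of arbitrary plane point(s) via the radial isochrons."""
    a, b = p.semi_axes
    theta = np.arctan2(np.asarray(y) / b, np.asarray(x) / a)
    return phase_of_angle(theta, p)


def with_eps(p: EricaParams, eps: float) -> EricaParams:
    """Copy of params with a different kick amplitude."""
    return replace(p, eps=float(eps))


def with_T_osc(p: EricaParams, T_osc: float) -> EricaParams:
    """Copy of params with a different intrinsic period."""
    return replace(p, T_osc=float(T_osc))
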