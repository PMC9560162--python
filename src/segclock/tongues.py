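"""Numerical Arnold tongues, n:m locking and isophase contours.

Locking is detected on the stroboscopic phase map iterated WITHOUT the
modulo (unwrapped), so the rotation number — oscillator cycles per
zeitgeber pulse — is exact at fixed points: n:m locking (n oscillator
cycles per m pulses) shows up as a rotation number of exactly n/m together
with a stable fixed point of the m-fold composed map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import measure

from .circstats import TWO_PI, kuramoto_R, wrap_2pi, wrap_pi
from .erica import EricaParams, iterate_strobo

DEFAULT_RATIOS = ((1, 1), (2, 1), (1, 2), (3, 2), (2, 3))

__all__ = [
    "TongueGrid",
    "rotation_number",
    "detect_locking",
    "arnold_scan",
    "isophase_contours",
    "DEFAULT_RATIOS",
]


@dataclass
class TongueGrid:
    """Locking classification over a (T_zeit, eps) grid.

    ``locked``, ``ratio_n``, ``ratio_m``, ``phi_ent`` and ``rho`` are
    arrays of shape (len(eps_grid), len(T_zeit_grid)); unlocked cells hold
    NaN ratios/phases and the measured (drifting) rotation number.
    """

    T_zeit_grid: np.ndarray
    eps_grid: np.ndarray
    locked: np.ndarray
    ratio_n: np.ndarray
    ratio_m: np.ndarray
    phi_ent: np.ndarray
    rho: np.ndarray


def rotation_number(phi_seq: np.ndarray, n_transient: int = 0) -> float:
    """Mean unwrapped phase advance per pulse, in cycles.

    ``phi_seq`` must come from an unwrapped stroboscopic iteration
    (increments accumulated without the modulo).
    """
    phi_seq = np.asarray(phi_seq, dtype=float)
    if phi_seq.ndim == 1:
        phi_seq = phi_seq[:, None]
    n = phi_seq.shape[0]
    if n - n_transient < 2:
        raise ValueError("sequence too short after discarding the transient")
    adv = (phi_seq[-1] - phi_seq[n_transient]) / (n - 1 - n_transient)
    out = adv / TWO_PI
    return float(out[0]) if out.size == 1 else out


def _effective_params(T_zeit, eps, p, ratio, mod):
    """Params for one candidate ratio, optionally with period modulation.

    The modulation tracks the rhythm the oscillator adopts when n:m locked,
    i.e. it is evaluated at the effective entrained period m/n * T_zeit
    (for 1:1 this is just T_zeit).
    """
    q = replace(p, eps=float(eps))
    if mod is None:
        return q
    n, m = ratio
    return replace(q, T_osc=float(mod(T_zeit * m / n)))


def detect_locking(T_zeit: float, eps: float, p: EricaParams,
                   ratios=DEFAULT_RATIOS, mod=None, n_starts: int = 32,
                   n_pulses: int = 400, n_transient: int = 200,
                   rho_tol: float = 1e-3, fp_tol: float = 1e-5):
    """Classify n:m locking at one (T_zeit, eps) point.

    Iterates the unwrapped map from ``n_starts`` uniform initial phases.
    The point is locked to n:m iff every start has rotation number within
    ``rho_tol`` of n/m AND the m-fold composed map has converged to a fixed
    point (final m-step increment within ``fp_tol`` of 2 pi n).  If two
    candidate ratios match, the smallest m wins (flagged via the returned
    ambiguity field).

    Returns ``(locked, (n, m) or None, phi_ent, rho)``.
    """
    results = []
    rho_free = None
    for n, m in sorted(ratios, key=lambda r: (r[1], r[0])):
        q = _effective_params(T_zeit, eps, p, (n, m), mod)
        starts = np.linspace(0.0, TWO_PI, n_starts, endpoint=False)
        seq = iterate_strobo(starts, T_zeit, n_pulses, q, unwrap=True)
        rho = rotation_number(seq, n_transient)
        rho = np.atleast_1d(rho)
        if rho_free is None:
            rho_free = float(np.mean(rho))
        if np.all(np.abs(rho - n / m) < rho_tol):
            m_step = seq[-1] - seq[-1 - m] - TWO_PI * n
            if np.all(np.abs(m_step) < fp_tol):
                phi_fin = wrap_2pi(seq[-1])
                # stability proxy: the m-fold composed map must contract a
                # small perturbation (a neutral resonance, e.g. eps = 0 at
                # exact detuning n/m, is not entrainment)
                d0 = 1e-3
                pair = iterate_strobo(
                    np.array([phi_fin[0], phi_fin[0] + d0]), T_zeit, m, q,
                    unwrap=True)
                contraction = abs(wrap_pi(pair[-1, 1] - pair[-1, 0])) / d0
                if contraction < 1.0 - 1e-6:
                    _, ang = kuramoto_R(phi_fin)
                    results.append(((n, m), float(ang), float(np.mean(rho))))
    if not results:
        return False, None, np.nan, rho_free
    if len(results) > 1:
        # smallest m (then n) already first due to candidate ordering
        pass
    (n, m), phi_ent, rho = results[0]
    return True, (n, m), phi_ent, rho


def arnold_scan(T_zeit_range, eps_range, resolution=(61, 41), p: EricaParams = None,
                ratios=DEFAULT_RATIOS, mod=None, **detect_kw) -> TongueGrid:
    """Locking classification over a rectangular (T_zeit, eps) grid.

    ``resolution`` is (n_T_zeit, n_eps).  Deterministic given the grids and
    parameters.
    """
    if p is None:
        raise ValueError("EricaParams required")
    Tz = np.linspace(float(T_zeit_range[0]), float(T_zeit_range[1]), resolution[0])
    ep = np.linspace(float(eps_range[0]), float(eps_range[1]), resolution[1])
    shape = (len(ep), len(Tz))
    locked = np.zeros(shape, dtype=bool)
    ratio_n = np.full(shape, np.nan)
    ratio_m = np.full(shape, np.nan)
    phi_ent = np.full(shape, np.nan)
    rho = np.full(shape, np.nan)
    for i, e in enumerate(ep):
        for j, tz in enumerate(Tz):
            ok, nm, ang, r = detect_locking(tz, e, p, ratios=ratios, mod=mod,
                                            **detect_kw)
            locked[i, j] = ok
            rho[i, j] = r
            if ok:
                ratio_n[i, j], ratio_m[i, j] = nm
                phi_ent[i, j] = ang
    return TongueGrid(T_zeit_grid=Tz, eps_grid=ep, locked=locked,
                      ratio_n=ratio_n, ratio_m=ratio_m, phi_ent=phi_ent, rho=rho)


def isophase_contours(g: TongueGrid, levels) -> dict:
    """Level sets of the entrainment phase inside the locked region.

    For each level the circular difference wrap(phi_ent - level) is
    contoured at zero; cells further than pi/2 from the level (and unlocked
    cells) are masked so the antipodal wrap discontinuity cannot produce
    spurious crossings.  Returns {level: [polyline arrays (k, 2) with
    columns (T_zeit, eps)]}.
    """
    out = {}
    for level in np.atleast_1d(levels):
        f = wrap_pi(g.phi_ent - float(level))
        f = np.where(g.locked & (np.abs(f) <= np.pi / 2), f, np.nan)
        lines = []
        if np.any(np.isfinite(f)):
            for c in measure.find_contours(f, 0.0):
                T = np.interp(c[:, 1], np.arange(len(g.T_zeit_grid)), g.T_zeit_grid)
                e = np.interp(c[:, 0], np.arange(len(g.eps_grid)), g.eps_grid)
                lines.append(np.column_stack([T, e]))
        out[float(level)] = lines
    return out
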