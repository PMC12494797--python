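"""Primary SAXS analysis: Guinier fit, dimensionless Kratky, Porod and
correlation volumes, and the molecular-mass estimates they imply.

The Guinier approximation I(q) ≈ I(0)·exp(−q²Rg²/3) holds for q·Rg ≲ 1.3;
the fit window is found by self-consistent iteration of the qmax·Rg limit.
Masses follow the two standard routes: Vp = 2π²I(0)/Q with the Porod
invariant Q = ∫q²I dq (Guinier-extrapolated below qmin, q⁻⁴ tail above the
cutoff), mass ≈ Vp/1.6e3 Å³ per kDa; and the correlation volume
Vc = I(0)/∫qI dq with the protein power-law calibration
mass[Da] = (Vc²/Rg)/0.1231.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .core import ScatteringCurve

__all__ = [
    "GuinierResult", "InvariantSet", "guinier_fit", "kratky_dimensionless",
    "porod_volume", "correlation_volume", "compute_invariants",
]

#: Porod-volume mass calibration, Å³ per kDa of protein
POROD_DIVISOR = 1.6e3
#: correlation-volume protein calibration (Rambo–Tainer), QR units per Da
VC_KC = 0.1231


@dataclass
class GuinierResult:
    Rg: float
    I0: float
    q_range: tuple
    n_points: int
    Rg_sigma: float
    I0_sigma: float
    fit_residuals: np.ndarray = field(repr=False, default=None)
    q_fit: np.ndarray = field(repr=False, default=None)


@dataclass
class InvariantSet:
    porod_Q: float = np.nan
    Vp: float = np.nan
    Vc: float = np.nan
    mass_porod: float = np.nan   # kDa
    mass_vc: float = np.nan      # kDa
    q_cutoff: float = np.nan


class GuinierError(ValueError):
    pass


def _wlin(x, y, w):
    """Weighted straight-line fit returning slope, intercept and std errors."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    inter = ym - slope * xm
    var_slope = 1.0 / sxx
    var_inter = 1.0 / W + xm ** 2 / sxx
    return slope, inter, np.sqrt(var_slope), np.sqrt(var_inter)


def guinier_fit(curve: ScatteringCurve, qmaxRg_limit: float = 1.3,
                qmin_override: float | None = None) -> GuinierResult:
    """Weighted linear fit of ln I vs q² on the largest self-consistent
    low-q window with qmax·Rg ≤ limit.

    Raises :class:`GuinierError` when no window satisfies the limit or the
    fitted slope is non-negative (aggregation/repulsion signature).
    """
    qmin = qmin_override if qmin_override is not None else 0.0
    base = (curve.q >= qmin) & (curve.I > 0)
    q = curve.q[base]
    I = curve.I[base]
    sig = curve.sigma[base]
    if q.size < 5:
        raise GuinierError("fewer than 5 usable points for Guinier fit")

    def fit_upto(n):
        x = q[:n] ** 2
        y = np.log(I[:n])
        w = (I[:n] / sig[:n]) ** 2  # σ_lnI = σ/I
        slope, inter, s_sl, s_in = _wlin(x, y, w)
        if slope >= 0:
            raise GuinierError(
                "non-negative Guinier slope (Rg^2 < 0): aggregation or "
                "inter-particle repulsion signature")
        Rg = np.sqrt(-3.0 * slope)
        return Rg, inter, slope, s_sl, s_in

    n = q.size
    # shrink until self-consistent: qmax·Rg <= limit
    while n >= 5:
        try:
            Rg, inter, slope, s_sl, s_in = fit_upto(n)
        except GuinierError:
            n -= 1
            continue
        if q[n - 1] * Rg <= qmaxRg_limit:
            break
        # jump close to the predicted window, then refine one-by-one
        n_new = int(np.searchsorted(q, qmaxRg_limit / Rg, side="right"))
        n = n_new if n_new < n else n - 1
    else:
        raise GuinierError(
            f"no low-q window satisfies qmax*Rg <= {qmaxRg_limit}")
    I0 = float(np.exp(inter))
    x = q[:n] ** 2
    y = np.log(I[:n])
    resid = y - (inter + slope * x)
    Rg_sigma = float(3.0 * s_sl / (2.0 * np.sqrt(-3.0 * slope)))
    return GuinierResult(float(Rg), I0, (float(q[0]), float(q[n - 1])), int(n),
                         Rg_sigma, float(I0 * s_in), resid, q[:n].copy())


def kratky_dimensionless(curve: ScatteringCurve, guinier: GuinierResult):
    """Dimensionless Kratky transform (qRg, (qRg)²·I/I(0)).

    Returns (x, y, plateau) where the plateau estimate is the mean of y over
    the top decile of q — the high-q flexibility diagnostic (globular
    particles decay toward 0, flexible chains level off near or above 1).
    """
    if guinier.I0 <= 0:
        raise ValueError("I0 must be positive")
    x = curve.q * guinier.Rg
    y = x ** 2 * curve.I / guinier.I0
    hi = curve.q >= np.quantile(curve.q, 0.9)
    plateau = float(np.mean(y[hi]))
    return x, y, plateau


def _guinier_low_q_integrals(guinier: GuinierResult, qmin: float):
    """∫₀^qmin q²·I0·exp(−q²Rg²/3) dq and ∫₀^qmin q·I0·exp(−q²Rg²/3) dq."""
    a = guinier.Rg ** 2 / 3.0
    I0 = guinier.I0
    # ∫ q² e^{−a q²} dq = √π erf(√a q)/(4 a^{3/2}) − q e^{−a q²}/(2a)
    q2int = I0 * (np.sqrt(np.pi) * erf(np.sqrt(a) * qmin) / (4 * a ** 1.5)
                  - qmin * np.exp(-a * qmin ** 2) / (2 * a))
    # ∫ q e^{−a q²} dq = (1 − e^{−a q²})/(2a)
    q1int = I0 * (1.0 - np.exp(-a * qmin ** 2)) / (2 * a)
    return float(q2int), float(q1int)


def _porod_tail_fit(q: np.ndarray, I: np.ndarray):
    """Fit I = K·q⁻⁴ + c on the top 20% of the q window.

    The constant absorbs the flat high-q term present in measured (and
    discrete-bead simulated) curves; subtracting it before integrating is the
    standard Porod-law practice. K is clamped non-negative.
    """
    from scipy.optimize import nnls
    top = q >= 0.8 * q[-1]
    A = np.column_stack([q[top] ** -4, np.ones(top.sum())])
    (K, c), _ = nnls(A, np.maximum(I[top], 0.0))
    c = float(min(c, max(I.min(), 0.0)))
    return float(K), c


def porod_volume(curve: ScatteringCurve, guinier: GuinierResult,
                 q_cutoff: float | None = None,
                 porod_divisor: float = POROD_DIVISOR,
                 subtract_constant: bool = True) -> InvariantSet:
    """Porod invariant Q, Porod volume Vp = 2π²·I(0)/Q and the mass estimate.

    Q is assembled from an analytic Guinier extension below the first data
    point, the trapezoid on the (constant-subtracted) data up to ``q_cutoff``,
    and a q⁻⁴ Porod tail beyond it.
    """
    qcut = q_cutoff if q_cutoff is not None else float(curve.q[-1])
    m = curve.q <= qcut
    q, I = curve.q[m], curve.I[m]
    K, c = _porod_tail_fit(q, I)
    if not subtract_constant:
        K, c = float(np.mean(q[q >= 0.8 * q[-1]] ** 4
                             * I[q >= 0.8 * q[-1]])), 0.0
    low, _ = _guinier_low_q_integrals(guinier, float(q[0]))
    data_part = float(np.trapezoid(q ** 2 * np.maximum(I - c, 0.0), q))
    tail = K / float(q[-1])
    Q = low + data_part + tail
    if Q <= 0:
        raise ValueError("non-positive Porod invariant")
    Vp = 2 * np.pi ** 2 * guinier.I0 / Q
    return InvariantSet(porod_Q=float(Q), Vp=float(Vp),
                        mass_porod=float(Vp / porod_divisor), q_cutoff=qcut)


def correlation_volume(curve: ScatteringCurve, guinier: GuinierResult,
                       q_cutoff: float = 0.3, kc: float = VC_KC,
                       subtract_constant: bool = True) -> InvariantSet:
    """Correlation volume Vc = I(0)/∫₀^qcut q·I dq and the mass estimate
    mass[Da] = QR/kc with QR = Vc²/Rg (protein calibration)."""
    qcut = min(q_cutoff, float(curve.q[-1]))
    m = curve.q <= qcut
    q, I = curve.q[m], curve.I[m]
    if subtract_constant:
        _, c = _porod_tail_fit(q, I)
        I = np.maximum(I - c, 0.0)
    _, low = _guinier_low_q_integrals(guinier, float(q[0]))
    integral = low + float(np.trapezoid(q * I, q))
    if integral <= 0:
        raise ValueError("non-positive correlation integral")
    Vc = guinier.I0 / integral
    QR = Vc ** 2 / guinier.Rg
    return InvariantSet(Vc=float(Vc), mass_vc=float(QR / kc / 1e3),
                        q_cutoff=qcut)


def compute_invariants(curve: ScatteringCurve, guinier: GuinierResult,
                       q_cutoff: float | None = None,
                       porod_divisor: float = POROD_DIVISOR,
                       kc: float = VC_KC) -> InvariantSet:
    """Porod and correlation volumes combined into one InvariantSet."""
    p = porod_volume(curve, guinier, q_cutoff, porod_divisor)
    c = correlation_volume(curve, guinier,
                           q_cutoff if q_cutoff is not None else 0.3, kc)
    return InvariantSet(porod_Q=p.porod_Q, Vp=p.Vp, Vc=c.Vc,
                        mass_porod=p.mass_porod, mass_vc=c.mass_vc,
                        q_cutoff=p.q_cutoff)
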