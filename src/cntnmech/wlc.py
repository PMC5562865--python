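"""Worm-like chain elasticity: evaluation, inversion and branch fitting.

The worm-like chain (WLC) is the standard polymer model for the entropic
elasticity of an unfolded polypeptide stretched in an AFM pulling
experiment.  We use the Marko--Siggia interpolation formula

    F(x) = (kBT / Lp) * [ 1 / (4 (1 - x/Lc)^2) - 1/4 + x/Lc ]

with persistence length ``Lp`` (nm), contour length ``Lc`` (nm) and
thermal energy ``kBT`` (pN nm).  ``F`` is strictly increasing on
``[0, Lc)`` and diverges at full extension, which is what makes the
fitted contour length of each rising branch of a saw-tooth curve a
well-defined observable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import constants, optimize

__all__ = [
    "KB_PN_NM",
    "WLCParams",
    "WLCFit",
    "WLCDomainError",
    "InsufficientDataError",
    "wlc_force",
    "wlc_extension",
    "wlc_contour_from_point",
    "fit_wlc_segment",
]

#: Boltzmann constant in pN nm / K (1 J = 1e21 pN nm).
KB_PN_NM = constants.k * 1e21


class WLCDomainError(ValueError):
    """Extension or force outside the physical domain of the model."""


class InsufficientDataError(ValueError):
    """Too few samples to constrain a fit."""


@dataclasses.dataclass(frozen=True)
class WLCParams:
    """Parameters of one worm-like chain.

    Attributes
    ----------
    Lp : persistence length in nm (> 0).
    Lc : contour length in nm (> 0).
    T : temperature in K (> 0).
    """

    Lp: float
    Lc: float
    T: float = 300.0

    def __post_init__(self) -> None:
        if not (self.Lp > 0 and self.Lc > 0 and self.T > 0):
            raise ValueError(
                f"WLC parameters must be positive: Lp={self.Lp}, Lc={self.Lc}, T={self.T}"
            )

    @property
    def kBT(self) -> float:
        """Thermal energy in pN nm."""
        return KB_PN_NM * self.T


@dataclasses.dataclass
class WLCFit:
    """Result of fitting one rising branch of a force-extension curve."""

    params: WLCParams
    rms_residual: float
    n_points: int
    converged: bool


def wlc_force(x, p: WLCParams):
    """Marko--Siggia WLC force (pN) at extension ``x`` (nm).

    ``x`` may be a scalar or array; every element must satisfy
    ``0 <= x < Lc``.
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa >= p.Lc):
        raise WLCDomainError(f"extension must satisfy 0 <= x < Lc={p.Lc}")
    r = xa / p.Lc
    f = (p.kBT / p.Lp) * (0.25 / (1.0 - r) ** 2 - 0.25 + r)
    if np.isscalar(x):
        return float(f)
    return f


def _wlc_force_unchecked(xa: np.ndarray, Lp: float, Lc: float, kBT: float) -> np.ndarray:
    r = xa / Lc
    return (kBT / Lp) * (0.25 / (1.0 - r) ** 2 - 0.25 + r)


def wlc_extension(F: float, p: WLCParams, tol: float = 1e-6) -> float:
    """Invert the WLC: extension (nm) at which the chain exerts ``F`` pN.

    Bracketed bisection on ``[0, Lc (1 - 1e-9)]``; the forward map is
    strictly monotone so the root is unique.  ``tol`` is the force
    tolerance in pN.
    """
    if F < 0:
        raise WLCDomainError(f"force must be non-negative, got {F}")
    if F == 0:
        return 0.0
    lo, hi = 0.0, p.Lc * (1.0 - 1e-9)
    if wlc_force(hi, p) < F:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = wlc_force(mid, p)
        if abs(fm - F) < tol:
            return mid
        if fm < F:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def wlc_contour_from_point(x: float, F: float, Lp: float, T: float = 300.0) -> float:
    """Contour length whose WLC passes through the point ``(x, F)``.

    Monotone in Lc (larger chains are softer), solved by bisection.
    Useful when a known tension and extension pin down the chain, e.g.
    at the exit of a constant-force plateau.
    """
    if F <= 0 or x <= 0:
        raise WLCDomainError("need x > 0 and F > 0 to solve for Lc")
    kBT = KB_PN_NM * T
    lo = x * (1.0 + 1e-9)
    hi = x * 1e4
    if _wlc_force_unchecked(np.asarray(x), Lp, hi, kBT) > F:
        raise WLCDomainError(f"force {F} pN unreachably low at extension {x} nm")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = float(_wlc_force_unchecked(np.asarray(x), Lp, mid, kBT))
        if abs(fm - F) < 1e-9:
            return mid
        if fm > F:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit_wlc_segment(
    separation,
    force,
    Lp: float = 0.4,
    Lp_mode: str = "fixed",
    T: float = 300.0,
) -> WLCFit:
    """Least-squares WLC fit to one rising branch.

    Parameters
    ----------
    separation, force : arrays of tip-sample separation (nm) and force (pN).
    Lp : persistence length in nm.  With ``Lp_mode='fixed'`` (default) it
        is held at this value and only Lc is estimated, which keeps
        contour-length increments comparable across branches.
    Lp_mode : 'fixed' or 'free'.
    T : temperature in K.

    Returns a :class:`WLCFit`; non-convergence is flagged, not silent.
    """
    x = np.asarray(separation, dtype=float)
    f = np.asarray(force, dtype=float)
    if x.shape != f.shape:
        raise ValueError("separation and force must have equal length")
    if x.size < 5:
        raise InsufficientDataError(f"need >= 5 points for a WLC fit, got {x.size}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("separations must be strictly increasing")
    kBT = KB_PN_NM * T
    xmax = float(x[-1])

    def ssr_for_lc(lc: float) -> float:
        resid = _wlc_force_unchecked(x, Lp, lc, kBT) - f
        return float(resid @ resid)

    lo = xmax * (1.0 + 1e-6)
    hi = xmax * 20.0
    if Lp_mode == "fixed":
        res = optimize.minimize_scalar(
            ssr_for_lc, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        lc = float(res.x)
        converged = bool(res.success) and lc < hi * 0.999
        rms = float(np.sqrt(res.fun / x.size))
        return WLCFit(WLCParams(Lp, lc, T), rms, int(x.size), converged)
    if Lp_mode != "free":
        raise ValueError(f"Lp_mode must be 'fixed' or 'free', got {Lp_mode!r}")

    def resid(theta):
        lp, lc = theta
        return _wlc_force_unchecked(x, lp, lc, kBT) - f

    res = optimize.least_squares(
        resid,
        x0=[Lp, xmax * 1.1],
        bounds=([0.05, lo], [2.0, hi]),
    )
    lp_fit, lc_fit = res.x
    rms = float(np.sqrt(2.0 * res.cost / x.size))
    converged = bool(res.success) and lc_fit < hi * 0.999
    return WLCFit(WLCParams(float(lp_fit), float(lc_fit), T), rms, int(x.size), converged)
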