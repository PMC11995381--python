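"""Numerical Fourier-Abel-Hankel transform cycle for isotropic models.

The three representations of an isotropic structure -- the real-space
correlation ``gamma(r)``, the scattering intensity ``I(Q)`` and the
projected (SESANS) correlation ``G(z)`` -- form a closed transform cycle:
any two are related by a Fourier, Abel or Hankel transform.  This module
implements the three legs numerically; they serve both as generic
utilities for arbitrary isotropic models and as independent oracles for
the closed forms in :mod:`polysesans.models`.

Transform conventions (pinned by requiring the Gaussian test pair to close
the cycle):

====================  =====================================================
leg                   convention
====================  =====================================================
Fourier (r -> Q)      ``I(Q) = 4 pi \\int_0^inf r^2 gamma(r) sinc(Q r) dr``
Fourier (Q -> r)      ``gamma(r) = (1 / 2 pi^2) \\int_0^inf Q^2 F(Q) sinc(Q r) dQ``
Abel (r -> z)         ``G(z) = 2 \\int_z^inf gamma(r) r (r^2 - z^2)^{-1/2} dr``
Hankel (Q -> z)       ``G(z) = (1 / 2 pi) \\int_0^{Qmax} I(Q) J0(Q z) Q dQ``
====================  =====================================================

with ``sinc(x) = sin(x)/x``.  With these placements Abel(gamma) and
Hankel(Fourier(gamma)) coincide.  The Abel integrand's inverse-square-root
endpoint singularity is removed exactly by the substitution
``u^2 = r^2 - z^2``, turning the projection into
``G(z) = 2 \\int_0^inf gamma(sqrt(u^2 + z^2)) du``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy import integrate, interpolate, special

__all__ = [
    "Curve",
    "ConvergenceError",
    "abel_project",
    "hankel_project",
    "radial_fourier_invert",
    "radial_fourier_transform",
]

AXES = ("r", "z", "Q")


class ConvergenceError(ArithmeticError):
    """A transform integral failed to converge (non-decaying input, or an
    oscillatory tail that cannot be resolved at the requested point)."""


@dataclass
class Curve:
    """A sampled one-dimensional function with a named axis.

    Parameters
    ----------
    axis : {'r', 'z', 'Q'}
        Abscissa kind: real-space separation, spin-echo length, or
        momentum transfer.
    grid : array
        Strictly increasing, non-negative abscissae (length >= 2).
    values : array
        Ordinates, same length as ``grid``.
    errors : array, optional
        One-sigma uncertainties (e.g. counting errors from a histogram
        estimator); used as fit weights downstream.
    normalized_at_zero : bool
        Declares that the value extrapolated to the origin is 1.
    meta : dict
        Free-form metadata (units, provenance, truncation diagnostics).
    """

    axis: str
    grid: np.ndarray
    values: np.ndarray
    errors: Optional[np.ndarray] = None
    normalized_at_zero: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be 1-D with at least 2 points")
        if self.values.shape != self.grid.shape:
            raise ValueError("grid and values must have equal length")
        if np.any(self.grid < 0):
            raise ValueError("grid must be non-negative")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.grid.shape:
                raise ValueError("errors must match grid length")
        if self.normalized_at_zero:
            v0 = self.value_at_zero()
            if not np.isfinite(v0) or abs(v0 - 1.0) > 0.05:
                raise ValueError(
                    f"curve declared normalized_at_zero but extrapolates to {v0:.4g}"
                )

    def value_at_zero(self) -> float:
        """Linear extrapolation of the first two samples to the origin."""
        x0, x1 = self.grid[:2]
        y0, y1 = self.values[:2]
        if x0 == 0:
            return float(y0)
        return float(y0 - (y1 - y0) / (x1 - x0) * x0)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Cubic-spline interpolation within the sampled range."""
        spl = interpolate.CubicSpline(self.grid, self.values)
        return spl(x)


def _as_callable(obj: Union[Curve, Callable], axis: str) -> Callable:
    if isinstance(obj, Curve):
        if obj.axis != axis:
            raise ValueError(f"expected a curve on axis {axis!r}, got {obj.axis!r}")
        spl = interpolate.CubicSpline(obj.grid, obj.values)
        hi = obj.grid[-1]

        def fn(x):
            x = np.asarray(x, dtype=float)
            return np.where(x <= hi, spl(np.minimum(x, hi)), 0.0)

        return fn
    return obj


def _check_tail_decay(fn: Callable, scale: float) -> None:
    """Reject inputs whose tail does not decay faster than 1/r.

    ``r * gamma(r)`` must fall off at infinity for the Abel integral to
    exist; we require the integrand to have dropped by 10x between 20 and
    100 characteristic scales.
    """
    r1, r2 = 20.0 * scale, 100.0 * scale
    v1 = abs(float(np.asarray(fn(np.array([r1]))).ravel()[0])) * r1
    v2 = abs(float(np.asarray(fn(np.array([r2]))).ravel()[0])) * r2
    if v2 > 0.1 * v1 and v2 > 1e-300:
        raise ConvergenceError(
            "input does not decay fast enough for the Abel projection "
            f"(r*gamma at r={r2:g} is {v2:.3g}, vs {v1:.3g} at r={r1:g})"
        )


def abel_project(
    gamma: Union[Curve, Callable],
    z_grid: np.ndarray,
    scale: Optional[float] = None,
) -> Curve:
    """Abel (line) projection ``G(z) = 2 \\int_z^inf gamma r (r^2-z^2)^{-1/2} dr``.

    The substitution ``u^2 = r^2 - z^2`` removes the endpoint singularity
    exactly; the remaining smooth integral is evaluated by adaptive
    Gauss-Kronrod quadrature, truncated where the integrand has fallen
    below 1e-12 of its peak.

    Parameters
    ----------
    gamma : callable or Curve on the r axis
        The isotropic correlation function.
    z_grid : array
        Spin-echo lengths at which to evaluate the projection.
    scale : float, optional
        Characteristic decay length used for tail checks and truncation;
        inferred from the grid/curve extent when omitted.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    fn = _as_callable(gamma, "r")
    if scale is None:
        if isinstance(gamma, Curve):
            scale = float(gamma.grid[-1]) / 10.0
        else:
            scale = max(float(np.max(z_grid)), 1.0) / 2.0
    if not isinstance(gamma, Curve):
        _check_tail_decay(fn, scale)

    # truncate where |gamma| < 1e-12 of its near-origin magnitude
    u_max = _find_cutoff(fn, scale)
    out = np.empty_like(z_grid)
    for i, z in enumerate(z_grid):
        val, _ = integrate.quad(
            lambda u: float(np.asarray(fn(np.array([np.hypot(u, z)]))).ravel()[0]),
            0.0,
            u_max,
            limit=400,
            epsabs=1e-13,
            epsrel=1e-11,
        )
        out[i] = 2.0 * val
    return Curve(axis="z", grid=z_grid, values=out, meta={"transform": "abel"})


def _find_cutoff(fn: Callable, scale: float) -> float:
    ref = abs(float(np.asarray(fn(np.array([0.05 * scale]))).ravel()[0]))
    r = 10.0 * scale
    for _ in range(40):
        if abs(float(np.asarray(fn(np.array([r]))).ravel()[0])) < 1e-12 * max(ref, 1e-300):
            return r
        r *= 1.5
    return r


def hankel_project(
    intensity: Union[Curve, Callable],
    z_grid: np.ndarray,
    Q_max: float,
) -> Curve:
    """Hankel projection ``G(z) = (1/2 pi) \\int_0^{Qmax} I(Q) J0(Qz) Q dQ``.

    ``Q_max`` is a required explicit argument: for intensities with a
    ``Q^{-2}`` tail (e.g. the Debye function) the projection at ``z -> 0``
    grows without bound as the truncation is raised, and hiding the
    truncation behind a default would hide that artifact.  The returned
    curve carries a truncation-error estimate (the magnitude of the last
    decade of the integrand, an upper-bound proxy for the discarded tail)
    in ``meta['truncation_estimate']``.
    """
    if Q_max <= 0:
        raise ValueError("Q_max must be positive")
    z_grid = np.asarray(z_grid, dtype=float)
    fn = _as_callable(intensity, "Q")
    out = np.empty_like(z_grid)
    for i, z in enumerate(z_grid):
        def integrand(Q):
            return float(np.asarray(fn(np.array([Q]))).ravel()[0]) * special.j0(Q * z) * Q

        # resolve the Bessel oscillation: subdivide at its zeros
        if z > 0:
            pts = np.arange(1, int(Q_max * z / np.pi) + 1) * np.pi / z
            pts = pts[pts < Q_max][:4000]
        else:
            pts = None
        val, err = integrate.quad(
            integrand, 0.0, Q_max, limit=max(50, (0 if pts is None else len(pts)) + 100),
            points=pts, epsabs=1e-12, epsrel=1e-10,
        )
        if not np.isfinite(val):
            raise ConvergenceError(f"Hankel projection failed to converge at z={z:g}")
        out[i] = val / (2.0 * np.pi)
    tail, _ = integrate.quad(
        lambda Q: abs(float(np.asarray(fn(np.array([Q]))).ravel()[0])) * Q,
        0.9 * Q_max,
        Q_max,
        limit=200,
    )
    return Curve(
        axis="z",
        grid=z_grid,
        values=out,
        meta={"transform": "hankel", "Q_max": Q_max, "truncation_estimate": tail / (2 * np.pi)},
    )


def radial_fourier_transform(
    gamma: Union[Curve, Callable], Q_grid: np.ndarray, scale: float = 1.0
) -> Curve:
    """Spherical Fourier transform ``I(Q) = 4 pi \\int r^2 gamma(r) sinc(Qr) dr``."""
    Q_grid = np.asarray(Q_grid, dtype=float)
    fn = _as_callable(gamma, "r")
    r_max = _find_cutoff(fn, scale)
    out = np.empty_like(Q_grid)
    for i, Q in enumerate(Q_grid):
        if Q == 0:
            val, _ = integrate.quad(
                lambda r: r * r * float(np.asarray(fn(np.array([r]))).ravel()[0]),
                0, r_max, limit=400,
            )
            out[i] = 4.0 * np.pi * val
        else:
            val, _ = integrate.quad(
                lambda r: r * float(np.asarray(fn(np.array([r]))).ravel()[0]),
                0, r_max, weight="sin", wvar=Q, limit=2000,
            )
            out[i] = 4.0 * np.pi * val / Q
    return Curve(axis="Q", grid=Q_grid, values=out, meta={"transform": "fourier"})


def radial_fourier_invert(
    form_factor: Callable,
    r_grid: np.ndarray,
    Q_cut: float = 400.0,
) -> Curve:
    """Spherical inverse Fourier transform of an isotropic form factor,

    ``gamma(r) = (1 / 2 pi^2 r) \\int_0^inf Q F(Q) sin(Q r) dQ``,

    evaluated by sin-weighted adaptive quadrature up to ``Q_cut`` (beyond
    which the integrand must be negligible; a ``Q^{-2}`` form-factor tail
    makes the amplitude ``Q F(Q)`` fall off like ``1/Q``, which is
    integrable against the oscillation for ``r > 0`` but produces the
    well-known logarithmic divergence at ``r = 0``).

    Raises
    ------
    ConvergenceError
        If ``r = 0`` is requested for a form factor with a slowly decaying
        tail (the point-scatterer / divergent-correlation pathology), or
        if the amplitude has not decayed at ``Q_cut``.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    amp0 = abs(form_factor(1e-3)) * 1e-3
    tail_amp = abs(form_factor(Q_cut)) * Q_cut
    if np.any(r_grid == 0):
        raise ConvergenceError(
            "inverse Fourier transform at r = 0 requires an integrable "
            "Q^2 F(Q); a Q^-2 tail diverges there -- evaluate at r > 0"
        )
    if tail_amp > 10.0 * max(amp0, 1e-300):
        raise ConvergenceError(
            f"form-factor amplitude Q*F(Q) has not decayed at Q_cut={Q_cut:g}"
        )
    # detect a Q^-2 power tail and correct for the truncated part in closed
    # form: int_{Qc}^inf (A/Q) sin(Qr) dQ = A [pi/2 - Si(Qc r)]
    A = form_factor(Q_cut) * Q_cut**2
    has_q2_tail = A != 0 and abs(form_factor(2 * Q_cut) * 4 * Q_cut**2 / A - 1.0) < 0.3
    out = np.empty_like(r_grid)
    for i, r in enumerate(r_grid):
        val, _ = integrate.quad(
            lambda Q: Q * form_factor(Q),
            1e-12,
            Q_cut,
            weight="sin",
            wvar=r,
            limit=20000,
            epsabs=1e-12,
            epsrel=1e-10,
        )
        if has_q2_tail:
            val += A * (np.pi / 2.0 - special.sici(Q_cut * r)[0])
        out[i] = val / (2.0 * np.pi**2 * r)
    return Curve(
        axis="r",
        grid=r_grid,
        values=out,
        meta={"transform": "inverse-fourier", "q2_tail_corrected": bool(has_q2_tail)},
    )
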