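"""Closed-form scattering models for Gaussian polymer chains.

This module evaluates the real-space and reciprocal-space correlation
functions of the Gaussian (ideal) chain used in small-angle neutron
scattering (SANS) and spin-echo SANS (SESANS) analysis:

* :func:`debye_form_factor` -- the classic Debye function ``F(Q)``,
  depending on ``Q`` and the radius of gyration only through
  ``x = Q^2 Rg^2``.
* :func:`gamma_auto_divergent` -- the spherical inverse Fourier transform
  of the Debye function.  It diverges like ``1/r`` at the origin, which is
  the pathology that makes a naive real-space treatment of Gaussian-chain
  SESANS data impossible.
* :func:`gamma_auto` -- the non-divergent single-chain correlation
  function.  It agrees with the divergent form at separations beyond the
  radius of gyration but stays finite (and normalizable) at ``r = 0``.
* :func:`g0_projected` -- the normalized projected correlation function
  ``G0(z)`` measured by SESANS, obtained in closed form (exponential
  integrals) as the Abel transform of :func:`gamma_auto`.
* :func:`polarization` -- the neutron polarization ``P(z)`` including
  multiple scattering, ``P = exp[opacity * (G0(z) - 1)]``.

All lengths are unit-agnostic: callers pick one length unit and use it
consistently for ``r``, ``z``, ``Rg`` and ``1/Q``.

Mathematical background
-----------------------
The intra-chain correlation of a continuous Gaussian chain is a mixture of
Gaussian kernels over the contour separation ``u`` in [0, 1], with measure
``(1 - u) u^{-3/2}``; the ``u -> 0`` end of this measure produces the
``1/r`` divergence.  Carrying out the mixture integral gives

    gamma_div(eta) ∝ g(eta / 2),
    g(x) = sqrt(pi) (1/x + 2 x) erfc(x) - 2 exp(-x^2),

with ``eta = r / Rg``.  The non-divergent correlation replaces the mixture
measure below the contour cutoff ``u = 1/16`` by the integrable measure
``15 u^{-1/2}`` (continuously matched at the cutoff), which subtracts the
divergence while leaving the function untouched beyond ``eta ~ 1``:

    gamma_auto(eta) = [g(eta / 2) - 4 g(2 eta)] / 12,       gamma_auto(0) = 1.

Projecting along the neutron flight path (Abel transform) gives, with
``c = zeta^2 / 4`` and ``zeta = z / Rg``,

    G0(zeta) = [f(c) - f(16 c)] / (4 ln 2),
    f(x) = (1 + x) E1(x) - exp(-x),

where ``E1`` is the exponential integral.  At ``z = 0`` the bracket tends
to ``ln 16 = 4 ln 2``, hence ``G0(0) = 1`` and the dimensional projected
correlation at the origin is ``G(0) = N_c phi (1 - phi) (beta_H -
beta_D)^2 N^2 ln 2 / (8 pi Rg^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import special

__all__ = [
    "GaussianChainModel",
    "ContrastSpec",
    "InstrumentSpec",
    "DivergenceError",
    "chain_overlap_g",
    "projection_f",
    "debye_form_factor",
    "gamma_auto",
    "gamma_auto_divergent",
    "gamma_full",
    "gamma_full_prefactor",
    "g0_projected",
    "g_at_zero",
    "opacity_from_contrast",
    "polarization",
    "rg_bond_relation",
]

_SQRT_PI = math.sqrt(math.pi)
_LN2 = math.log(2.0)
# gamma_auto normalization: g(eta/2) - 4 g(2 eta) -> 12 as eta -> 0
_AUTO_NORM = 12.0
# switch point below which closed forms are replaced by series expansions
_SERIES_ETA = 1e-3

ArrayLike = Union[float, np.ndarray]


class DivergenceError(ZeroDivisionError):
    """Raised when a correlation function is evaluated at a point where it
    diverges by construction (e.g. the divergent Gaussian-chain correlation
    at ``r = 0``)."""


def rg_bond_relation(b: ArrayLike, N: int) -> ArrayLike:
    """Radius of gyration of a discrete ideal chain with ``N`` bonds.

    The exact finite-``N`` relation for ``N + 1`` equal-mass beads joined by
    Gaussian bonds of root-mean-square length ``b`` is

        Rg^2 = b^2 N (N + 2) / (6 (N + 1)),

    which tends to the familiar ``Rg = b sqrt(N / 6)`` for long chains (the
    two agree to better than 1% for ``N >= 100``).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return np.asarray(b) * math.sqrt(N * (N + 2) / (6.0 * (N + 1)))


@dataclass(frozen=True)
class GaussianChainModel:
    """Parameters of a single Gaussian chain.

    Parameters
    ----------
    Rg : float
        Radius of gyration (> 0), in the caller's length unit.
    N : int
        Number of bonds; the chain has ``N + 1`` beads.
    b : float, optional
        Effective (root-mean-square) bond length.  If given, it must be
        consistent with ``Rg`` through :func:`rg_bond_relation` to 1e-12
        relative; if omitted it is derived from that relation.
    """

    Rg: float
    N: int = 100
    b: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.Rg > 0):
            raise ValueError(f"Rg must be positive, got {self.Rg}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.b is None:
            object.__setattr__(
                self, "b", self.Rg / math.sqrt(self.N * (self.N + 2) / (6.0 * (self.N + 1)))
            )
        else:
            expected = rg_bond_relation(self.b, self.N)
            if abs(expected - self.Rg) > 1e-12 * self.Rg:
                raise ValueError(
                    f"Rg={self.Rg} and b={self.b} violate the Rg-b relation "
                    f"(expected Rg={expected!r} for N={self.N})"
                )

    @classmethod
    def from_bond_length(cls, b: float, N: int) -> "GaussianChainModel":
        """Build a model from the bond length via the exact Rg-b relation."""
        return cls(Rg=float(rg_bond_relation(b, N)), N=N, b=b)


@dataclass(frozen=True)
class ContrastSpec:
    """Isotope-labeling contrast of a melt of ``N_c`` chains.

    A fraction ``phi`` of the chains is deuterated; ``beta_H`` and
    ``beta_D`` are the scattering lengths of the hydrogenated and
    deuterated monomers.  ``n_c = N_c / V`` is the chain number density.
    """

    N_c: int
    phi: float
    beta_H: float
    beta_D: float
    n_c: float

    def __post_init__(self) -> None:
        if self.N_c < 1:
            raise ValueError("N_c must be >= 1")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        if not (self.n_c > 0):
            raise ValueError("n_c must be positive")

    @property
    def contrast_factor(self) -> float:
        """``phi (1 - phi) (beta_H - beta_D)^2`` -- the labeling contrast."""
        return self.phi * (1.0 - self.phi) * (self.beta_H - self.beta_D) ** 2


@dataclass(frozen=True)
class InstrumentSpec:
    """SESANS instrument and sample geometry.

    ``opacity`` is the dimensionless total-scattering exponent prefactor
    appearing in ``P(z) = exp[opacity (G0(z) - 1)]``.  It may be supplied
    directly, or constructed from contrast and geometry with
    :func:`opacity_from_contrast`.
    """

    wavelength: float
    thickness: float
    opacity: float = 0.0

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise ValueError("wavelength must be positive")
        if not (self.thickness > 0):
            raise ValueError("thickness must be positive")
        if self.opacity < 0:
            raise ValueError("opacity must be >= 0")


# ---------------------------------------------------------------------------
# shape functions
# ---------------------------------------------------------------------------

def chain_overlap_g(x: ArrayLike) -> ArrayLike:
    """Shape function ``g(x) = sqrt(pi)(1/x + 2x) erfc(x) - 2 exp(-x^2)``.

    Both real-space correlation functions of the Gaussian chain are
    combinations of ``g``: the divergent one is ``g(eta/2)`` (up to a
    constant) and the non-divergent one is ``g(eta/2) - 4 g(2 eta)``.
    ``g(x) ~ sqrt(pi)/x`` for small ``x`` and ``g(x) ~ exp(-x^2)/x^4`` for
    large ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DivergenceError("g(x) diverges at x = 0; evaluate at x > 0")
    return _SQRT_PI * (1.0 / x + 2.0 * x) * special.erfc(x) - 2.0 * np.exp(-x * x)


def projection_f(x: ArrayLike) -> ArrayLike:
    """Shape function ``f(x) = (1 + x) E1(x) - exp(-x)`` of the projected
    correlation, with ``E1`` the exponential integral.

    ``f`` diverges logarithmically at 0; the difference ``f(c) - f(16 c)``
    entering ``G0`` stays finite (it tends to ``4 ln 2``).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DivergenceError("f(x) diverges at x = 0; evaluate at x > 0")
    return (1.0 + x) * special.exp1(x) - np.exp(-x)


# ---------------------------------------------------------------------------
# reciprocal space
# ---------------------------------------------------------------------------

def debye_form_factor(Q: ArrayLike, model: GaussianChainModel) -> ArrayLike:
    """Debye form factor ``F(x) = 2 (exp(-x) - 1 + x) / x^2``, ``x = Q^2 Rg^2``.

    Normalized to ``F(0) = 1``; decays as ``2 / (Q Rg)^2`` at large ``Q``.
    """
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise ValueError("Q must be non-negative")
    x = (Q * model.Rg) ** 2
    out = np.empty_like(x)
    small = x < 1e-4
    xs = x[small]
    out[small] = 1.0 - xs / 3.0 + xs * xs / 12.0 - xs**3 / 60.0
    xl = x[~small]
    out[~small] = 2.0 * (np.expm1(-xl) + xl) / (xl * xl)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# real space
# ---------------------------------------------------------------------------

def gamma_auto_divergent(
    r: ArrayLike, model: GaussianChainModel, normalized: bool = True
) -> ArrayLike:
    """Divergent Gaussian-chain correlation, the inverse Fourier transform
    of the Debye function.

    With ``normalized=True`` (default) the function shares the tail
    normalization of :func:`gamma_auto` (``g(eta/2) / 12``, dimensionless),
    so the two can be compared directly at large separation.  With
    ``normalized=False`` it is the physical spherical inverse Fourier
    transform of :func:`debye_form_factor`,
    ``2 (4 pi Rg^2)^{-3/2} g(eta/2)``, in inverse-volume units.

    Raises
    ------
    DivergenceError
        At ``r = 0``, where the function grows without bound (by design:
        this is the pathology the non-divergent form removes, and a fit
        must never silently consume an infinite model value).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    if np.any(r == 0):
        raise DivergenceError(
            "the divergent Gaussian-chain correlation is unbounded at r = 0; "
            "use gamma_auto for a finite-origin model"
        )
    eta = r / model.Rg
    val = chain_overlap_g(eta / 2.0) / _AUTO_NORM
    if not normalized:
        val = val * _AUTO_NORM * 2.0 * (4.0 * math.pi * model.Rg**2) ** -1.5
    return val if val.ndim else float(val)


def gamma_auto(r: ArrayLike, model: GaussianChainModel) -> ArrayLike:
    """Non-divergent single-chain correlation function, normalized to 1 at the origin.

    ``gamma_auto(eta) = [g(eta/2) - 4 g(2 eta)] / 12`` with ``eta = r/Rg``.
    Finite on ``[0, inf)``, non-negative, decaying like the divergent form
    (``~ exp(-eta^2/4)``) at large separation, with which it agrees to
    better than 1% for ``eta >= 1``.  Below ``eta = 1e-3`` a second-order
    series is used to avoid catastrophic cancellation of the two ``1/eta``
    poles.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    eta = r / model.Rg
    out = np.empty_like(eta)
    small = eta < _SERIES_ETA
    es = eta[small]
    # 12 gamma_auto = 12 - 15 sqrt(pi) eta + 21 eta^2 + O(eta^4)
    out[small] = 1.0 - 1.25 * _SQRT_PI * es + 1.75 * es * es
    el = eta[~small]
    out[~small] = (chain_overlap_g(el / 2.0) - 4.0 * chain_overlap_g(2.0 * el)) / _AUTO_NORM
    return out if out.ndim else float(out)


def gamma_full_prefactor(model: GaussianChainModel, contrast: ContrastSpec) -> float:
    """Contrast/counting prefactor linking :func:`gamma_auto` to the full
    correlation of the labeled melt.

    Chosen so that the Abel projection of ``gamma_full`` at ``z = 0``
    equals the closed form returned by :func:`g_at_zero`:
    ``K = 3 N_c phi(1-phi)(beta_H-beta_D)^2 N^2 / (16 pi^{3/2} Rg^3)``.
    """
    return (
        3.0
        * contrast.N_c
        * contrast.contrast_factor
        * model.N**2
        / (16.0 * math.pi**1.5 * model.Rg**3)
    )


def gamma_full(
    r: ArrayLike, model: GaussianChainModel, contrast: ContrastSpec
) -> ArrayLike:
    """Correlation function of a partially deuterated Gaussian-chain melt,
    ``gamma_full = prefactor * gamma_auto``.

    Vanishes identically when there is no labeling contrast (``phi`` equal
    to 0 or 1, or ``beta_H == beta_D``); maximal at ``phi = 1/2``.
    """
    return gamma_full_prefactor(model, contrast) * gamma_auto(r, model)


# ---------------------------------------------------------------------------
# projection (SESANS) space
# ---------------------------------------------------------------------------

def g0_projected(z: ArrayLike, model: GaussianChainModel) -> ArrayLike:
    """Normalized projected correlation function ``G0(z) = G(z) / G(0)``.

    ``G0(zeta) = [f(c) - f(16 c)] / (4 ln 2)`` with ``c = zeta^2/4``,
    ``zeta = z/Rg`` and ``f(x) = (1+x) E1(x) - exp(-x)``.  Monotonically
    decreasing from 1 at ``z = 0`` to 0; equals the Abel transform of
    :func:`gamma_auto` normalized at zero.  Below ``zeta = 1e-3`` a series
    (including the ``c ln c`` term) replaces the cancellation-prone
    difference of exponential integrals.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be non-negative")
    zeta = z / model.Rg
    c = zeta * zeta / 4.0
    out = np.empty_like(c)
    small = zeta < _SERIES_ETA
    cs = c[small]
    # f(c) - f(16c) = 4 ln2 + c (15 ln c + 64 ln 2 - 30 + 15 EulerGamma) - (255/4) c^2
    lin = 15.0 * np.log(np.where(cs > 0, cs, 1.0)) + 64.0 * _LN2 - 30.0 + 15.0 * np.euler_gamma
    out[small] = 1.0 + (cs * lin - 63.75 * cs * cs) / (4.0 * _LN2)
    out[small & (c == 0)] = 1.0
    cl = c[~small]
    out[~small] = (projection_f(cl) - projection_f(16.0 * cl)) / (4.0 * _LN2)
    return out if out.ndim else float(out)


def g_at_zero(model: GaussianChainModel, contrast: ContrastSpec) -> float:
    """Projected correlation of the labeled melt at zero spin-echo length,

    ``G(0) = N_c phi (1 - phi) (beta_H - beta_D)^2 N^2 ln 2 / (8 pi Rg^2)``.

    This is the Abel transform of :func:`gamma_full` evaluated at the
    origin; it scales as ``N^2`` (coherent intra-chain pairs) and
    ``Rg^{-2}`` (projection of an object of that size).
    """
    return (
        contrast.N_c
        * contrast.contrast_factor
        * model.N**2
        * _LN2
        / (8.0 * math.pi * model.Rg**2)
    )


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def opacity_from_contrast(
    model: GaussianChainModel, contrast: ContrastSpec, instrument: InstrumentSpec
) -> float:
    """Dimensionless scattering opacity of the sample,

    ``Sigma = lambda^2 l n_c phi(1-phi)(beta_H-beta_D)^2 N^2 ln 2 / (8 pi Rg^2)``.

    This collapses every instrument and contrast constant of the
    multiple-scattering exponent into one number: ``P(z) =
    exp[Sigma (G0(z) - 1)]`` and the total scattering probability at
    ``z -> inf`` is ``1 - exp(-Sigma)``.
    """
    return (
        instrument.wavelength**2
        * instrument.thickness
        * contrast.n_c
        * contrast.contrast_factor
        * model.N**2
        * _LN2
        / (8.0 * math.pi * model.Rg**2)
    )


def polarization(
    z: ArrayLike,
    model: GaussianChainModel,
    opacity: Optional[float] = None,
    contrast: Optional[ContrastSpec] = None,
    instrument: Optional[InstrumentSpec] = None,
) -> ArrayLike:
    """Neutron polarization ``P(z) = exp[opacity (G0(z) - 1)]``.

    The exponential form accounts for multiple scattering; expanding to
    first order in ``opacity`` recovers the single-scattering result
    ``1 + opacity (G0(z) - 1)``.  ``P(0) = 1`` exactly and ``P`` saturates
    at ``exp(-opacity)`` for ``z`` much larger than the chain size.

    Either pass ``opacity`` directly, or pass ``contrast`` and
    ``instrument`` to construct it with :func:`opacity_from_contrast`
    (an instrument carrying a nonzero ``opacity`` field is also honored).
    """
    if opacity is None:
        if instrument is None:
            raise ValueError("provide opacity, or instrument (+ contrast)")
        if instrument.opacity > 0 or contrast is None:
            opacity = instrument.opacity
        else:
            opacity = opacity_from_contrast(model, contrast, instrument)
    if opacity < 0:
        raise ValueError("opacity must be >= 0")
    return np.exp(opacity * (g0_projected(z, model) - 1.0))
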