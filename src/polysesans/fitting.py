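"""Nonlinear least-squares extraction of the radius of gyration.

Three single-model fits, one per observable:

* :func:`fit_gamma` -- ``amplitude * gamma_auto(r / Rg)`` against a
  real-space correlation curve;
* :func:`fit_form_factor` -- the Debye function against a form-factor
  curve normalized to 1 at ``Q = 0`` (unit amplitude fixed);
* :func:`fit_sesans` -- the polarization model
  ``exp[opacity (G0(z/Rg) - 1)]`` against a SESANS spectrum, with
  ``Rg`` and ``opacity`` both free.

Weights come from the curve's counting errors when present, otherwise the
fit is unweighted.  Initialization uses the abscissa where the normalized
curve falls to half its zero-extrapolated value (``gamma_auto = 0.5`` at
``eta = 0.2899``, ``G0 = 0.5`` at ``zeta = 0.5005``) or a Guinier-slope
estimate for the form factor; on non-convergence the fit restarts from
0.5x and 2x the initial guess before giving up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np

from .models import GaussianChainModel, debye_form_factor, g0_projected, gamma_auto
from .transforms import Curve

__all__ = ["FitResult", "IdentifiabilityError", "fit_gamma", "fit_form_factor", "fit_sesans"]

# half-value abscissae of the normalized models, used for initialization
_ETA_HALF_GAMMA = 0.2899
_ZETA_HALF_G0 = 0.5005


class IdentifiabilityError(ValueError):
    """The data carry no information about the requested parameters
    (e.g. a flat polarization curve with no scattering signal)."""


@dataclass(frozen=True)
class FitResult:
    """Outcome of a radius-of-gyration fit.

    ``opacity_hat``/``opacity_stderr`` are populated by SESANS fits only.
    ``reduced_chisq`` is meaningful as an absolute goodness-of-fit number
    only for weighted fits.
    """

    Rg_hat: float
    Rg_stderr: float
    amplitude_hat: float
    reduced_chisq: float
    n_points: int
    converged: bool
    opacity_hat: Optional[float] = None
    opacity_stderr: Optional[float] = None
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and not (self.Rg_hat > 0):
            raise ValueError("a converged fit must report Rg_hat > 0")


def _weights(curve: Curve, mask: np.ndarray) -> Optional[np.ndarray]:
    if curve.errors is None:
        return None
    err = curve.errors[mask]
    if np.any(err <= 0):
        # bins with zero counts carry no weight information; give them the
        # median error so they neither dominate nor vanish
        err = np.where(err > 0, err, np.median(err[err > 0]) if np.any(err > 0) else 1.0)
    return 1.0 / err


def _run_fit(fitmodel, params, x, y, weights, rg_name="Rg"):
    """Fit with bounded restarts at 0.5x and 2x the initial Rg."""
    rg0 = params[rg_name].value
    best = None
    for factor in (1.0, 0.5, 2.0):
        params[rg_name].set(value=rg0 * factor)
        try:
            res = fitmodel.fit(y, params, x=x, weights=weights)
        except Exception:  # numerical failure in an lmfit iteration
            continue
        if res.success and np.isfinite(res.params[rg_name].value):
            if best is None or res.chisqr < best.chisqr:
                best = res
    return best


def _half_value_abscissa(grid: np.ndarray, values: np.ndarray, v0: float) -> float:
    """First abscissa where the curve crosses half its origin value."""
    below = np.nonzero(values <= 0.5 * v0)[0]
    if len(below) == 0:
        return float(grid[len(grid) // 2])
    return float(grid[below[0]])


def fit_gamma(
    curve: Curve,
    init: Optional[float] = None,
    r_min: float = 0.0,
    r_max: float = math.inf,
) -> FitResult:
    """Fit ``amplitude * gamma_auto(r; Rg)`` to a correlation curve.

    The amplitude is free (the estimator's absolute normalization need
    not match the model's origin normalization), so the fit never depends
    on an extrapolation of the data to ``r = 0``.  The default window is
    the full positive range of the data; ``r_min``/``r_max`` restrict it.
    """
    if curve.axis != "r":
        raise ValueError(f"expected a curve on axis 'r', got {curve.axis!r}")
    mask = (curve.grid > max(r_min, 0.0)) & (curve.grid <= r_max)
    if mask.sum() < 10:
        raise ValueError("need at least 10 points in the fit window")
    x, y = curve.grid[mask], curve.values[mask]
    if np.any(x <= 0):
        raise ValueError("gamma fits need positive abscissae")
    w = _weights(curve, mask)

    if init is None:
        init = _half_value_abscissa(x, y, curve.value_at_zero() if curve.grid[0] > 0
                                    else y[0]) / _ETA_HALF_GAMMA

    def model_fn(x, amplitude, Rg):
        return amplitude * gamma_auto(x, GaussianChainModel(Rg=Rg, N=100))

    fitmodel = lmfit.Model(model_fn)
    params = fitmodel.make_params(
        amplitude=dict(value=float(y[0] / gamma_auto(x[0], GaussianChainModel(Rg=init, N=100))), min=0),
        Rg=dict(value=float(init), min=1e-12),
    )
    res = _run_fit(fitmodel, params, x, y, w)
    if res is None:
        return FitResult(np.nan, np.nan, np.nan, np.nan, int(mask.sum()), False,
                         message="no restart converged")
    return FitResult(
        Rg_hat=float(res.params["Rg"].value),
        Rg_stderr=float(res.params["Rg"].stderr or np.nan),
        amplitude_hat=float(res.params["amplitude"].value),
        reduced_chisq=float(res.redchi),
        n_points=int(mask.sum()),
        converged=True,
    )


def fit_form_factor(
    curve: Curve,
    init: Optional[float] = None,
    Q_max: float = math.inf,
) -> FitResult:
    """Fit the Debye function to a form-factor curve normalized at zero.

    The amplitude is fixed at 1 (``F(0) = 1`` by construction of the
    estimator and of the model), leaving ``Rg`` as the only parameter.
    """
    if curve.axis != "Q":
        raise ValueError(f"expected a curve on axis 'Q', got {curve.axis!r}")
    mask = (curve.grid > 0) & (curve.grid <= Q_max) & (curve.values > 0)
    if mask.sum() < 10:
        raise ValueError("need at least 10 points in the fit window")
    x, y = curve.grid[mask], curve.values[mask]
    w = _weights(curve, mask)

    if init is None:
        # Guinier-regime estimate: the Debye function passes 0.7 near Q Rg ~ 1.06
        Qg = x[int(np.argmin(np.abs(y - 0.7)))]
        init = 1.06 / Qg if Qg > 0 else 1.0

    def model_fn(x, Rg):
        return debye_form_factor(x, GaussianChainModel(Rg=Rg, N=100))

    fitmodel = lmfit.Model(model_fn)
    params = fitmodel.make_params(Rg=dict(value=float(init), min=1e-12))
    res = _run_fit(fitmodel, params, x, y, w)
    if res is None:
        return FitResult(np.nan, np.nan, 1.0, np.nan, int(mask.sum()), False,
                         message="no restart converged")
    return FitResult(
        Rg_hat=float(res.params["Rg"].value),
        Rg_stderr=float(res.params["Rg"].stderr or np.nan),
        amplitude_hat=1.0,
        reduced_chisq=float(res.redchi),
        n_points=int(mask.sum()),
        converged=True,
    )


def fit_sesans(curve: Curve, init: Optional[float] = None) -> FitResult:
    """Two-parameter fit of the polarization model to a SESANS spectrum.

    ``P(z) = exp[opacity (G0(z/Rg) - 1)]`` with ``Rg`` and ``opacity``
    free; the covariance of both parameters is reported.  Polarization
    values must lie in (0, 1]; a curve identically 1 has no scattering
    signal and raises :class:`IdentifiabilityError`.
    """
    if curve.axis != "z":
        raise ValueError(f"expected a curve on axis 'z', got {curve.axis!r}")
    if np.any(curve.values <= 0) or np.any(curve.values > 1.0 + 1e-9):
        raise ValueError("polarization values must lie in (0, 1]")
    mask = curve.grid > 0
    if mask.sum() < 10:
        raise ValueError("need at least 10 points")
    x, y = curve.grid[mask], curve.values[mask]
    if np.all(y >= 1.0 - 1e-12):
        raise IdentifiabilityError(
            "polarization is identically 1: no scattering signal, Rg and "
            "opacity are unidentifiable"
        )
    w = _weights(curve, mask)

    opacity0 = -math.log(max(y.min(), 1e-12))
    if init is None:
        # G0 = 0.5 where ln P = -opacity/2, i.e. P = sqrt(P_saturation)
        target = math.sqrt(max(y.min(), 1e-12))
        below = np.nonzero(y <= target)[0]
        z_half = float(x[below[0]]) if len(below) else float(x[len(x) // 2])
        init = z_half / _ZETA_HALF_G0

    def model_fn(x, Rg, opacity):
        return np.exp(opacity * (g0_projected(x, GaussianChainModel(Rg=Rg, N=100)) - 1.0))

    fitmodel = lmfit.Model(model_fn)
    params = fitmodel.make_params(
        Rg=dict(value=float(init), min=1e-12),
        opacity=dict(value=float(max(opacity0, 1e-6)), min=0),
    )
    res = _run_fit(fitmodel, params, x, y, w)
    if res is None:
        return FitResult(np.nan, np.nan, np.nan, np.nan, int(mask.sum()), False,
                         message="no restart converged")
    return FitResult(
        Rg_hat=float(res.params["Rg"].value),
        Rg_stderr=float(res.params["Rg"].stderr or np.nan),
        amplitude_hat=1.0,
        reduced_chisq=float(res.redchi),
        n_points=int(mask.sum()),
        converged=True,
        opacity_hat=float(res.params["opacity"].value),
        opacity_stderr=float(res.params["opacity"].stderr or np.nan),
    )
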