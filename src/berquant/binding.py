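"""Four-parameter logistic (Hill) analysis of fluorescence titration curves.

The measured intensity F of a labeled probe titrated with a binding partner
at concentration C is modeled empirically as

    F(C) = F0 + (Finf - F0) / (1 + (EC50 / C)**n)

where F0 is the probe-alone intensity, Finf the intensity at saturation,
EC50 the partner concentration at which F - F0 = (Finf - F0)/2 and n the
Hill coefficient (curve steepness; n > 1 suggests multimeric complexes).
EC50 is read as an apparent equilibrium dissociation constant; when it
falls below the probe concentration it is only an upper limit on the true
Kd (see :mod:`berquant.equilibria` for the exact depletion treatment).

The fitter is exposed both as a scikit-learn style estimator
(:class:`FourParamLogistic`) and as thin functions operating on
:class:`~berquant.curves.TitrationCurve` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .curves import TitrationCurve

__all__ = [
    "four_param_logistic",
    "hill_bound_fraction",
    "FourParamLogistic",
    "FourParamFit",
    "ReplicateSummary",
    "fit_four_parameter",
    "predict_four_parameter",
    "summarize_replicates",
    "dna_affinity_effect",
]

PARAM_NAMES = ("f0", "f_inf", "ec50", "hill_n")


def four_param_logistic(c, f0: float, f_inf: float, ec50: float, hill_n: float):
    """Evaluate the four-parameter logistic model; F(0) = F0 by continuity."""
    c_arr = np.atleast_1d(np.asarray(c, dtype=float))
    out = np.full(c_arr.shape, float(f0))
    pos = c_arr > 0
    with np.errstate(over="ignore", divide="ignore"):
        ratio = (ec50 / c_arr[pos]) ** hill_n
    out[pos] = f0 + (f_inf - f0) / (1.0 + ratio)
    if np.isscalar(c) or np.ndim(c) == 0:
        return float(out[0])
    return out


def hill_bound_fraction(c, ec50: float, hill_n: float):
    """Fractional saturation 1/(1 + (EC50/C)^n) implied by the Hill curve."""
    c_arr = np.atleast_1d(np.asarray(c, dtype=float))
    out = np.zeros(c_arr.shape)
    pos = c_arr > 0
    with np.errstate(over="ignore", divide="ignore"):
        out[pos] = 1.0 / (1.0 + (ec50 / c_arr[pos]) ** hill_n)
    if np.isscalar(c) or np.ndim(c) == 0:
        return float(out[0])
    return out


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for the four-parameter logistic isotherm.

    Parameters
    ----------
    ec50_bounds, hill_bounds:
        Box constraints for the nonlinear least-squares fit. The defaults
        (EC50 in [0.1, 1e5] nM, n in [0.3, 5]) bracket the parameter ranges
        reported for protein-protein titrations of this kind.
    no_binding_fold_threshold:
        Minimum fitted dynamic range Finf/F0 for the curve to count as a
        detected interaction. Below it the fit is flagged
        ``binding_detected_ = False`` (parameters are still stored on the
        estimator; the functional wrapper withholds them).
    weighting:
        "none" (ordinary least squares, the default) or "relative"
        (sigma proportional to intensity, appropriate when well noise is
        multiplicative; gives near-nominal parameter confidence intervals
        under that noise model).
    max_nfev:
        Cap on model evaluations inside the optimizer.

    Attributes
    ----------
    f0_, f_inf_, ec50_, hill_n_ : float
        Fitted parameters (nan when the optimizer failed).
    param_sd_ : dict
        Asymptotic standard deviations from the fit covariance.
    r_squared_ : float
        Coefficient of determination on the fitted points.
    fold_change_ : float
        Finf/F0.
    converged_, binding_detected_ : bool
    message_ : str
        Diagnostic message for non-converged / no-binding outcomes.
    """

    def __init__(
        self,
        ec50_bounds: tuple[float, float] = (0.1, 1e5),
        hill_bounds: tuple[float, float] = (0.3, 5.0),
        no_binding_fold_threshold: float = 1.1,
        weighting: str = "none",
        max_nfev: int = 20000,
    ):
        self.ec50_bounds = ec50_bounds
        self.hill_bounds = hill_bounds
        self.no_binding_fold_threshold = no_binding_fold_threshold
        self.weighting = weighting
        self.max_nfev = max_nfev

    # ------------------------------------------------------------------
    def _initial_guess(self, c: np.ndarray, y: np.ndarray) -> np.ndarray:
        zero = c == 0
        f0 = float(np.mean(y[zero])) if zero.any() else float(np.min(y))
        f_inf = float(np.max(y))
        if f_inf <= f0:
            f_inf = f0 * 1.05
        half = 0.5 * (f0 + f_inf)
        pos = c > 0
        cp, yp = c[pos], y[pos]
        ec50 = float(np.exp(np.mean(np.log(cp))))  # fallback: geometric mean
        above = np.nonzero(yp >= half)[0]
        if above.size and above[0] > 0:
            i = above[0]
            c0, c1 = cp[i - 1], cp[i]
            y0, y1 = yp[i - 1], yp[i]
            if y1 != y0:
                ec50 = float(c0 + (half - y0) * (c1 - c0) / (y1 - y0))
        elif above.size:
            ec50 = float(cp[above[0]])
        lo_e, hi_e = self.ec50_bounds
        ec50 = float(np.clip(ec50, lo_e, hi_e))
        return np.array([f0, f_inf, ec50, 1.0])

    def fit(self, X, y):
        """Fit the isotherm to concentrations ``X`` (nM) and intensities ``y``."""
        c = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if c.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if c.size < 6:
            raise ValueError(
                f"at least 6 titration points are required for fitting, got {c.size}"
            )
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(y)) or np.any(y <= 0):
            raise ValueError("intensities must be positive and finite")

        p0 = self._initial_guess(c, y)
        y_hi = 10.0 * float(np.max(y))
        lower = [1e-9, 1e-9, self.ec50_bounds[0], self.hill_bounds[0]]
        upper = [y_hi, y_hi, self.ec50_bounds[1], self.hill_bounds[1]]
        p0 = np.clip(p0, lower, upper)

        if self.weighting not in ("none", "relative"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        sigma = y if self.weighting == "relative" else None
        self.n_points_ = int(c.size)
        try:
            popt, pcov = curve_fit(
                four_param_logistic,
                c,
                y,
                p0=p0,
                sigma=sigma,
                bounds=(lower, upper),
                max_nfev=self.max_nfev,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            self.converged_ = True
            self.message_ = "converged"
        except RuntimeError as exc:  # optimizer failure is a flagged result
            popt = np.full(4, np.nan)
            pcov = np.full((4, 4), np.nan)
            self.converged_ = False
            self.message_ = f"fit did not converge: {exc}"

        self.f0_, self.f_inf_, self.ec50_, self.hill_n_ = (float(v) for v in popt)
        with np.errstate(invalid="ignore"):
            sd = np.sqrt(np.diag(pcov))
        self.param_sd_ = dict(zip(PARAM_NAMES, (float(s) for s in sd)))
        if self.converged_:
            resid = y - four_param_logistic(c, *popt)
            ss_res = float(np.sum(resid**2))
            ss_tot = float(np.sum((y - np.mean(y)) ** 2))
            self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            self.sse_ = ss_res
            self.fold_change_ = self.f_inf_ / self.f0_
            self.binding_detected_ = self.fold_change_ >= self.no_binding_fold_threshold
            if not self.binding_detected_:
                self.message_ = (
                    "no binding detected: fitted dynamic range "
                    f"Finf/F0 = {self.fold_change_:.3f} is below the "
                    f"threshold {self.no_binding_fold_threshold}"
                )
        else:
            self.r_squared_ = np.nan
            self.sse_ = np.nan
            self.fold_change_ = np.nan
            self.binding_detected_ = False
        return self

    def predict(self, X):
        c = np.asarray(X, dtype=float).reshape(-1)
        return four_param_logistic(c, self.f0_, self.f_inf_, self.ec50_, self.hill_n_)


@dataclass(frozen=True)
class FourParamFit:
    """Result of fitting one titration curve.

    When ``binding_detected`` is False the model parameters are withheld
    (nan) and only the diagnostics are populated.
    """

    f0: float
    f_inf: float
    ec50: float  # nM
    hill_n: float
    r_squared: float
    param_sd: dict
    fold_change: float
    converged: bool
    binding_detected: bool
    n_points: int
    sse: float
    message: str = "converged"

    @property
    def ok(self) -> bool:
        return self.converged and self.binding_detected

    def predict(self, c):
        return four_param_logistic(c, self.f0, self.f_inf, self.ec50, self.hill_n)

    def bound_fraction(self, c):
        return hill_bound_fraction(c, self.ec50, self.hill_n)


def fit_four_parameter(
    curve: TitrationCurve,
    *,
    ec50_bounds: tuple[float, float] = (0.1, 1e5),
    hill_bounds: tuple[float, float] = (0.3, 5.0),
    no_binding_fold_threshold: float = 1.1,
    weighting: str = "none",
) -> FourParamFit:
    """Fit the four-parameter logistic model to a titration curve.

    Replicate wells are averaged per concentration before fitting; the
    zero-concentration point participates through F(0) = F0. Curves lacking
    a zero point or with fewer than 6 points are refused.
    """
    if not curve.has_zero_point:
        raise ValueError(
            "the curve must start with a zero-concentration point (defines F0)"
        )
    if curve.n_points < 6:
        raise ValueError(
            f"at least 6 titration points are required, got {curve.n_points}"
        )
    est = FourParamLogistic(
        ec50_bounds=ec50_bounds,
        hill_bounds=hill_bounds,
        no_binding_fold_threshold=no_binding_fold_threshold,
        weighting=weighting,
    ).fit(curve.concentrations, curve.mean_intensities)
    withhold = est.converged_ and not est.binding_detected_
    nan = float("nan")
    return FourParamFit(
        f0=nan if withhold else est.f0_,
        f_inf=nan if withhold else est.f_inf_,
        ec50=nan if withhold else est.ec50_,
        hill_n=nan if withhold else est.hill_n_,
        r_squared=est.r_squared_,
        param_sd={k: (nan if withhold else v) for k, v in est.param_sd_.items()},
        fold_change=est.fold_change_,
        converged=est.converged_,
        binding_detected=est.binding_detected_,
        n_points=est.n_points_,
        sse=est.sse_,
        message=est.message_,
    )


def predict_four_parameter(fit: FourParamFit, c) -> np.ndarray:
    """Evaluate a fitted model on a concentration grid (nM)."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentrations must be non-negative")
    return fit.predict(c)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +/- SD of one fitted parameter across independent experiments.

    The SD is withheld (None) when only a single experiment is available,
    matching the convention of reporting mean +/- SD of >= 2 replicates.
    """

    parameter: str
    mean: float
    sd: Optional[float]
    n_replicates: int


def summarize_replicates(
    fits: Iterable[FourParamFit],
    parameters: Sequence[str] = ("ec50", "hill_n", "f0", "f_inf", "fold_change"),
) -> dict[str, ReplicateSummary]:
    """Summarize fitted parameters over independent-experiment fits.

    Only converged fits with detected binding contribute. Raises if none do.
    """
    usable = [f for f in fits if f.ok]
    if not usable:
        raise ValueError("no converged fits with detected binding to summarize")
    out: dict[str, ReplicateSummary] = {}
    for name in parameters:
        vals = np.array([getattr(f, name) for f in usable], dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else None
        out[name] = ReplicateSummary(
            parameter=name, mean=float(np.mean(vals)), sd=sd, n_replicates=vals.size
        )
    return out


def dna_affinity_effect(ec50_with_dna: float, ec50_without_dna: float) -> float:
    """Fold effect of a DNA cofactor on binding affinity.

    Ratio EC50(+DNA) / EC50(-DNA): values > 1 mean the DNA weakens the
    protein-protein interaction, < 1 that it strengthens it.
    """
    if ec50_with_dna <= 0 or ec50_without_dna <= 0:
        raise ValueError("EC50 values must be positive")
    return float(ec50_with_dna) / float(ec50_without_dna)
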