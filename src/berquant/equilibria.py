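"""Exact equilibrium-binding models: 1:1 with ligand depletion, competition.

These closed-form / root-found solutions serve as thermodynamic references
for the empirical logistic fits. In a titration at probe concentration Ptot
comparable to Kd, the measured half-saturation concentration exceeds Kd
(floor at Ptot/2), so an EC50 below the probe concentration only bounds the
true Kd from above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "exact_complex",
    "exact_bound_fraction",
    "apparent_ec50",
    "BindingSystem",
    "CompetitionSystem",
    "CompetitionSolution",
    "solve_competition",
]


def exact_complex(kd: float, probe_total: float, partner_total: float) -> float:
    """Equilibrium 1:1 complex concentration (nM) from the mass balance.

    Solves [PX]^2 - (Ptot + Xtot + Kd) [PX] + Ptot Xtot = 0 taking the
    physical root, using the conjugate form 2 Ptot Xtot / (b + sqrt(b^2 -
    4 Ptot Xtot)) which is numerically stable at small Kd.
    """
    if kd < 0 or probe_total < 0 or partner_total < 0:
        raise ValueError("Kd and totals must be non-negative")
    if probe_total == 0 or partner_total == 0:
        return 0.0
    b = probe_total + partner_total + kd
    disc = b * b - 4.0 * probe_total * partner_total
    disc = max(disc, 0.0)
    return 2.0 * probe_total * partner_total / (b + np.sqrt(disc))


def exact_bound_fraction(kd: float, probe_total: float, partner_total: float) -> float:
    """Fraction of the probe in complex, [PX]/Ptot, in [0, 1]."""
    if probe_total < 0:
        raise ValueError("probe_total must be non-negative")
    if probe_total == 0:
        return 0.0
    return exact_complex(kd, probe_total, partner_total) / probe_total


def apparent_ec50(kd: float, probe_total: float) -> float:
    """Partner concentration at which the exact isotherm is half-saturated.

    Found by root-finding on the exact 1:1 bound fraction (saturating value
    1); analytically this equals Kd + Ptot/2, so the apparent EC50 always
    lies at or above max(Kd, Ptot/2) and converges to Kd as the probe is
    diluted away.
    """
    if kd < 0:
        raise ValueError("Kd must be non-negative")
    if probe_total <= 0:
        raise ValueError("probe_total must be positive")
    target = 0.5  # half of the saturating bound fraction (which is 1)
    hi = 4.0 * (kd + probe_total) + 1.0
    f = lambda x: exact_bound_fraction(kd, probe_total, x) - target
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-15, hi, xtol=1e-12, rtol=1e-14))


@dataclass(frozen=True)
class BindingSystem:
    """A single probe/partner binding system used to predict fluorescence.

    ``mode`` selects between the empirical Hill curve ("empirical-4PL",
    which uses ``hill_n``) and the exact depletion-aware 1:1 isotherm
    ("exact-1:1", which ignores it). Fluorescence is a linear combination
    of free-probe and complex concentrations with per-nM coefficients.
    """

    kd: float  # nM; read as EC50 in empirical mode
    probe_total: float  # nM
    mode: str = "exact-1:1"
    hill_n: float = 1.0
    coeff_free: float = 2.5  # a.u. per nM free probe
    coeff_complex: float = 5.5  # a.u. per nM complex

    def __post_init__(self) -> None:
        if self.mode not in ("exact-1:1", "empirical-4PL"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.kd <= 0 or self.probe_total <= 0:
            raise ValueError("kd and probe_total must be positive")
        if self.coeff_free < 0 or self.coeff_complex < 0:
            raise ValueError("fluorescence coefficients must be non-negative")

    def bound_fraction(self, partner_total) -> np.ndarray:
        x = np.atleast_1d(np.asarray(partner_total, dtype=float))
        if self.mode == "exact-1:1":
            fb = np.array(
                [exact_bound_fraction(self.kd, self.probe_total, xi) for xi in x]
            )
        else:
            from .binding import hill_bound_fraction

            fb = hill_bound_fraction(x, self.kd, self.hill_n)
        return fb

    def fluorescence(self, partner_total) -> np.ndarray:
        """Predicted intensity versus partner concentration (a.u.)."""
        fb = self.bound_fraction(partner_total)
        bound = self.probe_total * fb
        free = self.probe_total - bound
        return self.coeff_free * free + self.coeff_complex * bound


@dataclass(frozen=True)
class CompetitionSystem:
    """Probe P shared between two partners X and Y with independent 1:1 sites.

    Models a displacement titration: Y is present at a fixed total
    concentration while X is titrated over ``partner_x_totals``.
    """

    probe_total: float  # nM
    partner_x_totals: tuple[float, ...]  # nM grid
    partner_y_total: float  # nM
    kd_px: float  # nM
    kd_py: float  # nM
    coeff_p: float = 2.5  # a.u. per nM free probe
    coeff_px: float = 5.5
    coeff_py: float = 4.0

    def __post_init__(self) -> None:
        if self.probe_total <= 0 or self.partner_y_total < 0:
            raise ValueError("totals must be positive (Y total may be 0)")
        if self.kd_px <= 0 or self.kd_py <= 0:
            raise ValueError("dissociation constants must be positive")
        xs = tuple(float(x) for x in self.partner_x_totals)
        if any(x < 0 for x in xs):
            raise ValueError("partner X totals must be non-negative")
        object.__setattr__(self, "partner_x_totals", xs)


@dataclass(frozen=True)
class CompetitionSolution:
    """Species concentrations (nM) along the X titration, plus fluorescence."""

    partner_x_totals: np.ndarray
    free_p: np.ndarray
    free_x: np.ndarray
    free_y: np.ndarray
    complex_px: np.ndarray
    complex_py: np.ndarray
    fluorescence: np.ndarray
    max_relative_residual: float


def _solve_free_probe(pt: float, xt: float, yt: float, k1: float, k2: float) -> float:
    """Free [P] from the coupled mass-action equilibria via 1-D root finding.

    Substituting the X and Y balances gives the strictly increasing
    conservation function
        g(p) = p * (1 + Xt/(K1 + p) + Yt/(K2 + p)) - Ptot
    with a unique root in (0, Ptot].
    """
    g = lambda p: p * (1.0 + xt / (k1 + p) + yt / (k2 + p)) - pt
    return float(brentq(g, 0.0, pt, xtol=1e-16, rtol=8.9e-16, maxiter=200))


def solve_competition(system: CompetitionSystem) -> CompetitionSolution:
    """Solve the two-partner competition equilibrium on the X grid.

    Conservation of P, X and Y is verified to a relative residual of 1e-10;
    failure raises with the offending concentration named.
    """
    pt, yt = system.probe_total, system.partner_y_total
    k1, k2 = system.kd_px, system.kd_py
    xs = np.asarray(system.partner_x_totals, dtype=float)
    p = np.empty_like(xs)
    px = np.empty_like(xs)
    py = np.empty_like(xs)
    fx = np.empty_like(xs)
    fy = np.empty_like(xs)
    worst = 0.0
    for i, xt in enumerate(xs):
        pf = _solve_free_probe(pt, xt, yt, k1, k2)
        xf = xt * k1 / (k1 + pf)
        yf = yt * k2 / (k2 + pf)
        cpx = pf * xf / k1
        cpy = pf * yf / k2
        res_p = abs(pf + cpx + cpy - pt) / pt
        res_x = abs(xf + cpx - xt) / xt if xt > 0 else 0.0
        res_y = abs(yf + cpy - yt) / yt if yt > 0 else 0.0
        res = max(res_p, res_x, res_y)
        worst = max(worst, res)
        if res > 1e-10:
            raise RuntimeError(
                "competition equilibrium did not converge at "
                f"Xtot = {xt} nM (relative residual {res:.2e})"
            )
        p[i], px[i], py[i], fx[i], fy[i] = pf, cpx, cpy, xf, yf
    fluo = system.coeff_p * p + system.coeff_px * px + system.coeff_py * py
    return CompetitionSolution(
        partner_x_totals=xs,
        free_p=p,
        free_x=fx,
        free_y=fy,
        complex_px=px,
        complex_py=py,
        fluorescence=fluo,
        max_relative_residual=worst,
    )
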