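"""Synthetic plate-reader and light-scattering data generators.

The generators emulate the study design the analyses assume: a 40 nM
fluorescein-labeled probe titrated in duplicate wells against a partner on
a 12-point log-spaced grid from 1 to 1000 nM plus a zero-concentration
point, with multiplicative Gaussian well noise (default CV 2%) and an
optional additive floor. FRET designs add the acceptor-only and
donor+acceptor series with acceptor bleed-through into the donor channel.
Every generator returns the ground truth next to the data, and identical
configurations with identical seeds produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binding import four_param_logistic, hill_bound_fraction
from .curves import TitrationCurve
from .fret import FretExperiment
from .hydro import HydroParticle, diffusion_from_rh, ellipsoid_rh

__all__ = [
    "default_grid",
    "SyntheticConfig",
    "generate_titration",
    "generate_fret_triplet",
    "generate_dna_pair",
    "generate_hydro_observations",
]


def default_grid() -> tuple[float, ...]:
    """Zero plus 12 log-spaced partner concentrations from 1 to 1000 nM."""
    return (0.0, *np.logspace(0.0, 3.0, 12))


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth, design grid and noise model for one synthetic condition.

    The binding ground truth is the four-parameter logistic quadruple
    (f0, fold_change, ec50, hill_n); the FRET ground truth adds the true
    transfer efficiency ``e_true`` and the acceptor bleed-through
    coefficient. Noise is multiplicative Gaussian with coefficient of
    variation ``cv`` plus an additive Gaussian floor of SD ``additive_sd``
    (default 0 a.u.).
    """

    ec50: float = 120.0  # nM
    hill_n: float = 1.8
    f0: float = 100.0  # a.u.
    fold_change: float = 2.2  # Finf/F0
    e_true: Optional[float] = None
    bleed: float = 0.2  # acceptor signal fraction bleeding into donor channel
    acceptor_amplitude: float = 100.0  # a.u. at full acceptor saturation
    concentrations: tuple[float, ...] = field(default_factory=default_grid)
    replicates: int = 2
    probe_total: float = 40.0  # nM
    cv: float = 0.02
    additive_sd: float = 0.0  # a.u.
    n_experiments: int = 3
    seed: Optional[int] = None
    probe_name: str = "probe"
    partner_name: str = "partner"
    dna_context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill_n <= 0 or self.f0 <= 0:
            raise ValueError("ec50, hill_n and f0 must be positive")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.e_true is not None and not 0.0 <= self.e_true < 1.0:
            raise ValueError(f"e_true must lie in [0, 1), got {self.e_true}")
        if self.bleed < 0 or self.acceptor_amplitude < 0:
            raise ValueError("bleed and acceptor amplitude must be >= 0")
        grid = tuple(float(c) for c in self.concentrations)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("concentration grid must be strictly increasing")
        object.__setattr__(self, "concentrations", grid)
        if self.replicates < 1 or self.n_experiments < 1:
            raise ValueError("replicates and n_experiments must be >= 1")
        if self.cv < 0 or self.additive_sd < 0 or self.probe_total <= 0:
            raise ValueError("invalid noise/probe parameters")

    @property
    def f_inf(self) -> float:
        return self.f0 * self.fold_change

    def ground_truth(self) -> dict:
        """Serializable record of the generating parameters."""
        return {
            "f0": self.f0,
            "f_inf": self.f_inf,
            "ec50": self.ec50,
            "hill_n": self.hill_n,
            "fold_change": self.fold_change,
            "e_true": self.e_true,
            "bleed": self.bleed,
            "cv": self.cv,
            "additive_sd": self.additive_sd,
            "probe_total": self.probe_total,
            "replicates": self.replicates,
            "seed": self.seed,
        }


def _resolve_rng(config: SyntheticConfig, rng) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(config.seed)
    return rng


def _noisy_wells(
    rng: np.random.Generator, clean: np.ndarray, config: SyntheticConfig
) -> np.ndarray:
    """Per-well intensities: clean * (1 + N(0, cv)) + N(0, additive_sd)."""
    shape = (clean.size, config.replicates)
    vals = clean[:, None] * (1.0 + rng.normal(0.0, config.cv, shape)) if config.cv > 0 \
        else np.repeat(clean[:, None], config.replicates, axis=1).astype(float)
    if config.additive_sd > 0:
        vals = vals + rng.normal(0.0, config.additive_sd, shape)
    return vals


def _curve_from_wells(
    config: SyntheticConfig, wells: np.ndarray, series_label: str
) -> TitrationCurve:
    return TitrationCurve.from_measurements(
        config.concentrations,
        [tuple(row) for row in wells],
        probe_name=config.probe_name,
        partner_name=config.partner_name,
        probe_concentration=config.probe_total,
        dna_context=config.dna_context,
        series_label=series_label,
    )


def generate_titration(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> tuple[TitrationCurve, dict]:
    """One plain titration curve plus its ground-truth record."""
    rng = _resolve_rng(config, rng)
    c = np.asarray(config.concentrations)
    clean = four_param_logistic(c, config.f0, config.f_inf, config.ec50, config.hill_n)
    wells = _noisy_wells(rng, clean, config)
    return _curve_from_wells(config, wells, "plain"), config.ground_truth()


def generate_fret_triplet(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> tuple[FretExperiment, dict]:
    """A matched three-series FRET experiment plus ground truth.

    Series (i) is the donor logistic curve Fd(C); series (ii) is the
    acceptor bleed-through bleed * A * f_bound(C); series (iii) is
    Fd(C) * (1 - E_true * f_bound(C)) plus the series-(ii) signal, so the
    correction/efficiency pipeline applied to noise-free output returns
    E_true exactly.
    """
    if config.e_true is None:
        raise ValueError("config.e_true must be set for a FRET triplet")
    rng = _resolve_rng(config, rng)
    c = np.asarray(config.concentrations)
    fd = four_param_logistic(c, config.f0, config.f_inf, config.ec50, config.hill_n)
    fb = hill_bound_fraction(c, config.ec50, config.hill_n)
    fa = config.bleed * config.acceptor_amplitude * fb
    fda_raw = fd * (1.0 - config.e_true * fb) + fa
    series = {}
    for label, clean in (("d", fd), ("a", fa), ("da", fda_raw)):
        if label == "a":
            # acceptor-only wells may be exactly zero at C=0; keep them
            # strictly positive for the intensity invariant
            clean = np.maximum(clean, 1e-6)
        wells = _noisy_wells(rng, clean, config)
        wells = np.maximum(wells, 1e-9)
        series[label] = _curve_from_wells(config, wells, label)
    exp = FretExperiment(
        series_d=series["d"], series_a=series["a"], series_da=series["da"]
    )
    return exp, config.ground_truth()


def generate_dna_pair(
    config: SyntheticConfig,
    affinity_ratio: float,
    delta_e: float = 0.0,
    dna_context: str = "gap-DNA",
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, FretExperiment], dict]:
    """Paired FRET experiments without and with a DNA cofactor.

    The minus-DNA arm uses the base parameters; the plus-DNA arm scales the
    EC50 by ``affinity_ratio`` and shifts the true efficiency by
    ``delta_e``. Both arms draw independent noise from one seeded stream.
    """
    if affinity_ratio <= 0:
        raise ValueError("affinity_ratio must be positive")
    if config.e_true is None:
        raise ValueError("config.e_true must be set for a DNA pair")
    e_plus = config.e_true + delta_e
    if not 0.0 <= e_plus < 1.0:
        raise ValueError(
            f"plus-DNA efficiency {e_plus:.3f} falls outside [0, 1)"
        )
    rng = _resolve_rng(config, rng)
    minus_cfg = replace(config, dna_context=None)
    plus_cfg = replace(
        config,
        ec50=config.ec50 * affinity_ratio,
        e_true=e_plus,
        dna_context=dna_context,
    )
    minus, _ = generate_fret_triplet(minus_cfg, rng)
    plus, _ = generate_fret_triplet(plus_cfg, rng)
    truth = {
        "minus": minus_cfg.ground_truth(),
        "plus": plus_cfg.ground_truth(),
        "affinity_ratio": affinity_ratio,
        "delta_e": delta_e,
        "dna_context": dna_context,
    }
    return {"minus": minus, "plus": plus}, truth


def generate_hydro_observations(
    particles: Sequence[tuple[str, HydroParticle]],
    cv: float = 0.05,
    seed: Optional[int] = None,
    temperature: float = 297.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Noisy diffusion-coefficient and Mw observations for labeled particles.

    For each (label, particle) the true R_H comes from the ellipsoid model,
    D from the inverted Stokes-Einstein relation; D and Mw are perturbed
    multiplicatively with coefficient of variation ``cv``.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for label, particle in particles:
        rh = ellipsoid_rh(particle)
        d_true = diffusion_from_rh(rh, temperature=temperature)
        d_obs = d_true * (1.0 + rng.normal(0.0, cv)) if cv > 0 else d_true
        mw_obs = (
            particle.molar_mass * (1.0 + rng.normal(0.0, cv))
            if cv > 0
            else particle.molar_mass
        )
        rows.append(
            {
                "label": label,
                "true_rh_nm": rh,
                "true_mw_kda": particle.molar_mass,
                "d_m2_per_s": d_obs,
                "observed_mw_kda": mw_obs,
                "temperature_k": temperature,
            }
        )
    return pd.DataFrame(rows)
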