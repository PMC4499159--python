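"""Containers for fluorescence titration series.

A titration series records the fluorescence intensity of a fixed
concentration of a fluorescein-labeled probe protein as a function of the
concentration of an unlabeled (or acceptor-labeled) binding partner.
Measurements are performed in replicate wells; the zero-concentration wells
define the probe-alone intensity F0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: DNA contexts treated as categorical labels for model BER intermediates.
DNA_CONTEXTS = (None, "AP-DNA", "incised AP-DNA", "gap-DNA", "nick-DNA")

#: Series labels used in plate files: plain titration, donor-only (d),
#: acceptor-only (a) and donor+acceptor (da) series of a FRET design.
SERIES_LABELS = ("plain", "d", "a", "da")


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: partner concentration plus replicate intensities."""

    partner_concentration: float  # nM
    intensities: tuple[float, ...]  # a.u., one entry per replicate well

    def __post_init__(self) -> None:
        if self.partner_concentration < 0:
            raise ValueError(
                f"partner concentration must be non-negative, got "
                f"{self.partner_concentration}"
            )
        vals = tuple(float(v) for v in self.intensities)
        if len(vals) < 1:
            raise ValueError("at least one replicate intensity is required")
        if any(v <= 0 or not np.isfinite(v) for v in vals):
            raise ValueError(f"intensities must be positive and finite, got {vals}")
        object.__setattr__(self, "intensities", vals)

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities))


@dataclass
class TitrationCurve:
    """An ordered titration series for one probe/partner/DNA-context condition.

    Concentrations must be strictly increasing; duplicate wells at the same
    concentration should be pooled into one :class:`TitrationPoint`
    (see :meth:`from_measurements`).
    """

    probe_name: str
    partner_name: str
    points: Sequence[TitrationPoint]
    probe_concentration: float = 40.0  # nM
    dna_context: Optional[str] = None
    series_label: str = "plain"

    def __post_init__(self) -> None:
        if self.probe_concentration <= 0:
            raise ValueError("probe concentration must be positive")
        if self.dna_context not in DNA_CONTEXTS:
            raise ValueError(
                f"unknown dna_context {self.dna_context!r}; expected one of "
                f"{DNA_CONTEXTS}"
            )
        if self.series_label not in SERIES_LABELS:
            raise ValueError(
                f"unknown series_label {self.series_label!r}; expected one of "
                f"{SERIES_LABELS}"
            )
        self.points = tuple(self.points)
        if len(self.points) < 1:
            raise ValueError("a titration curve needs at least one point")
        conc = self.concentrations
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    @classmethod
    def from_measurements(
        cls,
        concentrations: Sequence[float],
        intensities: Sequence[Sequence[float]] | np.ndarray,
        **kwargs,
    ) -> "TitrationCurve":
        """Build a curve from parallel arrays, pooling duplicate concentrations.

        ``intensities[i]`` holds the replicate intensities for
        ``concentrations[i]``; wells repeated at the same concentration are
        merged into one point.
        """
        pooled: dict[float, list[float]] = {}
        for c, vals in zip(concentrations, intensities, strict=True):
            pooled.setdefault(float(c), []).extend(float(v) for v in np.atleast_1d(vals))
        points = [
            TitrationPoint(c, tuple(pooled[c])) for c in sorted(pooled)
        ]
        return cls(points=points, **kwargs)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.partner_concentration for p in self.points], dtype=float)

    @property
    def mean_intensities(self) -> np.ndarray:
        return np.array([p.mean_intensity for p in self.points], dtype=float)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def has_zero_point(self) -> bool:
        return self.points[0].partner_concentration == 0.0

    def key(self) -> tuple:
        """Grouping key (probe, partner, dna_context) ignoring series label."""
        return (self.probe_name, self.partner_name, self.dna_context)
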