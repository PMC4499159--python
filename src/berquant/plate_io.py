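"""Reading and writing the long-format plate CSV and hydrodynamics TSV.

Plate CSV dialect: comma-separated, UTF-8, '.' decimal, required header

    probe,probe_conc_nM,partner,dna_context,series,concentration_nM,replicate,intensity

One row per well. ``series`` is one of plain/d/a/da; the three series of a
FRET experiment share (probe, partner, dna_context). ``dna_context`` is
empty for no DNA. Units are embedded in column names: concentrations in
nM, intensities in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .curves import TitrationCurve
from .fret import FretExperiment

__all__ = [
    "PLATE_COLUMNS",
    "PlateData",
    "write_plate_csv",
    "read_plate_csv",
    "read_hydro_tsv",
]

PLATE_COLUMNS = (
    "probe",
    "probe_conc_nM",
    "partner",
    "dna_context",
    "series",
    "concentration_nM",
    "replicate",
    "intensity",
)

_NUMERIC = ("probe_conc_nM", "concentration_nM", "intensity")


@dataclass
class PlateData:
    """Parsed plate file: plain titration curves and assembled FRET designs."""

    curves: list[TitrationCurve] = field(default_factory=list)
    fret_experiments: list[FretExperiment] = field(default_factory=list)

    def __iter__(self):
        return iter(self.curves)


def _curve_rows(curve: TitrationCurve) -> Iterable[dict]:
    for point in curve.points:
        for rep, intensity in enumerate(point.intensities, start=1):
            yield {
                "probe": curve.probe_name,
                "probe_conc_nM": curve.probe_concentration,
                "partner": curve.partner_name,
                "dna_context": curve.dna_context or "",
                "series": curve.series_label,
                "concentration_nM": point.partner_concentration,
                "replicate": rep,
                "intensity": intensity,
            }


def write_plate_csv(
    items: Sequence[Union[TitrationCurve, FretExperiment]],
    path: Union[str, Path],
) -> None:
    """Write curves and/or FRET experiments as a long-format plate CSV."""
    rows: list[dict] = []
    for item in items:
        if isinstance(item, FretExperiment):
            for series in (item.series_d, item.series_a, item.series_da):
                rows.extend(_curve_rows(series))
        else:
            rows.extend(_curve_rows(item))
    if not rows:
        raise ValueError("nothing to write")
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_plate_csv(path: Union[str, Path]) -> PlateData:
    """Read and validate a plate CSV, grouping wells into titration curves.

    Wells are pooled by concentration inside each (probe, partner,
    dna_context, series) group and sorted; groups carrying the d, a and da
    series are assembled into :class:`FretExperiment` objects. Malformed
    numeric cells are reported with their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"plate file {path} lacks required columns {missing}")
    if raw.empty:
        raise ValueError(f"plate file {path} contains no data rows")

    def _exact_float(s: str) -> float:
        # Python float() is correctly rounded, unlike pandas' fast parser,
        # so write -> read round-trips bit-exactly.
        try:
            return float(s)
        except ValueError:
            return np.nan

    df = raw.copy()
    bad_lines: list[str] = []
    for col in _NUMERIC:
        stripped = raw[col].str.strip()
        converted = stripped.map(_exact_float)
        bad = converted.isna() | (stripped == "")
        for idx in df.index[bad]:
            # +2: header line plus 1-based numbering
            bad_lines.append(
                f"line {idx + 2}: column {col!r} has non-numeric value "
                f"{raw.at[idx, col]!r}"
            )
        df[col] = converted
    if bad_lines:
        raise ValueError(
            f"malformed plate file {path}:\n  " + "\n  ".join(bad_lines)
        )

    df["dna_context"] = df["dna_context"].replace("", None)
    curves: list[TitrationCurve] = []
    by_condition: dict[tuple, dict[str, TitrationCurve]] = {}
    group_cols = ["probe", "partner", "dna_context", "series", "probe_conc_nM"]
    for (probe, partner, dna, series, probe_conc), grp in df.groupby(
        group_cols, dropna=False, sort=True
    ):
        dna = None if (dna is None or (isinstance(dna, float) and np.isnan(dna))) else dna
        # deterministic well order regardless of row order in the file
        grp = grp.sort_values(["concentration_nM", "replicate", "intensity"])
        pooled = grp.groupby("concentration_nM")["intensity"].apply(list)
        curve = TitrationCurve.from_measurements(
            pooled.index.to_numpy(),
            pooled.to_list(),
            probe_name=probe,
            partner_name=partner,
            probe_concentration=float(probe_conc),
            dna_context=dna,
            series_label=series,
        )
        if series == "plain":
            curves.append(curve)
        else:
            by_condition.setdefault((probe, partner, dna), {})[series] = curve

    fret: list[FretExperiment] = []
    for key, series_map in sorted(
        by_condition.items(), key=lambda kv: tuple(str(k) for k in kv[0])
    ):
        missing_series = {"d", "a", "da"} - set(series_map)
        if missing_series:
            raise ValueError(
                f"FRET experiment {key} is missing series {sorted(missing_series)}"
            )
        fret.append(
            FretExperiment(
                series_d=series_map["d"],
                series_a=series_map["a"],
                series_da=series_map["da"],
            )
        )
    return PlateData(curves=curves, fret_experiments=fret)


def read_hydro_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a hydrodynamics observation table (TSV).

    Requires a ``label`` column and at least one of ``d_m2_per_s`` /
    ``observed_mw_kda``; an optional ``temperature_k`` column defaults to
    297 K.
    """
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise ValueError("hydro table needs a 'label' column")
    if not ({"d_m2_per_s", "observed_mw_kda"} & set(df.columns)):
        raise ValueError(
            "hydro table needs a 'd_m2_per_s' and/or 'observed_mw_kda' column"
        )
    if "temperature_k" not in df.columns:
        df["temperature_k"] = 297.0
    return df
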