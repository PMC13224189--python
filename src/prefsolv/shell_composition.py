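"""Model-free first-solvation-shell composition.

In the simplest approach the local mole fraction of cosolvent S2 in the
first shell is read directly off the measured transition energy,

    x2s = (E_T - E_T1) / (E_T2 - E_T1),

and the preferential-solvation parameter is the local-minus-bulk excess

    delta_s2 = x2s - x2.

delta_s2 > 0 means the cosolvent S2 is enriched around the solute;
delta_s2 < 0 means the base solvent S1 is preferred.  x2s can fall outside
[0, 1] for synergistic mixtures whose E_T exceeds both pure-solvent
values; such points are flagged, never clipped, so synergism stays
visible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .core_types import TitrationSeries, deviation_from_ideal
from .errors import DegenerateEndpointsError

#: Endpoint energies closer than this (kcal/mol) give an unusable composition scale.
_ENDPOINT_TOL = 1e-12


@dataclass(frozen=True)
class ShellPoint:
    """Shell composition at one bulk composition."""

    x2_bulk: float
    x2s: float
    delta_s2: float
    in_range: bool  # False when x2s falls outside [0, 1] (synergism)


@dataclass(frozen=True)
class ShellSeriesResult:
    """Per-point shell compositions plus grid-level summaries.

    Extrema are taken over the measured grid only (no interpolation of the
    isotherm); sign crossings of delta_s2 are located by linear
    interpolation between the two bracketing grid points.
    """

    mixture_name: str
    points: tuple[ShellPoint, ...]
    delta_max: tuple[float, float]  # (x2 at max, delta_s2 max)
    delta_min: tuple[float, float]
    sign_crossings: tuple[float, ...]


def shell_mole_fraction_simple(et, et1: float, et2: float):
    """Local S2 mole fraction from a measured energy and the pure-solvent scale.

    Raises :class:`~prefsolv.errors.DegenerateEndpointsError` when
    ``et1 == et2`` (the indicator cannot distinguish the solvents).  Values
    outside [0, 1] are returned as-is.
    """
    if abs(et2 - et1) <= _ENDPOINT_TOL:
        raise DegenerateEndpointsError(
            "endpoint energies coincide; shell composition is unidentifiable"
        )
    e = np.asarray(et, dtype=float)
    out = (e - et1) / (et2 - et1)
    return float(out) if out.ndim == 0 else out


def preferential_solvation_parameter(x2s, x2):
    """delta_s2 = x2s - x2 (dimensionless local-minus-bulk excess)."""
    out = np.asarray(x2s, dtype=float) - np.asarray(x2, dtype=float)
    return float(out) if out.ndim == 0 else out


def shell_series(series: TitrationSeries) -> ShellSeriesResult:
    """Shell composition curve for a whole titration series.

    Endpoint energies come from ``et1_pure``/``et2_pure`` when present,
    otherwise from the measured x2=0 and x2=1 rows.
    """
    et1, et2 = series.endpoint_energies()
    x2 = series.x2
    x2s = np.asarray(shell_mole_fraction_simple(series.et, et1, et2))
    delta = x2s - x2
    points = tuple(
        ShellPoint(
            x2_bulk=float(x),
            x2s=float(s),
            delta_s2=float(d),
            in_range=bool(0.0 <= s <= 1.0),
        )
        for x, s, d in zip(x2, x2s, delta)
    )
    imax = int(np.argmax(delta))
    imin = int(np.argmin(delta))
    crossings = []
    for i in range(len(delta) - 1):
        a, b = delta[i], delta[i + 1]
        if a == 0.0 and 0 < i < len(delta) - 1:
            crossings.append(float(x2[i]))
        elif a * b < 0:
            t = a / (a - b)
            crossings.append(float(x2[i] + t * (x2[i + 1] - x2[i])))
    return ShellSeriesResult(
        mixture_name=series.mixture_name,
        points=points,
        delta_max=(float(x2[imax]), float(delta[imax])),
        delta_min=(float(x2[imin]), float(delta[imin])),
        sign_crossings=tuple(crossings),
    )


def excess_energy_summary(series: TitrationSeries) -> dict[str, float]:
    """Two summaries of the deviation from the ideal mixing line.

    ``extreme_deviation`` is the signed deviation of largest magnitude over
    the grid; ``integrated_deviation`` is the trapezoid integral of the
    deviation over x2.  Both are in kcal/mol; neither is privileged as
    "the" excess energy since competing definitions exist in the
    literature.
    """
    et1, et2 = series.endpoint_energies()
    dev = np.asarray(deviation_from_ideal(series.et, series.x2, et1, et2))
    extreme = dev[int(np.argmax(np.abs(dev)))]
    integral = float(np.trapezoid(dev, series.x2))
    return {
        "extreme_deviation": float(extreme),
        "integrated_deviation": integral,
    }


def write_shell_table(result: ShellSeriesResult, path) -> None:
    """Write the (x2, x2s, delta_s2) table as comma-delimited text."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x2", "x2s", "delta_s2"])
        for p in result.points:
            writer.writerow([repr(p.x2_bulk), repr(p.x2s), repr(p.delta_s2)])
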