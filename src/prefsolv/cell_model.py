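"""Statistical cell model of ternary solutions.

Relates the shell log-odds of the cosolvent to the bulk log-ratio,

    ln(x2s / (1 - x2s)) = m' * ln(x2 / x1) + (omega1 - omega2) / (kB T),

so a straight-line fit of the transformed shell-composition data yields,
from the intercept, the difference between the solute-S1 and solute-S2
pair interaction energies in units of kB*T.  For two-state
exchange-generated data (no intersolvent complex) the law is exact with
slope m and intercept ln f2/1.

The two-state log-odds ln(x2s/(1-x2s)) is the working form; when the full
three-component shell composition is available, the ratio form
ln(x2s/x1s) can be used instead by passing x1s explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.constants import k as BOLTZMANN_J_PER_K
from scipy.stats import linregress

from .errors import InputError

#: Default experiment temperature: ambient, 22 degrees C.
DEFAULT_TEMPERATURE_K = 295.15


@dataclass(frozen=True)
class CellModelFit:
    """Linear cell-model fit and the derived interaction-energy difference."""

    slope: float
    intercept: float
    omega_diff: float  # omega1 - omega2, joules
    temperature: float  # kelvin
    r_squared: float
    n_points: int


def fit_cell_model(
    pairs: Sequence[tuple[float, float]],
    temperature: float = DEFAULT_TEMPERATURE_K,
    x1s: Sequence[float] | None = None,
) -> CellModelFit:
    """Fit the cell model to (x2 bulk, x2s shell) pairs.

    Boundary points (x2 or x2s at 0 or 1, where a log transform is
    undefined) are dropped with a warning, never clipped.  At least three
    interior points are required.  ``x1s`` switches the left side from the
    two-state log-odds to ln(x2s/x1s).
    """
    if temperature <= 0:
        raise InputError("temperature must be positive (kelvin)")
    pairs = list(pairs)
    if x1s is not None and len(x1s) != len(pairs):
        raise InputError("x1s must align with the (x2, x2s) pairs")

    xs, ys = [], []
    n_dropped = 0
    for i, (x2, x2s) in enumerate(pairs):
        denom = x1s[i] if x1s is not None else 1.0 - x2s
        if not (0.0 < x2 < 1.0) or x2s <= 0.0 or denom <= 0.0:
            n_dropped += 1
            continue
        xs.append(np.log(x2 / (1.0 - x2)))
        ys.append(np.log(x2s / denom))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} boundary point(s) where the log transform is undefined",
            stacklevel=2,
        )
    if len(xs) < 3:
        raise InputError(
            f"need at least 3 interior points for the cell-model fit, got {len(xs)}"
        )
    res = linregress(xs, ys)
    intercept = float(res.intercept)
    return CellModelFit(
        slope=float(res.slope),
        intercept=intercept,
        omega_diff=intercept * BOLTZMANN_J_PER_K * temperature,
        temperature=temperature,
        r_squared=float(res.rvalue**2),
        n_points=len(xs),
    )


def interaction_energy_difference(fit: CellModelFit, scale_1e21: bool = False) -> float:
    """omega1 - omega2 in joules, or in units of 1e-21 J when requested."""
    return fit.omega_diff / 1e-21 if scale_1e21 else fit.omega_diff
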