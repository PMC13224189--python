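"""Seeded generators of synthetic titration series and descriptor panels.

Every analysis stage in this package can be exercised without the original
spectra: the exchange model itself is the forward generator for titration
series, and the KAT relation is the forward generator for solvent panels.
The scenario library encodes the eight studied binary mixtures with their
fitted model parameters, so parameter-recovery tests run against realistic
isotherm shapes (near-linear, hyperbolic, sigmoid, concave).

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seed and spec give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_types import ExchangeParams, SolventDescriptor, TitrationSeries
from .errors import DomainError, InputError
from .exchange_model import exchange_model_energy

#: Default composition grid: 11 evenly spaced bulk mole fractions, matching
#: a typical volumetric titration series.
DEFAULT_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))

#: Default measurement noise on E_T, kcal/mol — roughly the jitter implied
#: by a +/-0.5 nm reading uncertainty on a band near 430 nm.
DEFAULT_SIGMA = 0.05

#: KAT coefficients (et0, a, b, c) fitted for the isoquinolinium indicator,
#: used as the generating truth for synthetic solvent panels.
REPORTED_KAT_COEFFICIENTS = (59.08, 6.16, 7.19, -1.75)

#: Descriptor ranges spanning common organic solvents and water.
DEFAULT_DESCRIPTOR_RANGES = {
    "pi_star": (0.0, 1.1),
    "alpha": (0.0, 1.2),
    "beta": (0.0, 1.0),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise level (kcal/mol) and the seed that generates it."""

    sigma: float = DEFAULT_SIGMA
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise InputError("noise sigma must be nonnegative")


def simulate_exchange_series(
    params: ExchangeParams,
    grid=DEFAULT_GRID,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
    mixture_name: str = "synthetic",
    cross_exponent: str = "half",
) -> TitrationSeries:
    """Titration series from the exchange model plus Gaussian noise.

    With ``noise.sigma == 0`` the exact model curve is returned, so a
    subsequent fit is a pure parameter-recovery exercise.
    """
    x2 = np.asarray(grid, dtype=float)
    if x2.size < 4:
        raise DomainError("grid must contain at least 4 compositions")
    if np.any((x2 < 0) | (x2 > 1)):
        raise DomainError("grid compositions must lie in [0, 1]")
    et = np.asarray(exchange_model_energy(x2, params, cross_exponent), dtype=float)
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        et = et + rng.normal(0.0, noise.sigma, size=et.shape)
    return TitrationSeries(
        mixture_name=mixture_name,
        points=tuple(zip(x2.tolist(), et.tolist())),
    )


def simulate_lser_panel(
    coefficients: tuple[float, float, float, float] = REPORTED_KAT_COEFFICIENTS,
    n_solvents: int = 10,
    descriptor_ranges: dict | None = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
) -> tuple[np.ndarray, list[SolventDescriptor]]:
    """Synthetic (energies, descriptors) panel from the KAT forward model.

    Descriptors are drawn uniformly (seeded) from the given ranges; panels
    whose (1, pi*, alpha, beta) design is rank-deficient are rejected and
    redrawn, up to 100 attempts.
    """
    if n_solvents < 4:
        raise InputError("a KAT panel needs at least 4 solvents")
    ranges = dict(DEFAULT_DESCRIPTOR_RANGES, **(descriptor_ranges or {}))
    for lo, hi in ranges.values():
        if not hi > lo:
            raise InputError("descriptor ranges must be non-degenerate")
    et0, a, b, c = coefficients
    rng = np.random.default_rng(noise.seed)
    for _ in range(100):
        pi = rng.uniform(*ranges["pi_star"], size=n_solvents)
        al = rng.uniform(*ranges["alpha"], size=n_solvents)
        be = rng.uniform(*ranges["beta"], size=n_solvents)
        X = np.column_stack([np.ones(n_solvents), pi, al, be])
        if np.linalg.matrix_rank(X) == 4:
            break
    else:
        raise InputError("failed to draw a full-rank descriptor panel in 100 attempts")
    energies = et0 + a * pi + b * al + c * be
    if noise.sigma > 0:
        energies = energies + rng.normal(0.0, noise.sigma, size=n_solvents)
    descriptors = [
        SolventDescriptor(name=f"solvent_{i:02d}", pi_star=float(pi[i]),
                          alpha=float(al[i]), beta=float(be[i]))
        for i in range(n_solvents)
    ]
    return energies, descriptors


def scenario_library() -> dict[str, ExchangeParams]:
    """The eight studied binary mixtures and their fitted model parameters.

    Keys are the mixture labels (S1 + S2, S2 the protic/polar cosolvent);
    values are the exchange-model parameter sets used as generating truths
    in round-trip tests.  Mixtures fitted with the water-structure
    correction carry variant="corrected" and a k value.
    """
    g, c = "general", "corrected"
    rows = [
        ("Water + MeOH", 2, 68.50, 69.05, 68.91, 0.39, 1.55, None, g),
        ("Water + EtOH", 2, 67.73, 69.05, 67.99, 0.74, 1.69, None, g),
        ("DMSO + MeOH", 2, 64.22, 68.50, 68.10, 0.83, 1.69, -0.0006, c),
        ("Benzene + MeOH", 2, 60.68, 68.70, 63.58, 2.17, 1.41, None, g),
        ("DMF + MeOH", 2, 63.53, 68.47, 68.33, 0.41, 1.29, None, g),
        ("DCE + Oct", 2, 62.53, 63.72, 66.71, 0.58, 0.91, -5.69, c),
        ("DMF + PropDiol", 2, 63.32, 68.77, 68.13, 0.11, 3.50, 0.0015, c),
        ("Diox + EG", 3, 60.84, 68.75, 64.77, 0.29, 2.19, None, g),
    ]
    return {
        name: ExchangeParams(
            m=m, et1=et1, et2=et2, et12=et12, f2_1=f2, f12_1=f12, k=k, variant=v
        )
        for name, m, et1, et2, et12, f2, f12, k, v in rows
    }


def reference_kat_panel() -> tuple[np.ndarray, list[SolventDescriptor]]:
    """Synthetic stand-in for a ten-solvent descriptor panel.

    Widely tabulated KAT descriptor values for the ten study solvents, with
    energies generated from :data:`REPORTED_KAT_COEFFICIENTS` — a clearly
    synthetic fixture (the study's own measured panel is not distributed),
    useful for demonstrations and smoke tests.
    """
    table = [
        # name, pi*, alpha, beta, epsilon_r
        ("benzene", 0.59, 0.00, 0.10, 2.27),
        ("1,4-dioxane", 0.55, 0.00, 0.37, 2.25),
        ("1,2-dichloroethane", 0.81, 0.00, 0.10, 10.36),
        ("1-octanol", 0.40, 0.77, 0.81, 10.30),
        ("ethanol", 0.54, 0.86, 0.75, 24.55),
        ("methanol", 0.60, 0.98, 0.66, 32.66),
        ("DMF", 0.88, 0.00, 0.69, 36.71),
        ("ethylene glycol", 0.92, 0.90, 0.52, 37.70),
        ("DMSO", 1.00, 0.00, 0.76, 46.45),
        ("water", 1.09, 1.17, 0.47, 78.36),
    ]
    et0, a, b, c = REPORTED_KAT_COEFFICIENTS
    descriptors = [
        SolventDescriptor(name=n, pi_star=p, alpha=al, beta=be, epsilon_r=eps)
        for n, p, al, be, eps in table
    ]
    energies = np.array([et0 + a * d.pi_star + b * d.alpha + c * d.beta for d in descriptors])
    return energies, descriptors
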