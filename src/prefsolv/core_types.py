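"""Domain types and elementary spectroscopic conversions.

The quantities used throughout the package:

* ``E_T`` — the molar transition energy of a solvatochromic indicator's
  charge-transfer absorption band, in kcal/mol, obtained from the band
  maximum as ``E_T = 28590 / lambda_max(nm)``.
* ``x2`` — the bulk mole fraction of the cosolvent S2 in a binary mixture
  S1 + S2.  By convention S2 is always the protic/polar cosolvent; the
  base solvent S1 has ``x1 = 1 - x2``.

Energies are carried in kcal/mol everywhere; any other unit is
presentation-layer only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InputError

#: Conversion constant between band maximum (nm) and molar transition
#: energy (kcal/mol): E_T = ET_CONVERSION_CONSTANT / lambda_max.
ET_CONVERSION_CONSTANT = 28590.0


def lambda_to_transition_energy(lambda_max):
    """Convert an absorption maximum (nm) to a molar transition energy (kcal/mol).

    ``E_T = 28590 / lambda_max``.  Accepts scalars or arrays.
    """
    lam = np.asarray(lambda_max, dtype=float)
    if np.any(lam <= 0):
        raise DomainError(f"lambda_max must be positive, got {lambda_max!r}")
    out = ET_CONVERSION_CONSTANT / lam
    return float(out) if out.ndim == 0 else out


def transition_energy_to_lambda(et):
    """Convert a molar transition energy (kcal/mol) to an absorption maximum (nm).

    Inverse of :func:`lambda_to_transition_energy`; round-trips to 1e-9 relative.
    """
    e = np.asarray(et, dtype=float)
    if np.any(e <= 0):
        raise DomainError(f"transition energy must be positive, got {et!r}")
    out = ET_CONVERSION_CONSTANT / e
    return float(out) if out.ndim == 0 else out


def ideal_mixture_energy(x2, et1, et2):
    """Transition energy of the ideal (linear-mixing) reference line.

    ``(1 - x2)*et1 + x2*et2`` — the energy expected if the first solvation
    shell had exactly the bulk composition.
    """
    x = np.asarray(x2, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise DomainError(f"x2 must lie in [0, 1], got {x2!r}")
    out = (1.0 - x) * et1 + x * et2
    return float(out) if out.ndim == 0 else out


def deviation_from_ideal(et_obs, x2, et1, et2):
    """Deviation of an observed energy from the ideal mixing line.

    Returns ``et_obs - ideal_mixture_energy(x2, et1, et2)``; negative values
    mean the measurement lies below the ideal line.
    """
    obs = np.asarray(et_obs, dtype=float)
    out = obs - np.asarray(ideal_mixture_energy(x2, et1, et2))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SolventDescriptor:
    """Kamlet-Abboud-Taft descriptors of one solvent.

    pi_star is the dipolarity/polarizability, alpha the hydrogen-bond donor
    acidity and beta the hydrogen-bond acceptor basicity, all dimensionless.
    epsilon_r (relative permittivity) and et30 (reference polarity,
    kcal/mol) are optional extras used only for reporting.
    """

    name: str
    pi_star: float
    alpha: float
    beta: float
    epsilon_r: float | None = None
    et30: float | None = None

    def __post_init__(self):
        if not self.name:
            raise InputError("solvent name must be nonempty")
        for label in ("pi_star", "alpha", "beta"):
            v = getattr(self, label)
            if not math.isfinite(v):
                raise InputError(f"{label} must be finite for {self.name!r}")
        if self.alpha < 0 or self.beta < 0:
            raise InputError(f"alpha and beta must be nonnegative for {self.name!r}")


@dataclass(frozen=True)
class TransitionBand:
    """An absorption band position expressed both ways (nm and kcal/mol)."""

    lambda_max: float
    et: float

    def __post_init__(self):
        if self.lambda_max <= 0:
            raise DomainError("lambda_max must be positive")
        expected = ET_CONVERSION_CONSTANT / self.lambda_max
        if abs(self.et - expected) > 1e-9 * abs(expected):
            raise InputError(
                f"inconsistent band: et={self.et} but 28590/{self.lambda_max} = {expected}"
            )

    @classmethod
    def from_lambda(cls, lambda_max: float) -> "TransitionBand":
        return cls(lambda_max, lambda_to_transition_energy(lambda_max))

    @classmethod
    def from_et(cls, et: float) -> "TransitionBand":
        return cls(transition_energy_to_lambda(et), et)


@dataclass(frozen=True)
class TitrationSeries:
    """One binary mixture's (x2, E_T) titration measurements.

    Points are canonically sorted by x2 on construction.  ``et1_pure`` and
    ``et2_pure`` optionally carry E_T measured in the pure solvents; when
    absent the x2=0 / x2=1 rows (if present) serve as endpoints.
    """

    mixture_name: str
    points: tuple[tuple[float, float], ...]
    et1_pure: float | None = None
    et2_pure: float | None = None

    def __post_init__(self):
        pts = tuple(sorted((float(x), float(e)) for x, e in self.points))
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise InputError("a titration series needs at least 2 points")
        xs = [p[0] for p in pts]
        if any(x < 0 or x > 1 for x in xs):
            raise DomainError("every x2 must lie in [0, 1]")
        if any(b - a <= 0 for a, b in zip(xs, xs[1:])):
            raise InputError("x2 values must be distinct (strictly increasing after sort)")
        if any(p[1] <= 0 for p in pts):
            raise DomainError("every transition energy must be positive")

    @property
    def x2(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def et(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    @property
    def n_points(self) -> int:
        return len(self.points)

    def endpoint_energies(self) -> tuple[float, float]:
        """Pure-solvent energies (et1, et2), preferring explicit values.

        Falls back to measured x2=0 / x2=1 rows; raises
        :class:`~prefsolv.errors.InputError` if an endpoint is unavailable.
        """
        et1 = self.et1_pure
        et2 = self.et2_pure
        if et1 is None and self.points[0][0] == 0.0:
            et1 = self.points[0][1]
        if et2 is None and self.points[-1][0] == 1.0:
            et2 = self.points[-1][1]
        if et1 is None or et2 is None:
            raise InputError(
                f"series {self.mixture_name!r} lacks pure-solvent endpoints "
                "(no et1_pure/et2_pure and no x2=0/x2=1 rows)"
            )
        return et1, et2


VALID_VARIANTS = ("general", "corrected")


@dataclass(frozen=True)
class ExchangeParams:
    """Parameter set of the two-step solvent-exchange model.

    m is the exchange order (number of solvent molecules exchanged),
    et1/et2/et12 the transition energies when the shell holds pure S1,
    pure S2, or the 1:1 intersolvent complex S12, and f2_1/f12_1 the
    preference of the solute for S2 and for S12 relative to S1.  The
    ``corrected`` variant adds the water-structure proportionality
    constant k (kcal/mol).
    """

    m: float
    et1: float
    et2: float
    et12: float
    f2_1: float
    f12_1: float
    k: float | None = None
    variant: str = "general"

    def __post_init__(self):
        if self.variant not in VALID_VARIANTS:
            raise InputError(f"variant must be one of {VALID_VARIANTS}, got {self.variant!r}")
        if self.m <= 0:
            raise DomainError("exchange order m must be positive")
        if self.f2_1 < 0 or self.f12_1 < 0:
            raise DomainError("f2/1 and f12/1 are nonnegative by construction")
        if self.variant == "corrected" and self.k is None:
            raise InputError("corrected variant requires the correction constant k")
        if self.variant == "general" and self.k is not None:
            raise InputError("general variant must not carry a correction constant k")

    @property
    def n_free(self) -> int:
        """Number of free parameters fitted for this variant (m is fixed)."""
        return 6 if self.variant == "corrected" else 5
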