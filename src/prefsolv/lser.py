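"""Kamlet-Abboud-Taft linear solvation energy relationship.

Fits E_T = E_T0 + a*pi_star + b*alpha + c*beta by ordinary least squares
over a panel of solvents with known KAT descriptors, and predicts E_T for
new solvents from a fitted relation.  Coefficient signs separate the
physical contributions: a positive a or b means polarity/polarizability or
HBD acidity blue-shifts the band, a negative c means HBA basicity
red-shifts it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .core_types import SolventDescriptor
from .errors import InputError, SingularDesignError

_DESIGN_COLUMNS = ("intercept", "pi_star", "alpha", "beta")


@dataclass(frozen=True)
class KatFit:
    """Fitted KAT relation: coefficients, fit quality and residuals."""

    et0: float
    a: float
    b: float
    c: float
    r_squared: float
    residuals: np.ndarray
    n_solvents: int

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.et0, self.a, self.b, self.c)


def _design_matrix(descriptors: Sequence[SolventDescriptor]) -> np.ndarray:
    return np.column_stack(
        [
            np.ones(len(descriptors)),
            [d.pi_star for d in descriptors],
            [d.alpha for d in descriptors],
            [d.beta for d in descriptors],
        ]
    )


def _collinear_columns(X: np.ndarray) -> tuple[str, ...]:
    """Name the smallest set of design columns involved in a rank deficiency."""
    for size in range(2, X.shape[1] + 1):
        for cols in combinations(range(X.shape[1]), size):
            sub = X[:, cols]
            if np.linalg.matrix_rank(sub) < len(cols):
                return tuple(_DESIGN_COLUMNS[i] for i in cols)
    return _DESIGN_COLUMNS


def fit_kat(
    energies: Sequence[float], descriptors: Sequence[SolventDescriptor]
) -> KatFit:
    """Ordinary least-squares fit of the four-coefficient KAT relation.

    Requires at least four solvents and a full-rank (1, pi*, alpha, beta)
    design; deterministic, unweighted.  Raises
    :class:`~prefsolv.errors.SingularDesignError` naming the collinear
    columns when the design is rank-deficient.
    """
    y = np.asarray(energies, dtype=float)
    if len(y) != len(descriptors):
        raise InputError(
            f"{len(y)} energies but {len(descriptors)} descriptors"
        )
    if len(y) < 4:
        raise SingularDesignError(
            f"at least 4 solvents are needed to fit 4 coefficients, got {len(y)}"
        )
    X = _design_matrix(descriptors)
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        cols = _collinear_columns(X)
        raise SingularDesignError(
            f"design matrix is rank-deficient (rank {rank}); collinear columns: {cols}",
            collinear_columns=cols,
        )
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta_hat
    resid = y - fitted
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(resid**2))
    r2 = 1.0 if tss == 0.0 else 1.0 - rss / tss
    return KatFit(
        et0=float(beta_hat[0]),
        a=float(beta_hat[1]),
        b=float(beta_hat[2]),
        c=float(beta_hat[3]),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        residuals=resid,
        n_solvents=len(y),
    )


def predict_kat(fit: KatFit, descriptor: SolventDescriptor) -> float:
    """Evaluate a fitted KAT relation for one solvent."""
    return (
        fit.et0
        + fit.a * descriptor.pi_star
        + fit.b * descriptor.alpha
        + fit.c * descriptor.beta
    )
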