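"""Two-step solvent-exchange model of preferential solvation.

The solute's first shell is occupied by base solvent S1, cosolvent S2, or
the 1:1 intersolvent complex S12.  Two exchange equilibria (S1 -> S2 and
S1 -> S12, with m molecules exchanged) give the local mole fractions

    x1s  : (1 - x2)^m
    x2s  : f2/1 * x2^m
    x12s : f12/1 * (x2 (1 - x2))^(m/2)

normalized to sum to one, and the observed transition energy is the
shell-weighted mean

    E_T = E_T1 * x1s + E_T2 * x2s + E_T12 * x12s.

The ``corrected`` variant adds a water-structure term for hydro-organic
mixtures at low cosolvent content,

    dE_T = k * f2/1 * x2^2 * [(1-x2)^2 + f12/1*(1-x2)*x2/2]
           / [(1-x2)^2 + f2/1*x2^2 + f12/1*x2*(1-x2)]^2,

with k a proportionality constant in kcal/mol.

The cross-term exponent deserves a note: some presentations write the
S12 weight as (x2(1-x2))^m, but the m = 2 special case of the same model
uses the power 1, i.e. m/2, which is also the form of the original
Bosch-Roses derivation (half an exchange unit of each solvent builds the
complex).  The default here is m/2; ``cross_exponent="printed"`` gives
the (x2(1-x2))^m form for comparison.

Fitting is bounded nonlinear least squares (scipy TRF) from a seeded
Latin-hypercube multi-start plus one informed start, so a fixed seed gives
a bit-reproducible fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .core_types import ExchangeParams, TitrationSeries
from .errors import DomainError, InputError, NonConvergenceError, WrongVariantError

CROSS_EXPONENT_MODES = ("half", "printed")

#: Two converged starts whose RSS differ by less than this are treated as ties.
_RSS_TIE_RTOL = 1e-9
_RSS_TIE_ATOL = 1e-12
#: Parameter spread (relative) across tied starts beyond which a fit is flagged unstable.
_STABILITY_RTOL = 0.01


def _cross_power(m: float, mode: str) -> float:
    if mode not in CROSS_EXPONENT_MODES:
        raise InputError(f"cross_exponent must be one of {CROSS_EXPONENT_MODES}")
    return m if mode == "printed" else m / 2.0


@dataclass(frozen=True)
class LocalComposition:
    """Local (first-shell) mole fractions of S1, S2 and the S12 complex."""

    x1s: float
    x2s: float
    x12s: float


def local_shell_fractions(
    x2: float, params: ExchangeParams, cross_exponent: str = "half"
) -> LocalComposition:
    """Local shell composition at one bulk composition.

    At the exact endpoints the limits (1,0,0) and (0,1,0) are returned,
    avoiding 0/0 when both f parameters vanish.
    """
    if not 0.0 <= x2 <= 1.0:
        raise DomainError(f"x2 must lie in [0, 1], got {x2}")
    if x2 == 0.0:
        return LocalComposition(1.0, 0.0, 0.0)
    if x2 == 1.0:
        return LocalComposition(0.0, 1.0, 0.0)
    p = _cross_power(params.m, cross_exponent)
    w1 = (1.0 - x2) ** params.m
    w2 = params.f2_1 * x2**params.m
    w12 = params.f12_1 * (x2 * (1.0 - x2)) ** p
    total = w1 + w2 + w12
    return LocalComposition(w1 / total, w2 / total, w12 / total)


def water_structure_correction(x2, params: ExchangeParams):
    """Water-structure correction term dE_T (kcal/mol) of the corrected variant.

    Vanishes identically at both endpoints.  Raises
    :class:`~prefsolv.errors.WrongVariantError` for general-variant
    parameters, which carry no k.
    """
    if params.variant != "corrected":
        raise WrongVariantError("correction term is defined only for the corrected variant")
    x = np.asarray(x2, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise DomainError(f"x2 must lie in [0, 1], got {x2!r}")
    x1 = 1.0 - x
    num = params.k * params.f2_1 * x**2 * (x1**2 + params.f12_1 * x1 * x / 2.0)
    den = (x1**2 + params.f2_1 * x**2 + params.f12_1 * x * x1) ** 2
    out = num / den
    return float(out) if out.ndim == 0 else out


def exchange_model_energy(x2, params: ExchangeParams, cross_exponent: str = "half"):
    """Model transition energy at bulk composition x2 (scalar or array).

    Shell-weighted mean of E_T1, E_T2, E_T12, plus the water-structure
    correction for the corrected variant.  Exactly E_T1 at x2=0 and E_T2
    at x2=1 for both variants.
    """
    p = _cross_power(params.m, cross_exponent)
    x = np.asarray(x2, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise DomainError(f"x2 must lie in [0, 1], got {x2!r}")
    x1 = 1.0 - x
    w1 = x1**params.m
    w2 = params.f2_1 * x**params.m
    w12 = params.f12_1 * (x * x1) ** p
    total = w1 + w2 + w12
    with np.errstate(invalid="ignore"):
        et = (params.et1 * w1 + params.et2 * w2 + params.et12 * w12) / total
    # endpoints analytically: w-total can underflow for large m
    et = np.where(x == 0.0, params.et1, et)
    et = np.where(x == 1.0, params.et2, et)
    if params.variant == "corrected":
        et = et + np.asarray(water_structure_correction(x, params))
    return float(et) if et.ndim == 0 else et


@dataclass(frozen=True)
class FitOptions:
    """Controls for the multi-start nonlinear fit.

    n_starts Latin-hypercube starts are drawn from the seeded generator, in
    addition to one informed start (endpoints at the data ends, E_T12 at
    the mid-grid energy, f's at 1, k at 0).  energy_pad widens the box
    constraint on the E parameters around the data range.
    """

    n_starts: int = 32
    seed: int = 1
    fix_endpoints: bool = False
    cross_exponent: str = "half"
    max_nfev: int = 5000
    ftol: float = 1e-12
    energy_pad: float = 5.0
    f_start_max: float = 5.0
    k_start_range: tuple[float, float] = (-10.0, 10.0)


@dataclass(frozen=True)
class StartRecord:
    """Diagnostics for one optimizer start."""

    index: int
    x0: tuple[float, ...]
    rss: float
    success: bool
    message: str
    params: tuple[float, ...] | None = None


@dataclass(frozen=True)
class ExchangeFit:
    """Result of fitting the exchange model to one titration series."""

    params: ExchangeParams
    rss: float
    r_squared: float
    sd: float
    n_points: int
    converged: bool
    n_starts: int
    best_start_seed: int
    stability_flag: bool
    covariance: np.ndarray | None = None
    start_log: tuple[StartRecord, ...] = field(default=(), repr=False)


def _pack_names(variant: str, fix_endpoints: bool) -> list[str]:
    names = [] if fix_endpoints else ["et1", "et2"]
    names += ["et12", "f2_1", "f12_1"]
    if variant == "corrected":
        names.append("k")
    return names


def _theta_to_params(
    theta: np.ndarray,
    names: list[str],
    variant: str,
    m: float,
    fixed: dict[str, float],
) -> ExchangeParams:
    vals = dict(fixed, **dict(zip(names, theta)))
    return ExchangeParams(
        m=m,
        et1=vals["et1"],
        et2=vals["et2"],
        et12=vals["et12"],
        f2_1=max(vals["f2_1"], 0.0),
        f12_1=max(vals["f12_1"], 0.0),
        k=vals.get("k"),
        variant=variant,
    )


def fit_exchange_model(
    series: TitrationSeries,
    variant: str = "general",
    m: float = 2.0,
    options: FitOptions | None = None,
) -> ExchangeFit:
    """Multi-start bounded least-squares fit of the exchange model.

    m is a fixed hyperparameter (never optimized continuously); the free
    parameters are E_T1, E_T2, E_T12, f2/1, f12/1 and, for the corrected
    variant, k.  The best converged start by RSS wins; exact ties go to
    the lowest start index.  Raises
    :class:`~prefsolv.errors.NonConvergenceError` with the per-start log
    when no start converges.
    """
    if variant not in ("general", "corrected"):
        raise InputError(f"unknown variant {variant!r}")
    if m <= 0:
        raise DomainError("exchange order m must be positive")
    opts = options or FitOptions()
    n_free = (5 if variant == "general" else 6) - (2 if opts.fix_endpoints else 0)
    if series.n_points <= n_free:
        raise InputError(
            f"{series.n_points} points cannot constrain {n_free} free parameters"
        )

    x2 = series.x2
    y = series.et
    lo_e = float(y.min()) - opts.energy_pad
    hi_e = float(y.max()) + opts.energy_pad
    names = _pack_names(variant, opts.fix_endpoints)
    fixed: dict[str, float] = {}
    if opts.fix_endpoints:
        et1, et2 = series.endpoint_energies()
        fixed = {"et1": et1, "et2": et2}

    lower, upper, start_lo, start_hi = [], [], [], []
    for name in names:
        if name.startswith("et"):
            lower.append(lo_e)
            upper.append(hi_e)
            start_lo.append(lo_e)
            start_hi.append(hi_e)
        elif name in ("f2_1", "f12_1"):
            lower.append(0.0)
            upper.append(np.inf)
            start_lo.append(0.0)
            start_hi.append(opts.f_start_max)
        else:  # k
            lower.append(-np.inf)
            upper.append(np.inf)
            start_lo.append(opts.k_start_range[0])
            start_hi.append(opts.k_start_range[1])

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = _theta_to_params(theta, names, variant, m, fixed)
        return exchange_model_energy(x2, p, opts.cross_exponent) - y

    # informed start: endpoints at the data ends, complex energy mid-grid
    informed = {
        "et1": float(y[0]),
        "et2": float(y[-1]),
        "et12": float(y[len(y) // 2]),
        "f2_1": 1.0,
        "f12_1": 1.0,
        "k": 0.0,
    }
    starts = [np.array([np.clip(informed[n], lower[i], upper[i]) for i, n in enumerate(names)])]
    if opts.n_starts > 0:
        sampler = qmc.LatinHypercube(d=len(names), seed=opts.seed)
        unit = sampler.random(opts.n_starts)
        scaled = qmc.scale(unit, start_lo, start_hi)
        starts.extend(np.asarray(row) for row in scaled)

    log: list[StartRecord] = []
    best = None
    for idx, x0 in enumerate(starts):
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lower, upper),
                method="trf",
                x_scale="jac",
                ftol=opts.ftol,
                xtol=opts.ftol,
                gtol=opts.ftol,
                max_nfev=opts.max_nfev,
            )
        except Exception as exc:  # pragma: no cover - optimizer-internal failure
            log.append(StartRecord(idx, tuple(x0), np.inf, False, str(exc)))
            continue
        rss = float(2.0 * res.cost)
        ok = bool(res.success) and np.all(np.isfinite(res.x))
        log.append(
            StartRecord(idx, tuple(x0), rss, ok, res.message, tuple(res.x) if ok else None)
        )
        if ok and (best is None or rss < best[0] - _RSS_TIE_ATOL):
            best = (rss, idx, res)

    if best is None:
        raise NonConvergenceError(
            f"no optimizer start converged for {series.mixture_name!r} "
            f"({variant}, m={m})",
            start_log=log,
        )

    rss, best_idx, res = best
    # polish: re-run from the winning start at machine-level tolerances so
    # badly scaled parameters (e.g. a near-zero k) reach full precision
    try:
        polished = least_squares(
            residuals,
            res.x,
            bounds=(lower, upper),
            method="trf",
            x_scale="jac",
            ftol=None,
            xtol=5e-16,
            gtol=None,
            max_nfev=opts.max_nfev,
        )
        if np.all(np.isfinite(polished.x)) and 2.0 * polished.cost <= rss:
            rss = float(2.0 * polished.cost)
            res = polished
    except Exception:  # pragma: no cover - keep the unpolished solution
        pass
    params = _theta_to_params(res.x, names, variant, m, fixed)

    # stability: do equally good starts disagree on the parameters?
    tied = [
        np.asarray(rec.params)
        for rec in log
        if rec.success and rec.rss <= rss * (1 + _RSS_TIE_RTOL) + _RSS_TIE_ATOL
    ]
    stability_flag = False
    if len(tied) > 1:
        stacked = np.vstack(tied)
        spread = stacked.max(axis=0) - stacked.min(axis=0)
        scale = np.maximum(np.abs(stacked).max(axis=0), 1e-8)
        stability_flag = bool(np.any(spread / scale > _STABILITY_RTOL))

    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 0:
        r2 = 1.0 - rss / tss
    else:
        r2 = 1.0 if rss <= 1e-12 else 0.0
    dof = series.n_points - len(names)
    sd = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")

    cov = None
    J = res.jac
    if J is not None and np.all(np.isfinite(J)):
        JTJ = J.T @ J
        if np.linalg.matrix_rank(JTJ) == JTJ.shape[0] and dof > 0:
            cov = np.linalg.inv(JTJ) * (rss / dof)

    return ExchangeFit(
        params=params,
        rss=rss,
        r_squared=float(min(r2, 1.0)),
        sd=sd,
        n_points=series.n_points,
        converged=True,
        n_starts=len(starts),
        best_start_seed=best_idx,
        stability_flag=stability_flag,
        covariance=cov,
        start_log=tuple(log),
    )


@dataclass(frozen=True)
class CandidateResult:
    """One (variant, m) candidate's outcome in a model comparison."""

    variant: str
    m: float
    fit: ExchangeFit | None
    error: str | None = None

    @property
    def converged(self) -> bool:
        return self.fit is not None and self.fit.converged


@dataclass(frozen=True)
class VariantComparison:
    """Candidates ranked best-first by (converged, stable, sd)."""

    ranked: tuple[CandidateResult, ...]

    @property
    def best(self) -> CandidateResult:
        return self.ranked[0]


def compare_model_variants(
    series: TitrationSeries,
    candidates: list[tuple[str, float]],
    options: FitOptions | None = None,
) -> VariantComparison:
    """Fit every candidate (variant, m) and rank them.

    Ranking: converged fits before failures, stable before flagged, then
    ascending residual standard deviation.  Non-converging candidates are
    kept in the report with their error message, never dropped silently.
    """
    if not candidates:
        raise InputError("at least one candidate (variant, m) is required")
    results = []
    for variant, m in candidates:
        try:
            fit = fit_exchange_model(series, variant, m, options)
            results.append(CandidateResult(variant, m, fit))
        except Exception as exc:
            results.append(CandidateResult(variant, m, None, error=str(exc)))

    def key(c: CandidateResult):
        if c.fit is None:
            return (1, 1, np.inf)
        return (0, int(c.fit.stability_flag), c.fit.sd)

    return VariantComparison(ranked=tuple(sorted(results, key=key)))
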