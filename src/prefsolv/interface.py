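"""File formats, the analysis report, and the end-to-end pipeline.

Series files are comma-delimited text with a header row naming ``x2`` and
exactly one of ``et`` (kcal/mol) or ``lambda_nm``; ``#`` starts a comment
line.  Descriptor panels carry ``name, pi_star, alpha, beta`` plus
optional ``epsilon_r`` and ``et30`` columns.  Reports serialize to JSON
with full float precision so a write/read round-trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd

from . import cell_model as cm
from . import exchange_model as xm
from . import shell_composition as sc
from .core_types import SolventDescriptor, TitrationSeries, lambda_to_transition_energy
from .errors import ParseError, PrefsolvError

log = logging.getLogger("prefsolv")

try:
    _VERSION = version("prefsolv")
except PackageNotFoundError:  # pragma: no cover - only when run un-installed
    _VERSION = "unknown"


def _data_line_numbers(path) -> list[int]:
    """1-based file line numbers of non-comment, non-blank lines (header first)."""
    numbers = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped and not stripped.startswith("#"):
                numbers.append(i)
    return numbers


def read_series(path, mixture_name: str | None = None) -> TitrationSeries:
    """Read a titration series from delimited text.

    Wavelength input (``lambda_nm``) is converted to E_T on the fly.
    Errors name the offending file line.
    """
    lines = _data_line_numbers(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:
        raise ParseError(f"{path}: not parseable as delimited text: {exc}") from exc
    cols = set(df.columns)
    if "x2" not in cols:
        raise ParseError(f"{path}: missing required column 'x2'")
    has_et, has_lam = "et" in cols, "lambda_nm" in cols
    if has_et and has_lam:
        raise ParseError(f"{path}: ambiguous input — both 'et' and 'lambda_nm' present")
    if not (has_et or has_lam):
        raise ParseError(f"{path}: need exactly one of 'et' or 'lambda_nm'")
    value_col = "et" if has_et else "lambda_nm"

    def line_of(row_idx: int) -> int:
        # +1 skips the header entry
        pos = row_idx + 1
        return lines[pos] if pos < len(lines) else -1

    points = []
    for idx, row in df.iterrows():
        x2, val = row["x2"], row[value_col]
        for label, v in (("x2", x2), (value_col, val)):
            if pd.isna(v) or not np.isreal(v):
                raise ParseError(f"{path}:{line_of(idx)}: non-numeric {label} value {v!r}")
        if not 0.0 <= float(x2) <= 1.0:
            raise ParseError(f"{path}:{line_of(idx)}: x2={x2} outside [0, 1]")
        et = float(val) if has_et else lambda_to_transition_energy(float(val))
        points.append((float(x2), et))
    try:
        return TitrationSeries(
            mixture_name=mixture_name or str(path), points=tuple(points)
        )
    except PrefsolvError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_series(series: TitrationSeries, path) -> None:
    df = pd.DataFrame({"x2": series.x2, "et": series.et})
    with open(path, "w") as fh:
        fh.write(f"# mixture: {series.mixture_name}\n")
        df.to_csv(fh, index=False)


def read_descriptors(path) -> list[SolventDescriptor]:
    """Read a solvent descriptor panel from delimited text."""
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    required = {"name", "pi_star", "alpha", "beta"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing descriptor column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SolventDescriptor(
                name=str(row["name"]),
                pi_star=float(row["pi_star"]),
                alpha=float(row["alpha"]),
                beta=float(row["beta"]),
                epsilon_r=float(row["epsilon_r"]) if "epsilon_r" in df.columns and pd.notna(row.get("epsilon_r")) else None,
                et30=float(row["et30"]) if "et30" in df.columns and pd.notna(row.get("et30")) else None,
            )
        )
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the one-mixture analysis pipeline."""

    seed: int = 1
    candidates: tuple[tuple[str, float], ...] = (
        ("general", 2.0),
        ("general", 3.0),
        ("corrected", 2.0),
    )
    n_starts: int = 32
    fix_endpoints: bool = False
    cross_exponent: str = "half"
    run_cell_model: bool = True
    temperature: float = cm.DEFAULT_TEMPERATURE_K
    curve_grid_size: int = 101


@dataclass
class AnalysisReport:
    """Everything the pipeline learned about one mixture, JSON-serializable."""

    mixture_name: str
    n_points: int
    endpoints: tuple[float, float] | None
    shell_table: list[dict] = field(default_factory=list)
    shell_summary: dict = field(default_factory=dict)
    variant_comparison: list[dict] = field(default_factory=list)
    best_fit: dict | None = None
    local_composition_curve: list[dict] = field(default_factory=list)
    cell_model: dict | None = None
    stage_errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, default=json_default)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        data = json.loads(text)
        if data.get("endpoints") is not None:
            data["endpoints"] = tuple(data["endpoints"])
        return cls(**data)

    @classmethod
    def read(cls, path) -> "AnalysisReport":
        with open(path) as fh:
            return cls.from_json(fh.read())


def json_default(obj):
    """Serialize numpy scalars that leak into report payloads."""
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


def _fit_to_dict(fit: xm.ExchangeFit) -> dict:
    p = fit.params
    return {
        "variant": p.variant,
        "m": float(p.m),
        "et1": float(p.et1),
        "et2": float(p.et2),
        "et12": float(p.et12),
        "f2_1": float(p.f2_1),
        "f12_1": float(p.f12_1),
        "k": None if p.k is None else float(p.k),
        "rss": fit.rss,
        "r_squared": fit.r_squared,
        "sd": fit.sd,
        "n_points": fit.n_points,
        "converged": fit.converged,
        "n_starts": fit.n_starts,
        "best_start_seed": fit.best_start_seed,
        "stability_flag": fit.stability_flag,
    }


def run_pipeline(series: TitrationSeries, config: PipelineConfig | None = None) -> AnalysisReport:
    """Shell composition -> model comparison -> local curves -> cell model.

    Stage failures are recorded in ``stage_errors`` and independent
    downstream stages still run; the report always carries a provenance
    block (seed, options, package version).
    """
    config = config or PipelineConfig()
    report = AnalysisReport(
        mixture_name=series.mixture_name,
        n_points=series.n_points,
        endpoints=None,
        provenance={
            "package": "prefsolv",
            "version": _VERSION,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
        },
    )
    try:
        report.endpoints = series.endpoint_energies()
    except PrefsolvError as exc:
        report.stage_errors["endpoints"] = str(exc)

    shell = None
    try:
        shell = sc.shell_series(series)
        report.shell_table = [dataclasses.asdict(p) for p in shell.points]
        report.shell_summary = {
            "delta_max": shell.delta_max,
            "delta_min": shell.delta_min,
            "sign_crossings": list(shell.sign_crossings),
            **sc.excess_energy_summary(series),
        }
        log.info("shell composition: delta_s2 extrema %s / %s",
                 shell.delta_max, shell.delta_min)
    except PrefsolvError as exc:
        report.stage_errors["shell_composition"] = str(exc)

    options = xm.FitOptions(
        n_starts=config.n_starts,
        seed=config.seed,
        fix_endpoints=config.fix_endpoints,
        cross_exponent=config.cross_exponent,
    )
    best_fit = None
    try:
        comparison = xm.compare_model_variants(series, list(config.candidates), options)
        report.variant_comparison = [
            {
                "variant": c.variant,
                "m": c.m,
                "converged": c.converged,
                "sd": c.fit.sd if c.fit else None,
                "stability_flag": c.fit.stability_flag if c.fit else None,
                "error": c.error,
            }
            for c in comparison.ranked
        ]
        if comparison.best.fit is not None:
            best_fit = comparison.best.fit
            report.best_fit = _fit_to_dict(best_fit)
            log.info("best variant: %s m=%g (sd=%.4g)", best_fit.params.variant,
                     best_fit.params.m, best_fit.sd)
        else:
            report.stage_errors["exchange_model"] = "no candidate converged"
    except PrefsolvError as exc:
        report.stage_errors["exchange_model"] = str(exc)

    if best_fit is not None:
        grid = np.linspace(0.0, 1.0, config.curve_grid_size)
        report.local_composition_curve = [
            {"x2": float(x), **dataclasses.asdict(
                xm.local_shell_fractions(float(x), best_fit.params, config.cross_exponent))}
            for x in grid
        ]

    if config.run_cell_model and shell is not None:
        try:
            pairs = [(p.x2_bulk, p.x2s) for p in shell.points]
            fit = cm.fit_cell_model(pairs, temperature=config.temperature)
            report.cell_model = dataclasses.asdict(fit)
        except PrefsolvError as exc:
            report.stage_errors["cell_model"] = str(exc)

    return report
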