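"""End-to-end orchestration: screening, modality battery, model comparison,
coefficient inference, diagnostics, and report writing.

The pipeline is a pure function of (input table, configuration): every
random stage receives an explicit seed derived from the configuration, and
the JSON report embeds a run manifest (config, package version) so any
report can be reproduced byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data import DEFAULT_ROLES, StudyTable, read_table
from .errors import SchemaError
from .modality import count_modes, dip_test, mode_ladder, sizer_map
from .regression import FitConfig, wald_table
from .selection import compare_models, fit_diagnostics

__all__ = ["RunConfig", "run_pipeline", "write_report"]

logger = logging.getLogger("cuspcat")

COMPARISON_COLUMNS = ("Loglikelihood", "Parameters", "AIC", "AICc", "BIC")


@dataclass
class RunConfig:
    """Configuration of a full analysis run (all seeds explicit)."""

    input: str | None = None
    roles: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLES))
    seed: int = 0
    significance: float = 0.01  # the study's significance policy
    n_starts: int = 10
    dip_n_mc: int = 999
    silverman_n_boot: int = 200
    max_modes: int = 6
    modality_level: float = 0.05
    sizer: bool = True
    k_override: dict[str, int] = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self):
        if not (0.0 < self.significance < 0.5):
            raise SchemaError("significance must lie in (0, 0.5)")
        if self.seed < 0:
            raise SchemaError("seed must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a flat key-value config document (YAML; JSON is valid YAML)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"config file {path!r} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def fit_config(self) -> FitConfig:
        return FitConfig(n_starts=self.n_starts, seed=self.seed)


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig, table: StudyTable | None = None) -> dict:
    """Execute the full analysis and return the report as a dict.

    Stages, in order: screening (listwise deletion), modality battery on
    the state column (dip test, mode ladder with critical bandwidths, KDE
    mode count, optional SiZer map), three-model comparison with the
    likelihood-ratio contrast, cusp Wald table at the configured
    significance level, and residual diagnostics.  When ``output_dir`` is
    set a partial report is persisted even if a stage fails.
    """
    report: dict = {
        "manifest": {
            "package": "cuspcat",
            "version": _version(),
            "config": config.to_dict(),
        }
    }
    timings: dict[str, float] = {}
    report["timings_s"] = timings
    stage = "screening"
    try:
        t0 = _stage(stage)
        if table is None:
            if config.input is None:
                raise SchemaError("config.input is required when no table is supplied")
            table = read_table(config.input, config.roles)
        report["screening"] = {
            "n_raw": table.n_raw,
            "n_analyzed": table.n_analyzed,
            "n_deleted": len(table.deletion_log),
            "deleted_rows": list(table.deletion_log),
        }
        timings[stage] = time.perf_counter() - t0

        stage = "modality"
        t0 = _stage(stage)
        state = table.state
        dip = dip_test(state, n_mc=config.dip_n_mc, seed=config.seed)
        k_sel, ladder = mode_ladder(
            state,
            level=config.modality_level,
            max_k=config.max_modes,
            n_boot=config.silverman_n_boot,
            seed=config.seed,
        )
        modality = {
            "dip": dip.to_dict(),
            "mode_count_rule_of_thumb": count_modes(state),
            "silverman_ladder": [r.to_dict() for r in ladder],
            "first_non_rejected_k": k_sel,
        }
        if config.sizer:
            modality["sizer"] = sizer_map(state).to_dict()
        report["modality"] = modality
        timings[stage] = time.perf_counter() - t0

        stage = "comparison"
        t0 = _stage(stage)
        comp = compare_models(table, config.fit_config(), k_override=config.k_override or None)
        report["comparison"] = comp.to_dict()
        report["fits"] = {name: fit.to_dict() for name, fit in comp.fits.items()}
        timings[stage] = time.perf_counter() - t0

        stage = "wald"
        t0 = _stage(stage)
        report["cusp_wald_table"] = wald_table(
            comp.fits["cusp"], significance=config.significance
        ).to_dict(orient="records")
        timings[stage] = time.perf_counter() - t0

        stage = "diagnostics"
        t0 = _stage(stage)
        diag = fit_diagnostics(comp.fits["cusp"], table)
        report["diagnostics"] = diag.to_dict()
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        report["error"] = {"stage": stage, "message": str(exc)}
        if config.output_dir:
            write_report(report, config.output_dir)
        logger.error("stage %s failed: %s", stage, exc)
        raise
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def _version() -> str:
    from . import __version__

    return __version__


def _fmt(value, width=14, nd=3) -> str:
    if isinstance(value, float):
        return f"{value:>{width}.{nd}f}"
    return f"{value!s:>{width}}"


def comparison_text(report: dict) -> str:
    """Plain-text model-comparison table (Loglikelihood ... BIC layout)."""
    lines = ["Models tested" + "".join(f"{c:>14}" for c in COMPARISON_COLUMNS)]
    for row in report.get("comparison", {}).get("table", []):
        lines.append(
            f"{row['model']:<13}"
            + _fmt(row["loglik"])
            + _fmt(row["k_used"])
            + _fmt(row["AIC"])
            + _fmt(row["AICc"])
            + _fmt(row["BIC"])
        )
    lr = report.get("comparison", {}).get("lr_linear_vs_cusp")
    if lr:
        lines.append(
            f"linear vs cusp: chi2({lr['df']}) = {lr['chi2']:.3f}, p = {lr['p']:.3g}"
        )
    return "\n".join(lines) + "\n"


def coefficients_text(report: dict) -> str:
    """Plain-text cusp coefficient table (estimate, CI, SE, z, p)."""
    header = ["term", "estimate", "ci95_low", "ci95_high", "se", "z", "p"]
    lines = [f"{header[0]:<8}" + "".join(f"{h:>12}" for h in header[1:])]
    for row in report.get("cusp_wald_table", []):
        lines.append(
            f"{row['term']:<8}"
            + "".join(_fmt(row[h], width=12) for h in header[1:-1])
            + _fmt(row["p"], width=12, nd=4)
            + ("  *" if row.get("significant") else "")
        )
    return "\n".join(lines) + "\n"


def write_report(report: dict, output_dir) -> dict[str, Path]:
    """Write the JSON report (full precision) and text tables (3 decimals).

    Returns the mapping of artifact names to paths.  The optional SiZer
    grid goes to its own JSON artifact to keep the main report readable.
    """
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    paths: dict[str, Path] = {}
    body = dict(report)
    sizer = body.get("modality", {}).get("sizer")
    if sizer is not None:
        body = json.loads(json.dumps(body))  # deep copy
        body["modality"]["sizer"] = "see sizer.json"
        paths["sizer"] = out / "sizer.json"
        paths["sizer"].write_text(json.dumps(sizer))
    paths["report"] = out / "report.json"
    paths["report"].write_text(json.dumps(body, indent=2, default=_json_default))
    if "comparison" in report:
        paths["comparison"] = out / "comparison.txt"
        paths["comparison"].write_text(comparison_text(report))
    if "cusp_wald_table" in report:
        paths["coefficients"] = out / "coefficients.txt"
        paths["coefficients"].write_text(coefficients_text(report))
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
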