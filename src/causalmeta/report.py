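"""Run orchestration, result serialization, and forest-plot export.

:func:`run` drives one analysis end to end from a :class:`RunConfig`:
validate inputs, estimate (with or without cross-fitting), and write the
three result tables (arm-0 means, arm-1 means, differences), a JSON run
manifest, a plain-text summary, and — for internal analyses — forest-plot
data plus a minimal rendered forest plot.  Every number in the summary is
read back from the serialized tables, so the tables are the single source
of truth.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossfit import CrossfitConfig, crossfit_estimate
from .data_model import (
    AnalysisSpec,
    ExternalCovariates,
    MultiSourceDataset,
    validate_inputs,
)
from .estimators import estimates_to_frames
from .nuisance import NuisanceFits, fit_nuisances

__all__ = ["RunConfig", "run", "fitted_model_report", "load_config"]

_ANALYSES = {
    "ate-internal": ("internal", "ATE"),
    "ate-external": ("external", "ATE"),
    "ste-internal": ("internal", "STE"),
    "ste-external": ("external", "STE"),
}


@dataclass
class RunConfig:
    """Everything one analysis run needs: data locations, column roles,
    the analysis specification, cross-fitting switches, output directory."""

    analysis: str
    data_path: str
    columns: dict
    output_dir: str
    spec: AnalysisSpec = field(default_factory=AnalysisSpec)
    crossfit: CrossfitConfig = field(default_factory=lambda: CrossfitConfig(enabled=False))
    external_path: Optional[str] = None
    external_columns: Optional[dict] = None
    sep: str = ","

    def __post_init__(self):
        if self.analysis not in _ANALYSES:
            raise ValueError(
                f"analysis must be one of {sorted(_ANALYSES)}, got {self.analysis!r}"
            )
        target, estimand = _ANALYSES[self.analysis]
        self.spec = self.spec.replace(target=target, estimand=estimand)


def load_config(path) -> RunConfig:
    """Read a YAML run configuration.

    Recognized keys: ``analysis``, ``data`` (path), ``columns`` (mapping with
    Y/S/A and optional EM/X), ``external`` (mapping with path and optional
    EM/X), ``spec`` (AnalysisSpec fields), ``cross_fitting``,
    ``replications``, ``seed``, ``output_dir``, ``sep``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    spec_kw = dict(cfg.get("spec") or {})
    for k in ("outcome_library", "treatment_library", "external_library"):
        if k in spec_kw:
            spec_kw[k] = tuple(spec_kw[k])
    if "seed" in cfg:
        spec_kw.setdefault("seed", int(cfg["seed"]))
    spec = AnalysisSpec(**spec_kw)
    cf = CrossfitConfig(
        enabled=bool(cfg.get("cross_fitting", False)),
        replications=int(cfg.get("replications", 100)),
        seed=int(cfg.get("seed", 0)),
    )
    ext = cfg.get("external") or {}
    return RunConfig(
        analysis=cfg["analysis"],
        data_path=cfg["data"],
        columns=dict(cfg.get("columns") or {}),
        output_dir=cfg.get("output_dir", "causalmeta_out"),
        spec=spec,
        crossfit=cf,
        external_path=ext.get("path"),
        external_columns={k: v for k, v in ext.items() if k != "path"},
        sep=cfg.get("sep", ","),
    )


def _load_inputs(config: RunConfig):
    roles = dict(config.columns)
    data = MultiSourceDataset.from_csv(config.data_path, sep=config.sep, **roles)
    external = None
    if config.external_path:
        ext_roles = dict(config.external_columns or {})
        ext_roles.setdefault("X", roles.get("X"))
        if ext_roles.get("X") is None:
            ext_roles.pop("X")
        external = ExternalCovariates.from_csv(
            config.external_path, sep=config.sep, **ext_roles)
    return data, external


def _summary_text(config: RunConfig, tables: dict[str, pd.DataFrame],
                  warnings_list: list[str]) -> str:
    df = tables["df_dif"]
    lines = [
        f"causalmeta {__version__} — analysis: {config.analysis}",
        f"treatment effect estimates (level {config.spec.level:.2f}):",
    ]
    for _, r in df.iterrows():
        line = (f"  target {r['target']}, subgroup {r['subgroup']}: "
                f"{r['estimate']:.4g} [CI {r['ci_low']:.4g}, {r['ci_high']:.4g}]")
        if np.isfinite(r.get("scb_low", np.nan)):
            line += f" [SCB {r['scb_low']:.4g}, {r['scb_high']:.4g}]"
        lines.append(line)
    if warnings_list:
        lines.append("warnings:")
        lines.extend(f"  - {w}" for w in warnings_list)
    return "\n".join(lines) + "\n"


def _forest_plot(df: pd.DataFrame, path: Path, use_scb: bool = False) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{t} / {g}" for t, g in zip(df["target"], df["subgroup"])]
    y = np.arange(len(df))[::-1]
    fig, ax = plt.subplots(figsize=(6, 1 + 0.4 * len(df)))
    lo_col, hi_col = (("scb_low", "scb_high") if use_scb
                      and np.isfinite(df["scb_low"]).all()
                      else ("ci_low", "ci_high"))
    ax.errorbar(
        df["estimate"], y,
        xerr=[df["estimate"] - df[lo_col], df[hi_col] - df["estimate"]],
        fmt="s", color="black", ecolor="black", capsize=3,
    )
    ax.set_yticks(y)
    ax.set_yticklabels(labels)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("treatment effect")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run(config: RunConfig, use_scb_in_plot: bool = False) -> dict:
    """Execute one analysis and write its result bundle to disk.

    Returns a dict with the output paths and in-memory tables.  Raises
    :class:`~causalmeta.data_model.ValidationError` (listing every violated
    rule) on invalid input.
    """
    import warnings as _warnings

    data, external = _load_inputs(config)
    report = validate_inputs(data, external, config.spec)
    report.raise_if_fatal()

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    caught: list[str] = list(report.warnings)
    fits = None
    with _warnings.catch_warnings(record=True) as wrec:
        _warnings.simplefilter("always")
        if config.crossfit.enabled:
            estimates = crossfit_estimate(data, external, config.spec,
                                          config.crossfit)
        else:
            fits = fit_nuisances(data, external, config.spec)
            from .estimators import effect
            estimates = effect(data, external, fits, config.spec)
        caught.extend(str(w.message) for w in wrec)

    tables = estimates_to_frames(estimates, level=config.spec.level)
    paths = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = str(p)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "analysis": config.analysis,
        "seed": config.spec.seed,
        "cross_fitting": config.crossfit.enabled,
        "replications": config.crossfit.replications if config.crossfit.enabled else None,
        "clip_counts": fits.clip_counts if fits is not None else None,
        "warnings": caught,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = str(outdir / "manifest.json")

    summary = _summary_text(config, tables, caught)
    (outdir / "summary.txt").write_text(summary)
    paths["summary"] = str(outdir / "summary.txt")

    if config.spec.target == "internal":
        forest = tables["df_dif"].copy()
        fp = outdir / "forest_data.csv"
        forest.to_csv(fp, index=False, float_format="%.10g")
        paths["forest_data"] = str(fp)
        _forest_plot(forest, outdir / "forest.png", use_scb=use_scb_in_plot)
        paths["forest_plot"] = str(outdir / "forest.png")

    return {"paths": paths, "tables": tables, "estimates": estimates,
            "fits": fits, "summary": summary}


def fitted_model_report(fits: Optional[NuisanceFits]) -> pd.DataFrame:
    """Diagnostics for the fitted working models of a non-cross-fit run:
    stacking weights and CV risks per nuisance, plus clip counts.

    After a cross-fit run the per-replication models are not retained;
    requesting the report then raises with an explicit notice (fit once
    without cross-fitting to inspect the working models).
    """
    if fits is None or not fits.models:
        raise ValueError(
            "fitted working models are unavailable under cross-fitting; "
            "re-run with cross-fitting disabled to inspect them"
        )
    rows = []

    def _add(nuisance, slfit):
        if slfit is None:
            return
        for name, w, r in zip(slfit.learner_names, slfit.weights, slfit.cv_risks):
            rows.append({"nuisance": nuisance, "learner": name,
                         "weight": float(w), "cv_risk": float(r)})

    outcome = fits.models.get("outcome")
    if outcome is not None:
        for a in (0, 1):
            _add(f"outcome_arm{a}", outcome.fits[a])
    treatment = fits.models.get("treatment")
    if treatment is not None:
        if treatment.kind == "joint":
            _add("treatment", treatment.joint_fit)
        else:
            for s, f in treatment.per_source.items():
                _add(f"treatment[{s}]", f)
    _add("external", fits.models.get("external"))
    df = pd.DataFrame(rows)
    df.attrs["clip_counts"] = fits.clip_counts
    return df
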