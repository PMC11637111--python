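"""End-to-end analysis orchestration: load, diagnose, fit, compare.

Runs the whole real-data workflow -- descriptive statistics, diagnosis
frequencies, multicollinearity diagnostics, one coefficient table per
requested model, deviance-residual summaries and the AIC/BIC comparison --
and writes every artifact as CSV plus a JSON manifest stamped with the
configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beta_family, gam, linear_ridge, selection
from .data_io import Dataset, load_table, prepare_beta_response
from .synthetic import gen_wdbc_like

__all__ = ["RunConfig", "run_analysis", "run_simulation"]

log = logging.getLogger("betaridge")

DEFAULT_MODELS = (
    {"name": "gam"},
    {"name": "beta"},
    {"name": "gam_beta"},
    {"name": "ridge", "k": "auto"},
    {"name": "beta_ridge", "k": 0.01},
)

MODEL_LABELS = {
    "ols": "OLS",
    "gam": "GAM",
    "beta": "Beta",
    "gam_beta": "GAM Beta",
    "ridge": "Ridge",
    "beta_ridge": "Beta Ridge",
}


@dataclass
class RunConfig:
    """Configuration of one analysis run (file input XOR generator block)."""

    input: str | None = None
    generator: dict | None = None
    response: str = "radius_mean"
    predictors: list | None = None
    beta_scale: float = 100.0
    models: list = field(default_factory=lambda: [dict(m) for m in DEFAULT_MODELS])
    outdir: str = "betaridge_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input is None) == (self.generator is None):
            raise ValueError(
                "exactly one of 'input' and 'generator' must be configured"
            )
        if not self.models:
            raise ValueError("model list must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ValueError(f"malformed YAML config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_stage(config: RunConfig) -> Dataset:
    if config.input is not None:
        probe = pd.read_csv(config.input, nrows=0)
        predictors = config.predictors or [
            c for c in probe.columns if c != config.response
        ]
        return load_table(config.input, config.response, predictors)
    genspec = dict(config.generator)
    kind = genspec.pop("kind", "wdbc_like")
    if kind != "wdbc_like":
        raise ValueError(f"unknown generator kind {kind!r}")
    data = gen_wdbc_like(int(genspec.get("n", 569)), seed=config.seed)
    if config.predictors:
        data = Dataset(
            data.X[list(config.predictors)], data.y, data.family_hint,
            data.response_name, data.provenance,
        )
    return data


def _beta_dataset(data: Dataset, scale: float) -> Dataset:
    return Dataset(
        data.X,
        prepare_beta_response(data.y, scale),
        family_hint="unit_interval",
        response_name=data.response_name,
        provenance=data.provenance,
    )


def _fit_one(spec: dict, data: Dataset, data_unit: Dataset):
    name = spec["name"]
    k = spec.get("k", "auto")
    k_pol = "hoerl_kennard" if k == "auto" else float(k)
    if name == "ols":
        return linear_ridge.fit_ols(data)
    if name == "ridge":
        return linear_ridge.fit_ridge(data, k_policy=k_pol)
    if name == "beta":
        return beta_family.fit_beta_ml(data_unit)
    if name == "beta_ridge":
        pol = "hoerl_kennard_analogue" if k == "auto" else float(k)
        return beta_family.fit_beta_ridge(data_unit, k_policy=pol)
    if name == "gam":
        return gam.fit_gam(data, spec.get("terms"), family="gaussian")
    if name == "gam_beta":
        return gam.fit_gam(data_unit, spec.get("terms"), family="beta")
    raise ValueError(f"unknown model {name!r}")


def _coefficient_table(fit) -> pd.DataFrame:
    if isinstance(fit, linear_ridge.RidgeFit):
        rows = pd.DataFrame(
            {
                "term": fit.params.index,
                "estimate": fit.params.to_numpy(),
                "estimate_sc": [np.nan] + list(fit.params_sc),
                "se_sc": [np.nan] + list(fit.bse_sc),
                "t_sc": [np.nan] + list(fit.tvalues_sc),
                "p": [np.nan] + list(fit.pvalues),
            }
        )
        return rows
    if isinstance(fit, beta_family.BetaRidgeFit):
        return pd.DataFrame(
            {"term": fit.params.index, "estimate": fit.params.to_numpy()}
        )
    if isinstance(fit, beta_family.BetaFit):
        return pd.DataFrame(
            {
                "term": fit.params.index,
                "estimate": fit.params.to_numpy(),
                "se": fit.bse.to_numpy(),
                "z": fit.zvalues.to_numpy(),
                "p": fit.pvalues.to_numpy(),
            }
        )
    if isinstance(fit, gam.GamFit):
        out = pd.DataFrame(
            {"term": fit.params.index, "estimate": fit.params.to_numpy()}
        )
        return out
    return pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )


def _five_number(resid: np.ndarray) -> dict:
    q = np.quantile(resid, [0.0, 0.25, 0.5, 0.75, 1.0])
    return dict(zip(["min", "q1", "median", "q3", "max"], map(float, q)))


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Any stage failure aborts with the stage name and removes partial
    outputs.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    stage = "load"

    def write(name: str, frame: pd.DataFrame):
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.6g")
        artifacts.append(name)

    try:
        log.info("stage: load")
        data = _load_stage(config)
        data_unit = _beta_dataset(data, config.beta_scale)

        stage = "describe"
        log.info("stage: describe")
        desc = data.to_frame().describe().T.reset_index(names="variable")
        write("descriptives.csv", desc)
        if "diagnosis" in data.X.columns:
            freq = (
                data.X["diagnosis"].value_counts().rename_axis("level")
                .to_frame("frequency").reset_index()
            )
            freq["percent"] = 100.0 * freq["frequency"] / len(data.X)
            write("diagnosis_frequencies.csv", freq)

        stage = "diagnose"
        log.info("stage: diagnose")
        report = selection.diagnose(data)
        write("correlation_matrix.csv",
              report.correlation.reset_index(names="variable"))
        write("vif.csv", report.vif.rename("vif").rename_axis("variable").reset_index())
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(
                {
                    "condition_number": report.condition_number,
                    "high_vif": report.high_vif,
                    "high_correlation_pairs": [
                        list(p) for p in report.high_correlation_pairs
                    ],
                },
                fh, indent=2,
            )
        artifacts.append("diagnostics.json")

        stage = "fit"
        fits = {}
        resid_rows = []
        for spec in config.models:
            label = MODEL_LABELS[spec["name"]]
            log.info("stage: fit %s", label)
            fit = _fit_one(spec, data, data_unit)
            fits[label] = fit
            write(f"coefficients_{spec['name']}.csv", _coefficient_table(fit))
            if isinstance(fit, beta_family.BetaFit):
                resid = beta_family.beta_deviance_residuals(fit)
            elif isinstance(fit, beta_family.BetaRidgeFit):
                y = fit.ml_fit.y
                gap = 2.0 * (
                    beta_family.beta_logpdf(
                        y, beta_family.saturated_mean(y, fit.ml_fit.phi),
                        fit.ml_fit.phi,
                    )
                    - beta_family.beta_logpdf(y, fit.fittedvalues, fit.ml_fit.phi)
                )
                resid = np.sign(y - fit.fittedvalues) * np.sqrt(
                    np.clip(gap, 0.0, np.inf)
                )
            elif isinstance(fit, gam.GamFit):
                resid = gam.gam_deviance_residuals(fit)
            else:
                resid = fit.resid
            resid_rows.append({"model": label, **_five_number(resid)})
        write("deviance_residuals_summary.csv", pd.DataFrame(resid_rows))

        stage = "compare"
        log.info("stage: compare")
        report = selection.compare_models(fits, n=data.n)
        write("model_comparison.csv", report.table)

        manifest = {
            "config_hash": config.digest(),
            "seed": config.seed,
            "n": data.n,
            "p": data.p,
            "aic_winner": report.aic_winner,
            "bic_winner": report.bic_winner,
            "artifacts": artifacts,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception as exc:
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"analysis failed in stage '{stage}': {exc}") from exc


def run_simulation(config_path, outdir, seed: int | None = None) -> dict:
    """Run a sweep from a YAML config; write long, pivot and marginal CSVs."""
    import yaml

    from .simulation import summarize, sweep
    from .synthetic import SimulationConfig

    with open(config_path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed YAML config {config_path}: {exc}") from exc
    known = {"n_grid", "rho_grid", "k_grid", "reps", "seed", "n", "p", "rho",
             "beta_true", "phi_true", "ridge_k", "D"}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown simulation config keys: {sorted(bad)}")
    base = SimulationConfig(
        p=int(raw.get("p", 4)),
        beta_true=np.asarray(
            raw.get("beta_true", [3.0, 0.5, 0.5, 0.5, 0.5]), dtype=float
        ),
        phi_true=float(raw.get("phi_true", 15.0)),
        reps=int(raw.get("reps", 1000)),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
    )
    table = sweep(
        raw.get("n_grid", [25, 50, 100, 200]),
        raw.get("rho_grid", [0.7, 0.8, 0.9]),
        raw.get("k_grid", [0.0, 0.01, 0.1]),
        base_config=base,
        reps=base.reps,
        seed=base.seed,
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "simulation_long.csv", index=False)
    pivot = table.pivot_table(
        index=["rho", "k", "model"], columns="n",
        values=["mean_aic", "mean_bic"],
    )
    pivot.to_csv(outdir / "simulation_pivot.csv")
    for margin in ("n", "rho", "k"):
        summarize(table, margin).to_csv(
            outdir / f"summary_by_{margin}.csv", index=False
        )
    return {"cells": int(len(table) / 5), "outdir": str(outdir)}
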