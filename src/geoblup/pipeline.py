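"""End-to-end orchestration: extrapolate -> fit -> predict -> compare.

A run reads the genotype/phenotype(/pedigree/TBV) files, performs the
stage-1 logistic extrapolation to the target time, fits each requested
covariance model by REML, writes GEBV tables and the comparison report,
and records a machine-readable provenance file (config, package version,
design defaults, stabilization notes).  Reruns with identical inputs and
config produce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .evaluate import comparison_table, render_report
from .growth import Stage1Result, run_stage1, series_from_long
from .kernels import KernelSpec
from .markers import GenotypeMatrix, read_genotypes
from .model import GenomicBLUPResults, ModelSpec, fit_model
from .pedigree import Pedigree
from .simulate import SimConfig, SimOutput, simulate_population

__all__ = ["RunConfig", "run_pipeline", "parse_model_spec", "write_sim_output", "parse_config_file"]

log = logging.getLogger("geoblup")


@dataclass(frozen=True)
class RunConfig:
    genotypes: str
    phenotypes: str
    outdir: str
    models: tuple[str, ...] = ("independent", "rr")
    pedigree: str | None = None
    tbv: str | None = None
    target_time: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model spec is required")
        for path, name in ((self.genotypes, "genotypes"), (self.phenotypes, "phenotypes")):
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        for path in (self.pedigree, self.tbv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")


def parse_model_spec(text: str) -> ModelSpec:
    """Parse ``kernel[:theta][+fixed][+pedigree]`` into a ModelSpec.

    Examples: ``rr``, ``gaussian``, ``gaussian:120``, ``rr+pedigree``,
    ``exponential+fixed``.
    """
    parts = text.strip().split("+")
    head = parts[0]
    theta = None
    if ":" in head:
        head, theta_s = head.split(":", 1)
        theta = float(theta_s)
    spec = ModelSpec(
        KernelSpec(head, theta),
        residual_mode="fixed" if "fixed" in parts[1:] else "pooled",
        pedigree_mode="on" if "pedigree" in parts[1:] else "off",
    )
    unknown = [p for p in parts[1:] if p not in ("fixed", "pedigree")]
    if unknown:
        raise ValueError(f"unknown model-spec modifiers {unknown} in {text!r}")
    return spec


def parse_config_file(path) -> dict:
    """Flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_sim_output(sim: SimOutput, outdir) -> dict:
    """Write a simulated population in the file dialects the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "pedigree": outdir / "pedigree.csv",
        "tbv": outdir / "tbv.csv",
        "truth": outdir / "true_target.csv",
    }
    geno = sim.genotypes.to_frame().astype(int)
    geno.to_csv(paths["genotypes"])
    sim.phenotypes.to_csv(paths["phenotypes"], index=False)
    ped = sim.pedigree.table[["father", "mother"]].reset_index()
    ped.to_csv(paths["pedigree"], index=False)
    sim.tbv.rename_axis("individual").to_csv(paths["tbv"])
    sim.true_target.rename_axis("individual").to_csv(paths["truth"])
    (outdir / "sim_params.json").write_text(json.dumps(sim.params, indent=2))
    return {k: str(v) for k, v in paths.items()}


def _read_tbv(path) -> pd.Series:
    t = pd.read_csv(path, index_col=0)
    t.index = t.index.map(str)
    return t.iloc[:, 0]


def run_pipeline(config: RunConfig) -> Path:
    """Run the full study; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "package": "geoblup",
        "version": __version__,
        "config": {
            **{k: getattr(config, k) for k in (
                "genotypes", "phenotypes", "pedigree", "tbv", "target_time", "seed")},
            "models": list(config.models),
        },
        "defaults": {
            "logistic_mean": "alpha / (1 + beta * exp(-gamma * t))",
            "prediction_se": "delta method with pooled residual variance",
            "kernel_theta": "profiled REML unless fixed in the model spec",
            "gamma_stabilization": "eigenvalue clipping at 0",
            "aic_parameters": "estimated covariance parameters only",
            "gebv": "BLUP of mu + g (+ father/mother/cross effects when fitted > 0)",
        },
        "stages": {},
    }

    log.info("reading inputs")
    genotypes = read_genotypes(config.genotypes)
    phenotypes = pd.read_csv(config.phenotypes)
    pedigree = Pedigree.read_csv(config.pedigree) if config.pedigree else None
    tbv = _read_tbv(config.tbv) if config.tbv else None

    log.info("stage 1: logistic extrapolation to t=%s", config.target_time)
    try:
        stage1 = run_stage1(series_from_long(phenotypes), config.target_time)
    except Exception as exc:
        raise RuntimeError(f"stage 1 (extrapolation) failed: {exc}") from exc
    stage1.to_csv(outdir / "stage1.csv")
    provenance["stages"]["stage1"] = {
        "pooled_variance": stage1.pooled_variance,
        "pooled_df": stage1.pooled_df,
        "n_individuals": stage1.n_individuals,
        "failures": list(stage1.failures),
    }

    fits: dict[str, GenomicBLUPResults] = {}
    for text in config.models:
        spec = parse_model_spec(text)
        log.info("fitting model %s", spec.label)
        try:
            res = fit_model(
                spec,
                stage1.predictions,
                genotypes,
                error_variances=stage1.error_variances,
                pedigree=pedigree,
            )
        except Exception as exc:
            raise RuntimeError(f"fit stage failed for model {text!r}: {exc}") from exc
        fits[spec.label] = res
        safe = spec.label.replace("+", "_")
        (outdir / f"fit_{safe}.json").write_text(json.dumps(res.to_dict(), indent=2))
        res.gebv_table().to_csv(outdir / f"gebv_{safe}.csv")
        (outdir / f"summary_{safe}.txt").write_text(res.summary() + "\n")

    log.info("comparing %d models", len(fits))
    table = comparison_table(fits, stage1, tbv)
    table.to_csv(outdir / "comparison.csv")
    (outdir / "report.txt").write_text(render_report(table) + "\n")
    provenance["stages"]["compare"] = {"aic_best": table["aic"].idxmin()}
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return outdir
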