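"""Run configuration, orchestration and file emission.

A run is described by a YAML (or JSON) configuration carrying the population
parameters plus execution settings (seed, replicates, output directory).  The
orchestrator solves the coefficients once, simulates each replicate with a
derived seed, summarises it, and writes:

    <output_dir>/
      config_echo.yaml      exact configuration used (re-runnable)
      coefficients.json     solved coefficients + targets + residuals
      run.log               seeds, residuals, wall time, summary blocks
      replicate_<k>/
        dataset.tsv         id, G*, E*, [risk,] status
        summary.json        empirical measures vs the requested ones

All emitted data files are deterministic functions of (config, seed); the log
additionally records wall time, which is informational only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mlm import EnvironmentDistribution, GeneralCoefficientTable
from .population import Dataset, hwe_genotype_freqs, sample_allele_freqs, simulate
from .solver import (
    ConstraintViolationError,
    InconsistentSpecError,
    InfeasibleParametersError,
    InteractionModel,
    PopulationSpec,
    solve_coefficients,
)
from .summaries import summarize

__all__ = ["RunConfig", "load_config", "build_config", "run", "read_dataset_tsv"]

logger = logging.getLogger("gxesim")

_DEFAULTS = {
    "seed": 0,
    "replicates": 1,
    "output_dir": "gxesim_out",
    "emit_risk": False,
    "rr31": 1.0,
    "w": 0.0,
    "env_or": 1.0,
    "causal_gene_index": 0,
    "causal_env_index": 0,
}


@dataclass
class RunConfig:
    spec: PopulationSpec
    seed: int = 0
    output_dir: Path = Path("gxesim_out")
    emit_risk: bool = False
    replicates: int = 1
    custom_table: GeneralCoefficientTable | None = None
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.spec.model is InteractionModel.CUSTOM and self.custom_table is None:
            raise ValueError("CUSTOM model requires a coefficient table path")


def _freqs_entry(entry, rng: np.random.Generator) -> tuple[float, float, float]:
    """One genotype-frequency triple from a config entry.

    Accepts an explicit ``[P1, P2, P3]`` triple, a scalar allele frequency
    (expanded by Hardy-Weinberg), or ``null``/``"random"`` for an allele
    frequency drawn uniformly from [0.1, 0.9].
    """
    if entry is None or entry == "random":
        p = float(sample_allele_freqs(1, rng)[0])
        logger.info("allele frequency not given; randomly selected %.4f", p)
        return hwe_genotype_freqs(p)
    if np.isscalar(entry):
        return hwe_genotype_freqs(float(entry))
    t = tuple(float(v) for v in entry)
    if len(t) != 3:
        raise ValueError(f"genotype_freqs entry must be a triple, got {entry!r}")
    return t


def build_config(raw: dict, base_dir: Path | str = ".") -> RunConfig:
    """Validate a raw configuration mapping into a :class:`RunConfig`.

    Missing execution settings fall back to defaults (logged); the population
    parameters themselves must be present except where a documented default
    exists (rr31=1, w=0, env_or=1, causal indices 0).
    """
    base_dir = Path(base_dir)
    raw = dict(raw)
    cfg = {**_DEFAULTS, **raw}
    for key, val in _DEFAULTS.items():
        if key not in raw:
            logger.info("config: %s not given, defaulting to %r", key, val)

    for required in ("n_individuals", "model"):
        if required not in cfg:
            raise ValueError(f"config is missing required field '{required}'")
    model = InteractionModel(str(cfg["model"]).upper())
    if "m" in cfg:
        cfg.setdefault("disease_freq", cfg["m"])
    if "disease_freq" not in cfg:
        raise ValueError("config is missing required field 'disease_freq' (alias 'm')")
    m = float(cfg["disease_freq"])
    if not 0.0 < m < 1.0:
        raise ValueError("disease_freq must lie in (0,1)")

    seed = int(cfg["seed"])
    # dedicated stream for randomly selected allele frequencies, independent
    # of the simulation streams
    freq_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1000,)))

    n_genes = int(cfg.get("n_genes", 0))
    entries = list(cfg.get("genotype_freqs", []))
    n_genes = max(n_genes, len(entries), 1)
    while len(entries) < n_genes:
        entries.append(None)
    genotype_freqs = tuple(_freqs_entry(e, freq_rng) for e in entries)

    n_envs = int(cfg.get("n_envs", 0))
    env_entries = list(cfg.get("environments", []))
    n_envs = max(n_envs, len(env_entries), 1)
    while len(env_entries) < n_envs:
        logger.info("config: environment %d not given, defaulting to normal(0,1)",
                    len(env_entries) + 1)
        env_entries.append({"kind": "normal", "mean": 0.0, "sd": 1.0})
    env_dists = tuple(EnvironmentDistribution.from_dict(e) for e in env_entries)

    table = None
    if cfg.get("custom_table") is not None:
        tpath = Path(cfg["custom_table"])
        if not tpath.is_absolute():
            tpath = base_dir / tpath
        table = GeneralCoefficientTable.from_json(tpath)
    if model is InteractionModel.CUSTOM and table is None:
        raise ValueError("CUSTOM model requires a 'custom_table' path")

    spec = PopulationSpec(
        n_individuals=int(cfg["n_individuals"]),
        genotype_freqs=genotype_freqs,
        env_dists=env_dists,
        disease_freq=m,
        model=model,
        rr31=float(cfg["rr31"]),
        w=float(cfg["w"]),
        env_or=float(cfg["env_or"]),
        causal_gene_index=int(cfg["causal_gene_index"]),
        causal_env_index=int(cfg["causal_env_index"]),
    )
    return RunConfig(
        spec=spec,
        seed=seed,
        output_dir=Path(cfg["output_dir"]),
        emit_risk=bool(cfg["emit_risk"]),
        replicates=int(cfg["replicates"]),
        custom_table=table,
        raw=raw,
    )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML or JSON run configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"configuration in {path} is not a mapping")
    return build_config(raw, base_dir=path.parent)


def _echo_dict(config: RunConfig) -> dict:
    d = config.spec.to_dict()
    d.update(
        seed=config.seed,
        replicates=config.replicates,
        output_dir=str(config.output_dir),
        emit_risk=config.emit_risk,
    )
    if config.custom_table is not None:
        d["custom_table_inline"] = config.custom_table.to_dict()
    return d


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run(config: RunConfig) -> int:
    """Execute a full run; returns 0 on success, 1 on infeasible parameters.

    The coefficient solve happens before any file is created, so an
    infeasible or inconsistent specification produces a diagnostic and no
    partial outputs.
    """
    t0 = time.perf_counter()
    spec = config.spec
    try:
        result = (
            None
            if spec.model is InteractionModel.CUSTOM
            else solve_coefficients(spec)
        )
    except (InfeasibleParametersError, InconsistentSpecError, ConstraintViolationError) as exc:
        logger.error("parametrization failed: %s", exc)
        return 1

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    echo = _echo_dict(config)
    (out / "config_echo.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    digest = hashlib.sha256(
        json.dumps(echo, sort_keys=True).encode()
    ).hexdigest()

    log_lines = [f"spec sha256: {digest}", f"root seed: {config.seed}"]
    if result is not None:
        _write_json(out / "coefficients.json", result.to_dict())
        log_lines.append(
            f"solver residual: {result.max_residual:.3e} (model {result.model.value})"
        )
    else:
        _write_json(out / "coefficients.json",
                    {"model": "CUSTOM", "table": config.custom_table.to_dict()})
        log_lines.append("custom coefficient table supplied; no solving")

    for k in range(config.replicates):
        rep_seed = config.seed + k
        ds = simulate(spec, rep_seed, coefficient_table=config.custom_table)
        rep_dir = out / f"replicate_{k + 1}"
        rep_dir.mkdir(exist_ok=True)
        ds.to_tsv(rep_dir / "dataset.tsv", include_risk=config.emit_risk)
        report = summarize(ds, spec)
        _write_json(rep_dir / "summary.json", report.to_dict())
        log_lines.append(f"--- replicate {k + 1} (seed {rep_seed}) ---")
        log_lines.append(report.render())
        logger.info("replicate %d written to %s", k + 1, rep_dir)

    log_lines.append(f"wall time: {time.perf_counter() - t0:.2f} s (informational)")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return 0


def read_dataset_tsv(path) -> Dataset:
    """Load a dataset previously written by :meth:`Dataset.to_tsv`."""
    df = pd.read_csv(path, sep="\t")
    gcols = sorted((c for c in df.columns if c.startswith("G")), key=lambda c: int(c[1:]))
    ecols = sorted((c for c in df.columns if c.startswith("E")), key=lambda c: int(c[1:]))
    if not gcols or not ecols or "status" not in df.columns:
        raise ValueError(f"{path} is not a simulator dataset (need G*, E*, status)")
    return Dataset(
        genotypes=df[gcols].to_numpy() + 1,  # risk-allele counts back to 1..3
        exposures=df[ecols].to_numpy(dtype=float),
        risk=df["risk"].to_numpy(dtype=float) if "risk" in df.columns else None,
        status=df["status"].to_numpy(),
        provenance={"source": str(path)},
    )
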