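"""End-to-end pipeline: merge -> select -> harmonize -> partition -> MR (-> simulate).

The pipeline is a pure function of (inputs, config, seed): rerunning with
the same configuration produces a bit-identical output bundle.  Every
stage writes a tab-separated table and a JSON manifest records inputs,
thresholds, seed and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigError, InsufficientInstrumentsError
from .gwas_io import (
    EXPOSURES,
    merge_by_snpid,
    read_table,
    read_trait_table,
    write_table,
)
from .harmonize import build_beta_table
from .mr import mvmr, single_variable_suite
from .nullsim import NullSimConfig, run_simulation_grid
from .pleiotropy import partition_table
from .selection import Thresholds, apply_thresholds

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    ``inputs`` maps each trait to ``{"path": ..., "dialect": ...}``;
    alternatively ``merged_path`` points at an already merged table.
    ``methods`` picks the estimators; MVMR runs on the total, shared and
    unique subsets, the single-variable suite per exposure on the total
    set.
    """

    out_dir: str = "lipidmr_out"
    inputs: dict = field(default_factory=dict)
    merged_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    partition_p: float = 5e-08
    methods: tuple = ("mvmr", "ivw", "egger", "simple_median", "weighted_median")
    mvmr_weighted: bool = True
    mvmr_intercept: bool = False
    simulation: NullSimConfig | None = None
    seed: int = 0
    n_boot: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        if raw.get("simulation"):
            sim = dict(raw["simulation"])
            for key in ("pc_grid", "pd_grid"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = NullSimConfig(**sim)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory handles to every stage output plus written paths."""

    merged: object
    selected: object
    beta_table: object
    partition: object
    mr_results: object  # DataFrame: method x exposure x subset
    sim_summary: object = None
    paths: dict = field(default_factory=dict)


def _load_merged(config: PipelineConfig):
    if config.merged_path:
        return read_table(config.merged_path)
    if not config.inputs:
        raise ConfigError("config needs either merged_path or per-trait inputs")
    tables = []
    for trait, spec in config.inputs.items():
        dialect = spec.get("dialect", "cad" if trait.lower() == "cad" else "lipid")
        tables.append(read_trait_table(spec["path"], trait, dialect))
    return merge_by_snpid(tables)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage, writing one table per stage plus a manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = {"seed": config.seed, "lipidmr": __version__}
    paths: dict[str, str] = {}

    merged = _load_merged(config)
    selected = apply_thresholds(merged, config.thresholds, reference=merged)
    if len(selected) == 0:
        raise InsufficientInstrumentsError("stage 'select': no SNP passed the thresholds")
    beta_table = build_beta_table(selected)
    partition = partition_table(beta_table, config.partition_p)

    subsets = {
        "total": beta_table,
        "shared": beta_table[beta_table["snp_id"].isin(partition.shared)],
        "unique": beta_table[beta_table["snp_id"].isin(partition.unique)],
    }
    mr_rows = []
    for subset_name, subset in subsets.items():
        if "mvmr" in config.methods and len(subset) >= 4:
            result = mvmr(
                subset, weighted=config.mvmr_weighted, intercept=config.mvmr_intercept
            )
            frame = result.to_frame()
            frame["subset"] = subset_name
            mr_rows.append(frame)
        single = [m for m in config.methods if m != "mvmr"]
        if single and subset_name == "total":
            for x in EXPOSURES:
                try:
                    suite = single_variable_suite(
                        subset, x, p_threshold=config.partition_p,
                        n_boot=config.n_boot, seed=config.seed,
                    )
                except InsufficientInstrumentsError:
                    logger.warning("too few instruments for exposure %s", x)
                    continue
                frame = suite.to_frame()
                frame = frame[frame["method"].isin(single + ["egger_intercept"])]
                frame["subset"] = subset_name
                mr_rows.append(frame)

    mr_results = pd.concat(mr_rows, ignore_index=True) if mr_rows else pd.DataFrame()

    sim_summary = None
    if config.simulation is not None:
        sim_summary = run_simulation_grid(merged, selected, config.simulation)

    # --- write bundle ----------------------------------------------------
    write_table(merged, out_dir / "merged.tsv", prov)
    paths["merged"] = str(out_dir / "merged.tsv")
    write_table(selected, out_dir / "selected.tsv", prov)
    paths["selected"] = str(out_dir / "selected.tsv")
    write_table(beta_table, out_dir / "beta_table.tsv", prov)
    paths["beta_table"] = str(out_dir / "beta_table.tsv")
    venn = pd.DataFrame(
        [{"region": k, "count": v} for k, v in partition.venn.items()]
    )
    write_table(venn, out_dir / "venn.tsv", prov)
    paths["venn"] = str(out_dir / "venn.tsv")
    for name in ("shared", "unique"):
        subset = subsets[name]
        if len(subset):
            write_table(subset, out_dir / f"{name}.tsv", prov)
            paths[name] = str(out_dir / f"{name}.tsv")
    if len(mr_results):
        write_table(mr_results, out_dir / "mr_results.tsv", prov)
        paths["mr_results"] = str(out_dir / "mr_results.tsv")
    if sim_summary is not None:
        write_table(sim_summary.summary, out_dir / "sim_summary.tsv", prov)
        paths["sim_summary"] = str(out_dir / "sim_summary.tsv")

    manifest = {
        "lipidmr": __version__,
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
        "partition_p": config.partition_p,
        "methods": list(config.methods),
        "inputs": config.inputs or {"merged_path": config.merged_path},
        "n_merged": int(len(merged)),
        "n_selected": int(len(selected)),
        "venn": partition.venn,
        "outputs": paths,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = str(manifest_path)

    return PipelineResult(
        merged=merged,
        selected=selected,
        beta_table=beta_table,
        partition=partition,
        mr_results=mr_results,
        sim_summary=sim_summary,
        paths=paths,
    )
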