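"""Readers, writers, configuration and run manifests.

CSV is the canonical interchange format: genotypes as a lines x markers
table ("NA" = missing call), phenotypes long-format with columns
(line, env, year, site_group, value), the GRM as a square line-indexed
table.  VCF genotype input is an optional convenience (requires cyvcf2).
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cv import EnrichmentSpec, ScenarioPlan, standard_enrichment
from .model import MCMCSettings

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "read_genotypes_vcf",
    "read_grm",
    "write_grm",
    "load_scenario_config",
    "RunManifest",
]

PHENO_COLUMNS = ["line", "env", "year", "site_group", "value"]


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a long-format phenotype (BLUE) table.

    Requires columns (line, env, year, site_group, value); duplicate
    (line, env) rows are an error naming the pair; missing trait values are
    permitted and left as NaN.
    """
    df = pd.read_csv(path, dtype={c: str for c in PHENO_COLUMNS[:-1]})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.isna() & df["value"].notna() & (df["value"].astype(str).str.strip() != "")
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable trait values at file rows {rows[:5]}")
    df["value"] = vals
    dup = df.duplicated(subset=["line", "env"], keep=False)
    if dup.any():
        pair = tuple(df.loc[dup, ["line", "env"]].iloc[0])
        raise ValueError(f"{path}: duplicated (line, env) record {pair}")
    return df[PHENO_COLUMNS]


def write_phenotypes(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[PHENO_COLUMNS].to_csv(path, index=False)


def read_genotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Lines x markers dosage CSV; first column line ids, 'NA' = missing."""
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df.index.name = "line"
    from .genotypes import validate_markers

    return validate_markers(df.astype(float))


def write_genotypes(m: pd.DataFrame, path: str | os.PathLike) -> None:
    m.to_csv(path, na_rep="NA")


def read_genotypes_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read a VCF into a lines x markers dosage matrix (alt-allele count).

    Diploid GT fields map to 0/1/2; any missing allele ('./.') maps to a
    missing call.  Requires cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, cols = [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        marker_ids.append(vid)
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        cols.append(dos)
    if not cols:
        raise ValueError(f"{path}: no variants found")
    mat = np.column_stack(cols)
    return pd.DataFrame(
        mat, index=pd.Index(samples, name="line"), columns=marker_ids
    )


def read_grm(path: str | os.PathLike) -> pd.DataFrame:
    g = pd.read_csv(path, index_col=0)
    g.index = g.index.astype(str)
    g.columns = g.columns.astype(str)
    from .genotypes import validate_grm

    return validate_grm(g)


def write_grm(g: pd.DataFrame, path: str | os.PathLike) -> None:
    g.to_csv(path)


def _enrichment_from_config(cfg, target_dataset: str) -> EnrichmentSpec | None:
    if cfg in (None, "none", False):
        return None
    if cfg == "standard":
        return standard_enrichment(target_dataset)
    if isinstance(cfg, dict) and "previous" in cfg:
        return standard_enrichment(target_dataset, list(cfg["previous"]))
    if isinstance(cfg, list):
        return EnrichmentSpec(
            [(s["dataset"], s.get("envs", "both"), bool(s.get("all_lines", True)))
             for s in cfg]
        )
    raise ValueError(f"cannot parse enrichment config: {cfg!r}")


def load_scenario_config(path: str | os.PathLike) -> tuple[ScenarioPlan, dict]:
    """Parse a YAML scenario config into a ScenarioPlan.

    Returns (plan, raw config dict).  Validation failures raise before any
    compute.  Expected keys: target_dataset (required), target_envs,
    tst_props, n_partitions, enrichment (none | standard |
    {previous: [...]} | explicit source list), mcmc {n_iter, burn_in, thin,
    prior_df, prior_r2}, include_ge, pool_envs, seed.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "target_dataset" not in cfg:
        raise ValueError(f"{path}: config must name a target_dataset")
    mcmc_cfg = cfg.get("mcmc", {})
    mcmc = MCMCSettings(
        n_iter=int(mcmc_cfg.get("n_iter", 10_000)),
        burn_in=int(mcmc_cfg.get("burn_in", 2_000)),
        thin=int(mcmc_cfg.get("thin", 5)),
        seed=int(cfg.get("seed", 0)),
        prior_df=float(mcmc_cfg.get("prior_df", 5.0)),
        prior_r2=float(mcmc_cfg.get("prior_r2", 0.5)),
    )
    plan = ScenarioPlan(
        target_dataset=str(cfg["target_dataset"]),
        target_envs=cfg.get("target_envs"),
        tst_props=tuple(cfg.get("tst_props", (0.15, 0.30, 0.50, 0.70))),
        n_partitions=int(cfg.get("n_partitions", 10)),
        enrichment=_enrichment_from_config(
            cfg.get("enrichment"), str(cfg["target_dataset"])
        ),
        mcmc=mcmc,
        include_ge=bool(cfg.get("include_ge", True)),
        pool_envs=bool(cfg.get("pool_envs", False)),
        seed=int(cfg.get("seed", 0)),
    )
    return plan, cfg


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline stage bit-identically."""

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = ""
    timings: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)

    def add_input(self, name: str, path: str | os.PathLike) -> None:
        self.input_checksums[name] = _sha256(path)

    def time_stage(self, name: str, start: float) -> None:
        self.timings[name] = round(time.time() - start, 3)

    def write(self, path: str | os.PathLike) -> None:
        """Atomic write (temp file + rename) at run end."""
        if not self.version:
            from . import __version__

            self.version = __version__
        tmp = str(path) + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        os.replace(tmp, path)

    @classmethod
    def read(cls, path: str | os.PathLike) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
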