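"""Sparse-testing cross-validation: random holdout partitions of target-
environment lines, training-set assembly with and without enrichment, and
the full scenario loop.

Two training strategies are compared.  *GBLUP* trains only on the unmasked
target-environment records of the target dataset.  *GBLUP_Ad* additionally
pulls in whole auxiliary datasets — the target dataset's off-site
(e.g. Obregon) environments and previous-season datasets — so that test
lines, though masked in every target environment, may still be observed in
auxiliary environments: tested lines in untested environments.

Partitions are repeated random holdouts (not disjoint folds): a training
fraction of 85/70/50/30% cannot form ten mutually exclusive folds, so each
of the ``n_partitions`` draws is an independent split at the requested
testing proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_away, spawn_seed
from .metrics import pearson_cor, percent_matching
from .model import MCMCSettings, fit_gibbs
from .simulate import AUXILIARY, TARGET

logger = logging.getLogger(__name__)

__all__ = [
    "CVPartition",
    "EnrichmentSpec",
    "ScenarioPlan",
    "make_partitions",
    "mask_target",
    "assemble_training",
    "standard_enrichment",
    "run_scenario",
]

DEFAULT_TST_PROPS = (0.15, 0.30, 0.50, 0.70)


@dataclass(frozen=True)
class CVPartition:
    """One random holdout split of the target-environment line set."""

    partition_id: int
    tst_prop: float
    test_lines: frozenset
    train_lines: frozenset

    def __post_init__(self) -> None:
        if self.test_lines & self.train_lines:
            raise ValueError("test and train line sets overlap")


@dataclass
class EnrichmentSpec:
    """Auxiliary data sources appended to the training set (GBLUP_Ad).

    Each source is (dataset_label, env_filter, use_all_lines) with
    env_filter in {"target", "auxiliary", "both"} selecting the site groups
    of that dataset to include.
    """

    sources: list[tuple[str, str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, env_filter, _ in self.sources:
            if env_filter not in (TARGET, AUXILIARY, "both"):
                raise ValueError(f"unknown env_filter {env_filter!r}")


def standard_enrichment(
    target_label: str, previous_labels: list[str] | None = None
) -> EnrichmentSpec:
    """The study-style enrichment: the target dataset's auxiliary (off-site)
    environments for the current season, plus whole previous-season
    datasets (their target and auxiliary environments)."""
    sources = [(target_label, AUXILIARY, True)]
    for lbl in previous_labels or []:
        sources.append((lbl, "both", True))
    return EnrichmentSpec(sources)


@dataclass
class ScenarioPlan:
    """One sparse-testing experiment over a target dataset."""

    target_dataset: str
    target_envs: list[str] | None = None  # default: the dataset's target envs
    tst_props: tuple[float, ...] = DEFAULT_TST_PROPS
    n_partitions: int = 10
    enrichment: EnrichmentSpec | None = None
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    include_ge: bool = True
    pool_envs: bool = False  # score pooled line x env cells instead of per-env
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")
        for p in self.tst_props:
            if not 0.0 < p < 1.0:
                raise ValueError(f"tst_prop {p} outside (0, 1)")


def make_partitions(
    line_ids: list[str],
    tst_props: tuple[float, ...],
    n_partitions: int,
    seed: int = 0,
) -> list[CVPartition]:
    """Repeated random holdout splits, ``n_partitions`` per testing proportion.

    Test-set size is round(tst_prop * n) with half-away rounding; a size of
    0 or n is rejected.  Deterministic under ``seed``.
    """
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    line_ids = list(line_ids)
    n = len(line_ids)
    out = []
    for ip, prop in enumerate(tst_props):
        if not 0.0 < prop < 1.0:
            raise ValueError(f"tst_prop {prop} outside (0, 1)")
        k = round_half_away(prop * n)
        if k <= 0 or k >= n:
            raise ValueError(
                f"tst_prop {prop} with {n} lines gives test size {k}; "
                "must leave both sets non-empty"
            )
        for pid in range(1, n_partitions + 1):
            rng = np.random.default_rng(spawn_seed(seed, ip, pid))
            test = rng.choice(n, size=k, replace=False)
            test_set = frozenset(line_ids[i] for i in test)
            out.append(
                CVPartition(
                    partition_id=pid,
                    tst_prop=prop,
                    test_lines=test_set,
                    train_lines=frozenset(line_ids) - test_set,
                )
            )
    return out


def mask_target(
    pheno: pd.DataFrame, partition: CVPartition, target_envs: list[str]
) -> pd.DataFrame:
    """Flag the partition's test-line records in the target environments.

    Returns a copy with a boolean ``masked`` column; no records are
    dropped.  Test lines with no record in any target environment are
    skipped with a warning (they cannot be scored).
    """
    if not target_envs:
        raise ValueError("target_envs must be non-empty")
    out = pheno.copy().reset_index(drop=True)
    in_target = out["env"].isin(target_envs)
    out["masked"] = in_target & out["line"].isin(partition.test_lines)
    present = set(out.loc[in_target, "line"])
    absent = partition.test_lines - present
    if absent:
        logger.warning(
            "%d test line(s) absent from all target environments; skipped in "
            "scoring: %s", len(absent), sorted(absent)[:5],
        )
    return out


def assemble_training(
    masked_table: pd.DataFrame,
    enrichment: EnrichmentSpec | None,
    library: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Build the model-ready record table for one partition.

    Without enrichment the result is exactly ``masked_table`` (the target
    records, masked cells flagged).  With enrichment, every record of each
    source (filtered to the requested site groups, all lines) is appended
    as observed — except records that coincide with a masked (line, env)
    cell, which are excluded with a logged count (leakage guard).
    """
    out = masked_table.copy().reset_index(drop=True)
    if enrichment is None or not enrichment.sources:
        return out
    if library is None:
        raise ValueError("enrichment requires a phenotype library")
    masked_cells = set(
        map(tuple, out.loc[out["masked"], ["line", "env"]].itertuples(index=False))
    )
    existing = set(map(tuple, out[["line", "env"]].itertuples(index=False)))
    pieces = [out]
    for label, env_filter, use_all_lines in enrichment.sources:
        if label not in library:
            raise KeyError(f"enrichment source {label!r} not in library")
        src = library[label]
        if env_filter != "both":
            src = src[src["site_group"] == env_filter]
        keys = list(map(tuple, src[["line", "env"]].itertuples(index=False)))
        leak = [k in masked_cells for k in keys]
        dup = [k in existing for k in keys]
        n_leak = int(np.sum(leak))
        if n_leak:
            logger.warning(
                "excluded %d enrichment record(s) from %s coinciding with "
                "masked target cells", n_leak, label,
            )
        keep = ~(np.array(leak) | np.array(dup))
        src = src.loc[keep].copy()
        existing.update(k for k, kp in zip(keys, keep) if kp)
        src["masked"] = False
        pieces.append(src)
    return pd.concat(pieces, ignore_index=True)


def _score_partition(
    masked: pd.DataFrame, preds: np.ndarray, target_envs: list[str], pool: bool
) -> list[dict]:
    """COR / PM_10 / PM_20 for one fitted partition.

    Scores observed vs predicted over the masked cells, either within each
    target environment (rows per env plus an 'across_envs' average row) or
    pooled over line x env cells.
    """
    tab = masked.loc[masked["masked"], ["line", "env", "value"]].copy()
    tab["pred"] = preds
    rows = []
    if pool:
        ids = tab["line"] + "|" + tab["env"]
        rows.append(
            {
                "env_or_across": "pooled",
                "COR": pearson_cor(tab["value"], tab["pred"]),
                "PM_10": percent_matching(tab["value"], tab["pred"], 0.10, ids),
                "PM_20": percent_matching(tab["value"], tab["pred"], 0.20, ids),
            }
        )
        return rows
    per_env = []
    for env in target_envs:
        sub = tab[tab["env"] == env]
        if len(sub) < 2:
            continue
        per_env.append(
            {
                "env_or_across": env,
                "COR": pearson_cor(sub["value"], sub["pred"]),
                "PM_10": percent_matching(sub["value"], sub["pred"], 0.10, sub["line"]),
                "PM_20": percent_matching(sub["value"], sub["pred"], 0.20, sub["line"]),
            }
        )
    rows.extend(per_env)
    if per_env:
        rows.append(
            {
                "env_or_across": "across_envs",
                "COR": float(np.nanmean([r["COR"] for r in per_env])),
                "PM_10": float(np.nanmean([r["PM_10"] for r in per_env])),
                "PM_20": float(np.nanmean([r["PM_20"] for r in per_env])),
            }
        )
    return rows


def run_scenario(
    plan: ScenarioPlan,
    library: dict[str, pd.DataFrame],
    grm: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute one sparse-testing scenario end to end.

    For every testing proportion and partition: mask the test lines in the
    target environments, assemble the GBLUP training set (and the GBLUP_Ad
    set when enrichment is configured), fit the Bayesian model, predict the
    masked cells and score them.  Returns (per-cell predictions table,
    per-partition metrics table).  A failed fit flags the partition and the
    scenario continues.
    """
    if plan.target_dataset not in library:
        raise KeyError(f"target dataset {plan.target_dataset!r} not in library")
    pheno = library[plan.target_dataset]
    target_envs = plan.target_envs or sorted(
        pheno.loc[pheno["site_group"] == TARGET, "env"].unique()
    )
    if not target_envs:
        raise ValueError("no target environments found")
    target_tab = pheno[pheno["env"].isin(target_envs)].reset_index(drop=True)
    line_ids = sorted(target_tab["line"].unique())

    models: list[tuple[str, EnrichmentSpec | None]] = [("GBLUP", None)]
    if plan.enrichment is not None and plan.enrichment.sources:
        models.append(("GBLUP_Ad", plan.enrichment))

    partitions = make_partitions(
        line_ids, plan.tst_props, plan.n_partitions, seed=plan.seed
    )
    metric_rows, pred_rows = [], []
    for part in partitions:
        masked = mask_target(target_tab, part, target_envs)
        ip = list(plan.tst_props).index(part.tst_prop)
        for im, (model_name, enrich) in enumerate(models):
            train = assemble_training(masked, enrich, library)
            # leakage audit: no masked cell may be an observed training record
            obs_cells = set(
                map(tuple, train.loc[~train["masked"], ["line", "env"]]
                    .itertuples(index=False))
            )
            msk_cells = set(
                map(tuple, masked.loc[masked["masked"], ["line", "env"]]
                    .itertuples(index=False))
            )
            assert not (obs_cells & msk_cells), "masked cells leaked into training"
            fit_seed = spawn_seed(plan.seed, 100 + ip, part.partition_id, im)
            mcmc = MCMCSettings(
                n_iter=plan.mcmc.n_iter,
                burn_in=plan.mcmc.burn_in,
                thin=plan.mcmc.thin,
                seed=fit_seed,
                prior_df=plan.mcmc.prior_df,
                prior_r2=plan.mcmc.prior_r2,
            )
            used_lines = sorted(set(train["line"]) | set(masked["line"]))
            sub_grm = grm.loc[used_lines, used_lines]
            try:
                fit = fit_gibbs(train, sub_grm, mcmc, include_ge=plan.include_ge)
                cells = masked.loc[masked["masked"], ["line", "env"]]
                preds = fit.predict(cells)
            except Exception:
                logger.exception(
                    "fit failed (model=%s tst=%s partition=%d); partition flagged",
                    model_name, part.tst_prop, part.partition_id,
                )
                metric_rows.append(
                    {
                        "scenario": plan.target_dataset,
                        "dataset": plan.target_dataset,
                        "env_or_across": "across_envs",
                        "model": model_name,
                        "tst_prop": part.tst_prop,
                        "partition": part.partition_id,
                        "COR": np.nan, "PM_10": np.nan, "PM_20": np.nan,
                        "failed": True,
                    }
                )
                continue
            for (ln, ev), pr, obs_v in zip(
                masked.loc[masked["masked"], ["line", "env"]].itertuples(index=False),
                preds,
                masked.loc[masked["masked"], "value"],
            ):
                pred_rows.append(
                    {
                        "scenario": plan.target_dataset,
                        "model": model_name,
                        "tst_prop": part.tst_prop,
                        "partition": part.partition_id,
                        "line": ln,
                        "env": ev,
                        "observed": obs_v,
                        "predicted": float(pr),
                    }
                )
            for row in _score_partition(masked, preds, target_envs, plan.pool_envs):
                metric_rows.append(
                    {
                        "scenario": plan.target_dataset,
                        "dataset": plan.target_dataset,
                        "model": model_name,
                        "tst_prop": part.tst_prop,
                        "partition": part.partition_id,
                        "failed": False,
                        **row,
                    }
                )
    metrics = pd.DataFrame(metric_rows)
    preds_df = pd.DataFrame(pred_rows)
    return preds_df, metrics
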