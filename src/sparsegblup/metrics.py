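"""Selection-accuracy metrics: correlation, top-fraction matching, relative
efficiency, and per-partition summaries.

Conventions: larger trait value = better (grain yield); an undefined metric
(constant vector, zero reference) is a NaN marker, never silently 0; the
relative efficiency of model b against reference r is the percentage change
of the sign-preserving squared correlation, so a negative baseline
correlation yields a negative RE.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away

__all__ = [
    "pearson_cor",
    "percent_matching",
    "relative_efficiency",
    "summarize",
]


def _check_scored(obs, pred, ids=None):
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("obs and pred must be 1-d and of equal length")
    if len(obs) < 2:
        raise ValueError("need at least 2 scored lines")
    if ids is None:
        ids = np.arange(len(obs))
    ids = np.asarray(ids, dtype=object)
    if len(ids) != len(obs):
        raise ValueError("ids length mismatch")
    if len(set(ids)) != len(ids):
        raise ValueError("line ids must be unique")
    return obs, pred, ids


def pearson_cor(obs, pred) -> float:
    """Pearson product-moment correlation; NaN when either vector is constant."""
    obs, pred, _ = _check_scored(obs, pred)
    if np.std(obs) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(stats.pearsonr(obs, pred).statistic)


def _top_ids(values: np.ndarray, ids: np.ndarray, k: int) -> set:
    # sort by value descending; ties broken by stable id order
    order = sorted(range(len(values)), key=lambda i: (-values[i], str(ids[i])))
    return {ids[i] for i in order[:k]}


def percent_matching(obs, pred, top_frac: float, ids=None) -> float:
    """Percent overlap of the observed-top and predicted-top ``top_frac`` lines.

    k = max(1, round(top_frac * n)) with half-away rounding; returns
    100 * |top_obs ∩ top_pred| / k.
    """
    if not 0.0 < top_frac < 1.0:
        raise ValueError("top_frac must be in (0, 1)")
    obs, pred, ids = _check_scored(obs, pred, ids)
    k = max(1, round_half_away(top_frac * len(obs)))
    a = _top_ids(obs, ids, k)
    b = _top_ids(pred, ids, k)
    return 100.0 * len(a & b) / k


def _signed_square(x: float) -> float:
    return float(np.sign(x) * x * x)


def relative_efficiency(
    cor_base: float, cor_ref: float, mode: str = "squared"
) -> float:
    """Percentage change of ``cor_base`` relative to ``cor_ref``.

    mode="squared" (default) compares sign-preserving squared correlations,
    so a negative baseline yields a negative RE; mode="raw" compares the
    correlations directly.  NaN (with a warning) when the reference is 0 or
    undefined.
    """
    if mode not in ("squared", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    if np.isnan(cor_base) or np.isnan(cor_ref):
        return float("nan")
    if cor_ref == 0:
        warnings.warn("relative efficiency undefined for zero reference")
        return float("nan")
    if mode == "squared":
        b, r = _signed_square(cor_base), _signed_square(cor_ref)
    else:
        b, r = cor_base, cor_ref
    return float(100.0 * (b - r) / abs(r))


_GROUP = ["scenario", "dataset", "env_or_across", "model", "tst_prop"]
_METRICS = ["COR", "PM_10", "PM_20"]


def summarize(rows: pd.DataFrame, reference_model: str = "GBLUP_Ad") -> pd.DataFrame:
    """Fold-wise mean / sd / se summaries of a per-partition metrics table.

    ``rows`` needs columns (scenario, dataset, env_or_across, model,
    tst_prop, partition, COR, PM_10, PM_20).  For each group, reports the
    across-partition mean, sample sd (n-1), se = sd / sqrt(n) and the count
    of undefined (NaN) partitions per metric; groups with a single defined
    partition get NaN sd/se.  When both a model and ``reference_model``
    are present in a (dataset, env, tst_prop) group, relative-efficiency
    columns are added: squared-correlation RE for COR, raw percentage
    change for the matching percentages.  An ``Across`` dataset block
    averages the dataset-level means (only when several datasets are
    summarised).
    """
    req = set(_GROUP + ["partition"] + _METRICS)
    if not req.issubset(rows.columns):
        raise ValueError(f"missing columns: {sorted(req - set(rows.columns))}")

    recs = []
    for key, grp in rows.groupby(_GROUP, sort=True):
        rec = dict(zip(_GROUP, key))
        for metric in _METRICS:
            vals = grp[metric].to_numpy(dtype=float)
            ok = vals[~np.isnan(vals)]
            rec[f"{metric}_mean"] = float(np.mean(ok)) if len(ok) else float("nan")
            rec[f"{metric}_sd"] = float(np.std(ok, ddof=1)) if len(ok) > 1 else float("nan")
            rec[f"{metric}_se"] = (
                rec[f"{metric}_sd"] / np.sqrt(len(ok)) if len(ok) > 1 else float("nan")
            )
            rec[f"{metric}_n_undefined"] = int(np.isnan(vals).sum())
        recs.append(rec)
    out = pd.DataFrame(recs)

    # relative efficiencies against the reference model within each stratum
    for metric, mode in (("COR", "squared"), ("PM_10", "raw"), ("PM_20", "raw")):
        out[f"{metric}_RE"] = np.nan
    strata = ["scenario", "dataset", "env_or_across", "tst_prop"]
    for _, grp in out.groupby(strata, sort=False):
        ref_rows = grp[grp["model"] == reference_model]
        if ref_rows.empty:
            continue
        ref = ref_rows.iloc[0]
        for idx in grp.index:
            for metric, mode in (("COR", "squared"), ("PM_10", "raw"), ("PM_20", "raw")):
                base = out.at[idx, f"{metric}_mean"]
                refv = ref[f"{metric}_mean"]
                if np.isnan(base) or np.isnan(refv) or refv == 0:
                    continue
                out.at[idx, f"{metric}_RE"] = relative_efficiency(base, refv, mode)

    datasets = out["dataset"].unique()
    if len(datasets) > 1:
        across = []
        for key, grp in out.groupby(
            ["scenario", "env_or_across", "model", "tst_prop"], sort=True
        ):
            rec = {
                "scenario": key[0],
                "dataset": "Across",
                "env_or_across": key[1],
                "model": key[2],
                "tst_prop": key[3],
            }
            for metric in _METRICS:
                rec[f"{metric}_mean"] = float(np.nanmean(grp[f"{metric}_mean"]))
            across.append(rec)
        out = pd.concat([out, pd.DataFrame(across)], ignore_index=True)
    return out
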