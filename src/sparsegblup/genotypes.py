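"""Marker quality control and the genomic relationship matrix.

A marker matrix is a pandas DataFrame of allele-dosage codes {0, 1, 2}
(float, NaN = missing call) with line identifiers as the index and marker
identifiers as columns.  A genomic relationship matrix (GRM) is a square
DataFrame indexed by line on both axes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "validate_markers",
    "allele_frequencies",
    "filter_markers",
    "impute_mean",
    "compute_grm",
    "validate_grm",
]

_SYM_TOL = 1e-8
_PSD_TOL = 1e-6


def validate_markers(m: pd.DataFrame) -> pd.DataFrame:
    """Check a marker matrix: unique line ids, codes restricted to {0,1,2,NaN}."""
    if m.index.has_duplicates:
        dupes = m.index[m.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate line ids: {dupes[:5]}")
    if m.columns.has_duplicates:
        raise ValueError("duplicate marker ids")
    vals = m.to_numpy(dtype=float)
    bad = np.isfinite(vals) & ~np.isin(vals, (0.0, 1.0, 2.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype codes must be 0/1/2 or missing; found {vals[r, c]!r} "
            f"at line {m.index[r]!r}, marker {m.columns[c]!r}"
        )
    return m


def allele_frequencies(m: pd.DataFrame) -> pd.Series:
    """Per-marker alternate-allele frequency over non-missing calls."""
    return m.mean(axis=0, skipna=True) / 2.0


def filter_markers(
    m: pd.DataFrame, maf_min: float = 0.05, pmv_max: float = 0.50
) -> pd.DataFrame:
    """Drop markers failing minor-allele-frequency or missingness thresholds.

    Keeps markers with MAF >= ``maf_min`` (computed on non-missing calls;
    ties at the threshold retained) and missing fraction <= ``pmv_max``.
    Monomorphic markers are always dropped.  Marker order is preserved and
    the operation is idempotent.  Defaults mirror the common 0.05 / 50%
    thresholds used in wheat genomic-selection pipelines.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5); got {maf_min}")
    if not 0 <= pmv_max <= 1:
        raise ValueError(f"pmv_max must be in [0, 1]; got {pmv_max}")
    p = allele_frequencies(m)
    maf = np.minimum(p, 1.0 - p)
    missing = m.isna().mean(axis=0)
    keep = (maf >= maf_min) & (maf > 0) & (missing <= pmv_max) & p.notna()
    if not keep.any():
        raise ValueError(
            f"all {m.shape[1]} markers removed by QC (maf_min={maf_min}, "
            f"pmv_max={pmv_max})"
        )
    return m.loc[:, keep[keep].index]


def impute_mean(m: pd.DataFrame) -> pd.DataFrame:
    """Replace missing calls by the marker's mean dosage over observed calls."""
    all_missing = m.isna().all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"markers with no non-missing calls: "
            f"{m.columns[all_missing].tolist()[:5]}"
        )
    return m.fillna(m.mean(axis=0))


def compute_grm(m: pd.DataFrame) -> pd.DataFrame:
    """VanRaden genomic relationship matrix (method 1).

    With M the n x k dosage matrix and p the observed allele frequencies,
    W = M - 2p and G = W W' / (2 * sum_k p_k (1 - p_k)).  Requires a fully
    observed matrix (run :func:`impute_mean` first) with at least two
    polymorphic markers.
    """
    if m.isna().any().any():
        raise ValueError("marker matrix has missing calls; impute first")
    vals = m.to_numpy(dtype=float)
    p = vals.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic markers for a GRM")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM undefined")
    w = vals - 2.0 * p
    g = (w @ w.T) / denom
    g = 0.5 * (g + g.T)  # enforce exact symmetry against fp drift
    return pd.DataFrame(g, index=m.index, columns=m.index)


def validate_grm(g: pd.DataFrame, psd_tol: float = _PSD_TOL) -> pd.DataFrame:
    """Check symmetry (1e-8) and positive semidefiniteness within tolerance."""
    if g.shape[0] != g.shape[1] or not g.index.equals(g.columns):
        raise ValueError("GRM must be square with identical row/column line ids")
    a = g.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=_SYM_TOL):
        raise ValueError("GRM is not symmetric within 1e-8")
    lo = float(np.linalg.eigvalsh(a).min())
    if lo < -psd_tol:
        raise ValueError(f"GRM is not PSD within tolerance (min eigenvalue {lo:g})")
    return g
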