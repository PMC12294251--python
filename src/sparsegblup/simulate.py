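"""Synthetic multi-environment wheat-trial generator.

Emulates a two-country sparse-testing design: each dataset (a target
population of environments, TPE, in a given season) phenotypes a cohort of
lines in a handful of *target* environments (the selection country) and a
handful of *auxiliary* environments (an off-season nursery such as Obregon),
with partially overlapping cohorts between consecutive seasons.

Phenotypes are environment-level adjusted line means (BLUEs) drawn from the
additive model

    Y_ij = mu + E_i + g_j + gE_ij + eps_ij

with E_i ~ N(0, var_env) iid over environments, g ~ MVN(0, var_g * G),
gE per environment ~ MVN(0, var_ge * G) independently across environments
(the block-diagonal covariance implied by a Hadamard product of the genomic
kernel with an identity over environments), and iid residuals.  In
auxiliary environments the line effect is a correlated copy g_aux with
cor(g, g_aux) = ``aux_genetic_correlation`` and equal marginal variance —
the knob that controls how informative cross-country enrichment data are
about merit in the target environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_away, spawn_seed

__all__ = [
    "TrialDesign",
    "GenerativeParams",
    "SyntheticTruth",
    "simulate_markers",
    "simulate_phenotypes",
    "make_study_designs",
    "simulate_design_pair",
]

TARGET = "target"
AUXILIARY = "auxiliary"


@dataclass
class TrialDesign:
    """One TPE-by-season trial: a line cohort phenotyped in a set of envs."""

    tpe_label: str
    year_label: str
    n_lines: int
    envs: list[tuple[str, str]]  # (env_id, site_group in {target, auxiliary})
    line_overlap_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if not 0.0 <= self.line_overlap_fraction <= 1.0:
            raise ValueError("line_overlap_fraction must be in [0, 1]")
        groups = {g for _, g in self.envs}
        if not groups:
            raise ValueError("design needs at least one environment")
        bad = groups - {TARGET, AUXILIARY}
        if bad:
            raise ValueError(f"unknown site_group(s): {sorted(bad)}")

    @property
    def label(self) -> str:
        return f"{self.tpe_label}_{self.year_label}"

    def env_ids(self, site_group: str | None = None) -> list[str]:
        return [e for e, g in self.envs if site_group is None or g == site_group]


@dataclass
class GenerativeParams:
    """Variance components and marker settings for the generator."""

    mu: float = 6.0
    var_env: float = 0.5
    var_g: float = 1.0
    var_ge: float = 1.0
    var_e: float = 1.0
    aux_genetic_correlation: float = 0.5
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("var_env", "var_g", "var_ge", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.aux_genetic_correlation <= 1.0:
            raise ValueError("aux_genetic_correlation must be in [-1, 1]")
        _check_maf_range(self.maf_range)


@dataclass
class SyntheticTruth:
    """Latent effects realised by one phenotype simulation."""

    env_effects: dict[str, float]
    line_effects: dict[str, float]
    aux_line_effects: dict[str, float]
    ge_effects: dict[tuple[str, str], float]
    genetic_values: dict[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "line": ln,
                "env": env,
                "ge_effect": ge,
                "genetic_value": self.genetic_values[(ln, env)],
            }
            for (ln, env), ge in self.ge_effects.items()
        ]
        return pd.DataFrame(rows)


def _check_maf_range(maf_range: tuple[float, float]) -> None:
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(
            f"maf_range must satisfy 0 < lo <= hi <= 0.5; got ({lo}, {hi})"
        )


def simulate_markers(
    n_lines: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
    line_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate biallelic dosages in Hardy-Weinberg proportions.

    Each marker's allele frequency is drawn uniformly from ``maf_range``;
    genotypes are Binomial(2, p) per line; missing calls are placed
    completely at random at ``missing_rate``.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    _check_maf_range(maf_range)
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_range[0], maf_range[1], size=n_markers)
    geno = rng.binomial(2, p, size=(n_lines, n_markers)).astype(float)
    if missing_rate > 0:
        geno[rng.random((n_lines, n_markers)) < missing_rate] = np.nan
    if line_ids is None:
        line_ids = [f"L{i + 1:04d}" for i in range(n_lines)]
    cols = [f"M{j + 1:05d}" for j in range(n_markers)]
    return pd.DataFrame(geno, index=pd.Index(line_ids, name="line"), columns=cols)


def _correlated_chol(grm: pd.DataFrame) -> np.ndarray:
    """Cholesky factor of G with a small ridge for numerical PD."""
    a = grm.to_numpy(dtype=float)
    lo = float(np.linalg.eigvalsh(a).min())
    if lo < -1e-6:
        raise ValueError(f"GRM not PSD within tolerance (min eigenvalue {lo:g})")
    n = a.shape[0]
    return np.linalg.cholesky(a + 1e-8 * np.trace(a) / n * np.eye(n))


def simulate_phenotypes(
    design: TrialDesign,
    grm: pd.DataFrame,
    params: GenerativeParams,
    line_ids: list[str] | None = None,
    seed: int | None = None,
    line_effects: pd.Series | None = None,
    aux_line_effects: pd.Series | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw one phenotype table (long format) for a trial design.

    Returns a DataFrame with columns (line, env, year, site_group, value)
    — one record per line x environment — and the realised latent effects.
    ``line_ids`` selects which rows of ``grm`` form the cohort (defaults to
    the first ``design.n_lines`` lines of the GRM).  ``line_effects`` /
    ``aux_line_effects`` inject pre-drawn genetic merits (indexed by line),
    so multi-season simulations can share a single g across datasets; when
    omitted, g and its auxiliary-group copy are drawn here.
    """
    if line_ids is None:
        line_ids = list(grm.index[: design.n_lines])
    if len(line_ids) != design.n_lines:
        raise ValueError("line_ids length must equal design.n_lines")
    sub = grm.loc[line_ids, line_ids]
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = len(line_ids)
    rho = params.aux_genetic_correlation
    chol = None

    if line_effects is not None:
        g = line_effects.loc[line_ids].to_numpy(dtype=float)
        if aux_line_effects is None:
            raise ValueError("aux_line_effects required when line_effects given")
        g_aux = aux_line_effects.loc[line_ids].to_numpy(dtype=float)
    elif params.var_g > 0:
        chol = _correlated_chol(sub)
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        g = np.sqrt(params.var_g) * (chol @ z1)
        g_aux = np.sqrt(params.var_g) * (
            chol @ (rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2)
        )
    else:
        g = np.zeros(n)
        g_aux = np.zeros(n)

    env_effects: dict[str, float] = {}
    ge: dict[tuple[str, str], float] = {}
    gvals: dict[tuple[str, str], float] = {}
    rows = []
    for env_id, group in design.envs:
        e_i = rng.normal(0.0, np.sqrt(params.var_env)) if params.var_env > 0 else 0.0
        env_effects[env_id] = float(e_i)
        if params.var_ge > 0:
            if chol is None:
                chol = _correlated_chol(sub)
            ge_vec = np.sqrt(params.var_ge) * (chol @ rng.standard_normal(n))
        else:
            ge_vec = np.zeros(n)
        eps = (
            rng.normal(0.0, np.sqrt(params.var_e), size=n)
            if params.var_e > 0
            else np.zeros(n)
        )
        g_used = g if group == TARGET else g_aux
        vals = params.mu + e_i + g_used + ge_vec + eps
        for j, ln in enumerate(line_ids):
            ge[(ln, env_id)] = float(ge_vec[j])
            gvals[(ln, env_id)] = float(params.mu + e_i + g_used[j] + ge_vec[j])
            rows.append(
                {
                    "line": ln,
                    "env": env_id,
                    "year": design.year_label,
                    "site_group": group,
                    "value": float(vals[j]),
                }
            )
    pheno = pd.DataFrame(rows, columns=["line", "env", "year", "site_group", "value"])
    truth = SyntheticTruth(
        env_effects=env_effects,
        line_effects={ln: float(v) for ln, v in zip(line_ids, g)},
        aux_line_effects={ln: float(v) for ln, v in zip(line_ids, g_aux)},
        ge_effects=ge,
        genetic_values=gvals,
    )
    return pheno, truth


# Cohort sizes and environment counts of the six TPE-by-season datasets the
# generator emulates: (tpe, year, n_lines, n_target_envs, n_auxiliary_envs).
_STUDY_ROWS = [
    ("TPE_1", "2021_2022", 166, 4, 3),
    ("TPE_1", "2022_2023", 166, 6, 6),
    ("TPE_2", "2021_2022", 166, 5, 3),
    ("TPE_2", "2022_2023", 165, 6, 6),
    ("TPE_3", "2021_2022", 112, 2, 3),
    ("TPE_3", "2022_2023", 166, 3, 6),
]


def make_study_designs(
    scale: float = 1.0, seed: int = 0, line_overlap_fraction: float = 0.2
) -> list[tuple[TrialDesign, TrialDesign]]:
    """Emit the three TPE year-pairs of the emulated study, optionally scaled.

    ``scale`` multiplies line and environment counts (floored; at least 2
    lines and 1 environment per site group survive).  Year pairs within a
    TPE share lines according to ``line_overlap_fraction``.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")

    def _mk(tpe: str, year: str, n_lines: int, n_t: int, n_a: int) -> TrialDesign:
        nl = max(2, int(np.floor(scale * n_lines)))
        nt = max(1, int(np.floor(scale * n_t)))
        na = max(1, int(np.floor(scale * n_a)))
        envs = [(f"{tpe}_{year}_IND_{i + 1}", TARGET) for i in range(nt)]
        envs += [(f"{tpe}_{year}_MEX_{i + 1}", AUXILIARY) for i in range(na)]
        return TrialDesign(tpe, year, nl, envs, line_overlap_fraction)

    out = []
    for k in range(0, len(_STUDY_ROWS), 2):
        d1 = _mk(*_STUDY_ROWS[k])
        d2 = _mk(*_STUDY_ROWS[k + 1])
        out.append((d1, d2))
    return out


def simulate_design_pair(
    pair: tuple[TrialDesign, TrialDesign],
    params: GenerativeParams,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, SyntheticTruth]]:
    """Simulate a consecutive-season pair sharing markers and some lines.

    Returns (marker matrix over the union cohort, {dataset label: phenotype
    table}, {dataset label: truth}).  The overlap between the two cohorts is
    ``round(line_overlap_fraction * min(n1, n2))`` lines.  Genetic merit g
    (and its auxiliary-group copy) is drawn once over the union cohort and
    shared by both seasons — a line's merit is a property of the line — while
    environment effects, G×E deviations and residuals are season-specific.
    """
    d1, d2 = pair
    n_overlap = round_half_away(d1.line_overlap_fraction * min(d1.n_lines, d2.n_lines))
    n_union = d1.n_lines + d2.n_lines - n_overlap
    markers = simulate_markers(
        n_union,
        params.n_markers,
        params.maf_range,
        params.missing_rate,
        seed=spawn_seed(params.seed, 0),
    )
    from .genotypes import compute_grm, filter_markers, impute_mean

    grm = compute_grm(impute_mean(filter_markers(markers)))
    lines = list(markers.index)
    ids1 = lines[: d1.n_lines]
    # season 2 reuses the last `n_overlap` lines of season 1's cohort
    ids2 = lines[d1.n_lines - n_overlap : d1.n_lines - n_overlap + d2.n_lines]

    rng = np.random.default_rng(spawn_seed(params.seed, 10))
    rho = params.aux_genetic_correlation
    if params.var_g > 0:
        chol = _correlated_chol(grm)
        z1 = rng.standard_normal(n_union)
        z2 = rng.standard_normal(n_union)
        g = np.sqrt(params.var_g) * (chol @ z1)
        g_aux = np.sqrt(params.var_g) * (
            chol @ (rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2)
        )
    else:
        g = np.zeros(n_union)
        g_aux = np.zeros(n_union)
    g_s = pd.Series(g, index=grm.index)
    g_aux_s = pd.Series(g_aux, index=grm.index)

    phenos: dict[str, pd.DataFrame] = {}
    truths: dict[str, SyntheticTruth] = {}
    for k, (design, ids) in enumerate(((d1, ids1), (d2, ids2))):
        ph, tr = simulate_phenotypes(
            design,
            grm,
            params,
            line_ids=ids,
            seed=spawn_seed(params.seed, 1 + k),
            line_effects=g_s,
            aux_line_effects=g_aux_s,
        )
        phenos[design.label] = ph
        truths[design.label] = tr
    return markers, phenos, truths
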