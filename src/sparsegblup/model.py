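"""Multi-environment Bayesian GBLUP with genotype-by-environment interaction.

The model for the adjusted line mean (BLUE) of line j in environment i is

    Y_ij = mu + E_i + g_j + gE_ij + eps_ij

with random environment effects E ~ N(0, var_env * I), genomic line effects
g ~ N(0, var_g * G) for a genomic relationship matrix G, interaction effects
gE ~ N(0, var_ge * (Zg G Zg' ∘ Ze I Ze')) — i.e. an independent MVN(0,
var_ge * G) per environment — and iid residuals.  Variance components carry
scaled-inverse-chi-square priors and the grand mean a flat prior; the
posterior is explored by Gibbs sampling.

:class:`BayesianGBLUP` is a scikit-learn style estimator: ``fit`` takes the
observed (line, env) records and their values, ``predict`` returns the
posterior-mean genetic value mu + E_i + g_j + gE_ij for any (line, env)
cell with a fitted environment and a line covered by G — including cells
never observed, which is the sparse-testing use case.

Sampling strategy: each random term is expressed in a basis that
simultaneously diagonalises its prior covariance (the eigenbasis of G) and
its data precision (the per-line record counts), so every full conditional
is diagonal and one iteration costs a handful of matrix-vector products.
The closed-form mixed-model oracle :func:`blup_oracle` provides an
independent check at fixed variance components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "MCMCSettings",
    "BayesianGBLUP",
    "build_kernels",
    "blup_oracle",
    "fit_gibbs",
    "predict_masked",
]

_EIG_TOL = 1e-8  # relative eigenvalue cutoff for the G basis
_SCALE_FLOOR = 1e-8  # floor for prior scales when var(y) degenerates


@dataclass
class VarianceComponents:
    """Variance components (and grand mean) of the multi-environment model."""

    var_env: float
    var_g: float
    var_ge: float
    var_e: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        for name in ("var_env", "var_g", "var_ge"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.var_e <= 0:
            raise ValueError("var_e must be > 0")


@dataclass
class MCMCSettings:
    """Gibbs-chain settings.

    prior_df and prior_r2 parameterise the scaled-inverse-chi-square
    variance priors: prior_r2 is the share of var(y) assigned a priori to
    the random terms jointly (split equally among them), the rest to the
    residual.
    """

    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_r2: float = 0.5

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_df <= 0:
            raise ValueError("prior_df must be > 0")
        if not 0.0 < self.prior_r2 < 1.0:
            raise ValueError("prior_r2 must be in (0, 1)")


def _as_cells(X) -> pd.DataFrame:
    """Coerce input records to a DataFrame with 'line' and 'env' columns."""
    if isinstance(X, pd.DataFrame):
        if not {"line", "env"}.issubset(X.columns):
            raise ValueError("record frame must have 'line' and 'env' columns")
        return X[["line", "env"]].reset_index(drop=True)
    arr = np.asarray(X, dtype=object)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("records must be an n x 2 array of (line, env)")
    return pd.DataFrame(arr, columns=["line", "env"])


def build_kernels(
    cells: pd.DataFrame, grm: pd.DataFrame, include_ge: bool = True
) -> dict[str, np.ndarray]:
    """Record-level covariance kernels for a set of (line, env) cells.

    Returns ``K_env`` (1 where two records share an environment), ``K_g``
    (the GRM expanded to records) and, when ``include_ge``, their
    elementwise product ``K_ge`` — the Hadamard-product G×E covariance,
    block-diagonal by environment on a complete layout.
    """
    cells = _as_cells(cells)
    missing = sorted(set(cells["line"]) - set(grm.index))
    if missing:
        raise ValueError(f"lines absent from GRM: {missing[:5]}")
    line_pos = pd.Index(grm.index).get_indexer(cells["line"])
    env_codes = pd.factorize(cells["env"])[0]
    g = grm.to_numpy(dtype=float)
    k_g = g[np.ix_(line_pos, line_pos)]
    k_env = (env_codes[:, None] == env_codes[None, :]).astype(float)
    out = {"K_env": k_env, "K_g": k_g}
    if include_ge:
        out["K_ge"] = k_g * k_env
    return out


class _TermBasis:
    """A random term u ~ N(0, sigma^2 G) observed through per-line counts.

    Reparameterises u = A c with c ~ N(0, sigma^2 I) such that the full
    conditional precision of c is diagonal: theta / var_e + 1 / sigma^2.
    """

    __slots__ = ("A", "theta", "m")

    def __init__(self, U: np.ndarray, d: np.ndarray, counts: np.ndarray) -> None:
        sd = np.sqrt(d)
        B = U * sd[None, :]  # n_lines x m, B B' = G
        M = B.T @ (counts[:, None] * B)
        theta, R = np.linalg.eigh(M)
        self.theta = np.clip(theta, 0.0, None)
        self.A = B @ R
        self.m = len(d)


class BayesianGBLUP(RegressorMixin, BaseEstimator):
    """Bayesian multi-environment GBLUP with an optional G×E term.

    Parameters
    ----------
    grm : pandas.DataFrame
        Genomic relationship matrix (square, line-indexed).  Must cover
        every line passed to ``fit`` or ``predict``.
    n_iter, burn_in, thin : int
        Gibbs chain length, discarded prefix and thinning stride.
    prior_df, prior_r2 : float
        Scaled-inverse-chi-square prior hyperparameters (see
        :class:`MCMCSettings`).
    include_ge : bool
        Fit the genotype-by-environment interaction term (default True).
    fix_variances : VarianceComponents or None
        When given, variance components are held at these values and only
        the effects (and mu) are sampled — used to validate the sampler
        against the closed-form BLUP.
    center_by_env : bool
        Subtract each environment's observed mean before fitting and add it
        back at prediction (default False: raw BLUEs are modelled).
    random_state : int
        Seed; identical seeds give identical fits.

    Attributes
    ----------
    mu_ : float
        Posterior mean of the grand mean.
    env_effects_, line_effects_ : pandas.Series
        Posterior means of E and g.
    ge_effects_ : pandas.DataFrame
        Posterior means of gE, lines x environments (zeros when
        ``include_ge=False``).
    variance_components_ : VarianceComponents
        Posterior means of the variance components.
    vc_draws_ : pandas.DataFrame
        Post-burn-in thinned draws of (mu, var_env, var_g, var_ge, var_e).
    chain_summary_ : pandas.DataFrame
        Posterior mean, sd and retained draw count per component.
    """

    def __init__(
        self,
        grm: pd.DataFrame | None = None,
        n_iter: int = 10_000,
        burn_in: int = 2_000,
        thin: int = 5,
        prior_df: float = 5.0,
        prior_r2: float = 0.5,
        include_ge: bool = True,
        fix_variances: VarianceComponents | None = None,
        center_by_env: bool = False,
        random_state: int = 0,
    ) -> None:
        self.grm = grm
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.prior_df = prior_df
        self.prior_r2 = prior_r2
        self.include_ge = include_ge
        self.fix_variances = fix_variances
        self.center_by_env = center_by_env
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y) -> "BayesianGBLUP":
        """Run the Gibbs sampler on observed (line, env) records.

        X holds the record identifiers (DataFrame with 'line'/'env' columns
        or an n x 2 array), y the observed trait values.
        """
        settings = MCMCSettings(
            self.n_iter, self.burn_in, self.thin, self.random_state,
            self.prior_df, self.prior_r2,
        )
        if self.grm is None:
            raise ValueError("a GRM must be supplied")
        cells = _as_cells(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(cells):
            raise ValueError("X and y lengths differ")
        if not np.isfinite(y).all():
            raise ValueError("y contains non-finite values")
        missing = sorted(set(cells["line"]) - set(self.grm.index))
        if missing:
            raise ValueError(f"lines absent from GRM: {missing[:5]}")

        self.lines_ = list(self.grm.index)
        self.envs_, env_idx = np.unique(cells["env"].to_numpy(), return_inverse=True)
        self.envs_ = list(self.envs_)
        n_env = len(self.envs_)
        n_obs = len(y)
        if n_obs < n_env + 2:
            raise ValueError(
                f"need at least n_env + 2 = {n_env + 2} observed records; got {n_obs}"
            )
        line_idx = pd.Index(self.grm.index).get_indexer(cells["line"])
        n_lines = len(self.lines_)

        if self.center_by_env:
            self.env_means_ = pd.Series(
                [y[env_idx == i].mean() for i in range(n_env)], index=self.envs_
            )
            y = y - self.env_means_.to_numpy()[env_idx]
        else:
            self.env_means_ = None

        g_mat = self.grm.to_numpy(dtype=float)
        evals, evecs = np.linalg.eigh(g_mat)
        if evals.min() < -1e-6:
            raise ValueError(
                f"GRM not PSD within tolerance (min eigenvalue {evals.min():g})"
            )
        keep = evals > _EIG_TOL * max(evals.max(), 1.0)
        U, d = evecs[:, keep], evals[keep]

        counts_g = np.bincount(line_idx, minlength=n_lines).astype(float)
        basis_g = _TermBasis(U, d, counts_g)
        env_rec: list[np.ndarray] = [np.where(env_idx == i)[0] for i in range(n_env)]
        if self.include_ge:
            bases_ge = []
            for i in range(n_env):
                c = np.bincount(line_idx[env_rec[i]], minlength=n_lines).astype(float)
                bases_ge.append(_TermBasis(U, d, c))
        counts_env = np.bincount(env_idx, minlength=n_env).astype(float)

        # -- priors (scales from the observed phenotypic variance)
        vy = max(float(np.var(y, ddof=1)) if n_obs > 1 else 0.0, _SCALE_FLOOR)
        df0 = settings.prior_df
        n_terms = 3 if self.include_ge else 2
        r2_term = settings.prior_r2 / n_terms
        mean_diag = float(np.mean(g_mat[line_idx, line_idx]))
        s_env = max(vy * r2_term * (df0 + 2) / df0, _SCALE_FLOOR)
        s_g = max(vy * r2_term * (df0 + 2) / (df0 * mean_diag), _SCALE_FLOOR)
        s_ge = s_g
        s_e = max(vy * (1 - settings.prior_r2) * (df0 + 2) / df0, _SCALE_FLOOR)

        rng = np.random.default_rng(settings.seed)
        fixed = self.fix_variances
        if fixed is not None:
            v_env, v_g, v_ge, v_e = (
                fixed.var_env, fixed.var_g, fixed.var_ge, fixed.var_e,
            )
        else:
            v_env = v_g = v_ge = v_e = vy / n_terms if vy > _SCALE_FLOOR else 1.0
            v_e = max(vy / 2, _SCALE_FLOOR * 10)

        mu = float(np.mean(y))
        e_eff = np.zeros(n_env)
        u_g = np.zeros(n_lines)
        c_g = np.zeros(basis_g.m)
        if self.include_ge:
            u_ge = np.zeros((n_env, n_lines))
            c_ge = [np.zeros(b.m) for b in bases_ge]
        resid = y - mu

        n_keep = (settings.n_iter - settings.burn_in + settings.thin - 1) // settings.thin
        acc_mu = 0.0
        acc_env = np.zeros(n_env)
        acc_g = np.zeros(n_lines)
        acc_ge = np.zeros((n_env, n_lines)) if self.include_ge else None
        draws = np.zeros((n_keep, 5))
        kept = 0

        for it in range(settings.n_iter):
            # grand mean (flat prior)
            resid += mu
            mu = float(rng.normal(resid.mean(), np.sqrt(v_e / n_obs)))
            resid -= mu

            # environment main effects (iid prior)
            if v_env > 0:
                resid += e_eff[env_idx]
                s_sum = np.bincount(env_idx, weights=resid, minlength=n_env)
                prec = counts_env / v_e + 1.0 / v_env
                e_mean = (s_sum / v_e) / prec
                e_eff = e_mean + rng.standard_normal(n_env) / np.sqrt(prec)
                resid -= e_eff[env_idx]

            # genomic main effects in the diagonalised basis
            if v_g > 0:
                resid += u_g[line_idx]
                v = np.bincount(line_idx, weights=resid, minlength=n_lines)
                prec = basis_g.theta / v_e + 1.0 / v_g
                c_mean = (basis_g.A.T @ v / v_e) / prec
                c_g = c_mean + rng.standard_normal(basis_g.m) / np.sqrt(prec)
                u_g = basis_g.A @ c_g
                resid -= u_g[line_idx]

            # G×E deviations, one independent term per environment
            if self.include_ge and v_ge > 0:
                for i in range(n_env):
                    rr = env_rec[i]
                    li = line_idx[rr]
                    resid[rr] += u_ge[i, li]
                    v = np.bincount(li, weights=resid[rr], minlength=n_lines)
                    b = bases_ge[i]
                    prec = b.theta / v_e + 1.0 / v_ge
                    c_mean = (b.A.T @ v / v_e) / prec
                    c_ge[i] = c_mean + rng.standard_normal(b.m) / np.sqrt(prec)
                    u_ge[i] = b.A @ c_ge[i]
                    resid[rr] -= u_ge[i, li]

            # variance components (scaled-inverse-chi-square full conditionals)
            if fixed is None:
                v_env = (df0 * s_env + float(e_eff @ e_eff)) / rng.chisquare(
                    df0 + n_env
                )
                v_g = (df0 * s_g + float(c_g @ c_g)) / rng.chisquare(df0 + basis_g.m)
                if self.include_ge:
                    ss = sum(float(c @ c) for c in c_ge)
                    m_tot = sum(b.m for b in bases_ge)
                    v_ge = (df0 * s_ge + ss) / rng.chisquare(df0 + m_tot)
                v_e = (df0 * s_e + float(resid @ resid)) / rng.chisquare(df0 + n_obs)
                if not np.isfinite(v_e) or v_e <= 0 or not np.isfinite(v_g):
                    raise RuntimeError(
                        f"Gibbs sampler produced a non-finite variance draw at "
                        f"iteration {it} (var_e={v_e!r}, var_g={v_g!r})"
                    )

            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                acc_mu += mu
                acc_env += e_eff
                acc_g += u_g
                if self.include_ge:
                    acc_ge += u_ge
                draws[kept] = (mu, v_env, v_g, v_ge if self.include_ge else 0.0, v_e)
                kept += 1

        self.n_draws_ = kept
        self.mu_ = acc_mu / kept
        self.env_effects_ = pd.Series(acc_env / kept, index=self.envs_)
        self.line_effects_ = pd.Series(acc_g / kept, index=self.lines_)
        ge_mean = (acc_ge / kept) if self.include_ge else np.zeros((n_env, n_lines))
        self.ge_effects_ = pd.DataFrame(
            ge_mean.T, index=self.lines_, columns=self.envs_
        )
        self.vc_draws_ = pd.DataFrame(
            draws[:kept], columns=["mu", "var_env", "var_g", "var_ge", "var_e"]
        )
        pm = self.vc_draws_.mean()
        self.variance_components_ = VarianceComponents(
            var_env=float(pm["var_env"]),
            var_g=float(pm["var_g"]),
            var_ge=float(pm["var_ge"]),
            var_e=float(pm["var_e"]) if pm["var_e"] > 0 else _SCALE_FLOOR,
            mu=float(pm["mu"]),
        )
        self.chain_summary_ = pd.DataFrame(
            {"mean": self.vc_draws_.mean(), "sd": self.vc_draws_.std(ddof=1),
             "n_draws": kept}
        )
        return self

    # -------------------------------------------------------------- predict
    def predict(self, X) -> np.ndarray:
        """Posterior-mean genetic value mu + E_i + g_j + gE_ij per cell.

        A pure lookup on the fitted posterior means — no refit.  Cells with
        an environment not seen at fit time or a line outside the GRM raise
        with the offending pairs listed.
        """
        if not hasattr(self, "mu_"):
            raise ValueError("estimator is not fitted")
        cells = _as_cells(X)
        bad = [
            (ln, ev)
            for ln, ev in zip(cells["line"], cells["env"])
            if ev not in self.env_effects_.index or ln not in self.line_effects_.index
        ]
        if bad:
            raise KeyError(f"unknown (line, env) cells: {bad[:5]}")
        e = self.env_effects_.loc[cells["env"]].to_numpy()
        g = self.line_effects_.loc[cells["line"]].to_numpy()
        ge = self.ge_effects_.to_numpy()[
            pd.Index(self.ge_effects_.index).get_indexer(cells["line"]),
            pd.Index(self.ge_effects_.columns).get_indexer(cells["env"]),
        ]
        out = self.mu_ + e + g + ge
        if self.env_means_ is not None:
            out = out + self.env_means_.loc[cells["env"]].to_numpy()
        return out


# --------------------------------------------------------------- functions
def blup_oracle(
    table: pd.DataFrame,
    grm: pd.DataFrame,
    vc: VarianceComponents,
    include_ge: bool = True,
) -> pd.DataFrame:
    """Closed-form mixed-model predictions at known variance components.

    ``table`` is a long record frame with columns (line, env, value) and a
    boolean ``masked`` column; masked records contribute nothing to the
    conditioning set.  Solves

        y_hat = mu_gls + V_cross (V_obs + var_e I)^-1 (y_obs - mu_gls)

    with V assembled from the record-level kernels, mu_gls the GLS estimate
    of the grand mean.  Returns the table with a ``prediction`` column.
    """
    if vc.var_e <= 0:
        raise ValueError("var_e must be > 0")
    table = table.reset_index(drop=True)
    masked = table["masked"].to_numpy(dtype=bool) if "masked" in table else np.zeros(
        len(table), dtype=bool
    )
    kern = build_kernels(table, grm, include_ge=include_ge)
    v_full = vc.var_env * kern["K_env"] + vc.var_g * kern["K_g"]
    if include_ge:
        v_full = v_full + vc.var_ge * kern["K_ge"]
    obs = ~masked
    y_obs = table.loc[obs, "value"].to_numpy(dtype=float)
    v_oo = v_full[np.ix_(obs, obs)] + vc.var_e * np.eye(obs.sum())
    try:
        vinv_1 = np.linalg.solve(v_oo, np.ones(obs.sum()))
        vinv_y = np.linalg.solve(v_oo, y_obs)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; adding 1e-8 ridge", RuntimeWarning)
        v_oo = v_oo + 1e-8 * np.eye(obs.sum())
        vinv_1 = np.linalg.solve(v_oo, np.ones(obs.sum()))
        vinv_y = np.linalg.solve(v_oo, y_obs)
    mu_hat = float(vinv_1 @ y_obs / (vinv_1 @ np.ones(obs.sum())))
    alpha = np.linalg.solve(v_oo, y_obs - mu_hat)
    preds = mu_hat + v_full[:, obs] @ alpha
    out = table.copy()
    out["prediction"] = preds
    return out


def fit_gibbs(
    table: pd.DataFrame,
    grm: pd.DataFrame,
    mcmc: MCMCSettings | None = None,
    include_ge: bool = True,
    fix_variances: VarianceComponents | None = None,
    center_by_env: bool = False,
) -> BayesianGBLUP:
    """Fit the model on the observed records of a long table.

    ``table`` needs columns (line, env, value) and optionally a boolean
    ``masked`` column; masked records are excluded from the likelihood.
    Returns the fitted :class:`BayesianGBLUP` (use ``predict`` for any
    cell, masked or observed).
    """
    mcmc = mcmc or MCMCSettings()
    masked = (
        table["masked"].to_numpy(dtype=bool)
        if "masked" in table
        else np.zeros(len(table), dtype=bool)
    )
    obs = table.loc[~masked]
    est = BayesianGBLUP(
        grm=grm,
        n_iter=mcmc.n_iter,
        burn_in=mcmc.burn_in,
        thin=mcmc.thin,
        prior_df=mcmc.prior_df,
        prior_r2=mcmc.prior_r2,
        include_ge=include_ge,
        fix_variances=fix_variances,
        center_by_env=center_by_env,
        random_state=mcmc.seed,
    )
    return est.fit(obs[["line", "env"]], obs["value"].to_numpy(dtype=float))


def predict_masked(
    fit: BayesianGBLUP, cells: list[tuple[str, str]] | pd.DataFrame
) -> np.ndarray:
    """Posterior-mean genetic values for a list of (line, env) cells."""
    return fit.predict(cells)
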