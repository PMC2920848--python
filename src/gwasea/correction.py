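"""Confounder correction of gene association scores.

Four interchangeable corrections of the raw best-SNP gene score:

* **Step-wise regression** (the default): forward/backward step-wise multiple
  linear regression of the gene z-score on the per-gene covariates (entry at
  p < 0.05, removal at p > 0.10).  The corrected z-score is the regression
  residual standardised to unit variance, and the corrected p-value is
  1 - Phi(z_corrected), treating the standardised residual as standard normal
  (a good, though not perfect, approximation).  This requires no genotype
  data, which is what makes the approach usable on meta-analysis summary
  statistics.
* **Sidak**: p = 1 - (1 - p_best)^N for N regional SNPs — exact if all SNPs
  were independent, hence over-corrects in the presence of LD.
* **Modified Sidak**: exponent (N+1)/2, assuming roughly half the SNPs in a
  region are in tight LD.
* **Permutation**: empirical tail probability of the observed score against a
  user-supplied stack of null score vectors (e.g. from phenotype-permuted
  scans), the gold standard when genotypes are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .covariates import DEFAULT_REGRESSION_COVARIATES

logger = logging.getLogger(__name__)

DEFAULT_ENTRY_P = 0.05
DEFAULT_REMOVAL_P = 0.10

# Corrected p is clamped into the open unit interval so downstream log/quantile
# transforms stay finite.
_P_EPS = 1e-300


@dataclass
class RegressionModel:
    """Fitted step-wise model: selected covariates in entry order, coefficients, p-values."""

    selected_covariates: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    p_values: dict[str, float]
    entry_p: float
    removal_p: float
    n_obs: int
    residual_std: float
    r_squared: float
    steps: list[str] = field(default_factory=list)
    dropped_collinear: list[str] = field(default_factory=list)

    def report_frame(self) -> pd.DataFrame:
        rows = [
            {"term": "intercept", "coefficient": self.coefficients["intercept"], "p_value": np.nan}
        ]
        for name in self.selected_covariates:
            rows.append(
                {"term": name, "coefficient": self.coefficients[name], "p_value": self.p_values[name]}
            )
        return pd.DataFrame(rows)

    def report_text(self) -> str:
        lines = [
            f"step-wise linear regression on {self.n_obs} genes "
            f"(entry p<{self.entry_p:g}, removal p>{self.removal_p:g})",
            f"R^2 = {self.r_squared:.4f}, residual std = {self.residual_std:.4f}",
        ]
        lines += [f"  {s}" for s in self.steps]
        lines.append(self.report_frame().to_string(index=False))
        return "\n".join(lines)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Least squares fit: (beta, t-test p-values per column, residuals, rank).

    Thin numpy implementation used inside the step-wise loop (called thousands
    of times in power simulations); validated against statsmodels OLS in the
    test suite.  A rank below the column count signals collinearity.
    """
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - rank
    sigma2 = resid @ resid / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    return beta, pvals, resid, int(rank)


def stepwise_select(
    y: np.ndarray,
    X: pd.DataFrame,
    entry_p: float = DEFAULT_ENTRY_P,
    removal_p: float = DEFAULT_REMOVAL_P,
) -> RegressionModel:
    """Forward/backward step-wise OLS of ``y`` on the columns of ``X``.

    At each forward step the candidate with the smallest partial t-test
    p-value enters if that p-value is below ``entry_p``; after every entry,
    any included covariate whose p-value has risen above ``removal_p`` is
    removed (worst first).  The loop runs until stable.  Collinear candidates
    (no variance, or duplicating the current model's column space) are
    dropped with a warning.
    """
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n = len(y)
    steps: list[str] = []
    dropped: list[str] = []

    # drop constant / all-NaN columns up front
    usable = []
    for j, name in enumerate(names):
        col = Xv[:, j]
        if np.isnan(col).all() or np.nanstd(col) == 0:
            dropped.append(name)
            logger.warning("stepwise_select: covariate %s has no variance; dropped", name)
        else:
            usable.append(j)

    selected: list[int] = []
    while True:
        changed = False
        remaining = [j for j in usable if j not in selected]
        # forward step
        best_j, best_p = None, np.inf
        for j in remaining:
            cols = selected + [j]
            Xc = np.column_stack([np.ones(n)] + [Xv[:, c] for c in cols])
            _, pvals, _, rank = _ols(y, Xc)
            if rank < Xc.shape[1]:
                if names[j] not in dropped:
                    dropped.append(names[j])
                    logger.warning(
                        "stepwise_select: covariate %s collinear with current model; dropped",
                        names[j],
                    )
                usable = [c for c in usable if c != j]
                continue
            p_new = pvals[-1]
            if p_new < best_p:
                best_p, best_j = p_new, j
        if best_j is not None and best_p < entry_p:
            selected.append(best_j)
            steps.append(f"+ {names[best_j]} (p={best_p:.3g})")
            changed = True
        # backward step(s)
        while len(selected) > 0:
            Xc = np.column_stack([np.ones(n)] + [Xv[:, c] for c in selected])
            _, pvals, _, _ = _ols(y, Xc)
            worst = int(np.argmax(pvals[1:]))
            if pvals[1 + worst] > removal_p:
                steps.append(f"- {names[selected[worst]]} (p={pvals[1 + worst]:.3g})")
                del selected[worst]
                changed = True
            else:
                break
        if not changed:
            break

    Xc = np.column_stack([np.ones(n)] + [Xv[:, c] for c in selected])
    beta, pvals, resid, _ = _ols(y, Xc)
    sel_names = [names[c] for c in selected]
    coefficients = {"intercept": float(beta[0])}
    p_values: dict[str, float] = {}
    for i, name in enumerate(sel_names):
        coefficients[name] = float(beta[1 + i])
        p_values[name] = float(pvals[1 + i])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return RegressionModel(
        selected_covariates=sel_names,
        coefficients=coefficients,
        p_values=p_values,
        entry_p=entry_p,
        removal_p=removal_p,
        n_obs=n,
        residual_std=float(resid.std()),
        r_squared=r2,
        steps=steps,
        dropped_collinear=dropped,
    )


def residual_to_p(resid: np.ndarray, standardize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Map regression residuals to (z_corrected, p_corrected).

    Residuals are centred by construction; with ``standardize`` (default) they
    are scaled to unit variance before the normal-tail mapping
    p = 1 - Phi(z), which is what makes the corrected p-values approximately
    uniform under the null.
    """
    z = resid - resid.mean()
    if standardize:
        sd = z.std()
        if sd > 0:
            z = z / sd
    p = special.ndtr(-z)
    return z, np.clip(p, _P_EPS, 1 - 1e-16)


def stepwise_regression_correct(
    scores: pd.DataFrame,
    covs: pd.DataFrame,
    entry_p: float = DEFAULT_ENTRY_P,
    removal_p: float = DEFAULT_REMOVAL_P,
    covariates: list[str] | None = None,
    missing: str = "impute",
    standardize: bool = True,
) -> tuple[pd.DataFrame, RegressionModel]:
    """Regress confounders out of the raw gene z-scores.

    Genes without SNPs are excluded from the fit and keep NaN corrected
    scores.  Masked (NaN) covariate values are mean-imputed by default
    (``missing="impute"``); with ``missing="drop"`` the offending covariate
    column is excluded from the candidate set entirely if it has any NaN.

    Returns a copy of ``scores`` with ``z_corrected`` / ``p_corrected`` filled,
    plus the fitted :class:`RegressionModel`.
    """
    covariates = covariates or [c for c in DEFAULT_REGRESSION_COVARIATES if c in covs.columns]
    scores = scores.copy()
    fit_mask = (~scores["excluded_no_snps"]) & scores["z_raw"].notna()
    genes = scores.index[fit_mask]
    y = scores.loc[genes, "z_raw"].to_numpy(dtype=float)

    X = covs.reindex(genes)[covariates].astype(float)
    if missing == "drop":
        keep = [c for c in covariates if not X[c].isna().any()]
        skipped = sorted(set(covariates) - set(keep))
        if skipped:
            logger.info("stepwise_regression_correct: covariates %s masked; skipped", skipped)
        X = X[keep]
    else:
        X = X.apply(lambda col: col.fillna(col.mean()))
        X = X.dropna(axis=1, how="all")  # resource entirely missing

    if len(genes) < 20 * max(1, X.shape[1]):
        logger.warning(
            "stepwise_regression_correct: only %d genes for %d covariates; "
            "fit may be unstable", len(genes), X.shape[1],
        )

    model = stepwise_select(y, X, entry_p=entry_p, removal_p=removal_p)
    # final refit of the selected model through statsmodels: authoritative
    # coefficients/p-values for the regression report
    import statsmodels.api as sm

    exog = sm.add_constant(X[model.selected_covariates].to_numpy())
    fit = sm.OLS(y, exog).fit()
    model.coefficients = {"intercept": float(fit.params[0])}
    for i, name in enumerate(model.selected_covariates):
        model.coefficients[name] = float(fit.params[1 + i])
        model.p_values[name] = float(fit.pvalues[1 + i])
    model.r_squared = float(fit.rsquared)
    model.residual_std = float(np.std(fit.resid))
    z_corr, p_corr = residual_to_p(np.asarray(fit.resid), standardize=standardize)

    scores["z_corrected"] = np.nan
    scores["p_corrected"] = np.nan
    scores.loc[genes, "z_corrected"] = z_corr
    scores.loc[genes, "p_corrected"] = p_corr
    return scores, model


def sidak_correct(p_best, n_snps):
    """Sidak multiple-SNP correction: p = 1 - (1 - p_best)^N.

    Exact for the minimum of N independent uniform p-values (the Beta(1, N)
    tail).  Vectorised; computed as -expm1(N log1p(-p)) for precision.
    """
    p = np.asarray(p_best, dtype=float)
    n = np.asarray(n_snps)
    if np.any(n < 1):
        raise ValueError("n_snps must be >= 1")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p_best must be in (0, 1]")
    out = -np.expm1(n * np.log1p(-np.clip(p, None, 1 - 1e-16)))
    out = np.where(p >= 1, 1.0, out)
    out = np.where(n == 1, p, out)  # identity exponent, exactly
    return out if out.ndim else float(out)


def modified_sidak_correct(p_best, n_snps):
    """Sidak with exponent (N+1)/2, discounting ~50% of regional SNPs as in tight LD."""
    n = np.asarray(n_snps)
    if np.any(n < 1):
        raise ValueError("n_snps must be >= 1")
    return sidak_correct(p_best, (n + 1) / 2.0)


def apply_analytic_correction(scores: pd.DataFrame, method: str = "sidak") -> pd.DataFrame:
    """Fill p_corrected/z_corrected of a score table via (modified) Sidak."""
    fn = {"sidak": sidak_correct, "modified_sidak": modified_sidak_correct}[method]
    scores = scores.copy()
    ok = ~scores["excluded_no_snps"]
    p = fn(scores.loc[ok, "p_best"].to_numpy(), scores.loc[ok, "n_snps"].to_numpy())
    p = np.clip(p, _P_EPS, 1 - 1e-16)
    scores["p_corrected"] = np.nan
    scores["z_corrected"] = np.nan
    scores.loc[ok, "p_corrected"] = p
    scores.loc[ok, "z_corrected"] = -special.ndtri(p)
    return scores


def permutation_correct(
    scores: pd.DataFrame,
    nulls,
    refine_threshold: float = 1e-3,
) -> pd.DataFrame:
    """Empirical correction against a stack of null score vectors.

    ``nulls`` is an (n_genes, n_replicates) array or DataFrame of raw best-SNP
    p-values (or any score on the same scale as ``p_best``), rows aligned to
    ``scores``.  The corrected p-value is the fraction of null replicates at
    least as significant (null <= observed); zero counts are floored at
    1/n_replicates, and genes with p below ``refine_threshold`` are flagged in
    ``needs_refinement`` as candidates for a larger null stack.
    """
    if isinstance(nulls, pd.DataFrame):
        if not nulls.index.equals(scores.index):
            raise ValueError("null stack rows are not aligned to the score table")
        null_arr = nulls.to_numpy(dtype=float)
    else:
        null_arr = np.asarray(nulls, dtype=float)
        if null_arr.ndim != 2 or null_arr.shape[0] != len(scores):
            raise ValueError("null stack rows are not aligned to the score table")
    n_rep = null_arr.shape[1]
    if n_rep < 2:
        raise ValueError("need at least 2 null replicates")

    scores = scores.copy()
    obs = scores["p_best"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        counts = (null_arr <= obs[:, None]).sum(axis=1)
    p = counts / n_rep
    p = np.maximum(p, 1.0 / n_rep)
    p[np.isnan(obs)] = np.nan
    scores["p_corrected"] = p
    ok = ~np.isnan(p)
    z = np.full(len(p), np.nan)
    z[ok] = -special.ndtri(np.clip(p[ok], _P_EPS, 1 - 1e-16))
    scores["z_corrected"] = z
    scores["needs_refinement"] = ok & (p < refine_threshold)
    return scores
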