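"""Negative-binomial GLM testing of treatment-specific temporal effects.

The central test compares two nested NB generalized linear models per gene:

    full:     log mu = batch + stress + time + stress:time   (+ offset)
    reduced:  log mu = batch + stress + time                 (+ offset)

with log size-factor offsets, variance function Var = mu + alpha * mu^2, and
a per-gene dispersion alpha estimated once (Cox-Reid adjusted profile
likelihood on the full design, optionally shrunk toward a mean-dispersion
trend) and reused in both fits.  Twice the log-likelihood difference is
referred to a chi-square with as many degrees of freedom as the interaction
adds to the design rank; genes significant after Benjamini-Hochberg
correction (default FDR < 0.01) are genes whose salt response differs over
time ("SSET" genes).  A per-time-point Wald contrast (stress main effect plus
the stress:time interaction at that time) flags genes differentially
expressed at specific times ("DEAT", default FDR < 0.05 and |log2FC| >= 1).

All factors are coded as treatment contrasts against a reference level; the
stress main effect therefore measures the salt/control difference at the
baseline time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io_model import (
    CountMatrix,
    SaltnetError,
    SampleSheet,
    TpmMatrix,
    align_check,
)

logger = logging.getLogger("saltnet.diffexpr")

LN2 = float(np.log(2.0))
_MIN_ALPHA = 1e-8
_MAX_ALPHA = 30.0


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Dummy-coded design matrix for one model formula.

    ``interaction_cols`` indexes the stress:time block (empty for the
    reduced model).  Reference levels (first declared level of each factor)
    are dropped, so the matrix is full rank for a complete factorial.
    """

    matrix: np.ndarray = field(repr=False)
    column_names: tuple[str, ...]
    terms: tuple[str, ...]
    interaction_cols: tuple[int, ...]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def require_full_rank(self) -> None:
        if self.rank < self.matrix.shape[1]:
            aliased = _aliased_columns(self.matrix, self.column_names)
            raise SaltnetError(f"design matrix is rank deficient; aliased: {aliased}")


def build_design(sheet: SampleSheet, interaction: bool = True) -> DesignSpec:
    """Build the (reduced or full) design matrix for a sample sheet.

    Terms: intercept + batch + stress + time (+ stress:time).  A factor with
    a single level contributes no columns (e.g. one batch).
    """
    tbl = sheet.table
    cols: list[np.ndarray] = [np.ones(len(tbl))]
    names: list[str] = ["Intercept"]

    def add_factor(name: str, series: pd.Series) -> list[np.ndarray]:
        added = []
        for lev in list(series.cat.categories)[1:]:
            v = (series == lev).to_numpy(dtype=float)
            cols.append(v)
            names.append(f"{name}[{lev}]")
            added.append(v)
        return added

    add_factor("batch", tbl["batch"])
    stress_cols = add_factor("stress", tbl["treatment"])
    stress_levels = list(tbl["treatment"].cat.categories)[1:]
    time_cols = add_factor("time", tbl["time"])
    time_levels = list(tbl["time"].cat.categories)[1:]

    inter_idx: list[int] = []
    terms = ["intercept", "batch", "stress", "time"]
    if interaction:
        for s_lev, s_col in zip(stress_levels, stress_cols):
            for t_lev, t_col in zip(time_levels, time_cols):
                inter_idx.append(len(cols))
                cols.append(s_col * t_col)
                names.append(f"stress[{s_lev}]:time[{t_lev}]")
        terms.append("stress:time")

    return DesignSpec(
        matrix=np.column_stack(cols),
        column_names=tuple(names),
        terms=tuple(terms),
        interaction_cols=tuple(inter_idx),
    )


def _aliased_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def estimate_size_factors(
    counts: CountMatrix, pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios size factors against a geometric-mean pseudo sample.

    Only genes with strictly positive counts in every sample enter the
    reference (the classic rule); ``pseudo_reference=True`` relaxes this by
    taking geometric means over positive entries only.
    """
    k = counts.values.astype(float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(k > 0, np.log(k), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        usable = np.isfinite(log_geo)
    else:
        usable = (k > 0).all(axis=1)
        if not usable.any():
            raise SaltnetError(
                "no gene has positive counts in all samples; re-run with "
                "pseudo_reference=True to use a positive-count reference"
            )
        log_geo = np.zeros(k.shape[0])
        log_geo[usable] = np.log(k[usable]).mean(axis=1)
    ratios = k[usable] / np.exp(log_geo[usable, None])
    sf = np.nanmedian(np.where(ratios > 0, ratios, np.nan), axis=0)
    if not np.all(np.isfinite(sf)) or (sf <= 0).any():
        raise SaltnetError("size factor estimation failed (zero/non-finite factor)")
    return sf


def filter_expressed(tpm: TpmMatrix, min_mean_tpm: float = 1.0) -> list[str]:
    """Genes whose mean TPM across all samples meets the threshold (inclusive)."""
    means = tpm.values.mean(axis=1)
    return [g for g, m in zip(tpm.genes, means) if m >= min_mean_tpm]


# ---------------------------------------------------------------------------
# NB likelihood + IRLS
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood; reduces to Poisson in the alpha -> 0 limit."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))
    inv = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + inv)
            - special.gammaln(inv)
            - special.gammaln(y + 1.0)
            + y * (np.log(alpha) + np.log(mu) - np.log1p(alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


@dataclass
class GeneFit:
    beta: np.ndarray
    mu: np.ndarray
    loglik: float
    converged: bool
    xtwx: np.ndarray


def _fit_gene(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 1e-6,
) -> GeneFit:
    """Per-gene IRLS for the NB GLM with log link and fixed dispersion.

    The working-response update uses weights mu/(1+alpha*mu); a small ridge
    stabilises near-singular weighted cross-products.  Convergence is judged
    on the relative change of the log-likelihood.
    """
    n, p = X.shape
    eta = np.log(np.maximum(y, 0.5))
    ll_old = -np.inf
    beta = np.zeros(p)
    converged = False
    eye = np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xw = X * w[:, None]
        A = X.T @ xw
        beta_new = np.linalg.solve(A + ridge * eye, X.T @ (w * z))
        eta = X @ beta_new + offset
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        ll = nb_loglik(y, mu, alpha)
        beta = beta_new
        if np.isfinite(ll) and abs(ll - ll_old) < tol * (abs(ll_old) + 0.1):
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    xtwx = X.T @ (X * w[:, None])
    return GeneFit(beta=beta, mu=mu, loglik=nb_loglik(y, mu, alpha), converged=converged, xtwx=xtwx)


@dataclass
class NbFit:
    """Stacked per-gene NB GLM fits against one design."""

    genes: list[str]
    design: DesignSpec
    coefficients: np.ndarray  # genes x columns, natural-log scale
    mu: np.ndarray  # genes x samples
    dispersion: np.ndarray  # per-gene alpha
    loglik: np.ndarray
    converged: np.ndarray


def fit_nb_glm(
    counts: CountMatrix,
    sheet: SampleSheet,
    design: DesignSpec,
    size_factors: np.ndarray,
    dispersion: np.ndarray | float,
    **irls_kwargs,
) -> NbFit:
    """Fit the NB GLM gene-by-gene with a log size-factor offset."""
    align_check(counts, sheet)
    design.require_full_rank()
    X = design.matrix
    offset = np.log(np.asarray(size_factors, dtype=float))
    k = counts.values
    alphas = np.broadcast_to(np.asarray(dispersion, dtype=float), (k.shape[0],))
    coefs = np.empty((k.shape[0], X.shape[1]))
    mus = np.empty_like(k, dtype=float)
    lls = np.empty(k.shape[0])
    conv = np.empty(k.shape[0], dtype=bool)
    for i in range(k.shape[0]):
        fit = _fit_gene(k[i].astype(float), X, offset, float(alphas[i]), **irls_kwargs)
        coefs[i] = fit.beta
        mus[i] = fit.mu
        lls[i] = fit.loglik
        conv[i] = fit.converged
    return NbFit(
        genes=list(counts.genes),
        design=design,
        coefficients=coefs,
        mu=mus,
        dispersion=np.array(alphas, dtype=float),
        loglik=lls,
        converged=conv,
    )


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


def _cr_apl(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float) -> float:
    """Cox-Reid adjusted profile log-likelihood at a fixed dispersion."""
    fit = _fit_gene(y, X, offset, alpha)
    sign, logdet = np.linalg.slogdet(fit.xtwx)
    if sign <= 0:
        return -np.inf
    return fit.loglik - 0.5 * logdet


def _maximize_alpha(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    prior: tuple[float, float] | None = None,
) -> float:
    """Maximise the CR adjusted profile likelihood over log alpha, optionally
    with a log-normal prior (mean log alpha, variance) for shrinkage."""

    def neg(log_a: float) -> float:
        val = _cr_apl(y, X, offset, float(np.exp(log_a)))
        if prior is not None:
            mu0, var0 = prior
            val -= (log_a - mu0) ** 2 / (2.0 * var0)
        return -val

    res = optimize.minimize_scalar(
        neg,
        bounds=(np.log(_MIN_ALPHA), np.log(_MAX_ALPHA)),
        method="bounded",
        options={"xatol": 0.01},
    )
    return float(np.exp(res.x))


def _dispersion_trend(mean_counts: np.ndarray, alphas: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0/mu + a1 by non-negative least squares with one
    round of outlier trimming."""
    keep = alphas > 1e-6
    if keep.sum() < 3:
        return 0.0, float(np.median(alphas))
    for _ in range(2):
        A = np.column_stack([1.0 / mean_counts[keep], np.ones(keep.sum())])
        coef, _ = optimize.nnls(A, alphas[keep])
        pred = coef[0] / mean_counts + coef[1]
        ratio = np.where(pred > 0, alphas / np.maximum(pred, 1e-12), np.inf)
        keep = (alphas > 1e-6) & (ratio < 10.0) & (ratio > 1e-2)
        if keep.sum() < 3:
            break
    return float(coef[0]), float(coef[1])


def estimate_dispersion(
    counts: CountMatrix,
    sheet: SampleSheet,
    design: DesignSpec,
    size_factors: np.ndarray,
    shrink: bool = True,
) -> np.ndarray:
    """Per-gene dispersion via Cox-Reid adjusted profile likelihood.

    With ``shrink=True`` (default) gene-wise estimates are shrunk toward a
    fitted mean-dispersion trend alpha(mu) = a0/mu + a1 using a log-normal
    prior whose width is the trend-residual spread in excess of the expected
    sampling noise, in the spirit of empirical-Bayes moderation used
    throughout RNA-seq analysis.  A small floor (0.05 on the log-alpha
    variance) guards against a degenerate zero-width prior when all genes
    share one dispersion.
    """
    align_check(counts, sheet)
    X = design.matrix
    offset = np.log(np.asarray(size_factors, dtype=float))
    k = counts.values.astype(float)
    if (k.sum(axis=1) == 0).any():
        raise SaltnetError("all-zero genes must be removed before dispersion estimation")
    n_genes, n = k.shape
    alphas = np.empty(n_genes)
    for i in range(n_genes):
        alphas[i] = _maximize_alpha(k[i], X, offset)
    if not shrink:
        return alphas
    norm_means = (k / np.exp(offset)[None, :]).mean(axis=1)
    a0, a1 = _dispersion_trend(norm_means, alphas)
    trend = np.maximum(a0 / norm_means + a1, _MIN_ALPHA)
    log_resid = np.log(np.maximum(alphas, _MIN_ALPHA)) - np.log(trend)
    s_lr = 1.4826 * np.median(np.abs(log_resid - np.median(log_resid)))
    df = max((n - X.shape[1]) / 2.0, 1.0)
    sampling_var = float(special.polygamma(1, df))
    prior_var = max(s_lr**2 - sampling_var, 0.05)
    shrunk = np.empty(n_genes)
    for i in range(n_genes):
        shrunk[i] = _maximize_alpha(
            k[i], X, offset, prior=(float(np.log(trend[i])), prior_var)
        )
    return shrunk


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through untouched."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise SaltnetError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def lrt_sset(
    counts: CountMatrix,
    sheet: SampleSheet,
    size_factors: np.ndarray | None = None,
    dispersion: np.ndarray | None = None,
    fdr_threshold: float = 0.01,
    shrink_dispersion: bool = True,
) -> pd.DataFrame:
    """Likelihood-ratio test of the stress:time interaction per gene.

    Returns one row per tested gene: lrt_stat (clamped at 0), df (rank the
    interaction adds), pvalue, fdr and the SSET call at ``fdr_threshold``.
    Genes with zero total count are excluded (``tested`` = False rows are
    not emitted; they are listed in the ``.attrs['skipped']`` of the result).
    """
    align_check(counts, sheet)
    skipped = [g for g, tot in zip(counts.genes, counts.values.sum(axis=1)) if tot == 0]
    if skipped:
        logger.info("excluding %d all-zero genes from testing", len(skipped))
        counts = counts.subset_features(
            [g for g in counts.genes if g not in set(skipped)]
        )
    full = build_design(sheet, interaction=True)
    reduced = build_design(sheet, interaction=False)
    full.require_full_rank()
    reduced.require_full_rank()
    df_test = full.rank - reduced.rank
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(
            counts, sheet, full, size_factors, shrink=shrink_dispersion
        )
    fit_full = fit_nb_glm(counts, sheet, full, size_factors, dispersion)
    fit_red = fit_nb_glm(counts, sheet, reduced, size_factors, dispersion)
    stat = np.maximum(0.0, 2.0 * (fit_full.loglik - fit_red.loglik))
    ok = fit_full.converged & fit_red.converged
    pval = np.where(ok, stats.chi2.sf(stat, df_test), np.nan)
    fdr = bh_adjust(pval)
    res = pd.DataFrame(
        {
            "gene": counts.genes,
            "lrt_stat": stat,
            "df": df_test,
            "pvalue": pval,
            "fdr": fdr,
            "converged": ok,
            "is_sset": (fdr < fdr_threshold) & ok,
        }
    )
    res.attrs["skipped"] = skipped
    res.attrs["dispersion"] = np.asarray(dispersion)
    res.attrs["size_factors"] = np.asarray(size_factors)
    return res


def wald_deat(
    counts: CountMatrix,
    sheet: SampleSheet,
    size_factors: np.ndarray | None = None,
    dispersion: np.ndarray | None = None,
    fdr_threshold: float = 0.05,
    min_abs_log2fc: float = 1.0,
    shrink_dispersion: bool = True,
) -> pd.DataFrame:
    """Per-time-point Wald test of the salt-vs-control contrast.

    For every post-baseline time t the contrast is stress + stress:time_t
    (on the natural-log scale); at the baseline itself it is the stress
    main effect.  FDR is controlled per time level across genes.
    """
    align_check(counts, sheet)
    keep = [g for g, tot in zip(counts.genes, counts.values.sum(axis=1)) if tot > 0]
    counts = counts.subset_features(keep)
    full = build_design(sheet, interaction=True)
    full.require_full_rank()
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(
            counts, sheet, full, size_factors, shrink=shrink_dispersion
        )
    fit = fit_nb_glm(counts, sheet, full, size_factors, dispersion)

    names = list(full.column_names)
    stress_levels = sheet.treatment_levels[1:]
    time_levels = sheet.time_levels
    rows = []
    covs = [np.linalg.pinv(_gene_xtwx(fit, i)) for i in range(len(counts.genes))]
    for s_lev in stress_levels:
        s_idx = names.index(f"stress[{s_lev}]")
        for t_lev in time_levels:
            c = np.zeros(len(names))
            c[s_idx] = 1.0
            inter_name = f"stress[{s_lev}]:time[{t_lev}]"
            if inter_name in names:
                c[names.index(inter_name)] = 1.0
            ests = fit.coefficients @ c
            ses = np.array([np.sqrt(max(c @ cov @ c, 0.0)) for cov in covs])
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(ses > 0, ests / ses, 0.0)
            p = np.where(ses > 0, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
            fdr = bh_adjust(p)
            log2fc = ests / LN2
            for i, g in enumerate(counts.genes):
                rows.append(
                    {
                        "gene": g,
                        "stress": s_lev,
                        "time": t_lev,
                        "log2fc": log2fc[i],
                        "se": ses[i] / LN2,
                        "wald_stat": z[i],
                        "pvalue": p[i],
                        "fdr": fdr[i],
                        "is_deat": bool(
                            np.isfinite(fdr[i])
                            and fdr[i] < fdr_threshold
                            and abs(log2fc[i]) >= min_abs_log2fc
                        ),
                    }
                )
    return pd.DataFrame(rows)


def _gene_xtwx(fit: NbFit, i: int) -> np.ndarray:
    X = fit.design.matrix
    mu = fit.mu[i]
    w = mu / (1.0 + fit.dispersion[i] * mu)
    return X.T @ (X * w[:, None])


def wald_deat_by_ecotype(
    counts: CountMatrix, sheet: SampleSheet, ecotype: str, **kwargs
) -> pd.DataFrame:
    """DEAT testing within one ecotype (samples subset before fitting)."""
    mask = (sheet.table["ecotype"] == ecotype).to_numpy()
    return wald_deat(counts.subset_samples(mask), sheet.subset(mask), **kwargs)


def lrt_sset_by_ecotype(
    counts: CountMatrix, sheet: SampleSheet, ecotype: str, **kwargs
) -> pd.DataFrame:
    """SSET testing within one ecotype (samples subset before fitting)."""
    mask = (sheet.table["ecotype"] == ecotype).to_numpy()
    return lrt_sset(counts.subset_samples(mask), sheet.subset(mask), **kwargs)
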