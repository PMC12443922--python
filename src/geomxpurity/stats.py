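"""Group-comparison statistics: tumor-aggregated negative-binomial
differential expression, random-intercept mixed models with marginal-means
contrasts, FDR control, and exact Wilcoxon tests.

The DE routine follows the familiar pseudobulk recipe: median-of-ratios
size factors, per-gene NB GLMs with a log link, gene-wise dispersions by
maximum (Cox–Reid-adjusted) profile likelihood shrunk toward a fitted
mean-dispersion trend in log space, and a Wald test on the condition
coefficient with Benjamini–Hochberg correction. The estimator deliberately
omits outlier replacement and independent filtering for determinism.

The linear mixed model is a single random intercept (patient) fitted by
REML with the variance ratio profiled out; p-values use containment
degrees of freedom. Tukey adjustment uses the studentized-range
distribution. Exact Wilcoxon tests enumerate the null by dynamic
programming (mid-ranked ties, zeros dropped).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import AOIDataset

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------

def pseudobulk(
    dataset: AOIDataset,
    surviving_aois: list[str],
    segment: str,
) -> pd.DataFrame:
    """Sum raw counts over each tumor's surviving AOIs of one segment.

    Returns a tumors x genes integer matrix; tumors without surviving AOIs
    of the segment are dropped with a log entry.
    """
    meta = dataset.aoi_meta
    keep = meta.index.isin(surviving_aois) & (meta["segment"] == segment)
    aois = list(meta.index[keep])
    if not aois:
        raise ValueError(f"no surviving {segment}+ AOIs to aggregate")
    tumor = meta.loc[aois, "tumor_id"]
    agg = dataset.counts[aois].T.groupby(tumor).sum()
    dropped = set(meta.loc[meta["segment"] == segment, "tumor_id"]) - set(agg.index)
    if dropped:
        logger.info("pseudobulk: %d tumors dropped (no surviving AOIs): %s",
                    len(dropped), sorted(dropped))
    agg.index.name = "tumor_id"
    return agg


# ---------------------------------------------------------------------------
# negative-binomial Wald DE
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene Wald-test results for a two-condition pseudobulk design."""

    table: pd.DataFrame            # baseMean, log2FoldChange, lfcSE, stat, pvalue, qvalue, dispersion
    size_factors: pd.Series
    excluded_genes: list[str]
    condition_levels: tuple[str, str]   # (reference, tested)


def median_of_ratios_size_factors(counts: np.ndarray, min_positive: int = 10) -> np.ndarray:
    """DESeq-style size factors (geometric-mean reference over all-positive genes).

    Falls back to geometric means over positive counts only when fewer than
    ``min_positive`` genes are positive in every sample.
    """
    counts = np.asarray(counts, dtype=float)  # samples x genes
    all_pos = (counts > 0).all(axis=0)
    if all_pos.sum() >= min_positive:
        logc = np.log(counts[:, all_pos])
        ref = logc.mean(axis=0)
        sf = np.exp(np.median(logc - ref, axis=1))
    else:
        warnings.warn(
            f"only {int(all_pos.sum())} genes positive in all samples; "
            "using positive-count geometric-mean reference"
        )
        any_pos = (counts > 0).any(axis=0)
        with np.errstate(divide="ignore"):
            logc = np.where(counts[:, any_pos] > 0, np.log(counts[:, any_pos]), np.nan)
        ref = np.nanmean(logc, axis=0)
        ratios = logc - ref
        sf = np.exp(np.nanmedian(ratios, axis=1))
    sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean 1
    return sf


def _irls_nb(Y, X, offset, alpha, beta0=None, n_iter=30, tol=1e-10):
    """Vectorized IRLS for per-gene NB GLMs sharing one design matrix.

    Y: (G, n) counts; X: (n, p); offset: (n,); alpha: scalar or (G,).
    Returns (beta (G, p), mu (G, n), fisher information (G, p, p)).
    """
    G, n = Y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (G,))
    if beta0 is None:
        eta0 = np.log(Y + 0.5) - offset[None, :]
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ eta0.T).T
    else:
        beta = beta0.copy()
    eye = np.eye(p) * 1e-10
    for _ in range(n_iter):
        xb = np.clip(beta @ X.T, -30.0, 30.0)
        mu = np.exp(xb + offset[None, :])
        W = mu / (1.0 + alpha[:, None] * mu)
        z = xb + (Y - mu) / mu
        A = np.einsum("gn,ni,nj->gij", W, X, X) + eye
        b = np.einsum("gn,gn,ni->gi", W, z, X)
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            break
    xb = np.clip(beta @ X.T, -30.0, 30.0)
    mu = np.exp(xb + offset[None, :])
    W = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("gn,ni,nj->gij", W, X, X)
    return beta, mu, A


def _nb_loglik(Y, mu, alpha):
    """NB log-likelihood per gene; alpha (G,) dispersion, var = mu + alpha mu^2."""
    r = 1.0 / alpha[:, None]
    return (
        special.gammaln(Y + r)
        - special.gammaln(r)
        - special.gammaln(Y + 1.0)
        + r * np.log(r / (r + mu))
        + Y * np.log(mu / (r + mu))
    ).sum(axis=1)


def nb_wald_de(
    counts: pd.DataFrame,
    condition: pd.Series,
    ref_level: str | None = None,
    prior_weight: float = 10.0,
    alpha_grid: np.ndarray | None = None,
    lowess_frac: float = 0.6,
) -> DEResult:
    """Two-condition negative-binomial Wald differential expression.

    Parameters
    ----------
    counts
        tumors x genes raw integer pseudobulk counts.
    condition
        Two-level label per tumor; the log2 fold change is tested level vs
        ``ref_level`` (default: alphabetically first level).
    prior_weight
        Weight of the mean-dispersion trend when shrinking gene-wise
        dispersions (weighted average in log-dispersion space against the
        residual degrees of freedom).
    """
    condition = condition.loc[counts.index]
    levels = sorted(condition.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition levels, got {levels}")
    if ref_level is None:
        ref_level = levels[0]
    test_level = [l for l in levels if l != ref_level][0]
    for lev in levels:
        if (condition == lev).sum() < 2:
            raise ValueError(f"condition {lev!r} has fewer than 2 tumors")

    Yall = counts.to_numpy(dtype=float)  # samples x genes
    sf = median_of_ratios_size_factors(Yall)
    size_factors = pd.Series(sf, index=counts.index, name="size_factor")

    nonzero = Yall.sum(axis=0) > 0
    excluded = list(counts.columns[~nonzero])
    if excluded:
        logger.info("nb_wald_de: excluding %d all-zero genes", len(excluded))
    genes = list(counts.columns[nonzero])
    Y = Yall[:, nonzero].T  # genes x samples
    G, n = Y.shape

    X = np.column_stack([np.ones(n), (condition == test_level).to_numpy(float)])
    offset = np.log(sf)
    base_mean = (Y / sf[None, :]).mean(axis=1)

    # gene-wise dispersion: Cox-Reid adjusted profile likelihood on a log grid
    if alpha_grid is None:
        alpha_grid = np.logspace(-4, 1, 31)
    apl = np.empty((G, len(alpha_grid)))
    beta_ws = None
    for j, a in enumerate(alpha_grid):
        beta_ws, mu, A = _irls_nb(Y, X, offset, a, beta0=beta_ws, n_iter=12)
        sign, logdet = np.linalg.slogdet(A)
        apl[:, j] = _nb_loglik(Y, mu, np.full(G, a)) - 0.5 * logdet
    best = np.argmax(apl, axis=1)
    log_a = np.log(alpha_grid)
    alpha_hat = np.exp(log_a[best])
    # parabolic refinement on interior maxima
    interior = (best > 0) & (best < len(alpha_grid) - 1)
    if interior.any():
        i = best[interior]
        y0, y1, y2 = (apl[interior, i - 1], apl[interior, i], apl[interior, i + 1])
        x0, x1, x2 = log_a[i - 1], log_a[i], log_a[i + 1]
        denom = (y0 - 2 * y1 + y2)
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        step = x2 - x1
        alpha_hat[interior] = np.exp(np.clip(x1 + shift * step, log_a[0], log_a[-1]))

    # mean-dispersion trend (lowess in log-log space) and log-space shrinkage
    log_mu = np.log(base_mean)
    trend = lowess(np.log(alpha_hat), log_mu, frac=lowess_frac, return_sorted=False)
    m_df = max(n - X.shape[1], 1)
    log_alpha_final = (m_df * np.log(alpha_hat) + prior_weight * trend) / (m_df + prior_weight)
    alpha_final = np.exp(log_alpha_final)

    beta, mu, A = _irls_nb(Y, X, offset, alpha_final, n_iter=30)
    cov = np.linalg.inv(A)
    se = np.sqrt(cov[:, 1, 1])
    stat = beta[:, 1] / se
    # t reference with residual df: small-sample calibration for the Wald
    # statistic under estimated dispersion (a normal reference is visibly
    # anticonservative at a dozen pseudobulk samples)
    pvals = 2.0 * stats.t.sf(np.abs(stat), max(n - X.shape[1], 1))
    qvals = bh_fdr(pvals)

    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": beta[:, 1] / _LN2,
            "lfcSE": se / _LN2,
            "stat": stat,
            "pvalue": pvals,
            "qvalue": qvals,
            "dispersion_genewise": alpha_hat,
            "dispersion": alpha_final,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return DEResult(
        table=table,
        size_factors=size_factors,
        excluded_genes=excluded,
        condition_levels=(ref_level, test_level),
    )


# ---------------------------------------------------------------------------
# random-intercept linear mixed model (profile REML)
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """REML fit of y = group + (1 | patient) with cell-means coding."""

    levels: list[str]
    beta: pd.Series                # cell means
    cov_beta: pd.DataFrame
    sigma2_resid: float
    sigma2_patient: float
    variance_ratio: float          # sigma2_patient / sigma2_resid
    df_containment: int
    n_obs: int
    notes: dict = field(default_factory=dict)


def _blockwise_gls(y, X, patient_codes, counts, lam):
    """GLS pieces for V = I + lam * Z Z' with a patient random intercept.

    Uses the Woodbury identity per patient block:
    Vinv = I - (lam / (1 + lam * n_i)) J within each block.
    Returns (XtVinvX, XtVinvy, ytVinvy, logdetV).
    """
    shrink = lam / (1.0 + lam * counts)  # per patient
    # block sums
    q = len(counts)
    p = X.shape[1]
    sum_y = np.zeros(q)
    sum_X = np.zeros((q, p))
    np.add.at(sum_y, patient_codes, y)
    np.add.at(sum_X, patient_codes, X)
    XtVinvX = X.T @ X - (sum_X * shrink[:, None]).T @ sum_X
    XtVinvy = X.T @ y - sum_X.T @ (shrink * sum_y)
    logdetV = float(np.sum(np.log1p(lam * counts)))

    def resid_quadform(beta: np.ndarray) -> float:
        # (y - Xb)' Vinv (y - Xb), computed from residuals to avoid the
        # cancellation of y'Vinv y - b'beta for well-fitting models
        r = y - X @ beta
        sum_r = np.zeros(q)
        np.add.at(sum_r, patient_codes, r)
        return float(r @ r - shrink @ sum_r**2)

    return XtVinvX, XtVinvy, resid_quadform, logdetV


def fit_random_intercept(
    y: pd.Series,
    group: pd.Series,
    patient: pd.Series,
) -> LMMFit:
    """REML fit of a one-way design with a patient random intercept.

    The variance ratio lambda = sigma2_patient / sigma2_resid is profiled
    out of the REML criterion; its score equation is solved by bracketed
    root-finding on the analytic profile gradient (machine-precision
    optimum). The boundary lambda = 0 (plain OLS) is used when the
    criterion is increasing there or the profile is degenerate.
    """
    y = np.asarray(y, dtype=float)
    if len(set(patient)) < 2:
        raise ValueError("need at least two patients")
    levels = sorted(pd.unique(group))
    X = np.column_stack([(np.asarray(group) == l).astype(float) for l in levels])
    codes, uniques = pd.factorize(np.asarray(patient))
    counts = np.bincount(codes).astype(float)
    n, p = X.shape

    if np.ptp(y) == 0:
        beta = pd.Series(y[0], index=levels)
        cov = pd.DataFrame(np.zeros((p, p)), index=levels, columns=levels)
        df_cont = n - np.linalg.matrix_rank(
            np.column_stack([X, np.eye(len(uniques))[codes]])
        )
        return LMMFit(levels, beta, cov, 0.0, 0.0, 0.0, df_cont, n,
                      notes={"degenerate": "constant response"})

    def reml_gradient(lam: float) -> float:
        """d/d lam of the (doubled) profile REML criterion.

        Uses the envelope theorem for the profiled beta; each trace term
        collapses to per-patient block sums via the Woodbury form of Vinv.
        """
        A, b, quadform, _ = _blockwise_gls(y, X, codes, counts, lam)
        beta = np.linalg.solve(A, b)
        qf = quadform(beta)
        if qf <= 0 or not np.isfinite(qf):
            return np.nan
        w = 1.0 / (1.0 + lam * counts)            # Vinv shrink per block
        r = y - X @ beta
        sum_r = np.zeros(len(counts))
        np.add.at(sum_r, codes, r)
        sum_X = np.zeros((len(counts), p))
        np.add.at(sum_X, codes, X)
        M = (sum_X * w[:, None]).T                # X' Vinv Z, shape (p, q)
        term_logdetV = float(np.sum(counts * w))
        term_logdetA = float(np.trace(np.linalg.solve(A, M @ M.T)))
        term_qf = float(np.sum((w * sum_r) ** 2))
        return term_logdetV - term_logdetA - (n - p) * term_qf / qf

    notes: dict = {}
    lam_hat = 0.0
    g0 = reml_gradient(0.0)
    if not np.isfinite(g0):
        warnings.warn("non-positive-definite REML profile; falling back to OLS")
        notes["fallback"] = "ols"
    elif g0 >= 0:
        # criterion increasing at the boundary: REML optimum at ratio 0
        notes["boundary"] = "variance ratio at zero (OLS fallback)"
    else:
        hi = 1.0
        while reml_gradient(hi) < 0 and hi < 1e8:
            hi *= 10.0
        if reml_gradient(hi) < 0:
            lam_hat = hi
            notes["boundary"] = "variance ratio at upper bound"
        else:
            lam_hat = float(
                optimize.brentq(reml_gradient, 0.0, hi, xtol=1e-14, rtol=1e-15)
            )

    A, b, quadform, _ = _blockwise_gls(y, X, codes, counts, lam_hat)
    beta = np.linalg.solve(A, b)
    qf = quadform(beta)
    sigma2 = qf / (n - p)
    cov = sigma2 * np.linalg.inv(A)
    df_cont = int(n - np.linalg.matrix_rank(np.column_stack([X, np.eye(len(uniques))[codes]])))
    return LMMFit(
        levels=levels,
        beta=pd.Series(beta, index=levels),
        cov_beta=pd.DataFrame(cov, index=levels, columns=levels),
        sigma2_resid=float(sigma2),
        sigma2_patient=float(lam_hat * sigma2),
        variance_ratio=float(lam_hat),
        df_containment=max(df_cont, 1),
        n_obs=n,
        notes=notes,
    )


@dataclass
class EMMResult:
    """Estimated marginal means and all pairwise Tukey-adjusted contrasts."""

    emmeans: pd.DataFrame
    contrasts: pd.DataFrame
    sigma2_resid: float
    sigma2_patient: float
    df: int


def emmeans_tukey(fit: LMMFit) -> EMMResult:
    """Marginal means per design cell plus Tukey-adjusted pairwise contrasts.

    With cell-means coding and no covariates the marginal means are the
    fitted cell means; the adjustment uses the studentized-range
    distribution with the containment denominator degrees of freedom. With
    two cells the adjustment is the identity (the k = 2 studentized range
    reduces to |t| * sqrt(2)).
    """
    k = len(fit.levels)
    if k > 4:
        raise ValueError("designs with more than 4 cells are not supported")
    df = fit.df_containment
    emm = pd.DataFrame(
        {
            "emmean": fit.beta,
            "SE": np.sqrt(np.diag(fit.cov_beta)),
            "df": df,
        }
    )
    rows = []
    for a, b in combinations(fit.levels, 2):
        est = fit.beta[a] - fit.beta[b]
        var = (
            fit.cov_beta.loc[a, a] + fit.cov_beta.loc[b, b] - 2 * fit.cov_beta.loc[a, b]
        )
        se = float(np.sqrt(max(var, 0.0)))
        if se == 0:
            tstat, p_raw, p_adj = 0.0, 1.0, 1.0
        else:
            tstat = est / se
            p_raw = 2.0 * stats.t.sf(abs(tstat), df)
            p_adj = float(stats.studentized_range.sf(abs(tstat) * np.sqrt(2.0), k, df))
            p_adj = min(max(p_adj, p_raw), 1.0)
        rows.append(
            {"contrast": f"{a} - {b}", "estimate": est, "SE": se,
             "t": tstat, "df": df, "p_raw": p_raw, "p_tukey": p_adj}
        )
    return EMMResult(
        emmeans=emm,
        contrasts=pd.DataFrame(rows),
        sigma2_resid=fit.sigma2_resid,
        sigma2_patient=fit.sigma2_patient,
        df=df,
    )


# ---------------------------------------------------------------------------
# FDR and exact rank tests
# ---------------------------------------------------------------------------

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


@dataclass
class RankTestResult:
    statistic: float
    pvalue: float
    n: int
    method: str


def wilcoxon_signed_rank_exact(
    x, y=None, exact_max_n: int = 25
) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test, exact for small samples.

    Differences of zero are dropped (Wilcoxon convention) and tied absolute
    differences are mid-ranked. For n <= ``exact_max_n`` the null
    distribution of W+ is enumerated over all 2^n sign assignments by
    dynamic programming (exact even with ties); the two-sided p-value is
    2 * min(P(W <= w), P(W >= w)) capped at 1. Larger samples use the
    tie-corrected normal approximation.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all differences are zero; p = 1")
        return RankTestResult(0.0, 1.0, 0, "degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        r2 = np.round(2 * ranks).astype(int)   # doubled ranks are integers even with ties
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            new = dist.copy()
            new[r:] += dist[: total + 1 - r]
            dist = new
        denom = 2.0**n
        w2 = int(round(2 * w_pos))
        p_le = dist[: w2 + 1].sum() / denom
        p_ge = dist[w2:].sum() / denom
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankTestResult(w_pos, p, n, "exact")
    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    _, t_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(t_counts**3 - t_counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return RankTestResult(w_pos, 1.0, n, "degenerate")
    z = (w_pos - mean) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return RankTestResult(w_pos, p, n, "normal")


def wilcoxon_rank_sum(x, y, exact_max_total: int = 20) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact by enumeration of the rank-sum null when m + n <= ``exact_max_total``
    and there are no ties; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    N = m + n
    ranks = stats.rankdata(combined)
    W = float(ranks[:m].sum())
    has_ties = len(np.unique(combined)) < N
    if N <= exact_max_total and not has_ties:
        smax = int(np.sum(np.arange(N - m + 1, N + 1)))
        ways = np.zeros((m + 1, smax + 1))
        ways[0, 0] = 1.0
        for i in range(1, N + 1):
            new = ways.copy()
            new[1:, i:] += ways[:-1, : smax + 1 - i]
            ways = new
        dist = ways[m]
        denom = special.comb(N, m, exact=True)
        w = int(round(W))
        p_le = dist[: w + 1].sum() / denom
        p_ge = dist[w:].sum() / denom
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankTestResult(W, p, N, "exact")
    mean = m * (N + 1) / 2.0
    _, t_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(t_counts**3 - t_counts) / (N * (N - 1))
    var = m * n / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        warnings.warn("all observations identical; p = 1")
        return RankTestResult(W, 1.0, N, "degenerate")
    z = (W - mean) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return RankTestResult(W, p, N, "normal")
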