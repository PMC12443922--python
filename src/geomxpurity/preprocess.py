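"""Gene filtering against negative probes, quantile normalization, and
parametric empirical-Bayes batch correction.

The processing order is fixed: filter genes against the negative-probe
background, quantile-normalize the retained counts, log2-transform, then
correct the experiment-run batch effect. :class:`NormalizedMatrix` carries
provenance flags so downstream stages can assert this order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AOIDataset

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """genes x AOIs real-valued expression on the log2(quantile + 1) scale."""

    data: pd.DataFrame
    normalized: bool = True
    batch_corrected: bool = False
    log_note: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def aoi_ids(self) -> list[str]:
        return list(self.data.columns)


def filter_genes_by_negative_probes(
    dataset: AOIDataset, k: float = 2.0
) -> tuple[list[str], pd.DataFrame]:
    """Retain genes whose signal exceeds the negative-probe background.

    Negative-probe counts are pooled over probes and AOIs to a single
    background mean ``m_neg`` and SD ``s_neg`` (a global limit of detection).
    A gene is retained iff its mean count exceeds ``m_neg + k*s_neg`` or its
    count variance exceeds the square of that threshold — i.e. expression
    mean or variance more than ``k`` background SDs above background.

    Returns the retained gene list and a per-gene report with the statistics
    and which rule fired.
    """
    neg = dataset.negprobe_counts.to_numpy(dtype=float).ravel()
    if neg.size < 2:
        raise ValueError("need at least two pooled negative-probe values to estimate an SD")
    m_neg = float(neg.mean())
    s_neg = float(neg.std(ddof=1))
    thresh = m_neg + k * s_neg

    counts = dataset.counts.to_numpy(dtype=float)
    gene_mean = counts.mean(axis=1)
    gene_var = counts.var(axis=1, ddof=1) if counts.shape[1] > 1 else np.zeros(len(gene_mean))
    pass_mean = gene_mean > thresh
    pass_var = gene_var > thresh**2
    retained = pass_mean | pass_var

    report = pd.DataFrame(
        {
            "mean": gene_mean,
            "variance": gene_var,
            "pass_mean": pass_mean,
            "pass_variance": pass_var,
            "retained": retained,
        },
        index=dataset.counts.index,
    )
    report.attrs["neg_mean"] = m_neg
    report.attrs["neg_sd"] = s_neg
    report.attrs["threshold"] = thresh
    kept = list(dataset.counts.index[retained])
    logger.info(
        "negative-probe filter: kept %d/%d genes (threshold %.3f = %.3f + %g*%.3f)",
        len(kept), len(report), thresh, m_neg, k, s_neg,
    )
    return kept, report


def quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Classic quantile normalization (pre-log scale).

    Every column is mapped onto the across-column mean of the order
    statistics; tied values within a column receive the mean of the
    reference values their tied positions span. The operation is idempotent
    and makes all column value multisets identical up to tie-averaging.
    """
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n_rows)
        mapped[order] = reference
        # average the reference values over tied positions
        s = pd.Series(mapped)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return out


def quantile_normalize(counts: pd.DataFrame, log_transform: bool = True) -> NormalizedMatrix:
    """Quantile-normalize a genes x AOIs count matrix, then log2(x + 1)."""
    qn = quantile_normalize_values(counts.to_numpy())
    if log_transform:
        qn = np.log2(qn + 1.0)
    data = pd.DataFrame(qn, index=counts.index, columns=counts.columns)
    return NormalizedMatrix(data=data, normalized=True, batch_corrected=False)


# ---------------------------------------------------------------------------
# parametric empirical-Bayes batch correction (ComBat-style)
# ---------------------------------------------------------------------------

def _design_matrix(batch: pd.Series, covariates: pd.DataFrame | None) -> tuple[np.ndarray, int, list[str]]:
    """Batch one-hot columns followed by protected covariate dummies.

    Covariates whose dummies are confounded with batch (rank-deficient
    design) are dropped with a warning.
    """
    batch_dummies = pd.get_dummies(batch, dtype=float)
    n_batch = batch_dummies.shape[1]
    design = batch_dummies
    dropped: list[str] = []
    if covariates is not None:
        for col in covariates.columns:
            dummies = pd.get_dummies(covariates[col], prefix=col, drop_first=True, dtype=float)
            cand = pd.concat([design, dummies], axis=1)
            if np.linalg.matrix_rank(cand.to_numpy()) < cand.shape[1]:
                warnings.warn(
                    f"covariate {col!r} is confounded with batch; "
                    "proceeding without it in the standardization design"
                )
                dropped.append(col)
                continue
            design = cand
    return design.to_numpy(dtype=float), n_batch, dropped


def correct_batch(
    norm: NormalizedMatrix,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    eb_tol: float = 1e-8,
    max_iter: int = 2000,
) -> NormalizedMatrix:
    """Remove a run/batch effect by parametric empirical-Bayes adjustment.

    Per gene the data are standardized against a design containing batch
    indicators plus protected biological covariates (e.g. arm, setting);
    per-batch gene-wise locations and scales are estimated, shrunk toward
    batch-level normal / inverse-gamma priors (method-of-moments hyperpriors,
    iterative conditional posterior updates to ``eb_tol``), and the data are
    adjusted and de-standardized. A final per-gene recentering restores each
    gene's grand mean exactly, so correction never moves global expression
    levels.

    With a single batch the input is returned unchanged.
    """
    if not norm.normalized:
        raise ValueError("correct_batch expects a normalized matrix")
    batch = batch.loc[norm.data.columns]
    levels = batch.unique()
    if len(levels) < 2:
        logger.info("single batch: no correction applied")
        return replace(norm, data=norm.data.copy(), batch_corrected=True)
    counts_per_batch = batch.value_counts()
    if (counts_per_batch < 2).any():
        raise ValueError("every batch needs at least two AOIs")

    X = norm.data.to_numpy(dtype=float)  # genes x samples
    n_genes, n_samples = X.shape
    design, n_batch, _ = _design_matrix(batch, covariates)
    batch_onehot = design[:, :n_batch]
    n_per_batch = batch_onehot.sum(axis=0)

    # per-gene OLS fit of the full design; first n_batch coefs are batch means
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (p, genes)
    grand_mean = (n_per_batch / n_samples) @ beta[:n_batch]  # (genes,)
    resid = X.T - design @ beta
    var_pooled = np.maximum((resid**2).mean(axis=0), 1e-12)  # (genes,)

    stand_mean = np.tile(grand_mean, (n_samples, 1))
    if design.shape[1] > n_batch:
        stand_mean = stand_mean + design[:, n_batch:] @ beta[n_batch:]
    Z = (X.T - stand_mean) / np.sqrt(var_pooled)  # samples x genes

    Z_adj = Z.copy()
    for b in range(n_batch):
        idx = batch_onehot[:, b] > 0
        nb = int(idx.sum())
        Zb = Z[idx]  # nb x genes
        gamma_hat = Zb.mean(axis=0)
        delta_hat = Zb.var(axis=0, ddof=1)

        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        V = max(delta_hat.var(ddof=1), 1e-12)
        a_prior = (2 * V + m**2) / V
        b_prior = (m * V + m**3) / V

        gamma_star = gamma_hat.copy()
        delta_star = np.maximum(delta_hat.copy(), 1e-12)
        ss0 = ((Zb - gamma_hat) ** 2).sum(axis=0)
        for _ in range(max_iter):
            if t2 > 0:
                g_new = (t2 * nb * gamma_hat + delta_star * gamma_bar) / (t2 * nb + delta_star)
            else:
                g_new = np.full_like(gamma_hat, gamma_bar)
            ssq = ss0 + nb * (gamma_hat - g_new) ** 2
            d_new = (b_prior + 0.5 * ssq) / (nb / 2.0 + a_prior - 1.0)
            d_new = np.maximum(d_new, 1e-12)
            change = max(
                np.max(np.abs(g_new - gamma_star)) if gamma_star.size else 0.0,
                np.max(np.abs(d_new - delta_star) / d_new),
            )
            gamma_star, delta_star = g_new, d_new
            if change < eb_tol:
                break

        Z_adj[idx] = (Zb - gamma_star) / np.sqrt(delta_star)

    out = Z_adj * np.sqrt(var_pooled) + stand_mean  # samples x genes
    out = out.T  # genes x samples
    # restore each gene's grand mean exactly
    out += (X.mean(axis=1) - out.mean(axis=1))[:, None]

    data = pd.DataFrame(out, index=norm.data.index, columns=norm.data.columns)
    return replace(norm, data=data, batch_corrected=True)


def preprocess_dataset(
    dataset: AOIDataset,
    k: float = 2.0,
    batch_correct: bool = True,
    covariate_columns: tuple[str, ...] = ("arm", "setting"),
) -> tuple[NormalizedMatrix, pd.DataFrame]:
    """Full preprocessing: gene filter, quantile normalization, batch correction.

    Returns the normalized (and, if requested, batch-corrected) matrix plus
    the per-gene filter report.
    """
    kept, report = filter_genes_by_negative_probes(dataset, k=k)
    norm = quantile_normalize(dataset.counts.loc[kept])
    if batch_correct and dataset.aoi_meta["batch"].nunique() > 1:
        covs = dataset.aoi_meta[list(covariate_columns)]
        norm = correct_batch(norm, dataset.aoi_meta["batch"], covariates=covs)
    return norm, report
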