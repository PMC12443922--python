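"""Expression-inferred broad copy-number profiles and hallmark calls.

Glioblastoma's defining broad alterations — chromosome 7 gain and
chromosome 10 loss — shift the average expression of genes along those
chromosomes. Following the reference-cell design of expression-CNV tools,
each query AOI's log expression is compared against the mean of a
non-malignant reference population (by default the IBA1+ macrophage
segments), clipped, median-centered, and smoothed by a moving average along
the genome within each chromosome. Per-chromosome mean scores are
thresholded into hallmark calls, and a 2-group Ward clustering on the
(chr7, chr10) score pair is reported alongside as the supervised grouping
aid an analyst would inspect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .io import GeneAnnotation
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class CNVProfile:
    """Smoothed per-AOI log-ratio track and per-chromosome scores."""

    smoothed: pd.DataFrame        # ordered genes x query AOIs
    gene_chromosome: pd.Series    # chromosome per ordered gene
    chrom_scores: pd.DataFrame    # query AOIs x chromosomes (mean smoothed log-ratio)
    window: int
    clip: float
    reference_aois: list[str]


def moving_average_in_blocks(values: np.ndarray, blocks: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of length ``window`` within contiguous blocks.

    ``values`` is (positions x columns); ``blocks`` labels each position's
    block (e.g. chromosome). The window shrinks at block edges so no
    smoothing crosses a block boundary.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    out = np.empty_like(values, dtype=float)
    start = 0
    n = len(blocks)
    while start < n:
        end = start
        while end < n and blocks[end] == blocks[start]:
            end += 1
        block = values[start:end]
        L = end - start
        cs = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
        idx = np.arange(L)
        lo = np.maximum(0, idx - half)
        hi = np.minimum(L - 1, idx + half)
        out[start:end] = (cs[hi + 1] - cs[lo]) / (hi + 1 - lo)[:, None]
        start = end
    return out


def compute_cnv_profile(
    norm: NormalizedMatrix,
    annotation: GeneAnnotation,
    reference_aois: list[str],
    query_aois: list[str] | None = None,
    window: int = 101,
    clip: float = 3.0,
    min_genes_per_chrom: int = 3,
    batch: pd.Series | None = None,
) -> CNVProfile:
    """Smoothed expression log-ratio profile of query AOIs vs a reference.

    Per gene: log-ratio = query log2 expression minus the mean reference
    log2 expression; values are centered per AOI by the genome-wide
    median, clipped to ``±clip``, smoothed by a centered ``window``-gene
    moving average within each chromosome (window truncated at chromosome
    edges), and re-centered. Genes absent from the annotation are excluded from CNV
    analysis only; chromosomes with fewer than ``min_genes_per_chrom``
    retained genes are dropped with a warning.

    When ``batch`` labels are supplied each query AOI is compared against
    the mean of the reference AOIs of its own experimental run, so any
    residual run-level gene bias cancels in the ratio (reference cells
    matched to the run, as in reference-cell CNV inference).
    """
    if not reference_aois:
        raise ValueError("reference_aois must be non-empty")
    missing_ref = sorted(set(reference_aois) - set(norm.data.columns))
    if missing_ref:
        raise KeyError(f"reference AOIs absent from matrix: {missing_ref[:10]}")
    if query_aois is None:
        query_aois = [a for a in norm.data.columns if a not in set(reference_aois)]
    if not query_aois:
        raise ValueError("no query AOIs")

    ann = annotation.ordered_genes(norm.genes)
    n_absent = len(norm.genes) - len(ann)
    if n_absent:
        logger.info("excluding %d genes without annotation from CNV analysis", n_absent)
    chrom_sizes = ann.groupby("chromosome").size()
    small = chrom_sizes[chrom_sizes < min_genes_per_chrom].index.tolist()
    if small:
        warnings.warn(f"chromosomes with fewer than {min_genes_per_chrom} genes excluded: {small}")
        ann = ann[~ann["chromosome"].isin(small)]
    chrom_sizes = ann.groupby("chromosome").size()
    if window > int(chrom_sizes.min()):
        raise ValueError(
            f"window {window} exceeds the smallest analyzed chromosome "
            f"({chrom_sizes.idxmin()}: {int(chrom_sizes.min())} genes)"
        )

    genes = list(ann.index)
    expr = norm.data.loc[genes]
    query_arr = expr[query_aois].to_numpy()
    if batch is None:
        ref_mean = expr[reference_aois].to_numpy().mean(axis=1)
        lr = query_arr - ref_mean[:, None]
    else:
        ref_batch = batch.loc[reference_aois]
        query_batch = batch.loc[query_aois]
        missing_batches = sorted(set(query_batch) - set(ref_batch))
        if missing_batches:
            raise ValueError(f"no reference AOIs for batches: {missing_batches}")
        ref_means = {
            b: expr[list(pd.Index(reference_aois)[(ref_batch == b).to_numpy()])]
            .to_numpy()
            .mean(axis=1)
            for b in set(ref_batch)
        }
        lr = np.column_stack(
            [query_arr[:, j] - ref_means[query_batch.iloc[j]] for j in range(len(query_aois))]
        )
    # center before clipping so profiles are invariant to a constant
    # offset of the query AOI (library-size remnants must not eat into
    # the clipping range)
    lr -= np.median(lr, axis=0, keepdims=True)
    lr = np.clip(lr, -clip, clip)
    chroms = ann["chromosome"].to_numpy()
    smoothed = moving_average_in_blocks(lr, chroms, window)
    smoothed -= np.median(smoothed, axis=0, keepdims=True)

    smoothed_df = pd.DataFrame(smoothed, index=genes, columns=query_aois)
    chrom_series = pd.Series(chroms, index=genes, name="chromosome")
    scores = (
        smoothed_df.groupby(chrom_series).mean().T
    )  # AOIs x chromosomes
    scores = scores[[c for c in annotation.chrom_order if c in scores.columns]]
    return CNVProfile(
        smoothed=smoothed_df,
        gene_chromosome=chrom_series,
        chrom_scores=scores,
        window=window,
        clip=clip,
        reference_aois=list(reference_aois),
    )


def score_and_call(
    profile: CNVProfile,
    gain_thresh: float = 0.15,
    loss_thresh: float = -0.15,
    gain_chrom: str = "7",
    loss_chrom: str = "10",
) -> pd.DataFrame:
    """Hallmark chr7-gain / chr10-loss calls plus a 2-group Ward clustering.

    An AOI is called gained iff its chr7 mean score strictly exceeds
    ``gain_thresh`` and lost iff its chr10 score is strictly below
    ``loss_thresh``. The hierarchical 2-cluster assignment on the
    (chr7 score, chr10 score) pair is reported for analyst review; with
    degenerate (identical) scores a single cluster is returned with a
    warning.
    """
    if not (gain_thresh > 0 > loss_thresh):
        raise ValueError("need gain_thresh > 0 > loss_thresh")
    for c in (gain_chrom, loss_chrom):
        if c not in profile.chrom_scores.columns:
            raise KeyError(f"chromosome {c!r} missing from profile scores")
    s7 = profile.chrom_scores[gain_chrom]
    s10 = profile.chrom_scores[loss_chrom]
    calls = pd.DataFrame(
        {
            "chr7_score": s7,
            "chr10_score": s10,
            "chr7_gain": s7 > gain_thresh,
            "chr10_loss": s10 < loss_thresh,
        }
    )
    pts = calls[["chr7_score", "chr10_score"]].to_numpy()
    if len(pts) < 2 or np.allclose(pts, pts[0]):
        warnings.warn("degenerate CNV scores: returning a single cluster")
        calls["cluster"] = 1
    else:
        link = sch.linkage(pts, method="ward", metric="euclidean")
        calls["cluster"] = sch.fcluster(link, t=2, criterion="maxclust")
    calls["has_hallmark_cnv"] = calls["chr7_gain"] | calls["chr10_loss"]
    return calls
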