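"""Aggregated Z-score signature scoring and tumor-level aggregation.

A signature score is the mean, over a gene set, of per-gene Z-scores
computed across a stated AOI population (the population actually being
compared, e.g. recurrent SOX2+ AOIs). Because Z-scoring removes gene-wise
location and scale, scores are invariant under any gene-wise affine
transform of the input and average to zero over the scored population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SignatureSet
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScoreMatrix:
    """AOIs (or tumors) x signatures score matrix."""

    scores: pd.DataFrame
    level: str = "aoi"          # 'aoi' or 'tumor'
    centered: bool = True
    scaled: bool = True


def aggregate_zscore(
    norm: NormalizedMatrix,
    sigs: SignatureSet | dict[str, list[str]],
    population: list[str] | None = None,
    min_fraction_present: float = 0.5,
) -> ScoreMatrix:
    """Score each signature on each AOI of ``population``.

    Per gene, Z = (x - mean) / SD across the population; the signature score
    of an AOI is the mean Z over the signature's genes present in the
    matrix. Zero-variance genes contribute 0 with a warning; a signature
    with no gene present raises an error.
    """
    sig_map = sigs.signatures if isinstance(sigs, SignatureSet) else dict(sigs)
    cols = list(norm.data.columns) if population is None else list(population)
    if len(cols) < 2:
        raise ValueError("need at least two AOIs to compute population Z-scores")
    X = norm.data[cols].to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    zero_var = sd[:, 0] == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance genes contribute 0 to scores")
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd_safe
    Z[zero_var] = 0.0
    zdf = pd.DataFrame(Z, index=norm.data.index, columns=cols)

    out = {}
    gene_index = set(norm.data.index)
    for name, genes in sig_map.items():
        present = [g for g in genes if g in gene_index]
        if not present:
            raise ValueError(f"signature {name!r} has no genes in the matrix")
        if len(present) < min_fraction_present * len(genes):
            warnings.warn(
                f"signature {name!r}: only {len(present)}/{len(genes)} genes present"
            )
        out[name] = zdf.loc[present].mean(axis=0)
    scores = pd.DataFrame(out)
    return ScoreMatrix(scores=scores, level="aoi")


def aggregate_by_tumor(scores: ScoreMatrix, aoi_meta: pd.DataFrame) -> ScoreMatrix:
    """Mean score per tumor over its scored (surviving) AOIs.

    Tumors with no scored AOI are simply absent from the output, consistent
    with the purity-filter exclusion report.
    """
    if scores.level != "aoi":
        raise ValueError("expected AOI-level scores")
    missing = sorted(set(scores.scores.index) - set(aoi_meta.index))
    if missing:
        raise KeyError(f"scored AOIs missing from metadata: {missing[:10]}")
    tumor = aoi_meta.loc[scores.scores.index, "tumor_id"]
    agg = scores.scores.groupby(tumor).mean()
    agg.index.name = "tumor_id"
    return ScoreMatrix(scores=agg, level="tumor", centered=scores.centered, scaled=scores.scaled)
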