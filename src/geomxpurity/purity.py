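"""Two-step tumor-purity AOI filtering.

Recurrent glioblastoma samples often have low tumor-cell density, so a
SOX2+ segment can be dominated by background (oligodendrocytes, TAMs).
The filter keeps a SOX2+ AOI if it carries hallmark CNV evidence
(chr7 gain or chr10 loss); an AOI without CNV evidence is excluded only
when a non-malignant signature (oligodendrocyte or TAM) scores high while
every malignant-state signature scores low. IBA1+ AOIs are filtered on
their TAM signature Z alone.

Signature-score columns are re-standardized (Z across the evaluated
population) before thresholding, so thresholds are in population-SD units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PurityCall:
    aoi_id: str
    decision: str          # 'keep' | 'exclude'
    rule: str
    evidence: dict


def _zscore_columns(scores: pd.DataFrame) -> pd.DataFrame:
    """Standardize each score column across the rows; zero variance -> 0."""
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=0)
    sd = sd.replace(0.0, np.nan)
    z = (scores - mean) / sd
    return z.fillna(0.0)


def classify_sox2_aois(
    cnv_calls: pd.DataFrame,
    scores: pd.DataFrame,
    malignant_sigs: list[str],
    oligo_sig: str,
    tam_sig: str,
    z_nonmalig_thresh: float = 1.0,
    z_malig_thresh: float = 0.0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Keep/exclude decision per SOX2+ AOI with its evidence.

    Exclude iff the AOI has no hallmark CNV call AND a non-malignant Z
    (oligodendrocyte or TAM) exceeds ``z_nonmalig_thresh`` AND the maximum
    malignant-state Z is below ``z_malig_thresh``. CNV evidence always
    dominates: a hallmark-positive AOI is never excluded.

    ``standardize=False`` treats the score columns as already being
    population Z-scores.
    """
    missing = sorted(set(scores.index) - set(cnv_calls.index))
    if missing:
        raise KeyError(f"AOIs scored but missing CNV calls: {missing[:10]}")
    for sig in [*malignant_sigs, oligo_sig, tam_sig]:
        if sig not in scores.columns:
            raise KeyError(f"signature {sig!r} missing from score matrix")
    z = _zscore_columns(scores) if standardize else scores
    rows = []
    for aoi in scores.index:
        has_cnv = bool(cnv_calls.loc[aoi, "chr7_gain"] or cnv_calls.loc[aoi, "chr10_loss"])
        max_malig = float(z.loc[aoi, malignant_sigs].max())
        oligo_z = float(z.loc[aoi, oligo_sig])
        tam_z = float(z.loc[aoi, tam_sig])
        nonmalig_high = (oligo_z > z_nonmalig_thresh) or (tam_z > z_nonmalig_thresh)
        malig_low = max_malig < z_malig_thresh
        if has_cnv:
            decision, rule = "keep", "hallmark_cnv"
        elif nonmalig_high and malig_low:
            decision, rule = "exclude", "non_malignant_dominant"
        else:
            decision, rule = "keep", "no_exclusion_evidence"
        rows.append(
            {
                "aoi_id": aoi,
                "decision": decision,
                "rule": rule,
                "has_hallmark_cnv": has_cnv,
                "max_malignant_z": max_malig,
                "oligodendrocyte_z": oligo_z,
                "tam_z": tam_z,
            }
        )
    calls = pd.DataFrame(rows).set_index("aoi_id")
    n_excl = int((calls["decision"] == "exclude").sum())
    logger.info("SOX2+ purity filter: excluded %d/%d AOIs", n_excl, len(calls))
    return calls


def filter_iba1_aois(
    scores: pd.DataFrame,
    tam_sig: str,
    tam_z_thresh: float = 0.0,
) -> pd.DataFrame:
    """Keep an IBA1+ AOI iff its TAM signature Z is >= ``tam_z_thresh``."""
    if tam_sig not in scores.columns:
        raise KeyError(f"signature {tam_sig!r} missing from score matrix")
    z = _zscore_columns(scores)
    tam_z = z[tam_sig]
    calls = pd.DataFrame(
        {
            "decision": np.where(tam_z >= tam_z_thresh, "keep", "exclude"),
            "rule": np.where(tam_z >= tam_z_thresh, "tam_z_at_or_above", "tam_z_below"),
            "tam_z": tam_z,
        },
        index=scores.index,
    )
    calls.index.name = "aoi_id"
    return calls


def exclusion_report(calls: pd.DataFrame, aoi_meta: pd.DataFrame, segment: str = "SOX2") -> pd.DataFrame:
    """Per-tumor survival summary: a tumor is excluded when no AOI of the
    given segment survives the filter.

    Returns one row per tumor with surviving/total AOI counts, arm,
    setting, and the excluded flag.
    """
    meta = aoi_meta.loc[calls.index]
    seg_mask = meta["segment"] == segment
    kept = calls["decision"] == "keep"
    df = pd.DataFrame(
        {
            "tumor_id": meta["tumor_id"],
            "patient_id": meta["patient_id"],
            "arm": meta["arm"],
            "setting": meta["setting"],
            "kept": kept & seg_mask,
            "is_segment": seg_mask,
        }
    )
    df = df[df["is_segment"]]
    summary = (
        df.groupby("tumor_id")
        .agg(
            patient_id=("patient_id", "first"),
            arm=("arm", "first"),
            setting=("setting", "first"),
            n_aois=("kept", "size"),
            n_surviving=("kept", "sum"),
        )
    )
    summary["excluded"] = summary["n_surviving"] == 0
    n_excl = int(summary["excluded"].sum())
    if n_excl:
        per_arm = summary[summary["excluded"]].groupby(["arm", "setting"]).size()
        logger.info("tumors excluded (no surviving %s+ AOIs): %d\n%s", segment, n_excl, per_arm)
    return summary
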