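"""Rule-based PD-1 positivity quantification from per-cell IHC features.

The module consumes per-cell feature tables exported by image-analysis
software (one row per detected cell: ROI, tumor, mean DAB optical density,
cell area in square micrometres) — it performs no image processing. Cells
smaller than the minimum area are removed from the denominator; an
included cell is positive when its mean DAB OD strictly exceeds the
intensity threshold. Percent positivity is computed per ROI and averaged
(unweighted) over a tumor's ROIs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import wilcoxon_rank_sum, wilcoxon_signed_rank_exact

logger = logging.getLogger(__name__)

CELL_COLUMNS = ("roi_id", "tumor_id", "dab_od_mean", "area_um2")

#: Default QuPath-style positivity rule: mean DAB OD > 0.3, area >= 20 um^2.
DEFAULT_OD_THRESHOLD = 0.3
DEFAULT_MIN_AREA = 20.0


@dataclass
class PositivityResult:
    """Per-ROI percent positive cells and the per-tumor unweighted means."""

    per_roi: pd.DataFrame      # roi_id index: tumor_id, n_included, n_positive, percent_positive
    per_tumor: pd.Series       # tumor_id -> mean percent over its ROIs


def classify_cells(
    cells: pd.DataFrame,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    min_area: float = DEFAULT_MIN_AREA,
) -> pd.DataFrame:
    """Add ``included`` and ``positive`` flags to a per-cell table.

    A cell is included iff area >= ``min_area`` (cells *smaller* than the
    cutoff are removed, so the boundary itself is kept) and positive iff it
    is included and its OD strictly exceeds ``od_threshold``.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    if (cells["dab_od_mean"] < 0).any():
        raise ValueError("negative DAB OD values")
    if (cells["area_um2"] <= 0).any():
        raise ValueError("non-positive cell areas")
    out = cells.copy()
    out["included"] = out["area_um2"] >= min_area
    out["positive"] = out["included"] & (out["dab_od_mean"] > od_threshold)
    return out


def percent_positive(flagged: pd.DataFrame) -> PositivityResult:
    """Percent positive per ROI (positives / included cells) and per tumor.

    ROIs with zero included cells are dropped with a warning; a tumor with
    no valid ROI is absent from the per-tumor output.
    """
    grp = flagged.groupby("roi_id")
    per_roi = grp.agg(
        tumor_id=("tumor_id", "first"),
        n_cells=("included", "size"),
        n_included=("included", "sum"),
        n_positive=("positive", "sum"),
    )
    empty = per_roi[per_roi["n_included"] == 0]
    if len(empty):
        warnings.warn(f"{len(empty)} ROIs with no included cells dropped")
        per_roi = per_roi[per_roi["n_included"] > 0]
    per_roi["percent_positive"] = 100.0 * per_roi["n_positive"] / per_roi["n_included"]
    per_tumor = per_roi.groupby("tumor_id")["percent_positive"].mean()
    per_tumor.name = "percent_positive"
    return PositivityResult(per_roi=per_roi, per_tumor=per_tumor)


def compare_groups(result: PositivityResult, design: pd.DataFrame) -> pd.DataFrame:
    """Paired and unpaired comparisons of per-tumor PD-1 positivity.

    ``design`` maps tumor_id (index) to patient_id, setting
    (primary/recurrent) and arm (treated/control). Performs, per arm, the
    paired signed-rank test between matched primary and recurrent tumors,
    and the unpaired rank-sum test between treated and control recurrences.
    Reports medians and IQRs alongside exact p-values.
    """
    vals = result.per_tumor
    missing = sorted(set(vals.index) - set(design.index))
    if missing:
        raise KeyError(f"tumors missing from design: {missing[:10]}")
    design = design.loc[vals.index]
    rows = []

    def _summary(v: np.ndarray) -> tuple[float, float]:
        return float(np.median(v)), float(np.percentile(v, 75) - np.percentile(v, 25))

    for arm in sorted(design["arm"].unique()):
        sub = design[design["arm"] == arm]
        wide = (
            pd.DataFrame({"value": vals.loc[sub.index], "patient": sub["patient_id"],
                          "setting": sub["setting"]})
            .pivot_table(index="patient", columns="setting", values="value")
        )
        if {"primary", "recurrent"}.issubset(wide.columns):
            pairs = wide.dropna(subset=["primary", "recurrent"])
            if len(pairs) < 2:
                raise ValueError(f"arm {arm!r}: fewer than 2 matched pairs")
            test = wilcoxon_signed_rank_exact(pairs["recurrent"], pairs["primary"])
            med_p, iqr_p = _summary(pairs["primary"].to_numpy())
            med_r, iqr_r = _summary(pairs["recurrent"].to_numpy())
            rows.append(
                {
                    "comparison": f"{arm}: recurrent vs primary (paired)",
                    "n": len(pairs),
                    "median_a": med_r, "iqr_a": iqr_r,
                    "median_b": med_p, "iqr_b": iqr_p,
                    "statistic": test.statistic,
                    "pvalue": test.pvalue,
                    "method": f"signed-rank ({test.method})",
                }
            )

    rec = design[design["setting"] == "recurrent"]
    treated = vals.loc[rec.index[rec["arm"] == "treated"]].to_numpy()
    control = vals.loc[rec.index[rec["arm"] == "control"]].to_numpy()
    if len(treated) and len(control):
        test = wilcoxon_rank_sum(treated, control)
        med_t, iqr_t = _summary(treated)
        med_c, iqr_c = _summary(control)
        rows.append(
            {
                "comparison": "recurrent: treated vs control (unpaired)",
                "n": len(treated) + len(control),
                "median_a": med_t, "iqr_a": iqr_t,
                "median_b": med_c, "iqr_b": iqr_c,
                "statistic": test.statistic,
                "pvalue": test.pvalue,
                "method": f"rank-sum ({test.method})",
            }
        )
    return pd.DataFrame(rows)
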