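"""End-to-end orchestration with plain-file handoff between stages.

Stages run in a fixed order (simulate -> preprocess -> cnv -> filter ->
score -> compare -> ihc); every stage reads the previous stage's declared
files from the working directory and writes its own, so each intermediate
is auditable. A manifest records a content hash for every output. A
missing upstream file produces an error naming the stage to run first.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import ihc as ihc_mod
from . import purity as purity_mod
from . import signatures as sig_mod
from . import stats as stats_mod
from .io import read_dataset, read_gene_annotation, read_gmt
from .preprocess import NormalizedMatrix, preprocess_dataset
from .synthetic import SimConfig, simulate_cohort, simulate_ihc_cells, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "cnv", "filter", "score", "compare", "ihc")


class PipelineError(RuntimeError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "outdir" not in cfg:
        raise PipelineError("config must define 'outdir'")
    return cfg


def _require(outdir: Path, fname: str, produced_by: str) -> Path:
    path = outdir / fname
    if not path.exists():
        raise PipelineError(
            f"missing input {fname!r}: run stage {produced_by!r} first"
        )
    return path


def _read_norm(outdir: Path) -> NormalizedMatrix:
    path = _require(outdir, "normalized.tsv", "preprocess")
    data = pd.read_csv(path, sep="\t", index_col=0)
    return NormalizedMatrix(data=data, normalized=True, batch_corrected=True)


def _load_dataset(outdir: Path):
    return read_dataset(
        _require(outdir, "counts.tsv", "simulate"),
        _require(outdir, "negprobes.tsv", "simulate"),
        _require(outdir, "aoi_meta.tsv", "simulate"),
    )


def _surviving(outdir: Path) -> pd.DataFrame:
    path = _require(outdir, "purity_calls.tsv", "filter")
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    params = dict(cfg.get("simulate") or {})
    params.setdefault("seed", cfg.get("seed", 0))
    sim_cfg = SimConfig(**params)
    dataset, ann, sigs, truth = simulate_cohort(sim_cfg)
    paths = write_cohort(outdir, dataset, ann, sigs, truth)
    return list(paths.values())


def stage_preprocess(cfg: dict, outdir: Path) -> list[Path]:
    params = cfg.get("preprocess") or {}
    dataset = _load_dataset(outdir)
    norm, report = preprocess_dataset(dataset, k=float(params.get("k", 2.0)))
    out_norm = outdir / "normalized.tsv"
    norm.data.to_csv(out_norm, sep="\t", index_label="gene_id")
    out_rep = outdir / "gene_filter.tsv"
    report.to_csv(out_rep, sep="\t", index_label="gene_id")
    return [out_norm, out_rep]


def stage_cnv(cfg: dict, outdir: Path) -> list[Path]:
    params = cfg.get("cnv") or {}
    dataset = _load_dataset(outdir)
    norm = _read_norm(outdir)
    ann = read_gene_annotation(_require(outdir, "genes.bed", "simulate"),
                               chrom_order=sorted({str(i) for i in range(1, 23)} |
                                                  {"X", "Y"}, key=_chrom_key))
    ref_segment = params.get("reference_segment", "IBA1")
    reference = dataset.segment_aois(ref_segment)
    query = dataset.segment_aois("SOX2")
    profile = cnv_mod.compute_cnv_profile(
        norm, ann, reference_aois=reference, query_aois=query,
        window=int(params.get("window", 101)), clip=float(params.get("clip", 3.0)),
        batch=dataset.aoi_meta["batch"],
    )
    calls = cnv_mod.score_and_call(
        profile,
        gain_thresh=float(params.get("gain_thresh", 0.15)),
        loss_thresh=float(params.get("loss_thresh", -0.15)),
    )
    out = outdir / "cnv_calls.tsv"
    calls.to_csv(out, sep="\t", index_label="aoi_id")
    return [out]


def _chrom_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def stage_filter(cfg: dict, outdir: Path) -> list[Path]:
    params = cfg.get("filter") or {}
    dataset = _load_dataset(outdir)
    norm = _read_norm(outdir)
    sigs = read_gmt(_require(outdir, "signatures.gmt", "simulate"),
                    roles=_require(outdir, "signature_roles.yml", "simulate"))
    calls_cnv = pd.read_csv(_require(outdir, "cnv_calls.tsv", "cnv"), sep="\t", index_col=0)

    sox2 = dataset.segment_aois("SOX2")
    iba1 = dataset.segment_aois("IBA1")
    malignant = sigs.by_role("malignant_state")
    oligo = params.get("oligo_sig", "oligodendrocyte")
    tam = params.get("tam_sig", "TAM")
    needed = {n: sigs[n] for n in malignant + [oligo, tam]}

    scores_sox2 = sig_mod.aggregate_zscore(norm, needed, population=sox2).scores
    calls_sox2 = purity_mod.classify_sox2_aois(
        calls_cnv, scores_sox2, malignant, oligo, tam,
        z_nonmalig_thresh=float(params.get("z_nonmalig_thresh", 1.0)),
        z_malig_thresh=float(params.get("z_malig_thresh", 0.0)),
    )
    scores_iba1 = sig_mod.aggregate_zscore(norm, {tam: sigs[tam]}, population=iba1).scores
    calls_iba1 = purity_mod.filter_iba1_aois(
        scores_iba1, tam, tam_z_thresh=float(params.get("tam_z_thresh", 0.0))
    )
    all_calls = pd.concat(
        [calls_sox2.assign(segment="SOX2"), calls_iba1.assign(segment="IBA1")]
    )
    out_calls = outdir / "purity_calls.tsv"
    all_calls.to_csv(out_calls, sep="\t", index_label="aoi_id")
    report = purity_mod.exclusion_report(all_calls, dataset.aoi_meta, segment="SOX2")
    out_rep = outdir / "tumor_exclusions.tsv"
    report.to_csv(out_rep, sep="\t", index_label="tumor_id")
    return [out_calls, out_rep]


def stage_score(cfg: dict, outdir: Path) -> list[Path]:
    dataset = _load_dataset(outdir)
    norm = _read_norm(outdir)
    sigs = read_gmt(_require(outdir, "signatures.gmt", "simulate"),
                    roles=_require(outdir, "signature_roles.yml", "simulate"))
    calls = _surviving(outdir)
    outputs = []
    for segment in ("SOX2", "IBA1"):
        surviving = [
            a for a in dataset.segment_aois(segment)
            if a in calls.index and calls.loc[a, "decision"] == "keep"
        ]
        if len(surviving) < 2:
            logger.warning("fewer than 2 surviving %s+ AOIs; skipping scores", segment)
            continue
        scored = sig_mod.aggregate_zscore(norm, sigs, population=surviving)
        out_aoi = outdir / f"scores_aoi_{segment}.tsv"
        scored.scores.to_csv(out_aoi, sep="\t", index_label="aoi_id")
        tumor_scores = sig_mod.aggregate_by_tumor(scored, dataset.aoi_meta)
        out_tumor = outdir / f"scores_tumor_{segment}.tsv"
        tumor_scores.scores.to_csv(out_tumor, sep="\t", index_label="tumor_id")
        outputs += [out_aoi, out_tumor]
    return outputs


def stage_compare(cfg: dict, outdir: Path) -> list[Path]:
    params = cfg.get("compare") or {}
    dataset = _load_dataset(outdir)
    calls = _surviving(outdir)
    outputs = []

    # tumor-aggregated DE: treated vs control recurrences per segment
    for segment in ("SOX2", "IBA1"):
        surviving = [
            a for a in dataset.segment_aois(segment)
            if a in calls.index and calls.loc[a, "decision"] == "keep"
        ]
        meta = dataset.aoi_meta
        rec = [a for a in surviving if meta.loc[a, "setting"] == "recurrent"]
        if not rec:
            continue
        pb = stats_mod.pseudobulk(dataset, rec, segment)
        cond = meta.drop_duplicates("tumor_id").set_index("tumor_id").loc[pb.index, "arm"]
        if cond.nunique() < 2 or (cond.value_counts() < 2).any():
            logger.warning("segment %s: not enough tumors per arm for DE", segment)
            continue
        de = stats_mod.nb_wald_de(pb, cond, ref_level="control",
                                  prior_weight=float(params.get("prior_weight", 10.0)))
        out = outdir / f"de_{segment}_recurrent_treated_vs_control.tsv"
        de.table.to_csv(out, sep="\t")
        outputs.append(out)

    # mixed-model comparison of a signature score across arm x setting
    sig_name = params.get("lmm_signature", "interferon")
    score_path = outdir / "scores_aoi_SOX2.tsv"
    if score_path.exists():
        scores = pd.read_csv(score_path, sep="\t", index_col=0)
        if sig_name in scores.columns:
            meta = dataset.aoi_meta.loc[scores.index]
            group = meta["arm"] + ":" + meta["setting"]
            fit = stats_mod.fit_random_intercept(scores[sig_name], group, meta["patient_id"])
            emm = stats_mod.emmeans_tukey(fit)
            emm.contrasts["qvalue"] = stats_mod.bh_fdr(emm.contrasts["p_tukey"])
            out = outdir / f"lmm_{sig_name}_SOX2.tsv"
            emm.contrasts.to_csv(out, sep="\t", index=False)
            outputs.append(out)
    else:
        raise PipelineError("missing input 'scores_aoi_SOX2.tsv': run stage 'score' first")
    return outputs


def stage_ihc(cfg: dict, outdir: Path) -> list[Path]:
    params = dict(cfg.get("ihc") or {})
    params.setdefault("seed", cfg.get("seed", 0))
    od = float(params.pop("od_threshold", ihc_mod.DEFAULT_OD_THRESHOLD))
    area = float(params.pop("min_area", ihc_mod.DEFAULT_MIN_AREA))
    cells, truth = simulate_ihc_cells(**params)
    flagged = ihc_mod.classify_cells(cells, od_threshold=od, min_area=area)
    result = ihc_mod.percent_positive(flagged)
    report = ihc_mod.compare_groups(result, truth)
    out_cells = outdir / "ihc_cells.tsv"
    cells.to_csv(out_cells, sep="\t", index=False)
    out_pct = outdir / "ihc_percent_positive.tsv"
    result.per_tumor.to_frame().join(truth).to_csv(out_pct, sep="\t", index_label="tumor_id")
    out_tests = outdir / "ihc_tests.tsv"
    report.to_csv(out_tests, sep="\t", index=False)
    return [out_cells, out_pct, out_tests]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "cnv": stage_cnv,
    "filter": stage_filter,
    "score": stage_score,
    "compare": stage_compare,
    "ihc": stage_ihc,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, stages: list[str] | None = None) -> dict:
    """Run the requested stages in fixed order; return the output manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = set(config.get("stages", STAGES))
    requested = list(STAGES) if stages is None else list(stages)
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    outputs: list[Path] = []
    for stage in STAGES:
        if stage not in requested or stage not in enabled:
            continue
        logger.info("running stage %s", stage)
        try:
            outputs += _STAGE_FUNCS[stage](config, outdir)
        except PipelineError:
            raise
        except Exception as exc:  # tag failures with their stage
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "config": {k: v for k, v in config.items() if k != "stages"},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
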