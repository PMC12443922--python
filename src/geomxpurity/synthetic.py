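"""Synthetic GeoMx-like cohorts and IHC cell tables with known ground truth.

The generator emulates the structure of a paired primary/recurrent
glioblastoma cohort profiled with segmented digital spatial profiling:

* patients with matched primary and recurrent tumors, a subset of
  recurrences treated;
* per tumor, several ROIs each contributing one SOX2+ (tumor-cell) and one
  IBA1+ (macrophage) AOI;
* AOI expression as a purity-weighted mixture of malignant,
  oligodendrocyte and TAM expression programs built from disjoint planted
  gene modules over a shared baseline;
* hallmark chromosome 7 gain / chromosome 10 loss applied as a
  multiplicative dosage to all genes on those chromosomes in the malignant
  program only;
* two experimental batches with location/scale distortion on log
  expression, lognormal library sizes, negative-binomial counting noise,
  and negative probes drawn from the same background as unexpressed genes.

Counts are integers; identical seed and config give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AOIDataset,
    GeneAnnotation,
    SignatureSet,
    build_gene_annotation,
    write_dataset,
    write_gene_annotation,
    write_gmt,
)

logger = logging.getLogger(__name__)

#: Role tags of the default planted signatures.
DEFAULT_MODULE_SIZES = {
    "MES": 30,
    "AC": 30,
    "OPC": 30,
    "NPC": 30,
    "oligodendrocyte": 30,
    "TAM": 30,
    "interferon": 20,
    "G1S": 15,
    "G2M": 15,
    "myeloid_complement": 15,
    "myeloid_scavenger": 15,
    "myeloid_microglial": 15,
    "myeloid_systemic": 15,
}

DEFAULT_ROLES = {
    "MES": "malignant_state",
    "AC": "malignant_state",
    "OPC": "malignant_state",
    "NPC": "malignant_state",
    "oligodendrocyte": "non_malignant",
    "TAM": "non_malignant",
    "interferon": "interferon",
    "G1S": "cell_cycle",
    "G2M": "cell_cycle",
    "myeloid_complement": "myeloid",
    "myeloid_scavenger": "myeloid",
    "myeloid_microglial": "myeloid",
    "myeloid_systemic": "myeloid",
}

MALIGNANT_STATES = ("MES", "AC", "OPC", "NPC")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the profiled cohort: 30 patients, 27 of 30 with a
    matched primary (paired_fraction 0.9), two thirds of recurrences
    treated, two experimental batches, NB dispersion 0.1.
    """

    n_patients: int = 30
    paired_fraction: float = 0.9
    treated_fraction: float = 2 / 3
    n_genes: int = 18000
    n_negprobes: int = 139
    aois_per_tumor: int = 3            # ROIs per tumor; each yields one SOX2+ and one IBA1+ AOI
    purity_grid: tuple[float, ...] = (0.0, 0.5, 0.7, 0.9)
    cnv_dosage: dict = field(default_factory=lambda: {"7": 1.5, "10": 0.5})
    batch_effects: dict = field(
        default_factory=lambda: {"run1": (0.0, 1.0), "run2": (0.3, 1.08)}
    )  # batch -> (location, scale) on log2 expression
    nb_dispersion: float = 0.1
    libsize_lognormal_sigma: float = 0.4
    libsize_mean: float = 1.0e5
    signature_module_sizes: dict = field(default_factory=lambda: dict(DEFAULT_MODULE_SIZES))
    module_elevation: float = 2.0       # log2 elevation of module genes in their program
    cell_cycle_elevation: float = 1.0   # log2 elevation of cycle modules in malignant cells
    interferon_elevation: float = 1.5   # patient-intrinsic interferon activation
    interferon_patient_fraction: float = 0.3
    background_fraction: float = 0.3    # genes expressed only at background level
    background_log2: float = 1.0
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    sox2_nonmalignant_mix: tuple[float, float] = (0.7, 0.3)  # (oligodendrocyte, TAM)
    iba1_mix: tuple[float, float] = (0.1, 0.9)               # (oligodendrocyte, TAM)
    de_n_genes: int = 0                 # genes with a planted treated-vs-control recurrence effect
    de_log2fc: float = 0.0
    n_chromosomes: int = 22
    cnv_window: int = 101               # smallest chromosome must hold at least this many genes
    seed: int = 0

    def validate(self) -> None:
        for name in ("paired_fraction", "treated_fraction", "background_fraction",
                     "interferon_patient_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.purity_grid:
            raise ValueError("purity_grid must be non-empty")
        if any(not 0.0 <= p <= 1.0 for p in self.purity_grid):
            raise ValueError("purity values must lie in [0, 1]")
        if any(d <= 0 for d in self.cnv_dosage.values()):
            raise ValueError("CNV dosages must be positive")
        if self.n_genes < sum(self.signature_module_sizes.values()):
            raise ValueError("n_genes smaller than the sum of signature module sizes")
        if self.n_genes // self.n_chromosomes < self.cnv_window:
            raise ValueError(
                f"fewer than cnv_window={self.cnv_window} genes per chromosome "
                f"({self.n_genes // self.n_chromosomes}); increase n_genes"
            )
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_patients < 1 or self.aois_per_tumor < 1:
            raise ValueError("n_patients and aois_per_tumor must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth: per-AOI composition and per-gene structure."""

    aoi_table: pd.DataFrame   # purity, chr7_gain, chr10_loss, batch, dominant_state
    gene_table: pd.DataFrame  # chromosome, module, expressed, true_log2fc
    config: SimConfig


def simulate_cohort(config: SimConfig) -> tuple[AOIDataset, GeneAnnotation, SignatureSet, GroundTruth]:
    """Generate a full cohort under ``config`` (one RNG stream, seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes

    # ---- genome: contiguous chromosome blocks, ordered positions ----------
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    per_chrom = np.full(config.n_chromosomes, G // config.n_chromosomes)
    per_chrom[: G % config.n_chromosomes] += 1
    gene_chrom = np.repeat(chroms, per_chrom)
    gene_ids = np.array([f"G{i:05d}" for i in range(G)])
    within = np.concatenate([np.arange(n) for n in per_chrom])
    ann = build_gene_annotation(
        pd.DataFrame({"chromosome": gene_chrom, "start": (within + 1) * 1000, "gene_id": gene_ids}),
        chrom_order=chroms,
    )

    # ---- baseline expression and planted modules --------------------------
    expressed = rng.random(G) >= config.background_fraction
    baseline = np.where(
        expressed,
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, G),
        config.background_log2,
    )
    off_hallmark = expressed & ~np.isin(gene_chrom, list(config.cnv_dosage))
    candidates = rng.permutation(np.flatnonzero(off_hallmark))
    need = sum(config.signature_module_sizes.values())
    if len(candidates) < need:
        raise ValueError("not enough expressed off-hallmark genes for the planted modules")
    module_of = np.full(G, "", dtype=object)
    sig_map: dict[str, list[str]] = {}
    pos = 0
    for name, size in config.signature_module_sizes.items():
        idx = candidates[pos : pos + size]
        pos += size
        module_of[idx] = name
        sig_map[name] = list(gene_ids[idx])
    signatures = SignatureSet(
        signatures=sig_map,
        roles={n: DEFAULT_ROLES.get(n, "malignant_state") for n in sig_map},
    )
    states = [s for s in MALIGNANT_STATES if s in sig_map]
    myeloid = [n for n in sig_map if DEFAULT_ROLES.get(n) == "myeloid"]

    in_module = {name: np.isin(gene_ids, genes) for name, genes in sig_map.items()}
    cc_mask = np.zeros(G, bool)
    for name in ("G1S", "G2M"):
        if name in in_module:
            cc_mask |= in_module[name]
    ifn_mask = in_module.get("interferon", np.zeros(G, bool))

    elev = config.module_elevation
    oligo_log2 = baseline + np.where(in_module.get("oligodendrocyte", np.zeros(G, bool)), elev, 0.0)

    dosage = np.ones(G)
    for chrom, d in config.cnv_dosage.items():
        dosage[gene_chrom == chrom] = d
    hallmark_planted = {c: d != 1.0 for c, d in config.cnv_dosage.items()}

    # planted treatment effect (treated recurrences only)
    lfc = np.zeros(G)
    if config.de_n_genes > 0:
        de_pool = np.flatnonzero(expressed & (module_of == ""))
        de_idx = rng.choice(de_pool, size=config.de_n_genes, replace=False)
        lfc[de_idx] = config.de_log2fc

    # ---- cohort structure --------------------------------------------------
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    perm = rng.permutation(config.n_patients)
    n_treated = int(round(config.treated_fraction * config.n_patients))
    treated = {patients[i] for i in perm[:n_treated]}
    perm2 = rng.permutation(config.n_patients)
    n_paired = int(round(config.paired_fraction * config.n_patients))
    paired = {patients[i] for i in perm2[:n_paired]}
    ifn_patients = {p for p in patients if rng.random() < config.interferon_patient_fraction}
    batch_names = list(config.batch_effects)

    tumors = []
    for p in patients:
        settings = ["primary", "recurrent"] if p in paired else ["recurrent"]
        for s in settings:
            tumors.append((f"T_{p}_{s}", p, s, "treated" if p in treated else "control"))

    negprobe_rel = np.full(config.n_negprobes, 2.0**config.background_log2)
    counts_cols: dict[str, np.ndarray] = {}
    neg_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    truth_rows = []

    mix_o_sox2, mix_t_sox2 = config.sox2_nonmalignant_mix
    mix_o_iba1, mix_t_iba1 = config.iba1_mix

    for tumor_id, patient, setting, arm in tumors:
        state = states[rng.integers(len(states))] if states else ""
        batch = batch_names[rng.integers(len(batch_names))]
        ifn = config.interferon_elevation if patient in ifn_patients else 0.0

        malig_log2 = baseline.copy()
        if state:
            malig_log2 = malig_log2 + np.where(in_module[state], elev, 0.0)
        malig_log2 += np.where(cc_mask, config.cell_cycle_elevation, 0.0)
        malig_lin = 2.0**(malig_log2 + np.where(ifn_mask, ifn, 0.0)) * dosage

        w = rng.uniform(0.0, 1.5, size=len(myeloid))
        tam_log2 = baseline + np.where(in_module.get("TAM", np.zeros(G, bool)), elev, 0.0)
        for wk, name in zip(w, myeloid):
            tam_log2 = tam_log2 + np.where(in_module[name], wk, 0.0)
        tam_lin = 2.0**(tam_log2 + np.where(ifn_mask, ifn, 0.0))
        oligo_lin = 2.0**(oligo_log2 + np.where(ifn_mask, ifn, 0.0))

        effect = 2.0**lfc if (setting == "recurrent" and arm == "treated") else None

        for r in range(config.aois_per_tumor):
            roi = f"{tumor_id}_R{r + 1}"
            core = f"{tumor_id}_C{r // 2 + 1}"
            for segment in ("SOX2", "IBA1"):
                aoi = f"{roi}_{segment}"
                if segment == "SOX2":
                    purity = float(rng.choice(config.purity_grid))
                    rel = purity * malig_lin + (1 - purity) * (
                        mix_o_sox2 * oligo_lin + mix_t_sox2 * tam_lin
                    )
                else:
                    purity = 0.0
                    rel = mix_o_iba1 * oligo_lin + mix_t_iba1 * tam_lin
                if effect is not None:
                    rel = rel * effect
                total = rel.sum() + negprobe_rel.sum()
                lib = np.exp(rng.normal(np.log(config.libsize_mean), config.libsize_lognormal_sigma))
                mu = lib * rel / total
                mu_neg = lib * negprobe_rel / total
                loc, scale = config.batch_effects[batch]
                mu = 2.0**(loc + scale * np.log2(np.maximum(mu, 1e-12)))
                mu_neg = 2.0**(loc + scale * np.log2(np.maximum(mu_neg, 1e-12)))
                counts_cols[aoi] = _nb_draw(rng, mu, config.nb_dispersion)
                neg_cols[aoi] = _nb_draw(rng, mu_neg, config.nb_dispersion)
                meta_rows.append(
                    {
                        "aoi_id": aoi, "roi_id": roi, "core_id": core,
                        "tumor_id": tumor_id, "patient_id": patient,
                        "setting": setting, "arm": arm, "segment": segment,
                        "batch": batch,
                    }
                )
                truth_rows.append(
                    {
                        "aoi_id": aoi,
                        "purity": purity,
                        "chr7_gain": purity > 0 and hallmark_planted.get("7", False),
                        "chr10_loss": purity > 0 and hallmark_planted.get("10", False),
                        "batch": batch,
                        "dominant_state": state,
                    }
                )

    aoi_ids = [m["aoi_id"] for m in meta_rows]
    counts = pd.DataFrame(counts_cols, index=pd.Index(gene_ids, name="gene_id"))[aoi_ids]
    negprobes = pd.DataFrame(
        neg_cols, index=pd.Index([f"NEG{i:03d}" for i in range(config.n_negprobes)], name="probe_id")
    )[aoi_ids]
    meta = pd.DataFrame(meta_rows).set_index("aoi_id")
    dataset = AOIDataset(counts=counts, negprobe_counts=negprobes, aoi_meta=meta)

    gene_table = pd.DataFrame(
        {
            "chromosome": gene_chrom,
            "module": module_of,
            "expressed": expressed,
            "true_log2fc": lfc,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = GroundTruth(
        aoi_table=pd.DataFrame(truth_rows).set_index("aoi_id"),
        gene_table=gene_table,
        config=config,
    )
    logger.info(
        "simulated cohort: %d patients, %d tumors, %d AOIs, %d genes",
        config.n_patients, len(tumors), len(aoi_ids), G,
    )
    return dataset, ann, signatures, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, var mu + dispersion*mu^2) via Gamma–Poisson mixing."""
    if dispersion < 1e-12:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mu * dispersion)
    return rng.poisson(lam)


def write_cohort(
    outdir: str | Path,
    dataset: AOIDataset,
    annotation: GeneAnnotation,
    signatures: SignatureSet,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the cohort in the on-disk formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_dataset(dataset, outdir)
    paths["annotation"] = outdir / "genes.bed"
    write_gene_annotation(annotation, paths["annotation"])
    paths["gmt"] = outdir / "signatures.gmt"
    paths["roles"] = outdir / "signature_roles.yml"
    write_gmt(signatures, paths["gmt"], paths["roles"])
    paths["truth_aoi"] = outdir / "truth_aoi.tsv"
    truth.aoi_table.to_csv(paths["truth_aoi"], sep="\t")
    paths["truth_gene"] = outdir / "truth_gene.tsv"
    truth.gene_table.to_csv(paths["truth_gene"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# direct pseudobulk simulation (for DE calibration at tumor level)
# ---------------------------------------------------------------------------

def simulate_pseudobulk_counts(
    n_per_group: int = 6,
    n_genes: int = 2000,
    dispersion: float = 0.1,
    mean_log: float = np.log(500.0),
    mean_log_sd: float = 1.5,
    libsize_sigma: float = 0.3,
    n_lfc_genes: int = 0,
    log2fc: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Two-condition tumor-level NB counts with optional planted fold changes.

    Returns (counts tumors x genes, condition labels, true per-gene log2FC).
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    q = np.exp(rng.normal(mean_log, mean_log_sd, n_genes))
    sf = np.exp(rng.normal(0.0, libsize_sigma, n))
    cond = np.array(["control"] * n_per_group + ["treated"] * n_per_group)
    lfc = np.zeros(n_genes)
    if n_lfc_genes > 0:
        idx = rng.choice(n_genes, size=n_lfc_genes, replace=False)
        lfc[idx] = log2fc
    mu = sf[:, None] * q[None, :] * np.where(cond[:, None] == "treated", 2.0**lfc[None, :], 1.0)
    counts = _nb_draw(rng, mu, dispersion)
    tumors = [f"T{i + 1:02d}" for i in range(n)]
    genes = [f"G{i:05d}" for i in range(n_genes)]
    return (
        pd.DataFrame(counts, index=pd.Index(tumors, name="tumor_id"), columns=genes),
        pd.Series(cond, index=tumors, name="condition"),
        pd.Series(lfc, index=genes, name="true_log2fc"),
    )


# ---------------------------------------------------------------------------
# IHC cell tables
# ---------------------------------------------------------------------------

def simulate_ihc_cells(
    n_tumors_per_arm: int = 7,
    pairs: bool = True,
    effect: float = 0.02,
    seed: int = 0,
    n_rois_per_tumor: int = 2,
    n_cells_per_roi: int = 500,
    base_fraction: float = 0.01,
    fraction_jitter_sd: float = 0.2,
    small_area_fraction: float = 0.1,
    arms: tuple[str, ...] = ("treated", "control"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell DAB OD / area tables with a planted positivity shift.

    Negative cells draw OD uniformly below the 0.3 threshold, positive
    cells above it; cell areas place ``small_area_fraction`` of cells under
    the 20 um^2 exclusion cutoff, independently of positivity. The
    recurrent-setting true positive fraction is ``base_fraction + effect``
    (clipped to [0, 1]), with per-tumor lognormal jitter.

    Returns the cell table and a per-tumor design/truth table
    (patient_id, setting, arm, true_fraction).
    """
    if n_tumors_per_arm < 1:
        raise ValueError("n_tumors_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    cells = []
    truth_rows = []
    for arm in arms:
        for i in range(n_tumors_per_arm):
            patient = f"{arm[:1].upper()}{i + 1:02d}"
            settings = ("primary", "recurrent") if pairs else ("recurrent",)
            jitter = np.exp(rng.normal(0.0, fraction_jitter_sd))
            for setting in settings:
                frac = base_fraction + (effect if setting == "recurrent" else 0.0)
                frac = float(np.clip(frac * jitter, 0.0, 1.0))
                tumor = f"T_{patient}_{setting}"
                truth_rows.append(
                    {"tumor_id": tumor, "patient_id": patient, "setting": setting,
                     "arm": arm, "true_fraction": frac}
                )
                for r in range(n_rois_per_tumor):
                    roi = f"{tumor}_R{r + 1}"
                    pos = rng.random(n_cells_per_roi) < frac
                    od = np.where(
                        pos,
                        rng.uniform(0.35, 1.2, n_cells_per_roi),
                        rng.uniform(0.0, 0.25, n_cells_per_roi),
                    )
                    small = rng.random(n_cells_per_roi) < small_area_fraction
                    area = np.where(
                        small,
                        rng.uniform(5.0, 19.9, n_cells_per_roi),
                        rng.uniform(20.0, 200.0, n_cells_per_roi),
                    )
                    cells.append(
                        pd.DataFrame(
                            {
                                "roi_id": roi,
                                "tumor_id": tumor,
                                "dab_od_mean": od,
                                "area_um2": area,
                            }
                        )
                    )
    cell_table = pd.concat(cells, ignore_index=True)
    truth = pd.DataFrame(truth_rows).set_index("tumor_id")
    return cell_table, truth
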