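"""Readers, writers and the central data model for segmented GeoMx cohorts.

The on-disk layout is deliberately plain: tab-separated count matrices
(genes x AOIs), a tab-separated AOI annotation table, a BED-like gene
annotation (chrom, start, gene_id), GMT signature files with a YAML sidecar
for role tags, and an optional MatrixMarket variant for large matrices.
Coordinates are 1-based and used only to order genes along the genome; no
interval arithmetic is performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Default chromosome sort order (autosomes numerically, then X, Y). An
#: explicit order avoids the lexicographic chr10 < chr2 trap.
DEFAULT_CHROM_ORDER: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

#: Columns every AOI annotation table must provide.
REQUIRED_META_COLUMNS = (
    "roi_id",
    "core_id",
    "tumor_id",
    "patient_id",
    "setting",
    "arm",
    "segment",
    "batch",
)

SETTINGS = ("primary", "recurrent")
ARMS = ("treated", "control")
SEGMENTS = ("SOX2", "IBA1")

SIGNATURE_ROLES = ("malignant_state", "non_malignant", "cell_cycle", "interferon", "myeloid")


class DataValidationError(ValueError):
    """Raised when an on-disk artifact or container violates its contract."""


@dataclass
class AOIDataset:
    """Counts and annotations for one GeoMx cohort.

    Parameters
    ----------
    counts
        genes x AOIs matrix of non-negative integer probe counts.
    negprobe_counts
        negative probes x AOIs matrix of non-negative integers. Negative
        probes target no transcript and estimate background.
    aoi_meta
        One row per AOI (index = aoi_id) with the columns in
        :data:`REQUIRED_META_COLUMNS`; ``nuclei_count`` is optional.
    """

    counts: pd.DataFrame
    negprobe_counts: pd.DataFrame
    aoi_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        cols = list(self.counts.columns)
        if len(set(cols)) != len(cols):
            raise DataValidationError("duplicate AOI ids in counts matrix")
        if len(set(self.counts.index)) != len(self.counts.index):
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dupes[:10]}")
        for name, other in (
            ("negprobe_counts", list(self.negprobe_counts.columns)),
            ("aoi_meta", list(self.aoi_meta.index)),
        ):
            if other != cols:
                missing = sorted(set(cols) ^ set(other))
                raise DataValidationError(
                    f"AOI ids of {name} do not match counts; offending ids: {missing[:10]}"
                )
        missing_cols = [c for c in REQUIRED_META_COLUMNS if c not in self.aoi_meta.columns]
        if missing_cols:
            raise DataValidationError(f"aoi_meta missing columns: {missing_cols}")
        for mat, name in ((self.counts, "counts"), (self.negprobe_counts, "negprobe_counts")):
            arr = mat.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise DataValidationError(f"{name} contains non-integer values")
            if (arr < 0).any():
                raise DataValidationError(f"{name} contains negative values")
        # every tumor maps to exactly one (patient, setting)
        mapping = self.aoi_meta.groupby("tumor_id")[["patient_id", "setting"]].nunique()
        bad = mapping[(mapping > 1).any(axis=1)].index.tolist()
        if bad:
            raise DataValidationError(
                f"tumor ids mapping to more than one (patient, setting): {bad}"
            )

    # -- conveniences ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_aois(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def aoi_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_aois(self, aoi_ids: Sequence[str]) -> "AOIDataset":
        """Restrict the dataset to the given AOIs (order as given)."""
        aoi_ids = list(aoi_ids)
        missing = sorted(set(aoi_ids) - set(self.counts.columns))
        if missing:
            raise KeyError(f"unknown AOI ids: {missing[:10]}")
        return AOIDataset(
            counts=self.counts[aoi_ids].copy(),
            negprobe_counts=self.negprobe_counts[aoi_ids].copy(),
            aoi_meta=self.aoi_meta.loc[aoi_ids].copy(),
        )

    def segment_aois(self, segment: str) -> list[str]:
        return list(self.aoi_meta.index[self.aoi_meta["segment"] == segment])


@dataclass
class GeneAnnotation:
    """Per-gene chromosome and start position with a genome-wide order index.

    ``table`` is indexed by gene_id with columns ``chromosome`` (normalized,
    no ``chr`` prefix), ``start`` (1-based) and ``order`` (0-based position in
    the genome ordering: chromosomes in the configured order, genes by start
    within a chromosome).
    """

    table: pd.DataFrame
    chrom_order: tuple[str, ...] = DEFAULT_CHROM_ORDER

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids in annotation: {dupes[:10]}")
        # order must strictly increase with start within chromosome
        for _, sub in self.table.groupby("chromosome", sort=False):
            s = sub.sort_values("start")
            if not s["order"].is_monotonic_increasing:
                raise DataValidationError("order index not increasing with start")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def ordered_genes(self, genes: Sequence[str] | None = None) -> pd.DataFrame:
        """Annotation rows for ``genes`` (those present), in genome order."""
        tab = self.table if genes is None else self.table.loc[self.table.index.intersection(genes)]
        return tab.sort_values("order")

    def chromosomes(self) -> list[str]:
        present = set(self.table["chromosome"])
        return [c for c in self.chrom_order if c in present]


@dataclass
class SignatureSet:
    """Named gene lists with a role tag per signature."""

    signatures: dict[str, list[str]]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.signatures.items():
            if not genes:
                raise DataValidationError(f"signature {name!r} has an empty gene list")
        unknown = {r for r in self.roles.values() if r not in SIGNATURE_ROLES}
        if unknown:
            raise DataValidationError(f"unknown signature roles: {sorted(unknown)}")

    def __getitem__(self, name: str) -> list[str]:
        return self.signatures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.signatures

    @property
    def names(self) -> list[str]:
        return list(self.signatures)

    def by_role(self, role: str) -> list[str]:
        """Signature names carrying the given role tag."""
        return [n for n in self.signatures if self.roles.get(n) == role]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_dataset(
    counts_path: str | Path,
    negprobe_path: str | Path,
    meta_path: str | Path,
) -> AOIDataset:
    """Load an :class:`AOIDataset` from three TSV files.

    Column order of the count matrices defines the AOI order; the metadata
    table is re-indexed to match and an error names any AOI present in one
    file but not another.
    """
    counts = _read_counts_tsv(counts_path)
    negprobes = _read_counts_tsv(negprobe_path)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)

    aois = list(counts.columns)
    for name, ids in (("negative-probe counts", set(negprobes.columns)), ("metadata", set(meta.index))):
        missing = sorted(set(aois) - ids)
        extra = sorted(ids - set(aois))
        if missing or extra:
            raise DataValidationError(
                f"AOI mismatch between counts and {name}: "
                f"missing={missing[:10]} extra={extra[:10]}"
            )
    return AOIDataset(counts=counts, negprobe_counts=negprobes[aois], aoi_meta=meta.loc[aois])


def write_dataset(dataset: AOIDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as counts.tsv / negprobes.tsv / aoi_meta.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "negprobes": outdir / "negprobes.tsv",
        "meta": outdir / "aoi_meta.tsv",
    }
    dataset.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    dataset.negprobe_counts.to_csv(paths["negprobes"], sep="\t", index_label="probe_id")
    dataset.aoi_meta.to_csv(paths["meta"], sep="\t", index_label="aoi_id")
    return paths


def read_gmt(path: str | Path, roles: Mapping[str, str] | str | Path | None = None) -> SignatureSet:
    """Parse a GMT file (name TAB description TAB gene ...).

    ``roles`` may be a mapping or the path of a YAML sidecar mapping
    signature names to role tags. Duplicate genes within one signature are
    deduplicated with a warning; an empty gene list is an error.
    """
    sigs: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                raise DataValidationError(f"{path}:{lineno}: signature {name!r} has no genes")
            if name in sigs:
                raise DataValidationError(f"{path}:{lineno}: duplicate signature name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(f"signature {name!r}: removed {len(genes) - len(deduped)} duplicate genes")
            sigs[name] = deduped
    role_map: dict[str, str] = {}
    if roles is not None:
        if isinstance(roles, (str, Path)):
            with open(roles) as fh:
                role_map = dict(yaml.safe_load(fh) or {})
        else:
            role_map = dict(roles)
    return SignatureSet(signatures=sigs, roles=role_map)


def write_gmt(sigs: SignatureSet, path: str | Path, roles_path: str | Path | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sigs.signatures.items():
            fh.write("\t".join([name, sigs.roles.get(name, "")] + list(genes)) + "\n")
    if roles_path is not None:
        with open(roles_path, "w") as fh:
            yaml.safe_dump(dict(sigs.roles), fh)


def _normalize_chrom(label: str) -> str:
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


def read_gene_annotation(
    path: str | Path,
    chrom_order: Sequence[str] = DEFAULT_CHROM_ORDER,
) -> GeneAnnotation:
    """Read a BED-like gene table (chrom, start, gene_id; extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise DataValidationError("gene annotation needs >=3 columns: chrom, start, gene_id")
    # tolerate a header row
    if not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    tab = pd.DataFrame(
        {
            "chromosome": df.iloc[:, 0].map(_normalize_chrom),
            "start": df.iloc[:, 1].astype(int),
            "gene_id": df.iloc[:, 2].astype(str),
        }
    )
    return build_gene_annotation(tab, chrom_order=chrom_order)


def build_gene_annotation(
    table: pd.DataFrame,
    chrom_order: Sequence[str] = DEFAULT_CHROM_ORDER,
) -> GeneAnnotation:
    """Assemble a :class:`GeneAnnotation` from a chromosome/start/gene_id frame."""
    tab = table.copy()
    if tab["gene_id"].duplicated().any():
        dupes = tab.loc[tab["gene_id"].duplicated(), "gene_id"].unique().tolist()
        raise DataValidationError(f"duplicate gene ids in annotation: {dupes[:10]}")
    order = {c: i for i, c in enumerate(chrom_order)}
    unknown = sorted(set(tab["chromosome"]) - set(order))
    if unknown:
        raise DataValidationError(f"chromosomes absent from configured order: {unknown}")
    tab["_rank"] = tab["chromosome"].map(order)
    tab = tab.sort_values(["_rank", "start"], kind="mergesort").drop(columns="_rank")
    tab["order"] = np.arange(len(tab))
    tab = tab.set_index("gene_id")
    return GeneAnnotation(table=tab, chrom_order=tuple(chrom_order))


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    out = ann.table.sort_values("order")
    out_df = pd.DataFrame(
        {"chrom": out["chromosome"].values, "start": out["start"].values, "gene_id": out.index}
    )
    out_df.to_csv(path, sep="\t", header=False, index=False)
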