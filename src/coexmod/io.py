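"""Readers and writers for the standard formats the pipeline touches.

The pipeline exchanges data as MatrixMarket coordinate triplets with sidecar
gene/barcode label files (the layout droplet pipelines emit), GMT gene-set
collections, and TSV/CSV sample-metadata tables.  The in-memory container is
:class:`ExpressionMatrix`: a genes x observations matrix tagged with the
transformation layer it carries (raw counts, log-normalised, or z-scaled).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("coexmod")

VALID_LAYERS = ("counts", "lognorm", "scaled")

#: Ordinal histology grades accepted by metadata validation.
PHENOTYPE_RANGES = {
    "steatosis": (0, 2),
    "lobular_inflammation": (0, 2),
    "fibrosis": (0, 1),
}


class FormatError(ValueError):
    """A file violates its declared format."""


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x observations expression matrix with axis labels and metadata.

    Parameters
    ----------
    values
        Dense ndarray or scipy sparse matrix, rows = genes, columns =
        observations (cells or bulk samples).
    gene_ids, obs_ids
        Ordered, duplicate-free axis labels.
    obs_meta
        Optional per-observation table indexed by ``obs_ids`` (donor,
        cell type, phenotype grades, covariates — any subset).
    layer_tag
        One of ``counts`` (non-negative raw counts), ``lognorm``
        (log1p-normalised) or ``scaled`` (z-scored).
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    obs_ids: list[str]
    obs_meta: pd.DataFrame | None = None
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        n_genes, n_obs = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_obs != len(self.obs_ids):
            raise ValueError(
                f"matrix has {n_obs} columns but {len(self.obs_ids)} obs ids"
            )
        for name, labels in (("gene", self.gene_ids), ("obs", self.obs_ids)):
            if len(set(labels)) != len(labels):
                seen: set[str] = set()
                dup = next(x for x in labels if x in seen or seen.add(x))
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if self.layer_tag not in VALID_LAYERS:
            raise ValueError(f"layer_tag must be one of {VALID_LAYERS}")
        if self.layer_tag == "counts":
            vmin = self.values.min() if not sp.issparse(self.values) else self.values.min()
            if vmin < 0:
                raise ValueError("counts layer contains negative values")
        if self.obs_meta is not None:
            missing = set(self.obs_ids) - set(map(str, self.obs_meta.index))
            if missing:
                raise ValueError(f"obs_meta missing rows for {sorted(missing)[:5]}")
            self.obs_meta = self.obs_meta.loc[self.obs_ids]

    # -- basic introspection ------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Return values as a dense float ndarray (copy if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_obs(self, mask_or_ids) -> "ExpressionMatrix":
        """Column subset preserving order; metadata carried along."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {o: i for i, o in enumerate(self.obs_ids)}
            idx = np.array([pos[o] for o in mask_or_ids], dtype=int)
        vals = self.values.tocsc()[:, idx] if sp.issparse(self.values) else self.values[:, idx]
        obs = [self.obs_ids[i] for i in idx]
        meta = self.obs_meta.iloc[idx] if self.obs_meta is not None else None
        return ExpressionMatrix(vals, list(self.gene_ids), obs, meta, self.layer_tag)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        vals = self.values.tocsr()[idx, :] if sp.issparse(self.values) else self.values[idx, :]
        return ExpressionMatrix(
            vals, [self.gene_ids[i] for i in idx], list(self.obs_ids),
            self.obs_meta, self.layer_tag,
        )

    def copy(self) -> "ExpressionMatrix":
        meta = None if self.obs_meta is None else self.obs_meta.copy()
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.obs_ids),
            meta, self.layer_tag,
        )


# ---------------------------------------------------------------------------
# MatrixMarket triplet I/O
# ---------------------------------------------------------------------------

def _read_label_file(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def read_mtx_triplet(matrix_path, genes_path, barcodes_path) -> ExpressionMatrix:
    """Read a MatrixMarket coordinate file plus gene/barcode sidecars.

    Entries absent from the triplet list are zero.  Genes and barcodes keep
    file order; duplicates are format errors.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    genes = _read_label_file(genes_path)
    barcodes = _read_label_file(barcodes_path)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"header declares {mat.shape[0]}x{mat.shape[1]} but label files "
            f"give {len(genes)} genes and {len(barcodes)} barcodes"
        )
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise FormatError(f"duplicate gene id: {g!r}")
        seen.add(g)
    return ExpressionMatrix(mat, genes, barcodes, layer_tag="counts")


def write_mtx_triplet(matrix: ExpressionMatrix, out_prefix, integer: bool = True):
    """Write counts as MatrixMarket coordinate + gene/barcode label files.

    Returns the three paths written.  Only nonzero entries appear in the body.
    """
    if matrix.layer_tag != "counts":
        raise ValueError("write_mtx_triplet requires the counts layer")
    vals = matrix.values if sp.issparse(matrix.values) else sp.coo_matrix(matrix.values)
    vals = sp.coo_matrix(vals)
    if integer:
        if not np.allclose(vals.data, np.round(vals.data)):
            raise FormatError("non-integer values cannot be written in integer dialect")
        vals = vals.astype(np.int64)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    mtx_path = out_prefix.with_suffix(".mtx")
    genes_path = Path(str(out_prefix) + ".genes.txt")
    barcodes_path = Path(str(out_prefix) + ".barcodes.txt")
    scipy.io.mmwrite(str(mtx_path), vals, field="integer" if integer else "real")
    genes_path.write_text("".join(g + "\n" for g in matrix.gene_ids))
    barcodes_path.write_text("".join(b + "\n" for b in matrix.obs_ids))
    return mtx_path, genes_path, barcodes_path


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets: ``sets[name] = (description, ordered gene list)``."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene...).

    Set order follows the file; duplicate genes within a set are collapsed,
    keeping first occurrence.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >= 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g != ""))
            if not genes:
                raise FormatError(f"line {lineno}: set {name!r} empty after parsing")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_metadata(path) -> pd.DataFrame:
    """Read a per-sample metadata table keyed by ``sample_id``.

    Ordinal histology grades are validated against their encoding
    (steatosis and lobular inflammation as 0, 1 or 2; fibrosis as 0 or 1);
    missing covariate values are flagged per row with a warning.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise FormatError("metadata must have a 'sample_id' column")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicated sample_id: {dup.iloc[0]!r}")
    df = df.set_index("sample_id")
    df.index = df.index.map(str)
    for col, (lo, hi) in PHENOTYPE_RANGES.items():
        if col in df.columns:
            vals = df[col].dropna()
            bad = vals[(vals < lo) | (vals > hi) | (vals != vals.round())]
            if len(bad):
                raise FormatError(
                    f"{col} value {bad.iloc[0]!r} outside its encoding "
                    f"(integers {lo}..{hi})"
                )
    covar_cols = [c for c in ("bmi", "age", "sex") if c in df.columns]
    if covar_cols:
        incomplete = df.index[df[covar_cols].isna().any(axis=1)]
        if len(incomplete):
            logger.warning(
                "missing covariate values for %d sample(s): %s",
                len(incomplete), list(incomplete[:5]),
            )
    return df


def write_sample_metadata(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index_label="sample_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunables of the downstream stages, each with a default.

    Every stochastic stage carries its own integer seed so a run is fully
    reproducible from the resolved config alone.
    """

    # QC (droplet-data conventions; the source study states only post-QC counts)
    min_genes: int = 200
    max_genes: int = 6000
    max_mito_frac: float = 0.2
    mito_prefix: str = "MT-"
    # feature selection / clustering
    n_hvgs: int = 2000
    n_pcs: int = 30
    k_neighbors: int = 15
    resolution: float = 1.0
    min_corr: float = 0.5            # nearest-centroid annotation floor
    # network construction
    powers: tuple = tuple(range(1, 21))
    r2_target: float = 0.8
    network_type: str = "signed-hybrid"
    corr_method: str = "pearson"
    b_net: int = 20                  # network resamples for the consensus
    resample_frac: float = 0.8
    min_module_size: int = 10
    cut_quantile: float = 0.99
    merge_corr: float = 0.85
    min_mean_kme: float = 0.3
    min_cells_per_type: int = 100
    # association / preservation
    b_assoc: int = 1999              # bootstrap replicates
    m_perm: int = 999                # preservation permutations
    phenotypes: tuple = ("lobular_inflammation", "fibrosis", "steatosis")
    covariates: tuple = ("bmi", "age", "sex")
    # enrichment
    min_set: int = 5
    max_set: int = 500
    # seeds (one per stochastic stage)
    seed_sim: int = 0
    seed_cluster: int = 1
    seed_net: int = 2
    seed_assoc: int = 3
    seed_perm: int = 4

    def __post_init__(self) -> None:
        for name in ("min_genes", "max_genes", "n_hvgs", "n_pcs", "k_neighbors",
                     "b_net", "min_module_size", "b_assoc", "m_perm",
                     "min_set", "max_set", "min_cells_per_type"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("seed_sim", "seed_cluster", "seed_net", "seed_assoc", "seed_perm"):
            if not isinstance(getattr(self, name), int):
                raise ValueError(f"{name} must be an integer seed")
        self.powers = tuple(self.powers)
        self.phenotypes = tuple(self.phenotypes)
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def log_resolved(self) -> None:
        """Log the full resolved configuration, seeds included."""
        for k, v in sorted(dataclasses.asdict(self).items()):
            logger.info("config %s = %r", k, v)
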