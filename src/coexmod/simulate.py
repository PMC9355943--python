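"""Synthetic single-cell, healthy-reference and bulk data with planted structure.

Every downstream stage of the pipeline is verifiable against the ground truth
these generators emit: negative-binomial droplet-style counts from several
cell types across donors with batch effects; planted co-expression modules
driven by per-cell latent factors; a "healthy" reference dataset in which a
configured fraction of modules keep their factor structure while the rest are
destroyed; and bulk samples whose planted module activities depend linearly on
ordinal histology grades (lobular inflammation 0-2, fibrosis 0-1) plus BMI,
age and sex.

The generative model: for a module gene g in a cell c of the module's cell
type, the log mean is

    log mu_gc = base_g + de_{t(c),g} + load_g * f_{m,c} + shift_{d(c)} + eps_gc

with module factor f ~ Normal(0, factor_sd) per cell, donor shift a log-scale
batch effect, and eps ~ Normal(0, noise_sd).  Counts are gamma-Poisson
(negative binomial) with gene dispersion scaled per donor, and a log-normal
cell library-size factor.  Background genes are conditionally independent
given library size, which keeps the false-positive module rate interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "SimConfig", "GroundTruth",
    "simulate_sc_dataset", "simulate_reference_dataset",
    "simulate_bulk_dataset", "simulate_candidate_genes",
    "simulate_geneset_collection",
]

# fixed covariate coefficients on planted module activity (SD units);
# they give the covariate adjustment something real to remove
_BMI_COEF = 0.1
_AGE_COEF = 0.1
_SEX_COEF = 0.2
_MIN_RESIDUAL_VAR = 0.05


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic datasets.

    Defaults mirror the scale of the study being emulated: 10 donors,
    2,000 cells per cell type, 600 genes with 5 planted modules of 30 genes,
    and a bulk cohort of 184 samples (160 cases, 24 controls).
    """

    n_donors: int = 10
    n_cell_types: int = 1
    cells_per_donor: int = 200          # per donor, summed over cell types
    n_genes: int = 600
    n_modules_per_type: int = 5
    module_size: int = 30
    factor_sd: float = 2.0
    noise_sd: float = 0.3
    module_base_offset: float = -1.5   # log-scale baseline shift for factor-
                                       # carrying genes, keeping each module a
                                       # small share of the cell library
    library_size_mean: float = 1500.0
    lib_sd: float = 0.4                  # log-normal sd of cell library factor
    nb_dispersion: float = 0.3
    donor_shift_sd: float = 0.3          # log-scale additive batch shift
    donor_disp_range: tuple = (0.8, 1.25)  # donor dispersion multiplier range
    celltype_de_sd: float = 0.5          # cell-type identity offsets
    n_ref_donors: int = 5
    frac_modules_preserved: float = 0.5
    n_bulk_samples: int = 184
    n_bulk_controls: int = 24
    bulk_library_size: float = 2e5
    bulk_dispersion: float = 0.05
    bulk_lib_sd: float = 0.2
    bulk_effect_scale: float = 1.0       # log-mean change per SD of activity
    phenotype_effect_grid: dict = field(
        default_factory=lambda: {"M-T1-1": {"lobular_inflammation": 0.5}}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_donors", "n_cell_types", "cells_per_donor", "n_genes",
                     "n_modules_per_type", "module_size", "n_bulk_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.module_size < 3:
            raise ValueError("module_size < 3: modules would be undetectable")
        if self.n_cell_types * self.n_modules_per_type * self.module_size > self.n_genes:
            raise ValueError(
                "n_cell_types * n_modules_per_type * module_size exceeds n_genes"
            )
        if not 0.0 <= self.frac_modules_preserved <= 1.0:
            raise ValueError("frac_modules_preserved must be in [0, 1]")
        self.donor_disp_range = tuple(self.donor_disp_range)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        import dataclasses as _dc
        known = {f.name for f in _dc.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml
        data = asdict(self)
        data["donor_disp_range"] = list(self.donor_disp_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted structure emitted by the simulator; acceptance scoring target.

    ``module_assignments`` maps each module gene to ``(cell_type, module_id)``;
    genes absent from the map are background.  ``phenotype_slopes`` are
    standardized slopes in SD-of-activity per phenotype unit.
    """

    gene_ids: list[str]
    cell_types: list[str]
    module_assignments: dict[str, tuple[str, str]]
    module_genes: dict[str, list[str]]
    module_cell_type: dict[str, str]
    factor_loadings: dict[str, float]
    phenotype_slopes: dict[str, dict[str, float]]
    batch_params: dict[str, tuple[float, float]]
    preserved_in_reference: dict[str, bool]
    candidate_gene_truth: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, genes in self.module_genes.items():
            for g in genes:
                ct, m = self.module_assignments[g]
                if m != mid:
                    raise ValueError(f"gene {g} assigned to {m} but listed in {mid}")
        extra = set(self.preserved_in_reference) - set(self.module_genes)
        if extra:
            raise ValueError(f"preserved flags for unknown modules: {sorted(extra)}")
        for slopes in self.phenotype_slopes.values():
            for v in slopes.values():
                if not np.isfinite(v):
                    raise ValueError("phenotype slope not finite")

    @property
    def background_genes(self) -> list[str]:
        return [g for g in self.gene_ids if g not in self.module_assignments]

    @property
    def module_ids(self) -> list[str]:
        return sorted(self.module_genes)

    def gene_labels(self, cell_type: str | None = None) -> pd.Series:
        """Per-gene module label ('background' for unassigned), optionally
        restricted to one cell type's modules."""
        lab = {}
        for g in self.gene_ids:
            ct_mid = self.module_assignments.get(g)
            if ct_mid is None or (cell_type is not None and ct_mid[0] != cell_type):
                lab[g] = "background"
            else:
                lab[g] = ct_mid[1]
        return pd.Series(lab, name="module")[self.gene_ids]

    def to_json(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["module_assignments"] = {
            g: tuple(v) for g, v in data["module_assignments"].items()
        }
        data["batch_params"] = {d: tuple(v) for d, v in data["batch_params"].items()}
        return cls(**data)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws with var = mu + phi*mu^2."""
    shape = 1.0 / phi
    lam = rng.gamma(np.broadcast_to(shape, mu.shape), mu * phi)
    return rng.poisson(lam)


def _plant_modules(cfg: SimConfig, rng: np.random.Generator, gene_ids, cell_types):
    """Disjoint module gene blocks drawn from a global permutation."""
    perm = rng.permutation(cfg.n_genes)
    assignments: dict[str, tuple[str, str]] = {}
    module_genes: dict[str, list[str]] = {}
    module_cell_type: dict[str, str] = {}
    loadings: dict[str, float] = {}
    pos = 0
    for ct in cell_types:
        for k in range(cfg.n_modules_per_type):
            mid = f"M-{ct}-{k + 1}"
            idx = perm[pos:pos + cfg.module_size]
            pos += cfg.module_size
            genes = [gene_ids[i] for i in idx]
            module_genes[mid] = genes
            module_cell_type[mid] = ct
            lds = rng.uniform(0.8, 1.2, cfg.module_size)
            for g, ld in zip(genes, lds):
                assignments[g] = (ct, mid)
                loadings[g] = float(ld)
    return assignments, module_genes, module_cell_type, loadings


def _compose_counts(cfg, rng, base, de, gene_row, module_genes, module_cell_type,
                    loadings, cell_type_of, donor_of, donor_shift, donor_disp,
                    factor_sd):
    """Assemble log-means and draw NB counts for one single-cell dataset."""
    n_cells = len(cell_type_of)
    logmu = base[:, None] + de[:, cell_type_of] \
        + np.asarray([donor_shift[d] for d in donor_of])[None, :]
    for mid in sorted(module_genes):
        ct_idx = module_cell_type[mid]
        genes = module_genes[mid]
        f = rng.normal(0.0, factor_sd, n_cells)
        mask = (cell_type_of == ct_idx).astype(float)
        rows = np.array([gene_row[g] for g in genes])
        lds = np.array([loadings[g] for g in genes])
        logmu[rows, :] += lds[:, None] * (f * mask)[None, :]
    logmu += rng.normal(0.0, cfg.noise_sd, logmu.shape)
    lib = rng.lognormal(0.0, cfg.lib_sd, n_cells)
    c0 = cfg.library_size_mean / np.exp(base).sum()
    mu = np.exp(logmu) * (c0 * lib)[None, :]
    phi = cfg.nb_dispersion * np.asarray([donor_disp[d] for d in donor_of])[None, :]
    return _nb_counts(rng, mu, phi)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_sc_dataset(cfg: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the case single-cell dataset and its ground truth.

    Deterministic: identical ``cfg`` (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    cell_types = [f"T{t + 1}" for t in range(cfg.n_cell_types)]
    donors = [f"D{d + 1:02d}" for d in range(cfg.n_donors)]

    base = rng.normal(0.0, 1.0, cfg.n_genes)
    de = rng.normal(0.0, cfg.celltype_de_sd, (cfg.n_genes, cfg.n_cell_types))
    assignments, module_genes, module_cell_type, loadings = _plant_modules(
        cfg, rng, gene_ids, cell_types
    )
    # module genes sit at a lower gene-intrinsic baseline so each planted
    # module is a small share of the cell library, as modules are of real
    # transcriptomes; library-size normalisation then behaves realistically
    for i, g in enumerate(gene_ids):
        if g in assignments:
            base[i] += cfg.module_base_offset
    donor_shift = {d: float(rng.normal(0.0, cfg.donor_shift_sd)) for d in donors}
    donor_disp = {d: float(rng.uniform(*cfg.donor_disp_range)) for d in donors}

    mids = sorted(module_genes)
    n_pres = int(round(cfg.frac_modules_preserved * len(mids)))
    pres_idx = set(rng.choice(len(mids), size=n_pres, replace=False).tolist())
    preserved = {mid: (i in pres_idx) for i, mid in enumerate(mids)}

    n_cells = cfg.n_donors * cfg.cells_per_donor
    donor_of = np.repeat(donors, cfg.cells_per_donor)
    ct_of = rng.integers(0, cfg.n_cell_types, n_cells)
    gene_row = {g: i for i, g in enumerate(gene_ids)}

    mct_idx = {mid: cell_types.index(ct) for mid, ct in module_cell_type.items()}
    counts = _compose_counts(
        cfg, rng, base, de, gene_row, module_genes, mct_idx, loadings,
        ct_of, donor_of, donor_shift, donor_disp, cfg.factor_sd,
    )

    obs_ids = [f"cell{i:05d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {"donor": donor_of, "cell_type": [cell_types[t] for t in ct_of]},
        index=obs_ids,
    )
    em = ExpressionMatrix(sp.csr_matrix(counts), gene_ids, obs_ids, meta, "counts")

    slopes = {
        mid: dict(cfg.phenotype_effect_grid.get(mid, {})) for mid in mids
        if cfg.phenotype_effect_grid.get(mid)
    }
    truth = GroundTruth(
        gene_ids=gene_ids,
        cell_types=cell_types,
        module_assignments=assignments,
        module_genes=module_genes,
        module_cell_type=module_cell_type,
        factor_loadings=loadings,
        phenotype_slopes=slopes,
        batch_params={d: (donor_shift[d], donor_disp[d]) for d in donors},
        preserved_in_reference=preserved,
    )
    # stash baseline log-means for the reference generator (not part of the
    # serialized truth contract)
    truth._base = base            # type: ignore[attr-defined]
    truth._de = de                # type: ignore[attr-defined]
    return em, truth


def simulate_reference_dataset(cfg: SimConfig, truth: GroundTruth) -> ExpressionMatrix:
    """Simulate the healthy external reference dataset.

    Modules flagged ``preserved_in_reference`` keep their latent-factor
    structure; for the rest, the factor is re-attached to random background
    genes so the original members' co-expression is destroyed.  Donors and
    cells are drawn fresh.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    gene_ids = truth.gene_ids
    cell_types = truth.cell_types
    base = getattr(truth, "_base", None)
    de = getattr(truth, "_de", None)
    if base is None:
        base = rng.normal(0.0, 1.0, len(gene_ids))
        for i, g in enumerate(gene_ids):
            if g in truth.module_assignments:
                base[i] += cfg.module_base_offset
        de = rng.normal(0.0, cfg.celltype_de_sd, (len(gene_ids), len(cell_types)))
    base = np.asarray(base, dtype=float).copy()

    donors = [f"R{d + 1:02d}" for d in range(cfg.n_ref_donors)]
    donor_shift = {d: float(rng.normal(0.0, cfg.donor_shift_sd)) for d in donors}
    donor_disp = {d: float(rng.uniform(*cfg.donor_disp_range)) for d in donors}

    background = truth.background_genes
    gene_row0 = {g: i for i, g in enumerate(gene_ids)}
    eff_genes: dict[str, list[str]] = {}
    eff_load: dict[str, float] = dict(truth.factor_loadings)
    for mid in sorted(truth.module_genes):
        if truth.preserved_in_reference.get(mid, False):
            eff_genes[mid] = truth.module_genes[mid]
        else:
            if len(background) < len(truth.module_genes[mid]):
                raise ValueError(
                    f"not enough background genes to scramble module {mid}"
                )
            picks = rng.choice(len(background), len(truth.module_genes[mid]),
                               replace=False)
            genes = [background[i] for i in sorted(picks.tolist())]
            eff_genes[mid] = genes
            for g, ld in zip(genes, rng.uniform(0.8, 1.2, len(genes))):
                eff_load[g] = float(ld)
                # replacement genes now carry a factor: same baseline shift
                # as planted module genes so library shares stay comparable
                base[gene_row0[g]] += cfg.module_base_offset

    n_cells = cfg.n_ref_donors * cfg.cells_per_donor
    donor_of = np.repeat(donors, cfg.cells_per_donor)
    ct_of = rng.integers(0, len(cell_types), n_cells)
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    mct_idx = {mid: cell_types.index(ct)
               for mid, ct in truth.module_cell_type.items()}
    counts = _compose_counts(
        cfg, rng, base, de, gene_row, eff_genes, mct_idx, eff_load,
        ct_of, donor_of, donor_shift, donor_disp, cfg.factor_sd,
    )
    obs_ids = [f"ref{i:05d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {"donor": donor_of, "cell_type": [cell_types[t] for t in ct_of]},
        index=obs_ids,
    )
    return ExpressionMatrix(sp.csr_matrix(counts), gene_ids, obs_ids, meta, "counts")


def simulate_bulk_dataset(cfg: SimConfig, truth: GroundTruth
                          ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the bulk cohort: counts plus a sample-metadata table.

    Controls carry grade-0 phenotypes; cases draw inflammation uniformly from
    {0,1,2} and fibrosis from {0,1}.  Each planted module's latent activity is
    slope*phenotype + covariate terms + noise, with the noise variance chosen
    so the marginal activity variance is 1 — slopes are therefore in SD-of-
    activity per phenotype unit, the scale the association stage reports.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    n = cfg.n_bulk_samples
    n_ctrl = min(cfg.n_bulk_controls, n)
    is_case = np.arange(n) >= n_ctrl

    inflammation = np.where(is_case, rng.integers(0, 3, n), 0)
    fibrosis = np.where(is_case, rng.integers(0, 2, n), 0)
    steatosis = np.where(is_case, rng.integers(0, 3, n), 0)
    bmi = rng.normal(42.0, 6.0, n)
    age = rng.normal(48.0, 11.0, n)
    sex = np.where(rng.random(n) < 0.7, "F", "M")
    male = (sex == "M").astype(float)

    pheno = {
        "lobular_inflammation": inflammation.astype(float),
        "fibrosis": fibrosis.astype(float),
        "steatosis": steatosis.astype(float),
    }
    z_bmi = (bmi - bmi.mean()) / bmi.std()
    z_age = (age - age.mean()) / age.std()
    covar_part = _BMI_COEF * z_bmi + _AGE_COEF * z_age + _SEX_COEF * male

    gene_ids = truth.gene_ids
    base = rng.normal(0.0, 1.0, len(gene_ids))
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    for genes in truth.module_genes.values():
        for g in genes:
            base[gene_row[g]] += cfg.module_base_offset
    logmu = np.tile(base[:, None], (1, n))
    for mid in sorted(truth.module_genes):
        slopes = truth.phenotype_slopes.get(mid, {})
        det = covar_part.copy()
        for p, slope in sorted(slopes.items()):
            if p not in pheno:
                raise ValueError(f"unknown phenotype in effect grid: {p}")
            det = det + slope * pheno[p]
        resid_var = 1.0 - det.var()
        if resid_var < _MIN_RESIDUAL_VAR:
            raise ValueError(
                f"planted effects for {mid} leave residual variance "
                f"{resid_var:.3f} < {_MIN_RESIDUAL_VAR}"
            )
        activity = det + rng.normal(0.0, np.sqrt(resid_var), n)
        rows = np.array([gene_row[g] for g in truth.module_genes[mid]])
        lds = np.array([truth.factor_loadings[g] for g in truth.module_genes[mid]])
        logmu[rows, :] += cfg.bulk_effect_scale * lds[:, None] * activity[None, :]

    lib = rng.lognormal(0.0, cfg.bulk_lib_sd, n)
    c0 = cfg.bulk_library_size / np.exp(base).sum()
    mu = np.exp(logmu) * (c0 * lib)[None, :]
    counts = _nb_counts(rng, mu, cfg.bulk_dispersion)

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "steatosis": steatosis,
            "lobular_inflammation": inflammation,
            "fibrosis": fibrosis,
            "bmi": np.round(bmi, 2),
            "age": np.round(age, 1),
            "sex": sex,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    em = ExpressionMatrix(counts.astype(np.int64), gene_ids, sample_ids,
                          meta, "counts")
    return em, meta


def simulate_candidate_genes(truth: GroundTruth, n_total: int,
                             planted_per_module: Mapping[str, int],
                             seed: int = 0) -> list[str]:
    """Candidate gene list with known enrichment in chosen modules.

    Planted members are drawn from the target modules, the remainder
    uniformly from background genes; ``truth.candidate_gene_truth`` records
    the planted counts.
    """
    rng = np.random.default_rng([seed, 3])
    planted: list[str] = []
    for mid in sorted(planted_per_module):
        k = planted_per_module[mid]
        genes = truth.module_genes.get(mid)
        if genes is None:
            raise ValueError(f"unknown module: {mid}")
        if k > len(genes):
            raise ValueError(
                f"requested {k} planted genes but module {mid} has {len(genes)}"
            )
        picks = rng.choice(len(genes), k, replace=False)
        planted.extend(genes[i] for i in sorted(picks.tolist()))
    if len(planted) > n_total:
        raise ValueError("sum of planted counts exceeds n_total")
    # remainder drawn uniformly from the whole gene universe (minus genes
    # already picked) so an unplanted list overlaps modules at the
    # hypergeometric rate
    pool = [g for g in truth.gene_ids if g not in set(planted)]
    n_rest = n_total - len(planted)
    if n_rest > len(pool):
        raise ValueError("n_total exceeds the number of available genes")
    picks = rng.choice(len(pool), n_rest, replace=False)
    out = planted + [pool[i] for i in sorted(picks.tolist())]
    truth.candidate_gene_truth = {
        mid: int(planted_per_module[mid]) for mid in sorted(planted_per_module)
    }
    return out


def simulate_geneset_collection(truth: GroundTruth, n_random: int = 10,
                                set_size: int = 25, seed: int = 0
                                ) -> GeneSetCollection:
    """GMT-style collection: one set per planted module plus random sets."""
    rng = np.random.default_rng([seed, 4])
    sets: dict[str, tuple[str, list[str]]] = {}
    for mid in sorted(truth.module_genes):
        sets[f"SET_{mid}"] = (f"planted module {mid}",
                              sorted(truth.module_genes[mid]))
    for j in range(n_random):
        picks = rng.choice(len(truth.gene_ids), set_size, replace=False)
        sets[f"RANDOM_{j + 1}"] = (
            "uniform random set",
            [truth.gene_ids[i] for i in sorted(picks.tolist())],
        )
    return GeneSetCollection(sets)
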