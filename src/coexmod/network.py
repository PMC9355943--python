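"""Robust weighted gene co-expression network analysis (rWGCNA) core.

Pipeline per cell type: pairwise gene correlations on per-donor-scaled
expression -> soft-thresholded adjacency (signed-hybrid by default: negative
correlations are clipped to zero so a module reads as a coherently up/down
regulated programme) -> topological overlap matrix (TOM)

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

-> average-linkage clustering of 1 - TOM with a static quantile tree cut.
Robustness comes from a consensus: the TOM is recomputed on B resamples of
80% of the cells and combined elementwise by the median before module
detection.  Module summaries are the eigengene (first principal component of
the module submatrix, sign-oriented along mean expression) and kIM
(intramodular connectivity: a gene's summed TOM similarity to the other
members), which downstream stages use as the gene centrality weight.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, GeneSetCollection, PipelineConfig

logger = logging.getLogger("coexmod")

__all__ = [
    "SoftPowerFit", "GeneModule", "ModuleSet",
    "pairwise_correlation", "adjacency", "pick_soft_power", "tom_similarity",
    "detect_modules", "consensus_modules", "module_eigengene", "compute_kim",
    "merge_modules", "qc_modules",
]


@dataclass
class SoftPowerFit:
    """Scale-free fit per candidate soft power and the selected exponent."""

    powers: list[int]
    r_squared: list[float]            # signed: R^2 * sign(slope)
    mean_connectivity: list[float]
    chosen_power: int


@dataclass
class GeneModule:
    """A named, cell-type-tagged gene set with kIM centrality weights."""

    module_id: str
    cell_type: str
    genes: list[str]
    kim: dict[str, float]             # raw intramodular connectivity
    kim_normalized: dict[str, float]  # kim scaled to sum 1
    eigengene: np.ndarray | None = None   # per-observation discovery score
    kme: dict[str, float] = field(default_factory=dict)  # gene-eigengene corr

    def __post_init__(self) -> None:
        if set(self.kim) != set(self.genes):
            raise ValueError(f"{self.module_id}: kim keys must equal genes")
        if any(v < 0 for v in self.kim.values()):
            raise ValueError(f"{self.module_id}: kIM weights must be >= 0")
        if not any(self.kim.values()):
            raise ValueError(f"{self.module_id}: kIM all zero")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class ModuleSet:
    """Modules detected for one cell type plus the unassigned background."""

    modules: list[GeneModule]
    background_genes: list[str]
    provenance: dict

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mod in self.modules:
            overlap = seen & set(mod.genes)
            if overlap:
                raise ValueError(
                    f"modules overlap within one cell type: {sorted(overlap)[:5]}"
                )
            seen.update(mod.genes)

    @property
    def all_genes(self) -> list[str]:
        out = []
        for mod in self.modules:
            out.extend(mod.genes)
        out.extend(self.background_genes)
        return out

    def labels(self, genes) -> list[str]:
        lab = {g: "background" for g in self.background_genes}
        for mod in self.modules:
            for g in mod.genes:
                lab[g] = mod.module_id
        return [lab[g] for g in genes]

    def to_json(self, path) -> None:
        data = {
            "provenance": self.provenance,
            "background_genes": self.background_genes,
            "modules": [
                {
                    "module_id": m.module_id,
                    "cell_type": m.cell_type,
                    "genes": m.genes,
                    "kim": {g: round(m.kim[g], 10) for g in m.genes},
                    "kim_normalized": {g: round(m.kim_normalized[g], 10)
                                       for g in m.genes},
                    "kme": {g: round(m.kme.get(g, 0.0), 10) for g in m.genes},
                }
                for m in self.modules
            ],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ModuleSet":
        with open(path) as fh:
            data = json.load(fh)
        modules = [
            GeneModule(
                module_id=m["module_id"], cell_type=m["cell_type"],
                genes=m["genes"], kim=m["kim"],
                kim_normalized=m["kim_normalized"], kme=m.get("kme", {}),
            )
            for m in data["modules"]
        ]
        return cls(modules, data["background_genes"], data.get("provenance", {}))

    def to_gmt(self) -> GeneSetCollection:
        return GeneSetCollection({
            m.module_id: (f"cell type {m.cell_type}", list(m.genes))
            for m in self.modules
        })


# ---------------------------------------------------------------------------
# correlations, adjacency, soft power
# ---------------------------------------------------------------------------

def pairwise_correlation(expr: ExpressionMatrix, method: str = "pearson"
                         ) -> np.ndarray:
    """Gene-gene correlation matrix; zero-variance genes get zero rows."""
    if expr.layer_tag not in ("scaled", "lognorm"):
        raise ValueError("pairwise_correlation requires scaled or lognorm data")
    if expr.n_obs < 30:
        raise ValueError("need >= 30 observations for a stable network")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method: {method!r}")
    X = expr.dense()
    if method == "spearman":
        from scipy.stats import rankdata
        X = rankdata(X, axis=1)
    sd = X.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance gene(s); correlations set to 0",
                       int(flat.sum()))
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.where(sd > 0, sd, 1.0) * np.sqrt(X.shape[1])
    Xn = Xc / denom[:, None]
    corr = Xn @ Xn.T
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, np.where(flat, 0.0, 1.0))
    return corr


def adjacency(corr: np.ndarray, power: float,
              network_type: str = "signed-hybrid") -> np.ndarray:
    """Soft-thresholded adjacency with zero diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    if network_type == "unsigned":
        adj = np.abs(corr) ** power
    elif network_type == "signed-hybrid":
        adj = np.clip(corr, 0.0, None) ** power
    else:
        raise ValueError(f"unknown network_type: {network_type!r}")
    np.fill_diagonal(adj, 0.0)
    return adj


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(freq) on log10(k) over connectivity bins."""
    k = k[k > 0]
    if k.size < 2:
        return -1.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return -1.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, _ = np.polyfit(xs, ys, 1)
    yhat = np.polyval(np.polyfit(xs, ys, 1), xs)
    ss_res = ((ys - yhat) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # WGCNA sign convention: positive when the degree distribution decreases
    # (slope < 0), so a perfect power law p(k) ~ k^-gamma scores +1
    return float(-r2 * np.sign(slope))


def pick_soft_power(corr: np.ndarray, powers=tuple(range(1, 21)),
                    r2_target: float = 0.8,
                    network_type: str = "signed-hybrid") -> SoftPowerFit:
    """Smallest power whose scale-free fit reaches ``r2_target``.

    Falls back to the best-fitting power (with a warning) if none reaches the
    target.
    """
    powers = [int(b) for b in powers]
    if powers != sorted(powers):
        raise ValueError("powers must be an ascending grid")
    r2s, means = [], []
    for beta in powers:
        adj = adjacency(corr, beta, network_type)
        k = adj.sum(axis=1)
        if not np.any(k > 0):
            raise ValueError("all genes disconnected at power %d" % beta)
        r2s.append(_scale_free_r2(k))
        means.append(float(k.mean()))
    chosen = None
    for beta, r2 in zip(powers, r2s):
        if r2 >= r2_target:
            chosen = beta
            break
    if chosen is None:
        chosen = powers[int(np.argmax(r2s))]
        logger.warning(
            "no power reached scale-free R^2 %.2f; using best power %d "
            "(R^2=%.3f)", r2_target, chosen, max(r2s),
        )
    return SoftPowerFit(powers, r2s, means, chosen)


# ---------------------------------------------------------------------------
# topological overlap and tree cutting
# ---------------------------------------------------------------------------

def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix; diagonal defined as 1."""
    if adj.min() < 0 or adj.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency must have zero diagonal")
    k = adj.sum(axis=1)
    shared = adj @ adj
    numer = shared + adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    return tom


def detect_modules(tom: np.ndarray, gene_ids, min_size: int = 10,
                   cut_quantile: float = 0.99, cell_type: str = "NA",
                   provenance: dict | None = None) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static quantile cut.

    Clusters smaller than ``min_size`` fall into the background.  Module ids
    are assigned by decreasing size as ``M-<cell_type>-<rank>``.
    """
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    if n < min_size:
        return ModuleSet([], gene_ids, provenance or {})
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, dist.T)  # exact symmetry for squareform
    link = sch.linkage(squareform(dist, checks=False), method="average")
    heights = link[:, 2]
    cut = float(np.quantile(heights, cut_quantile))
    flat = sch.fcluster(link, t=cut, criterion="distance")
    modules: list[tuple[list[str], np.ndarray]] = []
    for c in sorted(set(flat.tolist())):
        idx = np.flatnonzero(flat == c)
        if idx.size >= min_size:
            modules.append(([gene_ids[i] for i in idx], idx))
    # order by decreasing size, ties by first gene id for determinism
    modules.sort(key=lambda t: (-len(t[0]), t[0][0]))
    out: list[GeneModule] = []
    assigned: set[str] = set()
    for rank, (genes, idx) in enumerate(modules, start=1):
        kim_raw = _kim_from_tom(tom, idx)
        total = kim_raw.sum()
        out.append(GeneModule(
            module_id=f"M-{cell_type}-{rank}",
            cell_type=cell_type,
            genes=genes,
            kim={g: float(v) for g, v in zip(genes, kim_raw)},
            kim_normalized={g: float(v / total) for g, v in zip(genes, kim_raw)},
        ))
        assigned.update(genes)
    background = [g for g in gene_ids if g not in assigned]
    return ModuleSet(out, background, provenance or {})


def _kim_from_tom(tom: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = tom[np.ix_(idx, idx)]
    return sub.sum(axis=1) - np.diag(sub)


def compute_kim(tom: np.ndarray, gene_ids, module_genes
                ) -> tuple[dict[str, float], dict[str, float]]:
    """Intramodular connectivity: summed TOM similarity to other members.

    Returns raw and sum-to-1 normalized weights.
    """
    module_genes = list(module_genes)
    if len(module_genes) < 2:
        raise ValueError("kIM undefined for a singleton module")
    lookup = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in module_genes if g not in lookup]
    if missing:
        raise KeyError(f"module genes absent from TOM index: {missing[:5]}")
    idx = np.array([lookup[g] for g in module_genes])
    raw = _kim_from_tom(tom, idx)
    total = raw.sum()
    if total == 0:
        raise ValueError("kIM weights all zero (disconnected module)")
    return (
        {g: float(v) for g, v in zip(module_genes, raw)},
        {g: float(v / total) for g, v in zip(module_genes, raw)},
    )


# ---------------------------------------------------------------------------
# eigengenes, merging, QC
# ---------------------------------------------------------------------------

def module_eigengene(expr: ExpressionMatrix, genes) -> np.ndarray:
    """First principal component score of the module submatrix.

    Genes are standardized across observations; the score is scaled to unit
    variance and sign-oriented so its correlation with the module's mean
    expression is non-negative.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("eigengene needs >= 2 module genes")
    idx = expr.gene_index(genes)
    X = expr.dense()[idx, :]            # genes x obs
    sd = X.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValueError("all-constant module submatrix")
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    Z[sd == 0, :] = 0.0
    # first right singular vector of the genes x obs matrix = PC1 score
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    score = vt[0]
    s = score.std(ddof=0)
    if s == 0:
        raise ValueError("degenerate eigengene (zero variance)")
    score = score / s
    mean_expr = Z.mean(axis=0)
    orient = np.dot(score, mean_expr - mean_expr.mean())
    if orient < 0:
        score = -score
    return score


def merge_modules(expr: ExpressionMatrix, module_set: ModuleSet,
                  merge_corr: float = 0.85) -> ModuleSet:
    """Iteratively merge the module pair with the highest eigengene
    correlation while it exceeds ``merge_corr``; ties break by module id."""
    mods = {m.module_id: list(m.genes) for m in module_set.modules}
    cell_type = module_set.modules[0].cell_type if module_set.modules else "NA"
    while len(mods) >= 2:
        ids = sorted(mods)
        eig = {mid: module_eigengene(expr, mods[mid]) for mid in ids}
        best_pair, best_r = None, merge_corr
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                r = float(np.corrcoef(eig[a], eig[b])[0, 1])
                if r > best_r:
                    best_pair, best_r = (a, b), r
        if best_pair is None:
            break
        a, b = best_pair
        logger.info("merging %s into %s (eigengene r=%.3f)", b, a, best_r)
        mods[a] = mods[a] + [g for g in mods[b] if g not in set(mods[a])]
        del mods[b]
    tom = module_set.provenance.get("_tom")
    gene_ids = module_set.provenance.get("_tom_genes")
    out = []
    ordered = sorted(mods.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    for rank, (_, genes) in enumerate(ordered, start=1):
        if tom is not None:
            kim_raw, kim_norm = compute_kim(tom, gene_ids, genes)
        else:
            kim_raw = {g: 1.0 for g in genes}
            kim_norm = {g: 1.0 / len(genes) for g in genes}
        out.append(GeneModule(
            module_id=f"M-{cell_type}-{rank}", cell_type=cell_type,
            genes=genes, kim=kim_raw, kim_normalized=kim_norm,
        ))
    assigned = {g for m in out for g in m.genes}
    background = [g for g in module_set.all_genes if g not in assigned]
    return ModuleSet(out, background, module_set.provenance)


def qc_modules(expr: ExpressionMatrix, module_set: ModuleSet,
               min_size: int = 10, min_mean_kme: float = 0.3) -> ModuleSet:
    """Retain modules by size and mean gene-eigengene correlation (kME)."""
    kept: list[GeneModule] = []
    dropped_genes: list[str] = []
    dense = expr.dense()
    for mod in module_set.modules:
        if mod.size < min_size:
            dropped_genes.extend(mod.genes)
            continue
        eig = module_eigengene(expr, mod.genes)
        idx = expr.gene_index(mod.genes)
        kme = {}
        for g, row in zip(mod.genes, dense[idx, :]):
            sd = row.std(ddof=0)
            kme[g] = float(np.corrcoef(row, eig)[0, 1]) if sd > 0 else 0.0
        mean_kme = float(np.mean(list(kme.values())))
        if mean_kme < min_mean_kme:
            logger.info("dropping %s (mean kME %.3f < %.2f)",
                        mod.module_id, mean_kme, min_mean_kme)
            dropped_genes.extend(mod.genes)
            continue
        mod.kme = kme
        mod.eigengene = eig
        kept.append(mod)
    # re-rank ids by size after QC
    kept.sort(key=lambda m: (-m.size, m.genes[0]))
    for rank, mod in enumerate(kept, start=1):
        mod.module_id = f"M-{mod.cell_type}-{rank}"
    background = sorted(set(module_set.background_genes) | set(dropped_genes))
    return ModuleSet(kept, background, module_set.provenance)


# ---------------------------------------------------------------------------
# consensus over cell resamples
# ---------------------------------------------------------------------------

def consensus_modules(expr: ExpressionMatrix, cfg: PipelineConfig,
                      cell_type: str = "NA", seed: int | None = None
                      ) -> ModuleSet:
    """rWGCNA: consensus (elementwise-median) TOM over cell resamples.

    The soft power is chosen once on the full data and reused across
    resamples, so consensus differences reflect sampling only.  Each of
    ``cfg.b_net`` resamples draws ceil(resample_frac * n) observations
    without replacement; modules are detected on the median TOM, then merged
    and quality-controlled.
    """
    if expr.layer_tag != "scaled":
        raise ValueError("consensus_modules requires the scaled layer")
    if expr.n_obs < 100:
        raise ValueError("need >= 100 observations per cell type")
    n_sub = int(np.ceil(cfg.resample_frac * expr.n_obs))
    if n_sub > expr.n_obs:
        raise ValueError("resample size exceeds available observations")
    seed = cfg.seed_net if seed is None else seed
    rng = np.random.default_rng([seed, 0])

    corr_full = pairwise_correlation(expr, cfg.corr_method)
    fit = pick_soft_power(corr_full, cfg.powers, cfg.r2_target, cfg.network_type)
    logger.info("%s: soft power %d (signed R^2 %.3f)", cell_type,
                fit.chosen_power,
                fit.r_squared[fit.powers.index(fit.chosen_power)])

    dense = expr.dense()
    toms = np.empty((cfg.b_net, expr.n_genes, expr.n_genes))
    for b in range(cfg.b_net):
        cols = rng.choice(expr.n_obs, size=n_sub, replace=False)
        cols.sort()
        sub = ExpressionMatrix(dense[:, cols], list(expr.gene_ids),
                               [expr.obs_ids[i] for i in cols],
                               None, "scaled")
        corr = pairwise_correlation(sub, cfg.corr_method)
        adj = adjacency(corr, fit.chosen_power, cfg.network_type)
        toms[b] = tom_similarity(adj)
    consensus = np.median(toms, axis=0)
    del toms

    cfg_hash = hashlib.sha256(
        json.dumps({
            "power": fit.chosen_power, "b_net": cfg.b_net,
            "resample_frac": cfg.resample_frac, "network_type": cfg.network_type,
            "corr_method": cfg.corr_method, "min_module_size": cfg.min_module_size,
            "cut_quantile": cfg.cut_quantile, "merge_corr": cfg.merge_corr,
            "min_mean_kme": cfg.min_mean_kme,
        }, sort_keys=True).encode()
    ).hexdigest()[:12]
    provenance = {
        "cell_type": cell_type, "config_hash": cfg_hash, "seed": seed,
        "chosen_power": fit.chosen_power,
        "_tom": consensus, "_tom_genes": list(expr.gene_ids),
    }
    mset = detect_modules(consensus, expr.gene_ids, cfg.min_module_size,
                          cfg.cut_quantile, cell_type, provenance)
    mset = merge_modules(expr, mset, cfg.merge_corr)
    mset = qc_modules(expr, mset, cfg.min_module_size, cfg.min_mean_kme)
    # strip the in-memory TOM from serializable provenance, keep for callers
    mset.consensus_tom = provenance.pop("_tom")          # type: ignore[attr-defined]
    mset.tom_gene_ids = provenance.pop("_tom_genes")     # type: ignore[attr-defined]
    return mset
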