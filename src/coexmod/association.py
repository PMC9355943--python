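"""Module activity projection, preservation testing and phenotype association.

Module activity in any expression dataset (bulk samples or single cells) is
the weighted mean of z-scored module-gene expression, with weights the
module's kIM centrality normalized to sum 1 over the genes present.  Activity
is associated with ordinal histology grades (lobular inflammation encoded
0-2, fibrosis 0-1, steatosis 0-2) by ordinary least squares controlling for
BMI, age and sex, with bootstrap percentile confidence intervals and
two-sided bootstrap percentile p-values, Benjamini-Hochberg corrected across
modules within each phenotype.  Module preservation in an external reference
is tested by comparing the mean within-module pairwise correlation against
size-matched random gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .network import GeneModule

logger = logging.getLogger("coexmod")

__all__ = [
    "ModuleActivity", "module_activity", "preservation_test",
    "fit_linear_model", "bootstrap_percentile", "associate_modules",
    "bh_adjust", "activity_by_cluster",
]

_MAX_REDRAW_FRAC = 0.10


@dataclass
class ModuleActivity:
    """Observations x modules activity, raw and unit-variance standardized."""

    raw: pd.DataFrame
    standardized: pd.DataFrame
    weights: dict[str, dict[str, float]]      # module -> gene -> weight used
    scaling: dict[str, pd.DataFrame]          # module -> per-gene mean/SD used

    @property
    def obs_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def module_ids(self) -> list[str]:
        return list(self.raw.columns)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def _activity_single(expr_dense: np.ndarray, gene_ids: list[str],
                     module: GeneModule) -> tuple[np.ndarray, dict, pd.DataFrame]:
    present = [g for g in module.genes if g in set(gene_ids)]
    missing = [g for g in module.genes if g not in set(gene_ids)]
    if len(present) < 2:
        raise ValueError(
            f"{module.module_id}: fewer than 2 module genes present "
            f"(missing: {missing[:10]})"
        )
    if missing:
        logger.warning("%s: %d module gene(s) absent, dropped: %s",
                       module.module_id, len(missing), missing[:5])
    lookup = {g: i for i, g in enumerate(gene_ids)}
    idx = np.array([lookup[g] for g in present])
    X = expr_dense[idx, :]
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=0)
    Z = (X - mean[:, None]) / np.where(sd > 0, sd, 1.0)[:, None]
    Z[sd == 0, :] = 0.0
    w = np.array([module.kim_normalized[g] for g in present])
    total = w.sum()
    if total <= 0:
        raise ValueError(f"{module.module_id}: weights sum to zero over present genes")
    w = w / total
    act = w @ Z
    weights = {g: float(v) for g, v in zip(present, w)}
    scaling = pd.DataFrame({"mean": mean, "sd": sd}, index=present)
    return act, weights, scaling


def module_activity(expr: ExpressionMatrix, modules) -> ModuleActivity:
    """Weighted mean of z-scored module-gene expression per observation.

    Gene z-scores use the target dataset's own means and SDs (so single-cell
    modules project into an independent bulk cohort with no shared scale);
    weights are normalized kIM renormalized over genes present.  Both the raw
    and the unit-variance standardized activity are returned.
    """
    if isinstance(modules, GeneModule):
        modules = [modules]
    dense = expr.dense()
    raw, std, weights, scalings = {}, {}, {}, {}
    for mod in modules:
        act, w, scal = _activity_single(dense, expr.gene_ids, mod)
        raw[mod.module_id] = act
        s = act.std(ddof=0)
        std[mod.module_id] = act / s if s > 0 else act
        weights[mod.module_id] = w
        scalings[mod.module_id] = scal
    index = pd.Index(expr.obs_ids, name="obs_id")
    return ModuleActivity(
        raw=pd.DataFrame(raw, index=index),
        standardized=pd.DataFrame(std, index=index),
        weights=weights,
        scaling=scalings,
    )


# ---------------------------------------------------------------------------
# preservation in an external reference
# ---------------------------------------------------------------------------

def _mean_offdiag_corr(X: np.ndarray) -> float:
    """Mean off-diagonal pairwise Pearson correlation of rows of X."""
    sd = X.std(axis=1, ddof=0)
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    Z[sd == 0, :] = 0.0
    C = (Z @ Z.T) / X.shape[1]
    n = X.shape[0]
    return float((C.sum() - np.trace(C)) / (n * (n - 1)))


def preservation_test(module: GeneModule, reference: ExpressionMatrix,
                      m_perm: int = 999, seed: int = 0) -> dict:
    """Permutation test of module co-expression in an external dataset.

    Observed statistic: mean off-diagonal pairwise correlation among module
    genes in the reference.  Null: the same statistic for ``m_perm`` random
    gene sets of equal size drawn from reference-expressed genes.  Empirical
    p = (1 + #{null >= observed}) / (m_perm + 1).
    """
    if reference.layer_tag not in ("lognorm", "scaled"):
        raise ValueError("preservation_test requires lognorm or scaled data")
    if reference.n_obs < 50:
        raise ValueError("reference needs >= 50 observations")
    dense = reference.dense()
    expressed = np.flatnonzero(dense.std(axis=1, ddof=0) > 0)
    expr_genes = {reference.gene_ids[i] for i in expressed}
    present = [g for g in module.genes if g in expr_genes]
    if len(present) < 5:
        logger.warning("%s skipped: only %d module gene(s) expressed in reference",
                       module.module_id, len(present))
        return {
            "module_id": module.module_id, "n_genes_tested": len(present),
            "observed": np.nan, "null_mean": np.nan, "null_sd": np.nan,
            "z": np.nan, "p": np.nan, "skipped": True,
        }
    lookup = {g: i for i, g in enumerate(reference.gene_ids)}
    idx = np.array([lookup[g] for g in present])
    observed = _mean_offdiag_corr(dense[idx, :])
    rng = np.random.default_rng([seed, 5])
    null = np.empty(m_perm)
    for j in range(m_perm):
        pick = rng.choice(expressed, size=len(present), replace=False)
        null[j] = _mean_offdiag_corr(dense[pick, :])
    p = (1.0 + np.sum(null >= observed)) / (m_perm + 1.0)
    null_sd = null.std(ddof=1)
    z = (observed - null.mean()) / null_sd if null_sd > 0 else np.inf
    return {
        "module_id": module.module_id, "n_genes_tested": len(present),
        "observed": observed, "null_mean": float(null.mean()),
        "null_sd": float(null_sd), "z": float(z), "p": float(p),
        "skipped": False,
    }


def preservation_table(modules, reference: ExpressionMatrix, m_perm: int = 999,
                       seed: int = 0) -> pd.DataFrame:
    """Run preservation_test per module and BH-adjust across tested modules."""
    rows = [preservation_test(m, reference, m_perm, seed + i)
            for i, m in enumerate(modules)]
    df = pd.DataFrame(rows).set_index("module_id")
    tested = ~df["skipped"]
    padj = pd.Series(np.nan, index=df.index)
    if tested.any():
        padj[tested] = bh_adjust(df.loc[tested, "p"].to_numpy())
    df["p_adj"] = padj
    return df


# ---------------------------------------------------------------------------
# linear models with bootstrap percentile inference
# ---------------------------------------------------------------------------

def _design_matrix(meta: pd.DataFrame, phenotype: str, covariates
                   ) -> tuple[np.ndarray, list[str]]:
    cols = [phenotype]
    X = [meta[phenotype].to_numpy(dtype=float)]
    for c in covariates:
        if c == "sex":
            X.append((meta["sex"].astype(str) == "M").to_numpy(dtype=float))
            cols.append("sex_male")
        else:
            X.append(meta[c].to_numpy(dtype=float))
            cols.append(c)
    X.insert(0, np.ones(len(meta)))
    cols.insert(0, "intercept")
    return np.column_stack(X), cols


def fit_linear_model(y: np.ndarray, X: np.ndarray, names=None) -> pd.Series:
    """OLS coefficients (with intercept already in X)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        # identify a collinear column by rank after removal
        bad = [names[j] for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    import statsmodels.api as sm
    res = sm.OLS(y, X).fit()
    idx = names if names is not None else [f"x{i}" for i in range(X.shape[1])]
    return pd.Series(res.params, index=idx)


def _batched_ols_slope(y: np.ndarray, X: np.ndarray, idx: np.ndarray,
                       coef_pos: int) -> np.ndarray:
    """Phenotype coefficient for each bootstrap index row, batched."""
    Xb = X[idx]                        # B x n x p
    yb = y[idx]                        # B x n
    XtX = np.einsum("bni,bnj->bij", Xb, Xb)
    Xty = np.einsum("bni,bn->bi", Xb, yb)
    beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    return beta[:, coef_pos]


def bootstrap_percentile(y: np.ndarray, X: np.ndarray, coef_pos: int = 1,
                         b_assoc: int = 1999, seed: int = 0,
                         ci: tuple[float, float] = (2.5, 97.5)
                         ) -> tuple[float, float, float]:
    """Bootstrap percentile CI and two-sided percentile p for one coefficient.

    Rows of (y, X) are resampled with replacement ``b_assoc`` times and the
    model refit; p = 2 * min(#{b* <= 0} + 1, #{b* >= 0} + 1) / (B + 1),
    capped at 1.  Rank-deficient resamples are redrawn (error above 10%).
    """
    if b_assoc < 199:
        raise ValueError("b_assoc must be >= 199")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    rng = np.random.default_rng([seed, 6])
    betas = np.empty(b_assoc)
    filled = 0
    redraws = 0
    while filled < b_assoc:
        todo = b_assoc - filled
        idx = rng.integers(0, n, size=(todo, n))
        try:
            vals = _batched_ols_slope(y, X, idx, coef_pos)
            ok = np.isfinite(vals)
        except np.linalg.LinAlgError:
            # fall back to per-replicate fitting to salvage the valid draws
            vals = np.full(todo, np.nan)
            for b in range(todo):
                try:
                    coef, *_ = np.linalg.lstsq(X[idx[b]], y[idx[b]], rcond=None)
                    if np.linalg.matrix_rank(X[idx[b]]) == X.shape[1]:
                        vals[b] = coef[coef_pos]
                except np.linalg.LinAlgError:
                    pass
            ok = np.isfinite(vals)
        redraws += int((~ok).sum())
        if redraws > _MAX_REDRAW_FRAC * b_assoc:
            raise ValueError(
                f"more than {_MAX_REDRAW_FRAC:.0%} of bootstrap resamples were "
                "rank-deficient"
            )
        take = vals[ok]
        betas[filled:filled + len(take)] = take
        filled += len(take)
    if redraws:
        logger.info("redrew %d rank-deficient bootstrap resample(s)", redraws)
    lo, hi = np.percentile(betas, ci)
    n_le = int(np.sum(betas <= 0)) + 1
    n_ge = int(np.sum(betas >= 0)) + 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / (b_assoc + 1))
    return float(lo), float(hi), float(p)


def associate_modules(activity: ModuleActivity, meta: pd.DataFrame,
                      phenotypes=("lobular_inflammation", "fibrosis"),
                      covariates=("bmi", "age", "sex"),
                      b_assoc: int = 1999, seed: int = 0,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per (module, phenotype): OLS effect in SD-of-activity units, bootstrap
    percentile CI and p, BH-adjusted across modules within each phenotype.

    Samples with missing covariate values are dropped listwise; the per-model
    n is reported.
    """
    missing = set(activity.obs_ids) - set(map(str, meta.index))
    if missing:
        raise ValueError(f"metadata missing samples: {sorted(missing)[:5]}")
    meta = meta.loc[activity.obs_ids]
    rows = []
    for pi, phenotype in enumerate(phenotypes):
        needed = [phenotype] + [c for c in covariates]
        complete = meta[needed].notna().all(axis=1)
        n_used = int(complete.sum())
        if n_used < 20:
            raise ValueError(
                f"{phenotype}: only {n_used} complete samples (floor: 20)"
            )
        sub_meta = meta[complete]
        X, names = _design_matrix(sub_meta, phenotype, covariates)
        for mi, mid in enumerate(activity.module_ids):
            y = activity.standardized.loc[complete, mid].to_numpy()
            coefs = fit_linear_model(y, X, names)
            lo, hi, p = bootstrap_percentile(
                y, X, coef_pos=1, b_assoc=b_assoc,
                seed=seed + 1000 * pi + mi,
            )
            rows.append({
                "module_id": mid, "phenotype": phenotype,
                "beta": float(coefs[phenotype]), "ci_low": lo, "ci_high": hi,
                "p_boot": p, "n_samples": n_used,
                "covariates": ",".join(names[2:]),
            })
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    for phenotype in phenotypes:
        sel = df["phenotype"] == phenotype
        df.loc[sel, "p_adj"] = bh_adjust(df.loc[sel, "p_boot"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    return df.set_index(["module_id", "phenotype"])


# ---------------------------------------------------------------------------
# activity summaries per cell cluster
# ---------------------------------------------------------------------------

def activity_by_cluster(activity: ModuleActivity, cluster_labels
                        ) -> pd.DataFrame:
    """n / mean / median / quartiles of activity per (module, cluster), plus a
    specificity score: top cluster mean minus runner-up mean, in SD units."""
    labels = pd.Series(cluster_labels)
    missing = set(activity.obs_ids) - set(map(str, labels.index.astype(str)))
    if missing:
        raise ValueError(f"cluster labels missing for: {sorted(missing)[:5]}")
    labels = labels.loc[activity.obs_ids]
    rows = []
    for mid in activity.module_ids:
        act = activity.raw[mid]
        sd = act.std(ddof=0)
        means = act.groupby(labels.to_numpy()).mean().sort_values(ascending=False)
        if len(means) > 1 and sd > 0:
            specificity = float((means.iloc[0] - means.iloc[1]) / sd)
        else:
            specificity = 0.0
        for cl, group in act.groupby(labels.to_numpy()):
            q1, med, q3 = np.percentile(group, [25, 50, 75])
            rows.append({
                "module_id": mid, "cluster": cl, "n": len(group),
                "mean": float(group.mean()), "median": float(med),
                "q1": float(q1), "q3": float(q3),
                "top_cluster": means.index[0], "specificity": specificity,
            })
    return pd.DataFrame(rows).set_index(["module_id", "cluster"])
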