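"""Expression QC, cis-eQTL linear modelling and expression-trait correlation.

The eQTL model is ordinary least squares of (log2-CPM) expression on the
effect-allele dosage plus optional covariates, one (variant, gene) pair at
a time, with Benjamini-Hochberg FDR across all tested pairs within a
tissue.  A positive slope means the effect allele (a1) increases
expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "qc_filter",
    "cpm",
    "cis_pairs",
    "map_eqtls",
    "bh_fdr",
    "trait_correlation",
]

DEFAULT_CIS_WINDOW = 1_000_000
MIN_SAMPLE_READS = 1_000_000


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix for one tissue.

    ``values`` holds raw counts (``is_log=False``) or log2-CPM
    (``is_log=True``).
    """

    tissue: str
    values: pd.DataFrame
    is_log: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    def to_log2_cpm(self) -> "ExpressionMatrix":
        if self.is_log:
            return self
        return ExpressionMatrix(self.tissue, np.log2(cpm(self.values) + 1.0), is_log=True)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: count * 1e6 / sample library size."""
    totals = counts.sum(axis=0)
    return counts * 1e6 / totals


def qc_filter(
    expr: ExpressionMatrix,
    min_reads: int = MIN_SAMPLE_READS,
    cpm_threshold: float = 1.0,
    min_samples: int = 2,
) -> tuple[ExpressionMatrix, dict]:
    """Sample and gene QC on raw counts.

    Samples with library size below ``min_reads`` are dropped first; genes
    are then kept iff CPM > ``cpm_threshold`` in at least ``min_samples``
    of the surviving samples.  Returns the filtered matrix and a report of
    dropped ids.
    """
    if expr.is_log:
        raise ValueError("qc_filter expects raw counts, not log-transformed values")
    counts = expr.values
    totals = counts.sum(axis=0)
    keep_samples = totals >= min_reads
    dropped_samples = list(counts.columns[~keep_samples])
    counts = counts.loc[:, keep_samples]
    if counts.shape[1] == 0:
        raise ValueError("all samples dropped by the library-size filter")
    keep_genes = (cpm(counts) > cpm_threshold).sum(axis=1) >= min_samples
    dropped_genes = list(counts.index[~keep_genes])
    report = {
        "dropped_samples": dropped_samples,
        "dropped_genes": dropped_genes,
        "n_samples_kept": int(keep_samples.sum()),
        "n_genes_kept": int(keep_genes.sum()),
    }
    return ExpressionMatrix(expr.tissue, counts.loc[keep_genes], is_log=False), report


def cis_pairs(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = DEFAULT_CIS_WINDOW,
) -> list[tuple[str, str]]:
    """(variant, gene) pairs with |pos - TSS| <= window on a shared chromosome.

    ``variants`` needs columns rsid/chrom/pos; ``genes`` needs
    gene/chrom/tss.  The window bound is inclusive.
    """
    pairs: list[tuple[str, str]] = []
    for _, v in variants.iterrows():
        near = genes[(genes["chrom"].astype(str) == str(v["chrom"])) & ((genes["tss"] - v["pos"]).abs() <= window)]
        pairs.extend((v["rsid"], g) for g in near["gene"])
    return pairs


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order restored.

    p_adj(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _ols_assoc(y: np.ndarray, g: np.ndarray, covs: np.ndarray | None) -> tuple[float, float, float, float] | None:
    """Slope/SE/t/P of y ~ intercept + g + covs; None when the design is singular.

    Two-sided P from the t distribution with n - p - 2 degrees of freedom
    (p = number of covariates).
    """
    n = y.size
    X = np.column_stack([np.ones(n), g] if covs is None else [np.ones(n), g, covs])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        return None
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    dof = n - X.shape[1]
    if dof <= 0:
        return None
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    if se == 0:
        return None
    t = float(coef[1] / se)
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return float(coef[1]), se, t, max(p, np.nextafter(0.0, 1.0))


def map_eqtls(
    genotypes: pd.DataFrame,
    expr: ExpressionMatrix,
    covariates: pd.DataFrame | None = None,
    pairs: list[tuple[str, str]] | None = None,
    min_samples: int = 10,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """cis-eQTL mapping by per-pair OLS with BH-FDR within the tissue.

    ``genotypes`` is samples x variants (0/1/2 dosage of the effect
    allele); ``expr`` raw counts (auto log2(CPM+1)-transformed) or
    log2-CPM.  ``pairs`` restricts the tested (variant, gene) pairs;
    by default all variants x all genes are tested.  Pairs with constant
    dosage or a collinear design are skipped and logged.

    Returns a DataFrame with columns rsid, gene, tissue, beta, se, t, p,
    fdr, significant — FDR family = all tested pairs within this tissue.
    """
    expr = expr.to_log2_cpm()
    shared = [s for s in genotypes.index if s in expr.values.columns]
    if len(shared) < min_samples:
        raise ValueError(f"only {len(shared)} shared samples; need at least {min_samples}")
    G = genotypes.loc[shared]
    E = expr.values[shared]
    C = covariates.loc[shared].to_numpy(dtype=float) if covariates is not None else None
    if pairs is None:
        pairs = [(v, g) for v in G.columns for g in E.index]

    fast = C is None and not G.isna().any().any()
    rows: list[dict] = []
    if fast:
        # vectorized OLS for the no-covariate, no-missing case
        Gm = G.to_numpy(dtype=float)
        Em = E.to_numpy(dtype=float)
        n = Gm.shape[0]
        gc = Gm - Gm.mean(axis=0)
        ec = Em - Em.mean(axis=1, keepdims=True)
        g_ss = (gc**2).sum(axis=0)
        ok_var = g_ss > 0
        vidx = {v: i for i, v in enumerate(G.columns)}
        gidx = {g: i for i, g in enumerate(E.index)}
        cross = ec @ gc  # genes x variants
        with np.errstate(invalid="ignore", divide="ignore"):
            beta_all = cross / g_ss
            e_ss = (ec**2).sum(axis=1)
            rss = e_ss[:, None] - beta_all * cross
            dof = n - 2
            sigma2 = np.clip(rss, 0.0, None) / dof
            se_all = np.sqrt(sigma2 / g_ss)
            t_all = beta_all / se_all
        p_all = 2.0 * stats.t.sf(np.abs(t_all), dof)
        for rsid, gene in pairs:
            i, j = vidx[rsid], gidx[gene]
            if not ok_var[i] or not np.isfinite(t_all[j, i]):
                logger.info("skipping pair (%s, %s): constant dosage or degenerate fit", rsid, gene)
                continue
            rows.append(
                {"rsid": rsid, "gene": gene, "beta": beta_all[j, i], "se": se_all[j, i],
                 "t": t_all[j, i], "p": max(p_all[j, i], np.nextafter(0.0, 1.0))}
            )
    else:
        for rsid, gene in pairs:
            g = G[rsid].to_numpy(dtype=float)
            y = E.loc[gene].to_numpy(dtype=float)
            mask = ~np.isnan(g) & ~np.isnan(y)
            if C is not None:
                mask &= ~np.isnan(C).any(axis=1)
            if mask.sum() < min_samples:
                logger.info("skipping pair (%s, %s): only %d complete samples", rsid, gene, mask.sum())
                continue
            gm = g[mask]
            if np.ptp(gm) == 0:
                logger.info("skipping pair (%s, %s): constant dosage", rsid, gene)
                continue
            fit = _ols_assoc(y[mask], gm, C[mask] if C is not None else None)
            if fit is None:
                logger.warning("skipping pair (%s, %s): singular design (collinear covariate?)", rsid, gene)
                continue
            beta, se, t, p = fit
            rows.append({"rsid": rsid, "gene": gene, "beta": beta, "se": se, "t": t, "p": p})

    out = pd.DataFrame(rows, columns=["rsid", "gene", "beta", "se", "t", "p"])
    out.insert(2, "tissue", expr.tissue)
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["fdr"] <= fdr_threshold
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def trait_correlation(
    expression: pd.Series,
    traits: pd.DataFrame,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Pearson correlation of one gene's expression with each trait column.

    P values from t = r sqrt(n-2) / sqrt(1-r^2); missing trait entries are
    handled pairwise-complete.  Zero variance in either vector is an error.
    """
    if expression.std(ddof=0) == 0:
        raise ValueError("expression vector has zero variance")
    rows = []
    common = expression.index.intersection(traits.index)
    for trait in traits.columns:
        xv = expression.loc[common]
        yv = traits.loc[common, trait]
        mask = xv.notna() & yv.notna()
        n = int(mask.sum())
        if n < min_samples:
            raise ValueError(f"trait {trait!r}: only {n} complete paired observations (need {min_samples})")
        x, y = xv[mask].to_numpy(float), yv[mask].to_numpy(float)
        if np.ptp(y) == 0:
            raise ValueError(f"trait {trait!r} has zero variance")
        r, _ = stats.pearsonr(x, y)
        if abs(r) < 1.0:
            t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        else:
            t, p = np.inf if r > 0 else -np.inf, 0.0
        rows.append({"trait": trait, "r": float(r), "statistic": float(t), "p": max(p, np.nextafter(0.0, 1.0)), "n": n})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else pd.Series(dtype=float)
    return out
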