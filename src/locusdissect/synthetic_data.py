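"""Synthetic genotype / expression / trait / outcome / accessibility data.

The generator emulates the statistical structure the locus-dissection
analysis assumes, with a known ground truth for recovery tests:

* LD-blocked diploid genotypes from a latent multivariate Gaussian with
  exchangeable within-block correlation, thresholded at MAF-matched
  quantiles.  The latent correlation is calibrated (bivariate-normal
  tetrachoric inversion) so the realized *dosage* correlation matches the
  requested ``within_block_r``.
* per-tissue expression in which exactly one target gene carries a
  cis-eQTL of the planted causal variant in arterial tissues only, on top
  of a module/factor structure shared by blocks of genes;
* a binary outcome whose genetic effect is mediated purely through the
  arterial expression of the target gene (logistic model), plus a trait
  table with one column correlated with target-gene expression and
  pure-noise columns;
* pseudo-bulk accessibility in which one designated peak contains the
  causal variant and co-varies with target-gene group-level expression.

All randomness flows from a single seeded :class:`numpy.random.Generator`
passed down; identical configs (including seed) give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .atac_link import Peak
from .locus_catalog import GeneFeatureSet

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_outcome_and_traits",
    "simulate_accessibility",
    "make_locus_annotation",
    "locus_feature_sets",
    "simulate_study",
    "StudyBundle",
]

#: module id used for genes with no factor structure
UNASSIGNED = "grey"


@dataclass(frozen=True)
class SimConfig:
    """Free parameters of the synthetic study.

    Defaults follow the study design the analysis targets: an eQTL cohort
    of several hundred donors, a GWAS cohort of tens of thousands, a
    ~36-SNP locus in LD blocks, an arterial-only cis-eQTL on one target
    gene and a disease effect mediated through that expression.
    """

    n_samples_eqtl: int = 500
    n_samples_gwas: int = 20_000
    n_variants: int = 36
    ld_block_sizes: tuple[int, ...] = (6, 6, 6, 6, 6, 6)
    within_block_r: float = 0.5
    maf_range: tuple[float, float] = (0.1, 0.4)
    tissues: tuple[str, ...] = ("AOR", "MAM", "LIV", "SKLM")
    arterial_tissues: tuple[str, ...] = ("AOR", "MAM")
    n_genes: int = 60
    causal_variant_index: int = 14
    target_gene_index: int = 0
    decoy_gene_index: int = 1
    eqtl_beta: float = 0.5
    mediated_beta: float = 0.4
    n_modules: int = 2
    module_size: int = 20
    module_loading: float = 0.9
    trait_r: float = 0.3
    outcome_intercept: float = -1.0
    access_r: float = 0.6
    n_groups: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.ld_block_sizes) != self.n_variants:
            raise ValueError("ld_block_sizes must sum to n_variants")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must lie in [0, 1); 1 is a degenerate latent covariance")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.causal_variant_index < self.n_variants):
            raise ValueError("causal_variant_index out of range")
        if not (0 <= self.target_gene_index < self.n_genes):
            raise ValueError("target_gene_index out of range")
        if self.n_modules * self.module_size + 2 > self.n_genes:
            raise ValueError("n_genes too small for the module structure plus target and decoy genes")
        if not set(self.arterial_tissues) <= set(self.tissues):
            raise ValueError("arterial_tissues must be a subset of tissues")
        if not (0 < self.module_loading < 1):
            raise ValueError("module_loading must be in (0, 1)")

    @property
    def variant_ids(self) -> list[str]:
        return [f"rs_sim{i + 1:06d}" for i in range(self.n_variants)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene_sim{i + 1:04d}" for i in range(self.n_genes)]

    def module_assignments(self) -> dict[str, str]:
        """gene -> module id; the target gene loads on the first module."""
        genes = self.gene_ids
        out = {g: UNASSIGNED for g in genes}
        reserved = {self.target_gene_index, self.decoy_gene_index}
        pool = [i for i in range(self.n_genes) if i not in reserved]
        pos = 0
        for m in range(self.n_modules):
            for i in pool[pos : pos + self.module_size]:
                out[genes[i]] = f"factor{m + 1}"
            pos += self.module_size
        out[genes[self.target_gene_index]] = "factor1"
        return out


@dataclass
class SyntheticTruth:
    """Planted ground truth recovered by the acceptance tests."""

    causal_variant: str
    target_gene: str
    eqtl_beta: dict[str, float]
    disease_beta: float
    mediated_beta: float
    module_assignments: dict[str, str]

    def __post_init__(self) -> None:
        for tissue, beta in self.eqtl_beta.items():
            if beta != 0 and self.disease_beta != self.mediated_beta * beta:
                # pure mediation: disease effect = arterial eQTL effect x mediated effect
                raise ValueError("disease_beta inconsistent with pure mediation through arterial expression")


def _sample_ids(n: int, prefix: str = "S") -> list[str]:
    return [f"{prefix}{i + 1:06d}" for i in range(n)]


def _binary_corr(rho: float, p: float) -> float:
    """Correlation of two Bernoulli(p) indicators thresholded from a
    bivariate normal with latent correlation rho (equal thresholds)."""
    c = stats.norm.ppf(p)
    p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([c, c])
    return (p11 - p * p) / (p * (1 - p))


def _latent_rho(target_r: float, p: float) -> float:
    """Latent Gaussian correlation whose thresholded-indicator correlation
    at allele frequency p equals target_r (solved by bisection)."""
    if target_r <= 0:
        return 0.0
    return float(brentq(lambda rho: _binary_corr(rho, p) - target_r, 0.0, 1 - 1e-9, xtol=1e-6))


def simulate_genotypes(
    cfg: SimConfig,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "S",
) -> tuple[pd.DataFrame, list[int]]:
    """Draw LD-blocked diploid dosages.

    Two independent haplotypes per sample are thresholded from a latent
    exchangeable-correlation Gaussian per block; dosage = haplotype sum.
    Returns (samples x variants DataFrame with values {0,1,2}, block index
    per variant).
    """
    n = n_samples if n_samples is not None else cfg.n_samples_eqtl
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    # MAFs are a property of the variants, not of the cohort: derive them
    # from the config seed alone so both cohorts share them.  Variants in
    # one LD block share a MAF — with unequal allele frequencies two
    # binary variants cannot reach a high dosage correlation, so equal
    # within-block frequencies are required for the calibrated LD target.
    maf_rng = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, 0x1D)))
    block_mafs_draw = maf_rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=len(cfg.ld_block_sizes))
    mafs = np.repeat(block_mafs_draw, cfg.ld_block_sizes)
    dosage = np.empty((n, cfg.n_variants), dtype=np.int8)
    block_map: list[int] = []
    col = 0
    for b, size in enumerate(cfg.ld_block_sizes):
        block_map.extend([b] * size)
        block_mafs = mafs[col : col + size]
        rho = _latent_rho(cfg.within_block_r, float(block_mafs.mean()))
        shared = rng.standard_normal((2 * n, 1))
        noise = rng.standard_normal((2 * n, size))
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        alleles = (latent < stats.norm.ppf(block_mafs)[None, :]).astype(np.int8)
        dosage[:, col : col + size] = alleles[:n] + alleles[n:]
        col += size
    return pd.DataFrame(dosage, index=_sample_ids(n, sample_prefix), columns=cfg.variant_ids), block_map


def simulate_expression(
    genotypes: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Per-tissue expression with a module/factor structure and one planted eQTL.

    The target gene is ``eqtl_beta * dosage(causal variant)`` (arterial
    tissues only) plus its module factor plus noise; module genes are
    ``loading * factor + sqrt(1 - loading^2) * noise`` (unit variance);
    remaining genes are independent N(0, 1).  Gene variance is 1 aside
    from the genetic term.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    genes = cfg.gene_ids
    target = genes[cfg.target_gene_index]
    assignments = cfg.module_assignments()
    g_causal = genotypes.iloc[:, cfg.causal_variant_index].to_numpy(dtype=float)
    n = len(genotypes)
    loading = cfg.module_loading
    resid = np.sqrt(1.0 - loading**2)
    tissue_expr: dict[str, pd.DataFrame] = {}
    for tissue in cfg.tissues:
        factors = rng.standard_normal((cfg.n_modules, n))
        X = np.empty((cfg.n_genes, n))
        for j, gene in enumerate(genes):
            mod = assignments[gene]
            if mod == UNASSIGNED:
                X[j] = rng.standard_normal(n)
            else:
                f = factors[int(mod.removeprefix("factor")) - 1]
                X[j] = loading * f + resid * rng.standard_normal(n)
        if tissue in cfg.arterial_tissues:
            X[cfg.target_gene_index] += cfg.eqtl_beta * g_causal
        tissue_expr[tissue] = pd.DataFrame(X, index=genes, columns=genotypes.index)
    truth = SyntheticTruth(
        causal_variant=genotypes.columns[cfg.causal_variant_index],
        target_gene=target,
        eqtl_beta={t: (cfg.eqtl_beta if t in cfg.arterial_tissues else 0.0) for t in cfg.tissues},
        disease_beta=cfg.eqtl_beta * cfg.mediated_beta,
        mediated_beta=cfg.mediated_beta,
        module_assignments=assignments,
    )
    return tissue_expr, truth


def simulate_outcome_and_traits(
    genotypes: pd.DataFrame,
    expression: dict[str, pd.DataFrame],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Binary outcome mediated through arterial target-gene expression.

    outcome ~ Bernoulli(logistic(intercept + mediated_beta * x)) where x
    is the target gene's expression in the first arterial tissue.  The
    trait table has one column ("cad_severity") correlated with x at
    ``cfg.trait_r`` plus pure-noise columns.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    arterial = cfg.arterial_tissues[0]
    expr = expression[arterial]
    if list(expr.columns) != list(genotypes.index):
        raise ValueError("expression and genotype sample ids do not match")
    x = expr.iloc[cfg.target_gene_index].to_numpy(dtype=float)
    eta = cfg.outcome_intercept + cfg.mediated_beta * x
    outcome = pd.Series(
        (rng.uniform(size=len(x)) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8),
        index=genotypes.index,
        name="outcome",
    )
    x_std = (x - x.mean()) / x.std(ddof=0)
    r = cfg.trait_r
    traits = pd.DataFrame(
        {
            "cad_severity": r * x_std + np.sqrt(1.0 - r * r) * rng.standard_normal(len(x)),
            "noise_1": rng.standard_normal(len(x)),
            "noise_2": rng.standard_normal(len(x)),
            "noise_3": rng.standard_normal(len(x)),
        },
        index=genotypes.index,
    )
    return outcome, traits


def make_locus_annotation(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, list[Peak]]:
    """Deterministic genomic layout for the simulated locus.

    Variants sit on chromosome 7 in a ~28 kb window; the target gene's TSS
    is ~120 kb downstream of the locus (cis but not overlapping), the
    decoy gene physically spans the SNPs; all other genes live on another
    chromosome so they are never cis.  Ten 410-bp peaks are placed near
    the locus, one centered on the causal variant.
    """
    start = 19_032_000
    spacing = max(1, 28_000 // max(cfg.n_variants - 1, 1))
    positions = [start + i * spacing for i in range(cfg.n_variants)]
    variants = pd.DataFrame({"rsid": cfg.variant_ids, "chrom": "7", "pos": positions})
    genes = cfg.gene_ids
    rows = []
    for j, gene in enumerate(genes):
        if j == cfg.target_gene_index:
            rows.append({"gene": gene, "chrom": "7", "strand": "-", "tss": positions[-1] + 120_000})
        elif j == cfg.decoy_gene_index:
            rows.append({"gene": gene, "chrom": "7", "strand": "+", "tss": start - 60_000})
        else:
            rows.append({"gene": gene, "chrom": "12", "strand": "+", "tss": 5_000_000 + 10_000 * j})
    genes_df = pd.DataFrame(rows)
    causal_pos = positions[cfg.causal_variant_index]
    peaks = [Peak("7", causal_pos - 205, causal_pos + 205, "peak_causal")]
    for i in range(9):
        s = start - 40_000 + i * 9_000
        peaks.append(Peak("7", s, s + 410, f"peak_{i + 1}"))
    return variants, genes_df, peaks


def locus_feature_sets(cfg: SimConfig, variants: pd.DataFrame, genes_df: pd.DataFrame) -> list[GeneFeatureSet]:
    """Feature intervals for the decoy gene spanning the SNP cluster.

    Mirrors a gene whose final intron and 3'UTR cover the locus: the SNPs
    fall in the intron or the 3'UTR, never in the coding exon; the target
    gene has no intervals near the SNPs (all its SNP annotations are
    intergenic).
    """
    pos = variants["pos"]
    lo, hi = int(pos.min()), int(pos.max())
    mid = (lo + hi) // 2
    decoy = genes_df.iloc[cfg.decoy_gene_index]["gene"]
    intervals = [
        ("intron", lo - 5_000, mid),
        ("coding-exon", mid + 1, mid + 2),
        ("3'UTR", mid + 3, hi + 2_000),
    ]
    # keep SNPs out of the 2-bp token coding exon
    if ((pos == mid + 1) | (pos == mid + 2)).any():
        intervals[1] = ("coding-exon", hi + 2_001, hi + 2_002)
    return [GeneFeatureSet(gene=str(decoy), strand="+", intervals=intervals)]


def simulate_accessibility(
    cfg: SimConfig,
    peaks: list[Peak],
    genes_df: pd.DataFrame,
    causal_pos: int,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Pseudo-bulk accessibility with one peak coupled to the target gene.

    The designated peak is the one containing the (1-based) causal variant
    position — an error if no peak does.  Its accessibility correlates
    with target-gene group-level expression at ``cfg.access_r``; all other
    peaks and genes are independent noise.  Returns (peaks x groups
    accessibility, genes x groups expression, truth dict).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    designated = [p for p in peaks if p.contains_position(causal_pos)]
    if not designated:
        raise ValueError(f"no peak contains the causal variant position {causal_pos} (half-open [start, end))")
    target = cfg.gene_ids[cfg.target_gene_index]
    groups = [f"G{i + 1:03d}" for i in range(cfg.n_groups)]
    locus_genes = genes_df[genes_df["chrom"] == "7"]["gene"].tolist()
    g_target = rng.standard_normal(cfg.n_groups)
    expr = pd.DataFrame(
        rng.standard_normal((len(locus_genes), cfg.n_groups)),
        index=locus_genes,
        columns=groups,
    )
    expr.loc[target] = g_target
    r = cfg.access_r
    acc = pd.DataFrame(
        rng.standard_normal((len(peaks), cfg.n_groups)),
        index=[p.id for p in peaks],
        columns=groups,
    )
    acc.loc[designated[0].id] = r * g_target + np.sqrt(1.0 - r * r) * rng.standard_normal(cfg.n_groups)
    truth = {"linked_peak": designated[0].id, "target_gene": target, "planted_r": r}
    return acc, expr, truth


@dataclass
class StudyBundle:
    """Everything one simulated study produces, ready for the pipeline."""

    cfg: SimConfig
    genotypes_eqtl: pd.DataFrame
    genotypes_gwas: pd.DataFrame
    expression: dict[str, pd.DataFrame]
    traits: pd.DataFrame
    outcome: pd.Series
    variants: pd.DataFrame
    genes: pd.DataFrame
    peaks: list[Peak]
    features: list[GeneFeatureSet]
    accessibility: pd.DataFrame
    group_expression: pd.DataFrame
    truth: SyntheticTruth
    block_map: list[int] = field(default_factory=list)


def simulate_study(cfg: SimConfig) -> StudyBundle:
    """Simulate the full two-cohort study from one seeded generator.

    The eQTL cohort gets genotypes, multi-tissue expression and traits;
    the GWAS cohort gets its own genotypes and a binary outcome mediated
    through its own (latent) arterial expression; shared annotation and
    accessibility complete the bundle.
    """
    rng = np.random.default_rng(cfg.seed)
    geno_eqtl, block_map = simulate_genotypes(cfg, cfg.n_samples_eqtl, rng, sample_prefix="S")
    expr, truth = simulate_expression(geno_eqtl, cfg, rng)
    _, traits = simulate_outcome_and_traits(geno_eqtl, expr, cfg, rng)
    # independent GWAS cohort with the same MAFs/LD law but fresh draws
    geno_gwas, _ = simulate_genotypes(cfg, cfg.n_samples_gwas, rng, sample_prefix="P")
    expr_gwas, _ = simulate_expression(geno_gwas, cfg, rng)
    outcome, _ = simulate_outcome_and_traits(geno_gwas, expr_gwas, cfg, rng)
    variants, genes_df, peaks = make_locus_annotation(cfg)
    features = locus_feature_sets(cfg, variants, genes_df)
    causal_pos = int(variants.iloc[cfg.causal_variant_index]["pos"])
    acc, group_expr, _ = simulate_accessibility(cfg, peaks, genes_df, causal_pos, rng)
    return StudyBundle(
        cfg=cfg,
        genotypes_eqtl=geno_eqtl,
        genotypes_gwas=geno_gwas,
        expression=expr,
        traits=traits,
        outcome=outcome,
        variants=variants,
        genes=genes_df,
        peaks=peaks,
        features=features,
        accessibility=acc,
        group_expression=group_expr,
        truth=truth,
        block_map=block_map,
    )
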