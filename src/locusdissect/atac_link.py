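"""Peak-to-gene accessibility linkage and SNP-peak intersection.

Pseudo-bulk accessibility (peaks x groups) is correlated with group-level
gene expression for (peak, gene) pairs whose peak-center-to-TSS distance
is within a window; links pass an |r| and BH-FDR filter.  GWAS SNPs
(1-based positions) are intersected with peaks (BED convention: 0-based
half-open) — the coordinate conversion is centralized here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .eqtl import bh_fdr
from .locus_catalog import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "read_bed",
    "write_bed",
    "peak2gene",
    "intersect_snps",
    "snp_to_linked_genes",
]

DEFAULT_MAX_DIST = 250_000
DEFAULT_R_MIN = 0.45
DEFAULT_FDR_MAX = 1e-4


@dataclass(frozen=True)
class Peak:
    """An accessibility peak, 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.id}: start must be < end ({self.start} >= {self.end})")

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def contains_position(self, pos_1based: int) -> bool:
        """Containment of a 1-based SNP position (converted to the 0-based point pos-1)."""
        return self.start <= pos_1based - 1 < self.end


def read_bed(path) -> list[Peak]:
    """Read peaks from a BED file (chrom, start, end[, name])."""
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {i + 1}: expected at least 3 fields")
            name = fields[3] if len(fields) > 3 else f"peak_{i + 1}"
            peaks.append(Peak(fields[0], int(fields[1]), int(fields[2]), name))
    return peaks


def write_bed(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\n")


def _tss_from_annotation(genes: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware TSS table from an annotation with gene/chrom/strand/tss."""
    required = {"gene", "chrom", "tss"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene annotation missing column(s): {sorted(missing)}")
    return genes


def peak2gene(
    accessibility: pd.DataFrame,
    expression: pd.DataFrame,
    peaks: list[Peak],
    genes: pd.DataFrame,
    max_dist: int = DEFAULT_MAX_DIST,
    r_min: float = DEFAULT_R_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_groups: int = 20,
) -> pd.DataFrame:
    """Correlate peak accessibility with gene expression across groups.

    ``accessibility`` is peaks x groups, ``expression`` genes x groups
    (pseudo-bulk).  (peak, gene) pairs with peak-center-to-TSS distance <=
    ``max_dist`` on the same chromosome are tested with Pearson r and a
    t-transform P value; BH-FDR is taken over all tested pairs.  A link is
    retained iff |r| >= ``r_min`` and fdr <= ``fdr_max``.  Zero-variance
    peaks or genes are skipped and logged, never reported as r = 0.

    Returns all tested pairs with a boolean ``retained`` column.
    """
    genes = _tss_from_annotation(genes)
    groups = [g for g in accessibility.columns if g in expression.columns]
    if len(groups) < min_groups:
        raise ValueError(f"only {len(groups)} shared groups; need at least {min_groups}")
    acc = accessibility[groups]
    exp = expression[groups]
    peak_by_id = {p.id: p for p in peaks}
    rows = []
    tss = genes.set_index("gene")
    n = len(groups)
    for pid in acc.index:
        peak = peak_by_id.get(pid)
        if peak is None:
            continue
        a = acc.loc[pid].to_numpy(dtype=float)
        if np.ptp(a) == 0:
            logger.info("skipping zero-variance peak %s", pid)
            continue
        for gene in exp.index:
            if gene not in tss.index:
                continue
            grow = tss.loc[gene]
            if str(grow["chrom"]) != peak.chrom:
                continue
            dist = abs(peak.center - float(grow["tss"]))
            if dist > max_dist:
                continue
            e = exp.loc[gene].to_numpy(dtype=float)
            if np.ptp(e) == 0:
                logger.info("skipping zero-variance gene %s", gene)
                continue
            r, _ = stats.pearsonr(a, e)
            if abs(r) < 1.0:
                t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
                p = float(2.0 * stats.t.sf(abs(t), n - 2))
            else:
                p = 0.0
            rows.append({"peak": pid, "gene": gene, "r": float(r), "p": max(p, np.nextafter(0.0, 1.0)), "distance": float(dist)})
    links = pd.DataFrame(rows, columns=["peak", "gene", "r", "p", "distance"])
    if len(links):
        links["fdr"] = bh_fdr(links["p"].to_numpy())
        links["retained"] = (links["r"].abs() >= r_min) & (links["fdr"] <= fdr_max)
    else:
        links["fdr"] = pd.Series(dtype=float)
        links["retained"] = pd.Series(dtype=bool)
    return links


def intersect_snps(records: list[VariantRecord], peaks: list[Peak]) -> dict[str, list[Peak]]:
    """Map each SNP to every peak containing it.

    A SNP at 1-based position p corresponds to the 0-based point p-1 and
    is contained iff start <= p-1 < end.  Peaks may overlap; an empty
    result is valid.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    out: dict[str, list[Peak]] = {}
    for rec in records:
        tree = trees.get(rec.chrom)
        hits = [iv.data for iv in tree[rec.pos - 1]] if tree is not None else []
        out[rec.rsid] = sorted(hits, key=lambda p: (p.start, p.end, p.id))
    return out


def snp_to_linked_genes(
    records: list[VariantRecord],
    links: pd.DataFrame,
    intersections: dict[str, list[Peak]],
) -> dict[str, dict[str, float]]:
    """Compose SNP-peak intersections with peak-gene links.

    Returns {rsid: {gene: best |r|-signed correlation}} over retained
    links; a gene linked through several containing peaks is listed once
    with the strongest-|r| link.
    """
    retained = links[links["retained"]] if "retained" in links.columns else links
    by_peak: dict[str, list[tuple[str, float]]] = {}
    for _, row in retained.iterrows():
        by_peak.setdefault(row["peak"], []).append((row["gene"], float(row["r"])))
    out: dict[str, dict[str, float]] = {}
    for rec in records:
        best: dict[str, float] = {}
        for peak in intersections.get(rec.rsid, []):
            for gene, r in by_peak.get(peak.id, []):
                if gene not in best or abs(r) > abs(best[gene]):
                    best[gene] = r
        out[rec.rsid] = best
    return out
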