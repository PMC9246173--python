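"""GWAS locus catalogue: parsing, LD, lead SNP, span, and feature annotation.

The unit of analysis is a locus table of summary statistics — one row per
SNP with effect allele (a1), other allele (a2), log-odds beta, its standard
error and the association P value.  Positions are 1-based base-pair
coordinates written ``chrom:pos`` (BED conversion lives in
:mod:`locusdissect.atac_link`).
"""

from __future__ import annotations

import importlib.resources
import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "LDMatrix",
    "GeneFeatureSet",
    "SchemaError",
    "parse_locus_table",
    "write_locus_table",
    "load_hdac9_table",
    "compute_ld",
    "lead_snp",
    "locus_span",
    "wald_p",
    "log_wald_p",
    "annotate_snp",
]

REQUIRED_COLUMNS = ("rsid", "position", "a1", "a2", "beta", "se", "pvalue")

#: priority order used by :func:`annotate_snp`
FEATURE_PRIORITY = ("coding-exon", "5'UTR", "3'UTR", "intron")
FEATURE_TYPES = frozenset(FEATURE_PRIORITY)


class SchemaError(ValueError):
    """Raised when a locus table does not conform to the expected schema."""


@dataclass(frozen=True)
class VariantRecord:
    """One GWAS summary-statistics row.

    ``beta`` is the log-odds per copy of ``a1`` (the effect allele);
    ``pos`` is 1-based.
    """

    rsid: str
    chrom: str
    pos: int
    a1: str
    a2: str
    beta: float
    se: float
    pvalue: float
    traits: tuple[str, ...] = ()
    n: int | None = None
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.rsid}: pvalue must be in (0,1], got {self.pvalue}")
        if self.a1 == self.a2:
            raise ValueError(f"{self.rsid}: alleles a1 and a2 must differ")
        if self.pos <= 0:
            raise ValueError(f"{self.rsid}: pos must be positive, got {self.pos}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.rsid}: eaf must be in (0,1), got {self.eaf}")

    @property
    def z(self) -> float:
        return self.beta / self.se


_P_CLEAN = re.compile(r"\s*[x×]\s*10\^?", re.IGNORECASE)


def _parse_number(text: object) -> float:
    """Parse a numeric field, accepting scientific notation variants.

    Handles plain floats, ``1.25e-24``, ``1.25 x 10-24``, ``1.25 x 10^-24``
    and the unicode minus sign.
    """
    if isinstance(text, (int, float, np.integer, np.floating)):
        return float(text)
    s = str(text).strip().replace("−", "-").replace(" ", "")
    s = _P_CLEAN.sub("e", s)
    return float(s)


def parse_locus_table(path) -> list[VariantRecord]:
    """Read a locus TSV into validated :class:`VariantRecord` objects.

    Required columns: ``rsid``, ``position`` (``chrom:pos``), ``a1``,
    ``a2``, ``beta``, ``se``, ``pvalue``; optional ``trait``, ``n``,
    ``eaf``.  Row order is preserved; duplicate rsids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"locus table is missing required column(s): {', '.join(missing)}")
    dup = df["rsid"][df["rsid"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate rsid(s) in locus table: {', '.join(dup.unique())}")
    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            chrom, _, pos = str(row["position"]).partition(":")
            if not pos:
                raise ValueError(f"position {row['position']!r} is not 'chrom:pos'")
            traits = tuple(t.strip() for t in str(row["trait"]).split(",")) if "trait" in df.columns and pd.notna(row.get("trait")) else ()
            records.append(
                VariantRecord(
                    rsid=str(row["rsid"]).strip(),
                    chrom=chrom.strip(),
                    pos=int(pos),
                    a1=str(row["a1"]).strip(),
                    a2=str(row["a2"]).strip(),
                    beta=_parse_number(row["beta"]),
                    se=_parse_number(row["se"]),
                    pvalue=_parse_number(row["pvalue"]),
                    traits=traits,
                    n=int(row["n"]) if "n" in df.columns and pd.notna(row.get("n")) else None,
                    eaf=_parse_number(row["eaf"]) if "eaf" in df.columns and pd.notna(row.get("eaf")) else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"locus table line {line_no}: {exc}") from exc
    return records


def write_locus_table(records: list[VariantRecord], path) -> None:
    """Write records back to the TSV schema read by :func:`parse_locus_table`."""
    rows = []
    for r in records:
        rows.append(
            {
                "rsid": r.rsid,
                "position": f"{r.chrom}:{r.pos}",
                "a1": r.a1,
                "a2": r.a2,
                "beta": np.format_float_positional(r.beta, trim="-"),
                "se": np.format_float_positional(r.se, trim="-"),
                "pvalue": np.format_float_scientific(r.pvalue, trim="-"),
                "trait": ",".join(r.traits),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_hdac9_table() -> list[VariantRecord]:
    """Load the packaged 36-SNP catalogue for the HDAC9/TWIST1 CAD risk locus."""
    ref = importlib.resources.files("locusdissect") / "data" / "hdac9_locus_snps.tsv"
    with importlib.resources.as_file(ref) as path:
        return parse_locus_table(path)


@dataclass
class LDMatrix:
    """Signed composite LD (dosage correlation) between variants."""

    ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {m} ids")
        finite = np.isfinite(self.r)
        if not np.allclose(self.r[finite], self.r.T[finite.T], atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r)[np.isfinite(np.diag(self.r))], 1.0, atol=1e-12):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r[finite]) > 1 + 1e-12):
            raise ValueError("|r| must be <= 1")

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def subset(self, ids: list[str]) -> "LDMatrix":
        idx = [self.ids.index(i) for i in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


def compute_ld(genotypes: pd.DataFrame, variant_ids: list[str] | None = None, min_pairs: int = 30) -> LDMatrix:
    """Pairwise-complete Pearson correlation of dosage vectors (composite LD).

    ``genotypes`` is samples x variants with values 0/1/2 or NaN.
    Monomorphic variants or pairs with fewer than ``min_pairs`` complete
    observations (when any dosage is missing) yield NaN entries and a
    warning — never a silent 0.
    """
    if variant_ids is not None:
        genotypes = genotypes[variant_ids]
    ids = list(genotypes.columns)
    X = genotypes.to_numpy(dtype=float)
    m = X.shape[1]
    mono = np.nanstd(X, axis=0) == 0
    if mono.any():
        bad = [ids[i] for i in np.flatnonzero(mono)]
        warnings.warn(f"monomorphic variant(s) with undefined LD: {', '.join(bad)}", stacklevel=2)
    if np.isnan(X).any():
        r = genotypes.corr(min_periods=min_pairs).to_numpy()
        n_pairs = (~np.isnan(X[:, :, None]) & ~np.isnan(X[:, None, :])).sum(axis=0)
        if (n_pairs < min_pairs).any():
            warnings.warn("some variant pairs have fewer complete observations than min_pairs; entries set to NaN", stacklevel=2)
    else:
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples to compute LD")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X, rowvar=False)
    r = np.asarray(r, dtype=float).reshape(m, m)
    r[mono, :] = np.nan
    r[:, mono] = np.nan
    np.fill_diagonal(r, np.where(mono, np.nan, 1.0))
    # numerical guard: clip rounding excursions beyond +-1
    r = np.clip(r, -1.0, 1.0)
    out = LDMatrix(ids, r)
    return out


def lead_snp(records: list[VariantRecord]) -> VariantRecord:
    """The variant with the smallest P value.

    Ties are broken by larger |beta|/se, then lexicographic rsid.
    """
    if not records:
        raise ValueError("cannot select a lead SNP from an empty record list")
    return min(records, key=lambda r: (r.pvalue, -abs(r.z), r.rsid))


def locus_span(records: list[VariantRecord]) -> int:
    """Inclusive bp span of the locus: max(pos) - min(pos) + 1."""
    if not records:
        raise ValueError("empty record list")
    chroms = {r.chrom for r in records}
    if len(chroms) > 1:
        raise ValueError(f"records span multiple chromosomes: {sorted(chroms)}")
    positions = [r.pos for r in records]
    return max(positions) - min(positions) + 1


def log_wald_p(beta: float, se: float) -> float:
    """Natural log of the two-sided Wald P value, stable for large |z|."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    z = abs(beta / se)
    if not np.isfinite(z):
        raise ValueError("non-finite z score")
    return float(np.log(2.0) + stats.norm.logsf(z))


def wald_p(beta: float, se: float) -> float:
    """Two-sided Wald P value, 2*Phi(-|beta/se|), computed in log space.

    Values below double precision are floored at the smallest positive
    double so the result stays positive for |z| up to 40; use
    :func:`log_wald_p` when that precision matters.
    """
    p = float(np.exp(log_wald_p(beta, se)))
    return max(p, np.nextafter(0.0, 1.0))


@dataclass
class GeneFeatureSet:
    """Typed gene feature intervals (1-based, inclusive ends)."""

    gene: str
    strand: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for kind, start, end in self.intervals:
            if kind not in FEATURE_TYPES:
                raise ValueError(f"unknown feature type {kind!r}; expected one of {sorted(FEATURE_TYPES)}")
            if end < start:
                raise ValueError(f"negative-length interval {kind} [{start}, {end}]")


def annotate_snp(record: VariantRecord, features: list[GeneFeatureSet]) -> tuple[str, str]:
    """Label a SNP by the gene feature containing it.

    Returns ``(gene, feature-type)`` for the highest-priority containing
    interval (coding-exon > UTR > intron), or ``("", "intergenic")`` when
    no interval contains the position.  Interval ends are inclusive.
    """
    best: tuple[int, str, str] | None = None
    for fs in features:
        for kind, start, end in fs.intervals:
            if start <= record.pos <= end:
                rank = FEATURE_PRIORITY.index(kind)
                if best is None or rank < best[0]:
                    best = (rank, fs.gene, kind)
    if best is None:
        return ("", "intergenic")
    return (best[1], best[2])
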