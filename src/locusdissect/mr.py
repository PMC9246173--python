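"""Two-sample Mendelian randomization of gene expression on disease.

Per-variant Wald ratios (outcome effect / exposure effect) with
delta-method standard errors, fixed-effect inverse-variance-weighted
combination, allele harmonization between the exposure and outcome
summary statistics, and the HEIDI test for heterogeneity among LD-linked
instruments (heterogeneity suggests linkage with a separate causal
variant rather than a single shared one).

Also provides :func:`logistic_assoc`, a vectorized per-variant logistic
regression used to produce variant -> binary-outcome summary statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .locus_catalog import LDMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet",
    "MrResult",
    "WeakInstrumentError",
    "wald_ratio",
    "ivw",
    "heidi",
    "mr_with_heidi",
    "harmonize",
    "logistic_assoc",
]

DEFAULT_INSTRUMENT_Z = 3.0
HEIDI_R2_MIN = 0.05
HEIDI_R2_MAX = 0.9
#: exposure chi-square threshold for HEIDI instrument eligibility
HEIDI_Z2_MIN = 10.0
PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class WeakInstrumentError(ValueError):
    """Raised when an instrument's exposure association is too weak to use."""


@dataclass
class InstrumentSet:
    """Allele-harmonized per-variant exposure and outcome effects."""

    ids: list[str]
    b_zx: np.ndarray
    se_zx: np.ndarray
    b_zy: np.ndarray
    se_zy: np.ndarray
    ld: LDMatrix | None = None

    def __post_init__(self) -> None:
        for name in ("b_zx", "se_zx", "b_zy", "se_zy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        m = len(self.ids)
        if not all(getattr(self, a).shape == (m,) for a in ("b_zx", "se_zx", "b_zy", "se_zy")):
            raise ValueError("effect arrays must match the number of instrument ids")
        if np.any(self.se_zx <= 0) or np.any(self.se_zy <= 0):
            raise ValueError("standard errors must be positive")
        if self.ld is not None and list(self.ld.ids) != list(self.ids):
            self.ld = self.ld.subset(list(self.ids))

    @property
    def top_index(self) -> int:
        """Index of the instrument with the strongest exposure association."""
        return int(np.argmax((self.b_zx / self.se_zx) ** 2))

    def subset(self, idx) -> "InstrumentSet":
        idx = list(idx)
        return InstrumentSet(
            ids=[self.ids[i] for i in idx],
            b_zx=self.b_zx[idx],
            se_zx=self.se_zx[idx],
            b_zy=self.b_zy[idx],
            se_zy=self.se_zy[idx],
            ld=self.ld.subset([self.ids[i] for i in idx]) if self.ld is not None else None,
        )


@dataclass
class MrResult:
    estimate: float
    se: float
    pvalue: float
    method: str
    n_variants: int
    heidi_p: float | None = None
    heidi_n_snps: int | None = None

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        half = stats.norm.ppf(0.5 + level / 2) * self.se
        return (self.estimate - half, self.estimate + half)


def wald_ratio(
    b_zx: float,
    se_zx: float,
    b_zy: float,
    se_zy: float,
    z_min: float = DEFAULT_INSTRUMENT_Z,
) -> tuple[float, float]:
    """Per-variant causal-effect ratio b_zy / b_zx with delta-method SE.

    se^2 = se_zy^2 / b_zx^2 + b_zy^2 se_zx^2 / b_zx^4.  Instruments with
    |b_zx|/se_zx below ``z_min`` are refused (the ratio would blow up).
    """
    if se_zx <= 0 or se_zy <= 0:
        raise ValueError("standard errors must be positive")
    if abs(b_zx) / se_zx < z_min:
        raise WeakInstrumentError(
            f"instrument strength |b_zx|/se_zx = {abs(b_zx) / se_zx:.2f} is below the z >= {z_min} threshold"
        )
    b_xy = b_zy / b_zx
    var = se_zy**2 / b_zx**2 + b_zy**2 * se_zx**2 / b_zx**4
    return float(b_xy), float(np.sqrt(var))


def ivw(instruments: InstrumentSet, z_min: float = DEFAULT_INSTRUMENT_Z) -> MrResult:
    """Fixed-effect inverse-variance-weighted combination of Wald ratios.

    With a single valid instrument this is exactly the Wald ratio.
    Instruments below the strength threshold are dropped (logged); having
    none is an error.
    """
    ratios, variances, used = [], [], []
    for i, rsid in enumerate(instruments.ids):
        try:
            b, se = wald_ratio(instruments.b_zx[i], instruments.se_zx[i], instruments.b_zy[i], instruments.se_zy[i], z_min)
        except WeakInstrumentError:
            logger.info("dropping weak instrument %s", rsid)
            continue
        ratios.append(b)
        variances.append(se * se)
        used.append(rsid)
    if not ratios:
        raise WeakInstrumentError("no instruments pass the strength threshold")
    w = 1.0 / np.asarray(variances)
    est = float(np.sum(w * np.asarray(ratios)) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(est) / se)) if est != 0 else 1.0
    return MrResult(
        estimate=est,
        se=se,
        pvalue=max(p, np.nextafter(0.0, 1.0)),
        method="ivw" if len(used) > 1 else "ratio",
        n_variants=len(used),
    )


def heidi(
    instruments: InstrumentSet,
    z2_min: float = HEIDI_Z2_MIN,
    r2_min: float = HEIDI_R2_MIN,
    r2_max: float = HEIDI_R2_MAX,
) -> tuple[float | None, int]:
    """HEIDI heterogeneity test among LD-linked instruments.

    The top instrument (largest exposure chi-square) is the reference.
    Eligible instruments have exposure z^2 >= ``z2_min`` and LD r^2 to the
    top within [``r2_min``, ``r2_max``].  For each, d_i = b_xy(i) -
    b_xy(top); the covariance of d propagates the LD correlation of the
    z-scores through the delta method, and T = sum d_i^2 / Var(d_i) is
    referred to a weighted sum of 1-df chi-squares (eigenvalues of the
    correlation of the standardized d) via the Satterthwaite two-moment
    approximation.  A small P indicates heterogeneity — linkage rather
    than a single shared causal variant.

    Returns (p, n_snps_used); p is None with fewer than 3 eligible
    instruments (test not evaluated).
    """
    if instruments.ld is None:
        raise ValueError("HEIDI requires an LD matrix for the instruments")
    top = instruments.top_index
    z2 = (instruments.b_zx / instruments.se_zx) ** 2
    r_top = instruments.ld.r[top]
    eligible = [
        i
        for i in range(len(instruments.ids))
        if i != top and z2[i] >= z2_min and r2_min <= r_top[i] ** 2 <= r2_max and np.isfinite(r_top[i])
    ]
    n_used = len(eligible) + 1
    if len(eligible) < 2:  # need >= 3 instruments including the top
        return None, n_used
    sel = [top] + eligible
    bx, sx = instruments.b_zx[sel], instruments.se_zx[sel]
    by, sy = instruments.b_zy[sel], instruments.se_zy[sel]
    R = instruments.ld.r[np.ix_(sel, sel)]
    b_xy = by / bx
    d = b_xy[1:] - b_xy[0]

    # delta-method covariance of the ratios: cor(z_i, z_j) = r_ij on both
    # the exposure and outcome sides (independent samples)
    cov_ratio = R * np.outer(sy / bx, sy / bx) + R * np.outer(by * sx / bx**2, by * sx / bx**2)
    k = len(sel) - 1
    cov_d = cov_ratio[1:, 1:] - cov_ratio[1:, [0]] - cov_ratio[[0], 1:] + cov_ratio[0, 0]
    var_d = np.diag(cov_d).copy()
    T = float(np.sum(d**2 / var_d))
    corr_d = cov_d / np.sqrt(np.outer(var_d, var_d))
    eigvals = np.clip(np.linalg.eigvalsh((corr_d + corr_d.T) / 2), 0.0, None)
    s1, s2 = eigvals.sum(), float(np.sum(eigvals**2))
    if s1 <= 0 or s2 <= 0:
        return 1.0, n_used
    scale = s2 / s1
    dof = s1 * s1 / s2
    p = float(stats.chi2.sf(T / scale, dof))
    return max(p, np.nextafter(0.0, 1.0)), n_used


def mr_with_heidi(instruments: InstrumentSet, z_min: float = DEFAULT_INSTRUMENT_Z) -> MrResult:
    """IVW estimate annotated with the HEIDI test when evaluable."""
    res = ivw(instruments, z_min=z_min)
    if instruments.ld is not None and len(instruments.ids) >= 3:
        p_h, n_h = heidi(instruments)
        res.heidi_p = p_h
        res.heidi_n_snps = n_h if p_h is not None else None
    return res


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame, ld: LDMatrix | None = None) -> InstrumentSet:
    """Align outcome effects to the exposure effect allele.

    Both frames need columns rsid, a1, a2, beta, se (a1 = effect allele).
    Outcome betas are flipped when its alleles are swapped relative to the
    exposure; strand-ambiguous A/T and C/G variants are dropped with a
    warning; irreconcilable allele pairs are an error.
    """
    exp = exposure.set_index("rsid")
    out = outcome.set_index("rsid")
    shared = [r for r in exp.index if r in out.index]
    ids, bzx, szx, bzy, szy = [], [], [], [], []
    for rsid in shared:
        e, o = exp.loc[rsid], out.loc[rsid]
        ea = {str(e["a1"]).upper(), str(e["a2"]).upper()}
        if ea in PALINDROMIC:
            warnings.warn(f"dropping strand-ambiguous variant {rsid} ({e['a1']}/{e['a2']})", stacklevel=2)
            continue
        flip: bool
        if (e["a1"], e["a2"]) == (o["a1"], o["a2"]):
            flip = False
        elif (e["a1"], e["a2"]) == (o["a2"], o["a1"]):
            flip = True
        else:
            raise ValueError(
                f"{rsid}: alleles {o['a1']}/{o['a2']} in the outcome cannot be reconciled with {e['a1']}/{e['a2']}"
            )
        ids.append(rsid)
        bzx.append(float(e["beta"]))
        szx.append(float(e["se"]))
        bzy.append(-float(o["beta"]) if flip else float(o["beta"]))
        szy.append(float(o["se"]))
    return InstrumentSet(
        ids=ids,
        b_zx=np.array(bzx),
        se_zx=np.array(szx),
        b_zy=np.array(bzy),
        se_zy=np.array(szy),
        ld=ld.subset(ids) if ld is not None else None,
    )


def logistic_assoc(
    genotypes: pd.DataFrame,
    outcome: pd.Series,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Marginal logistic regression of a binary outcome on each variant.

    Newton-Raphson on the model logit P(y=1) = a + b*dosage, run for all
    variants simultaneously (vectorized across columns).  Returns a
    DataFrame with columns rsid, beta, se, z, p.
    """
    shared = genotypes.index.intersection(outcome.index)
    if len(shared) != len(genotypes.index) or len(shared) != len(outcome.index):
        raise ValueError("genotype and outcome sample ids do not match")
    G = genotypes.loc[shared].to_numpy(dtype=float)
    y = outcome.loc[shared].to_numpy(dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary 0/1")
    n, m = G.shape
    a = np.full(m, np.log(y.mean() / (1 - y.mean())))
    b = np.zeros(m)
    for _ in range(max_iter):
        eta = a[None, :] + G * b[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu
        # per-variant 2x2 Fisher information and score
        s0 = resid.sum(axis=0)
        s1 = (resid * G).sum(axis=0)
        i00 = w.sum(axis=0)
        i01 = (w * G).sum(axis=0)
        i11 = (w * G * G).sum(axis=0)
        det = i00 * i11 - i01 * i01
        da = (i11 * s0 - i01 * s1) / det
        db = (-i01 * s0 + i00 * s1) / det
        a += da
        b += db
        if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < tol:
            break
    eta = a[None, :] + G * b[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    i00 = w.sum(axis=0)
    i01 = (w * G).sum(axis=0)
    i11 = (w * G * G).sum(axis=0)
    det = i00 * i11 - i01 * i01
    se = np.sqrt(i00 / det)
    z = b / se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0.0, 1.0))
    return pd.DataFrame({"rsid": genotypes.columns, "beta": b, "se": se, "z": z, "p": p})
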