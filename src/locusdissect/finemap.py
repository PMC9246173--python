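"""Summary-statistics fine-mapping.

Two complementary models:

* a single-causal-variant model using Wakefield's approximate Bayes factor
  (ABF) per variant, giving posterior inclusion probabilities (PIPs) and a
  credible set;
* exhaustive enumeration of causal configurations of size up to ``k_max``
  under a joint multivariate-normal model of the z-scores given the LD
  matrix, giving PIPs plus a posterior over the number of causal variants
  (the quantity behind statements like "probability the locus contains one
  true causal variant").

Everything is computed in log space; no raw Bayes-factor products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from .locus_catalog import LDMatrix, VariantRecord

__all__ = [
    "FinemapPrior",
    "FinemapResult",
    "abf",
    "single_causal_pips",
    "enumerate_configs",
]

MAX_ENUM_VARIANTS = 64


@dataclass
class FinemapPrior:
    """Priors for the fine-mapping models.

    W
        prior variance of the causal effect on the beta (log-odds) scale,
        used by the single-causal ABF.  Default 0.04 = SD 0.2, conventional
        for binary traits.
    s2
        prior variance of the standardized (z-scale) joint effects in the
        configuration model; scalar or per-variant vector.  Default 25
        (prior z-SD 5, appropriate for genome-wide-significant loci).
    p_causal
        per-variant prior causal probability; ``None`` means 1/m.
    k_max
        largest configuration size enumerated (<= 3).
    """

    W: float = 0.04
    s2: float | np.ndarray = 25.0
    p_causal: float | None = None
    k_max: int = 2

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError("W must be positive")
        if np.any(np.asarray(self.s2) <= 0):
            raise ValueError("s2 must be positive")
        if self.p_causal is not None and not (0 < self.p_causal < 1):
            raise ValueError("p_causal must be in (0,1)")
        if not (1 <= self.k_max <= 3):
            raise ValueError("k_max must be in {1, 2, 3}")


@dataclass
class FinemapResult:
    ids: list[str]
    z: np.ndarray
    pip: np.ndarray
    credible_set: list[str]
    coverage: float
    log_abf: np.ndarray | None = None
    k_posterior: np.ndarray | None = None  # index j = P(exactly j causal variants)
    config_posterior: dict[tuple[int, ...], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any((self.pip < -1e-12) | (self.pip > 1 + 1e-12)):
            raise ValueError("PIPs must lie in [0, 1]")
        if self.k_posterior is not None and abs(self.k_posterior.sum() - 1.0) > 1e-8:
            raise ValueError("posterior over the number of causal variants must sum to 1")


def abf(z: float, se: float, W: float) -> float:
    """Log approximate Bayes factor (alternative vs null) for one variant.

    ``log ABF = 1/2 log(V/(V+W)) + W z^2 / (2 (V+W))`` with V = se^2.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if W <= 0:
        raise ValueError("W must be positive")
    if not np.isfinite(z):
        raise ValueError("non-finite z score")
    V = se * se
    return float(0.5 * np.log(V / (V + W)) + (W * z * z) / (2.0 * (V + W)))


def _credible_set(ids: list[str], pip: np.ndarray, coverage: float) -> list[str]:
    """Smallest prefix of PIP-sorted variants reaching cumulative coverage.

    Sorting is by descending PIP with rsid as the tie-break.
    """
    order = sorted(range(len(ids)), key=lambda i: (-pip[i], ids[i]))
    cum = 0.0
    members: list[str] = []
    total = pip.sum()
    target = min(coverage, total)
    for i in order:
        members.append(ids[i])
        cum += pip[i]
        if cum >= target - 1e-12:
            break
    return members


def single_causal_pips(
    records: list[VariantRecord],
    W: float = 0.04,
    coverage: float = 0.95,
) -> FinemapResult:
    """PIPs and credible set under the single-causal-variant ABF model.

    PIP_i = ABF_i / sum_j ABF_j, evaluated with log-sum-exp.
    """
    if not records:
        raise ValueError("no variant records supplied")
    ids = [r.rsid for r in records]
    z = np.array([r.z for r in records])
    labf = np.array([abf(r.z, r.se, W) for r in records])
    pip = np.exp(labf - logsumexp(labf))
    pip /= pip.sum()
    return FinemapResult(
        ids=ids,
        z=z,
        pip=pip,
        credible_set=_credible_set(ids, pip, coverage),
        coverage=coverage,
        log_abf=labf,
    )


def _config_log_bf(z: np.ndarray, R: np.ndarray, idx: tuple[int, ...], s2: np.ndarray) -> float:
    """log BF of configuration C vs the null, via the matrix identities.

    The alternative covariance is R + R_{.C} S R_{C.} with S = diag(s2_C),
    so by the determinant lemma and Woodbury only the |C| x |C| block
    enters:

        log BF = -1/2 log det(I + S R_CC) + 1/2 z_C' (S^-1 + R_CC)^-1 z_C
    """
    C = list(idx)
    Rcc = R[np.ix_(C, C)]
    S = np.diag(s2[C])
    k = len(C)
    sign, logdet = np.linalg.slogdet(np.eye(k) + S @ Rcc)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-positive determinant in configuration model")
    zc = z[C]
    quad = zc @ np.linalg.solve(np.diag(1.0 / s2[C]) + Rcc, zc)
    return float(-0.5 * logdet + 0.5 * quad)


def enumerate_configs(
    z: np.ndarray,
    ld: LDMatrix | np.ndarray,
    prior: FinemapPrior | None = None,
    coverage: float = 0.95,
    ridge: float = 1e-4,
) -> FinemapResult:
    """Exhaustive small-k fine-mapping over causal configurations.

    For each configuration C with |C| <= k_max the Bayes factor against
    the null is the ratio of multivariate-normal densities of the observed
    z-scores; the configuration prior is p_causal^|C| (1-p_causal)^(m-|C|).
    Returns per-variant PIPs (sum of posterior over configurations
    containing the variant) and the posterior over the number of causal
    variants.
    """
    prior = prior or FinemapPrior()
    if isinstance(ld, LDMatrix):
        ids = list(ld.ids)
        R = ld.r.copy()
    else:
        R = np.asarray(ld, dtype=float).copy()
        ids = [f"v{i}" for i in range(R.shape[0])]
    z = np.asarray(z, dtype=float)
    m = z.size
    if m > MAX_ENUM_VARIANTS:
        raise ValueError(f"enumeration guard: {m} variants exceeds the {MAX_ENUM_VARIANTS}-variant limit")
    if R.shape != (m, m):
        raise ValueError("LD matrix shape does not match the z vector")
    R = R + ridge * np.eye(m)
    # positive-definiteness check with eigenvalue-clipping fallback
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((R + R.T) / 2)
        if np.all(w < 1e-6):
            raise np.linalg.LinAlgError("LD matrix singular even after ridge regularization; increase the ridge")
        R = (V * np.clip(w, 1e-6, None)) @ V.T
    s2 = np.broadcast_to(np.asarray(prior.s2, dtype=float), (m,)).copy()
    p_c = prior.p_causal if prior.p_causal is not None else 1.0 / m
    log_pc, log_q = np.log(p_c), np.log1p(-p_c)

    configs: list[tuple[int, ...]] = [()]
    log_post = [m * log_q]  # null configuration: log BF = 0
    for k in range(1, prior.k_max + 1):
        log_prior_k = k * log_pc + (m - k) * log_q
        for idx in combinations(range(m), k):
            configs.append(idx)
            log_post.append(_config_log_bf(z, R, idx, s2) + log_prior_k)
    log_post = np.array(log_post)
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)
    post /= post.sum()

    pip = np.zeros(m)
    k_post = np.zeros(prior.k_max + 1)
    for c, p in zip(configs, post):
        k_post[len(c)] += p
        for i in c:
            pip[i] += p
    pip = np.clip(pip, 0.0, 1.0)
    return FinemapResult(
        ids=ids,
        z=z,
        pip=pip,
        credible_set=_credible_set(ids, pip, coverage),
        coverage=coverage,
        k_posterior=k_post,
        config_posterior={c: float(p) for c, p in zip(configs, post)},
    )
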