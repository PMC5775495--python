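"""Population divergence and QC statistics.

Implements the Weir & Cockerham (1984) two-population diploid F_ST
estimator from its variance components, per-site observed-heterozygosity
screening (a paralog collapse diagnostic), greedy windowed LD pruning on
genotype correlations, and a convenience PCA with Patterson scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, AnalysisError, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    """Weir-Cockerham variance components and theta.

    ``a`` (among populations), ``b`` (among individuals within
    populations) and ``c`` (within individuals) are per-site; the
    multi-locus estimate is the ratio of sums
    ``theta_global = sum(a) / sum(a + b + c)``, the standard
    combination, not a mean of per-site ratios.  Sites whose total
    variance is zero are excluded from both sums.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta_site: np.ndarray
    theta_global: float
    n_sites_used: int


def _resolve_samples(pm: PopulationMap | None, pop) -> list[str]:
    if isinstance(pop, str):
        if pm is None:
            raise ValueError("population label given but no population map")
        samples = pm.samples_in(pop)
        if not samples:
            raise ValueError(f"population {pop!r} has no samples")
        return samples
    return list(pop)


def wc_fst(
    gm: GenotypeMatrix,
    pm: PopulationMap | None,
    popA,
    popB,
    min_maf: float = 0.05,
    min_ind: int = 3,
) -> FstResult:
    """Weir-Cockerham F_ST between two populations.

    ``popA``/``popB`` are population labels (resolved through ``pm``) or
    explicit sample-id lists; they must be disjoint.  Sites are used
    only if the pooled minor-allele frequency is ``>= min_maf`` and each
    population has ``>= min_ind`` non-missing genotypes (inclusive
    bounds, unlike the strict global site filter).  Observed
    heterozygosity enters the within-individual component, so the
    estimator does not assume Hardy-Weinberg within populations.

    Raises
    ------
    AnalysisError
        If no site passes the filters.
    """
    sA = _resolve_samples(pm, popA)
    sB = _resolve_samples(pm, popB)
    if set(sA) & set(sB):
        raise ValueError("populations must be disjoint")

    def pop_stats(samples: list[str]):
        rows = [gm.sample_index(s) for s in samples]
        d = gm.dosage[rows]
        called = d != MISSING
        n = called.sum(axis=0).astype(float)  # individuals genotyped
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
            h = np.where(n > 0, ((d == 1) & called).sum(axis=0) / np.maximum(n, 1), np.nan)
        return n, p, h, alt

    n1, p1, h1, alt1 = pop_stats(sA)
    n2, p2, h2, alt2 = pop_stats(sB)

    n_pool = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p_pool = (alt1 + alt2) / (2.0 * np.maximum(n_pool, 1))
    maf = np.minimum(p_pool, 1.0 - p_pool)
    usable = (n1 >= min_ind) & (n2 >= min_ind) & (maf >= min_maf)
    if not usable.any():
        raise AnalysisError("wc_fst: no site passes the MAF / per-population count filters")

    r = 2.0
    n1u, n2u = n1[usable], n2[usable]
    p1u, p2u = p1[usable], p2[usable]
    h1u, h2u = h1[usable], h2[usable]
    nbar = (n1u + n2u) / r
    nc = (r * nbar - (n1u**2 + n2u**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1u * p1u + n2u * p2u) / (r * nbar)
    s2 = (n1u * (p1u - pbar) ** 2 + n2u * (p2u - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1u * h1u + n2u * h2u) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0

    total = a + b + c
    nonzero = total != 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_site = np.where(nonzero, a / np.where(nonzero, total, 1.0), np.nan)
    denom = total[nonzero].sum()
    if denom == 0.0 or not nonzero.any():
        raise AnalysisError("wc_fst: all usable sites have zero total variance")
    theta_global = float(a[nonzero].sum() / denom)
    logger.info(
        "wc_fst: %d/%d sites used, global theta = %.4f",
        int(nonzero.sum()), gm.n_sites, theta_global,
    )
    return FstResult(
        a=a, b=b, c=c, theta_site=theta_site,
        theta_global=theta_global, n_sites_used=int(nonzero.sum()),
    )


def site_heterozygosity(
    gm: GenotypeMatrix, flag_threshold: float = 0.60
) -> tuple[pd.DataFrame, float]:
    """Observed heterozygosity per site, flagging possible paralog collapse.

    Returns (table, flagged_fraction): per site the fraction of
    non-missing genotypes that are heterozygous, a flag for sites
    exceeding ``flag_threshold`` (default 0.60), and the overall
    fraction of flagged sites among those with at least one call.
    """
    called = gm.called
    n_called = called.sum(axis=0)
    n_het = ((gm.dosage == 1) & called).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    flagged = het > flag_threshold
    table = gm.sites[["chrom", "pos"]].copy()
    table["n_called"] = n_called
    table["het_obs"] = het
    table["flagged"] = flagged
    n_scored = int((n_called > 0).sum())
    frac = float(flagged.sum() / n_scored) if n_scored else 0.0
    return table, frac


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete observations."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, r2_max: float = 0.2, window: int = 50) -> GenotypeMatrix:
    """Greedy LD pruning on dosage correlations.

    Walking sites in genome order, a site is dropped when its squared
    genotype correlation r^2 with any of the previous ``window - 1``
    *retained* sites exceeds ``r2_max`` (composite LD on dosages,
    pairwise-complete observations).  Comparing against retained sites
    rather than a sliding raw-site window makes the operation
    deterministic, order-preserving and idempotent: re-pruning the
    output repeats exactly the comparisons that shaped it.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must be in (0, 1]")
    n = gm.n_sites
    if n <= 1:
        return gm.take_sites(np.arange(n))
    dos = np.where(gm.called, gm.dosage, np.nan).astype(float)
    kept: list[int] = []
    for j in range(n):
        ok = True
        for i in kept[-(window - 1):] if window > 1 else []:
            if _pairwise_r2(dos[:, i], dos[:, j]) > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    logger.info("ld_prune: retained %d/%d sites (r2 <= %g)", len(kept), n, r2_max)
    return gm.take_sites(np.array(kept, dtype=int))


def pca(gm: GenotypeMatrix, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the genotype matrix with Patterson scaling.

    Missing dosages are mean-imputed per site; columns are centered at
    twice the allele frequency and scaled by ``sqrt(p(1-p))``.  Returns
    sample coordinates (rows ordered as the matrix) and the fraction of
    variance explained per component.
    """
    if gm.n_samples < 2 or gm.n_sites < 2:
        raise AnalysisError("pca needs at least 2 samples and 2 sites")
    called = gm.called
    n_called = called.sum(axis=0)
    informative = n_called > 0
    d = np.where(called, gm.dosage, 0.0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = d.sum(axis=0) / (2.0 * np.maximum(n_called, 1))
    mean = 2.0 * p
    X = np.where(called, gm.dosage, mean[None, :]).astype(float) - mean[None, :]
    scale = np.sqrt(p * (1.0 - p))
    poly = informative & (scale > 0)
    if poly.sum() < 2:
        raise AnalysisError("pca: fewer than 2 polymorphic sites")
    X = X[:, poly] / scale[None, poly]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    k = min(n_components, len(s))
    coords = pd.DataFrame(
        U[:, :k] * s[:k],
        index=pd.Index(gm.sample_ids, name="sample"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return coords, frac[:k]
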