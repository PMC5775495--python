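"""Hybrid-index / interclass-heterozygosity estimation and classification.

For each sample we estimate jointly, by maximum likelihood over a panel
of species-diagnostic markers:

* **S** -- the ancestry proportion: the fraction of the sample's gene
  copies derived from species 1;
* **H** -- the interclass (interspecific) heterozygosity: the fraction
  of loci carrying one gene copy from each species.

The pair is constrained to the triangle ``H <= 2 * min(S, 1 - S)``.
Per locus, the three ancestry classes have probabilities
``P(both copies species 1) = S - H/2``, ``P(one from each) = H`` and
``P(both species 2) = 1 - S - H/2``; the genotype likelihood mixes
these with the parental allele frequencies of the species-1 allele
(``p1_s``, ``p2_s``), which are exactly (1, 0) for strictly diagnostic
loci.  On such loci the MLE has the closed form
``S_hat = (2 n11 + n12) / (2n)``, ``H_hat = n12 / n`` where
(n11, n12, n22) count species-1-homozygous, heterozygous and
species-2-homozygous genotypes; the grid optimizer is validated
against it.

Expected (S, H) anchors: pure parents (1, 0) / (0, 0), F1 (0.5, 1),
F2 (0.5, 0.5), first backcrosses (0.75, 0.5) / (0.25, 0.5).  Observed
F1 heterozygosity sits below 1 when low-depth genotyping undercalls
heterozygotes, so classification accepts an H calibration factor taken
from a known F1 control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, AnalysisError, GenotypeMatrix, PopulationMap, mask_low_depth

logger = logging.getLogger(__name__)

_TRI_TOL = 1e-9


@dataclass
class DiagnosticPanel:
    """Markers fixed for alternative alleles between the pure references.

    ``site_idx`` indexes into the genotype matrix the panel was built
    from; ``sp1_is_alt`` records orientation (whether the species-1
    allele is the ALT allele); ``p1``/``p2`` are the species-1-allele
    frequencies in the two parental gene pools (1 and 0 for strictly
    diagnostic sites, re-estimable for softer panels).
    """

    site_idx: np.ndarray
    sp1_is_alt: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    sites: pd.DataFrame | None = None

    @property
    def n_sites(self) -> int:
        return len(self.site_idx)

    def species1_dosage(self, gm: GenotypeMatrix, sample: str) -> np.ndarray:
        """Dosage of the species-1 allele for one sample at panel sites
        (MISSING preserved)."""
        g = gm.dosage[gm.sample_index(sample), self.site_idx]
        out = np.where(self.sp1_is_alt, g, 2 - g).astype(np.int16)
        out[g == MISSING] = MISSING
        return out


@dataclass
class AncestryEstimate:
    """Joint (S, H) maximum-likelihood point for one sample."""

    S: float
    H: float
    logL: float
    n_loci: int

    def __post_init__(self) -> None:
        if self.H > 2.0 * min(self.S, 1.0 - self.S) + 1e-6:
            raise ValueError("estimate violates the triangle constraint")


@dataclass
class ClassifyConfig:
    """Settings for nearest-anchor hybrid classification.

    ``h_f1_control`` rescales the expected-H axis of every hybrid
    anchor by the observed heterozygosity of a known F1 control (the
    anchors assume H(F1) = 1, which low-depth data does not reach).
    ``max_distance`` is the (S, H) euclidean radius beyond which a
    sample is labelled ambiguous/later-generation.
    """

    h_f1_control: float | None = None
    max_distance: float = 0.25


CLASS_LABELS = ("pure1", "pure2", "F1", "BC1", "BC2", "F2", "ambiguous")

# anchors ordered so that ties resolve toward the earlier generation
_ANCHORS = (
    ("pure1", 1.0, 0.0),
    ("pure2", 0.0, 0.0),
    ("F1", 0.5, 1.0),
    ("BC1", 0.75, 0.5),
    ("BC2", 0.25, 0.5),
    ("F2", 0.5, 0.5),
)


# ---------------------------------------------------------------------------
# panel discovery
# ---------------------------------------------------------------------------


def build_panel(
    gm: GenotypeMatrix, pm: PopulationMap, min_depth: int = 10
) -> DiagnosticPanel:
    """Find sites fixed for alternative alleles between the pure groups.

    Genotypes below ``min_depth`` reads are masked for the scan (the
    input matrix is not modified).  A site enters the panel when every
    remaining pure1 genotype is homozygous for one allele, every pure2
    genotype homozygous for the other, and both groups have at least
    one call.

    Raises
    ------
    AnalysisError
        If no site qualifies -- use more divergent references or more
        reference samples.
    """
    pure1 = pm.samples_with_role("pure1")
    pure2 = pm.samples_with_role("pure2")
    if not pure1 or not pure2:
        raise AnalysisError("panel discovery needs at least one pure1 and one pure2 population")
    masked = mask_low_depth(gm, min_depth)

    def fixed_dosage(samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
        rows = [masked.sample_index(s) for s in samples]
        d = masked.dosage[rows]
        called = d != MISSING
        n_called = called.sum(axis=0)
        any_het = ((d == 1) & called).any(axis=0)
        has0 = ((d == 0) & called).any(axis=0)
        has2 = ((d == 2) & called).any(axis=0)
        is_fixed = (n_called >= 1) & ~any_het & ~(has0 & has2)
        value = np.where(has2, 2, 0)
        return is_fixed, value

    fixed1, val1 = fixed_dosage(pure1)
    fixed2, val2 = fixed_dosage(pure2)
    keep = fixed1 & fixed2 & (val1 != val2)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise AnalysisError(
            "no diagnostic sites: the pure reference groups share variation "
            "(lower divergence) or have too few genotyped samples"
        )
    sp1_is_alt = val1[idx] == 2
    logger.info(
        "build_panel: %d diagnostic sites from %d (pure1 n=%d, pure2 n=%d, >=%d reads)",
        idx.size, gm.n_sites, len(pure1), len(pure2), min_depth,
    )
    return DiagnosticPanel(
        site_idx=idx,
        sp1_is_alt=sp1_is_alt,
        p1=np.ones(idx.size),
        p2=np.zeros(idx.size),
        sites=gm.sites.iloc[idx].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _class_conditionals(g1: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-locus genotype probabilities under the three ancestry classes.

    Returns an (n_loci, 3) array with columns for classes
    (both-species-1, interclass, both-species-2); ``g1`` is the
    species-1-allele dosage.
    """
    q1, q2 = 1.0 - p1, 1.0 - p2
    cond = np.empty((len(g1), 3))
    # class 11: two copies from species 1's gene pool
    cond[:, 0] = np.select([g1 == 2, g1 == 1], [p1 * p1, 2 * p1 * q1], q1 * q1)
    # interclass: one copy from each pool
    cond[:, 1] = np.select([g1 == 2, g1 == 1], [p1 * p2, p1 * q2 + p2 * q1], q1 * q2)
    # class 22: two copies from species 2's gene pool
    cond[:, 2] = np.select([g1 == 2, g1 == 1], [p2 * p2, 2 * p2 * q2], q2 * q2)
    return cond


def _check_triangle(S: float, H: float) -> None:
    if not (0.0 - _TRI_TOL <= S <= 1.0 + _TRI_TOL and 0.0 - _TRI_TOL <= H):
        raise ValueError(f"(S={S}, H={H}) outside the unit ranges")
    if H > 2.0 * min(S, 1.0 - S) + _TRI_TOL:
        raise ValueError(f"(S={S}, H={H}) outside the triangle H <= 2*min(S, 1-S)")


def sh_likelihood(
    genotypes: np.ndarray, panel: DiagnosticPanel, S: float, H: float
) -> float:
    """Log-likelihood of (S, H) for one sample's panel genotypes.

    ``genotypes`` is the species-1-allele dosage at panel sites
    (:data:`~cropwild.genio.MISSING` entries contribute nothing).
    Raises ``ValueError`` when (S, H) falls outside the triangle.
    """
    _check_triangle(S, H)
    if panel.n_sites == 0:
        raise AnalysisError("empty diagnostic panel")
    g = np.asarray(genotypes)
    ok = g != MISSING
    cond = _class_conditionals(g[ok], panel.p1[ok], panel.p2[ok])
    w = np.array([S - H / 2.0, H, 1.0 - S - H / 2.0]).clip(0.0)
    probs = cond @ w
    return float(np.log(np.clip(probs, 1e-300, None)).sum())


def _triangle_grid(step: float) -> tuple[np.ndarray, np.ndarray]:
    s = np.arange(0.0, 1.0 + step / 2, step)
    h = np.arange(0.0, 1.0 + step / 2, step)
    S, H = np.meshgrid(s, h, indexing="ij")
    ok = H <= 2.0 * np.minimum(S, 1.0 - S) + _TRI_TOL
    return S[ok], H[ok]


def _grid_loglik(
    cond: np.ndarray, counts: np.ndarray, S: np.ndarray, H: np.ndarray
) -> np.ndarray:
    W = np.stack([S - H / 2.0, H, 1.0 - S - H / 2.0]).clip(0.0)  # (3, G)
    probs = cond @ W  # (u, G)
    return counts @ np.log(np.clip(probs, 1e-300, None))


def estimate_sh(
    genotypes: np.ndarray,
    panel: DiagnosticPanel,
    grid_step: float = 0.005,
    refine: bool = True,
) -> AncestryEstimate | None:
    """Maximum-likelihood (S, H) over the triangle.

    A dense grid (default step 0.005 on both axes) locates the optimum,
    followed by two zoom rounds of local refinement (final resolution
    ``grid_step / 100``).  Returns ``None`` with a logged warning when
    the sample has no called panel genotype.
    """
    g = np.asarray(genotypes)
    ok = g != MISSING
    n_loci = int(ok.sum())
    if n_loci == 0:
        logger.warning("estimate_sh: no called panel genotypes; estimate withheld")
        return None
    # collapse loci with identical (genotype, p1, p2): sufficient statistics
    rows = np.column_stack([g[ok].astype(float), panel.p1[ok], panel.p2[ok]])
    uniq, counts = np.unique(rows, axis=0, return_counts=True)
    cond = _class_conditionals(uniq[:, 0].astype(int), uniq[:, 1], uniq[:, 2])
    counts = counts.astype(float)

    S, H = _triangle_grid(grid_step)
    ll = _grid_loglik(cond, counts, S, H)
    best = int(np.argmax(ll))
    s_hat, h_hat, ll_hat = float(S[best]), float(H[best]), float(ll[best])

    if refine:
        span, step = grid_step, grid_step / 10.0
        for _ in range(2):
            s_loc = np.arange(s_hat - span, s_hat + span + step / 2, step).clip(0.0, 1.0)
            h_loc = np.arange(h_hat - span, h_hat + span + step / 2, step).clip(0.0, 1.0)
            Sg, Hg = np.meshgrid(s_loc, h_loc, indexing="ij")
            Hg = np.minimum(Hg, 2.0 * np.minimum(Sg, 1.0 - Sg))
            llg = _grid_loglik(cond, counts, Sg.ravel(), Hg.ravel())
            b = int(np.argmax(llg))
            if llg[b] > ll_hat:
                s_hat, h_hat, ll_hat = float(Sg.ravel()[b]), float(Hg.ravel()[b]), float(llg[b])
            span, step = step, step / 10.0
    h_hat = min(h_hat, 2.0 * min(s_hat, 1.0 - s_hat))
    return AncestryEstimate(S=s_hat, H=h_hat, logL=ll_hat, n_loci=n_loci)


def closed_form_sh(n11: int, n12: int, n22: int) -> tuple[float, float]:
    """Closed-form MLE on a strictly diagnostic panel from genotype counts."""
    n = n11 + n12 + n22
    if n == 0:
        raise ValueError("no genotypes")
    return (2.0 * n11 + n12) / (2.0 * n), n12 / n


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_hybrid(
    est: AncestryEstimate, thresholds: ClassifyConfig | None = None
) -> str:
    """Assign the nearest expected-class label in (S, H) space.

    Anchors (pure parents, F1, F2, first backcrosses) are compared by
    euclidean distance, with the H coordinate of hybrid anchors scaled
    by ``h_f1_control`` when a known-F1 calibration is supplied.  Ties
    go to the earlier-generation class; a sample farther than
    ``max_distance`` from every anchor is labelled ``ambiguous``.
    """
    cfg = thresholds or ClassifyConfig()
    h_scale = cfg.h_f1_control if cfg.h_f1_control is not None else 1.0
    best_label, best_d = "ambiguous", np.inf
    for label, s0, h0 in _ANCHORS:
        d = float(np.hypot(est.S - s0, est.H - h0 * h_scale))
        if d < best_d - 1e-12:
            best_label, best_d = label, d
    if best_d > cfg.max_distance:
        return "ambiguous"
    return best_label


def estimate_samples(
    gm: GenotypeMatrix,
    panel: DiagnosticPanel,
    samples: list[str] | None = None,
    thresholds: ClassifyConfig | None = None,
    grid_step: float = 0.005,
    low_confidence_loci: int = 20,
) -> pd.DataFrame:
    """Estimate (S, H) and classify every requested sample.

    Returns a table with columns sample, S, H, logL, n_loci, class and
    low_confidence (fewer than ``low_confidence_loci`` called panel
    genotypes -- the standard error of H then rivals the spacing
    between hybrid classes).  Samples with zero called panel genotypes
    are omitted with a warning.
    """
    samples = list(gm.sample_ids) if samples is None else samples
    rows = []
    for s in samples:
        est = estimate_sh(panel.species1_dosage(gm, s), panel, grid_step=grid_step)
        if est is None:
            logger.warning("sample %s: no panel genotypes; skipped", s)
            continue
        rows.append(
            {
                "sample": s,
                "S": est.S,
                "H": est.H,
                "logL": est.logL,
                "n_loci": est.n_loci,
                "class": classify_hybrid(est, thresholds),
                "low_confidence": est.n_loci < low_confidence_loci,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "S", "H", "logL", "n_loci", "class", "low_confidence"]
    )


def write_panel_tsv(panel: DiagnosticPanel, path: str) -> None:
    """Panel export: chrom, pos, species1_allele."""
    if panel.sites is None:
        raise ValueError("panel carries no site table")
    out = panel.sites[["chrom", "pos"]].copy()
    out["species1_allele"] = np.where(
        panel.sp1_is_alt, panel.sites["alt"], panel.sites["ref"]
    )
    out.to_csv(path, sep="\t", index=False)
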