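"""Synthetic GBS-like hybrid-zone data with known ground truth.

The generator mirrors the statistical structure the downstream analyses
assume, so every stage of the pipeline can be validated against truth:

* two wild congeners whose allele frequencies diverge under the
  Balding-Nichols model (Beta-distributed population frequencies around
  a shared ancestral frequency, parameterized directly by F_ST);
* hybrid-zone individuals built by explicit gamete sampling (F1, F2,
  and first-generation backcrosses), with each individual's true
  ancestry proportion S and interclass heterozygosity H recorded at the
  ancestry-class level;
* a four-population tree (((P1,P2),P3),P4) with an admixture fraction
  ``f`` pushing P2 alleles into P3, for ABBA-BABA testing;
* a read-depth model in which per-genotype depth is negative-binomial
  and a heterozygote whose sampled reads all carry one allele is
  miscalled homozygous -- the mechanism behind heterozygote undercalling
  in low-depth GBS data.  Reads are error-free: allele dropout, not
  sequencing error, is the artefact being modelled.

All randomness flows through explicit seeds; identical configuration
plus seed gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, PopulationMap

#: Depth assigned to error-free ("perfect") genotype calls.
PERFECT_DEPTH = 100

CROSS_TYPES = ("F1", "F2", "BC1", "BC2")


@dataclass
class SimConfig:
    """Two-species hybrid-zone scenario.

    ``fst_target`` is the Balding-Nichols divergence parameter; the
    realized Weir-Cockerham estimate between the simulated pure groups
    concentrates around it.  ``cross_spec`` lists (cross type, count)
    pairs; BC1 backcrosses toward species 1, BC2 toward species 2.
    ``mean_depth``/``depth_dispersion`` parameterize the negative-
    binomial depth law used by :func:`apply_depth_model` (dispersion is
    the NB shape; smaller means more overdispersed).
    """

    n_sites: int = 2000
    fst_target: float = 0.35
    n_pure1: int = 15
    n_pure2: int = 15
    cross_spec: list[tuple[str, int]] = field(
        default_factory=lambda: [("F1", 8), ("F2", 4), ("BC1", 4), ("BC2", 4)]
    )
    mean_depth: float = 15.0
    depth_dispersion: float = 0.5
    seed: int = 0
    n_chromosomes: int = 17

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must be in (0, 1)")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        for ct, cnt in self.cross_spec:
            if ct not in CROSS_TYPES:
                raise ValueError(f"unknown cross type {ct!r}")
            if cnt < 0:
                raise ValueError("cross counts must be >= 0")


@dataclass
class FourPopConfig:
    """Four-population tree (((P1,P2),P3),P4) with P2 -> P3 admixture.

    Drift amounts are per-branch Balding-Nichols F parameters applied
    successively from the root.  ``admixture_fraction`` is the
    probability that a P3 gene copy is drawn from P2's allele frequency
    instead of P3's own -- the ground-truth introgression dose.
    """

    n_sites: int = 5000
    n1: int = 10
    n2: int = 10
    n3: int = 10
    n4: int = 10
    drift_p123: float = 0.05
    drift_p12: float = 0.05
    drift_p1: float = 0.05
    drift_p2: float = 0.05
    drift_p3: float = 0.05
    drift_p4: float = 0.15
    admixture_fraction: float = 0.0
    seed: int = 0
    n_chromosomes: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.admixture_fraction <= 1.0:
            raise ValueError("admixture_fraction must be in [0, 1]")
        for name in ("drift_p123", "drift_p12", "drift_p1", "drift_p2", "drift_p3", "drift_p4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# frequency draws
# ---------------------------------------------------------------------------


def balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    """Draw daughter allele frequencies around ancestral ``p`` at divergence ``fst``.

    Frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F); F -> 0 is no drift
    (returns ``p`` unchanged), larger F spreads frequencies toward
    fixation.
    """
    p = np.asarray(p, dtype=float)
    if fst == 0.0:
        return p.copy()
    scale = (1.0 - fst) / fst
    out = p.copy()
    seg = (p > 0.0) & (p < 1.0)  # alleles already fixed stay fixed
    out[seg] = rng.beta(p[seg] * scale, (1.0 - p[seg]) * scale)
    return out


def _ancestral_freqs(rng: np.random.Generator, n_sites: int) -> np.ndarray:
    # bounded away from 0/1 so the MAF filter has non-degenerate behavior
    return rng.uniform(0.05, 0.95, size=n_sites)


def _site_table(n_sites: int, n_chromosomes: int) -> pd.DataFrame:
    """Contiguous equal-count site runs per simulated chromosome, 1 kb apart."""
    n_chromosomes = max(1, min(n_chromosomes, max(n_sites, 1)))
    chrom_of = np.minimum(
        (np.arange(n_sites) * n_chromosomes) // max(n_sites, 1), n_chromosomes - 1
    )
    pos = np.zeros(n_sites, dtype=int)
    for c in range(n_chromosomes):
        idx = np.flatnonzero(chrom_of == c)
        pos[idx] = 1000 * (np.arange(len(idx)) + 1)
    return pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in chrom_of],
            "pos": pos,
            "ref": "A",
            "alt": "T",
        }
    )


# ---------------------------------------------------------------------------
# two-species hybrid zone
# ---------------------------------------------------------------------------


def _hw_genotypes(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    """``n`` Hardy-Weinberg diploids from per-site frequencies ``p``."""
    return rng.binomial(2, p[None, :], size=(n, len(p))).astype(np.int16)


def _gamete_pure(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    return rng.binomial(1, p[None, :], size=(n, len(p))).astype(np.int8)


def _gamete_f1(
    rng: np.random.Generator, p1: np.ndarray, p2: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """An F1 gamete: per locus, ancestry is species 1 or 2 with equal
    probability; the allele is drawn from that species' frequency.

    Returns (allele, ancestry) arrays; ancestry 1 = species 1.
    """
    anc = rng.integers(0, 2, size=(n, len(p1))) == 0  # True -> species 1
    allele = np.where(
        anc,
        rng.binomial(1, p1[None, :], size=(n, len(p1))),
        rng.binomial(1, p2[None, :], size=(n, len(p1))),
    ).astype(np.int8)
    return allele, anc.astype(np.int8)


def simulate_pair(cfg: SimConfig) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Simulate two diverged species plus a hybrid zone of known crosses.

    Returns a perfect-call genotype matrix (depth :data:`PERFECT_DEPTH`
    everywhere; pass it through :func:`apply_depth_model` for GBS-like
    data), a population map (populations ``sp1_ref``/``sp2_ref``/
    ``hybrid_zone`` with roles pure1/pure2/hybrid_zone), and a truth
    table with columns sample, population, cross_type, true_S, true_H.

    True (S, H) are defined on ancestry classes, not observed genotypes:
    an F1 is exactly (0.5, 1.0); for F2 and backcrosses the realized
    per-locus gamete ancestries are tallied.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_sites
    p_anc = _ancestral_freqs(rng, L)
    p1 = balding_nichols(rng, p_anc, cfg.fst_target)
    p2 = balding_nichols(rng, p_anc, cfg.fst_target)

    rows: list[np.ndarray] = []
    samples: list[str] = []
    assignments: dict[str, str] = {}
    truth_rows: list[dict] = []

    def add(name: str, pop: str, geno: np.ndarray, cross: str, s: float, h: float) -> None:
        samples.append(name)
        assignments[name] = pop
        rows.append(geno.astype(np.int16))
        truth_rows.append(
            {"sample": name, "population": pop, "cross_type": cross,
             "true_S": s, "true_H": h}
        )

    for i, g in enumerate(_hw_genotypes(rng, p1, cfg.n_pure1)):
        add(f"sp1_{i:03d}", "sp1_ref", g, "pure1", 1.0, 0.0)
    for i, g in enumerate(_hw_genotypes(rng, p2, cfg.n_pure2)):
        add(f"sp2_{i:03d}", "sp2_ref", g, "pure2", 0.0, 0.0)

    k = 0
    for cross, count in cfg.cross_spec:
        for _ in range(count):
            if cross == "F1":
                a = _gamete_pure(rng, p1, 1)[0]
                b = _gamete_pure(rng, p2, 1)[0]
                s, h = 0.5, 1.0
            elif cross == "F2":
                a, anc_a = _gamete_f1(rng, p1, p2, 1)
                b, anc_b = _gamete_f1(rng, p1, p2, 1)
                a, b, anc_a, anc_b = a[0], b[0], anc_a[0], anc_b[0]
                s = float((anc_a.sum() + anc_b.sum()) / (2.0 * L))
                h = float((anc_a != anc_b).mean())
            elif cross == "BC1":  # F1 x pure species 1
                a = _gamete_pure(rng, p1, 1)[0]
                b, anc_b = _gamete_f1(rng, p1, p2, 1)
                b, anc_b = b[0], anc_b[0]
                s = float((L + anc_b.sum()) / (2.0 * L))
                h = float((anc_b == 0).mean())
            else:  # BC2: F1 x pure species 2
                a = _gamete_pure(rng, p2, 1)[0]
                b, anc_b = _gamete_f1(rng, p1, p2, 1)
                b, anc_b = b[0], anc_b[0]
                s = float(anc_b.sum() / (2.0 * L))
                h = float((anc_b == 1).mean())
            add(f"hyb_{cross}_{k:03d}", "hybrid_zone", a + b, cross, s, h)
            k += 1

    dosage = np.vstack(rows) if rows else np.empty((0, L), dtype=np.int16)
    depth = np.full_like(dosage, PERFECT_DEPTH, dtype=np.int32)
    gm = GenotypeMatrix(samples, _site_table(L, cfg.n_chromosomes), dosage, depth)
    pm = PopulationMap(
        assignments,
        roles={"sp1_ref": "pure1", "sp2_ref": "pure2", "hybrid_zone": "hybrid_zone"},
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["p1"] = p1
    truth.attrs["p2"] = p2
    return gm, pm, truth


def simulate_diagnostic(
    n_sites: int,
    cross_spec: list[tuple[str, int]],
    n_pure1: int = 10,
    n_pure2: int = 10,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Idealized scenario: parents fixed for alternative alleles at every site.

    Species 1 is fixed for the alt allele, species 2 for the ref allele,
    so every site is strictly diagnostic.  Convenient for validating the
    S/H estimator against its closed form.
    """
    cfg = SimConfig(
        n_sites=n_sites,
        fst_target=0.99,  # ignored; frequencies overridden below
        n_pure1=n_pure1,
        n_pure2=n_pure2,
        cross_spec=cross_spec,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    L = n_sites
    p1 = np.ones(L)
    p2 = np.zeros(L)
    # reuse the gamete machinery with degenerate frequencies
    rows, samples, assignments, truth_rows = [], [], {}, []

    def add(name, pop, geno, cross, s, h):
        samples.append(name)
        assignments[name] = pop
        rows.append(geno.astype(np.int16))
        truth_rows.append(
            {"sample": name, "population": pop, "cross_type": cross,
             "true_S": s, "true_H": h}
        )

    for i in range(n_pure1):
        add(f"sp1_{i:03d}", "sp1_ref", np.full(L, 2), "pure1", 1.0, 0.0)
    for i in range(n_pure2):
        add(f"sp2_{i:03d}", "sp2_ref", np.zeros(L), "pure2", 0.0, 0.0)
    k = 0
    for cross, count in cross_spec:
        for _ in range(count):
            if cross == "F1":
                geno, s, h = np.ones(L), 0.5, 1.0
            elif cross == "F2":
                a, anc_a = _gamete_f1(rng, p1, p2, 1)
                b, anc_b = _gamete_f1(rng, p1, p2, 1)
                anc_a, anc_b = anc_a[0], anc_b[0]
                geno = (a[0] + b[0]).astype(np.int16)
                s = float((anc_a.sum() + anc_b.sum()) / (2.0 * L))
                h = float((anc_a != anc_b).mean())
            elif cross == "BC1":
                b, anc_b = _gamete_f1(rng, p1, p2, 1)
                anc_b = anc_b[0]
                geno = 1 + b[0]
                s = float((L + anc_b.sum()) / (2.0 * L))
                h = float((anc_b == 0).mean())
            else:
                b, anc_b = _gamete_f1(rng, p1, p2, 1)
                anc_b = anc_b[0]
                geno = b[0].astype(np.int16)
                s = float(anc_b.sum() / (2.0 * L))
                h = float((anc_b == 1).mean())
            add(f"hyb_{cross}_{k:03d}", "hybrid_zone", np.asarray(geno), cross, s, h)
            k += 1
    dosage = np.vstack(rows)
    depth = np.full_like(dosage, PERFECT_DEPTH, dtype=np.int32)
    gm = GenotypeMatrix(samples, _site_table(L, cfg.n_chromosomes), dosage, depth)
    pm = PopulationMap(
        assignments,
        roles={"sp1_ref": "pure1", "sp2_ref": "pure2", "hybrid_zone": "hybrid_zone"},
    )
    return gm, pm, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# read-depth model
# ---------------------------------------------------------------------------


def call_from_depth(
    dosage: np.ndarray, depth: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Re-call genotypes from true dosages given per-cell read depths.

    Reads are error-free draws from the true genotype (alt-allele
    probability 0, 1/2, or 1).  A call is heterozygous only if both
    alleles are seen; a true heterozygote at depth d is therefore
    miscalled homozygous with probability 2 * (1/2)^d.  Depth 0 gives a
    missing call.
    """
    dosage = np.asarray(dosage)
    out = dosage.copy().astype(np.int16)
    out[depth == 0] = MISSING
    het = (dosage == 1) & (depth > 0)
    if het.any():
        alt_reads = rng.binomial(depth[het], 0.5)
        calls = np.ones(alt_reads.shape, dtype=np.int16)
        calls[alt_reads == 0] = 0
        calls[alt_reads == depth[het]] = 2
        out[het] = calls
    out[dosage == MISSING] = MISSING
    return out


def apply_depth_model(
    gm: GenotypeMatrix,
    mean_depth: float,
    dispersion: float = 0.5,
    seed: int = 0,
) -> GenotypeMatrix:
    """Overlay GBS-like stochastic depth and re-call genotypes.

    Depth is negative-binomial with the given mean and shape
    (``dispersion``); ``mean_depth=math.inf`` is the identity on
    dosages.  Cells already missing stay missing with depth 0.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if math.isinf(mean_depth):
        return GenotypeMatrix(
            gm.sample_ids, gm.sites.copy(), gm.dosage.copy(), gm.depth.copy()
        )
    rng = np.random.default_rng(seed)
    shape = gm.dosage.shape
    if mean_depth == 0:
        depth = np.zeros(shape, dtype=np.int32)
    else:
        p = dispersion / (dispersion + mean_depth)
        depth = rng.negative_binomial(dispersion, p, size=shape).astype(np.int32)
    depth[gm.dosage == MISSING] = 0
    called = call_from_depth(gm.dosage, depth, rng)
    return GenotypeMatrix(gm.sample_ids, gm.sites.copy(), called, depth)


# ---------------------------------------------------------------------------
# four-population (ABBA-BABA) scenario
# ---------------------------------------------------------------------------


@dataclass
class FourPopData:
    """Output bundle of :func:`simulate_four_pop`."""

    freqs: pd.DataFrame  # chrom, pos, block, p1..p4 (true frequencies)
    gm: GenotypeMatrix
    pm: PopulationMap
    truth: dict


def simulate_four_pop(cfg: FourPopConfig) -> FourPopData:
    """Evolve frequencies along (((P1,P2),P3),P4) and sample genotypes.

    With probability ``admixture_fraction`` each P3 gene copy is drawn
    from P2's allele frequency (introgression from the domestic lineage
    into the recipient species); otherwise from P3's own.  Sites carry
    contiguous block ids (one block per simulated chromosome) for the
    jackknife.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_sites
    p_anc = _ancestral_freqs(rng, L)
    p123 = balding_nichols(rng, p_anc, cfg.drift_p123)
    p12 = balding_nichols(rng, p123, cfg.drift_p12)
    p1 = balding_nichols(rng, p12, cfg.drift_p1)
    p2 = balding_nichols(rng, p12, cfg.drift_p2)
    p3 = balding_nichols(rng, p123, cfg.drift_p3)
    p4 = balding_nichols(rng, p_anc, cfg.drift_p4)

    sites = _site_table(L, cfg.n_chromosomes)
    block = pd.factorize(sites["chrom"])[0]

    samples: list[str] = []
    assignments: dict[str, str] = {}
    rows: list[np.ndarray] = []
    f = cfg.admixture_fraction
    for pop, n, p in (("P1", cfg.n1, p1), ("P2", cfg.n2, p2), ("P4", cfg.n4, p4)):
        g = _hw_genotypes(rng, p, n)
        for i in range(n):
            name = f"{pop}_{i:03d}"
            samples.append(name)
            assignments[name] = pop
            rows.append(g[i])
    # P3: per gene copy, admixed draw from P2 with probability f
    for i in range(cfg.n3):
        copies = np.zeros(L, dtype=np.int16)
        for _copy in range(2):
            from_p2 = rng.random(L) < f
            allele = np.where(
                from_p2, rng.binomial(1, p2), rng.binomial(1, p3)
            )
            copies += allele.astype(np.int16)
        name = f"P3_{i:03d}"
        samples.append(name)
        assignments[name] = "P3"
        rows.append(copies)

    dosage = np.vstack(rows)
    depth = np.full_like(dosage, PERFECT_DEPTH, dtype=np.int32)
    gm = GenotypeMatrix(samples, sites, dosage, depth)
    pm = PopulationMap(
        assignments,
        roles={"P1": "wild_reference", "P2": "domestic", "P3": "hybrid_zone",
               "P4": "outgroup"},
    )
    freqs = sites[["chrom", "pos"]].copy()
    freqs["block"] = block
    freqs["p1"], freqs["p2"], freqs["p3"], freqs["p4"] = p1, p2, p3, p4
    truth = {"admixture_fraction": f, "config": cfg}
    return FourPopData(freqs=freqs, gm=gm, pm=pm, truth=truth)


# ---------------------------------------------------------------------------
# bundled whole-study scenario
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """One self-contained hybrid-zone study for the end-to-end pipeline.

    Two wild species diverge at ``fst_species``; a domesticated lineage
    branches off species 1 with an extra ``drift_domestic`` bottleneck;
    sympatric species-2 populations receive a fraction
    ``admixture_fraction`` of their gene copies from the domestic
    lineage (one control population receives none); a hybrid zone holds
    F1/F2/backcross individuals; an outgroup sits outside everything.
    Depth uses a milder overdispersion than the two-population default
    so that a workable fraction of sites survives the coverage screen
    while heterozygote undercalling remains in force.
    """

    n_sites: int = 4000
    fst_species: float = 0.35
    n_pure1: int = 12
    n_pure2: int = 12
    n_domestic: int = 8
    n_outgroup: int = 6
    n_recipient: int = 10
    cross_spec: list[tuple[str, int]] = field(
        default_factory=lambda: [("F1", 8), ("F2", 4), ("BC1", 4), ("BC2", 4)]
    )
    drift_domestic: float = 0.25
    drift_local: float = 0.03
    drift_outgroup: float = 0.50
    admixture_fraction: float = 0.2
    mean_depth: float = 15.0
    depth_dispersion: float = 2.0
    seed: int = 0
    n_chromosomes: int = 17


def simulate_study(cfg: StudyConfig) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Generate the bundled study scenario (perfect calls + depth overlay).

    Populations: ``sp1_ref`` (pure species-1 reference, also the wild
    H1 of the ABBA-BABA design), ``sp2_ref`` (pure species-2
    reference), ``domestic`` (donor lineage), ``hyb_zone`` (known
    crosses), ``rec1``/``rec2`` (species-2 recipients with domestic
    introgression), ``rec_ctrl`` (species-2 recipient without), and
    ``outgroup``.  Returns (matrix with GBS-like depths, population
    map, truth table); the truth table's ``attrs`` record the
    introgression dose per recipient population.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_sites
    p_anc = _ancestral_freqs(rng, L)
    p_sp1 = balding_nichols(rng, p_anc, cfg.fst_species)
    p_sp2 = balding_nichols(rng, p_anc, cfg.fst_species)
    p_dom = balding_nichols(rng, p_sp1, cfg.drift_domestic)
    p_out = balding_nichols(rng, p_anc, cfg.drift_outgroup)

    rows: list[np.ndarray] = []
    samples: list[str] = []
    assignments: dict[str, str] = {}
    truth_rows: list[dict] = []

    def add(name, pop, geno, cross, s, h):
        samples.append(name)
        assignments[name] = pop
        rows.append(np.asarray(geno, dtype=np.int16))
        truth_rows.append(
            {"sample": name, "population": pop, "cross_type": cross,
             "true_S": s, "true_H": h}
        )

    for i, g in enumerate(_hw_genotypes(rng, p_sp1, cfg.n_pure1)):
        add(f"sp1_{i:03d}", "sp1_ref", g, "pure1", 1.0, 0.0)
    for i, g in enumerate(_hw_genotypes(rng, p_sp2, cfg.n_pure2)):
        add(f"sp2_{i:03d}", "sp2_ref", g, "pure2", 0.0, 0.0)
    for i, g in enumerate(_hw_genotypes(rng, p_dom, cfg.n_domestic)):
        add(f"dom_{i:03d}", "domestic", g, "domestic", 1.0, 0.0)
    for i, g in enumerate(_hw_genotypes(rng, p_out, cfg.n_outgroup)):
        add(f"out_{i:03d}", "outgroup", g, "outgroup", np.nan, np.nan)

    doses = {"rec1": cfg.admixture_fraction, "rec2": cfg.admixture_fraction, "rec_ctrl": 0.0}
    for pop, f in doses.items():
        p_loc = balding_nichols(rng, p_sp2, cfg.drift_local)
        for i in range(cfg.n_recipient):
            copies = np.zeros(L, dtype=np.int16)
            for _ in range(2):
                from_dom = rng.random(L) < f
                copies += np.where(
                    from_dom, rng.binomial(1, p_dom), rng.binomial(1, p_loc)
                ).astype(np.int16)
            add(f"{pop}_{i:03d}", pop, copies, "recipient", np.nan, np.nan)

    k = 0
    for cross, count in cfg.cross_spec:
        for _ in range(count):
            if cross == "F1":
                a = _gamete_pure(rng, p_sp1, 1)[0]
                b = _gamete_pure(rng, p_sp2, 1)[0]
                s, h = 0.5, 1.0
            elif cross == "F2":
                a, anc_a = _gamete_f1(rng, p_sp1, p_sp2, 1)
                b, anc_b = _gamete_f1(rng, p_sp1, p_sp2, 1)
                a, b, anc_a, anc_b = a[0], b[0], anc_a[0], anc_b[0]
                s = float((anc_a.sum() + anc_b.sum()) / (2.0 * L))
                h = float((anc_a != anc_b).mean())
            elif cross == "BC1":
                a = _gamete_pure(rng, p_sp1, 1)[0]
                b, anc_b = _gamete_f1(rng, p_sp1, p_sp2, 1)
                b, anc_b = b[0], anc_b[0]
                s = float((L + anc_b.sum()) / (2.0 * L))
                h = float((anc_b == 0).mean())
            else:
                a = _gamete_pure(rng, p_sp2, 1)[0]
                b, anc_b = _gamete_f1(rng, p_sp1, p_sp2, 1)
                b, anc_b = b[0], anc_b[0]
                s = float(anc_b.sum() / (2.0 * L))
                h = float((anc_b == 1).mean())
            add(f"hyb_{cross}_{k:03d}", "hyb_zone", a + b, cross, s, h)
            k += 1

    dosage = np.vstack(rows)
    depth = np.full_like(dosage, PERFECT_DEPTH, dtype=np.int32)
    gm = GenotypeMatrix(samples, _site_table(L, cfg.n_chromosomes), dosage, depth)
    gm = apply_depth_model(
        gm, cfg.mean_depth, cfg.depth_dispersion, seed=cfg.seed + 1
    )
    pm = PopulationMap(
        assignments,
        roles={
            "sp1_ref": "pure1",
            "sp2_ref": "pure2",
            "domestic": "domestic",
            "hyb_zone": "hybrid_zone",
            "rec1": "hybrid_zone",
            "rec2": "hybrid_zone",
            "rec_ctrl": "hybrid_zone",
            "outgroup": "outgroup",
        },
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["introgression_dose"] = doses
    return gm, pm, truth


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, pm: PopulationMap | None, path: str) -> None:
    """Write a VCF v4.2 with GT:DP per genotype.

    Samples are ordered as in the population map when one is given
    (matrix order otherwise).  Missing calls are written ``./.:0``.
    """
    if pm is not None:
        order = [s for s in pm.assignments if s in set(gm.sample_ids)]
        gm = gm.take_samples(order)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cropwild-simulate\n")
        for chrom in pd.unique(gm.sites["chrom"]) if gm.n_sites else []:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            cells = [
                f"{_GT_STR[int(gm.dosage[i, j])]}:{int(gm.depth[i, j])}"
                for i in range(gm.n_samples)
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )
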