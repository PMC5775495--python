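"""Independent slow/brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: explicit
per-site loops, literal formula transcription, exhaustive enumeration.
"""

from __future__ import annotations

import numpy as np

from cropwild.genio import MISSING


def wc_fst_site_oracle(dosA: list[int], dosB: list[int]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components a, b, c for one site,
    two populations, diploid, transcribed literally from the estimator's
    definitions (r = 2 populations; n_i individuals; p_i sample allele
    frequency; h_i observed heterozygote fraction)."""
    r = 2
    pops = []
    for dos in (dosA, dosB):
        called = [g for g in dos if g != MISSING]
        n_i = len(called)
        p_i = sum(called) / (2 * n_i)
        h_i = sum(1 for g in called if g == 1) / n_i
        pops.append((n_i, p_i, h_i))
    nbar = sum(n for n, _, _ in pops) / r
    nc = (r * nbar - sum(n * n for n, _, _ in pops) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p, _ in pops) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in pops) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in pops) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def wc_fst_oracle(sitesA: list[list[int]], sitesB: list[list[int]]) -> float:
    """Multi-locus ratio-of-sums theta over per-site component sums."""
    num = den = 0.0
    for dosA, dosB in zip(sitesA, sitesB):
        a, b, c = wc_fst_site_oracle(dosA, dosB)
        if a + b + c != 0.0:
            num += a
            den += a + b + c
    return num / den


def d_statistic_oracle(freqs: list[tuple[float, float, float, float]]) -> float:
    """Patterson's D by per-site hand arithmetic."""
    num = den = 0.0
    for p1, p2, p3, p4 in freqs:
        abba = (1 - p1) * p2 * p3 * (1 - p4)
        baba = p1 * (1 - p2) * p3 * (1 - p4)
        num += abba - baba
        den += abba + baba
    return num / den


def panel_scan_oracle(gm, pure1_samples, pure2_samples, min_depth=10):
    """Brute-force scan for fixed differences between the pure groups."""
    rows1 = [gm.sample_index(s) for s in pure1_samples]
    rows2 = [gm.sample_index(s) for s in pure2_samples]
    hits = []
    for j in range(gm.n_sites):
        def calls(rows):
            out = []
            for i in rows:
                if gm.dosage[i, j] != MISSING and gm.depth[i, j] >= min_depth:
                    out.append(int(gm.dosage[i, j]))
            return out

        c1, c2 = calls(rows1), calls(rows2)
        if not c1 or not c2:
            continue
        if len(set(c1)) == 1 and len(set(c2)) == 1 and c1[0] != c2[0] \
                and c1[0] in (0, 2) and c2[0] in (0, 2):
            hits.append(j)
    return hits


def ld_prune_oracle(gm, r2_max):
    """Greedy pruning with exhaustive pairwise r^2 (no windowing);
    matches the windowed implementation when the window spans all sites."""
    dos = np.where(gm.dosage != MISSING, gm.dosage, np.nan).astype(float)
    kept: list[int] = []
    for j in range(gm.n_sites):
        ok = True
        for i in kept:
            pair = ~np.isnan(dos[:, i]) & ~np.isnan(dos[:, j])
            if pair.sum() < 2:
                continue
            x, y = dos[pair, i], dos[pair, j]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept
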