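"""Genotype I/O and site/genotype filtering.

This module owns the genotype data model used everywhere else in the
package: a samples x sites matrix of alt-allele dosages ({0, 1, 2} or
missing) with a parallel matrix of per-genotype read depths, plus site
coordinates.  Input comes from a VCF (GT plus DP, or AD when DP is
absent) or from the package's own genotype TSV format; filters are the
standard GBS quality screens (per-genotype depth, per-site call rate,
minor-allele frequency).

Missing dosage is encoded as -1 (``MISSING``); simulated missing calls
always carry depth 0.  Coordinates are 1-based inclusive, VCF style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage, used consistently across the package.
MISSING: int = -1

VALID_ROLES = frozenset(
    {"pure1", "pure2", "hybrid_zone", "domestic", "wild_reference", "outgroup"}
)


class FormatError(ValueError):
    """Raised when an input file does not satisfy the documented format."""


class AnalysisError(RuntimeError):
    """Raised when an analysis cannot proceed (e.g. no usable sites)."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites with dosages and read depths.

    Parameters
    ----------
    sample_ids
        Unique sample names, one per matrix row.
    sites
        Per-site table with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``; one row per matrix column.
    dosage
        ``(n_samples, n_sites)`` integer array of alt-allele dosages in
        {0, 1, 2}, with :data:`MISSING` for no-calls.
    depth
        ``(n_samples, n_sites)`` non-negative integer array of reads
        supporting each genotype call.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if self.dosage.shape != self.depth.shape:
            raise ValueError("dosage and depth must have identical shape")
        if self.dosage.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError("matrix shape does not match sample/site tables")
        ok = (self.dosage == MISSING) | ((self.dosage >= 0) & (self.dosage <= 2))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or MISSING")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")
        if len(self.sites):
            dup = self.sites.duplicated(subset=["chrom", "pos"])
            if dup.any():
                raise ValueError("site coordinates must be unique per (chrom, pos)")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.dosage != MISSING

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to site columns ``idx`` (order kept)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            depth=self.depth[:, idx],
        )

    def take_samples(self, samples: list[str]) -> "GenotypeMatrix":
        """New matrix restricted to the given samples, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        rows = [pos[s] for s in samples]
        return GenotypeMatrix(
            sample_ids=list(samples),
            sites=self.sites.copy(),
            dosage=self.dosage[rows],
            depth=self.depth[rows],
        )

    def sample_index(self, sample: str) -> int:
        return self.sample_ids.index(sample)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.sites.reset_index(drop=True).equals(
                other.sites.reset_index(drop=True)
            )
            and np.array_equal(self.dosage, other.dosage)
            and np.array_equal(self.depth, other.depth)
        )


@dataclass
class PopulationMap:
    """Sample -> population assignment plus population -> analysis role.

    Roles are drawn from :data:`VALID_ROLES`: ``pure1``/``pure2`` are the
    allopatric reference populations of the two hybridizing species,
    ``hybrid_zone`` holds putative hybrids, ``domestic`` the cultivated
    donor lineage, ``wild_reference`` an extra wild reference group, and
    ``outgroup`` the fourth taxon of the ABBA-BABA tests.
    """

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.roles.values()) - VALID_ROLES
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def populations_with_role(self, role: str) -> list[str]:
        return [p for p, r in self.roles.items() if r == role]

    def samples_with_role(self, role: str) -> list[str]:
        pops = set(self.populations_with_role(role))
        return [s for s, p in self.assignments.items() if p in pops]

    def check_covers(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without population assignment: {missing}")


@dataclass
class FilterConfig:
    """Thresholds for the standard site/genotype filters.

    ``min_genotype_depth`` masks genotypes supported by fewer reads;
    ``min_site_call_rate`` and ``min_maf`` are *strict* lower bounds
    (a site at exactly the threshold is dropped).  Relax to >= by
    nudging the threshold down if needed.
    """

    min_genotype_depth: int = 5
    min_site_call_rate: float = 0.8
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_site_call_rate <= 1.0:
            raise ValueError("min_site_call_rate must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.min_genotype_depth < 0:
            raise ValueError("min_genotype_depth must be >= 0")


@dataclass
class FilterReport:
    """Per-filter site attrition counts from :func:`filter_sites`."""

    n_sites_in: int
    n_fail_call_rate: int
    n_fail_maf: int
    n_sites_out: int


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; multi-allelic and non-SNP
    records are skipped and counted in the log.  Per-genotype depth is
    taken from FORMAT/DP, falling back to the sum of FORMAT/AD when DP
    is absent.  A missing GT becomes a missing dosage with depth 0.

    Raises
    ------
    FormatError
        If the VCF declares neither DP nor AD in its FORMAT header.
    OSError
        If the file cannot be read.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)  # raises OSError on unreadable input
    header = vcf.raw_header
    has_dp = "##FORMAT=<ID=DP," in header
    has_ad = "##FORMAT=<ID=AD," in header
    if not has_dp and not has_ad:
        raise FormatError(
            f"{path}: VCF FORMAT declares neither DP nor AD; "
            "per-genotype depth is required"
        )
    samples = list(vcf.samples)
    n = len(samples)

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if (not var.is_snp) or len(var.ALT) != 1:
            n_skipped += 1
            continue
        gts = var.genotype.array()  # (n, ploidy+1); -1 encodes '.'
        alleles = gts[:, :2]
        dos = np.where((alleles < 0).any(axis=1), MISSING, alleles.clip(0).sum(axis=1))
        if has_dp:
            dp = var.format("DP")
            dp = np.zeros(n, dtype=np.int32) if dp is None else dp[:, 0].astype(np.int64)
        else:
            ad = var.format("AD")
            if ad is None:
                dp = np.zeros(n, dtype=np.int64)
            else:
                dp = np.clip(ad, 0, None).sum(axis=1).astype(np.int64)
        dp = np.clip(dp, 0, None)  # cyvcf2 encodes missing as large negatives
        dp = np.where(dos == MISSING, 0, dp)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        dosage_cols.append(dos.astype(np.int16))
        depth_cols.append(dp.astype(np.int32))

    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    sites = pd.DataFrame({"chrom": chroms, "pos": positions, "ref": refs, "alt": alts})
    if dosage_cols:
        dosage = np.column_stack(dosage_cols)
        depth = np.column_stack(depth_cols)
    else:
        dosage = np.empty((n, 0), dtype=np.int16)
        depth = np.empty((n, 0), dtype=np.int32)
    logger.info("read_vcf: %d samples, %d biallelic SNPs from %s", n, len(sites), path)
    return GenotypeMatrix(samples, sites, dosage, depth)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def mask_low_depth(gm: GenotypeMatrix, min_depth: int) -> GenotypeMatrix:
    """Set every genotype supported by fewer than ``min_depth`` reads to missing.

    No sites are dropped; depths are kept as-is so that masking at a
    higher threshold later remains possible.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    dosage = gm.dosage.copy()
    dosage[gm.depth < min_depth] = MISSING
    return replace(gm, sites=gm.sites.copy(), dosage=dosage, depth=gm.depth.copy())


def site_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site minor-allele frequency over non-missing genotypes.

    Sites with no called genotypes get MAF 0.
    """
    called = gm.called
    n_called = called.sum(axis=0)
    alt_count = np.where(called, gm.dosage, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n_called > 0, alt_count / (2.0 * np.maximum(n_called, 1)), 0.0)
    return np.minimum(p_alt, 1.0 - p_alt)


def filter_sites(
    gm: GenotypeMatrix,
    cfg: FilterConfig | None = None,
    return_report: bool = False,
):
    """Apply depth masking plus the per-site call-rate and MAF screens.

    Genotypes below ``cfg.min_genotype_depth`` reads are masked first;
    sites are then retained only if the fraction of called genotypes is
    strictly greater than ``cfg.min_site_call_rate`` and the
    minor-allele frequency (computed from the remaining calls) is
    strictly greater than ``cfg.min_maf``.  Site order is preserved.

    An empty result is a warning, not an error.  With
    ``return_report=True``, also returns a :class:`FilterReport` with
    per-filter attrition counts.
    """
    cfg = cfg or FilterConfig()
    masked = mask_low_depth(gm, cfg.min_genotype_depth)
    call_rate = masked.called.sum(axis=0) / max(masked.n_samples, 1)
    pass_rate = call_rate > cfg.min_site_call_rate
    maf = site_maf(masked)
    pass_maf = maf > cfg.min_maf
    keep = pass_rate & pass_maf
    report = FilterReport(
        n_sites_in=gm.n_sites,
        n_fail_call_rate=int((~pass_rate).sum()),
        n_fail_maf=int((~pass_maf).sum()),
        n_sites_out=int(keep.sum()),
    )
    logger.info(
        "filter_sites: %d sites in, %d fail call rate (> %g), %d fail MAF (> %g), %d retained",
        report.n_sites_in,
        report.n_fail_call_rate,
        cfg.min_site_call_rate,
        report.n_fail_maf,
        cfg.min_maf,
        report.n_sites_out,
    )
    if report.n_sites_out == 0:
        logger.warning("filter_sites: no sites survived filtering")
    out = masked.take_sites(np.flatnonzero(keep))
    if return_report:
        return out, report
    return out


# ---------------------------------------------------------------------------
# genotype TSV round trip
# ---------------------------------------------------------------------------

_TSV_FIXED_COLS = ["chrom", "pos", "ref", "alt"]


def write_genotype_tsv(gm: GenotypeMatrix, path: str) -> None:
    """Write the matrix as a TSV: chrom, pos, ref, alt, then one
    ``dosage:depth`` column per sample, with ``.`` for a missing dosage."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_FIXED_COLS + gm.sample_ids) + "\n")
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            cells = []
            for i in range(gm.n_samples):
                d = gm.dosage[i, j]
                dos = "." if d == MISSING else str(int(d))
                cells.append(f"{dos}:{int(gm.depth[i, j])}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.ref}\t{row.alt}\t" + "\t".join(cells) + "\n"
            )


def read_genotype_tsv(path: str) -> GenotypeMatrix:
    """Read a matrix written by :func:`write_genotype_tsv` (lossless)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_FIXED_COLS)] != _TSV_FIXED_COLS:
            raise FormatError(
                f"{path}: expected header starting with {_TSV_FIXED_COLS}, got {header[:4]}"
            )
        samples = header[len(_TSV_FIXED_COLS):]
        chroms, positions, refs, alts = [], [], [], []
        dosage_rows, depth_rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(f"{path}:{lineno}: wrong number of columns")
            chroms.append(parts[0])
            positions.append(int(parts[1]))
            refs.append(parts[2])
            alts.append(parts[3])
            dos_row, dep_row = [], []
            for cell in parts[4:]:
                try:
                    dos_s, dep_s = cell.split(":")
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: malformed cell {cell!r}") from exc
                dos_row.append(MISSING if dos_s == "." else int(dos_s))
                dep_row.append(int(dep_s))
            dosage_rows.append(dos_row)
            depth_rows.append(dep_row)
    sites = pd.DataFrame({"chrom": chroms, "pos": positions, "ref": refs, "alt": alts})
    if dosage_rows:
        dosage = np.array(dosage_rows, dtype=np.int16).T
        depth = np.array(depth_rows, dtype=np.int32).T
    else:
        dosage = np.empty((len(samples), 0), dtype=np.int16)
        depth = np.empty((len(samples), 0), dtype=np.int32)
    return GenotypeMatrix(samples, sites, dosage, depth)


# ---------------------------------------------------------------------------
# population map TSV
# ---------------------------------------------------------------------------


def write_population_map(pm: PopulationMap, path: str) -> None:
    """Write a three-column TSV: sample, population, role."""
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\trole\n")
        for sample, pop in pm.assignments.items():
            fh.write(f"{sample}\t{pop}\t{pm.roles.get(pop, '')}\n")


def read_population_map(path: str) -> PopulationMap:
    """Read a population map TSV (sample, population, role)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample", "population", "role"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: population map needs columns {sorted(required)}")
    assignments = dict(zip(df["sample"], df["population"]))
    roles: dict[str, str] = {}
    for pop, role in zip(df["population"], df["role"]):
        if role:
            prev = roles.get(pop)
            if prev is not None and prev != role:
                raise FormatError(f"{path}: population {pop} has conflicting roles")
            roles[pop] = role
    return PopulationMap(assignments, roles)
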