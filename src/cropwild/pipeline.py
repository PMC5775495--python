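"""End-to-end orchestration: filter -> panel -> S/H -> F_ST -> D battery.

`run_all` drives the whole analysis from a :class:`RunConfig` built
either from input files (VCF + population map) or from the bundled
simulation scenario, writes one TSV per stage plus a plain-text summary
into the output directory, and logs every threshold and attrition count
along the way -- the filters are where reproducibility lives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ancestry, dstat, genio, popstats, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for :func:`run_all`.

    Exactly one of (``vcf`` + ``popmap``) or ``scenario`` must be set;
    ``scenario`` is keyword overrides for
    :class:`~cropwild.simulate.StudyConfig` (empty dict = defaults).
    ``fst_pairs`` lists population-label pairs; ``quartets`` lists
    (H1, H2, H3, H4) label tuples tested as one Bonferroni family.
    """

    outdir: str = "cropwild_out"
    vcf: str | None = None
    popmap: str | None = None
    scenario: dict | None = None
    seed: int = 0
    filter: genio.FilterConfig = field(default_factory=genio.FilterConfig)
    panel_min_depth: int = 10
    classify: ancestry.ClassifyConfig = field(default_factory=ancestry.ClassifyConfig)
    fst_pairs: list[tuple[str, str]] = field(default_factory=list)
    quartets: list[tuple[str, str, str, str]] = field(default_factory=list)
    family_size: int | None = None
    block_size: int = 100
    block_by_chrom: bool = False
    run_fst: bool = True
    run_dstat: bool = True
    run_ancestry: bool = True

    def __post_init__(self) -> None:
        has_files = self.vcf is not None or self.popmap is not None
        if has_files and self.scenario is not None:
            raise ValueError("give either input files or a simulation scenario, not both")
        if not has_files and self.scenario is None:
            raise ValueError("one of (vcf, popmap) or scenario is required")
        if has_files and (self.vcf is None or self.popmap is None):
            raise ValueError("both vcf and popmap are required for file input")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "filter" in raw:
            raw["filter"] = genio.FilterConfig(**raw["filter"])
        if "classify" in raw:
            raw["classify"] = ancestry.ClassifyConfig(**raw["classify"])
        if "fst_pairs" in raw:
            raw["fst_pairs"] = [tuple(p) for p in raw["fst_pairs"]]
        if "quartets" in raw:
            raw["quartets"] = [tuple(q) for q in raw["quartets"]]
        return cls(**raw)


def bundled_config(outdir: str = "cropwild_out", seed: int = 0) -> RunConfig:
    """The packaged demonstration study: two wild species, a hybrid
    zone, a domestic donor introgressing into two of three species-2
    recipient populations, and an outgroup."""
    return RunConfig(
        outdir=outdir,
        scenario={},
        seed=seed,
        fst_pairs=[("sp1_ref", "sp2_ref")],
        quartets=[
            ("sp1_ref", "domestic", "rec1", "outgroup"),
            ("sp1_ref", "domestic", "rec2", "outgroup"),
            ("sp1_ref", "domestic", "rec_ctrl", "outgroup"),
        ],
        block_by_chrom=True,
    )


def make_report(results: list[dstat.DTestResult]) -> pd.DataFrame:
    """D-battery summary table: tested group, D, raw and corrected p,
    the four quartet labels, plus n_sites_used and n_blocks."""
    return dstat.battery_table(results)


def _stage(name: str):
    logger.info("=== stage: %s ===", name)


def run_all(cfg: RunConfig) -> dict:
    """Run every configured stage; returns a dict of in-memory results.

    Writes into ``cfg.outdir``: ``genotypes_filtered.tsv``,
    ``panel.tsv``, ``ancestry_estimates.tsv``, ``fst.tsv``,
    ``dstat_results.tsv``, ``run_log.txt`` and ``summary.txt``.  A
    fatal stage error propagates with the stage name; TSVs written by
    earlier stages are left in place.  Deterministic given config +
    seed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    results: dict = {}

    _stage("input")
    if cfg.scenario is not None:
        study = simulate.StudyConfig(**{"seed": cfg.seed, **cfg.scenario})
        gm, pm, truth = simulate.simulate_study(study)
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        note(f"simulated scenario: {gm.n_samples} samples, {gm.n_sites} sites (seed {cfg.seed})")
        results["truth"] = truth
    else:
        gm = genio.read_vcf(cfg.vcf)
        pm = genio.read_population_map(cfg.popmap)
        note(f"loaded {gm.n_samples} samples x {gm.n_sites} sites from {cfg.vcf}")
    pm.check_covers(gm)
    results["pm"] = pm

    _stage("filter")
    try:
        filtered, rep = genio.filter_sites(gm, cfg.filter, return_report=True)
    except Exception as exc:  # pragma: no cover - defensive
        raise genio.AnalysisError(f"stage 'filter' failed: {exc}") from exc
    note(
        f"filter: {rep.n_sites_in} sites in; {rep.n_fail_call_rate} fail call rate "
        f"(> {cfg.filter.min_site_call_rate}), {rep.n_fail_maf} fail MAF "
        f"(> {cfg.filter.min_maf}); {rep.n_sites_out} retained "
        f"(genotypes masked below {cfg.filter.min_genotype_depth} reads)"
    )
    het_table, het_frac = popstats.site_heterozygosity(filtered)
    het_table.to_csv(outdir / "site_heterozygosity.tsv", sep="\t", index=False)
    note(f"QC: fraction of sites with observed heterozygosity > 0.60: {het_frac:.4f}")
    genio.write_genotype_tsv(filtered, str(outdir / "genotypes_filtered.tsv"))
    results["gm"] = filtered
    results["filter_report"] = rep

    if cfg.run_ancestry:
        _stage("panel")
        try:
            panel = ancestry.build_panel(filtered, pm, min_depth=cfg.panel_min_depth)
        except genio.AnalysisError as exc:
            raise genio.AnalysisError(f"stage 'panel' failed: {exc}") from exc
        ancestry.write_panel_tsv(panel, str(outdir / "panel.tsv"))
        note(f"panel: {panel.n_sites} diagnostic sites (>= {cfg.panel_min_depth} reads)")
        results["panel"] = panel

        _stage("ancestry")
        hz = pm.samples_with_role("hybrid_zone")
        targets = (
            pm.samples_with_role("pure1") + pm.samples_with_role("pure2") + hz
        )
        estimates = ancestry.estimate_samples(
            filtered, panel, samples=targets, thresholds=cfg.classify
        )
        estimates.to_csv(
            outdir / "ancestry_estimates.tsv", sep="\t", index=False, float_format="%.6g"
        )
        counts = estimates["class"].value_counts().to_dict()
        note(f"ancestry: {len(estimates)} samples classified: {counts}")
        results["estimates"] = estimates

    if cfg.run_fst and cfg.fst_pairs:
        _stage("fst")
        fst_rows = []
        for pa, pb in cfg.fst_pairs:
            try:
                r = popstats.wc_fst(filtered, pm, pa, pb)
            except genio.AnalysisError as exc:
                raise genio.AnalysisError(f"stage 'fst' failed for ({pa},{pb}): {exc}") from exc
            fst_rows.append(
                {"popA": pa, "popB": pb, "n_sites_used": r.n_sites_used,
                 "theta": r.theta_global}
            )
            note(f"fst: {pa} vs {pb}: theta = {r.theta_global:.4f} on {r.n_sites_used} sites")
        fst_df = pd.DataFrame(fst_rows)
        fst_df.to_csv(outdir / "fst.tsv", sep="\t", index=False, float_format="%.6g")
        results["fst"] = fst_df

    if cfg.run_dstat and cfg.quartets:
        _stage("dstat")
        try:
            battery = dstat.run_test_battery(
                filtered, pm, cfg.quartets,
                family_size=cfg.family_size,
                block_size=cfg.block_size,
                block_by_chrom=cfg.block_by_chrom,
            )
        except genio.AnalysisError as exc:
            raise genio.AnalysisError(f"stage 'dstat' failed: {exc}") from exc
        report = make_report(battery)
        report.to_csv(outdir / "dstat_results.tsv", sep="\t", index=False, float_format="%.6g")
        for r in battery:
            note(
                f"dstat: H3={r.h3}: D={r.D:.4f} Z={r.Z:.2f} p={r.p_raw:.3g} "
                f"p_adj={r.p_adj:.3g} ({r.n_sites_used} sites, {r.n_blocks} blocks)"
            )
        results["dstat"] = battery
        results["dstat_table"] = report

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    summary = ["cropwild run summary", "====================", ""]
    summary.extend(log_lines)
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    return results
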