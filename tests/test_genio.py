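import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cropwild import genio, simulate
from cropwild.genio import MISSING, FilterConfig, FormatError

from conftest import make_gm

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
{extra}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""
DP_LINE = '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n'
AD_LINE = '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic Depths">\n'


def write_vcf_text(tmp_path, body, extra=DP_LINE, samples="a\tb\tc"):
    p = tmp_path / "test.vcf"
    p.write_text(VCF_HEADER.format(extra=extra, samples=samples) + body)
    return str(p)


class TestReadVcf:
    def test_basic_dosage_encoding(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/0:12\t0/1:8\t1/1:20\n"
        gm = genio.read_vcf(write_vcf_text(tmp_path, body))
        assert gm.sample_ids == ["a", "b", "c"]
        assert gm.dosage[:, 0].tolist() == [0, 1, 2]
        assert gm.depth[:, 0].tolist() == [12, 8, 20]
        assert gm.sites.loc[0, "pos"] == 100

    def test_phased_and_missing_genotypes(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0|1:9\t1|0:7\t./.:5\n"
        gm = genio.read_vcf(write_vcf_text(tmp_path, body))
        assert gm.dosage[:, 0].tolist() == [1, 1, MISSING]
        assert gm.depth[2, 0] == 0  # missing GT forces depth 0

    def test_multiallelic_and_indel_skipped(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT:DP\t0/0:9\t0/1:9\t1/1:9\n"
            "chr1\t200\t.\tAT\tA\t.\tPASS\t.\tGT:DP\t0/0:9\t0/1:9\t1/1:9\n"
            "chr1\t300\t.\tC\tT\t.\tPASS\t.\tGT:DP\t0/0:9\t0/1:9\t1/1:9\n"
        )
        gm = genio.read_vcf(write_vcf_text(tmp_path, body))
        assert gm.n_sites == 1
        assert gm.sites.loc[0, "pos"] == 300

    def test_ad_fallback_when_dp_absent(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/0:5,0\t0/1:3,4\t1/1:0,9\n"
        gm = genio.read_vcf(write_vcf_text(tmp_path, body, extra=AD_LINE))
        assert gm.depth[:, 0].tolist() == [5, 7, 9]

    def test_no_depth_field_is_fatal(self, tmp_path):
        body = "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        with pytest.raises(FormatError, match="DP"):
            genio.read_vcf(write_vcf_text(tmp_path, body, extra=""))

    def test_roundtrip_with_simulated_vcf(self, tmp_path):
        cfg = simulate.SimConfig(n_sites=80, seed=11, n_pure1=4, n_pure2=4,
                                 cross_spec=[("F1", 2)])
        gm, pm, _ = simulate.simulate_pair(cfg)
        gm = simulate.apply_depth_model(gm, mean_depth=6, seed=12)
        path = tmp_path / "sim.vcf"
        simulate.write_vcf(gm, pm, str(path))
        assert genio.read_vcf(str(path)) == gm
        # missing calls are written with the documented "./.:0" sentinel
        text = path.read_text()
        assert "./.:0" in text


class TestMaskLowDepth:
    def test_manual_toy(self):
        gm = make_gm([[0, 1, 2], [2, 1, 0]], depth=[[10, 9, 5], [4, 0, 5]])
        out = genio.mask_low_depth(gm, 5)
        assert (out.dosage == MISSING).sum() == 2
        assert out.dosage[1, 0] == MISSING and out.dosage[1, 1] == MISSING
        assert out.dosage[0].tolist() == [0, 1, 2]

    def test_zero_threshold_is_identity(self):
        gm = make_gm([[0, 1], [2, MISSING]], depth=[[3, 1], [0, 0]])
        assert genio.mask_low_depth(gm, 0) == gm


class TestFilterSites:
    def test_call_rate_is_strict(self):
        # 10 samples, 8 called: rate exactly 0.8 fails the strict bound
        col = [0, 0, 1, 1, 1, 2, 2, 2, MISSING, MISSING]
        gm = make_gm(np.array(col).reshape(-1, 1))
        out = genio.filter_sites(gm, FilterConfig())
        assert out.n_sites == 0

    def test_maf_is_strict(self):
        # MAF exactly 0.05: 1 alt allele among 20 -> dropped
        col = [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        gm = make_gm(np.array(col).reshape(-1, 1))
        out = genio.filter_sites(gm, FilterConfig())
        assert out.n_sites == 0
        # one more alt copy clears 0.05
        col2 = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        gm2 = make_gm(np.array(col2).reshape(-1, 1))
        assert genio.filter_sites(gm2, FilterConfig()).n_sites == 1

    def test_counted_attrition_on_toy(self):
        # 12 sites x 10 samples: 4 fail call rate only, 3 fail MAF only, 5 pass
        rng = np.random.default_rng(3)
        cols, balanced = [], [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        for _ in range(4):  # low call rate, decent MAF among called
            cols.append([1, 1, 0, 0, 0, MISSING, MISSING, MISSING, 1, 0])
        for _ in range(3):  # full call rate, monomorphic
            cols.append([0] * 10)
        for _ in range(5):
            cols.append(list(rng.permutation(balanced)))
        gm = make_gm(np.array(cols).T)
        out, rep = genio.filter_sites(gm, FilterConfig(), return_report=True)
        assert rep.n_fail_call_rate == 4
        assert rep.n_fail_maf == 3
        assert rep.n_sites_out == out.n_sites == 5

    def test_depth_masking_applied_first(self):
        gm = make_gm([[0], [1], [2]], depth=[[4], [10], [10]])
        out = genio.filter_sites(
            gm, FilterConfig(min_genotype_depth=5, min_site_call_rate=0.5, min_maf=0.0)
        )
        # the depth-4 genotype no longer contributes to the allele counts
        assert out.n_sites == 1
        assert out.dosage[:, 0].tolist() == [MISSING, 1, 2]

    def test_idempotent_and_order_preserving(self):
        gm = simulate.simulate_pair(simulate.SimConfig(n_sites=300, seed=5, cross_spec=[]))[0]
        gm = simulate.apply_depth_model(gm, mean_depth=8, seed=6)
        cfg = FilterConfig()
        once = genio.filter_sites(gm, cfg)
        twice = genio.filter_sites(once, cfg)
        assert once == twice
        # retained sites keep genome order
        pos = once.sites.groupby("chrom")["pos"].apply(lambda s: s.is_monotonic_increasing)
        assert pos.all()


class TestTsvRoundTrip:
    def test_lossless_with_missing(self, tmp_path):
        gm, _, _ = simulate.simulate_pair(
            simulate.SimConfig(n_sites=50, seed=7, n_pure1=3, n_pure2=3,
                               cross_spec=[("F2", 2)])
        )
        gm = simulate.apply_depth_model(gm, mean_depth=4, seed=8)
        assert (gm.dosage == MISSING).any()  # the interesting case
        path = str(tmp_path / "g.tsv")
        genio.write_genotype_tsv(gm, path)
        assert genio.read_genotype_tsv(path) == gm

    def test_empty_matrix(self, tmp_path):
        gm = make_gm(np.empty((3, 0), dtype=np.int16))
        path = str(tmp_path / "empty.tsv")
        genio.write_genotype_tsv(gm, path)
        back = genio.read_genotype_tsv(path)
        assert back.n_sites == 0 and back.sample_ids == gm.sample_ids

    def test_malformed_header(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chromosome\tposition\ts1\n")
        with pytest.raises(FormatError):
            genio.read_genotype_tsv(str(p))


def test_population_map_roundtrip(tmp_path):
    pm = genio.PopulationMap(
        {"a": "X", "b": "X", "c": "Y"}, roles={"X": "pure1", "Y": "outgroup"}
    )
    path = str(tmp_path / "pm.tsv")
    genio.write_population_map(pm, path)
    back = genio.read_population_map(path)
    assert back.assignments == pm.assignments
    assert back.roles == pm.roles


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 12))
def test_filter_never_alters_retained_values(seed, n_sites):
    """Filtering drops columns and masks cells but never rewrites values."""
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, size=(6, n_sites)).astype(np.int16)
    depth = rng.integers(0, 15, size=(6, n_sites))
    dosage[depth == 0] = MISSING
    gm = make_gm(dosage, depth=depth)
    out = genio.filter_sites(gm, FilterConfig(min_site_call_rate=0.3, min_maf=0.01))
    kept = {(c, p): j for j, (c, p) in enumerate(zip(out.sites.chrom, out.sites.pos))}
    for j, (c, p) in enumerate(zip(gm.sites.chrom, gm.sites.pos)):
        if (c, p) in kept:
            jj = kept[(c, p)]
            masked = gm.depth[:, j] < 5
            assert np.array_equal(out.dosage[~masked, jj], gm.dosage[~masked, j])
            assert (out.dosage[masked, jj] == MISSING).all()
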