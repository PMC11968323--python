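"""VCF/BCF, gVCF blocking, and pileup output."""

import numpy as np
import pysam
import pytest

from glsim import (
    ErrorModelConfig,
    ReadSimConfig,
    SiteReadData,
    TruthCohort,
    TruthSite,
    expand_gvcf,
    explode_invariable,
    generate_truth,
    read_record_stream,
    score_reads,
    simulate_reads,
    write_gvcf,
    write_pileup,
    write_vcf,
)

from conftest import make_obs


@pytest.fixture
def sim(small_cohort, err_beta):
    cohort = explode_invariable(small_cohort)
    reads = simulate_reads(cohort, err_beta, ReadSimConfig(mean_depth=3.0), seed=7)
    return cohort, reads


def _hand_results(depths_per_site, n_sites=5, variant_at=None):
    """Deterministic invariable-heavy results with hand-set depths.

    depths_per_site: list (len n_sites) of per-sample depth lists.
    """
    n_samples = len(depths_per_site[0])
    names = [f"s{i}" for i in range(n_samples)]
    sites, stacks = [], []
    for pos in range(1, n_sites + 1):
        if variant_at is not None and pos == variant_at:
            site = TruthSite(
                "c", pos, "A", ("C",), tuple((0, 1) for _ in names)
            )
        else:
            site = TruthSite("c", pos, "A", (), tuple((0, 0) for _ in names))
        sites.append(site)
        stacks.append(
            SiteReadData(
                [
                    [make_obs("A", 23)] * depths_per_site[pos - 1][i]
                    for i in range(n_samples)
                ]
            )
        )
    cohort = TruthCohort(names, {"c": n_sites}, sites)
    results = score_reads(cohort, stacks, nonref_symbol="<NON_REF>")
    return cohort, results


class TestVcf:
    def test_parses_cleanly_and_depth_zero_convention(self, sim, tmp_path):
        cohort, reads = sim
        results = score_reads(cohort, reads)
        path = str(tmp_path / "out.vcf")
        write_vcf(results, cohort, path, command="unit-test")
        with pysam.VariantFile(path) as vf:
            recs = list(vf)
        assert len(recs) == len(cohort.sites)
        saw_zero = False
        for rec, res in zip(recs, results):
            for i, name in enumerate(cohort.sample_names):
                if res.depths[i] == 0:
                    saw_zero = True
                    assert rec.samples[name]["GT"] == (None, None)
                    assert rec.samples[name]["DP"] == 0
        assert saw_zero  # mean depth 3 guarantees some zero-depth samples

    def test_write_read_round_trip_fields(self, sim, tmp_path):
        cohort, reads = sim
        results = score_reads(cohort, reads)
        path = str(tmp_path / "out.vcf")
        write_vcf(results, cohort, path)
        with pysam.VariantFile(path) as vf:
            for rec, res in zip(vf, results):
                assert rec.pos == res.site.pos
                assert rec.ref == res.site.ref_allele
                assert (rec.alts or ()) == res.site.alt_alleles
                np.testing.assert_array_equal(
                    rec.info["I16"], res.annotation.i16
                )
                for i, name in enumerate(cohort.sample_names):
                    fmt = rec.samples[name]
                    assert fmt["DP"] == res.depths[i]
                    assert fmt["GQ"] == res.gqs[i]
                    n = len(res.pls[i])
                    assert list(fmt["PL"])[:n] == list(res.pls[i])
                    np.testing.assert_allclose(
                        np.array(fmt["GL"][:n], dtype=float),
                        res.gls[i].values,
                        atol=1e-4,  # VCF floats are single precision
                    )

    @pytest.mark.parametrize("mode,suffix", [("z", ".vcf.gz"), ("b", ".bcf"), ("u", ".bcf")])
    def test_compressed_modes_round_trip(self, sim, tmp_path, mode, suffix):
        cohort, reads = sim
        results = score_reads(cohort, reads)
        path = str(tmp_path / ("out" + suffix))
        write_vcf(results, cohort, path, mode=mode)
        with pysam.VariantFile(path) as vf:
            assert len(list(vf)) == len(cohort.sites)

    def test_unknown_mode(self, sim, tmp_path):
        cohort, reads = sim
        with pytest.raises(ValueError):
            write_vcf([], cohort, str(tmp_path / "x.vcf"), mode="q")


class TestGvcf:
    def test_single_block(self, tmp_path):
        """All-invariable run with depths in one range collapses to one block."""
        depths = [[3, 2], [4, 2], [3, 3], [5, 2], [3, 2]]
        cohort, results = _hand_results(depths)
        path = str(tmp_path / "g.vcf")
        write_gvcf(results, cohort, path, dp_breakpoints=(1,))
        with pysam.VariantFile(path) as vf:
            recs = list(vf)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.pos == 1 and rec.stop == 5
        assert rec.samples["s0"]["MIN_DP"] == 3
        assert rec.samples["s1"]["MIN_DP"] == 2
        assert rec.alts == ("<NON_REF>",)

    def test_variant_breaks_block(self, tmp_path):
        depths = [[2, 2]] * 5
        cohort, results = _hand_results(depths, variant_at=3)
        path = str(tmp_path / "g.vcf")
        write_gvcf(results, cohort, path, dp_breakpoints=(1,))
        with pysam.VariantFile(path) as vf:
            recs = list(vf)
        assert [(r.pos, r.stop) for r in recs] == [(1, 2), (3, 3), (4, 5)]
        assert recs[1].alts == ("C", "<NON_REF>")

    def test_depth_range_change_breaks_block(self, tmp_path):
        depths = [[2, 2], [2, 2], [9, 2], [9, 2], [2, 2]]
        cohort, results = _hand_results(depths)
        path = str(tmp_path / "g.vcf")
        write_gvcf(results, cohort, path, dp_breakpoints=(5,))
        with pysam.VariantFile(path) as vf:
            spans = [(r.pos, r.stop) for r in vf]
        assert spans == [(1, 2), (3, 4), (5, 5)]

    def test_expand_recovers_per_site_stream(self, sim, tmp_path):
        cohort, reads = sim
        gres = score_reads(cohort, reads, nonref_symbol="<NON_REF>")
        plain = score_reads(cohort, reads)
        vpath = str(tmp_path / "all.vcf")
        gpath = str(tmp_path / "g.vcf")
        write_vcf(plain, cohort, vpath)
        write_gvcf(gres, cohort, gpath, dp_breakpoints=(1, 5))
        assert expand_gvcf(gpath) == read_record_stream(vpath)

    def test_gvcf_is_smaller_on_invariable_heavy_fixture(self, sim, tmp_path):
        import os

        cohort, reads = sim
        gres = score_reads(cohort, reads, nonref_symbol="<NON_REF>")
        plain = score_reads(cohort, reads)
        vpath = str(tmp_path / "all.vcf")
        gpath = str(tmp_path / "g.vcf")
        write_vcf(plain, cohort, vpath)
        write_gvcf(gres, cohort, gpath)
        assert os.path.getsize(gpath) < os.path.getsize(vpath)

    def test_requires_nonref_scoring(self, sim, tmp_path):
        cohort, reads = sim
        plain = score_reads(cohort, reads)
        with pytest.raises(ValueError):
            write_gvcf(plain, cohort, str(tmp_path / "g.vcf"))

    def test_rejects_bad_breakpoints(self, sim, tmp_path):
        cohort, reads = sim
        gres = score_reads(cohort, reads, nonref_symbol="<NON_REF>")
        with pytest.raises(ValueError):
            write_gvcf(gres, cohort, str(tmp_path / "g.vcf"),
                       dp_breakpoints=(5, 5))

    def test_bcftools_dialect_symbol(self, tmp_path):
        depths = [[2, 2]] * 3
        names = ["s0", "s1"]
        sites = [
            TruthSite("c", p, "A", (), ((0, 0), (0, 0))) for p in (1, 2, 3)
        ]
        cohort = TruthCohort(names, {"c": 3}, sites)
        stacks = [
            SiteReadData([[make_obs("A", 23)] * 2, [make_obs("A", 23)] * 2])
            for _ in sites
        ]
        results = score_reads(cohort, stacks, nonref_symbol="<*>")
        path = str(tmp_path / "g.vcf")
        write_gvcf(results, cohort, path)
        with pysam.VariantFile(path) as vf:
            assert next(iter(vf)).alts == ("<*>",)


class TestPileup:
    def test_ascii_encoding_and_strand_case(self, tmp_path):
        site = TruthSite("c", 1, "A", ("C",), ((0, 1),))
        obs = [make_obs("A", 37), make_obs("A", 37), make_obs("C", 37)]
        cohort = TruthCohort(["s0"], {"c": 1}, [site])
        results = score_reads(cohort, [SiteReadData([obs])])
        path = str(tmp_path / "p.txt")
        write_pileup(results, cohort, path)
        cols = open(path).read().strip().split("\t")
        assert cols == ["c", "1", "A", "3", "AAC", "FFF"]  # 37+33 = 'F'

    def test_reverse_strand_lowercase(self, tmp_path):
        site = TruthSite("c", 1, "G", ("T",), ((0, 0),))
        obs = [make_obs("G", 30, strand=1), make_obs("T", 20, strand=0)]
        cohort = TruthCohort(["s0"], {"c": 1}, [site])
        results = score_reads(cohort, [SiteReadData([obs])])
        path = str(tmp_path / "p.txt")
        write_pileup(results, cohort, path)
        cols = open(path).read().strip().split("\t")
        assert cols[4] == "gT"
        assert cols[5] == chr(30 + 33) + chr(20 + 33)

    def test_zero_depth_columns(self, tmp_path):
        site = TruthSite("c", 1, "A", (), ((0, 0), (0, 0)))
        cohort = TruthCohort(["s0", "s1"], {"c": 1}, [site])
        results = score_reads(cohort, [SiteReadData([[make_obs("A", 23)], []])])
        path = str(tmp_path / "p.txt")
        write_pileup(results, cohort, path)
        cols = open(path).read().strip().split("\t")
        assert cols[6:9] == ["0", "*", "*"]


def test_cross_format_depth_consistency(sim, tmp_path):
    """Pileup depth columns match VCF DP for the same simulated reads."""
    cohort, reads = sim
    results = score_reads(cohort, reads)
    vpath = str(tmp_path / "o.vcf")
    ppath = str(tmp_path / "o.pileup")
    write_vcf(results, cohort, vpath)
    write_pileup(results, cohort, ppath)
    with pysam.VariantFile(vpath) as vf:
        vcf_dp = [
            [rec.samples[s]["DP"] for s in cohort.sample_names] for rec in vf
        ]
    pile_dp = [
        [int(line.split("\t")[3 + 3 * i]) for i in range(cohort.n_samples)]
        for line in open(ppath)
    ]
    assert vcf_dp == pile_dp
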