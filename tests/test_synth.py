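import numpy as np
import pandas as pd
import pytest

import cpgdyad as cd
from cpgdyad.chemistry import ErrorRates
from cpgdyad.panel import PanelLocus, write_panel_beds
from cpgdyad.synth import (
    CT_CAP,
    generate_rrbs_subset,
    mspi_fragments,
    resistant_truth,
    scenario,
)


class TestPanel:
    def test_default_composition(self, default_panel):
        assert len(default_panel) == 10
        assert default_panel.classes() == {
            "demethylating_standard": 4,
            "demethylating_fast_ox": 1,
            "icr_like": 2,
            "iap_like": 2,
            "satellite_like": 1,
        }

    def test_intervals_non_overlapping(self, default_panel):
        loci = sorted(default_panel.loci, key=lambda l: l.start)
        for a, b in zip(loci, loci[1:]):
            assert a.end <= b.start

    def test_every_mspi_site_contains_a_cpg(self, default_panel):
        for locus in default_panel:
            cpgs = set(locus.cpg_positions)
            for site in locus.mspi_sites:
                # CCGG starting at 0-based s holds the CpG C at 1-based s+2
                assert site + 2 in cpgs

    def test_bed_output_byte_identical_across_calls(self, tmp_path):
        p1 = write_panel_beds(cd.build_default_panel(3), tmp_path / "a")
        p2 = write_panel_beds(cd.build_default_panel(3), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_seed_changes_coordinates_not_composition(self):
        a = cd.build_default_panel(0)
        b = cd.build_default_panel(1)
        assert a.classes() == b.classes()
        assert [l.start for l in a] != [l.start for l in b]


class TestWgbsCalls:
    def test_fully_methylated_error_free(self, default_panel):
        lp = default_panel.loci[0].params
        tc = cd.simulate_timecourse([lp], [0], mode="exact")
        # override truth with a fully methylated state
        tc.distributions[lp.locus_id][0.0] = cd.DyadDistribution.point("m", "m")
        calls = cd.generate_wgbs_calls(
            tc,
            cd.LocusPanel([default_panel.loci[0]]),
            cd.ReadDepthModel(100),
            ErrorRates.error_free(),
            seed=1,
        )[0.0]
        assert (calls["meth_count"] == calls["total_count"]).all()

    def test_unmethylated_conversion_failure_rate(self, default_panel):
        lp = default_panel.loci[0].params
        tc = cd.simulate_timecourse([lp], [0], mode="exact")
        tc.distributions[lp.locus_id][0.0] = cd.DyadDistribution.point("u", "u")
        calls = cd.generate_wgbs_calls(
            tc,
            cd.LocusPanel([default_panel.loci[0]]),
            cd.ReadDepthModel(2000),
            ErrorRates(f=0.005, e_m=0.0, e_h_bs=0.0),
            seed=2,
        )[0.0]
        frac = calls["meth_count"].sum() / calls["total_count"].sum()
        assert frac == pytest.approx(0.005, abs=0.001)

    def test_zero_depth_warns_and_is_empty_of_reads(self, default_panel):
        lp = default_panel.loci[0].params
        tc = cd.simulate_timecourse([lp], [0], mode="exact")
        with pytest.warns(UserWarning, match="depth"):
            calls = cd.generate_wgbs_calls(
                tc,
                cd.LocusPanel([default_panel.loci[0]]),
                cd.ReadDepthModel(0),
                seed=3,
            )[0.0]
        assert calls["total_count"].sum() == 0

    def test_reproducible_by_seed(self, default_panel, twoi_timecourse):
        a = cd.generate_wgbs_calls(twoi_timecourse, default_panel, seed=11)
        b = cd.generate_wgbs_calls(twoi_timecourse, default_panel, seed=11)
        for t in a:
            pd.testing.assert_frame_equal(a[t], b[t])


class TestRrbs:
    def _toy_panel(self, cut_positions, cpg_positions, default_panel):
        locus = default_panel.loci[0]
        toy = PanelLocus(
            params=locus.params,
            chrom="chrT",
            start=0,
            end=500,
            cpg_positions=tuple(cpg_positions),
            mspi_sites=tuple(c - 1 for c in cut_positions),  # cut = site + 1
            cgi_flag=False,
        )
        return cd.LocusPanel([toy])

    def test_fragment_size_selection(self, default_panel):
        # cuts at 0, 100, 400: fragment [0,100) retained, [100,400) dropped
        panel = self._toy_panel([0, 100, 400], [10, 50, 150, 350], default_panel)
        calls = pd.DataFrame(
            dict(
                chrom=["chrT"] * 4,
                pos=[11, 51, 151, 351],  # 1-based = 0-based + 1
                strand=["+"] * 4,
                meth_count=[1] * 4,
                total_count=[2] * 4,
            )
        )
        out = generate_rrbs_subset(calls, panel, size_window=(40, 220))
        assert sorted(out["pos"]) == [11, 51]

    def test_unbounded_window_keeps_all_fragment_cpgs(self, default_panel):
        panel = self._toy_panel([0, 100, 400], [10, 50, 150, 350], default_panel)
        calls = pd.DataFrame(
            dict(
                chrom=["chrT"] * 4,
                pos=[11, 51, 151, 351],
                strand=["+"] * 4,
                meth_count=[0] * 4,
                total_count=[1] * 4,
            )
        )
        out = generate_rrbs_subset(calls, panel, size_window=(0, np.inf))
        assert sorted(out["pos"]) == [11, 51, 151, 351]

    def test_no_fragments_warns_empty(self, default_panel):
        panel = self._toy_panel([0], [10], default_panel)  # single cut: no fragment
        calls = pd.DataFrame(
            dict(chrom=["chrT"], pos=[11], strand=["+"], meth_count=[0], total_count=[1])
        )
        with pytest.warns(UserWarning, match="MspI"):
            out = generate_rrbs_subset(calls, panel)
        assert len(out) == 0

    def test_cgi_enrichment_on_default_panel(self, default_panel, twoi_timecourse):
        calls = cd.generate_wgbs_calls(twoi_timecourse, default_panel, seed=4)[0.0]
        rrbs = generate_rrbs_subset(calls, default_panel)
        cgi_pos = set()
        for locus in default_panel:
            if locus.cgi_flag:
                cgi_pos.update(range(locus.start, locus.end + 1))
        wgbs_frac = calls["pos"].isin(cgi_pos).mean()
        rrbs_frac = rrbs["pos"].isin(cgi_pos).mean()
        assert rrbs_frac > wgbs_frac

    def test_fragments_pool_sites_per_chromosome(self, default_panel):
        frags = mspi_fragments(default_panel)
        cuts = sorted(
            s + 1 for locus in default_panel for s in locus.mspi_sites
        )
        assert len(frags) == len(cuts) - 1


class TestHairpinReads:
    def test_fully_methylated_bs_reads_all_cc(self):
        reads = cd.generate_hairpin_reads(
            cd.DyadDistribution.point("m", "m"), 200, "BS",
            ErrorRates.error_free(), seed=1,
        )
        cc = reads[(reads.top_call == "C") & (reads.bottom_call == "C")]
        assert cc["count"].sum() == 200
        assert reads["count"].sum() == 200

    def test_hydroxymethylated_oxbs_reads_all_tt(self):
        reads = cd.generate_hairpin_reads(
            cd.DyadDistribution.point("h", "h"), 200, "oxBS",
            ErrorRates.error_free(), seed=1,
        )
        tt = reads[(reads.top_call == "T") & (reads.bottom_call == "T")]
        assert tt["count"].sum() == 200

    def test_hemi_hydroxy_bs_reads_ct(self):
        reads = cd.generate_hairpin_reads(
            cd.DyadDistribution.point("h", "u"), 100, "BS",
            ErrorRates.error_free(), seed=1,
        )
        ct = reads[(reads.top_call == "C") & (reads.bottom_call == "T")]
        assert ct["count"].sum() == 100

    def test_unknown_assay_rejected(self):
        with pytest.raises(ValueError, match="assay"):
            cd.generate_hairpin_reads(
                cd.DyadDistribution.point("u", "u"), 10, "TAB", seed=1
            )


class TestGlucmsCt:
    def test_noiseless_ct_arithmetic(self):
        # strand fractions (m,h,u) = (0.349, 0.25, 0.401)
        dist = cd.DyadDistribution(
            {("m", "m"): 0.349, ("h", "h"): 0.25, ("u", "u"): 0.401}
        )
        ct = cd.generate_glucms_ct(dist, cd.CtModel(sigma_ct=0.0), seed=0, replicates=1)
        by_enzyme = dict(zip(ct["enzyme"], ct["ct"]))
        assert by_enzyme["mock"] == pytest.approx(20.0)
        assert by_enzyme["mspi"] == pytest.approx(22.0)  # -log2(0.25)
        assert by_enzyme["hpaii"] == pytest.approx(20.0 - np.log2(0.599), abs=1e-9)

    def test_unmodified_locus_capped(self):
        ct = cd.generate_glucms_ct(
            cd.DyadDistribution.point("u", "u"), cd.CtModel(sigma_ct=0.0), seed=0
        )
        digested = ct[ct["enzyme"] != "mock"]
        assert (digested["ct"] == CT_CAP).all()
        assert digested["capped"].all()

    def test_seed_reproducibility(self):
        dist = cd.DyadDistribution({("m", "m"): 0.5, ("u", "u"): 0.5})
        a = cd.generate_glucms_ct(dist, seed=5)
        b = cd.generate_glucms_ct(dist, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_resistant_truth_convention(self):
        dist = cd.DyadDistribution({("m", "h"): 0.5, ("u", "u"): 0.5})
        r_mspi, r_hpaii = resistant_truth(dist)
        assert r_mspi == pytest.approx(0.25)  # strand 5hmC
        assert r_hpaii == pytest.approx(0.5)  # strand 5mC + 5hmC


class TestScenarios:
    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="serum_steady"):
            scenario("banana")

    def test_serum_steady_time_invariant(self):
        bundle = scenario(
            "serum_steady",
            overrides=dict(sample_times=(0.0, 24.0, 72.0), n_hairpin_reads=10,
                           mean_depth=1.0),
            seed=0,
        )
        for locus_id, by_time in bundle.timecourse.distributions.items():
            ref = by_time[0.0]
            for t, dist in by_time.items():
                assert dist.allclose(ref, tol=1e-10)

    def test_tet_loss_never_below_default(self):
        times = (0.0, 24.0, 48.0, 72.0)
        kw = dict(sample_times=times, n_hairpin_reads=10, mean_depth=1.0)
        tet = scenario("tet_loss", overrides=dict(kw), seed=0)
        base = scenario("twoi_timecourse", overrides=dict(kw), seed=0)
        for locus in base.panel:
            ft = tet.timecourse.strand_fractions(locus.locus_id)
            fb = base.timecourse.strand_fractions(locus.locus_id)
            for t in times:
                assert ft[t][0] >= fb[t][0] - 1e-12  # 5mC never lower
                assert ft[t][1] <= 1e-12  # no 5hmC without oxidation

    def test_dnmt3_kd_slow_monotone_loss(self):
        times = (0.0, 48.0, 96.0, 192.0, 384.0)
        bundle = scenario(
            "dnmt3_kd",
            overrides=dict(sample_times=times, n_hairpin_reads=10, mean_depth=1.0),
            seed=0,
        )
        for locus in bundle.panel:
            f = bundle.timecourse.strand_fractions(locus.locus_id)
            series = [f[t][0] for t in times]
            assert all(a >= b - 1e-12 for a, b in zip(series, series[1:]))
            # passive-style loss is slow: after 4 divisions (48 h) a
            # demethylating locus retains far more 5mC than under 2i
            rho_m = locus.params.serum_schedule.at(0).rho_m
            expected_factor = ((1 + rho_m) / 2) ** 4
            assert f[48.0][0] >= f[0.0][0] * expected_factor * 0.9

    def test_bundle_manifest_and_write(self, tmp_path):
        bundle = scenario(
            "twoi_timecourse",
            overrides=dict(sample_times=(0.0, 24.0), n_hairpin_reads=50,
                           mean_depth=2.0),
            seed=1,
        )
        out = bundle.write(tmp_path / "bundle")
        assert (out / "manifest.json").exists()
        assert (out / "hairpin_reads.csv").exists()
        assert (out / "ct_triplets.csv").exists()
        assert (out / "annotations" / "cgi.bed").exists()
        assert bundle.manifest["scenario"] == "twoi_timecourse"
        assert len(bundle.manifest["loci"]) == 10
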