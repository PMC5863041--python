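"""Generator correctness: determinism, geometry, mixture behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import slimfoot as sf
from slimfoot.simulate import CLASSES, fragment_kind, nucleosome_dyads


def oriented_midpoints(fs, site):
    from slimfoot.vplot import fragment_midpoints
    mids = fragment_midpoints(fs)
    return (mids - site.motif_center) * site.tss_sign


class TestSitePanel:
    def test_count_conservation_and_classes(self, small_panel):
        assert len(small_panel) == 25
        labels = pd.Series([s.class_label for s in small_panel.sites])
        assert labels.value_counts().to_dict() == {c: 5 for c in CLASSES}

    def test_same_seed_identical(self, small_params):
        a = sf.build_site_panel(small_params)
        b = sf.build_site_panel(small_params)
        assert a.sites == b.sites
        assert a.chrom_sizes == b.chrom_sizes

    def test_min_pairwise_spacing(self, small_panel):
        centers = np.sort([s.motif_center for s in small_panel.sites])
        assert np.diff(centers).min() >= 2000

    def test_tss_geometry(self, small_panel, small_params):
        for s in small_panel.sites:
            assert abs(s.tss_offset) == small_params.tss_distance
            assert s.tss_strand == ("+" if s.tss_offset > 0 else "-")

    def test_coordinates_within_bounds(self, small_panel):
        size = small_panel.chrom_sizes["chrS"]
        assert all(0 <= s.motif_center < size for s in small_panel.sites)

    @pytest.mark.parametrize("kwargs", [
        {"mnase_level": 0}, {"boundary_noise_sd": -1},
        {"midfrag_weight_at_unit_mnase": 1.5}, {"site_spacing": 1500},
        {"distal_side_prob": {"C4a": 1.2}},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sf.SimulationParams(**kwargs)


class TestChipFragments:
    def test_count_conservation(self, small_chip, small_panel, small_params):
        assert len(small_chip) == len(small_panel) * small_params.fragments_per_site

    def test_same_seed_identical(self, small_panel, small_params):
        a = sf.simulate_chip_fragments(small_panel, small_params, seed=5)
        b = sf.simulate_chip_fragments(small_panel, small_params, seed=5)
        pd.testing.assert_frame_equal(a.frags, b.frags)

    def test_cobound_distal_side_binomial(self):
        """At distal_side_prob 0.9, the fraction of co-bound fragments whose
        midpoint is TSS-distal is within 3 binomial SDs of 0.9."""
        p = sf.SimulationParams(n_sites_per_class=1, fragments_per_site=1000, seed=21)
        panel = sf.build_site_panel(p)
        fs = sf.simulate_chip_fragments(panel, p, seed=22)
        site = panel.by_class("C4a")[0]
        mask = (fs.site_ids() == site.site_id) & (fragment_kind(fs) == "cobound")
        off = oriented_midpoints(fs.subset(mask.to_numpy()), site)
        n = len(off)
        frac = (off < 0).mean()
        assert abs(frac - 0.9) <= 3 * np.sqrt(0.9 * 0.1 / n)

    def test_midfrag_disappears_at_high_mnase(self, small_panel):
        p1 = sf.SimulationParams(n_sites_per_class=5, fragments_per_site=200,
                                 mnase_level=1, seed=11)
        p27 = sf.SimulationParams(n_sites_per_class=5, fragments_per_site=200,
                                  mnase_level=27, seed=11)
        low = sf.simulate_chip_fragments(small_panel, p1, seed=30)
        high = sf.simulate_chip_fragments(small_panel, p27, seed=30)
        in_mid = lambda fs: int(((fs.lengths >= 140) & (fs.lengths < 160)).sum())
        assert in_mid(high) < in_mid(low)

    def test_midfrag_weight_monotone_in_mnase(self):
        weights = [sf.SimulationParams(mnase_level=m).mixture_weights("C2")["midfrag"]
                   for m in (1, 3, 9, 27)]
        assert all(a > b for a, b in zip(weights, weights[1:]))

    def test_mixture_weights_sum_to_one(self):
        for cls in CLASSES:
            for m in (1, 9, 27):
                w = sf.SimulationParams(mnase_level=m).mixture_weights(cls)
                assert np.isclose(sum(w.values()), 1.0)

    def test_cobound_lengths_truncated_and_distributed(self):
        """Every co-bound length is in [160, 220] and the empirical
        distribution matches the truncated normal (KS distance < 0.05)."""
        p = sf.SimulationParams(n_sites_per_class=5, fragments_per_site=5000, seed=41)
        panel = sf.build_site_panel(p)
        fs = sf.simulate_chip_fragments(panel, p, seed=42)
        lens = fs.lengths[(fragment_kind(fs) == "cobound").to_numpy()]
        assert len(lens) >= 10_000
        assert lens.min() >= 160 and lens.max() <= 220
        a, b = (160 - 190) / 12, (220 - 190) / 12
        d, _ = stats.kstest(lens, stats.truncnorm(a, b, loc=190, scale=12).cdf)
        assert d < 0.05

    def test_tf_only_sharp_at_low_noise(self):
        p = sf.SimulationParams(n_sites_per_class=1, fragments_per_site=500,
                                boundary_noise_sd=0.0, seed=43)
        panel = sf.build_site_panel(p)
        fs = sf.simulate_chip_fragments(panel, p, seed=44)
        lens = fs.lengths[(fragment_kind(fs) == "tf_only").to_numpy()]
        assert (lens == 2 * p.protected_halfwidth).all()


class TestNetseq:
    def test_c1_symmetric_initiation(self):
        p = sf.SimulationParams(n_sites_per_class=1, seed=51)
        panel = sf.build_site_panel(p)
        rs = sf.simulate_netseq_reads(panel, 2000, seed=52)
        site = panel.by_class("C1")[0]
        sub = rs.reads[rs.reads["name"] == f"{site.site_id}:C1"]
        n_sense = int((sub["strand"] == site.tss_strand).sum())
        n_anti = len(sub) - n_sense
        assert abs(n_sense - n_anti) <= 3 * np.sqrt(len(sub))

    def test_c4b_no_aborted_ends_near_motif(self):
        p = sf.SimulationParams(n_sites_per_class=2, seed=53)
        panel = sf.build_site_panel(p)
        rs = sf.simulate_netseq_reads(panel, 1000, seed=54)
        for site in panel.by_class("C4b"):
            sub = rs.reads[rs.reads["name"] == f"{site.site_id}:C4b"]
            anti = sub[sub["strand"] != site.tss_strand]
            off = (anti["pos"].to_numpy() - site.motif_center) * site.tss_sign
            assert ((off >= -50) & (off <= 0)).sum() == 0

    def test_c4a_aborted_ends_pile_near_motif(self):
        p = sf.SimulationParams(n_sites_per_class=2, seed=53)
        panel = sf.build_site_panel(p)
        rs = sf.simulate_netseq_reads(panel, 1000, seed=54, aborted_weight=0.3)
        for site in panel.by_class("C4a"):
            sub = rs.reads[rs.reads["name"] == f"{site.site_id}:C4a"]
            anti = sub[sub["strand"] != site.tss_strand]
            off = (anti["pos"].to_numpy() - site.motif_center) * site.tss_sign
            assert ((off >= -50) & (off <= 0)).all() and len(off) > 0

    def test_same_seed_identical(self, small_panel):
        a = sf.simulate_netseq_reads(small_panel, 100, seed=7)
        b = sf.simulate_netseq_reads(small_panel, 100, seed=7)
        pd.testing.assert_frame_equal(a.reads, b.reads)


@pytest.fixture(scope="module")
def panel():
    return sf.build_site_panel(sf.SimulationParams(n_sites_per_class=2, seed=61))


class TestNucleosomeFragments:
    @staticmethod
    def mean_side_position(fs, site, side):
        from slimfoot.vplot import fragment_midpoints
        mask = fs.frags["name"] == f"{site.site_id}:{site.class_label}|{side}"
        mids = fragment_midpoints(fs.subset(mask.to_numpy()))
        return ((mids - site.motif_center) * site.tss_sign).mean()

    def test_c4a_minus1_locked(self, panel):
        before = sf.simulate_nucleosome_fragments(panel, False, 25, seed=62,
                                                  fragments_per_site=2000)
        after = sf.simulate_nucleosome_fragments(panel, True, 25, seed=63,
                                                 fragments_per_site=2000)
        site = panel.by_class("C4a")[0]
        d = (self.mean_side_position(after, site, "minus1")
             - self.mean_side_position(before, site, "minus1"))
        assert abs(d) < 2.0

    def test_c1_plus1_moves_toward_motif(self, panel):
        before = sf.simulate_nucleosome_fragments(panel, False, 25, seed=62,
                                                  fragments_per_site=2000)
        after = sf.simulate_nucleosome_fragments(panel, True, 25, seed=63,
                                                 fragments_per_site=2000)
        site = panel.by_class("C1")[0]
        d = (self.mean_side_position(after, site, "plus1")
             - self.mean_side_position(before, site, "plus1"))
        assert abs(d - (-25)) < 2.0

    def test_dyad_rules(self):
        assert nucleosome_dyads("C1", False, 25) == {"minus1": -150, "plus1": 250}
        assert nucleosome_dyads("C1", True, 25) == {"minus1": -125, "plus1": 225}
        assert nucleosome_dyads("C4a", True, 25) == {"minus1": -150, "plus1": 225}
        assert nucleosome_dyads("C4b", False, 25) == {"minus1": -90, "plus1": 250}
        assert nucleosome_dyads("C4b", True, 25) == {"minus1": -115, "plus1": 225}

    def test_same_seed_identical(self, panel):
        a = sf.simulate_nucleosome_fragments(panel, False, 25, seed=64)
        b = sf.simulate_nucleosome_fragments(panel, False, 25, seed=64)
        pd.testing.assert_frame_equal(a.frags, b.frags)

    def test_negative_shift_rejected(self, panel):
        with pytest.raises(ValueError):
            sf.simulate_nucleosome_fragments(panel, True, -1, seed=0)
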