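"""NET-seq coverage/scoring, subcluster split, nucleosome shifts."""

import itertools

import numpy as np
import pandas as pd
import pytest

import slimfoot as sf
from slimfoot.fragio import StrandedReadSet
from slimfoot.netnuc import ShiftReport

from conftest import anchors_frame


def read_set(positions, strands, chrom="chrI"):
    reads = pd.DataFrame({"chrom": chrom, "pos": positions,
                          "strand": strands, "name": "."})
    return StrandedReadSet(reads, {chrom: 100000})


TELOMERES = pd.DataFrame({"chrom": ["chrI"], "start": [0], "end": [500]})


class TestNetseqCoverage:
    def test_plus_read_extension_window(self):
        rs = read_set([100], ["+"])
        dp = sf.netseq_coverage(rs, anchors_frame([90], ["+"]), W=50, extension=20)
        # 3' end at 100 extended 20 bp 5'-ward: covers [80, 100], 21 bases
        np.testing.assert_array_equal(np.flatnonzero(dp.sense) - 50, np.arange(-10, 11))
        assert dp.sense.sum() == 21

    def test_minus_read_extension_window(self):
        rs = read_set([100], ["-"])
        dp = sf.netseq_coverage(rs, anchors_frame([110], ["+"]), W=50, extension=20)
        # minus-strand 3' end extends rightward: [100, 120]
        np.testing.assert_array_equal(np.flatnonzero(dp.antisense) - 50,
                                      np.arange(-10, 11))

    def test_mass_conservation(self, small_panel):
        rs = sf.simulate_netseq_reads(small_panel, 200, seed=91)
        anchors = small_panel.anchors().drop(columns=["class_label"])
        W = 2000  # wide enough that every extension window fits fully
        dp = sf.netseq_coverage(rs, anchors, W=W, extension=20)
        assert dp.sense.sum() + dp.antisense.sum() == 21 * len(rs)

    def test_telomeric_anchor_dropped(self):
        rs = read_set([100], ["+"])
        dp = sf.netseq_coverage(rs, anchors_frame([100], ["+"]), W=50,
                                extension=20, telomeres=TELOMERES)
        assert dp.n_anchors == 0 and dp.sense.sum() == 0

    def test_negative_extension_rejected(self):
        with pytest.raises(ValueError):
            sf.netseq_coverage(read_set([1], ["+"]), anchors_frame([1], ["+"]),
                               extension=-1)


class TestAbortedScore:
    def test_no_antisense_scores_zero(self):
        rs = read_set([1100, 1200], ["+", "+"])
        s = sf.aborted_transcript_score(rs, anchors_frame([1000], ["+"]))
        assert s.iloc[0] == 0.0

    def test_sense_reads_do_not_contribute(self):
        # one antisense hit in-window; adding sense reads changes only the
        # normalization denominator, never the hit count
        rs1 = read_set([980, 1100], ["-", "+"])
        rs2 = read_set([980, 1100, 1200, 1300], ["-", "+", "+", "+"])
        a1 = sf.aborted_transcript_score(rs1, anchors_frame([1000], ["+"]))
        a2 = sf.aborted_transcript_score(rs2, anchors_frame([1000], ["+"]))
        assert a1.iloc[0] == 1000.0 / 2 and a2.iloc[0] == 1000.0 / 4

    def test_simulated_c4a_separates_from_c4b(self):
        """Per-site aborted scores separate the locked (4a) and pushed (4b)
        classes with effect size > 2."""
        p = sf.SimulationParams(n_sites_per_class=10, seed=92)
        panel = sf.build_site_panel(p)
        rs = sf.simulate_netseq_reads(panel, 500, seed=93)
        anchors = panel.anchors()
        scores = {}
        for cls in ("C4a", "C4b"):
            grp = anchors[anchors["class_label"] == cls].reset_index(drop=True)
            scores[cls] = sf.aborted_transcript_score(
                rs, grp.drop(columns=["class_label"])).to_numpy()
        pooled_sd = np.sqrt((scores["C4a"].var() + scores["C4b"].var()) / 2)
        effect = (scores["C4a"].mean() - scores["C4b"].mean()) / pooled_sd
        assert effect > 2


def brute_force_two_partition(scores):
    """Oracle: the optimal 2-partition of 1-D points is contiguous in sorted
    order; enumerate every contiguous split and minimize total within-SS."""
    xs = np.sort(np.asarray(scores, dtype=float))
    best = (np.inf, None)
    for k in range(1, len(xs)):
        lo, hi = xs[:k], xs[k:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best[0]:
            best = (cost, xs[k - 1])
    return best[1]  # threshold: max of low group


class TestSplitCluster4:
    def test_worked_example(self):
        scores = pd.Series([0, 0, 0, 5, 6, 7], index=list("abcdef"), dtype=float)
        labels, done = sf.split_cluster4(scores)
        assert done
        assert labels.tolist() == ["4b", "4b", "4b", "4a", "4a", "4a"]

    def test_all_identical_refused(self):
        labels, done = sf.split_cluster4(pd.Series([2.0, 2.0, 2.0]))
        assert not done and set(labels) == {"4"}

    def test_matches_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = np.round(rng.gamma(1.5, 2.0, size=rng.integers(2, 15)), 3)
            if np.allclose(x, x[0]):
                continue
            scores = pd.Series(x)
            labels, _ = sf.split_cluster4(scores)
            thr = brute_force_two_partition(x)
            expect = np.where(x <= thr, "4b", "4a")
            assert labels.tolist() == expect.tolist()

    def test_matches_sklearn_two_means(self):
        from sklearn.cluster import KMeans
        x = np.array([0.1, 0.0, 0.2, 4.8, 5.5, 6.1, 0.05])
        labels, _ = sf.split_cluster4(pd.Series(x))
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(x.reshape(-1, 1))
        hi = km.cluster_centers_.argmax()
        expect = np.where(km.labels_ == hi, "4a", "4b")
        assert labels.tolist() == expect.tolist()

    def test_too_few(self):
        with pytest.raises(ValueError):
            sf.split_cluster4(pd.Series([1.0]))


class TestNucleosomeProfile:
    def test_center_extension_window(self):
        frags = pd.DataFrame({"chrom": ["chrI"], "start": [100], "end": [160],
                              "name": ["."], "strand": ["."]})
        fs = sf.FragmentSet(frags, {"chrI": 1000})
        # center floor((100+159)/2) = 129 -> coverage on [104, 154]
        prof = sf.nucleosome_profile(fs, anchors_frame([129], ["+"]), W=60,
                                     halfwidth=25)
        np.testing.assert_array_equal(np.flatnonzero(prof) - 60, np.arange(-25, 26))
        assert prof.sum() == 51

    def test_mass_conservation(self, small_panel):
        fs = sf.simulate_nucleosome_fragments(small_panel, False, 25, seed=94,
                                              fragments_per_site=100)
        anchors = small_panel.anchors().drop(columns=["class_label"])
        prof = sf.nucleosome_profile(fs, anchors, W=1200, halfwidth=25)
        assert prof.sum() == 51 * len(fs)

    def test_maxima_at_configured_dyads(self):
        p = sf.SimulationParams(n_sites_per_class=10, seed=95)
        panel = sf.build_site_panel(p)
        fs = sf.simulate_nucleosome_fragments(panel, False, 25, seed=96,
                                              fragments_per_site=1000)
        anchors = panel.anchors()
        c1 = anchors[anchors["class_label"] == "C1"].reset_index(drop=True)
        prof = sf.nucleosome_profile(fs, c1.drop(columns=["class_label"]), W=500)
        W = 500
        left = -250 + int(np.argmax(prof[W - 250:W - 50 + 1]))
        right = 50 + int(np.argmax(prof[W + 50:W + 250 + 1]))
        assert abs(left - (-150)) <= 2 and abs(right - 250) <= 2


class TestNucleosomeShift:
    def gaussian_profile(self, peaks, W=500):
        x = np.arange(-W, W + 1)
        return sum(np.exp(-0.5 * ((x - mu) / 20.0) ** 2) for mu in peaks)

    def test_identical_profiles_zero_shift(self):
        prof = self.gaussian_profile([-150, 250])
        rep = sf.nucleosome_shift(prof, prof.copy(), W=500)
        assert rep.minus1_shift == 0 and rep.plus1_shift == 0

    def test_sign_convention_toward_anchor_negative(self):
        before = self.gaussian_profile([-150, 250])
        after = self.gaussian_profile([-125, 225])
        rep = sf.nucleosome_shift(before, after, W=500)
        assert rep.minus1_shift == -25 and rep.plus1_shift == -25

    def test_away_from_anchor_positive(self):
        before = self.gaussian_profile([-90, 250])
        after = self.gaussian_profile([-115, 250])
        rep = sf.nucleosome_shift(before, after, W=500)
        assert rep.minus1_shift == 25 and rep.plus1_shift == 0

    def test_flat_side_flagged(self):
        before = self.gaussian_profile([250])
        before[0:451] = 0.0  # flatten the minus-1 window entirely
        rep = sf.nucleosome_shift(before, before.copy(), W=500)
        assert rep.minus1_shift is None and rep.plus1_shift == 0

    def test_mismatched_windows_rejected(self):
        with pytest.raises(ValueError):
            sf.nucleosome_shift(np.zeros(11), np.zeros(13), W=5)
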