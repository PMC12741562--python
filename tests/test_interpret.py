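import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from rnamodnet.interpret import (Pwm, build_pwm, cluster_pwms,
                                 harvest_subsequences, metagene_profile,
                                 motif_score, scan_filter)
from rnamodnet.seqio import GenomicSite, TranscriptAnnotation
from rnamodnet.synthetic import consensus_pwm, generate_pwm_family


class TestScanFilter:
    def test_activation_count_and_sign(self, small_trained, small_split):
        _, te = small_split
        acts = scan_filter(small_trained, te[:10], 0)
        assert acts.shape == (10, 41 - small_trained.config.kernel_size + 1)
        assert (acts >= 0).all()

    def test_unknown_filter(self, small_trained):
        with pytest.raises(KeyError):
            scan_filter(small_trained, ["A" * 41], 999)

    def test_zero_weights_give_bias_activation(self, small_trained):
        net = small_trained
        saved = net.params["Wc"].copy(), net.params["bc"].copy()
        try:
            net.params["Wc"][:] = 0.0
            net.params["bc"][:] = -1.0
            acts = scan_filter(net, ["ACGU" * 10 + "A"], 0)
            np.testing.assert_allclose(acts, 0.0)  # ReLU clips the bias
            net.params["bc"][:] = 0.5
            acts = scan_filter(net, ["ACGU" * 10 + "A"], 0)
            np.testing.assert_allclose(acts, 0.5)
        finally:
            net.params["Wc"], net.params["bc"] = saved


class TestHarvest:
    def test_constant_activations_harvest_nothing(self):
        acts = np.ones((3, 5))
        with pytest.warns(UserWarning):
            subs, offs = harvest_subsequences(acts, ["ACGUACGUA"] * 3)
        assert subs == [] and len(offs) == 0

    def test_single_peak_harvested(self):
        acts = np.zeros((2, 5))
        acts[1, 3] = 10.0
        subs, offs = harvest_subsequences(acts, ["AAAAAAAAA", "ACGUACGUA"])
        assert subs == ["UACGU"] and list(offs) == [3]

    def test_planted_offset_is_histogram_mode(self, small_trained,
                                              small_windows):
        windows, truth = small_windows
        pos = [w for w in windows if w.label == 1]
        neg = [w for w in windows if w.label == 0]
        reports = [motif_score(small_trained, f, pos, neg)
                   for f in range(small_trained.config.conv_filters)]
        best = max(reports, key=lambda r: r.motif_score)
        assert best.motif_score > 0 and best.p_value < 0.01
        # harvested activation positions concentrate where a width-10
        # kernel overlaps the plant (motif span 12..19 -> starts 5..19),
        # and the planted offset itself is at or near the histogram peak
        hist = best.position_histogram
        mode = int(np.argmax(hist))
        assert 5 <= mode <= 19
        assert hist[12] >= 0.9 * hist.max()


class TestBuildPwm:
    def test_one_hot_rows_without_pseudocount(self):
        pwm = build_pwm(["ACGU"], pseudocount=0.0)
        np.testing.assert_array_equal(pwm.matrix, np.eye(4))

    def test_unanimous_column(self):
        pwm = build_pwm(["AAAA", "AAAA"], pseudocount=0.0)
        assert (pwm.matrix[:, 0] == 1.0).all()

    def test_direct_count(self):
        pwm = build_pwm(["AC", "GC"], pseudocount=0.0)
        np.testing.assert_allclose(pwm.matrix[0], [0.5, 0, 0.5, 0])
        np.testing.assert_allclose(pwm.matrix[1], [0, 1, 0, 0])

    def test_pseudocount_smoothing(self):
        pwm = build_pwm(["AAAA"], pseudocount=0.5)
        np.testing.assert_allclose(pwm.matrix[:, 0], 1.5 / 3.0)
        np.testing.assert_allclose(pwm.matrix.sum(axis=1), 1.0)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGU", "ACG"])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGU", min_size=6, max_size=6),
                    min_size=2, max_size=8))
    def test_permutation_invariance(self, subs):
        a = build_pwm(subs).matrix
        b = build_pwm(list(reversed(subs))).matrix
        np.testing.assert_allclose(a, b)


class TestMotifScore:
    def test_identical_classes_score_zero(self, small_trained, small_split):
        _, te = small_split
        r = motif_score(small_trained, 0, te[:20], te[:20])
        assert r.motif_score == pytest.approx(0.0)

    def test_score_is_mean_difference(self, small_trained, small_windows):
        windows, _ = small_windows
        pos = [w for w in windows if w.label == 1][:30]
        neg = [w for w in windows if w.label == 0][:30]
        r = motif_score(small_trained, 1, pos, neg)
        assert r.motif_score == pytest.approx(
            r.mean_activation_pos - r.mean_activation_neg, abs=1e-9)

    def test_empty_class_rejected(self, small_trained):
        with pytest.raises(ValueError):
            motif_score(small_trained, 0, [], ["A" * 41])


class TestClusterPwms:
    def test_duplicates_cluster_together(self):
        base = consensus_pwm("ACGUACGUAC")
        labels, _ = cluster_pwms([base, base, consensus_pwm("GGGGGGGGGG")],
                                 k=2)
        assert labels[0] == labels[1] != labels[2]

    def test_singletons_at_full_k(self):
        pwms = generate_pwm_family(consensus_pwm("ACGUACGUAC"), 4, noise=0.3,
                                   seed=1)
        labels, _ = cluster_pwms(pwms, k=4)
        assert len(set(labels)) == 4

    def test_two_families_perfectly_recovered(self):
        fam1 = generate_pwm_family(consensus_pwm("UUCGAAUCGG"), 10,
                                   noise=0.05, seed=2)
        fam2 = generate_pwm_family(consensus_pwm("GGGCCCGGAA"), 10,
                                   noise=0.05, seed=3)
        labels, _ = cluster_pwms(fam1 + fam2, k=2)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_mixed_widths_rejected(self):
        with pytest.raises(ValueError):
            cluster_pwms([consensus_pwm("ACGU"), consensus_pwm("ACGUA")], k=2)

    def test_need_k_or_height(self):
        with pytest.raises(ValueError):
            cluster_pwms([consensus_pwm("ACGU"), consensus_pwm("GGCC")])


def _coding_annotation(tmp_path, utr5=1000, cds=1000, utr3=1000):
    total = utr5 + cds + utr3
    gtf = (f'chr1\tt\texon\t1\t{total}\t.\t+\t.\ttranscript_id "t1";\n'
           f'chr1\tt\tCDS\t{utr5 + 1}\t{utr5 + cds}\t.\t+\t.\t'
           f'transcript_id "t1";\n')
    p = tmp_path / "meta.gtf"
    p.write_text(gtf)
    return TranscriptAnnotation.from_gtf(p)


class TestMetagene:
    def test_density_integrates_to_one(self, tmp_path):
        ann = _coding_annotation(tmp_path)
        sites = [GenomicSite("chr1", p) for p in range(0, 3000, 7)]
        centers, density, skipped = metagene_profile(sites, ann, bins=20)
        width = 3.0 / len(centers)
        assert (density * width).sum() == pytest.approx(1.0)
        assert skipped == 0

    def test_uniform_sites_give_flat_profile(self, tmp_path):
        ann = _coding_annotation(tmp_path)
        rng = np.random.default_rng(0)
        sites = [GenomicSite("chr1", int(p))
                 for p in rng.integers(0, 3000, size=6000)]
        _, density, _ = metagene_profile(sites, ann, bins=10)
        # uniform oracle: expected density 1/3 per unit of the 3-unit axis
        assert np.allclose(density, 1 / 3, atol=0.06)

    def test_stop_codon_spike(self, tmp_path):
        ann = _coding_annotation(tmp_path)
        sites = [GenomicSite("chr1", 1999)] * 50  # last CDS base
        centers, density, _ = metagene_profile(sites, ann, bins=10)
        assert centers[np.argmax(density)] == pytest.approx(1.95)

    def test_unannotated_sites_skipped_and_counted(self, tmp_path):
        ann = _coding_annotation(tmp_path)
        sites = [GenomicSite("chr1", 10), GenomicSite("chr9", 10)]
        _, _, skipped = metagene_profile(sites, ann, bins=5)
        assert skipped == 1
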