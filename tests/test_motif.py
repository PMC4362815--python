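import itertools

import numpy as np
import pytest

from regulomics.core import ChromSizes, GenomicInterval, RegionSet
from regulomics.motif import (
    PWM,
    DEFAULT_PRECISION,
    MotifHit,
    annotate_hits,
    occupancy_curve,
    read_meme,
    read_pwm_tsv,
    scan_genome,
    score_pvalue,
    score_site,
    score_threshold,
    write_pwm_tsv,
)
from regulomics.simulate import default_pwm


def _random_pwm(rng, width, motif_id="m"):
    freq = rng.dirichlet(np.ones(4) * 0.7, size=width)
    freq = np.clip(freq, 1e-3, None)
    freq /= freq.sum(axis=1, keepdims=True)
    bg = rng.dirichlet(np.ones(4) * 5.0)
    return PWM(motif_id, freq, background=bg)


def _enumerate(pwm):
    """Exact (score, probability) for every W-mer under the background."""
    lo = pwm.log_odds
    scores, probs = [], []
    for word in itertools.product(range(4), repeat=pwm.width):
        scores.append(sum(lo[i, b] for i, b in enumerate(word)))
        probs.append(np.prod([pwm.background[b] for b in word]))
    return np.array(scores), np.array(probs)


class TestPWM:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PWM("bad", [[0.5, 0.1, 0.1, 0.1]])

    def test_zero_probability_needs_pseudocount(self):
        with pytest.raises(ValueError):
            PWM("bad", [[1.0, 0.0, 0.0, 0.0]])
        pwm = PWM("ok", [[1.0, 0.0, 0.0, 0.0]], pseudocount=0.01)
        assert (pwm.freq > 0).all()
        assert pwm.freq[0].sum() == pytest.approx(1.0)

    def test_consensus_and_rc(self):
        pwm = PWM(
            "m",
            [[0.97, 0.01, 0.01, 0.01], [0.01, 0.01, 0.01, 0.97]],
        )
        assert pwm.consensus() == "AT"
        assert pwm.reverse_complement().consensus() == "AT"  # AT is its own RC


class TestScoreSite:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("flat", np.full((5, 4), 0.25))
        assert score_site(pwm, "ACGTA") == pytest.approx(0.0)

    def test_hand_computed(self):
        pwm = PWM(
            "m",
            [[0.97, 0.01, 0.01, 0.01], [0.01, 0.01, 0.01, 0.97]],
        )
        expected = 2 * np.log2(0.97 / 0.25)
        assert score_site(pwm, "AT") == pytest.approx(expected)
        assert score_site(pwm, "AT") == pytest.approx(3.9121, abs=1e-4)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(0)
        pwm = _random_pwm(rng, 6)
        seq = "ACGTGC"
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert score_site(pwm.reverse_complement(), rc) == pytest.approx(
            score_site(pwm, seq)
        )

    def test_ambiguous_base_rejected(self):
        pwm = PWM("flat", np.full((3, 4), 0.25))
        with pytest.raises(ValueError):
            score_site(pwm, "ANT")


class TestScorePvalue:
    @pytest.mark.parametrize("width", [2, 4, 6, 8])
    def test_dp_matches_enumeration(self, width):
        rng = np.random.default_rng(width)
        pwm = _random_pwm(rng, width)
        scores, probs = _enumerate(pwm)
        slack = width * DEFAULT_PRECISION  # grid-induced bracketing
        for q in (0.01, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99, 1.0):
            ts = float(np.quantile(scores, q))
            p_dp = score_pvalue(pwm, ts)
            p_hi = probs[scores >= ts - slack].sum()
            p_lo = probs[scores >= ts + slack].sum()
            assert p_lo - 1e-12 <= p_dp <= p_hi + 1e-12

    def test_max_score_closed_form(self):
        rng = np.random.default_rng(99)
        pwm = _random_pwm(rng, 5)
        best = np.prod(
            [pwm.background[pwm.log_odds[i].argmax()] for i in range(5)]
        )
        assert score_pvalue(pwm, pwm.max_score) == pytest.approx(best, rel=1e-9)

    def test_min_score_p_is_one(self):
        rng = np.random.default_rng(7)
        pwm = _random_pwm(rng, 4)
        assert score_pvalue(pwm, pwm.min_score) == 1.0
        assert score_pvalue(pwm, -1e9) == 1.0

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(13)
        pwm = _random_pwm(rng, 7)
        sweep = np.linspace(pwm.min_score, pwm.max_score, 200)
        ps = [score_pvalue(pwm, s) for s in sweep]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bad_precision(self):
        pwm = PWM("flat", np.full((3, 4), 0.25))
        with pytest.raises(ValueError):
            score_pvalue(pwm, 0.0, precision=0)


class TestScanGenome:
    def test_planted_consensus_recovered(self):
        rng = np.random.default_rng(42)
        pwm = default_pwm()
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        seq = seq[:5000] + pwm.consensus() + seq[5000 + pwm.width :]
        hits = scan_genome(pwm, {"c": seq}, p_threshold=1e-4)
        assert any(
            h.interval.start == 5000 and h.interval.strand == "+" for h in hits
        )

    def test_p_threshold_one_hits_everywhere(self):
        pwm = PWM("flat", np.full((3, 4), 0.25))
        hits = scan_genome(pwm, {"c": "ACGTACGT"}, p_threshold=1.0)
        assert len(hits) == 2 * (8 - 3 + 1)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(8)
        pwm = default_pwm(width=6)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        fwd = scan_genome(pwm, {"c": seq}, p_threshold=1e-2)
        rev = scan_genome(pwm, {"c": rc}, p_threshold=1e-2)
        n = len(seq)
        mirrored = sorted(
            (n - h.interval.end, "+" if h.interval.strand == "-" else "-",
             round(h.score, 6))
            for h in rev
        )
        original = sorted(
            (h.interval.start, h.interval.strand, round(h.score, 6)) for h in fwd
        )
        assert original == mirrored

    def test_unknown_chromosome_rejected(self):
        pwm = PWM("flat", np.full((3, 4), 0.25))
        with pytest.raises(ValueError):
            scan_genome(
                pwm, {"weird": "ACGT"}, genome=ChromSizes({"chr1": 100})
            )

    def test_ambiguous_windows_skipped(self):
        pwm = PWM("flat", np.full((3, 4), 0.25))
        hits = scan_genome(pwm, {"c": "ACNGT"}, p_threshold=1.0)
        # windows [0,3) and [2,5) contain N; only [1,4)... also has N at idx 2
        starts = {h.interval.start for h in hits}
        assert 0 not in starts and 1 not in starts and 2 not in starts


class TestOccupancyCurve:
    def _hits(self, rng, n=500):
        hits = []
        for i in range(n):
            hits.append(
                MotifHit(
                    interval=GenomicInterval("chr1", 10 * i, 10 * i + 5),
                    score=float(rng.uniform(0, 10)),
                    p_value=1e-5,
                    in_open_chromatin=bool(rng.random() < 0.5),
                    bound=bool(rng.random() < 0.3),
                )
            )
        return hits

    def test_no_peaks_all_zero(self, rng):
        hits = self._hits(rng)
        for h in hits:
            h.bound = False
        curve = occupancy_curve(hits)
        populated = curve.dropna(subset=["frac_bound_in_open"])
        assert (populated["frac_bound_in_open"] == 0).all()

    def test_everything_bound_all_one(self, rng):
        hits = self._hits(rng)
        for h in hits:
            h.bound = True
        curve = occupancy_curve(hits)
        for col in ("frac_bound_in_open", "frac_bound_outside"):
            vals = curve[col].dropna()
            assert (vals == 1).all()

    def test_counts_partition_hits(self, rng):
        hits = self._hits(rng)
        curve = occupancy_curve(hits)
        assert curve["n_in_open"].sum() + curve["n_outside"].sum() == len(hits)

    def test_fractions_in_unit_interval(self, rng):
        curve = occupancy_curve(self._hits(rng))
        for col in ("frac_bound_in_open", "frac_bound_outside"):
            vals = curve[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_empty_bins_reported_nan_not_zero(self):
        hits = [
            MotifHit(GenomicInterval("chr1", 0, 5), 0.5, 1e-5, True, True),
            MotifHit(GenomicInterval("chr1", 10, 15), 5.5, 1e-5, True, False),
        ]
        curve = occupancy_curve(hits, bin_width=1.0)
        middle = curve[(curve["bin_left"] > 0.5) & (curve["bin_left"] < 5)]
        assert middle["frac_bound_in_open"].isna().all()

    def test_unannotated_hits_rejected(self):
        hits = [MotifHit(GenomicInterval("chr1", 0, 5), 0.5, 1e-5)]
        with pytest.raises(ValueError):
            occupancy_curve(hits)

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            occupancy_curve([], bin_width=0)

    def test_annotate_hits_flags(self):
        peaks = RegionSet([GenomicInterval("chr1", 0, 10)])
        open_regions = RegionSet([GenomicInterval("chr1", 100, 200)])
        hits = [
            MotifHit(GenomicInterval("chr1", 5, 12), 1.0, 1e-5),
            MotifHit(GenomicInterval("chr1", 150, 157), 1.0, 1e-5),
        ]
        annotate_hits(hits, peaks, open_regions)
        assert hits[0].bound and not hits[0].in_open_chromatin
        assert not hits[1].bound and hits[1].in_open_chromatin


class TestPwmIO:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        pwm = _random_pwm(rng, 5)
        path = str(tmp_path / "m.tsv")
        write_pwm_tsv(pwm, path)
        back = read_pwm_tsv(path, "m")
        np.testing.assert_allclose(back.freq, pwm.freq, atol=1e-12)

    def test_meme_minimal_format(self, tmp_path):
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.3 C 0.2 G 0.2 T 0.3\n\n"
            "MOTIF TEST1\n"
            "letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0\n"
            " 0.7 0.1 0.1 0.1\n"
            " 0.1 0.7 0.1 0.1\n"
            " 0.1 0.1 0.1 0.7\n"
        )
        path = tmp_path / "m.meme"
        path.write_text(text)
        pwms = read_meme(str(path))
        assert len(pwms) == 1
        assert pwms[0].motif_id == "TEST1"
        assert pwms[0].width == 3
        assert pwms[0].consensus() == "ACT"
        np.testing.assert_allclose(pwms[0].background, [0.3, 0.2, 0.2, 0.3])


def test_threshold_inversion_consistent():
    rng = np.random.default_rng(2)
    pwm = _random_pwm(rng, 6)
    for p in (1e-2, 1e-3, 1e-4):
        cutoff = score_threshold(pwm, p)
        assert score_pvalue(pwm, cutoff) <= p
        assert score_pvalue(pwm, cutoff - 2 * DEFAULT_PRECISION) > p
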