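"""PWMs, scoring, thresholding, EM discovery, MEME I/O."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonkit.genomes import UpstreamRegion, reverse_complement
from regulonkit.motifs import (
    PWM,
    Profile,
    build_pwm,
    discover_motif,
    encode,
    estimate_background,
    project_symmetry,
    read_meme,
    scan,
    score_sequence,
    score_site,
    set_threshold,
    write_meme,
)


def region(seq, name="r1", genome="g"):
    return UpstreamRegion(
        operon=name, genome=genome, sequence=seq, offset_of_start=0,
        window=(len(seq), 0), strand="+", n_upstream=len(seq),
    )


class TestBuildPWM:
    def test_consensus_counting_with_shared_pseudocount(self):
        pwm = build_pwm(["TGACA", "TGACA"], pseudocount=0.5)
        f = pwm.frequencies
        # consensus base gets (2 + 0.5)/(2 + 2), the rest 0.5/(2+2) each
        assert f[0, 3] == pytest.approx(2.5 / 4)
        assert f[0, 0] == pytest.approx(0.5 / 4)
        assert np.allclose(f.sum(axis=1), 1.0)

    def test_palindrome_matrix_equals_its_reverse_complement(self):
        pwm = build_pwm(["TGACAA", "TGACAT", "GGACAT"], symmetry="palindrome")
        f = pwm.frequencies
        assert np.allclose(f, f[::-1, ::-1], atol=1e-9)

    def test_frequencies_recover_sampling_distribution(self):
        rng = np.random.default_rng(3)
        truth = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.6, 0.2, 0.1]] * 3)
        sites = [
            "".join("ACGT"[rng.choice(4, p=row)] for row in truth)
            for _ in range(200)
        ]
        pwm = build_pwm(sites, pseudocount=0.5)
        # multinomial CI at n=200: within ~3 sigma of truth
        sigma = np.sqrt(truth * (1 - truth) / 200)
        assert np.all(np.abs(pwm.frequencies - truth) < 3.5 * sigma + 0.01)

    def test_unequal_lengths_and_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"])
        with pytest.raises(ValueError):
            build_pwm(["ACGN", "ACGT"])
        with pytest.raises(ValueError):
            build_pwm(["ACGT"])


class TestSymmetryProjection:
    @given(st.integers(0, 2**31 - 1), st.sampled_from(
        ["palindrome", "direct_repeat", "inverted_repeat", "none"]
    ))
    @settings(max_examples=40, deadline=None)
    def test_projection_is_idempotent(self, seed, symmetry):
        rng = np.random.default_rng(seed)
        counts = rng.random((10, 4)) * 20
        spacer = 2 if symmetry in ("direct_repeat", "inverted_repeat") else 0
        once = project_symmetry(counts, symmetry, spacer)
        twice = project_symmetry(once, symmetry, spacer)
        assert np.allclose(once, twice, atol=1e-10)

    def test_spacer_columns_sit_at_background(self):
        counts = np.ones((10, 4)) * 5
        counts[4] = [20, 0, 0, 0]
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        out = project_symmetry(counts, "direct_repeat", spacer=2, background=bg)
        assert np.allclose(out[4], counts[4].sum() * bg)


class TestScoring:
    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = PWM(np.ones((4, 4)), pseudocount=0.0)
        scores = score_sequence(pwm, "ACGTACGT")
        assert np.allclose(scores.forward, 0.0)
        assert np.allclose(scores.reverse, 0.0)

    def test_consensus_attains_the_maximum_score(self):
        pwm = build_pwm(["TGACGTCA", "TGACGTCA", "TGACTTCA"])
        assert score_site(pwm, pwm.consensus) == pytest.approx(pwm.max_score())

    def test_extremes_match_exhaustive_enumeration_of_4mers(self):
        """Max/min over all 256 words equals brute-force enumeration."""
        rng = np.random.default_rng(9)
        pwm = PWM(rng.random((4, 4)) * 10, pseudocount=0.5)
        lo = pwm.log_odds
        brute = {}
        for word in itertools.product("ACGT", repeat=4):
            s = 0.0
            for i, b in enumerate(word):
                s += lo[i, "ACGT".index(b)]
            brute["".join(word)] = s
        scores = {w: score_site(pwm, w) for w in brute}
        assert max(scores.values()) == pytest.approx(max(brute.values()))
        assert min(scores.values()) == pytest.approx(min(brute.values()))
        best = max(brute, key=brute.get)
        assert scores[best] == pytest.approx(brute[best])

    def test_non_acgt_positions_are_skipped(self):
        pwm = build_pwm(["ACGT", "ACGT"])
        scores = score_sequence(pwm, "ACGTNACGT")
        assert np.isfinite(scores.forward[0])
        assert np.isnan(scores.forward[2])  # window covers the N


class TestThreshold:
    def test_threshold_is_minimum_training_score(self):
        pwm = build_pwm(["TGACGTCA", "TGTCGACA", "TGACGACA"])
        sites = ["TGACGTCA", "TGTCGACA", "TGACGACA"]
        expected = min(score_site(pwm, s) for s in sites)
        assert set_threshold(pwm, sites) == expected

    def test_single_site_threshold(self):
        pwm = build_pwm(["TGACGTCA", "TGACGTCA"])
        assert set_threshold(pwm, ["TGACGTCA"]) == score_site(pwm, "TGACGTCA")

    def test_adding_weaker_site_lowers_threshold_monotonically(self):
        pwm = build_pwm(["TGACGTCA", "TGACGTCA"])
        t1 = set_threshold(pwm, ["TGACGTCA"])
        t2 = set_threshold(pwm, ["TGACGTCA", "TTTTGTCA"])
        assert t2 <= t1

    def test_empty_training_set_is_an_error(self):
        pwm = build_pwm(["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            set_threshold(pwm, [])


class TestScan:
    def _profile(self):
        sites = ["TGACGTCA", "TGCCGGCA"]
        pwm = build_pwm(sites, symmetry="palindrome")
        return Profile(pwm=pwm, training_sites=sites, name="t")

    def test_training_site_recovered_in_its_own_region(self):
        prof = self._profile()
        r = region("TTTT" + "TGACGTCA" + "TTTT")
        sites = scan(prof, [r])
        assert any(s.offset == 4 for s in sites)

    def test_gc_rich_pwm_finds_nothing_in_poly_a(self):
        sites = ["GCGCGCGC", "GGGCGCCC"]
        pwm = build_pwm(sites, background=np.full(4, 0.25))
        prof = Profile(pwm=pwm, training_sites=sites, name="gc")
        assert scan(prof, [region("A" * 60)]) == []

    def test_translation_equivariance_under_prefix(self):
        prof = self._profile()
        base = "ATATGCGTAC" + "TGACGTCA" + "CCGGAAGTTA"
        hits0 = scan(prof, [region(base)])
        hits7 = scan(prof, [region("ACCGTTA" + base)])
        assert [s.offset + 7 for s in hits0] == [s.offset for s in hits7]
        assert [s.score for s in hits0] == pytest.approx([s.score for s in hits7])

    def test_reverse_complement_maps_offsets_and_preserves_scores(self):
        prof = self._profile()
        seq = "ATATGCGTAC" + "TGACGTCA" + "CCGGAAGTTA"
        fwd = scan(prof, [region(seq)])
        rev = scan(prof, [region(reverse_complement(seq))])
        w = prof.pwm.width
        L = len(seq)
        mapped = sorted(L - s.offset - w for s in fwd)
        assert mapped == sorted(s.offset for s in rev)
        assert sorted(s.score for s in fwd) == pytest.approx(
            sorted(s.score for s in rev)
        )

    def test_output_sorted_by_region_then_offset(self):
        prof = self._profile()
        regions = [
            region("TT" + "TGACGTCA" + "TT" + "TGACGTCA", name="b"),
            region("TGACGTCA" + "TTTT", name="a"),
        ]
        sites = scan(prof, regions)
        keys = [(s.region, s.offset) for s in sites]
        assert keys == sorted(keys)


class TestDiscover:
    def test_noiseless_palindromic_word_is_recovered_everywhere(self):
        rng = np.random.default_rng(4)
        word = "TTGACCGGTCAA"  # 12-bp palindrome
        regions = []
        for i in range(20):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 80))
            off = int(rng.integers(0, 80 - 12))
            regions.append(seq[:off] + word + seq[off + 12:])
        result = discover_motif(
            regions, width_range=(12, 16), width_step=2,
            symmetry="palindrome", n_restarts=8, seed=0,
        )
        assert result.width == 12
        assert result.pwm.consensus == word
        assert len(result.sites) == 20

    def test_palindrome_mode_returns_self_reverse_complement_pwm(self):
        rng = np.random.default_rng(5)
        regions = [
            "".join("ACGT"[b] for b in rng.integers(0, 4, 60)) for _ in range(6)
        ]
        result = discover_motif(
            regions, width_range=(8, 8), symmetry="palindrome",
            n_restarts=3, seed=1,
        )
        f = result.pwm.frequencies
        assert np.allclose(f, f[::-1, ::-1], atol=1e-9)

    def test_objective_trace_is_non_decreasing(self):
        rng = np.random.default_rng(6)
        regions = [
            "".join("ACGT"[b] for b in rng.integers(0, 4, 50)) for _ in range(5)
        ]
        result = discover_motif(
            regions, width_range=(6, 6), symmetry="none", n_restarts=2, seed=2,
        )
        trace = np.array(result.objective_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        regions = [
            "".join("ACGT"[b] for b in rng.integers(0, 4, 60)) for _ in range(5)
        ]
        r1 = discover_motif(regions, width_range=(8, 10), n_restarts=3, seed=5)
        r2 = discover_motif(regions, width_range=(8, 10), n_restarts=3, seed=5)
        assert np.array_equal(r1.pwm.counts, r2.pwm.counts)
        assert r1.log_likelihood == r2.log_likelihood

    def test_short_regions_excluded_and_all_short_is_error(self):
        with pytest.raises(ValueError):
            discover_motif(["ACGT", "ACGTA", "CCGT"], width_range=(8, 8))

    def test_em_matches_exhaustive_assignment_oracle_on_tiny_instance(self):
        """On a 5-region toy instance the EM solution dominates (and its
        site calls equal) a brute-force search over all one-site-per-
        region placements, each evaluated through an independent
        implementation of the penalized marginal likelihood."""
        rng = np.random.default_rng(8)
        word = "ACGT"  # its own reverse complement
        regions = []
        for i in range(5):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 10))
            off = int(rng.integers(0, 7))
            regions.append(seq[:off] + word + seq[off + 4:])
        w, gamma, pc = 4, 0.8, 0.5
        bg = estimate_background(regions)

        def marginal_ll(freq):
            # independent implementation: plain python/math loops
            total = 4 * pc * sum(
                bg[b] * math.log2(freq[i][b]) for i in range(w) for b in range(4)
            )
            for seq in regions:
                n = len(seq) - w + 1
                acc = (1 - gamma)
                for j in range(n):
                    for strand in (0, 1):
                        sub = seq[j : j + w]
                        if strand:
                            sub = reverse_complement(sub)
                        ratio = 1.0
                        for i, base in enumerate(sub):
                            b = "ACGT".index(base)
                            ratio *= freq[i][b] / bg[b]
                        acc += gamma / (2 * n) * ratio
                total += math.log2(acc)
            return total

        best_oracle, best_assign = -np.inf, None
        for assign in itertools.product(range(7), repeat=5):
            counts = np.zeros((w, 4))
            for seq, j in zip(regions, assign):
                for i, base in enumerate(seq[j : j + w]):
                    counts[i, "ACGT".index(base)] += 1
            freq = (counts + 4 * pc * bg) / (counts.sum(axis=1, keepdims=True) + 4 * pc)
            ll = marginal_ll(freq)
            if ll > best_oracle:
                best_oracle, best_assign = ll, assign

        result = discover_motif(
            regions, width_range=(4, 4), symmetry="none", n_restarts=20, seed=3,
        )
        assert result.log_likelihood >= best_oracle - 1e-6
        found = {s.region: s.offset for s in result.sites}
        assert found == {f"region{i}": j for i, j in enumerate(best_assign)}


class TestMemeIO:
    def test_roundtrip_preserves_frequencies_and_symmetry(self, tmp_path):
        sites = ["TGACGTCA", "TGCCGGCA", "TGACGCCA"]
        pwm = build_pwm(sites, symmetry="palindrome")
        prof = Profile(pwm=pwm, training_sites=sites, name="regX")
        path = tmp_path / "m.meme"
        write_meme([prof], path)
        back = read_meme(path)["regX"]
        assert back.symmetry == "palindrome"
        assert np.allclose(back.frequencies, pwm.frequencies, atol=2e-3)
        assert np.allclose(back.background, pwm.background, atol=1e-5)

    def test_biopython_parses_emitted_minimal_format(self, tmp_path):
        from Bio import motifs as bio_motifs

        rng = np.random.default_rng(11)
        sites = [
            "".join("ACGT"[b] for b in rng.integers(0, 4, 8)) for _ in range(400)
        ]
        pwm = build_pwm(sites)
        path = tmp_path / "m.meme"
        write_meme([pwm], path, names=["m1"])
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "minimal")
        assert len(parsed) == 1
        # Biopython reconstructs integer counts from nsites, so compare at
        # the counts-rounding resolution
        got = np.array([parsed[0].pwm[b] for b in "ACGT"]).T
        assert np.allclose(got, pwm.frequencies, atol=5e-3)
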