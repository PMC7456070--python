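"""Base-pair maximization, permutation null and PRF-signal calling."""
import numpy as np
import pytest

from prfscan import (
    ScanConfig,
    TranscriptModel,
    call_prf_signal,
    find_slippery_sites,
    max_basepair_fold,
    permutation_zscore,
)

from _oracles import dotbracket_pairs, exhaustive_max_pairs

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def random_seq(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))


class TestMaxBasepairFold:
    @pytest.mark.parametrize(
        "seq,min_loop,score",
        [
            ("AAAAAAAAAA", 3, 0),  # no complementary pairs
            ("GGGAAAACCC", 3, 3),
            ("GCGC", 3, 0),  # no pair satisfies j - i > min_loop
            ("GAAAC", 3, 1),  # loop of exactly min_loop unpaired bases
            ("GAAC", 3, 0),  # pair needs j - i > min_loop
        ],
    )
    def test_known_scores(self, seq, min_loop, score):
        got, structure = max_basepair_fold(seq, min_loop)
        assert got == score
        assert len(structure) == len(seq)

    def test_matches_exhaustive_oracle_short_sequences(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            n = int(rng.integers(1, 13))
            seq = random_seq(rng, n)
            for min_loop in (0, 1, 3):
                score, structure = max_basepair_fold(seq, min_loop)
                assert score == exhaustive_max_pairs(seq, min_loop), (seq, min_loop)
                self._check_structure(seq, structure, score, min_loop)

    @staticmethod
    def _check_structure(seq, structure, score, min_loop):
        pairs = dotbracket_pairs(structure)
        assert len(pairs) == score == structure.count("(")
        for i, j in pairs:
            assert (seq[i], seq[j]) in _PAIRS
            assert j - i > min_loop

    def test_structure_valid_on_longer_windows(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = random_seq(rng, 70)
            score, structure = max_basepair_fold(seq)
            self._check_structure(seq, structure, score, 3)

    def test_min_loop_monotonicity(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            seq = random_seq(rng, int(rng.integers(5, 60)))
            scores = [max_basepair_fold(seq, ml)[0] for ml in (0, 1, 2, 3, 5, 8)]
            assert scores == sorted(scores, reverse=True)

    def test_deterministic(self):
        seq = "GGCGAAAGCGCCAUUAGCUAAUGG"
        assert max_basepair_fold(seq) == max_basepair_fold(seq)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            max_basepair_fold("")


class TestPermutationZscore:
    def test_homopolymer_degenerate(self):
        null = permutation_zscore("A" * 30, n_perm=50, seed=0)
        assert null.degenerate
        assert null.z == 0.0
        assert null.p_perm == 1.0

    def test_reproducible_given_seed(self):
        seq = "GGCGAAAGCGCCAUUAGCUAAUGGACGUACGU"
        a = permutation_zscore(seq, n_perm=100, seed=42)
        b = permutation_zscore(seq, n_perm=100, seed=42)
        assert a == b
        c = permutation_zscore(seq, n_perm=100, seed=43)
        assert (a.z, a.p_perm) != (c.z, c.p_perm)  # different null draw

    def test_planted_hairpin_scores_above_null(self):
        stem = "GCAUGGCAUCGAUGCAUGGCAUCG"
        comp = stem.translate(str.maketrans("ACGU", "UGCA"))[::-1]
        window = stem + "GAAA" + comp + "ACGUACGUACGUACGU"
        null = permutation_zscore(window, n_perm=100, seed=3)
        assert not null.degenerate
        assert null.z > 2.0
        assert null.p_perm <= 1 / 101 * 2  # at most one shuffle ties


class TestCallPrfSignal:
    def _planted_model(self, rng, stem_len=24, spacer=6):
        stem = random_seq(rng, stem_len)
        comp = stem.translate(str.maketrans("ACGU", "UGCA"))[::-1]
        cassette = "GGGUUUC" + random_seq(rng, spacer) + stem + "GAAA" + comp
        pad = (-len(cassette) - 2) % 3
        cds = (
            "AUGGC"  # site start = 5 (= 2 mod 3)
            + cassette
            + random_seq(rng, pad + 30)
            + "UAA"
        )
        n = len(cds)
        cds = cds[: n - n % 3] if n % 3 else cds
        while len(cds) % 3:
            cds += "A"
        return TranscriptModel("t", cds)

    def test_site_near_cds_end_has_no_element(self):
        cds = "AUGCC" + "GGGUUUC"  # heptamer ends at the CDS end
        model = TranscriptModel("t", cds)
        (site,) = [s for s in find_slippery_sites(model) if s.trna_class == "phe"]
        sig = call_prf_signal(model, site)
        assert sig.element is None
        assert not sig.passes

    def test_planted_hairpin_passes(self):
        rng = np.random.default_rng(17)
        config = ScanConfig(seed=9)
        for _ in range(10):
            model = self._planted_model(rng)
            sites = [s for s in find_slippery_sites(model, config) if s.trna_class == "phe"]
            site = next(s for s in sites if s.start == 5)
            sig = call_prf_signal(model, site, config)
            assert sig.element is not None
            assert sig.element.pair_score >= 24
            assert sig.passes

    def test_window_reslices_and_spacer_in_range(self):
        rng = np.random.default_rng(19)
        config = ScanConfig(seed=2)
        model = self._planted_model(rng)
        site = next(s for s in find_slippery_sites(model, config) if s.start == 5)
        sig = call_prf_signal(model, site, config)
        e = sig.element
        assert config.min_spacer <= e.spacer <= config.max_spacer
        assert e.window_start == site.start + 7 + e.spacer
        assert e.window_end - e.window_start <= config.window_len
        assert len(e.structure) == e.window_end - e.window_start
        assert e.structure.count("(") == e.pair_score

    def test_shuffled_windows_rarely_pass(self):
        """With the hairpin replaced by shuffled bases the call is a test at
        alpha = 0.05, so the null pass rate must stay near that level."""
        rng = np.random.default_rng(23)
        config = ScanConfig(seed=31, n_perm=100)
        passes = 0
        n_constructs = 300
        for _ in range(n_constructs):
            # same geometry, fully random downstream content
            cds = "AUGGC" + "GGGUUUC" + random_seq(rng, 84) + "UAA"
            model = TranscriptModel("t", cds)
            site = next(s for s in find_slippery_sites(model, config) if s.start == 5)
            passes += call_prf_signal(model, site, config).passes
        # null 5% + 4 binomial sd margin
        assert passes / n_constructs <= 0.09
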