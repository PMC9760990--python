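"""PPM/PWM construction, scanning, consensus calling, and filter comparison."""

import math

import numpy as np
import pytest

import eboxnet as eb
from eboxnet.interpretation import (
    PositionMatrix,
    compare_filters,
    consensus_from_ppm,
    extract_all_filter_ppms,
    extract_filter_ppm,
    identify_motif_filters,
    information_content,
    motif_match,
    ppm_to_pwm,
    pwm_scan,
    top_information_filter,
)

UNIFORM = PositionMatrix(np.full((4, 3), 0.25))


class TestPositionMatrix:
    def test_probability_columns_must_be_stochastic(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PositionMatrix(np.full((4, 2), 0.3))
        with pytest.raises(ValueError, match="negative"):
            PositionMatrix(np.array([[1.2], [-0.2], [0.0], [0.0]]))

    def test_shape_enforced(self):
        with pytest.raises(ValueError, match="4xN"):
            PositionMatrix(np.full((3, 2), 1 / 3))

    def test_from_counts_adds_pseudocount_and_normalises(self):
        counts = np.zeros((4, 1))
        counts[0, 0] = 9.0
        ppm = PositionMatrix.from_counts(counts, pseudocount=0.5)
        assert ppm.values[:, 0] == pytest.approx([9.5 / 11, 0.5 / 11, 0.5 / 11, 0.5 / 11])


class TestPpmToPwm:
    def test_uniform_column_maps_to_zeros(self):
        pwm = ppm_to_pwm(UNIFORM, pseudocount=0.0)
        assert np.allclose(pwm.values, 0.0)

    def test_deterministic_column_formula(self):
        ppm = PositionMatrix(np.array([[1.0], [0.0], [0.0], [0.0]]))
        pwm = ppm_to_pwm(ppm, pseudocount=0.001)
        assert pwm.values[0, 0] == pytest.approx(math.log2((1.001 / 1.004) / 0.25))
        assert pwm.values[1, 0] == pytest.approx(math.log2((0.001 / 1.004) / 0.25))

    def test_background_exponentiation_identity(self):
        # sum_b q_b 2^pwm(b,j) = 1 for every column when pseudocount = 0
        rng = np.random.default_rng(0)
        cols = rng.dirichlet(np.ones(4), size=6).T
        pwm = ppm_to_pwm(PositionMatrix(cols), pseudocount=0.0)
        with np.errstate(divide="ignore"):
            total = (0.25 * np.exp2(pwm.values)).sum(axis=0)
        assert np.allclose(total, 1.0)

    def test_round_trip_recovers_pseudocounted_ppm(self):
        rng = np.random.default_rng(1)
        cols = rng.dirichlet(np.ones(4), size=8).T
        eps = 0.001
        pwm = ppm_to_pwm(PositionMatrix(cols), pseudocount=eps)
        back = 0.25 * np.exp2(pwm.values)
        back /= back.sum(axis=0, keepdims=True)
        assert np.allclose(back, (cols + eps) / (1 + 4 * eps), atol=1e-9)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            ppm_to_pwm(UNIFORM, background=(0.5, 0.5, 0.0, 0.0))


class TestPwmScan:
    CANON = ppm_to_pwm(eb.canonical_ppm())

    def test_finds_planted_motif_offset(self):
        seq = "A" * 10 + "CACGTG" + "A" * 10
        hit = pwm_scan(self.CANON, seq)
        assert hit.offset == 10

    def test_sequence_shorter_than_motif_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            pwm_scan(self.CANON, "ACGT")

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            width = rng.integers(2, 7)
            cols = rng.dirichlet(np.ones(4), size=width).T
            pwm = ppm_to_pwm(PositionMatrix(cols))
            L = rng.integers(width, 40)
            seq = "".join(rng.choice(list("ACGT"), size=L))
            best_score, best_off = -np.inf, -1
            for off in range(L - width + 1):
                s = sum(pwm.values["ACGT".index(seq[off + j]), j] for j in range(width))
                if s > best_score:
                    best_score, best_off = s, off
            hit = pwm_scan(pwm, seq)
            assert hit.score == pytest.approx(best_score, abs=1e-9)
            assert hit.offset == best_off

    def test_n_bases_use_background_weighted_average(self):
        pwm = ppm_to_pwm(PositionMatrix(np.array([[0.7], [0.1], [0.1], [0.1]])))
        expected = float(0.25 * pwm.values[:, 0].sum())
        assert pwm_scan(pwm, "N").score == pytest.approx(expected)

    def test_both_strands_finds_reverse_complement_instance(self):
        noncanon = ppm_to_pwm(eb.noncanonical_ppm())
        inst = "GGGGCGGCTGGGA"
        rc = inst.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq = "AT" * 20 + rc + "AT" * 20
        fwd = pwm_scan(noncanon, seq).score
        both = pwm_scan(noncanon, seq, both_strands=True).score
        assert both > fwd


class TestConsensusAndMatch:
    def test_uniform_column_ties_to_a_with_zero_ic(self):
        cons, ic = consensus_from_ppm(UNIFORM)
        assert cons == "AAA"
        assert np.allclose(ic, 0.0)

    def test_sharp_column_ic_matches_entropy_formula(self):
        col = np.array([[0.9], [0.033], [0.033], [0.034]])
        cons, ic = consensus_from_ppm(PositionMatrix(col))
        h = -sum(p * math.log2(p) for p in col[:, 0])
        assert cons == "A"
        assert ic[0] == pytest.approx(2 - h)
        assert ic[0] == pytest.approx(1.37, abs=0.02)

    def test_ground_truth_canonical_consensus(self):
        assert consensus_from_ppm(eb.canonical_ppm())[0] == "CACGTG"

    @pytest.mark.parametrize(
        "consensus,target,expected",
        [
            ("AACACGTGAA", "CACGTG", (2, 6)),
            ("AAAAAA", "CACGTG", (0, 1)),  # enumeration: best is 1 match (the A)
        ],
    )
    def test_motif_match_examples(self, consensus, target, expected):
        assert motif_match(consensus, target) == expected

    def test_motif_match_consistent_under_reversal(self):
        consensus, target = "GGCACGTGAA", "CACGTG"
        off, n = motif_match(consensus, target)
        off_r, n_r = motif_match(consensus[::-1], target[::-1])
        assert n == n_r
        assert off_r == len(consensus) - len(target) - off

    def test_target_longer_than_consensus_raises(self):
        with pytest.raises(ValueError, match="longer"):
            motif_match("ACG", "ACGT")


class TestCompareFilters:
    def test_identical_pwms_give_all_ties(self):
        pwm = ppm_to_pwm(eb.canonical_ppm())
        seqs = ["ACGTACGTACGT", "CACGTGCACGTG"]
        table = compare_filters(pwm, pwm, seqs, "same")
        assert (table.n_wins_a, table.n_wins_b, table.n_ties) == (0, 0, 2)

    def test_counts_partition_the_set(self):
        rng = np.random.default_rng(3)
        pwm_a = ppm_to_pwm(eb.canonical_ppm())
        pwm_b = ppm_to_pwm(eb.noncanonical_ppm())
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(40)]
        t = compare_filters(pwm_a, pwm_b, seqs, "rand")
        assert t.n_wins_a + t.n_wins_b + t.n_ties == t.n_sequences == 40

    def test_ground_truth_pwms_separate_their_own_target_sets(self, small_study):
        act = [s for _, s in small_study["activation"]]
        rep = [s for _, s in small_study["repression"]]
        pwm_c = ppm_to_pwm(eb.canonical_ppm())
        pwm_n = ppm_to_pwm(eb.noncanonical_ppm())
        ta = compare_filters(pwm_c, pwm_n, act, "act")
        tr = compare_filters(pwm_c, pwm_n, rep, "rep")
        assert ta.n_wins_a > ta.n_wins_b
        assert tr.n_wins_b > tr.n_wins_a


class _PwmFilterModel:
    """A stand-in trained model whose single synthetic 'filter' is an exact
    PWM match kernel, for testing the alignment-and-count extraction without
    any training."""

    def __init__(self, pwm, receptive_field):
        self._pwm = pwm
        self.receptive_field = receptive_field

    def conv_activations(self, sequences):
        from eboxnet.interpretation import _scan_scores

        pad = self.receptive_field - self._pwm.width
        out = []
        for seq in sequences:
            scores = _scan_scores(self._pwm, seq)[: len(seq) - self.receptive_field + 1]
            out.append(np.maximum(scores, 0.0))
        return np.stack(out)[:, :, None]


class TestFilterExtraction:
    def test_alignment_and_count_recovers_planted_motif(self):
        rng = np.random.default_rng(4)
        seqs = []
        for _ in range(60):
            s = list("".join(rng.choice(list("ACGT"), size=80)))
            pos = rng.integers(0, 80 - 12)
            s[pos : pos + 6] = "CACGTG"
            seqs.append("".join(s))
        model = _PwmFilterModel(ppm_to_pwm(eb.canonical_ppm()), receptive_field=12)
        ppm = extract_filter_ppm(model, 0, seqs)
        assert ppm.width == 12
        assert np.allclose(ppm.values.sum(axis=0), 1.0)
        cons, _ = consensus_from_ppm(ppm)
        _, n = motif_match(cons, "CACGTG")
        assert n == 6

    def test_extracted_ppm_width_matches_default_filter_length(self, trained_small, small_dataset):
        data, _ = small_dataset
        positives = [e.sequence for e in data.positives("train")]
        ppm = extract_filter_ppm(trained_small, 0, positives)
        assert ppm.width == 24
        assert np.allclose(ppm.values.sum(axis=0), 1.0)

    def test_all_filter_extraction_matches_single(self, trained_small, small_dataset):
        data, _ = small_dataset
        positives = [e.sequence for e in data.positives("train")][:40]
        ppms = extract_all_filter_ppms(trained_small, positives)
        assert len(ppms) == trained_small.config.n_filters
        live = [i for i, p in enumerate(ppms) if p is not None]
        i = live[0]
        single = extract_filter_ppm(trained_small, i, positives)
        assert np.allclose(ppms[i].values, single.values)

    def test_top_information_filter_prefers_sharp_motifs(self):
        sharp = eb.canonical_ppm()  # high peak conservation
        rng = np.random.default_rng(5)
        broad_cols = np.tile(np.array([0.4, 0.3, 0.2, 0.1])[:, None], (1, 24))
        broad = PositionMatrix(broad_cols / broad_cols.sum(0))
        assert top_information_filter([broad, sharp, None]) == 1
        assert information_content(broad).sum() > 0  # broad is informative in total

    def test_identify_motif_filters_assigns_distinct_filters(self):
        canon = eb.canonical_ppm()
        noncanon = eb.noncanonical_ppm()
        assigned = identify_motif_filters(
            [noncanon, None, canon],
            {"canonical": "CACGTG", "noncanonical": consensus_from_ppm(noncanon)[0]},
        )
        assert assigned == {"canonical": 2, "noncanonical": 0}
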