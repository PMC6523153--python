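"""Motif scanning: log-odds scores, exact p-values, targets, trio coverage."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bfawm.simulate import BASES, PWM
from bfawm.tfreg import (
    SCORE_GRANULARITY,
    TFModule,
    _int_scores,
    assign_targets,
    log_odds,
    match_tfs,
    pwm_pvalue,
    scan_promoter,
    select_top_trio,
)


def _uniform_pwm(length=3):
    return PWM("uni", np.full((length, 4), 0.25))


def _sharp_pwm(consensus="ACGT", p=0.85):
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, BASES.index(b)] = p
    return PWM("sharp", mat)


class TestMatchTfs:
    def test_intersection_case_insensitive(self):
        out = match_tfs(["Gli2", "BMP2", "arid3b"], ["GLI2", "ARID3B", "GCM1"])
        assert out == ["Gli2", "arid3b"]

    def test_empty_intersection(self):
        assert match_tfs(["BMP2"], ["GLI2"]) == []

    def test_duplicates_deduplicated(self):
        assert match_tfs(["GLI2", "gli2"], ["GLI2", "GLI2"]) == ["GLI2"]

    def test_empty_tf_list_rejected(self):
        with pytest.raises(ValueError):
            match_tfs(["GLI2"], [])


class TestLogOdds:
    def test_background_pwm_scores_zero(self):
        pwm = _uniform_pwm()
        S = log_odds(pwm)
        np.testing.assert_allclose(S, 0.0, atol=1e-12)

    def test_single_position_deterministic_base(self):
        pwm = PWM("one", np.array([[1.0, 0.0, 0.0, 0.0]]))
        S = log_odds(pwm)
        # pseudocount 0.01: log2((1.01/1.04)/0.25), slightly under 2 bits
        assert S[0, 0] == pytest.approx(math.log2((1.01 / 1.04) / 0.25))
        assert S[0, 0] < 2.0
        assert S[0, 1] == pytest.approx(math.log2((0.01 / 1.04) / 0.25))

    def test_monotone_in_probability(self):
        probs = np.linspace(0.05, 0.9, 10)
        scores = []
        for p in probs:
            rest = (1 - p) / 3
            pwm = PWM("m", np.array([[p, rest, rest, rest]]))
            scores.append(log_odds(pwm)[0, 0])
        assert np.all(np.diff(scores) > 0)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            log_odds(_uniform_pwm(), background=[0.5, 0.5, 0.0, 0.0])


class TestPValueOracle:
    @staticmethod
    def enumerate_pvalue(S_int, threshold_int, bg):
        """Exhaustive sum over all 4^L sequences on the same integer grid."""
        L = S_int.shape[0]
        p = 0.0
        for word in itertools.product(range(4), repeat=L):
            score = sum(S_int[i, b] for i, b in enumerate(word))
            if score >= threshold_int:
                p += math.prod(bg[b] for b in word)
        return p

    def test_dp_equals_enumeration_for_random_motifs(self, rng):
        bg = np.full(4, 0.25)
        for _ in range(20):
            L = int(rng.integers(1, 7))
            mat = rng.dirichlet(np.ones(4) * rng.uniform(0.2, 2.0), size=L)
            pwm = PWM("r", mat)
            S = log_odds(pwm)
            S_int = _int_scores(S)
            lo, hi = S_int.min(axis=1).sum(), S_int.max(axis=1).sum()
            for t_int in {lo, hi, (lo + hi) // 2, hi + 1}:
                dp = pwm_pvalue(S, t_int * SCORE_GRANULARITY)
                brute = self.enumerate_pvalue(S_int, t_int, bg)
                assert dp == pytest.approx(brute, abs=1e-12)

    def test_threshold_below_min_is_one(self):
        S = log_odds(_sharp_pwm("AC"))
        assert pwm_pvalue(S, -1e6) == 1.0

    def test_threshold_above_max_is_zero(self):
        S = log_odds(_sharp_pwm("AC"))
        assert pwm_pvalue(S, 1e6) == 0.0

    def test_nonuniform_background(self):
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        pwm = _sharp_pwm("AAT")
        S = log_odds(pwm, background=bg)
        S_int = _int_scores(S)
        t_int = int(S_int.max(axis=1).sum())  # only the consensus scores this
        dp = pwm_pvalue(S, t_int * SCORE_GRANULARITY, background=bg)
        brute = self.enumerate_pvalue(S_int, t_int, bg)
        assert dp == pytest.approx(brute, abs=1e-12)


class TestScanPromoter:
    def test_planted_consensus_found_at_position(self):
        pwm = _sharp_pwm("ACGTACGTAC")
        S = log_odds(pwm)
        rng = np.random.default_rng(0)
        seq = "".join(BASES[b] for b in rng.integers(0, 4, 300))
        seq = seq[:100] + pwm.consensus + seq[100 + 10:]
        hits = scan_promoter(S, seq)
        assert 101 in [h[0] for h in hits]  # 1-based

    def test_all_n_sequence_has_no_hits(self):
        S = log_odds(_sharp_pwm("ACG"))
        assert scan_promoter(S, "N" * 50) == []

    def test_windows_overlapping_n_skipped(self):
        # length 5: the consensus p-value is 4^-5 < 0.001, shorter motifs
        # cannot reach the default threshold at all
        pwm = _sharp_pwm("ACGTA")
        S = log_odds(pwm)
        hits = scan_promoter(S, "ACNT" + pwm.consensus)
        assert [h[0] for h in hits] == [5]

    def test_p_max_zero_gives_no_hits(self):
        pwm = _sharp_pwm("ACGT")
        assert scan_promoter(log_odds(pwm), pwm.consensus * 5, p_max=0.0) == []

    def test_sequence_shorter_than_motif_empty(self):
        assert scan_promoter(log_odds(_sharp_pwm("ACGTAC")), "ACG") == []


class TestAssignTargets:
    def _world(self):
        pwm = _sharp_pwm("ACGTTGCAAC")
        rng = np.random.default_rng(1)
        bgseq = lambda: "".join(BASES[b] for b in rng.integers(0, 4, 400))
        promoters = {
            "g_hit": bgseq()[:200] + pwm.consensus + bgseq()[:190],
            "g_miss": bgseq(),
        }
        return {"TF1": pwm}, promoters

    def test_planted_target_called(self):
        pwms, promoters = self._world()
        modules = assign_targets(["TF1"], pwms, promoters)
        assert "g_hit" in modules["TF1"].target_set

    def test_p_max_zero_empties_targets(self):
        pwms, promoters = self._world()
        modules = assign_targets(["TF1"], pwms, promoters, p_max=0.0)
        assert modules["TF1"].target_set == frozenset()

    def test_monotone_in_p_max(self):
        pwms, promoters = self._world()
        tight = assign_targets(["TF1"], pwms, promoters, p_max=1e-4)
        loose = assign_targets(["TF1"], pwms, promoters, p_max=1e-2)
        assert tight["TF1"].target_set <= loose["TF1"].target_set

    def test_tf_without_motif_dropped_with_warning(self):
        pwms, promoters = self._world()
        with pytest.warns(UserWarning, match="no motif"):
            modules = assign_targets(["TF1", "TF2"], pwms, promoters)
        assert "TF2" not in modules


class TestTrioSelection:
    @staticmethod
    def _modules(spec):
        return {tf: TFModule(tf, {g: (0.0, 0.0) for g in genes})
                for tf, genes in spec.items()}

    def test_hand_enumerated_instance(self):
        modules = self._modules(
            {"A": {1, 2, 3}, "B": {3, 4}, "C": {5}, "D": {1}}
        )
        trio, cov = select_top_trio(modules)
        assert set(trio) == {"A", "B", "C"} and cov == 5

    def test_identical_modules_tie_break_lexicographic(self):
        modules = self._modules({t: {1, 2} for t in "DCBA"})
        trio, cov = select_top_trio(modules)
        assert trio == ("A", "B", "C") and cov == 2

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            select_top_trio(self._modules({"A": {1}, "B": {2}}))

    def test_optimal_on_random_instances(self, rng):
        for _ in range(100):
            n_tf = int(rng.integers(3, 13))
            spec = {
                f"TF{k:02d}": set(rng.choice(30, size=rng.integers(0, 10), replace=False))
                for k in range(n_tf)
            }
            modules = self._modules(spec)
            trio, cov = select_top_trio(modules)
            best = max(
                len(set().union(*(spec[t] for t in c)))
                for c in itertools.combinations(spec, 3)
            )
            assert cov == best
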