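import numpy as np
import pytest

from mozear.errors import (
    DegenerateRepeatError,
    InsufficientDataError,
    InvalidInputError,
    PairingError,
)
from mozear.phonotaxis import (
    TONE_SET_HZ,
    PhonotacticProfile,
    ToneTrial,
    compare_paired,
    net_responders,
    normalize_repeat,
    profile_auc,
    response_range,
)
from mozear.smoothing import SmoothConfig


def profile_from_counts(counts, repeat_id="cage0", cond="glucose-day0", before=0):
    trials = tuple(
        ToneTrial(float(f), before, int(c)) for f, c in zip(TONE_SET_HZ, counts)
    )
    return PhonotacticProfile(repeat_id, cond, trials)


def triangle_counts(peak=20):
    tones = np.array(TONE_SET_HZ, float)
    return np.round(peak * np.where(tones <= 550, (tones - 350) / 200,
                                    (750 - tones) / 200)).astype(int)


class TestNetResponders:
    @pytest.mark.parametrize("before,during,expected",
                             [(4, 12, 8), (3, 3, 0), (5, 2, 0)])
    def test_subtraction_floored_at_zero(self, before, during, expected):
        assert net_responders(ToneTrial(550.0, before, during)) == expected

    def test_counts_above_group_size_rejected(self):
        with pytest.raises(InvalidInputError):
            ToneTrial(550.0, 0, 31)


class TestNormalizeRepeat:
    def test_normalizes_by_repeat_maximum(self):
        p = profile_from_counts(triangle_counts(20))
        (norm,) = normalize_repeat([p])
        assert norm.responses.max() == 1.0
        tone_10 = list(TONE_SET_HZ).index(450)  # count 10 out of max 20
        assert norm.responses[tone_10] == pytest.approx(0.5)

    def test_maximum_is_shared_across_days(self):
        # day1's own max (8) must map to 8/20, not 1.0
        day0 = profile_from_counts(triangle_counts(20), cond="glucose-day0")
        day1 = profile_from_counts(triangle_counts(8), cond="AMTP-day1")
        norm0, norm1 = normalize_repeat([day0, day1])
        assert norm0.responses.max() == 1.0
        assert norm1.responses.max() == pytest.approx(8 / 20)

    def test_idempotent_on_relative_shape(self):
        p = profile_from_counts(triangle_counts(20))
        (once,) = normalize_repeat([p])
        twice = once.net_counts / once.net_counts.max()
        np.testing.assert_allclose(once.responses, twice / twice.max() * once.responses.max())

    def test_all_zero_repeat_raises(self):
        p = profile_from_counts(np.zeros(17, int))
        with pytest.raises(DegenerateRepeatError):
            normalize_repeat([p])

    def test_mixed_repeats_rejected(self):
        a = profile_from_counts(triangle_counts(), repeat_id="cage0")
        b = profile_from_counts(triangle_counts(), repeat_id="cage1")
        with pytest.raises(InvalidInputError):
            normalize_repeat([a, b])


class TestProfileAuc:
    def test_zero_profile_zero_auc(self):
        p = profile_from_counts(triangle_counts(20))
        (norm,) = normalize_repeat([p])
        zero = PhonotacticProfile("cage0", "x", norm.trials,
                                  responses=np.zeros(17))
        assert profile_auc(zero) == 0.0

    def test_rectangle(self):
        p = profile_from_counts(triangle_counts(20))
        (norm,) = normalize_repeat([p])
        flat = PhonotacticProfile("cage0", "x", norm.trials,
                                  responses=np.full(17, 0.5))
        assert profile_auc(flat) == pytest.approx(0.5 * 400)

    def test_triangle_matches_trapezoid_oracle(self):
        # unit triangle over a 400-Hz base: trapezoid rule gives
        # (1/2) * 400 * 1 = 200 regardless of tone density
        tones = np.array(TONE_SET_HZ, float)
        tri = np.where(tones <= 550, (tones - 350) / 200, (750 - tones) / 200)
        p = profile_from_counts(triangle_counts(20))
        prof = PhonotacticProfile("cage0", "x", p.trials, responses=tri)
        oracle = np.trapezoid(tri, tones)
        assert profile_auc(prof) == pytest.approx(oracle)
        assert oracle == pytest.approx(200.0)

    def test_coarse_triangle_matches_trapezoid_oracle(self):
        trials = tuple(ToneTrial(f, 0, c) for f, c in
                       [(350.0, 0), (550.0, 20), (750.0, 0)])
        prof = PhonotacticProfile("cage0", "x", trials,
                                  responses=np.array([0.0, 1.0, 0.0]))
        assert profile_auc(prof) == pytest.approx(200.0)

    def test_order_invariant(self):
        rng = np.random.default_rng(5)
        resp = rng.random(17)
        p = profile_from_counts(triangle_counts(20))
        prof = PhonotacticProfile("cage0", "x", p.trials, responses=resp)
        perm = rng.permutation(17)
        shuffled = PhonotacticProfile(
            "cage0", "x", tuple(p.trials[i] for i in perm), responses=resp[perm])
        assert profile_auc(shuffled) == pytest.approx(profile_auc(prof))

    def test_unnormalized_profile_rejected(self):
        with pytest.raises(InvalidInputError):
            profile_auc(profile_from_counts(triangle_counts(20)))


class TestResponseRange:
    def tri_profile(self):
        tones = np.array(TONE_SET_HZ, float)
        tri = np.where(tones <= 550, (tones - 350) / 200, (750 - tones) / 200)
        base = profile_from_counts(triangle_counts(20))
        return PhonotacticProfile("cage0", "x", base.trials, responses=tri)

    def test_triangle_boundaries_at_analytic_crossings(self):
        # with a local smoother the piecewise-linear profile is
        # reproduced and the 25% threshold crossings sit at 400/700 Hz
        rng = response_range(self.tri_profile(), SmoothConfig(span=0.3, degree=2))
        assert rng.peak_hz == pytest.approx(550.0, abs=1.0)
        assert rng.lower_hz == pytest.approx(400.0, abs=1.0)
        assert rng.upper_hz == pytest.approx(700.0, abs=1.0)

    def test_flat_profile_spans_whole_range(self):
        base = profile_from_counts(triangle_counts(20))
        flat = PhonotacticProfile("cage0", "x", base.trials,
                                  responses=np.full(17, 0.8))
        rng = response_range(flat)
        assert rng.lower_hz == 350.0
        assert rng.upper_hz == 750.0

    def test_boundaries_bracket_peak(self):
        rng_gen = np.random.default_rng(9)
        base = profile_from_counts(triangle_counts(20))
        for _ in range(5):
            resp = rng_gen.random(17)
            prof = PhonotacticProfile("cage0", "x", base.trials, responses=resp)
            rr = response_range(prof)
            assert 350.0 <= rr.lower_hz <= rr.peak_hz <= rr.upper_hz <= 750.0

    def test_scaling_profile_leaves_range_scales_auc(self):
        prof = self.tri_profile()
        shrunk = PhonotacticProfile("cage0", "x", prof.trials,
                                    responses=0.3 * prof.responses)
        r1, r2 = response_range(prof), response_range(shrunk)
        assert (r1.lower_hz, r1.upper_hz) == (r2.lower_hz, r2.upper_hz)
        assert profile_auc(shrunk) == pytest.approx(0.3 * profile_auc(prof))


class TestComparePaired:
    def test_identical_vectors_p_one(self):
        x = np.arange(8.0)
        res = compare_paired(x, x)
        assert res.p_value == 1.0
        assert "zero_variance" in res.flags

    def test_all_shifted_pairs_exact_p(self):
        res = compare_paired(np.zeros(8), np.ones(8))
        assert res.p_value == pytest.approx(2 / 2**8)

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_paired(np.array([1.0]), np.array([2.0]))

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(PairingError):
            compare_paired(np.zeros(6), np.zeros(5))
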