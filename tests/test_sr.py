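"""Tests for the Sr isotope reduction chain and group statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleorange.constants import SR_CONSTANTS as C
from paleorange.sr import (
    BeamCycles,
    ReducedSpot,
    SpotAnalysis,
    baseline_subtract,
    kr_correct,
    kruskal_dunn,
    mass_bias,
    normalize_and_bracket,
    rb_correct,
    reduce_session,
    transect_summary,
    welch_t,
)
from paleorange.synthetic import BeamTruth, gen_beams


def _cycles(n=10, **masses):
    data = {m: np.full(n, masses.get(m, 0.0)) for m in
            ("m82", "m83", "m84", "m85", "m86", "m87", "m88")}
    df = pd.DataFrame(data)
    df.insert(0, "t_s", np.arange(n, dtype=float))
    return BeamCycles(df)


def _spot(baseline, ablation, role="sample"):
    return SpotAnalysis("s1", baseline, ablation, role=role)


class TestBaseline:
    def test_zero_baseline_is_identity(self):
        abl = _cycles(m86=1.0, m88=8.375209)
        net = baseline_subtract(_spot(_cycles(5), abl))
        assert np.allclose(net.data["m86"], 1.0)

    def test_constant_baseline_removed(self):
        abl = _cycles(m86=1.01, m88=8.385209)
        base = _cycles(5, m86=0.01, m88=0.01)
        net = baseline_subtract(_spot(base, abl))
        assert np.allclose(net.data["m86"], 1.0)
        assert np.allclose(net.data["m88"], 8.375209)

    def test_short_baseline_window_rejected(self):
        with pytest.raises(ValueError):
            baseline_subtract(_spot(_cycles(2), _cycles(10, m86=1.0)))


class TestKrCorrection:
    def test_no_kr_is_identity(self):
        net = _cycles(m84=0.0565, m86=1.0)
        out = kr_correct(net)
        assert np.allclose(out.data["m84"], 0.0565)
        assert np.allclose(out.data["m86"], 1.0)

    def test_known_spike_recovered(self):
        kr82 = 3e-4
        net = _cycles(
            m82=kr82,
            m84=0.0565 + kr82 * C.kr84_82,
            m86=1.0 + kr82 * C.kr86_82,
        )
        out = kr_correct(net)
        assert np.allclose(out.data["m84"] / out.data["m86"], 0.0565, atol=1e-6)

    def test_pure_kr_blank_reduced_to_zero(self):
        kr82 = 1e-3
        net = _cycles(m82=kr82, m84=kr82 * C.kr84_82, m86=kr82 * C.kr86_82)
        out = kr_correct(net)
        assert np.allclose(out.data["m84"], 0.0, atol=1e-15)
        assert np.allclose(out.data["m86"], 0.0, atol=1e-15)

    def test_kr83_averaging_option(self):
        kr82 = 3e-4
        kr83 = kr82 * (11.50 / 11.59)
        net = _cycles(m82=kr82, m83=kr83, m84=kr82 * C.kr84_82,
                      m86=1.0 + kr82 * C.kr86_82)
        out = kr_correct(net, use_kr83=True)
        assert np.allclose(out.data["m84"], 0.0, atol=1e-12)


class TestMassBias:
    def test_canonical_measurement_gives_zero(self):
        net = _cycles(m86=1.0, m88=C.r88_86_canonical)
        assert mass_bias(net) == pytest.approx(0.0, abs=1e-12)

    def test_half_power_bias(self):
        ratio = C.r88_86_canonical * (C.m_sr88 / C.m_sr86) ** 0.5
        net = _cycles(m86=1.0, m88=ratio)
        assert mass_bias(net) == pytest.approx(-0.5, abs=1e-12)

    def test_round_trip(self):
        beta = 1.83
        measured = C.r88_86_canonical * (C.m_sr88 / C.m_sr86) ** (-beta)
        net = _cycles(m86=1.0, m88=measured)
        assert mass_bias(net) == pytest.approx(beta, abs=1e-12)

    def test_nonpositive_beam_rejected(self):
        with pytest.raises(ValueError):
            mass_bias(_cycles(m86=0.0, m88=1.0))


class TestRbCorrection:
    def test_no_rb_is_identity(self):
        net = _cycles(m86=1.0, m87=0.71)
        assert np.allclose(rb_correct(net, beta=-1.8), 0.71)

    def test_beta_zero_is_natural_ratio_subtraction(self):
        rb85 = 1e-3
        net = _cycles(m85=rb85, m86=1.0, m87=0.71 + rb85 * C.rb87_85)
        assert np.allclose(rb_correct(net, beta=0.0), 0.71, atol=1e-15)

    def test_doped_spot_recovers_truth(self):
        beta = -1.8
        rb85 = 5e-4
        true87 = 0.7085
        rb87 = rb85 * C.rb87_85 * (C.m_rb87 / C.m_rb85) ** (-beta)
        net = _cycles(m85=rb85, m86=1.0, m87=true87 + rb87)
        sr87 = rb_correct(net, beta=beta)
        assert np.allclose(sr87, true87, atol=5e-5 * true87)


class TestBracketing:
    def _reduced(self, order, ratio, role="sample"):
        return ReducedSpot(f"s{order}", ratio, 1e-5, 0.0565, 0.0, -1.8,
                           role=role, order=order)

    def test_exact_standard_means_factor_one(self):
        spots = [
            self._reduced(0, C.seawater_87_86, "bracketing_standard"),
            self._reduced(1, 0.7085),
            self._reduced(2, C.seawater_87_86, "bracketing_standard"),
        ]
        out = normalize_and_bracket(spots)
        assert out[1].r87_86 == pytest.approx(0.7085, abs=1e-15)

    def test_linear_drift_removed_exactly(self):
        drift = lambda o: 1.0 + 5e-5 * o
        spots = [
            self._reduced(0, C.seawater_87_86 * drift(0), "bracketing_standard"),
            self._reduced(1, 0.7085 * drift(1)),
            self._reduced(2, C.seawater_87_86 * drift(2), "bracketing_standard"),
        ]
        out = normalize_and_bracket(spots)
        # interpolation of the factor is in 1/drift, not drift, so exact
        # removal holds to first order in the drift amplitude
        assert out[1].r87_86 == pytest.approx(0.7085, rel=1e-8)

    def test_idempotent_with_identical_standards(self):
        spots = [
            self._reduced(0, C.seawater_87_86, "bracketing_standard"),
            self._reduced(1, 0.7085),
            self._reduced(2, C.seawater_87_86, "bracketing_standard"),
        ]
        once = normalize_and_bracket(spots)
        twice = normalize_and_bracket(once)
        assert twice[1].r87_86 == pytest.approx(once[1].r87_86, abs=1e-15)

    def test_no_standards_rejected(self):
        with pytest.raises(ValueError):
            normalize_and_bracket([self._reduced(0, 0.7085)])


class TestFullChain:
    def test_zero_noise_recovery_within_5e5(self):
        truth = BeamTruth(sample_ratio=0.7085, beta=-1.8, noise_rel=0.0)
        spots, _ = gen_beams(seed=1, truth=truth)
        red = reduce_session(spots)
        for r in red:
            if r.role == "sample":
                assert abs(r.r87_86 - 0.7085) < 5e-5
                assert abs(r.beta - (-1.8)) < 1e-6
                assert abs(r.r84_86 - C.r84_86_natural) < 1e-6

    def test_recovery_with_drift_and_contamination(self):
        truth = BeamTruth(sample_ratio=0.7085, beta=-1.8, kr82_v=8e-4,
                          rb85_v=5e-4, drift_ppm=300, beta_drift=0.3,
                          noise_rel=0.0)
        spots, _ = gen_beams(seed=2, truth=truth)
        red = reduce_session(spots)
        for r in red:
            if r.role == "sample":
                assert abs(r.r87_86 - 0.7085) < 5e-5

    def test_unbiased_over_noisy_replicates(self):
        errs = []
        for s in range(200):
            truth = BeamTruth(sample_ratio=0.7085, beta=-1.8, noise_rel=5e-4)
            spots, _ = gen_beams(seed=1000 + s, truth=truth, n_samples=1,
                                 n_cycles=30)
            red = reduce_session(spots)
            samp = [r for r in red if r.role == "sample"][0]
            errs.append(samp.r87_86 - 0.7085)
        assert abs(float(np.mean(errs))) < 1e-5

    def test_invariant_to_uniform_beam_scaling(self):
        truth = BeamTruth(sample_ratio=0.7085, noise_rel=0.0, baseline_v=0.0)
        spots, _ = gen_beams(seed=3, truth=truth, n_samples=1)
        scaled = []
        for s in spots:
            b = BeamCycles(s.baseline.data.copy())
            a = BeamCycles(s.ablation.data.copy())
            cols = [c for c in a.data.columns if c.startswith("m")]
            a.data[cols] *= 3.0
            b.data[cols] *= 3.0
            scaled.append(SpotAnalysis(s.spot_id, b, a, role=s.role,
                                       tooth=s.tooth, transect=s.transect,
                                       order=s.order))
        r1 = [r.r87_86 for r in reduce_session(spots) if r.role == "sample"]
        r2 = [r.r87_86 for r in reduce_session(scaled) if r.role == "sample"]
        assert np.allclose(r1, r2, atol=1e-12)

    def test_heavy_rb_raises_overcorrection_flag(self):
        truth = BeamTruth(sample_ratio=0.7085, rb85_v=0.0, noise_rel=0.0)
        spots, _ = gen_beams(seed=4, truth=truth, n_samples=1)
        # dope mass 85 without the matching mass-87 signal: correction
        # drives 87Sr negative
        for s in spots:
            if s.role == "sample":
                s.ablation.data["m85"] += 3.0
        red = reduce_session(spots)
        samp = [r for r in red if r.role == "sample"][0]
        assert "rb_overcorrection" in samp.flags

    def test_seal_enamel_accuracy_check(self):
        truth = BeamTruth(drift_ppm=150, beta_drift=0.2, noise_rel=1e-4)
        spots, _ = gen_beams(seed=5, truth=truth)
        red = reduce_session(spots)
        seal = [r.r87_86 for r in red if r.role == "accuracy_standard"]
        assert np.mean(seal) == pytest.approx(C.seawater_87_86, abs=5e-5)


class TestSummaries:
    def test_single_spot_falls_back_to_internal_error(self):
        s = ReducedSpot("a", 0.7085, 4e-5, 0.0565, 0.0, -1.8,
                        tooth="T1", transect="1")
        out = transect_summary([s])
        assert out[0].mean == 0.7085
        assert out[0].two_se == 4e-5
        assert out[0].n_spots == 1

    def test_identical_spots_have_zero_scatter(self):
        spots = [
            ReducedSpot(f"a{i}", 0.7085, 4e-5, 0.0565, 0.0, -1.8,
                        tooth="T1", transect="1")
            for i in range(3)
        ]
        assert transect_summary(spots)[0].two_se == 0.0


class TestWelch:
    def test_identical_groups_not_significant(self):
        t, df, p = welch_t([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_textbook_example_matches_hand_calculation(self):
        a = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1])
        b = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0])
        t, df, p = welch_t(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == pytest.approx(df_hand, abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand), abs=1e-12)

    def test_crown_vs_base_contrast_is_significant(self):
        # intra-tooth contrast at the scale observed in a zoned molar:
        # crown near 0.7088, base near 0.7077
        rng = np.random.default_rng(8)
        crown = 0.708804 + 3e-4 * rng.standard_normal(12)
        base = 0.707706 + 2e-4 * rng.standard_normal(18)
        _, _, p = welch_t(crown, base)
        assert p < 0.001

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestKruskalDunn:
    def test_identical_groups_flat(self):
        H, p, pairs = kruskal_dunn({"a": [1, 1, 1], "b": [1, 1], "c": [1, 1]})
        assert H == 0.0 and p == 1.0
        assert (pairs["p_adj"] == 1.0).all()

    def test_permutation_oracle_for_h_statistic(self):
        rng = np.random.default_rng(11)
        groups = {
            "a": rng.normal(0.0, 1.0, 5),
            "b": rng.normal(0.8, 1.0, 5),
            "c": rng.normal(0.0, 1.0, 5),
        }
        H, p, _ = kruskal_dunn(groups)
        pooled = np.concatenate(list(groups.values()))
        sizes = [len(v) for v in groups.values()]
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            Hp = stats.kruskal(*parts).statistic
            if Hp >= H:
                count += 1
        p_perm = count / n_perm
        assert p == pytest.approx(p_perm, abs=0.05)

    def test_shifted_group_flagged_in_pairwise(self):
        rng = np.random.default_rng(12)
        groups = {
            "a": rng.normal(0, 1, 15),
            "b": rng.normal(0, 1, 15),
            "c": rng.normal(4, 1, 15),
        }
        H, p, pairs = kruskal_dunn(groups)
        assert p < 0.001
        sig = pairs[pairs["p_adj"] < 0.05]
        flagged = set(map(tuple, sig[["group_a", "group_b"]].to_numpy()))
        assert ("a", "c") in flagged and ("b", "c") in flagged
        ab = pairs[(pairs["group_a"] == "a") & (pairs["group_b"] == "b")]
        assert float(ab["p_adj"].iloc[0]) > 0.05
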