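"""Decision-time expectations, mixture likelihood, and stage posteriors."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from beadsampling import dtime
from beadsampling.dtime import (
    DTParams,
    dt_loglik,
    expected_stage_dts,
    joint_loglik,
    simulate_dt,
    stage_posteriors,
)


TWO_STAGE = DTParams((0.2, -1.6, 0.5, 0.35), (0.4, 0.3, 0.3, 0.4))


class TestExpectedStageDTs:
    def test_flat_difficulty_terms(self):
        params = DTParams((0.7, 0.0, 0.0, 0.3))
        y_c, y_s, _ = expected_stage_dts(np.array([0.2]), None, params, None)
        assert y_c[0] == pytest.approx(math.exp(0.7))
        assert y_s[0] == pytest.approx(math.exp(0.7))

    def test_symmetry_at_half(self):
        y_c, y_s, _ = expected_stage_dts(
            np.array([0.5]), None, DTParams(TWO_STAGE.stage1), None
        )
        assert y_c[0] == pytest.approx(y_s[0])

    def test_known_value(self):
        # direct evaluation of exp(b0 + b1 (1 - p1)) at p1 = 0.2
        params = DTParams((math.log(0.3) + 2.0, 1.0, 0.0, 0.3))
        y_c, _, _ = expected_stage_dts(np.array([0.2]), None, params, None)
        assert y_c[0] == pytest.approx(0.3 * math.exp(2.8))

    def test_second_stage_total_exceeds_first(self):
        for trigger in ("continue", "stop"):
            y_c, y_s, y2 = expected_stage_dts(
                np.array([0.3]), np.array([0.7]), TWO_STAGE, trigger
            )
            first = y_c[0] if trigger == "continue" else y_s[0]
            assert y2[0] > first


class TestStagePosteriors:
    def test_no_second_thought_means_stage1(self):
        w1, w2 = stage_posteriors(
            np.array([0.3]), np.array([0.6]), np.array([0.0]), "continue"
        )
        assert w1[0] == pytest.approx(1.0)
        assert w2[0] == pytest.approx(0.0)

    def test_certain_second_thought_continue_trigger(self):
        w1, w2 = stage_posteriors(
            np.array([0.3]), np.array([0.5]), np.array([1.0]), "continue"
        )
        assert w1[0] == pytest.approx(0.0)
        assert w2[0] == pytest.approx(1.0)

    def test_stop_trigger_with_p1_zero(self):
        w1, w2 = stage_posteriors(
            np.array([0.0]), np.array([0.5]), np.array([0.8]), "stop"
        )
        assert w1[0] == pytest.approx(1.0)

    def test_pair_sums_to_one(self, rng):
        p1, p2, ps = rng.random((3, 200))
        for trigger in ("continue", "stop"):
            w1, w2 = stage_posteriors(p1, p2, ps, trigger)
            assert np.allclose(w1 + w2, 1.0)
            assert np.all((w1 >= 0) & (w2 >= 0))

    def test_impossible_continue_signaled(self):
        with pytest.raises(ValueError):
            stage_posteriors(
                np.array([1.0]), np.array([1.0]), np.array([1.0]), "stop"
            )


class TestDTLoglik:
    def test_collapses_to_one_stage_density(self):
        dt = np.array([0.4, 1.2])
        p1 = np.array([0.3, 0.3])
        ll_mix = dt_loglik(
            dt,
            TWO_STAGE,
            p1,
            np.array([0.5, 0.5]),
            np.array([0.0, 0.0]),
            "continue",
        )
        one_stage = DTParams(TWO_STAGE.stage1)
        ll_one = dt_loglik(dt, one_stage, p1)
        assert ll_mix == pytest.approx(ll_one)

    def test_mixture_density_integrates_to_one(self):
        p1 = np.array([0.3])
        p2 = np.array([0.6])
        psec = np.array([0.5])

        def dens(t):
            return math.exp(
                dt_loglik(
                    np.array([t]), TWO_STAGE, p1, p2, psec, "continue",
                    total=True,
                )
            )

        integral, err = quad(dens, 1e-6, 200.0, limit=200)
        assert integral == pytest.approx(1.0, abs=1e-4)

    def test_lognormal_closed_form_at_median(self):
        params = DTParams((0.5, 0.0, 0.0, 1.0))
        y = math.exp(0.5)
        ll = dt_loglik(np.array([y]), params, np.array([0.3]))
        assert math.exp(ll) == pytest.approx(1.0 / (math.sqrt(2 * math.pi) * y))

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            dt_loglik(np.array([-0.1]), TWO_STAGE, np.array([0.3]),
                      np.array([0.5]), np.array([0.5]), "continue")


class TestJointLoglik:
    def test_sum_identity(self):
        assert joint_loglik(-10.5, -3.25) == pytest.approx(-13.75)

    def test_factorization_on_random_states(self, rng):
        """ln L(c, DT) evaluated directly equals ln L(c) + ln L(DT)."""
        for _ in range(1000):
            p1, p2, psec = rng.uniform(0.05, 0.95, 3)
            dt = float(rng.lognormal(-0.5, 0.5))
            w1, w2 = stage_posteriors(
                np.array([p1]), np.array([p2]), np.array([psec]), "continue"
            )
            p_stop = p1 + (1 - p1) * psec * p2
            ll_choice = math.log(1 - p_stop)  # a continue choice
            ll_dt = dt_loglik(
                np.array([dt]), TWO_STAGE, np.array([p1]), np.array([p2]),
                np.array([psec]), "continue",
            )
            # direct joint: P(continue) * [w1 f1(dt) + w2 f2(dt)]
            y_c, _, y2 = expected_stage_dts(
                np.array([p1]), np.array([p2]), TWO_STAGE, "continue"
            )
            f1 = math.exp(
                dt_loglik(np.array([dt]), DTParams(TWO_STAGE.stage1),
                          np.array([p1]))
            )
            s2 = TWO_STAGE.stage2[3]
            z = (math.log(dt) - math.log(y2[0])) / s2
            f2 = math.exp(-0.5 * z * z) / (dt * s2 * math.sqrt(2 * math.pi))
            direct = math.log((1 - p_stop) * (w1[0] * f1 + w2[0] * f2))
            assert abs(direct - (ll_choice + ll_dt)) < 1e-10


class TestSimulateDT:
    def test_sigma_to_zero_limit(self, rng):
        params = DTParams((0.2, -1.6, 0.5, 1e-9), (0.4, 0.3, 0.3, 1e-9))
        dt = simulate_dt("stage1", params, 0.3, 0.6, "continue", rng)
        y_c, _, _ = expected_stage_dts(
            np.array([0.3]), np.array([0.6]), params, "continue"
        )
        assert dt == pytest.approx(y_c[0], rel=1e-6)

    def test_sample_median_matches_expected_dt(self, rng):
        draws = [
            simulate_dt("stage2", TWO_STAGE, 0.3, 0.6, "continue", rng)
            for _ in range(20_000)
        ]
        _, _, y2 = expected_stage_dts(
            np.array([0.3]), np.array([0.6]), TWO_STAGE, "continue"
        )
        assert np.median(draws) == pytest.approx(y2[0], rel=0.02)

    def test_two_path_simulation_is_bimodal(self, rng):
        from beadsampling.dip import dip_statistic

        n = 2000
        fast = [
            simulate_dt("stage1", TWO_STAGE, 0.2, 0.5, "continue", rng)
            for _ in range(n)
        ]
        slow = [
            simulate_dt("stage2", TWO_STAGE, 0.2, 0.5, "continue", rng)
            for _ in range(n)
        ]
        mixed = np.log(np.concatenate([fast, slow]))
        unimodal = rng.normal(size=2 * n)
        assert dip_statistic(mixed) > 3 * dip_statistic(unimodal)

    def test_mean_dt_increases_with_psec(self, rng):
        """More second thoughts -> larger share of slow stage-2 decisions."""
        means = []
        for psec in (0.1, 0.4, 0.8):
            draws = []
            for _ in range(4000):
                path = "stage2" if rng.random() < psec else "stage1"
                draws.append(
                    simulate_dt(path, TWO_STAGE, 0.2, 0.5, "continue", rng)
                )
            means.append(np.mean(draws))
        assert means[0] < means[1] < means[2]
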