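import numpy as np
import pytest

from respiraflow import bayes, net
from respiraflow.bayes import (BayesConfig, UncertaintySummary, mc_forward,
                               mc_predict, predictive_moments,
                               reject_uncertain, sweep_inference_samples)
from respiraflow.net import ModelOutput


def _samples(resp_rows, rr_vals):
    return [ModelOutput(resp=np.asarray(r), rr=np.asarray(v))
            for r, v in zip(resp_rows, rr_vals)]


class TestPredictiveMoments:
    def test_identical_samples_have_zero_variance(self):
        s = _samples([np.ones(8)] * 5, [3.0] * 5)
        out = predictive_moments(s, BayesConfig(T=5, tau_inv=0.0))
        assert np.allclose(out.var_resp, 0.0)
        assert out.var_rr == 0.0
        assert out.score == 0.0

    def test_model_precision_term_is_additive(self):
        s = _samples([np.ones(8)] * 5, [3.0] * 5)
        out = predictive_moments(s, BayesConfig(T=5, tau_inv=0.3))
        assert np.allclose(out.var_resp, 0.3)
        assert out.var_rr == pytest.approx(0.3)

    def test_two_point_moments(self):
        s = _samples([np.zeros(4), np.zeros(4)], [10.0, 14.0])
        out = predictive_moments(s, BayesConfig(T=2))
        assert out.mean_rr == pytest.approx(12.0)
        assert out.var_rr == pytest.approx(4.0)   # population variance

    def test_second_moment_form_equals_two_pass_moments(self, rng):
        """The tau + E[f^2] - mean^2 implementation agrees with a direct
        two-pass mean/variance computation to 1e-10."""
        for _ in range(20):
            T = int(rng.integers(2, 12))
            resp = rng.normal(size=(T, 16))
            rr = rng.normal(size=T) * 10
            out = predictive_moments(_samples(resp, rr), BayesConfig(T=T))
            assert np.abs(out.var_resp - resp.var(axis=0)).max() < 1e-10
            assert abs(out.var_rr - rr.var()) < 1e-10
            assert np.abs(out.mean_resp - resp.mean(axis=0)).max() < 1e-10

    def test_sample_order_invariance(self, rng):
        resp = rng.normal(size=(6, 8))
        rr = rng.normal(size=6)
        a = predictive_moments(_samples(resp, rr), BayesConfig(T=6))
        perm = rng.permutation(6)
        b = predictive_moments(_samples(resp[perm], rr[perm]),
                               BayesConfig(T=6))
        assert np.allclose(a.var_resp, b.var_resp)
        assert a.score == pytest.approx(b.score)

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            predictive_moments(_samples([np.ones(4)], [1.0]), BayesConfig())

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            UncertaintySummary(np.zeros(4), np.zeros(4), 0.0, -1.0, 0.0)


class TestMcForward:
    def test_zero_dropout_gives_identical_passes(self, tiny_teacher, rng):
        x = rng.normal(size=(3, 128))
        outs = mc_forward(tiny_teacher, x,
                          BayesConfig(T=4, dropout_p=0.0))
        for o in outs[1:]:
            assert np.array_equal(o.resp, outs[0].resp)

    def test_fixed_seed_reproduces_sample_set(self, tiny_teacher, rng):
        x = rng.normal(size=(3, 128))
        cfg = BayesConfig(T=3, seed=9)
        a = mc_forward(tiny_teacher, x, cfg)
        b = mc_forward(tiny_teacher, x, cfg)
        for oa, ob in zip(a, b):
            assert np.array_equal(oa.resp, ob.resp)

    @pytest.mark.parametrize("seed", range(5))
    def test_active_dropout_produces_distinct_estimates(self, tiny_teacher,
                                                        rng, seed):
        x = rng.normal(size=(3, 128))
        outs = mc_forward(tiny_teacher, x, BayesConfig(T=10, seed=seed))
        assert len({float(o.rr) for o in outs}) >= 2

    def test_model_without_dropout_is_a_config_error(self, rng):
        model = net.build_teacher(net.teacher_config(width_scale=0.125,
                                                     seed=0, dropout_p=0.0))
        with pytest.raises(ValueError):
            mc_forward(model, rng.normal(size=(3, 128)),
                       BayesConfig(dropout_p=None))

    def test_pipeline_degenerates_to_deterministic_pass(self, tiny_teacher,
                                                        rng):
        x = rng.normal(size=(2, 3, 128))
        det = net.forward(tiny_teacher, x)
        s = predictive_moments(
            mc_forward(tiny_teacher, x, BayesConfig(T=3, dropout_p=0.0)),
            BayesConfig(T=3))
        assert np.allclose(np.stack([v.mean_resp for v in s]), det.resp)
        assert np.allclose([v.mean_rr for v in s], det.rr)
        assert np.allclose([v.var_rr for v in s], 0.0)


class TestRejection:
    def _summaries(self, scores):
        return [UncertaintySummary(np.zeros(2), np.zeros(2), 0.0, 0.0, s)
                for s in scores]

    def test_zero_fraction_rejects_nothing(self):
        kept, rejected = reject_uncertain(self._summaries([1.0, 2.0, 3.0]),
                                          BayesConfig(reject_fraction=0.0))
        assert len(kept) == 3 and len(rejected) == 0

    def test_four_percent_of_hundred_is_exactly_four(self, rng):
        scores = rng.normal(size=100) ** 2
        kept, rejected = reject_uncertain(self._summaries(scores),
                                          BayesConfig(reject_fraction=0.04))
        assert len(rejected) == 4
        assert set(rejected) == set(np.argsort(scores)[-4:])

    def test_partition_properties(self, rng):
        scores = rng.normal(size=37) ** 2
        kept, rejected = reject_uncertain(self._summaries(scores),
                                          BayesConfig(reject_fraction=0.2))
        assert len(kept) + len(rejected) == 37
        assert set(kept).isdisjoint(set(rejected))
        assert scores[rejected].min() >= scores[kept].max() - 1e-12

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            BayesConfig(reject_fraction=1.0)
        with pytest.raises(ValueError):
            BayesConfig(T=1)


class TestSweep:
    def test_table_schema(self, tiny_teacher, small_windows):
        df = sweep_inference_samples(tiny_teacher, small_windows[:6],
                                     [2, 4], seed=0)
        assert list(df["T"]) == [2, 4]
        for col in ("avg_rr_mae", "avg_rr_rmse", "pct_rejected",
                    "wall_time_s"):
            assert df[col].notna().all()

    def test_out_of_range_T_rejected(self, tiny_teacher, small_windows):
        with pytest.raises(ValueError):
            sweep_inference_samples(tiny_teacher, small_windows[:2], [1])
        with pytest.raises(ValueError):
            sweep_inference_samples(tiny_teacher, small_windows[:2], [65])

    def test_mean_estimates_stabilise_with_more_samples(self, tiny_teacher,
                                                        rng):
        """Monte-Carlo convergence: across independent seeds the spread of
        the predictive mean shrinks roughly as 1/sqrt(T)."""
        x = rng.normal(size=(1, 3, 128))
        def spread(T):
            means = [predictive_moments(
                mc_forward(tiny_teacher, x, BayesConfig(T=T, seed=s)),
                BayesConfig(T=T))[0].mean_rr for s in range(8)]
            return np.std(means)
        assert spread(32) < spread(2)
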