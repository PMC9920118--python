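import numpy as np
import pytest

from respiraflow import net
from respiraflow.nn.core import Tensor


class TestAttentionGate:
    def _gate(self, cx=3, cg=5, seed=0):
        return net.AttentionGate(cx, cg, np.random.default_rng(seed))

    def test_zero_psi_gives_half_coefficients(self, rng):
        gate = self._gate()
        gate.psi.w.data[:] = 0.0
        gate.psi.b.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 3, 8)))
        g = Tensor(rng.normal(size=(2, 5, 8)))
        out, alpha = gate(x, g)
        assert np.allclose(alpha.data, 0.5)
        assert np.allclose(out.data, 0.5 * x.data)

    def test_coefficients_strictly_inside_unit_interval(self, rng):
        gate = self._gate()
        out, alpha = gate(Tensor(rng.normal(size=(4, 3, 16)) * 5),
                          Tensor(rng.normal(size=(4, 5, 16)) * 5))
        assert np.all(alpha.data > 0.0) and np.all(alpha.data < 1.0)

    def test_matches_straight_line_recomputation(self, rng):
        """The gate output equals an independent numpy re-evaluation of the
        projection -> ReLU -> psi -> sigmoid -> rescale chain."""
        gate = self._gate()
        x = rng.normal(size=(1, 3, 8))
        g = rng.normal(size=(1, 5, 8))
        out, alpha = gate(Tensor(x), Tensor(g))
        ix = gate.ix.w.data[:, :, 0]          # (F, Cx)
        ig = gate.ig.w.data[:, :, 0]          # (F, Cg)
        bg = gate.ig.b.data
        psi = gate.psi.w.data[0, :, 0]        # (F,)
        bpsi = gate.psi.b.data[0]
        expected = np.empty((1, 3, 8))
        for pos in range(8):
            inter = np.maximum(ix @ x[0, :, pos] + ig @ g[0, :, pos] + bg, 0.0)
            a = 1.0 / (1.0 + np.exp(-(psi @ inter + bpsi)))
            expected[0, :, pos] = x[0, :, pos] * a
        assert np.allclose(out.data, expected)

    def test_half_resolution_gating_is_aligned(self, rng):
        gate = self._gate()
        out, alpha = gate(Tensor(rng.normal(size=(1, 3, 8))),
                          Tensor(rng.normal(size=(1, 5, 4))))
        assert out.shape == (1, 3, 8)

    def test_incompatible_lengths_raise(self, rng):
        with pytest.raises(ValueError):
            self._gate()(Tensor(rng.normal(size=(1, 3, 9))),
                         Tensor(rng.normal(size=(1, 5, 3))))


class TestArchitecture:
    @pytest.mark.parametrize("ned", [3, 4, 5])
    def test_teacher_reconstructs_input_length(self, rng, ned):
        cfg = net.teacher_config(width_scale=0.125, seed=0, ned=ned)
        model = net.TeacherNet(cfg)
        out = net.forward(model, rng.normal(size=(2, 3, 128)))
        assert out.resp.shape == (2, 128)
        assert np.all(np.isfinite(out.rr))

    @pytest.mark.parametrize("ned", [1, 2, 3, 4])
    def test_student_reconstructs_input_length(self, rng, ned):
        cfg = net.student_config(ned=ned, width_scale=0.125, seed=0)
        model = net.StudentNet(cfg)
        out = net.forward(model, rng.normal(size=(2, 3, 128)))
        assert out.resp.shape == (2, 128)
        assert np.all(np.isfinite(out.rr))

    def test_attention_coefficients_bounded_for_any_input(self, tiny_teacher,
                                                          rng):
        # z-normalised input scale: coefficients strictly inside (0, 1)
        out = net.forward(tiny_teacher, rng.normal(size=(2, 3, 128)))
        assert out.attention
        for alpha in out.attention.values():
            assert np.all(alpha > 0) and np.all(alpha < 1)
        # extreme amplification may saturate to the closed bounds in floats
        big = net.forward(tiny_teacher, rng.normal(size=(1, 3, 128)) * 10)
        for alpha in big.attention.values():
            assert np.all(alpha >= 0) and np.all(alpha <= 1)

    def test_wrong_shape_raises(self, tiny_teacher, rng):
        with pytest.raises(ValueError):
            net.forward(tiny_teacher, rng.normal(size=(2, 3, 64)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            net.ArchConfig(ned=0)
        with pytest.raises(ValueError):
            net.ArchConfig(dropout_p=1.0)
        with pytest.raises(ValueError):
            net.ArchConfig(base_filters=0)


class TestForwardDeterminism:
    def test_dropout_disabled_is_deterministic(self, tiny_teacher, rng):
        x = rng.normal(size=(2, 3, 128))
        a = net.forward(tiny_teacher, x)
        b = net.forward(tiny_teacher, x)
        assert np.array_equal(a.resp, b.resp)
        assert np.array_equal(a.rr, b.rr)

    def test_same_seed_reproduces_stochastic_pass(self, tiny_teacher, rng):
        x = rng.normal(size=(2, 3, 128))
        a = net.forward(tiny_teacher, x, mc_dropout=True, rng_seed=42)
        b = net.forward(tiny_teacher, x, mc_dropout=True, rng_seed=42)
        assert np.array_equal(a.resp, b.resp)

    def test_different_seeds_differ(self, tiny_teacher, rng):
        x = rng.normal(size=(1, 3, 128))
        differing = 0
        for s in range(10):
            a = net.forward(tiny_teacher, x, mc_dropout=True, rng_seed=2 * s)
            b = net.forward(tiny_teacher, x, mc_dropout=True,
                            rng_seed=2 * s + 1)
            differing += not np.array_equal(a.rr, b.rr)
        assert differing >= 9


class TestGradientFlow:
    def test_every_parameter_receives_gradient(self, rng):
        """No dead branches: across a few random batches every trainable
        parameter accumulates a nonzero gradient at least once."""
        from respiraflow.nn import core
        model = net.build_teacher(net.teacher_config(width_scale=0.125,
                                                     seed=4))
        touched = {name: False for name, _ in model.parameters()}
        for trial in range(3):
            x = rng.normal(size=(4, 3, 128))
            resp, rr, _, _ = model(Tensor(x), training=True,
                                   rng=np.random.default_rng(trial))
            loss = core.smooth_l1(resp, np.zeros_like(resp.data)) \
                + core.smooth_l1(rr, np.ones_like(rr.data))
            loss.backward()
            for name, p in model.parameters():
                if p.grad is not None and np.any(p.grad != 0):
                    touched[name] = True
            model.zero_grad()
        dead = [n for n, ok in touched.items() if not ok]
        assert not dead, f"parameters with no gradient: {dead[:5]}"


class TestCheckpointing:
    def test_save_load_round_trip(self, tmp_path, rng):
        from respiraflow.nn import core
        from respiraflow.nn.optim import Adam
        cfg = net.student_config(width_scale=0.125, seed=7)
        model = net.build_student(cfg)
        model.rr_norm = {"offset": np.array(25.0), "scale": np.array(9.0)}
        x = rng.normal(size=(1, 3, 128))
        # a few training steps so batch-norm running statistics are non-trivial
        opt = Adam(model.parameters(), lr=1e-3)
        for step in range(2):
            resp, rr, _, _ = model(Tensor(rng.normal(size=(4, 3, 128))),
                                   training=True,
                                   rng=np.random.default_rng(step))
            loss = core.smooth_l1(resp, np.zeros_like(resp.data)) \
                + core.smooth_l1(rr, np.zeros_like(rr.data))
            loss.backward()
            opt.step()
            opt.zero_grad()
        before = net.forward(model, x)
        path = tmp_path / "m.npz"
        net.save_checkpoint(model, path)
        back = net.load_model(path)
        after = net.forward(back, x)
        assert np.array_equal(before.resp, after.resp)
        assert np.array_equal(before.rr, after.rr)
        assert isinstance(back, net.StudentNet)

    def test_summary_reports_total(self, tiny_student):
        text = net.model_summary(tiny_student)
        assert "TOTAL" in text
        assert f"{tiny_student.n_parameters():d}" in text
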